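site_id	label	chrom	pos	ref_allele	alt_allele	consequence	cadd_phred	maf_total	is_eqtl	in_regulatory_element	hgmd_dm	hgmd_mutation_type	gene
rs4547091	c.-301C>T	chr11	89177368	C	T	regulatory	5.9	0.43	1	1	0	none	TYR
rs1042602	c.575C>A	chr11	89178528	C	A	missense	23.4	0.27	0	0	0	none	TYR
rs1126809	c.1205G>A	chr11	89284793	G	A	missense	25.8	0.17	0	0	1	missense_nonsense	TYR
dm_TYR_1	c.1A>G	chr11	89177566	A	G	missense	24.1	0.0002	0	0	1	missense_nonsense	TYR
dm_TYR_2	c.823G>T	chr11	89227850	G	T	nonsense	35.0	0.0001	0	0	1	missense_nonsense	TYR
dm_OCA2_1	c.1327G>A	chr15	27983407	G	A	missense	26.3	0.003	0	0	1	missense_nonsense	OCA2
dm_SLC45A2_1	c.1082C>T	chr5	33944794	C	T	missense	27.4	0.0004	0	0	1	missense_nonsense	SLC45A2
dm_GPR143_1	c.360+1G>A	chrX	9693300	G	A	splicing	25.0	0.0001	0	0	1	splicing	GPR143
dm_HPS1_1	c.1189C>T	chr10	98431927	C	T	missense	28.0	0.0002	0	0	1	missense_nonsense	HPS1
dm_SLC24A5_1	c.591G>A	chr15	48134287	G	A	missense	24.9	0.0003	0	0	1	missense_nonsense	SLC24A5
dm_TYRP1_1	c.1057C>T	chr9	12702539	C	T	missense	25.6	0.0002	0	0	1	missense_nonsense	TYRP1
syn_TYR_1	c.723C>T	chr11	89191579	C	T	synonymous	22.0	0.05	0	0	0	none	TYR
gross_OCA2_1	ex2_del	chr15	27990000	G	A	other	20.0	0.0001	0	0	1	gross_del	OCA2
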