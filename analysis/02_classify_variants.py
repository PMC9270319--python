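"""Apply the three variant-selection rules and assemble the TYR panel.

Classifies the packaged annotation table (common protein-coding,
regulatory, rare Mendelian) and reports which sites form the
common-variant haplotype panel.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parent))

import pandas as pd
from common import ensure_results

from tyrhap.variants import (
    build_tyr_panel,
    classify_common_coding,
    classify_rare_dm,
    classify_regulatory,
    default_sites,
)


def main() -> None:
    results = ensure_results()
    sites = default_sites()
    rows = [
        {
            "site_id": v.site_id,
            "label": v.label,
            "gene": v.gene,
            "cadd_phred": v.cadd_phred,
            "maf_total": v.maf_total,
            "common_coding": int(classify_common_coding(v)),
            "regulatory": int(classify_regulatory(v)),
            "rare_dm": int(classify_rare_dm(v)),
        }
        for v in sites
    ]
    df = pd.DataFrame(rows)
    df.to_csv(results / "variant_classes.tsv", sep="\t", index=False)

    panel = build_tyr_panel(sites)
    print(df.to_string(index=False))
    print("\npanel (promoter first, then coding by position):")
    for v in panel:
        print(f"  {v.site_id}  {v.label}")
    print(f"\nwrote {results / 'variant_classes.tsv'}")


if __name__ == "__main__":
    main()
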