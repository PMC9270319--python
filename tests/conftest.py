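import numpy as np
import pytest

from tyrhap.cohort import GenotypeCall, Subject
from tyrhap.variants import build_tyr_panel, default_sites


@pytest.fixture(scope="session")
def sites():
    return default_sites()


@pytest.fixture(scope="session")
def panel(sites):
    return build_tyr_panel(sites)


def make_call(
    subject_id,
    site_id,
    alleles,
    gq=99,
    depth=40,
    ab=None,
    passed=True,
):
    if ab is None and alleles is not None:
        ab = sum(alleles) / 2.0
    return GenotypeCall(
        subject_id=subject_id,
        site_id=site_id,
        alleles=alleles,
        genotype_quality=gq,
        depth=depth,
        allele_balance=ab if depth else None,
        passed_site_filters=passed,
    )


def make_subject(
    subject_id="S1",
    status="control",
    gender="female",
    ancestry="European",
    panel_genotypes=None,
    panel=None,
    extra_calls=(),
    **kwargs,
):
    s = Subject(subject_id=subject_id, status=status, gender=gender, ancestry=ancestry, **kwargs)
    if panel_genotypes is not None:
        for site, alleles in zip(panel, panel_genotypes):
            s.calls[site.site_id] = make_call(subject_id, site.site_id, alleles)
    for call in extra_calls:
        s.calls[call.site_id] = call
    return s


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240901)
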