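"""Shared study configuration for the analysis drivers.

The simulated cohort stands in for the restricted case-control resources;
it is regenerated deterministically (same seed) by each driver that needs
it, so the scripts can run independently and in any order.
"""

from math import log
from pathlib import Path

from tyrhap.simulate import DEFAULT_PENETRANCE, SimulationConfig

RESULTS = Path(__file__).resolve().parent.parent / "results"

# Main simulated case-control cohort: size on the order of the combined
# study cohorts, mixed ancestries, penetrance shaped like the reported
# associations (see docs/methods.md).
COHORT_CONFIG = SimulationConfig(n_subjects=30_000, seed=7, penetrance=DEFAULT_PENETRANCE)

# Endophenotype cohort: population-style, but with the rarest haplotypes'
# frequencies raised so every homozygous-diplotype group is populated at
# n = 60,000 (at the realistic ~1% [C;A;A] frequency a biobank-scale cohort
# would be needed to fill that group).
_TRAIT_FREQS = {
    "[C;C;G]": 0.27,
    "[T;C;G]": 0.24,
    "[C;A;G]": 0.15,
    "[T;A;G]": 0.09,
    "[C;C;A]": 0.12,
    "[T;C;A]": 0.05,
    "[C;A;A]": 0.05,
    "[T;A;A]": 0.03,
}
TRAIT_COHORT_CONFIG = SimulationConfig(
    n_subjects=60_000,
    seed=11,
    ancestry_mix={"European": 1.0},
    haplotype_freqs={"European": _TRAIT_FREQS},
    penetrance=DEFAULT_PENETRANCE,
)


def ensure_results() -> Path:
    RESULTS.mkdir(exist_ok=True)
    return RESULTS
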