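import numpy as np
import pandas as pd
import pytest

from adnahap.genotype_model import AggregatedCounts
from adnahap.panel_io import AlleleCounts, CohortMetadata, SNPPanel


def make_panel(n: int = 20) -> SNPPanel:
    """Deterministic n-SNP panel; first site is ref G / adaptive A."""
    refs = (["G", "C", "T", "A"] * ((n + 3) // 4))[:n]
    alts = (["A", "T", "C", "G"] * ((n + 3) // 4))[:n]
    return SNPPanel(
        pd.DataFrame(
            {
                "snp_id": [f"snp{i + 1:02d}" for i in range(n)],
                "chrom": "2",
                "pos": 46_550_000 + 1000 * np.arange(n),
                "ref": refs,
                "alt": alts,
                "adaptive": alts,
                "is_transition": [r + a in ("GA", "AG", "CT", "TC") for r, a in zip(refs, alts)],
            }
        )
    )


def agg(r: int, t: int, ind: str = "ind") -> AggregatedCounts:
    return AggregatedCounts(ind, r, t)


def cohort_of(pairs):
    return [AggregatedCounts(f"i{k}", r, t) for k, (r, t) in enumerate(pairs)]


@pytest.fixture
def panel20() -> SNPPanel:
    return make_panel(20)


@pytest.fixture
def panel3() -> SNPPanel:
    return make_panel(3)


@pytest.fixture
def counts_small(panel3) -> AlleleCounts:
    df = pd.DataFrame(
        {
            "individual_id": ["ind1", "ind1", "ind2"],
            "snp_id": ["snp01", "snp02", "snp01"],
            "n_adaptive": [2, 0, 1],
            "n_total": [3, 1, 1],
        }
    )
    return AlleleCounts(df, panel=panel3)


@pytest.fixture
def meta_study_bins() -> CohortMetadata:
    df = pd.DataFrame(
        {
            "individual_id": ["old1", "old2", "mid1", "new1", "gap1", "now1"],
            "date_bp": [5100.0, 2600.0, 1900.0, 800.0, 1750.0, "modern"],
            "group": "g",
            "region": "r",
        }
    )
    return CohortMetadata(df)
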