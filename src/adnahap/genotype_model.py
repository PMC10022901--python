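"""Genotype posteriors for the adaptive haplotype from aggregated read counts.

The panel SNPs are assumed to be in complete linkage: every read overlapping
any panel site carries either the adaptive haplotype allele or the
alternative one, so reads can be pooled across sites into a single pair
(r, t) per individual — r reads supporting the adaptive haplotype out of t
total. Conditional on the diploid genotype G (copies of the adaptive
haplotype), each read supports the adaptive allele with probability

    G = 2 :  1 - eps        (error only)
    G = 1 :  1/2            (either chromosome sampled)
    G = 0 :  eps

where ``eps`` is the per-read error probability combining sequencing error
and post-mortem deamination damage. The likelihood of each genotype is the
binomial probability of r successes in t trials at that rate, and the
posterior is the prior-weighted normalisation of the three likelihoods
(with a flat prior, binomial coefficients cancel and the posterior is the
likelihood triple renormalised).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy.special import logsumexp
from scipy.stats import binom

from .panel_io import AlleleCounts, SNPPanel

__all__ = [
    "ErrorModel",
    "AggregatedCounts",
    "GenotypePosterior",
    "HardCall",
    "NO_CALL",
    "aggregate_counts",
    "aggregate_cohort",
    "genotype_log_likelihoods",
    "genotype_likelihoods",
    "genotype_posterior",
    "hard_call",
    "call_table",
    "epsilon_sweep",
]

FLAT_PRIOR = (1.0 / 3.0, 1.0 / 3.0, 1.0 / 3.0)

#: Sentinel for individuals failing the coverage rule or posterior threshold.
NO_CALL: None = None


@dataclass(frozen=True)
class ErrorModel:
    """Per-read error probability, sequencing error plus aDNA damage."""

    epsilon: float = 0.01

    def __post_init__(self) -> None:
        if not 0.0 <= self.epsilon < 0.5:
            raise ValueError(f"epsilon must be in [0, 0.5), got {self.epsilon}")


@dataclass(frozen=True)
class AggregatedCounts:
    """Reads pooled across all panel SNPs for one individual."""

    individual_id: str
    r: int
    t: int
    per_snp_totals: tuple[int, ...] = field(default=())

    def __post_init__(self) -> None:
        if not 0 <= self.r <= self.t:
            raise ValueError(f"need 0 <= r <= t, got r={self.r}, t={self.t}")
        if self.per_snp_totals and sum(self.per_snp_totals) != self.t:
            raise ValueError("per_snp_totals do not sum to t")


@dataclass(frozen=True)
class GenotypePosterior:
    """Posterior over {2, 1, 0} copies of the adaptive haplotype."""

    individual_id: str
    probs: tuple[float, float, float]  # (P(G=2), P(G=1), P(G=0))

    def __post_init__(self) -> None:
        total = sum(self.probs)
        if not np.isclose(total, 1.0, atol=1e-9):
            raise ValueError(f"posterior does not sum to 1: {self.probs}")

    @property
    def map_genotype(self) -> int:
        """Copies of the adaptive haplotype with maximal posterior."""
        return (2, 1, 0)[int(np.argmax(self.probs))]

    @property
    def max_posterior(self) -> float:
        return float(max(self.probs))


@dataclass(frozen=True)
class HardCall:
    individual_id: str
    call: int | None  # 2, 1, 0 copies, or NO_CALL
    max_posterior: float


def aggregate_counts(
    counts: AlleleCounts, panel: SNPPanel, individual_id: str
) -> AggregatedCounts:
    """Pool reads over all panel SNPs for one individual.

    SNPs with no counts row contribute zero; an individual entirely absent
    from the table yields r = t = 0.
    """
    sub = counts.df[counts.df["individual_id"] == individual_id]
    per_site = dict(zip(sub["snp_id"], sub["n_total"]))
    per_snp_totals = tuple(int(per_site.get(s, 0)) for s in panel.snp_ids)
    return AggregatedCounts(
        individual_id=individual_id,
        r=int(sub["n_adaptive"].sum()),
        t=int(sub["n_total"].sum()),
        per_snp_totals=per_snp_totals,
    )


def aggregate_cohort(
    counts: AlleleCounts, panel: SNPPanel, individual_ids: Sequence[str]
) -> list[AggregatedCounts]:
    return [aggregate_counts(counts, panel, i) for i in individual_ids]


def genotype_log_likelihoods(
    r: int, t: int, error: ErrorModel
) -> np.ndarray:
    """Log binomial likelihoods for genotypes (2, 1, 0) copies.

    Computed in log space so large t does not underflow; eps = 0 is valid
    (0^0 = 1 convention of the binomial pmf).
    """
    if not 0 <= r <= t:
        raise ValueError(f"need 0 <= r <= t, got r={r}, t={t}")
    eps = error.epsilon
    with np.errstate(divide="ignore"):
        return binom.logpmf(r, t, [1.0 - eps, 0.5, eps])


def genotype_likelihoods(r: int, t: int, error: ErrorModel) -> np.ndarray:
    """Binomial likelihoods (B(r,t,1-eps), B(r,t,1/2), B(r,t,eps))."""
    return np.exp(genotype_log_likelihoods(r, t, error))


def genotype_posterior(
    agg: AggregatedCounts,
    error: ErrorModel,
    prior: Sequence[float] = FLAT_PRIOR,
) -> GenotypePosterior:
    """Posterior over genotypes; flat prior by default.

    The prior need not be normalised (the posterior is invariant to positive
    rescaling) but must be non-negative with a positive sum.
    """
    prior_arr = np.asarray(prior, dtype=float)
    if prior_arr.shape != (3,):
        raise ValueError("prior must have three entries (G=2, G=1, G=0)")
    if (prior_arr < 0).any() or prior_arr.sum() <= 0:
        raise ValueError(f"prior must be non-negative with positive sum: {prior}")
    with np.errstate(divide="ignore"):
        log_post = np.log(prior_arr) + genotype_log_likelihoods(agg.r, agg.t, error)
    log_post -= logsumexp(log_post)
    probs = np.exp(log_post)
    probs /= probs.sum()
    return GenotypePosterior(agg.individual_id, tuple(float(x) for x in probs))


def hard_call(
    posterior: GenotypePosterior,
    agg: AggregatedCounts,
    min_reads_per_site: int = 4,
    mode: Literal["per-site", "total"] = "per-site",
    call_threshold: float = 0.0,
) -> HardCall:
    """MAP genotype call gated by a coverage rule.

    ``per-site`` mode requires every panel SNP to carry at least
    ``min_reads_per_site`` reads (the literal reading of requiring four
    reads available at each position); ``total`` mode requires only the
    pooled total t to reach the threshold, which is far more permissive at
    typical aDNA coverage. Below ``call_threshold`` on the maximal posterior
    the individual is left uncalled.
    """
    if posterior.individual_id != agg.individual_id:
        raise ValueError("posterior and counts refer to different individuals")
    if mode == "per-site":
        totals = agg.per_snp_totals if agg.per_snp_totals else (agg.t,)
        passes = all(x >= min_reads_per_site for x in totals)
    elif mode == "total":
        passes = agg.t >= min_reads_per_site
    else:
        raise ValueError(f"unknown coverage mode {mode!r}")
    if not passes or posterior.max_posterior < call_threshold:
        return HardCall(posterior.individual_id, NO_CALL, posterior.max_posterior)
    return HardCall(
        posterior.individual_id, posterior.map_genotype, posterior.max_posterior
    )


def call_table(
    counts: AlleleCounts,
    panel: SNPPanel,
    individual_ids: Sequence[str],
    error: ErrorModel,
    min_reads_per_site: int = 4,
    mode: Literal["per-site", "total"] = "per-site",
    call_threshold: float = 0.0,
) -> pd.DataFrame:
    """Posterior/call table: one row per individual.

    Columns: individual_id, p2, p1, p0, call ("2"/"1"/"0"/"nocall"), r, t.
    """
    rows = []
    for ind in individual_ids:
        agg = aggregate_counts(counts, panel, ind)
        post = genotype_posterior(agg, error)
        call = hard_call(post, agg, min_reads_per_site, mode, call_threshold)
        rows.append(
            {
                "individual_id": ind,
                "p2": post.probs[0],
                "p1": post.probs[1],
                "p0": post.probs[2],
                "call": "nocall" if call.call is NO_CALL else str(call.call),
                "r": agg.r,
                "t": agg.t,
            }
        )
    return pd.DataFrame(rows, columns=["individual_id", "p2", "p1", "p0", "call", "r", "t"])


def epsilon_sweep(
    agg: AggregatedCounts, epsilons: Sequence[float]
) -> pd.DataFrame:
    """Posterior sensitivity to the assumed error rate.

    One row per epsilon with the posterior triple — a quick check that a
    call is robust across plausible aDNA error rates (the default grid in
    the command-line tool spans 0.001–0.05).
    """
    rows = []
    for eps in epsilons:
        post = genotype_posterior(agg, ErrorModel(eps))
        rows.append({"epsilon": eps, "p2": post.probs[0], "p1": post.probs[1], "p0": post.probs[2]})
    return pd.DataFrame(rows)
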