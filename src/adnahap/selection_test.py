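"""Empirical selection test against a genome-wide background.

The focal haplotype's observed frequency change between two time bins is
compared with the changes shown by background SNPs sampled across the
genome, estimated by the same HWE-mixture maximum-likelihood machinery on
the same individuals. Under neutrality the focal locus is exchangeable with
the background, so the one-sided add-one empirical p-value

    p = (1 + #{background change >= focal change}) / (1 + M)

is (sub-)uniform; a small p indicates a rise too steep for drift alone.
Background SNPs may optionally be retained only when their older-bin
frequency estimate is close to the focal one ("frequency matching"), since
the expected drift magnitude depends on the starting frequency.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .genotype_model import ErrorModel
from .frequency_model import batch_mle

__all__ = [
    "BackgroundCounts",
    "NullDistribution",
    "background_from_tables",
    "null_distribution",
    "empirical_pvalue",
    "calibrate_test",
]


@dataclass(frozen=True)
class BackgroundCounts:
    """Aggregated read counts for background SNPs, aligned to the focal bins.

    ``r`` and ``t`` are (M, B, N_max) arrays over SNPs, bins and
    individuals; bins smaller than N_max are zero-padded (zero coverage
    contributes nothing to the likelihood, so padding is inert).
    """

    snp_ids: tuple[str, ...]
    bin_labels: tuple[str, ...]
    bin_sizes: tuple[int, ...]
    r: np.ndarray
    t: np.ndarray

    def __post_init__(self) -> None:
        if self.r.shape != self.t.shape:
            raise ValueError("r and t shapes differ")
        if self.r.ndim != 3:
            raise ValueError("expected (M, B, N) count arrays")
        if self.r.shape[0] != len(self.snp_ids):
            raise ValueError("snp_ids length does not match count arrays")
        if self.r.shape[1] != len(self.bin_labels):
            raise ValueError("bin_labels length does not match count arrays")
        if (self.r < 0).any() or (self.r > self.t).any():
            raise ValueError("need 0 <= r <= t everywhere")

    @property
    def n_snps(self) -> int:
        return len(self.snp_ids)

    def bin_index(self, label: str) -> int:
        try:
            return self.bin_labels.index(label)
        except ValueError:
            raise KeyError(label) from None

    def to_frame(self) -> pd.DataFrame:
        """Long-format counts table (only rows with coverage)."""
        rows = []
        for si, snp in enumerate(self.snp_ids):
            for bi, label in enumerate(self.bin_labels):
                for j in range(self.bin_sizes[bi]):
                    tt = int(self.t[si, bi, j])
                    if tt == 0:
                        continue
                    rows.append(
                        {
                            "snp_id": snp,
                            "bin": label,
                            "individual_id": f"{label}_ind{j + 1:03d}",
                            "n_adaptive": int(self.r[si, bi, j]),
                            "n_total": tt,
                        }
                    )
        return pd.DataFrame(
            rows, columns=["snp_id", "bin", "individual_id", "n_adaptive", "n_total"]
        )


def background_from_tables(
    counts: pd.DataFrame, membership: dict[str, Sequence[str]]
) -> BackgroundCounts:
    """Build :class:`BackgroundCounts` from a long counts table.

    ``counts`` needs columns snp_id, individual_id, n_adaptive, n_total;
    ``membership`` maps bin label -> individual ids (the same rosters as
    the focal analysis). Missing (snp, individual) rows are zero coverage.
    """
    required = {"snp_id", "individual_id", "n_adaptive", "n_total"}
    missing = required - set(counts.columns)
    if missing:
        raise ValueError(f"background counts table missing columns: {missing}")
    snp_ids = tuple(pd.unique(counts["snp_id"]).astype(str))
    bin_labels = tuple(membership.keys())
    bin_sizes = tuple(len(v) for v in membership.values())
    n_max = max(bin_sizes, default=0)
    m = len(snp_ids)
    r = np.zeros((m, len(bin_labels), n_max), dtype=np.int64)
    t = np.zeros_like(r)
    snp_pos = {s: i for i, s in enumerate(snp_ids)}
    ind_pos: dict[str, tuple[int, int]] = {}
    for bi, ids in enumerate(membership.values()):
        for j, ind in enumerate(ids):
            ind_pos[str(ind)] = (bi, j)
    for row in counts.itertuples(index=False):
        loc = ind_pos.get(str(row.individual_id))
        if loc is None:
            continue  # individual outside every bin
        bi, j = loc
        si = snp_pos[str(row.snp_id)]
        r[si, bi, j] = int(row.n_adaptive)
        t[si, bi, j] = int(row.n_total)
    return BackgroundCounts(snp_ids, bin_labels, bin_sizes, r, t)


@dataclass(frozen=True)
class NullDistribution:
    """Per-background-SNP frequency-change statistics."""

    values: np.ndarray
    statistic: str
    n_dropped_degenerate: int = 0
    n_dropped_matching: int = 0

    def __post_init__(self) -> None:
        if len(self.values) < 1:
            raise ValueError("null distribution is empty")
        if not np.isfinite(self.values).all():
            raise ValueError("null distribution contains non-finite values")

    @property
    def count(self) -> int:
        return len(self.values)


def null_distribution(
    background: BackgroundCounts,
    bins: tuple[str, str],
    error: ErrorModel,
    matching: str = "none",
    tolerance: float = 0.05,
    focal_older_p: float | None = None,
) -> NullDistribution:
    """Older-to-newer ML frequency change for every usable background SNP.

    SNPs with an all-zero-coverage bin give no estimate there; they are
    dropped and counted (keeping them as zero change would bias the null
    toward no change). With ``matching='frequency-matched'`` only SNPs
    whose older-bin estimate lies within ``tolerance`` of
    ``focal_older_p`` are retained.
    """
    older, newer = bins
    oi, ni = background.bin_index(older), background.bin_index(newer)
    p_old = batch_mle(background.r[:, oi, :], background.t[:, oi, :], error)
    p_new = batch_mle(background.r[:, ni, :], background.t[:, ni, :], error)
    usable = np.isfinite(p_old) & np.isfinite(p_new)
    n_degenerate = int((~usable).sum())
    p_old, p_new = p_old[usable], p_new[usable]
    n_matching = 0
    if matching == "frequency-matched":
        if focal_older_p is None:
            raise ValueError("frequency matching needs focal_older_p")
        keep = np.abs(p_old - focal_older_p) <= tolerance
        n_matching = int((~keep).sum())
        p_old, p_new = p_old[keep], p_new[keep]
    elif matching != "none":
        raise ValueError(f"unknown matching mode {matching!r}")
    if len(p_old) == 0:
        raise ValueError(
            "no background SNPs survive filtering; "
            "increase the matching tolerance or supply more SNPs"
        )
    return NullDistribution(
        values=p_new - p_old,
        statistic=f"ml_frequency_change[{older}->{newer}]",
        n_dropped_degenerate=n_degenerate,
        n_dropped_matching=n_matching,
    )


def empirical_pvalue(focal_change: float, null: NullDistribution) -> float:
    """One-sided (increase) add-one empirical p-value, always in (0, 1]."""
    exceed = int(np.sum(null.values >= focal_change))
    return (1 + exceed) / (1 + null.count)


def calibrate_test(
    config,
    replicates: int = 1000,
    seed: int = 0,
    alpha: float = 0.05,
    bins: tuple[str, str] | None = None,
) -> dict:
    """Type-I error of the test under a drift-only null.

    Per replicate, ``config.background.n_snps`` background SNPs plus one
    focal SNP are drawn from the same neutral Wright–Fisher process (the
    focal SNP is exchangeable with the background); the achieved rejection
    rate at ``alpha`` is returned with its binomial standard error.
    """
    import dataclasses as _dc
    import warnings

    from .synthetic_data import simulate_neutral_background

    if replicates < 100:
        warnings.warn(
            f"only {replicates} replicates; the achieved rate is noisy",
            stacklevel=2,
        )
    if bins is None:
        labels = [b.label for b in config.bins]
        bins = (labels[0], labels[-1])
    error = ErrorModel(config.epsilon_true)
    bg_plus_focal = _dc.replace(
        config.background, n_snps=config.background.n_snps + 1
    )
    rejections = 0
    used = 0
    seeds = np.random.SeedSequence(seed).generate_state(replicates) % (2**31)
    for rep in range(replicates):
        rep_config = _dc.replace(
            config, seed=int(seeds[rep]), background=bg_plus_focal
        )
        background, _truth = simulate_neutral_background(rep_config)
        oi = background.bin_index(bins[0])
        ni = background.bin_index(bins[1])
        p_all_old = batch_mle(background.r[:, oi, :], background.t[:, oi, :], error)
        p_all_new = batch_mle(background.r[:, ni, :], background.t[:, ni, :], error)
        focal_old, focal_new = p_all_old[0], p_all_new[0]
        if not (np.isfinite(focal_old) and np.isfinite(focal_new)):
            continue  # focal locus unobserved: no test possible
        changes = p_all_new[1:] - p_all_old[1:]
        ok = np.isfinite(changes)
        if not ok.any():
            continue
        null = NullDistribution(changes[ok], "ml_frequency_change")
        p = empirical_pvalue(float(focal_new - focal_old), null)
        used += 1
        if p <= alpha:
            rejections += 1
    rate = rejections / used if used else float("nan")
    se = float(np.sqrt(rate * (1 - rate) / used)) if used else float("nan")
    return {
        "alpha": alpha,
        "achieved_rate": rate,
        "standard_error": se,
        "replicates_used": used,
        "replicates_requested": replicates,
    }
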