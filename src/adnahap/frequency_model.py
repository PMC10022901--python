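"""Maximum-likelihood haplotype-frequency estimation from pooled read counts.

Each individual i contributes a pair (r_i, t_i) of adaptive-supporting and
total reads pooled over the panel. Under Hardy–Weinberg equilibrium at
frequency p, the log-likelihood is the genotype mixture

    l(p) = sum_i log[ p^2 B(r_i, t_i, 1-eps)
                      + 2 p (1-p) B(r_i, t_i, 1/2)
                      + (1-p)^2 B(r_i, t_i, eps) ]

with B the binomial pmf. Individuals with t_i = 0 contribute log 1 = 0 and
never move the estimate. The mixture is not guaranteed unimodal in p, so the
MLE is found by a dense grid (step 1e-4) followed by golden-section
refinement in the best bracket, tie-breaking to the smallest p.

Confidence intervals are profile-likelihood by default: the set of p with
2[l(p_hat) - l(p)] below the chi-square(1 df) quantile, located by bisection
on each side of the MLE. A percentile bootstrap over individuals is provided
as an alternative since profile calibration is an asymptotic argument.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
from scipy.stats import binom, chi2

from .genotype_model import AggregatedCounts, ErrorModel

__all__ = [
    "FrequencyEstimate",
    "loglik",
    "mle_frequency",
    "ci_frequency",
    "log_mixture_components",
    "loglik_from_components",
    "batch_mle",
]

GRID_STEP = 1e-4
GOLDEN_TOL = 1e-9
BISECT_TOL = 1e-6
_INVPHI = (math.sqrt(5.0) - 1.0) / 2.0


@dataclass(frozen=True)
class FrequencyEstimate:
    """MLE of the adaptive-haplotype frequency with an interval estimate."""

    p_hat: float
    ci_low: float
    ci_high: float
    level: float
    n: int
    loglik_at_mle: float
    method: str = "profile"
    epsilon: float = 0.01
    degenerate: bool = False  # no individual carried any reads

    def __post_init__(self) -> None:
        if not (0.0 <= self.ci_low <= self.ci_high <= 1.0):
            raise ValueError(f"invalid CI [{self.ci_low}, {self.ci_high}]")
        if not self.ci_low - 1e-12 <= self.p_hat <= self.ci_high + 1e-12:
            raise ValueError("p_hat outside its own CI")


def log_mixture_components(
    cohort: Sequence[AggregatedCounts] | np.ndarray, error: ErrorModel
) -> np.ndarray:
    """Per-individual log binomial pmfs, shape (N, 3).

    Columns are log B(r, t, 1-eps), log B(r, t, 1/2), log B(r, t, eps) —
    the genotype-conditional read likelihoods for 2, 1 and 0 copies.
    ``cohort`` may be a sequence of :class:`AggregatedCounts` or an (N, 2)
    integer array of (r, t) rows.
    """
    if isinstance(cohort, np.ndarray):
        rt = np.asarray(cohort, dtype=np.int64)
        r, t = rt[:, 0], rt[:, 1]
    else:
        r = np.array([c.r for c in cohort], dtype=np.int64)
        t = np.array([c.t for c in cohort], dtype=np.int64)
    if r.size == 0:
        raise ValueError("cohort is empty")
    if (r < 0).any() or (r > t).any():
        raise ValueError("need 0 <= r <= t for every individual")
    eps = error.epsilon
    with np.errstate(divide="ignore"):
        out = np.stack(
            [
                binom.logpmf(r, t, 1.0 - eps),
                binom.logpmf(r, t, 0.5),
                binom.logpmf(r, t, eps),
            ],
            axis=-1,
        )
    return out


def _hwe_log_weights(p: np.ndarray) -> np.ndarray:
    """log of (p^2, 2p(1-p), (1-p)^2), shape p.shape + (3,)."""
    p = np.asarray(p, dtype=float)
    with np.errstate(divide="ignore"):
        return np.stack(
            [2.0 * np.log(p), np.log(2.0) + np.log(p) + np.log1p(-p), 2.0 * np.log1p(-p)],
            axis=-1,
        )


def loglik_from_components(p, log_b: np.ndarray) -> np.ndarray | float:
    """Evaluate l(p) from precomputed per-individual components.

    ``p`` may be a scalar or a 1-d grid; ``log_b`` has shape (N, 3). The
    per-individual mixture is computed with a max-shift so that arbitrarily
    deep coverage stays finite.
    """
    p_arr = np.atleast_1d(np.asarray(p, dtype=float))
    if (p_arr < 0).any() or (p_arr > 1).any():
        raise ValueError("p must lie in [0, 1]")
    shift = log_b.max(axis=1, keepdims=True)  # (N, 1)
    b = np.exp(log_b - shift)  # (N, 3), max entry 1
    w = np.exp(_hwe_log_weights(p_arr))  # (G, 3)
    mix = b @ w.T  # (N, G)
    with np.errstate(divide="ignore"):
        ll = np.log(mix) + shift
    total = ll.sum(axis=0)
    if np.isscalar(p) or np.asarray(p).ndim == 0:
        return float(total[0])
    return total


def loglik(
    p, cohort: Sequence[AggregatedCounts], error: ErrorModel
) -> np.ndarray | float:
    """HWE-mixture log-likelihood of frequency ``p`` for a cohort.

    Returns -inf where some individual's mixture term is exactly zero
    (e.g. p = 1 with eps = 0 and an individual whose reads all contradict
    the adaptive haplotype).
    """
    return loglik_from_components(p, log_mixture_components(cohort, error))


def _golden_section(f, lo: float, hi: float, tol: float = GOLDEN_TOL) -> float:
    """Maximise a unimodal-in-bracket function; ties resolve leftward."""
    a, b = lo, hi
    c = b - _INVPHI * (b - a)
    d = a + _INVPHI * (b - a)
    fc, fd = f(c), f(d)
    while b - a > tol:
        if fc >= fd:
            b, d, fd = d, c, fc
            c = b - _INVPHI * (b - a)
            fc = f(c)
        else:
            a, c, fc = c, d, fd
            d = a + _INVPHI * (b - a)
            fd = f(d)
    return 0.5 * (a + b)


def mle_frequency(
    cohort: Sequence[AggregatedCounts],
    error: ErrorModel,
    grid_step: float = GRID_STEP,
) -> FrequencyEstimate:
    """Maximum-likelihood frequency via dense grid plus golden-section.

    An all-zero-coverage cohort has a flat likelihood: the estimate is
    returned as 0.5 with ``degenerate=True`` and the trivial CI [0, 1].
    """
    if len(cohort) == 0:
        raise ValueError("cohort is empty")
    n = len(cohort)
    if all(c.t == 0 for c in cohort):
        return FrequencyEstimate(
            p_hat=0.5, ci_low=0.0, ci_high=1.0, level=0.95, n=n,
            loglik_at_mle=0.0, epsilon=error.epsilon, degenerate=True,
        )
    log_b = log_mixture_components(cohort, error)
    grid = np.arange(0.0, 1.0 + grid_step / 2, grid_step)
    grid[-1] = 1.0
    values = loglik_from_components(grid, log_b)
    k = int(np.argmax(values))  # first max -> smallest-p tie-break
    lo = grid[max(k - 1, 0)]
    hi = grid[min(k + 1, len(grid) - 1)]
    p_hat = _golden_section(lambda p: loglik_from_components(p, log_b), lo, hi)
    # keep the grid point if refinement did not actually improve
    if loglik_from_components(p_hat, log_b) < values[k]:
        p_hat = float(grid[k])
    ll = float(loglik_from_components(p_hat, log_b))
    return FrequencyEstimate(
        p_hat=float(p_hat), ci_low=0.0, ci_high=1.0, level=0.95, n=n,
        loglik_at_mle=ll, epsilon=error.epsilon,
    )


def _profile_bound(f, target: float, inside: float, outside: float) -> float:
    """Bisect for the p where l crosses ``target`` between inside/outside."""
    if f(outside) >= target:
        return outside
    lo, hi = inside, outside  # f(lo) >= target > f(hi)
    while abs(hi - lo) > BISECT_TOL:
        mid = 0.5 * (lo + hi)
        if f(mid) >= target:
            lo = mid
        else:
            hi = mid
    return lo


def ci_frequency(
    cohort: Sequence[AggregatedCounts],
    error: ErrorModel,
    level: float = 0.95,
    method: str = "profile",
    n_boot: int = 2000,
    seed: int | None = None,
) -> FrequencyEstimate:
    """Frequency estimate with a confidence interval.

    ``method='profile'`` inverts the likelihood-ratio statistic against the
    chi-square(1) quantile; ``method='bootstrap'`` is a seeded percentile
    bootstrap over individuals (the MLE recomputed per resample).
    """
    if not 0.0 < level < 1.0:
        raise ValueError(f"level must be in (0, 1), got {level}")
    est = mle_frequency(cohort, error)
    if est.degenerate:
        return replace(est, level=level, method=method)
    if method == "profile":
        log_b = log_mixture_components(cohort, error)
        f = lambda p: loglik_from_components(p, log_b)  # noqa: E731
        target = est.loglik_at_mle - 0.5 * chi2.ppf(level, df=1)
        lo = _profile_bound(f, target, est.p_hat, 0.0)
        hi = _profile_bound(f, target, est.p_hat, 1.0)
        return replace(est, ci_low=float(min(lo, est.p_hat)),
                       ci_high=float(max(hi, est.p_hat)), level=level,
                       method="profile")
    if method == "bootstrap":
        rng = np.random.default_rng(seed)
        rt = np.array([(c.r, c.t) for c in cohort], dtype=np.int64)
        stats = np.empty(n_boot)
        for i in range(n_boot):
            idx = rng.integers(0, len(cohort), size=len(cohort))
            log_b = log_mixture_components(rt[idx], error)
            stats[i] = _batch_argmax(log_b[None, :, :])[0]
        alpha = 1.0 - level
        lo, hi = np.quantile(stats, [alpha / 2, 1.0 - alpha / 2])
        return replace(est, ci_low=float(min(lo, est.p_hat)),
                       ci_high=float(max(hi, est.p_hat)), level=level,
                       method="bootstrap")
    raise ValueError(f"unknown CI method {method!r}")


# ---------------------------------------------------------------------------
# vectorised batch path (selection test, bootstrap)


def _grid_loglik_batch(log_b: np.ndarray, grid: np.ndarray) -> np.ndarray:
    """l(p) over a grid for many cohorts at once.

    ``log_b``: (M, N, 3) per-cohort, per-individual components;
    returns (M, G).
    """
    m, n, _ = log_b.shape
    shift = log_b.max(axis=2, keepdims=True)
    b = np.exp(log_b - shift).reshape(m * n, 3)
    w = np.exp(_hwe_log_weights(grid))  # (G, 3)
    mix = b @ w.T  # (M*N, G)
    with np.errstate(divide="ignore"):
        ll = np.log(mix).reshape(m, n, -1) + shift
    return ll.sum(axis=1)


def _batch_argmax(
    log_b: np.ndarray, coarse_step: float = 4e-3, fine_step: float = 1e-5
) -> np.ndarray:
    """Grid-zoom argmax of l(p) for many cohorts; accuracy ~``fine_step``.

    One shared coarse grid, then per-cohort local windows refined in two
    further zoom stages (each window spans the previous step).
    """
    shift = log_b.max(axis=2, keepdims=True)
    b = np.exp(log_b - shift)  # (M, N, 3)
    coarse = np.arange(0.0, 1.0 + coarse_step / 2, coarse_step)
    coarse[-1] = 1.0
    k = np.argmax(_grid_loglik_batch(log_b, coarse), axis=1)
    p0 = coarse[k]
    steps = [s for s in (coarse_step / 40, fine_step) if s < coarse_step]
    prev_step = coarse_step
    for step in steps:
        offsets = np.arange(-prev_step, prev_step + step / 2, step)
        local = np.clip(p0[:, None] + offsets[None, :], 0.0, 1.0)  # (M, G)
        w = np.exp(_hwe_log_weights(local))  # (M, G, 3)
        mix = np.einsum("mnk,mgk->mng", b, w)
        with np.errstate(divide="ignore"):
            ll = (np.log(mix) + shift).sum(axis=1)  # (M, G)
        p0 = local[np.arange(local.shape[0]), np.argmax(ll, axis=1)]
        prev_step = step
    return p0


def batch_mle(
    r: np.ndarray, t: np.ndarray, error: ErrorModel,
    coarse_step: float = 4e-3, fine_step: float = 1e-5,
) -> np.ndarray:
    """MLE frequencies for many cohorts sharing a layout.

    ``r`` and ``t`` are (M, N) integer arrays: M independent cohorts
    (e.g. background SNPs) of N individuals each. Rows with all t = 0 are
    degenerate and returned as NaN; callers decide how to report them.
    Agrees with :func:`mle_frequency` to within ``fine_step`` (bound by a
    dedicated equivalence test).
    """
    r = np.asarray(r, dtype=np.int64)
    t = np.asarray(t, dtype=np.int64)
    if r.shape != t.shape or r.ndim != 2:
        raise ValueError("r and t must be equal-shape (M, N) arrays")
    if (r < 0).any() or (r > t).any():
        raise ValueError("need 0 <= r <= t everywhere")
    eps = error.epsilon
    with np.errstate(divide="ignore"):
        log_b = np.stack(
            [
                binom.logpmf(r, t, 1.0 - eps),
                binom.logpmf(r, t, 0.5),
                binom.logpmf(r, t, eps),
            ],
            axis=-1,
        )  # (M, N, 3)
    p_hat = _batch_argmax(log_b, coarse_step, fine_step)
    p_hat[(t == 0).all(axis=1)] = np.nan
    return p_hat
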