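import math

import numpy as np
import pytest
from scipy.stats import chi2

from adnahap.genotype_model import AggregatedCounts, ErrorModel
from adnahap.frequency_model import (
    batch_mle,
    ci_frequency,
    loglik,
    mle_frequency,
)

from conftest import cohort_of


# ---------------------------------------------------------------------------
# independent oracle: plain-math likelihood and dense-grid maximiser


def oracle_loglik(p, pairs, eps):
    total = 0.0
    for r, t in pairs:
        b2 = math.comb(t, r) * (1 - eps) ** r * eps ** (t - r)
        b1 = math.comb(t, r) * 0.5**t
        b0 = math.comb(t, r) * eps**r * (1 - eps) ** (t - r)
        term = p**2 * b2 + 2 * p * (1 - p) * b1 + (1 - p) ** 2 * b0
        if term == 0.0:
            return -math.inf
        total += math.log(term)
    return total


def oracle_grid(pairs, eps, step=1e-5):
    grid = np.arange(0.0, 1.0 + step / 2, step)
    grid[-1] = 1.0
    values = np.array([oracle_loglik(p, pairs, eps) for p in grid])
    k = int(np.argmax(values))
    return grid, values, grid[k]


def oracle_ci(pairs, eps, level=0.95, step=1e-5):
    grid, values, p_hat = oracle_grid(pairs, eps, step)
    target = values.max() - 0.5 * chi2.ppf(level, df=1)
    inside = values >= target
    return grid[inside][0], grid[inside][-1]


class TestLoglik:
    def test_single_supporting_read_is_log_p(self):
        cohort = cohort_of([(1, 1)])
        err = ErrorModel(0.0)
        for p in (0.1, 0.33, 0.9):
            assert loglik(p, cohort, err) == pytest.approx(math.log(p), abs=1e-12)

    def test_single_opposing_read_is_log_1mp(self):
        cohort = cohort_of([(0, 1)])
        err = ErrorModel(0.0)
        for p in (0.1, 0.5, 0.77):
            assert loglik(p, cohort, err) == pytest.approx(math.log(1 - p), abs=1e-12)

    def test_mixed_cohort_matches_direct_summation(self):
        pairs = [(3, 4), (0, 5), (2, 2)]
        got = loglik(0.4, cohort_of(pairs), ErrorModel(0.01))
        assert got == pytest.approx(oracle_loglik(0.4, pairs, 0.01), abs=1e-10)

    def test_zero_coverage_contributes_nothing(self):
        pairs = [(3, 4), (2, 2)]
        err = ErrorModel(0.01)
        with_zero = cohort_of(pairs + [(0, 0)])
        without = cohort_of(pairs)
        assert loglik(0.37, with_zero, err) == pytest.approx(
            loglik(0.37, without, err), abs=1e-12
        )

    def test_out_of_domain_p_rejected(self):
        with pytest.raises(ValueError):
            loglik(1.5, cohort_of([(1, 1)]), ErrorModel(0.01))


class TestMLE:
    def test_analytic_extremes(self):
        err = ErrorModel(0.0)
        assert mle_frequency(cohort_of([(1, 1)]), err).p_hat == pytest.approx(1.0, abs=1e-6)
        assert mle_frequency(cohort_of([(0, 1)]), err).p_hat == pytest.approx(0.0, abs=1e-6)
        assert mle_frequency(cohort_of([(1, 1), (0, 1)]), err).p_hat == pytest.approx(
            0.5, abs=1e-6
        )

    def test_derived_cohort_matches_grid_oracle(self):
        pairs = [(3, 4), (0, 5), (2, 2)]
        est = mle_frequency(cohort_of(pairs), ErrorModel(0.01))
        _, _, p_oracle = oracle_grid(pairs, 0.01)
        assert est.p_hat == pytest.approx(p_oracle, abs=2e-4)

    def test_monotone_in_r_single_individual(self):
        err = ErrorModel(0.01)
        for t in range(1, 7):
            p_hats = [mle_frequency(cohort_of([(r, t)]), err).p_hat for r in range(t + 1)]
            assert np.all(np.diff(p_hats) >= 0)

    def test_degenerate_cohort_flagged(self):
        est = mle_frequency(cohort_of([(0, 0), (0, 0)]), ErrorModel(0.01))
        assert est.degenerate and est.p_hat == 0.5
        assert (est.ci_low, est.ci_high) == (0.0, 1.0)

    def test_random_cohorts_match_oracle(self):
        rng = np.random.default_rng(99)
        err = ErrorModel(0.01)
        for _ in range(25):
            n = int(rng.integers(1, 15))
            pairs = []
            for _ in range(n):
                t = int(rng.integers(0, 9))
                pairs.append((int(rng.integers(0, t + 1)), t))
            if all(t == 0 for _, t in pairs):
                continue
            est = mle_frequency(cohort_of(pairs), err)
            _, _, p_oracle = oracle_grid(pairs, 0.01)
            assert est.p_hat == pytest.approx(p_oracle, abs=2e-4)

    def test_high_coverage_matches_map_dosage(self):
        rng = np.random.default_rng(11)
        err = ErrorModel(0.0)
        g = rng.binomial(2, 0.42, size=60)
        t = rng.poisson(45, size=60) + 30
        r = np.where(g == 2, t, np.where(g == 1, rng.binomial(t, 0.5), 0))
        cohort = cohort_of(list(zip(r.tolist(), t.tolist())))
        # with eps = 0 and t >= 30, the MAP genotype is 2 iff all reads
        # support, 0 iff none do, else 1
        dosage = sum(
            2 if ri == ti else (0 if ri == 0 else 1)
            for ri, ti in zip(r.tolist(), t.tolist())
        )
        est = mle_frequency(cohort, err)
        assert abs(est.p_hat - dosage / (2 * len(cohort))) <= 0.01


class TestProfileCI:
    def test_flat_likelihood_gives_unit_interval(self):
        est = ci_frequency(cohort_of([(0, 0)] * 4), ErrorModel(0.01))
        assert (est.ci_low, est.ci_high) == (0.0, 1.0)

    def test_single_read_closed_form(self):
        # l(p) = log p: 2[l(1) - l(p)] <= q  <=>  p >= exp(-q/2)
        est = ci_frequency(cohort_of([(1, 1)]), ErrorModel(0.0), level=0.95)
        lower = math.exp(-0.5 * chi2.ppf(0.95, df=1))
        assert est.ci_low == pytest.approx(lower, abs=1e-5)
        assert est.ci_high == pytest.approx(1.0, abs=1e-9)

    def test_derived_cohort_matches_grid_inversion(self):
        pairs = [(3, 4), (0, 5), (2, 2)]
        est = ci_frequency(cohort_of(pairs), ErrorModel(0.01))
        lo, hi = oracle_ci(pairs, 0.01)
        assert est.ci_low == pytest.approx(lo, abs=2e-4)
        assert est.ci_high == pytest.approx(hi, abs=2e-4)

    def test_zero_coverage_individual_changes_nothing(self):
        pairs = [(2, 3), (1, 4), (0, 2)]
        err = ErrorModel(0.02)
        a = ci_frequency(cohort_of(pairs), err)
        b = ci_frequency(cohort_of(pairs + [(0, 0)]), err)
        assert a.p_hat == pytest.approx(b.p_hat, abs=1e-9)
        assert a.ci_low == pytest.approx(b.ci_low, abs=1e-6)
        assert a.ci_high == pytest.approx(b.ci_high, abs=1e-6)

    def test_bootstrap_method_runs_and_brackets_mle(self):
        pairs = [(2, 3), (1, 4), (0, 2), (3, 3), (1, 1), (0, 1)]
        est = ci_frequency(
            cohort_of(pairs), ErrorModel(0.01), method="bootstrap", n_boot=200, seed=5
        )
        assert est.method == "bootstrap"
        assert est.ci_low <= est.p_hat <= est.ci_high

    def test_invalid_level_rejected(self):
        with pytest.raises(ValueError):
            ci_frequency(cohort_of([(1, 1)]), ErrorModel(0.0), level=1.5)


class TestBatchMLE:
    def test_agrees_with_scalar_path(self):
        rng = np.random.default_rng(3)
        t = rng.poisson(1.5, size=(40, 20))
        r = rng.binomial(t, 0.4)
        p_batch = batch_mle(r, t, ErrorModel(0.01))
        for i in range(40):
            cohort = cohort_of(list(zip(r[i].tolist(), t[i].tolist())))
            if all(c.t == 0 for c in cohort):
                assert np.isnan(p_batch[i])
                continue
            scalar = mle_frequency(cohort, ErrorModel(0.01)).p_hat
            assert p_batch[i] == pytest.approx(scalar, abs=2e-4)

    def test_degenerate_rows_are_nan(self):
        r = np.zeros((2, 3), dtype=int)
        t = np.array([[0, 0, 0], [1, 0, 0]])
        p = batch_mle(r, t, ErrorModel(0.0))
        assert np.isnan(p[0]) and p[1] == pytest.approx(0.0, abs=1e-4)
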