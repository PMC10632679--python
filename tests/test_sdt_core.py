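import math

import numpy as np
import pytest
from scipy.stats import norm

from conftest import make_observer, session_frame
from oracles import auroc2_reference, hdi_bruteforce
from metacog.preprocess import ConfidenceCounts, preprocess_trials
from metacog.sdt_core import (fit_meta_d, fit_type1, hdi, match_t2_criteria,
                              type2_loglik, type2_roc)


def counts_from_type1(h, m, fa, cr, n_bins=2):
    """Counts with the type-1 marginals split evenly across bins."""
    def spread(left_total, right_total):
        v = np.zeros(2 * n_bins, dtype=int)
        for i in range(n_bins):
            v[i] = left_total // n_bins + (1 if i < left_total % n_bins else 0)
            v[n_bins + i] = (right_total // n_bins
                             + (1 if i < right_total % n_bins else 0))
        return v
    return ConfidenceCounts("s", "memory", n_bins,
                            spread(h, m), spread(fa, cr))


class TestFitType1:
    def test_symmetric_table_is_zero(self):
        fit = fit_type1(counts_from_type1(25, 25, 25, 25))
        assert fit.dprime == pytest.approx(0.0, abs=1e-12)
        assert fit.criterion == pytest.approx(0.0, abs=1e-12)

    def test_inverse_normal_oracle(self):
        fit = fit_type1(counts_from_type1(40, 10, 10, 40))
        expected = norm.ppf(0.8) - norm.ppf(0.2)
        assert fit.dprime == pytest.approx(expected, abs=1e-12)
        assert fit.dprime == pytest.approx(1.683, abs=1e-3)
        assert fit.criterion == pytest.approx(0.0, abs=1e-12)

    def test_equal_rates_give_zero_dprime(self):
        for h, n in ((10, 40), (30, 40)):
            fit = fit_type1(counts_from_type1(h, n - h, h, n - h))
            assert fit.dprime == pytest.approx(0.0, abs=1e-12)

    def test_exact_z_difference_identity(self):
        # the closed-form identity holds for whatever (padded) rates are used
        rng = np.random.default_rng(3)
        for _ in range(20):
            h, m, fa, cr = rng.integers(0, 30, 4)
            if h + m == 0 or fa + cr == 0:
                continue
            fit = fit_type1(counts_from_type1(h, m, fa, cr))
            assert fit.dprime == pytest.approx(
                norm.ppf(fit.hr) - norm.ppf(fit.far), abs=1e-12)
            assert fit.criterion == pytest.approx(
                -0.5 * (norm.ppf(fit.hr) + norm.ppf(fit.far)), abs=1e-12)

    def test_extreme_rates_padded_finite(self):
        fit = fit_type1(counts_from_type1(40, 0, 0, 40))
        assert np.isfinite(fit.dprime) and 0 < fit.hr < 1


class TestType2ROC:
    def _counts(self, correct_by_bin, incorrect_by_bin):
        # place corrects as (stim left, resp left), incorrects as
        # (stim right, resp left): bins map to cells n_bins - bin
        k = len(correct_by_bin)
        s1 = np.zeros(2 * k, dtype=int)
        s2 = np.zeros(2 * k, dtype=int)
        for b in range(1, k + 1):
            s1[k - b] = correct_by_bin[b - 1]
            s2[k - b] = incorrect_by_bin[b - 1]
        s2[-1] += 1   # keep both classes populated: one correct right trial
        s1[-1] += 1   # and one incorrect left trial
        return ConfidenceCounts("s", "memory", k, s1, s2)

    def test_identical_distributions_chance(self):
        c = ConfidenceCounts("s", "memory", 3,
                             np.array([5, 5, 5, 5, 5, 5]),
                             np.array([5, 5, 5, 5, 5, 5]))
        assert type2_roc(c).auroc2 == pytest.approx(0.5)

    def test_perfect_separation(self):
        k = 6
        s1 = np.zeros(2 * k, dtype=int)
        s2 = np.zeros(2 * k, dtype=int)
        s1[0] = 30          # stim left, resp left (correct), bin 6
        s2[k] = 30          # stim right, resp right? -> cell k is resp right conf 1
        c = ConfidenceCounts("s", "memory", k, s1, s2)
        # corrects all at bin 6, incorrects: make stim right respond left at bin 1
        s2b = np.zeros(2 * k, dtype=int)
        s2b[k - 1] = 30     # stim right, resp left, conf 1 (incorrect)
        s2b[2 * k - 1] = 1  # one correct right response keeps class valid
        c = ConfidenceCounts("s", "memory", k, s1, s2b)
        assert type2_roc(c).auroc2 == pytest.approx(1.0)

    def test_trapezoid_oracle(self):
        correct = (0, 0, 10, 10, 10, 10)
        incorrect = (10, 10, 10, 10, 0, 0)
        c = self._counts(correct, incorrect)
        # oracle on the pooled correct/incorrect distributions incl. the
        # filler right-response trials (both land in the top bin)
        corr = np.array(correct, dtype=float)
        inco = np.array(incorrect, dtype=float)
        corr[-1] += 1
        inco[-1] += 1
        assert type2_roc(c).auroc2 == pytest.approx(
            auroc2_reference(corr, inco), abs=1e-12)

    def test_requires_errors(self):
        k = 2
        s1 = np.array([10, 0, 0, 0])
        s2 = np.array([0, 0, 0, 10])
        with pytest.raises(ValueError):
            type2_roc(ConfidenceCounts("s", "memory", k, s1, s2))


class TestFitMetaD:
    def test_ideal_observer_m_ratio_near_one(self, ideal_counts):
        fit = fit_meta_d(ideal_counts)
        assert fit.converged
        assert 0.95 <= fit.m_ratio <= 1.05

    def test_shuffled_confidence_destroys_meta_d(self, ideal_session):
        df = ideal_session.copy()
        rng = np.random.default_rng(0)
        df["confidence_raw"] = rng.permutation(df["confidence_raw"].to_numpy())
        _, counts, _ = preprocess_trials(df)
        fit = fit_meta_d(counts[0])
        assert abs(fit.meta_d) < 0.15

    def test_grid_search_oracle_two_bins(self):
        c = ConfidenceCounts("s", "memory", 2,
                             np.array([14, 12, 9, 5]),
                             np.array([4, 8, 13, 15]))
        fit = fit_meta_d(c)
        pad = 1.0 / 8.0
        c1 = c.counts_s1 + pad
        c2 = c.counts_s2 + pad
        t1 = fit_type1(c, padding="always")
        crel = t1.criterion / t1.dprime

        def grid_max(md_grid, inc_l_grid, inc_r_grid):
            nl, nr = len(inc_l_grid), len(inc_r_grid)
            best = (-np.inf, None, None, None)
            for m in md_grid:
                mc = crel * m
                ll = type2_loglik(
                    np.tile(c1, (nl * nr, 1)), np.tile(c2, (nl * nr, 1)),
                    np.full(nl * nr, m), np.full(nl * nr, mc),
                    (mc + np.repeat(inc_l_grid, nr))[:, None],
                    (mc - np.tile(inc_r_grid, nl))[:, None])
                j = int(np.argmax(ll))
                if ll[j] > best[0]:
                    best = (ll[j], m, inc_l_grid[j // nr], inc_r_grid[j % nr])
            return best

        # dense two-stage grid over (meta_d, left increment, right increment)
        ll0, m0, il0, ir0 = grid_max(np.linspace(0.05, 4.0, 160),
                                     np.linspace(0.01, 3.0, 120),
                                     np.linspace(0.01, 3.0, 120))
        ll1, m1, _, _ = grid_max(
            np.linspace(m0 - 0.05, m0 + 0.05, 51),
            np.linspace(max(il0 - 0.06, 1e-3), il0 + 0.06, 49),
            np.linspace(max(ir0 - 0.06, 1e-3), ir0 + 0.06, 49))
        assert fit.meta_d == pytest.approx(m1, abs=0.01)
        assert fit.loglik >= ll1 - 1e-6

    def test_optimum_at_least_as_good_as_m_ratio_one(self, ideal_counts):
        fit = fit_meta_d(ideal_counts)
        pad = 1.0 / 24.0
        c1 = ideal_counts.counts_s1 + pad
        c2 = ideal_counts.counts_s2 + pad
        t1 = fit_type1(ideal_counts, padding="always")
        crel = t1.criterion / t1.dprime
        mc = crel * t1.dprime
        t2l, t2r = match_t2_criteria(c1[None], c2[None],
                                     [t1.dprime], [mc])
        at_dprime = type2_loglik(c1[None], c2[None], [t1.dprime], [mc],
                                 t2l, t2r)[0]
        assert fit.loglik >= at_dprime - 1e-6

    def test_meta_noise_monotonically_degrades_meta_d(self):
        fitted = []
        for noise in (0.0, 0.8, 2.0):
            obs = make_observer(meta_noise=noise)
            df = session_frame(obs, "memory", 5000, 21)
            _, counts, _ = preprocess_trials(df)
            fitted.append(fit_meta_d(counts[0]).meta_d)
        assert fitted[0] > fitted[1] > fitted[2]

    def test_large_meta_noise_gives_chance_auroc2(self):
        obs = make_observer(meta_noise=100.0)
        df = session_frame(obs, "memory", 8000, 5)
        _, counts, _ = preprocess_trials(df)
        assert abs(type2_roc(counts[0]).auroc2 - 0.5) < 0.02
        fit = fit_meta_d(counts[0])
        assert abs(fit.meta_d) < 0.1


class TestHDI:
    def test_standard_normal_quantile_oracle(self):
        x = np.random.default_rng(0).standard_normal(1_000_000)
        lo, hi = hdi(x)
        assert lo == pytest.approx(-1.96, abs=0.02)
        assert hi == pytest.approx(1.96, abs=0.02)

    def test_constant_samples_zero_width(self):
        lo, hi = hdi(np.full(100, 3.25))
        assert lo == hi == 3.25

    def test_matches_bruteforce_window_scan(self):
        x = np.array([2.1, -0.3, 0.7, 5.2, 0.9, 1.1, 1.0, -2.2, 0.4, 0.6,
                      1.4, 0.8, 0.2, 3.3, 1.2, 0.95, 0.5, 1.05, 0.85, 0.75])
        assert hdi(x, 0.5) == hdi_bruteforce(x, 0.5)
        assert hdi(x, 0.9) == hdi_bruteforce(x, 0.9)

    def test_input_validation(self):
        with pytest.raises(ValueError):
            hdi([1.0])
        with pytest.raises(ValueError):
            hdi([1.0, 2.0], mass=1.5)


def test_auroc2_invariant_to_response_relabel(ideal_counts):
    c = ideal_counts
    k = c.n_bins
    # swap response sides: reverse each stimulus vector
    swapped = ConfidenceCounts(c.subject_id, c.domain, k,
                               c.counts_s2[::-1].copy(),
                               c.counts_s1[::-1].copy())
    assert type2_roc(swapped).auroc2 == pytest.approx(type2_roc(c).auroc2)
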