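import numpy as np
import pandas as pd
import pytest
from scipy.stats import chi2

from oracles import ols_normal_equations
from metacog.synthetic_cohort import CohortConfig
from metacog.analysis_pipeline import (PipelineConfig, compute_difficulty_stats,
                                       demographics_check, ols_standardized,
                                       run_full_pipeline, run_spe_analyses,
                                       sign_pattern)

SMALL = PipelineConfig(
    cohort=CohortConfig(n_per_group=8, group_brackets=((18, 47), (48, 83)),
                        trials_per_domain=60, rng_seed=17),
    chains=2, warmup=250, draws=400, seed=17)


def toy_difficulty(levels, domain="memory"):
    return pd.DataFrame(dict(subject_id="s1", domain=domain,
                             trial_index=range(1, len(levels) + 1),
                             difficulty_level=levels,
                             confidence_raw=range(len(levels))))


class TestDifficultyStats:
    def test_constant_session_zero_sd(self):
        out = compute_difficulty_stats(toy_difficulty([4] * 10))
        assert out["sd_level"].iloc[0] == 0.0

    def test_perception_display_transform(self):
        out = compute_difficulty_stats(toy_difficulty([15] * 5, "perception"))
        assert out["mean_level_display"].iloc[0] == 0.0

    def test_hand_computed_moments(self):
        levels = [2, 3, 2, 3, 4]
        out = compute_difficulty_stats(toy_difficulty(levels))
        mean = sum(levels) / 5
        sd = (sum((x - mean) ** 2 for x in levels) / 5) ** 0.5
        assert out["mean_level"].iloc[0] == pytest.approx(mean)  # 2.8
        assert out["sd_level"].iloc[0] == pytest.approx(sd)


class TestOLSStandardized:
    def test_identity_regression(self):
        x = np.linspace(0, 1, 50)
        res = ols_standardized(x, x, outcome="y")[0]
        assert res.beta == pytest.approx(1.0)
        assert res.p_value < 1e-20

    def test_closed_form_oracle_ten_points(self):
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0, 7.0, 8.0, 9.0, 10.0])
        y = np.array([2.1, 2.9, 4.2, 3.8, 5.5, 6.1, 6.0, 7.7, 8.1, 9.4])
        zx = (x - x.mean()) / x.std()
        zy = (y - y.mean()) / y.std()
        expected = ols_normal_equations(zy, zx[:, None])[1]
        res = ols_standardized(y, x)[0]
        assert res.beta == pytest.approx(expected, abs=1e-12)

    def test_null_covariate_calibration(self):
        hits = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            y = rng.standard_normal(1000)
            x = rng.standard_normal(1000)
            r = ols_standardized(y, x)[0]
            hits += (abs(r.beta) < 0.1) and (r.p_value > 0.05)
        assert hits >= 18

    def test_rank_deficient_rejected(self):
        x = np.column_stack([np.arange(10.0), 2 * np.arange(10.0)])
        with pytest.raises(ValueError):
            ols_standardized(np.arange(10.0) + 0.5, x)

    def test_affine_rescaling_invariance(self):
        rng = np.random.default_rng(1)
        x = rng.uniform(18, 83, 100)
        y = -0.3 * x + rng.standard_normal(100)
        a = ols_standardized(y, x)[0]
        b = ols_standardized(y, 12.0 * x - 400.0)[0]
        assert a.beta == pytest.approx(b.beta, abs=1e-12)


class TestDemographics:
    def test_equal_counts_statistic_zero(self):
        df = pd.DataFrame(dict(age_group=[1, 1, 2, 2, 3, 3],
                               sex=["female", "male"] * 3))
        out = demographics_check(df)
        assert out["statistic"] == pytest.approx(0.0)
        assert out["p_value"] == pytest.approx(1.0)

    def test_hand_computed_chi_squared(self):
        counts = {1: (30, 20), 2: (25, 25), 3: (20, 30),
                  4: (28, 22), 5: (26, 24), 6: (21, 29)}
        rows = [dict(age_group=g, sex=s)
                for g, (f, m) in counts.items()
                for s in ["female"] * f + ["male"] * m]
        out = demographics_check(pd.DataFrame(rows))
        # oracle: sum (O - E)^2 / E with row/column-margin expectations
        obs = np.array([counts[g] for g in sorted(counts)], dtype=float)
        exp = obs.sum(1)[:, None] * obs.sum(0)[None, :] / obs.sum()
        stat = ((obs - exp) ** 2 / exp).sum()
        assert out["statistic"] == pytest.approx(stat, abs=1e-12)
        assert out["p_value"] == pytest.approx(chi2.sf(stat, 5), abs=1e-12)

    def test_extreme_imbalance_significant(self):
        rows = ([dict(age_group=1, sex="female")] * 50
                + [dict(age_group=2, sex="female")] * 25
                + [dict(age_group=2, sex="male")] * 25)
        assert demographics_check(pd.DataFrame(rows))["p_value"] < 0.05

    def test_missing_column_skipped(self):
        assert demographics_check(pd.DataFrame(dict(age_group=[1, 2]))) is None


class TestSPEAnalyses:
    def _tables(self, ratings):
        spes = pd.DataFrame(
            [dict(subject_id=f"s{i}", domain=d, phase=p, rating=r)
             for i, per_subj in enumerate(ratings)
             for (d, p), r in per_subj.items()])
        n = len(ratings)
        rng = np.random.default_rng(0)
        difficulty = pd.DataFrame(
            [dict(subject_id=f"s{i}", domain=d,
                  mean_level=5.0, sd_level=1.0,
                  mean_level_display=5.0 + rng.standard_normal())
             for i in range(n) for d in ("memory", "perception")])
        subjects = pd.DataFrame(
            [dict(subject_id=f"s{i}", age=20 + i, age_group=1)
             for i in range(n)])
        return spes, difficulty, subjects

    def test_identical_pre_post_null_paired_test(self):
        rng = np.random.default_rng(3)
        ratings = []
        for i in range(40):
            per = {}
            for d in ("memory", "perception"):
                r = int(rng.integers(3, 8))
                per[(d, "pre")] = r
                per[(d, "post")] = r
            ratings.append(per)
        spes, diff, subj = self._tables(ratings)
        _, tests = run_spe_analyses(spes, diff, subj)
        assert (tests["mean_difference"] == 0).all()

    def test_missing_phase_rejected(self):
        spes = pd.DataFrame([dict(subject_id="s0", domain="memory",
                                  phase="pre", rating=5)])
        with pytest.raises((ValueError, KeyError)):
            run_spe_analyses(spes, pd.DataFrame(), pd.DataFrame(
                dict(subject_id=["s0"], age=[30], age_group=[1])))


@pytest.fixture(scope="module")
def report():
    return run_full_pipeline(SMALL)


class TestFullPipeline:
    def test_report_structure(self, report):
        assert report.cohort_table["n"].sum() == 16
        assert len(report.subject_fits) == 32
        assert {"dprime", "m_ratio", "auroc2"} <= set(report.subject_fits)
        assert not report.posterior_summary.empty
        # per-group and all-ages M-ratio posteriors for both domains
        names = set(report.posterior_summary["parameter"])
        for d in ("memory", "perception"):
            assert f"group_mratio_{d}_all" in names
            assert f"group_mratio_{d}_g1" in names
        assert "cross_domain_rho_all" in names

    def test_every_stat_traceable(self, report):
        for df in (report.performance_regressions, report.bias_regressions,
                   report.spe_regressions):
            assert {"outcome", "covariate", "beta", "p_value"} <= set(df)
            assert df["p_value"].between(0, 1).all()

    def test_determinism(self, report):
        again = run_full_pipeline(SMALL)
        pd.testing.assert_frame_equal(report.subject_fits, again.subject_fits)
        a = report.posteriors["group_mratio_memory_all"].samples
        b = again.posteriors["group_mratio_memory_all"].samples
        assert np.array_equal(a, b)

    def test_report_written_to_disk(self, tmp_path, report):
        report.write(tmp_path)
        assert (tmp_path / "manifest.json").exists()
        assert (tmp_path / "posterior_summary.csv").exists()

    def test_sign_pattern_keys_present(self, report):
        sp = sign_pattern(report)
        assert {"bias_age_negative", "spe_age_negative", "dprime_age_null",
                "mratio_age_null", "efficiency_rho_positive",
                "bias_rho_positive"} <= set(sp)

    def test_stage_failure_names_stage(self):
        bad = pd.DataFrame(dict(subject_id=["s0"], domain=["memory"],
                                trial_index=[1], confidence_raw=[5]))
        with pytest.raises(RuntimeError, match="stage"):
            run_full_pipeline(SMALL, trials=bad, spes=pd.DataFrame(),
                              subjects=pd.DataFrame())
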