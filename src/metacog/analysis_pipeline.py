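"""Orchestration of the full local/global metacognition analysis.

Runs the study battery over a trial/SPE dataset (simulated or supplied in
the same schema): exclusions and binning, per-subject signal-detection
fits, first-order performance checks (d' and staircased difficulty versus
age), local metacognitive bias analyses (mean confidence versus age and its
cross-domain association), global self-performance-estimate (SPE) analyses
(age trends, pre/post paired tests, difficulty relationships, update
analyses, domain-generality), a demographic chi-squared check, and the
hierarchical Bayesian group-level inference (per-age-group M-ratios, the
M-ratio regression on age and task-difficulty covariates, and cross-domain
efficiency correlations).

Regression conventions: ordinary least squares on z-scored outcome and
covariates ("normalized betas"), two-sided p from the t distribution,
alpha = 0.05, no multiple-comparison correction.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from . import hierarchical_bayes as hb
from . import preprocess as pp
from . import sdt_core as sdt
from .synthetic_cohort import CohortConfig, PERCEPTION_START_LEVEL, generate_cohort

logger = logging.getLogger(__name__)

ALPHA = 0.05


@dataclass(frozen=True)
class RegressionResult:
    """One standardized OLS coefficient with its test."""

    outcome: str
    covariate: str
    beta: float
    se: float
    p_value: float
    n: int

    def row(self) -> dict:
        return dict(outcome=self.outcome, covariate=self.covariate,
                    beta=self.beta, se=self.se, p_value=self.p_value,
                    n=self.n)


@dataclass(frozen=True)
class PipelineConfig:
    """What to run and at what sampler budget."""

    cohort: CohortConfig = field(default_factory=CohortConfig)
    n_bins: int = 6
    seed: int = 0
    chains: int = 3
    warmup: int = 600
    draws: int = 1200
    subject_mle: bool = True          # per-subject ML meta-d' fits
    group_fits: bool = True           # per-age-group + all-ages M-ratio
    regression_fits: bool = True      # hierarchical M-ratio regression
    cross_domain_fits: bool = True    # rho, all ages
    cross_domain_per_group: bool = False


def compute_difficulty_stats(trials: pd.DataFrame) -> pd.DataFrame:
    """Per-subject mean and SD of the staircased difficulty level.

    ``mean_level_display`` maps perception to a harder-is-larger scale by
    subtracting the colour-count difference from its starting value (15),
    so display difficulty is comparable in direction across domains.
    """
    g = trials.groupby(["subject_id", "domain"])["difficulty_level"]
    out = g.agg(mean_level="mean", sd_level=lambda v: v.std(ddof=0)).reset_index()
    per = out["domain"] == "perception"
    out["mean_level_display"] = np.where(
        per, PERCEPTION_START_LEVEL - out["mean_level"], out["mean_level"])
    return out


def ols_standardized(y, x, outcome: str = "y",
                     names: tuple[str, ...] | None = None
                     ) -> list[RegressionResult]:
    """OLS of z-scored outcome on z-scored covariates (normalized betas).

    ``x`` may be a 1-D array, 2-D array, or DataFrame; two-sided p-values
    come from the coefficient t statistics.
    """
    import statsmodels.api as sm

    y = np.asarray(y, dtype=float)
    if isinstance(x, pd.DataFrame):
        names = tuple(x.columns)
        xmat = x.to_numpy(dtype=float)
    else:
        xmat = np.asarray(x, dtype=float)
        if xmat.ndim == 1:
            xmat = xmat[:, None]
        names = names or tuple(f"x{i}" for i in range(xmat.shape[1]))
    n, p = xmat.shape
    if n <= p + 1:
        raise ValueError("need n > number of covariates + 1")
    sds = xmat.std(axis=0)
    ysd = y.std()
    if np.any(sds == 0) or ysd == 0:
        raise ValueError("constant outcome or covariate")
    zx = (xmat - xmat.mean(axis=0)) / sds
    zy = (y - y.mean()) / ysd
    if np.linalg.matrix_rank(np.column_stack([np.ones(n), zx])) < p + 1:
        raise ValueError("rank-deficient design")
    fit = sm.OLS(zy, sm.add_constant(zx)).fit()
    return [RegressionResult(outcome=outcome, covariate=names[j],
                             beta=float(fit.params[j + 1]),
                             se=float(fit.bse[j + 1]),
                             p_value=float(fit.pvalues[j + 1]), n=n)
            for j in range(p)]


def run_performance_checks(fits: pd.DataFrame, difficulty: pd.DataFrame,
                           subjects: pd.DataFrame) -> pd.DataFrame:
    """First-order stability checks: six age regressions.

    Per domain: d' on age, mean staircased difficulty on age, SD of
    staircased difficulty on age.
    """
    rows = []
    for domain in ("memory", "perception"):
        f = fits[fits["domain"] == domain].merge(subjects, on="subject_id")
        d = difficulty[difficulty["domain"] == domain].merge(
            subjects, on="subject_id")
        if f["age"].nunique() <= 1:
            logger.warning("%s: no age variance; performance checks "
                           "degenerate", domain)
        for frame, col, label in ((f, "dprime", "dprime"),
                                  (d, "mean_level_display", "mean_difficulty"),
                                  (d, "sd_level", "sd_difficulty")):
            res = ols_standardized(frame[col], frame[["age"]].to_numpy(),
                                   outcome=f"{label}_{domain}", names=("age",))
            rows.extend(r.row() for r in res)
    return pd.DataFrame(rows)


def run_bias_analyses(trials: pd.DataFrame, subjects: pd.DataFrame
                      ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Local metacognitive bias battery.

    Metacognitive bias is each subject's mean raw confidence per domain.
    Returns (age regressions of mean and SD of confidence per domain;
    cross-domain regressions of memory confidence on perception confidence,
    overall and within each age group).
    """
    per_subj = (trials.groupby(["subject_id", "domain"])["confidence_raw"]
                .agg(mean_conf="mean", sd_conf=lambda v: v.std(ddof=0))
                .reset_index()
                .merge(subjects, on="subject_id"))
    rows = []
    for domain in ("memory", "perception"):
        sub = per_subj[per_subj["domain"] == domain]
        for col, label in (("mean_conf", "mean_confidence"),
                           ("sd_conf", "sd_confidence")):
            res = ols_standardized(sub[col], sub[["age"]].to_numpy(),
                                   outcome=f"{label}_{domain}", names=("age",))
            rows.extend(r.row() for r in res)
    wide = per_subj.pivot_table(index=["subject_id", "age_group"],
                                columns="domain",
                                values="mean_conf").reset_index()
    xrows = []
    res = ols_standardized(wide["memory"], wide[["perception"]].to_numpy(),
                           outcome="mean_confidence_memory_all",
                           names=("mean_confidence_perception",))
    xrows.extend(r.row() for r in res)
    for g, grp in wide.groupby("age_group"):
        res = ols_standardized(grp["memory"], grp[["perception"]].to_numpy(),
                               outcome=f"mean_confidence_memory_group{g}",
                               names=("mean_confidence_perception",))
        xrows.extend(r.row() for r in res)
    return pd.DataFrame(rows), pd.DataFrame(xrows)


def run_spe_analyses(spes: pd.DataFrame, difficulty: pd.DataFrame,
                     subjects: pd.DataFrame
                     ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Global SPE battery: age trends, difficulty relations, pre/post
    paired tests, update analyses, and domain-generality.

    Returns (tidy regression table, paired-test table).
    """
    need = spes.groupby("subject_id").size()
    if (need != 4).any():
        bad = need[need != 4].index[0]
        raise ValueError(f"subject {bad}: expected 4 SPE records "
                         "(2 domains x pre/post)")
    wide = spes.pivot_table(index="subject_id", columns=["domain", "phase"],
                            values="rating")
    wide.columns = [f"{d}_{p}" for d, p in wide.columns]
    wide = wide.reset_index().merge(subjects, on="subject_id")
    diff_wide = difficulty.pivot_table(index="subject_id", columns="domain",
                                       values="mean_level_display")
    diff_wide.columns = [f"difficulty_{d}" for d in diff_wide.columns]
    wide = wide.merge(diff_wide.reset_index(), on="subject_id")

    rows, trows = [], []
    for domain in ("memory", "perception"):
        pre, post = wide[f"{domain}_pre"], wide[f"{domain}_post"]
        for phase in ("pre", "post"):
            rows.extend(r.row() for r in ols_standardized(
                wide[f"{domain}_{phase}"], wide[["age"]].to_numpy(),
                outcome=f"spe_{phase}_{domain}", names=("age",)))
            rows.extend(r.row() for r in ols_standardized(
                wide[f"{domain}_{phase}"],
                wide[[f"difficulty_{domain}"]].to_numpy(),
                outcome=f"spe_{phase}_{domain}",
                names=("mean_difficulty",)))
        t, p = stats.ttest_rel(pre, post)
        trows.append(dict(test=f"spe_pre_vs_post_{domain}",
                          statistic=float(t), p_value=float(p),
                          mean_difference=float((post - pre).mean()),
                          n=len(wide)))
        update = post - pre
        if update.std() > 0:
            rows.extend(r.row() for r in ols_standardized(
                update, wide[[f"difficulty_{domain}"]].to_numpy(),
                outcome=f"spe_update_{domain}", names=("mean_difficulty",)))
            rows.extend(r.row() for r in ols_standardized(
                update, wide[["age"]].to_numpy(),
                outcome=f"spe_update_{domain}", names=("age",)))
        wide[f"agg_{domain}"] = (pre + post) / 2.0
        wide[f"update_{domain}"] = update
    rows.extend(r.row() for r in ols_standardized(
        wide["agg_memory"], wide[["agg_perception"]].to_numpy(),
        outcome="spe_aggregate_memory", names=("spe_aggregate_perception",)))
    if wide["update_memory"].std() > 0 and wide["update_perception"].std() > 0:
        rows.extend(r.row() for r in ols_standardized(
            wide["update_memory"], wide[["update_perception"]].to_numpy(),
            outcome="spe_update_memory", names=("spe_update_perception",)))
    return pd.DataFrame(rows), pd.DataFrame(trows)


def demographics_check(subjects: pd.DataFrame) -> dict | None:
    """Chi-squared test of sex proportions across age groups.

    Undisclosed sex is excluded; returns None (with a log notice) when no
    sex column is present.
    """
    if "sex" not in subjects.columns:
        logger.info("no sex column; demographics check skipped")
        return None
    sub = subjects[subjects["sex"].isin(["female", "male"])]
    table = pd.crosstab(sub["age_group"], sub["sex"])
    chi2, p, dof, _ = stats.chi2_contingency(table, correction=False)
    return dict(statistic=float(chi2), p_value=float(p), dof=int(dof),
                table=table)


def make_cohort_table(subjects: pd.DataFrame) -> pd.DataFrame:
    """Age-group composition table (n, mean age, range, SD, sex counts)."""
    rows = []
    for g, grp in subjects.groupby("age_group"):
        row = dict(age_group=g, n=len(grp), mean_age=grp["age"].mean(),
                   min_age=grp["age"].min(), max_age=grp["age"].max(),
                   sd_age=grp["age"].std(ddof=1))
        if "sex" in grp.columns:
            row["n_female"] = int((grp["sex"] == "female").sum())
            row["n_male"] = int((grp["sex"] == "male").sum())
        rows.append(row)
    return pd.DataFrame(rows)


def fit_subjects(counts: list[pp.ConfidenceCounts],
                 mle_meta_d: bool = True) -> pd.DataFrame:
    """Per-subject signal-detection fit table.

    Always includes d', criterion and AUROC2; optionally the ML meta-d'
    fit (meta_d, m_ratio, loglik, convergence flag).
    """
    rows = []
    for c in counts:
        t1 = sdt.fit_type1(c)
        row = dict(subject_id=c.subject_id, domain=c.domain,
                   dprime=t1.dprime, criterion=t1.criterion)
        try:
            row["auroc2"] = sdt.type2_roc(c).auroc2
        except ValueError:
            row["auroc2"] = np.nan
        if mle_meta_d:
            fit = sdt.fit_meta_d(c)
            row.update(meta_d=fit.meta_d, m_ratio=fit.m_ratio,
                       loglik=fit.loglik, converged=fit.converged)
        rows.append(row)
    return pd.DataFrame(rows)


@dataclass
class StudyReport:
    """All output tables of one pipeline run."""

    cohort_table: pd.DataFrame
    exclusion_report: pp.ExclusionReport
    subject_fits: pd.DataFrame
    difficulty_stats: pd.DataFrame
    performance_regressions: pd.DataFrame
    bias_regressions: pd.DataFrame
    bias_cross_domain: pd.DataFrame
    spe_regressions: pd.DataFrame
    spe_paired_tests: pd.DataFrame
    demographics: dict | None
    posterior_summary: pd.DataFrame
    posteriors: dict = field(default_factory=dict)

    def write(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        tables = dict(cohort_table=self.cohort_table,
                      subject_fits=self.subject_fits,
                      difficulty_stats=self.difficulty_stats,
                      performance_regressions=self.performance_regressions,
                      bias_regressions=self.bias_regressions,
                      bias_cross_domain=self.bias_cross_domain,
                      spe_regressions=self.spe_regressions,
                      spe_paired_tests=self.spe_paired_tests,
                      posterior_summary=self.posterior_summary)
        manifest = dict(exclusions=self.exclusion_report.to_dict())
        if self.demographics is not None:
            manifest["demographics"] = {
                k: v for k, v in self.demographics.items() if k != "table"}
        for name, df in tables.items():
            df.to_csv(out / f"{name}.csv", index=False)
            manifest.setdefault("tables", []).append(f"{name}.csv")
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))


def _counts_by_domain(counts: list[pp.ConfidenceCounts]
                      ) -> dict[str, list[pp.ConfidenceCounts]]:
    out: dict[str, list[pp.ConfidenceCounts]] = {}
    for c in counts:
        out.setdefault(c.domain, []).append(c)
    return out


def run_full_pipeline(config: PipelineConfig | None = None,
                      trials: pd.DataFrame | None = None,
                      spes: pd.DataFrame | None = None,
                      subjects: pd.DataFrame | None = None,
                      out_dir: str | Path | None = None) -> StudyReport:
    """Run the complete analysis battery; simulate a cohort if no data given.

    Deterministic given the config seeds.  Any stage failure aborts with an
    error naming the stage.
    """
    cfg = config or PipelineConfig()
    stage = "simulate"
    try:
        if trials is None:
            logger.info("simulating cohort (seed %d)", cfg.cohort.rng_seed)
            trials, spes, subjects = generate_cohort(cfg.cohort)
        if spes is None or subjects is None:
            raise ValueError("trials supplied without spes/subjects tables")

        stage = "preprocess"
        binned, counts, report = pp.preprocess_trials(trials, n_bins=cfg.n_bins)
        kept_ids = set(binned["subject_id"])
        subjects = subjects[subjects["subject_id"].isin(kept_ids)].copy()
        spes = spes[spes["subject_id"].isin(kept_ids)].copy()
        logger.info("exclusions: %s", report.to_dict())

        stage = "subject_fits"
        fits = fit_subjects(counts, mle_meta_d=cfg.subject_mle)

        stage = "difficulty"
        difficulty = compute_difficulty_stats(binned)

        stage = "performance_checks"
        perf = run_performance_checks(fits, difficulty, subjects)

        stage = "bias_analyses"
        bias_age, bias_cross = run_bias_analyses(binned, subjects)

        stage = "spe_analyses"
        spe_reg, spe_tests = run_spe_analyses(spes, difficulty, subjects)

        stage = "demographics"
        demo = demographics_check(subjects)

        stage = "hierarchical"
        posteriors: dict[str, hb.GroupPosterior] = {}
        by_domain = _counts_by_domain(counts)
        subj_group = subjects.set_index("subject_id")["age_group"]
        mcmc = dict(chains=cfg.chains, warmup=cfg.warmup, draws=cfg.draws)
        if cfg.group_fits:
            for domain, clist in by_domain.items():
                posteriors[f"group_mratio_{domain}_all"] = hb.fit_group_mratio(
                    clist, seed=cfg.seed + 101, name=f"group_mratio_{domain}_all",
                    **mcmc)
                for g in sorted(subjects["age_group"].unique()):
                    sub = [c for c in clist
                           if subj_group.get(c.subject_id) == g]
                    posteriors[f"group_mratio_{domain}_g{g}"] = \
                        hb.fit_group_mratio(
                            sub, seed=cfg.seed + 200 + 10 * g,
                            name=f"group_mratio_{domain}_g{g}", **mcmc)
        if cfg.regression_fits:
            for domain, clist in by_domain.items():
                ids = [c.subject_id for c in clist]
                meta = (pd.DataFrame({"subject_id": ids})
                        .merge(subjects, on="subject_id")
                        .merge(difficulty[difficulty["domain"] == domain],
                               on="subject_id"))
                age = meta["age"].to_numpy(dtype=float)
                # centre before squaring: raw age and age^2 are nearly
                # collinear over an adult age range
                design = hb.RegressionDesign.from_columns({
                    "age": age,
                    "age_sq": (age - age.mean()) ** 2,
                    "mean_difficulty": meta["mean_level_display"].to_numpy(),
                    "sd_difficulty": meta["sd_level"].to_numpy()})
                betas = hb.fit_mratio_regression(
                    clist, design, seed=cfg.seed + 301, **mcmc)
                for nm, post in betas.items():
                    post.name = f"mratio_reg_{domain}_{nm}"
                    posteriors[post.name] = post
        if cfg.cross_domain_fits and set(by_domain) == {"memory", "perception"}:
            rho = hb.fit_cross_domain(by_domain["memory"],
                                      by_domain["perception"],
                                      seed=cfg.seed + 401, **mcmc)
            rho.name = "cross_domain_rho_all"
            posteriors[rho.name] = rho
            if cfg.cross_domain_per_group:
                for g in sorted(subjects["age_group"].unique()):
                    cm = [c for c in by_domain["memory"]
                          if subj_group.get(c.subject_id) == g]
                    cp = [c for c in by_domain["perception"]
                          if subj_group.get(c.subject_id) == g]
                    rg = hb.fit_cross_domain(cm, cp,
                                             seed=cfg.seed + 500 + g, **mcmc)
                    rg.name = f"cross_domain_rho_g{g}"
                    posteriors[rg.name] = rg

        stage = "report"
        report_obj = StudyReport(
            cohort_table=make_cohort_table(subjects),
            exclusion_report=report,
            subject_fits=fits,
            difficulty_stats=difficulty,
            performance_regressions=perf,
            bias_regressions=bias_age,
            bias_cross_domain=bias_cross,
            spe_regressions=spe_reg,
            spe_paired_tests=spe_tests,
            demographics=demo,
            posterior_summary=hb.posterior_summary(posteriors)
            if posteriors else pd.DataFrame(),
            posteriors=posteriors)
        if out_dir is not None:
            report_obj.write(out_dir)
        return report_obj
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc


def sign_pattern(report: StudyReport) -> dict[str, bool]:
    """Qualitative conclusion pattern of the study analysis.

    True flags mean: local confidence bias and all four global SPEs decline
    with age; d', staircased difficulty and metacognitive efficiency show
    no age effect; metacognitive efficiency and bias are positively
    correlated across domains.
    """
    def reg(df, outcome, covariate):
        row = df[(df["outcome"] == outcome) & (df["covariate"] == covariate)]
        return row.iloc[0]

    def stable(r) -> bool:
        # "stable" = no age effect that is both statistically significant
        # and non-negligible in size (smaller than any effect the analysis
        # treats as meaningful)
        return bool(r["p_value"] > ALPHA or abs(r["beta"]) < 0.15)

    out: dict[str, bool] = {}
    bias = report.bias_regressions
    out["bias_age_negative"] = all(
        (r := reg(bias, f"mean_confidence_{d}", "age"))["beta"] < 0
        and r["p_value"] < ALPHA for d in ("memory", "perception"))
    spe = report.spe_regressions
    out["spe_age_negative"] = all(
        (r := reg(spe, f"spe_{ph}_{d}", "age"))["beta"] < 0
        and r["p_value"] < ALPHA
        for d in ("memory", "perception") for ph in ("pre", "post"))
    perf = report.performance_regressions
    out["dprime_age_null"] = all(
        stable(reg(perf, f"dprime_{d}", "age"))
        for d in ("memory", "perception"))
    out["difficulty_age_null"] = all(
        stable(reg(perf, f"{m}_{d}", "age"))
        for d in ("memory", "perception")
        for m in ("mean_difficulty", "sd_difficulty"))
    if report.posteriors:
        ages = [p for nm, p in report.posteriors.items()
                if "mratio_reg" in nm and nm.endswith("_age")]
        out["mratio_age_null"] = bool(ages) and all(
            p.hdi95[0] <= 0 <= p.hdi95[1] or abs(p.mean) < 0.15
            for p in ages)
        rho = report.posteriors.get("cross_domain_rho_all")
        if rho is not None:
            out["efficiency_rho_positive"] = rho.hdi95[0] > 0
    xdom = report.bias_cross_domain
    r = reg(xdom, "mean_confidence_memory_all", "mean_confidence_perception")
    out["bias_rho_positive"] = bool(r["beta"] > 0 and r["p_value"] < ALPHA)
    return out
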