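"""Group-level Bayesian inference on metacognitive efficiency.

Three hierarchical models over subjects' log M-ratios, each driven by the
subjects' type-2 confidence-count likelihoods rather than by noisy point
estimates:

* ``fit_group_mratio`` — subject log(M-ratio) ~ Normal(mu, sigma^2); reports
  the posterior of the group M-ratio exp(mu) with its 95% HDI.
* ``fit_mratio_regression`` — the subject-level mean is intercept + X @ beta
  on standardized covariates; reports each standardized beta.
* ``fit_cross_domain`` — subject (log M-ratio_mem, log M-ratio_per) ~
  bivariate Normal with correlation rho; reports rho (domain-generality).

Subject type-1 parameters (d', criterion) are fixed at their point
estimates.  Each subject contributes the response-conditional multinomial
likelihood of their confidence counts under the meta-d' model, with
meta-d' = exp(log M-ratio) * d', the type-1 criterion held at its fitted
relative position, and the ordered type-2 criteria treated as subject-level
latent parameters and sampled alongside log M-ratio.

Priors: mu, intercept, betas ~ Normal(0, 1); group SDs ~ half-Normal(1);
rho uniform on [-1, 1]; log criterion increments ~ Normal(log 0.5, 1.5^2).

Sampling is blocked Metropolis-within-Gibbs: conjugate draws for group
means and regression coefficients, random-walk Metropolis on transformed
scales for SDs and rho, vectorised elementwise random-walk updates for the
conditionally independent subject blocks (log M-ratio and per-response-side
criterion blocks, step sizes adapted during warm-up), plus interweaved
translation/scale moves that decorrelate the group location and scale from
the subject block.  Runs are multi-chain; split-R-hat and effective sample
size are recorded for every reported parameter and R-hat above 1.1 flags
the result as unconverged.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .preprocess import ConfidenceCounts
from .sdt_core import (_pad_value, fit_type1, hdi, match_t2_criteria,
                       type2_loglik)

logger = logging.getLogger(__name__)

DEFAULT_CHAINS = 3
DEFAULT_WARMUP = 1000
DEFAULT_DRAWS = 2000
RHAT_LIMIT = 1.1

# prior on log type-2 criterion increments
_INC_PRIOR_MEAN = math.log(0.5)
_INC_PRIOR_SD = 1.5


# ---------------------------------------------------------------------------
# diagnostics
# ---------------------------------------------------------------------------

def split_rhat(chains: np.ndarray) -> float:
    """Split-R-hat of a (chains, draws) sample array."""
    x = np.asarray(chains, dtype=float)
    m, n = x.shape
    half = n // 2
    parts = np.concatenate([x[:, :half], x[:, half:2 * half]], axis=0)
    means = parts.mean(axis=1)
    vars_ = parts.var(axis=1, ddof=1)
    w = vars_.mean()
    b = half * means.var(ddof=1)
    var_plus = (half - 1) / half * w + b / half
    if w <= 0:
        return 1.0
    return float(math.sqrt(var_plus / w))


def _ess(chains: np.ndarray) -> float:
    try:
        import arviz as az
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            idata = az.from_dict(posterior={"p": np.asarray(chains)})
            return float(az.ess(idata)["p"].values)
    except Exception:  # pragma: no cover - diagnostic fallback
        return float("nan")


@dataclass
class GroupPosterior:
    """Posterior summary for one reported group-level parameter."""

    name: str
    samples: np.ndarray  # (chains, draws)
    mean: float
    hdi95: tuple[float, float]
    rhat: float
    ess: float
    n_subjects: int
    seed: int
    converged: bool
    extra: dict = field(default_factory=dict)

    @classmethod
    def from_chains(cls, name: str, chains: np.ndarray, n_subjects: int,
                    seed: int, extra: dict | None = None) -> "GroupPosterior":
        chains = np.asarray(chains, dtype=float)
        rhat = split_rhat(chains)
        post = cls(name=name, samples=chains, mean=float(chains.mean()),
                   hdi95=hdi(chains.ravel()), rhat=rhat, ess=_ess(chains),
                   n_subjects=n_subjects, seed=seed,
                   converged=bool(rhat <= RHAT_LIMIT), extra=extra or {})
        if not post.converged:
            logger.warning("parameter %s unconverged: R-hat %.3f", name, rhat)
        return post

    def summary_row(self) -> dict:
        return dict(parameter=self.name, mean=self.mean,
                    hdi_lo=self.hdi95[0], hdi_hi=self.hdi95[1],
                    rhat=self.rhat, ess=self.ess,
                    n_subjects=self.n_subjects, seed=self.seed,
                    converged=self.converged)


@dataclass(frozen=True)
class RegressionDesign:
    """Standardized covariate matrix for the hierarchical regression."""

    matrix: np.ndarray  # (n_subjects, p), each column zero-mean unit-SD
    names: tuple[str, ...]

    @classmethod
    def from_columns(cls, columns: dict[str, np.ndarray]) -> "RegressionDesign":
        cols, names = [], []
        for name, raw in columns.items():
            v = np.asarray(raw, dtype=float)
            sd = v.std(ddof=0)
            if sd == 0:
                raise ValueError(f"covariate {name!r} is constant")
            cols.append((v - v.mean()) / sd)
            names.append(name)
        return cls(matrix=np.column_stack(cols), names=tuple(names))

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame,
                       columns: tuple[str, ...]) -> "RegressionDesign":
        return cls.from_columns({c: df[c].to_numpy() for c in columns})


# ---------------------------------------------------------------------------
# subject-level likelihood block
# ---------------------------------------------------------------------------

class SubjectData:
    """Fixed per-subject quantities entering the type-2 likelihood.

    The type-2 multinomial likelihood uses the raw counts (zero cells simply
    contribute nothing); padding is applied only to the type-1 point
    estimates and to the padded copies used for criterion initialisation.
    """

    def __init__(self, counts_list: list[ConfidenceCounts]):
        if not counts_list:
            raise ValueError("no subjects supplied")
        k = counts_list[0].n_bins
        pad = _pad_value(k)
        ids, dprimes, crits, c1s, c2s = [], [], [], [], []
        for c in counts_list:
            if c.n_bins != k:
                raise ValueError("inconsistent n_bins across subjects")
            t1 = fit_type1(c, padding="always")
            if t1.dprime <= 0:
                raise ValueError(f"subject {c.subject_id}/{c.domain}: "
                                 "d' <= 0, M-ratio undefined")
            ids.append(c.subject_id)
            dprimes.append(t1.dprime)
            crits.append(t1.criterion)
            c1s.append(c.counts_s1.astype(float))
            c2s.append(c.counts_s2.astype(float))
        self.subject_ids = tuple(ids)
        self.n_bins = k
        self.dprime = np.array(dprimes)
        self.crel = np.array(crits) / self.dprime
        self.c1 = np.vstack(c1s)
        self.c2 = np.vstack(c2s)
        self.c1_padded = self.c1 + pad
        self.c2_padded = self.c2 + pad

    @property
    def n_subjects(self) -> int:
        return len(self.subject_ids)

    def loglik(self, y: np.ndarray, dl: np.ndarray,
               dr: np.ndarray) -> np.ndarray:
        """Type-2 log-likelihood per subject at log M-ratio ``y`` with log
        criterion increments ``dl`` (left side) and ``dr`` (right side)."""
        meta_d = np.exp(np.clip(y, -8.0, 4.0)) * self.dprime
        meta_c = self.crel * meta_d
        t2l = meta_c[:, None] + np.cumsum(np.exp(dl), axis=1)
        t2r = meta_c[:, None] - np.cumsum(np.exp(dr), axis=1)
        return type2_loglik(self.c1, self.c2, meta_d, meta_c, t2l, t2r)

    def init_state(self, rng: np.random.Generator) -> "SubjectState":
        """Starting point: coarse log M-ratio scan with distribution-matched
        criteria, small jitter for chain dispersion."""
        n = self.n_subjects
        grid = np.linspace(-2.0, 1.0, 9)
        best_y = np.zeros(n)
        best_ll = np.full(n, -np.inf)
        best_l = np.zeros((n, self.n_bins - 1))
        best_r = np.zeros((n, self.n_bins - 1))
        for g in grid:
            meta_d = math.exp(g) * self.dprime
            meta_c = self.crel * meta_d
            t2l, t2r = match_t2_criteria(self.c1_padded, self.c2_padded,
                                         meta_d, meta_c)
            ll = type2_loglik(self.c1, self.c2, meta_d, meta_c, t2l, t2r)
            better = ll > best_ll
            best_ll = np.where(better, ll, best_ll)
            best_y = np.where(better, g, best_y)
            sel = better[:, None]
            best_l = np.where(sel, t2l - meta_c[:, None], best_l)
            best_r = np.where(sel, meta_c[:, None] - t2r, best_r)
        y = best_y + 0.05 * rng.standard_normal(n)
        inc_l = np.maximum(np.diff(best_l, axis=1, prepend=0.0), 1e-3)
        inc_r = np.maximum(np.diff(best_r, axis=1, prepend=0.0), 1e-3)
        dl = np.log(inc_l) + 0.02 * rng.standard_normal(inc_l.shape)
        dr = np.log(inc_r) + 0.02 * rng.standard_normal(inc_r.shape)
        st = SubjectState(y=y, dl=dl, dr=dr, ll=None)
        st.ll = self.loglik(y, dl, dr)
        return st


@dataclass
class SubjectState:
    y: np.ndarray   # (n,) log M-ratio
    dl: np.ndarray  # (n, K-1) log increments, left-response criteria
    dr: np.ndarray  # (n, K-1) right-response criteria
    ll: np.ndarray | None


def _inc_logprior(d: np.ndarray) -> np.ndarray:
    return (-0.5 * ((d - _INC_PRIOR_MEAN) / _INC_PRIOR_SD) ** 2).sum(axis=1)


class _StepAdapter:
    """Robbins-Monro step-size adaptation toward a target acceptance rate."""

    def __init__(self, shape, init=0.3, target=0.35):
        self.step = np.full(shape, init, dtype=float)
        self.target = target
        self._acc = np.zeros(shape)
        self._cnt = 0

    def record(self, accepted) -> None:
        self._acc += accepted
        self._cnt += 1
        if self._cnt >= 25:
            rate = self._acc / self._cnt
            self.step *= np.exp(np.clip(rate - self.target, -0.5, 0.5))
            self.step = np.clip(self.step, 1e-3, 5.0)
            self._acc[...] = 0.0
            self._cnt = 0


class _SubjectSampler:
    """MH updates of one domain's subject block (log M-ratio + criteria)."""

    def __init__(self, data: SubjectData, rng: np.random.Generator):
        self.data = data
        self.state = data.init_state(rng)
        n = data.n_subjects
        self.ad_y = _StepAdapter(n, init=0.3, target=0.44)
        self.ad_l = _StepAdapter(n, init=0.15)
        self.ad_r = _StepAdapter(n, init=0.15)

    def update(self, mu_i: np.ndarray | float, sig: float,
               rng: np.random.Generator, adapt: bool) -> None:
        st, data = self.state, self.data
        n = data.n_subjects
        # log M-ratio, elementwise
        prop = st.y + self.ad_y.step * rng.standard_normal(n)
        ll_prop = data.loglik(prop, st.dl, st.dr)
        logr = (ll_prop - st.ll
                - 0.5 * ((prop - mu_i) ** 2 - (st.y - mu_i) ** 2) / sig ** 2)
        acc = np.log(rng.random(n)) < logr
        st.y = np.where(acc, prop, st.y)
        st.ll = np.where(acc, ll_prop, st.ll)
        if adapt:
            self.ad_y.record(acc)
        # criterion blocks, one response side at a time (joint within side)
        for d_attr, adapter in (("dl", self.ad_l), ("dr", self.ad_r)):
            cur = getattr(st, d_attr)
            prop = cur + adapter.step[:, None] * rng.standard_normal(cur.shape)
            if d_attr == "dl":
                ll_prop = data.loglik(st.y, prop, st.dr)
            else:
                ll_prop = data.loglik(st.y, st.dl, prop)
            logr = (ll_prop - st.ll + _inc_logprior(prop) - _inc_logprior(cur))
            acc = np.log(rng.random(n)) < logr
            setattr(st, d_attr, np.where(acc[:, None], prop, cur))
            st.ll = np.where(acc, ll_prop, st.ll)
            if adapt:
                adapter.record(acc)

    def translate(self, mu_shift_logp, rng: np.random.Generator,
                  step: float = 0.1):
        """Joint shift of all log M-ratios and the group location.

        ``mu_shift_logp(delta)`` returns the group-level log-density change
        of shifting the location by delta; returns the accepted delta (0.0
        if rejected).  The group-normal subject terms cancel.
        """
        st, data = self.state, self.data
        delta = step * rng.standard_normal()
        prop = st.y + delta
        ll_prop = data.loglik(prop, st.dl, st.dr)
        logr = ll_prop.sum() - st.ll.sum() + mu_shift_logp(delta)
        if math.log(rng.random()) < logr:
            st.y = prop
            st.ll = ll_prop
            return delta
        return 0.0

    def rescale(self, mu_i, log_sig: float, rng: np.random.Generator,
                step: float = 0.15, prior_scale: float = 1.0) -> float:
        """Joint rescale of residuals and the group SD (funnel escape).

        Group-normal terms cancel against the Jacobian, leaving the data
        likelihoods, the half-Normal prior on sigma and a +t remainder.
        """
        st, data = self.state, self.data
        t = step * rng.standard_normal()
        prop = mu_i + (st.y - mu_i) * math.exp(t)
        ll_prop = data.loglik(prop, st.dl, st.dr)
        s_old, s_new = math.exp(log_sig), math.exp(log_sig + t)
        logr = (ll_prop.sum() - st.ll.sum()
                + _halfnormal_logpdf(s_new, prior_scale)
                - _halfnormal_logpdf(s_old, prior_scale) + t)
        if math.log(rng.random()) < logr:
            st.y = prop
            st.ll = ll_prop
            return log_sig + t
        return log_sig


def _halfnormal_logpdf(s: float, scale: float = 1.0) -> float:
    return -0.5 * (s / scale) ** 2 if s > 0 else -np.inf


def _update_sigma(log_sig, y, mu_i, rng, step=0.3, prior_scale=1.0):
    n = len(y)
    rss = float(((y - mu_i) ** 2).sum())

    def target(ls):
        s = math.exp(ls)
        return (-n * ls - 0.5 * rss / s ** 2
                + _halfnormal_logpdf(s, prior_scale) + ls)  # + log-Jacobian

    prop = log_sig + step * rng.standard_normal()
    if math.log(rng.random()) < target(prop) - target(log_sig):
        return prop
    return log_sig


# ---------------------------------------------------------------------------
# models
# ---------------------------------------------------------------------------

def fit_group_mratio(counts_list: list[ConfidenceCounts], *, seed: int = 0,
                     chains: int = DEFAULT_CHAINS, warmup: int = DEFAULT_WARMUP,
                     draws: int = DEFAULT_DRAWS,
                     name: str = "group_mratio") -> GroupPosterior:
    """Hierarchical posterior for the group-level M-ratio.

    Subject log(M-ratio) ~ Normal(mu, sigma^2); the reported group M-ratio
    is exp(mu).  Requires at least 5 subjects.
    """
    if len(counts_list) < 5:
        raise ValueError("group fit requires >= 5 subjects")
    data = SubjectData(counts_list)
    n = data.n_subjects
    seqs = np.random.SeedSequence(seed).spawn(chains)
    mu_out = np.empty((chains, draws))
    sig_out = np.empty((chains, draws))
    for ci in range(chains):
        rng = np.random.default_rng(seqs[ci])
        sampler = _SubjectSampler(data, rng)
        mu = float(sampler.state.y.mean()) + 0.05 * rng.standard_normal()
        log_sig = math.log(max(float(sampler.state.y.std()), 0.1))
        for it in range(warmup + draws):
            adapt = it < warmup
            sig = math.exp(log_sig)
            sampler.update(mu, sig, rng, adapt)
            y = sampler.state.y
            prec = n / sig ** 2 + 1.0  # prior mu ~ N(0, 1)
            mean = (y.sum() / sig ** 2) / prec
            mu = mean + rng.standard_normal() / math.sqrt(prec)
            log_sig = _update_sigma(log_sig, y, mu, rng)
            mu += sampler.translate(
                lambda d: -0.5 * ((mu + d) ** 2 - mu ** 2), rng)
            log_sig = sampler.rescale(mu, log_sig, rng)
            if it >= warmup:
                mu_out[ci, it - warmup] = mu
                sig_out[ci, it - warmup] = math.exp(log_sig)
    return GroupPosterior.from_chains(
        name, np.exp(mu_out), n, seed,
        extra=dict(sigma_mean=float(sig_out.mean()),
                   mu_rhat=split_rhat(mu_out)))


def fit_mratio_regression(counts_list: list[ConfidenceCounts],
                          design: RegressionDesign, *, seed: int = 0,
                          chains: int = DEFAULT_CHAINS,
                          warmup: int = DEFAULT_WARMUP,
                          draws: int = DEFAULT_DRAWS
                          ) -> dict[str, GroupPosterior]:
    """Hierarchical regression of subject log M-ratio on covariates.

    Subject log(M-ratio) ~ Normal(b0 + X @ beta, sigma^2) with X
    standardized per covariate; returns one posterior per standardized beta
    (plus the intercept under key ``"intercept"``).
    """
    data = SubjectData(counts_list)
    n = data.n_subjects
    x = np.asarray(design.matrix, dtype=float)
    if x.shape[0] != n:
        raise ValueError("design rows must align with subjects")
    if np.any(x.std(axis=0) == 0):
        raise ValueError("constant covariate in design")
    xt = np.column_stack([np.ones(n), x])
    p = xt.shape[1]
    xtx = xt.T @ xt
    seqs = np.random.SeedSequence(seed).spawn(chains)
    coef_out = np.empty((chains, draws, p))
    for ci in range(chains):
        rng = np.random.default_rng(seqs[ci])
        sampler = _SubjectSampler(data, rng)
        coef = np.linalg.lstsq(xt, sampler.state.y, rcond=None)[0]
        log_sig = math.log(
            max(float((sampler.state.y - xt @ coef).std()), 0.1))
        for it in range(warmup + draws):
            adapt = it < warmup
            sig = math.exp(log_sig)
            sampler.update(xt @ coef, sig, rng, adapt)
            y = sampler.state.y
            # conjugate joint draw of (b0, beta); prior N(0, 1) each
            prec = xtx / sig ** 2 + np.eye(p)
            chol = np.linalg.cholesky(prec)
            mean = np.linalg.solve(prec, xt.T @ y / sig ** 2)
            coef = mean + np.linalg.solve(chol.T, rng.standard_normal(p))
            log_sig = _update_sigma(log_sig, y, xt @ coef, rng)
            b0 = coef[0]
            coef[0] += sampler.translate(
                lambda d: -0.5 * ((b0 + d) ** 2 - b0 ** 2), rng)
            log_sig = sampler.rescale(xt @ coef, log_sig, rng)
            if it >= warmup:
                coef_out[ci, it - warmup] = coef
    out: dict[str, GroupPosterior] = {}
    for j, pname in enumerate(("intercept",) + tuple(design.names)):
        out[pname] = GroupPosterior.from_chains(
            f"beta_{pname}" if j else "intercept", coef_out[:, :, j], n, seed)
    return out


def _align_counts(counts_mem, counts_per):
    by_id_m = {c.subject_id: c for c in counts_mem}
    by_id_p = {c.subject_id: c for c in counts_per}
    if set(by_id_m) != set(by_id_p):
        raise ValueError("subject mismatch between domains")
    ids = sorted(by_id_m)
    return [by_id_m[i] for i in ids], [by_id_p[i] for i in ids]


def fit_cross_domain(counts_mem: list[ConfidenceCounts],
                     counts_per: list[ConfidenceCounts], *, seed: int = 0,
                     chains: int = DEFAULT_CHAINS, warmup: int = DEFAULT_WARMUP,
                     draws: int = DEFAULT_DRAWS) -> GroupPosterior:
    """Posterior for the cross-domain correlation of metacognitive efficiency.

    Subject (log M-ratio_mem, log M-ratio_per) ~ bivariate Normal with
    correlation rho (uniform prior on [-1, 1]); returns the posterior on
    rho.  The two domains must contain the same subjects.
    """
    counts_mem, counts_per = _align_counts(counts_mem, counts_per)
    datas = [SubjectData(counts_mem), SubjectData(counts_per)]
    n = datas[0].n_subjects
    seqs = np.random.SeedSequence(seed).spawn(chains)
    rho_out = np.empty((chains, draws))

    def bvn_loglik(yy, mu, sig, rho):
        z = (yy - mu) / sig
        q = (z[:, 0] ** 2 - 2 * rho * z[:, 0] * z[:, 1] + z[:, 1] ** 2)
        return (-n * (math.log(sig[0]) + math.log(sig[1]))
                - 0.5 * n * math.log(1 - rho ** 2)
                - 0.5 * q.sum() / (1 - rho ** 2))

    for ci in range(chains):
        rng = np.random.default_rng(seqs[ci])
        samplers = [_SubjectSampler(datas[0], rng),
                    _SubjectSampler(datas[1], rng)]
        yy = np.column_stack([samplers[0].state.y, samplers[1].state.y])
        mu = yy.mean(axis=0)
        sig = np.maximum(yy.std(axis=0), 0.1)
        # start rho at the empirical correlation of the initial subject
        # estimates (dispersed per chain); a fixed zero start can leave all
        # chains in the same slowly-mixing neighbourhood of the
        # rho-subject-block coupling without tripping R-hat
        r0 = float(np.clip(np.corrcoef(yy[:, 0], yy[:, 1])[0, 1],
                           -0.9, 0.9))
        zrho = math.atanh(r0) + 0.15 * rng.standard_normal()
        zrho_step = 0.2
        zrho_acc = 0.0
        zrho_cnt = 0
        for it in range(warmup + draws):
            adapt = it < warmup
            rho = math.tanh(zrho)
            r = max(min(rho, 0.999), -0.999)
            for d in (0, 1):
                o = 1 - d
                yo = samplers[o].state.y
                cond_mean = mu[d] + r * sig[d] / sig[o] * (yo - mu[o])
                cond_sd = sig[d] * math.sqrt(max(1 - r ** 2, 1e-12))
                samplers[d].update(cond_mean, cond_sd, rng, adapt)
            yy = np.column_stack([samplers[0].state.y, samplers[1].state.y])
            # conjugate bivariate mean; prior mu ~ N(0, I)
            cov = np.array([[sig[0] ** 2, r * sig[0] * sig[1]],
                            [r * sig[0] * sig[1], sig[1] ** 2]])
            covinv = np.linalg.inv(cov)
            prec = n * covinv + np.eye(2)
            mean = np.linalg.solve(prec, covinv @ yy.sum(axis=0))
            chol = np.linalg.cholesky(prec)
            mu = mean + np.linalg.solve(chol.T, rng.standard_normal(2))
            # SDs: random walk on log scale against the bivariate likelihood
            for d in (0, 1):
                ls = math.log(sig[d])
                prop_ls = ls + 0.2 * rng.standard_normal()
                sig_prop = sig.copy()
                sig_prop[d] = math.exp(prop_ls)
                cur = bvn_loglik(yy, mu, sig, r) + _halfnormal_logpdf(sig[d]) + ls
                new = (bvn_loglik(yy, mu, sig_prop, r)
                       + _halfnormal_logpdf(sig_prop[d]) + prop_ls)
                if math.log(rng.random()) < new - cur:
                    sig = sig_prop
            # interweaved translation/scale moves per margin: the
            # standardized bivariate quadratic is invariant to shifting
            # (y_d, mu_d) and to rescaling residuals of one margin with its
            # SD (determinant change cancels against the Jacobian)
            for d in (0, 1):
                mud = mu[d]
                delta = samplers[d].translate(
                    lambda dd: -0.5 * ((mud + dd) ** 2 - mud ** 2), rng)
                mu[d] += delta
                st = samplers[d].state
                t = 0.15 * rng.standard_normal()
                prop = mu[d] + (st.y - mu[d]) * math.exp(t)
                ll_prop = datas[d].loglik(prop, st.dl, st.dr)
                s_new = sig[d] * math.exp(t)
                logr = (ll_prop.sum() - st.ll.sum()
                        + _halfnormal_logpdf(s_new)
                        - _halfnormal_logpdf(sig[d]) + t)
                if math.log(rng.random()) < logr:
                    st.y = prop
                    st.ll = ll_prop
                    sig[d] = s_new
                yy = np.column_stack([samplers[0].state.y,
                                      samplers[1].state.y])
            # rho: random walk on atanh scale (step adapted during warm-up),
            # uniform prior on [-1, 1]
            prop_z = zrho + zrho_step * rng.standard_normal()
            rp = math.tanh(prop_z)
            cur = bvn_loglik(yy, mu, sig, r) + math.log(1 - r ** 2)
            new = bvn_loglik(yy, mu, sig, rp) + math.log(1 - rp ** 2)
            accepted = math.log(rng.random()) < new - cur
            if accepted:
                zrho = prop_z
            if adapt:
                zrho_acc += accepted
                zrho_cnt += 1
                if zrho_cnt >= 25:
                    zrho_step *= math.exp(zrho_acc / zrho_cnt - 0.44)
                    zrho_step = min(max(zrho_step, 1e-3), 2.0)
                    zrho_acc, zrho_cnt = 0.0, 0
            if it >= warmup:
                rho_out[ci, it - warmup] = math.tanh(zrho)
    return GroupPosterior.from_chains("rho", rho_out, n, seed)


def posterior_summary(posteriors: dict[str, GroupPosterior] | list[GroupPosterior]
                      ) -> pd.DataFrame:
    """Tidy summary table (parameter, mean, hdi, rhat, ess, ...)."""
    if isinstance(posteriors, dict):
        posteriors = list(posteriors.values())
    return pd.DataFrame([p.summary_row() for p in posteriors])
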