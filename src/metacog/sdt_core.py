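"""Single-subject type-1 and type-2 signal detection.

Type-1: d' = z(HR) - z(FAR) and criterion c = -(z(HR) + z(FAR))/2 under an
equal-variance Gaussian model, with the 'left' response designated as the
signal.  Type-2: the empirical type-2 ROC (confidence conditional on
correct/incorrect) and its area AUROC2, and the maximum-likelihood meta-d'
fit — the type-1 sensitivity that best explains the observed
response-conditional confidence counts — yielding metacognitive efficiency
M-ratio = meta-d'/d'.

Evidence convention: stimulus 'left' has mean +d'/2, 'right' has -d'/2; the
observer responds 'left' when evidence exceeds the criterion.  Count vectors
follow the canonical layout of ``preprocess.ConfidenceCounts``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize
from scipy.special import ndtr
from scipy.stats import norm

from .preprocess import ConfidenceCounts

_TINY = 1e-300


def _pad_value(n_bins: int) -> float:
    # 1/(2 * number of response cells per stimulus class)
    return 1.0 / (2.0 * 2 * n_bins)


@dataclass(frozen=True)
class SDTFit:
    """Equal-variance Gaussian type-1 fit: d' = z(hr) - z(far)."""

    dprime: float
    criterion: float
    hr: float
    far: float


@dataclass(frozen=True)
class Type2ROC:
    p_conf_given_correct: np.ndarray   # over bins 1..K (low to high)
    p_conf_given_incorrect: np.ndarray
    roc_points: np.ndarray             # (K+1, 2): cumulated (FAR2, HR2)
    auroc2: float


@dataclass(frozen=True)
class MetaDFit:
    meta_d: float
    m_ratio: float
    type1: SDTFit
    type2_criteria: np.ndarray  # (2, n_bins-1): [left ascending, right descending]
    loglik: float
    converged: bool


def fit_type1(counts: ConfidenceCounts, padding: str = "auto") -> SDTFit:
    """Type-1 d' and criterion from a confidence count table.

    ``padding='auto'`` adds 1/(2*2*n_bins) to every count cell only when the
    raw hit or false-alarm rate would be 0 or 1 (keeping z finite);
    ``'always'`` pads unconditionally (the convention used inside the meta-d'
    fit); ``'never'`` disables padding.
    """
    s1 = counts.counts_s1.astype(float)
    s2 = counts.counts_s2.astype(float)
    k = counts.n_bins
    if s1.sum() == 0 or s2.sum() == 0:
        raise ValueError("both stimulus classes must have trials")

    def rates(pad: float) -> tuple[float, float]:
        hr = (s1[:k].sum() + k * pad) / (s1.sum() + 2 * k * pad)
        far = (s2[:k].sum() + k * pad) / (s2.sum() + 2 * k * pad)
        return hr, far

    hr, far = rates(0.0)
    if padding == "always" or (padding == "auto" and
                               (hr in (0.0, 1.0) or far in (0.0, 1.0))):
        hr, far = rates(_pad_value(k))
    elif padding not in ("auto", "never", "always"):
        raise ValueError(f"unknown padding mode {padding!r}")
    zh, zf = norm.ppf(hr), norm.ppf(far)
    return SDTFit(dprime=float(zh - zf), criterion=float(-0.5 * (zh + zf)),
                  hr=float(hr), far=float(far))


def _correct_incorrect_by_bin(counts: ConfidenceCounts
                              ) -> tuple[np.ndarray, np.ndarray]:
    """Trial counts per confidence bin (1..K) for correct / incorrect trials."""
    k = counts.n_bins
    s1, s2 = counts.counts_s1, counts.counts_s2
    # response left cells: index i holds confidence k - i; right: i - (k - 1)
    correct = np.zeros(k, dtype=float)
    incorrect = np.zeros(k, dtype=float)
    for i in range(k):
        correct[k - 1 - i] += s1[i]        # stim left, resp left, conf k - i
        incorrect[k - 1 - i] += s2[i]      # stim right, resp left
    for i in range(k, 2 * k):
        correct[i - k] += s2[i]            # stim right, resp right, conf i-k+1
        incorrect[i - k] += s1[i]          # stim left, resp right
    return correct, incorrect


def type2_roc(counts: ConfidenceCounts) -> Type2ROC:
    """Empirical type-2 ROC and its area (AUROC2).

    Confidence distributions conditional on correct vs. incorrect (pooled
    across responses) are cumulated from the highest confidence level down;
    the area is computed by the trapezoid rule.
    """
    correct, incorrect = _correct_incorrect_by_bin(counts)
    if correct.sum() == 0 or incorrect.sum() == 0:
        raise ValueError("type-2 ROC requires >= 1 correct and >= 1 incorrect trial")
    p_c = correct / correct.sum()
    p_i = incorrect / incorrect.sum()
    hr2 = np.concatenate([[0.0], np.cumsum(p_c[::-1])])
    far2 = np.concatenate([[0.0], np.cumsum(p_i[::-1])])
    auroc2 = float(np.trapezoid(hr2, far2))
    return Type2ROC(p_conf_given_correct=p_c, p_conf_given_incorrect=p_i,
                    roc_points=np.column_stack([far2, hr2]), auroc2=auroc2)


# ---------------------------------------------------------------------------
# meta-d' likelihood machinery (batch-ready: leading axis = subjects)
# ---------------------------------------------------------------------------

def _cell_probs(meta_d, meta_c, t2_left, t2_right):
    """Cell probabilities under the meta-d' model.

    Parameters broadcast over a leading batch axis: ``meta_d``, ``meta_c``
    shape (B,), ``t2_left`` (B, K-1) ascending above meta_c, ``t2_right``
    (B, K-1) descending below.  Returns (p1, p2, p_left1, p_left2): cell
    probability tables (B, 2K) in canonical order for stimulus left/right
    and the response-'left' probabilities per stimulus.
    """
    meta_d = np.atleast_1d(np.asarray(meta_d, dtype=float))
    meta_c = np.atleast_1d(np.asarray(meta_c, dtype=float))
    t2_left = np.atleast_2d(np.asarray(t2_left, dtype=float))
    t2_right = np.atleast_2d(np.asarray(t2_right, dtype=float))
    # boundaries of the left-response region, descending: l_{K-1}..l_1, meta_c;
    # right-response region, descending: meta_c, r_1..r_{K-1}
    b_left = np.concatenate([t2_left[:, ::-1], meta_c[:, None]], axis=1)
    b_right = np.concatenate([meta_c[:, None], t2_right], axis=1)
    out = []
    p_left = []
    for sign in (+1.0, -1.0):          # stimulus left, right
        mu = sign * meta_d[:, None] / 2.0
        # left-response cells via upper tails (accurate for extreme mu)
        tail = ndtr(mu - b_left)       # P(x > b), increasing along columns
        pl_cells = np.concatenate(
            [tail[:, :1], tail[:, 1:] - tail[:, :-1]], axis=1)
        # right-response cells via lower tails
        cdf = ndtr(b_right - mu)       # P(x < b), decreasing along columns
        pr_cells = np.concatenate(
            [cdf[:, :-1] - cdf[:, 1:], cdf[:, -1:]], axis=1)
        out.append(np.concatenate(
            [np.maximum(pl_cells, 0.0), np.maximum(pr_cells, 0.0)], axis=1))
        p_left.append(tail[:, -1])     # P(x > meta_c)
    return out[0], out[1], p_left[0], p_left[1]


def type2_loglik(counts_s1, counts_s2, meta_d, meta_c, t2_left, t2_right):
    """Response-conditional type-2 log-likelihood (batched over subjects).

    For each stimulus class and response, each confidence cell contributes
    n * log(P(cell | stimulus) / P(response | stimulus)).
    """
    counts_s1 = np.atleast_2d(np.asarray(counts_s1, dtype=float))
    counts_s2 = np.atleast_2d(np.asarray(counts_s2, dtype=float))
    p1, p2, _, _ = _cell_probs(meta_d, meta_c, t2_left, t2_right)
    k = counts_s1.shape[1] // 2
    ll = np.zeros(counts_s1.shape[0])
    for counts, p in ((counts_s1, p1), (counts_s2, p2)):
        # normalise by the summed side mass so pcond is a proper conditional
        # distribution even when a response region's probability underflows
        presp = np.concatenate(
            [np.repeat(p[:, :k].sum(axis=1, keepdims=True), k, axis=1),
             np.repeat(p[:, k:].sum(axis=1, keepdims=True), k, axis=1)],
            axis=1)
        pcond = np.clip(p, _TINY, None) / np.clip(presp, _TINY, None)
        ll += (counts * np.log(np.clip(pcond, _TINY, 1.0))).sum(axis=1)
    return ll


def match_t2_criteria(counts_s1, counts_s2, meta_d, meta_c, n_iter: int = 50):
    """Type-2 criteria matching the observed response-conditional confidence
    distributions under the meta-d' model (batched; bisection per criterion).

    For each response side, criterion j is the evidence threshold at which
    the model's stimulus-mixture tail probability of 'confidence >= j+1
    given this response' equals the observed (padded) proportion.  Returns
    (t2_left ascending, t2_right descending), shapes (B, K-1).
    """
    c1 = np.atleast_2d(np.asarray(counts_s1, dtype=float))
    c2 = np.atleast_2d(np.asarray(counts_s2, dtype=float))
    meta_d = np.atleast_1d(np.asarray(meta_d, dtype=float))
    meta_c = np.atleast_1d(np.asarray(meta_c, dtype=float))
    b, k2 = c1.shape
    k = k2 // 2
    mu1 = meta_d / 2.0
    mu2 = -meta_d / 2.0

    # left response: cells 0..K-1 hold confidence K..1; tail conf >= j+1 is
    # the cumulative count over cells 0..K-1-j
    nl1, nl2 = c1[:, :k], c2[:, :k]
    tot_l = nl1.sum(axis=1) + nl2.sum(axis=1)
    w1 = nl1.sum(axis=1) / tot_l
    w2 = nl2.sum(axis=1) / tot_l
    q_left = (np.cumsum(nl1 + nl2, axis=1)[:, :k - 1]) / tot_l[:, None]
    denom1 = np.clip(1.0 - ndtr(meta_c - mu1), _TINY, None)
    denom2 = np.clip(1.0 - ndtr(meta_c - mu2), _TINY, None)

    lo = np.repeat(meta_c[:, None], k - 1, axis=1)
    hi = lo + 14.0
    for _ in range(n_iter):
        mid = 0.5 * (lo + hi)
        g = (w1[:, None] * (1.0 - ndtr(mid - mu1[:, None])) / denom1[:, None]
             + w2[:, None] * (1.0 - ndtr(mid - mu2[:, None])) / denom2[:, None])
        too_high = g > q_left  # tail too fat -> move criterion up
        lo = np.where(too_high, mid, lo)
        hi = np.where(too_high, hi, mid)
    # column j solved l_{K-1-j}; reverse to ascending l_1..l_{K-1}
    t2_left = (0.5 * (lo + hi))[:, ::-1]

    # right response: cells K..2K-1 hold confidence 1..K; tail conf >= j+1
    # cumulates from the highest-confidence end (most negative evidence)
    nr1, nr2 = c1[:, k:], c2[:, k:]
    tot_r = nr1.sum(axis=1) + nr2.sum(axis=1)
    v1 = nr1.sum(axis=1) / tot_r
    v2 = nr2.sum(axis=1) / tot_r
    q_right = (np.cumsum((nr1 + nr2)[:, ::-1], axis=1)[:, :k - 1]
               / tot_r[:, None])[:, ::-1]
    den1 = np.clip(ndtr(meta_c - mu1), _TINY, None)
    den2 = np.clip(ndtr(meta_c - mu2), _TINY, None)

    hi = np.repeat(meta_c[:, None], k - 1, axis=1)
    lo = hi - 14.0
    for _ in range(n_iter):
        mid = 0.5 * (lo + hi)
        g = (v1[:, None] * ndtr(mid - mu1[:, None]) / den1[:, None]
             + v2[:, None] * ndtr(mid - mu2[:, None]) / den2[:, None])
        too_high = g > q_right
        hi = np.where(too_high, mid, hi)
        lo = np.where(too_high, lo, mid)
    t2_right = 0.5 * (lo + hi)
    return t2_left, t2_right


def fit_meta_d(counts: ConfidenceCounts, max_meta_d: float = 10.0) -> MetaDFit:
    """Maximum-likelihood meta-d' and M-ratio for one subject x domain.

    Maximizes the response-conditional multinomial likelihood of the
    confidence counts under an equal-variance Gaussian model with free
    sensitivity meta-d', the type-1 criterion held at the fitted relative
    position (meta_c = (c/d') * meta-d'), and free ordered type-2 criteria
    on each response side.  Counts are padded (1/(2*2*n_bins) per cell)
    before the fit.  Non-convergence is flagged, parameters still returned.
    """
    k = counts.n_bins
    pad = _pad_value(k)
    c1 = counts.counts_s1.astype(float) + pad
    c2 = counts.counts_s2.astype(float) + pad
    t1 = fit_type1(counts, padding="always")
    if abs(t1.dprime) < 1e-12:
        raise ValueError("d' is zero; meta-d' model is not estimable")
    c_rel = t1.criterion / t1.dprime

    def unpack(theta):
        md = theta[0]
        mc = c_rel * md
        inc_l = np.maximum(theta[1:k], 1e-6)
        inc_r = np.maximum(theta[k:], 1e-6)
        t2l = mc + np.cumsum(inc_l)
        t2r = mc - np.cumsum(inc_r)
        return md, mc, t2l, t2r

    def nll(theta):
        md, mc, t2l, t2r = unpack(theta)
        return -type2_loglik(c1, c2, md, mc, t2l, t2r)[0]

    # start at meta-d' = d' with distribution-matched criteria
    md0 = t1.dprime
    mc0 = c_rel * md0
    t2l0, t2r0 = match_t2_criteria(c1, c2, md0, mc0)
    inc_l0 = np.maximum(np.diff(np.concatenate([[mc0], t2l0[0]])), 1e-4)
    inc_r0 = np.maximum(np.diff(np.concatenate([[mc0], t2r0[0]]) * -1.0), 1e-4)
    theta0 = np.concatenate([[md0], inc_l0, inc_r0])

    bounds = ([(-max_meta_d, max_meta_d)]
              + [(1e-6, 20.0)] * (2 * (k - 1)))
    res = minimize(nll, theta0, method="L-BFGS-B", bounds=bounds,
                   options=dict(ftol=1e-12, gtol=1e-8, maxiter=1000))
    md, mc, t2l, t2r = unpack(res.x)
    m_ratio = float(md / t1.dprime)
    return MetaDFit(meta_d=float(md), m_ratio=m_ratio, type1=t1,
                    type2_criteria=np.vstack([t2l, t2r]),
                    loglik=float(-res.fun), converged=bool(res.success))


def hdi(samples, mass: float = 0.95) -> tuple[float, float]:
    """Highest-density interval: the shortest contiguous interval containing
    ceil(mass * n) of the sorted samples."""
    x = np.sort(np.asarray(samples, dtype=float).ravel())
    x = x[np.isfinite(x)]
    n = x.size
    if n < 2:
        raise ValueError("hdi requires at least 2 finite samples")
    if not 0.0 < mass < 1.0:
        raise ValueError("mass must lie in (0, 1)")
    m = min(int(np.ceil(mass * n)), n)
    widths = x[m - 1:] - x[:n - m + 1]
    i = int(np.argmin(widths))
    return float(x[i]), float(x[i + m - 1])
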