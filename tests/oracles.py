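"""Independent reference computations used by the test suite.

These deliberately avoid the package's own code paths wherever possible:
the staircase oracle solves the exact Markov chain, the regression oracle
uses raw normal equations, the meta-d' oracle is a dense grid search over
the same likelihood surface.
"""

from __future__ import annotations

import numpy as np
from scipy.special import ndtr


def staircase_stationary_accuracy(p_correct: dict[int, float], floor: int,
                                  ceiling: int, harder_direction: int
                                  ) -> float:
    """Exact long-run accuracy of a 2-down-1-up staircase.

    State = (difficulty level, consecutive-correct counter in {0, 1});
    two consecutive correct -> one step harder, any error -> one step
    easier, clipped to [floor, ceiling].  Builds the transition matrix,
    solves for the stationary distribution, and returns the expected
    per-trial accuracy.
    """
    levels = list(range(floor, ceiling + 1))
    index = {(lv, cc): i for i, (lv, cc) in
             enumerate((lv, cc) for lv in levels for cc in (0, 1))}
    n = len(index)
    P = np.zeros((n, n))

    def clip(lv: int) -> int:
        return min(max(lv, floor), ceiling)

    for lv in levels:
        p = p_correct[lv]
        easier = clip(lv - harder_direction)
        harder = clip(lv + harder_direction)
        P[index[(lv, 0)], index[(lv, 1)]] += p
        P[index[(lv, 0)], index[(easier, 0)]] += 1 - p
        P[index[(lv, 1)], index[(harder, 0)]] += p
        P[index[(lv, 1)], index[(easier, 0)]] += 1 - p

    # stationary distribution: left null vector of (P - I), normalized
    a = np.vstack([P.T - np.eye(n), np.ones(n)])
    b = np.concatenate([np.zeros(n), [1.0]])
    pi, *_ = np.linalg.lstsq(a, b, rcond=None)
    pi = np.clip(pi, 0.0, None)
    pi /= pi.sum()
    acc = sum(pi[index[(lv, cc)]] * p_correct[lv]
              for lv in levels for cc in (0, 1))
    return float(acc)


def perception_accuracy_by_level(sens: float, floor: int = 1,
                                 ceiling: int = 30) -> dict[int, float]:
    """Unbiased 2AFC accuracy per colour-difference level: Phi(d'/2) with
    d' = sens * level / 15."""
    return {lv: float(ndtr(sens * (lv / 15.0) / 2.0))
            for lv in range(floor, ceiling + 1)}


def ols_normal_equations(y: np.ndarray, x: np.ndarray) -> np.ndarray:
    """Closed-form OLS coefficients (intercept first) via normal equations."""
    xt = np.column_stack([np.ones(len(y)), x])
    return np.linalg.solve(xt.T @ xt, xt.T @ y)


def hdi_bruteforce(samples, mass: float = 0.95) -> tuple[float, float]:
    """Shortest interval by exhaustive scan over all sorted windows."""
    x = np.sort(np.asarray(samples, dtype=float))
    m = int(np.ceil(mass * len(x)))
    best = (float("inf"), None, None)
    for i in range(len(x) - m + 1):
        w = x[i + m - 1] - x[i]
        if w < best[0]:
            best = (w, x[i], x[i + m - 1])
    return float(best[1]), float(best[2])


def auroc2_reference(n_correct_by_bin, n_incorrect_by_bin) -> float:
    """Trapezoid area under the cumulated conditional confidence curves."""
    c = np.asarray(n_correct_by_bin, dtype=float)
    i = np.asarray(n_incorrect_by_bin, dtype=float)
    hr = np.concatenate([[0.0], np.cumsum((c / c.sum())[::-1])])
    far = np.concatenate([[0.0], np.cumsum((i / i.sum())[::-1])])
    area = 0.0
    for k in range(1, len(hr)):
        area += 0.5 * (hr[k] + hr[k - 1]) * (far[k] - far[k - 1])
    return float(area)
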