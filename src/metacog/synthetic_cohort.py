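"""Synthetic cohorts of observers performing staircased 2AFC sessions.

Generates trial-level behavioural data for two cognitive domains (short-term
memory and perceptual discrimination) under an equal-variance Gaussian signal
detection model, with per-trial confidence on a 201-point slider, a
2-down-1-up difficulty staircase, and pre/post-task global self-performance
estimates (SPEs) on a 0-10 Likert scale.

The generative observer has four independently configurable metacognitive
characteristics: first-order sensitivity (a per-domain scaling of d'),
metacognitive efficiency (second-order evidence noise, parameterised through
a target M-ratio), metacognitive bias (an additive confidence offset), and a
global SPE level.  Age trends on bias, SPE, efficiency and sensitivity are
linear in years and configurable; the defaults emulate an age-stratified
design of 6 groups x 50 subjects (ages 18-83, 100 trials per domain) with
stable first-order performance and efficiency but declining confidence.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

DOMAINS = ("memory", "perception")

#: staircase anchor levels: memory starts at a 2-item set, perception at a
#: red/blue count difference of 15
MEMORY_START_LEVEL = 2
PERCEPTION_START_LEVEL = 15


@dataclass(frozen=True)
class StaircaseSpec:
    """Bounds and starting level of a 2-down-1-up difficulty staircase."""

    start: int
    floor: int
    ceiling: int
    #: +1 if larger level = harder (memory set size), -1 if larger = easier
    #: (perception colour-count difference)
    harder_direction: int

    def __post_init__(self) -> None:
        if not self.floor <= self.start <= self.ceiling:
            raise ValueError("staircase start level outside [floor, ceiling]")
        if self.harder_direction not in (-1, 1):
            raise ValueError("harder_direction must be +1 or -1")


DEFAULT_STAIRCASES = {
    "memory": StaircaseSpec(start=MEMORY_START_LEVEL, floor=2, ceiling=15,
                            harder_direction=+1),
    "perception": StaircaseSpec(start=PERCEPTION_START_LEVEL, floor=1,
                                ceiling=30, harder_direction=-1),
}


@dataclass
class StaircaseState:
    """Mutable state of one running staircase."""

    domain: str
    level: int
    consecutive_correct: int
    floor: int
    ceiling: int
    harder_direction: int
    history: list[int] = field(default_factory=list)

    @classmethod
    def fresh(cls, domain: str, spec: StaircaseSpec | None = None) -> "StaircaseState":
        spec = spec or DEFAULT_STAIRCASES[domain]
        return cls(domain=domain, level=spec.start, consecutive_correct=0,
                   floor=spec.floor, ceiling=spec.ceiling,
                   harder_direction=spec.harder_direction)

    def update(self, correct: bool) -> None:
        """Apply the 2-down-1-up rule after one trial.

        Two consecutive correct responses step one level harder; any error
        steps one level easier.  The consecutive-correct counter resets on
        every error and on every (attempted) level change; levels are clipped
        to [floor, ceiling].
        """
        self.history.append(self.level)
        if correct:
            self.consecutive_correct += 1
            if self.consecutive_correct >= 2:
                self.level = self._clip(self.level + self.harder_direction)
                self.consecutive_correct = 0
        else:
            self.level = self._clip(self.level - self.harder_direction)
            self.consecutive_correct = 0

    def _clip(self, level: int) -> int:
        return min(max(level, self.floor), self.ceiling)


@dataclass(frozen=True)
class ObserverParams:
    """Generative parameters of one synthetic subject.

    ``sens_*`` scale the difficulty->d' psychometric law per domain.
    ``meta_noise_*`` is the SD of zero-mean Gaussian noise added to the
    decision evidence before the confidence computation: 0 gives an ideal
    metacognitive observer (M-ratio 1), larger values degrade meta-d' while
    leaving d' untouched.  ``conf_bias_*`` shifts the confidence slider
    additively; ``conf_gain`` is the slope of the evidence->slider map.
    ``spe_mean_*`` is the expected global self-performance estimate (0-10).
    """

    subject_id: str
    age: int
    age_group: int
    sens_memory: float
    sens_perception: float
    meta_noise_memory: float
    meta_noise_perception: float
    conf_bias_memory: float
    conf_bias_perception: float
    conf_gain: float
    spe_mean_memory: float
    spe_mean_perception: float
    criterion: float = 0.0
    decision_noise_memory: float = 0.0
    decision_noise_perception: float = 0.0
    rt_mu_log: float = 0.2
    rt_sd_log: float = 0.5
    rt_p_slow: float = 0.0025
    sex: str = "female"

    def __post_init__(self) -> None:
        if self.age < 18:
            raise ValueError("age must be >= 18")
        if self.meta_noise_memory < 0 or self.meta_noise_perception < 0:
            raise ValueError("meta_noise must be >= 0")
        if self.decision_noise_memory < 0 or self.decision_noise_perception < 0:
            raise ValueError("decision_noise must be >= 0")
        if self.conf_gain <= 0:
            raise ValueError("conf_gain must be > 0")
        for v in (self.spe_mean_memory, self.spe_mean_perception):
            if not 0.0 <= v <= 10.0:
                raise ValueError("spe_mean must lie in [0, 10]")

    def sens(self, domain: str) -> float:
        return self.sens_memory if domain == "memory" else self.sens_perception

    def meta_noise(self, domain: str) -> float:
        return (self.meta_noise_memory if domain == "memory"
                else self.meta_noise_perception)

    def conf_bias(self, domain: str) -> float:
        return (self.conf_bias_memory if domain == "memory"
                else self.conf_bias_perception)

    def decision_noise(self, domain: str) -> float:
        return (self.decision_noise_memory if domain == "memory"
                else self.decision_noise_perception)

    def spe_mean(self, domain: str) -> float:
        return (self.spe_mean_memory if domain == "memory"
                else self.spe_mean_perception)


@dataclass(frozen=True)
class TrialRecord:
    subject_id: str
    domain: str
    trial_index: int  # 1-based within subject x domain
    difficulty_level: int
    stimulus_side: str
    response_side: str
    correct: bool
    confidence_raw: int
    rt_decision: float
    rt_confidence: float


@dataclass(frozen=True)
class SPERecord:
    subject_id: str
    domain: str
    phase: str  # "pre" | "post"
    rating: int


@dataclass(frozen=True)
class CohortConfig:
    """Population and design parameters for a synthetic cohort.

    Defaults emulate an age-stratified adult-lifespan study: 6 age groups of
    50 subjects, 100 staircased trials per domain, first-order sensitivity
    and metacognitive efficiency flat in age, and negative linear age trends
    in local confidence bias (slider units/year) and global SPEs (Likert
    units/year).  Age slopes act on population means relative to
    ``reference_age``; cross-domain correlations induce domain-generality of
    efficiency, bias and SPEs.
    """

    n_per_group: int = 50
    group_brackets: tuple[tuple[int, int], ...] = (
        (18, 27), (28, 37), (38, 47), (48, 57), (58, 67), (68, 83))
    trials_per_domain: int = 100
    reference_age: float = 48.0

    # first-order sensitivity (log-normal across subjects)
    sens_memory_mean: float = 2.7
    sens_perception_mean: float = 2.3
    sens_sd_log: float = 0.25
    sens_age_slope_log: float = 0.0  # per year, on log sensitivity

    # metacognitive efficiency: target M-ratio, log-normal across subjects,
    # correlated across domains; meta_noise = sqrt(1/M^2 - 1)
    mratio_memory_mean: float = 1.0
    mratio_perception_mean: float = 0.55
    mratio_sd_log: float = 0.4
    mratio_cross_domain_rho: float = 0.8
    mratio_age_slope_log: float = 0.0  # per year, on log M-ratio
    mratio_clip: tuple[float, float] = (0.1, 2.5)

    # local confidence bias (slider units)
    conf_bias_mean: float = 0.0
    conf_bias_sd: float = 18.0
    conf_bias_cross_domain_rho: float = 0.8
    conf_bias_age_slope: float = -0.3  # slider units per year

    # confidence gain (log-normal)
    conf_gain_mean: float = 1.5
    conf_gain_sd_log: float = 0.3

    # global self-performance estimates (0-10 Likert)
    spe_mean: float = 5.5
    spe_sd: float = 1.3
    spe_cross_domain_rho: float = 0.7
    spe_age_slope: float = -0.025  # Likert units per year
    spe_post_offset: float = 0.0
    spe_rating_noise_sd: float = 0.8

    # type-1 criterion
    criterion_mean: float = 0.0
    criterion_sd: float = 0.1

    # response times (log-normal base, rare slow trials beyond 30 s)
    rt_mu_log: float = 0.2
    rt_sd_log: float = 0.5
    rt_p_slow: float = 0.0025

    staircases: dict = field(default_factory=lambda: dict(DEFAULT_STAIRCASES))
    rng_seed: int = 0

    def __post_init__(self) -> None:
        for sd in (self.sens_sd_log, self.mratio_sd_log, self.conf_bias_sd,
                   self.conf_gain_sd_log, self.spe_sd, self.criterion_sd,
                   self.spe_rating_noise_sd):
            if sd < 0:
                raise ValueError("between-subject SDs must be >= 0")
        brackets = sorted(self.group_brackets)
        for lo, hi in brackets:
            if lo > hi or lo < 18:
                raise ValueError(f"invalid age bracket ({lo}, {hi})")
        for (lo1, hi1), (lo2, hi2) in zip(brackets, brackets[1:]):
            if hi1 >= lo2:
                raise ValueError("age brackets must not overlap")

    def bracket_of(self, age: int) -> int:
        """1-based age-group index for ``age``; raises if outside all brackets."""
        for i, (lo, hi) in enumerate(self.group_brackets, start=1):
            if lo <= age <= hi:
                return i
        raise ValueError(f"age {age} outside all configured brackets")


#: Empirical calibration constant of the meta-noise -> M-ratio map under the
#: signed-evidence confidence rule: the fitted M-ratio of a large-n session
#: tracks 1/sqrt(1 + k * sigma^2) with k ~= 2.5 (response conditioning makes
#: second-order noise more destructive than the naive 1/sqrt(1 + sigma^2)).
_META_NOISE_CALIBRATION = 2.5

#: Matching constant for the decision-noise route to supra-optimal M-ratios:
#: with response jitter delta added after the evidence (confidence still reads
#: the clean evidence), fitted M tracks sqrt(1 + k2 * delta^2), k2 ~= 2.6.
_DECISION_NOISE_CALIBRATION = 2.6


def meta_noise_for_mratio(m_ratio: float) -> float:
    """Second-order noise SD targeting a given fitted M-ratio (<= 1)."""
    if not 0.0 < m_ratio <= 1.0:
        raise ValueError("target M-ratio must lie in (0, 1]")
    return math.sqrt(max(1.0 / m_ratio**2 - 1.0, 0.0)
                     / _META_NOISE_CALIBRATION)


def decision_noise_for_mratio(m_ratio: float) -> float:
    """First-order response-jitter SD targeting a fitted M-ratio (>= 1).

    Decision noise applied after the evidence degrades d' but not the
    confidence signal, so the fitted meta-d' exceeds the fitted d' — the
    standard route to supra-optimal metacognitive efficiency.
    """
    if m_ratio < 1.0:
        raise ValueError("decision-noise route requires target M-ratio >= 1")
    return math.sqrt((m_ratio**2 - 1.0) / _DECISION_NOISE_CALIBRATION)


def noises_for_mratio(m_ratio: float) -> tuple[float, float]:
    """(meta_noise, decision_noise) pair targeting a fitted M-ratio."""
    if m_ratio <= 1.0:
        return meta_noise_for_mratio(m_ratio), 0.0
    return 0.0, decision_noise_for_mratio(m_ratio)


def _correlated_pair(rng: np.random.Generator, rho: float) -> tuple[float, float]:
    """Two standard-normal draws with correlation rho (shared-factor form)."""
    if not -1.0 <= rho <= 1.0:
        raise ValueError("correlation must lie in [-1, 1]")
    z0 = rng.standard_normal()
    z1, z2 = rng.standard_normal(2)
    a = math.sqrt(abs(rho))
    b = math.sqrt(1.0 - abs(rho))
    sign = 1.0 if rho >= 0 else -1.0
    return a * z0 + b * z1, sign * a * z0 + b * z2


def sample_observer(cfg: CohortConfig, age: int,
                    rng: np.random.Generator | int,
                    subject_id: str = "s0") -> ObserverParams:
    """Draw one observer's generative parameters from the population model.

    Population means receive the configured linear age slopes (relative to
    ``cfg.reference_age``); between-subject variation uses the configured
    SDs, with cross-domain correlation for efficiency, bias and SPE.
    """
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    group = cfg.bracket_of(int(age))
    dage = age - cfg.reference_age

    sens_mem = math.exp(math.log(cfg.sens_memory_mean)
                        + cfg.sens_age_slope_log * dage
                        + cfg.sens_sd_log * rng.standard_normal())
    sens_per = math.exp(math.log(cfg.sens_perception_mean)
                        + cfg.sens_age_slope_log * dage
                        + cfg.sens_sd_log * rng.standard_normal())

    zm, zp = _correlated_pair(rng, cfg.mratio_cross_domain_rho)
    lo, hi = cfg.mratio_clip
    m_mem = min(max(math.exp(math.log(cfg.mratio_memory_mean)
                             + cfg.mratio_age_slope_log * dage
                             + cfg.mratio_sd_log * zm), lo), hi)
    m_per = min(max(math.exp(math.log(cfg.mratio_perception_mean)
                             + cfg.mratio_age_slope_log * dage
                             + cfg.mratio_sd_log * zp), lo), hi)
    noise_mem, dnoise_mem = noises_for_mratio(m_mem)
    noise_per, dnoise_per = noises_for_mratio(m_per)

    zbm, zbp = _correlated_pair(rng, cfg.conf_bias_cross_domain_rho)
    bias_mean = cfg.conf_bias_mean + cfg.conf_bias_age_slope * dage
    bias_mem = bias_mean + cfg.conf_bias_sd * zbm
    bias_per = bias_mean + cfg.conf_bias_sd * zbp

    gain = math.exp(math.log(cfg.conf_gain_mean)
                    + cfg.conf_gain_sd_log * rng.standard_normal())

    zsm, zsp = _correlated_pair(rng, cfg.spe_cross_domain_rho)
    spe_mean = cfg.spe_mean + cfg.spe_age_slope * dage
    spe_mem = min(max(spe_mean + cfg.spe_sd * zsm, 0.0), 10.0)
    spe_per = min(max(spe_mean + cfg.spe_sd * zsp, 0.0), 10.0)

    crit = cfg.criterion_mean + cfg.criterion_sd * rng.standard_normal()
    sex = "female" if rng.random() < 0.5 else "male"

    return ObserverParams(
        subject_id=subject_id, age=int(age), age_group=group,
        sens_memory=sens_mem, sens_perception=sens_per,
        meta_noise_memory=noise_mem, meta_noise_perception=noise_per,
        conf_bias_memory=bias_mem, conf_bias_perception=bias_per,
        conf_gain=gain, spe_mean_memory=spe_mem, spe_mean_perception=spe_per,
        criterion=crit, decision_noise_memory=dnoise_mem,
        decision_noise_perception=dnoise_per,
        rt_mu_log=cfg.rt_mu_log, rt_sd_log=cfg.rt_sd_log,
        rt_p_slow=cfg.rt_p_slow, sex=sex)


def psychometric_dprime(obs: ObserverParams | float, domain: str,
                        level: float) -> float:
    """Difficulty -> d' law, anchored at the staircase starting levels.

    memory: d' = sens * (2 / set_size) — larger memorisation sets are harder;
    perception: d' = sens * (difference / 15) — larger colour-count
    differences are easier.  At the starting level each law returns the
    observer's sensitivity constant unchanged.
    """
    if level < 1:
        raise ValueError("difficulty level must be >= 1")
    sens = obs.sens(domain) if isinstance(obs, ObserverParams) else float(obs)
    if domain == "memory":
        return sens * (MEMORY_START_LEVEL / level)
    if domain == "perception":
        return sens * (level / PERCEPTION_START_LEVEL)
    raise ValueError(f"unknown domain {domain!r}")


def _confidence_from_evidence(obs: ObserverParams, domain: str,
                              x2: float, response_side: str) -> int:
    """Map second-order evidence to the -100..+100 slider.

    The signed distance of the (noisy) second-order evidence from the
    criterion, taken in the direction of the chosen response, is squashed
    logistically onto the slider range, then shifted by the subject's
    additive confidence bias and clipped.  Second-order evidence that lands
    on the wrong side of the criterion (contradicting the response) yields
    low confidence, as in the standard meta-d' generative model.
    """
    direction = 1.0 if response_side == "left" else -1.0
    u = obs.conf_gain * direction * (x2 - obs.criterion)
    squashed = 200.0 / (1.0 + math.exp(-u)) - 100.0  # in (-100, 100)
    conf = round(squashed + obs.conf_bias(domain))
    return int(min(max(conf, -100), 100))


def _rt_draw(obs: ObserverParams, z: float, u_slow: float, e_slow: float) -> float:
    if u_slow < obs.rt_p_slow:
        return 30.0 + 10.0 * e_slow
    return math.exp(obs.rt_mu_log + obs.rt_sd_log * z)


def _trial_from_draws(obs: ObserverParams, domain: str, level: int,
                      trial_index: int, stimulus_side: str,
                      z1: float, z2: float, z3: float,
                      rt_draws: tuple) -> TrialRecord:
    dprime = psychometric_dprime(obs, domain, level)
    mu = dprime / 2.0 if stimulus_side == "left" else -dprime / 2.0
    x = mu + z1
    # response jitter degrades the decision but not the confidence signal
    x_resp = x + obs.decision_noise(domain) * z3
    response_side = "left" if x_resp > obs.criterion else "right"
    correct = response_side == stimulus_side
    x2 = x + obs.meta_noise(domain) * z2
    conf = _confidence_from_evidence(obs, domain, x2, response_side)
    za, ua, ea, zb, ub, eb = rt_draws
    return TrialRecord(
        subject_id=obs.subject_id, domain=domain, trial_index=trial_index,
        difficulty_level=int(level), stimulus_side=stimulus_side,
        response_side=response_side, correct=correct, confidence_raw=conf,
        rt_decision=_rt_draw(obs, za, ua, ea),
        rt_confidence=_rt_draw(obs, zb, ub, eb))


def simulate_trial(obs: ObserverParams, domain: str, level: int,
                   rng: np.random.Generator | int,
                   trial_index: int = 1,
                   stimulus_side: str | None = None) -> TrialRecord:
    """Simulate one 2AFC trial at a fixed difficulty level.

    Evidence x ~ Normal(+-d'/2, 1) (left stimulus positive); the response is
    'left' when x exceeds the type-1 criterion.  Second-order evidence
    x2 = x + Normal(0, meta_noise) drives the confidence slider.
    """
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    if stimulus_side is None:
        stimulus_side = "left" if rng.random() < 0.5 else "right"
    z1, z2, z3 = rng.standard_normal(3)
    rt = (rng.standard_normal(), rng.random(), rng.standard_exponential(),
          rng.standard_normal(), rng.random(), rng.standard_exponential())
    return _trial_from_draws(obs, domain, level, trial_index, stimulus_side,
                             z1, z2, z3, rt)


def _balanced_sides(n: int, rng: np.random.Generator) -> list[str]:
    sides = ["left"] * (n // 2) + ["right"] * (n - n // 2)
    rng.shuffle(sides)
    return sides


def run_staircase_session(obs: ObserverParams, domain: str, n_trials: int,
                          rng: np.random.Generator | int,
                          staircase: StaircaseSpec | None = None
                          ) -> list[TrialRecord]:
    """Run one 2-down-1-up staircased session of ``n_trials`` 2AFC trials.

    Stimulus sides are exactly balanced (50/50, shuffled).  Difficulty steps
    one level harder after two consecutive correct responses and one level
    easier after any error, clipped to the staircase bounds.
    """
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    state = StaircaseState.fresh(domain, staircase)
    sides = _balanced_sides(n_trials, rng)
    z1 = rng.standard_normal(n_trials)
    z2 = rng.standard_normal(n_trials)
    z3 = rng.standard_normal(n_trials)
    zrt = rng.standard_normal((n_trials, 2))
    urt = rng.random((n_trials, 2))
    ert = rng.standard_exponential((n_trials, 2))
    records: list[TrialRecord] = []
    for t in range(n_trials):
        rt = (zrt[t, 0], urt[t, 0], ert[t, 0], zrt[t, 1], urt[t, 1], ert[t, 1])
        rec = _trial_from_draws(obs, domain, state.level, t + 1, sides[t],
                                z1[t], z2[t], z3[t], rt)
        records.append(rec)
        state.update(rec.correct)
    return records


def generate_spes(obs: ObserverParams, rng: np.random.Generator | int,
                  cfg: CohortConfig | None = None) -> list[SPERecord]:
    """Pre- and post-task global SPE ratings for both domains (4 records)."""
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    cfg = cfg or CohortConfig()
    out = []
    for domain in DOMAINS:
        for phase in ("pre", "post"):
            offset = cfg.spe_post_offset if phase == "post" else 0.0
            raw = (obs.spe_mean(domain) + offset
                   + cfg.spe_rating_noise_sd * rng.standard_normal())
            out.append(SPERecord(subject_id=obs.subject_id, domain=domain,
                                 phase=phase,
                                 rating=int(round(min(max(raw, 0.0), 10.0)))))
    return out


def _quantile_t2_criteria(meta_d: float, meta_c: float,
                          n_bins: int) -> tuple[np.ndarray, np.ndarray]:
    """Type-2 criteria at equal-occupancy (quantile) positions.

    Criteria are placed so each confidence bin receives equal probability
    conditional on the response, mirroring the per-subject quantile binning
    applied to slider confidence in preprocessing.  Solved by bisection on
    the stimulus-mixture tail probabilities.
    """
    from scipy.special import ndtr as _ndtr

    mus = np.array([meta_d / 2.0, -meta_d / 2.0])

    def tail_above(x):  # P(evidence > x), stimulus mixture
        return 0.5 * (_ndtr(mus[0] - x) + _ndtr(mus[1] - x))

    p_resp_left = tail_above(meta_c)
    targets = 1.0 - np.arange(1, n_bins) / n_bins  # conditional tail masses
    lo = np.full(n_bins - 1, meta_c)
    hi = lo + 14.0
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        g = tail_above(mid) / p_resp_left
        high = g > targets
        lo = np.where(high, mid, lo)
        hi = np.where(high, hi, mid)
    t2_left = 0.5 * (lo + hi)

    p_resp_right = 1.0 - p_resp_left
    hi = np.full(n_bins - 1, meta_c)
    lo = hi - 14.0
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        g = (1.0 - tail_above(mid)) / p_resp_right
        high = g > targets
        hi = np.where(high, mid, hi)
        lo = np.where(high, lo, mid)
    t2_right = 0.5 * (lo + hi)
    return t2_left, t2_right


def simulate_metad_counts(dprime: float, criterion: float, m_ratio: float,
                          n_trials: int, rng: np.random.Generator | int,
                          n_bins: int = 6,
                          criterion_spacing: float | None = None,
                          subject_id: str = "s0",
                          domain: str = "memory"):
    """Simulate a confidence count table directly from the meta-d' model.

    Type-1 responses come from an equal-variance Gaussian observer with
    sensitivity ``dprime`` and criterion ``criterion``; for each trial the
    confidence bin is then drawn from the meta-d' model's response-
    conditional distribution with sensitivity meta-d' = m_ratio * dprime
    and the type-1 criterion held at its relative position.  Type-2
    criteria sit at equal-occupancy (quantile) positions by default,
    matching the quantile-binned count tables the preprocessing stage
    produces; pass ``criterion_spacing`` for fixed spacing instead.  This
    is the canonical generative process for parameter-recovery studies of
    metacognitive efficiency.
    """
    from .preprocess import ConfidenceCounts
    from .sdt_core import _cell_probs

    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    if dprime <= 0:
        raise ValueError("dprime must be > 0")
    meta_d = m_ratio * dprime
    meta_c = (criterion / dprime) * meta_d
    if criterion_spacing is None:
        t2_left, t2_right = _quantile_t2_criteria(meta_d, meta_c, n_bins)
    else:
        inc = criterion_spacing * np.arange(1, n_bins)
        t2_left = meta_c + inc
        t2_right = meta_c - inc
    p1, p2, _, _ = _cell_probs(meta_d, meta_c, t2_left, t2_right)
    # type-1 response outcome per stimulus under (dprime, criterion)
    from scipy.special import ndtr as _ndtr
    p_left = {"left": 1.0 - _ndtr(criterion - dprime / 2.0),
              "right": 1.0 - _ndtr(criterion + dprime / 2.0)}
    n_left_stim = n_trials // 2
    counts = {}
    for stim, n_stim, p in (("left", n_left_stim, p1[0]),
                            ("right", n_trials - n_left_stim, p2[0])):
        n_resp_left = rng.binomial(n_stim, p_left[stim])
        v = np.zeros(2 * n_bins, dtype=int)
        k = n_bins
        pl = p[:k] / p[:k].sum()
        pr = p[k:] / p[k:].sum()
        v[:k] = rng.multinomial(n_resp_left, pl)
        v[k:] = rng.multinomial(n_stim - n_resp_left, pr)
        counts[stim] = v
    return ConfidenceCounts(subject_id=subject_id, domain=domain,
                            n_bins=n_bins, counts_s1=counts["left"],
                            counts_s2=counts["right"])


def generate_cohort(cfg: CohortConfig | None = None,
                    seed: int | None = None
                    ) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Generate a full cohort: (trial table, SPE table, subject table).

    Exactly ``n_per_group`` subjects per age bracket, ``trials_per_domain``
    staircased trials per subject per domain, four SPE records per subject.
    Fully reproducible: one master seed fans out to per-subject streams via
    ``numpy.random.SeedSequence.spawn``.  The subject table carries the
    generative parameters (``true_*`` columns) for parameter-recovery use.
    """
    cfg = cfg or CohortConfig()
    master = np.random.SeedSequence(cfg.rng_seed if seed is None else seed)
    n_subjects = cfg.n_per_group * len(cfg.group_brackets)
    seeds = master.spawn(n_subjects)

    trial_rows: list[tuple] = []
    spe_rows: list[tuple] = []
    subj_rows: list[dict] = []
    idx = 0
    for gi, (lo, hi) in enumerate(cfg.group_brackets, start=1):
        for _ in range(cfg.n_per_group):
            rng = np.random.default_rng(seeds[idx])
            sid = f"sub{idx:04d}"
            age = int(rng.integers(lo, hi + 1))
            obs = sample_observer(cfg, age, rng, subject_id=sid)
            for domain in DOMAINS:
                for rec in run_staircase_session(
                        obs, domain, cfg.trials_per_domain, rng,
                        cfg.staircases.get(domain)):
                    trial_rows.append((
                        sid, age, gi, domain, rec.trial_index,
                        rec.difficulty_level, rec.response_side,
                        rec.stimulus_side, rec.correct, rec.confidence_raw,
                        rec.rt_decision, rec.rt_confidence))
            for s in generate_spes(obs, rng, cfg):
                spe_rows.append((sid, s.domain, s.phase, s.rating))
            subj_rows.append(dict(
                subject_id=sid, age=age, age_group=gi, sex=obs.sex,
                true_sens_memory=obs.sens_memory,
                true_sens_perception=obs.sens_perception,
                true_meta_noise_memory=obs.meta_noise_memory,
                true_meta_noise_perception=obs.meta_noise_perception,
                true_decision_noise_memory=obs.decision_noise_memory,
                true_decision_noise_perception=obs.decision_noise_perception,
                true_conf_bias_memory=obs.conf_bias_memory,
                true_conf_bias_perception=obs.conf_bias_perception,
                true_conf_gain=obs.conf_gain,
                true_spe_mean_memory=obs.spe_mean_memory,
                true_spe_mean_perception=obs.spe_mean_perception,
                true_criterion=obs.criterion))
            idx += 1

    trials = pd.DataFrame(trial_rows, columns=[
        "subject_id", "age", "age_group", "domain", "trial_index",
        "difficulty_level", "response_side", "stimulus_side", "correct",
        "confidence_raw", "rt_decision_s", "rt_confidence_s"])
    spes = pd.DataFrame(spe_rows,
                        columns=["subject_id", "domain", "phase", "rating"])
    subjects = pd.DataFrame(subj_rows)
    return trials, spes, subjects
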