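"""Trial/subject exclusions, confidence quantile binning, count assembly.

Turns a raw trial table into the sufficient statistic of the meta-d' model:
per subject x domain, response-conditional trial counts over (response side x
confidence bin) for each stimulus class.  The 'left' response is designated
as the signal for hit/false-alarm bookkeeping.

All operations here are deterministic (no RNG anywhere in this module).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

RT_LIMIT_S = 30.0
BURN_IN_TRIALS = 20
DEFAULT_N_BINS = 6

_REQUIRED_COLS = ("subject_id", "domain", "trial_index", "confidence_raw")


@dataclass(frozen=True)
class ConfidenceCounts:
    """Response-conditional confidence counts for one subject x domain.

    ``counts_s1`` (stimulus 'left') and ``counts_s2`` (stimulus 'right') are
    integer vectors of length ``2 * n_bins`` in canonical order: (response
    left, highest confidence) down to (response left, lowest), then (response
    right, lowest) up to (response right, highest).
    """

    subject_id: str
    domain: str
    n_bins: int
    counts_s1: np.ndarray
    counts_s2: np.ndarray

    def __post_init__(self) -> None:
        s1 = np.asarray(self.counts_s1, dtype=int)
        s2 = np.asarray(self.counts_s2, dtype=int)
        object.__setattr__(self, "counts_s1", s1)
        object.__setattr__(self, "counts_s2", s2)
        if s1.shape != (2 * self.n_bins,) or s2.shape != (2 * self.n_bins,):
            raise ValueError("count vectors must have length 2 * n_bins")
        if (s1 < 0).any() or (s2 < 0).any():
            raise ValueError("counts must be non-negative")
        if s1.sum() == 0 or s2.sum() == 0:
            raise ValueError(
                f"{self.subject_id}/{self.domain}: a stimulus class has no trials")

    @property
    def n_trials(self) -> int:
        return int(self.counts_s1.sum() + self.counts_s2.sum())


@dataclass
class ExclusionReport:
    """Bookkeeping of trial and subject exclusions, one tally per rule."""

    n_trials_in: int = 0
    n_burnin_excluded: int = 0
    n_rt_excluded: int = 0
    n_trials_out: int = 0
    subjects_excluded: list = field(default_factory=list)

    def to_dict(self) -> dict:
        return dict(n_trials_in=self.n_trials_in,
                    n_burnin_excluded=self.n_burnin_excluded,
                    n_rt_excluded=self.n_rt_excluded,
                    n_trials_out=self.n_trials_out,
                    subjects_excluded=list(self.subjects_excluded))


def _check_columns(trials: pd.DataFrame, extra: tuple[str, ...] = ()) -> None:
    missing = [c for c in (*_REQUIRED_COLS, *extra) if c not in trials.columns]
    if missing:
        raise ValueError(f"trial table missing columns: {missing}")


def exclude_trials(trials: pd.DataFrame,
                   burn_in: int = BURN_IN_TRIALS,
                   rt_limit: float = RT_LIMIT_S
                   ) -> tuple[pd.DataFrame, ExclusionReport]:
    """Drop staircase burn-in trials, then slow trials.

    The first ``burn_in`` trials per subject x domain are removed (staircase
    stabilisation), then any remaining trial whose decision or confidence
    response time exceeds ``rt_limit`` seconds.  Each rule is tallied
    separately in the report.
    """
    report = ExclusionReport(n_trials_in=len(trials))
    if trials.empty:
        return trials.copy(), report
    _check_columns(trials, extra=("rt_decision_s", "rt_confidence_s"))

    kept = trials[trials["trial_index"] > burn_in]
    report.n_burnin_excluded = len(trials) - len(kept)
    slow = (kept["rt_decision_s"] > rt_limit) | (kept["rt_confidence_s"] > rt_limit)
    report.n_rt_excluded = int(slow.sum())
    kept = kept[~slow].copy()
    report.n_trials_out = len(kept)
    return kept, report


def exclude_constant_confidence_subjects(
        trials: pd.DataFrame) -> tuple[pd.DataFrame, ExclusionReport]:
    """Drop subjects whose confidence never varies within a domain.

    A subject giving one identical rating for every trial of either domain
    precludes estimation of metacognitive efficiency and is removed from
    both domains.
    """
    report = ExclusionReport(n_trials_in=len(trials))
    if trials.empty:
        report.n_trials_out = 0
        return trials.copy(), report
    _check_columns(trials)
    nunique = trials.groupby(["subject_id", "domain"])["confidence_raw"].nunique()
    bad = nunique[nunique <= 1]
    bad_subjects = sorted(set(bad.index.get_level_values("subject_id")))
    for sid in bad_subjects:
        domains = sorted(bad.loc[sid].index) if sid in bad.index else []
        report.subjects_excluded.append(
            dict(subject_id=sid, reason="constant confidence",
                 domains=domains))
    kept = trials[~trials["subject_id"].isin(bad_subjects)].copy()
    report.n_trials_out = len(kept)
    return kept, report


def bin_confidence(trials: pd.DataFrame,
                   n_bins: int = DEFAULT_N_BINS) -> pd.DataFrame:
    """Assign per-subject, per-domain quantile confidence bins (1..n_bins).

    Bins are equal-probability quantile bins of the raw slider values,
    estimated separately for each subject within each domain.  Ties are
    broken by stable rank order (first occurrence gets the lower rank), so
    bin occupancies differ by at most one when enough distinct values exist,
    and the assignment is invariant to any strictly monotone transform of
    the slider scale.
    """
    _check_columns(trials)
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    sizes = trials.groupby(["subject_id", "domain"])["confidence_raw"].size()
    too_few = sizes[sizes < n_bins]
    if len(too_few):
        sid, dom = too_few.index[0]
        raise ValueError(
            f"subject {sid} has fewer than {n_bins} trials in {dom}")
    out = trials.copy()
    rank = out.groupby(["subject_id", "domain"])["confidence_raw"] \
              .rank(method="first").astype(int)
    n = out.groupby(["subject_id", "domain"])["confidence_raw"] \
           .transform("size").astype(int)
    out["confidence_bin"] = ((rank - 1) * n_bins // n + 1).astype(int)
    return out


def assemble_counts(trials: pd.DataFrame,
                    n_bins: int = DEFAULT_N_BINS) -> list[ConfidenceCounts]:
    """Cross-tabulate binned trials into per-subject ConfidenceCounts.

    Layout per stimulus class (length 2*n_bins): response 'left' from
    highest to lowest confidence, then response 'right' from lowest to
    highest.  Zero cells are retained (padding is a fit-time concern).
    """
    _check_columns(trials, extra=("confidence_bin", "stimulus_side",
                                  "response_side"))
    out: list[ConfidenceCounts] = []
    for (sid, dom), grp in trials.groupby(["subject_id", "domain"], sort=True):
        vecs = {}
        for stim in ("left", "right"):
            sub = grp[grp["stimulus_side"] == stim]
            if sub.empty:
                raise ValueError(
                    f"{sid}/{dom}: stimulus class {stim!r} absent")
            v = np.zeros(2 * n_bins, dtype=int)
            bins = sub["confidence_bin"].to_numpy()
            left = (sub["response_side"] == "left").to_numpy()
            # response left: index n_bins - bin; response right: n_bins - 1 + bin
            idx = np.where(left, n_bins - bins, n_bins - 1 + bins)
            np.add.at(v, idx, 1)
            vecs[stim] = v
        out.append(ConfidenceCounts(subject_id=sid, domain=dom, n_bins=n_bins,
                                    counts_s1=vecs["left"],
                                    counts_s2=vecs["right"]))
    return out


def counts_to_frame(counts: list[ConfidenceCounts]) -> pd.DataFrame:
    """Serialize count tables: one row per subject x domain, 4*n_bins columns.

    Columns ``s1_00..`` / ``s2_00..`` follow the canonical cell order.
    """
    rows = []
    for c in counts:
        row = {"subject_id": c.subject_id, "domain": c.domain,
               "n_bins": c.n_bins}
        for i, v in enumerate(c.counts_s1):
            row[f"s1_{i:02d}"] = int(v)
        for i, v in enumerate(c.counts_s2):
            row[f"s2_{i:02d}"] = int(v)
        rows.append(row)
    return pd.DataFrame(rows)


def frame_to_counts(df: pd.DataFrame) -> list[ConfidenceCounts]:
    out = []
    for _, row in df.iterrows():
        k = int(row["n_bins"])
        s1 = np.array([row[f"s1_{i:02d}"] for i in range(2 * k)], dtype=int)
        s2 = np.array([row[f"s2_{i:02d}"] for i in range(2 * k)], dtype=int)
        out.append(ConfidenceCounts(subject_id=row["subject_id"],
                                    domain=row["domain"], n_bins=k,
                                    counts_s1=s1, counts_s2=s2))
    return out


def preprocess_trials(trials: pd.DataFrame, n_bins: int = DEFAULT_N_BINS
                      ) -> tuple[pd.DataFrame, list[ConfidenceCounts],
                                 ExclusionReport]:
    """Full preprocessing chain: exclusions -> binning -> count assembly."""
    kept, rep_trials = exclude_trials(trials)
    kept, rep_subj = exclude_constant_confidence_subjects(kept)
    report = ExclusionReport(
        n_trials_in=rep_trials.n_trials_in,
        n_burnin_excluded=rep_trials.n_burnin_excluded,
        n_rt_excluded=rep_trials.n_rt_excluded,
        n_trials_out=rep_subj.n_trials_out,
        subjects_excluded=rep_subj.subjects_excluded)
    binned = bin_confidence(kept, n_bins=n_bins)
    counts = assemble_counts(binned, n_bins=n_bins)
    return binned, counts, report
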