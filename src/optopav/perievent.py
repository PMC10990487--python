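"""Peri-event alignment and windowed AUC statistics.

dF/F0 traces are cut into trials x time matrices aligned to a schedule event
(cue onset, laser onset, or the *expected* laser onset on omission trials),
baselined on a pre-event window, and summarized as trapezoidal AUC over an
analysis window — the response-magnitude metric used for learning curves
(cue window 0–1.5 s), omission dips, and terminal-stimulation pharmacology
(0–20 s and 0–5 s windows).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .errors import AlignmentError, AnalysisError
from .preprocess import DffTrace
from .task import LASER_PAIRED, NON_LASER, OMISSION, EventSchedule, TaskConfig

logger = logging.getLogger(__name__)

CUE_ONSET = "cue_onset"
LASER_ONSET = "laser_onset"
OMISSION_EXPECTED_LASER = "omission_expected_laser"
EVENT_LABELS = (CUE_ONSET, LASER_ONSET, OMISSION_EXPECTED_LASER)

#: Columns of the tidy AUC table consumed by the stats layer.
AUC_COLUMNS = ("subject", "session", "trial_type", "condition",
               "window_lo_s", "window_hi_s", "auc")


@dataclass(frozen=True)
class PeriEventTensor:
    """Trials x samples dF/F matrix on a shared relative-time grid."""

    data: np.ndarray            # (n_trials, n_samples), baselined dF/F
    rel_t: np.ndarray           # seconds relative to the alignment event
    event_label: str
    baseline_window_s: tuple[float, float]
    trial_indices: tuple[int, ...] = ()
    fs: float = 0.0

    def __post_init__(self) -> None:
        if self.data.ndim != 2 or self.data.shape[1] != len(self.rel_t):
            raise AnalysisError("data must be (n_trials, len(rel_t))")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    def mean_trace(self) -> np.ndarray:
        return self.data.mean(axis=0)


def _event_times(schedule: EventSchedule, event_label: str,
                 trial_types: Optional[Sequence[str]]) -> tuple[list[float], list[int]]:
    cfg = schedule.config or TaskConfig()
    times, indices = [], []
    for tr in schedule.trials:
        if event_label == CUE_ONSET:
            if trial_types is not None and tr.type not in trial_types:
                continue
            t_ev = tr.cue_onset_s
        elif event_label == LASER_ONSET:
            if tr.type != LASER_PAIRED:
                continue
            t_ev = tr.laser_onset_s
        elif event_label == OMISSION_EXPECTED_LASER:
            if tr.type != OMISSION:
                continue
            t_ev = tr.expected_laser_onset_s(cfg.laser_delay_s)
        else:
            raise AnalysisError(f"unknown event label {event_label!r}; "
                                f"known: {EVENT_LABELS}")
        times.append(t_ev)
        indices.append(tr.index)
    return times, indices


def align(dff: DffTrace, schedule: EventSchedule, event_label: str = CUE_ONSET,
          window_s: tuple[float, float] = (-5.0, 10.0),
          baseline_window_s: tuple[float, float] = (-2.0, 0.0),
          trial_types: Optional[Sequence[str]] = None) -> PeriEventTensor:
    """Cut dF/F0 into an event-aligned tensor with per-trial baselining.

    Each selected trial contributes the dF/F segment on the common relative
    grid ``[window_s[0], window_s[1])`` (half-open, step 1/fs, values taken by
    linear interpolation of the uniformly sampled trace) minus the mean of its
    own baseline window.  ``laser_onset`` selects laser-paired trials;
    ``omission_expected_laser`` selects omission trials and aligns to
    cue onset + laser delay.  Trials whose window falls outside the recording
    are dropped with a warning; if all are dropped an error is raised.
    """
    lo, hi = window_s
    blo, bhi = baseline_window_s
    if hi <= lo:
        raise AnalysisError("window_s must satisfy lo < hi")
    if bhi > 0 or bhi <= blo:
        raise AnalysisError("baseline window must precede t = 0 (blo < bhi <= 0)")
    if not (lo <= blo and bhi <= hi):
        raise AnalysisError("baseline window must lie inside the alignment window")

    fs = dff.fs
    n_rel = int(round((hi - lo) * fs))
    rel_t = lo + np.arange(n_rel) / fs

    times, indices = _event_times(schedule, event_label, trial_types)
    if not times:
        raise AlignmentError(f"no trials match event label {event_label!r}")

    t0, t1 = dff.t[0], dff.t[-1]
    rows, kept = [], []
    for t_ev, idx in zip(times, indices):
        if t_ev + rel_t[0] < t0 or t_ev + rel_t[-1] > t1:
            logger.warning("dropping trial %d: window [%.1f, %.1f] s outside "
                           "recording [%.1f, %.1f] s", idx, t_ev + lo, t_ev + hi, t0, t1)
            continue
        rows.append(np.interp(t_ev + rel_t, dff.t, dff.dff))
        kept.append(idx)
    if not rows:
        raise AlignmentError("every trial fell outside the recording")

    data = np.asarray(rows)
    bmask = (rel_t >= blo) & (rel_t < bhi)
    if not bmask.any():
        raise AnalysisError("baseline window contains no samples")
    data = data - data[:, bmask].mean(axis=1, keepdims=True)
    return PeriEventTensor(data=data, rel_t=rel_t, event_label=event_label,
                           baseline_window_s=(blo, bhi),
                           trial_indices=tuple(kept), fs=fs)


def trial_auc(tensor: PeriEventTensor,
              window_s: tuple[float, float]) -> np.ndarray:
    """Trapezoidal AUC of each trial over ``window_s`` (dF/F · s; may be negative)."""
    lo, hi = window_s
    if hi <= lo:
        raise AnalysisError("AUC window must satisfy lo < hi")
    mask = (tensor.rel_t >= lo - 1e-12) & (tensor.rel_t <= hi + 1e-12)
    if mask.sum() < 2:
        raise AnalysisError(
            f"AUC window [{lo}, {hi}] s contains {int(mask.sum())} samples "
            f"of the grid [{tensor.rel_t[0]:.3f}, {tensor.rel_t[-1]:.3f}] s")
    return np.trapezoid(tensor.data[:, mask], tensor.rel_t[mask], axis=1)


def make_auc_table(tensor: PeriEventTensor, window_s: tuple[float, float],
                   subject: str, session: int, trial_type: str,
                   condition: str = "vehicle") -> pd.DataFrame:
    """Per-trial AUC rows in the tidy table layout used downstream."""
    aucs = trial_auc(tensor, window_s)
    return pd.DataFrame({
        "subject": subject, "session": session, "trial_type": trial_type,
        "condition": condition, "window_lo_s": window_s[0],
        "window_hi_s": window_s[1], "auc": aucs,
    })


def session_curve(auc_table: pd.DataFrame) -> pd.DataFrame:
    """Learning curve: mean AUC per subject x session x trial type.

    Expects a tidy per-trial table (columns ``subject, session, trial_type,
    auc``).  Fails listing missing cells if the subject x session x type grid
    is incomplete, so the repeated-measures ANOVA downstream stays balanced.
    """
    missing_cols = set(AUC_COLUMNS[:3] + ("auc",)) - set(auc_table.columns)
    if missing_cols:
        raise AnalysisError(f"AUC table missing columns {sorted(missing_cols)}")
    curve = (auc_table.groupby(["subject", "session", "trial_type"], sort=True)
             ["auc"].mean().rename("auc_mean").reset_index())
    subjects = curve["subject"].unique()
    sessions = curve["session"].unique()
    types = curve["trial_type"].unique()
    full = {(su, se, ty) for su in subjects for se in sessions for ty in types}
    have = set(map(tuple, curve[["subject", "session", "trial_type"]].to_numpy()))
    missing = full - have
    if missing:
        raise AnalysisError(f"incomplete design; missing cells: {sorted(missing)[:10]}")
    return curve


def omission_auc(tensor: PeriEventTensor,
                 window_s: tuple[float, float] = (0.0, 2.0)) -> float:
    """Mean-over-trials AUC for one subject's omission-aligned tensor.

    Negative when the expected-stimulation dip is present.
    """
    if tensor.event_label != OMISSION_EXPECTED_LASER:
        raise AnalysisError("tensor must be aligned to omission_expected_laser")
    if tensor.n_trials == 0:
        raise AnalysisError("no omission trials in tensor")
    return float(trial_auc(tensor, window_s).mean())
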