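"""Opto-Pavlovian task structure: configuration, trials, and schedule generation.

A session presents two 7-s cues in a pseudorandom order: a laser-predictive
cue (red laser onto midbrain dopamine neurons, starting 2 s after cue onset
and lasting 5 s at 20 Hz / 10 ms pulses) and a non-laser cue followed by
nothing.  Inter-trial intervals are uniform on [45, 75] s and no trial type
repeats more than three times in a row.  Omission sessions keep the same
laser-predictive cue but withhold the laser on a fixed subset of its
presentations (10 of 30 under defaults, i.e. one third).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

from .errors import ConfigError, ScheduleError

LASER_PAIRED = "laser_paired"
NON_LASER = "non_laser"
OMISSION = "omission"
TRIAL_TYPES = (LASER_PAIRED, NON_LASER, OMISSION)


@dataclass(frozen=True)
class TaskConfig:
    """Timing and count parameters of one opto-Pavlovian session.

    Defaults reproduce the training design: 30 laser-paired and 30 non-laser
    cues, 7 s cues, laser from 2 s to 7 s after cue onset, ITI uniform on
    [45, 75] s, and at most 3 consecutive trials of the same type.  With
    ``omission_mode`` the laser-predictive cue is still shown
    ``n_laser_trials`` times but ``n_omission_trials`` of those presentations
    omit the laser (defaults: 20 laser + 10 omission + 30 non-laser).
    """

    cue_duration_s: float = 7.0
    laser_delay_s: float = 2.0
    laser_duration_s: float = 5.0
    pulse_rate_hz: float = 20.0
    pulse_width_s: float = 0.010
    iti_low_s: float = 45.0
    iti_high_s: float = 75.0
    n_laser_trials: int = 30
    n_nonlaser_trials: int = 30
    omission_mode: bool = False
    n_omission_trials: int = 10
    max_run_length: int = 3
    n_pulses_terminal: int = 100  # terminal-stimulation mode (100 pulses at 20 Hz)

    def __post_init__(self) -> None:
        if min(self.cue_duration_s, self.laser_delay_s, self.laser_duration_s,
               self.pulse_rate_hz, self.pulse_width_s) <= 0:
            raise ConfigError("all durations and rates must be > 0")
        if not (0 < self.iti_low_s <= self.iti_high_s):
            raise ConfigError(
                f"require 0 < iti_low_s <= iti_high_s, got "
                f"[{self.iti_low_s}, {self.iti_high_s}]")
        if self.laser_delay_s + self.laser_duration_s > self.cue_duration_s:
            raise ConfigError(
                "laser epoch must end by cue offset: "
                f"{self.laser_delay_s} + {self.laser_duration_s} > {self.cue_duration_s}")
        if min(self.n_laser_trials, self.n_nonlaser_trials) < 0:
            raise ConfigError("trial counts must be >= 0")
        if self.max_run_length < 1:
            raise ConfigError("max_run_length must be >= 1")
        if self.omission_mode and not (0 <= self.n_omission_trials < self.n_laser_trials):
            raise ConfigError(
                "omission_mode requires 0 <= n_omission_trials < n_laser_trials")

    @property
    def type_counts(self) -> dict[str, int]:
        """Exact per-type trial counts for one session."""
        if self.omission_mode:
            return {
                LASER_PAIRED: self.n_laser_trials - self.n_omission_trials,
                OMISSION: self.n_omission_trials,
                NON_LASER: self.n_nonlaser_trials,
            }
        return {LASER_PAIRED: self.n_laser_trials, NON_LASER: self.n_nonlaser_trials}

    @property
    def n_trials(self) -> int:
        return sum(self.type_counts.values())

    @classmethod
    def training(cls, **kw) -> "TaskConfig":
        return cls(omission_mode=False, **kw)

    @classmethod
    def omission(cls, **kw) -> "TaskConfig":
        return cls(omission_mode=True, **kw)

    def with_(self, **kw) -> "TaskConfig":
        return replace(self, **kw)


@dataclass(frozen=True)
class Trial:
    """One cue presentation with absolute event times (s from recording start)."""

    index: int
    type: str
    cue_onset_s: float
    cue_offset_s: float
    laser_onset_s: Optional[float] = None
    laser_offset_s: Optional[float] = None

    def __post_init__(self) -> None:
        if self.type not in TRIAL_TYPES:
            raise ConfigError(f"unknown trial type {self.type!r}")
        if self.cue_offset_s <= self.cue_onset_s:
            raise ConfigError("cue_offset_s must exceed cue_onset_s")
        has_laser = self.laser_onset_s is not None
        if has_laser != (self.type == LASER_PAIRED):
            raise ConfigError("laser times present iff type is laser_paired")
        if has_laser and not (self.cue_onset_s <= self.laser_onset_s < self.laser_offset_s
                              <= self.cue_offset_s):
            raise ConfigError("laser epoch must lie within the cue epoch")

    def expected_laser_onset_s(self, laser_delay_s: float) -> float:
        """Time at which the laser would have started (omission alignment)."""
        return self.cue_onset_s + laser_delay_s


@dataclass(frozen=True)
class EventSchedule:
    """Ordered trial list for one session, with provenance (session index, seed)."""

    trials: tuple[Trial, ...]
    session_index: int = 1
    seed: Optional[int] = None
    config: Optional[TaskConfig] = None

    def __post_init__(self) -> None:
        onsets = [tr.cue_onset_s for tr in self.trials]
        if any(b <= a for a, b in zip(onsets, onsets[1:])):
            raise ConfigError("trial onsets must be strictly increasing")
        for prev, nxt in zip(self.trials, self.trials[1:]):
            if nxt.cue_onset_s < prev.cue_offset_s:
                raise ConfigError(
                    f"trials {prev.index} and {nxt.index} overlap in time")

    def __len__(self) -> int:
        return len(self.trials)

    def of_type(self, *types: str) -> tuple[Trial, ...]:
        return tuple(tr for tr in self.trials if tr.type in types)

    @property
    def type_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for tr in self.trials:
            counts[tr.type] = counts.get(tr.type, 0) + 1
        return counts

    @property
    def itis_s(self) -> np.ndarray:
        """Cue-offset-to-next-cue-onset intervals, one per trial gap."""
        return np.array([nxt.cue_onset_s - prev.cue_offset_s
                         for prev, nxt in zip(self.trials, self.trials[1:])])

    @property
    def end_s(self) -> float:
        """Time of the last cue offset (0.0 for an empty schedule)."""
        return self.trials[-1].cue_offset_s if self.trials else 0.0


def _max_run(labels: list[str]) -> int:
    best = run = 0
    prev = object()
    for lab in labels:
        run = run + 1 if lab == prev else 1
        prev = lab
        best = max(best, run)
    return best


def _feasible(counts: dict[str, int], max_run: int) -> bool:
    # A type with m occurrences needs ceil(m / max_run) - 1 separators drawn
    # from the remaining trials.
    total = sum(counts.values())
    for m in counts.values():
        if m > 0 and -(-m // max_run) - 1 > total - m:
            return False
    return True


def generate_schedule(config: TaskConfig, seed: int,
                      session_index: int = 1,
                      max_retries: int = 10_000) -> EventSchedule:
    """Generate one session's pseudorandom trial schedule.

    Trial-type counts are allocated exactly (not drawn independently) and the
    order is resampled by shuffling until no type occurs more than
    ``config.max_run_length`` times consecutively.  ITIs (cue offset to next
    cue onset, and the lead-in before the first cue) are uniform on
    [iti_low_s, iti_high_s].  Deterministic given ``seed``.

    Raises
    ------
    ScheduleError
        If the run-length constraint is infeasible for the configured counts,
        or no valid shuffle is found within ``max_retries``.
    """
    counts = config.type_counts
    labels = [t for t, m in counts.items() for _ in range(m)]
    nonzero = {t: m for t, m in counts.items() if m > 0}
    # The run-length constraint orders *different* trial types; with a single
    # type present (e.g. a stimulation-only session) it is vacuous.
    if len(nonzero) > 1 and not _feasible(nonzero, config.max_run_length):
        raise ScheduleError(
            f"run-length constraint max_run_length={config.max_run_length} is "
            f"infeasible for trial counts {nonzero}")

    rng = np.random.default_rng(seed)
    if labels:
        for _ in range(max_retries):
            order = rng.permutation(len(labels))
            shuffled = [labels[i] for i in order]
            if len(nonzero) <= 1 or _max_run(shuffled) <= config.max_run_length:
                break
        else:
            raise ScheduleError(
                f"no shuffle satisfying max_run_length={config.max_run_length} "
                f"found in {max_retries} attempts for counts {nonzero}")
    else:
        shuffled = []

    itis = rng.uniform(config.iti_low_s, config.iti_high_s, size=len(shuffled))
    trials = []
    t = 0.0
    for i, (lab, iti) in enumerate(zip(shuffled, itis)):
        cue_on = float(t + iti)
        cue_off = cue_on + config.cue_duration_s
        laser_on = laser_off = None
        if lab == LASER_PAIRED:
            laser_on = cue_on + config.laser_delay_s
            laser_off = laser_on + config.laser_duration_s
        trials.append(Trial(index=i, type=lab, cue_onset_s=cue_on,
                            cue_offset_s=cue_off, laser_onset_s=laser_on,
                            laser_offset_s=laser_off))
        t = cue_off
    return EventSchedule(trials=tuple(trials), session_index=session_index,
                         seed=seed, config=config)


def generate_pulse_train(rate_hz: float, n_pulses: int, width_s: float,
                         t0: float = 0.0) -> np.ndarray:
    """Onset/offset times of an optogenetic pulse train.

    Returns an ``(n_pulses, 2)`` array of (onset, offset) seconds; consecutive
    onsets are exactly ``1 / rate_hz`` apart.  The default stimulation used for
    terminal experiments is 20 Hz, 100 pulses, 10 ms width.
    """
    if rate_hz <= 0 or width_s <= 0:
        raise ConfigError("rate_hz and width_s must be > 0")
    if n_pulses < 1:
        raise ConfigError("n_pulses must be >= 1")
    if rate_hz * width_s >= 1:
        raise ConfigError(
            f"duty cycle {rate_hz * width_s:.3f} >= 1: pulses would overlap")
    onsets = t0 + np.arange(n_pulses) / rate_hz
    return np.column_stack([onsets, onsets + width_s])
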