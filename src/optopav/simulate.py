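"""Forward model: synthetic two-channel photometry traces for an opto-Pavlovian session.

The dimensionless "biological" signal is

    s(t) = tonic + sum_e  A_e * k(t - t_e),      k(t) = (1 - e^(-t/tau_r)) e^(-t/tau_d)

a tonic neuromodulator level plus transient kernels at cue/laser/omission
events.  Both channels share multiplicative bleaching B(t) (double
exponential) and a low-frequency motion term m(t); only the signal (470 nm)
channel sees s(t):

    F_470(t) = g_s * B(t) * (1 + m(t)) * (1 + s(t)) + eps_s(t)
    F_405(t) = g_c * B(t) * (1 + m(t))              + eps_c(t)

so that regressing the control channel onto the signal channel and dividing
out the fit recovers s(t) up to noise — the structure the isosbestic dF/F0
procedure assumes.

Cue-response amplitudes grow across sessions as a saturating exponential
A(s) = A_max (1 - e^(-s/lambda)); omission trials place a negative-amplitude
kernel at the expected laser onset (a dip below the tonic level); drug
conditions scale every response amplitude by a factor in [0, 1].
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import signal as sps

from .errors import ConfigError, SimulationError
from .task import (LASER_PAIRED, NON_LASER, OMISSION, EventSchedule, TaskConfig)

# --------------------------------------------------------------------------
# Transient kernel


def transient_kernel(t: np.ndarray, tau_rise_s: float, tau_decay_s: float) -> np.ndarray:
    """k(t) = (1 - e^(-t/tau_r)) e^(-t/tau_d) for t >= 0, else 0."""
    t = np.asarray(t, dtype=float)
    out = np.zeros_like(t)
    pos = t >= 0
    tp = t[pos]
    out[pos] = -np.expm1(-tp / tau_rise_s) * np.exp(-tp / tau_decay_s)
    return out


def kernel_peak_time(tau_rise_s: float, tau_decay_s: float) -> float:
    """Analytic argmax of the transient kernel: tau_r * ln(1 + tau_d / tau_r)."""
    return tau_rise_s * np.log1p(tau_decay_s / tau_rise_s)


def kernel_peak_value(tau_rise_s: float, tau_decay_s: float) -> float:
    return float(transient_kernel(np.array([kernel_peak_time(tau_rise_s, tau_decay_s)]),
                                  tau_rise_s, tau_decay_s)[0])


def kernel_integral(tau_rise_s: float, tau_decay_s: float,
                    lo: float = 0.0, hi: float = np.inf) -> float:
    """Closed-form integral of the kernel over [lo, hi] (lo, hi >= 0)."""
    if lo < 0:
        lo = 0.0
    tau_p = tau_rise_s * tau_decay_s / (tau_rise_s + tau_decay_s)

    def antideriv(t: float) -> float:
        # integral from 0 to t of e^(-u/tau_d) - e^(-u/tau_p)
        if np.isinf(t):
            return tau_decay_s - tau_p
        return tau_decay_s * -np.expm1(-t / tau_decay_s) - tau_p * -np.expm1(-t / tau_p)

    return antideriv(hi) - antideriv(lo)


def kernel_derivative(t: np.ndarray, tau_rise_s: float, tau_decay_s: float) -> np.ndarray:
    """Analytic dk/dt for t >= 0 (0 for t < 0)."""
    t = np.asarray(t, dtype=float)
    out = np.zeros_like(t)
    pos = t >= 0
    tp = t[pos]
    er = np.exp(-tp / tau_rise_s)
    ed = np.exp(-tp / tau_decay_s)
    out[pos] = ed * (er / tau_rise_s - (1 - er) / tau_decay_s)
    return out


@dataclass(frozen=True)
class KernelParams:
    """Region-specific transient kinetics (rise/decay time constants)."""

    tau_rise_s: float
    tau_decay_s: float
    amplitude: float = 1.0
    region_label: str = "NAc_dopamine"

    def __post_init__(self) -> None:
        if self.tau_rise_s <= 0:
            raise ConfigError("tau_rise_s must be > 0")
        if self.tau_decay_s <= self.tau_rise_s:
            raise ConfigError("tau_decay_s must exceed tau_rise_s")

    @property
    def peak_time_s(self) -> float:
        return kernel_peak_time(self.tau_rise_s, self.tau_decay_s)


#: Kinetic presets.  Decay ordering LH_dopamine < NAc_dopamine < LH_orexin
#: encodes the observed region ordering (hypothalamic dopamine is the fastest,
#: the slow calcium indicator in orexin neurons the slowest); the absolute
#: values are generator defaults, not measured constants.
REGION_PRESETS: dict[str, KernelParams] = {
    "LH_dopamine": KernelParams(0.15, 0.8, region_label="LH_dopamine"),
    "NAc_dopamine": KernelParams(0.25, 1.5, region_label="NAc_dopamine"),
    "LH_orexin": KernelParams(0.8, 4.0, region_label="LH_orexin"),
}


# --------------------------------------------------------------------------
# Ground truth


@dataclass(frozen=True)
class GroundTruth:
    """Generator parameters: true amplitudes, learning curve, artifacts, noise.

    Amplitudes are in dF/F units.  ``a_max`` and ``learning_rate_sessions``
    parameterize the cue-response learning curve A(s) = a_max (1 - e^(-s/lr));
    ``laser_amplitude`` is the (session-independent) response to the laser
    itself; ``dip_amplitude`` (< 0) is the transient placed at the expected
    laser onset on omission trials, a dip below the tonic level
    ``tonic_level`` (> 0, the basal extrasynaptic neuromodulator tone).
    ``condition_scales`` multiplies every response amplitude per drug
    condition.
    """

    a_max: float = 0.04
    learning_rate_sessions: float = 3.0
    nonlaser_amplitude: float = 0.005
    laser_amplitude: float = 0.08
    dip_amplitude: float = -0.02
    tonic_level: float = 0.05
    gain_signal: float = 200.0
    gain_control: float = 120.0
    bleach_tau_fast_s: float = 120.0
    bleach_tau_slow_s: float = 5000.0
    bleach_frac_fast: float = 0.10
    bleach_floor: float = 0.6
    motion_sd: float = 0.005
    motion_band_hz: tuple[float, float] = (0.1, 1.0)
    noise_sd_signal: float = 1.0
    noise_sd_control: float = 0.6
    condition_scales: dict[str, float] = field(default_factory=lambda: {
        "vehicle": 1.0, "SCH23390": 1.0, "raclopride": 0.3,
        "anesthetized": 1.0, "freely_moving": 1.0,
    })

    def __post_init__(self) -> None:
        if self.dip_amplitude > 0:
            raise ConfigError("dip_amplitude must be <= 0 (a dip)")
        if self.tonic_level < 0:
            raise ConfigError("tonic_level must be >= 0")
        bad = {k: v for k, v in self.condition_scales.items() if not 0 <= v <= 1}
        if bad:
            raise ConfigError(f"condition scale factors must lie in [0, 1]: {bad}")

    def scaled(self, factor: float) -> "GroundTruth":
        """Copy with every response amplitude multiplied (per-subject variability)."""
        return dataclasses.replace(
            self,
            a_max=self.a_max * factor,
            nonlaser_amplitude=self.nonlaser_amplitude * factor,
            laser_amplitude=self.laser_amplitude * factor,
            dip_amplitude=self.dip_amplitude * factor,
        )

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["motion_band_hz"] = list(self.motion_band_hz)
        return d


def learning_amplitude(session_index: int, cue_type: str, truth: GroundTruth) -> float:
    """True cue-response amplitude for a given session and cue type.

    Laser-paired (and omission) cues follow the saturating learning curve
    A(s) = a_max (1 - e^(-s / lambda)); the non-laser cue elicits a small
    constant response.  Non-decreasing in the session index.
    """
    if session_index < 1:
        raise ConfigError("session_index is 1-based")
    if cue_type in (LASER_PAIRED, OMISSION):
        return truth.a_max * -np.expm1(-session_index / truth.learning_rate_sessions)
    if cue_type == NON_LASER:
        return truth.nonlaser_amplitude
    raise ConfigError(f"unknown cue type {cue_type!r}")


# --------------------------------------------------------------------------
# Raw trace container


@dataclass(frozen=True)
class RawTrace:
    """Uniformly sampled two-channel recording (405 nm control, 470 nm signal)."""

    t: np.ndarray
    f_control: np.ndarray
    f_signal: np.ndarray
    fs: float

    def __post_init__(self) -> None:
        if not (len(self.t) == len(self.f_control) == len(self.f_signal)):
            raise ConfigError("t, f_control, f_signal must have equal length")
        if self.fs <= 0:
            raise ConfigError("fs must be > 0")
        if len(self.t) and (np.min(self.f_control) <= 0 or np.min(self.f_signal) <= 0):
            raise SimulationError("fluorescence must be strictly positive")

    def __len__(self) -> int:
        return len(self.t)


# --------------------------------------------------------------------------
# Trace synthesis


def _bleach(t: np.ndarray, truth: GroundTruth) -> np.ndarray:
    """Double-exponential bleaching, B(0) = 1, floor > 0."""
    fast = np.exp(-t / truth.bleach_tau_fast_s)
    slow = np.exp(-t / truth.bleach_tau_slow_s)
    w = truth.bleach_frac_fast
    shape = w * fast + (1 - w) * slow
    return truth.bleach_floor + (1 - truth.bleach_floor) * shape


def _motion(n: int, fs: float, truth: GroundTruth, rng: np.random.Generator) -> np.ndarray:
    """Shared band-limited (default 0.1-1 Hz) motion term with sd = motion_sd."""
    if truth.motion_sd == 0 or n == 0:
        return np.zeros(n)
    lo, hi = truth.motion_band_hz
    hi = min(hi, 0.45 * fs)  # keep the band below Nyquist
    white = rng.standard_normal(n)
    sos = sps.butter(2, [lo, hi], btype="bandpass", fs=fs, output="sos")
    padlen = 3 * 8  # 3 * (2 * sections * 2), sosfiltfilt default for 2 sections
    if n <= padlen:
        return np.zeros(n)
    band = sps.sosfiltfilt(sos, white)
    sd = band.std()
    return band * (truth.motion_sd / sd) if sd > 0 else np.zeros(n)


def true_events(schedule: EventSchedule, truth: GroundTruth,
                condition: str = "vehicle") -> list[dict]:
    """Ground-truth event list (time, amplitude, kind) for a schedule.

    Laser-paired trials carry a learned cue response at cue onset plus a
    laser response at laser onset; omission trials carry the same learned cue
    response plus a negative dip at the *expected* laser onset; non-laser
    trials carry only the small constant cue response.
    """
    scale = truth.condition_scales.get(condition)
    if scale is None:
        raise ConfigError(f"unknown condition {condition!r}; "
                          f"known: {sorted(truth.condition_scales)}")
    cfg = schedule.config or TaskConfig()
    s = schedule.session_index
    events = []

    def add(trial, kind, time_s, amp):
        events.append({"trial_index": trial.index, "trial_type": trial.type,
                       "kind": kind, "time_s": float(time_s),
                       "amplitude": float(amp * scale)})

    for tr in schedule.trials:
        if tr.type == OMISSION:
            # Omission trials carry only the negative prediction-error dip at
            # the expected laser onset; the net signal deviation around the
            # withheld stimulation is the dip itself.
            add(tr, "dip", tr.expected_laser_onset_s(cfg.laser_delay_s),
                truth.dip_amplitude)
            continue
        add(tr, "cue", tr.cue_onset_s, learning_amplitude(s, tr.type, truth))
        if tr.type == LASER_PAIRED:
            add(tr, "laser", tr.laser_onset_s, truth.laser_amplitude)
    return events


def _add_kernels(s: np.ndarray, t: np.ndarray, fs: float, events: list[dict],
                 kernel: KernelParams) -> None:
    """Add A_e * k(t - t_e) in place, using a finite support window per event."""
    support = kernel.tau_rise_s + 30.0 * kernel.tau_decay_s
    n = len(t)
    for ev in events:
        if ev["amplitude"] == 0.0:
            continue
        i0 = max(0, int(np.ceil((ev["time_s"] - t[0]) * fs)))
        i1 = min(n, int(np.ceil((ev["time_s"] + support - t[0]) * fs)) + 1)
        if i0 >= i1:
            continue
        s[i0:i1] += ev["amplitude"] * transient_kernel(
            t[i0:i1] - ev["time_s"], kernel.tau_rise_s, kernel.tau_decay_s)


def simulate_traces(schedule: EventSchedule, kernel: KernelParams,
                    truth: GroundTruth, fs: float, seed: int,
                    condition: str = "vehicle",
                    tail_s: float = 30.0) -> tuple[RawTrace, dict]:
    """Simulate a two-channel raw trace for one session.

    Returns the trace and a ground-truth manifest (every true event time and
    amplitude, all generator parameters, the seed).  Deterministic given
    ``seed``.

    Raises
    ------
    SimulationError
        If the configured dip would push fluorescence non-positive.
    """
    if fs < 20:
        raise ConfigError("fs must be >= 20 Hz to resolve the fastest kernel")
    rng = np.random.default_rng(seed)
    duration = schedule.end_s + tail_s
    n = int(np.ceil(duration * fs)) + 1
    t = np.arange(n) / fs

    events = true_events(schedule, truth, condition)
    s = np.full(n, truth.tonic_level)
    _add_kernels(s, t, fs, events, kernel)

    if np.min(1.0 + s) <= 0:
        tmin = t[int(np.argmin(s))]
        raise SimulationError(
            f"fluorescence would be non-positive near t = {tmin:.1f} s: "
            "dip amplitude exceeds tonic + baseline level")

    bleach = _bleach(t, truth)
    motion = _motion(n, fs, truth, rng)
    shared = bleach * (1.0 + motion)
    f_signal = truth.gain_signal * shared * (1.0 + s)
    f_control = truth.gain_control * shared
    if truth.noise_sd_signal > 0:
        f_signal = f_signal + truth.noise_sd_signal * rng.standard_normal(n)
    if truth.noise_sd_control > 0:
        f_control = f_control + truth.noise_sd_control * rng.standard_normal(n)

    if np.min(f_signal) <= 0 or np.min(f_control) <= 0:
        raise SimulationError(
            "noise drove fluorescence non-positive; increase gains or lower noise")

    trace = RawTrace(t=t, f_control=f_control, f_signal=f_signal, fs=float(fs))
    manifest = {
        "seed": int(seed),
        "session_index": int(schedule.session_index),
        "condition": condition,
        "fs": float(fs),
        "n_samples": int(n),
        "kernel": dataclasses.asdict(kernel),
        "truth": truth.to_dict(),
        "events": events,
    }
    return trace, manifest


def noiseless(truth: GroundTruth) -> GroundTruth:
    """Copy of ``truth`` with stochastic sources (noise, motion) switched off.

    Deterministic bleaching is kept: a perfectly constant control channel
    would make the isosbestic fit degenerate.
    """
    return dataclasses.replace(truth, motion_sd=0.0, noise_sd_signal=0.0,
                               noise_sd_control=0.0)
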