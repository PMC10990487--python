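"""Isosbestic dF/F0 correction and filtering.

The 405 nm channel is neuromodulator-insensitive and captures the bleaching
and motion artifacts shared with the 470 nm signal channel.  A single
ordinary-least-squares line fitted over the whole recording maps the control
channel onto the signal channel; the fitted control is used as F0 in the
standard normalization dF/F0 = (F(t) - F0(t)) / F0(t).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import signal as sps

from .errors import DegenerateFitError, PreprocessError
from .simulate import RawTrace


@dataclass(frozen=True)
class IsosbesticFit:
    """OLS line mapping the control channel onto the signal channel."""

    slope: float
    intercept: float
    residual_sd: float

    def f0(self, f_control: np.ndarray) -> np.ndarray:
        """Fitted control channel, used as F0(t)."""
        return self.slope * np.asarray(f_control, dtype=float) + self.intercept


@dataclass(frozen=True)
class DffTrace:
    """dF/F0 time series with its sampling grid and fit provenance."""

    t: np.ndarray
    dff: np.ndarray
    fs: float
    fit: Optional[IsosbesticFit] = None

    def __post_init__(self) -> None:
        if len(self.t) != len(self.dff):
            raise PreprocessError("t and dff must have equal length")
        if not np.all(np.isfinite(self.dff)):
            raise PreprocessError("dff contains non-finite values")

    def __len__(self) -> int:
        return len(self.t)


def fit_isosbestic(control: np.ndarray, signal: np.ndarray) -> IsosbesticFit:
    """Least-squares fit of ``signal ~ slope * control + intercept``.

    Raises
    ------
    DegenerateFitError
        If the control channel is constant (the line is undefined).
    """
    control = np.asarray(control, dtype=float)
    signal = np.asarray(signal, dtype=float)
    if control.shape != signal.shape or control.ndim != 1 or len(control) < 2:
        raise PreprocessError("control and signal must be equal-length 1-d, n >= 2")
    if np.ptp(control) == 0:
        raise DegenerateFitError("control channel is constant; isosbestic fit undefined")
    slope, intercept = np.polyfit(control, signal, 1)
    resid = signal - (slope * control + intercept)
    return IsosbesticFit(slope=float(slope), intercept=float(intercept),
                         residual_sd=float(resid.std()))


def compute_dff(raw: RawTrace, fit: Optional[IsosbesticFit] = None) -> DffTrace:
    """dF/F0 with F0(t) the fitted 405 nm control channel.

    dff(t) = (f_signal(t) - F0(t)) / F0(t),  F0(t) = slope * f_control(t) + intercept.

    Raises
    ------
    PreprocessError
        If the fitted F0 is non-positive anywhere (lists the offending time
        range).
    """
    if fit is None:
        fit = fit_isosbestic(raw.f_control, raw.f_signal)
    f0 = fit.f0(raw.f_control)
    bad = f0 <= 0
    if np.any(bad):
        tb = raw.t[bad]
        raise PreprocessError(
            f"fitted F0 <= 0 at {bad.sum()} samples between "
            f"t = {tb[0]:.3f} s and t = {tb[-1]:.3f} s")
    dff = (raw.f_signal - f0) / f0
    return DffTrace(t=raw.t, dff=dff, fs=raw.fs, fit=fit)


def lowpass(trace: DffTrace, cutoff_hz: float) -> DffTrace:
    """Zero-phase second-order Butterworth low-pass (unit DC gain).

    Zero-phase (forward-backward) filtering preserves the event latencies the
    kinetics analysis depends on.
    """
    if not 0 < cutoff_hz < trace.fs / 2:
        raise PreprocessError(
            f"cutoff {cutoff_hz} Hz must lie in (0, fs/2) = (0, {trace.fs / 2})")
    sos = sps.butter(2, cutoff_hz, btype="lowpass", fs=trace.fs, output="sos")
    filtered = sps.sosfiltfilt(sos, trace.dff)
    return DffTrace(t=trace.t, dff=filtered, fs=trace.fs, fit=trace.fit)


def preprocess(raw: RawTrace, lowpass_hz: Optional[float] = None) -> DffTrace:
    """Full preprocessing: isosbestic fit, dF/F0, optional zero-phase low-pass."""
    dff = compute_dff(raw)
    if lowpass_hz is not None:
        dff = lowpass(dff, lowpass_hz)
    return dff
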