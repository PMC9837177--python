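"""Fluorescence preprocessing and behavioral event detection.

Covers grand-mean dF/F normalization, zero-phase band-pass filtering with
overlapping spatial binning, wheel-movement and saccade detection, the
pupil-based sustained-attention metric, and dual-wavelength hemodynamic
correction.

All temporal filters are zero-phase (forward-backward Butterworth) so that
event-timing claims downstream are not biased by filter delay.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal as sps

from .synth import SessionTensor

__all__ = [
    "compute_dff",
    "bandpass_and_bin",
    "detect_wheel_movements",
    "detect_saccades",
    "pupil_attention_metric",
    "zscore_session",
    "hemodynamic_correct",
    "HemodynamicFit",
]


def compute_dff(raw: np.ndarray, frame_rate: float, pre_stim: float, open_loop: float) -> SessionTensor:
    """Normalize a raw-intensity tensor to dF/F with a grand-mean F0.

    F0 is the scalar grand average of the session over trials, pixels and
    frames; the output is ``(I - F0) / F0``.
    """
    raw = np.asarray(raw, dtype=float)
    if np.any(raw <= 0):
        raise ValueError("raw intensities must be positive")
    f0 = raw.mean()
    if f0 <= 0:
        raise ValueError("nonpositive F0")
    return SessionTensor(
        data=((raw - f0) / f0),
        frame_rate=frame_rate,
        pre_stim=pre_stim,
        open_loop=open_loop,
    )


def _butter_sos(low: float | None, high: float | None, fs: float, order: int = 2):
    nyq = fs / 2.0
    if high is not None and high >= nyq:
        raise ValueError(f"high cutoff {high} Hz exceeds Nyquist {nyq} Hz")
    if low is not None and high is not None:
        return sps.butter(order, [low, high], btype="bandpass", fs=fs, output="sos")
    if low is not None:
        return sps.butter(order, low, btype="highpass", fs=fs, output="sos")
    return sps.butter(order, high, btype="lowpass", fs=fs, output="sos")


def _bin_overlapping(frame_stack: np.ndarray, win: int, stride: int) -> np.ndarray:
    """Mean-pool (..., x, y, t) spatially with overlapping windows.

    Edge windows are truncated to the grid.
    """
    *lead, h, w, t = frame_stack.shape
    ys = list(range(0, max(h - win, 0) + 1, stride)) or [0]
    xs = list(range(0, max(w - win, 0) + 1, stride)) or [0]
    out = np.empty((*lead, len(ys), len(xs), t), dtype=frame_stack.dtype)
    for i, y0 in enumerate(ys):
        for j, x0 in enumerate(xs):
            out[..., i, j, :] = frame_stack[
                ..., y0 : min(y0 + win, h), x0 : min(x0 + win, w), :
            ].mean(axis=(-3, -2))
    return out


def bandpass_and_bin(
    tensor: SessionTensor,
    low: float = 0.1,
    high: float = 8.0,
    bin_um: float = 130.0,
    overlap: float = 0.5,
    pixel_size: float = 65.0,
    target_fps: float = 30.0,
) -> SessionTensor:
    """Zero-phase band-pass per pixel, overlapping-mean binning, resampling.

    The band-pass is 0.1-8 Hz by default; binning windows are ``bin_um``
    square with 50% overlap; 50 fps inputs are polyphase-resampled to the
    30 fps analysis rate.
    """
    fs = tensor.frame_rate
    if fs <= 2 * high:
        raise ValueError("frame rate must exceed twice the high cutoff")
    sos = _butter_sos(low, high, fs)
    data = sps.sosfiltfilt(sos, tensor.data, axis=-1)

    win = max(1, int(round(bin_um / pixel_size)))
    stride = max(1, int(round(win * (1.0 - overlap))))
    if win > 1:
        data = _bin_overlapping(data, win, stride)

    if abs(fs - target_fps) > 1e-9:
        from fractions import Fraction

        frac = Fraction(target_fps / fs).limit_denominator(100)
        data = sps.resample_poly(data, frac.numerator, frac.denominator, axis=-1)
        fs = target_fps

    return SessionTensor(
        data=np.ascontiguousarray(data),
        frame_rate=fs,
        pre_stim=tensor.pre_stim,
        open_loop=tensor.open_loop,
    )


def detect_wheel_movements(
    velocity: np.ndarray, fs: float, threshold: float = 20.0
) -> pd.DataFrame:
    """Flag wheel movements at zero-crossings followed by a supra-threshold excursion.

    A candidate onset is a velocity sign change; the event is kept when the
    absolute velocity exceeds ``threshold`` before the next sign change.
    Direction is the velocity sign after the crossing (positive = cw).
    Returns a table with columns kind, time_s, direction.
    """
    v = np.asarray(velocity, dtype=float)
    sign = np.sign(v)
    # treat exact zeros as continuation of previous sign
    for i in range(1, sign.size):
        if sign[i] == 0:
            sign[i] = sign[i - 1]
    crossings = np.flatnonzero(np.diff(sign) != 0) + 1
    segments = np.concatenate([[0], crossings, [v.size]])
    events = []
    for s, e in zip(segments[:-1], segments[1:]):
        seg = v[s:e]
        if seg.size == 0 or s == 0:
            continue  # the first segment has no preceding crossing
        if np.max(np.abs(seg)) >= threshold:
            events.append(
                {"kind": "wheel", "time_s": s / fs, "direction": float(np.sign(seg[np.argmax(np.abs(seg))]))}
            )
    return pd.DataFrame(events, columns=["kind", "time_s", "direction"])


def detect_saccades(
    position: np.ndarray,
    fs: float,
    k_mad: float = 6.0,
    min_duration_s: float = 0.06,
    min_magnitude_deg: float = 1.5,
) -> pd.DataFrame:
    """Detect saccades by velocity thresholding with duration/magnitude rejection.

    Candidate events are contiguous runs where eye velocity exceeds
    ``k_mad`` robust SDs (median absolute deviation scaled).  Events lasting
    <= 60 ms or smaller than 1.5 degrees are discarded.  Returns a table
    with time, magnitude, duration, peak velocity, start and landing
    positions.
    """
    pos = np.asarray(position, dtype=float)
    vel = np.gradient(pos) * fs
    mad = np.median(np.abs(vel - np.median(vel)))
    thr = k_mad * 1.4826 * max(mad, 1e-12)
    above = np.abs(vel) > thr
    if not above.any():
        return pd.DataFrame(
            columns=[
                "kind",
                "time_s",
                "magnitude",
                "duration_ms",
                "peak_velocity",
                "start_pos",
                "landing_pos",
            ]
        )
    edges = np.diff(above.astype(int))
    starts = list(np.flatnonzero(edges == 1) + 1)
    ends = list(np.flatnonzero(edges == -1) + 1)
    if above[0]:
        starts.insert(0, 0)
    if above[-1]:
        ends.append(above.size)
    events = []
    for s, e in zip(starts, ends):
        duration = (e - s) / fs
        s0 = max(s - 1, 0)
        e0 = min(e, pos.size - 1)
        magnitude = pos[e0] - pos[s0]
        if duration <= min_duration_s or abs(magnitude) < min_magnitude_deg:
            continue
        events.append(
            {
                "kind": "saccade",
                "time_s": s / fs,
                "magnitude": float(magnitude),
                "duration_ms": duration * 1e3,
                "peak_velocity": float(vel[s:e][np.argmax(np.abs(vel[s:e]))]),
                "start_pos": float(pos[s0]),
                "landing_pos": float(pos[e0]),
            }
        )
    return pd.DataFrame(
        events,
        columns=[
            "kind",
            "time_s",
            "magnitude",
            "duration_ms",
            "peak_velocity",
            "start_pos",
            "landing_pos",
        ],
    )


def pupil_attention_metric(
    trace: np.ndarray,
    fs: float,
    stim_onset_idx: int,
    pre_s: float = 1.0,
    open_loop_s: float = 1.5,
) -> float:
    """Pupil-area change pA for one trial.

    pA = max pupil area in the open-loop window (0, open_loop] after
    stimulus onset minus the mean area over the 1 s before onset.
    """
    trace = np.asarray(trace, dtype=float)
    pre = int(round(pre_s * fs))
    post = int(round(open_loop_s * fs))
    if stim_onset_idx - pre < 0 or stim_onset_idx + post > trace.size:
        raise ValueError("trace does not cover the [-1 s, +open_loop] window")
    baseline = trace[stim_onset_idx - pre : stim_onset_idx].mean()
    peak = trace[stim_onset_idx + 1 : stim_onset_idx + post + 1].max()
    return float(peak - baseline)


def zscore_session(values: np.ndarray) -> np.ndarray:
    """Z-score per-trial pA values against the session mean and SD."""
    values = np.asarray(values, dtype=float)
    sd = values.std()
    if sd == 0:
        return np.zeros_like(values)
    return (values - values.mean()) / sd


@dataclass
class HemodynamicFit:
    """Per-pixel coefficients of the dual-wavelength correction."""

    detrend_a_blue: np.ndarray
    detrend_b_blue: np.ndarray
    detrend_a_violet: np.ndarray
    detrend_b_violet: np.ndarray
    regress_c: np.ndarray
    regress_d: np.ndarray


def _linear_detrend_dff(x: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Fit F(t) ~ a t + b per pixel; return ((F - (a t + b)) / b, a, b)."""
    t = np.arange(x.shape[-1], dtype=float)
    t_mean = t.mean()
    t_var = ((t - t_mean) ** 2).sum()
    x_mean = x.mean(axis=-1, keepdims=True)
    a = ((x - x_mean) * (t - t_mean)).sum(axis=-1, keepdims=True) / t_var
    b = x_mean - a * t_mean
    # a zero intercept (e.g. an all-zero channel) cannot normalize; keep the
    # detrended numerator unscaled there
    b_safe = np.where(b == 0, 1.0, b)
    return (x - (a * t + b)) / b_safe, a[..., 0], b[..., 0]


def _spatial_downsample(x: np.ndarray, factor: int) -> np.ndarray:
    if factor <= 1:
        return x
    h, w = x.shape[0], x.shape[1]
    h2, w2 = h // factor, w // factor
    x = x[: h2 * factor, : w2 * factor]
    return x.reshape(h2, factor, w2, factor, -1).mean(axis=(1, 3))


def hemodynamic_correct(
    blue: np.ndarray,
    violet: np.ndarray,
    fs: float,
    violet_lowpass_hz: float = 5.0,
    final_lowpass_hz: float = 8.0,
    pixel_size: float = 65.0,
    target_pixel_size: float = 50.0,
) -> tuple[np.ndarray, HemodynamicFit]:
    """Remove the hemodynamic artifact from blue-channel fluorescence.

    Per pixel: (1) both channels are linearly detrended and normalized by
    the trend intercept; (2) the violet (calcium-independent) channel is
    low-pass filtered at 5 Hz (6th-order Butterworth, zero-phase) and
    regressed onto the blue channel; (3) the fitted violet contribution is
    subtracted; (4) the corrected trace is low-pass filtered at 8 Hz and
    spatially downsampled toward ``target_pixel_size`` pixels.

    A constant violet channel cannot be regressed; those pixels get c = 0
    with a warning.
    """
    blue = np.asarray(blue, dtype=float)
    violet = np.asarray(violet, dtype=float)
    if blue.shape != violet.shape:
        raise ValueError("blue and violet must have equal shapes")
    if blue.ndim == 1:
        blue = blue[None, None, :]
        violet = violet[None, None, :]

    blue_dff, a_b, b_b = _linear_detrend_dff(blue)
    violet_dff, a_v, b_v = _linear_detrend_dff(violet)

    sos = sps.butter(6, violet_lowpass_hz, btype="lowpass", fs=fs, output="sos")
    violet_lp = sps.sosfiltfilt(sos, violet_dff, axis=-1)

    v_mean = violet_lp.mean(axis=-1, keepdims=True)
    v_var = ((violet_lp - v_mean) ** 2).sum(axis=-1)
    cov = ((violet_lp - v_mean) * (blue_dff - blue_dff.mean(axis=-1, keepdims=True))).sum(
        axis=-1
    )
    degenerate = v_var < 1e-18
    if degenerate.any():
        warnings.warn(
            "constant violet channel in some pixels; regression skipped (c = 0)",
            RuntimeWarning,
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        c = np.where(degenerate, 0.0, cov / np.where(degenerate, 1.0, v_var))
    d = blue_dff.mean(axis=-1) - c * violet_lp.mean(axis=-1)

    corrected = blue_dff - (c[..., None] * violet_lp + d[..., None])

    sos8 = sps.butter(6, final_lowpass_hz, btype="lowpass", fs=fs, output="sos")
    corrected = sps.sosfiltfilt(sos8, corrected, axis=-1)

    factor = max(1, int(round(target_pixel_size / pixel_size)))
    corrected = _spatial_downsample(corrected, factor)

    fit = HemodynamicFit(
        detrend_a_blue=a_b,
        detrend_b_blue=b_b,
        detrend_a_violet=a_v,
        detrend_b_violet=b_v,
        regress_c=c,
        regress_d=d,
    )
    return corrected, fit
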