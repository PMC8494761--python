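"""Preprocessing of raw tonometric records.

Channel selection, Henderson-weighted moving-average smoothing, zero-phase
Butterworth band-limiting (default 0.005-30 Hz, the band carrying radial
pulse energy) and cubic-spline baseline correction anchored at the detected
pulse feet.  All operations preserve signal length and sampling rate.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import replace

import numpy as np
from scipy import signal as sps
from scipy.interpolate import CubicSpline

from .synth import RawPulseRecord

__all__ = [
    "select_channel",
    "henderson_weights",
    "henderson_smooth",
    "bandpass_filter",
    "correct_baseline",
]

log = logging.getLogger(__name__)


def select_channel(record: RawPulseRecord) -> RawPulseRecord:
    """Keep the channel with the largest peak-to-peak amplitude.

    Single-channel records pass through unchanged; amplitude ties break to
    the lowest channel index.
    """
    if record.samples.size == 0:
        raise ValueError("empty record")
    if record.samples.ndim == 1:
        return record
    ranges = record.samples.max(axis=0) - record.samples.min(axis=0)
    best = int(np.argmax(ranges))  # argmax returns the first (lowest) index on ties
    return replace(record, samples=record.samples[:, best])


def henderson_weights(term_count: int) -> np.ndarray:
    """Closed-form symmetric Henderson filter weights.

    For a (2m+1)-term filter with n = m + 2 and offsets j = -m..m:

        w_j = 315 [(n-1)^2 - j^2][n^2 - j^2][(n+1)^2 - j^2](3n^2 - 16 - 11 j^2)
              / (8 n (n^2-1)(4n^2-1)(4n^2-9)(4n^2-25))

    The weights sum to 1 and reproduce cubic polynomials exactly, which is
    why the filter smooths without flattening pulse peaks the way a flat
    moving average would.
    """
    if term_count % 2 == 0 or term_count < 5:
        raise ValueError("term_count must be an odd integer >= 5")
    m = (term_count - 1) // 2
    n = m + 2
    j = np.arange(-m, m + 1, dtype=float)
    num = (
        315.0
        * ((n - 1) ** 2 - j**2)
        * (n**2 - j**2)
        * ((n + 1) ** 2 - j**2)
        * (3 * n**2 - 16 - 11 * j**2)
    )
    den = 8.0 * n * (n**2 - 1) * (4 * n**2 - 1) * (4 * n**2 - 9) * (4 * n**2 - 25)
    return num / den


def henderson_smooth(signal: np.ndarray, term_count: int = 13) -> np.ndarray:
    """Symmetric Henderson-weighted moving average with reflection padding."""
    signal = np.asarray(signal, dtype=float)
    if term_count > signal.size:
        raise ValueError("term_count exceeds signal length")
    w = henderson_weights(term_count)
    m = (term_count - 1) // 2
    padded = np.pad(signal, m, mode="reflect")
    return np.convolve(padded, w[::-1], mode="valid")


def bandpass_filter(
    signal: np.ndarray,
    sampling_rate: float,
    low: float = 0.005,
    high: float = 30.0,
    order: int = 4,
) -> np.ndarray:
    """Zero-phase Butterworth band-pass retaining [low, high] Hz.

    Designed as second-order sections and applied forward-backward
    (``sosfiltfilt``), so the passband is traversed twice (effective order
    2x) with no phase distortion; DC is removed by the high-pass edge.
    """
    signal = np.asarray(signal, dtype=float)
    if not (0.0 < low < high < sampling_rate / 2.0):
        raise ValueError("need 0 < low < high < sampling_rate/2")
    sos = sps.butter(order, [low, high], btype="bandpass", fs=sampling_rate, output="sos")
    # Guard against numerically unstable designs (extreme band edge ratios).
    _, poles, _ = sps.sos2zpk(sos)
    if np.any(np.abs(poles) >= 1.0 - 1e-12):
        raise ValueError(
            "Butterworth design numerically unstable at this order/rate; "
            "reduce the filter order"
        )
    if signal.size == 0:
        return signal.copy()
    return sps.sosfiltfilt(sos, signal)


def correct_baseline(
    signal: np.ndarray,
    sampling_rate: float,
    foot_times: np.ndarray,
) -> np.ndarray:
    """Subtract a cubic spline through the (foot time, value) anchor points.

    The corrected signal is ~0 at every foot.  With fewer than 4 feet a cubic
    spline is under-determined, so the function falls back to a linear
    detrend and logs a warning.
    """
    signal = np.asarray(signal, dtype=float)
    foot_times = np.asarray(foot_times, dtype=float)
    if foot_times.size and np.any(np.diff(foot_times) <= 0):
        raise ValueError("foot times must be strictly increasing")
    if foot_times.size < 4:
        log.warning(
            "baseline correction needs >= 4 feet (got %d); falling back to linear detrend",
            foot_times.size,
        )
        warnings.warn("fewer than 4 feet: linear detrend fallback", stacklevel=2)
        return sps.detrend(signal, type="linear")
    t = np.arange(signal.size) / sampling_rate
    knot_vals = np.interp(foot_times, t, signal)
    spline = CubicSpline(foot_times, knot_vals, bc_type="natural", extrapolate=True)
    return signal - spline(t)
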