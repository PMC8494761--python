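"""Radial augmentation index (rAIx) via the fourth-derivative shoulder.

For type-C (radial) waveforms the late-systolic shoulder — the inflection or
secondary peak produced by the reflected (tidal) wave — is located at the
second negative-to-positive zero-crossing of the fourth derivative, counted
from the pulse onset.  The rAIx is the late-systolic amplitude over the
early-systolic (percussion peak) amplitude, x100 %, both measured from the
normalized foot; it is corrected to a reference heart rate of 75 bpm because
the index falls roughly linearly as heart rate rises.

Waveforms whose tidal wave is vague or absent cannot yield a reliable rAIx
and are flagged for exclusion; the sharpness index (see
:mod:`pulsesharp.sharpness`) remains computable on those morphologies.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.signal import savgol_filter

from .segment import EnsemblePulse
from .sharpness import find_percussion_peak

__all__ = [
    "AixFeatures",
    "smooth_derivative",
    "detect_shoulder",
    "compute_raix",
    "correct_raix_hr",
    "assess_exclusion",
    "extract_aix",
]

log = logging.getLogger(__name__)

#: Savitzky-Golay smoothing-differentiation parameters on the 800-sample grid.
SG_WINDOW = 21
SG_POLYORDER = 5

#: Default linear heart-rate correction slope, % per bpm.
HR_SLOPE_DEFAULT = 0.48

#: A shoulder candidate below this normalized amplitude is not a credible
#: late-systolic wave (the bare descending-limb inflection of a tidal-free
#: pulse sits near 0.07).
SHOULDER_MIN_AMPLITUDE = 0.2

#: Shoulder acceptance window: after the percussion peak, before this
#: fraction of the pulse duration.
SHOULDER_MAX_U = 0.6


@dataclass
class AixFeatures:
    """Augmentation features of one ensemble pulse."""

    peak: tuple[float, float]
    shoulder: tuple[float, float] | None
    raix: float | None
    raix75: float | None
    hr: float | None
    tidal_quality: str  # "clear", "vague" or "absent"


def smooth_derivative(pulse: EnsemblePulse, order: int) -> np.ndarray:
    """k-th derivative (per second) by local-polynomial smoothing.

    Savitzky-Golay differentiation (window 21, polynomial order 5) rather
    than repeated differencing, since plain numerical differentiation
    amplifies high-frequency noise — the reason fourth-derivative methods
    need a smoothing differentiator in the first place.
    """
    if not (1 <= order <= 4):
        raise ValueError("derivative order must be 1-4")
    dt = pulse.duration_s / (pulse.samples.size - 1)
    return savgol_filter(pulse.samples, SG_WINDOW, SG_POLYORDER, deriv=order, delta=dt)


def _neg_to_pos_crossings(d4: np.ndarray, start: int = 0) -> list[float]:
    """Fractional indices where d4 crosses from negative to non-negative."""
    out = []
    for i in range(max(start, 1), d4.size - 1):
        if d4[i] < 0.0 <= d4[i + 1]:
            frac = d4[i] / (d4[i] - d4[i + 1])
            out.append(i + frac)
    return out


def detect_shoulder(
    pulse: EnsemblePulse,
    min_amplitude: float = SHOULDER_MIN_AMPLITUDE,
    max_u: float = SHOULDER_MAX_U,
) -> tuple[tuple[float, float] | None, str]:
    """Locate the late-systolic shoulder; classify the tidal-wave quality.

    The candidate is the second negative-to-positive zero-crossing of the
    fourth derivative counted from the pulse onset (if that crossing falls
    before the percussion peak — a miscount on unusual morphologies — the
    first crossing after the peak is used instead).  The crossing marks the
    onset of the shoulder region; the shoulder itself is refined to the local
    maximum of the waveform just after the crossing, or, for inflection-type
    shoulders that never turn upward, to the flattest point (maximum of the
    first derivative).  The candidate is accepted as *clear* only when it
    lies after the peak, before ``max_u`` of the duration, and at a
    normalized amplitude of at least ``min_amplitude``; otherwise the tidal
    wave is *vague*.  With no crossing after the peak at all it is *absent*.
    """
    y = pulse.samples
    n = y.size
    if float(np.ptp(y)) == 0.0:
        return None, "absent"
    peak = find_percussion_peak(pulse)
    i_peak = peak[0] * (n - 1)
    d4 = smooth_derivative(pulse, 4)
    # Ignore the first 2% of samples: boundary transients of the smoothing
    # differentiator can fabricate a crossing at the very edge.
    crossings = _neg_to_pos_crossings(d4, start=max(2, n // 50))
    after_peak = [c for c in crossings if c > i_peak]
    if not after_peak:
        return None, "absent"
    candidate = crossings[1] if len(crossings) >= 2 and crossings[1] > i_peak else after_peak[0]

    # Refine within the shoulder region following the crossing.  The window
    # runs through the shoulder acceptance region (slightly past max_u so a
    # shoulder top just inside the limit is still resolvable); taking the
    # FIRST local maximum below keeps the refinement from drifting onto
    # later waves, and the acceptance window itself rejects the dicrotic
    # wave, which sits beyond 0.6 of the duration in radial morphology.
    d1 = smooth_derivative(pulse, 1)
    j0 = int(np.ceil(candidate))
    j1 = min(n - 1, int((max_u + 0.05) * n))
    if j1 <= j0 + 1:
        return None, "vague"
    seg_d1 = d1[j0:j1]
    down = np.flatnonzero((seg_d1[:-1] > 0) & (seg_d1[1:] <= 0))
    if down.size:  # a genuine local maximum: derivative falls through zero
        j = j0 + int(down[0])
        frac = seg_d1[down[0]] / (seg_d1[down[0]] - seg_d1[down[0] + 1])
        idx = j + float(frac)
    else:
        # Inflection-type shoulder: the first local maximum of the slope
        # after the crossing (the flattening point), not the global argmax,
        # which on long windows would drift onto the dicrotic upstroke.
        rising_ends = np.flatnonzero(np.diff(seg_d1) < 0)
        idx = j0 + (int(rising_ends[0]) if rising_ends.size else int(np.argmax(seg_d1)))
    u_sh = idx / (n - 1)
    y_sh = float(pulse.value_at(u_sh))
    shoulder = (float(u_sh), y_sh)
    if u_sh <= peak[0] or u_sh >= max_u or y_sh < min_amplitude:
        return shoulder, "vague"
    return shoulder, "clear"


def compute_raix(pulse: EnsemblePulse, shoulder: tuple[float, float]) -> float:
    """rAIx = 100 * (late systolic amplitude / early systolic amplitude).

    Amplitudes are measured from the normalized foot (y = 0); with the peak
    normalized to 1, the index reduces to 100 * y_shoulder.
    """
    if shoulder is None:
        raise ValueError("shoulder undefined: tidal wave vague or absent")
    peak = find_percussion_peak(pulse)
    return 100.0 * shoulder[1] / peak[1]


def correct_raix_hr(raix: float, hr: float, slope: float = HR_SLOPE_DEFAULT) -> float:
    """Correct the rAIx to a reference heart rate of 75 bpm.

    ``raix@75 = raix + slope * (hr - 75)`` with slope > 0 restoring the
    roughly linear decrease of the index with heart rate.  At 75 bpm the
    correction is an exact identity.
    """
    if not (np.isfinite(raix) and np.isfinite(hr)):
        raise ValueError("raix and hr must be finite")
    if not (30.0 <= hr <= 200.0):
        raise ValueError("hr must lie in 30-200 bpm")
    return raix + slope * (hr - 75.0)


def assess_exclusion(pulse: EnsemblePulse) -> str:
    """'analyzable' when the tidal shoulder is clear, else 'excluded'."""
    _, quality = detect_shoulder(pulse)
    return "analyzable" if quality == "clear" else "excluded"


def extract_aix(pulse: EnsemblePulse, hr: float | None = None, hr_slope: float = HR_SLOPE_DEFAULT) -> AixFeatures:
    """Full augmentation-feature extraction on one ensemble pulse."""
    peak = find_percussion_peak(pulse)
    shoulder, quality = detect_shoulder(pulse)
    hr = hr if hr is not None else pulse.source_hr
    if quality != "clear":
        return AixFeatures(peak, shoulder, None, None, hr, quality)
    raix = compute_raix(pulse, shoulder)
    raix75 = correct_raix_hr(raix, hr, hr_slope) if hr is not None else None
    return AixFeatures(peak, shoulder, raix, raix75, hr, quality)
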