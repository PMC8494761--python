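"""Synthetic radial-pulse generation with known ground truth.

A single beat is modelled as the sum of three Gaussian bumps — percussion,
tidal and dicrotic waves — placed along one cardiac cycle.  A scalar
*blunting* parameter ``b`` in [0, 1] emulates vascular aging: it widens the
percussion wave and raises the tidal-to-percussion amplitude ratio, which is
the morphological pattern seen when ensemble-average radial pulses are
stratified by age.  Records (concatenated beats plus white noise and slow
sinusoidal baseline drift) and whole cohorts with an age-driven blunting
mapping can be generated reproducibly from a seed.

The generator emits ground truth alongside every record: beat (cycle) start
times and the analytically derived intersecting-tangent foot time of the
noise-free template, so that onset-detection accuracy can be measured
without circular reference to the detector under test.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "PulseModelParams",
    "NoiseSpec",
    "CohortSpec",
    "RawPulseRecord",
    "generate_single_pulse",
    "single_pulse_components",
    "itm_foot_time",
    "template_at_foot",
    "generate_series",
    "generate_cohort",
    "params_for_shoulder_ratio",
    "write_waveform",
]

# Blunting mapping constants: sigma_p(b) = sigma_p0 * (1 + SIGMA_P_GAIN * b),
# a_t(b)/a_p = TIDAL_BASE + TIDAL_GAIN * b, and the tidal wave returns
# earlier with stiffening, t_t(b) = t_t0 - TIDAL_ADVANCE * b (faster wave
# reflection is the textbook mechanism of the age-related morphology change).
# Overridable per parameter set.
SIGMA_P_GAIN = 2.0
TIDAL_BASE = 0.35
TIDAL_GAIN = 0.5
TIDAL_ADVANCE = 0.04


@dataclass(frozen=True)
class PulseModelParams:
    """Parameters of the three-component single-beat model.

    Component centres ``t_p < t_t < t_d`` are seconds from beat onset;
    amplitudes are arbitrary pressure units; widths are the Gaussian sigma in
    seconds.  ``sigma_p`` is the *base* percussion width: the effective width
    used at generation time is ``sigma_p * (1 + 2 b)``.  ``a_t=None`` means
    "derive the tidal amplitude from the blunting mapping
    ``a_p * (0.35 + 0.5 b)``"; an explicit value (including 0 for a
    tidal-free morphology) overrides the mapping.
    """

    heart_rate: float = 72.0  # bpm; cycle_length = 60 / heart_rate
    t_p: float = 0.13
    t_t: float = 0.29
    t_d: float = 0.55
    a_p: float = 1.0
    a_t: float | None = None
    a_d: float = 0.25
    sigma_p: float = 0.018
    sigma_t: float = 0.040
    sigma_d: float = 0.055
    blunting: float = 0.0
    tidal_advance: float = TIDAL_ADVANCE
    sampling_rate: float = 1000.0

    @property
    def cycle_length(self) -> float:
        return 60.0 / self.heart_rate

    @property
    def sigma_p_eff(self) -> float:
        return self.sigma_p * (1.0 + SIGMA_P_GAIN * self.blunting)

    @property
    def t_t_eff(self) -> float:
        return self.t_t - self.tidal_advance * self.blunting

    @property
    def a_t_eff(self) -> float:
        if self.a_t is not None:
            return self.a_t
        return self.a_p * (TIDAL_BASE + TIDAL_GAIN * self.blunting)

    def validate(self) -> None:
        if not (0.0 <= self.blunting <= 1.0):
            raise ValueError(f"blunting must be in [0, 1], got {self.blunting}")
        if not (0.0 < self.t_p < self.t_t_eff < self.t_d < self.cycle_length):
            raise ValueError(
                "component centres must satisfy 0 < t_p < t_t < t_d < cycle_length; "
                f"got t_p={self.t_p}, t_t(b)={self.t_t_eff}, t_d={self.t_d}, "
                f"cycle_length={self.cycle_length:.3f}"
            )
        if min(self.sigma_p, self.sigma_t, self.sigma_d) <= 0.0:
            raise ValueError("all component widths must be positive")
        if self.a_p <= 0.0 or self.a_t_eff < 0.0 or self.a_d < 0.0:
            raise ValueError("amplitudes must satisfy a_p > 0, a_t >= 0, a_d >= 0")
        if self.a_t_eff > self.a_p:
            raise ValueError("percussion must dominate: a_t <= a_p")
        if self.sampling_rate <= 0.0:
            raise ValueError("sampling_rate must be positive")
        if not (30.0 <= self.heart_rate <= 200.0):
            raise ValueError("heart_rate must lie in 30-200 bpm")


@dataclass(frozen=True)
class NoiseSpec:
    """Additive artifact model: white noise plus slow sinusoidal drift."""

    white_sd: float = 0.0
    drift_amplitude: float = 0.0
    drift_frequency: float = 0.05  # Hz, below the high-pass edge being probed
    seed: int = 0

    def validate(self) -> None:
        if self.white_sd < 0.0 or self.drift_amplitude < 0.0:
            raise ValueError("noise amplitudes must be non-negative")
        if not (0.0 < self.drift_frequency < 0.5):
            raise ValueError("drift frequency must lie in (0, 0.5) Hz")


@dataclass(frozen=True)
class CohortSpec:
    """Specification of a synthetic cohort with an age-driven blunting law.

    Ages are drawn on [age_min, age_max] (years); the study population this
    emulates spanned 20-84 years with an age distribution skewed young, hence
    the shifted-exponential default.  Blunting follows
    ``b = clip(intercept + slope * (age - age_min) + N(0, noise_sd), 0, 0.95)``.
    A small fraction of subjects is generated tidal-free (a_t = 0), the
    morphology for which the augmentation index is not measurable.
    """

    n_subjects: int = 100
    age_min: float = 20.0
    age_max: float = 84.0
    age_distribution: str = "exponential"  # or "uniform"
    age_scale: float = 15.0  # exponential scale in years
    female_fraction: float = 0.73
    blunting_slope: float = 0.0115  # per year
    blunting_intercept: float = 0.05
    blunting_noise_sd: float = 0.06
    hr_mean: float = 70.0
    hr_sd: float = 9.0
    tidal_free_fraction: float = 0.045
    duration: float = 10.0  # seconds per record
    noise: NoiseSpec = field(default_factory=lambda: NoiseSpec(white_sd=0.01, drift_amplitude=0.05))
    seed: int = 0

    def validate(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        if not (20.0 <= self.age_min <= self.age_max <= 84.0):
            raise ValueError("ages must lie within 20-84 years")
        if self.age_min == self.age_max:
            warnings.warn("degenerate age sampler: zero age range", stacklevel=2)
        if not (0.0 <= self.female_fraction <= 1.0):
            raise ValueError("female_fraction must lie in [0, 1]")
        if not (0.0 <= self.tidal_free_fraction <= 1.0):
            raise ValueError("tidal_free_fraction must lie in [0, 1]")


@dataclass
class RawPulseRecord:
    """A sampled pressure record: the unit of ingestion.

    ``samples`` has shape (n,) for single-channel or (n, n_channels) for
    multichannel data.  Ground-truth fields are populated by the generator
    and absent (None) for records read from disk.
    """

    samples: np.ndarray
    sampling_rate: float
    subject_id: str = "anon"
    age: float | None = None
    sex: int | None = None  # 0 = man, 1 = woman
    heart_rate: float | None = None
    sbp: float | None = None
    dbp: float | None = None
    truth_onsets: np.ndarray | None = None  # beat (cycle) start times, s
    truth_feet: np.ndarray | None = None  # intersecting-tangent foot times, s

    @property
    def n_channels(self) -> int:
        return 1 if self.samples.ndim == 1 else self.samples.shape[1]

    @property
    def duration(self) -> float:
        return self.samples.shape[0] / self.sampling_rate


def _component(t: np.ndarray, a: float, c: float, s: float, cycle: float) -> np.ndarray:
    """Periodic Gaussian bump: neighbouring-cycle copies are summed so that
    concatenated beats are continuous at cycle boundaries (the diastolic
    decay runs smoothly into the next upstroke, as in a real pulse train)."""
    t = np.asarray(t, dtype=float)
    out = np.zeros_like(t)
    for k in (-1.0, 0.0, 1.0):
        out = out + a * np.exp(-0.5 * ((t - c - k * cycle) / s) ** 2)
    return out


def single_pulse_components(params: PulseModelParams) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Return (t, percussion, tidal, dicrotic) for one cycle."""
    params.validate()
    n = int(round(params.cycle_length * params.sampling_rate))
    t = np.arange(n) / params.sampling_rate
    cyc = params.cycle_length
    perc = _component(t, params.a_p, params.t_p, params.sigma_p_eff, cyc)
    tidal = _component(t, params.a_t_eff, params.t_t_eff, params.sigma_t, cyc)
    dicr = _component(t, params.a_d, params.t_d, params.sigma_d, cyc)
    return t, perc, tidal, dicr


def generate_single_pulse(params: PulseModelParams) -> np.ndarray:
    """One noise-free cycle of the three-component beat model.

    Deterministic: no randomness is involved.  The value at t=0 is the sum of
    component tails only (numerically ~0 for physiological parameters).
    """
    _, perc, tidal, dicr = single_pulse_components(params)
    return perc + tidal + dicr


def _beat_value(params: PulseModelParams, t: np.ndarray | float) -> np.ndarray | float:
    t = np.asarray(t, dtype=float)
    cyc = params.cycle_length
    return (
        _component(t, params.a_p, params.t_p, params.sigma_p_eff, cyc)
        + _component(t, params.a_t_eff, params.t_t_eff, params.sigma_t, cyc)
        + _component(t, params.a_d, params.t_d, params.sigma_d, cyc)
    )


def _beat_slope(params: PulseModelParams, t: np.ndarray | float) -> np.ndarray | float:
    t = np.asarray(t, dtype=float)
    out = np.zeros_like(t)
    cyc = params.cycle_length
    for a, c, s in (
        (params.a_p, params.t_p, params.sigma_p_eff),
        (params.a_t_eff, params.t_t_eff, params.sigma_t),
        (params.a_d, params.t_d, params.sigma_d),
    ):
        for k in (-1.0, 0.0, 1.0):
            x = t - c - k * cyc
            out = out + a * np.exp(-0.5 * (x / s) ** 2) * (-x / s**2)
    return out


def itm_foot_time(params: PulseModelParams) -> float:
    """Intersecting-tangent foot time of the noise-free beat template.

    Reference fiducial for onset-detection accuracy: the tangent at the point
    of maximum upslope on the percussion rising limb is intersected with the
    horizontal line through the pre-upstroke minimum.  Evaluated on the
    analytic waveform (closed-form derivative, dense search + refinement),
    independently of any detector operating on sampled data.
    """
    params.validate()
    # Search the rising limb only.
    tt = np.linspace(0.0, params.t_p, 4001)
    sl = np.asarray(_beat_slope(params, tt))
    i = int(np.argmax(sl))
    # Golden-section style refinement via a fine local grid.
    lo = tt[max(i - 1, 0)]
    hi = tt[min(i + 1, len(tt) - 1)]
    tf = np.linspace(lo, hi, 2001)
    slf = np.asarray(_beat_slope(params, tf))
    j = int(np.argmax(slf))
    t_ms = float(tf[j])
    m = float(slf[j])
    y_ms = float(_beat_value(params, t_ms))
    # Pre-upstroke minimum: the beat is periodic, so the end-diastolic trough
    # may sit just before the cycle boundary; search half a cycle back.
    tb = np.linspace(t_ms - 0.5 * params.cycle_length, t_ms, 4001)
    y_min = float(np.min(_beat_value(params, tb)))
    return t_ms - (y_ms - y_min) / m


def template_at_foot(params: PulseModelParams) -> np.ndarray:
    """The single-beat template rolled to start at the (sampled) ITM foot.

    This is the beat an onset-splitting pipeline recovers from a noise-free
    record, rolled by the foot time rounded to the sampling grid; the
    reference for ensemble-fidelity checks.
    """
    beat = generate_single_pulse(params)
    shift = int(round(itm_foot_time(params) * params.sampling_rate))
    return np.roll(beat, -shift)


def generate_series(
    params: PulseModelParams,
    duration: float = 60.0,
    noise: NoiseSpec | None = None,
    subject_id: str = "anon",
    **meta,
) -> RawPulseRecord:
    """Concatenate beats into a record with seeded noise and baseline drift.

    Ground-truth cycle starts and intersecting-tangent foot times are
    attached to the returned record.  Reproducible from ``noise.seed``.
    """
    params.validate()
    noise = noise or NoiseSpec()
    noise.validate()
    if duration < 2.0 * params.cycle_length:
        raise ValueError("duration must cover at least 2 cardiac cycles")

    beat = generate_single_pulse(params)
    n_total = int(round(duration * params.sampling_rate))
    n_beats = int(np.ceil(n_total / beat.size))
    signal = np.tile(beat, n_beats)[:n_total]

    onsets = np.arange(n_beats) * beat.size / params.sampling_rate
    onsets = onsets[onsets < duration]
    foot_offset = itm_foot_time(params)
    feet = onsets + foot_offset

    rng = np.random.default_rng(noise.seed)
    t = np.arange(n_total) / params.sampling_rate
    if noise.drift_amplitude > 0.0:
        phase = rng.uniform(0.0, 2.0 * np.pi)
        signal = signal + noise.drift_amplitude * np.sin(
            2.0 * np.pi * noise.drift_frequency * t + phase
        )
    if noise.white_sd > 0.0:
        signal = signal + rng.normal(0.0, noise.white_sd, n_total)

    return RawPulseRecord(
        samples=signal,
        sampling_rate=params.sampling_rate,
        subject_id=subject_id,
        heart_rate=params.heart_rate,
        truth_onsets=onsets,
        truth_feet=feet,
        **meta,
    )


def _sample_ages(spec: CohortSpec, rng: np.random.Generator) -> np.ndarray:
    if spec.age_min == spec.age_max:
        return np.full(spec.n_subjects, spec.age_min)
    if spec.age_distribution == "uniform":
        return rng.uniform(spec.age_min, spec.age_max, spec.n_subjects)
    if spec.age_distribution == "exponential":
        # Shifted exponential, resampled into range (skewed-young population).
        ages = spec.age_min + rng.exponential(spec.age_scale, spec.n_subjects)
        bad = ages > spec.age_max
        while bad.any():
            ages[bad] = spec.age_min + rng.exponential(spec.age_scale, int(bad.sum()))
            bad = ages > spec.age_max
        return ages
    raise ValueError(f"unknown age distribution: {spec.age_distribution!r}")


def generate_cohort(
    spec: CohortSpec,
) -> tuple[list[RawPulseRecord], pd.DataFrame]:
    """Generate per-subject records plus a ground-truth table.

    The truth table has columns ``subject_id, age, sex, hr, blunting,
    tidal_free, seed``; blunting increases with age per the cohort mapping,
    and sex is encoded 0 = man, 1 = woman.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    ages = _sample_ages(spec, rng)
    sexes = (rng.uniform(size=spec.n_subjects) < spec.female_fraction).astype(int)
    hrs = np.clip(rng.normal(spec.hr_mean, spec.hr_sd, spec.n_subjects), 50.0, 95.0)
    blunt = np.clip(
        spec.blunting_intercept
        + spec.blunting_slope * (ages - spec.age_min)
        + rng.normal(0.0, spec.blunting_noise_sd, spec.n_subjects),
        0.0,
        0.95,
    )
    tidal_free = rng.uniform(size=spec.n_subjects) < spec.tidal_free_fraction

    records: list[RawPulseRecord] = []
    rows = []
    for i in range(spec.n_subjects):
        subj_seed = int((spec.seed + 7919 * (i + 1)) % 2**31)
        params = PulseModelParams(
            heart_rate=float(hrs[i]),
            blunting=float(blunt[i]),
            a_t=0.0 if tidal_free[i] else None,
        )
        noise = replace(spec.noise, seed=subj_seed)
        sid = f"S{i:04d}"
        rec = generate_series(
            params,
            duration=spec.duration,
            noise=noise,
            subject_id=sid,
            age=float(ages[i]),
            sex=int(sexes[i]),
        )
        records.append(rec)
        rows.append(
            dict(
                subject_id=sid,
                age=float(ages[i]),
                sex=int(sexes[i]),
                hr=float(hrs[i]),
                blunting=float(blunt[i]),
                tidal_free=bool(tidal_free[i]),
                seed=subj_seed,
            )
        )
    return records, pd.DataFrame(rows)


def params_for_shoulder_ratio(
    rho: float,
    base: PulseModelParams | None = None,
) -> PulseModelParams:
    """Construct beat parameters whose tidal shoulder sits at a known height.

    Solves for the tidal amplitude such that the normalized waveform height at
    the late-systolic (tidal) local extremum equals ``rho`` of the percussion
    peak height, giving a beat with ground-truth augmentation ratio
    ``100 * rho`` percent.
    """
    if not (0.0 < rho < 1.0):
        raise ValueError("rho must lie in (0, 1)")
    base = base or PulseModelParams()

    def shoulder_ratio(a_t: float) -> float:
        p = replace(base, a_t=a_t)
        t = np.linspace(0.0, p.cycle_length, 8001)
        y = np.asarray(_beat_value(p, t))
        peak = float(y.max())
        # Height at the late-systolic extremum/plateau near the tidal centre:
        # the point of maximal (least negative) slope, or the local maximum.
        win = (t > p.t_p + 1.5 * p.sigma_p_eff) & (t < p.t_t_eff + 2.0 * p.sigma_t)
        sl = np.asarray(_beat_slope(p, t))[win]
        yw = y[win]
        j = int(np.argmax(sl))
        if sl[j] > 0:  # distinct bump: walk to its top
            jj = j
            while jj + 1 < yw.size and yw[jj + 1] >= yw[jj]:
                jj += 1
            j = jj
        return float(yw[j]) / peak

    from scipy.optimize import brentq

    a_t = brentq(lambda a: shoulder_ratio(a) - rho, 1e-6, base.a_p, xtol=1e-10)
    return replace(base, a_t=float(a_t))


def write_waveform(path: str | Path, record: RawPulseRecord) -> None:
    """Write a record as delimited text with `# key=value` header lines."""
    path = Path(path)
    lines = [f"# fs_hz={record.sampling_rate:g}", f"# subject_id={record.subject_id}"]
    for key in ("age", "sex", "heart_rate", "sbp", "dbp"):
        val = getattr(record, key)
        if val is not None:
            lines.append(f"# {key}={val:g}")
    buf = io.StringIO()
    samples = np.atleast_2d(record.samples.T).T
    np.savetxt(buf, samples, fmt="%.9g", delimiter="\t")
    path.write_text("\n".join(lines) + "\n" + buf.getvalue())
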