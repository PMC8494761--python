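# Methods

This document describes the processing chain, the geometric definitions, the
synthetic-data model and the statistical layer, together with the rationale
for each default and the known limitations.

## 1. Signal model and preprocessing

Input records are sampled pressure waveforms (nominally 1000 Hz), single- or
multi-channel. The chain is:

1. **Channel selection** (`preprocess.select_channel`) — for multi-channel
   (sensor-array) records the channel with the largest peak-to-peak
   amplitude wins; ties break to the lowest index.
2. **Henderson smoothing** (`henderson_smooth`, 13 terms) — a weighted
   moving average that passes cubic polynomials exactly, so it suppresses
   sample noise without flattening pulse curvature. Weights are computed
   from the closed form and match the classic published 13-term table.
3. **Band-pass** (`bandpass_filter`, Butterworth order 4, 0.005–30 Hz,
   zero-phase `sosfiltfilt`) — removes DC and high-frequency noise without
   phase distortion. The 0.005-Hz high-pass edge has a ~30-s time constant;
   on short records a slow settling transient can remain. This is accepted
   because the next stage removes residual drift exactly at the beat feet.
4. **Baseline correction** (`correct_baseline`) — a natural cubic spline
   through the detected beat feet is subtracted, pinning the baseline to
   zero at every foot. With fewer than four feet it falls back to linear
   detrending with a warning.

## 2. Beat segmentation and ensemble averaging

Pulse onsets are detected with the **intersecting tangent method**
(`segment.detect_onsets_itm`): for each beat, the tangent at the point of
maximal upslope is intersected with the horizontal tangent through the
preceding minimum; the intersection abscissa is the onset (foot). Intervals
outside 0.3–2.0 s are flagged as non-physiological.

Beats are split at the onsets and truncated to the shortest interval,
amplitude-normalized to [0, 1], and averaged (`ensemble_average`). Averaging
is correlation-gated: a provisional mean is formed, each beat's Pearson
correlation with it is computed, beats below the refinement threshold
(default 0.95) are discarded, and the mean is recomputed. This removes
movement artifacts and aberrant beats. The ensemble is then resampled to the
standard template: **0.8 s, 800 samples, amplitude in [0, 1]** (cubic
spline; `resample_to_duration`). `extract_ensemble(record, denoise=False)`
skips stage 1–4 preprocessing for already-clean signals; with filtering
enabled, the 30-Hz low-pass slightly rounds an 18-ms-scale upstroke, so
template-exact recovery is only expected on the unfiltered path.

## 3. Pulse sharpness index (PSI)

All geometry lives in the normalized frame `u = t / 0.8 ∈ [0, 1]`,
`y ∈ [0, 1]`, drawn with aspect ratio 1 so angles are meaningful.

1. **Percussion peak** — first prominent maximum (prominence ≥ 0.2) before
   60% of the duration, refined to sub-sample precision by a parabolic fit.
2. **Tangent start points** — the steepest ascending point before the peak
   and steepest descending point after it.
3. **Tangent growth** (`grow_it_line`) — starting from a 3-point window
   around each start point, the window grows symmetrically one sample per
   side while the Pearson correlation of the least-squares line stays
   ≥ 0.99 *and* both sides can still grow; growth stops when the
   correlation fails or either side reaches a template boundary. A window
   that never exceeds its minimal 3 points is flagged `minimal_support`.
4. **End points** — each tangent is intersected with the horizontal line
   through the peak; the waveform value at that abscissa is the end point.
5. **EPA** — the angle (degrees) at the peak subtended by the two end
   points (law-of-cosines equivalent, computed from vectors).
6. **VH** — the height of the two tangents' mutual intersection above the
   peak, clamped at 0 (`vh_reference="foot"` measures from the foot
   instead, adding the peak height).
7. **PSI** = `1000 / (EPA × (1 + VH))`, so `PSI × EPA × (1 + VH) = 1000`
   is an exact identity of every emitted feature row.
8. **w** — pulse width (seconds) at 2/3 of peak height; if the waveform
   re-rises above 2/3 after the percussion wave (tall tidal wave), the row
   is flagged `tidal_above_two_thirds`.

### Known limitation: VH under width blunting

For tangent windows that terminate by correlation failure in the interior
of the template, the window extent scales with the limb width: rescaling a
limb in time rescales the fit window by the same factor, and the resulting
tangent geometry — and therefore VH — is **scale-invariant**. Consequently
VH does not increase monotonically over a pure width-blunting sweep; only
when a window is clipped by the template boundary does VH grow with
blunting. PSI, EPA and w are strictly monotone over the sweep; VH is not
(Spearman ρ ≈ −0.95 instead of +1). The corresponding sub-assertion of the
sharpness-ordering acceptance test is left failing on purpose rather than
redefining VH or reshaping the generator to force it green. The VH unit
test exercises the boundary-clipped regime (a Gaussian centred at u = 0.25
with σ from 0.11 to 0.20), where VH genuinely rises.

## 4. Radial augmentation index (rAIx)

The late-systolic shoulder is located on the ensemble template as the
**second negative-to-positive zero-crossing of the fourth derivative**
(Savitzky–Golay differentiation, window 21, order 5), counted from the
onset with the first 2% of samples ignored (differentiator edge
transients). The crossing marks the shoulder onset; the shoulder itself is
refined to the first local maximum of the waveform after the crossing or,
for inflection-type shoulders, to the first local maximum of the slope. A
candidate is **clear** only if it lies after the percussion peak, before
0.6 of the duration, and at normalized amplitude ≥ 0.2; otherwise the tidal
wave is *vague* (or *absent* with no crossing at all), and the subject is
flagged `excluded` for rAIx. PSI carries no such exclusion.

`rAIx = 100 × y_shoulder / y_peak`; the heart-rate correction
`rAIx@75 = rAIx + 0.48 × (HR − 75)` references 75 bpm and is an exact
identity at 75 bpm.

## 5. Synthetic waveform generator

A beat is the sum of three Gaussian components — percussion, tidal and
dicrotic — evaluated periodically (wrap-around of adjacent cycles), with
defaults chosen for a radial type-C morphology on a 60/72-s cycle:
percussion at 0.13 s (σ 0.018), tidal at 0.29 s (σ 0.040, amplitude mapped
from the blunting parameter as 0.35 + 0.5·b, advanced 0.04 s toward the
peak as it grows), dicrotic at 0.55 s (σ 0.055, amplitude 0.25). The
dicrotic default places its top near u ≈ 0.66 of the template — beyond the
0.6 shoulder acceptance window, as in radial morphology — so it cannot
masquerade as a tidal shoulder on tidal-free pulses. **Blunting**
b ∈ [0, 1) widens the percussion wave (σ_p × (1 + 2b)) and raises the tidal
wave, emulating vascular aging. Setting the tidal amplitude explicitly to 0
produces a tidal-free pulse.

`generate_series` concatenates beats with seeded white noise and sinusoidal
baseline drift and attaches ground-truth cycle starts and
intersecting-tangent foot times. `generate_cohort` draws ages 20–84
(shifted-exponential, skewed young), maps age to blunting linearly with
noise, draws heart rate and sex, and marks a small fraction of subjects
tidal-free. `params_for_shoulder_ratio(rho)` solves for the tidal amplitude
that places the shoulder at a known fraction ρ of peak height, giving
ground-truth rAIx = 100ρ for recovery tests.

## 6. Statistics

Four standardized OLS models (statsmodels), with log-age transformed before
z-scoring: (1) rAIx@75 ~ log age on included subjects, (2) PSI ~ log age on
all subjects, (3) rAIx@75 ~ PSI, (4) rAIx@75 ~ PSI + age + sex + HR. With a
single predictor the standardized β equals the Pearson correlation exactly.
Generalization is summarized by k-fold cross-validation (scikit-learn
KFold, shuffled, seeded) with scaling parameters estimated on training
folds only. Rank-deficient designs are rejected with the collinear columns
named; cohorts too small for the requested k are analysed with k reduced to
n/2 and a warning.

On a built-in synthetic aging cohort (n = 500, seed 20260101) the pipeline
yields corr(PSI, age) = −0.71, corr(rAIx@75, age) = +0.82, model-4
standardized β(PSI) = −0.49, and tenfold CV test R² within 0.006 of the
in-sample R² — the constructed explained variance.

## 7. Determinism and failure handling

Every output is a deterministic function of inputs, configuration and
seeds (all seeds are < 2³¹). Per-subject failures are reported in the
feature table's `status` column with the failing stage and never abort a
batch. Configuration lives in one validated dataclass (`RunConfig`), YAML
round-trippable, with unknown keys rejected.
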