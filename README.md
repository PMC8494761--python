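# pulsesharp

Radial-pulse waveform analysis: the **pulse sharpness index (PSI)** — a
geometric measure of how sharp the percussion peak of an arterial pulse is —
together with the **radial augmentation index (rAIx)**, tonometric
preprocessing, beat segmentation / ensemble averaging, a synthetic-waveform
generator and a small statistics layer for cohort analyses.

## What it computes

Each beat is reduced to a normalized template: duration 0.8 s on an
800-sample grid, amplitude scaled to [0, 1], plotted with aspect ratio 1 so
that angles are well defined.

* **PSI** — tangent lines are grown along the ascending and descending limbs
  of the percussion wave (symmetric windows that expand while the
  point-line correlation stays ≥ 0.99). Each tangent is intersected with the
  horizontal line through the peak; the waveform points at those two
  intersection abscissae are the *end points*. The angle at the peak
  subtended by the two end points is the **end-point angle (EPA, degrees)**;
  the height of the tangents' mutual intersection above the peak is the
  **vertex height (VH)**. Then

  ```
  PSI = 1000 / (EPA × (1 + VH))
  ```

  Sharp, narrow pulses give small EPA and large PSI; blunted pulses give
  large EPA and small PSI. The pulse width at 2/3 height (**w**, seconds) is
  reported alongside.

* **rAIx** — the late-systolic shoulder is located at the second
  negative-to-positive zero-crossing of the Savitzky–Golay fourth
  derivative, refined to the local maximum (or flattening point) just after
  it. rAIx = 100 × shoulder height / peak height, corrected to a 75-bpm
  reference as `rAIx@75 = rAIx + 0.48 × (HR − 75)`. Pulses without a
  measurable tidal wave are flagged `excluded` for rAIx — PSI remains
  computable on every morphology.

## Worked example

```python
from pulsesharp import PulseModelParams, NoiseSpec, generate_series
from pulsesharp.segment import extract_ensemble
from pulsesharp.sharpness import extract_sharpness
from pulsesharp.raix import extract_aix

params = PulseModelParams(blunting=0.3)
record = generate_series(params, duration=30.0,
                         noise=NoiseSpec(white_sd=0.01, drift_amplitude=0.05, seed=1))
pulse = extract_ensemble(record)          # denoise, segment, ensemble-average
f = extract_sharpness(pulse)
print(f"PSI  = {f.psi:.2f}")
print(f"EPA  = {f.epa_deg:.1f} deg, VH = {f.vh:.3f}, w = {f.w_s*1000:.0f} ms")
ax = extract_aix(pulse)
print(f"rAIx = {ax.raix:.1f} % ({ax.tidal_quality}), rAIx@75 = {ax.raix75:.1f} %")
```

prints

```
PSI  = 18.17
EPA  = 51.4 deg, VH = 0.071, w = 50 ms
rAIx = 50.1 % (clear), rAIx@75 = 48.7 %
```

## Command line

```
pulsesharp simulate --n 20 --seed 1 --out cohort/        # synthetic cohort + truth.csv
pulsesharp extract cohort/S0000.txt --out pulse.csv      # one ensemble pulse
pulsesharp features cohort/*.txt --out features.csv      # PSI/rAIx feature table
pulsesharp stats --cohort features.csv --out report.json # four-model analysis
pulsesharp run --config config.yaml                      # full file-level pipeline
```

`pulsesharp run` reads every `*.txt`/`*.tsv` waveform in `input_dir` (plain
text, `# key=value` headers with a mandatory `# fs_hz=...` line, one sample
row per time step), joins optional cohort metadata, and writes
`features.csv` + `report.json`.

## Modules

| module | contents |
|---|---|
| `pulsesharp.synth` | three-Gaussian beat model, aging/blunting cohort generator, ground-truth onsets |
| `pulsesharp.preprocess` | channel selection, 13-term Henderson smoothing, zero-phase Butterworth band-pass, cubic-spline baseline correction |
| `pulsesharp.segment` | intersecting-tangent onset detection, beat splitting, correlation-gated ensemble averaging, 800-sample template resampling |
| `pulsesharp.sharpness` | percussion peak, tangent-line growth, end points, EPA, VH, PSI, width |
| `pulsesharp.raix` | fourth-derivative shoulder detection, rAIx, heart-rate correction, exclusion flag |
| `pulsesharp.stats` | Pearson r, standardized OLS, k-fold CV, four-model cohort report |
| `pulsesharp.io` / `pulsesharp.pipeline` / `pulsesharp.cli` | file formats, run configuration, orchestration, CLI |

## Testing

```
python -m pytest -o addopts= -p no:cacheprovider -q tests/
python scripts/acceptance.py --seed 20260101 --out acceptance.json
```

One known-red assertion is deliberate: over a pure width-blunting sweep, VH
is not strictly increasing (it is scale-invariant for interior tangent
windows — see `docs/methods.md`), so the VH sub-assertion of the sharpness
ordering acceptance test fails by design. PSI, EPA and w behave strictly
monotonically.

See `docs/methods.md` for the full method description, default parameter
rationale and limitations.
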