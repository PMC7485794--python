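# canopychl

Estimation of crop canopy chlorophyll content (mg/L) from 400–1000 nm
hyperspectral reflectance — "chlorophyll inversion" — as a tested, reusable
Python pipeline. The package is aimed at precision-agriculture and remote
sensing researchers who work with push-broom (e.g. UAV-mounted) hyperspectral
imagers and wet-chemistry ground truth, and at anyone who wants a compact,
fully seeded reference implementation of the underlying chemometric stack.

## What it implements

Given per-sample canopy spectra `X ∈ R^{n×J}` and ground-truth chlorophyll
`y` (from optical densities, `Chl = 5.134·OD₆₆₃ + 20.436·OD₆₄₅`), the
workflow is:

1. **Radiometric calibration** — two-point black–white correction
   `ρ_t = (DN_t − DN₁)/(DN₂ − DN₁)·(ρ₂ − ρ₁) + ρ₁` against dark/white
   reference panels; boundary-band removal (255 → 253 bands for a
   400–1000 nm grid at 2.35 nm) and cropping to the chlorophyll-sensitive
   400–800 nm interval. ROI-mean extraction from ENVI-style cubes.
2. **Preprocessing** — Savitzky–Golay smoothing (window 11, order 3 by
   default) and per-band SNR `10·log₁₀(E[x²]/Var[x])`.
3. **Screening** — per-band association with chlorophyll via Pearson
   correlation, distance correlation, and the maximal information
   coefficient (MIC).
4. **Band selection** — the successive projections algorithm (SPA): start
   from the largest-norm column of the calibration matrix, then repeatedly
   select the unselected wavelength with the largest residual after
   orthogonal projection, minimising collinearity; followed by exhaustive
   multiple-linear-regression subset refinement that keeps the subset with
   the smallest cross-validated RMSE.
5. **Inversion** — an extreme learning machine (ELM: random hidden layer,
   pseudoinverse output weights `β = H⁺y`) whose input weights and hidden
   biases are optimised by particle swarm optimisation (PSO-ELM), with the
   standard velocity update `v ← w·v + c₁r₁(p−x) + c₂r₂(g−x)` and position
   update `x ← x + m·v`.
6. **Tuning** — an L25(5⁵) orthogonal-array experiment over the PSO
   parameters (pop, w, C₁, C₂, m) with Taguchi-style marginal sums
   `W_ij = Σ R²` over the five runs at each (level i, factor j), selecting
   the per-factor argmax.
7. **Evaluation** — validation-set R² and RMSE (mg/L).

Because no field campaign data ship with the package, a first-class
synthetic-data module generates seeded canopy-like spectra (logistic red
edge whose inflection shifts with chlorophyll, saturating blue/red
absorption wells at 430/670 nm, configurable sensor noise) with chlorophyll
drawn from a truncated normal matching published field statistics
(mean 54.66, SD 26.94, range 2.60–99.70 mg/L, n = 196). Every stage is
exercised and tested against this generator's known ground truth.

## Worked example

```python
import canopychl as cc

report = cc.run_pipeline(cc.PipelineConfig(seed=1, do_screening=False))
print(f"validation R2   : {report.r2:.3f}")
print(f"validation RMSE : {report.rmse:.3f} mg/L")
print(f"baseline ELM R2 : {report.baseline_elm_r2:.3f}")
print(f"refined bands   : {[round(b, 1) for b in report.refined_bands]}")
```

prints

```
validation R2   : 0.999
validation RMSE : 0.475 mg/L
baseline ELM R2 : 0.991
refined bands   : [403.5, 683.2, 718.4, 737.2, 749.0, 791.3]
```

i.e. on a 196-sample synthetic scene (165 modeling / 31 validation after the
stratified 84/16 split) the PSO-optimised ELM explains 99.9% of validation
variance with a 0.47 mg/L error, beating the plain random-layer ELM
(R² 0.991, RMSE 1.99 mg/L), from six SPA-selected wavelengths in the blue
absorption and red-edge regions. On real field data both models are
substantially noisier; the synthetic scene's role is to verify that the
machinery recovers a known signal.

The same stages are available from the shell:

```bash
canopychl simulate --n-samples 196 --seed 1 --out spectra.csv
canopychl preprocess spectra.csv --out smoothed.csv
canopychl select-bands smoothed.csv --n-candidates 10 --out bands.json
canopychl train smoothed.csv --method pso-elm --out model.json
canopychl run-all --seed 1 --out runs/demo
```

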