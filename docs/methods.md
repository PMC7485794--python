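# Methods

This note records the models, conventions and design choices behind
`canopychl`, in the spirit of a methods appendix: what is computed, under
which assumptions, and what the synthetic experiments do and do not show.

## Wavelength grid and calibration

A grid from `start` to `end` nm at `step` nm holds `floor((end−start)/step)`
bands, band *k* centred at `start + (k+0.5)·step`. For the reference sensor
(400–1000 nm at 2.35 nm) this gives 255 bands; published band counts fix the
count but not the centre positions, so the half-step-offset convention is
normative for this package. One band is removed at each boundary (253
effective bands), and analysis is restricted to the closed interval
400–800 nm, where canopy reflectance is chlorophyll-sensitive.

DN→reflectance conversion is the two-point affine black–white correction
`ρ_t = (DN_t − DN₁)/(DN₂ − DN₁)·(ρ₂ − ρ₁) + ρ₁`. It is strictly monotone in
`DN_t` whenever the white panel's DN and reflectivity exceed the dark
panel's, and inverts the package's simulated affine sensor exactly at zero
sensor noise (a tested round-trip identity). Regions of interest are
averaged with explicit 0/1 pixel masks rather than any scene-classification
step: masks give a testable contract and keep the module free of
classifier dependencies. The ENVI reader handles the classic text header
plus raw binary in bsq/bil/bip interleaves — deliberately minimal.

## Preprocessing

Savitzky–Golay smoothing runs along the wavelength axis (default window 11
bands ≈ 26 nm, polynomial order 3 — conventional for grids of a few nm;
both configurable). Edges are handled by a least-squares polynomial fit
over the terminal window, so constants and polynomials up to the filter
order pass through exactly.

Band SNR is defined as `10·log₁₀(E[x²]/Var[x])` across samples, with the
population variance; a cross-sample definition was chosen because "signal"
here is the band's mean reflectance level and "noise" its sample scatter. A
constant band reports `+inf`. A pooled (all-bands) summary is also provided
since the per-band/pooled reading of an SNR range is ambiguous in general.

## Screening measures

* Pearson correlation: constant bands report 0 with a warning rather than
  raising, so a flat saturated band cannot abort a pipeline run.
* Distance correlation: the classical (biased) V-statistic from doubly
  centred pairwise-distance matrices; it lies in [0,1] and is zero in the
  population limit only under independence. The O(n²) cost is irrelevant at
  field-campaign sample sizes.
* MIC: estimated by exhaustive search over grid shapes `r×c` with
  `r·c ≤ n^0.6`, equipartitioning one axis into quantile bins and
  optimising the other axis's cut points by dynamic programming (cuts only
  between distinct values; max-plus recursion over a precomputed row-score
  matrix), normalising by `log₂ min(r,c)` and maximising over shapes and
  both orientations. This is an approximation of the full MIC search
  — adequate for ranking bands, and it attains 1 on noiseless monotone
  relationships and stays low (< 0.25 at n = 200) under independence.

## SPA and MLR refinement

SPA operates on the calibration matrix `X_cal` = smoothed modeling-set
reflectance restricted to 400–800 nm (rows = samples, columns =
wavelengths). Iteration 1 selects the largest-ℓ₂-norm column; iteration k
projects every unselected residual into the null space of the last selected
residual vector and selects the largest-norm result. Residual norms are
non-increasing (projection is non-expansive); residuals below 1e−12 are
treated as exactly collinear and terminate selection early. The default
candidate count is N = 10.

Refinement enumerates all nonempty candidate subsets and scores each by
5-fold cross-validated RMSE of an OLS fit with intercept. Cross-validated
rather than training RMSE is essential: training RMSE is monotone in subset
size and would always retain every candidate, making "smallest RMSE"
vacuous. Near-ties (within 1e−9 absolute or 1e−6 relative) resolve to the
smaller subset, then lexicographic order, so the argmin is deterministic in
floating point. Singular within-fold designs score `+inf`.

## ELM and PSO-ELM

The ELM draws input weights and hidden biases uniformly on [−1,1] from a
seeded generator, forms `H = σ(XWᵀ + b)` (sigmoid default) and solves
`β = H⁺y` by pseudoinverse — the minimum-norm least-squares solution,
verified against a normal-equations oracle in the tests. Features are
z-scored on the modeling set before entering the network; raw reflectance
spans only ~0.02–0.45, which would leave the sigmoid layer nearly linear.

PSO uses the global-best topology: `v ← w·v + c₁r₁(pbest−x) + c₂r₂(gbest−x)`
with velocities clamped to half the box width, then `x ← x + m·v` clipped
to [−1,1] per dimension. The velocity-position coefficient `m` scales the
position step; this is the only standard reading consistent with published
values of order 0.02–1 for that parameter. Inertia schedules given as a
pair `(w_start, w_end)` interpolate linearly over the iteration budget
(`0.9∼0.3` style); the endpoints are exact. A particle's fitness in
PSO-ELM is the validation RMSE of the ELM whose input layer it encodes and
whose output weights are refit analytically on the training set
(configurable to training RMSE). Using the same held-out set for swarm
fitness and final reporting mirrors the published workflow but does leak
the validation set into model selection; for unbiased error estimates pass
an inner split as the fitness set and keep a untouched test set.

Defaults: 20 hidden nodes, pop = 50, w = 0.9→0.3, c₁ = 1.65, c₂ = 2.8,
m = 0.2, 100 iterations — the published tuned configuration for this model
family. The hidden-node count has no principled automatic rule here; a
validation sweep is the supported mechanism if it must be data-driven.

## Orthogonal-array tuning

The L25(5⁵) array is built by the Galois-field generator: for run
`r = 5a + b`, the level indices are `(a, b, a+b, 2a+b, 3a+b) mod 5`. This
reproduces the canonical blocked layout (runs 1–5 at the first population
level, etc.) and satisfies both balance (each level five times per factor)
and pairwise orthogonality (every ordered factor pair sees all 25 level
pairs once). Marginal analysis sums run R² per (level, factor) cell; each
column of `W` partitions the same 25 runs, so its column sums all equal the
total R² — a conservation law asserted in the tests. Ties warn and resolve
to the lowest level index. Per-run seeds derive from the master seed via
`SeedSequence(master, spawn_key=(run,))`.

On the package's reference 25-run R² table the marginal sums select
pop = 50, w = 0.9→0.3, c₁ = 1.65 and m = 0.2; for C₂ the sums peak at 1.65
(3.838 vs 3.737 at 2.8), although the published run that produced the table
reported 2.8 as its final choice. `marginal_analysis` reports the argmax;
the pipeline default keeps the published final configuration.

## Synthetic scenes

The generator emulates the gross shape of a rice-canopy reflectance
spectrum and the published chlorophyll distribution:

* chlorophyll ~ truncated normal (rejection sampling) with parent mean
  54.66, SD 26.94, truncated to [2.60, 99.70] mg/L; truncation shrinks the
  realised SD to ≈ 22 mg/L, which is accepted — the parent parameters, not
  the realised moments, are the configuration contract;
* baseline: visible shelf 0.15 rising through a logistic red edge
  (width 15 nm) to a NIR plateau 0.45; the inflection starts at 700 nm and
  shifts by 0.12 nm per mg/L (≈ 12 nm over the observed range, typical of
  red-edge behaviour);
* absorption wells at 430 and 670 nm (Gaussian, σ 25/30 nm) with
  Beer–Lambert-style depth `D·(1 − exp(−g·Chl/D))`, initial slopes
  g = 2.4e−3 / 2.1e−3 per mg/L and saturation depths D = 0.12 / 0.14.
  Saturation matters: if depth were exactly linear in chlorophyll, every
  dip band would be perfectly collinear with the chlorophyll-linear
  direction already spanned by the red-edge bands, and a
  collinearity-minimising selector would provably never visit the planted
  wavelengths;
* noise: 1% multiplicative then 0.002 additive Gaussian reflectance noise,
  then clipping to [0,1] (physical bounds). The simulated sensor maps
  reflectance to DN affinely (gain 4000, offset 100) and images the
  calibration panels through the same map.

The `planted_bands` field lists exactly the wavelengths through which
chlorophyll enters the model (active dip centres plus the red-edge base),
giving tests an unambiguous recovery target. With these defaults, at zero
noise the SPA+MLR subset contains a band within 15 nm of every planted
wavelength, and the full pipeline at default noise reaches validation
R² ≥ 0.9.

What the generator does *not* emulate: radiative transfer and canopy
geometry (no PROSPECT/SAIL coupling, no BRDF), atmosphere, water/soil/weed
interference, spatial correlation between plots, or measurement error in
the wet-chemistry ground truth. Passing the synthetic-recovery tests
therefore demonstrates that the algorithms are implemented correctly and
can extract a red-edge/absorption signal of realistic shape and magnitude —
not that field-campaign accuracies (which are far lower, R² ≈ 0.7–0.8) are
reproduced. The published field results depend on an undeposited 2018–2019
campaign dataset and are out of reach of any reimplementation.

## Problem sizes and runtime policy

The default study conditions are n = 196 samples (165/31 split after the
stratified 84/16 partition), 253→170 analysed bands, 10 SPA candidates,
20 hidden nodes, and a 50-particle, 100-iteration swarm. The paired
PSO-ELM vs ELM comparison in the acceptance checks uses 20 seeds at
pop = 20 / 40 iterations — enough for the swarm to dominate the random
baseline by a wide margin while keeping the comparison a matter of seconds.
The orthogonal-array experiment in the test suite runs at reduced iteration
counts for the same reason; the design, seeding, and analysis path are
identical to a full-size run.

## Numerical conventions

* Grid band counts use `floor((end−start)/step + 1e−9)` to absorb float
  error when the ratio is integral.
* SPA residual floor 1e−12; selected sets always have full column rank.
* CV-RMSE tie tolerance: 1e−9 absolute, 1e−6 relative.
* Sample SD (n−1) for chlorophyll summaries; population variance for SNR;
  reported statistics rounded to 2 decimals.
* All stochastic stages draw from `numpy` `SeedSequence` substreams of one
  master seed; identical configuration and seed reproduce every artifact
  bit for bit.
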