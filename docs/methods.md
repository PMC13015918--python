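# Methods

## The MNF transform

Data are arranged as a matrix `X` of `m` pixel spectra (rows) across `v`
wavenumbers (columns), unrolled row-major from the `y × x` image where
one exists. Given a noise covariance estimate `Σ_δ = V Λ_δ Vᵀ`:

1. **Whitening** `W = X V Λ_δ^{-1/2}` — the noise component of `W` has
   unit variance and is decorrelated across bands. For a diagonal
   `Σ_δ` this reduces to dividing each column by its noise standard
   deviation.
2. **Signal decomposition** `WᵀW = G Λ_ω Gᵀ` — because the noise is
   white after step 1, ordering components by variance is ordering by
   SNR. Computed by SVD of `W` (numerically safer than forming `WᵀW`;
   a direct eigendecomposition path is retained for cross-testing).
3. **Truncation** to the top `K` components:
   `Φ_K = V Λ_δ^{-1/2} G_K` (forward) and
   `R = G_Kᵀ Λ_δ^{1/2} Vᵀ` (reconstruction).
4. **Denoising** `D = (X Φ_K) R`.

With `K = v` the composition `Φ_K R` is the identity; with white noise
(`Σ_δ ∝ I`) the transform is exactly uncentred truncated-SVD (PCA)
denoising, which the test suite uses as an independent oracle. Neither
decomposition mean-centres the data — the raw cross-products `NᵀN` and
`WᵀW` are used, matching the fast-MNF implementation lineage this
package is compatible with.

Multiplying all noise variances by a constant rescales the eigenvalues
but preserves the eigenvectors and the component ordering, so the
denoised output is invariant to global noise scaling. This matters
below: it makes several calibration constants (SG filter gain, variance
denominator convention) provably immaterial to the output.

**Sign convention.** Eigenvectors are defined up to sign; each column of
`G` (and `V`) is flipped so its largest-magnitude entry is positive,
making factor images and regression tests reproducible across LAPACK
builds. Ordering between components whose eigenvalues are separated by
less than ~1e-12 is not guaranteed stable.

**Degenerate noise.** `whiten` refuses singular or non-positive
covariances, naming the offending band; `fit_mnf` instead floors
degenerate variances at 1e-12 with a warning, because rank-deficient
adjacent-difference estimates (small patches, `m < v`) are a scenario
the package deliberately supports for study.

## Noise models

### Adjacent differencing (standard MNF)

`N_i = X_i − X_{i+1}` over the unrolled order, `Σ_δ = NᵀN`. Dense: it
captures the strong inter-band correlation of real detector noise. The
pairs that straddle image-row boundaries are not spatially adjacent; for
a 512×512 frame they are 511 of 262 143 pairs (< 0.2 %), negligible for
whole images, and an option drops them. The estimator is
order-dependent by construction — that is the failure mode the rest of
the package addresses, and tests assert the failure rather than hide it.

### Silent-region diagonal model (iMNF)

The base variance is the mean per-band variance of a Savitzky–Golay
first derivative over a silent spectral window. The derivative is a
high-pass filter: slowly varying residual chemistry and baseline survive
differentiation as near-constants while noise passes through, so the
column variances isolate noise. Variances use the population
denominator (`n`); at the pixel counts involved the distinction from
`n−1` is far below other error terms, and by scalar invariance it cannot
affect the output either way.

Implementation details that required decisions:

- **Filter edges.** Only interior derivative values enter the variance;
  the filter's polynomial edge extrapolation is discarded. Where
  per-band variances are needed (window selection, QC), the derivative
  is computed over a half-window-extended index range so region-edge
  bands get proper interior values; bands within half a window of the
  axis ends are reported as NaN (unassessable) rather than
  extrapolated.
- **Filter gain.** The derivative-domain variance differs from the raw
  noise variance by the filter's white-noise gain `Σ cᵢ²` (0.1 for
  window 5 / order 2 / unit spacing). `sg_base_variance` returns the
  derivative-domain value; `estimate_noise_imnf` divides it out
  (`gain_correct=True`, the default) so the stored base variance and
  profile sit on the physical absorbance-variance scale and can be
  compared to delta-method predictions. Being a pure scalar, the choice
  does not change the denoised output at all.
- **Defaults.** Window 5, polynomial order 2. Validity requires an odd
  window of at least `polyorder + 2`. A sweep over windows 5–11 and
  orders 2–4 (valid combinations) changes the profile only by a scalar,
  so the denoised outputs agree to a mean spectral cosine similarity
  of effectively 1 — asserted as a property test.

The base variance is then scaled across the axis. Absorbance is
`A = −log₁₀ T`; noise that is approximately constant in transmittance
appears in absorbance with a standard deviation `σ_T / (T·ln 10)` (first
order), i.e. variance inversely proportional to `T²`. With `T̄ = 10^(−Ā)`
computed from the mean spectrum (base-10 Beer–Lambert convention,
clamped below at 1e-6 for saturated bands) and `T̄_ref` the mean of `T̄`
over the silent window:

```
σ²_profile(ν) = σ²_base · (T̄_ref / T̄(ν))²      (floored at 1e-12)
Σ_δ = diag(σ²_profile)
```

The diagonal form deliberately ignores inter-band noise correlation;
that trade-off is what buys spatial invariance. The
`offdiag_noise_correlation` helper quantifies how much correlation an
adjacent-difference estimate actually carries, so users can judge the
trade-off on their own data.

**Silent windows.** Defaults: 1750–1800 cm⁻¹ for fingerprint-only (QCL)
axes, 1750–2200 cm⁻¹ where the axis extends that far (FTIR). The
automated selector slides a window (default width 50 cm⁻¹, one-band
stride) across a candidate interval and keeps the one with the lowest
mean per-band first-derivative variance; first-derivative rather than
raw variance is used because the heuristic should find the quietest
*noise* stretch, not the flattest baseline (a raw-variance alternative
would conflate the two). A QC pass flags any band in the region whose
derivative variance exceeds 5× the region median (both width and factor
are configuration, as no principled universal value exists); because the
first-derivative kernel has a zero centre tap, a narrow contaminant
shows up in its neighbours' variances, so flags cover the full filter
footprint of an exceedance. The check is report-only.

## Patch-wise and streaming operation

Cubes beyond memory are processed in disjoint row-major tiles (edge
tiles are remainders; no overlap or blending — a consistent global noise
model is the cure for seams, and stitching artifice would mask exactly
the effect under study). The operational rule: **the noise covariance
is estimated once, globally** (from the full data or a seeded uniform
random subset, default 50 000 spectra) **and applied unchanged to every
patch**. Two signal modes:

- `global` — one MNF model applied everywhere. The projection is
  implemented as a batched per-row product, which makes each output row
  a bitwise-pure function of its input row; whole-image, patch-wise,
  streamed and permuted applications therefore agree exactly, not just
  approximately. (Blocked BLAS matrix products do not have this
  property; the per-row path costs a few× in speed and is the default
  because exact recomposition is a correctness contract here.)
- `per_patch` — the signal eigendecomposition is refit inside each
  patch against the same static noise covariance; the memory-bounded
  mode. The same `K` is used everywhere.

Re-estimating the *noise* per patch is the documented anti-pattern: it
injects patch-composition variance into the noise model and degrades
with shrinking patch size. It is provided as the explicitly named
`denoise_patchwise_naive` so the pathology can be reproduced and
tested, never for production use.

Streaming reads, denoises and writes one patch at a time (peak resident
data: one patch), records a one-patch-granularity JSON checkpoint, and
can resume after interruption. A float32 output mode halves the
footprint at a per-band relative error below 1e-5 on phantoms.

## The phantom generator

Phantoms emulate the spatial and chemical heterogeneity of prostate
tissue cores: four classes (background, stroma-, epithelium- and
blood-like), each a sum of absorption bands including Amide I
(1656 cm⁻¹) and Amide II (1546 cm⁻¹) with distinct I/II ratios so
ratio-preservation metrics have spread. Band profiles are compactly
supported (a Gaussian shifted and clipped to zero beyond ±3 widths), so
the silent interval is exactly zero by construction; the spec validator
rejects any class band whose ±3-width support intrudes on it. Layouts:
`stripes` (deterministic), `blobs` (argmax of smoothed Gaussian random
fields, with softmax partial-volume mixing across boundaries — real
tissue pixels straddle class boundaries, and without this blending the
adjacent-difference comparator is unfairly strawmanned by pure-spectrum
jumps), `cores` (concentric disc). Default axes: QCL-style 952–1800
cm⁻¹ at 2 cm⁻¹ (425 bands); FTIR-style 952–2500 cm⁻¹ at 4 cm⁻¹
covering the extended silent region.

**Noise is injected in the transmittance domain**:
`T_noisy = 10^(−A) + ε`, `ε ~ N(0, σ_T²)` iid, then
`A_noisy = −log₁₀ max(T_noisy, 10⁻⁶)`. The inverse-square law the iMNF
estimator assumes thus *emerges* from the logarithm rather than being
baked into absorbance — the estimator is tested against the mechanism,
not against itself. The default `σ_T = 0.005` is chosen so denoising is
visibly nontrivial (silent-region absorbance noise σ ≈ 2.2×10⁻³, SNR of
order tens against default band peaks); the instruments themselves
publish no noise figure, and the value is configuration. An optional
correlated-noise stage (per-pixel random-slope baselines, sinusoidal
fringes with random phase) produces strong off-diagonal noise
correlation on purpose — the documented failure mode of the diagonal
approximation.

What the phantoms do **not** contain: scattering (Mie) artefacts,
instrument line shapes, atmospheric vapour, detector nonlinearity, or
spatially varying noise levels. Passing tests therefore demonstrate the
algebraic and statistical contracts of the methods — invariances,
parameter recovery, relative orderings — not clinical performance on
real tissue.

## Evaluation metrics

- Adjacency cosine similarity and the percentage of pairs below 0.99 /
  0.95 — how badly sampling or shuffling breaks the adjacency
  assumption.
- Silent-region variance: mean over region bands of per-band variance
  across pixels (per-band-then-averaged, since the quantity measures
  residual noise per band, not pixel heterogeneity).
- Amide I/II ratio per pixel, bands looked up by nearest axis value (no
  interpolation, matching discrete instrument sampling); pixels with a
  nonpositive denominator are excluded as NaN.
- R² as squared Pearson correlation by default — scale-insensitive, so
  a denoiser that rescales but preserves relative ratios is not
  penalised; an identity-line variant (`method="identity"`) is available
  where bias should count.
- Difference maps at a query wavenumber, and the edge-transition count
  `(h−1, h·w−1)` of row-major unrolling.

## Numerical choices and degenerate inputs

- Wavenumber intervals are inclusive on both ends everywhere
  (truncation, wax removal, silent regions) — off-by-one band counts are
  a classic drift source and are pinned by tests (1000–1800 at 2 cm⁻¹ →
  401 bands; 1360–1490 → 66 bands removed).
- Linear baseline subtraction anchors at the first and last retained
  band (endpoints map exactly to zero); a least-squares-line variant is
  available (`method="lstsq"`) since either reading of "linear baseline"
  is defensible.
- Default `K = 30` retained bands, in line with established
  spectral-pathology practice; default second-derivative parameters
  window 19, order 4.
- `fit_mnf` transform matrices are stored C-contiguous so a
  serialisation round-trip reproduces the projection bitwise.
- User-facing band selection is always by wavenumber, never by index.

## Problem sizes

Tests and the acceptance script run on phantoms of 32×32 to 100×100
pixels at 425 bands (1 024–10 000 spectra) — sizes at which every
decomposition is exact and fast while all asserted properties
(invariances, parameter recovery within stated tolerances, bitwise
patch equivalences) are already fully expressed; the streaming engine
is what scales the same code to out-of-core cubes.

## Known limitations

- The diagonal noise model cannot whiten correlated noise (fringing,
  baseline drift); on perfectly ordered data with strong correlated
  noise the standard adjacent-difference MNF can denoise better. The
  package ships the stressor generator and the off-diagonal correlation
  metric to make this trade-off measurable.
- The inverse-square transmittance scaling is a first-order model;
  detector-regime changes across the axis are not modelled.
- The silent-window heuristic assumes such a window exists within the
  candidate interval; exotic chemistry inside it is only flagged (QC),
  not corrected.
- No scatter or vapour correction; conversion from vendor instrument
  formats is assumed upstream (ENVI/HDF5/CSV are supported).
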