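# imnf — spatially invariant MNF denoising for infrared tissue images

Hyperspectral infrared microscopy (FTIR and QCL) of tissue produces
cubes of millions of pixel spectra whose signal-to-noise ratio is
limited by acquisition time. **Minimum noise fraction (MNF)** denoising
is the workhorse fix: whiten the noise, rotate to components ordered by
SNR, keep the top *K*, transform back. Its weakness is the noise model —
the standard estimator differences **adjacent pixels**
(`N_i = X_i − X_{i+1}`, `Σ_δ = NᵀN`), which silently assumes the rows of
the data matrix are in image order. Shuffle, mask, subsample or patch
the data and the estimate, and the denoising with it, collapses.

This package implements, alongside the standard (fast-)MNF, the
**spatially invariant iMNF** noise model: a diagonal noise covariance
built from global column statistics only,

```
σ²_base        = mean per-band variance of the Savitzky–Golay first
                 derivative over a biologically silent window
                 (QCL: 1750–1800 cm⁻¹, FTIR: 1750–2200 cm⁻¹)
T̄              = 10^(−Ā)            (mean transmittance spectrum)
σ²_profile(ν)  = σ²_base · (T̄_ref / T̄(ν))²
Σ_δ            = diag(σ²_profile)
```

The inverse-square transmittance scaling reflects the physics of the
absorbance transform: noise that is roughly constant in transmittance is
amplified in absorbance wherever transmittance is small (strong bands).
Because every ingredient is a column mean or variance, the model — and
therefore the denoised output — is indifferent to pixel order, which is
exactly what masked tissue extractions, random label samples and
patch-wise out-of-core processing need.

The package is aimed at spectroscopic-pathology and hyperspectral-
imaging practitioners. It provides:

- the MNF transform proper (`fit_mnf`, `denoise`, `pca_denoise`,
  `factor_images`) with an SVD-stabilised decomposition,
- both noise estimators (`estimate_noise_adjacent`,
  `estimate_noise_imnf`) plus automated silent-window selection and a
  narrow-band contaminant QC check,
- a patch-wise / streaming engine with a single static global noise
  model (`plan_patches`, `denoise_patchwise`, `stream_denoise`),
- a tissue-phantom generator with ground truth whose noise is injected
  in the transmittance domain (`make_phantom`, `add_noise`),
- evaluation metrics (adjacency cosine similarity, silent-region
  variance, Amide I/Amide II ratio preservation, difference maps),
- preprocessing (baseline, truncation, wax removal, vector
  normalisation, SG derivatives), ENVI/HDF5/CSV I/O and a thin `imnf`
  command-line interface.

## Worked example

```python
import numpy as np
from imnf import (add_noise, make_phantom, qcl_spec, estimate_noise_imnf,
                  fit_mnf, denoise, default_silent_region, silent_variance,
                  amide_ratio, r_squared)

phantom = add_noise(make_phantom(qcl_spec(shape=(64, 64), style="blobs", seed=3)))
cube = phantom.noisy                      # 4096 spectra × 425 bands

noise = estimate_noise_imnf(cube)         # diagonal, order-free
model = fit_mnf(cube, noise, k=30)        # top 30 SNR-ordered components
result = denoise(cube, model)

region = default_silent_region(cube)
print(silent_variance(cube, region), silent_variance(result.cube, region))
print(r_squared(amide_ratio(cube), amide_ratio(result.cube)))
```

prints (seed 3):

```
4.698712483212392e-06 3.3026528789264324e-07
0.9472944917406009
```

Residual noise in the chemistry-free silent window drops about 14-fold,
while the Amide I/Amide II ratio — a per-pixel biochemical readout —
stays essentially intact (R² ≈ 0.95 against the raw data). Running the
same denoising on randomly shuffled pixels and un-shuffling afterwards
reproduces this output to machine precision (see
`examples/02_spatial_invariance.py`); the standard adjacent-difference
MNF produces a completely different, distorted image under the same
treatment. The `examples/` directory holds one short script per
capability, each printing the numbers it computes.

Command line equivalent:

```sh
imnf simulate --preset qcl --shape 64 64 --seed 3 --out phantom.h5
imnf denoise noisy.h5 --noise imnf --silent-region auto --bands 30 --out denoised.h5
imnf evaluate denoised.h5 --against noisy.h5 --out report.json
```

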