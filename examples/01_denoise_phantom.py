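"""Generate a tissue phantom and denoise it with iMNF.

Builds a 64×64 QCL-style phantom (425 bands, 952–1800 cm⁻¹) with noise
injected in the transmittance domain, estimates the spatially invariant
diagonal noise covariance from the 1750–1800 cm⁻¹ silent window, and
reconstructs from the top 30 SNR-ordered components.
"""

import numpy as np

from imnf import (
    add_noise,
    amide_ratio,
    default_silent_region,
    denoise,
    estimate_noise_imnf,
    fit_mnf,
    make_phantom,
    qcl_spec,
    r_squared,
    silent_variance,
)

phantom = add_noise(make_phantom(qcl_spec(shape=(64, 64), style="blobs", seed=3)))
cube = phantom.noisy

noise = estimate_noise_imnf(cube)
print(f"base noise variance (absorbance²): {noise.base_variance:.3e}")
print(f"silent window: {noise.region.lo:.0f}-{noise.region.hi:.0f} cm⁻¹, "
      f"QC clean: {noise.region.qc.clean}")

model = fit_mnf(cube, noise, k=30)
result = denoise(cube, model)

region = default_silent_region(cube)
v_raw = silent_variance(cube, region)
v_den = silent_variance(result.cube, region)
print(f"silent-region variance: raw {v_raw:.3e} -> denoised {v_den:.3e} "
      f"({v_raw / v_den:.1f}x reduction)")
# residual noise in the chemistry-free window drops by roughly an order
# of magnitude while the signal subspace is untouched

err_raw = np.abs(cube.spectra - phantom.clean.spectra).mean()
err_den = np.abs(result.cube.spectra - phantom.clean.spectra).mean()
print(f"mean abs error vs clean truth: raw {err_raw:.2e} -> denoised {err_den:.2e}")

r2 = r_squared(amide_ratio(cube), amide_ratio(result.cube))
print(f"Amide I/II ratio preservation R² vs raw: {r2:.3f}")
# close to 1: the biochemical ratio map survives denoising
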