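"""The standard preprocessing pipeline around denoising.

Linear baseline subtraction, denoising, truncation to the fingerprint
region (1800–1000 cm⁻¹), wax-window removal (1490–1360 cm⁻¹), vector
normalisation and second-derivative conversion (window 19, order 4).
"""

import numpy as np

from imnf import (
    add_noise,
    apply_pipeline,
    denoise,
    estimate_noise_imnf,
    fit_mnf,
    make_phantom,
    qcl_spec,
)

phantom = add_noise(make_phantom(qcl_spec(shape=(32, 32), style="blobs", seed=3)))
cube = phantom.noisy
print(f"input: {cube.n_spectra} spectra × {cube.n_bands} bands")

cube = apply_pipeline(cube, [("baseline", {})])
cube = denoise(cube, fit_mnf(cube, estimate_noise_imnf(cube), k=30)).cube

cube = apply_pipeline(cube, [
    ("truncate", {"lo": 1000.0, "hi": 1800.0}),      # 401 bands
    ("remove_band", {"lo": 1360.0, "hi": 1490.0}),   # −66 wax bands
    ("normalise", {}),
    ("sg", {"window": 19, "polyorder": 4, "deriv": 2}),
])
print(f"output: {cube.n_spectra} spectra × {cube.n_bands} bands "
      f"(fingerprint minus wax window)")
norms_before_deriv = "unit-norm spectra, then 2nd derivative"
print(f"axis: {cube.axis[0]:.0f}-{cube.axis[-1]:.0f} cm⁻¹; {norms_before_deriv}")
print(f"2nd-derivative amplitude range: [{cube.spectra.min():.3e}, "
      f"{cube.spectra.max():.3e}]")
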