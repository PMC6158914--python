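"""Vessel inpainting with the improved BSCB transport/diffusion scheme.

The marked vessel pixels are filled by propagating neighbourhood-mean
smoothness information along isophotes, alternating with curvature
diffusion.  After inpainting, the cup interior is much closer to the
vessel-free image the retina would show without occlusions.
"""

import dataclasses

import numpy as np

from cupseg import (
    BSCBParams, PhantomSpec, VesselParams, extract_green, inpaint,
    inpaint_band, make_phantom,
)

spec = PhantomSpec(seed=42)
img, truth = make_phantom(spec)
clean_img, _ = make_phantom(dataclasses.replace(spec, n_vessels=0, noise_sigma=0.0))

green = extract_green(img)
reference = extract_green(clean_img)

omega = truth.vessel_mask
band = inpaint_band(omega, VesselParams(band_radius=2))
result = inpaint(green, omega, band, BSCBParams())

v = omega.pixels
before = np.abs(green.pixels - reference.pixels)[v].mean()
after = np.abs(result.pixels - reference.pixels)[v].mean()

print(f"vessel pixels filled       : {omega.count()}")
print(f"MAE vs vessel-free, before : {before:.1f} intensity units")
print(f"MAE vs vessel-free, after  : {after:.1f} intensity units")
print(f"untouched outside the band : {np.array_equal(result.pixels[~band.pixels], green.pixels[~band.pixels])}")

# The reconstruction error at vessel pixels roughly halves (the rest is
# mostly the sensor noise the phantom adds); pixels outside the dilated
# band are bit-identical to the input by contract.
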