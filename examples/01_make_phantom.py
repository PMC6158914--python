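"""Generate a synthetic fundus phantom and inspect its ground truth.

The phantom emulates what the segmentation method has to cope with: a
bright elliptical optic disc, a brighter cup inside it with a soft rim,
dark vessels crossing the cup boundary, and sensor noise.
"""

import numpy as np

from cupseg import PhantomSpec, make_phantom

img, truth = make_phantom(PhantomSpec(seed=42))

print(f"image shape            : {img.pixels.shape}")
print(f"green channel range    : {img.pixels[..., 1].min():.1f} .. {img.pixels[..., 1].max():.1f}")
print(f"cup mask pixels        : {truth.cup_mask.count()}")
print(f"disc mask pixels       : {truth.disc_mask.count()}")
print(f"vessel mask pixels     : {truth.vessel_mask.count()}")
print(f"true vertical CDR      : {truth.true_cdr:.3f}")
print(f"vessels crossing cup   : {np.any(truth.vessel_mask.pixels & truth.cup_mask.pixels)}")

# The true CDR is the ratio of the vertical pixel extents of cup and
# disc; around 0.5 is a healthy-looking eye, above ~0.6 suggests
# glaucomatous cupping.
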