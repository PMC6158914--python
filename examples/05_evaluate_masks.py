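"""Evaluate a segmentation against a reference mask.

Works on any pair of binary masks (e.g. PNG files via
cupseg.read_mask): pixel precision/recall/F-score, the radial boundary
distance between the traced contours, and the vertical cup-to-disc
ratio when a disc mask is supplied.
"""

import numpy as np

from cupseg import BinaryMask, evaluate

rr, cc = np.meshgrid(np.arange(200), np.arange(200), indexing="ij")
truth = BinaryMask((rr - 100) ** 2 / 40**2 + (cc - 100) ** 2 / 50**2 <= 1, role="cup")
pred = BinaryMask((rr - 102) ** 2 / 38**2 + (cc - 100) ** 2 / 49**2 <= 1, role="cup")
disc = BinaryMask((rr - 100) ** 2 / 80**2 + (cc - 100) ** 2 / 95**2 <= 1, role="disc")

rep = evaluate(pred, truth, disc=disc)
for key, value in rep.as_dict().items():
    print(f"{key:12s}: {value:.4f}" if isinstance(value, float) else f"{key:12s}: {value}")

# distance_px is the mean absolute radial gap between the two contours
# over 360 rays from the reference centroid; cdr uses the prediction's
# vertical extent against the disc's.
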