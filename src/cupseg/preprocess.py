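"""Contrast enhancement of the green channel by top-hat / bottom-hat
morphology.

The optic-cup boundary is a low-contrast bright-inside / darker-outside
transition.  Adding the top-hat (small bright details) and subtracting
the bottom-hat (small dark details, mostly vessels) sharpens it:

    U = (U_G + T_hat(U_G)) - B_hat(U_G)

with a flat square structuring element, default 5x5.  Borders are
reflect-padded so both hats vanish identically on constant images.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .errors import ParameterError
from .image_io import GrayImage


@dataclass
class EnhanceParams:
    """Structuring-element settings for the hat transforms.

    se_size
        Side length of the flat square structuring element, odd, >= 3
        (default 5).  Even sizes are rejected unless ``allow_even`` is
        set; the parameter-sweep harness uses that escape hatch to
        reproduce even-sized sweeps (the anchor then sits top-left of
        centre, scipy's convention).
    clamp
        Clip the enhanced image back to [0, 255] (default True).
    """

    se_size: int = 5
    clamp: bool = True
    allow_even: bool = False

    def __post_init__(self) -> None:
        if self.se_size < 2 or int(self.se_size) != self.se_size:
            raise ParameterError(f"se_size must be an integer >= 2, got {self.se_size}")
        if self.se_size % 2 == 0 and not self.allow_even:
            raise ParameterError(
                f"se_size must be odd (got {self.se_size}); even sizes are only "
                "permitted with allow_even=True in the sweep harness"
            )


def _opening(pix: np.ndarray, size: int) -> np.ndarray:
    return ndimage.grey_opening(pix, size=(size, size), mode="reflect")


def _closing(pix: np.ndarray, size: int) -> np.ndarray:
    return ndimage.grey_closing(pix, size=(size, size), mode="reflect")


def top_hat(img: GrayImage, p: EnhanceParams) -> GrayImage:
    """White top-hat: image minus its opening.  Everywhere >= 0."""
    out = img.pixels - _opening(img.pixels, p.se_size)
    return GrayImage(out, stage=img.stage)


def bottom_hat(img: GrayImage, p: EnhanceParams) -> GrayImage:
    """Black bottom-hat: closing minus the image.  Everywhere >= 0."""
    out = _closing(img.pixels, p.se_size) - img.pixels
    return GrayImage(out, stage=img.stage)


def enhance(img: GrayImage, p: EnhanceParams) -> GrayImage:
    """Hat-transform contrast enhancement, optionally clipped to [0, 255]."""
    out = (
        img.pixels
        + (img.pixels - _opening(img.pixels, p.se_size))
        - (_closing(img.pixels, p.se_size) - img.pixels)
    )
    if p.clamp:
        out = np.clip(out, 0.0, 255.0)
    return GrayImage(out, stage="enhanced")
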