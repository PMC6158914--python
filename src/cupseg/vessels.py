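"""Blood-vessel extraction by median-filter differencing.

Vessels are darker than the surrounding disc tissue, so a median filter
raises their intensity towards the local background.  The difference

    U_sub = U_med - U

is positive on vessel pixels; thresholding it (strictly > tau, default
tau = 0) gives the raw vessel mask.  Two pieces of plumbing follow:
small-component removal (the zero threshold also fires on noise) and
dilation of the mask into the band the inpainting stage diffuses over.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .errors import ParameterError, ShapeMismatchError
from .image_io import BinaryMask, GrayImage

_EIGHT = np.ones((3, 3), dtype=bool)  # 8-connectivity structure


@dataclass
class VesselParams:
    median_size: int = 9  #: median window side, odd, >= 3
    tau: float = 0.0  #: threshold on U_sub; 0 reproduces the strict > 0 rule
    min_component: int = 10  #: smallest 8-connected component kept, pixels
    band_radius: int = 2  #: Euclidean dilation radius for the inpainting band

    def __post_init__(self) -> None:
        if self.median_size < 3 or self.median_size % 2 == 0:
            raise ParameterError(f"median_size must be odd >= 3, got {self.median_size}")
        if self.min_component < 0 or self.band_radius < 0:
            raise ParameterError("min_component and band_radius must be >= 0")


def disc_structure(radius: int) -> np.ndarray:
    """Flat Euclidean disc: pixel included iff its centre is within
    ``radius`` of the origin.  Radius 1 is the 4-neighbourhood cross."""
    if radius == 0:
        return np.ones((1, 1), dtype=bool)
    r = np.arange(-radius, radius + 1)
    return (r[:, None] ** 2 + r[None, :] ** 2) <= radius**2


def median_image(img: GrayImage, p: VesselParams) -> GrayImage:
    """Per-pixel median over the ``median_size`` window, reflect-padded."""
    med = ndimage.median_filter(img.pixels, size=p.median_size, mode="reflect")
    return GrayImage(med, stage="median")


def difference_image(img: GrayImage, med: GrayImage) -> GrayImage:
    """U_sub = U_med - U; positive where the image is locally dark."""
    if img.shape != med.shape:
        raise ShapeMismatchError(f"shapes differ: {img.shape} vs {med.shape}")
    return GrayImage(med.pixels - img.pixels, stage="difference")


def binarize_vessels(diff: GrayImage, tau: float = 0.0) -> BinaryMask:
    """Mask of pixels where the difference image is strictly above tau."""
    return BinaryMask(diff.pixels > tau, role="vessel")


def clean_vessel_mask(mask: BinaryMask, p: VesselParams) -> BinaryMask:
    """Drop 8-connected components smaller than ``min_component`` pixels."""
    if p.min_component <= 1:
        return BinaryMask(mask.pixels.copy(), role=mask.role)
    labels, n = ndimage.label(mask.pixels, structure=_EIGHT)
    if n == 0:
        return BinaryMask(mask.pixels.copy(), role=mask.role)
    sizes = np.bincount(labels.ravel())
    keep = sizes >= p.min_component
    keep[0] = False
    return BinaryMask(keep[labels], role=mask.role)


def inpaint_band(mask: BinaryMask, p: VesselParams) -> BinaryMask:
    """Dilate the inpainting region by a Euclidean disc of band_radius."""
    if p.band_radius == 0:
        return BinaryMask(mask.pixels.copy(), role="inpaint_band")
    out = ndimage.binary_dilation(mask.pixels, structure=disc_structure(p.band_radius))
    return BinaryMask(out, role="inpaint_band")


def extract_vessels(img: GrayImage, p: VesselParams) -> BinaryMask:
    """Full extraction: median, difference, threshold, cleanup."""
    med = median_image(img, p)
    diff = difference_image(img, med)
    return clean_vessel_mask(binarize_vessels(diff, p.tau), p)
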