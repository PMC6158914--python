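"""Reading and writing fundus images and binary masks.

Conventions fixed here and used by every other module:

* arrays are indexed ``(row, col)``, 0-based, row 0 at the top;
* intensities are carried as floats in the nominal range [0, 255] so the
  PDE stages do not quantize; quantization to 8 bit happens only on write;
* masks are boolean grids, written as PNG with 0 = background and
  255 = foreground.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np

from .errors import FormatError, ShapeMismatchError

#: allowed stage tags for a GrayImage
GRAY_STAGES = frozenset({"green", "enhanced", "median", "difference", "inpainted"})

#: allowed role tags for a BinaryMask
MASK_ROLES = frozenset({"vessel", "inpaint_region", "inpaint_band", "cup", "disc"})


@dataclass
class FundusImage:
    """24-bit colour fundus photograph, channels ordered R, G, B."""

    pixels: np.ndarray  # H x W x 3 float64 in [0, 255]

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.float64)
        if self.pixels.ndim != 3 or self.pixels.shape[2] != 3:
            raise FormatError(
                f"FundusImage needs an HxWx3 array, got shape {self.pixels.shape}"
            )
        h, w = self.pixels.shape[:2]
        if h < 32 or w < 32:
            raise FormatError(f"image too small: {h}x{w}, need at least 32x32")
        if self.pixels.min() < 0 or self.pixels.max() > 255:
            raise FormatError("channel values must lie in [0, 255]")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape[:2]


@dataclass
class GrayImage:
    """Single-channel real-valued image with a processing-stage tag."""

    pixels: np.ndarray  # H x W float64
    stage: str = "green"

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.float64)
        if self.pixels.ndim != 2:
            raise FormatError(f"GrayImage needs a 2-D array, got {self.pixels.shape}")
        if not np.isfinite(self.pixels).all():
            raise FormatError("GrayImage must be finite everywhere")
        if self.stage not in GRAY_STAGES:
            raise FormatError(f"unknown stage tag {self.stage!r}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


@dataclass
class BinaryMask:
    """Boolean grid with a role tag saying what it delineates."""

    pixels: np.ndarray  # H x W bool
    role: str = "vessel"

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels).astype(bool)
        if self.pixels.ndim != 2:
            raise FormatError(f"BinaryMask needs a 2-D array, got {self.pixels.shape}")
        if self.role not in MASK_ROLES:
            raise FormatError(f"unknown role tag {self.role!r}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape

    def count(self) -> int:
        return int(self.pixels.sum())


def read_fundus(path: str | Path) -> FundusImage:
    """Read a PNG/TIFF/JPEG raster as a :class:`FundusImage`.

    A 4-channel (RGBA) raster silently drops its alpha channel.  16-bit
    inputs are linearly rescaled to [0, 255] (``255 * v / 65535``).
    Single-channel input is rejected: the method's channel selection is
    part of the algorithm, so a grayscale file is ambiguous.
    """
    path = Path(path)
    try:
        raw = iio.imread(path)
    except FileNotFoundError:
        raise
    except Exception as exc:  # decoder failures vary by backend
        raise OSError(f"could not read image file {path}: {exc}") from exc
    if raw.ndim == 2 or (raw.ndim == 3 and raw.shape[2] == 1):
        raise FormatError(f"{path}: 3 channels required, got a single-channel raster")
    if raw.ndim != 3 or raw.shape[2] not in (3, 4):
        raise FormatError(f"{path}: unsupported raster shape {raw.shape}")
    pix = raw[:, :, :3].astype(np.float64)
    if raw.dtype == np.uint16:
        pix = pix * (255.0 / 65535.0)
    elif raw.dtype not in (np.uint8, np.dtype(bool)):
        # float rasters: assume already on a [0,1] or [0,255] scale
        if pix.max() <= 1.0:
            pix = pix * 255.0
    return FundusImage(np.clip(pix, 0.0, 255.0))


def extract_green(img: FundusImage) -> GrayImage:
    """Return the green channel, the channel with the best cup contrast."""
    return GrayImage(img.pixels[:, :, 1].copy(), stage="green")


def read_mask(path: str | Path, shape: tuple[int, int], role: str = "cup") -> BinaryMask:
    """Read a PNG mask, threshold at the midpoint, check the shape."""
    raw = iio.imread(Path(path))
    if raw.ndim == 3:
        raw = raw[:, :, 0]
    if raw.shape != tuple(shape):
        raise ShapeMismatchError(
            f"mask shape {raw.shape} does not match expected {tuple(shape)}"
        )
    thresh = 0.5 if raw.dtype.kind == "f" else np.iinfo(raw.dtype).max / 2
    return BinaryMask(raw > thresh, role=role)


def write_mask(path: str | Path, mask: BinaryMask) -> None:
    """Write a mask as 8-bit PNG, 0 = background, 255 = foreground."""
    iio.imwrite(Path(path), (mask.pixels.astype(np.uint8) * 255))


def write_gray(path: str | Path, img: GrayImage) -> None:
    """Quantize to 8 bit (round, clip) and write as PNG."""
    q = np.clip(np.rint(img.pixels), 0, 255).astype(np.uint8)
    iio.imwrite(Path(path), q)


def write_fundus(path: str | Path, img: FundusImage) -> None:
    q = np.clip(np.rint(img.pixels), 0, 255).astype(np.uint8)
    iio.imwrite(Path(path), q)
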