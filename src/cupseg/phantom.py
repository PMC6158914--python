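"""Synthetic fundus phantoms with exact ground truth.

A phantom emulates the structures the segmentation method cares about:
a bright elliptical optic disc on a darker background, a brighter
elliptical cup inside it with a smooth intensity ramp at its rim, dark
curvilinear vessels (quadratic Bezier strips) running from outside the
disc across the cup boundary, and additive Gaussian noise.  The green
channel carries the full signal (red = 0.8x, blue = 0.4x green): only
the green channel is consumed by the method.

Ground truth (cup / disc / vessel masks and the vertical CDR) comes
from the analytic ellipses and the rendered vessel strips, so every
pipeline stage can be scored without external data.  Identical spec and
seed give bit-identical output.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .errors import ParameterError
from .image_io import BinaryMask, FundusImage
from .metrics import vertical_cdr
from .vessels import disc_structure


@dataclass
class PhantomSpec:
    height: int = 480
    width: int = 480
    disc_center: tuple[float, float] = (240.0, 240.0)  # (row, col)
    disc_axes: tuple[float, float] = (110.0, 125.0)  # (vertical, horizontal) semi-axes
    cup_axes: tuple[float, float] = (55.0, 62.0)
    bg_level: float = 60.0
    disc_level: float = 140.0
    cup_level: float = 210.0
    rim_softness: float = 6.0  # px width of the intensity ramp at the cup edge
    n_vessels: int = 5
    vessel_width: float = 3.0
    vessel_depth: float = 70.0
    noise_sigma: float = 4.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (self.bg_level < self.disc_level < self.cup_level):
            raise ParameterError("levels must satisfy bg < disc < cup")
        if not (
            0 < self.cup_axes[0] < self.disc_axes[0]
            and 0 < self.cup_axes[1] < self.disc_axes[1]
        ):
            raise ParameterError("cup ellipse must lie strictly inside the disc ellipse")
        if self.height < 32 or self.width < 32:
            raise ParameterError("phantom must be at least 32x32")
        if self.noise_sigma < 0 or self.vessel_width <= 0 or self.rim_softness <= 0:
            raise ParameterError("invalid noise_sigma / vessel_width / rim_softness")


@dataclass
class PhantomTruth:
    cup_mask: BinaryMask
    disc_mask: BinaryMask
    vessel_mask: BinaryMask
    true_cdr: float


def _elliptic_q(shape, center, axes) -> np.ndarray:
    """q(r, c) = ((r-r0)/a_v)^2 + ((c-c0)/a_h)^2; q <= 1 is the ellipse."""
    rr, cc = np.meshgrid(
        np.arange(shape[0], dtype=np.float64),
        np.arange(shape[1], dtype=np.float64),
        indexing="ij",
    )
    return ((rr - center[0]) / axes[0]) ** 2 + ((cc - center[1]) / axes[1]) ** 2


def _bezier_points(p0, p1, p2, n: int) -> np.ndarray:
    t = np.linspace(0.0, 1.0, n)[:, None]
    return (1 - t) ** 2 * p0 + 2 * (1 - t) * t * p1 + t**2 * p2


def _draw_vessels(spec: PhantomSpec, rng: np.random.Generator) -> np.ndarray:
    """Rasterize quadratic Bezier strips from outside the disc into the
    cup, guaranteeing each crosses the cup boundary."""
    strip = np.zeros((spec.height, spec.width), dtype=bool)
    r0, c0 = spec.disc_center
    for _ in range(spec.n_vessels):
        theta = rng.uniform(0.0, 2.0 * np.pi)
        # start outside the disc, end well inside the cup
        start = np.array(
            [r0 + 1.25 * spec.disc_axes[0] * np.sin(theta),
             c0 + 1.25 * spec.disc_axes[1] * np.cos(theta)]
        )
        end = np.array(
            [r0 + 0.35 * spec.cup_axes[0] * np.sin(theta + rng.uniform(-0.4, 0.4)),
             c0 + 0.35 * spec.cup_axes[1] * np.cos(theta + rng.uniform(-0.4, 0.4))]
        )
        mid = 0.5 * (start + end)
        perp = np.array([-(end - start)[1], (end - start)[0]])
        norm = np.linalg.norm(perp)
        if norm > 0:
            mid = mid + perp / norm * rng.uniform(-0.25, 0.25) * np.linalg.norm(end - start)
        length = np.linalg.norm(end - start)
        pts = _bezier_points(start, mid, end, max(int(4 * length), 16))
        rr = np.clip(np.rint(pts[:, 0]).astype(int), 0, spec.height - 1)
        cc = np.clip(np.rint(pts[:, 1]).astype(int), 0, spec.width - 1)
        strip[rr, cc] = True
    radius = max(int(round(spec.vessel_width / 2)), 1)
    return ndimage.binary_dilation(strip, structure=disc_structure(radius))


def make_phantom(spec: PhantomSpec | None = None) -> tuple[FundusImage, PhantomTruth]:
    """Render one phantom and its exact ground truth."""
    spec = spec or PhantomSpec()
    rng = np.random.default_rng(spec.seed)
    shape = (spec.height, spec.width)

    q_disc = _elliptic_q(shape, spec.disc_center, spec.disc_axes)
    q_cup = _elliptic_q(shape, spec.disc_center, spec.cup_axes)
    disc_mask = q_disc <= 1.0
    cup_mask = q_cup <= 1.0

    signal = np.full(shape, spec.bg_level, dtype=np.float64)
    signal[disc_mask] = spec.disc_level
    # smooth rim ramp centred on the cup ellipse: approximate signed
    # distance (px, positive inside) from the normalized elliptic radius
    d_px = (1.0 - np.sqrt(q_cup)) * np.sqrt(spec.cup_axes[0] * spec.cup_axes[1])
    ramp = np.clip(d_px / spec.rim_softness + 0.5, 0.0, 1.0)
    signal += (spec.cup_level - spec.disc_level) * ramp * disc_mask

    vessel_mask = (
        _draw_vessels(spec, rng)
        if spec.n_vessels > 0
        else np.zeros(shape, dtype=bool)
    )
    signal[vessel_mask] -= spec.vessel_depth

    if spec.noise_sigma > 0:
        signal = signal + rng.normal(0.0, spec.noise_sigma, size=shape)

    green = np.clip(signal, 0.0, 255.0)
    pixels = np.stack([0.8 * green, green, 0.4 * green], axis=-1)
    img = FundusImage(np.clip(pixels, 0.0, 255.0))

    truth = PhantomTruth(
        cup_mask=BinaryMask(cup_mask, role="cup"),
        disc_mask=BinaryMask(disc_mask, role="disc"),
        vessel_mask=BinaryMask(vessel_mask, role="vessel"),
        true_cdr=0.0,
    )
    truth.true_cdr = vertical_cdr(truth.cup_mask, truth.disc_mask)
    return img, truth


def _child_seed(seed: int, i: int) -> int:
    # stated counter scheme: reproducible across platforms, < 2^31
    return (seed * 100_003 + i) % 2**31


def make_suite(
    n: int, base: PhantomSpec | None = None, seed: int = 0
) -> list[tuple[FundusImage, PhantomTruth]]:
    """Deterministic suite of ``n`` phantoms with jittered geometry.

    Disc axes jitter by +-10%, the centre by +-10 px, and the target CDR
    is swept across [0.3, 0.8] (with a small jitter), so the suite spans
    the clinically relevant range from normal to advanced cupping.
    """
    if n < 1:
        raise ParameterError("n must be >= 1")
    base = base or PhantomSpec()
    suite = []
    for i in range(n):
        cs = _child_seed(seed, i)
        rng = np.random.default_rng(cs)
        target_cdr = 0.55 if n == 1 else 0.3 + 0.5 * i / (n - 1)
        target_cdr = float(np.clip(target_cdr + rng.uniform(-0.01, 0.01), 0.25, 0.85))
        disc_axes = (
            base.disc_axes[0] * rng.uniform(0.9, 1.1),
            base.disc_axes[1] * rng.uniform(0.9, 1.1),
        )
        center = (
            base.disc_center[0] + rng.uniform(-10, 10),
            base.disc_center[1] + rng.uniform(-10, 10),
        )
        cup_axes = (target_cdr * disc_axes[0], target_cdr * disc_axes[1])
        spec = dataclasses.replace(
            base,
            disc_center=center,
            disc_axes=disc_axes,
            cup_axes=cup_axes,
            seed=cs,
        )
        suite.append(make_phantom(spec))
    return suite
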