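"""Optic-cup segmentation with a local Chan-Vese (LCV) level set.

The cup is the brightest region inside the disc but its boundary is
unsharp and the surrounding rim is inhomogeneous, so a purely global
two-phase Chan-Vese fit is complemented by a local term computed on the
difference between a box-filtered image and the image itself:

    E(phi) = mu * Length(phi)
           + int_in (I - c1)^2 + int_out (I - c2)^2
           + alpha * [ int_in (Id - d1)^2 + int_out (Id - d2)^2 ]

with Id = boxmean(I, w) - I, in/out defined through a smoothed Heaviside
of the level-set function phi (positive inside), and c1, c2, d1, d2 the
region means that minimize each quadratic term.  alpha = 0.1 and
mu = 0.1 * 255^2 are the defaults for a single bright, inhomogeneous
target.

Seeding is automatic: the centroid of the largest high-intensity
component initializes a circle, and phi evolves by normalized gradient
descent with backtracking (so the energy never increases between
redistancing steps) and periodic signed-distance reinitialization.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from . import _diff
from .errors import (
    ConvergenceError,
    DegenerateInputError,
    ParameterError,
    ShapeMismatchError,
)
from .image_io import BinaryMask, GrayImage

_EIGHT = np.ones((3, 3), dtype=bool)
_HEAVISIDE_EPS = 1.5  # px width of the smoothed Heaviside / Dirac pair


@dataclass
class LCVParams:
    """Weights and numerics of the LCV evolution.

    alpha
        Weight of the local fitting term (default 0.1; 0 recovers the
        global Chan-Vese model).
    mu
        Weight of the contour-length penalty (default 0.1 * 255^2, the
        classical Chan-Vese scaling for intensities in [0, 255]).
    local_window
        Side of the box mean defining the local difference image
        (odd, default 15).
    dt
        Per-iteration movement cap in pixels: the descent force is
        normalized to unit maximum, so phi changes by at most dt per
        step (default 1.0, the CFL-style choice; backtracking halves it
        whenever a step would raise the energy).
    iters
        Iteration cap (default 1500; the stall-based early stop makes
        the high cap cheap for small cups, while the largest cups need
        around a thousand unit-capped steps).
    reinit_every
        Iterations between signed-distance reinitializations (default 50).
    seed_radius_frac
        Initial circle radius as a fraction of the shorter image side.
    seed_percentile
        Intensity percentile defining the relatively-high-intensity
        region the seed centroid is taken from (default 97).
    stall_iters
        Early stop once the {phi > 0} mask has been unchanged for
        ``reinit_every + stall_iters`` consecutive iterations, i.e. a
        redistancing has had the chance to free a stuck descent and did
        not (0 disables; default 15).
    """

    alpha: float = 0.1
    mu: float = 0.1 * 255.0**2
    local_window: int = 15
    dt: float = 1.0
    iters: int = 1500
    reinit_every: int = 50
    seed_radius_frac: float = 0.15
    seed_percentile: float = 97.0
    stall_iters: int = 15

    def __post_init__(self) -> None:
        if self.alpha < 0 or self.mu < 0:
            raise ParameterError("alpha and mu must be >= 0")
        if not (0.0 < self.seed_radius_frac < 0.5):
            raise ParameterError("seed_radius_frac must lie in (0, 0.5)")
        if not (50.0 < self.seed_percentile < 100.0):
            raise ParameterError("seed_percentile must lie in (50, 100)")
        if self.local_window < 1 or self.local_window % 2 == 0:
            raise ParameterError("local_window must be odd >= 1")
        if self.dt <= 0 or self.iters < 1 or self.reinit_every < 1:
            raise ParameterError("invalid dt / iters / reinit_every")


@dataclass
class LevelSetField:
    """Signed level-set function, positive inside the evolving region."""

    phi: np.ndarray

    def __post_init__(self) -> None:
        self.phi = np.asarray(self.phi, dtype=np.float64)
        if not np.isfinite(self.phi).all():
            raise ParameterError("phi must be finite everywhere")


@dataclass
class SegmentationResult:
    cup_mask: BinaryMask
    contour: "Contour"  # metrics.Contour; forward ref avoids a cycle
    seed: tuple[float, float]  # (row, col)
    iterations_run: int
    energy_trace: np.ndarray
    #: indices into energy_trace where a redistancing reset the energy;
    #: the trace is non-increasing between consecutive reinit indices
    reinit_indices: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))


def heaviside(z: np.ndarray) -> np.ndarray:
    """H_eps(z) = 1/2 (1 + (2/pi) arctan(z/eps)), eps = 1.5 px."""
    return 0.5 * (1.0 + (2.0 / np.pi) * np.arctan(z / _HEAVISIDE_EPS))


def dirac(z: np.ndarray) -> np.ndarray:
    """Derivative of the smoothed Heaviside."""
    return (_HEAVISIDE_EPS / np.pi) / (_HEAVISIDE_EPS**2 + z * z)


def local_difference(img: GrayImage, p: LCVParams) -> np.ndarray:
    """Id = boxmean(I, local_window) - I, reflect-padded."""
    if p.local_window == 1:
        return np.zeros_like(img.pixels)
    box = ndimage.uniform_filter(img.pixels, size=p.local_window, mode="reflect")
    return box - img.pixels


def select_seed(img: GrayImage, p: LCVParams | None = None) -> tuple[float, float]:
    """Centroid (row, col) of the largest relatively-bright component.

    Thresholds the image at its ``seed_percentile`` intensity
    percentile, keeps the largest 8-connected component and returns its
    pixel centroid.
    """
    p = p or LCVParams()
    pix = img.pixels
    if pix.max() - pix.min() < 1e-12:
        raise DegenerateInputError("cannot seed on a constant image")
    thr = np.percentile(pix, p.seed_percentile)
    region = pix >= thr
    labels, n = ndimage.label(region, structure=_EIGHT)
    if n == 0:
        raise DegenerateInputError("high-intensity region is empty")
    sizes = np.bincount(labels.ravel())
    sizes[0] = 0
    best = int(sizes.argmax())
    rows, cols = np.nonzero(labels == best)
    return float(rows.mean()), float(cols.mean())


def init_phi(
    seed: tuple[float, float], radius: float, shape: tuple[int, int]
) -> LevelSetField:
    """Signed distance to a circle: phi = radius - |x - seed|."""
    h, w = shape
    r0, c0 = seed
    if not (0 <= r0 < h and 0 <= c0 < w):
        raise ParameterError(f"seed {seed} lies outside the {h}x{w} image")
    if radius <= 0:
        raise ParameterError("radius must be positive")
    rr, cc = np.meshgrid(np.arange(h), np.arange(w), indexing="ij")
    dist = np.sqrt((rr - r0) ** 2 + (cc - c0) ** 2)
    return LevelSetField(radius - dist)


def _region_means(values: np.ndarray, h: np.ndarray) -> tuple[float, float]:
    win = float(h.sum())
    wout = float((1.0 - h).sum())
    m_in = float((values * h).sum() / win) if win > 0 else 0.0
    m_out = float((values * (1.0 - h)).sum() / wout) if wout > 0 else 0.0
    return m_in, m_out


def _energy(
    pix: np.ndarray, idiff: np.ndarray, phi: np.ndarray, p: LCVParams
) -> float:
    h = heaviside(phi)
    c1, c2 = _region_means(pix, h)
    length = float((dirac(phi) * _diff.grad_mag(phi)).sum())
    e = p.mu * length
    e += float((h * (pix - c1) ** 2).sum() + ((1.0 - h) * (pix - c2) ** 2).sum())
    if p.alpha > 0:
        d1, d2 = _region_means(idiff, h)
        e += p.alpha * float(
            (h * (idiff - d1) ** 2).sum() + ((1.0 - h) * (idiff - d2) ** 2).sum()
        )
    return e


def lcv_energy(img: GrayImage, phi: LevelSetField, p: LCVParams | None = None) -> float:
    """LCV energy of ``phi`` on ``img`` with the minimizing region means."""
    p = p or LCVParams()
    if img.shape != phi.phi.shape:
        raise ShapeMismatchError("image and phi shapes differ")
    return _energy(img.pixels, local_difference(img, p), phi.phi, p)


def reinitialize(phi: np.ndarray) -> np.ndarray:
    """Redistance phi to a signed Euclidean distance of the {phi > 0} set,
    preserving the sign pattern exactly."""
    mask = phi > 0
    if mask.all() or not mask.any():
        return phi.copy()
    inside = ndimage.distance_transform_edt(mask)
    outside = ndimage.distance_transform_edt(~mask)
    return inside - outside


def _descent_force(
    pix: np.ndarray, idiff: np.ndarray, phi: np.ndarray, p: LCVParams
) -> np.ndarray:
    h = heaviside(phi)
    c1, c2 = _region_means(pix, h)
    force = p.mu * _diff.curvature(phi) - (pix - c1) ** 2 + (pix - c2) ** 2
    if p.alpha > 0:
        d1, d2 = _region_means(idiff, h)
        force = force - p.alpha * ((idiff - d1) ** 2 - (idiff - d2) ** 2)
    return dirac(phi) * force


def evolve(
    img: GrayImage, phi: LevelSetField, p: LCVParams | None = None
) -> SegmentationResult:
    """Gradient-descent evolution of the LCV energy.

    Each iteration moves phi along the normalized negative gradient with
    a per-pixel cap of ``dt`` pixels; the step is halved (up to 8 times)
    whenever it would raise the energy, so the recorded energy trace is
    non-increasing between reinitializations.  Stops at the iteration
    cap, or earlier when the foreground mask stalls.

    Returns the largest 8-connected component of {phi > 0}, holes
    filled, with its traced boundary contour.
    """
    from .metrics import mask_to_contour  # local import: metrics uses BinaryMask only

    p = p or LCVParams()
    pix = img.pixels
    if pix.shape != phi.phi.shape:
        raise ShapeMismatchError("image and phi shapes differ")
    idiff = local_difference(img, p)
    cur = phi.phi.copy()
    seed = select_seed(img, p)

    energy = _energy(pix, idiff, cur, p)
    trace = [energy]
    reinits: list[int] = []
    prev_mask = cur > 0
    stall = 0
    n = 0
    for n in range(1, p.iters + 1):
        force = _descent_force(pix, idiff, cur, p)
        top = float(np.abs(force).max())
        if top <= 0:
            break
        direction = force / top
        step = p.dt
        for _ in range(8):
            cand = cur + step * direction
            e_cand = _energy(pix, idiff, cand, p)
            if e_cand <= energy:
                cur, energy = cand, e_cand
                break
            step *= 0.5
        # a fully rejected step leaves phi unchanged; the next
        # redistancing reshapes the landscape and usually frees it
        trace.append(energy)
        mask = cur > 0
        if not mask.any():
            raise ConvergenceError(
                "level set collapsed to an empty region; try a larger seed radius"
            )
        if np.array_equal(mask, prev_mask):
            stall += 1
            if p.stall_iters and stall >= p.reinit_every + p.stall_iters:
                break
        else:
            stall = 0
        prev_mask = mask
        if n % p.reinit_every == 0:
            cur = reinitialize(cur)
            energy = _energy(pix, idiff, cur, p)
            reinits.append(len(trace))
            trace.append(energy)

    mask = cur > 0
    if not mask.any():
        raise ConvergenceError(
            "level set collapsed to an empty region; try a larger seed radius"
        )
    labels, ncomp = ndimage.label(mask, structure=_EIGHT)
    sizes = np.bincount(labels.ravel())
    sizes[0] = 0
    cup = ndimage.binary_fill_holes(labels == int(sizes.argmax()))
    cup_mask = BinaryMask(cup, role="cup")
    return SegmentationResult(
        cup_mask=cup_mask,
        contour=mask_to_contour(cup_mask),
        seed=seed,
        iterations_run=n,
        energy_trace=np.asarray(trace),
        reinit_indices=np.asarray(reinits, dtype=int),
    )


def segment_cup(img: GrayImage, p: LCVParams | None = None) -> SegmentationResult:
    """Seed automatically and evolve: the full cup-identification step."""
    p = p or LCVParams()
    seed = select_seed(img, p)
    radius = p.seed_radius_frac * min(img.shape)
    phi = init_phi(seed, radius, img.shape)
    return evolve(img, phi, p)
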