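"""Vessel inpainting with an improved BSCB transport/diffusion scheme.

The Bertalmio-Sapiro-Caselles-Ballester (BSCB) model fills a region
Omega by transporting smoothness information (a Laplacian measure L of
the image) along isophotes — the curves of constant intensity, which run
perpendicular to the gradient:

    dU/dt = grad(L) . T          inside Omega        (inpainting)
    dU/dt = g_eps * k * |grad U| inside Omega^eps    (diffusion)

where T is the unit isophote direction, k the Euclidean curvature of the
isophotes, Omega^eps a dilation of Omega, and g_eps a smooth weight
supported on Omega^eps.  The two updates alternate: a block of transport
steps, then a couple of curvature-diffusion steps that keep the
prolonged isophotes from crossing.

The improvement implemented here replaces the single-pixel second
differences u_xx, u_yy in L by their 3x3 neighbourhood means, which
suppresses the influence of pixel noise on the transported information.
Set ``nbhd=1`` to recover the classic single-pixel scheme.

Discretization: explicit Euler with rate ``dt``, central differences,
reflect boundaries, unit grid spacing.  The continuous model obeys a
maximum principle (no new extrema arise), but the central-difference
transport term does not, so each update is followed by a local
extremum-diminishing limiter: changed pixels are clipped to the 3x3
min/max of the previous iterate.  The limiter leaves small in-range
updates untouched, keeps fill fronts free to advance, and makes the
scheme stable on large noisy regions.  Pixels outside Omega^eps are
never touched, bit-exact.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from . import _diff
from .errors import NumericalError, ParameterError, ShapeMismatchError
from .image_io import BinaryMask, GrayImage

_DEG_EPS = 1e-8  # gradient magnitude below which the isophote direction is undefined


@dataclass
class BSCBParams:
    """Free constants of the explicit BSCB scheme.

    dt
        Improvement rate of the explicit update (default 0.1, stable at
        unit grid spacing).
    total_iters
        Cap on the total number of elementary updates (default 3000).
    inpaint_steps, diffuse_steps
        Consecutive transport / diffusion updates per cycle (defaults
        15 and 2, the classic BSCB recipe).
    nbhd
        Side of the square neighbourhood averaged to build the
        propagation information; 3 is the improved scheme, 1 the
        classic single-pixel one.
    stop_tol
        Early stop once the mean absolute change per Omega pixel per
        elementary update, measured over a full cycle, falls below this
        (default 1e-4 intensity units).
    smooth_sigma
        Gaussian width used to build the band weight g_eps.
    laplacian_mode
        "sum" combines the averaged second differences as u_xx + u_yy
        (the discrete Laplacian, default); "product" multiplies them.
    limiter
        Apply the 3x3 extremum-diminishing limiter after each update
        (default True; disable only to study the raw scheme).
    plateau_cycles, plateau_ratio
        Secondary stop: give up once the cycle residual has improved by
        less than ``1 - plateau_ratio`` over the last ``plateau_cycles``
        cycles (0 disables).  Catches noise-dominated regions whose
        residual floors far above stop_tol.
    """

    dt: float = 0.1
    total_iters: int = 3000
    inpaint_steps: int = 15
    diffuse_steps: int = 2
    nbhd: int = 3
    stop_tol: float = 1e-4
    smooth_sigma: float = 1.0
    laplacian_mode: str = "sum"
    limiter: bool = True
    plateau_cycles: int = 12
    plateau_ratio: float = 0.99

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ParameterError("dt must be positive")
        if self.nbhd < 1 or self.nbhd % 2 == 0:
            raise ParameterError(f"nbhd must be odd >= 1, got {self.nbhd}")
        if self.inpaint_steps + self.diffuse_steps < 1:
            raise ParameterError("inpaint_steps + diffuse_steps must be >= 1")
        if self.inpaint_steps < 1 or self.diffuse_steps < 0:
            raise ParameterError("need inpaint_steps >= 1 and diffuse_steps >= 0")
        if self.laplacian_mode not in ("sum", "product"):
            raise ParameterError("laplacian_mode must be 'sum' or 'product'")
        if self.stop_tol < 0 or self.smooth_sigma <= 0 or self.total_iters < 1:
            raise ParameterError("invalid stop_tol / smooth_sigma / total_iters")
        if self.plateau_cycles < 0 or not (0 < self.plateau_ratio <= 1):
            raise ParameterError("invalid plateau_cycles / plateau_ratio")


@dataclass
class InpaintState:
    """Evolving inpainting state: current estimate plus fixed geometry."""

    u: np.ndarray  # H x W float64, current estimate
    omega: np.ndarray  # H x W bool, region to fill
    band: np.ndarray  # H x W bool, omega dilated (diffusion support)
    g: np.ndarray  # H x W float64 in [0,1], band weight g_eps
    n: int = 0  # elementary updates applied so far
    last_residual: float = float("inf")  # mean |applied update| in omega

    def __post_init__(self) -> None:
        # flat indices of omega/band, cached for the inner loop
        self._om_idx = np.flatnonzero(self.omega.ravel())
        self._bd_idx = np.flatnonzero(self.band.ravel())


def init_state(
    img: GrayImage, omega: BinaryMask, band: BinaryMask, p: BSCBParams
) -> InpaintState:
    """Build the initial state U^0 = U with the band weight g_eps.

    g_eps is the Gaussian-smoothed indicator of the band, renormalized
    to [0, 1] and set to exactly zero outside the band, so diffusion
    fades smoothly towards the band edge and never leaks outside it.
    """
    om = np.asarray(omega.pixels, bool)
    bd = np.asarray(band.pixels, bool)
    if om.shape != img.shape or bd.shape != img.shape:
        raise ShapeMismatchError("omega/band shape must match the image")
    if (om & ~bd).any():
        raise ShapeMismatchError("omega must be a subset of band")
    g = ndimage.gaussian_filter(bd.astype(np.float64), p.smooth_sigma, mode="constant")
    top = g.max()
    if top > 0:
        g = np.clip(g / top, 0.0, 1.0)
    g[~bd] = 0.0
    return InpaintState(u=img.pixels.astype(np.float64).copy(), omega=om, band=bd, g=g)


def _neighborhood_mean(a: np.ndarray, nbhd: int) -> np.ndarray:
    if nbhd == 1:
        return a
    return ndimage.uniform_filter(a, size=nbhd, mode="reflect")


def propagation_info(state: InpaintState, p: BSCBParams | None = None) -> np.ndarray:
    """Smoothness measure L-bar transported along isophotes.

    Second differences u_xx, u_yy are averaged over the ``nbhd`` x
    ``nbhd`` neighbourhood and combined as a sum (discrete Laplacian,
    default) or a product.
    """
    p = p or BSCBParams()
    uxx = _neighborhood_mean(_diff.second_x(state.u), p.nbhd)
    uyy = _neighborhood_mean(_diff.second_y(state.u), p.nbhd)
    if p.laplacian_mode == "product":
        return uxx * uyy
    return uxx + uyy


def isophote_direction(state: InpaintState) -> np.ndarray:
    """Unit vector along the isophote, (-u_y, u_x)/|grad u|, as an
    H x W x 2 array with components ordered (x, y) = (col, row).
    Zero wherever the gradient is (numerically) zero."""
    gx = _diff.grad_x(state.u)
    gy = _diff.grad_y(state.u)
    mag = np.sqrt(gx * gx + gy * gy)
    inv = np.where(mag >= _DEG_EPS, 1.0 / np.maximum(mag, _DEG_EPS), 0.0)
    out = np.empty(state.u.shape + (2,), dtype=np.float64)
    np.multiply(-gy, inv, out=out[..., 0])
    np.multiply(gx, inv, out=out[..., 1])
    return out


def _sliding3(u: np.ndarray, op) -> np.ndarray:
    """Separable 3x3 sliding min or max with edge replication.
    ``op`` is np.minimum or np.maximum."""
    a = np.empty_like(u)
    op(u[:-2, :], u[1:-1, :], out=a[1:-1, :])
    op(a[1:-1, :], u[2:, :], out=a[1:-1, :])
    op(u[0, :], u[1, :], out=a[0, :])
    op(u[-1, :], u[-2, :], out=a[-1, :])
    out = np.empty_like(u)
    op(a[:, :-2], a[:, 1:-1], out=out[:, 1:-1])
    op(out[:, 1:-1], a[:, 2:], out=out[:, 1:-1])
    op(a[:, 0], a[:, 1], out=out[:, 0])
    op(a[:, -1], a[:, -2], out=out[:, -1])
    return out


def _masked_update(
    state: InpaintState, du: np.ndarray, idx: np.ndarray, limiter: bool
) -> np.ndarray:
    """Apply du at the flat indices ``idx``, optionally clipped to the
    3x3 min/max of the previous iterate; returns |applied update|."""
    uflat = state.u.ravel()
    before = uflat[idx]
    cand = before + du.ravel()[idx]
    if limiter:
        lo = _sliding3(state.u, np.minimum).ravel()[idx]
        hi = _sliding3(state.u, np.maximum).ravel()[idx]
        cand = np.clip(cand, lo, hi)
    uflat[idx] = cand
    return np.abs(cand - before)


def inpaint_step(state: InpaintState, p: BSCBParams) -> InpaintState:
    """One explicit transport update, applied inside Omega only."""
    L = propagation_info(state, p)
    lx = _diff.grad_x(L)
    ly = _diff.grad_y(L)
    t = isophote_direction(state)
    du = p.dt * (lx * t[..., 0] + ly * t[..., 1])
    idx = state._om_idx
    if not np.isfinite(du.ravel()[idx]).all():
        raise NumericalError(
            f"transport update non-finite at iteration {state.n}; try a smaller dt"
        )
    applied = _masked_update(state, du, idx, p.limiter)
    state.n += 1
    state.last_residual = float(applied.mean()) if applied.size else 0.0
    return state


def diffuse_step(state: InpaintState, p: BSCBParams) -> InpaintState:
    """One curvature-driven diffusion update inside the band."""
    k = _diff.curvature(state.u)
    mag = _diff.grad_mag(state.u)
    du = p.dt * state.g * k * mag
    idx = state._bd_idx
    if not np.isfinite(du.ravel()[idx]).all():
        raise NumericalError(
            f"diffusion update non-finite at iteration {state.n}; try a smaller dt"
        )
    _masked_update(state, du, idx, p.limiter)
    state.n += 1
    return state


def _band_bbox(band: np.ndarray, margin: int = 6) -> tuple[slice, slice]:
    rows = np.flatnonzero(band.any(axis=1))
    cols = np.flatnonzero(band.any(axis=0))
    r0 = max(int(rows[0]) - margin, 0)
    r1 = min(int(rows[-1]) + margin + 1, band.shape[0])
    c0 = max(int(cols[0]) - margin, 0)
    c1 = min(int(cols[-1]) + margin + 1, band.shape[1])
    return slice(r0, r1), slice(c0, c1)


def inpaint(
    img: GrayImage, omega: BinaryMask, band: BinaryMask, p: BSCBParams | None = None
) -> GrayImage:
    """Run the full alternating scheme to convergence or the iteration cap.

    Stops when the mean absolute change per Omega pixel per elementary
    update over a whole cycle drops below ``stop_tol``, when the cycle
    residual plateaus, or at ``total_iters``.  Pixels outside the band
    are returned bit-exactly equal to the input.  The iteration is
    confined to the bounding box of the band (padded by a margin larger
    than the stencil reach), which is exactly equivalent to full-frame
    iteration because pixels outside the band never change.
    """
    p = p or BSCBParams()
    out = img.pixels.astype(np.float64).copy()
    om_full = np.asarray(omega.pixels, bool)
    if not om_full.any():
        # nothing to fill: the evolution is the identity
        return GrayImage(out, stage="inpainted")
    win = _band_bbox(np.asarray(band.pixels, bool))
    sub_img = GrayImage(out[win], stage=img.stage)
    sub_om = BinaryMask(om_full[win], role="inpaint_region")
    sub_bd = BinaryMask(np.asarray(band.pixels, bool)[win], role="inpaint_band")
    state = init_state(sub_img, sub_om, sub_bd, p)
    history: list[float] = []
    while state.n < p.total_iters:
        cycle_start = state.u.copy()
        steps = 0
        for _ in range(p.inpaint_steps):
            if state.n >= p.total_iters:
                break
            inpaint_step(state, p)
            steps += 1
        for _ in range(p.diffuse_steps):
            if state.n >= p.total_iters:
                break
            diffuse_step(state, p)
            steps += 1
        delta = state.u.ravel()[state._om_idx] - cycle_start.ravel()[state._om_idx]
        resid = float(np.abs(delta).mean()) / max(steps, 1)
        state.last_residual = resid
        history.append(resid)
        if resid < p.stop_tol:
            break
        if (
            p.plateau_cycles
            and len(history) > p.plateau_cycles
            and history[-1] > p.plateau_ratio * history[-1 - p.plateau_cycles]
        ):
            break
    changed = state.band
    out_win = out[win]
    out_win[changed] = state.u[changed]
    out[win] = out_win
    return GrayImage(out, stage="inpainted")
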