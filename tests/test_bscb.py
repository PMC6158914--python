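"""BSCB transport/diffusion scheme: stencils against hand-rolled
finite-difference oracles, plus the fixed-point and locality contracts."""

import numpy as np
import pytest
from scipy import ndimage

from cupseg import bscb, vessels
from cupseg.errors import ParameterError, ShapeMismatchError
from cupseg.image_io import BinaryMask, GrayImage


def _state(u, omega=None, band=None, p=None):
    p = p or bscb.BSCBParams()
    u = np.asarray(u, float)
    if omega is None:
        omega = np.zeros(u.shape, bool)
    if band is None:
        band = omega.copy()
    return bscb.init_state(
        GrayImage(u), BinaryMask(omega, role="vessel"),
        BinaryMask(band, role="inpaint_band"), p,
    )


def oracle_second(u, axis):
    """Pixel-by-pixel second difference with edge replication."""
    padded = np.pad(u, 1, mode="edge")
    out = np.empty_like(u)
    for i in range(u.shape[0]):
        for j in range(u.shape[1]):
            if axis == "x":
                out[i, j] = padded[i + 1, j + 2] - 2 * padded[i + 1, j + 1] + padded[i + 1, j]
            else:
                out[i, j] = padded[i + 2, j + 1] - 2 * padded[i + 1, j + 1] + padded[i, j + 1]
    return out


def oracle_nbhd_mean(a):
    """3x3 neighbourhood mean with reflect padding, looped."""
    padded = np.pad(a, 1, mode="symmetric")
    out = np.empty_like(a)
    for i in range(a.shape[0]):
        for j in range(a.shape[1]):
            out[i, j] = padded[i : i + 3, j : j + 3].mean()
    return out


def oracle_grad(a):
    padded = np.pad(a, 1, mode="edge")
    gx = 0.5 * (padded[1:-1, 2:] - padded[1:-1, :-2])
    gy = 0.5 * (padded[2:, 1:-1] - padded[:-2, 1:-1])
    return gx, gy


class TestPropagationInfo:
    def test_constant_is_zero(self):
        st = _state(np.full((9, 9), 50.0))
        assert np.all(bscb.propagation_info(st) == 0)

    def test_quadratic_row_profile(self):
        """u = i^2 has second difference 2 along rows and 0 along
        columns, so the summed propagation info is 2 in the interior."""
        rr = np.arange(9, dtype=float)
        u = np.tile((rr**2)[:, None], (1, 9))
        st = _state(u)
        L = bscb.propagation_info(st)
        assert np.allclose(L[3:-3, 3:-3], 2.0)

    def test_matches_exhaustive_oracle(self, rng):
        u = rng.normal(100, 20, size=(7, 7))
        st = _state(u)
        for mode in ("sum", "product"):
            p = bscb.BSCBParams(laplacian_mode=mode)
            uxx = oracle_nbhd_mean(oracle_second(u, "x"))
            uyy = oracle_nbhd_mean(oracle_second(u, "y"))
            want = uxx + uyy if mode == "sum" else uxx * uyy
            assert np.allclose(bscb.propagation_info(st, p), want, atol=1e-12)

    def test_single_pixel_variant(self, rng):
        u = rng.normal(0, 1, size=(6, 6))
        st = _state(u)
        p = bscb.BSCBParams(nbhd=1)
        want = oracle_second(u, "x") + oracle_second(u, "y")
        assert np.allclose(bscb.propagation_info(st, p), want, atol=1e-12)


class TestIsophoteDirection:
    def test_row_ramp_runs_along_rows(self):
        """Intensity varying with row only: isophotes are horizontal,
        the direction is the unit x (column) vector up to sign."""
        u = np.tile(np.arange(8, dtype=float)[:, None], (1, 8))
        t = bscb.isophote_direction(_state(u))
        assert np.allclose(np.abs(t[..., 0]), 1.0)
        assert np.allclose(t[..., 1], 0.0)

    def test_constant_gives_zero_vectors(self):
        t = bscb.isophote_direction(_state(np.full((6, 6), 9.0)))
        assert np.all(t == 0)

    def test_diagonal_ramp(self):
        rr, cc = np.meshgrid(np.arange(10.0), np.arange(10.0), indexing="ij")
        u = 3.0 * (rr + cc)
        t = bscb.isophote_direction(_state(u))
        inner = t[2:-2, 2:-2]
        # unit vectors along (1, -1)/sqrt(2) up to sign, perpendicular to grad
        assert np.allclose(np.abs(inner[..., 0]), 1 / np.sqrt(2), atol=1e-9)
        assert np.allclose(inner[..., 0] + inner[..., 1], 0.0, atol=1e-9)

    def test_unit_norm_or_zero(self, rng):
        u = rng.normal(0, 30, size=(12, 12))
        t = bscb.isophote_direction(_state(u))
        norms = np.hypot(t[..., 0], t[..., 1])
        assert np.all((np.abs(norms - 1) < 1e-9) | (norms == 0))


class TestSteps:
    def test_empty_omega_is_identity(self):
        u = np.arange(36.0).reshape(6, 6)
        st = _state(u)
        bscb.inpaint_step(st, bscb.BSCBParams())
        assert np.array_equal(st.u, u)

    def test_constant_is_fixed_point_of_both(self):
        om = np.zeros((8, 8), bool)
        om[3:5, 3:5] = True
        band = ndimage.binary_dilation(om)
        st = _state(np.full((8, 8), 33.0), om, band)
        p = bscb.BSCBParams()
        bscb.inpaint_step(st, p)
        bscb.diffuse_step(st, p)
        assert np.all(st.u == 33.0)

    def test_inpaint_step_matches_pointwise_oracle(self, rng):
        """The transport update at a masked pixel equals
        dt * grad(L-bar) . T computed by the looped oracle."""
        rr, cc = np.meshgrid(np.arange(9.0), np.arange(9.0), indexing="ij")
        u = 5.0 * rr + 2.0 * cc
        u[4, 4] = 0.0  # perturbed hole pixel
        om = np.zeros((9, 9), bool)
        om[4, 4] = True
        p = bscb.BSCBParams(limiter=False)
        st = _state(u.copy(), om, ndimage.binary_dilation(om), p)
        bscb.inpaint_step(st, p)
        L = oracle_nbhd_mean(oracle_second(u, "x")) + oracle_nbhd_mean(oracle_second(u, "y"))
        lx, ly = oracle_grad(L)
        gx, gy = oracle_grad(u)
        mag = np.hypot(gx, gy)[4, 4]
        tx, ty = (-gy[4, 4] / mag, gx[4, 4] / mag)
        want = u[4, 4] + p.dt * (lx[4, 4] * tx + ly[4, 4] * ty)
        assert st.u[4, 4] == pytest.approx(want, abs=1e-12)
        assert np.array_equal(st.u[~om], u[~om])

    def test_diffuse_ramp_invariant(self):
        """Straight isophotes have zero curvature: a linear ramp is
        (numerically) invariant under the diffusion update."""
        rr, cc = np.meshgrid(np.arange(10.0), np.arange(10.0), indexing="ij")
        u = 4.0 * rr + 1.0 * cc
        band = np.zeros((10, 10), bool)
        band[3:7, 3:7] = True
        st = _state(u.copy(), np.zeros((10, 10), bool), band)
        bscb.diffuse_step(st, bscb.BSCBParams())
        assert np.allclose(st.u, u, atol=1e-8)

    def test_diffuse_shrinks_dark_cone(self):
        """Curvature flow raises a dark radial dip: level sets shrink."""
        rr, cc = np.meshgrid(np.arange(15.0), np.arange(15.0), indexing="ij")
        dist = np.hypot(rr - 7, cc - 7)
        u = np.minimum(dist * 10.0, 60.0)
        band = dist <= 4
        p = bscb.BSCBParams(limiter=False)
        st = _state(u.copy(), np.zeros_like(band), band, p)
        bscb.diffuse_step(st, p)
        ring = band & (dist >= 2)
        assert np.all(st.u[ring] >= u[ring])
        assert st.u[ring].mean() > u[ring].mean()


class TestInitState:
    def test_g_profile(self):
        band = np.zeros((30, 30), bool)
        band[5:25, 5:25] = True
        st = _state(np.zeros((30, 30)), np.zeros_like(band), band)
        assert st.g[15, 15] == pytest.approx(1.0, abs=1e-6)
        assert np.all(st.g[~band] == 0.0)
        assert st.g.min() >= 0 and st.g.max() <= 1

    def test_omega_outside_band_rejected(self):
        om = np.zeros((8, 8), bool)
        om[0, 0] = True
        band = np.zeros((8, 8), bool)
        band[4:, 4:] = True
        with pytest.raises(ShapeMismatchError):
            _state(np.zeros((8, 8)), om, band)


class TestInpaint:
    def test_empty_omega_identity(self, rng):
        u = rng.normal(100, 10, size=(20, 20))
        empty = BinaryMask(np.zeros((20, 20), bool), role="vessel")
        out = bscb.inpaint(GrayImage(u), empty, empty)
        assert np.array_equal(out.pixels, u)
        assert out.stage == "inpainted"

    def test_locality_bit_exact(self, rng):
        u = rng.normal(120, 15, size=(30, 30))
        om = np.zeros((30, 30), bool)
        om[10:14, 10:20] = True
        band = ndimage.binary_dilation(om, vessels.disc_structure(2))
        out = bscb.inpaint(
            GrayImage(u), BinaryMask(om, role="vessel"),
            BinaryMask(band, role="inpaint_band"),
            bscb.BSCBParams(total_iters=200),
        )
        assert np.array_equal(out.pixels[~band], u[~band])

    def test_constant_fixed_point(self):
        u = np.full((20, 20), 88.0)
        om = np.zeros((20, 20), bool)
        om[8:12, 8:12] = True
        band = ndimage.binary_dilation(om)
        out = bscb.inpaint(
            GrayImage(u), BinaryMask(om, role="vessel"),
            BinaryMask(band, role="inpaint_band"),
        )
        assert np.array_equal(out.pixels, u)

    def test_boundedness_on_noisy_input(self, rng):
        u = np.clip(rng.normal(128, 30, size=(40, 40)), 0, 255)
        om = rng.random((40, 40)) < 0.3
        band = ndimage.binary_dilation(om, vessels.disc_structure(2))
        out = bscb.inpaint(
            GrayImage(u), BinaryMask(om, role="vessel"),
            BinaryMask(band, role="inpaint_band"),
            bscb.BSCBParams(total_iters=500),
        )
        assert out.pixels.min() >= u.min() - 5
        assert out.pixels.max() <= u.max() + 5


def test_param_validation():
    with pytest.raises(ParameterError):
        bscb.BSCBParams(dt=0)
    with pytest.raises(ParameterError):
        bscb.BSCBParams(nbhd=2)
    with pytest.raises(ParameterError):
        bscb.BSCBParams(laplacian_mode="mean")
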