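"""F-score, radial boundary distance, and vertical CDR."""

import numpy as np
import pytest

from cupseg import metrics
from cupseg.errors import DegenerateInputError, ShapeMismatchError
from cupseg.image_io import BinaryMask


def circle_contour(center, radius, n=720):
    th = np.linspace(0, 2 * np.pi, n, endpoint=False)
    verts = np.stack([center[0] + radius * np.sin(th), center[1] + radius * np.cos(th)], axis=1)
    return metrics.Contour(vertices=verts, centroid=center)


def box_mask(shape, r0, r1, c0, c1, role="cup"):
    m = np.zeros(shape, bool)
    m[r0:r1, c0:c1] = True
    return BinaryMask(m, role=role)


class TestConfusionAndF:
    def test_perfect_overlap(self):
        a = box_mask((20, 20), 5, 10, 5, 13)
        c = metrics.confusion(a, a)
        assert (c.tp, c.fp, c.fn) == (40, 0, 0)
        assert metrics.f_score(c) == 1.0

    def test_disjoint(self):
        a = box_mask((20, 20), 0, 1, 0, 10)
        b = box_mask((20, 20), 10, 12, 0, 10)
        c = metrics.confusion(a, b)
        assert (c.tp, c.fp, c.fn) == (0, 10, 20)
        assert metrics.f_score(c) == 0.0

    def test_superset(self):
        truth = box_mask((20, 20), 5, 10, 5, 11)  # 30 px
        pred = BinaryMask(truth.pixels.copy(), role="cup")
        pred.pixels[4, 5:10] = True  # 5 extra px
        c = metrics.confusion(pred, truth)
        assert (c.tp, c.fp, c.fn) == (30, 5, 0)

    def test_two_thirds_exact(self):
        c = metrics.ConfusionCounts(tp=2, fp=1, fn=1)
        assert metrics.f_score(c) == pytest.approx(2 / 3, abs=0)

    def test_all_zero_counts_error(self):
        with pytest.raises(DegenerateInputError):
            metrics.f_score(metrics.ConfusionCounts(0, 0, 0))

    def test_swap_symmetry(self, rng):
        """Swapping prediction and truth swaps fp/fn and leaves F fixed."""
        for _ in range(5):
            a = BinaryMask(rng.random((15, 15)) > 0.6, role="cup")
            b = BinaryMask(rng.random((15, 15)) > 0.6, role="cup")
            if not (a.pixels.any() or b.pixels.any()):
                continue
            assert metrics.f_score(metrics.confusion(a, b)) == pytest.approx(
                metrics.f_score(metrics.confusion(b, a))
            )

    def test_shape_mismatch(self):
        with pytest.raises(ShapeMismatchError):
            metrics.confusion(box_mask((10, 10), 0, 1, 0, 1), box_mask((9, 9), 0, 1, 0, 1))


class TestMaskToContour:
    def test_single_pixel_diamond(self):
        m = np.zeros((5, 5), bool)
        m[2, 2] = True
        c = metrics.mask_to_contour(BinaryMask(m, role="cup"))
        assert len(c.vertices) == 4
        assert np.allclose(sorted(np.abs(c.vertices - 2).sum(axis=1)), [0.5] * 4)

    def test_rectangle_encloses_its_pixels(self):
        mask = box_mask((20, 20), 5, 10, 6, 14)
        c = metrics.mask_to_contour(mask)
        rr, cc = np.nonzero(mask.pixels)
        assert c.vertices[:, 0].min() == pytest.approx(4.5)
        assert c.vertices[:, 0].max() == pytest.approx(9.5)
        assert c.vertices[:, 1].min() == pytest.approx(5.5)
        assert c.vertices[:, 1].max() == pytest.approx(13.5)
        assert c.centroid == (pytest.approx(rr.mean()), pytest.approx(cc.mean()))

    def test_disc_centroid(self):
        rr, cc = np.meshgrid(np.arange(30), np.arange(30), indexing="ij")
        m = (rr - 15) ** 2 + (cc - 15) ** 2 <= 64
        c = metrics.mask_to_contour(BinaryMask(m, role="cup"))
        assert c.centroid[0] == pytest.approx(15, abs=0.5)
        assert c.centroid[1] == pytest.approx(15, abs=0.5)

    def test_empty_and_multicomponent_rejected(self):
        with pytest.raises(DegenerateInputError):
            metrics.mask_to_contour(BinaryMask(np.zeros((5, 5), bool), role="cup"))
        m = np.zeros((10, 10), bool)
        m[1, 1] = m[8, 8] = True
        with pytest.raises(DegenerateInputError, match="2 components"):
            metrics.mask_to_contour(BinaryMask(m, role="cup"))


class TestBoundaryDistance:
    def test_identical_contours_zero(self):
        c = circle_contour((50.0, 50.0), 10.0)
        assert metrics.boundary_distance(c, c, 360) == 0.0

    def test_concentric_circles(self):
        ce = circle_contour((50.0, 50.0), 10.0)
        cm = circle_contour((50.0, 50.0), 12.0)
        assert metrics.boundary_distance(ce, cm, 360) == pytest.approx(2.0, abs=0.1)

    def test_ray_miss_reports_angle(self):
        ce = circle_contour((50.0, 50.0), 10.0)
        far = circle_contour((200.0, 200.0), 3.0)
        with pytest.raises(DegenerateInputError, match="deg"):
            metrics.boundary_distance(ce, far, 36)

    def test_monotone_along_radial_morph(self):
        """Interpolating the algorithm curve radially toward the expert
        curve can only shrink the distance."""
        ce = circle_contour((40.0, 40.0), 10.0)
        base = circle_contour((40.0, 40.0), 16.0)
        ds = []
        for lam in (0.0, 0.5, 1.0):
            verts = base.vertices + lam * (ce.vertices - base.vertices)
            cm = metrics.Contour(vertices=verts, centroid=(40.0, 40.0))
            ds.append(metrics.boundary_distance(ce, cm, 180))
        assert ds[0] >= ds[1] >= ds[2]


class TestVerticalCDR:
    def test_stated_arithmetic(self):
        cup = box_mask((120, 50), 30, 70, 10, 30)   # rows 30..69 -> 40
        disc = box_mask((120, 50), 10, 110, 5, 45, role="disc")  # rows 10..109 -> 100
        assert metrics.vertical_cdr(cup, disc) == pytest.approx(0.4, abs=0)

    def test_identity(self):
        m = box_mask((50, 50), 10, 30, 10, 30)
        assert metrics.vertical_cdr(m, m) == 1.0

    def test_translation_and_scale_invariance(self):
        cup = box_mask((200, 200), 50, 90, 20, 40)
        disc = box_mask((200, 200), 30, 130, 80, 120, role="disc")
        v = metrics.vertical_cdr(cup, disc)
        cup2 = box_mask((200, 200), 50, 90, 120, 140)  # horizontal shift
        assert metrics.vertical_cdr(cup2, disc) == v
        # doubling both vertical extents preserves the ratio
        cup3 = box_mask((400, 200), 50, 130, 20, 40)
        disc3 = box_mask((400, 200), 30, 230, 80, 120, role="disc")
        assert metrics.vertical_cdr(cup3, disc3) == v

    def test_empty_mask_error(self):
        with pytest.raises(DegenerateInputError):
            metrics.vertical_cdr(
                BinaryMask(np.zeros((10, 10), bool), role="cup"),
                box_mask((10, 10), 0, 5, 0, 5, role="disc"),
            )


def test_evaluate_report_fields():
    pred = box_mask((60, 60), 20, 40, 20, 40)
    truth = box_mask((60, 60), 21, 41, 20, 40)
    disc = box_mask((60, 60), 10, 50, 10, 50, role="disc")
    rep = metrics.evaluate(pred, truth, disc=disc)
    assert 0 < rep.f_score <= 1
    assert rep.distance_px is not None and rep.distance_px < 2
    assert rep.cdr == pytest.approx(20 / 40)
    d = rep.as_dict()
    assert set(d) == {"precision", "recall", "f_score", "distance_px", "cdr", "n_angles"}


from hypothesis import given, settings, strategies as st


@settings(max_examples=50, deadline=None, derandomize=True)
@given(tp=st.integers(0, 500), fp=st.integers(0, 500), fn=st.integers(0, 500))
def test_f_score_bounds_and_symmetry_property(tp, fp, fn):
    """F lies in [0, 1], is 1 iff the masks agree exactly, and is
    invariant under swapping prediction and truth (fp <-> fn)."""
    if tp + fp + fn == 0:
        return
    f = metrics.f_score(metrics.ConfusionCounts(tp, fp, fn))
    assert 0.0 <= f <= 1.0
    assert (f == 1.0) == (fp == 0 and fn == 0 and tp > 0)
    assert f == metrics.f_score(metrics.ConfusionCounts(tp, fn, fp))
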