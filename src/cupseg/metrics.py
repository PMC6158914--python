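"""Evaluation criteria: pixel-wise F-score, radial boundary distance,
and the vertical cup-to-disc ratio (CDR).

* F-score: harmonic mean of pixel precision TP/(TP+FP) and recall
  TP/(TP+FN) between a predicted and a reference mask.
* Boundary distance D: rays are cast from the centroid of the expert
  contour C_e at n equally spaced angles; D is the mean absolute
  difference between the radial distances at which each ray meets C_e
  and the algorithm contour C_m.
* Vertical CDR: ratio of the vertical diameters (inclusive row extents)
  of the cup and disc masks; the clinical glaucoma indicator.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import ndimage
from skimage import measure

from .errors import DegenerateInputError, ParameterError, ShapeMismatchError
from .image_io import BinaryMask

_EIGHT = np.ones((3, 3), dtype=bool)


@dataclass
class ConfusionCounts:
    tp: int
    fp: int
    fn: int


@dataclass
class Contour:
    """Closed ordered polygon in (row, col) image coordinates.

    The vertex list is implicitly closed (last connects to first) and
    ordered counter-clockwise in display orientation (row axis pointing
    down).  ``centroid`` is the reference point rays are cast from; for
    mask-derived contours it is the foreground pixel centroid.
    """

    vertices: np.ndarray  # N x 2 float, (row, col)
    centroid: tuple[float, float]

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=np.float64)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 2:
            raise ParameterError("vertices must be an Nx2 array of (row, col)")
        if len(self.vertices) < 3:
            raise ParameterError("a contour needs at least 3 vertices")


@dataclass
class MetricsReport:
    precision: float
    recall: float
    f_score: float
    distance_px: Optional[float] = None
    cdr: Optional[float] = None
    n_angles: int = 360

    def as_dict(self) -> dict:
        return {
            "precision": self.precision,
            "recall": self.recall,
            "f_score": self.f_score,
            "distance_px": self.distance_px,
            "cdr": self.cdr,
            "n_angles": self.n_angles,
        }


def confusion(pred: BinaryMask, truth: BinaryMask) -> ConfusionCounts:
    """Exact pixel counts of true/false positives and false negatives."""
    if pred.shape != truth.shape:
        raise ShapeMismatchError(f"shapes differ: {pred.shape} vs {truth.shape}")
    a, b = pred.pixels, truth.pixels
    return ConfusionCounts(
        tp=int((a & b).sum()), fp=int((a & ~b).sum()), fn=int((~a & b).sum())
    )


def precision_recall(c: ConfusionCounts) -> tuple[float, float]:
    prec = c.tp / (c.tp + c.fp) if (c.tp + c.fp) else 0.0
    rec = c.tp / (c.tp + c.fn) if (c.tp + c.fn) else 0.0
    return prec, rec


def f_score(c: ConfusionCounts) -> float:
    """Harmonic mean of precision and recall; 0 when TP = 0."""
    if c.tp + c.fp + c.fn == 0:
        raise DegenerateInputError("F-score undefined: all confusion counts are zero")
    if c.tp == 0:
        return 0.0
    prec, rec = precision_recall(c)
    return 2.0 * prec * rec / (prec + rec)


def mask_to_contour(mask: BinaryMask) -> Contour:
    """Trace the outer boundary of a single-component mask at the 0.5
    iso-level (marching squares), counter-clockwise, with the foreground
    pixel centroid as reference point."""
    pix = mask.pixels
    if not pix.any():
        raise DegenerateInputError("cannot trace an empty mask")
    _, ncomp = ndimage.label(pix, structure=_EIGHT)
    if ncomp != 1:
        raise DegenerateInputError(f"mask has {ncomp} components, need exactly 1")
    padded = np.pad(pix.astype(np.float64), 1)
    contours = measure.find_contours(padded, 0.5)
    verts = max(contours, key=len) - 1.0  # undo padding offset
    if np.allclose(verts[0], verts[-1]):
        verts = verts[:-1]
    # enforce counter-clockwise orientation (positive shoelace area in
    # (x, y) = (col, -row) display coordinates)
    x, y = verts[:, 1], -verts[:, 0]
    area2 = float(np.dot(x, np.roll(y, -1)) - np.dot(np.roll(x, -1), y))
    if area2 < 0:
        verts = verts[::-1]
    rows, cols = np.nonzero(pix)
    return Contour(vertices=verts, centroid=(float(rows.mean()), float(cols.mean())))


def _ray_hits(origin: np.ndarray, direction: np.ndarray, verts: np.ndarray) -> float:
    """Farthest intersection distance of a ray with a closed polygon,
    or NaN when the ray misses entirely."""
    p = verts
    q = np.roll(verts, -1, axis=0)
    e = q - p  # segment vectors
    w = p - origin
    # 2-D cross products; row/col treated as plain Cartesian coordinates
    denom = direction[0] * e[:, 1] - direction[1] * e[:, 0]
    num_t = w[:, 0] * e[:, 1] - w[:, 1] * e[:, 0]
    num_s = w[:, 0] * direction[1] - w[:, 1] * direction[0]
    with np.errstate(divide="ignore", invalid="ignore"):
        t = num_t / denom
        s = num_s / denom
    ok = (np.abs(denom) > 1e-12) & (s >= -1e-9) & (s <= 1 + 1e-9) & (t > 1e-9)
    if not ok.any():
        return float("nan")
    return float(t[ok].max())


def boundary_distance(c_e: Contour, c_m: Contour, n_angles: int = 360) -> float:
    """Mean absolute radial difference between two contours.

    Rays start at the centroid of ``c_e`` (the expert curve) at angles
    2*pi*k/n_angles; each radial distance is to the farthest
    intersection with the contour, which selects the outer boundary for
    mildly non-convex curves.
    """
    if n_angles < 1:
        raise ParameterError("n_angles must be >= 1")
    origin = np.asarray(c_e.centroid, dtype=np.float64)
    d = np.empty(n_angles)
    for k in range(n_angles):
        theta = 2.0 * np.pi * k / n_angles
        # x = col ~ cos, y = row ~ sin; any fixed convention works since
        # both contours are probed with the same ray
        direction = np.array([np.sin(theta), np.cos(theta)])
        de = _ray_hits(origin, direction, c_e.vertices)
        dm = _ray_hits(origin, direction, c_m.vertices)
        if np.isnan(de) or np.isnan(dm):
            raise DegenerateInputError(
                f"ray at angle {np.degrees(theta):.1f} deg misses a contour; "
                "contours must be star-shaped about the expert centroid"
            )
        d[k] = abs(de - dm)
    return float(d.mean())


def vertical_cdr(cup: BinaryMask, disc: BinaryMask) -> float:
    """CDR = C_V / D_V with inclusive vertical pixel extents."""
    if not cup.pixels.any():
        raise DegenerateInputError("cup mask is empty")
    if not disc.pixels.any():
        raise DegenerateInputError("disc mask is empty")
    def vdiam(m: np.ndarray) -> int:
        rows = np.flatnonzero(m.any(axis=1))
        return int(rows[-1] - rows[0] + 1)
    return vdiam(cup.pixels) / vdiam(disc.pixels)


def evaluate(
    pred: BinaryMask,
    truth: BinaryMask,
    disc: Optional[BinaryMask] = None,
    n_angles: int = 360,
) -> MetricsReport:
    """Full report: precision/recall/F, boundary distance, optional CDR.

    The boundary distance is skipped (None) when either mask is not a
    single component, since the radial criterion is defined on closed
    curves only.
    """
    c = confusion(pred, truth)
    prec, rec = precision_recall(c)
    f = f_score(c)
    dist: Optional[float] = None
    try:
        dist = boundary_distance(
            mask_to_contour(truth), mask_to_contour(pred), n_angles
        )
    except DegenerateInputError:
        dist = None
    cdr = vertical_cdr(pred, disc) if disc is not None else None
    return MetricsReport(
        precision=prec, recall=rec, f_score=f,
        distance_px=dist, cdr=cdr, n_angles=n_angles,
    )
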