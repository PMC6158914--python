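"""Finite-difference stencils shared by the PDE stages.

All derivatives are central differences on a unit grid with
edge-replicating (reflect) boundaries, so constants have exactly zero
derivatives everywhere including the border.  Convention: x is the
column direction, y is the row direction.

Implemented with direct slicing (no padding allocations): these kernels
sit in the innermost loop of the inpainting scheme.
"""

from __future__ import annotations

import numpy as np


def grad_x(u: np.ndarray) -> np.ndarray:
    """du/dx (column direction), central difference."""
    out = np.empty_like(u)
    out[:, 1:-1] = 0.5 * (u[:, 2:] - u[:, :-2])
    out[:, 0] = 0.5 * (u[:, 1] - u[:, 0])
    out[:, -1] = 0.5 * (u[:, -1] - u[:, -2])
    return out


def grad_y(u: np.ndarray) -> np.ndarray:
    """du/dy (row direction), central difference."""
    out = np.empty_like(u)
    out[1:-1, :] = 0.5 * (u[2:, :] - u[:-2, :])
    out[0, :] = 0.5 * (u[1, :] - u[0, :])
    out[-1, :] = 0.5 * (u[-1, :] - u[-2, :])
    return out


def second_x(u: np.ndarray) -> np.ndarray:
    """d2u/dx2: u(i, j+1) - 2 u(i, j) + u(i, j-1)."""
    out = np.empty_like(u)
    core = out[:, 1:-1]
    np.add(u[:, 2:], u[:, :-2], out=core)
    core -= u[:, 1:-1]
    core -= u[:, 1:-1]
    out[:, 0] = u[:, 1] - u[:, 0]
    out[:, -1] = u[:, -2] - u[:, -1]
    return out


def second_y(u: np.ndarray) -> np.ndarray:
    """d2u/dy2: u(i+1, j) - 2 u(i, j) + u(i-1, j)."""
    out = np.empty_like(u)
    core = out[1:-1, :]
    np.add(u[2:, :], u[:-2, :], out=core)
    core -= u[1:-1, :]
    core -= u[1:-1, :]
    out[0, :] = u[1, :] - u[0, :]
    out[-1, :] = u[-2, :] - u[-1, :]
    return out


def grad_mag(u: np.ndarray) -> np.ndarray:
    gx, gy = grad_x(u), grad_y(u)
    return np.sqrt(gx * gx + gy * gy)


def curvature(u: np.ndarray, eps: float = 1e-8) -> np.ndarray:
    """Euclidean curvature of the isophotes, div(grad u / |grad u|),
    with the gradient magnitude regularized by ``eps``."""
    gx, gy = grad_x(u), grad_y(u)
    mag = np.sqrt(gx * gx + gy * gy) + eps
    return grad_x(gx / mag) + grad_y(gy / mag)
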