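"""Grid-based vector-field comparison for in silico perturbation readout.

Two fields live on a shared rectangular grid over the embedding: the
pseudotime gradient under unperturbed conditions and a perturbation
displacement field (from any engine — per-cell 2-vectors are plain input).
The nodewise inner product classifies each grid region as accessible
(product > 0: perturbation flow still follows the developmental direction)
or inaccessible (product < 0: flow reversed).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np

from .io import DataError

logger = logging.getLogger("growthplate")


@dataclass
class VectorFieldGrid:
    """2-vectors on an (nx, ny) grid with per-node kernel support."""

    x_nodes: np.ndarray  # (nx,)
    y_nodes: np.ndarray  # (ny,)
    vectors: np.ndarray  # (nx, ny, 2); zero at masked nodes
    support: np.ndarray  # (nx, ny) kernel-weighted cell mass
    mask: np.ndarray     # (nx, ny) True = node supported

    def same_grid(self, other: "VectorFieldGrid") -> bool:
        return (np.array_equal(self.x_nodes, other.x_nodes)
                and np.array_equal(self.y_nodes, other.y_nodes))


@dataclass
class AccessibilityMap:
    """Per-node inner product and sign class (+1 accessible, -1 inaccessible,
    0 neutral or masked)."""

    x_nodes: np.ndarray
    y_nodes: np.ndarray
    inner_product: np.ndarray
    label: np.ndarray
    mask: np.ndarray


def make_grid(xy: np.ndarray, nx: int = 40, ny: int = 40,
              margin: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Axis-aligned grid over the bounding box with a fractional margin."""
    if nx < 2 or ny < 2:
        raise DataError("grid needs nx, ny >= 2")
    xmin, xmax = xy[:, 0].min(), xy[:, 0].max()
    ymin, ymax = xy[:, 1].min(), xy[:, 1].max()
    dx = (xmax - xmin) or 1.0
    dy = (ymax - ymin) or 1.0
    return (np.linspace(xmin - margin * dx, xmax + margin * dx, nx),
            np.linspace(ymin - margin * dy, ymax + margin * dy, ny))


def _kernel_weights(xy: np.ndarray, x_nodes: np.ndarray, y_nodes: np.ndarray,
                    bandwidth: float | None) -> tuple[np.ndarray, float]:
    if bandwidth is None:
        spacing = (np.diff(x_nodes).mean() + np.diff(y_nodes).mean()) / 2.0
        bandwidth = 1.5 * spacing
    gx, gy = np.meshgrid(x_nodes, y_nodes, indexing="ij")
    nodes = np.column_stack([gx.ravel(), gy.ravel()])
    d2 = ((nodes[:, None, :] - xy[None, :, :]) ** 2).sum(axis=2)
    return np.exp(-d2 / (2.0 * bandwidth**2)), bandwidth


def smooth_vectors_to_grid(xy: np.ndarray, vectors: np.ndarray, nx: int = 40,
                           ny: int = 40, bandwidth: float | None = None,
                           min_support: float = 1.0, margin: float = 0.05,
                           x_nodes: np.ndarray | None = None,
                           y_nodes: np.ndarray | None = None) -> VectorFieldGrid:
    """Gaussian-kernel-weighted mean of per-cell vectors at each grid node.

    Nodes whose kernel-weighted support falls below ``min_support`` are
    masked and carry zero vectors.
    """
    xy = np.asarray(xy, dtype=float)
    vectors = np.asarray(vectors, dtype=float)
    if xy.ndim != 2 or xy.shape[0] == 0:
        raise DataError("need at least one cell")
    if vectors.shape != xy.shape:
        raise DataError("one 2-vector per cell required")
    if not (np.all(np.isfinite(xy)) and np.all(np.isfinite(vectors))):
        raise DataError("non-finite coordinates or vectors")
    if x_nodes is None or y_nodes is None:
        x_nodes, y_nodes = make_grid(xy, nx, ny, margin)
    W, _ = _kernel_weights(xy, x_nodes, y_nodes, bandwidth)
    support = W.sum(axis=1).reshape(len(x_nodes), len(y_nodes))
    num = (W @ vectors).reshape(len(x_nodes), len(y_nodes), 2)
    mask = support >= min_support
    vec = np.zeros_like(num)
    vec[mask] = num[mask] / support[mask, None]
    return VectorFieldGrid(x_nodes, y_nodes, vec, support, mask)


def pseudotime_gradient_grid(xy: np.ndarray, pseudotime: np.ndarray, nx: int = 40,
                             ny: int = 40, bandwidth: float | None = None,
                             min_support: float = 1.0, margin: float = 0.05,
                             x_nodes: np.ndarray | None = None,
                             y_nodes: np.ndarray | None = None) -> VectorFieldGrid:
    """Numerical gradient of kernel-smoothed pseudotime on the grid.

    Interior nodes use central differences, boundary nodes one-sided ones.
    A constant pseudotime yields an all-zero field with a warning.
    """
    xy = np.asarray(xy, dtype=float)
    pt = np.asarray(pseudotime, dtype=float)
    if not np.all(np.isfinite(pt)):
        raise DataError("non-finite pseudotime")
    if x_nodes is None or y_nodes is None:
        x_nodes, y_nodes = make_grid(xy, nx, ny, margin)
    if np.ptp(pt) == 0:
        warnings.warn("constant pseudotime: gradient field is zero everywhere")
        shape = (len(x_nodes), len(y_nodes))
        return VectorFieldGrid(x_nodes, y_nodes, np.zeros(shape + (2,)),
                               np.zeros(shape), np.zeros(shape, dtype=bool))
    W, _ = _kernel_weights(xy, x_nodes, y_nodes, bandwidth)
    support = W.sum(axis=1).reshape(len(x_nodes), len(y_nodes))
    # scalar field smoothed with all cells (tiny weights still define a value)
    field = (W @ pt).reshape(len(x_nodes), len(y_nodes)) / np.maximum(support, 1e-300)
    gx, gy = np.gradient(field, x_nodes, y_nodes)
    vec = np.dstack([gx, gy])
    mask = support >= min_support
    vec[~mask] = 0.0
    return VectorFieldGrid(x_nodes, y_nodes, vec, support, mask)


def inner_product_map(g: VectorFieldGrid, v: VectorFieldGrid,
                      eps: float = 0.0) -> AccessibilityMap:
    """Nodewise inner product of two fields; sign classifies accessibility.

    Masks are united; |inner product| <= eps is neutral.
    """
    if not g.same_grid(v):
        raise DataError("vector fields live on different grids")
    ip = (g.vectors * v.vectors).sum(axis=2)
    mask = g.mask & v.mask
    label = np.zeros(ip.shape, dtype=int)
    label[mask & (ip > eps)] = 1
    label[mask & (ip < -eps)] = -1
    ip = np.where(mask, ip, 0.0)
    return AccessibilityMap(g.x_nodes, g.y_nodes, ip, label, mask)


def interpolate_grid_vectors(grid: VectorFieldGrid, xy: np.ndarray) -> np.ndarray:
    """Bilinear interpolation of the grid field at arbitrary points."""
    from scipy.interpolate import RegularGridInterpolator

    interp = RegularGridInterpolator(
        (grid.x_nodes, grid.y_nodes), grid.vectors,
        bounds_error=False, fill_value=None,
    )
    return interp(np.asarray(xy, dtype=float))
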