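"""Raster/vector geometry helpers shared across modules.

All rasterization follows the package convention: pixel ``(row, col)``
covers ``[col*p, (col+1)*p) x [row*p, (row+1)*p)`` nm and a pixel belongs
to a polygon iff its centre does.
"""

from __future__ import annotations

import numpy as np
import shapely
from shapely.geometry import Polygon

from .errors import ParameterError


def pixel_centers(shape: tuple[int, int], pixel_size_nm: float, origin_nm=(0.0, 0.0)):
    """Return (X, Y) centre coordinates in nm for an (H, W) grid."""
    h, w = shape
    x = origin_nm[0] + (np.arange(w) + 0.5) * pixel_size_nm
    y = origin_nm[1] + (np.arange(h) + 0.5) * pixel_size_nm
    return np.meshgrid(x, y)


def rasterize_polygon(
    poly: Polygon, shape: tuple[int, int], pixel_size_nm: float, origin_nm=(0.0, 0.0)
) -> np.ndarray:
    """Boolean (H, W) mask of pixels whose centres fall inside ``poly``."""
    if pixel_size_nm <= 0:
        raise ParameterError("pixel_size_nm must be > 0")
    minx, miny, maxx, maxy = poly.bounds
    h, w = shape
    c0 = max(int((minx - origin_nm[0]) / pixel_size_nm) - 1, 0)
    c1 = min(int((maxx - origin_nm[0]) / pixel_size_nm) + 2, w)
    r0 = max(int((miny - origin_nm[1]) / pixel_size_nm) - 1, 0)
    r1 = min(int((maxy - origin_nm[1]) / pixel_size_nm) + 2, h)
    mask = np.zeros(shape, dtype=bool)
    if c1 <= c0 or r1 <= r0:
        return mask
    x = origin_nm[0] + (np.arange(c0, c1) + 0.5) * pixel_size_nm
    y = origin_nm[1] + (np.arange(r0, r1) + 0.5) * pixel_size_nm
    X, Y = np.meshgrid(x, y)
    mask[r0:r1, c0:c1] = shapely.contains_xy(poly, X.ravel(), Y.ravel()).reshape(X.shape)
    return mask


def erode_polygon(poly: Polygon, width_nm: float) -> Polygon | None:
    """Inward offset; returns None when the erosion empties the polygon."""
    inner = poly.buffer(-width_nm)
    if inner.is_empty or inner.area <= 0:
        return None
    if inner.geom_type == "MultiPolygon":  # keep the dominant piece
        inner = max(inner.geoms, key=lambda g: g.area)
    return inner


def max_feret(points: np.ndarray) -> float:
    """Maximum caliper diameter of a 2D point set (convex-hull pairwise)."""
    hull = _hull(points)
    d2 = ((hull[:, None, :] - hull[None, :, :]) ** 2).sum(-1)
    return float(np.sqrt(d2.max()))


def min_feret(points: np.ndarray) -> float:
    """Minimum caliper width: smallest extent over all hull-edge normals."""
    hull = _hull(points)
    if len(hull) < 3:
        return 0.0
    edges = np.diff(np.vstack([hull, hull[:1]]), axis=0)
    lengths = np.hypot(edges[:, 0], edges[:, 1])
    keep = lengths > 0
    if not keep.any():
        return 0.0
    normals = np.stack([-edges[keep, 1], edges[keep, 0]], axis=1) / lengths[keep, None]
    proj = hull @ normals.T  # (n_pts, n_edges)
    widths = proj.max(axis=0) - proj.min(axis=0)
    return float(widths.min())


def _hull(points: np.ndarray) -> np.ndarray:
    from scipy.spatial import ConvexHull, QhullError

    points = np.asarray(points, dtype=float)
    if len(points) < 3:
        return points
    try:
        return points[ConvexHull(points).vertices]
    except QhullError:  # collinear set
        return points
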