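"""Chromatic registration and coordinate-based colocalization (CBC).

Chromatic aberration between two imaging channels is modelled as a 2D
affine transform estimated by least squares from matched bead
coordinates. Colocalization between two localization channels is scored
per localization with the standard CBC statistic: for each point of
channel A, the area-normalized neighbour-count curves of both channels

    D(r_k) = N(r_k) * r_max^2 / (N(r_max) * r_k^2),   r_k = k*r_max/n

are rank-correlated (Spearman, average ranks for ties) and the
correlation is damped by ``exp(-d/r_max)`` where ``d`` is the distance
to the nearest channel-B point. Scores live in [-1, 1]: +1 means
perfectly correlated clustering, 0 no correlation, -1 anti-correlation.
The radius schedule defaults to r_max = 300 nm over 10 radii; the
defaults are conventional and should be stated with any reported score.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy.spatial import cKDTree

from .errors import ComputationError, ParameterError
from .io_formats import LocalizationTable
from .sr_quant import SegmentedObject

DEFAULT_R_MAX_NM = 300.0
DEFAULT_N_RADII = 10


@dataclasses.dataclass
class AffineTransform2D:
    """x -> A @ x + b in nm coordinates."""

    matrix: np.ndarray
    offset_nm: np.ndarray

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float).reshape(2, 2)
        self.offset_nm = np.asarray(self.offset_nm, dtype=float).reshape(2)
        if abs(np.linalg.det(self.matrix)) <= 1e-12:
            raise ParameterError("affine linear part is singular")

    @classmethod
    def identity(cls) -> "AffineTransform2D":
        return cls(np.eye(2), np.zeros(2))

    @classmethod
    def from_params(
        cls, scale: float = 1.0, rotation_deg: float = 0.0, shift_nm=(0.0, 0.0)
    ) -> "AffineTransform2D":
        th = np.deg2rad(rotation_deg)
        rot = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
        return cls(scale * rot, np.asarray(shift_nm, dtype=float))

    def __call__(self, points: np.ndarray) -> np.ndarray:
        return np.asarray(points, dtype=float) @ self.matrix.T + self.offset_nm

    def compose(self, other: "AffineTransform2D") -> "AffineTransform2D":
        """self after other: x -> self(other(x))."""
        return AffineTransform2D(
            self.matrix @ other.matrix, self.matrix @ other.offset_nm + self.offset_nm
        )

    def invert(self) -> "AffineTransform2D":
        inv = np.linalg.inv(self.matrix)
        return AffineTransform2D(inv, -inv @ self.offset_nm)


def estimate_affine(coords_a: np.ndarray, coords_b: np.ndarray) -> tuple[AffineTransform2D, float]:
    """Least-squares affine T minimizing sum ||T(A_i) - B_i||^2.

    Returns the transform and the RMS residual in nm. Requires at least
    3 matched, non-collinear pairs.
    """
    a = np.asarray(coords_a, dtype=float)
    b = np.asarray(coords_b, dtype=float)
    if a.shape != b.shape or a.ndim != 2 or a.shape[1] != 2:
        raise ParameterError("matched coordinate arrays must both be (n, 2)")
    if len(a) < 3:
        raise ParameterError("need at least 3 matched bead pairs")
    centred = a - a.mean(axis=0)
    if np.linalg.matrix_rank(centred, tol=1e-9 * max(np.abs(centred).max(), 1.0)) < 2:
        raise ParameterError("bead configuration is collinear; affine is degenerate")
    design = np.column_stack([a, np.ones(len(a))])
    sol, *_ = np.linalg.lstsq(design, b, rcond=None)
    t = AffineTransform2D(sol[:2].T, sol[2])
    resid = t(a) - b
    rms = float(np.sqrt(np.mean(np.sum(resid**2, axis=1))))
    return t, rms


def apply_affine(t: AffineTransform2D, table: LocalizationTable) -> LocalizationTable:
    """Map coordinates through ``t``; all other fields are untouched."""
    df = table.data.copy()
    mapped = t(table.xy)
    df["x_nm"] = mapped[:, 0]
    df["y_nm"] = mapped[:, 1]
    return LocalizationTable(df)


@dataclasses.dataclass
class CbcResult:
    scores: np.ndarray  # per channel-A localization, in [-1, 1]
    r_max_nm: float
    n_radii: int

    @property
    def mean(self) -> float:
        return float(np.mean(self.scores)) if len(self.scores) else float("nan")

    @property
    def median(self) -> float:
        return float(np.median(self.scores)) if len(self.scores) else float("nan")


def _rank(values: np.ndarray) -> np.ndarray:
    """Average ranks along the last axis (ties averaged)."""
    order = np.argsort(values, axis=-1, kind="stable")
    ranks = np.empty_like(values)
    n = values.shape[-1]
    idx = np.arange(n, dtype=float)
    np.put_along_axis(ranks, order, np.broadcast_to(idx, values.shape).copy(), axis=-1)
    sorted_vals = np.take_along_axis(values, order, axis=-1)
    # average ranks over runs of equal values
    for row in range(values.shape[0]):
        sv = sorted_vals[row]
        start = 0
        for i in range(1, n + 1):
            if i == n or sv[i] != sv[start]:
                if i - start > 1:
                    avg = (start + i - 1) / 2.0
                    ranks[row, order[row, start:i]] = avg
                start = i
    return ranks


def _spearman_rows(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    rx = _rank(x)
    ry = _rank(y)
    rx = rx - rx.mean(axis=1, keepdims=True)
    ry = ry - ry.mean(axis=1, keepdims=True)
    num = (rx * ry).sum(axis=1)
    den = np.sqrt((rx**2).sum(axis=1) * (ry**2).sum(axis=1))
    out = np.zeros(len(x))
    ok = den > 0
    out[ok] = num[ok] / den[ok]
    return out


def cbc(
    locs_a: LocalizationTable,
    locs_b: LocalizationTable,
    r_max_nm: float = DEFAULT_R_MAX_NM,
    n_radii: int = DEFAULT_N_RADII,
) -> CbcResult:
    """Per-localization CBC scores of channel A against channel B.

    A point with no same- or other-channel neighbour within ``r_max``
    scores 0 (defined, not an error). Self-counting within channel A is
    excluded.
    """
    if len(locs_a) == 0 or len(locs_b) == 0:
        raise ParameterError("both channels must be non-empty")
    if r_max_nm <= 0:
        raise ParameterError("r_max_nm must be > 0")
    if n_radii < 3:
        raise ParameterError("n_radii must be >= 3")
    a = locs_a.xy
    b = locs_b.xy
    radii = r_max_nm * np.arange(1, n_radii + 1) / n_radii
    tree_a = cKDTree(a)
    tree_b = cKDTree(b)

    def neighbour_counts(tree, pts, self_exclude):
        lists = tree.query_ball_point(pts, r_max_nm)
        counts = np.zeros((len(pts), n_radii))
        for i, idx in enumerate(lists):
            idx = np.asarray(idx)
            d = np.hypot(*(tree.data[idx] - pts[i]).T) if len(idx) else np.empty(0)
            if self_exclude:
                d = d[d > 0] if len(d) else d
            counts[i] = np.searchsorted(np.sort(d), radii, side="right")
        return counts

    n_a = neighbour_counts(tree_a, a, self_exclude=True)
    n_b = neighbour_counts(tree_b, a, self_exclude=False)
    d_nearest, _ = tree_b.query(a, k=1)
    scores = np.zeros(len(a))
    valid = (n_a[:, -1] > 0) & (n_b[:, -1] > 0)
    if valid.any():
        norm = r_max_nm**2 / radii**2
        d_a = n_a[valid] * norm / n_a[valid, -1][:, None]
        d_b = n_b[valid] * norm / n_b[valid, -1][:, None]
        rho = _spearman_rows(d_a, d_b)
        scores[valid] = rho * np.exp(-d_nearest[valid] / r_max_nm)
    return CbcResult(scores, r_max_nm, n_radii)


def assign_to_objects(
    locs: LocalizationTable, objects: list[SegmentedObject], image_shape: tuple[int, int]
) -> np.ndarray:
    """Class label ('pit'/'plaque'/'none') of the object containing each localization."""
    if not objects:
        return np.full(len(locs), "none", dtype=object)
    p = objects[0].pixel_size_nm
    ox, oy = objects[0].origin_nm
    class_map = np.full(image_shape, "none", dtype=object)
    for obj in objects:
        class_map[obj.pixels[:, 0], obj.pixels[:, 1]] = obj.cls
    xy = locs.xy
    col = np.floor((xy[:, 0] - ox) / p).astype(int)
    row = np.floor((xy[:, 1] - oy) / p).astype(int)
    out = np.full(len(locs), "none", dtype=object)
    ok = (col >= 0) & (col < image_shape[1]) & (row >= 0) & (row < image_shape[0])
    out[ok] = class_map[row[ok], col[ok]]
    return out


def cbc_by_class(
    locs_a: LocalizationTable,
    objects: list[SegmentedObject],
    locs_b: LocalizationTable,
    image_shape: tuple[int, int],
    r_max_nm: float = DEFAULT_R_MAX_NM,
    n_radii: int = DEFAULT_N_RADII,
) -> dict[str, float]:
    """Mean CBC score grouped by the class of the containing object.

    Classes with zero assigned localizations are absent from the output.
    """
    result = cbc(locs_a, locs_b, r_max_nm, n_radii)
    labels = assign_to_objects(locs_a, objects, image_shape)
    out: dict[str, float] = {}
    for cls in ("pit", "plaque", "unclassified"):
        sel = labels == cls
        if sel.any():
            out[cls] = float(result.scores[sel].mean())
    return out
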