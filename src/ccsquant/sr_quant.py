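"""Rendering, segmentation and pit/plaque classification of SR scenes.

The morphometric rules implemented here operate on localization tables
rendered at 20 nm/pixel:

* a **pit** is a cluster with equivalent diameter in [100, 200] nm that
  is circular (circularity >= 0.7) or donut-shaped (>= 1 hole), and at
  least 2-fold brighter (localizations per pixel) than the scattered
  single-molecule background;
* a **plaque** is a cluster larger than 200 nm in every direction
  (minimum Feret diameter > 200 nm) whose brightness stays below the
  2-fold boundary;
* everything else is left unclassified.

Per-cell metrics are evaluated inside a peripheral band (default 3 um
wide) along the cell outline: pit density is the number of pits whose
centroid falls in the band divided by the band area, and the
plaque-covered area fraction is the plaque area intersected with the
band divided by the band area.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu
from skimage.measure import euler_number, label, perimeter, regionprops

from .errors import ComputationError, ParameterError
from .geometry import erode_polygon, max_feret, min_feret, rasterize_polygon
from .io_formats import CellOutline, LocalizationTable

DEFAULT_PIXEL_NM = 20.0


@dataclasses.dataclass
class RenderedImage:
    """Raster of localization mass; brightness = localizations per pixel."""

    pixels: np.ndarray
    pixel_size_nm: float = DEFAULT_PIXEL_NM
    origin_nm: tuple[float, float] = (0.0, 0.0)
    display_only: bool = False

    @property
    def total_mass(self) -> float:
        return float(self.pixels.sum())


@dataclasses.dataclass
class ClassifierParams:
    """Thresholds of the pit/plaque morphometric rules."""

    pit_diameter_min_nm: float = 100.0
    pit_diameter_max_nm: float = 200.0
    pit_brightness_ratio_min: float = 2.0
    pit_circularity_min: float = 0.7
    plaque_min_extent_nm: float = 200.0
    plaque_brightness_ratio_max: float = 2.0
    threshold: float | str = "auto"

    def __post_init__(self) -> None:
        if not (0 < self.pit_diameter_min_nm < self.pit_diameter_max_nm):
            raise ParameterError("pit diameter bounds must satisfy 0 < min < max")
        if self.pit_brightness_ratio_min <= 0 or self.plaque_brightness_ratio_max <= 0:
            raise ParameterError("brightness ratios must be > 0")


@dataclasses.dataclass
class SegmentedObject:
    """One connected cluster with its morphometrics and class label."""

    label: int
    pixels: np.ndarray  # (n, 2) array of (row, col)
    pixel_size_nm: float
    origin_nm: tuple[float, float]
    centroid_nm: tuple[float, float]
    area_um2: float
    perimeter_um: float
    circularity: float
    equivalent_diameter_nm: float
    feret_max_nm: float
    feret_min_nm: float
    hole_count: int
    mean_brightness: float
    brightness_ratio: float | None = None
    cls: str = "unclassified"

    @property
    def n_pixels(self) -> int:
        return len(self.pixels)


def render(
    table: LocalizationTable,
    pixel_size_nm: float = DEFAULT_PIXEL_NM,
    mode: str = "normalized_gaussian",
    bounds_nm: tuple[float, float, float, float] | None = None,
) -> RenderedImage:
    """Rasterize a localization table at ``pixel_size_nm`` (default 20).

    ``histogram`` drops each localization into its containing pixel;
    ``normalized_gaussian`` spreads each localization as a unit-integral
    2D Gaussian of sd equal to its uncertainty (falling back to one
    pixel when the uncertainty is absent), so total image mass equals
    the number of rendered localizations up to edge clipping. Image
    bounds default to the data bounding box plus a 3-sd margin; pass
    ``bounds_nm = (x0, y0, x1, y1)`` to fix the field explicitly.
    """
    if pixel_size_nm <= 0:
        raise ParameterError("pixel_size_nm must be > 0")
    if mode not in ("histogram", "normalized_gaussian"):
        raise ParameterError(f"unknown render mode {mode!r}")
    xy = table.xy if len(table) else np.empty((0, 2))
    sd = table.uncertainty_nm if len(table) else np.empty(0)
    sd = np.where(np.isfinite(sd) & (sd > 0), sd, pixel_size_nm)
    if bounds_nm is None:
        if len(xy) == 0:
            bounds_nm = (0.0, 0.0, pixel_size_nm, pixel_size_nm)
        else:
            margin = 3 * (sd.max() if mode == "normalized_gaussian" else 0) + pixel_size_nm
            bounds_nm = (
                xy[:, 0].min() - margin,
                xy[:, 1].min() - margin,
                xy[:, 0].max() + margin,
                xy[:, 1].max() + margin,
            )
    x0, y0, x1, y1 = bounds_nm
    x0 = np.floor(x0 / pixel_size_nm) * pixel_size_nm
    y0 = np.floor(y0 / pixel_size_nm) * pixel_size_nm
    w = max(int(np.ceil((x1 - x0) / pixel_size_nm)), 1)
    h = max(int(np.ceil((y1 - y0) / pixel_size_nm)), 1)
    img = np.zeros((h, w))
    if len(xy) == 0:
        return RenderedImage(img, pixel_size_nm, (x0, y0))
    if mode == "histogram":
        col = np.floor((xy[:, 0] - x0) / pixel_size_nm).astype(int)
        row = np.floor((xy[:, 1] - y0) / pixel_size_nm).astype(int)
        ok = (col >= 0) & (col < w) & (row >= 0) & (row < h)
        np.add.at(img, (row[ok], col[ok]), 1.0)
        return RenderedImage(img, pixel_size_nm, (x0, y0))
    # normalized_gaussian: per-axis integrated-Gaussian weights on a window
    from scipy.special import ndtr

    k = int(np.ceil(3 * sd.max() / pixel_size_nm)) + 1
    offs = np.arange(-k, k + 1)
    cx = (xy[:, 0] - x0) / pixel_size_nm
    cy = (xy[:, 1] - y0) / pixel_size_nm
    ix = np.floor(cx).astype(int)[:, None] + offs[None, :]
    iy = np.floor(cy).astype(int)[:, None] + offs[None, :]
    s = (sd / pixel_size_nm)[:, None]

    def axis_w(i, c):
        lo = (i - c[:, None]) / s
        hi = (i + 1 - c[:, None]) / s
        return ndtr(hi) - ndtr(lo)

    wx = axis_w(ix, cx)
    wy = axis_w(iy, cy)
    weights = wy[:, :, None] * wx[:, None, :]  # (n, ky, kx)
    rows = np.broadcast_to(iy[:, :, None], weights.shape)
    cols = np.broadcast_to(ix[:, None, :], weights.shape)
    ok = (rows >= 0) & (rows < h) & (cols >= 0) & (cols < w)
    np.add.at(img, (rows[ok], cols[ok]), weights[ok])
    return RenderedImage(img, pixel_size_nm, (x0, y0))


def display_filter(image: RenderedImage) -> RenderedImage:
    """3x3 uniform mean convolution (reflected edges) for display only."""
    smoothed = ndimage.uniform_filter(image.pixels, size=3, mode="reflect")
    return RenderedImage(smoothed, image.pixel_size_nm, image.origin_nm, display_only=True)


def estimate_background_brightness(
    image: RenderedImage, object_mask: np.ndarray | None = None
) -> float:
    """Mean of non-zero pixels outside segmented objects (0 when empty).

    The non-zero restriction targets the scattered single-molecule
    background: empty pixels carry no information about the brightness
    of an isolated localization.
    """
    px = image.pixels
    outside = px > 0
    if object_mask is not None:
        outside &= ~object_mask
    if not outside.any():
        return 0.0
    return float(px[outside].mean())


def auto_threshold(image: RenderedImage) -> float:
    """Otsu on the log1p-transformed rendered image, mapped back."""
    vals = np.log1p(image.pixels)
    if vals.max() == vals.min():
        return float(np.expm1(vals.max()))
    return float(np.expm1(threshold_otsu(vals)))


def segment(
    image: RenderedImage,
    params: ClassifierParams | None = None,
    brightness_image: RenderedImage | None = None,
) -> list[SegmentedObject]:
    """Binarize, label 8-connected components and fill morphometrics.

    Brightness statistics (localizations per pixel) are taken from
    ``brightness_image`` — typically a histogram render on the same grid
    — falling back to the segmented image itself. Objects smaller than
    2 pixels are discarded; a blank image yields an empty list.
    """
    params = params or ClassifierParams()
    if image.display_only:
        raise ParameterError("display-filtered images must not be quantified")
    thr = auto_threshold(image) if params.threshold == "auto" else float(params.threshold)
    binary = image.pixels > thr
    if not binary.any():
        return []
    labels = label(binary, connectivity=2)
    return objects_from_labels(labels, image, brightness_image)


#: objects whose initial equivalent diameter is below this are re-sized at
#: half-maximum to strip localization-precision broadening; larger objects
#: are insensitive to it and keep the global-threshold footprint.
HALF_MAX_REFINE_BELOW_NM = 400.0


def _half_max_refine(footprint: np.ndarray, pixels: np.ndarray) -> np.ndarray | None:
    """Largest component of the footprint above half its interior level.

    The interior level is the footprint's upper quartile: it sits on the
    plateau of a blurred compact object while resisting inflation by
    shot-noise maxima.
    """
    vals = pixels[footprint]
    peak = np.percentile(vals, 75)
    refined = footprint & (pixels > 0.5 * peak)
    if refined.sum() < 2:
        return None
    comps = label(refined, connectivity=2)
    sizes = np.bincount(comps.ravel())
    sizes[0] = 0
    best = comps == sizes.argmax()
    return best if best.sum() >= 2 else None


def objects_from_labels(
    labels: np.ndarray,
    image: RenderedImage,
    brightness_image: RenderedImage | None = None,
    refine_below_nm: float = HALF_MAX_REFINE_BELOW_NM,
) -> list[SegmentedObject]:
    """Morphometrics for every labelled component of ``labels``."""
    p = image.pixel_size_nm
    bright_px = (brightness_image or image).pixels
    out: list[SegmentedObject] = []
    for region in regionprops(labels):
        if region.area < 2:
            continue
        d_init = 2 * np.sqrt(region.area / np.pi) * p
        footprint = labels == region.label
        if d_init <= refine_below_nm:
            refined = _half_max_refine(footprint, image.pixels)
            if refined is not None:
                footprint = refined
        rows, cols = np.nonzero(footprint)
        coords = np.column_stack([rows, cols])
        area_px = float(len(coords))
        r0, r1 = rows.min(), rows.max() + 1
        c0, c1 = cols.min(), cols.max() + 1
        mask = footprint[r0:r1, c0:c1]
        per_px = perimeter(mask, neighborhood=4)
        circ = 4 * np.pi * area_px / per_px**2 if per_px > 0 else 1.0
        circ = min(circ, 1.05)
        holes = 1 - euler_number(mask, connectivity=2)
        # Feret diameters on pixel-corner points (pixel extent, not centres)
        corners = np.concatenate(
            [coords + [dr, dc] for dr in (0, 1) for dc in (0, 1)]
        ).astype(float)
        corners_nm = corners[:, ::-1] * p  # (x, y)
        weights = image.pixels[rows, cols]
        wsum = weights.sum()
        if wsum > 0:
            wr = (rows * weights).sum() / wsum
            wc = (cols * weights).sum() / wsum
        else:
            wr, wc = rows.mean(), cols.mean()
        centroid = (image.origin_nm[0] + (wc + 0.5) * p, image.origin_nm[1] + (wr + 0.5) * p)
        out.append(
            SegmentedObject(
                label=int(region.label),
                pixels=coords,
                pixel_size_nm=p,
                origin_nm=image.origin_nm,
                centroid_nm=centroid,
                area_um2=area_px * (p / 1000.0) ** 2,
                perimeter_um=per_px * p / 1000.0,
                circularity=float(circ),
                equivalent_diameter_nm=2 * np.sqrt(area_px / np.pi) * p,
                feret_max_nm=max_feret(corners_nm),
                feret_min_nm=min_feret(corners_nm),
                hole_count=int(max(holes, 0)),
                mean_brightness=float(bright_px[rows, cols].mean()),
            )
        )
    return out


def object_mask(objects: list[SegmentedObject], shape: tuple[int, int]) -> np.ndarray:
    mask = np.zeros(shape, dtype=bool)
    for obj in objects:
        mask[obj.pixels[:, 0], obj.pixels[:, 1]] = True
    return mask


def classify_object(obj: SegmentedObject, params: ClassifierParams) -> str:
    """Apply the pit/plaque rules; requires ``brightness_ratio`` to be set."""
    if obj.brightness_ratio is None:
        raise ComputationError("brightness_ratio unset: estimate the background first")
    d = obj.equivalent_diameter_nm
    pit_geom = (
        params.pit_diameter_min_nm <= d <= params.pit_diameter_max_nm
        and (obj.circularity >= params.pit_circularity_min or obj.hole_count >= 1)
    )
    if pit_geom and obj.brightness_ratio >= params.pit_brightness_ratio_min:
        return "pit"
    if (
        obj.feret_min_nm > params.plaque_min_extent_nm
        and obj.brightness_ratio < params.plaque_brightness_ratio_max
    ):
        return "plaque"
    return "unclassified"


def classify_objects(
    objects: list[SegmentedObject], background_brightness: float, params: ClassifierParams | None = None
) -> list[SegmentedObject]:
    """Set brightness ratios from the background estimate and label all objects."""
    params = params or ClassifierParams()
    for obj in objects:
        obj.brightness_ratio = (
            obj.mean_brightness / background_brightness if background_brightness > 0 else np.inf
        )
        obj.cls = classify_object(obj, params)
    return objects


def detect_embedded_pits(
    plaque_obj: SegmentedObject,
    image: RenderedImage,
    params: ClassifierParams,
    background_brightness: float,
    brightness_image: RenderedImage | None = None,
) -> tuple[list[SegmentedObject], SegmentedObject]:
    """Recover pits sitting on top of a plaque.

    The plaque footprint is re-thresholded at the pit brightness
    boundary (2x background); sub-components passing the pit geometric
    rules are returned as pits and their pixels are removed from the
    plaque, whose morphometrics are recomputed on the residual.
    Returns ``(pits, residual_plaque)``.
    """
    if plaque_obj.cls != "plaque":
        raise ParameterError("detect_embedded_pits expects a plaque object")
    foot = np.zeros(image.pixels.shape, dtype=bool)
    foot[plaque_obj.pixels[:, 0], plaque_obj.pixels[:, 1]] = True
    thr = params.pit_brightness_ratio_min * background_brightness
    sub = foot & (image.pixels > thr)
    pits: list[SegmentedObject] = []
    if sub.any():
        sub_labels = label(sub, connectivity=2)
        for cand in objects_from_labels(sub_labels, image, brightness_image):
            d = cand.equivalent_diameter_nm
            geom = (
                params.pit_diameter_min_nm <= d <= params.pit_diameter_max_nm
                and (cand.circularity >= params.pit_circularity_min or cand.hole_count >= 1)
            )
            if geom:
                cand.brightness_ratio = (
                    cand.mean_brightness / background_brightness
                    if background_brightness > 0
                    else np.inf
                )
                cand.cls = "pit"
                pits.append(cand)
    if not pits:
        return [], plaque_obj
    residual = foot.copy()
    for pit in pits:
        residual[pit.pixels[:, 0], pit.pixels[:, 1]] = False
    res_labels = label(residual, connectivity=2)
    res_objs = objects_from_labels(res_labels, image, brightness_image)
    if not res_objs:
        return pits, plaque_obj
    biggest = max(res_objs, key=lambda o: o.n_pixels)
    biggest.brightness_ratio = plaque_obj.brightness_ratio
    biggest.cls = "plaque"
    # sanity: recovered pit pixels and residual plaque pixels are disjoint
    pit_set = {tuple(px) for p_ in pits for px in p_.pixels}
    assert not pit_set & {tuple(px) for px in biggest.pixels}
    return pits, biggest


@dataclasses.dataclass
class RoiBand:
    """Peripheral band of the cell at the working raster."""

    outline: CellOutline
    width_um: float
    mask: np.ndarray
    pixel_size_nm: float
    origin_nm: tuple[float, float]

    @property
    def area_um2(self) -> float:
        return float(self.mask.sum()) * (self.pixel_size_nm / 1000.0) ** 2


def peripheral_roi(
    outline: CellOutline,
    width_um: float = 3.0,
    pixel_size_nm: float = DEFAULT_PIXEL_NM,
    shape: tuple[int, int] | None = None,
    origin_nm: tuple[float, float] = (0.0, 0.0),
) -> RoiBand:
    """Band of ``width_um`` (default 3) inside the cell edge, rasterized.

    When the inward erosion empties the cell the band degrades to the
    entire cell, with a warning.
    """
    if width_um <= 0:
        raise ParameterError("band width must be > 0")
    poly = outline.polygon
    if shape is None:
        _, _, maxx, maxy = poly.bounds
        shape = (
            int(np.ceil((maxy - origin_nm[1]) / pixel_size_nm)) + 1,
            int(np.ceil((maxx - origin_nm[0]) / pixel_size_nm)) + 1,
        )
    cell_mask = rasterize_polygon(poly, shape, pixel_size_nm, origin_nm)
    inner = erode_polygon(poly, width_um * 1000.0)
    if inner is None:
        warnings.warn("band width exceeds the cell inradius; using the whole cell")
        band_mask = cell_mask
    else:
        band_mask = cell_mask & ~rasterize_polygon(inner, shape, pixel_size_nm, origin_nm)
    return RoiBand(outline, width_um, band_mask, pixel_size_nm, origin_nm)


@dataclasses.dataclass
class CcsMetrics:
    """Per-cell summary inside the peripheral ROI."""

    n_pits: int
    pit_density_per_um2: float
    n_plaques: int
    plaque_area_fraction: float
    roi_area_um2: float


def ccs_metrics(objects: list[SegmentedObject], roi: RoiBand) -> CcsMetrics:
    """Pit density and plaque-covered area fraction inside the ROI.

    A pit counts iff its centroid lies in the ROI; a plaque contributes
    the area of its intersection with the ROI.
    """
    area = roi.area_um2
    if area <= 0:
        raise ComputationError("ROI has zero area")
    h, w = roi.mask.shape
    p = roi.pixel_size_nm
    n_pits = 0
    n_plaques = 0
    plaque_px_in = 0
    for obj in objects:
        dr = int(round((obj.origin_nm[1] - roi.origin_nm[1]) / p))
        dc = int(round((obj.origin_nm[0] - roi.origin_nm[0]) / p))
        if obj.cls == "pit":
            col = int((obj.centroid_nm[0] - roi.origin_nm[0]) / p)
            row = int((obj.centroid_nm[1] - roi.origin_nm[1]) / p)
            if 0 <= row < h and 0 <= col < w and roi.mask[row, col]:
                n_pits += 1
        elif obj.cls == "plaque":
            rows = obj.pixels[:, 0] + dr
            cols = obj.pixels[:, 1] + dc
            ok = (rows >= 0) & (rows < h) & (cols >= 0) & (cols < w)
            inside = roi.mask[rows[ok], cols[ok]].sum()
            if inside:
                n_plaques += 1
                plaque_px_in += int(inside)
    return CcsMetrics(
        n_pits=n_pits,
        pit_density_per_um2=n_pits / area,
        n_plaques=n_plaques,
        plaque_area_fraction=plaque_px_in * (p / 1000.0) ** 2 / area,
        roi_area_um2=area,
    )


def analyze_scene(
    table: LocalizationTable,
    outline: CellOutline | None = None,
    params: ClassifierParams | None = None,
    pixel_size_nm: float = DEFAULT_PIXEL_NM,
    mode: str = "normalized_gaussian",
    bounds_nm: tuple[float, float, float, float] | None = None,
    band_width_um: float = 3.0,
) -> dict:
    """Full SR pipeline: render -> segment -> classify -> ROI metrics.

    Without an outline the ROI defaults to the entire rendered field.
    Returns a dict with the rendered image, background estimate,
    classified objects (embedded pits split out of plaques) and metrics.
    """
    params = params or ClassifierParams()
    image = render(table, pixel_size_nm, mode, bounds_nm)
    if mode == "histogram":
        hist = image
    else:  # brightness (localizations/pixel) is counted, not density-estimated
        hist = render(table, pixel_size_nm, "histogram", bounds_nm=(
            image.origin_nm[0], image.origin_nm[1],
            image.origin_nm[0] + image.pixels.shape[1] * pixel_size_nm,
            image.origin_nm[1] + image.pixels.shape[0] * pixel_size_nm,
        ))
    objects = segment(image, params, brightness_image=hist)
    bg = estimate_background_brightness(hist, object_mask(objects, image.pixels.shape))
    objects = classify_objects(objects, bg, params)
    final: list[SegmentedObject] = []
    for obj in objects:
        if obj.cls == "plaque":
            pits, residual = detect_embedded_pits(obj, image, params, bg, hist)
            final.extend(pits)
            final.append(residual)
        else:
            final.append(obj)
    if outline is not None:
        roi = peripheral_roi(outline, band_width_um, pixel_size_nm,
                             shape=image.pixels.shape, origin_nm=image.origin_nm)
    else:
        full = RoiBand(
            outline=None, width_um=np.inf, mask=np.ones(image.pixels.shape, dtype=bool),
            pixel_size_nm=pixel_size_nm, origin_nm=image.origin_nm,
        )
        roi = full
    metrics = ccs_metrics(final, roi)
    return {
        "image": image,
        "background_brightness": bg,
        "objects": final,
        "roi": roi,
        "metrics": metrics,
    }
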