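"""Membrane-translocation biosensor analysis (PIP3 reporter).

A PH-domain biosensor redistributes from the cytoplasm to the plasma
membrane when PIP3 is produced. The readout is the ratio of mean
intensity in a peripheral membrane band to mean intensity in the
remaining cytoplasm, per frame. Because human "blind scoring" of
responsive cells is not reproducible, responsiveness here is an explicit
statistical criterion: a cell responds iff its ratio exceeds
baseline mean + k * baseline sd for a minimum number of consecutive
post-stimulus frames (defaults k=3, 2 frames).
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
from skimage.filters import threshold_otsu

from .errors import ComputationError, ParameterError
from .geometry import erode_polygon, rasterize_polygon
from .io_formats import CellOutline, MovieStack


def membrane_cytoplasm_masks(
    outline: CellOutline,
    band_width_um: float,
    pixel_size_nm: float,
    shape: tuple[int, int],
    origin_nm: tuple[float, float] = (0.0, 0.0),
) -> tuple[np.ndarray, np.ndarray]:
    """Split the cell into a peripheral membrane band and the cytoplasm.

    The two masks are disjoint and jointly exhaustive of the cell mask.
    A band consuming the entire cell is an error (the ratio would be
    undefined).
    """
    if band_width_um <= 0:
        raise ParameterError("band width must be > 0")
    poly = outline.polygon
    cell = rasterize_polygon(poly, shape, pixel_size_nm, origin_nm)
    inner = erode_polygon(poly, band_width_um * 1000.0)
    if inner is None:
        raise ParameterError("membrane band consumes the whole cell; reduce the width")
    cyto = rasterize_polygon(inner, shape, pixel_size_nm, origin_nm) & cell
    if not cyto.any():
        raise ParameterError("membrane band consumes the whole cell; reduce the width")
    membrane = cell & ~cyto
    return membrane, cyto


@dataclasses.dataclass
class TranslocationTrace:
    """Membrane/cytoplasm ratio over time for one cell."""

    time_s: np.ndarray
    ratio: np.ndarray  # NaN where undefined
    baseline_frames: np.ndarray
    responsive: bool | None = None


def mc_ratio_trace(
    movie: MovieStack,
    membrane_mask: np.ndarray,
    cytoplasm_mask: np.ndarray,
    baseline_frames,
) -> TranslocationTrace:
    """Per-frame membrane/cytoplasm intensity ratio.

    Each frame is background-subtracted (mean of sub-Otsu pixels; a
    uniform frame has background 0) before the two mask means are
    ratioed. Non-positive cytoplasm means give missing values with a
    warning. The ratio is invariant to global multiplicative scaling of
    a frame.
    """
    baseline_frames = np.asarray(baseline_frames, dtype=int)
    if baseline_frames.size == 0:
        raise ParameterError("baseline_frames must be non-empty")
    if membrane_mask.shape != movie.shape[1:] or cytoplasm_mask.shape != movie.shape[1:]:
        raise ParameterError("mask shape does not match the movie field")
    ratio = np.full(movie.n_frames, np.nan)
    for t in range(movie.n_frames):
        frame = movie.data[t].astype(float)
        if frame.max() > frame.min():
            thr = threshold_otsu(frame)
            below = frame <= thr
            bg = float(frame[below].mean()) if below.any() else 0.0
        else:
            bg = 0.0
        m = (frame - bg)[membrane_mask].mean()
        c = (frame - bg)[cytoplasm_mask].mean()
        if c <= 0:
            warnings.warn(f"frame {t}: non-positive cytoplasm mean; ratio missing")
            continue
        ratio[t] = m / c
    return TranslocationTrace(movie.times_s, ratio, baseline_frames)


def score_responsive(
    traces: list[TranslocationTrace], k_sd: float = 3.0, min_consecutive: int = 2
) -> tuple[float, list[bool]]:
    """Fraction of cells whose ratio rises significantly after stimulation.

    A trace is responsive iff its ratio exceeds
    ``baseline mean + k_sd * baseline sd`` for at least
    ``min_consecutive`` consecutive post-baseline frames. A degenerate
    (zero-sd) baseline falls back to an absolute tolerance of 1e-6.
    """
    if min_consecutive < 1:
        raise ParameterError("min_consecutive must be >= 1")
    flags: list[bool] = []
    for trace in traces:
        base = trace.ratio[trace.baseline_frames]
        base = base[np.isfinite(base)]
        if len(base) < 3:
            raise ParameterError("each trace needs >= 3 valid baseline frames")
        sd = base.std()
        if sd == 0:
            warnings.warn("degenerate baseline (sd=0); using absolute tolerance 1e-6")
            thr = base.mean() + 1e-6
        else:
            thr = base.mean() + k_sd * sd
        post_start = int(trace.baseline_frames.max()) + 1
        post = trace.ratio[post_start:]
        above = np.isfinite(post) & (post > thr)
        run = 0
        hit = False
        for a in above:
            run = run + 1 if a else 0
            if run >= min_consecutive:
                hit = True
                break
        trace.responsive = hit
        flags.append(hit)
    if not flags:
        raise ComputationError("no traces supplied")
    return float(np.mean(flags)), flags
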