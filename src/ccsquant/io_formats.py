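"""Readers/writers and shared coordinate conventions.

Conventions used throughout the package:

* continuous coordinates are in nanometres, origin at the top-left corner
  of the field, x rightward, y downward;
* raster pixel ``i`` covers the half-open interval ``[i*p, (i+1)*p)`` nm;
* frames are 0-based and time is ``frame * frame_interval_s``.

Localization tables are delimited text in one of two dialects:

``thunderstorm``
    The public default export schema of the ThunderSTORM ImageJ plugin:
    ``"x [nm]", "y [nm]", "frame"`` mandatory, ``"intensity [photon]"``
    and ``"uncertainty [nm]"`` optional.
``generic``
    Explicit-unit column names: ``x_nm, y_nm, frame`` mandatory,
    ``intensity, uncertainty_nm, channel`` optional.

Unknown extra columns are carried along opaquely and survive a
write/read round trip.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import tifffile
import yaml
from shapely.geometry import Polygon
from shapely.geometry.polygon import orient

from .errors import ConfigurationError, FormatError, InputError, ParameterError

#: canonical internal column order
CANONICAL_COLUMNS = ["x_nm", "y_nm", "frame", "intensity", "uncertainty_nm", "channel"]

_DIALECTS = {
    "thunderstorm": {
        "x_nm": "x [nm]",
        "y_nm": "y [nm]",
        "frame": "frame",
        "intensity": "intensity [photon]",
        "uncertainty_nm": "uncertainty [nm]",
        "channel": "channel",
    },
    "generic": {c: c for c in CANONICAL_COLUMNS},
}
_MANDATORY = ["x_nm", "y_nm", "frame"]


@dataclasses.dataclass
class LocalizationTable:
    """A set of fitted single-molecule positions.

    Wraps a :class:`pandas.DataFrame` with canonical columns
    ``x_nm, y_nm, frame, intensity, uncertainty_nm, channel`` (plus any
    extra columns preserved from the source file). All consumers treat
    the table as an unordered set: row order never affects results.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.data
        for col, default in (("intensity", 1.0), ("uncertainty_nm", np.nan), ("channel", 0)):
            if col not in df.columns:
                df[col] = default
        for col in ("x_nm", "y_nm"):
            vals = np.asarray(df[col], dtype=float)
            if not np.all(np.isfinite(vals)):
                raise FormatError(f"non-finite values in column {col!r}")
            df[col] = vals
        frames = np.asarray(df["frame"])
        if len(frames) and (np.any(frames < 0) or np.any(frames != np.floor(frames))):
            raise FormatError("frame indices must be non-negative integers")
        df["frame"] = frames.astype(np.int64) if len(frames) else df["frame"].astype(np.int64)
        unc = np.asarray(df["uncertainty_nm"], dtype=float)
        if np.any(unc[np.isfinite(unc)] <= 0):
            raise FormatError("uncertainty_nm must be > 0 where present")

    def __len__(self) -> int:
        return len(self.data)

    @property
    def xy(self) -> np.ndarray:
        """(n, 2) array of coordinates in nm."""
        return self.data[["x_nm", "y_nm"]].to_numpy(dtype=float)

    @property
    def uncertainty_nm(self) -> np.ndarray:
        return self.data["uncertainty_nm"].to_numpy(dtype=float)

    @property
    def channel(self) -> np.ndarray:
        return self.data["channel"].to_numpy()

    def select_channel(self, channel) -> "LocalizationTable":
        return LocalizationTable(
            self.data[self.data["channel"] == channel].reset_index(drop=True).copy()
        )

    @classmethod
    def from_arrays(
        cls,
        x_nm: Sequence[float],
        y_nm: Sequence[float],
        frame: Sequence[int] | int = 0,
        intensity: Sequence[float] | float = 1.0,
        uncertainty_nm: Sequence[float] | float = np.nan,
        channel: Sequence[int] | int = 0,
    ) -> "LocalizationTable":
        n = len(np.atleast_1d(x_nm))
        df = pd.DataFrame(
            {
                "x_nm": np.asarray(x_nm, dtype=float),
                "y_nm": np.asarray(y_nm, dtype=float),
                "frame": np.broadcast_to(np.asarray(frame), n).copy(),
                "intensity": np.broadcast_to(np.asarray(intensity, dtype=float), n).copy(),
                "uncertainty_nm": np.broadcast_to(
                    np.asarray(uncertainty_nm, dtype=float), n
                ).copy(),
                "channel": np.broadcast_to(np.asarray(channel), n).copy(),
            }
        )
        return cls(df)

    @classmethod
    def empty(cls) -> "LocalizationTable":
        return cls.from_arrays(np.empty(0), np.empty(0), np.empty(0, dtype=int))

    def equals(self, other: "LocalizationTable", atol_nm: float = 0.0) -> bool:
        a = self.data[CANONICAL_COLUMNS]
        b = other.data[CANONICAL_COLUMNS]
        if len(a) != len(b):
            return False
        if len(a) == 0:
            return True
        num = ["x_nm", "y_nm", "intensity", "uncertainty_nm"]
        close = np.allclose(a[num], b[num], atol=atol_nm, rtol=0, equal_nan=True)
        return close and (a["frame"] == b["frame"]).all() and (a["channel"] == b["channel"]).all()


def read_localizations(path, dialect: str = "thunderstorm", sep: str = ",") -> LocalizationTable:
    """Read a delimited-text localization table.

    Units are normalized to nm; a missing uncertainty column yields
    absent (NaN) uncertainties and a missing channel column defaults to
    channel 0. Row count is preserved.
    """
    path = Path(path)
    if dialect not in _DIALECTS:
        raise ParameterError(f"unknown dialect {dialect!r}")
    if not path.exists():
        raise InputError(f"no such file: {path}")
    try:
        raw = pd.read_csv(path, sep=sep)
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise FormatError(f"cannot parse {path}: {exc}") from exc
    mapping = _DIALECTS[dialect]
    for key in _MANDATORY:
        if mapping[key] not in raw.columns:
            raise FormatError(
                f"{path}: missing mandatory column {mapping[key]!r} for dialect {dialect!r}"
            )
    rename = {v: k for k, v in mapping.items() if v in raw.columns}
    df = raw.rename(columns=rename)
    for col in ("x_nm", "y_nm", "intensity", "uncertainty_nm"):
        if col in df.columns:
            coerced = pd.to_numeric(df[col], errors="coerce")
            bad = coerced.isna() & df[col].notna()
            if bad.any():
                row = int(np.flatnonzero(bad.to_numpy())[0])
                raise FormatError(
                    f"{path}: non-numeric value in column {col!r} at data row {row}"
                )
            df[col] = coerced
    return LocalizationTable(df)


def write_localizations(
    table: LocalizationTable, path, dialect: str = "thunderstorm", sep: str = ","
) -> None:
    """Write ``table`` so that :func:`read_localizations` recovers it."""
    if dialect not in _DIALECTS:
        raise ParameterError(f"unknown dialect {dialect!r}")
    mapping = _DIALECTS[dialect]
    df = table.data.rename(columns=mapping)
    ordered = [mapping[c] for c in CANONICAL_COLUMNS] + [
        c for c in df.columns if c not in mapping.values()
    ]
    try:
        df[ordered].to_csv(path, sep=sep, index=False)
    except OSError as exc:
        raise InputError(f"cannot write {path}: {exc}") from exc


@dataclasses.dataclass
class MovieStack:
    """A single-channel time-lapse stack (T, H, W) with calibration."""

    data: np.ndarray
    frame_interval_s: float
    pixel_size_nm: float
    channel: str = "0"

    def __post_init__(self) -> None:
        arr = np.asarray(self.data)
        if arr.ndim == 2:
            arr = arr[None]
        if arr.ndim != 3 or arr.shape[0] < 1:
            raise ParameterError("movie data must be (T, H, W) with T >= 1")
        if not (self.frame_interval_s > 0):
            raise ConfigurationError("frame_interval_s must be > 0")
        if not (self.pixel_size_nm > 0):
            raise ConfigurationError("pixel_size_nm must be > 0")
        if not np.all(np.isfinite(arr)):
            raise FormatError("movie intensities must be finite")
        if arr.min() < 0:
            raise FormatError("movie intensities must be >= 0")
        self.data = arr

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def shape(self):
        return self.data.shape

    @property
    def times_s(self) -> np.ndarray:
        return np.arange(self.n_frames) * self.frame_interval_s


def write_movie(stack: MovieStack, path) -> None:
    """Write a multi-page grayscale TIFF; calibration goes in the description tag."""
    meta = {
        "frame_interval_s": stack.frame_interval_s,
        "pixel_size_nm": stack.pixel_size_nm,
        "channel": stack.channel,
    }
    tifffile.imwrite(
        path, stack.data, description=json.dumps(meta), photometric="minisblack"
    )


def read_movie(path, frame_interval_s: float | None = None, pixel_size_nm: float | None = None) -> MovieStack:
    """Read a multi-page TIFF as a :class:`MovieStack`.

    Calibration is taken from the JSON description tag when present;
    otherwise the caller must supply it.
    """
    path = Path(path)
    if not path.exists():
        raise InputError(f"no such file: {path}")
    try:
        with tifffile.TiffFile(path) as tif:
            arr = tif.asarray()
            desc = tif.pages[0].description
    except Exception as exc:
        raise InputError(f"cannot read TIFF {path}: {exc}") from exc
    meta = {}
    if desc:
        try:
            meta = json.loads(desc)
        except (json.JSONDecodeError, TypeError):
            meta = {}
    fi = frame_interval_s if frame_interval_s is not None else meta.get("frame_interval_s")
    px = pixel_size_nm if pixel_size_nm is not None else meta.get("pixel_size_nm")
    if fi is None or px is None:
        raise ConfigurationError(
            f"{path}: no calibration in metadata; supply frame_interval_s and pixel_size_nm"
        )
    if arr.ndim == 2:
        arr = arr[None]
    return MovieStack(arr, float(fi), float(px), str(meta.get("channel", "0")))


@dataclasses.dataclass
class CellOutline:
    """A closed, simple cell-boundary polygon in nm (counter-clockwise)."""

    vertices_nm: np.ndarray

    def __post_init__(self) -> None:
        verts = np.asarray(self.vertices_nm, dtype=float)
        if verts.ndim != 2 or verts.shape[1] != 2 or verts.shape[0] < 3:
            raise ParameterError("outline needs >= 3 (x, y) vertices")
        poly = Polygon(verts)
        if not poly.is_valid:
            raise ParameterError("outline polygon is self-intersecting or degenerate")
        if poly.area <= 0:
            raise ParameterError("outline polygon has non-positive area")
        poly = orient(poly, sign=1.0)  # fix winding CCW
        self.vertices_nm = np.asarray(poly.exterior.coords)[:-1]

    @property
    def polygon(self) -> Polygon:
        return Polygon(self.vertices_nm)

    @property
    def area_um2(self) -> float:
        return self.polygon.area / 1e6


def write_outline(outline: CellOutline, path) -> None:
    with open(path, "w") as fh:
        json.dump({"vertices_nm": outline.vertices_nm.tolist()}, fh)


def read_outline(path) -> CellOutline:
    path = Path(path)
    if not path.exists():
        raise InputError(f"no such file: {path}")
    with open(path) as fh:
        obj = json.load(fh)
    if "vertices_nm" not in obj:
        raise FormatError(f"{path}: ROI JSON must contain 'vertices_nm'")
    return CellOutline(np.asarray(obj["vertices_nm"], dtype=float))


def load_config(path) -> dict:
    """Load a YAML or JSON run-configuration file into a plain dict."""
    path = Path(path)
    if not path.exists():
        raise InputError(f"no such file: {path}")
    text = path.read_text()
    try:
        if path.suffix.lower() == ".json":
            return json.loads(text)
        return yaml.safe_load(text) or {}
    except Exception as exc:
        raise FormatError(f"cannot parse config {path}: {exc}") from exc


def save_config(config: dict, path) -> None:
    path = Path(path)
    if path.suffix.lower() == ".json":
        path.write_text(json.dumps(config, indent=2, sort_keys=True))
    else:
        path.write_text(yaml.safe_dump(config, sort_keys=True))
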