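"""Reading and writing angiograms, FAZ polygons, sidecar metadata and metric tables.

Coordinate convention used throughout the package: the image origin sits at the
*center* of the top-left pixel, x runs rightward along columns, y downward along
rows, both in millimetres.  A pixel is an ``mm_per_pixel`` x ``mm_per_pixel``
square, so pixel (row i, col j) has its center at ``(j * mm_per_pixel,
i * mm_per_pixel)`` and areas are pixel counts times ``mm_per_pixel ** 2``.
Polygons (FAZ outlines) live in the same physical frame.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile
from shapely.geometry import Polygon as _ShapelyPolygon

__all__ = [
    "EnFaceAngiogram",
    "FazPolygon",
    "MetricRecord",
    "read_angiogram",
    "write_angiogram",
    "read_faz_polygon",
    "write_faz_polygon",
    "write_metrics",
    "read_metrics",
    "METRIC_COLUMNS",
]

#: default physical scale of a 3x3 mm scan sampled on a 245x245 grid
DEFAULT_MM_PER_PIXEL = 3.0 / 245.0

_PLEXUS_VALUES = ("SCP", "DCP")


@dataclass
class EnFaceAngiogram:
    """One plexus' en-face angiogram: intensity grid plus scan metadata.

    ``intensities`` is a float array normalized to [0, 1]; ``signal_strength``
    is the device quality score on a 0-10 scale (scans below 7 are considered
    poor quality downstream).
    """

    intensities: np.ndarray
    mm_per_pixel: float = DEFAULT_MM_PER_PIXEL
    plexus: str = "SCP"
    signal_strength: float = 10.0
    participant_id: str = ""
    eye: str = ""

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.intensities.ndim != 2:
            raise ValueError("intensities must be a 2-D grid")
        h, w = self.intensities.shape
        if h < 32 or w < 32:
            raise ValueError(f"image too small ({h}x{w}); need at least 32x32")
        if not np.all(np.isfinite(self.intensities)):
            raise ValueError("intensities must be finite")
        if np.any(self.intensities < 0):
            raise ValueError("intensities must be nonnegative")
        if not self.mm_per_pixel > 0:
            raise ValueError("mm_per_pixel must be positive")
        if self.plexus not in _PLEXUS_VALUES:
            raise ValueError(f"plexus must be one of {_PLEXUS_VALUES}, got {self.plexus!r}")
        if not 0.0 <= float(self.signal_strength) <= 10.0:
            raise ValueError("signal_strength must lie in [0, 10]")

    @property
    def shape(self) -> tuple[int, int]:
        return self.intensities.shape

    @property
    def field_mm(self) -> tuple[float, float]:
        """Physical (height, width) of the imaged field in mm."""
        h, w = self.intensities.shape
        return (h * self.mm_per_pixel, w * self.mm_per_pixel)


@dataclass
class FazPolygon:
    """Foveal avascular zone outline as an ordered (x_mm, y_mm) vertex list."""

    vertices: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.vertices, dtype=float)
        if v.ndim != 2 or v.shape[1] != 2:
            raise ValueError("vertices must be an (n, 2) array of (x_mm, y_mm)")
        if len(v) < 3:
            raise ValueError(f"polygon needs at least 3 vertices, got {len(v)}")
        if not np.all(np.isfinite(v)):
            raise ValueError("polygon vertices must be finite")
        poly = _ShapelyPolygon(v)
        if not poly.is_simple:
            raise ValueError("polygon must be simple (non-self-intersecting)")
        if poly.area <= 0:
            raise ValueError("polygon must have positive area")
        self.vertices = v

    def shapely(self) -> _ShapelyPolygon:
        return _ShapelyPolygon(self.vertices)

    @property
    def area_mm2(self) -> float:
        return float(self.shapely().area)

    @property
    def centroid(self) -> tuple[float, float]:
        c = self.shapely().centroid
        return (float(c.x), float(c.y))


#: stable column order for metric tables
METRIC_COLUMNS = [
    "participant_id",
    "eye",
    "vd_scp",
    "vd_dcp",
    "fd_scp",
    "fd_dcp",
    "pd_large_scp",
    "faz_area_scp",
    "faz_area_dcp",
    "signal_strength_scp",
    "signal_strength_dcp",
]


@dataclass
class MetricRecord:
    """Per-eye OCTA outcome metrics.

    vd_* are skeleton length densities in mm/mm^2, fd_* dimensionless
    box-counting dimensions, pd_large_scp a percentage of region area,
    faz_area_* in mm^2.  Fields for an absent plexus are None.
    """

    participant_id: str = ""
    eye: str = ""
    vd_scp: float | None = None
    vd_dcp: float | None = None
    fd_scp: float | None = None
    fd_dcp: float | None = None
    pd_large_scp: float | None = None
    faz_area_scp: float | None = None
    faz_area_dcp: float | None = None
    signal_strength_scp: float | None = None
    signal_strength_dcp: float | None = None

    def __post_init__(self) -> None:
        for name in ("vd_scp", "vd_dcp", "faz_area_scp", "faz_area_dcp"):
            v = getattr(self, name)
            if v is not None and v < 0:
                raise ValueError(f"{name} must be nonnegative, got {v}")
        if self.pd_large_scp is not None and not 0 <= self.pd_large_scp <= 100:
            raise ValueError("pd_large_scp must lie in [0, 100]")

    def as_dict(self) -> dict:
        return {k: getattr(self, k) for k in METRIC_COLUMNS}


# ---------------------------------------------------------------------------
# images + sidecars

_SIDECAR_REQUIRED = ("mm_per_pixel", "plexus", "signal_strength")


def _normalize(raw: np.ndarray) -> np.ndarray:
    """Map raw pixel values onto [0, 1] preserving order.

    Integer images divide by their dtype maximum so 8- and 16-bit encodings of
    the same scene agree to quantization error; float images are assumed to be
    already on a [0, 1]-like scale and are clipped.
    """
    if np.issubdtype(raw.dtype, np.integer):
        return raw.astype(float) / float(np.iinfo(raw.dtype).max)
    out = raw.astype(float)
    if out.size and out.max() > 1.0:
        out = out / out.max()
    return np.clip(out, 0.0, 1.0)


def read_angiogram(image_path: str | Path, sidecar_path: str | Path) -> EnFaceAngiogram:
    """Read a grayscale angiogram (TIFF/PNG) and its JSON metadata sidecar."""
    image_path, sidecar_path = Path(image_path), Path(sidecar_path)
    with open(sidecar_path) as fh:
        meta = json.load(fh)
    for key in _SIDECAR_REQUIRED:
        if key not in meta:
            raise ValueError(f"sidecar {sidecar_path} is missing required field {key!r}")
    mmpp = meta["mm_per_pixel"]
    if isinstance(mmpp, (list, tuple)):
        if len(mmpp) != 2 or not np.isclose(mmpp[0], mmpp[1]):
            raise ValueError(f"non-square pixels are not supported: mm_per_pixel={mmpp}")
        mmpp = mmpp[0]
    if image_path.suffix.lower() in (".tif", ".tiff"):
        raw = tifffile.imread(image_path)
    else:
        raw = iio.imread(image_path)
    raw = np.asarray(raw)
    if raw.ndim == 3:  # grayscale stored with a channel axis
        raw = raw[..., 0]
    return EnFaceAngiogram(
        intensities=_normalize(raw),
        mm_per_pixel=float(mmpp),
        plexus=str(meta["plexus"]),
        signal_strength=float(meta["signal_strength"]),
        participant_id=str(meta.get("participant_id", "")),
        eye=str(meta.get("eye", "")),
    )


def write_angiogram(
    angiogram: EnFaceAngiogram,
    image_path: str | Path,
    sidecar_path: str | Path | None = None,
    bit_depth: int = 16,
) -> None:
    """Write an angiogram as 8- or 16-bit grayscale TIFF/PNG plus JSON sidecar."""
    image_path = Path(image_path)
    if bit_depth == 16:
        arr = np.round(np.clip(angiogram.intensities, 0, 1) * 65535).astype(np.uint16)
    elif bit_depth == 8:
        arr = np.round(np.clip(angiogram.intensities, 0, 1) * 255).astype(np.uint8)
    else:
        raise ValueError("bit_depth must be 8 or 16")
    if image_path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(image_path, arr)
    else:
        iio.imwrite(image_path, arr)
    if sidecar_path is None:
        sidecar_path = image_path.with_suffix(".json")
    meta = {
        "mm_per_pixel": angiogram.mm_per_pixel,
        "plexus": angiogram.plexus,
        "signal_strength": angiogram.signal_strength,
        "participant_id": angiogram.participant_id,
        "eye": angiogram.eye,
    }
    with open(sidecar_path, "w") as fh:
        json.dump(meta, fh, indent=1)


# ---------------------------------------------------------------------------
# polygons


def read_faz_polygon(path: str | Path) -> FazPolygon:
    """Read a FAZ outline from a two-column (x_mm, y_mm) CSV.

    A single header line is tolerated; vertex order is preserved and validated
    (at least 3 vertices, simple, positive area).
    """
    df = pd.read_csv(path, header=None, comment="#")
    if df.shape[1] != 2:
        raise ValueError(f"expected 2 columns of coordinates, got {df.shape[1]}")
    # drop a header row if the first line is not numeric
    first = pd.to_numeric(df.iloc[0], errors="coerce")
    if first.isna().any():
        df = df.iloc[1:]
    coords = df.apply(pd.to_numeric, axis=0).to_numpy(dtype=float)
    if np.isnan(coords).any():
        raise ValueError(f"non-numeric vertex data in {path}")
    return FazPolygon(coords)


def write_faz_polygon(polygon: FazPolygon, path: str | Path) -> None:
    pd.DataFrame(polygon.vertices, columns=["x_mm", "y_mm"]).to_csv(path, index=False, header=False)


# ---------------------------------------------------------------------------
# metric tables


def write_metrics(records: Sequence[MetricRecord], path: str | Path) -> None:
    """Write per-eye metric records as CSV (or JSON if the suffix is .json).

    Column order is stable (METRIC_COLUMNS); an empty record list produces a
    header-only CSV.
    """
    path = Path(path)
    rows = [r.as_dict() for r in records]
    df = pd.DataFrame(rows, columns=METRIC_COLUMNS)
    if path.suffix.lower() == ".json":
        df.to_json(path, orient="records", indent=1)
    else:
        df.to_csv(path, index=False)


def read_metrics(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    if path.suffix.lower() == ".json":
        df = pd.read_json(path, orient="records")
        if df.empty:
            df = pd.DataFrame(columns=METRIC_COLUMNS)
        return df[METRIC_COLUMNS]
    return pd.read_csv(path)
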