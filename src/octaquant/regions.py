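"""Region construction and the per-eye outcome metrics.

The region of measurement is a fovea-centered annulus (inner diameter 1 mm,
outer diameter 2.5 mm by default) with the manually outlined foveal avascular
zone (FAZ) masked out.  Within that region the pipeline computes vessel
density (skeleton length per area, mm/mm^2), perfusion density of large
vessels (% of region area), and box-counting fractal dimension; FAZ area is
reported from the polygon itself.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import shapely

from .io import EnFaceAngiogram, FazPolygon, MetricRecord
from .vessels import (
    BinaryVesselMask,
    SkeletonMap,
    binarize,
    detect_large_vessels,
    skeletonize,
)

__all__ = [
    "AnnulusSpec",
    "MeasurementRegion",
    "annulus_mask",
    "faz_center",
    "faz_area",
    "faz_raster",
    "measurement_region",
    "vessel_density",
    "large_vessel_perfusion_density",
    "fractal_dimension_boxcount",
    "compute_metric_record",
]

logger = logging.getLogger(__name__)


@dataclass
class AnnulusSpec:
    """Fovea-centered ring: 1 mm inner and 2.5 mm outer diameter by default."""

    center: tuple[float, float]
    inner_radius_mm: float = 0.5
    outer_radius_mm: float = 1.25

    def __post_init__(self) -> None:
        if not 0 < self.inner_radius_mm < self.outer_radius_mm:
            raise ValueError(
                f"need 0 < inner < outer radius, got {self.inner_radius_mm}, {self.outer_radius_mm}"
            )


@dataclass
class MeasurementRegion:
    """Annulus minus FAZ interior, as a pixel mask with its physical area."""

    mask: np.ndarray
    area_mm2: float
    mm_per_pixel: float

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.area_mm2 <= 0:
            raise ValueError("measurement region must have positive area")


def _pixel_centers(grid_shape: tuple[int, int], mm_per_pixel: float):
    h, w = grid_shape
    y = np.arange(h) * mm_per_pixel
    x = np.arange(w) * mm_per_pixel
    return np.meshgrid(x, y)  # xx, yy


def annulus_mask(
    spec: AnnulusSpec, grid_shape: tuple[int, int], mm_per_pixel: float
) -> np.ndarray:
    """Rasterize the annulus: pixel included iff its center lies in
    [inner_radius, outer_radius) of the annulus center."""
    h, w = grid_shape
    cx, cy = spec.center
    half = 0.5 * mm_per_pixel
    if (
        cx - spec.outer_radius_mm < -half
        or cy - spec.outer_radius_mm < -half
        or cx + spec.outer_radius_mm > (w - 0.5) * mm_per_pixel
        or cy + spec.outer_radius_mm > (h - 0.5) * mm_per_pixel
    ):
        raise ValueError("annulus does not fit inside the imaged field")
    xx, yy = _pixel_centers(grid_shape, mm_per_pixel)
    r = np.hypot(xx - cx, yy - cy)
    return (r >= spec.inner_radius_mm) & (r < spec.outer_radius_mm)


def faz_center(polygon: FazPolygon) -> tuple[float, float]:
    """Area centroid of the FAZ outline (anchors the measurement annulus)."""
    return polygon.centroid


def faz_area(polygon: FazPolygon) -> float:
    """Absolute (shoelace) area of the FAZ outline in mm^2."""
    return polygon.area_mm2


def faz_raster(
    polygon: FazPolygon, grid_shape: tuple[int, int], mm_per_pixel: float
) -> np.ndarray:
    """Pixels whose centers lie inside the FAZ polygon."""
    xx, yy = _pixel_centers(grid_shape, mm_per_pixel)
    shp = polygon.shapely()
    return shapely.contains_xy(shp, xx.ravel(), yy.ravel()).reshape(grid_shape)


def measurement_region(
    annulus: np.ndarray,
    polygon: FazPolygon | None,
    mm_per_pixel: float,
) -> MeasurementRegion:
    """Annulus pixels minus the FAZ interior.

    With no polygon supplied the region is the bare annulus (a warning is
    logged, since an unmasked FAZ biases density measurements downward).
    """
    annulus = np.asarray(annulus, dtype=bool)
    if polygon is None:
        logger.warning("no FAZ polygon supplied; measurement region equals the annulus")
        mask = annulus
    else:
        mask = annulus & ~faz_raster(polygon, annulus.shape, mm_per_pixel)
    area = float(mask.sum()) * mm_per_pixel**2
    if area <= 0:
        raise ValueError("measurement region is empty")
    return MeasurementRegion(mask=mask, area_mm2=area, mm_per_pixel=mm_per_pixel)


def vessel_density(skeleton: SkeletonMap, region: MeasurementRegion) -> float:
    """Vessel density: in-region skeleton length (mm) per region area (mm^2)."""
    from .vessels import estimate_skeleton_length

    if skeleton.skeleton.shape != region.mask.shape:
        raise ValueError("skeleton and region shapes differ")
    restricted = skeleton.skeleton & region.mask
    length = estimate_skeleton_length(restricted, region.mm_per_pixel)
    return length / region.area_mm2


def large_vessel_perfusion_density(
    large_mask: BinaryVesselMask | np.ndarray, region: MeasurementRegion
) -> float:
    """Large-vessel perfusion density: % of region pixels that are large vessel."""
    m = large_mask.mask if isinstance(large_mask, BinaryVesselMask) else np.asarray(large_mask, bool)
    if m.shape != region.mask.shape:
        raise ValueError("mask and region shapes differ")
    n_region = int(region.mask.sum())
    if n_region == 0:
        raise ValueError("measurement region is empty")
    return 100.0 * int((m & region.mask).sum()) / n_region


def fractal_dimension_boxcount(
    mask: BinaryVesselMask | np.ndarray,
    region: MeasurementRegion | np.ndarray | None = None,
    min_box_px: int = 2,
    max_box_divisor: int = 4,
) -> float:
    """Box-counting fractal dimension (Dbox) of in-region vessel foreground.

    Boxes of side s (powers of two from ``min_box_px`` up to
    ``min(H, W) // max_box_divisor``) are laid on an axis-aligned grid anchored
    at the region's bounding-box corner; a box counts when it contains at
    least one in-region foreground pixel.  Dbox is the OLS slope of
    log N(s) against log(1/s).
    """
    m = mask.mask if isinstance(mask, BinaryVesselMask) else np.asarray(mask, bool)
    if region is not None:
        rmask = region.mask if isinstance(region, MeasurementRegion) else np.asarray(region, bool)
        fg = m & rmask
    else:
        fg = m
    if not fg.any():
        raise ValueError("no in-region foreground: fractal dimension undefined")

    rows, cols = np.nonzero(fg)
    r0, c0 = rows.min(), cols.min()
    rows = rows - r0
    cols = cols - c0
    h, w = m.shape

    sizes = []
    s = min_box_px
    smax = min(h, w) // max_box_divisor
    while s <= smax:
        sizes.append(s)
        s *= 2
    if len(sizes) < 2:
        raise ValueError("image too small for the box-size ladder")

    counts = []
    for s in sizes:
        boxes = {(int(r), int(c)) for r, c in zip(rows // s, cols // s)}
        counts.append(len(boxes))
    slope = np.polyfit(np.log(1.0 / np.asarray(sizes, float)), np.log(counts), 1)[0]
    return float(slope)


def compute_metric_record(
    scp_image: EnFaceAngiogram | None,
    dcp_image: EnFaceAngiogram | None = None,
    scp_faz: FazPolygon | None = None,
    dcp_faz: FazPolygon | None = None,
    inner_radius_mm: float = 0.5,
    outer_radius_mm: float = 1.25,
    capillary_only_vd: bool = False,
    binarize_kwargs: dict | None = None,
) -> MetricRecord:
    """Run the full post-processing chain on one eye's plexus images.

    Each plexus gets its own annulus centered on its own FAZ centroid (the FAZ
    of the deep plexus is considerably larger than the superficial one).
    Large-vessel perfusion density is computed for the SCP only.  Missing
    images leave their fields None.  ``capillary_only_vd`` subtracts the
    detected large-vessel mask from the skeleton substrate before measuring
    vessel density on the SCP.
    """
    if scp_image is None and dcp_image is None:
        raise ValueError("at least one plexus image is required")
    bk = binarize_kwargs or {}
    rec: dict = {}

    for label, img, poly in (("scp", scp_image, scp_faz), ("dcp", dcp_image, dcp_faz)):
        if img is None:
            continue
        mmpp = img.mm_per_pixel
        h, w = img.shape
        if poly is not None:
            center = faz_center(poly)
            rec[f"faz_area_{label}"] = faz_area(poly)
        else:
            center = ((w - 1) / 2 * mmpp, (h - 1) / 2 * mmpp)
        spec = AnnulusSpec(center, inner_radius_mm, outer_radius_mm)
        ann = annulus_mask(spec, (h, w), mmpp)
        region = measurement_region(ann, poly, mmpp)

        vessel_mask = binarize(img, **bk)
        substrate = vessel_mask.mask
        if label == "scp":
            large = detect_large_vessels(img)
            rec["pd_large_scp"] = large_vessel_perfusion_density(large, region)
            if capillary_only_vd:
                substrate = substrate & ~large.mask
        skel = skeletonize(substrate, mm_per_pixel=mmpp)
        rec[f"vd_{label}"] = vessel_density(skel, region)
        rec[f"fd_{label}"] = fractal_dimension_boxcount(vessel_mask, region)
        rec[f"signal_strength_{label}"] = img.signal_strength

    pid = (scp_image or dcp_image).participant_id
    eye = (scp_image or dcp_image).eye
    return MetricRecord(participant_id=pid, eye=eye, **rec)
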