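"""Synthetic en-face angiograms and cohorts with known ground truth.

Angiogram scenes emulate what the image pipeline consumes: a handful of
branching-free large vessels (smooth random-walk tubes, 30-80 um wide),
a capillary mesh (jittered square lattice of short 1-2 px segments), a
central avascular zone free of vessels, Gaussian blur and speckle-like
additive noise.  Every scene carries exhaustive truth: the binary vessel and
large-vessel masks, the rasterized centerlines, the analytic centerline
length, and the FAZ outline polygon.

Cohort tables emulate the statistical structure of a three-group (AD / MCI /
control) case-control study: per-group covariate distributions, additive
group offsets on each OCTA metric, linear covariate effects, and Gaussian
residual noise; the generating coefficients are returned alongside so
downstream estimators can be checked against truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
import shapely
from skimage.draw import line as _draw_line

from .io import DEFAULT_MM_PER_PIXEL, EnFaceAngiogram, FazPolygon

__all__ = [
    "AngioSceneParams",
    "AngiogramTruth",
    "CohortParams",
    "generate_vessel_network",
    "generate_scene_pair",
    "generate_cohort",
    "generate_enrollment",
    "METRIC_NAMES",
    "GROUPS",
]

GROUPS = ("AD", "MCI", "control")

METRIC_NAMES = (
    "vd_scp",
    "vd_dcp",
    "fd_scp",
    "fd_dcp",
    "pd_large_scp",
    "faz_area_scp",
    "faz_area_dcp",
)


# ---------------------------------------------------------------------------
# angiogram scenes


@dataclass
class AngioSceneParams:
    """Parameters of one synthetic en-face angiogram scene.

    ``capillary_density`` is the target capillary skeleton length per unit
    area (mm/mm^2) over the full field; ``faz_area_mm2`` defaults to the
    superficial-plexus magnitude (0.31 mm^2); use ~1.11 mm^2 for deep-plexus
    scenes.  ``noise_sd`` is the additive Gaussian noise scale on the [0, 1]
    intensity image and maps monotonically onto the signal-strength metadata.
    """

    field_mm: float = 3.0
    grid_px: int = 245
    n_large_vessels: int = 3
    large_width_um: tuple[float, float] = (30.0, 80.0)
    capillary_density: float = 15.0
    faz_area_mm2: float = 0.31
    noise_sd: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.field_mm > 0:
            raise ValueError("field_mm must be positive")
        if self.grid_px < 32:
            raise ValueError("grid_px must be at least 32")
        if self.n_large_vessels < 0:
            raise ValueError("n_large_vessels must be nonnegative")
        if self.capillary_density < 0:
            raise ValueError("capillary_density must be nonnegative")
        if self.faz_area_mm2 < 0:
            raise ValueError("faz_area_mm2 must be nonnegative")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")
        wmin_px = self.large_width_um[0] / 1000.0 / self.mm_per_pixel
        wmax_px = self.large_width_um[1] / 1000.0 / self.mm_per_pixel
        if self.n_large_vessels > 0 and (wmax_px > self.grid_px / 8 or wmin_px < 0.8):
            raise ValueError(
                f"grid too small to render requested vessel widths "
                f"({self.large_width_um} um maps to {wmin_px:.2f}-{wmax_px:.2f} px "
                f"on a {self.grid_px} px grid)"
            )

    @property
    def mm_per_pixel(self) -> float:
        return self.field_mm / self.grid_px


@dataclass
class AngiogramTruth:
    """A rendered scene plus everything needed to verify the pipeline on it."""

    image: EnFaceAngiogram
    vessel_mask: np.ndarray
    large_vessel_mask: np.ndarray
    centerline_mask: np.ndarray
    skeleton_length_mm: float
    large_length_mm: float
    capillary_length_mm: float
    faz_polygon: FazPolygon
    params: AngioSceneParams


def _faz_polygon(params: AngioSceneParams, rng: np.random.Generator) -> FazPolygon:
    """Irregular ellipse-like FAZ outline with exactly the target polygon area."""
    n = 64
    c = params.field_mm / 2.0
    cx = c + rng.uniform(-0.03, 0.03)
    cy = c + rng.uniform(-0.03, 0.03)
    ratio = rng.uniform(0.75, 0.95)
    theta = rng.uniform(0, np.pi)
    area = max(params.faz_area_mm2, 1e-6)
    a = np.sqrt(area / (np.pi * ratio))
    b = ratio * a
    phi = np.linspace(0, 2 * np.pi, n, endpoint=False)
    wobble = 1.0 + 0.06 * np.sin(3 * phi + rng.uniform(0, 2 * np.pi))
    ex = a * np.cos(phi) * wobble
    ey = b * np.sin(phi) * wobble
    ct, st = np.cos(theta), np.sin(theta)
    x = cx + ct * ex - st * ey
    y = cy + st * ex + ct * ey
    poly = FazPolygon(np.column_stack([x, y]))
    # rescale about the centroid so the shoelace area matches exactly
    scale = np.sqrt(area / poly.area_mm2)
    gx, gy = poly.centroid
    v = poly.vertices.copy()
    v[:, 0] = gx + (v[:, 0] - gx) * scale
    v[:, 1] = gy + (v[:, 1] - gy) * scale
    return FazPolygon(v)


def _segment_distance_mask(
    shape: tuple[int, int], p0: np.ndarray, p1: np.ndarray, radius: float
) -> tuple[slice, slice, np.ndarray]:
    """Pixels within ``radius`` of segment p0-p1 (px coords, row/col), cropped."""
    h, w = shape
    rmin = max(int(np.floor(min(p0[0], p1[0]) - radius - 1)), 0)
    rmax = min(int(np.ceil(max(p0[0], p1[0]) + radius + 1)), h - 1)
    cmin = max(int(np.floor(min(p0[1], p1[1]) - radius - 1)), 0)
    cmax = min(int(np.ceil(max(p0[1], p1[1]) + radius + 1)), w - 1)
    if rmin > rmax or cmin > cmax:
        return slice(0, 0), slice(0, 0), np.zeros((0, 0), bool)
    rr, cc = np.mgrid[rmin : rmax + 1, cmin : cmax + 1]
    d = p1 - p0
    L2 = float(d @ d)
    if L2 == 0:
        dist = np.hypot(rr - p0[0], cc - p0[1])
    else:
        t = np.clip(((rr - p0[0]) * d[0] + (cc - p0[1]) * d[1]) / L2, 0.0, 1.0)
        dist = np.hypot(rr - (p0[0] + t * d[0]), cc - (p0[1] + t * d[1]))
    return slice(rmin, rmax + 1), slice(cmin, cmax + 1), dist <= radius


def _walk_large_vessel(
    params: AngioSceneParams,
    rng: np.random.Generator,
    avoid_center_px: np.ndarray,
    avoid_radius_px: float,
) -> np.ndarray:
    """Smooth random-walk centerline crossing the field, steered off the FAZ.

    Returns an (n, 2) float array of (row, col) pixel coordinates; the walk
    starts on one edge heading inward and ends where it leaves the field.
    """
    n = params.grid_px
    side = rng.integers(0, 4)
    u = rng.uniform(0.15, 0.85) * (n - 1)
    if side == 0:  # top, heading down
        pos, ang = np.array([0.0, u]), np.pi / 2
    elif side == 1:  # bottom, heading up
        pos, ang = np.array([float(n - 1), u]), -np.pi / 2
    elif side == 2:  # left, heading right
        pos, ang = np.array([u, 0.0]), 0.0
    else:  # right, heading left
        pos, ang = np.array([u, float(n - 1)]), np.pi
    ang += rng.uniform(-0.35, 0.35)

    step = 2.0
    pts = [pos.copy()]
    for _ in range(4 * n):
        ang += rng.normal(0.0, 0.10)
        d = np.array([np.sin(ang), np.cos(ang)])  # (row, col) step
        nxt = pos + step * d
        rel = nxt - avoid_center_px
        dist = np.linalg.norm(rel)
        if dist < avoid_radius_px:
            # steer radially outward until the step clears the avoidance disk
            out = rel / max(dist, 1e-9)
            d = d + 1.5 * out
            d = d / np.linalg.norm(d)
            nxt = pos + step * d
            ang = np.arctan2(d[0], d[1])
        if not (0 <= nxt[0] <= n - 1 and 0 <= nxt[1] <= n - 1):
            # clip the final step to the field boundary
            t_best = 1.0
            for axis in (0, 1):
                for bound in (0.0, float(n - 1)):
                    denom = nxt[axis] - pos[axis]
                    if abs(denom) > 1e-12:
                        t = (bound - pos[axis]) / denom
                        if 0 <= t < t_best:
                            cand = pos + t * (nxt - pos)
                            if -1e-9 <= cand[0] <= n - 1 + 1e-9 and -1e-9 <= cand[1] <= n - 1 + 1e-9:
                                t_best = t
            end = pos + t_best * (nxt - pos)
            if np.linalg.norm(end - pos) > 1e-6:
                pts.append(end)
            break
        pos = nxt
        pts.append(pos.copy())
    return np.array(pts)


def _polyline_length_px(pts: np.ndarray) -> float:
    if len(pts) < 2:
        return 0.0
    return float(np.sum(np.linalg.norm(np.diff(pts, axis=0), axis=1)))


def _draw_polyline(mask: np.ndarray, pts: np.ndarray) -> None:
    for p0, p1 in zip(pts[:-1], pts[1:]):
        rr, cc = _draw_line(
            int(round(p0[0])), int(round(p0[1])), int(round(p1[0])), int(round(p1[1]))
        )
        ok = (rr >= 0) & (rr < mask.shape[0]) & (cc >= 0) & (cc < mask.shape[1])
        mask[rr[ok], cc[ok]] = True


def _capillary_mesh(
    params: AngioSceneParams,
    rng: np.random.Generator,
    faz_shape: shapely.Geometry,
    large_mask: np.ndarray,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Jittered square-lattice capillary mesh avoiding the FAZ and large vessels.

    Returns (capillary mask, capillary centerline mask, analytic length in mm).
    Lattice spacing is chosen so the expected skeleton length per area matches
    ``capillary_density``; edges run along the lattice axes with occasional
    diagonals, each drawn 1 px wide (a random quarter are thickened to 2 px).
    """
    n = params.grid_px
    mmpp = params.mm_per_pixel
    mask = np.zeros((n, n), bool)
    lines = np.zeros((n, n), bool)
    if params.capillary_density <= 0:
        return mask, lines, 0.0

    p_diag = 0.15
    density_px = params.capillary_density * mmpp  # length(px) per px^2
    d = (2.0 + p_diag * np.sqrt(2.0)) / density_px
    jitter = 0.1 * d

    ni = int(np.ceil(n / d)) + 2
    base = np.arange(ni) * d - d / 2
    nodes = np.empty((ni, ni, 2))
    nodes[..., 0] = base[:, None] + rng.uniform(-jitter, jitter, (ni, ni))
    nodes[..., 1] = base[None, :] + rng.uniform(-jitter, jitter, (ni, ni))

    segments: list[tuple[np.ndarray, np.ndarray]] = []
    for i in range(ni):
        for j in range(ni):
            a = nodes[i, j]
            if i + 1 < ni:
                segments.append((a, nodes[i + 1, j]))
            if j + 1 < ni:
                segments.append((a, nodes[i, j + 1]))
            if i + 1 < ni and j + 1 < ni and rng.random() < p_diag:
                if rng.random() < 0.5:
                    segments.append((a, nodes[i + 1, j + 1]))
                else:
                    segments.append((nodes[i, j + 1], nodes[i + 1, j]))

    # large vessels blocked out with a 1 px margin
    if large_mask.any():
        from scipy import ndimage as ndi

        blocked = ndi.binary_dilation(large_mask, iterations=2)
    else:
        blocked = large_mask

    # buffer by ~2 px so rounded Bresenham pixels cannot land inside the FAZ
    avoid = faz_shape.buffer(2.0 * mmpp)
    shapely.prepare(avoid)
    total_px = 0.0
    for a, b in segments:
        # clip both endpoints to the field
        if not (0 <= a[0] <= n - 1 and 0 <= a[1] <= n - 1):
            continue
        if not (0 <= b[0] <= n - 1 and 0 <= b[1] <= n - 1):
            continue
        ar, ac = int(round(a[0])), int(round(a[1]))
        br, bc = int(round(b[0])), int(round(b[1]))
        # sample points along the segment for the exclusion tests
        ts = np.linspace(0, 1, 5)
        sr = a[0] + ts * (b[0] - a[0])
        sc = a[1] + ts * (b[1] - a[1])
        x_mm = sc * mmpp
        y_mm = sr * mmpp
        if shapely.contains_xy(avoid, x_mm, y_mm).any():
            continue
        if blocked[np.round(sr).astype(int), np.round(sc).astype(int)].any():
            continue
        rr, cc = _draw_line(ar, ac, br, bc)
        lines[rr, cc] = True
        # render as a thin tube with a *physical* radius (9 or 13.5 um,
        # i.e. ~1 or ~2 px at the native 12.2 um/px sampling) so scenes scale
        # consistently with grid resolution; the floor of 0.72 px keeps
        # obliquely oriented capillaries from under-rendering to a dim,
        # diagonally-connected Bresenham chain.
        radius_um = 13.5 if rng.random() < 0.25 else 9.0
        radius = max(radius_um / 1000.0 / mmpp, 0.72)
        rs, cs, hit = _segment_distance_mask(
            (n, n), np.array([float(ar), float(ac)]), np.array([float(br), float(bc)]), radius
        )
        mask[rs, cs] |= hit
        total_px += float(np.hypot(br - ar, bc - ac))
    return mask, lines, total_px * mmpp


def generate_vessel_network(params: AngioSceneParams) -> AngiogramTruth:
    """Render one synthetic en-face angiogram with exhaustive ground truth.

    Deterministic per seed: identical parameters give bitwise-identical
    scenes.  The FAZ interior contains no vessel pixels by construction, and
    ``skeleton_length_mm`` is the analytic length of the generating
    centerlines (large vessels plus capillary segments).
    """
    rng = np.random.default_rng(params.seed)
    n = params.grid_px
    mmpp = params.mm_per_pixel

    faz = _faz_polygon(params, rng)
    faz_shape = faz.shapely()
    cx, cy = faz.centroid
    faz_center_px = np.array([cy / mmpp, cx / mmpp])  # (row, col)
    faz_reach_px = (
        np.max(np.hypot(faz.vertices[:, 0] - cx, faz.vertices[:, 1] - cy)) / mmpp
    )

    large_mask = np.zeros((n, n), bool)
    large_lines = np.zeros((n, n), bool)
    large_len_mm = 0.0
    wmin, wmax = params.large_width_um
    for _ in range(params.n_large_vessels):
        w_px = rng.uniform(wmin, wmax) / 1000.0 / mmpp
        avoid = faz_reach_px + w_px / 2 + 2.0
        pts = _walk_large_vessel(params, rng, faz_center_px, avoid)
        if len(pts) < 2:
            continue
        radius = w_px / 2.0
        for p0, p1 in zip(pts[:-1], pts[1:]):
            rs, cs, hit = _segment_distance_mask((n, n), p0, p1, radius)
            large_mask[rs, cs] |= hit
        _draw_polyline(large_lines, pts)
        large_len_mm += _polyline_length_px(pts) * mmpp

    cap_mask, cap_lines, cap_len_mm = _capillary_mesh(params, rng, faz_shape, large_mask)

    vessel_mask = large_mask | cap_mask
    centerlines = large_lines | cap_lines

    # render intensities: bright vessels on a dark background
    img = np.full((n, n), 0.12)
    img[cap_mask] = 0.80
    img[large_mask] = 1.00
    from scipy import ndimage as ndi

    img = ndi.gaussian_filter(img, 0.5, mode="nearest")
    if params.noise_sd > 0:
        img = img + rng.normal(0.0, params.noise_sd, img.shape)
    img = np.clip(img, 0.0, 1.0)

    signal_strength = float(np.clip(round(10.0 - 30.0 * params.noise_sd, 1), 0.0, 10.0))
    plexus = "SCP" if params.n_large_vessels > 0 else "DCP"
    angiogram = EnFaceAngiogram(
        intensities=img,
        mm_per_pixel=mmpp,
        plexus=plexus,
        signal_strength=signal_strength,
    )
    return AngiogramTruth(
        image=angiogram,
        vessel_mask=vessel_mask,
        large_vessel_mask=large_mask,
        centerline_mask=centerlines,
        skeleton_length_mm=large_len_mm + cap_len_mm,
        large_length_mm=large_len_mm,
        capillary_length_mm=cap_len_mm,
        faz_polygon=faz,
        params=params,
    )


def generate_scene_pair(
    seed: int,
    scp_params: AngioSceneParams | None = None,
    dcp_params: AngioSceneParams | None = None,
) -> tuple[AngiogramTruth, AngiogramTruth]:
    """One eye's SCP + DCP scene pair.

    The deep plexus is rendered as an independent mesh-only scene (no large
    vessels) with a larger avascular zone, denser mesh, mirroring how the two
    plexuses differ anatomically.
    """
    if scp_params is None:
        scp_params = AngioSceneParams(seed=seed)
    if dcp_params is None:
        dcp_params = AngioSceneParams(
            n_large_vessels=0, capillary_density=21.0, faz_area_mm2=1.11, seed=seed + 1_000_000
        )
    scp = generate_vessel_network(scp_params)
    dcp = generate_vessel_network(dcp_params)
    dcp.image.plexus = "DCP"
    return scp, dcp


# ---------------------------------------------------------------------------
# cohorts


def _default_covariates() -> dict:
    # per-group moments of the emulated case-control study population
    return {
        "age_mean": {"AD": 74.9, "MCI": 77.9, "control": 76.7},
        "age_sd": {"AD": 6.0, "MCI": 6.4, "control": 5.3},
        "frac_female": {"AD": 0.73, "MCI": 0.44, "control": 0.45},
        "frac_chinese": {"AD": 0.84, "MCI": 0.82, "control": 0.79},
        "diabetes_prev": {"AD": 0.41, "MCI": 0.32, "control": 0.14},
        "sbp_mean": {"AD": 148.0, "MCI": 139.0, "control": 131.0},
        "sbp_sd": {"AD": 11.0, "MCI": 18.0, "control": 16.0},
        "dbp_mean": {"AD": 73.0, "MCI": 70.0, "control": 70.0},
        "dbp_sd": {"AD": 9.0, "MCI": 9.0, "control": 8.0},
        "signal_strength_mean": {"AD": 9.8, "MCI": 9.8, "control": 9.6},
        "signal_strength_sd": {"AD": 0.8, "MCI": 0.5, "control": 0.7},
    }


def _default_baseline() -> dict:
    # control-group metric levels
    return {
        "vd_scp": 15.66,
        "vd_dcp": 21.54,
        "fd_scp": 1.861,
        "fd_dcp": 1.879,
        "pd_large_scp": 6.92,
        "faz_area_scp": 0.31,
        "faz_area_dcp": 1.11,
    }


def _default_effects() -> dict:
    # additive group offsets vs control per metric
    return {
        "vd_scp": {"MCI": -0.72, "AD": -0.88},
        "vd_dcp": {"MCI": -0.73, "AD": -1.12},
        "fd_scp": {"MCI": -0.011, "AD": -0.008},
        "fd_dcp": {"MCI": -0.003, "AD": -0.004},
        "pd_large_scp": {"MCI": -0.53, "AD": 0.10},
        "faz_area_scp": {"MCI": 0.041, "AD": 0.034},
        "faz_area_dcp": {"MCI": 0.129, "AD": 0.016},
    }


def _default_residual_sd() -> dict:
    return {
        "vd_scp": 0.96,
        "vd_dcp": 1.55,
        "fd_scp": 0.010,
        "fd_dcp": 0.013,
        "pd_large_scp": 1.16,
        "faz_area_scp": 0.12,
        "faz_area_dcp": 0.47,
    }


def _default_covariate_coefs() -> dict:
    """Linear covariate effects on each metric (per unit of centered covariate).

    Small plausible magnitudes: densities fall slightly with age and systolic
    pressure, rise with scan signal strength; diabetes depresses densities.
    The fractal dimension moves an order of magnitude less, matching its
    scale.  These only need to be non-zero so covariate adjustment is
    genuinely exercised.
    """
    dens = {"age": -0.03, "signal_strength": 0.40, "sbp": -0.006, "diabetes": -0.20}
    fd = {"age": -0.0004, "signal_strength": 0.004, "sbp": -0.00006, "diabetes": -0.002}
    faz = {"age": 0.002, "signal_strength": 0.0, "sbp": 0.0, "diabetes": 0.0}
    return {
        "vd_scp": dict(dens),
        "vd_dcp": dict(dens),
        "fd_scp": dict(fd),
        "fd_dcp": dict(fd),
        "pd_large_scp": dict(dens),
        "faz_area_scp": dict(faz),
        "faz_area_dcp": dict(faz),
    }


#: covariate centering used by the generator (roughly the pooled sample means)
_COVARIATE_CENTER = {"age": 76.8, "signal_strength": 9.7, "sbp": 138.5, "diabetes": 0.0}


@dataclass
class CohortParams:
    """Generating parameters of a synthetic three-group cohort."""

    n_per_group: Mapping[str, int] = field(
        default_factory=lambda: {"AD": 24, "MCI": 37, "control": 29}
    )
    covariates: dict = field(default_factory=_default_covariates)
    baseline: dict = field(default_factory=_default_baseline)
    group_effects: dict = field(default_factory=_default_effects)
    residual_sd: dict = field(default_factory=_default_residual_sd)
    covariate_coefs: dict = field(default_factory=_default_covariate_coefs)
    seed: int = 0

    def __post_init__(self) -> None:
        for g, n in self.n_per_group.items():
            if g not in GROUPS:
                raise ValueError(f"unknown group {g!r}")
            if n <= 0:
                raise ValueError(f"n_per_group[{g!r}] must be positive, got {n}")
        for key in ("frac_female", "frac_chinese", "diabetes_prev"):
            for g, p in self.covariates[key].items():
                if not 0 <= p <= 1:
                    raise ValueError(f"{key}[{g!r}] = {p} is not a probability")
        for m, sd in self.residual_sd.items():
            if sd <= 0:
                raise ValueError(f"residual_sd[{m!r}] must be positive")
        for m, offs in self.group_effects.items():
            if offs.get("control", 0.0) != 0.0:
                raise ValueError(f"control offset for {m!r} must be 0")


def generate_cohort(params: CohortParams) -> tuple[pd.DataFrame, dict]:
    """Simulate a cohort table plus the record of its true generating effects.

    Each participant row carries group membership, covariates (age, female,
    chinese, diabetes, sbp, dbp, signal_strength) and every OCTA metric,
    built as control baseline + group offset + centered linear covariate
    terms + Gaussian noise.  Returns ``(table, truth)`` where ``truth`` holds
    the generating offsets, covariate coefficients and residual scales.
    """
    rng = np.random.default_rng(params.seed)
    cov = params.covariates
    rows = []
    pid = 0
    for g in GROUPS:
        ng = params.n_per_group.get(g, 0)
        for _ in range(ng):
            pid += 1
            age = rng.normal(cov["age_mean"][g], cov["age_sd"][g])
            female = int(rng.random() < cov["frac_female"][g])
            chinese = int(rng.random() < cov["frac_chinese"][g])
            diabetes = int(rng.random() < cov["diabetes_prev"][g])
            sbp = rng.normal(cov["sbp_mean"][g], cov["sbp_sd"][g])
            dbp = rng.normal(cov["dbp_mean"][g], cov["dbp_sd"][g])
            ss = float(
                np.clip(rng.normal(cov["signal_strength_mean"][g], cov["signal_strength_sd"][g]), 0, 10)
            )
            row = {
                "participant_id": f"P{pid:04d}",
                "group": g,
                "age": age,
                "female": female,
                "chinese": chinese,
                "diabetes": diabetes,
                "sbp": sbp,
                "dbp": dbp,
                "signal_strength": ss,
            }
            covvals = {"age": age, "signal_strength": ss, "sbp": sbp, "diabetes": diabetes}
            for m in METRIC_NAMES:
                mu = params.baseline[m] + params.group_effects[m].get(g, 0.0)
                for cname, coef in params.covariate_coefs[m].items():
                    mu += coef * (covvals[cname] - _COVARIATE_CENTER[cname])
                row[m] = mu + rng.normal(0.0, params.residual_sd[m])
            rows.append(row)
    table = pd.DataFrame(rows)
    truth = {
        "group_effects": params.group_effects,
        "covariate_coefs": params.covariate_coefs,
        "residual_sd": params.residual_sd,
        "baseline": params.baseline,
    }
    return table, truth


def generate_enrollment(
    n_fatigue: int = 15,
    n_poor_quality: int = 53,
    n_eye_disease: int = 7,
    n_clean: int = 90,
    seed: int = 0,
    quality_threshold: float = 7.0,
) -> pd.DataFrame:
    """Simulate an enrollment roster with per-participant exclusion flags.

    Excluded-for-quality participants get both eyes below the signal-strength
    threshold; clean participants get at least one good eye.  The roster is
    shuffled so exclusion reasons are not ordered.
    """
    rng = np.random.default_rng(seed)
    rows = []
    counts = [
        ("fatigue", n_fatigue),
        ("quality", n_poor_quality),
        ("eye_disease", n_eye_disease),
        ("clean", n_clean),
    ]
    pid = 0
    for kind, n in counts:
        for _ in range(n):
            pid += 1
            if kind == "quality":
                ss_od = rng.uniform(3.0, quality_threshold - 0.5)
                ss_os = rng.uniform(3.0, quality_threshold - 0.5)
            else:
                ss_od = rng.uniform(quality_threshold, 10.0)
                ss_os = rng.uniform(5.0, 10.0)
            rows.append(
                {
                    "participant_id": f"E{pid:04d}",
                    "fatigue": kind == "fatigue",
                    "eye_disease": kind == "eye_disease",
                    "signal_strength_od": round(ss_od, 1),
                    "signal_strength_os": round(ss_os, 1),
                }
            )
    df = pd.DataFrame(rows)
    return df.sample(frac=1.0, random_state=int(rng.integers(2**31))).reset_index(drop=True)
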