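"""Contour completion and airway morphometry.

Per-ray wall fits are turned into closed inner and outer contours (one vertex
per ray, ordered by angle) and the four airway metrics:

TD
    total (outer) diameter -- mean distance between antipodal outer points,
    or the equivalent-circle diameter of the outer polygon.
LA
    lumen area -- shoelace area of the inner polygon.
WA
    wall area -- outer polygon area minus LA.
WT
    wall thickness -- median of (outer - inner) border distance over rays
    with a trusted measurement; completed rays never contribute to WT.

Rays without a trusted fit get their inner point completed in one of two
ways.  The *standard* rule fits a least-squares ellipse through the measured
inner points and intersects each missing ray with it.  The *modified* rule
takes the median attenuation at the measured inner points and walks each
missing ray outward from the lumen centre to the first position reaching that
median; near a bright vessel this keeps the lumen border at the true wall
instead of letting the smeared contrast drag it inward.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from skimage.measure import EllipseModel

from .image_io import HUImage, sample_points
from .radial_profiles import RayProfile, cast_profiles
from .wall_detection import (
    IBMConfig,
    WallFit,
    _DiscTable,
    _pooled_profile,
    auto_wall_hu,
    classify_validity,
    estimate_levels,
    fit_pooled_wall,
    fwhm_edges,
    inner_only_fit,
    integral_fit,
)

__all__ = [
    "Contour",
    "AirwayMeasurement",
    "complete_inner_standard",
    "complete_inner_modified",
    "complete_outer",
    "compute_metrics",
    "measure_airway",
    "ALGORITHMS",
]

ALGORITHMS = ("fwhm", "standard_ibm", "modified_ibm")

#: minimum number of measured points for a conic (ellipse) fit
_MIN_ELLIPSE_POINTS = 5


@dataclass
class Contour:
    """Closed polygon with one vertex per ray, ordered by ray angle."""

    points: np.ndarray  # (n_rays, 2) physical mm
    source: list[str]  # measured | ellipse_completed | medianhu_completed | offset_completed
    flags: list[str] = field(default_factory=list)

    def radii(self, center: tuple[float, float]) -> np.ndarray:
        return np.hypot(self.points[:, 0] - center[0], self.points[:, 1] - center[1])


@dataclass
class AirwayMeasurement:
    """The four airway metrics plus provenance."""

    TD_mm: float
    LA_mm2: float
    WA_mm2: float
    WT_mm: float
    algorithm: str
    n_valid_rays: int
    center_mm: tuple[float, float]
    flags: list[str] = field(default_factory=list)


def _polygon_area(points: np.ndarray) -> float:
    x, y = points[:, 0], points[:, 1]
    return 0.5 * float(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))


def _polygon_centroid(points: np.ndarray) -> tuple[float, float]:
    x, y = points[:, 0], points[:, 1]
    cross = x * np.roll(y, -1) - np.roll(x, -1) * y
    a = 0.5 * np.sum(cross)
    if abs(a) < 1e-12:
        return (float(x.mean()), float(y.mean()))
    cx = np.sum((x + np.roll(x, -1)) * cross) / (6.0 * a)
    cy = np.sum((y + np.roll(y, -1)) * cross) / (6.0 * a)
    return (float(cx), float(cy))


def _check_simple(points: np.ndarray, label: str) -> None:
    from shapely.geometry import Polygon

    if not Polygon(points).is_valid:
        warnings.warn(f"{label} contour is self-intersecting", stacklevel=3)


def _ray_dirs(n_rays: int) -> np.ndarray:
    ang = 2.0 * np.pi * np.arange(n_rays) / n_rays
    return np.stack([np.cos(ang), np.sin(ang)], axis=1)


def _fit_ellipse(points: np.ndarray) -> EllipseModel:
    model = EllipseModel.from_estimate(points)
    if not model:
        raise ValueError("ellipse fit failed on measured inner points")
    return model


def _ray_ellipse_intersection(
    center: tuple[float, float], direction: np.ndarray, model: EllipseModel
) -> tuple[float, bool]:
    """Distance along the ray to the ellipse (nearer intersection).

    When the ray misses the ellipse, returns the distance of closest approach
    and a flag.
    """
    (xc, yc), (a, b), theta = model.center, model.axis_lengths, model.theta
    ct, st = np.cos(theta), np.sin(theta)
    rot = np.array([[ct, st], [-st, ct]])
    o = rot @ np.array([center[0] - xc, center[1] - yc])
    u = rot @ direction
    qa = (u[0] / a) ** 2 + (u[1] / b) ** 2
    qb = 2.0 * (o[0] * u[0] / a**2 + o[1] * u[1] / b**2)
    qc = (o[0] / a) ** 2 + (o[1] / b) ** 2 - 1.0
    disc = qb**2 - 4.0 * qa * qc
    if disc >= 0:
        sq = np.sqrt(disc)
        roots = [(-qb - sq) / (2 * qa), (-qb + sq) / (2 * qa)]
        pos = [t for t in roots if t > 0]
        if pos:
            return float(min(pos)), False
    t_star = max(-qb / (2.0 * qa), 1e-6)
    return float(t_star), True


def complete_inner_standard(
    fits: Sequence[WallFit], center: tuple[float, float]
) -> Contour:
    """Ellipse-based inner-contour completion (standard rule).

    Every detected inner point participates -- including points on rays whose
    outer border failed next to a vessel; only rays with no detectable inner
    point are filled from the fitted ellipse.
    """
    n = len(fits)
    dirs = _ray_dirs(n)
    measured = [f for f in fits if f.has_inner]
    points = np.zeros((n, 2))
    source = ["measured"] * n
    flags: list[str] = []
    for f in measured:
        points[f.ray_index] = center + f.inner_pos_mm * dirs[f.ray_index]
    invalid_idx = [f.ray_index for f in fits if not f.has_inner]
    if invalid_idx:
        if len(measured) < _MIN_ELLIPSE_POINTS:
            raise ValueError("insufficient wall points for ellipse completion")
        model = _fit_ellipse(np.array([points[f.ray_index] for f in measured]))
        for i in invalid_idx:
            t, missed = _ray_ellipse_intersection(center, dirs[i], model)
            points[i] = center + t * dirs[i]
            source[i] = "ellipse_completed"
            if missed:
                flags.append(f"ray{i}:ellipse_closest_approach")
    _check_simple(points, "inner")
    return Contour(points, source, flags)


def complete_inner_modified(
    fits: Sequence[WallFit],
    profiles: Sequence[RayProfile],
    center: tuple[float, float],
) -> Contour:
    """Median-attenuation inner-contour completion (modified rule).

    The threshold is the median HU at the inner points of the fully valid
    rays; every ray without a trusted fit -- including vessel-adjacent rays
    whose detected inner point is contrast-contaminated -- gets its inner
    point at the first continuous position (scanning outward from the centre)
    whose attenuation reaches that threshold.  Rays that never reach it fall
    back to the ellipse rule and are flagged.
    """
    n = len(fits)
    dirs = _ray_dirs(n)
    trusted = [f for f in fits if f.valid]
    if not trusted:
        raise ValueError("no valid fits for modified completion")
    threshold = float(np.median([f.inner_hu for f in trusted]))
    points = np.zeros((n, 2))
    source = ["measured"] * n
    flags: list[str] = []
    for f in trusted:
        points[f.ray_index] = center + f.inner_pos_mm * dirs[f.ray_index]
    ellipse = None
    for f in fits:
        if f.valid:
            continue
        i = f.ray_index
        prof = profiles[i]
        r = _first_reach(prof, threshold)
        if r is not None:
            points[i] = center + r * dirs[i]
            source[i] = "medianhu_completed"
            continue
        if len(trusted) < _MIN_ELLIPSE_POINTS:
            raise ValueError(
                f"ray {i} never reaches the median inner HU and too few "
                "trusted points remain for an ellipse fallback"
            )
        if ellipse is None:
            ellipse = _fit_ellipse(np.array([points[f2.ray_index] for f2 in trusted]))
        t, _ = _ray_ellipse_intersection(center, dirs[i], ellipse)
        points[i] = center + t * dirs[i]
        source[i] = "ellipse_completed"
        flags.append(f"ray{i}:medianhu_fallback_ellipse")
    _check_simple(points, "inner")
    return Contour(points, source, flags)


def _first_reach(profile: RayProfile, threshold: float) -> float | None:
    pos, hu = profile.positions, profile.hu
    if hu[0] >= threshold:
        return float(pos[0])
    idx = np.nonzero(hu >= threshold)[0]
    if idx.size == 0:
        return None
    i = int(idx[0])
    f = (threshold - hu[i - 1]) / (hu[i] - hu[i - 1])
    return float(pos[i - 1] + f * (pos[i] - pos[i - 1]))


def complete_outer(
    fits: Sequence[WallFit], inner: Contour, center: tuple[float, float]
) -> Contour:
    """Outer contour: measured where trusted, inner + median WT elsewhere."""
    n = len(fits)
    dirs = _ray_dirs(n)
    valid = [f for f in fits if f.valid]
    if not valid:
        raise ValueError("no valid fits")
    wt_med = float(np.median([f.wall_thickness_mm for f in valid]))
    points = np.zeros((n, 2))
    source = ["measured"] * n
    inner_r = inner.radii(center)
    for f in fits:
        i = f.ray_index
        if f.valid:
            points[i] = center + f.outer_pos_mm * dirs[i]
        else:
            points[i] = center + (inner_r[i] + wt_med) * dirs[i]
            source[i] = "offset_completed"
    _check_simple(points, "outer")
    return Contour(points, source)


def compute_metrics(
    inner: Contour,
    outer: Contour,
    fits: Sequence[WallFit],
    algorithm: str = "standard_ibm",
    center: tuple[float, float] = (0.0, 0.0),
    td_mode: str = "antipodal",
) -> AirwayMeasurement:
    n = len(inner.points)
    if n % 2 or len(outer.points) != n:
        raise ValueError("contours must have the same even number of points")
    la = abs(_polygon_area(inner.points))
    outer_area = abs(_polygon_area(outer.points))
    wa = outer_area - la
    if wa < 0:
        raise ValueError("outer contour inside inner contour")
    if td_mode == "antipodal":
        half = n // 2
        td = float(
            np.mean(np.hypot(*(outer.points[:half] - outer.points[half:]).T))
        )
    elif td_mode == "equivalent_circle":
        td = 2.0 * float(np.sqrt(outer_area / np.pi))
    else:
        raise ValueError(f"unknown td_mode {td_mode!r}")
    valid = [f for f in fits if f.valid]
    if not valid:
        raise ValueError("no valid fits")
    wt = float(np.median([f.wall_thickness_mm for f in valid]))
    return AirwayMeasurement(
        TD_mm=td,
        LA_mm2=la,
        WA_mm2=wa,
        WT_mm=wt,
        algorithm=algorithm,
        n_valid_rays=len(valid),
        center_mm=center,
        flags=list(inner.flags) + list(outer.flags),
    )


def _fit_all_rays(
    profiles: Sequence[RayProfile],
    cfg: IBMConfig,
    algorithm: str,
    spacing_mm: float | None = None,
) -> tuple[list[WallFit], float | None]:
    sigma = cfg.effective_sigma(spacing_mm)
    levels = [estimate_levels(p, cfg.search_min_mm, sigma) for p in profiles]
    wall_hu = None
    init = None
    table = None
    pooled_ok = False
    hu_p_airway = None
    if algorithm != "fwhm":
        wall_hu = auto_wall_hu(levels, cfg, profiles, sigma)
        if cfg.wall_hu_mode in ("auto_model", "fixed"):
            eligible = np.array(
                [
                    not lv.outer_missing
                    and lv.hu_outer <= cfg.outer_max_hu
                    and lv.prominence >= cfg.prominence_min_hu
                    for lv in levels
                ]
            )
            if eligible.any():
                pooled = _pooled_profile(profiles, eligible)
                res = fit_pooled_wall(pooled, cfg, sigma)
                if res is not None:
                    init = (res[1], res[2])
                    hu_p_airway = float(
                        np.median(
                            [lv.hu_outer for lv, e in zip(levels, eligible) if e]
                        )
                    )
                    pooled_lv = estimate_levels(pooled, cfg.search_min_mm, sigma)
                    pooled_ok = pooled_lv.prominence >= cfg.prominence_min_hu
                    # re-estimate per-ray levels with the peak search confined
                    # around the airway wall so noise spikes elsewhere cannot
                    # capture the peak and displace the fitting windows
                    mid = 0.5 * (res[1] + res[2])
                    lo = max(cfg.search_min_mm, mid - 2.0 * sigma - 0.5)
                    hi = mid + 2.0 * sigma + 0.5
                    levels = [
                        estimate_levels(p, lo, sigma, search_max_mm=hi)
                        for p in profiles
                    ]
        if cfg.curvature_correction:
            table = _DiscTable(profiles[0].positions, sigma, c_max=profiles[0].positions[-1])
    fits: list[WallFit] = []
    for prof, lv in zip(profiles, levels):
        if algorithm == "fwhm":
            ci, co = fwhm_edges(prof, lv)
            if ci is not None and co is not None and ci < co:
                attempt = WallFit(prof.index, ci, co, prof.hu_at(ci), valid=True)
            else:
                attempt = WallFit(prof.index, None, None, None, False, "order_violation")
        else:
            # the prominence cut is relaxed per ray once the airway-level wall
            # signal is established: a hard per-ray cut at the detection margin
            # selects rays on their noise and biases the thickness median
            prom_min = cfg.prominence_min_hu * (0.5 if pooled_ok else 1.0)
            trustworthy = (
                not prof.tainted
                and not lv.outer_missing
                and lv.hu_outer <= cfg.outer_max_hu
                and lv.prominence >= prom_min
                and wall_hu > lv.hu_outer + 50.0
            )
            if trustworthy:
                attempt = integral_fit(prof, lv, cfg, wall_hu, sigma, init, table)
            else:
                attempt = WallFit(prof.index, None, None, None, False, "order_violation")
        fit = _classify(lv, attempt, prof, cfg, prom_min=None if algorithm == "fwhm" else prom_min)
        if (
            algorithm != "fwhm"
            and not fit.valid
            and fit.invalid_reason == "bright_outside"
            and not prof.tainted
            and init is not None
        ):
            # the outer border is unrecoverable next to the vessel but the
            # inner point may still be detectable (and contrast-contaminated)
            res_inner = inner_only_fit(
                prof, lv, cfg, wall_hu, sigma, init, table, hu_p_airway
            )
            if res_inner is not None:
                fit = WallFit(
                    prof.index, res_inner[0], None, res_inner[1], False, "bright_outside"
                )
        fits.append(fit)
    return fits, wall_hu


def _classify(lv, attempt, prof, cfg, prom_min=None):
    if prom_min is None:
        return classify_validity(lv, attempt, prof, cfg)
    relaxed = replace_prominence(cfg, prom_min)
    return classify_validity(lv, attempt, prof, relaxed)


def replace_prominence(cfg: IBMConfig, prom_min: float) -> IBMConfig:
    from dataclasses import replace

    return replace(cfg, prominence_min_hu=prom_min)


def measure_airway(
    image: HUImage,
    seed: tuple[float, float],
    algorithm: str = "standard_ibm",
    cfg: IBMConfig | None = None,
    n_rays: int = 128,
    step_mm: float = 0.1,
    max_len_mm: float = 15.0,
    max_center_iter: int = 5,
    center_tol_mm: float = 0.1,
) -> AirwayMeasurement:
    """Measure one airway from a lumen seed point.

    The centre is refined iteratively: profiles are cast from the current
    centre, borders fitted and classified, the inner contour completed
    (ellipse rule for ``fwhm``/``standard_ibm``, median-HU rule for
    ``modified_ibm``), and the centre moved to the inner-polygon centroid,
    until it moves less than ``center_tol_mm`` or ``max_center_iter`` rounds.
    """
    if algorithm not in ALGORITHMS:
        raise ValueError(f"unknown algorithm {algorithm!r}; expected one of {ALGORITHMS}")
    cfg = cfg or IBMConfig()
    step_mm = min(step_mm, image.spacing_mm)
    seed_hu, clamped = sample_points(image, np.array([seed]))
    if clamped[0] or seed_hu[0] > cfg.lumen_seed_max_hu:
        raise ValueError(
            f"seed point is not inside a dark lumen (HU {seed_hu[0]:.0f} > "
            f"{cfg.lumen_seed_max_hu:.0f})"
        )
    center = (float(seed[0]), float(seed[1]))
    flags: list[str] = []
    for _ in range(max_center_iter):
        if not image.contains_point(center):
            raise ValueError("centre iteration left the image")
        profiles = cast_profiles(image, center, n_rays, step_mm, max_len_mm)
        fits, _ = _fit_all_rays(profiles, cfg, algorithm, image.spacing_mm)
        if algorithm == "modified_ibm":
            inner = complete_inner_modified(fits, profiles, center)
        else:
            inner = complete_inner_standard(fits, center)
        new_center = _polygon_centroid(inner.points)
        moved = float(np.hypot(new_center[0] - center[0], new_center[1] - center[1]))
        center = new_center
        if moved < center_tol_mm:
            break
    else:
        flags.append("center_not_converged")
    outer = complete_outer(fits, inner, center)
    meas = compute_metrics(inner, outer, fits, algorithm, center, cfg.td_mode)
    meas.flags.extend(flags)
    return meas
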