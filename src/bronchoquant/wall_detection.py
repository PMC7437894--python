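"""Per-ray airway wall border localization.

The wall along one ray is described by an ideal two-edge model: attenuation
rises from the lumen level ``HU_l`` to the wall density ``W`` at the inner
border ``c_in`` and falls to the outer plateau ``HU_p`` at the outer border
``c_out``, each edge blurred by the scanner point-spread function modelled as
an isotropic Gaussian of SD ``sigma``.  In the planar (curvature-free) limit
the profile is::

    f(x) = HU_l + (W - HU_l) * Phi((x - c_in)/sigma) + (HU_p - W) * Phi((x - c_out)/sigma)

with ``Phi`` the standard normal CDF.  Real airway borders are closed curves,
and for lumina only a few blur widths across the planar limit is badly wrong:
the 2-D blur of a disc of radius ``c`` seen along a radial ray is exactly a
Marcum-Q function, ``D_c(x) = P(|x e + z| <= c)`` with ``z ~ N(0, sigma^2 I)``,
i.e. the noncentral chi-square CDF with 2 degrees of freedom.  The
curvature-aware model (default) therefore replaces each ``Phi`` edge with the
corresponding blurred-disc profile; it converges to the planar form as
``c/sigma`` grows.  Under curvature correction the lumen level is fixed at
air (-1000 HU) because the sampled centre of a small lumen is itself blurred
upward and no longer measures the true lumen density.

Border positions are found by integral matching: starting from
full-width-at-half-maximum (FWHM) estimates, ``c_in`` and ``c_out`` are
alternately adjusted by bisection until the model's trapezoidal integral over
a window on the lumen side (resp. outer side) of the wall peak equals the
measured profile's integral over the same window.  Unlike FWHM edge
placement, the integral criterion is insensitive to blur, so thin walls are
not overestimated.

Rays whose outer plateau is brightened by an adjacent vessel (enhanced or
not), whose wall peak is too weak, or which left the image are classified
invalid and carry no fabricated border positions; contour completion deals
with them downstream.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.special import ndtr
from scipy.stats import ncx2

from .radial_profiles import RayProfile

__all__ = [
    "IBMConfig",
    "LevelEstimate",
    "WallFit",
    "wall_model",
    "disc_profile",
    "annular_wall_model",
    "estimate_levels",
    "fwhm_edges",
    "integral_fit",
    "classify_validity",
    "auto_wall_hu",
]

#: clamp range for automatically estimated wall density (HU)
_WALL_HU_CLAMP = (-300.0, 200.0)

#: unblurred attenuation of air filling the lumen (HU)
HU_AIR = -1000.0


@dataclass
class IBMConfig:
    """Tunable parameters of the integral-based method.

    psf_sigma_mm
        Assumed Gaussian SD of the scanner/kernel blur (soft-kernel default).
    prominence_min_hu
        Minimum wall-peak height above the brighter plateau for a ray to count
        as seeing a wall at all.
    outer_max_hu
        A ray whose outer plateau exceeds this is considered to run into a
        vessel or mediastinum rather than parenchyma.
    wall_hu_mode
        How the per-airway wall density is obtained.  ``fixed`` (default) uses
        ``wall_hu_fixed``, preset to 0 HU: airway wall is radiologically
        water-like soft tissue, and at soft-kernel blur only the
        density-thickness product of a sub-millimetre wall is identifiable,
        so the density is assumed and the thickness measured.  ``auto_model``
        instead fits the edge model to the ray-pooled profile with a
        soft-tissue ridge prior; ``auto_max_peak`` takes the tallest wall
        peak over eligible rays.
    curvature_correction
        Use the blurred-disc (Marcum-Q) edge model instead of the planar CDF
        model; matters for lumina within a few blur widths of the centre.
    resampling_blur
        Account for the blur added by pixel integration and bilinear
        resampling: sigma_eff^2 = psf^2 + spacing^2/12 + spacing^2/6.
    """

    psf_sigma_mm: float = 0.6
    prominence_min_hu: float = 100.0
    outer_max_hu: float = -500.0
    wall_hu_mode: str = "fixed"
    wall_hu_fixed: float | None = 0.0
    max_alternations: int = 5
    convergence_mm: float = 0.01
    search_min_mm: float = 0.3
    td_mode: str = "antipodal"
    lumen_seed_max_hu: float = -900.0
    curvature_correction: bool = True
    resampling_blur: bool = True

    def __post_init__(self) -> None:
        if self.wall_hu_mode not in ("auto_model", "auto_max_peak", "fixed"):
            raise ValueError(f"unknown wall_hu_mode {self.wall_hu_mode!r}")
        if self.td_mode not in ("antipodal", "equivalent_circle"):
            raise ValueError(f"unknown td_mode {self.td_mode!r}")
        if self.psf_sigma_mm <= 0:
            raise ValueError("psf_sigma_mm must be > 0 for integral fitting")
        if self.wall_hu_mode == "fixed" and self.wall_hu_fixed is None:
            raise ValueError("wall_hu_fixed required when wall_hu_mode='fixed'")

    def effective_sigma(self, spacing_mm: float | None = None) -> float:
        """Blur SD as seen by the radial profiles (mm)."""
        if not self.resampling_blur or spacing_mm is None:
            return self.psf_sigma_mm
        return float(
            np.sqrt(self.psf_sigma_mm**2 + spacing_mm**2 / 12.0 + spacing_mm**2 / 6.0)
        )


@dataclass
class LevelEstimate:
    """Plateau and peak levels of one radial profile (HU / mm).

    ``hu_outer`` is NaN when the profile is too short to hold the outer
    plateau window; such rays are later classified invalid.
    """

    hu_lumen: float
    hu_peak: float
    peak_pos_mm: float
    hu_outer: float

    @property
    def outer_missing(self) -> bool:
        return not np.isfinite(self.hu_outer)

    @property
    def prominence(self) -> float:
        """Wall-peak height above the outer plateau.

        The outer tissue is the reference because failure of wall detection is
        driven by low contrast between wall and surroundings; the lumen floor
        of a small airway is legitimately raised by blur and would understate
        the contrast.
        """
        ref = self.hu_outer if not self.outer_missing else self.hu_lumen
        return self.hu_peak - ref


@dataclass
class WallFit:
    """Detection result for one ray.

    The inner and outer border can fail independently: a ray running into a
    vessel has no recoverable outer border (``valid`` False) yet may still
    carry a detected -- possibly contrast-contaminated -- inner point, which
    participates in contour completion but never in thickness or outer-border
    statistics.  Where detection failed no position is fabricated (``None``).
    """

    ray_index: int
    inner_pos_mm: float | None
    outer_pos_mm: float | None
    inner_hu: float | None
    valid: bool
    invalid_reason: str = "none"  # none|low_prominence|bright_outside|order_violation|border_taint

    @property
    def has_inner(self) -> bool:
        return self.inner_pos_mm is not None

    @property
    def wall_thickness_mm(self) -> float | None:
        if self.inner_pos_mm is None or self.outer_pos_mm is None:
            return None
        return self.outer_pos_mm - self.inner_pos_mm


def wall_model(
    x: np.ndarray,
    hu_lumen: float,
    wall_hu: float,
    hu_outer: float,
    c_in: float,
    c_out: float,
    sigma: float,
) -> np.ndarray:
    """Planar-limit blurred two-edge wall profile (see module docstring)."""
    x = np.asarray(x, dtype=float)
    return (
        hu_lumen
        + (wall_hu - hu_lumen) * ndtr((x - c_in) / sigma)
        + (hu_outer - wall_hu) * ndtr((x - c_out) / sigma)
    )


def disc_profile(x: np.ndarray, c: float, sigma: float) -> np.ndarray:
    """Radial profile of the indicator of a disc of radius ``c`` after 2-D
    Gaussian blur of SD ``sigma`` (Marcum-Q form)."""
    x = np.asarray(x, dtype=float)
    if c <= 0:
        return np.zeros_like(x)
    return ncx2.cdf((c / sigma) ** 2, 2, (x / sigma) ** 2)


def annular_wall_model(
    x: np.ndarray,
    hu_lumen: float,
    wall_hu: float,
    hu_outer: float,
    c_in: float,
    c_out: float,
    sigma: float,
) -> np.ndarray:
    """Curvature-aware wall profile: concentric discs of radius c_out (wall
    over background) and c_in (air lumen over wall), blurred in 2-D."""
    return (
        hu_outer
        + (wall_hu - hu_outer) * disc_profile(x, c_out, sigma)
        + (hu_lumen - wall_hu) * disc_profile(x, c_in, sigma)
    )


class _DiscTable:
    """Linear-interpolation table of ``disc_profile`` over border radius.

    The integral fit evaluates the blurred-disc profile on the fixed sample
    grid for hundreds of candidate radii per ray; a table over a 0.02 mm
    radius grid amortizes the noncentral chi-square evaluations.
    """

    def __init__(self, positions: np.ndarray, sigma: float, c_max: float, dc: float = 0.02):
        self.positions = positions
        self.sigma = sigma
        self.c_grid = np.arange(dc, c_max + 2 * dc, dc)
        cc, xx = np.meshgrid(self.c_grid, positions, indexing="ij")
        self.table = ncx2.cdf((cc / sigma) ** 2, 2, (xx / sigma) ** 2)

    def eval(self, c: float, mask: np.ndarray) -> np.ndarray:
        g = self.c_grid
        if c <= g[0]:
            return self.table[0, mask] * max(c / g[0], 0.0)
        i = min(int((c - g[0]) / (g[1] - g[0])), len(g) - 2)
        f = (c - g[i]) / (g[1] - g[0])
        return (1.0 - f) * self.table[i, mask] + f * self.table[i + 1, mask]


def estimate_levels(
    profile: RayProfile,
    search_min_mm: float = 0.3,
    psf_sigma_mm: float = 0.6,
    search_max_mm: float | None = None,
) -> LevelEstimate:
    """Locate the wall peak and estimate lumen/outer plateau levels.

    The peak is the maximum sample at positions >= ``search_min_mm`` (first
    such sample on ties), optionally restricted to <= ``search_max_mm`` when a
    per-airway wall radius is already known and noise spikes elsewhere should
    not capture the peak.  The lumen level is the mean over the innermost
    fifth of the centre-to-peak run; the outer level is the median over a
    1.5 mm window starting 3 sigma beyond the peak, clipped to the profile
    end and NaN when that window is empty.
    """
    pos, hu = profile.positions, profile.hu
    search = pos >= search_min_mm
    if search_max_mm is not None:
        search &= pos <= search_max_mm
    if int(search.sum()) < 10:
        raise ValueError("profile too short beyond search_min_mm")
    idx = int(np.argmax(np.where(search, hu, -np.inf)))
    peak_pos = float(pos[idx])
    hu_peak = float(hu[idx])
    lum_end = max(0.2 * peak_pos, 2.0 * profile.step_mm)
    hu_lumen = float(hu[pos <= lum_end].mean())
    out_lo = peak_pos + 3.0 * psf_sigma_mm
    out_hi = out_lo + 1.5
    m = (pos >= out_lo) & (pos <= out_hi)
    hu_outer = float(np.median(hu[m])) if m.any() else float("nan")
    return LevelEstimate(hu_lumen, hu_peak, peak_pos, hu_outer)


def _cross_up(pos, hu, level, lo_idx, hi_idx):
    """First upward crossing of `level` in [lo_idx, hi_idx], linear interp."""
    for i in range(lo_idx + 1, hi_idx + 1):
        if hu[i - 1] < level <= hu[i]:
            f = (level - hu[i - 1]) / (hu[i] - hu[i - 1])
            return float(pos[i - 1] + f * (pos[i] - pos[i - 1]))
    return None


def _cross_down(pos, hu, level, lo_idx, hi_idx):
    for i in range(lo_idx + 1, hi_idx + 1):
        if hu[i - 1] >= level > hu[i]:
            f = (hu[i - 1] - level) / (hu[i - 1] - hu[i])
            return float(pos[i - 1] + f * (pos[i] - pos[i - 1]))
    return None


def fwhm_edges(
    profile: RayProfile, levels: LevelEstimate
) -> tuple[float | None, float | None]:
    """Half-maximum edge positions (inner, outer); a side with no crossing is None."""
    pos, hu = profile.positions, profile.hu
    pk = int(np.argmin(np.abs(pos - levels.peak_pos_mm)))
    inner = _cross_up(pos, hu, (levels.hu_lumen + levels.hu_peak) / 2.0, 0, pk)
    outer = None
    if not levels.outer_missing:
        outer = _cross_down(pos, hu, (levels.hu_outer + levels.hu_peak) / 2.0, pk, len(pos) - 1)
    return inner, outer


def _invalid(ray_index: int, reason: str) -> WallFit:
    return WallFit(ray_index, None, None, None, valid=False, invalid_reason=reason)


def _bisect_edge(residual, lo: float, hi: float, n_iter: int = 40) -> float | None:
    r_lo, r_hi = residual(lo), residual(hi)
    if r_lo == 0.0:
        return lo
    if r_hi == 0.0:
        return hi
    if r_lo * r_hi > 0:
        return None
    for _ in range(n_iter):
        mid = 0.5 * (lo + hi)
        r_mid = residual(mid)
        if r_lo * r_mid <= 0:
            hi, r_hi = mid, r_mid
        else:
            lo, r_lo = mid, r_mid
    return 0.5 * (lo + hi)


def integral_fit(
    profile: RayProfile,
    levels: LevelEstimate,
    cfg: IBMConfig,
    wall_hu: float,
    sigma: float | None = None,
    init: tuple[float, float] | None = None,
    _table: "_DiscTable | None" = None,
    hu_outer_override: float | None = None,
) -> WallFit:
    """Fit the inner and outer border by split-window integral matching.

    Starting from the FWHM edges (or the supplied ``init``), ``c_in`` is
    chosen so that the model's trapezoidal integral over the lumen-side window
    ``[c_in_prev - 4 sigma, peak]`` equals the profile's, then ``c_out``
    likewise over the outer-side window ``[peak, c_out_prev + 4 sigma]``; the
    two solves alternate until both edges move less than ``convergence_mm``.
    Each 1-D equation is solved by bisection (the window integral is monotone
    in the edge position).
    """
    if levels.outer_missing:
        return _invalid(profile.index, "order_violation")
    sigma = cfg.psf_sigma_mm if sigma is None else sigma
    # a per-airway (pooled) outer plateau is less noisy than the per-ray median
    hu_p = levels.hu_outer if hu_outer_override is None else hu_outer_override
    hu_l = HU_AIR if cfg.curvature_correction else levels.hu_lumen
    if not (wall_hu > max(hu_l, hu_p) + 50.0):
        raise ValueError("wall_hu must exceed both plateau levels by at least 50 HU")
    if init is not None:
        # a per-airway (pooled-profile) starting estimate beats per-ray FWHM,
        # which badly overshoots the outer edge of thin blurred walls
        c_in, c_out = init
    else:
        c_in, c_out = fwhm_edges(profile, levels)
    if c_in is None or c_out is None:
        return _invalid(profile.index, "order_violation")
    pos, hu = profile.positions, profile.hu
    pk = levels.peak_pos_mm

    if cfg.curvature_correction:
        table = _table or _DiscTable(pos, sigma, c_max=pos[-1])

        def edge(c, mask):
            return table.eval(c, mask)

    else:

        def edge(c, mask):
            return ndtr(-(pos[mask] - c) / sigma)  # 1 - Phi((x-c)/s) = disc analogue

    # model on a masked grid given both edges; written with the "disc" edge
    # convention: f = P + (W-P)*edge(c_out) + (L-W)*edge(c_in)
    def model_on(mask, ci, co):
        return hu_p + (wall_hu - hu_p) * edge(co, mask) + (hu_l - wall_hu) * edge(ci, mask)

    for _ in range(cfg.max_alternations):
        win_lo = max(0.0, c_in - 4.0 * sigma)
        m_a = (pos >= win_lo) & (pos <= pk)
        xa, ya = pos[m_a], hu[m_a]
        if xa.size < 2:
            return _invalid(profile.index, "order_violation")
        data_a = np.trapezoid(ya, xa)

        def res_in(c, _m=m_a, _x=xa, _d=data_a, _co=c_out):
            return np.trapezoid(model_on(_m, c, _co), _x) - _d

        # the peak sample is only grid-accurate, so the true edge may sit up
        # to about one blur width beyond it; the window integral stays
        # monotone in the edge position over the extended bracket
        new_in = _bisect_edge(res_in, win_lo if win_lo > 0 else 1e-3, pk + sigma)
        if new_in is None:
            return _invalid(profile.index, "order_violation")

        win_hi = min(pos[-1], c_out + 4.0 * sigma)
        m_b = (pos >= pk) & (pos <= win_hi)
        xb, yb = pos[m_b], hu[m_b]
        if xb.size < 2:
            return _invalid(profile.index, "order_violation")
        data_b = np.trapezoid(yb, xb)

        def res_out(c, _m=m_b, _x=xb, _d=data_b, _ci=new_in):
            return np.trapezoid(model_on(_m, _ci, c), _x) - _d

        new_out = _bisect_edge(res_out, max(new_in + 0.02, pk - sigma), win_hi)
        if new_out is None:
            return _invalid(profile.index, "order_violation")

        moved = max(abs(new_in - c_in), abs(new_out - c_out))
        c_in, c_out = float(new_in), float(new_out)
        if moved < cfg.convergence_mm:
            break

    if not (0.0 < c_in < c_out):
        return _invalid(profile.index, "order_violation")
    return WallFit(
        ray_index=profile.index,
        inner_pos_mm=c_in,
        outer_pos_mm=c_out,
        inner_hu=profile.hu_at(c_in),
        valid=True,
    )


def inner_only_fit(
    profile: RayProfile,
    levels: LevelEstimate,
    cfg: IBMConfig,
    wall_hu: float,
    sigma: float,
    init: tuple[float, float],
    _table: "_DiscTable | None" = None,
    hu_outer_airway: float | None = None,
) -> tuple[float, float] | None:
    """Inner border on a ray whose outer border is unrecoverable.

    Next to a vessel the profile climbs from the lumen into soft tissue and
    never returns to parenchyma; the ideal airway model knows nothing of
    vessels, so the lumen-side window equation is solved with the model's
    belief -- the airway-level parenchyma plateau -- on the far side.
    Brightness smeared from the vessel inflates the measured window integral
    relative to that model, dragging the detected point toward the lumen, and
    heavy contrast defeats the solve entirely: the ray then has no detectable
    inner point at all.  This is the standard method's characteristic failure
    next to vessels, graded by the vessel's enhancement.

    Returns (c_in, inner_hu) or None.
    """
    hu_p = hu_outer_airway if hu_outer_airway is not None else levels.hu_outer
    if not np.isfinite(hu_p):
        return None
    hu_l = HU_AIR if cfg.curvature_correction else levels.hu_lumen
    c_in, c_out = init
    pos, hu = profile.positions, profile.hu
    pk = levels.peak_pos_mm

    if cfg.curvature_correction:
        table = _table or _DiscTable(pos, sigma, c_max=pos[-1])

        def edge_in(c, mask):
            return table.eval(c, mask)

    else:

        def edge_in(c, mask):
            return ndtr(-(pos[mask] - c) / sigma)

    for _ in range(2):
        win_lo = max(0.0, c_in - 4.0 * sigma)
        m_a = (pos >= win_lo) & (pos <= pk)
        xa, ya = pos[m_a], hu[m_a]
        if xa.size < 2:
            return None
        data_a = np.trapezoid(ya, xa)
        out_step = edge_in(c_out, m_a)

        def res_in(c, _m=m_a, _x=xa, _d=data_a, _os=out_step):
            model = (
                hu_p
                + (wall_hu - hu_p) * _os
                + (hu_l - wall_hu) * edge_in(c, _m)
            )
            return np.trapezoid(model, _x) - _d

        new_in = _bisect_edge(res_in, win_lo if win_lo > 0 else 1e-3, pk + sigma)
        if new_in is None:
            return None
        done = abs(new_in - c_in) < cfg.convergence_mm
        c_in = float(new_in)
        if done:
            break
    if not 0.0 < c_in:
        return None
    return c_in, profile.hu_at(c_in)


def classify_validity(
    levels: LevelEstimate, fit_attempt: WallFit, profile: RayProfile, cfg: IBMConfig
) -> WallFit:
    """Demote fits on rays where wall detection cannot be trusted.

    Checked in order: the profile left the image (``border_taint``); the outer
    plateau is missing or brighter than parenchyma can be, i.e. the ray runs
    into a vessel or mediastinum (``bright_outside``); the wall peak is not
    prominent enough (``low_prominence``); the integral fit itself failed
    (``order_violation``).  Valid fits pass through unchanged.
    """
    if profile.tainted:
        return _invalid(profile.index, "border_taint")
    if levels.outer_missing or levels.hu_outer > cfg.outer_max_hu:
        return _invalid(profile.index, "bright_outside")
    if levels.prominence < cfg.prominence_min_hu:
        return _invalid(profile.index, "low_prominence")
    return fit_attempt


def _pooled_profile(profiles: Sequence[RayProfile], eligible: np.ndarray) -> RayProfile:
    hu = np.mean(np.stack([p.hu for p in profiles])[eligible], axis=0)
    p0 = profiles[0]
    return RayProfile(-1, 0.0, p0.step_mm, p0.positions.copy(), hu, tainted=False)


#: floor (HU) on the pooled-profile residual scale: raster/interpolation
#: systematics remain even in noiseless renders
_POOLED_NOISE_FLOOR_HU = 3.0

#: soft-tissue prior on the wall density: centre and SD (HU).  Airway wall is
#: soft tissue, radiologically close to water.
_WALL_HU_PRIOR = (0.0, 75.0)


def fit_pooled_wall(
    pooled: RayProfile, cfg: IBMConfig, sigma: float | None = None
) -> tuple[float, float, float] | None:
    """Estimate (wall_hu, c_in, c_out) on a ray-pooled profile.

    Integral matching over 1-D windows cannot separate wall density from wall
    thickness for walls thinner than the blur (only their product is pinned),
    so the density is estimated from the *shape* of the pooled profile: a
    least-squares fit of the edge model over (c_in, c_out) in which the wall
    density, entering linearly, is concentrated out in closed form.  For thin
    walls the shape constraint itself degenerates (a blurred thin bar is
    nearly indistinguishable from a scaled blurred delta), so the density
    carries a weak soft-tissue ridge prior (0 +/- 75 HU, i.e. water-like):
    negligible when the data identify the density, decisive when they cannot.
    Returns (wall_hu, c_in, c_out) or None when the pooled profile has no
    usable wall signature.
    """
    from scipy.optimize import least_squares

    sigma = cfg.psf_sigma_mm if sigma is None else sigma
    lv = estimate_levels(pooled, cfg.search_min_mm, sigma)
    if lv.outer_missing:
        return None
    ci0, co0 = fwhm_edges(pooled, lv)
    if ci0 is None or co0 is None:
        return None
    pos, hu = pooled.positions, pooled.hu
    m = (pos >= max(0.0, ci0 - 4.0 * sigma)) & (pos <= min(pos[-1], co0 + 4.0 * sigma))
    xm, ym = pos[m], hu[m]
    if xm.size < 8:
        return None
    hu_p = lv.hu_outer
    hu_l = HU_AIR if cfg.curvature_correction else lv.hu_lumen
    w0, w_sd = _WALL_HU_PRIOR
    # residual scale from the outer plateau of the pooled profile itself;
    # adjacent samples are correlated over roughly one blur width, so the
    # per-sample weights are deflated by sigma/step when balancing the prior
    tail = (pos >= lv.peak_pos_mm + 3.0 * sigma) & (pos <= lv.peak_pos_mm + 3.0 * sigma + 1.5)
    noise = max(float(np.std(hu[tail])) if tail.sum() > 3 else 0.0, _POOLED_NOISE_FLOOR_HU)
    n_corr = max(sigma / pooled.step_mm, 1.0)
    lam = n_corr * (noise / w_sd) ** 2

    if cfg.curvature_correction:
        def edge(c):
            return disc_profile(xm, c, sigma)
    else:
        def edge(c):
            return ndtr(-(xm - c) / sigma)

    def split(p):
        ci, co = p
        e_in, e_out = edge(ci), edge(co)
        g = e_out - e_in
        r0 = ym - hu_p * (1.0 - e_out) - hu_l * e_in
        w = (np.dot(g, r0) + lam * w0) / (np.dot(g, g) + lam)
        return r0, g, w

    def resid(p):
        r0, g, w = split(p)
        return np.concatenate(
            [(r0 - w * g) / (noise * np.sqrt(n_corr)), [(w - w0) / w_sd]]
        )

    try:
        sol = least_squares(resid, x0=[ci0, min(co0, ci0 + 3.0)], method="lm")
    except Exception:
        return None
    ci, co = float(sol.x[0]), float(sol.x[1])
    if not (0.0 < ci < co <= pos[-1]):
        return None
    _, _, w = split(sol.x)
    return float(w), ci, co


def auto_wall_hu(
    levels: Sequence[LevelEstimate],
    cfg: IBMConfig,
    profiles: Sequence[RayProfile] | None = None,
    sigma: float | None = None,
) -> float:
    """Per-airway wall density estimate (single constant for all rays)."""
    if cfg.wall_hu_mode == "fixed":
        return float(cfg.wall_hu_fixed)
    bright = np.array(
        [lv.outer_missing or lv.hu_outer > cfg.outer_max_hu for lv in levels]
    )
    prominent = np.array([lv.prominence >= cfg.prominence_min_hu for lv in levels])
    eligible = ~bright & prominent
    if not eligible.any():
        raise ValueError("no wall signal: every ray is vessel-adjacent or featureless")
    peaks = np.array([lv.hu_peak for lv in levels])
    w_peak = float(np.clip(peaks[~bright].max(), *_WALL_HU_CLAMP))
    if cfg.wall_hu_mode == "auto_max_peak" or profiles is None:
        return w_peak
    pooled = _pooled_profile(profiles, eligible)
    res = fit_pooled_wall(pooled, cfg, sigma)
    if res is None:
        return w_peak
    return float(np.clip(res[0], *_WALL_HU_CLAMP))
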