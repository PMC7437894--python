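import numpy as np
import pytest

from bronchoquant.contour_metrics import (
    Contour,
    complete_inner_modified,
    complete_inner_standard,
    complete_outer,
    compute_metrics,
    measure_airway,
)
from bronchoquant.phantom import PhantomSpec, ground_truth, render_phantom
from bronchoquant.radial_profiles import RayProfile, cast_profiles
from bronchoquant.wall_detection import IBMConfig, WallFit


def circle_fits(n, radius, wt=1.0, missing=(), center=(0.0, 0.0)):
    fits = []
    for i in range(n):
        if i in missing:
            fits.append(WallFit(i, None, None, None, False, "bright_outside"))
        else:
            fits.append(WallFit(i, radius, radius + wt, -400.0, True))
    return fits


class TestCompleteInnerStandard:
    def test_circle_completion(self):
        missing = set(range(20, 52))  # 32 contiguous missing rays
        fits = circle_fits(128, 5.0, missing=missing)
        contour = complete_inner_standard(fits, (0.0, 0.0))
        radii = contour.radii((0.0, 0.0))
        assert np.allclose(radii[sorted(missing)], 5.0, atol=0.01)
        assert all(contour.source[i] == "ellipse_completed" for i in missing)

    def test_ellipse_polar_form(self):
        """Completed point on an axis-aligned ellipse matches the polar form."""
        a, b = 6.0, 4.0
        n = 64
        ang = 2 * np.pi * np.arange(n) / n
        fits = []
        for i in range(n):
            if i == 10:
                fits.append(WallFit(i, None, None, None, False, "bright_outside"))
            else:
                r = a * b / np.hypot(b * np.cos(ang[i]), a * np.sin(ang[i]))
                fits.append(WallFit(i, r, r + 1, -400.0, True))
        contour = complete_inner_standard(fits, (0.0, 0.0))
        expected = a * b / np.hypot(b * np.cos(ang[10]), a * np.sin(ang[10]))
        assert contour.radii((0.0, 0.0))[10] == pytest.approx(expected, abs=0.01)

    def test_too_few_points(self):
        fits = circle_fits(8, 5.0, missing=range(4, 8))
        with pytest.raises(ValueError, match="insufficient"):
            complete_inner_standard(fits, (0.0, 0.0))


def flat_profile(i, n, value=-1000.0, step=0.1, length=15.0):
    pos = np.arange(0.0, length + step / 2, step)
    return RayProfile(i, 2 * np.pi * i / n, step, pos, np.full_like(pos, value))


class TestCompleteInnerModified:
    def test_all_valid_is_identity(self):
        fits = circle_fits(16, 5.0)
        profiles = [flat_profile(i, 16) for i in range(16)]
        contour = complete_inner_modified(fits, profiles, (0.0, 0.0))
        assert np.allclose(contour.radii((0.0, 0.0)), 5.0)
        assert all(s == "measured" for s in contour.source)

    def test_linear_interpolation_of_threshold(self):
        """Crossing of -500 between (-1000 @ 4.9, -400 @ 5.0) sits at 4.9833."""
        n = 16
        fits = []
        for i in range(n):
            if i == 0:
                fits.append(WallFit(i, None, None, None, False, "bright_outside"))
            else:
                fits.append(WallFit(i, 5.0, 6.0, -500.0, True))
        pos = np.arange(0.0, 15.05, 0.1)
        hu = np.where(pos <= 4.9, -1000.0, np.minimum((pos - 4.9) * 6000 - 1000, -100.0))
        profiles = [RayProfile(i, 2 * np.pi * i / n, 0.1, pos, hu.copy()) for i in range(n)]
        contour = complete_inner_modified(fits, profiles, (0.0, 0.0))
        assert contour.radii((0.0, 0.0))[0] == pytest.approx(4.9833, abs=0.0005)
        assert contour.source[0] == "medianhu_completed"

    def test_never_reaching_falls_back_to_ellipse(self):
        fits = circle_fits(16, 5.0, missing=(3,))
        profiles = [flat_profile(i, 16) for i in range(16)]  # never reaches -400
        contour = complete_inner_modified(fits, profiles, (0.0, 0.0))
        assert contour.source[3] == "ellipse_completed"
        assert any("fallback" in f for f in contour.flags)


class TestCompleteOuter:
    def test_identity_when_all_valid(self):
        fits = circle_fits(16, 5.0, wt=1.0)
        inner = complete_inner_standard(fits, (0.0, 0.0))
        outer = complete_outer(fits, inner, (0.0, 0.0))
        assert np.allclose(outer.radii((0.0, 0.0)), 6.0)

    def test_offset_completion_uses_median_wt(self):
        n = 16
        fits = []
        wts = [0.9, 1.0, 1.3]
        for i in range(n):
            if i == 5:
                fits.append(WallFit(i, None, None, None, False, "bright_outside"))
            else:
                wt = wts[i % 3]
                fits.append(WallFit(i, 5.0, 5.0 + wt, -400.0, True))
        inner = complete_inner_standard(fits, (0.0, 0.0))
        outer = complete_outer(fits, inner, (0.0, 0.0))
        assert outer.source[5] == "offset_completed"
        assert outer.radii((0.0, 0.0))[5] == pytest.approx(
            inner.radii((0.0, 0.0))[5] + 1.0, abs=1e-6
        )


class TestComputeMetrics:
    def _regular_contour(self, n, radius):
        ang = 2 * np.pi * np.arange(n) / n
        pts = radius * np.stack([np.cos(ang), np.sin(ang)], axis=1)
        return Contour(pts, ["measured"] * n)

    def test_regular_polygon_closed_forms(self):
        """128-gon on r=5 and r=6: shoelace areas and antipodal TD."""
        n = 128
        inner = self._regular_contour(n, 5.0)
        outer = self._regular_contour(n, 6.0)
        fits = circle_fits(n, 5.0, wt=1.0)
        m = compute_metrics(inner, outer, fits)
        gon = lambda r: 0.5 * n * r**2 * np.sin(2 * np.pi / n)
        assert m.LA_mm2 == pytest.approx(gon(5.0), abs=0.005)  # 78.51
        assert m.WA_mm2 == pytest.approx(gon(6.0) - gon(5.0), abs=0.01)  # 34.55
        assert m.TD_mm == pytest.approx(12.0, abs=1e-9)
        assert m.WT_mm == pytest.approx(1.0)

    def test_unit_square_shoelace(self):
        pts = np.array([[0.0, 0.0], [1.0, 0.0], [1.0, 1.0], [0.0, 1.0]])
        inner = Contour(pts, ["measured"] * 4)
        outer = Contour(pts * 2 - 0.5, ["measured"] * 4)
        fits = circle_fits(4, 1.0, wt=0.5)
        m = compute_metrics(inner, outer, fits)
        assert m.LA_mm2 == pytest.approx(1.0)

    def test_wt_median_robust_to_outlier(self):
        n = 8
        wts = [0.8, 0.9, 1.1, 5.0, 0.8, 0.9, 1.1, 5.0]
        fits = [WallFit(i, 5.0, 5.0 + wts[i], -400.0, True) for i in range(n)]
        inner = self._regular_contour(n, 5.0)
        outer = self._regular_contour(n, 6.0)
        m = compute_metrics(inner, outer, fits)
        assert m.WT_mm == pytest.approx(1.0)

    def test_inverted_contours_rejected(self):
        inner = self._regular_contour(8, 6.0)
        outer = self._regular_contour(8, 5.0)
        with pytest.raises(ValueError, match="outer"):
            compute_metrics(inner, outer, circle_fits(8, 5.0))

    def test_equivalent_circle_td(self):
        n = 128
        inner = self._regular_contour(n, 5.0)
        outer = self._regular_contour(n, 6.0)
        m = compute_metrics(inner, outer, circle_fits(n, 5.0), td_mode="equivalent_circle")
        assert m.TD_mm == pytest.approx(12.0, rel=1e-3)


class TestMeasureAirway:
    def test_standard_equals_modified_when_vessel_free(self, clean_phantom):
        spec, img = clean_phantom
        a = measure_airway(img, spec.airway_center, "standard_ibm")
        b = measure_airway(img, spec.airway_center, "modified_ibm")
        assert a.TD_mm == pytest.approx(b.TD_mm, abs=1e-9)
        assert a.LA_mm2 == pytest.approx(b.LA_mm2, abs=1e-9)
        assert a.n_valid_rays == b.n_valid_rays == 128

    def test_center_refinement_from_offset_seed(self, clean_phantom):
        spec, img = clean_phantom
        seed = (spec.airway_center[0] + 1.0, spec.airway_center[1])
        m = measure_airway(img, seed, "standard_ibm")
        assert np.hypot(
            m.center_mm[0] - spec.airway_center[0],
            m.center_mm[1] - spec.airway_center[1],
        ) < 0.2

    def test_seed_outside_lumen_rejected(self, clean_phantom):
        spec, img = clean_phantom
        with pytest.raises(ValueError, match="lumen"):
            measure_airway(img, (2.0, 2.0), "standard_ibm")

    def test_unknown_algorithm(self, clean_phantom):
        spec, img = clean_phantom
        with pytest.raises(ValueError, match="algorithm"):
            measure_airway(img, spec.airway_center, "laplacian")

    def test_fwhm_overestimates_wall(self, clean_phantom):
        spec, img = clean_phantom
        m = measure_airway(img, spec.airway_center, "fwhm")
        assert m.WT_mm > 1.3  # true WT is 1.0; FWHM inflates blurred walls

    def test_modified_contour_wider_than_standard_at_contact(self, pa_phantom):
        """Enhanced-vessel contact: the median-HU rule keeps the lumen border
        out at the wall while the contaminated ellipse pulls it inward."""
        spec, img = pa_phantom
        from bronchoquant.contour_metrics import _fit_all_rays
        from bronchoquant.radial_profiles import cast_profiles

        profiles = cast_profiles(img, spec.airway_center)
        cfg = IBMConfig()
        fits, _ = _fit_all_rays(profiles, cfg, "standard_ibm", img.spacing_mm)
        std = complete_inner_standard(fits, spec.airway_center)
        mod = complete_inner_modified(fits, profiles, spec.airway_center)
        contact = [f.ray_index for f in fits if not f.valid]
        assert contact
        r_std = std.radii(spec.airway_center)[contact]
        r_mod = mod.radii(spec.airway_center)[contact]
        assert r_mod.mean() > r_std.mean()

    def test_rotation_invariance(self):
        """Rotating the scene changes each metric by well under 1%."""
        results = []
        for angle in (0.0, 37.0, 90.0):
            spec = PhantomSpec(
                lumen_radius_mm=3.0, wall_thickness_mm=1.0,
                vessel_radius_mm=3.0, vessel_hu=725.0,
                vessel_gap_mm=-0.5, vessel_angle_deg=angle,
            )
            img = render_phantom(spec)
            m = measure_airway(img, spec.airway_center, "modified_ibm")
            results.append([m.TD_mm, m.LA_mm2, m.WA_mm2, m.WT_mm])
        results = np.array(results)
        rel_spread = (results.max(axis=0) - results.min(axis=0)) / results.mean(axis=0)
        assert rel_spread.max() < 0.01
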