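import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from handdose.constants import MEV_TO_J
from handdose.dosimetry import (
    DosePoint,
    SlopeFit,
    average_replicates,
    build_report,
    dose_from_tally,
    extrapolate_dose_mgy,
    fit_dose_response,
    hp007_msv,
    normalized_stats,
)
from handdose.geometry import Box, Region, SceneGeometry
from handdose.materials import get_material
from handdose.transport import DoseTally

WATER = get_material("water")
AIR = get_material("air")


def one_gram_scene():
    # 1 cm^3 water cube = exactly 1 g scoring mass
    world = Region("world", Box((0, 0, 0), (100.0,) * 3), AIR)
    det = Region("det", Box((0, 0, 0), (1.0, 1.0, 1.0)), WATER,
                 scoring=True)
    return SceneGeometry([world, det])


def tally_with(edep_det_mev, histories=10, scene=None):
    scene = scene or one_gram_scene()
    t = DoseTally.empty([r.name for r in scene.regions])
    block = np.zeros((histories, len(scene.regions)))
    block[:, 1] = edep_det_mev / histories
    t.add_history_block(block)
    return t


class TestDoseFromTally:
    def test_zero_tally_gives_zero_doses(self):
        scene = one_gram_scene()
        t = DoseTally.empty([r.name for r in scene.regions])
        t.add_history_block(np.zeros((5, 2)))
        points = dose_from_tally(t, scene)
        assert all(p.dose_gy == 0.0 for p in points)

    def test_unit_conversion_1mev_in_1g(self):
        # 1 MeV in 1 g -> 1.602176634e-10 Gy
        scene = one_gram_scene()
        t = tally_with(1.0, scene=scene)
        (point,) = dose_from_tally(t, scene)
        assert point.dose_gy == pytest.approx(1.602176634e-10, rel=1e-12)
        assert MEV_TO_J == 1.602176634e-13

    def test_merged_tally_is_history_weighted_mean(self):
        # merge-algebra oracle: dose of merged = weighted mean of doses
        scene = one_gram_scene()
        a = tally_with(2.0, histories=10, scene=scene)
        b = tally_with(9.0, histories=30, scene=scene)
        (pa,) = dose_from_tally(a, scene)
        (pb,) = dose_from_tally(b, scene)
        (pm,) = dose_from_tally(a.merge(b), scene)
        per_hist = (pa.dose_gy / 10 * 10 + pb.dose_gy / 30 * 30) / 40
        assert pm.dose_gy / 40 == pytest.approx(per_hist, rel=1e-12)

    def test_zero_mass_region_impossible_by_construction(self):
        with pytest.raises(ValueError):
            Box((0, 0, 0), (0.0, 1.0, 1.0))


def _normal_equations_oracle(x, y):
    # textbook closed form: slope and intercept from raw sums
    n = len(x)
    sx, sy = sum(x), sum(y)
    sxx, sxy = sum(v * v for v in x), sum(a * b for a, b in zip(x, y))
    slope = (n * sxy - sx * sy) / (n * sxx - sx * sx)
    intercept = (sy - slope * sx) / n
    ybar = sy / n
    ss_res = sum((yi - slope * xi - intercept) ** 2 for xi, yi in zip(x, y))
    ss_tot = sum((yi - ybar) ** 2 for yi in y)
    return slope, intercept, 1.0 - ss_res / ss_tot


class TestFitDoseResponse:
    def test_noiseless_line(self):
        pts = [
            DosePoint(n, "index_distal", 2e-15 * n, 0.0)
            for n in (100, 1000, 10_000, 100_000)
        ]
        fit = fit_dose_response(pts)
        assert fit.slope_gy_per_decay == pytest.approx(2e-15, rel=1e-12)
        assert fit.intercept_gy == pytest.approx(0.0, abs=1e-18)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-12)

    def test_matches_normal_equations_oracle(self):
        x = [100.0, 500.0, 2500.0, 12_500.0, 62_500.0]
        y = [3.1e-14, 1.4e-13, 7.7e-13, 3.4e-12, 1.74e-11]
        pts = [DosePoint(xi, "r", yi, 0.0) for xi, yi in zip(x, y)]
        fit = fit_dose_response(pts)
        slope, intercept, r2 = _normal_equations_oracle(x, y)
        assert fit.slope_gy_per_decay == pytest.approx(slope, rel=1e-12)
        assert fit.intercept_gy == pytest.approx(intercept, rel=1e-12)
        assert fit.r_squared == pytest.approx(r2, rel=1e-12)

    def test_replicates_averaged_before_fit(self):
        pts = [
            DosePoint(100, "r", 1e-13, 0.0),
            DosePoint(100, "r", 3e-13, 0.0),
            DosePoint(1000, "r", 2e-12, 0.0),
            DosePoint(10_000, "r", 2e-11, 0.0),
        ]
        fit = fit_dose_response(pts)
        avg = average_replicates(pts)
        assert len(avg) == 3
        x = [p.n_decays for p in avg]
        y = [p.dose_gy for p in avg]
        slope, _, _ = _normal_equations_oracle(x, y)
        assert fit.slope_gy_per_decay == pytest.approx(slope, rel=1e-12)

    def test_too_few_levels_rejected(self):
        pts = [DosePoint(n, "r", 1e-13, 0.0) for n in (100, 1000)]
        with pytest.raises(ValueError):
            fit_dose_response(pts)

    def test_mixed_regions_rejected(self):
        pts = [
            DosePoint(100, "a", 1e-13, 0.0),
            DosePoint(1000, "b", 1e-12, 0.0),
            DosePoint(10_000, "a", 1e-11, 0.0),
        ]
        with pytest.raises(ValueError):
            fit_dose_response(pts)


class TestExtrapolation:
    def test_reference_index_dose(self):
        fit = SlopeFit("index", 5.68e-15, 0.0, 1.0)
        dose = extrapolate_dose_mgy(fit, 3.6e10)
        assert round(dose, 3) == 0.204

    def test_reference_small_dose(self):
        fit = SlopeFit("small", 1.07e-15, 0.0, 1.0)
        assert round(extrapolate_dose_mgy(fit, 3.6e10), 3) == 0.039

    def test_zero_decays(self):
        fit = SlopeFit("x", 1e-15, 0.0, 1.0)
        assert extrapolate_dose_mgy(fit, 0) == 0.0

    def test_negative_decays_rejected(self):
        fit = SlopeFit("x", 1e-15, 0.0, 1.0)
        with pytest.raises(ValueError):
            extrapolate_dose_mgy(fit, -1)


class TestHp007:
    def test_identity_at_unit_quality_factor(self):
        assert hp007_msv(0.204) == pytest.approx(0.204)
        assert hp007_msv(0.078) == pytest.approx(0.078)
        assert hp007_msv(0.0) == 0.0

    def test_invalid_quality_factor(self):
        with pytest.raises(ValueError):
            hp007_msv(1.0, 0.0)
        with pytest.raises(ValueError):
            hp007_msv(-1.0)


class TestNormalizedStats:
    def test_reference_upper_bound(self):
        # 0.204 mSv at 0.3 GBq -> 0.68 mSv/GBq
        (lo, hi), _, _ = normalized_stats([0.204, 0.039], 0.3)
        assert hi == pytest.approx(0.68)

    def test_unit_activity_identity(self):
        vals = [0.1, 0.2, 0.3]
        (lo, hi), mean, median = normalized_stats(vals, 1.0)
        assert (lo, hi) == (0.1, 0.3)
        assert mean == pytest.approx(0.2)
        assert median == pytest.approx(0.2)

    def test_matches_sorting_oracle(self, rng):
        vals = rng.random(17).tolist()
        (lo, hi), mean, median = normalized_stats(vals, 2.0)
        scaled = sorted(v / 2.0 for v in vals)
        assert lo == pytest.approx(scaled[0])
        assert hi == pytest.approx(scaled[-1])
        assert mean == pytest.approx(sum(scaled) / len(scaled))
        assert median == pytest.approx(scaled[len(scaled) // 2])

    def test_even_count_median_mid_interpolated(self):
        (_, _), _, median = normalized_stats([1.0, 2.0, 3.0, 10.0], 1.0)
        assert median == pytest.approx(2.5)

    def test_contract_errors(self):
        with pytest.raises(ValueError):
            normalized_stats([], 1.0)
        with pytest.raises(ValueError):
            normalized_stats([1.0], 0.0)


class TestPipelineProperties:
    @settings(max_examples=50, deadline=None)
    @given(
        slope=st.floats(1e-17, 1e-13),
        n=st.floats(1.0, 1e12),
        k=st.floats(0.01, 100.0),
    )
    def test_pipeline_linearity(self, slope, n, k):
        fit = SlopeFit("x", slope, 0.0, 1.0)
        a = hp007_msv(extrapolate_dose_mgy(fit, k * n))
        b = k * hp007_msv(extrapolate_dose_mgy(fit, n))
        assert a == pytest.approx(b, rel=1e-9)


class TestBuildReport:
    def test_reference_slopes_reproduce_dose_column(self):
        fits = {
            f: SlopeFit(f, s, 0.0, 1.0)
            for f, s in {
                "thumb": 1.82e-16,
                "index": 5.68e-15,
                "middle": 5.25e-15,
                "ring": 2.16e-15,
                "small": 1.07e-15,
            }.items()
        }
        rep = build_report(fits, 300e6, 120.0, 3.6e10)
        assert round(rep.fingers["index"]["dose_mgy"], 3) == 0.204
        assert round(rep.fingers["middle"]["dose_mgy"], 3) == 0.189
        assert round(rep.fingers["ring"]["dose_mgy"], 3) == 0.078
        assert round(rep.fingers["small"]["dose_mgy"], 3) == 0.039
        # Hp(0.07) numerically equals absorbed dose at Q = 1
        for f, vals in rep.fingers.items():
            assert vals["hp007_msv"] == pytest.approx(vals["dose_mgy"])
        assert rep.fingers["index"]["norm_msv_per_gbq"] == pytest.approx(
            0.68, abs=5e-3
        )

    def test_distal_region_names_accepted(self):
        fits = {"index_distal": SlopeFit("index_distal", 1e-15, 0.0, 1.0)}
        rep = build_report(fits, 1e9, 60.0, 1e10)
        assert "index" in rep.fingers

    def test_unknown_finger_rejected(self):
        with pytest.raises(ValueError):
            build_report(
                {"pinky": SlopeFit("pinky", 1e-15, 0.0, 1.0)},
                1e9, 60.0, 1e10,
            )
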