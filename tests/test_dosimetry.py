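"""Gamma analysis, DVH computation, and the group comparison harness."""

import numpy as np
import pandas as pd
import pytest

from sctkit.dosimetry import (
    DVHCurve,
    GammaCriteria,
    dvh,
    dvh_metrics,
    gamma_index,
    group_comparison,
    relative_dvh_difference,
)
from sctkit.grid import ImageGrid, Modality
from sctkit.phantom import PhantomSpec, generate_dose, generate_pair

from helpers_gamma import brute_force_pass_rate, smooth_dose_pair


def dose_grid(arr, spacing=1.0):
    return ImageGrid(arr, spacing, Modality.DOSE)


class TestGamma:
    def test_identical_doses_pass_everywhere(self, rng):
        ref, _ = smooth_dose_pair(rng)
        res = gamma_index(dose_grid(ref), dose_grid(ref.copy()))
        assert res.pass_rate == 1.0
        assert np.nanmax(res.gamma_map) == pytest.approx(0.0, abs=1e-9)

    def test_uniform_five_percent_error_fails_all(self):
        """Uniform 10 vs 10.5 Gy at 3%/3mm global: no spatial gradient can
        absorb a flat 5% dose error, so gamma = 5/3 at every voxel."""
        ref = np.full((12, 12), 10.0)
        evl = np.full((12, 12), 10.5)
        res = gamma_index(dose_grid(ref), dose_grid(evl),
                          GammaCriteria(mode="global"))
        assert res.pass_rate == 0.0
        assert np.allclose(res.gamma_map, 5.0 / 3.0, atol=1e-9)

    def test_uniform_small_error_passes_all(self):
        ref = np.full((12, 12), 10.0)
        evl = np.full((12, 12), 10.2)  # 2% < 3%
        res = gamma_index(dose_grid(ref), dose_grid(evl), GammaCriteria(mode="global"))
        assert res.pass_rate == 1.0

    @pytest.mark.parametrize("mode", ["local", "global"])
    @pytest.mark.parametrize("crit", [1.0, 3.0])
    def test_matches_exhaustive_oracle(self, rng, mode, crit):
        ref, evl = smooth_dose_pair(rng)
        c = GammaCriteria(dose_diff_percent=crit, dta_mm=crit, mode=mode)
        res = gamma_index(dose_grid(ref), dose_grid(evl), c)
        oracle = brute_force_pass_rate(ref, evl, (1.0, 1.0), c)
        assert res.pass_rate == pytest.approx(oracle, abs=1e-12)

    def test_threshold_defines_evaluated_set(self, rng):
        ref, evl = smooth_dose_pair(rng)
        res = gamma_index(dose_grid(ref), dose_grid(evl))
        assert res.n_evaluated == int((ref >= 0.1 * ref.max()).sum())
        assert np.isnan(res.gamma_map[ref < 0.1 * ref.max()]).all()

    def test_monotone_in_criteria(self, rng):
        ref, evl = smooth_dose_pair(rng)
        rates = [
            gamma_index(dose_grid(ref), dose_grid(evl),
                        GammaCriteria(dose_diff_percent=c, dta_mm=c)).pass_rate
            for c in (1.0, 2.0, 3.0)
        ]
        assert rates[0] <= rates[1] <= rates[2]

    def test_global_at_least_local(self, rng):
        ref, evl = smooth_dose_pair(rng)
        c_local = GammaCriteria(dose_diff_percent=2, dta_mm=2, mode="local")
        c_global = GammaCriteria(dose_diff_percent=2, dta_mm=2, mode="global")
        assert (
            gamma_index(dose_grid(ref), dose_grid(evl), c_global).pass_rate
            >= gamma_index(dose_grid(ref), dose_grid(evl), c_local).pass_rate
        )

    def test_geometry_mismatch_rejected(self):
        with pytest.raises(ValueError):
            gamma_index(dose_grid(np.ones((8, 8))), dose_grid(np.ones((9, 9))))

    def test_invalid_criteria_rejected(self):
        with pytest.raises(ValueError):
            GammaCriteria(dose_diff_percent=0)
        with pytest.raises(ValueError):
            GammaCriteria(mode="both")


class TestDVH:
    def test_four_voxel_toy_case(self):
        dose = np.array([[1.0, 2.0], [3.0, 4.0]])
        mask = np.ones((2, 2), bool)
        curve = dvh(dose_grid(dose), mask, bin_width_gy=0.5)
        v_at = lambda d: curve.volume_pct[np.searchsorted(curve.dose_edges_gy, d)]
        assert v_at(2.5) == 50.0
        assert curve.volume_pct[0] == 100.0
        assert curve.volume_pct[-1] == 0.0

    def test_uniform_dose_is_a_step(self):
        dose = np.full((4, 4), 10.0)
        curve = dvh(dose_grid(dose), np.ones((4, 4), bool), bin_width_gy=1.0)
        below = curve.dose_edges_gy <= 10.0
        assert np.all(curve.volume_pct[below] == 100.0)
        assert np.all(curve.volume_pct[~below] == 0.0)

    def test_matches_counting_oracle_and_monotone(self, rng):
        dose = rng.uniform(0, 20, (16, 16))
        mask = rng.random((16, 16)) < 0.4
        curve = dvh(dose_grid(dose), mask, bin_width_gy=0.7)
        doses = dose[mask]
        for edge, vol in zip(curve.dose_edges_gy, curve.volume_pct):
            assert vol == pytest.approx(100.0 * np.mean(doses >= edge))
        assert np.all(np.diff(curve.volume_pct) <= 1e-12)

    def test_empty_structure_rejected(self):
        with pytest.raises(ValueError):
            dvh(dose_grid(np.ones((4, 4))), np.zeros((4, 4), bool))


class TestDVHMetrics:
    def test_toy_mean_and_vx(self):
        dose = np.array([[1.0, 2.0], [3.0, 4.0]])
        mask = np.ones((2, 2), bool)
        m = dvh_metrics(dose_grid(dose), mask, v_levels_gy=[0.0, 2.5])
        assert m["D_mean"] == 2.5
        assert m["D_max"] == 4.0
        assert m["V_0Gy"] == 100.0
        assert m["V_2.5Gy"] == 50.0

    def test_random_case_matches_direct_counting(self, rng):
        dose = rng.uniform(0, 30, (12, 12))
        mask = rng.random((12, 12)) < 0.5
        m = dvh_metrics(dose_grid(dose), mask, v_levels_gy=[5.0])
        assert m["D_mean"] == pytest.approx(dose[mask].mean())
        assert m["V_5Gy"] == pytest.approx(100.0 * np.mean(dose[mask] >= 5.0))


class TestRelativeDifference:
    def test_identical_is_zero(self):
        assert relative_dvh_difference(20.0, 20.0) == 0.0

    def test_sign_and_magnitude(self):
        assert relative_dvh_difference(20.0, 19.0) == pytest.approx(-5.0)
        assert relative_dvh_difference(20.0, 21.0) == pytest.approx(5.0)

    def test_zero_reference_is_undefined_not_infinite(self):
        assert np.isnan(relative_dvh_difference(0.0, 1.0))

    def test_percentage_point_mode(self):
        assert relative_dvh_difference(95.0, 93.0, mode="percentage_point") == -2.0


class TestGroupComparison:
    def test_identical_groups_p_one(self):
        df = pd.DataFrame({"group": [1, 1, 1, 2, 2, 2], "rate": [0.9, 0.8, 0.85, 0.9, 0.8, 0.85]})
        out = group_comparison(df, ["rate"])
        assert out.loc[0, "p_value"] == 1.0
        assert out.loc[0, "group1_mean"] == pytest.approx(out.loc[0, "group2_mean"])

    def test_summaries_equal_direct_averages(self, rng):
        df = pd.DataFrame({"group": [1] * 5 + [2] * 5, "rate": rng.uniform(0.7, 1.0, 10)})
        out = group_comparison(df, ["rate"])
        assert out.loc[0, "group1_mean"] == pytest.approx(df[df.group == 1].rate.mean())
        assert out.loc[0, "group2_sd"] == pytest.approx(df[df.group == 2].rate.std(ddof=1))

    def test_singleton_group_p_undefined(self):
        df = pd.DataFrame({"group": [1, 2, 2], "rate": [0.9, 0.8, 0.85]})
        out = group_comparison(df, ["rate"])
        assert np.isnan(out.loc[0, "p_value"])

    def test_discrepant_anatomy_lowers_pass_rate(self):
        """Dose pairs from misaligned (Group 2) phantom anatomy agree less
        than pairs from aligned (Group 1) anatomy."""
        crit = GammaCriteria(dose_diff_percent=2, dta_mm=2, mode="global")
        rates = {1: [], 2: []}
        for seed in range(3):
            for group, level in ((1, 0.0), (2, 1.0)):
                spec = PhantomSpec(grid_size=64, discrepancy_level=level, seed=30 + seed)
                _, _, labels = generate_pair(spec)
                d_ct = generate_dose(spec, labels, source="ct")
                d_mr = generate_dose(spec, labels, source="mr")
                rates[group].append(gamma_index(d_ct, d_mr, crit).pass_rate)
        assert np.mean(rates[2]) <= np.mean(rates[1])
        assert all(r == 1.0 for r in rates[1])  # aligned anatomy: identical doses
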