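"""BED conversion and DVH metrics against brute-force voxel oracles."""

import numpy as np
import pytest

from pmapdose import (
    BinaryMask,
    DoseGrid,
    FractionationScheme,
    GridGeometry,
    compute_plan_metrics,
    cumulative_dvh,
    d_at_volume,
    dose_stats,
    ptv_coverage,
    to_bed,
    v_at_dose,
)
from pmapdose.dosimetry import EmptyStructureError

from conftest import random_dose_mask

FX = FractionationScheme(66.0, 33)


def uniform_pair(value, shape=(4, 4, 4)):
    geo = GridGeometry(shape, (1.0, 1.0, 1.0))
    return DoseGrid(geo, np.full(shape, float(value))), BinaryMask(geo, np.ones(shape, bool))


class TestBed:
    def test_zero_dose_maps_to_zero(self):
        d, _ = uniform_pair(0.0)
        assert np.all(to_bed(d, FX, 3.0).values == 0.0)

    def test_large_alpha_beta_limit_recovers_physical(self, rng):
        d, _ = random_dose_mask(rng)[0], None
        bed = to_bed(d, FX, 1e9)
        assert np.allclose(bed.values, d.values, rtol=1e-6)

    def test_closed_form_60gy_30fx(self):
        # 60 Gy in 30 fx at alpha/beta 10: 60 * (1 + 2/10) = 72 Gy
        d, _ = uniform_pair(60.0)
        bed = to_bed(d, FractionationScheme(60.0, 30), 10.0)
        assert np.allclose(bed.values, 72.0)

    def test_bed_dominates_physical_and_is_monotone(self, rng):
        d1, _ = random_dose_mask(rng)
        bed1 = to_bed(d1, FX, 3.0)
        assert np.all(bed1.values >= d1.values)
        d2 = DoseGrid(d1.geometry, d1.values + 5.0)
        assert np.all(to_bed(d2, FX, 3.0).values >= bed1.values)

    def test_parameter_errors(self):
        d, _ = uniform_pair(10.0)
        with pytest.raises(ValueError):
            to_bed(d, FX, 0.0)
        with pytest.raises(ValueError):
            FractionationScheme(60.0, 0)
        bed = to_bed(d, FX, 3.0)
        with pytest.raises(ValueError, match="physical"):
            to_bed(bed, FX, 3.0)


class TestCumulativeDvh:
    def test_uniform_dose_step(self):
        d, m = uniform_pair(10.0)
        curve = cumulative_dvh(d, m)
        assert d_at_volume(curve, 50.0) == pytest.approx(10.0, abs=0.1)
        k_below = np.searchsorted(curve.dose_edges, 10.0, side="right") - 1
        assert curve.cum_volume_fraction[k_below] == 1.0
        assert curve.cum_volume_fraction[-1] == 0.0

    def test_two_voxel_split(self):
        geo = GridGeometry((1, 1, 2), (1, 1, 1))
        d = DoseGrid(geo, np.array([[[0.0, 10.0]]]))
        m = BinaryMask(geo, np.ones((1, 1, 2), bool))
        curve = cumulative_dvh(d, m)
        k = np.searchsorted(curve.dose_edges, 5.0)
        assert curve.cum_volume_fraction[k] == pytest.approx(0.5)

    def test_matches_counting_oracle_on_random_grid(self, rng):
        d, m = random_dose_mask(rng, shape=(32, 32, 32))
        curve = cumulative_dvh(d, m, bin_width=0.5)
        doses = d.values[m.values]
        for k in rng.integers(0, curve.dose_edges.size, 20):
            expected = np.count_nonzero(doses >= curve.dose_edges[k]) / doses.size
            assert curve.cum_volume_fraction[k] == pytest.approx(expected, abs=1e-12)

    def test_empty_structure_error(self, geo16):
        d = DoseGrid(geo16, np.zeros(geo16.shape))
        empty = BinaryMask(geo16, np.zeros(geo16.shape, bool))
        with pytest.raises(EmptyStructureError, match="empty"):
            cumulative_dvh(d, empty)


class TestVAtDose:
    def test_boundaries(self, rng):
        d, m = random_dose_mask(rng)
        assert v_at_dose(d, m, 0.0) == 100.0
        assert v_at_dose(d, m, float(d.values.max()) + 1.0) == 0.0

    def test_matches_voxel_loop(self, rng):
        d, m = random_dose_mask(rng, shape=(24, 24, 24))
        expected = 100.0 * np.count_nonzero(d.values[m.values] >= 20.0) / m.voxel_count
        assert v_at_dose(d, m, 20.0) == pytest.approx(expected, abs=1e-12)

    def test_non_increasing_in_threshold(self, rng):
        d, m = random_dose_mask(rng)
        vals = [v_at_dose(d, m, x) for x in np.linspace(0, 75, 40)]
        assert all(a >= b for a, b in zip(vals, vals[1:]))


class TestDAtVolume:
    def test_uniform_dose(self):
        d, m = uniform_pair(10.0)
        curve = cumulative_dvh(d, m)
        assert d_at_volume(curve, 95.0) == pytest.approx(10.0, abs=0.1)
        assert d_at_volume(curve, 5.0) == pytest.approx(10.0, abs=0.1)

    def test_q100_is_minimum_dose(self, rng):
        d, m = random_dose_mask(rng)
        curve = cumulative_dvh(d, m)
        dmin = float(d.values[m.values].min())
        assert d_at_volume(curve, 100.0) == pytest.approx(dmin, abs=0.1)

    def test_within_bin_of_sort_quantile_oracle(self, rng):
        for _ in range(5):
            d, m = random_dose_mask(rng, shape=(20, 20, 20))
            curve = cumulative_dvh(d, m)
            doses = np.sort(d.values[m.values])[::-1]
            for q in (95.0, 50.0, 5.0):
                # dose received by at least q% of voxels: the ceil(qN/100)-th highest
                k = int(np.ceil(q / 100.0 * doses.size)) - 1
                assert d_at_volume(curve, q) == pytest.approx(doses[k], abs=0.1)

    def test_monotone_non_increasing_in_q(self, rng):
        d, m = random_dose_mask(rng)
        curve = cumulative_dvh(d, m)
        qs = np.linspace(1, 100, 34)
        vals = [d_at_volume(curve, q) for q in qs]
        assert all(a >= b - 1e-12 for a, b in zip(vals, vals[1:]))


class TestDoseStats:
    @pytest.mark.parametrize(
        "doses, expected",
        [([10.0, 10.0], (10.0, 10.0)), ([0.0, 20.0], (10.0, 20.0))],
    )
    def test_hand_cases(self, doses, expected):
        geo = GridGeometry((1, 1, 2), (1, 1, 1))
        d = DoseGrid(geo, np.array(doses).reshape(1, 1, 2))
        m = BinaryMask(geo, np.ones((1, 1, 2), bool))
        assert dose_stats(d, m) == pytest.approx(expected)

    def test_matches_voxel_loop(self, rng):
        d, m = random_dose_mask(rng, shape=(24, 24, 24))
        doses = d.values[m.values]
        mean, mx = dose_stats(d, m)
        assert mean == pytest.approx(float(np.sum(doses) / doses.size), abs=1e-9)
        assert mx == float(np.max(doses))
        assert float(np.min(doses)) <= mean <= mx


class TestPtvCoverage:
    def test_full_and_zero_coverage(self):
        d, m = uniform_pair(66.0)
        assert ptv_coverage(d, m, FX) == 100.0
        d_low, _ = uniform_pair(0.9 * 66.0)
        assert ptv_coverage(d_low, m, FX) == 0.0

    def test_painted_plan_matches_count(self, phantom, plan_pair, fx):
        d_ini, _ = plan_pair
        ptv = phantom["PTV"]
        expected = (
            100.0
            * np.count_nonzero(d_ini.values[ptv.values] >= 0.95 * fx.prescription_dose)
            / ptv.voxel_count
        )
        assert ptv_coverage(d_ini, ptv, fx) == pytest.approx(expected, abs=1e-12)


class TestPlanMetricsPanel:
    def test_zero_dose_plan(self, phantom):
        d = DoseGrid(phantom.geometry, np.zeros(phantom.geometry.shape))
        with pytest.warns(UserWarning, match="HIV"):
            panel = compute_plan_metrics(d, phantom, FX)
        assert panel.ptv95 == 0.0
        assert panel["LungH_V5"] == 0.0
        assert panel["2Lungs_Dmean"] == 0.0
        assert panel["SpinalCord_Dmax"] == 0.0
        assert panel.ic == 0.0
        assert np.isnan(panel.hiv)

    def test_fields_match_individual_operations(self, phantom, plan_pair, fx):
        d_ini, _ = plan_pair
        panel = compute_plan_metrics(d_ini, phantom, fx)
        assert panel["LungH_V20"] == v_at_dose(d_ini, phantom["LungH"], 20.0)
        assert panel["Heart_Dmean"] == dose_stats(d_ini, phantom["Heart"])[0]
        assert panel["SpinalCord_Dmax"] == dose_stats(d_ini, phantom["SpinalCord"])[1]
        assert panel.ptv95 == ptv_coverage(d_ini, phantom["PTV"], fx)
        bed = to_bed(d_ini, fx, 3.0)
        assert panel.dmean_pmap_bed == dose_stats(bed, phantom["Pmap"])[0]
        for voi, x in (("LungH", 5), ("LungH", 30), ("2Lungs", 13), ("Heart", 40)):
            assert 0.0 <= panel[f"{voi}_V{x}"] <= 100.0
        assert panel["LungH_Dmean"] <= panel["LungH_Dmax"]

    def test_pmap_mean_is_bed_not_physical(self, phantom, plan_pair, fx):
        d_ini, _ = plan_pair
        panel = compute_plan_metrics(d_ini, phantom, fx)
        physical_mean = dose_stats(d_ini, phantom["Pmap"])[0]
        assert panel.dmean_pmap_bed > physical_mean
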