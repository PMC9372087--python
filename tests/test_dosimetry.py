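"""DVH construction and dose-volume indices against voxel-counting closed forms."""

import numpy as np
import pytest

from contoureval.dosimetry import (
    cumulative_dvh,
    dose_at_volume,
    evaluate_dosimetry,
    mean_max_dose,
    metric_value,
    volume_at_dose,
)
from contoureval.grids import (
    BinaryMask,
    EmptyStructureError,
    Geometry,
    PlanConfig,
    StructureSet,
)


@pytest.fixture
def geom():
    return Geometry((10, 10, 4), (2.0, 2.0, 5.0))


def _grid(geom, values):
    from contoureval.grids import VolumeGrid

    return VolumeGrid(values, geom.spacing, geom.origin)


def _full(geom):
    return BinaryMask(geom, np.ones(geom.shape, bool))


class TestCumulativeDVH:
    def test_uniform_dose_is_step_function(self, geom):
        dose = _grid(geom, np.full(geom.shape, 4500.0))
        curve = cumulative_dvh(dose, _full(geom))
        at = lambda d: float(np.interp(d, curve.dose_edges, curve.cum_volume_pct))
        assert at(0) == 100.0
        assert at(4500) == 100.0
        assert curve.cum_volume_pct[-1] == 0.0

    def test_two_level_structure_is_50pct_between_levels(self, geom):
        vals = np.full(geom.shape, 1000.0)
        vals[5:] = 2000.0  # exactly half the voxels
        curve = cumulative_dvh(_grid(geom, vals), _full(geom))
        for d in (1001, 1500, 2000):
            i = np.searchsorted(curve.dose_edges, d)
            assert curve.cum_volume_pct[i] == pytest.approx(50.0)

    def test_edge_values_independent_of_bin_width(self, geom):
        rng = np.random.default_rng(0)
        dose = _grid(geom, rng.uniform(0, 3000, geom.shape))
        coarse = cumulative_dvh(dose, _full(geom), bin_width_cGy=10.0)
        fine = cumulative_dvh(dose, _full(geom), bin_width_cGy=5.0)
        # shared edges every 10 cGy have identical (count-based) values
        shared = coarse.dose_edges[coarse.dose_edges <= fine.dose_edges[-1]]
        c = dict(zip(coarse.dose_edges, coarse.cum_volume_pct))
        f = dict(zip(fine.dose_edges, fine.cum_volume_pct))
        for e in shared:
            assert c[e] == pytest.approx(f[e])

    def test_curve_non_increasing_starts_at_100(self, geom):
        rng = np.random.default_rng(1)
        dose = _grid(geom, rng.uniform(0, 500, geom.shape) + 1.0)
        curve = cumulative_dvh(dose, _full(geom))
        assert curve.cum_volume_pct[0] == 100.0
        assert (np.diff(curve.cum_volume_pct) <= 1e-12).all()

    def test_empty_mask_and_bad_bin_raise(self, geom):
        dose = _grid(geom, np.zeros(geom.shape))
        with pytest.raises(EmptyStructureError):
            cumulative_dvh(dose, BinaryMask(geom, np.zeros(geom.shape, bool)))
        with pytest.raises(ValueError):
            cumulative_dvh(dose, _full(geom), bin_width_cGy=0.0)


class TestDoseAtVolume:
    def test_uniform_dose_any_volume_is_that_dose(self, geom):
        curve = cumulative_dvh(_grid(geom, np.full(geom.shape, 1800.0)), _full(geom))
        for v in (0.03 / _full(geom).volume_cc * 100, 15.0, 50.0, 99.0):
            assert dose_at_volume(curve, volume_pct=v) == pytest.approx(1800.0, abs=1.0)

    def test_two_level_d50_is_hot_level(self, geom):
        vals = np.full(geom.shape, 1000.0)
        vals[5:] = 2000.0
        curve = cumulative_dvh(_grid(geom, vals), _full(geom))
        assert dose_at_volume(curve, volume_pct=50.0) == pytest.approx(2000.0, abs=1.0)

    def test_d100_is_minimum_dose(self, geom):
        rng = np.random.default_rng(2)
        vals = rng.uniform(500, 4000, geom.shape)
        curve = cumulative_dvh(_grid(geom, vals), _full(geom))
        assert dose_at_volume(curve, volume_pct=100.0) == pytest.approx(vals.min(), abs=1.0)

    def test_absolute_cc_spec(self, geom):
        vals = np.full(geom.shape, 1000.0)
        vals[5:] = 2000.0
        mask = _full(geom)
        curve = cumulative_dvh(_grid(geom, vals), mask)
        half_cc = mask.volume_cc / 2.0
        assert dose_at_volume(curve, volume_cc=half_cc) == pytest.approx(2000.0, abs=1.0)
        with pytest.raises(ValueError):
            dose_at_volume(curve, volume_cc=mask.volume_cc * 1.01)

    def test_exactly_one_spec_required(self, geom):
        curve = cumulative_dvh(_grid(geom, np.ones(geom.shape)), _full(geom))
        with pytest.raises(ValueError):
            dose_at_volume(curve)
        with pytest.raises(ValueError):
            dose_at_volume(curve, volume_pct=50.0, volume_cc=1.0)


class TestVolumeAtDose:
    def test_full_coverage_is_100(self, geom):
        plan = PlanConfig(prescription_cGy=4500.0)
        curve = cumulative_dvh(_grid(geom, np.full(geom.shape, 4600.0)), _full(geom))
        assert volume_at_dose(curve, dose_pct_rx=100.0, plan=plan) == pytest.approx(100.0)

    def test_zero_dose_gives_zero_coverage(self, geom):
        plan = PlanConfig(prescription_cGy=4500.0)
        curve = cumulative_dvh(_grid(geom, np.zeros(geom.shape)), _full(geom))
        assert volume_at_dose(curve, dose_pct_rx=100.0, plan=plan) == 0.0

    def test_fractional_coverage_counts_voxels(self):
        g = Geometry((10, 10, 1), (1, 1, 1))
        vals = np.zeros(g.shape)
        vals.ravel()[:94] = 5000.0  # 94 of 100 voxels at prescription
        from contoureval.grids import VolumeGrid

        curve = cumulative_dvh(VolumeGrid(vals, g.spacing), BinaryMask(g, np.ones(g.shape, bool)))
        plan = PlanConfig(prescription_cGy=5000.0)
        assert volume_at_dose(curve, dose_pct_rx=100.0, plan=plan) == pytest.approx(94.0)

    def test_percent_spec_needs_plan(self, geom):
        curve = cumulative_dvh(_grid(geom, np.ones(geom.shape)), _full(geom))
        with pytest.raises(ValueError):
            volume_at_dose(curve, dose_pct_rx=100.0)

    def test_round_trip_consistency(self, geom):
        rng = np.random.default_rng(3)
        vals = rng.uniform(0, 3000, geom.shape)
        curve = cumulative_dvh(_grid(geom, vals), _full(geom))
        for v in (15.0, 30.0, 50.0, 99.0):
            d = dose_at_volume(curve, volume_pct=v)
            assert volume_at_dose(curve, dose_cGy=d) >= v - 0.5  # within one bin


class TestMeanMax:
    def test_uniform_field(self, geom):
        dose = _grid(geom, np.full(geom.shape, 1200.0))
        assert mean_max_dose(dose, _full(geom)) == (1200.0, 1200.0)

    def test_hand_computed_mean_max(self):
        g = Geometry((3, 1, 1), (1, 1, 1))
        from contoureval.grids import VolumeGrid

        dose = VolumeGrid(np.array([0.0, 1000.0, 2000.0]).reshape(3, 1, 1), g.spacing)
        mean, mx = mean_max_dose(dose, BinaryMask(g, np.ones(g.shape, bool)))
        assert mean == pytest.approx(1000.0)
        assert mx == pytest.approx(2000.0)

    def test_mean_not_above_max_on_random_fields(self, geom):
        rng = np.random.default_rng(4)
        for _ in range(5):
            dose = _grid(geom, rng.uniform(0, 6000, geom.shape))
            mask = BinaryMask(geom, rng.random(geom.shape) < 0.5)
            if mask.is_empty():
                continue
            mean, mx = mean_max_dose(dose, mask)
            assert mean <= mx

    def test_mean_matches_dvh_integral(self, geom):
        rng = np.random.default_rng(5)
        dose = _grid(geom, rng.uniform(0, 3000, geom.shape))
        mask = _full(geom)
        mean, _ = mean_max_dose(dose, mask)
        curve = cumulative_dvh(dose, mask, bin_width_cGy=1.0)
        integral = np.trapezoid(curve.cum_volume_pct / 100.0, curve.dose_edges)
        assert mean == pytest.approx(integral, abs=1.0)


class TestEvaluateDosimetry:
    def _case(self, seed=0):
        import contoureval as ce

        img, manual = ce.generate_phantom(seed)
        plan = PlanConfig()
        dose = ce.synth_dose(manual, plan, seed=seed + 1)
        return dose, manual, plan

    def test_identical_sets_give_zero_deltas(self):
        dose, manual, plan = self._case()
        auto = StructureSet(dict(manual.structures), "auto")
        out = evaluate_dosimetry(dose, manual, auto, plan)
        wide = out.dropna(subset=["metric"]).pivot_table(
            index=["structure", "metric"], columns="provenance", values="value")
        assert np.allclose(wide["manual"], wide["auto"])

    def test_shift_into_low_dose_lowers_target_mean(self):
        dose, manual, plan = self._case(1)
        ctv = manual["CTV"]
        shifted = np.roll(ctv.voxels, 12, axis=1)  # push toward the dose falloff
        auto = StructureSet({"CTV": BinaryMask(ctv.geometry, shifted)}, "auto")
        out = evaluate_dosimetry(dose, manual, auto, plan)
        dmean = out[(out.structure == "CTV") & (out.metric == "Dmean")]
        m = dmean[dmean.provenance == "manual"].value.iloc[0]
        a = dmean[dmean.provenance == "auto"].value.iloc[0]
        assert a < m

    def test_manual_plan_meets_all_constraints(self):
        dose, manual, plan = self._case(2)
        out = evaluate_dosimetry(dose, manual, manual, plan)
        flags = out[(out.provenance == "manual") & out.constraint.notna()]
        assert len(flags) == len(plan.constraints)
        assert flags.constraint_pass.all()

    def test_missing_structure_flagged_not_fatal(self):
        dose, manual, plan = self._case(3)
        partial = StructureSet(
            {k: v for k, v in manual.structures.items() if k != "Rectum"}, "auto")
        out = evaluate_dosimetry(dose, manual, partial, plan)
        row = out[(out.structure == "Rectum") & (out.provenance == "auto")]
        assert (row.status == "missing").all()

    def test_structure_order_does_not_change_values(self):
        dose, manual, plan = self._case(4)
        reordered = StructureSet(dict(reversed(list(manual.structures.items()))), "auto")
        a = evaluate_dosimetry(dose, manual, manual, plan)
        b = evaluate_dosimetry(dose, manual, reordered, plan)
        key = ["structure", "provenance", "metric", "constraint"]
        merged = a.merge(b, on=key, suffixes=("_a", "_b"))
        assert np.allclose(merged.value_a.astype(float), merged.value_b.astype(float),
                           equal_nan=True)


class TestMetricShorthand:
    def test_all_table_metrics_parse(self, geom):
        dose = _grid(geom, np.full(geom.shape, 2000.0))
        mask = _full(geom)
        plan = PlanConfig(prescription_cGy=2000.0)
        for m in ("Dmean", "Dmax", "D99%", "D50%", "D30%", "D15%", "D0.03cc", "V100%"):
            v = metric_value(m, dose, mask, plan)
            expected = 100.0 if m == "V100%" else 2000.0
            assert v == pytest.approx(expected, abs=1.0)

    def test_unknown_metric_rejected(self, geom):
        dose = _grid(geom, np.ones(geom.shape))
        with pytest.raises(ValueError):
            metric_value("Q7", dose, _full(geom), PlanConfig())
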