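"""Field-in-field weight algebra and the two-step planning scheme."""

import numpy as np
import pytest

import fifplan as fp
from fifplan.engine import EngineConfig
from fifplan.metrics import compute_dvh, dose_at_volume, volume_at_dose
from fifplan.planner import FIFConfig, build_step1_plan, build_step2_plan, evaluate_step1, step1_weights


class TestStep1Weights:
    def test_cohort_average_weight_split(self):
        """D_max = 107.3%, D_th = 105% reproduces the reported average
        main/sub weight split 0.979 / 0.021."""
        f, w_main, w_sub = step1_weights(107.3, 105.0, 1.0)
        assert round(w_main, 3) == 0.979
        assert round(w_sub, 3) == 0.021
        assert np.isclose(w_main, 105.0 / 107.3)

    def test_no_hotspot_is_noop(self):
        assert step1_weights(105.0, 105.0, 1.0) == (0.0, 1.0, 0.0)
        assert step1_weights(101.0, 105.0, 0.7) == (0.0, 0.7, 0.0)

    @pytest.mark.parametrize("d_max,w", [(107.3, 1.0), (110.0, 0.5), (120.0, 2.0)])
    def test_weight_conservation_and_bounds(self, d_max, w):
        f, w_main, w_sub = step1_weights(d_max, 105.0, w)
        assert 0 < f < 1
        assert w_main + w_sub == pytest.approx(w, abs=1e-12)
        assert w_main > 0 and w_sub > 0
        assert f == pytest.approx((d_max - 105.0) / d_max)

    def test_blocked_dose_reduced_by_f_on_linear_toy(self):
        """Two-point toy under a transmission-free linear engine: the blocked
        point's dose drops by exactly the factor (1 - f)."""
        d_max, d_th = 110.0, 105.0
        f, w_main, w_sub = step1_weights(d_max, d_th, 1.0)
        unit_dose_hot = d_max  # unit-weight main beam dose at the hotspot
        blocked = w_main * unit_dose_hot  # sub-beam contributes nothing there
        assert blocked == pytest.approx((1 - f) * unit_dose_hot)
        assert blocked == pytest.approx(d_th)
        unit_dose_cold = 100.0
        unblocked = w_main * unit_dose_cold + w_sub * unit_dose_cold
        assert unblocked == pytest.approx(unit_dose_cold, abs=1e-12)

    def test_invalid_threshold(self):
        with pytest.raises(ValueError):
            step1_weights(107.0, 0.0)


class TestStep2Algebra:
    def test_intermediate_threshold_midpoint(self):
        assert (107.8 + 105.0) / 2 == pytest.approx(106.4)  # the printed example
        eps = 1e-6
        assert (105.0 + 2 * eps + 105.0) / 2 == pytest.approx(105.0 + eps)

    def test_reconstructed_four_subbeam_split_matches_report(self):
        """With D_max ~ 107.8 and an intermediate-plan maximum ~ 106.5 the
        reconstructed weights agree with the reported FIF-4SF split
        0.973 / 0.013 / 0.014 (consistency illustration, hence tolerances)."""
        d_max, d_th = 107.8, 105.0
        d_ith = (d_max + d_th) / 2
        _, w_main_fif, w_sub1 = step1_weights(d_max, d_ith, 1.0)
        w_ithmax = 106.5
        w_main_2nd = w_main_fif * d_th / w_ithmax
        w_sub2 = w_main_fif - w_main_2nd
        assert w_main_2nd == pytest.approx(0.973, abs=0.002)
        assert w_sub1 == pytest.approx(0.013, abs=0.001)
        assert w_sub2 == pytest.approx(0.014, abs=0.002)


class TestEvaluateStep1:
    def test_identical_doses(self, head, dose_original):
        _, _, ptv = head
        assert evaluate_step1(dose_original, dose_original, ptv) == 0.0

    def test_uniform_shift(self, head, dose_original):
        _, _, ptv = head
        shifted = fp.DoseGrid(dose_original.data - 2.0, dose_original.origin, dose_original.spacing)
        assert evaluate_step1(dose_original, shifted, ptv) == pytest.approx(2.0)

    def test_matches_sorted_percentile_oracle(self, head, dose_original):
        _, _, ptv = head
        rng = np.random.default_rng(4)
        other = fp.DoseGrid(
            dose_original.data * rng.uniform(0.97, 1.0, size=dose_original.shape),
            dose_original.origin,
            dose_original.spacing,
        )
        def oracle_d95(dose):
            v = np.sort(dose.data[ptv.data])[::-1]
            return v[int(np.ceil(0.95 * v.size)) - 1]
        expected = oracle_d95(dose_original) - oracle_d95(other)
        assert evaluate_step1(dose_original, other, ptv) == pytest.approx(expected, abs=1e-12)


class TestStep1EndToEnd:
    def test_plan_structure(self, fif_result):
        plan = fif_result.step1.plan
        assert len(plan.beams) == 4
        roles = sorted(b.role for b in plan.beams)
        assert roles == ["main", "main", "sub1", "sub1"]
        subs = plan.sub_beams()
        mains = plan.main_beams()
        # sub weights complement the reduced mains
        for m, s in zip(mains, subs):
            assert m.weight + s.weight == pytest.approx(1.0, abs=1e-12)
            assert s.weight > 0
            assert s.geometry == m.geometry
            assert not np.array_equal(s.aperture.right_tips, m.aperture.right_tips) or not np.array_equal(s.aperture.left_tips, m.aperture.left_tips)

    def test_hotspots_removed(self, head, fif_result, dose_original):
        _, _, ptv = head
        v105_before = volume_at_dose(compute_dvh(dose_original, ptv), 105.0)
        v105_after = volume_at_dose(compute_dvh(fif_result.step1.dose, ptv), 105.0)
        assert v105_before > 1.0
        assert v105_after <= 0.2

    def test_unblocked_doses_conserved_without_transmission(self, head, original_plan, engine, dose_original):
        """The closed-form weight contract: with zero MLC transmission the
        pre-normalization dose is bit-level unchanged wherever both sub-beams
        are open, and reduced in the blocked shadow."""
        density, _, ptv = head
        eng0 = engine.variant(EngineConfig(transmission=0.0))
        cfg = FIFConfig(engine=eng0.cfg)
        dose0, _ = eng0.plan_dose(original_plan)
        res = build_step1_plan(original_plan, dose0, density, ptv, cfg, eng0)
        raw_before = sum(eng0.beam_dose(b).data for b in original_plan.beams)
        raw_after = sum(eng0.beam_dose(b).data for b in res.plan.beams)
        from fifplan.geometry import dcs_to_bev
        open_everywhere = np.ones(ptv.data.sum(), dtype=bool)
        centers = ptv.voxel_centers(ptv.data)
        for b in res.plan.sub_beams():
            bev = dcs_to_bev(centers, b.geometry)
            open_everywhere &= b.aperture.is_open(bev[:, 0], bev[:, 1])
        before = raw_before[ptv.data]
        after = raw_after[ptv.data]
        assert np.allclose(after[open_everywhere], before[open_everywhere], atol=1e-9)
        assert np.all(after[~open_everywhere] < before[~open_everywhere])

    def test_former_hotspot_maximum_pulled_to_threshold(self, head, original_plan, engine):
        density, _, ptv = head
        eng0 = engine.variant(EngineConfig(transmission=0.0))
        cfg = FIFConfig(engine=eng0.cfg)
        dose0, _ = eng0.plan_dose(original_plan)
        res = build_step1_plan(original_plan, dose0, density, ptv, cfg, eng0)
        hot = fp.find_hotspots(dose0, cfg.d_th, within=ptv)
        assert res.dose.data[hot.data].max() <= cfg.d_th + 0.5

    def test_no_hotspot_returns_original_with_notice(self, head, original_plan, engine, dose_original):
        density, _, ptv = head
        cfg = FIFConfig(d_th=200.0)
        res = build_step1_plan(original_plan, dose_original, density, ptv, cfg, engine)
        assert not res.applied
        assert res.plan is original_plan
        assert "unnecessary" in res.notice


class TestAutoFIF:
    def test_default_conditions_select_two_subbeam_scheme(self, fif_result):
        assert fif_result.report.scheme == "FIF"
        assert fif_result.report.delta_d95_step1 <= 1.0
        assert len(fif_result.plan.beams) == 4

    def test_no_hotspot_selects_none(self, head, original_plan, engine, dose_original):
        density, _, ptv = head
        res = fp.autofif(
            original_plan, density, ptv, FIFConfig(d_th=200.0), engine=engine, dose_orig=dose_original
        )
        assert res.report.scheme == "none"
        assert res.plan is original_plan

    def test_severe_conditions_escalate_to_four_subbeams(self, severe_result):
        rep = severe_result.report
        assert rep.scheme == "FIF-4SF"
        assert rep.delta_d95_step1 > 1.0
        assert rep.delta_d95_final < rep.delta_d95_step1
        assert len(severe_result.plan.beams) == 6
        roles = sorted(b.role for b in severe_result.plan.beams)
        assert roles == ["main", "main", "sub1", "sub1", "sub2", "sub2"]

    def test_zero_criterion_forces_escalation_when_d95_drops(self, head, original_plan, engine, severe_cfg):
        density, _, ptv = head
        eng = engine.variant(severe_cfg.engine)
        cfg = FIFConfig(d_th=severe_cfg.d_th, criterion_pp=0.0, engine=severe_cfg.engine)
        res = fp.autofif(original_plan, density, ptv, cfg, engine=eng)
        assert (res.report.scheme == "FIF-4SF") == (res.report.delta_d95_step1 > 0.0)

    def test_report_weight_table_consistent(self, fif_result):
        weights = {w["id"]: w["weight"] for w in fif_result.report.weights}
        for b in fif_result.plan.beams:
            assert weights[b.id] == pytest.approx(b.weight)
        assert all(w["weight"] >= 0 for w in fif_result.report.weights)
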