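"""Frame-resolved screw errors and SME/MAE/2SD statistics."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from screwsight.core import RigidTransform
from screwsight.detection import DetectedScrew, ScrewPlan
from screwsight.frames import EndplatePlane, MidPedicleLocus, build_screw_frame
from screwsight.metrics import (
    AccuracyRecord,
    angular_deviation,
    bonferroni,
    regional_comparison,
    region_of_level,
    screw_errors,
    summarize,
)


def _scene(side="L", tail=(-10.0, -26.0, 0.0), axis=(0.0, 1.0, 0.0), length=35.0):
    tail = np.asarray(tail, float)
    axis = np.asarray(axis, float) / np.linalg.norm(axis)
    plan = ScrewPlan(level="T7", side=side, tail=tail, tip=tail + axis * length,
                     radius=2.25, length=length)
    frame = build_screw_frame(plan, EndplatePlane(point=(0, 0, -11), normal=(0, 0, 1)))
    locus = MidPedicleLocus(point=tail + 12.0 * axis, arc_param=12.0,
                            wall_distance=2.0)
    return plan, frame, locus


class TestAngularDeviation:
    def test_parallel_is_zero(self):
        assert angular_deviation((0, 0, 1), (0, 0, 1)) == 0.0

    def test_orthogonal_is_ninety(self):
        assert angular_deviation((1, 0, 0), (0, 1, 0)) == pytest.approx(90.0)

    def test_constructed_small_angle(self):
        a = (0.0, 0.0, 1.0)
        th = np.radians(1.58)
        b = (0.0, np.sin(th), np.cos(th))
        assert angular_deviation(a, b) == pytest.approx(1.58, abs=1e-9)

    def test_symmetric(self):
        a, b = (1, 0, 0), (0.6, 0.8, 0)
        assert angular_deviation(a, b) == angular_deviation(b, a)

    def test_zero_vector_rejected(self):
        with pytest.raises(ValueError):
            angular_deviation((0, 0, 0), (1, 0, 0))


class TestScrewErrors:
    def test_exact_placement_all_zero(self):
        plan, frame, locus = _scene()
        det = DetectedScrew(tip=plan.tip, tail=plan.tail, fit_score=1.0)
        rec = screw_errors(plan, det, RigidTransform.identity(), frame, locus)
        for col in ("tail_ml", "tail_ap", "tail_si", "tip_ml", "tip_ap", "tip_si",
                    "mid_ml", "mid_si"):
            assert getattr(rec, col) == pytest.approx(0.0, abs=1e-9)
        assert rec.angle_deg == pytest.approx(0.0, abs=1e-9)

    def test_pure_ml_offset(self):
        plan, frame, locus = _scene(side="L")
        off = 1.0 * frame.e_ml
        det = DetectedScrew(tip=plan.tip + off, tail=plan.tail + off, fit_score=1.0)
        rec = screw_errors(plan, det, RigidTransform.identity(), frame, locus)
        assert rec.tail_ml == pytest.approx(1.0, abs=1e-9)
        assert rec.tip_ml == pytest.approx(1.0, abs=1e-9)
        assert rec.mid_ml == pytest.approx(1.0, abs=1e-9)
        for col in ("tail_ap", "tail_si", "tip_ap", "tip_si", "mid_si"):
            assert getattr(rec, col) == pytest.approx(0.0, abs=1e-9)
        assert rec.angle_deg == pytest.approx(0.0, abs=1e-9)

    def test_two_degree_rotation_about_si_through_tail(self):
        plan, frame, locus = _scene(side="L")
        th = np.radians(2.0)
        R = RigidTransform.from_rotvec(frame.e_si * th, center=plan.tail)
        det = DetectedScrew(tip=R.apply(plan.tip), tail=plan.tail, fit_score=1.0)
        rec = screw_errors(plan, det, RigidTransform.identity(), frame, locus)
        assert rec.angle_deg == pytest.approx(2.0, abs=1e-6)
        assert abs(rec.tip_ml) == pytest.approx(plan.length * np.sin(th), rel=1e-3)
        assert abs(rec.mid_ml) == pytest.approx(locus.arc_param * np.tan(th), rel=1e-2)
        assert rec.tail_ml == pytest.approx(0.0, abs=1e-9)

    def test_equivariance_under_registration_transform(self, rng):
        """Moving the postop scene rigidly does not change resolved errors."""
        plan, frame, locus = _scene(side="R", tail=(10.0, -26.0, 0.0))
        off = 0.7 * frame.e_ml - 0.4 * frame.e_si
        det0 = DetectedScrew(tip=plan.tip + off, tail=plan.tail + off, fit_score=1.0)
        rec0 = screw_errors(plan, det0, RigidTransform.identity(), frame, locus)
        T = RigidTransform.from_rotvec(rng.normal(size=3) * 0.1,
                                       rng.normal(size=3) * 8)
        det1 = DetectedScrew(tip=T.apply(det0.tip), tail=T.apply(det0.tail),
                             fit_score=1.0)
        rec1 = screw_errors(plan, det1, T, frame, locus)
        for col in ("tail_ml", "tail_ap", "tail_si", "tip_ml", "tip_ap",
                    "tip_si", "mid_ml", "mid_si", "angle_deg"):
            assert getattr(rec1, col) == pytest.approx(getattr(rec0, col), abs=1e-9)

    def test_axis_parallel_to_plane_raises(self):
        from screwsight.frames import NoIntersectionError

        plan, frame, locus = _scene()
        det = DetectedScrew(tip=plan.tail + 35.0 * frame.e_si, tail=plan.tail,
                            fit_score=1.0)
        with pytest.raises(NoIntersectionError):
            screw_errors(plan, det, RigidTransform.identity(), frame, locus)


def _record(level="T7", side="L", **kw):
    base = dict(tail_ml=0.0, tail_ap=0.0, tail_si=0.0, tip_ml=0.0, tip_ap=0.0,
                tip_si=0.0, mid_ml=0.0, mid_si=0.0, angle_deg=0.0)
    base.update(kw)
    return AccuracyRecord(level=level, side=side, **base)


class TestRecordInvariants:
    def test_euclidean_bounds(self, rng):
        for _ in range(50):
            vals = rng.normal(size=3)
            r = _record(tail_ml=vals[0], tail_ap=vals[1], tail_si=vals[2])
            assert r.tail_3d >= max(abs(v) for v in vals) - 1e-12
            assert r.tail_3d <= sum(abs(v) for v in vals) + 1e-12

    def test_region_assignment(self):
        assert region_of_level("T2") == "upper thoracic"
        assert region_of_level("T6") == "upper thoracic"
        assert region_of_level("T7") == "lower thoracic"
        assert region_of_level("T12") == "lower thoracic"
        assert region_of_level("L1") == "lumbar"
        assert region_of_level("L4") == "lumbar"


class TestSummarize:
    def test_plus_minus_one(self):
        recs = [_record(tail_ml=1.0), _record(tail_ml=-1.0)]
        s = summarize(recs)["all"]
        assert s.sme["tail_ml"] == pytest.approx(0.0)
        assert s.mae["tail_ml"] == pytest.approx(1.0)
        assert s.precision["tail_ml"] == pytest.approx(2 * np.sqrt(2.0))

    def test_all_zero(self):
        s = summarize([_record(), _record()])["all"]
        assert s.sme["tip_ml"] == 0.0
        assert s.mae["tip_ml"] == 0.0
        assert s.precision["tip_ml"] == 0.0

    def test_matches_declared_deviations_passthrough(self, rng):
        """A stubbed perfect pipeline: summary equals statistics of the
        planted deviations exactly."""
        devs = rng.normal(0, 1.2, size=20)
        recs = [_record(mid_ml=d) for d in devs]
        s = summarize(recs)["all"]
        assert s.sme["mid_ml"] == pytest.approx(devs.mean(), abs=1e-9)
        assert s.mae["mid_ml"] == pytest.approx(np.abs(devs).mean(), abs=1e-9)
        assert s.precision["mid_ml"] == pytest.approx(2 * devs.std(ddof=1), abs=1e-9)

    def test_single_record_precision_undefined(self):
        s = summarize([_record()])["all"]
        assert np.isnan(s.precision["tail_ml"])

    def test_euclidean_columns_mae_only(self):
        s = summarize([_record(tail_ml=1.0), _record(tail_ml=2.0)])["all"]
        assert "tail_3d" in s.mae
        assert "tail_3d" not in s.sme
        assert "tail_3d" not in s.precision

    def test_permutation_invariance(self, rng):
        recs = [_record(tip_si=v) for v in rng.normal(size=9)]
        s1 = summarize(recs)["all"]
        s2 = summarize(list(rng.permutation(recs)))["all"]
        for c in s1.sme:
            assert s2.sme[c] == pytest.approx(s1.sme[c], abs=1e-12)
            assert s2.mae[c] == pytest.approx(s1.mae[c], abs=1e-12)

    def test_mae_dominates_abs_sme(self, rng):
        for seed in range(5):
            r = np.random.default_rng(seed)
            recs = [_record(tail_ap=v) for v in r.normal(0.3, 1.0, size=12)]
            s = summarize(recs)["all"]
            for c in s.sme:
                assert s.mae[c] >= abs(s.sme[c]) - 1e-12

    @settings(max_examples=60, derandomize=True, deadline=None)
    @given(
        vals=st.lists(
            st.floats(-10.0, 10.0, allow_nan=False), min_size=2, max_size=30
        )
    )
    def test_summary_invariants_property(self, vals):
        """MAE >= |SME| and precision >= 0 for any signed error sample."""
        recs = [_record(mid_ml=v) for v in vals]
        s = summarize(recs)["all"]
        assert s.mae["mid_ml"] >= abs(s.sme["mid_ml"]) - 1e-12
        assert s.precision["mid_ml"] >= 0.0

    def test_by_region_grouping(self):
        recs = [_record(level="T3"), _record(level="T9"), _record(level="L2")]
        s = summarize(recs, group="region")
        assert set(s) == {"upper thoracic", "lower thoracic", "lumbar"}
        assert all(v.n == 1 for v in s.values())


class TestRegionalComparison:
    def test_null_calibration(self):
        """Three regions drawn from one distribution: ANOVA p exceeds 0.05
        in at least 90% of seeded replicates."""
        n_ok = 0
        for seed in range(100):
            rng = np.random.default_rng(seed)
            recs = []
            for lvl, n in (("T3", 10), ("T9", 10), ("L2", 10)):
                recs += [_record(level=lvl, mid_ml=v)
                         for v in rng.normal(0, 1, size=n)]
            out = regional_comparison(recs, "mid_ml")
            n_ok += out["anova_p"] > 0.05
        assert n_ok >= 90

    def test_planted_effect_detected(self):
        rng = np.random.default_rng(0)
        recs = [_record(level="T3", mid_ml=v) for v in rng.normal(0, 0.01, 8)]
        recs += [_record(level="T9", mid_ml=1 + v) for v in rng.normal(0, 0.01, 8)]
        recs += [_record(level="L2", mid_ml=v) for v in rng.normal(0, 0.01, 8)]
        out = regional_comparison(recs, "mid_ml")
        assert out["anova_p"] < 0.01
        worst = [p for p in out["pairwise"]
                 if set(p["groups"]) == {"lower thoracic", "upper thoracic"}][0]
        assert worst["p_bonferroni"] < 0.01

    def test_bonferroni_multiplies_and_caps(self):
        assert bonferroni([0.01, 0.2, 0.5]) == pytest.approx([0.03, 0.6, 1.0])

    def test_missing_region_warned(self):
        rng = np.random.default_rng(1)
        recs = [_record(level="T3", mid_ml=v) for v in rng.normal(size=5)]
        recs += [_record(level="T9", mid_ml=v) for v in rng.normal(size=5)]
        recs += [_record(level="L1", mid_ml=0.0)]  # n=1, dropped
        out = regional_comparison(recs, "mid_ml")
        assert out["warnings"]
        assert set(out["group_n"]) == {"upper thoracic", "lower thoracic"}
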