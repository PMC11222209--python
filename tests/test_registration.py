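"""Rigid registration: SVD alignment, mutual information, refinement,
perturbation analysis."""

import numpy as np
import pytest

import screwsight as ss
from screwsight.core import CTVolume, LabelMask, RigidTransform, mask_centroid
from screwsight.registration import (
    DegenerateLandmarksWarning,
    InsufficientPointsError,
    RefinementProblem,
    RegistrationError,
    mutual_information,
    perturbation_analysis,
    random_perturbation,
    svd_point_align,
    transform_discrepancy,
)


class TestSvdPointAlign:
    def test_identity_when_target_equals_source(self, rng):
        pts = rng.normal(size=(5, 3)) * 20
        T = svd_point_align(pts, pts)
        assert np.allclose(T.rotation, np.eye(3), atol=1e-9)
        assert np.allclose(T.translation, 0, atol=1e-9)

    @pytest.mark.parametrize("seed", range(10))
    def test_recovers_random_rigid_transform(self, seed):
        rng = np.random.default_rng(seed)
        src = rng.normal(size=(4, 3)) * 30
        T_true = RigidTransform.from_rotvec(rng.normal(size=3),
                                            rng.normal(size=3) * 10)
        T = svd_point_align(src, T_true.apply(src))
        assert np.allclose(T.as_matrix(), T_true.as_matrix(), atol=1e-9)

    def test_reflected_target_still_proper_rotation(self):
        src = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1.0]])
        dst = src * np.array([-1.0, 1.0, 1.0])  # mirrored
        T = svd_point_align(src, dst)
        assert np.linalg.det(T.rotation) == pytest.approx(1.0, abs=1e-9)

    def test_too_few_points(self):
        with pytest.raises(InsufficientPointsError):
            svd_point_align([[0, 0, 0]], [[1, 0, 0]])

    def test_collinear_points_warn(self):
        src = np.array([[0, 0, 0], [1, 0, 0], [2, 0, 0.0]])
        with pytest.warns(DegenerateLandmarksWarning):
            svd_point_align(src, src + [0, 1, 0])

    def test_matches_small_angle_grid_search(self):
        """Oracle: exhaustive small-angle grid search on a 3-point problem."""
        rng = np.random.default_rng(7)
        src = rng.normal(size=(3, 3)) * 10
        T_true = RigidTransform.from_rotvec([0.02, -0.03, 0.04], [1.0, -0.5, 2.0])
        dst = T_true.apply(src)

        def cost(rv):
            R = RigidTransform.from_rotvec(rv).rotation
            t = dst.mean(0) - R @ src.mean(0)
            return np.sum((src @ R.T + t - dst) ** 2)

        grid = np.linspace(-0.06, 0.06, 13)
        best = min(
            ((rx, ry, rz) for rx in grid for ry in grid for rz in grid),
            key=cost,
        )
        T = svd_point_align(src, dst)
        from scipy.spatial.transform import Rotation

        rv_fit = Rotation.from_matrix(T.rotation).as_rotvec()
        assert np.allclose(rv_fit, best, atol=0.01)  # grid resolution


def _masked_volume(rng, shape=(16, 18, 20)):
    data = rng.normal(300, 120, size=shape).astype(np.float32)
    labels = np.zeros(shape, dtype=np.int16)
    labels[3:12, 4:14, 5:16] = 1
    vol = CTVolume(data, np.diag([0.5, 0.5, 0.625, 1.0]))
    mask = LabelMask(labels, vol.affine, {1: "T7"})
    return vol, mask


class TestMutualInformation:
    def test_self_mi_equals_masked_entropy(self, rng):
        """Oracle: MI of a volume with itself under a full mask is the
        histogram entropy (identical binning on both axes makes the joint
        histogram diagonal)."""
        vol, _ = _masked_volume(rng)
        mask = LabelMask(np.ones(vol.shape, np.int16), vol.affine, {1: "T7"})
        mi = mutual_information(vol, vol, RigidTransform.identity(), mask, 1,
                               n_bins=32)
        vals = vol.data[mask.labels == 1].astype(np.float64)
        lo, hi = vals.min(), vals.max()
        bins = np.clip(((vals - lo) / (hi - lo) * 32).astype(int), 0, 31)
        p = np.bincount(bins, minlength=32) / len(bins)
        entropy = -np.sum(p[p > 0] * np.log(p[p > 0]))
        assert mi == pytest.approx(entropy, abs=1e-9)

    def test_constant_moving_volume_gives_zero(self, rng):
        vol, mask = _masked_volume(rng)
        flat = CTVolume(np.full(vol.shape, 100.0, np.float32), vol.affine)
        mi = mutual_information(vol, flat, RigidTransform.identity(), mask, 1)
        assert mi == pytest.approx(0.0, abs=1e-12)

    def test_consistent_permutation_invariance(self, rng):
        """Shuffling voxels identically in both volumes leaves MI unchanged."""
        vol, mask = _masked_volume(rng)
        mov = CTVolume(rng.normal(500, 80, size=vol.shape).astype(np.float32),
                       vol.affine)
        mi0 = mutual_information(vol, mov, RigidTransform.identity(), mask, 1)
        perm = rng.permutation(np.prod(vol.shape))
        # permute along a fixed flat order; the joint histogram is identical
        v2 = CTVolume(vol.data.reshape(-1)[perm].reshape(vol.shape), vol.affine)
        m2 = CTVolume(mov.data.reshape(-1)[perm].reshape(vol.shape), vol.affine)
        l2 = LabelMask(mask.labels.reshape(-1)[perm].reshape(vol.shape),
                       vol.affine, {1: "T7"})
        mi1 = mutual_information(v2, m2, RigidTransform.identity(), l2, 1)
        assert mi1 == pytest.approx(mi0, abs=1e-9)

    def test_metal_exclusion_drops_voxels(self, rng):
        vol, mask = _masked_volume(rng)
        mov = CTVolume(vol.data.copy(), vol.affine)
        mov.data[5:8, 6:9, 7:10] = 4000.0
        full = mutual_information(vol, mov, RigidTransform.identity(), mask, 1)
        excl = mutual_information(vol, mov, RigidTransform.identity(), mask, 1,
                                  moving_exclusion_threshold=2100.0)
        assert np.isfinite(excl) and excl != pytest.approx(full)

    def test_empty_overlap_raises(self, rng):
        vol, mask = _masked_volume(rng)
        far = RigidTransform(np.eye(3), np.array([500.0, 0.0, 0.0]))
        with pytest.raises(RegistrationError):
            mutual_information(vol, vol, far, mask, 1)

    def test_too_few_bins_rejected(self, rng):
        vol, mask = _masked_volume(rng)
        with pytest.raises(ValueError):
            mutual_information(vol, vol, RigidTransform.identity(), mask, 1,
                               n_bins=1)


class TestTransformDiscrepancy:
    def test_equal_transforms(self):
        T = RigidTransform.from_rotvec([0.1, 0, 0.2], [1, 2, 3])
        td, rd = transform_discrepancy(T, T, (10, 0, 0))
        assert td == pytest.approx(0.0, abs=1e-12)
        assert rd == pytest.approx(0.0, abs=1e-9)

    def test_pure_translation_offset(self):
        T2 = RigidTransform.from_rotvec([0.05, 0.1, 0], [3, 1, 0])
        T1 = RigidTransform(np.eye(3), np.array([2.0, 0, 0])).compose(T2)
        td, rd = transform_discrepancy(T1, T2, (5.0, 5.0, 5.0))
        assert td == pytest.approx(2.0, abs=1e-9)
        assert rd == pytest.approx(0.0, abs=1e-9)

    def test_rotation_about_reference_point(self):
        ref = np.array([4.0, -3.0, 7.0])
        T2 = RigidTransform.from_rotvec([0, 0.02, 0.01], [1, 1, 1])
        R = RigidTransform.from_rotvec([0, 0, np.radians(2.0)], center=ref)
        T1 = R.compose(T2)
        td, rd = transform_discrepancy(T1, T2, ref)
        assert td == pytest.approx(0.0, abs=1e-9)
        assert rd == pytest.approx(2.0, abs=1e-9)


class TestRegisterLevel:
    def test_self_registration_is_identity(self, clean_spec, clean_preop):
        """Registering a level to an unmoved copy of itself stays at identity."""
        pre, mask, plans, gt = clean_preop
        pairs = [
            (p, ss.DetectedScrew(tip=p.tip, tail=p.tail, fit_score=1.0,
                                 level=p.level, side=p.side))
            for p in plans
        ]
        thr = clean_spec.metal_threshold
        res = ss.register_level(pre, mask, "T7", pre, pairs, thr)
        c = mask_centroid(mask, 1)
        td, rd = transform_discrepancy(res.T, RigidTransform.identity(), c)
        assert td < 0.05
        assert rd < 0.05

    def test_known_motion_recovered_with_subvoxel_bead_error(self, analyzed, spec):
        rep = analyzed.fiducial_report
        assert rep.mae_mm < spec.spacing[2]  # below one axial voxel

    def test_mi_final_not_below_init(self, analyzed):
        for reg in analyzed.registrations.values():
            assert reg.mi_final >= reg.mi_init

    def test_determinism(self, spec, preop_case, postop_case, analyzed):
        pre, mask, plans, _ = preop_case
        post, gt, _, _ = postop_case
        pairs = list(zip([p for p, _ in analyzed.matches.pairs],
                         analyzed.detections))
        r1 = ss.register_level(pre, mask, "T7", post, pairs, spec.metal_threshold)
        r2 = ss.register_level(pre, mask, "T7", post, pairs, spec.metal_threshold)
        assert np.array_equal(r1.T.as_matrix(), r2.T.as_matrix())
        assert r1.mi_final == r2.mi_final

    def test_reverse_registration_converges_to_inverse(
        self, spec, preop_case, postop_case, analyzed
    ):
        """B->A refinement started at inverse(T) stays at the inverse."""
        from screwsight.core import resample_mask

        pre, mask, plans, _ = preop_case
        post, gt, _, _ = postop_case
        T = analyzed.registrations["T7"].T
        mask_post = resample_mask(mask, T, post)
        problem = RefinementProblem(
            post, mask_post, "T7", pre, metal_threshold=np.inf,
        )
        T_rev, _, _, _ = problem.refine(T.inverse())
        c = mask_centroid(mask_post, 1)
        td, rd = transform_discrepancy(T_rev, T.inverse(), c)
        assert td < 0.3
        assert rd < 0.3

    def test_single_screw_level_degenerate_flagged(
        self, spec, preop_case, postop_case, analyzed
    ):
        pre, mask, plans, _ = preop_case
        post, gt, _, _ = postop_case
        pairs = [
            (p, d)
            for (p, _), d in zip(analyzed.matches.pairs, analyzed.detections)
            if p.side == "L"
        ]
        res = ss.register_level(
            pre, mask, "T7", post, pairs, spec.metal_threshold,
            problem=analyzed.problems["T7"],
        )
        assert res.degenerate_init
        c = mask_centroid(mask, 1)
        td, rd = transform_discrepancy(res.T, analyzed.registrations["T7"].T, c)
        assert td < 0.5  # still lands at the same optimum

    def test_no_matched_screws_raises(self, spec, preop_case, postop_case):
        pre, mask, _, _ = preop_case
        post, _, _, _ = postop_case
        with pytest.raises(RegistrationError):
            ss.register_level(pre, mask, "T7", post, [], spec.metal_threshold)


class TestPerturbationAnalysis:
    @staticmethod
    def _baseline_identity(centroid):
        from screwsight.registration import RegistrationResult

        T = RigidTransform.identity()
        return RegistrationResult(
            level="T7", T=T, mi_final=0.0, init_T=T, converged=True, n_iterations=0
        )

    def test_identity_stub_reports_applied_magnitudes(self):
        class FakeProblem:
            centroid = np.array([1.0, 2.0, 3.0])

        problem = FakeProblem()
        baseline = self._baseline_identity(problem.centroid)
        rep = perturbation_analysis(
            problem, baseline, n=10, rot_deg=2.0, trans_mm=2.0, seed=5,
            refine_fn=lambda T0: T0,  # no re-convergence
        )
        assert np.allclose(rep.translation_discrepancies_mm, 2.0, atol=1e-9)
        assert np.allclose(rep.rotation_discrepancies_deg, 2.0, atol=1e-9)

    def test_zero_replicates_empty_report(self):
        class FakeProblem:
            centroid = np.zeros(3)

        rep = perturbation_analysis(
            FakeProblem(), self._baseline_identity(np.zeros(3)), n=0
        )
        assert rep.n_perturbations == 0
        assert len(rep.translation_discrepancies_mm) == 0

    def test_perturbation_magnitudes_exact(self, rng):
        c = np.array([10.0, -5.0, 3.0])
        P = random_perturbation(rng, 2.0, 2.0, c)
        assert P.rotation_angle_deg() == pytest.approx(2.0, abs=1e-9)
        assert np.linalg.norm(P.apply(c) - c) == pytest.approx(2.0, abs=1e-9)

    def test_well_conditioned_phantom_reconverges(self, analyzed):
        """Restarts from 2 deg / 2 mm perturbed inits land on the baseline."""
        rep = perturbation_analysis(
            analyzed.problems["T7"], analyzed.registrations["T7"],
            n=3, seed=17,
        )
        assert rep.mean_translation_mm < 0.1
        assert rep.n_perturbations == 3
        assert (rep.translation_discrepancies_mm >= 0).all()
        assert (rep.rotation_discrepancies_deg >= 0).all()
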