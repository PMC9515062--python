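"""Rigid transforms, Horn fits, correspondence matching, localization."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.spatial.transform import Rotation

from fidloc import (
    DegenerateGeometryError,
    LocalizationStatus,
    RigidTransform,
    Volume,
    compose_chain,
    default_geometry,
    horn_absolute_orientation,
    localize_marker,
    match_candidates_to_geometry,
    to_euler_angles,
)


def random_transform(seed) -> RigidTransform:
    rng = np.random.default_rng(seed)
    rot = Rotation.random(random_state=np.random.RandomState(seed))
    return RigidTransform(rot.as_matrix(), rng.uniform(-100, 100, 3))


class TestTransformAlgebra:
    def test_identity_is_neutral(self):
        a = random_transform(1)
        np.testing.assert_allclose(
            a.compose(RigidTransform.identity()).matrix(), a.matrix(), atol=1e-12
        )

    def test_inverse_composes_to_identity(self):
        a = random_transform(2)
        np.testing.assert_allclose(
            a.invert().compose(a).matrix(), np.eye(4), atol=1e-9
        )

    @settings(derandomize=True, deadline=None, max_examples=50)
    @given(st.integers(0, 2**31 - 1))
    def test_composition_equals_sequential_application(self, seed):
        a, b = random_transform(seed), random_transform(seed + 1)
        p = np.random.default_rng(seed).uniform(-50, 50, (5, 3))
        np.testing.assert_allclose(
            a.compose(b).apply(p), a.apply(b.apply(p)), atol=1e-9
        )

    def test_reflection_rejected(self):
        with pytest.raises(ValueError, match="reflection"):
            RigidTransform(np.diag([1.0, 1.0, -1.0]), np.zeros(3))


class TestEulerAngles:
    def test_identity(self):
        np.testing.assert_allclose(
            to_euler_angles(RigidTransform.identity()), (0, 0, 0), atol=1e-12
        )

    def test_quarter_turn_about_z(self):
        t = RigidTransform.from_euler_degrees((90, 0, 0))
        np.testing.assert_allclose(to_euler_angles(t), (90, 0, 0), atol=1e-9)

    def test_round_trip(self):
        for seed in range(50):
            t = random_transform(seed)
            angles = to_euler_angles(t)
            if abs(abs(angles[1]) - 90.0) < 1.0:
                continue
            back = RigidTransform.from_euler_degrees(angles)
            np.testing.assert_allclose(back.rotation, t.rotation, atol=1e-9)

    def test_gimbal_lock_flagged(self):
        t = RigidTransform.from_euler_degrees((10.0, 90.0, 5.0))
        with pytest.warns(RuntimeWarning, match="gimbal"):
            to_euler_angles(t)


class TestComposeChain:
    def test_chain_of_identities(self):
        reg = {"a": RigidTransform.identity(), "b": RigidTransform.identity()}
        np.testing.assert_allclose(
            compose_chain(["a", "b"], reg).matrix(), np.eye(4), atol=1e-12
        )

    def test_inverse_pair_cancels(self):
        reg = {"a": random_transform(3)}
        np.testing.assert_allclose(
            compose_chain(["~a", "a"], reg).matrix(), np.eye(4), atol=1e-9
        )

    def test_missing_transform(self):
        with pytest.raises(KeyError, match="missing"):
            compose_chain(["nope"], {})

    def test_ct_to_us_chain_reproduces_simulated_target(self):
        """Projecting a CT point through the composed marker/tracking chain
        must land on its simulated position in the ultrasound frame."""
        reg = {
            "marker_to_ct": random_transform(10),
            "sensorholder_to_marker": random_transform(11),
            "sensorholder_to_tracker": random_transform(12),
            "tracker_to_us": random_transform(13),
        }
        chain = ["~marker_to_ct", "~sensorholder_to_marker",
                 "sensorholder_to_tracker", "tracker_to_us"]
        t_ct_us = compose_chain(chain, reg)
        p_ct = np.array([10.0, -20.0, 35.0])
        expected = reg["tracker_to_us"].apply(
            reg["sensorholder_to_tracker"].apply(
                reg["sensorholder_to_marker"].invert().apply(
                    reg["marker_to_ct"].invert().apply(p_ct)
                )
            )
        )
        np.testing.assert_allclose(t_ct_us.apply(p_ct), expected, atol=1e-9)


class TestHorn:
    def test_identity_fit(self):
        pts = np.random.default_rng(0).uniform(-40, 40, (8, 3))
        t, fre = horn_absolute_orientation(pts, pts)
        np.testing.assert_allclose(t.matrix(), np.eye(4), atol=1e-9)
        assert fre < 1e-9

    def test_exact_recovery_of_constructed_transform(self):
        pts = np.random.default_rng(1).uniform(-40, 40, (8, 3))
        truth = RigidTransform.from_euler_degrees((90, 0, 0), (10, 0, 0))
        t, fre = horn_absolute_orientation(pts, truth.apply(pts))
        np.testing.assert_allclose(t.matrix(), truth.matrix(), atol=1e-9)
        assert fre < 1e-9

    def test_noisy_fit_translation_error_statistics(self):
        """Monte-Carlo: with 8 points and 0.1 mm iid noise the recovered
        translation stays well below 0.15 mm on average."""
        rng = np.random.default_rng(7)
        errors, fres = [], []
        for seed in range(1000):
            src = rng.uniform(-50, 50, (8, 3))
            truth = random_transform(seed)
            tgt = truth.apply(src) + rng.normal(0, 0.1, (8, 3))
            t, fre = horn_absolute_orientation(src, tgt)
            errors.append(np.linalg.norm(t.translation - truth.translation))
            fres.append(fre)
        errors = np.asarray(errors)
        assert errors.mean() < 0.15
        assert np.median(errors) < 0.15
        # FRE reflects the injected noise level (sigma * sqrt(3) per point,
        # reduced by the 6 fitted dof over 24 observations)
        assert 0.05 < np.mean(fres) < 0.25

    def test_collinear_points_rejected(self):
        src = np.column_stack([np.arange(8.0), np.zeros(8), np.zeros(8)])
        with pytest.raises(DegenerateGeometryError, match="collinear"):
            horn_absolute_orientation(src, src)


class TestMatching:
    def test_permuted_true_points_give_correct_bijection(self, geo315):
        truth = random_transform(21)
        pts = truth.apply(geo315.feature_centroids)
        perm = np.random.default_rng(3).permutation(8)
        result = match_candidates_to_geometry(pts[perm], geo315, tau=1.0,
                                              fre_threshold=1.0)
        assert result.status is LocalizationStatus.SUCCESS
        assert result.fre < 1e-6
        # order[j] indexes the permuted candidate list; it must point back
        # at geometry feature j
        assert [perm[result.order[j]] for j in range(8)] == list(range(8))

    def test_distractors_never_displace_true_features(self, geo315):
        """8 true points + 4 random distractors: the matcher must pick the
        true 8 with the correct ordering in every seed."""
        failures = 0
        for seed in range(1000):
            rng = np.random.default_rng(seed)
            truth = random_transform(seed)
            pts = truth.apply(geo315.feature_centroids)
            lo, hi = pts.min(0) - 20, pts.max(0) + 20
            distract = []
            while len(distract) < 4:
                p = rng.uniform(lo, hi)
                if np.min(np.linalg.norm(pts - p, axis=1)) > 6.0:
                    distract.append(p)
            cand = np.vstack([pts, distract])
            order = rng.permutation(12)
            result = match_candidates_to_geometry(cand[order], geo315, tau=1.0,
                                                  fre_threshold=1.0)
            ok = (
                result.status is LocalizationStatus.SUCCESS
                and [order[result.order[j]] for j in range(8)] == list(range(8))
            )
            failures += not ok
        assert failures == 0

    def test_missing_feature_yields_failure_not_wrong_success(self, geo315):
        """With only 7 true points present no subset may pass verification."""
        wrong = 0
        for seed in range(200):
            rng = np.random.default_rng(10_000 + seed)
            truth = random_transform(seed)
            pts = truth.apply(geo315.feature_centroids)[:7]
            lo, hi = pts.min(0) - 20, pts.max(0) + 20
            distract = []
            while len(distract) < 5:
                p = rng.uniform(lo, hi)
                if np.min(np.linalg.norm(pts - p, axis=1)) > 6.0:
                    distract.append(p)
            cand = np.vstack([pts, distract])
            result = match_candidates_to_geometry(cand, geo315, tau=1.0,
                                                  fre_threshold=1.0)
            wrong += result.status is LocalizationStatus.SUCCESS
        assert wrong == 0

    def test_insufficient_candidates(self, geo315):
        pts = geo315.feature_centroids[:5]
        result = match_candidates_to_geometry(pts, geo315)
        assert result.status is LocalizationStatus.INSUFFICIENT_CANDIDATES

    def test_invariant_to_input_order_and_rigid_motion(self, geo315):
        truth = random_transform(31)
        pts = truth.apply(geo315.feature_centroids)
        base = match_candidates_to_geometry(pts, geo315, tau=1.0, fre_threshold=1.0)
        shuffled = match_candidates_to_geometry(
            pts[::-1], geo315, tau=1.0, fre_threshold=1.0
        )
        np.testing.assert_allclose(
            base.transform.matrix(), shuffled.transform.matrix(), atol=1e-9
        )
        motion = random_transform(32)
        moved = match_candidates_to_geometry(
            motion.apply(pts), geo315, tau=1.0, fre_threshold=1.0
        )
        np.testing.assert_allclose(
            moved.transform.matrix(),
            motion.compose(base.transform).matrix(),
            atol=1e-6,
        )


class TestLocalizeMarker:
    def test_one_millimetre_slices(self, clean_scene, geo315):
        volume, truth = clean_scene
        loc = localize_marker(volume, geo315)
        assert loc.success
        assert np.linalg.norm(loc.transform.translation - truth.translation) < 0.3
        rot_err = truth.invert().compose(loc.transform).rotation_angle_degrees()
        assert rot_err < 0.3
        assert len(loc.correspondences) == 8
        assert loc.provenance["n_components"] >= 8

    def test_five_millimetre_slices(self, thick_scene, geo315):
        volume, truth = thick_scene
        loc = localize_marker(volume, geo315)
        assert loc.success
        assert np.linalg.norm(loc.transform.translation - truth.translation) < 1.0

    def test_air_only_volume(self, geo315):
        air = Volume(np.full((20, 20, 20), -1000.0), (1, 1, 1), (0, 0, 0))
        loc = localize_marker(air, geo315)
        assert loc.status is LocalizationStatus.INSUFFICIENT_CANDIDATES
        assert not loc.success

    def test_report_is_json_serializable(self, clean_scene, geo315):
        import json

        volume, _ = clean_scene
        loc = localize_marker(volume, geo315)
        text = json.dumps(loc.report())
        parsed = json.loads(text)
        assert parsed["status"] == "success"
        assert len(parsed["marker_to_image_matrix"]) == 4
        assert len(parsed["correspondences"]) == 8
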