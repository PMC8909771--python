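"""Rigid fits, FRE/TRE metrics and constellation correspondence."""

import numpy as np
import pytest

import ablateguide as ag
from ablateguide.registration import (DegenerateConfigurationError,
                                      MatchingFailureError, match_brute_force)


def _random_points(rng, n=20, span=200.0):
    return rng.uniform(0, span, size=(n, 3))


def _random_transform(rng):
    return ag.RigidTransform.from_euler(rng.uniform(-40, 40, 3),
                                        rng.uniform(-80, 80, 3))


class TestRigidTransform:
    def test_proper_rotation_enforced(self):
        with pytest.raises(ValueError):
            ag.RigidTransform(np.diag([1.0, 1.0, -1.0]), np.zeros(3))

    def test_compose_then_inverse_is_identity(self, rng):
        a, b = _random_transform(rng), _random_transform(rng)
        c = a.compose(b)
        pts = _random_points(rng, 5)
        np.testing.assert_allclose(c.apply(pts), a.apply(b.apply(pts)), atol=1e-9)
        np.testing.assert_allclose(c.inverse().apply(c.apply(pts)), pts, atol=1e-9)

    def test_json_round_trip(self, tmp_path, rng):
        t = _random_transform(rng)
        t.save(tmp_path / "t.json")
        back = ag.RigidTransform.load(tmp_path / "t.json")
        np.testing.assert_allclose(back.rotation, t.rotation)
        np.testing.assert_allclose(back.translation, t.translation)


class TestFitRigid:
    def test_self_registration_gives_identity(self, rng):
        pts = _random_points(rng)
        res = ag.fit_rigid(pts, pts)
        np.testing.assert_allclose(res.transform.rotation, np.eye(3), atol=1e-12)
        assert res.fre < 1e-12

    def test_recovers_generating_transform(self, rng):
        pts = _random_points(rng)
        truth = _random_transform(rng)
        res = ag.fit_rigid(pts, truth.apply(pts))
        np.testing.assert_allclose(res.transform.rotation, truth.rotation, atol=1e-9)
        np.testing.assert_allclose(res.transform.translation, truth.translation,
                                   atol=1e-9)
        assert res.fre < 1e-9

    def test_fre_squared_is_mean_squared_residual(self, rng):
        pts = _random_points(rng)
        noisy = pts + rng.normal(0, 1.0, pts.shape)
        res = ag.fit_rigid(pts, noisy)
        assert res.fre**2 == pytest.approx(np.mean(res.residuals**2))

    def test_reflection_guard_on_near_planar_sets(self, rng):
        # points nearly coplanar: naive orthogonal factor may be a reflection
        pts = _random_points(rng, 10)
        pts[:, 2] = 0.01 * rng.standard_normal(10)
        truth = _random_transform(rng)
        res = ag.fit_rigid(pts, truth.apply(pts))
        assert np.linalg.det(res.transform.rotation) == pytest.approx(1.0)
        assert res.fre < 1e-9

    def test_collinear_points_rejected(self):
        pts = np.outer(np.arange(5.0), np.array([1.0, 2.0, 3.0]))
        with pytest.raises(DegenerateConfigurationError):
            ag.fit_rigid(pts, pts)

    def test_invariant_to_pair_order_and_common_motion(self, rng):
        pts = _random_points(rng, 12)
        noisy = pts + rng.normal(0, 0.5, pts.shape)
        base = ag.fit_rigid(pts, noisy)
        perm = rng.permutation(12)
        shuffled = ag.fit_rigid(pts[perm], noisy[perm])
        assert shuffled.fre == pytest.approx(base.fre)
        common = _random_transform(rng)
        moved = ag.fit_rigid(common.apply(pts), common.apply(noisy))
        assert moved.fre == pytest.approx(base.fre)

    def test_mean_fre_squared_matches_expectation(self, rng):
        """E[FRE^2] = (1 - 2/N) * 3 sigma^2 for isotropic fiducial noise."""
        n, sigma, trials = 20, 0.5, 500
        pts = _random_points(rng, n)
        fre2 = []
        for _ in range(trials):
            res = ag.fit_rigid(pts, pts + rng.normal(0, sigma, pts.shape))
            fre2.append(res.fre**2)
        expected = (1 - 2 / n) * 3 * sigma**2
        assert np.mean(fre2) == pytest.approx(expected, rel=0.07)


class TestConstellation:
    def test_signatures_sorted_distances(self):
        c = ag.Constellation([[0, 0, 0], [3, 0, 0], [0, 4, 0]])
        sig = c.signatures()
        np.testing.assert_allclose(sig[0], [3, 4])
        np.testing.assert_allclose(sig[1], [3, 5])

    def test_non_repetitive_check(self):
        square = ag.Constellation([[0, 0, 0], [1, 0, 0], [1, 1, 0], [0, 1, 0]])
        assert not square.is_non_repetitive(0.1)
        scalene = ag.Constellation([[0, 0, 0], [5, 0, 0], [1, 9, 0], [3, 2, 7]])
        assert scalene.is_non_repetitive(0.1)


class TestMatchConstellation:
    def test_exact_self_match_identity(self, scene, rng):
        ref = scene.fiducial_constellation()
        perm = rng.permutation(len(ref))
        res = ag.match_constellation(ref.points[perm], ref)
        assert res.fre < 1e-9
        assert {r: o for o, r in res.correspondence} == {
            int(p): i for i, p in enumerate(perm)}

    def test_transformed_noiseless_reproduces_transform(self, scene, rng):
        ref = scene.fiducial_constellation()
        truth = _random_transform(rng)
        obs = truth.apply(ref.points)[rng.permutation(len(ref))]
        res = ag.match_constellation(obs, ref)
        np.testing.assert_allclose(res.transform.rotation, truth.rotation, atol=1e-6)
        assert res.fre < 1e-6

    @pytest.mark.parametrize("occluded", [0, 2])
    def test_recovery_under_noise_and_occlusion(self, scene, tracker_frame, occluded):
        ref = scene.fiducial_constellation()
        n_trials, good = 60, 0
        for s in range(n_trials):
            trial_rng = np.random.default_rng(1000 + s)
            model = ag.ObservationModel(sigma=0.5, occlusion_prob=0.0,
                                        frame=tracker_frame)
            keep = np.arange(len(ref))
            if occluded:
                keep = np.sort(trial_rng.choice(len(ref), len(ref) - occluded,
                                                replace=False))
            obs = ag.observe_markers(ref.points[keep], model, trial_rng)
            res = ag.match_constellation(obs.points, ref)
            truth_map = {i: int(keep[t]) for i, t in enumerate(obs.true_indices)}
            good += int(dict(res.correspondence) == truth_map)
        assert good == n_trials

    def test_agrees_with_brute_force_oracle_on_small_sets(self, rng):
        for s in range(10):
            trial = np.random.default_rng(s)
            pts = _random_points(trial, 6, span=100)
            ref = ag.Constellation(pts)
            truth = _random_transform(trial)
            obs = truth.apply(pts) + trial.normal(0, 0.3, pts.shape)
            obs = obs[trial.permutation(6)]
            fast = ag.match_constellation(obs, ref)
            oracle = match_brute_force(obs, ref)
            assert sorted(fast.correspondence) == sorted(oracle.correspondence)
            assert fast.fre == pytest.approx(oracle.fre, abs=1e-9)

    def test_matching_failure_raises(self, rng):
        ref = ag.Constellation(_random_points(rng, 8, span=100))
        junk = rng.uniform(500, 900, size=(8, 3))
        with pytest.raises(MatchingFailureError):
            ag.match_constellation(junk, ref, fre_ceiling=0.5)

    def test_too_few_observed_rejected(self, rng):
        ref = ag.Constellation(_random_points(rng, 8))
        with pytest.raises(ValueError):
            ag.match_constellation(ref.points[:3], ref)

    def test_outlier_removal_does_not_increase_fre(self, rng):
        pts = _random_points(rng, 10)
        noisy = pts + rng.normal(0, 0.3, pts.shape)
        noisy[0] += 8.0  # one gross outlier
        full = ag.fit_rigid(pts, noisy)
        trimmed = ag.fit_rigid(pts, noisy,
                               [(i, i) for i in range(1, 10)])
        assert trimmed.fre <= full.fre


class TestTargetRegistrationError:
    def test_identity_gives_zero(self, rng):
        pts = _random_points(rng, 6)
        res = ag.fit_rigid(pts, pts)
        tre = ag.target_registration_error(res, ag.RigidTransform.identity(),
                                           [[10, 20, 30]])
        assert tre[0] == pytest.approx(0.0, abs=1e-9)

    def test_pure_translation_error_is_constant(self, rng):
        pts = _random_points(rng, 6)
        res = ag.fit_rigid(pts, pts)
        truth = ag.RigidTransform(np.eye(3), (2.0, 0.0, 0.0))
        tre = ag.target_registration_error(res, truth, _random_points(rng, 5))
        np.testing.assert_allclose(tre, 2.0, atol=1e-9)

    def test_lever_arm_grows_with_target_distance(self):
        """Rotational registration error amplifies with distance from the
        fiducial centroid (the classic TRE lever arm)."""
        tres = {50.0: [], 100.0: [], 150.0: []}
        for s in range(100):
            trial = np.random.default_rng(s)
            pts = trial.uniform(-30, 30, size=(20, 3))  # centred constellation
            noisy = pts + trial.normal(0, 0.5, pts.shape)
            res = ag.fit_rigid(pts, noisy)
            for d in tres:
                u = trial.standard_normal(3)
                u /= np.linalg.norm(u)
                tres[d].append(ag.target_registration_error(
                    res, ag.RigidTransform.identity(), [d * u])[0])
        means = [np.mean(tres[d]) for d in (50.0, 100.0, 150.0)]
        assert means[0] < means[1] < means[2]
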