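"""The alignment loop and its building blocks."""

import numpy as np
import pytest
from scipy.stats import kstest

from drwpicp import (
    DegenerateError,
    PerturbParams,
    PointCloud,
    RigidTransform,
    StopParams,
    WeightParams,
    apply_transform,
    assign_weights,
    build_neighbor_index,
    correspond,
    drwp_icp,
    line_search_step,
    perturb_transform,
    perturbation_range,
    sample_perturbation,
    trimmed_mean_distance,
    vanilla_icp,
)
from drwpicp.register import NoInliersError, _interpolate
from drwpicp.synthdata import SceneSpec, make_scene, random_rigid_transform

from conftest import random_transform


class TestCorrespond:
    def test_self_correspondence_at_identity(self, random_cloud):
        index = build_neighbor_index(random_cloud)
        corr = correspond(random_cloud, index, RigidTransform.identity())
        np.testing.assert_array_equal(corr.pairs[:, 0], corr.pairs[:, 1])
        assert np.all(corr.distances == 0)

    def test_equidistant_tie_goes_to_lower_id(self):
        ref = PointCloud(points=[[1.0, 0, 0], [-1.0, 0, 0]], ids=[9, 4])
        f = PointCloud(points=[[0.0, 0, 0]])
        corr = correspond(f, build_neighbor_index(ref),
                          RigidTransform.identity())
        assert corr.pairs[0, 1] == 4

    def test_matches_exhaustive_scan(self, rng):
        f = PointCloud(points=rng.standard_normal((300, 3)))
        ref = PointCloud(points=rng.standard_normal((250, 3)))
        t = random_transform(17, max_angle=0.5, max_translation=1.0)
        corr = correspond(f, build_neighbor_index(ref), t)
        mapped = t.transform_points(f.points)
        full = np.linalg.norm(mapped[:, None] - ref.points[None], axis=2)
        np.testing.assert_array_equal(corr.ref_positions,
                                      np.argmin(full, axis=1))
        np.testing.assert_allclose(corr.distances, full.min(axis=1),
                                   atol=1e-12)


class TestTrimmedMeanDistance:
    def test_drops_the_largest_value(self):
        assert trimmed_mean_distance([1, 2, 3, 4, 100.0], 0.2) == \
            pytest.approx(2.5)

    def test_zero_trim_is_plain_mean(self, rng):
        d = rng.uniform(0, 10, size=37)
        assert trimmed_mean_distance(d, 0.0) == pytest.approx(d.mean())

    def test_matches_sort_and_average_oracle(self, rng):
        d = rng.exponential(size=1000)
        n_c = int(np.floor(0.1 * len(d)))
        expected = np.sort(d)[: len(d) - n_c].mean()
        assert trimmed_mean_distance(d, 0.1) == pytest.approx(expected,
                                                              abs=1e-12)


class TestAssignWeights:
    def test_literal_rule_direct_values(self):
        # raw weight d/alpha_mean = 0.4 before normalization
        w = assign_weights(np.array([1.0, 1.0]), 2.5, 1.0)
        np.testing.assert_allclose(w, [0.5, 0.5])
        raw = 1.0 / 2.5
        assert raw == pytest.approx(0.4)

    def test_cutoff_branch_zeroes_far_pairs(self):
        w = assign_weights(np.array([3.0, 1.0, 1.0]), 2.5, 1.0)
        assert w[0] == 0 and w[1] > 0

    def test_zero_distance_gets_zero_weight(self):
        w = assign_weights(np.array([0.0, 1.0]), 2.5, 1.0)
        assert w[0] == 0

    def test_all_excluded_raises(self):
        with pytest.raises(NoInliersError):
            assign_weights(np.array([5.0, 6.0]), 2.5, 1.0)

    def test_widened_cutoff_keeps_far_pairs(self):
        w = assign_weights(np.array([3.0, 1.0]), 2.5, 1.0, cutoff_scale=3.0)
        assert w[0] > 0


class TestLineSearchStep:
    @staticmethod
    def _setup(rng, t_start):
        ref = PointCloud(points=rng.uniform(-5, 5, size=(200, 3)))
        index = build_neighbor_index(ref)
        f = PointCloud(points=ref.points.copy())
        corr = correspond(f, index, t_start)
        return f, index, corr

    def test_full_step_chosen_on_clean_problem(self, rng):
        t0 = random_transform(5, max_angle=0.05, max_translation=0.1)
        f, index, corr = self._setup(rng, t0)
        t, rms = line_search_step(f, index, t0, corr)
        assert rms < 1e-9  # full step lands exactly on the reference

    def test_never_worse_than_exhaustive_lambda_scan(self, rng):
        from drwpicp.core import estimate_rigid_transform, rms_error
        t0 = random_transform(6, max_angle=0.8, max_translation=3.0)
        f, index, corr = self._setup(rng, t0)
        t, rms = line_search_step(f, index, t0, corr)
        dst = index.cloud.points[corr.ref_positions]
        cand = estimate_rigid_transform(f.points, dst, None)
        best = min(rms_error(f, index,
                             cand if lam == 1.0 else _interpolate(t0, cand, lam))
                   for lam in (1.0, 0.5, 0.25, 0.125))
        assert rms == pytest.approx(best, abs=1e-12)

    def test_too_few_nonzero_weights_rejected(self, rng):
        t0 = RigidTransform.identity()
        f, index, corr = self._setup(rng, t0)
        corr.weights = np.zeros(len(f.points))
        corr.weights[:2] = 0.5
        with pytest.raises(DegenerateError):
            line_search_step(f, index, t0, corr)


class TestPerturbationRange:
    def test_equal_transforms_give_zero_range(self):
        t = random_transform(1)
        assert np.all(perturbation_range(t, t) == 0)

    def test_pure_translations(self):
        a = RigidTransform.from_axis_angle([0, 0, 1], 0.0, [1.0, 2.0, 3.0])
        b = RigidTransform.identity()
        r = perturbation_range(a, b)
        np.testing.assert_array_equal(r[:3, 3], [1, 2, 3])
        assert np.all(r[:3, :3] == 0)

    def test_elementwise_arithmetic(self):
        a, b = random_transform(2), random_transform(3)
        np.testing.assert_array_equal(perturbation_range(a, b),
                                      np.abs(a.matrix - b.matrix))


class TestSamplePerturbation:
    def test_zero_range_gives_zero(self, rng):
        assert sample_perturbation(0.0, 2.0, rng) == 0.0

    def test_draws_stay_in_support(self, rng):
        draws = [sample_perturbation(2.0, 1.5, rng) for _ in range(2000)]
        assert np.max(np.abs(draws)) <= 3.0

    def test_empirical_cdf_matches_cubic_law(self):
        rng = np.random.default_rng(99)
        draws = np.array([sample_perturbation(1.0, 1.0, rng)
                          for _ in range(100_000)])
        stat = kstest(draws, lambda x: (x ** 3 + 1.0) / 2.0).statistic
        assert stat < 0.01


class TestPerturbTransform:
    def test_zero_range_is_identity_perturbation(self, rng):
        t = random_transform(4)
        out = perturb_transform(t, np.zeros((4, 4)), PerturbParams(), rng)
        np.testing.assert_allclose(out.matrix, t.matrix, atol=1e-12)

    def test_translation_only_range_bounds(self, rng):
        t = random_transform(8)
        r = np.zeros((4, 4))
        r[:3, 3] = [1.0, 2.0, 0.5]
        params = PerturbParams(scale=1.5)
        for _ in range(200):
            out = perturb_transform(t, r, params, rng)
            np.testing.assert_allclose(out.rotation, t.rotation, atol=1e-9)
            delta = out.translation - t.translation
            assert np.all(np.abs(delta) <= 1.5 * r[:3, 3] + 1e-12)

    def test_rotation_magnitude_bounded_by_relative_angle(self, rng):
        t_init = random_transform(10, max_angle=0.5)
        t_temp = random_transform(11, max_angle=0.5)
        rel = t_init.rotation @ t_temp.rotation.T
        angle = np.arccos(np.clip((np.trace(rel) - 1) / 2, -1, 1))
        r = perturbation_range(t_init, t_temp)
        for _ in range(100):
            out = perturb_transform(t_temp, r, PerturbParams(scale=1.0), rng)
            delta = out.rotation @ t_temp.rotation.T
            dangle = np.arccos(np.clip((np.trace(delta) - 1) / 2, -1, 1))
            assert dangle <= angle + 1e-9


class TestDrwpIcp:
    def test_identical_clouds_converge_immediately(self, random_cloud):
        res = drwp_icp(random_cloud, random_cloud)
        assert res.converged and res.reason == "tolerance"
        assert res.restarts_used == 0 and res.iterations == 0
        assert res.rms_trace[-1] == 0

    def test_recovers_known_transform_on_surface_scene(self):
        truth = random_rigid_transform(np.random.default_rng(50),
                                       np.deg2rad(25), 80.0)
        spec = SceneSpec(n_points=2000, rng_seed=3, true_transform=truth,
                         resample_floating=False)
        scene = make_scene(spec)
        res = drwp_icp(scene.floating_1, scene.reference)
        delta = res.transform.compose(truth)
        assert np.degrees(delta.rotation_angle()) < 0.5
        diag = scene.reference.bounding_box_diagonal()
        assert np.linalg.norm(delta.translation) < 0.005 * diag

    def test_trace_monotone_and_rigid_output(self):
        spec = SceneSpec(n_points=1000, rng_seed=5, noise_variance=2.0,
                         true_transform=random_rigid_transform(
                             np.random.default_rng(51), 0.5, 50.0))
        scene = make_scene(spec)
        res = drwp_icp(scene.floating_1, scene.reference)
        values = list(res.rms_trace)
        assert all(a >= b for a, b in zip(values, values[1:]))
        rot = res.transform.rotation
        np.testing.assert_allclose(rot.T @ rot, np.eye(3), atol=1e-9)
        assert np.linalg.det(rot) == pytest.approx(1.0, abs=1e-9)

    def test_reduction_identity_with_features_disabled(self):
        spec = SceneSpec(n_points=800, rng_seed=9, noise_variance=1.0,
                         true_transform=random_rigid_transform(
                             np.random.default_rng(52), 0.4, 30.0))
        scene = make_scene(spec)
        t0 = random_transform(60, max_angle=0.3, max_translation=20.0)
        reduced = drwp_icp(scene.floating_1, scene.reference, t_init=t0,
                           weight=WeightParams(mode="uniform",
                                               trim_fraction=0.0),
                           perturb=PerturbParams(max_restarts=0),
                           lambdas=(1.0,))
        baseline = vanilla_icp(scene.floating_1, scene.reference, t_init=t0)
        assert list(reduced.rms_trace) == list(baseline.rms_trace)
        np.testing.assert_array_equal(reduced.transform.matrix,
                                      baseline.transform.matrix)

    def test_agrees_with_baseline_on_easy_instance(self):
        spec = SceneSpec(n_points=1500, rng_seed=2,
                         true_transform=random_rigid_transform(
                             np.random.default_rng(53), 0.15, 10.0),
                         resample_floating=False)
        scene = make_scene(spec)
        a = drwp_icp(scene.floating_1, scene.reference)
        b = vanilla_icp(scene.floating_1, scene.reference)
        assert abs(a.rms_trace[-1] - b.rms_trace[-1]) < 1e-3 * \
            scene.reference.bounding_box_diagonal()

    def test_escapes_adversarial_start_more_often_than_baseline(self):
        # near-180-degree starts on the asymmetric head: the perturbed robust
        # loop should end below the plain baseline in most seeds
        drwp_better = 0
        n_seeds = 8
        for seed in range(n_seeds):
            truth = random_rigid_transform(np.random.default_rng(70 + seed),
                                           np.deg2rad(170), 30.0)
            spec = SceneSpec(n_points=1200, rng_seed=seed,
                             true_transform=truth, resample_floating=False)
            scene = make_scene(spec)
            a = drwp_icp(scene.floating_1, scene.reference,
                         perturb=PerturbParams(rng_seed=seed),
                         stop=StopParams(max_iterations=150))
            b = vanilla_icp(scene.floating_1, scene.reference,
                            stop=StopParams(max_iterations=150))
            if a.rms_trace[-1] <= b.rms_trace[-1]:
                drwp_better += 1
        assert drwp_better > n_seeds / 2

    def test_never_exceeds_iteration_budget(self):
        spec = SceneSpec(n_points=500, rng_seed=1, noise_variance=5.0)
        scene = make_scene(spec)
        res = drwp_icp(scene.floating_1, scene.reference,
                       t_init=random_transform(80),
                       stop=StopParams(max_iterations=20))
        assert res.iterations <= 20


class TestVanillaIcp:
    def test_identical_clouds_identity(self, random_cloud):
        res = vanilla_icp(random_cloud, random_cloud)
        assert res.converged
        np.testing.assert_allclose(res.transform.matrix, np.eye(4))

    def test_converges_on_small_offset(self, rng):
        ref = PointCloud(points=rng.uniform(-5, 5, size=(500, 3)))
        t = random_transform(90, max_angle=0.05, max_translation=0.2)
        floating = apply_transform(ref, t.inverse())
        res = vanilla_icp(floating, ref)
        assert res.rms_trace[-1] < 1e-3 * 10 * np.sqrt(3)
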