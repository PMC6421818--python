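"""Objective, closed-form updates, solver behavior, and bias correction."""

import numpy as np
import pytest

from nlscfcm import (ModelParams, NonlocalConfig, correct_image, fcm_fit,
                     fit, make_dataset, objective, truncated_gaussian_kernel,
                     update_bias, update_centers, update_membership)
from nlscfcm.model import init_centers, memberships_from_centers

from conftest import random_model_instance


def brute_force_objective(x, y, u, v, b, s_map, alpha, kernel, m=2.0):
    """Literal triple-loop evaluation of the objective, including the
    clipped-window renormalized kernel sum."""
    c = u.shape[0]
    rows, cols = x.shape
    rho = kernel.rho
    total = 0.0
    for i in range(c):
        for r0 in range(rows):
            for c0 in range(cols):
                wsum = 0.0
                mass = 0.0
                for dr in range(-rho, rho + 1):
                    for dc in range(-rho, rho + 1):
                        r1, c1 = r0 + dr, c0 + dc
                        if not (0 <= r1 < rows and 0 <= c1 < cols):
                            continue
                        mass += kernel.weights[dr + rho, dc + rho]
                wsum = mass / mass  # renormalized kernel mass is 1
                bracket = (alpha[r0, c0] * (1 - s_map[i, r0, c0])
                           * (x[r0, c0] - b[r0, c0] * v[i]) ** 2
                           + (1 - alpha[r0, c0])
                           * (y[r0, c0] - b[r0, c0] * v[i]) ** 2)
                total += u[i, r0, c0] ** m * wsum * bracket
    return total


class TestObjective:
    def test_zero_on_perfect_fit(self):
        truth, obs = make_dataset(shape=(32, 32),
                                  class_intensities=(10, 100, 200),
                                  bias_amplitude=0.0, noise_percent=0.0,
                                  seed=0)
        c = 3
        u = np.zeros((c,) + obs.shape)
        for i in range(c):
            u[i] = truth.labels == i
        v = truth.class_intensities
        b = np.ones_like(obs)
        s = np.zeros((c,) + obs.shape)
        alpha = np.full(obs.shape, 0.5)
        j = objective(obs, obs, u, v, b, s, alpha,
                      truncated_gaussian_kernel(1.0, 1))
        assert j == 0.0

    def test_reduces_to_fcm_objective(self, rng):
        x = rng.uniform(0, 1, size=(8, 8))
        u = rng.dirichlet(np.ones(3), size=(8, 8)).transpose(2, 0, 1)
        v = np.array([0.2, 0.5, 0.9])
        b = np.ones_like(x)
        s = np.zeros((3, 8, 8))
        alpha = np.ones_like(x)
        j = objective(x, x * 0, u, v, b, s, alpha,
                      truncated_gaussian_kernel(1.0, 1))
        fcm_j = np.sum(u**2 * (x[None] - v.reshape(-1, 1, 1)) ** 2)
        assert abs(j - fcm_j) < 1e-10

    def test_matches_triple_loop_oracle(self):
        x, y, u, v, b, s, alpha = random_model_instance(0)
        kern = truncated_gaussian_kernel(1.0, 1)
        j = objective(x, y, u, v, b, s, alpha, kern)
        j_ref = brute_force_objective(x, y, u, v, b, s, alpha, kern)
        assert abs(j - j_ref) < 1e-10

    def test_gauge_invariance(self):
        x, y, u, v, b, s, alpha = random_model_instance(1)
        kern = truncated_gaussian_kernel(1.0, 1)
        j1 = objective(x, y, u, v, b, s, alpha, kern)
        j2 = objective(x, y, u, v / 3.0, 3.0 * b, s, alpha, kern)
        assert abs(j1 - j2) < 1e-10


class TestUpdates:
    def test_single_class_membership(self):
        x, y, _, _, b, s, alpha = random_model_instance(2, c=1)
        u = update_membership(x, y, np.array([0.5]), b, s[:1], alpha)
        np.testing.assert_allclose(u, 1.0)

    def test_equal_distances_give_uniform_membership(self):
        x = np.full((6, 6), 0.5)
        y = x.copy()
        b = np.ones_like(x)
        v = np.array([0.4, 0.6])  # symmetric about x
        s = np.zeros((2, 6, 6))
        alpha = np.ones_like(x)
        u = update_membership(x, y, v, b, s, alpha)
        np.testing.assert_allclose(u, 0.5)

    def test_centers_reduce_to_fcm(self, rng):
        x = rng.uniform(0, 1, size=(7, 7))
        u = rng.dirichlet(np.ones(3), size=(7, 7)).transpose(2, 0, 1)
        b = np.ones_like(x)
        s = np.zeros((3, 7, 7))
        alpha = np.ones_like(x)
        v = update_centers(x, x * 0, u, b, s, alpha)
        expected = np.sum(u**2 * x[None], axis=(1, 2)) / np.sum(u**2,
                                                                axis=(1, 2))
        np.testing.assert_allclose(v, expected, rtol=1e-12)

    def test_one_hot_centers_are_class_means(self):
        x = np.where(np.arange(36).reshape(6, 6) < 18, 2.0, 8.0)
        u = np.stack([(x < 5).astype(float), (x >= 5).astype(float)])
        s = np.zeros((2, 6, 6))
        alpha = np.ones_like(x)
        v = update_centers(x, x, u, np.ones_like(x), s, alpha)
        np.testing.assert_allclose(v, [2.0, 8.0])

    def test_bias_fixed_point_at_unity(self):
        truth, obs = make_dataset(shape=(32, 32),
                                  class_intensities=(10, 100, 200),
                                  bias_amplitude=0.0, noise_percent=0.0,
                                  seed=0)
        u = np.stack([(truth.labels == i).astype(float) for i in range(3)])
        s = np.zeros_like(u)
        alpha = np.full(obs.shape, 0.7)
        b = update_bias(obs, obs, u, truth.class_intensities, s, alpha)
        np.testing.assert_allclose(b, 1.0, atol=1e-12)

    def test_bias_homogeneity_in_centers(self):
        x, y, u, v, b, s, alpha = random_model_instance(3)
        b1 = update_bias(x, y, u, v, s, alpha)
        b2 = update_bias(x, y, u, 2.0 * v, s, alpha)
        np.testing.assert_allclose(b2, b1 / 2.0, rtol=1e-10)


class TestFit:
    def test_exact_recovery_on_clean_phantom(self, clean_phantom):
        truth, obs = clean_phantom
        res = fit(obs, ModelParams(c=3))
        from nlscfcm import evaluate_segmentation
        rep = evaluate_segmentation(res.labels, truth.labels, 3,
                                    include_background=True)
        assert all(v == 1.0 for v in rep.per_class_js.values())

    def test_single_class(self, rng):
        x = rng.uniform(50, 60, size=(32, 32))
        res = fit(x, ModelParams(c=1, max_iter=5))
        np.testing.assert_allclose(res.memberships, 1.0)
        assert res.labels.max() == 0

    def test_converges_on_noisy_biased_phantom(self, noisy_phantom):
        truth, obs = noisy_phantom
        res = fit(obs, ModelParams(c=4, max_iter=100))
        assert res.converged
        assert res.iterations_run <= 100
        assert res.final_center_shift < 1e-3
        assert res.max_membership_residual < 1e-10

    def test_deterministic(self, noisy_phantom):
        _, obs = noisy_phantom
        r1 = fit(obs, ModelParams(c=4, max_iter=10))
        r2 = fit(obs, ModelParams(c=4, max_iter=10))
        np.testing.assert_array_equal(r1.labels, r2.labels)
        np.testing.assert_array_equal(r1.centers, r2.centers)

    def test_reduction_matches_fcm_trajectory(self, noisy_phantom):
        _, obs = noisy_phantom
        r1 = fit(obs, ModelParams(c=4, alpha_fixed=1.0,
                                  use_local_weight=False,
                                  estimate_bias=False, max_iter=40))
        r2 = fcm_fit(obs, 4, max_iter=40)
        assert len(r1.center_history) == len(r2.center_history)
        for a, b in zip(r1.center_history, r2.center_history):
            np.testing.assert_allclose(a, b, atol=1e-8)

    def test_objective_trace_non_increasing(self, noisy_phantom):
        _, obs = noisy_phantom
        res = fit(obs, ModelParams(c=4, max_iter=100))
        trace = np.asarray(res.objective_trace)
        assert np.all(np.diff(trace) <= 1e-9)

    def test_solution_invariant_to_initial_center_scale(self, clean_phantom):
        # the mean-1 bias gauge pins the (b, v) -> (gamma b, v/gamma)
        # ambiguity, so scaling the initial centers leaves the solution
        truth, obs = clean_phantom
        v0 = np.array([5.0, 90.0, 190.0])
        r1 = fit(obs, ModelParams(c=3, initial_centers=v0))
        r2 = fit(obs, ModelParams(c=3, initial_centers=1.1 * v0))
        np.testing.assert_array_equal(r1.labels, r2.labels)
        # centers agree up to the convergence resolution eps * scale
        np.testing.assert_allclose(np.sort(r1.centers), np.sort(r2.centers),
                                   atol=1e-3 * obs.max())

    def test_mask_restricts_foreground(self, noisy_phantom):
        truth, obs = noisy_phantom
        res = fit(obs, ModelParams(c=3, max_iter=30), mask=truth.foreground)
        assert abs(res.bias[truth.foreground].mean() - 1.0) < 1e-9

    def test_nonfinite_image_rejected(self):
        x = np.ones((40, 40))
        x[0, 0] = np.nan
        with pytest.raises(ValueError):
            fit(x, ModelParams(c=2))


class TestCorrectImage:
    def test_identity_bias(self, rng):
        x = rng.uniform(0, 1, size=(8, 8))
        np.testing.assert_array_equal(correct_image(x, np.ones_like(x)), x)

    def test_exact_division(self, rng):
        b = rng.uniform(0.5, 1.5, size=(8, 8))
        np.testing.assert_allclose(correct_image(2.0 * b, b), 2.0)

    def test_true_bias_restores_phantom(self):
        truth, obs = make_dataset(shape=(64, 64), bias_amplitude=0.3,
                                  noise_percent=0.0, seed=5)
        np.testing.assert_allclose(correct_image(obs, truth.bias),
                                   truth.true_image, atol=1e-6)

    def test_nonpositive_bias_rejected(self):
        x = np.ones((4, 4))
        b = np.ones((4, 4))
        b[2, 2] = 0.0
        with pytest.raises(ValueError):
            correct_image(x, b)


class TestInitialization:
    def test_quantile_fallback_on_constant_background(self):
        # dominant zero background would duplicate quantile centers
        x = np.zeros((40, 40))
        x[:10, :10] = 100.0
        v = init_centers(x, 4)
        assert len(np.unique(v)) == 4

    def test_memberships_from_centers_sum_to_one(self, rng):
        x = rng.uniform(0, 1, size=(10, 10))
        u = memberships_from_centers(x, np.array([0.2, 0.5, 0.8]))
        np.testing.assert_allclose(u.sum(axis=0), 1.0, atol=1e-12)

    def test_zero_distance_one_hot(self):
        x = np.full((5, 5), 0.5)
        u = memberships_from_centers(x, np.array([0.5, 0.9]))
        np.testing.assert_allclose(u[0], 1.0)
        np.testing.assert_allclose(u[1], 0.0)
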