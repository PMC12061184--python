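"""Fitting engine: soft-thresholding, working quantities, coordinate updates
(against brute-force oracles), full-fit behavior."""

import warnings

import numpy as np
import pytest

from grnmc import _kernels
from grnmc.core_model import (
    ClassifierCoefficients,
    ClassLabels,
    ExpressionData,
    Hyperparameters,
    NetworkCoefficients,
    clipped_probabilities,
    class_probabilities,
)
from grnmc.graph_penalty import graph_from_network
from grnmc.optimizer import (
    ConvergenceWarning,
    CoordinateState,
    FitConfig,
    fit,
    soft_threshold,
    update_beta,
    update_intercept,
    update_theta,
    working_quantities,
)

from conftest import random_instance, random_lambdas, weak_signal_instance


@pytest.mark.parametrize(
    "a,b,expected",
    [
        (2.0, 1.0, 1.0),
        (-2.0, 1.0, -1.0),
        (0.5, 1.0, 0.0),
        (-0.5, 1.0, 0.0),
        (3.0, 0.0, 3.0),
        (0.0, 0.0, 0.0),
        (1.0, 1.0, 0.0),  # boundary b == |a|
    ],
)
def test_soft_threshold_branch_table(a, b, expected):
    assert soft_threshold(a, b) == expected


def test_soft_threshold_rejects_negative_threshold():
    with pytest.raises(ValueError):
        soft_threshold(1.0, -0.5)


class TestWorkingQuantities:
    def test_hand_evaluation_at_zero_parameters(self):
        # two classes, all parameters zero: pi = 1/2, zeta = 1/4,
        # k = 0 + (1 - 1/2)/(1/4) = 2 for the observed class
        X = np.array([[1.0], [2.0]])
        data = ExpressionData(X, np.zeros((2, 1)))
        labels = ClassLabels(np.array([[1.0, 0.0], [0.0, 1.0]]))
        B = NetworkCoefficients([[0.0]])
        coef = ClassifierCoefficients([0.0, 0.0], [[0.0], [0.0]])
        wq = working_quantities(data, labels, B, coef)
        np.testing.assert_allclose(wq.zeta, 0.25)
        np.testing.assert_allclose(wq.k_work, [[2.0, -2.0], [-2.0, 2.0]])

    def test_finite_under_extreme_probabilities(self):
        X = np.array([[1.0], [-1.0]])
        data = ExpressionData(X, np.zeros((2, 1)))
        labels = ClassLabels(np.array([[1.0, 0.0], [0.0, 1.0]]))
        B = NetworkCoefficients([[1.0]])
        coef = ClassifierCoefficients([0.0, 0.0], [[80.0], [-80.0]])
        wq = working_quantities(data, labels, B, coef)
        assert np.all(np.isfinite(wq.k_work))
        assert np.all(wq.zeta >= 1e-10 * (1 - 1e-10) - 1e-16)
        assert np.all(wq.zeta <= 0.25)

    def test_matches_scalar_loop(self, rng):
        data, labels, B, coef = random_instance(rng)
        wq = working_quantities(data, labels, B, coef)
        P = clipped_probabilities(
            np.atleast_2d(class_probabilities(data.X, B, coef))
        )
        for i in range(data.n):
            for g in range(labels.G):
                eta_ig = coef.theta0[g] + data.X[i] @ B.B @ coef.Theta[g]
                z = labels.Z[i, g]
                pg = P[i, g]
                assert wq.zeta[i, g] == pytest.approx(pg * (1 - pg))
                assert wq.k_work[i, g] == pytest.approx(
                    eta_ig + (z - pg) / (pg * (1 - pg))
                )


def _make_state(rng, square=False, lambdas=None):
    data, labels, B, coef = random_instance(rng, n=10, p=3, k=4, square=square)
    wq = working_quantities(data, labels, B, coef)
    lam = lambdas or Hyperparameters(0.3, 0.2, 0.25, 0.0)
    Ls = graph_from_network(B, coef).Ls if square else None
    return data, labels, CoordinateState(
        X=data.X, Y=data.Y, Z=labels.Z, B=B.B.copy(), Theta=coef.Theta.copy(),
        theta0=coef.theta0.copy(), k_work=wq.k_work, zeta=wq.zeta, lambdas=lam,
        Ls=Ls,
    )


def _surrogate(state, Ls=None):
    """Penalized quadratic surrogate at frozen working quantities."""
    eta = state.theta0[None, :] + (state.X @ state.B) @ state.Theta.T
    val = 0.5 * np.sum(state.zeta * (state.k_work - eta) ** 2)
    val += 0.5 * np.sum((state.Y - state.X @ state.B) ** 2)
    val += state.lambdas.lambda1 * np.abs(state.B).sum()
    val += 0.5 * state.lambdas.lambda2 * np.sum(state.B**2)
    val += state.lambdas.lambda3 * np.abs(state.Theta).sum()
    if Ls is not None and state.lambdas.lambda4 > 0:
        for g in range(state.Theta.shape[0]):
            val += 0.5 * state.lambdas.lambda4 * (
                state.Theta[g] @ Ls[g] @ state.Theta[g]
            )
    return val


def _grid_minimize(fun, lo=-3.0, hi=3.0, coarse=0.01, fine=1e-4):
    """Two-stage brute-force 1-D minimization by full function evaluation."""
    grid = np.arange(lo, hi + coarse / 2, coarse)
    vals = np.array([fun(t) for t in grid])
    t0 = grid[np.argmin(vals)]
    grid2 = np.arange(t0 - coarse, t0 + coarse + fine / 2, fine)
    vals2 = np.array([fun(t) for t in grid2])
    return grid2[np.argmin(vals2)], vals2.min()


class TestCoordinateUpdates:
    def test_beta_update_beats_grid_search(self, rng):
        _, _, state = _make_state(rng)
        for (j, l) in [(0, 0), (2, 1), (3, 2)]:
            new = update_beta(j, l, state)

            def q(t, j=j, l=l):
                s = CoordinateState(**{**vars(state)})
                s.B = state.B.copy()
                s.B[l, j] = t
                return _surrogate(s)

            t_star, q_star = _grid_minimize(q)
            assert q(new) <= q_star + 1e-9 * max(1.0, abs(q_star))
            assert abs(new - t_star) <= 2e-4

    def test_theta_update_beats_grid_search(self, rng):
        _, _, state = _make_state(
            rng, square=True, lambdas=Hyperparameters(0.3, 0.2, 0.25, 0.8)
        )
        for (g, j) in [(0, 0), (1, 2), (2, 1)]:
            new = update_theta(g, j, state, state.Ls[g])

            def q(t, g=g, j=j):
                s = CoordinateState(**{**vars(state)})
                s.Theta = state.Theta.copy()
                s.Theta[g, j] = t
                return _surrogate(s, Ls=state.Ls)

            t_star, q_star = _grid_minimize(q)
            assert q(new) <= q_star + 1e-9 * max(1.0, abs(q_star))
            assert abs(new - t_star) <= 2e-4

    def test_beta_update_reduces_to_lasso_when_theta_zero(self, rng):
        data, labels, state = _make_state(rng)
        state.Theta = np.zeros_like(state.Theta)
        j, l = 1, 2
        new = update_beta(j, l, state)
        y_partial = data.Y[:, j] - data.X @ state.B[:, j] + state.B[l, j] * data.X[:, l]
        num = soft_threshold(float(data.X[:, l] @ y_partial), state.lambdas.lambda1)
        den = float(np.sum(data.X[:, l] ** 2)) + state.lambdas.lambda2
        assert new == pytest.approx(num / den)

    def test_huge_l1_zeroes_the_coordinate(self, rng):
        _, _, state = _make_state(rng, lambdas=Hyperparameters(1e6, 0, 1e6, 0))
        assert update_beta(0, 0, state) == 0.0
        assert update_theta(0, 0, state) == 0.0

    def test_intercept_is_weighted_mean_of_working_residual(self, rng):
        data, labels, state = _make_state(rng)
        for g in range(state.Theta.shape[0]):
            fitted = (data.X @ state.B) @ state.Theta[g]
            w = state.zeta[:, g]
            expected = np.sum(w * (state.k_work[:, g] - fitted)) / np.sum(w)
            assert update_intercept(g, state) == pytest.approx(expected)

    def test_intercept_zero_by_symmetry_at_zero_parameters(self):
        X = np.array([[1.0], [2.0], [3.0], [4.0]])
        data = ExpressionData(X, np.zeros((4, 1)))
        labels = ClassLabels(np.array([[1, 0], [0, 1], [1, 0], [0, 1]], dtype=float))
        B = NetworkCoefficients([[0.0]])
        coef = ClassifierCoefficients([0.0, 0.0], [[0.0], [0.0]])
        wq = working_quantities(data, labels, B, coef)
        state = CoordinateState(
            X=data.X, Y=data.Y, Z=labels.Z, B=B.B, Theta=coef.Theta,
            theta0=coef.theta0, k_work=wq.k_work, zeta=wq.zeta,
            lambdas=Hyperparameters(),
        )
        assert update_intercept(0, state) == pytest.approx(0.0)


class TestKernelAgainstReference:
    """The compiled sweeps must replay the reference updates coordinate-for-
    coordinate (same cyclic order, same residual bookkeeping)."""

    @pytest.mark.parametrize("square", [False, True])
    def test_beta_sweep(self, rng, square):
        data, labels, state = _make_state(rng, square=square)
        frozen = np.zeros((data.p, data.k), dtype=bool)
        if square:
            np.fill_diagonal(frozen, True)
        # reference: sequential single-coordinate updates
        ref = CoordinateState(**{**vars(state)})
        ref.B = state.B.copy()
        for j in range(data.k):
            for l in range(data.p):
                if not frozen[l, j]:
                    ref.B[l, j] = update_beta(j, l, ref)
        # kernel
        B = state.B.copy()
        eta = state.theta0[None, :] + (data.X @ B) @ state.Theta.T
        U = state.zeta * (state.k_work - eta)
        E = data.Y - data.X @ B
        C = (data.X**2).T @ state.zeta
        xsq = np.sum(data.X**2, axis=0)
        _kernels.sweep_beta(
            data.X, B, state.Theta, E, U, state.zeta, C, xsq,
            state.lambdas.lambda1, state.lambdas.lambda2, frozen,
        )
        np.testing.assert_allclose(B, ref.B, atol=1e-10)
        np.testing.assert_allclose(E, data.Y - data.X @ B, atol=1e-10)

    def test_theta_sweep(self, rng):
        data, labels, state = _make_state(
            rng, square=True, lambdas=Hyperparameters(0.3, 0.2, 0.25, 0.8)
        )
        ref = CoordinateState(**{**vars(state)})
        ref.Theta = state.Theta.copy()
        G = state.Theta.shape[0]
        for g in range(G):
            for j in range(data.k):
                ref.Theta[g, j] = update_theta(g, j, ref, state.Ls[g])
        Theta = state.Theta.copy()
        F = data.X @ state.B
        eta = state.theta0[None, :] + F @ Theta.T
        U = state.zeta * (state.k_work - eta)
        D = state.zeta.T @ (F * F)
        for g in range(G):
            theta_g = np.ascontiguousarray(Theta[g])
            u_g = np.ascontiguousarray(U[:, g])
            zeta_g = np.ascontiguousarray(state.zeta[:, g])
            _kernels.sweep_theta_class(
                F, theta_g, u_g, zeta_g, np.ascontiguousarray(D[g]),
                np.ascontiguousarray(state.Ls[g]),
                state.lambdas.lambda3, state.lambdas.lambda4, True,
            )
            Theta[g] = theta_g
        np.testing.assert_allclose(Theta, ref.Theta, atol=1e-10)

    def test_full_sweep_decreases_surrogate(self, rng):
        data, labels, state = _make_state(rng)
        before = _surrogate(state)
        frozen = np.zeros((data.p, data.k), dtype=bool)
        for j in range(data.k):
            for l in range(data.p):
                state.B[l, j] = update_beta(j, l, state)
        for g in range(state.Theta.shape[0]):
            for j in range(data.k):
                state.Theta[g, j] = update_theta(g, j, state)
        assert _surrogate(state) <= before + 1e-10


class TestFit:
    def test_fully_penalized_limit_predicts_majority_class(self, rng):
        inst = None
        while inst is None:
            inst = weak_signal_instance(rng, n=60)
        data, labels = inst
        res = fit(data, labels, Hyperparameters(1e8, 0.0, 1e8, 0.0))
        assert np.all(res.B.B == 0)
        assert np.all(res.coef.Theta == 0)
        majority = labels.class_names[np.argmax(labels.Z.sum(axis=0))]
        pred, _ = res.predict(data.X)
        assert np.all(pred == majority)

    def test_separable_two_class_toy_reaches_full_training_accuracy(self):
        rng = np.random.default_rng(5)
        n = 20
        X = rng.standard_normal((n, 2))
        Bt = np.array([[1.0, 0.5], [-0.3, 0.8]])
        Y = X @ Bt + 0.1 * rng.standard_normal((n, 2))
        data = ExpressionData(X, Y)
        y = (X[:, 0] > 0).astype(int)
        labels = ClassLabels.from_labels(y, ["0", "1"])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ConvergenceWarning)
            res = fit(data, labels, Hyperparameters(0.05, 0.0, 0.05, 0.0))
        pred, _ = res.predict(data.X)
        assert np.mean(pred == y.astype(str)) == 1.0

    def test_predict_tie_breaks_to_lowest_class_index(self, rng):
        data, labels, _, _ = random_instance(rng)
        G = labels.G
        res = fit(data, labels, Hyperparameters(1e8, 0, 1e8, 0))
        res.coef.theta0[:] = 0.0  # force exact ties
        pred, P = res.predict(data.X)
        assert np.all(pred == labels.class_names[0])
        np.testing.assert_allclose(P, 1.0 / G)

    def test_predicted_probabilities_delegate_to_class_probabilities(self, rng):
        inst = None
        while inst is None:
            inst = weak_signal_instance(rng, n=50)
        data, labels = inst
        res = fit(data, labels, Hyperparameters(0.1, 0.1, 0.1, 0.0))
        _, P = res.predict(data.X)
        Xs = res.standardizer.transform_x(data.X)
        np.testing.assert_allclose(
            P, np.atleast_2d(class_probabilities(Xs, res.B, res.coef))
        )

    def test_lasso_limit_matches_reference_solver(self, rng):
        """lambda2 = lambda4 = 0, classifier frozen: per-target lasso."""
        from sklearn.linear_model import Lasso

        n, p, k = 40, 5, 3
        X = rng.standard_normal((n, p))
        X = (X - X.mean(0)) / X.std(0)
        Bt = np.where(rng.random((p, k)) < 0.5, 1.0, 0.0)
        Y = X @ Bt + 0.5 * rng.standard_normal((n, k))
        Y = (Y - Y.mean(0)) / Y.std(0)
        data = ExpressionData(X, Y)
        labels = ClassLabels.from_labels(np.arange(n) % 3)
        lam1 = 4.0
        cfg = FitConfig(tol=1e-12, max_cycles=500, standardize=False)
        res = fit(data, labels, Hyperparameters(lam1, 0, 0, 0), cfg,
                  fit_classifier=False)
        ref = Lasso(alpha=lam1 / n, fit_intercept=False, tol=1e-12, max_iter=50000)
        for j in range(k):
            ref.fit(X, Y[:, j])
            np.testing.assert_allclose(res.B.B[:, j], ref.coef_, atol=1e-4)

    def test_kkt_fixed_point_at_convergence(self, rng):
        inst = None
        while inst is None:
            inst = weak_signal_instance(rng, n=80)
        data, labels = inst
        lam = Hyperparameters(0.5, 0.1, 0.5, 0.0)
        cfg = FitConfig(tol=1e-13, max_cycles=2000)
        res = fit(data, labels, lam, cfg)
        assert res.converged
        wq = working_quantities(data, labels, res.B, res.coef)
        std = res.standardizer
        state = CoordinateState(
            X=std.transform_x(data.X), Y=std.transform_y(data.Y), Z=labels.Z,
            B=res.B.B.copy(), Theta=res.coef.Theta.copy(),
            theta0=res.coef.theta0.copy(), k_work=None, zeta=None, lambdas=lam,
        )
        wq = working_quantities(
            ExpressionData(state.X, state.Y), labels, res.B, res.coef
        )
        state.k_work, state.zeta = wq.k_work, wq.zeta
        for l, j in zip(*np.nonzero(res.B.B)):
            moved = update_beta(j, l, state) - state.B[l, j]
            assert abs(moved) < 1e-6

    def test_objective_trace_monotone_in_operating_regime(self, rng):
        for _ in range(5):
            inst = weak_signal_instance(rng, n=80)
            if inst is None:
                continue
            data, labels = inst
            res = fit(data, labels, random_lambdas(rng, lambda4_choices=(0.0,)))
            tr = np.array(res.objective_trace)
            assert np.all(tr[1:] <= tr[:-1] + 1e-8 * np.maximum(1, np.abs(tr[:-1])))
            assert not res.diverged

    def test_divergence_is_reported_not_silent(self):
        """Three consecutive objective increases beyond slack must be flagged
        with a warning; transient sub-slack bumps and recoveries must not."""
        from grnmc.optimizer import DivergenceMonitor

        mon = DivergenceMonitor()
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always")
            assert not mon.update(100.0, 99.0)
            assert not mon.update(99.0, 99.0 + 1e-9)  # within slack
            assert not mon.update(99.0, 100.0)
            assert not mon.update(100.0, 101.0)
            assert not mon.update(101.0, 100.5)  # recovery resets the count
            assert not mon.update(100.5, 101.0)
            assert not mon.update(101.0, 102.0)
            assert mon.update(102.0, 103.0)  # third straight increase
        assert mon.diverged
        assert any(issubclass(w.category, ConvergenceWarning) for w in caught)

    def test_self_regulation_frozen_in_square_case(self, rng):
        inst = None
        while inst is None:
            inst = weak_signal_instance(rng, n=60, square=True)
        data, labels = inst
        res = fit(data, labels, Hyperparameters(0.1, 0.1, 0.1, 0.5))
        assert np.all(np.diag(res.B.B) == 0.0)

    def test_network_back_transformation(self, rng):
        inst = None
        while inst is None:
            inst = weak_signal_instance(rng, n=60)
        data, labels = inst
        res = fit(data, labels, Hyperparameters(0.1, 0.1, 0.1, 0.0))
        B_raw = res.network_original_scale()
        s = res.standardizer
        np.testing.assert_allclose(
            B_raw, res.B.B * s.y_scale[None, :] / s.x_scale[:, None]
        )
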