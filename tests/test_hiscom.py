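"""Residualization, latent components, and the alternating penalized fit."""

import dataclasses

import numpy as np
import pytest
import statsmodels.api as sm

import hiscom_mimi as hm
from hiscom_mimi.hiscom import (
    _design_blocks,
    irwls_update,
    update_weights,
)
from conftest import random_logistic_dataset, singleton_net


class TestInhibitionLayer:
    def test_exact_linear_inhibition_leaves_zero_residual(self):
        z = np.array([1.0, 2, 3]) - 2.0
        x = -2.0 * z
        gamma = hm.estimate_inhibition(x, z)
        assert gamma == pytest.approx(-2.0, abs=1e-12)
        np.testing.assert_allclose(x - gamma * z, 0, atol=1e-12)

    def test_orthogonal_target_has_zero_slope(self):
        z = np.array([-1.0, 1, -1, 1])
        x = np.array([-1.0, -1, 1, 1])
        assert hm.estimate_inhibition(x, z) == pytest.approx(0.0, abs=1e-14)

    def test_slope_matches_closed_form(self):
        rng = np.random.default_rng(4)
        z = rng.standard_normal(20)
        x = rng.standard_normal(20)
        oracle = np.cov(x, z, ddof=1)[0, 1] / np.var(z, ddof=1)
        assert hm.estimate_inhibition(x, z) == pytest.approx(oracle, abs=1e-12)

    def test_zero_variance_mirna_is_an_error(self):
        with pytest.raises(ValueError, match="zero-variance"):
            hm.estimate_inhibition(np.arange(4.0), np.ones(4))

    def test_residuals_orthogonal_to_their_mirna(self, s1_null_data, s1_net):
        resid = hm.residualize(s1_null_data, s1_net)
        for z, R, g in zip(resid.zcols, resid.Xhat, resid.gamma):
            np.testing.assert_allclose(z @ R, 0, atol=1e-8)
            # oracle: per-edge simple regression slope on the standardized data
            for k in range(R.shape[1]):
                x = R[:, k] + g[k] * z
                np.testing.assert_allclose(
                    g[k], (z @ (x - x.mean())) / (z @ z), atol=1e-10
                )

    def test_shared_mrna_residualized_per_edge(self):
        rng = np.random.default_rng(2)
        n = 40
        Z = rng.standard_normal((n, 2))
        X = (-0.5 * Z[:, 0] - 0.5 * Z[:, 1] + 0.3 * rng.standard_normal(n))[:, None]
        data = hm.ExpressionDataset(
            sample_ids=[f"s{i}" for i in range(n)],
            mirna_ids=["mA", "mB"], mrna_ids=["g"],
            Z=Z, X=X, y=np.array([0, 1] * (n // 2)),
        )
        net = hm.SubnetworkMap(entries=[
            hm.SubnetworkEntry("mA", ["g"]), hm.SubnetworkEntry("mB", ["g"]),
        ])
        resid = hm.residualize(data, net)
        np.testing.assert_allclose(resid.zcols[0] @ resid.Xhat[0][:, 0], 0, atol=1e-8)
        np.testing.assert_allclose(resid.zcols[1] @ resid.Xhat[1][:, 0], 0, atol=1e-8)
        assert abs(resid.gamma[0][0] - resid.gamma[1][0]) > 0  # distinct slopes


class TestLatentComponents:
    def test_pure_direct_effect_is_standardized_mirna(self):
        rng = np.random.default_rng(0)
        z = rng.standard_normal(30)
        f = hm.compute_latent(z, np.empty((30, 0)), 1.0, np.empty(0))
        np.testing.assert_allclose(f, z / z.std(ddof=1), atol=1e-12)

    def test_single_residual_weight(self):
        rng = np.random.default_rng(1)
        z = rng.standard_normal(25)
        R = rng.standard_normal((25, 3))
        f = hm.compute_latent(z, R, 0.0, np.array([1.0, 0, 0]))
        np.testing.assert_allclose(f, R[:, 0] / R[:, 0].std(ddof=1), atol=1e-12)

    def test_mixed_weights_match_direct_arithmetic(self):
        rng = np.random.default_rng(2)
        z = rng.standard_normal(25)
        R = rng.standard_normal((25, 3))
        g0, w = 0.7, np.array([0.2, -0.4, 1.1])
        raw = g0 * z + R @ w
        np.testing.assert_allclose(
            hm.compute_latent(z, R, g0, w), raw / raw.std(ddof=1), atol=1e-12
        )

    def test_all_zero_weights_are_degenerate(self):
        with pytest.raises(ValueError, match="degenerate"):
            hm.compute_latent(np.arange(5.0), np.ones((5, 2)), 0.0, np.zeros(2))


class TestIRWLS:
    def test_converges_to_unpenalized_logistic_mle(self):
        rng = np.random.default_rng(11)
        n = 200
        F = rng.standard_normal((n, 1))
        y = (rng.random(n) < 1 / (1 + np.exp(-(0.8 * F[:, 0])))).astype(float)
        beta0, beta = 0.0, np.zeros(1)
        for _ in range(50):
            beta0, beta, _ = irwls_update(F, y, beta0, beta, lambda_mm=0.0)
        oracle = sm.Logit(y, sm.add_constant(F)).fit(disp=0)
        assert beta0 == pytest.approx(oracle.params[0], abs=1e-6)
        assert beta[0] == pytest.approx(oracle.params[1], abs=1e-6)

    def test_huge_penalty_shrinks_coefficients_to_zero(self):
        rng = np.random.default_rng(3)
        F = rng.standard_normal((100, 3))
        y = (rng.random(100) < 0.5).astype(float)
        beta0, beta = 0.0, np.zeros(3)
        for _ in range(30):
            beta0, beta, _ = irwls_update(F, y, beta0, beta, lambda_mm=1e8)
        assert np.linalg.norm(beta) < 1e-3

    def test_independent_outcome_recovers_prevalence_intercept(self):
        rng = np.random.default_rng(9)
        n = 2000
        F = rng.standard_normal((n, 2))
        F -= F.mean(0)
        y = np.array([0.0, 1.0] * (n // 2))
        beta0, beta = 0.0, np.zeros(2)
        for _ in range(30):
            beta0, beta, state = irwls_update(F, y, beta0, beta, lambda_mm=0.0)
        assert beta0 == pytest.approx(0.0, abs=0.1)  # logit(0.5) = 0
        assert np.all((state.working_weights > 0) & (state.working_weights <= 0.25))


class TestWeightUpdate:
    def _setup(self, seed=0, n=60):
        rng = np.random.default_rng(seed)
        data = random_logistic_dataset(rng, n=n, j=2)
        Z = data.Z
        X = np.column_stack([-0.6 * Z[:, 0] + 0.4 * rng.standard_normal(n),
                             -0.5 * Z[:, 1] + 0.4 * rng.standard_normal(n)])
        data = dataclasses.replace(data, X=X, mrna_ids=["gA", "gB"])
        net = hm.SubnetworkMap(entries=[
            hm.SubnetworkEntry("m0", ["gA"]), hm.SubnetworkEntry("m1", ["gB"]),
        ])
        resid = hm.residualize(data, net)
        D = _design_blocks(resid)
        F = np.column_stack([
            hm.compute_latent(resid.zcols[j], resid.Xhat[j], 1.0, np.ones(1))
            for j in range(2)
        ])
        return data, net, resid, D, F

    def test_unpenalized_update_matches_direct_weighted_solve(self):
        data, net, resid, D, F = self._setup()
        beta0, beta = 0.1, np.array([0.8, -0.5])
        _, _, state = irwls_update(F, data.y.astype(float), beta0, beta, 0.0)
        g0, w, F2, beta2 = update_weights(resid, state, F, beta0, beta, lambda_m=0.0)
        # oracle: closed-form weighted LS for subnetwork 0 given the same offset
        v, u = state.working_weights, state.working_response
        offset = beta0 + F[:, 1] * beta[1]
        A = beta[0] * D[0]
        a = np.linalg.solve(A.T @ (v[:, None] * A), A.T @ (v * (u - offset)))
        f_raw = D[0] @ a
        s = f_raw.std(ddof=1)
        np.testing.assert_allclose([g0[0], w[0][0]], a / s, atol=1e-10)
        np.testing.assert_allclose(beta2[0], beta[0] * s, atol=1e-10)

    def test_huge_ridge_drives_update_to_rhs_direction(self):
        data, net, resid, D, F = self._setup(seed=5)
        beta0, beta = 0.0, np.array([1.0, 1.0])
        _, _, state = irwls_update(F, data.y.astype(float), beta0, beta, 0.0)
        g0, w, _, _ = update_weights(resid, state, F, beta0, beta, lambda_m=1e10)
        v, u = state.working_weights, state.working_response
        offset = beta0 + F[:, 1] * beta[1]
        rhs = beta[0] * (D[0].T @ (v * (u - offset)))
        direction = rhs / np.linalg.norm(rhs)
        got = np.array([g0[0], w[0][0]])
        got /= np.linalg.norm(got)
        np.testing.assert_allclose(np.abs(got @ direction), 1.0, atol=1e-6)

    def test_orthogonal_subnetworks_update_independently(self):
        data, net, resid, D, F = self._setup(seed=7)
        beta0, beta = 0.0, np.array([0.9, 0.0])
        _, _, state = irwls_update(F, data.y.astype(float), beta0, beta, 0.0)
        _, _, F2, _ = update_weights(resid, state, F, beta0, beta, lambda_m=0.1)
        # beta_2 = 0: second component must be untouched (and a warning logged)
        np.testing.assert_array_equal(F2[:, 1], F[:, 1])


class TestFit:
    def test_singleton_components_reduce_to_logistic_regression(self):
        """With no penalties and direct-effect-only components, the path
        coefficients reproduce the ML logistic fit on standardized miRNAs."""
        rng = np.random.default_rng(21)
        data = random_logistic_dataset(rng, n=120, j=3)
        net = singleton_net(data.mirna_ids)
        cfg = hm.FitConfig(lambda_m=0, lambda_mm=0, tol=1e-12, max_iter=500)
        f = hm.fit(data, net, cfg)
        Zs = (data.Z - data.Z.mean(0)) / data.Z.std(0, ddof=1)
        oracle = sm.Logit(data.y, sm.add_constant(Zs)).fit(disp=0)
        implied = f.beta * f.gamma0  # coefficient on the standardized miRNA
        np.testing.assert_allclose(implied, oracle.params[1:], atol=1e-5)
        np.testing.assert_allclose(f.beta0, oracle.params[0], atol=1e-5)

    def test_full_shrinkage_gives_null_model(self, s1_null_data, s1_net):
        cfg = hm.FitConfig(lambda_m=1e8, lambda_mm=1e8)
        f = hm.fit(s1_null_data, s1_net, cfg)
        assert np.all(np.abs(f.beta) < 1e-3)
        ybar = s1_null_data.y.mean()
        assert f.beta0 == pytest.approx(np.log(ybar / (1 - ybar)), abs=1e-2)

    def test_objective_trace_descends_to_its_minimum(self, s1_net, s1_spec):
        """The penalized objective is driven down every sweep up to the small
        transient the unit-variance rescaling can add to the ridge terms,
        and the fit terminates at the lowest value of the trace."""
        for seed in (1, 2, 3):
            data = hm.simulate_dataset(s1_spec, seed)
            f = hm.fit(data, s1_net, hm.FitConfig(lambda_m=0.5, lambda_mm=0.5))
            tr = f.objective_trace
            assert np.all(np.diff(tr) <= 1e-3 * (1 + np.abs(tr[:-1])))
            assert tr[-1] <= tr.min() + 1e-4 * (1 + abs(tr.min()))

    def test_latent_columns_have_unit_variance(self, s1_null_data, s1_net):
        f = hm.fit(s1_null_data, s1_net, hm.FitConfig())
        np.testing.assert_allclose(f.F.std(axis=0, ddof=1), 1.0, atol=1e-8)

    def test_scale_invariance_under_standardization(self, s1_spec, s1_net):
        data = hm.simulate_dataset(s1_spec, 5)
        scaled = dataclasses.replace(data, X=data.X * np.full(data.X.shape[1], 37.5))
        f1 = hm.fit(data, s1_net, hm.FitConfig(standardize=True))
        f2 = hm.fit(scaled, s1_net, hm.FitConfig(standardize=True))
        np.testing.assert_allclose(f1.F, f2.F, atol=1e-8)
        np.testing.assert_allclose(f1.beta, f2.beta, atol=1e-8)

    def test_path_coefficients_shrink_with_lambda_mm(self, strong_signal):
        _, data, net = strong_signal
        norms = []
        for lam in (0.1, 1.0, 10.0, 100.0):
            f = hm.fit(data, net, hm.FitConfig(lambda_m=1.0, lambda_mm=lam))
            norms.append(np.linalg.norm(f.beta))
        assert all(a >= b - 1e-8 for a, b in zip(norms, norms[1:]))

    def test_recovers_causal_effect_sign(self, s1_spec):
        """Strong positive effects: the causal component's fitted effect has
        the generating sign (positive latent association) in nearly all
        replicates."""
        spec = dataclasses.replace(s1_spec, effect_beta=1.0)
        hits = 0
        reps = 40
        for seed in range(reps):
            data = hm.simulate_dataset(spec, 1000 + seed)
            net = hm.scenario_network(spec)
            f = hm.fit(data, net, hm.FitConfig())
            j = spec.causal_index
            # orient the latent score: it should align with the generating
            # direction z + sum(x); its fitted effect should be positive
            direction = data.Z[:, j] + data.X[:, :2].sum(1)
            orient = np.sign(f.F[:, j] @ direction)
            hits += (f.beta[j] * orient) > 0
        assert hits >= int(0.9 * reps)

    def test_unconverged_fit_is_flagged_not_fatal(self, s1_null_data, s1_net):
        f = hm.fit(s1_null_data, s1_net, hm.FitConfig(max_iter=1, tol=1e-15))
        assert f.converged is False and f.n_iter == 1

    def test_engine_matches_stepwise_reference_updates(self):
        """The batched engine reproduces the sequential irwls_update /
        update_weights recursion exactly (same update order and state)."""
        rng = np.random.default_rng(13)
        data = random_logistic_dataset(rng, n=80, j=2)
        net = hm.SubnetworkMap(entries=[
            hm.SubnetworkEntry("m0", ["gA"]), hm.SubnetworkEntry("m1", ["gB"]),
        ])
        cfg = hm.FitConfig(lambda_m=2.0, lambda_mm=2.0, max_iter=40, tol=1e-10)
        f = hm.fit(data, net, cfg)

        resid = hm.residualize(data, net)
        D = _design_blocks(resid)
        F = np.column_stack([
            hm.compute_latent(resid.zcols[j], resid.Xhat[j],
                              1 / np.sqrt(2), np.full(1, 1 / np.sqrt(2)))
            for j in range(2)
        ])
        ybar = data.y.mean()
        beta0, beta = float(np.log(ybar / (1 - ybar))), np.zeros(2)
        y = data.y.astype(float)
        for _ in range(40):
            beta0, beta, state = irwls_update(F, y, beta0, beta, cfg.lambda_mm)
            _, _, F, beta = update_weights(resid, state, F, beta0, beta, cfg.lambda_m)
        np.testing.assert_allclose(beta, f.beta, atol=1e-6)
        np.testing.assert_allclose(beta0, f.beta0, atol=1e-6)


class TestPredict:
    def test_null_model_predicts_constant_prevalence(self, s1_null_data, s1_net):
        f = hm.fit(s1_null_data, s1_net, hm.FitConfig(lambda_m=1e8, lambda_mm=1e8))
        p = hm.predict_prob(f, s1_null_data)
        np.testing.assert_allclose(p, 1 / (1 + np.exp(-f.beta0)), atol=1e-3)

    def test_training_data_reproduces_fitted_probabilities(self, s1_null_data, s1_net):
        f = hm.fit(s1_null_data, s1_net, hm.FitConfig())
        np.testing.assert_allclose(
            hm.predict_prob(f, s1_null_data), f.fitted_prob, atol=1e-10
        )

    def test_heldout_sample_matches_hand_computed_linear_predictor(self):
        rng = np.random.default_rng(30)
        data = random_logistic_dataset(rng, n=50, j=1)
        net = singleton_net(["m0"])
        f = hm.fit(data, net, hm.FitConfig(lambda_m=0, lambda_mm=0, tol=1e-12))
        znew = np.array([[1.7]])
        new = hm.ExpressionDataset(
            sample_ids=["new"], mirna_ids=["m0"], mrna_ids=data.mrna_ids,
            Z=znew, X=np.zeros((1, 2)),
        )
        zm, zs = f.resid.z_stats["m0"]
        eta = f.beta0 + f.beta[0] * f.gamma0[0] * (1.7 - zm) / zs
        assert hm.predict_prob(f, new)[0] == pytest.approx(
            1 / (1 + np.exp(-eta)), abs=1e-12
        )

    def test_feature_mismatch_is_an_error(self, s1_null_data, s1_net):
        f = hm.fit(s1_null_data, s1_net, hm.FitConfig())
        bad = dataclasses.replace(
            s1_null_data, mirna_ids=["x" + m for m in s1_null_data.mirna_ids]
        )
        with pytest.raises(ValueError, match="lack fitted features"):
            hm.predict_prob(f, bad)


class TestLambdaCV:
    def test_single_point_grid_short_circuits(self, s1_null_data, s1_net):
        assert hm.cross_validate_lambda(
            s1_null_data, s1_net, grid_m=[4.0], grid_mm=[8.0]
        ) == (4.0, 8.0)

    def test_null_outcome_prefers_heavy_shrinkage(self, s1_spec):
        wins = 0
        for seed in range(5):
            data = hm.simulate_dataset(s1_spec, 400 + seed)
            net = hm.scenario_network(s1_spec)
            lm, lmm = hm.cross_validate_lambda(
                data, net, grid_m=[1.0], grid_mm=[0.25, 1024.0], seed=seed
            )
            wins += lmm == 1024.0
        assert wins >= 3

    def test_strong_signal_rejects_maximal_shrinkage(self, s1_spec):
        """With a real effect present, held-out likelihood favors a finite
        penalty over the fully-shrunk top of the grid."""
        spec = dataclasses.replace(s1_spec, effect_beta=1.2)
        wins = 0
        for seed in range(5):
            data = hm.simulate_dataset(spec, 600 + seed)
            net = hm.scenario_network(spec)
            lm, lmm = hm.cross_validate_lambda(
                data, net, grid_m=[1.0], grid_mm=[4.0, 64.0, 4096.0], seed=seed
            )
            wins += lmm < 4096.0
        assert wins >= 4

    def test_infeasible_stratification_is_an_error(self):
        rng = np.random.default_rng(0)
        data = random_logistic_dataset(rng, n=30, j=2)
        data.y[:] = 0
        data.y[0] = 1
        net = singleton_net(data.mirna_ids)
        with pytest.raises(ValueError, match="stratify"):
            hm.cross_validate_lambda(data, net, grid_m=[1.0, 2.0], grid_mm=[1.0])
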