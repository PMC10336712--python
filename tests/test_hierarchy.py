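"""Hierarchical model: density contract, sampler correctness, diagnostics."""

import numpy as np
import pytest

from _oracles import density_oracle, quadrature_posterior_mu, toy_dataset
from metapriors.hierarchy import (
    HierarchicalEffectsModel,
    McmcSettings,
    ModelSpec,
    PosteriorDraws,
    compute_dic,
    fit_model,
    gelman_rubin,
    log_posterior,
    residual_deviance,
    split_rhat,
)


def _toy6():
    return toy_dataset(
        y=[-0.2, 0.1, -0.4, 0.0, -0.1, 0.3],
        se=[0.2, 0.25, 0.3, 0.2, 0.15, 0.25],
        areas=["a", "a", "a", "b", "b", "b"],
    )


def _full_point(data, **overrides):
    point = {
        "M": -0.1, "eta": 0.4, "kappa": 2.0, "nu": 0.05,
        "mu": np.array([-0.15, 0.05]), "tau2": np.array([0.04, 0.09]),
        "theta": data.y * 0.9,
    }
    point.update(overrides)
    return point


class TestLogPosterior:
    def test_outside_support_is_minus_inf(self):
        data = _toy6()
        spec = ModelSpec(variance_family="gamma")
        assert log_posterior(spec, data, _full_point(data, eta=5.1)) == -np.inf
        assert log_posterior(spec, data, _full_point(data, tau2=np.array([-0.01, 0.09]))) == -np.inf
        assert log_posterior(spec, data, _full_point(data, kappa=51.0)) == -np.inf

    def test_normal_kernel_unit_move(self):
        data = toy_dataset(y=[0.2], se=[0.1], areas=["a"])
        spec = ModelSpec(variance_family="gamma")
        # near-flat theta prior (huge tau^2) so only the y-kernel moves
        base = {"M": 0.0, "eta": 1.0, "kappa": 2.0, "nu": 0.05,
                "mu": np.array([0.2]), "tau2": np.array([1e6])}
        at_y = log_posterior(spec, data, {**base, "theta": np.array([0.2])})
        off = log_posterior(spec, data, {**base, "theta": np.array([0.3])})
        assert off - at_y == pytest.approx(-0.5, abs=1e-6)

    @pytest.mark.parametrize("family", ["lognormal", "gamma", "halfnormal"])
    @pytest.mark.parametrize("model", ["model1", "model2"])
    def test_matches_independent_density_oracle(self, family, model):
        data = toy_dataset(
            y=[-0.2, 0.1, -0.4, 0.0, -0.1, 0.3],
            se=[0.2, 0.25, 0.3, 0.2, 0.15, 0.25],
            areas=["a", "a", "a", "b", "b", "b"],
            comparison=["active_vs_active", "active_vs_inactive"] * 3,
        )
        spec = ModelSpec(model=model, variance_family=family)
        point = _full_point(data, B=0.1)
        if family == "halfnormal":
            point["kappa"], point["nu"] = 0.01, 0.3
        ours = log_posterior(spec, data, point)
        oracle = density_oracle(spec, data, point)
        # both are exact log densities; the implementation drops constant
        # terms nowhere, so agreement is to float precision
        assert ours == pytest.approx(oracle, abs=1e-8)

    def test_dimension_mismatch_is_structural_error(self):
        data = _toy6()
        with pytest.raises(ValueError, match="shape"):
            log_posterior(ModelSpec(), data, _full_point(data, mu=np.zeros(3)))


class TestResidualDeviance:
    def test_perfect_fit_zero(self):
        data = _toy6()
        assert residual_deviance(data, data.y) == 0.0

    def test_two_se_off_is_four(self):
        data = toy_dataset(y=[0.1], se=[0.2], areas=["a"])
        assert residual_deviance(data, np.array([0.1 + 0.4])) == pytest.approx(4.0)

    def test_matches_independent_sum(self, rng):
        data = _toy6()
        theta = rng.normal(size=6)
        expected = sum((yi - ti) ** 2 / si**2 for yi, si, ti in zip(data.y, data.se, theta))
        assert residual_deviance(data, theta) == pytest.approx(expected)


class TestDic:
    def test_degenerate_draws_pd_zero(self, fitted_model1, small_dataset):
        data, _ = small_dataset
        draws = fitted_model1.draws
        theta0 = draws.stacked("theta")[:1].repeat(20, axis=0).reshape(2, 10, -1)
        degenerate = PosteriorDraws(
            M=np.zeros((2, 10)), eta=np.ones((2, 10)), kappa=np.ones((2, 10)),
            nu=np.ones((2, 10)), mu=np.zeros((2, 10, data.n_areas)),
            tau2=np.ones((2, 10, data.n_areas)), B=None, theta=theta0,
            deviance=np.zeros((2, 10)), theta_mean=theta0[0, 0],
            area_index=data.area_index, spec=ModelSpec(), seed=0,
        )
        dbar, p_d, dic = compute_dic(degenerate, data)
        assert p_d == pytest.approx(0.0, abs=1e-9)
        assert dic == pytest.approx(dbar)

    def test_saturated_model_pd_near_n(self, small_dataset, rng):
        data, _ = small_dataset
        n = len(data)
        theta = data.y + data.se * rng.standard_normal((2, 4000, n))
        sat = PosteriorDraws(
            M=np.zeros((2, 4000)), eta=np.ones((2, 4000)), kappa=np.ones((2, 4000)),
            nu=np.ones((2, 4000)), mu=np.zeros((2, 4000, data.n_areas)),
            tau2=np.ones((2, 4000, data.n_areas)), B=None, theta=theta,
            deviance=np.zeros((2, 4000)), theta_mean=theta.mean(axis=(0, 1)),
            area_index=data.area_index, spec=ModelSpec(), seed=0,
        )
        _, p_d, _ = compute_dic(sat, data)
        # pD of the saturated normal model equals the record count
        assert p_d == pytest.approx(n, rel=0.05)

    def test_identity_and_positive_pd_on_fit(self, fitted_model1):
        d = fitted_model1.diagnostics
        assert d.dic == d.dbar + d.p_d
        assert d.p_d >= 0


class TestGelmanRubin:
    def test_iid_chains_near_one(self, rng):
        x = rng.standard_normal((4, 10_000))
        assert 0.99 < split_rhat(x) < 1.01

    def test_separated_chains_flagged(self, rng):
        x = rng.standard_normal((2, 2_000))
        x[1] += 10.0
        assert split_rhat(x) > 1.1

    def test_single_chain_rejected(self):
        with pytest.raises(ValueError, match="2 chains"):
            split_rhat(np.zeros((1, 100)))

    def test_constant_chains_undefined(self):
        assert np.isnan(split_rhat(np.ones((3, 100))))

    def test_named_parameter_lookup(self, fitted_model1):
        r = gelman_rubin(fitted_model1.draws, "M")
        assert np.isfinite(r)
        with pytest.raises(KeyError):
            gelman_rubin(fitted_model1.draws, "nope")

    def test_agrees_with_arviz(self, rng):
        az = pytest.importorskip("arviz")
        x = rng.standard_normal((3, 1_000)) + np.linspace(0, 0.3, 3)[:, None]
        ours = split_rhat(x)
        theirs = float(az.rhat(az.from_dict(posterior={"x": x}), method="split")["x"].values)
        assert ours == pytest.approx(theirs, abs=1e-6)


class TestFit:
    def test_same_seed_identical_draws(self):
        data = _toy6()
        settings = McmcSettings(n_chains=2, n_burn_in=200, n_samples=400, seed=11)
        r1 = HierarchicalEffectsModel(data).fit(settings)
        r2 = HierarchicalEffectsModel(data).fit(settings)
        np.testing.assert_array_equal(r1.draws.M, r2.draws.M)
        np.testing.assert_array_equal(r1.draws.tau2, r2.draws.tau2)

    def test_draw_shapes(self, fitted_model1, small_dataset):
        data, _ = small_dataset
        d = fitted_model1.draws
        assert d.M.shape == (3, 2_000)
        assert d.mu.shape == (3, 2_000, data.n_areas)
        assert d.theta.shape == (3, 2_000, len(data))
        assert np.all(d.tau2 > 0)

    def test_refuses_single_area_without_pinning(self):
        data = toy_dataset(y=[0.1, 0.2, 0.3], se=[0.1] * 3, areas=["a"] * 3)
        with pytest.raises(ValueError, match="fewer than 2 areas"):
            HierarchicalEffectsModel(data)

    def test_model2_requires_comparison_type(self):
        data = _toy6()
        with pytest.raises(ValueError, match="comparison_type"):
            HierarchicalEffectsModel(data, model="model2")

    def test_shrinkage_toward_overall_mean(self, fitted_model1, small_dataset):
        data, _ = small_dataset
        y, a = data.y, data.area_codes
        m_post = fitted_model1.posterior_mean("M")
        mu_post = fitted_model1.posterior_mean("mu")
        for k in range(data.n_areas):
            raw = y[a == k].mean()
            lo, hi = sorted((raw, m_post))
            assert lo - 0.02 <= mu_post[k] <= hi + 0.02

    def test_single_area_tight_se_recovers_common_value(self):
        c = 0.7
        data = toy_dataset(y=[c] * 4, se=[0.001] * 4, areas=["only"] * 4)
        spec = ModelSpec(fixed={"tau2": [1e-4], "eta": 4.0, "kappa": 1.0, "nu": 1.0})
        res = HierarchicalEffectsModel(data, spec).fit(
            McmcSettings(n_chains=2, n_burn_in=500, n_samples=2_000, seed=2)
        )
        assert res.posterior_mean("mu")[0] == pytest.approx(c, abs=0.01)

    def test_matches_grid_quadrature_with_pinned_hyperparameters(self):
        data = _toy6()
        tau2 = [0.05, 0.08]
        eta = 0.3
        spec = ModelSpec(fixed={"tau2": tau2, "eta": eta, "kappa": 1.0, "nu": 1.0})
        res = HierarchicalEffectsModel(data, spec).fit(
            McmcSettings(n_chains=3, n_burn_in=1_000, n_samples=9_000, seed=4)
        )
        mu_oracle, m_oracle = quadrature_posterior_mu(data, tau2, eta)
        np.testing.assert_allclose(res.posterior_mean("mu"), mu_oracle, atol=0.01)
        assert res.posterior_mean("M") == pytest.approx(m_oracle, abs=0.02)

    def test_functional_wrapper(self, small_dataset):
        data, _ = small_dataset
        draws, diag = fit_model(
            data, ModelSpec(), McmcSettings(n_chains=2, n_burn_in=200, n_samples=400, seed=1)
        )
        assert draws.n_chains == 2 and diag.dic == diag.dbar + diag.p_d


class TestPersistence:
    def test_npz_round_trip(self, fitted_model1, tmp_path):
        path = fitted_model1.draws.save(tmp_path / "draws.npz")
        back = PosteriorDraws.load(path)
        np.testing.assert_array_equal(back.M, fitted_model1.draws.M)
        np.testing.assert_array_equal(back.theta, fitted_model1.draws.theta)
        assert back.area_index == fitted_model1.draws.area_index
        assert back.spec.variance_family == fitted_model1.spec.variance_family

    def test_summary_table(self, fitted_model1):
        tab = fitted_model1.summary()
        assert "M" in tab.index and "deviance" in tab.index
        assert {"mean", "sd", "rhat"} <= set(tab.columns)
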