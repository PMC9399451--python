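import json

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import minimize

from maxhab import maxent
from maxhab.maxent import Feature, FeatureExpansion, ModelConfig

from conftest import make_binary_expansion


def penalized_objective(lam, m_pres, x_bg, penalty):
    s = x_bg @ lam
    smax = s.max()
    log_z = smax + np.log(np.exp(s - smax).sum())
    return lam @ m_pres - log_z - penalty @ np.abs(lam)


def oracle_optimum(m_pres, x_bg, penalty):
    """Generic convex optimizer on the penalized objective.

    The L1 term is handled exactly by the positive/negative split
    lam = u - v with u, v >= 0, which makes the problem smooth and convex.
    """
    f = x_bg.shape[1]

    def neg(uv):
        lam = uv[:f] - uv[f:]
        return -(lam @ m_pres) + _log_z(x_bg, lam) + penalty @ (uv[:f] + uv[f:])

    def _log_z(x, lam):
        s = x @ lam
        smax = s.max()
        return smax + np.log(np.exp(s - smax).sum())

    res = minimize(
        neg,
        np.zeros(2 * f),
        method="L-BFGS-B",
        bounds=[(0, None)] * 2 * f,
        options={"ftol": 1e-14, "gtol": 1e-10, "maxiter": 5000},
    )
    return -res.fun


def random_expansion(rng, n_features):
    n_pres, n_bg = 8, 30
    xb = rng.uniform(size=(n_bg, n_features))
    # pin the background min-max to [0,1] so the expansion invariant holds
    xb[0] = 0.0
    xb[1] = 1.0
    xp = rng.uniform(size=(n_pres, n_features))
    return FeatureExpansion(
        features=[Feature(f"v{j}", "linear") for j in range(n_features)],
        norm_min=np.zeros(n_features),
        norm_max=np.ones(n_features),
        x_presence=xp,
        x_background=xb,
    )


class TestBuildFeatures:
    @staticmethod
    def table(n_pres=5, n_bg=40, seed=0, categorical=False):
        rng = np.random.default_rng(seed)
        n = n_pres + n_bg
        df = pd.DataFrame({"role": ["presence"] * n_pres + ["background"] * n_bg})
        if categorical:
            df["geo"] = rng.integers(1, 5, size=n)
        else:
            df["a"] = rng.normal(10, 2, size=n)
            df["b"] = rng.uniform(size=n)
        return df

    def test_lq_gives_linear_plus_square_per_variable(self):
        table = self.table()
        exp = maxent.build_features(table, ModelConfig("LQ"), {"a": "continuous", "b": "continuous"})
        kinds = [f.kind for f in exp.features]
        assert kinds.count("linear") == 2 and kinds.count("quadratic") == 2

    def test_categorical_expands_to_one_indicator_per_class(self):
        table = self.table(categorical=True)
        exp = maxent.build_features(table, ModelConfig("L"), {"geo": "categorical"})
        assert exp.n_features == 4
        assert all(f.kind == "category" for f in exp.features)

    def test_lqh_with_50_knots_yields_104_features_for_two_variables(self):
        table = self.table(n_bg=400)  # plenty of distinct quantiles
        exp = maxent.build_features(
            table, ModelConfig("LQH"), {"a": "continuous", "b": "continuous"}, n_hinge_knots=50
        )
        assert exp.n_features == 2 * (1 + 1 + 50)

    def test_design_values_lie_in_unit_interval(self):
        table = self.table(n_bg=100, seed=3)
        exp = maxent.build_features(table, ModelConfig("LQH"), {"a": "continuous", "b": "continuous"})
        for x in (exp.x_presence, exp.x_background):
            assert x.min() >= 0.0 and x.max() <= 1.0

    def test_constant_variable_is_dropped_with_remaining_survivors(self):
        table = self.table()
        table["c"] = 5.0
        exp = maxent.build_features(
            table, ModelConfig("LQ"),
            {"a": "continuous", "b": "continuous", "c": "continuous"},
        )
        assert "c" not in {f.variable for f in exp.features}

    def test_class_seen_only_at_presences_is_kept(self):
        table = self.table(categorical=True)
        table.loc[table["role"] == "presence", "geo"] = 99
        exp = maxent.build_features(table, ModelConfig("L"), {"geo": "categorical"})
        assert any(f.param == 99.0 for f in exp.features)


class TestFit:
    def test_closed_form_binary_feature(self):
        # bg feature (0,0,1,1), presences all 1, penalty 0.1:
        # stationarity gives e^lam/(1+e^lam) = 1 - 0.1, i.e. lam = ln 9
        exp = make_binary_expansion([0, 0, 1, 1], [1, 1, 1])
        model = maxent.fit(exp, ModelConfig("L", 1.0), betas=np.array([0.1]))
        assert model.weights[0] == pytest.approx(np.log(9.0), abs=1e-6)

    def test_matched_means_give_the_uniform_model(self):
        # presence mean equals background mean exactly -> any positive
        # penalty zeroes every weight and the raw distribution is uniform
        exp = make_binary_expansion([0, 1, 0, 1], [0, 1])
        model = maxent.fit(exp, ModelConfig("L", 1.0), betas=np.array([0.05]))
        assert model.n_params == 0
        raw = maxent.predict_raw(model, exp.x_background)
        np.testing.assert_allclose(raw, 0.25, atol=1e-12)

    def test_huge_multiplier_zeroes_all_weights(self):
        rng = np.random.default_rng(1)
        exp = random_expansion(rng, 4)
        model = maxent.fit(exp, ModelConfig("L", 1e6), betas=np.full(4, 0.01))
        assert model.n_params == 0

    @pytest.mark.parametrize("seed,n_features,rm", [
        (0, 2, 0.5), (1, 3, 1.0), (2, 4, 2.0), (3, 5, 5.0), (4, 6, 1.0),
        (5, 6, 0.5), (6, 2, 2.0), (7, 4, 1.0),
    ])
    def test_objective_matches_generic_convex_optimizer(self, seed, n_features, rm):
        rng = np.random.default_rng(seed)
        exp = random_expansion(rng, n_features)
        betas = rng.uniform(0.01, 0.2, size=n_features)
        config = ModelConfig("L", rm)
        model = maxent.fit(exp, config, betas=betas, tol=1e-10, kkt_tol=1e-8)
        penalty = rm * betas
        mine = penalized_objective(model.weights, exp.x_presence.mean(axis=0), exp.x_background, penalty)
        oracle = oracle_optimum(exp.x_presence.mean(axis=0), exp.x_background, penalty)
        assert mine == pytest.approx(oracle, abs=1e-6)

    def test_kkt_stationarity_on_fitted_models(self, fitted_lq):
        model, expansion = fitted_lq
        check_kkt(model, expansion, tol=1e-4)

    def test_unpenalized_gain_is_nonincreasing_in_rm(self):
        rng = np.random.default_rng(9)
        exp = random_expansion(rng, 5)
        betas = np.full(5, 0.05)
        gains = []
        for rm in (0.5, 1.0, 2.0, 5.0):
            model = maxent.fit(exp, ModelConfig("L", rm), betas=betas)
            m = exp.x_presence.mean(axis=0)
            s = exp.x_background @ model.weights
            log_z = np.log(np.exp(s - s.max()).sum()) + s.max()
            gains.append(model.weights @ m - log_z)
        assert all(g1 >= g2 - 1e-8 for g1, g2 in zip(gains, gains[1:]))

    def test_n_params_never_exceeds_feature_count(self, fitted_lq):
        model, expansion = fitted_lq
        assert 0 < model.n_params <= expansion.n_features

    def test_entropy_matches_definition(self, fitted_lq):
        model, expansion = fitted_lq
        raw = maxent.predict_raw(model, expansion.x_background)
        assert raw.sum() == pytest.approx(1.0, abs=1e-6)
        assert model.entropy == pytest.approx(-(raw * np.log(raw)).sum(), abs=1e-9)


def check_kkt(model, expansion, tol=1e-4):
    """Softened moment-matching: active features equal their presence mean
    to within rm*beta; inactive features are within the penalty band."""
    m_pres = expansion.x_presence.mean(axis=0)
    s = expansion.x_background @ model.weights
    q = np.exp(s - s.max())
    q /= q.sum()
    e_model = q @ expansion.x_background
    gap = m_pres - e_model
    penalty = model.config.regularization_multiplier * model.betas
    active = model.weights != 0
    capped = np.abs(model.weights) >= maxent.LAMBDA_MAX
    assert not capped.any()
    assert np.all(np.abs(np.abs(gap[active]) - penalty[active]) <= tol)
    assert np.all(np.abs(gap[~active]) <= penalty[~active] + tol)


class TestPredict:
    def test_uniform_model_raw_is_one_over_b_and_cloglog_is_1_minus_e_inv(self):
        exp = make_binary_expansion([0, 1, 0, 1], [0, 1])
        model = maxent.fit(exp, ModelConfig("L", 1.0), betas=np.array([0.05]))
        raw = maxent.predict_raw(model, exp.x_background)
        np.testing.assert_allclose(raw, 1 / 4)
        clog = maxent.predict_cloglog(model, exp.x_background)
        np.testing.assert_allclose(clog, 1 - np.exp(-1.0), atol=1e-12)

    def test_single_positive_weight_makes_raw_increase_in_the_feature(self):
        exp = make_binary_expansion([0.0, 0.25, 0.5, 0.75, 1.0], [0.9, 1.0])
        model = maxent.fit(exp, ModelConfig("L", 1.0), betas=np.array([0.05]))
        assert model.weights[0] > 0
        raw = maxent.predict_raw(model, np.linspace(0, 1, 7).reshape(-1, 1))
        assert np.all(np.diff(raw) > 0)

    def test_cloglog_preserves_raw_ordering_and_stays_in_unit_interval(self, fitted_lq):
        model, expansion = fitted_lq
        raw = maxent.predict_raw(model, expansion.x_background)
        clog = maxent.predict_cloglog(model, expansion.x_background)
        assert np.all((clog > 0) & (clog < 1))
        order = np.argsort(raw)
        assert np.all(np.diff(clog[order]) >= 0)


class TestContribution:
    def test_percents_sum_to_100(self, fitted_lq):
        model, _ = fitted_lq
        contrib = maxent.percent_contribution(model)
        assert sum(contrib.values()) == pytest.approx(100.0, abs=0.01)

    def test_single_active_variable_takes_all_credit(self):
        exp = make_binary_expansion([0, 0, 1, 1], [1, 1])
        model = maxent.fit(exp, ModelConfig("L", 1.0), betas=np.array([0.1]))
        assert maxent.percent_contribution(model) == {"f": 100.0}

    def test_all_zero_model_reports_unnormalized_zeros(self):
        exp = make_binary_expansion([0, 1], [0, 1])
        model = maxent.fit(exp, ModelConfig("L", 1e6), betas=np.array([1.0]))
        assert maxent.percent_contribution(model) == {"f": 0.0}


class TestSerialization:
    def test_json_round_trips_the_model_state(self, fitted_lq):
        model, _ = fitted_lq
        payload = json.loads(model.to_json())
        assert payload["schema_version"] == 1
        assert payload["config"]["feature_class"] == "LQ"
        np.testing.assert_allclose(payload["weights"], model.weights)
        np.testing.assert_allclose(payload["log_z"], model.log_z)
        assert len(payload["features"]) == model.expansion.n_features
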