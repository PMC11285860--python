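"""Covariate derivation and the ZINB regression machinery."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from passflow import synthetic, weather as wm
from passflow.config import SimConfig, ZINBParams, DEFAULT_ZINB


class TestDeriveCovariates:
    def _weather(self, heading, sunshine=240.0):
        return pd.DataFrame({
            "date": ["2021-09-01"], "temp_c": [10.0],
            "wind_heading_deg": [heading], "rain_mm": [0.0],
            "windspeed_ms": [2.0], "sunshine_min": [sunshine],
        })

    @pytest.mark.parametrize("offset,expected", [
        (0.0, 1.0),      # wind from the full-headwind bearing
        (180.0, -1.0),   # straight tailwind
        (90.0, 0.0),     # orthogonal wind
    ])
    def test_headwind_index(self, offset, expected):
        out = wm.derive_covariates(self._weather(225.0 + offset))
        assert out["h"].iloc[0] == pytest.approx(expected, abs=1e-12)

    def test_sunshine_boundaries(self):
        assert wm.derive_covariates(
            self._weather(0.0, 480.0))["s"].iloc[0] == pytest.approx(1.0)
        assert wm.derive_covariates(
            self._weather(0.0, 0.0))["s"].iloc[0] == pytest.approx(0.0)

    def test_heading_normalized_mod_360(self):
        out = wm.derive_covariates(self._weather(585.0))  # = 225
        assert out["h"].iloc[0] == pytest.approx(1.0)


class TestCauchit:
    def test_at_zero(self):
        assert wm.cauchit(0.0) == pytest.approx(0.5)

    @given(st.floats(-1e6, 1e6, allow_nan=False))
    def test_bounded_and_symmetric(self, eta):
        p = wm.cauchit(eta)
        assert 0.0 < p < 1.0
        assert wm.cauchit(-eta) == pytest.approx(1.0 - p, abs=1e-12)

    @given(st.floats(-100, 100), st.floats(0.001, 100))
    def test_monotone(self, eta, step):
        assert wm.cauchit(eta + step) > wm.cauchit(eta)


def naive_zinb_loglik(y, X, Z, beta, gamma, theta):
    """Direct per-observation mixture-probability summation (oracle)."""
    total = 0.0
    for i in range(len(y)):
        mu = math.exp(float(X[i] @ beta))
        pi = 0.5 + math.atan(float(Z[i] @ gamma)) / math.pi
        nb = stats.nbinom.pmf(y[i], theta, theta / (theta + mu))
        prob = (1 - pi) * nb + (pi if y[i] == 0 else 0.0)
        total += math.log(prob)
    return total


class TestZinbLoglik:
    def test_hand_computed_single_observation(self):
        # y=0, mu=1, theta=1, pi=0.5: L = 0.5 + 0.5 * (1/2)^1 = 0.75
        ll = wm.zinb_loglik(np.array([0]), np.ones((1, 1)), np.zeros((1, 1)),
                            np.array([0.0]), np.array([0.0]), 1.0)
        assert ll == pytest.approx(math.log(0.75), abs=1e-12)

    def test_matches_naive_oracle_on_random_instances(self):
        rng = np.random.default_rng(123)
        for _ in range(100):
            n = rng.integers(5, 51)
            p, q = rng.integers(1, 4), rng.integers(1, 3)
            X = np.column_stack([np.ones(n), rng.normal(0, 1, (n, p - 1))]) \
                if p > 1 else np.ones((n, 1))
            Z = np.column_stack([np.ones(n), rng.normal(0, 1, (n, q - 1))]) \
                if q > 1 else np.ones((n, 1))
            beta = rng.normal(0, 1, p)
            gamma = rng.normal(0, 1, q)
            theta = float(rng.uniform(0.2, 5.0))
            y = rng.poisson(2.0, n)
            assert wm.zinb_loglik(y, X, Z, beta, gamma, theta) == \
                pytest.approx(naive_zinb_loglik(y, X, Z, beta, gamma, theta),
                              abs=1e-8)

    def test_poisson_limit(self):
        """pi -> 0 and huge theta: ZINB loglik -> Poisson loglik."""
        rng = np.random.default_rng(1)
        n = 30
        y = rng.poisson(4.0, n)
        X = np.ones((n, 1))
        Z = np.ones((n, 1))
        beta = np.array([math.log(4.0)])
        ll = wm.zinb_loglik(y, X, Z, beta, np.array([-1e8]), 1e6)
        pois = stats.poisson.logpmf(y, 4.0).sum()
        assert ll == pytest.approx(pois, abs=1e-4)

    def test_rejects_nonfinite_design(self):
        with pytest.raises(ValueError):
            wm.zinb_loglik(np.array([1]), np.array([[np.inf]]),
                           np.ones((1, 1)), np.array([1.0]),
                           np.array([0.0]), 1.0)


def _sim_data(seed, n_days=191):
    cfg = SimConfig(rng_seed=seed, n_days=n_days)
    wx = synthetic.simulate_weather(cfg)
    tot = synthetic.simulate_daily_totals(wx, cfg.zinb_params, seed)
    return wx.assign(total_count=tot["total_count"].to_numpy())


COUNT_TERMS = [t for t in DEFAULT_ZINB["beta"] if t != "intercept"]
ZERO_TERMS = [t for t in DEFAULT_ZINB["gamma"] if t != "intercept"]


class TestFitZinb:
    def test_refit_is_deterministic(self):
        data = _sim_data(21)
        f1 = wm.fit_zinb_terms(data, COUNT_TERMS, ZERO_TERMS)
        f2 = wm.fit_zinb_terms(data, COUNT_TERMS, ZERO_TERMS)
        assert (f1.beta == f2.beta).all()
        assert (f1.gamma == f2.gamma).all()
        assert f1.theta == f2.theta

    def test_aic_identity(self):
        data = _sim_data(22)
        fit = wm.fit_zinb_terms(data, COUNT_TERMS, ZERO_TERMS)
        assert fit.aic == pytest.approx(2 * fit.k_params - 2 * fit.loglik)

    def test_nesting_never_hurts_loglik(self):
        data = _sim_data(23)
        small = wm.fit_zinb_terms(data, ["temperature"], [])
        big = wm.fit_zinb_terms(data, ["temperature", "headwind"], [])
        assert big.loglik >= small.loglik - 1e-6

    def test_all_zero_counts_rejected(self):
        data = _sim_data(24)
        data["total_count"] = 0
        with pytest.raises(ValueError):
            wm.fit_zinb_terms(data, COUNT_TERMS, ZERO_TERMS)

    def test_no_structural_zeros_predicts_small_pi(self):
        """Data without zero inflation yields near-zero fitted pi."""
        rng = np.random.default_rng(3)
        n = 600
        temp = rng.normal(10, 4, n)
        mu = np.exp(1.0 + 0.2 * temp)
        y = rng.negative_binomial(2.0, 2.0 / (2.0 + mu))
        data = pd.DataFrame({"temp_c": temp, "total_count": y})
        fit = wm.fit_zinb_terms(data, ["temperature"], [])
        pi_hat = wm.cauchit(fit.gamma["intercept"])
        assert pi_hat < 0.05

    def test_matches_statsmodels_with_logit_link(self):
        """Same MLE as the reference ZINB when both use a logit zero link."""
        import statsmodels.discrete.count_model as cm
        data = _sim_data(25)
        X, _ = wm.build_design(data, ["temperature", "headwind"])
        Z, _ = wm.build_design(data, ["temperature"])
        y = data["total_count"].to_numpy()
        ours = wm.fit_zinb(y, X, Z, ["intercept", "temperature", "headwind"],
                           ["intercept", "temperature"], zero_link="logit")
        ref = cm.ZeroInflatedNegativeBinomialP(
            y, X, exog_infl=Z, p=2).fit(method="bfgs", maxiter=500, disp=0)
        # statsmodels orders params [infl..., count..., alpha] with
        # alpha = 1/theta
        ref_gamma = ref.params[:2]
        ref_beta = ref.params[2:5]
        ref_theta = 1.0 / ref.params[-1]
        assert ours.loglik == pytest.approx(ref.llf, abs=0.05)
        assert np.allclose(ours.beta.to_numpy(), ref_beta, atol=0.05)
        assert np.allclose(ours.gamma.to_numpy(), ref_gamma, atol=0.15)
        assert ours.theta == pytest.approx(ref_theta, rel=0.1)


class TestAllSubsets:
    def test_model_count(self):
        data = _sim_data(31, n_days=60)
        best, table = wm.all_subsets_select(
            data, ["temperature", "rainfall"], ["temperature"])
        assert len(table) == 8  # 4 count subsets x 2 zero subsets

    def test_duplicate_candidates_rejected(self):
        data = _sim_data(32, n_days=40)
        with pytest.raises(ValueError, match="duplicate"):
            wm.all_subsets_select(data, ["temperature", "temperature"], [])

    def test_marginality_excludes_orphan_interactions(self):
        data = _sim_data(33, n_days=60)
        best, table = wm.all_subsets_select(
            data, ["sunshine", "temperature", "sunshine:temperature"], [])
        # subsets: {}, {s}, {t}, {s,t}, {s,t,s:t} -> 5
        assert len(table) == 5

    def test_cap_enforced(self):
        data = _sim_data(34, n_days=40)
        with pytest.raises(ValueError, match="cap"):
            wm.all_subsets_select(data, ["temperature", "rainfall"],
                                  ["headwind"], cap=2)

    def test_strong_single_signal_selected(self):
        """With only temperature active, selection keeps it."""
        rng = np.random.default_rng(8)
        n = 300
        temp = rng.normal(10, 5, n)
        wind = rng.uniform(-1, 1, n)
        mu = np.exp(1.0 + 0.3 * temp)
        y = rng.negative_binomial(1.0, 1.0 / (1.0 + mu))
        zero = rng.random(n) < 0.3
        y[zero] = 0
        data = pd.DataFrame({"temp_c": temp, "h": wind, "total_count": y})
        best, _ = wm.all_subsets_select(data, ["temperature", "headwind"], [])
        assert "temperature" in best.beta.index
        assert "headwind" not in best.beta.index


class TestImportanceRanking:
    def test_fifteen_models_per_term(self):
        """7 candidates at size 3: each term sits in C(6,2)=15 models."""
        data = _sim_data(41, n_days=50)
        cands = ["temperature", "rainfall", "sunshine", "headwind",
                 "windspeed", "t2", "t3"]
        data["t2"] = data["temp_c"] ** 2 / 100
        data["t3"] = data["windspeed_ms"] ** 2 / 10
        out = wm.importance_ranking(data, cands, sizes=(3,), interactions=())
        assert (out["n_models"] == 15).all()
        assert sorted(out["rank"]) == list(range(1, 8))

    def test_sizes_larger_than_pool_rejected(self):
        data = _sim_data(42, n_days=40)
        with pytest.raises(ValueError):
            wm.importance_ranking(data, ["temperature"], sizes=(3,))

    def test_duplicated_covariate_ties(self):
        """A cloned covariate gets the same mean AIC as the original."""
        data = _sim_data(43, n_days=80)
        data["temp_copy"] = data["temp_c"]
        out = wm.importance_ranking(
            data, ["temperature", "temp_copy", "rainfall"],
            sizes=(2,), interactions=())
        a = out.set_index("term")["mean_aic"]
        assert a["temperature"] == pytest.approx(a["temp_copy"], abs=0.3)

    def test_dominant_covariate_ranks_first(self):
        data = _sim_data(44)
        out = wm.importance_ranking(
            data, ["temperature", "windspeed"], sizes=(1,), interactions=())
        assert out.loc[out["rank"] == 1, "term"].iloc[0] == "temperature"


class TestBootstrapPredictions:
    def test_reproducible_and_ordered_bands(self):
        data = _sim_data(51, n_days=80)
        kw = dict(count_terms=["temperature"], zero_terms=["temperature"],
                  focal="temperature", B=5, seed=9, grid_size=7)
        a = wm.bootstrap_predictions(data, **kw)
        b = wm.bootstrap_predictions(data, **kw)
        pd.testing.assert_frame_equal(a, b)
        assert (a["lower_95"] <= a["upper_95"]).all()

    def test_bands_contain_point_curve(self):
        data = _sim_data(52)
        out = wm.bootstrap_predictions(
            data, ["temperature"], ["temperature"], "temperature",
            B=60, seed=2, grid_size=9)
        inside = ((out["predicted"] >= out["lower_95"])
                  & (out["predicted"] <= out["upper_95"]))
        assert inside.all()

    def test_temperature_curve_monotone_at_default_params(self):
        """Temperature has a consistently positive effect on migration."""
        data = _sim_data(53)
        fit = wm.fit_zinb_terms(data, COUNT_TERMS, ZERO_TERMS)
        med = data.median(numeric_only=True)
        grid = pd.DataFrame({c: np.full(25, med[c]) for c in
                             ("h", "rain_mm", "s", "windspeed_ms")})
        grid["temp_c"] = np.linspace(2, 20, 25)
        pred = wm.predict_expected(fit, grid)
        assert (np.diff(pred) > 0).all()

    def test_small_B_rejected(self):
        data = _sim_data(54, n_days=40)
        with pytest.raises(ValueError):
            wm.bootstrap_predictions(data, ["temperature"], [],
                                     "temperature", B=1)
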