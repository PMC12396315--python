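"""Contact-model tests: design construction, linear-predictor algebra,
gradient correctness, HPDI/direction summaries, LKJ prior consistency,
sampler determinism, LOO identity and predictive checks."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import special, stats

from lingcontact._hlogit import (
    DesignData,
    HLogitModel,
    HLogitStructure,
    corr_chol_forward,
    lkj_chol_logp_grad,
    sample_lkj_corr,
)
from lingcontact._nuts import nuts
from lingcontact.errors import (
    InvalidComparisonError,
    InvalidInputError,
    InvalidSubsetError,
    NotConvergedError,
)
from lingcontact.models import (
    ModelSpec,
    PosteriorDraws,
    build_design,
    delta_p,
    delta_p_draws,
    fit_model,
    hpdi,
    linear_predictor,
    loo_compare,
    predictive_check,
    prob_direction,
)
from lingcontact.synthetic import ContactEffectTruth, simulate_pair_observations


@pytest.fixture(scope="module")
def small_obs():
    truth = ContactEffectTruth(
        alpha_true=0.75, beta_A_true=0.2, beta_G_true=0.5,
        sigma_state=0.25, sigma_AA=0.1, sigma_pair=0.15, sigma_broad=0.15,
        rho=0.1,
    )
    obs, rec = simulate_pair_observations(
        truth, 8, 6, 40, area_labels=("Africa", "Europe", "Oceania"), seed=42
    )
    assert (obs[(obs.G == 1)]["A"] == 1).any() and (obs[(obs.G == 1)]["A"] == 0).any()
    return obs, rec


@pytest.fixture(scope="module")
def small_fit(small_obs):
    obs, _ = small_obs
    spec = ModelSpec.for_id("m1")
    data = build_design(obs, spec)
    return fit_model(spec, data, chains=2, draws=250, warmup=300, seed=5)


class TestBuildDesign:
    def test_group_indices_dense_and_counts_match(self, small_obs):
        obs, _ = small_obs
        data = build_design(obs, ModelSpec.for_id("m1"))
        assert sorted(set(data.state_idx)) == list(range(len(data.state_labels)))
        for lab, n in obs.groupby("state").size().items():
            j = data.state_labels.index(lab)
            assert (data.state_idx == j).sum() == n
        # baseline rows carry -1 pair indices
        assert ((data.pair_idx == -1) == (data.G == 0)).all()

    def test_subset_rules(self, small_obs):
        obs, _ = small_obs
        m4 = build_design(obs, ModelSpec.for_id("m4"))
        m5 = build_design(obs, ModelSpec.for_id("m5"))
        m3 = build_design(obs, ModelSpec.for_id("m3"))
        n_baseline = (obs.G == 0).sum()
        assert (m4.G == 0).sum() == n_baseline  # baselines always retained
        assert (m5.G == 0).sum() == n_baseline
        assert (m4.G == 1).sum() + (m5.G == 1).sum() == (m3.G == 1).sum()

    def test_empty_subset_raises(self, small_obs):
        obs, _ = small_obs
        no_same_area = obs[(obs.G == 0) | (obs.A == 0)]
        with pytest.raises(InvalidSubsetError):
            build_design(no_same_area, ModelSpec.for_id("m4"))


class TestLinearPredictor:
    def _point_fit(self, alpha, beta_A, beta_G, S=3):
        spec = ModelSpec.for_id("m1")
        n = 4
        data = DesignData(
            y=np.zeros(n), A=np.array([0, 1, 0, 1.0]), G=np.array([0, 0, 1, 1.0]),
            state_idx=np.zeros(n, dtype=int), state_labels=[f"s{i}" for i in range(S)],
            aa_idx=np.zeros(n, dtype=int), aa_labels=["c"],
            broad_idx=np.array([-1, -1, 0, 0]), broad_labels=["b"],
            pair_idx=np.array([-1, -1, 0, 0]), pair_labels=["p"],
        )
        nd = 10
        draws = {
            "alpha": np.full((1, nd), alpha),
            "beta_A": np.full((1, nd), beta_A),
            "beta_G": np.full((1, nd), beta_G),
            "state_eff": np.zeros((1, nd, S, 3)),
            "aa_eff": np.zeros((1, nd, 1, 2)),
            "broad_eff": np.zeros((1, nd, 1)),
            "pair_eff": np.zeros((1, nd, 1)),
            "sigma_state": np.zeros((1, nd, 3)),
            "sigma_aa": np.zeros((1, nd, 2)),
            "sigma_broad": np.zeros((1, nd)),
            "sigma_pair": np.zeros((1, nd)),
            "R_state": np.tile(np.eye(3), (1, nd, 1, 1)),
            "R_aa": np.tile(np.eye(2), (1, nd, 1, 1)),
        }
        return PosteriorDraws(spec=spec, data=data, draws=draws, diagnostics={}, converged=True)

    def test_reductions(self):
        fit = self._point_fit(0.6, 0.2, 0.4)
        eta = linear_predictor(fit)
        assert np.allclose(eta[:, 0], 0.6)  # A=0, G=0
        assert np.allclose(eta[:, 1], 0.8)  # + beta_A
        assert np.allclose(eta[:, 2], 1.0)  # + beta_G
        assert np.allclose(eta[:, 3], 1.2)  # + both

    def test_matches_independent_formula_with_random_parameters(self, rng):
        spec = ModelSpec.for_id("m1")
        n, S, C, B, P = 60, 4, 3, 2, 5
        data = DesignData(
            y=rng.integers(0, 2, n).astype(float),
            A=rng.integers(0, 2, n).astype(float),
            G=rng.integers(0, 2, n).astype(float),
            state_idx=rng.integers(0, S, n),
            state_labels=[f"s{i}" for i in range(S)],
            aa_idx=rng.integers(0, C, n), aa_labels=[f"c{i}" for i in range(C)],
            broad_idx=rng.integers(0, B, n), broad_labels=[f"b{i}" for i in range(B)],
            pair_idx=rng.integers(0, P, n), pair_labels=[f"p{i}" for i in range(P)],
        )
        model = HLogitModel(spec.structure, data)
        params = {
            "alpha": 0.3, "beta_A": -0.2, "beta_G": 0.7,
            "state_eff": rng.normal(size=(S, 3)),
            "aa_eff": rng.normal(size=(C, 2)),
            "broad_eff": rng.normal(size=B),
            "pair_eff": rng.normal(size=P),
        }
        eta = model.eta(params, data)
        # independent row-by-row evaluation of the model formula
        for i in range(n):
            s, c, b, p = data.state_idx[i], data.aa_idx[i], data.broad_idx[i], data.pair_idx[i]
            want = (
                params["alpha"]
                + params["state_eff"][s, 0]
                + params["aa_eff"][c, 0]
                + (params["beta_A"] + params["state_eff"][s, 1]) * data.A[i]
                + (
                    params["beta_G"] + params["state_eff"][s, 2]
                    + params["aa_eff"][c, 1] + params["broad_eff"][b] + params["pair_eff"][p]
                ) * data.G[i]
            )
            assert math.isclose(eta[i], want, rel_tol=1e-12)

    def test_delta_p_point_mass_arithmetic(self):
        fit = self._point_fit(special.logit(0.7), 0.0, 0.4)
        es = delta_p(fit, "global", "genetic")
        expected = special.expit(special.logit(0.7) + 0.4) - 0.7
        assert math.isclose(es.delta_p_mean, expected, rel_tol=1e-9)
        assert math.isclose(expected, 0.0768, abs_tol=5e-4)
        assert es.hpdi89_low == pytest.approx(expected)

    def test_delta_p_null_is_exactly_zero(self):
        fit = self._point_fit(0.5, 0.3, 0.0)
        dp = delta_p_draws(fit, "global", "genetic")
        assert np.all(dp == 0.0)

    def test_delta_p_sign_matches_fixed_effect(self):
        for beta in (-0.8, -0.1, 0.1, 0.8):
            fit = self._point_fit(0.4, 0.0, beta)
            dp = delta_p_draws(fit, "global", "genetic")
            assert np.all(np.sign(dp) == np.sign(beta))

    def test_nonconverged_fit_refuses_summaries(self):
        fit = self._point_fit(0.5, 0.1, 0.2)
        fit.converged = False
        with pytest.raises(NotConvergedError):
            delta_p(fit, "global", "genetic")
        assert delta_p(fit, "global", "genetic", force=True)


class TestGradients:
    def test_full_model_gradient_matches_finite_differences(self, rng):
        for kwargs in (
            dict(has_area=True, has_genetic=True, has_aa=True, has_pairs=True),
            dict(has_area=True, has_genetic=False, has_aa=True, has_pairs=False),
            dict(has_area=False, has_genetic=True, has_aa=False, has_pairs=True),
        ):
            st = HLogitStructure(**kwargs)
            n = 120
            data = DesignData(
                y=rng.integers(0, 2, n).astype(float),
                A=rng.integers(0, 2, n).astype(float),
                G=rng.integers(0, 2, n).astype(float),
                state_idx=rng.integers(0, 4, n), state_labels=list("abcd"),
                aa_idx=rng.integers(0, 3, n), aa_labels=list("xyz"),
                broad_idx=np.where(rng.random(n) < 0.7, rng.integers(0, 2, n), -1),
                broad_labels=["b0", "b1"],
                pair_idx=np.where(rng.random(n) < 0.7, rng.integers(0, 4, n), -1),
                pair_labels=[f"p{i}" for i in range(4)],
            )
            model = HLogitModel(st, data)
            theta = rng.normal(size=model.dim) * 0.4
            _, grad = model.logp_grad(theta)
            eps = 1e-6
            for i in rng.choice(model.dim, size=min(25, model.dim), replace=False):
                tp, tm = theta.copy(), theta.copy()
                tp[i] += eps
                tm[i] -= eps
                fd = (model.logp_grad(tp)[0] - model.logp_grad(tm)[0]) / (2 * eps)
                assert math.isclose(fd, grad[i], rel_tol=1e-4, abs_tol=1e-6)


class TestCorrPrior:
    def test_cholesky_factor_valid(self, rng):
        for dim in (2, 3):
            y = rng.normal(size=dim * (dim - 1) // 2)
            L, _, _ = corr_chol_forward(y, dim)
            R = L @ L.T
            assert np.allclose(np.diag(R), 1.0)
            assert np.all(np.linalg.eigvalsh(R) > 0)

    def test_nuts_on_transform_density_matches_onion_sampler(self):
        # the unconstrained LKJ(2) density (transform + Jacobian) must induce
        # the same correlation distribution as direct onion-method sampling;
        # marginal of each correlation for d=3, eta=2 is 2*Beta(2.5, 2.5)-1
        dim, eta = 3, 2.0
        def lg(yv):
            lp, gy, *_ = lkj_chol_logp_grad(yv, dim, eta)
            return lp, gy
        res = nuts(lg, np.zeros(3), 300, 1500, np.random.default_rng(17))
        rs = []
        for y in res.draws:
            L, _, _ = corr_chol_forward(y, dim)
            R = L @ L.T
            rs.extend([R[1, 0], R[2, 0], R[2, 1]])
        rs = np.asarray(rs)
        beta_sd = 2 * math.sqrt(2.5 * 2.5 / (5.0**2 * 6.0))
        assert abs(rs.mean()) < 0.05
        assert abs(rs.std() - beta_sd) < 0.05
        rng = np.random.default_rng(18)
        onion = np.array([sample_lkj_corr(dim, eta, rng)[1, 0] for _ in range(2000)])
        assert abs(onion.mean()) < 0.05
        assert abs(onion.std() - beta_sd) < 0.05


class TestHpdi:
    def test_order_statistics_window(self):
        samples = np.arange(1, 101, dtype=float)
        lo, hi = hpdi(samples, 0.89)
        assert hi - lo == 88.0
        assert lo == 1.0  # leftmost tie

    def test_constant_samples_zero_width(self):
        lo, hi = hpdi(np.full(50, 3.3), 0.89)
        assert lo == hi == 3.3

    def test_normal_quantiles(self, rng):
        x = rng.standard_normal(200_000)
        lo, hi = hpdi(x, 0.89)
        q = stats.norm.ppf(0.945)
        assert abs(lo + q) < 0.03
        assert abs(hi - q) < 0.03

    def test_nested_mass(self, rng):
        x = rng.standard_normal(5000)
        lo50, hi50 = hpdi(x, 0.50)
        lo89, hi89 = hpdi(x, 0.89)
        assert lo89 <= lo50 and hi50 <= hi89

    def test_guards(self):
        with pytest.raises(InvalidInputError):
            hpdi(np.array([1.0]), 0.89)
        with pytest.raises(InvalidInputError):
            hpdi(np.array([1.0, 2.0]), 1.5)


class TestProbDirection:
    def test_counting(self, rng):
        assert prob_direction(np.array([1.0, 2.0, 3.0])) == 1.0
        assert prob_direction(np.array([-1.0, 1.0])) == 0.5
        x = rng.standard_normal(10_001)
        assert prob_direction(x) == np.mean(x > 0)


class TestFit:
    def test_smoke_fit_recovers_roughly_and_reports_diagnostics(self, small_fit, small_obs):
        _, rec = small_obs
        assert {"rhat_max", "ess_min", "n_divergent"} <= set(small_fit.diagnostics)
        beta_G = small_fit.flat("beta_G")
        assert abs(beta_G.mean() - rec["beta_G_true"]) < 3 * beta_G.std() + 0.2
        # positive-definite reconstructed covariances draw by draw
        R = small_fit.flat("R_state")
        sig = small_fit.flat("sigma_state")
        for i in (0, len(R) // 2, len(R) - 1):
            cov = np.diag(sig[i]) @ R[i] @ np.diag(sig[i])
            assert np.all(np.linalg.eigvalsh(cov) > 0)

    def test_seed_determinism(self, small_obs):
        obs, _ = small_obs
        spec = ModelSpec.for_id("m3")
        data = build_design(obs, spec)
        f1 = fit_model(spec, data, chains=1, draws=60, warmup=80, seed=11)
        f2 = fit_model(spec, data, chains=1, draws=60, warmup=80, seed=11)
        assert np.array_equal(f1.flat("alpha"), f2.flat("alpha"))
        assert np.array_equal(f1.flat("beta_G"), f2.flat("beta_G"))

    def test_loo_self_comparison_is_zero(self, small_fit):
        table = loo_compare([small_fit, small_fit], force=True)
        assert np.allclose(table["delta_elpd"], 0.0, atol=1e-9)

    def test_loo_mismatched_rows_rejected(self, small_fit, small_obs):
        obs, _ = small_obs
        spec = ModelSpec.for_id("m4")
        data = build_design(obs, spec)
        other = fit_model(spec, data, chains=1, draws=50, warmup=60, seed=3)
        with pytest.raises(InvalidComparisonError):
            loo_compare([small_fit, other], force=True)

    def test_posterior_predictive_covers_observed(self, small_fit):
        out = predictive_check(small_fit, mode="posterior", n_rep=100, seed=1, force=True)
        both = out[out.condition == "baseline"].iloc[0]
        assert both["replicated_q05"] <= both["observed_rate"] <= both["replicated_q95"]

    def test_prior_predictive_baseline_above_half(self, small_fit):
        # intercept prior centers baseline sharing above 0.5
        out = predictive_check(small_fit, mode="prior", n_rep=300, seed=2, force=True)
        base = out[out.condition == "baseline"].iloc[0]
        assert base["replicated_mean"] > 0.5
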