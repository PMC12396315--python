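"""Bayesian multilevel logistic contact models (m1-m5) and their summaries.

m1 regresses statewise sharing on both areal colocation (A) and genetic
contact (G) with varying intercepts/slopes by feature state and by area
combination, plus genetic slopes nested by contact pair within broad pair.
m2 keeps the areal terms only; m3-m5 keep the genetic terms only and are
fitted on all pairs, same-area pairs, and different-area pairs respectively.
Priors: intercept N(0.75, 0.5) — baseline sharing of a binarized state is
at least 0.5, hence the positive prior mean — fixed effects N(0, 1.5),
group SDs half-normal(0, 2), correlations LKJ(2).

Fitting uses the package's NUTS sampler (non-centered parameterization,
analytic gradients); diagnostics (rank-normalized split R-hat, bulk ESS)
and PSIS-LOO go through arviz.  Posterior contrasts are reported as
probability differences (delta-P) with highest-posterior-density intervals.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import arviz as az
import numpy as np
import pandas as pd

from ._hlogit import (
    DesignData,
    HLogitModel,
    HLogitStructure,
    log1p_exp,
    sample_lkj_corr,
    sigmoid,
)
from ._nuts import nuts
from .errors import (
    InvalidComparisonError,
    InvalidInputError,
    InvalidSubsetError,
    NotConvergedError,
)

logger = logging.getLogger(__name__)

MODEL_IDS = ("m0", "m1", "m2", "m3", "m4", "m5")


@dataclass(frozen=True)
class PriorConfig:
    intercept_mean: float = 0.75
    intercept_sd: float = 0.5
    fixed_sd: float = 1.5
    group_sd_scale: float = 2.0
    lkj_eta: float = 2.0

    def __post_init__(self) -> None:
        for name in ("intercept_sd", "fixed_sd", "group_sd_scale", "lkj_eta"):
            if getattr(self, name) <= 0:
                raise InvalidInputError(f"{name} must be > 0")


@dataclass(frozen=True)
class ModelSpec:
    """One of the contact models; ``m0`` is the intercept-only reference."""

    model_id: str
    includes_area: bool
    includes_genetic: bool
    subset_rule: str = "all"  # all | same_area_only | different_area_only
    priors: PriorConfig = field(default_factory=PriorConfig)

    @classmethod
    def for_id(cls, model_id: str, priors: PriorConfig | None = None) -> "ModelSpec":
        priors = priors or PriorConfig()
        table = {
            "m0": dict(includes_area=False, includes_genetic=False, subset_rule="all"),
            "m1": dict(includes_area=True, includes_genetic=True, subset_rule="all"),
            "m2": dict(includes_area=True, includes_genetic=False, subset_rule="all"),
            "m3": dict(includes_area=False, includes_genetic=True, subset_rule="all"),
            "m4": dict(includes_area=False, includes_genetic=True, subset_rule="same_area_only"),
            "m5": dict(includes_area=False, includes_genetic=True, subset_rule="different_area_only"),
        }
        if model_id not in table:
            raise InvalidInputError(f"unknown model id {model_id!r}")
        return cls(model_id=model_id, priors=priors, **table[model_id])

    @property
    def structure(self) -> HLogitStructure:
        return HLogitStructure(
            has_area=self.includes_area,
            has_genetic=self.includes_genetic,
            has_aa=self.includes_area,  # area-combination terms ride with A
            has_pairs=self.includes_genetic,
            intercept_mean=self.priors.intercept_mean,
            intercept_sd=self.priors.intercept_sd,
            fixed_sd=self.priors.fixed_sd,
            group_sd_scale=self.priors.group_sd_scale,
            lkj_eta=self.priors.lkj_eta,
        )


def build_design(observations: pd.DataFrame, spec: ModelSpec) -> DesignData:
    """Index-code the observation table for one model.

    ``same_area_only`` keeps same-area contact rows (m4), ``different_area_only``
    different-area contact rows (m5); baseline rows are always retained.
    Group index maps are dense, in sorted label order; baseline rows carry -1
    in the pair/broad columns.
    """
    need = {"state", "same_state", "G", "A"}
    if not need <= set(observations.columns):
        raise InvalidInputError(f"observations must carry columns {sorted(need)}")
    obs = observations
    if spec.subset_rule == "same_area_only":
        obs = obs[(obs["G"] == 0) | (obs["A"] == 1)]
    elif spec.subset_rule == "different_area_only":
        obs = obs[(obs["G"] == 0) | (obs["A"] == 0)]
    elif spec.subset_rule != "all":
        raise InvalidInputError(f"unknown subset rule {spec.subset_rule!r}")
    if obs.empty:
        raise InvalidSubsetError(f"subset {spec.subset_rule!r} left no observations")
    if spec.includes_genetic and not (obs["G"] == 1).any():
        raise InvalidSubsetError(f"subset {spec.subset_rule!r} left no contact rows")

    def dense_index(series: pd.Series) -> tuple[np.ndarray, list[str]]:
        labels = sorted(x for x in series.dropna().unique())
        lookup = {lab: i for i, lab in enumerate(labels)}
        idx = np.array([lookup.get(x, -1) for x in series], dtype=int)
        return idx, [str(x) for x in labels]

    state_idx, state_labels = dense_index(obs["state"].astype(str))
    data = DesignData(
        y=obs["same_state"].to_numpy(dtype=float),
        A=obs["A"].to_numpy(dtype=float),
        G=obs["G"].to_numpy(dtype=float),
        state_idx=state_idx,
        state_labels=state_labels,
    )
    if spec.includes_area:
        if "area_combination" not in obs.columns:
            raise InvalidInputError("area model needs an area_combination column")
        data.aa_idx, data.aa_labels = dense_index(obs["area_combination"].astype(str))
    if spec.includes_genetic:
        data.broad_idx, data.broad_labels = dense_index(obs["broad_pair_id"])
        data.pair_idx, data.pair_labels = dense_index(obs["pair_id"])
    return data


@dataclass
class EffectSummary:
    scope: str
    condition: str
    delta_p_mean: float
    hpdi89_low: float
    hpdi89_high: float
    hpdi50_low: float
    hpdi50_high: float
    p_direction: float


@dataclass
class PosteriorDraws:
    """Joint posterior draws of one fitted contact model."""

    spec: ModelSpec
    data: DesignData
    draws: dict[str, np.ndarray]  # leading axes (chain, draw)
    diagnostics: dict
    converged: bool

    @property
    def n_chains(self) -> int:
        return self.draws["alpha"].shape[0]

    @property
    def n_draws(self) -> int:
        return self.draws["alpha"].shape[1]

    def flat(self, name: str) -> np.ndarray:
        """Draws with chain and draw axes merged."""
        v = self.draws[name]
        return v.reshape(-1, *v.shape[2:])

    def require_converged(self, force: bool = False) -> None:
        if not self.converged and not force:
            raise NotConvergedError(
                f"{self.spec.model_id}: diagnostics violated ({self.diagnostics}); "
                "pass force=True to summarize anyway"
            )


_REPORTED_KEYS = (
    "alpha", "beta_A", "beta_G", "sigma_state", "sigma_aa", "sigma_broad", "sigma_pair",
)


def fit_model(
    spec: ModelSpec,
    data: DesignData,
    chains: int = 4,
    draws: int = 1000,
    warmup: int = 500,
    seed: int = 0,
    target_accept: float = 0.9,
    ess_min: float = 400.0,
    rhat_max: float = 1.01,
) -> PosteriorDraws:
    """Fit one model by NUTS and package constrained posterior draws.

    Chains run sequentially from seeds spawned off ``seed``.  The fit is
    flagged non-converged when any reported parameter has rank-normalized
    split R-hat above ``rhat_max`` or bulk ESS below ``ess_min``, or when
    post-warmup divergences occurred; summaries then refuse unless forced.
    """
    model = HLogitModel(spec.structure, data)
    seeds = np.random.SeedSequence(seed).spawn(chains)
    unconstrained = np.empty((chains, draws, model.dim))
    n_div = 0
    for c in range(chains):
        rng = np.random.default_rng(seeds[c])
        theta0 = rng.uniform(-1.0, 1.0, size=model.dim) * 0.5
        res = nuts(
            model.logp_grad, theta0, warmup, draws, rng,
            target_accept=target_accept,
        )
        unconstrained[c] = res.draws
        n_div += res.n_divergent
        logger.info(
            "%s chain %d: accept %.2f, step %.3g, divergent %d",
            spec.model_id, c, res.accept_rate, res.step_size, res.n_divergent,
        )

    # constrain draw by draw
    out: dict[str, list] = {}
    for c in range(chains):
        for d in range(draws):
            params = model.unpack(unconstrained[c, d])
            for k, v in params.items():
                if v is None:
                    continue
                out.setdefault(k, []).append(v)
    packed: dict[str, np.ndarray] = {}
    for k, vals in out.items():
        arr = np.asarray(vals, dtype=float)
        packed[k] = arr.reshape(chains, draws, *arr.shape[1:])

    diag_vars = {}
    for k in _REPORTED_KEYS:
        if k in packed:
            v = packed[k]
            diag_vars[k] = v if v.ndim == 2 else v.reshape(chains, draws, -1)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        idata = az.from_dict(posterior=diag_vars)
        rhat = az.rhat(idata)
        ess = az.ess(idata)

        def _agg(ds, fn):
            vals = [np.atleast_1d(ds[k].values) for k in diag_vars]
            flat = np.concatenate([v.ravel() for v in vals])
            return float(fn(flat)) if np.any(np.isfinite(flat)) else float("nan")

        rhat_max_obs = _agg(rhat, np.nanmax)
        ess_min_obs = _agg(ess, np.nanmin)
    converged = (rhat_max_obs < rhat_max) and (ess_min_obs >= ess_min) and (n_div == 0)
    if n_div:
        logger.warning("%s: %d post-warmup divergent transitions", spec.model_id, n_div)
    diagnostics = {
        "rhat_max": rhat_max_obs,
        "ess_min": ess_min_obs,
        "n_divergent": int(n_div),
        "chains": chains,
        "draws": draws,
        "warmup": warmup,
        "seed": seed,
    }
    return PosteriorDraws(
        spec=spec, data=data, draws=packed, diagnostics=diagnostics, converged=converged
    )


def linear_predictor(fit: PosteriorDraws, data: DesignData | None = None) -> np.ndarray:
    """Linear predictor eta for every (draw, observation).

    Evaluates the fitted model's predictor row set (or a new ``data`` bundle
    with compatible group indexing; unseen levels coded -1 contribute zero).
    Returns an array of shape (n_total_draws, n_obs).
    """
    model = HLogitModel(fit.spec.structure, fit.data)
    d = data if data is not None else fit.data
    n_total = fit.n_chains * fit.n_draws
    eta = np.empty((n_total, d.n_obs))
    keys = [k for k in fit.draws]
    flats = {k: fit.flat(k) for k in keys}
    for i in range(n_total):
        params = {k: flats[k][i] for k in keys}
        params["alpha"] = float(flats["alpha"][i])
        if "beta_A" in flats:
            params["beta_A"] = float(flats["beta_A"][i])
        if "beta_G" in flats:
            params["beta_G"] = float(flats["beta_G"][i])
        eta[i] = model.eta(params, d)
    return eta


def hpdi(samples: np.ndarray, mass: float = 0.89) -> tuple[float, float]:
    """Shortest contiguous interval containing ceil(mass * n) sorted samples.

    Ties in width are broken leftmost.  Degenerate (constant) samples give a
    zero-width interval.
    """
    x = np.sort(np.asarray(samples, dtype=float).ravel())
    n = x.size
    if n < 2:
        raise InvalidInputError("need >= 2 samples for an HPDI")
    if not 0.0 < mass < 1.0:
        raise InvalidInputError("mass must be in (0, 1)")
    w = int(np.ceil(mass * n))
    w = min(max(w, 1), n)
    widths = x[w - 1 :] - x[: n - w + 1]
    i = int(np.argmin(widths))
    return float(x[i]), float(x[i + w - 1])


def prob_direction(samples: np.ndarray) -> float:
    """Fraction of draws strictly greater than zero."""
    x = np.asarray(samples, dtype=float).ravel()
    if x.size < 1:
        raise InvalidInputError("need >= 1 sample")
    return float(np.mean(x > 0))


def delta_p_draws(
    fit: PosteriorDraws,
    scope: str = "global",
    condition: str = "genetic",
    force: bool = False,
) -> np.ndarray:
    """Per-draw probability difference for toggling one contact condition.

    Global scope contrasts the fixed effect at the population mean of all
    varying effects (zero offsets): delta-P = invlogit(alpha + beta) -
    invlogit(alpha).  Per-state scope adds that state's varying intercept
    and the condition's varying slope to both arms.
    """
    fit.require_converged(force=force)
    if condition == "genetic":
        if not fit.spec.includes_genetic:
            raise InvalidInputError(f"{fit.spec.model_id} has no genetic effect")
        beta = fit.flat("beta_G")
        slope_col = 1 + int(fit.spec.includes_area)
    elif condition == "area":
        if not fit.spec.includes_area:
            raise InvalidInputError(f"{fit.spec.model_id} has no areal effect")
        beta = fit.flat("beta_A")
        slope_col = 1
    else:
        raise InvalidInputError("condition must be 'genetic' or 'area'")
    alpha = fit.flat("alpha")
    if scope == "global":
        base = alpha
        slope = beta
    else:
        try:
            j = fit.data.state_labels.index(scope)
        except ValueError:
            raise InvalidInputError(f"unknown state {scope!r}") from None
        se = fit.flat("state_eff")
        base = alpha + se[:, j, 0]
        slope = beta + se[:, j, slope_col]
    return sigmoid(base + slope) - sigmoid(base)


def delta_p(
    fit: PosteriorDraws,
    scope: str = "global",
    condition: str = "genetic",
    force: bool = False,
) -> EffectSummary:
    """Posterior delta-P summary: mean, 50% and 89% HPDIs, P(effect > 0)."""
    dp = delta_p_draws(fit, scope=scope, condition=condition, force=force)
    lo89, hi89 = hpdi(dp, 0.89)
    lo50, hi50 = hpdi(dp, 0.50)
    return EffectSummary(
        scope=scope,
        condition=condition,
        delta_p_mean=float(dp.mean()),
        hpdi89_low=lo89,
        hpdi89_high=hi89,
        hpdi50_low=lo50,
        hpdi50_high=hi50,
        p_direction=prob_direction(dp),
    )


def state_effect_table(
    fit: PosteriorDraws, condition: str = "genetic", force: bool = False
) -> pd.DataFrame:
    """Per-state baseline sharing probability and delta-P summaries."""
    fit.require_converged(force=force)
    rows = []
    alpha = fit.flat("alpha")
    se = fit.flat("state_eff")
    for j, state in enumerate(fit.data.state_labels):
        base = sigmoid(alpha + se[:, j, 0])
        dp = delta_p_draws(fit, scope=state, condition=condition, force=force)
        lo89, hi89 = hpdi(dp, 0.89)
        lo50, hi50 = hpdi(dp, 0.50)
        rows.append(
            {
                "state": state,
                "baseline_mean": float(base.mean()),
                "delta_p_mean": float(dp.mean()),
                "hpdi89_low": lo89,
                "hpdi89_high": hi89,
                "hpdi50_low": lo50,
                "hpdi50_high": hi50,
                "p_direction": prob_direction(dp),
            }
        )
    return pd.DataFrame(rows)


def pointwise_loglik(fit: PosteriorDraws) -> np.ndarray:
    """Bernoulli log likelihood per (chain, draw, observation)."""
    eta = linear_predictor(fit)
    y = fit.data.y
    ll = y * eta - log1p_exp(eta)
    return ll.reshape(fit.n_chains, fit.n_draws, -1)


def loo_compare(fits: list[PosteriorDraws], force: bool = False) -> pd.DataFrame:
    """PSIS-LOO comparison of fits sharing identical response rows.

    Returns one row per model with elpd_loo, its SE, p_loo, the count of
    high Pareto-k points, and the pairwise difference to the best model
    (delta_elpd, delta_se from the pointwise elpd differences).
    """
    if len(fits) < 1:
        raise InvalidInputError("need at least one fit")
    y0 = fits[0].data.y
    for f in fits[1:]:
        if f.data.n_obs != len(y0) or not np.array_equal(f.data.y, y0):
            raise InvalidComparisonError("fits do not share identical response rows")
    for f in fits:
        f.require_converged(force=force)
    results = []
    pointwise = []
    for f in fits:
        ll = pointwise_loglik(f)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            idata = az.from_dict(
                posterior={"alpha": f.draws["alpha"]},
                log_likelihood={"y": ll},
            )
            loo = az.loo(idata, pointwise=True)
        k = np.asarray(loo.pareto_k)
        results.append(
            {
                "model": f.spec.model_id,
                "elpd_loo": float(loo.elpd_loo),
                "se": float(loo.se),
                "p_loo": float(loo.p_loo),
                "n_high_pareto_k": int(np.sum(k > 0.7)),
            }
        )
        pointwise.append(np.asarray(loo.loo_i))
    best = int(np.argmax([r["elpd_loo"] for r in results]))
    for i, r in enumerate(results):
        diff = pointwise[best] - pointwise[i]
        r["delta_elpd"] = float(np.sum(diff))
        r["delta_se"] = float(np.sqrt(len(diff) * np.var(diff, ddof=1))) if i != best else 0.0
    return pd.DataFrame(results).set_index("model")


def _prior_params(spec: ModelSpec, data: DesignData, rng: np.random.Generator) -> dict:
    st = spec.structure
    S, ds = len(data.state_labels), st.ds
    params: dict = {
        "alpha": float(rng.normal(st.intercept_mean, st.intercept_sd)),
        "state_eff": np.zeros((S, ds)),
    }
    sig_s = np.abs(rng.normal(0, st.group_sd_scale, size=ds))
    R = sample_lkj_corr(ds, st.lkj_eta, rng) if ds > 1 else np.ones((1, 1))
    L = np.linalg.cholesky(R)
    params["state_eff"] = rng.standard_normal((S, ds)) @ (sig_s[:, None] * L).T
    if st.has_area:
        params["beta_A"] = float(rng.normal(0, st.fixed_sd))
    if st.has_genetic:
        params["beta_G"] = float(rng.normal(0, st.fixed_sd))
    if st.has_aa and data.aa_labels:
        da = st.da
        sig_a = np.abs(rng.normal(0, st.group_sd_scale, size=da))
        Ra = sample_lkj_corr(da, st.lkj_eta, rng) if da > 1 else np.ones((1, 1))
        La = np.linalg.cholesky(Ra)
        params["aa_eff"] = rng.standard_normal((len(data.aa_labels), da)) @ (sig_a[:, None] * La).T
    if st.has_pairs:
        sb = abs(rng.normal(0, st.group_sd_scale))
        sp = abs(rng.normal(0, st.group_sd_scale))
        params["broad_eff"] = rng.normal(0, sb, size=len(data.broad_labels))
        params["pair_eff"] = rng.normal(0, sp, size=len(data.pair_labels))
    return params


def predictive_check(
    fit: PosteriorDraws,
    mode: str = "posterior",
    n_rep: int = 200,
    seed: int = 0,
    force: bool = False,
) -> pd.DataFrame:
    """Prior or posterior predictive check of per-condition sharing rates.

    Replicated datasets are drawn from the requested predictive distribution;
    for each (G, A) condition the observed sharing rate is compared with the
    replicated distribution (central 90% band and the observed rate's
    quantile within the replicates).  Conditions with no rows are skipped.
    """
    if mode not in ("prior", "posterior"):
        raise InvalidInputError("mode must be 'prior' or 'posterior'")
    data = fit.data
    rng = np.random.default_rng(seed)
    model = HLogitModel(fit.spec.structure, data)
    if mode == "posterior":
        fit.require_converged(force=force)
        n_total = fit.n_chains * fit.n_draws
        take = rng.choice(n_total, size=min(n_rep, n_total), replace=False)
        flats = {k: fit.flat(k) for k in fit.draws}
        param_list = []
        for i in take:
            p = {k: flats[k][i] for k in flats}
            p["alpha"] = float(flats["alpha"][i])
            if "beta_A" in flats:
                p["beta_A"] = float(flats["beta_A"][i])
            if "beta_G" in flats:
                p["beta_G"] = float(flats["beta_G"][i])
            param_list.append(p)
    else:
        param_list = [_prior_params(fit.spec, data, rng) for _ in range(n_rep)]

    conditions = [("baseline", data.G == 0), ("contact", data.G == 1)]
    conditions += [
        ("baseline_same_area", (data.G == 0) & (data.A == 1)),
        ("baseline_diff_area", (data.G == 0) & (data.A == 0)),
        ("contact_same_area", (data.G == 1) & (data.A == 1)),
        ("contact_diff_area", (data.G == 1) & (data.A == 0)),
    ]
    rep_rates = {name: [] for name, _ in conditions}
    for p in param_list:
        pi = sigmoid(model.eta(p, data))
        y_rep = (rng.random(data.n_obs) < pi).astype(float)
        for name, mask in conditions:
            if mask.sum() == 0:
                continue
            rep_rates[name].append(float(y_rep[mask].mean()))
    rows = []
    for name, mask in conditions:
        n = int(mask.sum())
        if n == 0:
            logger.warning("predictive check: condition %s has no rows, skipped", name)
            continue
        reps = np.asarray(rep_rates[name])
        obs = float(data.y[mask].mean())
        rows.append(
            {
                "condition": name,
                "n_rows": n,
                "observed_rate": obs,
                "replicated_mean": float(reps.mean()),
                "replicated_q05": float(np.quantile(reps, 0.05)),
                "replicated_q95": float(np.quantile(reps, 0.95)),
                "observed_quantile": float(np.mean(reps < obs) + 0.5 * np.mean(reps == obs)),
            }
        )
    return pd.DataFrame(rows)
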