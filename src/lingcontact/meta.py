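"""Second-stage measurement-error meta-analyses over first-stage effects.

Each first-stage effect enters as a (mean, SD) pair on the probability-
difference scale.  The main-effect model regresses the effect on categorical
covariates (model, sensitivity status, parameter, dataset) with a global
intercept; the feature-state model uses group-indexed means with no
intercept.  Both are y_i ~ Normal(mu_i, sigma_i) with the sigma_i fixed at
the observed SDs and Normal(0, 1.5) priors on all coefficients — a pure
measurement-error model with no residual heterogeneity term.  (A
random-effects tau can be enabled for users who want one; it is off by
default by design.)

With fixed sigma_i and Gaussian priors the posterior is itself Gaussian, so
fitting is exact: coefficients are sampled from the closed-form multivariate
normal posterior rather than by MCMC.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import InvalidInputError
from .models import PosteriorDraws, delta_p_draws, hpdi, prob_direction

logger = logging.getLogger(__name__)

#: Default domain-group classifications.  g1: six top-level feature classes;
#: g2: phonology subdivided into its three subdomains.
G1_CLASSES = (
    "lexical semantics",
    "lexical classes",
    "grammatical categories",
    "linear order",
    "other grammar",
    "phonology",
)
G2_CLASSES = ("prosody", "vocalic", "consonantal")

CONTACT_TYPES = (
    "genetic_all",
    "genetic_different_area",
    "genetic_same_area",
    "same_area",
)


@dataclass(frozen=True)
class MetaObservation:
    """One first-stage effect estimate with its categorical covariates."""

    y: float
    sigma: float
    m: str = "m1"  # model label, m1 reference
    s: str = "main"  # sensitivity status, main reference
    p: str = "genetic"  # parameter label, genetic reference
    d: str = "GBI"  # dataset label, GBI reference
    g: str | None = None  # domain group (state-level analysis)

    def __post_init__(self) -> None:
        if not self.sigma > 0:
            raise InvalidInputError("sigma must be > 0")


@dataclass
class MetaFit:
    """Exact Gaussian posterior over meta-regression coefficients."""

    coef_names: list[str]
    draws: np.ndarray  # (n_draws, n_coefs)
    design: np.ndarray
    observations: pd.DataFrame
    factors: dict[str, tuple[str, list[str]]] = field(default_factory=dict)
    # factor -> (reference level, non-reference levels in design order)

    def coef(self, name: str) -> np.ndarray:
        return self.draws[:, self.coef_names.index(name)]


def collect_meta_observations(
    fits: dict[tuple[str, str, str], PosteriorDraws], force: bool = False
) -> pd.DataFrame:
    """Meta-observation table from first-stage fits.

    ``fits`` maps (model_id, sensitivity_status, dataset) to a fitted model.
    Each genetic-capable fit contributes a genetic-contact row; m1 fits also
    contribute an areal row.  y and sigma are the posterior mean and SD of
    the global delta-P.  Missing combinations are logged gaps, not errors.
    """
    rows = []
    for (model_id, status, dataset), fit in sorted(fits.items()):
        effects = []
        if fit.spec.includes_genetic:
            effects.append("genetic")
        if fit.spec.includes_area:
            effects.append("areal")
        for p in effects:
            dp = delta_p_draws(fit, scope="global",
                               condition="genetic" if p == "genetic" else "area",
                               force=force)
            sd = float(dp.std(ddof=1))
            if sd == 0:
                raise InvalidInputError(
                    f"degenerate first-stage fit ({model_id},{status},{dataset}): zero SD"
                )
            rows.append({"y": float(dp.mean()), "sigma": sd, "m": model_id,
                         "s": status, "p": p, "d": dataset})
    if not rows:
        logger.warning("no first-stage effects collected")
    return pd.DataFrame(rows)


def _conjugate_posterior(
    X: np.ndarray, y: np.ndarray, sigma: np.ndarray, prior_sd: float,
    n_draws: int, seed: int,
) -> np.ndarray:
    """Exact N(m, V) posterior draws for y ~ N(X b, sigma^2), b ~ N(0, prior_sd^2)."""
    w = 1.0 / sigma**2
    lam = X.T @ (w[:, None] * X) + np.eye(X.shape[1]) / prior_sd**2
    cov = np.linalg.inv(lam)
    mean = cov @ (X.T @ (w * y))
    rng = np.random.default_rng(seed)
    chol = np.linalg.cholesky(cov)
    return mean[None, :] + rng.standard_normal((n_draws, X.shape[1])) @ chol.T


def fit_main_meta(
    observations: pd.DataFrame,
    prior_sd: float = 1.5,
    n_draws: int = 4000,
    seed: int = 0,
) -> MetaFit:
    """Main-effect meta-analysis: intercept plus categorical coefficients.

    mu_i = alpha + b_m[m_i] + b_s[s_i] + b_p[p_i] + b_d[d_i] with treatment
    coding (references: m1, main, genetic, GBI).  Levels never observed are
    dropped with a warning.
    """
    obs = observations.reset_index(drop=True)
    if len(obs) < 2:
        raise InvalidInputError("need >= 2 meta observations")
    if (obs["sigma"] <= 0).any():
        raise InvalidInputError("all sigma must be > 0")
    cols = [np.ones(len(obs))]
    names = ["intercept"]
    factors: dict[str, tuple[str, list[str]]] = {}
    references = {"m": "m1", "s": "main", "p": "genetic", "d": "GBI"}
    for factor, ref in references.items():
        if factor not in obs.columns:
            continue
        levels = [l for l in sorted(obs[factor].astype(str).unique()) if l != ref]
        kept = []
        for level in levels:
            ind = (obs[factor].astype(str) == level).to_numpy(dtype=float)
            if ind.sum() == 0:
                logger.warning("level %s=%s never observed; coefficient dropped", factor, level)
                continue
            cols.append(ind)
            names.append(f"{factor}:{level}")
            kept.append(level)
        factors[factor] = (ref, kept)
    X = np.column_stack(cols)
    draws = _conjugate_posterior(
        X, obs["y"].to_numpy(float), obs["sigma"].to_numpy(float), prior_sd, n_draws, seed
    )
    return MetaFit(coef_names=names, draws=draws, design=X, observations=obs, factors=factors)


def fit_state_meta(
    state_effects: pd.DataFrame,
    grouping: str = "g",
    prior_sd: float = 1.5,
    n_draws: int = 4000,
    seed: int = 0,
) -> MetaFit:
    """Feature-state meta-analysis: group-indexed means, no global intercept.

    ``state_effects`` carries columns y, sigma and the grouping column
    (domain-group label per state).  Fitted separately per contact type and
    per classification by the caller.  Empty groups are dropped with a
    warning; states lacking a group raise.
    """
    obs = state_effects.reset_index(drop=True)
    if grouping not in obs.columns:
        raise InvalidInputError(f"no grouping column {grouping!r}")
    if obs[grouping].isna().any():
        missing = obs.index[obs[grouping].isna()].tolist()
        raise InvalidInputError(f"states without a domain group: rows {missing[:5]}")
    groups = sorted(obs[grouping].astype(str).unique())
    cols, names = [], []
    for gr in groups:
        ind = (obs[grouping].astype(str) == gr).to_numpy(dtype=float)
        if ind.sum() == 0:
            logger.warning("empty domain group %s dropped", gr)
            continue
        cols.append(ind)
        names.append(f"g:{gr}")
    X = np.column_stack(cols)
    draws = _conjugate_posterior(
        X, obs["y"].to_numpy(float), obs["sigma"].to_numpy(float), prior_sd, n_draws, seed
    )
    return MetaFit(
        coef_names=names, draws=draws, design=X, observations=obs,
        factors={grouping: ("", [n.split(":", 1)[1] for n in names])},
    )


def marginal_contrasts(fit: MetaFit) -> pd.DataFrame:
    """Average marginal effect of each categorical level versus its reference.

    For every factor level, the posterior distribution of the average
    difference in mu when every observed row is switched to that level versus
    the reference, averaged over the observed covariate rows; summarized by
    the median and 50/80/89% HPDIs plus P(contrast > 0).
    """
    rows = []
    for factor, (ref, levels) in fit.factors.items():
        if ref == "":  # group-mean model: contrast all unordered group pairs
            for i, g1 in enumerate(levels):
                for g2 in levels[i + 1 :]:
                    diff = fit.coef(f"g:{g1}") - fit.coef(f"g:{g2}")
                    rows.append(_summarize_contrast(factor, g1, g2, diff))
            continue
        for level in levels:
            name = f"{factor}:{level}"
            j = fit.coef_names.index(name)
            # brute-force averaging over observed rows: switch the factor's
            # dummies, difference the linear predictor, average per draw
            X_lvl = fit.design.copy()
            X_ref = fit.design.copy()
            for other in levels:
                jo = fit.coef_names.index(f"{factor}:{other}")
                X_lvl[:, jo] = 1.0 if other == level else 0.0
                X_ref[:, jo] = 0.0
            dmu = (X_lvl - X_ref) @ fit.draws.T  # (n_rows, n_draws)
            diff = dmu.mean(axis=0)
            rows.append(_summarize_contrast(factor, level, ref, diff))
    return pd.DataFrame(rows)


def _summarize_contrast(factor: str, level: str, ref: str, diff: np.ndarray) -> dict:
    lo89, hi89 = hpdi(diff, 0.89)
    lo80, hi80 = hpdi(diff, 0.80)
    lo50, hi50 = hpdi(diff, 0.50)
    return {
        "factor": factor,
        "level": level,
        "reference": ref,
        "median": float(np.median(diff)),
        "hpdi50_low": lo50, "hpdi50_high": hi50,
        "hpdi80_low": lo80, "hpdi80_high": hi80,
        "hpdi89_low": lo89, "hpdi89_high": hi89,
        "p_direction": prob_direction(diff),
        "hpdi89_includes_zero": bool(lo89 <= 0.0 <= hi89),
    }


def group_difference_matrix(fit: MetaFit) -> pd.DataFrame:
    """Pairwise posterior median differences between domain-group means.

    Cell (i, j) holds median(beta_i - beta_j); NaN-diagonal.  A companion
    boolean column layout is avoided: the "no evidence" flag (89% HPDI of
    the difference includes zero) is returned in the long companion frame
    from :func:`marginal_contrasts`.
    """
    groups = [n.split(":", 1)[1] for n in fit.coef_names]
    mat = np.full((len(groups), len(groups)), np.nan)
    for i, g1 in enumerate(groups):
        for j, g2 in enumerate(groups):
            if i == j:
                continue
            diff = fit.coef(f"g:{g1}") - fit.coef(f"g:{g2}")
            mat[i, j] = float(np.median(diff))
    return pd.DataFrame(mat, index=groups, columns=groups)
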