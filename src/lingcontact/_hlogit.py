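"""Log posterior and analytic gradient of the hierarchical logistic models.

The contact models are Bernoulli-logit regressions with correlated varying
intercepts and slopes.  This module owns the unconstrained parameterization
used by the sampler:

* varying effects are non-centered — standard-normal matrices scaled by
  ``diag(sigma) @ L`` where L is the Cholesky factor of an LKJ-distributed
  correlation matrix;
* group SDs live on the log scale with half-normal(0, 2) priors;
* correlation Cholesky factors are parameterized by canonical partial
  correlations (tanh of unconstrained values), the standard triangular
  bijection, with the LKJ(2) density and the transform Jacobian included.

Gradients are hand-derived and verified against finite differences in the
test suite.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


def sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x, dtype=float)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def log1p_exp(x: np.ndarray) -> np.ndarray:
    """log(1 + exp(x)) computed stably."""
    out = np.where(x > 0, x, 0.0) + np.log1p(np.exp(-np.abs(x)))
    return out


# ---------------------------------------------------------------------------
# Correlation Cholesky transform (canonical partial correlations)
# ---------------------------------------------------------------------------


def n_corr_free(dim: int) -> int:
    return dim * (dim - 1) // 2


def corr_chol_forward(y: np.ndarray, dim: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Build the Cholesky factor L of a correlation matrix from y.

    Returns (L, z, c) where z = tanh(y) are the canonical partial
    correlations and c[i, j] is the residual squared norm available before
    filling entry (i, j) (needed by both the Jacobian and the gradient).
    """
    # clamp away from +-1: beyond this the LKJ density underflows anyway and
    # the exploding gradient surfaces as a rejected divergent trajectory
    z_flat = np.clip(np.tanh(y), -1.0 + 1e-12, 1.0 - 1e-12)
    L = np.zeros((dim, dim))
    L[0, 0] = 1.0
    z = np.zeros((dim, dim))
    c = np.zeros((dim, dim))
    idx = 0
    for i in range(1, dim):
        acc = 1.0
        for j in range(i):
            z[i, j] = z_flat[idx]
            c[i, j] = acc
            L[i, j] = z[i, j] * np.sqrt(acc)
            acc *= 1.0 - z[i, j] ** 2
            idx += 1
        L[i, i] = np.sqrt(acc)
    return L, z, c


def lkj_chol_logp_grad(y: np.ndarray, dim: int, eta: float) -> tuple[float, np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """LKJ(eta) log density on L(y) plus the y -> L Jacobian, with gradient.

    Returns (logp, dlogp/dy, L, z, c).  The likelihood's own gradient with
    respect to L is chained through :func:`corr_chol_backward` separately.
    """
    L, z, c = corr_chol_forward(y, dim)
    logp = 0.0
    grad_y = np.zeros_like(y)
    idx = 0
    for i in range(1, dim):
        # LKJ density on the Cholesky factor: sum_k (dim - k - 1 + 2 eta - 2) log L[k,k]
        coeff = dim - (i + 1) + 2.0 * eta - 2.0
        logp += coeff * np.log(L[i, i])
        for j in range(i):
            zij = z[i, j]
            # Jacobian: log dL[i,j]/dz[i,j] + log dz/dy
            logp += 0.5 * np.log(c[i, j]) + np.log1p(-zij**2)
            # d logp / d z[i,m] contributions:
            #   L[i,i]^2 = prod_k (1 - z[i,k]^2)  -> d log L[i,i] / d z = -z/(1-z^2)
            #   c[i,j] = prod_{k<j} (1 - z[i,k]^2)
            idx += 1
        # gradient wrt z for row i, then chain through tanh
        row_grad = np.zeros(i)
        coeff_ii = coeff
        for m in range(i):
            zim = z[i, m]
            g = coeff_ii * (-zim / (1.0 - zim**2))  # from log L[i,i]
            # from jacobian terms 0.5 log c[i,j] for j > m
            for j in range(m + 1, i):
                g += 0.5 * (-2.0 * zim / (1.0 - zim**2))
            # from log(1 - z_im^2) tanh jacobian of its own entry
            g += -2.0 * zim / (1.0 - zim**2)
            row_grad[m] = g
        base = idx - i
        grad_y[base : base + i] = row_grad * (1.0 - z[i, :i] ** 2)  # dz/dy
    return float(logp), grad_y, L, z, c


def corr_chol_backward(dL: np.ndarray, y: np.ndarray, z: np.ndarray, c: np.ndarray, dim: int) -> np.ndarray:
    """Chain a gradient with respect to L back to the unconstrained y."""
    grad_y = np.zeros_like(y)
    idx = 0
    for i in range(1, dim):
        dz = np.zeros(i)
        sqc = np.sqrt(c[i, :i])
        Lii = np.sqrt(c[i, i - 1] * (1.0 - z[i, i - 1] ** 2)) if i >= 1 else 1.0
        for m in range(i):
            zim = z[i, m]
            g = dL[i, m] * sqc[m]  # direct dependence of L[i,m] on z[i,m]
            # L[i,j] for j > m depends on z[i,m] through sqrt(c[i,j])
            for j in range(m + 1, i):
                Lij = z[i, j] * sqc[j]
                g += dL[i, j] * Lij * (-zim / (1.0 - zim**2))
            # L[i,i] depends on all z[i,m]
            g += dL[i, i] * Lii * (-zim / (1.0 - zim**2))
            dz[m] = g
        grad_y[idx : idx + i] = dz * (1.0 - z[i, :i] ** 2)
        idx += i
    return grad_y


def sample_lkj_corr(dim: int, eta: float, rng: np.random.Generator) -> np.ndarray:
    """Draw a correlation matrix from LKJ(eta)."""
    if dim == 1:
        return np.ones((1, 1))
    return _lkj_onion(dim, eta, rng)


def _lkj_onion(dim: int, eta: float, rng: np.random.Generator) -> np.ndarray:
    """Onion-method LKJ sample (Lewandowski, Kurowicka & Joe 2009)."""
    beta = eta + (dim - 2) / 2.0
    u = rng.beta(beta, beta)
    R = np.array([[1.0, 2 * u - 1.0], [2 * u - 1.0, 1.0]])
    for k in range(2, dim):
        beta -= 0.5
        y = rng.beta(k / 2.0, beta)
        w = rng.standard_normal(k)
        w /= np.linalg.norm(w)
        w *= np.sqrt(y)
        A = np.linalg.cholesky(R)
        new_col = A @ w
        R = np.block([[R, new_col[:, None]], [new_col[None, :], np.ones((1, 1))]])
    return R


# ---------------------------------------------------------------------------
# Model definition
# ---------------------------------------------------------------------------


@dataclass
class DesignData:
    """Index-coded observation bundle consumed by the sampler."""

    y: np.ndarray
    A: np.ndarray
    G: np.ndarray
    state_idx: np.ndarray
    state_labels: list[str]
    aa_idx: np.ndarray | None = None
    aa_labels: list[str] = field(default_factory=list)
    broad_idx: np.ndarray | None = None
    broad_labels: list[str] = field(default_factory=list)
    pair_idx: np.ndarray | None = None
    pair_labels: list[str] = field(default_factory=list)

    @property
    def n_obs(self) -> int:
        return int(self.y.size)


@dataclass
class HLogitStructure:
    """Which terms the linear predictor carries (m1 / m2 / m3-m5)."""

    has_area: bool
    has_genetic: bool
    has_aa: bool  # area-combination varying intercept (+ genetic slope in m1)
    has_pairs: bool  # nested broad/pair genetic slopes
    intercept_mean: float = 0.75
    intercept_sd: float = 0.5
    fixed_sd: float = 1.5
    group_sd_scale: float = 2.0
    lkj_eta: float = 2.0

    @property
    def ds(self) -> int:
        """Columns of the per-state effect matrix: intercept + active slopes."""
        return 1 + int(self.has_area) + int(self.has_genetic)

    @property
    def da(self) -> int:
        if not self.has_aa:
            return 0
        return 2 if (self.has_area and self.has_genetic) else 1


class HLogitModel:
    """Packed-vector view of one hierarchical logistic model on one dataset."""

    def __init__(self, structure: HLogitStructure, data: DesignData):
        self.st = structure
        self.data = data
        self.S = len(data.state_labels)
        self.C = len(data.aa_labels) if structure.has_aa else 0
        self.B = len(data.broad_labels) if structure.has_pairs else 0
        self.P = len(data.pair_labels) if structure.has_pairs else 0
        ds, da = structure.ds, structure.da
        sizes = {
            "alpha": 1,
            "beta_A": int(structure.has_area),
            "beta_G": int(structure.has_genetic),
            "z_state": self.S * ds,
            "u_state": ds,
            "y_state": n_corr_free(ds),
            "z_aa": self.C * da,
            "u_aa": da,
            "y_aa": n_corr_free(da),
            "z_broad": self.B,
            "u_broad": int(structure.has_pairs),
            "z_pair": self.P,
            "u_pair": int(structure.has_pairs),
        }
        self.slices: dict[str, slice] = {}
        off = 0
        for name, size in sizes.items():
            self.slices[name] = slice(off, off + size)
            off += size
        self.dim = off
        d = data
        self._rA = d.A.astype(float)
        self._rG = d.G.astype(float)
        self._y = d.y.astype(float)
        if structure.has_pairs and d.broad_idx is not None:
            self._bmask = (d.broad_idx >= 0).astype(float)
            self._bclip = np.clip(d.broad_idx, 0, None)
            self._pmask = (d.pair_idx >= 0).astype(float)
            self._pclip = np.clip(d.pair_idx, 0, None)

    # -- packing helpers ---------------------------------------------------

    def _get(self, theta: np.ndarray, name: str) -> np.ndarray:
        return theta[self.slices[name]]

    def unpack(self, theta: np.ndarray) -> dict:
        """Constrained parameters implied by one unconstrained vector."""
        st = self.st
        ds, da = st.ds, st.da
        out: dict = {"alpha": float(self._get(theta, "alpha")[0])}
        out["beta_A"] = float(self._get(theta, "beta_A")[0]) if st.has_area else None
        out["beta_G"] = float(self._get(theta, "beta_G")[0]) if st.has_genetic else None
        sigma_state = np.exp(self._get(theta, "u_state"))
        if ds > 1:
            L_state, _, _ = corr_chol_forward(self._get(theta, "y_state"), ds)
        else:
            L_state = np.ones((1, 1))
        M_state = sigma_state[:, None] * L_state
        out["sigma_state"] = sigma_state
        out["R_state"] = L_state @ L_state.T
        out["state_eff"] = self._get(theta, "z_state").reshape(self.S, ds) @ M_state.T
        if st.has_aa:
            sigma_aa = np.exp(self._get(theta, "u_aa"))
            if da > 1:
                L_aa, _, _ = corr_chol_forward(self._get(theta, "y_aa"), da)
            else:
                L_aa = np.ones((1, 1))
            M_aa = sigma_aa[:, None] * L_aa
            out["sigma_aa"] = sigma_aa
            out["R_aa"] = L_aa @ L_aa.T
            out["aa_eff"] = self._get(theta, "z_aa").reshape(self.C, da) @ M_aa.T
        if st.has_pairs:
            out["sigma_broad"] = float(np.exp(self._get(theta, "u_broad")[0]))
            out["sigma_pair"] = float(np.exp(self._get(theta, "u_pair")[0]))
            out["broad_eff"] = out["sigma_broad"] * self._get(theta, "z_broad")
            out["pair_eff"] = out["sigma_pair"] * self._get(theta, "z_pair")
        return out

    # -- linear predictor --------------------------------------------------

    def eta(self, params: dict, data: DesignData | None = None) -> np.ndarray:
        """Assemble the linear predictor for every observation.

        Unseen group levels (index -1) contribute zero, the population-mean
        prediction for a new group.
        """
        st = self.st
        d = data if data is not None else self.data
        A = d.A.astype(float)
        G = d.G.astype(float)
        eta = np.full(d.n_obs, params["alpha"], dtype=float)
        se = params["state_eff"]
        sidx = d.state_idx
        valid = sidx >= 0
        eta[valid] += se[sidx[valid], 0]
        col = 1
        if st.has_area:
            slope = np.full(d.n_obs, params["beta_A"])
            slope[valid] += se[sidx[valid], col]
            eta += slope * A
            col += 1
        if st.has_genetic:
            slope = np.full(d.n_obs, params["beta_G"])
            slope[valid] += se[sidx[valid], col]
            if st.has_aa and params.get("aa_eff") is not None and d.aa_idx is not None:
                ae = params["aa_eff"]
                avalid = d.aa_idx >= 0
                eta[avalid] += ae[d.aa_idx[avalid], 0]
                if ae.shape[1] > 1:
                    slope[avalid] += ae[d.aa_idx[avalid], 1]
            if st.has_pairs and d.broad_idx is not None:
                bvalid = d.broad_idx >= 0
                slope[bvalid] += params["broad_eff"][d.broad_idx[bvalid]]
                pvalid = d.pair_idx >= 0
                slope[pvalid] += params["pair_eff"][d.pair_idx[pvalid]]
            eta += slope * G
        elif st.has_aa and d.aa_idx is not None:
            ae = params["aa_eff"]
            avalid = d.aa_idx >= 0
            eta[avalid] += ae[d.aa_idx[avalid], 0]
        return eta

    # -- log posterior and gradient ---------------------------------------

    def logp_grad(self, theta: np.ndarray) -> tuple[float, np.ndarray]:
        st = self.st
        d = self.data
        ds, da = st.ds, st.da
        grad = np.zeros(self.dim)

        alpha = self._get(theta, "alpha")[0]
        beta_A = self._get(theta, "beta_A")[0] if st.has_area else 0.0
        beta_G = self._get(theta, "beta_G")[0] if st.has_genetic else 0.0

        z_state = self._get(theta, "z_state").reshape(self.S, ds)
        u_state = self._get(theta, "u_state")
        sigma_state = np.exp(u_state)
        if ds > 1:
            y_state = self._get(theta, "y_state")
            lkj_lp_s, lkj_gy_s, L_state, zc_s, cc_s = lkj_chol_logp_grad(y_state, ds, st.lkj_eta)
        else:
            L_state = np.ones((1, 1))
        M_state = sigma_state[:, None] * L_state
        E_state = z_state @ M_state.T

        if st.has_aa:
            z_aa = self._get(theta, "z_aa").reshape(self.C, da)
            u_aa = self._get(theta, "u_aa")
            sigma_aa = np.exp(u_aa)
            if da > 1:
                y_aa = self._get(theta, "y_aa")
                lkj_lp_a, lkj_gy_a, L_aa, zc_a, cc_a = lkj_chol_logp_grad(y_aa, da, st.lkj_eta)
            else:
                L_aa = np.ones((1, 1))
            M_aa = sigma_aa[:, None] * L_aa
            E_aa = z_aa @ M_aa.T
        if st.has_pairs:
            z_broad = self._get(theta, "z_broad")
            z_pair = self._get(theta, "z_pair")
            u_broad = self._get(theta, "u_broad")[0]
            u_pair = self._get(theta, "u_pair")[0]
            sigma_broad, sigma_pair = np.exp(u_broad), np.exp(u_pair)
            b_broad = sigma_broad * z_broad
            b_pair = sigma_pair * z_pair

        A, G, y = self._rA, self._rG, self._y
        sidx = d.state_idx
        eta = alpha + E_state[sidx, 0]
        col = 1
        if st.has_area:
            slopeA = beta_A + E_state[sidx, col]
            eta += slopeA * A
            colA = col
            col += 1
        if st.has_genetic:
            slopeG = beta_G + E_state[sidx, col]
            colG = col
            if st.has_aa:
                eta += E_aa[d.aa_idx, 0]
                if da > 1:
                    slopeG = slopeG + E_aa[d.aa_idx, 1]
            if st.has_pairs:
                slopeG = slopeG + b_broad[self._bclip] * self._bmask
                slopeG = slopeG + b_pair[self._pclip] * self._pmask
            eta += slopeG * G
        elif st.has_aa:
            eta += E_aa[d.aa_idx, 0]

        # Bernoulli-logit likelihood
        lp = float(np.sum(y * eta - log1p_exp(eta)))
        r = y - sigmoid(eta)

        # gradient wrt eta components
        grad[self.slices["alpha"]] = r.sum()
        G_E = np.zeros((self.S, ds))
        G_E[:, 0] = np.bincount(sidx, weights=r, minlength=self.S)
        if st.has_area:
            rA = r * A
            grad[self.slices["beta_A"]] = rA.sum()
            G_E[:, colA] = np.bincount(sidx, weights=rA, minlength=self.S)
        if st.has_genetic:
            rG = r * G
            grad[self.slices["beta_G"]] = rG.sum()
            G_E[:, colG] = np.bincount(sidx, weights=rG, minlength=self.S)
            if st.has_aa:
                G_Eaa = np.zeros((self.C, da))
                G_Eaa[:, 0] = np.bincount(d.aa_idx, weights=r, minlength=self.C)
                if da > 1:
                    G_Eaa[:, 1] = np.bincount(d.aa_idx, weights=rG, minlength=self.C)
            if st.has_pairs:
                g_broad = np.bincount(self._bclip, weights=rG * self._bmask, minlength=self.B)
                g_pair = np.bincount(self._pclip, weights=rG * self._pmask, minlength=self.P)
        elif st.has_aa:
            G_Eaa = np.zeros((self.C, da))
            G_Eaa[:, 0] = np.bincount(d.aa_idx, weights=r, minlength=self.C)

        # chain rule through E = z @ M^T, M = diag(sigma) @ L
        dz_state = G_E @ M_state
        dM_state = G_E.T @ z_state
        dsig_state = np.sum(dM_state * L_state, axis=1)
        grad[self.slices["z_state"]] = dz_state.ravel()
        grad[self.slices["u_state"]] = dsig_state * sigma_state
        if ds > 1:
            dL_state = sigma_state[:, None] * dM_state
            grad[self.slices["y_state"]] = corr_chol_backward(dL_state, y_state, zc_s, cc_s, ds)
            lp += lkj_lp_s
            grad[self.slices["y_state"]] += lkj_gy_s
        if st.has_aa:
            dz_aa = G_Eaa @ M_aa
            dM_aa = G_Eaa.T @ z_aa
            dsig_aa = np.sum(dM_aa * L_aa, axis=1)
            grad[self.slices["z_aa"]] = dz_aa.ravel()
            grad[self.slices["u_aa"]] = dsig_aa * sigma_aa
            if da > 1:
                dL_aa = sigma_aa[:, None] * dM_aa
                grad[self.slices["y_aa"]] = corr_chol_backward(dL_aa, y_aa, zc_a, cc_a, da)
                lp += lkj_lp_a
                grad[self.slices["y_aa"]] += lkj_gy_a
        if st.has_pairs:
            grad[self.slices["z_broad"]] = sigma_broad * g_broad
            grad[self.slices["z_pair"]] = sigma_pair * g_pair
            grad[self.slices["u_broad"]] = sigma_broad * float(np.dot(g_broad, z_broad))
            grad[self.slices["u_pair"]] = sigma_pair * float(np.dot(g_pair, z_pair))

        # priors
        lp += -0.5 * (alpha - st.intercept_mean) ** 2 / st.intercept_sd**2
        grad[self.slices["alpha"]] += -(alpha - st.intercept_mean) / st.intercept_sd**2
        if st.has_area:
            lp += -0.5 * beta_A**2 / st.fixed_sd**2
            grad[self.slices["beta_A"]] += -beta_A / st.fixed_sd**2
        if st.has_genetic:
            lp += -0.5 * beta_G**2 / st.fixed_sd**2
            grad[self.slices["beta_G"]] += -beta_G / st.fixed_sd**2
        for zname in ("z_state", "z_aa", "z_broad", "z_pair"):
            z = self._get(theta, zname)
            if z.size:
                lp += -0.5 * float(np.dot(z, z))
                grad[self.slices[zname]] += -z
        s2 = st.group_sd_scale**2
        for uname in ("u_state", "u_aa", "u_broad", "u_pair"):
            u = self._get(theta, uname)
            if u.size:
                sig = np.exp(u)
                lp += float(np.sum(-0.5 * sig**2 / s2 + u))
                grad[self.slices[uname]] += -(sig**2) / s2 + 1.0
        return lp, grad
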