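"""Design stage: joint up-scaling of individual-level confounders and
estimation of the generalized ecological propensity score (EPS).

Two submodels are fitted jointly by MCMC over the in-sample areas S:

* an up-scaling model: each of the K mixed-type individual-level variables
  m_ijk is linked to a latent area-level value M_ik through
  g_k(M_ik) = nu_k + xi_ik, with flat intercepts nu_k and S x K spatial
  random effects xi carrying a multivariate intrinsic CAR (MICAR) prior whose
  K x K precision has a Wishart(v, B) prior (v > K - 1; B defaults to the
  inverse empirical correlation of the pooled records);
* a conditional Gaussian exposure model
  X_i | C_i, M_i ~ N(delta_0 + C'delta_C + M'delta_M, sigma_X^2), whose
  confounder term M'delta_M defines the in-sample score Z^(0).

Because the two are one joint posterior, uncertainty in the up-scaled M feeds
into Z^(0): areas with more survey subjects get tighter score posteriors.
The score is identified only up to affine transformations absorbed by the
other exposure-model terms, so comparisons against a generating truth must be
made after affine alignment.

Sampling is Metropolis-within-Gibbs: single-site random-walk updates for xi
(vectorised over colour classes of the neighbour graph) and nu, conjugate
updates for delta, the residual variances, and the Wishart precision; the
MICAR impropriety is resolved by hard per-draw centering of each xi column
with a compensating shift of the intercept.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .inference import AdaptiveScale, ConvergenceReport, MCMCResult, MCMCSettings, run_mcmc
from .simulate import EcologicalDataset, IndividualDataset
from .spatial import SpatialDomain

__all__ = [
    "UpscalingModelSpec",
    "EPSModelSpec",
    "DesignStageResult",
    "fit_design_stage",
    "balancing_check",
    "micar_neg_energy",
    "micar_full_conditional",
]


def _expit(x):
    return 1.0 / (1.0 + np.exp(-x))


def micar_neg_energy(xi: np.ndarray, Q: np.ndarray, Sig_inv: np.ndarray) -> float:
    """Unnormalised log-density of the intrinsic multivariate CAR field:
    -1/2 tr(Sigma_xi^-1 xi' Q xi), i.e. the improper joint precision is the
    Kronecker product Q (x) Sigma_xi^-1 of the neighbour-graph Laplacian with
    the between-variable precision."""
    return -0.5 * float(np.trace(Sig_inv @ xi.T @ Q @ xi))


def micar_full_conditional(
    xi: np.ndarray, i: int, neighbors: np.ndarray, Sig_inv: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Full conditional of one area's K-vector under the MICAR prior:
    Gaussian with mean the average of its neighbours' vectors and covariance
    Sigma_xi / n_i."""
    n_i = len(neighbors)
    mean = xi[neighbors].mean(axis=0)
    cov = np.linalg.inv(Sig_inv) / n_i
    return mean, cov


@dataclass
class UpscalingModelSpec:
    """Links/priors of the up-scaling model.

    ``variable_types`` tags each individual-level variable as "continuous"
    (Gaussian, identity link), "binary" (Bernoulli, logit link) or
    "categorical:T" (T-category multinomial logit with T - 1 non-reference
    latent columns).  ``v`` and ``B`` parameterise the Wishart prior on the
    MICAR precision; ``spatial=False`` swaps the MICAR for independent
    N(0, Sigma_xi) effects (a no-spatial-smoothing variant used in tests).
    """

    variable_types: list[str] = field(default_factory=list)
    v: float | None = None  # Wishart dof; default K* + 1
    B: np.ndarray | None = None  # Wishart scale; default inv(corr(records))
    spatial: bool = True


@dataclass
class EPSModelSpec:
    prior_var_delta: float = 100.0
    sigma_X_prior: tuple = (1.0, 0.1)  # Gamma(shape, rate) on the precision
    pooled_variance: bool = False  # report one pooled score variance


@dataclass
class DesignStageResult:
    """Posterior summaries of the in-sample score and up-scaled confounders.

    ``Z0_var`` holds per-area posterior variances by default (strictly more
    informative); ``Z0_var_pooled`` is their mean, matching a single-variance
    reading of the downstream uncertainty model.
    """

    in_sample_ids: list[str]
    in_sample_idx: np.ndarray  # indices into the full domain
    Z0_mean: np.ndarray
    Z0_var: np.ndarray
    Z0_var_pooled: float
    M_mean: np.ndarray
    M_sd: np.ndarray
    mcmc: MCMCResult
    subdomain: SpatialDomain

    @property
    def diagnostics(self) -> ConvergenceReport:
        return self.mcmc.report

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"area_id": self.in_sample_ids, "Z0_mean": self.Z0_mean,
                           "Z0_var": self.Z0_var})
        for k in range(self.M_mean.shape[1]):
            df[f"M{k + 1}_mean"] = self.M_mean[:, k]
            df[f"M{k + 1}_sd"] = self.M_sd[:, k]
        return df


# ---------------------------------------------------------------------------
# Column expansion and sufficient statistics
# ---------------------------------------------------------------------------

class _Variable:
    """One individual-level variable with its latent columns and sufficient
    statistics over the in-sample areas."""

    def __init__(self, kind: str, data_by_area: list[np.ndarray], col0: int):
        self.kind = kind.split(":")[0]
        self.n = np.array([len(v) for v in data_by_area], dtype=float)
        if self.kind == "continuous":
            self.n_cols = 1
            self.s1 = np.array([v.sum() for v in data_by_area])
            self.s2 = np.array([(v ** 2).sum() for v in data_by_area])
        elif self.kind == "binary":
            self.n_cols = 1
            self.ones = np.array([v.sum() for v in data_by_area])
        elif self.kind == "categorical":
            self.T = int(kind.split(":")[1])
            self.n_cols = self.T - 1
            self.counts = np.zeros((len(data_by_area), self.T))
            for i, v in enumerate(data_by_area):
                for t in range(self.T):
                    self.counts[i, t] = np.sum(v == t)
        else:
            raise ValueError(f"unknown variable type {kind!r}")
        self.cols = list(range(col0, col0 + self.n_cols))

    # --- latent columns -> EPS design columns ------------------------------
    def m_cols(self, eta: np.ndarray) -> np.ndarray:
        """Map latent columns eta = nu + xi (n, n_cols) to design columns:
        the value itself (continuous), the success probability (binary) or
        the non-reference category probabilities (categorical)."""
        if self.kind == "continuous":
            return eta
        if self.kind == "binary":
            return _expit(eta)
        ex = np.exp(eta - eta.max(axis=1, keepdims=True))
        denom = np.exp(-eta.max(axis=1, keepdims=True)) + ex.sum(axis=1, keepdims=True)
        return ex / denom

    def loglik(self, eta: np.ndarray, rows: np.ndarray, sigma2: float | None) -> np.ndarray:
        """Per-area record log-likelihood for the given rows (up to const)."""
        if self.kind == "continuous":
            mu = eta[:, 0]
            return -0.5 / sigma2 * (self.n[rows] * mu ** 2 - 2 * mu * self.s1[rows])
        if self.kind == "binary":
            p = _expit(eta[:, 0])
            return self.ones[rows] * np.log(p) + (self.n[rows] - self.ones[rows]) * np.log1p(-p)
        full = np.concatenate([np.zeros((eta.shape[0], 1)), eta], axis=1)
        logp = full - np.logaddexp.reduce(full, axis=1, keepdims=True)
        return (self.counts[rows] * logp).sum(axis=1)


class _DesignStageModel:
    """Gibbs model for the joint up-scaling + EPS posterior (see module doc)."""

    def __init__(
        self,
        variables: list[_Variable],
        X: np.ndarray,
        Cmat: np.ndarray,
        sub: SpatialDomain,
        up: UpscalingModelSpec,
        eps: EPSModelSpec,
    ):
        self.vars = variables
        self.X = X
        self.C = Cmat
        self.sub = sub
        self.S = len(X)
        self.K = sum(v.n_cols for v in variables)
        self.up = up
        self.eps = eps

        self.v_dof = up.v if up.v is not None else self.K + 1
        if self.v_dof <= self.K - 1:
            raise ValueError(
                f"Wishart degrees of freedom must exceed K - 1 = {self.K - 1}"
            )
        if up.B is not None:
            B = np.asarray(up.B, dtype=float)
            if np.linalg.eigvalsh(B).min() <= 0:
                raise ValueError("Wishart scale matrix B must be positive definite")
            self.B = B
        else:
            self.B = np.eye(self.K)

        self.A = sub.adjacency() if up.spatial else None
        self.Q = sub.laplacian() if up.spatial else None
        self.ncomp = sub.n_components() if up.spatial else 0
        self.deg = sub.n_neighbors.astype(float) if up.spatial else np.ones(self.S)
        self.colors = sub.coloring() if up.spatial else [np.arange(self.S)]
        if up.spatial and self.ncomp > 1:
            warnings.warn(
                "in-sample neighbour graph has multiple components; "
                "xi columns are centred globally", stacklevel=2
            )

        self.p_delta = 1 + Cmat.shape[1] + self.K
        self.m_slice = slice(1 + Cmat.shape[1], self.p_delta)
        self.cont_idx = [i for i, v in enumerate(self.vars) if v.kind == "continuous"]
        self.diagnostic_params = ("delta", "sigma2_X", "nu", "Z0")

    # -- helpers ------------------------------------------------------------
    def _mcols(self, nu: np.ndarray, xi: np.ndarray) -> np.ndarray:
        out = np.empty((xi.shape[0], self.K))
        for v in self.vars:
            out[:, v.cols] = v.m_cols(nu[v.cols][None, :] + xi[:, v.cols])
        return out

    def init_state(self, rng) -> dict:
        nu = np.zeros(self.K)
        xi = np.zeros((self.S, self.K))
        for v in self.vars:
            if v.kind == "continuous":
                pooled = v.s1.sum() / v.n.sum()
                nu[v.cols[0]] = pooled
                with np.errstate(invalid="ignore"):
                    dev = np.where(v.n > 0, v.s1 / np.maximum(v.n, 1) - pooled, 0.0)
                xi[:, v.cols[0]] = dev * v.n / (v.n + 2.0)
            elif v.kind == "binary":
                p = (v.ones.sum() + 1.0) / (v.n.sum() + 2.0)
                nu[v.cols[0]] = np.log(p / (1 - p))
            else:
                tot = v.counts.sum(axis=0) + 1.0
                nu[v.cols] = np.log(tot[1:] / tot[0])
        for c in range(self.K):
            xi[:, c] -= xi[:, c].mean()
        sigma2_m = {}
        for vi in self.cont_idx:
            v = self.vars[vi]
            mean_i = np.where(v.n > 0, v.s1 / np.maximum(v.n, 1), 0.0)
            ss = (v.s2 - v.n * mean_i ** 2).sum()
            sigma2_m[vi] = max(ss / max(v.n.sum() - (v.n > 0).sum(), 1.0), 1e-3)
        M = self._mcols(nu, xi)
        W = np.column_stack([np.ones(self.S), self.C, M])
        delta, *_ = np.linalg.lstsq(W, self.X, rcond=None)
        resid = self.X - W @ delta
        state = {
            "nu": nu,
            "xi": xi,
            "Sig_inv": np.eye(self.K),
            "sigma2_m": sigma2_m,
            "delta": delta,
            "sigma2_X": max(float(resid.var()), 1e-4),
            "M": M,
            "xmean": W @ delta,
            "_sc_xi": AdaptiveScale(self.S * self.K, init=0.2),
            "_sc_nu": AdaptiveScale(self.K, init=0.05),
        }
        return state

    # -- sweep --------------------------------------------------------------
    def sweep(self, state, rng, tune: bool) -> None:
        self._update_xi(state, rng, tune)
        self._update_nu(state, rng, tune)
        self._center(state)
        self._update_Sig_inv(state, rng)
        self._update_sigma2_m(state, rng)
        self._update_delta(state, rng)
        self._update_sigma2_X(state, rng)

    def _update_xi(self, state, rng, tune) -> None:
        # Single-site scalar random-walk per latent column, vectorised over
        # colour classes (mutually non-adjacent sites have independent MICAR
        # full conditionals, so simultaneous updates are valid).
        xi, nu = state["xi"], state["nu"]
        P = state["Sig_inv"]
        delta_m = state["delta"][self.m_slice]
        scales = state["_sc_xi"].scale.reshape(self.S, self.K)
        acc = np.zeros((self.S, self.K))
        col_coef = [delta_m[np.array(v.cols)] for v in self.vars]
        for cls in self.colors:
            xiP = xi[cls] @ P
            SP = (self.A[cls] @ xi) @ P if self.up.spatial else None
            for vi, v in enumerate(self.vars):
                eta_cur = nu[v.cols][None, :] + xi[np.ix_(cls, v.cols)]
                m_cur = v.m_cols(eta_cur)
                s2 = state["sigma2_m"].get(vi) if v.kind == "continuous" else None
                ll_cur = v.loglik(eta_cur, cls, s2)
                for j, c in enumerate(v.cols):
                    eps = scales[cls, c] * rng.standard_normal(len(cls))
                    d = -0.5 * (
                        self.deg[cls] * (2 * eps * xiP[:, c] + eps ** 2 * P[c, c])
                        - (2 * eps * SP[:, c] if self.up.spatial else 0.0)
                    )
                    eta_new = eta_cur.copy()
                    eta_new[:, j] += eps
                    ll_new = v.loglik(eta_new, cls, s2)
                    m_new = v.m_cols(eta_new)
                    xm_new = state["xmean"][cls] + (m_new - m_cur) @ col_coef[vi]
                    d += ll_new - ll_cur
                    d += -0.5 / state["sigma2_X"] * (
                        (self.X[cls] - xm_new) ** 2
                        - (self.X[cls] - state["xmean"][cls]) ** 2
                    )
                    accept = np.log(rng.random(len(cls))) < d
                    if accept.any():
                        rows = cls[accept]
                        xi[rows, c] += eps[accept]
                        state["xmean"][rows] = xm_new[accept]
                        state["M"][np.ix_(rows, v.cols)] = m_new[accept]
                        eta_cur[accept] = eta_new[accept]
                        m_cur[accept] = m_new[accept]
                        ll_cur[accept] = ll_new[accept]
                        xiP[accept] = xi[rows] @ P
                    acc[cls, c] = accept
        if tune:
            state["_sc_xi"].update(acc.ravel())

    def _update_nu(self, state, rng, tune) -> None:
        xi, nu = state["xi"], state["nu"]
        delta_m = state["delta"][self.m_slice]
        scales = state["_sc_nu"].scale
        acc = np.zeros(self.K)
        rows = np.arange(self.S)
        for v in self.vars:
            s2 = state["sigma2_m"].get(self.vars.index(v)) if v.kind == "continuous" else None
            for j, c in enumerate(v.cols):
                eps = scales[c] * rng.standard_normal()
                eta_cur = nu[v.cols][None, :] + xi[:, v.cols]
                eta_new = eta_cur.copy()
                eta_new[:, j] += eps
                dll = v.loglik(eta_new, rows, s2).sum() - v.loglik(eta_cur, rows, s2).sum()
                m_new = v.m_cols(eta_new)
                xm_new = state["xmean"] + (m_new - state["M"][:, v.cols]) @ delta_m[np.array(v.cols)]
                d_x = -0.5 / state["sigma2_X"] * (
                    ((self.X - xm_new) ** 2).sum() - ((self.X - state["xmean"]) ** 2).sum()
                )
                if np.log(rng.random()) < dll + d_x:
                    nu[c] += eps
                    state["xmean"] = xm_new
                    state["M"][:, v.cols] = m_new
                    acc[c] = 1.0
        if tune:
            state["_sc_nu"].update(acc)

    def _center(self, state) -> None:
        # Hard sum-to-zero for each xi column; the global shift moves into nu,
        # leaving nu + xi (hence M and the X-model mean) unchanged.
        mu = state["xi"].mean(axis=0)
        state["xi"] -= mu
        state["nu"] += mu

    def _update_Sig_inv(self, state, rng) -> None:
        xi = state["xi"]
        if self.up.spatial:
            quad = xi.T @ (self.Q @ xi)
            df = self.v_dof + self.S - self.ncomp
        else:
            quad = xi.T @ xi
            df = self.v_dof + self.S
        rate = self.B + quad
        rate = 0.5 * (rate + rate.T) + 1e-10 * np.eye(self.K)
        scale = np.linalg.inv(rate)
        scale = 0.5 * (scale + scale.T)
        draw = sps.wishart.rvs(df=df, scale=scale, random_state=rng)
        state["Sig_inv"] = np.atleast_2d(draw)

    def _update_sigma2_m(self, state, rng) -> None:
        nu, xi = state["nu"], state["xi"]
        for vi in self.cont_idx:
            v = self.vars[vi]
            mu = nu[v.cols[0]] + xi[:, v.cols[0]]
            ssr = (v.s2 - 2 * mu * v.s1 + v.n * mu ** 2).sum()
            shape = 1.0 + v.n.sum() / 2.0
            rate = 0.1 + ssr / 2.0
            state["sigma2_m"][vi] = 1.0 / rng.gamma(shape, 1.0 / rate)

    def _update_delta(self, state, rng) -> None:
        W = np.column_stack([np.ones(self.S), self.C, state["M"]])
        prec = W.T @ W / state["sigma2_X"] + np.eye(self.p_delta) / self.eps.prior_var_delta
        L = np.linalg.cholesky(prec)
        b = W.T @ self.X / state["sigma2_X"]
        mean = np.linalg.solve(prec, b)
        z = rng.standard_normal(self.p_delta)
        state["delta"] = mean + np.linalg.solve(L.T, z)
        state["xmean"] = W @ state["delta"]

    def _update_sigma2_X(self, state, rng) -> None:
        a0, b0 = self.eps.sigma_X_prior
        ssr = ((self.X - state["xmean"]) ** 2).sum()
        state["sigma2_X"] = 1.0 / rng.gamma(a0 + self.S / 2.0, 1.0 / (b0 + ssr / 2.0))

    def monitor(self, state) -> dict:
        # The score is identified only up to affine transformations absorbed
        # by delta_0/delta_C (and downstream by the outcome-model intercept),
        # so each draw is centred over the in-sample areas; this removes the
        # unidentified common level from the reported per-area variances.
        z0 = state["M"] @ state["delta"][self.m_slice]
        return {
            "delta": state["delta"],
            "sigma2_X": state["sigma2_X"],
            "nu": state["nu"],
            "Z0": z0 - z0.mean(),
            "M": state["M"],
            "_xi_colsum": state["xi"].sum(axis=0),
        }


# ---------------------------------------------------------------------------
# Public API
# ---------------------------------------------------------------------------

def fit_design_stage(
    indiv: IndividualDataset,
    eco: EcologicalDataset,
    domain: SpatialDomain,
    upscaling: UpscalingModelSpec | None = None,
    eps: EPSModelSpec | None = None,
    mcmc: MCMCSettings | None = None,
) -> DesignStageResult:
    """Fit the joint up-scaling + EPS model on the in-sample areas.

    In-sample areas are those with ``ell == 0``; each must have at least one
    individual record.  The neighbour structure is rebuilt on the in-sample
    subset from centroid distances (auto-expanded so every area keeps at
    least one neighbour).
    """
    upscaling = upscaling or UpscalingModelSpec()
    eps = eps or EPSModelSpec()
    mcmc = mcmc or MCMCSettings()

    mask = eco.ell == 0
    sub, idx = domain.subdomain(mask)
    records = indiv.by_area(sub.area_ids)
    if any(len(r) == 0 for r in records):
        bad = [sub.area_ids[i] for i, r in enumerate(records) if len(r) == 0]
        raise ValueError(f"in-sample areas without individual records: {bad[:5]}")

    types = upscaling.variable_types or list(indiv.types)
    variables: list[_Variable] = []
    col0 = 0
    for k, t in enumerate(types):
        v = _Variable(t, [r[:, k] for r in records], col0)
        variables.append(v)
        col0 += v.n_cols

    spec = UpscalingModelSpec(
        variable_types=types, v=upscaling.v, B=upscaling.B, spatial=upscaling.spatial
    )
    if spec.B is None:
        pooled = np.vstack([r for r in records if len(r)])
        expanded = _expand_columns(pooled, types)
        corr = np.corrcoef(expanded, rowvar=False)
        corr = np.atleast_2d(corr) + 1e-6 * np.eye(expanded.shape[1])
        spec.B = np.linalg.inv(corr)

    Cmat = eco.C[idx].reshape(len(idx), -1)
    model = _DesignStageModel(variables, eco.X[idx], Cmat, sub, spec, eps)
    result = run_mcmc(model, mcmc)

    z0 = result.stacked("Z0")
    m = result.stacked("M")
    pooled_var = float(z0.var(axis=0, ddof=1).mean())
    return DesignStageResult(
        in_sample_ids=list(sub.area_ids),
        in_sample_idx=idx,
        Z0_mean=z0.mean(axis=0),
        Z0_var=z0.var(axis=0, ddof=1),
        Z0_var_pooled=pooled_var,
        M_mean=m.mean(axis=0),
        M_sd=m.std(axis=0, ddof=1),
        mcmc=result,
        subdomain=sub,
    )


def _expand_columns(records: np.ndarray, types: list[str]) -> np.ndarray:
    cols = []
    for k, t in enumerate(types):
        kind = t.split(":")[0]
        if kind == "categorical":
            T = int(t.split(":")[1])
            for lev in range(1, T):
                cols.append((records[:, k] == lev).astype(float))
        else:
            cols.append(records[:, k].astype(float))
    return np.column_stack(cols)


def _residualize(y: np.ndarray, Z: np.ndarray) -> np.ndarray:
    Z1 = np.column_stack([np.ones(len(y)), Z])
    coef, *_ = np.linalg.lstsq(Z1, y, rcond=None)
    return y - Z1 @ coef


def balancing_check(
    result: DesignStageResult, eco: EcologicalDataset
) -> pd.DataFrame:
    """Check the balancing property of the estimated score on simulated data.

    For each latent confounder k (M_true known from the generator), reports
    the partial correlation of exposure X with M_k (i) given C only and
    (ii) given C and the posterior-mean score.  Balancing predicts (ii) is
    attenuated toward zero relative to (i).
    """
    idx = result.in_sample_idx
    if len(idx) < 10:
        raise ValueError("balance report unreliable with fewer than 10 in-sample areas")
    X = eco.X[idx]
    C = eco.C[idx].reshape(len(idx), -1)
    M = eco.M_true[idx]
    CZ = np.column_stack([C, result.Z0_mean])
    rows = []
    for k in range(M.shape[1]):
        r_c = np.corrcoef(_residualize(X, C), _residualize(M[:, k], C))[0, 1]
        r_cz = np.corrcoef(_residualize(X, CZ), _residualize(M[:, k], CZ))[0, 1]
        rows.append({
            "confounder": f"M{k + 1}",
            "partial_corr_given_C": r_c,
            "partial_corr_given_C_Z0": r_cz,
            "attenuated": abs(r_cz) < abs(r_c),
        })
    return pd.DataFrame(rows)
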