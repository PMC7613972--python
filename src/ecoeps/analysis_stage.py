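"""Analysis stage: health-effect regression with propensity-score adjustment.

Fits the Poisson disease-mapping model

    Y_i ~ Poisson(E_i mu_i),
    log(mu_i) = beta_0 + X_i beta_X + C_i' beta_C + f(Z_i) + theta_i,

in one of five variants:

``naive``          no confounder-score term (ecological baseline);
``benchmark``      the latent confounders M entered directly (simulation only);
``complete_case``  in-sample areas only, score from the design stage through
                   the uncertainty model;
``eps_mar``        all areas: uncertainty model for the in-sample score,
                   Gaussian imputation model with ICAR spatial residual for
                   the out-of-sample score (missing-at-random);
``eps_mnar``       additionally a logistic selection model for the
                   missingness indicator, allowing missingness to depend on
                   the score itself.

The design stage is data here: its posterior mean and variance of the
in-sample score parameterise the uncertainty model
Z*^(0)_i ~ N(Zhat^(0)_i, sigma2hat_i) and are never updated (the two-stage
"cut").  Outcome, uncertainty, imputation and selection submodels are fitted
jointly, so information flows between them — in particular the outcome data
feed back into the imputed scores, but never into the design stage.

Sampling: Gamerman-style IWLS Metropolis-Hastings for the regression blocks
(near-Gibbs mixing for GLM coefficients), vectorised single-site random-walk
updates for theta and the latent scores, exact GMRF draws for the ICAR field,
and conjugate updates for variances.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .basis import Basis, make_basis
from .design_stage import DesignStageResult
from .inference import AdaptiveScale, ConvergenceReport, MCMCResult, MCMCSettings, run_mcmc
from .simulate import EcologicalDataset
from .spatial import SpatialDomain

__all__ = [
    "OutcomeModelSpec",
    "ImputationModelSpec",
    "MissingnessModelSpec",
    "HealthEffectResult",
    "fit_outcome_model",
    "percent_change",
]

VARIANTS = ("naive", "benchmark", "complete_case", "eps_mar", "eps_mnar")


@dataclass
class OutcomeModelSpec:
    """Outcome-model settings: functional form of the score term, priors.

    ``f_spec`` in {"linear", "quadratic", "spline"}; the basis is frozen from
    the in-sample score before fitting.  All regression coefficients carry
    N(0, 10) priors; the heterogeneity variance a weakly informative
    Inverse-Gamma(0.5, 0.0005) (the usual disease-mapping choice, letting the
    posterior track small heterogeneity).
    ``uncertainty_variance`` selects per-area or pooled design-stage score
    variances in the uncertainty model.
    """

    f_spec: str = "quadratic"
    f_df: int = 4  # spline degrees of freedom when f_spec == "spline"
    prior_var_beta: float = 10.0
    theta_prior: tuple = (0.5, 0.0005)  # Inverse-Gamma(shape, scale) on sigma2_theta
    uncertainty_variance: str = "per_area"  # or "pooled"
    benchmark_quadratic: bool = False  # add M1^2, M2^2 terms in the benchmark
    include_phi_outcome: bool = False  # optional ICAR residual in the outcome


@dataclass
class ImputationModelSpec:
    """Score-imputation model: Z_i ~ N(g0 + X g_X + s_q(C) + phi_i, s2_Z).

    ``s_q_spec`` chooses the covariate term ("spline" default, "linear", or
    "none"); ``include_X`` / ``include_phi`` drop the exposure term or the
    ICAR field (used for degenerate-model checks and sensitivity analyses).
    """

    s_q_spec: str = "spline"
    s_q_df: int = 4
    include_X: bool = True
    include_phi: bool = True
    prior_var_gamma: float = 10.0
    sigma2_phi_prior: tuple = (2.0, 1.0)  # Inverse-Gamma
    sigma2_Z_prior: tuple = (1.0, 0.1)  # Gamma(shape, rate) on the precision
    in_sample: str = "pinned"  # in-sample Z in this likelihood: pinned | latent


@dataclass
class MissingnessModelSpec:
    """Logistic selection model logit(pi) = a0 + X a_X + C'a_C + Z a_Z.

    ``a_Z_mode`` is "estimated" or ("fixed", value): the score coefficient is
    unidentifiable from data alone, so sensitivity analyses fix it.
    """

    a_Z_mode: object = "estimated"
    prior_var_a: float = 10.0

    def fixed_a_z(self):
        if isinstance(self.a_Z_mode, tuple) and self.a_Z_mode[0] == "fixed":
            val = float(self.a_Z_mode[1])
            if not np.isfinite(val):
                raise ValueError("fixed a_Z must be finite")
            return val
        if self.a_Z_mode == "estimated":
            return None
        raise ValueError(f"invalid a_Z_mode {self.a_Z_mode!r}")


@dataclass
class HealthEffectResult:
    variant: str
    beta_X_draws: np.ndarray
    beta_X_summary: dict
    beta_names: list[str]
    mcmc: MCMCResult
    f_basis: Basis | None = None
    Z_imputed: dict | None = None  # out-of-sample score posterior summaries
    Zstar0: dict | None = None  # in-sample latent score posterior summaries
    area_ids: list[str] = field(default_factory=list)

    @property
    def diagnostics(self) -> ConvergenceReport:
        return self.mcmc.report


def _poisson_loglik(Y, logE, eta):
    lam = np.exp(np.clip(logE + eta, -700, 700))
    return Y * eta - lam


class _IWLSBlock:
    """Gamerman (1997)-style MH update for a GLM coefficient block: propose
    from the Gaussian IWLS approximation of the full conditional and correct
    with the asymmetric acceptance ratio."""

    def __init__(self, prior_var: float):
        self.prior_var = prior_var

    def _approx(self, W, Y, logE, offset, beta):
        eta = W @ beta + offset
        lam = np.exp(np.clip(logE + eta, -700, 30))
        prec = W.T @ (lam[:, None] * W) + np.eye(W.shape[1]) / self.prior_var
        grad = W.T @ (Y - lam) - beta / self.prior_var
        L = np.linalg.cholesky(prec)
        mean = beta + np.linalg.solve(prec, grad)
        return mean, L, prec

    def update(self, W, Y, logE, offset, beta, rng):
        mean, L, prec = self._approx(W, Y, logE, offset, beta)
        z = rng.standard_normal(len(beta))
        prop = mean + np.linalg.solve(L.T, z)
        mean_r, L_r, prec_r = self._approx(W, Y, logE, offset, prop)

        def logq(x, m, Lc):
            d = x - m
            v = Lc.T @ d
            return np.log(np.diag(Lc)).sum() - 0.5 * v @ v

        ll_cur = _poisson_loglik(Y, logE, W @ beta + offset).sum()
        ll_prop = _poisson_loglik(Y, logE, W @ prop + offset).sum()
        lp_cur = -0.5 * beta @ beta / self.prior_var
        lp_prop = -0.5 * prop @ prop / self.prior_var
        logr = (ll_prop + lp_prop + logq(beta, mean_r, L_r)
                - ll_cur - lp_cur - logq(prop, mean, L))
        if np.log(rng.random()) < logr:
            return prop, True
        return beta, False


class _OutcomeModel:
    """Joint Gibbs model for one analysis-stage variant (see module doc)."""

    def __init__(
        self,
        *,
        Y,
        E,
        W_fixed,
        beta_names,
        f_basis,
        Zhat0,
        Zvar0,
        in_idx,
        out_idx,
        W_imp,
        Qn,
        ncomp,
        ell,
        W_miss,
        spec: OutcomeModelSpec,
        imp: ImputationModelSpec,
        miss: MissingnessModelSpec | None,
        mnar: bool,
    ):
        self.Y = Y
        self.logE = np.log(E)
        self.W = W_fixed
        self.beta_names = beta_names
        self.f = f_basis
        self.Zhat0 = Zhat0
        self.Zvar0 = Zvar0
        self.in_idx = in_idx
        self.out_idx = out_idx
        self.W_imp = W_imp
        self.Qn = Qn
        self.ncomp = ncomp
        self.ell = ell
        self.W_miss = W_miss
        self.spec = spec
        self.imp = imp
        self.miss = miss
        self.mnar = mnar
        self.N = len(Y)
        self.has_score = f_basis is not None
        self.has_imp = out_idx is not None and len(out_idx) > 0
        self.p_fix = W_fixed.shape[1]
        self.p_f = f_basis.n_cols if self.has_score else 0
        self.block = _IWLSBlock(spec.prior_var_beta)
        self.diagnostic_params = ("beta", "sigma2_theta")

    # -- assembly helpers ---------------------------------------------------
    def _zfull(self, state):
        z = np.zeros(self.N)
        z[self.in_idx] = state["Zstar0"]
        if self.has_imp:
            z[self.out_idx] = state["Z1"]
        return z

    def _z_pinned(self, state):
        """Score vector entering the imputation/selection likelihoods:
        in-sample values pinned at the design-stage posterior mean (or the
        latent Z*^(0) when the alternative reading is selected)."""
        z = np.zeros(self.N)
        if self.imp.in_sample == "pinned":
            z[self.in_idx] = self.Zhat0
        else:
            z[self.in_idx] = state["Zstar0"]
        if self.has_imp:
            z[self.out_idx] = state["Z1"]
        return z

    def _eta(self, state):
        eta = self.W @ state["beta"][: self.p_fix] + state["theta"]
        if self.has_score:
            eta = eta + state["F"] @ state["beta"][self.p_fix:]
        return eta

    # -- state --------------------------------------------------------------
    def init_state(self, rng) -> dict:
        beta = np.zeros(self.p_fix + self.p_f)
        beta[0] = np.log(np.maximum(self.Y.sum() / np.exp(self.logE).sum(), 1e-8))
        state = {
            "beta": beta,
            "theta": np.zeros(self.N),
            "sigma2_theta": 0.05,
            "_sc_theta": AdaptiveScale(self.N, init=0.1),
        }
        if self.has_score:
            state["Zstar0"] = self.Zhat0.copy()
            state["_sc_z0"] = AdaptiveScale(len(self.in_idx), init=0.2)
            if self.has_imp:
                state["Z1"] = np.full(len(self.out_idx), self.Zhat0.mean())
                state["_sc_z1"] = AdaptiveScale(len(self.out_idx), init=0.3)
                zp = self._z_pinned(state)
                g, *_ = np.linalg.lstsq(self.W_imp, zp, rcond=None)
                state["gamma"] = g
                state["phi"] = np.zeros(self.N)
                state["sigma2_phi"] = 0.5
                resid = zp - self.W_imp @ g
                state["sigma2_Z"] = max(float(resid.var()), 1e-3)
                if self.mnar:
                    a = np.zeros(self.W_miss.shape[1] + 1)  # last = a_Z
                    frac = np.clip(self.ell.mean(), 0.02, 0.98)
                    a[0] = np.log(frac / (1 - frac))
                    az = self.miss.fixed_a_z()
                    if az is not None:
                        a[-1] = az
                    state["a"] = a
                    state["_sc_a"] = AdaptiveScale(len(a), init=0.1)
            state["F"] = self.f.evaluate(self._zfull(state))
        return state

    # -- sweep --------------------------------------------------------------
    def sweep(self, state, rng, tune: bool) -> None:
        self._update_beta(state, rng)
        self._update_theta(state, rng, tune)
        self._interweave_beta_theta(state, rng)
        self._update_sigma2_theta(state, rng)
        if self.has_score:
            self._update_zstar0(state, rng, tune)
            if self.has_imp:
                self._update_z1(state, rng, tune)
                self._update_gamma(state, rng)
                if self.imp.include_phi:
                    self._update_phi(state, rng)
                    self._update_sigma2_phi(state, rng)
                self._update_sigma2_Z(state, rng)
                if self.mnar:
                    self._update_a(state, rng, tune)

    def _update_beta(self, state, rng) -> None:
        if self.has_score:
            Wfull = np.concatenate([self.W, state["F"]], axis=1)
        else:
            Wfull = self.W
        beta, _ = self.block.update(Wfull, self.Y, self.logE, state["theta"], state["beta"], rng)
        state["beta"] = beta

    def _update_theta(self, state, rng, tune) -> None:
        eta0 = self._eta(state) - state["theta"]
        th = state["theta"]
        sc = state["_sc_theta"].scale
        eps = sc * rng.standard_normal(self.N)
        thp = th + eps
        d = (_poisson_loglik(self.Y, self.logE, eta0 + thp)
             - _poisson_loglik(self.Y, self.logE, eta0 + th))
        d += -0.5 * (thp ** 2 - th ** 2) / state["sigma2_theta"]
        acc = np.log(rng.random(self.N)) < d
        th[acc] = thp[acc]
        if tune:
            state["_sc_theta"].update(acc)

    def _interweave_beta_theta(self, state, rng) -> None:
        # Translation interweaving: beta -> beta + delta, theta -> theta -
        # W delta leaves the Poisson likelihood invariant, and delta given
        # the invariance has a conjugate Gaussian conditional from the theta
        # and beta priors.  An exact Gibbs step along the otherwise slow
        # ridge between the regression block and the heterogeneity field.
        if self.has_score:
            Wfull = np.concatenate([self.W, state["F"]], axis=1)
        else:
            Wfull = self.W
        p = Wfull.shape[1]
        s2 = state["sigma2_theta"]
        pv = self.spec.prior_var_beta
        prec = Wfull.T @ Wfull / s2 + np.eye(p) / pv
        b = Wfull.T @ state["theta"] / s2 - state["beta"] / pv
        L = np.linalg.cholesky(prec)
        mean = np.linalg.solve(prec, b)
        delta = mean + np.linalg.solve(L.T, rng.standard_normal(p))
        state["beta"] = state["beta"] + delta
        state["theta"] = state["theta"] - Wfull @ delta

    def _update_sigma2_theta(self, state, rng) -> None:
        a0, b0 = self.spec.theta_prior
        sh = a0 + self.N / 2.0
        ra = b0 + 0.5 * (state["theta"] ** 2).sum()
        state["sigma2_theta"] = 1.0 / rng.gamma(sh, 1.0 / ra)
        self._interweave_theta_scale(state, rng)

    def _interweave_theta_scale(self, state, rng) -> None:
        # Ancillarity-sufficiency interweaving: with u = theta/sigma held
        # fixed, move log(sigma) jointly rescaling theta.  Breaks the
        # centered-parameterization funnel when heterogeneity is small.
        a0, b0 = self.spec.theta_prior
        sig = np.sqrt(state["sigma2_theta"])
        if sig <= 0:
            return
        u = state["theta"] / sig
        eta0 = self._eta(state) - state["theta"]
        ls = np.log(sig)

        def logtarget(ls_):
            s2 = np.exp(2 * ls_)
            ll = _poisson_loglik(self.Y, self.logE, eta0 + u * np.exp(ls_)).sum()
            # IG(a0, b0) on sigma2 plus the d(sigma2)/d(log sigma) Jacobian
            return ll - (a0 + 1) * np.log(s2) - b0 / s2 + 2 * ls_

        prop = ls + 0.3 * rng.standard_normal()
        if np.log(rng.random()) < logtarget(prop) - logtarget(ls):
            state["sigma2_theta"] = float(np.exp(2 * prop))
            state["theta"] = u * np.exp(prop)

    def _score_eta_delta(self, state, idx, z_new, z_old):
        bf = state["beta"][self.p_fix:]
        return (self.f.evaluate(z_new) - self.f.evaluate(z_old)) @ bf

    def _update_zstar0(self, state, rng, tune) -> None:
        idx = self.in_idx
        z = state["Zstar0"]
        eta = self._eta(state)
        eps = state["_sc_z0"].scale * rng.standard_normal(len(idx))
        zp = z + eps
        deta = self._score_eta_delta(state, idx, zp, z)
        d = (_poisson_loglik(self.Y[idx], self.logE[idx], eta[idx] + deta)
             - _poisson_loglik(self.Y[idx], self.logE[idx], eta[idx]))
        d += -0.5 * ((zp - self.Zhat0) ** 2 - (z - self.Zhat0) ** 2) / self.Zvar0
        if self.has_imp and self.imp.in_sample == "latent":
            mu = (self.W_imp @ state["gamma"] + state["phi"])[idx]
            d += -0.5 * ((zp - mu) ** 2 - (z - mu) ** 2) / state["sigma2_Z"]
        acc = np.log(rng.random(len(idx))) < d
        if acc.any():
            z[acc] = zp[acc]
            state["F"][idx[acc]] = self.f.evaluate(z[acc])
        if tune:
            state["_sc_z0"].update(acc)
        # Independence refresh from the uncertainty-model prior: the prior
        # and proposal densities cancel, leaving a pure likelihood ratio.
        # Breaks the slow coupling between the score field and the f(Z)
        # coefficients that a pure random walk exhibits.
        zp = self.Zhat0 + np.sqrt(self.Zvar0) * rng.standard_normal(len(idx))
        eta = self._eta(state)
        deta = self._score_eta_delta(state, idx, zp, z)
        d = (_poisson_loglik(self.Y[idx], self.logE[idx], eta[idx] + deta)
             - _poisson_loglik(self.Y[idx], self.logE[idx], eta[idx]))
        if self.has_imp and self.imp.in_sample == "latent":
            mu = (self.W_imp @ state["gamma"] + state["phi"])[idx]
            d += -0.5 * ((zp - mu) ** 2 - (z - mu) ** 2) / state["sigma2_Z"]
        acc = np.log(rng.random(len(idx))) < d
        if acc.any():
            z[acc] = zp[acc]
            state["F"][idx[acc]] = self.f.evaluate(z[acc])

    def _update_z1(self, state, rng, tune) -> None:
        idx = self.out_idx
        z = state["Z1"]
        eta = self._eta(state)
        mu = (self.W_imp @ state["gamma"] + state["phi"])[idx]
        eps = state["_sc_z1"].scale * rng.standard_normal(len(idx))
        zp = z + eps
        deta = self._score_eta_delta(state, idx, zp, z)
        d = (_poisson_loglik(self.Y[idx], self.logE[idx], eta[idx] + deta)
             - _poisson_loglik(self.Y[idx], self.logE[idx], eta[idx]))
        d += -0.5 * ((zp - mu) ** 2 - (z - mu) ** 2) / state["sigma2_Z"]
        if self.mnar:
            a = state["a"]
            lin0 = self.W_miss[idx] @ a[:-1]
            d += (self.ell[idx] * (lin0 + a[-1] * zp) - np.logaddexp(0, lin0 + a[-1] * zp))
            d -= (self.ell[idx] * (lin0 + a[-1] * z) - np.logaddexp(0, lin0 + a[-1] * z))
        acc = np.log(rng.random(len(idx))) < d
        if acc.any():
            z[acc] = zp[acc]
            state["F"][idx[acc]] = self.f.evaluate(z[acc])
        if tune:
            state["_sc_z1"].update(acc)

    def _update_gamma(self, state, rng) -> None:
        zres = self._z_pinned(state) - state["phi"]
        p = self.W_imp.shape[1]
        prec = self.W_imp.T @ self.W_imp / state["sigma2_Z"] + np.eye(p) / self.imp.prior_var_gamma
        b = self.W_imp.T @ zres / state["sigma2_Z"]
        L = np.linalg.cholesky(prec)
        mean = np.linalg.solve(prec, b)
        state["gamma"] = mean + np.linalg.solve(L.T, rng.standard_normal(p))

    def _update_phi(self, state, rng) -> None:
        # Exact GMRF draw: ICAR prior + Gaussian imputation likelihood.  The
        # joint precision Q/s2_phi + I/s2_Z shares Q's eigenbasis, so one
        # eigendecomposition (cached) replaces a per-sweep Cholesky.
        if not hasattr(self, "_Q_eig"):
            lam, V = np.linalg.eigh(self.Qn)
            self._Q_eig = (np.maximum(lam, 0.0), V)
        lam, V = self._Q_eig
        zres = self._z_pinned(state) - self.W_imp @ state["gamma"]
        d = lam / state["sigma2_phi"] + 1.0 / state["sigma2_Z"]
        b = V.T @ (zres / state["sigma2_Z"])
        phi = V @ (b / d + rng.standard_normal(self.N) / np.sqrt(d))
        shift = phi.mean()
        phi -= shift  # hard sum-to-zero; level moves into gamma_0
        state["phi"] = phi
        state["gamma"][0] += shift

    def _update_sigma2_phi(self, state, rng) -> None:
        a0, b0 = self.imp.sigma2_phi_prior
        quad = state["phi"] @ (self.Qn @ state["phi"])
        sh = a0 + (self.N - self.ncomp) / 2.0
        ra = b0 + 0.5 * quad
        state["sigma2_phi"] = 1.0 / rng.gamma(sh, 1.0 / ra)

    def _update_sigma2_Z(self, state, rng) -> None:
        a0, b0 = self.imp.sigma2_Z_prior
        resid = self._z_pinned(state) - self.W_imp @ state["gamma"] - state["phi"]
        sh = a0 + self.N / 2.0
        ra = b0 + 0.5 * (resid ** 2).sum()
        state["sigma2_Z"] = 1.0 / rng.gamma(sh, 1.0 / ra)

    def _update_a(self, state, rng, tune) -> None:
        a = state["a"]
        z = self._z_pinned(state)
        fixed_az = self.miss.fixed_a_z()
        sc = state["_sc_a"].scale
        acc = np.zeros(len(a))
        lin = self.W_miss @ a[:-1] + a[-1] * z

        def loglik(linpred):
            return (self.ell * linpred - np.logaddexp(0, linpred)).sum()

        ll = loglik(lin)
        for j in range(len(a)):
            if j == len(a) - 1 and fixed_az is not None:
                continue
            eps = sc[j] * rng.standard_normal()
            col = self.W_miss[:, j] if j < len(a) - 1 else z
            lin_new = lin + eps * col
            lp = -0.5 * ((a[j] + eps) ** 2 - a[j] ** 2) / self.miss.prior_var_a
            ll_new = loglik(lin_new)
            if np.log(rng.random()) < ll_new - ll + lp:
                a[j] += eps
                lin = lin_new
                ll = ll_new
                acc[j] = 1.0
        if tune:
            state["_sc_a"].update(acc)

    # -- monitoring ---------------------------------------------------------
    def monitor(self, state) -> dict:
        out = {"beta": state["beta"], "sigma2_theta": state["sigma2_theta"]}
        if self.has_score:
            out["Zstar0"] = state["Zstar0"]
            if self.has_imp:
                out["Z1"] = state["Z1"]
                out["gamma"] = state["gamma"]
                out["sigma2_Z"] = state["sigma2_Z"]
                out["sigma2_phi"] = state["sigma2_phi"]
                if self.imp.include_phi:
                    out["_phi_sum"] = float(state["phi"].sum())
                if self.mnar:
                    out["a"] = state["a"]
        return out


# ---------------------------------------------------------------------------
# Public API
# ---------------------------------------------------------------------------

def fit_outcome_model(
    eco: EcologicalDataset,
    design_result: DesignStageResult | None,
    domain: SpatialDomain,
    variant: str,
    outcome: OutcomeModelSpec | None = None,
    imputation: ImputationModelSpec | None = None,
    missingness: MissingnessModelSpec | None = None,
    mcmc: MCMCSettings | None = None,
) -> HealthEffectResult:
    """Fit one analysis-stage variant and summarise the exposure effect.

    ``design_result`` supplies (Zhat0, sigma2hat) for the EPS variants and is
    treated strictly as fixed data (no feedback to the design stage).
    """
    if variant not in VARIANTS:
        raise ValueError(f"variant must be one of {VARIANTS}")
    outcome = outcome or OutcomeModelSpec()
    imputation = imputation or ImputationModelSpec()
    mcmc = mcmc or MCMCSettings()

    needs_score = variant in ("complete_case", "eps_mar", "eps_mnar")
    if needs_score and design_result is None:
        raise ValueError(f"variant {variant!r} requires a design-stage result")
    if variant == "benchmark" and eco.M_true.size == 0:
        raise ValueError("benchmark variant requires the latent confounders M_true")
    mnar = variant == "eps_mnar"
    if mnar and missingness is None:
        missingness = MissingnessModelSpec()

    # --- assemble data for the requested variant --------------------------
    if variant == "complete_case":
        keep = design_result.in_sample_idx
    else:
        keep = np.arange(eco.n_areas)
    Y, E = eco.Y[keep], eco.E[keep]
    X = eco.X[keep]
    Cm = eco.C[keep].reshape(len(keep), -1)

    cols = [np.ones(len(keep)), X - X.mean()]
    names = ["beta0", "beta_X"]
    for q in range(Cm.shape[1]):
        cols.append(Cm[:, q] - Cm[:, q].mean())
        names.append(f"beta_C{q + 1}" if Cm.shape[1] > 1 else "beta_C")
    if variant == "benchmark":
        M = eco.M_true[keep]
        for k in range(M.shape[1]):
            cols.append(M[:, k] - M[:, k].mean())
            names.append(f"beta_M{k + 1}")
        if outcome.benchmark_quadratic:
            for k in (0, 1):
                sq = M[:, k] ** 2
                cols.append(sq - sq.mean())
                names.append(f"beta_M{k + 1}sq")
    W_fixed = np.column_stack(cols)

    f_basis = None
    Zhat0 = Zvar0 = None
    in_idx = out_idx = None
    W_imp = Qn = None
    ncomp = 0
    ell = None
    W_miss = None
    if needs_score:
        Zhat0 = design_result.Z0_mean.copy()
        if outcome.uncertainty_variance == "pooled":
            Zvar0 = np.full(len(Zhat0), design_result.Z0_var_pooled)
        else:
            Zvar0 = design_result.Z0_var.copy()
        Zvar0 = np.maximum(Zvar0, 1e-12)
        f_basis = make_basis(outcome.f_spec, Zhat0, df=outcome.f_df)
        if outcome.f_spec == "spline" and len(Zhat0) <= outcome.f_df:
            raise ValueError("fewer in-sample areas than spline degrees of freedom")
        if variant == "complete_case":
            in_idx = np.arange(len(keep))
            out_idx = np.array([], dtype=int)
        else:
            in_idx = design_result.in_sample_idx
            out_idx = np.setdiff1d(np.arange(eco.n_areas), in_idx)
            if len(out_idx) > 0:
                imp_cols = [np.ones(eco.n_areas)]
                if imputation.include_X:
                    imp_cols.append(X - X.mean())
                if imputation.s_q_spec != "none":
                    sq = make_basis(imputation.s_q_spec, Cm[:, 0], df=imputation.s_q_df)
                    imp_cols.append(sq.evaluate(Cm[:, 0]))
                    imp_cols.extend(Cm[:, q] for q in range(1, Cm.shape[1]))
                W_imp = np.column_stack(imp_cols)
                Qn = domain.laplacian()
                ncomp = domain.n_components()
        if mnar:
            ell = eco.ell[keep].astype(float)
            W_miss = np.column_stack([np.ones(len(keep)), X - X.mean(), Cm])

    model = _OutcomeModel(
        Y=Y, E=E, W_fixed=W_fixed, beta_names=names, f_basis=f_basis,
        Zhat0=Zhat0, Zvar0=Zvar0, in_idx=in_idx, out_idx=out_idx,
        W_imp=W_imp, Qn=Qn, ncomp=ncomp, ell=ell, W_miss=W_miss,
        spec=outcome, imp=imputation, miss=missingness, mnar=mnar,
    )
    result = run_mcmc(model, mcmc)

    beta = result.stacked("beta")
    bx = beta[:, names.index("beta_X")]
    lo, hi = np.quantile(bx, [0.025, 0.975])
    summary = {"mean": float(bx.mean()), "sd": float(bx.std(ddof=1)),
               "lower": float(lo), "upper": float(hi)}
    if not (lo <= summary["mean"] <= hi):  # pragma: no cover - defensive
        warnings.warn("posterior mean outside the credible interval", stacklevel=2)

    z_imp = zstar = None
    if needs_score:
        zs = result.stacked("Zstar0")
        zstar = {"mean": zs.mean(axis=0), "sd": zs.std(axis=0, ddof=1),
                 "area_ids": [eco.area_ids[i] for i in keep[in_idx]]}
        if model.has_imp:
            z1 = result.stacked("Z1")
            z_imp = {"mean": z1.mean(axis=0), "sd": z1.std(axis=0, ddof=1),
                     "area_ids": [eco.area_ids[i] for i in out_idx]}

    return HealthEffectResult(
        variant=variant,
        beta_X_draws=bx,
        beta_X_summary=summary,
        beta_names=names,
        mcmc=result,
        f_basis=f_basis,
        Z_imputed=z_imp,
        Zstar0=zstar,
        area_ids=[eco.area_ids[i] for i in keep],
    )


def percent_change(
    result: HealthEffectResult | np.ndarray,
    delta_x: float = 1.0,
    transform: str = "identity",
    baseline: float | None = None,
) -> dict:
    """Posterior percent change in risk for an exposure increment.

    Per draw: 100 (exp(beta_X * D) - 1), where D = delta_x on the identity
    scale, or D = sqrt(x0 + delta_x) - sqrt(x0) when the exposure entered the
    model on the square-root scale (``transform="sqrt_scale"``; ``baseline``
    x0 required).  Also returns P(risk > 1), the posterior probability of a
    positive effect (1/2 exactly when all draws are zero, by convention).
    """
    draws = result.beta_X_draws if isinstance(result, HealthEffectResult) else np.asarray(result)
    if transform == "identity":
        D = delta_x
    elif transform == "sqrt_scale":
        if baseline is None:
            raise ValueError("sqrt_scale transform requires a baseline exposure value")
        D = np.sqrt(baseline + delta_x) - np.sqrt(baseline)
    else:
        raise ValueError(f"unknown transform {transform!r}")
    pc = 100.0 * (np.exp(draws * D) - 1.0)
    pos = draws * D
    p_risk = float(np.mean(pos > 0) + 0.5 * np.mean(pos == 0))
    return {
        "mean": float(pc.mean()),
        "lower": float(np.quantile(pc, 0.025)),
        "upper": float(np.quantile(pc, 0.975)),
        "p_risk_gt_1": p_risk,
    }
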