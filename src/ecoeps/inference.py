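"""MCMC execution and convergence diagnostics shared by both model stages.

Models are plain objects implementing a small protocol:

``init_state(rng) -> dict``
    build the initial parameter state;
``sweep(state, rng, tune) -> None``
    one full Metropolis-within-Gibbs sweep updating the state in place
    (``tune=True`` during burn-in enables proposal-scale adaptation);
``monitor(state) -> dict``
    name -> scalar or 1-d array of the quantities to retain.

The driver runs independent chains seeded from a single ``numpy``
``SeedSequence``, applies burn-in and thinning, and reports the classic
Gelman-Rubin potential scale reduction factor together with arviz effective
sample sizes.  Convergence failure is reported, never raised.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "MCMCSettings",
    "ConvergenceReport",
    "MCMCResult",
    "AdaptiveScale",
    "gelman_rubin",
    "run_mcmc",
]


@dataclass
class MCMCSettings:
    """Chain management: counts, burn-in, thinning, seed.

    The ``paper`` profile mirrors the reference computation (2 chains of
    100,000 iterations, 80,000 burn-in, thinning 10); the ``fast`` profile is
    sized for desk-scale runs and tests.
    """

    n_chains: int = 2
    n_iter: int = 3000
    n_burnin: int = 1500
    thin: int = 1
    seed: int = 0
    rhat_threshold: float = 1.1

    def __post_init__(self) -> None:
        if not (0 <= self.n_burnin < self.n_iter):
            raise ValueError("require 0 <= n_burnin < n_iter")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")
        if self.n_chains < 1:
            raise ValueError("n_chains must be >= 1")

    @property
    def n_retained(self) -> int:
        """Retained draws per chain: ceil((n_iter - n_burnin) / thin)."""
        return (self.n_iter - self.n_burnin + self.thin - 1) // self.thin

    @classmethod
    def profile(cls, name: str, seed: int = 0) -> "MCMCSettings":
        if name == "fast":
            return cls(n_chains=2, n_iter=3000, n_burnin=1500, thin=1, seed=seed)
        if name == "paper":
            return cls(n_chains=2, n_iter=100_000, n_burnin=80_000, thin=10, seed=seed)
        raise ValueError(f"unknown MCMC profile {name!r}")


@dataclass
class ConvergenceReport:
    rhat: dict
    ess: dict
    converged: bool
    threshold: float = 1.1

    @property
    def monitored(self) -> list[str]:
        return list(self.rhat)

    def max_rhat(self) -> float:
        vals = [np.nanmax(np.atleast_1d(v)) for v in self.rhat.values()]
        return float(np.nanmax(vals)) if vals else np.nan


@dataclass
class MCMCResult:
    """Retained draws (name -> array of shape (chain, draw, *param)) plus the
    convergence report and the settings used."""

    draws: dict
    report: ConvergenceReport
    settings: MCMCSettings
    manifest: dict = field(default_factory=dict)

    def stacked(self, name: str) -> np.ndarray:
        """Draws pooled over chains: shape (chain*draw, *param)."""
        d = self.draws[name]
        return d.reshape(-1, *d.shape[2:])

    def summary(self, name: str, ci: float = 0.95) -> dict:
        x = self.stacked(name)
        lo, hi = (1 - ci) / 2, 1 - (1 - ci) / 2
        return {
            "mean": x.mean(axis=0),
            "sd": x.std(axis=0, ddof=1),
            "lower": np.quantile(x, lo, axis=0),
            "upper": np.quantile(x, hi, axis=0),
        }


class AdaptiveScale:
    """Robbins-Monro adaptation of per-parameter random-walk scales toward a
    target acceptance rate.  Adaptation happens only while tuning (burn-in),
    leaving the post-burn-in kernel fixed and valid."""

    def __init__(self, n: int, init: float = 0.1, target: float = 0.44):
        self.log_scale = np.full(n, np.log(init))
        self.target = target
        self.t = 0

    @property
    def scale(self) -> np.ndarray:
        return np.exp(self.log_scale)

    def update(self, accepted) -> None:
        self.t += 1
        step = self.t ** -0.6
        self.log_scale += step * (np.asarray(accepted, dtype=float) - self.target)
        np.clip(self.log_scale, -12.0, 6.0, out=self.log_scale)


def gelman_rubin(chains: np.ndarray) -> float | np.ndarray:
    """Classic Gelman-Rubin potential scale reduction factor.

    ``chains`` has shape (m, n) or (m, n, p): m chains of n draws of one (or
    p) scalar parameter(s).  Rhat = sqrt(((n-1)/n * W + B/n) / W) with W the
    mean within-chain variance and B = n * var(chain means) the between-chain
    variance.
    """
    chains = np.asarray(chains, dtype=float)
    scalar = chains.ndim == 2
    if scalar:
        chains = chains[:, :, None]
    m, n, _ = chains.shape
    if m < 2 or n < 2:
        out = np.full(chains.shape[2], np.nan)
        return float(out[0]) if scalar else out
    W = chains.var(axis=1, ddof=1).mean(axis=0)
    B = n * chains.mean(axis=1).var(axis=0, ddof=1)
    var_hat = (n - 1) / n * W + B / n
    with np.errstate(divide="ignore", invalid="ignore"):
        rh = np.sqrt(var_hat / W)
    rh = np.where(W == 0, 1.0, rh)
    return float(rh[0]) if scalar else rh


def run_mcmc(model, settings: MCMCSettings) -> MCMCResult:
    """Run independent chains of the model's Gibbs sweep and collect draws."""
    import arviz as az

    seeds = np.random.SeedSequence(settings.seed).spawn(settings.n_chains)
    all_draws: list[dict] = []
    for c in range(settings.n_chains):
        rng = np.random.default_rng(seeds[c])
        state = model.init_state(rng)
        kept: dict[str, list] = {}
        for it in range(settings.n_iter):
            model.sweep(state, rng, tune=it < settings.n_burnin)
            if it >= settings.n_burnin and (it - settings.n_burnin) % settings.thin == 0:
                for name, val in model.monitor(state).items():
                    kept.setdefault(name, []).append(np.copy(val))
        all_draws.append({k: np.asarray(v) for k, v in kept.items()})

    draws = {
        name: np.stack([d[name] for d in all_draws], axis=0)
        for name in all_draws[0]
    }

    # Rhat for every monitored parameter; the (slower) ESS computation is
    # restricted to the model's declared diagnostic set when present.  Names
    # starting with "_" are archive-only derived quantities (e.g. constraint
    # residuals) and are excluded from diagnostics entirely.
    diag = set(getattr(model, "diagnostic_params", draws.keys()))
    rhat: dict[str, np.ndarray] = {}
    ess: dict[str, np.ndarray] = {}
    for name, arr in draws.items():
        if name.startswith("_"):
            continue
        flat = arr.reshape(arr.shape[0], arr.shape[1], -1)
        rh = np.atleast_1d(gelman_rubin(flat))
        if name in diag:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                es = np.array(
                    [float(az.ess(flat[:, :, j])) for j in range(flat.shape[2])]
                )
        else:
            es = np.full(flat.shape[2], np.nan)
        if arr.ndim == 2:
            rhat[name] = rh[0]
            ess[name] = es[0]
        else:
            rhat[name] = rh.reshape(arr.shape[2:])
            ess[name] = es.reshape(arr.shape[2:])

    max_rh = np.nanmax([np.nanmax(np.atleast_1d(v)) for v in rhat.values()])
    report = ConvergenceReport(
        rhat=rhat,
        ess=ess,
        converged=bool(max_rh < settings.rhat_threshold),
        threshold=settings.rhat_threshold,
    )
    if not report.converged:
        warnings.warn(
            f"MCMC not converged: max Rhat = {max_rh:.3f} "
            f">= {settings.rhat_threshold}",
            stacklevel=2,
        )
    manifest = {
        "n_chains": settings.n_chains,
        "n_iter": settings.n_iter,
        "n_burnin": settings.n_burnin,
        "thin": settings.thin,
        "seed": settings.seed,
        "constraint_handling": "hard per-draw centering with intercept compensation",
    }
    return MCMCResult(draws=draws, report=report, settings=settings, manifest=manifest)
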