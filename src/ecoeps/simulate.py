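"""Synthetic data generator for the simulation study.

Emulates an area-referenced environmental-health study over a planar areal
domain.  Per replicate it produces:

* two independent exponential-covariance Gaussian processes, one driving the
  measured confounder C and one driving the third latent confounder;
* K = 5 correlated mixed-type latent area-level confounders M (three Gaussian,
  two Beta) linked through a Gaussian copula with a fixed correlation matrix;
* a continuous exposure X drawn conditionally on C and M;
* Poisson health counts Y with expected counts E ~ Uniform[15, 30], a log-risk
  linear in (X, C, M) plus exchangeable Gaussian heterogeneity theta (the
  nonlinear scenario adds quadratic terms in the first two confounders);
* individual-level survey records m_ij (20 subjects per area by default) whose
  marginals are centred on the area-level confounders and coupled through the
  same copula correlation;
* optionally, a binary missingness indicator per area (MAR: logistic in X, C;
  MNAR: additionally in the true confounder score Z_true), which deletes the
  individual-level records of missing areas while keeping Y, E, X, C
  everywhere.

Z_true, the exposure-model linear combination of M with coefficients
(0.2, 0.3, 0.4, 0.1, 0.1), is the generating analogue of the generalized
ecological propensity score and is carried in the dataset for evaluation.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .spatial import GPConfig, SpatialDomain, simulate_gp

__all__ = [
    "SimulationConfig",
    "EcologicalDataset",
    "IndividualDataset",
    "R_M_DEFAULT",
    "gaussian_copula_sample",
    "generate_ecological",
    "generate_individual",
    "apply_missingness",
    "generate_dataset",
]

#: Copula correlation between the five latent confounders (lower triangle as
#: printed: M1-M2 0.7; M1-M3 0.3, M2-M3 0.2; M1-M4 0.2, M2-M4 0.1, M3-M4 0.4;
#: M1-M5 0.2, M2-M5 0.1, M3-M5 0.4, M4-M5 0.5).
R_M_DEFAULT = np.array(
    [
        [1.0, 0.7, 0.3, 0.2, 0.2],
        [0.7, 1.0, 0.2, 0.1, 0.1],
        [0.3, 0.2, 1.0, 0.4, 0.4],
        [0.2, 0.1, 0.4, 1.0, 0.5],
        [0.2, 0.1, 0.4, 0.5, 1.0],
    ]
)

#: Exposure-model coefficients on (M1..M5); their M-linear combination is Z_true.
DELTA_M_TRUE = np.array([0.2, 0.3, 0.4, 0.1, 0.1])

#: Outcome-model coefficients on (M1..M5) in the linear scenario.
BETA_M_TRUE = np.array([0.2, 0.2, 0.2, 0.2, 0.2])

MAR_COEFS = {"intercept": -0.4, "X": 0.6, "C": 0.5}
MNAR_COEFS = {"intercept": -0.9, "X": 0.7, "C": 0.7, "Z": 1.0}


@dataclass
class SimulationConfig:
    """Study conditions for one simulation design/scenario.

    Defaults reproduce the reference simulation study: exposure effect 0.20,
    confounder coefficients 0.2 each (quadratic terms of 0.2 on M1, M2 in the
    nonlinear scenario), exposure residual sd 0.25, measured-confounder
    sd 0.5 around its spatial process, heterogeneity sd 0.05, and
    expected counts uniform on [15, 30].
    """

    design: str = "full"  # full | MAR | MNAR
    scenario: str = "linear"  # linear | nonlinear
    n_subjects_per_area: int = 20
    beta_X_true: float = 0.20
    beta_C_true: float = 0.20
    beta_M_true: np.ndarray = field(default_factory=lambda: BETA_M_TRUE.copy())
    quad_coef: float = 0.20  # coefficient on M1^2 and M2^2, nonlinear scenario
    delta_C_true: float = 0.30
    delta_M_true: np.ndarray = field(default_factory=lambda: DELTA_M_TRUE.copy())
    exposure_sd: float = 0.25
    c_sd: float = 0.5
    copula_corr: np.ndarray = field(default_factory=lambda: R_M_DEFAULT.copy())
    beta_shapes: tuple = ((12.0, 12.0), (6.0, 14.0))  # margins of M4, M5
    outcome_theta_sd: float = 0.05
    E_range: tuple = (15.0, 30.0)
    gp_effective_range: float = 20.0  # km, within the 15-25 km band
    gp_sigma2: float = 1.0
    missingness_coefs: dict | None = None
    indiv_sd: float = 1.0  # residual sd of continuous individual records
    n_replicates: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        if self.design not in {"full", "MAR", "MNAR"}:
            raise ValueError(f"unknown design {self.design!r}")
        if self.scenario not in {"linear", "nonlinear"}:
            raise ValueError(f"unknown scenario {self.scenario!r}")
        R = np.asarray(self.copula_corr, dtype=float)
        if not np.allclose(R, R.T) or not np.allclose(np.diag(R), 1.0):
            raise ValueError("copula_corr must be symmetric with unit diagonal")
        if np.linalg.eigvalsh(R).min() <= 0:
            raise ValueError("copula_corr must be positive definite")
        if not np.isfinite(self.beta_X_true):
            raise ValueError("beta_X_true must be finite")
        if self.E_range[0] < 1:
            raise ValueError("E_range lower bound must be >= 1")
        if self.missingness_coefs is None:
            self.missingness_coefs = (
                dict(MAR_COEFS) if self.design == "MAR" else dict(MNAR_COEFS)
            )
        needed = {"intercept", "X", "C"} | ({"Z"} if self.design == "MNAR" else set())
        if self.design != "full" and not needed.issubset(self.missingness_coefs):
            raise ValueError(f"missingness_coefs must contain {sorted(needed)}")

    def gp_config(self) -> GPConfig:
        return GPConfig.from_effective_range(self.gp_effective_range, self.gp_sigma2)


@dataclass
class EcologicalDataset:
    """Per-area outcome, exposure, covariates and the latent truth."""

    area_ids: list[str]
    Y: np.ndarray  # observed counts
    E: np.ndarray  # expected counts
    X: np.ndarray  # continuous exposure
    C: np.ndarray  # measured confounder
    M_true: np.ndarray  # (N, 5) latent confounders
    Z_true: np.ndarray  # exposure-model linear combination of M_true
    theta_true: np.ndarray
    ell: np.ndarray  # 1 = individual-level data missing in the area

    @property
    def n_areas(self) -> int:
        return len(self.area_ids)

    def validate(self) -> None:
        if np.any(self.Y < 0) or not np.issubdtype(self.Y.dtype, np.integer):
            raise ValueError("Y must be nonnegative integers")
        if np.any(self.E <= 0):
            raise ValueError("E must be positive")
        if not set(np.unique(self.ell)).issubset({0, 1}):
            raise ValueError("ell must be binary")

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "area_id": self.area_ids,
                "Y": self.Y,
                "E": self.E,
                "X": self.X,
                "C": self.C,
            }
        )
        for k in range(self.M_true.shape[1]):
            df[f"M{k + 1}"] = self.M_true[:, k]
        df["Z_true"] = self.Z_true
        df["theta"] = self.theta_true
        df["ell"] = self.ell
        return df

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "EcologicalDataset":
        mcols = sorted(c for c in df.columns if c.startswith("M") and c[1:].isdigit())
        return cls(
            area_ids=df["area_id"].astype(str).tolist(),
            Y=df["Y"].to_numpy(dtype=int),
            E=df["E"].to_numpy(dtype=float),
            X=df["X"].to_numpy(dtype=float),
            C=df["C"].to_numpy(dtype=float),
            M_true=df[mcols].to_numpy(dtype=float) if mcols else np.empty((len(df), 0)),
            Z_true=df.get("Z_true", pd.Series(np.nan, index=df.index)).to_numpy(float),
            theta_true=df.get("theta", pd.Series(np.nan, index=df.index)).to_numpy(float),
            ell=df.get("ell", pd.Series(0, index=df.index)).to_numpy(int),
        )


@dataclass
class IndividualDataset:
    """Survey records keyed to areas: columns m1..mK plus type tags."""

    records: pd.DataFrame  # columns: area_id, subject_id, m1..mK
    types: list[str]  # per-variable tags: "continuous" | "binary"

    @property
    def n_vars(self) -> int:
        return len(self.types)

    def validate(self, domain: SpatialDomain | None = None) -> None:
        if domain is not None:
            known = set(domain.area_ids)
            if not set(self.records["area_id"].astype(str)).issubset(known):
                raise ValueError("individual record references unknown area_id")
        for k, t in enumerate(self.types):
            if t == "binary":
                vals = set(self.records[f"m{k + 1}"].unique())
                if not vals.issubset({0, 1}):
                    raise ValueError(f"binary variable m{k + 1} has values {vals}")

    def by_area(self, area_ids: list[str]) -> list[np.ndarray]:
        """Per-area record matrices (n_i, K) in the order of ``area_ids``."""
        cols = [f"m{k + 1}" for k in range(self.n_vars)]
        grouped = {aid: g[cols].to_numpy(float) for aid, g in self.records.groupby("area_id")}
        return [grouped.get(aid, np.empty((0, self.n_vars))) for aid in area_ids]


# ---------------------------------------------------------------------------
# Copula sampling
# ---------------------------------------------------------------------------

def gaussian_copula_sample(
    corr: np.ndarray,
    marginals: list[dict],
    n: int,
    seed: int | np.random.Generator,
) -> np.ndarray:
    """Draw ``n`` rows from a Gaussian copula with the given marginals.

    Latent draws Z ~ N(0, corr) are pushed through the standard normal cdf to
    uniforms, then through each marginal's inverse cdf.  Supported marginal
    specs (``family`` key): ``normal`` (loc, scale; either may be a length-n
    array), ``beta`` (a, b), ``bernoulli`` (p, scalar or length-n; the uniform
    is thresholded at 1 - p so the success probability is exactly p).
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    corr = np.asarray(corr, dtype=float)
    K = corr.shape[0]
    if len(marginals) != K:
        raise ValueError("one marginal spec per copula dimension is required")
    try:
        L = np.linalg.cholesky(corr)
    except np.linalg.LinAlgError as exc:
        raise ValueError("copula correlation matrix is not positive definite") from exc
    z = rng.standard_normal((n, K)) @ L.T
    u = stats.norm.cdf(z)
    out = np.empty((n, K))
    for k, spec in enumerate(marginals):
        fam = spec["family"]
        if fam == "normal":
            out[:, k] = spec["loc"] + spec["scale"] * z[:, k]
        elif fam == "beta":
            out[:, k] = stats.beta.ppf(u[:, k], spec["a"], spec["b"])
        elif fam == "bernoulli":
            out[:, k] = (u[:, k] > 1.0 - np.asarray(spec["p"])).astype(float)
        else:
            raise ValueError(f"unsupported marginal family {fam!r}")
    return out


# ---------------------------------------------------------------------------
# Ecological-scale generation
# ---------------------------------------------------------------------------

def generate_ecological(
    domain: SpatialDomain,
    config: SimulationConfig,
    seed: int | np.random.Generator,
) -> EcologicalDataset:
    """Generate the full ecological dataset for one replicate.

    Steps: two independent GP draws zeta1, zeta2; C ~ N(zeta1, c_var); the
    five latent confounders from the copula (M3 centred on zeta2); exposure
    X ~ N(0.3 C + M' delta_M, exposure_sd^2); E ~ U(E_range);
    theta ~ N(0, outcome_theta_sd^2); Y ~ Poisson(E exp(log-risk)).
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    N = domain.n_areas
    gp = config.gp_config()
    zeta1 = simulate_gp(domain, gp, rng)
    zeta2 = simulate_gp(domain, gp, rng)

    C = rng.normal(zeta1, config.c_sd)

    (a4, b4), (a5, b5) = config.beta_shapes
    marginals = [
        {"family": "normal", "loc": 0.0, "scale": 1.0},
        {"family": "normal", "loc": 0.0, "scale": 1.0},
        {"family": "normal", "loc": zeta2, "scale": 1.0},
        {"family": "beta", "a": a4, "b": b4},
        {"family": "beta", "a": a5, "b": b5},
    ]
    M = gaussian_copula_sample(config.copula_corr, marginals, N, rng)

    X = rng.normal(config.delta_C_true * C + M @ config.delta_M_true, config.exposure_sd)
    Z_true = M @ config.delta_M_true
    theta = rng.normal(0.0, config.outcome_theta_sd, N)
    E = rng.uniform(config.E_range[0], config.E_range[1], N)

    log_risk = config.beta_X_true * X + config.beta_C_true * C + M @ config.beta_M_true + theta
    if config.scenario == "nonlinear":
        log_risk = log_risk + config.quad_coef * (M[:, 0] ** 2 + M[:, 1] ** 2)
    Y = rng.poisson(E * np.exp(log_risk))

    eco = EcologicalDataset(
        area_ids=list(domain.area_ids),
        Y=Y.astype(int),
        E=E,
        X=X,
        C=C,
        M_true=M,
        Z_true=Z_true,
        theta_true=theta,
        ell=np.zeros(N, dtype=int),
    )
    eco.validate()
    return eco


def generate_individual(
    domain: SpatialDomain,
    eco: EcologicalDataset,
    config: SimulationConfig,
    seed: int | np.random.Generator,
) -> IndividualDataset:
    """Generate the per-area survey records.

    Each subject's five measurements come from one K-dimensional Gaussian
    copula draw with the same correlation used for the area-level confounders;
    marginals are N(M_ik, 1) for the three continuous variables and
    Bernoulli(M_ik) for the two generated from Beta area-level values.
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    J = config.n_subjects_per_area
    N = eco.n_areas
    if eco.n_areas != domain.n_areas:
        raise ValueError("ecological dataset does not match the domain")
    # One copula draw per subject; areas vectorised by repeating M rows.
    Mrep = np.repeat(eco.M_true, J, axis=0)
    marginals = [
        {"family": "normal", "loc": Mrep[:, 0], "scale": config.indiv_sd},
        {"family": "normal", "loc": Mrep[:, 1], "scale": config.indiv_sd},
        {"family": "normal", "loc": Mrep[:, 2], "scale": config.indiv_sd},
        {"family": "bernoulli", "p": Mrep[:, 3]},
        {"family": "bernoulli", "p": Mrep[:, 4]},
    ]
    m = gaussian_copula_sample(config.copula_corr, marginals, N * J, rng)
    df = pd.DataFrame(m, columns=[f"m{k + 1}" for k in range(5)])
    df.insert(0, "subject_id", np.tile(np.arange(J), N))
    df.insert(0, "area_id", np.repeat(eco.area_ids, J))
    indiv = IndividualDataset(records=df, types=["continuous"] * 3 + ["binary"] * 2)
    indiv.validate(domain)
    return indiv


def missingness_probability(
    eco: EcologicalDataset, config: SimulationConfig
) -> np.ndarray:
    """Plug-in logistic probability that an area's survey data are missing."""
    co = config.missingness_coefs
    eta = co["intercept"] + co["X"] * eco.X + co["C"] * eco.C
    if config.design == "MNAR":
        eta = eta + co["Z"] * eco.Z_true
    return 1.0 / (1.0 + np.exp(-eta))


def apply_missingness(
    eco: EcologicalDataset,
    indiv: IndividualDataset,
    config: SimulationConfig,
    seed: int | np.random.Generator,
) -> tuple[EcologicalDataset, IndividualDataset]:
    """Draw the missingness indicator and delete survey records accordingly.

    Ecological Y, E, X, C are retained everywhere; only the individual-level
    confounder information disappears where ell = 1.  Under design "full" the
    inputs are returned unchanged with a warning.
    """
    if config.design == "full":
        warnings.warn("apply_missingness is a no-op under design='full'", stacklevel=2)
        return eco, indiv
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    p = missingness_probability(eco, config)
    ell = rng.binomial(1, p)
    eco_out = dataclasses.replace(eco, ell=ell.astype(int))
    missing_ids = {aid for aid, m in zip(eco.area_ids, ell) if m == 1}
    kept = indiv.records[~indiv.records["area_id"].isin(missing_ids)].reset_index(drop=True)
    return eco_out, IndividualDataset(records=kept, types=list(indiv.types))


def generate_dataset(
    domain: SpatialDomain,
    config: SimulationConfig,
    seed: int | np.random.Generator,
) -> tuple[EcologicalDataset, IndividualDataset]:
    """Generate one complete replicate: ecological + individual data, with
    missingness applied when the design requests it."""
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    eco = generate_ecological(domain, config, rng)
    indiv = generate_individual(domain, eco, config, rng)
    if config.design != "full":
        eco, indiv = apply_missingness(eco, indiv, config, rng)
    return eco, indiv


# ---------------------------------------------------------------------------
# Serialization
# ---------------------------------------------------------------------------

def write_replicate(
    out_dir: str | Path,
    replicate: int,
    eco: EcologicalDataset,
    indiv: IndividualDataset,
    config: SimulationConfig,
) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    eco.to_frame().to_csv(out / f"eco_{replicate:03d}.csv", index=False)
    indiv.records.to_csv(out / f"indiv_{replicate:03d}.csv", index=False)
    side = {
        k: (v.tolist() if isinstance(v, np.ndarray) else v)
        for k, v in dataclasses.asdict(config).items()
    }
    side["replicate"] = replicate
    with open(out / f"config_{replicate:03d}.json", "w") as fh:
        json.dump(side, fh, indent=2)
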