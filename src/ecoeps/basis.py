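"""Deterministic regression bases for flexible functional forms.

Used for f(Z), the propensity-score term in the outcome model, and s_q(C),
the covariate term in the imputation model.  A basis is frozen from reference
values (location/scale/knots) before fitting, so that evaluating it at new
points during MCMC is deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["Basis", "make_basis"]


@dataclass
class Basis:
    kind: str  # "linear" | "quadratic" | "spline"
    center: float = 0.0
    scale: float = 1.0
    knots: np.ndarray | None = None  # all knots incl. boundaries, for splines

    @property
    def n_cols(self) -> int:
        if self.kind == "linear":
            return 1
        if self.kind == "quadratic":
            return 2
        return len(self.knots) - 1

    def evaluate(self, z: np.ndarray) -> np.ndarray:
        z = np.asarray(z, dtype=float)
        t = (z - self.center) / self.scale
        if self.kind == "linear":
            return t[:, None]
        if self.kind == "quadratic":
            return np.column_stack([t, t * t])
        if self.kind == "spline":
            return _natural_cubic(t, (self.knots - self.center) / self.scale)
        raise ValueError(f"unknown basis kind {self.kind!r}")


def _natural_cubic(x: np.ndarray, knots: np.ndarray) -> np.ndarray:
    """Natural cubic spline basis (linear beyond the boundary knots).

    ``knots`` are sorted and include the boundaries; returns len(knots) - 1
    columns: x itself plus the standard truncated-power differences.
    """
    k = np.sort(np.asarray(knots, dtype=float))
    K = len(k)
    if K < 3:
        raise ValueError("natural cubic spline needs at least 3 knots")

    def d(j: int) -> np.ndarray:
        num = np.maximum(x - k[j], 0.0) ** 3 - np.maximum(x - k[K - 1], 0.0) ** 3
        return num / (k[K - 1] - k[j])

    cols = [x]
    dlast = d(K - 2)
    for j in range(K - 2):
        cols.append(d(j) - dlast)
    return np.column_stack(cols)


def make_basis(kind: str, reference: np.ndarray, df: int = 4) -> Basis:
    """Freeze a basis from reference values (e.g. the in-sample score).

    ``kind`` is "linear", "quadratic", or "spline"; for splines, ``df``
    columns are produced using df - 1 interior knots at equally spaced
    quantiles plus the 1st/99th-percentile boundaries.
    """
    ref = np.asarray(reference, dtype=float)
    center, scale = float(ref.mean()), float(ref.std() + 1e-12)
    if kind in ("linear", "quadratic"):
        return Basis(kind, center, scale)
    if kind == "spline":
        if len(ref) <= df + 1:
            raise ValueError("fewer reference points than spline degrees of freedom")
        qs = np.linspace(0, 1, df + 1)[1:-1]
        interior = np.quantile(ref, qs)
        bounds = np.quantile(ref, [0.01, 0.99])
        knots = np.unique(np.concatenate([[bounds[0]], interior, [bounds[1]]]))
        if len(knots) < 3:
            raise ValueError("degenerate reference distribution for spline basis")
        return Basis("spline", center, scale, knots=knots)
    raise ValueError(f"unknown basis kind {kind!r}")
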