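"""Areal geography: centroids, distances, distance-based neighbourhoods, and
spatially correlated Gaussian-process simulation.

The methods in this package operate on a collection of non-overlapping areal
units.  All that is needed downstream is (i) a pairwise centroid distance
matrix, (ii) a symmetric neighbour structure in which every area has at least
one neighbour, and (iii) draws of zero-mean Gaussian processes with an
exponential covariance over those distances.  A regular lattice stands in for
a real administrative geography by default; a centroid table can be supplied
for real applications.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

__all__ = [
    "SpatialDomain",
    "GPConfig",
    "build_domain",
    "build_lattice",
    "build_from_centroids",
    "simulate_gp",
    "write_neighbors",
    "read_neighbors",
]


@dataclass
class SpatialDomain:
    """Areal units with centroid distances and a symmetric neighbour graph.

    Attributes
    ----------
    area_ids : list of str
        Stable identifiers, one per area.
    centroids : (N, 2) ndarray
        Planar centroid coordinates in km.
    dist : (N, N) ndarray
        Symmetric centroid distance matrix in km, zero diagonal.
    neighbors : list of ndarray
        Per-area index arrays of neighbouring areas (symmetric relation).
    """

    area_ids: list[str]
    centroids: np.ndarray
    dist: np.ndarray
    neighbors: list[np.ndarray]
    cutoff: float = field(default=np.nan)

    @property
    def n_areas(self) -> int:
        return len(self.area_ids)

    @property
    def n_neighbors(self) -> np.ndarray:
        return np.array([len(nb) for nb in self.neighbors])

    def adjacency(self) -> np.ndarray:
        """Dense symmetric 0/1 adjacency matrix."""
        A = np.zeros((self.n_areas, self.n_areas))
        for i, nb in enumerate(self.neighbors):
            A[i, nb] = 1.0
        return A

    def laplacian(self) -> np.ndarray:
        """Graph Laplacian Q = D - A of the neighbour graph (the improper
        precision of an intrinsic CAR field up to a variance factor)."""
        A = self.adjacency()
        return np.diag(A.sum(axis=1)) - A

    def graph(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(range(self.n_areas))
        for i, nb in enumerate(self.neighbors):
            g.add_edges_from((i, int(s)) for s in nb)
        return g

    def n_components(self) -> int:
        return nx.number_connected_components(self.graph())

    def component_labels(self) -> np.ndarray:
        labels = np.empty(self.n_areas, dtype=int)
        for c, comp in enumerate(nx.connected_components(self.graph())):
            labels[list(comp)] = c
        return labels

    def coloring(self) -> list[np.ndarray]:
        """Greedy proper colouring of the neighbour graph; areas within one
        colour class are mutually non-adjacent and can be updated jointly in
        single-site MCMC schemes."""
        colors = nx.greedy_color(self.graph(), strategy="largest_first")
        n_col = max(colors.values()) + 1
        return [
            np.array(sorted(i for i, c in colors.items() if c == col), dtype=int)
            for col in range(n_col)
        ]

    def subdomain(self, mask: np.ndarray) -> tuple["SpatialDomain", np.ndarray]:
        """Restrict to the areas where ``mask`` is True, rebuilding the
        neighbour sets from distances with the same cutoff/expansion rule.

        Returns the restricted domain and the original indices it retains.
        """
        idx = np.flatnonzero(np.asarray(mask, dtype=bool))
        if idx.size == 0:
            raise ValueError("subdomain mask selects no areas")
        d = self.dist[np.ix_(idx, idx)]
        cut = self.cutoff if np.isfinite(self.cutoff) else _default_cutoff(d, 4)
        nbrs = _neighbors_from_distances(d, cut)
        sub = SpatialDomain(
            area_ids=[self.area_ids[i] for i in idx],
            centroids=self.centroids[idx],
            dist=d,
            neighbors=nbrs,
            cutoff=cut,
        )
        return sub, idx

    def validate(self) -> None:
        N = self.n_areas
        if self.dist.shape != (N, N):
            raise ValueError("distance matrix shape mismatch")
        if not np.allclose(self.dist, self.dist.T):
            raise ValueError("distance matrix must be symmetric")
        if np.any(np.diag(self.dist) != 0) or np.any(self.dist < 0):
            raise ValueError("distances must be nonnegative with zero diagonal")
        for i, nb in enumerate(self.neighbors):
            if len(nb) == 0:
                raise ValueError(f"area {i} has no neighbor")
            for s in nb:
                if i not in self.neighbors[int(s)]:
                    raise ValueError("neighbour relation is not symmetric")


@dataclass
class GPConfig:
    """Exponential-covariance Gaussian process: sigma^2 * exp(-psi * d).

    ``effective_range`` is the distance at which correlation drops to 0.05,
    i.e. -log(0.05) / psi (km).
    """

    sigma2: float = 1.0
    psi: float = -np.log(0.05) / 20.0  # 20 km effective range
    jitter: float = 1e-8

    def __post_init__(self) -> None:
        if self.sigma2 <= 0 or self.psi <= 0:
            raise ValueError("sigma2 and psi must be positive")

    @property
    def effective_range(self) -> float:
        return -np.log(0.05) / self.psi

    @classmethod
    def from_effective_range(cls, range_km: float, sigma2: float = 1.0) -> "GPConfig":
        return cls(sigma2=sigma2, psi=-np.log(0.05) / range_km)

    def covariance(self, dist: np.ndarray) -> np.ndarray:
        return self.sigma2 * np.exp(-self.psi * dist)


def _neighbors_from_distances(dist: np.ndarray, cutoff: float) -> list[np.ndarray]:
    """Distance-cutoff neighbour sets, auto-expanded per area until nonempty
    and then symmetrised (so every area ends up with >= 1 neighbour)."""
    N = dist.shape[0]
    if N < 2:
        raise ValueError("at least two areas are required to build neighbours")
    adj = (dist <= cutoff) & ~np.eye(N, dtype=bool)
    off = dist + np.where(np.eye(N, dtype=bool), np.inf, 0.0)
    for i in range(N):
        if not adj[i].any():
            s = int(np.argmin(off[i]))
            adj[i, s] = adj[s, i] = True
    adj |= adj.T
    return [np.flatnonzero(adj[i]) for i in range(N)]


def _default_cutoff(dist: np.ndarray, min_neighbors: int) -> float:
    """Smallest radius giving every area at least ``min_neighbors`` neighbours."""
    N = dist.shape[0]
    k = min(min_neighbors, N - 1)
    off = dist + np.where(np.eye(N, dtype=bool), np.inf, 0.0)
    kth = np.sort(off, axis=1)[:, k - 1]
    return float(kth.max())


def build_lattice(
    nx_: int,
    ny: int,
    spacing: float = 1.5,
    cutoff: float | None = None,
    min_neighbors: int = 4,
) -> SpatialDomain:
    """Regular ``nx_`` x ``ny`` lattice of areas with centroid spacing in km.

    The default 1.5 km spacing makes a 25 x 25 lattice span roughly 0-51 km,
    comparable to an urban ward geography.
    """
    if nx_ < 1 or ny < 1:
        raise ValueError("lattice dimensions must be positive")
    if nx_ * ny < 2:
        raise ValueError("a single area has no possible neighbour")
    gx, gy = np.meshgrid(np.arange(nx_), np.arange(ny), indexing="ij")
    cent = np.column_stack([gx.ravel(), gy.ravel()]).astype(float) * spacing
    ids = [f"a{i:04d}" for i in range(len(cent))]
    return _finalise(ids, cent, cutoff, min_neighbors)


def build_from_centroids(
    table: pd.DataFrame | str | Path,
    cutoff: float | None = None,
    min_neighbors: int = 4,
) -> SpatialDomain:
    """Build a domain from a delimited table with columns (area_id, x, y),
    coordinates in km."""
    if not isinstance(table, pd.DataFrame):
        table = pd.read_csv(table, sep=None, engine="python")
    required = {"area_id", "x", "y"}
    if not required.issubset(table.columns):
        raise ValueError(f"centroid table needs columns {sorted(required)}")
    if len(table) == 0:
        raise ValueError("empty centroid table")
    ids = table["area_id"].astype(str).tolist()
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate area ids in centroid table")
    cent = table[["x", "y"]].to_numpy(dtype=float)
    if not np.all(np.isfinite(cent)):
        raise ValueError("non-finite coordinates in centroid table")
    if len(ids) < 2:
        raise ValueError("a single area has no possible neighbour")
    return _finalise(ids, cent, cutoff, min_neighbors)


def _finalise(
    ids: list[str], cent: np.ndarray, cutoff: float | None, min_neighbors: int
) -> SpatialDomain:
    dist = squareform(pdist(cent))
    cut = _default_cutoff(dist, min_neighbors) if cutoff is None else float(cutoff)
    dom = SpatialDomain(ids, cent, dist, _neighbors_from_distances(dist, cut), cut)
    dom.validate()
    return dom


def build_domain(mode: str, **params) -> SpatialDomain:
    """Dispatch constructor: ``mode`` is ``lattice`` or ``centroid_table``."""
    if mode == "lattice":
        return build_lattice(**params)
    if mode == "centroid_table":
        return build_from_centroids(**params)
    raise ValueError(f"unknown domain mode {mode!r}")


def simulate_gp(
    domain: SpatialDomain, config: GPConfig, seed: int | np.random.Generator
) -> np.ndarray:
    """One draw of a zero-mean Gaussian process with covariance
    sigma^2 exp(-psi d) over the domain's centroid distances.

    A small diagonal jitter (config.jitter * sigma2) stabilises the Cholesky
    factorisation; failure even with jitter is reported as LinAlgError.
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    cov = config.covariance(domain.dist)
    cov[np.diag_indices_from(cov)] += config.jitter * config.sigma2
    try:
        L = np.linalg.cholesky(cov)
    except np.linalg.LinAlgError as exc:  # pragma: no cover - defensive
        raise np.linalg.LinAlgError(
            "GP covariance not positive definite even after jitter"
        ) from exc
    return L @ rng.standard_normal(domain.n_areas)


def write_neighbors(domain: SpatialDomain, path: str | Path) -> None:
    """Export the symmetric adjacency as 'i s' pairs, one per line, 1-based."""
    with open(path, "w") as fh:
        for i, nb in enumerate(domain.neighbors):
            for s in nb:
                fh.write(f"{i + 1} {int(s) + 1}\n")


def read_neighbors(path: str | Path, n_areas: int) -> list[np.ndarray]:
    adj = [set() for _ in range(n_areas)]
    with open(path) as fh:
        for line in fh:
            if not line.strip():
                continue
            i, s = (int(t) - 1 for t in line.split())
            adj[i].add(s)
            adj[s].add(i)
    return [np.array(sorted(a), dtype=int) for a in adj]
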