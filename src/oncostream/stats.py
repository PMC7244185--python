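"""Order parameters and spatial statistics for flock/stream/scatter states.

* polarization ψ — norm of the mean heading: 1 for a flock, ~0 for a
  balanced two-way stream or disorder.
* nematic polarization γ (2D) — modulus of the mean double-angle phasor,
  insensitive to the sign of each heading: ~1 for flocks AND streams.
* nematic order J (any d) — scalar order parameter from the second-moment
  matrix Q = <ω⊗ω>: J = (d λ_max − 1)/(d − 1), with the dominant
  eigenvector as the nematic mean direction (defined up to sign).
  In 2D, J coincides with γ.
* cluster statistics — connected components of the "distance ≤ R" graph
  in the periodic box, summarised by the size-weighted mean cluster size
  Σ_k |C_k|²/N (the expected size of the cluster containing a random cell).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components
from scipy.spatial import cKDTree

from .model import CellConfiguration, ModelParams, total_potential

DEFAULT_CLUSTER_RADIUS = 10.0  # μm


@dataclass
class OrderStats:
    """Order parameters of one configuration at one time point."""

    psi: float
    gamma: float | None  # 2D only
    J: float
    nematic_direction: np.ndarray
    mean_cluster_size: float | None = None
    total_potential: float | None = None
    time: float = 0.0


@dataclass
class ClusterPartition:
    labels: np.ndarray  # cluster id per cell
    sizes: np.ndarray  # cells per cluster
    R: float

    @property
    def n_clusters(self) -> int:
        return len(self.sizes)


def polarization(orientations) -> float:
    """ψ = |mean of the unit headings|."""
    w = np.atleast_2d(np.asarray(orientations, dtype=float))
    if w.shape[0] == 0:
        raise ValueError("polarization of an empty set is undefined")
    return float(np.linalg.norm(w.mean(axis=0)))


def nematic_polarization_2d(orientations) -> float:
    """γ = sqrt(<cos 2θ>² + <sin 2θ>²) for planar headings.

    Invariant under ω_i → −ω_i; equals 1 iff all headings share an axis.
    """
    w = np.atleast_2d(np.asarray(orientations, dtype=float))
    if w.shape[1] != 2:
        raise ValueError("nematic_polarization_2d requires d=2; use nematic_order")
    theta = np.arctan2(w[:, 1], w[:, 0])
    return float(np.hypot(np.cos(2 * theta).mean(), np.sin(2 * theta).mean()))


def nematic_order(orientations, d: int | None = None):
    """Scalar nematic order J and the nematic mean direction.

    Builds M = (1/N) Σ ω_i⊗ω_i and returns
    J = (d λ_max − 1)/(d − 1) together with the dominant eigenvector,
    its sign fixed so the first nonzero component is positive.
    """
    w = np.atleast_2d(np.asarray(orientations, dtype=float))
    if w.shape[0] == 0:
        raise ValueError("nematic_order of an empty set is undefined")
    dim = d if d is not None else w.shape[1]
    M = (w.T @ w) / w.shape[0]
    evals, evecs = np.linalg.eigh(M)
    lam = evals[-1]
    v = evecs[:, -1]
    nz = np.nonzero(np.abs(v) > 1e-12)[0]
    if len(nz) and v[nz[0]] < 0:
        v = -v
    J = (dim * lam - 1.0) / (dim - 1.0)
    return float(J), v


def color_by_nematic(orientations) -> np.ndarray:
    """+1/−1 per cell by the sign of <ω_i, nematic direction>.

    Cells exactly orthogonal to the nematic axis get +1 (a measure-zero
    tie, broken positively).
    """
    w = np.atleast_2d(np.asarray(orientations, dtype=float))
    _, direction = nematic_order(w)
    dots = w @ direction
    return np.where(dots < 0, -1, 1)


def cluster_partition(positions, R: float = DEFAULT_CLUSTER_RADIUS,
                      L: float | None = None) -> ClusterPartition:
    """Connected components of the "minimum-image distance ≤ R" graph."""
    if R <= 0:
        raise ValueError("cluster radius R must be positive")
    pos = np.atleast_2d(np.asarray(positions, dtype=float))
    tree = cKDTree(pos, boxsize=L) if L is not None else cKDTree(pos)
    pairs = tree.query_pairs(R, output_type="ndarray")
    n = pos.shape[0]
    if len(pairs):
        ones = np.ones(len(pairs), dtype=np.int8)
        adj = coo_matrix((ones, (pairs[:, 0], pairs[:, 1])), shape=(n, n))
    else:
        adj = coo_matrix((n, n), dtype=np.int8)
    n_comp, labels = connected_components(adj, directed=False)
    sizes = np.bincount(labels, minlength=n_comp)
    return ClusterPartition(labels=labels, sizes=sizes, R=R)


def mean_cluster_size(partition: ClusterPartition) -> float:
    """Size-weighted mean cluster size Σ_k |C_k|²/N.

    This averages over *cells*, not clusters: it is the expected size of
    the cluster containing a uniformly chosen cell.
    """
    n = int(partition.sizes.sum())
    return float(np.sum(partition.sizes.astype(float) ** 2) / n)


def order_stats(config: CellConfiguration, params: ModelParams,
                R: float = DEFAULT_CLUSTER_RADIUS,
                include_potential: bool = True) -> OrderStats:
    """All order parameters of one configuration."""
    w = config.orientations
    J, direction = nematic_order(w)
    gamma = nematic_polarization_2d(w) if config.d == 2 else None
    part = cluster_partition(config.positions, R=R, L=params.L)
    return OrderStats(
        psi=polarization(w),
        gamma=gamma,
        J=J,
        nematic_direction=direction,
        mean_cluster_size=mean_cluster_size(part),
        total_potential=total_potential(config, params) if include_potential else None,
        time=config.time,
    )


def trajectory_stats(trajectory, R: float = DEFAULT_CLUSTER_RADIUS) -> pd.DataFrame:
    """Tidy per-snapshot table: time, psi, gamma, J, cluster size, potential."""
    rows = []
    for cfg in trajectory.states:
        st = order_stats(cfg, trajectory.params, R=R)
        rows.append(
            {
                "time": st.time,
                "psi": st.psi,
                "gamma": st.gamma if st.gamma is not None else np.nan,
                "J": st.J,
                "mean_cluster_size": st.mean_cluster_size,
                "total_potential": st.total_potential,
            }
        )
    return pd.DataFrame(rows)
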