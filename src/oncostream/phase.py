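"""(α, β) parameter sweeps, loess surface smoothing and phase regions.

A sweep runs several seeded replicates per (α, β) grid point at fixed N,
records the final-time order parameters, smooths each statistic with a
2-D local quadratic regression (tricube weights), and classifies grid
points into flock / stream regions with a scattering overlay:

    flock   : ψ > 0.8
    stream  : γ > 0.7 and ψ ≤ 0.8
    scatter : size-weighted mean cluster size < 600   (overlay flag;
              the criterion is independent of the other two, so it is
              reported alongside the exclusive flock/stream label)
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .model import ModelParams
from .simulate import SimulationConfig, run
from .stats import DEFAULT_CLUSTER_RADIUS, order_stats

PSI_FLOCK_THRESHOLD = 0.8
GAMMA_STREAM_THRESHOLD = 0.7
CLUSTER_SCATTER_THRESHOLD = 600.0


@dataclass
class PhaseGrid:
    """Raw and smoothed results of an (α, β) sweep at fixed N."""

    alpha_values: np.ndarray
    beta_values: np.ndarray
    N: int
    replicates: int
    raw: pd.DataFrame  # long format: alpha, beta, replicate, seed, psi, gamma, J, cluster
    smoothed: dict = field(default_factory=dict)  # stat name -> (n_alpha, n_beta) array
    labels: np.ndarray | None = None
    scatter_overlay: np.ndarray | None = None

    def surface(self, stat: str, span: float = 0.75) -> np.ndarray:
        if stat not in self.smoothed:
            self.smoothed[stat] = smooth_surface(
                self.raw["alpha"].to_numpy(),
                self.raw["beta"].to_numpy(),
                self.raw[stat].to_numpy(),
                self.alpha_values,
                self.beta_values,
                span=span,
            )
        return self.smoothed[stat]

    def classify(self, span: float = 0.75):
        nematic = "gamma" if self.raw["gamma"].notna().all() else "J"
        self.labels, self.scatter_overlay = classify_regions(
            self.surface("psi", span),
            self.surface(nematic, span),
            self.surface("mean_cluster_size", span),
        )
        return self.labels, self.scatter_overlay

    def flock_area_fraction(self) -> float:
        if self.labels is None:
            self.classify()
        return float(np.mean(self.labels == "flock"))


def default_grid(n_alpha: int = 8, n_beta: int = 8):
    """Near-geometric default grids over α ∈ [10, 200], β ∈ [0.1, 10]."""
    return (
        np.geomspace(10.0, 200.0, n_alpha),
        np.geomspace(0.1, 10.0, n_beta),
    )


def sweep_seed(base_seed: int, i_alpha: int, i_beta: int, replicate: int) -> int:
    """Deterministic per-run seed derived from the sweep's base seed."""
    ss = np.random.SeedSequence([int(base_seed), i_alpha, i_beta, replicate])
    return int(ss.generate_state(1)[0] % (2**31))


def run_sweep(alpha_values, beta_values, N: int, params_template: ModelParams,
              sim_config: SimulationConfig, replicates: int = 5,
              base_seed: int = 0,
              cluster_radius: float = DEFAULT_CLUSTER_RADIUS) -> PhaseGrid:
    """Replicated seeded runs over the (α, β) grid, final-time statistics.

    Results are ordered by (α index, β index, replicate); a failed run is
    recorded with NaN statistics rather than aborting the sweep.
    """
    alpha_values = np.asarray(alpha_values, dtype=float)
    beta_values = np.asarray(beta_values, dtype=float)
    rows = []
    for ia, alpha in enumerate(alpha_values):
        for ib, beta in enumerate(beta_values):
            params = params_template.replace(alpha=float(alpha), beta=float(beta))
            for rep in range(replicates):
                seed = sweep_seed(base_seed, ia, ib, rep)
                row = {
                    "alpha": float(alpha),
                    "beta": float(beta),
                    "replicate": rep,
                    "seed": seed,
                }
                try:
                    traj = run(params, sim_config.replace(seed=seed), N)
                    st = order_stats(traj.final, params, R=cluster_radius,
                                     include_potential=False)
                    row.update(
                        psi=st.psi,
                        gamma=st.gamma if st.gamma is not None else np.nan,
                        J=st.J,
                        mean_cluster_size=st.mean_cluster_size,
                        error="",
                    )
                except Exception as err:  # pragma: no cover - defensive
                    row.update(psi=np.nan, gamma=np.nan, J=np.nan,
                               mean_cluster_size=np.nan, error=str(err))
                rows.append(row)
    raw = pd.DataFrame(rows)
    return PhaseGrid(alpha_values=alpha_values, beta_values=beta_values,
                     N=N, replicates=replicates, raw=raw)


def _loess_2d(x, y, z, x_eval, y_eval, span: float = 0.75, degree: int = 2):
    """Local polynomial regression on scattered (x, y, z) data.

    For each evaluation point the ``span`` fraction of nearest data
    points (in range-normalised coordinates) is fit by weighted least
    squares with tricube weights; the fitted value at the point is
    returned.  ``degree`` 1 or 2.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    z = np.asarray(z, float)
    keep = np.isfinite(z)
    x, y, z = x[keep], y[keep], z[keep]
    n = len(z)
    n_params = 3 if degree == 1 else 6
    if n < n_params:
        raise ValueError(f"loess needs at least {n_params} points, got {n}")
    sx = np.ptp(x) or 1.0
    sy = np.ptp(y) or 1.0
    k = max(n_params, int(np.ceil(span * n)))
    k = min(k, n)
    out = np.empty(len(x_eval))
    for m, (xe, ye) in enumerate(zip(x_eval, y_eval)):
        dx = (x - xe) / sx
        dy = (y - ye) / sy
        dist = np.hypot(dx, dy)
        idx = np.argpartition(dist, k - 1)[:k]
        dmax = dist[idx].max()
        if dmax == 0:
            out[m] = z[idx].mean()
            continue
        u = np.clip(dist[idx] / dmax, 0.0, 1.0)
        w = (1.0 - u**3) ** 3
        w[w <= 0] = 1e-12
        X = [np.ones(k), dx[idx], dy[idx]]
        if degree == 2:
            X += [dx[idx] ** 2, dx[idx] * dy[idx], dy[idx] ** 2]
        X = np.column_stack(X)
        sw = np.sqrt(w)
        coef, *_ = np.linalg.lstsq(X * sw[:, None], z[idx] * sw, rcond=None)
        out[m] = coef[0]
    return out


def smooth_surface(alpha, beta, values, alpha_grid, beta_grid,
                   span: float = 0.75, degree: int = 2,
                   clip: tuple | None = None) -> np.ndarray:
    """Loess-smoothed surface of a statistic on the (α, β) grid.

    Returns an (n_alpha, n_beta) array.  Fitted values are clipped to
    the data range by default (order parameters stay in [0, 1], cluster
    sizes stay non-negative) since local quadratics can overshoot.
    """
    A, B = np.meshgrid(alpha_grid, beta_grid, indexing="ij")
    fitted = _loess_2d(alpha, beta, values, A.ravel(), B.ravel(),
                       span=span, degree=degree)
    if clip is None:
        vals = np.asarray(values, float)
        vals = vals[np.isfinite(vals)]
        clip = (vals.min(), vals.max())
    return np.clip(fitted.reshape(A.shape), clip[0], clip[1])


def classify_regions(psi_surface, nematic_surface, cluster_surface,
                     psi_threshold: float = PSI_FLOCK_THRESHOLD,
                     gamma_threshold: float = GAMMA_STREAM_THRESHOLD,
                     cluster_threshold: float = CLUSTER_SCATTER_THRESHOLD):
    """Exclusive flock/stream/unclassified labels plus a scatter overlay.

    Flock takes precedence over stream; the scattering criterion (small
    mean cluster size) is independent of both and returned as a boolean
    overlay.
    """
    psi = np.asarray(psi_surface, float)
    nem = np.asarray(nematic_surface, float)
    clus = np.asarray(cluster_surface, float)
    labels = np.full(psi.shape, "unclassified", dtype=object)
    labels[(nem > gamma_threshold) & (psi <= psi_threshold)] = "stream"
    labels[psi > psi_threshold] = "flock"
    scatter_overlay = clus < cluster_threshold
    return labels, scatter_overlay
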