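"""Time integration and seeded initial conditions.

The equations of motion are integrated with explicit Euler steps; after
each step positions are wrapped back into the periodic box and headings
are renormalised onto the unit sphere (projection-by-normalisation, an
O(dt²) correction per step since the drift is already tangent).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .model import (
    DEFAULT_EPSILON,
    CellConfiguration,
    ModelParams,
    minimum_image,
    rhs,
    wrap_positions,
)


@dataclass(frozen=True)
class SimulationConfig:
    """Integration settings.

    dt : integration step (h), default 0.05
    T : final time (h)
    seed : RNG seed for the initial condition
    record_every : interval between stored snapshots (h)
    init_mode : one of {"random", "flock", "stream"}
    epsilon : singularity floor passed to the force evaluation
    """

    dt: float = 0.05
    T: float = 1000.0
    seed: int = 0
    record_every: float = 10.0
    init_mode: str = "random"
    epsilon: float = DEFAULT_EPSILON

    def __post_init__(self):
        if not (0 < self.dt <= self.record_every <= self.T or self.T == 0):
            raise ValueError("need 0 < dt <= record_every <= T")
        if self.init_mode not in ("random", "flock", "stream"):
            raise ValueError(f"unknown init_mode {self.init_mode!r}")

    def replace(self, **kw) -> "SimulationConfig":
        return replace(self, **kw)


@dataclass
class Trajectory:
    """Recorded snapshots of one run, with full provenance."""

    times: np.ndarray
    states: list  # list of CellConfiguration
    params: ModelParams
    sim_config: SimulationConfig
    n_cells: int = 0

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        if self.states:
            self.n_cells = self.states[0].n_cells

    @property
    def final(self) -> CellConfiguration:
        return self.states[-1]

    def __len__(self) -> int:
        return len(self.states)


def _random_directions(rng: np.random.Generator, n: int, d: int) -> np.ndarray:
    """Uniform draws on the unit circle / sphere."""
    if d == 2:
        theta = rng.uniform(0.0, 2.0 * np.pi, size=n)
        return np.column_stack([np.cos(theta), np.sin(theta)])
    v = rng.normal(size=(n, 3))
    return v / np.linalg.norm(v, axis=1, keepdims=True)


def init_random(N: int, params: ModelParams, seed) -> CellConfiguration:
    """Positions i.i.d. uniform in the box, headings isotropic."""
    if N < 1:
        raise ValueError("N must be >= 1")
    rng = np.random.default_rng(seed)
    pos = rng.uniform(0.0, params.L, size=(N, params.d))
    ori = _random_directions(rng, N, params.d)
    return CellConfiguration(pos, ori, time=0.0)


def _min_pair_rsq(pos: np.ndarray, omega: np.ndarray, params: ModelParams) -> float:
    """Smallest r_ij² over ordered pairs for a common heading omega."""
    from .model import normalized_distance_sq

    N = pos.shape[0]
    best = np.inf
    for i in range(N):
        d = pos - pos[i]
        d -= params.L * np.round(d / params.L)
        dd = np.einsum("ij,ij->i", d, d)
        proj = d @ omega
        rsq = (dd - params.e2 * proj**2) / params.b**2
        rsq[i] = np.inf
        best = min(best, float(rsq.min()))
    return best


def _place_non_overlapping(N: int, params: ModelParams, rng: np.random.Generator,
                           max_attempts: int = 5) -> np.ndarray:
    """Rejection-sample positions with all pairwise centre distances > a.

    Sufficient for r_ij > 1 regardless of headings since
    r_ij >= ||x_j - x_i|| / a.
    """
    # cheap feasibility bound: points at pairwise distance > a cannot be
    # denser than one per (a/sqrt(d))^d cell of a cubic lattice
    capacity = (np.floor(params.L / params.a) + 1) ** params.d * 2 ** params.d
    if N > capacity:
        raise RuntimeError(
            f"cannot place {N} cells at pairwise distance > {params.a} in a "
            f"box of side {params.L} (capacity about {int(capacity)})"
        )
    for _ in range(max_attempts):
        pos = np.empty((N, params.d))
        pos[0] = rng.uniform(0.0, params.L, size=params.d)
        count = 1
        tries = 0
        limit = 100 * N
        while count < N and tries < limit:
            cand = rng.uniform(0.0, params.L, size=params.d)
            diff = pos[:count] - cand
            diff -= params.L * np.round(diff / params.L)
            if np.min(np.einsum("ij,ij->i", diff, diff)) > params.a**2:
                pos[count] = cand
                count += 1
            tries += 1
        if count == N:
            return pos
    raise RuntimeError(
        f"could not place {N} non-overlapping cells of radius {params.a} "
        f"in a box of side {params.L}"
    )


def init_flock(N: int, params: ModelParams, seed, direction=None) -> CellConfiguration:
    """Perfect flock: common heading, no pair with r_ij <= 1.

    Such a state is a fixed point of the relative dynamics and is merely
    transported at speed c.
    """
    rng = np.random.default_rng(seed)
    if direction is None:
        direction = np.zeros(params.d)
        direction[0] = 1.0
    direction = np.asarray(direction, dtype=float)
    direction = direction / np.linalg.norm(direction)
    pos = _place_non_overlapping(N, params, rng)
    ori = np.tile(direction, (N, 1))
    return CellConfiguration(pos, ori, time=0.0)


def init_stream(N: int, params: ModelParams, seed, direction=None) -> CellConfiguration:
    """Two-way stream: non-overlapping positions, headings ±direction.

    The sign is set by which half of the box (transverse coordinate) the
    cell occupies, giving two counter-moving lanes.
    """
    rng = np.random.default_rng(seed)
    if direction is None:
        direction = np.zeros(params.d)
        direction[0] = 1.0
    direction = np.asarray(direction, dtype=float)
    direction = direction / np.linalg.norm(direction)
    pos = _place_non_overlapping(N, params, rng)
    sign = np.where(pos[:, 1] < params.L / 2.0, 1.0, -1.0)
    ori = sign[:, None] * direction[None, :]
    return CellConfiguration(pos, ori, time=0.0)


def initial_condition(N: int, params: ModelParams, sim_config: SimulationConfig) -> CellConfiguration:
    mode = sim_config.init_mode
    if mode == "random":
        return init_random(N, params, sim_config.seed)
    if mode == "flock":
        return init_flock(N, params, sim_config.seed)
    return init_stream(N, params, sim_config.seed)


def _advance(config: CellConfiguration, params: ModelParams,
             sim_config: SimulationConfig, n_steps: int) -> CellConfiguration:
    """Advance ``n_steps`` Euler steps through the compiled kernel."""
    from ._kernels import integrate_chunk, n_bins

    pos = np.ascontiguousarray(config.positions.copy())
    ori = np.ascontiguousarray(config.orientations.copy())
    ok = np.isfinite(pos).all(axis=1) & np.isfinite(ori).all(axis=1)
    if not ok.all():
        raise FloatingPointError(
            f"non-finite state for cell {int(np.argmin(ok))} "
            f"at t={config.time:.4f}"
        )
    bad = integrate_chunk(
        pos, ori, params.L, n_bins(params.L, params.a), params.a, params.b,
        params.e2, sim_config.epsilon, params.c, params.alpha, params.beta,
        sim_config.dt, n_steps,
    )
    if bad >= 0:
        raise FloatingPointError(
            f"non-finite state for cell {bad} near t={config.time:.4f}"
            f"+{n_steps}*dt"
        )
    return CellConfiguration(pos, ori, time=config.time + n_steps * sim_config.dt)


def step(config: CellConfiguration, params: ModelParams,
         sim_config: SimulationConfig) -> CellConfiguration:
    """One explicit Euler step with wrapping and renormalisation."""
    return _advance(config, params, sim_config, 1)


def run(params: ModelParams, sim_config: SimulationConfig, N: int,
        initial: CellConfiguration | None = None) -> Trajectory:
    """Integrate from t=0 to T, recording every ``record_every`` hours."""
    config = initial.copy() if initial is not None else initial_condition(N, params, sim_config)
    times = [0.0]
    states = [config.copy()]
    n_steps = int(round(sim_config.T / sim_config.dt))
    rec_stride = max(1, int(round(sim_config.record_every / sim_config.dt)))
    done = 0
    while done < n_steps:
        chunk = min(rec_stride, n_steps - done)
        try:
            config = step_many(config, params, sim_config, chunk)
        except FloatingPointError as err:
            raise FloatingPointError(
                f"integration failed between steps {done} and {done + chunk}: {err}"
            ) from err
        done += chunk
        times.append(done * sim_config.dt)
        states.append(config.copy())
    return Trajectory(times=np.array(times), states=states,
                      params=params, sim_config=sim_config)


def step_many(config: CellConfiguration, params: ModelParams,
              sim_config: SimulationConfig, n_steps: int) -> CellConfiguration:
    """``n_steps`` consecutive Euler steps (identical to repeated step())."""
    return _advance(config, params, sim_config, n_steps)
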