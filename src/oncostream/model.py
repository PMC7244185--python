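"""Geometry, interaction potential and equations of motion.

Each of the N cells is an ellipse (2D) or prolate ellipsoid (3D) with
semi-major axis ``a`` along its heading ``omega_i`` and semi-minor axis
``b``.  Crowding is measured by the *tension*

    V_i = sum_{j != i} Phi(r_ij^2),

where ``r_ij`` is the normalised centre distance: the Euclidean distance
rescaled by the cell's extent in the direction of the neighbour,

    r_ij^2 = (||x_j - x_i||^2 - e^2 [(x_j - x_i) . omega_i]^2) / b^2,

with eccentricity ``e = sqrt(1 - b^2/a^2)``.  ``r_ij < 1`` roughly means
cell j overlaps the ellipse of cell i; note r_ij != r_ji in general
because each cell measures distance in its own body frame.

The overdamped dynamics combine self-propulsion at constant speed ``c``
with descent of each cell's own tension:

    dx_i/dt     = c * omega_i - alpha * grad_x V_i
    domega_i/dt = -beta * P_perp(omega_i) grad_omega V_i,

where ``P_perp(w) = I - w (x) w`` keeps the heading on the unit sphere.
All lengths are in micrometres and times in hours.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from ._kernels import compute_forces

DEFAULT_EPSILON = 1e-6


@dataclass(frozen=True)
class ModelParams:
    """Geometric, mechanical and domain parameters.

    Parameters
    ----------
    a, b : float
        Semi-major / semi-minor axis of the cell (μm); ``a >= b > 0``.
    c : float
        Self-propulsion speed (μm/h).
    alpha : float
        Repulsion strength (μm²/h); scales the positional tension descent.
    beta : float
        Steering strength (1/h); scales the orientational tension descent.
    L : float
        Side length of the periodic box (μm).
    d : int
        Spatial dimension, 2 or 3.
    """

    a: float
    b: float
    c: float
    alpha: float
    beta: float
    L: float
    d: int = 2

    def __post_init__(self):
        if not (self.a >= self.b > 0):
            raise ValueError(f"need a >= b > 0, got a={self.a}, b={self.b}")
        if self.c < 0 or self.alpha < 0 or self.beta < 0:
            raise ValueError("c, alpha, beta must be non-negative")
        if self.L <= 0:
            raise ValueError("box length L must be positive")
        if self.d not in (2, 3):
            raise ValueError(f"dimension d must be 2 or 3, got {self.d}")

    @property
    def e(self) -> float:
        """Eccentricity sqrt(1 - b²/a²) ∈ [0, 1); 0 for circular cells."""
        return float(np.sqrt(self.e2))

    @property
    def e2(self) -> float:
        return 1.0 - (self.b / self.a) ** 2

    @property
    def cutoff(self) -> float:
        """Centre-distance beyond which Phi vanishes (equals ``a``)."""
        return self.a

    def replace(self, **kw) -> "ModelParams":
        return replace(self, **kw)


@dataclass
class CellConfiguration:
    """Positions and unit headings of N cells in the periodic box."""

    positions: np.ndarray  # (N, d), wrapped into [0, L)
    orientations: np.ndarray  # (N, d), unit rows
    time: float = 0.0

    def __post_init__(self):
        self.positions = np.atleast_2d(np.asarray(self.positions, dtype=float))
        self.orientations = np.atleast_2d(np.asarray(self.orientations, dtype=float))
        if self.positions.shape != self.orientations.shape:
            raise ValueError("positions and orientations must have the same shape")
        if self.positions.shape[0] < 1:
            raise ValueError("need at least one cell")

    @property
    def n_cells(self) -> int:
        return self.positions.shape[0]

    @property
    def d(self) -> int:
        return self.positions.shape[1]

    def validate(self, params: ModelParams, atol: float = 1e-9) -> None:
        norms = np.linalg.norm(self.orientations, axis=1)
        if not np.allclose(norms, 1.0, atol=atol):
            raise ValueError("orientations must be unit vectors")
        if np.any(self.positions < 0) or np.any(self.positions >= params.L):
            raise ValueError("positions must lie in [0, L)")

    def copy(self) -> "CellConfiguration":
        return CellConfiguration(
            self.positions.copy(), self.orientations.copy(), self.time
        )


@dataclass
class PairGeometry:
    """Minimum-image geometry of an ordered pair (i, j)."""

    displacement: np.ndarray  # x_j - x_i, minimum image
    longitudinal: float  # <x_j - x_i, omega_i>
    r_sq: float  # normalised squared distance


def semi_axes_for_eccentricity(e: float, area_product: float = 16.0):
    """Semi-axes (a, b) with eccentricity ``e`` at fixed product a*b.

    Varying cell shape at constant a*b keeps the cell area π·a·b fixed,
    so shape effects are not confounded with density effects.  The
    default product 16 μm² matches the reference round cell a = b = 4 μm
    (and gives a ≈ 5.44, b ≈ 2.94 at e = 0.84, the reference ellipse).
    """
    if not (0 <= e < 1):
        raise ValueError("eccentricity must lie in [0, 1)")
    ratio = np.sqrt(1.0 - e**2)  # b/a
    a = np.sqrt(area_product / ratio)
    return float(a), float(a * ratio)


def minimum_image(p, q, L):
    """Displacement q - p with each component folded into [-L/2, L/2]."""
    v = np.asarray(q, dtype=float) - np.asarray(p, dtype=float)
    return v - L * np.round(v / L)


def wrap_positions(x, L):
    """Fold positions into the half-open box [0, L)."""
    out = np.mod(x, L)
    # np.mod can return L exactly for tiny negative inputs
    out[out >= L] = 0.0
    return out


def guard_singularity(s, epsilon: float = DEFAULT_EPSILON):
    """Floor the normalised squared distance at ``epsilon``.

    Phi diverges like 1/s as two centres coincide; flooring s keeps the
    forces finite (and large) when random initial conditions place two
    centres arbitrarily close.
    """
    return np.maximum(s, epsilon)


def phi(s):
    """Repulsion kernel: (1/s) exp(-1/(1-s)) on (0, 1), 0 for s >= 1.

    Smooth with compact support; all derivatives vanish at s = 1 so the
    interaction switches off continuously at contact.
    """
    s = np.asarray(s, dtype=float)
    if np.any(s <= 0):
        raise ValueError("phi requires s > 0 (apply guard_singularity first)")
    out = np.zeros_like(s)
    inside = s < 1.0
    si = s[inside]
    out[inside] = np.exp(-1.0 / (1.0 - si)) / si
    return out if out.ndim else float(out)


def phi_prime(s):
    """Derivative of :func:`phi`; non-positive everywhere on its domain."""
    s = np.asarray(s, dtype=float)
    if np.any(s <= 0):
        raise ValueError("phi_prime requires s > 0")
    out = np.zeros_like(s)
    inside = s < 1.0
    si = s[inside]
    u = 1.0 - si
    E = np.exp(-1.0 / u)
    out[inside] = E * (-1.0 / si**2 - 1.0 / (si * u**2))
    return out if out.ndim else float(out)


def normalized_distance_sq(displacement, omega, params: ModelParams):
    """r_ij² for a minimum-image displacement seen from heading ``omega``.

    Reduces to ``||d||²/a²`` for circular cells.  Not symmetric under
    i <-> j: the roles of the two headings differ.
    """
    d = np.asarray(displacement, dtype=float)
    proj = float(np.dot(d, omega))
    return (float(np.dot(d, d)) - params.e2 * proj**2) / params.b**2


def pair_geometry(i: int, j: int, config: CellConfiguration, params: ModelParams) -> PairGeometry:
    disp = minimum_image(config.positions[i], config.positions[j], params.L)
    return PairGeometry(
        displacement=disp,
        longitudinal=float(np.dot(disp, config.orientations[i])),
        r_sq=normalized_distance_sq(disp, config.orientations[i], params),
    )


def tension(i: int, config: CellConfiguration, params: ModelParams,
            epsilon: float = DEFAULT_EPSILON) -> float:
    """Tension V_i = sum_{j != i} Phi(r_ij²) by the direct double loop."""
    V = 0.0
    for j in range(config.n_cells):
        if j == i:
            continue
        g = pair_geometry(i, j, config, params)
        V += phi(guard_singularity(g.r_sq, epsilon))
    return V


def grad_x_tension(i: int, config: CellConfiguration, params: ModelParams,
                   epsilon: float = DEFAULT_EPSILON) -> np.ndarray:
    """Analytic gradient of V_i with respect to x_i.

    Uses grad_x r_ij² = (2/b²) (e² (d·ω_i) ω_i − d) with d = x_j − x_i.
    """
    omega = config.orientations[i]
    g = np.zeros(config.d)
    for j in range(config.n_cells):
        if j == i:
            continue
        pg = pair_geometry(i, j, config, params)
        s = guard_singularity(pg.r_sq, epsilon)
        fp = phi_prime(s)
        if fp == 0.0:
            continue
        grad_r2 = (2.0 / params.b**2) * (
            params.e2 * pg.longitudinal * omega - pg.displacement
        )
        g += fp * grad_r2
    return g


def grad_omega_tension(i: int, config: CellConfiguration, params: ModelParams,
                       epsilon: float = DEFAULT_EPSILON) -> np.ndarray:
    """Analytic gradient of V_i with respect to ω_i as a free vector.

    grad_ω r_ij² = −(2e²/b²)(d·ω_i) d; identically zero for circular
    cells (e = 0), which is why round cells never steer.
    """
    g = np.zeros(config.d)
    for j in range(config.n_cells):
        if j == i:
            continue
        pg = pair_geometry(i, j, config, params)
        s = guard_singularity(pg.r_sq, epsilon)
        fp = phi_prime(s)
        if fp == 0.0:
            continue
        g += fp * (-2.0 * params.e2 / params.b**2) * pg.longitudinal * pg.displacement
    return g


def project_tangent(omega, v):
    """Project v onto the plane orthogonal to the unit vector omega."""
    omega = np.asarray(omega, dtype=float)
    v = np.asarray(v, dtype=float)
    return v - np.dot(v, omega) * omega


def all_forces(config: CellConfiguration, params: ModelParams,
               epsilon: float = DEFAULT_EPSILON):
    """(V_i, grad_x V_i, grad_ω V_i) for every cell via the fast kernels."""
    return compute_forces(
        config.positions, config.orientations,
        params.L, params.a, params.b, params.e2, epsilon,
    )


def total_potential(config: CellConfiguration, params: ModelParams,
                    epsilon: float = DEFAULT_EPSILON) -> float:
    """Monitored total potential V = Σ_i V_i (double-counts each pair once
    per body frame; the two contributions differ because r_ij != r_ji)."""
    V, _, _ = all_forces(config, params, epsilon)
    return float(np.sum(V))


def rhs(config: CellConfiguration, params: ModelParams,
        epsilon: float = DEFAULT_EPSILON):
    """Right-hand side of the equations of motion.

    Returns ``(dx_dt, domega_dt)``; each ``domega_i/dt`` is orthogonal
    to ``omega_i`` by construction of the tangent projection.
    """
    _, gx, gw = all_forces(config, params, epsilon)
    omega = config.orientations
    dx = params.c * omega - params.alpha * gx
    # project each grad_w onto the tangent plane of its heading
    gw_tan = gw - np.sum(gw * omega, axis=1, keepdims=True) * omega
    dw = -params.beta * gw_tan
    return dx, dw
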