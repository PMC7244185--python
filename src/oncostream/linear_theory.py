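"""Closed-form two-cell steering dynamics ("indirect alignment").

For two cells at fixed relative position d = x_j − x_i, descending the
tension rotates each heading away from the separation axis: the
normalised distance r_ij² = (‖d‖² − e²(d·ω_i)²)/b² is largest — and the
tension smallest — when the heading is orthogonal to d.  Linearising the
heading equation at frozen geometry gives a closed rate law

    dθ/dt = C · sin(2θ),      C = (β e²/b²) Φ'(r_ij²) ‖d‖²  ≤ 0,

where θ is the angle from the separation vector to the cell's
*transverse* axis (the broadside direction ω_i⊥).  Since Φ' ≤ 0 the
rest points θ = 0, π are stable: the broadside axis locks onto the
separation vector, i.e. the heading converges to ±π/2 from d.  For the
heading-to-separation angle θ_h = π/2 − θ the same law reads
dθ_h/dt = −C sin(2θ_h), with ±π/2 stable.

Because neither cell uses the other's velocity, both headings align with
the hyperplane orthogonal to d; in 2D this forces ω_i = ±ω_j — the
origin of flocks (same sign) and streams (opposite signs).

This module is the analytic oracle the test-suite holds the full
simulator against.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .model import CellConfiguration, ModelParams, phi_prime


@dataclass(frozen=True)
class TwoCellState:
    """Frozen two-cell geometry.

    theta : angle between the heading ω_i and the separation x_j − x_i
            (radians, in (−π, π]).
    separation : centre distance |x_j − x_i| (μm), > 0.
    """

    theta: float
    separation: float

    def __post_init__(self):
        if not self.separation > 0:
            raise ValueError("separation must be positive")
        if not (-np.pi < self.theta <= np.pi):
            raise ValueError("theta must lie in (-pi, pi]")


def pair_r_sq(separation: float, theta: float, params: ModelParams) -> float:
    """r_ij² for a pair at given centre distance and heading angle."""
    return (
        separation**2 * (1.0 - params.e2 * np.cos(theta) ** 2) / params.b**2
    )


def steering_coefficient(separation: float, theta: float,
                         params: ModelParams) -> float:
    """Linearised steering rate constant C = (β e²/b²) Φ'(r_ij²) ‖d‖².

    Non-positive everywhere (Φ' ≤ 0); zero for circular cells (e = 0)
    and outside the interaction support (r_ij ≥ 1, in particular whenever
    the separation exceeds a).
    """
    if params.e2 == 0.0:
        return 0.0
    rsq = pair_r_sq(separation, theta, params)
    if rsq >= 1.0:
        return 0.0
    return float(
        params.beta * params.e2 / params.b**2 * phi_prime(rsq) * separation**2
    )


def theta_rate(theta: float, C: float) -> float:
    """dθ/dt = C·sin(2θ) for the transverse-axis angle θ.

    Equilibria at θ ∈ {0, ±π/2, π}; with C < 0, θ = 0 and π are stable
    (broadside locked onto the separation vector — the heading orthogonal
    to it) while ±π/2 (head-on) are unstable.
    """
    return C * np.sin(2.0 * theta)


def heading_angle_rate(theta_heading: float, C: float) -> float:
    """Rate of the heading-to-separation angle: −C·sin(2θ_h).

    The complement of :func:`theta_rate`; with C < 0 the stable rest
    points are θ_h = ±π/2.
    """
    return -C * np.sin(2.0 * theta_heading)


def two_cell_configuration(separation: float, theta: float,
                           params: ModelParams) -> CellConfiguration:
    """Build the canonical two-cell state used by the oracle tests.

    Cell i sits at the box centre with heading at angle ``theta`` from
    the separation vector, which points along +x toward cell j (heading
    +x as well, so the geometry is symmetric under the nematic flip).
    """
    if params.d != 2:
        raise ValueError("the two-cell oracle is a planar construction")
    mid = params.L / 2.0
    pos = np.array([[mid, mid], [mid + separation, mid]])
    ori = np.array(
        [[np.cos(theta), np.sin(theta)], [np.cos(theta), np.sin(theta)]]
    )
    return CellConfiguration(pos, ori, time=0.0)
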