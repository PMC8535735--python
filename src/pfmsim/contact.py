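"""Node-to-analytic-sphere penalty contact with regularized Coulomb friction.

Each muscle node inside the sphere receives a radial penalty force
proportional to its penetration depth; a tangential force opposes the
relative sliding velocity, capped by the Coulomb cone mu * |normal| and
regularized below a threshold sliding speed to avoid stick-slip chatter in
explicit stepping.  The reaction on the (1-DOF, vertically translating)
sphere is minus the sum of the nodal forces.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DegenerateContactError, InvalidParameterError
from .geometry import RigidSphere

__all__ = ["ContactParams", "ContactResult", "sphere_contact", "auto_penalty_stiffness"]


@dataclass
class ContactParams:
    """Contact model parameters.

    ``penalty_stiffness`` (N/mm per node) of ``None`` requests auto-scaling
    at simulation setup so that quasi-static support of the sphere stays
    well below ``penetration_tolerance``.
    """

    friction_coefficient: float = 0.03
    penalty_stiffness: float | None = None
    friction_regularization_velocity: float = 1.0   # mm/s
    penetration_tolerance: float = 0.1              # mm
    enabled: bool = True

    def __post_init__(self):
        if self.friction_coefficient < 0.0:
            raise InvalidParameterError("friction_coefficient must be >= 0")
        if self.penalty_stiffness is not None and self.penalty_stiffness <= 0.0:
            raise InvalidParameterError("penalty_stiffness must be > 0")
        if self.friction_regularization_velocity <= 0.0:
            raise InvalidParameterError("friction_regularization_velocity must be > 0")
        if self.penetration_tolerance <= 0.0:
            raise InvalidParameterError("penetration_tolerance must be > 0")


@dataclass
class ContactResult:
    node_forces: np.ndarray        # (N, 3), N on the muscle nodes
    sphere_reaction: np.ndarray    # (3,), N on the sphere
    dissipation_increment: float   # mJ, >= 0 (friction work over dt)
    max_penetration: float         # mm
    spring_energy: float           # mJ, elastic energy stored in the penalty
    n_active: int


def auto_penalty_stiffness(
    sphere: RigidSphere, young_modulus: float, characteristic_edge: float,
    gravity: float = 9810.0, n_support: int = 6, target_penetration: float = 0.005,
) -> float:
    """Default penalty: stiff enough that a handful of nodes carrying the
    sphere's weight (the worst case: the pinch line where the descending
    head presses sheet material against the attachment margin) penetrate
    only ``target_penetration`` mm, and never softer than 10 E h."""
    static = sphere.mass * gravity / (n_support * target_penetration)
    return max(10.0 * young_modulus * characteristic_edge, static)


def sphere_contact(
    positions: np.ndarray,
    velocities: np.ndarray,
    sphere: RigidSphere,
    params: ContactParams,
    dt: float = 0.0,
    penalty_stiffness: float | None = None,
    node_mask: np.ndarray | None = None,
    viscous_cap: np.ndarray | None = None,
) -> ContactResult:
    """Evaluate contact forces between muscle nodes and the rigid sphere.

    ``positions``/``velocities`` are current nodal values (N, 3); the sphere
    carries its own center and vertical velocity.  ``dt`` scales the friction
    dissipation increment (pass 0 for a force-only query).  ``node_mask``
    restricts contact to a subset of nodes (the simulator excludes the
    constrained attachment margin, which stands for the bony insertion line
    rather than free muscle surface).  ``viscous_cap`` (per-node, N per mm/s)
    bounds the regularizing viscous coefficient so explicit integration of
    the near-stick regime stays stable; the Coulomb bound mu*|normal| always
    holds regardless.
    """
    pos = np.asarray(positions, dtype=float)
    vel = np.asarray(velocities, dtype=float)
    if pos.shape != vel.shape:
        raise InvalidParameterError("positions and velocities must have the same shape")
    k = penalty_stiffness if penalty_stiffness is not None else params.penalty_stiffness
    if k is None:
        raise InvalidParameterError("penalty_stiffness unresolved (auto value not computed)")

    n_nodes = pos.shape[0]
    forces = np.zeros((n_nodes, 3))
    rel = pos - sphere.center
    dist = np.linalg.norm(rel, axis=1)
    if np.any(dist < 1e-9):
        raise DegenerateContactError("node coincides with sphere center")
    active = dist < sphere.radius
    if node_mask is not None:
        active &= node_mask
    if not np.any(active) or not params.enabled:
        return ContactResult(
            node_forces=forces,
            sphere_reaction=np.zeros(3),
            dissipation_increment=0.0,
            max_penetration=0.0,
            spring_energy=0.0,
            n_active=0,
        )

    d = dist[active]
    normal = rel[active] / d[:, None]
    depth = sphere.radius - d
    fn_mag = k * depth
    fn = fn_mag[:, None] * normal

    v_sphere = np.array([0.0, 0.0, sphere.vertical_velocity])
    v_rel = vel[active] - v_sphere
    v_t = v_rel - np.einsum("ni,ni->n", v_rel, normal)[:, None] * normal
    speed = np.linalg.norm(v_t, axis=1)
    # regularized Coulomb: linear-viscous below the threshold sliding speed
    scale = params.friction_coefficient * fn_mag / np.maximum(
        speed, params.friction_regularization_velocity
    )
    if viscous_cap is not None:
        scale = np.minimum(scale, np.asarray(viscous_cap)[active])
    ft = -scale[:, None] * v_t

    forces[active] = fn + ft
    reaction = -forces.sum(axis=0)
    dissipation = float(-np.einsum("ni,ni->", ft, v_t) * dt)
    return ContactResult(
        node_forces=forces,
        sphere_reaction=reaction,
        dissipation_increment=max(dissipation, 0.0),
        max_penetration=float(depth.max()),
        spring_energy=float(0.5 * k * np.sum(depth ** 2)),
        n_active=int(active.sum()),
    )
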