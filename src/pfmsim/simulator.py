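"""Central-difference explicit dynamics of the muscle sheet and the sphere.

The muscle nodes and the 1-DOF (vertical) rigid sphere are integrated with
the leapfrog / central-difference scheme under gravity, internal SVK forces,
penalty contact and mass-proportional damping, with the outer-rim nodes held
fixed.  An energy ledger (gravity work vs kinetic + strain + contact spring
+ friction + damping) is maintained as a verification instrument, snapshots
are stored on the published output schedule (every 0.03 s of a 0.15 s run),
and a dense monitor series tracks field peaks between snapshots.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .contact import ContactParams, auto_penalty_stiffness, sphere_contact
from .errors import InstabilityError, InvalidParameterError, SetupError
from .geometry import Mesh, RigidSphere
from .mechanics import (
    MaterialParams,
    TetKernel,
    dilatational_wave_speed,
    lumped_nodal_masses,
)

__all__ = [
    "SimulationConfig",
    "EnergyLedger",
    "SimState",
    "FieldSnapshot",
    "MonitorSeries",
    "RunResult",
    "ExplicitSim",
    "initialize",
    "run",
]


@dataclass
class SimulationConfig:
    """Run controls.  Defaults mirror the published protocol: 0.15 s of
    descent, snapshots every 0.03 s, gravity 9810 mm/s^2 along -Z, friction
    coefficient 0.03, initial vertical gap 23 mm."""

    duration: float = 0.15
    snapshot_interval: float = 0.03
    gravity: float = 9810.0
    cfl_factor: float = 0.8
    contact: ContactParams = field(default_factory=ContactParams)
    damping_ratio: float = 0.05
    initial_gap: float = 23.0
    rng_seed: int = 0
    mesh_edge: float = 3.0
    monitor_every: int = 100
    stiffening_safety: float = 1.5
    gravity_on_muscle: bool = False
    element_viscosity: float = 0.1

    def __post_init__(self):
        if self.duration <= 0.0:
            raise InvalidParameterError(f"duration must be > 0, got {self.duration}")
        if self.snapshot_interval <= 0.0:
            raise InvalidParameterError("snapshot_interval must be > 0")
        ratio = self.duration / self.snapshot_interval
        if abs(ratio - round(ratio)) > 1e-6:
            raise InvalidParameterError(
                f"snapshot_interval ({self.snapshot_interval}) must divide "
                f"duration ({self.duration})"
            )
        if not 0.0 < self.cfl_factor <= 1.0:
            raise InvalidParameterError(f"cfl_factor must lie in (0, 1], got {self.cfl_factor}")
        if self.damping_ratio < 0.0:
            raise InvalidParameterError("damping_ratio must be >= 0")
        if self.initial_gap < 0.0:
            raise InvalidParameterError("initial_gap must be >= 0")
        if self.stiffening_safety < 1.0:
            raise InvalidParameterError("stiffening_safety must be >= 1")


@dataclass
class EnergyLedger:
    """mJ (N*mm).  Dissipation terms are non-decreasing in time."""

    kinetic: float = 0.0
    strain: float = 0.0
    contact_spring: float = 0.0
    external_work: float = 0.0
    friction_dissipation: float = 0.0
    damping_dissipation: float = 0.0

    def residual(self) -> float:
        return self.external_work - (
            self.kinetic
            + self.strain
            + self.contact_spring
            + self.friction_dissipation
            + self.damping_dissipation
        )


@dataclass
class SimState:
    time: float
    u: np.ndarray                 # (N, 3) nodal displacements, mm
    v: np.ndarray                 # (N, 3) nodal velocities (half-step), mm/s
    sphere_z: float               # sphere center height, mm
    sphere_v: float               # sphere vertical velocity, mm/s
    ledger: EnergyLedger = field(default_factory=EnergyLedger)


@dataclass
class FieldSnapshot:
    time: float
    u: np.ndarray                 # (N, 3)
    cauchy_stress: np.ndarray     # (E, 3, 3), MPa
    green_strain: np.ndarray      # (E, 3, 3)
    sphere_z: float


@dataclass
class MonitorSeries:
    """Dense scalar time series sampled every ``monitor_every`` steps."""

    time: np.ndarray
    peak_von_mises: np.ndarray          # MPa, field max at that instant
    peak_principal_stress: np.ndarray   # MPa
    peak_principal_strain: np.ndarray
    max_uz: np.ndarray                  # mm, descent-positive nodal max
    ux_span: np.ndarray                 # mm, max(u_X) - min(u_X) over nodes
    max_penetration: np.ndarray         # mm
    energy_residual: np.ndarray         # mJ
    sphere_drop: np.ndarray             # mm


@dataclass
class RunResult:
    snapshots: list[FieldSnapshot]
    monitors: MonitorSeries
    final_state: SimState
    stats: dict


def _von_mises_batch(sig: np.ndarray) -> np.ndarray:
    s11, s22, s33 = sig[:, 0, 0], sig[:, 1, 1], sig[:, 2, 2]
    s12, s13, s23 = sig[:, 0, 1], sig[:, 0, 2], sig[:, 1, 2]
    return np.sqrt(
        0.5
        * (
            (s11 - s22) ** 2
            + (s22 - s33) ** 2
            + (s33 - s11) ** 2
            + 6.0 * (s12 ** 2 + s13 ** 2 + s23 ** 2)
        )
    )


def estimate_fundamental_frequency(
    mesh: Mesh, material: MaterialParams
) -> float:
    """Lowest-mode estimate (rad/s): first bending mode of a cantilever plate
    of the sheet's thickness and longest lateral span.  Used only to convert
    the damping ratio into a mass-proportional coefficient; the true lowest
    mode of the hammock is of this bending type, far below any dilatational
    frequency."""
    t = mesh.estimate_thickness()
    ext = mesh.node_coords.max(axis=0) - mesh.node_coords.min(axis=0)
    span = float(max(ext[0], ext[1]))
    e, nu, rho = material.young_modulus, material.poisson_ratio, material.density
    flex = e * t ** 2 / (12.0 * rho * (1.0 - nu ** 2))
    return 1.875 ** 2 / span ** 2 * math.sqrt(flex)


class ExplicitSim:
    """Holds the precomputed kernel, masses and constraints for one run."""

    def __init__(
        self,
        mesh: Mesh,
        material: MaterialParams,
        sphere: RigidSphere,
        config: SimulationConfig,
    ):
        if "fixed_rim" not in mesh.node_sets or len(mesh.node_sets["fixed_rim"]) == 0:
            raise SetupError('mesh must carry a non-empty "fixed_rim" node set')
        self.mesh = mesh
        self.material = material
        self.sphere = sphere
        self.config = config
        self.kernel = TetKernel(mesh, material)
        if config.element_viscosity > 0.0:
            self.kernel.enable_viscosity(config.element_viscosity)
        self.masses = lumped_nodal_masses(mesh, material)
        self.free = np.ones(mesh.n_nodes, dtype=bool)
        self.free[mesh.node_sets["fixed_rim"]] = False
        self.penalty = (
            config.contact.penalty_stiffness
            if config.contact.penalty_stiffness is not None
            else auto_penalty_stiffness(
                sphere, material.young_modulus, mesh.characteristic_edge, config.gravity
            )
        )
        self.alpha = 2.0 * config.damping_ratio * estimate_fundamental_frequency(
            mesh, material
        )
        # base step from the conservative altitude measure and a contact cap;
        # at run time the step shrinks adaptively with the SVK tangent
        # stiffening of the most stretched element
        c = dilatational_wave_speed(material)
        self._dt_mesh = config.cfl_factor * mesh.min_altitude() / (
            c * config.stiffening_safety
        )
        m_min = float(self.masses[self.free].min()) if np.any(self.free) else float(self.masses.min())
        self._dt_contact = config.cfl_factor * 2.0 / math.sqrt(self.penalty / m_min)
        self.dt_base = min(self._dt_mesh, self._dt_contact)
        self._last_trc = 3.0
        self._last_visc_power = 0.0
        # stability cap on the friction regularization viscosity (explicit
        # viscous limit ~ m/dt; 0.25 leaves margin)
        self._viscous_cap = 0.25 * self.masses / self.dt_base
        self.model_size = float(
            np.max(mesh.node_coords.max(axis=0) - mesh.node_coords.min(axis=0))
        )
        ext = mesh.node_coords.max(axis=0) - mesh.node_coords.min(axis=0)
        self._bbox_extents = ext

    # -- state construction --------------------------------------------

    def initialize(self) -> SimState:
        """Zero displacements/velocities, sphere at its placed height; raises
        if the assembled configuration already penetrates."""
        res = sphere_contact(
            self.mesh.node_coords,
            np.zeros_like(self.mesh.node_coords),
            self.sphere,
            self.config.contact,
            penalty_stiffness=self.penalty,
        )
        if res.max_penetration > 1e-9:
            raise SetupError(
                f"initial penetration {res.max_penetration:.3g} mm; raise the sphere"
            )
        return SimState(
            time=0.0,
            u=np.zeros_like(self.mesh.node_coords),
            v=np.zeros_like(self.mesh.node_coords),
            sphere_z=float(self.sphere.center[2]),
            sphere_v=float(self.sphere.vertical_velocity),
        )

    # -- force evaluation ----------------------------------------------

    def _stiffening_factor(self, max_trc: float) -> float:
        """SVK tangent wave-speed growth: c_tan/c ~ sqrt((3 lam^2 - 1)/2)
        with lam^2 bounded by trace(C) - 2 (the two lateral stretches of a
        stretched element are below 1)."""
        lam2 = max(1.0, max_trc - 2.0)
        return math.sqrt((3.0 * lam2 - 1.0) / 2.0)

    def _forces(self, u: np.ndarray, v: np.ndarray, sphere_z: float, sphere_v: float,
                dt: float):
        cfg = self.config
        f, max_trc, visc_power = self.kernel.internal_forces_ex(u, v)
        self._last_trc = max_trc
        self._last_visc_power = visc_power
        sph = replace(
            self.sphere,
            center=np.array([self.sphere.center[0], self.sphere.center[1], sphere_z]),
            vertical_velocity=sphere_v,
        )
        cres = sphere_contact(
            self.mesh.node_coords + u, v, sph, cfg.contact, dt=dt,
            penalty_stiffness=self.penalty, node_mask=self.free,
            viscous_cap=self._viscous_cap,
        )
        f += cres.node_forces
        # mass-proportional damping
        damp = -self.alpha * self.masses[:, None] * v
        f += damp
        if cfg.gravity_on_muscle:
            f[:, 2] -= self.masses * cfg.gravity
        f_sphere = -self.sphere.mass * cfg.gravity + (
            cres.sphere_reaction[2] if cfg.contact.enabled else 0.0
        )
        return f, f_sphere, cres, damp

    def step(self, state: SimState, dt: float) -> SimState:
        """One central-difference step (functional form used by tests; the
        production loop in :meth:`run` is the same update, fused)."""
        new = SimState(
            time=state.time,
            u=state.u.copy(),
            v=state.v.copy(),
            sphere_z=state.sphere_z,
            sphere_v=state.sphere_v,
            ledger=replace(state.ledger),
        )
        self._advance(new, dt)
        return new

    def _advance(self, st: SimState, dt: float) -> None:
        f, f_sphere, cres, _ = self._forces(st.u, st.v, st.sphere_z, st.sphere_v, dt)
        a = f / self.masses[:, None]
        a[~self.free] = 0.0
        v_old = st.v.copy()
        st.v = st.v + dt * a
        st.v[~self.free] = 0.0
        st.u = st.u + dt * st.v
        a_s = f_sphere / self.sphere.mass
        sv_old = st.sphere_v
        st.sphere_v = st.sphere_v + dt * a_s
        st.sphere_z = st.sphere_z + dt * st.sphere_v
        st.time += dt
        # ledger: dissipations accumulate; conservative terms are state funcs
        vbar = 0.5 * (v_old + st.v)
        st.ledger.friction_dissipation += cres.dissipation_increment
        st.ledger.damping_dissipation += float(
            (self.alpha * np.einsum("n,ni,ni->", self.masses, vbar, vbar)
             + self._last_visc_power) * dt
        )
        self._refresh_state_energies(st, cres.spring_energy)

    def _refresh_state_energies(self, st: SimState, spring: float) -> None:
        cfg = self.config
        st.ledger.kinetic = float(
            0.5 * np.einsum("n,ni,ni->", self.masses, st.v, st.v)
            + 0.5 * self.sphere.mass * st.sphere_v ** 2
        )
        st.ledger.strain = self.kernel.strain_energy(st.u)
        st.ledger.contact_spring = spring
        w = self.sphere.mass * cfg.gravity * (self.sphere.center[2] - st.sphere_z)
        if cfg.gravity_on_muscle:
            w += cfg.gravity * float(np.dot(self.masses, -st.u[:, 2]))
        st.ledger.external_work = float(w)

    # -- full run --------------------------------------------------------

    def run(self) -> RunResult:
        cfg = self.config
        n_snap = int(round(cfg.duration / cfg.snapshot_interval))
        snap_times = cfg.snapshot_interval * np.arange(1, n_snap + 1)

        st = self.initialize()
        snapshots = [self._snapshot(st)]
        mon_rows = [self._monitor_row(st, 0.0)]
        max_pen_run = 0.0
        t = 0.0
        dt_prev = 0.0          # interval behind the current velocity half-step
        istep = 0
        isnap = 0
        tiny = 1e-12

        while t < cfg.duration - tiny:
            istep += 1
            # dt=1 makes the contact dissipation increment a power; it is
            # scaled by the actual step below once dt is chosen
            f, f_sphere, cres, _ = self._forces(st.u, st.v, st.sphere_z, st.sphere_v, 1.0)
            # joint stability bound: elastic (with stretch stiffening) and
            # penalty frequencies add in quadrature on a contacting node;
            # the penalty cap engages only once contact is active or within
            # one generous step of starting
            dt_el = self._dt_mesh / self._stiffening_factor(self._last_trc)
            near = cres.n_active > 0
            if not near:
                top = float((self.mesh.node_coords[:, 2] + st.u[:, 2])[self.free].max())
                clearance = (st.sphere_z - self.sphere.radius) - top
                near = clearance < 2.0 * abs(st.sphere_v) * dt_el + 1.0
            if near:
                dt = 1.0 / math.sqrt(dt_el ** -2 + self._dt_contact ** -2)
            else:
                dt = dt_el
            next_stop = snap_times[isnap] if isnap < n_snap else cfg.duration
            dt = min(dt, next_stop - t)
            a = f / self.masses[:, None]
            a[~self.free] = 0.0
            v_old = st.v
            # variable-step leapfrog: velocity advances over the midpoint span
            st.v = st.v + 0.5 * (dt_prev + dt) * a
            st.v[~self.free] = 0.0
            st.u = st.u + dt * st.v
            st.sphere_v = st.sphere_v + 0.5 * (dt_prev + dt) * f_sphere / self.sphere.mass
            st.sphere_z = st.sphere_z + dt * st.sphere_v
            t += dt
            st.time = t
            dt_prev = dt
            vbar = 0.5 * (v_old + st.v)
            st.ledger.friction_dissipation += cres.dissipation_increment * dt
            st.ledger.damping_dissipation += float(
                (self.alpha * np.einsum("n,ni,ni->", self.masses, vbar, vbar)
                 + self._last_visc_power) * dt
            )
            max_pen_run = max(max_pen_run, cres.max_penetration)

            if not np.isfinite(st.u).all() or np.abs(st.u).max() > 10.0 * self.model_size:
                raise InstabilityError(
                    f"explicit integration diverged at t={st.time:.5f} s "
                    f"with dt={dt:.3e} s",
                    dt=dt,
                )
            at_snap = isnap < n_snap and t >= snap_times[isnap] - tiny
            if istep % cfg.monitor_every == 0 or at_snap or t >= cfg.duration - tiny:
                self._refresh_state_energies(st, cres.spring_energy)
                mon_rows.append(self._monitor_row(st, max_pen_run))
                if at_snap:
                    snapshots.append(self._snapshot(st))
                    isnap += 1
        n_steps = istep
        dt = dt_prev

        monitors = MonitorSeries(
            time=np.array([r[0] for r in mon_rows]),
            peak_von_mises=np.array([r[1] for r in mon_rows]),
            peak_principal_stress=np.array([r[2] for r in mon_rows]),
            peak_principal_strain=np.array([r[3] for r in mon_rows]),
            max_uz=np.array([r[4] for r in mon_rows]),
            ux_span=np.array([r[5] for r in mon_rows]),
            max_penetration=np.array([r[6] for r in mon_rows]),
            energy_residual=np.array([r[7] for r in mon_rows]),
            sphere_drop=np.array([r[8] for r in mon_rows]),
        )
        stats = {
            "dt": dt,
            "n_steps": n_steps,
            "penalty_stiffness": self.penalty,
            "mass_damping_alpha": self.alpha,
            "max_penetration": max_pen_run,
            "energy_residual_max": float(np.abs(monitors.energy_residual).max()),
            "external_work_peak": float(
                max(abs(st.ledger.external_work), 1e-30)
            ),
            "sphere_drop": float(self.sphere.center[2] - st.sphere_z),
        }
        return RunResult(snapshots=snapshots, monitors=monitors, final_state=st, stats=stats)

    # -- sampling helpers ------------------------------------------------

    def _snapshot(self, st: SimState) -> FieldSnapshot:
        return FieldSnapshot(
            time=st.time,
            u=st.u.copy(),
            cauchy_stress=self.kernel.cauchy_stresses(st.u),
            green_strain=self.kernel.green_strains(st.u),
            sphere_z=st.sphere_z,
        )

    def _monitor_row(self, st: SimState, max_pen: float):
        sig = self.kernel.cauchy_stresses(st.u)
        eps = self.kernel.green_strains(st.u)
        vm = float(_von_mises_batch(sig).max())
        ps = float(np.linalg.eigvalsh(sig)[:, -1].max())
        pe = float(np.linalg.eigvalsh(eps)[:, -1].max())
        max_uz = float(np.max(-st.u[:, 2]))
        ux = st.u[:, 0]
        span = float(ux.max() - ux.min())
        return (
            st.time,
            vm,
            ps,
            pe,
            max_uz,
            span,
            max_pen,
            st.ledger.residual(),
            float(self.sphere.center[2] - st.sphere_z),
        )


def initialize(
    mesh: Mesh, material: MaterialParams, sphere: RigidSphere, config: SimulationConfig
) -> SimState:
    """Build a zeroed initial state (raises on initial penetration)."""
    return ExplicitSim(mesh, material, sphere, config).initialize()


def run(
    mesh: Mesh, material: MaterialParams, sphere: RigidSphere, config: SimulationConfig
) -> RunResult:
    """Run the full simulation; snapshots on the configured schedule plus a
    dense monitor series.  Deterministic for fixed inputs."""
    return ExplicitSim(mesh, material, sphere, config).run()
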