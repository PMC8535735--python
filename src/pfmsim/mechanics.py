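"""Material law, tetrahedral element kinematics and internal-force kernels.

The muscle is modelled as a Saint Venant-Kirchhoff solid: the isotropic
linear-elastic law (two constants E, nu) expressed in the Green-Lagrange
strain measure, so the published small-strain constants remain valid under
the large rotations and stretches of head passage while the response stays
objective.  A strict small-strain (engineering) mode is retained for
verification against textbook linear elasticity.

Units: mm-ton-s-MPa.  Stresses in MPa, densities in ton/mm^3, forces in N.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .errors import InvalidParameterError, MeshingError
from .geometry import Mesh

try:  # pragma: no cover - exercised implicitly
    from numba import njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False

    def njit(*args, **kwargs):  # type: ignore[misc]
        def wrap(fn):
            return fn

        return wrap if not (args and callable(args[0])) else args[0]

__all__ = [
    "MaterialParams",
    "ElementState",
    "lame_constants",
    "sphere_mass",
    "lumped_nodal_masses",
    "green_strain",
    "svk_stress",
    "cauchy_from_pk2",
    "element_internal_forces",
    "strain_energy_density",
    "dilatational_wave_speed",
    "stable_dt",
    "TetKernel",
]


@dataclass(frozen=True)
class MaterialParams:
    """Isotropic elastic constants; defaults are the pelvic-floor-muscle row
    of the published material table."""

    young_modulus: float = 0.2        # MPa
    poisson_ratio: float = 0.4
    density: float = 1.12e-9          # ton/mm^3

    def __post_init__(self):
        if self.young_modulus <= 0.0:
            raise InvalidParameterError(f"young_modulus must be > 0, got {self.young_modulus}")
        if not 0.0 < self.poisson_ratio < 0.5:
            raise InvalidParameterError(
                f"poisson_ratio must lie strictly in (0, 0.5), got {self.poisson_ratio}"
            )
        if self.density <= 0.0:
            raise InvalidParameterError(f"density must be > 0, got {self.density}")


@dataclass
class ElementState:
    """Per-element kinematic and stress state."""

    deformation_gradient: np.ndarray   # (3, 3)
    green_strain: np.ndarray           # (3, 3) symmetric
    pk2_stress: np.ndarray             # (3, 3) symmetric, MPa
    cauchy_stress: np.ndarray          # (3, 3) symmetric, MPa


def lame_constants(material: MaterialParams) -> tuple[float, float]:
    """(lambda, mu) from (E, nu)."""
    e, nu = material.young_modulus, material.poisson_ratio
    lam = e * nu / ((1.0 + nu) * (1.0 - 2.0 * nu))
    mu = e / (2.0 * (1.0 + nu))
    return lam, mu


def sphere_mass(diameter: float, density: float) -> float:
    """Mass of a solid sphere, (pi/6) D^3 rho (ton for mm and ton/mm^3)."""
    if diameter <= 0.0:
        raise InvalidParameterError(f"diameter must be > 0, got {diameter}")
    if density < 0.0:
        raise InvalidParameterError(f"density must be >= 0, got {density}")
    return math.pi / 6.0 * diameter ** 3 * density


def lumped_nodal_masses(mesh: Mesh, material: MaterialParams) -> np.ndarray:
    """Row-sum (equal-split) lumped masses: each tet contributes rho*V/4 to
    its four nodes.  Total equals rho * mesh volume to machine precision."""
    vols = mesh.tet_volumes()
    if np.any(vols <= 0.0):
        raise MeshingError("non-positive element volume in mass lumping")
    contrib = material.density * vols / 4.0
    masses = np.zeros(mesh.n_nodes)
    np.add.at(masses, mesh.tets.ravel(), np.repeat(contrib, 4))
    return masses


def green_strain(f: np.ndarray) -> np.ndarray:
    """Green-Lagrange strain E = (F^T F - I) / 2."""
    f = np.asarray(f, dtype=float)
    eye = np.eye(3)
    return 0.5 * (f.swapaxes(-1, -2) @ f - eye)


def svk_stress(strain: np.ndarray, material: MaterialParams) -> np.ndarray:
    """Second Piola-Kirchhoff stress of the Saint Venant-Kirchhoff law:
    S = lambda tr(E) I + 2 mu E."""
    lam, mu = lame_constants(material)
    strain = np.asarray(strain, dtype=float)
    tr = np.trace(strain, axis1=-2, axis2=-1)
    return lam * tr[..., None, None] * np.eye(3) + 2.0 * mu * strain


def cauchy_from_pk2(f: np.ndarray, s: np.ndarray) -> np.ndarray:
    """Push-forward sigma = F S F^T / det(F)."""
    f = np.asarray(f, dtype=float)
    s = np.asarray(s, dtype=float)
    det = np.linalg.det(f)
    if np.any(det <= 0.0):
        raise MeshingError("inverted configuration: det(F) <= 0")
    sig = f @ s @ f.swapaxes(-1, -2) / det[..., None, None]
    return 0.5 * (sig + sig.swapaxes(-1, -2))


def strain_energy_density(strain: np.ndarray, material: MaterialParams) -> np.ndarray:
    """SVK energy per unit reference volume: lambda/2 tr(E)^2 + mu E:E (MPa)."""
    lam, mu = lame_constants(material)
    strain = np.asarray(strain, dtype=float)
    tr = np.trace(strain, axis1=-2, axis2=-1)
    return 0.5 * lam * tr ** 2 + mu * np.einsum("...ij,...ij->...", strain, strain)


def _reference_gradients(ref_coords: np.ndarray) -> tuple[np.ndarray, float]:
    """Shape-function gradients (4, 3) and reference volume of one tet."""
    d = (ref_coords[1:] - ref_coords[0]).T      # 3x3, columns are edges
    vol = np.linalg.det(d) / 6.0
    if vol <= 0.0:
        raise MeshingError(f"non-positive reference volume {vol:.3e}")
    dinv = np.linalg.inv(d)
    grads = np.empty((4, 3))
    grads[1:] = dinv
    grads[0] = -dinv.sum(axis=0)
    return grads, vol


def element_internal_forces(
    ref_coords: np.ndarray,
    displacements: np.ndarray,
    material: MaterialParams,
    small_strain: bool = False,
) -> tuple[np.ndarray, ElementState]:
    """Internal nodal forces of one linear tet (total-Lagrangian SVK kernel).

    Forces are the negative gradient of the element strain energy with
    respect to nodal positions; they sum to zero.  ``small_strain=True``
    switches to the engineering-strain law (verification only; not
    objective under finite rotation).
    """
    ref = np.asarray(ref_coords, dtype=float).reshape(4, 3)
    u = np.asarray(displacements, dtype=float).reshape(4, 3)
    grads, vol = _reference_gradients(ref)
    f = np.eye(3) + u.T @ grads                      # F_ij = d x_i / d X_j
    if small_strain:
        grad_u = u.T @ grads
        strain = 0.5 * (grad_u + grad_u.T)
        s = svk_stress(strain, material)
        p = s                                        # engineering stress
    else:
        strain = green_strain(f)
        s = svk_stress(strain, material)
        p = f @ s                                    # first Piola-Kirchhoff
    forces = -vol * grads @ p.T                      # (4, 3)
    det = np.linalg.det(f)
    if det <= 0.0:
        raise MeshingError("inverted current configuration: det(F) <= 0")
    state = ElementState(
        deformation_gradient=f,
        green_strain=green_strain(f),
        pk2_stress=s,
        cauchy_stress=cauchy_from_pk2(f, svk_stress(green_strain(f), material)),
    )
    return forces, state


def dilatational_wave_speed(material: MaterialParams) -> float:
    """c = sqrt(E (1-nu) / ((1+nu)(1-2nu) rho)) in mm/s."""
    e, nu, rho = material.young_modulus, material.poisson_ratio, material.density
    return math.sqrt(e * (1.0 - nu) / ((1.0 + nu) * (1.0 - 2.0 * nu) * rho))


def stable_dt(
    mesh: Mesh,
    material: MaterialParams,
    cfl_factor: float = 1.0,
    length_measure: str = "edge",
) -> float:
    """CFL-stable explicit step: cfl * characteristic length / wave speed.

    ``length_measure`` selects the element characteristic length: "edge"
    (minimum edge, the textbook estimate) or "altitude" (minimum altitude
    3V/A_max, conservative for sheared elements).
    """
    if not 0.0 < cfl_factor <= 1.0:
        raise InvalidParameterError(f"cfl_factor must lie in (0, 1], got {cfl_factor}")
    if length_measure == "edge":
        h = mesh.min_edge()
    elif length_measure == "altitude":
        h = mesh.min_altitude()
    else:
        raise InvalidParameterError(f"unknown length_measure {length_measure!r}")
    return cfl_factor * h / dilatational_wave_speed(material)


@njit(cache=True, fastmath=True)
def _svk_forces_loop(u, v, tets, grads, vols, etas, lam, mu, out):  # pragma: no cover
    """Serial total-Lagrangian SVK force assembly (compiled hot loop) with
    optional element strain-rate viscosity (etas, MPa*s per element; damps
    element-level ringing, objective because a rigid rotation has zero
    Green-strain rate).

    Returns (max trace(F^T F), viscous dissipation power): the trace bounds
    the squared principal stretch for adaptive step control.
    """
    out[:] = 0.0
    max_trc = 0.0
    visc_power = 0.0
    n_e = tets.shape[0]
    f = np.empty((3, 3))
    fdot = np.empty((3, 3))
    c = np.empty((3, 3))
    edot = np.empty((3, 3))
    s = np.empty((3, 3))
    p = np.empty((3, 3))
    use_visc = v.shape[0] == u.shape[0]
    for e in range(n_e):
        for i in range(3):
            for j in range(3):
                acc = 1.0 if i == j else 0.0
                for a in range(4):
                    acc += u[tets[e, a], i] * grads[e, a, j]
                f[i, j] = acc
        for i in range(3):
            for j in range(3):
                acc = 0.0
                for k in range(3):
                    acc += f[k, i] * f[k, j]
                c[i, j] = acc
        trc = c[0, 0] + c[1, 1] + c[2, 2]
        if trc > max_trc:
            max_trc = trc
        tr = 0.5 * (trc - 3.0)
        for i in range(3):
            for j in range(3):
                e_ij = 0.5 * (c[i, j] - (1.0 if i == j else 0.0))
                s[i, j] = 2.0 * mu * e_ij + (lam * tr if i == j else 0.0)
        if use_visc:
            eta = etas[e]
            for i in range(3):
                for j in range(3):
                    acc = 0.0
                    for a in range(4):
                        acc += v[tets[e, a], i] * grads[e, a, j]
                    fdot[i, j] = acc
            # Green-strain rate sym(F^T Fdot); viscous PK2 = eta * Edot
            for i in range(3):
                for j in range(3):
                    acc = 0.0
                    for k in range(3):
                        acc += 0.5 * (f[k, i] * fdot[k, j] + f[k, j] * fdot[k, i])
                    edot[i, j] = acc
            for i in range(3):
                for j in range(3):
                    s[i, j] += eta * edot[i, j]
                    visc_power += vols[e] * eta * edot[i, j] * edot[i, j]
        for i in range(3):
            for j in range(3):
                acc = 0.0
                for k in range(3):
                    acc += f[i, k] * s[k, j]
                p[i, j] = acc
        vol = vols[e]
        for a in range(4):
            node = tets[e, a]
            for i in range(3):
                acc = 0.0
                for j in range(3):
                    acc += grads[e, a, j] * p[i, j]
                out[node, i] -= vol * acc
    return max_trc, visc_power


class TetKernel:
    """Vectorized total-Lagrangian SVK kernel over a whole mesh.

    Precomputes reference shape-function gradients and volumes once; per
    step evaluates deformation gradients, internal forces and the strain
    energy for a given displacement field.
    """

    def __init__(self, mesh: Mesh, material: MaterialParams):
        self.mesh = mesh
        self.material = material
        x = mesh.node_coords[mesh.tets]              # (E, 4, 3)
        d = (x[:, 1:] - x[:, :1]).transpose(0, 2, 1)  # (E, 3, 3) edge columns
        vols = np.linalg.det(d) / 6.0
        if np.any(vols <= 0.0):
            raise MeshingError("non-positive reference volume in kernel setup")
        dinv = np.linalg.inv(d)
        grads = np.empty((mesh.n_tets, 4, 3))
        grads[:, 1:, :] = dinv
        grads[:, 0, :] = -dinv.sum(axis=1)
        self.grads = grads
        self.vols = vols
        self.lam, self.mu = lame_constants(material)
        self._flat = mesh.tets.ravel()
        self._eye = np.eye(3)
        self.etas: np.ndarray | None = None

    def enable_viscosity(self, fraction: float) -> None:
        """Element strain-rate viscosity eta_e = fraction * rho * c * h_e
        (h_e: element altitude); a standard explicit-dynamics stabilizer
        that damps element-level ringing without affecting slow response."""
        if fraction <= 0.0:
            self.etas = None
            return
        x = self.mesh.node_coords[self.mesh.tets]
        faces = [(1, 2, 3), (0, 2, 3), (0, 1, 3), (0, 1, 2)]
        amax = np.zeros(self.mesh.n_tets)
        for (i, j, k) in faces:
            area = 0.5 * np.linalg.norm(
                np.cross(x[:, j] - x[:, i], x[:, k] - x[:, i]), axis=1
            )
            amax = np.maximum(amax, area)
        h = 3.0 * self.vols / amax
        c = dilatational_wave_speed(self.material)
        self.etas = fraction * self.material.density * c * h

    def deformation_gradients(self, u: np.ndarray) -> np.ndarray:
        ue = u[self.mesh.tets]                       # (E, 4, 3)
        return self._eye + np.einsum("eai,eaj->eij", ue, self.grads)

    def green_strains(self, u: np.ndarray) -> np.ndarray:
        f = self.deformation_gradients(u)
        return 0.5 * (np.einsum("eki,ekj->eij", f, f) - self._eye)

    def _pk2(self, strain: np.ndarray) -> np.ndarray:
        tr = np.trace(strain, axis1=1, axis2=2)
        return self.lam * tr[:, None, None] * self._eye + 2.0 * self.mu * strain

    def internal_forces(self, u: np.ndarray) -> np.ndarray:
        """Assembled nodal internal forces (N, 3) for displacements u."""
        return self.internal_forces_ex(u)[0]

    def internal_forces_ex(
        self, u: np.ndarray, v: np.ndarray | None = None
    ) -> tuple[np.ndarray, float, float]:
        """(forces, max trace(F^T F), viscous power).  The trace bounds the
        squared principal stretch and drives adaptive step control; passing
        nodal velocities activates the element strain-rate viscosity."""
        vv = (
            np.ascontiguousarray(v)
            if (v is not None and self.etas is not None)
            else np.empty((0, 3))
        )
        if _HAVE_NUMBA:
            out = np.empty((self.mesh.n_nodes, 3))
            trc, visc = _svk_forces_loop(
                np.ascontiguousarray(u), vv, self.mesh.tets, self.grads,
                self.vols,
                self.etas if self.etas is not None else np.zeros(self.mesh.n_tets),
                self.lam, self.mu, out,
            )
            return out, float(trc), float(visc)
        f = self.deformation_gradients(u)
        strain = 0.5 * (np.einsum("eki,ekj->eij", f, f) - self._eye)
        s = self._pk2(strain)
        visc = 0.0
        if vv.shape[0] == u.shape[0]:
            fdot = np.einsum("eai,eaj->eij", vv[self.mesh.tets], self.grads)
            edot = 0.5 * (
                np.einsum("eki,ekj->eij", f, fdot)
                + np.einsum("ekj,eki->eij", f, fdot)
            )
            s = s + self.etas[:, None, None] * edot
            visc = float(
                np.einsum("e,e,eij,eij->", self.vols, self.etas, edot, edot)
            )
        p = np.einsum("eik,ejk->eij", f, s)          # F S (S symmetric)
        contrib = -self.vols[:, None, None] * np.einsum(
            "eaj,eij->eai", self.grads, p
        )                                            # (E, 4, 3)
        flat = contrib.reshape(-1, 3)
        out = np.empty((self.mesh.n_nodes, 3))
        for c in range(3):
            out[:, c] = np.bincount(
                self._flat, weights=flat[:, c], minlength=self.mesh.n_nodes
            )
        trc = float(np.einsum("eij,eij->e", f, f).max())
        return out, trc, visc

    def strain_energy(self, u: np.ndarray) -> float:
        strain = self.green_strains(u)
        psi = 0.5 * self.lam * np.trace(strain, axis1=1, axis2=2) ** 2 + self.mu * np.einsum(
            "eij,eij->e", strain, strain
        )
        return float(np.dot(self.vols, psi))

    def cauchy_stresses(self, u: np.ndarray) -> np.ndarray:
        f = self.deformation_gradients(u)
        strain = 0.5 * (np.einsum("eki,ekj->eij", f, f) - self._eye)
        s = self._pk2(strain)
        det = np.linalg.det(f)
        sig = np.einsum("eik,ekl,ejl->eij", f, s, f) / det[:, None, None]
        return 0.5 * (sig + sig.transpose(0, 2, 1))

    def max_principal_stretch_sq(self, u: np.ndarray) -> float:
        """Largest eigenvalue of C = F^T F over all elements (squared stretch);
        used to bound the tangent-stiffness growth of the SVK law."""
        f = self.deformation_gradients(u)
        c = np.einsum("eki,ekj->eij", f, f)
        return float(np.linalg.eigvalsh(c)[:, -1].max())
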