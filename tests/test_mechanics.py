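"""Constitutive law, element kernels, mass lumping and step estimates,
checked against closed forms and independent finite-difference oracles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import pfmsim as pm
from pfmsim.errors import InvalidParameterError
from pfmsim.mechanics import (
    TetKernel,
    lame_constants,
    strain_energy_density,
)


def rotation(axis, angle):
    axis = np.asarray(axis, float)
    axis /= np.linalg.norm(axis)
    k = np.array(
        [[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]], [-axis[1], axis[0], 0]]
    )
    return np.eye(3) + np.sin(angle) * k + (1 - np.cos(angle)) * (k @ k)


class TestSphereMass:
    def test_d90_is_three_kilograms(self):
        assert pm.sphere_mass(90.0, 7.86e-9) == pytest.approx(3.000e-3, rel=1e-3)

    def test_d80_closed_form(self):
        assert pm.sphere_mass(80.0, 7.86e-9) == pytest.approx(2.107e-3, rel=1e-3)

    def test_zero_density(self):
        assert pm.sphere_mass(50.0, 0.0) == 0.0

    def test_invalid_diameter(self):
        with pytest.raises(InvalidParameterError):
            pm.sphere_mass(-1.0, 1.0)


class TestMassLumping:
    def test_total_mass_conserved(self, mesh3, material):
        masses = pm.lumped_nodal_masses(mesh3, material)
        assert masses.sum() == pytest.approx(
            material.density * mesh3.total_volume, rel=1e-12
        )
        assert np.all(masses > 0.0)

    def test_single_tet_split(self, material):
        # unit-volume tet: each node receives rho/4
        coords = np.array(
            [[0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 6.0]], dtype=float
        )  # volume = 1 mm^3
        mesh = pm.Mesh(node_coords=coords, tets=np.array([[0, 1, 2, 3]]))
        masses = pm.lumped_nodal_masses(mesh, pm.MaterialParams(density=1.12e-9))
        assert np.allclose(masses, 2.8e-10)

    def test_density_linearity(self, mesh3, material):
        m1 = pm.lumped_nodal_masses(mesh3, material)
        m2 = pm.lumped_nodal_masses(
            mesh3, pm.MaterialParams(density=2 * material.density)
        )
        assert np.allclose(m2, 2 * m1)


class TestStrainAndStress:
    def test_green_strain_identity(self):
        assert np.allclose(pm.green_strain(np.eye(3)), 0.0)

    def test_green_strain_uniaxial(self):
        lam = 1.3
        e = pm.green_strain(np.diag([lam, 1.0, 1.0]))
        assert e[0, 0] == pytest.approx((lam ** 2 - 1) / 2)
        assert abs(e).sum() == pytest.approx(e[0, 0])

    def test_green_strain_rotation_objectivity(self):
        r = rotation([1, 2, 3], 0.9)
        assert np.allclose(pm.green_strain(r), 0.0, atol=1e-12)

    def test_lame_constants_of_published_material(self, material):
        lam, mu = lame_constants(material)
        assert lam == pytest.approx(0.2857, rel=1e-3)
        assert mu == pytest.approx(0.07143, rel=1e-3)

    def test_svk_zero_strain(self, material):
        assert np.allclose(pm.svk_stress(np.zeros((3, 3)), material), 0.0)

    def test_incompressible_limit_rejected(self):
        with pytest.raises(InvalidParameterError):
            pm.MaterialParams(poisson_ratio=0.5)

    def test_small_strain_uniaxial_slope_is_young_modulus(self, material):
        """Lateral-free uniaxial response at 0.1% strain: S11/eps -> E
        within 0.5% (fixed-point iteration on the lateral strains)."""
        eps = 1e-3
        lat = -material.poisson_ratio * eps
        for _ in range(60):
            s = pm.svk_stress(np.diag([eps, lat, lat]), material)
            lam, mu = lame_constants(material)
            lat = lat - s[1, 1] / (lam + 2 * mu)
        s = pm.svk_stress(np.diag([eps, lat, lat]), material)
        assert abs(s[1, 1]) < 1e-10 and abs(s[2, 2]) < 1e-10
        assert s[0, 0] / eps == pytest.approx(material.young_modulus, rel=5e-3)

    def test_cauchy_identity_map(self, material):
        s = np.diag([1.0, 2.0, 3.0])
        assert np.allclose(pm.cauchy_from_pk2(np.eye(3), s), s)

    def test_cauchy_rotation_preserves_invariants(self, material):
        s = np.array([[1.0, 0.2, 0.0], [0.2, -0.5, 0.1], [0.0, 0.1, 2.0]])
        r = rotation([0, 1, 1], 1.1)
        sig = pm.cauchy_from_pk2(r, s)
        assert np.allclose(sig, r @ s @ r.T)
        assert np.allclose(np.sort(np.linalg.eigvalsh(sig)),
                           np.sort(np.linalg.eigvalsh(s)))

    def test_von_mises_matches_eigenvalue_oracle(self, material):
        rng = np.random.default_rng(3)
        for _ in range(50):
            f = np.eye(3) + 0.3 * rng.normal(size=(3, 3))
            if np.linalg.det(f) <= 0.1:
                continue
            s = pm.svk_stress(pm.green_strain(f), material)
            sig = pm.cauchy_from_pk2(f, s)
            ev = np.linalg.eigvalsh(sig)
            oracle = np.sqrt(
                0.5 * ((ev[0] - ev[1]) ** 2 + (ev[1] - ev[2]) ** 2 + (ev[2] - ev[0]) ** 2)
            )
            assert pm.von_mises(sig) == pytest.approx(oracle, abs=1e-10)


class TestElementForces:
    def test_zero_displacement_zero_force(self, single_tet, material):
        forces, state = pm.element_internal_forces(
            single_tet, np.zeros((4, 3)), material
        )
        assert np.allclose(forces, 0.0)
        assert np.allclose(state.cauchy_stress, 0.0)

    def test_rigid_rotation_is_force_free(self, single_tet, material):
        r = rotation([1, 1, 0], 1.3)
        disp = single_tet @ r.T - single_tet
        forces, _ = pm.element_internal_forces(single_tet, disp, material)
        scale = material.young_modulus * 9.0  # E x area scale (3 mm edges)
        assert np.abs(forces).max() < 1e-8 * scale

    def test_forces_sum_to_zero(self, single_tet, material):
        rng = np.random.default_rng(11)
        disp = 0.3 * rng.normal(size=(4, 3))
        forces, _ = pm.element_internal_forces(single_tet, disp, material)
        assert np.allclose(forces.sum(axis=0), 0.0, atol=1e-12)

    def test_forces_match_energy_gradient(self, single_tet, material):
        """Central finite differences of the element strain energy reproduce
        the internal forces to relative 1e-4."""
        from pfmsim.mechanics import _reference_gradients

        grads, vol = _reference_gradients(single_tet)

        def energy(disp):
            f = np.eye(3) + disp.T @ grads
            return vol * strain_energy_density(pm.green_strain(f), material)

        rng = np.random.default_rng(5)
        disp = 0.15 * rng.normal(size=(4, 3))
        forces, _ = pm.element_internal_forces(single_tet, disp, material)
        h = 1e-6
        for a in range(4):
            for i in range(3):
                dp = disp.copy(); dp[a, i] += h
                dm = disp.copy(); dm[a, i] -= h
                grad = (energy(dp) - energy(dm)) / (2 * h)
                assert -grad == pytest.approx(forces[a, i], rel=1e-4, abs=1e-12)

    def test_batch_kernel_matches_single_element(self, mesh3, material):
        kernel = TetKernel(mesh3, material)
        rng = np.random.default_rng(9)
        u = 0.05 * rng.normal(size=mesh3.node_coords.shape)
        assembled = kernel.internal_forces(u)
        e = 17
        ref = mesh3.node_coords[mesh3.tets[e]]
        forces, _ = pm.element_internal_forces(ref, u[mesh3.tets[e]], material)
        # element contribution recovered from a one-element mesh
        sub = pm.Mesh(node_coords=ref.copy(), tets=np.array([[0, 1, 2, 3]]))
        single = TetKernel(sub, material).internal_forces(u[mesh3.tets[e]])
        assert np.allclose(single, forces, atol=1e-12)
        assert assembled.shape == mesh3.node_coords.shape


class TestWaveSpeedAndStep:
    def test_dilatational_wave_speed_closed_form(self, material):
        assert pm.dilatational_wave_speed(material) == pytest.approx(1.956e4, rel=1e-3)

    def test_stable_dt_edge_formula(self, mesh3, material):
        dt = pm.stable_dt(mesh3, material, cfl_factor=1.0)
        assert dt == pytest.approx(
            mesh3.min_edge() / pm.dilatational_wave_speed(material), rel=1e-12
        )

    def test_two_millimetre_edge_reference_value(self, material):
        # a 2 mm minimum edge gives dt ~ 1.02e-4 s at unit CFL
        c = pm.dilatational_wave_speed(material)
        assert 2.0 / c == pytest.approx(1.02e-4, rel=5e-3)

    def test_halving_cfl_halves_dt(self, mesh3, material):
        full = pm.stable_dt(mesh3, material, cfl_factor=1.0)
        half = pm.stable_dt(mesh3, material, cfl_factor=0.5)
        assert half == pytest.approx(full / 2)

    def test_invalid_cfl(self, mesh3, material):
        with pytest.raises(InvalidParameterError):
            pm.stable_dt(mesh3, material, cfl_factor=0.0)


@settings(max_examples=25, deadline=None)
@given(
    angle=st.floats(0.0, 3.1),
    ax=st.tuples(
        st.floats(-1, 1), st.floats(-1, 1), st.floats(0.1, 1)
    ),
    stretch=st.floats(0.7, 1.8),
)
def test_energy_rotation_invariance(angle, ax, stretch):
    """Strain energy depends only on the stretch, never on superposed
    rigid rotation; it vanishes iff the Green strain vanishes."""
    material = pm.MaterialParams()
    f = np.diag([stretch, 1.0, 1.0])
    r = rotation(np.asarray(ax), angle)
    e1 = strain_energy_density(pm.green_strain(f), material)
    e2 = strain_energy_density(pm.green_strain(r @ f), material)
    assert e2 == pytest.approx(e1, rel=1e-9, abs=1e-15)
    if abs(stretch - 1.0) > 1e-6:
        assert e1 > 0.0
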