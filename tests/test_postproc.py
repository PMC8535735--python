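"""Invariant extraction and the metrics report, including the published
extension-ratio arithmetic."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import pfmsim as pm
from pfmsim.errors import InvalidParameterError
from pfmsim.simulator import FieldSnapshot, MonitorSeries


def rotation(axis, angle):
    axis = np.asarray(axis, float)
    axis /= np.linalg.norm(axis)
    k = np.array(
        [[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]], [-axis[1], axis[0], 0]]
    )
    return np.eye(3) + np.sin(angle) * k + (1 - np.cos(angle)) * (k @ k)


class TestVonMises:
    def test_uniaxial(self):
        assert pm.von_mises(np.diag([2.5, 0, 0])) == pytest.approx(2.5)

    def test_hydrostatic_is_null(self):
        assert pm.von_mises(3.7 * np.eye(3)) == pytest.approx(0.0, abs=1e-12)

    def test_pure_shear(self):
        tau = 0.8
        t = np.zeros((3, 3)); t[0, 1] = t[1, 0] = tau
        assert pm.von_mises(t) == pytest.approx(np.sqrt(3) * tau)

    def test_asymmetric_input_rejected(self):
        t = np.zeros((3, 3)); t[0, 1] = 1.0
        with pytest.raises(InvalidParameterError):
            pm.von_mises(t)


class TestMaxPrincipal:
    def test_diagonal(self):
        assert pm.max_principal(np.diag([3.0, 1.0, -2.0])) == pytest.approx(3.0)

    def test_embedded_two_by_two_block(self):
        a, b = 1.2, 0.7
        t = np.diag([a, a, -5.0]).astype(float)
        t[0, 1] = t[1, 0] = b
        assert pm.max_principal(t) == pytest.approx(a + abs(b))

    def test_thousand_random_tensors_match_root_oracle(self):
        """Largest eigenvalue agrees with the characteristic-polynomial
        root oracle to 1e-10."""
        rng = np.random.default_rng(123)
        for _ in range(1000):
            m = rng.normal(size=(3, 3))
            t = 0.5 * (m + m.T)
            i1 = np.trace(t)
            i2 = 0.5 * (i1 ** 2 - np.trace(t @ t))
            i3 = np.linalg.det(t)
            roots = np.roots([1.0, -i1, i2, -i3])
            oracle = np.max(roots.real)
            assert pm.max_principal(t) == pytest.approx(oracle, abs=1e-10)


@settings(max_examples=40, deadline=None)
@given(
    angle=st.floats(0, 3.1),
    ax=st.tuples(st.floats(-1, 1), st.floats(-1, 1), st.floats(0.1, 1)),
)
def test_invariants_are_rotation_invariant(angle, ax):
    t = np.array([[1.0, 0.3, -0.2], [0.3, -0.7, 0.5], [-0.2, 0.5, 2.0]])
    r = rotation(np.asarray(ax), angle)
    tr = r @ t @ r.T
    tr = 0.5 * (tr + tr.T)
    assert abs(pm.von_mises(tr) - pm.von_mises(t)) < 1e-10
    assert abs(pm.max_principal(tr) - pm.max_principal(t)) < 1e-10


def make_monitors(times, uz, ux, vm=None, ps=None, pe=None):
    n = len(times)
    z = np.zeros(n)
    return MonitorSeries(
        time=np.asarray(times, float),
        peak_von_mises=np.asarray(vm if vm is not None else z, float),
        peak_principal_stress=np.asarray(ps if ps is not None else z, float),
        peak_principal_strain=np.asarray(pe if pe is not None else z, float),
        max_uz=np.asarray(uz, float),
        ux_span=np.asarray(ux, float),
        max_penetration=z.copy(),
        energy_residual=z.copy(),
        sphere_drop=z.copy(),
    )


class TestDisplacementExtrema:
    def test_all_zero_series(self):
        m = make_monitors([0.0, 0.1], [0.0, 0.0], [0.0, 0.0])
        (uz, tz), (ux, tx) = pm.displacement_extrema(m)
        assert (uz, tz) == (0.0, 0.0) and (ux, tx) == (0.0, 0.0)

    def test_known_extrema_recovered(self):
        m = make_monitors([0.0, 0.05, 0.1], [1.0, 7.0, 3.0], [0.2, 0.4, 5.5])
        (uz, tz), (ux, tx) = pm.displacement_extrema(m)
        assert (uz, tz) == (7.0, 0.05)
        assert (ux, tx) == (5.5, 0.1)

    def test_span_definition_from_node_fields(self):
        # one node at +a, another at -b: span = a + b at that instant
        u = np.zeros((2, 3)); u[0, 0] = 2.0; u[1, 0] = -3.0
        assert u[:, 0].max() - u[:, 0].min() == pytest.approx(5.0)

    def test_empty_series_rejected(self):
        m = make_monitors([], [], [])
        with pytest.raises(InvalidParameterError):
            pm.displacement_extrema(m)


class TestExtensionRatios:
    @pytest.mark.parametrize(
        "uz, ux, expect_z, expect_x",
        [
            (50.684, 140.21, 126.71, 200.30),
            (52.509, 129.38, 131.27, 184.83),
            (50.358, 127.11, 125.895, 181.59),
            (0.0, 0.0, 0.0, 0.0),
        ],
    )
    def test_published_displacements_give_published_percentages(
        self, uz, ux, expect_z, expect_x
    ):
        rz, rx = pm.extension_ratios(uz, ux, height=40.0, length=70.0)
        assert rz == pytest.approx(expect_z, abs=5.1e-3)
        assert rx == pytest.approx(expect_x, abs=5.1e-3)

    def test_invalid_dimensions(self):
        with pytest.raises(InvalidParameterError):
            pm.extension_ratios(1.0, 1.0, height=0.0)


class TestPeakReport:
    def test_single_maximum_recovered_exactly(self):
        times = [0.0, 0.02, 0.04, 0.06]
        vm = [0.0, 0.5, 2.0, 1.0]
        pe = [0.0, 0.9, 0.4, 0.1]
        m = make_monitors(times, [0, 1, 4, 2], [0, 2, 3, 8], vm=vm, ps=vm, pe=pe)
        n_e = 3
        snap = FieldSnapshot(
            time=0.06,
            u=np.zeros((5, 3)),
            cauchy_stress=np.zeros((n_e, 3, 3)),
            green_strain=np.zeros((n_e, 3, 3)),
            sphere_z=0.0,
        )
        rep = pm.peak_report([snap], m, 90.0)
        assert (rep.max_von_mises, rep.t_von_mises) == (2.0, 0.04)
        assert (rep.max_principal_strain, rep.t_principal_strain) == (0.9, 0.02)
        assert (rep.max_uz, rep.t_uz) == (4.0, 0.04)
        assert (rep.ux_span, rep.t_ux) == (8.0, 0.06)

    def test_ratios_consistent_with_extrema(self):
        m = make_monitors([0.0, 0.1], [0, 20.0], [0, 35.0])
        snap = FieldSnapshot(0.1, np.zeros((2, 3)), np.zeros((1, 3, 3)),
                             np.zeros((1, 3, 3)), 0.0)
        rep = pm.peak_report([snap], m, 90.0, height=40.0, length=70.0)
        rz, rx = pm.extension_ratios(rep.max_uz, rep.ux_span)
        assert rep.extension_ratio_z == pytest.approx(rz)
        assert rep.extension_ratio_x == pytest.approx(rx)

    def test_missing_snapshots_rejected(self):
        m = make_monitors([0.0], [0.0], [0.0])
        with pytest.raises(InvalidParameterError):
            pm.peak_report([], m, 90.0)

    def test_frame_has_one_row_per_diameter(self):
        m = make_monitors([0.0, 0.1], [0, 1.0], [0, 1.0])
        snap = FieldSnapshot(0.1, np.zeros((2, 3)), np.zeros((1, 3, 3)),
                             np.zeros((1, 3, 3)), 0.0)
        reports = [pm.peak_report([snap], m, d) for d in (100.0, 80.0, 90.0)]
        frame = pm.metrics_frame(reports)
        assert list(frame["diameter"]) == [80.0, 90.0, 100.0]
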