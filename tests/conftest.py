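"""Shared fixtures: the default surrogate, meshes at two resolutions and the
full three-diameter sweep (run once per session and reused by the acceptance
checks)."""

from __future__ import annotations

import numpy as np
import pytest

import pfmsim as pm


@pytest.fixture(scope="session")
def params():
    return pm.PFMGeometryParams()


@pytest.fixture(scope="session")
def solid(params):
    return pm.build_pfm_surrogate(params)


@pytest.fixture(scope="session")
def mesh3(solid, params):
    """Default-run mesh (3 mm) with the attachment bands selected."""
    mesh = pm.tetrahedralize(solid, 3.0)
    pm.select_fixed_rim(mesh, params)
    return mesh


@pytest.fixture(scope="session")
def mesh_coarse(solid, params):
    """Coarse 5 mm mesh for fast dynamic tests."""
    mesh = pm.tetrahedralize(solid, 5.0)
    pm.select_fixed_rim(mesh, params)
    return mesh


@pytest.fixture(scope="session")
def material():
    return pm.MaterialParams()


@pytest.fixture(scope="session")
def single_tet():
    """Reference unit-scale tetrahedron (mm)."""
    return np.array(
        [[0.0, 0.0, 0.0], [3.0, 0.0, 0.0], [0.0, 3.0, 0.0], [0.0, 0.0, 3.0]]
    )


@pytest.fixture(scope="session")
def sweep(mesh3, params, material):
    """Full descent runs for the three published head diameters at the
    package's default study conditions."""
    out = {}
    for d in (80.0, 90.0, 100.0):
        sphere = pm.place_sphere(mesh3, d)
        cfg = pm.SimulationConfig()
        result = pm.run(mesh3, material, sphere, cfg)
        report = pm.peak_report(
            result.snapshots, result.monitors, d,
            height=params.height, length=params.length,
            mesh=mesh3, geometry_params=params,
        )
        out[d] = (result, report)
    return out
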