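"""Configuration loading, mesh/field writers and run manifests.

Field output is ASCII VTK XML (.vtu) with a PVD time-series index so any
standard viewer reproduces the published contour plots from raw data; mesh
exchange additionally supports Gmsh MSH 2.2 and Abaqus INP (nodes, C3D4
elements, NSET for the fixed rim).  All writers are thin and text-only;
state is float64 internally and float32 in VTK files.
"""

from __future__ import annotations

import hashlib
import json
import xml.etree.ElementTree as ET
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .contact import ContactParams
from .errors import ConfigError
from .geometry import Mesh, PFMGeometryParams
from .mechanics import MaterialParams
from .simulator import SimulationConfig

__all__ = [
    "SphereSpec",
    "load_config",
    "write_vtu",
    "read_vtu",
    "write_pvd",
    "write_snapshot_series",
    "write_msh",
    "write_inp",
    "RunManifest",
    "make_manifest",
]


@dataclass(frozen=True)
class SphereSpec:
    """Fetal-head sphere request: which diameters to run and the head density."""

    diameters: tuple[float, ...] = (80.0, 90.0, 100.0)
    density: float = 7.86e-9

    def __post_init__(self):
        if not self.diameters or any(d <= 0 for d in self.diameters):
            raise ConfigError(f"sphere diameters must be > 0, got {self.diameters}")
        if self.density < 0:
            raise ConfigError("sphere density must be >= 0")


_GEOMETRY_KEYS = {
    "length", "width", "height", "sheet_thickness", "hiatus_semiaxes",
    "bowl_profile", "plateau_fraction", "rng_seed",
}
_MATERIAL_KEYS = {"young_modulus", "poisson_ratio", "density"}
_SPHERE_KEYS = {"diameter", "diameters", "density"}
_CONTACT_KEYS = {
    "friction_coefficient", "penalty_stiffness",
    "friction_regularization_velocity", "penetration_tolerance", "enabled",
}
_SIMULATION_KEYS = {
    "duration", "snapshot_interval", "gravity", "cfl_factor", "damping_ratio",
    "initial_gap", "rng_seed", "mesh_edge", "monitor_every",
    "stiffening_safety", "gravity_on_muscle", "element_viscosity",
}
_SECTIONS = {"geometry", "material", "sphere", "contact", "simulation"}


def _check_keys(section: str, data: dict, valid: set[str]) -> None:
    unknown = set(data) - valid
    if unknown:
        raise ConfigError(
            f"unknown key(s) {sorted(unknown)} in section {section!r}; "
            f"valid keys: {sorted(valid)}"
        )


def load_config(
    path: str | Path | None = None,
) -> tuple[PFMGeometryParams, MaterialParams, SphereSpec, SimulationConfig]:
    """Parse a YAML config; omitted keys fall back to the published defaults
    (70x60x40 mm dimensions, E=0.2 MPa, nu=0.4, rho=1.12e-9 ton/mm^3 muscle,
    7.86e-9 ton/mm^3 head, mu=0.03, 23 mm gap, 0.15 s duration)."""
    raw = {}
    if path is not None:
        text = Path(path).read_text()
        raw = yaml.safe_load(text) or {}
        if not isinstance(raw, dict):
            raise ConfigError("config root must be a mapping")
    unknown = set(raw) - _SECTIONS
    if unknown:
        raise ConfigError(
            f"unknown section(s) {sorted(unknown)}; valid sections: {sorted(_SECTIONS)}"
        )

    geo_raw = dict(raw.get("geometry") or {})
    _check_keys("geometry", geo_raw, _GEOMETRY_KEYS)
    if "hiatus_semiaxes" in geo_raw:
        geo_raw["hiatus_semiaxes"] = tuple(float(v) for v in geo_raw["hiatus_semiaxes"])
    mat_raw = dict(raw.get("material") or {})
    _check_keys("material", mat_raw, _MATERIAL_KEYS)
    sph_raw = dict(raw.get("sphere") or {})
    _check_keys("sphere", sph_raw, _SPHERE_KEYS)
    con_raw = dict(raw.get("contact") or {})
    _check_keys("contact", con_raw, _CONTACT_KEYS)
    sim_raw = dict(raw.get("simulation") or {})
    _check_keys("simulation", sim_raw, _SIMULATION_KEYS)

    if "diameter" in sph_raw and "diameters" in sph_raw:
        raise ConfigError("give either sphere.diameter or sphere.diameters, not both")
    diameters = sph_raw.pop("diameters", None)
    single = sph_raw.pop("diameter", None)
    if single is not None:
        diameters = [single]
    try:
        geometry = PFMGeometryParams(**geo_raw)
        material = MaterialParams(**mat_raw)
        sphere = SphereSpec(
            diameters=tuple(float(d) for d in diameters) if diameters else (80.0, 90.0, 100.0),
            density=float(sph_raw.get("density", 7.86e-9)),
        )
        contact = ContactParams(**con_raw)
        sim = SimulationConfig(contact=contact, **sim_raw)
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"config validation failed: {exc}") from exc
    return geometry, material, sphere, sim


# ---------------------------------------------------------------------------
# VTK XML (ASCII) unstructured-grid writer/reader
# ---------------------------------------------------------------------------


def _fmt(arr: np.ndarray) -> str:
    return " ".join(repr(float(v)) for v in np.asarray(arr, dtype=np.float32).ravel())


def write_vtu(
    path: str | Path,
    mesh: Mesh,
    point_data: dict[str, np.ndarray] | None = None,
    cell_data: dict[str, np.ndarray] | None = None,
) -> None:
    """Write the tet mesh with attached nodal/element fields (ASCII .vtu)."""
    path = Path(path)
    n, e = mesh.n_nodes, mesh.n_tets
    parts = [
        '<?xml version="1.0"?>',
        '<VTKFile type="UnstructuredGrid" version="0.1" byte_order="LittleEndian">',
        "<UnstructuredGrid>",
        f'<Piece NumberOfPoints="{n}" NumberOfCells="{e}">',
        "<Points>",
        '<DataArray type="Float32" NumberOfComponents="3" format="ascii">',
        _fmt(mesh.node_coords),
        "</DataArray>",
        "</Points>",
        "<Cells>",
        '<DataArray type="Int32" Name="connectivity" format="ascii">',
        " ".join(map(str, mesh.tets.ravel())),
        "</DataArray>",
        '<DataArray type="Int32" Name="offsets" format="ascii">',
        " ".join(str(4 * (i + 1)) for i in range(e)),
        "</DataArray>",
        '<DataArray type="UInt8" Name="types" format="ascii">',
        " ".join(["10"] * e),
        "</DataArray>",
        "</Cells>",
    ]

    def emit(tag: str, data: dict[str, np.ndarray]):
        parts.append(f"<{tag}>")
        for name, arr in data.items():
            arr = np.asarray(arr)
            ncomp = 1 if arr.ndim == 1 else arr.shape[1]
            parts.append(
                f'<DataArray type="Float32" Name="{name}" '
                f'NumberOfComponents="{ncomp}" format="ascii">'
            )
            parts.append(_fmt(arr))
            parts.append("</DataArray>")
        parts.append(f"</{tag}>")

    emit("PointData", point_data or {})
    emit("CellData", cell_data or {})
    parts += ["</Piece>", "</UnstructuredGrid>", "</VTKFile>"]
    path.write_text("\n".join(parts))


def read_vtu(path: str | Path):
    """Read back an ASCII .vtu written by :func:`write_vtu`.

    Returns (points, tets, point_data, cell_data) with float32 fields.
    """
    root = ET.parse(str(path)).getroot()
    piece = root.find(".//Piece")
    points = np.array(
        piece.find("Points/DataArray").text.split(), dtype=np.float32
    ).reshape(-1, 3)
    conn = None
    for da in piece.find("Cells"):
        if da.get("Name") == "connectivity":
            conn = np.array(da.text.split(), dtype=np.int64).reshape(-1, 4)

    def collect(tag):
        out = {}
        node = piece.find(tag)
        if node is None:
            return out
        for da in node:
            ncomp = int(da.get("NumberOfComponents", "1"))
            arr = np.array((da.text or "").split(), dtype=np.float32)
            out[da.get("Name")] = arr.reshape(-1, ncomp) if ncomp > 1 else arr
        return out

    return points, conn, collect("PointData"), collect("CellData")


def write_pvd(path: str | Path, entries: list[tuple[float, str]]) -> None:
    """PVD index: list of (time, relative vtu filename)."""
    lines = [
        '<?xml version="1.0"?>',
        '<VTKFile type="Collection" version="0.1" byte_order="LittleEndian">',
        "<Collection>",
    ]
    for t, fname in entries:
        lines.append(f'<DataSet timestep="{t!r}" group="" part="0" file="{fname}"/>')
    lines += ["</Collection>", "</VTKFile>"]
    Path(path).write_text("\n".join(lines))


def write_snapshot_series(snapshots, mesh: Mesh, outdir: str | Path,
                          basename: str = "fields") -> list[Path]:
    """One .vtu per snapshot (displacement vector, von Mises, max principal
    stress and strain) plus a PVD index; returns the written paths."""
    from .postproc import max_principal, von_mises

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    entries, paths = [], []
    for i, snap in enumerate(snapshots):
        fname = f"{basename}_{i:04d}.vtu"
        write_vtu(
            outdir / fname,
            mesh,
            point_data={"displacement": snap.u},
            cell_data={
                "von_mises": von_mises(snap.cauchy_stress),
                "max_principal_stress": max_principal(snap.cauchy_stress),
                "max_principal_strain": max_principal(snap.green_strain),
            },
        )
        entries.append((snap.time, fname))
        paths.append(outdir / fname)
    pvd = outdir / f"{basename}.pvd"
    write_pvd(pvd, entries)
    paths.append(pvd)
    return paths


# ---------------------------------------------------------------------------
# Gmsh MSH 2.2 and Abaqus INP exporters
# ---------------------------------------------------------------------------


def write_msh(path: str | Path, mesh: Mesh) -> None:
    """Gmsh MSH 2.2 ASCII export (4-node tetrahedra, element type 4)."""
    lines = ["$MeshFormat", "2.2 0 8", "$EndMeshFormat", "$Nodes", str(mesh.n_nodes)]
    for i, p in enumerate(mesh.node_coords, start=1):
        lines.append(f"{i} {p[0]:.9g} {p[1]:.9g} {p[2]:.9g}")
    lines += ["$EndNodes", "$Elements", str(mesh.n_tets)]
    for i, t in enumerate(mesh.tets, start=1):
        lines.append(f"{i} 4 2 0 1 {t[0]+1} {t[1]+1} {t[2]+1} {t[3]+1}")
    lines.append("$EndElements")
    Path(path).write_text("\n".join(lines) + "\n")


def write_inp(path: str | Path, mesh: Mesh, part_name: str = "PFM") -> None:
    """Abaqus INP export: *NODE, C3D4 *ELEMENT and one *NSET per node set
    (exchange convenience for cross-checks in commercial solvers)."""
    lines = [f"*HEADING", f"pfmsim export, part {part_name}", "*NODE"]
    for i, p in enumerate(mesh.node_coords, start=1):
        lines.append(f"{i}, {p[0]:.9g}, {p[1]:.9g}, {p[2]:.9g}")
    lines.append(f"*ELEMENT, TYPE=C3D4, ELSET={part_name}")
    for i, t in enumerate(mesh.tets, start=1):
        lines.append(f"{i}, {t[0]+1}, {t[1]+1}, {t[2]+1}, {t[3]+1}")
    for name, idx in mesh.node_sets.items():
        lines.append(f"*NSET, NSET={name.upper()}")
        ids = [str(j + 1) for j in np.asarray(idx)]
        for start in range(0, len(ids), 16):
            lines.append(", ".join(ids[start:start + 16]))
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Run manifest
# ---------------------------------------------------------------------------


@dataclass
class RunManifest:
    config_hash: str
    software_version: str
    rng_seed: int
    n_nodes: int
    n_tets: int
    min_edge: float
    characteristic_edge: float
    material: dict
    diameter: float
    flags: dict

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, sort_keys=True)


def make_manifest(
    geometry: PFMGeometryParams,
    material: MaterialParams,
    diameter: float,
    config: SimulationConfig,
    mesh: Mesh,
    flags: dict | None = None,
) -> RunManifest:
    payload = {
        "geometry": asdict(geometry),
        "material": asdict(material),
        "diameter": diameter,
        "simulation": {
            k: v for k, v in asdict(config).items() if not isinstance(v, dict)
        },
        "contact": asdict(config.contact),
    }
    blob = json.dumps(payload, sort_keys=True, default=str).encode()
    return RunManifest(
        config_hash=hashlib.sha256(blob).hexdigest(),
        software_version=__version__,
        rng_seed=config.rng_seed,
        n_nodes=mesh.n_nodes,
        n_tets=mesh.n_tets,
        min_edge=mesh.min_edge(),
        characteristic_edge=mesh.characteristic_edge,
        material=asdict(material),
        diameter=diameter,
        flags=flags or {},
    )
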