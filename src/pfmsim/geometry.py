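"""Parametric pelvic-floor-muscle surrogate geometry and tetrahedral meshing.

The deformable body is a "hammock": a constant-thickness curved sheet spanning
a rectangular footprint (length x width), sagging into a funnel whose bounding
box height matches the prescribed model height, pierced by an elliptical
urogenital hiatus at the footprint center.  It stands in for a subject-specific
MRI reconstruction; only the bounding dimensions, the presence of a central
hiatus smaller than the fetal head, and the constrained outer margin are
treated as faithful features.

Coordinates: X along the 70 mm length, Y along the 60 mm width, Z vertical
(descent is -Z).  Units are mm throughout (mm-ton-s-MPa system).

Meshing strategy: a structured annular grid of quadrilateral columns between
the hiatus ellipse (inner boundary) and the footprint rectangle (outer
boundary), spaced by 3-D arc length along each spoke so element edges track
the target size even on the steep funnel wall; columns are extruded through
the sheet thickness and each hexahedral cell is split into six tetrahedra with
the Kuhn (main-diagonal) pattern, which is conforming on structured grids and,
for vertically sheared columns, provably yields uniform positive volumes.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components

from .errors import InvalidParameterError, MeshingError, SelectionError

__all__ = [
    "PFMGeometryParams",
    "HammockSolid",
    "Mesh",
    "RigidSphere",
    "build_pfm_surrogate",
    "tetrahedralize",
    "select_fixed_rim",
    "place_sphere",
]


@dataclass(frozen=True)
class PFMGeometryParams:
    """Parameters of the hammock-with-hiatus surrogate.

    Defaults reproduce the published model dimensions: 70 mm length (X),
    60 mm width (Y), 40 mm bounding height (Z), with a 6 mm sheet and a
    50 x 30 mm elliptical hiatus so that every head diameter in the studied
    range (80-100 mm) must stretch the opening to pass.
    """

    length: float = 70.0
    width: float = 60.0
    height: float = 40.0
    sheet_thickness: float = 6.0
    hiatus_semiaxes: tuple[float, float] = (25.0, 15.0)
    bowl_profile: float = 1.0
    plateau_fraction: float = 0.55
    rng_seed: int = 0

    def __post_init__(self):
        a, b = self.hiatus_semiaxes
        for name in ("length", "width", "height", "sheet_thickness", "bowl_profile"):
            if getattr(self, name) <= 0.0:
                raise InvalidParameterError(f"{name} must be > 0, got {getattr(self, name)}")
        if a <= 0.0 or b <= 0.0:
            raise InvalidParameterError(f"hiatus_semiaxes must be > 0, got {self.hiatus_semiaxes}")
        if 2.0 * a >= self.length or 2.0 * b >= self.width:
            raise InvalidParameterError(
                "hiatus must fit strictly inside the footprint: "
                f"semiaxes {self.hiatus_semiaxes} vs footprint {self.length} x {self.width}"
            )
        if self.sheet_thickness >= self.height:
            raise InvalidParameterError(
                f"sheet_thickness ({self.sheet_thickness}) must be < height ({self.height})"
            )
        if not 0.0 < self.plateau_fraction < 1.0:
            raise InvalidParameterError("plateau_fraction must lie in (0, 1)")

    @property
    def sag(self) -> float:
        """Mid-surface sag depth (mm): bounding height minus sheet thickness."""
        return self.height - self.sheet_thickness


class HammockSolid:
    """Watertight solid description of the sagging sheet with a hiatus.

    The mid-surface is z_mid(x, y) = -sag * s(rho) where rho is the
    normalized elliptical footprint radius, s == 1 on a central plateau
    (rho <= plateau_fraction), s == 0 at the outer margin, with a cosine
    ramp raised to the ``bowl_profile`` exponent in between.  The solid is
    the set of points within half the sheet thickness of the mid-surface
    (measured along Z), inside the footprint and outside the hiatus ellipse.
    """

    def __init__(self, params: PFMGeometryParams):
        self.params = params

    # -- scalar fields -------------------------------------------------

    def footprint_radius(self, x, y):
        """Normalized elliptical radius: 1 on the footprint's inscribed ellipse."""
        p = self.params
        return np.sqrt((2.0 * np.asarray(x) / p.length) ** 2 + (2.0 * np.asarray(y) / p.width) ** 2)

    def midsurface_z(self, x, y):
        # bowl wall: steep at the attachment margin (the whole footprint is
        # the bowl mouth, as in the anatomical levator funnel), levelling
        # into a flat full-depth floor around the hiatus
        p = self.params
        rho = self.footprint_radius(x, y)
        u = (rho - p.plateau_fraction) / (1.0 - p.plateau_fraction)
        u = np.clip(u, 0.0, 1.0)
        s = np.cos(0.5 * np.pi * u) ** p.bowl_profile
        return -p.sag * s

    def contains(self, points: np.ndarray) -> np.ndarray:
        """Boolean membership for an (N, 3) array of points."""
        p = self.params
        pts = np.asarray(points, dtype=float).reshape(-1, 3)
        x, y, z = pts[:, 0], pts[:, 1], pts[:, 2]
        a, b = p.hiatus_semiaxes
        in_foot = (np.abs(x) <= p.length / 2.0) & (np.abs(y) <= p.width / 2.0)
        out_hiatus = (x / a) ** 2 + (y / b) ** 2 >= 1.0
        zm = self.midsurface_z(x, y)
        in_sheet = np.abs(z - zm) <= p.sheet_thickness / 2.0
        return in_foot & out_hiatus & in_sheet

    # -- derived quantities --------------------------------------------

    @property
    def volume(self) -> float:
        """Exact solid volume (mm^3): the sheet is a vertical extrusion, so
        volume = (footprint area - hiatus area) * thickness."""
        p = self.params
        a, b = p.hiatus_semiaxes
        return (p.length * p.width - math.pi * a * b) * p.sheet_thickness

    def bounding_box(self) -> tuple[np.ndarray, np.ndarray]:
        """(min_corner, max_corner); Z extent equals the model height because
        the plateau ring around the hiatus reaches full sag."""
        p = self.params
        lo = np.array([-p.length / 2.0, -p.width / 2.0, -p.sag - p.sheet_thickness / 2.0])
        hi = np.array([p.length / 2.0, p.width / 2.0, p.sheet_thickness / 2.0])
        return lo, hi

    def describe(self) -> str:
        """Canonical JSON description; byte-identical for identical params."""
        p = self.params
        payload = {
            "kind": "hammock_with_hiatus",
            "length": p.length,
            "width": p.width,
            "height": p.height,
            "sheet_thickness": p.sheet_thickness,
            "hiatus_semiaxes": list(p.hiatus_semiaxes),
            "bowl_profile": p.bowl_profile,
            "plateau_fraction": p.plateau_fraction,
            "rng_seed": p.rng_seed,
            "midsurface": "cosine ramp, plateau at full sag",
        }
        return json.dumps(payload, sort_keys=True, separators=(",", ":"))


def build_pfm_surrogate(params: PFMGeometryParams) -> HammockSolid:
    """Construct the parametric solid; validation lives in the params type."""
    return HammockSolid(params)


@dataclass
class Mesh:
    """Linear-tetrahedron mesh with named node sets."""

    node_coords: np.ndarray           # (N, 3) float64, mm
    tets: np.ndarray                  # (E, 4) int32
    node_sets: dict[str, np.ndarray] = field(default_factory=dict)
    characteristic_edge: float = 0.0  # median edge length, mm

    @property
    def n_nodes(self) -> int:
        return self.node_coords.shape[0]

    @property
    def n_tets(self) -> int:
        return self.tets.shape[0]

    def tet_volumes(self) -> np.ndarray:
        x = self.node_coords[self.tets]
        d = x[:, 1:] - x[:, :1]
        return np.einsum("ei,ei->e", d[:, 0], np.cross(d[:, 1], d[:, 2])) / 6.0

    @property
    def total_volume(self) -> float:
        return float(self.tet_volumes().sum())

    def unique_edges(self) -> np.ndarray:
        pairs = self.tets[:, [0, 1, 0, 2, 0, 3, 1, 2, 1, 3, 2, 3]].reshape(-1, 2)
        pairs = np.sort(pairs, axis=1)
        return np.unique(pairs, axis=0)

    def edge_lengths(self) -> np.ndarray:
        e = self.unique_edges()
        return np.linalg.norm(self.node_coords[e[:, 0]] - self.node_coords[e[:, 1]], axis=1)

    def min_edge(self) -> float:
        return float(self.edge_lengths().min())

    def min_altitude(self) -> float:
        """Smallest tetrahedron altitude, 3V / max face area; the conservative
        characteristic length for explicit time stepping on sheared elements."""
        x = self.node_coords[self.tets]
        vols = self.tet_volumes()
        faces = [(1, 2, 3), (0, 2, 3), (0, 1, 3), (0, 1, 2)]
        amax = np.zeros(self.n_tets)
        for (i, j, k) in faces:
            area = 0.5 * np.linalg.norm(
                np.cross(x[:, j] - x[:, i], x[:, k] - x[:, i]), axis=1
            )
            amax = np.maximum(amax, area)
        return float((3.0 * np.abs(vols) / amax).min())

    def estimate_thickness(self) -> float:
        """Median vertical extent of coincident-(x, y) node columns."""
        xy = np.round(self.node_coords[:, :2], 6)
        _, inv = np.unique(xy, axis=0, return_inverse=True)
        z = self.node_coords[:, 2]
        zmax = np.full(inv.max() + 1, -np.inf)
        zmin = np.full(inv.max() + 1, np.inf)
        np.maximum.at(zmax, inv, z)
        np.minimum.at(zmin, inv, z)
        spread = zmax - zmin
        spread = spread[spread > 0]
        return float(np.median(spread)) if spread.size else 0.0

    def validate(self) -> None:
        if self.tets.min() < 0 or self.tets.max() >= self.n_nodes:
            raise MeshingError("tetrahedron node index out of range")
        vols = self.tet_volumes()
        if not np.all(vols > 0.0):
            bad = int(np.sum(vols <= 0.0))
            raise MeshingError(
                f"{bad} non-positive-volume tetrahedra (min signed volume {vols.min():.3e} mm^3)"
            )
        # single connected component over the edge graph
        e = self.unique_edges()
        adj = coo_matrix(
            (np.ones(len(e)), (e[:, 0], e[:, 1])), shape=(self.n_nodes, self.n_nodes)
        )
        n_comp, _ = connected_components(adj, directed=False)
        if n_comp != 1:
            raise MeshingError(f"mesh has {n_comp} connected components, expected 1")
        for name, idx in self.node_sets.items():
            if len(idx) and (np.min(idx) < 0 or np.max(idx) >= self.n_nodes):
                raise MeshingError(f"node set {name!r} references nodes out of range")


# Kuhn split of the unit hexahedron along the (0,0,0)-(1,1,1) diagonal:
# one tetrahedron per axis-permutation path.  Corner bit order: (di, dj, dk).
_KUHN_PATHS = []
for perm in ((0, 1, 2), (0, 2, 1), (1, 0, 2), (1, 2, 0), (2, 0, 1), (2, 1, 0)):
    v = [0, 0, 0]
    path = [tuple(v)]
    for axis in perm:
        v = list(v)
        v[axis] = 1
        path.append(tuple(v))
    _KUHN_PATHS.append(path)


def _outer_boundary_point(phi: float, length: float, width: float) -> np.ndarray:
    """Intersection of the ray at angle phi with the footprint rectangle."""
    c, s = math.cos(phi), math.sin(phi)
    scale = 1.0 / max(abs(c) / (length / 2.0), abs(s) / (width / 2.0))
    return np.array([scale * c, scale * s])


def tetrahedralize(solid: HammockSolid, target_edge: float) -> Mesh:
    """Mesh the hammock solid with linear tetrahedra of roughly uniform
    3-D edge length ``target_edge`` (mm, must lie in [1, 5]).

    Node sets are left empty; populate "fixed_rim" with
    :func:`select_fixed_rim`.
    """
    if not 1.0 <= target_edge <= 5.0:
        raise InvalidParameterError(f"target_edge must lie in [1, 5] mm, got {target_edge}")
    p = solid.params
    a, b = p.hiatus_semiaxes

    # circumferential resolution from the mean of inner/outer perimeters
    perim_in = math.pi * (3 * (a + b) - math.sqrt((3 * a + b) * (a + 3 * b)))  # Ramanujan
    perim_out = 2.0 * (p.length + p.width)
    # multiple of 4 so spokes hit the rectangle's axis extremes exactly
    n_v = max(16, 4 * int(round(0.5 * (perim_in + perim_out) / (4.0 * target_edge))))

    # both boundary curves sampled uniformly by their own arc length (matched
    # at phi = 0 and paired by cumulative arc fraction) so circumferential
    # spacing is uniform even at the rectangle corners
    phi_fine = np.linspace(0.0, 2.0 * math.pi, 4096)
    ell = np.stack([a * np.cos(phi_fine), b * np.sin(phi_fine)], axis=1)
    s_ell = np.concatenate([[0.0], np.cumsum(np.linalg.norm(np.diff(ell, axis=0), axis=1))])
    rect = np.stack([_outer_boundary_point(phi, p.length, p.width) for phi in phi_fine])
    s_rect = np.concatenate([[0.0], np.cumsum(np.linalg.norm(np.diff(rect, axis=0), axis=1))])
    frac = np.arange(n_v) / n_v
    inner = np.stack(
        [
            np.interp(frac * s_ell[-1], s_ell, ell[:, 0]),
            np.interp(frac * s_ell[-1], s_ell, ell[:, 1]),
        ],
        axis=1,
    )
    outer = np.stack(
        [
            np.interp(frac * s_rect[-1], s_rect, rect[:, 0]),
            np.interp(frac * s_rect[-1], s_rect, rect[:, 1]),
        ],
        axis=1,
    )

    # spokes: fine polyline from hiatus rim to footprint rectangle, with the
    # mid-surface height, measured in 3-D arc length
    n_fine = 256
    t_fine = np.linspace(0.0, 1.0, n_fine)
    spoke_xy = inner[:, None, :] + t_fine[None, :, None] * (outer - inner)[:, None, :]
    spoke_z = solid.midsurface_z(spoke_xy[..., 0], spoke_xy[..., 1])
    seg = np.sqrt(
        np.sum(np.diff(spoke_xy, axis=1) ** 2, axis=2) + np.diff(spoke_z, axis=1) ** 2
    )
    arclen = np.concatenate([np.zeros((n_v, 1)), np.cumsum(seg, axis=1)], axis=1)
    n_u = max(3, int(math.ceil(arclen[:, -1].max() / target_edge)))

    # resample every spoke at equal arc-length fractions
    base_xy = np.empty((n_u + 1, n_v, 2))
    for j in range(n_v):
        targets = np.linspace(0.0, arclen[j, -1], n_u + 1)
        tt = np.interp(targets, arclen[j], t_fine)
        base_xy[:, j, 0] = inner[j, 0] + tt * (outer[j, 0] - inner[j, 0])
        base_xy[:, j, 1] = inner[j, 1] + tt * (outer[j, 1] - inner[j, 1])
    base_z = solid.midsurface_z(base_xy[..., 0], base_xy[..., 1])

    # vertical extrusion through the sheet thickness
    n_z = max(1, int(round(p.sheet_thickness / target_edge)))
    dz = p.sheet_thickness / n_z
    n_nodes = (n_u + 1) * n_v * (n_z + 1)
    coords = np.empty((n_nodes, 3))

    def nid(iu, iv, iz):
        return (iu * n_v + (iv % n_v)) * (n_z + 1) + iz

    iu_g, iv_g, iz_g = np.meshgrid(
        np.arange(n_u + 1), np.arange(n_v), np.arange(n_z + 1), indexing="ij"
    )
    ids = (iu_g * n_v + iv_g) * (n_z + 1) + iz_g
    coords[ids.ravel(), 0] = np.broadcast_to(base_xy[..., 0][..., None], iu_g.shape).ravel()
    coords[ids.ravel(), 1] = np.broadcast_to(base_xy[..., 1][..., None], iu_g.shape).ravel()
    coords[ids.ravel(), 2] = (
        np.broadcast_to(base_z[..., None], iu_g.shape)
        - p.sheet_thickness / 2.0
        + iz_g * dz
    ).ravel()

    tets = []
    for path in _KUHN_PATHS:
        corner_ids = []
        for (di, dj, dk) in path:
            iu = iu_g[: n_u, :, : n_z] + di
            iv = iv_g[: n_u, :, : n_z] + dj
            iz = iz_g[: n_u, :, : n_z] + dk
            corner_ids.append(((iu * n_v + (iv % n_v)) * (n_z + 1) + iz).ravel())
        tets.append(np.stack(corner_ids, axis=1))
    tets = np.concatenate(tets, axis=0).astype(np.int32)

    mesh = Mesh(node_coords=coords, tets=tets)
    vols = mesh.tet_volumes()
    flip = vols < 0.0
    if np.any(flip):
        mesh.tets[flip] = mesh.tets[flip][:, [0, 1, 3, 2]]
        vols = mesh.tet_volumes()
    if not np.all(vols > 1e-9):
        raise MeshingError(
            f"degenerate tetrahedra after orientation fix: min volume {vols.min():.3e} mm^3 "
            f"(n_u={n_u}, n_v={n_v}, n_z={n_z})"
        )
    mesh.characteristic_edge = float(np.median(mesh.edge_lengths()))
    mesh.validate()
    return mesh


def select_fixed_rim(
    mesh: Mesh,
    params: PFMGeometryParams,
    band: float | None = None,
    sides: tuple[str, ...] = ("x-",),
    midline_gap_halfwidth: float | None = 24.0,
) -> Mesh:
    """Populate the "fixed_rim" node set: nodes within ``band`` mm of the
    selected attachment margin(s) of the footprint.

    ``sides`` picks which margins are constrained: any of "x-", "x+", "y-",
    "y+" or "all".  The default is the anterior x = -L/2 margin — the
    pubococcygeal insertion on the pubic bone, the one constrained margin of
    the model.  On the anterior margin the insertion is two lateral bands
    flanking the midline urogenital gap (where urethra and vagina pass and
    no muscle attaches); ``midline_gap_halfwidth`` (mm) leaves that central
    stretch of an "x" margin free.  Pass ``None`` (or use "all") to clamp
    margins continuously.  Default band is half the characteristic edge.
    """
    if band is None:
        band = 0.5 * mesh.characteristic_edge
    valid = {"x-", "x+", "y-", "y+", "all"}
    if not sides or not set(sides) <= valid:
        raise InvalidParameterError(f"sides must be drawn from {sorted(valid)}, got {sides}")
    x, y = mesh.node_coords[:, 0], mesh.node_coords[:, 1]
    on_rim = np.zeros(mesh.n_nodes, dtype=bool)
    gap = midline_gap_halfwidth
    lateral = (
        np.ones(mesh.n_nodes, dtype=bool)
        if (gap is None or "all" in sides)
        else np.abs(y) >= gap
    )
    if "all" in sides or "x-" in sides:
        on_rim |= (x <= -params.length / 2.0 + band) & lateral
    if "all" in sides or "x+" in sides:
        on_rim |= (x >= params.length / 2.0 - band) & lateral
    if "all" in sides or "y-" in sides:
        on_rim |= y <= -params.width / 2.0 + band
    if "all" in sides or "y+" in sides:
        on_rim |= y >= params.width / 2.0 - band
    a, b = params.hiatus_semiaxes
    on_hiatus = (x / a) ** 2 + (y / b) ** 2 <= 1.0 + 1e-9
    selected = np.flatnonzero(on_rim & ~on_hiatus)
    if selected.size == 0:
        raise SelectionError(
            f"fixed-rim selection empty for band {band} mm; widen the band"
        )
    mesh.node_sets["fixed_rim"] = selected.astype(np.int64)
    return mesh


@dataclass
class RigidSphere:
    """Analytic rigid sphere standing in for the fetal head.

    Motion is constrained to vertical translation (-Z); mass follows from the
    diameter and the head density, (pi/6) D^3 rho.
    """

    diameter: float
    density: float = 7.86e-9          # ton/mm^3
    center: np.ndarray = field(default_factory=lambda: np.zeros(3))
    vertical_velocity: float = 0.0

    def __post_init__(self):
        if self.diameter <= 0.0:
            raise InvalidParameterError(f"diameter must be > 0, got {self.diameter}")
        if self.density < 0.0:
            raise InvalidParameterError(f"density must be >= 0, got {self.density}")
        self.center = np.asarray(self.center, dtype=float).reshape(3)

    @property
    def radius(self) -> float:
        return 0.5 * self.diameter

    @property
    def mass(self) -> float:
        """ton; (pi/6) D^3 rho."""
        return math.pi / 6.0 * self.diameter ** 3 * self.density


def place_sphere(
    mesh: Mesh, diameter: float, density: float = 7.86e-9, gap: float = 23.0
) -> RigidSphere:
    """Position the sphere above the hiatus center so that its lowest surface
    point sits exactly ``gap`` mm (vertically) above the closest mesh node
    beneath it; zero initial velocity, zero initial penetration."""
    if diameter <= 0.0:
        raise InvalidParameterError(f"diameter must be > 0, got {diameter}")
    if gap < 0.0:
        raise InvalidParameterError(f"gap must be >= 0, got {gap}")
    r = 0.5 * diameter
    xy = mesh.node_coords[:, :2]
    rad2 = np.sum(xy ** 2, axis=1)
    under = rad2 < r ** 2
    if not np.any(under):
        raise InvalidParameterError("no mesh node lies under the sphere footprint")
    # vertical distance from node to the lower sphere surface equals gap when
    # z_center = gap + max_n (z_n + sqrt(r^2 - r_n^2))
    zc = gap + np.max(
        mesh.node_coords[under, 2] + np.sqrt(r ** 2 - rad2[under])
    )
    return RigidSphere(
        diameter=diameter, density=density, center=np.array([0.0, 0.0, zc])
    )


def mesh_fingerprint(mesh: Mesh) -> str:
    """SHA-256 over node coordinates and connectivity (reproducibility aid)."""
    h = hashlib.sha256()
    h.update(np.ascontiguousarray(mesh.node_coords).tobytes())
    h.update(np.ascontiguousarray(mesh.tets).tobytes())
    return h.hexdigest()
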