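"""Field post-processing: equivalent/principal invariants, displacement
extrema, extension ratios and the per-diameter metrics report.

Conventions: stress is Cauchy stress (what a deformed-configuration contour
plot shows), strain is the principal Green-Lagrange value, "maximum Z
displacement" is the descent-positive nodal maximum over all nodes and
times, and the X "span" is max(u_X) - min(u_X) over nodes at one instant,
maximized over time.  Extension ratios divide these extrema by the model
height (Z) and length (X), in percent.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass

import numpy as np
import pandas as pd

from .errors import InvalidParameterError
from .simulator import FieldSnapshot, MonitorSeries

__all__ = [
    "von_mises",
    "max_principal",
    "displacement_extrema",
    "extension_ratios",
    "peak_report",
    "MetricsReport",
    "metrics_frame",
]

_SYM_TOL = 1e-8


def _check_symmetric(t: np.ndarray) -> np.ndarray:
    t = np.asarray(t, dtype=float)
    if t.shape[-2:] != (3, 3):
        raise InvalidParameterError(f"expected a 3x3 tensor, got shape {t.shape}")
    scale = max(np.abs(t).max(), 1.0)
    if np.abs(t - t.swapaxes(-1, -2)).max() > _SYM_TOL * scale:
        raise InvalidParameterError("tensor is not symmetric within tolerance")
    return t


def von_mises(stress: np.ndarray) -> float | np.ndarray:
    """Equivalent (von Mises) stress, rotation-invariant:
    sqrt(((s1-s2)^2 + (s2-s3)^2 + (s3-s1)^2) / 2) on principal values."""
    t = _check_symmetric(stress)
    s11, s22, s33 = t[..., 0, 0], t[..., 1, 1], t[..., 2, 2]
    s12, s13, s23 = t[..., 0, 1], t[..., 0, 2], t[..., 1, 2]
    vm = np.sqrt(
        0.5
        * (
            (s11 - s22) ** 2
            + (s22 - s33) ** 2
            + (s33 - s11) ** 2
            + 6.0 * (s12 ** 2 + s13 ** 2 + s23 ** 2)
        )
    )
    return float(vm) if vm.ndim == 0 else vm


def max_principal(tensor: np.ndarray) -> float | np.ndarray:
    """Largest eigenvalue of a symmetric 3x3 tensor (batched on leading axes)."""
    t = _check_symmetric(tensor)
    ev = np.linalg.eigvalsh(t)[..., -1]
    return float(ev) if ev.ndim == 0 else ev


def displacement_extrema(
    monitors: MonitorSeries,
) -> tuple[tuple[float, float], tuple[float, float]]:
    """((max descent u_Z, time), (u_X span, time)) from the dense monitors."""
    if monitors.time.size == 0:
        raise InvalidParameterError("empty monitor series")
    iz = int(np.argmax(monitors.max_uz))
    ix = int(np.argmax(monitors.ux_span))
    return (
        (float(monitors.max_uz[iz]), float(monitors.time[iz])),
        (float(monitors.ux_span[ix]), float(monitors.time[ix])),
    )


def extension_ratios(
    max_uz: float, ux_span: float, height: float = 40.0, length: float = 70.0
) -> tuple[float, float]:
    """(ratio_Z %, ratio_X %): vertical extremum over model height and X span
    over model length, both in percent."""
    if height <= 0.0 or length <= 0.0:
        raise InvalidParameterError("height and length must be > 0")
    return 100.0 * max_uz / height, 100.0 * ux_span / length


@dataclass
class MetricsReport:
    """Machine-readable analog of the published per-diameter result tables."""

    diameter: float
    max_von_mises: float          # MPa, peak over the dense monitor series
    t_von_mises: float            # s
    von_mises_end: float          # MPa, at the final snapshot
    max_principal_stress: float   # MPa
    t_principal_stress: float
    principal_stress_end: float
    max_principal_strain: float
    t_principal_strain: float
    principal_strain_end: float
    max_uz: float                 # mm, descent-positive
    t_uz: float
    ux_span: float                # mm
    t_ux: float
    extension_ratio_z: float      # percent
    extension_ratio_x: float      # percent
    peak_region: str = ""

    def to_dict(self) -> dict:
        return asdict(self)


def _peak(series: np.ndarray, time: np.ndarray) -> tuple[float, float]:
    i = int(np.argmax(series))
    return float(series[i]), float(time[i])


def classify_region(xy: np.ndarray, length: float, width: float,
                    hiatus_semiaxes: tuple[float, float]) -> str:
    """Coarse surrogate-region label for a planform point."""
    a, b = hiatus_semiaxes
    x, y = float(xy[0]), float(xy[1])
    if (x / (1.3 * a)) ** 2 + (y / (1.3 * b)) ** 2 <= 1.0:
        return "hiatus_rim"
    if abs(x) >= 0.85 * length / 2.0 or abs(y) >= 0.85 * width / 2.0:
        return "fixed_rim"
    return "mid_sheet"


def peak_report(
    snapshots: list[FieldSnapshot],
    monitors: MonitorSeries,
    diameter: float,
    height: float = 40.0,
    length: float = 70.0,
    mesh=None,
    geometry_params=None,
) -> MetricsReport:
    """Assemble the metrics report: peaks and occurrence times from the dense
    monitors, end-time values from the final snapshot."""
    if not snapshots:
        raise InvalidParameterError("missing snapshots (run did not complete)")
    if monitors.time.size == 0:
        raise InvalidParameterError("empty monitor series")
    final = snapshots[-1]
    vm_end = float(von_mises(final.cauchy_stress).max())
    ps_end = float(max_principal(final.cauchy_stress).max())
    pe_end = float(max_principal(final.green_strain).max())

    vm_pk, vm_t = _peak(monitors.peak_von_mises, monitors.time)
    ps_pk, ps_t = _peak(monitors.peak_principal_stress, monitors.time)
    pe_pk, pe_t = _peak(monitors.peak_principal_strain, monitors.time)
    (uz, t_uz), (ux, t_ux) = displacement_extrema(monitors)
    rz, rx = extension_ratios(uz, ux, height=height, length=length)

    region = ""
    if mesh is not None and geometry_params is not None:
        vm_field = von_mises(final.cauchy_stress)
        e = int(np.argmax(vm_field))
        centroid = mesh.node_coords[mesh.tets[e]].mean(axis=0)
        region = classify_region(
            centroid[:2],
            geometry_params.length,
            geometry_params.width,
            geometry_params.hiatus_semiaxes,
        )

    return MetricsReport(
        diameter=diameter,
        max_von_mises=vm_pk,
        t_von_mises=vm_t,
        von_mises_end=vm_end,
        max_principal_stress=ps_pk,
        t_principal_stress=ps_t,
        principal_stress_end=ps_end,
        max_principal_strain=pe_pk,
        t_principal_strain=pe_t,
        principal_strain_end=pe_end,
        max_uz=uz,
        t_uz=t_uz,
        ux_span=ux,
        t_ux=t_ux,
        extension_ratio_z=rz,
        extension_ratio_x=rx,
        peak_region=region,
    )


def metrics_frame(reports: list[MetricsReport]) -> pd.DataFrame:
    """One row per head diameter, columns mirroring the published tables."""
    return pd.DataFrame([r.to_dict() for r in reports]).sort_values("diameter").reset_index(
        drop=True
    )
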