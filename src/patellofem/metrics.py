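"""Output measures: thresholded contact-stress statistics, Von Mises
equivalent stress, contact area, and clinical alignment indices.

Mean contact stress and mean VMes follow the literature inclusion rule:
only elements/faces with stress above tau = 0.271 MPa enter the mean
(including everything would dilute the mean with near-zero values).
Contact area is the sum of undeformed areas of patellar faces carrying any
positive pressure (numeric floor 1e-6 MPa); the threshold tau is *not*
applied to area by default, but a thresholded variant is available.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .fem.elasticity import element_stresses, von_mises
from .fem.materials import MaterialParams
from .fem.tetmesh import TetMesh
from .geometry.knee import KneeModel
from .solver import Solution

TAU_DEFAULT = 0.271            # MPa inclusion threshold
PRESSURE_FLOOR = 1e-6          # MPa numeric floor for "contacting"


class MetricsError(ValueError):
    pass


@dataclass
class StressMetrics:
    peak_pressure: float
    mean_pressure: float | None
    contact_area: float
    peak_vmes_patella: float
    mean_vmes_patella: float | None
    peak_vmes_trochlea: float
    mean_vmes_trochlea: float | None
    tau: float = TAU_DEFAULT


@dataclass
class AlignmentMetrics:
    patellar_tilt: float       # deg
    bisect_offset: float       # %
    tt_tg: float               # mm, + lateral


def _require_converged(sol: Solution) -> None:
    if not sol.converged:
        raise MetricsError(
            f"solution did not converge (status={sol.status!r}); refusing to "
            "report stress metrics"
        )


def pressure_stats(sol: Solution, tau: float = TAU_DEFAULT) -> tuple[float, float | None]:
    """(peak, mean) contact pressure over patellar faces.

    Peak over all contacting faces; mean area-weighted over faces with
    pressure > tau.  If no face passes the threshold the mean is None
    (absent), never zero.
    """
    _require_converged(sol)
    p = sol.face_pressure
    active = p > PRESSURE_FLOOR
    peak = float(p[active].max()) if active.any() else 0.0
    inc = p > tau
    if not inc.any():
        return peak, None
    A = sol.face_areas[inc]
    return peak, float(np.sum(p[inc] * A) / np.sum(A))


def contact_area(sol: Solution, tau: float | None = None) -> float:
    """Summed undeformed area of contacting patellar faces (mm^2).

    ``tau=None`` uses the numeric floor (any positive pressure); passing a
    threshold reproduces the alternative thresholded reading.
    """
    _require_converged(sol)
    cut = PRESSURE_FLOOR if tau is None else tau
    return float(sol.face_areas[sol.face_pressure > cut].sum())


def vmes_field(mesh: TetMesh, material: MaterialParams, u: np.ndarray) -> np.ndarray:
    """Per-element Von Mises equivalent stress sqrt(3 J2), MPa."""
    return von_mises(element_stresses(mesh, material, u))


def _interface_elements(mesh: TetMesh, surface: str) -> np.ndarray:
    if surface == "articular":
        nodes = mesh.articular_surface
    elif surface == "bone_interface":
        nodes = mesh.bone_interface
    else:
        raise MetricsError(
            f"unknown surface {surface!r}; expected 'articular' or 'bone_interface'"
        )
    mask = np.zeros(mesh.n_nodes, dtype=bool)
    mask[nodes] = True
    return np.where(mask[mesh.tets].any(axis=1))[0]


def vmes_stats(
    field: np.ndarray,
    mesh: TetMesh,
    surface: str = "bone_interface",
    tau: float = TAU_DEFAULT,
) -> tuple[float, float | None]:
    """(peak, mean) VMes over elements adjacent to the requested interface.

    Same tau inclusion rule as the pressure mean; mean is volume-weighted.
    """
    sel = _interface_elements(mesh, surface)
    vals = field[sel]
    peak = float(vals.max()) if len(vals) else 0.0
    inc = vals > tau
    if not inc.any():
        return peak, None
    vol = mesh.volumes()[sel][inc]
    return peak, float(np.sum(vals[inc] * vol) / np.sum(vol))


def stress_metrics(
    sol: Solution,
    femur_mesh: TetMesh,
    patella_mesh: TetMesh,
    material: MaterialParams,
    tau: float = TAU_DEFAULT,
    vmes_surface: str = "bone_interface",
) -> StressMetrics:
    """All stress outputs of one solve."""
    peak_p, mean_p = pressure_stats(sol, tau)
    area = contact_area(sol)
    vm_p = vmes_field(patella_mesh, material, sol.u_patella)
    vm_f = vmes_field(femur_mesh, material, sol.u_femur)
    pk_vp, mn_vp = vmes_stats(vm_p, patella_mesh, vmes_surface, tau)
    pk_vf, mn_vf = vmes_stats(vm_f, femur_mesh, vmes_surface, tau)
    return StressMetrics(
        peak_pressure=peak_p,
        mean_pressure=mean_p,
        contact_area=area,
        peak_vmes_patella=pk_vp,
        mean_vmes_patella=mn_vp,
        peak_vmes_trochlea=pk_vf,
        mean_vmes_trochlea=mn_vf,
        tau=tau,
    )


# ---------------------------------------------------------------------------
# alignment indices


def _landmark(model: KneeModel, name: str) -> np.ndarray:
    if name not in model.landmarks:
        raise MetricsError(f"missing landmark {name!r}")
    return np.asarray(model.landmarks[name], dtype=float)


def _groove_reference_point(model: KneeModel) -> np.ndarray:
    """Deepest trochlear groove point used for TT-TG and bisect offset.

    By clinical convention the groove is read on the most proximal axial
    image with full cartilage cover; the builder records that station.
    """
    poly = _landmark(model, "sulcus_polyline")
    z_ref = model.meta.get("ttg_station_z")
    if z_ref is None:
        return poly[int(np.argmax([0.0]))] if len(poly) == 1 else poly[len(poly) // 2]
    return poly[int(np.argmin(np.abs(poly[:, 2] - float(z_ref))))]


def patellar_tilt(model: KneeModel, translation: np.ndarray | None = None) -> float:
    """Axial-plane angle (deg) between the patellar transverse axis
    (medial edge midpoint -> most lateral point) and the posterior condylar
    baseline; positive when the lateral edge is posterior."""
    lat = _landmark(model, "most_lateral_patellar_point")
    med = _landmark(model, "medial_patellar_edge_midpoint")
    ax = lat - med  # translation cancels in the difference
    sign = 1.0 if model.side == "right" else -1.0
    return float(np.degrees(np.arctan2(-ax[1], sign * ax[0])))


def bisect_offset(model: KneeModel, translation: np.ndarray | None = None) -> float:
    """Percent of patellar width lateral to the sagittal plane through the
    deepest trochlear groove point; may exceed 100 for subluxation."""
    t = np.zeros(3) if translation is None else np.asarray(translation, float)
    lat = _landmark(model, "most_lateral_patellar_point") + t
    med = _landmark(model, "medial_patellar_edge_midpoint") + t
    x_ref = _groove_reference_point(model)[0]
    sign = 1.0 if model.side == "right" else -1.0
    width = sign * (lat[0] - med[0])
    if width <= 0:
        raise MetricsError("degenerate patellar transverse axis")
    return float(100.0 * sign * (lat[0] - x_ref) / width)


def tt_tg(model: KneeModel) -> float:
    """TT-TG distance (mm): lateral offset along the posterior condylar
    baseline between the tibial tuberosity and the trochlear groove."""
    tub = _landmark(model, "tibial_tuberosity_reference")
    groove = _groove_reference_point(model)
    sign = 1.0 if model.side == "right" else -1.0
    return float(sign * (tub[0] - groove[0]))


def alignment_metrics(model: KneeModel, sol: Solution | None = None) -> AlignmentMetrics:
    t = sol.patella_translation if sol is not None else None
    return AlignmentMetrics(
        patellar_tilt=patellar_tilt(model, t),
        bisect_offset=bisect_offset(model, t),
        tt_tg=tt_tg(model),
    )
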