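"""Parametric patella generator.

Builds a Wiberg-like patella as a loft of axial sections: a posterior
articular surface with a median ridge and medial/lateral facets, closed
anteriorly by the bony body.  The articular facets are carved to conform to
a reference groove profile (by default the mid-station arc of the trochlea
it will articulate with), while the bony outline carries the configured
patellar tilt — so the transverse-axis landmarks read the tilt exactly
without sacrificing articular congruence.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np
from scipy.interpolate import PchipInterpolator

from . import trochlea as _tro
from .profiles import AxialProfile, anterior_arc
from .surface import (
    REGION_CARTILAGE,
    GeometryError,
    LoftGrid,
    SurfaceMesh,
    ThicknessMap,
)


@dataclass
class PatellaParams:
    """Patellar shape and placement parameters (mm, deg)."""

    width: float = 34.0
    height: float = 32.0
    thickness_ap: float = 15.0
    tilt_deg: float = 0.0            # axial-plane tilt of the bony body (+ = lateral edge posterior)
    center_x: float = 0.0            # lateral position of the patellar center
    ridge_x: float = 0.0             # world x of the median ridge apex
    ridge_depth: float | None = None # None -> conform to the supplied trochlea
    ridge_angle: float = 138.0
    sagittal_radius: float = 500.0   # proximal-distal articular convexity
    edge_lift_coef: float = 0.012    # facet edges curve anteriorly (mm / mm^2)
    edge_lift_start: float = 11.0    # conforming half-width before lift begins
    clearance: float = 0.4           # unloaded articular standoff
    cart_z_half: float = 13.0        # articular cartilage half-height


def template_arc(depth: float, angle_deg: float) -> Callable[[np.ndarray], np.ndarray]:
    """Canonical normal-groove arc with the sulcus at (0, 0).

    Used as the articular template of a morphologically normal patella when
    the articulating trochlea is dysplastic.
    """
    x, i_mc, i_s, i_lc = _tro._arc_x_samples(
        -_tro.W_MED0, _tro.X_MC0, 0.0, _tro.X_LC, _tro.W_LAT, 56
    )
    y, y_s = anterior_arc(
        _tro.X_MC0, _tro.Y_MC0, _tro.X_LC, _tro.Y_LC, depth, 0.0, angle_deg,
        -_tro.W_MED0, _tro.Y_EDGE, _tro.W_LAT, _tro.Y_EDGE, x,
    )
    return PchipInterpolator(x, y - y_s, extrapolate=True)


def trochlea_arc_function(
    trochlea: SurfaceMesh, grid: LoftGrid
) -> Callable[[np.ndarray], np.ndarray]:
    """Mid-station anterior arc of a generated trochlea as y(x)."""
    i_ref = grid.station_nearest(0.0)
    ids = grid.vertex_ids[i_ref, : grid.n_arc]
    x = trochlea.vertices[ids, 0]
    y = trochlea.vertices[ids, 1]
    return PchipInterpolator(x, y, extrapolate=True)


def generate_patella(
    params: PatellaParams,
    trochlea: SurfaceMesh | None = None,
    trochlea_grid: LoftGrid | None = None,
    n_sections: int = 21,
    n_art: int = 36,
    n_ant: int = 20,
    seed: int = 0,
    jitter: float = 0.0,
) -> tuple[SurfaceMesh, ThicknessMap, dict, LoftGrid]:
    """Generate the patellar surface, thickness map and landmarks."""
    if trochlea is not None:
        bbox = trochlea.vertices[:, 0]
        if params.width > (bbox.max() - bbox.min()):
            raise GeometryError(
                "incompatible scale: patella wider than the trochlea bounding box"
            )
    if params.ridge_depth is None:
        if trochlea is None or trochlea_grid is None:
            raise GeometryError(
                "a trochlea is required when ridge_depth is not specified"
            )
        ref = trochlea_arc_function(trochlea, trochlea_grid)
    else:
        ref = template_arc(params.ridge_depth, params.ridge_angle)

    rng = np.random.default_rng(seed)
    alpha = np.radians(params.tilt_deg)
    h2 = params.height / 2.0
    zs = np.linspace(-h2, h2, n_sections)

    sections, labels, profiles = [], [], []
    for z in zs:
        s = _width_scale(abs(z), h2)
        half = 0.47 * params.width * s
        xs = np.linspace(params.center_x - half, params.center_x + half, n_art)
        lift = params.edge_lift_coef * np.maximum(
            np.abs(xs - params.center_x) - params.edge_lift_start, 0.0
        ) ** 2
        y_art = (
            np.asarray(ref(xs - params.ridge_x))
            + params.clearance
            + lift
            + z * z / (2.0 * params.sagittal_radius)
        )
        if jitter > 0.0:
            y_art = y_art + rng.normal(0.0, jitter, n_art)

        A = (params.width / 2.0 + 1.0) * s
        B = params.thickness_ap * (0.35 + 0.65 * s)
        y_c = max(y_art[0], y_art[-1]) + 1.0 + A * abs(np.sin(alpha))
        th = np.linspace(0.0, np.pi, n_ant + 2)
        ex, ey = A * np.cos(th), B * np.sin(th)
        rot_x = ex * np.cos(alpha) + ey * np.sin(alpha)
        rot_y = -ex * np.sin(alpha) + ey * np.cos(alpha)
        ant = np.stack([params.center_x + rot_x, y_c + rot_y], axis=1)

        pts = np.concatenate([np.stack([xs, y_art], axis=1), ant], axis=0)
        lab = np.zeros(len(pts), dtype=np.uint8)
        if abs(z) <= params.cart_z_half:
            lab[:n_art][np.abs(xs - params.center_x) <= 0.45 * params.width] = (
                REGION_CARTILAGE
            )
        sections.append(pts)
        labels.append(lab)
        ridge_idx = int(np.argmin(y_art))
        profiles.append(
            AxialProfile(
                z, pts.copy(),
                sulcus_index=max(1, min(ridge_idx, n_art - 2)),
                lc_index=n_art - 1, mc_index=0,
                baseline=np.array([1.0, 0.0]),
            )
        )

    mesh, grid = _loft(sections, zs, labels, n_art, profiles)
    thickness = ThicknessMap(_patella_thickness(mesh, params))
    landmarks = _patella_landmarks(mesh, grid, params, n_art, n_ant)
    return mesh, thickness, landmarks, grid


def _loft(sections, zs, labels, n_art, profiles):
    from .loft import loft_closed_sections

    return loft_closed_sections(sections, zs, np.stack(labels), n_art, profiles)


def _width_scale(az: float, h2: float) -> float:
    """Width taper toward the proximal/distal poles."""
    if az <= 9.0:
        return 1.0
    t = (az - 9.0) / (h2 - 9.0 + 1.5)
    return float(np.sqrt(max(1.0 - t * t, 0.1)))


def _patella_thickness(mesh: SurfaceMesh, p: PatellaParams) -> np.ndarray:
    t = np.zeros(mesh.n_vertices)
    cart = mesh.cartilage_mask
    v = mesh.vertices
    tx = np.clip(1.0 - ((v[:, 0] - p.center_x) / (0.52 * p.width)) ** 2, 0.0, 1.0)
    tz = np.clip(1.0 - (v[:, 2] / (p.cart_z_half + 1.0)) ** 2, 0.0, 1.0)
    t[cart] = 1.8 + 1.4 * (tx * tz)[cart]
    return t


def _patella_landmarks(
    mesh: SurfaceMesh, grid: LoftGrid, p: PatellaParams, n_art: int, n_ant: int
) -> dict:
    v = mesh.vertices
    iz0 = grid.station_nearest(0.0)
    C = grid.vertex_ids.shape[1]
    lateral = v[grid.vertex_ids[iz0, n_art]]          # ellipse theta=0 end
    medial = v[grid.vertex_ids[iz0, C - 1]]           # ellipse theta=pi end
    ridge = v[grid.vertex_ids[iz0, grid.profiles[iz0].sulcus_index]]
    n_grid = grid.vertex_ids.size
    return {
        "most_lateral_patellar_point": lateral.copy(),
        "medial_patellar_edge_midpoint": medial.copy(),
        "patellar_ridge_apex": ridge.copy(),
        "patella_inferior_pole": v[n_grid].copy(),
        "patella_superior_pole": v[n_grid + 1].copy(),
        "patella_center": v[: n_grid].mean(axis=0),
    }
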