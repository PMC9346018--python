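"""Parametric femoral trochlea generator.

Synthesizes a watertight distal-femur segment (bone + articular cartilage
labels) as a loft of axial profiles.  Two morphologies are supported through
:class:`DysplasiaParams`: a normally grooved trochlea, and a severely
dysplastic one with a flat-to-convex proximal groove, medial facet
hypoplasia and a supratrochlear spur (Dejour type D features).

The generated frame has the deepest mid-trochlear sulcus point at the
origin, +x lateral along the posterior condylar baseline, +y anterior,
+z proximal.  All lengths in mm.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .loft import loft_closed_sections
from .profiles import AxialProfile, anterior_arc
from .surface import (
    REGION_CARTILAGE,
    GeometryError,
    LoftGrid,
    SurfaceMesh,
    ThicknessMap,
)

# fixed construction constants (mm) -- distal femur of a typical adult female
Z_DISTAL = -24.0
Z_PROXIMAL = 20.0
W_LAT = 25.0              # lateral half-width of the section
W_MED0 = 23.0             # medial half-width before facet hypoplasia scaling
X_LC = 15.0               # lateral condylar prominence
X_MC0 = -13.0             # medial condylar prominence before scaling
Y_LC = 24.0               # anterior height of LC
Y_MC0 = 22.0              # anterior height of MC
Y_EDGE = 8.0              # anterior height at the section's side edges
POST_DEPTH = 26.0         # posterior extent of the condylar arc below Y_EDGE
Z_NOTCH = -10.0           # station where the groove starts diving into the notch
NOTCH_COEF = 0.08         # quadratic dive rate (mm / mm^2)
CART_Z_MIN = -24.0        # distal margin of trochlear cartilage (into the notch)
CART_Z_FULL = 12.0        # most proximal station with full-arc cartilage cover
CART_Z_MAX = 18.0         # proximal cartilage margin (tapering cover)

_PARAM_RANGES = {
    "sulcus_depth": (-4.0, 8.0),
    "sulcus_angle": (100.0, 179.0),
    "spur_height": (0.0, 6.0),
    "medial_facet_scale": (0.4, 1.2),
    "groove_lateral_offset": (-6.0, 6.0),
    "proximal_depth": (-5.0, 8.0),
}


class ConfigurationError(ValueError):
    """A generator parameter is outside its documented range."""


@dataclass
class DysplasiaParams:
    """Shape parameters of the trochlear groove.

    sulcus_depth : groove depth (mm) at the central/distal trochlea; must be
        >= 0 for the healthy preset, may reach <= 0 proximally for dysplasia.
    sulcus_angle : opening angle of the groove (deg); ~138 deg is normal,
        > 150 deg is dysplastic.
    spur_height : supratrochlear spur prominence (mm), dysplastic only.
    medial_facet_scale : multiplier on medial facet width/height (hypoplasia
        when < 1).
    groove_lateral_offset : lateral shift of the groove line (mm).
    proximal_depth : groove depth at the proximal margin; defaults to
        0.7 * sulcus_depth (healthy taper), negative values give the
        flat/convex proximal trochlea of type-D dysplasia.
    """

    sulcus_depth: float = 5.0
    sulcus_angle: float = 138.0
    spur_height: float = 0.0
    medial_facet_scale: float = 1.0
    groove_lateral_offset: float = 0.0
    proximal_depth: float | None = None

    def __post_init__(self) -> None:
        if self.proximal_depth is None:
            self.proximal_depth = 0.7 * self.sulcus_depth
        for name, (lo, hi) in _PARAM_RANGES.items():
            v = getattr(self, name)
            if not (lo <= v <= hi):
                raise ConfigurationError(
                    f"parameter {name}={v} outside documented range [{lo}, {hi}]"
                )


HEALTHY_TROCHLEA = dict(
    sulcus_depth=5.0,
    sulcus_angle=138.0,
    spur_height=0.0,
    medial_facet_scale=1.0,
    groove_lateral_offset=0.0,
    proximal_depth=3.5,
)

DYSPLASTIC_D_TROCHLEA = dict(
    sulcus_depth=1.5,
    sulcus_angle=162.0,
    spur_height=2.0,
    medial_facet_scale=0.75,
    groove_lateral_offset=2.0,
    proximal_depth=-1.5,
)


def _smoothstep(t: np.ndarray | float) -> np.ndarray | float:
    t = np.clip(t, 0.0, 1.0)
    return t * t * (3.0 - 2.0 * t)


def _depth_profile(z: float, p: DysplasiaParams) -> float:
    """Groove depth along the axis: distal value blending to proximal value."""
    t = _smoothstep((z - (-5.0)) / (Z_PROXIMAL - (-5.0)))
    return float(p.sulcus_depth + (p.proximal_depth - p.sulcus_depth) * t)


def _arc_x_samples(
    x_edge_m: float, x_mc: float, x_s: float, x_lc: float, x_edge_l: float, n_arc: int
) -> tuple[np.ndarray, int, int, int]:
    """Arc abscissae that contain MC, S and LC exactly; returns indices."""
    knots = [x_edge_m, x_mc, x_s, x_lc, x_edge_l]
    spans = np.diff(knots)
    counts = np.maximum(3, np.round(spans / spans.sum() * (n_arc - 1)).astype(int))
    # adjust the largest segment so the total matches exactly
    counts[int(np.argmax(counts))] += (n_arc - 1) - counts.sum()
    xs = [np.array([x_edge_m])]
    for a, b, c in zip(knots[:-1], knots[1:], counts):
        xs.append(np.linspace(a, b, c + 1)[1:])
    x = np.concatenate(xs)
    i_mc = int(counts[0])
    i_s = int(counts[0] + counts[1])
    i_lc = int(counts[0] + counts[1] + counts[2])
    return x, i_mc, i_s, i_lc


def trochlea_section(
    z: float, p: DysplasiaParams, n_arc: int, n_post: int
) -> tuple[np.ndarray, int, int, int, np.ndarray]:
    """One axial section contour.  Returns (points (C,2), i_mc, i_s, i_lc,
    cartilage-candidate mask over the arc columns)."""
    mfs = p.medial_facet_scale
    w_m = W_MED0 * mfs
    x_mc = X_MC0 * mfs
    y_mc = Y_MC0 * (0.8 + 0.2 * mfs)
    y_lc = Y_LC
    # trochlea flattens onto the anterior cortex proximally
    fac = 1.0 - 0.015 * max(z - 10.0, 0.0)
    y_mc *= fac
    y_lc *= fac
    x_s = p.groove_lateral_offset
    depth = _depth_profile(z, p)

    x_arc, i_mc, i_s, i_lc = _arc_x_samples(-w_m, x_mc, x_s, X_LC, W_LAT, n_arc)
    y_arc, _ = anterior_arc(
        x_mc, y_mc, X_LC, y_lc, depth, x_s, p.sulcus_angle,
        -w_m, Y_EDGE, W_LAT, Y_EDGE, x_arc,
    )

    # groove dives posteriorly into the intercondylar notch distally
    drop = NOTCH_COEF * max(Z_NOTCH - z, 0.0) ** 2
    if drop > 0.0:
        w = np.ones_like(x_arc)
        lat_t = np.clip((x_arc - X_LC) / (W_LAT - X_LC), 0.0, 1.0)
        med_t = np.clip((x_mc - x_arc) / (x_mc + w_m), 0.0, 1.0)
        w *= 0.5 * (1.0 + np.cos(np.pi * lat_t))
        w *= 0.5 * (1.0 + np.cos(np.pi * med_t))
        y_arc = y_arc - drop * w

    # supratrochlear spur: anterior bump over the groove, proximal only
    if p.spur_height > 0.0:
        ramp = _smoothstep((z - 6.0) / 8.0)
        if ramp > 0.0:
            y_arc = y_arc + p.spur_height * ramp * np.exp(-(((x_arc - x_s) / 8.0) ** 2))

    # posterior condylar arc: half-ellipse closing the section
    cx = 0.5 * (W_LAT + (-w_m))
    a = 0.5 * (W_LAT - (-w_m))
    b = POST_DEPTH + 0.0
    t = np.linspace(0.0, np.pi, n_post + 2)[1:-1]
    post = np.stack([cx + a * np.cos(t), Y_EDGE - b * np.sin(t)], axis=1)

    pts = np.concatenate([np.stack([x_arc, y_arc], axis=1), post], axis=0)
    return pts, i_mc, i_s, i_lc, x_arc


def generate_trochlea(
    params: DysplasiaParams,
    n_stations: int = 29,
    n_arc: int = 56,
    n_post: int = 28,
    seed: int = 0,
    jitter: float = 0.0,
) -> tuple[SurfaceMesh, ThicknessMap, dict, LoftGrid]:
    """Generate the femoral trochlea surface, thickness map and landmarks.

    Deterministic for a fixed seed; vertex jitter (mm, default 0) perturbs
    the anterior arc only and is used for robustness testing.
    """
    if n_stations < 4:
        raise ConfigurationError("n_stations must be >= 4")
    rng = np.random.default_rng(seed)
    zs = np.linspace(Z_DISTAL, Z_PROXIMAL, n_stations)

    sections, labels, profiles = [], [], []
    for z in zs:
        pts, i_mc, i_s, i_lc, x_arc = trochlea_section(z, params, n_arc, n_post)
        if jitter > 0.0:
            pts[1 : n_arc - 1, 1] += rng.normal(0.0, jitter, n_arc - 2)
        lab = np.zeros(len(pts), dtype=np.uint8)
        lab[: len(x_arc)][_cartilage_arc_mask(z, x_arc, i_mc, i_s, i_lc)] = (
            REGION_CARTILAGE
        )
        sections.append(pts)
        labels.append(lab)
        profiles.append(
            AxialProfile(z, pts.copy(), i_s, i_lc, i_mc, np.array([1.0, 0.0]))
        )

    mesh, grid = loft_closed_sections(
        sections, zs, np.stack(labels), n_arc, profiles
    )

    # center the frame on the deepest mid-trochlear sulcus point
    i_ref = int(np.argmin(np.abs(zs)))
    s_ref = mesh.vertices[grid.vertex_ids[i_ref, profiles[i_ref].sulcus_index]].copy()
    mesh.vertices -= s_ref
    grid.z_stations = grid.z_stations - s_ref[2]
    for prof in grid.profiles:
        prof.z -= s_ref[2]
        prof.contour -= s_ref[:2]

    thickness = ThicknessMap(_thickness_field(mesh, grid, params))
    landmarks = _trochlea_landmarks(mesh, grid, params, s_ref)
    return mesh, thickness, landmarks, grid


def _cartilage_arc_mask(
    z: float, x_arc: np.ndarray, i_mc: int, i_s: int, i_lc: int
) -> np.ndarray:
    """Columns of the section labeled cartilage (anterior arc band)."""
    mask = np.zeros(len(x_arc), dtype=bool)
    if not (CART_Z_MIN <= z <= CART_Z_MAX):
        return mask
    x_lo = x_arc[max(i_mc - 2, 1)]
    x_hi = x_arc[min(i_lc + 2, len(x_arc) - 2)]
    if z > CART_Z_FULL:
        # cover narrows toward the groove at the proximal margin
        f = (z - CART_Z_FULL) / (CART_Z_MAX - CART_Z_FULL)
        x_s = x_arc[i_s]
        x_lo = x_lo + 0.9 * f * (x_s - x_lo)
        x_hi = x_hi - 0.9 * f * (x_hi - x_s)
    mask[: len(x_arc)] = (x_arc >= x_lo) & (x_arc <= x_hi)
    return mask


def _thickness_field(mesh: SurfaceMesh, grid: LoftGrid, p: DysplasiaParams) -> np.ndarray:
    """Smooth cartilage thickness, thickest over the groove center."""
    t = np.zeros(mesh.n_vertices)
    cart = mesh.cartilage_mask
    v = mesh.vertices
    x_s = 0.0  # sulcus is at x=0 after centering (up to the groove offset shift)
    span_x = 0.5 * (X_LC - X_MC0)
    z_mid = 0.5 * (CART_Z_MIN + CART_Z_MAX)
    span_z = 0.5 * (CART_Z_MAX - CART_Z_MIN)
    tx = np.clip(1.0 - ((v[:, 0] - x_s) / (1.6 * span_x)) ** 2, 0.0, 1.0)
    tz = np.clip(1.0 - ((v[:, 2] - z_mid) / (1.3 * span_z)) ** 2, 0.0, 1.0)
    t[cart] = 1.4 + 1.2 * (tx * tz)[cart]
    return t


def _trochlea_landmarks(
    mesh: SurfaceMesh, grid: LoftGrid, p: DysplasiaParams, s_ref: np.ndarray
) -> dict:
    v = mesh.vertices
    i_ref = int(np.argmin(np.abs(grid.z_stations)))
    prof = grid.profiles[i_ref]
    lc = v[grid.vertex_ids[i_ref, prof.lc_index]]
    mc = v[grid.vertex_ids[i_ref, prof.mc_index]]

    poly = []
    for i, prof_i in enumerate(grid.profiles):
        z = grid.z_stations[i]
        if CART_Z_MIN - s_ref[2] <= z <= CART_Z_MAX - s_ref[2]:
            poly.append(v[grid.vertex_ids[i, prof_i.sulcus_index]])
    sulcus_polyline = np.asarray(poly)

    w_m = W_MED0 * p.medial_facet_scale
    lm = {
        "LC": lc.copy(),
        "MC": mc.copy(),
        "sulcus_polyline": sulcus_polyline,
        "adductor_tubercle": np.array([-(w_m + 3.0), 0.0, 14.0]) - s_ref,
        "lateral_epicondyle": np.array([W_LAT + 3.0, 0.0, 2.0]) - s_ref,
        "posterior_condylar_axis": np.array(
            [np.array([0.0, Y_EDGE - 0.6 * POST_DEPTH, 0.0]) - s_ref, [1.0, 0.0, 0.0]]
        ),
    }
    return lm
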