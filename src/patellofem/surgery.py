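"""Virtual sulcus-deepening trochleoplasty.

The operator relocates the trochlear sulcus S to S1 by a lateralization L
(along the posterior condylar baseline BL) and a deepening D
(perpendicular to BL, posteriorly), scaled by a correction factor f.  Two
correction planes bound the osteotomy: a proximal one where the trochlea
first becomes fully cartilage-covered and a distal one where the groove
turns into the intercondylar notch.  At each axial station between the
planes the anterior subchondral contour is rebuilt as a smoothed
LC-S1-MC line; the displacement tapers to zero over a configurable blend
width outside the band.  The osteochondral flap is re-draped onto the new
bed: the per-vertex cartilage thickness map is carried unchanged (the
procedure moves the flap, it does not thin cartilage).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import PchipInterpolator
from shapely.geometry import Point, Polygon

from .geometry.knee import KneeModel
from .geometry.surface import GeometryError

DEFAULT_L_MEAN = 6.1   # mm mean lateralization (from the reported TT-TG change)
DEFAULT_D_MEAN = 4.0   # mm mean deepening (configurable; no printed value)


class SurgeryError(ValueError):
    pass


@dataclass(frozen=True)
class SurgeryParams:
    """Correction parameters of the virtual trochleoplasty."""

    L_mean: float = DEFAULT_L_MEAN      # mm
    D_mean: float = DEFAULT_D_MEAN      # mm
    f: float = 1.0                      # correction factor (0.5 / 1.0 / 1.5 nominal)
    proximal_z: float | None = None     # mm; located automatically when None
    distal_z: float | None = None
    blend: float = 3.0                  # mm taper outside the correction band
    contour_mode: str = "smooth"        # "smooth" pchip | "straight" two segments

    def __post_init__(self) -> None:
        if self.L_mean < 0 or self.D_mean < 0:
            raise SurgeryError("L_mean and D_mean must be non-negative")
        if self.f < 0:
            raise SurgeryError("correction factor must be non-negative")
        if (
            self.proximal_z is not None
            and self.distal_z is not None
            and self.proximal_z <= self.distal_z
        ):
            raise SurgeryError("proximal plane must be proximal to the distal plane")
        if self.contour_mode not in ("smooth", "straight"):
            raise SurgeryError("contour_mode must be 'smooth' or 'straight'")


@dataclass
class OsteotomyResult:
    model: KneeModel
    s1_polyline: np.ndarray          # displaced sulcus line (k, 3)
    wedge_volume: float              # mm^3 of resected bone
    displacement: np.ndarray         # per-femoral-vertex displacement magnitude
    proximal_z: float
    distal_z: float
    params: SurgeryParams


def tt_tg_change(p: SurgeryParams) -> float:
    """Reduction of the TT-TG distance produced by the correction: the
    groove lateralizes by f*L_mean toward the (fixed) tibial tuberosity."""
    return p.f * p.L_mean


def locate_correction_planes(
    model: KneeModel, notch_angle_threshold: float = 45.0
) -> tuple[float, float]:
    """Locate the proximal/distal correction planes on a generated model.

    Proximal: the most proximal station whose full anterior arc (MC..LC)
    is cartilage-labeled.  Distal: the most distal station before the
    sulcus polyline's tangent to the axis exceeds the notch-turn threshold.
    """
    grid = model.femur_grid
    if grid is None or not grid.profiles:
        raise SurgeryError(
            "model carries no station grid; provide the correction planes "
            "explicitly via SurgeryParams"
        )
    mesh = model.femur_surface
    cart = mesh.cartilage_mask

    proximal_z = None
    for i in reversed(range(len(grid.z_stations))):
        prof = grid.profiles[i]
        cols = np.arange(prof.mc_index, prof.lc_index + 1)
        if cart[grid.vertex_ids[i, cols]].all():
            proximal_z = float(grid.z_stations[i])
            break
    if proximal_z is None:
        raise SurgeryError(
            "no station is fully cartilage-covered; override the proximal "
            "plane manually"
        )

    poly = np.asarray(model.landmarks["sulcus_polyline"], float)
    if len(poly) < 2:
        raise SurgeryError("sulcus polyline too short to locate the distal plane")
    order = np.argsort(poly[:, 2])
    poly = poly[order]
    tan = np.diff(poly, axis=0)
    dz = np.abs(tan[:, 2])
    lat = np.linalg.norm(tan[:, :2], axis=1)
    ang = np.degrees(np.arctan2(lat, dz))  # angle of the tangent to the +z axis
    distal_z = float(poly[0, 2])
    for i in range(len(ang)):
        if ang[i] <= notch_angle_threshold:
            distal_z = float(poly[i, 2])
            break
    else:
        raise SurgeryError(
            "sulcus tangent exceeds the notch threshold everywhere; override "
            "the distal plane manually"
        )
    if distal_z >= proximal_z:
        raise SurgeryError(
            "located planes are inverted; override the planes manually"
        )
    return proximal_z, distal_z


def new_sulcus_point(profile, L: float, D: float) -> np.ndarray:
    """S1 = S + L * (lateral BL direction) + D * (posterior normal).

    In the model frame BL = +x (lateral) and anterior = +y, so
    S1 = S + (L, -D).  Raises when S1 leaves the bone contour (deepening
    exceeds the local bone stock).
    """
    bl = np.asarray(profile.baseline, float)
    lateral = bl / np.linalg.norm(bl)
    # posterior = lateral rotated by -90 deg: (x, y) -> (y, -x)
    posterior = np.array([lateral[1], -lateral[0]])
    s1 = np.asarray(profile.sulcus, float) + L * lateral + D * posterior
    contour = Polygon(profile.contour)
    if not contour.covers(Point(s1)):  # boundary counts as inside (L=D=0)
        raise SurgeryError(
            f"deepening exceeds local bone stock at station z={profile.z:.1f}: "
            f"S1={s1.round(2).tolist()} leaves the bone contour"
        )
    return s1


def _band_scale(z: np.ndarray, distal_z: float, proximal_z: float, blend: float):
    """1 inside the correction band, cosine taper to 0 over ``blend``."""
    s = np.zeros_like(z, dtype=float)
    inside = (z >= distal_z) & (z <= proximal_z)
    s[inside] = 1.0
    if blend > 0:
        below = (z < distal_z) & (z >= distal_z - blend)
        s[below] = 0.5 * (1 + np.cos(np.pi * (distal_z - z[below]) / blend))
        above = (z > proximal_z) & (z <= proximal_z + blend)
        s[above] = 0.5 * (1 + np.cos(np.pi * (z[above] - proximal_z) / blend))
    return s


def apply_trochleoplasty(model: KneeModel, p: SurgeryParams) -> OsteotomyResult:
    """Apply the virtual sulcus-deepening trochleoplasty.

    Identity at f=0; displacement support confined to the correction band
    plus the blend taper; thickness map preserved exactly (flap re-draped).
    """
    grid = model.femur_grid
    if grid is None:
        raise SurgeryError("model carries no station grid")
    if p.proximal_z is not None and p.distal_z is not None:
        proximal_z, distal_z = float(p.proximal_z), float(p.distal_z)
    else:
        proximal_z, distal_z = locate_correction_planes(model)
        if p.proximal_z is not None:
            proximal_z = float(p.proximal_z)
        if p.distal_z is not None:
            distal_z = float(p.distal_z)

    out = model.copy()
    mesh = out.femur_surface
    gridc = out.femur_grid
    zs = gridc.z_stations
    scale = _band_scale(zs, distal_z, proximal_z, p.blend)

    L_f = p.f * p.L_mean
    D_f = p.f * p.D_mean

    wedge = 0.0
    disp = np.zeros(mesh.n_vertices)
    s1_line = []
    station_widths = np.gradient(zs)

    for i, prof in enumerate(gridc.profiles):
        s = scale[i]
        if s <= 0.0 or (L_f == 0.0 and D_f == 0.0):
            if s > 0:
                ids = gridc.vertex_ids[i, prof.sulcus_index]
                s1_line.append(mesh.vertices[ids].copy())
            continue
        try:
            s1 = new_sulcus_point(prof, s * L_f, s * D_f)
        except SurgeryError as exc:
            raise SurgeryError(f"station {i}: {exc}") from exc

        cols = np.arange(prof.mc_index, prof.lc_index + 1)
        ids = gridc.vertex_ids[i, cols]
        x = mesh.vertices[ids, 0]
        y_old = mesh.vertices[ids, 1].copy()
        mc = prof.mc
        lc = prof.lc

        if p.contour_mode == "smooth":
            knots_x = [mc[0], s1[0], lc[0]]
            knots_y = [mc[1], s1[1], lc[1]]
            fint = PchipInterpolator(knots_x, knots_y)
            y_new = np.asarray(fint(x))
        else:
            y_new = np.where(
                x <= s1[0],
                mc[1] + (s1[1] - mc[1]) * (x - mc[0]) / (s1[0] - mc[0]),
                s1[1] + (lc[1] - s1[1]) * (x - s1[0]) / (lc[0] - s1[0]),
            )
        # the anchors LC/MC stay, interior replaced
        y_new[0] = y_old[0]
        y_new[-1] = y_old[-1]
        if np.any(np.diff(x) <= 0):
            raise SurgeryError(f"station {i}: non-monotone arc after remap")

        mesh.vertices[ids, 1] = y_new
        disp[ids] = np.abs(y_new - y_old)
        wedge += np.trapezoid(np.maximum(y_old - y_new, 0.0), x) * station_widths[i]

        # update the profile bookkeeping
        prof.contour[cols, 1] = y_new
        new_s_col = int(cols[np.argmin(np.abs(x - s1[0]))])
        prof.sulcus_index = new_s_col
        s1_line.append(
            np.array([s1[0], float(np.interp(s1[0], x, y_new)), prof.z])
        )

    s1_polyline = np.asarray(s1_line) if s1_line else np.empty((0, 3))

    # landmarks: the sulcus polyline follows the displaced groove
    poly = np.asarray(out.landmarks["sulcus_polyline"], float)
    if len(s1_polyline):
        newpoly = poly.copy()
        for j in range(len(newpoly)):
            zj = newpoly[j, 2]
            k = int(np.argmin(np.abs(s1_polyline[:, 2] - zj)))
            if abs(s1_polyline[k, 2] - zj) < 1e-6:
                newpoly[j] = s1_polyline[k]
            else:
                sc = _band_scale(np.array([zj]), distal_z, proximal_z, p.blend)[0]
                newpoly[j, 0] += sc * L_f
                newpoly[j, 1] -= sc * D_f
        out.landmarks["sulcus_polyline"] = newpoly
    out.meta = dict(out.meta)
    out.meta["surgery"] = dataclasses.asdict(p)

    return OsteotomyResult(
        model=out,
        s1_polyline=s1_polyline,
        wedge_volume=float(wedge),
        displacement=disp,
        proximal_z=proximal_z,
        distal_z=distal_z,
        params=p,
    )
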