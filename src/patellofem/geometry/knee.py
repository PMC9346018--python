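"""Knee model assembly: presets emulating a healthy and a severely
trochleodysplastic (type D) knee.

The presets target the clinical indices of the two study conditions the
package is calibrated to: the dysplastic knee a TT-TG distance near 17 mm,
patellar tilt 18 deg and bisect offset 76 %; the healthy knee tilt 12 deg
and bisect offset 48.5 %.  All remaining shape parameters are the
generators' own design choices and are documented as such, not as
patient-derived anatomy.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from scipy.interpolate import RegularGridInterpolator

from .patella import PatellaParams, generate_patella
from .surface import GeometryError, LoftGrid, SurfaceMesh, ThicknessMap
from .trochlea import (
    CART_Z_FULL,
    DYSPLASTIC_D_TROCHLEA,
    HEALTHY_TROCHLEA,
    ConfigurationError,
    DysplasiaParams,
    generate_trochlea,
)

REQUIRED_LANDMARKS = (
    "LC",
    "MC",
    "sulcus_polyline",
    "adductor_tubercle",
    "lateral_epicondyle",
    "medial_patellar_edge_midpoint",
    "most_lateral_patellar_point",
    "tibial_tuberosity_reference",
    "posterior_condylar_axis",
)


@dataclass
class KneeModel:
    """Bone + cartilage surfaces, thickness maps and named landmarks."""

    femur_surface: SurfaceMesh
    patella_surface: SurfaceMesh
    femur_thickness: ThicknessMap
    patella_thickness: ThicknessMap
    landmarks: dict
    side: str = "right"
    femur_grid: LoftGrid | None = None
    patella_grid: LoftGrid | None = None
    meta: dict = field(default_factory=dict)

    def validate(self) -> None:
        for name in REQUIRED_LANDMARKS:
            if name not in self.landmarks:
                raise GeometryError(f"missing landmark {name!r}")
        self.femur_surface.validate()
        self.patella_surface.validate()
        if self.femur_surface.side != self.side or self.patella_surface.side != self.side:
            raise GeometryError("inconsistent side flags across parts")

    def mirrored(self) -> "KneeModel":
        """Reflect across the sagittal plane (right <-> left)."""
        lm = {}
        for k, v in self.landmarks.items():
            a = np.array(v, dtype=float, copy=True)
            a[..., 0] *= -1.0
            lm[k] = a
        return KneeModel(
            self.femur_surface.mirrored(),
            self.patella_surface.mirrored(),
            self.femur_thickness.copy(),
            self.patella_thickness.copy(),
            lm,
            side=("left" if self.side == "right" else "right"),
            femur_grid=self.femur_grid,
            patella_grid=self.patella_grid,
            meta=dict(self.meta),
        )

    def copy(self) -> "KneeModel":
        import copy as _copy

        return KneeModel(
            self.femur_surface.copy(),
            self.patella_surface.copy(),
            self.femur_thickness.copy(),
            self.patella_thickness.copy(),
            {k: np.array(v, copy=True) for k, v in self.landmarks.items()},
            side=self.side,
            femur_grid=_copy.deepcopy(self.femur_grid),
            patella_grid=_copy.deepcopy(self.patella_grid),
            meta=dict(self.meta),
        )


PRESETS = {
    "healthy": dict(
        trochlea=HEALTHY_TROCHLEA,
        tilt_deg=12.0,
        bisect_offset=48.5,
        tt_tg=9.0,
        ridge_depth=None,  # articular facets conform to the trochlea
    ),
    "dysplastic_D": dict(
        trochlea=DYSPLASTIC_D_TROCHLEA,
        tilt_deg=18.0,
        bisect_offset=76.0,
        tt_tg=17.0,
        ridge_depth=2.5,   # flattened (Wiberg II/III-like) patellar ridge
    ),
}

_RESOLUTION_KEYS = ("n_stations", "n_arc", "n_post", "n_sections", "n_art", "n_ant")
_TARGET_KEYS = ("tilt_deg", "bisect_offset", "tt_tg", "ridge_depth")
_TROCHLEA_KEYS = tuple(f.name for f in dataclasses.fields(DysplasiaParams))
_PATELLA_KEYS = tuple(
    f.name
    for f in dataclasses.fields(PatellaParams)
    if f.name not in ("tilt_deg", "center_x", "ridge_x", "ridge_depth")
)
VALID_OVERRIDE_KEYS = _TROCHLEA_KEYS + _PATELLA_KEYS + _TARGET_KEYS + _RESOLUTION_KEYS + (
    "jitter",
)

DEFAULT_RESOLUTION = dict(
    n_stations=29, n_arc=56, n_post=28, n_sections=21, n_art=36, n_ant=20
)
COARSE_RESOLUTION = dict(
    n_stations=23, n_arc=38, n_post=16, n_sections=15, n_art=26, n_ant=12
)


def trochlea_height_function(
    trochlea: SurfaceMesh, grid: LoftGrid
) -> Callable[[np.ndarray, np.ndarray], np.ndarray]:
    """Anterior trochlear surface height y(x, z) from the loft grid."""
    ids = grid.vertex_ids[:, : grid.n_arc]
    x = trochlea.vertices[ids[0], 0]          # arc abscissae are z-invariant
    z = grid.z_stations
    y = trochlea.vertices[ids.reshape(-1), 1].reshape(ids.shape)
    interp = RegularGridInterpolator(
        (z, x), y, bounds_error=False, fill_value=None
    )

    def h(xq: np.ndarray, zq: np.ndarray) -> np.ndarray:
        return interp(np.stack([zq, xq], axis=-1))

    return h


def build_knee(
    preset: str = "healthy",
    overrides: dict | None = None,
    seed: int = 0,
    resolution: dict | None = None,
) -> KneeModel:
    """Build a fully populated :class:`KneeModel` from a named preset.

    ``overrides`` accepts generator parameters, clinical-index targets and
    resolution controls; an unknown key raises with the valid key list.
    """
    if preset not in PRESETS:
        raise ConfigurationError(
            f"unknown preset {preset!r}; valid presets: {sorted(PRESETS)}"
        )
    cfg = {k: (dict(v) if isinstance(v, dict) else v) for k, v in PRESETS[preset].items()}
    overrides = dict(overrides or {})
    for key in overrides:
        if key not in VALID_OVERRIDE_KEYS:
            raise ConfigurationError(
                f"unknown override {key!r}; valid keys: {sorted(VALID_OVERRIDE_KEYS)}"
            )
    res = dict(DEFAULT_RESOLUTION)
    res.update(resolution or {})
    for k in _RESOLUTION_KEYS:
        if k in overrides:
            res[k] = int(overrides.pop(k))
    jitter = float(overrides.pop("jitter", 0.0))

    troch_kwargs = dict(cfg["trochlea"])
    for k in list(overrides):
        if k in _TROCHLEA_KEYS:
            troch_kwargs[k] = overrides.pop(k)
    targets = {k: cfg[k] for k in ("tilt_deg", "bisect_offset", "tt_tg", "ridge_depth")}
    for k in list(overrides):
        if k in _TARGET_KEYS:
            targets[k] = overrides.pop(k)

    t_params = DysplasiaParams(**troch_kwargs)
    femur, femur_t, lm, femur_grid = generate_trochlea(
        t_params,
        n_stations=res["n_stations"],
        n_arc=res["n_arc"],
        n_post=res["n_post"],
        seed=seed,
        jitter=jitter,
    )

    # patellar placement from the clinical-index targets
    p_kwargs = {k: overrides.pop(k) for k in list(overrides) if k in _PATELLA_KEYS}
    p_params = PatellaParams(**p_kwargs)
    alpha = np.radians(targets["tilt_deg"])
    half_ax = (p_params.width / 2.0 + 1.0) * np.cos(alpha)
    center_x = 2.0 * half_ax * (targets["bisect_offset"] / 100.0 - 0.5)
    p_params = dataclasses.replace(
        p_params,
        tilt_deg=targets["tilt_deg"],
        center_x=float(center_x),
        ridge_x=0.0 if targets["ridge_depth"] is None else float(center_x),
        ridge_depth=targets["ridge_depth"],
    )
    patella, patella_t, plm, patella_grid = generate_patella(
        p_params,
        femur,
        femur_grid,
        n_sections=res["n_sections"],
        n_art=res["n_art"],
        n_ant=res["n_ant"],
        seed=seed + 1,
        jitter=jitter,
    )

    # place the patella at the configured start pose: shift anteriorly so the
    # unloaded cartilage layers have exactly the configured standoff
    height = trochlea_height_function(femur, femur_grid)
    v = patella.vertices
    zq = np.clip(v[:, 2], femur_grid.z_stations[0], femur_grid.z_stations[-1])
    xq = np.clip(
        v[:, 0],
        femur.vertices[femur_grid.vertex_ids[0, 0], 0],
        femur.vertices[femur_grid.vertex_ids[0, femur_grid.n_arc - 1], 0],
    )
    gap = v[:, 1] - height(xq, zq)
    dy = p_params.clearance - float(gap.min())
    patella.vertices[:, 1] += dy
    for k in plm:
        plm[k] = np.asarray(plm[k], dtype=float)
        plm[k][..., 1] += dy

    lm.update(plm)

    # tibial tuberosity reference: fixed lateral offset from the groove point
    # used for TT-TG (groove at the most proximal fully covered station)
    full_z = [
        z for z in femur_grid.z_stations if z <= CART_Z_FULL - _shift_z(femur_grid)
    ]
    ttg_station_z = max(full_z)
    poly = lm["sulcus_polyline"]
    groove_pt = poly[int(np.argmin(np.abs(poly[:, 2] - ttg_station_z)))]
    lm["tibial_tuberosity_reference"] = np.array(
        [groove_pt[0] + targets["tt_tg"], -10.0, -58.0]
    )

    model = KneeModel(
        femur, patella, femur_t, patella_t, lm,
        side="right",
        femur_grid=femur_grid,
        patella_grid=patella_grid,
        meta=dict(
            preset=preset,
            seed=seed,
            targets=targets,
            resolution=res,
            trochlea_params=troch_kwargs,
            ttg_station_z=float(groove_pt[2]),
            patella_center_x=float(center_x),
            clearance=p_params.clearance,
        ),
    )
    return model


def _shift_z(grid: LoftGrid) -> float:
    """z-offset applied when centering the frame on the mid-trochlear sulcus."""
    from .trochlea import Z_DISTAL

    return Z_DISTAL - float(grid.z_stations[0])
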