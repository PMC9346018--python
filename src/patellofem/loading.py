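"""Flexion-angle-specific load cases.

The femur is fixed in space; the patella keeps its three translational
rigid-body degrees of freedom (rotations constrained at the configured
start orientation).  Loads comprise the three-component quadriceps force
(RF/VI, VM, VL; 276 N total split 111:67:98 by cross-sectional area), a
three-spring patellar tendon fan (total stiffness 4334 N/mm, split
equally, tension-only), and the medial/lateral patellofemoral ligaments
(6.45 and 5.42 N/mm, with prestrain).

Tibiofemoral kinematics enter only through the one role they play here:
placing the patellar tendon origin (the tibial tuberosity) for each
flexion angle by a planar rotation of the tibia about the posterior
condylar axis.  Quadriceps direction vectors per flexion angle are an
editable configuration table; the shipped defaults point the resultant
along the femoral shaft with a posterior inclination that grows with
flexion and small medial/lateral components for VM and VL.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .geometry.knee import KneeModel

QUADRICEPS_TOTAL = 276.0                     # N
MUSCLE_SPLIT = {"RF_VI": 111.0, "VM": 67.0, "VL": 98.0}
TENDON_STIFFNESS_TOTAL = 4334.0              # N/mm, three-spring fan
MPFL_STIFFNESS = 6.45                        # N/mm
LPFL_STIFFNESS = 5.42                        # N/mm
DEFAULT_PRESTRAIN = 0.02
THETA_RANGE = (30.0, 75.0)

# per-theta quadriceps direction table: posterior inclination of the pull
# (deg from the +z femoral axis, toward -y) and the fixed coronal-plane
# angles of VM (medial) and VL (lateral).
DEFAULT_DIRECTION_TABLE = {
    "theta": [30.0, 45.0, 60.0, 75.0],
    "posterior_angle": [6.0, 9.0, 12.0, 15.0],
    "vm_coronal_angle": -32.0,
    "vl_coronal_angle": 22.0,
}

# start-pose table: proximal-distal patellar engagement per flexion angle
DEFAULT_START_POSE_Z = {30.0: 4.0, 45.0: 0.0, 60.0: -5.0, 75.0: -9.0}

FLEXION_CENTER = np.array([0.0, -8.0, -14.0])  # posterior condylar axis point


class LoadCaseError(ValueError):
    """Invalid load-case configuration."""


@dataclass(frozen=True)
class SpringElement:
    """Uniaxial spring between two attachment points.

    ``origin`` is fixed to the femur/tibia (world), ``insertion`` rides on
    the patellar rigid body.  Tension-only springs exert no force when
    shorter than their rest length.
    """

    name: str
    origin: np.ndarray
    insertion: np.ndarray
    stiffness: float
    rest_length: float
    tension_only: bool = True

    def __post_init__(self) -> None:
        if self.stiffness <= 0:
            raise LoadCaseError(f"spring {self.name}: stiffness must be positive")


def spring_force(
    s: SpringElement, origin: np.ndarray, insertion: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Force pair (at origin, at insertion) for displaced endpoints.

    Hookean along the axis: F = k (L - L0); clamped to zero in compression
    for tension-only elements.  Newton's third law holds exactly.
    """
    d = np.asarray(insertion, float) - np.asarray(origin, float)
    L = float(np.linalg.norm(d))
    if L < 1e-9:
        raise LoadCaseError(f"spring {s.name}: coincident endpoints")
    stretch = L - s.rest_length
    if s.tension_only and stretch <= 0.0:
        z = np.zeros(3)
        return z, z.copy()
    f = s.stiffness * stretch * (d / L)
    return f, -f


def spring_stiffness_block(
    s: SpringElement, origin: np.ndarray, insertion: np.ndarray
) -> np.ndarray:
    """3x3 tangent d(insertion force)/d(insertion position)."""
    d = np.asarray(insertion, float) - np.asarray(origin, float)
    L = float(np.linalg.norm(d))
    n = d / L
    stretch = L - s.rest_length
    if s.tension_only and stretch <= 0.0:
        return np.zeros((3, 3))
    k_ax = s.stiffness * np.outer(n, n)
    k_geo = s.stiffness * stretch / L * (np.eye(3) - np.outer(n, n))
    return k_ax + k_geo


def muscle_components(total: float) -> tuple[float, float, float]:
    """Split a total quadriceps force into (RF/VI, VM, VL) proportional to
    111 : 67 : 98, summing to the total exactly."""
    if total < 0:
        raise LoadCaseError("total muscle force must be non-negative")
    ref = np.array([MUSCLE_SPLIT["RF_VI"], MUSCLE_SPLIT["VM"], MUSCLE_SPLIT["VL"]])
    c = ref / ref.sum() * total
    c[0] = total - c[1] - c[2]
    return float(c[0]), float(c[1]), float(c[2])


@dataclass(frozen=True)
class MuscleLoad:
    components: dict            # name -> magnitude (N)
    directions: dict            # name -> unit vector (3,)

    @property
    def total(self) -> float:
        return float(sum(self.components.values()))

    def resultant(self) -> np.ndarray:
        return np.sum(
            [m * np.asarray(self.directions[k]) for k, m in self.components.items()],
            axis=0,
        )


@dataclass(frozen=True)
class LoadCase:
    theta: float
    springs: tuple              # 5 SpringElements (3 tendon + MPFL + LPFL)
    muscle: MuscleLoad
    start_translation: np.ndarray   # initial patellar rigid translation guess
    config: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.springs) != 5:
            raise LoadCaseError("a load case carries exactly 5 springs")


def _muscle_directions(theta: float, table: dict) -> dict:
    th = np.asarray(table["theta"], float)
    if not (th[0] <= theta <= th[-1]):
        raise LoadCaseError(
            f"flexion angle {theta} outside the direction table range "
            f"[{th[0]}, {th[-1]}] (no extrapolation)"
        )
    post = np.radians(np.interp(theta, th, np.asarray(table["posterior_angle"], float)))
    out = {}
    for name, cor in (
        ("RF_VI", 0.0),
        ("VM", np.radians(table["vm_coronal_angle"])),
        ("VL", np.radians(table["vl_coronal_angle"])),
    ):
        v = np.array(
            [np.sin(cor) * np.cos(post), -np.sin(post), np.cos(cor) * np.cos(post)]
        )
        out[name] = v / np.linalg.norm(v)
    return out


def _tuberosity_position(
    model: KneeModel, theta: float, rotation_fraction: float = 0.55
) -> np.ndarray:
    """Rotate the extension-pose tibial tuberosity about the flexion axis.

    The tibia swings posteriorly with flexion; the tendon origin tracks a
    configurable fraction of the flexion angle (femoral rollback makes the
    tendon-to-shaft angle grow slower than the joint angle).
    """
    p0 = np.asarray(model.landmarks["tibial_tuberosity_reference"], float)
    axis_pt = model.landmarks.get("posterior_condylar_axis")
    c = np.asarray(axis_pt[0], float) if axis_pt is not None else FLEXION_CENTER
    a = np.radians(rotation_fraction * theta)
    d = p0 - c
    y = d[1] * np.cos(a) + d[2] * np.sin(a)
    z = -d[1] * np.sin(a) + d[2] * np.cos(a)
    return np.array([p0[0], c[1] + y, c[2] + z])


def _start_translation(model: KneeModel, theta: float, config: dict) -> np.ndarray:
    table = config.get("start_pose_z", DEFAULT_START_POSE_Z)
    zs = sorted(table)
    z_off = float(np.interp(theta, zs, [table[z] for z in zs]))
    x_off = 0.0
    if "surgery" in model.meta and "patellar_ridge_apex" in model.landmarks:
        # a deepening trochleoplasty medializes patellar tracking: start the
        # equilibrium search with the ridge near the relocated groove
        poly = np.asarray(model.landmarks["sulcus_polyline"], float)
        z_ref = model.meta.get("ttg_station_z", 0.0)
        s1_x = poly[int(np.argmin(np.abs(poly[:, 2] - z_ref))), 0]
        apex_x = float(model.landmarks["patellar_ridge_apex"][0])
        lateral = 1.0 if model.side == "right" else -1.0
        x_off = s1_x - apex_x + 2.0 * lateral
    x_off += float(config.get("start_x_offset", 0.0))
    return np.array([x_off, 0.0, z_off])


def build_load_case(model: KneeModel, theta: float, config: dict | None = None) -> LoadCase:
    """Construct the load case for one flexion angle.

    Pure: the same model, configuration and angle always give an identical
    load case.  Raises for angles outside the configured table range.
    """
    config = dict(config or {})
    if not (THETA_RANGE[0] <= theta <= THETA_RANGE[1]):
        raise LoadCaseError(
            f"flexion angle {theta} outside supported range {THETA_RANGE}"
        )
    lm = model.landmarks
    for needed in (
        "tibial_tuberosity_reference",
        "patella_inferior_pole",
        "adductor_tubercle",
        "medial_patellar_edge_midpoint",
        "lateral_epicondyle",
        "most_lateral_patellar_point",
    ):
        if needed not in lm:
            raise LoadCaseError(f"model landmarks incomplete: missing {needed!r}")

    t0 = _start_translation(model, theta, config)
    prestrain = float(config.get("prestrain", DEFAULT_PRESTRAIN))
    tendon_total = float(config.get("tendon_stiffness", TENDON_STIFFNESS_TOTAL))
    tendon_prestrain = float(config.get("tendon_prestrain", 0.0))

    tub = _tuberosity_position(
        model, theta, float(config.get("tibia_rotation_fraction", 0.55))
    )
    pole = np.asarray(lm["patella_inferior_pole"], float)
    springs = []
    for i, dx in enumerate((-5.0, 0.0, 5.0)):
        origin = tub + np.array([dx, 0.0, 0.0])
        insertion = pole + np.array([dx * 0.6, 0.0, 0.0])
        L = float(np.linalg.norm((insertion + t0) - origin))
        springs.append(
            SpringElement(
                name=f"tendon_{i}",
                origin=origin,
                insertion=insertion,
                stiffness=tendon_total / 3.0,
                rest_length=L / (1.0 + tendon_prestrain),
                tension_only=True,
            )
        )
    for name, o_lm, i_lm, k in (
        ("MPFL", "adductor_tubercle", "medial_patellar_edge_midpoint", MPFL_STIFFNESS),
        ("LPFL", "lateral_epicondyle", "most_lateral_patellar_point", LPFL_STIFFNESS),
    ):
        origin = np.asarray(lm[o_lm], float)
        insertion = np.asarray(lm[i_lm], float)
        L = float(np.linalg.norm((insertion + t0) - origin))
        springs.append(
            SpringElement(
                name=name,
                origin=origin,
                insertion=insertion,
                stiffness=float(config.get(f"{name.lower()}_stiffness", k)),
                rest_length=L / (1.0 + prestrain),
                tension_only=True,
            )
        )

    total = float(config.get("muscle_total", QUADRICEPS_TOTAL))
    rf, vm, vl = muscle_components(total)
    directions = _muscle_directions(
        theta, config.get("direction_table", DEFAULT_DIRECTION_TABLE)
    )
    muscle = MuscleLoad(
        components={"RF_VI": rf, "VM": vm, "VL": vl}, directions=directions
    )
    return LoadCase(
        theta=float(theta),
        springs=tuple(springs),
        muscle=muscle,
        start_translation=t0,
        config=config,
    )
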