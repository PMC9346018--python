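"""Analytic verification benchmarks for the contact solver.

Each benchmark builds its own mesh, runs the solver, and returns the FE
quantities next to the closed-form oracle:

* confined compression of a unit cube (constrained modulus
  E(1-nu)/((1+nu)(1-2nu)));
* rigid-sphere indentation of a bonded cartilage slab against the Winkler
  elastic-foundation prediction p0 = kf*delta0, F = pi*R*kf*delta0^2;
* rigid-sphere indentation of a thick slab at nu=0.3 against the Hertz
  half-space solution p0 = (6 F E*^2 / (pi^3 R^2))^(1/3).

For the Hertz comparison the continuum peak is also estimated by fitting
the Hertz pressure profile p(r) = p0 sqrt(1 - r^2/a^2) to the nodal
pressures; the fit suppresses the single-node overshoot of constant-strain
tetrahedra at the contact center.
"""

from __future__ import annotations

import numpy as np
import scipy.sparse as sp
from scipy.optimize import least_squares

from .fem.elasticity import assemble, element_stresses
from .fem.materials import MaterialParams
from .fem.tetmesh import extrude_cartilage
from .geometry.surface import SurfaceMesh, ThicknessMap
from .solver import RigidSphere, SolverSettings, solve_quasistatic


def grid_patch(n: int, size: float, z: float = 0.0):
    """Regular triangulated square patch in the x-y plane (normals +z)."""
    xs = np.linspace(-size / 2.0, size / 2.0, n)
    X, Y = np.meshgrid(xs, xs)
    V = np.stack([X.ravel(), Y.ravel(), np.full(n * n, z)], axis=1)
    F = []
    for i in range(n - 1):
        for j in range(n - 1):
            a = i * n + j
            F += [[a, a + 1, a + n + 1], [a, a + n + 1, a + n]]
    return V, np.asarray(F, dtype=np.int64)


def slab_mesh(n: int, size: float, thickness: float, layers: int):
    V, F = grid_patch(n, size)
    sm = SurfaceMesh(V, F, np.ones(len(V), dtype=np.uint8))
    return extrude_cartilage(sm, ThicknessMap(np.full(len(V), thickness)), layers=layers)


def confined_compression(n_side: int = 1, strain: float = 0.01,
                         material: MaterialParams | None = None) -> dict:
    """Uniaxial-strain compression of a laterally constrained unit cube."""
    m = material or MaterialParams()
    verts = np.array([[0, 0, 0], [1, 0, 0], [1, 1, 0], [0, 1, 0]], float)
    sm = SurfaceMesh(verts, np.array([[0, 1, 2], [0, 2, 3]]),
                     np.ones(4, dtype=np.uint8))
    mesh = extrude_cartilage(sm, ThicknessMap(np.ones(4)), layers=1)
    K = assemble(mesh, m).tocsc()
    nodes = mesh.nodes
    fixed: dict[int, float] = {}
    for i in range(mesh.n_nodes):
        fixed[3 * i] = 0.0
        fixed[3 * i + 1] = 0.0
        if nodes[i, 2] > -1e-9:
            fixed[3 * i + 2] = -strain
        elif nodes[i, 2] < -1.0 + 1e-9:
            fixed[3 * i + 2] = 0.0
    idx = np.array(sorted(fixed))
    vals = np.array([fixed[i] for i in idx])
    free = np.setdiff1d(np.arange(3 * mesh.n_nodes), idx)
    u = np.zeros(3 * mesh.n_nodes)
    u[idx] = vals
    if len(free):
        rhs = -K[free][:, idx] @ vals
        u[free] = sp.linalg.spsolve(K[free][:, free].tocsc(), rhs)
    s = element_stresses(mesh, m, u)
    axial = float(-s[:, 2].mean()) / strain
    return {
        "fe_modulus": axial,
        "oracle_modulus": m.constrained_modulus,
        "stress_voigt": s,
        "displacement": u,
        "mesh": mesh,
        "material": m,
    }


def foundation_indentation(
    n: int = 25, size: float = 10.0, thickness: float = 3.0, layers: int = 3,
    R: float = 10.0, force: float = 10.0,
    material: MaterialParams | None = None,
    penalty: float = 400.0, formulation: str = "penalty",
) -> dict:
    """Rigid sphere on a bonded cartilage slab vs the Winkler oracle."""
    m = material or MaterialParams()
    slab = slab_mesh(n, size, thickness, layers)
    sol = solve_quasistatic(
        None, (slab, None), m,
        SolverSettings(n_load_steps=2, penalty_stiffness=penalty,
                       formulation=formulation),
        rigid_master=RigidSphere(np.array([0.0, 0.0, R + 0.02]), R),
        external_force=np.array([0.0, 0.0, -force]),
        translation_lock=(True, True, False),
    )
    kf = m.constrained_modulus / thickness
    delta0 = np.sqrt(force / (np.pi * R * kf))
    p0 = kf * delta0
    return {
        "solution": sol,
        "fe_peak": float(sol.node_pressure.max()),
        "oracle_p0": float(p0),
        "ratio": float(sol.node_pressure.max() / p0),
        "contact_radius_oracle": float(np.sqrt(2 * R * delta0)),
        "mesh": slab,
    }


def _fit_hertz_peak(r: np.ndarray, p: np.ndarray, p0_guess: float, a_guess: float):
    def resid(x):
        p0, a = x
        prof = p0 * np.sqrt(np.clip(1.0 - (r / a) ** 2, 0.0, None))
        return prof - p

    out = least_squares(resid, x0=[p0_guess, a_guess],
                        bounds=([1e-6, 1e-3], [np.inf, np.inf]))
    return float(out.x[0]), float(out.x[1])


def hertz_indentation(
    n: int = 33, size: float = 16.0, thickness: float = 10.0, layers: int = 5,
    R: float = 15.0, force: float = 8.0, nu: float = 0.3,
    penalty: float = 300.0,
) -> dict:
    """Rigid sphere on a thick compressible slab vs the Hertz oracle."""
    m = MaterialParams(E=5.0, nu=nu, mu=0.0)
    slab = slab_mesh(n, size, thickness, layers)
    sol = solve_quasistatic(
        None, (slab, None), m,
        SolverSettings(n_load_steps=2, penalty_stiffness=penalty),
        rigid_master=RigidSphere(np.array([0.0, 0.0, R + 0.01]), R),
        external_force=np.array([0.0, 0.0, -force]),
        translation_lock=(True, True, False),
    )
    Estar = m.E / (1.0 - nu * nu)
    a_h = (3.0 * force * R / (4.0 * Estar)) ** (1.0 / 3.0)
    p0 = 3.0 * force / (2.0 * np.pi * a_h * a_h)

    pts = slab.nodes[slab.articular_surface]
    r = np.hypot(pts[:, 0], pts[:, 1])
    act = sol.node_pressure > 1e-6
    fitted_p0, fitted_a = _fit_hertz_peak(
        r[act], sol.node_pressure[act], p0, a_h
    )
    return {
        "solution": sol,
        "fe_peak": float(sol.node_pressure.max()),
        "fitted_peak": fitted_p0,
        "fitted_radius": fitted_a,
        "oracle_p0": float(p0),
        "oracle_a": float(a_h),
        "ratio_raw": float(sol.node_pressure.max() / p0),
        "ratio_fitted": float(fitted_p0 / p0),
        "mesh": slab,
    }
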