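"""Quasi-static patellofemoral contact solver.

Unknowns are the patellar rigid translation (3 DOF; rotations are held at
the configured start orientation) together with the nodal displacements of
both cartilage bodies.  Femoral cartilage is fixed to rigid bone at its
osteochondral interface; patellar cartilage rides the patellar rigid body
at its interface.  Contact is node-to-surface (patellar articular nodes
against the deformed femoral articular surface) with a penalty
regularization and an optional augmented-Lagrange outer loop; detection is
a deterministic k-d-tree proximity search.  The linearized systems are
solved with a sparse direct factorization, so repeated runs are bitwise
identical.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
from scipy.sparse.linalg import splu
from scipy.spatial import cKDTree

from .fem.elasticity import assemble
from .fem.materials import MaterialParams
from .fem.tetmesh import TetMesh
from .loading import LoadCase, spring_force, spring_stiffness_block


@dataclass
class SolverSettings:
    formulation: str = "penalty"          # "penalty" | "augmented_lagrange"
    penalty_stiffness: float = 200.0      # MPa/mm
    friction_enabled: bool = False
    newton_tol: float = 1e-6              # residual norm fraction of applied load
    max_iterations: int = 80
    n_load_steps: int = 4
    al_max_outer: int = 10
    al_penetration_tol: float = 5e-3      # mm
    line_search: bool = True
    detection_radius: float = 8.0         # mm candidate search radius
    max_increment: float = 3.0            # mm Newton step cap
    smooth_master_normals: bool = True    # interpolate master vertex normals
                                          # (C1-ish gap on faceted masters)

    def __post_init__(self) -> None:
        if self.penalty_stiffness <= 0:
            raise ValueError("penalty_stiffness must be positive")
        if self.newton_tol <= 0:
            raise ValueError("newton_tol must be positive")
        if self.formulation not in ("penalty", "augmented_lagrange"):
            raise ValueError(f"unknown contact formulation {self.formulation!r}")


@dataclass
class RigidSphere:
    """Analytic rigid spherical indenter riding the translation dofs.

    Used by the verification benchmarks: the gap R - |x - c| and radial
    normal are exact, removing master-facet discretization error."""

    center: np.ndarray
    radius: float


@dataclass
class Solution:
    """Converged (or flagged) state of one quasi-static solve."""

    patella_translation: np.ndarray
    u_femur: np.ndarray | None            # (3 n_f,) full nodal displacements
    u_patella: np.ndarray | None
    slave_nodes: np.ndarray               # articular node ids of the slave body
    node_pressure: np.ndarray             # (n_slave,) MPa, >= 0
    node_tangential: np.ndarray           # (n_slave, 3) MPa tangential traction
    face_pressure: np.ndarray             # per slave articular face, MPa
    face_tangential: np.ndarray           # per face tangential magnitude, MPa
    face_areas: np.ndarray                # undeformed areas, mm^2
    converged: bool
    status: str                           # "converged" | "dislocated" | "max_iterations"
    iterations: int
    residual_history: list
    diagnostics: dict = field(default_factory=dict)

    def active_faces(self) -> np.ndarray:
        return self.face_pressure > 1e-6


# ---------------------------------------------------------------------------
# geometry kernels


def _closest_point_on_triangles(p: np.ndarray, a, b, c):
    """Vectorized closest point on triangle (Ericson's region test)."""
    ab = b - a
    ac = c - a
    ap = p - a
    d1 = np.einsum("ij,ij->i", ab, ap)
    d2 = np.einsum("ij,ij->i", ac, ap)
    bp = p - b
    d3 = np.einsum("ij,ij->i", ab, bp)
    d4 = np.einsum("ij,ij->i", ac, bp)
    cp = p - c
    d5 = np.einsum("ij,ij->i", ab, cp)
    d6 = np.einsum("ij,ij->i", ac, cp)

    vc = d1 * d4 - d3 * d2
    vb = d5 * d2 - d1 * d6
    va = d3 * d6 - d5 * d4
    denom = va + vb + vc
    denom = np.where(np.abs(denom) < 1e-30, 1.0, denom)
    v = vb / denom
    w = vc / denom
    out = a + v[:, None] * ab + w[:, None] * ac
    bary = np.stack([1.0 - v - w, v, w], axis=1)

    def _safe_div(num, den):
        return np.clip(np.where(np.abs(den) < 1e-30, 0.0, num / np.where(den == 0, 1.0, den)), 0.0, 1.0)

    # vertex regions
    m = (d1 <= 0) & (d2 <= 0)
    out[m], bary[m] = a[m], [1, 0, 0]
    m = (d3 >= 0) & (d4 <= d3)
    out[m], bary[m] = b[m], [0, 1, 0]
    m = (d6 >= 0) & (d5 <= d6)
    out[m], bary[m] = c[m], [0, 0, 1]
    # edges
    m = (vc <= 0) & (d1 >= 0) & (d3 <= 0)
    if m.any():
        t = _safe_div(d1, d1 - d3)
        out[m] = a[m] + t[m, None] * ab[m]
        bary[m] = np.stack([1 - t[m], t[m], np.zeros(int(m.sum()))], axis=1)
    m = (vb <= 0) & (d2 >= 0) & (d6 <= 0)
    if m.any():
        t = _safe_div(d2, d2 - d6)
        out[m] = a[m] + t[m, None] * ac[m]
        bary[m] = np.stack([1 - t[m], np.zeros(int(m.sum())), t[m]], axis=1)
    m = (va <= 0) & ((d4 - d3) >= 0) & ((d5 - d6) >= 0)
    if m.any():
        t = _safe_div(d4 - d3, (d4 - d3) + (d5 - d6))
        out[m] = b[m] + t[m, None] * (c[m] - b[m])
        bary[m] = np.stack([np.zeros(int(m.sum())), 1 - t[m], t[m]], axis=1)
    return out, bary


def detect_contact(
    slave_points: np.ndarray,
    master_vertices: np.ndarray,
    master_faces: np.ndarray,
    radius: float = 8.0,
    k: int = 8,
    smooth_normals: bool = False,
    drop_boundary: bool = True,
) -> dict:
    """Node-to-surface proximity pairing with signed gaps.

    For every slave node within ``radius`` of a master face: the paired
    face, barycentric weights of the closest point, the face outward normal
    and the signed gap (positive = penetration, negative = open).
    Degenerate master triangles are skipped.
    """
    tri = master_vertices[master_faces]
    nvec = np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0])
    twice_area = np.linalg.norm(nvec, axis=1)
    good = twice_area > 1e-12
    normals = np.zeros_like(nvec)
    normals[good] = nvec[good] / twice_area[good, None]
    if smooth_normals:
        # area-weighted vertex normals, interpolated at the closest point
        vnormals = np.zeros_like(master_vertices)
        np.add.at(vnormals, master_faces.ravel(), np.repeat(nvec, 3, axis=0))
        vn_len = np.linalg.norm(vnormals, axis=1)
        nz = vn_len > 1e-12
        vnormals[nz] /= vn_len[nz, None]

    cent = tri.mean(axis=1)
    tree = cKDTree(cent)
    kq = min(k, len(cent))
    _, idx = tree.query(slave_points, k=kq)
    if kq == 1:
        idx = idx[:, None]

    ns = len(slave_points)
    flat_slave = np.repeat(np.arange(ns), kq)
    flat_face = idx.ravel()
    P = slave_points[flat_slave]
    T = tri[flat_face]
    cp, bary = _closest_point_on_triangles(P, T[:, 0], T[:, 1], T[:, 2])
    d2 = np.einsum("ij,ij->i", P - cp, P - cp)
    d2 = np.where(good[flat_face], d2, np.inf)

    d2m = d2.reshape(ns, kq)
    best_local = np.argmin(d2m, axis=1)
    bestd = d2m[np.arange(ns), best_local]
    pick_best = np.arange(ns) * kq + best_local

    # keep every candidate whose projection is interior to its face: a node
    # wedged into a concave corner (e.g. the deepened groove) then carries a
    # pair on each wall instead of flipping between them.  On smooth regions
    # only the true closest face has an interior projection, so no pair is
    # double-counted.
    interior_proj = (bary > 1e-6).all(axis=1) & (d2 <= radius * radius)
    has_interior = interior_proj.reshape(ns, kq).any(axis=1)
    need_fallback = (~has_interior) & (np.sqrt(np.minimum(bestd, 1e30)) <= radius)

    fallback_keep = np.zeros(ns, dtype=bool)
    fallback_keep[need_fallback] = True
    if drop_boundary:
        # release fallback pairs whose closest point lies on the free
        # boundary of the master patch (edge normals are ill-defined there)
        edges = np.sort(
            np.concatenate(
                [master_faces[:, [0, 1]], master_faces[:, [1, 2]], master_faces[:, [2, 0]]]
            ),
            axis=1,
        )
        nvert = len(master_vertices)
        keys, counts = np.unique(edges[:, 0] * nvert + edges[:, 1], return_counts=True)
        bkeys = set(keys[counts == 1].tolist())
        bverts = np.zeros(nvert, dtype=bool)
        for kk in bkeys:
            bverts[kk // nvert] = True
            bverts[kk % nvert] = True
        for i in np.where(need_fallback)[0]:
            j = pick_best[i]
            bw_i = bary[j]
            fv = master_faces[flat_face[j]]
            zero = bw_i < 1e-8
            if not zero.any():
                continue
            sup = fv[~zero]
            if len(sup) == 1 and bverts[sup[0]]:
                fallback_keep[i] = False
            elif len(sup) == 2:
                a2, b2 = sorted(int(v) for v in sup)
                if a2 * nvert + b2 in bkeys:
                    fallback_keep[i] = False

    sel = np.where(interior_proj)[0].tolist()
    sel += [pick_best[i] for i in np.where(fallback_keep)[0]]
    sel = np.asarray(sorted(set(sel)), dtype=np.int64)

    face = flat_face[sel]
    cpb = cp[sel]
    if smooth_normals:
        bw = bary[sel]
        n = np.einsum("ik,ikj->ij", bw, vnormals[master_faces[face]])
        nlen = np.linalg.norm(n, axis=1)
        bad = nlen < 1e-8
        n[bad] = normals[face][bad]
        n[~bad] /= nlen[~bad, None]
    else:
        n = normals[face]
    slave_ids = flat_slave[sel]
    gap = -np.einsum("ij,ij->i", slave_points[slave_ids] - cpb, n)

    return {
        "slave": slave_ids,
        "face": face,
        "bary": bary[sel],
        "normal": n,
        "gap": gap,
        "closest": cpb,
    }


def _tributary_areas(mesh: TetMesh) -> np.ndarray:
    """Per-articular-node tributary area (1/3 of adjacent face areas)."""
    areas = mesh.surface_face_areas()
    out = np.zeros(mesh.n_nodes)
    np.add.at(out, mesh.surface_faces.ravel(), np.repeat(areas / 3.0, 3))
    return out[mesh.articular_surface]


# ---------------------------------------------------------------------------
# reduced-DOF system


class _System:
    """Condensed DOF layout: [femur free | patella free | rigid translation]."""

    def __init__(
        self,
        femur: TetMesh | None,
        patella: TetMesh | None,
        material: MaterialParams,
        rigid_master: tuple[np.ndarray, np.ndarray] | None = None,
    ):
        self.femur = femur
        self.patella = patella
        self.material = material
        self.rigid_master = rigid_master
        self.maps: dict[str, np.ndarray] = {}

        blocks = []
        offset = 0
        if femur is not None:
            free = self._free_nodes(femur)
            self.maps["femur_free"] = free
            blocks.append(("femur", assemble(femur, material), free, offset))
            offset += 3 * len(free)
        if patella is not None:
            free = self._free_nodes(patella)
            self.maps["patella_free"] = free
            blocks.append(("patella", assemble(patella, material), free, offset))
            offset += 3 * len(free)
        self.t_offset = offset
        self.n_dof = offset + 3
        self._build_K0(blocks)

    @staticmethod
    def _free_nodes(mesh: TetMesh) -> np.ndarray:
        fixed = np.zeros(mesh.n_nodes, dtype=bool)
        fixed[mesh.bone_interface] = True
        return np.where(~fixed)[0]

    def _build_K0(self, blocks) -> None:
        rows, cols, vals = [], [], []
        for name, K, free, off in blocks:
            dof = (3 * free[:, None] + np.arange(3)).ravel()
            Kff = K[dof][:, dof].tocoo()
            rows.append(Kff.row + off)
            cols.append(Kff.col + off)
            vals.append(Kff.data)
            if name == "patella":
                bdof = (3 * self.patella.bone_interface[:, None] + np.arange(3)).ravel()
                Kfb = K[dof][:, bdof].tocsc()
                for a in range(3):
                    col = np.asarray(
                        Kfb[:, np.arange(a, len(bdof), 3)].sum(axis=1)
                    ).ravel()
                    nz = np.nonzero(col)[0]
                    rows += [nz + off, np.full(len(nz), self.t_offset + a)]
                    cols += [np.full(len(nz), self.t_offset + a), nz + off]
                    vals += [col[nz], col[nz]]
                Kbb = K[bdof][:, bdof]
                for a in range(3):
                    for b in range(3):
                        v = Kbb[np.arange(a, len(bdof), 3)][
                            :, np.arange(b, len(bdof), 3)
                        ].sum()
                        rows.append(np.array([self.t_offset + a]))
                        cols.append(np.array([self.t_offset + b]))
                        vals.append(np.array([v]))
        self.K0 = sp.coo_matrix(
            (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
            shape=(self.n_dof, self.n_dof),
        ).tocsr()

    def full_displacements(self, u: np.ndarray):
        t = u[self.t_offset : self.t_offset + 3]
        uf = up = None
        off = 0
        if self.femur is not None:
            free = self.maps["femur_free"]
            uf = np.zeros(3 * self.femur.n_nodes)
            uf.reshape(-1, 3)[free] = u[off : off + 3 * len(free)].reshape(-1, 3)
            off += 3 * len(free)
        if self.patella is not None:
            free = self.maps["patella_free"]
            up = np.zeros(3 * self.patella.n_nodes)
            up.reshape(-1, 3)[free] = u[off : off + 3 * len(free)].reshape(-1, 3)
            up.reshape(-1, 3)[self.patella.bone_interface] = t
            off += 3 * len(free)
        return uf, up, t

    def body_dof_index(self, body: str, nodes: np.ndarray) -> np.ndarray:
        """Reduced dof ids (len(nodes), 3); -1 where interface-driven."""
        off = 3 * len(self.maps["femur_free"]) if (
            body == "patella" and self.femur is not None
        ) else 0
        mesh = self.femur if body == "femur" else self.patella
        pos = -np.ones(mesh.n_nodes, dtype=np.int64)
        free = self.maps[f"{body}_free"]
        pos[free] = np.arange(len(free))
        p = pos[nodes]
        return np.where(p[:, None] >= 0, off + 3 * p[:, None] + np.arange(3), -1)


# ---------------------------------------------------------------------------
# assembly of the nonlinear terms


def _contact_assembly(system: _System, settings: SolverSettings, u, state):
    """Contact forces, tangent triplets and per-node tractions at state u."""
    kp = settings.penalty_stiffness
    slave_body = "patella" if system.patella is not None else "femur"
    slave_mesh = system.patella if slave_body == "patella" else system.femur
    uf, up, t = system.full_displacements(u)
    u_slave = up if slave_body == "patella" else uf
    s_nodes = slave_mesh.articular_surface
    s_pts = slave_mesh.nodes[s_nodes] + u_slave.reshape(-1, 3)[s_nodes]

    if isinstance(system.rigid_master, RigidSphere):
        return _sphere_contact_assembly(system, settings, u, state, s_pts, s_nodes,
                                        slave_body)
    if system.rigid_master is not None:
        mv = system.rigid_master[0] + t
        mfc = system.rigid_master[1]
        master_deformable = False
    else:
        fm = system.femur
        mv = (fm.nodes + uf.reshape(-1, 3))[fm.articular_surface]
        remap = -np.ones(fm.n_nodes, dtype=np.int64)
        remap[fm.articular_surface] = np.arange(len(fm.articular_surface))
        mfc = remap[fm.surface_faces]
        master_deformable = True

    frozen = state.get("frozen")
    if frozen is not None:
        # frozen pairing: same faces/weights/normals, gaps re-evaluated at
        # the current configuration (smooth subproblem for the stagger loop)
        det = dict(frozen)
        cp_cur = np.einsum("ik,ikj->ij", det["bary"], mv[mfc[det["face"]]])
        det["gap"] = -np.einsum(
            "ij,ij->i", s_pts[det["slave"]] - cp_cur, det["normal"]
        )
        det["closest"] = cp_cur
    else:
        det = detect_contact(
            s_pts, mv, mfc,
            radius=settings.detection_radius,
            smooth_normals=settings.smooth_master_normals,
        )
    areas = state["areas"]
    lam_mult = state.get("multipliers")
    gap = det["gap"]
    p_trial = (lam_mult[det["slave"]] if lam_mult is not None else 0.0) + kp * gap
    active = p_trial > 0.0

    n_slave = len(s_nodes)
    node_p = np.zeros(n_slave)
    node_t = np.zeros((n_slave, 3))
    f = np.zeros(system.n_dof)
    rows: list = []
    cols: list = []
    vals: list = []

    state["gap"] = np.zeros(n_slave)
    sl = det["slave"][active]
    np.maximum.at(state["gap"], sl, gap[active])
    state["active_pairs"] = int(active.sum())
    if len(sl) == 0:
        return f, (rows, cols, vals), node_p, node_t

    fcx = det["face"][active]
    bary = det["bary"][active]
    nrm = det["normal"][active]
    press = p_trial[active]
    A = areas[sl]
    np.maximum.at(node_p, sl, press)

    sdof = system.body_dof_index(slave_body, s_nodes[sl])
    fvec = (A * press)[:, None] * nrm
    np.add.at(f, sdof.ravel(), fvec.ravel())

    if settings.friction_enabled and system.material.mu > 0:
        anchors = state.setdefault("anchors", {})
        slip = np.zeros((len(sl), 3))
        closest = det["closest"][active]
        for j, s_id in enumerate(sl):
            key = int(s_id)
            if key not in anchors:
                anchors[key] = closest[j].copy()
            d = s_pts[s_id] - anchors[key]
            slip[j] = d - np.dot(d, nrm[j]) * nrm[j]
        eps = 1e-3
        mag = np.sqrt(np.einsum("ij,ij->i", slip, slip) + eps * eps)
        ft = -(system.material.mu * press * A)[:, None] * slip / mag[:, None]
        np.add.at(f, sdof.ravel(), ft.ravel())
        np.add.at(node_t, sl, ft / np.maximum(A, 1e-12)[:, None])

    if master_deformable:
        fm = system.femur
        mnodes = fm.articular_surface[mfc[fcx]]
        mdof = np.stack(
            [system.body_dof_index("femur", mnodes[:, j]) for j in range(3)], axis=1
        )  # (k, 3 verts, 3 comps)
        react = -fvec[:, None, :] * bary[:, :, None]
        ok = mdof >= 0
        np.add.at(f, mdof[ok], react[ok])
    else:
        f[system.t_offset : system.t_offset + 3] -= fvec.sum(axis=0)

    kA = kp * A
    for ci in range(3):
        for cj in range(3):
            block = kA * nrm[:, ci] * nrm[:, cj]
            rows.append(sdof[:, ci])
            cols.append(sdof[:, cj])
            vals.append(block)
            if master_deformable:
                for vtx in range(3):
                    md = mdof[:, vtx]
                    ok = md[:, 0] >= 0
                    w = bary[:, vtx]
                    bw = (block * w)[ok]
                    rows += [sdof[ok, ci], md[ok, ci]]
                    cols += [md[ok, cj], sdof[ok, cj]]
                    vals += [-bw, -bw]
                    for vtx2 in range(3):
                        md2 = mdof[:, vtx2]
                        ok2 = ok & (md2[:, 0] >= 0)
                        rows.append(md[ok2, ci])
                        cols.append(md2[ok2, cj])
                        vals.append((block * w * bary[:, vtx2])[ok2])
            else:
                ti = system.t_offset + ci
                tj = system.t_offset + cj
                rows += [np.full(len(sl), ti), sdof[:, ci], np.array([ti])]
                cols += [sdof[:, cj], np.full(len(sl), tj), np.array([tj])]
                vals += [-block, -block, np.array([block.sum()])]

    return f, (rows, cols, vals), node_p, node_t


def _sphere_contact_assembly(system, settings, u, state, s_pts, s_nodes, slave_body):
    """Exact contact against an analytic rigid sphere riding the t dofs."""
    kp = settings.penalty_stiffness
    sph = system.rigid_master
    t = u[system.t_offset : system.t_offset + 3]
    c = np.asarray(sph.center, float) + t
    d = s_pts - c
    dist = np.linalg.norm(d, axis=1)
    gap_all = sph.radius - dist
    lam_mult = state.get("multipliers")
    p_trial = (lam_mult if lam_mult is not None else 0.0) + kp * gap_all
    active = (p_trial > 0.0) & (dist > 1e-9)

    n_slave = len(s_nodes)
    node_p = np.zeros(n_slave)
    node_t = np.zeros((n_slave, 3))
    f = np.zeros(system.n_dof)
    rows: list = []
    cols: list = []
    vals: list = []
    state["gap"] = np.where(active, gap_all, 0.0)
    state["active_pairs"] = int(active.sum())
    sl = np.where(active)[0]
    if len(sl) == 0:
        return f, (rows, cols, vals), node_p, node_t

    nrm = d[sl] / dist[sl][:, None]           # outward sphere normal
    press = p_trial[sl]
    A = state["areas"][sl]
    node_p[sl] = press
    sdof = system.body_dof_index(slave_body, s_nodes[sl])
    fvec = (A * press)[:, None] * nrm
    np.add.at(f, sdof.ravel(), fvec.ravel())
    f[system.t_offset : system.t_offset + 3] -= fvec.sum(axis=0)

    kA = kp * A
    # geometric (curvature) term of the exact spherical gap
    geo = A * press / dist[sl]
    for ci in range(3):
        for cj in range(3):
            block = kA * nrm[:, ci] * nrm[:, cj]
            block = block + geo * ((ci == cj) - nrm[:, ci] * nrm[:, cj])
            ti = system.t_offset + ci
            tj = system.t_offset + cj
            rows += [sdof[:, ci], np.full(len(sl), ti), sdof[:, ci], np.array([ti])]
            cols += [sdof[:, cj], sdof[:, cj], np.full(len(sl), tj), np.array([tj])]
            vals += [block, -block, -block, np.array([block.sum()])]
    return f, (rows, cols, vals), node_p, node_t


def _spring_assembly(system: _System, case: LoadCase | None, u):
    if case is None:
        return np.zeros(system.n_dof), np.zeros((3, 3)), {}
    t = u[system.t_offset : system.t_offset + 3]
    f = np.zeros(system.n_dof)
    Kt = np.zeros((3, 3))
    per = {}
    for s in case.springs:
        ins = np.asarray(s.insertion) + t
        _, fi = spring_force(s, s.origin, ins)
        f[system.t_offset : system.t_offset + 3] += fi
        Kt += spring_stiffness_block(s, s.origin, ins)
        per[s.name] = fi
    return f, Kt, per


def _tangent(system: _System, trip, Kspring, damping: float = 0.0) -> sp.csc_matrix:
    rows, cols, vals = trip
    K = system.K0
    if rows:
        Kc = sp.coo_matrix(
            (
                np.concatenate(vals).astype(float),
                (np.concatenate(rows), np.concatenate(cols)),
            ),
            shape=K.shape,
        )
        K = K + Kc.tocsr()
    if damping > 0.0:
        # Levenberg-style regularization: biases Newton toward gradient
        # descent without moving the converged equilibrium
        K = K + sp.identity(K.shape[0], format="csr") * damping
    to = system.t_offset
    i, j = np.meshgrid(np.arange(3), np.arange(3), indexing="ij")
    Ks = sp.coo_matrix(
        (Kspring.ravel(), (to + i.ravel(), to + j.ravel())), shape=K.shape
    )
    K = (K + Ks.tocsr()).tocsc()
    # regularize free-floating translation dofs before contact engages
    d = K.diagonal()[to : to + 3]
    reg_idx = to + np.where(d <= 1e-9)[0]
    locked = getattr(system, "locked", np.empty(0, dtype=np.int64))
    extra_idx = np.concatenate([reg_idx, locked]).astype(np.int64)
    extra_val = np.concatenate([np.ones(len(reg_idx)), np.full(len(locked), 1e8)])
    if len(extra_idx):
        R = sp.coo_matrix((extra_val, (extra_idx, extra_idx)), shape=K.shape)
        K = (K + R.tocsc()).tocsc()
    return K


# ---------------------------------------------------------------------------
# the solve


def solve_quasistatic(
    case: LoadCase | None,
    meshes: tuple[TetMesh | None, TetMesh | None],
    material: MaterialParams,
    settings: SolverSettings | None = None,
    rigid_master: tuple[np.ndarray, np.ndarray] | RigidSphere | None = None,
    external_force: np.ndarray | None = None,
    translation_lock: tuple[bool, bool, bool] = (False, False, False),
) -> Solution:
    """Solve the quasi-static contact equilibrium.

    ``translation_lock`` constrains individual rigid-translation components
    (e.g. guiding an indenter vertically in an axisymmetric benchmark).

    ``meshes`` is (femoral cartilage, patellar cartilage); the patellar
    slot may be None when a rigid indenter surface (``rigid_master``)
    riding the translational dofs replaces it (verification problems).
    ``external_force`` is an extra dead load on the translation dofs.
    Non-convergence never raises: the Solution carries ``converged`` /
    ``status`` and diagnostics.
    """
    settings = settings or SolverSettings()
    femur, patella = meshes
    system = _System(femur, patella, material, rigid_master=rigid_master)
    system.locked = system.t_offset + np.where(np.asarray(translation_lock))[0]
    slave_mesh = patella if patella is not None else femur
    state: dict = {"areas": _tributary_areas(slave_mesh)}

    f_applied = np.zeros(system.n_dof)
    if case is not None:
        f_applied[system.t_offset : system.t_offset + 3] += case.muscle.resultant()
    if external_force is not None:
        f_applied[system.t_offset : system.t_offset + 3] += np.asarray(
            external_force, float
        )
    applied_norm = max(float(np.linalg.norm(f_applied)), 1e-12)

    u = np.zeros(system.n_dof)
    if case is not None:
        u[system.t_offset : system.t_offset + 3] = case.start_translation

    residual_history: list[float] = []
    it_count = 0
    converged = False
    last = {}

    def evaluate(uv, lam):
        fc, trip, node_p, node_t = _contact_assembly(system, settings, uv, state)
        fs, Kspring, per = _spring_assembly(system, case, uv)
        r = system.K0 @ uv - fc - fs - lam * f_applied
        r[system.locked] = 0.0
        return {
            "r": r, "fc": fc, "trip": trip, "Kspring": Kspring,
            "node_p": node_p, "node_t": node_t, "per_spring": per,
        }

    def newton_inner(uv, lam, budget, cap=None):
        nonlocal it_count
        ok = False
        ev = evaluate(uv, lam)
        damping = 0.0
        best = np.inf
        since_best = 0
        cap = settings.max_increment if cap is None else cap
        for _ in range(budget):
            rn = float(np.linalg.norm(ev["r"]))
            residual_history.append(rn)
            if rn <= settings.newton_tol * max(lam * applied_norm, 1e-9):
                ok = True
                break
            if rn < 0.95 * best:
                best, since_best = rn, 0
                damping *= 0.3
                if damping < 1.0:
                    damping = 0.0
            else:
                since_best += 1
                if since_best >= 6:
                    # stagnation: damp toward gradient flow (pseudo-time)
                    damping = max(4.0 * damping, 50.0)
                    since_best = 0
            K = _tangent(system, ev["trip"], ev["Kspring"], damping)
            du = splu(K).solve(-ev["r"])
            step = float(np.max(np.abs(du)))
            if step > cap:
                du *= cap / step
            alpha = 1.0
            if settings.line_search:
                for _ in range(4):
                    trial = evaluate(uv + alpha * du, lam)
                    if float(np.linalg.norm(trial["r"])) < rn:
                        ev_next = trial
                        break
                    alpha *= 0.5
                else:
                    ev_next = evaluate(uv + alpha * du, lam)
            else:
                ev_next = evaluate(uv + du, lam)
            uv = uv + alpha * du
            ev = ev_next
            it_count += 1
        return uv, ok, ev

    def newton(uv, lam, final=True):
        # free-detection Newton, then (when pairing chatter prevents full
        # convergence) a staggered loop: freeze the pairing, converge the
        # smooth subproblem, release and re-verify.  The stagger loop only
        # runs at the final load level; intermediate levels just hand their
        # best state to the next one.
        budget = settings.max_iterations if final else max(
            settings.max_iterations // 2, 10)
        uv, ok, ev = newton_inner(uv, lam, budget)
        can_freeze = (
            system.rigid_master is None
            and system.femur is not None
            and system.patella is not None
        )
        if ok or not can_freeze or not final:
            return uv, ok, ev
        u_best, ev_best = uv.copy(), ev
        r_best = float(np.linalg.norm(ev["r"]))
        for _ in range(3):
            uff, upf, tf_ = system.full_displacements(uv)
            s_nodes = system.patella.articular_surface
            s_pts = system.patella.nodes[s_nodes] + upf.reshape(-1, 3)[s_nodes]
            fmm = system.femur
            mvv = (fmm.nodes + uff.reshape(-1, 3))[fmm.articular_surface]
            remap = -np.ones(fmm.n_nodes, dtype=np.int64)
            remap[fmm.articular_surface] = np.arange(len(fmm.articular_surface))
            mfcc = remap[fmm.surface_faces]
            state["frozen"] = detect_contact(
                s_pts, mvv, mfcc,
                radius=settings.detection_radius,
                smooth_normals=settings.smooth_master_normals,
            )
            uv, _, ev = newton_inner(uv, lam, 30, cap=0.5)
            state["frozen"] = None
            uv, ok, ev = newton_inner(uv, lam, 8)
            rn = float(np.linalg.norm(ev["r"]))
            if ok:
                return uv, ok, ev
            if rn < r_best:
                u_best, ev_best, r_best = uv.copy(), ev, rn
            else:
                # the frozen excursion made things worse: restart from the
                # best verified state with a damped short free phase
                uv = u_best.copy()
                uv, ok, ev = newton_inner(uv, lam, 12, cap=0.25)
                rn = float(np.linalg.norm(ev["r"]))
                if ok:
                    return uv, ok, ev
                if rn < r_best:
                    u_best, ev_best, r_best = uv.copy(), ev, rn
        return u_best, ok, ev_best

    ev = evaluate(u, 0.0)
    schedule = np.linspace(1.0 / settings.n_load_steps, 1.0, settings.n_load_steps)
    for i, lam in enumerate(schedule):
        u, converged, ev = newton(u, lam, final=(i == len(schedule) - 1))

    if settings.formulation == "augmented_lagrange" and converged:
        n_slave = len(slave_mesh.articular_surface)
        lam_mult = np.zeros(n_slave)
        for _ in range(settings.al_max_outer):
            pen = float(np.max(state.get("gap", np.zeros(1)), initial=0.0))
            if pen < settings.al_penetration_tol:
                break
            lam_mult = np.maximum(
                lam_mult + settings.penalty_stiffness * state["gap"], 0.0
            )
            state["multipliers"] = lam_mult
            u, converged, ev = newton(u, 1.0)

    uf, up, t = system.full_displacements(u)
    node_p, node_t = ev["node_p"], ev["node_t"]
    faces = slave_mesh.surface_faces
    face_p = node_p[faces].mean(axis=1)
    face_t = np.linalg.norm(node_t, axis=1)[faces].mean(axis=1)

    status = "converged" if converged else "max_iterations"
    if converged and case is not None:
        if state.get("active_pairs", 0) == 0 or abs(t[0]) > 28.0:
            status = "dislocated"

    # per-family force balance on the rigid body / slave body
    fc = ev["fc"]
    if system.patella is not None:
        sdof = system.body_dof_index("patella", slave_mesh.articular_surface)
        ok = sdof[:, 0] >= 0
        contact_total = np.array([fc[sdof[ok, a]].sum() for a in range(3)])
    else:
        contact_total = fc[system.t_offset : system.t_offset + 3].copy()
    per_spring = ev["per_spring"]
    spring_total = (
        np.sum(list(per_spring.values()), axis=0) if per_spring else np.zeros(3)
    )

    return Solution(
        patella_translation=t.copy(),
        u_femur=uf,
        u_patella=up,
        slave_nodes=slave_mesh.articular_surface.copy(),
        node_pressure=node_p,
        node_tangential=node_t,
        face_pressure=face_p,
        face_tangential=face_t,
        face_areas=slave_mesh.surface_face_areas(),
        converged=converged,
        status=status,
        iterations=it_count,
        residual_history=residual_history,
        diagnostics={
            "residual_norm": float(np.linalg.norm(ev["r"])),
            "applied_norm": applied_norm,
            "muscle_force": (
                case.muscle.resultant() if case is not None else np.zeros(3)
            ),
            "external_force": (
                np.asarray(external_force, float)
                if external_force is not None
                else np.zeros(3)
            ),
            "spring_forces": {k: v.copy() for k, v in per_spring.items()},
            "spring_total": np.asarray(spring_total, float),
            "contact_total": contact_total,
            "max_penetration": float(
                np.max(state.get("gap", np.zeros(1)), initial=0.0)
            ),
            "active_pairs": int(state.get("active_pairs", 0)),
            "locked_components": np.asarray(translation_lock, dtype=bool),
        },
    )


def residual_report(sol: Solution, case: LoadCase | None = None) -> dict:
    """Force-balance summary per force family on the patellar rigid body."""
    d = sol.diagnostics
    total = (
        np.asarray(d["muscle_force"], float)
        + np.asarray(d["external_force"], float)
        + np.asarray(d["spring_total"], float)
        + np.asarray(d["contact_total"], float)
    )
    locked = np.asarray(d.get("locked_components", [False] * 3), dtype=bool)
    total = np.where(locked, 0.0, total)  # guide reactions carry locked dofs
    applied = max(float(d["applied_norm"]), 1e-12)
    return {
        "muscle": np.asarray(d["muscle_force"], float),
        "springs": np.asarray(d["spring_total"], float),
        "contact": np.asarray(d["contact_total"], float),
        "net": total,
        "net_fraction_of_applied": float(np.linalg.norm(total)) / applied,
        "residual_norm": d["residual_norm"],
        "residual_fraction_of_applied": d["residual_norm"] / applied,
        "converged": sol.converged,
        "status": sol.status,
    }
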