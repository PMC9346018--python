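"""Tetrahedral cartilage meshes by prismatic extrusion.

The articular cartilage layer is extruded from the labeled surface patch
along inward vertex normals through the per-vertex thickness map, split
into conforming 4-node tetrahedra (three per prism, smallest-global-index
diagonal rule), and tagged with the node sets the solver needs: the outer
shell is the articular surface, the inner shell the (rigid) bone interface.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ..geometry.surface import GeometryError, SurfaceMesh, ThicknessMap


@dataclass
class TetMesh:
    """Linear tetrahedral mesh of one cartilage body."""

    nodes: np.ndarray              # (n, 3) mm
    tets: np.ndarray               # (m, 4) positively oriented
    part: str                      # "femur" | "patella"
    bone_interface: np.ndarray     # node ids on the osteochondral interface
    articular_surface: np.ndarray  # node ids on the articular surface
    rim: np.ndarray                # node ids on the lateral free rim
    surface_faces: np.ndarray      # (k, 3) articular triangles (outward)
    node_thickness: np.ndarray     # (n,) local cartilage thickness carried per node

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_elements(self) -> int:
        return len(self.tets)

    def volumes(self) -> np.ndarray:
        X = self.nodes[self.tets]
        M = X[:, 1:] - X[:, :1]
        return np.linalg.det(M) / 6.0

    def surface_face_areas(self) -> np.ndarray:
        v = self.nodes
        f = self.surface_faces
        return 0.5 * np.linalg.norm(
            np.cross(v[f[:, 1]] - v[f[:, 0]], v[f[:, 2]] - v[f[:, 0]]), axis=1
        )


def scale_thickness(tmap: ThicknessMap, factor: float) -> ThicknessMap:
    """Uniformly scale a thickness map within the sensitivity envelope
    (+/-40 %, i.e. factor in [0.6, 1.4])."""
    if not (0.6 <= factor <= 1.4):
        raise ValueError(
            f"thickness factor {factor} outside the sensitivity envelope [0.6, 1.4]"
        )
    return tmap.scaled(factor)


def _split_prism(p0, p1, p2, q0, q1, q2) -> list[tuple]:
    """Split one prism into 3 tets with globally consistent diagonals.

    Bottom triangle (p0,p1,p2), top (q0,q1,q2), vertically paired.  The
    triangle is rotated so the smallest bottom index leads; the interior
    quad diagonal then follows the smallest-index rule, which is symmetric
    between prisms sharing a quad face.
    """
    idx = np.argmin([p0, p1, p2])
    for _ in range(idx):
        p0, p1, p2 = p1, p2, p0
        q0, q1, q2 = q1, q2, q0
    if min(p1, q2) < min(p2, q1):
        return [(p0, p1, p2, q2), (p0, p1, q2, q1), (p0, q1, q2, q0)]
    return [(p0, p1, p2, q1), (p0, q1, p2, q2), (p0, q1, q2, q0)]


def extrude_cartilage(
    surface: SurfaceMesh,
    thickness: ThicknessMap,
    layers: int = 3,
    part: str = "femur",
) -> TetMesh:
    """Extrude the cartilage patch of ``surface`` into a tet mesh.

    The articular (outer) shell keeps the patch triangulation; ``layers``
    element layers span the thickness, giving ~3*layers*n_triangles
    tetrahedra.
    """
    if layers < 1:
        raise ValueError("layers must be >= 1")
    faces = surface.cartilage_faces()
    if len(faces) == 0:
        raise GeometryError("surface has no cartilage patch to extrude")
    vids = np.unique(faces)
    local = -np.ones(surface.n_vertices, dtype=np.int64)
    local[vids] = np.arange(len(vids))
    patch_faces = local[faces]
    pv = surface.vertices[vids]
    t = thickness.values[vids]
    if np.any(t <= 0):
        raise GeometryError("cartilage thickness must be positive on the patch")

    normals = surface.vertex_normals()[vids]  # outward
    nv = len(pv)
    shells = [pv - normals * (t * k / layers)[:, None] for k in range(layers + 1)]
    nodes = np.concatenate(shells, axis=0)

    tets = []
    for k in range(layers):
        base = k * nv
        top = (k + 1) * nv
        for a, b, c in patch_faces:
            # prism from articular side (shallow) to bone side (deep);
            # global ids offset per shell
            tets.extend(_split_prism(base + a, base + b, base + c,
                                     top + a, top + b, top + c))
    tets = np.asarray(tets, dtype=np.int64)

    # orientation and inversion check
    X = nodes[tets]
    vol = np.linalg.det(X[:, 1:] - X[:, :1]) / 6.0
    flip = vol < 0
    if np.any(flip):
        tets[flip] = tets[flip][:, [0, 2, 1, 3]]
        vol = np.abs(vol)
    bad = vol < 1e-9
    if np.any(bad):
        culprits = np.unique(tets[bad] % nv)[:10]
        raise GeometryError(
            "self-intersecting extrusion (thickness exceeds local curvature "
            f"radius) near surface vertices {vids[culprits].tolist()}"
        )

    # boundary vertices of the patch (edges used once)
    edges = np.sort(
        np.concatenate([patch_faces[:, [0, 1]], patch_faces[:, [1, 2]],
                        patch_faces[:, [2, 0]]]), axis=1
    )
    uniq, counts = np.unique(edges, axis=0, return_counts=True)
    boundary_local = np.unique(uniq[counts == 1])

    articular = np.arange(nv)
    bone = np.arange(layers * nv, (layers + 1) * nv)
    rim = np.concatenate(
        [k * nv + boundary_local for k in range(1, layers)]
    ) if layers > 1 else np.empty(0, dtype=np.int64)

    node_thickness = np.tile(t, layers + 1)
    return TetMesh(
        nodes=nodes,
        tets=tets,
        part=part,
        bone_interface=bone,
        articular_surface=articular,
        rim=rim.astype(np.int64),
        surface_faces=patch_faces,
        node_thickness=node_thickness,
    )
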