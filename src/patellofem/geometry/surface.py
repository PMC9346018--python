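"""Core surface-mesh containers shared by the whole pipeline.

Everything lives in one consistent unit system (mm, N, MPa) and one frame:
origin at the deepest mid-trochlear sulcus point, +x lateral along the
posterior condylar baseline (BL), +y anterior, +z proximal.  Models are
generated as right knees; left knees are obtained by mirroring.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import trimesh

REGION_BONE = 0
REGION_CARTILAGE = 1


class GeometryError(ValueError):
    """Raised when a geometric construction or validation fails."""


@dataclass
class SurfaceMesh:
    """Triangulated closed surface with per-vertex tissue labels.

    Parameters
    ----------
    vertices : (n, 3) float array, mm
    triangles : (m, 3) int array
        Consistently oriented (outward) triangle connectivity.
    region : (n,) uint8 array
        ``REGION_CARTILAGE`` on the articular patch, ``REGION_BONE`` elsewhere.
    side : {"right", "left"}
    """

    vertices: np.ndarray
    triangles: np.ndarray
    region: np.ndarray
    side: str = "right"

    def __post_init__(self) -> None:
        self.vertices = np.ascontiguousarray(self.vertices, dtype=float)
        self.triangles = np.ascontiguousarray(self.triangles, dtype=np.int64)
        if self.region is None:
            self.region = np.zeros(len(self.vertices), dtype=np.uint8)
        self.region = np.ascontiguousarray(self.region, dtype=np.uint8)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 3:
            raise GeometryError("vertices must be (n, 3)")
        if self.triangles.ndim != 2 or self.triangles.shape[1] != 3:
            raise GeometryError("triangles must be (m, 3)")
        if len(self.region) != len(self.vertices):
            raise GeometryError("region labels must be per-vertex")
        if self.side not in ("right", "left"):
            raise GeometryError(f"side must be 'right' or 'left', got {self.side!r}")

    # -- derived quantities -------------------------------------------------

    def to_trimesh(self) -> trimesh.Trimesh:
        return trimesh.Trimesh(self.vertices, self.triangles, process=False)

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def cartilage_mask(self) -> np.ndarray:
        return self.region == REGION_CARTILAGE

    def cartilage_faces(self) -> np.ndarray:
        """Faces whose three vertices are all cartilage-labeled."""
        return self.triangles[self.cartilage_mask[self.triangles].all(axis=1)]

    def face_areas(self) -> np.ndarray:
        v = self.vertices
        t = self.triangles
        return 0.5 * np.linalg.norm(
            np.cross(v[t[:, 1]] - v[t[:, 0]], v[t[:, 2]] - v[t[:, 0]]), axis=1
        )

    def vertex_normals(self) -> np.ndarray:
        """Area-weighted outward vertex normals."""
        return np.asarray(self.to_trimesh().vertex_normals)

    def is_watertight(self) -> bool:
        return bool(self.to_trimesh().is_watertight)

    def validate(self) -> None:
        """Check the structural invariants (watertight, non-degenerate,
        connected cartilage patch)."""
        tm = self.to_trimesh()
        if not tm.is_watertight:
            raise GeometryError("surface has boundary edges (not watertight)")
        if np.any(self.face_areas() <= 1e-12):
            raise GeometryError("surface contains zero-area triangles")
        if tm.volume < 0:
            raise GeometryError("triangles are not consistently outward-oriented")
        if not self.cartilage_patch_connected():
            raise GeometryError("cartilage region is not a single connected patch")

    def cartilage_patch_connected(self) -> bool:
        faces = self.cartilage_faces()
        if len(faces) == 0:
            return True
        # union-find over cartilage faces sharing vertices
        ids = {v: i for i, v in enumerate(np.unique(faces))}
        parent = list(range(len(ids)))

        def find(a: int) -> int:
            while parent[a] != a:
                parent[a] = parent[parent[a]]
                a = parent[a]
            return a

        for f in faces:
            a, b, c = (ids[v] for v in f)
            for u, v in ((a, b), (b, c)):
                ra, rb = find(u), find(v)
                if ra != rb:
                    parent[ra] = rb
        roots = {find(i) for i in ids.values()}
        return len(roots) == 1

    def mirrored(self) -> "SurfaceMesh":
        """Reflect across the sagittal plane x = 0 and flip handedness."""
        v = self.vertices.copy()
        v[:, 0] *= -1.0
        t = self.triangles[:, ::-1].copy()
        return SurfaceMesh(
            v, t, self.region.copy(), side=("left" if self.side == "right" else "right")
        )

    def copy(self) -> "SurfaceMesh":
        return SurfaceMesh(
            self.vertices.copy(), self.triangles.copy(), self.region.copy(), self.side
        )


@dataclass
class ThicknessMap:
    """Per-vertex cartilage thickness (mm); zero on bone vertices."""

    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.ascontiguousarray(self.values, dtype=float)
        if np.any(self.values < 0):
            raise GeometryError("cartilage thickness must be non-negative")

    def scaled(self, factor: float) -> "ThicknessMap":
        return ThicknessMap(self.values * float(factor))

    def copy(self) -> "ThicknessMap":
        return ThicknessMap(self.values.copy())


@dataclass
class LoftGrid:
    """Structured bookkeeping for lofted surfaces.

    The generators build surfaces station-by-station; the virtual surgery
    operator edits stations directly, so the vertex grid and the per-station
    profiles are carried alongside the unstructured triangle mesh.
    """

    z_stations: np.ndarray          # (S,) axial station coordinates, mm
    vertex_ids: np.ndarray          # (S, C) vertex index grid
    profiles: list                  # per-station AxialProfile
    n_arc: int                      # columns [0, n_arc) form the anterior arc

    def station_nearest(self, z: float) -> int:
        return int(np.argmin(np.abs(self.z_stations - z)))
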