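"""Lofting of closed axial sections into watertight triangle surfaces."""

from __future__ import annotations

import numpy as np
import trimesh

from .surface import GeometryError, LoftGrid, SurfaceMesh


def loft_closed_sections(
    sections: list[np.ndarray],
    zs: np.ndarray,
    labels: np.ndarray,
    n_arc: int,
    profiles: list | None = None,
    side: str = "right",
) -> tuple[SurfaceMesh, LoftGrid]:
    """Loft a stack of closed 2D sections (same point count) into a closed
    surface with end caps.

    Parameters
    ----------
    sections : list of (C, 2) arrays, one per station, consistent ordering.
    zs : (S,) station coordinates.
    labels : (S, C) per-point region labels.
    n_arc : number of leading columns forming the anterior arc.
    """
    S = len(sections)
    C = len(sections[0])
    if any(len(s) != C for s in sections):
        raise GeometryError("all sections must have the same point count")
    zs = np.asarray(zs, dtype=float)

    verts = np.empty((S * C + 2, 3))
    for i, sec in enumerate(sections):
        verts[i * C : (i + 1) * C, :2] = sec
        verts[i * C : (i + 1) * C, 2] = zs[i]
    # cap centroids (distal = first station, proximal = last)
    verts[S * C] = [*sections[0].mean(axis=0), zs[0]]
    verts[S * C + 1] = [*sections[-1].mean(axis=0), zs[-1]]

    vid = np.arange(S * C).reshape(S, C)
    tris = []
    for i in range(S - 1):
        j = np.arange(C)
        j1 = (j + 1) % C
        a, b = vid[i, j], vid[i, j1]
        c, d = vid[i + 1, j], vid[i + 1, j1]
        tris.append(np.stack([a, b, c], axis=1))
        tris.append(np.stack([c, b, d], axis=1))
    j = np.arange(C)
    j1 = (j + 1) % C
    tris.append(np.stack([np.full(C, S * C), vid[0, j1], vid[0, j]], axis=1))
    tris.append(np.stack([np.full(C, S * C + 1), vid[-1, j], vid[-1, j1]], axis=1))
    triangles = np.concatenate(tris, axis=0)

    # normalize to outward orientation
    vol = trimesh.Trimesh(verts, triangles, process=False).volume
    if vol < 0:
        triangles = triangles[:, ::-1]

    region = np.zeros(len(verts), dtype=np.uint8)
    region[: S * C] = np.asarray(labels, dtype=np.uint8).reshape(-1)

    mesh = SurfaceMesh(verts, triangles, region, side=side)
    grid = LoftGrid(zs.copy(), vid, list(profiles) if profiles else [], n_arc)
    return mesh, grid
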