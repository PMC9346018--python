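"""Surface mesh and landmark I/O.

STL and PLY go through trimesh; the per-vertex ``region`` label is carried
as a custom PLY vertex property and is necessarily dropped for STL (with a
logged warning).  OFF is read and written directly so that non-triangle
faces can be rejected with their face index instead of being silently
triangulated.  Landmarks travel as a JSON sidecar ``{name: [x, y, z]}``.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import trimesh

from .surface import SurfaceMesh

log = logging.getLogger(__name__)

_FORMATS = ("stl", "ply", "off")


class MeshIOError(ValueError):
    """Malformed mesh file or unsupported content."""


def _format_of(path: Path, fmt: str | None) -> str:
    f = (fmt or path.suffix.lstrip(".")).lower()
    if f not in _FORMATS:
        raise MeshIOError(f"unsupported mesh format {f!r}; supported: {_FORMATS}")
    return f


def write_mesh(mesh: SurfaceMesh, path: str | Path, fmt: str | None = None) -> None:
    path = Path(path)
    f = _format_of(path, fmt)
    tm = trimesh.Trimesh(mesh.vertices, mesh.triangles, process=False)
    if f == "stl":
        if np.any(mesh.region):
            log.warning(
                "STL cannot carry vertex region labels; labels dropped for %s", path
            )
        path.write_bytes(tm.export(file_type="stl"))
    elif f == "ply":
        tm.vertex_attributes["region"] = mesh.region.astype(np.uint8)
        path.write_bytes(tm.export(file_type="ply", encoding="ascii"))
    else:
        _write_off(mesh, path)


def read_mesh(path: str | Path, fmt: str | None = None) -> SurfaceMesh:
    path = Path(path)
    f = _format_of(path, fmt)
    if not path.exists():
        raise MeshIOError(f"mesh file not found: {path}")
    if f == "off":
        return _read_off(path)
    try:
        # STL stores unshared triangle soup; merge duplicate vertices there
        tm = trimesh.load_mesh(str(path), file_type=f, process=(f == "stl"))
    except Exception as exc:  # noqa: BLE001 - normalize parser failures
        raise MeshIOError(f"failed to parse {path}: {exc}") from exc
    region = np.zeros(len(tm.vertices), dtype=np.uint8)
    if f == "ply":
        raw = tm.metadata.get("_ply_raw", {})
        vdata = raw.get("vertex", {}).get("data")
        if vdata is not None:
            try:
                region = np.asarray(vdata["region"], dtype=np.uint8).reshape(-1)
            except (KeyError, ValueError, TypeError):
                pass
    return SurfaceMesh(
        np.asarray(tm.vertices, dtype=float),
        np.asarray(tm.faces, dtype=np.int64),
        region,
    )


def _write_off(mesh: SurfaceMesh, path: Path) -> None:
    lines = ["OFF", f"{len(mesh.vertices)} {len(mesh.triangles)} 0"]
    lines += [f"{x:.9g} {y:.9g} {z:.9g}" for x, y, z in mesh.vertices]
    lines += [f"3 {a} {b} {c}" for a, b, c in mesh.triangles]
    path.write_text("\n".join(lines) + "\n")


def _read_off(path: Path) -> SurfaceMesh:
    tokens: list[str] = []
    for lineno, line in enumerate(path.read_text().splitlines(), 1):
        body = line.split("#", 1)[0].strip()
        if body:
            tokens.extend(body.split())
    if not tokens or tokens[0] != "OFF":
        raise MeshIOError(f"{path}: missing OFF header")
    try:
        nv, nf = int(tokens[1]), int(tokens[2])
        pos = 4
        verts = np.array(tokens[pos : pos + 3 * nv], dtype=float).reshape(nv, 3)
        pos += 3 * nv
        faces = np.empty((nf, 3), dtype=np.int64)
        for i in range(nf):
            k = int(tokens[pos])
            if k != 3:
                raise MeshIOError(
                    f"{path}: face {i} has {k} vertices; only triangles supported"
                )
            faces[i] = [int(t) for t in tokens[pos + 1 : pos + 4]]
            pos += 1 + k
    except (ValueError, IndexError) as exc:
        raise MeshIOError(f"{path}: malformed OFF record: {exc}") from exc
    return SurfaceMesh(verts, faces, np.zeros(nv, dtype=np.uint8))


def write_landmarks(landmarks: dict, path: str | Path) -> None:
    payload = {k: np.asarray(v, dtype=float).tolist() for k, v in landmarks.items()}
    Path(path).write_text(json.dumps(payload, indent=1))


def read_landmarks(path: str | Path) -> dict:
    data = json.loads(Path(path).read_text())
    return {k: np.asarray(v, dtype=float) for k, v in data.items()}
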