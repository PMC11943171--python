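"""Mesh and landmark I/O.

Supported mesh formats: VTK legacy ASCII PolyData (read/written natively —
this is the format the pipeline uses for its own outputs, with optional
per-vertex scalar fields), PLY and STL (through trimesh). Landmarks travel
as CSV with a ``name,x,y,z`` header (mm) or the JSON equivalent
``{"RS": [x, y, z], ...}``.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Dict, Optional

import numpy as np
import pandas as pd

from .mesh import LandmarkSet, MalformedMeshError, SurfaceMesh

__all__ = [
    "read_mesh",
    "write_mesh",
    "read_landmarks",
    "write_landmarks",
    "read_vtk_polydata",
    "write_vtk_polydata",
]

_FORMATS = ("vtk", "ply", "stl")


def _infer_format(path: Path, fmt: Optional[str]) -> str:
    if fmt is None:
        fmt = path.suffix.lstrip(".").lower()
    fmt = fmt.lower()
    if fmt not in _FORMATS:
        raise ValueError(f"unsupported mesh format {fmt!r}; expected one of {_FORMATS}")
    return fmt


def read_mesh(path, fmt: Optional[str] = None) -> SurfaceMesh:
    """Read a triangulated surface (mm) from VTK/PLY/STL.

    STL stores an unindexed triangle soup, so duplicated corner vertices are
    merged on load; VTK and PLY round-trip vertex arrays exactly.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = _infer_format(path, fmt)
    if fmt == "vtk":
        mesh, _ = read_vtk_polydata(path)
    else:
        import trimesh

        tm = trimesh.load(str(path), file_type=fmt, process=False)
        mesh = SurfaceMesh.from_trimesh(tm)
        if fmt == "stl":
            tm.merge_vertices()
            mesh = SurfaceMesh.from_trimesh(tm)
    if mesh.n_faces == 0:
        raise MalformedMeshError(f"{path} contains no faces")
    return mesh.validate()


def write_mesh(
    mesh: SurfaceMesh,
    path,
    fmt: Optional[str] = None,
    point_scalars: Optional[Dict[str, np.ndarray]] = None,
) -> Path:
    """Write a mesh; ``point_scalars`` (per-vertex fields) only for VTK."""
    path = Path(path)
    fmt = _infer_format(path, fmt)
    path.parent.mkdir(parents=True, exist_ok=True)
    if fmt == "vtk":
        write_vtk_polydata(mesh, path, point_scalars=point_scalars)
    else:
        if point_scalars:
            raise ValueError("per-vertex scalars are only supported for VTK output")
        mesh.to_trimesh().export(str(path), file_type=fmt)
    return path


# ---------------------------------------------------------------------------
# VTK legacy ASCII PolyData
# ---------------------------------------------------------------------------


def write_vtk_polydata(
    mesh: SurfaceMesh, path, point_scalars: Optional[Dict[str, np.ndarray]] = None
) -> None:
    v, f = mesh.vertices, mesh.faces
    lines = [
        "# vtk DataFile Version 3.0",
        "radsym surface mesh (mm)",
        "ASCII",
        "DATASET POLYDATA",
        f"POINTS {len(v)} double",
    ]
    lines.extend(" ".join(f"{x:.17g}" for x in row) for row in v)
    lines.append(f"POLYGONS {len(f)} {4 * len(f)}")
    lines.extend(f"3 {a} {b} {c}" for a, b, c in f)
    if point_scalars:
        lines.append(f"POINT_DATA {len(v)}")
        for name, values in point_scalars.items():
            values = np.asarray(values, dtype=float).reshape(-1)
            if len(values) != len(v):
                raise ValueError(f"scalar field {name!r} length != vertex count")
            lines.append(f"SCALARS {name} double 1")
            lines.append("LOOKUP_TABLE default")
            lines.extend(f"{x:.17g}" for x in values)
    Path(path).write_text("\n".join(lines) + "\n")


def read_vtk_polydata(path):
    """Parse legacy ASCII PolyData. Returns (mesh, point_scalars dict)."""
    tokens = []
    text = Path(path).read_text()
    if "ASCII" not in text.split("\n", 4)[2].upper():
        raise MalformedMeshError(f"{path}: only ASCII legacy VTK is supported")
    # tokenise everything after the 4-line header
    body = text.split("\n", 3)[3]
    tokens = body.split()
    pos = 0

    def take(n=1):
        nonlocal pos
        out = tokens[pos : pos + n]
        pos += n
        return out

    verts = faces = None
    scalars: Dict[str, np.ndarray] = {}
    n_points = 0
    while pos < len(tokens):
        key = take()[0].upper()
        if key == "DATASET":
            if take()[0].upper() != "POLYDATA":
                raise MalformedMeshError(f"{path}: not a POLYDATA file")
        elif key == "POINTS":
            n_points = int(take()[0])
            take()  # dtype
            verts = np.array(take(3 * n_points), dtype=float).reshape(n_points, 3)
        elif key == "POLYGONS":
            n_polys = int(take()[0])
            n_ints = int(take()[0])
            raw = np.array(take(n_ints), dtype=np.int64)
            faces, i = [], 0
            for _ in range(n_polys):
                k = raw[i]
                poly = raw[i + 1 : i + 1 + k]
                i += 1 + k
                for j in range(1, k - 1):  # fan-triangulate
                    faces.append((poly[0], poly[j], poly[j + 1]))
            faces = np.array(faces, dtype=np.int64)
        elif key == "POINT_DATA":
            take()
        elif key == "SCALARS":
            name = take()[0]
            take(2)  # dtype, n_components (assumed 1)
            peek = tokens[pos].upper()
            if peek == "LOOKUP_TABLE":
                take(2)
            scalars[name] = np.array(take(n_points), dtype=float)
        else:
            continue
    if verts is None or faces is None or len(faces) == 0:
        raise MalformedMeshError(f"{path}: missing POINTS or POLYGONS")
    return SurfaceMesh(verts, faces), scalars


# ---------------------------------------------------------------------------
# Landmarks
# ---------------------------------------------------------------------------


def write_landmarks(landmarks: LandmarkSet, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if path.suffix.lower() == ".json":
        path.write_text(
            json.dumps({k: list(map(float, v)) for k, v in landmarks.points.items()}, indent=1)
        )
    else:
        rows = [{"name": k, "x": v[0], "y": v[1], "z": v[2]} for k, v in landmarks.points.items()]
        pd.DataFrame(rows).to_csv(path, index=False)
    return path


def read_landmarks(path) -> LandmarkSet:
    path = Path(path)
    if path.suffix.lower() == ".json":
        return LandmarkSet(json.loads(path.read_text()))
    df = pd.read_csv(path)
    return LandmarkSet({r["name"]: (r["x"], r["y"], r["z"]) for _, r in df.iterrows()})
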