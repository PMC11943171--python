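"""Core geometric types: triangulated surfaces, landmarks, rigid motions, label volumes.

All coordinates are in millimetres. A :class:`SurfaceMesh` is the universal
currency of the pipeline: a vertex array, a triangle index array, and (lazily)
outward area-weighted vertex normals. Landmarks are a small named set of 3D
points (radial styloid ``RS``, distal styloid notch ``DSN``, and optionally a
dorsal distal-radius point ``DDR``) used only for rigid alignment and for the
articular-plane definition.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, Optional

import numpy as np

__all__ = [
    "SurfaceMesh",
    "LandmarkSet",
    "RigidTransform",
    "LabelVolume",
    "MalformedMeshError",
]


class MalformedMeshError(ValueError):
    """Raised when a mesh violates its structural invariants."""


@dataclass
class SurfaceMesh:
    """A triangulated surface in mm.

    Parameters
    ----------
    vertices : (n, 3) float array
    faces : (m, 3) int array of vertex indices, counter-clockwise when viewed
        from outside (outward normals by the right-hand rule).
    """

    vertices: np.ndarray
    faces: np.ndarray
    _vertex_normals: Optional[np.ndarray] = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.vertices = np.ascontiguousarray(np.asarray(self.vertices, dtype=float))
        self.faces = np.ascontiguousarray(np.asarray(self.faces, dtype=np.int64))
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 3:
            raise MalformedMeshError("vertices must be an (n, 3) array")
        if self.faces.ndim != 2 or self.faces.shape[1] != 3:
            raise MalformedMeshError("faces must be an (m, 3) array")

    # -- basic counts -------------------------------------------------
    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_faces(self) -> int:
        return len(self.faces)

    def copy(self) -> "SurfaceMesh":
        return SurfaceMesh(self.vertices.copy(), self.faces.copy())

    # -- structural checks --------------------------------------------
    def validate(self) -> "SurfaceMesh":
        """Check the structural invariants, raising :class:`MalformedMeshError`.

        Faces must reference three distinct, in-range vertices and every
        vertex must be used by at least one face (no isolated vertices).
        """
        if self.n_faces == 0:
            raise MalformedMeshError("mesh has no faces")
        f = self.faces
        if f.min() < 0 or f.max() >= self.n_vertices:
            raise MalformedMeshError("face index out of range")
        if np.any((f[:, 0] == f[:, 1]) | (f[:, 1] == f[:, 2]) | (f[:, 0] == f[:, 2])):
            raise MalformedMeshError("degenerate face with repeated vertex index")
        used = np.zeros(self.n_vertices, dtype=bool)
        used[f.ravel()] = True
        if not used.all():
            raise MalformedMeshError(f"{(~used).sum()} isolated vertices")
        return self

    def remove_unreferenced_vertices(self) -> "SurfaceMesh":
        """Return a copy with isolated vertices dropped and faces re-indexed."""
        used = np.zeros(self.n_vertices, dtype=bool)
        used[self.faces.ravel()] = True
        remap = -np.ones(self.n_vertices, dtype=np.int64)
        remap[used] = np.arange(used.sum())
        return SurfaceMesh(self.vertices[used], remap[self.faces])

    # -- derived geometry ---------------------------------------------
    @property
    def face_centers(self) -> np.ndarray:
        v = self.vertices
        return v[self.faces].mean(axis=1)

    @property
    def face_normals_weighted(self) -> np.ndarray:
        """Area-weighted face normals: 0.5 * (e1 x e2), |n| = triangle area."""
        v = self.vertices
        t = v[self.faces]
        return 0.5 * np.cross(t[:, 1] - t[:, 0], t[:, 2] - t[:, 0])

    @property
    def face_areas(self) -> np.ndarray:
        return np.linalg.norm(self.face_normals_weighted, axis=1)

    @property
    def area(self) -> float:
        return float(self.face_areas.sum())

    def vertex_normals(self) -> np.ndarray:
        """Outward unit vertex normals (area-weighted average of face normals)."""
        if self._vertex_normals is not None:
            return self._vertex_normals
        fn = self.face_normals_weighted
        vn = np.zeros_like(self.vertices)
        for k in range(3):
            np.add.at(vn, self.faces[:, k], fn)
        norms = np.linalg.norm(vn, axis=1)
        norms[norms == 0] = 1.0
        self._vertex_normals = vn / norms[:, None]
        return self._vertex_normals

    def signed_volume(self) -> float:
        """Volume enclosed by a closed surface via the divergence theorem.

        Positive when face winding is outward-consistent.
        """
        t = self.vertices[self.faces]
        return float(np.einsum("ij,ij->i", t[:, 0], np.cross(t[:, 1], t[:, 2])).sum() / 6.0)

    def euler_characteristic(self) -> int:
        edges = np.sort(
            np.concatenate([self.faces[:, [0, 1]], self.faces[:, [1, 2]], self.faces[:, [2, 0]]]),
            axis=1,
        )
        n_edges = len(np.unique(edges, axis=0))
        return self.n_vertices - n_edges + self.n_faces

    def mean_edge_length(self) -> float:
        v = self.vertices
        e = np.concatenate(
            [
                v[self.faces[:, 0]] - v[self.faces[:, 1]],
                v[self.faces[:, 1]] - v[self.faces[:, 2]],
                v[self.faces[:, 2]] - v[self.faces[:, 0]],
            ]
        )
        return float(np.linalg.norm(e, axis=1).mean())

    @property
    def bounds(self) -> np.ndarray:
        """(2, 3) array: [min_corner, max_corner] in mm."""
        return np.array([self.vertices.min(axis=0), self.vertices.max(axis=0)])

    def centroid(self) -> np.ndarray:
        """Arithmetic mean of the vertex positions (unweighted)."""
        return self.vertices.mean(axis=0)

    # -- interop -------------------------------------------------------
    def to_trimesh(self):
        import trimesh

        return trimesh.Trimesh(vertices=self.vertices, faces=self.faces, process=False)

    @classmethod
    def from_trimesh(cls, tm) -> "SurfaceMesh":
        return cls(np.asarray(tm.vertices, dtype=float), np.asarray(tm.faces, dtype=np.int64))


class LandmarkSet:
    """Named anatomical points in mm. ``RS`` and ``DSN`` are mandatory for
    pairwise alignment; ``DDR`` is additionally required in atlas mode."""

    REQUIRED = ("RS", "DSN")

    def __init__(self, points: Dict[str, Iterable[float]]):
        self.points: Dict[str, np.ndarray] = {
            str(k): np.asarray(v, dtype=float).reshape(3) for k, v in points.items()
        }
        for name in self.REQUIRED:
            if name not in self.points:
                raise ValueError(f"landmark set missing required point {name!r}")

    def __getitem__(self, name: str) -> np.ndarray:
        return self.points[name]

    def __contains__(self, name: str) -> bool:
        return name in self.points

    def names(self):
        return list(self.points.keys())

    def as_array(self, names=None) -> np.ndarray:
        names = names if names is not None else self.names()
        return np.stack([self.points[n] for n in names])

    def copy(self) -> "LandmarkSet":
        return LandmarkSet({k: v.copy() for k, v in self.points.items()})

    def transformed(self, fn) -> "LandmarkSet":
        """Apply ``fn`` (mapping (k,3)->(k,3) arrays) to all points."""
        names = self.names()
        pts = fn(self.as_array(names))
        return LandmarkSet(dict(zip(names, pts)))

    def check_within(self, mesh: SurfaceMesh, pad_mm: float = 2.0) -> bool:
        lo, hi = mesh.bounds
        arr = self.as_array()
        return bool(np.all(arr >= lo - pad_mm) and np.all(arr <= hi + pad_mm))

    def __eq__(self, other) -> bool:
        return isinstance(other, LandmarkSet) and set(self.names()) == set(other.names()) and all(
            np.array_equal(self.points[n], other.points[n]) for n in self.names()
        )


@dataclass
class RigidTransform:
    """A proper rigid motion x -> R @ x + t (rotation det +1, translation mm)."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self) -> None:
        self.rotation = np.asarray(self.rotation, dtype=float).reshape(3, 3)
        self.translation = np.asarray(self.translation, dtype=float).reshape(3)
        if not np.allclose(self.rotation @ self.rotation.T, np.eye(3), atol=1e-8):
            raise ValueError("rotation must be orthonormal")
        if np.linalg.det(self.rotation) < 0:
            raise ValueError("rotation must be proper (det +1), not a reflection")

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))

    def apply(self, points: np.ndarray) -> np.ndarray:
        return np.asarray(points, dtype=float) @ self.rotation.T + self.translation

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """Return self ∘ other (apply ``other`` first)."""
        return RigidTransform(
            self.rotation @ other.rotation,
            self.rotation @ other.translation + self.translation,
        )

    def inverse(self) -> "RigidTransform":
        return RigidTransform(self.rotation.T, -self.rotation.T @ self.translation)


@dataclass
class LabelVolume:
    """Binary occupancy volume with physical voxel spacing and origin (mm).

    Voxel center (i, j, k) sits at ``origin + spacing * (i, j, k)``.
    """

    data: np.ndarray
    spacing: np.ndarray
    origin: np.ndarray

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data).astype(bool)
        self.spacing = np.asarray(self.spacing, dtype=float).reshape(3)
        self.origin = np.asarray(self.origin, dtype=float).reshape(3)
        if self.data.ndim != 3:
            raise ValueError("label volume must be 3-D")
        if np.any(self.spacing <= 0):
            raise ValueError("voxel spacing must be strictly positive")

    @property
    def n_foreground(self) -> int:
        return int(self.data.sum())
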