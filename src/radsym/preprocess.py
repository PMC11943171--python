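"""Rigid preprocessing of paired bone meshes.

The pairwise pipeline standardises a left/right pair into one common frame in
four steps: (1) mirror the right mesh across the x-axis so both sides share
chirality; (2) align each bone's long (first principal) axis with +z via
Rodrigues' rotation formula, with the articular end (the end nearer the RS
landmark) pointing toward +z, shift the lowest vertex to the origin, and crop
to the distal-most 50 mm; (3) rigidly align the right mesh onto the left by
least squares over three correspondences (RS, DSN, mesh centroid); (4) crop
both to the distal-most 43 mm and decimate to a common vertex budget.

All operations co-transform the landmark set, and all rigid operations
preserve pairwise distances exactly (up to floating point).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Tuple

import numpy as np

from .decimate import decimate
from .mesh import LabelVolume, LandmarkSet, MalformedMeshError, RigidTransform, SurfaceMesh

__all__ = [
    "PreprocessConfig",
    "extract_isosurface",
    "mirror_x",
    "principal_axis_align",
    "shift_lowest_to_origin",
    "crop_by_plane",
    "rigid_align_landmarks",
    "isolate_articular_surface",
    "preprocess_pair",
    "rodrigues_rotation",
]


@dataclass
class PreprocessConfig:
    crop_long_mm: float = 50.0
    crop_final_mm: float = 43.0
    target_vertices: int = 5295


class EmptyResultError(ValueError):
    """A crop or mask removed every vertex."""


class DegenerateGeometryError(ValueError):
    """Point configuration too degenerate for the requested operation."""


# ---------------------------------------------------------------------------
# Isosurface extraction
# ---------------------------------------------------------------------------


def extract_isosurface(volume: LabelVolume, level: float = 0.5) -> SurfaceMesh:
    """Marching-cubes surface of a binary label volume, in mm.

    The binary occupancy is lightly Gaussian-smoothed (1 voxel) before
    contouring — marching cubes on a raw 0/1 field produces a faceted
    surface whose area is inflated by ~10% — and ``level`` is interpreted
    as a fraction of the smoothed foreground peak, so small components
    (down to a single voxel) still yield a closed surface. The volume is
    padded with one background layer so solid components close; face
    winding is fixed to outward (positive enclosed volume).
    """
    from scipy.ndimage import gaussian_filter
    from skimage import measure

    if not 0.0 < level < 1.0:
        raise ValueError("level must be in (0, 1)")
    if volume.n_foreground == 0:
        raise EmptyResultError("label volume has empty foreground")
    padded = np.pad(volume.data.astype(np.float32), 1)
    smoothed = gaussian_filter(padded, sigma=1.0)
    verts, faces, _, _ = measure.marching_cubes(
        smoothed, level=level * float(smoothed.max()), spacing=tuple(volume.spacing)
    )
    verts = verts - volume.spacing + volume.origin  # undo pad, to physical frame
    mesh = SurfaceMesh(verts, faces)
    if mesh.signed_volume() < 0:
        mesh = SurfaceMesh(mesh.vertices, mesh.faces[:, ::-1])
    return mesh


# ---------------------------------------------------------------------------
# Mirroring and axis alignment
# ---------------------------------------------------------------------------


def mirror_x(mesh: SurfaceMesh, landmarks: LandmarkSet) -> Tuple[SurfaceMesh, LandmarkSet]:
    """Negate x-coordinates; flip winding so outward normals stay outward."""
    v = mesh.vertices.copy()
    v[:, 0] = -v[:, 0]
    out = SurfaceMesh(v, mesh.faces[:, ::-1].copy())
    return out, landmarks.transformed(lambda p: p * np.array([-1.0, 1.0, 1.0]))


def rodrigues_rotation(axis: np.ndarray, angle: float) -> np.ndarray:
    """Rotation matrix about a unit ``axis`` by ``angle`` (Rodrigues' formula)."""
    k = np.asarray(axis, dtype=float)
    k = k / np.linalg.norm(k)
    K = np.array([[0, -k[2], k[1]], [k[2], 0, -k[0]], [-k[1], k[0], 0]])
    return np.eye(3) + np.sin(angle) * K + (1.0 - np.cos(angle)) * (K @ K)


def principal_axis_align(
    mesh: SurfaceMesh, landmarks: LandmarkSet
) -> Tuple[SurfaceMesh, LandmarkSet, RigidTransform]:
    """Rotate so the first principal axis of the vertex cloud is +z.

    The sign is fixed anatomically: the end nearer the RS landmark (the
    articular end) gets the larger z. Raises when the vertex cloud has no
    dominant axis.
    """
    v = mesh.vertices
    centroid = v.mean(axis=0)
    cov = np.cov((v - centroid).T)
    evals, evecs = np.linalg.eigh(cov)
    if evals[-1] <= 0 or (evals[-1] - evals[-2]) / evals[-1] < 1e-8:
        raise DegenerateGeometryError("vertex cloud has no unambiguous principal axis")
    axis = evecs[:, -1]
    if np.dot(landmarks["RS"] - centroid, axis) < 0:
        axis = -axis
    z = np.array([0.0, 0.0, 1.0])
    c = float(np.clip(np.dot(axis, z), -1.0, 1.0))
    cross = np.cross(axis, z)
    s = np.linalg.norm(cross)
    if s < 1e-12:
        R = np.eye(3) if c > 0 else rodrigues_rotation(np.array([1.0, 0.0, 0.0]), np.pi)
    else:
        R = rodrigues_rotation(cross / s, float(np.arctan2(s, c)))
    xf = RigidTransform(R, np.zeros(3))
    return (
        SurfaceMesh(xf.apply(v), mesh.faces.copy()),
        landmarks.transformed(xf.apply),
        xf,
    )


def shift_lowest_to_origin(
    mesh: SurfaceMesh, landmarks: LandmarkSet
) -> Tuple[SurfaceMesh, LandmarkSet]:
    """Translate so the minimum-z vertex sits exactly at (0, 0, 0)."""
    low = mesh.vertices[np.argmin(mesh.vertices[:, 2])]
    return (
        SurfaceMesh(mesh.vertices - low, mesh.faces.copy()),
        landmarks.transformed(lambda p: p - low),
    )


# ---------------------------------------------------------------------------
# Plane crops
# ---------------------------------------------------------------------------


def crop_by_plane(
    mesh: SurfaceMesh, point, normal, keep: str = "below", cap: bool = False
) -> SurfaceMesh:
    """Cut the mesh with a plane, keeping one half-space.

    ``keep="below"`` retains vertices with ``(v - point) . normal <= 0``.
    Faces crossing the plane are clipped with interpolated boundary vertices,
    so the retained extent is geometrically exact. With ``cap`` the planar
    cut is sealed with a triangle fan per boundary loop (valid for the
    star-shaped cross-sections of tubular bones), keeping closed inputs
    watertight.
    """
    import trimesh.intersections

    point = np.asarray(point, dtype=float)
    normal = np.asarray(normal, dtype=float)
    normal = normal / np.linalg.norm(normal)
    if keep not in ("below", "above"):
        raise ValueError("keep must be 'below' or 'above'")
    side = -normal if keep == "below" else normal
    d = (mesh.vertices - point) @ side
    if np.all(d >= 0):  # plane does not cut anything off
        return mesh.copy()
    if np.all(d < -1e-12):
        raise EmptyResultError("crop plane removes the entire mesh")
    sliced = trimesh.intersections.slice_mesh_plane(
        mesh.to_trimesh(), plane_normal=side, plane_origin=point
    )
    if len(sliced.faces) == 0:
        raise EmptyResultError("crop plane removes the entire mesh")
    sliced.merge_vertices()  # clip points are duplicated per cut face
    out = SurfaceMesh.from_trimesh(sliced).remove_unreferenced_vertices()
    if cap:
        out = _cap_planar_boundary(out, point, side)
    return out


def _cap_planar_boundary(mesh: SurfaceMesh, point, side, tol=1e-6, snap=False) -> SurfaceMesh:
    """Seal boundary loops lying near the cut plane with centroid fans.

    With ``snap`` the loop vertices are projected exactly onto the plane
    first (used when capping after decimation, which may move rim vertices
    slightly off-plane)."""
    f = mesh.faces
    edges = np.concatenate([f[:, [0, 1]], f[:, [1, 2]], f[:, [2, 0]]])
    keys = np.sort(edges, axis=1)
    uniq, inv, counts = np.unique(keys, axis=0, return_inverse=True, return_counts=True)
    boundary_edges = edges[(counts == 1)[inv]]
    if len(boundary_edges) == 0:
        return mesh
    dist = (mesh.vertices - point) @ side
    on_plane = np.abs(dist) < tol
    boundary_edges = boundary_edges[on_plane[boundary_edges].all(axis=1)]
    if len(boundary_edges) == 0:
        return mesh
    verts = mesh.vertices
    if snap:
        verts = verts.copy()
        loop_ids = np.unique(boundary_edges)
        verts[loop_ids] -= np.outer(dist[loop_ids], side)
    # walk directed boundary edges into loops
    nxt = {int(a): int(b) for a, b in boundary_edges}
    new_verts = [verts]
    new_faces = [f]
    visited = set()
    base = len(verts)
    for start in list(nxt):
        if start in visited:
            continue
        loop = [start]
        visited.add(start)
        cur = nxt.get(start)
        while cur is not None and cur != start and cur not in visited:
            loop.append(cur)
            visited.add(cur)
            cur = nxt.get(cur)
        if cur != start or len(loop) < 3:
            continue
        center = verts[loop].mean(axis=0)
        cid = base
        base += 1
        new_verts.append(center[None, :])
        fan = np.array([[cid, b, a] for a, b in zip(loop, loop[1:] + [loop[0]])])
        # outward cap normal points away from the kept half-space
        va, vb = verts[fan[:, 1]] - center, verts[fan[:, 2]] - center
        fn = np.cross(va, vb)
        if fn.sum(axis=0) @ (-side) < 0:
            fan = fan[:, [0, 2, 1]]
        fan = fan[np.linalg.norm(fn, axis=1) > 1e-12]  # drop degenerate slivers
        new_faces.append(fan)
    return SurfaceMesh(np.vstack(new_verts), np.vstack(new_faces))


def isolate_articular_surface(mesh: SurfaceMesh, landmarks: LandmarkSet) -> SurfaceMesh:
    """Sub-mesh distal of the DSN plane (vertex z >= z(DSN)).

    The articular surface is isolated by the plane perpendicular to the bone
    axis through the DSN landmark; faces are kept whole (vertex predicate,
    no clipping) so the articular mask is a strict vertex subset.
    """
    if "DSN" not in landmarks:
        raise ValueError("DSN landmark required for articular isolation")
    z_cut = landmarks["DSN"][2]
    keep = mesh.vertices[:, 2] >= z_cut
    if not keep.any():
        raise EmptyResultError("DSN plane lies above the whole mesh")
    face_keep = keep[mesh.faces].all(axis=1)
    if not face_keep.any():
        raise EmptyResultError("no complete face distal of the DSN plane")
    return SurfaceMesh(mesh.vertices, mesh.faces[face_keep]).remove_unreferenced_vertices()


def articular_mask(mesh: SurfaceMesh, landmarks: LandmarkSet) -> np.ndarray:
    """Boolean per-vertex mask of the articular (distal-of-DSN) region."""
    return mesh.vertices[:, 2] >= landmarks["DSN"][2]


# ---------------------------------------------------------------------------
# Landmark-based rigid alignment (Kabsch)
# ---------------------------------------------------------------------------


def rigid_align_landmarks(source_points: np.ndarray, target_points: np.ndarray) -> RigidTransform:
    """Least-squares proper rigid motion mapping source points onto targets.

    Solves the orthogonal Procrustes (Kabsch) problem restricted to rotations
    with determinant +1 — no scaling, no reflection.
    """
    from scipy.spatial.transform import Rotation

    src = np.asarray(source_points, dtype=float)
    tgt = np.asarray(target_points, dtype=float)
    if src.shape != tgt.shape or src.ndim != 2 or src.shape[0] < 3:
        raise ValueError("need >= 3 paired 3-D points")
    mu_s, mu_t = src.mean(axis=0), tgt.mean(axis=0)
    s0, t0 = src - mu_s, tgt - mu_t
    if np.linalg.matrix_rank(s0, tol=1e-9 * max(1.0, np.abs(s0).max())) < 2:
        raise DegenerateGeometryError("source points are collinear")
    rot, _ = Rotation.align_vectors(t0, s0)
    R = rot.as_matrix()
    return RigidTransform(R, mu_t - R @ mu_s)


# ---------------------------------------------------------------------------
# Full pairwise preprocessing
# ---------------------------------------------------------------------------


def _standardize_single(mesh, lm, crop_long_mm):
    mesh, lm, _ = principal_axis_align(mesh, lm)
    mesh, lm = shift_lowest_to_origin(mesh, lm)
    z_max = mesh.vertices[:, 2].max()
    if z_max > crop_long_mm:
        # keep the distal-most crop_long_mm of bone (the final crop re-cuts
        # below this, so the rim is left open here)
        mesh = crop_by_plane(mesh, (0, 0, z_max - crop_long_mm), (0, 0, 1), keep="above")
        mesh, lm = shift_lowest_to_origin(mesh, lm)
    return mesh, lm


def preprocess_pair(
    left: SurfaceMesh,
    left_landmarks: LandmarkSet,
    right: SurfaceMesh,
    right_landmarks: LandmarkSet,
    config: PreprocessConfig = PreprocessConfig(),
) -> Tuple[SurfaceMesh, LandmarkSet, SurfaceMesh, LandmarkSet]:
    """Standardise a left/right pair into one corresponded analysis frame.

    Returns the preprocessed ``(left, left_landmarks, right, right_landmarks)``
    with the mirrored right rigidly aligned onto the left, both cropped to the
    final length and decimated to the common vertex budget.
    """
    for lm in (left_landmarks, right_landmarks):
        for name in ("RS", "DSN"):
            if name not in lm:
                raise ValueError(f"landmark {name} required for pairwise preprocessing")
    # Step 1: mirror the right side
    right, right_landmarks = mirror_x(right, right_landmarks)
    # Step 2: per-side axis alignment, origin shift, long crop
    left, left_landmarks = _standardize_single(left, left_landmarks, config.crop_long_mm)
    right, right_landmarks = _standardize_single(right, right_landmarks, config.crop_long_mm)
    # Step 3: rigid alignment of right onto left via RS, DSN, centroid.
    # The centroid correspondence is refined once on the commonly-cropped
    # meshes: centroids of the per-side long crops are biased by each side's
    # own crop window, so after the first alignment the final crop plane is
    # fixed in the common frame and the alignment is recomputed with
    # centroids of identically-cropped meshes.
    right0, right0_landmarks = right, right_landmarks
    src = np.stack([right_landmarks["RS"], right_landmarks["DSN"], right.centroid()])
    tgt = np.stack([left_landmarks["RS"], left_landmarks["DSN"], left.centroid()])
    xf = rigid_align_landmarks(src, tgt)
    left_cropped = None
    for _ in range(3):
        right = SurfaceMesh(xf.apply(right0.vertices), right0.faces.copy())
        right_landmarks = right0_landmarks.transformed(xf.apply)
        z_max = min(left.vertices[:, 2].max(), right.vertices[:, 2].max())
        plane = (0.0, 0.0, z_max - config.crop_final_mm)
        left_cropped = crop_by_plane(left, plane, (0, 0, 1), keep="above")
        right_cropped = crop_by_plane(right, plane, (0, 0, 1), keep="above")
        src = np.stack(
            [right_landmarks["RS"], right_landmarks["DSN"], right_cropped.centroid()]
        )
        tgt = np.stack(
            [left_landmarks["RS"], left_landmarks["DSN"], left_cropped.centroid()]
        )
        xf_new = rigid_align_landmarks(src, tgt).compose(xf)
        delta = np.abs(xf_new.apply(right0.centroid()) - xf.apply(right0.centroid())).max()
        xf = xf_new
        if delta < 1e-6:
            break
    # Step 4: shared final crop, decimation, then capping of the cut.
    # Decimation runs on the open crop (its boundary quadrics keep the rim
    # crisp); the rim is sealed afterwards so the analysed surfaces are
    # watertight and the cap triangulation is tied to the rim.
    right = SurfaceMesh(xf.apply(right0.vertices), right0.faces.copy())
    right_landmarks = right0_landmarks.transformed(xf.apply)
    z_max = min(left.vertices[:, 2].max(), right.vertices[:, 2].max())
    plane = (0.0, 0.0, z_max - config.crop_final_mm)
    left = crop_by_plane(left, plane, (0, 0, 1), keep="above")
    right = crop_by_plane(right, plane, (0, 0, 1), keep="above")
    shift = left.vertices[np.argmin(left.vertices[:, 2])].copy()
    left = SurfaceMesh(left.vertices - shift, left.faces)
    right = SurfaceMesh(right.vertices - shift, right.faces)
    left_landmarks = left_landmarks.transformed(lambda p: p - shift)
    right_landmarks = right_landmarks.transformed(lambda p: p - shift)
    if config.target_vertices and left.n_vertices > config.target_vertices:
        left = decimate(left, config.target_vertices)
    if config.target_vertices and right.n_vertices > config.target_vertices:
        right = decimate(right, config.target_vertices)
    zp = np.zeros(3)
    up = np.array([0.0, 0.0, 1.0])
    left = _cap_planar_boundary(left, zp, up, tol=1.0, snap=True)
    right = _cap_planar_boundary(right, zp, up, tol=1.0, snap=True)
    return left, left_landmarks, right, right_landmarks
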