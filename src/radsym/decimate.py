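"""Quadric-error mesh decimation (Garland–Heckbert edge collapse).

Vertices accumulate plane quadrics from their incident faces (area weighted);
edges are collapsed greedily in order of quadric error, placing the merged
vertex at the minimiser of the combined quadric when that solve is well
conditioned and stays near the edge, otherwise at the best of (midpoint,
endpoints). Each collapse removes exactly one vertex, so the requested
vertex count is hit exactly whenever enough valid edges remain. Collapses
that would flip a surviving face normal are rejected, keeping the
simplified surface close to the input.
"""

from __future__ import annotations

import heapq
import warnings

import numpy as np

from .mesh import SurfaceMesh

__all__ = ["decimate"]


def _vertex_quadrics(mesh: SurfaceMesh) -> np.ndarray:
    v, f = mesh.vertices, mesh.faces
    t = v[f]
    n = np.cross(t[:, 1] - t[:, 0], t[:, 2] - t[:, 0])
    area2 = np.linalg.norm(n, axis=1)
    good = area2 > 1e-14
    n_unit = np.zeros_like(n)
    n_unit[good] = n[good] / area2[good, None]
    d = -np.einsum("ij,ij->i", n_unit, t[:, 0])
    p = np.concatenate([n_unit, d[:, None]], axis=1)  # plane (a, b, c, d)
    Kf = p[:, :, None] * p[:, None, :] * (0.5 * area2)[:, None, None]
    Q = np.zeros((len(v), 4, 4))
    for k in range(3):
        np.add.at(Q, f[:, k], Kf)
    _add_boundary_quadrics(mesh, n_unit, Q)
    return Q


def _add_boundary_quadrics(mesh: SurfaceMesh, face_normals_unit, Q) -> None:
    """Constrain open-boundary edges with perpendicular plane quadrics so the
    cut rings of cropped meshes keep their shape (standard boundary handling
    for quadric decimation)."""
    f = mesh.faces
    edges = np.concatenate([f[:, [0, 1]], f[:, [1, 2]], f[:, [2, 0]]])
    face_of_edge = np.tile(np.arange(len(f)), 3)
    keys = np.sort(edges, axis=1)
    uniq, inv, counts = np.unique(keys, axis=0, return_inverse=True, return_counts=True)
    boundary = counts[inv] == 1
    if not boundary.any():
        return
    v = mesh.vertices
    for (i, j), fid in zip(edges[boundary], face_of_edge[boundary]):
        e = v[j] - v[i]
        elen = np.linalg.norm(e)
        if elen < 1e-14:
            continue
        # plane through the edge, perpendicular to the adjacent face
        n = np.cross(e / elen, face_normals_unit[fid])
        nn = np.linalg.norm(n)
        if nn < 1e-14:
            continue
        n = n / nn
        p = np.append(n, -n @ v[i])
        Kb = np.outer(p, p) * (10.0 * elen**2)  # strong weight: keep boundary crisp
        Q[i] += Kb
        Q[j] += Kb


def _quadric_cost(Q: np.ndarray, x: np.ndarray) -> float:
    h = np.append(x, 1.0)
    return float(h @ Q @ h)


def _optimal_position(Q, pu, pv, max_dist):
    A = Q[:3, :3]
    b = -Q[:3, 3]
    mid = 0.5 * (pu + pv)
    try:
        x = np.linalg.solve(A, b)
        # keep the solve only when well conditioned and local to the edge
        if (
            np.isfinite(x).all()
            and np.dot(x - mid, x - mid) <= max_dist * max_dist
            and np.linalg.cond(A) < 1e7
        ):
            return x, _quadric_cost(Q, x)
    except np.linalg.LinAlgError:
        pass
    best_x, best_c = mid, _quadric_cost(Q, mid)
    for cand in (pu, pv):
        c = _quadric_cost(Q, cand)
        if c < best_c:
            best_x, best_c = cand, c
    return best_x, best_c


def decimate(mesh: SurfaceMesh, target_vertex_count: int) -> SurfaceMesh:
    """Reduce ``mesh`` to ``target_vertex_count`` vertices by edge collapse.

    If the target is not below the current count the input is returned
    unchanged (with a warning when it exceeds it).
    """
    n = mesh.n_vertices
    if target_vertex_count >= n:
        if target_vertex_count > n:
            warnings.warn("decimation target >= current vertex count; returning input unchanged")
        return mesh.copy()
    if target_vertex_count < 4:
        raise ValueError("cannot decimate below 4 vertices")

    pos = mesh.vertices.copy()
    Q = _vertex_quadrics(mesh)
    alive = np.ones(n, dtype=bool)
    max_jump = 4.0 * mesh.mean_edge_length()

    faces = {i: tuple(face) for i, face in enumerate(mesh.faces)}
    vert_faces = [set() for _ in range(n)]
    adj = [set() for _ in range(n)]
    for fid, face in faces.items():
        a, b, c = face
        vert_faces[a].add(fid)
        vert_faces[b].add(fid)
        vert_faces[c].add(fid)
        adj[a].update((b, c))
        adj[b].update((a, c))
        adj[c].update((a, b))

    version = np.zeros(n, dtype=np.int64)
    heap: list = []

    def push(u, w):
        a, b = (u, w) if u < w else (w, u)
        x, cost = _optimal_position(Q[a] + Q[b], pos[a], pos[b], max_jump)
        heapq.heappush(heap, (cost, a, b, version[a], version[b], x))

    for u in range(n):
        for w in adj[u]:
            if u < w:
                push(u, w)

    remaining = n
    while remaining > target_vertex_count and heap:
        cost, u, v, vu, vv, x = heapq.heappop(heap)
        if not (alive[u] and alive[v]) or version[u] != vu or version[v] != vv:
            continue
        if v not in adj[u]:
            continue
        # faces surviving the collapse (those containing u or v but not both)
        dead = vert_faces[u] & vert_faces[v]
        affected = [fid for fid in (vert_faces[u] | vert_faces[v]) if fid not in dead]
        if affected:
            tris = np.array([faces[fid] for fid in affected])
            old = pos[tris]
            new = old.copy()
            hit = (tris == u) | (tris == v)
            new[hit] = x
            n_old = np.cross(old[:, 1] - old[:, 0], old[:, 2] - old[:, 0])
            n_new = np.cross(new[:, 1] - new[:, 0], new[:, 2] - new[:, 0])
            if np.any(np.einsum("ij,ij->i", n_old, n_new) <= 0):
                continue
        # perform collapse: v merges into u at position x
        pos[u] = x
        Q[u] = Q[u] + Q[v]
        alive[v] = False
        for fid in dead:
            for w in faces[fid]:
                vert_faces[w].discard(fid)
            del faces[fid]
        for fid in list(vert_faces[v]):
            face = faces[fid]
            faces[fid] = tuple(u if w == v else w for w in face)
            vert_faces[v].discard(fid)
            vert_faces[u].add(fid)
        # adjacency update
        adj[u].discard(v)
        for w in adj[v]:
            if w != u:
                adj[w].discard(v)
                adj[w].add(u)
                adj[u].add(w)
        adj[v].clear()
        for w in adj[u]:
            adj[w].discard(v)
        remaining -= 1
        version[u] += 1
        for w in adj[u]:
            push(u, w)

    if remaining > target_vertex_count:
        warnings.warn(f"decimation stalled at {remaining} vertices (target {target_vertex_count})")
    out_faces = np.array([list(face) for face in faces.values()], dtype=np.int64)
    return SurfaceMesh(pos, out_faces).remove_unreferenced_vertices()
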