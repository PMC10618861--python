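"""Quadric-error-metric edge-collapse decimation.

A deliberately compact implementation: enough to downsample fixture and
specimen meshes while preserving watertightness and signed volume within a
configurable tolerance. Collapses that would create non-manifold topology
(link-condition violations) or flipped triangles are rejected.
"""

from __future__ import annotations

import heapq

import numpy as np

from .mesh import MeshError, TriMesh, VertebraMesh

__all__ = ["decimate_mesh", "decimate_trimesh"]


def _face_quadrics(V: np.ndarray, F: np.ndarray) -> np.ndarray:
    t = V[F]
    n = np.cross(t[:, 1] - t[:, 0], t[:, 2] - t[:, 0])
    norms = np.linalg.norm(n, axis=1, keepdims=True)
    norms[norms == 0] = 1.0
    n = n / norms
    d = -np.einsum("ij,ij->i", n, t[:, 0])
    p = np.column_stack([n, d])  # plane (a,b,c,d)
    area = 0.5 * norms[:, 0]
    return np.einsum("i,ik,il->ikl", area, p, p)  # (m,4,4), area-weighted


def _collapse_cost(Q: np.ndarray, v: np.ndarray) -> float:
    h = np.append(v, 1.0)
    return float(h @ Q @ h)


def decimate_trimesh(mesh: TriMesh, target_faces: int, volume_tol: float = 0.05) -> TriMesh:
    if target_faces < 4:
        raise ValueError("target_faces must be >= 4 (a closed surface needs >= 4 faces)")
    if len(mesh.faces) <= target_faces:
        return mesh
    if not mesh.is_watertight():
        raise MeshError("decimation requires a watertight input mesh")
    vol0 = mesh.signed_volume()
    V = mesh.vertices.copy()
    F = mesh.faces.copy()
    alive_f = np.ones(len(F), dtype=bool)
    # vertex -> set of incident faces
    vfaces: list[set] = [set() for _ in range(len(V))]
    for fi, f in enumerate(F):
        for vi in f:
            vfaces[vi].add(fi)
    Qf = _face_quadrics(V, F)
    Qv = np.zeros((len(V), 4, 4))
    for fi, f in enumerate(F):
        for vi in f:
            Qv[vi] += Qf[fi]

    def neighbours(v):
        out = set()
        for fi in vfaces[v]:
            out.update(F[fi])
        out.discard(v)
        return out

    def edge_entry(a, b):
        Q = Qv[a] + Qv[b]
        # try the quadric-optimal position, fall back to midpoint/endpoints
        A = Q.copy()
        A[3] = [0, 0, 0, 1]
        candidates = [0.5 * (V[a] + V[b]), V[a], V[b]]
        try:
            opt = np.linalg.solve(A, [0, 0, 0, 1])[:3]
            candidates.insert(0, opt)
        except np.linalg.LinAlgError:
            pass
        costs = [_collapse_cost(Q, c) for c in candidates]
        k = int(np.argmin(costs))
        # short edges first keeps coverage uniform on smooth regions; the
        # quadric term still defers collapses across sharp features
        length2 = float(np.sum((V[a] - V[b]) ** 2))
        return length2 * (1.0 + costs[k]), candidates[k]

    heap = []
    version = {}

    def push(a, b):
        if a > b:
            a, b = b, a
        cost, pos = edge_entry(a, b)
        version[(a, b)] = version.get((a, b), 0) + 1
        heapq.heappush(heap, (cost, version[(a, b)], a, b, pos))

    seen_edges = set()
    for f in F:
        for a, b in ((f[0], f[1]), (f[1], f[2]), (f[2], f[0])):
            key = (min(a, b), max(a, b))
            if key not in seen_edges:
                seen_edges.add(key)
                push(*key)

    n_alive = int(alive_f.sum())
    merged = np.arange(len(V))  # union-find for collapsed vertices

    def find(v):
        while merged[v] != v:
            merged[v] = merged[merged[v]]
            v = merged[v]
        return v

    while n_alive > target_faces and heap:
        cost, ver, a, b, pos = heapq.heappop(heap)
        a, b = find(a), find(b)
        if a == b:
            continue
        key = (min(a, b), max(a, b))
        if version.get(key) != ver:
            continue
        na, nb = neighbours(a), neighbours(b)
        if b not in na:
            continue  # edge no longer exists
        # link condition: shared neighbours must be exactly the two opposite
        # vertices of the edge's two incident faces
        shared_faces = vfaces[a] & vfaces[b]
        if len(shared_faces) != 2:
            continue
        opposite = set()
        for fi in shared_faces:
            opposite.update(int(v) for v in F[fi] if v != a and v != b)
        if (na & nb) != opposite:
            continue
        moved_faces = (vfaces[a] | vfaces[b]) - shared_faces
        # volume-preserving placement (Lindstrom-Turk style): minimize the
        # quadric subject to exact conservation of the enclosed volume
        c6 = 0.0
        for fi in vfaces[a] | vfaces[b]:
            v0, v1, v2 = V[F[fi][0]], V[F[fi][1]], V[F[fi][2]]
            c6 += float(v0 @ np.cross(v1, v2))
        g = np.zeros(3)
        for fi in moved_faces:
            tri = list(F[fi])
            while tri[0] != a and tri[0] != b:
                tri = tri[1:] + tri[:1]
            g += np.cross(V[tri[1]], V[tri[2]])
        Q = Qv[a] + Qv[b]
        K = np.zeros((4, 4))
        K[:3, :3] = Q[:3, :3]
        K[:3, 3] = g / 2.0
        K[3, :3] = g
        rhs = np.concatenate([-Q[:3, 3], [c6]])
        edge_len = np.linalg.norm(V[a] - V[b])
        try:
            cand = np.linalg.solve(K, rhs)[:3]
            if np.linalg.norm(cand - 0.5 * (V[a] + V[b])) < 3.0 * edge_len + 1e-12:
                pos = cand
        except np.linalg.LinAlgError:
            pass
        # geometric guard: no normal flips among surviving faces
        flip = False
        for fi in moved_faces:
            tri_old = V[F[fi]]
            n_old = np.cross(tri_old[1] - tri_old[0], tri_old[2] - tri_old[0])
            tri_new = np.array(
                [pos if find(v) in (a, b) else V[find(v)] for v in F[fi]]
            )
            n_new = np.cross(tri_new[1] - tri_new[0], tri_new[2] - tri_new[0])
            if n_old @ n_new <= 1e-14:
                flip = True
                break
        if flip:
            continue
        # perform collapse: b -> a at pos
        V[a] = pos
        Qv[a] = Qv[a] + Qv[b]
        merged[b] = a
        for fi in shared_faces:
            alive_f[fi] = False
            n_alive -= 1
            for v in F[fi]:
                vfaces[v].discard(fi)
        for fi in list(vfaces[b]):
            F[fi][F[fi] == b] = a
            vfaces[a].add(fi)
            vfaces[b].discard(fi)
        for nb_v in neighbours(a):
            push(min(a, nb_v), max(a, nb_v))

    if n_alive > target_faces:
        raise MeshError(
            f"decimation stalled at {n_alive} faces (target {target_faces}); "
            "remaining collapses would break manifoldness"
        )
    faces = np.array([[find(v) for v in f] for f in F[alive_f]], dtype=np.int64)
    used, inv = np.unique(faces, return_inverse=True)
    out = TriMesh(V[used], inv.reshape(faces.shape))
    if not out.is_watertight():
        raise MeshError("decimation broke watertightness")
    vol1 = out.signed_volume()
    if abs(vol1 - vol0) > volume_tol * abs(vol0):
        raise MeshError(
            f"decimation changed signed volume by {abs(vol1 - vol0) / abs(vol0):.1%} "
            f"(tolerance {volume_tol:.0%})"
        )
    return out


def decimate_mesh(vert: VertebraMesh, target_faces: int, volume_tol: float = 0.05) -> VertebraMesh:
    """Decimate a vertebra, re-mapping facet patches to surviving faces.

    Each original patch face is re-assigned to the nearest surviving face by
    centroid; patch disjointness is preserved by first-come assignment.
    """
    if len(vert.mesh.faces) <= target_faces:
        return vert
    out = decimate_trimesh(vert.mesh, target_faces, volume_tol)
    patches = {}
    if vert.facet_patches:
        from scipy.spatial import cKDTree

        tree = cKDTree(out.face_centroids())
        taken = set()
        old_centroids = vert.mesh.face_centroids()
        for label, idx in vert.facet_patches.items():
            _, nearest = tree.query(old_centroids[idx], workers=1)
            keep = [int(fi) for fi in np.unique(nearest) if fi not in taken]
            taken.update(keep)
            patches[label] = np.array(keep, dtype=np.int64)
    return VertebraMesh(out, vert.name, patches)
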