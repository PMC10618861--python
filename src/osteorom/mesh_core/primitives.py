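"""Canonical closed meshes used by tests, oracles and the fixture generator."""

from __future__ import annotations

import numpy as np

from .mesh import TriMesh

__all__ = ["box", "icosphere", "heightfield_solid"]


def box(extents=(1.0, 1.0, 1.0), center=(0.0, 0.0, 0.0)) -> TriMesh:
    e = np.asarray(extents, dtype=float) / 2.0
    c = np.asarray(center, dtype=float)
    corners = np.array(
        [[sx, sy, sz] for sx in (-1, 1) for sy in (-1, 1) for sz in (-1, 1)],
        dtype=float,
    )
    verts = corners * e + c
    # 12 triangles, outward winding
    faces = np.array(
        [
            [0, 1, 3], [0, 3, 2],  # -x
            [4, 6, 7], [4, 7, 5],  # +x
            [0, 4, 5], [0, 5, 1],  # -y
            [2, 3, 7], [2, 7, 6],  # +y
            [0, 2, 6], [0, 6, 4],  # -z
            [1, 5, 7], [1, 7, 3],  # +z
        ],
        dtype=np.int64,
    )
    return TriMesh(verts, faces)


def icosphere(subdivisions: int = 2, radius: float = 1.0, center=(0.0, 0.0, 0.0)) -> TriMesh:
    phi = (1.0 + np.sqrt(5.0)) / 2.0
    verts = np.array(
        [
            [-1, phi, 0], [1, phi, 0], [-1, -phi, 0], [1, -phi, 0],
            [0, -1, phi], [0, 1, phi], [0, -1, -phi], [0, 1, -phi],
            [phi, 0, -1], [phi, 0, 1], [-phi, 0, -1], [-phi, 0, 1],
        ],
        dtype=float,
    )
    faces = np.array(
        [
            [0, 11, 5], [0, 5, 1], [0, 1, 7], [0, 7, 10], [0, 10, 11],
            [1, 5, 9], [5, 11, 4], [11, 10, 2], [10, 7, 6], [7, 1, 8],
            [3, 9, 4], [3, 4, 2], [3, 2, 6], [3, 6, 8], [3, 8, 9],
            [4, 9, 5], [2, 4, 11], [6, 2, 10], [8, 6, 7], [9, 8, 1],
        ],
        dtype=np.int64,
    )
    for _ in range(subdivisions):
        cache: dict[tuple, int] = {}
        vlist = [v for v in verts]

        def midpoint(i, j):
            key = (min(i, j), max(i, j))
            if key not in cache:
                cache[key] = len(vlist)
                vlist.append(0.5 * (vlist[i] + vlist[j]))
            return cache[key]

        new_faces = []
        for a, b, c in faces:
            ab, bc, ca = midpoint(a, b), midpoint(b, c), midpoint(c, a)
            new_faces += [[a, ab, ca], [b, bc, ab], [c, ca, bc], [ab, bc, ca]]
        verts = np.array(vlist)
        faces = np.array(new_faces, dtype=np.int64)
    verts = verts / np.linalg.norm(verts, axis=1, keepdims=True) * radius
    return TriMesh(verts + np.asarray(center, dtype=float), faces)


def heightfield_solid(
    xs: np.ndarray,
    zs: np.ndarray,
    top_y: np.ndarray,
    bottom_y: np.ndarray,
) -> tuple[TriMesh, np.ndarray, np.ndarray]:
    """Closed solid between two y-height fields on a rectangular (x, z) grid.

    ``top_y``/``bottom_y`` are (len(xs), len(zs)) arrays (scalars broadcast)
    with top > bottom everywhere. Returns (mesh, top_face_ids,
    bottom_face_ids) so callers can label the curved surfaces (facet
    patches).
    """
    xs = np.asarray(xs, dtype=float)
    zs = np.asarray(zs, dtype=float)
    nx, nz = len(xs), len(zs)
    gx, gz = np.meshgrid(xs, zs, indexing="ij")
    top = np.broadcast_to(np.asarray(top_y, dtype=float), (nx, nz))
    bot = np.broadcast_to(np.asarray(bottom_y, dtype=float), (nx, nz))
    if not np.all(top > bot):
        raise ValueError("heightfield_solid: top surface must lie above bottom")

    def vid(i, k, layer):  # layer 0 = top, 1 = bottom
        return layer * nx * nz + i * nz + k

    verts = np.concatenate(
        [
            np.column_stack([gx.ravel(), top.ravel(), gz.ravel()]),
            np.column_stack([gx.ravel(), bot.ravel(), gz.ravel()]),
        ]
    )
    faces = []
    top_ids, bot_ids = [], []
    for i in range(nx - 1):
        for k in range(nz - 1):
            a, b, c, d = vid(i, k, 0), vid(i + 1, k, 0), vid(i + 1, k + 1, 0), vid(i, k + 1, 0)
            # top: outward normal +y
            top_ids += [len(faces), len(faces) + 1]
            faces += [[a, c, b], [a, d, c]]
            a, b, c, d = vid(i, k, 1), vid(i + 1, k, 1), vid(i + 1, k + 1, 1), vid(i, k + 1, 1)
            bot_ids += [len(faces), len(faces) + 1]
            faces += [[a, b, c], [a, c, d]]
    # side walls along the four perimeter strips
    for i in range(nx - 1):
        t0, t1 = vid(i, 0, 0), vid(i + 1, 0, 0)
        b0, b1 = vid(i, 0, 1), vid(i + 1, 0, 1)
        faces += [[t0, t1, b1], [t0, b1, b0]]
        t0, t1 = vid(i, nz - 1, 0), vid(i + 1, nz - 1, 0)
        b0, b1 = vid(i, nz - 1, 1), vid(i + 1, nz - 1, 1)
        faces += [[t0, b1, t1], [t0, b0, b1]]
    for k in range(nz - 1):
        t0, t1 = vid(0, k, 0), vid(0, k + 1, 0)
        b0, b1 = vid(0, k, 1), vid(0, k + 1, 1)
        faces += [[t0, b1, t1], [t0, b0, b1]]
        t0, t1 = vid(nx - 1, k, 0), vid(nx - 1, k + 1, 0)
        b0, b1 = vid(nx - 1, k, 1), vid(nx - 1, k + 1, 1)
        faces += [[t0, t1, b1], [t0, b1, b0]]
    mesh = TriMesh(verts, np.array(faces, dtype=np.int64))
    if mesh.signed_volume() < 0:  # fix handedness once, keeping ids aligned
        mesh = TriMesh(mesh.vertices, mesh.faces[:, ::-1])
    return mesh, np.array(top_ids, dtype=np.int64), np.array(bot_ids, dtype=np.int64)
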