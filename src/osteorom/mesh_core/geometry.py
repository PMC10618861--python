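"""Geometric primitives shared across modules: sphere fitting and patch
extrusion."""

from __future__ import annotations

import numpy as np

from .mesh import FacetPatch, MeshError, TriMesh

__all__ = ["SphereFit", "fit_sphere", "extrude_patch"]


class SphereFit:
    """Result of a least-squares sphere fit."""

    __slots__ = ("center", "radius", "rms")

    def __init__(self, center: np.ndarray, radius: float, rms: float):
        self.center = center
        self.radius = radius
        self.rms = rms

    def __repr__(self):
        return f"SphereFit(center={self.center!r}, radius={self.radius:.6g}, rms={self.rms:.3g})"


def fit_sphere(points: np.ndarray) -> SphereFit:
    """Algebraic (linear least-squares) sphere fit.

    Solves |p|^2 = 2 c·p + (r^2 - |c|^2) for (c, r). Deterministic, needs no
    initialization; raises on fewer than 4 points or a coplanar point set
    (the sphere is then under-determined).
    """
    points = np.asarray(points, dtype=float)
    if points.ndim != 2 or points.shape[1] != 3:
        raise ValueError("points must be (n, 3)")
    if len(points) < 4:
        raise ValueError(f"sphere fit needs >= 4 points, got {len(points)}")
    centered = points - points.mean(axis=0)
    sv = np.linalg.svd(centered, compute_uv=False)
    if sv[-1] < 1e-9 * max(sv[0], 1e-30):
        raise ValueError("sphere fit under-determined: points are (near-)coplanar")
    A = np.column_stack([2.0 * points, np.ones(len(points))])
    b = np.einsum("ij,ij->i", points, points)
    sol, *_ = np.linalg.lstsq(A, b, rcond=None)
    center = sol[:3]
    radius = float(np.sqrt(sol[3] + center @ center))
    resid = np.linalg.norm(points - center, axis=1) - radius
    return SphereFit(center, radius, float(np.sqrt(np.mean(resid**2))))


def _patch_boundary_directed(faces: np.ndarray) -> np.ndarray:
    """Directed boundary edges of a face subset, in the subset's winding."""
    de = np.concatenate([faces[:, [0, 1]], faces[:, [1, 2]], faces[:, [2, 0]]])
    und = np.sort(de, axis=1)
    uniq, inverse, counts = np.unique(und, axis=0, return_inverse=True, return_counts=True)
    return de[(counts == 1)[inverse]]


def extrude_patch(patch: FacetPatch, direction: np.ndarray, distance: float) -> TriMesh:
    """Extrude a facet patch into a closed prism along ``direction``.

    The patch surface forms the (flipped) base, its translated copy the top,
    and boundary-edge quads the walls; for a near-planar patch the signed
    volume is ~ patch area x distance. Used to build the articulation gap
    volumes that replace the paper's manual facet-duplication step.
    """
    if distance <= 0:
        raise ValueError("extrusion distance must be > 0")
    direction = np.asarray(direction, dtype=float)
    nrm = np.linalg.norm(direction)
    if nrm == 0:
        raise ValueError("extrusion direction must be nonzero")
    direction = direction / nrm
    if patch.area <= 0:
        raise MeshError("cannot extrude a zero-area patch")
    faces = patch.mesh.faces[patch.faces]
    used, inv = np.unique(faces, return_inverse=True)
    local = inv.reshape(faces.shape)
    bottom_v = patch.mesh.vertices[used]
    top_v = bottom_v + direction * distance
    nv = len(used)
    vertices = np.concatenate([bottom_v, top_v])
    bottom_faces = local[:, ::-1]  # flipped: outward normal opposes extrusion
    top_faces = local + nv
    remap = np.full(used.max() + 1, -1, dtype=np.int64)
    remap[used] = np.arange(nv)
    boundary = remap[_patch_boundary_directed(faces)]
    walls = []
    for a, b in boundary:
        walls.append([a, b, b + nv])
        walls.append([a, b + nv, a + nv])
    prism = TriMesh(vertices, np.concatenate([bottom_faces, top_faces, np.array(walls)]))
    if not prism.is_watertight():
        raise MeshError("patch extrusion produced a non-watertight prism")
    if prism.signed_volume() < 0:
        prism = TriMesh(prism.vertices, prism.faces[:, ::-1])
    return prism
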