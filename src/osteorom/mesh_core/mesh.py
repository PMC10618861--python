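"""Triangle-mesh containers, topology validation and repair.

Everything downstream (chain building, pose sweeps, articulation volumes)
assumes the invariants enforced here: meshes are manifold, watertight and
consistently outward-wound (signed volume > 0). Vertebra meshes may consist
of several closed components; each component must satisfy the invariants.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "MeshError",
    "MeshValidationError",
    "TriMesh",
    "FacetPatch",
    "VertebraMesh",
    "PATCH_LABELS",
    "merge_meshes",
]

PATCH_LABELS = ("left_pre", "right_pre", "left_post", "right_post")


class MeshError(ValueError):
    pass


class MeshValidationError(MeshError):
    """Raised when a mesh fails manifoldness/watertightness validation.

    Carries a ``report`` dict with defect counts and offending entities.
    """

    def __init__(self, message: str, report: dict | None = None):
        super().__init__(message)
        self.report = report or {}


@dataclass
class TriMesh:
    vertices: np.ndarray  # (n, 3) float64, millimetres
    faces: np.ndarray  # (m, 3) int

    def __post_init__(self):
        self.vertices = np.ascontiguousarray(self.vertices, dtype=float)
        self.faces = np.ascontiguousarray(self.faces, dtype=np.int64)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 3:
            raise MeshError("vertices must be (n, 3)")
        if self.faces.ndim != 2 or self.faces.shape[1] != 3:
            raise MeshError("faces must be (m, 3)")
        if len(self.faces) and self.faces.max() >= len(self.vertices):
            raise MeshError("face index out of range")

    # -- basic quantities -------------------------------------------------

    @property
    def triangles(self) -> np.ndarray:
        return self.vertices[self.faces]

    def face_normals(self, normalized: bool = True) -> np.ndarray:
        t = self.triangles
        n = np.cross(t[:, 1] - t[:, 0], t[:, 2] - t[:, 0])
        if normalized:
            lens = np.linalg.norm(n, axis=1, keepdims=True)
            lens[lens == 0] = 1.0
            n = n / lens
        return n

    def face_areas(self) -> np.ndarray:
        t = self.triangles
        return 0.5 * np.linalg.norm(np.cross(t[:, 1] - t[:, 0], t[:, 2] - t[:, 0]), axis=1)

    def face_centroids(self) -> np.ndarray:
        return self.triangles.mean(axis=1)

    def area(self) -> float:
        return float(self.face_areas().sum())

    def signed_volume(self) -> float:
        t = self.triangles
        return float(np.einsum("ij,ij->i", t[:, 0], np.cross(t[:, 1], t[:, 2])).sum() / 6.0)

    def bounds(self) -> np.ndarray:
        return np.array([self.vertices.min(axis=0), self.vertices.max(axis=0)])

    # -- topology ---------------------------------------------------------

    def directed_edges(self) -> np.ndarray:
        f = self.faces
        return np.concatenate([f[:, [0, 1]], f[:, [1, 2]], f[:, [2, 0]]])

    def edge_report(self) -> dict:
        """Count how often each undirected edge is used and by which sign."""
        de = self.directed_edges()
        und = np.sort(de, axis=1)
        uniq, inverse, counts = np.unique(und, axis=0, return_inverse=True, return_counts=True)
        boundary = uniq[counts == 1]
        nonmanifold = uniq[counts > 2]
        # orientation consistency: an interior edge must appear once per direction
        flipped = de[:, 0] > de[:, 1]
        dir_count = np.zeros(len(uniq))
        np.add.at(dir_count, inverse, np.where(flipped, -1.0, 1.0))
        inconsistent = uniq[(counts == 2) & (dir_count != 0)]
        return {
            "boundary_edges": boundary,
            "nonmanifold_edges": nonmanifold,
            "inconsistent_edges": inconsistent,
        }

    def is_watertight(self) -> bool:
        rep = self.edge_report()
        return (
            len(rep["boundary_edges"]) == 0
            and len(rep["nonmanifold_edges"]) == 0
            and len(rep["inconsistent_edges"]) == 0
        )

    def face_components(self) -> np.ndarray:
        """Label faces by vertex-connected component."""
        from scipy.sparse import coo_matrix
        from scipy.sparse.csgraph import connected_components

        n = len(self.vertices)
        f = self.faces
        rows = np.concatenate([f[:, 0], f[:, 1], f[:, 2]])
        cols = np.concatenate([f[:, 1], f[:, 2], f[:, 0]])
        g = coo_matrix((np.ones(len(rows)), (rows, cols)), shape=(n, n))
        _, vlabel = connected_components(g, directed=False)
        return vlabel[f[:, 0]]

    # -- repair -----------------------------------------------------------

    def oriented(self) -> "TriMesh":
        """Return a copy with consistent winding and outward normals.

        Winding is propagated across shared edges per connected component;
        each closed component is then flipped if its signed volume is
        negative.
        """
        faces = self.faces.copy()
        m = len(faces)
        # map undirected edge -> incident faces
        de = np.concatenate([faces[:, [0, 1]], faces[:, [1, 2]], faces[:, [2, 0]]])
        face_of = np.tile(np.arange(m), 3)
        und = np.sort(de, axis=1)
        order = np.lexsort((und[:, 1], und[:, 0]))
        und_s, de_s, fo_s = und[order], de[order], face_of[order]
        # group boundaries
        new_edge = np.any(np.diff(und_s, axis=0) != 0, axis=1)
        starts = np.concatenate([[0], np.nonzero(new_edge)[0] + 1, [len(und_s)]])
        adj: list[list[tuple[int, bool]]] = [[] for _ in range(m)]
        for a, b in zip(starts[:-1], starts[1:]):
            if b - a != 2:
                continue
            f1, f2 = fo_s[a], fo_s[a + 1]
            same_dir = np.array_equal(de_s[a], de_s[a + 1])
            adj[f1].append((f2, same_dir))
            adj[f2].append((f1, same_dir))
        flip = np.zeros(m, dtype=bool)
        seen = np.zeros(m, dtype=bool)
        for seed in range(m):
            if seen[seed]:
                continue
            stack = [seed]
            seen[seed] = True
            while stack:
                f = stack.pop()
                for g, same_dir in adj[f]:
                    # consistently wound neighbours traverse a shared edge in
                    # opposite directions
                    want = flip[f] ^ same_dir
                    if not seen[g]:
                        flip[g] = want
                        seen[g] = True
                        stack.append(g)
        faces[flip] = faces[flip][:, ::-1]
        out = TriMesh(self.vertices.copy(), faces)
        comp = out.face_components()
        for c in np.unique(comp):
            sel = comp == c
            sub = TriMesh(out.vertices, out.faces[sel])
            if sub.signed_volume() < 0:
                out.faces[sel] = out.faces[sel][:, ::-1]
        return out

    def boundary_loops(self) -> list[np.ndarray]:
        rep = self.edge_report()
        b = rep["boundary_edges"]
        if len(b) == 0:
            return []
        # recover directed boundary edges (the single use direction, reversed
        # to walk the hole with outward-consistent winding)
        de = self.directed_edges()
        und = np.sort(de, axis=1)
        uniq, counts = np.unique(und, axis=0, return_counts=True)
        single = {tuple(e) for e, c in zip(uniq, counts) if c == 1}
        nxt: dict[int, int] = {}
        for a, b2 in de:
            if (min(a, b2), max(a, b2)) in single:
                nxt[int(b2)] = int(a)
        loops = []
        while nxt:
            start, cur = next(iter(nxt.items()))
            loop = [start]
            while cur != start:
                loop.append(cur)
                cur = nxt.pop(cur)
            nxt.pop(start, None)
            loops.append(np.array(loop))
        return loops

    def fill_holes(self, max_boundary_edges: int = 100) -> "TriMesh":
        """Fan-fill boundary loops shorter than ``max_boundary_edges``."""
        loops = self.boundary_loops()
        if not loops:
            return self
        new_faces = [self.faces]
        for loop in loops:
            if len(loop) > max_boundary_edges:
                raise MeshValidationError(
                    f"hole with {len(loop)} boundary edges exceeds repair limit "
                    f"{max_boundary_edges}",
                    {"boundary_edges": len(loop)},
                )
            fan = np.column_stack(
                [np.full(len(loop) - 2, loop[0]), loop[1:-1], loop[2:]]
            )
            new_faces.append(fan)
        return TriMesh(self.vertices.copy(), np.concatenate(new_faces))

    def validate(
        self,
        repair: bool = True,
        max_boundary_edges: int = 100,
        check_self_intersections: bool = False,
    ) -> "TriMesh":
        """Return a repaired mesh satisfying the invariants, or raise.

        Small holes are fan-filled (when ``repair``), winding is made
        consistent and outward. Non-manifold edges are never repaired.
        """
        mesh = self
        rep = mesh.edge_report()
        if len(rep["nonmanifold_edges"]):
            raise MeshValidationError(
                f"{len(rep['nonmanifold_edges'])} non-manifold edges",
                {k: len(v) for k, v in rep.items()},
            )
        if len(rep["boundary_edges"]):
            if not repair:
                raise MeshValidationError(
                    f"{len(rep['boundary_edges'])} boundary edges (mesh not closed)",
                    {k: len(v) for k, v in rep.items()},
                )
            mesh = mesh.fill_holes(max_boundary_edges)
        mesh = mesh.oriented()
        rep = mesh.edge_report()
        if any(len(v) for v in rep.values()):
            raise MeshValidationError(
                "mesh not watertight after repair",
                {k: len(v) for k, v in rep.items()},
            )
        if mesh.signed_volume() <= 0:
            raise MeshValidationError("non-positive signed volume after orientation")
        from ..collision import cross_component_intersections, self_intersections

        bad = cross_component_intersections(mesh)
        if bad:
            raise MeshValidationError(
                f"{bad} intersecting face pairs between components"
            )
        if check_self_intersections:
            bad = self_intersections(mesh)
            if bad:
                raise MeshValidationError(f"{bad} self-intersecting face pairs")
        return mesh

    def transformed(self, T: np.ndarray) -> "TriMesh":
        from ..transforms import apply_transform

        return TriMesh(apply_transform(T, self.vertices), self.faces.copy())

    def copy(self) -> "TriMesh":
        return TriMesh(self.vertices.copy(), self.faces.copy())

    def submesh(self, face_indices: np.ndarray) -> "TriMesh":
        """Extract faces (re-indexing vertices)."""
        faces = self.faces[np.asarray(face_indices, dtype=int)]
        used, inv = np.unique(faces, return_inverse=True)
        return TriMesh(self.vertices[used], inv.reshape(faces.shape))


def merge_meshes(meshes: list[TriMesh]) -> TriMesh:
    """Disjoint union (vertex blocks concatenated, faces offset)."""
    vs, fs, off = [], [], 0
    for m in meshes:
        vs.append(m.vertices)
        fs.append(m.faces + off)
        off += len(m.vertices)
    return TriMesh(np.concatenate(vs), np.concatenate(fs))


@dataclass
class FacetPatch:
    """A labelled subset of a vertebra's faces (one zygapophyseal facet)."""

    parent: str
    side: str  # "left" | "right"
    kind: str  # "pre" | "post"
    faces: np.ndarray  # indices into the parent mesh's face array
    mesh: TriMesh  # parent mesh (shared, not copied)

    def __post_init__(self):
        self.faces = np.asarray(self.faces, dtype=np.int64)
        if len(self.faces) == 0:
            raise MeshError(f"empty facet patch {self.label}")

    @property
    def label(self) -> str:
        return f"{self.side}_{self.kind}"

    @property
    def triangles(self) -> np.ndarray:
        return self.mesh.vertices[self.mesh.faces[self.faces]]

    def vertex_indices(self) -> np.ndarray:
        return np.unique(self.mesh.faces[self.faces])

    @property
    def vertices(self) -> np.ndarray:
        return self.mesh.vertices[self.vertex_indices()]

    @property
    def area(self) -> float:
        t = self.triangles
        return float(
            0.5 * np.linalg.norm(np.cross(t[:, 1] - t[:, 0], t[:, 2] - t[:, 0]), axis=1).sum()
        )

    @property
    def centroid(self) -> np.ndarray:
        """Area-weighted centroid of the patch surface."""
        t = self.triangles
        a = 0.5 * np.linalg.norm(np.cross(t[:, 1] - t[:, 0], t[:, 2] - t[:, 0]), axis=1)
        return (t.mean(axis=1) * a[:, None]).sum(axis=0) / a.sum()

    @property
    def mean_normal(self) -> np.ndarray:
        """Area-weighted unit mean normal of the patch."""
        t = self.triangles
        n = np.cross(t[:, 1] - t[:, 0], t[:, 2] - t[:, 0]).sum(axis=0)
        norm = np.linalg.norm(n)
        if norm == 0:
            raise MeshError(f"degenerate facet patch {self.label}")
        return n / norm


@dataclass
class VertebraMesh:
    """A vertebra: closed triangle mesh plus labelled facet patches.

    ``facet_patches`` maps labels in ``PATCH_LABELS`` to face-index arrays.
    Terminal vertebrae may lack pre- or post-patches.
    """

    mesh: TriMesh
    name: str = "vertebra"
    facet_patches: dict = field(default_factory=dict)

    def __post_init__(self):
        nfaces = len(self.mesh.faces)
        seen = np.zeros(nfaces, dtype=bool)
        for label, idx in list(self.facet_patches.items()):
            if label not in PATCH_LABELS:
                raise MeshError(f"unknown facet patch label {label!r}")
            idx = np.asarray(idx, dtype=np.int64)
            if len(idx) == 0:
                raise MeshError(f"facet patch {label} is empty")
            if idx.min() < 0 or idx.max() >= nfaces:
                raise MeshError(f"facet patch {label} has out-of-range face indices")
            if seen[idx].any():
                raise MeshError(f"facet patch {label} overlaps another patch")
            seen[idx] = True
            self.facet_patches[label] = idx

    def patch(self, label: str) -> FacetPatch:
        if label not in self.facet_patches:
            raise KeyError(f"vertebra {self.name!r} has no facet patch {label!r}")
        side, kind = label.split("_")
        return FacetPatch(self.name, side, kind, self.facet_patches[label], self.mesh)

    def has_patch(self, label: str) -> bool:
        return label in self.facet_patches

    def transformed(self, T: np.ndarray) -> "VertebraMesh":
        return VertebraMesh(
            self.mesh.transformed(T),
            self.name,
            {k: v.copy() for k, v in self.facet_patches.items()},
        )

    def copy(self) -> "VertebraMesh":
        return VertebraMesh(
            self.mesh.copy(), self.name, {k: v.copy() for k, v in self.facet_patches.items()}
        )
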