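"""OBJ / PLY / STL reading and writing, plus facet-annotation sidecars.

Only the geometry channels are handled (vertices + triangular faces);
normals, texture coordinates and colours are ignored on read and not
written. PLY is read in ascii and binary little/big-endian form and written
as ascii so artifacts stay text-only.
"""

from __future__ import annotations

import json
import struct
from pathlib import Path

import numpy as np
import yaml

from .mesh import MeshError, TriMesh, VertebraMesh

__all__ = [
    "read_mesh",
    "write_mesh",
    "load_mesh",
    "save_vertebra",
    "load_annotations",
    "save_annotations",
]


# -- OBJ --------------------------------------------------------------------


def _read_obj(path: Path) -> TriMesh:
    verts, faces = [], []
    with open(path) as fh:
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            if parts[0] == "v":
                verts.append([float(x) for x in parts[1:4]])
            elif parts[0] == "f":
                idx = [int(tok.split("/")[0]) for tok in parts[1:]]
                idx = [i - 1 if i > 0 else len(verts) + i for i in idx]
                for k in range(1, len(idx) - 1):  # fan-triangulate polygons
                    faces.append([idx[0], idx[k], idx[k + 1]])
    if not verts:
        raise MeshError(f"no vertices in {path}")
    return TriMesh(np.array(verts), np.array(faces, dtype=np.int64))


def _write_obj(mesh: TriMesh, path: Path) -> None:
    with open(path, "w") as fh:
        fh.write("# osteorom OBJ export\n")
        for v in mesh.vertices:
            fh.write(f"v {v[0]:.9g} {v[1]:.9g} {v[2]:.9g}\n")
        for f in mesh.faces:
            fh.write(f"f {f[0] + 1} {f[1] + 1} {f[2] + 1}\n")


# -- PLY --------------------------------------------------------------------

_PLY_TYPES = {
    "char": "i1", "uchar": "u1", "int8": "i1", "uint8": "u1",
    "short": "i2", "ushort": "u2", "int16": "i2", "uint16": "u2",
    "int": "i4", "uint": "u4", "int32": "i4", "uint32": "u4",
    "float": "f4", "float32": "f4", "double": "f8", "float64": "f8",
}


def _read_ply(path: Path) -> TriMesh:
    with open(path, "rb") as fh:
        if fh.readline().strip() != b"ply":
            raise MeshError(f"{path} is not a PLY file")
        fmt = None
        elements = []  # (name, count, [(prop_name, dtype) or ("list", idx_t, val_t, name)])
        while True:
            line = fh.readline()
            if not line:
                raise MeshError("unexpected end of PLY header")
            tok = line.decode("ascii", "replace").split()
            if not tok:
                continue
            if tok[0] == "format":
                fmt = tok[1]
            elif tok[0] == "element":
                elements.append((tok[1], int(tok[2]), []))
            elif tok[0] == "property":
                if tok[1] == "list":
                    elements[-1][2].append(("list", tok[2], tok[3], tok[4]))
                else:
                    elements[-1][2].append((tok[2], tok[1]))
            elif tok[0] == "end_header":
                break
        verts = faces = None
        if fmt == "ascii":
            for name, count, props in elements:
                rows = [fh.readline().split() for _ in range(count)]
                if name == "vertex":
                    cols = [p[0] for p in props]
                    arr = np.array(rows, dtype=float)
                    verts = arr[:, [cols.index("x"), cols.index("y"), cols.index("z")]]
                elif name == "face":
                    faces = []
                    for r in rows:
                        n = int(r[0])
                        poly = [int(x) for x in r[1 : 1 + n]]
                        for k in range(1, n - 1):
                            faces.append([poly[0], poly[k], poly[k + 1]])
                    faces = np.array(faces, dtype=np.int64)
        else:
            endian = "<" if "little" in fmt else ">"
            for name, count, props in elements:
                if name == "vertex":
                    dt = np.dtype([(p[0], endian + _PLY_TYPES[p[1]]) for p in props])
                    arr = np.frombuffer(fh.read(dt.itemsize * count), dtype=dt)
                    verts = np.column_stack([arr["x"], arr["y"], arr["z"]]).astype(float)
                elif name == "face":
                    faces = []
                    for p in props:
                        if p[0] != "list":
                            raise MeshError("unsupported scalar face property")
                        idx_t = endian + _PLY_TYPES[p[1]]
                        val_t = endian + _PLY_TYPES[p[2]]
                        idx_size = np.dtype(idx_t).itemsize
                        val_size = np.dtype(val_t).itemsize
                        for _ in range(count):
                            n = int(np.frombuffer(fh.read(idx_size), dtype=idx_t)[0])
                            poly = np.frombuffer(fh.read(val_size * n), dtype=val_t)
                            for k in range(1, n - 1):
                                faces.append([poly[0], poly[k], poly[k + 1]])
                    faces = np.array(faces, dtype=np.int64)
                else:  # skip unknown fixed-size elements
                    row = sum(np.dtype(endian + _PLY_TYPES[p[1]]).itemsize for p in props if p[0] != "list")
                    fh.read(row * count)
        if verts is None or faces is None:
            raise MeshError(f"PLY {path} lacks vertex or face element")
        return TriMesh(verts, faces)


def _write_ply(mesh: TriMesh, path: Path) -> None:
    with open(path, "w") as fh:
        fh.write("ply\nformat ascii 1.0\ncomment osteorom export\n")
        fh.write(f"element vertex {len(mesh.vertices)}\n")
        fh.write("property double x\nproperty double y\nproperty double z\n")
        fh.write(f"element face {len(mesh.faces)}\n")
        fh.write("property list uchar int vertex_indices\nend_header\n")
        for v in mesh.vertices:
            fh.write(f"{v[0]:.17g} {v[1]:.17g} {v[2]:.17g}\n")
        for f in mesh.faces:
            fh.write(f"3 {f[0]} {f[1]} {f[2]}\n")


# -- STL --------------------------------------------------------------------


def _weld(tri_soup: np.ndarray) -> TriMesh:
    flat = tri_soup.reshape(-1, 3)
    uniq, inv = np.unique(flat.round(decimals=9), axis=0, return_inverse=True)
    return TriMesh(uniq, inv.reshape(-1, 3).astype(np.int64))


def _read_stl(path: Path) -> TriMesh:
    raw = open(path, "rb").read()
    if raw[:5] == b"solid" and b"facet" in raw[:500]:
        tris = []
        cur = []
        for line in raw.decode("ascii", "replace").splitlines():
            tok = line.split()
            if tok[:1] == ["vertex"]:
                cur.append([float(x) for x in tok[1:4]])
                if len(cur) == 3:
                    tris.append(cur)
                    cur = []
        return _weld(np.array(tris))
    n = struct.unpack("<I", raw[80:84])[0]
    dt = np.dtype([("n", "<f4", 3), ("v", "<f4", (3, 3)), ("attr", "<u2")])
    rec = np.frombuffer(raw[84 : 84 + n * dt.itemsize], dtype=dt)
    return _weld(rec["v"].astype(float))


def _write_stl(mesh: TriMesh, path: Path) -> None:
    normals = mesh.face_normals()
    with open(path, "w") as fh:
        fh.write("solid osteorom\n")
        for n, t in zip(normals, mesh.triangles):
            fh.write(f"facet normal {n[0]:.9g} {n[1]:.9g} {n[2]:.9g}\n outer loop\n")
            for v in t:
                fh.write(f"  vertex {v[0]:.9g} {v[1]:.9g} {v[2]:.9g}\n")
            fh.write(" endloop\nendfacet\n")
        fh.write("endsolid osteorom\n")


_READERS = {".obj": _read_obj, ".ply": _read_ply, ".stl": _read_stl}
_WRITERS = {".obj": _write_obj, ".ply": _write_ply, ".stl": _write_stl}


def read_mesh(path) -> TriMesh:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    ext = path.suffix.lower()
    if ext not in _READERS:
        raise MeshError(f"unsupported mesh format {ext!r} (OBJ, PLY, STL supported)")
    return _READERS[ext](path)


def write_mesh(mesh: TriMesh, path) -> None:
    path = Path(path)
    ext = path.suffix.lower()
    if ext not in _WRITERS:
        raise MeshError(f"unsupported mesh format {ext!r}")
    _WRITERS[ext](mesh, path)


# -- annotation sidecars -----------------------------------------------------


def load_annotations(path) -> dict:
    """Load a {patch label -> face index list} sidecar (YAML or JSON)."""
    path = Path(path)
    with open(path) as fh:
        data = json.load(fh) if path.suffix.lower() == ".json" else yaml.safe_load(fh)
    return {str(k): np.asarray(v, dtype=np.int64) for k, v in data.items()}


def save_annotations(patches: dict, path) -> None:
    path = Path(path)
    data = {k: [int(i) for i in v] for k, v in patches.items()}
    with open(path, "w") as fh:
        if path.suffix.lower() == ".json":
            json.dump(data, fh)
        else:
            yaml.safe_dump(data, fh)


def _sidecar_for(path: Path) -> Path | None:
    for suffix in (".patches.yaml", ".patches.yml", ".patches.json"):
        cand = path.with_suffix(suffix)
        if cand.exists():
            return cand
    return None


def load_mesh(
    path,
    validate: bool = True,
    name: str | None = None,
    annotations=None,
    max_boundary_edges: int = 100,
) -> VertebraMesh:
    """Load a vertebra mesh with optional validation and facet annotations.

    When ``validate`` is set the mesh is repaired (small holes filled,
    winding fixed) and checked for manifoldness/watertightness; defects
    beyond repair raise MeshValidationError with counts. Facet patches are
    taken from ``annotations`` (path or dict) or a ``<stem>.patches.yaml``
    sidecar when present.
    """
    path = Path(path)
    mesh = read_mesh(path)
    if validate:
        mesh = mesh.validate(max_boundary_edges=max_boundary_edges)
    if annotations is None:
        sidecar = _sidecar_for(path)
        patches = load_annotations(sidecar) if sidecar else {}
    elif isinstance(annotations, (str, Path)):
        patches = load_annotations(annotations)
    else:
        patches = dict(annotations)
    return VertebraMesh(mesh, name or path.stem, patches)


def save_vertebra(vert: VertebraMesh, mesh_path, annotation_path=None) -> None:
    write_mesh(vert.mesh, mesh_path)
    if annotation_path is None:
        annotation_path = Path(mesh_path).with_suffix(".patches.yaml")
    save_annotations(vert.facet_patches, annotation_path)
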