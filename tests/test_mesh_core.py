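import numpy as np
import pytest

from osteorom import transforms as tf
from osteorom.mesh_core import (
    FacetPatch,
    MeshValidationError,
    TriMesh,
    decimate_mesh,
    decimate_trimesh,
    extrude_patch,
    fit_sphere,
    load_mesh,
    primitives,
    read_mesh,
    save_vertebra,
    write_mesh,
)


class TestIO:
    def test_unit_cube_obj(self, tmp_path):
        path = tmp_path / "cube.obj"
        write_mesh(primitives.box(), path)
        vert = load_mesh(path, validate=True)
        assert len(vert.mesh.vertices) == 8
        assert len(vert.mesh.faces) == 12
        assert vert.mesh.is_watertight()
        assert vert.mesh.signed_volume() == pytest.approx(1.0)

    def test_cube_missing_face_reports_boundary_edges(self, tmp_path):
        cube = primitives.box()
        broken = TriMesh(cube.vertices, cube.faces[:-1])
        path = tmp_path / "broken.obj"
        write_mesh(broken, path)
        with pytest.raises(MeshValidationError) as err:
            read_mesh(path).validate(repair=False)
        assert err.value.report["boundary_edges"] == 3  # one triangle leaves 3 open edges
        # a full missing quad (two triangles) leaves the 4 boundary edges
        broken4 = TriMesh(cube.vertices, cube.faces[:-2])
        with pytest.raises(MeshValidationError) as err:
            broken4.validate(repair=False)
        assert err.value.report["boundary_edges"] == 4

    def test_hole_filling_repairs_small_holes(self):
        cube = primitives.box()
        broken = TriMesh(cube.vertices, cube.faces[:-2])
        repaired = broken.validate(repair=True)
        assert repaired.is_watertight()
        assert repaired.signed_volume() == pytest.approx(1.0)

    @pytest.mark.parametrize("ext", ["ply", "obj", "stl"])
    def test_roundtrip_preserves_volume(self, tmp_path, default_vertebra, ext):
        vert, _ = default_vertebra
        path = tmp_path / f"v.{ext}"
        write_mesh(vert.mesh, path)
        back = read_mesh(path)
        if ext != "stl":  # STL welds vertices, count not preserved
            assert len(back.vertices) == len(vert.mesh.vertices)
        assert back.signed_volume() == pytest.approx(vert.mesh.signed_volume(), rel=1e-6)

    def test_obj_ply_topology_roundtrip(self, tmp_path, default_vertebra):
        vert, _ = default_vertebra
        p1, p2 = tmp_path / "v.obj", tmp_path / "v.ply"
        write_mesh(vert.mesh, p1)
        m1 = read_mesh(p1)
        write_mesh(m1, p2)
        m2 = read_mesh(p2)
        assert np.array_equal(m1.faces, m2.faces)
        assert m2.signed_volume() == pytest.approx(vert.mesh.signed_volume(), rel=1e-6)

    def test_annotation_sidecar_roundtrip(self, tmp_path, default_vertebra):
        vert, _ = default_vertebra
        save_vertebra(vert, tmp_path / "v.ply")
        back = load_mesh(tmp_path / "v.ply")
        assert set(back.facet_patches) == set(vert.facet_patches)
        for label in vert.facet_patches:
            assert np.array_equal(back.facet_patches[label], vert.facet_patches[label])

    def test_unreadable_file(self, tmp_path):
        with pytest.raises(FileNotFoundError):
            load_mesh(tmp_path / "nope.ply")


class TestDecimate:
    def test_icosphere_volume_preserved(self):
        ico = primitives.icosphere(3)
        out = decimate_trimesh(ico, 320)
        assert len(out.faces) <= 320
        assert out.is_watertight()
        assert abs(out.signed_volume() - ico.signed_volume()) < 0.05 * ico.signed_volume()

    def test_below_target_is_noop(self):
        ico = primitives.icosphere(1)
        assert decimate_trimesh(ico, 1000) is ico

    def test_target_too_small_errors(self):
        with pytest.raises(ValueError):
            decimate_trimesh(primitives.icosphere(1), 3)

    def test_patch_remap(self, default_vertebra):
        vert, _ = default_vertebra
        out = decimate_mesh(vert, len(vert.mesh.faces) // 2)
        assert len(out.mesh.faces) <= len(vert.mesh.faces) // 2
        seen = set()
        for label, idx in out.facet_patches.items():
            assert len(idx) > 0
            assert not seen & set(idx.tolist())
            seen.update(idx.tolist())
            # remapped patch stays near the original patch centroid
            d = np.linalg.norm(
                out.patch(label).centroid - vert.patch(label).centroid
            )
            assert d < 1.0


class TestFitSphere:
    def test_octahedron_exact(self):
        pts = np.array(
            [[1, 0, 0], [-1, 0, 0], [0, 1, 0], [0, -1, 0], [0, 0, 1], [0, 0, -1]],
            dtype=float,
        )
        fit = fit_sphere(pts)
        assert np.allclose(fit.center, 0, atol=1e-12)
        assert fit.radius == pytest.approx(1.0, abs=1e-12)

    def test_noise_free_recovery(self, rng):
        dirs = rng.normal(size=(200, 3))
        dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
        pts = np.array([1.0, 2.0, 3.0]) + 5.0 * dirs
        fit = fit_sphere(pts)
        assert np.allclose(fit.center, [1, 2, 3], atol=1e-9)
        assert fit.radius == pytest.approx(5.0, abs=1e-9)
        assert fit.rms < 1e-9

    def test_noisy_monte_carlo(self):
        # 95th-percentile centre error over 100 seeds stays below 0.02 R
        radius, sigma = 5.0, 0.05 * 5.0
        errors = []
        for seed in range(100):
            r = np.random.default_rng(seed)
            dirs = r.normal(size=(500, 3))
            dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
            pts = radius * dirs + r.normal(0, sigma, (500, 3))
            errors.append(np.linalg.norm(fit_sphere(pts).center))
        assert np.quantile(errors, 0.95) < 0.02 * radius

    def test_rigid_invariance(self, rng):
        dirs = rng.normal(size=(50, 3))
        dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
        pts = np.array([0.5, -1.0, 2.0]) + 3.0 * dirs
        fit = fit_sphere(pts)
        T = tf.compose(tf.translation([4, -2, 7]), tf.random_rotation(rng, 180.0))
        fit2 = fit_sphere(tf.apply_transform(T, pts))
        assert np.allclose(fit2.center, tf.apply_transform(T, fit.center[None])[0], atol=1e-9)
        assert fit2.radius == pytest.approx(fit.radius, abs=1e-9)

    def test_degenerate_inputs(self):
        with pytest.raises(ValueError):
            fit_sphere(np.zeros((3, 3)))
        coplanar = np.column_stack([np.arange(10.0), np.arange(10.0) ** 2, np.zeros(10)])
        with pytest.raises(ValueError):
            fit_sphere(coplanar)


def _square_patch():
    mesh = TriMesh(
        np.array([[0, 0, 0], [1, 0, 0], [1, 0, 1], [0, 0, 1]], dtype=float),
        np.array([[0, 2, 1], [0, 3, 2]]),
    )
    return FacetPatch("t", "left", "pre", np.array([0, 1]), mesh)


class TestExtrudePatch:
    def test_planar_square_volume(self):
        patch = _square_patch()
        prism = extrude_patch(patch, patch.mean_normal, 2.0)
        assert prism.is_watertight()
        assert prism.signed_volume() == pytest.approx(2.0, abs=1e-6)

    def test_zero_distance_errors(self):
        with pytest.raises(ValueError):
            extrude_patch(_square_patch(), np.array([0, 1, 0]), 0.0)

    def test_curved_patch_volume_matches_projection(self, default_vertebra):
        vert, _ = default_vertebra
        patch = vert.patch("left_pre")
        h = 1.3
        d = patch.mean_normal
        prism = extrude_patch(patch, d, h)
        # independent oracle: translational sweep volume = h x projected area
        tri = patch.triangles
        vec_areas = 0.5 * np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0])
        expected = h * float(vec_areas.sum(axis=0) @ d)
        assert prism.signed_volume() == pytest.approx(expected, rel=1e-9)
        areas = np.linalg.norm(vec_areas, axis=1)
        assert prism.signed_volume() <= areas.sum() * h + 1e-9

    def test_random_patches_watertight(self, rng):
        ico = primitives.icosphere(2)
        adj: dict[int, set] = {}
        edge_map: dict[tuple, list] = {}
        for fi, f in enumerate(ico.faces):
            for a, b in ((f[0], f[1]), (f[1], f[2]), (f[2], f[0])):
                edge_map.setdefault((min(a, b), max(a, b)), []).append(fi)
        for pair in edge_map.values():
            if len(pair) == 2:
                adj.setdefault(pair[0], set()).add(pair[1])
                adj.setdefault(pair[1], set()).add(pair[0])
        for trial in range(100):
            seed_face = int(rng.integers(len(ico.faces)))
            patch_faces = {seed_face}
            frontier = [seed_face]
            target = int(rng.integers(3, 40))
            while frontier and len(patch_faces) < target:
                nxt = frontier.pop(0)
                for g in adj[nxt]:
                    if g not in patch_faces:
                        patch_faces.add(g)
                        frontier.append(g)
            patch = FacetPatch("ico", "left", "pre", np.array(sorted(patch_faces)), ico)
            prism = extrude_patch(patch, patch.mean_normal, 0.4)
            assert prism.is_watertight(), f"trial {trial} not watertight"
            assert prism.signed_volume() > 0
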