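import numpy as np
import pytest

from osteorom.pose_analysis import (
    RomEnvelope,
    alpha_shape,
    alpha_shape_volume,
    cosine_correct,
    extrema_and_sums,
    grid_corrected_volume,
    max_turn_pose,
    sfp_export,
    sfp_points,
)
from osteorom.rom_engine import PoseGrid


class TestCosineCorrect:
    def test_zero_yaw_unchanged(self):
        out = cosine_correct([(7.0, 0.0, 3.0)])
        assert np.allclose(out, [(7.0, 0.0, 3.0)])

    def test_ninety_yaw_kills_roll(self):
        out = cosine_correct([(10.0, 90.0, 5.0)])
        assert out[0][0] == pytest.approx(0.0, abs=1e-9)
        assert tuple(out[0][1:]) == (90.0, 5.0)

    def test_clamp_warns(self):
        with pytest.warns(UserWarning):
            cosine_correct([(10.0, 120.0, 0.0)])

    def test_full_grid_volume_analytic(self):
        grid = PoseGrid(roll=(-180, 180), yaw=(-90, 90), pitch=(-180, 180), step=2)
        expected = 360.0 * 360.0 * 360.0 / np.pi
        assert grid_corrected_volume(grid) == pytest.approx(expected, rel=0.005)


def _cube_cloud(center, side=1.0, n=5):
    xs = np.linspace(0, side, n)
    p = np.stack(np.meshgrid(xs, xs, xs, indexing="ij"), axis=-1).reshape(-1, 3)
    return p + np.asarray(center, dtype=float)


class TestAlphaShape:
    def test_dense_cube_grid(self):
        xs = np.arange(10) * 2.0
        pts = np.stack(np.meshgrid(xs, xs, xs, indexing="ij"), axis=-1).reshape(-1, 3)
        vol, used = alpha_shape_volume(pts, alpha=50.0)
        assert vol == pytest.approx(18.0**3, rel=0.02)
        assert used == 50.0

    def test_unit_tetrahedron(self):
        pts = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1]], dtype=float)
        vol, _ = alpha_shape_volume(pts, alpha=1e6)
        assert vol == pytest.approx(1.0 / 6.0, abs=1e-9)

    def test_two_cluster_critical_fallback(self):
        pts = np.vstack([_cube_cloud((0, 0, 0)), _cube_cloud((120, 0, 0))])
        shape = alpha_shape(pts, alpha=50.0)
        assert shape.critical_alpha > 50.0
        assert shape.alpha_used == shape.critical_alpha
        assert shape.contains_all_points()
        assert shape.volume >= 2.0  # at least the two unit cubes

    def test_too_few_points_warns(self):
        with pytest.warns(UserWarning):
            vol, _ = alpha_shape_volume(np.zeros((3, 3)))
        assert vol == 0.0

    def test_coplanar_zero_volume(self):
        pts = np.column_stack([np.arange(10.0), (np.arange(10.0) * 3) % 7, np.zeros(10)])
        with pytest.warns(UserWarning):
            vol, _ = alpha_shape_volume(pts)
        assert vol == 0.0

    def test_volume_monotone_under_added_poses(self):
        # nested grid pose sets (balls of growing radius on the 2-degree
        # sampling lattice), as produced by real sweeps
        xs = np.arange(-10, 11, 2.0)
        grid = np.stack(np.meshgrid(xs, xs, xs, indexing="ij"), axis=-1).reshape(-1, 3)
        r2 = (grid**2).sum(axis=1)
        prev = 0.0
        for radius in (4.0, 6.0, 8.0, 10.0):
            shape = alpha_shape(grid[r2 <= radius**2], 50.0)
            assert shape.volume >= prev - 1e-9
            prev = shape.volume

    def test_correction_fairness_across_yaw(self):
        """Equal corrected-extent pose discs at yaw 0 vs 60 get equal volumes."""
        vols = []
        for y0 in (0.0, 60.0):
            poses = []
            for corrected_roll in np.arange(-10, 10.1, 2.0):
                roll = corrected_roll / np.cos(np.radians(y0))
                for dy in np.arange(-10, 10.1, 2.0):
                    if corrected_roll**2 + dy**2 > 100.0:
                        continue
                    for pitch in np.arange(-6, 6.1, 2.0):
                        poses.append((roll, y0 + dy, pitch))
            corrected = cosine_correct(np.array(poses))
            # fold out the cos(y0+dy) vs cos(y0) difference: compare in a
            # common frame centred on y0
            corrected[:, 1] -= y0
            vols.append(alpha_shape(corrected, 50.0).volume)
        assert vols[1] == pytest.approx(vols[0], rel=0.05)


class TestEnvelopesAndSums:
    def test_single_joint_range(self):
        poses = [(r, 0.0, 0.0) for r in range(-10, 11, 2)]
        env = RomEnvelope("J", np.array(poses, dtype=float))
        summary = extrema_and_sums([env])
        assert summary.summed_range["roll"] == pytest.approx(20.0)

    def test_additivity_over_identical_joints(self):
        poses = np.array([(r, y, p) for r in (-20.0, 20.0) for y in (-5.0, 5.0) for p in (0.0, 2.0)])
        envs = [RomEnvelope(f"J{i}", poses) for i in range(7)]
        summary = extrema_and_sums(envs)
        assert summary.summed_range["roll"] == pytest.approx(280.0)
        for ax in ("roll", "yaw", "pitch"):
            assert summary.summed_range[ax] == pytest.approx(
                summary.summed_pos[ax] - summary.summed_neg[ax]
            )

    def test_contributions_partition_sums(self):
        rng = np.random.default_rng(5)
        envs = [
            RomEnvelope(f"J{i}", rng.uniform(-30, 30, (25, 3))) for i in range(4)
        ]
        summary = extrema_and_sums(envs)
        for ax in ("roll", "yaw", "pitch"):
            total = sum(c for _, c in summary.contributions[ax])
            assert total == pytest.approx(summary.summed_range[ax])

    def test_empty_envelope_contributes_zero_with_warning(self):
        with pytest.warns(UserWarning):
            env = RomEnvelope("E", np.empty((0, 3)))
        with pytest.warns(UserWarning):
            summary = extrema_and_sums([env])
        assert summary.summed_range["roll"] == 0.0

    def test_persistence_roundtrip_sums(self, four_chain_coarse, tmp_path):
        from osteorom.rom_engine import read_records_csv, sweep_joint

        chain, _ = four_chain_coarse
        grid = PoseGrid(roll=(-16, 16), yaw=(-16, 16), pitch=(-16, 16), step=8)
        envs_mem, envs_csv = [], []
        for j in range(chain.n_joints):
            label = chain.joint_label(j)
            recs = sweep_joint(chain, j, grid, csv_path=tmp_path / f"{label}.csv")
            envs_mem.append(RomEnvelope.from_records(label, recs))
            envs_csv.append(
                RomEnvelope.from_records(label, read_records_csv(tmp_path / f"{label}.csv"))
            )
        s1 = extrema_and_sums(envs_mem)
        s2 = extrema_and_sums(envs_csv)
        assert s1.summed_range == s2.summed_range
        assert s1.summed_pos == s2.summed_pos


class TestMaxTurn:
    def test_single_viable_pose(self, four_chain_coarse):
        chain, _ = four_chain_coarse
        envs = [
            RomEnvelope(chain.joint_label(j), np.array([[0.0, 0.0, 0.0]]))
            for j in range(chain.n_joints)
        ]
        turn = max_turn_pose(chain, envs)
        assert all(p == (0.0, 0.0, 0.0) for p in turn["poses"].values())

    def test_lexicographic_priority(self, four_chain_coarse):
        chain, _ = four_chain_coarse
        poses = np.array([(0.0, 10.0, 0.0), (8.0, 10.0, -4.0), (8.0, 10.0, 6.0)])
        envs = [
            RomEnvelope(chain.joint_label(j), poses) for j in range(chain.n_joints)
        ]
        turn = max_turn_pose(chain, envs)
        assert all(p == (8.0, 10.0, 6.0) for p in turn["poses"].values())

    def test_exclusion_reduces_summed_yaw_additively(self, four_chain_coarse):
        from osteorom.rom_engine import sweep_joint

        chain, _ = four_chain_coarse
        grid = PoseGrid(roll=(-8, 8), yaw=(-24, 24), pitch=(-8, 8), step=8)
        envs = [
            RomEnvelope.from_records(chain.joint_label(j), sweep_joint(chain, j, grid))
            for j in range(chain.n_joints)
        ]
        full = max_turn_pose(chain, envs)
        caudal = chain.joint_label(0)
        reduced = max_turn_pose(chain, envs, exclude_joints=[caudal])
        yaw_full = sum(p[1] for p in full["poses"].values())
        yaw_reduced = sum(p[1] for p in reduced["poses"].values())
        assert yaw_full - yaw_reduced == pytest.approx(full["poses"][caudal][1])


class TestSfp:
    def test_onp_maps_to_long_axis(self, three_chain):
        chain, _ = three_chain
        env = RomEnvelope("J", np.array([[0.0, 0.0, 0.0]]))
        dirs, roll = sfp_points(env, chain.joints[0])
        assert np.allclose(dirs[0], chain.joints[0].x_axis, atol=1e-12)
        assert roll[0] == 0.0

    def test_pure_yaw_sweep_on_equator(self, three_chain):
        chain, _ = three_chain
        yaws = np.arange(-90.0, 91.0, 10.0)
        env = RomEnvelope("J", np.column_stack([np.zeros_like(yaws), yaws, np.zeros_like(yaws)]))
        dirs, _ = sfp_points(env, chain.joints[0])
        # all directions lie in the plane normal to the joint y-axis
        assert np.abs(dirs @ chain.joints[0].y_axis).max() < 1e-9
        assert np.allclose(np.linalg.norm(dirs, axis=1), 1.0, atol=1e-12)

    def test_point_count_bijection(self, three_chain, tmp_path, rng):
        chain, _ = three_chain
        poses = rng.uniform(-20, 20, (37, 3))
        env = RomEnvelope("J", poses)
        dirs = sfp_export(env, chain.joints[0], tmp_path / "sfp.ply")
        assert len(dirs) == 37
        text = (tmp_path / "sfp.ply").read_text()
        assert "element vertex 37" in text
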