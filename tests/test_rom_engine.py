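import numpy as np
import pytest

from osteorom import transforms as tf
from osteorom.collision import CollisionBody, collide, voxel_overlap
from osteorom.rom_engine import (
    JointContext,
    PoseGrid,
    PoseRecord,
    build_articulation_volumes,
    read_records_csv,
    sweep_joint,
    write_records_csv,
)
from osteorom.rom_engine.sweep import SweepError
from osteorom.synthetic_vertebrae import ChainRecipe, VertebraParams, make_chain
from conftest import COARSE, scan_axis_limit


class TestPoseGrid:
    def test_sample_count(self):
        grid = PoseGrid(roll=(-2, 2), yaw=(-2, 2), pitch=(-2, 2), step=2)
        assert grid.n_samples == 27
        assert len(list(grid.samples())) == 27

    def test_degenerate_grid(self):
        grid = PoseGrid(roll=(0, 0), yaw=(0, 0), pitch=(0, 0), step=2)
        assert grid.n_samples == 1

    def test_bounds_must_contain_zero(self):
        with pytest.raises(SweepError):
            PoseGrid(roll=(2, 10))
        with pytest.raises(SweepError):
            PoseGrid(step=-1)


class TestPoseRecord:
    def test_viable_flag_coding(self):
        rec = PoseRecord(0, 0, 0, True, True, True)
        assert rec.viable is True
        for flags in ((False, True, True), (True, False, True), (True, True, False)):
            assert PoseRecord(0, 0, 0, *flags).viable is False


class TestArticulationVolumes:
    def test_onp_intersects_both_prisms(self, three_chain):
        chain, _ = three_chain
        ctx = JointContext(chain, 0)
        rec = ctx.classify(0.0, 0.0, 0.0)
        assert rec.viable and rec.articulated_left and rec.articulated_right

    def test_dorsal_translation_disarticulates(self, three_chain):
        chain, _ = three_chain
        left, right = build_articulation_volumes(chain, 0)
        gap = chain.spacing[0]["facet_gap"]
        moved = chain.vertebra_world(1).mesh.transformed(tf.translation([0, 10 * gap, 0]))
        body = CollisionBody(moved)
        assert not collide(body, CollisionBody(left))
        assert not collide(body, CollisionBody(right))

    def test_prism_volumes_mirror_symmetric(self, three_chain):
        chain, _ = three_chain
        left, right = build_articulation_volumes(chain, 0)
        assert left.signed_volume() == pytest.approx(right.signed_volume(), abs=1e-6)

    def test_missing_patch_errors(self, three_chain):
        chain, _ = three_chain
        stripped = chain.vertebrae[0].copy()
        del stripped.facet_patches["left_pre"]
        from osteorom.chain_builder import VertebralChain

        broken = VertebralChain(
            [stripped] + [v for v in chain.vertebrae[1:]],
            chain.onp_transforms,
        )
        broken.spacing = chain.spacing
        broken.build_joints()
        with pytest.raises(SweepError):
            build_articulation_volumes(broken, 0)

    def test_margin_monotonicity(self, three_chain):
        """Growing the gap-prism margin can only grow the articulated set."""
        chain, _ = three_chain
        gap = chain.spacing[0]["facet_gap"]
        ctx_small = JointContext(chain, 0, margin=0.5 * gap)
        ctx_big = JointContext(chain, 0, margin=3.0 * gap)
        for pose in [(0, 0, p) for p in range(40, 61, 2)]:
            small = ctx_small.classify(*pose)
            big = ctx_big.classify(*pose)
            if small.articulated_left:
                assert big.articulated_left
            if small.articulated_right:
                assert big.articulated_right


class TestClassify:
    def test_colliding_pose_still_reports_articulation(self, three_chain):
        chain, _ = three_chain
        ctx = JointContext(chain, 0)
        rec = ctx.classify(0.0, 0.0, -18.0)  # ventral pitch past centrum contact
        assert not rec.collision_free
        assert rec.articulated_left and rec.articulated_right
        assert not rec.viable

    def test_disarticulation_angle_matches_voxel_oracle(self, three_chain):
        """Dorsal-pitch disarticulation angle against the voxel oracle."""
        chain, _ = three_chain
        ctx = JointContext(chain, 0)
        limit = scan_axis_limit(ctx, 2, +1)
        rec = ctx.classify(0.0, 0.0, limit + 2.0)
        assert not (rec.articulated_left and rec.articulated_right)
        # voxel overlap between the posed anterior vertebra and the prism
        left = ctx.prisms[0]
        T_in = ctx.joint.pose_transform(0, 0, limit - 2.0)
        T_out = ctx.joint.pose_transform(0, 0, limit + 4.0)
        ant = chain.vertebra_world(1).mesh
        ov_in, amb_in = voxel_overlap(ant.transformed(T_in), left, divisions=80)
        ov_out, _ = voxel_overlap(ant.transformed(T_out), left, divisions=80)
        assert ov_in or amb_in
        assert not ov_out

    def test_spinous_contact_angle_matches_2d_oracle(self):
        """Tall spinous processes cap dorsal pitch by bone contact; the
        contact angle is predicted independently by rotating the blade
        rectangle in the sagittal plane."""
        over = {"spinous_height": 9.0, **COARSE}
        chain, truth = make_chain(ChainRecipe(n_vertebrae=2, overrides={0: over, 1: over}))
        ctx = JointContext(chain, 0)
        limit = scan_axis_limit(ctx, 2, +1)
        rec = ctx.classify(0.0, 0.0, limit + 2.0)
        assert not rec.collision_free
        # 2-D oracle: blades are axis-aligned rectangles in the xy-plane
        p = truth.vertebra_truths[0].params
        cor = truth.cors_world[0][:2]
        ant_T = chain.onp_transforms[1]
        blade_faces = truth.vertebra_truths[1].parts["spinous"]
        pts = chain.vertebrae[1].mesh.vertices[
            np.unique(chain.vertebrae[1].mesh.faces[blade_faces])
        ]
        pts = tf.apply_transform(ant_T, pts)[:, :2]
        # densify the rectangle boundary
        corners = pts[np.lexsort((pts[:, 1], pts[:, 0]))]
        lo, hi = pts.min(axis=0), pts.max(axis=0)
        edge = np.concatenate(
            [
                np.column_stack([np.linspace(lo[0], hi[0], 200), np.full(200, y)])
                for y in (lo[1], hi[1])
            ]
            + [
                np.column_stack([np.full(200, x), np.linspace(lo[1], hi[1], 200)])
                for x in (lo[0], hi[0])
            ]
        )
        post_blades = truth.vertebra_truths[0].parts["spinous"]
        post_pts = chain.vertebrae[0].mesh.vertices[
            np.unique(chain.vertebrae[0].mesh.faces[post_blades])
        ][:, :2]
        plo, phi = post_pts.min(axis=0), post_pts.max(axis=0)
        rel = edge - cor
        contact = None
        for deg in np.arange(0.0, 80.0, 0.25):
            c, s = np.cos(np.radians(deg)), np.sin(np.radians(deg))
            rot = np.column_stack([rel[:, 0] * c - rel[:, 1] * s, rel[:, 0] * s + rel[:, 1] * c]) + cor
            inside = (
                (rot[:, 0] >= plo[0]) & (rot[:, 0] <= phi[0])
                & (rot[:, 1] >= plo[1]) & (rot[:, 1] <= phi[1])
            )
            if inside.any():
                contact = deg
                break
        assert contact is not None
        assert abs((limit + 2.0) - contact) <= 2.0 + 0.25


class TestSweep:
    def test_record_count_and_determinism(self, four_chain_coarse, tmp_path):
        chain, _ = four_chain_coarse
        grid = PoseGrid(roll=(-8, 8), yaw=(-8, 8), pitch=(-8, 8), step=4)
        r1 = sweep_joint(chain, 1, grid, csv_path=tmp_path / "a.csv")
        r2 = sweep_joint(chain, 1, grid, csv_path=tmp_path / "b.csv")
        assert len(r1) == grid.n_samples
        assert [(r.angles, r.viable) for r in r1] == [(r.angles, r.viable) for r in r2]
        assert (tmp_path / "a.csv").read_bytes() == (tmp_path / "b.csv").read_bytes()

    def test_degenerate_grid_onp_only(self, four_chain_coarse):
        chain, _ = four_chain_coarse
        grid = PoseGrid(roll=(0, 0), yaw=(0, 0), pitch=(0, 0), step=2)
        recs = sweep_joint(chain, 0, grid)
        assert len(recs) == 1 and recs[0].viable

    def test_order_independence(self, four_chain_coarse, rng):
        chain, _ = four_chain_coarse
        grid = PoseGrid(roll=(-16, 16), yaw=(-16, 16), pitch=(-16, 16), step=8)
        records = {r.angles: r.viable for r in sweep_joint(chain, 0, grid)}
        ctx = JointContext(chain, 0)
        poses = list(records)
        rng.shuffle(poses)
        for pose in poses:
            assert ctx.classify(*pose).viable == records[pose]

    def test_grid_refinement_consistent_on_shared_points(self, four_chain_coarse):
        chain, _ = four_chain_coarse
        coarse = {r.angles: r.viable for r in sweep_joint(
            chain, 0, PoseGrid(roll=(-16, 16), yaw=(0, 0), pitch=(-16, 16), step=8))}
        fine = {r.angles: r.viable for r in sweep_joint(
            chain, 0, PoseGrid(roll=(-16, 16), yaw=(0, 0), pitch=(-16, 16), step=4))}
        for pose, viable in coarse.items():
            assert fine[pose] == viable

    def test_csv_roundtrip(self, four_chain_coarse, tmp_path):
        chain, _ = four_chain_coarse
        grid = PoseGrid(roll=(-8, 8), yaw=(-8, 8), pitch=(-8, 8), step=8)
        recs = sweep_joint(chain, 2, grid, csv_path=tmp_path / "s.csv")
        back = read_records_csv(tmp_path / "s.csv")
        assert [(r.angles, r.viable) for r in recs] == [(r.angles, r.viable) for r in back]
        write_records_csv(back, tmp_path / "s2.csv")
        assert (tmp_path / "s.csv").read_bytes() == (tmp_path / "s2.csv").read_bytes()
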