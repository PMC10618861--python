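from __future__ import annotations

import csv
import itertools
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from ..collision import CollisionBody, RotationSweepTester, collide
from ..mesh_core import TriMesh, extrude_patch
from ..mesh_core.mesh import MeshError


class SweepError(ValueError):
    pass


@dataclass(frozen=True)
class PoseGrid:
    """Per-axis inclusive bounds (degrees) and a fixed step (default 2)."""

    roll: tuple = (-90.0, 90.0)
    yaw: tuple = (-90.0, 90.0)
    pitch: tuple = (-90.0, 60.0)
    step: float = 2.0

    def __post_init__(self):
        if self.step <= 0:
            raise SweepError("grid step must be > 0")
        for name in ("roll", "yaw", "pitch"):
            lo, hi = getattr(self, name)
            if not (lo <= 0.0 <= hi):
                raise SweepError(f"{name} bounds must contain 0 (the neutral pose)")
            for v in (lo, hi):
                if abs(round(v / self.step) * self.step - v) > 1e-9:
                    raise SweepError(f"{name} bounds must be multiples of the step")

    def axis_samples(self, name: str) -> np.ndarray:
        lo, hi = getattr(self, name)
        n = int(np.floor((hi - lo) / self.step + 1e-9)) + 1
        return lo + self.step * np.arange(n)

    @property
    def n_samples(self) -> int:
        return (
            len(self.axis_samples("roll"))
            * len(self.axis_samples("yaw"))
            * len(self.axis_samples("pitch"))
        )

    def samples(self):
        return itertools.product(
            self.axis_samples("roll"),
            self.axis_samples("yaw"),
            self.axis_samples("pitch"),
        )


@dataclass
class PoseRecord:
    """One sampled joint pose with its viability flags (paper's 0/1 coding)."""

    roll: float
    yaw: float
    pitch: float
    collision_free: bool
    articulated_left: bool
    articulated_right: bool
    viable: bool = field(init=False)
    note: str = ""

    def __post_init__(self):
        self.viable = bool(
            self.collision_free and self.articulated_left and self.articulated_right
        )

    @property
    def angles(self) -> tuple:
        return (self.roll, self.yaw, self.pitch)


def test_collision(mesh_a: TriMesh, mesh_b: TriMesh) -> bool:
    """True iff two watertight meshes intersect (surfaces cross or one
    contains the other). Symmetric in its arguments."""
    for m, side in ((mesh_a, "first"), (mesh_b, "second")):
        if not m.is_watertight():
            raise MeshError(f"collision test requires watertight meshes ({side} input)")
    return collide(CollisionBody(mesh_a), CollisionBody(mesh_b))


def build_articulation_volumes(chain, j: int, margin: float | None = None):
    """Left/right articulation gap prisms for joint j, in world (ONP) frame.

    Each prism extrudes the posterior vertebra's prezygapophyseal facet along
    its mean normal by (ONP facet gap + margin); margin defaults to one facet
    gap, i.e. prism length = 2x the ONP facet gap. The prisms live in the
    posterior vertebra's frame: they stay put while the anterior vertebra is
    animated.
    """
    posterior = chain.vertebra_world(j)
    if chain.spacing:
        gap = chain.spacing[j]["facet_gap"]
    else:
        from ..chain_builder import measure_joint_gaps

        gap = measure_joint_gaps(chain, j)["facet_gap"]
    if margin is None:
        margin = gap
    out = []
    for side in ("left", "right"):
        label = f"{side}_pre"
        if not posterior.has_patch(label):
            raise SweepError(
                f"posterior vertebra {posterior.name!r} lacks facet patch {label!r}"
            )
        patch = posterior.patch(label)
        out.append(extrude_patch(patch, patch.mean_normal, gap + margin))
    return tuple(out)


class JointContext:
    """Pre-computed geometry for sweeping one joint of a chain."""

    def __init__(self, chain, j: int, margin: float | None = None):
        if not chain.joints:
            chain.build_joints()
        self.chain = chain
        self.j = j
        self.joint = chain.joints[j]
        self.label = chain.joint_label(j)
        self.static_body = CollisionBody(chain.vertebra_world(j).mesh)
        self.moving_body = CollisionBody(chain.vertebra_world(j + 1).mesh)
        left, right = build_articulation_volumes(chain, j, margin=margin)
        self.prisms = (left, right)
        self.prism_bodies = (CollisionBody(left), CollisionBody(right))
        cor = self.joint.cor
        self._bone_test = RotationSweepTester(self.moving_body, self.static_body, cor)
        self._prism_tests = tuple(
            RotationSweepTester(self.moving_body, b, cor) for b in self.prism_bodies
        )

    def classify(self, roll: float, yaw: float, pitch: float) -> PoseRecord:
        """Classify one pose of this joint (all other joints neutral).

        Geometry errors annotate the record (pose marked non-viable) rather
        than aborting a sweep.
        """
        try:
            T = self.joint.pose_transform(roll, yaw, pitch)
            posed = self.moving_body.transformed(T)
            collision_free = not self._bone_test.intersects(posed)
            articulated_left = self._prism_tests[0].intersects(posed)
            articulated_right = self._prism_tests[1].intersects(posed)
            return PoseRecord(
                roll, yaw, pitch, collision_free, articulated_left, articulated_right
            )
        except Exception as err:  # noqa: BLE001 - annotate, never abort a sweep
            return PoseRecord(roll, yaw, pitch, False, False, False, note=str(err))


def classify_pose(chain, j: int, pose, margin: float | None = None) -> PoseRecord:
    return JointContext(chain, j, margin=margin).classify(*pose)


_CSV_FIELDS = (
    "roll", "yaw", "pitch",
    "collision_free", "articulated_left", "articulated_right", "viable",
)


def _fmt_angle(v: float) -> str:
    return str(int(v)) if float(v).is_integer() else repr(float(v))


def write_records_csv(records, path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(_CSV_FIELDS)
        for r in records:
            w.writerow(
                [_fmt_angle(r.roll), _fmt_angle(r.yaw), _fmt_angle(r.pitch)]
                + [int(r.collision_free), int(r.articulated_left),
                   int(r.articulated_right), int(r.viable)]
            )


def read_records_csv(path) -> list:
    out = []
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            rec = PoseRecord(
                float(row["roll"]), float(row["yaw"]), float(row["pitch"]),
                bool(int(row["collision_free"])),
                bool(int(row["articulated_left"])),
                bool(int(row["articulated_right"])),
            )
            if rec.viable != bool(int(row["viable"])):
                raise SweepError(f"inconsistent viability flags in {path}")
            out.append(rec)
    return out


def sweep_joint(
    chain,
    j: int,
    grid: PoseGrid,
    csv_path=None,
    margin: float | None = None,
    progress: bool = False,
) -> list:
    """Exhaustively classify every grid pose of joint j.

    Exactly one PoseRecord per grid point, deterministic given inputs; only
    the swept joint is actuated. Records are streamed to ``csv_path`` while
    computing when given.
    """
    ctx = JointContext(chain, j, margin=margin)
    records = []
    writer = fh = None
    if csv_path is not None:
        fh = open(Path(csv_path), "w", newline="")
        writer = csv.writer(fh)
        writer.writerow(_CSV_FIELDS)
    try:
        total = grid.n_samples
        for i, (r, y, p) in enumerate(grid.samples()):
            rec = ctx.classify(r, y, p)
            records.append(rec)
            if writer is not None:
                writer.writerow(
                    [_fmt_angle(rec.roll), _fmt_angle(rec.yaw), _fmt_angle(rec.pitch),
                     int(rec.collision_free), int(rec.articulated_left),
                     int(rec.articulated_right), int(rec.viable)]
                )
            if progress and (i + 1) % 5000 == 0:
                print(f"  {ctx.label}: {i + 1}/{total} poses", flush=True)
    finally:
        if fh is not None:
            fh.close()
    return records
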