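"""Quantitative outputs from viable pose sets.

Viable (roll, yaw, pitch) samples are cosine-corrected to remove the Euler
pose-space distortion (roll-pitch axis degeneracy as yaw approaches +-90),
hulled by a 3-D alpha shape whose volume (cubed degrees) quantifies overall
joint mobility, and summed across joints into whole-chain range-of-motion
figures. A lexicographic maximum-turn composition and spherical frame
projection (SFP) exports are provided for visualisation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from . import transforms as tf

__all__ = [
    "cosine_correct",
    "grid_corrected_volume",
    "AlphaShape",
    "alpha_shape",
    "alpha_shape_volume",
    "RomEnvelope",
    "ChainSummary",
    "extrema_and_sums",
    "max_turn_pose",
    "sfp_points",
    "sfp_export",
    "plot_pose_space",
    "plot_summary",
]

AXES = ("roll", "yaw", "pitch")


def cosine_correct(poses) -> np.ndarray:
    """Map (roll, yaw, pitch) -> (roll*cos(yaw), yaw, pitch), degrees.

    Consistent with the intrinsic roll->yaw->pitch rotation order, in which
    the roll and pitch axes become degenerate at yaw = +-90 deg. |yaw| > 90
    is clamped (cos treated as 0) with a warning.
    """
    poses = np.atleast_2d(np.asarray(poses, dtype=float))
    if poses.shape[1] != 3:
        raise ValueError("poses must be (n, 3) (roll, yaw, pitch)")
    yaw = poses[:, 1]
    if np.any(np.abs(yaw) > 90.0 + 1e-9):
        warnings.warn("poses with |yaw| > 90 deg: cosine factor clamped at 0")
    factor = np.maximum(np.cos(np.radians(np.clip(yaw, -90.0, 90.0))), 0.0)
    out = poses.copy()
    out[:, 0] = poses[:, 0] * factor
    return out


def grid_corrected_volume(grid) -> float:
    """Total cosine-corrected volume of a pose grid, in cubed degrees.

    Midpoint rule over grid cells: each cell contributes
    step^3 * cos(yaw at the cell centre). Over the full Euler grid
    (roll, pitch in [-180, 180], yaw in [-90, 90]) this approaches
    360 * 360 * 360/pi.
    """
    spans = []
    for name in ("roll", "pitch"):
        s = grid.axis_samples(name)
        spans.append(s[-1] - s[0])
    yaw = grid.axis_samples("yaw")
    mids = 0.5 * (yaw[:-1] + yaw[1:])
    return float(spans[0] * spans[1] * np.sum(np.cos(np.radians(mids)) * grid.step))


# -- alpha shapes ------------------------------------------------------------


def _circumradii(points: np.ndarray, simplices: np.ndarray) -> np.ndarray:
    """Circumsphere radius of each tetrahedron.

    Degenerate (flat) slivers that qhull emits for cospherical inputs get
    radius 0: they contribute no volume but stay in the shape at every
    threshold, so they keep facet connectivity intact. (A flat tetrahedron
    bridging distant clusters cannot be Delaunay: its circumsphere would
    contain other points.)
    """
    p = points[simplices]
    a = p[:, 1:] - p[:, :1]  # (m, 3, 3)
    rhs = 0.5 * np.einsum("mij,mij->mi", a, a)
    radii = np.zeros(len(simplices))
    ok = np.abs(np.linalg.det(a)) > 1e-12
    if ok.any():
        centers = np.linalg.solve(a[ok], rhs[ok][..., None])[..., 0]
        radii[ok] = np.linalg.norm(centers, axis=1)
    return radii


def _tet_volumes(points: np.ndarray, simplices: np.ndarray) -> np.ndarray:
    p = points[simplices]
    a = p[:, 1:] - p[:, :1]
    return np.abs(np.linalg.det(a)) / 6.0


class _UnionFind:
    def __init__(self, n: int):
        self.parent = np.arange(n)

    def find(self, i: int) -> int:
        p = self.parent
        while p[i] != i:
            p[i] = p[p[i]]
            i = p[i]
        return i

    def union(self, i: int, j: int) -> None:
        ri, rj = self.find(i), self.find(j)
        if ri != rj:
            self.parent[rj] = ri


@dataclass
class AlphaShape:
    """A 3-D alpha shape: kept Delaunay tetrahedra at the working alpha."""

    points: np.ndarray
    alpha_used: float
    critical_alpha: float
    volume: float
    simplices: np.ndarray  # kept tetrahedra (k, 4)

    def contains_all_points(self) -> bool:
        used = np.unique(self.simplices)
        return len(used) == len(self.points)


def _encloses(simplices, neighbors, radii, n_points, threshold) -> bool:
    """All points covered by kept tets and kept tets form one region."""
    kept = np.nonzero(radii <= threshold)[0]
    if not len(kept):
        return False
    if len(np.unique(simplices[kept])) < n_points:
        return False
    pos = np.full(len(radii), -1)
    pos[kept] = np.arange(len(kept))
    uf = _UnionFind(len(kept))
    for row, t in enumerate(kept):
        for nb in neighbors[t]:
            if nb >= 0 and pos[nb] >= 0:
                uf.union(row, pos[nb])
    root = uf.find(0)
    return all(uf.find(i) == root for i in range(len(kept)))


def alpha_shape(points, alpha: float = 50.0) -> AlphaShape:
    """Delaunay-based 3-D alpha shape with critical-alpha fallback.

    A tetrahedron belongs to the shape iff its circumradius <= alpha. The
    critical alpha is the smallest circumradius threshold at which the shape
    encloses every input point as a single region (every point is a vertex
    of a kept tetrahedron and the kept tetrahedra are facet-connected);
    alpha_used = max(alpha, critical). Degenerate inputs (< 4 points or all
    coplanar) give volume 0 with a warning.
    """
    from scipy.spatial import Delaunay, QhullError

    points = np.asarray(points, dtype=float)
    if points.ndim != 2 or points.shape[1] != 3:
        raise ValueError("points must be (n, 3)")
    empty = AlphaShape(points, float(alpha), 0.0, 0.0, np.empty((0, 4), dtype=int))
    if len(points) < 4:
        warnings.warn("alpha shape of < 4 points has zero volume")
        return empty
    try:
        tri = Delaunay(points)
    except QhullError:
        warnings.warn("degenerate (coplanar) point set: alpha-shape volume 0")
        return empty
    radii = _circumradii(points, tri.simplices)
    n_pts = len(np.unique(tri.simplices))
    finite = np.unique(radii[np.isfinite(radii)])
    lo, hi = 0, len(finite) - 1
    if not len(finite) or not _encloses(tri.simplices, tri.neighbors, radii, n_pts, finite[-1]):
        warnings.warn("no alpha threshold encloses all points; using all tetrahedra")
        critical = float(finite[-1]) if len(finite) else 0.0
    else:
        while lo < hi:
            mid = (lo + hi) // 2
            if _encloses(tri.simplices, tri.neighbors, radii, n_pts, finite[mid]):
                hi = mid
            else:
                lo = mid + 1
        critical = float(finite[lo])
    alpha_used = max(float(alpha), critical)
    kept = radii <= alpha_used
    volume = float(_tet_volumes(points, tri.simplices[kept]).sum())
    return AlphaShape(points, alpha_used, critical, volume, tri.simplices[kept])


def alpha_shape_volume(points, alpha: float = 50.0) -> tuple[float, float]:
    """(volume in cubed degrees, alpha actually used)."""
    shape = alpha_shape(points, alpha)
    return shape.volume, shape.alpha_used


# -- envelopes and chain summaries -------------------------------------------


@dataclass
class RomEnvelope:
    """Viable pose set of one joint with its alpha-shape mobility volume.

    Extrema are computed on the raw (uncorrected) angles; the alpha shape
    and its volume on the cosine-corrected coordinates.
    """

    joint: str
    viable_poses: np.ndarray
    corrected_poses: np.ndarray = field(default=None)
    alpha: float = 50.0
    alpha_used: float = field(default=None)
    critical_alpha: float = field(default=None)
    volume: float = field(default=None)
    extrema: dict = field(default=None)

    def __post_init__(self):
        self.viable_poses = np.asarray(self.viable_poses, dtype=float).reshape(-1, 3)
        if self.corrected_poses is None:
            self.corrected_poses = (
                cosine_correct(self.viable_poses)
                if len(self.viable_poses)
                else np.empty((0, 3))
            )
        if self.volume is None:
            if len(self.viable_poses) == 0:
                warnings.warn(f"joint {self.joint}: empty viable set")
                self.volume, self.alpha_used, self.critical_alpha = 0.0, self.alpha, 0.0
            else:
                shape = alpha_shape(self.corrected_poses, self.alpha)
                self.volume = shape.volume
                self.alpha_used = shape.alpha_used
                self.critical_alpha = shape.critical_alpha
        if self.extrema is None:
            if len(self.viable_poses) == 0:
                self.extrema = {ax: (0.0, 0.0) for ax in AXES}
            else:
                self.extrema = {
                    ax: (
                        float(self.viable_poses[:, i].min()),
                        float(self.viable_poses[:, i].max()),
                    )
                    for i, ax in enumerate(AXES)
                }

    @classmethod
    def from_records(cls, joint: str, records, alpha: float = 50.0) -> "RomEnvelope":
        poses = np.array([r.angles for r in records if r.viable], dtype=float)
        return cls(joint, poses.reshape(-1, 3), alpha=alpha)

    def to_dict(self) -> dict:
        return {
            "joint": self.joint,
            "n_viable": int(len(self.viable_poses)),
            "alpha": self.alpha,
            "alpha_used": self.alpha_used,
            "critical_alpha": self.critical_alpha,
            "volume_deg3": self.volume,
            "extrema": {ax: list(v) for ax, v in self.extrema.items()},
        }


@dataclass
class ChainSummary:
    """Whole-chain sums of the per-joint signed extrema, per axis."""

    envelopes: list
    summed_pos: dict = field(default=None)
    summed_neg: dict = field(default=None)
    summed_range: dict = field(default=None)
    contributions: dict = field(default=None)

    def __post_init__(self):
        if self.summed_pos is None:
            self.summed_pos = {}
            self.summed_neg = {}
            self.summed_range = {}
            self.contributions = {}
            for ax in AXES:
                mins = [e.extrema[ax][0] for e in self.envelopes]
                maxs = [e.extrema[ax][1] for e in self.envelopes]
                self.summed_pos[ax] = float(np.sum(maxs))
                self.summed_neg[ax] = float(np.sum(mins))
                self.summed_range[ax] = self.summed_pos[ax] - self.summed_neg[ax]
                self.contributions[ax] = [
                    (e.joint, float(hi - lo)) for e, lo, hi in zip(self.envelopes, mins, maxs)
                ]

    def to_dict(self) -> dict:
        return {
            "joints": [e.to_dict() for e in self.envelopes],
            "summed_pos": self.summed_pos,
            "summed_neg": self.summed_neg,
            "summed_range": self.summed_range,
            "contributions": self.contributions,
        }


def extrema_and_sums(envelopes) -> ChainSummary:
    """Chain summary from per-joint envelopes (>= 1 joint required)."""
    envelopes = list(envelopes)
    if not envelopes:
        raise ValueError("need at least one joint envelope")
    for e in envelopes:
        if len(e.viable_poses) == 0:
            warnings.warn(f"joint {e.joint}: empty viable set contributes zeros")
    return ChainSummary(envelopes)


def max_turn_pose(chain, envelopes, exclude_joints=()) -> dict:
    """Maximum neck-turn composition: per joint the viable pose with maximal
    deflection for yaw, then roll, then pitch (priority descending).

    Joints named in ``exclude_joints`` are held at the neutral pose (the
    joint-exclusion experiment). The composed chain is checked for
    whole-chain self-collision, which is reported, not enforced.
    """
    from .collision import CollisionBody, collide

    by_label = {e.joint: e for e in envelopes}
    chosen = []
    for j in range(chain.n_joints):
        label = chain.joint_label(j)
        if label in exclude_joints:
            chosen.append((0.0, 0.0, 0.0))
            continue
        env = by_label[label]
        if len(env.viable_poses) == 0:
            raise ValueError(f"joint {label} has an empty viable set")
        poses = [tuple(p) for p in env.viable_poses]
        chosen.append(max(poses, key=lambda t: (t[1], t[0], t[2])))
    from .chain_builder import pose_chain

    transforms = pose_chain(chain, chosen)
    bodies = [
        CollisionBody(chain.vertebra_world(i, transforms).mesh)
        for i in range(len(chain.vertebrae))
    ]
    collisions = [
        (chain.vertebrae[i].name, chain.vertebrae[k].name)
        for i in range(len(bodies))
        for k in range(i + 2, len(bodies))
        if collide(bodies[i], bodies[k])
    ]
    return {
        "poses": {chain.joint_label(j): chosen[j] for j in range(chain.n_joints)},
        "transforms": transforms,
        "self_collisions": collisions,
    }


# -- spherical frame projection ----------------------------------------------


def sfp_points(envelope: RomEnvelope, joint_frame) -> tuple[np.ndarray, np.ndarray]:
    """Viable poses mapped to rotated long-axis directions on the unit sphere.

    Returns (directions (n, 3), roll scalars (n,)); one point per viable
    pose (the roll component is encoded as the scalar channel).
    """
    if len(envelope.viable_poses) == 0:
        raise ValueError("empty viable set")
    A = joint_frame.axes
    dirs = np.empty((len(envelope.viable_poses), 3))
    for i, (r, y, p) in enumerate(envelope.viable_poses):
        R = tf.joint_rotation(r, y, p)[:3, :3]
        dirs[i] = A @ (R @ np.array([1.0, 0.0, 0.0]))
    return dirs, envelope.viable_poses[:, 0].copy()


def sfp_export(envelope: RomEnvelope, joint_frame, path) -> np.ndarray:
    """Write the SFP point cloud as an ascii PLY with a per-point roll scalar."""
    dirs, roll = sfp_points(envelope, joint_frame)
    with open(path, "w") as fh:
        fh.write("ply\nformat ascii 1.0\ncomment osteorom SFP export\n")
        fh.write(f"element vertex {len(dirs)}\n")
        fh.write("property double x\nproperty double y\nproperty double z\n")
        fh.write("property double roll\nend_header\n")
        for d, r in zip(dirs, roll):
            fh.write(f"{d[0]:.9g} {d[1]:.9g} {d[2]:.9g} {r:.9g}\n")
    return dirs


# -- static plots ------------------------------------------------------------


def plot_pose_space(envelope: RomEnvelope, path) -> None:
    """Corrected pose-space scatter with the alpha-hull wireframe."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig = plt.figure(figsize=(6, 5))
    ax = fig.add_subplot(projection="3d")
    pts = envelope.corrected_poses
    if len(pts):
        ax.scatter(pts[:, 0], pts[:, 1], pts[:, 2], s=3, alpha=0.4)
        shape = alpha_shape(pts, envelope.alpha)
        for tet in shape.simplices[:: max(1, len(shape.simplices) // 400)]:
            for a, b in ((0, 1), (0, 2), (0, 3), (1, 2), (1, 3), (2, 3)):
                seg = pts[[tet[a], tet[b]]]
                ax.plot(seg[:, 0], seg[:, 1], seg[:, 2], "k-", lw=0.2, alpha=0.25)
    ax.set_xlabel("roll x cos(yaw) [deg]")
    ax.set_ylabel("yaw [deg]")
    ax.set_zlabel("pitch [deg]")
    ax.set_title(f"{envelope.joint}: {envelope.volume:.0f} deg^3 (alpha {envelope.alpha_used:.0f})")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_summary(summary: ChainSummary, path) -> None:
    """Stacked per-joint contribution bars of summed ROM per axis."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes_ = plt.subplots(1, 2, figsize=(10, 4))
    colors = {"roll": "tab:red", "yaw": "gold", "pitch": "tab:blue"}
    for i, ax_name in enumerate(AXES):
        bottom = 0.0
        for joint, contrib in summary.contributions[ax_name]:
            axes_[0].bar(i, contrib, bottom=bottom, color=colors[ax_name],
                         edgecolor="white", linewidth=1.0)
            bottom += contrib
    axes_[0].set_xticks(range(3), AXES)
    axes_[0].set_ylabel("summed range [deg]")
    axes_[0].set_title("summed ROM per axis (white lines part joint contributions)")
    vols = [e.volume for e in summary.envelopes]
    axes_[1].bar(range(len(vols)), vols, color="tab:gray")
    axes_[1].set_xticks(range(len(vols)), [e.joint for e in summary.envelopes], rotation=45)
    axes_[1].set_ylabel("alpha-shape volume [deg^3]")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
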