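"""Arrange vertebrae into an osteological neutral pose (ONP) chain.

A chain is an ordered caudal->cranial list of vertebrae with one joint per
adjacent pair. Each joint's centre of rotation is the centre of a sphere
fitted to the ventral outline of the anterior (cranial) vertebra's
postzygapophyseal facets; rotating a joint rigidly moves every vertebra
cranial to it (hierarchically downstream) and leaves caudal vertebrae fixed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import transforms as tf
from .collision import CollisionBody, collide, min_surface_distance
from .mesh_core import VertebraMesh, fit_sphere

__all__ = [
    "JointFrame",
    "VertebralChain",
    "build_joint_frame",
    "pose_chain",
    "align_onp",
    "set_spacing",
    "ChainError",
]


class ChainError(ValueError):
    pass


@dataclass
class JointFrame:
    """Centre of rotation and orthonormal roll/yaw/pitch axes for one joint.

    x_axis: roll (series long axis), y_axis: yaw (dorso-ventral),
    z_axis: pitch (latero-lateral); right-handed.
    """

    cor: np.ndarray
    x_axis: np.ndarray
    y_axis: np.ndarray
    z_axis: np.ndarray
    anterior: str = ""
    posterior: str = ""
    fit_radius: float = float("nan")
    fit_rms: float = float("nan")

    def __post_init__(self):
        A = self.axes
        if not np.allclose(A @ A.T, np.eye(3), atol=1e-9):
            raise ChainError("joint axes must be orthonormal")
        if np.linalg.det(A) < 0:
            raise ChainError("joint axes must be right-handed")

    @property
    def axes(self) -> np.ndarray:
        """3x3 matrix with x, y, z axes as columns."""
        return np.column_stack([self.x_axis, self.y_axis, self.z_axis])

    def pose_transform(self, roll: float, yaw: float, pitch: float) -> np.ndarray:
        """World transform rotating the anterior side about this joint."""
        A4 = np.eye(4)
        A4[:3, :3] = self.axes
        R = tf.compose(A4, tf.joint_rotation(roll, yaw, pitch), tf.invert(A4))
        return tf.rotation_about(R, self.cor)

    def transformed(self, T: np.ndarray) -> "JointFrame":
        R = T[:3, :3]
        return JointFrame(
            tf.apply_transform(T, self.cor[None])[0],
            R @ self.x_axis,
            R @ self.y_axis,
            R @ self.z_axis,
            self.anterior,
            self.posterior,
            self.fit_radius,
            self.fit_rms,
        )


@dataclass
class VertebralChain:
    """Caudal->cranial vertebra list, ONP placement and joint frames.

    ``vertebrae`` hold mesh data in their own local frames;
    ``onp_transforms[i]`` places vertebra i in the shared ONP world frame.
    """

    vertebrae: list
    onp_transforms: list
    joints: list = field(default_factory=list)
    spacing: list = field(default_factory=list)  # per joint: {"body_gap", "facet_gap"}

    def __post_init__(self):
        if self.joints and len(self.joints) != len(self.vertebrae) - 1:
            raise ChainError("need exactly one joint per adjacent vertebra pair")

    @property
    def n_joints(self) -> int:
        return len(self.vertebrae) - 1

    def joint_label(self, j: int) -> str:
        return f"{self.vertebrae[j].name}-{self.vertebrae[j + 1].name}"

    def joint_index(self, label: str) -> int:
        for j in range(self.n_joints):
            if self.joint_label(j) == label:
                return j
        raise KeyError(f"no joint labelled {label!r}")

    def vertebra_world(self, i: int, pose_transforms=None) -> VertebraMesh:
        T = (pose_transforms or self.onp_transforms)[i]
        return self.vertebrae[i].transformed(T)

    def build_joints(self, up=(0.0, 1.0, 0.0)) -> None:
        self.joints = [
            build_joint_frame(
                self.vertebra_world(j + 1),
                self.vertebra_world(j),
                up=up,
            )
            for j in range(self.n_joints)
        ]


def _series_axes(anterior_centroid, posterior_centroid, up) -> np.ndarray:
    x = np.asarray(anterior_centroid, dtype=float) - np.asarray(posterior_centroid, dtype=float)
    nx = np.linalg.norm(x)
    if nx < 1e-12:
        raise ChainError("degenerate series direction")
    x = x / nx
    up = np.asarray(up, dtype=float)
    y = up - (up @ x) * x
    ny = np.linalg.norm(y)
    if ny < 1e-9:
        raise ChainError("up direction parallel to series axis")
    y = y / ny
    z = np.cross(x, y)
    return np.column_stack([x, y, z])


def build_joint_frame(
    anterior: VertebraMesh,
    posterior: VertebraMesh,
    up=(0.0, 1.0, 0.0),
    outline: str = "all",
) -> JointFrame:
    """Joint frame from the anterior vertebra's postzygapophyseal facets.

    The COR is the centre of a least-squares sphere through the facet
    vertices of both postzygapophyseal patches (``outline='boundary'``
    restricts the fit to patch boundary vertices). The x-axis runs caudal ->
    cranial between vertebral centroids, y is dorsal (``up`` projected), z
    completes the right-handed frame.
    """
    pts = []
    for label in ("left_post", "right_post"):
        if not anterior.has_patch(label):
            raise ChainError(
                f"anterior vertebra {anterior.name!r} lacks facet patch {label!r}"
            )
        patch = anterior.patch(label)
        if outline == "boundary":
            from .mesh_core.geometry import _patch_boundary_directed

            faces = anterior.mesh.faces[patch.faces]
            idx = np.unique(_patch_boundary_directed(faces))
            pts.append(anterior.mesh.vertices[idx])
        else:
            pts.append(patch.vertices)
    fit = fit_sphere(np.concatenate(pts))
    axes = _series_axes(
        anterior.mesh.vertices.mean(axis=0), posterior.mesh.vertices.mean(axis=0), up
    )
    return JointFrame(
        fit.center,
        axes[:, 0],
        axes[:, 1],
        axes[:, 2],
        anterior=anterior.name,
        posterior=posterior.name,
        fit_radius=fit.radius,
        fit_rms=fit.rms,
    )


def pose_chain(chain: VertebralChain, joint_angles) -> list:
    """Per-vertebra world transforms for the given per-joint angle triples.

    Rotations compose intrinsically as roll -> yaw -> pitch about each ONP
    joint frame; actuating joint j moves vertebrae cranial to j only. The
    all-zero pose returns the ONP transforms exactly.
    """
    angles = np.asarray(joint_angles, dtype=float)
    if angles.shape != (chain.n_joints, 3):
        raise ChainError(
            f"expected {chain.n_joints} (roll, yaw, pitch) triples, got {angles.shape}"
        )
    if not chain.joints:
        raise ChainError("chain has no joint frames (call build_joints first)")
    out = [chain.onp_transforms[0]]
    acc = np.eye(4)
    for j in range(chain.n_joints):
        r, y, p = angles[j]
        if (r, y, p) != (0.0, 0.0, 0.0):
            acc = acc @ chain.joints[j].pose_transform(r, y, p)
        out.append(acc @ chain.onp_transforms[j + 1])
    return out


# -- ONP alignment -----------------------------------------------------------

_PLANES = ((0, 1), (1, 2), (0, 2))  # sagittal (xy), frontal (yz), transverse (xz)


def _silhouette(triangles: np.ndarray, plane: tuple):
    from shapely.geometry import Polygon
    from shapely.ops import unary_union

    polys = []
    for t in triangles:
        p = Polygon(t[:, list(plane)])
        if p.is_valid and p.area > 0:
            polys.append(p)
    return unary_union(polys)


def _patch_sphere_center(vert: VertebraMesh, kind: str) -> np.ndarray:
    pts = np.concatenate(
        [vert.patch(f"{side}_{kind}").vertices for side in ("left", "right")]
    )
    return fit_sphere(pts).center


def align_onp(
    anterior: VertebraMesh,
    posterior: VertebraMesh,
    initial_guess: np.ndarray | None = None,
    overlap_floor: float = 0.5,
    maxiter: int = 400,
) -> tuple[np.ndarray, float]:
    """Refine the anterior vertebra's transform into osteological neutral pose.

    ONP is formalized as: the sphere fitted to the anterior vertebra's
    postzygapophyseal facets is concentric with the sphere fitted to the
    posterior vertebra's prezygapophyseal facets (which pins the
    translation), and the rotation maximizes the mean intersection-over-
    union of the facing facet silhouettes projected on the sagittal,
    frontal and transverse planes. Returns (transform, overlap score);
    raises ChainError if the best pose interpenetrates or scores below
    ``overlap_floor``.
    """
    from scipy.optimize import minimize

    guess = np.eye(4) if initial_guess is None else np.asarray(initial_guess, dtype=float)
    pre_fit = fit_sphere(
        np.concatenate([posterior.patch(f"{s}_pre").vertices for s in ("left", "right")])
    )
    post_fit = fit_sphere(
        np.concatenate([anterior.patch(f"{s}_post").vertices for s in ("left", "right")])
    )
    target_center = pre_fit.center
    # facing facets sit on concentric spheres separated by the facet gap;
    # map the moving facet radially onto the fixed facet's sphere so the
    # projected silhouettes coincide when aligned
    gap_scale = pre_fit.radius / post_fit.radius
    post_body = CollisionBody(posterior.mesh)

    moving0 = anterior.transformed(guess)
    pivot = _patch_sphere_center(moving0, "post")

    fixed_sil = {
        (side, plane): _silhouette(posterior.patch(f"{side}_pre").triangles, plane)
        for side in ("left", "right")
        for plane in _PLANES
    }

    def transform_for(rotvec_deg: np.ndarray) -> np.ndarray:
        from scipy.spatial.transform import Rotation

        R = np.eye(4)
        R[:3, :3] = Rotation.from_rotvec(rotvec_deg, degrees=True).as_matrix()
        T = tf.compose(tf.rotation_about(R, pivot), guess)
        # re-pin concentricity: translate so the facet spheres coincide
        moved_center = tf.apply_transform(T, _patch_sphere_center(anterior, "post")[None])[0]
        return tf.compose(tf.translation(target_center - moved_center), T)

    def score(rotvec_deg: np.ndarray) -> float:
        T = transform_for(rotvec_deg)
        moved = anterior.transformed(T)
        vals = []
        for side in ("left", "right"):
            tri = moved.patch(f"{side}_post").triangles
            tri = target_center + gap_scale * (tri - target_center)
            for plane in _PLANES:
                a = _silhouette(tri, plane)
                b = fixed_sil[(side, plane)]
                union = a.union(b).area
                vals.append(a.intersection(b).area / union if union > 0 else 0.0)
        return float(np.mean(vals))

    res = minimize(
        lambda v: -score(v),
        np.zeros(3),
        method="Nelder-Mead",
        options={
            "maxiter": maxiter,
            "xatol": 1e-3,
            "fatol": 1e-7,
            "initial_simplex": np.vstack([np.zeros(3), np.eye(3) * 2.0]),
        },
    )
    best = transform_for(res.x)
    overlap = score(res.x)
    if overlap < overlap_floor:
        raise ChainError(
            f"ONP refinement failed: facet overlap {overlap:.3f} below floor {overlap_floor}"
        )
    if collide(CollisionBody(anterior.transformed(best).mesh), post_body):
        raise ChainError("ONP refinement failed: vertebrae interpenetrate at optimum")
    return best, overlap


# -- spacing -----------------------------------------------------------------


def _body_submesh(vert_world: VertebraMesh, margin: float = 0.1):
    """Vertebral-body faces: the part of the mesh below the facet patches.

    Components lying entirely below every facet patch are taken as the
    vertebral body; when none qualifies (single-component scan meshes) the
    faces whose centroids lie below the facets are used instead.
    """
    patch_pts = [vert_world.patch(lbl).vertices for lbl in vert_world.facet_patches]
    cutoff = min(p[:, 1].min() for p in patch_pts) - margin
    mesh = vert_world.mesh
    comp = mesh.face_components()
    vert_max_y = {}
    for c in np.unique(comp):
        faces = mesh.faces[comp == c]
        vert_max_y[c] = mesh.vertices[np.unique(faces)][:, 1].max()
    below = [c for c, ymax in vert_max_y.items() if ymax < cutoff]
    if below:
        sel = np.nonzero(np.isin(comp, below))[0]
    else:
        centroids = mesh.face_centroids()
        sel = np.nonzero(centroids[:, 1] < cutoff)[0]
    if not len(sel):
        raise ChainError(f"no vertebral-body faces below facets in {vert_world.name}")
    return mesh.submesh(sel)


def measure_joint_gaps(chain: VertebralChain, j: int, transforms=None) -> dict:
    """Measured minimum body gap and facet gap (mm) at one joint."""
    post = chain.vertebra_world(j, transforms)
    ant = chain.vertebra_world(j + 1, transforms)
    body_gap = min_surface_distance(_body_submesh(post), _body_submesh(ant))
    facet_gap = float("inf")
    for side in ("left", "right"):
        pre = post.patch(f"{side}_pre")
        po = ant.patch(f"{side}_post")
        from .mesh_core import TriMesh

        g = min_surface_distance(
            TriMesh(post.mesh.vertices, post.mesh.faces[pre.faces]),
            TriMesh(ant.mesh.vertices, ant.mesh.faces[po.faces]),
        )
        facet_gap = min(facet_gap, g)
    return {"body_gap": body_gap, "facet_gap": facet_gap}


def _centrum_length(vert: VertebraMesh) -> float:
    body = _body_submesh(vert)
    b = body.bounds()
    return float(b[1][0] - b[0][0])


def check_onp_viability(chain: VertebralChain) -> None:
    """Raise unless the all-zero pose is collision-free and articulated."""
    from .rom_engine import JointContext

    for j in range(chain.n_joints):
        ctx = JointContext(chain, j)
        rec = ctx.classify(0.0, 0.0, 0.0)
        if not rec.viable:
            raise ChainError(
                f"ONP pose not viable at joint {chain.joint_label(j)}: "
                f"collision_free={rec.collision_free}, "
                f"articulated={rec.articulated_left}/{rec.articulated_right}"
            )


def set_spacing(
    chain: VertebralChain,
    body_gap_ratio: float,
    zyg_gap_ratio: float,
    tol: float = 0.005,
    max_iter: int = 12,
    recheck: bool = True,
) -> VertebralChain:
    """Translate vertebrae so measured gap ratios match the targets.

    Ratios are gaps over the mean adjacent centrum length. Each joint gets a
    2-dof correction (series axis, dorso-ventral axis) applied to all
    cranially downstream vertebrae, solved by damped Newton iteration on the
    measured gaps; ``tol`` is in ratio units.
    """
    if body_gap_ratio <= 0 or zyg_gap_ratio <= 0:
        raise ChainError("spacing ratios must be > 0")
    onp = [T.copy() for T in chain.onp_transforms]
    out = VertebralChain(chain.vertebrae, onp)
    for j in range(out.n_joints):
        ref = 0.5 * (
            _centrum_length(out.vertebra_world(j))
            + _centrum_length(out.vertebra_world(j + 1))
        )
        target = np.array([body_gap_ratio * ref, zyg_gap_ratio * ref])
        step = 0.02 * ref

        def residual() -> np.ndarray:
            g = measure_joint_gaps(out, j)
            return np.array([g["body_gap"], g["facet_gap"]]) - target

        def shift(vec3):
            T = tf.translation(vec3)
            for k in range(j + 1, len(out.vertebrae)):
                out.onp_transforms[k] = T @ out.onp_transforms[k]

        for _ in range(max_iter):
            r0 = residual()
            if np.all(np.abs(r0) < tol * ref):
                break
            J = np.zeros((2, 2))
            for col, axis in enumerate((np.array([step, 0, 0]), np.array([0, step, 0]))):
                shift(axis)
                J[:, col] = (residual() - r0) / step
                shift(-axis)
            try:
                delta = np.linalg.solve(J, -r0)
            except np.linalg.LinAlgError:
                raise ChainError(f"spacing adjustment singular at joint {out.joint_label(j)}")
            delta = np.clip(delta, -0.5 * ref, 0.5 * ref)
            shift(np.array([delta[0], delta[1], 0.0]))
        else:
            r = residual()
            if np.any(np.abs(r) >= tol * ref):
                raise ChainError(
                    f"spacing did not converge at joint {out.joint_label(j)}: "
                    f"residual ratios {r / ref}"
                )
        out.spacing.append(measure_joint_gaps(out, j))
    out.build_joints()
    if recheck:
        check_onp_viability(out)
    return out
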