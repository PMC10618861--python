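"""Parametric generator of watertight vertebra meshes and fixture chains.

Vertebrae are stylized, not anatomical: a centrum (polygonal cylinder with
optionally tilted end faces), paired pre- and postzygapophyseal blocks whose
articular surfaces are patches of concentric spheres centred on the intended
joint centre of rotation, optional dorsally pointing lateral ridges on the
prezygapophyses, and a dorsal spinous blade. Because every rotation axis
passes through the facet-sphere centre, facet surfaces slide concentrically
and range of motion is governed by exactly the features the generator
parametrizes: facet footprint extent (disarticulation), ridge height and
facet tilt (roll), centrum end-face tilt (pitch), and spinous height
(dorsal pitch).

Local frame: +x cranial, +y dorsal, +z left. Units are millimetres. All
geometry is deterministic given the seed; left/right structures are exact
mirror images when no noise is requested.

A vertebra is emitted as a disjoint union of closed components (the
components do not touch), which is rigid-body-equivalent to a fused bone for
every downstream computation.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from . import transforms as tf
from .chain_builder import VertebralChain, check_onp_viability
from .mesh_core import TriMesh, VertebraMesh, merge_meshes
from .mesh_core.primitives import box, heightfield_solid

__all__ = [
    "VertebraParams",
    "ChainRecipe",
    "VertebraTruth",
    "ChainTruth",
    "make_vertebra",
    "make_chain",
    "perturb_chain",
    "GeneratorError",
]


class GeneratorError(ValueError):
    pass


@dataclass(frozen=True)
class VertebraParams:
    centrum_length: float = 10.0
    centrum_radius: float = 3.0
    centrum_face_tilt: float = 5.0  # degrees; 0 = square faces
    prezyg_length: float = 4.0
    postzyg_length: float = 3.7  # ~ prezyg_length * Rf / (Rf + gap): nested facets match angularly
    facet_tilt: float = 10.0  # anterior tilt of the facet plane, degrees
    facet_width: float = 2.2
    lateral_ridge_height: float = 0.5
    facet_sphere_radius: float = 6.0
    spinous_height: float = 4.0
    neural_canal_radius: float = 1.5
    body_gap: float = 1.0  # gap to each neighbouring centrum (baked into layout)
    facet_gap: float = 0.5  # radial gap between articulating facet spheres
    seed: int = 0
    noise: float = 0.0  # vertex jitter sd (mm), breaks exact symmetry
    centrum_segments: int = 16  # even
    facet_divisions: tuple = (6, 4)  # grid cells along (x, z) on each facet

    # fixed construction constants
    _plate: float = field(default=0.6, repr=False)
    _ridge_clearance: float = field(default=0.8, repr=False)
    _ridge_width: float = field(default=0.6, repr=False)
    _blade_halfwidth: float = field(default=0.35, repr=False)

    def validate(self) -> None:
        positive = (
            "centrum_length", "centrum_radius", "prezyg_length", "postzyg_length",
            "facet_width", "facet_sphere_radius", "spinous_height",
            "neural_canal_radius", "body_gap", "facet_gap",
        )
        for name in positive:
            if getattr(self, name) <= 0:
                raise GeneratorError(f"{name} must be > 0")
        for name in ("centrum_face_tilt", "facet_tilt"):
            v = getattr(self, name)
            if not (0.0 <= v <= 60.0):
                raise GeneratorError(f"{name} must be within [0, 60] degrees")
        if self.lateral_ridge_height < 0:
            raise GeneratorError("lateral_ridge_height must be >= 0")
        if self.centrum_segments < 6 or self.centrum_segments % 2:
            raise GeneratorError("centrum_segments must be an even number >= 6")
        # derived feasibility
        L, Rc = self.centrum_length, self.centrum_radius
        cut = 2.0 * (self.cor_height + Rc) * np.tan(np.radians(self.centrum_face_tilt))
        if L - cut < 0.2 * L:
            raise GeneratorError(
                "centrum_face_tilt and centrum_length produce self-intersecting "
                "end faces (ventral edges cross)"
            )
        for R, length, what in (
            (self.facet_sphere_radius, self.postzyg_length, "postzyg_length"),
            (self.facet_sphere_radius + self.facet_gap, self.prezyg_length, "prezyg_length"),
        ):
            xoff = R * np.sin(np.radians(self.facet_tilt)) + 0.5 * length
            rho2 = xoff**2 + self.facet_z_out**2
            if rho2 > (0.98 * R) ** 2:
                raise GeneratorError(
                    f"facet footprint ({what}, facet_width, facet_tilt) exceeds "
                    "facet_sphere_radius: facet surface would leave the sphere"
                )
        if self.neural_canal_radius <= self.facet_gap + self._plate + 0.05:
            raise GeneratorError(
                "neural_canal_radius too small for facet_gap: prezygapophyseal "
                "plate would intersect the centrum"
            )

    # -- derived layout ----------------------------------------------------

    @property
    def facet_z_in(self) -> float:
        return self.neural_canal_radius

    @property
    def facet_z_out(self) -> float:
        return self.facet_z_in + self.facet_width

    @property
    def base_height(self) -> float:
        """Lowest point of the postzygapophyseal facet sphere."""
        return self.centrum_radius + self.neural_canal_radius

    @property
    def cor_height(self) -> float:
        return self.base_height + self.facet_sphere_radius

    def cor_caudal(self) -> np.ndarray:
        """Centre of the postzygapophyseal facet sphere (the caudal joint COR)."""
        return np.array(
            [-0.5 * self.centrum_length - 0.5 * self.body_gap, self.cor_height, 0.0]
        )

    def cor_cranial(self) -> np.ndarray:
        """Centre of the prezygapophyseal facet sphere (the cranial joint COR)."""
        return np.array(
            [0.5 * self.centrum_length + 0.5 * self.body_gap, self.cor_height, 0.0]
        )


@dataclass
class VertebraTruth:
    """Generator ground truth for one vertebra (local frame)."""

    params: VertebraParams
    cor_caudal: np.ndarray
    cor_cranial: np.ndarray
    facet_sphere_radius: float
    parts: dict  # part name -> face index array


def _mirror(mesh: TriMesh) -> TriMesh:
    v = mesh.vertices.copy()
    v[:, 2] = -v[:, 2]
    return TriMesh(v, mesh.faces[:, ::-1].copy())


def _cap_y(center: np.ndarray, radius: float, x: np.ndarray, z: np.ndarray) -> np.ndarray:
    rho2 = (x - center[0]) ** 2 + z**2
    if np.any(rho2 >= radius**2):
        raise GeneratorError("facet footprint exceeds facet sphere")
    return center[1] - np.sqrt(radius**2 - rho2)


def _zyg_block(p: VertebraParams, kind: str):
    """One left-side zygapophyseal block (mesh, facet face ids)."""
    tilt = np.radians(p.facet_tilt)
    nfx, nfz = p.facet_divisions
    if kind == "pre":
        radius = p.facet_sphere_radius + p.facet_gap
        center = p.cor_cranial()
        length = p.prezyg_length
        z_lo, z_hi = p.facet_z_in, p.facet_z_out
    else:
        radius = p.facet_sphere_radius
        center = p.cor_caudal()
        length = p.postzyg_length
        # nested facets subtend the same solid angle about the COR: the
        # postzygapophyseal footprint is the prezygapophyseal one scaled
        # radially inward
        s = radius / (radius + p.facet_gap)
        z_lo, z_hi = s * p.facet_z_in, s * p.facet_z_out
    xc = center[0] - radius * np.sin(tilt)
    xs = np.linspace(xc - 0.5 * length, xc + 0.5 * length, nfx + 1)
    zs_facet = np.linspace(z_lo, z_hi, nfz + 1)
    gx, gz = np.meshgrid(xs, zs_facet, indexing="ij")
    cap = _cap_y(center, radius, gx, gz)
    if kind == "post":
        # spherical bottom (the facet), flat top
        top = np.full_like(cap, cap.max() + p._plate)
        mesh, _, bot_ids = heightfield_solid(xs, zs_facet, top, cap)
        return mesh, bot_ids
    # prezygapophysis: spherical top (the facet) plus a lateral ridge strip
    z_r0 = p.facet_z_out + p._ridge_clearance
    zs = np.concatenate([zs_facet, [z_r0, z_r0 + p._ridge_width]])
    gx, gz = np.meshgrid(xs, zs, indexing="ij")
    top = np.empty_like(gx)
    top[:, : nfz + 1] = cap
    edge = cap[:, -1]
    top[:, nfz + 1 :] = (edge + p.lateral_ridge_height)[:, None]
    bottom = center[1] - radius - p._plate
    mesh, top_ids, _ = heightfield_solid(xs, zs, top, np.full_like(top, bottom))
    # facet patch = top cells lying fully within the facet z-range
    top_ids = top_ids.reshape(nfx, nfz + 2, 2)[:, :nfz].ravel()
    return mesh, top_ids


def _centrum(p: VertebraParams) -> TriMesh:
    L, Rc = p.centrum_length, p.centrum_radius
    tan_t = np.tan(np.radians(p.centrum_face_tilt))
    n_half = p.centrum_segments // 2
    theta = np.linspace(0.0, np.pi, n_half + 1)
    y_half = Rc * np.cos(theta)
    z_half = Rc * np.sin(theta)
    # full ring, exact mirror symmetry: top -> +z -> bottom -> -z -> top
    y = np.concatenate([y_half, y_half[-2:0:-1]])
    z = np.concatenate([z_half, -z_half[-2:0:-1]])
    # end faces tilt about a latero-lateral line through the COR height, so
    # the ventral edges angle caudally and the face gap opens with depth
    cut = (p.cor_height - y) * tan_t
    x_cran = 0.5 * L - cut
    x_caud = -0.5 * L + cut
    n = len(y)
    v_cran = np.column_stack([x_cran, y, z])
    v_caud = np.column_stack([x_caud, y, z])
    verts = [v_cran, v_caud]
    faces = []
    for i in range(n):
        k = (i + 1) % n
        # side wall quad (cranial ring 0..n-1, caudal ring n..2n-1)
        faces += [[i, k, n + k], [i, n + k, n + i]]
    c_cran = len(verts[0]) + len(verts[1])
    verts.append(v_cran.mean(axis=0, keepdims=True))
    for i in range(n):
        k = (i + 1) % n
        faces.append([c_cran, k, i])
    c_caud = c_cran + 1
    verts.append(v_caud.mean(axis=0, keepdims=True))
    for i in range(n):
        k = (i + 1) % n
        faces.append([c_caud, n + i, n + k])
    mesh = TriMesh(np.concatenate(verts), np.array(faces, dtype=np.int64))
    if mesh.signed_volume() < 0:
        mesh = TriMesh(mesh.vertices, mesh.faces[:, ::-1])
    return mesh


def _blade(p: VertebraParams) -> TriMesh:
    L = p.centrum_length
    x0, x1 = -0.5 * L + 0.4, 0.5 * L - 1.2
    cap_top = p.cor_height - np.sqrt(
        max(p.facet_sphere_radius**2 - p.facet_z_out**2 - (0.5 * p.postzyg_length) ** 2, 0.0)
    )
    y0 = max(cap_top + p._plate, p.base_height) + p.lateral_ridge_height + 0.3
    return box(
        extents=(x1 - x0, p.spinous_height, 2 * p._blade_halfwidth),
        center=(0.5 * (x0 + x1), y0 + 0.5 * p.spinous_height, 0.0),
    )


def make_vertebra(params: VertebraParams, name: str = "vertebra"):
    """Generate one vertebra; returns (VertebraMesh, VertebraTruth).

    The postzygapophyseal facet vertices lie exactly on a sphere of radius
    ``facet_sphere_radius`` centred on the caudal joint COR (the generator
    ground truth recovered by the sphere fit); prezygapophyseal facets lie
    on a concentric sphere ``facet_gap`` further out.
    """
    params.validate()
    pieces = [("centrum", _centrum(params), {})]
    pre_mesh, pre_patch = _zyg_block(params, "pre")
    post_mesh, post_patch = _zyg_block(params, "post")
    pieces.append(("left_prezyg", pre_mesh, {"left_pre": pre_patch}))
    pieces.append(("right_prezyg", _mirror(pre_mesh), {"right_pre": pre_patch.copy()}))
    pieces.append(("left_postzyg", post_mesh, {"left_post": post_patch}))
    pieces.append(("right_postzyg", _mirror(post_mesh), {"right_post": post_patch.copy()}))
    pieces.append(("spinous", _blade(params), {}))

    meshes, parts, patches = [], {}, {}
    offset = 0
    for part_name, mesh, patch in pieces:
        meshes.append(mesh)
        parts[part_name] = np.arange(offset, offset + len(mesh.faces), dtype=np.int64)
        for label, ids in patch.items():
            patches[label] = np.asarray(ids, dtype=np.int64) + offset
        offset += len(mesh.faces)
    merged = merge_meshes(meshes)
    if params.noise > 0:
        rng = np.random.default_rng(params.seed)
        merged = TriMesh(
            merged.vertices + rng.normal(0.0, params.noise, merged.vertices.shape),
            merged.faces,
        )
    vert = VertebraMesh(merged, name, patches)
    truth = VertebraTruth(
        params,
        params.cor_caudal(),
        params.cor_cranial(),
        params.facet_sphere_radius,
        parts,
    )
    return vert, truth


@dataclass(frozen=True)
class ChainRecipe:
    """Recipe for a caudal->cranial fixture chain.

    ``overrides`` maps a vertebra index to a dict of VertebraParams fields,
    allowing cranio-caudal gradients. The facet sphere geometry
    (centrum_radius, neural_canal_radius, facet_sphere_radius) must be
    uniform so facing facets are concentric at ONP.
    """

    n_vertebrae: int = 4
    base: VertebraParams = field(default_factory=VertebraParams)
    overrides: dict = field(default_factory=dict)
    body_gap_ratio: float = 0.10
    zyg_gap_ratio: float = 0.05
    noise: float = 0.0
    seed: int = 0

    def vertebra_params(self) -> list:
        if self.n_vertebrae < 2:
            raise GeneratorError("a chain needs at least 2 vertebrae")
        out = []
        for i in range(self.n_vertebrae):
            p = replace(self.base, **self.overrides.get(i, {}))
            out.append(p)
        ref = float(np.mean([p.centrum_length for p in out]))
        bg = self.body_gap_ratio * ref
        gf = self.zyg_gap_ratio * ref
        out = [
            replace(p, body_gap=bg, facet_gap=gf, noise=self.noise, seed=self.seed + i)
            for i, p in enumerate(out)
        ]
        for p in out[1:]:
            for name in ("centrum_radius", "neural_canal_radius", "facet_sphere_radius"):
                if getattr(p, name) != getattr(out[0], name):
                    raise GeneratorError(
                        f"{name} must be uniform along a chain (facet spheres "
                        "must be concentric at ONP)"
                    )
        return out


@dataclass
class ChainTruth:
    recipe: ChainRecipe
    cors_world: list  # per joint, 3-vectors
    facet_sphere_radius: float
    vertebra_truths: list


def make_chain(recipe: ChainRecipe, names=None, check: bool = True):
    """Build a fixture chain in ONP; returns (VertebralChain, ChainTruth)."""
    plist = recipe.vertebra_params()
    if names is None:
        # caudal -> cranial naming, e.g. C5, C4, C3, C2 for 4 vertebrae
        names = [f"C{recipe.n_vertebrae - i + 1}" for i in range(recipe.n_vertebrae)]
    verts, truths, onp = [], [], []
    x = 0.0
    for i, p in enumerate(plist):
        if i > 0:
            x += 0.5 * plist[i - 1].centrum_length + p.body_gap + 0.5 * p.centrum_length
        v, t = make_vertebra(p, names[i])
        verts.append(v)
        truths.append(t)
        onp.append(tf.translation([x, 0.0, 0.0]))
    chain = VertebralChain(verts, onp)
    chain.spacing = [
        {"body_gap": plist[j + 1].body_gap, "facet_gap": plist[j + 1].facet_gap}
        for j in range(chain.n_joints)
    ]
    chain.build_joints()
    cors = [
        tf.apply_transform(onp[j + 1], truths[j + 1].cor_caudal[None])[0]
        for j in range(chain.n_joints)
    ]
    truth = ChainTruth(recipe, cors, plist[0].facet_sphere_radius, truths)
    if check:
        check_onp_viability(chain)
    return chain, truth


def perturb_chain(
    chain: VertebralChain,
    onp_rotation_sd: float = 0.0,
    spacing_scale: float = 1.0,
    seed: int = 0,
    max_retries: int = 10,
) -> VertebralChain:
    """Random small ONP rotations and scaled inter-vertebral spacing.

    Used by sensitivity sweeps. Rotations (sd in degrees) are applied about
    each vertebra's centroid; spacing_scale scales the caudal->cranial
    translation deltas. The perturbed chain must remain ONP-viable; the
    perturbation is resampled up to ``max_retries`` times, then raises.
    """
    if onp_rotation_sd < 0 or spacing_scale <= 0:
        raise GeneratorError("need onp_rotation_sd >= 0 and spacing_scale > 0")
    if onp_rotation_sd == 0.0 and spacing_scale == 1.0:
        return chain
    from .chain_builder import ChainError

    from .chain_builder import measure_joint_gaps

    rng = np.random.default_rng(seed)
    # scale the inter-vertebral BODY GAP, not the whole translation delta
    if chain.spacing:
        gaps = [s["body_gap"] for s in chain.spacing]
    else:
        gaps = [measure_joint_gaps(chain, j)["body_gap"] for j in range(chain.n_joints)]
    last_err = None
    for _ in range(max_retries):
        onp = []
        prev_old = None
        prev_new = None
        for i, T in enumerate(chain.onp_transforms):
            pos = T[:3, 3]
            if i == 0:
                new_pos = pos
            else:
                delta = pos - prev_old
                direction = delta / np.linalg.norm(delta)
                new_pos = prev_new + delta + (spacing_scale - 1.0) * gaps[i - 1] * direction
            prev_old, prev_new = pos, new_pos
            T2 = T.copy()
            T2[:3, 3] = new_pos
            if onp_rotation_sd > 0:
                ang = abs(rng.normal(0.0, onp_rotation_sd))
                R = tf.random_rotation(rng, ang)
                centroid = tf.apply_transform(T2, chain.vertebrae[i].mesh.vertices).mean(axis=0)
                T2 = tf.compose(tf.rotation_about(R, centroid), T2)
            onp.append(T2)
        out = VertebralChain(chain.vertebrae, onp)
        out.build_joints()
        try:
            check_onp_viability(out)
            return out
        except ChainError as err:
            last_err = err
    raise GeneratorError(f"perturbation kept breaking ONP viability: {last_err}")
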