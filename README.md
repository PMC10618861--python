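# osteorom

Automated, exhaustive assessment of osteological intervertebral range of
motion (ROM) for vertebral chains given as triangle meshes.

Given per-vertebra watertight meshes (OBJ/PLY/STL) with zygapophyseal
facet-patch annotations — or fully synthetic chains from the built-in
parametric generator — osteorom:

1. arranges the vertebrae in an **osteological neutral pose** (ONP: facing
   facet silhouettes aligned, facet spheres concentric) and adjusts
   inter-vertebral spacing to requested body/facet gap ratios;
2. places a **joint coordinate system** at each joint's centre of rotation,
   defined as the centre of a least-squares sphere fitted to the anterior
   vertebra's postzygapophyseal facets (x = roll about the series long axis,
   y = yaw, z = pitch);
3. **exhaustively samples interacting roll/yaw/pitch rotations** on a fixed
   grid (default 2° steps) per joint, classifying every pose as viable iff
   the adjacent bone meshes do not intersect *and* the moving vertebra still
   intersects the left and right articulation gap volumes (prisms extruded
   from the prezygapophyseal facets — disarticulation at 0% facet overlap);
4. maps viable poses into a **cosine-corrected pose space**
   `(roll·cos yaw, yaw, pitch)`, hulls them with a 3-D **alpha shape**
   (alpha = 50, or the critical alpha when larger) whose volume in cubed
   degrees quantifies overall joint mobility, and sums per-joint extrema
   into whole-chain ROM figures;
5. composes **maximum neck-turn** poses (lexicographic yaw > roll > pitch,
   with optional joint exclusion) and exports spherical-frame-projection
   (SFP) point clouds and static plots.

The geometry core (mesh I/O, validation, quadric decimation, tri–tri
collision with a voxel-overlap verification oracle, Delaunay alpha shapes)
is implemented in-package on numpy/scipy/shapely.

## CLI

```bash
rom fixtures --out fix/ --n-vertebrae 4          # synthetic chain + ground truth
rom sweep --chain fix/chain.yaml --out sweeps/   # exhaustive per-joint pose CSVs
rom analyze --chain fix/chain.yaml --sweeps sweeps/ --out report/
rom max-turn --chain fix/chain.yaml --sweeps sweeps/ --exclude C8-C7 --out turn.json
rom sensitivity --out sens/                      # ONP/spacing perturbation sweep
rom demo --out demo/                             # end-to-end 3-joint fixture run
```

Chain definitions are YAML files listing ordered caudal→cranial mesh paths,
facet annotation sidecars (`{patch label: [face indices]}` for
`left_pre/right_pre/left_post/right_post`), per-vertebra 4×4 ONP transforms
and spacing. Every run writes a reproducibility manifest (config + package
version + config hash); all randomness flows from the single `--seed`.

## Working with specimen scans

Scanned vertebrae can be used directly: clean/decimate
(`osteorom.mesh_core.decimate_mesh`, watertightness enforced, facet patches
re-mapped), annotate the four facet patches per vertebra in a sidecar YAML,
list the meshes caudal→cranial in a chain YAML, refine the manual placement
with `rom build-chain --refine-onp`, then sweep and analyze as above.
Occiput–C1 and C1–C2 joints are out of scope (atlas anatomy breaks the
facet-based articulation criterion).
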