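# wristkin

Carpal-bone kinematics from segmented surface models.

The wrist's eight carpal bones (scaphoid, lunate, triquetrum, pisiform,
trapezium, trapezoid, capitate, hamate) move in a coupled, fully
three-dimensional way that two nominal degrees of freedom —
flexion-extension (FE) and radial-ulnar deviation (RUD) — only coarsely
describe. Given per-position surface models of the radius and the carpal
bones (e.g. segmented from MRI) plus two radius landmarks, `wristkin`
reconstructs each bone's rigid displacement from the neutral wrist
position and describes it by its **helical (screw) axis**, the
coordinate-invariant line about which the bone rotates and along which
it translates. The package targets biomechanics researchers who want a
tested, scriptable reference implementation of this analysis — and a
synthetic wrist generator with known ground truth for validating every
stage by parameter recovery.

## Method

1. **Radius-based registration.** Every scan's radius surface is turned
   into a point cloud, down-sampled to ~3000 points and rigidly aligned
   to a per-hand reference radius with **coherent point drift** (CPD):
   the source points are Gaussian-mixture centroids moved coherently by
   one rigid transform (scale fixed at 1, uniform outlier component),
   fitted to the target cloud by EM. The resulting transform 𝓣 is
   propagated to that scan's carpal meshes, so all scans share the
   reference attitude while intra-scan geometry is untouched.
2. **Frames.** The radius frame: X along the radial long axis (smallest
   principal moment of inertia, pointing distally), Y toward the radial
   styloid (the FE axis), Z = X × Y (palmar, the RUD axis), origin at
   the projection of the distal epicondyle onto the X line. Each carpal
   bone, treated as a homogeneous dense solid, carries its centroid and
   principal inertial axes as an intrinsic landmark-free frame; axis
   signs are unified across positions of one protocol. Left hands are
   mirrored across the radius frame's sagittal plane so both hands share
   one sign convention (flexion +, radial deviation +, pronation +).
3. **Helical axis.** For the displacement (R, t) of a bone from neutral,
   the rotation angle is θ = atan2(‖a‖, (tr R − 1)/2) with a the axial
   vector of (R − Rᵀ)/2, the axis direction n = a/‖a‖, the slide s = n·t
   and the axis point the unique p ⊥ n with (I − R)p = t − s n. The
   rotation is additionally decomposed into intrinsic Cardan angles
   about the radius frame's Y (FE), Z (RUD) and X (pro-/supination) axes.
4. **Descriptors and statistics.** Bone-to-radius distance ‖Cₐ − O_R‖₂;
   per-position mean/sd tables for the pooled, left and right groups;
   and a paired t-test t = D̄/(σ̂/√n) between hands per bone × position ×
   quantity — 128 p-values for a complete protocol; bone-volume tables
   with the population (divisor n) standard deviation.

The synthetic generator (`wristkin.synthetic`) emits complete scenarios
— 5 subjects × 2 hands, FE at 0°/±30°/±60° and RUD at 0°/+10°/±20°/−40°,
per-scan pose perturbation and vertex noise — built from known per-bone
screws, so the pipeline's output can be compared against exact ground
truth.

## Worked example

`examples/04_full_pipeline.py` generates a one-subject scenario with
known screws, runs the full pipeline and prints (abridged):

```
48 kinematics records (8 bones x 3 non-neutral positions x 2 hands)

  subject hand      bone position  ha_angle_deg  ha_translation_mm  fe_deg
0    sub1    L  capitate      F30        21.870             -0.782  21.652
2    sub1    L    lunate      F30        13.906             -0.548  13.690
...
max |recovered - true| rotation angle: 1.69e-10 deg
```

At 30° flexion the capitate rotates ~22° about its helical axis with a
0.8 mm slide, the lunate ~14° — the distal row tracks the wrist, the
proximal row moves less — and with no measurement noise the pipeline
reproduces the generator's ground-truth screws to ~1e-10 degrees.
`examples/05_left_right_statistics.py` prints the study-style summary
table and reports `p-values below 0.05: 5 / 128` — with left hands equal
to right up to noise, about 5% of the paired tests cross 0.05 by chance.

Other examples: mass properties vs closed forms (`01`), helical-axis
extraction and decomposition (`02`), CPD registration recovery (`03`).
A thin CLI wraps the same library calls:

```bash
wristkin simulate --seed 1 --out scenario/
wristkin run --manifest scenario/manifest.yaml --out results/
wristkin report --in results/
```

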