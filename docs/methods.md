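# Methods

This note documents the models, conventions and numerical choices behind
`wristkin`, and what the synthetic validation does and does not show.

## Geometry and mass properties

All geometry is in millimetres. Bone surfaces are closed, consistently
oriented triangle meshes; `load_mesh` accepts STL/PLY/OFF, welds
duplicated STL vertices, repairs a globally inverted orientation (signed
volume < 0) and refuses non-manifold surfaces. Face indices are 0-based
internally regardless of file dialect.

Bones are treated as homogeneous solids of unit density: only the
centroid, the principal-axis directions and the *ratios* of moments
matter downstream, none of which depend on the density value. Volume,
centroid and the centroidal inertia tensor come from exact
signed-tetrahedron (divergence-theorem) integrals over the faces;
principal moments are the eigenvalues sorted descending, the axes the
corresponding eigenvectors made right-handed. Moments within 1e-6
relative are flagged near-symmetric: the frame then carries no shape
information in the degenerate plane and downstream code treats such
axes as arbitrary (for the radius frame only the *long* axis —
smallest moment — must be separated, so cylinder-like radii are fine).

Principal axes are defined up to sign. `unify_axis_signs` picks, among
the four column-sign patterns that keep det = +1, the one maximizing
trace(referenceᵀ·frame); ties (only possible for 90°-symmetric inputs)
resolve toward fewer flips with a warning. Within one subject, hand and
protocol, every bone's frames are unified against that bone's
neutral-position frame; the neutral frame itself uses a canonical rule
(first nonzero component of each axis positive, right-handedness
restored on the last axis).

## Registration

Rigid coherent point drift, authored here: source points are isotropic
Gaussian-mixture centroids with shared variance σ², moved by one rigid
transform (scale locked at 1 — same bone, same subject; anisotropic
scaling would be unphysical), plus a uniform outlier component of weight
w. EM alternates soft correspondences with a closed-form weighted
Procrustes update; convergence when the relative change of the negative
log-likelihood drops below `tol`. Defaults: w = 0.1, tol = 1e-8,
max_iter = 150. The E-step kernel is negligible beyond 7σ (exp(−24.5) ≈
2e-11, below `tol`), so for large clouds with small σ it is assembled
sparsely from a KD-tree neighbour search; this changes nothing
numerically at the stated tolerance. The pipeline warm-starts EM from a
centroid/principal-axes pre-alignment (best of the four proper sign
patterns by nearest-neighbour cost) and then initialises σ² from
post-init nearest-neighbour residuals; `cpd_rigid` called without an
initial transform uses the standard all-pairs initialisation.

Two down-sampling rules exist, both deterministic and seed-free:

- `downsample`: voxel-grid binning with centroid representatives, pitch
  solved by bisection to land within 10% of the target count.
- `stride_downsample`: every k-th stored point.

The pipeline uses the stride rule (target 3000 points, applied to scan
and reference clouds alike). The reason is measured, not aesthetic:
voxel representatives are re-quantized in each cloud's own pose, so two
independently voxelized copies of the same surface are *different*
samplings of it, and the GMM fit then shows a bias of up to ~2° in the
least-constrained mode (twist about the radius' long axis); a voxel
cloud registered against a full-resolution cloud retains a ~1e-3 rad
systematic offset from the centroids' inward bias. The stride rule
applies the identical selection to every cloud, so rigid copies remain
corresponding point sets and the registration is unbiased. Registration
groups are per hand; left and right radii are never co-registered
(mirror geometry). Each scan registers directly to the reference
(no within-subject chaining); the reference defaults to subject 1's
neutral FE scan of each hand.

Propagation applies the scan's transform to every carpal vertex;
connectivity untouched, so intra-scan inter-bone geometry is exactly
preserved.

## Frames, mirroring and sign conventions

Radius frame: X = smallest-moment principal axis (the long axis — the
operational definition adopted here), oriented from the centroid toward
the distal epicondyle landmark; Y = unit component of (styloid −
centroid) orthogonal to X; Z = X × Y; origin = projection of the
epicondyle landmark onto the X line ("intersection of the axis with the
epicondyle" names a surface, so the projection of the picked point is
used). Landmarks are inputs: the generator emits them, real use requires
manual picking; automatic detection is out of scope. Whether X points
proximally or distally only flips reporting signs; distal is chosen and
pinned by the sign-convention tests.

Left hands are reflected across the radius frame's Y = 0 (sagittal)
plane before kinematic analysis, with face winding flipped to keep
outward normals. Reflecting across the plane whose normal is the frame's
own Y axis is an involution that maps the left-hand frame onto a
right-convention frame exactly, so both hands share flexion +, radial
deviation +, pronation + and their records can be pooled and paired.

## Helical axis and decomposition

The displacement of a bone from neutral is formed directly from its
frames: R = A_moved·A_neutralᵀ, t maps the neutral centroid onto the
moved one. This equals the least-squares rigid fit of the four markers
{centroid, centroid + each axis tip} in the noiseless case (tested), and
those markers are exactly what the frames encode. Angle via
atan2(‖a‖, (tr R − 1)/2) — numerically stable at small angles; near
θ = π (impossible within the wrist's range of motion, handled for
completeness) the direction comes from the dominant column of R + I.
The axis point solves (I − R)p = t − (n·t)n via the half-angle closed
form p = ½(t⊥ + (n × t⊥)/tan(θ/2)), then the p·n = 0 convention is
re-applied in whatever frame the point is reported in. Rotations below
1e-8 rad are pure translations: flagged degenerate, direction = t/‖t‖,
axis point reported at the neutral centroid.

The (n, θ) ↔ (−n, −θ) ambiguity is fixed by orienting n toward the
motion's nominal radius axis (Y for FE, Z for RUD) and keeping the
right-hand-rule sign, which makes flexion/radial deviation positive and
extension/ulnar deviation negative — verified bone-by-bone in the
synthetic scenario. The translation along the axis is signed by the
oriented direction. Cardan decomposition uses the intrinsic sequence
Y → Z → X (primary motion first; configurable), refusing |FE| or |RUD|
≥ 90° (gimbal region, outside the wrist RoM). Mean axis directions are
the principal eigenvector of Σnᵢnᵢᵀ — invariant to per-axis sign flips —
oriented by the motion reference axis.

## Statistics

Tables use the sample sd (divisor n − 1); the paired t-test is
t = D̄/(σ̂/√n) with the sample sd of the differences, two-sided p from
Student's t with n − 1 df (the test is stated one-threshold in the
emulated study; two-sided is the conservative reading). No
multiple-testing correction is applied, mirroring the study's report of
128 raw p-values. Degenerate cases: all-zero differences give t = 0,
p = 1; zero sd with nonzero mean gives t = ±∞, p = 0, flagged. Subjects
missing one hand at a position are excluded from that pair test and
logged.

Bone-volume tables are the per-subject mean across positions and hands,
summarised with the arithmetic mean and the *population* (divisor n)
standard deviation — the convention verified analytically against the
emulated study's printed SD row for all eight bones. The printed *mean*
row of that table is inconsistent with the arithmetic mean of its own
per-subject values (e.g. scaphoid 1961.5 printed vs 2172.2 computed)
while the SD row matches the population sd exactly; this package reports
the arithmetic mean and documents the discrepancy rather than
reproducing it.

## Synthetic scenarios: what they emulate and what they do not

The generator reproduces the study conditions: 5 subjects × 2 hands, FE
scans at 0°/±30°/±60°, RUD at 0°/+10°/±20°/−40°, a global per-scan pose
disturbance (up to 15° and 20 mm, emulating scanner/arm placement), and
0.1 mm iid Gaussian vertex noise. Left-hand geometry is the mirror image
of a right-convention scene drawn with the same per-subject motion
parameters and independent per-hand noise, which makes the left/right
paired tests an exact null — the basis of the calibration check (the
fraction of 128 p-values below 0.05 across replicates sits in the
binomial band around 5%).

Bones are ellipsoids, not anatomical shapes: every downstream quantity
(inertial frames, screws, distances) is shape-agnostic, and ellipsoids
carry analytic volume/inertia oracles. Semi-axes are strongly triaxial
(~1 : 0.78 : 0.40, both principal-moment gaps near 30%) so the inertial
frames are well conditioned against vertex noise, with per-subject size
scaling in [0.85, 1.15] loosely echoing real volume spread. The radius
is one shared template per hand — an elongated ellipsoid with a
styloid-like process, dorsal tubercle, notch, interosseous-crest ridge
and a gentle shaft bend, i.e. as asymmetric as a real distal radius,
which is what pins the registration's soft twist mode. The template is
shared across subjects deliberately: two differently-shaped radii have
no ground-truth rigid alignment, so per-subject radius shape would make
exact recovery ill-defined; the generator isolates rigid-motion
recovery. Cartilage is not generated (its role is descriptive, not
computed). Default mesh resolutions are icosphere subdivision 5
(10242 vertices) for radius and bones — the level at which curved-solid
mass properties agree with closed forms to 0.1% and frame noise at
0.1 mm vertex noise stays well inside the recovery bounds.

The motion model is a caricature: distal-row bones track the wrist angle
about the motion's nominal axis (capitate gain largest), the proximal
row moves with smaller gains, and during RUD the scaphoid, lunate and
triquetrum receive FE-dominant screws; slides stay within ~3 mm. Base
gains and slides echo the magnitudes reported for real wrists; per-hand
jitter is additive (0.3° angle, 0.1 mm slide) so that no nominal screw
can flip sign and the null differences are exactly normal. Passing
recovery tests therefore demonstrates the correctness of the *pipeline
mathematics* under realistic noise — not the anatomical realism of
carpal motion, ligament or contact constraints, which are out of scope.

## Validation summary

With zero noise and zero perturbation the pipeline reproduces every
ground-truth screw parameter to better than 1e-9 (angle in degrees,
slide and axis point in mm, direction components), including through the
left-hand mirror path; under the default noise and perturbations the
rotation-angle error stays below 0.5° and the axis-direction error below
2° for rotations of at least 10°. Registration recovers noiseless rigid
transforms to ~1e-6 rad, and a 3000-point down-sample registers within
0.2°/0.2 mm of the full-cloud result. The test suite recomputes all of
these plus the closed-form and brute-force oracles cited above; the
problem sizes used there (two to five subjects, subdivision-3 to -5
meshes) are the package's own choice of desk-scale validation.

## Known limitations

- CPD is local: it relies on the inertia pre-alignment (or a good
  initial transform) for large misalignments; group-wise unbiased
  registration and non-rigid variants are out of scope.
- Instantaneous helical axes between adjacent positions are not
  computed (neutral-referenced axes only), matching the analysis the
  package reproduces.
- Real segmented bones violate the generator's assumptions (shape
  change across positions, segmentation artefacts, cartilage); the
  recovery bounds quoted above do not automatically transfer.
- The paired test assumes matched subjects with both hands; n = 5 gives
  the t-test little power, which is inherent to the emulated design.
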