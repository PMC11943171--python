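# Methods

`radsym` quantifies bilateral (left–right) symmetry and population
variability of distal-radius surface meshes with a landmark-free
morphometric pipeline: rigid standardisation, control-point diffeomorphic
registration with a varifold data term, deterministic atlas (mean-shape)
estimation, signed correspondence-distance statistics, and kernel PCA of the
deformation momenta with a nonparametric test cascade. Because the CT cohort
it emulates is not publicly deposited, all quantitative validation runs on
synthetic distal-radius phantoms with known ground truth; the published
per-patient summary tables are bundled and used to validate the aggregation
rules only.

## Rigid preprocessing

A left/right pair is standardised in four steps:

1. **Mirroring.** The right mesh's x-coordinates are negated and face
   winding flipped, so both sides share chirality.
2. **Axis alignment and length.** Each bone is rotated so the first
   principal axis of its vertex cloud lies along +z (Rodrigues' rotation
   about `cross(axis, z)`), with the articular end — the end nearer the RS
   landmark — toward +z. The minimum-z vertex is translated to the origin
   and the distal-most 50 mm kept.
3. **Landmark alignment.** The mirrored right bone is rigidly aligned onto
   the left by least squares (Kabsch, rotations only — no scaling or
   reflection) over three correspondences: the radial styloid (RS), the
   distal styloid notch (DSN), and the mesh centroid (unweighted vertex
   mean). Because the centroid of a per-side crop depends on that side's own
   crop window, the centroid correspondence is refined on identically
   cropped meshes: after the first alignment the final 43 mm crop plane is
   fixed in the common frame, centroids are recomputed on both crops, and
   the alignment is re-estimated (up to three passes; it converges in one
   or two). Without this refinement the crop-window offset leaks into the
   alignment as a spurious rotation whose lever arm inflates distances at
   the proximal end.
4. **Final crop and resolution.** Both meshes are cut at the same plane
   43 mm below the distal end (clipping crossing faces with interpolated
   vertices, so the cut is geometrically exact), decimated to a common
   vertex budget (5,295 by default) by quadric edge collapse, and the cut
   rim is then sealed with a planar centroid fan.

Two choices here deserve emphasis, both made after the open cut proved to
be the dominant source of spurious deformation:

* **Capping.** An open boundary is nearly invisible to the varifold metric,
  which gives the registration cheap "curl" modes at the rim; on coarse
  phantom pairs these inflated measured deformations several-fold. Sealed
  surfaces remove those modes. Capping also matches how surfaces extracted
  from cropped label volumes by marching cubes behave (they are closed).
* **Decimate, then cap.** Decimation runs on the open crop with standard
  boundary-constraint quadrics (perpendicular plane per boundary edge), so
  the rim keeps its outline; the cap fan is built on the decimated rim.
  Capping first would let the large flat cap decimate differently on the
  two sides and slide tangentially during registration.

The articular surface is the sub-mesh distal of the plane through the DSN
landmark perpendicular to the bone axis (vertex predicate `z >= z(DSN)`).

For atlas runs, every mesh (right sides mirrored first) is standardised the
same way and rigidly aligned to the first subject's right bone using RS,
DSN, DDR and the centroid.

## Deformation model and registration

The deformation is the control-point LDDMM/geodesic-shooting model: control
points `c` on a regular grid carry momenta `alpha`; the velocity field is
`v(x) = sum_j K(x, c_j) alpha_j` with the Gaussian kernel
`K(x, y) = exp(-|x - y|^2 / sigma_V^2)` — note there is **no factor 2** in
the denominator, so kernel widths quoted here are in that convention. The
Hamiltonian equations are integrated over unit time with a midpoint (RK2)
scheme on `T` time points; mesh vertices are transported through the same
flow. Energy (the Hamiltonian) is conserved to well under 1% at `T = 10`.

The data term is the unoriented varifold discrepancy with the Cauchy–Binet
(squared-cosine) normal kernel on face centers/area-weighted normals and a
Gaussian spatial kernel of width `sigma_W`. The cost is

    C(alpha) = d_W^2(flow(source), target) / (2 sigma_eps^2) + H(c, alpha).

Defaults follow the configuration of the study being emulated: deformation
kernel width `sigma_V = 2 mm`, attachment width `sigma_W = 4 mm`, noise std
`sigma_eps = 0.0005 mm`, `T = 10` time points, convergence tolerance `1e-4`
(relative cost change), frozen control points. `sigma_eps = 0.0005` makes
the data term dominate by ~6 orders of magnitude; it is retained as the
default for fidelity, but it is badly conditioned on coarse or noisy
meshes, and the parameter is an explicit knob. On decimated desk-scale
meshes (600–1,000 vertices, surface discretisation error ~0.1 mm) a noise
std commensurate with that error is the statistically sensible setting.

Gradients of the cost with respect to the initial momenta (and, for free
templates, the template vertices) are exact discrete adjoints — hand-derived
vector–Jacobian products back-propagated through each RK2 step — and agree
with central finite differences to ~1e-8 relative on small systems (the
test suite enforces 1e-4).

Two optimisers are provided:

* `gradient_descent` (default): steepest descent with a backtracking line
  search (halve on failure, grow 1.5x on success; first step bounded by
  0.1 sigma_V), stopping at the relative-cost tolerance. Its early stopping
  acts as implicit regularisation: it does not chase the varifold
  discrepancy floor that two independently decimated triangulations of the
  same surface always retain, which matters because the extreme default
  data weight makes that floor worth more than any kinetic-energy penalty.
* `lbfgs`: quasi-Newton minimisation. It reaches far lower attachment values
  and much tighter point-to-point recovery on clean oracle problems
  (sphere-translation recovery ~0.03 mm vs ~0.5 mm for steepest descent),
  but on coarse real-world-like pairs it converts the discrepancy floor
  into tangential drift that inflates the symmetry statistic. The
  registration-correctness oracles therefore use `lbfgs`, while the
  cohort statistics pipelines use `gradient_descent`.

Control points are a regular grid at `sigma_V` spacing by default, pruned
of points farther than two spacings from the surface. Desk-scale runs use a
4 mm grid pruned at ~2 kernel widths (K ≈ 250–350 on a 43 mm phantom);
points farther out exert essentially no velocity on the surface
(`exp(-(4/2)^2) ≈ 0.02`). One grid is shared by all subjects of a cohort
run so the flattened momenta are directly comparable across subjects.

## Statistics

The symmetry statistic is the per-vertex signed correspondence distance
between a source mesh and its deformed image: magnitude = Euclidean
distance, sign = sign of the displacement's component along the source's
outward vertex normal (positive = outward). Subject summaries (mean, SD,
max, median) are taken over |signed distance|; the sign is kept for surface
maps and boxplots (outliers flagged above the 99.8th percentile). Group
tables report the unweighted mean of per-subject means; the cohort row is
the unweighted mean over all subjects. This aggregation reproduces the
published cohort values (0.53 mm pairwise whole-bone, 0.98/0.65 mm atlas
whole/articular) from the bundled per-patient tables to printed precision.

For group analysis the per-subject momenta are flattened, each column
z-scored (zero-variance columns set to 0), and RBF-kernel PCA applied with
`gamma = 1 / (n_features * Var(X))` by default. Tests on the PC scores:
Shapiro–Wilk normality per PC, Kruskal–Wallis across the four sex/age
groups, and all six pairwise Welch t-tests, at the 0.05 level with raw
p-values (a Holm option exists, off by default, mirroring the original
analysis which reported uncorrected values).

Statistical calibration runs at the momenta level rather than through full
pipeline replicates: subjects are drawn from a six-factor latent model
(smooth deformation fields are low-rank — the generator's own subject
variation uses six harmonics) and pushed through the identical
standardise → kPCA → test code path. The null type-I error of the
Kruskal–Wallis test sits at the nominal 5%; a sex-linked offset field twice
the within-group deformation scale is detected by all four cross-sex Welch
contrasts at p < 0.01 in essentially every replicate. "Twice the
within-group scale" is interpreted as a field whose magnitude is 2x the RMS
magnitude of the subject-variation field, which is the natural reading for
deformation offsets; an offset of 2 SD along a single feature axis would be
undetectable in principle at these sample sizes.

## The phantom generator

The phantom is a stylised distal radius: a superellipse-section tube
(shaft radius 7 mm, slight dorso-volar flattening) of 60 mm pre-crop
length, a smooth epiphyseal flare (scale 1.8) toward the distal end, a
styloid bump (4 mm, RS at its apex), an ulnar notch (DSN at its floor), a
dorsal rim point (DDR), and a rounded distal dome closing the articular
end. Landmarks are snapped to mesh vertices. It is not anatomically exact;
its purpose is controlled ground truth at realistic scale (43 mm analysed
length, ~5,300 vertices after preprocessing at full budget).

Pairs: the right side is the mirrored left displaced by a seeded
radial-basis field (10 Gaussian centers, 6 mm width — commensurate with the
sigma_V = 2 mm deformation model) rescaled so its mean vertex magnitude
equals the requested asymmetry amplitude exactly; each side then receives a
random rigid pose (rotations up to 30 degrees, translations up to 20 mm —
large enough to exercise alignment, small enough to keep the principal axis
unambiguous). Cohorts follow the emulated design: 2 sexes x 2 age bands,
n = 10 per group by default, per-subject smooth shape variation (six
seeded harmonics, 1 mm scale), group-specific smooth offsets (a sex-linked
pattern and a weaker age-linked pattern), and per-subject asymmetry
amplitudes uniform in 0.3–0.8 mm, matching the range of the published
per-patient means. Everything is a pure function of (parameters, seed), and
every pair ships its exact per-vertex displacement field.

What the phantom does **not** model: CT noise and partial-volume effects,
manual segmentation variability, trabecular interiors, real articular
geometry, pathology. Passing the synthetic studies therefore demonstrates
that the pipeline machinery recovers known truth under the stated noise
sources (pose, decimation, landmark displacement by the asymmetry field),
not that it certifies clinical accuracy on real CT data.

## Problem sizes and known limitations

Desk-scale runs use ~900-vertex generated phantoms analysed at ~600
vertices with a 4 mm control grid; the generator's defaults remain at the
realistic ~9,000/5,295-vertex budget. Scaling down has one important
consequence: the varifold discrepancy floor between two independently
decimated triangulations grows with edge length, and the registration noise
floor of the symmetry statistic is empirically ~0.2x the mean edge length
(~0.13 mm at 600 vertices, projected ~0.05 mm at the full budget).

The dominant systematic error of the pairwise statistic is not
registration but **alignment residual**: the three-point rigid alignment
uses two landmarks near the distal end, so landmark displacement by the
very asymmetry being measured tips the bone slightly and the lever arm
inflates distances toward the proximal end. The original study observed
exactly this pattern (largest deviations in the metaphyseal region,
distances growing proximally from the landmarks); the phantom reproduces
it. Consequently recovered cohort means overshoot small injected
amplitudes (by ~0.1–0.25 mm at 0.3–0.6 mm injected) while remaining
monotone in the injected amplitude.

Other numerical choices: decimation hits the requested vertex count exactly
(each edge collapse removes one vertex) and rejects collapses that flip
surviving face normals; near-singular quadric solves fall back to
midpoint/endpoint placement limited to 4x the mean edge length; voxelization
decides inside/outside by z-column ray parity with merged duplicate
crossings (requires watertight input); degenerate (zero-area) faces are
skipped by the varifold with a warning; kPCA eigen-scores follow the
`eigenvector * sqrt(eigenvalue)` convention, so at most n-1 components are
nonzero after centering.
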