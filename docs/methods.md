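# Methods

This note records the models, parameter choices and numerical decisions
behind osteofabric, and what the synthetic-phantom validation does and
does not establish about real scans.

## Scan conditioning

All filters compute in 32-bit float, preserve grid shape and spacing,
and treat background removal as masking rather than value destruction.
The default chain is median filter (cubic kernel 3, reflective edges) →
intensity-domain mean-shift smoothing (window 5, range bandwidth = half
the Otsu inter-class gap, ≤ 10 iterations or until the largest move is
below 10⁻³ of the intensity range) → polynomial bias flattening
(degree 3 in normalised coordinates, one robust re-fit excluding
> 2 SD residuals, fitted over bone voxels so the air background cannot
dilute the field; the global mean is preserved) → difference of
Gaussians (σ = 0.75 and 3.0 voxels, the midpoints of the working
ranges 0.5–1.0 and 2.0–4.0; un-normalised by default) → Otsu threshold
on a 256-bin histogram.

The segmentation input is the threshold of the bias-corrected median
volume. We validated the alternative of unioning a mean-shift-derived
cortical mask with a DoG-derived trabecular mask on phantoms at SNR 5:
it lowered trabecular Dice by 0.05–0.25, because the DoG at these
sigmas responds to strut *edges* (adding shells and cavity halos) and
the mean-shift smoothing erodes thin bright rods — it is genuinely a
cortical-ROI filter. Both volumes remain chain outputs for inspection
and custom ROI work.

## Compartment segmentation

The labelling is a dual-surface scheme with one interpretable knob, the
closing radius (default 6 voxels):

1. periosteal surface: Euclidean closing of the bone mask (EDT-based,
   input padded so the closing cannot bleed past the bone ends),
   followed by 6-connected hole filling → whole-bone region;
2. endosteal region: the internal non-bone space closed **slice-wise in
   the transverse plane** and hole-filled per slice. In-plane the
   endosteal contour is convex or nearly so, so the closing bridges the
   voids between struts without advancing into the wall — and, unlike a
   3-D closing, cannot eat through the thin cortical caps at the bone
   ends, whose slices contain no internal space at all. This step
   assumes the long axis is the slice axis; `align_long_axis` (principal
   inertia axis → slice axis, with a degeneracy flag for near-spherical
   masks) guarantees it;
3. bone inside the endosteal region is trabecular (label 2), the rest
   cortical (label 1); internal non-bone is cavity (label 3). Labels
   partition the grid and cortical ∪ trabecular equals the input mask
   exactly.

The closing radius must exceed the strut diameter (to bridge
inter-strut voids) and stay well below the cortical thickness; 6 voxels
(150 µm at the 25 µm default spacing) satisfies both for the strut
sizes this toolkit targets. Trabecular components smaller than
27 voxels (26-connectivity) are returned to the cavity label by the
denoiser; total voxel count is conserved.

Midshaft selection: per-slice outer perimeter of the whole-bone mask
(Crofton estimator — voxel-edge counting overestimates circumference),
restricted to slices with cross-sectional area ≥ half the median
occupied-slice area (otherwise stray specks past the bone tip win the
minimum). The search window is the contiguous run within 2% of the
minimum perimeter; within it the slice with the largest cortical area
wins, ties breaking to the window centre.

## Morphometry

Areas are voxel counts × spacing² (mm²), volumes × spacing³ (mm³).
BV/TV is emitted for both readings of TV — the whole bone (labels
1+2+3) and the trabecular compartment (labels 2+3) — since either
convention is defensible. "Average" areas are means over the
diaphyseal slices between 25% and 75% of P–D, with midshaft-only values
alongside.

Local thickness follows the largest-inscribed-sphere definition with a
voxel-ball convention: the sphere at centre c has integer radius
m = ⌊EDT(c) − ε⌋ and diameter 2m + 1 voxels, and a voxel joins a ball
when its centre lies within m + ½ of the ball centre. This is the only
convention we found that simultaneously reports a lone voxel as one
voxel thick and slabs/rods within one voxel of their nominal width;
thickness values are therefore quantised to odd voxel counts. A
brute-force per-voxel search is the in-repo oracle on small masks.

## Fabric mapping

Lattice: cubic grid, pitch s = 500 µm, or 3 × Tb.Th when the mean
trabecular width exceeds 167 µm (the width at which the two rules
cross); radius of influence r = s, giving 50% linear overlap of
adjacent VOI diameters. Centres start half a pitch inside the ROI
bounding box; only centres whose ball intersects the ROI are kept.

Normals are the normalised gradient of the Gaussian-smoothed (σ = 1
voxel) trabecular mask at surface voxels (bone with a 6-connected
background neighbour). Each VOI's orientation tensor is
C = ⟨nnᵀ⟩/tr, eigenvalues λ₁ ≥ λ₂ ≥ λ₃ summing to 1;
DA = 1 − λ₃/λ₁ and the material axis is the λ₃ eigenvector, reported
sign-free with non-negative long-axis component. VOIs with fewer than
50 normals are undefined and carry the sentinel DA = 0, which the
histogram (bin width 0.05, ties to the lower bin) discards before the
mode (Ani.M) is taken. Plate-like samples ((λ₂ − λ₃)/λ₁ < 0.05) are
flagged degenerate rather than given an arbitrary in-plane axis.

The independent oracle is a mean-intercept-length estimator: stratified
bundles of parallel probes over quasi-uniform (golden-spiral)
directions, MIL = bone length / entry crossings per direction, ellipsoid
fitted by least squares on 1/MIL², axis = longest MIL direction,
DA = 1 − MIL_min/MIL_max. Cross-checks require axis agreement within
15° on strongly aligned phantoms and Spearman ≥ 0.9 between the two DA
estimates across a phantom series spanning DA 0–0.9.

High-anisotropy filtering keeps DA ≥ 0.65 (boundary inclusive). The
coherence summary quantifies "aligned regions of high anisotropy": per
axial third, (3η₁ − 1)/2 with η₁ the top eigenvalue of the mean outer
product of sample axes (0 uniform, 1 identical), undefined below 5
samples.

## Compactness profiling

Sections are binarised (largest connected component kept, interior
holes preserved — they are the signal). Centres: section centre =
centroid of the filled region; medullary centre = centroid of interior
non-bone (falling back to the section centre for solid sections);
ontogenetic centre = the point minimising global sigmoid-fit residual,
found by single-pixel coordinate descent — an operational reading of
the growth-centre concept, flagged as an interpretation.

The profile uses 60 sectors × 51 radial bins, radii normalised per
sector to the outermost bone pixel so d = 1 tracks the periosteal
boundary of non-circular sections; empty cells are undefined and
excluded. Damaged sections (missing wedges) are handled by letting the
affected sectors come back undefined. The four-parameter sigmoid is
fitted by bounded trust-region least squares from five fixed starts
(best RSS wins), cells weighted by pixel count; fits with
Max − Min < 0.05 are flagged degenerate. The slope at P is
(Max − Min)/(4S). Per-sector fits report across-sector mean, SD and
median (mean primary).

The lifestyle discriminant ships as a coefficient-file interface plus a
refit utility (unpenalised logistic regression on R_min, positive score
= terrestrial, boundary score 0 conservatively called aquatic); no
published constants are hard-coded.

## Synthetic phantoms

Phantoms are tubular shafts (constant, sinusoidally narrowing, or
flared outer radius; cortical caps close the ends the way epiphyses
close real bones — an open pipe would defeat any hole-filling-based
whole-bone mask) whose cavity is filled by rods: axes drawn from a von
Mises–Fisher distribution about the long axis (concentration
κ = 1/σ²) or uniformly, anchored uniformly in the cavity, rasterised
until the target fill is met within 0.02 (error outside that band).
Exact labels, per-voxel rod orientations, achieved fill and true strut
width are returned as ground truth. Imaging degradation is blur →
additive Gaussian noise → multiplicative polynomial bias (±10%), all
deterministic given the seed; SNR = contrast / noise SD.

The canonical study phantom (`femur_phantom_spec`) is a 4 mm shaft,
outer radius 1.10–1.25 mm narrowing at midlength, 0.25 mm cortex,
cavity fill 0.3, 25 µm voxels, PSF σ = 0.5 voxel (FWHM ≈ 1.2 voxels),
SNR 5, quadratic bias; ~2.1 M voxels, ≥ 64³ of them trabecular
compartment. Aligned-fabric scatter is 7.5°.

Strut width is 100 µm for fabric studies and 150 µm for
segmentation-accuracy studies, and the distinction matters: a 500 µm
VOI over a 150 µm-strut network at fill 0.3 contains only ~13 struts,
so even a perfectly disordered network measures median DA ≈ 0.4 — the
VOI statistic assumes averaging over many struts, and 100 µm struts
(~30 per VOI) restore that regime. Conversely, reliable thresholding
of individual struts needs ≥ 6 voxels across a strut, hence 150 µm at
25 µm voxels for the Dice studies. Both widths sit in the range the
lattice rule itself implies for real material (cutover at 167 µm).

What passing phantoms shows — and does not. The phantoms exercise
geometry, orientation statistics, partial-volume blur, additive noise
and smooth bias at realistic scales, so they validate the estimators'
geometric correctness and the pipeline's end-to-end bookkeeping. They
do not emulate diagenetic infill of fossil pore space, matrix of
near-bone density, ring or beam-hardening artifacts beyond a smooth
bias, plate-dominated fabrics (plates appear only to exercise the
degeneracy flag), or cross-scanner intensity conventions; results on
real fossil material additionally depend on those factors.

## Multivariate layer

Feature tables join per-module metric CSVs on specimen id; columns
with > 50% missing are dropped with a warning, remaining gaps are
mean-imputed and flagged, and a complete-case view is available. PCA
is on the correlation matrix (z-scored variables), component signs
fixed so each column's largest-magnitude loading is positive;
zero-variance columns are dropped with a warning. No phylogenetic
correction is applied, by design. Group separation is read as
axis-aligned score-range overlap per component pair, with singleton
groups reported as point intervals.

## Determinism and sizes

Every stochastic step takes an explicit seed; the pipeline derives
per-stage seeds from one global seed. Test problem sizes (≤ 2.1 M-voxel
phantoms, 64³ fabric balls, 10-phantom estimator comparisons) keep the
full suite around one to two minutes on one CPU while leaving every
stage's accuracy measurable; the acceptance script re-runs the two
study phantoms end-to-end in under a minute.
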