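# Methods

This note records the models, algorithms and numerical choices behind
`screwsight`, and what the synthetic validation does and does not
demonstrate.

## Geometry and conventions

All computation happens in world millimetres under the radiographic RAS
convention (+x right, +y anterior, +z superior); voxel grids carry a NIfTI
4×4 affine and are never assumed axis-aligned or isotropic. Rigid transforms
are proper rotations plus translations, stored as matrices internally and
serialised as unit quaternion (x, y, z, w) + translation. Intensity
resampling is trilinear; label masks are resampled nearest-neighbour so
labels never blend. Out-of-field voxels take the volume minimum (air), which
keeps thresholds and masks unaffected by padding.

## Screw detection

Screws are the only objects above the metal threshold. 26-connected
supra-threshold components below half a nominal shaft volume (beads, streak
speckle) are discarded. Each remaining component seeds a 5-DOF shaft model —
tip position (3) and axis direction (2), with the shaft length fixed to the
plan, which both removes a poorly-constrained DOF and disambiguates the tip
from the tulip head. The initial axis is the leading eigenvector of the
component's coordinate covariance (components whose leading eigenvalue is
less than 4× the next are rejected as degenerate); the initial tip sits one
radius inside the component's anterior extreme, because the poly-axial tulip
concentrates extra metal at the posterior end and would drag a
centroid-anchored initialisation several millimetres off the shaft.

The fit maximises mean clipped intensity inside the capsule (shaft +
hemispheric tip cap) minus the mean in a coaxial shell (radial distance
r→2r, restricted to the shaft's axial extent so the tulip never enters the
contrast term). Intensities are clipped at the 99th percentile of the local
neighbourhood so streak artefact cannot dominate either mean. Optimisation
is Powell from the initialisation over a cylindrical region of interest
around the initial shaft (margin 3r + 3 mm). On phantoms this recovers
tip/tail to ≲0.25 mm at noise σ = 20 HU.

Plan↔detection correspondence is a Hungarian assignment on tip-to-tip
distances (after an optional coarse pre-alignment); surplus plans or
detections are reported explicitly, and assignments whose optimal cost is
within 1 mm of an alternative are flagged ambiguous rather than silently
accepted.

## Per-vertebra registration

Initialisation is closed-form Kabsch/Umeyama: centroid subtraction, SVD of
the cross-covariance, determinant correction to a proper rotation, no
scaling. Levels with a single screw leave rotation about the screw axis
unconstrained; the vertebra mask centroid paired with the centroid of nearby
postoperative metal is appended as a pseudo-landmark and the result is
flagged, keeping the pipeline automatic for every level.

The refinement maximises mutual information over 6 rigid DOF
(rotation-vector × translation, rotations taken about the vertebra
centroid and scaled to arc-length at a 30 mm lever so all six parameters
live on comparable millimetre scales). MI uses a 32-bin joint histogram in
natural-log units with partial-volume (trilinear) weighting: each masked
preoperative voxel distributes its weight over the 8 surrounding
postoperative voxels, and each corner keeps or loses its own weight
depending on whether it is below the metal-exclusion threshold. The
per-corner (rather than per-point) exclusion matters: a hard all-corners
test makes the objective discontinuous as the transform sweeps voxels across
the metal boundary and litters the optimum with micro-minima; the soft form
keeps MI continuous and restarts then reconverge to within ~0.001 mm of each
other. The preoperative mask is the vertebra's own label; fiducial beads,
when present, are additionally excluded on both sides via spheres dilated by
two mean voxels.

The pyramid smooths both volumes with Gaussian σ = {2, 1, 0} voxels; at
each stage Powell runs to a parameter tolerance of 1e-4 mm-equivalent (at
most 30 iterations, with up to two direction-set restarts if a stage stalls
at its cap). The masked fixed-side sample is a deterministic stride
subsample (4000/6000/12000 voxels coarse→fine) whose positions carry a
frozen sub-voxel jitter, with fixed-side intensities interpolated at the
jittered positions. The jitter matters: when both scans share one voxel
lattice, partial-volume MI has artifact local maxima wherever the transform
re-aligns the lattices, and without off-grid sampling restarted
registrations occasionally converged to such maxima 2–7° from the baseline;
with it, restarts agree to ~0.001 mm / 0.001°. The reported `mi_final` is
evaluated at
the finest stage and the refinement falls back to its initialisation in the
(pathological) case where the coarse stages end somewhere worse, so
`mi_final ≥ MI(init)` holds by construction.

Transform comparisons (perturbation analysis, ground-truth scoring) use
Δ = T₁∘T₂⁻¹, reporting the rotation angle of Δ (from the trace) and the
displacement of the vertebra mask centroid under Δ. The centroid reference
makes the translation figure independent of the arbitrary world origin.

## Anatomical frame and mid-pedicle point

The inferior endplate is found among exterior surface voxels of the level's
label whose outward direction (gradient of a smoothed indicator) lies within
45° of inferior and which sit in the inferior 30% of the label's extent.
Because parallel inferior-facing surfaces exist (posterior elements) and
staircase voxelisation biases gradient directions on tilted faces, the plane
itself is selected by a deterministic 300-iteration RANSAC (0.4 mm inlier
band — just above the half-slice staircase amplitude) and polished by
least-squares on its inliers. On phantoms this recovers constructed endplate
normals to <0.3° across tilts up to 10°.

Frame axes: e_AP along the planned shaft; e_SI the endplate normal
Gram-Schmidt-orthogonalised against e_AP; e_ML = e_SI × e_AP with the sign
chosen so medial is positive for the screw's side (sagittal midplane x = 0).
This makes the frame right-handed on one side and mirrored on the other —
the price of pooling left and right screws in one medial-positive axis, and
exactly what the target plots assume.

The mid-pedicle point lives on the **planned** trajectory: the medial
pedicle wall is represented by label-boundary voxels facing medially within
10 mm of the trajectory, the trajectory is sampled every 0.1 mm across the
wall's axial extent, and each sample's distance to the nearest wall voxel is
signed negative when the sample sits outside the label (breached). The
arg-min sample is the locus; ties break toward the smaller arc length.
Anchoring to the plan keeps the analysis plane fixed (the origin of the
target plots); the actual screw's mid-pedicle error is measured where the
detected axis pierces the plane through the locus normal to e_AP.

## Error resolution and statistics

Planned landmarks, the locus and the frame axes are mapped through the
fitted per-level transform into postoperative space; errors are detected-
minus-planned offsets resolved on the mapped axes. This expresses every
error in the anatomically anchored planned frame regardless of inter-scan
motion. Summaries report, per metric: SME (mean of signed errors — bias),
MAE (mean of absolute errors — accuracy), and precision as 2 × sample SD
(n−1) of signed errors. Euclidean composites (tip/tail 3D, mid-pedicle 2D)
report MAE only; their signed mean is undefined. Groups with n < 2 report
precision as NaN, never 0. Regional comparison is one-way ANOVA on absolute
errors across upper thoracic (T2–T6), lower thoracic (T7–T12) and lumbar
regions, with all-pairs t-tests Bonferroni-multiplied and capped at 1.

## The phantom: what it emulates, and what it does not

Each vertebra is an analytic solid — elliptic-cylinder body (32 × 24 ×
22 mm) with a flat inferior endplate, two pedicles (radius 4 mm, ~8° medial
angulation) flanking a 6 mm canal, and a posterior-element block — rendered
at 0.5 × 0.5 mm in-plane / 0.625 mm slices with five intensity classes (air
−1000, soft tissue 40, trabecular 250, cortical 1200, metal 3000 HU), a
1.2 mm cortical shell (Euclidean distance transform), Gaussian blur
(σ = 0.25 mm, emulating the reconstruction kernel / partial volume) and
additive Gaussian noise (default σ = 20 HU). The trabecular interior
carries an anatomy-locked pseudo-random texture (SD 60 HU, correlation
2.5–6 mm, a seeded sum of random cosines evaluated in vertebra-local
coordinates): it renders identically in both scans and moves rigidly with
the vertebra, standing in for real trabecular structure. Without it the
uniform plateaus give MI almost no rotational signal and restarted
registrations scatter among micro-minima; with it they reconverge to
~0.001 mm / 0.001°. Screws are metal capsules (hemispheric tip) along the
deviated trajectory with a wider tulip capsule at the tail; beads are 1 mm
metal spheres. Metal is rasterised with linear partial-volume coverage so
sub-voxel positions are recoverable (a flag restores pure binary plateaus
for tests of the intensity model itself).

Planted deviations are rigid (frame translation + angulation about the
tail), which preserves the shaft length exactly — consistent with a robotic
execution error model and with the detector's fixed-length shaft.

The phantom deliberately omits: streak/beam-hardening artefact (the fit
clips intensities instead of modelling streaks), real trabecular
microarchitecture, cortical thickness variation, degenerative anatomy and
deformity, soft-tissue structure, and any non-rigid change between scans.
Passing phantom validation therefore demonstrates that the *algorithms*
recover known geometry under CT-like sampling, blur, noise and metal
occlusion — not that the pipeline is robust to every artefact of clinical
CT. The registration defaults for real data (metal threshold 2500 HU) are
exposed but untested against real scans here.

## Study conditions for the validation cohort

The acceptance study uses five two-level phantoms spread across spine
regions (T4, T7, T11, L1, T9 starts), bilateral screws (20 total) with
deviations drawn uniformly up to 3 mm / 5°, per-level motions up to
10° / 10 mm (large enough to defeat identity initialisation, small enough to
keep field-of-view overlap), four beads per level (40 total), noise
σ = 20 HU, and the 10 × (2°, 2 mm) perturbation protocol on one level per
phantom (50 replicates). Problem sizes were chosen so the whole study runs
in roughly a quarter hour on one CPU.

## Known limitations

* The capsule-contrast screw objective is a declared engineering choice; no
  published objective exists for the detection step it implements.
* Mid-pedicle wall extraction is voxel-based; a marching-cubes surface would
  change wall distances by up to ~half a voxel.
* Perturbation consistency on phantoms (~0.001 mm) is far tighter than any
  real-scan figure would be: the phantom's texture is exactly rigid and
  noise is white, so the MI optimum is unusually sharp.
* Single-screw levels rely on a metal-centroid pseudo-landmark whose
  anatomical meaning is loose; the degeneracy flag should be checked
  downstream.
* ANOVA assumes independent screws; within-level left/right pairs are not
  modelled.
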