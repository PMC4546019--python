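# Methods

`muinpaint` studies — and corrects — a failure mode of MR-based attenuation
correction (MR-AC) in PET/MR of the head and neck: metallic dental work
destroys the MR signal around the implant, and the Dixon-segmented
attenuation map (mu-map) assigns air (mu = 0) to a region that is really
soft tissue. Rays through that region are then under-corrected and the
reconstructed PET activity is biased low in and around the void. The package
contains the correction algorithm, a synthetic phantom that generates the
study conditions, a PET simulator that reproduces the bias mechanism, and
the metrics used to quantify the effect.

## The phantom

Because no patient data can ship with the package, a seeded generator
emulates the relevant anatomy on a 96 × 96 × 48 grid at 2.6 × 2.6 × 3.1 mm
(the mu-map voxel size of the integrated PET/MR scanner this work targets;
the axial extent is reduced to desk scale). The head is an ellipsoid on a
neck cylinder; soft tissue has mu = 0.1 cm^-1 exactly, a 6-mm subcutaneous
shell has fat attenuation (0.086 cm^-1), and the oral cavity and two
paranasal sinuses are internal air. Cavities always keep at least a
one-voxel tissue wall to the outside: the synthetic mouth is closed, so an
artifact-free mu-map never contains a genuine breach and the identity
contract of the correction (artifact-free in, bitwise-identical out) is
well-posed.

Reference regions (tongue, lower tongue, left/right masticatory muscles,
cerebellum) are ellipsoids placed at plausible offsets; the tracer activity
is a per-region plateau map (cerebellum hottest, masticatory muscles
coldest) smoothed with a 3-mm Gaussian and clipped positive inside tissue.
The Dixon-water-like image maps soft tissue to 100, fat to 50, air to 0 and
adds smoothed Gaussian noise (std 10, smoothing 4 mm) inside the body —
roughly the contrast and noise of a fast Dixon acquisition, and enough
inter-subject variation that a 30-subject average is measurably smoother
than any single subject. Population variability is modelled by jittering
every structure's center and semi-axes with 2-mm (ROIs and cavities: 1-mm)
Gaussian perturbations.

Dental artifacts are injected only into the Dixon-style map (the truth map
is untouched; the water image is voided as well, since the susceptibility
effect hits every image of the acquisition). A void is a union of three
seeded ellipsoidal lobes around a dental centroid, elongated along the
dental arch, grown by bisection until the newly-air volume hits the target
within 15%, and constrained to one connected component. The generator covers
the observed 1.6–520.8 mL range. Two topological classes exist by
construction:

* **inner** — the void (plus a one-voxel dilation) stays inside the body and
  at least two voxels away from anatomical air;
* **outer** — a 5-mm-radius cylindrical channel through the cheek connects
  the void to the background, breaching the body outline.

## PET simulation

The scanner is modelled per axial slice as a 2-D parallel-beam system
(63 angles over 180°, 96 bins at 2.6 mm): the attenuation-correction bias is
an in-plane path-length effect, so full 3-D geometry adds cost without
coverage. The projector is a sparse matrix assembled by ray-driven sampling
(step: half the voxel size) with bilinear interpolation; backprojection is
its exact transpose, so the adjoint dot-product identity holds to machine
precision. Expected data follow the ordinary-Poisson model
`prompts = exp(-∫mu dl) · ∫activity dl + background` with an optional flat
per-slice background as a scatter surrogate, and counts are Poisson-sampled
per bin with a fixed seed (2 × 10^6 counts per phantom by default).

Reconstruction is OP-OSEM with the clinical protocol as default — 3
iterations, 21 subsets (angle-interleaved processing order via a
coprime-stride permutation), 4-mm Gaussian post-filter
(sigma = FWHM/2.3548, applied in-plane and axially) — with the attenuation
factors of a *chosen* mu-map in the system model. Reconstructing the same
sinogram once with the artifactual map and once with the corrected map is
exactly how the mismatch bias arises in practice. Zero-sensitivity voxels
are excluded from updates; the non-attenuation-corrected (NAC) image used
by the contour step is a 2-iteration reconstruction with unit attenuation.

## The correction

1. **Void detection.** Connected components (26-connectivity) of
   sub-threshold voxels (air threshold 0.005 cm^-1 — far below fat, above
   float noise) intersecting the anatomical envelope. A component is
   **outer** if its in-envelope part reaches, through a 6-connected air
   path, the background air touching the grid boundary; **inner** otherwise.
   The generous/conservative connectivity split (26 for merging, 6 for the
   breach test) avoids classifying a cavity behind a sub-voxel tissue wall
   as breached.

2. **Contour closing (outer voids only).** A two-region Chan–Vese level-set
   energy with a spatially switched data term: on a 3-voxel dilation of the
   breaching voids the data term reads the NAC-PET image (whose apparent
   body edge survives the artifact), elsewhere it reads the mu-map. Both
   channels are normalized to [0, 1] by a 1st–99th percentile stretch, which
   makes contours invariant to global intensity scaling (tracer and count
   level). Region means are global; the level set starts from the signed
   distance to the naive body threshold, is re-initialized by distance
   transform every 20 iterations, advances with a normalized speed of at
   most 0.45 voxels per iteration, and stops when fewer than 1 in 10^5
   voxels change side over five consecutive iterations (maximum 300
   iterations; non-convergence is returned as a flag, not an error). The
   PET weight is set automatically from the contrast between the PET
   background outside the body and the PET signal adjacent to the voids,
   clamped to [0.5, 4]. Enclosed, background-connected air inside the
   recovered contour is filled with 0.1 cm^-1; because the zero level can
   sit sub-voxel inside the true surface, the fill region is grown within
   the switch region up to the anatomical envelope, so no true background
   voxel is ever touched and no void voxel stays connected to background.

3. **Atlas fill (both classes).** An atlas is built from 30 artifact-free
   subjects: the voxelwise-mean water image, the stable oral-cavity air
   core (air in ≥ 90% of subjects inside a dental bounding region), and a
   *dental fill template* — the core dilated by 28 mm, confined to the
   dental region (it must never reach the sinus floor) and cleared of
   population anatomical air (air in ≥ 30% of subjects, one-voxel guard).
   The patient's water image is aligned to the atlas by a deterministic
   12-dof affine registration (mean squares on normalized smoothed images,
   multi-resolution, dense sampling; sub-threshold voxels excluded from the
   metric so large voids do not drag the alignment), and the template is
   warped to patient space with nearest-neighbor interpolation.

   Each remaining void component is then filled with 0.1 cm^-1 where it
   overlaps the template, and the completion/reversal policy is applied to
   the overlap fraction with *strict* thresholds: above 80% the whole
   component is filled (completing artifact voids that extend beyond the
   template), below 10% everything is reversed (absorbing registration and
   jitter error), in between the partial fill stands. A component whose
   overlap with a permissive population anatomical-air map (air in ≥ 10% of
   subjects) exceeds 50% is recognized as anatomy (oral cavity, sinus) and
   reversed outright — the reproducible analog of a manually drawn template
   that never covers anatomical air. The high completion threshold is what
   keeps sinuses connected to an artifact from being filled.

The whole correction is idempotent, only ever adds attenuation, changes no
voxel outside the detected voids, and passes an artifact-free map through
bitwise unchanged.

## Quantification

For paired reconstructions (artifactual vs corrected attenuation) the
per-ROI metrics on mean and maximum SUV are

    eps_rel = (SUV_dixon − SUV_inpainted) / SUV_inpainted × 100 %
    eps_abs =  SUV_dixon − SUV_inpainted

linked by `eps_rel = 100·eps_abs/SUV_inpainted`; −100% marks total signal
loss. Voxelwise difference images use the same formulas with 0/0 reported
as 0 so the images are NaN-free. Cohort summaries report mean ± sample
standard deviation (ddof = 1) and range per ROI, split by artifact class,
plus the Spearman correlation between void volume and |eps_rel| of the
inpainted area. Distance dependence is operationalized as Euclidean
distance shells from the void surface. Matched pairs are compared with a
two-sided Wilcoxon signed-rank test: exact enumeration of all 2^n sign
assignments for n ≤ 12, normal approximation with tie and continuity
correction above. SUV scaling defaults (200 MBq, 70 kg) only affect
absolute displays; every relative metric is scale-invariant.

## What the simulation shows — and what it cannot

On the stock cohort (5 inner voids of 2–16 mL, 5 outer voids of 15–300 mL,
seeded) the simulation reproduces the qualitative physics: mean relative
bias of the inpainted area around −45% to −66%, shrinking monotonically with
distance from the void (tongue, then cerebellum), growing with void volume
(Spearman rho = +1 over the outer sweep), and small regions of *positive*
bias adjacent to large voids in low-uptake tissue. These magnitudes are
phantom-dependent: the phantom has no bone, no scatter beyond a flat
surrogate, no scanner resolution model, and its ROI geometry is plausible
rather than patient-derived, so passing tests validate the mechanism and the
correction contracts, not clinical effect sizes.

Known limitations:

* The fill value is uniformly 0.1 cm^-1, as in the method modelled; where a
  void overlaps the fat shell the corrected map slightly over-attenuates
  (fat is 0.086). On the largest stock void (300 mL, ~23% fat) this leaves
  a +6.6% residual versus a truth-attenuation reconstruction; across the
  stock cohort the mean residual is ~1.6%. A truth-valued fill removes the
  residual exactly, confirming its origin.
* The published description of the contour step's PET penalty is realized
  here as a switched two-channel data term, validated by its closure
  contract (no void voxel remains background-connected) rather than by
  equational identity with the original implementation.
* Registration is affine; the anatomical-air recognition absorbs the
  residual misalignment (a few mm) that affine registration leaves on
  strongly jittered subjects.
* ROI statistics are computed on the reconstruction grid (identical to the
  mu-map grid in the default experiment); `resample_to` covers cross-grid
  use.
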