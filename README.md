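# muinpaint

Correction of metal-implant signal voids in MR-based PET attenuation maps,
with a synthetic head/neck phantom and PET simulator to quantify the bias
the voids cause.

## The problem

Combined PET/MR systems derive the 511-keV attenuation map (mu-map) from a
Dixon MR sequence. Metallic dental work destroys the MR signal around the
implant, so the segmented mu-map assigns air (mu = 0 cm^-1) to a region
that is really soft tissue (mu ≈ 0.1 cm^-1). Attenuation-corrected PET then
underestimates activity in and around the void — severely enough to matter
for tumor quantification in the head and neck. The voids come in two
topological classes: **inner** voids fully enclosed by the anatomical
surface, and **outer** voids that breach the body contour and merge with
the background air, so that the body outline itself is lost.

This package implements an automatic *inpainting* correction:

1. breached outlines are closed by a two-region Chan–Vese level set whose
   data term switches, inside the void region, from the mu-map to the
   non-attenuation-corrected (NAC) PET image — the apparent body edge on
   NAC-PET survives the artifact;
2. enclosed voids are filled with the soft-tissue value (0.1 cm^-1) where
   they overlap a dental template derived from an atlas of artifact-free
   subjects, aligned to the patient by affine registration of the
   Dixon-water images; components filled more than 80% are completed,
   components filled less than 10% are considered errors and reversed
   (strict thresholds — this is what keeps sinuses connected to an artifact
   from being filled).

The effect of the correction on reconstructed PET is quantified per region
of interest on mean and maximum standardized uptake value (SUV):

    eps_rel = (SUV_dixon − SUV_inpainted) / SUV_inpainted × 100 %
    eps_abs =  SUV_dixon − SUV_inpainted

where `dixon` denotes reconstruction with the artifactual map and
`inpainted` with the corrected map; −100% marks total loss of signal.

Since no patient data ship with the package, a seeded phantom generator
produces ground-truth mu-maps, activity maps, Dixon-water-like images and
reference ROIs, with injectable voids of both classes (1.6–520.8 mL), and a
2-D parallel-beam OP-OSEM simulator (3 iterations, 21 subsets, 4-mm
Gaussian post-filter by default) reproduces the attenuation-mismatch
mechanism. See `docs/methods.md` for the model details and limitations.

## Worked example

Simulate a cohort of two phantoms — one enclosed 6-mL void and one
breaching 133-mL void — reconstruct PET with the artifactual and the
corrected map, and report the bias:

```python
from muinpaint import ArtifactSpec, ExperimentConfig, run_experiment

cfg = ExperimentConfig(
    artifacts=(
        ArtifactSpec(artifact_class="inner", target_volume_ml=6.0, seed=0),
        ArtifactSpec(artifact_class="outer", target_volume_ml=133.0, seed=100),
    ),
    seed=1,
)
result = run_experiment(cfg, out_dir="scratch/demo")
for run in result.runs:
    b = run.report.rois["inpainted_area"]
    print(
        f"{run.report.artifact_class:5s} {run.phantom.artifact_volume_ml:6.1f} mL  "
        f"eps_rel_mean = {b.eps_rel_mean:6.1f} %"
    )
```

prints

```
inner    6.1 mL  eps_rel_mean =  -52.8 %
outer  140.4 mL  eps_rel_mean =  -62.8 %
```

i.e. ignoring the void biases the mean SUV of the corrected region by about
−53% (enclosed void) and −63% (breaching void) relative to the corrected
reconstruction — same sign and order of magnitude as observed clinically,
with the magnitude depending on the phantom. The output directory contains
all volumes as NIfTI (`mu_truth`, `mu_dixon`, `mu_inpainted`, `pet_*`),
per-run bias tables, fill reports, distance-shell tables and a cohort
summary split by artifact class.

The same stages are available from the shell:

```bash
muinpaint simulate --seed 1 --artifact-class outer --volume-ml 133 --out sim/
muinpaint experiment --stock --seed 1 --out results_experiment/
```

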