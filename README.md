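# perilesion

Perilesional and tract-level white-matter integrity analysis after
ischemic stroke, built around free-water-corrected diffusion tensor
imaging. The package quantifies how microstructural damage extends
*beyond* the visible lesion — into normal-appearing white matter — and how
that damage relates to cognitive outcome, and it ships a synthetic
diffusion-phantom generator so the entire chain is testable without
patient data.

It is aimed at neuroimaging researchers who have: multi-shell
diffusion-weighted volumes (NIfTI + FSL-style `bvals`/`bvecs`), a binary
stroke-lesion mask, per-bundle tract masks (e.g. from TractSeg's 72-bundle
segmentation), and per-subject cognitive scores.

## The model

Each voxel's diffusion signal is decomposed into a freely diffusing
isotropic compartment and a tissue compartment (the bi-tensor, free-water
elimination model):

    S_k = S0 [ f exp(−b_k d_w) + (1 − f) exp(−b_k g_kᵀ D g_k) ]

with free-water fraction `f ∈ [0, 1]`, fixed free-water diffusivity
`d_w = 3.0×10⁻³ mm²/s` and a positive-semidefinite tissue tensor `D`
(log-Cholesky parameterized, fitted per voxel by trust-region nonlinear
least squares with an analytic Jacobian, optional spatial regularization).
From `D`'s eigenvalues λ₁ ≥ λ₂ ≥ λ₃ the maps are

* **MD_T** = (λ₁+λ₂+λ₃)/3 — mean diffusivity,
* **FA_T** = √(3/2) ‖λ − MD‖ / ‖λ‖ — fractional anisotropy,
* **MO_T** = 3√6 det(Ã) — mode of anisotropy of the unit-norm deviatoric
  tensor (+1 stick-like, −1 planar),
* **FW** = f,

plus the uncorrected FA/MD/MO from a standard weighted-least-squares
single-tensor fit. Correcting for free water removes the CSF/edema
partial-volume bias that otherwise depresses FA near lesions.

Around the lesion, concentric expansion shells at 2, 4, 6, 8 and 10 mm
(Euclidean distance transform, voxel-center to voxel-center) are
intersected with the lesioned tracts (every bundle passing through the
lesion), and each measure's mean per shell is converted to a Z-score
against a control cohort evaluated at the same locations
(`Z = (patient − mean_controls) / sd_controls`, sample SD). Tract-level
statistics classify each bundle as affected/unaffected relative to the
lesion side (infratentorial counts as contralateral to supratentorial
lesions and vice versa), compare groups (controls vs. no/mild vs. major
vascular cognitive disorder) with ANOVA/Tukey HSD, ANCOVA and Cohen's d,
regress cognitive-domain Z-scores on tract measures adjusting for lesion
volume and depression, and control the false discovery rate per
affected/unaffected family with Benjamini–Hochberg. Vascular cognitive
disorder is classified from domain composite Z-scores: mild for a
composite between −1.5 and −2.0 (4.4 % of a normal population), major
below −2.0.

## Worked example

Generate a phantom with two crossing bundles and a lesion whose damage
decays with distance, then recover the perilesional gradient as a
control-referenced Z-profile:

```python
from perilesion import (default_spec, generate_phantom,
                        generate_control_cohort, build_geometry,
                        load_registry, ring_means, zscore_profile,
                        aggregate_profiles)

spec = default_spec(grid_shape=(20, 20, 20), noise_sigma=0.0, seed=42)
_, truth = generate_phantom(spec)
geo = build_geometry(truth.lesion_mask, truth.bundle_masks,
                     load_registry(), truth.affine)
print(sorted(geo.lesioned_tracts), round(geo.lesion_volume_mL, 2))

patient = truth.to_scalar_maps("patient")
controls = generate_control_cohort(spec, 23, return_truth=True)
cmeans = [ring_means(t.to_scalar_maps(f"c{i}"), geo)
          for i, (_, t) in enumerate(controls)]
profile = aggregate_profiles(
    zscore_profile(ring_means(patient, geo), cmeans))
print(profile.query("measure in ('FA_T', 'FW')")
      .pivot(index="distance_mm", columns="measure", values="z").round(2))
```

Output:

```
['CC_4'] 0.45
measure       FA_T      FW
distance_mm
2.0         -33.85  143.30
4.0         -21.50   94.31
6.0         -13.17   58.84
8.0          -8.13   36.12
10.0         -5.17   23.64
```

The lesion sits on the CC_4 bundle (0.45 mL). FA_T is most depressed in
the 2 mm shell and recovers toward the control level with distance, while
the free-water excess decays the same way — the perilesional damage
gradient. (The Z magnitudes are large because this noiseless phantom's
controls vary only by their 3 % biological coefficient of variation; with
measurement noise the scale becomes realistic.)

The same chain runs from a shell via the `perilesion` console script
(`generate`, `fit`, `rings`, `zscore`, `cognition`, `regress`, `run`), and
`perilesion run --config config.yaml` executes the full
phantom → fit → geometry → profile → statistics pipeline into a run
directory with a manifest and Figure-style TSV tables.

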