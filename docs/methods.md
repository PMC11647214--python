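# Methods

This note documents the models, the synthetic data, the numerical choices
and the limitations of `perilesion`, in the order the pipeline runs them.

## Diffusion models

**Single-tensor fit.** `fit_dti` solves ln S = ln S0 − b gᵀDg per voxel by
weighted least squares, with weights equal to the squared predicted signal
(the standard correction for log-transformed Rician/Gaussian noise),
iterated once from an OLS start. Eigenvalues are sorted descending and
negative values clipped to zero; voxels with no positive signal are
flagged invalid rather than failing the fit. At least 7 volumes
(6 non-collinear directions + b0) are required.

**Free-water (bi-tensor) fit.** `fit_free_water` minimizes, per voxel,

    Σ_k ( S_k/S0 − [ f e^{−b_k d_w} + (1−f) e^{−b_k g_kᵀ D g_k} ] )²

over f ∈ [0, 1] and positive-semidefinite D. Internally b is expressed in
ms/µm² and D in µm²/ms so all parameters are O(1).

* `d_water = 3.0×10⁻³ mm²/s` — the diffusivity of free water at body
  temperature. Fixing it is what makes the two-compartment problem
  identifiable.
* D is parameterized by its log-Cholesky factor (log of the diagonal,
  raw off-diagonals), so positive semidefiniteness holds by construction
  and the optimization is unconstrained in those 6 parameters; f is
  box-bounded in [0, 1].
* The solver is scipy's trust-region-reflective nonlinear least squares
  with an analytic Jacobian; `ftol = 1e-6` (relative objective decrease),
  `max_iter = 100` function evaluations.
* Initialization: D from the single-tensor fit with the water contribution
  removed, D_t = (D₀ − f₀ d_w I)/(1 − f₀), eigenvalues clipped to
  [0.05, 2.8] µm²/ms; f₀ compares the b0-normalized mean signal of the
  highest shell against a typical tissue attenuation (MD 0.6 µm²/ms) and
  the free-water attenuation, clipped to [0.05, 0.9]. A second start at
  f = 0.05 with the raw single-tensor D guards against the known f–MD
  local-minimum trade-off; the lower-cost solution wins. The second start
  is skipped when the first already reaches a near-zero residual.
* Multi-shell data (≥ 2 distinct nonzero b-values) is required; on a
  single shell the decomposition is ill-posed and the fit refuses to run.
  All shells, including b = 50/150/350, enter both fits.
* Spatial regularization: with `reg_weight > 0`, outer sweeps append
  penalty residuals √(w·N/6)·(θ − θ̄) pulling each voxel's 6 tensor
  parameters toward their 6-neighborhood mean from the previous sweep
  (up to 10 sweeps, stopping when the largest parameter change falls
  below 1e-4). `reg_weight = 0` (the default) reproduces the pure
  voxelwise fit, which is the behavior verified against the forward-model
  oracle. The penalty form is this package's documented choice; the
  default weight 0.1 (relative scale) is deliberately small.
* Degenerate voxels: when the fitted tissue tensor's MD exceeds 0.9·d_w,
  tissue is indistinguishable from water, so the voxel is reported as
  FW = 1 and flagged unidentifiable (values are still returned). Voxels
  with f > 0.99 are likewise flagged.

**Scalar invariants.** MD is the eigenvalue mean; FA = √(3/2)·‖λ−MD‖/‖λ‖;
MO = 3√6·det(Ã) with Ã the deviatoric tensor normalized to unit Frobenius
norm, which confines MO to [−1, 1] (+1 prolate/stick, −1 oblate/planar).
All-zero eigenvalues return (0, 0, 0) by convention. These are the
standard tensor-invariant definitions.

## Synthetic phantoms

The generator's defaults mirror the study conditions the analysis was
designed for: 2 mm isotropic voxels; 3 b=0 volumes plus 100
diffusion-weighted volumes at b = 50 (3×), 150 (7×), 350 (30×) and
1000 (60×) s/mm²; 23 controls; lesion volumes of order 1 mL. Gradient
directions are deterministic Fibonacci-sphere point sets per shell.

* Bundles are geometric tubes (straight or circular-arc) carrying an
  axisymmetric tissue tensor (default eigenvalues (1.5, 0.3, 0.3)×10⁻³
  mm²/s) oriented along the local tangent. Where exactly two bundles
  overlap, the tissue signal is the equal-weight mean of the two bundles'
  attenuations — a crossing-fiber region; more than two overlapping
  bundles is rejected as ill-defined. Non-bundle voxels carry isotropic
  background tissue (0.7×10⁻³ mm²/s).
* The lesion is a sphere. At distance d (mm) from its surface (Euclidean
  distance transform), each bundle tensor's deviatoric part is shrunk by
  `fa_depression_amp · exp(−d / decay_scale)` (defaults 0.6 and 4 mm) and
  the free-water fraction is elevated by `fw_elevation_amp · exp(−d /
  decay_scale)` (default 0.4) above the 0.05 background; inside the lesion
  f is at least 0.8. Exponential decay makes the FW elevation
  non-increasing and the anisotropy non-decreasing toward baseline with
  distance — the damage gradient the profile analysis is meant to detect.
* Noise is Rician (two independent Gaussian channels of scale
  `noise_sigma · S0` added in quadrature), the magnitude-MRI convention.
* Controls are generated lesion-free on the same grid, with bundle
  eigenvalues and background f perturbed multiplicatively at a 3 %
  coefficient of variation per subject; per-subject random streams use
  fixed offsets of the single phantom seed, so everything is
  bit-reproducible. Shared geometry deliberately replaces the
  control-to-patient registration a real study needs.

What the phantom does **not** emulate: brain anatomy or atlas-shaped
bundles, EPI distortion, motion, eddy currents, gibbs ringing, spatially
correlated noise, or registration error. Passing tests therefore validate
the *analysis chain* — model fitting, geometry, Z-scoring, statistics —
not robustness to acquisition artifacts, which the out-of-scope
preprocessing tools handle in practice.

## Lesion geometry

Expansion distances default to 2, 4, 6, 8, 10 mm — multiples of the 2 mm
voxel. The distance transform measures voxel-center to nearest
lesion-voxel-center distance with per-axis spacing; the shell at d_i
contains voxels with distance in (d_{i−1}, d_i]. Shells (not cumulative
regions) are the default because a per-distance profile is the analysis
target; a cumulative mode exists for sensitivity analysis. Note the
half-open interval puts a voxel at exactly 4.0 mm in the 4 mm shell.

Side classification: a lateralized tract is affected iff its
hemisphere-and-region compartment contains lesion; the infratentorial
region counts as contralateral to supratentorial lesions and vice versa.
Bilateral or mixed lesions mark every lesion-containing compartment
affected (a documented extension — such patients exist but no explicit
rule is standard). Commissural/midline bundles are assigned to the
affected family. The fornix (CSF partial volume) and the 14 striatal
projection bundles (overlap with thalamic projections) are excluded from
tract statistics, leaving 56 of the 72 registry bundles.

## Z-profiles and tract means

Ring evaluation is restricted to ring ∩ lesioned-tract voxels, lesion
voxels always excluded (whole-ring evaluation is available as a
sensitivity flag). Controls are evaluated at the patient's exact
locations; per-control means are computed first, then the mean and sample
SD (n−1 denominator — material at n = 23) across controls form the
Z-score. Empty intersections become missing values, excluded pairwise,
never imputed. Per-tract Z-scores are averaged unweighted across lesioned
tracts into one Z per distance and measure; cohort curves carry a
normal-theory 95 % CI (mean ± 1.96·SE). Tract means for controls average
left/right homologues into one row per bundle.

## Cognition

Raw test scores are Z-scored against normative (age band, sex, education)
cells, education on the Dutch 7-category scale; lower-is-better tests are
sign-flipped. Domain composites are unweighted means of available test
Z-scores (the construction is configurable; no weighting scheme is
claimed). Status: major VCD if any composite < −2.0, mild if any
composite in [−2.0, −1.5], else none — the boundary values −1.5 and −2.0
both count as mild, stated explicitly because "between −1.5 and −2.0" is
boundary-ambiguous. The −1.5 cut-off corresponds to 4.4 % of a standard
normal population (vs. 13.6 % for the conventional −1.0), which is the
specificity argument for it.

## Statistics

ANOVA uses scipy's F-test, Tukey HSD the studentized-range implementation
in statsmodels. ANCOVA fits outcome ~ group + covariates by OLS and tests
the group factor with a partial F; constant covariates are dropped with a
warning (they carry no adjustment information and would make the design
singular), and rank-deficient designs are rejected naming the collinear
columns. Cohen's d uses the pooled SD and is oriented
reference-minus-comparison (control first), so a measure lower in
patients gives positive d. Per-tract regressions are OLS with the
tract-measure coefficient reported alongside adjusted R². BH-FDR is the
step-up procedure (via statsmodels), applied separately per family —
one family per (analysis × measure × side) — so affected and unaffected
analyses never influence each other's q-values. Missing depression
indicators are imputed by the mode, ties breaking toward the lower code
(symptom absent; conservative). Two-group baseline comparisons default to
Welch's t-test, with the pooled-variance test behind a flag.

## Pipeline and problem sizes

The pipeline fans a single run seed into fixed-offset substreams per stage
and writes a manifest with the config hash and warning counts; identical
config + seed reproduce byte-identical tables. Scalar maps can come from
the full bi-tensor fit or analytically from phantom ground truth
(`maps_source`), which exercises the identical downstream chain at a
fraction of the cost — the test suite uses ground-truth maps for
cohort-level checks and real fits for recovery and smoke tests. Default
cohort sizes are 66 patients and 23 controls; the shipped tests and the
acceptance script run 16³–20³ grids with cohorts of 4–23, sizes chosen so
the whole suite completes in minutes while every code path is exercised.

## Known limitations

* The bi-tensor fit assumes a single tissue compartment per voxel; in
  simulated crossings the fitted "tissue tensor" is an effective tensor,
  which is precisely the mechanism the crossing-fiber analyses probe, but
  voxelwise ground-truth recovery is only exact for single-bundle voxels.
* The regularized mode is a local smoothness penalty, not a variational
  reconstruction; its weight has no closed-form calibration.
* Phantom Z-scores are much larger than in vivo values when noise is
  switched off, because control variance then reflects only the 3 %
  biological CV.
* The cognitive normative tables are configuration fixtures; no actual
  normative dataset ships with the package.
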