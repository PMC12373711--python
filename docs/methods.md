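# Methods

## The measurement model

Input volumes are assumed already reconstructed, MNI-normalized and
(optionally) smoothed; this package starts at intensity normalization.
Each subject's volume is divided by its mean over a whole-brain binary
mask ("global SUVmean normalization"), which removes dose/weight/
injection variability and makes values unitless ratios near 1.  The
package does not prescribe a specific brain mask; for synthetic data it
defaults to the union of atlas-labelled voxels.  Normalization is exact
(masked mean = 1 to machine precision), idempotent, and invariant to
positive rescaling of the input.

Region SUVmean is the unweighted voxel average within the region's
label.  Network SUVmean is by default the voxel-count-weighted mean of
member regions, which equals the voxel average over the network mask —
the network is itself treated as an ROI.  An unweighted (mean of region
means) variant exists behind a flag for sensitivity analysis.  When the
pipeline starts from a pre-extracted region table, global normalization
is assumed already applied upstream; the run manifest records which
input mode was used.

The parcellation is an integer label volume plus a region table with a
required `network` column mapping each region to one of the seven
canonical resting-state networks or to `unassigned`.  The published
246-region-to-7-network lookup is not public, so the mapping is an
input, not a built-in constant; `unassigned` regions (e.g. subcortical)
are excluded from all network-level computation, with a log message.
Label volumes must be integer-valued (floats are rounded only within
1e-6).  Voxel indexing is 0-based and mm coordinates always go through
the NIfTI affine.

## Inference

* **Region/network comparison** — pooled-variance (Student) two-sample
  *t*, two-tailed; Welch available by flag.  The pooled default matches
  the convention under which the published effect sizes back-compute
  from their printed group summaries.  Effect size is Cohen's *D* on the
  pooled SD, signed with group 1 = patients, so positive values mean
  patient hypermetabolism.  FDR (Benjamini–Hochberg) is applied within
  each network's family of member regions; the seven whole-network rows
  form their own family.  Both raw p and q are reported, since the
  published per-region p-values appear uncorrected.
* **Categorical covariates** — Pearson χ² without continuity correction
  by default; Yates and Fisher's exact variants are exposed.  On the
  published hypertension counts (52/174 vs 39/206) the three give
  p = 0.013, 0.018 and 0.016 respectively; the printed value (0.016)
  matches the exact test, but since the variant used was not stated, the
  default stays Pearson and all three remain callable.
* **Voxelwise comparison** — the same pooled *t* per voxel within a
  network mask; FDR over the masked voxels at q < 0.05; the resulting
  significance mask is split by sign and decomposed into 26-connectivity
  connected components.  Clusters report voxel count, unweighted
  centroid mapped to mm, and signed peak *t*; no minimum cluster extent
  is imposed.  No random-field or cluster-level familywise inference is
  attempted — voxel-level FDR only.
* **Metabolic connectivity** — edges are Pearson correlations across
  subjects within a group, so the exchangeable unit is the subject and
  the permutation test re-splits the pooled cohort into the original
  group sizes.  The test statistic is the raw difference Δr (exact under
  the permutation null); a Fisher-z variant is available.  p-values use
  the add-one convention (p ≥ 1/(B+1) > 0), making them valid FDR
  inputs.  Each network's analysis draws from its own RNG stream derived
  from the master seed and the network name, so adding or removing a
  network never changes another's p-values; the 21 inter-network edges
  form their own family and stream.  B defaults to 10000; the analysis
  drivers and the acceptance script use B = 2000, which bounds the
  attainable p at 1/2001 ≈ 0.0005 and is sufficient for q < 0.05
  decisions at these family sizes.
* **Correlation analyses** — exact t-transform p-values, computed over
  the pooled cohort (N = 380) by default: the published (r, p) pairs
  back-compute at the pooled size and not at either group size.
  Per-group mode exists.  Network-vs-member-region correlations keep the
  region inside the network mean by default (the part-whole coupling is
  part of the reported quantity); a leave-one-out flag removes the
  region's voxel-weighted contribution for sensitivity checks, and with
  independent regions it drives the median correlation to ≈ 0 where the
  raw version stays positive.  No multiplicity correction is applied in
  this module by default, matching how such correlations are reported;
  FDR is available on request.

## The synthetic cohort generator

Each group's subjects × regions matrix is drawn from a multivariate
normal with mean = regional baseline plus any group-specific point
effects, and covariance C = D·R·D where D holds regional SDs and R is a
structured correlation matrix: a common within-network inter-subject
correlation ρ (default 0.3) inside each network block, an optional
global factor ρ_g linking all assigned networks, zero for unassigned
regions, and explicit per-edge overrides.  R is validated positive
definite; infeasible targets are repaired by eigenvalue clipping with a
logged warning, and sampling uses the Cholesky factor so a fixed seed
gives identical cohorts.  Draws below SUV 0.01 trigger a whole-subject
redraw — at realistic parameters this is a < 1e-15 event, so the
Gaussian distribution is effectively untouched.  Covariates are drawn
independently of SUV (binary by per-group prevalence, continuous by
per-group mean/SD); a coupling hook between vascular risk factors and
SUV is deliberately absent by default, since the motivating analysis
reports but does not adjust for the covariate imbalance.

The default ("study conditions") design uses group sizes 174/206, the
published control-group regional means and SDs as baselines, one
somatomotor point effect of +0.048 SUV in patients on a region with
baseline 0.814 (0.083) — the published trunk-region shift, Cohen's
*D* ≈ 0.59 — one dorsal-attention edge with inter-subject correlation
0.6 in patients vs 0.0 in controls, and the published covariate
prevalences.  Two values are not stated anywhere and were fixed once as
field-plausible: the within-network inter-subject correlation ρ = 0.3
(metabolic covariance networks show moderate within-network coupling)
and a global factor ρ_g = 0.2 (residual global coupling that survives
global-mean normalization; it yields network-level correlations of
≈ 0.2–0.4, all p < 0.001 at N = 380, the reported inter-network
pattern).

Volume rendering paints each region's SUVmean into its voxels, adds
independent Gaussian voxel noise, and smooths with an isotropic Gaussian
kernel specified as FWHM in mm (σ = FWHM/2.3548, converted to voxels
through the affine).  What the generator does **not** emulate: scanner
physics (attenuation, partial volume, reconstruction artefacts),
spatially correlated physiological noise, anatomical variability, or
any SUV–covariate coupling.  Passing tests therefore demonstrate the
statistical machinery — calibration, power, determinism — on data with
the assumed covariance structure, not robustness to real-PET artefacts.

## Numerical and design choices

* Fixture atlases pack 7 × k regions as rectangular blocks into a small
  grid (default 24³, 2 mm MNI-like affine); infeasible packings raise
  rather than producing malformed atlases.  Tests and drivers use the
  14-region fixture; computation scales linearly in regions and the code
  paths are identical at 246.
* Analysis problem sizes: the drivers and acceptance script use the full
  380-subject cohort, B = 2000 permutations, 500 null cohorts
  (7000 region tests) for type-I calibration, and 25 replicates for edge
  power — sizes chosen so every Monte-Carlo bound in the tests has
  comfortable slack while a full run stays interactive.
* Degenerate inputs fail loudly: zero-variance samples in a *t* test,
  zero-variance nodes in a correlation matrix (named in the error), zero
  table margins in χ², p-values outside [0, 1], empty masks, too-few
  subjects.  Empty significance masks yield empty cluster lists, not
  errors.
* Determinism: one master seed; `numpy.random.default_rng` throughout;
  per-analysis streams via `SeedSequence([master, crc32(name)])`.
  Pipeline TSV outputs are byte-identical across runs with the same
  config and seed; the manifest records seed, B, versions and input
  hashes.

## Known limitations

* Inter-subject (group-level) connectivity cannot produce per-subject
  connectomes; individual-level metabolic connectivity methods are out
  of scope.
* The permutation p of a sampled (non-exhaustive) test depends on the
  Monte-Carlo draw; it is invariant to subject ordering only in
  distribution (the observed r and Δr are exactly invariant).  The
  exhaustive enumeration is tested at small n as the oracle.
* Spatial normalization, registration and PET reconstruction are
  upstream of this package; volumes must already be in a common space.
* The whole-network "no difference" pattern of the motivating study
  emerges at full parcellation scale, where one shifted region dilutes
  into many; at the 14-region fixture scale a strong point effect can
  reach whole-network significance.
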