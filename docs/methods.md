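# Methods

## The model

The analysis treats the corpus callosum (CC) as a bundle of homotopic
commissural fibers, each attributable to one cortical resting-state network.
Three nested quantities carry the analysis:

- **Voxel-level connection probability.** For subject *s*, CC voxel *v* and
  network *n* ∈ 1..K, FN(s,v,n) counts accepted network-*n* streamlines
  through *v* (binarized per streamline: a looping streamline increments a
  voxel once). P(s,v,n) = FN/ΣₙFN is a categorical profile over networks,
  defined on the subject's support (voxels with any accepted streamline) and
  zero elsewhere. The population map P(v,n) is the plain arithmetic mean over
  subjects; the hard segmentation is its voxel-wise argmax.
- **Subregion-level scalars.** P(s,n) = Σᵥ P(s,v,n)/V averages over the V
  voxels of the fixed template CC mask (not the subject support), so subjects
  with sparse tractograms correctly score low. DI(s,n) is the
  probability-weighted mean of a diffusion index over voxels with weight > 0
  and FA > 0.2; the FA gate (applied from the subject's FA volume for all
  four indices) screens out gray-matter/CSF partial volume.
- **Lifespan trajectories.** DI = A·age + B·age² + C per subregion × index,
  by ordinary least squares; adjusted R² uses p = 2 (age, age²; the intercept
  is not counted). The turning point −A/(2B) is the age of peak FA or minimum
  diffusivity, flagged when it falls outside the observed age range.

## The synthetic study

**Phantom.** A 32×44×20 grid of 2-mm voxels (RAS axes, midsagittal plane at
world x = 0, no voxel center on the plane). The CC is the two voxel columns
nearest the plane over a 34-slice anterior–posterior extent and 6-slice
height (408 voxels). K disjoint crossing zones tile the central band of the
slab anterior→posterior with one-voxel gaps, in the order LN, DMN, FPN, VA,
SM, DA, VIS for K = 7 (matching the rostrum→splenium topography of the real
parcellation; labels 1..17 in order for K = 17). Each network also owns a
pair of homotopic cortical blobs at |x| ≈ 25 mm. Construction is
deterministic; the ground-truth zone labels are what real data never
provides.

**Tractograms.** An on-target network-*n* streamline runs from a uniformly
sampled point in the left blob, straight through an assigned zone-*n* voxel,
to the right blob, resampled to ≤ 1-mm point spacing. Crossing voxels cycle
through a shuffled list, so the default 48 streamlines per network cover
every zone voxel (16 crossing columns for K = 7). Endpoint jitter (Gaussian,
default SD 1 mm) perturbs endpoints and thereby the downstream acceptance
rate; crossing jitter (uniform, default ±0.5 mm = a quarter voxel) wiggles
the crossing *within* its assigned voxel. Off-target streamlines (default 5 %
of the total) either arc within one hemisphere or cross the CC but end in
unlabeled tissue; all must be rejected. Consequences chosen deliberately:
inter-subject variability lives in counts and acceptance, not in topography,
so the zero-jitter ground-truth-recovery invariant extends to the default
settings and split-half Dice measures pipeline reproducibility (it sits at
1.0), not residual anatomical variability. Raising the crossing jitter past
half a voxel is the knob that blurs zone borders.

**Diffusion volumes.** Zone-*n* voxels carry the generative quadratic value
for (index, network *n*) at the subject's age, plus optional covariate
effects, one subject-level noise draw shared by the zone (SD = the row's
noise_sd), and optional voxel-level noise (default 0, so the extracted
DI(s,n) has exactly the calibrated subject-level residual). CC voxels outside
every zone imitate partial volume: 90 % (configurable) get FA below the 0.2
threshold, deterministically in scan order so that noise-free volumes are
bit-identical across seeds; diffusivities there take fixed plausible
background values (MD 1.0, RD 0.7, AD 1.8 ×10⁻³ mm²/s). FA is clipped to
[0,1], diffusivities to > 0.

**Generative coefficients.** The default model table holds the 28 fitted
lifespan trajectories of a reference population (n = 1086, ages 21–90,
seven decade groups of sizes 73/41/42/413/305/188/24), with printing scales
(FA ×10⁻²/×10⁻⁴; diffusivities ×10⁻³/×10⁻⁵/×10⁻⁷ mm²/s) expanded to absolute
units once, at model construction. Residual noise per row is calibrated so
the quadratic signal explains the row's R² under uniform ages:
σ² = Var_age[q(age)]·(1−R²)/R². Covariate effects default to zero (their real
magnitudes are not published); nonzero values act around fixed references
(TIV 1400 cm³, sex 0.5, education 10 y) so the intercept stays
interpretable. Cohort education and TIV decline with age following the
reference demographics; sex is Bernoulli(1/2).

## Numerical conventions

- **Rasterization.** Streamlines are resampled to a quarter of the smallest
  voxel dimension and mapped to nearest voxel centers (voxel-centered
  convention, out-of-grid points clipped); duplicates are removed per
  streamline. Verified against an independent dense point-mapping oracle.
- **Label dilation.** Per-label Euclidean distance transforms with physical
  sampling; a voxel joins the nearest label within the radius, distance ties
  go to the lower label index, original labels are never overwritten.
- **Hard segmentation ties** go to the lower network index; all-zero voxels
  stay unlabeled. Dice is reported per label plus size-weighted (headline)
  and unweighted means, since a single multi-label Dice reduction is not
  canonical.
- **Split-half matching** stratifies on (decade age group × sex), shuffles
  each stratum and deals alternately; odd subjects alternate between halves
  via a global toggle (single-subject strata warn).
- **Quadratic fits** center ages internally and map coefficients and their
  covariance back to the raw-age parameterization exactly (T-matrix
  substitution), which keeps the design well conditioned while reporting
  Table-style raw intercepts. Verified against an exact rational-arithmetic
  normal-equations oracle.
- **ANCOVA** is an OLS with group dummies + covariates; the omnibus F
  compares against the covariates-only model, and pairwise contrasts are
  dummy-coefficient differences with pooled-error t tests
  (Bonferroni m = g(g−1)/2). The repeated-measures comparison of subregions
  is deliberately simplified to residualization (on age, sex, education,
  TIV) plus paired t tests with Bonferroni m = K(K−1)/2 — no sphericity
  machinery.
- **Seeding.** One global seed fans out as SeedSequence([seed, stage]) and
  SeedSequence([seed, stage, subject]); every stage is independently
  re-runnable and byte-reproducible.

## Design choices where the design was open

- **Homotopic rule.** "Connecting network n" is read as both endpoints in the
  *same* network, opposite hemispheres; heterotopic streamlines are rejected
  and tallied in the QC log, because the per-voxel normalization over
  networks presumes one network per streamline.
- **DI weights** default to the population atlas channel (the map a
  native-space analysis would transform onto each subject); a config switch
  (`weight_source="subject"`) uses the subject's own map. In this package's
  single common space the two differ only through inter-subject count
  variability.
- **P(s,n) denominator** is the template V, fixed per phantom (V = 408 at the
  default geometry; the reference template's V = 3440 is specific to its
  1-mm-pipeline CC mask and is not reproduced).
- **Raw vs residualized P(s,n)** entering the ANCOVA: raw, letting the model
  adjust — equivalent under the linear model.

## What the phantom does and does not emulate

It reproduces: network-specific crossing topography, homotopic endpoint
geometry, streamline rejection classes, partial-volume FA exclusion, the
published lifespan trajectory shapes with realistic residual variance, and
cohort demographics. It does not reproduce: anatomical variability of the
crossing topography across subjects (so split-half Dice ≈ 1 validates the
pipeline, not a reproducibility claim about brains), native↔template
registration error, curved callosal geometry, heterotopic fibers, or any age
effect on connection probability (the default generator holds topology fixed
across age; the group-comparison machinery is validated with injected
effects and null simulations instead). Passing tests therefore demonstrate
correctness of the estimators under the stated generative model, not
robustness to real-data artifacts.

## Problem sizes and known limitations

Tests and drivers use a 200-subject phantom study (48 streamlines per
network per subject) for atlas/reproducibility work and single n = 1086
cohorts for trajectory recovery; the null calibration of the ANCOVA uses
2,000 replicates of a balanced 140-subject design.

Two precision limits are inherent and surfaced by the acceptance suite
rather than hidden. First, the adjusted-R² identity can only be checked to
one unit of the printed precision when its input R² is itself rounded to
three decimals (for the MD/FPN row, r²_adj(0.203) = 0.2015, which rounds to
0.202 against a printed 0.201 that the unrounded R² would yield). Second, a
single n = 1086 cohort estimates each row's R² with a sampling SD of about
0.015–0.02 and FA intercepts with SE ≈ 2.3–3.9 % of their value, so
whole-table recovery inside ±0.02 (R²) or ±2 % (FA intercepts) at one fixed
seed is not statistically guaranteed; the corresponding strict checks are
kept in the suite as documentation of that limit, while the 3-standard-error
recovery check passes for all 84 coefficients. Finally, the analytic turning
points −A/(2B) of the generative FA rows (≈ 35–48 y) do not all match the
peak-age labels published alongside them (35–50 y, e.g. DA labeled 35 y vs
−A/2B ≈ 43.6 y); this package reports the analytic extremum and leaves the
discrepancy visible in `results/turning_ages.tsv`.
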