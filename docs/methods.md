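# Methods

## The design this package implements

`morphotrait` implements the statistical machinery of a split-sample
("exploration–validation") brain–behavior association study relating a
continuous self-report trait score (the 28-item short Autism-Spectrum
Quotient total, AQ-28) to structural brain measures in two stratified
samples of young adults (n = 204 and n = 304, ages 20–26). The workflow
has four analysis layers:

1. **Voxel screening (exploration sample).** Each in-mask voxel is
   regressed on the AQ total plus five nuisance covariates (age, sex,
   handedness, education as two dummies, intracranial volume). P-values
   come from Freedman–Lane permutation of nuisance-model residuals (the
   standard scheme of neuroimaging permutation-GLM tools; close-to-exact
   type-I control in the presence of nuisance effects) or, behind a flag,
   from the parametric Student-t reference. Voxels with p below a lenient
   uncorrected threshold (default 0.05) are split by the sign of the AQ
   slope and partitioned into connected components (26-connectivity by
   default, 6 available); components of at least `k_min` voxels (100 for
   gray-matter maps, 50 for FA skeletons) become candidate ROIs. Cluster
   extent is reported in voxels and mm³ (count × voxel volume; 8 mm³ at
   2 mm isotropic).
2. **ROI validation (validation sample).** Each candidate ROI's mean
   signal is partially correlated with the AQ total (same covariates) in
   the independent sample; p-values use t = r·√(df/(1−r²)) with
   df = n − 2 − c (c = covariate columns, intercept excluded — the df
   convention is stated because summary reports rarely give one). A ROI
   "replicates" when p < family_alpha / K (Bonferroni over the K ROIs) and,
   by default, its sign matches the exploration-stage sign; direction is
   intrinsic to the notion of confirming the *same* association, so the
   sign requirement is on by default with a lenient flag available.
3. **Structural coupling.** Coupling between two regions is the partial
   correlation across subjects of their morphometry values after removing
   the covariates — computed *pairwise* (correlate residualized region
   vectors), not by inverse-covariance partialling over all remaining
   regions: the pairwise reading matches how such matrices are described
   and produces the dense positive matrices structural-covariance studies
   show, whereas full partialling would not. The matrix is computed twice
   (with and without AQ as an extra control), Fisher r-to-z transformed,
   and a pair is called trait-influenced when |ΔZ| = |z_with − z_without|
   exceeds z_crit (default 1.96). Non-zero coupling is separately tested
   per pair at family_alpha divided by the pair count.
4. **Summary statistics.** One-way ANOVA recomputable from per-group
   (n, mean, sample SD) with η², Pearson χ² (no continuity correction)
   with φ / Cramér's V, and Shapiro–Wilk normality — the layer that
   reproduces a two-sample demographics table from printed numbers alone.

## Conventions chosen where the design was open

- **Pair count.** The Bonferroni family size for coupling defaults to the
  `paper` convention n²/2 (2312 for 68 regions, 3528 for 84) so that the
  published per-pair levels are reproduced; the mathematically standard
  n(n−1)/2 (`unique`, 2278/3486) is available. The package always computes
  the quotient family_alpha / n_pairs (0.05/2312 = 2.16×10⁻⁵,
  0.05/3528 = 1.42×10⁻⁵) rather than hard-coding any printed level.
- **Two-sided screening** is implemented as two one-sided suprathreshold
  maps (positive/negative slope) that are never merged, since candidate
  ROIs are reported separately by direction of association.
- **Peak voxel** ties break to the lexicographically smallest coordinate.
- **Permutation p-values** use the +1/+1 smoothed estimator
  (1 + #exceedances)/(1 + n_perm), so p is never zero; n_perm < 100 is
  rejected as an unstable tail estimate. Default n_perm is 1000 in tests
  and 5000 for production screening runs.
- **Sample-purity guard.** Validation-stage functions reject any subject
  labeled as exploration; no stage mixes the samples.
- **Region labels** use the standard 34-per-hemisphere cortical
  parcellation naming (68 cortical labels); the volumetric set appends
  bilateral amygdala, caudate, hippocampus, pallidum, accumbens, putamen,
  thalamus and cerebellum (84). Ordering (left then right hemisphere) is a
  package convention for heatmaps and CSV headers.

## The synthetic-cohort generator

The generator's defaults are the study conditions: two samples of 204 and
304 subjects drawn with identical category probabilities per sample (sex
~51 % male, education 12/43/45 % low/middle/high, ~10 % left-handed), ages
uniform on 20–26, and AQ-28 totals from per-sample truncated normals with
means 55.63 / 57.05 and SDs 8.96 / 8.70. The truncation interval defaults
to [28, 112], the attainable range of 28 items scored 1–4 — chosen because
the published score-range statements (a 0–3 item scale, a "0–150"
potential range, an observed maximum of 91) are mutually inconsistent, and
[28, 112] is the only convention containing the observed maxima; it is
configurable. ICV is normal with mean 1.5×10⁶ mm³ and SD 1.5×10⁵ mm³
(typical adult values; the source reports none).

**Regional morphometry** follows a linear latent-factor model:
value(s,r) = intercept_r + β_age·age + β_sex·[M] + β_icv·icv +
Σ_k λ_rk f_sk + slope_r·AQ + ε. The shared factors (default 4, loadings
uniform on a per-measure range, e.g. 0.03–0.09 mm against 0.12 mm noise
for thickness) induce the dense positive coupling structure the coupling
analysis rests on, with within-sample partial correlations around 0.3–0.5.
Thickness defaults sit around a 2.5 mm cortical mean, volumes around a few
thousand mm³ per region.

**Voxel maps** are white Gaussian noise fields smoothed with an isotropic
Gaussian kernel (default σ = 4 mm at 2 mm voxels, the smoothing used for
modulated gray-matter images) and renormalized by the kernel's ℓ2 norm so
the per-voxel SD stays at its configured value. The default 32³ grid at
2 mm makes voxel and mm³ cluster sizes both reportable; the mask covers
the grid interior. Injected effects add slope·(AQ − mean AQ) inside a
sphere.

**Coupling modulation.** The operation that creates the alternative
hypothesis for the ΔZ test injects a *shared AQ loading* into both members
of a pair (strength in region-SD units per AQ SD), so the pair's
correlation carries trait variance that conditioning on AQ removes. A pure
trait-by-region interaction (scaling one region's contribution to the
other by AQ) was considered and rejected: linear partialling of AQ leaves
an interaction term untouched, so such a construction is provably
invisible to the |ΔZ| criterion (numerically, |ΔZ| stays at its ~0.005
null level at n = 500 for any interaction strength). Strengths around 10
region-SDs per AQ SD push the targeted pair's |ΔZ| past 1.96 at n ≈ 500
while untargeted pairs (not sharing a modulated region) are exactly
unchanged.

What the generator does **not** emulate: atlas geometry and anatomical
label boundaries, spatial autocorrelation structure of real modulated
gray-matter images beyond stationary Gaussian smoothing, item-level AQ
psychometrics, measurement floor/ceiling effects, or site/scanner
artifacts. Passing tests therefore certify the statistical machinery —
error control, power, calibration — under a faithful null and controlled
alternatives, not the anatomical realism of any map.

## Operating characteristics

The Monte-Carlo harness sizes its default scenarios to run on a desk
machine in minutes, with full-scale parameters configurable:

- **Null familywise replication** (`null_replication_simulation`): 200
  replicates on a 16³ grid with n_perm = 300 at n = 204/304. Each
  replicate runs generate → screen → validate; the familywise rate of a
  spurious "replicated" verdict is Bonferroni-bounded by 0.05 and observed
  well below it (screening must *also* produce a ≥100-voxel cluster for a
  false replication to be possible).
- **Validation power** (`power_simulation`): operates at the ROI level —
  per replicate a validation-sample ROI mean is constructed whose
  covariate-adjusted correlation with adjusted AQ equals the target ρ, and
  it is tested at α/K alongside K−1 null ROIs (default K = 10, so
  α_adj = 0.005). This isolates the validation stage's power and matches
  the closed-form anchor Φ(√(n−c−3)·atanh ρ − z_{1−α/2}) used as an
  independent oracle in the tests; at ρ = 0.3, n = 304, the design's power
  exceeds 0.99. Recovery through the full screen-then-validate path is
  exercised separately with injected voxel clusters.
- **ΔZ calibration** (`delta_z_calibration`): the null distribution of the
  maximum off-diagonal |ΔZ| at the pooled n ≈ 508. Because adding a
  noise covariate perturbs each partial correlation by O(1/n), the maximum
  over 2278 pairs concentrates far below 0.5 (95th percentile ≈ 0.017),
  showing that an observed "all |ΔZ| < 0.5" is exactly what a null cohort
  of this size produces — and also that the fixed 1.96 cutoff is extremely
  conservative for nested covariate sets on the same sample, a known
  weakness of applying a standard-normal two-sample calibration to this
  statistic. The harness quantifies rather than repairs this.

## Numerical notes and limitations

- Residualization uses dense least squares (`numpy.linalg.lstsq`);
  rank-deficient designs are rejected with the collinear columns named via
  pivoted QR. Voxels constant under the model get t = 0 with a warning,
  using a round-off-scale relative tolerance on the residual variance.
- Partial correlations are clipped to [−1, 1]; |r| = 1 returns p = 0;
  zero-variance residuals (at a relative 1e-10 tolerance) raise a
  degenerate-data error rather than returning NaN.
- All generators and experiments derive stage seeds from a master seed by
  drawing 31-bit integers from a seeded generator in a fixed, documented
  order; identical (config, seed) reproduces tables, arrays and reports
  bit-identically.
- The age-row F statistic of a demographics table is not asserted
  anywhere: recomputing it from 2-decimal rounded means is
  rounding-unstable (the value moves by a factor of ~2 within the rounding
  interval), unlike the AQ and categorical rows which are stable to one
  unit in the last printed digit.
- TFCE and FWE cluster-mass inference are out of scope; the pooled-sample
  analysis is represented by running the standard screening on the pooled
  cohort.
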