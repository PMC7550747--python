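# Methods note

This note records the statistical model, the defaults and why they were
chosen, what the synthetic generator does and does not emulate, and the
numerical decisions that affect results.

## 1. Single-case inference

### Model

A patient's biomarker value x* is compared against a normative sample
x₁…xₙ assumed i.i.d. normal. The case is treated as one additional draw
from the same distribution under the null, giving the Crawford–Howell
modified t:

    t = (x* − x̄) / (s · √((n + 1) / n)),    df = n − 1

where x̄ and s are the control sample mean and (n − 1)-denominator SD.
p-values come from the Student-t CDF (`scipy.stats.t`); tails are
`"two"` (default for ROI panels), `"less"`, or `"greater"`.

The naive alternative — z = (x* − x̄)/s referred to N(0, 1) — ignores the
sampling error of x̄ and s and is anti-conservative: at n = 5 its
two-tailed rejection rate at α = 0.05 is roughly 0.15. The modified t is
exactly calibrated under normality at any n ≥ 2. `casemap` exposes the
z-score for effect-size reporting but bases all inference on t.

Assumptions: control values approximately normal within the age window;
the case exchangeable with controls under the null; independence across
controls. Heavy-tailed or skewed biomarkers violate the normality
assumption and will inflate tail error; no nonparametric fallback is
provided.

### Normative cohort construction

- **Age window**: controls with |age − subject age| ≤ 10 years (closed
  interval). Ten years balances cohort size against age-related drift in
  GM volumes; it is a parameter (`age_deviation`) everywhere it appears.
  Fewer than 5 matched controls logs a warning; zero raises an error
  asking the caller to widen the window.
- **TIV normalization**: volume and surface-area measures are divided by
  each subject's estimated total intracranial volume before comparison
  (head-size confound). Thickness and curvature are not TIV-scaled —
  they do not scale with head size. A guard refuses to normalize
  already-normalized records.
- **Degenerate cohorts** (n < 2 or zero variance) raise rather than
  silently returning infinities.

### Multiple comparisons

ROI panels are corrected with Benjamini–Hochberg step-up FDR at q = 0.05
across the panel actually tested (one correction pass per subject per
panel). Significance is strict: adjusted p < q. BH assumes independence
or positive dependence across tests; regional GM measures are positively
correlated, which is the favorable case.

## 2. Voxelwise comparison

Inputs are spatially registered, modulated gray-matter probability maps
on a common grid; the package checks grid/affine agreement and never
resamples.

- **Smoothing**: subject and every control get the *same* Gaussian
  kernel (default FWHM 8 mm; σ = FWHM / (2√(2 ln 2)) per axis, divided
  by the voxel size so anisotropic voxels smooth isotropically in mm).
  `scipy.ndimage.gaussian_filter` with `mode="wrap"` is used so the
  kernel conserves total image mass; with brain data padded by
  background this is equivalent to zero-padding in practice and keeps
  the smoothing operator exactly mass-preserving, which the tests
  verify.
- **Analysis mask**: voxels where the smoothed control mean ≥ 0.1
  (gray-matter floor, the conventional VBM absolute threshold) and the
  control SD ≥ 1e-6 (excludes degenerate voxels).
- **Statistic**: the same modified t applied per voxel (vectorized),
  default one-tailed `"less"` since the question is GM *decrease*.
- **Binarization**: uncorrected p < 0.005 (strict), the conventional
  exploratory single-subject VBM threshold. No cluster-level or FWE
  correction is implemented; per-patient binary maps are meant to feed
  the group overlap stage, where consistency across patients supplies
  the effective error control.

## 3. Group overlap maps

Per-patient binary maps on a common grid are summed and divided by the
number of patients, giving a voxelwise probability of atrophy. Consensus
maps threshold this at a fraction (inclusive ≥; defaults 0.75 and 0.90).
Region atrophy prevalence counts patients with at least `min_voxels`
(default 1) suprathreshold voxels inside a region mask, reported as a
count and a percentage. These are descriptive summaries, not inferential
maps.

## 4. Clinical association and longitudinal change

- **Disease burden** (Huntington's disease): Age × (CAG − 35.5). CAG
  below 35.5 yields a negative burden and logs a warning rather than
  raising, since the formula is sometimes applied to intermediate
  alleles.
- **Pearson r** with p from the exact t transform on n − 2 df
  (scipy); requires n ≥ 3 and non-degenerate variance.
- **Partial correlation** r(x, y | z) from the three pairwise
  correlations,
  r_xy·z = (r_xy − r_xz·r_yz) / √((1 − r_xz²)(1 − r_yz²)),
  with p from t on n − 3 df. This is algebraically identical to
  correlating the OLS residuals of x on z with those of y on z; the
  test suite verifies agreement with that residualization oracle to
  1e-10. Near-collinear z (|r| ≥ 1 − 1e-12 with either variable)
  raises.
- **Annualized rate**: OLS slope of biomarker against time in years
  (intervals given in months). With two sessions this reduces to the
  difference quotient.
- **Group rate comparison**: pooled-variance two-sample t-test
  (`scipy.stats.ttest_ind`). Both groups constant and equal returns
  t = 0, p = 1 instead of scipy's NaN; constant but unequal raises.

## 5. Synthetic data generator

The generator exists so that every pipeline can be exercised end-to-end
with known ground truth; it emulates the *statistical structure* of a
structural-MRI study, not MRI physics.

- **Reproducibility**: each subject gets an independent RNG stream via
  `np.random.SeedSequence(seed, spawn_key=...)`, so adding subjects or
  requesting images does not perturb existing subjects' data. The same
  seed always reproduces the same study byte-for-byte.
- **Scalar biomarkers**: per-region normal draws with plausible means
  and SDs; TIV ~ |N(1.5×10⁶, 1.2×10⁵)| mm³; ages uniform in a
  configurable range (default 30–65); patient CAG uniform integers in
  40–48. Implanted ROI effects shift a chosen subject's biomarker by a
  stated number of control SDs.
- **Images**: a solid-ellipsoid gray-matter template (intensity 0.8
  inside semi-axes 0.42 × grid) plus i.i.d. Gaussian voxel noise
  (default SD 0.05), clipped to ≥ 0. Focal lesions subtract
  `effect × noise_sd` inside a sphere. Real GM maps have spatially
  correlated noise, partial-volume gradients, and anatomy; none of that
  is modeled — detection performance on this generator is optimistic
  relative to real data.
- **Longitudinal series**: linear trajectories with a stated annual
  rate plus optional i.i.d. session noise.
- Default cohort sizes (24 controls, 23 patients) match the scale of a
  typical single-site neurodegenerative-disease study and keep the
  worked examples fast.

## 6. Numerical choices

- p-values never rounded internally; reports serialize floats with
  `%.12g` and CSVs are read back with round-trip float parsing, so
  write→read is exact.
- BH adjustment uses a stable sort and a reversed cumulative minimum;
  tie handling therefore matches the textbook step-up procedure exactly
  (verified against a brute-force oracle and against
  `statsmodels.stats.multitest` in the test suite).
- t-CDF accuracy is checked against a 30-significant-digit regularized
  incomplete-beta evaluation (mpmath) to 1e-6 absolute.
- Seeds derived from a user seed are reduced mod 2³¹ so they stay valid
  for every RNG API.

## 7. Open design decisions and limitations

- No voxelwise multiple-comparison correction (FWE/cluster/permutation);
  the uncorrected-p + group-overlap design is deliberate but limits
  single-patient voxelwise claims to exploratory use.
- Age matching by windowing, not covariate regression. A normative
  regression model (e.g., age + sex GAM) would use controls more
  efficiently; windowing was chosen for transparency at small n.
- TIV correction by division (proportion method) rather than the
  residual method; the two differ when TIV–volume scaling is not
  proportional.
- Normality of control biomarkers is assumed, not tested.
- The package performs no image preprocessing (segmentation,
  registration, modulation); inputs are taken at face value on a shared
  grid.

## 8. End-to-end performance characterization

One documented end-to-end property of the panel pipeline: with 20
controls, a 12-region panel, two-tailed testing and BH-FDR at q = 0.05,
a −3 SD single-region deficit is detected in roughly 40–50% of
replicates, not ≥ 95%. This is a power fact, not a bug: the expected
modified t is −3·√(20/21) ≈ −2.93 (p ≈ 0.009 two-tailed), while BH
rank-1 significance over 12 tests needs p < 0.0042. Reliable (≥ 95%)
detection at these settings requires roughly a −5 SD deficit, a larger
control sample, a smaller panel, or one-tailed testing. The
specificity side is well behaved: healthy subjects are flagged
anywhere in the panel at ≈ 5%. `casemap.evaluation.roi_panel_study`
reproduces both numbers.
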