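# Methods

## The normative model

The package quantifies, per individual, how much plasma melatonin
deviates from the level expected for that individual's pineal gland
volume (PGV), using controls as the reference population.

Melatonin (nM) and PGV (mm³) are natural-log transformed; both are
strictly positive and right-skewed, and hormone–volume relationships
are closer to linear on the log-log scale. On the control sample the
conditional mean m(x) of log-melatonin given log-PGV x is estimated by
LOESS: at each training point, a weighted least-squares polynomial over
the `ceil(span·n)` nearest neighbours (ties at the boundary distance
included), with tricube weights `(1−u³)³` on distance normalized by the
neighbourhood maximum. The conditional SD s(x) is the square root of a
second, local-constant (degree-0) kernel smooth of the squared
residuals. The deviation score of subject i is

    z_i = (log mel_i − m(log PGV_i)) / s(log PGV_i),

classified low / normal / high with strict inequalities at ±threshold
(default 2 SD units). For a well-specified fit, scoring the controls
themselves gives mean(z) ≈ 0 and SD(z) ≈ 1 — the self-normalization
property the test suite checks.

Assumptions: a smooth conditional mean and SD of log-melatonin in
log-PGV; independent residuals (no family structure is modelled);
controls are an unbiased reference for the covariate effect.

### Tunable parameters

| parameter | default | meaning |
|---|---|---|
| `span` | 0.75 | neighbourhood fraction; conventional LOESS default, sensible for reference samples of ~50 controls |
| `degree` | 1 | local polynomial degree (0–2); local-linear avoids boundary bias of degree 0 without the variance of degree 2 |
| `robustness_iters` | 0 | bisquare re-weighting passes; off by default since the exclusion filter already screens gross outliers |
| `scale_floor` | 1e-6 | minimum admissible local SD (log units); guards the z denominator in degenerate (noiseless) fits |
| `threshold` | 2 | extreme-deviance cut in SD units |

### Numerical choices

- **Variance pass at degree 0.** A local-linear smooth of squared
  residuals can dip negative near the boundaries of the covariate range;
  after flooring, the resulting near-zero SD turns boundary subjects
  into astronomically large |z|. The kernel-weighted mean of squares is
  nonnegative by construction, at the cost of some boundary bias in the
  SD curve.
- **Evaluation and extrapolation.** Fitted values are computed at the
  training abscissae and interpolated linearly in between; duplicated
  abscissae are collapsed to their mean fit. Outside the control range
  the curves are clamped to the boundary fit, a warning is emitted, and
  scored subjects carry a `clamped` flag — they are flagged rather than
  dropped, since dropping would silently change the group denominators.
- **Degenerate neighbourhoods.** Zero distance spread falls back to a
  weighted mean; a neighbourhood with fewer positively weighted points
  than the polynomial needs likewise degrades to degree 0.
- **Ties and sign conventions.** Mann–Whitney U uses midranks, the
  tie-corrected permutation variance, and no continuity correction by
  default (configurable); z is oriented positive when the second group
  stochastically exceeds the first, and an all-tied comparison
  degenerates to z = 0, p = 1 rather than 0/0.
- **Percentile exclusion.** The PGV screen excludes records strictly
  above the pooled empirical 99th percentile, computed by linear
  interpolation of the *exclusive*-CDF (Weibull/type-6) plotting
  positions, so that a planted 1% tail sits above the threshold rather
  than straddling the top legitimate record. The filter is skipped with
  a warning below n = 10, where an empirical 99th percentile is
  meaningless.
- **Power.** `required_n` searches integer n against the exact
  noncentral-t power of the two-sided test (not the normal
  approximation), for one-sample, equal two-sample and unequal-ratio
  designs.

### Covariate corrections

To check that group differences in deviation scores are not secondary
to age or total brain volume (TBV), the outcome can be pre-corrected on
either of two routes, both estimated on controls only and applied to
everyone: a linear OLS of log-melatonin on the covariates, or a
sequential LOESS normative correction (one covariate at a time, order
configurable — a multivariate smoother is deliberately out of scope).
Each pass replaces log-melatonin by its residual from the control trend
plus the control mean, preserving the scale; the PGV-normative analysis
is then re-run on the corrected table. Control-only fitting everywhere
prevents the group effect under study from leaking into the reference.

## The synthetic cohort generator

The generator emulates the structure of a three-group clinical cohort
(ASD probands, unaffected first-degree relatives, typically developing
controls). Default group sizes 78/90/47; per-group sex ratios, age, IQ
and SRS distributions and the arithmetic means/SDs of melatonin
(0.08/0.13/0.14 nM), PGV (96.1/96.2/108.8 mm³) and TBV
(1169.1/1135.7/1152.7 cm³) are calibrated to published descriptive
tables for such a cohort.

Mechanics:

- Age, PGV and TBV are truncated normals (age ≥ 4 years — the youngest
  plausible MRI participant — PGV and TBV > 0), with the location
  parameter solved so the *truncated* mean still equals the target.
- Log-melatonin is `A_g + b·(log PGV − c) + ε`, with `c` the expected
  control log-PGV, slope `b = 0.35` by default (control log-log
  correlation ≈ 0.3, a weak-to-moderate dependence in line with reports
  on healthy cohorts), and `ε` Gaussian. `A_g` and the noise SD are
  solved per group from the target arithmetic mean and SD by exact
  moment matching under the group's PGV distribution (the correction
  factors `E[(PGV/e^c)^{kb}]` are computed by quadrature), so simulated
  arithmetic moments converge to the targets as n grows. Targets whose
  SD/mean ratio is incompatible with the planted slope raise an error
  naming the group.
- The group-level melatonin deficit enters as the PGV-independent
  intercept offset implied by the group's target mean (ASD ≈ −0.51 log
  units, relatives ≈ −0.01 under the defaults, control 0) — the
  generator's default causal structure places the deficit in the
  melatonin pathway, not the gland. A `pgv_mediated` mode equalizes the
  intercepts instead, so group differences flow only through gland
  volume, for contrast experiments.
- `planted_truth()` returns the exact control curve, offsets and noise
  SDs — the oracle for recovery tests. Optional cyst-like records with
  ~8× PGV are appended and flagged in a `planted_outlier` column; their
  melatonin is drawn at the group-typical volume, since a cyst inflates
  the measured volume, not hormone output.

What the generator does **not** emulate: family/genetic correlation
between relatives and probands, assay noise structure, circadian
time-of-day variation, segmentation error, or cyst/calcification
partial-volume effects. Passing tests therefore demonstrate that the
pipeline recovers the structure it assumes — not that real cohorts
satisfy those assumptions.

## Problem sizes used in the tests

Monte-Carlo assertions use the smallest sizes at which their stated
tolerances are statistically comfortable: study scale (n = 215) for
self-normalization and report-level checks; 20× group sizes for curve
monotonicity, no-op corrections, slope/offset recovery and the
extreme-low majority; 100× for generator moment calibration (sampling
error of a group mean ≈ 0.5% there, against 2% tolerances). Fixed seeds
make every stochastic test reproducible.

## Known limitations

- A single covariate per smoother; multi-covariate correction is
  sequential, so strongly correlated covariates are order-dependent.
- The local SD inherits boundary bias from the degree-0 variance pass;
  deviation scores of subjects near the extremes of the control PGV
  range are correspondingly less calibrated (and flagged when clamped).
- With ~47 controls, LOESS at span 0.75 has a handful of effective
  degrees of freedom; the normative curve is a trend estimate, not a
  fine-grained dose-response.
- Rank-based p-values use the large-sample normal approximation; exact
  enumeration is only practical (and used, in tests) for tiny samples.
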