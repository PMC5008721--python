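# Methods

This note documents the models and procedures implemented in `metadrift`,
the parameter choices that matter, what the synthetic-data generator does
and does not emulate, and the numerical decisions behind the code.

## Study design assumed by the workflow

The workflow targets repeated-measures untargeted metabolomics: each
patient is sampled at three timepoints — before an intervention (PRE),
shortly after (POST) and at a one-year follow-up (FU) — and all serum
samples are measured by LC-HRMS in one batch, in randomized order, with a
solvent blank (BL) followed by a pooled QC injected after every third serum
sample and an extra BL+QC pair opening and closing the run.  At the default
cohort size of 44 patients this gives 132 serum, 46 blank and 46 QC
injections.  The pooled QC is an aliquot mixture of all study samples, so
its intensity trajectory along injection order is a direct readout of
instrument sensitivity drift; blanks reveal system peaks (impurities of the
measurement system).

Input begins at the grouped feature matrix (features x injections, peak
areas); raw-file conversion, peak detection and retention-time alignment
are upstream tools' business and out of scope.  Positive- and negative-mode
features live in one table with a per-feature `ion_mode` column; all
filtering and statistics operate on the merged table.

## Filters

* **System peaks**: mean non-missing blank intensity / mean non-missing QC
  intensity > 0.5.  The ratio rule is scale-free; the threshold is
  configurable.  Features absent from all blanks are never flagged.
* **Poorly detected**: detected in fewer than 80% of QCs.  QCs are
  technical replicates of one pool, so absence there indicates unreliable
  detection regardless of biology.
* Both run **before** drift correction so junk features cannot pollute the
  spline fits; the RSD filter (below) runs after correction, per the
  workflow's ordering.

## Drift correction

Per feature, the 50% conditional quantile of QC intensity *y* as a function
of injection order *x* is estimated by nonparametric quantile regression on
a cubic B-spline basis with 16 degrees of freedom: 12 internal knots at
equally spaced quantiles of the QC orders, boundary knots at the ends of
the full run so the basis covers every injection.  The check loss
`sum rho_tau(y - B(x) beta)` with `rho_tau(u) = u (tau - 1[u<0])` is
minimized **exactly** as a linear program (HiGHS via
`scipy.optimize.linprog`); an IRLS fit was tried first but converged slowly
and unreliably at this design size, while the LP solves each 46-point,
16-column problem in ~5 ms and satisfies the subgradient optimality
property (the counts of strictly negative/positive residuals stay within
the basis dimension of `tau*n` / `(1-tau)*n`; asserted in tests, with a
brute-force interpolation-enumeration oracle pinning the optimum on small
instances).

Correction is multiplicative and median-anchored:
`corrected(i) = raw(i) * median(QC) / curve(order_i)` for every injection
(serum, QC and blank alike), so QCs lying exactly on the curve collapse to
their median and corrected values keep the original intensity scale.  The
curve is clamped to its boundary values outside the first/last QC rather
than extrapolated — spline extrapolation is wild, and the interleaving
brackets every serum sample anyway.  A feature whose fitted curve is not
strictly positive anywhere a value needs correcting is passed through
uncorrected and reported as a failure.  When a feature has fewer than 17
non-missing QCs the basis dimension falls back to `max(4, floor(n/3))` with
a warning.

After correction, features with QC coefficient of variation above 30% are
dropped (only well measured or well corrected features enter statistics).

## Feature selection

Two contrasts are analyzed with the same machinery: PRE vs POST
(short-term) and PRE vs FU (long-term).  Intensities are natural-log
transformed first — the noise is multiplicative, so the log scale is where
a paired t-test's assumptions are closest to holding; this is switchable.
Only serum samples enter; QCs and blanks never do.

* **Univariate**: paired t-test per feature on per-patient differences,
  pairs with missing values dropped, Benjamini-Hochberg FDR adjustment
  across features (via statsmodels), significance at adjusted p < 0.01.
  Degenerate cases are pinned by convention: zero-variance zero-mean
  differences give p = 1; zero-variance nonzero-mean give the p -> 0 limit.
* **Multivariate**: a supervised Random Forest (300 trees, 30 variables
  tried at each split, scikit-learn) classifying the two timepoints.
  Importance is out-of-bag permutation mean decrease accuracy (MDA): per
  tree, the drop in OOB accuracy when one feature's OOB values are
  permuted, averaged over all trees (features a tree never splits on
  contribute exactly zero, so only split-on features need permuting — same
  average, much faster).  A feature is influential when MDA > 0.  Missing
  values are imputed with half the feature's minimum observed value for the
  forest only.
* A feature is **selected** within a contrast when both criteria hold (AND;
  OR is available), and the **final set** is the intersection of the two
  contrasts' selections.  V- and Lambda-patterned features (whose PRE and
  FU levels coincide) are thereby excluded from the final set by design —
  the point of measuring both horizons.
* Forest proximities (fraction of trees where two samples share a leaf) are
  embedded by classical metric MDS on `1 - proximity` (double-centered
  squared dissimilarities, top-2 eigenvectors scaled by the root
  eigenvalue).  The unsupervised variant classifies real rows against
  column-permuted copies, the standard construction.

## Trend patterns

For each selected feature the median intensity per timepoint over all
patients defines two steps, POST/PRE and FU/POST.  A step is a move only
when it leaves the band `[1 - eps, 1 + eps]`; the calls are increasing /
decreasing (at least one move, all moves in one direction), V (down then
up), Lambda (up then down), flat (no move).  The default tolerance is
**eps = 0.03**: it has to be below 0.04, otherwise published reference
trajectories whose second step is a genuine 4-9% move (e.g. a V-pattern
with steps 0.66 then 1.09) would be flattened into unidirectional calls,
and comfortably above zero so that sampling noise in medians (about 2% at
44 patients under the default noise model) does not manufacture spurious
moves.  The mean-based ratio triple (POST/PRE, FU/POST, FU/PRE) is reported
alongside because mean and median trajectories can genuinely disagree for
skewed features — one reference metabolite (arginine) is the documented
example, and the classifier is not expected to reproduce its block from
mean ratios.

## Annotation

Accurate-mass-only annotation: theoretical m/z is monoisotopic mass plus or
minus one proton mass (1.00727646 Da) for [M+H]+ / [M-H]-; a candidate
matches when |ppm error| <= 10 and the adduct polarity equals the feature's
ionization mode.  The 10 ppm default is deliberate: the bundled panel's
printed m/z values deviate up to ~9 ppm from theory, so a 5 ppm gate would
reject real annotations.  Electron mass is ignored (sub-ppm at these
masses).  A match with an expected retention time within 0.5 min is level 1
(identified against a standard); otherwise level 2 (putatively annotated).
The bundled reference list covers 36 serum metabolites with formulas,
expected RTs and a cardiovascular-risk flag on the 9 established markers
(TMAO, indoxyl sulphate, choline, alanine, phenylalanine, tyrosine, valine,
leucine/isoleucine, ornithine); no online database queries at runtime.

## Clinical outcomes

The weight-loss ratio is weight(FU)/weight(PRE); patients strictly below
the cohort median form the high-weight-loss group, ties go to low weight
loss.  The per-metabolite group comparison uses the per-patient decline
`d = log(FU/PRE)` — unit-free, so intensity rescaling cannot change it —
with Welch's two-sample t-test by default (Mann-Whitney switchable); for
weight groups a comparison of log FU levels is also provided.  Diabetes
remission (HbA1c < 6.5% without pharmacological treatment) is consumed as a
precomputed flag; the package does not adjudicate it from medication data.

## Synthetic-data generator

The generator is the package's test bed and defines its study conditions:

* intensity(f, i) = baseline_f x drift_f(order_i) x pattern_f(timepoint,
  patient) x exp(eps), with eps ~ N(0, sigma), sigma = sqrt(ln(1 +
  noise_cv^2)) and noise_cv = 0.08 — log-normal keeps intensities positive
  and the CV scale-stable; baselines are log-uniform over 10^4..10^7.
* drift_f is a mixture of 2-4 low-frequency cosine components (0.5-2 cycles
  per run) drawn from a pool shared across features, rescaled so the curve
  spans `[1 - a, 1 + a]` with the amplitude `a` uniform in [0.15, 0.45] per
  feature.  The amplitude is defined as the maximal fractional deviation
  from baseline; with this normalization the raw median pooled-QC CV of a
  default run lands at ~0.2 (the value pooled-QC monitoring typically shows
  before correction), and no smooth curve could reach that calibration if
  the same range were read as a peak-to-trough span.  Correction brings the
  median QC CV to ~0.07, comfortably under the 0.1 benchmark.
* differential features follow the four patterns with log2 multipliers
  (0, e/2, e), (0, -e/2, -e), (0, -e, 0), (0, e, 0) at PRE/POST/FU for
  effect size e (default: 40 features each at e = 1); each patient's
  exponent is scaled by a median-1 log-normal random effect (CV 0.2) to
  mimic the strong individual responses such cohorts show.  Because the
  random effect has median one, the recorded ground-truth medians are the
  analytic pattern values.
* system peaks (5%) appear in blanks at QC level; other features' blanks
  sit at 1% of baseline.  Poorly detected features (5%) are missing at
  random in 60% of all injections.  Patient covariates (weights, diabetes,
  remission, centers) are drawn to match the cohort's reported summary
  statistics (e.g. baseline weight ~ N(126.4, 19.5) kg, weight ratio
  ~ N(0.70, 0.06), 24/44 diabetic, 9/24 remitting).

What the generator does **not** emulate — and hence what passing tests do
not certify about real data: correlated features (adduct/isotope clusters),
heavy-tailed or intensity-dependent noise, missingness that depends on
abundance, retention-time drift, batch boundaries, or any real biological
covariance structure.  Recovery results on synthetic tables are therefore a
correctness check of the machinery, not a power guarantee for real cohorts.

## Problem sizes and runtime

Full-scale runs (923 features, 224 injections) are used where the claim is
about the study scale itself: the drift-correction efficacy check runs 20
such seeds (~90 s total; each full correction pass is ~4 s).  Property and
recovery tests use smaller tables chosen to keep each test in seconds while
leaving the tested effect overwhelming relative to its standard error:
200-300 features for recovery/null-FDR suites, 12-15 points for the
LP-enumeration oracle (C(12,4) interpolations), 20 patients for the null
pipeline.  All randomness flows from explicit seeds; the pipeline spawns
per-stage seeds deterministically from one master seed, so every stage is
individually reproducible and a rerun with the same config produces a
byte-identical report.

## Known limitations

* The second-stage "attunement" is evaluation of the QC-fitted curve at
  every sample's order plus median re-anchoring; refitting a second
  quantile regression on all samples would be an alternative reading, not
  implemented.
* MDA ties at exactly zero are treated as non-influential (the > 0 gate is
  strict), which slightly deflates recall when many redundant informative
  features split importance.
* The blank filter's ratio rule is one of two defensible readings
  (presence/absence being the other); the threshold and rule are exposed in
  config.
* Annotation is accurate-mass only; isobars within tolerance are returned
  ranked by |ppm| and level, not resolved.
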