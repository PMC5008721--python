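# metadrift

Post-processing and statistics for **untargeted LC-HRMS metabolomics** with
repeated measures.  The package takes an XCMS-style grouped feature matrix
(rows = metabolic features with median m/z, median RT and ionization mode;
columns = injections; values = peak areas) plus a sample sheet describing a
run of serum samples interleaved with solvent blanks (BLs) and pooled
quality controls (QCs), and carries it through:

1. **Filtering** — system peaks (visible in blanks: mean blank / mean QC
   intensity > 0.5) and poorly detected features (seen in < 80% of QCs) are
   removed.
2. **Drift correction** — per feature, the conditional median of the pooled-QC
   intensities *y* along injection order *x* is fit by nonparametric quantile
   regression on a cubic B-spline basis,

   minimize Σⱼ ρ_τ(yⱼ − B(xⱼ)·β),  ρ_τ(u) = u·(τ − 1[u<0]),

   with τ = 0.5 and 16 degrees of freedom, solved exactly as a linear
   program.  Every injection *i* is then re-anchored multiplicatively:
   corrected(i) = raw(i) · median(QC) / curve(orderᵢ).  A post-correction
   30% relative-standard-deviation filter on the QCs keeps only well measured
   or well corrected features.
3. **Feature selection** — per time contrast (PRE vs POST, PRE vs FU), a
   feature is selected when its Random-Forest out-of-bag permutation
   importance (mean decrease accuracy) is > 0 **and** its
   Benjamini–Hochberg-adjusted paired-t p-value is < 0.01 (forests: 300
   trees, 30 variables tried per split, on log intensities).  The final set
   is the intersection of both contrasts — features carrying both short- and
   long-term information.  MDS of the forest proximity matrix provides the
   visual check.
4. **Trends & annotation** — each selected feature's median trajectory over
   PRE/POST/FU is classified as increasing, decreasing, V (down then up) or
   Λ (up then down), and features are putatively annotated by accurate mass
   (±10 ppm, [M+H]⁺/[M−H]⁻) against a bundled 36-metabolite serum panel with
   cardiovascular-risk flags; a retention-time match upgrades the annotation
   to "identified".
5. **Clinical outcomes** — a median split of the weight-loss ratio
   (weight FU / weight PRE) into high/low weight loss, and Welch tests of
   the per-patient decline log(FU/PRE) between diabetes-remission and
   non-remission patients.

Because studies of this kind rarely deposit raw data, the package ships a
**synthetic-data generator** (`metadrift.simulate`) that emulates the full
study design — 44 patients × 3 timepoints = 132 serum injections, a BL+QC
pair after every third serum sample (46 + 46 in one batch), smooth
multiplicative injection-order drift, log-normal measurement noise, system
peaks, sparse features and trend-patterned differential features — with
complete ground truth, so every stage is testable end to end.

## Worked example

```sh
metadrift simulate --seed 3 --out sim
metadrift filter   --table sim/feature_table.csv --sheet sim/sample_sheet.csv --out filt
metadrift correct  --table filt/filtered_table.csv --sheet sim/sample_sheet.csv --out corr
metadrift select   --table corr/analysis_table.csv --sheet sim/sample_sheet.csv --seed 3 --out sel
metadrift trends   --table corr/analysis_table.csv --sheet sim/sample_sheet.csv \
                   --features sel/final_features.csv --out tr
metadrift outcomes --table corr/analysis_table.csv --sheet sim/sample_sheet.csv \
                   --features sel/final_features.csv --out outc
```

prints

```
wrote 923 features x 224 injections to sim
kept 831/923 features
median QC CV 0.212 -> 0.072; 831 features pass RSD <= 0.3
PRE_POST: 109 selected, OOB error 0.000
PRE_FU: 78 selected, OOB error 0.000
final intersection: 31 features
pattern
decreasing    16
increasing    15
weight-loss median ratio 0.699; median reduction 37.4 kg (IQR 11.97 kg)
remission comparison written for 31 features
```

Reading the numbers: 92 of 923 simulated features are junk (46 system peaks
flagged by the blank filter, 46 sparse features by the detection filter);
drift correction brings the median pooled-QC coefficient of variation from
0.212 down to 0.072, so all remaining features pass the 30% RSD gate.  The
forests separate pre- from post-surgery samples perfectly on this synthetic
effect size, and the intersection of the two contrasts retains only
monotone (increasing/decreasing) features — V and Λ features are excluded
by construction because their PRE and FU levels coincide, which is exactly
why single-timepoint designs mislead.  The same stages are available as
library calls (`simulate`, `blank_filter`, `correct_table`,
`select_contrast`, `trend_table`, `weight_groups`, ...), and
`metadrift run-all --seed 1 --out rundir` executes everything in one go with
a machine-readable `run_report.json`.

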