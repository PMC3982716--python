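# Methods

## Comparative-Ct quantification

Relative expression is computed by the standard comparative-Ct method
assuming amplification efficiency 2 for every assay: replicate Ct
values are combined by arithmetic mean (no outlier rejection),
ΔCt is taken against the normalizer assay of the same nucleic-acid
class (default RNU66 for miR targets, β-actin for mRNA targets), ΔΔCt
against the calibrator sample (default MCF12A, a normal mammary
epithelial line), and RQ = 2^−ΔΔCt. Averaging happens on the Ct
(log) scale, not on RQ: the replicate mean of a log-normal quantity is
taken where the noise is approximately additive.

Censored wells ("Undetermined": no amplification within the cycle
ceiling, default `max_cycles = 40`) are handled by policy. The default
`impute_max` substitutes the ceiling and propagates a per-cell censored
flag into the expression matrix, which keeps undetectable miRs
representable as near-zero RQ while marking them as baseline-limited —
this matters downstream, where enormous fold inductions measured
against a censored baseline are lower bounds set by the instrument, not
measurements. `drop` discards censored replicates (erroring if a group
empties), `error` refuses censored input. Efficiency-corrected
(standard-curve) quantification is out of scope.

Numerical guarantees, enforced by tests: RQ > 0 everywhere;
−log2(RQ) reproduces ΔΔCt to 1e−12; adding a constant to every Ct of a
sample leaves that sample's RQ row unchanged (normalizer cancellation);
RQ is strictly decreasing in target Ct.

## Threshold classification

For each marker the classifier searches for the expression cutoff that
best separates hypermethylator (positive) from non-hypermethylator
samples, where a sample is called "diminished" — predicting
hypermethylator status — iff its RQ is **strictly below** the cutoff
(at-threshold values are not diminished). Candidates are the midpoints
between consecutive distinct observed values plus one sentinel on each
side (offset by half the observed range, or 0.5 for constant data);
this grid visits every achievable confusion matrix once, so the search
is exact. The default objective is the correct-assignment fraction
CA = (TP+TN)/n; `max_youden` (sensitivity + specificity − 1) and
`prevalence_weighted` (π·sens + (1−π)·spec at a user-supplied prior π,
the expected posterior correctness; with π equal to the observed
prevalence it coincides with CA) are alternatives. Ties are broken by
maximal Youden's J, then by the lowest threshold — deterministic, and
favouring sensitivity at equal CA.

Diagnostic metrics are kept as exact proportions; ratios with zero
denominator are reported as not-applicable (None), never 0. Reports
render whole percents with half-up rounding (14/16 → 88%). No ROC-AUC,
cross-validation or confidence intervals are computed: with 16
training samples these single-marker cutoffs are descriptive, and the
training-set CA is an optimistic estimate of out-of-sample accuracy.

## miR scores and group statistics

The call matrix over the six-marker panel (miR-29c, miR-148a, miR-148b,
miR-26a, miR-26b, miR-203) is binary; the miR score is its row sum,
an integer 0–6 counting the panel miRs a line has lost. Group summaries
are mean ± SEM with SEM = s/√n using the n−1 sample standard deviation.
The unpaired two-tailed t-test defaults to Student (pooled variance),
the conventional reading of "unpaired t-test" in spreadsheet-era
analyses; Welch is available by flag. No multiple-testing correction is
applied anywhere — per-marker differential-expression and correlation
p-values are nominal, and reports say so. A marker with zero variance
across all samples is flagged degenerate (p not-applicable) rather than
given the vacuous t = 0; two genuinely identical groups return
t = 0, p = 1.

## Correlations

Pearson r with the two-tailed p from t = r·√((n−2)/(1−r²)) on n−2 df
(scipy's implementation). Score associations correlate the miR score
with the promoter methylation score and the biomarker-gene expression
score — integer counts on 0–9 over the nine methylation-sensitive
biomarker genes (CEACAM6, CDH1, CST6, ESR1, GNA11, MUC1, MYB, TFF3,
SCNN1A), consumed as given, never recomputed from methylation-specific
PCR. Co-regulation runs all C(k,2) marker pairs on raw RQ values by
default; because RQ is multiplicative a log2 option exists, and on a
monotone-related pair the two give different r (rank structure is
preserved, linearity is not). Zero-variance vectors and n < 3 are
errors, not NaNs.

## Perturbation summaries

Each (cell line, readout) experiment must contain an untransfected
control arm (n ≥ 2). Every other arm is summarised as
fold_change = mean(treated RQ)/mean(control RQ) — the ratio of arm
means, not the mean of per-replicate ratios, matching grouped ΔΔCt
reporting — with percent_reduction = (1 − fold_change)·100 emitted
alongside, so knockdown ("73% reduction") and induction ("3.2-fold")
are two renderings of one number and direction is never ambiguous.
Significance vs the untransfected arm is an unpaired two-tailed t-test
with stars at p < 0.05 / 0.005 / 0.0005, monotone in p by construction.

## Reference cohort

The 16-line cohort (10 hypermethylator, 6 non-hypermethylator) ships as
a reconstructed call matrix: the published per-miR exception lists
determine every cell, giving 49 diminished calls across the
hypermethylator rows, hypermethylator scores (5,5,5,5,6,5,1,6,5,6)
(mean 4.9, SEM 0.46) and per-miR confusion counts — e.g. miR-29c
TP 6 / FP 1 / TN 5 / FN 4 → CA 69%, and miR-148b TP 10 / FP 1 → CA 94%.
The source is internally inconsistent about BT20: its per-miR lists
give non-hypermethylator scores {2,2,1,0,0,0} (mean 0.83), while the
printed group mean 0.67 ± 0.33 requires one fewer call. Both variants
are shipped (`prose` and `printed_mean`, differing only in BT20's
miR-26b call) and neither is corrected toward the other. Two published
per-miR CA values (miR-26b 94%, miR-203 81%) disagree with the counts
the same source's exception lists imply (88% and 75%); the package
reports what the encoded counts give — notably the `printed_mean`
variant does reproduce miR-26b's 94%. A companion noise-free Ct table
(`reference_ct_table`) places diminished cells 3.5 cycles above the
calibrator ΔCt and non-diminished cells at it, so the full
quantify → fit → call → score chain reproduces the call matrix exactly.

## Synthetic cohorts

Simulation is at the Ct level so normalisation and calibration are
exercised, not bypassed. Defaults mirror the study design: 10 + 6
samples plus calibrator, the six-marker panel, triplicates. Per well,
Ct = normalizer mean (22 ± 0.25 cycles across samples) + base ΔCt
(3 cycles) + group shift (4 cycles for hypermethylator samples — a
16-fold expression drop, the order of magnitude separating the groups
for informative markers; per-marker overrides allowed) + a per-sample
biological effect (SD 0.5 cycles) + replicate noise (SD 0.3 cycles,
typical TaqMan technical spread), clipped to [0, 40]. True per-line RQ
magnitudes for the real cohort are published only as bar graphs, so
these parameters are order-of-magnitude choices, fixed once.
Methylation and expression scores are monotone functions of the
sample's true diminished-marker count rescaled to the 0–9 biomarker
scale, plus bounded integer jitter (±1 by default) — enough to make
sign recovery non-trivial without drowning the signal. One seeded
`numpy` generator drives everything; a fixed seed gives byte-identical
output.

What passing on synthetic data does **not** show: the simulator draws
independent Gaussian Ct noise per marker, so it has no miR–miR
co-regulation structure, no assay-efficiency differences, no
plate/batch effects, and group membership determines the shift
deterministically. Pipeline correctness and power under clean
separation are tested; robustness to real-world artefacts is not.

## Problem sizes and numerical choices

Stochastic checks use: 200 random instances (n ≤ 64) for
threshold-search/brute-force agreement; 1000 simulated null cohorts
(15,000 pairs) for the co-regulation type-I rate, which lands within
Monte-Carlo error of the nominal 5%; 100 simulated cohorts for
end-to-end label recovery via the composite score. These sizes give
stable estimates in seconds on one core. Floating-point comparisons in
tests use 1e−12 absolute tolerance for algebraic identities and
documented looser bands for Monte-Carlo rates. TSV readers parse floats
in exactly-rounding mode so every output table round-trips through its
reader bit-for-bit.

## Known limitations

- Single-marker thresholds and the composite score are fit and
  evaluated on the same 16 lines; all diagnostic metrics are
  training-set metrics.
- Efficiency is assumed exactly 2; no standard-curve correction.
- The Fig-style "15% SEM" error-bar convention some instruments report
  is not modelled; replicate-level SEM is computed from the data.
- Correlation defaults operate on raw RQ; heavy right-skew can make a
  few high-expressing lines dominate r (use the log2 option to check).
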