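# Methods

`evpanel` implements a biomarker-discovery pipeline for targeted
plasma-EV proteomics measured by proximity extension assay (PEA). This note
documents the statistical model behind each stage, the defaults and why they
were chosen, what the synthetic cohorts do and do not emulate, and the
numerical conventions that make every run reproducible.

## NPX and the analyzable protein set

PEA reports protein abundance as NPX, a log2-scale relative unit derived
from qPCR cycle thresholds in three steps: extension-control correction
(`dCt = Ct_analyte − Ct_ext`), inter-plate correction
(`ddCt = dCt − dCt_IPC`), and a per-analyte correction factor
(`NPX = CF − ddCt`). One NPX unit is one doubling of signal. The
implementation is exact arithmetic on long-format readout tables; control
consistency (one IPC per plate × analyte, one CF per analyte) is validated
up front.

Two sequential filters define the analyzable set. A protein is removed when
more than half of its observed values sit below the assay's limit of
detection (the threshold is configurable; the protein-level reading of
"under the LOD" is not standardized, so the rule and its default are
explicit here). In retained proteins, below-LOD cells become missing rather
than being substituted with the LOD, so that all missingness is handled by
one mechanism — in-split median imputation — downstream. Second, proteins
missing in strictly more than 30% of samples are removed; the boundary is
strict, so exactly 30% is retained. Filter reports reconcile:
input − retained = |removed|.

A reverse-normalization utility shifts each sample's NPX by
`log2(pre-dilution concentration / fixed assay concentration)`, undoing the
dilution-to-fixed-concentration step for sensitivity re-analysis. The log2
concentration-ratio form is this package's reconstruction of that check.

## Univariate statistics

Group comparisons pass through a normality gate: a one-sample
Kolmogorov–Smirnov test against a normal with the sample's mean and SD, at
alpha 0.05. With estimated parameters this test is anti-conservative (it
passes samples too easily); it is nevertheless the default because it is the
stated method of the workflow being reproduced, and a Lilliefors-corrected
variant is available behind a flag. Gaussian-looking proteins are compared
by Student's t (equal variances) or one-way ANOVA; otherwise Wilcoxon
rank-sum or Kruskal–Wallis. The baseline-vs-follow-up comparison runs
unpaired by default because those are unpaired tests; a paired mode (paired
t / signed-rank over subjects with both timepoints) exists but is off.
p-values are Benjamini–Hochberg adjusted across proteins (statsmodels).
The volcano rule labels a protein up/down only when q < 0.05 *and*
|ΔNPX| > 1 — both inequalities strict; 1 log2 unit is exactly a 2-fold
linear change.

Single-marker ROC uses the empirical AUC (midrank convention for ties) with
the operating point chosen by Youden's J over observed thresholds
(score ≥ threshold ⇒ positive). The AUC confidence interval is DeLong by
default, falling back to a seeded stratified bootstrap (2000 replicates)
when the DeLong variance degenerates.

## Projections

PCA and PLS-DA run on centered, unit-variance-scaled, median-imputed data.
PLS-DA is the classical NIPALS algorithm against a centered one-indicator-
column-per-class response; it is implemented in-package (and cross-checked
against scikit-learn's PLS in the tests) because the stability loop needs
thousands of cheap fits and column-truncatable rotations. Since `P'W` is
triangular for NIPALS, truncating the full rotation's columns equals
refitting with fewer components — this is what makes the repeated-CV
component search cheap. Components are sign-fixed so the largest-magnitude
weight (loading for PCA) is positive, giving bit-reproducible output. VIP is
the standard formula over unit-norm weights and per-component explained
response sum of squares; mean squared VIP is 1 by construction. The latent-
variable count is chosen by stratified 5-fold CV repeated 10 times,
minimizing balanced misclassification with max-score class assignment (the
error metric is this package's choice; ties go to the smaller count).

## The three selectors

Each selector sees the training split only, already median-imputed and
z-scored, and returns at most its top five proteins with a deterministic
lexicographic tie-break.

**Boruta-style shadow selection.** Each of `n_iter` (default 500) iterations
appends a column-permuted shadow copy of the matrix, fits a bootstrap CART
random forest (default 500 trees, mtry = √p), and scores a hit for every
real feature whose importance beats the best shadow. Hits are tested against
Binomial(n_iter, ½), two-sided at confidence 0.01 with Bonferroni correction
across features, yielding confirmed / tentative / rejected sets. The
importance measure is the out-of-bag permutation-importance Z-score (mean
OOB error increase over its across-tree standard error), the convention of
permutation-importance Boruta implementations. Gini impurity importance is
available as an option but is markedly more liberal at this sample size: a
single chance-associated feature (|r| ≈ 0.4 under a fixed labeling) beats
all shadows in most iterations and gets confirmed, whereas its OOB
permutation importance does not dominate fresh shadow maxima. Features are
ranked by median importance across iterations; when fewer than five are
confirmed, the ranking falls back to tentative features so the top-five
contract always holds. The forest and the elastic-net path are numba-
compiled; both are validated against scikit-learn on identical inputs in the
test suite.

**Elastic net.** A glmnet-style coordinate-descent logistic path with L1/L2
mixing 0.5 over 30 log-spaced penalties from the data-derived maximum.
The penalty maximizes mean validation AUC over 5 stratified internal folds
(fold count is this package's choice; the reference workflow states only the
mixing and the AUC measure). AUC plateaus along the path, and ties resolve
to the strongest penalty, so the selector is deliberately sparse — it may
return fewer than five proteins, or none. The CV-*optimal* penalty is used
here; the 1-SE rule is reserved for the downstream ridge classifier.

**PLS-DA/VIP.** Component count by the repeated CV above, then the top five
proteins by VIP.

## The MCCV stability loop

Eligible samples are healthy controls versus patient baselines. One hundred
Monte-Carlo splits assign ~70% of each class to training (nearest-integer
rounding per class, so 28/29 gives constant 20+20 training sets; stratification
is this package's choice and can be disabled). Within each split: training
medians impute missing values in train and test alike; the selector runs on
the z-scored training matrix; a ridge-penalized logistic classifier is fit
on the selected (standardized) features — for the PLS-DA selector, on the
PLS component scores of those features — and applied to the test split using
the training imputation/standardization/penalty without retuning. The ridge
penalty is chosen per split by 10-fold CV of the binomial deviance over 100
log-spaced values in [1e-4, 1e3], taking the largest penalty within one
standard error of the minimum (λ.1se). Fold count, loss, and grid are this
package's settings around the stated 1-SE rule. The path is fit by Newton/
IRLS batched across the grid with per-penalty step halving.

Performance is reported as (i) the per-split test-AUC distribution
(median + IQR) and (ii) a pooled out-of-fold AUC: each subject's held-out
predicted probabilities are reduced to their median, and the AUC is computed
over these per-subject medians, with a subject-resampling bootstrap CI
(2000 replicates by default; the resampling-heavy validation runs use 200).
Per-protein selection frequencies accumulate across splits; a selector's
stable set is the proteins selected in ≥ 60% of splits.

Two consensus rules are implemented because the source workflow states both
and they disagree on its own printed frequency table: `top_k_aggregate`
(default, k = 2) ranks proteins by selection frequency summed across
selectors; `stable_intersection` intersects the three stable sets, which on
the printed table keeps only the top protein because one panel member falls
at 53% under the elastic net. The discrepancy is surfaced in the output
rather than adjudicated. The chosen panel is re-evaluated on a fresh set of
100 splits with the same ridge workflow and no reselection. All randomness
descends from one root seed via `SeedSequence` spawning.

## Treatment-response analysis

%ΔSLD is `100 · (SLD_followup − SLD_baseline) / SLD_baseline` (RECIST sum of
longest diameters; negative = regression). Per protein, within-patient
ΔNPX (follow-up − baseline) is correlated with %ΔSLD by Spearman's rho on
midranks with BH correction across proteins; p-values use scipy's
t-approximation at every n (the pipeline's n is 27, where the approximation
is adequate). ρ < 0 means the protein rises with tumor regression. Patients
are also binned into ΔNPX quartiles by rank (value ties broken by subject
id), remainder subjects going to the lower quartiles first — n = 27 gives
sizes (7, 7, 7, 6) — and Q1 vs Q4 %ΔSLD is compared by t-test or Wilcoxon
per the normality gate, BH-corrected across proteins as a second family.
Rank-based (rather than cut-point) quartiles were chosen for determinism.
Patients without follow-up imaging are excluded.

## The synthetic cohorts

The generator emulates the study conditions: 28 controls, 29 patients (27
with follow-up), 60 proteins, per-protein baseline NPX independent normal
with means drawn once per cohort (N(4, 1.5²)) and noise SD 1; two planted
diagnostic proteins shifted by +2 NPX (a 4-fold change, i.e. 2·SD) in
patient baselines; follow-up = baseline − 0.5 × planted effect + fresh
noise, modelling partial treatment response; 5% MCAR missingness; the lower
5% tail of each protein's control distribution flagged below-LOD (flagged,
not truncated — the filter owns censoring). Three planted response proteins
couple ΔNPX to %ΔSLD through a Gaussian copula: a latent severity normal
drives %ΔSLD through a monotone log-normal transform (baseline SLD
log-normal around 80 mm), and the planted proteins share the latent at
Pearson `2·sin(πρ/6)`, which yields Spearman ρ (default 0.6) exactly in
population. Ct-level data is generated backwards from target NPX values with
plate-structured controls, rounded to 3 decimals, so the NPX round trip is
exact by construction.

What the generator does *not* emulate: inter-protein correlation (proteins
are independent, which makes recovery oracles exact but understates the
redundancy among real co-regulated markers), plate effects beyond a single
inter-plate control, assay cross-reactivity, informative (non-MCAR)
missingness, and clinical covariates such as age or smoking — subgroup
sensitivity analyses are exercised by subsetting, not by simulating
confounders. Passing tests therefore demonstrate that the machinery recovers
planted structure under clean conditions and stays calibrated under none;
they do not certify performance on correlated, confounded real cohorts.

## Problem sizes and numerical choices

The resampling-heavy validation runs use the full study geometry (57
samples, 60 proteins, 100 MCCV splits, 10 pipeline seeds) with Boruta scaled
to 40 shadow iterations over 50-tree forests inside the loop and the full
100 × 100 for the standalone null-calibration check; the pooled-
AUC bootstrap uses 200 replicates there. These are the package's simulation-
scale choices and are deliberately documented rather than buried in test
code. Degenerate inputs are handled explicitly: zero-variance samples fail
the normality gate; constant ΔNPX vectors are excluded from correlation with
a warning; proteins with fewer than three values per group are excluded from
testing; an all-NaN training column imputes to 0 (standardized scale);
empty elastic-net selections predict the training prevalence. Probabilities
are clipped to (1e-12, 1 − 1e-12); linear predictors to ±35 before the
logistic.

## Known limitations

The panel re-evaluation uses fresh splits of the *same* cohort that chose
the panel, so it inherits the selection optimism of the source workflow;
on effect-free cohorts the chosen "best noise pair" evaluates above chance
on average. The pooled OOF AUC of a null cohort has a null sampling SD of
about 0.076 at 57 subjects (and stability selection adds variance), so
single-cohort null AUCs routinely land outside ±0.1 of 0.5; the null-safety
validation reports the observed rates honestly. KS-with-estimated-parameters
is anti-conservative, as noted. Selection frequencies, not p-values, are the
unit of evidence for the panel — the pipeline makes no formal error-rate
claim about the consensus itself.
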