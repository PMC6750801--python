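# Methods

`vmptb` re-implements, as a tested library, the statistical core of a
longitudinal vaginal-microbiome analysis of spontaneous preterm birth (PTB)
in a 2:1 matched case-control design: 45 PTB cases (delivery 23w0d–36w6d)
and 90 term (TB, ≥ 39w) controls matched on ethnicity, age and household
income. The pipeline starts from taxonomic profiles (samples × taxa
relative-abundance tables with read depths); no sequence processing is in
scope. Because the motivating cohort data are controlled-access, the package
ships a synthetic-cohort generator that encodes the study's assumed
statistical structure and serves as the test bed for every stage.

## Data model and selection rules

Relative abundances are compositional: each sample's row sums to 1, with the
classified read depth carried alongside. Samples need at least 1,000 reads
(inclusive) to enter any analysis. Gestational age is stored in integer days
(0–315); weeks appear only at I/O boundaries. Cross-sectional analyses use
the earliest sample per subject inside an inclusive gestational-day window —
days 42–167 for the risk model — with ties broken by lexicographic
sample_id (the package-wide tie rule).

Case matching proceeds in loosening passes: pass 0 requires exact ethnicity,
age within ±2 years and the same income bracket; later passes widen the age
tolerance by 2 years up to ±10, then drop income, then drop age (ethnicity
is always required). Controls are consumed without replacement; within a
pass the closest-age candidate wins, with a seeded shuffle breaking exact
ties. The source design did not document its pass schedule, so this one is a
deterministic, documented choice; matching sees only the three keys.

## Vagitypes, filtering, transforms

A sample's *vagitype* (community state type) is its most abundant taxon,
provided that taxon holds ≥ 30% of reads; otherwise the sample is
unassigned. The predominant-taxon rule is used instead of clustering because
it is not dataset-dependent. Low-abundance taxa are removed unless ≥ 5% of
profiles show ≥ 1% abundance or ≥ 15% show ≥ 0.1% (all cutoffs inclusive).

The shared abundance transform is the soft-threshold log:
`log10((max(a − 0.001, 0) + 0.001) / 0.001)`, mapping [0, 1] to [0, 3],
continuous and monotone. It is used for classifier features, the
longitudinal response and the taxa block of the sparse CCA, keeping one
transform across modules (the source analyses say "log-transformed" without
fixing base or zero-handling; the uniform choice is ours). Diversity is
Shannon entropy in nats (the index is not named in the source's main text;
Shannon is the package's choice).

## Differential screening

One earliest sample per subject; abundances below 1e-5 are rounded to zero;
each retained taxon gets a two-sided Mann–Whitney U test of PTB vs TB,
exact by enumeration when the pooled size is ≤ 12 without ties, otherwise
the tie-corrected normal approximation with continuity correction (the
source does not state its variant; the switch is logged). P-values are
adjusted by Benjamini–Hochberg step-up; taxa with q < 0.05 are flagged.
Medians and 75th percentiles (linear interpolation) are computed on the
floored values so they describe exactly what was tested. The L. crispatus
vagitype-by-outcome contrast uses Fisher's exact test with the
"at most as probable" two-sided rule. Mann–Whitney and Fisher are routed
through scipy.stats; BH is a few lines of numpy with statsmodels as the
test-time oracle.

## Two-step PTB risk model

Features are soft-threshold-log abundances of filter-passing taxa (or, for
the clinical comparator, 11 clinical variables min–max normalized inside
each training fold). Training is two-step: (1) keep features with two-sided
Mann–Whitney p ≤ 0.05; (2) fit L1-regularized logistic regression
minimizing `Σ ln(1 + exp(−y_i (w·x_i + b))) + C‖w‖₁` with labels ±1 and an
unpenalized intercept. Note the convention: **C multiplies the penalty**, so
larger C means more shrinkage — the reciprocal of scikit-learn's `C`. The
solver splits w into positive and negative parts and runs bound-constrained
L-BFGS-B on the smooth reformulation (objective tolerance 1e-8); with
separable data at C = 0 no finite minimizer exists and the solver stops at
its iteration cap with a warning. C is chosen by stratified 5-fold grid
search (13 log-spaced points, 1e-3…1e3, seeded) maximizing inner AUROC —
fold count and grid are package choices; the source states only "grid
search and nested cross-validation".

Generalization is estimated leave-one-subject-out: the *entire* two-step
procedure (filter, grid search, fit, and any normalization) reruns without
the held-out subject, so nothing about that subject can leak into its own
fold. Sensitivity and specificity use decision threshold 0 on w·x + b;
AUROC is the tie-corrected rank statistic. Significance comes from a
permutation test: each permutation shuffles the outcome labels, reruns the
full two-step training, and records the refit model's AUROC on the
(permuted) training cohort; the observed value uses the same statistic, so
observed and null are exchangeable under no association and
`p = (1 + #{null ≥ observed}) / (1 + n_perm)` is never zero. Re-running the
leave-one-out loop inside each of thousands of permutations is not done:
one model per permutation is both the literal reading of the procedure and
the only computationally sane one.

The published 4-taxon score ships as a frozen profile —
`0.775·L(Samn) + 0.751·L(BVAB1) + 0.116·L(TM7) + 0.011·L(Pcl2)` with L the
shared transform, range [0, 4.959]. Its coefficients derive from
controlled-access data and are not re-estimated here.

## Vagitype CTMC

Vagitype series per subject (states L. crispatus, L. iners, BVAB1,
G. vaginalis, Other; unassigned and non-focal vagitypes map to Other) are
interval-censored panel data: only the state at visit times is known, so an
interval contributes `[exp(Q·Δt)]_{rs}` to the likelihood — exact
transition times are never assumed. Intensities carry a log-linear outcome
effect, `q_rs(z) = q⁰_rs · exp(β_rs z)` with z = 1 for PTB. Only
transitions observed at least 4 times (pooled over outcome groups; pooling
is the package default) are modeled; the rest are fixed at zero, without
which the MLE does not converge. Optimization is L-BFGS-B on
log-intensities (positivity by construction) with 3 seeded starts; standard
errors come from a central-difference observed-information matrix. The
matrix exponential is scipy's scaling-and-squaring Padé. Stationary
distributions are read off P(100,000 days) and cross-checked against the
null space of Qᵀ; the dynamic-balance diagnostic reports
P_ij(t) − P_ji(t) at t = 91 days (one trimester = 13 weeks, a documented
choice) plus the detailed-balance flux π_i P_ij − π_j P_ji as a secondary
column, since the source's phrase admits both readings.

## Longitudinal mixed model

Per taxon: response = soft-threshold-log abundance; fixed effects
intercept, outcome, BMI, pH, ethnicity indicator (0 = African ancestry),
and linear gestational-age terms; a penalized cubic B-spline smoother of
gestational age *per outcome level* (the smoother-by-outcome interaction),
10 basis functions, second-difference penalty; and a random subject
intercept. The penalty is recast as a variance component by eigen-splitting
the penalty matrix (null space — constant and linear — moves to the fixed
effects), giving a two-variance-component linear mixed model whose
smoothing parameter λ = σ²/σ_f² and variances are estimated by profiled
REML (Nelder–Mead over the two log-ratios; n ≤ ~1000 makes dense Cholesky
cheap). The two outcome-level smoothers share one λ by default. Effect
contributions are ANOVA-style Wald F tests for fixed effects and
approximate Wald χ² for each smoother's coefficients; fitted trajectories
carry 98% pointwise bands from the mixed-model posterior covariance of
[β, b]. This penalized-B-spline representation stands in for a thin-plate
GAMM as a model-class approximation; no installed Python package combines
penalized smoothers with random effects, so the REML fit is implemented
directly (with an unpenalized least-squares mode tested against the normal
equations). Ancestry-stratified fits drop the ethnicity and outcome terms
within each ancestry × outcome stratum and flag strata below 5 subjects as
low-power.

## Cytokines and sparse CCA

Nine cytokines (IL-1β, eotaxin, IL-8, TNF-α, IL-17A, MIP-1β, IL-6, IP-10,
RANTES) are retained when fewer than 30% of readings are out of range;
surviving out-of-range values are imputed at the nearer detection limit.
One earliest sample per subject per trimester enters (trimester boundaries
98/196 days, a documented convention). Sparse CCA follows the penalized
matrix decomposition: standardize both blocks, then per component maximize
u'X'Yv subject to ‖·‖₂ ≤ 1 and l1 budgets (cx, cy) by alternating
soft-thresholded power iterations (the threshold found by bisection); the
objective is asserted non-decreasing every iteration; later components come
from the deflated cross-covariance. Canonical correlations are Pearson
correlations of the block variates; fits are run separately per outcome
group. Sign convention: the largest-magnitude taxa weight per component is
positive. Correlation-circle coordinates are each variable's correlations
with its own block's variates, computed after Gram–Schmidt
orthogonalization of the variates within a block (deflation does not make
variates uncorrelated; orthogonalizing guarantees the coordinates stay in
the unit disk). Default penalties cx = cy = 2.0. Note the first canonical
correlation under independence grows with the l1 budget (~0.45–0.55 at the
defaults with n = 100); null-calibration checks therefore run at the
strictest budget (1.0), where the null correlation concentrates below 0.35.
This criterion-vs-penalty dependence is inherent to the diagonal-covariance
PMD criterion, which coincides with classical CCA only on within-block
whitened data (the form the cross-check test uses).

## Synthetic cohort generator

The generator is first-class, tested code; its defaults *are* the study
conditions and every parameter is retained as ground truth for recovery
tests.

* **Design**: 45 PTB cases and a 300-subject TB pool matched 2:1 on
  ethnicity/age/income → 135 subjects. Clinical covariates mirror the
  reference cohort's descriptive table (≈78% African ancestry, ~72–78%
  lowest income bracket with ~8% missing, history of PTB 31% vs 10%, PPROM
  58% vs 0%, mean age 26).
* **Dynamics**: each subject's vagitype path is an exact CTMC simulation
  (exponential holding times, embedded jump chain) over visits every 28
  days from day 60 until delivery; deliveries (PTB uniform on 161–258 days,
  TB on 273–294) truncate the schedule. The term chain drifts toward
  L. crispatus, the preterm chain toward BVAB1; the rates are plausible
  placeholders (the literature gives none) with truth recorded.
* **Compositions**: Dirichlet-multinomial over a 27-taxon panel. Each
  vagitype has a concentration template with the dominant taxon holding
  55–80% of template mass; the "Other" template is a mixed anaerobic
  profile. PTB multiplies template mass by exp(effect) for the signature
  taxa (BVAB1 +0.85, S. amnii +0.85, Prevotella cluster 2 +0.75, TM7-H1
  +0.75 log-units) and down-weights L. crispatus (−0.6), total
  concentration preserved. These effects were calibrated once so the
  default cohort sits in the intended operating range — the four signature
  taxa recovered at q < 0.05 in ≥ 90% of cohorts and leave-one-out AUROC in
  the mid-0.7s to mid-0.8s — and are not revisited per analysis.
* **Read depth**: negative binomial, mean 50,000, dispersion 8, plus a 2%
  chance of a failed low-depth sample (100–2,000 reads) to exercise the QC
  floor.
* **Cytokines**: log10 concentration = per-cytokine baseline + loadings on
  soft-threshold-log abundances of dysbiotic taxa (IL-1β, IL-6, MIP-1β and
  eotaxin load on the four signature taxa plus G. vaginalis and
  A. vaginae) + Gaussian noise (SD 0.3 log10); values outside per-cytokine
  detection windows are censored at the bound and flagged.
* **pH** rises with the non-Lactobacillus fraction of the composition, tying
  a clinical covariate to the microbiome as in real cohorts.

What the generator does **not** emulate: sequencing error and primer bias,
taxonomic misclassification, within-state temporal autocorrelation beyond
the Markov property, batch effects, covariate-dependent visit schedules,
or real cytokine assay noise structure. Passing tests therefore demonstrate
correctness and calibration of the *methods* under the assumed generating
process, not performance claims about clinical data.

## Numerical choices and degenerate inputs

* Proportion rows are accepted within 1e-6 of 1 and renormalized (only when
  off by more than 1e-9, keeping text round-trips stable); worse is an error.
* Zero-depth samples, empty tables, duplicate identifiers: errors at read
  time. An all-filtered table is allowed with a warning.
* Intercept-only models (no feature survives the filter) are returned
  flagged, with the unpenalized log-odds intercept.
* The L1 solver zeroes coordinates below 1e-8 (positive/negative split
  leaves numerically-zero dust); early L-BFGS-B stops are warnings, with
  the best bounded iterate returned, and only non-finite iterates raise.
* CTMC likelihoods clamp transition probabilities at 1e-300 before logs;
  reducible chains report the P(t) row with a warning.
* REML uses Nelder–Mead on two log-variance-ratios (x-tolerance 1e-4);
  non-convergence raises. Rank-deficient fixed designs raise naming the
  aliased term.
* All simulation randomness flows from numpy Generators seeded from a
  single integer; derived seeds stay below 2³¹.

## Problem sizes used by the test-suite and acceptance script

Simulation-heavy checks run at the sizes stated in their tests: the default
135-subject cohort for end-to-end checks; 200 single-visit null cohorts for
false-discovery calibration; 200 replicates × 99 permutations (n = 30,
p = 10, 3-point C grid, 3 folds) for permutation-test calibration; 200
subjects × 9 visits for CTMC recovery; 100 subjects × 7 visits for the
mixed model; n = 100 for sparse-CCA support recovery. The acceptance script
evaluates the permutation test at 199 permutations with a 5-point C grid.
These sizes are the package's chosen defaults for routine verification; the
functions themselves accept arbitrary sizes.

## Known limitations

* The GAMM uses penalized B-splines, not thin-plate splines; λ and basis
  dimension choices can shift smoother p-values relative to other software.
* The CTMC assumes time-homogeneous intensities and no misclassification
  layer over vagitype calls.
* The permutation test's statistic is training-cohort AUROC of the refit
  model, not a nested leave-one-out AUROC (see above); its null
  distribution carries a point mass when no feature survives the filter,
  which keeps the test valid but slightly conservative.
* Sparse CCA treats within-block covariance as identity (the standard PMD
  simplification); its "canonical correlations" are not classical CCA
  correlations except on whitened data.
* match_controls is greedy per pass and does not guarantee globally optimal
  assignment.
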