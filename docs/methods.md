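# Methods

## Pair-indicator features and rank invariance

For an ordered gene pair (a, b) and sample s the feature is
`1[expr(a,s) > expr(b,s)]` with a **strict** inequality; ties score 0.
Ties are the only reading consistent with a binary score whose value-1 case
is defined as "strictly higher"; in continuous expression data exact ties
essentially never occur, so the choice matters only for degenerate inputs.
Each unordered pair is enumerated once, oriented by input gene order — the
reversed orientation is the complement of the indicator (when no tie) and
adds no information.

Because the feature depends only on the within-sample ordering of two
values, any strictly increasing transform applied per sample — log scales,
quantile scaling, platform-specific intensity warps — leaves all indicators
and hence all risk scores unchanged. This is asserted bit-for-bit in the
test suite over random cohorts and random monotone warps, and it is the
justification for scoring a validation cohort from another platform with no
renormalization.

## Constancy filter

A pair is dropped when its majority indicator value occurs in strictly more
than `constancy_threshold` of samples (default 0.80). The boundary is kept:
a pair constant in exactly 80% of samples survives. Filtering is
idempotent and order-preserving. For large universes (~2,500 genes,
~3.1 M pairs) the indicators are evaluated in chunks and only survivors are
retained, so the full pair × sample matrix never needs to exist in memory.

## Log-rank screening

Each pair splits the cohort into indicator-0 and indicator-1 groups, which
are compared by the standard two-group log-rank test: over distinct event
times the statistic is `(Σ(O1−E1))² / ΣV` with hypergeometric moments
summed per distinct time (ties pooled), and p comes from the asymptotic
χ²(1) distribution. Selection requires p **strictly** below `alpha`
(default 1e-4) and both groups of size ≥ `min_group_size` (default 2; a
formally defined but numerically fragile singleton-group test is never
accepted). No multiple-testing correction is applied — screening on a raw,
very small α across tens of thousands of pairs is the intended design, and
its false-positive rate is verified by simulation (10,000 null pairs,
selection rate within 3 binomial SE of α). The test is vectorized across
pairs; a 10,000-pair screen at n = 150 runs in about a second.

`alpha` may be set to 1, turning the screen into a pass-through (useful for
pipeline testing); p-values equal to exactly 1 (zero-variance pairs) still
fail the strict inequality.

## Lasso Cox and stability selection

The penalized model is L1-only Cox regression fit by glmnet-style
coordinate descent (`sksurv.linear_model.CoxnetSurvivalAnalysis`) along a
decreasing penalty path of `n_lambda` = 100 points down to
`alpha_min_ratio` = 0.1 of the maximal penalty. The truncated path floor
is a numerical choice: with binary indicator features and many correlated
candidates the dense small-penalty tail is ill-conditioned and expensive,
and in every profiled setting the cross-validated optimum sat mid-path.
Binary 0/1 features are **not** standardized before penalization —
standardizing indicator features would inflate the coefficients of
unbalanced pairs and distort the sparsity pattern.

Penalty selection uses k-fold cross-validation (default 10 folds,
event-stratified) on the Verweij–van Houwelingen partial-likelihood
deviance, `−2·[ℓ(all; β₋ₖ) − ℓ(train₋ₖ; β₋ₖ)]`, which is well defined for
small folds. The penalized partial likelihood uses the Breslow tie
approximation (what coordinate-descent Cox solvers implement); the
unpenalized Cox fits in the evaluation stage use Efron's correction (via
lifelines), and a dedicated test exhibits the difference between the two on
a heavily tied fixture.

"The most stable model" is made operational as: repeat the
cross-validation `repeats` times (default 1000) with reshuffled folds; per
repetition, read the non-zero coefficient set of the **full-data** path at
that repetition's chosen penalty (folds pick the penalty, the full fit
supplies coefficients — cv.glmnet semantics); keep the most frequent set,
breaking ties toward the smaller then lexicographically earlier set. Final
coefficients are the penalized estimates at the largest full-path penalty
whose support equals the modal set; if no path point matches exactly, a
path restricted to the modal pairs supplies them at the largest penalty
keeping all of them active. Coefficients are reported penalized, not
re-fit: shrunken magnitudes are part of the signature. An empty modal
support raises an error suggesting a weaker penalty rule rather than
returning an empty signature. Either the deviance minimizer (`min`,
default) or the one-standard-error rule (`1se`) may pick the penalty.

All randomness flows from a single integer seed through one
`numpy.random.Generator`; a fixed seed and configuration reproduces the CV
curves, the modal support, and every coefficient bit-for-bit.

## Risk scoring and stratification

`risk_score` computes Σ βᵢ·indicatorᵢ per sample directly from raw
expression. The 1-year discrimination is summarized by the
cumulative-case / dynamic-control time-dependent ROC: cases are subjects
with an observed event by the horizon, controls are subjects still under
observation past it, and subjects censored before the horizon enter through
inverse-probability-of-censoring weights — cases weighted by `1/G(T⁻)`,
controls by `1/G(horizon)`, with `G` the Kaplan–Meier estimate of the
censoring survival function. With no censoring the weights are all 1 and
the estimator reduces to the empirical ROC; an unweighted variant
(`ipcw=False`) is available for sensitivity analysis. AUC is the
trapezoidal integral over all distinct score thresholds, which equals the
IPCW-weighted Mann–Whitney statistic with ½ credit for score ties (asserted
against an exhaustive pairwise oracle).

The "optimal" cutoff maximizes Youden's index (sensitivity + specificity −
1), breaking ties toward the lower threshold so the high-risk group is as
large as possible. Group assignment is strict: score > cutoff → high,
score ≤ cutoff → low. Group survival is compared by per-group
Kaplan–Meier curves and the log-rank test; Cox tables report Wald hazard
ratios with 95% CIs `exp(β ± 1.96·SE)`. Clinical covariates enter the Cox
models as: age numeric in years, grade and stage as ordinal integers 1–4,
gender as 0/1 — one hazard ratio per variable, matching how such models are
conventionally reported (dummy coding was considered and rejected for v1 as
it changes the reporting unit). Cohort summary percentages are rounded
half-up to one decimal. Between-group feature comparisons (e.g. supplied
immune-cell fractions) use the two-sided Mann–Whitney test with the
direction taken from the median difference and significance stars at
0.05/0.01/0.001.

## Synthetic cohorts

The generator emulates the statistical structure the pipeline assumes,
with defaults describing a pancreatic-cancer-like training cohort: 177
samples, a 200-gene immune universe, 5 planted pairs with unit log-hazard
effects and prevalence 0.5, an exponential baseline with mean survival
1.5 years, a 40% censoring target under a 10-year administrative horizon,
and clinical covariates with cohort-table-like marginals (≈55% male, ≈84%
stage II, age ≈ N(65, 10)) whose default hazard effects (0.028/year for
age, 0.32/grade) mirror typical reported univariate hazard ratios.

Mechanics worth knowing:

* **Planted orderings are imposed by construction**: the two genes' values
  are swapped wherever the drawn ordering disagrees with the latent
  Bernoulli state, giving exact control of the pair indicator without
  touching either gene's value set.
* **The two genes of a planted pair share one log-normal marginal.** With
  independent marginals the swap construction can make a cross pair
  (planted gene vs a mid-range background gene) an *exact duplicate* of the
  planted indicator, which renders the planted pair unidentifiable for any
  sparse model. Sharing the marginal makes the planted pair the unique
  noise-free readout of the latent state; cross pairs still correlate with
  it through max/min order statistics, as genuinely correlated features
  should.
* **Censoring** is administrative-plus-exponential; the exponential rate is
  found by bisection on the realized censored fraction of the drawn event
  times, so the target is hit almost exactly and the result is
  deterministic given the seed. An infeasible target (administrative
  censoring alone exceeds it) raises.
* **Platform distortion** warps each sample through an independent strictly
  increasing map `a + b·log1p(x)^γ` (b, γ > 0); a deliberately
  order-reversing override exists for negative-control tests.

What the generator does **not** emulate: gene–gene co-expression structure,
cohort batch effects, non-proportional hazards, or immune-cell
deconvolution inputs — backgrounds are i.i.d. log-normal plus planted
signal. Passing tests therefore demonstrate correctness of the machinery
and recoverability of planted rank signal under proportional hazards, not
performance on real tumor data.

## Problem sizes in the shipped experiments

The end-to-end recovery experiment in the acceptance suite uses 20 seeded
runs of a 300-sample training / 100-sample validation design over 200 genes
with 5 planted pairs (|log-hazard| = 1, ~40% censoring) and 100
cross-validation repetitions per run, with the planted pairs as the sole
hazard drivers; screening calibration uses 10,000 null pairs at n = 150;
oracle-equivalence checks use 20 random fixtures of n ≤ 25. These sizes
were chosen so the full suite completes in a few minutes on one CPU while
keeping every statistical bar (recovery ≥ 4/5 pairs in ≥ 80% of runs,
validation log-rank p < .05 in ≥ 90%, training 1-year AUC ≥ 0.75, screen
false-positive rate within 3 SE of α) meaningfully testable. Under these
conditions the occasional losses are at the screening stage: with five
planted pairs the marginal (single-pair) hazard ratio is attenuated by the
variance of the other pairs' contributions, so a planted pair's log-rank p
can land just above 1e-4.

## Known limitations

* The asymptotic χ²(1) log-rank p-value is used even at the extreme 1e-4
  tail; no permutation option in v1.
* The stability notion is support frequency under fold reshuffling only —
  no subsampling/bootstrap stability selection, no per-pair selection
  probabilities.
* No proportional-hazards diagnostics, no elastic-net mixing, no
  confidence intervals for the penalized coefficients.
* Gene identifiers are matched case-sensitively by exact string; probe and
  patient collapsing require explicit mappings; no GEO SOFT parsing or
  identifier liftover.
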