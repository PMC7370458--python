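# Methods

## Instruments

**QLQ-C30 v3.0.** Items q1–q28 are coded 1–4 ("not at all" … "very
much"), q29–q30 are coded 1–7. The 15 scale scores follow the official
scoring manual: raw score RS = mean of answered items; functional scales
use `S = (1 − (RS−1)/range)·100` (higher = better), symptom scales and
global health use `S = ((RS−1)/range)·100`; range is 3 for 4-point and 6
for 7-point items. A scale is computable iff at least half of its items
(rounded up) were answered — the half-completion rule. Missing items are
NaN; 0 is never a missing code. No imputation anywhere. `binarize_v3_items`
collapses q1–q5 to {1 = "no", 2 = "yes"} for coefficient sets estimated on
version-2 questionnaires.

**EQ-5D-3L value sets.** A tariff is additive: utility = 1 − per-domain
level decrements − predicate-triggered extras (`any_gt_1` for the "any
dysfunction" constant, `any_eq_3` for the N3 term). Packaged sets: the
Dutch TTO tariff (Lamers et al., 2006; floor −0.329) and the UK MVH A1
tariff (Dolan, 1997; floor −0.594). Which UK 3L variant a given published
algorithm assumed is not always documented, so the UK file records its
source and is swappable. All unit tests use a toy tariff so the suite
never depends on the published constants.

## Mapping model families

**Models 1–3 (linear panel).** The utility is regressed on (1) the 14
functional + symptom scale scores, (2) the 30 items as continuous
covariates, or (3) item-level dummies with level 1 as reference (levels
2–4, or 2–7 for q29/q30). The estimator is a random-intercept linear
model `y_ij = x_ij'β + b_i + e_ij` fitted by profiled REML: the marginal
cluster covariance `σ²(I + λJ)` admits a Sherman–Morrison inverse, so
the whole fit is a one-dimensional profile over λ with a GLS solve per
candidate (bounded search on log λ in [−12, 8], boundary λ = 0 checked
explicitly). Inference on the fixed effects is a cluster-robust sandwich
with a G/(G−1) small-sample factor and t statistics on G−1 degrees of
freedom (G = patients). The label "RE model" vs "OLS model" is used
interchangeably in this literature; a pooled-OLS-with-cluster-robust-SE
fallback is available via `method="ols"` (identical to fixing λ = 0).
statsmodels `MixedLM` is used in the test suite as an independent
cross-check of the point estimates (agreement ~1e−7) but is not on the
fitting path, because selection needs many cheap refits and MixedLM does
not expose a cluster sandwich for its fixed effects.

**Backward selection.** From the family's full candidate set, the single
coefficient with the largest p-value above α = 0.05 is dropped and the
model refit, until all p ≤ α. The order of removal is not prescribed
beyond "one at a time", so ties are broken deterministically: larger p
first, then smaller |coefficient|, then lexicographic name. The
intercept is never a candidate. Dummy levels are dropped individually.
If everything is eliminated, an intercept-only model is returned with a
warning.

**Sign pruning.** A surviving coefficient whose sign contradicts
clinical expectation (functional scales +, symptoms −, reversed on the
disutility scale; q1–q28 −, q29/q30 +, dummies inherit their item's
sign) is *non-logical*. All violations are removed simultaneously, the
model refit, backward selection re-run, and the loop iterated to a fixed
point (cap: 20 rounds — never reached in practice; a cap exists because
removal can change other coefficients' signs). Every removal is logged
with term, p-value, coefficient and reason, so the audit trail shows
exactly which terms left the model and why.

**Model 4 (response mapping).** One proportional-odds logit per EQ-5D
domain on the five functional scale scores (statsmodels `OrderedModel`,
BFGS), no selection. With L the latent predictor offset by the first
threshold and κ the offset of the second, the level probabilities are
`Prob1 = 1/(1+e^L)`, `Prob2 = 1/(1+e^(L−κ)) − Prob1`,
`Prob3 = 1 − Prob1 − Prob2`. Two scoring modes exist because "most
likely probability method" admits two readings: `most_likely` (default,
matching the name) scores the modal level per domain, ties resolved to
the better level and logged; `expected` averages the tariff over the
joint distribution of the five domains (full 3⁵-state enumeration, which
for additive tariffs with extras is exact, and reduces to
constant − Σ prob·decrement without extras). Every prediction records
its mode. If a training fold never shows level 3 for a domain, the model
stores a single threshold and fixes Prob3 = 0 rather than failing; a
domain with only one observed level is an error named after the domain.
The most-likely mode concentrates predictions on modal states, which on
a cohort whose domains are mostly at level 1 biases mean predictions
upward — visible in the replica's results and a known property of the
method, not a defect.

**Model 5 (beta regression).** Disutility d = 1 − u is truncated to
[0, 1] (the ~0.2% of negative utilities map to d > 1 and are truncated
to 1 with a logged count; the prescribed "standardized value" subtraction
is under-specified, truncation is this package's reading) and compressed
into the open interval by `y′ = (d(N−1)+0.5)/N` with N = training-sample
size, stored with the model so prediction inverts the same transform.
statsmodels `BetaModel` with logit mean link and constant precision (the
conventional defaults; the source text states neither), warm-started
from an OLS fit on the logit scale for determinism. Candidates are
global health plus all scale scores; selection and pruning run on the
link scale with the reversed sign convention. Predicted utilities are
strictly inside the image of the inverse transform: they can never reach
1 nor produce negative utilities.

**Model 6 (separate equations).** Classes {u < 0.6, 0.6 ≤ u < 1, u = 1}
(0.6 relates to scoring "extreme problems" on some dimension; the
ceiling class uses a 1e−12 tolerance). A 3-class `MNLogit` on the 14
scale scores — exempt from selection, as is conventional for the
class-membership step — plus model-1-style submodels on the low and mid
subgroups (each with selection and pruning). Prediction is the
probability-weighted mixture, hence bounded by its components. An empty
class in training is an error naming the class.

## Synthetic cohort generator

The generator reproduces the *published structure* of the motivating
cohort, not its patient-level data: 473 patients, 1905 paired complete
questionnaires (~4 visits each, 1 + Poisson counts adjusted to the exact
total), scale-score means and EQ-5D level frequencies at their published
values, a right-skewed utility distribution with a ceiling spike at 1
and a ~0.2% worse-than-dead tail, and within-patient correlation.

Mechanism: patient trait + visit noise give a standardized latent health
z (between/within SDs 0.75/0.66, i.e. intra-patient correlation ≈ 0.56).
Each QLQ item loads on z with correlation 0.8 plus idiosyncratic noise;
its cutpoints are solved (discretized shifted normal, spacing 1.1, or
0.8 for the 7-point items) so each scale's mean matches its target
exactly in expectation. Each EQ-5D domain loads on z through its own
noise (SD 1.0 ⇒ loading ≈ 0.71) with cutpoints placed at the normal
quantiles of the published level frequencies, so domain marginals match
by construction. The observed utility is always the generating tariff
applied to the generated EQ-5D response — the two instruments are
internally consistent, and utility-side structure (ceiling mass ≈ 0.32,
SD ≈ 0.177 vs published 0.171, negative fraction ≈ 0.23%, Spearman with
physical functioning ≈ 0.71) *emerges* from the latent mechanism rather
than being painted on. The loadings and spacings were calibrated once,
by moment matching against the published marginals, and then frozen.
`ceiling_mass` and `negative_utility_prob` knobs can force additional
full-health or worst-state visits on top (defaults 0).

What it does **not** emulate: inter-scale correlations beyond the
single-factor structure (no correlation matrix was published — real
symptom clusters are richer than one latent dimension), treatment-arm
effects on quality of life, informative dropout or time trends, and
item-level missingness mechanisms other than MCAR (the restoration step
guarantees functional scales stay computable, which is the precondition
of the incomplete-questionnaire path). Passing tests on this cohort
therefore demonstrate that the *procedures* behave correctly under the
published study conditions, not that any particular fitted coefficient
generalizes to real patients.

Parameter-recovery datasets are simpler by design: scale scores are
independent truncated normals on [0, 100] with the published moments,
and the outcome is built from a known coefficient set (linear with
patient random intercept SD 0.05 and noise SD 0.09, truncated at the
ceiling 1; or a beta draw with logit mean equal to the link-scale
predictor and precision 10, decompressed through the same open-interval
transform the fit applies). Fitting a correctly-specified model to such
data must recover the generating coefficients within Monte-Carlo error;
the ceiling truncation (~3% of rows) introduces a small attenuation that
stays within 3 MC standard errors of the mean over 20 replicates at
n = 1905 — the package's core recovery property.

## Validation

Folds are assigned at questionnaire (row) level by default — mirroring
the original design, which acknowledged that rows of one patient can
land in both training and test folds; a `patient` grouping mode keeps
patients intact (largest first onto the smallest fold) for users who
want leakage-free folds. Row-level fold sizes differ by at most 1,
remainder to the lowest-index folds; 1905 rows give exactly 5 × 381.
Each fold re-runs the *entire* fitting procedure (selection + pruning)
on the training folds. Both pooled metrics over the concatenated
held-out predictions and per-fold means are reported, since the original
tables do not say which was used. The t-test is paired by default
(unpaired behind a flag); a zero-variance difference or constant vector
yields a missing statistic with a warning rather than a crash. Metrics
print at 3 decimals; full precision is kept internally. A fold whose fit
fails is flagged in the report, never silently pooled.

Incomplete questionnaires are evaluated per model: a row is eligible iff
every scale the model actually uses is computable under the half rule,
and the eligible count is reported next to the metrics.

## CEA sensitivity layer

The original cost-effectiveness evaluation was a discrete-event
simulation whose structure, transition times and literature utilities
cannot be reconstructed from published material; reproducing its
absolute ICERs is a non-goal. What the layer preserves is the question
the simulation answered: how sensitive is the ICER to the utility
source. Each arm accrues `QALY = utility × time_in_state + fixed_qaly`,
where the fixed remainder carries the (survival-driven) between-arm QALY
difference of the subsequent health states; incremental costs are a
fixed input (default €30,163, the published incremental cost). Utility
uncertainty is propagated by method-of-moments beta distributions
(`ν = m(1−m)/se² − 1`, shapes (mν, (1−m)ν) — exact moment match), 10,000
samples. The point ICER is mean Δcost over mean ΔQALY of the cloud (the
probabilistic-CEA convention; the mean of per-sample ratios is unstable
near ΔQALY = 0), the 95% interval is the 2.5/97.5 percentile of the
per-sample ratios. All sources share one seed (common random numbers),
so ICER differences between sources are not blurred by sampling noise
and identical sources differ by exactly zero. Beta support excludes
negative utilities by construction; the rare worse-than-dead
observations affect the arm means, not the PSA support. A zero ΔQALY is
flagged as a dominance boundary, not divided through.

## Problem sizes and determinism

The default study replica (1905 rows, 6 families, 5-fold CV, incomplete
evaluation on 400 rows at 15% missingness, 10,000 PSA samples) runs in
well under a minute on a single core; the acceptance script's 2 × 20
replicate recovery runs take a few seconds. Every stochastic step draws
from a `SeedSequence`-spawned substream of one master seed, so reports
are byte-identical across runs (wall-clock provenance is deliberately
kept out of the report JSON). Replicate seeds derived from a master seed
are reduced below 2³¹.

## Known limitations

- The single-latent-factor cohort makes the six families perform more
  similarly than they would on real data with richer symptom structure.
- Model 4's most-likely mode inherits the coarse granularity of modal
  states (few distinct predicted values; upward mean bias on
  predominantly healthy cohorts). The expected mode is smoother but is
  not the default, to keep the method's name honest.
- Linear-family predictions are deliberately not clipped to ≤ 1;
  published mapping algorithms can and do predict above 1.
- The CEA layer's fixed QALY remainder is an input, not a survival
  model; only the utility-source sensitivity is meaningful, not absolute
  ICERs.
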