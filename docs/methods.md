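# Methods

## Data model and cleaning

A case report is a mapping from M categorical clinical features to sets of
terms; an empty set is a missing value. Cleaning follows spontaneous-report
conventions: the placeholder tokens `UNK`, `UNKNOWN`, `()` (case-insensitive)
and blank cells are missing; doses are unified to milligrams (g ×1000,
µg/mcg ×0.001, unknown units → missing) and dichotomized at 100 mg, with
exactly 100 mg in the "less than 100 mg" class (the large class is a strict
inequality); ages fall into `<18 / 18-39 / 40-64 / 65+` with boundaries
18, 40, 65, and 65 assigned to the oldest bin (the published bin labels
leave 65 itself ambiguous; the oldest-bin rule is the package's choice).

Endpoint labeling: a report is positive iff the endpoint term is present in
the endpoint feature, excluded iff that feature is missing, else negative.
Rendering is deterministic; multi-valued slots join terms with "and";
missing slots print "unknown". Label leakage is prevented structurally —
for an adverse-event endpoint only the endpoint term is excised, for an
outcomes endpoint the whole trailing clause is dropped. A fuzzed corpus
scan asserts that no rendered sentence contains an endpoint-feature term.

Stratified splitting shuffles each class with a seeded generator and uses
floor allocation with largest-remainder correction (remainders to the
earliest split), so class totals are conserved exactly and each split's
class ratio tracks the global one. The split is a pure function of
(records, ratios, seed).

tf-idf summaries use the smoothed-idf dialect `log((1+N)/(1+df)) + 1` with
L2 document normalization (scikit-learn's default) because the source
procedure names tf-idf without a formula; corpus-level scores are the
per-document values averaged over all documents, ties alphabetical.

## Classifier

Both classifier kinds sit behind one contract: fit on (train, dev), emit a
per-report positive-endpoint probability.

* **token-logistic** — logistic regression on binary token presence,
  full-batch gradient descent (default 300 steps, learning rate 0.5 in the
  library default; the simulation studies use 200 steps at 1.0). The fit is
  deterministic given the data, so it is bitwise reproducible and fast
  enough for hundreds of Monte-Carlo pipeline runs.
* **transformer** — a from-scratch bidirectional self-attention encoder in
  numpy with manual backpropagation: learned token and position embeddings,
  post-layer-norm residual blocks (multi-head attention + ReLU feed-
  forward), and a two-way softmax head on the CLS token (no hidden layer).
  Adam with linear warmup; whitespace/lowercase tokenization with an OOV
  token. Defaults (hidden 32, 2 layers, 4 heads, 300 steps) are desk-scale;
  analytic gradients are verified against central finite differences in the
  test suite.

Training records (step, dev loss, dev accuracy) at every checkpoint and
restores the checkpoint with maximum dev accuracy, earliest step on ties;
the decision threshold is 0.5. Both choices are package conventions where
the source procedure is silent.

## Do-calculus probing

For term t of feature j, the do stratum L1 holds the predicted
probabilities of reports containing t; the not-do stratum L2 those of
reports whose feature j is observed but lacks t; reports with feature j
missing enter neither. The test is an upper-tailed two-sample z on the
stratum means with unbiased variances (Welch form; a pooled variant is
available for sensitivity analysis). Groups below `min_group_size`
(default 30, the usual normal-approximation heuristic) are skipped and
logged. Degenerate zero-variance strata: equal means give (z = 0, p = 0.5);
unequal means give a signed infinite sentinel — (+inf, 0) when the do mean
is larger, (−inf, 1) when smaller. Exactly-constant strata are detected
before the variance computation because summing n identical floats perturbs
the mean at machine precision and would otherwise produce an arbitrary
0/0 ratio.

The multiplicity family is every term tested in one run, across features;
Bonferroni is the default (conservative), Benjamini–Hochberg selectable.
Enriched terms (adjusted p < α = 0.05) are ranked by z descending, ties
alphabetical; each feature's top enriched term is reported as that
feature's root cause. By default all labeled reports enter the analysis
(the procedure is defined over the dataset, and the classifier's
probabilities are deterministic given its parameters); a test-only scope
flag restricts probing to held-out reports.

## Causal tree

The root level holds the single globally highest-z enriched term (a
per-feature-roots mode exists behind a flag). For each node, enrichment is
re-run inside the stratum of reports containing every term on the node's
path, over features not yet fixed (self-conditioning is degenerate); a
stratum below twice `min_group_size` stops the branch. Candidate children
are pooled across the level's parents and ranked by z; level N retains at
most N nodes — the published cap "at level N keep ≤ N factors" read as a
per-level total, which reproduces the widening 1-2-3 shape of the source
figures. Whether that cap was originally applied per parent or pooled is
not fully specified; pooling is implemented because it makes the cap a
global significance filter rather than a per-branch quota.

## Robustness metrics

Runs are ranked enriched-term lists (z descending, ties alphabetical so
prefixes are well defined). The average percentage of common enriched
terms is `mean_i |∩_all runs| / |run_i| × 100`, which is 100 iff all runs
are set-equal. POT(k) is the size of the intersection of all runs' top-k
prefixes divided by k (the prefix size; the source wording is ambiguous
between k and the full run length, and k is implemented as the stated
definition). `repeat_runs` reseeds only the classifier, holding data and
split fixed, so the metrics isolate training stochasticity; with the
deterministic token-logistic fit they are exactly 100% / 1.0, and the
transformer provides genuine seed-to-seed variation.

## Disproportionality baselines

2×2 tables count term × endpoint over labeled reports whose feature is
observed — the same cohort as the do/not-do partition, so the methods see
identical evidence. PRR = [a/(a+b)]/[c/(c+d)] with Pearson χ² (no
continuity correction by default; Yates behind a flag); signal iff a ≥ 3,
PRR ≥ 2, χ² ≥ 4; c = 0 gives an infinite sentinel with the other gates
still applied. ROR = ad/bc with log-normal 95% CI; any zero cell triggers
Haldane–Anscombe +0.5 on all four cells (ROR only); signal iff the lower
limit exceeds 1. EBGM follows the DuMouchel gamma-Poisson shrinker:
a ~ Poisson(λE) with E = (a+b)(a+c)/n from the table margins (independence
model; stratified E is out of scope), λ ~ two-component gamma mixture.
Hyperparameters maximize the exact negative-binomial-mixture marginal
likelihood by multi-start (5, seeded) bounded L-BFGS-B on log shapes/rates
and logit weight; optimization failure raises with diagnostics rather than
defaulting. The posterior is the conjugate gamma mixture; EBGM =
exp(E[ln λ | a]) via digamma, EB05 by root-finding on the mixture CDF.
Closed forms are verified against brute-force numerical integration of
prior × likelihood (a route that never uses conjugacy) to 1e-4.

## Synthetic generator

The generator emulates a cleaned spontaneous-report extract: seven features
(gender, age group, primary suspect drug, dose class, indication,
multi-valued adverse events, outcomes), per-term prevalences (single-valued
features draw one term from the normalized prevalences; multi-valued
features include terms independently), per-feature missing-at-random rates,
and a binary endpoint from a logistic model: intercept + main-effect
log-odds of present terms + interaction log-odds active only when both
members are present. Positives receive the endpoint term; negatives draw
another outcomes term. Effects are parameterized on the log-odds scale so
closed-form oracles are exact.

Reference study conditions (the package defaults): n = 5,000 reports,
APAP +2.0 log-odds at prevalence 0.3, high dose +1.5 at 0.4, a +1.5
female-within-APAP interaction, intercept −1.5 (endpoint prevalence ≈ 0.5);
every feature keeps zero-effect negative-control terms. The null
configuration (type-I studies) uses 30 terms over six features, n = 3,000,
all effects zero. The generator does **not** emulate duplicate reports,
reporting-over-time dynamics, term misspelling/synonymy, or missingness
that depends on the outcome — so passing recovery tests show the machinery
is correct under its stated model, not that real FAERS extracts satisfy
that model.

## What the procedure does and does not control

Two properties of the published procedure, measured here and worth stating
plainly, follow from probing a classifier with the same labels it was
fitted on:

* **Null calibration fails.** Under a global null the fitted weights are
  pure noise, but the z-test's numerator (the do/not-do gap, driven by the
  term's own fitted weight) and denominator (the spread of predicted
  probabilities, driven by all the other noise weights) shrink at the same
  rate, so z is scale-invariant in the noise and its null spread grows like
  sqrt(n / #terms) instead of staying standard normal (measured sd ≈ 12 at
  n = 3,000 with 30 terms; family-wise error ≈ 1 under Bonferroni at
  α = 0.05). Held-out probing does not remove the effect, because the
  fitted noise weight is deterministic given the model.
* **With real signal, controls are still inflated ~2×.** The denominator
  becomes signal-dominated, but a zero-effect term's fitted noise weight
  still widens its own gap; the control z is approximately the term's
  sampling z times sd(label residual)/sd(p′) ≈ 2, giving each control a
  ~5% tail beyond the Bonferroni threshold. Early stopping at the
  dev-accuracy-optimal checkpoint attenuates but does not remove this
  (measured: the rate of runs with ≥1 false control is insensitive to
  checkpoint granularity).

Planted effects of realistic size are nevertheless recovered essentially
always (the signal z is an order of magnitude above the inflated null), and
this asymmetry — excellent sensitivity, unreliable specificity guarantees —
is consistent with the very large z-scores the procedure reports on real
data. Users should read the enriched set as a sensitive screen to be
confirmed by the disproportionality baselines or external evidence, not as
a calibrated hypothesis test.

## Numerical and degenerate-input choices

Cross-entropy clamps probabilities at 1e-12; accuracy uses threshold 0.5;
the z-test requires ≥ 2 observations per stratum and `min_group_size` 30 by
default; EBGM expected counts are floored at 1e-10; EB05 root-finding
brackets by CDF doubling from [1e-12, 1]; the EBGM fit requires ≥ 20
tables. Ranking ties anywhere break alphabetically. All random draws flow
through `numpy.random.default_rng` with explicit seeds; the token-logistic
path is bitwise deterministic, the transformer reproducible to float
accumulation order on a fixed platform.

## Problem sizes

The simulation studies run at n = 5,000 reports (recovery, containment,
robustness), n = 8,000 (tree recovery, 20 seeds), and n = 3,000 × 100-200
runs (null calibration) with the token-logistic classifier — sizes at which
every reported rate is stable across reruns while the full suite stays
desk-scale. The transformer is exercised on smaller separable corpora where
its behavior is checked against the deterministic logistic oracle on
identical data.
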