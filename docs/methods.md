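# Methods

## Model and scope

Every response variable y (a column of the samples x responses matrix, assumed
log-scale) is analysed under the normal linear model

    y_jk...i = mu + a_j + b_k + (ab)_jk + ... + eps,   eps ~ N(0, sigma^2),

on a **balanced, orthogonal** factorial design with 1–3 treatment factors,
equal replication in every cell, and an optional randomized-complete-block
structure (every block contains every treatment cell equally often). Balance is
verified at construction/load and imbalance is rejected with a per-cell count
report — unbalanced designs, covariates, mixed models and GLMs are out of
scope. Blocks are design structure, not hypotheses: their SS is removed before
treatment testing, never pooled into the residual, and never subject to
selection.

Under balance the ANOVA decomposition is computed from marginal means: the
effect of a term is its marginal mean minus the grand mean and all lower-order
effects it contains, and the term SS is the sum of squared effects. This is
identical to least-squares projection onto the term's contrast space (the test
suite checks agreement with a dense sequential-projection oracle to 1e-10
relative) but costs O(N·R) for a whole response matrix, which is what makes the
frameworks vectorisable over thousands of responses.

### Degenerate inputs and ties

A zero-variance response (total corrected SS = 0) yields F = NaN and p = 1 for
every term, is excluded from the count of tests R in the multiplicity
correction (it carries no test), and is filtered with no model assigned — mass
analysis never aborts mid-matrix. A non-zero numerator over a zero residual
yields F = inf, p = 0. Ties at p = level count as significant (≤). Response
ranks are ascending by (adjusted p, raw p), ties sharing the minimum rank with
stable input order.

## One-way collapses of a factorial model

The overall test of a model M is a one-way F test whose numerator pools the SS
of M's treatment terms and whose denominator pools the residual with the SS
and df of the dropped terms ("inflated residual" semantics). Degrees of
freedom follow the **standard** convention by default: df1 = sum of retained
term dfs, df2 = N − 1 − df_block − df1. A compatibility mode **as-printed**
reproduces the (t_A + t_B − 1, N − (t_A + t_B)) counting sometimes quoted for
the two-factor additive model; it is defined only for additive (or saturated)
models — for a single-factor or saturated model the two conventions coincide,
and for models containing an interaction the as-printed counting has no
agreed definition, so it raises. Neither convention is asserted "correct";
both are exposed and the default is the standard one.

A **lack-of-fit** variant keeps the designed residual df instead: the pooled
treatment SS is split into the model's one-way component and a lack-of-fit
remainder, both tested against the saturated-model residual mean square. It is
available as the overall test in MRF via `oneway="lack-of-fit"`.

## Multiplicity

Bonferroni (FWER) and Benjamini–Hochberg step-up (FDR) adjusted p-values come
from `statsmodels.stats.multitest.multipletests`. On top of them the package
defines the per-response adjustment factor c^(r): R under Bonferroni and the
operational ratio adjusted/raw under B-H (1 when the raw p is exactly 0, since
the abstract definition is a multiplier and any multiplier fixes 0). The
response-specific significance level alpha / c^(r) is what survivors carry
into model selection under RFM, and what adjusts per-term p-values for the
marginal (per-term) assessment. The exact per-test FWER level
1 − (1 − alpha)^(1/R) and its Bonferroni bound alpha/R are provided for
reference.

## Model selection

The predictive model is the set of significant treatment terms completed
under **marginality**: a retained interaction forces all its lower-order
terms in. Default selection is a **single pass** against the saturated
residual — each term's F uses MS_res, matching how the term tests are
defined in the structured ANOVA table — with **sequential pooling** as an
option (interactions tested first; dropped terms pool their SS/df into the
residual before lower-order terms are tested; a term marginal to a retained
interaction is never dropped). The hierarchical candidate space has 5 models
for two crossed factors and 19 for three; a non-hierarchical flag exposes all
2^T significant-term patterns, which is also how `group_by_model(...,
by="pattern")` reproduces up-to-8 groups for a two-factor design.

## The frameworks

* **RFM** corrects the saturated one-way p-values across responses, filters,
  and selects models for survivors at alpha/c^(r). Filtered responses are
  reported as "filtered" (no model), deliberately distinct from a selected
  null model.
* **MRF** selects at the unadjusted alpha for every response, then corrects
  and filters on the predictive-model one-way test (null-model responses get
  p = 1 and rank last).
* **RMF** takes ranking and c^(r) from the saturated test, selects for every
  response at alpha/c^(r), and filters on the predictive-model one-way test
  at that same response-specific level (the adjusted value min(1, c·p_pred)
  is recorded, so "passed" is equivalent to adjusted ≤ alpha).
* **MSF** corrects each term's R p-values separately (or all R×p tests
  globally); because main effects can be declared non-significant under a
  significant interaction, marginality violations are flagged per response.
  An optional pre-selection step restricts the tested terms to each
  response's predictive model.

### Statistical behaviour worth knowing

RFM is conservative: a response with overall saturated F = 2 on a 4x3 design
with 3 replicates has p = 0.075 and is filtered at 5% even when a single main
effect carries all the signal; MRF, having dropped the null interaction,
retains it. Conversely MRF's selection-before-filtering has a cost for strict
FDR control: for a true-null response the predictive-model p-value is
approximately the minimum of the term p-values over the k candidate terms
(each term is selected only when its own p ≤ alpha, and the one-way retest of
a selected term reproduces roughly the same p), so the null p-distribution is
super-uniform by about a factor k near 0 and B-H over such p-values yields an
FDR near k·pi0·alpha rather than ≤ pi0·alpha. With half the responses null in
a 2x2 design (k = 3 terms) the simulation engine measures RFM's FDR well
under the nominal 5% and MRF's above it (≈6%); the corresponding acceptance
check on MRF is left failing rather than relaxed, since it follows from the
pipeline's definition, not from an implementation choice. With smaller null
proportions, stronger selection levels, or FWER-oriented Bonferroni filtering
the exceedance shrinks.

## Synthetic-data generator

The simulator emulates replicated factorial screens analysed on the log
scale. Built-in designs: 2x2, 3x2x4, and 3x2x4 with a randomized complete
block structure (blocks = replicates). Per response:

* the true model is null with probability 0.5 (default), otherwise uniform
  over the marginality-closed non-null models (configurable as explicit
  model-label probabilities);
* for each true term, effect coefficients are drawn in an orthonormal
  contrast basis of the term's effect space (Helmert tensor products over the
  cell grid), with magnitude uniform on [1, 3] sigma units and random sign —
  so "effect size" is exact per free parameter and every drawn term has a
  non-zero effect;
* errors are i.i.d. N(0, sigma^2) with sigma^2 = 1 by default; RCB scenarios
  add per-block effects N(0, sigma_b^2) (default sigma_b^2 = sigma^2) and,
  optionally, a common correlation rho (default 0.7) within contiguous blocks
  of 10 responses.

Everything is reproducible from a single integer seed (one generator, fixed
call order). What the generator does **not** emulate: heavy-tailed or skewed
abundance noise, missing values, mean–variance coupling, and realistic
'omics-wide correlation beyond the block-exchangeable structure — so passing
error-rate tests here demonstrates the pipelines' behaviour under their own
model assumptions, not robustness to real-data pathologies.

Error metrics per dataset: fp_pct and fn_pct are percentages of all R
responses (falsely declared non-constant / falsely declared constant), fdp is
false discoveries over max(1, discoveries), and the model-fit percentages
(correct / overfit = strict superset / underfit = strict subset /
misspecified = neither) are computed over surviving responses (NaN when
nothing survives). The full study grid — 3 designs x R in {500, 1000, 20000}
x {3, 4, 5} replicates x 50 simulations — enumerates 1350 datasets; the
acceptance script and test suite run the 2x2, R = 500, 3-replicate corner (50
datasets, about 25,000 responses per pipeline) so the whole default suite
completes in a few minutes on one CPU, with the larger scenarios available
through `scenario_grid`.

## Relevance reporting

Fold changes are base^(prediction − baseline prediction) with predictions
taken from the selected predictive model (identical to back-transformed cell
means when the model is saturated); maximal fold increase and decrease over
non-baseline conditions give a single importance ranking. For multi-level
factors the per-term relevance axis is √MS_T, tested against
MS_T/MS_res = 1 at the response's multiplicity-corrected level; a biological
threshold on MS_T marks relevance. Default plot thresholds: p = 0.05 and
fold change 4, both settable. Contrast sets (orthogonal, zero-sum; integer
patterns normalised to unit length internally) split a factor's SS into named
single- or multi-df rows plus a "deviations" remainder, e.g. a linear salt
trend plus curvature, or an ecotype split of four genotypes.

## Numerical choices

* Residual SS is total minus explained, clipped at 0 against roundoff; the
  zero-variance threshold on mean squares is 1e-12.
* Adjusted p-values are capped at 1 (min(1, c·p)).
* CSV outputs use pandas' shortest round-trip float representation, so a rerun
  with the same configuration is byte-identical; read them back with
  `float_precision="round_trip"` for exact equality.
* Scenario seeds inside a grid are drawn once from the base seed and stay
  below 2^31.
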