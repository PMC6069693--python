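# massanova

Stage-wise mass-univariate ANOVA for 'omics experiments with factorial
treatment structures.

## The problem

High-throughput experiments (lipidomics, metabolomics, transcriptomics, ...)
measure hundreds to tens of thousands of response variables on a designed
experiment — typically a replicated factorial such as 4 genotypes x 3 salt
levels. Screening each response with a univariate ANOVA raises two coupled
questions:

1. **Multiplicity.** Testing R responses at level α inflates the familywise
   error to α* = 1 − (1 − α)^R (0.40 for R = 10 at α = 0.05), so the
   per-response tests must be corrected (Bonferroni for FWER, Benjamini–
   Hochberg for FDR). Standard corrections apply to *one* test per response —
   but a factorial ANOVA produces one test per model term.
2. **Structure.** Collapsing the factorial to a single one-way treatment
   factor (all level combinations as unstructured groups) admits a correction
   but discards the information the design was built to provide: which main
   effects and interactions drive each response.

The resolution is stage-wise: every analysis is an ordering of three steps —
**RANK** responses by an overall one-way F test, **FILTER** non-significant
responses after a multiplicity correction, and **MODEL** each response by
selecting its predictive model (significant terms plus everything marginal to
them) with term-wise F tests. The order matters:

| framework | order | overall test is of | character |
|---|---|---|---|
| **RFM** | rank → filter → model | the *saturated* model | conservative; right for marginal (per-term) assessment |
| **MRF** | model → rank → filter | the *predictive* model (dropped terms pooled into the residual) | more powerful; right for overall assessment and prediction |
| **RMF** | rank → model → filter | the predictive model, filtered at the response-specific level α/c^(r) | mitigates RFM's conservativeness |
| **MSF** | per-term corrections | each explanatory term separately (or one global R×p correction) | can violate marginality; violations are flagged |

For a two-factor design the saturated one-way statistic is
F = [(SS_A + SS_B + SS_AB)/(t_A t_B − 1)] / [SS_res/(N − t_A t_B)], while the
additive predictive model tests (SS_A + SS_B) against SS_res + SS_AB with
inflated residual df: a response with a strong main effect but a null
interaction can fail the first and pass the second. Survivors carry a
response-specific significance level α/c^(r) (c^(r) the multiplicity
adjustment factor) into model selection, per-term adjusted p-values, and
relevance measures: predicted fold changes to a baseline condition and the
generalised volcano axis √MS_T for multi-level factors.

The package provides the balanced-ANOVA core (orthogonal SS decomposition,
one-way collapses, lack-of-fit partitions, orthogonal contrasts, cell-mean
prediction), the corrections, F-test model selection under marginality, the
four frameworks, a simulation engine with known truth for measuring FP/FN/FDP
and model-misspecification rates, and file/CLI interfaces.

## Worked example

With a samples x responses CSV (first column sample id, values log2
abundances) and a design table mapping samples to factor levels:

```bash
massanova analyze \
  --responses responses.csv --design design.csv \
  --model "Genotype*Salt" --framework rfm --framework mrf \
  --correction bh --alpha 0.05 \
  --baseline "Genotype=Col,Salt=0" --out demo_out
```

```
running RFM (bh, alpha=0.05) on 12 responses
RFM: 7 of 12 responses pass the filter -> demo_out/rfm_overall.csv
running MRF (bh, alpha=0.05) on 12 responses
MRF: 7 of 12 responses pass the filter -> demo_out/mrf_overall.csv
```

`rfm_overall.csv` then holds, per response, the overall one-way p-value, its
B-H adjusted value, the adjustment factor c, the rank, the filter outcome, the
selected predictive model, and the maximal fold change to the baseline
condition:

```
response   p_raw   p_adj        c  rank  passed    model  max_fold_increase  max_fold_decrease
   lip00 0.00000 0.00000 12.00000     1    True Genotype            2.37491            1.22575
   lip04 0.00216 0.00370  1.71429     7    True     Salt            1.91275            1.00000
   lip07 0.12879 0.19319  1.50000     8   False filtered                NaN                NaN
```

Reading: `lip00` is differentially expressed overall (adjusted p ≈ 2e-6), its
predictive model contains only the Genotype main effect, and its abundance
rises at most 2.37-fold over the no-salt Columbia baseline under any
condition. `lip07` fails the 5% FDR filter and receives no model ("filtered",
deliberately distinct from a selected null model). `rfm_groups.csv` partitions
the responses by predictive model (here: 4 x Genotype, 3 x Salt, 5 filtered),
and `rfm_terms.csv` holds per-term adjusted p-values and √MS_T for the
generalised volcano and heatmap views (`massanova report --in demo_out
--volcano --heatmap`).

The same analysis is available as a library (`massanova.run_rfm(Y, design,
correction="bh", alpha=0.05)`), and `massanova simulate --config grid.yaml
--seed 7 --out sims/` runs a simulation grid and writes per-dataset and
summary error metrics.

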