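# megax

Multi-dataset case/control gene-expression **mega-analysis**: meta-analysis of
log2 fold changes recomputed from each study's expression matrix rather than
from published summary statistics, plus the surrounding stages a study of a
candidate driver gene needs — covariate regression on study-level effects,
signed literature-network assembly with expression-consistency filtering, and
gene-set over-representation analysis.

It is aimed at transcriptomics researchers pooling a handful to a few dozen
public case/control series (e.g. GEO microarray datasets) for a single disease
and asking whether a gene of interest moves consistently, why studies
disagree, and how the gene's literature neighbourhood relates to those
expression shifts.

## The model

For gene *g* in study *i*, the effect size is the log2 fold change
`y_i = mean(case) − mean(control)` on the log2 scale with Welch standard
error `se_i = sqrt(s²_case/n_case + s²_control/n_control)`.  Pooling uses
inverse-variance weights:

- Cochran's heterogeneity statistic `Q = Σ w_i (y_i − ŷ_F)²` with
  `w_i = 1/se_i²` and `df = k − 1`;
- `I² = 100·max(0, (Q − df)/Q)`;
- DerSimonian–Laird between-study variance
  `τ² = max(0, (Q − df)/(Σw − Σw²/Σw))`;
- fixed-effects weights `1/se_i²`, random-effects weights `1/(se_i² + τ²)`;
  the **fixed-effects model is selected iff `Q ≤ df`** (truncated I² is
  zero), otherwise random effects;
- two-sided normal p-value for the pooled estimate, 95% CI
  `ŷ ± 1.959964·SE`, and per-study weights reported normalized so the
  largest is 1 (forest-plot convention).

The **partial mega-analysis** re-pools only the top `floor(k·fraction)`
studies ranked by |LFC| (default fraction 0.5, minimum 2 studies) — a screen
for genes that move strongly in a subset of datasets.  Note this selection
inflates |pooled LFC| under the null by construction; the package documents
and tests that bias (see `docs/methods.md`).

Downstream, study-level LFCs are regressed on study covariates (sample size,
country, study age) by OLS with joint F-tests for categorical factors;
literature relations with polarity are assembled into a *diagnostic* network
(genes pushed in opposite directions by the driver and the disease) and a
*prognostic* network (driver→gene→disease chains); and gene lists are scored
against GMT collections with the hypergeometric upper tail, BH-FDR and
Jaccard similarity.

## Worked example

Simulate 11 studies (n = 30/30 each) of a gene with true δ = −0.6,
between-study variance τ² = 0.15, and an extra −0.9 shift in the three
French cohorts, then pool:

```python
from megax import (MegaAnalysis, SimulationTruth, default_study_grid,
                   simulate_effect_table)

truth = SimulationTruth(gene_truth={"PPARG": -0.6}, tau2=0.15,
                        covariate_effects={"country": {"FR": -0.9}}, seed=11)
grid = default_study_grid(11, 30, 30,
                          country=["FR" if i < 3 else "US" for i in range(11)])
model = MegaAnalysis(simulate_effect_table(truth, grid))
print(model.fit().summary())
print(model.fit_partial(0.5).summary())
```

```
Mega-analysis of PPARG (11 studies, random-effects model)
========================================================================
  pooled LFC -0.8462   SE 0.2050   95% CI [-1.2479, -0.4444]   p 3.66e-05
  Q 69.3327 (df 10, p 5.96e-11)   ISq 85.58%   tau2 0.3956
...
Mega-analysis of PPARG (5 studies, random-effects model)
========================================================================
  pooled LFC -1.4962   SE 0.1622   95% CI [-1.8142, -1.1782]   p 2.9e-20
  Q 7.8961 (df 4, p 0.0955)   ISq 49.34%   tau2 0.0649
```

The full pooled LFC (−0.85) sits between the two country strata and Q/I²
flag the heterogeneity the country shift induced; the partial analysis keeps
the five largest-|LFC| studies (the French cohorts plus the strongest US
draws) and sharpens the estimate to −1.50 — illustrating both what the
procedure is for and why its magnitude must be read with the documented
selection bias in mind.  `megax.fit_mlr` on the same effects attributes the
spread to country.

A command-line interface mirrors the library (`megax simulate`, `megax
effects`, `megax pool`, `megax mlr`, `megax network`, `megax enrich`,
`megax run --config run.yaml`).

## Packaged fixtures

`megax.load_table1_studies()` ships the metadata of the 12 qualifying lung
squamous cell carcinoma (LSCC) datasets (285 controls / 375 cases);
`load_diagnostic_relations()` and `load_prognostic_relations()` ship the
signed PPARG/LSCC literature edges behind the diagnostic (12 genes: 8
positive, 4 negative markers) and prognostic (3 promoters, 1 inhibitor)
networks.

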