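# Methods

## Effect sizes

Each study contributes, per gene, the difference of group means on the log2
scale (case − control).  Intensity matrices whose values fall outside
[−10, 30] are treated as linear-scale and transformed with `log2(x + 1)`;
the pseudo-count keeps zeros finite and makes the transform reproducible
bit-for-bit.  The standard error is the Welch two-sample form
`sqrt(s²_case/n_case + s²_control/n_control)` with unbiased group variances —
an assumption-light choice that supplies the per-study variance
inverse-variance pooling needs without imposing equal group variances.
Samples with missing values are dropped per gene; a gene needs at least two
usable samples per group, and genes with any missing value in a study are
excluded from that study's effect table (logged).  Duplicate gene symbols
(multiple probes) collapse to the row with the highest mean expression,
ties broken by first occurrence.  A standardized-effect variant exists but
the pipeline pools raw LFC, which is the quantity the downstream consistency
and reporting steps interpret.

## Pooling and model selection

Heterogeneity uses Cochran's Q against the fixed-effects pooled mean with
df = k − 1, I² = 100·max(0, (Q−df)/Q), and the DerSimonian–Laird (DL)
moment estimator τ² = max(0, (Q−df)/c), c = Σw − Σw²/Σw.  DL is the classic
Q-based estimator and the natural partner of the Q/df/I² vocabulary; REML,
Paule–Mandel and Hartung–Knapp adjustments are deliberately out of scope.
Model choice is rule-based, not test-based: fixed effects iff Q ≤ df (the
point where truncated I² and τ² are zero), else random effects.  The p-value
of Q is reported for information only and plays no role in selection.  The
pooled estimate carries a two-sided normal (z) p-value and a z-based 95% CI
(`±1.959964·SE`).  Per-study weights are reported normalized by their
maximum, range (0, 1], the convention used for forest-plot weight bars.

Known limitation: with k ≈ 10 studies and appreciable τ², z-based DL
intervals undercover — in the limit of dominant heterogeneity their coverage
approaches P(|t_{k−1}| ≤ 1.96) ≈ 92.4% at k = 11, and the package's own
simulations at k = 11, τ² = 0.2 measure ≈ 91–92%.  This is a property of the
estimator family implemented, not a defect of the simulator; consumers
needing nominal small-k coverage should treat the CI as approximate.

### Partial mega-analysis

`select_top_datasets` keeps the `floor(k·fraction)` effects with the largest
|LFC| (ties broken by input order; at least two studies required), and the
partial analysis re-runs heterogeneity, model selection and pooling on that
subset.  With k = 11 and fraction 0.5 exactly 5 studies are retained — the
floor rule is the only rounding consistent with that pairing.  Ranking is by
|LFC|, not |LFC/SE|: the subset is defined by effect magnitude, not
significance.  The procedure is a discovery screen, and it is biased by
construction: under δ = 0 with between-study variance, the partial |pooled
LFC| is stochastically larger than the full-analysis value (the test suite
measures the partial estimate exceeding the full one in ~89% of 2000 null
replicates).  Partial results should therefore be read as "strong in a
subset", never as unbiased magnitude estimates.

## Covariate regression

Study-level LFCs are regressed by ordinary least squares on study covariates:
numeric factors (total/group sample size, study age in years) enter as-is,
categorical factors (country, organism) are one-hot coded against a
first-level reference.  Each factor gets one p-value — the coefficient t-test
for single columns, a partial F-test for multi-level categoricals.  A 1/se²
weighted variant is available behind a flag; unweighted OLS is the default
because the regression is meant to explain the raw study-level effects.
With ~11 studies and a many-level country factor the design is nearly
saturated, so the fit raises on rank deficiency (naming the aliased terms),
refuses when no residual degrees of freedom remain, and warns below 3.
Simulations in the suite confirm per-factor type-I error ≈ 5% under null
covariates and >80% power for a −1.0 country shift affecting 3 of 11 studies
(τ² = 0.05, n = 30/30).

## Networks

Relations are signed edges (source, target, polarity ±1, kind, provenance),
unique per (source, target, kind); two edges between the same pair with
opposing polarity are rejected as conflicting.  The **diagnostic network**
intersects driver→gene and disease→gene edges and keeps contra-directional
genes: disease +1 / driver −1 ⇒ positive marker, the reverse ⇒ negative
marker.  When pooled results are supplied, each marker is labelled
consistent/inconsistent by comparing sign(pooled LFC) from the *full*
mega-analysis with the disease polarity (|pooled LFC| < 1e-9 is untestable →
"untested"); inconsistent genes stay in the network but are dropped from the
default marker report.  The **prognostic network** chains driver→gene and
gene→disease edges: driver-inhibited disease-promoters and driver-activated
disease-inhibitors.  Pooled directions are attached for annotation only — a
prognostic gene is not removed when its expression moves with rather than
against the literature direction, since the chain logic (upstream regulation)
is not an expression prediction.  Membership is set-semantic: relation-row
order never changes it.

## Enrichment

The "gene-set enrichment" stage is over-representation analysis on a fixed
list (the signature of reported overlap counts and Jaccard similarities),
not rank-based GSEA: for a query of n genes in a universe of N, a set with K
universe members and overlap k scores `P[X ≥ k]` under
Hypergeometric(N, K, n), with Benjamini–Hochberg q-values across all tested
sets and Jaccard |query∩set|/|query∪set| reported per row.  The universe
defaults to the union of the collection's members and is overridable;
literature-mining backends use proprietary backgrounds, so printed p-values
from such tools are not reproducible and are not a target here.  Rows sort
by ascending p, ties by set name.

## Synthetic data

The generator emulates a multi-study case/control collection on the log2
scale: per-gene baseline μ_g ~ U(6, 10) (mid-range log2 intensity), true
effect δ_g, study-level effect δ_gs = δ_g + covariate shifts + N(0, τ²),
and Gaussian samples N(μ_g, σ²) / N(μ_g + δ_gs, σ²) with σ =
`base_noise_sd` = 1.0 by default — a typical within-group SD for array
expression on the log2 scale.  Covariate effects enter additively on δ,
either per categorical level or per numeric unit, which makes the covariate
regression testable against known truth.  An effect-level shortcut draws
LFC ~ N(δ + shifts, τ² + SE²) with SE = σ·sqrt(1/n₀ + 1/n₁) directly; a KS
test in the suite confirms the two simulators agree in distribution.  All
randomness comes from streams keyed by (seed, purpose, study, gene), so any
block regenerates independently and results do not depend on generation
order.

What the generator does *not* emulate: probe-level artifacts, batch
structure, normalization differences between platforms, heavy-tailed or
count-based noise, and gene–gene correlation.  Passing calibration tests
therefore demonstrates correctness of the statistical machinery under the
stated Gaussian model, not robustness to real microarray pathology.

## Problem sizes and numerical choices

Monte-Carlo suites use 500–2000 replicates at k = 11 (k = 50 for τ²
recovery), sizes at which binomial error on calibration rates is ~1
percentage point and the whole suite runs in well under a minute.
Degenerate inputs are first-class: zero-variance effects are flagged rather
than silently given infinite weight, pooling requires k ≥ 2 and positive
SEs, and pooled effects below 1e-9 in magnitude are treated as directionless
in consistency checks.  The DL cross-check against an independent
meta-analysis reference (r-metafor, method "DL", z test) agrees to 1e-6 on
estimate, SE, τ², Q and p.

## Fixture notes

The packaged study table preserves the printed metadata of the 12 qualifying
LSCC datasets; one row's country is normalized to "Netherlands" (from a
truncated spelling) so the table has the 8 distinct countries its source
describes.  The diagnostic relation fixture stores the printed symbol "MI21"
verbatim (almost certainly MIR21); an opt-in alias map rewrites it.  The
positive/negative marker split follows the network figure (4 disease-down
genes); the accompanying text once lists a fifth (PTEN), a discrepancy
recorded here and resolved in favour of the figure.
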