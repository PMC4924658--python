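# sigdriver

Robust gene-signature discovery and interaction-network driver
prioritization for multi-study cancer expression data.

Small microarray or expression cohorts yield unstable gene signatures: a
gene that looks differentially expressed in one cohort often vanishes in the
next. `sigdriver` implements a workflow that addresses this by (1) merging
several studies into one cohort and removing study (batch) effects with a
parametric empirical-Bayes adjustment, (2) resampling the integrated cohort
into *virtual datasets* and keeping only genes called consistently across
them, and (3) projecting the surviving signatures (or differentially
abundant proteins from a paired proteomics screen) onto a protein–protein
interaction network, where candidate driver proteins are ranked by network
topology. Pathway enrichment and median-split survival analysis complete the
picture. A synthetic-data module generates every input with the statistical
structure the analysis assumes, so the whole pipeline runs and is tested
without any external download.

## The statistics at the core

**Empirical-Bayes batch correction.** Expression follows the location/scale
batch model y_gjs = α_g + β_g x_j + γ_sg + δ_sg ε_gj, with additive batch
offsets γ_sg ~ N(γ̄_s, τ²_s) and multiplicative dispersions δ²_sg under an
inverse-gamma prior. Hyperparameters are estimated by method of moments and
(γ*, δ²*) by iterated conditional posterior updates; the corrected value is
y* = σ_g/δ*_sg · (z_gj − γ*_sg) + α_g + β_g x_j, so the case/control effect
β_g is protected.

**Permutation d-statistic with FDR.** Each gene is scored with
d_i = (x̄_case − x̄_control)/(s_i + s₀), where s_i is the pooled standard
error and s₀ is chosen to make the spread of d uniform across the range of
s. Ordered observed scores are compared to their expected order statistics
under group-label permutations; genes departing by at least Δ are called,
and FDR(Δ) is the median permuted count of scores beyond the calling cutoffs
divided by the number of calls. Calls additionally require a linear fold
change max(fc, 1/fc) ≥ 1.2, and Δ is chosen as the smallest grid value with
estimated FDR ≤ 0.05. A gene is a **robust signature** when it is called
with a consistent direction in at least m of k virtual datasets (default
6 of 8).

**Network driver ranking.** Significant proteins seed a one-hop expansion of
an interaction edge table; after cleaning (self-loops, isolates, largest
connected component) and optional Steiner-tree reduction (metric-closure MST
approximation), every node gets degree k_n and clustering coefficient
CC = 2e_n/(k_n(k_n−1)), with e_n the edge count among its neighbors. Roots
are ranked by descending k_n, ties broken by ascending CC: a high-degree,
zero-CC root is a bottleneck hub — the driver-candidate profile.

**Downstream statistics.** Pathway over-representation uses the right-tailed
Fisher exact (hypergeometric upper-tail) test with Benjamini–Hochberg
adjustment; the proteomics filter is a paired two-class t-test at p < 0.001
where a negative control − treated difference means up-regulation under
treatment; survival uses the Kaplan–Meier product-limit estimator with the
Mantel–Cox log-rank test after a median split of marker expression.

## Worked example

```bash
sigdriver demo --out demo_run --seed 1
```

runs the full pipeline on a freshly simulated scenario (2,000 genes, three
studies of (10, 10), (5, 12) and (11, 16) control/case samples, 5% planted
differential expression at |log2 FC| = 1.5, a 2,000-node scale-free
interaction atlas with 17 planted hubs, 500-protein paired proteomics and a
200-patient survival table) and prints:

```
robust signatures: 100 (sensitivity 1.0, precision 1.0)
top root: G00414 (degree 18, CC 0.006535947712418301)
log-rank p: 6.458e-11
```

All 100 planted differentially expressed genes — and nothing else — survive
the 6-of-8 consensus filter; the top-ranked root protein is one of the
planted hubs (18 interaction partners, near-zero clustering); and the
high-expression survival group's threefold hazard is detected by the
log-rank test. `demo_run/` contains every intermediate table (merged and
corrected matrices, per-gene signature calls, the network as SIF with a
node-attribute table, root ranking, enrichment results, Kaplan–Meier
curves) plus `manifest.json` recording seeds, parameters and per-stage
counts. The same stages are available individually (`sigdriver integrate`,
`consensus-de`, `netbuild`, `enrich`, `prot-diff`, `survival`) and as
library calls:

```python
from sigdriver import SimulationConfig, simulate_multistudy_expression, \
    BatchEffectModel, merge_on_shared_genes, run_consensus

cohort, truth = simulate_multistudy_expression(SimulationConfig(seed=1))
merged = merge_on_shared_genes(cohort.split_by_study())
results = BatchEffectModel(merged).fit()     # Model -> Results
corrected = results.corrected()
table, sam_results, plan = run_consensus(corrected, k=8, m=6, seed=1)
print(sam_results[0].summary())
```

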