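# Methods

This note documents the models, defaults and numerical choices behind
`sigdriver`, and what the synthetic-data experiments do and do not
demonstrate.

## Synthetic data model

The generators produce inputs with exactly the structure the downstream
stages assume, so every stage can be validated by parameter recovery.

**Expression.** y_gjs = α_g + β_g x_j + γ_sg + δ_sg ε_gj on the log2 scale:
per-gene baseline α_g ~ N(7, 1), case effect β_g = ±log2_fc for the planted
fraction of genes (direction split 50/50 so that direction-consistency logic
in consensus calling is exercised) and 0 otherwise, additive batch offsets
γ_sg ~ N(0, batch_shift_sd²), multiplicative dispersions δ_sg lognormal with
unit mean and coefficient of variation batch_scale_sd, and residual noise
ε ~ N(0, noise_sd²). This is the parametric location/scale model the
empirical-Bayes correction assumes, which is deliberate: it makes the
correction testable by recovery rather than only by variance reduction.
Defaults: three studies with (control, case) sizes (10, 10), (5, 12),
(11, 16) — a small integrated multi-cohort design — 2,000 genes, 5% planted
differential expression at |log2 FC| = 1.5, batch_shift_sd = 1.0,
batch_scale_sd = 0.2, noise_sd = 0.5. The noise and batch scales are
conventions chosen to be realistic for log2 microarray data (per-gene
residual SD of roughly half a log2 unit; batch offsets comparable to or
larger than the biological effect), not estimates of any particular cohort.

**Interaction networks.** Preferential attachment (Barabási–Albert,
attachment = 2) with a configurable number of planted hubs, each wired to
extra random partners until its degree is at least twice the 90th degree
percentile (plus 5). The generator asserts afterwards that every hub clears
the final 90th percentile. Node ids can be aliased to the expression gene
universe so that expression, proteomics and network truths refer to the same
entities.

**Survival.** Exponential event times; the high-expression half of the
samples has hazard baseline_hazard × hazard_ratio (baseline 0.02/month).
Censoring is by independent exponential times with the rate chosen so the
expected censored fraction equals censor_rate — the standard mechanism that
keeps the product-limit estimator unbiased. Marker expression is drawn
N(7, 0.5) vs N(5, 0.5) for high/low, so the median split recovers the truth
groups.

**Paired proteomics.** Log2 abundances ~ N(25, 2) per protein, i.i.d.
N(0, noise_sd²) measurement noise on every control and treated replicate,
and a fixed treated-minus-control shift of ±shift for the planted proteins.
With 3 pairs the paired t has 2 degrees of freedom, so even a 40-sigma shift
occasionally fails p < 0.001 when the sample SD of the three differences is
inflated; power statements in the tests are therefore made at fixed seeds,
not as universal claims.

**What passing tests do not show.** The generators match the analysis
assumptions by construction. Passing recovery tests demonstrates internal
correctness and calibration, not robustness to the ways real cohorts violate
the model: heavy-tailed noise, probe-level artifacts, correlated genes,
batch-by-group confounding, informative censoring and missing-not-at-random
proteomics intensities are all absent.

## Batch integration

Standardization fits, per gene, batch means plus a control/case covariate by
least squares; the grand mean is the sample-size-weighted average of batch
means, and the pooled variance is the mean squared residual from the full
fit (maximum-likelihood denominator N). The group covariate is removed
before shrinkage and re-added after adjustment — the paper-shaped workflow
does not say whether biological class should be protected during batch
correction, and protecting it is the choice that cannot destroy signal.
Hyperpriors use method of moments: normal (γ̄_s, τ²_s) across genes for the
additive effects, inverse-gamma (λ_s, θ_s) matched to the mean and variance
of the within-batch dispersions. Conditional posterior updates are iterated
to a max-absolute-change tolerance of 1e−4 (default, 200 iterations max;
non-convergence raises an error carrying the last iterate). Zero-variance
genes get a pooled-scale floor of 1e−8 and are reported, not dropped. With a
single batch the correction is the identity by definition. A cohort with
fewer than two genes falls back to a point prior (τ² = 0) and a flat
dispersion prior, since moments across genes are then undefined.

Because the default design is group-unbalanced across batches, raw per-gene
group-mean differences are *not* identical before and after correction —
removing batch offsets also removes batch-composition leakage from the raw
contrast. What is preserved is the fitted group effect: on simulated data
the planted ±1.5 log2 signal survives correction unchanged and no systematic
shift appears across null genes (tested).

Validation is dual-route: recovery of planted shifts against generator
truth, plus agreement (max abs difference < 1e−2, dominated by iteration
stopping rules) with an independent empirical-Bayes batch-correction
implementation, which is used only as a cross-check. The group covariate is
passed to the reference as numeric 0/1 because its categorical covariate
path builds a rank-deficient design.

## Consensus differential expression

The d-statistic follows the classic moderated form
d = (x̄_case − x̄_control)/(s + s₀), with s the pooled standard error of the
two group means. s₀ is selected from the percentiles {0, 5, …, 100} of the
s distribution by minimizing the coefficient of variation of
median-absolute-deviations of d across s-quantile windows (min(100, n/10)
windows); including percentile 0 guarantees the objective never worsens
relative to s₀ = 0. Permutations are group-label reassignments: all
C(n, n_case) distinct assignments are enumerated whenever they fit in the
budget B (default 200), making small designs seed-independent; otherwise B
assignments are sampled. Calling pairs ordered observed scores with expected
order statistics; Δ defaults to the smallest multiple of 0.05 with estimated
FDR ≤ 0.05. The estimator uses the median permuted exceedance count without
a π₀ correction, which is conservative (near-1 estimates on null data,
verified by test). Fold change is computed as 2^(difference of log2 means)
and filtered symmetrically, max(fc, 1/fc) ≥ 1.2, so down-regulation passes
on equal terms. Ties in the d-ranking are broken by gene id for determinism.

Virtual datasets: `mixed` mode (default) mirrors an 8-dataset design —
k − n_studies random plans plus one per-study plan holding each study's full
sample set. Random plan sizes are drawn uniformly from 5–11 controls and
7–16 cases, the observed per-study range of the reference design. Robustness
is support ≥ m (default 6 of 8) with all calling datasets agreeing on
direction; a direction conflict vetoes robustness regardless of support.
The m-of-k + direction-consistency rule is an interpretation — the
reference workflow reports a robust-signature count but not its exact
definition — and m is therefore a visible parameter, not a constant.

## Network analysis

Edge tables (2-column TSV or SIF, including multi-target SIF lines) are
unioned with per-edge source tags; self-loops are dropped and tallied.
"Direct and indirect interactions" is read as a one-hop induced expansion by
default (seeds, their neighbors, and all edges among them), with order 2 and
a star (non-induced) variant available, since the reported root/interactor
counts are consistent with a sparse first-neighbor expansion but the
construction is ambiguous. Cleaning removes self-loops and isolates and
keeps the largest connected component, breaking size ties toward the
component containing the lexicographically smallest node id; cleaning is
idempotent (tested).

The Steiner reduction is the metric-closure MST approximation (shortest-path
closure over terminals, MST, expansion, pruning of non-terminal leaves),
guaranteeing cost ≤ 2(1 − 1/t) × optimal for t terminals; the tests verify
the bound against exhaustive optima on small graphs. Edges are unweighted
and cost is the edge count, as no edge weights exist in the inputs. CC uses
the standard 2e_n/(k_n(k_n−1)) with the k_n < 2 convention CC = 0, which
keeps root ranking total. Ranking is by descending degree, then ascending
CC, then id — degree captures regulatory reach, and among equally connected
roots the one whose partners are mutually unconnected (a bottleneck) ranks
first.

## Enrichment, proteomics, survival

Fisher right tail is the hypergeometric upper tail P(X ≥ x), delegated to
the scipy survival function (log-space internally) and verified against
exact rational arithmetic to 1e−12. Benjamini–Hochberg adjustment is
reported alongside raw p because the reference workflow reports raw Fisher p
only; the universe defaults to all genes of the integrated matrix.

The paired t-test reports the difference as control − treated, so a negative
difference means up-regulation under treatment — the only reading consistent
with a negative difference being labeled "up" in the reference results.
Proteins with missing values in any pair are excluded (no imputation);
zero-variance differences yield p = 1 when the mean difference is zero and
the p → 0 limit otherwise, flagged as degenerate either way.

Median split assigns ties to the low group (high = strictly above the
median), a deterministic rule that keeps both groups non-empty for any
non-constant marker. The log-rank test uses the standard Mantel–Cox
hypergeometric variance with no additional tie correction; time points where
one group has no subjects at risk contribute nothing. Both the product-limit
curve and the log-rank statistic are cross-checked against an independent
survival-analysis library.

## Problem sizes and determinism

Default simulations are desk-scale: 2,000 genes, 64 samples, 8 virtual
datasets × 200 permutations, 2,000-node networks, 200 survival replicates —
sizes at which the full pipeline completes in a few seconds while leaving
every statistical behavior observable. Every generator and every stochastic
stage is a pure function of an explicit seed; the pipeline derives per-stage
seeds from a master seed, records them in the run manifest, and reproduces
all outputs byte for byte on rerun.

## Known limitations

- The non-parametric empirical-Bayes variant (no distributional priors) is
  not implemented; heavy-tailed batch effects are shrunk under normal /
  inverse-gamma assumptions regardless.
- The consensus caller supports two-class designs only (no multi-class or
  survival-mode scoring) and no local-FDR refinement.
- Network analysis stops at degree and clustering coefficient; betweenness
  or closeness centralities, which can change driver ranking, are out of
  scope.
- The Steiner reduction is an approximation; exact optima are used only as
  test oracles on small graphs.
- Survival analysis is two-group Kaplan–Meier / log-rank; no Cox regression
  or covariate adjustment.
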