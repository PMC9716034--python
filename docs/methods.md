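# Methods

This note documents the models behind each pipeline stage, the defaults
and why they were chosen, what the synthetic generator does and does not
emulate, and the numerical decisions that matter when reading results.

## Synthetic data model

Each disease cohort is simulated at gene-by-sample scale on a log2-like
intensity scale (baseline ~ N(7, 1); real microarray matrices are
usually analyzed after log2 transformation, and the pipeline assumes its
inputs are on that scale).  For gene *g*, sample *s*:

```
y[g,s] = baseline[g]
       + effect · sign(g) · 1[s case, g planted differential]
       + loading · f_m[s] · 1[g in module m]
       + coupling · f_imm[s] · 1[g shared immune differential]
       + γ[g, b(s)] + δ[g, b(s)] · ε[g,s]
```

with independent standard-normal module factors `f_m` and noise `ε`.

* **One-factor modules.** Each planted module shares a latent factor.
  The within-module Pearson correlation then has the closed form
  `r = loading² / (loading² + σ²)`, which the tests check by simulation.
  Default loading 2.0 with σ = 1 gives r = 0.8, comfortably above the
  0.7 edge threshold, so planted modules are discoverable by design.
* **Immune coupling.** The latent factor of one designated module is
  also added (loading 1.0) to the genes planted as immune differential
  genes in both diseases.  This makes the module–immune-eigengene
  correlation stage have a unique correct answer: the expected
  correlation between a coupled-module gene and a shared immune gene is
  `2·1/√(5·2) ≈ 0.63`, while uncoupled modules are independent of the
  immune set.
* **Differential genes.** 200 genes per disease receive a ±2σ case
  shift.  19 of them are shared between diseases, immune-listed, and
  same-direction (the planted key genes); 5 more are shared and
  immune-listed but opposite-direction, so the same-trend rule has
  something to reject.  Direction signs are random per gene.
* **Batches.** Each disease is assembled from two batches of unequal
  size (14+14 and 16+16 case+control; 30/30 per disease in total).  The
  second batch gets a per-gene additive offset ~ N(1, 0.5) and a
  multiplicative residual scale ~ LogNormal(0, 0.2) — exactly the
  location/scale model class ComBat assumes, so correction is testable
  against truth.
* **Mixtures.** A non-negative signature matrix (5 cell types × 40
  marker genes each by default; markers ~10× background) and Dirichlet
  fractions generate bulk mixtures `S·f + noise`.

What the generator does **not** emulate: probe-level artifacts,
platform-specific normalization, heavy-tailed noise, correlated noise
across modules, gene-length or GC biases, and realistic immune-gene
biology.  Passing tests therefore demonstrate algorithmic correctness
and recoverability under the stated model, not performance on any real
cohort.

## Batch correction

Parametric empirical-Bayes ComBat, the classic default.  Genes are
standardized using a design that contains batch indicators and — by
default — the case/control covariate, so group signal is protected
during standardization (`protect_group=False` reproduces the
covariate-free variant).  Batch location γ̂ and scale δ̂² per gene are
shrunk toward a normal and an inverse-gamma prior fitted by the method
of moments, via the standard iterative posterior solution (convergence
1e-4).  One batch in, identity out.  Batches with a single sample and
zero-variance genes are errors, not warnings.  The implementation is
cross-checked against sva::ComBat (R) to 2e-3 absolute on simulated
matrices.

A useful closed-form fact used in tests: when every gene carries the
same batch shift and the same residual distribution, the prior variance
of γ across genes collapses to zero and the EB posterior removes the
shift exactly; with gene-varying shifts shrinkage leaves a small,
prior-ward bias — that is expected EB behavior, not a defect.

## Moderated t

Two-group linear model per gene; pooled variance s² on d = n₁+n₂−2 df;
`(d₀, s₀²)` estimated by matching the mean and variance of log s² to the
scaled-F model via digamma/trigamma (Newton inversion of the trigamma
function).  When the observed spread of log-variances does not exceed
its sampling component, d₀ = ∞ and every gene uses the common
(arithmetic-mean) variance — in that limit the moderated t equals the
ordinary pooled t.  p-values come from t on d₀+d df (normal when
d₀ = ∞).  All-constant genes get p = 1 with a warning.  Agreement with
limma's eBayes is verified to ~1e-5 relative in the test suite.

DEG selection is a strict raw-p cut at 0.05 with no multiplicity
adjustment, matching common practice in two-cohort intersection designs
where the intersection itself filters false positives; a
Benjamini–Hochberg mode exists behind a flag.

## Network discovery

Correlation p-values use t = r√(n−2)/√(1−r²).  Both screening thresholds
are strict inequalities (|r| > 0.40 for relatedness to an immune DEG,
|r| > 0.70 for edges).  Immune DEGs are included as network nodes;
a flag can exclude them.  Correlation p-values are not adjusted.

Louvain is implemented from scratch: greedy local moving maximizing
weighted modularity at resolution 1, community aggregation, repeated to
convergence.  Three robustness choices beyond the textbook algorithm:

* a node whose stay-gain is negative may split into an empty community;
* after the aggregation phases converge, one node-level local-moving
  pass runs on the original graph seeded from the coarse partition,
  undoing unfavourable early merges;
* 10 seeded restarts (restart 0 from singletons, later restarts from
  random coarse partitions) keep the best-Q result.

With these, the returned partition matches exhaustive-search optima on
batteries of random ≤8-node graphs and recovers planted partitions
(4×50 nodes, p_in=0.3, p_out=0.01) at adjusted Rand index ≥ 0.9.  Tie
breaks take the first best-gain community in the shuffled visit order;
the seed is recorded in the output.  Module density is the unweighted
2E/(n(n−1)).

## Eigengenes and key-gene selection

A module eigengene is the first right singular vector of the z-scored
module submatrix (scores across samples), oriented to correlate
positively with the module's mean standardized profile; a singleton
immune set degenerates to that gene's standardized profile.  The key
module maximizes |r| against the immune eigengene — absolute rather
than signed correlation, so anti-correlated coupling is not missed
(`use_absolute=False` restores the signed rule).  Key genes are the
immune DEGs whose direction agrees across the two diseases.

## Diagnostics

One stratified 7:3 split (total train size = round(0.7·n), class quotas
by largest remainder) feeds all four families so AUCs are comparable.
The L1 logistic path uses a 100-point λ grid log-spaced four decades
below λ_max = max|X'(y−ȳ)|/n on standardized features, 10-fold
stratified CV, λ at minimum mean held-out binomial deviance, and maps
coefficients back to the expression scale.  The signature score is
reported without the intercept (the conventional printed form), with
the intercept available separately.  Random forests report both Gini
impurity-decrease and permutation-accuracy importances, because the two
measure different things; boosting reports gain.  The SVM defaults to
an RBF kernel on train-standardized inputs and feeds decision values to
the ROC.  AUC is computed by midranks — exactly the pair-counting
probability with ties at ½ — and is checked against an O(n²)
enumeration oracle.

Exact AUC values on synthetic data depend on the split seed; the seed
is therefore mandatory and logged in every evaluation object.

## Deconvolution

Per sample: restrict to signature genes present in the mixture (≥50%
required), z-score the signature globally and the sample vector, fit a
linear ν-SVR for each ν ∈ {0.25, 0.5, 0.75} (C = 1, tol 1e-4, capped
iterations — libsvm does not terminate reliably at tighter tolerances
on noiseless systems), keep the ν with the smallest reconstruction
RMSE, clip negative coefficients, renormalize to the simplex.  Samples
with no positive coefficient are flagged failures (zero rows).
Quantile normalization of mixtures is available but off by default, as
is a permutation p-value per sample.  The Wilcoxon group test is the
rank-sum form: exact p by a dynamic-programming enumeration of rank-sum
counts when both groups have ≤10 tie-free observations, otherwise the
tie- and continuity-corrected normal approximation (agreeing with
scipy's asymptotic branch to 1e-9).

## Problem sizes and defaults

Defaults are sized so the full pipeline on one disease pair (2,000
genes, 60+60 samples) runs in seconds and the complete test suite plus
acceptance script in a few minutes on one CPU: recovery-rate loops use
30–100 generator seeds, the key-module rate uses 800-gene studies, and
the null-calibration matrix is 2,000 × 20.  These sizes are choices of
the package, stated here so they can be scaled up when more compute is
available.

## Known limitations

* ComBat and the moderated t assume roughly Gaussian residuals; heavy
  tails will mis-calibrate both.
* The DEG screen (raw p < 0.05) feeds correlated genes to the network
  stage; modules whose latent factor happens to be imbalanced between
  groups can enter the network as a block.  This mirrors what happens
  on real data with correlated expression programs.
* ν-SVR deconvolution assumes the mixture is (approximately) a
  non-negative linear combination of the signature profiles after
  standardization; unmodeled cell types bias fractions toward their
  nearest modeled neighbors.
* The Louvain restarts make small-graph optima reliable but carry no
  global-optimality guarantee on large graphs — none exists for
  modularity maximization.
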