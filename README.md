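# idegnet

Cross-disease discovery of immune gene modules and diagnostic signatures
from bulk transcriptomes.

## The problem

Two clinically linked diseases — the motivating setting is ankylosing
spondylitis (AS) and low bone mineral density (LBMD) — are profiled as
separate case/control microarray cohorts, each assembled from two batches.
The question is which immune-related genes are dysregulated in *both*
diseases, how they organize into co-expressed modules, and whether the
shared genes carry diagnostic information.  `idegnet` implements that
analysis as a tested, reusable pipeline:

1. **Merge & batch-correct** — same-disease datasets are intersected on
   common genes and corrected with parametric empirical-Bayes
   location/scale adjustment (ComBat):
   `y_gbs = α_g + x_s'β_g + γ_gb + δ_gb ε_gbs`, with γ and δ² shrunk
   toward normal / inverse-gamma priors.
2. **Differential expression** — per-gene moderated t:
   `s̃²_g = (d₀s₀² + d s²_g)/(d₀ + d)`, `t̃_g = logFC_g / (s̃_g √(1/n₁+1/n₂))`
   on `d₀+d` degrees of freedom, with `(d₀, s₀²)` from moment matching on
   `log s²`.  DEGs are genes at raw `p < 0.05`.
3. **I-DEGs and key genes** — DEGs of both diseases intersected with an
   immune-related gene list (ImmPort-style) give the I-DEGs; those with
   the same up/down trend in both diseases are the key genes.
4. **Network & communities** — DEGs with an I-DEG partner at `|r| > 0.40`
   (`p < 0.05`) form the node pool; edges require `|r| > 0.70` with
   weight `|r|`.  Weighted Louvain maximizes
   `Q = Σ_c [Σ_in/2m − (Σ_tot/2m)²]`; modules under 30 genes are dropped
   and densities `2E/(n(n−1))` tabulated.
5. **Key module** — each module is summarized by its eigengene (first
   principal component of the standardized module expression); the
   I-DEG set is the "immune module" and the module whose eigengene best
   correlates with the immune eigengene is the key module.
6. **Diagnostics** — the key-gene signature is evaluated on a shared
   stratified 7:3 split by L1-penalized logistic regression (λ at
   minimum cross-validated deviance), random forest, gradient boosting
   and an RBF SVM; AUC is the Mann–Whitney pair-counting probability.
7. **Immune infiltration** — bulk mixtures are deconvolved into cell-type
   fractions by linear ν-SVR against a signature matrix (CIBERSORT
   scheme, ν ∈ {0.25, 0.5, 0.75}, non-negative simplex projection), with
   Wilcoxon rank-sum group tests and gene–cell correlations.

A synthetic-data generator (`idegnet.synthetic`) plants all of this
structure — differential genes overlapping a designated immune list,
one-factor gene modules with an immune-coupled module, two unequal
batches per disease, Dirichlet cell-type mixtures — so every stage is
testable against known ground truth without any downloads.

## Worked example

The numbered scripts under `analysis/` run the whole study on synthetic
data (later scripts read the outputs of earlier ones):

```bash
python analysis/01_simulate.py --seed 1
python analysis/02_preprocess.py
python analysis/03_differential_expression.py
python analysis/04_network_modules.py --seed 1
python analysis/05_diagnostics.py --seed 1
python analysis/06_immune_infiltration.py --seed 1
```

With seed 1 this prints, among other things:

```
disease1: batch variance fraction 0.193 -> 0.006
disease1: 145 up / 128 down DEGs
I-DEGs: 25; same-trend key genes: 19
disease1: 202 related genes, 238 edges, Q=0.670, key module M1
disease1 AUC: LASSO=1.000, RF=1.000, XGBoost=1.000, SVM=1.000
mean absolute fraction error vs truth: 0.0307
marker genes matched to their own cell type: 5/5
```

Reading: ComBat removed nearly all between-batch variance (19.3% → 0.6%
of per-gene variance); the moderated t recovered the planted
differential genes; exactly the 19 planted same-trend immune genes
survive the three-way intersection and same-trend rule; the
co-expression network clusters into a module whose eigengene tracks the
immune module; the 19-gene signature separates cases from controls
perfectly on this synthetic effect size; and deconvolution recovers the
known mixing fractions to ~0.03 mean absolute error.  Small summary
tables land in `results/`, full matrices in `scratch/data/`.

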