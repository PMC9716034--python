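"""Dataset merging, empirical-Bayes batch correction and PCA embedding.

Same-disease datasets are merged on their common genes; batch effects are
then removed with parametric empirical-Bayes location/scale adjustment
(ComBat).  Per gene g, batch b the model is

    y_gbs = alpha_g + x_s' beta_g + gamma_gb + delta_gb * eps_gbs

with eps ~ N(0, sigma_g^2).  Genes are standardized by the grand mean and
pooled variance (the case/control covariate is part of the standardization
design by default so biological signal is protected), batch location and
scale estimates are shrunk toward normal / inverse-gamma priors fitted by
the method of moments, then data are adjusted and back-transformed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .study import GROUP_CASE, ExpressionStudy


def intersect_and_merge(studies: list[ExpressionStudy]) -> ExpressionStudy:
    """Merge same-disease studies on the sorted intersection of their genes.

    Columns are the concatenated samples; each sample's batch id is the
    index of its source study unless the source already carries distinct
    batch labels.  Values are copied unchanged.
    """
    if len(studies) < 2:
        raise ValueError("need at least two studies to merge")
    common = set(studies[0].genes)
    for st in studies[1:]:
        common &= set(st.genes)
    if not common:
        raise ValueError("gene intersection across studies is empty")
    genes = sorted(common)

    all_samples: list[str] = []
    for st in studies:
        all_samples.extend(st.samples)
    if len(all_samples) != len(set(all_samples)):
        raise ValueError("duplicate sample ids across studies")

    exprs, phenos = [], []
    for i, st in enumerate(studies, start=1):
        exprs.append(st.expr.loc[genes])
        ph = st.pheno.copy()
        if len(set(ph["batch"])) == 1 and len(studies) > 1:
            ph = ph.assign(batch=f"batch{i}")
        phenos.append(ph)
    expr = pd.concat(exprs, axis=1)
    pheno = pd.concat(phenos, axis=0)
    return ExpressionStudy(expr, pheno)


@dataclass
class BatchModel:
    """Fitted ComBat parameters, JSON-serializable via ``to_dict``."""

    batches: list[str]
    gamma_star: pd.DataFrame      # genes x batches, shrunken location effects
    delta2_star: pd.DataFrame     # genes x batches, shrunken scale effects (>0)
    gamma_bar: dict[str, float]   # normal-prior means per batch
    tau2: dict[str, float]        # normal-prior variances per batch
    a_prior: dict[str, float]     # inverse-gamma shape per batch
    b_prior: dict[str, float]     # inverse-gamma scale per batch

    def to_dict(self) -> dict:
        return {
            "batches": self.batches,
            "gamma_star": self.gamma_star.to_dict(orient="list"),
            "delta2_star": self.delta2_star.to_dict(orient="list"),
            "gamma_bar": self.gamma_bar,
            "tau2": self.tau2,
            "a_prior": self.a_prior,
            "b_prior": self.b_prior,
        }


def _aprior(delta_hat: np.ndarray) -> float:
    m, s2 = delta_hat.mean(), delta_hat.var(ddof=1)
    return (2 * s2 + m**2) / s2


def _bprior(delta_hat: np.ndarray) -> float:
    m, s2 = delta_hat.mean(), delta_hat.var(ddof=1)
    return (m * s2 + m**3) / s2


def _postmean(g_hat, g_bar, n, d_star, t2):
    return (t2 * n * g_hat + d_star * g_bar) / (t2 * n + d_star)


def _postvar(sum2, n, a, b):
    return (0.5 * sum2 + b) / (n / 2.0 + a - 1.0)


def _it_sol(z_batch, g_hat, d_hat, g_bar, t2, a, b, conv=1e-4, max_iter=500):
    """Iterative EB solution for one batch (vectorized over genes)."""
    n = z_batch.shape[1]
    g_old, d_old = g_hat.copy(), d_hat.copy()
    for _ in range(max_iter):
        g_new = _postmean(g_hat, g_bar, n, d_old, t2)
        sum2 = ((z_batch - g_new[:, None]) ** 2).sum(axis=1)
        d_new = _postvar(sum2, n, a, b)
        change = max(
            np.abs(g_new - g_old).max() / np.maximum(np.abs(g_old), 1e-12).max(),
            np.abs(d_new - d_old).max() / np.maximum(np.abs(d_old), 1e-12).max(),
        )
        g_old, d_old = g_new, d_new
        if change < conv:
            break
    return g_old, d_old


def combat(
    study: ExpressionStudy, protect_group: bool = True
) -> tuple[ExpressionStudy, BatchModel]:
    """Parametric empirical-Bayes batch correction.

    With a single batch the input is returned unchanged (gamma = 0,
    delta^2 = 1).  A batch containing one sample or a zero-variance gene
    raises ``ValueError``.
    """
    batches = list(pd.unique(study.batches))
    y = study.values()
    n_genes, n_samples = y.shape

    if len(batches) == 1:
        ident = BatchModel(
            batches=[str(batches[0])],
            gamma_star=pd.DataFrame(0.0, index=study.genes, columns=[str(batches[0])]),
            delta2_star=pd.DataFrame(1.0, index=study.genes, columns=[str(batches[0])]),
            gamma_bar={str(batches[0]): 0.0}, tau2={str(batches[0]): 0.0},
            a_prior={str(batches[0]): 0.0}, b_prior={str(batches[0]): 0.0},
        )
        return ExpressionStudy(study.expr.copy(), study.pheno.copy(),
                               study.disease), ident

    batch_masks = {b: (study.batches == b).to_numpy() for b in batches}
    for b, mask in batch_masks.items():
        if mask.sum() < 2:
            raise ValueError(f"batch {b!r} has fewer than 2 samples")

    # design: batch indicators + (optionally) the case/control covariate
    design_cols = [batch_masks[b].astype(float) for b in batches]
    if protect_group:
        design_cols.append(study.case_mask().astype(float))
    design = np.column_stack(design_cols)

    beta, *_ = np.linalg.lstsq(design, y.T, rcond=None)  # (p, genes)
    n_batch = np.array([batch_masks[b].sum() for b in batches], dtype=float)
    grand_mean = (n_batch / n_samples) @ beta[: len(batches)]
    resid = y - (design @ beta).T
    var_pooled = (resid**2).mean(axis=1)
    degenerate = var_pooled <= 1e-12
    if np.any(degenerate):
        bad = list(study.genes[degenerate])
        raise ValueError(f"zero-variance genes: {bad[:10]}")

    stand_mean = np.tile(grand_mean[:, None], (1, n_samples))
    if protect_group:
        stand_mean = stand_mean + np.outer(beta[-1], study.case_mask().astype(float))
    z = (y - stand_mean) / np.sqrt(var_pooled)[:, None]

    gamma_hat = np.column_stack([z[:, batch_masks[b]].mean(axis=1) for b in batches])
    delta_hat = np.column_stack(
        [z[:, batch_masks[b]].var(axis=1, ddof=1) for b in batches]
    )

    gamma_star = np.empty_like(gamma_hat)
    delta2_star = np.empty_like(delta_hat)
    g_bar, t2, a_pr, b_pr = {}, {}, {}, {}
    for j, b in enumerate(batches):
        gb = float(gamma_hat[:, j].mean())
        tj = float(gamma_hat[:, j].var(ddof=1))
        aj = float(_aprior(delta_hat[:, j]))
        bj = float(_bprior(delta_hat[:, j]))
        g_bar[str(b)], t2[str(b)], a_pr[str(b)], b_pr[str(b)] = gb, tj, aj, bj
        g_star, d_star = _it_sol(
            z[:, batch_masks[b]], gamma_hat[:, j], delta_hat[:, j], gb, tj, aj, bj
        )
        gamma_star[:, j] = g_star
        delta2_star[:, j] = np.maximum(d_star, 1e-12)

    adjusted = z.copy()
    for j, b in enumerate(batches):
        cols = batch_masks[b]
        adjusted[:, cols] = (z[:, cols] - gamma_star[:, j][:, None]) / np.sqrt(
            delta2_star[:, j]
        )[:, None]
    corrected = adjusted * np.sqrt(var_pooled)[:, None] + stand_mean

    model = BatchModel(
        batches=[str(b) for b in batches],
        gamma_star=pd.DataFrame(gamma_star, index=study.genes,
                                columns=[str(b) for b in batches]),
        delta2_star=pd.DataFrame(delta2_star, index=study.genes,
                                 columns=[str(b) for b in batches]),
        gamma_bar=g_bar, tau2=t2, a_prior=a_pr, b_prior=b_pr,
    )
    out = ExpressionStudy(
        pd.DataFrame(corrected, index=study.genes, columns=study.samples),
        study.pheno.copy(), study.disease,
    )
    return out, model


def pca_embed(study: ExpressionStudy, k: int = 2) -> pd.DataFrame:
    """Top-k principal-component sample coordinates (gene-centered, unscaled).

    Returns a DataFrame indexed by sample with columns ``PC1..PCk`` plus a
    ``explained`` attribute-style column set in ``.attrs['explained']``.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > min(study.expr.shape):
        raise ValueError("k exceeds matrix rank bound")
    y = study.values()
    centered = y - y.mean(axis=1, keepdims=True)
    # samples are observations: SVD of the samples x genes matrix
    u, s, vt = np.linalg.svd(centered.T, full_matrices=False)
    coords = u[:, :k] * s[:k]
    total = float((s**2).sum())
    explained = (s[:k] ** 2) / total if total > 0 else np.zeros(k)
    out = pd.DataFrame(
        coords, index=study.samples, columns=[f"PC{i + 1}" for i in range(k)]
    )
    out.attrs["explained"] = explained
    return out


def collapse_duplicate_genes(expr: pd.DataFrame) -> pd.DataFrame:
    """Collapse duplicated gene ids by keeping the max-mean row per id."""
    if expr.index.is_unique:
        return expr
    means = expr.mean(axis=1)
    order = np.argsort(-means.to_numpy(), kind="stable")
    dedup = expr.iloc[order]
    dedup = dedup[~dedup.index.duplicated(keep="first")]
    return dedup.sort_index()


def batch_variance_fraction(study: ExpressionStudy) -> float:
    """Mean per-gene fraction of variance attributable to batch means.

    Used to quantify how much batch structure remains before/after
    correction; warns and returns NaN when a gene has zero variance.
    """
    y = study.values()
    batches = list(pd.unique(study.batches))
    total = y.var(axis=1)
    if np.any(total <= 0):
        warnings.warn("zero-variance genes excluded from batch-variance fraction")
    between = np.zeros_like(total)
    grand = y.mean(axis=1)
    for b in batches:
        mask = (study.batches == b).to_numpy()
        between += mask.sum() * (y[:, mask].mean(axis=1) - grand) ** 2
    between /= y.shape[1]
    ok = total > 0
    return float((between[ok] / total[ok]).mean())
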