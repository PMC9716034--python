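"""Signature-based immune-cell deconvolution and group comparison.

Bulk mixtures are decomposed into cell-type fractions by nu-support-
vector regression against a signature matrix (the CIBERSORT scheme):
per sample, both sides are restricted to the common signature genes and
z-scored, a linear nu-SVR is fit for each candidate nu in {0.25, 0.5,
0.75}, the nu with the smallest root-mean-square reconstruction error
wins, negative coefficients are clipped to zero and the rest renormalized
to the simplex.  Cell-type fractions are compared between case and
control with a two-sided Wilcoxon rank-sum test (exact enumeration for
small tie-free groups, tie- and continuity-corrected normal
approximation otherwise).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.svm import NuSVR

from .network import correlation_p
from .study import GROUP_CASE, ExpressionStudy


@dataclass
class DeconvConfig:
    nu_grid: tuple[float, ...] = (0.25, 0.5, 0.75)
    min_gene_overlap: float = 0.5    # required fraction of signature genes
    quantile_normalize: bool = False
    permutations: int = 0            # optional empirical p per sample


@dataclass
class DeconvolutionResult:
    fractions: pd.DataFrame          # samples x cell types, rows on the simplex
    diagnostics: pd.DataFrame        # per sample: best_nu, rmse, corr, failed
    perm_p: pd.Series | None = None


def _quantile_normalize(mat: np.ndarray) -> np.ndarray:
    ranks = np.argsort(np.argsort(mat, axis=0), axis=0)
    means = np.sort(mat, axis=0).mean(axis=1)
    return means[ranks]


def deconvolve(mixture: pd.DataFrame, signature: pd.DataFrame,
               config: DeconvConfig | None = None,
               seed: int = 0) -> DeconvolutionResult:
    """nu-SVR fraction estimation for every mixture column.

    ``mixture`` is genes × samples; ``signature`` genes × cell types.
    Raises if fewer than half the signature genes are present or the
    signature is rank deficient.  A sample whose coefficients are all
    non-positive is flagged as failed with a zero row.
    """
    cfg = config or DeconvConfig()
    if signature.shape[1] < 2:
        raise ValueError("need at least 2 cell types")
    common = [g for g in signature.index if g in mixture.index]
    if len(common) < cfg.min_gene_overlap * signature.shape[0]:
        raise ValueError(
            f"only {len(common)}/{signature.shape[0]} signature genes in mixture"
        )
    sig = signature.loc[common].to_numpy(dtype=float)
    if np.linalg.matrix_rank(sig) < sig.shape[1]:
        raise ValueError("signature matrix is rank deficient")
    mix = mixture.loc[common].to_numpy(dtype=float)
    if cfg.quantile_normalize:
        mix = _quantile_normalize(mix)

    # CIBERSORT standardization: signature z-scored as one block
    x = (sig - sig.mean()) / sig.std()

    cells = list(signature.columns)
    samples = list(mixture.columns)
    frac = np.zeros((len(samples), len(cells)))
    diag_rows = []
    rng = np.random.default_rng(seed)
    perm_p = []

    for s_idx, sample in enumerate(samples):
        y_raw = mix[:, s_idx]
        y = (y_raw - y_raw.mean()) / (y_raw.std() or 1.0)
        best = None
        for nu in cfg.nu_grid:
            model = NuSVR(nu=nu, C=1.0, kernel="linear", tol=1e-4,
                          max_iter=100_000)
            model.fit(x, y)
            coef = model.coef_.ravel()
            pred = x @ coef + model.intercept_
            rmse = float(np.sqrt(np.mean((pred - y) ** 2)))
            if best is None or rmse < best[1]:
                best = (nu, rmse, coef, pred)
        nu, rmse, coef, pred = best
        corr = float(np.corrcoef(pred, y)[0, 1]) if y.std() > 0 else 0.0
        w = np.clip(coef, 0.0, None)
        failed = w.sum() <= 0
        if not failed:
            frac[s_idx] = w / w.sum()
        diag_rows.append((nu, rmse, corr, failed))

        if cfg.permutations > 0:
            null = np.empty(cfg.permutations)
            for b in range(cfg.permutations):
                null[b] = np.corrcoef(x @ coef, rng.permutation(y))[0, 1]
            perm_p.append(float((np.sum(null >= corr) + 1) /
                                (cfg.permutations + 1)))

    fractions = pd.DataFrame(frac, index=samples, columns=cells)
    diagnostics = pd.DataFrame(
        diag_rows, index=samples, columns=["best_nu", "rmse", "corr", "failed"]
    )
    pp = pd.Series(perm_p, index=samples) if perm_p else None
    return DeconvolutionResult(fractions=fractions, diagnostics=diagnostics,
                               perm_p=pp)


# ---------------------------------------------------------------------------
# Wilcoxon rank-sum group comparison
# ---------------------------------------------------------------------------

def _exact_ranksum_p(w: float, n1: int, n2: int) -> float:
    """Two-sided exact p for the rank-sum W of group 1 (no ties).

    Dynamic programme over the count of size-k subsets of ranks 1..n with
    each attainable sum; symmetric two-sided rule |W - mu| >= |w - mu|.
    """
    n = n1 + n2
    max_sum = n * (n + 1) // 2
    # counts[k][s] = number of k-subsets of {1..r} summing to s
    counts = np.zeros((n1 + 1, max_sum + 1))
    counts[0, 0] = 1.0
    for r in range(1, n + 1):
        for k in range(min(r, n1), 0, -1):
            counts[k, r:] += counts[k - 1, :-r] if r > 0 else counts[k - 1]
    dist = counts[n1]
    total = dist.sum()
    mu = n1 * (n + 1) / 2.0
    dev = abs(w - mu)
    sums = np.arange(max_sum + 1)
    p = dist[np.abs(sums - mu) >= dev - 1e-9].sum() / total
    return float(min(1.0, p))


def ranksum_test(a, b, exact_max: int = 10) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum test; returns (W, p).

    W is the rank-sum of the first group.  Exact enumeration when both
    groups have at most ``exact_max`` observations and there are no ties;
    otherwise a normal approximation with tie and continuity corrections.
    Identical constant samples give p = 1.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    n1, n2 = len(a), len(b)
    if n1 < 2 or n2 < 2:
        raise ValueError("both groups need at least 2 observations")
    pooled = np.concatenate([a, b])
    ranks = stats.rankdata(pooled)
    w = float(ranks[:n1].sum())
    _, tie_counts = np.unique(pooled, return_counts=True)
    has_ties = np.any(tie_counts > 1)

    if np.ptp(pooled) == 0:
        return w, 1.0
    if not has_ties and n1 <= exact_max and n2 <= exact_max:
        return w, _exact_ranksum_p(w, n1, n2)

    n = n1 + n2
    mu = n1 * (n + 1) / 2.0
    tie_term = float(((tie_counts**3 - tie_counts).sum()) / (n * (n - 1)))
    sigma2 = n1 * n2 / 12.0 * ((n + 1) - tie_term)
    if sigma2 <= 0:
        return w, 1.0
    z = (abs(w - mu) - 0.5) / np.sqrt(sigma2)
    return w, float(min(1.0, 2.0 * stats.norm.sf(max(z, 0.0))))


def significance_stars(p: float) -> str:
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def compare_groups(fractions: pd.DataFrame, groups: pd.Series) -> pd.DataFrame:
    """Per-cell-type two-sided rank-sum test of case vs control fractions."""
    groups = groups.loc[fractions.index]
    case = fractions.loc[groups == GROUP_CASE]
    control = fractions.loc[groups != GROUP_CASE]
    rows = []
    for cell in fractions.columns:
        w, p = ranksum_test(case[cell].to_numpy(), control[cell].to_numpy())
        rows.append((cell, w, p, significance_stars(p)))
    return pd.DataFrame(rows, columns=["cell_type", "W", "p", "stars"]
                        ).set_index("cell_type")


def cell_gene_correlation(fractions: pd.DataFrame, study: ExpressionStudy,
                          genes) -> dict[str, pd.DataFrame]:
    """Pearson r/p for (cell, gene) and (cell, cell) pairs on shared samples."""
    shared = [s for s in fractions.index if s in study.samples]
    if len(shared) < 3:
        raise ValueError("need at least 3 shared samples")
    genes = [g for g in genes if g in study.genes]
    expr = study.expr.loc[genes, shared].to_numpy(dtype=float)
    frac = fractions.loc[shared].to_numpy(dtype=float).T
    n = len(shared)

    def block(xa, names_a, xb, names_b):
        za = xa - xa.mean(axis=1, keepdims=True)
        zb = xb - xb.mean(axis=1, keepdims=True)
        sa = np.sqrt((za**2).sum(axis=1))
        sb = np.sqrt((zb**2).sum(axis=1))
        with np.errstate(divide="ignore", invalid="ignore"):
            r = np.clip((za @ zb.T) / np.outer(sa, sb), -1, 1)
        r = np.nan_to_num(r, nan=0.0)
        return (pd.DataFrame(r, index=names_a, columns=names_b),
                pd.DataFrame(correlation_p(r, n), index=names_a,
                             columns=names_b))

    cg_r, cg_p = block(frac, list(fractions.columns), expr, genes)
    cc_r, cc_p = block(frac, list(fractions.columns), frac,
                       list(fractions.columns))
    np.fill_diagonal(cc_r.values, 1.0)
    np.fill_diagonal(cc_p.values, 0.0)
    return {"cell_gene_r": cg_r, "cell_gene_p": cg_p,
            "cell_cell_r": cc_r, "cell_cell_p": cc_p}
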