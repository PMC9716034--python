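"""Immune-DEG identification, module eigengenes and key-module selection.

The immune DEGs (I-DEGs) are the genes differential in both diseases and
present on the immune-related gene list.  Each discovered module is
summarized by its eigengene — the first principal component of the
module's per-gene standardized expression across samples — and the
I-DEG set itself is treated as one "immune module".  The discovered
module whose eigengene correlates most strongly (max |r| by default)
with the immune eigengene is the key module.  I-DEGs whose up/down
direction agrees in both diseases are the key I-DEGs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .network import correlation_p
from .study import ExpressionStudy


def intersect_idegs(degs_d1: pd.DataFrame, degs_d2: pd.DataFrame,
                    irg_list) -> pd.DataFrame:
    """Genes differential in both diseases and on the immune gene list.

    ``degs_d*`` are select_degs tables (gene-indexed with a ``direction``
    column).  Symbols are upper-cased before matching.  Returns a table
    indexed by gene with ``direction_d1`` / ``direction_d2`` columns.
    """
    def norm(idx) -> pd.Index:
        return pd.Index([str(g).upper() for g in idx])

    d1 = degs_d1.copy()
    d1.index = norm(d1.index)
    d2 = degs_d2.copy()
    d2.index = norm(d2.index)
    irgs = {str(g).upper() for g in irg_list}
    common = sorted(set(d1.index) & set(d2.index) & irgs)
    if not common:
        warnings.warn("no I-DEGs: empty three-way intersection")
    return pd.DataFrame(
        {
            "direction_d1": d1.loc[common, "direction"],
            "direction_d2": d2.loc[common, "direction"],
        },
        index=pd.Index(common, name="gene"),
    )


@dataclass
class Eigengene:
    module: str
    scores: pd.Series            # sample-length summary vector
    explained: float             # fraction of variance carried by PC1
    flipped: bool                # True if the raw PC1 sign was inverted


def module_eigengene(study: ExpressionStudy, genes, module_id: str = "module"
                     ) -> Eigengene:
    """First principal component of the module's standardized expression.

    Genes are z-scored, the first right-singular vector across samples is
    the eigengene, oriented to correlate positively with the module's
    mean standardized profile.  Constant genes are dropped with a warning.
    """
    genes = [g for g in genes if g in study.genes]
    if len(genes) < 2:
        raise ValueError("module needs at least 2 genes present in the study")
    if len(study.samples) < 3:
        raise ValueError("need at least 3 samples")
    x = study.expr.loc[genes].to_numpy(dtype=float)
    sd = x.std(axis=1)
    if np.any(sd == 0):
        warnings.warn("constant genes dropped from module eigengene")
        x = x[sd > 0]
        if x.shape[0] < 2:
            raise ValueError("fewer than 2 variable genes in module")
        sd = sd[sd > 0]
    z = (x - x.mean(axis=1, keepdims=True)) / sd[:, None]

    u, s, vt = np.linalg.svd(z, full_matrices=False)
    scores = vt[0]
    explained = float(s[0] ** 2 / (s**2).sum())

    mean_profile = z.mean(axis=0)
    flip = float(np.dot(scores, mean_profile)) < 0
    if flip:
        scores = -scores
    return Eigengene(
        module=module_id,
        scores=pd.Series(scores, index=study.samples, name=module_id),
        explained=explained,
        flipped=bool(flip),
    )


def immune_module_eigengene(study: ExpressionStudy, ideg_genes) -> Eigengene:
    """Eigengene of the I-DEG set treated as a single immune module.

    A singleton I-DEG set degenerates to that gene's standardized profile.
    """
    genes = [g for g in ideg_genes if g in study.genes]
    if len(genes) == 1:
        x = study.expr.loc[genes[0]].to_numpy(dtype=float)
        sd = x.std()
        if sd == 0:
            raise ValueError("single immune gene is constant")
        z = (x - x.mean()) / sd / np.sqrt(len(x))
        return Eigengene("immune", pd.Series(z, index=study.samples,
                                             name="immune"), 1.0, False)
    return module_eigengene(study, genes, module_id="immune")


def module_immune_correlation(
    module_mes: dict[str, Eigengene], immune_me: Eigengene,
    use_absolute: bool = True,
) -> tuple[pd.DataFrame, str]:
    """Pearson r (and p) of every module eigengene against the immune one.

    Returns the full correlation table plus the key-module id: the module
    maximizing |r| (or signed r with ``use_absolute=False``).
    """
    imm = immune_me.scores
    n = len(imm)
    if n < 3:
        raise ValueError("need at least 3 samples for module correlation")
    rows = []
    for mid, me in module_mes.items():
        if not me.scores.index.equals(imm.index):
            raise ValueError(f"sample order mismatch for module {mid}")
        r = float(np.corrcoef(me.scores, imm)[0, 1])
        rows.append((mid, r, float(correlation_p(np.array(r), n))))
    tab = pd.DataFrame(rows, columns=["module", "r", "p"]).set_index("module")
    crit = tab["r"].abs() if use_absolute else tab["r"]
    key = str(crit.idxmax())
    return tab, key


@dataclass
class KeyIdegSet:
    table: pd.DataFrame          # gene-indexed: direction_d1/d2, same_trend
    key_genes: list[str]

    def directions(self) -> dict[str, str]:
        sub = self.table.loc[self.key_genes]
        return dict(zip(sub.index, sub["direction_d1"]))


def key_idegs(ideg_table: pd.DataFrame) -> KeyIdegSet:
    """I-DEGs with the same expression trend in both diseases.

    ``ideg_table`` comes from :func:`intersect_idegs`.  Idempotent; the
    key list is always a subset of the input genes.
    """
    tab = ideg_table.copy()
    tab["same_trend"] = tab["direction_d1"] == tab["direction_d2"]
    key = sorted(tab.index[tab["same_trend"]])
    return KeyIdegSet(table=tab, key_genes=key)
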