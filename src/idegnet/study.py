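"""Core expression-study container and plain-text I/O.

An :class:`ExpressionStudy` couples a gene-by-sample expression matrix
(log2-scale values, genes as rows) with per-sample phenotype annotation:
case/control group, batch of origin and a disease tag.  All pipeline
stages consume and produce this container.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

GROUP_CASE = "case"
GROUP_CONTROL = "control"

PHENO_COLUMNS = ("sample", "group", "batch", "disease")


@dataclass
class ExpressionStudy:
    """Gene × sample expression matrix with sample annotation.

    Parameters
    ----------
    expr
        DataFrame of shape (genes, samples); index = unique gene ids,
        columns = unique sample ids.  Values are real (log2-like scale).
    pheno
        DataFrame indexed by sample id with columns ``group``
        (``"case"``/``"control"``), ``batch`` and ``disease``.
    """

    expr: pd.DataFrame
    pheno: pd.DataFrame
    disease: str = field(default="")

    def __post_init__(self) -> None:
        if not self.expr.index.is_unique:
            raise ValueError("gene ids must be unique")
        if not self.expr.columns.is_unique:
            raise ValueError("sample ids must be unique")
        missing = set(self.expr.columns) - set(self.pheno.index)
        if missing:
            raise ValueError(f"samples lack phenotype rows: {sorted(missing)[:5]}")
        self.pheno = self.pheno.loc[self.expr.columns]
        bad = set(self.pheno["group"]) - {GROUP_CASE, GROUP_CONTROL}
        if bad:
            raise ValueError(f"unknown group labels: {sorted(bad)}")
        if self.expr.isna().any().any():
            raise ValueError("expression matrix contains missing values")
        if not self.disease:
            tags = self.pheno["disease"].unique()
            self.disease = str(tags[0]) if len(tags) == 1 else "mixed"

    # -- convenience accessors -------------------------------------------------
    @property
    def genes(self) -> pd.Index:
        return self.expr.index

    @property
    def samples(self) -> pd.Index:
        return self.expr.columns

    @property
    def groups(self) -> pd.Series:
        return self.pheno["group"]

    @property
    def batches(self) -> pd.Series:
        return self.pheno["batch"]

    def case_mask(self) -> np.ndarray:
        return (self.groups == GROUP_CASE).to_numpy()

    def subset_genes(self, genes) -> "ExpressionStudy":
        genes = [g for g in genes if g in self.expr.index]
        return ExpressionStudy(self.expr.loc[genes], self.pheno.copy(), self.disease)

    def values(self) -> np.ndarray:
        return self.expr.to_numpy(dtype=float)


# ---------------------------------------------------------------------------
# Plain-text readers / writers (TSV, gene-list TXT)
# ---------------------------------------------------------------------------

def write_study(study: ExpressionStudy, expr_path, pheno_path) -> None:
    """Write expression TSV (genes as rows) and phenotype TSV."""
    study.expr.to_csv(expr_path, sep="\t", index_label="gene")
    pheno = study.pheno.reset_index(names="sample")
    pheno[list(PHENO_COLUMNS)].to_csv(pheno_path, sep="\t", index=False)


def read_study(expr_path, pheno_path) -> ExpressionStudy:
    expr = pd.read_csv(expr_path, sep="\t", index_col=0)
    pheno = pd.read_csv(pheno_path, sep="\t").set_index("sample")
    return ExpressionStudy(expr, pheno)


def write_gene_list(genes, path) -> None:
    Path(path).write_text("\n".join(str(g) for g in genes) + "\n")


def read_gene_list(path) -> list[str]:
    """One gene symbol per line (ImmPort-style list); blank lines ignored."""
    return [ln.strip() for ln in Path(path).read_text().splitlines() if ln.strip()]


def read_signature_matrix(path) -> pd.DataFrame:
    """LM22-dialect signature TSV: first column gene symbol, header cell types."""
    sig = pd.read_csv(path, sep="\t", index_col=0)
    if sig.shape[1] < 2:
        raise ValueError("signature matrix needs at least 2 cell-type columns")
    return sig
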