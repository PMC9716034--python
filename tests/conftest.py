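import numpy as np
import pandas as pd
import pytest

from idegnet import StudyConfig, generate_study
from idegnet.study import ExpressionStudy


def make_study(values, groups, batches=None, genes=None, disease="d1"):
    """Small hand-built ExpressionStudy for unit tests."""
    values = np.asarray(values, dtype=float)
    n_genes, n_samples = values.shape
    genes = genes or [f"g{i + 1}" for i in range(n_genes)]
    samples = [f"s{i + 1}" for i in range(n_samples)]
    batches = batches or ["b1"] * n_samples
    pheno = pd.DataFrame(
        {"group": groups, "batch": batches, "disease": disease}, index=samples
    )
    expr = pd.DataFrame(values, index=genes, columns=samples)
    return ExpressionStudy(expr, pheno, disease)


def two_group_study(rng, n_genes=50, n1=10, n2=10):
    vals = rng.standard_normal((n_genes, n1 + n2))
    groups = ["case"] * n1 + ["control"] * n2
    return make_study(vals, groups)


@pytest.fixture(scope="session")
def default_study():
    """One generator run at default scale, shared across read-only tests."""
    studies, truth = generate_study(StudyConfig(), seed=11)
    return studies, truth


@pytest.fixture
def rng():
    return np.random.default_rng(202)
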