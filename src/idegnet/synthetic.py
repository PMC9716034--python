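"""Synthetic two-disease expression studies with planted ground truth.

The generator emulates the structure of a paired-cohort immune
transcriptomics study: two diseases, each assembled from two batches of
differing size, case/control groups, a designated "immune" gene list,
planted differential genes overlapping that list, planted co-expressed
gene communities driven by latent factors (one community per disease
coupled to the immune differential genes), and batch location/scale
distortions of the class ComBat models.

Expression model per gene g, sample s (log2-like scale):

    y[g, s] = baseline[g]
              + effect * sign(g) * 1[s is case and g planted DEG]
              + loading * f_m[s] * 1[g in module m]
              + coupling * f_imm[s] * 1[g shared immune DEG]
              + gamma[g, b(s)] + delta[g, b(s)] * eps[g, s]

with i.i.d. standard-normal factors f and noise eps.  Under the
one-factor model the within-module correlation has the closed form
r = loading^2 / (loading^2 + sigma^2).

Cell-type mixtures for deconvolution are generated separately:
mixture column = S @ f + noise, fractions f from a Dirichlet.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .study import GROUP_CASE, GROUP_CONTROL, ExpressionStudy

UP = "up"
DOWN = "down"


@dataclass
class StudyConfig:
    """Knobs of the two-disease generator; defaults are the study conditions."""

    n_genes: int = 2000
    #: (case, control) sizes for each batch; two batches of differing size.
    batch_sizes: tuple[tuple[int, int], ...] = ((14, 14), (16, 16))
    n_immune: int = 200          # size of the designated immune gene list
    n_deg: int = 200             # planted DEGs per disease
    n_shared_immune_same: int = 19   # immune DEGs planted in both diseases, same trend
    n_shared_immune_opposite: int = 5  # immune DEGs shared but opposite trend
    module_sizes: tuple[int, ...] = (40, 50, 60, 70, 80)
    loading: float = 2.0         # latent-factor loading (factor strength)
    coupling: float = 1.0        # immune-module factor loading on shared immune DEGs
    effect: float = 2.0          # case-vs-control shift on planted DEGs, units of sigma
    noise_sd: float = 1.0
    baseline_mean: float = 7.0   # log2-like expression location
    baseline_sd: float = 1.0
    batch_shift: float = 1.0     # mean additive offset of the second batch
    batch_shift_sd: float = 0.5  # per-gene spread of the additive offset
    batch_scale_sd: float = 0.2  # log-sd of the per-gene multiplicative effect
    diseases: tuple[str, ...] = ("disease1", "disease2")


@dataclass
class StudyTruth:
    """Everything planted by :func:`generate_study`, for truth-recovery tests."""

    immune_genes: list[str]
    #: disease -> {gene: "up"|"down"}
    deg_direction: dict[str, dict[str, str]]
    #: disease -> {module id: [genes]}; module ids are "M1".."Mk"
    modules: dict[str, dict[str, list[str]]]
    #: disease -> id of the module whose factor also drives the immune DEGs
    immune_coupled_module: dict[str, str]
    #: genes planted as immune DEGs in both diseases with matching direction
    key_idegs: dict[str, str]
    #: disease -> batch -> {"shift": per-gene offsets, "scale": per-gene factors}
    batch_effects: dict[str, dict[str, dict[str, list[float]]]]
    loadings: dict[str, float] = field(default_factory=dict)

    def shared_immune_degs(self) -> set[str]:
        """Immune genes planted as DEGs in every disease (any trend)."""
        sets = [set(d) for d in self.deg_direction.values()]
        common = set.intersection(*sets) if sets else set()
        return common & set(self.immune_genes)


def _sample_frame(cfg: StudyConfig, disease: str) -> pd.DataFrame:
    rows = []
    for b, (n_case, n_control) in enumerate(cfg.batch_sizes, start=1):
        batch = f"{disease}_b{b}"
        for grp, n in ((GROUP_CASE, n_case), (GROUP_CONTROL, n_control)):
            for i in range(n):
                rows.append((f"{disease}_b{b}_{grp}{i + 1}", grp, batch, disease))
    frame = pd.DataFrame(rows, columns=["sample", "group", "batch", "disease"])
    return frame.set_index("sample")


def generate_study(
    config: StudyConfig | None = None, seed: int = 0
) -> tuple[dict[str, ExpressionStudy], StudyTruth]:
    """Generate one expression study per disease plus the planted truth.

    Deterministic: the same ``(config, seed)`` reproduces bit-identical
    matrices.  Raises ``ValueError`` if the requested modules do not fit
    into the gene universe.
    """
    cfg = config or StudyConfig()
    for counts in cfg.batch_sizes:
        if any(n <= 0 for n in counts):
            raise ValueError("all per-batch group sizes must be positive")
    if any(m < 2 for m in cfg.module_sizes):
        raise ValueError("module sizes must be >= 2")
    if sum(cfg.module_sizes) > cfg.n_genes:
        big = max(cfg.module_sizes)
        raise ValueError(
            f"planted modules (largest {big} genes) exceed gene count {cfg.n_genes}"
        )
    if cfg.n_shared_immune_same + cfg.n_shared_immune_opposite > cfg.n_immune:
        raise ValueError("shared immune DEGs exceed the immune list size")

    rng = np.random.default_rng(seed)
    genes = np.array([f"G{i:05d}" for i in range(1, cfg.n_genes + 1)])

    immune = [str(g) for g in rng.choice(genes, size=cfg.n_immune,
                                         replace=False)]
    n_shared = cfg.n_shared_immune_same + cfg.n_shared_immune_opposite
    shared = [str(g) for g in rng.choice(immune, size=n_shared,
                                         replace=False)]
    same_trend = shared[: cfg.n_shared_immune_same]
    opposite = shared[cfg.n_shared_immune_same:]

    key_dirs = {g: (UP if rng.random() < 0.5 else DOWN) for g in same_trend}

    # per-disease DEG sets: the shared immune genes plus disease-private genes
    deg_direction: dict[str, dict[str, str]] = {}
    non_shared = [str(g) for g in genes if g not in set(shared)]
    rng.shuffle(non_shared)
    n_private = cfg.n_deg - n_shared
    if n_private < 0:
        raise ValueError("n_deg smaller than the number of shared immune DEGs")
    offset = 0
    for d_idx, disease in enumerate(cfg.diseases):
        dirs = dict(key_dirs)
        for g in opposite:
            dirs[g] = UP if d_idx == 0 else DOWN
        private = non_shared[offset: offset + n_private]
        offset += n_private
        for g in private:
            dirs[g] = UP if rng.random() < 0.5 else DOWN
        deg_direction[disease] = dirs

    # planted modules: disjoint, drawn outside the shared immune genes so the
    # immune coupling stays a factor assignment rather than module membership
    pool = [str(g) for g in genes if g not in set(shared)]
    rng.shuffle(pool)
    modules_per_disease: dict[str, dict[str, list[str]]] = {}
    coupled: dict[str, str] = {}
    pool_off = 0
    for disease in cfg.diseases:
        mods: dict[str, list[str]] = {}
        for k, size in enumerate(cfg.module_sizes, start=1):
            mods[f"M{k}"] = sorted(pool[pool_off: pool_off + size])
            pool_off += size
        modules_per_disease[disease] = mods
        coupled[disease] = f"M{1 + int(rng.integers(len(cfg.module_sizes)))}"

    studies: dict[str, ExpressionStudy] = {}
    batch_effects: dict[str, dict[str, dict[str, list[float]]]] = {}
    gene_pos = {g: i for i, g in enumerate(genes)}

    for disease in cfg.diseases:
        pheno = _sample_frame(cfg, disease)
        n_samples = len(pheno)
        baseline = rng.normal(cfg.baseline_mean, cfg.baseline_sd, size=cfg.n_genes)
        y = np.tile(baseline[:, None], (1, n_samples))

        case = (pheno["group"] == GROUP_CASE).to_numpy()
        for g, direction in deg_direction[disease].items():
            sign = 1.0 if direction == UP else -1.0
            y[gene_pos[g], case] += sign * cfg.effect * cfg.noise_sd

        factors = rng.standard_normal((len(cfg.module_sizes), n_samples))
        for k, (mid, members) in enumerate(modules_per_disease[disease].items()):
            idx = [gene_pos[g] for g in members]
            y[idx, :] += cfg.loading * factors[k][None, :]
        # immune coupling: the coupled module's factor also drives the genes
        # planted as immune DEGs in both diseases
        k_coupled = int(coupled[disease][1:]) - 1
        idx = [gene_pos[g] for g in shared]
        y[idx, :] += cfg.coupling * factors[k_coupled][None, :]

        eps = rng.standard_normal((cfg.n_genes, n_samples)) * cfg.noise_sd
        batch_effects[disease] = {}
        for b_idx, batch in enumerate(pheno["batch"].unique()):
            cols = (pheno["batch"] == batch).to_numpy()
            if b_idx == 0 or (cfg.batch_shift == 0 and cfg.batch_shift_sd == 0
                              and cfg.batch_scale_sd == 0):
                shift = np.zeros(cfg.n_genes)
                scale = np.ones(cfg.n_genes)
            else:
                shift = rng.normal(cfg.batch_shift, cfg.batch_shift_sd, cfg.n_genes)
                scale = np.exp(rng.normal(0.0, cfg.batch_scale_sd, cfg.n_genes))
            y[:, cols] += shift[:, None] + (scale[:, None] - 1.0) * eps[:, cols]
            batch_effects[disease][batch] = {
                "shift": shift.tolist(), "scale": scale.tolist(),
            }
        y += eps

        expr = pd.DataFrame(y, index=genes, columns=pheno.index)
        studies[disease] = ExpressionStudy(expr, pheno, disease)

    truth = StudyTruth(
        immune_genes=sorted(immune),
        deg_direction=deg_direction,
        modules=modules_per_disease,
        immune_coupled_module=coupled,
        key_idegs=key_dirs,
        batch_effects=batch_effects,
        loadings={"module": cfg.loading, "coupling": cfg.coupling},
    )
    return studies, truth


# ---------------------------------------------------------------------------
# Cell-type mixtures for deconvolution
# ---------------------------------------------------------------------------

@dataclass
class MixtureConfig:
    n_cell_types: int = 5
    genes_per_type: int = 50     # marker genes per cell type
    n_samples: int = 40
    alpha: float = 1.0           # symmetric Dirichlet concentration
    noise_sd: float = 0.0        # additive Gaussian noise on the mixture
    marker_high: float = 10.0    # marker expression in its own cell type
    base_low: float = 1.0        # background expression elsewhere


@dataclass
class MixtureTruth:
    signature: pd.DataFrame      # genes x cell types, non-negative
    fractions: pd.DataFrame      # samples x cell types, rows on the simplex
    noise_sd: float


def generate_mixtures(
    config: MixtureConfig | None = None, seed: int = 0
) -> tuple[pd.DataFrame, pd.DataFrame, MixtureTruth]:
    """Bulk mixtures with known cell-type fractions.

    Returns ``(mixture, signature, truth)`` where ``mixture`` is genes ×
    samples and each mixture column is ``signature @ fractions + noise``.
    """
    cfg = config or MixtureConfig()
    if cfg.n_cell_types < 2:
        raise ValueError("need at least 2 cell types")
    rng = np.random.default_rng(seed)

    n_genes = cfg.n_cell_types * cfg.genes_per_type
    genes = [f"SIG{i:04d}" for i in range(1, n_genes + 1)]
    cells = [f"CellType{j + 1}" for j in range(cfg.n_cell_types)]

    sig = np.full((n_genes, cfg.n_cell_types), cfg.base_low, dtype=float)
    sig += rng.uniform(0.0, 0.5, size=sig.shape)          # mild background texture
    for j in range(cfg.n_cell_types):
        rows = slice(j * cfg.genes_per_type, (j + 1) * cfg.genes_per_type)
        sig[rows, j] = cfg.marker_high + rng.uniform(0.0, 2.0, cfg.genes_per_type)
    signature = pd.DataFrame(sig, index=genes, columns=cells)
    if np.linalg.matrix_rank(sig) < cfg.n_cell_types:
        raise ValueError("signature matrix is rank deficient")

    frac = rng.dirichlet([cfg.alpha] * cfg.n_cell_types, size=cfg.n_samples)
    samples = [f"Mix{i + 1}" for i in range(cfg.n_samples)]
    fractions = pd.DataFrame(frac, index=samples, columns=cells)

    mix = sig @ frac.T
    if cfg.noise_sd > 0:
        mix = mix + rng.normal(0.0, cfg.noise_sd, size=mix.shape)
    mixture = pd.DataFrame(mix, index=genes, columns=samples)
    truth = MixtureTruth(signature=signature, fractions=fractions,
                         noise_sd=cfg.noise_sd)
    return mixture, signature, truth


# ---------------------------------------------------------------------------
# Truth serialization (JSON round-trip)
# ---------------------------------------------------------------------------

def write_truth(truth: StudyTruth, path) -> None:
    payload = {
        "immune_genes": truth.immune_genes,
        "deg_direction": truth.deg_direction,
        "modules": truth.modules,
        "immune_coupled_module": truth.immune_coupled_module,
        "key_idegs": truth.key_idegs,
        "batch_effects": truth.batch_effects,
        "loadings": truth.loadings,
    }
    Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))


def read_truth(path) -> StudyTruth:
    payload = json.loads(Path(path).read_text())
    return StudyTruth(**payload)
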