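"""End-to-end driver: from raw two-batch studies to key genes, modules,
diagnostic AUCs and cell fractions.

Each stage delegates to the corresponding module; this file only wires
them together and collects a result bundle, so the numbered analysis
scripts and the acceptance checks share one code path.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from . import deconv, dea, diagnostics, modules, network, preprocess, synthetic
from .study import ExpressionStudy


@dataclass
class DiseaseResult:
    study: ExpressionStudy                   # batch-corrected
    fit: dea.ModeratedFit
    degs: pd.DataFrame
    related_genes: set = field(default_factory=set)
    network: network.CoexprNetwork | None = None
    partition: network.ModulePartition | None = None
    network_density: float = float("nan")
    module_density: dict = field(default_factory=dict)
    me_table: pd.DataFrame | None = None
    key_module: str = ""
    model_evals: dict = field(default_factory=dict)


@dataclass
class PipelineResult:
    per_disease: dict[str, DiseaseResult]
    ideg_table: pd.DataFrame
    key: modules.KeyIdegSet


def key_ideg_stage(studies: dict[str, ExpressionStudy], irg_list,
                   alpha: float = 0.05) -> tuple[dict[str, DiseaseResult],
                                                 pd.DataFrame,
                                                 modules.KeyIdegSet]:
    """Batch-correct, test, intersect: the stages that determine key genes."""
    if len(studies) != 2:
        raise ValueError("pipeline expects exactly two disease studies")
    per: dict[str, DiseaseResult] = {}
    for disease, raw in studies.items():
        corrected, _ = preprocess.combat(raw)
        fit = dea.moderated_t_table(corrected)
        degs = dea.select_degs(fit, alpha=alpha)
        per[disease] = DiseaseResult(study=corrected, fit=fit, degs=degs)
    d1, d2 = list(per)
    ideg_table = modules.intersect_idegs(per[d1].degs, per[d2].degs, irg_list)
    key = modules.key_idegs(ideg_table)
    return per, ideg_table, key


def run_pipeline(studies: dict[str, ExpressionStudy], irg_list,
                 seed: int = 0, alpha: float = 0.05,
                 r_related: float = 0.40, r_edge: float = 0.70,
                 min_module: int = 30) -> PipelineResult:
    """Full analysis on two pre-merged studies (one per disease)."""
    per, ideg_table, key = key_ideg_stage(studies, irg_list, alpha=alpha)
    idegs = list(ideg_table.index)

    for disease, res in per.items():
        st = res.study
        present_idegs = [g for g in idegs if g in st.genes]
        deg_genes = [g for g in res.degs.index if g not in set(present_idegs)]
        if not present_idegs or not deg_genes:
            continue
        cors = network.pearson_with_p(st, present_idegs, deg_genes)
        related = network.select_related_genes(cors, r_min=r_related,
                                               alpha=alpha)
        related |= set(present_idegs)        # I-DEG nodes included by default
        res.related_genes = related
        net = network.build_network(st, related, r_min=r_edge, alpha=alpha)
        res.network = net
        if net.edges.empty:
            continue
        part = network.louvain_partition(net, seed=seed)
        part = network.filter_modules(part, min_size=min_module)
        res.partition = part
        if len(net.nonisolated()) >= 2:
            res.network_density = network.graph_density(net, net.nonisolated())
        res.module_density = network.module_densities(net, part)

        mods = part.modules()
        if mods:
            mes = {m: modules.module_eigengene(st, genes, m)
                   for m, genes in mods.items()}
            imm = modules.immune_module_eigengene(st, present_idegs)
            res.me_table, res.key_module = modules.module_immune_correlation(
                mes, imm)

        if len(key.key_genes) >= 2:
            res.model_evals = diagnostics.evaluate_models(
                st, key.key_genes, seed=seed)

    return PipelineResult(per_disease=per, ideg_table=ideg_table, key=key)


def recovery_metrics(result: PipelineResult,
                     truth: synthetic.StudyTruth) -> dict[str, float]:
    """Sensitivity/precision of key-gene recovery against planted truth."""
    found = set(result.key.key_genes)
    planted = set(truth.key_idegs)
    tp = len(found & planted)
    sens = tp / len(planted) if planted else float("nan")
    prec = tp / len(found) if found else 0.0
    dirs_ok = all(
        result.key.table.loc[g, "direction_d1"] == truth.key_idegs[g]
        for g in (found & planted)
    )
    return {"sensitivity": sens, "precision": prec,
            "directions_correct": float(dirs_ok),
            "n_found": float(len(found)), "n_planted": float(len(planted))}


def deconvolution_stage(mixture: pd.DataFrame, signature: pd.DataFrame,
                        groups: pd.Series | None = None,
                        seed: int = 0) -> dict:
    """Fractions, optional group tests; a thin wrapper for scripts."""
    res = deconv.deconvolve(mixture, signature, seed=seed)
    out = {"result": res}
    if groups is not None:
        out["group_tests"] = deconv.compare_groups(res.fractions, groups)
    return out
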