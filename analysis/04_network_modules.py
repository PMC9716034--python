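#!/usr/bin/env python
"""Immune-anchored co-expression networks, Louvain modules, key module.

DEGs with an immune-DEG partner at |r| > 0.40 (p < 0.05) form the node
pool; edges require |r| > 0.70 (p < 0.05) with weight |r|.  Louvain
communities below 30 genes are dropped, module densities are tabulated
against the whole-network density, and the module whose eigengene best
tracks the immune-module eigengene is the key module.
"""

import argparse
import json
from pathlib import Path

import pandas as pd

from idegnet import read_study
from idegnet.modules import (immune_module_eigengene, module_eigengene,
                             module_immune_correlation)
from idegnet.network import (build_network, filter_modules, graph_density,
                             louvain_partition, module_densities,
                             pearson_with_p, select_related_genes)

ROOT = Path(__file__).resolve().parents[1]
DATA = ROOT / "scratch" / "data"
RESULTS = ROOT / "results"


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    args = ap.parse_args()

    ideg = pd.read_csv(RESULTS / "03_idegs.tsv", sep="\t", index_col=0)
    report = {}
    density_rows = []
    for disease in ("disease1", "disease2"):
        st = read_study(DATA / f"{disease}_corrected.tsv",
                        DATA / f"{disease}_pheno.tsv")
        degs = pd.read_csv(DATA / f"{disease}_degs.tsv", sep="\t",
                           index_col=0)
        idegs = [g for g in ideg.index if g in st.genes]
        others = [g for g in degs.index if g not in set(idegs)]
        cors = pearson_with_p(st, idegs, others)
        related = select_related_genes(cors) | set(idegs)
        net = build_network(st, related)
        net.edges.to_csv(DATA / f"{disease}_edges.tsv", sep="\t",
                         index=False)
        part = filter_modules(louvain_partition(net, seed=args.seed))
        dens = module_densities(net, part)
        whole = graph_density(net, net.nonisolated())
        for m, d in sorted(dens.items()):
            density_rows.append((disease, m, part.sizes[m], round(d, 6)))

        mes = {m: module_eigengene(st, genes, m)
               for m, genes in part.modules().items()}
        key_module = ""
        me_corr = {}
        if mes:
            imm = immune_module_eigengene(st, idegs)
            tab, key_module = module_immune_correlation(mes, imm)
            me_corr = {m: round(float(r), 4) for m, r in tab["r"].items()}

        report[disease] = {
            "n_related_degs": len(related),
            "n_edges": len(net.edges),
            "network_density": round(whole, 6),
            "modularity_q": round(part.modularity, 4),
            "modules_kept": {m: int(s) for m, s in part.sizes.items()},
            "me_correlation_with_immune_module": me_corr,
            "key_module": key_module,
        }
        print(f"{disease}: {len(related)} related genes, "
              f"{len(net.edges)} edges, Q={part.modularity:.3f}, "
              f"key module {key_module or 'none'}")

    pd.DataFrame(density_rows,
                 columns=["disease", "module", "size", "density"]).to_csv(
        RESULTS / "04_module_density.tsv", sep="\t", index=False)
    (RESULTS / "04_network_summary.json").write_text(
        json.dumps(report, indent=1))


if __name__ == "__main__":
    main()
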