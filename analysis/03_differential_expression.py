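#!/usr/bin/env python
"""Moderated-t differential expression and immune-DEG intersection.

Genes at raw p < 0.05 in both diseases that sit on the immune list are
the I-DEGs; those with the same up/down trend in both diseases are the
key genes carried into the diagnostic signature.
"""

import json
from pathlib import Path

from idegnet import read_gene_list, read_study
from idegnet.dea import moderated_t_table, select_degs
from idegnet.modules import intersect_idegs, key_idegs

ROOT = Path(__file__).resolve().parents[1]
DATA = ROOT / "scratch" / "data"
RESULTS = ROOT / "results"


def main() -> None:
    irg = read_gene_list(DATA / "immune_genes.txt")
    degs = {}
    counts = {}
    for disease in ("disease1", "disease2"):
        st = read_study(DATA / f"{disease}_corrected.tsv",
                        DATA / f"{disease}_pheno.tsv")
        fit = moderated_t_table(st)
        tab = select_degs(fit)
        degs[disease] = tab
        tab.to_csv(DATA / f"{disease}_degs.tsv", sep="\t")
        counts[disease] = {
            "up": int((tab["direction"] == "up").sum()),
            "down": int((tab["direction"] == "down").sum()),
            "prior_df": round(float(fit.df_prior), 2),
        }
        print(f"{disease}: {counts[disease]['up']} up / "
              f"{counts[disease]['down']} down DEGs")

    ideg = intersect_idegs(degs["disease1"], degs["disease2"], irg)
    key = key_idegs(ideg)
    ideg.to_csv(RESULTS / "03_idegs.tsv", sep="\t")
    (RESULTS / "03_deg_summary.json").write_text(json.dumps(
        {"deg_counts": counts, "n_idegs": len(ideg),
         "key_idegs": key.directions()}, indent=1))
    print(f"I-DEGs: {len(ideg)}; same-trend key genes: {len(key.key_genes)}")


if __name__ == "__main__":
    main()
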