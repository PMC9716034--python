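#!/usr/bin/env python
"""Diagnostic value of the key-gene signature in both diseases.

One stratified 7:3 split per disease feeds four classifier families;
the LASSO score form (coefficient * expression per gene), feature
importances and test AUCs are tabulated.
"""

import argparse
import json
from pathlib import Path

import pandas as pd

from idegnet import read_study
from idegnet.diagnostics import evaluate_models

ROOT = Path(__file__).resolve().parents[1]
DATA = ROOT / "scratch" / "data"
RESULTS = ROOT / "results"


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    args = ap.parse_args()

    summary = json.loads((RESULTS / "03_deg_summary.json").read_text())
    signature = sorted(summary["key_idegs"])
    print(f"signature genes: {signature}")

    auc_rows = []
    report = {}
    for disease in ("disease1", "disease2"):
        st = read_study(DATA / f"{disease}_corrected.tsv",
                        DATA / f"{disease}_pheno.tsv")
        evals = evaluate_models(st, signature, seed=args.seed)
        lasso = evals["LASSO"].extras["model"]
        score_terms = " + ".join(
            f"{c:.2f}*exp({g})" for g, c in zip(lasso.features, lasso.coef)
            if abs(c) > 1e-12
        )
        report[disease] = {
            "lasso_lambda": round(float(lasso.lam), 5),
            "lasso_score": score_terms,
            "auc": {f: round(ev.auc, 4) for f, ev in evals.items()},
            "rf_gini_importance": {g: round(v, 4) for g, v in
                                   evals["RF"].importance.items()},
            "xgb_gain_importance": {g: round(v, 4) for g, v in
                                    evals["XGBoost"].importance.items()},
        }
        for f, ev in evals.items():
            auc_rows.append((disease, f, round(ev.auc, 4)))
        print(f"{disease} AUC: " + ", ".join(
            f"{f}={ev.auc:.3f}" for f, ev in evals.items()))
        print(f"  LASSO score = {score_terms}")

    pd.DataFrame(auc_rows, columns=["disease", "model", "auc"]).to_csv(
        RESULTS / "05_auc.tsv", sep="\t", index=False)
    (RESULTS / "05_models.json").write_text(json.dumps(report, indent=1))


if __name__ == "__main__":
    main()
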