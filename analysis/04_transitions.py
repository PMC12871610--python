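#!/usr/bin/env python
"""Classify bivalency dynamics between stages and check them against truth.

Builds the specific/shared/specific partitions for consecutive stage pairs,
summarizes expression of the S3->S4 groups, and scores the called bivalent
sets against the planted truth.  All outputs are small tables in results/.
"""

import json
import sys
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parent))
from common import RESULTS, SCRATCH, SIM_DIR, STAGES

from bivalink import (
    StageCallSet,
    classify_transition,
    read_expression_table,
    summarize_group_expression,
)


def load_calls() -> dict[str, StageCallSet]:
    table = pd.read_csv(SCRATCH / "bivalent_calls.tsv", sep="\t")
    calls = {}
    for stage, sub in table.groupby("stage"):
        sub = sub.set_index("gene_id").rename(
            columns={"normK27": "norm_k27", "normK4": "norm_k4", "b_g": "b"}
        )
        calls[stage] = StageCallSet(
            stage=stage, table=sub[["norm_k27", "norm_k4", "b", "is_bivalent"]],
            theta=float("nan"),
        )
    return calls


def main() -> None:
    calls = load_calls()
    truth = pd.read_csv(SIM_DIR / "truth.tsv", sep="\t", index_col="gene_id")
    expression = read_expression_table(SIM_DIR / "expression.tsv")
    RESULTS.mkdir(parents=True, exist_ok=True)

    summary = {"transitions": [], "truth_recovery": {}}
    for a, b in zip(STAGES, STAGES[1:]):
        part = classify_transition(calls[a], calls[b])
        part.to_frame().to_csv(RESULTS / f"transition_{a}_vs_{b}.tsv", sep="\t", index=False)
        summary["transitions"].append(
            {"pair": f"{a}->{b}", "counts": part.counts, "fractions": part.fractions}
        )
        print(f"{a}->{b}: {part.counts} shared/{b} = {part.fractions[f'shared_of_{b}']:.3f}")

    # expression of the S3->S4 transition groups at S4
    part = classify_transition(calls["S3"], calls["S4"])
    expr = summarize_group_expression(part.groups(), expression, stage="S4")
    expr.table.to_csv(RESULTS / "transition_S3_S4_expression.tsv", sep="\t",
                      float_format="%.6g")
    print("\nexpression (FPKM) of S3->S4 groups at S4:")
    print(expr.table.to_string())

    for stage in STAGES:
        called = calls[stage].bivalent_genes
        planted = set(truth.index[truth[stage] == "bivalent"])
        tp = len(called & planted)
        summary["truth_recovery"][stage] = {
            "planted": len(planted),
            "called": len(called),
            "precision": tp / len(called) if called else None,
            "recall": tp / len(planted) if planted else None,
        }
    with open(RESULTS / "transition_summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
        fh.write("\n")
    rec = summary["truth_recovery"]
    print("\ntruth recovery:",
          {s: (rec[s]["precision"], rec[s]["recall"]) for s in STAGES})


if __name__ == "__main__":
    main()
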