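#!/usr/bin/env python
"""Score the pipeline's calls against the planted truth.

Compares results/pipeline/ outputs with results/sim/truth.json: recall and
empirical FDR of cohort-specific eRNA calls, direction agreement, and
recovery of planted eRNA -> target-gene links by the windowed
best-correlation model.  Writes results/evaluation.tsv.
"""

import argparse
import json
import os
import sys

import pandas as pd

sys.path.insert(0, os.path.join(os.path.dirname(__file__), "..", "src"))

import erna_scout as es  # noqa: E402


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--sim-dir", default="results/sim")
    ap.add_argument("--pipeline-dir", default="results/pipeline")
    ap.add_argument("--out", default="results/evaluation.tsv")
    args = ap.parse_args()

    with open(os.path.join(args.sim_dir, "truth.json")) as fh:
        truth = json.load(fh)
    cand = es.read_bed(os.path.join(args.pipeline_dir, "candidates.bed"), merged=True)
    de = pd.read_csv(os.path.join(args.pipeline_dir, "de.tsv"), sep="\t")
    link = pd.read_csv(os.path.join(args.pipeline_dir, "linkage.tsv"), sep="\t")

    matches = es.match_planted_regions(truth, cand)
    planted_ids = {v for v in matches.values() if v}
    called = set(de.loc[de["label"] != "unclassified", "region_id"])
    tp = len(called & planted_ids)
    recall = tp / len(matches)
    fdr = (len(called) - tp) / max(len(called), 1)

    bestmap = dict(zip(link["region_id"], link.get("best_corr_gene_id", [])))
    targets = {p["name"]: p["target_gene"] for p in truth["planted_ernas"]}
    link_hits = sum(
        1 for name, rid in matches.items() if rid and bestmap.get(rid) == targets[name]
    )

    rows = [
        ("planted_ernas", len(matches)),
        ("cohort_specific_calls", len(called)),
        ("recall", round(recall, 4)),
        ("empirical_fdr", round(fdr, 4)),
        ("linkage_recovery", round(link_hits / len(matches), 4)),
    ]
    out = pd.DataFrame(rows, columns=["metric", "value"])
    os.makedirs(os.path.dirname(args.out), exist_ok=True)
    out.to_csv(args.out, sep="\t", index=False)
    print(out.to_string(index=False))


if __name__ == "__main__":
    main()
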