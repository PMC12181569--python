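#!/usr/bin/env python
"""Receptor calls, surrogate subtypes, and the mean-signature score.

ER status is called from probe 205225_at at intensity 500, HER2 from
216836_s_at at 4800, subtypes follow the surrogate ER/HER2 table, and
the senescence-signature score is the mean over genes of per-gene mean
probe intensity on the normalized scale. Per-sample outputs go to
scratch/annotated/; the call/subtype distribution to results/.
"""

from pathlib import Path

import pandas as pd

from senscan import (
    assign_subtypes,
    call_er,
    call_her2,
    io,
    score_signature,
)

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    pre = ROOT / "scratch" / "preprocessed"
    matrix = io.read_expression(
        pre / "expression.tsv",
        samples_path=pre / "samples.tsv",
        shared_probes=io.read_shared_probes(pre / "shared_probes.txt"),
    )
    signature = io.read_signature(ROOT / "scratch" / "cohort" / "signature.tsv")

    er = call_er(matrix)
    her2 = call_her2(matrix)
    subtype = assign_subtypes(er, her2)
    scoring = score_signature(matrix, signature)

    out = ROOT / "scratch" / "annotated"
    out.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(
        {"score": scoring.scores, "er_status": er, "her2_status": her2,
         "subtype": subtype}
    ).to_csv(out / "scores_calls.tsv", sep="\t", index_label="sample_id")

    results = ROOT / "results"
    results.mkdir(exist_ok=True)
    dist = pd.DataFrame(
        {
            "er_positive": [(er == "positive").mean()],
            "her2_positive": [(her2 == "positive").mean()],
            "score_q1": [scoring.scores.quantile(0.25)],
            "score_median": [scoring.scores.median()],
            "score_q3": [scoring.scores.quantile(0.75)],
        }
    )
    dist.round(4).to_csv(results / "annotation_summary.tsv", sep="\t",
                         index=False)
    print(
        f"scored {len(scoring.scores)} samples over "
        f"{len(scoring.genes_used)} genes; ER+ "
        f"{100 * (er == 'positive').mean():.1f}%, HER2+ "
        f"{100 * (her2 == 'positive').mean():.1f}%"
    )
    if scoring.genes_dropped:
        print(f"genes without probes (excluded): {scoring.genes_dropped}")


if __name__ == "__main__":
    main()
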