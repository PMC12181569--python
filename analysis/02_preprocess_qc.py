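#!/usr/bin/env python
"""Normalize, deduplicate, and QC-filter the simulated database.

Scaling normalization pins every array's shared-probe mean to 1000;
duplicate samples (identical shared-probe vectors) are collapsed keeping
the earliest dataset's copy; the five-parameter QC rule excludes arrays
failing three or more metrics. Audit tables go to results/, the cleaned
matrix to scratch/preprocessed/.
"""

from pathlib import Path

import pandas as pd

from senscan import io, qc_filter, remove_duplicates, scale_normalize

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    cohort = ROOT / "scratch" / "cohort"
    matrix = io.read_expression(
        cohort / "expression.tsv",
        samples_path=cohort / "samples.tsv",
        shared_probes=io.read_shared_probes(cohort / "shared_probes.txt"),
    )
    n0 = matrix.n_samples
    normalized = scale_normalize(matrix)
    deduped, removed = remove_duplicates(normalized)
    qc_records = [
        r for r in io.read_qc(cohort / "qc.tsv")
        if r.sample_id in set(deduped.sample_ids)
    ]
    annotated, passed, flagged, excluded = qc_filter(qc_records)
    clean = deduped.subset_samples(
        [s for s in deduped.sample_ids if s not in set(excluded)]
    )

    out = ROOT / "scratch" / "preprocessed"
    out.mkdir(parents=True, exist_ok=True)
    io.write_expression(clean, out / "expression.tsv",
                        samples_path=out / "samples.tsv")
    io.write_shared_probes(clean, out / "shared_probes.txt")

    results = ROOT / "results"
    results.mkdir(exist_ok=True)
    pd.DataFrame(removed, columns=["retained", "removed"]).to_csv(
        results / "duplicates_removed.tsv", sep="\t", index=False
    )
    status = pd.Series([r.status for r in annotated]).value_counts()
    status.rename_axis("status").to_frame("n_samples").to_csv(
        results / "qc_status_counts.tsv", sep="\t"
    )
    pd.DataFrame(
        [{"sample_id": r.sample_id, **r.metric_pass, "status": r.status}
         for r in annotated if r.status != "pass"]
    ).to_csv(results / "qc_flagged_excluded.tsv", sep="\t", index=False)

    print(
        f"{n0} samples -> {deduped.n_samples} after removing "
        f"{len(removed)} duplicates -> {clean.n_samples} after excluding "
        f"{len(excluded)} QC outliers ({len(flagged)} flagged but kept)"
    )


if __name__ == "__main__":
    main()
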