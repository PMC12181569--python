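#!/usr/bin/env python
"""Quartile-bounded minimum-p survival scan on the signature score.

Every distinct score value between the lower and upper quartiles is
tried as a dichotomization cutoff; each split is tested with a binary
Cox model (HR oriented high vs low); the minimum-p cutoff is selected
(ties broken by the strongest hazard ratio) and the per-cutoff p-value
family is Benjamini–Hochberg adjusted. Writes the per-cutoff table and
group Kaplan–Meier curves to results/ and a significance-vs-cutoff plot
to scratch/figures/.
"""

import json
from pathlib import Path

import pandas as pd

from senscan import cutoff_scan, io
from senscan.survival import km_frame

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    annotated = pd.read_csv(
        ROOT / "scratch" / "annotated" / "scores_calls.tsv",
        sep="\t", index_col="sample_id",
    )
    clinical = io.clinical_to_frame(
        io.read_clinical(ROOT / "scratch" / "cohort" / "clinical.csv")
    ).loc[annotated.index]

    scan = cutoff_scan(
        annotated["score"].to_numpy(),
        clinical["rfs_months"].to_numpy(float),
        clinical["event"].to_numpy(int),
    )

    results = ROOT / "results"
    results.mkdir(exist_ok=True)
    scan.frame().to_csv(results / "scan.tsv", sep="\t", index=False,
                        float_format="%.5g")
    pd.concat(
        [km_frame(scan.km_low, "low"), km_frame(scan.km_high, "high")]
    ).to_csv(results / "km_curves.tsv", sep="\t", index=False,
             float_format="%.5g")
    selected = {
        "cutoff": scan.selected_cutoff,
        "hr_high_vs_low": scan.selected_hr,
        "ci95": [float(x) for x in scan.selected.ci95[0]],
        "p": scan.selected_p,
        "q_bh": scan.selected_q,
        "n_low": int(scan.n_low_at[scan.selected_index]),
        "n_high": int(scan.n_high_at[scan.selected_index]),
        "median_rfs_low_months": scan.km_low.median_months,
        "median_rfs_high_months": scan.km_high.median_months,
        "quartile_bounds": list(scan.quartile_bounds),
        "n_cutoffs_scanned": len(scan.cutoffs),
        "max_q_over_scan": float(scan.q_at.max()),
    }
    (results / "scan_selected.json").write_text(
        json.dumps(selected, indent=2) + "\n"
    )
    _plot(scan)
    print(
        f"scanned {len(scan.cutoffs)} cutoffs in "
        f"[{scan.quartile_bounds[0]:.1f}, {scan.quartile_bounds[1]:.1f}]; "
        f"selected {scan.selected_cutoff:.1f}: HR {scan.selected_hr:.3f} "
        f"(95% CI {selected['ci95'][0]:.3f}-{selected['ci95'][1]:.3f}), "
        f"p {scan.selected_p:.3g}, BH q {scan.selected_q:.3g}; "
        f"max q across the scan {selected['max_q_over_scan']:.3g}"
    )


def _plot(scan) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    import numpy as np

    fig, ax = plt.subplots(figsize=(6, 4))
    ax.plot(scan.cutoffs, -np.log10(scan.p_at), lw=1)
    ax.scatter(
        [scan.selected_cutoff],
        [-np.log10(scan.selected_p)],
        color="red", zorder=3, label="selected cutoff",
    )
    ax.axhline(-np.log10(0.05), ls="--", c="gray", lw=0.8)
    ax.set_xlabel("signature score cutoff")
    ax.set_ylabel("-log10 p (high vs low)")
    ax.legend()
    fig.tight_layout()
    figdir = ROOT / "scratch" / "figures"
    figdir.mkdir(parents=True, exist_ok=True)
    fig.savefig(figdir / "significance_vs_cutoff.png", dpi=150)
    plt.close(fig)


if __name__ == "__main__":
    main()
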