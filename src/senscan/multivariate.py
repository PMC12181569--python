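"""Paired multivariate Cox models and Table-style cohort summarization.

Clinical covariates in merged microarray databases are missing for large,
covariate-specific subsets of patients. Rather than one pooled model on
the (small) intersection of complete cases, the signature's independence
from each clinical factor is assessed in *pairs*: one two-covariate Cox
model per clinical variable, fit on the cases complete for that variable,
with the dropped-case count logged per model.
"""

from __future__ import annotations

import logging
from typing import Iterable, List, Optional, Sequence

import numpy as np
import pandas as pd

from .io import clinical_to_frame
from .survival import ConvergenceError, cox_fit
from .types import UNKNOWN, ClinicalRecord, CoxResult, PipelineError

logger = logging.getLogger(__name__)

#: reference level first; remaining levels become indicator columns
_CATEGORICAL_LEVELS = {
    "er_status": ["negative", "positive"],
    "her2_status": ["negative", "positive"],
    "node_status": ["negative", "positive"],
    "subtype": ["luminal_a", "luminal_b", "her2_enriched", "basal"],
}
_CONTINUOUS = {"size_cm", "age_years"}
PAIRABLE_COVARIATES = tuple(_CATEGORICAL_LEVELS) + tuple(sorted(_CONTINUOUS))


class CollinearityError(PipelineError):
    """The paired design matrix is rank-deficient (degenerate pairing)."""


def _encode_covariate(values: pd.Series, name: str) -> pd.DataFrame:
    """Reference-code a clinical covariate; rows with unknowns become NaN."""
    if name in _CONTINUOUS:
        out = pd.DataFrame({name: pd.to_numeric(values, errors="coerce")})
        return out
    levels = _CATEGORICAL_LEVELS[name]
    vals = values.where(values != UNKNOWN)
    bad = vals.dropna()[~vals.dropna().isin(levels)]
    if len(bad):
        raise ValueError(f"{name}: unexpected level(s) {sorted(set(bad))}")
    cols = {}
    for level in levels[1:]:  # levels[0] is the reference
        col = (vals == level).astype(float)
        col[vals.isna()] = np.nan
        cols[f"{name}_{level}"] = col
    return pd.DataFrame(cols)


def paired_cox(
    group,
    covariate: pd.Series,
    times,
    events,
    covariate_name: Optional[str] = None,
    min_complete: int = 10,
) -> CoxResult:
    """Two-covariate Cox model: signature group + one clinical covariate.

    ``group`` is the binary high/low signature indicator at the selected
    cutoff (or any binary/continuous signature coding). Cases missing the
    covariate are dropped (pairwise completeness) and the count is
    logged. Categorical covariates are reference-coded (negative/first
    level as reference; subtype reference = luminal_a). Refuses to fit on
    fewer than ``min_complete`` complete cases, and raises
    :class:`CollinearityError` when the covariate duplicates the group.
    """
    name = covariate_name or getattr(covariate, "name", None)
    if name is None:
        raise ValueError("covariate_name required for unnamed covariates")
    group = np.asarray(group, float)
    times = np.asarray(times, float)
    events = np.asarray(events, int)
    covariate = pd.Series(np.asarray(covariate, object))
    encoded = _encode_covariate(covariate, name)
    design = pd.concat(
        [pd.DataFrame({"signature_high": group}), encoded], axis=1
    )
    complete = ~design.isna().any(axis=1)
    n_dropped = int((~complete).sum())
    if n_dropped:
        logger.info(
            "paired model %s: dropped %d/%d cases missing the covariate",
            name, n_dropped, len(design),
        )
    design = design[complete.to_numpy()]
    t, d = times[complete.to_numpy()], events[complete.to_numpy()]
    if len(design) < min_complete:
        raise PipelineError(
            f"paired model {name}: only {len(design)} complete cases "
            f"(< {min_complete})"
        )
    kept_cols = [c for c in design.columns if design[c].nunique() > 1]
    if len(kept_cols) < design.shape[1]:
        dropped_cols = sorted(set(design.columns) - set(kept_cols))
        logger.info(
            "paired model %s: dropping constant column(s) %s",
            name, dropped_cols,
        )
        design = design[kept_cols]
    if "signature_high" not in design.columns or design.shape[1] < 2:
        raise PipelineError(
            f"paired model {name}: covariate has < 2 observed levels "
            "among complete cases"
        )
    if np.linalg.matrix_rank(design.to_numpy() - design.to_numpy().mean(0)) < design.shape[1]:
        raise CollinearityError(
            f"paired model {name}: design matrix is rank deficient "
            "(covariate collinear with the signature group?)"
        )
    if d.sum() == 0:
        raise PipelineError(f"paired model {name}: no events among complete cases")
    try:
        return cox_fit(design, t, d)
    except ConvergenceError as exc:
        raise CollinearityError(
            f"paired model {name}: fit failed ({exc})"
        ) from exc


def paired_cox_table(
    group,
    records: Sequence[ClinicalRecord],
    times,
    events,
    covariates: Iterable[str] = PAIRABLE_COVARIATES,
) -> pd.DataFrame:
    """One row per paired model: signature HR/CI/p plus the covariate's.

    For categorical covariates with several non-reference levels (subtype)
    the first non-reference indicator is reported in the covariate columns
    and the remaining levels appear in extra rows.
    """
    frame = clinical_to_frame(records)
    rows = []
    for name in covariates:
        try:
            res = paired_cox(
                group, frame[name], times, events, covariate_name=name
            )
        except PipelineError as exc:
            logger.warning("paired model %s skipped: %s", name, exc)
            continue
        summary = res.summary_frame()
        sig = summary.loc["signature_high"]
        for cov_name, cov in summary.drop(index="signature_high").iterrows():
            rows.append(
                {
                    "covariate": cov_name,
                    "n_used": res.n_used,
                    "n_events": res.n_events,
                    "hr_signature": sig["hr"],
                    "ci_signature_low": sig["ci95_low"],
                    "ci_signature_high": sig["ci95_high"],
                    "p_signature": sig["p"],
                    "hr_covariate": cov["hr"],
                    "ci_covariate_low": cov["ci95_low"],
                    "ci_covariate_high": cov["ci95_high"],
                    "p_covariate": cov["p"],
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# cohort summary
# ---------------------------------------------------------------------------

#: variables whose percentages are taken over the total cohort size even
#: though other variables use the non-missing denominator (mirrors the
#: mixed convention of clinical characteristics tables for these cohorts)
_TOTAL_DENOMINATOR = {"event", "er_status", "her2_status"}


def summarize_cohort(
    records: Sequence[ClinicalRecord],
    total_denominator_vars: Optional[set] = None,
) -> pd.DataFrame:
    """Clinical-characteristics summary table.

    One row per variable level with count, denominator and percentage
    (one decimal), plus mean +/- SD rows for age and tumor size and a
    median follow-up row. Percentages for event/ER/HER2 use the total
    cohort as denominator; node status and subtype use the non-missing
    count — the convention is overridable per call.
    """
    if not records:
        raise ValueError("summarize_cohort needs at least one record")
    if total_denominator_vars is None:
        total_denominator_vars = _TOTAL_DENOMINATOR
    frame = clinical_to_frame(records)
    n_total = len(frame)
    rows: List[dict] = [
        {"variable": "total", "level": "", "count": n_total,
         "denominator": n_total, "percent": 100.0},
        {
            "variable": "follow_up",
            "level": "median_months",
            "value": float(frame["rfs_months"].median()),
        },
    ]

    def categorical(variable: str, series: pd.Series, levels: List[str]):
        known = series[series != UNKNOWN]
        denom = n_total if variable in total_denominator_vars else len(known)
        for level in levels:
            count = int((known == level).sum())
            rows.append(
                {
                    "variable": variable,
                    "level": level,
                    "count": count,
                    "denominator": denom,
                    "percent": (
                        round(100.0 * count / denom, 1) if denom else np.nan
                    ),
                }
            )
        rows.append(
            {
                "variable": variable,
                "level": "unknown",
                "count": int(len(series) - len(known)),
                "denominator": n_total,
            }
        )

    event = frame["event"].map({1: "yes", 0: "no"})
    categorical("event", event, ["yes", "no"])
    for var in ("er_status", "her2_status", "node_status"):
        categorical(var, frame[var], ["positive", "negative"])
    categorical(
        "subtype",
        frame["subtype"],
        ["basal", "luminal_a", "luminal_b", "her2_enriched"],
    )
    for var in ("age_years", "size_cm"):
        vals = pd.to_numeric(frame[var], errors="coerce").dropna()
        rows.append(
            {
                "variable": var,
                "level": "mean_sd",
                "count": int(len(vals)),
                "value": float(vals.mean()) if len(vals) else np.nan,
                "sd": float(vals.std(ddof=1)) if len(vals) > 1 else np.nan,
            }
        )
    table = pd.DataFrame(rows)
    _audit_percentages(table)
    return table


def _audit_percentages(table: pd.DataFrame) -> None:
    """Internal consistency: every percentage recomputes from its own
    count/denominator."""
    mask = table["percent"].notna() if "percent" in table else []
    for _, row in table[mask].iterrows():
        expected = round(100.0 * row["count"] / row["denominator"], 1)
        if abs(expected - row["percent"]) > 1e-9:
            raise AssertionError(
                f"summary percentage inconsistent for {row['variable']}"
            )


def percentage_of(table: pd.DataFrame, variable: str, level: str) -> float:
    row = table[(table["variable"] == variable) & (table["level"] == level)]
    if not len(row):
        raise KeyError(f"no row for {variable}/{level}")
    return float(row["percent"].iloc[0])
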