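"""Readers and writers for the pipeline's plain-text interchange formats.

Formats (artifact conventions; the underlying study names none):

* expression: TSV, first column ``probe_id``, header row = sample ids,
  body = non-negative linear intensities. Provenance (dataset/platform
  per sample) travels in a sidecar samples TSV when a file holds more
  than one dataset.
* clinical: CSV with a named header; ``sample_id``, ``rfs_months`` and
  ``event`` are required, covariates optional. Empty string and ``NA``
  both read as unknown; unknowns are written as ``NA``.
* signature: two-column TSV ``gene<TAB>probe``; duplicated rows collapse.
* qc: TSV with the five per-sample metrics.
"""

from __future__ import annotations

import dataclasses
import json
import math
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .types import (
    UNKNOWN,
    ClinicalRecord,
    ExpressionMatrix,
    FormatError,
    QCRecord,
    SignatureDefinition,
    SyntheticTruth,
)

_NA_TOKENS = {"", "na", "nan", "none", "null"}


def _is_na(value) -> bool:
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return True
    return isinstance(value, str) and value.strip().lower() in _NA_TOKENS


# ---------------------------------------------------------------------------
# expression
# ---------------------------------------------------------------------------

def read_expression(
    path,
    dataset_label: str = "dataset1",
    platform_label: str = "GPL570",
    shared_probes: Optional[Sequence[str]] = None,
    samples_path=None,
) -> ExpressionMatrix:
    """Read a probe x sample intensity TSV into an :class:`ExpressionMatrix`.

    ``dataset_label``/``platform_label`` label every sample in the file;
    alternatively ``samples_path`` points at a sidecar TSV with columns
    ``sample_id``, ``dataset``, ``platform`` covering all samples. When
    ``shared_probes`` is omitted, every probe is treated as shared.
    """
    try:
        df = pd.read_csv(path, sep="\t", index_col=0)
    except (pd.errors.ParserError, pd.errors.EmptyDataError) as exc:
        raise FormatError(f"{path}: cannot parse expression table: {exc}")
    if df.index.has_duplicates:
        raise FormatError(f"{path}: duplicate probe identifiers")
    if df.columns.has_duplicates:
        raise FormatError(f"{path}: duplicate sample identifiers")
    try:
        values = df.astype(float)
    except ValueError as exc:
        raise FormatError(f"{path}: non-numeric intensity: {exc}")
    if samples_path is not None:
        samples = pd.read_csv(samples_path, sep="\t", dtype=str)
        for col in ("sample_id", "dataset", "platform"):
            if col not in samples.columns:
                raise FormatError(f"{samples_path}: missing column {col!r}")
        samples = samples.set_index("sample_id")
        missing = values.columns.difference(samples.index)
        if len(missing):
            raise FormatError(
                f"{samples_path}: no provenance for samples {list(missing)[:5]}"
            )
        dataset_of = samples["dataset"].reindex(values.columns)
        platform_of = samples["platform"].reindex(values.columns)
    else:
        dataset_of = pd.Series(dataset_label, index=values.columns)
        platform_of = pd.Series(platform_label, index=values.columns)
    if shared_probes is None:
        shared_probes = values.index
    return ExpressionMatrix(
        values=values,
        dataset_of=dataset_of,
        platform_of=platform_of,
        shared_probes=pd.Index(shared_probes),
    )


def write_expression(
    matrix: ExpressionMatrix,
    path,
    samples_path=None,
    float_format: str = "%.10g",
) -> None:
    """Write the intensity TSV (and, optionally, the provenance sidecar)."""
    out = matrix.values.copy()
    out.index.name = "probe_id"
    out.to_csv(path, sep="\t", float_format=float_format)
    if samples_path is not None:
        pd.DataFrame(
            {
                "sample_id": matrix.sample_ids,
                "dataset": matrix.dataset_of.to_numpy(),
                "platform": matrix.platform_of.to_numpy(),
            }
        ).to_csv(samples_path, sep="\t", index=False)


def write_shared_probes(matrix: ExpressionMatrix, path) -> None:
    Path(path).write_text("\n".join(map(str, matrix.shared_probes)) + "\n")


def read_shared_probes(path) -> pd.Index:
    lines = [ln.strip() for ln in Path(path).read_text().splitlines()]
    return pd.Index([ln for ln in lines if ln])


# ---------------------------------------------------------------------------
# clinical
# ---------------------------------------------------------------------------

_STATUS_ALIASES = {
    "positive": "positive",
    "pos": "positive",
    "1": "positive",
    "negative": "negative",
    "neg": "negative",
    "0": "negative",
}


def _parse_status(value, field: str, sample: str) -> str:
    if _is_na(value):
        return UNKNOWN
    key = str(value).strip().lower()
    if key == UNKNOWN:
        return UNKNOWN
    if key not in _STATUS_ALIASES:
        raise FormatError(f"{sample}: unrecognized {field} value {value!r}")
    return _STATUS_ALIASES[key]


def _parse_float(value, field: str, sample: str) -> Optional[float]:
    if _is_na(value):
        return None
    try:
        return float(value)
    except (TypeError, ValueError):
        raise FormatError(f"{sample}: non-numeric {field} value {value!r}")


def read_clinical(path) -> list:
    """Read the clinical CSV into a list of :class:`ClinicalRecord`.

    Unknowns stay unknown — nothing is imputed. The event column accepts
    0/1 integers or "0"/"1" strings.
    """
    df = pd.read_csv(path, dtype=str)
    for col in ("sample_id", "rfs_months", "event"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing required column {col!r}")
    records = []
    for row in df.itertuples(index=False):
        d = row._asdict()
        sid = str(d["sample_id"])
        rfs = _parse_float(d["rfs_months"], "rfs_months", sid)
        event = _parse_float(d["event"], "event", sid)
        if rfs is None or event is None:
            raise FormatError(f"{sid}: rfs_months and event are required")
        if event not in (0.0, 1.0):
            raise FormatError(f"{sid}: event must be 0 or 1, got {event!r}")
        subtype = d.get("subtype")
        records.append(
            ClinicalRecord(
                sample_id=sid,
                rfs_months=rfs,
                event=int(event),
                er_status=_parse_status(d.get("er_status"), "er_status", sid),
                her2_status=_parse_status(
                    d.get("her2_status"), "her2_status", sid
                ),
                node_status=_parse_status(
                    d.get("node_status"), "node_status", sid
                ),
                size_cm=_parse_float(d.get("size_cm"), "size_cm", sid),
                age_years=_parse_float(d.get("age_years"), "age_years", sid),
                subtype=UNKNOWN if _is_na(subtype) else str(subtype),
            )
        )
    return records


def clinical_to_frame(records: Iterable[ClinicalRecord]) -> pd.DataFrame:
    df = pd.DataFrame([dataclasses.asdict(r) for r in records])
    return df.set_index("sample_id", drop=False)


def write_clinical(records: Iterable[ClinicalRecord], path) -> None:
    df = clinical_to_frame(records).drop(columns="sample_id")
    df = df.replace({UNKNOWN: "NA"})
    df.index.name = "sample_id"
    df.to_csv(path, na_rep="NA")


# ---------------------------------------------------------------------------
# signature
# ---------------------------------------------------------------------------

def read_signature(path, name: Optional[str] = None) -> SignatureDefinition:
    """Read a two-column gene/probe TSV into a :class:`SignatureDefinition`.

    Rows are grouped per gene; exact duplicate rows collapse; row order is
    irrelevant (genes and probes are sorted for a canonical layout).
    """
    try:
        df = pd.read_csv(path, sep="\t", dtype=str)
    except pd.errors.EmptyDataError:
        raise FormatError(f"{path}: empty signature file")
    cols = [c.lower() for c in df.columns]
    if "gene" not in cols or "probe" not in cols:
        raise FormatError(f"{path}: signature needs 'gene' and 'probe' columns")
    df.columns = cols
    df = df.dropna(subset=["gene", "probe"])
    if df.empty:
        raise FormatError(f"{path}: signature has no rows")
    probes_of = {}
    for gene, sub in df.groupby("gene", sort=True):
        probes_of[str(gene)] = tuple(sorted(set(sub["probe"].astype(str))))
    return SignatureDefinition(
        name=name or Path(str(path)).stem, probes_of=probes_of
    )


def write_signature(sig: SignatureDefinition, path) -> None:
    rows = [
        {"gene": gene, "probe": probe}
        for gene in sorted(sig.probes_of)
        for probe in sig.probes_of[gene]
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# QC metrics
# ---------------------------------------------------------------------------

_QC_COLUMNS = (
    "sample_id",
    "background_signal",
    "raw_q",
    "percent_present",
    "biob_detected",
    "ratio_3to5",
)


def read_qc(path) -> list:
    df = pd.read_csv(path, sep="\t")
    for col in _QC_COLUMNS:
        if col not in df.columns:
            raise FormatError(f"{path}: missing QC column {col!r}")
    records = []
    for row in df.itertuples(index=False):
        d = row._asdict()
        biob = d["biob_detected"]
        if isinstance(biob, str):
            biob = biob.strip().lower() in {"true", "1", "yes"}
        records.append(
            QCRecord(
                sample_id=str(d["sample_id"]),
                background_signal=float(d["background_signal"]),
                raw_q=float(d["raw_q"]),
                percent_present=float(d["percent_present"]),
                biob_detected=bool(biob),
                ratio_3to5=float(d["ratio_3to5"]),
            )
        )
    return records


def qc_to_frame(records: Iterable[QCRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        row = {c: getattr(r, c) for c in _QC_COLUMNS}
        if r.status is not None:
            row["status"] = r.status
        rows.append(row)
    return pd.DataFrame(rows).set_index("sample_id", drop=False)


def write_qc(records: Iterable[QCRecord], path) -> None:
    qc_to_frame(records).drop(columns="sample_id").to_csv(
        path, sep="\t", index_label="sample_id"
    )


# ---------------------------------------------------------------------------
# synthetic truth
# ---------------------------------------------------------------------------

TRUTH_SCHEMA_VERSION = 1


def write_truth(truth: SyntheticTruth, path) -> None:
    d = dataclasses.asdict(truth)
    d["schema_version"] = TRUTH_SCHEMA_VERSION
    if truth.true_group is not None:
        d["true_group"] = {
            str(k): int(v) for k, v in truth.true_group.items()
        }
    if truth.dataset_scale_factors is not None:
        d["dataset_scale_factors"] = [
            float(x) for x in truth.dataset_scale_factors
        ]
    Path(path).write_text(json.dumps(d, indent=2, default=float) + "\n")


def read_truth(path) -> SyntheticTruth:
    d = json.loads(Path(path).read_text())
    d.pop("schema_version", None)
    group = d.pop("true_group", None)
    sf = d.pop("dataset_scale_factors", None)
    truth = SyntheticTruth(**d)
    if group is not None:
        truth.true_group = pd.Series(group, dtype=int)
    if sf is not None:
        truth.dataset_scale_factors = np.asarray(sf, float)
    return truth
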