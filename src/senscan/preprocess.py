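"""Cohort merging, secondary scaling normalization, duplicate removal, QC.

The merged database is assembled from independently MAS5-normalized
per-dataset matrices that share a common probe subset. Three steps turn
them into one analysis cohort:

1. a per-array scaling normalization that rescales every sample so the
   mean intensity over the shared probes equals a preset target (1000),
2. removal of duplicated samples (identical expression vectors across
   datasets; the copy from the earliest dataset in the supplied priority
   order is retained),
3. a five-parameter array-QC filter (background signal, raw Q, percent
   present calls, bioB spike detection, GAPDH/ACTB 3'-to-5' ratio) where
   continuous metrics pass inside a mean +/- z*SD band computed across
   all samples of the merged batch.

Normalization runs before duplicate detection and QC banding so that
cross-dataset comparisons happen on a common scale.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass
from typing import Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .types import (
    QC_CONTINUOUS_METRICS,
    ExpressionMatrix,
    FormatError,
    PipelineError,
    QCRecord,
)

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# merge
# ---------------------------------------------------------------------------

def merge_cohorts(matrices: Sequence[ExpressionMatrix]) -> ExpressionMatrix:
    """Column-concatenate per-dataset matrices on their common probe set.

    Probes are intersected (order taken from the first matrix); the shared
    probe designation is the intersection of the inputs' shared sets.
    Sample ids must be globally unique.
    """
    if not matrices:
        raise ValueError("no matrices to merge")
    probes = matrices[0].probe_ids
    shared = matrices[0].shared_probes
    for m in matrices[1:]:
        probes = probes.intersection(m.probe_ids, sort=False)
        shared = shared.intersection(m.shared_probes, sort=False)
    if not len(probes):
        raise PipelineError("matrices share no probes")
    values = pd.concat([m.values.loc[probes] for m in matrices], axis=1)
    dataset_of = pd.concat([m.dataset_of for m in matrices])
    platform_of = pd.concat([m.platform_of for m in matrices])
    merged = ExpressionMatrix(
        values=values,
        dataset_of=dataset_of,
        platform_of=platform_of,
        shared_probes=shared,
    )
    logger.info(
        "merged %d matrices: %d probes (%d shared), %d samples",
        len(matrices), len(probes), len(shared), merged.n_samples,
    )
    return merged


# ---------------------------------------------------------------------------
# scaling normalization
# ---------------------------------------------------------------------------

def scale_normalize(
    matrix: ExpressionMatrix, target_mean: float = 1000.0
) -> ExpressionMatrix:
    """Rescale each sample so its shared-probe mean equals ``target_mean``.

    One multiplicative factor per sample — computed only from the shared
    probes but applied to every probe — so within-sample probe ratios are
    preserved exactly and the operation is idempotent.
    """
    if not len(matrix.shared_probes):
        raise PipelineError("scale_normalize needs a non-empty shared probe set")
    shared_means = matrix.shared_values().mean(axis=0)
    bad = shared_means[shared_means <= 0]
    if len(bad):
        raise PipelineError(
            "cannot normalize samples with non-positive shared-probe mean: "
            + ", ".join(map(str, bad.index[:5]))
        )
    factors = target_mean / shared_means
    out = matrix.copy()
    out.values = out.values.mul(factors, axis=1)
    return out


# ---------------------------------------------------------------------------
# duplicate-sample removal
# ---------------------------------------------------------------------------

def _round_significant(a: np.ndarray, digits: int) -> np.ndarray:
    """Round to ``digits`` significant figures, elementwise (0 stays 0)."""
    a = np.asarray(a, float)
    out = np.zeros_like(a)
    nz = a != 0
    with np.errstate(divide="ignore"):
        exp = np.floor(np.log10(np.abs(a[nz])))
    scale = 10.0 ** (exp - digits + 1)
    out[nz] = np.round(a[nz] / scale) * scale
    return out


def remove_duplicates(
    matrices,
    dataset_priority: Optional[Sequence[str]] = None,
    precision: int = 4,
) -> Tuple[ExpressionMatrix, List[Tuple[str, str]]]:
    """Drop samples whose shared-probe expression vector duplicates another's.

    Accepts either a list of per-dataset matrices in publication-priority
    order (first = earliest publication) or one merged matrix plus an
    explicit ``dataset_priority``. Two samples are duplicates iff their
    shared-probe vectors are identical after rounding to ``precision``
    significant figures. Within a duplicate group the sample whose dataset
    has the highest priority survives (ties within one dataset: smallest
    sample id, so the outcome never depends on column order).

    Returns the deduplicated matrix and ``removed`` pairs
    ``(retained_id, removed_id)``.
    """
    if isinstance(matrices, ExpressionMatrix):
        merged = matrices
        if dataset_priority is None:
            dataset_priority = list(dict.fromkeys(merged.dataset_of))
    else:
        matrices = list(matrices)
        if dataset_priority is None:
            dataset_priority = [m.dataset_of.iloc[0] for m in matrices]
        merged = merge_cohorts(matrices) if len(matrices) > 1 else matrices[0]
    rank = {ds: i for i, ds in enumerate(dataset_priority)}
    unknown = set(merged.dataset_of) - set(rank)
    if unknown:
        raise ValueError(f"datasets without a priority rank: {sorted(unknown)}")

    rounded = _round_significant(merged.shared_values().to_numpy(), precision)
    groups: dict = {}
    for j, sid in enumerate(merged.sample_ids):
        groups.setdefault(rounded[:, j].tobytes(), []).append(sid)

    removed: List[Tuple[str, str]] = []
    drop: List[str] = []
    for members in groups.values():
        if len(members) == 1:
            continue
        keeper = min(
            members, key=lambda s: (rank[merged.dataset_of[s]], str(s))
        )
        for sid in members:
            if sid != keeper:
                removed.append((keeper, sid))
                drop.append(sid)
    keep = [s for s in merged.sample_ids if s not in set(drop)]
    logger.info(
        "duplicate removal: %d of %d samples removed", len(drop),
        merged.n_samples,
    )
    return merged.subset_samples(keep), sorted(removed, key=lambda p: str(p[1]))


# ---------------------------------------------------------------------------
# five-parameter QC
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class QCRule:
    """Configuration of the per-sample QC decision.

    ``z`` sets the half-width of the tolerance band (mean +/- z*SD across
    all samples) for each continuous metric; bioB passes iff the spike was
    detected. A sample is excluded when at least ``exclude_min_failures``
    metrics fail, flagged (kept but reported) when between
    ``flag_min_failures`` and ``exclude_min_failures - 1`` fail, and
    passes with zero failures. The default (exclude at >= 3 failures)
    keeps borderline arrays; the stricter reading of the rule — any single
    failure excludes — is ``QCRule(exclude_min_failures=1)``.
    """

    z: float = 1.96
    exclude_min_failures: int = 3
    flag_min_failures: int = 1

    def __post_init__(self):
        if self.z <= 0:
            raise ValueError("z must be positive")
        if not 1 <= self.flag_min_failures <= self.exclude_min_failures:
            raise ValueError("need 1 <= flag_min_failures <= exclude_min_failures")


def qc_filter(
    records: Iterable[QCRecord], rule: QCRule = QCRule()
) -> Tuple[List[QCRecord], List[str], List[str], List[str]]:
    """Evaluate the five-metric QC rule over one batch of samples.

    Returns ``(annotated_records, passed_ids, flagged_ids, excluded_ids)``
    where annotated records carry per-metric pass booleans and the derived
    status. Bands are computed across all samples of the batch (population
    SD, ddof=0).
    """
    records = list(records)
    if len(records) < 3:
        raise PipelineError("QC banding needs at least 3 samples")
    frame = pd.DataFrame(
        {
            m: [getattr(r, m) for r in records]
            for m in QC_CONTINUOUS_METRICS
        },
        index=[r.sample_id for r in records],
    )
    if frame.isna().any().any():
        raise FormatError("QC metric values missing")
    mean = frame.mean(axis=0)
    sd = frame.std(axis=0, ddof=0)
    low, high = mean - rule.z * sd, mean + rule.z * sd

    annotated: List[QCRecord] = []
    passed, flagged, excluded = [], [], []
    for r in records:
        metric_pass = {
            m: bool(low[m] <= getattr(r, m) <= high[m])
            for m in QC_CONTINUOUS_METRICS
        }
        metric_pass["biob_detected"] = bool(r.biob_detected)
        n_fail = sum(not ok for ok in metric_pass.values())
        if n_fail >= rule.exclude_min_failures:
            status = "excluded"
        elif n_fail >= rule.flag_min_failures:
            status = "flagged"
        else:
            status = "pass"
        annotated.append(
            dataclasses.replace(r, metric_pass=metric_pass, status=status)
        )
        {"pass": passed, "flagged": flagged, "excluded": excluded}[
            status
        ].append(r.sample_id)
    logger.info(
        "QC: %d pass, %d flagged, %d excluded (z=%.2f, exclude at >=%d failures)",
        len(passed), len(flagged), len(excluded), rule.z,
        rule.exclude_min_failures,
    )
    return annotated, passed, flagged, excluded
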