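"""End-to-end orchestration of the analysis stages.

``run_pipeline`` strings together normalization, duplicate removal, QC
exclusion, receptor/subtype annotation, signature scoring, the cutoff
scan, and the paired multivariate models, keeping a patient-accounting
log of every filtering step. Each stage remains individually callable;
this module only sequences them.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from . import annotate, multivariate, preprocess, survival
from .io import clinical_to_frame
from .preprocess import QCRule
from .types import (
    ClinicalRecord,
    ExpressionMatrix,
    QCRecord,
    ScanResult,
    SignatureDefinition,
)

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    target_mean: float = 1000.0
    dup_precision: int = 4
    qc_rule: QCRule = field(default_factory=QCRule)
    er_probe: str = annotate.ER_PROBE
    er_cutoff: float = annotate.ER_CUTOFF
    her2_probe: str = annotate.HER2_PROBE
    her2_cutoff: float = annotate.HER2_CUTOFF
    p_source: str = "cox"
    ties: str = "efron"
    quartile_bounds: Tuple[float, float] = (0.25, 0.75)
    paired_covariates: Sequence[str] = multivariate.PAIRABLE_COVARIATES


@dataclass
class PipelineResult:
    matrix: ExpressionMatrix  # normalized, deduplicated, QC-passed cohort
    clinical: List[ClinicalRecord]
    scores: pd.Series
    er_calls: pd.Series
    her2_calls: pd.Series
    subtypes: pd.Series
    scan: ScanResult
    paired: pd.DataFrame
    summary: pd.DataFrame
    removed_duplicates: List[Tuple[str, str]]
    qc_excluded: List[str]
    qc_flagged: List[str]
    qc_records: List[QCRecord]

    @property
    def analysis_ids(self) -> pd.Index:
        return self.matrix.sample_ids


def run_pipeline(
    matrix: ExpressionMatrix,
    clinical: Sequence[ClinicalRecord],
    qc: Sequence[QCRecord],
    signature: SignatureDefinition,
    config: Optional[PipelineConfig] = None,
    dataset_priority: Optional[Sequence[str]] = None,
) -> PipelineResult:
    config = config or PipelineConfig()
    n0 = matrix.n_samples
    normalized = preprocess.scale_normalize(matrix, config.target_mean)
    deduped, removed = preprocess.remove_duplicates(
        normalized, dataset_priority=dataset_priority,
        precision=config.dup_precision,
    )
    qc_annotated, _, flagged, excluded = preprocess.qc_filter(
        [r for r in qc if r.sample_id in set(deduped.sample_ids)],
        config.qc_rule,
    )
    analysis = deduped.subset_samples(
        [s for s in deduped.sample_ids if s not in set(excluded)]
    )
    logger.info(
        "patient accounting: %d raw -> %d after duplicate removal -> %d "
        "after QC exclusion", n0, deduped.n_samples, analysis.n_samples,
    )

    clin_by_id = {r.sample_id: r for r in clinical}
    kept_clinical = [clin_by_id[s] for s in analysis.sample_ids]
    frame = clinical_to_frame(kept_clinical)
    times = frame["rfs_months"].to_numpy(float)
    events = frame["event"].to_numpy(int)

    er = annotate.call_er(analysis, config.er_probe, config.er_cutoff)
    her2 = annotate.call_her2(analysis, config.her2_probe, config.her2_cutoff)
    subtypes = annotate.assign_subtypes(er, her2)
    scoring = annotate.score_signature(analysis, signature)
    scores = scoring.scores

    scan = survival.cutoff_scan(
        scores.to_numpy(), times, events,
        p_source=config.p_source, ties=config.ties,
        quartile_bounds=config.quartile_bounds,
    )
    group = (scores.to_numpy() > scan.selected_cutoff).astype(int)
    paired = multivariate.paired_cox_table(
        group, kept_clinical, times, events,
        covariates=config.paired_covariates,
    )
    summary = multivariate.summarize_cohort(kept_clinical)
    return PipelineResult(
        matrix=analysis,
        clinical=kept_clinical,
        scores=scores,
        er_calls=er,
        her2_calls=her2,
        subtypes=subtypes,
        scan=scan,
        paired=paired,
        summary=summary,
        removed_duplicates=removed,
        qc_excluded=excluded,
        qc_flagged=flagged,
        qc_records=qc_annotated,
    )
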