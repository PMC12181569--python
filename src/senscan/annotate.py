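"""Expression-surrogate receptor calls, St Gallen-style subtypes, scoring.

Receptor status is called directly from normalized probe intensities:
estrogen receptor (ESR1) from probe set 205225_at at a cutoff of 500,
HER2/ERBB2 from probe set 216836_s_at at a cutoff of 4800 (values at or
above the cutoff call positive; the boundary convention is configurable).
Progesterone receptor is deliberately absent — the arrays carry no
reliable probe set for it.

The signature score is the unweighted mean over genes of per-gene mean
probe intensity, computed on the normalized (linear) scale. Scores scale
linearly with the intensities, which is why scoring always follows the
scaling normalization.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, List, Optional

import numpy as np
import pandas as pd

from .types import (
    NEGATIVE,
    POSITIVE,
    UNKNOWN,
    ExpressionMatrix,
    PipelineError,
    SignatureDefinition,
)

logger = logging.getLogger(__name__)

ER_PROBE = "205225_at"
ER_CUTOFF = 500.0
HER2_PROBE = "216836_s_at"
HER2_CUTOFF = 4800.0


def _call_probe(
    matrix: ExpressionMatrix,
    probe: str,
    cutoff: float,
    boundary_positive: bool = True,
) -> pd.Series:
    if probe not in matrix.probe_ids:
        raise PipelineError(f"receptor probe {probe!r} absent from matrix")
    x = matrix.values.loc[probe]
    positive = (x >= cutoff) if boundary_positive else (x > cutoff)
    calls = pd.Series(
        np.where(positive, POSITIVE, NEGATIVE), index=matrix.sample_ids
    )
    logger.info(
        "probe %s at cutoff %g: %d positive / %d samples",
        probe, cutoff, int(positive.sum()), matrix.n_samples,
    )
    return calls


def call_er(
    matrix: ExpressionMatrix,
    probe: str = ER_PROBE,
    cutoff: float = ER_CUTOFF,
    boundary_positive: bool = True,
) -> pd.Series:
    """Estrogen-receptor surrogate call per sample (positive/negative)."""
    return _call_probe(matrix, probe, cutoff, boundary_positive)


def call_her2(
    matrix: ExpressionMatrix,
    probe: str = HER2_PROBE,
    cutoff: float = HER2_CUTOFF,
    boundary_positive: bool = True,
) -> pd.Series:
    """HER2/ERBB2 surrogate call per sample (positive/negative)."""
    return _call_probe(matrix, probe, cutoff, boundary_positive)


def assign_subtype(
    er: str, her2: str, proliferation_high: Optional[bool] = None
) -> str:
    """Surrogate intrinsic subtype from ER/HER2 (+ optional proliferation).

    ER-/HER2- -> basal; ER-/HER2+ -> her2_enriched; ER+/HER2+ ->
    luminal_b. The ER+/HER2- split between luminal A and luminal B needs a
    proliferation marker; with ``proliferation_high`` unavailable the call
    defaults to luminal_a and a warning is logged once per process.
    Unknown receptor status yields subtype ``unknown``.
    """
    if er == UNKNOWN or her2 == UNKNOWN:
        return UNKNOWN
    if er == NEGATIVE:
        return "basal" if her2 == NEGATIVE else "her2_enriched"
    if her2 == POSITIVE:
        return "luminal_b"
    if proliferation_high is None:
        _warn_no_proliferation()
        return "luminal_a"
    return "luminal_b" if proliferation_high else "luminal_a"


_warned = False


def _warn_no_proliferation() -> None:
    global _warned
    if not _warned:
        logger.warning(
            "no proliferation marker supplied; ER+/HER2- samples are all "
            "assigned luminal_a"
        )
        _warned = True


def assign_subtypes(
    er: pd.Series,
    her2: pd.Series,
    proliferation_high: Optional[pd.Series] = None,
) -> pd.Series:
    """Vectorized :func:`assign_subtype` over aligned call series."""
    out = {}
    for sid in er.index:
        prolif = (
            None
            if proliferation_high is None or sid not in proliferation_high
            else bool(proliferation_high[sid])
        )
        out[sid] = assign_subtype(er[sid], her2[sid], prolif)
    return pd.Series(out, index=er.index)


@dataclass
class SignatureScores:
    """Per-sample signature scores plus a report of unusable genes/probes."""

    scores: pd.Series
    genes_used: List[str]
    genes_dropped: List[str] = field(default_factory=list)
    missing_probes: Dict[str, list] = field(default_factory=dict)


def score_signature(
    matrix: ExpressionMatrix,
    signature: SignatureDefinition,
    pool_probes: bool = False,
) -> SignatureScores:
    """Mean-signature score per sample.

    Default ("gene-then-probe") averaging: each gene's value is the mean of
    its available probes, and the score is the unweighted mean over genes —
    the signature is defined in gene-level units. ``pool_probes=True``
    instead averages all available probes in one pool (every probe weighted
    equally regardless of how many probes its gene has).

    Genes with no probe present in the matrix are excluded from the mean
    and reported in the result, never silently dropped; if no gene is
    representable a :class:`PipelineError` lists the missing probes.
    """
    present = set(matrix.probe_ids)
    gene_values = {}
    pooled: List[pd.Series] = []
    genes_dropped, missing = [], {}
    for gene, probes in signature.probes_of.items():
        avail = [p for p in probes if p in present]
        lost = [p for p in probes if p not in present]
        if lost:
            missing[gene] = lost
        if not avail:
            genes_dropped.append(gene)
            continue
        sub = matrix.values.loc[avail]
        gene_values[gene] = sub.mean(axis=0)
        pooled.append(sub)
    if not gene_values:
        raise PipelineError(
            f"signature {signature.name!r}: no gene has a probe in the "
            f"matrix; missing probes: {missing}"
        )
    if pool_probes:
        scores = pd.concat(pooled).mean(axis=0)
    else:
        scores = pd.DataFrame(gene_values).mean(axis=1)
    scores.name = signature.name
    if genes_dropped:
        logger.warning(
            "signature %s: %d/%d genes had no available probe: %s",
            signature.name, len(genes_dropped), len(signature.probes_of),
            genes_dropped,
        )
    return SignatureScores(
        scores=scores.reindex(matrix.sample_ids),
        genes_used=sorted(gene_values),
        genes_dropped=sorted(genes_dropped),
        missing_probes=missing,
    )
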