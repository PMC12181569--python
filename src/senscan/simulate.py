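"""Synthetic multi-dataset cohort generator with recorded ground truth.

The generator emulates the statistical structure the pipeline assumes, so
every downstream stage is testable without any external download:

* log-normal linear-scale intensities with a heavy right tail, multiplied
  by per-dataset scale factors in [0.5, 2] that make the scaling
  normalization consequential;
* receptor-surrogate probes (205225_at, 216836_s_at) drawn from
  two-component mixtures placed strictly on either side of the 500/4800
  call cutoffs at the configured positive fractions;
* signature probes sharing one latent per-sample senescence factor with
  probe-specific noise, so the mean-signature score carries a controllable
  link to the hazard;
* relapse-free survival from a proportional-hazards model (exponential
  baseline by default, Weibull shape exposed) with independent
  exponential censoring calibrated to the target event fraction plus an
  administrative cap;
* injected exact-copy duplicate samples spanning datasets, and QC
  outliers with several metrics displaced far outside the 95% band.

Construction detail that makes ground truth exact: the generator first
builds the matrix on the *normalized* scale — each sample's shared-probe
mean equals the 1000 target exactly, with receptor probes drawn truncated
on the correct side of their cutoffs and the remaining shared probes
rescaled to restore the mean — and only then multiplies by the dataset
scale factors to produce the raw cohort. Scaling normalization therefore
recovers the generated normalized matrix (to float precision), so the
recorded true score cutoff, true high/low grouping, and receptor statuses
coincide with what the pipeline computes.
"""

from __future__ import annotations

import dataclasses
import logging
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from . import annotate
from .types import (
    NEGATIVE,
    POSITIVE,
    UNKNOWN,
    ClinicalRecord,
    ExpressionMatrix,
    QCRecord,
    ScanResult,
    SignatureDefinition,
    SyntheticTruth,
)

logger = logging.getLogger(__name__)

_QC_BASELINE = {
    "background_signal": (60.0, 10.0),
    "raw_q": (2.0, 0.3),
    "percent_present": (45.0, 5.0),
    "ratio_3to5": (1.25, 0.15),
}
_OUTLIER_SHIFT_SD = 8.0  # displacement of spoiled continuous metrics


def default_signature(n_genes: int = 25) -> SignatureDefinition:
    """A synthetic senescence-style signature: every fifth gene carries two
    probe sets, the rest one (mirrors real signatures where some genes map
    to multiple probes)."""
    probes_of = {}
    for i in range(n_genes):
        gene = f"SEN{i + 1:03d}"
        probes = [f"{gene.lower()}_s_at"]
        if i % 5 == 0:
            probes.append(f"{gene.lower()}_x_at")
        probes_of[gene] = tuple(probes)
    return SignatureDefinition(name="synthetic_senescence", probes_of=probes_of)


def calibrate_censor_rate(
    hazards: np.ndarray, admin_cap: float, target_event_fraction: float
) -> float:
    """Censoring hazard giving the target expected event fraction.

    For exponential event time with rate lambda_i, independent exponential
    censoring with rate mu, and administrative cap tau, the event
    probability is lambda/(lambda+mu) * (1 - exp(-(lambda+mu)*tau)); the
    mean over samples is monotone decreasing in mu, so the root is found
    by bisection. Returns 0 when even uncensored follow-up cannot reach
    the target.
    """
    hazards = np.asarray(hazards, float)

    def event_fraction(mu: float) -> float:
        lam_mu = hazards + mu
        return float(
            np.mean(hazards / lam_mu * (1.0 - np.exp(-lam_mu * admin_cap)))
        )

    if event_fraction(0.0) <= target_event_fraction:
        logger.warning(
            "administrative cap alone yields <= target event fraction; "
            "censoring hazard set to 0"
        )
        return 0.0
    hi = 1.0
    while event_fraction(hi) > target_event_fraction:
        hi *= 4.0
    return float(
        brentq(
            lambda mu: event_fraction(mu) - target_event_fraction, 0.0, hi,
            xtol=1e-12,
        )
    )


def _truncated_log_offsets(
    rng: np.random.Generator, n: int, loc: float = 0.7, scale: float = 0.5
) -> np.ndarray:
    """|N(loc, scale)| clipped to [0.02, 2]: multiplicative distance from a
    call cutoff, bounded so receptor probes cannot dominate the shared
    mean."""
    return np.clip(np.abs(rng.normal(loc, scale, n)), 0.02, 2.0)


def generate_cohort(
    truth: SyntheticTruth,
) -> Tuple[ExpressionMatrix, List[ClinicalRecord], List[QCRecord], SyntheticTruth]:
    """Generate (expression, clinical, qc, filled-in truth) for one cohort.

    The returned truth is a copy of the input with realized quantities
    attached: dataset scale factors, censoring hazard, true score cutoff
    and per-sample high/low group, injected duplicate pairs and QC outlier
    ids, and the realized event fraction.
    """
    truth = dataclasses.replace(truth)
    rng = np.random.default_rng(truth.seed)
    n = truth.n_samples
    sample_ids = [f"S{i + 1:05d}" for i in range(n)]

    # dataset assignment: contiguous, roughly equal blocks
    block = np.array_split(np.arange(n), truth.n_datasets)
    dataset_names = [f"DS{k + 1:02d}" for k in range(truth.n_datasets)]
    dataset_of = pd.Series(index=pd.Index(sample_ids), dtype=object)
    for name, idx in zip(dataset_names, block):
        dataset_of.iloc[idx] = name
    platform_of = pd.Series("GPL570", index=dataset_of.index)

    if truth.dataset_scale_factors is None:
        truth.dataset_scale_factors = np.exp(
            rng.uniform(np.log(0.5), np.log(2.0), truth.n_datasets)
        )
    scale_of_sample = dataset_of.map(
        dict(zip(dataset_names, truth.dataset_scale_factors))
    ).astype(float)

    # ---- probe universe -------------------------------------------------
    signature = default_signature(truth.n_signature_genes)
    sig_probes = signature.all_probes
    filler = [f"flr{i + 1:04d}_at" for i in range(truth.n_filler_probes)]
    pspec = [f"psp{i + 1:04d}_at" for i in range(truth.n_platform_specific)]
    probes = (
        sig_probes + [annotate.ER_PROBE, annotate.HER2_PROBE] + filler + pspec
    )
    shared = pd.Index(sig_probes + [annotate.ER_PROBE, annotate.HER2_PROBE] + filler)

    # ---- intensities on the normalized scale ----------------------------
    z = rng.normal(0.0, 1.0, n)  # latent senescence factor
    values = pd.DataFrame(
        0.0, index=pd.Index(probes), columns=pd.Index(sample_ids)
    )
    for plist, is_sig in ((sig_probes, True), (filler + pspec, False)):
        mu = rng.normal(np.log(500.0), 0.7, len(plist))
        noise = rng.normal(0.0, 0.5, (len(plist), n))
        logx = mu[:, None] + noise
        if is_sig:
            loading = rng.uniform(0.3, 0.6, len(plist))
            logx = logx + loading[:, None] * z[None, :]
        values.loc[plist] = np.exp(logx)

    er_latent = rng.random(n) < truth.er_positive_fraction
    her2_latent = rng.random(n) < truth.her2_positive_fraction
    er_off = _truncated_log_offsets(rng, n)
    her2_off = _truncated_log_offsets(rng, n)
    values.loc[annotate.ER_PROBE] = annotate.ER_CUTOFF * np.exp(
        np.where(er_latent, er_off, -er_off)
    )
    values.loc[annotate.HER2_PROBE] = annotate.HER2_CUTOFF * np.exp(
        np.where(her2_latent, her2_off, -her2_off)
    )

    # pin each sample's shared-probe mean to exactly 1000 without moving
    # the receptor probes off their side of the cutoffs
    receptor = [annotate.ER_PROBE, annotate.HER2_PROBE]
    non_receptor_shared = shared.difference(receptor, sort=False)
    target_sum = 1000.0 * len(shared) - values.loc[receptor].sum(axis=0)
    if (target_sum <= 0).any():
        raise RuntimeError("receptor intensities exceed the shared-mean budget")
    factors = target_sum / values.loc[non_receptor_shared].sum(axis=0)
    adjust_rows = values.index.difference(receptor, sort=False)
    values.loc[adjust_rows] = values.loc[adjust_rows].mul(factors, axis=1)

    normalized = ExpressionMatrix(
        values=values,
        dataset_of=dataset_of,
        platform_of=platform_of,
        shared_probes=shared,
    )

    # ---- ground-truth score, grouping, survival -------------------------
    scores = annotate.score_signature(normalized, signature).scores
    score_arr = scores.to_numpy()
    truth.true_cutoff = float(
        np.quantile(score_arr, truth.true_group_quantile)
    )
    group = score_arr > truth.true_cutoff
    truth.true_group = pd.Series(group.astype(int), index=scores.index)

    if truth.effect_mode == "group":
        eta = truth.true_log_hr * group.astype(float)
    else:
        eta = truth.true_log_hr * (score_arr - score_arr.mean()) / score_arr.std()
    hazards = truth.baseline_hazard_rate * np.exp(eta)

    if truth.censor_rate is None:
        if truth.weibull_shape != 1.0:
            raise NotImplementedError(
                "automatic censoring calibration assumes the exponential "
                "baseline; pass censor_rate explicitly for Weibull shapes"
            )
        truth.censor_rate = calibrate_censor_rate(
            hazards, truth.admin_cap_months, truth.target_event_fraction
        )

    # T from cumulative hazard lambda * t^shape
    e = rng.exponential(1.0, n)
    t_event = (e / hazards) ** (1.0 / truth.weibull_shape)
    if truth.censor_rate > 0:
        t_cens = rng.exponential(1.0 / truth.censor_rate, n)
    else:
        t_cens = np.full(n, np.inf)
    t_cens = np.minimum(t_cens, truth.admin_cap_months)
    rfs = np.round(np.minimum(t_event, t_cens), truth.time_decimals)
    event = (t_event <= t_cens).astype(int)
    truth.realized_event_fraction = float(event.mean())

    # ---- clinical covariates --------------------------------------------
    node_known = rng.random(n) < truth.node_known_fraction
    node_pos = rng.random(n) < truth.node_positive_fraction
    age_known = rng.random(n) < 0.8
    size_known = rng.random(n) < 0.6
    age = np.clip(rng.normal(54.1, 12.5, n), 20.0, 95.0)
    # lognormal matched to mean 2.52, SD 1.42 cm
    size_sigma = np.sqrt(np.log(1.0 + (1.42 / 2.52) ** 2))
    size = np.clip(
        rng.lognormal(np.log(2.52) - size_sigma**2 / 2.0, size_sigma, n),
        0.1,
        12.0,
    )
    prolif_high = rng.random(n) < 0.15  # splits luminal B off ER+/HER2-

    clinical: List[ClinicalRecord] = []
    for i, sid in enumerate(sample_ids):
        er = POSITIVE if er_latent[i] else NEGATIVE
        her2 = POSITIVE if her2_latent[i] else NEGATIVE
        clinical.append(
            ClinicalRecord(
                sample_id=sid,
                rfs_months=float(rfs[i]),
                event=int(event[i]),
                er_status=er,
                her2_status=her2,
                node_status=(
                    (POSITIVE if node_pos[i] else NEGATIVE)
                    if node_known[i]
                    else UNKNOWN
                ),
                size_cm=float(size[i]) if size_known[i] else None,
                age_years=float(age[i]) if age_known[i] else None,
                subtype=annotate.assign_subtype(
                    er, her2, proliferation_high=bool(prolif_high[i])
                ),
            )
        )

    # ---- QC metrics ------------------------------------------------------
    qc_draws = {
        m: rng.normal(loc, sd, n) for m, (loc, sd) in _QC_BASELINE.items()
    }
    qc_draws["percent_present"] = np.clip(
        qc_draws["percent_present"], 0.0, 100.0
    )
    qc_draws["ratio_3to5"] = np.maximum(qc_draws["ratio_3to5"], 0.05)
    biob = np.ones(n, bool)

    # ---- injected duplicates and QC outliers -----------------------------
    duplicate_pairs: List[Tuple[str, str]] = []
    dup_targets: List[int] = []
    if truth.n_duplicates:
        if truth.n_datasets < 2:
            raise ValueError("duplicate injection needs >= 2 datasets")
        first, last = block[0], block[-1]
        if truth.n_duplicates > min(len(first), len(last)):
            raise ValueError("too many duplicate pairs for the dataset sizes")
        sources = rng.choice(first, truth.n_duplicates, replace=False)
        targets = rng.choice(last, truth.n_duplicates, replace=False)
        dup_targets = list(targets)
        for s, t in zip(sources, targets):
            duplicate_pairs.append((sample_ids[s], sample_ids[t]))
    truth.duplicate_pairs = duplicate_pairs

    outlier_ids: List[str] = []
    if truth.n_qc_outliers:
        eligible = np.setdiff1d(np.arange(n), np.asarray(dup_targets, int))
        chosen = rng.choice(eligible, truth.n_qc_outliers, replace=False)
        for i in chosen:
            for m in ("background_signal", "raw_q", "ratio_3to5"):
                qc_draws[m][i] += _OUTLIER_SHIFT_SD * _QC_BASELINE[m][1]
            biob[i] = False
            outlier_ids.append(sample_ids[i])
    truth.qc_outlier_ids = sorted(outlier_ids)

    # ---- raw matrix (dataset scale factors), duplicate overwrite ---------
    raw_values = normalized.values.mul(scale_of_sample, axis=1)
    for src_id, tgt_id in duplicate_pairs:
        raw_values[tgt_id] = raw_values[src_id]
        src_i, tgt_i = sample_ids.index(src_id), sample_ids.index(tgt_id)
        src_rec = clinical[src_i]
        clinical[tgt_i] = dataclasses.replace(src_rec, sample_id=tgt_id)
        for m in qc_draws:
            qc_draws[m][tgt_i] = qc_draws[m][src_i]
        biob[tgt_i] = biob[src_i]
        truth.true_group.loc[tgt_id] = truth.true_group.loc[src_id]

    qc = [
        QCRecord(
            sample_id=sid,
            background_signal=float(qc_draws["background_signal"][i]),
            raw_q=float(qc_draws["raw_q"][i]),
            percent_present=float(qc_draws["percent_present"][i]),
            biob_detected=bool(biob[i]),
            ratio_3to5=float(qc_draws["ratio_3to5"][i]),
        )
        for i, sid in enumerate(sample_ids)
    ]

    matrix = ExpressionMatrix(
        values=raw_values,
        dataset_of=dataset_of,
        platform_of=platform_of,
        shared_probes=shared,
    )
    logger.info(
        "generated cohort: n=%d, %d datasets, event fraction %.3f, "
        "%d duplicates, %d QC outliers",
        n, truth.n_datasets, truth.realized_event_fraction,
        len(duplicate_pairs), len(outlier_ids),
    )
    return matrix, clinical, qc, truth


# ---------------------------------------------------------------------------
# recovery report
# ---------------------------------------------------------------------------

def truth_report(
    truth: SyntheticTruth,
    scan: Optional[ScanResult] = None,
    removed_pairs: Optional[List[Tuple[str, str]]] = None,
    qc_excluded_ids: Optional[List[str]] = None,
) -> Dict[str, object]:
    """Compare pipeline outputs against the generator's ground truth.

    Reports estimated-vs-true hazard ratio (when a scan is supplied) and
    the duplicate/QC-outlier detection confusion counts (when the
    preprocessing outputs are supplied).
    """
    report: Dict[str, object] = {
        "true_hr": float(np.exp(truth.true_log_hr)),
        "true_cutoff": truth.true_cutoff,
    }
    known = set(truth.true_group.index) if truth.true_group is not None else None
    if scan is not None:
        report["estimated_hr"] = scan.selected_hr
        report["estimated_cutoff"] = scan.selected_cutoff
        report["selected_p"] = scan.selected_p
        report["log_hr_error"] = float(
            np.log(scan.selected_hr) - truth.true_log_hr
        )
    if removed_pairs is not None:
        detected = {pair[1] for pair in removed_pairs}
        injected = {pair[1] for pair in truth.duplicate_pairs}
        if known is not None and not detected <= known:
            raise ValueError(
                "duplicate report references samples outside the cohort"
            )
        tp = len(detected & injected)
        report["duplicates"] = {
            "true_positives": tp,
            "false_positives": len(detected - injected),
            "false_negatives": len(injected - detected),
            "precision": tp / len(detected) if detected else None,
            "recall": tp / len(injected) if injected else None,
        }
    if qc_excluded_ids is not None:
        excluded = set(qc_excluded_ids)
        if known is not None and not excluded <= known:
            raise ValueError(
                "QC report references samples outside the cohort"
            )
        injected = set(truth.qc_outlier_ids)
        tp = len(excluded & injected)
        report["qc_outliers"] = {
            "true_positives": tp,
            "false_positives": len(excluded - injected),
            "false_negatives": len(injected - excluded),
        }
    return report
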