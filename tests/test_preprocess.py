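"""Scaling normalization, duplicate-sample removal, and the QC filter."""

import dataclasses

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from senscan import (
    QCRecord,
    QCRule,
    merge_cohorts,
    qc_filter,
    remove_duplicates,
    scale_normalize,
)
from senscan.types import PipelineError

from conftest import toy_matrix


def frame(arr, probes, samples):
    return pd.DataFrame(arr, index=probes, columns=samples)


class TestScaleNormalize:
    def test_sample_already_at_target_is_unchanged(self):
        vals = frame([[500.0], [1500.0]], ["a", "b"], ["S1"])
        out = scale_normalize(toy_matrix(vals))
        np.testing.assert_allclose(out.values.to_numpy(), vals.to_numpy())

    def test_constant_matrix_becomes_target(self):
        vals = frame(np.full((4, 3), 7.0), list("abcd"), ["S1", "S2", "S3"])
        out = scale_normalize(toy_matrix(vals))
        np.testing.assert_allclose(out.values.to_numpy(), 1000.0)

    def test_hand_computed_factors_apply_to_all_probes(self):
        # shared probes a, b; platform-specific probe c is rescaled by the
        # same per-sample factor computed from a and b alone
        vals = frame(
            [[100.0, 400.0], [300.0, 600.0], [50.0, 80.0]],
            ["a", "b", "c"],
            ["S1", "S2"],
        )
        out = scale_normalize(toy_matrix(vals, shared=["a", "b"]))
        f1 = 1000.0 / 200.0  # mean(100, 300)
        f2 = 1000.0 / 500.0  # mean(400, 600)
        np.testing.assert_allclose(
            out.values.to_numpy(),
            [[100 * f1, 400 * f2], [300 * f1, 600 * f2], [50 * f1, 80 * f2]],
        )

    def test_idempotent_and_ratio_preserving(self, rng):
        vals = frame(
            rng.lognormal(6, 1, (10, 6)),
            [f"p{i}" for i in range(10)],
            [f"S{j}" for j in range(6)],
        )
        m = toy_matrix(vals, shared=[f"p{i}" for i in range(7)])
        once = scale_normalize(m)
        twice = scale_normalize(once)
        np.testing.assert_allclose(
            once.values.to_numpy(), twice.values.to_numpy(), rtol=1e-12
        )
        ratio_before = m.values.iloc[0] / m.values.iloc[1]
        ratio_after = once.values.iloc[0] / once.values.iloc[1]
        np.testing.assert_allclose(ratio_before, ratio_after, rtol=1e-12)

    @settings(derandomize=True, max_examples=25, deadline=None)
    @given(
        st.lists(
            st.floats(min_value=0.5, max_value=5e4),
            min_size=3,
            max_size=8,
        ),
        st.floats(min_value=10.0, max_value=5e4),
    )
    def test_shared_mean_hits_target_for_any_input(self, column, target):
        vals = frame(
            np.array(column)[:, None], [f"p{i}" for i in range(len(column))],
            ["S1"],
        )
        out = scale_normalize(toy_matrix(vals), target_mean=target)
        assert out.shared_values().mean(axis=0)["S1"] == pytest.approx(
            target, rel=1e-9
        )

    def test_all_zero_sample_names_the_offender(self):
        vals = frame([[0.0, 10.0], [0.0, 30.0]], ["a", "b"], ["bad", "ok"])
        with pytest.raises(PipelineError, match="bad"):
            scale_normalize(toy_matrix(vals))


def _cohort_with_duplicate(rng, copy_into="DS02"):
    probes = [f"p{i}" for i in range(6)]
    a = toy_matrix(
        frame(rng.lognormal(6, 1, (6, 4)), probes, ["A1", "A2", "A3", "A4"]),
        dataset="DS01",
    )
    b_vals = frame(rng.lognormal(6, 1, (6, 3)), probes, ["B1", "B2", "B3"])
    b_vals["B2"] = a.values["A3"]  # exact copy across datasets
    b = toy_matrix(b_vals, dataset=copy_into)
    return a, b


class TestRemoveDuplicates:
    def test_later_copy_removed_first_publication_retained(self, rng):
        a, b = _cohort_with_duplicate(rng)
        merged, removed = remove_duplicates([a, b])
        assert removed == [("A3", "B2")]
        assert "B2" not in merged.sample_ids and "A3" in merged.sample_ids

    def test_no_duplicates_returns_concatenation(self, rng):
        probes = [f"p{i}" for i in range(5)]
        a = toy_matrix(frame(rng.lognormal(6, 1, (5, 3)), probes, list("XYZ")))
        b = toy_matrix(
            frame(rng.lognormal(6, 1, (5, 2)), probes, list("UV")),
            dataset="DS02",
        )
        merged, removed = remove_duplicates([a, b])
        assert removed == []
        assert list(merged.sample_ids) == list("XYZUV")

    def test_three_way_group_keeps_single_survivor(self, rng):
        probes = [f"p{i}" for i in range(5)]
        col = rng.lognormal(6, 1, 5)
        mats = []
        for k, sid in enumerate(["A1", "B1", "C1"]):
            vals = frame(
                np.column_stack([col, rng.lognormal(6, 1, 5)]),
                probes,
                [sid, f"{sid}x"],
            )
            mats.append(toy_matrix(vals, dataset=f"DS{k + 1:02d}"))
        merged, removed = remove_duplicates(mats)
        assert sorted(r[1] for r in removed) == ["B1", "C1"]
        assert all(r[0] == "A1" for r in removed)
        # brute-force pairwise comparison agrees on who duplicates whom
        big = merge_cohorts(mats)
        arr = big.values.round(10).to_numpy()
        pairs = {
            (big.sample_ids[i], big.sample_ids[j])
            for i in range(arr.shape[1])
            for j in range(i + 1, arr.shape[1])
            if np.array_equal(arr[:, i], arr[:, j])
        }
        assert pairs == {("A1", "B1"), ("A1", "C1"), ("B1", "C1")}

    def test_order_stability_within_dataset(self, rng):
        a, b = _cohort_with_duplicate(rng)
        _, removed1 = remove_duplicates([a, b])
        b_perm = b.subset_samples(["B3", "B2", "B1"])
        _, removed2 = remove_duplicates([a, b_perm])
        assert removed1 == removed2

    def test_normalized_scalar_multiples_collapse(self, rng):
        # the same array re-scaled (different dataset scale factor) becomes
        # an exact duplicate after scaling normalization
        probes = [f"p{i}" for i in range(6)]
        base = rng.lognormal(6, 1, 6)
        vals = frame(
            np.column_stack([base, 1.7 * base, rng.lognormal(6, 1, 6)]),
            probes,
            ["A1", "B1", "B2"],
        )
        m = toy_matrix(vals)
        m.dataset_of[:] = ["DS01", "DS02", "DS02"]
        norm = scale_normalize(m)
        _, removed = remove_duplicates(norm, dataset_priority=["DS01", "DS02"])
        assert removed == [("A1", "B1")]


def _qc_record(sid, **overrides):
    base = dict(
        sample_id=sid,
        background_signal=60.0,
        raw_q=2.0,
        percent_present=45.0,
        biob_detected=True,
        ratio_3to5=1.25,
    )
    base.update(overrides)
    return QCRecord(**base)


def _batch(n=20, jitter=0.01):
    # tight cluster so displaced samples are unambiguous outliers
    return [
        _qc_record(
            f"S{i}",
            background_signal=60.0 + jitter * ((-1) ** i),
            raw_q=2.0 + 0.001 * i,
            percent_present=45.0 + 0.01 * i,
            ratio_3to5=1.25 + 0.001 * i,
        )
        for i in range(n)
    ]


class TestQCFilter:
    def test_sample_at_batch_mean_passes(self):
        records = _batch()
        annotated, passed, flagged, excluded = qc_filter(records)
        assert records[0].sample_id in passed
        assert annotated[0].status == "pass"
        assert all(annotated[0].metric_pass.values())

    def test_three_failures_excluded_under_default_rule(self):
        records = _batch() + [
            _qc_record(
                "bad",
                biob_detected=False,
                background_signal=60.0 + 5 * 10.0,
                raw_q=2.0 + 5 * 0.3,
            )
        ]
        _, _, _, excluded = qc_filter(records)
        assert excluded == ["bad"]

    def test_single_failure_flagged_not_excluded(self):
        records = _batch() + [_qc_record("weird", ratio_3to5=9.0)]
        annotated, passed, flagged, excluded = qc_filter(records)
        assert flagged == ["weird"]
        assert excluded == []
        status = {r.sample_id: r for r in annotated}
        assert status["weird"].metric_pass["ratio_3to5"] is False

    def test_stricter_rule_excludes_single_failure(self):
        records = _batch() + [_qc_record("weird", ratio_3to5=9.0)]
        _, _, _, excluded = qc_filter(
            records, QCRule(exclude_min_failures=1)
        )
        assert excluded == ["weird"]

    @pytest.mark.parametrize("n_fail,expected", [(0, "pass"), (1, "flagged"),
                                                 (2, "flagged"), (3, "excluded"),
                                                 (4, "excluded")])
    def test_rule_table_enumeration(self, n_fail, expected):
        spoil = [
            dict(background_signal=500.0),
            dict(raw_q=50.0),
            dict(ratio_3to5=30.0),
            dict(biob_detected=False),
        ]
        overrides = {}
        for s in spoil[:n_fail]:
            overrides.update(s)
        records = _batch() + [_qc_record("probe", **overrides)]
        annotated, *_ = qc_filter(records)
        assert annotated[-1].status == expected

    def test_partition_is_exact(self, small_cohort):
        _, _, qc, _ = small_cohort
        _, passed, flagged, excluded = qc_filter(qc)
        ids = [r.sample_id for r in qc]
        union = set(passed) | set(flagged) | set(excluded)
        assert union == set(ids)
        assert len(passed) + len(flagged) + len(excluded) == len(ids)

    def test_too_few_samples_rejected(self):
        with pytest.raises(PipelineError):
            qc_filter(_batch(2))
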