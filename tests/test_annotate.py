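"""Receptor surrogate calls, subtype assignment, signature scoring."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from senscan import (
    SignatureDefinition,
    assign_subtype,
    call_er,
    call_her2,
    score_signature,
)
from senscan.types import PipelineError

from conftest import toy_matrix


def receptor_matrix(er_vals, her2_vals):
    samples = [f"S{i}" for i in range(len(er_vals))]
    vals = pd.DataFrame(
        [er_vals, her2_vals, [100.0] * len(er_vals)],
        index=["205225_at", "216836_s_at", "filler_at"],
        columns=samples,
    )
    return toy_matrix(vals)


class TestReceptorCalls:
    @pytest.mark.parametrize(
        "intensity,expected",
        [(501.0, "positive"), (499.0, "negative"), (500.0, "positive")],
    )
    def test_er_cutoff_500(self, intensity, expected):
        m = receptor_matrix([intensity], [100.0])
        assert call_er(m).iloc[0] == expected

    @pytest.mark.parametrize(
        "intensity,expected",
        [(4801.0, "positive"), (0.0, "negative"), (4800.0, "positive")],
    )
    def test_her2_cutoff_4800(self, intensity, expected):
        m = receptor_matrix([100.0], [intensity])
        assert call_her2(m).iloc[0] == expected

    def test_boundary_convention_configurable(self):
        m = receptor_matrix([500.0], [4800.0])
        assert call_er(m, boundary_positive=False).iloc[0] == "negative"

    def test_missing_probe_is_configuration_error(self):
        m = receptor_matrix([600.0], [100.0])
        with pytest.raises(PipelineError):
            call_er(m, probe="999999_at")

    def test_monotone_in_intensity(self, rng):
        # raising any sample's intensity never flips positive -> negative
        lo = rng.uniform(0, 5000, 50)
        hi = lo + rng.uniform(0, 2000, 50)
        calls_lo = call_er(receptor_matrix(lo, np.full(50, 100.0)))
        calls_hi = call_er(receptor_matrix(hi, np.full(50, 100.0)))
        flipped = (calls_lo == "positive") & (calls_hi == "negative")
        assert not flipped.any()


class TestSubtype:
    @pytest.mark.parametrize(
        "er,her2,prolif,expected",
        [
            ("negative", "negative", None, "basal"),
            ("negative", "positive", None, "her2_enriched"),
            ("positive", "positive", None, "luminal_b"),
            ("positive", "positive", False, "luminal_b"),
            ("positive", "negative", True, "luminal_b"),
            ("positive", "negative", False, "luminal_a"),
            ("positive", "negative", None, "luminal_a"),
            ("unknown", "positive", None, "unknown"),
            ("positive", "unknown", True, "unknown"),
        ],
    )
    def test_st_gallen_surrogate_table(self, er, her2, prolif, expected):
        assert assign_subtype(er, her2, prolif) == expected


def sig(probes_of, name="sig"):
    return SignatureDefinition(name=name, probes_of=probes_of)


def expr(values_by_probe, samples=("S1",)):
    vals = pd.DataFrame(values_by_probe, index=list(samples)).T
    return toy_matrix(vals)


class TestScoreSignature:
    def test_single_gene_single_probe_is_identity(self):
        m = expr({"pA": [321.0]})
        out = score_signature(m, sig({"G1": ("pA",)}))
        assert out.scores["S1"] == 321.0

    def test_two_genes_arithmetic_mean(self):
        m = expr({"pA": [100.0], "pB": [300.0]})
        out = score_signature(m, sig({"G1": ("pA",), "G2": ("pB",)}))
        assert out.scores["S1"] == 200.0

    def test_gene_then_probe_nested_mean(self):
        # five genes, one with two probes: probes average within the gene
        # first, so the two-probe gene is not over-weighted
        m = expr(
            {
                "pA1": [100.0],
                "pA2": [200.0],
                "pB": [50.0],
                "pC": [250.0],
                "pD": [400.0],
                "pE": [1000.0],
            }
        )
        s = sig(
            {
                "A": ("pA1", "pA2"),
                "B": ("pB",),
                "C": ("pC",),
                "D": ("pD",),
                "E": ("pE",),
            }
        )
        # gene values: A=150, B=50, C=250, D=400, E=1000 -> mean 370
        assert score_signature(m, s).scores["S1"] == pytest.approx(370.0)
        # probe pooling weights every probe equally instead
        pooled = score_signature(m, s, pool_probes=True)
        assert pooled.scores["S1"] == pytest.approx(
            (100 + 200 + 50 + 250 + 400 + 1000) / 6
        )

    def test_invariant_to_gene_and_probe_order(self, rng):
        probes = {f"p{i}": rng.lognormal(6, 1, 4) for i in range(6)}
        m = expr(probes, samples=[f"S{j}" for j in range(4)])
        fwd = sig({"A": ("p0", "p1"), "B": ("p2",), "C": ("p3", "p4", "p5")})
        rev = sig({"C": ("p5", "p4", "p3"), "B": ("p2",), "A": ("p1", "p0")})
        pd.testing.assert_series_equal(
            score_signature(m, fwd).scores,
            score_signature(m, rev).scores,
            check_names=False,
        )

    def test_homogeneous_of_degree_one(self, rng):
        probes = {f"p{i}": rng.lognormal(6, 1, 3) for i in range(4)}
        m = expr(probes, samples=["S1", "S2", "S3"])
        s = sig({"A": ("p0", "p1"), "B": ("p2",), "C": ("p3",)})
        base = score_signature(m, s).scores
        scaled_m = m.copy()
        scaled_m.values *= 3.5
        scaled = score_signature(scaled_m, s).scores
        np.testing.assert_allclose(scaled, 3.5 * base, rtol=1e-12)

    def test_missing_probes_reported_not_silently_dropped(self):
        m = expr({"pA": [100.0], "pB1": [40.0]})
        s = sig({"A": ("pA",), "B": ("pB1", "pB_gone"), "C": ("pC_gone",)})
        out = score_signature(m, s)
        assert out.genes_dropped == ["C"]
        assert out.missing_probes == {"B": ["pB_gone"], "C": ["pC_gone"]}
        assert out.scores["S1"] == pytest.approx((100.0 + 40.0) / 2)

    def test_no_representable_gene_is_scoring_error(self):
        m = expr({"pX": [1.0]})
        with pytest.raises(PipelineError, match="missing"):
            score_signature(m, sig({"A": ("gone_at",)}))


@settings(derandomize=True, max_examples=30, deadline=None)
@given(st.floats(min_value=0.1, max_value=1e4), st.floats(min_value=0.1, max_value=1e4))
def test_score_lies_between_gene_extremes(v1, v2):
    m = expr({"pA": [v1], "pB": [v2]})
    score = score_signature(m, sig({"A": ("pA",), "B": ("pB",)})).scores["S1"]
    assert min(v1, v2) - 1e-9 <= score <= max(v1, v2) + 1e-9
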