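"""Footprint calling, confidence tiers, estimation, and enrichment test."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from sbkit import simulate as sim
from sbkit.footprints import (
    FootprintCandidate,
    ValidationRecord,
    annotate_candidates,
    assign_confidence,
    call_candidates,
    estimate_true_footprints,
    exon_enrichment_test,
    pooled_validation_rate,
)
from sbkit.genome import AnnotationSet, GenomicInterval, ReferenceGenome

VALIDATION = [ValidationRecord("high", 12, 12), ValidationRecord("low", 18, 1)]


def table(sites, plus=5, minus=5):
    return {("chr1", p): (plus, minus) for p in sites}


class TestCallCandidates:
    def test_filters_apply_in_order(self):
        # tumor has {a,b,c,d}; a in normal, b clonal, c shared with
        # another tumor; only d survives
        a, b, c, d = 10, 20, 30, 40
        calls = call_candidates(
            tumor_tables={"t1": table([a, b, c, d]), "t2": table([c])},
            normal_table=table([a]),
            clonal_insertions={"t1": [("chr1", b)]},
        )
        assert [cand.pos for cand in calls["t1"]] == [d]
        assert calls["t2"] == []  # c was redundant across tumors

    def test_dual_strand_rule(self):
        calls = call_candidates(
            tumor_tables={"t1": {("chr1", 10): (5, 0), ("chr1", 20): (1, 1)}},
            normal_table={},
        )
        assert [c.pos for c in calls["t1"]] == [20]

    def test_missing_normal_is_an_error(self):
        with pytest.raises(ValueError, match="normal"):
            call_candidates({"t1": table([10])}, None)

    def test_set_subtraction_steps_commute(self):
        rng = np.random.default_rng(0)
        sites = lambda: table(rng.choice(200, size=40, replace=False))
        t1, t2, normal = sites(), sites(), sites()
        clonal = {"t1": list(sites())}
        ref = call_candidates({"t1": t1, "t2": t2}, normal, clonal)
        # permuting the sample order must not change any sample's calls
        perm = call_candidates({"t2": t2, "t1": t1}, normal, clonal)
        assert {s: [c.pos for c in v] for s, v in ref.items()} == {
            s: [c.pos for c in v] for s, v in perm.items()
        }

    def test_recall_on_simulated_library(self):
        base = sim.random_genome({"chr1": 20_000}, seed=40)
        index_pos = [p for p in range(500, 20_000, 500)]
        seq = list(base["chr1"])
        for p in index_pos:
            seq[p : p + 2] = "TA"
        genome = ReferenceGenome({"chr1": "".join(seq)})
        footprints = {"t1": [("chr1", 500), ("chr1", 1000)], "t2": [("chr1", 1500)]}
        insertions = {"t1": [("chr1", 2000)], "t2": [("chr1", 2500)]}
        tables, truth = sim.simulate_footprint_library(
            genome, footprints, insertions, depth=500, seed=41
        )
        clonal = {s: list(v) for s, v in insertions.items()}
        calls = call_candidates(
            {s: tables[s] for s in ("t1", "t2")}, tables["normal"], clonal
        )
        called = {s: {(c.chrom, c.pos) for c in v} for s, v in calls.items()}
        # every endogenous and ITR-junction locus is filtered out
        for s in ("t1", "t2"):
            bad = truth[
                (truth["sample"] == s) & (truth["truth_class"] != "footprint")
            ]
            assert not called[s] & set(zip(bad["chrom"], bad["pos"]))
            # at depth 500 every true footprint has reads on both strands
            assert called[s] == set(footprints[s])


class TestConfidence:
    def test_percentile_threshold(self):
        # 25th percentile of {100,200,300,400} by linear interpolation is 175
        assert float(np.percentile([100, 200, 300, 400], 25)) == 175.0
        cand = [FootprintCandidate("t", "c", 1, 90, 90)]  # depth 180
        assert assign_confidence(cand, [100, 200, 300, 400], 25)[0].confidence == "high"
        cand = [FootprintCandidate("t", "c", 1, 85, 85)]  # depth 170
        assert assign_confidence(cand, [100, 200, 300, 400], 25)[0].confidence == "low"

    def test_below_min_reference_is_low_for_any_percentile(self):
        cand = [FootprintCandidate("t", "c", 1, 10, 10)]  # depth 20
        for q in (0, 25, 50, 99):
            assert assign_confidence(cand, [100, 200], q)[0].confidence == "low"

    def test_percentile_zero_boundary(self):
        cand = [FootprintCandidate("t", "c", 1, 50, 50)]  # depth 100 == min
        assert assign_confidence(cand, [100, 200], 0)[0].confidence == "high"

    def test_empty_reference_rejected(self):
        with pytest.raises(ValueError, match="non-empty"):
            assign_confidence([], [])

    def test_high_tier_is_more_precise_than_low_on_known_truth(self):
        """Deep (clonal-scale) footprints land in the high tier; shallow
        subclonal ITR leftovers land low — precision must be ordered."""
        rng = np.random.default_rng(50)
        true_fp = [
            FootprintCandidate("t", "c", i, int(p), int(m))
            for i, (p, m) in enumerate(zip(rng.poisson(100, 40), rng.poisson(100, 40)))
        ]
        artifacts = [
            FootprintCandidate("t", "c", 1000 + i, int(p) + 1, int(m) + 1)
            for i, (p, m) in enumerate(zip(rng.poisson(8, 60), rng.poisson(8, 60)))
        ]
        truth = {c.pos: c.pos < 1000 for c in true_fp + artifacts}
        clonal_depths = rng.poisson(200, 30)
        tiered = assign_confidence(true_fp + artifacts, clonal_depths, 25)
        prec = {}
        for tier in ("high", "low"):
            members = [c for c in tiered if c.confidence == tier]
            assert members
            prec[tier] = np.mean([truth[c.pos] for c in members])
        assert prec["high"] >= prec["low"]


class TestEstimation:
    @pytest.mark.parametrize(
        "n_high,n_low,expected", [(149, 69, 153), (133, 104, 139), (2, 95, 8)]
    )
    def test_reported_estimates(self, n_high, n_low, expected):
        assert estimate_true_footprints(n_high, n_low, VALIDATION) == expected

    def test_pooled_rates(self):
        rates = pooled_validation_rate(VALIDATION)
        assert rates["high"] == 1.0
        assert round(100 * rates["low"], 1) == 5.6

    def test_zero_tested_rejected(self):
        bad = [ValidationRecord("high", 0, 0), ValidationRecord("low", 18, 1)]
        with pytest.raises(ValueError, match="no tested"):
            estimate_true_footprints(10, 10, bad)

    @settings(max_examples=50, derandomize=True)
    @given(
        nh=st.integers(0, 300),
        nl=st.integers(0, 300),
        dh=st.integers(0, 50),
        dl=st.integers(0, 50),
    )
    def test_monotone_in_counts_and_rates(self, nh, nl, dh, dl):
        recs = [ValidationRecord("high", 12, 12), ValidationRecord("low", 18, 1)]
        base = estimate_true_footprints(nh, nl, recs)
        assert estimate_true_footprints(nh + dh, nl + dl, recs) >= base
        better = [ValidationRecord("high", 12, 12), ValidationRecord("low", 18, 2)]
        assert estimate_true_footprints(nh, nl, better) >= base


class TestAnnotation:
    def test_summary_counts_and_percentages(self, toy_annotation):
        cands = {
            "t1": [
                FootprintCandidate("t1", "chr1", 150, 2, 2),  # exon
                FootprintCandidate("t1", "chr1", 500, 2, 2),  # intron
                FootprintCandidate("t1", "chr1", 600, 2, 2),  # intron
                FootprintCandidate("t1", "chr1", 5000, 2, 2),  # intergenic
            ]
        }
        annotated, summary = annotate_candidates(cands, toy_annotation)
        assert [c.feature_class for c in annotated["t1"]] == [
            "exon",
            "intron",
            "intron",
            "intergenic",
        ]
        row = summary[summary["sample"] == "t1"].iloc[0]
        assert row["n_candidates"] == 4
        assert row["pct_intron"] == 50.0
        assert row["pct_exon"] == 25.0
        total = summary[summary["sample"] == "total"].iloc[0]
        assert total["n_candidates"] == 4

    def test_empty_candidate_set(self, toy_annotation):
        annotated, summary = annotate_candidates({"t1": []}, toy_annotation)
        assert annotated["t1"] == []
        total = summary[summary["sample"] == "total"].iloc[0]
        assert total["n_candidates"] == 0 and total["pct_exon"] == 0.0


class TestEnrichmentTest:
    def test_null_gives_z_zero(self):
        res = exon_enrichment_test(15, 1000, 0.015)
        assert res.z == 0.0 and res.p_value == 1.0

    def test_against_normal_cdf_oracle(self):
        res = exon_enrichment_test(13, 552, 0.015)
        z = (13 / 552 - 0.015) / math.sqrt(0.015 * 0.985 / 552)
        assert res.z == pytest.approx(z)
        assert res.p_value == pytest.approx(2 * (1 - stats.norm.cdf(abs(z))), abs=1e-12)
        assert res.p_value == pytest.approx(0.0984, abs=5e-4)

    def test_doubling_n_scales_z_by_sqrt2(self):
        r1 = exon_enrichment_test(13, 552, 0.015)
        r2 = exon_enrichment_test(26, 1104, 0.015)
        assert r2.z == pytest.approx(r1.z * math.sqrt(2))

    def test_invalid_p0(self):
        for p0 in (0.0, 1.0, -0.1, 1.5):
            with pytest.raises(ValueError):
                exon_enrichment_test(1, 10, p0)

    def test_small_expected_count_warns(self):
        with pytest.warns(UserWarning, match="normal approximation"):
            exon_enrichment_test(1, 100, 0.01)
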