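"""Transposition mechanics and screen simulation."""

import numpy as np
import pytest

from sbkit import simulate as sim
from sbkit.genome import FOOTPRINT_VARIANTS, ReferenceGenome, build_ta_index, scan_motif

TN = "GGGCCC"  # stand-in transposon body


class TestInsertionExcision:
    def test_insertion_duplicates_target_ta(self):
        out = sim.apply_insertion("AATAGC", 2, TN)
        assert out == "AATA" + TN + "TAGC"
        assert len(out) - 6 == len(TN) + 2

    def test_insertion_requires_ta(self):
        with pytest.raises(ValueError, match="not a TA"):
            sim.apply_insertion("AATAGC", 1, TN)

    @pytest.mark.parametrize("variant,expected", [
        ("TACAGTA", "AATACAGTAGC"),
        ("TACTGTA", "AATACTGTAGC"),
    ])
    def test_excision_leaves_five_bp_footprint(self, variant, expected):
        inserted = sim.apply_insertion("AATAGC", 2, TN)
        out = sim.apply_excision(inserted, 2, TN, variant)
        assert out == expected
        assert len(out) - len("AATAGC") == 5

    def test_excision_requires_integrated_transposon(self):
        with pytest.raises(ValueError, match="no integrated transposon"):
            sim.apply_excision("AATAGC", 2, TN)

    def test_round_trip_differs_only_by_footprint(self, small_genome):
        seq = small_genome["chr1"]
        index = build_ta_index(small_genome)
        rng = np.random.default_rng(0)
        for p in rng.choice(index.positions["chr1"], size=20, replace=False):
            p = int(p)
            for variant in FOOTPRINT_VARIANTS:
                out = sim.apply_excision(sim.apply_insertion(seq, p, TN), p, TN, variant)
                assert out == seq[:p] + variant + seq[p + 2 :]
                # the footprint locus carries the consensus and is found by the scanner
                hits = scan_motif(ReferenceGenome({"c": out}), "TACWGTA", both_strands=False)
                assert p in [h.start for h in hits]


@pytest.fixture(scope="module")
def setup(two_chrom_genome, two_chrom_ta_index):
    concat = sim.ConcatemerSpec(chrom="chr1", position=100_000)
    return two_chrom_genome, two_chrom_ta_index, concat


class TestLocalHopping:

    def test_all_local_when_p_local_one(self, setup):
        genome, index, concat = setup
        events = sim.simulate_transposition(
            genome, concat, 200, p_local=1.0, local_window=50_000, seed=1, ta_index=index
        )
        for e in events:
            assert e.chrom == "chr1"
            assert abs(e.target - concat.position) <= 50_000

    def test_local_fraction_matches_ta_share_when_p_local_zero(self, setup):
        genome, index, concat = setup
        window = 50_000
        events = sim.simulate_transposition(
            genome, concat, 10_000, p_local=0.0, local_window=window, seed=2, ta_index=index
        )
        n_local_ta = index.count_in("chr1", concat.position - window, concat.position + window)
        # p_local=0 samples uniformly from the non-local stratum, so the
        # chance of landing inside the window by accident is zero
        share = n_local_ta / index.total_ta_count
        assert 0.05 < share < 0.5  # the stratification is non-trivial
        in_window = sum(
            1
            for e in events
            if e.chrom == "chr1" and abs(e.target - concat.position) <= window
        )
        assert in_window == 0

    def test_mixture_fraction_within_binomial_noise(self, setup):
        genome, index, concat = setup
        window, p_local, n = 50_000, 0.85, 10_000
        events = sim.simulate_transposition(
            genome, concat, n, p_local=p_local, local_window=window, seed=3, ta_index=index
        )
        in_window = sum(
            1
            for e in events
            if e.chrom == "chr1" and abs(e.target - concat.position) <= window
        )
        sd = np.sqrt(n * p_local * (1 - p_local))
        assert abs(in_window - n * p_local) < 3 * sd

    def test_seed_reproducibility(self, setup):
        genome, index, concat = setup
        a = sim.simulate_transposition(genome, concat, 50, seed=9, ta_index=index)
        b = sim.simulate_transposition(genome, concat, 50, seed=9, ta_index=index)
        assert a == b

    def test_targets_are_ta_positions(self, setup):
        genome, index, concat = setup
        events = sim.simulate_transposition(genome, concat, 100, seed=4, ta_index=index)
        for e in events:
            assert genome[e.chrom][e.target : e.target + 2] == "TA"


class TestReplicates:
    def test_tier_means_recovered_over_seeds(self, two_chrom_ta_index):
        """Pure-Poisson replicates recover the 100/50/12.5 spike tiers
        within 10% on average (law of large numbers)."""
        from sbkit.clonality import normalize_to_max

        tumor = sim.make_clonal_tumor(
            two_chrom_ta_index, seed=5, tier_sizes={1.0: 1, 0.5: 1, 0.125: 1}, n_background=0
        )
        by_tier = {1.0: [], 0.5: [], 0.125: []}
        site_tier = dict(tumor.clone_sites)
        for s in range(100):
            (prof,) = sim.simulate_replicates(tumor, n_replicates=1, depth=10_000, seed=s)
            norm = normalize_to_max(prof)
            for site, v in norm.values.items():
                by_tier[site_tier[site]].append(v)
        for tier, expected in [(1.0, 100.0), (0.5, 50.0), (0.125, 12.5)]:
            mean = np.mean(by_tier[tier])
            assert abs(mean - expected) / expected < 0.10

    def test_absent_sites_never_appear(self, two_chrom_ta_index):
        tumor = sim.make_clonal_tumor(two_chrom_ta_index, seed=6, n_background=0)
        profiles = sim.simulate_replicates(tumor, depth=5_000, seed=7)
        allowed = set(tumor.all_sites)
        for prof in profiles:
            assert set(prof.counts) <= allowed

    def test_ligation_points_bounded_by_reads(self, two_chrom_ta_index):
        tumor = sim.make_clonal_tumor(two_chrom_ta_index, seed=8)
        for prof in sim.simulate_replicates(tumor, depth=30_000, seed=9):
            for reads, lps in prof.counts.values():
                assert 0 <= lps <= reads
            assert prof.total_reads == sum(r for r, _ in prof.counts.values())

    def test_seed_reproduces_counts_exactly(self, two_chrom_ta_index):
        tumor = sim.make_clonal_tumor(two_chrom_ta_index, seed=10)
        a = sim.simulate_replicates(tumor, depth=10_000, seed=11)
        b = sim.simulate_replicates(tumor, depth=10_000, seed=11)
        assert [p.counts for p in a] == [p.counts for p in b]

    def test_negative_binomial_inflates_variance(self, two_chrom_ta_index):
        tumor = sim.make_clonal_tumor(
            two_chrom_ta_index, seed=12, tier_sizes={1.0: 1}, n_background=0
        )
        site = next(iter(tumor.clone_sites))
        draws = {disp: [] for disp in (0.0, 0.5)}
        for disp in draws:
            for s in range(60):
                (prof,) = sim.simulate_replicates(
                    tumor, n_replicates=1, depth=1_000, dispersion=disp, seed=1000 + s
                )
                draws[disp].append(prof.counts.get(site, (0, 0))[0])
        assert np.var(draws[0.5]) > 2 * np.var(draws[0.0])

    def test_parameter_validation(self, two_chrom_ta_index):
        tumor = sim.make_clonal_tumor(two_chrom_ta_index, seed=13)
        with pytest.raises(ValueError):
            sim.simulate_replicates(tumor, n_replicates=0)
        with pytest.raises(ValueError):
            sim.simulate_replicates(tumor, depth=0)


class TestFootprintLibrary:
    @pytest.fixture()
    def library(self):
        # genome with 2 endogenous footprint-consensus loci plus room
        # for 1 true footprint and 1 surviving insertion per tumor
        rng = np.random.default_rng(20)
        base = sim.random_genome({"chr1": 4_000}, seed=20)
        seq = list(base["chr1"])
        seq[100:107] = "TACAGTA"
        seq[900:907] = "TACTGTA"
        seq[2000:2002] = "TA"
        seq[3000:3002] = "TA"
        genome = ReferenceGenome({"chr1": "".join(seq)})
        tables, truth = sim.simulate_footprint_library(
            genome,
            footprint_sites={"t1": [("chr1", 2000)]},
            insertion_sites={"t1": [("chr1", 3000)]},
            depth=1_000,
            seed=21,
        )
        return genome, tables, truth

    def test_truth_table_distinguishes_classes(self, library):
        genome, tables, truth = library
        t1 = truth[truth["sample"] == "t1"]
        classes = dict(zip(zip(t1["chrom"], t1["pos"]), t1["truth_class"]))
        assert classes[("chr1", 2000)] == "footprint"
        assert classes[("chr1", 3000)] == "itr_junction"
        assert classes[("chr1", 100)] == "endogenous"
        assert classes[("chr1", 900)] == "endogenous"

    def test_normal_contains_exactly_endogenous_loci(self, library):
        genome, tables, truth = library
        normal = truth[truth["sample"] == "normal"]
        assert set(normal["truth_class"]) == {"endogenous"}
        endo = set(
            truth.loc[
                (truth["sample"] == "t1") & (truth["truth_class"] == "endogenous"),
                "pos",
            ]
        )
        assert set(normal["pos"]) == endo

    def test_both_strands_covered_at_high_depth(self, library):
        genome, tables, truth = library
        t = tables["t1"]
        fp = t[(t["chrom"] == "chr1") & (t["pos"] == 2000)].iloc[0]
        assert fp["plus_reads"] >= 1 and fp["minus_reads"] >= 1
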