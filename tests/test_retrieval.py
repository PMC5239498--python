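"""IS retrieval: tag trimming, seed mapping, collapsing, collision filter."""
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sbinsite import retrieval, simulate
from sbinsite.types import LamRead, ToyGenome

from conftest import brute_force_single_linkage, make_collection, rng_seeds

TAG = simulate.DEFAULT_VECTOR_TAG


def _read(seq, rid="r1"):
    return LamRead(read_id=rid, sample_id="S1", sequence=seq)


class TestTrimVectorTag:
    def test_exact_prefix_emitted_verbatim(self):
        flank = "TACCGTTAGGCCATTAGGCCATTAGGCATC"
        flanks, tallies = retrieval.trim_vector_tag([_read(TAG + flank)])
        assert flanks == [("r1", flank)]
        assert tallies == {"no_tag": 0, "short_flank": 0}

    def test_two_tag_mismatches_discarded(self):
        bad = "GG" + TAG[2:]
        flanks, tallies = retrieval.trim_vector_tag([_read(bad + "T" * 30)], max_mismatch=1)
        assert flanks == [] and tallies["no_tag"] == 1

    def test_one_mismatch_tolerated(self):
        near = ("G" if TAG[0] != "G" else "C") + TAG[1:]
        flanks, _ = retrieval.trim_vector_tag([_read(near + "T" * 30)], max_mismatch=1)
        assert len(flanks) == 1

    def test_short_flank_tallied(self):
        flanks, tallies = retrieval.trim_vector_tag([_read(TAG + "TACGT")])
        assert flanks == [] and tallies["short_flank"] == 1

    def test_empty_stream(self):
        flanks, tallies = retrieval.trim_vector_tag([])
        assert flanks == [] and sum(tallies.values()) == 0

    def test_simulated_error_free_reads_all_pass(self, small_genome):
        ins = simulate.simulate_insertions(small_genome, 30, seed=1)
        reads, _ = simulate.simulate_lam_reads(ins, small_genome, reads_total=100, seed=2)
        flanks, tallies = retrieval.trim_vector_tag(reads)
        assert len(flanks) == len(reads)
        assert sum(tallies.values()) == 0


class TestMapFlanks:
    def test_error_free_flank_maps_to_true_junction(self, small_genome, small_index):
        ins = simulate.simulate_insertions(small_genome, 20, seed=3)
        reads, _ = simulate.simulate_lam_reads(ins, small_genome, reads_total=200, seed=4)
        flanks, _ = retrieval.trim_vector_tag(reads)
        mapped, tallies = retrieval.map_flanks(flanks, small_genome, index=small_index)
        assert len(mapped) == len(flanks)
        truth = {r.read_id: (r.truth.chrom, r.truth.ta_start) for r in reads}
        for read_id, chrom, pos in mapped:
            assert truth[read_id] == (chrom, pos)

    def test_duplicated_seed_locus_is_multimapped(self):
        unit = "TACCGGTTAACCGGATCGTG"  # 20-mer, starts with TA
        seq = "C" * 50 + unit + "C" * 50 + unit + "C" * 50
        g = ToyGenome(chrom_names=["c"], sequences={"c": seq})
        mapped, tallies = retrieval.map_flanks([("r1", unit + "C" * 10)], g)
        assert mapped == [] and tallies["multimapped"] == 1

    def test_unmapped_and_short_flank(self, small_genome, small_index):
        mapped, tallies = retrieval.map_flanks(
            [("r1", "TA" + "CG" * 15), ("r2", "TACG")], small_genome, index=small_index
        )
        assert tallies["short_flank"] == 1
        assert tallies["unmapped"] + tallies["multimapped"] == 1

    def test_low_error_rate_mapping_rate(self, small_genome, small_index):
        """>=95% of reads at 0.5% substitution error map to their true junction."""
        ins = simulate.simulate_insertions(small_genome, 100, seed=5)
        reads, _ = simulate.simulate_lam_reads(
            ins, small_genome, reads_total=2000, error_rate=0.005, seed=6
        )
        flanks, _ = retrieval.trim_vector_tag(reads)
        mapped, _ = retrieval.map_flanks(flanks, small_genome, index=small_index)
        truth = {r.read_id: (r.truth.chrom, r.truth.ta_start) for r in reads}
        correct = sum(truth[rid] == (c, p) for rid, c, p in mapped)
        assert correct / len(reads) >= 0.95


class TestCollapseSites:
    def test_merge_within_window(self, toy_two_chrom):
        mapped = [("r%d" % i, "chrA", 1000) for i in range(5)]
        mapped += [("r%d" % (5 + i), "chrA", 1002) for i in range(2)]
        col = retrieval.collapse_sites(mapped, toy_two_chrom, merge_window=3)
        assert len(col.sites) == 1
        assert col.sites[0].ta_start == 1000
        assert col.sites[0].read_count == 7

    def test_beyond_window_stays_separate(self, toy_two_chrom):
        mapped = [("r1", "chrA", 1000), ("r2", "chrA", 1010)]
        col = retrieval.collapse_sites(mapped, toy_two_chrom, merge_window=3)
        assert len(col.sites) == 2

    def test_empty_input(self, toy_two_chrom):
        col = retrieval.collapse_sites([], toy_two_chrom)
        assert col.sites == [] and col.total_reads_mapped == 0

    def test_snap_and_flag(self):
        g = ToyGenome(chrom_names=["c"], sequences={"c": "CCCCTACCCCCCCCCCCCCC"})
        near = retrieval.collapse_sites([("r1", "c", 5)], g, merge_window=3)
        assert near.sites[0].ta_start == 4 and not near.sites[0].flagged_no_TA
        far = retrieval.collapse_sites([("r1", "c", 15)], g, merge_window=3)
        assert far.sites[0].ta_start == 15 and far.sites[0].flagged_no_TA

    @settings(derandomize=True, max_examples=60, deadline=None)
    @given(
        st.dictionaries(
            st.integers(min_value=0, max_value=300),
            st.integers(min_value=1, max_value=5),
            min_size=1,
            max_size=40,
        ),
        st.integers(min_value=1, max_value=10),
    )
    def test_matches_single_linkage_oracle(self, pos_counts, window):
        """Collapse equals brute-force single-linkage on all small inputs."""
        # TA everywhere so snapping never moves the representative
        g = ToyGenome(chrom_names=["c"], sequences={"c": "TA" * 400})
        pos_counts = {2 * p: c for p, c in pos_counts.items()}
        mapped = [
            (f"r{p}_{i}", "c", p) for p, c in pos_counts.items() for i in range(c)
        ]
        col = retrieval.collapse_sites(mapped, g, merge_window=2 * window)
        got = sorted((s.ta_start, s.read_count) for s in col.sites)
        assert got == brute_force_single_linkage(pos_counts, 2 * window)


class TestRoundTrip:
    @pytest.mark.parametrize("seed", rng_seeds(77, 3))
    def test_error_free_round_trip_recovers_emitted_truth(self, small_genome, small_index, seed):
        """simulate -> retrieve at error_rate=0 recovers every insertion that
        emitted at least one read, at exact positions with exact counts."""
        ins = simulate.simulate_insertions(small_genome, 80, seed=seed)
        reads, dropped = simulate.simulate_lam_reads(
            ins, small_genome, reads_total=4000, error_rate=0.0, seed=seed + 1
        )
        assert len(reads) + dropped == 4000
        col = retrieval.retrieve_sites(reads, small_genome, index=small_index)
        col.check()
        truth_counts: dict[tuple, int] = {}
        for r in reads:
            key = (r.truth.chrom, r.truth.ta_start)
            truth_counts[key] = truth_counts.get(key, 0) + 1
        got = {(s.chrom, s.ta_start): s.read_count for s in col.sites}
        assert got == truth_counts
        assert col.total_reads_mapped + col.total_reads_discarded == len(reads)
        for s in col.sites:
            assert not s.flagged_no_TA
            assert small_genome.has_ta(s.chrom, s.ta_start)


class TestCollisionFilter:
    def test_clear_winner_kept(self):
        a = make_collection([1000], sample_id="A", counts=[100])
        b = make_collection([1000], sample_id="B", counts=[5])
        (fa, fb), report = retrieval.filter_cross_sample_collisions([a, b], ratio_threshold=10)
        assert len(fa.sites) == 1 and len(fb.sites) == 0
        assert report[0][3] == "A"

    def test_ambiguous_removed_from_all(self):
        a = make_collection([1000], sample_id="A", counts=[30])
        b = make_collection([1000], sample_id="B", counts=[20])
        (fa, fb), report = retrieval.filter_cross_sample_collisions([a, b], ratio_threshold=10)
        assert fa.sites == [] and fb.sites == []
        assert report[0][3] is None

    def test_disjoint_unchanged(self):
        a = make_collection([1000], sample_id="A")
        b = make_collection([2000], sample_id="B")
        (fa, fb), report = retrieval.filter_cross_sample_collisions([a, b])
        assert report == []
        assert len(fa.sites) == 1 and len(fb.sites) == 1

    def test_single_collection_identity(self):
        a = make_collection([1, 2], sample_id="A")
        out, report = retrieval.filter_cross_sample_collisions([a])
        assert out == [a] and report == []
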