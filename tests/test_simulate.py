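"""Synthetic-data generator: TA constraints, seeding, read construction."""
import numpy as np
import pytest
from scipy import stats

from sbinsite import io, simulate
from sbinsite.types import ToyGenome, TrueInsertion, revcomp

from conftest import rng_seeds


class TestSimulateGenome:
    def test_gc_zero_gives_at_only_genome(self):
        g = simulate.simulate_genome(1, 10_000, 0.0, seed=1)
        assert set(g.sequences["chr1"]) == {"A", "T"}
        seq = g.sequences["chr1"]
        assert all(seq[p : p + 2] == "TA" for p in g.ta_index["chr1"])

    def test_ta_index_matches_direct_scan(self):
        g = simulate.simulate_genome(1, 100_000, 0.5, seed=7)
        seq = g.sequences["chr1"]
        # independent oracle: python substring scan
        expected, start = [], 0
        while (hit := seq.find("TA", start)) != -1:
            expected.append(hit)
            start = hit + 1
        assert g.ta_index["chr1"].tolist() == expected
        # TA count within 3 sigma of the binomial expectation at GC=0.5
        n = len(seq) - 1
        p = 1 / 16
        assert abs(len(expected) - n * p) < 3 * np.sqrt(n * p * (1 - p))

    def test_seeded_determinism(self):
        a = simulate.simulate_genome(2, 20_000, 0.5, seed=7)
        b = simulate.simulate_genome(2, 20_000, 0.5, seed=7)
        assert a.sequences == b.sequences

    @pytest.mark.parametrize("kwargs", [{"length_per_chrom": 0}, {"gc_fraction": 1.0}, {"gc_fraction": -0.1}])
    def test_invalid_parameters(self, kwargs):
        args = {"n_chrom": 1, "length_per_chrom": 1000, "gc_fraction": 0.5, "seed": 1}
        args.update(kwargs)
        with pytest.raises(ValueError):
            simulate.simulate_genome(**args)


class TestSimulateAnnotations:
    def test_tss_strand_convention(self):
        from sbinsite.types import GeneModel

        plus = GeneModel("g1", "chr1", "+", 1000, 3000)
        minus = GeneModel("g2", "chr1", "-", 1000, 3000)
        assert plus.tss == 1000
        assert minus.tss == 2999

    def test_spans_in_bounds_and_ids_unique(self, small_genome):
        genes = simulate.simulate_annotations(small_genome, 50, 2000, seed=5)
        assert len({g.gene_id for g in genes}) == 50
        for g in genes:
            assert 0 <= g.start < g.end <= small_genome.length(g.chrom)
            assert g.start <= g.tss < g.end
        classes = {g.expression_class for g in genes}
        assert "T_cell_expressed" in classes

    def test_capacity_error(self, small_genome):
        with pytest.raises(ValueError):
            simulate.simulate_annotations(small_genome, 10_000, 1_000_000, seed=1)


class TestSimulateInsertions:
    def test_every_insertion_on_ta_all_modes(self, small_genome, small_genes):
        for mode, bias in [
            ("uniform_TA", None),
            ("tss_biased", {"genes": small_genes, "factor": 5.0}),
            ("planted_cis", {"chrom": "chr1", "center": 100_000, "span_bp": 50_000, "n_sites": 5}),
        ]:
            ins = simulate.simulate_insertions(small_genome, 50, mode=mode, bias_params=bias, seed=3)
            assert len(ins) == 50
            assert len({(i.chrom, i.ta_start) for i in ins}) == 50
            for i in ins:
                assert small_genome.has_ta(i.chrom, i.ta_start)

    def test_uniform_positions_pass_ks_against_uniform(self):
        """Positions on a 1 Mb genome look uniform (alpha=0.01) in >=95/100 runs."""
        g = simulate.simulate_genome(1, 1_000_000, 0.5, seed=21)
        L = g.length("chr1")
        ok = 0
        for seed in rng_seeds(100, 100):
            ins = simulate.simulate_insertions(g, 500, mode="uniform_TA", seed=seed)
            pos = np.array([i.ta_start for i in ins]) / L
            if stats.kstest(pos, "uniform").pvalue >= 0.01:
                ok += 1
        assert ok >= 95

    def test_planted_cis_places_exact_sites_in_span(self, small_genome):
        bias = {"chrom": "chr2", "center": 100_000, "span_bp": 40_000, "n_sites": 10}
        ins = simulate.simulate_insertions(
            small_genome, 100, mode="planted_cis", bias_params=bias, seed=9
        )
        in_span = [
            i for i in ins if i.chrom == "chr2" and 80_000 <= i.ta_start < 120_000
        ]
        assert len(in_span) >= 10  # 10 planted; uniform remainder may add more

    def test_planted_span_without_enough_ta_raises(self):
        g = ToyGenome(chrom_names=["c"], sequences={"c": "TA" + "C" * 99_998})
        with pytest.raises(ValueError):
            simulate.simulate_insertions(
                g, 2, mode="planted_cis",
                bias_params={"chrom": "c", "center": 50_000, "span_bp": 10_000, "n_sites": 2},
                seed=1,
            )

    def test_one_dominant_abundance(self, small_genome):
        ins = simulate.simulate_insertions(
            small_genome, 100, abundance_model="one_dominant",
            abundance_params={"frac": 0.40}, seed=4,
        )
        w = sorted((i.clone_weight for i in ins), reverse=True)
        assert w[0] == pytest.approx(0.40)
        assert all(x == pytest.approx((1 - 0.40) / 99) for x in w[1:])
        assert sum(w) == pytest.approx(1.0)

    def test_weights_sum_to_one(self, small_genome):
        for model in ["uniform", "dirichlet"]:
            ins = simulate.simulate_insertions(small_genome, 30, abundance_model=model, seed=6)
            assert sum(i.clone_weight for i in ins) == pytest.approx(1.0)

    def test_too_many_clones_raises(self):
        g = ToyGenome(chrom_names=["c"], sequences={"c": "TATA" + "C" * 100})
        with pytest.raises(ValueError):
            simulate.simulate_insertions(g, 10, seed=1)

    def test_chromosome_marginals_match_ta_weights(self, small_genome):
        """Chi-square of chromosome counts vs TA weights, alpha=0.01, >=95/100."""
        ta = np.array([len(small_genome.ta_index[c]) for c in small_genome.chrom_names], float)
        ok = 0
        for seed in rng_seeds(55, 100):
            ins = simulate.simulate_insertions(small_genome, 300, seed=seed)
            obs = np.array(
                [sum(i.chrom == c for i in ins) for c in small_genome.chrom_names], float
            )
            exp = obs.sum() * ta / ta.sum()
            if stats.chisquare(obs, f_exp=exp).pvalue >= 0.01:
                ok += 1
        assert ok >= 95


class TestSimulateLamReads:
    def test_error_free_reads_carry_tag_and_true_junction(self, small_genome):
        ins = simulate.simulate_insertions(small_genome, 1, seed=2)
        reads, dropped = simulate.simulate_lam_reads(
            ins, small_genome, reads_total=10, error_rate=0.0, seed=3
        )
        tag = simulate.DEFAULT_VECTOR_TAG
        assert len(reads) + dropped == 10
        i = ins[0]
        seq = small_genome.sequences[i.chrom]
        for r in reads:
            assert r.sequence.startswith(tag)
            flank20 = r.sequence[len(tag) : len(tag) + 20]
            if i.orientation == "+":
                assert flank20 == seq[i.ta_start : i.ta_start + 20]
            else:
                assert flank20 == revcomp(seq[i.ta_start + 2 - 20 : i.ta_start + 2])
            assert flank20.startswith("TA")

    def test_per_clone_counts_multinomial(self):
        # AT-only genome: no restriction sites, so no reads are dropped and
        # per-clone counts are exactly multinomial(reads_total, weights)
        g = simulate.simulate_genome(1, 100_000, 0.0, seed=13)
        ins = simulate.simulate_insertions(g, 3, seed=8)
        weights = [0.5, 0.3, 0.2]
        for i, w in zip(ins, weights):
            i.clone_weight = w
        reads, dropped = simulate.simulate_lam_reads(ins, g, reads_total=1000, seed=9)
        assert dropped == 0 and len(reads) == 1000
        counts = {i.clone_id: 0 for i in ins}
        for r in reads:
            counts[r.truth.clone_id] += 1
        for i, w in zip(ins, weights):
            sigma = np.sqrt(1000 * w * (1 - w))
            assert abs(counts[i.clone_id] - 1000 * w) <= 3 * sigma

    def test_enzyme_site_near_junction_drops_all_reads(self):
        # TA junction with an ACGT site 8 nt downstream: flank truncated to 8
        # < min_flank=20 -> every read dropped
        seq = "C" * 100 + "TA" + "GGGGGG" + "ACGT" + "GGTTGGTTGG" * 10
        g = ToyGenome(chrom_names=["c"], sequences={"c": seq})
        ins = [TrueInsertion("cl1", "c", 100, "+", 1.0)]
        reads, dropped = simulate.simulate_lam_reads(ins, g, reads_total=5, seed=1)
        assert reads == [] and dropped == 5

    def test_fastq_round_trip_and_seeded_bytes(self, small_genome, tmp_path):
        ins = simulate.simulate_insertions(small_genome, 20, seed=5)
        out = []
        for run in range(2):
            reads, _ = simulate.simulate_lam_reads(
                ins, small_genome, reads_total=500, error_rate=0.01, seed=42
            )
            path = tmp_path / f"r{run}.fastq"
            io.write_fastq(reads, path)
            out.append(path.read_bytes())
        assert out[0] == out[1]
        back = io.read_fastq(tmp_path / "r0.fastq")
        assert len(back) == len(reads)
        assert back[0].sequence == reads[0].sequence

    def test_short_tag_rejected(self, small_genome):
        ins = simulate.simulate_insertions(small_genome, 2, seed=1)
        with pytest.raises(ValueError):
            simulate.simulate_lam_reads(ins, small_genome, vector_tag="ACGTACGT", seed=1)
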