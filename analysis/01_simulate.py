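#!/usr/bin/env python
"""Simulate the study's raw material: a 10 Mb toy genome, gene annotation,
three polyclonal donor samples of SB insertions, and LAM-PCR-style junction
reads (three-enzyme fragmentation, vector-tagged).

Large outputs (FASTA/FASTQ) go to scratch/sim/; they are regenerated, not
versioned.  Run before 02_retrieve.py.
"""
from pathlib import Path

from sbinsite import pipeline

OUT = Path("scratch/sim")

CONFIG = {
    "seed": 20260917,
    "outdir": str(OUT),
    "simulate": {
        "genome": {"n_chrom": 4, "length_per_chrom": 2_500_000, "gc_fraction": 0.45},
        "genes": {"n_genes": 300, "mean_len": 8000, "tcell_fraction": 0.3},
        "samples": [
            {"sample_id": "HD1", "n_clones": 250, "reads_total": 25_000},
            {"sample_id": "HD2", "n_clones": 120, "reads_total": 12_000},
            {"sample_id": "HD3", "n_clones": 150, "reads_total": 15_000},
        ],
    },
}


def main() -> None:
    params = pipeline.validate_config(CONFIG)
    OUT.mkdir(parents=True, exist_ok=True)
    genome, genes, sample_reads = pipeline._resolve_inputs(
        CONFIG, params, CONFIG["seed"], OUT
    )
    print(f"genome: {len(genome.chrom_names)} chromosomes, "
          f"{genome.total_length / 1e6:.1f} Mb, {genome.total_ta:,} TA sites")
    print(f"genes: {len(genes)} "
          f"({sum(g.expression_class == 'T_cell_expressed' for g in genes)} T-cell-expressed)")
    for sample_id, reads in sample_reads:
        print(f"{sample_id}: {len(reads):,} junction reads emitted -> {OUT}/reads_{sample_id}.fastq")


if __name__ == "__main__":
    main()
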