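#!/usr/bin/env python
"""Clonal abundance over the three donors pooled: each IS's share of total
junction reads, labels for clones above 3%, and the polyclonality verdict.
"""
from pathlib import Path

import pandas as pd

from sbinsite import annotate, clonality, io

SIM = Path("scratch/sim")
RESULTS = Path("results")


def main() -> None:
    genome = io.read_fasta(SIM / "genome.fa")
    genes = io.read_gff3(SIM / "genes.gff3")
    cols = [
        io.read_is_bed(RESULTS / f"is_{s}.bed", s, genome=genome)
        for s in ("HD1", "HD2", "HD3")
    ]
    pooled = cols[0].__class__(sample_id="pooled", sites=[s for c in cols for s in c.sites])
    annotations, _ = annotate.nearest_tss(pooled, genes)
    nearest = {a.is_id: a.nearest_gene_id for a in annotations}
    records = clonality.clonal_abundance(cols, pool=True, nearest_gene=nearest)
    labeled, verdict = clonality.flag_dominance(records)
    pd.DataFrame(
        [{"is_id": r.is_id, "nearest_gene": r.nearest_gene_id, "percent": r.percent}
         for r in records]
    ).to_csv(RESULTS / "abundance.tsv", sep="\t", index=False)
    print(f"{len(records)} clones; top clone {records[0].percent:.2f}% "
          f"(nearest gene {records[0].nearest_gene_id})")
    print(f"clones above 3%: {len(labeled)}")
    for r in labeled:
        print(f"  {r.is_id}  {r.percent:.2f}%  nearest gene {r.nearest_gene_id}")
    print(f"verdict: {verdict}")


if __name__ == "__main__":
    main()
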