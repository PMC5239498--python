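#!/usr/bin/env python
"""Nearest-gene set overrepresentation: recover a planted 5x insertion
preference for 'T-cell-expressed' genes by exact hypergeometric testing
with BH correction — the in-repo analogue of a GREAT-style analysis.
"""
from pathlib import Path

import numpy as np
import pandas as pd

from sbinsite import annotate, cis, simulate
from sbinsite.types import IntegrationSite, ISCollection

RESULTS = Path("results")


def main() -> None:
    genome = simulate.simulate_genome(1, 80_000_000, 0.45, seed=601)
    genes = simulate.simulate_annotations(genome, 800, 20_000, seed=602, tcell_fraction=0.4)
    tcell = [g.gene_id for g in genes if g.expression_class == "T_cell_expressed"]
    ids = [g.gene_id for g in genes]
    rng = np.random.default_rng(603)
    sets = {"T_cell_expressed": tcell}
    for j in range(3):
        sets[f"random_set_{j}"] = rng.choice(ids, size=len(tcell), replace=False).tolist()

    ins = simulate.simulate_insertions(
        genome, 800, mode="tss_biased",
        bias_params={"genes": genes, "factor": 5.0}, seed=604,
    )
    col = ISCollection(sample_id="S1")
    col.sites = [IntegrationSite("S1", i.chrom, i.ta_start, 1) for i in ins]
    col.total_reads_mapped = len(col.sites)
    annotations, _ = annotate.nearest_tss(col, genes)
    results = cis.gene_set_enrichment(annotations, sets, genes)
    RESULTS.mkdir(exist_ok=True)
    pd.DataFrame(
        [{"set_id": r.set_id, "k": r.k, "K": r.K, "n": r.n, "N": r.N, "p": r.p, "q": r.q}
         for r in results]
    ).to_csv(RESULTS / "enrichment.tsv", sep="\t", index=False)
    for r in results:
        print(f"{r.set_id}: k={r.k}/{r.K}, hits n={r.n} of N={r.N}, "
              f"p={r.p:.3g}, q={r.q:.3g}")
    top = results[0]
    print(f"top-ranked set: {top.set_id} "
          f"({'planted bias recovered' if top.set_id == 'T_cell_expressed' and top.q < 0.05 else 'no significant enrichment'})")


if __name__ == "__main__":
    main()
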