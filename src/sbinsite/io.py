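"""Standard-format I/O: FASTA, GFF3, BED6, FASTQ, GMT.

BED intervals for integration sites span the duplicated TA dinucleotide:
(chrom, ta_start, ta_start + 2).  FASTQ is written with constant Q30
qualities (Phred+33); the simulator does not model quality-dependent errors.
"""
from __future__ import annotations

import pandas as pd
from Bio import SeqIO
from Bio.SeqIO.QualityIO import FastqGeneralIterator

from .types import GeneModel, IntegrationSite, ISCollection, LamRead, ToyGenome


def write_fasta(genome: ToyGenome, path) -> None:
    with open(path, "w") as fh:
        for name in genome.chrom_names:
            fh.write(f">{name}\n")
            seq = genome.sequences[name]
            for i in range(0, len(seq), 80):
                fh.write(seq[i : i + 80] + "\n")


def read_fasta(path) -> ToyGenome:
    names, seqs = [], {}
    for rec in SeqIO.parse(str(path), "fasta"):
        names.append(rec.id)
        seqs[rec.id] = str(rec.seq).upper()
    return ToyGenome(chrom_names=names, sequences=seqs)


def write_fastq(reads: list[LamRead], path) -> None:
    with open(path, "w") as fh:
        for r in reads:
            fh.write(f"@{r.read_id}\n{r.sequence}\n+\n{'?' * len(r.sequence)}\n")


def read_fastq(path, sample_id: str = "S1") -> list[LamRead]:
    with open(path) as fh:
        return [
            LamRead(read_id=title.split()[0], sample_id=sample_id, sequence=seq.upper())
            for title, seq, _qual in FastqGeneralIterator(fh)
        ]


def write_gff3(genes: list[GeneModel], path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            attrs = f"ID={g.gene_id};expression_class={g.expression_class}"
            fh.write(
                f"{g.chrom}\tsbinsite\tgene\t{g.start + 1}\t{g.end}\t.\t{g.strand}\t.\t{attrs}\n"
            )


def read_gff3(path) -> list[GeneModel]:
    import gffutils

    db = gffutils.create_db(
        str(path), ":memory:", force=True, keep_order=True, merge_strategy="create_unique"
    )
    genes = []
    for feat in db.features_of_type("gene", order_by=("seqid", "start")):
        genes.append(
            GeneModel(
                gene_id=feat.attributes["ID"][0],
                chrom=feat.seqid,
                strand=feat.strand,
                start=feat.start - 1,
                end=feat.end,
                expression_class=feat.attributes.get("expression_class", ["none"])[0],
            )
        )
    return genes


def write_genes_bed(genes: list[GeneModel], path) -> None:
    rows = [(g.chrom, g.start, g.end, g.gene_id, 0, g.strand) for g in genes]
    pd.DataFrame(rows).to_csv(path, sep="\t", header=False, index=False)


def write_is_bed(collection: ISCollection, path) -> None:
    rows = [
        (s.chrom, s.ta_start, s.ta_start + 2, s.is_id, s.read_count, "+")
        for s in collection.sites
    ]
    pd.DataFrame(rows, columns=["chrom", "start", "end", "name", "score", "strand"]).to_csv(
        path, sep="\t", header=False, index=False
    )


def read_is_bed(path, sample_id: str, genome: ToyGenome | None = None) -> ISCollection:
    df = pd.read_csv(
        path, sep="\t", header=None, names=["chrom", "start", "end", "name", "score", "strand"]
    )
    sites = []
    for row in df.itertuples(index=False):
        flagged = bool(genome is not None and not genome.has_ta(row.chrom, int(row.start)))
        sites.append(
            IntegrationSite(
                sample_id=sample_id,
                chrom=row.chrom,
                ta_start=int(row.start),
                read_count=int(row.score),
                flagged_no_TA=flagged,
            )
        )
    col = ISCollection(sample_id=sample_id, sites=sites)
    col.total_reads_mapped = sum(s.read_count for s in sites)
    return col


def write_truth_bed(insertions, reads_per_clone: dict[str, int], path) -> None:
    """BED6 ground truth: name=clone_id, score=emitted read count."""
    rows = [
        (i.chrom, i.ta_start, i.ta_start + 2, i.clone_id, reads_per_clone.get(i.clone_id, 0), i.orientation)
        for i in insertions
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", header=False, index=False)


def read_gmt(path) -> dict[str, list[str]]:
    sets = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) >= 3:
                sets[parts[0]] = [g for g in parts[2:] if g]
    return sets


def write_gmt(gene_sets: dict[str, list[str]], path, description: str = "na") -> None:
    with open(path, "w") as fh:
        for set_id, members in gene_sets.items():
            fh.write("\t".join([set_id, description, *members]) + "\n")
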