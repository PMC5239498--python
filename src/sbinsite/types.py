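"""Domain containers shared across the pipeline.

All genomic coordinates are 0-based, half-open.  An integration site (IS) is
identified by the 0-based start of its TA dinucleotide on the plus strand;
Sleeping Beauty duplicates the same TA on both strands, so the site key is
strand-free.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(COMPLEMENT)[::-1]


def ta_positions(seq: str) -> np.ndarray:
    """All 0-based start positions p with seq[p:p+2] == 'TA', sorted."""
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    if arr.size < 2:
        return np.empty(0, dtype=np.int64)
    hit = (arr[:-1] == ord("T")) & (arr[1:] == ord("A"))
    return np.flatnonzero(hit).astype(np.int64)


@dataclass
class ToyGenome:
    """Chromosome sequences plus the index of TA dinucleotide starts.

    The TA index enumerates the only legal Sleeping Beauty insertion targets.
    """

    chrom_names: list[str]
    sequences: dict[str, str]
    ta_index: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.ta_index:
            self.ta_index = {c: ta_positions(self.sequences[c]) for c in self.chrom_names}

    def length(self, chrom: str) -> int:
        return len(self.sequences[chrom])

    @property
    def total_length(self) -> int:
        return sum(len(s) for s in self.sequences.values())

    @property
    def total_ta(self) -> int:
        return sum(len(v) for v in self.ta_index.values())

    def has_ta(self, chrom: str, pos: int) -> bool:
        seq = self.sequences[chrom]
        return 0 <= pos <= len(seq) - 2 and seq[pos : pos + 2] == "TA"


@dataclass
class GeneModel:
    """A gene span with its transcription start site (TSS).

    ``tss`` is ``start`` on the plus strand and ``end - 1`` on the minus
    strand.  ``expression_class`` is a categorical label used only for biased
    simulation and for building gene sets.
    """

    gene_id: str
    chrom: str
    strand: str
    start: int
    end: int
    expression_class: str = "none"

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValueError(f"gene {self.gene_id}: start must be < end")
        if self.strand not in "+-":
            raise ValueError(f"gene {self.gene_id}: strand must be + or -")

    @property
    def tss(self) -> int:
        return self.start if self.strand == "+" else self.end - 1


@dataclass
class TrueInsertion:
    """Ground-truth insertion: one marked clone and its relative size."""

    clone_id: str
    chrom: str
    ta_start: int
    orientation: str
    clone_weight: float


@dataclass
class LamRead:
    """A simulated LAM-PCR junction read: vector tag + genomic flank."""

    read_id: str
    sample_id: str
    sequence: str
    truth: TrueInsertion | None = None


@dataclass
class IntegrationSite:
    sample_id: str
    chrom: str
    ta_start: int
    read_count: int
    flagged_no_TA: bool = False

    @property
    def is_id(self) -> str:
        return f"{self.sample_id}:{self.chrom}:{self.ta_start}"


@dataclass
class ISCollection:
    """Unique integration sites of one sample, with read accounting.

    Invariant: the site read counts sum to ``total_reads_mapped`` and the
    discard reasons partition ``total_reads_discarded``.
    """

    sample_id: str
    sites: list[IntegrationSite] = field(default_factory=list)
    total_reads_mapped: int = 0
    discarded: dict[str, int] = field(
        default_factory=lambda: {"no_tag": 0, "short_flank": 0, "unmapped": 0, "multimapped": 0}
    )

    @property
    def total_reads_discarded(self) -> int:
        return sum(self.discarded.values())

    def check(self) -> None:
        assert sum(s.read_count for s in self.sites) == self.total_reads_mapped


@dataclass
class TssAnnotation:
    is_id: str
    nearest_gene_id: str
    signed_distance: int
    bin_label: str


@dataclass
class LogoMatrix:
    """Per-position base frequencies in windows flanking the IS TA."""

    offsets: list[int]
    freq: dict[int, dict[str, float]]
    n_sites: int
    n_skipped: int = 0


@dataclass
class AbundanceRecord:
    is_id: str
    nearest_gene_id: str
    percent: float


@dataclass
class CISCluster:
    chrom: str
    start: int
    end: int
    member_is_ids: list[str]

    @property
    def n_is(self) -> int:
        return len(self.member_is_ids)


@dataclass
class CISResult:
    observed_clusters: list[CISCluster]
    n_sim: int
    null_cluster_counts: np.ndarray
    p_global: float
    per_cluster_p: list[float]


@dataclass
class EnrichmentResult:
    set_id: str
    k: int
    K: int
    n: int
    N: int
    p: float
    q: float
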