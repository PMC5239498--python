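"""Synthetic-data generator for Sleeping Beauty integration-site analysis.

Emulates the statistical structure the downstream analysis assumes: a toy
genome with its TA-dinucleotide index, gene annotations with TSSs, a true
insertion landscape (uniform over TA sites, TSS/gene-biased, or with a
planted common-insertion-site cluster), and LAM-PCR-style junction reads
fragmented by restriction enzymes.

Sleeping Beauty integrates exclusively at TA dinucleotides and duplicates
the TA on insertion; every simulated insertion therefore sits on a genomic
TA, and junction reads start with a vector tag followed by the genomic
flank, whose first two bases are that TA.
"""
from __future__ import annotations

import numpy as np

from .types import GeneModel, LamRead, ToyGenome, TrueInsertion, revcomp

BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

#: 20-mer stand-in for the SB IR/DR junction tag (the real sequence is a
#: vector property, not a model parameter; retrieval shares this config value).
DEFAULT_VECTOR_TAG = "TCGACTTGTGGTCTCGCTGT"

#: Recognition sequences of HpyCH4IV, AciI and BfaI.
DEFAULT_ENZYMES = ("ACGT", "CCGC", "CTAG")

DEFAULT_MIN_FLANK = 20


def _rng(seed) -> np.random.Generator:
    return np.random.default_rng(seed)


def sample_without_replacement(rng: np.random.Generator, n_pool: int, k: int) -> np.ndarray:
    """Draw k distinct indices from range(n_pool), uniformly, in O(k).

    Rejection top-up sampler: efficient because k << n_pool throughout this
    package; avoids numpy's O(n_pool) permutation path inside Monte Carlo
    loops.
    """
    if k > n_pool:
        raise ValueError(f"cannot draw {k} distinct items from a pool of {n_pool}")
    if k * 3 > n_pool:  # dense draws: fall back to permutation
        return rng.permutation(n_pool)[:k]
    chosen: set[int] = set()
    out = np.empty(k, dtype=np.int64)
    filled = 0
    while filled < k:
        need = k - filled
        draw = rng.integers(0, n_pool, size=need + need // 2 + 8)
        for v in draw:
            if v not in chosen:
                chosen.add(int(v))
                out[filled] = v
                filled += 1
                if filled == k:
                    break
    return out


def simulate_genome(
    n_chrom: int, length_per_chrom: int, gc_fraction: float, seed: int | None
) -> ToyGenome:
    """I.i.d.-base toy genome at the stated GC content, with its TA index.

    Bases are drawn independently with P(G)=P(C)=gc/2 and P(A)=P(T)=(1-gc)/2.
    ``gc_fraction`` may be 0 (an A/T-only genome, maximally TA-dense) but not
    1, which would leave no TA target at all.
    """
    if length_per_chrom <= 0:
        raise ValueError("length_per_chrom must be positive")
    if not (0.0 <= gc_fraction < 1.0):
        raise ValueError("gc_fraction must lie in [0, 1)")
    rng = _rng(seed)
    p_at = (1.0 - gc_fraction) / 2.0
    p_gc = gc_fraction / 2.0
    probs = np.array([p_at, p_gc, p_gc, p_at])  # A C G T
    names = [f"chr{i + 1}" for i in range(n_chrom)]
    seqs: dict[str, str] = {}
    for name in names:
        idx = rng.choice(4, size=length_per_chrom, p=probs)
        seqs[name] = BASES[idx].tobytes().decode("ascii")
    return ToyGenome(chrom_names=names, sequences=seqs)


def simulate_annotations(
    genome: ToyGenome,
    n_genes: int,
    mean_len: int,
    seed: int | None,
    tcell_fraction: float = 0.2,
    max_occupancy: float = 2.0,
) -> list[GeneModel]:
    """Place genes uniformly at random; overlaps allowed, strands ~50/50.

    A ``tcell_fraction`` of genes is labeled ``T_cell_expressed`` for use as
    a gene set and as the target of biased-insertion simulation.  Lengths are
    uniform in [mean_len/2, 3*mean_len/2].
    """
    if n_genes < 1:
        raise ValueError("n_genes must be >= 1")
    if n_genes * mean_len > max_occupancy * genome.total_length:
        raise ValueError("requested genes exceed genome capacity")
    rng = _rng(seed)
    lengths = np.array([genome.length(c) for c in genome.chrom_names], dtype=float)
    chrom_p = lengths / lengths.sum()
    n_tcell = int(round(tcell_fraction * n_genes))
    tcell_ids = set(rng.choice(n_genes, size=n_tcell, replace=False).tolist())
    genes: list[GeneModel] = []
    width = len(str(n_genes))
    for i in range(n_genes):
        ci = rng.choice(len(lengths), p=chrom_p)
        chrom = genome.chrom_names[ci]
        glen = int(rng.integers(max(2, mean_len // 2), mean_len + mean_len // 2 + 1))
        glen = min(glen, genome.length(chrom) - 1)
        start = int(rng.integers(0, genome.length(chrom) - glen))
        strand = "+" if rng.random() < 0.5 else "-"
        genes.append(
            GeneModel(
                gene_id=f"G{i + 1:0{width}d}",
                chrom=chrom,
                strand=strand,
                start=start,
                end=start + glen,
                expression_class="T_cell_expressed" if i in tcell_ids else "none",
            )
        )
    return genes


def _flat_ta(genome: ToyGenome):
    """Concatenated TA index with per-chromosome offsets for global draws."""
    chroms, arrays, offsets = [], [], []
    for c in genome.chrom_names:
        chroms.append(c)
        arrays.append(genome.ta_index[c])
        offsets.append(len(genome.ta_index[c]))
    counts = np.array(offsets, dtype=np.int64)
    bounds = np.concatenate([[0], np.cumsum(counts)])
    return chroms, arrays, bounds


def _flat_index_to_site(genome: ToyGenome, flat_idx: np.ndarray):
    chroms, arrays, bounds = _flat_ta(genome)
    out = []
    for v in flat_idx:
        ci = int(np.searchsorted(bounds, v, side="right") - 1)
        out.append((chroms[ci], int(arrays[ci][v - bounds[ci]])))
    return out


def _clone_weights(rng, n: int, model: str, params: dict) -> np.ndarray:
    if model == "uniform":
        return np.full(n, 1.0 / n)
    if model == "dirichlet":
        alpha = float(params.get("alpha", 1.0))
        return rng.dirichlet(np.full(n, alpha))
    if model == "one_dominant":
        frac = float(params.get("frac", 0.4))
        if n == 1:
            return np.array([1.0])
        w = np.full(n, (1.0 - frac) / (n - 1))
        w[0] = frac
        return w
    raise ValueError(f"unknown abundance model: {model}")


def simulate_insertions(
    genome: ToyGenome,
    n_clones: int,
    mode: str = "uniform_TA",
    bias_params: dict | None = None,
    abundance_model: str = "dirichlet",
    abundance_params: dict | None = None,
    seed: int | None = None,
) -> list[TrueInsertion]:
    """Draw one TA-constrained insertion per clone plus clone weights.

    Modes
    -----
    uniform_TA : uniform without replacement over all genomic TA positions.
    tss_biased : TA positions inside genes of ``bias_params['bias_class']``
        get sampling weight ``bias_params['factor']`` (genes passed as
        ``bias_params['genes']``); emulates the moderate preference of SB
        for expressed genes.
    planted_cis : ``bias_params`` = {chrom, center, span_bp, n_sites} places
        n_sites inside the span, the rest uniform elsewhere.
    """
    rng = _rng(seed)
    total_ta = genome.total_ta
    if n_clones > total_ta:
        raise ValueError("n_clones exceeds the number of genomic TA positions")
    bias_params = bias_params or {}
    abundance_params = abundance_params or {}
    chroms, arrays, bounds = _flat_ta(genome)

    if mode == "uniform_TA":
        flat = sample_without_replacement(rng, total_ta, n_clones)
        sites = _flat_index_to_site(genome, flat)
    elif mode == "planted_cis":
        chrom = bias_params["chrom"]
        center = int(bias_params["center"])
        span = int(bias_params["span_bp"])
        n_sites = int(bias_params["n_sites"])
        ta = genome.ta_index[chrom]
        lo, hi = center - span // 2, center + span // 2
        in_span = ta[(ta >= lo) & (ta < hi)]
        if len(in_span) < n_sites:
            raise ValueError("planted span contains fewer TA positions than n_sites")
        if n_sites > n_clones:
            raise ValueError("n_sites exceeds n_clones")
        picked = in_span[np.sort(sample_without_replacement(rng, len(in_span), n_sites))]
        sites = [(chrom, int(p)) for p in picked]
        # remaining clones uniform over TA positions outside the planted set
        chosen = set(sites)
        while len(sites) < n_clones:
            flat = sample_without_replacement(rng, total_ta, n_clones - len(sites) + 8)
            for chrom_pos in _flat_index_to_site(genome, flat):
                if chrom_pos not in chosen:
                    chosen.add(chrom_pos)
                    sites.append(chrom_pos)
                    if len(sites) == n_clones:
                        break
    elif mode == "tss_biased":
        genes: list[GeneModel] = bias_params["genes"]
        factor = float(bias_params.get("factor", 5.0))
        bias_class = bias_params.get("bias_class", "T_cell_expressed")
        logw = np.zeros(total_ta)
        for g in genes:
            if g.expression_class != bias_class:
                continue
            ci = chroms.index(g.chrom)
            ta = arrays[ci]
            i0, i1 = np.searchsorted(ta, [g.start, g.end])
            logw[bounds[ci] + i0 : bounds[ci] + i1] = np.log(factor)
        # Gumbel top-k == weighted sampling without replacement
        keys = logw + rng.gumbel(size=total_ta)
        flat = np.argpartition(-keys, n_clones - 1)[:n_clones]
        sites = _flat_index_to_site(genome, np.sort(flat))
    else:
        raise ValueError(f"unknown insertion mode: {mode}")

    weights = _clone_weights(rng, n_clones, abundance_model, abundance_params)
    orient = np.where(rng.random(n_clones) < 0.5, "+", "-")
    width = len(str(n_clones))
    out = []
    for i, (chrom, pos) in enumerate(sites):
        assert genome.has_ta(chrom, pos), "insertion off a TA dinucleotide"
        out.append(
            TrueInsertion(
                clone_id=f"clone{i + 1:0{width}d}",
                chrom=chrom,
                ta_start=pos,
                orientation=str(orient[i]),
                clone_weight=float(weights[i]),
            )
        )
    return out


def _oriented_region(genome: ToyGenome, ins: TrueInsertion, max_len: int) -> str:
    """Genomic sequence read downstream of the junction in insertion
    orientation; begins with the duplicated TA on either strand."""
    seq = genome.sequences[ins.chrom]
    if ins.orientation == "+":
        return seq[ins.ta_start : ins.ta_start + max_len]
    stop = ins.ta_start + 2
    return revcomp(seq[max(0, stop - max_len) : stop])


def _earliest_cut(region: str, patterns: tuple[str, ...]) -> int:
    """Offset of the nearest restriction recognition site, or len(region).

    Double-stranded recognition: each enzyme's site and its reverse
    complement are both searched.  The fragment is truncated at the
    recognition start (no overhang chemistry modeled).
    """
    cut = len(region)
    for pat in patterns:
        for p in (pat, revcomp(pat)):
            hit = region.find(p)
            if hit != -1 and hit < cut:
                cut = hit
    return cut


def simulate_lam_reads(
    insertions: list[TrueInsertion],
    genome: ToyGenome,
    vector_tag: str = DEFAULT_VECTOR_TAG,
    enzymes: tuple[str, ...] = DEFAULT_ENZYMES,
    reads_total: int = 50_000,
    flank_len_range: tuple[int, int] = (30, 60),
    error_rate: float = 0.0,
    seed: int | None = None,
    sample_id: str = "S1",
    min_flank: int = DEFAULT_MIN_FLANK,
) -> tuple[list[LamRead], int]:
    """LAM-PCR-style junction reads: vector tag + genomic flank.

    Reads per clone are multinomial(reads_total, clone_weights).  Each flank
    reads downstream of the junction in the insertion's orientation, is
    truncated at the nearest restriction site when that lies closer than the
    drawn flank length, and receives i.i.d. substitution errors at
    ``error_rate``.  Flanks shorter than ``min_flank`` after truncation are
    dropped and tallied; the return is ``(reads, n_dropped)`` with
    ``len(reads) + n_dropped == reads_total``.
    """
    if len(vector_tag) < 12:
        raise ValueError("vector_tag must be at least 12 nt")
    rng = _rng(seed)
    weights = np.array([i.clone_weight for i in insertions])
    weights = weights / weights.sum()
    per_clone = rng.multinomial(reads_total, weights)
    lo, hi = flank_len_range
    reads: list[LamRead] = []
    n_dropped = 0
    read_no = 0
    for ins, n_reads in zip(insertions, per_clone):
        if n_reads == 0:
            continue
        region = _oriented_region(genome, ins, hi)
        cut = _earliest_cut(region, tuple(enzymes))
        max_avail = min(cut, len(region))
        if max_avail < min_flank:
            n_dropped += int(n_reads)
            continue
        drawn = rng.integers(lo, hi + 1, size=n_reads)
        for L in drawn:
            eff = min(int(L), max_avail)
            if eff < min_flank:
                n_dropped += 1
                continue
            seq = vector_tag + region[:eff]
            if error_rate > 0.0:
                seq = _mutate(rng, seq, error_rate)
            read_no += 1
            reads.append(
                LamRead(
                    read_id=f"{sample_id}:r{read_no:07d}",
                    sample_id=sample_id,
                    sequence=seq,
                    truth=ins,
                )
            )
    return reads, n_dropped


def _mutate(rng: np.random.Generator, seq: str, rate: float) -> str:
    n_err = rng.binomial(len(seq), rate)
    if n_err == 0:
        return seq
    pos = rng.choice(len(seq), size=n_err, replace=False)
    arr = list(seq)
    for p in pos:
        alts = [b for b in "ACGT" if b != arr[p]]
        arr[p] = alts[int(rng.integers(0, 3))]
    return "".join(arr)
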