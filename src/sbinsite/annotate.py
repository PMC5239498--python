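"""Genomic characterization of an integration-site set.

Three read-outs diagnose whether integrations look random: the
chromosome-level distribution against a TA-weighted expectation, the
distance-to-nearest-TSS profile (promoter-targeting propensity), and the
base composition flanking the insertion TA (the SB consensus motif).
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .types import GeneModel, ISCollection, LogoMatrix, ToyGenome, TssAnnotation

DEFAULT_BIN_EDGES_KB = (1.0, 10.0, 100.0, 1000.0)
DEFAULT_FLANK = 5


@dataclass
class ChromDistribution:
    table: pd.DataFrame  # chrom, observed, expected
    chi2: float | None
    p_value: float | None
    note: str = ""


def chromosome_distribution(sites: ISCollection, genome: ToyGenome) -> ChromDistribution:
    """Observed vs TA-weighted expected IS counts per chromosome.

    Expected counts are proportional to each chromosome's share of genomic
    TA dinucleotides — the null of TA-constrained random integration.  The
    chi-square test has n_chrom - 1 degrees of freedom and is skipped (with
    a notice) for single-chromosome genomes.
    """
    observed = {c: 0 for c in genome.chrom_names}
    for s in sites.sites:
        observed[s.chrom] += 1
    n = sum(observed.values())
    ta_counts = np.array([len(genome.ta_index[c]) for c in genome.chrom_names], dtype=float)
    expected = n * ta_counts / ta_counts.sum()
    table = pd.DataFrame(
        {
            "chrom": genome.chrom_names,
            "observed": [observed[c] for c in genome.chrom_names],
            "expected": expected,
        }
    )
    if len(genome.chrom_names) < 2 or n == 0:
        return ChromDistribution(table, None, None, note="chi-square skipped: <2 chromosomes or no sites")
    chi2, p = stats.chisquare(table["observed"].to_numpy(float), f_exp=expected)
    return ChromDistribution(table, float(chi2), float(p))


def _bin_label(distance_bp: int, edges_kb) -> str:
    """Symmetric signed bins; edges in kb, outer tails open."""
    kb = distance_bp / 1000.0
    edges = sorted(edges_kb)
    bounds = [-e for e in reversed(edges)] + list(edges)
    if kb < bounds[0]:
        return f"<{bounds[0]:g}kb"
    for lo, hi in zip(bounds[:-1], bounds[1:]):
        if lo <= kb < hi:
            return f"[{lo:g},{hi:g})kb"
    return f">={bounds[-1]:g}kb"


def nearest_tss(
    sites: ISCollection,
    genes: list[GeneModel],
    bin_edges_kb=DEFAULT_BIN_EDGES_KB,
) -> tuple[list[TssAnnotation], pd.DataFrame]:
    """Annotate each IS with its nearest gene by TSS distance.

    Distance is measured from the IS TA start to the TSS base and signed in
    gene orientation: negative upstream of the TSS, 0 at the TSS.  Ties on
    |distance| resolve to the lexicographically smaller gene_id.  Sites on
    chromosomes without any gene are left unannotated.  The second return is
    the binned frequency table; frequencies sum to 100% over annotated sites.
    """
    if not genes:
        raise ValueError("nearest_tss requires at least one gene")
    per_chrom: dict[str, tuple[np.ndarray, list[GeneModel]]] = {}
    for chrom in {g.chrom for g in genes}:
        gs = sorted((g for g in genes if g.chrom == chrom), key=lambda g: (g.tss, g.gene_id))
        per_chrom[chrom] = (np.array([g.tss for g in gs], dtype=np.int64), gs)
    annotations: list[TssAnnotation] = []
    for s in sites.sites:
        best: GeneModel | None = None
        best_d = None
        if s.chrom in per_chrom:
            tss_arr, gs = per_chrom[s.chrom]
            i = int(np.searchsorted(tss_arr, s.ta_start))
            cand_idx = {max(0, i - 1), min(len(gs) - 1, i)}
            # neighbours with equal TSS share |distance|; widen to cover ties
            cands = set()
            for j in cand_idx:
                cands.add(j)
                t = tss_arr[j]
                k = j
                while k - 1 >= 0 and tss_arr[k - 1] == t:
                    k -= 1
                    cands.add(k)
                k = j
                while k + 1 < len(gs) and tss_arr[k + 1] == t:
                    k += 1
                    cands.add(k)
            for j in sorted(cands):
                g = gs[j]
                d = abs(s.ta_start - g.tss)
                if best is None or d < best_d or (d == best_d and g.gene_id < best.gene_id):
                    best, best_d = g, d
        if best is None:
            # nearest gene is undefined across chromosomes: leave such sites
            # unannotated rather than invent a distance
            continue
        raw = s.ta_start - best.tss
        signed = raw if best.strand == "+" else -raw
        annotations.append(
            TssAnnotation(
                is_id=s.is_id,
                nearest_gene_id=best.gene_id,
                signed_distance=int(signed),
                bin_label=_bin_label(int(signed), bin_edges_kb),
            )
        )
    if annotations:
        labels = [a.bin_label for a in annotations]
        counts = pd.Series(labels).value_counts()
        order = _bin_order(bin_edges_kb)
        table = pd.DataFrame(
            {
                "bin": order,
                "count": [int(counts.get(b, 0)) for b in order],
            }
        )
        table["percent"] = 100.0 * table["count"] / table["count"].sum()
    else:
        table = pd.DataFrame(columns=["bin", "count", "percent"])
    return annotations, table


def _bin_order(edges_kb) -> list[str]:
    edges = sorted(edges_kb)
    bounds = [-e for e in reversed(edges)] + list(edges)
    out = [f"<{bounds[0]:g}kb"]
    out += [f"[{lo:g},{hi:g})kb" for lo, hi in zip(bounds[:-1], bounds[1:])]
    out.append(f">={bounds[-1]:g}kb")
    return out


def build_logo(
    sites: ISCollection,
    genome: ToyGenome,
    flank: int = DEFAULT_FLANK,
    consensus_margin: float = 5.0,
) -> tuple[LogoMatrix, str]:
    """Base-frequency matrix around the insertion TA, plus consensus string.

    Offsets run -flank..+flank+1 relative to the TA start, so offsets 0/+1
    are the duplicated TA itself (degenerate T and A for unflagged sites).
    Sites whose window runs off a chromosome end are skipped and counted.
    The consensus reports the majority base per offset, or "X/Y" when the
    runner-up is within ``consensus_margin`` percentage points.
    """
    offsets = list(range(-flank, flank + 2))
    usable = 0
    skipped = 0
    counts = {o: {b: 0 for b in "ACGT"} for o in offsets}
    for s in sites.sites:
        if s.flagged_no_TA:
            continue
        seq = genome.sequences[s.chrom]
        lo, hi = s.ta_start + offsets[0], s.ta_start + offsets[-1]
        if lo < 0 or hi >= len(seq):
            skipped += 1
            continue
        usable += 1
        for o in offsets:
            counts[o][seq[s.ta_start + o]] += 1
    if usable == 0:
        raise ValueError("no usable sites for logo construction")
    freq = {o: {b: counts[o][b] / usable for b in "ACGT"} for o in offsets}
    consensus_parts = []
    for o in offsets:
        ranked = sorted(freq[o].items(), key=lambda kv: (-kv[1], kv[0]))
        top, second = ranked[0], ranked[1]
        if (top[1] - second[1]) * 100.0 <= consensus_margin and second[1] > 0:
            consensus_parts.append(f"{top[0]}/{second[0]}")
        else:
            consensus_parts.append(top[0])
    logo = LogoMatrix(offsets=offsets, freq=freq, n_sites=usable, n_skipped=skipped)
    return logo, " ".join(consensus_parts)


def plot_logo(logo: LogoMatrix, path) -> None:
    """Minimal stacked-letter logo rendering (information-scaled heights)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    colors = {"A": "#2ca02c", "C": "#1f77b4", "G": "#ff7f0e", "T": "#d62728"}
    fig, ax = plt.subplots(figsize=(max(4, len(logo.offsets) * 0.6), 3))
    for x, o in enumerate(logo.offsets):
        f = logo.freq[o]
        ic = 2.0 + sum(p * np.log2(p) for p in f.values() if p > 0)
        y = 0.0
        for base, p in sorted(f.items(), key=lambda kv: kv[1]):
            h = p * ic
            if h <= 0:
                continue
            ax.bar(x, h, bottom=y, color=colors[base], width=0.8)
            if h > 0.12:
                ax.text(x, y + h / 2, base, ha="center", va="center", fontsize=9, color="white")
            y += h
    ax.set_xticks(range(len(logo.offsets)), [str(o) for o in logo.offsets])
    ax.set_ylim(0, 2)
    ax.set_ylabel("bits")
    ax.set_xlabel("offset from TA start")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
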