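# Methods

`sbinsite` implements the computational safety assessment applied to
Sleeping Beauty (SB)-engineered cell products: given junction reads from a
LAM-PCR-style library (or pre-mapped sites), it retrieves unique vector
integration sites (IS), characterizes their genomic distribution,
estimates clonal abundance, and tests for common insertion sites (CIS) and
gene-set overrepresentation. Because no public sequencing data accompanies
the analysis this package models, every stage is exercised against a
synthetic-data generator whose statistical structure matches what the
analysis assumes.

## Coordinate and site conventions

All coordinates are 0-based, half-open. SB integrates exclusively at TA
dinucleotides and duplicates the TA on insertion, so an IS is identified by
the 0-based start of its TA on the plus strand; the site key is strand-free
because the same TA is duplicated on both strands. An insertion's
orientation only determines which genomic flank the junction read covers.

## Synthetic data

* **Genome** — i.i.d. bases at a configurable GC content (default 0.45,
  roughly mammalian). The TA index (every position p with
  `seq[p:p+2] == "TA"`) is the exhaustive set of legal insertion targets;
  at GC 0.45 about 7.5% of positions start a TA.
* **Genes** — uniformly placed spans (overlaps allowed), strands 50/50,
  lengths uniform in [mean/2, 3·mean/2]; TSS = start on `+`, end−1 on `−`.
  A configurable fraction carries the label `T_cell_expressed`, used both
  as a gene set and as the target of biased simulation.
* **Insertions** — one TA per clone, drawn without replacement:
  `uniform_TA` (uniform over the TA index — the null the analysis assumes),
  `tss_biased` (TA positions inside labeled gene bodies get weight
  `factor`, default 5; weighted sampling without replacement via the
  Gumbel top-k construction), or `planted_cis` (`n_sites` TAs inside a
  stated span, remainder uniform). Clone weights follow `uniform`,
  `dirichlet(alpha)` (default alpha=1 — a realistic polyclonal pool where
  no clone approaches 3% at 500 clones) or `one_dominant(frac)`.
* **Junction reads** — per-clone read counts are
  multinomial(reads_total, clone weights). A read is the configured
  20-mer vector tag (a stand-in for the SB IR/DR junction sequence, which
  is a vector property, shared by simulator and retrieval as config)
  followed by the genomic flank read downstream of the junction in the
  insertion's orientation. The flank length is uniform in [30, 60] nt but
  is truncated at the nearest restriction recognition site — HpyCH4IV
  (ACGT), AciI (CCGC), BfaI (CTAG), matched on both strands, recognition
  sequence only, no overhang chemistry. Truncated flanks shorter than 20 nt
  are dropped and tallied. Substitution errors are i.i.d. per base
  (default 0); indels are not modeled. Qualities are constant Q30 —
  the generator does not emulate quality-dependent error profiles, PCR
  amplification bias, or paired ends, so green tests establish recovery of
  the *positional and count* structure, not robustness to instrument
  artifacts.

An important emergent property: a clone whose junction lies closer than
20 nt to a restriction site emits **no** reads and is invisible to any
retrieval. This is the real retrievability limitation of LAM-PCR that
multi-enzyme designs mitigate; round-trip recovery is therefore defined
over insertions with at least one emitted read.

## IS retrieval

Tag trimming accepts a prefix within 1 mismatch of the tag. Mapping is a
desk-scale stand-in for a production aligner: an exact 20-mer seed looked
up in a sorted k-mer index of the genome (reverse-strand hits via the
reverse-complemented query), accepted only if the seed occurs at exactly
one genomic locus and the full-length oriented extension has ≤2
substitutions. If the leading seed occurs nowhere (an error inside it),
the trailing 20-mer of the flank is consulted as a rescue seed; without
this, sensitivity at a 0.5% per-base error rate caps near 90% because the
chance of an error inside a 20-mer is 1 − 0.995²⁰ ≈ 9.5%. Mapped junctions
within 3 bp are collapsed by single linkage; the merged site takes the
member position with most reads (ties → leftmost) and the summed count,
snapping to the nearest TA within 3 bp and flagging sites that cannot be
snapped. Reads are conserved exactly: mapped + {no_tag, short_flank,
unmapped, multimapped} = input. Sites present in several samples are kept
only where one sample's count is ≥10× all others, else removed everywhere
(cross-contamination heuristic). Externally aligned BED6 input bypasses
mapping entirely.

## Characterization

* **Chromosome distribution** — observed counts vs expectation
  proportional to each chromosome's TA count; chi-square with
  n_chrom − 1 df (skipped with a notice for single-chromosome genomes).
* **TSS profile** — each IS is assigned the gene with minimal |IS TA start
  − TSS| on its chromosome (ties → lexicographically smaller gene id; sites
  on gene-less chromosomes are left unannotated). Distance is signed in
  gene orientation, negative upstream. Binned frequencies use symmetric
  decade edges ±{1, 10, 100, 1000} kb by default (configurable; signed and
  absolute tables are both derivable from the emitted annotations).
* **Logo** — base frequencies at offsets −5..+6 around the TA start over
  unflagged sites (windows off a chromosome end are skipped and counted).
  Offsets 0/+1 are degenerate T/A by construction for unflagged sites. The
  consensus reports the majority base, or "X/Y" when the runner-up is
  within 5 percentage points — the threshold chosen so degenerate calls of
  the "A/G" kind are reported rather than suppressed.

## Clonal abundance

Abundance of clone i is 100·reads_i / Σreads over the (optionally pooled)
collections — read counts proxy clone size; no sonication-fragment or UMI
correction is available in this protocol, a known limitation of the
estimator. Clones above the 3% label threshold are reported with their
nearest gene. The polyclonality verdict uses a separate alarm threshold
(default 20%) which is an artifact parameter: the source analysis states
no numeric dominance criterion. Two algebraic identities are tested:
scale invariance, and pooled abundance = read-weighted mixture of
per-sample abundances.

## CIS statistics

Detection: pooled IS are position-sorted per chromosome; every site
anchors a window of `window` bp (default 100 kb) extending right; anchored
runs with ≥ `min_is` members (default 4) qualify, and overlapping
qualifying runs are merged. A merged cluster may span more than one window
width; each constituent run spans at most `window`. An exhaustive-window
brute-force oracle pins these semantics in the tests.

Significance is empirical: each of `n_sim` null draws (default 1000)
places the observed number of sites uniformly without replacement on the
genome-wide TA index (a per-chromosome-preserving null is available by
flag) and re-runs detection identically. All p-values carry the +1
correction, `p = (1 + #{null ≥ obs}) / (1 + n_sim)`, so they are never
zero and are monotone in the observed statistic. Two statistics are
reported:

* `p_global` — null probability of at least the observed **cluster
  count**. It asks "are clusters more numerous than random?" and is the
  right summary at low density: at ~0.3 IS/Mb the null count is
  essentially degenerate at zero, so any observed CIS is significant and,
  conversely, a clean product reports p ≈ 1.
* `per_cluster_p` — null probability that **any** window holds at least
  that cluster's membership (a sim-wise-maximum statistic, hence
  family-wise across clusters). This is the operative test for a localized
  hotspot on a dense background: at 5 IS/Mb the null itself produces ~5
  clusters of 4 per draw (E[qualifying anchors] = n·P(Binom(n−1, w/L) ≥
  min_is−1) ≈ 7 for n=500, w=100 kb, L=100 Mb), so count excess carries
  almost no power, while a 10-site window never arises under that null.

## Gene-set overrepresentation

The hosted regulatory-domain tool used in the original analysis is not
reproduced; the in-repo substitute tests the deduplicated nearest-gene
list against each set by the exact hypergeometric upper tail
(`P(X ≥ k)`, X ~ Hypergeom(N universe genes, K set genes, n hit genes))
with Benjamini–Hochberg correction across sets. Two geometric conditions —
both satisfied by real mammalian data and required of any synthetic
scenario — determine whether this readout can see a gene-body insertion
bias at all: gene length must be well below TSS spacing (else an insertion
inside a biased gene is nearest to a neighbor's TSS), and the hit list
must stay well below the universe (else deduplication saturates the
contrast). The packaged scenario is human-like scaled ~1:40 — 800 genes of
mean 20 kb on 80 Mb (one TSS per 100 kb, ~20% genic), 800 insertions
(the scale of a real IS study), set = the 40% of genes labeled
T-cell-expressed with 5× propensity; a pre-freeze power analysis measured
a 97.5% recovery rate (q < 0.05, rank 1) with median q ≈ 3×10⁻⁵.

## Reproducibility and numerics

Every stochastic routine takes a seed and uses `numpy.random.Generator`;
the pipeline fans a single global seed into per-stage substreams through
`SeedSequence` spawn keys, so stages are individually reproducible and a
fixed config yields a byte-identical report. Sampling without replacement
from the TA index uses an O(k) rejection top-up sampler (k ≪ pool
everywhere here) to keep Monte Carlo loops off numpy's O(N) permutation
path. Ties are fixed and documented (collapse: most reads then leftmost;
nearest gene: smaller id; consensus: alphabetical among equals). Degenerate
inputs raise (`ValueError`) rather than guess: zero reads for abundance,
empty gene lists for TSS annotation, more sites than TA positions for the
Monte Carlo null.

## Known limitations

Substitution-only error model; no PCR/amplification bias, UMIs or
sonication correction (read counts are the abundance estimator, as in the
modeled protocol); the mapper is exact-seed based and not a general
aligner (a BED import path admits externally aligned data); the
enrichment substitute uses nearest genes, not regulatory domains; the
synthetic genome is i.i.d. and contains none of the repeat structure that
makes real multimapping hard.
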