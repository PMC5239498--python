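import numpy as np
import pytest

from sbinsite import retrieval, simulate
from sbinsite.types import IntegrationSite, ISCollection, ToyGenome


def make_collection(positions, chrom="chr1", sample_id="S1", counts=None):
    """ISCollection from raw positions (helper for constructed inputs)."""
    counts = counts or [1] * len(positions)
    sites = [
        IntegrationSite(sample_id=sample_id, chrom=chrom, ta_start=int(p), read_count=int(c))
        for p, c in zip(positions, counts)
    ]
    col = ISCollection(sample_id=sample_id, sites=sites)
    col.total_reads_mapped = sum(counts)
    return col


@pytest.fixture(scope="session")
def small_genome():
    """2 x 200 kb, GC 0.45 — cheap substrate for unit tests."""
    return simulate.simulate_genome(2, 200_000, 0.45, seed=11)


@pytest.fixture(scope="session")
def small_genes(small_genome):
    return simulate.simulate_annotations(small_genome, 40, 3000, seed=12)


@pytest.fixture(scope="session")
def small_index(small_genome):
    return retrieval.KmerIndex(small_genome, k=20)


@pytest.fixture(scope="session")
def toy_two_chrom():
    """Two equal chromosomes of pure TA repeats: equal TA counts by
    construction, for hand-computable chi-square examples."""
    seq = "TA" * 5000
    return ToyGenome(chrom_names=["chrA", "chrB"], sequences={"chrA": seq, "chrB": seq})


def brute_force_single_linkage(positions_counts: dict[int, int], window: int):
    """Independent collapse oracle: single-linkage clusters of positions
    with gap <= window; representative = most reads, ties -> leftmost."""
    out = []
    cluster = []
    for p in sorted(positions_counts):
        if cluster and p - cluster[-1] > window:
            out.append(cluster)
            cluster = []
        cluster.append(p)
    if cluster:
        out.append(cluster)
    result = []
    for cl in out:
        rep = sorted(cl, key=lambda p: (-positions_counts[p], p))[0]
        result.append((rep, sum(positions_counts[p] for p in cl)))
    return sorted(result)


def brute_force_cis(positions: list[int], window: int, min_is: int):
    """Exhaustive-window CIS oracle: every window anchored at a site,
    qualifying windows merged by shared membership (repeated set union)."""
    pos = sorted(positions)
    n = len(pos)
    qualifying = []
    for i in range(n):
        members = frozenset(j for j in range(n) if pos[i] <= pos[j] <= pos[i] + window)
        if len(members) >= min_is:
            qualifying.append(set(members))
    changed = True
    while changed:
        changed = False
        for a in range(len(qualifying)):
            for b in range(a + 1, len(qualifying)):
                if qualifying[a] & qualifying[b]:
                    qualifying[a] |= qualifying[b]
                    del qualifying[b]
                    changed = True
                    break
            if changed:
                break
    clusters = sorted(tuple(sorted(pos[j] for j in q)) for q in qualifying)
    return clusters


def rng_seeds(master: int, n: int) -> list[int]:
    ss = np.random.SeedSequence(master)
    return [int(s) % (2**31) for s in ss.generate_state(n)]
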