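"""Clonal abundance from integration-site read counts.

Each unique IS marks one originally transduced clone; its share of total
junction sequencing reads estimates the clone's relative size.  Read counts
are the protocol's estimator — no sonication-fragment or UMI correction is
applied, a documented limitation of this proxy.
"""
from __future__ import annotations

from .types import AbundanceRecord, ISCollection

DEFAULT_LABEL_THRESHOLD = 3.0
#: Artifact parameter: no numeric dominance criterion exists in the source
#: analysis; 20% is a conservative alarm for a single clone.
DEFAULT_ALARM_THRESHOLD = 20.0


def clonal_abundance(
    collections: ISCollection | list[ISCollection],
    pool: bool = True,
    nearest_gene: dict[str, str] | None = None,
) -> list[AbundanceRecord]:
    """Relative abundance (%) of each IS over the (pooled) read total.

    percent_i = 100 * read_count_i / sum(read_counts); records sorted by
    descending percent.  With ``pool=False`` each sample is normalized
    separately (records from all samples are still returned together).
    ``nearest_gene`` optionally maps is_id -> gene_id for labeling.
    """
    if isinstance(collections, ISCollection):
        collections = [collections]
    nearest_gene = nearest_gene or {}
    groups = [collections] if pool else [[c] for c in collections]
    records: list[AbundanceRecord] = []
    for group in groups:
        total = sum(s.read_count for c in group for s in c.sites)
        if total == 0:
            raise ValueError("zero total reads: abundance undefined")
        for c in group:
            for s in c.sites:
                records.append(
                    AbundanceRecord(
                        is_id=s.is_id,
                        nearest_gene_id=nearest_gene.get(s.is_id, ""),
                        percent=100.0 * s.read_count / total,
                    )
                )
    records.sort(key=lambda r: (-r.percent, r.is_id))
    return records


def flag_dominance(
    records: list[AbundanceRecord],
    label_threshold: float = DEFAULT_LABEL_THRESHOLD,
    alarm_threshold: float = DEFAULT_ALARM_THRESHOLD,
) -> tuple[list[AbundanceRecord], str]:
    """Label clones above ``label_threshold`` %; verdict on polyclonality.

    The verdict is "polyclonal" iff no clone exceeds ``alarm_threshold`` %,
    else "dominant_clone_present".
    """
    if not records:
        raise ValueError("empty abundance record list")
    labeled = [r for r in records if r.percent > label_threshold]
    verdict = (
        "polyclonal"
        if all(r.percent <= alarm_threshold for r in records)
        else "dominant_clone_present"
    )
    return labeled, verdict
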