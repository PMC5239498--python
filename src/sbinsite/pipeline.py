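"""End-to-end orchestration: simulate -> retrieve -> annotate -> clonality
-> CIS -> enrichment, with a single JSON report plus TSV bundle.

A single global seed fans out to per-stage substreams through
``numpy.random.SeedSequence`` spawn keys, so each stage is individually
reproducible and the whole run is deterministic for a fixed config.
"""
from __future__ import annotations

import json
import logging
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from . import annotate, cis, clonality, io, retrieval, simulate
from .types import ISCollection, ToyGenome

log = logging.getLogger("sbinsite")

SCHEMA_VERSION = "1.0"

DEFAULT_PARAMS = {
    "vector_tag": simulate.DEFAULT_VECTOR_TAG,
    "enzymes": list(simulate.DEFAULT_ENZYMES),
    "flank_len_range": [30, 60],
    "error_rate": 0.0,
    "min_flank": simulate.DEFAULT_MIN_FLANK,
    "max_tag_mismatch": 1,
    "seed_len": retrieval.DEFAULT_SEED_LEN,
    "max_map_mismatch": 2,
    "merge_window": retrieval.DEFAULT_MERGE_WINDOW,
    "collision_ratio": 10.0,
    "bin_edges_kb": [1.0, 10.0, 100.0, 1000.0],
    "flank": annotate.DEFAULT_FLANK,
    "pool": True,
    "label_threshold": clonality.DEFAULT_LABEL_THRESHOLD,
    "alarm_threshold": clonality.DEFAULT_ALARM_THRESHOLD,
    "window": cis.DEFAULT_WINDOW,
    "min_is": cis.DEFAULT_MIN_IS,
    "n_sim": cis.DEFAULT_N_SIM,
    "per_chromosome_null": False,
}


def _stage_seed(seed: int, key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(key,)))


def _stage_seed_int(seed: int, key: int) -> int:
    return int(np.random.SeedSequence(seed, spawn_key=(key,)).generate_state(1)[0] % (2**31))


def load_config(path) -> dict:
    import yaml

    with open(path) as fh:
        return yaml.safe_load(fh)


def validate_config(config: dict) -> dict:
    params = dict(DEFAULT_PARAMS)
    params.update(config.get("params", {}))
    if params["min_is"] < 1 or params["window"] <= 0:
        raise ValueError("window and min_is must be positive")
    if not (0 <= params["error_rate"] < 1):
        raise ValueError("error_rate must lie in [0,1)")
    if len(params["vector_tag"]) < 12:
        raise ValueError("vector_tag must be >= 12 nt")
    if "simulate" not in config and "inputs" not in config:
        raise ValueError("config needs a 'simulate' or an 'inputs' section")
    if "seed" not in config:
        raise ValueError("config needs a global seed")
    return params


def run_pipeline(config: dict, outdir: str | Path | None = None) -> dict:
    """Run every stage of the IS safety analysis; returns the report dict.

    Stage failures abort with a stage-named RuntimeError; outputs written
    before the failure are retained in ``outdir``.
    """
    params = validate_config(config)
    seed = int(config["seed"])
    outdir = Path(outdir or config.get("outdir", "sbinsite_out"))
    outdir.mkdir(parents=True, exist_ok=True)
    report: dict = {"schema_version": SCHEMA_VERSION, "parameters": params, "seed": seed}

    def stage(name):
        log.info("stage %s: parameters=%s", name, {k: params[k] for k in sorted(params)})

    try:
        stage("inputs")
        genome, genes, sample_reads = _resolve_inputs(config, params, seed, outdir)
    except Exception as e:  # noqa: BLE001
        raise RuntimeError(f"stage inputs failed: {e}") from e

    try:
        stage("retrieve")
        index = retrieval.KmerIndex(genome, k=params["seed_len"])
        collections: list[ISCollection] = []
        for sample_id, reads in sample_reads:
            col = retrieval.retrieve_sites(
                reads,
                genome,
                vector_tag=params["vector_tag"],
                max_tag_mismatch=params["max_tag_mismatch"],
                seed_len=params["seed_len"],
                max_map_mismatch=params["max_map_mismatch"],
                merge_window=params["merge_window"],
                min_flank=params["min_flank"],
                sample_id=sample_id,
                index=index,
            )
            collections.append(col)
            log.info(
                "sample %s: %d IS, %d reads mapped, discards %s",
                sample_id, len(col.sites), col.total_reads_mapped, col.discarded,
            )
        collections, collision_report = retrieval.filter_cross_sample_collisions(
            collections, ratio_threshold=params["collision_ratio"]
        )
        for col in collections:
            io.write_is_bed(col, outdir / f"is_{col.sample_id}.bed")
        report["samples"] = [
            {
                "sample_id": c.sample_id,
                "n_is": len(c.sites),
                "reads_mapped": c.total_reads_mapped,
                "reads_discarded": dict(c.discarded),
            }
            for c in collections
        ]
        report["total_junction_reads"] = int(sum(c.total_reads_mapped for c in collections))
        report["total_unique_is"] = int(sum(len(c.sites) for c in collections))
        report["collisions"] = [
            {"chrom": c, "ta_start": p, "counts": cnt, "kept_in": win}
            for c, p, cnt, win in collision_report
        ]
    except Exception as e:  # noqa: BLE001
        raise RuntimeError(f"stage retrieve failed: {e}") from e

    pooled = ISCollection(sample_id="pooled", sites=[s for c in collections for s in c.sites])
    pooled.total_reads_mapped = sum(s.read_count for s in pooled.sites)

    try:
        stage("annotate")
        chrom_dist = annotate.chromosome_distribution(pooled, genome)
        chrom_dist.table.to_csv(outdir / "chrom_distribution.tsv", sep="\t", index=False)
        report["chromosome_distribution"] = {
            "rows": chrom_dist.table.to_dict(orient="records"),
            "chi2": chrom_dist.chi2,
            "p_value": chrom_dist.p_value,
            "note": chrom_dist.note,
        }
        annotations, tss_table = annotate.nearest_tss(
            pooled, genes, bin_edges_kb=params["bin_edges_kb"]
        )
        pd.DataFrame(
            [
                {
                    "is_id": a.is_id,
                    "nearest_gene_id": a.nearest_gene_id,
                    "signed_distance": a.signed_distance,
                    "abs_distance": abs(a.signed_distance),
                    "bin": a.bin_label,
                }
                for a in annotations
            ]
        ).to_csv(outdir / "tss_annotations.tsv", sep="\t", index=False)
        tss_table.to_csv(outdir / "tss_table.tsv", sep="\t", index=False)
        report["tss_table"] = tss_table.to_dict(orient="records")
        logo, consensus = annotate.build_logo(pooled, genome, flank=params["flank"])
        logo_json = {
            "offsets": logo.offsets,
            "freq": {str(o): logo.freq[o] for o in logo.offsets},
            "consensus": consensus,
            "n_sites": logo.n_sites,
            "n_skipped": logo.n_skipped,
        }
        with open(outdir / "logo.json", "w") as fh:
            json.dump(logo_json, fh, indent=1)
        report["logo"] = logo_json
    except Exception as e:  # noqa: BLE001
        raise RuntimeError(f"stage annotate failed: {e}") from e

    try:
        stage("clonality")
        nearest = {a.is_id: a.nearest_gene_id for a in annotations}
        records = clonality.clonal_abundance(collections, pool=params["pool"], nearest_gene=nearest)
        labeled, verdict = clonality.flag_dominance(
            records,
            label_threshold=params["label_threshold"],
            alarm_threshold=params["alarm_threshold"],
        )
        pd.DataFrame(
            [{"is_id": r.is_id, "nearest_gene_id": r.nearest_gene_id, "percent": r.percent} for r in records]
        ).to_csv(outdir / "abundance.tsv", sep="\t", index=False)
        report["abundance"] = {
            "n_records": len(records),
            "labeled": [
                {"is_id": r.is_id, "nearest_gene_id": r.nearest_gene_id, "percent": r.percent}
                for r in labeled
            ],
            "verdict": verdict,
            "max_percent": records[0].percent if records else 0.0,
        }
        log.info("clonality verdict: %s (%d clones > %.1f%%)", verdict, len(labeled), params["label_threshold"])
    except Exception as e:  # noqa: BLE001
        raise RuntimeError(f"stage clonality failed: {e}") from e

    try:
        stage("cis")
        result = cis.cis_montecarlo(
            pooled,
            genome,
            window=params["window"],
            min_is=params["min_is"],
            n_sim=params["n_sim"],
            seed=_stage_seed_int(seed, 10),
            per_chromosome_null=params["per_chromosome_null"],
        )
        pd.DataFrame(
            [
                {
                    "chrom": c.chrom,
                    "start": c.start,
                    "end": c.end,
                    "n_is": c.n_is,
                    "p": p,
                    "members": ",".join(c.member_is_ids),
                }
                for c, p in zip(result.observed_clusters, result.per_cluster_p)
            ]
        ).to_csv(outdir / "cis_clusters.tsv", sep="\t", index=False)
        report["cis"] = {
            "n_clusters": len(result.observed_clusters),
            "p_global": result.p_global,
            "n_sim": result.n_sim,
            "clusters": [
                {"chrom": c.chrom, "start": c.start, "end": c.end, "n_is": c.n_is, "p": p}
                for c, p in zip(result.observed_clusters, result.per_cluster_p)
            ],
        }
        log.info("CIS: %d clusters, p_global=%.4g", len(result.observed_clusters), result.p_global)
    except Exception as e:  # noqa: BLE001
        raise RuntimeError(f"stage cis failed: {e}") from e

    try:
        stage("enrich")
        gene_sets = _resolve_gene_sets(config, genes)
        if gene_sets:
            enr = cis.gene_set_enrichment(annotations, gene_sets, genes)
            pd.DataFrame(
                [
                    {"set_id": r.set_id, "k": r.k, "K": r.K, "n": r.n, "N": r.N, "p": r.p, "q": r.q}
                    for r in enr
                ]
            ).to_csv(outdir / "enrichment.tsv", sep="\t", index=False)
            report["enrichment"] = [
                {"set_id": r.set_id, "k": r.k, "K": r.K, "n": r.n, "N": r.N, "p": r.p, "q": r.q}
                for r in enr
            ]
        else:
            report["enrichment"] = []
    except Exception as e:  # noqa: BLE001
        raise RuntimeError(f"stage enrich failed: {e}") from e

    validate_report(report)
    with open(outdir / "report.json", "w") as fh:
        json.dump(report, fh, indent=1, default=_jsonable)
    return report


def _jsonable(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serializable: {type(o)}")


def _resolve_inputs(config, params, seed, outdir):
    """Either simulate the inputs or load them from paths."""
    if "simulate" in config:
        sim = config["simulate"]
        g = sim["genome"]
        genome = simulate.simulate_genome(
            n_chrom=g.get("n_chrom", 4),
            length_per_chrom=g["length_per_chrom"],
            gc_fraction=g.get("gc_fraction", 0.45),
            seed=_stage_seed_int(seed, 1),
        )
        io.write_fasta(genome, outdir / "genome.fa")
        gn = sim["genes"]
        genes = simulate.simulate_annotations(
            genome,
            n_genes=gn["n_genes"],
            mean_len=gn.get("mean_len", 5000),
            seed=_stage_seed_int(seed, 2),
            tcell_fraction=gn.get("tcell_fraction", 0.2),
        )
        io.write_gff3(genes, outdir / "genes.gff3")
        sample_reads = []
        for si, spec_ in enumerate(sim["samples"]):
            sample_id = spec_.get("sample_id", f"S{si + 1}")
            bias = dict(spec_.get("bias_params", {}))
            if spec_.get("mode") == "tss_biased":
                bias.setdefault("genes", genes)
            insertions = simulate.simulate_insertions(
                genome,
                n_clones=spec_["n_clones"],
                mode=spec_.get("mode", "uniform_TA"),
                bias_params=bias,
                abundance_model=spec_.get("abundance_model", "dirichlet"),
                abundance_params=spec_.get("abundance_params", {}),
                seed=_stage_seed_int(seed, 100 + si),
            )
            reads, n_dropped = simulate.simulate_lam_reads(
                insertions,
                genome,
                vector_tag=params["vector_tag"],
                enzymes=tuple(params["enzymes"]),
                reads_total=spec_.get("reads_total", 20000),
                flank_len_range=tuple(params["flank_len_range"]),
                error_rate=params["error_rate"],
                seed=_stage_seed_int(seed, 200 + si),
                sample_id=sample_id,
                min_flank=params["min_flank"],
            )
            per_clone: dict[str, int] = {}
            for r in reads:
                per_clone[r.truth.clone_id] = per_clone.get(r.truth.clone_id, 0) + 1
            io.write_truth_bed(insertions, per_clone, outdir / f"truth_{sample_id}.bed")
            io.write_fastq(reads, outdir / f"reads_{sample_id}.fastq")
            log.info("sample %s: %d reads emitted, %d dropped", sample_id, len(reads), n_dropped)
            sample_reads.append((sample_id, reads))
        return genome, genes, sample_reads
    inputs = config["inputs"]
    genome = io.read_fasta(inputs["genome_fasta"])
    genes = io.read_gff3(inputs["genes_gff3"]) if "genes_gff3" in inputs else []
    sample_reads = []
    for entry in inputs.get("reads_fastq", []):
        sample_reads.append(
            (entry["sample_id"], io.read_fastq(entry["path"], sample_id=entry["sample_id"]))
        )
    return genome, genes, sample_reads


def _resolve_gene_sets(config, genes) -> dict[str, list[str]]:
    if "gene_sets_gmt" in config.get("inputs", {}):
        return io.read_gmt(config["inputs"]["gene_sets_gmt"])
    classes: dict[str, list[str]] = {}
    for g in genes:
        if g.expression_class != "none":
            classes.setdefault(g.expression_class, []).append(g.gene_id)
    return classes


def load_schema() -> dict:
    with resources.files("sbinsite").joinpath("report_schema.json").open() as fh:
        return json.load(fh)


def validate_report(report: dict, schema: dict | None = None, path: str = "$") -> None:
    """Minimal JSON-schema-subset validation (type/required/properties/items)."""
    schema = schema or load_schema()
    _validate(report, schema, path)


_TYPES = {
    "object": dict,
    "array": list,
    "string": str,
    "boolean": bool,
    "integer": (int, np.integer),
    "number": (int, float, np.integer, np.floating),
}


def _validate(value, schema, path):
    t = schema.get("type")
    if t is not None:
        py = _TYPES[t]
        if t in ("integer", "number") and isinstance(value, bool):
            raise ValueError(f"{path}: expected {t}, got bool")
        if not isinstance(value, py):
            raise ValueError(f"{path}: expected {t}, got {type(value).__name__}")
    for key in schema.get("required", []):
        if key not in value:
            raise ValueError(f"{path}: missing required key '{key}'")
    for key, sub in schema.get("properties", {}).items():
        if isinstance(value, dict) and key in value:
            _validate(value[key], sub, f"{path}.{key}")
    if "items" in schema and isinstance(value, list):
        for i, item in enumerate(value):
            _validate(item, schema["items"], f"{path}[{i}]")
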