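"""End-to-end comparative analysis: orchestrates every stage from a config.

The run mirrors a full comparative chloroplast-genome study: per-genome
feature statistics, IR/SC junction table, repeat tables, per-region
alignments concatenated into a partitioned supermatrix, sliding
identity, p-distance and group divergence, marker ranking, indel coding
with its parsimony tree, and per-partition maximum-parsimony trees with
bootstrap support.  Stage failures are logged and recorded in the
manifest rather than aborting the run.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import align as al
from . import divergence as dv
from . import indels as il
from . import parsimony as mp
from . import quadripartite as qp
from . import repeats as rp
from .records import PlastomeRecord, base_composition, gene_inventory

log = logging.getLogger(__name__)

PARTITIONS = ("whole", "lsc", "ssc", "ir", "coding", "spacers", "introns")


@dataclass
class RunConfig:
    records: list  # paths to GenBank files or PlastomeRecord objects
    reference: str  # record id
    seed: int
    groups: dict[str, str] = field(default_factory=dict)
    marker_min_len: int = 350
    marker_threshold: float = 5.0
    region_min_len: int = 200
    bootstrap: int = 100
    min_ir_len: int = 1000
    out_dir: str | None = None

    def __post_init__(self):
        if self.seed is None:
            raise ValueError("seed is mandatory")


def _load(records) -> list[PlastomeRecord]:
    from . import io as pio
    out = []
    for r in records:
        out.append(r if isinstance(r, PlastomeRecord) else pio.read_genbank(r))
    return out


def _classify_partition(region_set: al.RegionSet, part: qp.IRPartition,
                        n: int) -> str:
    mid = ((region_set.ref_span[0] + region_set.ref_span[1]) // 2) % n
    for name in ("lsc", "irb", "ssc", "ira"):
        s, e = getattr(part, name)
        if (mid - s % n) % n < (e - s):
            return {"irb": "ir", "ira": "ir"}.get(name, name)
    return "lsc"


def run(config: RunConfig) -> dict:
    """Execute the full analysis; returns a result bundle with a manifest."""
    results: dict = {}
    status: dict[str, str] = {}
    records = _load(config.records)
    by_id = {r.id: r for r in records}
    if config.reference not in by_id:
        raise ValueError(f"reference {config.reference!r} not among inputs")
    reference = by_id[config.reference]

    def stage(name):
        def deco(fn):
            try:
                results[name] = fn()
                status[name] = "ok"
            except Exception as exc:  # noqa: BLE001 - degraded-run contract
                log.warning("stage %s failed: %s", name, exc)
                status[name] = f"failed: {exc}"
            return fn
        return deco

    @stage("genome_stats")
    def _stats():
        rows = []
        for rec in records:
            inv = gene_inventory(rec)
            comp = base_composition(rec.sequence)
            try:
                part = qp.detect_inverted_repeats(rec, config.min_ir_len)
                ir_len, lsc_len, ssc_len = (part.ir_length,
                                            part.region_length("lsc"),
                                            part.region_length("ssc"))
            except qp.NoQuadripartiteStructure:
                part, ir_len, lsc_len, ssc_len = None, None, None, None
            rows.append({"record": rec.id, "taxon": rec.taxon,
                         "size_bp": rec.length, "lsc_bp": lsc_len,
                         "ssc_bp": ssc_len, "ir_bp": ir_len,
                         "at_percent": comp["at_percent"],
                         "unique_genes": inv.unique_genes, "trna": inv.trna,
                         "rrna": inv.rrna,
                         "protein_coding": inv.protein_coding,
                         "duplicated_in_ir": inv.duplicated_in_ir})
            results.setdefault("partitions_by_record", {})[rec.id] = part
        return pd.DataFrame(rows)

    @stage("junctions")
    def _junctions():
        reports = []
        for rec in records:
            part = results["partitions_by_record"].get(rec.id)
            if part is not None:
                reports.append(qp.junction_profile(rec, part))
        return qp.compare_junctions(reports)

    @stage("repeats")
    def _repeats():
        per_genome = {rec.id: rp.scan_genome(rec) for rec in records}
        return {"hits": per_genome, "summary": rp.repeat_summary(per_genome)}

    @stage("alignments")
    def _alignments():
        part = results["partitions_by_record"][reference.id]
        regions = al.extract_homologous_regions(
            records, reference, categories="both",
            min_len=config.region_min_len)
        msas, categories = [], {}
        for rs in regions:
            msa = al.progressive_msa(rs.seqs, region=rs.name)
            msas.append(msa)
            categories[rs.name] = (rs.category,
                                   _classify_partition(rs, part, reference.length))
        matrix = al.concatenate(msas)
        return {"regions": regions, "msas": msas, "categories": categories,
                "supermatrix": matrix}

    @stage("identity")
    def _identity():
        return al.sliding_identity(results["alignments"]["supermatrix"].supermatrix,
                                   reference.id)

    @stage("divergence")
    def _divergence():
        dm = dv.p_distance(results["alignments"]["supermatrix"].supermatrix)
        out = {"p_distance": dm}
        if config.groups:
            out["group_means"] = dv.group_divergence(dm, config.groups)
        return out

    @stage("markers")
    def _markers():
        part = results["partitions_by_record"][reference.id]
        regions = al.extract_homologous_regions(
            records, reference, categories="both",
            min_len=config.marker_min_len, single_copy_only=True,
            partition=part)
        reports = []
        for rs in regions:
            msa = al.progressive_msa(rs.seqs, region=rs.name)
            reports.append(dv.marker_report(msa, category=rs.category))
        ranked = dv.rank_markers(reports, config.marker_threshold)
        out = {"all": reports, "ranked": ranked,
               "table": dv.markers_table(ranked)}
        try:
            out["regression"] = dv.pis_variability_regression(reports)
        except ValueError as exc:
            out["regression"] = None
            log.warning("PIS regression unavailable: %s", exc)
        return out

    @stage("indels")
    def _indels():
        events = []
        for msa in results["alignments"]["msas"]:
            if results["alignments"]["categories"][msa.region][0] != "coding":
                continue
            events.extend(il.extract_indel_events(msa))
        taxa = [r.id for r in records]
        matrix = il.code_binary(events, taxa, informative_only=True)
        out = {"events": events, "informative": il.informative_events(events),
               "matrix": matrix}
        if matrix.shape[1] > 0 and len(taxa) >= 4:
            cm = mp.CharacterMatrix.from_binary(matrix)
            best_len, best = mp.exhaustive_search(cm, max_taxa=10)
            out["mp"] = {"length": best_len,
                         "newick": mp.topology_to_newick(best[0], taxa)}
        return out

    @stage("mp_trees")
    def _mp_trees():
        bundle = results["alignments"]
        matrix = bundle["supermatrix"]
        cats = bundle["categories"]
        taxa = matrix.supermatrix.taxa
        rng = np.random.default_rng(config.seed)
        out = {}
        for part_name in PARTITIONS:
            cols = []
            for region, start, end in matrix.partitions:
                cat, struct = cats[region]
                keep = (part_name == "whole"
                        or (part_name == "coding" and cat == "coding")
                        or (part_name == "spacers" and cat == "noncoding"
                            and "-intron" not in region and "-" in region)
                        or (part_name == "introns" and "-intron" in region)
                        or (part_name in ("lsc", "ssc", "ir") and struct == part_name))
                if keep:
                    cols.append((start, end))
            if not cols:
                continue
            rows = {t: "".join(matrix.supermatrix.rows[t][s:e] for s, e in cols)
                    for t in taxa}
            msa = al.Msa(region=part_name, rows=rows)
            cm = mp.CharacterMatrix.from_msa(msa)
            boot = mp.bootstrap_support(cm, replicates=config.bootstrap,
                                        seed=int(rng.integers(2**31)))
            ci, ri = mp.ci_ri(boot.topology, cm)
            L, pct_var, n_var, n_pis, pct_pis = dv.site_stats(msa)
            out[part_name] = {
                "aligned_length": L, "variable_sites": n_var,
                "pct_variable": pct_var, "informative_sites": n_pis,
                "pct_informative": pct_pis, "tree_length": boot.best_length,
                "ci": ci, "ri": ri,
                "newick": boot.newick(taxa),
                "support": {",".join(sorted(taxa[i] for i in s)): v
                            for s, v in boot.support.items()},
            }
        return out

    manifest = {
        "seed": config.seed,
        "reference": config.reference,
        "n_records": len(records),
        "parameters": {
            "marker_min_len": config.marker_min_len,
            "marker_threshold": config.marker_threshold,
            "region_min_len": config.region_min_len,
            "bootstrap": config.bootstrap,
            "min_ir_len": config.min_ir_len,
        },
        "stages": status,
        "n_partitions": len(results.get("mp_trees", {})),
    }
    results["manifest"] = manifest
    if config.out_dir:
        write_outputs(results, config.out_dir)
    return results


def write_outputs(results: dict, out_dir) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if isinstance(results.get("genome_stats"), pd.DataFrame):
        results["genome_stats"].to_csv(out / "genome_stats.tsv", sep="\t",
                                       index=False)
    if isinstance(results.get("junctions"), pd.DataFrame):
        results["junctions"].to_csv(out / "junctions.tsv", sep="\t", index=False)
    rep = results.get("repeats")
    if isinstance(rep, dict):
        rep["summary"]["table"].to_csv(out / "repeats.tsv", sep="\t", index=False)
    mk = results.get("markers")
    if isinstance(mk, dict):
        mk["table"].to_csv(out / "markers.tsv", sep="\t", index=False)
    idl = results.get("indels")
    if isinstance(idl, dict):
        idl["matrix"].to_csv(out / "indel_matrix.tsv", sep="\t")
    trees = results.get("mp_trees")
    if isinstance(trees, dict):
        serializable = {k: {kk: vv for kk, vv in v.items()}
                        for k, v in trees.items()}
        (out / "mp_trees.json").write_text(json.dumps(serializable, indent=1))
    (out / "manifest.json").write_text(json.dumps(results["manifest"], indent=1))
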