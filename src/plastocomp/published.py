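"""Analysis of the eight published Araliaceae/Apiaceae plastomes.

This module drives the full pipeline over the study's deposited genomes
(the five newly sequenced Araliaceae plastomes plus Panax ginseng,
Eleutherococcus senticosus and the Daucus carota outgroup) and compares
the recomputed statistics with the published values, emitting a
per-quantity diff for inspection.  The GenBank records must be supplied
locally (e.g. downloaded once with ``fetch_accessions``); nothing is
bundled with the package.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from . import pipeline
from .records import base_composition, gene_inventory
from .quadripartite import detect_inverted_repeats

#: the five newly sequenced genomes
NEW_ACCESSIONS = {
    "KC456163": "Aralia undulata",
    "KC456164": "Brassaiopsis hainla",
    "KC456167": "Kalopanax septemlobus",
    "KC456165": "Metapanax delavayi",
    "KC456166": "Schefflera delavayi",
}
#: previously published genomes completing the eight-taxon data set
EXTRA_ACCESSIONS = {
    "JN637765": "Eleutherococcus senticosus",
    "AY582139": "Panax ginseng",
    "DQ898156": "Daucus carota",
}
ALL_ACCESSIONS = {**NEW_ACCESSIONS, **EXTRA_ACCESSIONS}

GROUPS = {
    "KC456164": "asian_palmate", "JN637765": "asian_palmate",
    "KC456167": "asian_palmate", "KC456165": "asian_palmate",
    "KC456166": "asian_palmate",
    "KC456163": "aralia_panax", "AY582139": "aralia_panax",
}

#: published per-genome features (size, LSC, SSC, IR in bp; AT %)
PUBLISHED_GENOME_FEATURES = {
    "KC456163": {"size_bp": 156_333, "lsc_bp": 86_028, "ssc_bp": 18_089,
                 "ir_bp": 26_108, "at_percent": 61.9},
    "KC456164": {"size_bp": 156_459, "lsc_bp": 86_566, "ssc_bp": 18_021,
                 "ir_bp": 25_936, "at_percent": 62.0},
    "KC456167": {"size_bp": 156_413, "lsc_bp": 86_466, "ssc_bp": 18_119,
                 "ir_bp": 25_914, "at_percent": 62.0},
    "KC456165": {"size_bp": 156_343, "lsc_bp": 86_360, "ssc_bp": 18_131,
                 "ir_bp": 25_926, "at_percent": 62.0},
    "KC456166": {"size_bp": 156_341, "lsc_bp": 86_122, "ssc_bp": 19_117,
                 "ir_bp": 25_551, "at_percent": 62.2},
}
PUBLISHED_SUMMARY = {
    "unique_genes": 114, "trna": 30, "rrna": 4, "protein_coding": 80,
    "repeats_total": 140, "repeats_palindromic": 78,
    "repeats_noncoding": 83, "p_between_groups": 0.011,
    "p_within_asian_palmate": 0.005, "p_within_aralia_panax": 0.01,
    "n_markers": 26, "top_marker": "trnK-rps16",
    "informative_indels": 65,
}


def fetch_accessions(out_dir, email: str = "plastocomp@example.org") -> None:
    """Download the eight records from NCBI into ``out_dir`` (one-time;
    requires network access)."""
    from Bio import Entrez, SeqIO
    Entrez.email = email
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for acc in ALL_ACCESSIONS:
        dest = out / f"{acc}.gb"
        if dest.exists():
            continue
        with Entrez.efetch(db="nucleotide", id=acc, rettype="gb",
                           retmode="text") as handle:
            dest.write_text(handle.read())


def load_records(records_dir):
    from . import io as pio
    recs = []
    missing = []
    for acc in ALL_ACCESSIONS:
        path = Path(records_dir) / f"{acc}.gb"
        if not path.exists():
            missing.append(acc)
        else:
            recs.append(pio.read_genbank(path))
    if missing:
        raise FileNotFoundError(
            f"missing GenBank records in {records_dir}: {', '.join(missing)}; "
            "download them once with plastocomp.published.fetch_accessions")
    return recs


def run_published_analysis(records_dir, seed: int = 1, out_dir=None) -> dict:
    """Recompute the published genome statistics and report diffs.

    Returns the pipeline result bundle plus a ``diff`` DataFrame with
    one row per recomputed quantity (recomputed, published, delta).
    """
    records = load_records(records_dir)
    config = pipeline.RunConfig(
        records=records, reference="AY582139", seed=seed, groups=GROUPS,
        marker_min_len=350, marker_threshold=5.0, region_min_len=200,
        bootstrap=500, out_dir=out_dir)
    results = pipeline.run(config)

    rows = []

    def add(name, recomputed, published):
        delta = (None if recomputed is None or published is None
                 or isinstance(published, str)
                 else recomputed - published)
        rows.append({"quantity": name, "recomputed": recomputed,
                     "published": published, "delta": delta})

    stats = results.get("genome_stats")
    if isinstance(stats, pd.DataFrame):
        for acc, pub in PUBLISHED_GENOME_FEATURES.items():
            row = stats[stats.record.str.startswith(acc)]
            if row.empty:
                continue
            row = row.iloc[0]
            for key, val in pub.items():
                add(f"{acc}:{key}", row[key], val)
        five = stats[stats.record.str.match("|".join(NEW_ACCESSIONS))]
        if not five.empty:
            for key in ("unique_genes", "trna", "rrna", "protein_coding"):
                add(key, int(five[key].iloc[0]), PUBLISHED_SUMMARY[key])

    rep = results.get("repeats")
    if isinstance(rep, dict):
        new_hits = {k: v for k, v in rep["hits"].items()
                    if any(k.startswith(a) for a in NEW_ACCESSIONS)}
        total = sum(len(v) for v in new_hits.values())
        pal = sum(1 for v in new_hits.values() for h in v
                  if h.type == "palindromic")
        nc = sum(1 for v in new_hits.values() for h in v
                 if h.context in ("", "noncoding"))
        add("repeats_total", total, PUBLISHED_SUMMARY["repeats_total"])
        add("repeats_palindromic", pal, PUBLISHED_SUMMARY["repeats_palindromic"])
        add("repeats_noncoding", nc, PUBLISHED_SUMMARY["repeats_noncoding"])

    div = results.get("divergence")
    if isinstance(div, dict) and "group_means" in div:
        gm = div["group_means"]
        add("p_between_groups", gm.get("between:aralia_panax|asian_palmate"),
            PUBLISHED_SUMMARY["p_between_groups"])
        add("p_within_asian_palmate", gm.get("within:asian_palmate"),
            PUBLISHED_SUMMARY["p_within_asian_palmate"])
        add("p_within_aralia_panax", gm.get("within:aralia_panax"),
            PUBLISHED_SUMMARY["p_within_aralia_panax"])

    mk = results.get("markers")
    if isinstance(mk, dict):
        add("n_markers", len(mk["ranked"]), PUBLISHED_SUMMARY["n_markers"])
        if mk["ranked"]:
            add("top_marker", mk["ranked"][0].region,
                PUBLISHED_SUMMARY["top_marker"])

    idl = results.get("indels")
    if isinstance(idl, dict):
        add("informative_indels", len(idl["informative"]),
            PUBLISHED_SUMMARY["informative_indels"])

    results["diff"] = pd.DataFrame(rows)
    if out_dir:
        results["diff"].to_csv(Path(out_dir) / "published_diff.tsv", sep="\t",
                               index=False)
    return results
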