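"""Readers/writers for GenBank, FASTA, aligned FASTA and Newick.

Biopython does the flat-file heavy lifting; this module converts between
its objects and the package's :class:`~plastocomp.records.PlastomeRecord`
(1-based inclusive GenBank locations become 0-based half-open intervals
at this boundary) and enforces the round-trip guarantees the rest of the
pipeline relies on.
"""

from __future__ import annotations

import logging
from pathlib import Path

import dendropy
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqFeature import CompoundLocation, SeqFeature, SimpleLocation
from Bio.SeqRecord import SeqRecord

from .records import Feature, PlastomeRecord

log = logging.getLogger(__name__)

_FEATURE_KINDS = {"gene", "CDS", "tRNA", "rRNA", "exon", "intron"}


def _feature_name(bio_feature) -> str | None:
    q = bio_feature.qualifiers
    for key in ("gene", "locus_tag", "product"):
        if key in q and q[key]:
            return q[key][0]
    return None


def read_genbank(path) -> PlastomeRecord:
    """Read one annotated genome from a GenBank flat file."""
    try:
        bio = SeqIO.read(str(path), "genbank")
    except ValueError as exc:
        raise ValueError(f"{path}: not a readable GenBank record: {exc}") from exc
    seq = str(bio.seq).upper()
    if not seq or set(seq) == {"N"}:
        raise ValueError(f"{path}: record has no usable ORIGIN sequence")
    circular = bio.annotations.get("topology", "circular") == "circular"
    taxon = bio.annotations.get("organism", "") or ""

    features = []
    n = len(seq)
    for bf in bio.features:
        if bf.type not in _FEATURE_KINDS:
            continue
        name = _feature_name(bf)
        if name is None:
            log.warning("%s: skipping %s feature without a name", path, bf.type)
            continue
        try:
            intervals = []
            parts = bf.location.parts
            for part in parts:
                s, e = int(part.start), int(part.end)
                strand = -1 if part.strand == -1 else 1
                intervals.append((s, e, strand))
            # re-join a feature split across the origin into one wrapping interval
            if (circular and len(intervals) == 2
                    and intervals[0][2] == intervals[1][2]):
                (s1, e1, st), (s2, e2, _) = intervals
                if st == 1 and e1 == n and s2 == 0:
                    intervals = [(s1, e1 + e2, st)]
                elif st == -1 and e2 == n and s1 == 0:
                    intervals = [(s2, e2 + e1, st)]
            pseudo = "pseudo" in bf.qualifiers or "pseudogene" in bf.qualifiers
            features.append(Feature(name=name, kind=bf.type,
                                    intervals=intervals, pseudo=pseudo))
        except (ValueError, TypeError) as exc:
            log.warning("%s: skipping feature %s with unparseable location: %s",
                        path, name, exc)
    return PlastomeRecord(id=bio.id or bio.name, sequence=seq, taxon=taxon,
                          circular=circular, features=features)


def write_genbank(record: PlastomeRecord, path) -> None:
    n = record.length
    bio = SeqRecord(Seq(record.sequence), id=record.id, name=record.id[:16],
                    description=record.taxon)
    bio.annotations["molecule_type"] = "DNA"
    bio.annotations["topology"] = "circular" if record.circular else "linear"
    if record.taxon:
        bio.annotations["organism"] = record.taxon
    for f in record.features:
        locs = []
        for s, e, strand in f.intervals:
            if e > n:  # wrapping interval -> canonical two-part join
                first = SimpleLocation(s, n, strand)
                second = SimpleLocation(0, e - n, strand)
                locs.extend([first, second] if strand == 1 else [second, first])
            else:
                locs.append(SimpleLocation(s, e, strand))
        location = locs[0] if len(locs) == 1 else CompoundLocation(locs)
        qualifiers = {"gene": [f.name]}
        if f.pseudo:
            qualifiers["pseudo"] = [""]
        bio.features.append(SeqFeature(location, type=f.kind, qualifiers=qualifiers))
    SeqIO.write(bio, str(path), "genbank")


def read_fasta(path) -> dict[str, str]:
    """Read FASTA into an ordered {id: sequence} mapping (gaps preserved)."""
    out: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in out:
            raise ValueError(f"{path}: duplicate identifier {rec.id!r}")
        out[rec.id] = str(rec.seq).upper()
    return out


def write_fasta(seqs: dict[str, str], path, width: int = 70) -> None:
    if len(set(seqs)) != len(seqs):
        raise ValueError("duplicate identifiers")
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


def read_newick(source) -> dendropy.Tree:
    """Read one Newick tree from a path or a string."""
    try:
        is_file = Path(str(source)).exists()
    except OSError:
        is_file = False
    if is_file:
        return dendropy.Tree.get(path=str(source), schema="newick",
                                 preserve_underscores=True)
    return dendropy.Tree.get(data=str(source), schema="newick",
                             preserve_underscores=True)


def write_newick(tree: dendropy.Tree, path) -> None:
    tree.write(path=str(path), schema="newick", suppress_rooting=True,
               unquoted_underscores=True)
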