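"""Annotated circular-genome data model.

Coordinates are 0-based half-open throughout the package; GenBank I/O
converts at the boundary.  A feature interval may extend past the end of
a circular sequence (``end > length``), meaning it wraps through the
origin; every interval satisfies ``start < end`` after this unwrapping.
"""

from __future__ import annotations

from dataclasses import dataclass, field

VALID_BASES = set("ACGTN")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class Feature:
    """One annotated feature: gene, CDS, tRNA, rRNA, exon or intron.

    ``intervals`` is an ordered list of ``(start, end, strand)`` with
    strand ``+1``/``-1``; multi-interval features concatenate in listed
    order (spliced genes, trans-spliced rps12, origin-wrapping genes).
    """

    name: str
    kind: str  # gene | CDS | tRNA | rRNA | exon | intron
    intervals: list[tuple[int, int, int]]
    pseudo: bool = False

    def __post_init__(self):
        if not self.intervals:
            raise ValueError(f"feature {self.name!r} has no intervals")
        for s, e, st in self.intervals:
            if not s < e:
                raise ValueError(f"feature {self.name!r}: interval start must precede end")
            if st not in (1, -1):
                raise ValueError(f"feature {self.name!r}: strand must be +1 or -1")

    @property
    def span(self) -> tuple[int, int]:
        """Minimal (start, end) covering all intervals (unwrapped coords)."""
        return (min(s for s, _, _ in self.intervals),
                max(e for _, e, _ in self.intervals))

    @property
    def length(self) -> int:
        return sum(e - s for s, e, _ in self.intervals)


@dataclass
class PlastomeRecord:
    """A (usually circular) annotated plastid genome."""

    id: str
    sequence: str
    taxon: str = ""
    circular: bool = True
    features: list[Feature] = field(default_factory=list)

    def __post_init__(self):
        if not self.id:
            raise ValueError("record id must be nonempty")
        self.sequence = self.sequence.upper()
        bad = set(self.sequence) - VALID_BASES
        if bad:
            raise ValueError(f"record {self.id}: ambiguity codes not supported: {sorted(bad)}")

    @property
    def length(self) -> int:
        return len(self.sequence)

    def genes(self, include_pseudo: bool = False):
        for f in self.features:
            if f.kind in ("gene", "CDS", "tRNA", "rRNA") and (include_pseudo or not f.pseudo):
                yield f


@dataclass
class GeneInventory:
    unique_genes: int
    trna: int
    rrna: int
    protein_coding: int
    duplicated_in_ir: int
    total_with_duplicates: int
    intron_containing: list[tuple[str, int]]


def extract_feature_sequence(record: PlastomeRecord, feature: Feature) -> str:
    """Spliced, strand-corrected sequence of a feature.

    Minus-strand intervals are reverse-complemented individually and the
    pieces concatenated in listed order, which handles mixed-strand
    trans-spliced genes.  Intervals with ``end > length`` read through
    the origin (circular records only).
    """
    n = record.length
    pieces = []
    for s, e, strand in feature.intervals:
        if e > n:
            if not record.circular:
                raise ValueError(
                    f"feature {feature.name!r} wraps the origin of a linear record")
            piece = record.sequence[s:] + record.sequence[: e - n]
        else:
            if s < 0 or e > n:
                raise ValueError(f"feature {feature.name!r} out of range")
            piece = record.sequence[s:e]
        if strand == -1:
            piece = reverse_complement(piece)
        pieces.append(piece)
    return "".join(pieces)


def _gene_class(feature: Feature) -> str:
    name = feature.name.lower()
    if feature.kind == "tRNA" or name.startswith("trn"):
        return "trna"
    if feature.kind == "rRNA" or name.startswith("rrn"):
        return "rrna"
    return "protein"


def gene_inventory(record: PlastomeRecord) -> GeneInventory:
    """Count unique genes, IR duplicates and intron-containing genes.

    Copies are deduplicated by gene name, so IR-duplicated genes and the
    trans-spliced rps12 count once; pseudogene copies are excluded from
    the unique count entirely.
    """
    by_name: dict[str, list[Feature]] = {}
    for f in record.genes(include_pseudo=False):
        if f.kind == "CDS" and any(g.name == f.name and g.kind == "gene"
                                   for g in record.features):
            continue  # gene feature carries the locus; CDS is redundant
        by_name.setdefault(f.name, []).append(f)

    counts = {"trna": 0, "rrna": 0, "protein": 0}
    duplicated = 0
    intron_containing: list[tuple[str, int]] = []
    for name, feats in sorted(by_name.items()):
        counts[_gene_class(feats[0])] += 1
        if len(feats) > 1:
            duplicated += 1
        n_introns = max(len(f.intervals) for f in feats) - 1
        if n_introns > 0:
            intron_containing.append((name, n_introns))
    unique = sum(counts.values())
    return GeneInventory(
        unique_genes=unique,
        trna=counts["trna"],
        rrna=counts["rrna"],
        protein_coding=counts["protein"],
        duplicated_in_ir=duplicated,
        total_with_duplicates=unique + duplicated,
        intron_containing=intron_containing,
    )


def base_composition(seq: str) -> dict:
    """Base fractions over non-N positions, plus AT% to one decimal."""
    seq = seq.upper()
    counts = {b: seq.count(b) for b in "ACGT"}
    total = sum(counts.values())
    if total == 0:
        raise ValueError("composition undefined: no unambiguous bases")
    frac = {b: c / total for b, c in counts.items()}
    frac["at_percent"] = round(100.0 * (counts["A"] + counts["T"]) / total, 1)
    return frac
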