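"""Quadripartite structure: IR detection, partition and junction profiling.

A plastome is partitioned into LSC-IRb-SSC-IRa by locating the longest
pair of disjoint, exactly reverse-complementary segments (the inverted
repeats).  The four junction points are named J_LB (LSC/IRb), J_SB
(IRb/SSC), J_SA (SSC/IRa) and J_LA (IRa/LSC); genes near them (rps19,
ycf1, ndhF, trnH) are profiled by how far a border cuts into them or how
far they sit from it.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .records import Feature, PlastomeRecord, reverse_complement

_MOD = (1 << 61) - 1
_BASE = 1_000_003


class NoQuadripartiteStructure(ValueError):
    """No inverted-repeat pair of the required length exists."""


@dataclass
class IRPartition:
    """Region coordinates as (start, end) with end possibly > genome
    length to denote wrapping through the origin; start is in [0, n)."""

    lsc: tuple[int, int]
    irb: tuple[int, int]
    ssc: tuple[int, int]
    ira: tuple[int, int]
    genome_length: int

    def region_length(self, name: str) -> int:
        s, e = getattr(self, name)
        return e - s

    @property
    def ir_length(self) -> int:
        return self.region_length("irb")

    @property
    def junctions(self) -> dict[str, int]:
        n = self.genome_length
        return {
            "J_LB": self.irb[0] % n,
            "J_SB": self.ssc[0] % n,
            "J_SA": self.ira[0] % n,
            "J_LA": self.lsc[0] % n,
        }

    def region_sequence(self, record: PlastomeRecord, name: str) -> str:
        s, e = getattr(self, name)
        n = record.length
        if e <= n:
            return record.sequence[s:e]
        return record.sequence[s:] + record.sequence[: e - n]


class _Hasher:
    """Polynomial rolling hash with O(1) substring hashes."""

    def __init__(self, s: str):
        n = len(s)
        self.pre = [0] * (n + 1)
        self.pw = [1] * (n + 1)
        for i, ch in enumerate(s):
            self.pre[i + 1] = (self.pre[i] * _BASE + ord(ch)) % _MOD
            self.pw[i + 1] = (self.pw[i] * _BASE) % _MOD

    def window(self, i: int, length: int) -> int:
        return (self.pre[i + length] - self.pre[i] * self.pw[length]) % _MOD


def _find_pair(s2: str, rc2: str, ha: _Hasher, hb: _Hasher, n: int,
               length: int, circular: bool) -> tuple[int, int] | None:
    """Find (i, j): s[i:i+length] == revcomp(s[j:j+length]), disjoint on
    the circle.  s2/rc2 are the (doubled, for circular input) sequence
    and its reverse complement."""
    limit = len(s2) - length
    table: dict[int, list[int]] = {}
    for p in range(limit + 1):
        table.setdefault(hb.window(p, length), []).append(p)
    best = None
    imax = n if circular else limit + 1
    for i in range(min(imax, limit + 1)):
        hits = table.get(ha.window(i, length))
        if not hits:
            continue
        for p in hits:
            # rc2[p:p+length] is revcomp of s2[len(s2)-p-length : len(s2)-p]
            j = (len(s2) - p - length) % n if circular else len(s2) - p - length
            ii = i % n if circular else i
            if circular:
                if (j - ii) % n < length or (ii - j) % n < length:
                    continue
            else:
                if not (ii + length <= j or j + length <= ii):
                    continue
            if s2[i:i + length] != rc2[p:p + length]:
                continue  # hash collision
            cand = (min(ii, j), max(ii, j))
            if best is None or cand < best:
                best = cand
        if best is not None and not circular:
            break
    return best


def detect_inverted_repeats(record: PlastomeRecord,
                            min_ir_len: int = 1000) -> IRPartition:
    """Locate the IR pair and partition the genome LSC-IRb-SSC-IRa.

    The pair returned is the longest pair of disjoint, exactly
    reverse-complementary segments of length >= ``min_ir_len`` (ties
    broken by leftmost coordinates); the longer single-copy gap becomes
    the LSC.  Raises :class:`NoQuadripartiteStructure` when no such pair
    exists.
    """
    s = record.sequence
    n = len(s)
    if n < 4 * min_ir_len:
        raise NoQuadripartiteStructure(
            f"genome of {n} bp cannot hold two IRs of >= {min_ir_len} bp")
    s2 = s + s if record.circular else s
    rc2 = reverse_complement(s2)
    ha, hb = _Hasher(s2), _Hasher(rc2)

    lo, hi = min_ir_len, n // 2
    if _find_pair(s2, rc2, ha, hb, n, lo, record.circular) is None:
        raise NoQuadripartiteStructure(
            f"no inverted repeat of >= {min_ir_len} bp found")
    while lo < hi:
        mid = (lo + hi + 1) // 2
        if _find_pair(s2, rc2, ha, hb, n, mid, record.circular) is not None:
            lo = mid
        else:
            hi = mid - 1
    length = lo
    i, j = _find_pair(s2, rc2, ha, hb, n, length, record.circular)
    return _partition_from_copies(record, i, j, length)


def _partition_from_copies(record: PlastomeRecord, i: int, j: int,
                           length: int) -> IRPartition:
    n = record.length
    gap_ij = (j - (i + length)) % n  # single-copy gap after copy at i
    gap_ji = (i - (j + length)) % n
    # decide which gap is LSC
    if gap_ij != gap_ji:
        lsc_after_i = gap_ij > gap_ji
    else:
        # tie: the gap free of rRNA annotation is the LSC, else orientation order
        def rrna_count(start, glen):
            c = 0
            for f in record.features:
                if f.kind == "rRNA" or f.name.lower().startswith("rrn"):
                    fs = f.span[0] % n
                    if (fs - start) % n < glen:
                        c += 1
            return c
        lsc_after_i = rrna_count((i + length) % n, gap_ij) <= rrna_count(
            (j + length) % n, gap_ji)
    if lsc_after_i:
        lsc_start, lsc_len = (i + length) % n, gap_ij
        irb_start, ssc_len, ira_start = j, gap_ji, i
    else:
        lsc_start, lsc_len = (j + length) % n, gap_ji
        irb_start, ssc_len, ira_start = i, gap_ij, j

    def unwrap(start, ln):
        return (start, start + ln)

    return IRPartition(
        lsc=unwrap(lsc_start, lsc_len),
        irb=unwrap(irb_start, length),
        ssc=unwrap((irb_start + length) % n, ssc_len),
        ira=unwrap(ira_start, length),
        genome_length=n,
    )


# --- junction profiling ----------------------------------------------------

#: junction each profiled gene is assessed against
PROFILE_GENES = {"rps19": "J_LB", "ycf1": "J_SA", "ndhF": "J_SB", "trnH": "J_LA"}


@dataclass
class JunctionEntry:
    record_id: str
    gene: str
    junction: str
    relation: str  # inside_region | spans_junction | missing
    overlap_into_ir: int = 0
    distance_to_border: int = 0
    pseudo_copy_length: int | None = None


def _rotated_span(feature: Feature, lsc_start: int, n: int) -> tuple[int, int]:
    """Feature span in the frame where the LSC begins at position 0."""
    starts = []
    for s, e, _ in feature.intervals:
        rs = (s - lsc_start) % n
        starts.append((rs, rs + (e - s)))
    lo = min(r[0] for r in starts)
    hi = max(r[1] for r in starts)
    if hi - lo > n // 2:  # pieces straddle the rotated origin
        lo = min(r[0] for r in starts if r[0] > n // 2) - n
        hi = max((r[1] for r in starts if r[1] <= n // 2), default=lo)
    return lo, hi


def junction_profile(record: PlastomeRecord, part: IRPartition) -> list[JunctionEntry]:
    """Profile rps19/ycf1/ndhF/trnH against their IR/SC borders.

    Reports, per gene, either the bp by which the IR extends into it
    (``spans_junction``; for rps19 and ycf1 this equals the pseudogene
    copy length on the opposite IR) or its distance to the border
    (``inside_region``).  Genes absent from the annotation are reported
    as ``missing``.
    """
    n = record.length
    lsc_start = part.lsc[0] % n
    l_lsc = part.region_length("lsc")
    l_ir = part.ir_length
    l_ssc = part.region_length("ssc")
    # rotated-frame region borders
    borders = {"J_LB": l_lsc, "J_SB": l_lsc + l_ir,
               "J_SA": l_lsc + l_ir + l_ssc, "J_LA": n}
    irb_iv = (l_lsc, l_lsc + l_ir)
    ira_iv = (l_lsc + l_ir + l_ssc, n)

    entries = []
    for gene, junction in PROFILE_GENES.items():
        cands = [f for f in record.genes(include_pseudo=False)
                 if f.name.lower().startswith(gene.lower())]
        if not cands:
            entries.append(JunctionEntry(record.id, gene, junction, "missing"))
            continue
        jpos = borders[junction] % n if junction == "J_LA" else borders[junction]

        def dist_to_junction(f):
            lo, hi = _rotated_span(f, lsc_start, n)
            jp = borders[junction]
            d = min(abs(lo - jp), abs(hi - jp), abs(lo - (jp - n)), abs(hi - (jp - n)))
            return d
        feat = min(cands, key=dist_to_junction)
        lo, hi = _rotated_span(feat, lsc_start, n)
        overlap = 0
        for a, b in (irb_iv, ira_iv):
            overlap += max(0, min(hi, b) - max(lo, a))
            # wrapped copy of the gene span
            overlap += max(0, min(hi + n, b) - max(lo + n, a))
        if overlap > 0:
            entries.append(JunctionEntry(
                record.id, gene, junction, "spans_junction",
                overlap_into_ir=overlap, pseudo_copy_length=overlap))
        else:
            jp = borders[junction]
            d = min(abs(x - y) for x in (lo, hi) for y in (jp, jp - n))
            entries.append(JunctionEntry(
                record.id, gene, junction, "inside_region", distance_to_border=d))
    return entries


def compare_junctions(reports: list[list[JunctionEntry]]) -> pd.DataFrame:
    """Cross-species junction table, one row per (species, gene)."""
    if not reports:
        raise ValueError("at least one junction report required")
    rows = []
    for report in reports:
        for e in report:
            rows.append({
                "record": e.record_id, "gene": e.gene, "junction": e.junction,
                "relation": e.relation, "overlap_into_ir": e.overlap_into_ir,
                "distance_to_border": e.distance_to_border,
                "pseudo_copy_length": e.pseudo_copy_length,
            })
    return pd.DataFrame(rows)
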