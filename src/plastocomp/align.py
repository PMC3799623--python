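"""Homologous-region extraction and alignment.

Whole-genome alignment is produced by annotation-anchored extraction of
homologous regions (shared genes, their introns, and the intergenic
spacers between consecutive shared genes) followed by per-region
progressive multiple alignment and column-wise concatenation.  The
pairwise engine is global Needleman-Wunsch with affine (Gotoh) gap
scoring; profiles are merged with sum-of-pairs column scoring under
"once a gap, always a gap".
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .records import PlastomeRecord, extract_feature_sequence, reverse_complement

GAP = "-"


@dataclass
class Msa:
    """Gap-aligned homologous sequences with a region label."""

    region: str
    rows: dict[str, str]  # taxon -> gapped sequence, equal lengths

    def __post_init__(self):
        lengths = {len(s) for s in self.rows.values()}
        if len(lengths) > 1:
            raise ValueError(f"Msa {self.region!r}: rows of unequal length")

    @property
    def taxa(self) -> list[str]:
        return list(self.rows)

    @property
    def n_columns(self) -> int:
        return len(next(iter(self.rows.values()))) if self.rows else 0

    def degapped(self, taxon: str) -> str:
        return self.rows[taxon].replace(GAP, "")

    def source_map(self, taxon: str) -> list[int | None]:
        """Per alignment column, the 0-based source coordinate (None at gaps)."""
        out, pos = [], 0
        for ch in self.rows[taxon]:
            if ch == GAP:
                out.append(None)
            else:
                out.append(pos)
                pos += 1
        return out

    def column(self, j: int) -> list[str]:
        return [s[j] for s in self.rows.values()]


@dataclass
class PartitionedMatrix:
    supermatrix: Msa
    partitions: list[tuple[str, int, int]]  # (region, start_col, end_col)


# --- pairwise ---------------------------------------------------------------

_BASES = "ACGTN"
_BASE_IDX = {b: i for i, b in enumerate(_BASES)}


def _gotoh(sub: np.ndarray, gap_open: float, gap_extend: float):
    """Global affine-gap DP over a precomputed (m x n) column-score matrix.

    A gap of length k costs gap_open + (k-1)*gap_extend.  Returns the
    score and the aligned index path as (i, j) pairs with -1 marking a
    gap.  Tie-break prefers diagonal, then up (gap in the second
    sequence), then left.
    """
    m, n = sub.shape
    NEG = -1e30
    M = np.full((m + 1, n + 1), NEG)
    X = np.full((m + 1, n + 1), NEG)  # gap in seq b (consumes a; "up")
    Y = np.full((m + 1, n + 1), NEG)  # gap in seq a (consumes b; "left")
    M[0, 0] = 0.0
    for i in range(1, m + 1):
        X[i, 0] = gap_open + (i - 1) * gap_extend
    for j in range(1, n + 1):
        Y[0, j] = gap_open + (j - 1) * gap_extend
    for i in range(1, m + 1):
        prev_best = np.maximum(np.maximum(M[i - 1], X[i - 1]), Y[i - 1])
        M[i, 1:] = prev_best[:-1] + sub[i - 1]
        X[i, 1:] = np.maximum(np.maximum(M[i - 1, 1:], Y[i - 1, 1:]) + gap_open,
                              X[i - 1, 1:] + gap_extend)
        X[i, 0] = gap_open + (i - 1) * gap_extend
        # Y[i,j] = max(Y[i,j-1]+ext, max(M,X)[i,j-1]+open); unrolled this is
        # a prefix max of C[k] = max(M,X)[i,k] + open - (k+1)*ext
        A = np.maximum(M[i], X[i])
        j_idx = np.arange(1, n + 1)
        C = A[:-1] + gap_open - j_idx * gap_extend
        Y[i, 1:] = np.maximum.accumulate(C) + j_idx * gap_extend
    # traceback
    path = []
    i, j = m, n
    layer = int(np.argmax([M[i, j], X[i, j], Y[i, j]]))  # 0=M,1=X,2=Y
    score = [M[i, j], X[i, j], Y[i, j]][layer]
    while i > 0 or j > 0:
        if layer == 0:
            path.append((i - 1, j - 1))
            prev = [M[i - 1, j - 1], X[i - 1, j - 1], Y[i - 1, j - 1]]
            target = M[i, j] - sub[i - 1, j - 1]
            layer = int(np.argmax(np.isclose(prev, target, atol=1e-6)))
            i, j = i - 1, j - 1
        elif layer == 1:
            path.append((i - 1, -1))
            if np.isclose(M[i - 1, j] + gap_open, X[i, j], atol=1e-6):
                layer = 0
            elif np.isclose(X[i - 1, j] + gap_extend, X[i, j], atol=1e-6):
                layer = 1
            else:
                layer = 2
            i -= 1
        else:
            path.append((-1, j - 1))
            if np.isclose(Y[i, j - 1] + gap_extend, Y[i, j], atol=1e-6):
                layer = 2
            elif np.isclose(M[i, j - 1] + gap_open, Y[i, j], atol=1e-6):
                layer = 0
            else:
                layer = 1
            j -= 1
        if i == 0 and j == 0:
            break
    path.reverse()
    return float(score), path


def needleman_wunsch(a: str, b: str, match: float = 1.0, mismatch: float = -1.0,
                     gap_open: float = -4.0, gap_extend: float = -1.0
                     ) -> tuple[float, Msa]:
    """Optimal global alignment of two DNA sequences under affine gaps."""
    if not a or not b:
        raise ValueError("needleman_wunsch requires nonempty sequences")
    av = np.frombuffer(a.encode(), dtype=np.uint8)
    bv = np.frombuffer(b.encode(), dtype=np.uint8)
    sub = np.where(av[:, None] == bv[None, :], match, mismatch)
    score, path = _gotoh(sub, gap_open, gap_extend)
    row_a = "".join(a[i] if i >= 0 else GAP for i, _ in path)
    row_b = "".join(b[j] if j >= 0 else GAP for _, j in path)
    return score, Msa(region="pairwise", rows={"a": row_a, "b": row_b})


def alignment_score(a: str, b: str, **kw) -> float:
    return needleman_wunsch(a, b, **kw)[0]


# --- progressive MSA --------------------------------------------------------

def _kmer_set(seq: str, k: int) -> set[str]:
    return {seq[i:i + k] for i in range(max(0, len(seq) - k + 1))}


def kmer_distance(a: str, b: str, k: int = 8) -> float:
    """1 minus the fraction of shared k-mers (relative to the smaller set)."""
    sa, sb = _kmer_set(a, k), _kmer_set(b, k)
    if not sa or not sb:
        return 1.0
    return 1.0 - len(sa & sb) / min(len(sa), len(sb))


def _nj_join_order(dist: np.ndarray):
    """Neighbor-joining; returns the nested join structure over leaf
    indices, e.g. ((0, 2), (1, 3)).  Deterministic: ties broken by the
    smallest (i, j)."""
    n = dist.shape[0]
    if n == 1:
        return 0
    nodes = list(range(n))
    reps: list = list(range(n))
    D = dist.astype(float).copy()
    while len(nodes) > 2:
        L = len(nodes)
        r = D.sum(axis=1)
        best = None
        for i in range(L):
            for j in range(i + 1, L):
                q = (L - 2) * D[i, j] - r[i] - r[j]
                if best is None or q < best[0] - 1e-12:
                    best = (q, i, j)
        _, i, j = best
        new_rep = (reps[i], reps[j])
        d_new = 0.5 * (D[i] + D[j] - D[i, j])
        keep = [x for x in range(L) if x not in (i, j)]
        D2 = np.zeros((L - 1, L - 1))
        D2[:-1, :-1] = D[np.ix_(keep, keep)]
        D2[-1, :-1] = d_new[keep]
        D2[:-1, -1] = d_new[keep]
        reps = [reps[x] for x in keep] + [new_rep]
        nodes = nodes[:L - 1]
        D = D2
    return (reps[0], reps[1])


def _profile_freq(msa: Msa) -> np.ndarray:
    """(columns x 5) base-count matrix over A,C,G,T,N (gaps excluded)."""
    L = msa.n_columns
    F = np.zeros((L, 5))
    for row in msa.rows.values():
        for j, ch in enumerate(row):
            if ch != GAP:
                F[j, _BASE_IDX.get(ch, 4)] += 1
    return F


def _merge_profiles(pa: Msa, pb: Msa, match, mismatch, gap_open, gap_extend,
                    region: str) -> Msa:
    S = np.full((5, 5), mismatch)
    np.fill_diagonal(S, match)
    S[4, :] = S[:, 4] = 0.0  # N is neutral
    fa, fb = _profile_freq(pa), _profile_freq(pb)
    na = max(1, len(pa.rows))
    nb = max(1, len(pb.rows))
    sub = (fa @ S @ fb.T) / (na * nb)
    _, path = _gotoh(sub, gap_open, gap_extend)
    rows: dict[str, str] = {}
    for name, row in pa.rows.items():
        rows[name] = "".join(row[i] if i >= 0 else GAP for i, _ in path)
    for name, row in pb.rows.items():
        rows[name] = "".join(row[j] if j >= 0 else GAP for _, j in path)
    return Msa(region=region, rows=rows)


def progressive_msa(seqs: dict[str, str], region: str = "region",
                    match: float = 1.0, mismatch: float = -1.0,
                    gap_open: float = -4.0, gap_extend: float = -1.0,
                    k: int = 8) -> Msa:
    """Progressive multiple alignment guided by a k-mer-distance NJ tree."""
    names = list(seqs)
    if not names:
        raise ValueError("no sequences to align")
    if len(names) == 1:
        return Msa(region=region, rows=dict(seqs))
    n = len(names)
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            D[i, j] = D[j, i] = kmer_distance(seqs[names[i]], seqs[names[j]], k)
    order = _nj_join_order(D)

    def build(node) -> Msa:
        if isinstance(node, int):
            return Msa(region=region, rows={names[node]: seqs[names[node]]})
        left, right = node
        return _merge_profiles(build(left), build(right), match, mismatch,
                               gap_open, gap_extend, region)

    merged = build(order)
    # restore input row order
    return Msa(region=region, rows={nm: merged.rows[nm] for nm in names})


def concatenate(msas: list[Msa]) -> PartitionedMatrix:
    """Column-wise concatenation into a partitioned supermatrix."""
    if not msas:
        raise ValueError("nothing to concatenate")
    taxa = set(msas[0].rows)
    for m in msas:
        if set(m.rows) != taxa:
            raise ValueError(f"taxon sets differ between regions "
                             f"({m.region!r} vs {msas[0].region!r})")
    order = list(msas[0].rows)
    parts = []
    rows = {t: [] for t in order}
    col = 0
    for m in msas:
        parts.append((m.region, col, col + m.n_columns))
        col += m.n_columns
        for t in order:
            rows[t].append(m.rows[t])
    super_msa = Msa(region="concatenated",
                    rows={t: "".join(chunks) for t, chunks in rows.items()})
    return PartitionedMatrix(supermatrix=super_msa, partitions=parts)


def sliding_identity(msa: Msa, reference_taxon: str, window: int = 100,
                     step: int = 25) -> pd.DataFrame:
    """Per-taxon percent identity to a reference in sliding windows.

    Identity per window = matching non-gap columns / columns where both
    sequences have a base; windows with nothing to compare yield NaN.
    Rows are keyed by the reference (degapped) coordinate of the window
    start.
    """
    if reference_taxon not in msa.rows:
        raise ValueError(f"reference {reference_taxon!r} not in alignment")
    L = msa.n_columns
    if window > L:
        raise ValueError("window exceeds alignment length")
    ref = msa.rows[reference_taxon]
    ref_coord = []
    pos = 0
    for ch in ref:
        ref_coord.append(pos)
        if ch != GAP:
            pos += 1
    recs = []
    for start in range(0, L - window + 1, step):
        for taxon, row in msa.rows.items():
            if taxon == reference_taxon:
                continue
            compared = matches = 0
            for jj in range(start, start + window):
                a, b = ref[jj], row[jj]
                if a != GAP and b != GAP:
                    compared += 1
                    if a == b:
                        matches += 1
            ident = 100.0 * matches / compared if compared else np.nan
            recs.append({"ref_start": ref_coord[start], "col_start": start,
                         "taxon": taxon, "identity": ident,
                         "compared": compared})
    return pd.DataFrame(recs)


# --- homologous-region extraction ------------------------------------------

@dataclass
class RegionSet:
    """Unaligned homologous sequences for one region across taxa."""

    name: str
    category: str  # coding | noncoding
    seqs: dict[str, str] = field(default_factory=dict)
    ref_span: tuple[int, int] = (0, 0)


def _gene_features(record: PlastomeRecord) -> dict[str, list]:
    out: dict[str, list] = {}
    for f in record.genes(include_pseudo=False):
        out.setdefault(f.name, []).append(f)
    return out


def _pick_copy(feats):
    """IR-duplicated genes contribute one copy: the lowest-coordinate one."""
    return min(feats, key=lambda f: f.span)


def extract_homologous_regions(records: list[PlastomeRecord],
                               reference: PlastomeRecord,
                               categories: str = "both",
                               min_len: int = 200,
                               single_copy_only: bool = False,
                               partition=None) -> list[RegionSet]:
    """Extract per-taxon sequences of every homologous region.

    Regions are genes shared (by name) among all records, their introns,
    and the intergenic spacers between consecutive shared genes in
    reference order (named "geneA-geneB").  Regions shorter than
    ``min_len`` in the reference are dropped; ``single_copy_only``
    excludes regions whose reference midpoint falls inside the
    reference IR (requires or computes an IR partition).
    """
    import logging
    log = logging.getLogger(__name__)
    if categories not in ("coding", "noncoding", "both"):
        raise ValueError("categories must be coding|noncoding|both")
    gene_maps = {r.id: _gene_features(r) for r in records}
    ref_map = gene_maps[reference.id]
    shared = [name for name in ref_map
              if all(name in gene_maps[r.id] for r in records)]
    ref_order = sorted(shared, key=lambda nm: _pick_copy(ref_map[nm]).span)

    ir_spans = []
    if single_copy_only:
        if partition is None:
            from .quadripartite import detect_inverted_repeats
            partition = detect_inverted_repeats(reference)
        ir_spans = [partition.irb, partition.ira]

    def in_ir(span):
        mid = (span[0] + span[1]) // 2 % reference.length
        return any((mid - s % reference.length) % reference.length < (e - s)
                   for s, e in ir_spans)

    out: list[RegionSet] = []

    def add(name, category, per_taxon, ref_span):
        if ref_span[1] - ref_span[0] < min_len:
            return
        if single_copy_only and in_ir(ref_span):
            return
        if categories != "both" and category != categories:
            return
        if any(not s for s in per_taxon.values()):
            log.warning("region %s empty in some taxon; dropped", name)
            return
        out.append(RegionSet(name=name, category=category, seqs=per_taxon,
                             ref_span=ref_span))

    # genes (spliced) and their introns
    for name in ref_order:
        ref_feat = _pick_copy(ref_map[name])
        per_taxon, intron_sets = {}, None
        ok = True
        for rec in records:
            feat = _pick_copy(gene_maps[rec.id][name])
            per_taxon[rec.id] = extract_feature_sequence(rec, feat)
            ivs = sorted(feat.intervals)
            introns = []
            for (s1, e1, st), (s2, e2, _) in zip(ivs, ivs[1:]):
                if s2 > e1:
                    seq = rec.sequence[e1:s2]
                    introns.append(seq if st == 1 else reverse_complement(seq))
            if intron_sets is None:
                intron_sets = [[iv] for iv in introns]
            elif len(introns) == len(intron_sets):
                for k2, iv in enumerate(introns):
                    intron_sets[k2].append(iv)
            else:
                ok = False
        add(name, "coding", per_taxon, ref_feat.span)
        if ok and intron_sets:
            ref_ivs = sorted(ref_feat.intervals)
            for k2, seq_list in enumerate(intron_sets):
                label = f"{name}-intron" if len(intron_sets) == 1 else f"{name}-intron{k2+1}"
                span = (ref_ivs[k2][1], ref_ivs[k2 + 1][0])
                add(label, "noncoding",
                    {rec.id: seq_list[i2] for i2, rec in enumerate(records)}, span)

    # intergenic spacers between consecutive shared genes (reference order)
    for ga, gb in zip(ref_order, ref_order[1:]):
        per_taxon = {}
        ok = True
        ref_span = None
        for rec in records:
            fa = _pick_copy(gene_maps[rec.id][ga])
            fb = _pick_copy(gene_maps[rec.id][gb])
            s, e = fa.span[1], fb.span[0]
            if rec.id == reference.id:
                ref_span = (s, e)
            if e <= s:
                ok = False
                break
            per_taxon[rec.id] = rec.sequence[s:e]
        if ok and ref_span:
            add(f"{ga}-{gb}", "noncoding", per_taxon, ref_span)
    return out
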