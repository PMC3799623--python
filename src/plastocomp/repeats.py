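"""Detection and classification of tandem, dispersed and palindromic repeats.

The repeat model is REPuter-like: two equal-length copies compared under
a Hamming (mismatch-only) distance, jointly constrained by a maximum
mismatch count (default 3) and a minimum identity (default 0.90), with
type-specific minimum sizes (15 bp tandem array span, 30 bp dispersed,
20 bp palindromic) and a maximum gap of 3 kb between palindromic arms.

A hit is *maximal*: extending either end by one base would violate a
constraint.  Dispersed and palindromic hits are found by seed-and-extend
on exact k-mer seeds with k = ceil((min_len - max_mm) / (max_mm + 1)),
the pigeonhole floor below which no valid hit can avoid containing an
exact seed, so the search is complete; tandem arrays are found by a
vectorised per-period scan.  Hits wholly contained in a longer hit of
the same type are dropped (the deterministic analogue of manual
redundancy filtering).
"""

from __future__ import annotations

from bisect import bisect_left, bisect_right
from dataclasses import dataclass, field

import numpy as np

from .records import PlastomeRecord, reverse_complement


@dataclass
class RepeatHit:
    type: str                      # tandem | dispersed | palindromic
    copy1: tuple[int, int]         # dispersed/palindromic: first copy; tandem: array span
    copy2: tuple[int, int] | None  # second copy; None for tandem
    length: int                    # copy length, or array span for tandem
    mismatches: int | None
    identity: float | None
    unit: int | None = None       # tandem unit length
    copies: float | None = None   # tandem copy number
    context: str = ""             # "" until located; gene name or "noncoding"
    merged_from: int = 1

    def intervals(self) -> list[tuple[int, int]]:
        return [self.copy1] if self.copy2 is None else [self.copy1, self.copy2]


def _seed_k(min_len: int, max_mm: int, min_ident: float = 0.0) -> int:
    """Exact-seed completeness floor.

    A valid window with mm mismatches has length >= max(min_len,
    mm/(1-min_ident)) (the identity constraint), hence an exact run of
    at least ceil((L-mm)/(mm+1)); the floor is the minimum over
    feasible mm."""
    import math
    best = None
    for mm in range(max_mm + 1):
        if mm == 0:
            lmin = min_len
        elif min_ident >= 1.0:
            continue
        else:
            lmin = max(min_len, math.ceil(mm / (1.0 - min_ident) - 1e-9))
        k = math.ceil((lmin - mm) / (mm + 1))
        best = k if best is None else min(best, k)
    return max(1, best if best is not None else min_len)


def _enumerate_pairs(a: str, b: str, *, min_len: int, max_mm: int,
                     min_ident: float, mode: str, max_gap: int | None = None,
                     max_len: int | None = None):
    """All maximal window pairs between ``a`` and ``b`` on shared diagonals.

    mode='dispersed': b is a itself; a window (s, e) on diagonal ``off``
    pairs a[s:e] with a[s+off:e+off], copies forbidden to overlap.
    mode='palindromic': b is revcomp(a); the partner of window (s, e) on
    diagonal ``off`` is a[len(a)-off-e : len(a)-off-s], i.e. the segment
    whose reverse complement matches.  Yields (copy1, copy2, mm, length).
    """
    n, nb = len(a), len(b)
    k = _seed_k(min_len, max_mm, min_ident)
    table: dict[str, list[int]] = {}
    for j in range(nb - k + 1):
        table.setdefault(b[j:j + k], []).append(j)

    covered: dict[int, list[tuple[int, int]]] = {}
    seen: set[tuple[int, int, int]] = set()
    out = []

    for i in range(n - k + 1):
        partners = table.get(a[i:i + k])
        if not partners:
            continue
        for j in partners:
            off = j - i
            if mode == "dispersed" and off < max(1, min_len):
                continue  # copies would overlap (cap below min_len) or off<=0
            exts = covered.get(off)
            if exts and any(lo <= i and i + k <= hi for lo, hi in exts):
                continue  # same exact run as an earlier seed: identical windows
            t0 = max(0, -off)
            t1 = min(n, nb - off)
            # walk out from the exact seed collecting mismatch positions
            left: list[int] = []
            p = i - 1
            while p >= t0 and len(left) <= max_mm:
                if a[p] != b[p + off]:
                    left.append(p)
                p -= 1
            right: list[int] = []
            p = i + k
            while p < t1 and len(right) <= max_mm:
                if a[p] != b[p + off]:
                    right.append(p)
                p += 1
            # the exact-match run containing this seed; later seeds inside it
            # see the same mismatch neighbourhood and can be skipped
            run_lo = left[0] + 1 if left else t0
            run_hi = right[0] if right else t1
            covered.setdefault(off, []).append((run_lo, run_hi))

            sent_l = (left[-1], True) if len(left) > max_mm else (t0 - 1, False)
            sent_r = (right[-1], True) if len(right) > max_mm else (t1, False)
            inner = sorted(left[:max_mm] + right[:max_mm])
            pts = [sent_l] + [(m, True) for m in inner] + [sent_r]
            mmpos = [m for m, real in pts if real]

            def mm_in(s, e):
                return bisect_left(mmpos, e) - bisect_right(mmpos, s - 1)

            def ok(s, e):
                length = e - s
                if length < min_len or s < t0 or e > t1:
                    return False
                mm = mm_in(s, e)
                if mm > max_mm or (length - mm) / length < min_ident:
                    return False
                if max_len is not None and length > max_len:
                    return False
                if mode == "dispersed":
                    if length > off:      # copies overlap
                        return False
                else:
                    c2s, c2e = n - off - e, n - off - s
                    if c2s >= e:
                        gap = c2s - e
                    elif s >= c2e:
                        gap = s - c2e
                    else:
                        return False      # arms overlap
                    if max_gap is not None and gap > max_gap:
                        return False
                return True

            for ai in range(len(pts) - 1):
                for bi in range(ai + 1, len(pts)):
                    if bi - ai - 1 > max_mm:
                        break
                    ws, we = pts[ai][0] + 1, pts[bi][0]
                    if we - ws < min_len:
                        continue
                    if mode == "dispersed":
                        cap = off
                        if max_len is not None:
                            cap = min(cap, max_len)
                        if we - ws > cap:
                            cands = [(s, s + cap) for s in range(ws, we - cap + 1)]
                        else:
                            cands = [(ws, we)]
                    else:
                        # a window may be clipped where the two arms would
                        # collide at the palindrome centre (a match, not a
                        # mismatch, so it is no hamming boundary)
                        e_max = (n - off) // 2          # copy1 left of centre
                        s_min = (n - off) - e_max       # copy2 side
                        cands = [(ws, we), (ws, min(we, e_max)),
                                 (max(ws, s_min), we)]
                    for s, e in dict.fromkeys(cands):
                        length = e - s
                        if (s, e, off) in seen:
                            continue
                        if not ok(s, e):
                            continue
                        if ok(s - 1, e) or ok(s, e + 1):
                            continue  # extensible, not maximal
                        seen.add((s, e, off))
                        mm = mm_in(s, e)
                        if mode == "dispersed":
                            out.append(((s, e), (s + off, e + off), mm, length))
                        else:
                            out.append(((s, e), (n - off - e, n - off - s),
                                        mm, length))
    return out


def _normalize_pair(c1, c2, n: int | None):
    if n is None:
        a, b = c1, c2
    else:
        a = (c1[0] % n, c1[0] % n + (c1[1] - c1[0]))
        b = (c2[0] % n, c2[0] % n + (c2[1] - c2[0]))
    return (a, b) if a <= b else (b, a)


def _drop_contained(hits: list[RepeatHit]) -> list[RepeatHit]:
    """Drop hits whose every copy interval lies inside a longer hit's."""
    kept = []
    for h in hits:
        contained = False
        for g in hits:
            if g is h or g.length < h.length:
                continue
            if g.length == h.length and g.intervals() == h.intervals():
                continue
            ivs_h, ivs_g = h.intervals(), g.intervals()
            if len(ivs_h) == len(ivs_g) and all(
                    gs <= hs and he <= ge
                    for (hs, he), (gs, ge) in zip(ivs_h, ivs_g)):
                contained = True
                break
        if not contained:
            kept.append(h)
    return kept


def _pair_hits(seq: str, mode: str, min_len: int, max_mm: int,
               min_ident: float, max_gap: int | None,
               circular: bool) -> list[RepeatHit]:
    n = len(seq)
    s = seq + seq if circular else seq
    b = s if mode == "dispersed" else reverse_complement(s)
    raw = _enumerate_pairs(s, b, min_len=min_len, max_mm=max_mm,
                           min_ident=min_ident, mode=mode, max_gap=max_gap,
                           max_len=n if circular else None)
    hits: dict[tuple, RepeatHit] = {}
    for c1, c2, mm, length in raw:
        key = _normalize_pair(c1, c2, n if circular else None)
        if key[0] == key[1]:
            continue  # the same genomic segment twice (circular artifact)
        if circular and (c1[0] >= n and c2[0] >= n):
            continue  # shifted duplicate of a hit already in frame
        if key not in hits:
            a, b2 = key
            hits[key] = RepeatHit(type=mode, copy1=a, copy2=b2, length=length,
                                  mismatches=mm, identity=(length - mm) / length)
    out = sorted(hits.values(), key=lambda h: (h.copy1, h.copy2))
    return _drop_contained(out)


def find_dispersed(seq: str, min_len: int = 30, max_mm: int = 3,
                   min_ident: float = 0.90,
                   circular: bool = False) -> list[RepeatHit]:
    """Maximal same-strand repeat pairs (non-overlapping copies)."""
    if len(seq) < min_len:
        return []
    return _pair_hits(seq, "dispersed", min_len, max_mm, min_ident, None, circular)


def find_palindromic(seq: str, min_len: int = 20, max_mm: int = 3,
                     min_ident: float = 0.90, max_gap: int = 3000,
                     circular: bool = False) -> list[RepeatHit]:
    """Maximal inverted-repeat pairs with arm separation <= max_gap."""
    if len(seq) < min_len:
        return []
    return _pair_hits(seq, "palindromic", min_len, max_mm, min_ident,
                      max_gap, circular)


def find_tandem(seq: str, min_total: int = 15, max_mm: int = 3,
                min_ident: float = 0.90, circular: bool = False,
                max_unit: int | None = None) -> list[RepeatHit]:
    """Maximal tandem arrays (adjacent duplicated units), one hit per array.

    An array with unit length p spanning [x, y) is a run where
    seq[t] matches seq[t+p] for t in [x, y-p) under the mismatch and
    identity constraints, with at least two full unit copies and
    span >= min_total.  Identity is computed over the shifted
    self-comparison.
    """
    n = len(seq)
    if n < min_total:
        return []
    s = seq + seq if circular else seq
    arr = np.frombuffer(s.encode(), dtype=np.uint8)
    nn = len(arr)
    max_p = max_unit if max_unit is not None else nn // 2
    cand: list[tuple[int, int, int, int]] = []  # (x, span, p, mm)
    for p in range(1, max_p + 1):
        neq = arr[p:] != arr[:-p]
        limit = nn - p  # comparison coords [0, limit)
        need = max(p, min_total - p)
        if need > limit:
            continue
        mmp = np.flatnonzero(neq)
        r0 = max(1, -(-(need - max_mm) // (max_mm + 1)))
        bounds = np.concatenate(([-1], mmp, [limit]))
        runs = np.diff(bounds) - 1
        anchors = np.flatnonzero(runs >= r0)  # run g lies between bounds[g], bounds[g+1]
        if anchors.size == 0:
            continue
        mcount = len(mmp)
        pairs = set()
        for g in anchors:
            for kmm in range(0, max_mm + 1):
                for lshift in range(0, kmm + 1):
                    a0 = g - 1 - lshift      # index into mmp of left bounding mm
                    b0 = a0 + kmm + 1
                    if a0 < -1 or b0 > mcount:
                        continue
                    pairs.add((a0, b0))
        mlist = mmp.tolist()

        def mm_at(idx):
            return -1 if idx == -1 else (limit if idx == mcount else mlist[idx])

        def valid(x, e_cmp, kmm):
            run = e_cmp - x
            if x < 0 or e_cmp > limit or run < p:
                return False
            span = run + p
            if span < min_total or (circular and span > n):
                return False
            if kmm > max_mm or (run - kmm) / run < min_ident:
                return False
            return True

        for a0, b0 in pairs:
            x, e_cmp = mm_at(a0) + 1, mm_at(b0)
            kmm = b0 - a0 - 1
            if not valid(x, e_cmp, kmm):
                continue
            # one-base extensions (each adds the bounding mismatch)
            if a0 >= 0 and valid(x - 1, e_cmp, kmm + 1):
                continue
            if b0 < mcount and valid(x, e_cmp + 1, kmm + 1):
                continue
            if a0 == -1 and x > 0 and valid(x - 1, e_cmp, kmm):
                continue
            if b0 == mcount and e_cmp < limit and valid(x, e_cmp + 1, kmm):
                continue
            cand.append((x, e_cmp - x + p, p, kmm))

    # canonical frame + containment/period dedupe
    best: dict[tuple[int, int], tuple[int, int]] = {}
    for x, span, p, kmm in cand:
        if circular and x >= n:
            continue
        key = (x, span)
        if key not in best or p < best[key][0]:
            best[key] = (p, kmm)
    hits = []
    items = sorted(best.items())
    for (x, span), (p, kmm) in items:
        contained = any(x2 <= x and x + span <= x2 + sp2 and sp2 > span
                        for (x2, sp2), _ in items)
        if contained:
            continue
        run = span - p
        hits.append(RepeatHit(type="tandem", copy1=(x, x + span), copy2=None,
                              length=span, mismatches=kmm,
                              identity=(run - kmm) / run, unit=p,
                              copies=span / p))
    return hits


# --- merge / precedence / context ------------------------------------------

_PRECEDENCE = ("tandem", "palindromic", "dispersed")


def _overlap(a: tuple[int, int], b: tuple[int, int]) -> bool:
    return a[0] < b[1] and b[0] < a[1]


def _merge_same_type(hits: list[RepeatHit]) -> list[RepeatHit]:
    """Union-merge overlapping hits of one type into single motifs.

    Pair hits merge when both their first and second copies overlap;
    tandem arrays merge when their spans overlap.
    """
    hits = list(hits)
    changed = True
    while changed:
        changed = False
        out: list[RepeatHit] = []
        for h in hits:
            merged = False
            for idx, g in enumerate(out):
                if h.copy2 is None and g.copy2 is None:
                    hit_overlap = _overlap(h.copy1, g.copy1)
                elif h.copy2 is not None and g.copy2 is not None:
                    hit_overlap = (_overlap(h.copy1, g.copy1)
                                   and _overlap(h.copy2, g.copy2))
                else:
                    hit_overlap = False
                if hit_overlap:
                    c1 = (min(h.copy1[0], g.copy1[0]), max(h.copy1[1], g.copy1[1]))
                    c2 = None if h.copy2 is None else (
                        min(h.copy2[0], g.copy2[0]), max(h.copy2[1], g.copy2[1]))
                    out[idx] = RepeatHit(
                        type=h.type, copy1=c1, copy2=c2,
                        length=c1[1] - c1[0],
                        mismatches=None, identity=None,
                        unit=min(x for x in (h.unit, g.unit) if x) if h.unit else None,
                        copies=None,
                        merged_from=h.merged_from + g.merged_from)
                    merged = changed = True
                    break
            if not merged:
                out.append(h)
        hits = out
    return hits


def merge_and_classify(tandem: list[RepeatHit], dispersed: list[RepeatHit],
                       palindromic: list[RepeatHit]) -> list[RepeatHit]:
    """Merge overlapping same-type hits and resolve type precedence.

    Each genomic region carries at most one repeat type; tandem takes
    precedence over the other types (and palindromic over dispersed), so
    a region identifiable as both tandem and dispersed is emitted as
    tandem only.  Idempotent.  Output sorted by position.
    """
    by_type = {"tandem": _merge_same_type(tandem),
               "palindromic": _merge_same_type(palindromic),
               "dispersed": _merge_same_type(dispersed)}
    kept: list[RepeatHit] = []
    claimed: list[tuple[int, int]] = []
    for t in _PRECEDENCE:
        for h in sorted(by_type[t], key=lambda x: x.copy1):
            if any(_overlap(iv, c) for iv in h.intervals() for c in claimed):
                continue
            kept.append(h)
        claimed.extend(iv for h in kept if h.type == t for iv in h.intervals())
    return sorted(kept, key=lambda h: (h.copy1, h.type))


def locate_repeats(hits: list[RepeatHit], record: PlastomeRecord) -> list[RepeatHit]:
    """Annotate each hit as coding (gene name) or noncoding by the
    position of its first copy's midpoint (half-open containment)."""
    n = record.length
    for h in hits:
        mid = ((h.copy1[0] + h.copy1[1]) // 2) % n
        context = "noncoding"
        for f in record.genes(include_pseudo=False):
            for s, e, _ in f.intervals:
                if (mid - s) % n < (e - s):
                    context = f.name
                    break
            if context != "noncoding":
                break
        h.context = context
    return hits


def repeat_summary(per_genome: dict[str, list[RepeatHit]],
                   length_bin: int = 15, bin_start: int = 15) -> dict:
    """Counts by type, by length class (15-30, 31-45, ...) and location."""
    import pandas as pd
    rows = []
    for genome, hits in per_genome.items():
        for h in hits:
            # classes 15-30, 31-45, 46-60, ... (first class one wider)
            if h.length <= bin_start + length_bin:
                label = f"{bin_start}-{bin_start + length_bin}"
            else:
                idx = (h.length - bin_start - length_bin - 1) // length_bin
                lo = bin_start + length_bin + 1 + idx * length_bin
                label = f"{lo}-{lo + length_bin - 1}"
            rows.append({"genome": genome, "type": h.type, "length": h.length,
                         "length_class": label,
                         "location": "noncoding" if h.context in ("", "noncoding")
                         else "coding"})
    df = pd.DataFrame(rows)
    total = len(df)
    if total == 0:
        return {"total": 0, "by_type": pd.DataFrame(), "by_length": pd.DataFrame(),
                "by_location": pd.DataFrame(), "table": df}
    def tally(col):
        t = df.groupby(col).size().rename("count").to_frame()
        t["percent"] = 100.0 * t["count"] / total
        return t
    return {"total": total, "by_type": tally("type"),
            "by_length": tally("length_class"),
            "by_location": tally("location"), "table": df}


def scan_genome(record: PlastomeRecord, min_tandem: int = 15,
                min_dispersed: int = 30, min_palindromic: int = 20,
                max_mm: int = 3, min_ident: float = 0.90,
                max_gap: int = 3000, ir_exclusion: int = 10_000) -> list[RepeatHit]:
    """Full repeat scan of one genome, excluding the IR duplication.

    Hits longer than ``ir_exclusion`` are dropped, as is any hit whose
    two copies lie mostly inside the two detected IR copies (the IRa/IRb
    duplication itself, which per-genome repeat statistics exclude).
    """
    seq = record.sequence
    circ = record.circular
    tan = find_tandem(seq, min_tandem, max_mm, min_ident, circular=circ)
    dis = find_dispersed(seq, min_dispersed, max_mm, min_ident, circular=circ)
    pal = find_palindromic(seq, min_palindromic, max_mm, min_ident, max_gap,
                           circular=circ)
    dis = [h for h in dis if h.length <= ir_exclusion]
    pal = [h for h in pal if h.length <= ir_exclusion]
    tan = [h for h in tan if h.length <= ir_exclusion]

    ir_copies = None
    try:
        from .quadripartite import detect_inverted_repeats
        part = detect_inverted_repeats(record)
        ir_copies = (part.irb, part.ira)
    except Exception:  # noqa: BLE001 - non-quadripartite input is fine
        pass
    if ir_copies is not None:
        n = record.length

        def frac_in(iv, region):
            s, e = iv
            rs, re_ = region
            ov = 0
            for shift in (0, n, -n):
                ov = max(ov, min(e + shift, re_) - max(s + shift, rs))
            return max(0, ov) / (e - s)

        def is_ir_self(h):
            if h.copy2 is None:
                return False
            a, b = h.copy1, h.copy2
            hit = max(min(frac_in(a, ir_copies[0]), frac_in(b, ir_copies[1])),
                      min(frac_in(a, ir_copies[1]), frac_in(b, ir_copies[0])))
            return hit > 0.9 and h.length > 0.5 * (ir_copies[0][1] - ir_copies[0][0])

        dis = [h for h in dis if not is_ir_self(h)]
        pal = [h for h in pal if not is_ir_self(h)]
    hits = merge_and_classify(tan, dis, pal)
    return locate_repeats(hits, record)
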