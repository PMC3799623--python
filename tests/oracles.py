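"""Independent brute-force oracles used across the test suite.

Each oracle implements the operation's definition directly (enumeration
over all candidates), sharing no code with the production search paths.
"""

from __future__ import annotations

import itertools

import numpy as np

from plastocomp.records import reverse_complement
from plastocomp.repeats import RepeatHit, _drop_contained


def hamming(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


def _diag_mm_prefix(s: str, t: str, off: int):
    """Prefix mismatch counts along the diagonal comparing s[x] to t[x+off]."""
    lim = min(len(s), len(t) - off)
    pre = [0]
    for x in range(max(0, -off), lim):
        pre.append(pre[-1] + (s[x] != t[x + off]))
    return max(0, -off), pre


def brute_dispersed(s, min_len=30, max_mm=3, min_ident=0.90):
    """All maximal same-strand pairs by exhaustive (i, j, L) enumeration."""
    n = len(s)
    diags = {}
    for off in range(1, n):
        t0, pre = _diag_mm_prefix(s, s, off)
        diags[off] = (t0, pre)

    def valid(i, j, L):
        if L < min_len or i < 0 or j + L > n or i + L > j:
            return False
        off = j - i
        t0, pre = diags[off]
        mm = pre[i - t0 + L] - pre[i - t0]
        return mm <= max_mm and (L - mm) / L >= min_ident

    hits = []
    for i in range(n):
        for j in range(i + min_len, n - min_len + 1):
            for L in range(min_len, min(j - i, n - j) + 1):
                if (valid(i, j, L) and not valid(i - 1, j - 1, L + 1)
                        and not valid(i, j, L + 1)):
                    mm = hamming(s[i:i + L], s[j:j + L])
                    hits.append(RepeatHit("dispersed", (i, i + L), (j, j + L),
                                          L, mm, (L - mm) / L))
    return _drop_contained(hits)


def brute_palindromic(s, min_len=20, max_mm=3, min_ident=0.90, max_gap=3000):
    n = len(s)

    def valid(i, j, L):
        if L < min_len or i < 0 or j + L > n or j < i + L:
            return False
        if j - (i + L) > max_gap:
            return False
        mm = hamming(s[i:i + L], reverse_complement(s[j:j + L]))
        return mm <= max_mm and (L - mm) / L >= min_ident

    hits = []
    for i in range(n):
        for j in range(i + min_len, n - min_len + 1):
            for L in range(min_len, min(j - i, n - j) + 1):
                if (valid(i, j, L) and not valid(i - 1, j, L + 1)
                        and not valid(i, j - 1, L + 1)):
                    mm = hamming(s[i:i + L], reverse_complement(s[j:j + L]))
                    hits.append(RepeatHit("palindromic", (i, i + L),
                                          (j, j + L), L, mm, (L - mm) / L))
    return _drop_contained(hits)


def brute_tandem(s, min_total=15, max_mm=3, min_ident=0.90):
    """Scan all periods p <= n/2 for maximal tandem arrays."""
    n = len(s)

    def valid(x, y, p):
        span = y - x
        run = span - p
        if span < min_total or run < p or x < 0 or y > n:
            return False
        mm = hamming(s[x:y - p], s[x + p:y])
        return mm <= max_mm and (run - mm) / run >= min_ident

    cand = {}
    for p in range(1, n // 2 + 1):
        for x in range(n):
            for y in range(x + max(min_total, 2 * p), n + 1):
                if (valid(x, y, p) and not valid(x - 1, y, p)
                        and not valid(x, y + 1, p)):
                    key = (x, y - x)
                    if key not in cand or p < cand[key][0]:
                        cand[key] = (p, hamming(s[x:y - p], s[x + p:y]))
    items = sorted(cand.items())
    hits = []
    for (x, span), (p, mm) in items:
        if any(x2 <= x and x + span <= x2 + sp2 and sp2 > span
               for (x2, sp2), _ in items):
            continue
        run = span - p
        hits.append(RepeatHit("tandem", (x, x + span), None, span, mm,
                              (run - mm) / run, unit=p, copies=span / p))
    return hits


def pair_key(hits):
    return sorted((h.copy1, h.copy2, h.length) for h in hits)


def tandem_key(hits):
    return sorted((h.copy1, h.unit, h.length, h.mismatches) for h in hits)


# --- alignment --------------------------------------------------------------

def brute_nw_score(a, b, match=1, mismatch=-1, gap_open=-4, gap_extend=-1):
    """Best global alignment score by enumerating every alignment."""
    best = [-1e9]

    def score(cols):
        s, run = 0, None
        for x, y in cols:
            if x == "-" or y == "-":
                which = "a" if x == "-" else "b"
                s += gap_extend if run == which else gap_open
                run = which
            else:
                s += match if x == y else mismatch
                run = None
        return s

    def rec(i, j, cols):
        if i == len(a) and j == len(b):
            best[0] = max(best[0], score(cols))
            return
        if i < len(a) and j < len(b):
            rec(i + 1, j + 1, cols + [(a[i], b[j])])
        if i < len(a):
            rec(i + 1, j, cols + [(a[i], "-")])
        if j < len(b):
            rec(i, j + 1, cols + [("-", b[j])])

    rec(0, 0, [])
    return best[0]


# --- parsimony --------------------------------------------------------------

def brute_fitch_steps(topology, column: str) -> int:
    """Minimum changes for one column by enumerating all internal-state
    assignments (column[k] is the state of taxon k; '?' is missing)."""
    internals = []

    def collect(t):
        if isinstance(t, int):
            return
        internals.append(t)
        collect(t[0])
        collect(t[1])

    collect(topology)
    best = 10 ** 9
    for assign in itertools.product("ACGT", repeat=len(internals)):
        amap = {id(t): st for t, st in zip(internals, assign)}

        def state(t):
            return column[t] if isinstance(t, int) else amap[id(t)]

        cost = 0 if column[0] == "?" or state(topology) == column[0] else 1

        def walk(t):
            nonlocal cost
            if isinstance(t, int):
                return
            for c in t:
                cs = state(c)
                if cs != "?" and cs != state(t):
                    cost += 1
                walk(c)

        walk(topology)
        best = min(best, cost)
    return best


def split_tally(topologies):
    """Split frequencies by direct counting."""
    from plastocomp.parsimony import splits
    tally = {}
    for t in topologies:
        for s in splits(t):
            tally[s] = tally.get(s, 0) + 1
    return tally


# --- site statistics --------------------------------------------------------

def classify_columns(rows: list[str]):
    """(n_variable, n_pis) by direct per-column classification."""
    missing = set("-N?")
    n_var = n_pis = 0
    for col in zip(*rows):
        if any(c in missing for c in col):
            continue
        counts = {}
        for c in col:
            counts[c] = counts.get(c, 0) + 1
        if len(counts) >= 2:
            n_var += 1
            if sum(1 for v in counts.values() if v >= 2) >= 2:
                n_pis += 1
    return n_var, n_pis


def hand_p_distance(row_a: str, row_b: str, skip_cols: set[int]) -> float:
    diff = comp = 0
    for j, (x, y) in enumerate(zip(row_a, row_b)):
        if j in skip_cols:
            continue
        comp += 1
        diff += x != y
    return diff / comp


def random_dna(rng: np.random.Generator, n: int) -> str:
    return "".join("ACGT"[i] for i in rng.integers(0, 4, n))
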