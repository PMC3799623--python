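"""Maximum parsimony: Fitch length, tree search, bootstrap, consensus.

Characters are unordered states scored by the two-pass Fitch algorithm
on bitmask state sets (missing data '?'/gap/N joins any state).  An
unrooted binary topology over taxa 0..n-1 is represented as a nested
2-tuple attached to one reference leaf: ``(1, (2, 3))`` together with
leaf 0 denotes the unrooted quartet 0,1|2,3 shape.  Splits are
canonicalised as the frozenset of taxon indices on the side not
containing taxon 0, so topologies compare independently of their
representation.

Exhaustive search enumerates all (2n-5)!! topologies by stepwise
addition and is the authority at small n; heuristic search uses random
addition orders plus NNI/SPR branch swapping.  Bootstrap support for a
split is the percentage of replicate MP trees containing it (each
replicate's equally parsimonious trees share one vote).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .align import GAP, Msa

_DNA_MASK = {"A": 1, "C": 2, "G": 4, "T": 8,
             "N": 15, "?": 15, GAP: 15,
             "0": 1, "1": 2}
FULL = 15


@dataclass
class CharacterMatrix:
    """Taxa-by-columns state matrix with per-column weights."""

    taxa: list[str]
    masks: np.ndarray          # (n_taxa, n_cols) uint8 bitmasks
    weights: np.ndarray        # (n_cols,) ints

    def __post_init__(self):
        if self.masks.shape[0] != len(self.taxa):
            raise ValueError("row count does not match taxa")
        if self.weights is None:
            self.weights = np.ones(self.masks.shape[1], dtype=int)

    @property
    def n_taxa(self) -> int:
        return len(self.taxa)

    @property
    def n_columns(self) -> int:
        return int(self.weights.sum())

    @classmethod
    def from_msa(cls, msa: Msa) -> "CharacterMatrix":
        taxa = msa.taxa
        arr = np.zeros((len(taxa), msa.n_columns), dtype=np.uint8)
        for i, t in enumerate(taxa):
            arr[i] = [_DNA_MASK.get(ch, 15) for ch in msa.rows[t]]
        return cls(taxa=taxa, masks=arr,
                   weights=np.ones(arr.shape[1], dtype=int))

    @classmethod
    def from_binary(cls, df) -> "CharacterMatrix":
        taxa = list(df.index)
        arr = np.where(df.to_numpy(dtype=int) == 1, 2, 1).astype(np.uint8)
        return cls(taxa=taxa, masks=arr,
                   weights=np.ones(arr.shape[1], dtype=int))

    def compress(self) -> "CharacterMatrix":
        """Collapse identical columns into weighted patterns."""
        cols, inv = np.unique(self.masks, axis=1, return_inverse=True)
        w = np.zeros(cols.shape[1], dtype=self.weights.dtype)
        np.add.at(w, inv, self.weights)
        return CharacterMatrix(taxa=self.taxa, masks=cols, weights=w)

    def resampled(self, rng: np.random.Generator) -> "CharacterMatrix":
        """Bootstrap resample: multinomial redraw of column weights."""
        total = int(self.weights.sum())
        p = self.weights / total
        w = rng.multinomial(total, p)
        return CharacterMatrix(taxa=self.taxa, masks=self.masks, weights=w)


# --- topology plumbing ------------------------------------------------------

def leaves_of(topology) -> set[int]:
    if isinstance(topology, int):
        return {topology}
    a, b = topology
    return leaves_of(a) | leaves_of(b)


def splits(topology, root_leaf: int = 0) -> frozenset[frozenset[int]]:
    """Nontrivial splits, each as the frozenset side not containing the
    root leaf."""
    out = []

    def walk(node) -> set[int]:
        if isinstance(node, int):
            return {node}
        a, b = node
        la, lb = walk(a), walk(b)
        cluster = la | lb
        out.append(frozenset(cluster))
        return cluster

    walk(topology)
    total = leaves_of(topology) | {root_leaf}
    return frozenset(c for c in out
                     if 1 < len(c) < len(total) - 1)


def rf_distance(top_a, top_b) -> int:
    sa, sb = splits(top_a), splits(top_b)
    return len(sa ^ sb)


def topology_to_newick(topology, taxa: list[str], root_leaf: int = 0,
                       support: dict[frozenset, float] | None = None) -> str:
    def fmt(node):
        if isinstance(node, int):
            return taxa[node]
        a, b = node
        label = ""
        if support is not None:
            cl = frozenset(leaves_of(node))
            if cl in support:
                label = f"{support[cl]:g}"
        return f"({fmt(a)},{fmt(b)}){label}"

    return f"({taxa[root_leaf]},{fmt(topology)});"


# --- Fitch ------------------------------------------------------------------

def fitch_steps(topology, matrix: CharacterMatrix,
                root_leaf: int = 0) -> np.ndarray:
    """Per-pattern minimum state changes (unweighted) on the tree formed
    by joining ``topology`` to ``root_leaf``."""
    masks = matrix.masks

    def walk(node):
        if isinstance(node, int):
            return masks[node], 0
        a, b = node
        ma, sa = walk(a)
        mb, sb = walk(b)
        inter = ma & mb
        miss = inter == 0
        m = np.where(miss, ma | mb, inter).astype(np.uint8)
        return m, sa + sb + miss.astype(np.int64)

    m, s = walk(topology)
    extra = ((m & masks[root_leaf]) == 0).astype(np.int64)
    return s + extra


def fitch_length(topology, matrix: CharacterMatrix, root_leaf: int = 0) -> int:
    """Weighted Fitch tree length."""
    leaf_set = leaves_of(topology) | {root_leaf}
    if leaf_set != set(range(matrix.n_taxa)):
        raise ValueError("tree leaves do not match matrix taxa")
    return int((fitch_steps(topology, matrix, root_leaf) * matrix.weights).sum())


# --- search -----------------------------------------------------------------

def _insertions(topology, new_leaf):
    """All topologies obtained by attaching new_leaf on every edge
    (including the edge to the root leaf)."""
    results = [(topology, new_leaf)]

    def rec(node):
        if isinstance(node, int):
            return [(node, new_leaf)]
        a, b = node
        subs = [(x, b) for x in rec(a)] + [(a, y) for y in rec(b)]
        subs.append((node, new_leaf))
        return subs

    if isinstance(topology, int):
        return results
    a, b = topology
    results += [(x, b) for x in rec(a)] + [(a, y) for y in rec(b)]
    return results


def enumerate_topologies(n_taxa: int):
    """Yield every unrooted binary topology over taxa 0..n-1 exactly once
    (as the subtree attached to leaf 0)."""
    if n_taxa < 3:
        raise ValueError("need at least three taxa")

    def rec(top, next_taxon):
        if next_taxon == n_taxa:
            yield top
            return
        for t in _insertions(top, next_taxon):
            yield from rec(t, next_taxon + 1)

    yield from rec((1, 2), 3)


def n_unrooted_topologies(n_taxa: int) -> int:
    """(2n-5)!! for n >= 3."""
    out = 1
    for k in range(3, 2 * n_taxa - 4, 2):
        out *= k
    return out


def exhaustive_search(matrix: CharacterMatrix, max_taxa: int = 10):
    """All minimum-length trees by complete enumeration (n <= max_taxa)."""
    n = matrix.n_taxa
    if n < 3:
        raise ValueError("tree inference needs at least three taxa")
    if n > max_taxa:
        raise ValueError(
            f"{n} taxa exceed the exhaustive limit {max_taxa}; "
            "use heuristic_search")
    m = matrix.compress()
    best_len, best = None, []
    for top in enumerate_topologies(n):
        ln = int((fitch_steps(top, m) * m.weights).sum())
        if best_len is None or ln < best_len:
            best_len, best = ln, [top]
        elif ln == best_len:
            best.append(top)
    return best_len, best


def _spr_neighbors(topology):
    """Subtree-prune-regraft neighbourhood (reference leaf stays put)."""
    neighbors = []

    def prune(node, path):
        """Yield (pruned_subtree, remaining) for every removable subtree."""
        if isinstance(node, int):
            return
        a, b = node
        yield a, _replace(topology, path, b)
        yield b, _replace(topology, path, a)
        yield from prune(a, path + (0,))
        yield from prune(b, path + (1,))

    def _replace(node, path, new):
        if not path:
            return new
        a, b = node
        if path[0] == 0:
            return (_replace(a, path[1:], new), b)
        return (a, _replace(b, path[1:], new))

    for sub, rest in prune(topology, ()):
        for t in _insertions(rest, None):
            neighbors.append(_subst(t, sub))
    return neighbors


def _subst(node, sub):
    if node is None:
        return sub
    if isinstance(node, int):
        return node
    a, b = node
    return (_subst(a, sub), _subst(b, sub))


def _nni_neighbors(topology):
    """Nearest-neighbour interchanges across internal edges."""
    out = []

    def rec(node, rebuild):
        if isinstance(node, int):
            return
        a, b = node
        if not isinstance(a, int):  # internal edge node-a: swap b across it
            c, d = a
            out.append(rebuild(((b, d), c)))
            out.append(rebuild(((c, b), d)))
        if not isinstance(b, int):
            c, d = b
            out.append(rebuild((c, (a, d))))
            out.append(rebuild((d, (c, a))))
        rec(a, lambda x, _b=b: rebuild((x, _b)))
        rec(b, lambda x, _a=a: rebuild((_a, x)))

    rec(topology, lambda x: x)
    return out


def heuristic_search(matrix: CharacterMatrix, n_addition: int = 100,
                     swap: str = "SPR", seed: int | None = None,
                     keep_max: int = 1000):
    """Random stepwise-addition starts with branch swapping to a local
    optimum; returns (best_length, best_topologies) deduplicated by
    split set, capped at keep_max."""
    n = matrix.n_taxa
    if n < 4:
        return exhaustive_search(matrix)
    if swap not in ("SPR", "NNI"):
        raise ValueError("swap must be SPR or NNI")
    m = matrix.compress()
    rng = np.random.default_rng(seed)
    neigh = _spr_neighbors if swap == "SPR" else _nni_neighbors

    def score(top):
        return int((fitch_steps(top, m) * m.weights).sum())

    best_len = None
    best: dict[frozenset, tuple] = {}
    for _ in range(n_addition):
        order = [0] + [int(x) for x in rng.permutation(np.arange(1, n))]
        # map: representation is attached at order[0]=0 so splits stay canonical
        top = (order[1], order[2])
        for taxon in order[3:]:
            top = min(_insertions(top, int(taxon)), key=score)
        cur, cur_len = top, score(top)
        improved = True
        while improved:
            improved = False
            for cand in neigh(cur):
                ln = score(cand)
                if ln < cur_len:
                    cur, cur_len = cand, ln
                    improved = True
                    break
        if best_len is None or cur_len < best_len:
            best_len, best = cur_len, {splits(cur): cur}
        elif cur_len == best_len and len(best) < keep_max:
            best.setdefault(splits(cur), cur)
    return best_len, list(best.values())


# --- bootstrap & consensus --------------------------------------------------

@dataclass
class BootstrapResult:
    topology: tuple
    best_length: int
    support: dict[frozenset, float]  # cluster -> percent
    replicates: int

    def newick(self, taxa: list[str]) -> str:
        return topology_to_newick(self.topology, taxa, support=self.support)

    def min_support(self) -> float:
        return min(self.support.values()) if self.support else float("nan")


def _search(matrix, mode, rng_seed, n_addition):
    if mode == "exhaustive" or (mode == "auto" and matrix.n_taxa <= 7):
        return exhaustive_search(matrix, max_taxa=10)
    return heuristic_search(matrix, n_addition=n_addition, seed=rng_seed)


def bootstrap_support(matrix: CharacterMatrix, replicates: int = 500,
                      seed: int | None = None, search: str = "auto",
                      n_addition: int = 5) -> BootstrapResult:
    """Nonparametric bootstrap: resample columns with replacement, find
    the replicate MP tree(s), and report for each split of the best
    original tree the percentage of replicates whose MP trees contain
    it."""
    rng = np.random.default_rng(seed)
    m = matrix.compress()
    best_len, best = _search(m, search, int(rng.integers(2**31)), n_addition)
    ref = best[0]
    ref_splits = splits(ref)
    counts = {s: 0.0 for s in ref_splits}
    for _ in range(replicates):
        rm = m.resampled(rng)
        _, rep_best = _search(rm, search, int(rng.integers(2**31)), n_addition)
        k = len(rep_best)
        for top in rep_best:
            ssplits = splits(top)
            for s in ref_splits:
                if s in ssplits:
                    counts[s] += 1.0 / k
    support = {s: 100.0 * c / replicates for s, c in counts.items()}
    return BootstrapResult(topology=ref, best_length=best_len,
                           support=support, replicates=replicates)


def majority_consensus(topologies: list, cutoff: float = 0.5):
    """Majority-rule consensus: clusters with frequency > cutoff.

    Returns (clusters, frequencies) where clusters is the laminar family
    of retained splits (sides not containing taxon 0) and frequencies
    maps each to its percentage.
    """
    if not topologies:
        raise ValueError("no trees")
    leaf_sets = {frozenset(leaves_of(t)) for t in topologies}
    if len(leaf_sets) > 1:
        raise ValueError("trees have different leaf sets")
    tally: dict[frozenset, int] = {}
    for t in topologies:
        for s in splits(t):
            tally[s] = tally.get(s, 0) + 1
    n = len(topologies)
    kept = {s: 100.0 * c / n for s, c in tally.items() if c / n > cutoff}
    return sorted(kept, key=len, reverse=True), kept


def consensus_newick(clusters, frequencies, taxa: list[str],
                     root_leaf: int = 0) -> str:
    """Newick for a (possibly multifurcating) consensus tree, internal
    nodes labelled with split frequencies."""
    others = frozenset(i for i in range(len(taxa)) if i != root_leaf)
    ordered = sorted((frozenset(c) for c in clusters), key=len, reverse=True)

    def build(members, available):
        parts, used = [], set()
        for cl in available:
            if cl <= members and not (cl & used):
                sub = build(cl, [c for c in available if c < cl])
                label = f"{frequencies[cl]:.0f}" if cl in frequencies else ""
                parts.append(f"{sub}{label}")
                used |= cl
        parts += [taxa[i] for i in sorted(members - used)]
        return "(" + ",".join(parts) + ")"

    return f"({taxa[root_leaf]},{build(others, ordered)});"


def ci_ri(topology, matrix: CharacterMatrix):
    """Consistency and retention indices (all columns included).

    CI = sum(min steps) / sum(observed steps); RI scales observed steps
    between the minimum and the maximum (star-tree) steps.  RI is None
    when there is no parsimony-informative variation.
    """
    m = matrix.compress()
    obs = fitch_steps(topology, m).astype(float)
    mins = np.zeros(m.masks.shape[1])
    maxs = np.zeros(m.masks.shape[1])
    for j in range(m.masks.shape[1]):
        col = m.masks[:, j]
        present = col[col != FULL]
        if present.size == 0:
            continue
        states, counts = np.unique(present, return_counts=True)
        mins[j] = max(0, len(states) - 1)
        maxs[j] = present.size - counts.max()
    w = m.weights
    sum_min = float((mins * w).sum())
    sum_obs = float((obs * w).sum())
    sum_max = float((maxs * w).sum())
    ci = 1.0 if sum_obs == 0 else sum_min / sum_obs
    ri = None if sum_max == sum_min else (sum_max - sum_obs) / (sum_max - sum_min)
    return ci, ri
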