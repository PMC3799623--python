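"""Synthetic plastome families with complete ground truth.

The generator emulates the structure of a real chloroplast genome at
desk scale: a circular quadripartite layout (default LSC 12 kb, IRs
3 kb, SSC 2 kb) with genes laid out in every region, a gene straddling
the LSC/IRb junction (rps19-like, with a mirrored pseudogene fragment
in IRa), a gene straddling IRb/SSC (ycf1-like), genes at known
distances from the SSC and LSC borders (ndhF-like, trnH-like), planted
tandem/dispersed/palindromic repeats, and taxa diverged along a known
tree under a Jukes-Cantor substitution process with geometric-length
indels.  The two IR copies co-evolve: the IR is simulated once and IRa
is always the exact reverse complement of IRb.

Indels are restricted to neutral zones (outside genes and planted
repeats) by default so structural truths stay checkable; the true
multiple alignment of every region is tracked through all indels.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import dendropy
import numpy as np

from .align import Msa
from .records import Feature, PlastomeRecord, reverse_complement

_BASES = "ACGT"

DEFAULT_TREE = ("(((palmate_s:0.004,((palmate_b:0.003,palmate_e:0.003):0.002,"
                "(palmate_k:0.003,palmate_m:0.003):0.002):0.002):0.003,"
                "(aralia_a:0.005,panax_p:0.005):0.003):0.010,outgroup:0.030);")

#: taxon -> clade map matching the default tree
DEFAULT_GROUPS = {
    "palmate_s": "palmate", "palmate_b": "palmate", "palmate_e": "palmate",
    "palmate_k": "palmate", "palmate_m": "palmate",
    "aralia_a": "aralia-panax", "panax_p": "aralia-panax",
    "outgroup": "outgroup",
}


@dataclass
class PlantedRepeat:
    kind: str          # tandem | dispersed | palindromic
    length: int        # copy length (dispersed/palindromic arm) or unit length
    mismatches: int = 0
    gap: int = 10      # palindromic arm separation / dispersed copy separation
    n_copies: int = 2  # tandem only
    region: str = "lsc"
    position: int | None = None  # region-local; auto-placed when None


@dataclass
class SimulationConfig:
    seed: int
    tree: str = DEFAULT_TREE
    lsc_len: int = 12_000
    ir_len: int = 3_000
    ssc_len: int = 2_000
    n_lsc_genes: int = 8
    n_ir_genes: int = 3
    n_ssc_genes: int = 1
    gene_spacer: int = 300
    rps19_len: int = 280
    rps19_overlap: int = 45    # bp of rps19 inside IRb
    ycf1_len: int = 600
    ycf1_overlap: int = 300    # bp of ycf1 inside IRb
    ndhf_len: int = 600
    ndhf_distance: int = 400   # distance from the IRb/SSC border
    trnh_len: int = 75
    trnh_distance: int = 10    # distance from the IRa/LSC border
    rate_scale: float = 1.0    # multiplies every branch length
    indel_rate: float = 0.1    # indel events per substitution, roughly
    indel_p: float = 0.4       # geometric length parameter (mean 1/p)
    at_fraction: float = 0.62  # ancestral base composition (plastome-like)
    indels_everywhere: bool = False
    planted: list[PlantedRepeat] = field(default_factory=lambda: [
        PlantedRepeat("dispersed", 40, mismatches=2, gap=600),
        PlantedRepeat("palindromic", 25, mismatches=0, gap=12),
        PlantedRepeat("tandem", 9, n_copies=2),
    ])

    def __post_init__(self):
        if self.seed is None:
            raise ValueError("seed is mandatory")
        if self.rate_scale < 0 or self.indel_rate < 0:
            raise ValueError("rates must be nonnegative")


@dataclass
class _FeatureDef:
    name: str
    kind: str
    strand: int
    pseudo: bool
    # exon pieces as (region, start_id, end_id_inclusive) over ancestor ids
    pieces: list[tuple[str, int, int]]


@dataclass
class AncestorState:
    """Region residue lists: each residue is (column_id, base, neutral)."""
    regions: dict[str, list[tuple[int, str, bool]]]
    masters: dict[str, list[int]]       # region -> master column order
    features: list[_FeatureDef]
    planted: list[dict]
    next_id: dict[str, int]


@dataclass
class TruthBundle:
    tree: str
    alignments: dict[str, Msa]                 # region -> true leaf alignment
    ir_coords: dict[str, dict[str, tuple[int, int]]]
    planted: list[dict]
    branch_substitutions: dict[str, int]       # child node label -> events
    config: SimulationConfig | None = None


def _random_seq(rng, n, at: float = 0.62):
    p = [at / 2, (1 - at) / 2, (1 - at) / 2, at / 2]  # A, C, G, T
    return "".join(_BASES[i] for i in rng.choice(4, size=n, p=p))


def _mutate_copy(rng, seq, n_mm):
    s = list(seq)
    if n_mm == 0:
        return seq
    pos = rng.choice(len(s), size=n_mm, replace=False)
    for p in pos:
        s[p] = _BASES[(_BASES.index(s[p]) + 1 + rng.integers(0, 3)) % 4]
    return "".join(s)


def build_ancestor(config: SimulationConfig
                   ) -> tuple[PlastomeRecord, AncestorState]:
    """Construct the ancestral quadripartite genome and its truth seed."""
    rng = np.random.default_rng(config.seed)
    L1, LI, L2 = config.lsc_len, config.ir_len, config.ssc_len
    at = config.at_fraction
    seqs = {"lsc": list(_random_seq(rng, L1, at)),
            "irb": list(_random_seq(rng, LI, at)),
            "ssc": list(_random_seq(rng, L2, at))}
    neutral = {r: [True] * len(s) for r, s in seqs.items()}
    features: list[_FeatureDef] = []

    def protect(region, start, end):
        if start < 0 or end > len(neutral[region]):
            raise ValueError(
                f"gene layout overflows the {region} region "
                f"([{start}, {end}) in {len(neutral[region])} bp)")
        for i in range(start, end):
            neutral[region][i] = False

    def add_gene(name, kind, pieces, strand=1, pseudo=False):
        for region, s, e in pieces:
            protect(region, s, e)
        features.append(_FeatureDef(name, kind, strand, pseudo,
                                    [(r, s, e - 1) for r, s, e in pieces]))

    # junction genes -------------------------------------------------------
    add_gene("trnH", "tRNA",
             [("lsc", config.trnh_distance,
               config.trnh_distance + config.trnh_len)])
    rps19_lsc = config.rps19_len - config.rps19_overlap
    add_gene("rps19", "gene", [("lsc", L1 - rps19_lsc, L1),
                               ("irb", 0, config.rps19_overlap)])
    ycf1_ssc = config.ycf1_len - config.ycf1_overlap
    add_gene("ycf1", "gene", [("irb", LI - config.ycf1_overlap, LI),
                              ("ssc", 0, ycf1_ssc)])
    add_gene("ndhF", "gene", [("ssc", config.ndhf_distance,
                               config.ndhf_distance + config.ndhf_len)],
             strand=-1)
    # keep the stated junction distances exact: no indels between the
    # borders and their profiled genes
    protect("lsc", 0, config.trnh_distance)
    protect("ssc", 0, config.ndhf_distance)

    # ordinary genes, evenly spaced; a couple carry introns ----------------
    def fill(region, count, start, end, prefix):
        cursor = start
        for i in range(count):
            size = 300 + 150 * (i % 4)
            if cursor + size > end:
                break
            name = f"{prefix}{i + 1}"
            n_introns = 1 if (region == "lsc" and i == 1) else (
                2 if (region == "lsc" and i == 3) else 0)
            if n_introns:
                exon = size // (n_introns + 1) - 40
                pieces, p = [], cursor
                for _ in range(n_introns + 1):
                    pieces.append((region, p, p + exon))
                    p += exon + 60  # 60 bp introns
                protect(region, cursor, p)  # keep exon structure indel-free
                features.append(_FeatureDef(name, "gene", 1, False,
                                            [(r, s, e - 1) for r, s, e in pieces]))
            else:
                kind = "tRNA" if i == count - 1 and region == "lsc" else "gene"
                add_gene(name if kind == "gene" else f"trn{prefix.upper()}{i}",
                         kind, [(region, cursor, cursor + size)],
                         strand=1 if i % 2 == 0 else -1)
            cursor += size + config.gene_spacer

    fill("lsc", config.n_lsc_genes,
         config.trnh_distance + config.trnh_len + config.gene_spacer,
         L1 - rps19_lsc - config.gene_spacer, "lg")
    fill("irb", config.n_ir_genes, config.rps19_overlap + 150,
         LI - config.ycf1_overlap - 150, "ig")
    fill("ssc", config.n_ssc_genes,
         config.ndhf_distance + config.ndhf_len + config.gene_spacer,
         L2, "sg")

    # planted repeats in free (still-neutral) stretches --------------------
    planted_registry = []

    def free_interval(region, needed):
        run = 0
        for i, ok in enumerate(neutral[region]):
            run = run + 1 if ok else 0
            if run >= needed + 20:
                return i - needed - 10
        raise ValueError(f"no room for a {needed} bp planted repeat in {region}")

    for pr in config.planted:
        if pr.kind == "tandem":
            span = pr.length * pr.n_copies
            pos = pr.position if pr.position is not None else free_interval(pr.region, span)
            unit = _random_seq(rng, pr.length)
            motif = unit * pr.n_copies
            seqs[pr.region][pos:pos + span] = list(motif)
            protect(pr.region, pos, pos + span)
            planted_registry.append({"kind": "tandem", "region": pr.region,
                                     "span": (pos, pos + span),
                                     "unit": pr.length, "copies": pr.n_copies})
        else:
            c1 = _random_seq(rng, pr.length)
            c2 = _mutate_copy(rng, c1, pr.mismatches)
            if pr.kind == "palindromic":
                c2 = reverse_complement(c2)
            if pr.kind == "palindromic" or pr.position is not None:
                # contiguous placement (palindromic arms honour pr.gap)
                total = 2 * pr.length + pr.gap
                pos = (pr.position if pr.position is not None
                       else free_interval(pr.region, total))
                p2 = pos + pr.length + pr.gap
            else:
                # dispersed copies may sit in different intergenic stretches
                pos = free_interval(pr.region, pr.length)
                seqs[pr.region][pos:pos + pr.length] = list(c1)
                protect(pr.region, pos, pos + pr.length)
                p2 = free_interval(pr.region, pr.length)
            seqs[pr.region][pos:pos + pr.length] = list(c1)
            seqs[pr.region][p2:p2 + pr.length] = list(c2)
            protect(pr.region, pos, pos + pr.length)
            protect(pr.region, p2, p2 + pr.length)
            planted_registry.append({"kind": pr.kind, "region": pr.region,
                                     "copy1": (pos, pos + pr.length),
                                     "copy2": (p2, p2 + pr.length),
                                     "mismatches": pr.mismatches})

    # keep the planted IR exactly maximal: forbid chance single-base
    # reverse-complement extension at the LSC and SSC flanks
    comp = {"A": "T", "T": "A", "C": "G", "G": "C"}
    if seqs["lsc"][-1] == comp[seqs["lsc"][0]]:
        seqs["lsc"][-1] = seqs["lsc"][0]
    if seqs["ssc"][0] == comp[seqs["ssc"][-1]]:
        seqs["ssc"][0] = seqs["ssc"][-1]

    regions = {r: [(i, seqs[r][i], neutral[r][i] or config.indels_everywhere)
                   for i in range(len(seqs[r]))] for r in seqs}
    state = AncestorState(
        regions=regions,
        masters={r: [i for i, _, _ in regions[r]] for r in regions},
        features=features,
        planted=planted_registry,
        next_id={r: len(regions[r]) for r in regions},
    )
    record = _assemble_record("ancestor", "ancestor", state, config)
    return record, state


def _assemble_record(rec_id: str, taxon: str,
                     state_or_regions, config) -> PlastomeRecord:
    if isinstance(state_or_regions, AncestorState):
        regions = state_or_regions.regions
        features = state_or_regions.features
    else:
        regions, features = state_or_regions
    seq = {r: "".join(b for _, b, _ in regions[r]) for r in regions}
    l1, li, l2 = len(seq["lsc"]), len(seq["irb"]), len(seq["ssc"])
    genome = seq["lsc"] + seq["irb"] + seq["ssc"] + reverse_complement(seq["irb"])
    offsets = {"lsc": 0, "irb": l1, "ssc": l1 + li}
    ira_off = l1 + li + l2
    pos_of = {r: {cid: i for i, (cid, _, _) in enumerate(regions[r])}
              for r in regions}

    feats: list[Feature] = []
    for fd in features:
        intervals = []
        for region, sid, eid in fd.pieces:
            s = pos_of[region][sid]
            e = pos_of[region][eid] + 1
            intervals.append((offsets[region] + s, offsets[region] + e, fd.strand))
        # merge contiguous pieces (e.g. a gene running across a junction)
        merged = [intervals[0]]
        for iv in intervals[1:]:
            ls, le, st = merged[-1]
            if iv[0] == le and iv[2] == st:
                merged[-1] = (ls, iv[1], st)
            else:
                merged.append(iv)
        feats.append(Feature(fd.name, fd.kind, merged, pseudo=fd.pseudo))
        # mirror any IRb-overlapping portion into IRa
        irb_lo, irb_hi = l1, l1 + li
        mirror = []
        for s, e, st in merged:
            os_, oe = max(s, irb_lo), min(e, irb_hi)
            if os_ < oe:
                u, v = os_ - irb_lo, oe - irb_lo
                mirror.append((ira_off + li - v, ira_off + li - u, -st))
        if mirror:
            covers_all = sum(e - s for s, e, _ in mirror) == sum(
                e - s for s, e, _ in merged)
            feats.append(Feature(fd.name, fd.kind, sorted(mirror),
                                 pseudo=not covers_all))
    return PlastomeRecord(id=rec_id, sequence=genome, taxon=taxon,
                          circular=True, features=feats)


def evolve_family(state: AncestorState, config: SimulationConfig
                  ) -> tuple[list[PlastomeRecord], TruthBundle]:
    """Evolve the ancestor along the configured tree.

    Substitutions follow a Jukes-Cantor event process (events per site
    Poisson with mean = branch length x rate_scale); indels are
    geometric-length insertions/deletions placed in neutral zones.  The
    IR evolves once (IRa stays the mirror of IRb) and the true
    alignment of each region is tracked through every indel.
    """
    rng = np.random.default_rng(config.seed + 1)
    tree = dendropy.Tree.get(data=config.tree, schema="newick",
                             preserve_underscores=True)
    branch_subs: dict[str, int] = {}
    leaf_regions: dict[str, dict] = {}
    masters = state.masters

    def evolve_branch(regions, blen, label):
        regions = {r: list(v) for r, v in regions.items()}
        events = 0
        for r, residues in regions.items():
            n = len(residues)
            if n == 0 or blen <= 0:
                continue
            k = rng.poisson(blen * n)
            events += k
            for site in rng.integers(0, n, size=k):
                cid, base, neut = residues[site]
                newb = _BASES[(_BASES.index(base) + 1 + rng.integers(0, 3)) % 4]
                residues[site] = (cid, newb, neut)
            n_indels = rng.poisson(config.indel_rate * blen * n)
            for _ in range(n_indels):
                neutral_sites = [i for i, (_, _, ok) in enumerate(residues) if ok]
                if not neutral_sites:
                    break
                length = int(rng.geometric(config.indel_p))
                at = int(neutral_sites[rng.integers(0, len(neutral_sites))])
                if rng.random() < 0.5 and len(residues) > length:
                    # deletion of up to `length` neutral residues from `at`
                    end = at
                    while (end < len(residues) and end - at < length
                           and residues[end][2]):
                        end += 1
                    del residues[at:end]
                else:
                    anchor = residues[at][0]
                    new = []
                    for _ in range(length):
                        cid = state.next_id[r]
                        state.next_id[r] += 1
                        new.append((cid, _BASES[rng.integers(0, 4)], True))
                    residues[at + 1:at + 1] = new
                    mpos = masters[r].index(anchor)
                    masters[r][mpos + 1:mpos + 1] = [c for c, _, _ in new]
        branch_subs[label] = events
        return regions

    counter = {"n": 0}

    def walk(node, regions):
        for child in node.child_nodes():
            blen = (child.edge.length or 0.0) * config.rate_scale
            counter["n"] += 1
            label = (child.taxon.label if child.taxon
                     else f"node{counter['n']}")
            child_regions = evolve_branch(regions, blen, label)
            if child.is_leaf():
                leaf_regions[child.taxon.label] = child_regions
            else:
                walk(child, child_regions)

    walk(tree.seed_node, state.regions)

    records = []
    ir_coords: dict[str, dict] = {}
    for taxon in sorted(leaf_regions):
        regions = leaf_regions[taxon]
        rec = _assemble_record(taxon, taxon, (regions, state.features), config)
        records.append(rec)
        l1 = len(regions["lsc"])
        li = len(regions["irb"])
        l2 = len(regions["ssc"])
        ir_coords[taxon] = {"lsc": (0, l1), "irb": (l1, l1 + li),
                            "ssc": (l1 + li, l1 + li + l2),
                            "ira": (l1 + li + l2, l1 + 2 * li + l2)}

    alignments = {}
    for r, master in masters.items():
        rows = {}
        for taxon in sorted(leaf_regions):
            bymap = {cid: b for cid, b, _ in leaf_regions[taxon][r]}
            rows[taxon] = "".join(bymap.get(cid, "-") for cid in master)
        alignments[r] = Msa(region=r, rows=rows)

    truth = TruthBundle(tree=config.tree, alignments=alignments,
                        ir_coords=ir_coords, planted=state.planted,
                        branch_substitutions=branch_subs, config=config)
    return records, truth


def simulate_family(config: SimulationConfig
                    ) -> tuple[list[PlastomeRecord], TruthBundle]:
    """Build the ancestor and evolve the whole family in one call."""
    _, state = build_ancestor(config)
    return evolve_family(state, config)


def write_fixtures(records: list[PlastomeRecord], truth: TruthBundle,
                   out_dir, force: bool = False) -> None:
    """Write GenBank + FASTA per taxon, the true tree and a truth JSON."""
    from . import io as pio
    out = Path(out_dir)
    if out.exists() and any(out.iterdir()) and not force:
        raise FileExistsError(f"{out} exists; pass force=True to overwrite")
    out.mkdir(parents=True, exist_ok=True)
    for rec in records:
        pio.write_genbank(rec, out / f"{rec.id}.gb")
    pio.write_fasta({r.id: r.sequence for r in records}, out / "genomes.fasta")
    (out / "true_tree.nwk").write_text(truth.tree + "\n")
    payload = {
        "schema": 1,
        "tree": truth.tree,
        "ir_coords": truth.ir_coords,
        "planted": truth.planted,
        "branch_substitutions": truth.branch_substitutions,
        "alignments": {r: m.rows for r, m in truth.alignments.items()},
    }
    (out / "truth.json").write_text(json.dumps(payload, indent=1))
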