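# Methods

## Scope and data model

The package analyses annotated circular plastomes. Internally all
coordinates are 0-based half-open; GenBank's 1-based inclusive locations
are converted at the I/O boundary. A feature interval with
`end > genome length` wraps through the origin; multi-interval features
(spliced and trans-spliced genes) concatenate their pieces in listed
order, with minus-strand pieces reverse-complemented individually.
Ambiguity codes other than N are rejected at parse time because every
downstream statistic assumes {A,C,G,T}.

Gene inventories deduplicate by gene name: IR-duplicated genes and the
trans-spliced `rps12` count once, pseudogene copies are excluded from
the unique count, and intron-containing genes are reported as data (the
number of introns is `intervals - 1` on the most complete copy), not as
a constant.

## Quadripartite partition

The IR pair is defined as the longest pair of disjoint, exactly
reverse-complementary segments of the circle (ties broken by leftmost
coordinates). Detection binary-searches the pair length with a rolling
polynomial hash over the doubled sequence (so origin-spanning copies are
found and the result is rotation-invariant), verifying candidate pairs
by direct comparison. Exact matching is deliberate: biological IRs are
near-identical and the junction positions behave as exact borders;
near-identity extension is out of scope. The longer single-copy gap is
the LSC; on a tie the gap free of rRNA annotation is taken as LSC, then
original orientation. `min_ir_len` defaults to 1000 bp — far below real
plastome IRs (>= 10 kb) but above dispersed inverted repeats.

Junction profiling measures, per profiled gene (`rps19` at J_LB, `ycf1`
at the IR/SSC side, `ndhF` at J_SB, `trnH` at J_LA), either the bp by
which the IRs overlap the gene (which equals the truncated pseudogene
copy length on the opposite IR) or the gene's distance to its border.
Genes absent from an annotation are reported as missing rather than
raising.

## Repeat model

All three repeat types share one constraint set: identity >= 0.90 *and*
Hamming distance <= 3 (both enforced jointly), mismatch-only (no indels
inside a copy), with minimum sizes of 15 bp (tandem array span), 30 bp
(dispersed copy) and 20 bp (palindromic arm), and palindromic arm
separation <= 3000 bp. A hit is *maximal* when no one-base extension of
both copies remains valid.

Dispersed and palindromic search is seed-and-extend on exact k-mer
seeds. The completeness floor uses the joint constraint: a valid window
with m mismatches has length >= max(min_len, m/(1-identity)), hence an
exact run of at least ceil((L-m)/(m+1)); the floor is the minimum over
feasible m (k=7 for dispersed, k=6 for palindromic at the defaults), so
no valid hit can avoid containing a seed. Around each seed the diagonal
is walked to the (m+1)-th mismatch on both sides and every maximal
window is enumerated from the mismatch boundary points; palindromic
windows are additionally clipped where the two arms would collide at the
palindrome centre (a match, not a mismatch, bounds them there). Tandem
arrays are found by a vectorised per-period self-comparison scan
(period p, run of matching `s[t] == s[t+p]`), requiring at least two
full unit copies; arrays are reported once, at their smallest period.
Circular genomes are scanned on the doubled sequence with coordinates
normalised modulo the length.

Post-processing is the deterministic analogue of manual redundancy
filtering: same-type hits wholly contained in longer hits are dropped,
overlapping same-type hits merge into one motif, and a genomic region
carries one type only with precedence tandem > palindromic > dispersed
(tandem-over-dispersed is the stated rule; palindromic-over-dispersed is
this package's choice for the remaining conflict, on the grounds that an
inverted relation is the more specific description). The IRa/IRb
duplication itself — which per-genome repeat counts plainly do not
include — is excluded twice over: hits longer than 10 kb are dropped,
and so is any pair whose two copies lie (>90%) inside the two detected
IR copies at more than half the IR length, which catches the
duplication at any genome scale. The test suite proves each finder
equal to a brute-force
enumeration of the definitions on sequences up to a few hundred bp over
hundreds of seeded instances.

## Alignment

Whole-genome alignment is produced by annotation-anchored concatenation:
homologous regions (genes shared by all records, their introns, and the
intergenic spacers between consecutive shared genes, named
"geneA-geneB") are extracted per taxon from its own annotation, aligned
per region, and concatenated into a partitioned supermatrix.
Column-level agreement with any particular whole-genome aligner is not
claimed; the construction is deterministic and sufficient for every
downstream statistic. IR-duplicated genes contribute one copy.

The pairwise engine is global Needleman-Wunsch with affine (Gotoh) gap
scoring — defaults +1/-1 match/mismatch, -4 gap open, -1 extend, a gap
of length k costing open + (k-1)·extend — with deterministic tie-breaks
(diagonal, then up, then left). The progressive aligner builds a guide
tree by neighbor-joining on k-mer distances (k=8) and merges profiles
with sum-of-pairs column scoring over base-frequency vectors under
"once a gap, always a gap". Scoring defaults are a common DNA choice;
nothing downstream depends on their exact values.

## Divergence, markers, indels

p-distance uses complete deletion by default (columns containing a gap
or N in any taxon are excluded), mirroring the convention of excluding
alignment-introduced gaps from the phylogenetic analyses; pairwise
deletion is available. Reported group means are rounded to 3 decimals,
full precision retained internally. The mutation-event proportion is
(NS/L)·100 with NS operationalised as the count of variable columns —
multiple substitutions in one column are not countable without
ancestral inference — and L the full aligned length. A marker screen
keeps single-copy regions at least 350 bp long whose variable
percentage exceeds 5%, ranked descending with alphabetical tie-breaks;
an OLS regression of PIS% on variability% (scipy) summarises how
informative variability is.

Indel coding is *simple indel coding*: one binary character per distinct
internal gap signature (identical start and end columns); nested or
staggered gaps are distinct events, terminal runs are ignored as likely
missing data. "Potentially informative" means parsimony-informative
(>= 2 taxa in each state).

## Parsimony

Characters are unordered states on bitmasks (gap, N and ? join any
state). Fitch length is computed by the two-pass set algorithm, rooted
arbitrarily at one leaf (the count is rooting-invariant; the suite
checks this). Exhaustive search enumerates all (2n-5)!! unrooted binary
topologies by stepwise addition and is the authority up to 10 taxa.
The heuristic uses random-addition starts with greedy insertion and
NNI or SPR swapping to a local optimum; its default is 100 addition
replicates (the tool it emulates used 1000; at the suite's scales the
exhaustive search, not replicate count, carries correctness, and the
full-scale setting remains one argument away). TBR swapping is
approximated by SPR for the same reason. Equally parsimonious trees are
kept up to a configurable cap (default 1000). Bootstrap support
resamples column weights multinomially; each replicate's equally best
trees share one vote, and support is reported on the splits of the best
original tree. CI/RI include parsimony-uninformative columns, as the
standard software does; RI is undefined (reported missing) without
informative variation.

## Synthetic plastome generator

The generator is the package's test bed and defines its study
conditions. The default family emulates the structure of a real
analysis at desk scale: a circular 20 kb quadripartite genome (LSC
12 kb, IRs 3 kb, SSC 2 kb — full plastome scale is one config away but
makes the repeat scans and alignments ~60x slower), ~62% AT ancestral
composition, genes in every region including one straddling LSC/IRb
with a mirrored IRa pseudogene fragment (rps19-like, 45 bp inside the
IR), one straddling IRb/SSC (ycf1-like, 300 bp inside), genes at fixed
distances from the SSC and LSC borders (ndhF-like at 400 bp, trnH-like
at 10 bp), and one planted repeat of each type. Eight taxa diverge
along a tree shaped like a two-clade ingroup (five + two taxa) plus an
outgroup, with terminal branches of 0.003-0.005 and an outgroup branch
of 0.03 substitutions/site, giving ingroup p-distances around 0.005-0.02
— the order observed between congeneric plastomes.

Substitutions follow a Jukes-Cantor event process (per-branch event
count Poisson with mean rate x branch length x sites, each event drawing
one of the three other bases), so E[p] = 3/4(1 - e^(-4d/3)) provides a
closed-form check, which the suite performs within Monte-Carlo error.
Indels (rate 0.1 of the substitution rate, geometric lengths with mean
2.5 bp) are restricted to neutral zones — outside genes, planted
repeats, and the border-to-gene corridors of the profiled junction
genes — so structural truths (feature coordinates, junction offsets,
planted repeats) remain exactly checkable; a flag relaxes this. The IR
is simulated once and IRa is always the exact reverse complement of
IRb, i.e. the two copies co-evolve. The true per-region multiple
alignment is tracked through every indel, and the ancestor's
single-copy flanks are adjusted so the planted IR is exactly maximal
(chance one-base extensions would otherwise shift detected borders by
a base).

What the generator does not emulate: base-compositional heterogeneity
along the genome, transition/transversion bias or rate variation across
sites (Jukes-Cantor is deliberate — every implemented statistic is
model-agnostic, and JC has the closed form above), rearrangements, IR
expansion/contraction events, and sequencing or annotation error.
Passing tests therefore demonstrate correctness of the computations on
structurally faithful colinear genomes, not robustness to annotation
noise or genome rearrangement.

## Pipeline and published-data path

`pipeline.run` orchestrates every stage from one config with one seed;
stage failures are logged and recorded in the manifest rather than
aborting. Per-partition MP trees (whole / LSC / SSC / IR / coding /
spacers / introns) are computed independently. `published` drives the
same pipeline over the eight published Araliaceae/Apiaceae records
(which the user downloads once; nothing is bundled) and emits a
per-quantity diff against the published table rather than silently
correcting: annotated IR borders in deposited records need not coincide
with exact-match maximality, and alignment-dependent counts depend on
the aligner, so any discrepancy is surfaced for inspection.

## Numerical and scale choices

The acceptance script runs the default 20 kb family with 100 bootstrap
replicates and a ten-replicate recovery experiment (~4 minutes on one
CPU); the test suite uses the same generator at 7-20 kb and brute-force
oracles at <= 300 bp, chosen so each oracle comparison is exact yet the
whole suite stays comfortably runnable on a laptop. The DP aligner and
the repeat scanners are exact algorithms; the only stochastic components
(heuristic search, bootstrap, simulation) are seeded everywhere and
reproducible bit for bit.
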