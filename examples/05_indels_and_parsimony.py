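"""Code indels as binary characters and build maximum-parsimony trees.

Gap runs in coding-region alignments are coded by simple indel coding
(one binary character per distinct gap signature); the sequence
supermatrix gets an exhaustive/heuristic MP search with bootstrap
support, tree length and the CI/RI homoplasy indices.
"""

import plastocomp as pc
from plastocomp.parsimony import CharacterMatrix

records, truth = pc.simulate_family(pc.SimulationConfig(seed=7))
reference = next(r for r in records if r.id == "panax_p")
taxa = sorted(r.id for r in records)

regions = pc.extract_homologous_regions(records, reference, min_len=200)
coding_msas = [pc.progressive_msa(r.seqs, region=r.name)
               for r in regions if r.category == "coding"]

events = []
for msa in coding_msas:
    events.extend(pc.extract_indel_events(msa))
matrix = pc.code_binary(events, taxa, informative_only=True)
print(f"{len(events)} indel events in {len(coding_msas)} coding regions, "
      f"{matrix.shape[1]} parsimony-informative")
print("(the default generator protects genes from indels, so exon events"
      " are expected to be zero here; noncoding regions do accumulate them)")

all_msas = [pc.progressive_msa(r.seqs, region=r.name) for r in regions]
noncoding_events = [e for msa in all_msas
                    for e in pc.extract_indel_events(msa)]
nc_matrix = pc.code_binary(noncoding_events, taxa, informative_only=True)
print(f"{len(noncoding_events)} events over all regions, "
      f"{nc_matrix.shape[1]} parsimony-informative")
if nc_matrix.shape[1] > 0:
    cm_indel = CharacterMatrix.from_binary(nc_matrix)
    best_len, best = pc.exhaustive_search(cm_indel)
    print(f"indel-only MP tree length {best_len}: "
          f"{pc.topology_to_newick(best[0], taxa)}")

supermatrix = pc.concatenate(
    [pc.progressive_msa(r.seqs, region=r.name) for r in regions]).supermatrix
cm = CharacterMatrix.from_msa(supermatrix)
boot = pc.bootstrap_support(cm, replicates=100, seed=1)
ci, ri = pc.ci_ri(boot.topology, cm)
print(f"\nMP tree length {boot.best_length}, CI {ci:.3f}, "
      f"RI {ri if ri is None else round(ri, 3)}")
print("tree with bootstrap support:")
print(" ", boot.newick(supermatrix.taxa))
print("\ntrue tree:")
print(" ", truth.tree)
print("\nHigh support (near 100) on every ingroup split means the"
      " whole-genome matrix resolves the generating topology decisively;"
      " the indel matrix alone is far sparser and resolves less.")
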