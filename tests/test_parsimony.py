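"""Fitch length, tree search, bootstrap, consensus and homoplasy indices."""

import numpy as np
import pytest

import plastocomp as pc
from oracles import brute_fitch_steps, split_tally
from plastocomp.align import Msa
from plastocomp.parsimony import (CharacterMatrix, consensus_newick,
                                  enumerate_topologies, fitch_steps,
                                  n_unrooted_topologies)


def matrix_from_columns(cols):
    """cols: list of strings, one char per taxon ('?' = missing)."""
    n = len(cols[0])
    rows = {f"t{i}": "".join(c[i] for c in cols).replace("?", "N")
            for i in range(n)}
    return CharacterMatrix.from_msa(Msa(region="m", rows=rows))


class TestFitch:
    def test_invariant_matrix_zero_steps(self):
        m = matrix_from_columns(["AAAA", "CCCC"])
        for top in enumerate_topologies(4):
            assert pc.fitch_length(top, m) == 0

    def test_quartet_column(self):
        m = matrix_from_columns(["AATT"])
        assert pc.fitch_length((1, (2, 3)), m) == 1   # 01|23
        assert pc.fitch_length((2, (1, 3)), m) == 2   # 02|13

    def test_three_taxon_star_minimum(self):
        m = matrix_from_columns(["ACG"])
        assert pc.fitch_length((1, 2), m) == 2

    @pytest.mark.parametrize("seed", range(15))
    def test_matches_brute_force_assignment_minimum(self, seed):
        rng = np.random.default_rng(seed)
        n = 5
        cols = ["".join(rng.choice(list("ACGT?"), size=n)) for _ in range(4)]
        m = matrix_from_columns(cols)
        for top in enumerate_topologies(n):
            want = sum(brute_fitch_steps(top, c) for c in cols)
            assert pc.fitch_length(top, m) == want

    def test_invariant_under_representation(self):
        # the same unrooted topology in different nested forms
        m = matrix_from_columns(["AATT", "ACGT", "AGCT"])
        forms = [(1, (2, 3)), ((2, 3), 1), ((3, 2), 1)]
        lengths = {pc.fitch_length(t, m) for t in forms}
        assert len(lengths) == 1

    def test_duplicate_column_additivity(self, rng):
        cols = ["ACGTT", "AATTC", "CCGGA"]
        m1 = matrix_from_columns(cols)
        m2 = matrix_from_columns(cols + [cols[0]])
        for top in enumerate_topologies(5):
            extra = int(fitch_steps(top, matrix_from_columns([cols[0]]))[0])
            assert pc.fitch_length(top, m2) == pc.fitch_length(top, m1) + extra

    def test_leaf_mismatch_rejected(self):
        m = matrix_from_columns(["AATT"])
        with pytest.raises(ValueError):
            pc.fitch_length((1, (2, 4)), m)


class TestSearch:
    def test_topology_count_closed_form(self):
        assert n_unrooted_topologies(8) == 10395
        assert sum(1 for _ in enumerate_topologies(8)) == 10395
        assert sum(1 for _ in enumerate_topologies(5)) == 15

    def test_single_pis_column_groups_shared_states(self):
        m = matrix_from_columns(["AATT"])
        best_len, best = pc.exhaustive_search(m)
        assert best_len == 1
        assert len(best) == 1 and pc.splits(best[0]) == {frozenset({2, 3})}

    @pytest.mark.parametrize("seed", range(10))
    def test_exhaustive_is_global_minimum_at_tiny_n(self, seed):
        rng = np.random.default_rng(seed)
        m = CharacterMatrix(
            taxa=[f"t{i}" for i in range(5)],
            masks=rng.choice([1, 2], size=(5, 6)).astype(np.uint8),
            weights=np.ones(6, dtype=int))
        best_len, best = pc.exhaustive_search(m)
        lengths = [pc.fitch_length(t, m) for t in enumerate_topologies(5)]
        assert best_len == min(lengths)
        assert len(best) == lengths.count(best_len)

    @pytest.mark.parametrize("seed", range(20))
    def test_heuristic_matches_exhaustive(self, seed):
        rng = np.random.default_rng(1000 + seed)
        n = int(rng.integers(5, 8))
        m = CharacterMatrix(
            taxa=[f"t{i}" for i in range(n)],
            masks=rng.choice([1, 2, 4, 8], size=(n, 10)).astype(np.uint8),
            weights=np.ones(10, dtype=int))
        b, _ = pc.exhaustive_search(m)
        h, _ = pc.heuristic_search(m, n_addition=30, seed=seed)
        assert h == b

    def test_more_addition_replicates_never_worse(self):
        rng = np.random.default_rng(5)
        m = CharacterMatrix(
            taxa=[f"t{i}" for i in range(7)],
            masks=rng.choice([1, 2, 4, 8], size=(7, 15)).astype(np.uint8),
            weights=np.ones(15, dtype=int))
        l1, _ = pc.heuristic_search(m, n_addition=1, seed=0)
        l100, _ = pc.heuristic_search(m, n_addition=100, seed=0)
        assert l100 <= l1

    def test_heuristic_never_beats_user_tree(self, rng):
        m = CharacterMatrix(
            taxa=[f"t{i}" for i in range(6)],
            masks=rng.choice([1, 2, 4, 8], size=(6, 12)).astype(np.uint8),
            weights=np.ones(12, dtype=int))
        h, _ = pc.heuristic_search(m, n_addition=20, seed=1)
        for top in enumerate_topologies(6):
            assert h <= pc.fitch_length(top, m)
            break


class TestBootstrap:
    def test_unanimous_split_gets_100(self):
        cols = ["AATT"] * 12
        m = matrix_from_columns(cols)
        res = pc.bootstrap_support(m, replicates=50, seed=0)
        assert res.support[frozenset({2, 3})] == 100.0

    def test_support_reproducible_with_seed(self):
        rng = np.random.default_rng(2)
        m = CharacterMatrix(
            taxa=[f"t{i}" for i in range(6)],
            masks=rng.choice([1, 2, 4, 8], size=(6, 30)).astype(np.uint8),
            weights=np.ones(30, dtype=int))
        a = pc.bootstrap_support(m, replicates=40, seed=7)
        b = pc.bootstrap_support(m, replicates=40, seed=7)
        assert a.support == b.support

    def test_strong_signal_high_support(self, family):
        records, truth = family
        msa = truth.alignments["lsc"]
        m = CharacterMatrix.from_msa(msa)
        res = pc.bootstrap_support(m, replicates=60, seed=3)
        # whole-region signal: every ingroup split near-unanimous
        assert res.min_support() >= 90.0


class TestConsensus:
    def test_identical_trees_full_frequencies(self):
        tops = [(1, (2, 3))] * 4
        clusters, freq = pc.majority_consensus(tops)
        assert freq == {frozenset({2, 3}): 100.0}

    def test_two_of_three_retained(self):
        tops = [(1, (2, 3)), (1, (2, 3)), (3, (1, 2))]
        clusters, freq = pc.majority_consensus(tops)
        assert freq[frozenset({2, 3})] == pytest.approx(200 / 3)
        assert frozenset({1, 2}) not in freq

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_brute_split_tally(self, seed):
        rng = np.random.default_rng(seed)
        all_tops = list(enumerate_topologies(6))
        tops = [all_tops[i] for i in rng.integers(0, len(all_tops), 9)]
        clusters, freq = pc.majority_consensus(tops)
        tally = split_tally(tops)
        want = {s: 100.0 * c / len(tops) for s, c in tally.items()
                if c / len(tops) > 0.5}
        assert freq == want

    def test_newick_output_contains_frequencies(self):
        tops = [(1, (2, 3))] * 2
        clusters, freq = pc.majority_consensus(tops)
        nwk = consensus_newick(clusters, freq, ["A", "B", "C", "D"])
        assert nwk.startswith("(A,") and "100" in nwk

    def test_leaf_set_mismatch_rejected(self):
        with pytest.raises(ValueError):
            pc.majority_consensus([(1, (2, 3)), (1, 2)])


class TestCiRi:
    def test_homoplasy_free_ci_one(self):
        m = matrix_from_columns(["AATT", "CCGG", "TTAA"])
        best_len, best = pc.exhaustive_search(m)
        ci, ri = pc.ci_ri(best[0], m)
        assert ci == 1.0 and ri == 1.0

    def test_wrong_tree_column_ci_half(self):
        m = matrix_from_columns(["ATAT"])  # pairs 0,2 | 1,3
        ci, ri = pc.ci_ri((1, (2, 3)), m)  # groups 0,1 | 2,3 instead
        assert ci == 0.5 and ri == 0.0

    def test_ri_missing_without_informative_variation(self):
        m = matrix_from_columns(["AAAT"])
        ci, ri = pc.ci_ri((1, (2, 3)), m)
        assert ri is None

    @pytest.mark.parametrize("seed", range(20))
    def test_bounds_on_random_matrices(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 8))
        m = CharacterMatrix(
            taxa=[f"t{i}" for i in range(n)],
            masks=rng.choice([1, 2, 4, 8, 15], size=(n, 20)).astype(np.uint8),
            weights=np.ones(20, dtype=int))
        _, best = pc.exhaustive_search(m)
        ci, ri = pc.ci_ri(best[0], m)
        assert 0 < ci <= 1.0
        if ri is not None:
            assert 0.0 <= ri <= 1.0


class TestRecovery:
    def test_clean_simulation_recovers_generating_topology(self):
        cfg = pc.SimulationConfig(seed=5, indel_rate=0.0)
        records, truth = pc.simulate_family(cfg)
        msa = pc.concatenate([truth.alignments[r]
                              for r in ("lsc", "irb", "ssc")]).supermatrix
        m = CharacterMatrix.from_msa(msa)
        best_len, best = pc.exhaustive_search(m)
        taxa = msa.taxa
        import dendropy
        tns = dendropy.TaxonNamespace()
        true_t = dendropy.Tree.get(data=truth.tree, schema="newick",
                                   taxon_namespace=tns,
                                   preserve_underscores=True)
        got = dendropy.Tree.get(data=pc.topology_to_newick(best[0], taxa),
                                schema="newick", taxon_namespace=tns,
                                preserve_underscores=True)
        true_t.encode_bipartitions()
        got.encode_bipartitions()
        rf = dendropy.calculate.treecompare.symmetric_difference(true_t, got)
        assert rf == 0
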