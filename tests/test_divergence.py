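"""p-distance, site statistics, marker ranking and the PIS regression."""

import numpy as np
import pytest

import plastocomp as pc
from oracles import classify_columns, hand_p_distance, random_dna
from plastocomp.align import Msa
from plastocomp.divergence import MarkerReport


def random_msa(rng, n_taxa, ncol, gap_frac=0.05):
    rows = {}
    for i in range(n_taxa):
        s = [("ACGT"[rng.integers(0, 4)]) for _ in range(ncol)]
        for j in range(ncol):
            if rng.random() < gap_frac:
                s[j] = "-"
        rows[f"t{i}"] = "".join(s)
    return Msa(region="x", rows=rows)


class TestPDistance:
    def test_identical_rows_zero(self):
        msa = Msa(region="x", rows={"a": "ACGT", "b": "ACGT", "c": "ACGT"})
        dm = pc.p_distance(msa)
        assert np.allclose(dm.matrix, 0)

    def test_simple_quarter(self):
        msa = Msa(region="x", rows={"a": "AAAA", "b": "AAAT"})
        assert pc.p_distance(msa).value("a", "b") == 0.25

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_hand_count(self, seed):
        rng = np.random.default_rng(seed)
        msa = random_msa(rng, 4, 200)
        rows = list(msa.rows.values())
        skip = {j for j in range(200)
                if any(r[j] in "-N?" for r in rows)}
        dm = pc.p_distance(msa, deletion="complete")
        taxa = msa.taxa
        for i in range(4):
            for j in range(i + 1, 4):
                want = hand_p_distance(msa.rows[taxa[i]], msa.rows[taxa[j]], skip)
                assert abs(dm.matrix[i, j] - want) < 1e-12

    def test_pairwise_deletion_differs_per_pair(self, rng):
        msa = Msa(region="x", rows={"a": "ACGTAC", "b": "ACCTAC",
                                    "c": "--GTAC"})
        dm = pc.p_distance(msa, deletion="pairwise")
        assert dm.value("a", "b") == pytest.approx(1 / 6)
        assert dm.value("a", "c") == 0.0

    def test_row_and_column_order_invariance(self, rng):
        msa = random_msa(rng, 5, 120)
        dm = pc.p_distance(msa)
        perm = list(rng.permutation(120))
        shuffled = Msa(region="x", rows={
            t: "".join(msa.rows[t][j] for j in perm) for t in msa.taxa[::-1]})
        dm2 = pc.p_distance(shuffled)
        for a in msa.taxa:
            for b in msa.taxa:
                assert abs(dm.value(a, b) - dm2.value(a, b)) < 1e-12

    def test_no_comparable_sites_error(self):
        msa = Msa(region="x", rows={"a": "--", "b": "AC"})
        with pytest.raises(ValueError):
            pc.p_distance(msa)


class TestGroupDivergence:
    def test_two_singletons_between_equals_pair(self):
        msa = Msa(region="x", rows={"a": "AAAA", "b": "AATT"})
        dm = pc.p_distance(msa)
        means = pc.group_divergence(dm, {"a": "g1", "b": "g2"})
        assert means == {"between:g1|g2": 0.5}

    def test_means_equal_hand_computation(self):
        from plastocomp.divergence import DistanceMatrix
        m = np.array([[0, .1, .2, .3], [.1, 0, .4, .5],
                      [.2, .4, 0, .6], [.3, .5, .6, 0]])
        dm = DistanceMatrix(taxa=list("abcd"), matrix=m, deletion="complete")
        groups = {"a": "x", "b": "x", "c": "y", "d": "y"}
        means = pc.group_divergence(dm, groups)
        assert means["within:x"] == pytest.approx(0.1)
        assert means["within:y"] == pytest.approx(0.6)
        assert means["between:x|y"] == pytest.approx(np.mean([.2, .3, .4, .5]))

    def test_simulated_groups_are_ordered(self, family):
        records, _ = family
        regions = pc.extract_homologous_regions(
            records, next(r for r in records if r.id == "panax_p"),
            min_len=100)
        msas = [pc.progressive_msa(r.seqs, region=r.name) for r in regions]
        dm = pc.p_distance(pc.concatenate(msas).supermatrix)
        means = pc.group_divergence(dm, pc.DEFAULT_GROUPS)
        # outgroup is farther than any ingroup comparison
        assert means["between:outgroup|palmate"] > means["within:palmate"]
        assert means["between:aralia-panax|outgroup"] > \
            means["between:aralia-panax|palmate"]


class TestSiteStats:
    def test_constant_alignment(self):
        msa = Msa(region="x", rows={t: "AAAA" for t in "abcd"})
        L, pv, nv, npis, ppis = pc.site_stats(msa)
        assert (L, pv, nv, npis, ppis) == (4, 0.0, 0, 0, 0.0)

    def test_pis_definition(self):
        msa = Msa(region="x", rows={"a": "AA", "b": "AA", "c": "TA", "d": "TT"})
        L, pv, nv, npis, ppis = pc.site_stats(msa)
        # col 0: A/A/T/T -> variable and PIS; col 1: A/A/A/T -> variable only
        assert nv == 2 and npis == 1

    def test_gap_columns_excluded_but_counted_in_L(self):
        msa = Msa(region="x", rows={"a": "A-T", "b": "A-A", "c": "C-T"})
        L, pv, nv, npis, ppis = pc.site_stats(msa)
        assert L == 3 and nv == 2
        assert pv == pytest.approx(100 * 2 / 3)

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_brute_classifier(self, seed):
        rng = np.random.default_rng(seed)
        msa = random_msa(rng, 6, 150)
        L, pv, nv, npis, ppis = pc.site_stats(msa)
        want_v, want_p = classify_columns(list(msa.rows.values()))
        assert (nv, npis) == (want_v, want_p)
        assert npis <= nv <= L
        assert ppis <= pv

    def test_mutation_proportion_identity(self, rng):
        for _ in range(20):
            msa = random_msa(rng, 4, 100)
            L, pv, nv, _, _ = pc.site_stats(msa)
            assert pc.mutation_event_proportion(msa) == pytest.approx(pv)


class TestMarkers:
    def _report(self, region, pct, pis=1.0, cat="noncoding"):
        return MarkerReport(region=region, category=cat, aligned_length=100,
                            n_variable=int(pct), pct_variable=pct,
                            n_pis=int(pis), pct_pis=pis)

    def test_threshold_100_empty(self):
        assert pc.rank_markers([self._report("a", 50)], threshold_pct=100) == []

    def test_ranking_descending_with_alphabetical_ties(self):
        reports = [self._report("b", 8.0), self._report("a", 8.0),
                   self._report("z", 12.0), self._report("q", 3.0)]
        ranked = pc.rank_markers(reports, threshold_pct=5.0)
        assert [r.region for r in ranked] == ["z", "a", "b"]
        assert [r.rank for r in ranked] == [1, 2, 3]

    def test_planted_divergent_spacer_ranked_first(self):
        rng = np.random.default_rng(3)
        quiet = Msa(region="quiet", rows={
            t: "ACGT" * 100 for t in "abcd"})
        rows = {}
        base = random_dna(rng, 400)
        for t in "abcd":
            s = list(base)
            for p in rng.integers(0, 400, 30 if t != "a" else 0):
                s[p] = "ACGT"[rng.integers(0, 4)]
            rows[t] = "".join(s)
        hot = Msa(region="hot", rows=rows)
        reports = [pc.marker_report(quiet), pc.marker_report(hot)]
        ranked = pc.rank_markers(reports, threshold_pct=1.0)
        assert ranked[0].region == "hot"


class TestRegression:
    def test_perfect_collinearity(self):
        reports = [MarkerReport(f"r{i}", "noncoding", 100, i, float(i),
                                i // 2, 0.5 * i) for i in range(1, 6)]
        r2, p, slope = pc.pis_variability_regression(reports)
        assert r2 == pytest.approx(1.0)
        assert slope == pytest.approx(0.5)

    def test_r2_matches_closed_form(self):
        x = np.array([1.0, 2.0, 4.0, 5.0, 9.0])
        y = np.array([0.5, 1.6, 1.9, 3.1, 4.0])
        reports = [MarkerReport(f"r{i}", "noncoding", 100, 0, xi, 0, yi)
                   for i, (xi, yi) in enumerate(zip(x, y))]
        r2, p, slope = pc.pis_variability_regression(reports)
        # closed form: R^2 = 1 - SSE/SST for the least-squares line
        b, a = np.polyfit(x, y, 1)
        sse = ((y - (a + b * x)) ** 2).sum()
        sst = ((y - y.mean()) ** 2).sum()
        assert r2 == pytest.approx(1 - sse / sst)
        assert slope == pytest.approx(b)

    def test_positive_slope_on_shared_rate_regions(self):
        rng = np.random.default_rng(11)
        reports = []
        for i in range(40):
            rate = rng.uniform(0.01, 0.2)
            msa = Msa(region=f"r{i}", rows={
                t: "".join("ACGT"[rng.integers(0, 4)]
                           if rng.random() < rate else "A"
                           for _ in range(300))
                for t in "abcdef"})
            reports.append(pc.marker_report(msa))
        r2, p, slope = pc.pis_variability_regression(reports)
        assert slope > 0 and p < 0.05

    def test_zero_variance_rejected(self):
        reports = [MarkerReport(f"r{i}", "noncoding", 100, 5, 5.0, 2, 2.0)
                   for i in range(4)]
        with pytest.raises(ValueError):
            pc.pis_variability_regression(reports)
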