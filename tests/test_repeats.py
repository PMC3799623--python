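"""Repeat finders against brute-force oracles, merge/precedence rules."""

import numpy as np
import pytest

import plastocomp as pc
from oracles import (brute_dispersed, brute_palindromic, brute_tandem,
                     pair_key, random_dna, tandem_key)
from plastocomp.records import PlastomeRecord, reverse_complement
from plastocomp.repeats import RepeatHit, merge_and_classify


def plant_copy(rng, s, length, n_mm, invert=False, gap=None):
    """Duplicate a random segment elsewhere in s; returns the new string."""
    i = int(rng.integers(0, len(s) // 3))
    seg = list(s[i:i + length])
    for p in rng.choice(length, size=n_mm, replace=False):
        seg[p] = "ACGT"[("ACGT".index(seg[p]) + 1) % 4]
    seg = "".join(seg)
    if invert:
        seg = reverse_complement(seg)
    j = (i + length + gap if gap is not None
         else int(rng.integers(i + length + 5, len(s) - length)))
    return s[:j] + seg + s[j + length:]


class TestDispersed:
    def test_random_sequence_empty(self):
        rng = np.random.default_rng(42)
        assert pc.find_dispersed(random_dna(rng, 200)) == []

    def test_planted_pair_matches_oracle(self):
        rng = np.random.default_rng(1)
        s = plant_copy(rng, random_dna(rng, 400), 40, 2)
        hits = pc.find_dispersed(s)
        assert len(hits) >= 1 and any(h.length >= 40 for h in hits)
        assert pair_key(hits) == pair_key(brute_dispersed(s))

    @pytest.mark.parametrize("seed", range(12))
    def test_oracle_equivalence(self, seed):
        rng = np.random.default_rng(seed)
        s = random_dna(rng, 150)
        if seed % 2:
            s = plant_copy(rng, s, int(rng.integers(30, 45)),
                           int(rng.integers(0, 4)))
        assert pair_key(pc.find_dispersed(s)) == pair_key(brute_dispersed(s))


class TestPalindromic:
    def test_planted_hairpin_recovered(self):
        rng = np.random.default_rng(5)
        s = random_dna(rng, 300)
        arm = random_dna(rng, 25)
        block = arm + random_dna(rng, 10) + reverse_complement(arm)
        s = s[:100] + block + s[100 + len(block):]
        hits = pc.find_palindromic(s)
        # the planted arms are covered by a maximal hit (possibly extended
        # by chance matches in the flanks)
        assert any(h.copy1[0] <= 100 and 125 <= h.copy1[1]
                   and h.copy2[0] <= 135 and 160 <= h.copy2[1]
                   for h in hits)

    def test_gap_rule(self):
        rng = np.random.default_rng(6)
        s = random_dna(rng, 2000)
        plants = []
        for pos, gap in ((50, 0), (300, 100), (700, 900)):
            arm = random_dna(rng, 24)  # distinct arms: no cross-pairing
            s = (s[:pos] + arm + s[pos + 24:pos + 24 + gap]
                 + reverse_complement(arm) + s[pos + 48 + gap:])
            plants.append((pos, gap))
        hits = pc.find_palindromic(s, max_gap=500)

        def covered(pos, gap):
            return any(h.copy1[0] <= pos and pos + 24 <= h.copy1[1]
                       and h.copy2[0] <= pos + 24 + gap
                       and pos + 48 + gap <= h.copy2[1] for h in hits)
        assert covered(50, 0) and covered(300, 100)
        assert not covered(700, 900)  # beyond the 500 bp gap limit
        assert all(h.copy2[0] - h.copy1[1] <= 500 for h in hits)

    @pytest.mark.parametrize("seed", range(12))
    def test_oracle_equivalence(self, seed):
        rng = np.random.default_rng(100 + seed)
        s = random_dna(rng, 140)
        if seed % 2:
            s = plant_copy(rng, s, int(rng.integers(20, 32)),
                           int(rng.integers(0, 3)), invert=True,
                           gap=int(rng.integers(0, 40)))
        max_gap = 3000 if seed % 3 else 30
        assert (pair_key(pc.find_palindromic(s, max_gap=max_gap))
                == pair_key(brute_palindromic(s, max_gap=max_gap)))


class TestTandem:
    def test_short_array_filtered(self):
        rng = np.random.default_rng(7)
        s = random_dna(rng, 60) + "ACGTACGTACGT" + random_dna(rng, 60)
        assert all(h.length >= 15 for h in pc.find_tandem(s))

    def test_two_copy_array_found(self):
        rng = np.random.default_rng(8)
        unit = "AACCGGTTA"
        s = random_dna(rng, 50) + unit * 2 + random_dna(rng, 50)
        hits = pc.find_tandem(s)
        assert any(h.unit == 9 and h.copy1[0] <= 50 and 68 <= h.copy1[1]
                   for h in hits)

    @pytest.mark.parametrize("seed", range(10))
    def test_oracle_equivalence(self, seed):
        rng = np.random.default_rng(200 + seed)
        s = random_dna(rng, 70)
        if seed % 2:
            u = int(rng.integers(5, 12))
            k = 2 + int(rng.integers(0, 2))
            i = int(rng.integers(0, 70 - u * k))
            s = s[:i] + s[i:i + u] * k + s[i + u * k:]
        assert tandem_key(pc.find_tandem(s)) == tandem_key(brute_tandem(s))


class TestCircularity:
    def test_origin_spanning_pair_found_iff_found_after_rotation(self):
        rng = np.random.default_rng(9)
        s = random_dna(rng, 500)
        s = plant_copy(rng, s, 40, 1)
        # place one copy across the origin by rotating
        def norm(hits, n, shift):
            out = set()
            for h in hits:
                ivs = tuple(sorted(((a + shift) % n, b - a)
                                   for a, b in h.intervals()))
                out.add((h.type, ivs, h.length))
            return out
        base = norm(pc.find_dispersed(s, circular=True), 500, 0)
        for shift in (123, 480):
            rot = s[shift:] + s[:shift]
            got = norm(pc.find_dispersed(rot, circular=True), 500, shift)
            assert got == base


class TestMergeClassify:
    def H(self, type, c1, c2=None, length=None, **kw):
        length = length if length is not None else c1[1] - c1[0]
        return RepeatHit(type, c1, c2, length, kw.get("mm", 0), 1.0,
                         unit=kw.get("unit"))

    def test_disjoint_hits_unchanged(self):
        tan = [self.H("tandem", (0, 20), unit=5)]
        dis = [self.H("dispersed", (100, 140), (200, 240))]
        pal = [self.H("palindromic", (300, 325), (330, 355))]
        out = merge_and_classify(tan, dis, pal)
        assert len(out) == 3
        assert {h.type for h in out} == {"tandem", "dispersed", "palindromic"}

    def test_tandem_takes_precedence_over_dispersed(self):
        # the same region qualifies as a 2-copy tandem and a dispersed pair
        tan = [self.H("tandem", (50, 90), unit=20)]
        dis = [self.H("dispersed", (50, 70), (70, 90))]
        out = merge_and_classify(tan, dis, [])
        assert [h.type for h in out] == ["tandem"]

    def test_overlapping_dispersed_merged_to_union(self):
        dis = [self.H("dispersed", (10, 50), (200, 240)),
               self.H("dispersed", (30, 70), (220, 260))]
        out = merge_and_classify([], dis, [])
        assert len(out) == 1
        assert out[0].copy1 == (10, 70) and out[0].copy2 == (200, 260)

    def test_idempotence(self):
        rng = np.random.default_rng(10)
        hits = []
        for _ in range(15):
            a = int(rng.integers(0, 900))
            b = a + int(rng.integers(15, 60))
            c = int(rng.integers(0, 900))
            t = ["tandem", "dispersed", "palindromic"][int(rng.integers(3))]
            hits.append(self.H(t, (a, b),
                               None if t == "tandem" else (c, c + b - a)))
        tan = [h for h in hits if h.type == "tandem"]
        dis = [h for h in hits if h.type == "dispersed"]
        pal = [h for h in hits if h.type == "palindromic"]
        once = merge_and_classify(tan, dis, pal)
        twice = merge_and_classify(
            [h for h in once if h.type == "tandem"],
            [h for h in once if h.type == "dispersed"],
            [h for h in once if h.type == "palindromic"])
        assert [(h.type, h.copy1, h.copy2) for h in once] == \
            [(h.type, h.copy1, h.copy2) for h in twice]


class TestContextAndSummary:
    def test_context_assignment(self, family):
        records, truth = family
        rec = records[0]
        # a hit inside a known gene is coding; half-open boundary counts in
        gene = next(f for f in rec.features if f.name == "lg1")
        s, e, _ = gene.intervals[0]
        hits = [RepeatHit("dispersed", (s, s + 30), (e + 50, e + 80), 30, 0, 1.0),
                RepeatHit("dispersed", (s - 30, s), (e + 50, e + 80), 30, 0, 1.0)]
        located = pc.locate_repeats(hits, rec)
        assert located[0].context == "lg1"
        assert located[1].context == "noncoding"

    def test_planted_repeats_recovered_in_ancestor_scan(self, family):
        # scanned before divergence: every planted repeat must be found
        # (later substitutions may erode marginal-identity arrays)
        _, truth = family
        ancestor, _ = pc.build_ancestor(truth.config)
        hits = pc.scan_genome(ancestor)
        spans = [iv for h in hits for iv in h.intervals()]
        for planted in truth.planted:
            want = planted["span"] if planted["kind"] == "tandem" else planted["copy1"]
            assert any(s <= want[0] and want[1] <= e for s, e in spans), planted

    def test_ir_duplication_excluded_from_stats(self, family):
        records, truth = family
        rec = records[0]
        hits = pc.scan_genome(rec)
        assert all(h.length <= 10_000 for h in hits)
        # the IRa/IRb pair itself must not appear as a palindromic hit
        irb = truth.ir_coords[rec.id]["irb"]
        ir_len = irb[1] - irb[0]
        assert not any(h.type == "palindromic" and h.length > 0.5 * ir_len
                       for h in hits)

    def test_summary_counts(self):
        hits = {"g1": [RepeatHit("tandem", (0, 20), None, 20, 0, 1.0),
                       RepeatHit("palindromic", (50, 75), (80, 105), 25, 0, 1.0),
                       RepeatHit("palindromic", (200, 240), (300, 340), 40, 0, 1.0)]}
        summary = pc.repeat_summary(hits)
        assert summary["total"] == 3
        assert summary["by_type"].loc["palindromic", "count"] == 2
        assert abs(summary["by_type"].loc["palindromic", "percent"] - 200 / 3) < 1e-9
        assert summary["by_length"].loc["15-30", "count"] == 2
        assert summary["by_length"].loc["31-45", "count"] == 1
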