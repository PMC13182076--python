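"""Detector tests: dot plot, palindromes, tandem arrays, telomeres, motifs."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rdnascan.repeats import (
    canonical_matches,
    detect_telomeres,
    find_palindromes,
    find_tandem_arrays,
    half_identity,
    motif_longest_exact_match,
    self_dotplot,
)
from rdnascan.sequtil import random_dna, revcomp

dna = st.text(alphabet="ACGT", min_size=30, max_size=200)


def brute_force_points(seq, k):
    """O(n^2) nested-loop oracle: every exact k-mer pair, both orientations."""
    n = len(seq)
    sense, anti = set(), set()
    for i in range(n - k + 1):
        for j in range(n - k + 1):
            if i != j and seq[i: i + k] == seq[j: j + k]:
                sense.add((i, j))
            if seq[i: i + k] == revcomp(seq[j: j + k]):
                anti.add((i, j))
    return sense, anti


def points_from_matches(matches, k):
    sense, anti = set(), set()
    for m in matches:
        if m.orientation == "sense":
            d = m.t_start - m.q_start
            for i in range(m.q_start, m.q_end - k + 1):
                sense.add((i, i + d))
        else:
            s = m.q_start + m.t_end - k  # start-coordinate pairing sum
            for i in range(m.q_start, m.q_end - k + 1):
                anti.add((i, s - i))
    return sense, anti


class TestSelfDotplot:
    def test_simple_direct_repeat(self):
        matches = canonical_matches(self_dotplot("ACGTACGT", k=4, min_run=4,
                                                 merge_gap=0))
        sense = [m for m in matches if m.orientation == "sense"]
        assert any(
            (m.q_start, m.q_end, m.t_start, m.t_end) == (0, 4, 4, 8) for m in sense
        )

    def test_seq_plus_revcomp_gives_antisense_run(self):
        s = random_dna(60, np.random.default_rng(0))
        seq = s + revcomp(s)
        matches = [
            m for m in canonical_matches(self_dotplot(seq, k=12, min_run=20))
            if m.orientation == "antisense"
        ]
        assert matches
        top = max(matches, key=lambda m: m.length)
        assert top.q_start == 0 and top.t_end == 120

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_brute_force_oracle_on_random_sequence(self, seed):
        rng = np.random.default_rng(seed)
        # random core with planted repeats to guarantee non-trivial matches
        core = random_dna(300, rng)
        unit = random_dna(30, rng)
        seq = core[:100] + unit * 3 + core[100:200] + revcomp(unit) + core[200:]
        k = 12
        got = points_from_matches(self_dotplot(seq, k=k, min_run=k, merge_gap=0), k)
        expected = brute_force_points(seq, k)
        assert got == expected

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(dna)
    def test_brute_force_equivalence_property(self, seq):
        k = 8
        if len(seq) < k:
            return
        got = points_from_matches(self_dotplot(seq, k=k, min_run=k, merge_gap=0), k)
        assert got == brute_force_points(seq, k)

    def test_symmetry(self, chrom_truth):
        chrom, _ = chrom_truth
        matches = self_dotplot(chrom[:6000])
        keys = {
            (m.q_start, m.q_end, m.t_start, m.t_end, m.orientation)
            for m in matches
        }
        for m in matches:
            assert (m.t_start, m.t_end, m.q_start, m.q_end, m.orientation) in keys

    def test_revcomp_invariance(self):
        rng = np.random.default_rng(5)
        core = random_dna(200, rng)
        unit = random_dna(25, rng)
        seq = core[:50] + unit * 3 + core[50:] + revcomp(unit)
        n = len(seq)

        def norm(matches):
            out = set()
            for m in canonical_matches(matches):
                out.add((m.q_end - m.q_start, m.orientation))
            return out

        a = self_dotplot(seq, k=10, min_run=10, merge_gap=0)
        b = self_dotplot(revcomp(seq), k=10, min_run=10, merge_gap=0)
        # mirrored coordinates: x -> n - x swaps and reverses intervals
        mirrored = {
            (n - m.q_start - (n - m.q_end), m.orientation) for m in canonical_matches(b)
        }
        assert norm(a) == mirrored

    def test_short_sequence_raises(self):
        with pytest.raises(ValueError):
            self_dotplot("ACG", k=4)


class TestPalindromes:
    def test_perfect_100bp_palindrome(self):
        s = random_dna(50, np.random.default_rng(1))
        seq = s + revcomp(s)
        calls = find_palindromes(self_dotplot(seq, k=10, min_run=10),
                                 min_arm=20, max_loop=10, seq=seq)
        assert len(calls) == 1
        c = calls[0]
        assert c.loop_length == 0
        assert c.left_arm == (0, 50) and c.right_arm == (50, 100)
        assert c.half_identity == 1.0

    def test_no_antisense_matches_gives_empty(self):
        calls = find_palindromes([], min_arm=20, max_loop=10)
        assert calls == []

    def test_planted_divergent_palindrome_boundaries(self):
        # truth from the generator: 1% arm divergence, 20 seeds
        from rdnascan.synth import make_palindrome

        rng = np.random.default_rng(9)
        flank_l = random_dna(300, rng)
        flank_r = random_dna(300, rng)
        arm = random_dna(800, rng)
        for seed in range(20):
            seq = flank_l + make_palindrome(arm, 0.01, seed=seed) + flank_r
            calls = find_palindromes(
                self_dotplot(seq), min_arm=100, max_loop=50, seq=seq
            )
            assert calls
            top = calls[0]
            assert abs(top.left_arm[0] - 300) <= 20
            assert abs(top.right_arm[1] - 1900) <= 20

    def test_top_call_is_nts_palindrome(self, full_run):
        top = full_run.scan.palindromes[0]
        assert abs(top.span - 4200) <= 20
        assert abs(top.left_arm[0] - 150) <= 10

    def test_half_identity_against_direct_loop_oracle(self, chrom_truth):
        chrom, _ = chrom_truth
        calls = find_palindromes(self_dotplot(chrom), min_arm=1000,
                                 max_loop=100, seq=chrom)
        c = calls[0]
        # independent base-wise loop over arm positions
        a = c.pairing_sum
        comp = dict(zip("ACGT", "TGCA"))
        n_match = sum(
            1
            for x in range(c.left_arm[0], c.left_arm[1])
            if chrom[x] == comp[chrom[a - x]]
        )
        expected = n_match / (c.left_arm[1] - c.left_arm[0])
        assert half_identity(chrom, c) == pytest.approx(expected)
        assert round(100 * c.half_identity) == 99

    def test_zero_length_arm_raises(self, chrom_truth):
        from rdnascan.repeats import PalindromeCall

        with pytest.raises(ValueError):
            half_identity("ACGT", PalindromeCall((0, 0), (0, 0), 0))


class TestTandemArrays:
    def test_exact_triple(self):
        seq = "GATCC" * 3
        calls = find_tandem_arrays(seq, self_dotplot(seq, k=5, min_run=5))
        assert len(calls) == 1
        c = calls[0]
        assert (c.unit_length, c.copies) == (5, 3)
        assert c.mean_pairwise_identity == 1.0

    def test_default_upr_period_260_x5(self, full_run):
        _, truth = full_run.chrom, full_run.truth
        upr = truth.get("UPR")
        hits = [
            a for a in full_run.scan.arrays
            if a.start < upr.end and upr.start < a.end
        ]
        assert len(hits) == 1
        assert hits[0].unit_length == 260
        assert hits[0].copies == 5

    def test_period_matches_autocorrelation_oracle(self, full_run):
        # brute-force autocorrelation over offsets 5..1000 on the UPR
        # subsequence; the canonical minimal unit is the smallest offset
        # whose identity score reaches 95% of the best (multiples of the
        # true period score equally well up to mutation noise, so a raw
        # argmax is ill-defined)
        chrom, truth = full_run.chrom, full_run.truth
        upr = truth.get("UPR")
        sub = chrom[upr.start: upr.end]
        scores = {}
        for p in range(5, 1001):
            matches = sum(1 for i in range(len(sub) - p) if sub[i] == sub[i + p])
            scores[p] = matches / (len(sub) - p)
        best = max(scores.values())
        oracle_p = min(p for p, s in scores.items() if s >= 0.95 * best)
        call = [a for a in full_run.scan.arrays
                if a.start < upr.end and upr.start < a.end][0]
        assert call.unit_length == oracle_p == 260

    def test_period_idempotent_under_extension(self):
        rng = np.random.default_rng(4)
        unit = random_dna(40, rng)
        for copies in (4, 8):
            seq = unit * copies
            calls = find_tandem_arrays(seq, self_dotplot(seq))
            assert len(calls) == 1
            assert calls[0].unit_length == 40

    def test_all_truth_arrays_recovered_within_10bp(self, full_run):
        truth_arrays = full_run.truth.of_type("tandem_array", "telomere")
        calls = full_run.scan.arrays
        for tf in truth_arrays:
            match = [
                c for c in calls
                if abs(c.start - tf.start) <= 10 and abs(c.end - tf.end) <= 10
            ]
            assert match, f"array {tf.id} not recovered"
            if "unit_length" in tf.attributes:
                assert match[0].unit_length == tf.attributes["unit_length"]
                assert match[0].copies == tf.attributes["copies"]
        # and no spurious arrays
        for c in calls:
            near = [
                tf for tf in truth_arrays
                if abs(c.start - tf.start) <= 10 and abs(c.end - tf.end) <= 10
            ]
            assert near, f"spurious array call at {c.start}-{c.end}"


class TestTelomeres:
    def test_pure_array(self):
        seq = "TTAGGG" * 25
        calls = detect_telomeres(seq)
        assert len(calls) >= 1
        c = calls[0]
        assert c.repeat_count == 25.0
        assert c.purity == 1.0

    def test_default_chromosome_two_calls(self, full_run):
        calls = full_run.scan.telomeres
        assert len(calls) == 2
        by_end = {c.end: c for c in calls}
        assert by_end["left"].motif == "CCCTAA"
        assert by_end["right"].motif == "TTAGGG"
        assert by_end["left"].start == 0
        assert by_end["right"].stop == 20300

    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    def test_random_sequence_has_no_telomeres(self, seed):
        seq = random_dna(10000, np.random.default_rng(100 + seed))
        # exhaustive-window oracle: confirm no terminal window of >= 4
        # motif copies exists before asserting the detector agrees
        for motif in ("TTAGGG", "CCCTAA"):
            assert seq[:24].count(motif) < 4 and seq[-24:].count(motif) < 4
        assert detect_telomeres(seq) == []


class TestMotifSearch:
    def test_query_equals_region(self):
        L, hits = motif_longest_exact_match("ACGTACGTTG", "ACGTACGTTG")
        assert L == 10
        assert (0, "+") in hits

    def test_pro_motif_hits_both_palindrome_halves(self, full_run):
        truth = full_run.truth
        pal = truth.get("palindrome_NTS")
        from rdnascan.plan import PRO_MOTIF

        L, hits = motif_longest_exact_match(
            PRO_MOTIF, full_run.chrom[pal.start: pal.end]
        )
        assert L == 15
        strands = {s for _, s in hits}
        assert strands == {"+", "-"}
        mid = pal.length // 2
        assert any(p < mid for p, _ in hits) and any(p >= mid for p, _ in hits)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.text(alphabet="ACGT", min_size=5, max_size=40),
           st.text(alphabet="ACGT", min_size=5, max_size=200))
    def test_against_dp_oracle(self, query, region):
        # classic DP longest-common-substring over both strands
        def lcs(a, b):
            best = 0
            prev = [0] * (len(b) + 1)
            for i in range(1, len(a) + 1):
                cur = [0] * (len(b) + 1)
                for j in range(1, len(b) + 1):
                    if a[i - 1] == b[j - 1]:
                        cur[j] = prev[j - 1] + 1
                        best = max(best, cur[j])
                prev = cur
            return best

        expected = max(lcs(query, region), lcs(query, revcomp(region)))
        got, hits = motif_longest_exact_match(query, region)
        assert got == expected
        if got:
            assert hits

    def test_empty_inputs_raise(self):
        with pytest.raises(ValueError):
            motif_longest_exact_match("", "ACGT")
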