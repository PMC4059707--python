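import math
import random

import pytest
from hypothesis import given, settings, strategies as st

from milksieve import (
    MiRNAIndex,
    ReferenceIndex,
    ScoringScheme,
    SequenceRecord,
    SubjectSet,
    Tag,
    containment_match,
    editing_aware_map,
    evalue,
    hamming_map,
    local_search,
    reverse_complement,
    smith_waterman,
    solve_karlin,
)
from milksieve.validation import brute_containment, brute_hamming_map

MIRNA = "TCGGACCAGGCTTCATTCCCC"  # 21 nt


def _rseq(rng, n):
    return "".join(rng.choice("ACGT") for _ in range(n))


class TestContainment:
    @pytest.fixture()
    def index(self):
        return MiRNAIndex([SequenceRecord("mir-1", MIRNA)])

    def test_identity_hit(self, index):
        (hit,) = containment_match(Tag(MIRNA, 1), index)
        assert hit.length_delta == 0 and hit.offset == 0

    def test_tag_one_short_hits(self, index):
        (hit,) = containment_match(Tag(MIRNA[:-1], 1), index)
        assert hit.length_delta == -1

    def test_tag_two_short_misses(self, index):
        assert containment_match(Tag(MIRNA[:-2], 1), index) == []

    def test_tag_one_long_hits(self, index):
        (hit,) = containment_match(Tag(MIRNA + "A", 1), index)
        assert hit.length_delta == 1 and hit.offset == 0

    def test_internal_mismatch_misses(self, index):
        mutated = MIRNA[:10] + ("A" if MIRNA[10] != "A" else "C") + MIRNA[11:]
        assert containment_match(Tag(mutated, 1), index) == []

    def test_agrees_with_brute_force_scan(self):
        rng = random.Random(11)
        for _ in range(200):
            mirnas = [
                SequenceRecord(f"m{i}", _rseq(rng, rng.randint(18, 24)))
                for i in range(25)
            ]
            base = mirnas[0].seq
            tag_seq = rng.choice(
                [base, base[1:], base[:-1], "G" + base, base + "C", _rseq(rng, 20)]
            )
            index = MiRNAIndex(mirnas)
            got = {
                (h.mirna_id, h.offset, h.length_delta) for h in index.lookup(tag_seq)
            }
            assert got == brute_containment(tag_seq, mirnas)


class TestKarlin:
    def test_lambda_satisfies_identity(self):
        params = solve_karlin(ScoringScheme(1, -2))
        residual = 0.25 * math.exp(params.lam) + 0.75 * math.exp(-2 * params.lam) - 1
        assert abs(residual) < 1e-9

    def test_lambda_matches_bisection_oracle(self):
        params = solve_karlin(ScoringScheme(1, -2))
        lo, hi = 1e-9, 10.0
        f = lambda lam: 0.25 * math.exp(lam) + 0.75 * math.exp(-2 * lam) - 1
        for _ in range(60):
            mid = (lo + hi) / 2
            if f(mid) < 0:
                lo = mid
            else:
                hi = mid
        assert params.lam == pytest.approx((lo + hi) / 2, abs=1e-6)

    def test_plus_one_minus_one_root_is_ln3(self):
        # (1/4)e^l + (3/4)e^-l = 1  =>  e^l = 3
        params = solve_karlin(ScoringScheme(1, -1))
        assert params.lam == pytest.approx(math.log(3), abs=1e-9)

    def test_all_negative_scores_error(self):
        with pytest.raises(ValueError):
            solve_karlin(ScoringScheme(-1, -1))

    def test_evalue_monotone_decreasing_in_score(self):
        params = solve_karlin(ScoringScheme(1, -2))
        es = [evalue(s, 21, 10000, params) for s in range(5, 25)]
        assert all(a > b for a, b in zip(es, es[1:]))


class TestLocalSearch:
    def test_exact_substring_is_significant(self):
        rng = random.Random(3)
        subject = _rseq(rng, 300)
        tag_seq = subject[100:120]
        subjects = SubjectSet([SequenceRecord("s1", subject)])
        params = solve_karlin(ScoringScheme())
        hits = local_search(Tag(tag_seq, 1), subjects, params, evalue_max=0.01)
        assert hits and hits[0].subject_id == "s1"
        assert hits[0].evalue < 0.01
        assert hits[0].score == 20.0

    def test_no_shared_word_no_hit(self):
        subjects = SubjectSet([SequenceRecord("s1", "A" * 200)])
        params = solve_karlin(ScoringScheme())
        assert local_search(Tag("C" * 21, 1), subjects, params) == []

    def test_threshold_monotonicity(self):
        rng = random.Random(4)
        subject = _rseq(rng, 300)
        subjects = SubjectSet([SequenceRecord("s1", subject)])
        params = solve_karlin(ScoringScheme())
        tag = Tag(subject[50:70], 1)
        (hit,) = local_search(tag, subjects, params, evalue_max=0.01)
        assert local_search(tag, subjects, params, evalue_max=hit.evalue / 2) == []

    def test_reported_score_is_full_smith_waterman_optimum(self):
        rng = random.Random(5)
        scheme = ScoringScheme()
        params = solve_karlin(scheme)
        for _ in range(30):
            subject = _rseq(rng, 150)
            tag_seq = _rseq(rng, 10) + subject[40:52] + _rseq(rng, 3)
            subjects = SubjectSet([SequenceRecord("s", subject)])
            for hit in local_search(Tag(tag_seq, 1), subjects, params, evalue_max=10.0):
                best = max(
                    smith_waterman(tag_seq, subject, scheme)[0],
                    smith_waterman(reverse_complement(tag_seq), subject, scheme)[0],
                )
                assert hit.score == pytest.approx(best)


class TestHammingMap:
    def test_verbatim_tag_maps_at_source(self):
        rng = random.Random(6)
        genome = [SequenceRecord("chr1", _rseq(rng, 1000))]
        idx = ReferenceIndex(genome)
        tag = Tag(genome[0].seq[200:221], 1)
        hits = hamming_map(tag, idx, k=0)
        assert any(h.pos == 200 and h.strand == "+" and not h.mismatches for h in hits)

    def test_one_substitution_needs_k1(self):
        rng = random.Random(7)
        genome = [SequenceRecord("chr1", _rseq(rng, 1000))]
        idx = ReferenceIndex(genome)
        src = genome[0].seq[300:321]
        mutated = src[:10] + ("A" if src[10] != "A" else "C") + src[11:]
        assert hamming_map(Tag(mutated, 1), idx, k=0) == []
        hits = hamming_map(Tag(mutated, 1), idx, k=1)
        assert any(h.pos == 300 and len(h.mismatches) == 1 for h in hits)

    def test_minus_strand_hit(self):
        rng = random.Random(8)
        genome = [SequenceRecord("chr1", _rseq(rng, 1000))]
        idx = ReferenceIndex(genome)
        tag = Tag(reverse_complement(genome[0].seq[500:521]), 1)
        hits = hamming_map(tag, idx, k=0)
        assert any(h.pos == 500 and h.strand == "-" for h in hits)

    def test_agrees_with_sliding_window_oracle(self):
        rng = random.Random(9)
        for trial in range(60):
            genome = [
                SequenceRecord(f"g{i}", _rseq(rng, rng.randint(300, 1500)))
                for i in range(2)
            ]
            idx = ReferenceIndex(genome)
            if trial % 2:
                src = genome[trial % 2].seq
                start = rng.randrange(len(src) - 21)
                seq = list(src[start : start + 21])
                for _ in range(rng.randint(0, 2)):
                    seq[rng.randrange(21)] = rng.choice("ACGT")
                tag_seq = "".join(seq)
            else:
                tag_seq = _rseq(rng, rng.randint(17, 25))
            k = rng.choice([0, 1, 2])
            got = {
                (h.chrom, h.pos, h.strand)
                for h in hamming_map(Tag(tag_seq, 1), idx, k)
            }
            assert got == brute_hamming_map(tag_seq, genome, k)


class TestEditingAwareMap:
    def _genome(self):
        rng = random.Random(10)
        seq = _rseq(rng, 800)
        # guarantee an A and a C inside the probe window
        seq = seq[:400] + "ATCCGATTGACCTGAAGCTAA" + seq[421:]
        return [SequenceRecord("chr1", seq)]

    def test_editing_plus_other_mismatch_is_returned(self):
        genome = self._genome()
        idx = ReferenceIndex(genome)
        src = genome[0].seq[400:421]
        read = list(src)
        ai = src.index("A")
        ci = src.index("C")
        read[ai] = "G"  # ref A -> read G: editing-compatible
        read[ci] = "A"  # ref C -> read A: not editing
        hits = editing_aware_map(Tag("".join(read), 1), idx)
        assert any(h.pos == 400 for h in hits)

    def test_two_non_editing_mismatches_not_returned(self):
        genome = self._genome()
        idx = ReferenceIndex(genome)
        src = genome[0].seq[400:421]
        read = list(src)
        positions = [i for i, b in enumerate(src) if b == "A"][:2]
        assert len(positions) == 2
        for p in positions:
            read[p] = "C"  # ref A -> read C: not in the editing set
        hits = editing_aware_map(Tag("".join(read), 1), idx)
        assert all(h.pos != 400 or h.strand != "+" for h in hits)

    def test_single_tc_edit_is_returned(self):
        genome = self._genome()
        idx = ReferenceIndex(genome)
        src = genome[0].seq[400:421]
        ti = src.index("T")
        read = src[:ti] + "C" + src[ti + 1 :]
        hits = editing_aware_map(Tag(read, 1), idx)
        assert any(h.pos == 400 and len(h.mismatches) == 1 for h in hits)


def test_map_hits_export_as_bed6():
    from milksieve.match import MapHit, maphits_to_bed

    hit = MapHit(tag_seq="ACGTACGTACGTACGTACGTA", chrom="chr1", pos=100,
                 strand="-", mismatches=((3, "A", "G"),))
    line = maphits_to_bed([hit]).strip()
    assert line == "chr1\t100\t121\tACGTACGTACGTACGTACGTA\t1\t-"
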