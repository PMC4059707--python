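import random

import pytest
from hypothesis import given, settings, strategies as st

from milksieve import (
    CleaningConfig,
    QualityRead,
    clean_reads,
    collapse,
    quality_filter,
    trim_adapter,
)

ADAPTER = "AGATCGGAAGAGCACA"


def _read(seq, qual=38):
    return QualityRead("r", seq, tuple([qual] * len(seq)))


class TestTrimAdapter:
    def test_full_adapter_occurrence(self):
        insert = "ACGTACGTACGTACGTACGT"
        read = _read(insert + ADAPTER[:12] + "AAAA")
        out = trim_adapter(read, ADAPTER[:12], 6)
        assert out.seq == insert
        assert len(out.qual) == len(insert)

    def test_missing_adapter_signals_none(self):
        assert trim_adapter(_read("ACGTTGCA" * 4), ADAPTER[:12], 6) is None

    def test_adapter_prefix_at_three_prime_end(self):
        insert = "ACGTTGCAACGTTGCAACGTTGCAACGTTG"
        read = _read(insert + ADAPTER[:6])
        out = trim_adapter(read, ADAPTER[:12], 6)
        assert out.seq == insert

    def test_leftmost_occurrence_wins(self):
        adapter = "AGATCG"
        read = _read("CCCCCC" + adapter + "TTTT" + adapter)
        out = trim_adapter(read, adapter, 6)
        assert out.seq == "CCCCCC"


class TestQualityFilter:
    def test_n_base_rejected_first(self):
        read = QualityRead("r", "ACGTN" + "A" * 15, tuple([5] * 20))
        assert quality_filter(read) == "N-base"

    def test_five_bases_below_q10_fails(self):
        qual = [9] * 5 + [38] * 15
        read = QualityRead("r", "ACGTACGTACGTACGTACGT", tuple(qual))
        assert quality_filter(read) == "Q10-count"

    def test_boundary_counts_pass(self):
        # exactly 4 bases < Q10 and exactly 6 < Q13: at, not over, the limits
        qual = [9] * 4 + [12] * 2 + [38] * 14
        read = QualityRead("r", "ACGTACGTACGTACGTACGT", tuple(qual))
        assert quality_filter(read) is None

    def test_seven_bases_below_q13_fails(self):
        qual = [12] * 7 + [38] * 13
        read = QualityRead("r", "ACGTACGTACGTACGTACGT", tuple(qual))
        assert quality_filter(read) == "Q13-count"

    def test_sixteen_nt_read_fails_min_length(self):
        assert quality_filter(_read("ACGT" * 4)) == "min-length"

    def test_seventeen_nt_read_passes(self):
        assert quality_filter(_read("ACGTACGTACGTACGTC")) is None

    def test_polya_tail_fails(self):
        assert quality_filter(_read("CGCGCGCGCG" + "A" * 10)) == "poly-A"

    def test_five_prime_primer_contaminant_fails(self):
        config = CleaningConfig()
        seq = config.adapter5[:10] + "CGCGCGCGCG"
        assert quality_filter(_read(seq), config) == "5p-primer"


class TestCollapse:
    def test_counts_and_order(self):
        tags, stats = collapse(["AAC" * 7, "AAC" * 7, "GGT" * 7])
        assert [(t.seq, t.count) for t in tags] == [("AAC" * 7, 2), ("GGT" * 7, 1)]
        assert stats.unique_tags == 2

    def test_empty_stream(self):
        tags, stats = collapse([])
        assert tags == [] and stats.surviving_reads == 0

    def test_ten_copies_collapse_to_one_tag(self):
        tags, stats = collapse(["ACGTACGTACGTACGTA"] * 10)
        assert len(tags) == 1 and tags[0].count == 10


@settings(max_examples=30, deadline=None, derandomize=True)
@given(st.integers(0, 2**31 - 1))
def test_read_conservation_and_order_independence(seed):
    """Inputs = survivors + rejects, and shuffling reads changes no counts."""
    rng = random.Random(seed)
    adapter = "TCGTATGCCGTCTTCTGCTTG"
    reads = []
    for i in range(rng.randint(1, 60)):
        kind = rng.random()
        if kind < 0.5:
            insert = "".join(rng.choice("ACGT") for _ in range(rng.randint(10, 25)))
            seq = (insert + adapter)[:36]
        elif kind < 0.7:
            seq = "".join(rng.choice("ACGT") for _ in range(36))  # often no adapter
        else:
            seq = ("N" + "".join(rng.choice("ACGT") for _ in range(16)) + adapter)[:36]
        qual = tuple(rng.choice([8, 12, 35, 38]) for _ in seq)
        reads.append(QualityRead(f"r{i}", seq, qual))
    tags, stats = clean_reads(reads, "s")
    assert stats.input_reads == stats.surviving_reads + stats.total_rejected
    assert sum(t.count for t in tags) == stats.surviving_reads
    for tag in tags:
        assert len(tag.seq) >= 17
        assert "N" not in tag.seq
    shuffled = reads[:]
    rng.shuffle(shuffled)
    tags2, stats2 = clean_reads(shuffled, "s")
    assert tags2 == tags
    assert stats2.rejected_by_rule == stats.rejected_by_rule


def test_tags_fasta_carries_counts_in_headers(tmp_path):
    from milksieve.preprocess import Tag, write_tags_fasta

    path = tmp_path / "tags.fa"
    write_tags_fasta([Tag("ACGTACGTACGTACGTA", 7), Tag("TTTTACGTACGTACGTA", 2)], path)
    assert path.read_text() == (
        ">tag1_x7\nACGTACGTACGTACGTA\n>tag2_x2\nTTTTACGTACGTACGTA\n"
    )
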