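"""Raw-read cleaning and tag collapsing.

The cleaning rules mirror standard small-RNA practice on 36 bp single-end
data: trim the 3' adapter, reject reads with any N, with more than 4 bases
below Q10 or more than 6 bases below Q13, shorter than 17 nt after
trimming, poly-A artefacts, and 5' primer contaminants.  Survivors are
collapsed into unique counted tags.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

from .io import QualityRead

__all__ = [
    "Tag",
    "CleanStats",
    "CleaningConfig",
    "trim_adapter",
    "quality_filter",
    "collapse",
    "clean_reads",
]

MIN_TAG_LEN = 17


@dataclass(frozen=True)
class Tag:
    """A unique insert sequence with the number of reads collapsed into it."""

    seq: str
    count: int
    sample_id: str = ""

    def __post_init__(self) -> None:
        if self.count < 1:
            raise ValueError("Tag count must be >= 1")

    def __len__(self) -> int:
        return len(self.seq)


@dataclass
class CleanStats:
    """Per-sample accounting of the cleaning cascade.

    Invariant: input_reads == surviving_reads + sum(rejected_by_rule.values()).
    """

    input_reads: int = 0
    rejected_by_rule: dict[str, int] = field(default_factory=dict)
    surviving_reads: int = 0
    unique_tags: int = 0

    def reject(self, rule: str) -> None:
        self.rejected_by_rule[rule] = self.rejected_by_rule.get(rule, 0) + 1

    @property
    def total_rejected(self) -> int:
        return sum(self.rejected_by_rule.values())


@dataclass(frozen=True)
class CleaningConfig:
    adapter3: str = "TCGTATGCCGTCTTCTGCTTG"
    adapter5: str = "GTTCAGAGTTCTACAGTCCGACGATC"
    min_overlap: int = 6
    min_length: int = MIN_TAG_LEN
    max_below_q10: int = 4
    max_below_q13: int = 6
    polya_fraction: float = 0.8
    polya_run: int = 8
    primer5_prefix: int = 10


# fixed rule order => deterministic attribution when several rules fire
RULE_ORDER = ("N-base", "Q10-count", "Q13-count", "min-length", "poly-A", "5p-primer")


def trim_adapter(
    read: QualityRead, adapter3: str, min_overlap: int = 6
) -> QualityRead | None:
    """Truncate a read at the leftmost occurrence of the 3' adapter.

    A full adapter occurrence anywhere, or a >= ``min_overlap`` adapter
    prefix at the read's 3' end, marks the insert boundary.  Returns the
    trimmed read, or ``None`` (missing-adapter signal) when no such
    occurrence exists.  An adapter at position 0 (adapter dimer) yields an
    empty insert, which the length rule rejects downstream.
    """
    if min_overlap < 1 or len(adapter3) < min_overlap:
        raise ValueError("require adapter3 length >= min_overlap >= 1")
    cut = read.seq.find(adapter3)
    if cut == -1:
        # adapter prefix hanging off the 3' end
        for ov in range(min(len(read.seq), len(adapter3) - 1), min_overlap - 1, -1):
            if read.seq.endswith(adapter3[:ov]):
                cut = len(read.seq) - ov
                break
    if cut == -1:
        return None
    return QualityRead(id=read.id, seq=read.seq[:cut], qual=read.qual[:cut])


def quality_filter(
    read: QualityRead, config: CleaningConfig = CleaningConfig()
) -> str | None:
    """Return the first violated rule name, or ``None`` if the read passes.

    Rules run in the fixed order N-base, Q10-count, Q13-count, min-length,
    poly-A, 5'-primer; quality rules act on the trimmed insert.
    """
    if "N" in read.seq:
        return "N-base"
    if sum(1 for q in read.qual if q < 10) > config.max_below_q10:
        return "Q10-count"
    if sum(1 for q in read.qual if q < 13) > config.max_below_q13:
        return "Q13-count"
    if len(read.seq) < config.min_length:
        return "min-length"
    a_frac = read.seq.count("A") / len(read.seq)
    if a_frac >= config.polya_fraction or read.seq.endswith("A" * config.polya_run):
        return "poly-A"
    if len(config.adapter5) >= config.primer5_prefix and read.seq.startswith(
        config.adapter5[: config.primer5_prefix]
    ):
        return "5p-primer"
    return None


def collapse(inserts: list[str], sample_id: str = "") -> tuple[list[Tag], CleanStats]:
    """Collapse cleaned insert sequences into unique counted tags.

    Tags are sorted by descending count, ties broken lexicographically, so
    the output is independent of input order.
    """
    counts = Counter(inserts)
    tags = [
        Tag(seq=s, count=c, sample_id=sample_id)
        for s, c in sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    ]
    stats = CleanStats(
        input_reads=len(inserts),
        surviving_reads=len(inserts),
        unique_tags=len(tags),
    )
    return tags, stats


def clean_reads(
    reads, sample_id: str = "", config: CleaningConfig = CleaningConfig()
) -> tuple[list[Tag], CleanStats]:
    """Full cleaning pass: trim, filter, collapse.

    Returns the collapsed tags and a :class:`CleanStats` whose read
    accounting is conserved (inputs = survivors + rejects).
    """
    inserts: list[str] = []
    stats = CleanStats()
    for read in reads:
        stats.input_reads += 1
        trimmed = trim_adapter(read, config.adapter3, config.min_overlap)
        if trimmed is None:
            stats.reject("missing-adapter")
            continue
        rule = quality_filter(trimmed, config)
        if rule is not None:
            stats.reject(rule)
            continue
        inserts.append(trimmed.seq)
    tags, _ = collapse(inserts, sample_id)
    stats.surviving_reads = len(inserts)
    stats.unique_tags = len(tags)
    return tags, stats


def write_tags_fasta(tags: list[Tag], path) -> None:
    """Write collapsed tags as FASTA with the count in the header
    (``tag{N}_x{count}``)."""
    with open(path, "w") as out:
        for i, tag in enumerate(tags, start=1):
            out.write(f">tag{i}_x{tag.count}\n{tag.seq}\n")
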