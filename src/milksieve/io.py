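"""Sequence I/O and miRNA identifier parsing.

All sequence data is normalized to the uppercase DNA alphabet on input
(U -> T), so every downstream matcher works in a single alphabet.  FASTA
and FASTQ records are read through Biopython and wrapped in the light
containers the pipeline passes around.
"""

from __future__ import annotations

import gzip
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

from Bio import SeqIO
from Bio.SeqIO.QualityIO import FastqGeneralIterator

__all__ = [
    "SequenceRecord",
    "QualityRead",
    "MiRNAIdentity",
    "ParseError",
    "read_fasta",
    "write_fasta",
    "read_fastq",
    "write_fastq",
    "parse_mirna_id",
    "reverse_complement",
]

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    """Reverse complement of a DNA-alphabet sequence."""
    return seq.translate(_COMPLEMENT)[::-1]


def _normalize(seq: str) -> str:
    return seq.upper().replace("U", "T")


class ParseError(ValueError):
    """Raised on malformed FASTA/FASTQ input or an unparseable identifier."""


@dataclass(frozen=True)
class SequenceRecord:
    """A named reference sequence (plant miRNA, ncRNA, genome, transcript...)."""

    id: str
    seq: str
    description: str = ""

    def __post_init__(self) -> None:
        if not self.seq:
            raise ParseError(f"empty sequence for record {self.id!r}")

    def __len__(self) -> int:
        return len(self.seq)


@dataclass(frozen=True)
class QualityRead:
    """A sequencing read with per-base Phred scores."""

    id: str
    seq: str
    qual: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.qual) != len(self.seq):
            raise ParseError(
                f"read {self.id!r}: {len(self.seq)} bases but "
                f"{len(self.qual)} quality scores"
            )

    def __len__(self) -> int:
        return len(self.seq)


_MIRNA_RE = re.compile(
    r"^(?P<prefix>[a-zA-Z]{3,4})-miR(?P<num>\d+)(?P<variant>[a-z0-9.\-]*)"
    r"(?P<star>\*?)$"
)


@dataclass(frozen=True)
class MiRNAIdentity:
    """Structured form of a mature plant miRNA identifier like ``ath-miR166a``.

    ``family`` groups paralogs by the numeric part of the name (MIR166 spans
    ath-miR166a, zma-miR166...); ``is_star`` flags the passenger strand
    (trailing ``*`` in the raw identifier).
    """

    species_prefix: str
    family: str
    variant: str
    is_star: bool

    def render(self) -> str:
        star = "*" if self.is_star else ""
        return f"{self.species_prefix}-miR{self.family[3:]}{self.variant}{star}"


def parse_mirna_id(raw: str) -> MiRNAIdentity:
    """Parse ``<prefix>-miR<number><variant>[*]`` into its components.

    Raises :class:`ParseError` (carrying the raw string) for nonstandard
    names; callers that aggregate by family catch this and file the entry
    under family ``UNKNOWN``.
    """
    m = _MIRNA_RE.match(raw.strip())
    if m is None:
        raise ParseError(f"unparseable miRNA identifier: {raw!r}")
    return MiRNAIdentity(
        species_prefix=m.group("prefix"),
        family="MIR" + m.group("num"),
        variant=m.group("variant"),
        is_star=bool(m.group("star")),
    )


def _open_text(path: str | Path):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path)


def read_fasta(path: str | Path) -> list[SequenceRecord]:
    """Read a FASTA file into a list of normalized :class:`SequenceRecord`.

    The record id is the first whitespace-delimited header token; the rest
    of the header line becomes the description.  Duplicate ids and empty
    sequences are errors.
    """
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    with _open_text(path) as handle:
        for rec in SeqIO.parse(handle, "fasta"):
            if rec.id in seen:
                raise ParseError(f"duplicate FASTA id {rec.id!r} in {path}")
            seen.add(rec.id)
            seq = _normalize(str(rec.seq))
            if not seq:
                raise ParseError(f"empty sequence for FASTA id {rec.id!r}")
            desc = rec.description[len(rec.id):].strip()
            records.append(SequenceRecord(id=rec.id, seq=seq, description=desc))
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path) -> None:
    with open(path, "w") as out:
        for rec in records:
            header = rec.id if not rec.description else f"{rec.id} {rec.description}"
            out.write(f">{header}\n{rec.seq}\n")


def read_fastq(path: str | Path, encoding: str = "offset-33") -> Iterator[QualityRead]:
    """Stream a 4-line FASTQ file as :class:`QualityRead` records.

    ``encoding`` selects the Phred offset: ``offset-33`` (modern default)
    or ``offset-64`` (older Illumina pipelines).  Sequences are normalized
    (U->T, uppercase); quality strings are not touched beyond decoding.
    """
    offsets = {"offset-33": 33, "offset-64": 64}
    if encoding not in offsets:
        raise ValueError(f"unknown quality encoding {encoding!r}")
    offset = offsets[encoding]
    with _open_text(path) as handle:
        n = 0
        try:
            for title, seq, qual in FastqGeneralIterator(handle):
                n += 1
                if len(seq) != len(qual):
                    raise ParseError(
                        f"FASTQ record {n} (near line {4 * n}): sequence/quality "
                        f"length mismatch ({len(seq)} vs {len(qual)})"
                    )
                scores = tuple(ord(c) - offset for c in qual)
                if any(q < 0 for q in scores):
                    raise ParseError(
                        f"FASTQ record {n}: negative Phred score under {encoding} "
                        "(wrong offset?)"
                    )
                yield QualityRead(
                    id=title.split()[0], seq=_normalize(seq), qual=scores
                )
        except ValueError as exc:
            if isinstance(exc, ParseError):
                raise
            raise ParseError(
                f"malformed FASTQ near record {n + 1} (line {4 * n + 1}): {exc}"
            ) from exc


def write_fastq(
    reads: Iterable[QualityRead], path: str | Path, encoding: str = "offset-33"
) -> None:
    offset = {"offset-33": 33, "offset-64": 64}[encoding]
    with open(path, "w") as out:
        for read in reads:
            qual = "".join(chr(q + offset) for q in read.qual)
            out.write(f"@{read.id}\n{read.seq}\n+\n{qual}\n")
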