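"""Sequence-comparison primitives for the screening cascade.

Three matchers cover everything the cascade needs:

* :func:`containment_match` — the plant-miRNA criterion: gap-free,
  mismatch-free containment with a length difference of at most one
  nucleotide between tag and mature miRNA.
* :func:`local_search` — seed-and-extend Smith–Waterman with ungapped
  Karlin–Altschul E-values (E = K·m·n·e^{-λS}), standing in for a BLASTN
  screen at a configurable E-value cutoff.
* :func:`hamming_map` / :func:`editing_aware_map` — exhaustive gap-free
  end-to-end mapping with at most k mismatches via a pigeonhole seed
  partition, with an A-to-I-editing-aware two-mismatch variant.

Coordinates are 0-based half-open; minus-strand hits report positions on
the forward reference.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Iterable, Sequence

import numpy as np
from scipy.optimize import brentq

from .io import SequenceRecord, reverse_complement
from .preprocess import Tag

__all__ = [
    "ContainmentHit",
    "LocalHit",
    "MapHit",
    "KarlinParams",
    "ScoringScheme",
    "MiRNAIndex",
    "ReferenceIndex",
    "containment_match",
    "solve_karlin",
    "evalue",
    "local_search",
    "smith_waterman",
    "hamming_map",
    "editing_aware_map",
]


# ---------------------------------------------------------------------------
# containment matching


@dataclass(frozen=True)
class ContainmentHit:
    """A gap-free, mismatch-free containment between a tag and a miRNA."""

    tag_seq: str
    mirna_id: str
    offset: int  # 0-based start of the shorter sequence within the longer
    length_delta: int  # len(tag) - len(miRNA), in {-1, 0, +1}


class MiRNAIndex:
    """Hash index over mature miRNA sequences for O(1) containment lookup.

    For each miRNA we index the full sequence and both length-minus-one
    substrings, so the three admissible cases (equal length, tag one short,
    tag one long) are all dictionary lookups.
    """

    def __init__(self, mirnas: Iterable[SequenceRecord]):
        self._full: dict[str, list[str]] = {}
        self._trimmed: dict[str, list[tuple[str, int]]] = {}  # sub -> (id, offset)
        for rec in mirnas:
            self._full.setdefault(rec.seq, []).append(rec.id)
            if len(rec.seq) >= 2:
                self._trimmed.setdefault(rec.seq[1:], []).append((rec.id, 1))
                self._trimmed.setdefault(rec.seq[:-1], []).append((rec.id, 0))

    def lookup(self, tag_seq: str) -> list[ContainmentHit]:
        hits: list[ContainmentHit] = []
        for mid in self._full.get(tag_seq, ()):
            hits.append(ContainmentHit(tag_seq, mid, 0, 0))
        # tag one nucleotide shorter: tag is a trimmed form of the miRNA
        for mid, off in self._trimmed.get(tag_seq, ()):
            hits.append(ContainmentHit(tag_seq, mid, off, -1))
        # tag one nucleotide longer: a trimmed form of the tag is the miRNA
        if len(tag_seq) >= 2:
            for sub, off in ((tag_seq[1:], 1), (tag_seq[:-1], 0)):
                for mid in self._full.get(sub, ()):
                    hits.append(ContainmentHit(tag_seq, mid, off, +1))
        # dedupe (a palindrome-ish duplicate id can arise only via _full twice)
        seen = set()
        out = []
        for h in hits:
            key = (h.mirna_id, h.offset, h.length_delta)
            if key not in seen:
                seen.add(key)
                out.append(h)
        return out


def containment_match(tag: Tag, index: MiRNAIndex) -> list[ContainmentHit]:
    """All miRNAs containing, contained in, or equal to the tag (|Δlen| ≤ 1)."""
    return index.lookup(tag.seq)


# ---------------------------------------------------------------------------
# Karlin–Altschul statistics


@dataclass(frozen=True)
class ScoringScheme:
    match: float = 1.0
    mismatch: float = -2.0
    gap_open: float = -5.0
    gap_extend: float = -2.0

    def score(self, a: str, b: str) -> float:
        return self.match if a == b else self.mismatch


@dataclass(frozen=True)
class KarlinParams:
    """λ and K of the ungapped local-alignment score distribution."""

    lam: float
    K: float
    background: tuple[float, ...]


def _pair_score_distribution(
    scheme: ScoringScheme, background: Sequence[float]
) -> dict[float, float]:
    """Probability of each aligned-pair score under the background model."""
    dist: dict[float, float] = {}
    for i, pi in enumerate(background):
        for j, pj in enumerate(background):
            s = scheme.match if i == j else scheme.mismatch
            dist[s] = dist.get(s, 0.0) + pi * pj
    return dist


def solve_karlin(
    scheme: ScoringScheme,
    background: Sequence[float] = (0.25, 0.25, 0.25, 0.25),
    max_terms: int = 60,
) -> KarlinParams:
    """Solve the ungapped Karlin–Altschul parameters for a match/mismatch scheme.

    λ is the unique positive root of sum_ij p_i p_j exp(λ s_ij) = 1,
    located by scalar root finding to 1e-12.  K follows the classical
    lattice-case series: with σ = sum_{k>=1} (1/k)[E(e^{λ S_k}; S_k < 0)
    + P(S_k >= 0)], span δ and relative entropy H = λ E(s e^{λ s}),

        K = δ λ e^{-2σ} / (H (1 - e^{-λ δ})).

    Requires a negative expected score and some positive score.
    """
    if abs(sum(background) - 1.0) > 1e-9:
        raise ValueError("background frequencies must sum to 1")
    dist = _pair_score_distribution(scheme, background)
    expected = sum(s * p for s, p in dist.items())
    if expected >= 0 or max(dist) <= 0:
        raise ValueError(
            "no positive Karlin-Altschul root: need negative expected score "
            "and at least one positive score"
        )

    def phi(lam: float) -> float:
        return sum(p * math.exp(lam * s) for s, p in dist.items()) - 1.0

    hi = 1.0
    while phi(hi) < 0:
        hi *= 2.0
    lam = float(brentq(phi, 1e-12, hi, xtol=1e-14, rtol=8.9e-16))

    # lattice span δ: gcd of score differences (scores assumed rational)
    fracs = [Fraction(s).limit_denominator(10**6) for s in dist]
    denom = math.lcm(*[f.denominator for f in fracs])
    ints = [int(f * denom) for f in fracs]
    delta = math.gcd(*[abs(v) for v in ints if v != 0]) / denom

    H = lam * sum(s * p * math.exp(lam * s) for s, p in dist.items())

    # σ via exact convolution of the integer-lattice score distribution
    base = {int(round(s / delta)): p for s, p in dist.items()}
    conv = {0: 1.0}
    sigma = 0.0
    for k in range(1, max_terms + 1):
        new: dict[int, float] = {}
        for s1, p1 in conv.items():
            for s2, p2 in base.items():
                new[s1 + s2] = new.get(s1 + s2, 0.0) + p1 * p2
        conv = new
        term = sum(
            p * (math.exp(lam * s * delta) if s < 0 else 1.0)
            for s, p in conv.items()
        )
        sigma += term / k
    K = delta * lam * math.exp(-2.0 * sigma) / (H * (1.0 - math.exp(-lam * delta)))
    return KarlinParams(lam=lam, K=K, background=tuple(background))


def evalue(score: float, m: int, n: int, params: KarlinParams) -> float:
    """Expected number of chance alignments scoring >= score: K·m·n·e^{-λS}."""
    return params.K * m * n * math.exp(-params.lam * score)


# ---------------------------------------------------------------------------
# local search (seed-and-extend Smith–Waterman)


@dataclass(frozen=True)
class LocalHit:
    tag_seq: str
    subject_id: str
    score: float
    evalue: float
    subject_span: tuple[int, int]


def smith_waterman(
    query: str, subject: str, scheme: ScoringScheme
) -> tuple[float, tuple[int, int]]:
    """Best local alignment score of query vs subject (affine gaps).

    Returns the score and the 0-based half-open subject span of one
    best-scoring alignment.  Full quadratic DP with traceback of the span
    start — queries here are short tags (<= ~40 nt), so this stays cheap.
    """
    m, n = len(query), len(subject)
    NEG = float("-inf")
    go, ge = scheme.gap_open, scheme.gap_extend
    # H: best alignment ending at (i, j); start[i][j]: subject start of that
    # alignment.  E/F carry affine gap states with their own starts.
    H = [[0.0] * (n + 1) for _ in range(m + 1)]
    Hs = [[0] * (n + 1) for _ in range(m + 1)]
    E = [[NEG] * (n + 1) for _ in range(m + 1)]
    Es = [[0] * (n + 1) for _ in range(m + 1)]
    F = [[NEG] * (n + 1) for _ in range(m + 1)]
    Fs = [[0] * (n + 1) for _ in range(m + 1)]
    best, best_end, best_start = 0.0, 0, 0
    for i in range(1, m + 1):
        qi = query[i - 1]
        for j in range(1, n + 1):
            e_ext, e_open = E[i][j - 1] + ge, H[i][j - 1] + go
            if e_ext >= e_open:
                E[i][j], Es[i][j] = e_ext, Es[i][j - 1]
            else:
                E[i][j], Es[i][j] = e_open, Hs[i][j - 1]
            f_ext, f_open = F[i - 1][j] + ge, H[i - 1][j] + go
            if f_ext >= f_open:
                F[i][j], Fs[i][j] = f_ext, Fs[i - 1][j]
            else:
                F[i][j], Fs[i][j] = f_open, Hs[i - 1][j]
            diag = H[i - 1][j - 1] + scheme.score(qi, subject[j - 1])
            dstart = Hs[i - 1][j - 1] if H[i - 1][j - 1] > 0 else j - 1
            h, hs = 0.0, j
            if diag > h:
                h, hs = diag, dstart
            if E[i][j] > h:
                h, hs = E[i][j], Es[i][j]
            if F[i][j] > h:
                h, hs = F[i][j], Fs[i][j]
            H[i][j], Hs[i][j] = h, hs
            if h > best:
                best, best_end, best_start = h, j, hs
    return float(best), (best_start, best_end)


class SubjectSet:
    """A named collection of subject sequences with a shared k-mer seed index."""

    def __init__(self, records: Iterable[SequenceRecord], word_size: int = 7):
        self.records = list(records)
        self.word_size = word_size
        self.total_length = sum(len(r) for r in self.records)
        self._seeds: dict[str, set[int]] = {}
        for idx, rec in enumerate(self.records):
            for p in range(len(rec.seq) - word_size + 1):
                self._seeds.setdefault(rec.seq[p : p + word_size], set()).add(idx)

    def candidates(self, query: str) -> set[int]:
        """Indices of subjects sharing at least one exact word with query."""
        w = self.word_size
        hits: set[int] = set()
        for p in range(len(query) - w + 1):
            hits |= self._seeds.get(query[p : p + w], set())
        return hits


def local_search(
    tag: Tag,
    subjects: SubjectSet,
    params: KarlinParams,
    evalue_max: float = 0.01,
    scheme: ScoringScheme = ScoringScheme(),
    both_strands: bool = True,
) -> list[LocalHit]:
    """Seeded local similarity search with Karlin–Altschul significance.

    Exact shared words (default 7-mers) nominate subjects; each nominated
    subject is then scored by a full Smith–Waterman, so a reported score is
    the true optimum for that subject.  E-values use m = tag length and
    n = total subject-set length.  Minus-strand similarity is probed by
    searching the reverse complement of the tag.
    """
    queries = [tag.seq]
    if both_strands:
        rc = reverse_complement(tag.seq)
        if rc != tag.seq:
            queries.append(rc)
    m, n = len(tag.seq), subjects.total_length
    best_per_subject: dict[int, tuple[float, tuple[int, int]]] = {}
    for q in queries:
        for idx in subjects.candidates(q):
            score, span = smith_waterman(q, subjects.records[idx].seq, scheme)
            if idx not in best_per_subject or score > best_per_subject[idx][0]:
                best_per_subject[idx] = (score, span)
    hits = []
    for idx, (score, span) in best_per_subject.items():
        e = evalue(score, m, n, params)
        if e <= evalue_max:
            hits.append(
                LocalHit(
                    tag_seq=tag.seq,
                    subject_id=subjects.records[idx].id,
                    score=score,
                    evalue=e,
                    subject_span=span,
                )
            )
    hits.sort(key=lambda h: (-h.score, h.subject_id))
    return hits


# ---------------------------------------------------------------------------
# mismatch-limited end-to-end mapping


@dataclass(frozen=True)
class MapHit:
    tag_seq: str
    chrom: str
    pos: int  # 0-based start on the forward reference
    strand: str  # "+" or "-"
    mismatches: tuple[tuple[int, str, str], ...]  # (read_pos, read_base, ref_base)


class ReferenceIndex:
    """Exact k-mer position index over a set of reference sequences.

    Serves the pigeonhole seed partition of :func:`hamming_map`: a read with
    at most k mismatches must contain at least one of k+1 disjoint exact
    segments, each of which is looked up here.  Indexes are built lazily per
    requested word length and cached.
    """

    def __init__(self, records: Iterable[SequenceRecord]):
        self.records = list(records)
        self._indexes: dict[int, dict[str, list[tuple[int, int]]]] = {}

    def _index_for(self, q: int) -> dict[str, list[tuple[int, int]]]:
        if q not in self._indexes:
            idx: dict[str, list[tuple[int, int]]] = {}
            for ri, rec in enumerate(self.records):
                seq = rec.seq
                for p in range(len(seq) - q + 1):
                    idx.setdefault(seq[p : p + q], []).append((ri, p))
            self._indexes[q] = idx
        return self._indexes[q]

    def occurrences(self, word: str) -> list[tuple[int, int]]:
        return self._index_for(len(word)).get(word, [])


def _verify_placement(
    read: str, ref: str, pos: int, k: int
) -> tuple[tuple[int, str, str], ...] | None:
    if pos < 0 or pos + len(read) > len(ref):
        return None
    mm = []
    for i, base in enumerate(read):
        r = ref[pos + i]
        if base != r:
            mm.append((i, base, r))
            if len(mm) > k:
                return None
    return tuple(mm)


def hamming_map(tag: Tag, genome: ReferenceIndex, k: int = 1) -> list[MapHit]:
    """Every gap-free end-to-end placement of the tag with <= k mismatches.

    Both strands are scanned; a minus-strand hit reports the forward-strand
    position, with mismatch read positions given on the original read.
    Exhaustive by the pigeonhole principle: the read is cut into k+1 exact
    segments and every segment occurrence seeds a full verification.
    """
    if k not in (0, 1, 2):
        raise ValueError("k must be 0, 1 or 2")
    hits: list[MapHit] = []
    seen: set[tuple[int, int, str]] = set()
    L = len(tag.seq)
    seg = L // (k + 1)
    if seg < 1:
        raise ValueError("tag too short for the requested mismatch budget")
    for strand, read in (("+", tag.seq), ("-", reverse_complement(tag.seq))):
        for s in range(k + 1):
            off = s * seg
            word = read[off : off + seg] if s < k else read[off:]
            for ri, p in genome.occurrences(word):
                start = p - off
                key = (ri, start, strand)
                if key in seen:
                    continue
                mm = _verify_placement(read, genome.records[ri].seq, start, k)
                if mm is None:
                    continue
                seen.add(key)
                if strand == "-":
                    mm = tuple(
                        sorted(
                            (L - 1 - i, reverse_complement(b), reverse_complement(r))
                            for i, b, r in mm
                        )
                    )
                hits.append(
                    MapHit(
                        tag_seq=tag.seq,
                        chrom=genome.records[ri].id,
                        pos=start,
                        strand=strand,
                        mismatches=mm,
                    )
                )
    hits.sort(key=lambda h: (h.chrom, h.pos, h.strand))
    return hits


# reference base -> read base pairs that are compatible with A-to-I editing
# as it appears in sequencing: A>G on the sense strand, T>C on the antisense
# image.  APOBEC-type C>T / G>A can be enabled via `extra_pairs`.
EDITING_PAIRS: frozenset[tuple[str, str]] = frozenset({("A", "G"), ("T", "C")})


def editing_aware_map(
    tag: Tag,
    genome: ReferenceIndex,
    extra_pairs: frozenset[tuple[str, str]] = frozenset(),
) -> list[MapHit]:
    """Two-mismatch mapping where at least one mismatch is an editing change.

    Keeps placements with <= 2 mismatches of which at least one has
    (reference base, read base) in the editing set {A>G, T>C}; a perfect
    placement (0 mismatches) also qualifies.  Placements whose mismatches
    are all non-editing are dropped.

    Mismatch tuples store bases in original-read orientation; for a
    minus-strand hit the reference-vs-read change at the locus is the
    complement of the stored pair, so the stored pair is checked directly
    against the editing set (the strand flip is already folded into
    EDITING_PAIRS containing both A>G and its antisense image T>C).
    """
    pairs = EDITING_PAIRS | extra_pairs
    out = []
    for hit in hamming_map(tag, genome, k=2):
        if not hit.mismatches:
            out.append(hit)
            continue
        if hit.strand == "+":
            changes = [(r, b) for _, b, r in hit.mismatches]
        else:
            # stored bases are read-oriented; recover ref->read on the read's
            # own strand by complementing the forward-reference pair
            changes = [
                (reverse_complement(r), reverse_complement(b))
                for _, b, r in hit.mismatches
            ]
        if any(c in pairs for c in changes):
            out.append(hit)
    return out


def maphits_to_bed(hits: list[MapHit]) -> str:
    """Render map hits as BED6 lines (chrom, start, end, tag, mismatches, strand)."""
    lines = [
        f"{h.chrom}\t{h.pos}\t{h.pos + len(h.tag_seq)}\t{h.tag_seq}\t"
        f"{len(h.mismatches)}\t{h.strand}"
        for h in hits
    ]
    return "\n".join(lines) + ("\n" if lines else "")
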