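"""Brute-force reference oracles for cross-checking the optimized engines.

Every function here is deliberately naive — substring scans, sliding-window
comparisons, exhaustive structure enumeration — and shares no code path
with the indexed/DP implementations it validates.  They are exponential or
quadratic and only usable at small problem sizes; the test suite and the
reproducibility script run them on randomized instances and require exact
agreement.
"""

from __future__ import annotations

from typing import Iterable, Iterator, Sequence

import numpy as np

from .energy import (
    INF,
    EnergyModel,
    _pair,
    score_duplex_structure,
    score_fold_structure,
)
from .io import SequenceRecord, reverse_complement

__all__ = [
    "brute_containment",
    "brute_hamming_map",
    "enumerate_duplex_structures",
    "brute_duplex_mfe",
    "enumerate_fold_structures",
    "brute_fold_mfe",
    "naive_pearson",
]


def brute_containment(
    tag_seq: str, mirnas: Iterable[SequenceRecord]
) -> set[tuple[str, int, int]]:
    """All (mirna_id, offset, length_delta) by direct substring scanning."""
    out: set[tuple[str, int, int]] = set()
    for rec in mirnas:
        delta = len(tag_seq) - len(rec.seq)
        if delta == 0 and tag_seq == rec.seq:
            out.add((rec.id, 0, 0))
        elif delta == -1:
            off = rec.seq.find(tag_seq)
            while off != -1:
                out.add((rec.id, off, -1))
                off = rec.seq.find(tag_seq, off + 1)
        elif delta == 1:
            off = tag_seq.find(rec.seq)
            while off != -1:
                out.add((rec.id, off, 1))
                off = tag_seq.find(rec.seq, off + 1)
    return out


def brute_hamming_map(
    tag_seq: str, references: Sequence[SequenceRecord], k: int
) -> set[tuple[str, int, str]]:
    """All (chrom, pos, strand) placements with <= k mismatches.

    Vectorized sliding-window comparison over every offset of both strands
    — no index, no pigeonhole.
    """
    out: set[tuple[str, int, str]] = set()
    L = len(tag_seq)
    for strand, read in (("+", tag_seq), ("-", reverse_complement(tag_seq))):
        arr = np.frombuffer(read.encode(), dtype=np.uint8)
        for rec in references:
            if len(rec.seq) < L:
                continue
            ref = np.frombuffer(rec.seq.encode(), dtype=np.uint8)
            windows = np.lib.stride_tricks.sliding_window_view(ref, L)
            mm = (windows != arr).sum(axis=1)
            for pos in np.nonzero(mm <= k)[0]:
                out.add((rec.id, int(pos), strand))
    return out


def enumerate_duplex_structures(
    mirna: str, site: str, max_bulge: int, max_loop: int
) -> Iterator[tuple[tuple[int, int], ...]]:
    """Every admissible intermolecular structure (non-empty pair chains).

    A structure is a chain of pairs (i, j) with i strictly increasing and j
    strictly decreasing whose consecutive gaps satisfy the bulge/internal
    caps.  Exponential; use on sequences of a dozen nucleotides.
    """
    M, N = len(mirna), len(site)
    anchors = [
        (i, j) for i in range(M) for j in range(N) if _pair(mirna[i], site[j])
    ]

    def extend(chain: list[tuple[int, int]]) -> Iterator[tuple[tuple[int, int], ...]]:
        yield tuple(chain)
        i0, j0 = chain[-1]
        for i in range(i0 + 1, M):
            gi = i - i0 - 1
            if gi > max_bulge + max_loop:
                break
            for j in range(j0 - 1, -1, -1):
                gj = j0 - j - 1
                if gj > max_bulge + max_loop:
                    break
                if _pair(mirna[i], site[j]) is None:
                    continue
                if gi == 0 or gj == 0:
                    if gi + gj > max_bulge and gi + gj > 0:
                        continue
                elif gi > max_loop or gj > max_loop:
                    continue
                chain.append((i, j))
                yield from extend(chain)
                chain.pop()

    for a in anchors:
        yield from extend([a])


def brute_duplex_mfe(
    mirna: str,
    site: str,
    model: EnergyModel,
    max_bulge: int = 2,
    max_loop: int = 2,
) -> float:
    """Minimum duplex energy by exhaustive enumeration (0 if nothing binds)."""
    best = 0.0
    for structure in enumerate_duplex_structures(mirna, site, max_bulge, max_loop):
        e = score_duplex_structure(mirna, site, structure, model, max_bulge, max_loop)
        if e < best:
            best = e
    return best


def enumerate_fold_structures(
    window: str, pairable
) -> Iterator[tuple[tuple[int, int], ...]]:
    """Every non-crossing pair set with hairpin loops >= 3 nt.

    ``pairable(i, j)`` gates admissible pairs.  Yields each structure once
    (including the empty one) via interval recursion.
    """
    n = len(window)

    def rec(i: int, j: int) -> Iterator[tuple[tuple[int, int], ...]]:
        if j - i < 4:
            yield ()
            return
        # position i unpaired
        yield from rec(i + 1, j)
        # position i paired with some k
        for k in range(i + 4, j + 1):
            if not pairable(i, k):
                continue
            for inner in rec(i + 1, k - 1):
                for outer in rec(k + 1, j):
                    yield ((i, k),) + inner + outer

    yield from rec(0, n - 1)


def brute_fold_mfe(
    window: str,
    model: EnergyModel,
    constraint: frozenset[int] = frozenset(),
) -> float:
    """Minimum fold energy by exhaustive enumeration under the same model."""

    def pairable(i: int, j: int) -> bool:
        return (
            i not in constraint
            and j not in constraint
            and _pair(window[i], window[j]) is not None
        )

    best = 0.0
    for structure in enumerate_fold_structures(window, pairable):
        e = score_fold_structure(window, structure, model)
        if e < best:
            best = e
    return best


def naive_pearson(x: Sequence[float], y: Sequence[float]) -> float:
    """Two-pass product-moment correlation, no library calls."""
    n = len(x)
    if n != len(y) or n < 2:
        raise ValueError("need two equal-length vectors of n >= 2")
    mx = sum(x) / n
    my = sum(y) / n
    sxy = sum((a - mx) * (b - my) for a, b in zip(x, y))
    sxx = sum((a - mx) ** 2 for a in x)
    syy = sum((b - my) ** 2 for b in y)
    if sxx == 0 or syy == 0:
        raise ValueError("undefined correlation for a constant vector")
    return sxy / (sxx * syy) ** 0.5
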