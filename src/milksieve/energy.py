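"""Nearest-neighbor free-energy machinery for miRNA:target scanning.

Two dynamic programs share one :class:`EnergyModel`:

* :func:`duplex_mfe` — minimum free energy of an intermolecular
  miRNA:site duplex with bounded bulges and internal loops (the
  hybridization energy the scanners threshold at −17 kcal/mol).
* :func:`fold_mfe` — a Zuker-style single-sequence MFE fold used for
  target-site accessibility: :func:`delta_g_open` is the energy cost of
  forcing the site's window positions unpaired.

The stack table is a compact Turner-style set (Watson–Crick + G·U wobble
stacks, kcal/mol at 37 °C) with linear loop penalties; dangling ends and
terminal-AU terms are omitted so every returned structure can be re-scored
term-by-term (and exhaustively enumerated at small n) under exactly the
same model.  Absolute energies are therefore approximate; the −17 / −10
thresholds downstream are configuration, not physics.

Sequences are handled in the DNA alphabet (U normalized to T upstream);
the allowed pairs are A·T, G·C and the G·T image of the G·U wobble.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

__all__ = [
    "EnergyModel",
    "DuplexResult",
    "FoldResult",
    "load_default_model",
    "duplex_mfe",
    "fold_mfe",
    "delta_g_open",
    "score_duplex_structure",
    "score_fold_structure",
]

INF = float("inf")

ALLOWED_PAIRS = frozenset({"AT", "TA", "CG", "GC", "GT", "TG"})
WC_PAIRS = frozenset({"AT", "TA", "CG", "GC"})


@dataclass(frozen=True)
class EnergyModel:
    """Stacking energies and loop penalties, all in kcal/mol."""

    stacks: dict[tuple[str, str], float]
    duplex_init: float = 4.09
    bulge_base: float = 3.8
    bulge_slope: float = 0.5
    internal_base: float = 1.7
    internal_slope: float = 0.5
    hairpin_base: float = 5.4
    hairpin_slope: float = 0.3
    ml_init: float = 3.4
    ml_branch: float = 0.4
    ml_unpaired: float = 0.1
    max_fold_bulge: int = 10
    max_fold_internal: int = 10  # per side

    def stack(self, p1: str, p2: str) -> float:
        return self.stacks[(p1, p2)]

    def bulge(self, size: int) -> float:
        return self.bulge_base + self.bulge_slope * (size - 1)

    def internal(self, size: int) -> float:
        return self.internal_base + self.internal_slope * size

    def hairpin(self, size: int) -> float:
        return self.hairpin_base + self.hairpin_slope * (size - 3)


def _mirror(stacks: dict[tuple[str, str], float]) -> dict[tuple[str, str], float]:
    """Complete a stack table under helix-reversal symmetry.

    Reading a helix from the other strand maps stack (p1, p2) onto
    (reverse(p2), reverse(p1)); both spellings denote the same physical
    stack and must carry the same energy.
    """
    full = dict(stacks)
    for (p1, p2), e in stacks.items():
        full.setdefault((p2[::-1], p1[::-1]), e)
    return full


def load_default_model(path: str | Path | None = None) -> EnergyModel:
    """Load the packaged stack table (or a user TSV: pair1, pair2, kcal/mol)."""
    if path is None:
        source = resources.files("milksieve").joinpath("data/stack_energies.tsv")
        text = source.read_text()
    else:
        text = Path(path).read_text()
    stacks: dict[tuple[str, str], float] = {}
    for row in csv.reader(text.splitlines(), delimiter="\t"):
        if not row or row[0].startswith("#"):
            continue
        p1, p2, e = row[0], row[1], float(row[2])
        if p1 not in ALLOWED_PAIRS or p2 not in ALLOWED_PAIRS:
            raise ValueError(f"unknown pair in stack table: {p1}/{p2}")
        stacks[(p1, p2)] = e
    return EnergyModel(stacks=_mirror(stacks))


def _pair(a: str, b: str) -> str | None:
    p = a + b
    return p if p in ALLOWED_PAIRS else None


# ---------------------------------------------------------------------------
# intermolecular duplex


@dataclass(frozen=True)
class DuplexResult:
    mfe: float
    structure: tuple[tuple[int, int], ...]  # (i in miRNA, j in site), i asc, j desc
    bulges: tuple[int, ...] = ()
    internal_loops: tuple[int, ...] = ()

    @property
    def bound(self) -> bool:
        return bool(self.structure)


def _duplex_transition(
    model: EnergyModel,
    p_prev: str,
    p_next: str,
    gi: int,
    gj: int,
    max_bulge: int,
    max_loop: int,
) -> float:
    """Energy of extending pair p_prev by p_next across (gi, gj) unpaired bases.

    Returns +inf for inadmissible loops.  Internal-loop admissibility is
    per-side (each side <= max_loop); the penalty is charged on the total.
    """
    if gi == 0 and gj == 0:
        return model.stack(p_prev, p_next)
    if gi == 0 or gj == 0:
        size = gi + gj
        return model.bulge(size) if size <= max_bulge else INF
    if gi <= max_loop and gj <= max_loop:
        return model.internal(gi + gj)
    return INF


def duplex_mfe(
    mirna: str,
    site: str,
    model: EnergyModel,
    max_bulge: int = 2,
    max_loop: int = 2,
) -> DuplexResult:
    """Minimum free energy of the intermolecular miRNA:site duplex.

    The miRNA (5'->3', index i) pairs antiparallel against the site
    (index j decreasing).  The duplex initiation penalty is charged once;
    unpaired overhangs are free.  When no admissible pair exists at all the
    unbound convention applies: empty structure, mfe 0.
    """
    M, N = len(mirna), len(site)
    if M == 0 or N == 0:
        raise ValueError("empty sequence")
    best: dict[tuple[int, int], float] = {}
    back: dict[tuple[int, int], tuple[int, int] | None] = {}
    order: list[tuple[int, int]] = []
    for i in range(M):
        for j in range(N - 1, -1, -1):
            p = _pair(mirna[i], site[j])
            if p is None:
                continue
            e, src = model.duplex_init, None
            for i0 in range(max(0, i - max_bulge - max_loop - 1), i):
                for j0 in range(j + 1, min(N, j + max_bulge + max_loop + 2)):
                    if (i0, j0) not in best:
                        continue
                    p0 = _pair(mirna[i0], site[j0])
                    t = _duplex_transition(
                        model, p0, p, i - i0 - 1, j0 - j - 1, max_bulge, max_loop
                    )
                    if t < INF and best[(i0, j0)] + t < e:
                        e, src = best[(i0, j0)] + t, (i0, j0)
            best[(i, j)] = e
            back[(i, j)] = src
            order.append((i, j))
    if not best:
        return DuplexResult(mfe=0.0, structure=())
    end = min(best, key=lambda k: (best[k], k))
    mfe = best[end]
    if mfe > 0:
        # binding costs more than it gains: the unbound state is the minimum
        return DuplexResult(mfe=0.0, structure=())
    pairs: list[tuple[int, int]] = []
    cur: tuple[int, int] | None = end
    while cur is not None:
        pairs.append(cur)
        cur = back[cur]
    pairs.reverse()
    bulges, internals = [], []
    for (i0, j0), (i1, j1) in zip(pairs, pairs[1:]):
        gi, gj = i1 - i0 - 1, j0 - j1 - 1
        if gi + gj == 0:
            continue
        (bulges if (gi == 0 or gj == 0) else internals).append(gi + gj)
    return DuplexResult(
        mfe=mfe,
        structure=tuple(pairs),
        bulges=tuple(bulges),
        internal_loops=tuple(internals),
    )


def score_duplex_structure(
    mirna: str,
    site: str,
    pairs: tuple[tuple[int, int], ...],
    model: EnergyModel,
    max_bulge: int = 2,
    max_loop: int = 2,
) -> float:
    """Re-score a duplex pair list term-by-term; +inf if inadmissible."""
    if not pairs:
        return 0.0
    e = model.duplex_init
    prev = pairs[0]
    if _pair(mirna[prev[0]], site[prev[1]]) is None:
        return INF
    for nxt in pairs[1:]:
        if nxt[0] <= prev[0] or nxt[1] >= prev[1]:
            return INF
        p0 = _pair(mirna[prev[0]], site[prev[1]])
        p1 = _pair(mirna[nxt[0]], site[nxt[1]])
        if p1 is None:
            return INF
        e += _duplex_transition(
            model, p0, p1, nxt[0] - prev[0] - 1, prev[1] - nxt[1] - 1,
            max_bulge, max_loop,
        )
        prev = nxt
    return e


# ---------------------------------------------------------------------------
# single-sequence fold


@dataclass(frozen=True)
class FoldResult:
    mfe: float
    pairs: tuple[tuple[int, int], ...]


def fold_mfe(
    window: str,
    model: EnergyModel,
    constraint: frozenset[int] | set[int] = frozenset(),
    max_len: int = 200,
) -> FoldResult:
    """Zuker-style MFE fold over non-crossing structures.

    Loop energies: stacks from the model table; hairpins (minimum loop 3),
    bulges (<= max_fold_bulge) and internal loops (each side
    <= max_fold_internal) with linear penalties; multibranch loops with
    affine init/branch/unpaired terms.  ``constraint`` positions are forced
    unpaired.  Exterior bases are free, so the MFE is never positive.
    """
    n = len(window)
    if n > max_len:
        raise ValueError(f"window of {n} nt exceeds the configured cap {max_len}")
    if n == 0:
        return FoldResult(mfe=0.0, pairs=())
    bcap = model.max_fold_bulge
    icap = model.max_fold_internal

    def pairable(i: int, j: int) -> str | None:
        if i in constraint or j in constraint or j - i - 1 < 3:
            return None
        return _pair(window[i], window[j])

    V = [[INF] * n for _ in range(n)]
    M = [[INF] * n for _ in range(n)]
    M1 = [[INF] * n for _ in range(n)]
    vb: dict[tuple[int, int], tuple] = {}
    mb: dict[tuple[int, int], tuple] = {}
    m1b: dict[tuple[int, int], tuple] = {}

    for span in range(4, n):
        for i in range(0, n - span):
            j = i + span
            p = pairable(i, j)
            if p is not None:
                e, choice = model.hairpin(j - i - 1), ("hairpin",)
                # stack / bulge / internal to an inner pair (k, l)
                for s1 in range(0, min(max(bcap, icap), j - i - 2) + 1):
                    k = i + 1 + s1
                    for s2 in range(0, min(max(bcap, icap), j - k - 1) + 1):
                        l = j - 1 - s2
                        if l - k - 1 < 3:
                            break
                        q = pairable(k, l)
                        if q is None or V[k][l] == INF:
                            continue
                        t = _duplex_transition(model, p, q, s1, s2, bcap, icap)
                        if t < INF and V[k][l] + t < e:
                            e, choice = V[k][l] + t, ("loop", k, l)
                # multibranch: closing pair + >= 2 branches inside
                for u in range(i + 1, j - 1):
                    if M[i + 1][u] < INF and M1[u + 1][j - 1] < INF:
                        cand = (
                            model.ml_init
                            + model.ml_branch
                            + M[i + 1][u]
                            + M1[u + 1][j - 1]
                        )
                        if cand < e:
                            e, choice = cand, ("ml", u)
                V[i][j] = e
                vb[(i, j)] = choice
            # M1: exactly one branch, optional trailing unpaired
            e1, c1 = INF, None
            if V[i][j] < INF:
                e1, c1 = V[i][j] + model.ml_branch, ("v",)
            if j > i and M1[i][j - 1] + model.ml_unpaired < e1:
                e1, c1 = M1[i][j - 1] + model.ml_unpaired, ("trail",)
            if e1 < INF:
                M1[i][j] = e1
                m1b[(i, j)] = c1
            # M: >= 1 branch, leading unpaired and splits allowed
            em, cm = INF, None
            if M1[i][j] < INF:
                em, cm = M1[i][j], ("m1",)
            if j > i and M[i + 1][j] + model.ml_unpaired < em:
                em, cm = M[i + 1][j] + model.ml_unpaired, ("lead",)
            for u in range(i, j):
                if M[i][u] < INF and M1[u + 1][j] < INF:
                    cand = M[i][u] + M1[u + 1][j]
                    if cand < em:
                        em, cm = cand, ("split", u)
            if em < INF:
                M[i][j] = em
                mb[(i, j)] = cm

    # exterior loop
    W = [0.0] * (n + 1)
    wb: list[tuple | None] = [None] * (n + 1)
    for j in range(1, n + 1):
        W[j], wb[j] = W[j - 1], None
        for i in range(0, j):
            if V[i][j - 1] < INF and W[i] + V[i][j - 1] < W[j]:
                W[j], wb[j] = W[i] + V[i][j - 1], ("pair", i, j - 1)

    pairs: list[tuple[int, int]] = []

    def trace_v(i: int, j: int) -> None:
        pairs.append((i, j))
        choice = vb[(i, j)]
        if choice[0] == "loop":
            trace_v(choice[1], choice[2])
        elif choice[0] == "ml":
            trace_m(i + 1, choice[1])
            trace_m1(choice[1] + 1, j - 1)

    def trace_m1(i: int, j: int) -> None:
        choice = m1b[(i, j)]
        if choice[0] == "v":
            trace_v(i, j)
        else:
            trace_m1(i, j - 1)

    def trace_m(i: int, j: int) -> None:
        choice = mb[(i, j)]
        if choice[0] == "m1":
            trace_m1(i, j)
        elif choice[0] == "lead":
            trace_m(i + 1, j)
        else:
            u = choice[1]
            trace_m(i, u)
            trace_m1(u + 1, j)

    j = n
    while j > 0:
        if wb[j] is None:
            j -= 1
        else:
            _, i, jj = wb[j]
            trace_v(i, jj)
            j = i
    pairs.sort()
    return FoldResult(mfe=W[n], pairs=tuple(pairs))


def score_fold_structure(
    window: str,
    pairs: tuple[tuple[int, int], ...],
    model: EnergyModel,
) -> float:
    """Loop-decomposition energy of a pair list; +inf if inadmissible.

    Used both as the audit that a fold's reported MFE matches its returned
    structure and as the scorer behind the exhaustive enumeration oracle.
    """
    if not pairs:
        return 0.0
    plist = sorted(pairs)
    used = [idx for p in plist for idx in p]
    if len(set(used)) != len(used):
        return INF
    for i, j in plist:
        if i >= j or _pair(window[i], window[j]) is None:
            return INF
    # nesting tree; partial overlap means a pseudoknot -> inadmissible
    stack: list[tuple[int, int]] = []
    children: dict[tuple[int, int], list[tuple[int, int]]] = {p: [] for p in plist}
    for p in plist:
        while stack and stack[-1][1] < p[0]:
            stack.pop()
        if stack:
            top = stack[-1]
            if not (top[0] < p[0] and p[1] < top[1]):
                return INF
            children[top].append(p)
        stack.append(p)
    e = 0.0
    for (i, j), kids in children.items():
        unpaired = (j - i - 1) - sum(l - k + 1 for k, l in kids)
        if not kids:
            if j - i - 1 < 3:
                return INF
            e += model.hairpin(j - i - 1)
        elif len(kids) == 1:
            (k, l) = kids[0]
            s1, s2 = k - i - 1, j - l - 1
            p1, p2 = _pair(window[i], window[j]), _pair(window[k], window[l])
            t = _duplex_transition(
                model, p1, p2, s1, s2, model.max_fold_bulge, model.max_fold_internal
            )
            if t == INF:
                return INF
            e += t
        else:
            e += (
                model.ml_init
                + model.ml_branch * (len(kids) + 1)
                + model.ml_unpaired * unpaired
            )
    return e


def delta_g_open(
    window: str,
    site_span: tuple[int, int],
    model: EnergyModel,
) -> float:
    """Free-energy cost of opening the site: constrained MFE − free MFE (>= 0)."""
    start, end = site_span
    if not (0 <= start <= end <= len(window)):
        raise ValueError("site span outside window")
    free = fold_mfe(window, model).mfe
    constrained = fold_mfe(window, model, constraint=frozenset(range(start, end))).mfe
    return max(0.0, constrained - free)


def dot_bracket(length: int, pairs: tuple[tuple[int, int], ...]) -> str:
    """Dot-bracket rendering of a non-crossing pair list."""
    out = ["."] * length
    for i, j in pairs:
        out[i], out[j] = "(", ")"
    return "".join(out)
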