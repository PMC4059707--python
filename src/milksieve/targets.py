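"""miRNA:target scanners and three-way consensus prediction.

Three scanners embody the acceptance rules of the classical predictors:

* :func:`miranda_scan` — weighted complementarity alignment (canonical
  pair +5, G:U wobble +2, 5' positional weighting), kept when the score
  exceeds 130, the duplex MFE is below −17 kcal/mol, and the seed region
  (miRNA positions 2–8) is gap-free and perfectly Watson–Crick paired.
* :func:`rnahybrid_scan` — duplex MFE with bulges and internal loops
  capped at 2 nt, kept when the MFE is −17 kcal/mol or lower.
* :func:`pita_scan` — perfect 7/8-mer Watson–Crick seed anchors scored by
  ΔΔG = duplex MFE + ΔG_open (site-accessibility cost), kept below −10.

:func:`consensus` intersects the three per-transcript target lists and
ranks by alignment score (descending) then duplex MFE (ascending).
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .energy import EnergyModel, delta_g_open, duplex_mfe
from .io import SequenceRecord, reverse_complement

__all__ = [
    "TargetSite",
    "ConsensusTarget",
    "ScanConfig",
    "miranda_scan",
    "rnahybrid_scan",
    "pita_scan",
    "consensus",
    "scan_all",
]

# complement on the transcript strand (DNA letters; transcript T == RNA U)
_WC = {"A": "T", "T": "A", "C": "G", "G": "C"}
_WOBBLE = {("G", "T"), ("T", "G")}  # miRNA G : transcript U and vice versa


@dataclass(frozen=True)
class ScanConfig:
    miranda_min_score: float = 130.0
    miranda_max_mfe: float = -17.0
    rnahybrid_max_mfe: float = -17.0
    pita_max_ddg: float = -10.0
    pair_canonical: float = 5.0
    pair_wobble: float = 2.0
    pair_mismatch: float = -3.0
    gap_open: float = -8.0
    gap_extend: float = -2.0
    weight5p: float = 4.0  # scale on miRNA positions 1-10
    weighted_span: int = 10
    seed_start: int = 2  # miRNA positions, 1-based, inclusive
    seed_end: int = 8
    max_bulge: int = 2
    max_loop: int = 2
    accessibility_flank: int = 70
    window_step: int = 7
    window_pad: int = 8


@dataclass(frozen=True)
class TargetSite:
    mirna_id: str
    transcript_id: str
    region: str
    site_span: tuple[int, int]  # 0-based half-open on the transcript
    align_score: float
    duplex_mfe: float
    ddg: float
    seed_ok: bool
    method: str


@dataclass(frozen=True)
class ConsensusTarget:
    mirna_id: str
    transcript_id: str
    region: str
    align_score: float
    duplex_mfe: float
    ddg: float
    sites: tuple[TargetSite, ...]


def _pair_score(m: str, t: str, config: ScanConfig) -> tuple[float, str]:
    """Score and class ('canonical'/'wobble'/'mismatch') of pairing miRNA
    base m against transcript base t."""
    if _WC[m] == t:
        return config.pair_canonical, "canonical"
    if (m, t) in _WOBBLE:
        return config.pair_wobble, "wobble"
    return config.pair_mismatch, "mismatch"


def _complement_align(
    mirna: str, window: str, config: ScanConfig
) -> tuple[float, list[tuple[int | None, int | None]], tuple[int, int]]:
    """Best local complementarity alignment of the miRNA against a window.

    The miRNA runs 5'->3' (index i); the window is scanned antiparallel,
    which is realized by aligning against the reversed window.  Pair scores
    at miRNA positions 1..weighted_span are scaled by weight5p (gap costs
    are not scaled).  Returns (score, aligned columns as (i, j) with None
    for a gap, window span 5'->3').
    """
    rev = window[::-1]
    m, n = len(mirna), len(rev)
    NEG = float("-inf")
    H = [[0.0] * (n + 1) for _ in range(m + 1)]
    E = [[NEG] * (n + 1) for _ in range(m + 1)]
    F = [[NEG] * (n + 1) for _ in range(m + 1)]
    ptr: dict[tuple[str, int, int], tuple] = {}
    best, bi, bj = 0.0, 0, 0
    for i in range(1, m + 1):
        w = config.weight5p if i <= config.weighted_span else 1.0
        for j in range(1, n + 1):
            eo, ee = H[i][j - 1] + config.gap_open, E[i][j - 1] + config.gap_extend
            E[i][j] = max(eo, ee)
            ptr[("E", i, j)] = ("H", i, j - 1) if eo >= ee else ("E", i, j - 1)
            fo, fe = H[i - 1][j] + config.gap_open, F[i - 1][j] + config.gap_extend
            F[i][j] = max(fo, fe)
            ptr[("F", i, j)] = ("H", i - 1, j) if fo >= fe else ("F", i - 1, j)
            s, _ = _pair_score(mirna[i - 1], rev[j - 1], config)
            diag = H[i - 1][j - 1] + w * s
            h, src = 0.0, None
            if diag > h:
                h, src = diag, ("H", i - 1, j - 1, "diag")
            if E[i][j] > h:
                h, src = E[i][j], ("E", i, j, "gap")
            if F[i][j] > h:
                h, src = F[i][j], ("F", i, j, "gap")
            H[i][j] = h
            ptr[("H", i, j)] = src
            if h > best:
                best, bi, bj = h, i, j
    # traceback
    cols: list[tuple[int | None, int | None]] = []
    state: tuple = ("H", bi, bj)
    jmin, jmax = bj, bj
    while True:
        kind, i, j = state
        if kind == "H":
            src = ptr.get(("H", i, j))
            if src is None:
                break
            if src[-1] == "diag":
                cols.append((i - 1, j - 1))
                jmin = min(jmin, j)
                state = ("H", i - 1, j - 1)
            else:
                state = (src[0], src[1], src[2])
        elif kind == "E":
            cols.append((None, j - 1))
            jmin = min(jmin, j)
            state = ptr[("E", i, j)]
        else:
            cols.append((i - 1, None))
            state = ptr[("F", i, j)]
    cols.reverse()
    # map reversed-window coordinates back to the forward window
    span = (len(window) - bj, len(window) - jmin + 1)
    cols = [
        (i, None if j is None else len(window) - 1 - j) for i, j in cols
    ]
    return best, cols, span


def _seed_ok(
    mirna: str, window: str, cols: list[tuple[int | None, int | None]],
    config: ScanConfig,
) -> bool:
    """Seed rule: miRNA positions seed_start..seed_end (1-based from the 5'
    end) must be aligned without gaps and paired canonically."""
    seed = set(range(config.seed_start - 1, config.seed_end))
    paired: dict[int, str] = {}
    for i, j in cols:
        if i is not None and i in seed:
            if j is None:
                return False
            paired[i] = _pair_score(mirna[i], window[j], config)[1]
    if set(paired) != seed:
        return False
    if any(cls != "canonical" for cls in paired.values()):
        return False
    # reject transcript-side gaps interrupting the seed block
    idx = [k for k, (i, _) in enumerate(cols) if i is not None and i in seed]
    if idx and any(
        cols[k][0] is None for k in range(min(idx), max(idx) + 1)
    ):
        return False
    return True


def _windows(transcript: str, mirna_len: int, config: ScanConfig):
    width = mirna_len + config.window_pad
    if len(transcript) <= width:
        yield 0, transcript
        return
    for start in range(0, len(transcript) - width + 1, config.window_step):
        yield start, transcript[start : start + width]
    tail = len(transcript) - width
    if tail % config.window_step:
        yield tail, transcript[tail:]


def miranda_scan(
    mirna_id: str,
    mirna: str,
    transcript: SequenceRecord,
    model: EnergyModel,
    config: ScanConfig = ScanConfig(),
    region: str = "3UTR",
) -> list[TargetSite]:
    """Weighted complementarity scan; one best site per transcript window,
    thresholded on score, duplex MFE and the strict seed rule."""
    sites: dict[tuple[int, int], TargetSite] = {}
    for start, window in _windows(transcript.seq, len(mirna), config):
        score, cols, (w0, w1) = _complement_align(mirna, window, config)
        if score <= config.miranda_min_score:
            continue
        if not _seed_ok(mirna, window, cols, config):
            continue
        site_seq = window[w0:w1]
        mfe = duplex_mfe(
            mirna, site_seq, model, config.max_bulge, config.max_loop
        ).mfe
        if not mfe < config.miranda_max_mfe:
            continue
        span = (start + w0, start + w1)
        site = TargetSite(
            mirna_id=mirna_id,
            transcript_id=transcript.id,
            region=region,
            site_span=span,
            align_score=score,
            duplex_mfe=mfe,
            ddg=float("nan"),
            seed_ok=True,
            method="miranda",
        )
        prev = sites.get(span)
        if prev is None or site.align_score > prev.align_score:
            sites[span] = site
    return _best_nonoverlapping(list(sites.values()))


def rnahybrid_scan(
    mirna_id: str,
    mirna: str,
    transcript: SequenceRecord,
    model: EnergyModel,
    config: ScanConfig = ScanConfig(),
    region: str = "3UTR",
) -> list[TargetSite]:
    """Hybridization-energy scan: duplex MFE with 2-nt bulge/loop caps,
    sites kept at MFE <= the −17 kcal/mol threshold."""
    sites = []
    for start, window in _windows(transcript.seq, len(mirna), config):
        res = duplex_mfe(mirna, window, model, config.max_bulge, config.max_loop)
        if not res.structure or not res.mfe <= config.rnahybrid_max_mfe:
            continue
        j_hi = max(j for _, j in res.structure) + 1
        j_lo = min(j for _, j in res.structure)
        sites.append(
            TargetSite(
                mirna_id=mirna_id,
                transcript_id=transcript.id,
                region=region,
                site_span=(start + j_lo, start + j_hi),
                align_score=0.0,
                duplex_mfe=res.mfe,
                ddg=float("nan"),
                seed_ok=True,
                method="rnahybrid",
            )
        )
    return _best_nonoverlapping(sites, key=lambda s: s.duplex_mfe)


def pita_scan(
    mirna_id: str,
    mirna: str,
    transcript: SequenceRecord,
    model: EnergyModel,
    config: ScanConfig = ScanConfig(),
    region: str = "3UTR",
) -> list[TargetSite]:
    """Accessibility-aware scan anchored at perfect Watson–Crick seeds.

    Anchors are exact complements of miRNA positions 2–8 (7-mer) or 2–9
    (8-mer); G:U and mismatches in the seed are rejected by construction.
    ΔΔG = duplex MFE + opening cost of the site within a ±flank window;
    sites kept at ΔΔG < −10.
    """
    sites: dict[tuple[int, int], TargetSite] = {}
    seq = transcript.seq
    for seed_len in (7, 8):
        seed = mirna[1 : 1 + seed_len]  # miRNA positions 2..(1+seed_len)
        probe = reverse_complement(seed)
        p = seq.find(probe)
        while p != -1:
            # miRNA position 1 pairs just 3' of the seed match
            q = p + seed_len  # transcript index pairing miRNA position 1
            lo = max(0, q + 1 - len(mirna))
            hi = min(len(seq), q + 1)
            site_seq = seq[lo:hi]
            dup = duplex_mfe(
                mirna, site_seq, model, config.max_bulge, config.max_loop
            ).mfe
            w0 = max(0, lo - config.accessibility_flank)
            w1 = min(len(seq), hi + config.accessibility_flank)
            open_cost = delta_g_open(seq[w0:w1], (lo - w0, hi - w0), model)
            ddg = dup + open_cost
            if not ddg < config.pita_max_ddg:
                p = seq.find(probe, p + 1)
                continue
            span = (lo, hi)
            site = TargetSite(
                mirna_id=mirna_id,
                transcript_id=transcript.id,
                region=region,
                site_span=span,
                align_score=0.0,
                duplex_mfe=dup,
                ddg=ddg,
                seed_ok=True,
                method="pita",
            )
            prev = sites.get(span)
            if prev is None or site.ddg < prev.ddg:
                sites[span] = site
            p = seq.find(probe, p + 1)
    return sorted(sites.values(), key=lambda s: s.ddg)


def _best_nonoverlapping(sites: list[TargetSite], key=None) -> list[TargetSite]:
    """Collapse overlapping windowed hits, keeping the best per locus."""
    if key is None:
        key = lambda s: (-s.align_score, s.duplex_mfe)
    chosen: list[TargetSite] = []
    for site in sorted(sites, key=key):
        if all(
            site.site_span[1] <= c.site_span[0] or site.site_span[0] >= c.site_span[1]
            for c in chosen
        ):
            chosen.append(site)
    chosen.sort(key=lambda s: s.site_span)
    return chosen


def scan_all(
    mirna_id: str,
    mirna: str,
    transcripts: list[SequenceRecord],
    model: EnergyModel,
    config: ScanConfig = ScanConfig(),
    region: str = "3UTR",
) -> dict[str, list[TargetSite]]:
    """Run all three scanners over a transcript set."""
    out: dict[str, list[TargetSite]] = {"miranda": [], "rnahybrid": [], "pita": []}
    for tr in transcripts:
        out["miranda"] += miranda_scan(mirna_id, mirna, tr, model, config, region)
        out["rnahybrid"] += rnahybrid_scan(mirna_id, mirna, tr, model, config, region)
        out["pita"] += pita_scan(mirna_id, mirna, tr, model, config, region)
    return out


def consensus(
    mirna_id: str,
    per_method: dict[str, list[TargetSite]],
    top_k: int = 25,
) -> list[ConsensusTarget]:
    """Transcripts selected by all three methods, ranked and truncated.

    Ranking is lexicographic: alignment score descending, duplex MFE
    ascending, transcript id.  The alignment score of a consensus target is
    its best miranda score; the MFE is the lowest across methods.
    """
    by_method = {
        m: {s.transcript_id: s for s in _best_per_transcript(sites)}
        for m, sites in per_method.items()
    }
    if set(by_method) != {"miranda", "rnahybrid", "pita"}:
        raise ValueError("need site lists for miranda, rnahybrid and pita")
    shared = (
        set(by_method["miranda"])
        & set(by_method["rnahybrid"])
        & set(by_method["pita"])
    )
    out = []
    for tid in shared:
        trio = tuple(by_method[m][tid] for m in ("miranda", "rnahybrid", "pita"))
        out.append(
            ConsensusTarget(
                mirna_id=mirna_id,
                transcript_id=tid,
                region=trio[0].region,
                align_score=by_method["miranda"][tid].align_score,
                duplex_mfe=min(s.duplex_mfe for s in trio),
                ddg=by_method["pita"][tid].ddg,
                sites=trio,
            )
        )
    out.sort(key=lambda c: (-c.align_score, c.duplex_mfe, c.transcript_id))
    return out[:top_k]


def _best_per_transcript(sites: list[TargetSite]) -> list[TargetSite]:
    best: dict[str, TargetSite] = {}
    for s in sites:
        cur = best.get(s.transcript_id)
        if cur is None:
            best[s.transcript_id] = s
            continue
        if s.method == "pita":
            if s.ddg < cur.ddg:
                best[s.transcript_id] = s
        elif s.method == "rnahybrid":
            if s.duplex_mfe < cur.duplex_mfe:
                best[s.transcript_id] = s
        elif (s.align_score, -s.duplex_mfe) > (cur.align_score, -cur.duplex_mfe):
            best[s.transcript_id] = s
    return list(best.values())
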