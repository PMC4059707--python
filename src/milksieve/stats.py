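"""Descriptive statistics over plant-miRNA profiles.

Length distributions of surviving tags, pairwise Pearson correlation of
per-sample miRNA count profiles (two-sided t reference, n-2 df), and the
correlation-matrix summary with its mean off-diagonal r.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
from scipy import stats as sps

from .pipeline import PlantMiRNAProfile
from .preprocess import Tag

__all__ = [
    "CorrelationResult",
    "UndefinedCorrelationError",
    "length_distribution",
    "pearson",
    "profile_pearson",
    "correlation_matrix",
    "mean_offdiagonal",
    "load_porcine_correlation_table",
    "format_matrix",
]


class UndefinedCorrelationError(ValueError):
    """Pearson r is undefined for a constant vector (reported NA, never 0)."""


@dataclass(frozen=True)
class CorrelationResult:
    r: float
    p_value: float  # nan when n < 3
    n: int


def length_distribution(tags: list[Tag]) -> dict[int, int]:
    """Read counts by insert length (tag counts are the weights).

    The returned dict has no flags; callers treat lengths outside 17–30 nt
    as anomalous when reporting.
    """
    out: dict[int, int] = {}
    for tag in tags:
        out[len(tag.seq)] = out.get(len(tag.seq), 0) + tag.count
    return dict(sorted(out.items()))


def pearson(x, y) -> CorrelationResult:
    """Product-moment correlation with a two-sided t test (n-2 df).

    Raises :class:`UndefinedCorrelationError` when either vector is
    constant; for n == 2 the r is exact but p is undefined (nan).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 2:
        raise ValueError("need two equal-length 1-d vectors with n >= 2")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise UndefinedCorrelationError("constant vector")
    n = len(x)
    if n == 2:
        r = float(np.sign((x[1] - x[0]) * (y[1] - y[0])))
        return CorrelationResult(r=r, p_value=float("nan"), n=2)
    res = sps.pearsonr(x, y)
    return CorrelationResult(r=float(res.statistic), p_value=float(res.pvalue), n=n)


def profile_pearson(
    a: PlantMiRNAProfile, b: PlantMiRNAProfile, species: str = "union"
) -> CorrelationResult:
    """Correlate two profiles over their species union (absent species = 0).

    ``species="intersection"`` restricts to shared species for sensitivity
    analysis.
    """
    if species == "union":
        keys = sorted(set(a.entries) | set(b.entries))
    elif species == "intersection":
        keys = sorted(set(a.entries) & set(b.entries))
    else:
        raise ValueError("species must be 'union' or 'intersection'")
    x = [a.entries.get(k, 0) for k in keys]
    y = [b.entries.get(k, 0) for k in keys]
    return pearson(x, y)


def correlation_matrix(
    profiles: list[PlantMiRNAProfile], species: str = "union"
) -> list[list[CorrelationResult | None]]:
    """Symmetric matrix of pairwise profile correlations.

    Unit diagonal; an undefined pair (constant vector) propagates as None.
    """
    if len(profiles) < 2:
        raise ValueError("need at least two profiles")
    k = len(profiles)
    matrix: list[list[CorrelationResult | None]] = [
        [None] * k for _ in range(k)
    ]
    for i in range(k):
        matrix[i][i] = CorrelationResult(r=1.0, p_value=0.0, n=len(profiles[i].entries))
        for j in range(i + 1, k):
            try:
                res = profile_pearson(profiles[i], profiles[j], species)
            except UndefinedCorrelationError:
                res = None
            matrix[i][j] = res
            matrix[j][i] = res
    return matrix


def mean_offdiagonal(matrix: list[list[CorrelationResult | None]]) -> float:
    """Arithmetic mean of the defined upper-triangle r values."""
    rs = [
        matrix[i][j].r
        for i in range(len(matrix))
        for j in range(i + 1, len(matrix))
        if matrix[i][j] is not None
    ]
    if not rs:
        raise ValueError("no defined off-diagonal correlations")
    return float(np.mean(rs))


def load_porcine_correlation_table(
    path: str | Path | None = None,
) -> tuple[list[str], list[list[CorrelationResult | None]]]:
    """Load the packaged six-sample porcine milk-exosome correlation matrix.

    The table holds the published pairwise Pearson r (with two-sided p in
    brackets) among six porcine breast-milk exosome plant-miRNA profiles
    (three day-0 samples plus days 14, 21, 28); the per-cell n is not
    recoverable from the printed matrix and is stored as 0.
    """
    if path is None:
        text = (
            resources.files("milksieve")
            .joinpath("data/porcine_exosome_pearson.tsv")
            .read_text()
        )
    else:
        text = Path(path).read_text()
    rows = [r for r in csv.reader(text.splitlines(), delimiter="\t") if r and not r[0].startswith("#")]
    names = rows[0][1:]
    k = len(names)
    matrix: list[list[CorrelationResult | None]] = [[None] * k for _ in range(k)]
    for i, row in enumerate(rows[1:]):
        matrix[i][i] = CorrelationResult(r=1.0, p_value=0.0, n=0)
        for j, cell in enumerate(row[1:]):
            if not cell.strip():
                continue
            r_str, p_str = cell.replace(")", "").split("(")
            res = CorrelationResult(r=float(r_str), p_value=float(p_str), n=0)
            matrix[i][j] = res
            matrix[j][i] = res
    return names, matrix


def format_matrix(
    names: list[str], matrix: list[list[CorrelationResult | None]]
) -> str:
    """Render a matrix as TSV with 'r (p)' cells (NA for undefined pairs)."""
    lines = ["\t" + "\t".join(names)]
    for i, name in enumerate(names):
        cells = []
        for j in range(len(names)):
            res = matrix[i][j]
            if res is None:
                cells.append("NA")
            elif i == j:
                cells.append("1")
            else:
                cells.append(f"{res.r:.3f} ({res.p_value:.4g})")
        lines.append(name + "\t" + "\t".join(cells))
    return "\n".join(lines) + "\n"
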