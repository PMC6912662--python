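"""Symbolic recurrence matrices, line structures and SRQA measures.

Two m-histories are *symbolic recurrent* when they share the same ordinal
pattern.  The n x n symbolic recurrence matrix stores, for each pair (t, s),
the shared symbol index, or a sentinel when the symbols differ; the classical
indicator matrices SR and SR(pi) are recovered as ``cell != SENTINEL`` and
``cell == pi`` respectively, and SR decomposes exactly as the cell-wise sum of
the SR(pi).

From the matrix we quantify:

* the global symbolic recurrence rate ``SRR = (1/n^2) sum_{t,s} SR_ts`` and
  its per-symbol decomposition ``SRR(pi)``;
* diagonal lines (repeated symbol subsequences, main diagonal excluded) and
  the determinism ``D = sum_l l n(l) / (n^2 SRR)``;
* vertical lines per monotone symbol (persistence of a single pattern), with
  trapping time (mean vertical length), the fraction of that symbol's
  recurrence mass on vertical lines, and Shannon entropies (nats) of the line
  length distributions.

For embedding dimension m only the strictly increasing and strictly
decreasing patterns can repeat at consecutive time points, so vertical lines
exist only for those two symbols.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal

import numpy as np

from .symbolic import Symbol, SymbolSequence

__all__ = [
    "SENTINEL",
    "SymbolicRecurrenceMatrix",
    "LineDistribution",
    "SRQAMeasures",
    "recurrence_matrix",
    "global_srr",
    "symbol_srr",
    "diagonal_lines",
    "vertical_lines",
    "determinism",
    "trapping_time",
    "line_entropy",
    "rline_vertical",
    "compute_measures",
    "srp_plot_data",
]

#: cell value marking "no recurrence"; outside the valid symbol range [0, m!-1]
SENTINEL: int = -1


@dataclass(frozen=True)
class SymbolicRecurrenceMatrix:
    """Symbol-coded recurrence structure of a symbol sequence.

    ``cell[t, s]`` holds the shared symbol index when the histories at t and
    s recur, else :data:`SENTINEL`.  Symmetric, with a sentinel-free main
    diagonal (every state recurs with itself).
    """

    cell: np.ndarray
    m: int

    @property
    def n(self) -> int:
        return self.cell.shape[0]

    @property
    def recurrent(self) -> np.ndarray:
        """Boolean SR indicator matrix."""
        return self.cell != SENTINEL


@dataclass
class LineDistribution:
    """Histogram of maximal line lengths (>= min length) in the matrix.

    ``lengths`` maps line length to count.  Diagonal distributions are
    global (symbols may vary along a run); vertical distributions are scoped
    to one symbol.
    """

    kind: Literal["diagonal", "vertical"]
    lengths: dict[int, int] = field(default_factory=dict)
    symbol_scope: Symbol | None = None

    @property
    def total_points(self) -> int:
        """Recurrence points on lines: sum of length x count."""
        return sum(l * c for l, c in self.lengths.items())

    @property
    def total_lines(self) -> int:
        return sum(self.lengths.values())

    def __bool__(self) -> bool:
        return bool(self.lengths)


@dataclass(frozen=True)
class SRQAMeasures:
    """All symbolic recurrence measures of one window."""

    n: int
    m: int
    srr: float
    srr_by_symbol: np.ndarray
    determinism_d: float
    ent_d: float
    vbar: dict[int, float]  # symbol index -> trapping time
    rline_v: dict[int, float]  # symbol index -> vertical-line mass fraction
    ent_v: dict[int, float]  # symbol index -> vertical length entropy


def _run_lengths(mask: np.ndarray) -> np.ndarray:
    """Lengths of maximal runs of True in a 1-D boolean array."""
    if mask.size == 0:
        return np.empty(0, dtype=np.int64)
    padded = np.concatenate(([False], mask, [False]))
    d = np.diff(padded.astype(np.int8))
    starts = np.flatnonzero(d == 1)
    ends = np.flatnonzero(d == -1)
    return ends - starts


def recurrence_matrix(symbols: SymbolSequence) -> SymbolicRecurrenceMatrix:
    """Build the n x n symbol-coded recurrence matrix of a symbol sequence."""
    if symbols.n < 1:
        raise ValueError("cannot build a recurrence matrix from an empty sequence")
    idx = symbols.indices
    eq = idx[:, None] == idx[None, :]
    cell = np.where(eq, idx[:, None], SENTINEL)
    return SymbolicRecurrenceMatrix(cell=cell, m=symbols.m)


def global_srr(M: SymbolicRecurrenceMatrix) -> float:
    """Global symbolic recurrence rate, main diagonal included."""
    return float(M.recurrent.sum()) / M.n**2


def symbol_srr(M: SymbolicRecurrenceMatrix, pi: Symbol | int) -> float:
    """Recurrence rate to one symbol; sums over symbols to :func:`global_srr`."""
    k = pi.index if isinstance(pi, Symbol) else int(pi)
    return float((M.cell == k).sum()) / M.n**2


def diagonal_lines(M: SymbolicRecurrenceMatrix, min_len: int = 2) -> LineDistribution:
    """Distribution of maximal diagonal runs of recurrent cells.

    The main diagonal is excluded; both triangles are scanned (the matrix is
    symmetric, so each structure is counted twice, consistent with the
    full-matrix normalisation of determinism).  Symbols may vary along a run.
    """
    rec = M.recurrent
    dist = LineDistribution(kind="diagonal")
    for offset in range(1, M.n):
        for diag in (np.diagonal(rec, offset), np.diagonal(rec, -offset)):
            for length in _run_lengths(np.asarray(diag)):
                if length >= min_len:
                    dist.lengths[int(length)] = dist.lengths.get(int(length), 0) + 1
    return dist


def vertical_lines(
    M: SymbolicRecurrenceMatrix, delta: Symbol | int, min_len: int = 2
) -> LineDistribution:
    """Distribution of maximal vertical runs of cells recurrent to ``delta``.

    Main-diagonal cells participate in runs: the cell (t, t) carries the
    symbol of history t, and a vertical line expresses that one ordinal
    pattern persists in time.
    """
    scope = delta if isinstance(delta, Symbol) else Symbol.from_index(int(delta), M.m)
    k = scope.index
    dist = LineDistribution(kind="vertical", symbol_scope=scope)
    hit = M.cell == k
    for s in range(M.n):
        for length in _run_lengths(hit[:, s]):
            if length >= min_len:
                dist.lengths[int(length)] = dist.lengths.get(int(length), 0) + 1
    return dist


def determinism(diag: LineDistribution, srr: float, n: int) -> float:
    """Fraction of recurrence mass lying on diagonal lines (main diagonal
    excluded from the numerator)."""
    if srr <= 0:
        raise ValueError("determinism undefined for srr = 0")
    return diag.total_points / (n**2 * srr)


def trapping_time(vert: LineDistribution) -> float:
    """Mean vertical line length; 0 for an empty distribution."""
    if not vert.lengths:
        return 0.0
    return vert.total_points / vert.total_lines


def line_entropy(dist: LineDistribution) -> float:
    """Shannon entropy (nats) of the line length distribution; 0 if empty."""
    total = dist.total_lines
    if total == 0:
        return 0.0
    p = np.array(list(dist.lengths.values()), dtype=float) / total
    return float(-(p * np.log(p)).sum()) + 0.0


def rline_vertical(vert: LineDistribution, srr_delta: float, n: int) -> float:
    """Fraction of a symbol's recurrence mass lying on vertical lines.

    Defined as ``sum_l l n(l) / (n^2 SRR(delta))``, mirroring determinism;
    0 by convention when the symbol never recurs.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if srr_delta <= 0:
        return 0.0
    return vert.total_points / (n**2 * srr_delta)


def compute_measures(window_symbols: SymbolSequence) -> SRQAMeasures:
    """Compute every SRQA measure of a window's symbol sequence.

    Vertical measures are computed for the two monotone symbols (the
    strictly increasing pattern, index 0, and the strictly decreasing
    pattern, index m!-1), the only ones that can form vertical lines.
    """
    if window_symbols.n < 2:
        raise ValueError("need at least 2 symbols to compute recurrence measures")
    M = recurrence_matrix(window_symbols)
    n, m = M.n, M.m
    mf = math.factorial(m)
    srr = global_srr(M)
    srr_by_symbol = np.array([symbol_srr(M, k) for k in range(mf)])
    diag = diagonal_lines(M)
    det = determinism(diag, srr, n)
    ent_d = line_entropy(diag)
    vbar: dict[int, float] = {}
    rline: dict[int, float] = {}
    ent_v: dict[int, float] = {}
    for k in (0, mf - 1):  # increasing, decreasing
        vert = vertical_lines(M, k)
        vbar[k] = trapping_time(vert)
        rline[k] = rline_vertical(vert, float(srr_by_symbol[k]), n)
        ent_v[k] = line_entropy(vert)
    return SRQAMeasures(
        n=n,
        m=m,
        srr=srr,
        srr_by_symbol=srr_by_symbol,
        determinism_d=det,
        ent_d=ent_d,
        vbar=vbar,
        rline_v=rline,
        ent_v=ent_v,
    )


def srp_plot_data(M: SymbolicRecurrenceMatrix) -> np.ndarray:
    """Points of the symbolic recurrence plot.

    Returns an array of rows ``(t, s, symbol_index)`` for every recurrent
    cell, with 1-based coordinates matching the t = 1..n convention of the
    plots; the set is symmetric under (t, s) -> (s, t).
    """
    t, s = np.nonzero(M.recurrent)
    return np.column_stack([t + 1, s + 1, M.cell[t, s]])
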