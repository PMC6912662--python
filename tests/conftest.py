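"""Shared fixtures and independent brute-force oracles.

The oracles re-derive recurrence structure by direct cell-by-cell scans,
independently of the library's vectorized implementations, so the two can
be checked against each other on random inputs.
"""

from __future__ import annotations

import math

import numpy as np
import pytest
from hypothesis import settings

from srqa.symbolic import SymbolSequence, symbolize_window

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")

#: the seven-value demonstration series used throughout the docs
SERIES1 = [3, 9, 7, 6, 5, 10, 4]

#: its ordinal patterns for m=3, derived by hand from the sorting rule
SERIES1_SYMBOLS = [(0, 2, 1), (2, 1, 0), (2, 1, 0), (1, 0, 2), (2, 0, 1)]


@pytest.fixture
def series1_symbols() -> SymbolSequence:
    return symbolize_window(SERIES1, m=3)


def brute_force_matrix(indices: np.ndarray) -> np.ndarray:
    """O(n^2) double-loop recurrence indicator, True where symbols match."""
    n = len(indices)
    out = np.zeros((n, n), dtype=bool)
    for t in range(n):
        for s in range(n):
            out[t, s] = indices[t] == indices[s]
    return out


def brute_force_diagonal_lines(rec: np.ndarray, min_len: int = 2) -> dict[int, int]:
    """Count maximal diagonal runs of True, cell by cell, skipping the main
    diagonal, over both triangles."""
    n = rec.shape[0]
    counts: dict[int, int] = {}
    for offset in list(range(-(n - 1), 0)) + list(range(1, n)):
        cells = []
        for t in range(n):
            s = t + offset
            if 0 <= s < n:
                cells.append(rec[t, s])
        run = 0
        for val in cells + [False]:
            if val:
                run += 1
            else:
                if run >= min_len:
                    counts[run] = counts.get(run, 0) + 1
                run = 0
    return counts


def brute_force_vertical_lines(
    cell: np.ndarray, symbol: int, min_len: int = 2
) -> dict[int, int]:
    """Count maximal vertical runs of cells equal to ``symbol``, column by
    column, main-diagonal cells included."""
    n = cell.shape[0]
    counts: dict[int, int] = {}
    for s in range(n):
        run = 0
        for t in range(n + 1):
            hit = t < n and cell[t, s] == symbol
            if hit:
                run += 1
            else:
                if run >= min_len:
                    counts[run] = counts.get(run, 0) + 1
                run = 0
    return counts


def random_symbol_sequence(
    rng: np.random.Generator, n: int, m: int = 3
) -> SymbolSequence:
    return SymbolSequence(indices=rng.integers(0, math.factorial(m), n), m=m)
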