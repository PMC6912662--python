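"""Ordinal-pattern symbolization of real-valued time series.

A window of ``m`` consecutive values (an *m-history*) is mapped to the
permutation of ``{0, ..., m-1}`` that sorts it: the symbol ``(i1, ..., im)``
satisfies ``x[i1] <= x[i2] <= ... <= x[im]``, with ties broken in favour of
the smaller offset so that the symbol is unique.  Symbols are elements of the
symmetric group S_m and are indexed lexicographically, e.g. for ``m = 3``::

    (0,1,2)=0  (0,2,1)=1  (1,0,2)=2  (1,2,0)=3  (2,0,1)=4  (2,1,0)=5

Because the map depends only on the rank order of the values it is invariant
under any strictly increasing transform of the series.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import permutations
from typing import Iterable, Sequence

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "Symbol",
    "SymbolSequence",
    "all_symbols",
    "symbol_index",
    "symbolize_history",
    "symbolize_window",
    "max_embedding_dimension",
]


@dataclass(frozen=True)
class Symbol:
    """An ordinal pattern: a permutation of ``{0, ..., m-1}``.

    ``index`` is the rank of the permutation in lexicographic order over all
    ``m!`` permutations.
    """

    permutation: tuple[int, ...]

    def __post_init__(self) -> None:
        m = len(self.permutation)
        if sorted(self.permutation) != list(range(m)):
            raise ValueError(
                f"permutation {self.permutation!r} is not a bijection on 0..{m - 1}"
            )

    @property
    def m(self) -> int:
        return len(self.permutation)

    @property
    def index(self) -> int:
        return symbol_index(self.permutation)

    @classmethod
    def from_index(cls, index: int, m: int) -> "Symbol":
        if not 0 <= index < math.factorial(m):
            raise ValueError(f"index {index} out of range for m={m}")
        # decode Lehmer code
        avail = list(range(m))
        perm = []
        for k in range(m - 1, 0, -1):
            f = math.factorial(k)
            perm.append(avail.pop(index // f))
            index %= f
        perm.append(avail[0])
        return cls(tuple(perm))

    @property
    def is_monotone(self) -> bool:
        """True for the strictly increasing or strictly decreasing pattern.

        These are the only patterns that can occur at two consecutive time
        points of a series, hence the only ones producing vertical lines in a
        symbolic recurrence plot.
        """
        p = self.permutation
        return p == tuple(range(self.m)) or p == tuple(range(self.m - 1, -1, -1))

    def __str__(self) -> str:  # e.g. "(1,0,2)"
        return "(" + ",".join(map(str, self.permutation)) + ")"


def symbol_index(perm: Sequence[int]) -> int:
    """Lexicographic rank of a permutation of ``{0..m-1}`` (Lehmer code)."""
    m = len(perm)
    rank = 0
    for i, p in enumerate(perm):
        smaller_right = sum(1 for q in perm[i + 1 :] if q < p)
        rank += smaller_right * math.factorial(m - 1 - i)
    return rank


def all_symbols(m: int) -> list[Symbol]:
    """All ``m!`` symbols in lexicographic (index) order."""
    return [Symbol(p) for p in permutations(range(m))]


@dataclass(frozen=True)
class SymbolSequence:
    """The symbol of every m-history of a window, in temporal order.

    ``indices[t]`` is the lexicographic index of the symbol of the history
    starting at (0-based) position ``t``; the sequence has ``n = T - m + 1``
    entries for a window of length ``T``.
    """

    indices: np.ndarray
    m: int

    def __post_init__(self) -> None:
        object.__setattr__(self, "indices", np.asarray(self.indices, dtype=np.int64))
        if self.indices.ndim != 1:
            raise ValueError("indices must be one-dimensional")
        mf = math.factorial(self.m)
        if self.indices.size and not (
            (self.indices >= 0).all() and (self.indices < mf).all()
        ):
            raise ValueError(f"symbol indices must lie in [0, {mf - 1}]")

    @property
    def n(self) -> int:
        return int(self.indices.size)

    @property
    def symbols(self) -> list[Symbol]:
        return [Symbol.from_index(int(i), self.m) for i in self.indices]

    def __len__(self) -> int:
        return self.n


def symbolize_history(values: Iterable[float]) -> Symbol:
    """Map one m-history to its unique ordinal pattern.

    The returned permutation ``(i1, ..., im)`` lists the offsets in ascending
    order of value; equal values are ordered by ascending offset (stable
    sort), which is exactly the uniqueness rule.

    >>> symbolize_history((6, 5, 10)).permutation
    (1, 0, 2)
    """
    arr = np.asarray(list(values), dtype=float)
    if arr.ndim != 1 or arr.size < 2:
        raise ValueError("an m-history needs at least 2 values")
    return Symbol(tuple(int(i) for i in np.argsort(arr, kind="stable")))


def symbolize_window(window: Iterable[float], m: int = 3) -> SymbolSequence:
    """Symbolize every m-history of a window of length ``T >= m``.

    Returns the sequence of ``n = T - m + 1`` symbols in temporal order.
    """
    arr = np.asarray(list(window), dtype=float)
    if m < 2:
        raise ValueError("embedding dimension m must be >= 2")
    if arr.ndim != 1 or arr.size < m:
        raise ValueError(f"window of length {arr.size} is shorter than m={m}")
    histories = sliding_window_view(arr, m)
    perms = np.argsort(histories, axis=1, kind="stable")
    # vectorized Lehmer rank: sum over positions of (#smaller entries to the
    # right) * (m-1-i)!
    n = perms.shape[0]
    rank = np.zeros(n, dtype=np.int64)
    for i in range(m - 1):
        smaller = (perms[:, i + 1 :] < perms[:, i : i + 1]).sum(axis=1)
        rank += smaller * math.factorial(m - 1 - i)
    return SymbolSequence(indices=rank, m=m)


def max_embedding_dimension(w: int) -> int:
    """Largest admissible embedding dimension for a window of ``w`` values.

    Requires every one of the ``m!`` symbols to have expected frequency at
    least 5 under independence, i.e. ``5 * m! <= w``; e.g. ``w = 30`` admits
    at most ``m = 3``.
    """
    if w < 2:
        raise ValueError("window length must be >= 2")
    m = 1
    while 5 * math.factorial(m + 1) <= w:
        m += 1
    return m
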