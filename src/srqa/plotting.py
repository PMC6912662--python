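"""Rendering of symbolic recurrence plots."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from .recurrence import SymbolicRecurrenceMatrix, srp_plot_data
from .symbolic import all_symbols

# one distinguishable colour per symbol, in lexicographic symbol order;
# increasing pattern black and decreasing red, as is conventional for SRPs
_COLORS = ["black", "tab:blue", "tab:green", "tab:orange", "tab:purple", "red"]


def plot_srp(
    M: SymbolicRecurrenceMatrix,
    ax: "plt.Axes | None" = None,
    point_size: float = 6.0,
) -> "plt.Axes":
    """Scatter the recurrent cells of ``M``, coloured by symbol.

    Axes are the 1-based time indices of the two m-histories; the legend
    lists the symbols in lexicographic order.
    """
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 5))
    pts = srp_plot_data(M)
    symbols = all_symbols(M.m)
    for k, sym in enumerate(symbols):
        sel = pts[pts[:, 2] == k]
        if sel.size:
            color = _COLORS[k % len(_COLORS)]
            ax.scatter(sel[:, 0], sel[:, 1], s=point_size, color=color, label=str(sym))
    ax.set_xlabel("t")
    ax.set_ylabel("s")
    ax.set_xlim(0.5, M.n + 0.5)
    ax.set_ylim(0.5, M.n + 0.5)
    ax.set_aspect("equal")
    ax.legend(fontsize="x-small", loc="upper right")
    return ax


def save_srp(M: SymbolicRecurrenceMatrix, path: str | Path) -> None:
    ax = plot_srp(M)
    ax.figure.savefig(path, dpi=150, bbox_inches="tight")
    plt.close(ax.figure)
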