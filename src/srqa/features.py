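"""Windowing of RR records and assembly of the per-window covariate vector.

A beat-annotated RR record is cut into consecutive, non-overlapping windows
of a fixed number of beats (30, 60, 120 or 200 by default).  A window is
labelled AF when strictly more than half of its beats carry the AF rhythm
annotation; any other rhythm (normal sinus, flutter, junctional, ...) counts
toward non-AF.

Each window yields 18 covariates: the per-symbol recurrence rates SRR(pi)
for the 6 ordinal patterns of length 3, determinism D and the diagonal line
entropy, the vertical-line mass fraction, vertical entropy and trapping time
for the increasing and decreasing patterns, and four distributional summaries
of the raw RR intervals — mean, median, coefficient of variation
CV = sd/mean, and the coefficient of variation of the median
VMe = sum_i |RR_i - Me(RR)| / sum_i RR_i.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .recurrence import compute_measures
from .symbolic import Symbol, all_symbols, max_embedding_dimension, symbolize_window

__all__ = [
    "AF",
    "NON_AF",
    "RRRecord",
    "WindowSpec",
    "LabeledWindow",
    "feature_columns",
    "FEATURE_COLUMNS",
    "ALL_COLUMNS",
    "make_windows",
    "rr_statistics",
    "extract_features",
    "build_dataset",
]

logger = logging.getLogger(__name__)

AF = "AF"
NON_AF = "nonAF"

#: per-beat rhythm vocabulary
RHYTHMS = ("AF", "N", "OTHER")


@dataclass
class RRRecord:
    """A beat-indexed RR interval series with per-beat rhythm labels."""

    record_id: str
    rr_ms: np.ndarray
    beat_rhythm: np.ndarray

    def __post_init__(self) -> None:
        self.rr_ms = np.asarray(self.rr_ms, dtype=float)
        self.beat_rhythm = np.asarray(self.beat_rhythm, dtype=object)
        if self.rr_ms.shape != self.beat_rhythm.shape:
            raise ValueError("rr_ms and beat_rhythm must have equal length")
        if self.rr_ms.size and not (self.rr_ms > 0).all():
            raise ValueError("all RR intervals must be positive")
        bad = set(self.beat_rhythm) - set(RHYTHMS)
        if bad:
            raise ValueError(f"unknown rhythm labels: {sorted(bad)}")

    def __len__(self) -> int:
        return int(self.rr_ms.size)


@dataclass(frozen=True)
class WindowSpec:
    """Windowing configuration: ``w`` beats per window, embedding dimension
    ``m`` (windows are consecutive and non-overlapping, stride = w)."""

    w: int = 60
    m: int = 3
    allow_small_window: bool = False

    def __post_init__(self) -> None:
        if self.m < 2:
            raise ValueError("embedding dimension m must be >= 2")
        if self.w < self.m + 1:
            raise ValueError(f"window size w={self.w} too small for m={self.m}")
        if not self.allow_small_window and max_embedding_dimension(self.w) < self.m:
            raise ValueError(
                f"w={self.w} does not admit m={self.m}: symbol frequencies need "
                f"5*m! = {5 * math.factorial(self.m)} <= w "
                "(pass allow_small_window=True to override)"
            )


@dataclass(frozen=True)
class LabeledWindow:
    rr_ms: np.ndarray
    label: str  # AF | nonAF
    record_id: str
    window_idx: int  # 0-based position within the record


def feature_columns(m: int = 3) -> list[str]:
    """Canonical covariate column names, in fixed order."""
    srr_names = [
        "srr_" + "".join(map(str, s.permutation)) for s in all_symbols(m)
    ]
    return srr_names + [
        "det_d",
        "ent_d",
        "rline_v_inc",
        "rline_v_dec",
        "ent_v_inc",
        "ent_v_dec",
        "vbar_inc",
        "vbar_dec",
        "rr_mean",
        "rr_median",
        "cv",
        "vme",
    ]


FEATURE_COLUMNS: list[str] = feature_columns(3)
ALL_COLUMNS: list[str] = FEATURE_COLUMNS + ["label", "record_id", "window_idx"]


def make_windows(record: RRRecord, spec: WindowSpec) -> list[LabeledWindow]:
    """Cut a record into consecutive w-beat windows with majority AF labels.

    The trailing remainder (< w beats) is dropped.  A window is AF iff
    strictly more than w/2 of its beats are annotated AF.
    """
    w = spec.w
    count = len(record) // w
    if count == 0:
        logger.warning(
            "record %s has %d beats, shorter than one window of %d; no windows",
            record.record_id,
            len(record),
            w,
        )
        return []
    out = []
    for i in range(count):
        sl = slice(i * w, (i + 1) * w)
        n_af = int((record.beat_rhythm[sl] == "AF").sum())
        label = AF if n_af * 2 > w else NON_AF
        out.append(
            LabeledWindow(
                rr_ms=record.rr_ms[sl].copy(),
                label=label,
                record_id=record.record_id,
                window_idx=i,
            )
        )
    return out


def rr_statistics(rr: Sequence[float] | np.ndarray) -> tuple[float, float, float, float]:
    """Mean, median, CV and VMe of an RR interval sequence.

    CV uses the sample (n-1) standard deviation.  VMe is the sum of absolute
    deviations from the median divided by the sum of the intervals; both are
    scale-invariant dispersion measures.
    """
    arr = np.asarray(rr, dtype=float)
    if arr.size < 2:
        raise ValueError("need at least 2 RR intervals")
    if not (arr > 0).all():
        raise ValueError("RR intervals must be positive")
    mean = float(arr.mean())
    median = float(np.median(arr))
    cv = float(arr.std(ddof=1) / mean)
    vme = float(np.abs(arr - median).sum() / arr.sum())
    return mean, median, cv, vme


def extract_features(window: LabeledWindow, spec: WindowSpec) -> dict:
    """The full covariate vector of one labeled window, as a flat dict."""
    m = spec.m
    seq = symbolize_window(window.rr_ms, m=m)
    meas = compute_measures(seq)
    mean, median, cv, vme = rr_statistics(window.rr_ms)
    inc, dec = 0, math.factorial(m) - 1
    row: dict = {}
    for k, sym in enumerate(all_symbols(m)):
        row["srr_" + "".join(map(str, sym.permutation))] = float(meas.srr_by_symbol[k])
    row.update(
        det_d=meas.determinism_d,
        ent_d=meas.ent_d,
        rline_v_inc=meas.rline_v[inc],
        rline_v_dec=meas.rline_v[dec],
        ent_v_inc=meas.ent_v[inc],
        ent_v_dec=meas.ent_v[dec],
        vbar_inc=meas.vbar[inc],
        vbar_dec=meas.vbar[dec],
        rr_mean=mean,
        rr_median=median,
        cv=cv,
        vme=vme,
        label=window.label,
        record_id=window.record_id,
        window_idx=window.window_idx,
    )
    return row


def build_dataset(records: Iterable[RRRecord], spec: WindowSpec) -> pd.DataFrame:
    """Row-per-window feature table over one or more records.

    Rows are ordered by record order, then window index.  Raises if no
    record yields a single complete window.
    """
    rows = []
    for record in records:
        for window in make_windows(record, spec):
            rows.append(extract_features(window, spec))
    if not rows:
        raise ValueError("no windows could be produced from the given records")
    cols = feature_columns(spec.m) + ["label", "record_id", "window_idx"]
    return pd.DataFrame(rows, columns=cols)
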