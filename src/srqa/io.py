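"""Reading and writing RR records, feature tables, and PhysioNet import.

The canonical RR record file is a TSV with a required header line
``beat_index\trr_ms\trhythm`` and one row per beat: a 1-based strictly
consecutive beat index, a positive RR interval in milliseconds, and a rhythm
label (AF, N or OTHER).  Lines starting with ``#`` are comments.  The format
stores RR intervals rather than beat timestamps because the analysis
consumes RR directly; adapters difference timestamps once at import.

The PhysioNet MIT-BIH Atrial Fibrillation Database adapter converts WFDB
beat annotations and rhythm-change annotations ("(AFIB", "(N", ...) into a
canonical record: RR intervals are successive beat-time differences, and
each beat is labelled by the rhythm regime in force at its time.  Reading
WFDB files needs the optional ``wfdb`` package; the conversion logic itself
(`rr_from_beat_annotations`) is pure and dependency-free.
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .features import RHYTHMS, RRRecord

__all__ = [
    "read_rr_record",
    "write_rr_record",
    "read_feature_table",
    "write_feature_table",
    "rr_from_beat_annotations",
    "import_physionet_afdb",
]

_HEADER = ("beat_index", "rr_ms", "rhythm")


class RRParseError(ValueError):
    """Malformed RR record file; message names the offending line."""


def write_rr_record(record: RRRecord, path: str | Path) -> None:
    lines = ["\t".join(_HEADER)]
    for i, (rr, rhythm) in enumerate(zip(record.rr_ms, record.beat_rhythm), start=1):
        lines.append(f"{i}\t{rr:.6g}\t{rhythm}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_rr_record(path: str | Path, record_id: str | None = None) -> RRRecord:
    """Parse a canonical RR record file, validating every row.

    Accepts LF or CRLF line endings; raises :class:`RRParseError` naming the
    1-based line number of the first malformed row.
    """
    path = Path(path)
    rr: list[float] = []
    rhythm: list[str] = []
    header_seen = False
    expected_index = 1
    for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t")
        if not header_seen:
            if tuple(f.strip() for f in fields) != _HEADER:
                raise RRParseError(
                    f"{path}: line {lineno}: expected header "
                    f"'{chr(9).join(_HEADER)}', got {line!r}"
                )
            header_seen = True
            continue
        if len(fields) != 3:
            raise RRParseError(f"{path}: line {lineno}: expected 3 fields, got {len(fields)}")
        try:
            idx = int(fields[0])
            val = float(fields[1])
        except ValueError as exc:
            raise RRParseError(f"{path}: line {lineno}: {exc}") from None
        if idx != expected_index:
            raise RRParseError(
                f"{path}: line {lineno}: beat_index {idx}, expected {expected_index}"
            )
        if val <= 0:
            raise RRParseError(f"{path}: line {lineno}: rr_ms must be positive, got {val}")
        lab = fields[2].strip()
        if lab not in RHYTHMS:
            raise RRParseError(
                f"{path}: line {lineno}: rhythm {lab!r} not in {RHYTHMS}"
            )
        rr.append(val)
        rhythm.append(lab)
        expected_index += 1
    if not header_seen:
        raise RRParseError(f"{path}: missing header line")
    return RRRecord(
        record_id=record_id or path.stem,
        rr_ms=np.array(rr, dtype=float),
        beat_rhythm=np.array(rhythm, dtype=object),
    )


def write_feature_table(table: pd.DataFrame, path: str | Path) -> None:
    """Feature CSV: UTF-8, '.' decimal separator, full float precision."""
    table.to_csv(path, index=False, encoding="utf-8")


def read_feature_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, encoding="utf-8")


#: WFDB aux rhythm strings mapped to the canonical vocabulary
_RHYTHM_MAP = {"(AFIB": "AF", "(N": "N"}


def rr_from_beat_annotations(
    beat_times_s: Sequence[float],
    rhythm_changes: Sequence[tuple[float, str]],
    record_id: str = "imported",
) -> RRRecord:
    """Convert beat times + rhythm-change annotations into an RR record.

    ``beat_times_s`` are QRS annotation times in seconds; RR intervals are
    their successive differences in milliseconds.  ``rhythm_changes`` is a
    list of ``(time_s, aux_string)`` marking the onset of a rhythm regime
    ("(AFIB" -> AF, "(N" -> N, anything else -> OTHER).  Each RR interval is
    labelled by the regime in force at the time of its closing beat; beats
    before the first rhythm annotation are OTHER.
    """
    times = np.asarray(beat_times_s, dtype=float)
    if times.size < 2:
        raise ValueError("need at least 2 beat annotations to form an RR interval")
    if not (np.diff(times) > 0).all():
        raise ValueError("beat times must be strictly increasing")
    rr = np.diff(times) * 1000.0
    changes = sorted(rhythm_changes, key=lambda c: c[0])
    change_times = np.array([c[0] for c in changes], dtype=float)
    change_labels = ["OTHER"] + [_RHYTHM_MAP.get(c[1], "OTHER") for c in changes]
    regime = np.searchsorted(change_times, times[1:], side="right")
    labels = np.array([change_labels[r] for r in regime], dtype=object)
    return RRRecord(record_id=record_id, rr_ms=rr, beat_rhythm=labels)


def import_physionet_afdb(record_path: str | Path) -> RRRecord:
    """Read a local WFDB AFDB record (``.qrs`` beats, ``.atr`` rhythms).

    This input is optional and external: it requires the ``wfdb`` package
    (``pip install srqa[physionet]``) and a locally downloaded record.
    """
    try:
        import wfdb  # noqa: PLC0415 — optional dependency
    except ImportError as exc:
        raise ImportError(
            "reading PhysioNet records requires the optional 'wfdb' package "
            "(install with: pip install srqa[physionet]); this input is "
            "optional — the canonical TSV format and the synthetic generators "
            "need no download"
        ) from exc
    record_path = Path(record_path)
    base = str(record_path)
    try:
        qrs = wfdb.rdann(base, "qrs")
        atr = wfdb.rdann(base, "atr")
    except FileNotFoundError as exc:
        raise FileNotFoundError(
            f"WFDB annotation files for {base!r} not found; this external "
            "input is optional — download the record from PhysioNet first"
        ) from exc
    fs = float(qrs.fs)
    beat_times = np.asarray(qrs.sample, dtype=float) / fs
    changes = [
        (float(s) / fs, aux.rstrip("\x00"))
        for s, aux in zip(atr.sample, atr.aux_note)
        if aux and aux.startswith("(")
    ]
    return rr_from_beat_annotations(beat_times, changes, record_id=record_path.stem)
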