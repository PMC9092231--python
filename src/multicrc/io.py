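"""Readers and writers for the CRC data dialects.

CSV dialects (comma- or tab-delimited, auto-detected):

* capture-history tables: header ``e1,...,ek,count``, one row per history;
  writers always emit the full ``2**k - 1`` rows in lexicographic pattern
  order (the analysis requires explicit zeros, never missing cells);
* individual records: header ``e1,...,ek``, one 0/1 row per individual;
* event-count tables: header ``event,pattern,count`` where ``pattern`` is the
  prior-receipt pattern over events ``1..j-1`` (empty for event 1).

Each type also round-trips through a JSON mirror.
"""

from __future__ import annotations

import csv
import io as _io
import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .tables import (
    CaptureHistoryTable,
    EventCountTable,
    IndividualRecords,
    ValidationError,
    pattern_str,
    validate_history_table,
)

__all__ = [
    "read_history_csv",
    "write_history_csv",
    "read_individuals_csv",
    "read_event_counts_csv",
    "write_event_counts_csv",
    "history_to_json",
    "history_from_json",
    "event_counts_to_json",
    "event_counts_from_json",
    "read_table_auto",
]


def _read_delimited(path_or_buf) -> pd.DataFrame:
    """Read a comma- or tab-delimited file with a header row."""
    try:
        return pd.read_csv(path_or_buf, sep=None, engine="python", dtype=str,
                           skipinitialspace=True)
    except (pd.errors.ParserError, pd.errors.EmptyDataError, UnicodeDecodeError) as exc:
        raise ValidationError(f"could not parse delimited input: {exc}") from exc


def _event_columns(columns: Sequence[str]) -> list[str]:
    cols = [c for c in columns if c.strip().lower() != "count"]
    if len(cols) < 2:
        raise ValidationError(
            f"expected at least 2 event columns, found {list(columns)}"
        )
    return cols


def read_history_csv(path_or_buf) -> CaptureHistoryTable:
    df = _read_delimited(path_or_buf)
    if "count" not in [c.strip().lower() for c in df.columns]:
        raise ValidationError("capture-history CSV needs a 'count' column")
    count_col = next(c for c in df.columns if c.strip().lower() == "count")
    event_cols = _event_columns(df.columns)
    rows = [
        (tuple(r[c] for c in event_cols), r[count_col]) for _, r in df.iterrows()
    ]
    return validate_history_table(rows, k=len(event_cols),
                                  event_names=tuple(event_cols))


def write_history_csv(t: CaptureHistoryTable, path) -> None:
    pats = sorted(t.patterns)  # lexicographic
    lookup = t.as_dict()
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow([f"e{j+1}" for j in range(t.k)] + ["count"])
        for p in pats:
            w.writerow(list(p) + [lookup[pattern_str(p)]])


def read_individuals_csv(path_or_buf) -> IndividualRecords:
    df = _read_delimited(path_or_buf)
    event_cols = _event_columns(df.columns)
    try:
        rows = df[event_cols].astype(np.int64).to_numpy()
    except ValueError as exc:
        raise ValidationError(f"individual records must be 0/1: {exc}") from exc
    return IndividualRecords(k=len(event_cols), rows=rows)


def read_event_counts_csv(path_or_buf) -> EventCountTable:
    df = _read_delimited(path_or_buf)
    need = {"event", "pattern", "count"}
    cols = {c.strip().lower(): c for c in df.columns}
    if not need <= set(cols):
        raise ValidationError(
            "event-count CSV needs columns event,pattern,count; got "
            + ",".join(df.columns)
        )
    records: dict[int, dict[str, str]] = {}
    for _, r in df.iterrows():
        j = int(r[cols["event"]])
        pat = r[cols["pattern"]]
        pat = "" if (pat is None or (isinstance(pat, float) and np.isnan(pat))) else str(pat).strip()
        records.setdefault(j, {})[pat] = r[cols["count"]]
    k = max(records) if records else 0
    if sorted(records) != list(range(1, k + 1)):
        raise ValidationError("event-count CSV must cover events 1..k")
    return EventCountTable(k=k, cells=tuple(records[j] for j in range(1, k + 1)))


def write_event_counts_csv(ec: EventCountTable, path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["event", "pattern", "count"])
        for j, cell in enumerate(ec.cells, start=1):
            for pat in sorted(cell):
                w.writerow([j, pat, cell[pat]])


def history_to_json(t: CaptureHistoryTable) -> dict:
    return {
        "type": "capture_history",
        "k": t.k,
        "event_names": list(t.event_names),
        "counts": {pattern_str(p): int(c) for p, c in sorted(zip(t.patterns, t.counts))},
        "warnings": list(t.warnings),
    }


def history_from_json(obj: dict) -> CaptureHistoryTable:
    t = CaptureHistoryTable.from_counts(obj["counts"], k=int(obj["k"]))
    names = tuple(obj.get("event_names") or ())
    if names:
        t = CaptureHistoryTable(k=t.k, counts=t.counts, event_names=names)
    return t


def event_counts_to_json(ec: EventCountTable) -> dict:
    return {
        "type": "event_counts",
        "k": ec.k,
        "events": [dict(sorted(c.items())) for c in ec.cells],
    }


def event_counts_from_json(obj: dict) -> EventCountTable:
    return EventCountTable(k=int(obj["k"]), cells=tuple(obj["events"]))


def read_table_auto(path, input_format: str = "history") -> CaptureHistoryTable:
    """Read any supported dialect and return a capture-history table.

    ``input_format`` is one of ``history``, ``individual``, ``eventcount``.
    ``.json`` files use the JSON mirrors, anything else the CSV dialects.
    """
    from .tables import aggregate_individuals, convert_event_counts

    path = Path(path)
    if path.suffix.lower() == ".json":
        obj = json.loads(path.read_text())
        if input_format == "history" or obj.get("type") == "capture_history":
            return history_from_json(obj)
        if input_format == "eventcount" or obj.get("type") == "event_counts":
            return convert_event_counts(event_counts_from_json(obj))
        raise ValidationError(f"unsupported JSON payload for {input_format!r}")
    if input_format == "history":
        return read_history_csv(path)
    if input_format == "individual":
        return aggregate_individuals(read_individuals_csv(path))
    if input_format == "eventcount":
        return convert_event_counts(read_event_counts_csv(path))
    raise ValidationError(f"unknown input format {input_format!r}")
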