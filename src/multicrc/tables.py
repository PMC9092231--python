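"""Core data model for multi-source capture-recapture (CRC) data.

A CRC study with ``k`` encounter events classifies every observed individual
by a *capture history*: a length-``k`` binary vector whose j-th entry records
whether the individual was encountered at event j.  The all-zero history is
unobservable (those individuals were never seen), so a study exposes exactly
``2**k - 1`` observable histories.  Three input dialects are supported:

* capture-history tables — one count per observable history,
* individual records — one 0/1 row per observed individual,
* event-count tables — the aggregate field format in which each event's
  count is cross-tabulated only by receipt of the *previous* events'
  identifiers (event j has ``2**(j-1)`` cells).

The event-count format arises when no identifying information is collected:
at event j field teams tally people by which of the earlier events' unique
objects they hold.  It contains exactly the same ``2**k - 1`` numbers as a
history table, aggregated differently; :func:`convert_event_counts` inverts
the aggregation exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "CaptureHistoryTable",
    "EventCountTable",
    "IndividualRecords",
    "Descriptives",
    "ValidationError",
    "observable_patterns",
    "validate_history_table",
    "aggregate_individuals",
    "convert_event_counts",
    "event_counts_from_histories",
    "descriptive_stats",
]


class ValidationError(ValueError):
    """Raised when CRC input data violate the data-model invariants."""


Pattern = tuple[int, ...]


def _as_pattern(p, k: int | None = None) -> Pattern:
    """Coerce a history given as '101', (1,0,1) or [1,0,1] to a tuple of ints."""
    if isinstance(p, str):
        p = p.strip()
        if not set(p) <= {"0", "1"}:
            raise ValidationError(f"pattern {p!r} is not a binary string")
        pat = tuple(int(c) for c in p)
    else:
        try:
            pat = tuple(int(v) for v in p)
        except (TypeError, ValueError) as exc:
            raise ValidationError(f"pattern {p!r} is not a binary vector") from exc
        if not set(pat) <= {0, 1}:
            raise ValidationError(f"pattern {pat!r} has entries outside {{0,1}}")
    if k is not None and len(pat) != k:
        raise ValidationError(
            f"pattern {''.join(map(str, pat))!r} has length {len(pat)}, expected {k}"
        )
    return pat


def pattern_str(p: Pattern) -> str:
    return "".join(str(int(v)) for v in p)


def observable_patterns(k: int) -> list[Pattern]:
    """The 2**k - 1 observable histories, in canonical order.

    Canonical order sorts by number of captures, then by the history read as
    a binary number, descending — for k=3: 100, 010, 001, 110, 101, 011, 111.
    Event 1 is the leftmost position.
    """
    if k < 2:
        raise ValidationError(f"need at least 2 encounter events, got k={k}")
    pats = [p for p in product((0, 1), repeat=k) if any(p)]
    pats.sort(key=lambda p: (sum(p), -int(pattern_str(p), 2)))
    return pats


def _int_count(value, where: str) -> int:
    """Parse a count, rejecting floats and negatives (counts of people)."""
    if isinstance(value, bool):
        raise ValidationError(f"{where}: count {value!r} is not an integer")
    if isinstance(value, float) or isinstance(value, np.floating):
        if float(value) != int(value):
            raise ValidationError(f"{where}: count {value!r} is not an integer")
        raise ValidationError(
            f"{where}: count {value!r} given as a float; counts must be integers"
        )
    try:
        n = int(value)
    except (TypeError, ValueError) as exc:
        raise ValidationError(f"{where}: count {value!r} is not an integer") from exc
    if isinstance(value, str) and ("." in value or "e" in value.lower()):
        raise ValidationError(f"{where}: count {value!r} is not an integer")
    if n < 0:
        raise ValidationError(f"{where}: negative count {n}")
    return n


@dataclass(frozen=True)
class CaptureHistoryTable:
    """Counts over the ``2**k - 1`` observable capture histories.

    ``counts[i]`` corresponds to ``observable_patterns(k)[i]``.  ``warnings``
    records validation notes (zero-filled patterns, consistency flags).
    """

    k: int
    counts: np.ndarray
    event_names: tuple[str, ...] = ()
    warnings: tuple[str, ...] = ()

    def __post_init__(self):
        pats = observable_patterns(self.k)
        counts = np.asarray(self.counts, dtype=np.int64)
        if counts.shape != (len(pats),):
            raise ValidationError(
                f"expected {len(pats)} counts for k={self.k}, got shape {counts.shape}"
            )
        if (counts < 0).any():
            raise ValidationError("capture history counts must be nonnegative")
        object.__setattr__(self, "counts", counts)
        if not self.event_names:
            object.__setattr__(
                self, "event_names", tuple(f"event{j+1}" for j in range(self.k))
            )
        elif len(self.event_names) != self.k:
            raise ValidationError("need one event name per event")

    @property
    def patterns(self) -> list[Pattern]:
        return observable_patterns(self.k)

    @property
    def n(self) -> int:
        """Total number of distinct observed individuals."""
        return int(self.counts.sum())

    def count_of(self, pattern) -> int:
        pat = _as_pattern(pattern, self.k)
        if not any(pat):
            raise ValidationError("the all-zero history is unobservable")
        return int(self.counts[self.patterns.index(pat)])

    def as_dict(self) -> dict[str, int]:
        return {pattern_str(p): int(c) for p, c in zip(self.patterns, self.counts)}

    @classmethod
    def from_counts(cls, counts: Mapping, k: int, **kw) -> "CaptureHistoryTable":
        """Build a table from a {pattern: count} mapping; missing cells are 0."""
        pats = observable_patterns(k)
        arr = np.zeros(len(pats), dtype=np.int64)
        for raw, c in counts.items():
            pat = _as_pattern(raw, k)
            if not any(pat):
                raise ValidationError(
                    "history of all zeros supplied: the never-captured cell is "
                    "unobservable and must not appear"
                )
            arr[pats.index(pat)] = _int_count(c, f"history {pattern_str(pat)}")
        return cls(k=k, counts=arr, **kw)

    def marginal_pair(self, a: int, b: int) -> tuple[int, int, int]:
        """Collapse to two events (0-based indices): (n_a, n_b, overlap m)."""
        pats = np.array(self.patterns)
        n_a = int(self.counts[pats[:, a] == 1].sum())
        n_b = int(self.counts[pats[:, b] == 1].sum())
        m = int(self.counts[(pats[:, a] == 1) & (pats[:, b] == 1)].sum())
        return n_a, n_b, m


@dataclass(frozen=True)
class EventCountTable:
    """Aggregate field format: per-event counts by prior-identifier receipt.

    ``cells[j]`` (0-based event index) maps each prior-receipt pattern — a
    binary string over events ``1..j`` (the empty string for event 1) — to a
    count.  Event j+1 has exactly ``2**j`` cells; in total ``2**k - 1``.
    """

    k: int
    cells: tuple[dict[str, int], ...]

    def __post_init__(self):
        if self.k < 2:
            raise ValidationError(f"need at least 2 encounter events, got k={self.k}")
        if len(self.cells) != self.k:
            raise ValidationError(f"need one cell map per event ({self.k})")
        norm = []
        for j, cell in enumerate(self.cells):
            want = {"".join(bits) for bits in product("01", repeat=j)}
            got = {str(s) for s in cell}
            if got != want:
                raise ValidationError(
                    f"event {j+1} must have exactly the {2**j} prior-receipt "
                    f"patterns of length {j}; got {sorted(got)}"
                )
            norm.append(
                {s: _int_count(cell[s], f"event {j+1}, prior pattern {s!r}") for s in sorted(cell)}
            )
        object.__setattr__(self, "cells", tuple(norm))

    @property
    def event_totals(self) -> list[int]:
        return [sum(c.values()) for c in self.cells]

    @classmethod
    def from_nested(cls, cells: Sequence[Mapping[str, int]]) -> "EventCountTable":
        return cls(k=len(cells), cells=tuple(dict(c) for c in cells))


@dataclass(frozen=True)
class IndividualRecords:
    """One binary capture vector per observed individual."""

    k: int
    rows: np.ndarray

    def __post_init__(self):
        rows = np.asarray(self.rows, dtype=np.int64)
        if rows.size == 0:
            rows = rows.reshape(0, self.k)
        if rows.ndim != 2 or rows.shape[1] != self.k:
            raise ValidationError(f"rows must be an (n, {self.k}) array")
        if not np.isin(rows, (0, 1)).all():
            raise ValidationError("individual records must contain only 0/1 entries")
        if rows.shape[0] and (rows.sum(axis=1) == 0).any():
            bad = int(np.flatnonzero(rows.sum(axis=1) == 0)[0])
            raise ValidationError(
                f"row {bad} is all zeros: never-captured individuals are unobservable"
            )
        object.__setattr__(self, "rows", rows)


@dataclass(frozen=True)
class Descriptives:
    """Summary statistics of a capture-history table.

    f_i counts individuals captured exactly i times; u_j counts those first
    captured at event j; fi_series pairs (i, log f_i - log C(k, i)) — roughly
    linear except under time-by-heterogeneity structure — and ui_series pairs
    (j, u_j), linear under uniform capture and concave down under individual
    heterogeneity.
    """

    n: int
    n_j: tuple[int, ...]
    f_i: tuple[int, ...]
    u_j: tuple[int, ...]
    fi_series: tuple[tuple[int, float], ...]
    ui_series: tuple[tuple[int, int], ...]


def validate_history_table(rows: Iterable, k: int, event_names=()) -> CaptureHistoryTable:
    """Validate raw (pattern, count) records into a :class:`CaptureHistoryTable`.

    Missing observable patterns are filled with an explicit 0 and listed in
    the table's warnings (analysis requires all ``2**k - 1`` cells; observed
    zeros are fine, missing values are not).  Duplicate patterns, the
    all-zero pattern, negative or fractional counts are rejected.
    """
    pats = observable_patterns(k)
    seen: dict[Pattern, int] = {}
    for i, (raw_pat, raw_count) in enumerate(rows):
        pat = _as_pattern(raw_pat, k)
        if not any(pat):
            raise ValidationError(
                f"row {i}: the all-zero history is the unobserved cell and must "
                "not appear in the data"
            )
        if pat in seen:
            raise ValidationError(
                f"row {i}: duplicate pattern {pattern_str(pat)}"
            )
        seen[pat] = _int_count(raw_count, f"row {i} ({pattern_str(pat)})")
    warnings = []
    missing = [pattern_str(p) for p in pats if p not in seen]
    if missing:
        warnings.append(
            "missing observable patterns filled with 0: " + ", ".join(missing)
        )
    counts = np.array([seen.get(p, 0) for p in pats], dtype=np.int64)
    return CaptureHistoryTable(
        k=k, counts=counts, event_names=tuple(event_names), warnings=tuple(warnings)
    )


def aggregate_individuals(records: IndividualRecords) -> CaptureHistoryTable:
    """Tabulate individual capture vectors into a capture-history table."""
    pats = observable_patterns(records.k)
    index = {p: i for i, p in enumerate(pats)}
    counts = np.zeros(len(pats), dtype=np.int64)
    for row in records.rows:
        counts[index[tuple(int(v) for v in row)]] += 1
    warnings = ()
    if records.rows.shape[0] == 0:
        warnings = ("no individual records supplied; table is all zeros",)
    return CaptureHistoryTable(k=records.k, counts=counts, warnings=warnings)


def convert_event_counts(ec: EventCountTable) -> CaptureHistoryTable:
    """Exactly invert the event-count aggregation into capture histories.

    Processes events j = k..1 (backward recursion).  The cell recorded at
    event j for prior-receipt pattern S determines the history with captures
    at exactly S and j, once the already-resolved histories that extend it
    with later captures are subtracted:

        count(S + 1 + 0...0) = ec_j(S) - sum over resolved histories with
                               prefix (S, 1) and at least one later capture.

    A negative derived count means the recorded event counts are mutually
    inconsistent (a recording error, or identifier loss between rounds).
    """
    k = ec.k
    resolved: dict[Pattern, int] = {}
    for j in range(k, 0, -1):
        for s_str, c in ec.cells[j - 1].items():
            prefix = tuple(int(ch) for ch in s_str) + (1,)
            later = sum(
                cnt
                for pat, cnt in resolved.items()
                if pat[:j] == prefix and any(pat[j:])
            )
            value = c - later
            if value < 0:
                raise ValidationError(
                    f"inconsistent event counts: event {j}, prior pattern "
                    f"{s_str or '(none)'} implies a negative count "
                    f"({c} recorded, {later} already accounted for by later "
                    "captures); check for recording errors or identifier loss"
                )
            resolved[prefix + (0,) * (k - j)] = value
    table = CaptureHistoryTable.from_counts(
        {p: c for p, c in resolved.items()}, k=k
    )
    # sum of per-event samples must weakly exceed the distinct-individual total
    if sum(ec.event_totals) < table.n:
        table = CaptureHistoryTable(
            k=k,
            counts=table.counts,
            warnings=table.warnings
            + ("sum of per-event samples is smaller than the number of distinct individuals",),
        )
    return table


def event_counts_from_histories(t: CaptureHistoryTable) -> EventCountTable:
    """Aggregate a history table into the event-count field format."""
    cells: list[dict[str, int]] = []
    for j in range(1, t.k + 1):
        cell = {
            "".join(bits): 0 for bits in product("01", repeat=j - 1)
        }
        for pat, c in zip(t.patterns, t.counts):
            if pat[j - 1] == 1:
                cell[pattern_str(pat[: j - 1])] += int(c)
        cells.append(cell)
    return EventCountTable(k=t.k, cells=tuple(cells))


def descriptive_stats(t: CaptureHistoryTable) -> Descriptives:
    """Per-event totals, capture-frequency and first-capture distributions."""
    if t.n == 0:
        raise ValidationError("empty table: no observed individuals to describe")
    pats = np.array(t.patterns)
    n_j = tuple(int(t.counts[pats[:, j] == 1].sum()) for j in range(t.k))
    caps = pats.sum(axis=1)
    f_i = tuple(int(t.counts[caps == i].sum()) for i in range(1, t.k + 1))
    first = np.argmax(pats, axis=1)  # leftmost 1
    u_j = tuple(int(t.counts[first == j].sum()) for j in range(t.k))
    from math import comb, log

    fi_series = tuple(
        (i, log(f) - log(comb(t.k, i))) for i, f in enumerate(f_i, start=1) if f > 0
    )
    ui_series = tuple((j + 1, u) for j, u in enumerate(u_j))
    return Descriptives(
        n=t.n, n_j=n_j, f_i=f_i, u_j=u_j, fi_series=fi_series, ui_series=ui_series
    )
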