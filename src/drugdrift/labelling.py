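"""Repurposing-event labelling from relation streams and release tables.

Two label sources are supported, mirroring how repurposing evidence is
dated in practice:

* a *stream* of dated subject-predicate-object triples (drug TREATS
  condition, dated by the source publication), where an event is the first
  appearance of a new condition for a drug that already has an established
  use; and
* a sequence of dated *release tables* of curated may_treat / may_prevent
  pairs, where an event is a pair present in a release but in no earlier
  release, for a drug already listed before.

Events are mapped onto an embedding snapshot schedule by rounding the
event date up to the earliest snapshot at or after it, so that a training
window ending at that snapshot ends at (not after) the publication.
"""

from __future__ import annotations

import bisect
import dataclasses
import datetime as _dt
import re
from collections.abc import Iterable, Sequence

import numpy as np

from .embeddings import SnapshotSchedule

__all__ = [
    "RelationTriple",
    "ReleaseTable",
    "RepurposingEvent",
    "LabelSeries",
    "normalize_drug_name",
    "events_from_stream",
    "events_from_releases",
    "map_event_to_snapshot",
    "build_label_series",
]

STREAM_PREDICATES = frozenset({"TREATS", "PREVENTS", "AFFECTS"})
DEFAULT_EVENT_PREDICATES = frozenset({"TREATS", "PREVENTS"})
RELEASE_RELATIONS = frozenset({"may_treat", "may_prevent"})

# Dosage tokens stripped during name normalization: pure numbers and units.
_NUMBER_RE = re.compile(r"^\d+(\.\d+)?$")
_UNIT_TOKENS = frozenset({"ml", "mg", "g", "mcg", "ug", "µg", "l", "iu", "%", "mg/ml"})


@dataclasses.dataclass(frozen=True)
class RelationTriple:
    """One dated subject-predicate-object assertion extracted from a document."""

    document_id: str
    date: _dt.date
    predicate: str
    subject: str
    object: str

    def __post_init__(self) -> None:
        if self.predicate not in STREAM_PREDICATES:
            raise ValueError(
                f"unknown predicate {self.predicate!r}; expected one of {sorted(STREAM_PREDICATES)}"
            )
        if not self.subject or not self.object:
            raise ValueError("triple subject and object names must be non-empty")


@dataclasses.dataclass(frozen=True)
class ReleaseTable:
    """One dated release of curated (drug, relation, condition) pairs."""

    date: _dt.date
    pairs: frozenset[tuple[str, str, str]]  # (drug, relation-kind, condition)

    def __post_init__(self) -> None:
        for _, rela, _ in self.pairs:
            if rela not in RELEASE_RELATIONS:
                raise ValueError(f"unknown relation kind {rela!r}")


@dataclasses.dataclass(frozen=True)
class RepurposingEvent:
    """First appearance of a new drug-condition relation, with its dated source."""

    drug: str
    condition: str
    date: _dt.date
    source: str  # "release-diff" | "stream"


@dataclasses.dataclass(frozen=True)
class LabelSeries:
    """Per-snapshot binary labels for one drug, aligned to a schedule."""

    drug: str
    labels: tuple[int, ...]

    def __post_init__(self) -> None:
        if any(v not in (0, 1) for v in self.labels):
            raise ValueError("labels must be binary")

    def __len__(self) -> int:
        return len(self.labels)

    def as_array(self) -> np.ndarray:
        return np.asarray(self.labels, dtype=np.int8)


def normalize_drug_name(raw: str) -> str:
    """Reduce a drug name to base form by stripping dosage tokens.

    Lowercases, removes tokens that are pure numbers or units (ml, mg, g,
    mcg, ug, µg, l, iu, %, mg/ml) wherever they occur, and collapses
    whitespace.  Idempotent: normalizing a normalized name is a no-op.

    >>> normalize_drug_name("0.05 ml ranibizumab")
    'ranibizumab'
    """
    if not raw or not raw.strip():
        raise ValueError("cannot normalize an empty name")
    kept = [
        tok
        for tok in raw.lower().split()
        if tok not in _UNIT_TOKENS and not _NUMBER_RE.match(tok)
    ]
    result = " ".join(kept)
    if not result:
        raise ValueError(f"name {raw!r} is all dosage tokens; nothing left after stripping")
    return result


def events_from_stream(
    triples: Iterable[RelationTriple],
    predicates: frozenset[str] | set[str] = DEFAULT_EVENT_PREDICATES,
) -> list[RepurposingEvent]:
    """Detect repurposing events from a dated triple stream.

    Triples are filtered to ``predicates``, names normalized, and the
    stream sorted by date.  For each drug, the condition(s) carried by its
    earliest-dated triple(s) form the baseline (a drug's debut use is not
    an event); every later first-seen (drug, condition) pair yields one
    event dated at that triple's publication date.
    """
    rows: list[tuple[_dt.date, str, str]] = []
    for t in triples:
        if t.predicate not in predicates:
            continue
        rows.append((t.date, normalize_drug_name(t.subject), normalize_drug_name(t.object)))
    rows.sort()

    first_date: dict[str, _dt.date] = {}
    for date, drug, _ in rows:
        first_date.setdefault(drug, date)

    seen: set[tuple[str, str]] = set()
    events: list[RepurposingEvent] = []
    for date, drug, condition in rows:
        if (drug, condition) in seen:
            continue
        seen.add((drug, condition))
        if date > first_date[drug]:
            events.append(RepurposingEvent(drug, condition, date, source="stream"))
    events.sort(key=lambda e: (e.date, e.drug, e.condition))
    return events


def events_from_releases(
    releases: Sequence[ReleaseTable],
    relation_kinds: frozenset[str] | set[str] = RELEASE_RELATIONS,
) -> list[RepurposingEvent]:
    """Detect repurposing events by diffing consecutive release tables.

    The first release is the baseline.  In every later release, each
    (drug, condition) pair absent from all earlier releases — for a drug
    that was already present earlier — becomes one event dated at that
    release's date.  Drugs debuting in a later release establish their
    baseline there without an event.
    """
    dates = [r.date for r in releases]
    if len(set(dates)) != len(dates):
        raise ValueError("release dates must be unique")
    if dates != sorted(dates):
        raise ValueError("releases must be sorted by date")

    seen_pairs: set[tuple[str, str]] = set()
    seen_drugs: set[str] = set()
    events: list[RepurposingEvent] = []
    for i, release in enumerate(releases):
        pairs = {
            (normalize_drug_name(d), normalize_drug_name(c))
            for d, rela, c in release.pairs
            if rela in relation_kinds
        }
        if i > 0:
            for drug, condition in sorted(pairs - seen_pairs):
                if drug in seen_drugs:
                    events.append(
                        RepurposingEvent(drug, condition, release.date, source="release-diff")
                    )
        seen_pairs |= pairs
        seen_drugs |= {d for d, _ in pairs}
    events.sort(key=lambda e: (e.date, e.drug, e.condition))
    return events


def map_event_to_snapshot(event_date: _dt.date, schedule: SnapshotSchedule) -> int | None:
    """Index of the earliest snapshot dated on/after ``event_date``; None if past the end."""
    idx = bisect.bisect_left(schedule.snapshot_dates, event_date)
    return idx if idx < len(schedule) else None


def build_label_series(
    drug: str,
    events: Sequence[RepurposingEvent],
    schedule: SnapshotSchedule,
) -> LabelSeries:
    """Binary per-snapshot label series: 1 where some event maps, else 0."""
    labels = [0] * len(schedule)
    for event in events:
        if event.drug != drug:
            raise ValueError(f"event for {event.drug!r} passed to series for {drug!r}")
        idx = map_event_to_snapshot(event.date, schedule)
        if idx is not None:
            labels[idx] = 1
    return LabelSeries(drug=drug, labels=tuple(labels))
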