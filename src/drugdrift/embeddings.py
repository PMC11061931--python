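"""Temporal word embeddings: one continuous model, snapshotted on a schedule.

The corpus is consumed in a single chronological pass.  Documents falling
between consecutive snapshot dates form a *chunk*; after training on a
chunk the current vectors are copied out as that date's snapshot.  Because
the same model is trained throughout, snapshots live in a common vector
space and no post-hoc alignment (Procrustes etc.) is needed to compare a
word's vectors across time.

A word enters a snapshot once its cumulative corpus frequency reaches the
configured minimum; once qualified it never drops out, so snapshot
vocabularies grow monotonically.
"""

from __future__ import annotations

import dataclasses
import datetime as _dt
import json
import pathlib
import warnings
from collections.abc import Iterable, Mapping, Sequence

import numpy as np
from sklearn.base import BaseEstimator

from .dates import add_months, months_between, parse_date
from .sgns import IncrementalSGNS

__all__ = [
    "SnapshotSchedule",
    "EmbeddingConfig",
    "EmbeddingSnapshot",
    "EmbeddingStore",
    "DriftSeries",
    "TemporalWordEmbedding",
    "build_snapshot_schedule",
    "train_temporal_embeddings",
    "restrict_to_lexicon",
    "cosine_similarity",
    "drift_series",
    "nearest_neighbours",
    "save_store",
    "load_store",
]


@dataclasses.dataclass(frozen=True)
class SnapshotSchedule:
    """Snapshot dates on a regular month grid after an excluded start date."""

    start_date: _dt.date
    snapshot_dates: tuple[_dt.date, ...]
    interval_months: int

    def __post_init__(self) -> None:
        if self.interval_months < 1:
            raise ValueError("interval_months must be >= 1")
        for i, d in enumerate(self.snapshot_dates):
            expected = add_months(self.start_date, (i + 1) * self.interval_months)
            if d != expected:
                raise ValueError(
                    f"snapshot {i} is {d}, expected {expected} "
                    f"(start {self.start_date} + {(i + 1) * self.interval_months} months)"
                )

    def __len__(self) -> int:
        return len(self.snapshot_dates)

    def index_of(self, date: _dt.date) -> int:
        return self.snapshot_dates.index(date)

    def subsample(self, step: int) -> "SnapshotSchedule":
        """Every ``step``-th snapshot (e.g. 6-monthly labels on a bi-monthly grid)."""
        if step < 1:
            raise ValueError("step must be >= 1")
        return SnapshotSchedule(
            start_date=self.start_date,
            snapshot_dates=self.snapshot_dates[step - 1 :: step],
            interval_months=self.interval_months * step,
        )


@dataclasses.dataclass(frozen=True)
class EmbeddingConfig:
    """Hyperparameters of the incremental skip-gram trainer.

    Defaults follow the common literature-scale setting: context window 5,
    minimum cumulative frequency 50, 5 epochs per chunk, 50-dimensional
    vectors.
    """

    context_window: int = 5
    min_frequency: int = 50
    epochs_per_chunk: int = 5
    dimension: int = 50
    seed: int = 0
    negative: int = 5
    alpha: float = 0.025
    min_alpha: float = 1e-4

    def __post_init__(self) -> None:
        for name in ("context_window", "min_frequency", "epochs_per_chunk", "dimension", "negative"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")


class EmbeddingSnapshot:
    """Frozen word → vector mapping at one schedule date."""

    def __init__(self, index: int, date: _dt.date, words: Sequence[str], matrix: np.ndarray):
        matrix = np.asarray(matrix, dtype=np.float32)
        if matrix.ndim != 2 or matrix.shape[0] != len(words):
            raise ValueError("matrix must be (n_words, dimension)")
        self.index = index
        self.date = date
        self.words = tuple(words)
        self.matrix = matrix
        self._pos = {w: i for i, w in enumerate(self.words)}

    def __contains__(self, word: str) -> bool:
        return word in self._pos

    def __len__(self) -> int:
        return len(self.words)

    @property
    def dimension(self) -> int:
        return self.matrix.shape[1]

    def vector(self, word: str) -> np.ndarray:
        try:
            return self.matrix[self._pos[word]]
        except KeyError:
            raise KeyError(f"word {word!r} not present in snapshot {self.index} ({self.date})")

    def vocabulary(self) -> frozenset[str]:
        return frozenset(self.words)


@dataclasses.dataclass
class EmbeddingStore:
    """A schedule-aligned time series of embedding snapshots."""

    schedule: SnapshotSchedule
    config: EmbeddingConfig
    snapshots: list[EmbeddingSnapshot]

    def __post_init__(self) -> None:
        if len(self.snapshots) != len(self.schedule):
            raise ValueError("one snapshot per schedule date required")
        for i, (snap, date) in enumerate(zip(self.snapshots, self.schedule.snapshot_dates)):
            if snap.index != i or snap.date != date:
                raise ValueError(f"snapshot {i} misaligned with schedule date {date}")

    def __len__(self) -> int:
        return len(self.snapshots)

    def vector(self, word: str, snapshot_index: int) -> np.ndarray:
        return self.snapshots[snapshot_index].vector(word)

    def presence(self, word: str) -> np.ndarray:
        """Boolean mask over snapshots: where is the word's vector available?"""
        return np.array([word in snap for snap in self.snapshots], dtype=bool)


@dataclasses.dataclass(frozen=True)
class DriftSeries:
    """Cosine similarity of one word's vectors to a fixed reference snapshot.

    A declining series is the *inceptive drift* signal: the word's context
    is moving away from what it was at the reference date.  Entries are NaN
    where the word had not yet qualified.
    """

    word: str
    reference_index: int
    values: np.ndarray  # float, NaN where absent

    def present(self) -> np.ndarray:
        return ~np.isnan(self.values)


def build_snapshot_schedule(
    start_date: str | _dt.date, end_date: str | _dt.date, interval_months: int
) -> SnapshotSchedule:
    """Snapshot dates ``start + k*interval`` for k = 1, 2, ... while <= end.

    The start date itself is not a snapshot; the last snapshot equals the
    end date exactly when the span is a whole multiple of the interval.
    Month-end starts produce month-end snapshots.
    """
    start = parse_date(start_date)
    end = parse_date(end_date)
    if end < start:
        raise ValueError(f"end_date {end} precedes start_date {start}")
    if interval_months < 1:
        raise ValueError("interval_months must be >= 1")
    n = months_between(start, end) // interval_months
    dates = tuple(add_months(start, k * interval_months) for k in range(1, n + 1))
    return SnapshotSchedule(start_date=start, snapshot_dates=dates, interval_months=interval_months)


def _record_fields(doc) -> tuple[str, _dt.date, list[str]]:
    """Accept corpus records as objects, mappings, or (id, date, text) tuples."""
    if isinstance(doc, Mapping):
        ident, date, text = doc["id"], doc["date"], doc["text"]
    elif hasattr(doc, "date") and hasattr(doc, "tokens"):
        return doc.id, doc.date, list(doc.tokens)
    else:
        ident, date, text = doc
    tokens = text.split() if isinstance(text, str) else list(text)
    return ident, parse_date(date), tokens


class TemporalWordEmbedding(BaseEstimator):
    """Estimator that learns an :class:`EmbeddingStore` from a dated corpus.

    Parameters mirror :class:`EmbeddingConfig`; ``schedule`` fixes the
    snapshot dates.  After :meth:`fit`, the trained time series is in
    ``store_`` and the live skip-gram model in ``model_``.
    """

    def __init__(
        self,
        schedule: SnapshotSchedule | None = None,
        context_window: int = 5,
        min_frequency: int = 50,
        epochs_per_chunk: int = 5,
        dimension: int = 50,
        seed: int = 0,
        negative: int = 5,
        alpha: float = 0.025,
        min_alpha: float = 1e-4,
    ) -> None:
        self.schedule = schedule
        self.context_window = context_window
        self.min_frequency = min_frequency
        self.epochs_per_chunk = epochs_per_chunk
        self.dimension = dimension
        self.seed = seed
        self.negative = negative
        self.alpha = alpha
        self.min_alpha = min_alpha

    def _config(self) -> EmbeddingConfig:
        return EmbeddingConfig(
            context_window=self.context_window,
            min_frequency=self.min_frequency,
            epochs_per_chunk=self.epochs_per_chunk,
            dimension=self.dimension,
            seed=self.seed,
            negative=self.negative,
            alpha=self.alpha,
            min_alpha=self.min_alpha,
        )

    def fit(self, corpus: Iterable, y=None) -> "TemporalWordEmbedding":
        if self.schedule is None:
            raise ValueError("a SnapshotSchedule is required")
        schedule = self.schedule
        config = self._config()
        model = IncrementalSGNS(
            dimension=config.dimension,
            window=config.context_window,
            negative=config.negative,
            alpha=config.alpha,
            min_alpha=config.min_alpha,
            seed=config.seed,
        )
        snapshots: list[EmbeddingSnapshot] = []
        chunk: list[list[str]] = []
        k = 0  # next snapshot to emit
        prev_date: _dt.date | None = None
        prev_id: str | None = None

        def emit_snapshot() -> None:
            words = model.qualifying_words(config.min_frequency)
            matrix = (
                np.stack([model.vector(w) for w in words]).copy()
                if words
                else np.zeros((0, config.dimension), dtype=np.float32)
            )
            snapshots.append(
                EmbeddingSnapshot(len(snapshots), schedule.snapshot_dates[len(snapshots)], words, matrix)
            )

        for doc in corpus:
            ident, date, tokens = _record_fields(doc)
            if prev_date is not None and date < prev_date:
                raise ValueError(
                    f"corpus not sorted by date: record {ident!r} ({date}) "
                    f"follows {prev_id!r} ({prev_date})"
                )
            prev_date, prev_id = date, ident
            if date < schedule.start_date:
                raise ValueError(f"record {ident!r} dated {date} precedes corpus start")
            if not schedule.snapshot_dates or date > schedule.snapshot_dates[-1]:
                raise ValueError(f"record {ident!r} dated {date} falls after the last snapshot")
            while date > schedule.snapshot_dates[k]:
                model.train_chunk(chunk, config.epochs_per_chunk)
                chunk = []
                emit_snapshot()
                k += 1
            chunk.append(tokens)
        while k < len(schedule):
            model.train_chunk(chunk, config.epochs_per_chunk)
            chunk = []
            emit_snapshot()
            k += 1

        self.model_ = model
        self.store_ = EmbeddingStore(schedule=schedule, config=config, snapshots=snapshots)
        return self


def train_temporal_embeddings(
    corpus: Iterable, schedule: SnapshotSchedule, config: EmbeddingConfig | None = None
) -> EmbeddingStore:
    """One-call wrapper over :class:`TemporalWordEmbedding`."""
    config = config or EmbeddingConfig()
    est = TemporalWordEmbedding(schedule=schedule, **dataclasses.asdict(config))
    return est.fit(corpus).store_


def restrict_to_lexicon(store: EmbeddingStore, lexicon: Iterable[str]) -> EmbeddingStore:
    """Intersect every snapshot's vocabulary with ``lexicon`` (e.g. drugs only)."""
    lex = set(lexicon)
    snapshots = []
    for snap in store.snapshots:
        keep = [i for i, w in enumerate(snap.words) if w in lex]
        snapshots.append(
            EmbeddingSnapshot(
                snap.index,
                snap.date,
                [snap.words[i] for i in keep],
                snap.matrix[keep] if keep else np.zeros((0, snap.dimension), dtype=np.float32),
            )
        )
    if snapshots and all(len(s) == 0 for s in snapshots):
        warnings.warn("lexicon restriction produced empty snapshots", stacklevel=2)
    return EmbeddingStore(schedule=store.schedule, config=store.config, snapshots=snapshots)


def cosine_similarity(u: np.ndarray, v: np.ndarray) -> float:
    u = np.asarray(u, dtype=np.float64)
    v = np.asarray(v, dtype=np.float64)
    if u.shape != v.shape or u.ndim != 1:
        raise ValueError("vectors must be 1-D and of equal length")
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu == 0.0 or nv == 0.0:
        raise ValueError("cosine similarity undefined for a zero vector")
    return float(np.clip(np.dot(u, v) / (nu * nv), -1.0, 1.0))


def drift_series(store: EmbeddingStore, word: str, reference_index: int = 0) -> DriftSeries:
    """Cosine of each snapshot's vector for ``word`` against the reference snapshot."""
    if word not in store.snapshots[reference_index]:
        raise KeyError(f"word {word!r} absent at reference snapshot {reference_index}")
    ref = store.vector(word, reference_index)
    values = np.full(len(store), np.nan)
    for i, snap in enumerate(store.snapshots):
        if word in snap:
            values[i] = cosine_similarity(snap.vector(word), ref)
    values[reference_index] = 1.0  # cos(v, v) = 1 by definition
    return DriftSeries(word=word, reference_index=reference_index, values=values)


def nearest_neighbours(
    store: EmbeddingStore, word: str, snapshot_index: int, k: int
) -> list[tuple[str, float]]:
    """Top-k other words by cosine similarity at one snapshot, ties lexicographic."""
    snap = store.snapshots[snapshot_index]
    if word not in snap:
        raise KeyError(f"word {word!r} absent at snapshot {snapshot_index}")
    if k <= 0:
        return []
    q = snap.vector(word)
    scored = [
        (other, cosine_similarity(snap.vector(other), q)) for other in snap.words if other != word
    ]
    scored.sort(key=lambda t: (-t[1], t[0]))
    return scored[:k]


# -- persistence ------------------------------------------------------------

_MANIFEST = "manifest.json"


def _snapshot_filename(index: int, date: _dt.date) -> str:
    return f"snapshot_{index:04d}_{date.isoformat()}.txt"


def save_store(store: EmbeddingStore, path: str | pathlib.Path) -> None:
    """Write one word2vec-text file per snapshot plus a JSON manifest."""
    root = pathlib.Path(path)
    root.mkdir(parents=True, exist_ok=True)
    manifest = {
        "start_date": store.schedule.start_date.isoformat(),
        "interval_months": store.schedule.interval_months,
        "dates": [d.isoformat() for d in store.schedule.snapshot_dates],
        "config": dataclasses.asdict(store.config),
    }
    (root / _MANIFEST).write_text(json.dumps(manifest, indent=1) + "\n")
    for snap in store.snapshots:
        lines = [f"{len(snap)} {snap.dimension}"]
        for w, row in zip(snap.words, snap.matrix):
            lines.append(w + " " + " ".join(f"{x:.9g}" for x in row))
        (root / _snapshot_filename(snap.index, snap.date)).write_text("\n".join(lines) + "\n")


def load_store(path: str | pathlib.Path) -> EmbeddingStore:
    root = pathlib.Path(path)
    manifest = json.loads((root / _MANIFEST).read_text())
    config = EmbeddingConfig(**manifest["config"])
    schedule = SnapshotSchedule(
        start_date=parse_date(manifest["start_date"]),
        snapshot_dates=tuple(parse_date(d) for d in manifest["dates"]),
        interval_months=manifest["interval_months"],
    )
    snapshots = []
    for i, date in enumerate(schedule.snapshot_dates):
        fname = _snapshot_filename(i, date)
        text = (root / fname).read_text().splitlines()
        try:
            n, dim = (int(x) for x in text[0].split())
        except (IndexError, ValueError):
            raise ValueError(f"{fname}: line 1: malformed header, expected 'V D'")
        words, rows = [], []
        for ln, line in enumerate(text[1 : n + 1], start=2):
            parts = line.split()
            if len(parts) != dim + 1:
                raise ValueError(f"{fname}: line {ln}: expected word + {dim} floats")
            words.append(parts[0])
            rows.append(np.array(parts[1:], dtype=np.float32))
        if len(words) != n:
            raise ValueError(f"{fname}: header declares {n} words, found {len(words)}")
        matrix = np.stack(rows) if rows else np.zeros((0, dim), dtype=np.float32)
        snapshots.append(EmbeddingSnapshot(i, date, words, matrix))
    return EmbeddingStore(schedule=schedule, config=config, snapshots=snapshots)
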