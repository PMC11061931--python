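import datetime as dt

import numpy as np
import pytest

from drugdrift.embeddings import (
    EmbeddingConfig,
    EmbeddingSnapshot,
    EmbeddingStore,
    build_snapshot_schedule,
)
from drugdrift.synthetic import SyntheticConfig, generate_world


@pytest.fixture
def tiny_config():
    """A small but complete synthetic world: 12 drugs over 12 bi-monthly intervals."""
    return SyntheticConfig(
        n_drugs=12,
        n_conditions=4,
        vocab_background=30,
        event_rate=0.5,
        drift_magnitude=0.8,
        drift_lead=2,
        docs_per_interval=24,
        tokens_per_doc=11,
        publication_lag_months=2,
        start_date=dt.date(2000, 1, 31),
        end_date=dt.date(2002, 1, 31),
        interval_months=2,
        seed=7,
    )


@pytest.fixture
def tiny_world(tiny_config):
    return generate_world(tiny_config)


def make_store(vectors_by_word, start="2000-01-31", interval=2, min_frequency=1):
    """Build an EmbeddingStore from {word: [vec_at_t0, vec_at_t1, ...]}.

    A ``None`` entry marks the word as absent from that snapshot.
    """
    n_snap = max(len(v) for v in vectors_by_word.values())
    dim = len(next(vec for vecs in vectors_by_word.values() for vec in vecs if vec is not None))
    schedule = build_snapshot_schedule(start, _end_date(start, interval, n_snap), interval)
    snapshots = []
    for i, date in enumerate(schedule.snapshot_dates):
        words = [w for w, vecs in sorted(vectors_by_word.items())
                 if i < len(vecs) and vecs[i] is not None]
        matrix = (
            np.array([vectors_by_word[w][i] for w in words], dtype=np.float32)
            if words else np.zeros((0, dim), dtype=np.float32)
        )
        snapshots.append(EmbeddingSnapshot(i, date, words, matrix))
    config = EmbeddingConfig(dimension=dim, min_frequency=min_frequency)
    return EmbeddingStore(schedule=schedule, config=config, snapshots=snapshots)


def _end_date(start, interval, n_snap):
    from drugdrift.dates import add_months, parse_date

    return add_months(parse_date(start), interval * n_snap)
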