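import dataclasses
import datetime as dt

import numpy as np
import pytest

from drugdrift.embeddings import (
    EmbeddingConfig,
    build_snapshot_schedule,
    cosine_similarity,
    drift_series,
    load_store,
    nearest_neighbours,
    restrict_to_lexicon,
    save_store,
    train_temporal_embeddings,
)
from drugdrift.dates import months_between
from drugdrift.synthetic import generate_corpus, generate_world

from conftest import make_store


class TestSchedule:
    def test_month_enumeration(self):
        s = build_snapshot_schedule("2000-01-31", "2000-07-31", 2)
        assert [d.isoformat() for d in s.snapshot_dates] == [
            "2000-03-31", "2000-05-31", "2000-07-31",
        ]

    def test_empty_span_excludes_start(self):
        assert len(build_snapshot_schedule("2000-05-31", "2000-05-31", 2)) == 0

    def test_end_before_start_rejected(self):
        with pytest.raises(ValueError, match="precedes"):
            build_snapshot_schedule("2001-01-31", "2000-01-31", 2)

    @pytest.mark.parametrize("start,end,interval", [
        ("2000-01-31", "2010-01-31", 2),
        ("1999-02-28", "2003-07-28", 3),
        ("2000-01-15", "2001-02-10", 1),
    ])
    def test_count_closed_form(self, start, end, interval):
        s = build_snapshot_schedule(start, end, interval)
        expected = months_between(s.start_date, dt.date.fromisoformat(end[:10])
                                  if isinstance(end, str) else end) // interval
        assert len(s) == expected

    def test_subsample_semi_annual_from_bimonthly(self):
        s = build_snapshot_schedule("2000-01-31", "2002-01-31", 2)
        sub = s.subsample(3)
        assert sub.interval_months == 6
        assert [d.isoformat() for d in sub.snapshot_dates] == [
            "2000-07-31", "2001-01-31", "2001-07-31", "2002-01-31",
        ]


@pytest.fixture(scope="module")
def small_store_and_world():
    """A small trained store shared by the training-behaviour tests."""
    from drugdrift.synthetic import SyntheticConfig

    cfg = SyntheticConfig(
        n_drugs=10, n_conditions=4, vocab_background=20, event_rate=0.5,
        drift_magnitude=0.8, drift_lead=3, docs_per_interval=40, tokens_per_doc=9,
        start_date=dt.date(2000, 1, 31), end_date=dt.date(2001, 7, 31), seed=2,
    )
    world = generate_world(cfg)
    schedule = build_snapshot_schedule(cfg.start_date, cfg.end_date, 2)
    config = EmbeddingConfig(context_window=3, min_frequency=2, epochs_per_chunk=2,
                             dimension=16, seed=0)
    store = train_temporal_embeddings(generate_corpus(world, cfg), schedule, config)
    return store, world, cfg


class TestTraining:
    def test_unsorted_corpus_names_offending_record(self):
        schedule = build_snapshot_schedule("2000-01-31", "2000-05-31", 2)
        docs = [
            {"id": "a", "date": "2000-03-01", "text": "x y"},
            {"id": "b", "date": "2000-02-01", "text": "x y"},
        ]
        with pytest.raises(ValueError, match="'b'"):
            train_temporal_embeddings(docs, schedule, EmbeddingConfig(min_frequency=1))

    def test_empty_chunk_snapshot_identical_to_predecessor(self):
        schedule = build_snapshot_schedule("2000-01-31", "2000-07-31", 2)
        docs = [{"id": f"d{i}", "date": "2000-02-15", "text": "alpha beta gamma alpha"}
                for i in range(30)]
        store = train_temporal_embeddings(
            docs, schedule, EmbeddingConfig(context_window=2, min_frequency=2,
                                            epochs_per_chunk=1, dimension=8)
        )
        # chunks 2 and 3 are empty: vectors must be bitwise identical
        assert store.snapshots[1].words == store.snapshots[0].words
        np.testing.assert_array_equal(store.snapshots[1].matrix, store.snapshots[0].matrix)
        np.testing.assert_array_equal(store.snapshots[2].matrix, store.snapshots[0].matrix)

    def test_default_dimension_is_50(self):
        schedule = build_snapshot_schedule("2000-01-31", "2000-03-31", 2)
        docs = [{"id": f"d{i}", "date": "2000-02-15", "text": "aspirin patient"}
                for i in range(60)]
        store = train_temporal_embeddings(docs, schedule, EmbeddingConfig())
        assert store.vector("aspirin", 0).shape == (50,)

    def test_word_below_min_frequency_absent_everywhere(self):
        schedule = build_snapshot_schedule("2000-01-31", "2000-05-31", 2)
        docs = [{"id": "d0", "date": "2000-02-15", "text": "rare common common common"}]
        store = train_temporal_embeddings(
            docs, schedule, EmbeddingConfig(min_frequency=2, dimension=4)
        )
        for snap in store.snapshots:
            assert "rare" not in snap
        assert "common" in store.snapshots[0]

    def test_vocabulary_grows_monotonically(self, small_store_and_world):
        store, _, _ = small_store_and_world
        for a, b in zip(store.snapshots, store.snapshots[1:]):
            assert a.vocabulary() <= b.vocabulary()

    def test_determinism(self):
        schedule = build_snapshot_schedule("2000-01-31", "2000-05-31", 2)
        docs = [{"id": f"d{i}", "date": "2000-02-15", "text": "a b c d e a b"}
                for i in range(20)]
        cfg = EmbeddingConfig(context_window=2, min_frequency=1, dimension=8, seed=9)
        s1 = train_temporal_embeddings(docs, schedule, cfg)
        s2 = train_temporal_embeddings(docs, schedule, cfg)
        for a, b in zip(s1.snapshots, s2.snapshots):
            np.testing.assert_array_equal(a.matrix, b.matrix)


class TestLexicon:
    def test_empty_lexicon_empties_all_snapshots(self, small_store_and_world):
        store, _, _ = small_store_and_world
        with pytest.warns(UserWarning):
            out = restrict_to_lexicon(store, set())
        assert all(len(s) == 0 for s in out.snapshots)

    def test_intersection(self):
        store = make_store({
            "aspirin": [[1, 0]], "patient": [[0, 1]], "balaglitazone": [[1, 1]],
        })
        out = restrict_to_lexicon(store, {"aspirin", "balaglitazone"})
        assert set(out.snapshots[0].words) == {"aspirin", "balaglitazone"}

    def test_lexicon_word_never_qualifying_stays_absent(self, small_store_and_world):
        store, world, _ = small_store_and_world
        out = restrict_to_lexicon(store, set(world.drugs) | {"neverseen"})
        for snap in out.snapshots:
            assert "neverseen" not in snap


class TestCosine:
    def test_identity(self):
        v = np.array([0.3, -1.2, 0.5])
        assert cosine_similarity(v, v) == pytest.approx(1.0)

    def test_orthogonal(self):
        assert cosine_similarity([1, 0], [0, 1]) == pytest.approx(0.0)

    def test_closed_form(self):
        assert cosine_similarity([1, 1], [1, 0]) == pytest.approx(1 / np.sqrt(2))

    def test_zero_vector_rejected(self):
        with pytest.raises(ValueError, match="zero"):
            cosine_similarity([0, 0], [1, 0])

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            cosine_similarity([1, 0, 0], [1, 0])


class TestDrift:
    def test_hand_vectors(self):
        store = make_store({"w": [[1, 0], [0, 1]]})
        series = drift_series(store, "w", reference_index=0)
        np.testing.assert_allclose(series.values, [1.0, 0.0], atol=1e-7)

    def test_reference_value_is_exactly_one(self, small_store_and_world):
        store, world, _ = small_store_and_world
        word = world.drugs[0]
        series = drift_series(store, word, reference_index=0)
        assert series.values[0] == 1.0
        present = series.values[series.present()]
        assert np.all(present >= -1.0) and np.all(present <= 1.0)

    def test_absent_word_rejected(self, small_store_and_world):
        store, _, _ = small_store_and_world
        with pytest.raises(KeyError):
            drift_series(store, "nosuchword", 0)

    def test_event_drugs_drift_more_than_stable_drugs(self):
        """Contextual drift shows up as declining self-similarity for event drugs."""
        from drugdrift.synthetic import SyntheticConfig

        cfg = SyntheticConfig(
            n_drugs=20, n_conditions=6, vocab_background=40, event_rate=0.5,
            drift_magnitude=0.8, drift_lead=4, docs_per_interval=200, tokens_per_doc=11,
            start_date=dt.date(2000, 1, 31), end_date=dt.date(2002, 1, 31), seed=4,
        )
        world = generate_world(cfg)
        schedule = build_snapshot_schedule(cfg.start_date, cfg.end_date, 2)
        store = train_temporal_embeddings(
            generate_corpus(world, cfg), schedule,
            EmbeddingConfig(context_window=3, min_frequency=5, epochs_per_chunk=3,
                            dimension=25, seed=1),
        )
        event_drugs = {e.drug for e in world.events}
        finals = {True: [], False: []}
        for drug in world.drugs:
            series = drift_series(store, drug, reference_index=0)
            finals[drug in event_drugs].append(series.values[-1])
        assert len(finals[True]) and len(finals[False])
        assert np.mean(finals[True]) < np.mean(finals[False])


class TestNearestNeighbours:
    def test_k_zero(self):
        store = make_store({"a": [[1, 0]], "b": [[0, 1]]})
        assert nearest_neighbours(store, "a", 0, 0) == []

    def test_matches_brute_force(self):
        rng = np.random.default_rng(0)
        words = [f"w{i}" for i in range(12)]
        store = make_store({w: [rng.standard_normal(6).tolist()] for w in words})
        query = "w3"
        got = nearest_neighbours(store, query, 0, 5)
        snap = store.snapshots[0]
        brute = sorted(
            ((w, cosine_similarity(snap.vector(w), snap.vector(query)))
             for w in words if w != query),
            key=lambda t: (-t[1], t[0]),
        )[:5]
        assert [w for w, _ in got] == [w for w, _ in brute]
        np.testing.assert_allclose([s for _, s in got], [s for _, s in brute])

    def test_query_excluded(self, small_store_and_world):
        store, world, _ = small_store_and_world
        word = world.drugs[0]
        neigh = nearest_neighbours(store, word, len(store) - 1, 10)
        assert word not in [w for w, _ in neigh]


class TestPersistence:
    def test_roundtrip_exact(self, small_store_and_world, tmp_path):
        store, _, _ = small_store_and_world
        save_store(store, tmp_path / "store")
        back = load_store(tmp_path / "store")
        assert back.schedule == store.schedule
        assert back.config == store.config
        for a, b in zip(store.snapshots, back.snapshots):
            assert a.words == b.words
            np.testing.assert_array_equal(a.matrix, b.matrix)

    def test_manifest_and_format_grammar(self, small_store_and_world, tmp_path):
        import json

        store, _, _ = small_store_and_world
        save_store(store, tmp_path / "store")
        manifest = json.loads((tmp_path / "store" / "manifest.json").read_text())
        assert len(manifest["dates"]) == len(store.schedule)
        files = sorted((tmp_path / "store").glob("snapshot_*.txt"))
        assert len(files) == len(store.schedule)
        lines = files[0].read_text().splitlines()
        n, d = (int(x) for x in lines[0].split())
        assert len(lines) == n + 1
        for line in lines[1:]:
            parts = line.split()
            assert len(parts) == d + 1
            [float(x) for x in parts[1:]]  # every payload token parses as a float

    def test_malformed_file_names_line(self, small_store_and_world, tmp_path):
        store, _, _ = small_store_and_world
        save_store(store, tmp_path / "store")
        target = sorted((tmp_path / "store").glob("snapshot_*.txt"))[0]
        lines = target.read_text().splitlines()
        lines[1] = "brokenword 0.1 0.2"
        target.write_text("\n".join(lines) + "\n")
        with pytest.raises(ValueError, match="line 2"):
            load_store(tmp_path / "store")
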