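import datetime as dt
import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from drugdrift.embeddings import build_snapshot_schedule
from drugdrift.labelling import (
    LabelSeries,
    RelationTriple,
    ReleaseTable,
    build_label_series,
    events_from_releases,
    events_from_stream,
    map_event_to_snapshot,
    normalize_drug_name,
)


class TestNormalize:
    @pytest.mark.parametrize("raw, expected", [
        ("0.05 ml ranibizumab", "ranibizumab"),
        ("ranibizumab", "ranibizumab"),
        ("aspirin 500 mg", "aspirin"),
        ("Fish   Oil", "fish oil"),
        ("insulin 100 iu / something", "insulin / something"),
        ("0.5 % eye drops", "eye drops"),
    ])
    def test_examples(self, raw, expected):
        assert normalize_drug_name(raw) == expected

    @given(st.text(alphabet="abcdef23. MG", min_size=1).filter(str.strip))
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_idempotent(self, raw):
        from hypothesis import assume

        try:
            once = normalize_drug_name(raw)
        except ValueError:
            assume(False)  # name was all dosage; nothing to re-normalize
        assert normalize_drug_name(once) == once

    def test_all_dosage_rejected(self):
        with pytest.raises(ValueError, match="dosage"):
            normalize_drug_name("0.05 ml")
        with pytest.raises(ValueError):
            normalize_drug_name("   ")


def _t(pmid, date, subj, obj, pred="TREATS"):
    return RelationTriple(pmid, dt.date.fromisoformat(date), pred, subj, obj)


def brute_force_stream_events(triples, predicates=frozenset({"TREATS", "PREVENTS"})):
    """Prefix-diff oracle: for every date, diff the cumulative pair set against
    the previous date's, skipping pairs whose drug debuts on that date."""
    rows = sorted(
        (t.date, normalize_drug_name(t.subject), normalize_drug_name(t.object))
        for t in triples if t.predicate in predicates
    )
    dates = sorted({r[0] for r in rows})
    events = []
    for i, date in enumerate(dates):
        prev_pairs = {(d, c) for dd, d, c in rows if dd < date}
        prev_drugs = {d for d, _ in prev_pairs}
        now_pairs = {(d, c) for dd, d, c in rows if dd <= date}
        for drug, cond in sorted(now_pairs - prev_pairs):
            if drug in prev_drugs:
                events.append((drug, cond, date))
    return events


class TestStreamEvents:
    def test_empty(self):
        assert events_from_stream([]) == []

    def test_new_condition_for_known_drug_is_event(self):
        triples = [
            _t("p1", "1990-04-30", "fish oil", "Raynaud phenomenon"),
            _t("p2", "2002-06-15", "fish oil", "Raynaud disease"),
        ]
        events = events_from_stream(triples)
        assert len(events) == 1
        ev = events[0]
        assert (ev.drug, ev.condition, ev.date.isoformat(), ev.source) == (
            "fish oil", "raynaud disease", "2002-06-15", "stream",
        )

    def test_repeat_condition_not_an_event(self):
        triples = [
            _t("p1", "2000-01-01", "d", "c1"),
            _t("p2", "2001-01-01", "d", "c1"),
            _t("p3", "2002-01-01", "d", "c2"),
        ]
        events = events_from_stream(triples)
        assert [(e.drug, e.condition, e.date.isoformat()) for e in events] == [
            ("d", "c2", "2002-01-01")
        ]

    def test_debut_conditions_are_baseline_not_events(self):
        # two conditions on the drug's first date: both baseline
        triples = [
            _t("p1", "2000-01-01", "d", "c1"),
            _t("p2", "2000-01-01", "d", "c2"),
            _t("p3", "2001-01-01", "d", "c3"),
        ]
        events = events_from_stream(triples)
        assert [(e.condition) for e in events] == ["c3"]

    def test_affects_excluded_by_default(self):
        triples = [
            _t("p1", "2000-01-01", "d", "c1"),
            _t("p2", "2001-01-01", "d", "c2", pred="AFFECTS"),
        ]
        assert events_from_stream(triples) == []
        with_affects = events_from_stream(triples, {"TREATS", "PREVENTS", "AFFECTS"})
        assert len(with_affects) == 1

    def test_matches_brute_force_oracle_on_random_streams(self):
        rng = np.random.default_rng(12)
        base = dt.date(2000, 1, 1)
        for trial in range(30):
            n = int(rng.integers(1, 120))
            triples = [
                _t(
                    f"p{i}",
                    (base + dt.timedelta(days=int(rng.integers(0, 1500)))).isoformat(),
                    f"drug{int(rng.integers(6))}",
                    f"cond{int(rng.integers(8))}",
                )
                for i in range(n)
            ]
            got = [(e.drug, e.condition, e.date) for e in events_from_stream(triples)]
            assert got == brute_force_stream_events(triples)


class TestReleaseEvents:
    def _release(self, date, *pairs):
        return ReleaseTable(
            dt.date.fromisoformat(date),
            frozenset((d, "may_treat", c) for d, c in pairs),
        )

    def test_single_release_is_baseline(self):
        rel = self._release("2006-06-30", ("d", "c1"))
        assert events_from_releases([rel]) == []

    def test_added_pair_for_existing_drug(self):
        r1 = self._release("2006-06-30", ("d", "c1"))
        r2 = self._release("2006-12-31", ("d", "c1"), ("d", "c2"))
        events = events_from_releases([r1, r2])
        assert [(e.drug, e.condition, e.date.isoformat(), e.source) for e in events] == [
            ("d", "c2", "2006-12-31", "release-diff")
        ]

    def test_identical_releases_no_events(self):
        r1 = self._release("2006-06-30", ("d", "c1"))
        r2 = self._release("2006-12-31", ("d", "c1"))
        assert events_from_releases([r1, r2]) == []

    def test_debut_drug_in_later_release_is_baseline(self):
        r1 = self._release("2006-06-30", ("d", "c1"))
        r2 = self._release("2006-12-31", ("d", "c1"), ("e", "c9"))
        assert events_from_releases([r1, r2]) == []

    def test_duplicate_release_dates_rejected(self):
        r1 = self._release("2006-06-30", ("d", "c1"))
        with pytest.raises(ValueError, match="unique"):
            events_from_releases([r1, r1])

    def test_unsorted_releases_rejected(self):
        r1 = self._release("2006-06-30", ("d", "c1"))
        r2 = self._release("2006-01-31", ("d", "c2"))
        with pytest.raises(ValueError, match="sorted"):
            events_from_releases([r1, r2])


class TestSnapshotMapping:
    schedule = build_snapshot_schedule("2017-01-31", "2017-11-30", 2)

    def test_exact_hit(self):
        assert map_event_to_snapshot(dt.date(2017, 5, 31), self.schedule) == 1

    def test_between_snapshots_rounds_up(self):
        assert map_event_to_snapshot(dt.date(2017, 6, 1), self.schedule) == 2

    def test_after_last_is_none(self):
        assert map_event_to_snapshot(dt.date(2017, 12, 1), self.schedule) is None


class TestLabelSeries:
    def test_event_at_final_snapshot_only(self):
        from drugdrift.labelling import RepurposingEvent

        schedule = build_snapshot_schedule("2016-11-30", "2017-11-30", 2)
        events = [RepurposingEvent("balaglitazone", "c", dt.date(2017, 11, 30), "stream")]
        series = build_label_series("balaglitazone", events, schedule)
        assert list(series.labels) == [0, 0, 0, 0, 0, 1]

    def test_no_events_all_zero(self):
        schedule = build_snapshot_schedule("2016-11-30", "2017-11-30", 2)
        assert set(build_label_series("d", [], schedule).labels) == {0}

    def test_two_events_two_ones(self):
        from drugdrift.labelling import RepurposingEvent

        schedule = build_snapshot_schedule("2016-11-30", "2017-11-30", 2)
        events = [
            RepurposingEvent("d", "c1", dt.date(2017, 1, 31), "stream"),
            RepurposingEvent("d", "c2", dt.date(2017, 9, 30), "stream"),
        ]
        series = build_label_series("d", events, schedule)
        assert sum(series.labels) == 2

    def test_foreign_event_rejected(self):
        from drugdrift.labelling import RepurposingEvent

        schedule = build_snapshot_schedule("2016-11-30", "2017-11-30", 2)
        with pytest.raises(ValueError):
            build_label_series("d", [RepurposingEvent("e", "c", dt.date(2017, 1, 1), "stream")],
                               schedule)

    def test_ones_count_distinct_mapped_indices(self):
        from drugdrift.labelling import RepurposingEvent

        schedule = build_snapshot_schedule("2016-11-30", "2017-11-30", 2)
        # two events in the same interval collapse onto one snapshot
        events = [
            RepurposingEvent("d", "c1", dt.date(2017, 1, 10), "stream"),
            RepurposingEvent("d", "c2", dt.date(2017, 1, 20), "stream"),
        ]
        assert sum(build_label_series("d", events, schedule).labels) == 1


def test_release_roundtrip_recovers_ground_truth(tiny_world, tiny_config):
    """Releases built from the triple stream, then diffed, recover every event
    with its date rounded up to the covering release."""
    from drugdrift.synthetic import generate_releases, generate_triples

    triples = generate_triples(tiny_world, tiny_config)
    # anchor the grid at the baseline-triple date so the first (baseline)
    # release predates every event publication
    releases = generate_releases(triples, 6, first_release_date=triples[0].date)
    recovered = events_from_releases(releases)
    got = {(e.drug, e.condition): e.date for e in recovered}
    pub = {(t.subject, t.object): t.date for t in triples}
    expected = {}
    for ev in tiny_world.events:
        p = pub[(ev.drug, ev.condition)]
        expected[(ev.drug, ev.condition)] = min(r.date for r in releases if r.date >= p)
    assert got == expected
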