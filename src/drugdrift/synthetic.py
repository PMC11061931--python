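"""Synthetic corpus, predication stream and release tables with known events.

The generator builds a miniature literature world: each condition owns a
topic (a set of characteristic context words), each drug has a baseline
condition it treats, and every abstract mentions exactly one drug
surrounded by tokens drawn from a mixture of topic and background words.

A drug selected for a repurposing event acquires a second condition.  Its
context mixture starts admitting the new condition's topic words with a
weight that ramps linearly from 0 to ``drift_magnitude`` over
``drift_lead`` intervals, completing exactly at the event date; the
corresponding relation triple is published ``publication_lag_months``
later, and release tables pick it up at the next release.  The contextual
drift therefore *precedes* the published evidence, which is what makes
prediction from embedding trajectories possible in principle.

Ground-truth events are written to a separate file only, never into the
corpus or relation formats.
"""

from __future__ import annotations

import dataclasses
import datetime as _dt
import math
import pathlib
from collections.abc import Iterable, Iterator, Sequence

import numpy as np

from .dates import add_months, months_between, parse_date
from .labelling import RelationTriple, ReleaseTable

__all__ = [
    "SyntheticConfig",
    "SyntheticWorld",
    "SyntheticDocument",
    "GroundTruthEvent",
    "generate_world",
    "generate_corpus",
    "generate_triples",
    "generate_releases",
    "write_fixtures",
    "new_topic_weight",
]

TOPIC_WORDS_PER_CONDITION = 20
TOPIC_SHARE = 0.7  # fraction of context tokens drawn from topics vs background

_PRED_TO_RELA = {"TREATS": "may_treat", "PREVENTS": "may_prevent"}


@dataclasses.dataclass(frozen=True)
class SyntheticConfig:
    """Parameters of the synthetic world; identical config + seed ⇒ identical bytes."""

    n_drugs: int = 200
    n_conditions: int = 20
    vocab_background: int = 500
    event_rate: float = 0.3
    drift_magnitude: float = 0.8
    drift_lead: int = 6
    docs_per_interval: int = 400
    tokens_per_doc: int = 15
    publication_lag_months: int = 2
    start_date: _dt.date = _dt.date(2000, 1, 31)
    end_date: _dt.date = _dt.date(2004, 1, 31)
    interval_months: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "start_date", parse_date(self.start_date))
        object.__setattr__(self, "end_date", parse_date(self.end_date))
        if not (0.0 <= self.event_rate <= 1.0):
            raise ValueError("event_rate must be in [0, 1]")
        if not (0.0 <= self.drift_magnitude <= 1.0):
            raise ValueError("drift_magnitude must be in [0, 1]")
        for name in ("n_drugs", "n_conditions", "vocab_background", "drift_lead",
                     "docs_per_interval", "tokens_per_doc", "publication_lag_months"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.interval_months < 1:
            raise ValueError("interval_months must be >= 1")
        if self.start_date >= self.end_date:
            raise ValueError("start_date must precede end_date")

    def interval_dates(self) -> tuple[_dt.date, ...]:
        """End dates of the generation intervals (the snapshot grid)."""
        n = months_between(self.start_date, self.end_date) // self.interval_months
        return tuple(add_months(self.start_date, k * self.interval_months) for k in range(1, n + 1))


@dataclasses.dataclass(frozen=True)
class GroundTruthEvent:
    drug: str
    condition: str
    date: _dt.date
    interval_index: int


@dataclasses.dataclass(frozen=True)
class SyntheticWorld:
    drugs: tuple[str, ...]
    conditions: tuple[str, ...]
    condition_topics: dict[str, tuple[str, ...]]
    background_words: tuple[str, ...]
    baseline: dict[str, str]  # drug -> baseline condition
    events: tuple[GroundTruthEvent, ...]


@dataclasses.dataclass(frozen=True)
class SyntheticDocument:
    id: str
    date: _dt.date
    tokens: tuple[str, ...]

    @property
    def text(self) -> str:
        return " ".join(self.tokens)


def new_topic_weight(event_interval: int, drift_lead: int, drift_magnitude: float,
                     interval: int) -> float:
    """Mixing weight of the new condition's topic at a given interval.

    Ramps linearly from 0 (at ``event_interval - drift_lead``) to
    ``drift_magnitude`` at the event interval, and stays there afterwards.
    """
    if drift_lead == 0:
        return drift_magnitude if interval >= event_interval else 0.0
    progress = (interval - (event_interval - drift_lead)) / drift_lead
    return drift_magnitude * float(np.clip(progress, 0.0, 1.0))


def generate_world(config: SyntheticConfig) -> SyntheticWorld:
    """Draw the drug lexicon, topics, baseline uses and ground-truth events."""
    if config.event_rate > 0 and config.n_drugs > 0 and config.n_conditions < 2:
        raise ValueError("need at least 2 conditions to repurpose a drug onto a new one")
    rng = np.random.default_rng([config.seed, 0])
    drugs = tuple(f"drug{i:05d}" for i in range(config.n_drugs))
    conditions = tuple(f"cond{i:03d}" for i in range(config.n_conditions))
    topics = {
        c: tuple(f"{c}x{j:02d}" for j in range(TOPIC_WORDS_PER_CONDITION)) for c in conditions
    }
    background = tuple(f"filler{i:05d}" for i in range(config.vocab_background))

    if config.n_drugs and not config.n_conditions:
        raise ValueError("drugs require at least one condition for a baseline use")
    base_idx = rng.integers(config.n_conditions, size=config.n_drugs) if config.n_drugs else np.zeros(0, int)
    baseline = {d: conditions[base_idx[i]] for i, d in enumerate(drugs)}

    events: list[GroundTruthEvent] = []
    if config.n_drugs and config.event_rate > 0:
        has_event = rng.random(config.n_drugs) < config.event_rate
        grid = config.interval_dates()
        lag_intervals = math.ceil(config.publication_lag_months / config.interval_months)
        lo = config.drift_lead
        hi = len(grid) - 1 - lag_intervals
        if has_event.any() and lo > hi:
            raise ValueError(
                f"no interval can host an event: need index in [{lo}, {hi}] "
                f"(drift_lead={config.drift_lead}, lag={config.publication_lag_months} months, "
                f"{len(grid)} intervals)"
            )
        for i in np.flatnonzero(has_event):
            shift = rng.integers(config.n_conditions - 1)
            new_c = (base_idx[i] + 1 + shift) % config.n_conditions
            k = int(rng.integers(lo, hi + 1))
            events.append(GroundTruthEvent(drugs[i], conditions[new_c], grid[k], k))
    events.sort(key=lambda e: (e.date, e.drug))
    return SyntheticWorld(
        drugs=drugs,
        conditions=conditions,
        condition_topics=topics,
        background_words=background,
        baseline=baseline,
        events=tuple(events),
    )


def _interval_assignment(n_drugs: int, docs: int, seed: int, interval: int) -> np.ndarray:
    """Drug index for each document of one interval (balanced, shuffled, seeded)."""
    if n_drugs == 0 or docs == 0:
        return np.zeros(0, dtype=np.int64)
    rng = np.random.default_rng([seed, 1, interval])
    reps = -(-docs // n_drugs)
    pool = np.concatenate([rng.permutation(n_drugs) for _ in range(reps)])
    return pool[:docs]


def generate_corpus(world: SyntheticWorld, config: SyntheticConfig) -> Iterator[SyntheticDocument]:
    """Yield the dated abstract stream in chronological order."""
    if config.tokens_per_doc < 1:
        raise ValueError("tokens_per_doc must be >= 1 (a document needs its drug mention)")
    grid = config.interval_dates()
    n_ctx = config.tokens_per_doc - 1
    drugs = np.array(world.drugs)
    cond_index = {c: i for i, c in enumerate(world.conditions)}
    base_idx = np.array([cond_index[world.baseline[d]] for d in world.drugs], dtype=np.int64)
    new_idx = np.full(len(world.drugs), -1, dtype=np.int64)
    event_at = np.full(len(world.drugs), -1, dtype=np.int64)
    drug_pos = {d: i for i, d in enumerate(world.drugs)}
    for ev in world.events:
        i = drug_pos[ev.drug]
        new_idx[i] = cond_index[ev.condition]
        event_at[i] = ev.interval_index
    topic_flat = np.array(
        [w for c in world.conditions for w in world.condition_topics[c]]
    ) if world.conditions else np.array([], dtype="U1")
    bg = np.array(world.background_words)
    topic_share = TOPIC_SHARE if len(bg) else 1.0
    if not len(topic_flat):
        topic_share = 0.0
        if not len(bg) and n_ctx > 0 and len(drugs):
            raise ValueError("no context vocabulary: both topics and background are empty")

    doc_no = 0
    for k, date in enumerate(grid):
        assign = _interval_assignment(len(world.drugs), config.docs_per_interval, config.seed, k)
        ndocs = len(assign)
        if ndocs == 0:
            continue
        rng = np.random.default_rng([config.seed, 2, k])
        w = np.zeros(ndocs)
        for row, di in enumerate(assign):
            if event_at[di] >= 0:
                w[row] = new_topic_weight(
                    int(event_at[di]), config.drift_lead, config.drift_magnitude, k
                )
        if n_ctx:
            topic_mask = rng.random((ndocs, n_ctx)) < topic_share
            use_new = rng.random((ndocs, n_ctx)) < w[:, None]
            word_j = rng.integers(TOPIC_WORDS_PER_CONDITION, size=(ndocs, n_ctx))
            bg_j = rng.integers(max(len(bg), 1), size=(ndocs, n_ctx))
            cond_choice = np.where(
                use_new & (new_idx[assign][:, None] >= 0),
                new_idx[assign][:, None],
                base_idx[assign][:, None],
            )
            if len(topic_flat):
                topic_tokens = topic_flat[cond_choice * TOPIC_WORDS_PER_CONDITION + word_j]
            else:
                topic_tokens = np.full((ndocs, n_ctx), "", dtype="U1")
            bg_tokens = bg[bg_j] if len(bg) else np.full((ndocs, n_ctx), "", dtype="U1")
            ctx = np.where(topic_mask, topic_tokens, bg_tokens)
        mid = n_ctx // 2
        for row in range(ndocs):
            drug = drugs[assign[row]]
            if n_ctx:
                toks = ctx[row].tolist()
                tokens = tuple(toks[:mid] + [drug] + toks[mid:])
            else:
                tokens = (drug,)
            yield SyntheticDocument(id=f"D{doc_no:08d}", date=date, tokens=tokens)
            doc_no += 1


def _first_mentions(world: SyntheticWorld, config: SyntheticConfig) -> dict[str, tuple[_dt.date, str]]:
    """First (date, document id) at which each drug is mentioned."""
    grid = config.interval_dates()
    out: dict[str, tuple[_dt.date, str]] = {}
    doc_no = 0
    for k, date in enumerate(grid):
        assign = _interval_assignment(len(world.drugs), config.docs_per_interval, config.seed, k)
        for row, di in enumerate(assign):
            drug = world.drugs[di]
            if drug not in out:
                out[drug] = (date, f"D{doc_no + row:08d}")
        doc_no += len(assign)
        if len(out) == len(world.drugs):
            break
    return out


def generate_triples(world: SyntheticWorld, config: SyntheticConfig) -> list[RelationTriple]:
    """Baseline TREATS triples at first mention; event triples lagged by publication delay."""
    first = _first_mentions(world, config)
    triples: list[RelationTriple] = []
    for drug in world.drugs:
        if drug in first:
            date, pmid = first[drug]
            triples.append(
                RelationTriple(pmid, date, "TREATS", drug, world.baseline[drug])
            )
    for n, ev in enumerate(world.events):
        pub = add_months(ev.date, config.publication_lag_months)
        triples.append(RelationTriple(f"EV{n:06d}", pub, "TREATS", ev.drug, ev.condition))
    triples.sort(key=lambda t: (t.date, t.subject, t.object))
    return triples


def generate_releases(
    triples: Sequence[RelationTriple],
    release_interval_months: int,
    first_release_date: _dt.date | str | None = None,
    last_release_date: _dt.date | str | None = None,
) -> list[ReleaseTable]:
    """Cumulative release tables at regular dates covering the triple stream.

    Each release holds every (drug, relation, condition) pair published on
    or before its date, so tables grow monotonically.  By default the
    release grid starts one interval after the first triple and ends at
    the first boundary covering the last triple.
    """
    if release_interval_months < 1:
        raise ValueError("release_interval_months must be >= 1")
    dates = [t.date for t in triples]
    if dates != sorted(dates):
        raise ValueError("triple stream must be sorted by date")
    if first_release_date is None:
        if not triples:
            return []
        first_release_date = add_months(dates[0], release_interval_months)
    first_release_date = parse_date(first_release_date)
    last_needed = parse_date(last_release_date) if last_release_date else (dates[-1] if dates else first_release_date)

    releases: list[ReleaseTable] = []
    rdate = first_release_date
    i = 0
    cum: set[tuple[str, str, str]] = set()
    while True:
        while i < len(triples) and triples[i].date <= rdate:
            t = triples[i]
            rela = _PRED_TO_RELA.get(t.predicate)
            if rela is not None:
                cum.add((t.subject, rela, t.object))
            i += 1
        releases.append(ReleaseTable(date=rdate, pairs=frozenset(cum)))
        if rdate >= last_needed:
            break
        rdate = add_months(first_release_date, release_interval_months * len(releases))
    return releases


def write_fixtures(
    world: SyntheticWorld,
    corpus: Iterable[SyntheticDocument],
    triples: Sequence[RelationTriple],
    releases: Sequence[ReleaseTable],
    out_dir: str | pathlib.Path,
) -> dict[str, pathlib.Path]:
    """Write all artifacts in their external formats, plus the ground-truth events.

    Output is byte-deterministic for a fixed world/config.  The events file
    exists for test assertions only and is not part of any input format.
    """
    import json

    root = pathlib.Path(out_dir)
    root.mkdir(parents=True, exist_ok=True)
    paths = {
        "corpus": root / "corpus.jsonl",
        "predications": root / "predications.tsv",
        "releases_dir": root / "releases",
        "lexicon": root / "lexicon.txt",
        "events": root / "events.tsv",
    }
    with paths["corpus"].open("w") as fh:
        for doc in corpus:
            fh.write(
                json.dumps({"id": doc.id, "date": doc.date.isoformat(), "text": doc.text}) + "\n"
            )
    with paths["predications"].open("w") as fh:
        fh.write("PMID\tDATE\tPREDICATE\tSUBJECT_NAME\tOBJECT_NAME\n")
        for t in triples:
            fh.write(f"{t.document_id}\t{t.date.isoformat()}\t{t.predicate}\t{t.subject}\t{t.object}\n")
    paths["releases_dir"].mkdir(exist_ok=True)
    for rel in releases:
        fname = paths["releases_dir"] / f"RELEASE_{rel.date.isoformat()}.psv"
        with fname.open("w") as fh:
            fh.write("DRUG|RELA|CONDITION\n")
            for drug, rela, cond in sorted(rel.pairs):
                fh.write(f"{drug}|{rela}|{cond}\n")
    paths["lexicon"].write_text("".join(d + "\n" for d in world.drugs))
    with paths["events"].open("w") as fh:
        fh.write("DRUG\tCONDITION\tDATE\n")
        for ev in world.events:
            fh.write(f"{ev.drug}\t{ev.condition}\t{ev.date.isoformat()}\n")
    return paths
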