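"""Readers and writers for the external interchange formats.

* corpus: JSON-lines, one ``{"id", "date", "text"}`` record per line,
  sorted by date;
* predication stream: TSV with header
  ``PMID  DATE  PREDICATE  SUBJECT_NAME  OBJECT_NAME``;
* release tables: one ``RELEASE_YYYY-MM-DD.psv`` per release, pipe-
  delimited ``DRUG|RELA|CONDITION`` rows;
* drug lexicon: one canonical name per line;
* events: TSV ``DRUG  CONDITION  DATE  [SOURCE]``.
"""

from __future__ import annotations

import json
import pathlib
import re
from collections.abc import Iterator, Sequence

from .dates import parse_date
from .labelling import RelationTriple, ReleaseTable, RepurposingEvent
from .synthetic import SyntheticDocument

__all__ = [
    "read_corpus",
    "read_predications",
    "write_predications",
    "read_release_file",
    "read_release_dir",
    "read_lexicon",
    "read_events",
    "write_events",
]

_RELEASE_NAME = re.compile(r"RELEASE_(\d{4}-\d{2}-\d{2})\.psv$")


def read_corpus(path: str | pathlib.Path) -> Iterator[SyntheticDocument]:
    """Stream documents from a JSON-lines corpus file."""
    with pathlib.Path(path).open() as fh:
        for ln, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            try:
                rec = json.loads(line)
                doc = SyntheticDocument(
                    id=rec["id"], date=parse_date(rec["date"]), tokens=tuple(rec["text"].split())
                )
            except (KeyError, ValueError) as exc:
                raise ValueError(f"{path}: line {ln}: malformed corpus record ({exc})")
            yield doc


def read_predications(path: str | pathlib.Path) -> list[RelationTriple]:
    lines = pathlib.Path(path).read_text().splitlines()
    if not lines or lines[0].split("\t") != ["PMID", "DATE", "PREDICATE", "SUBJECT_NAME", "OBJECT_NAME"]:
        raise ValueError(f"{path}: missing or malformed predication header")
    triples = []
    for ln, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        parts = line.split("\t")
        if len(parts) != 5:
            raise ValueError(f"{path}: line {ln}: expected 5 tab-separated fields")
        pmid, date, pred, subj, obj = parts
        triples.append(RelationTriple(pmid, parse_date(date), pred, subj, obj))
    return triples


def write_predications(triples: Sequence[RelationTriple], path: str | pathlib.Path) -> None:
    with pathlib.Path(path).open("w") as fh:
        fh.write("PMID\tDATE\tPREDICATE\tSUBJECT_NAME\tOBJECT_NAME\n")
        for t in triples:
            fh.write(
                f"{t.document_id}\t{t.date.isoformat()}\t{t.predicate}\t{t.subject}\t{t.object}\n"
            )


def read_release_file(path: str | pathlib.Path) -> ReleaseTable:
    path = pathlib.Path(path)
    m = _RELEASE_NAME.search(path.name)
    if not m:
        raise ValueError(f"{path.name}: release files must be named RELEASE_YYYY-MM-DD.psv")
    date = parse_date(m.group(1))
    pairs = set()
    lines = path.read_text().splitlines()
    start = 1 if lines and lines[0] == "DRUG|RELA|CONDITION" else 0
    for ln, line in enumerate(lines[start:], start=start + 1):
        if not line.strip():
            continue
        parts = line.split("|")
        if len(parts) != 3:
            raise ValueError(f"{path.name}: line {ln}: expected DRUG|RELA|CONDITION")
        pairs.add(tuple(parts))
    return ReleaseTable(date=date, pairs=frozenset(pairs))


def read_release_dir(path: str | pathlib.Path) -> list[ReleaseTable]:
    """All RELEASE_*.psv files in a directory, sorted by release date."""
    files = sorted(pathlib.Path(path).glob("RELEASE_*.psv"))
    releases = [read_release_file(f) for f in files]
    releases.sort(key=lambda r: r.date)
    return releases


def read_lexicon(path: str | pathlib.Path) -> list[str]:
    return [line.strip() for line in pathlib.Path(path).read_text().splitlines() if line.strip()]


def read_events(path: str | pathlib.Path) -> list[RepurposingEvent]:
    lines = pathlib.Path(path).read_text().splitlines()
    if not lines or not lines[0].startswith("DRUG\tCONDITION\tDATE"):
        raise ValueError(f"{path}: missing events header")
    has_source = lines[0].split("\t")[-1] == "SOURCE"
    events = []
    for line in lines[1:]:
        if not line.strip():
            continue
        parts = line.split("\t")
        source = parts[3] if has_source else "ground-truth"
        events.append(RepurposingEvent(parts[0], parts[1], parse_date(parts[2]), source))
    return events


def write_events(events: Sequence[RepurposingEvent], path: str | pathlib.Path) -> None:
    with pathlib.Path(path).open("w") as fh:
        fh.write("DRUG\tCONDITION\tDATE\tSOURCE\n")
        for e in events:
            fh.write(f"{e.drug}\t{e.condition}\t{e.date.isoformat()}\t{e.source}\n")
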