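"""Citation-record data model and plain-text readers/writers.

Citation corpora are stored as JSON-lines, one indexed article per line::

    {"id": "A1", "anns": [["D_ofloxacin", ["AE"]], ["D_tendinopathy", ["CI"]]]}

``id`` is an opaque article identifier; each annotation is a descriptor
identifier plus the (possibly empty) list of qualifiers attached to it,
mirroring how MEDLINE couples MeSH descriptors with qualifiers such as
*adverse effects* or *chemically induced*.  All identifiers are opaque
strings; no vocabulary-specific validation is performed here.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import pandas as pd

__all__ = [
    "Annotation",
    "CitationRecord",
    "Corpus",
    "read_corpus",
    "write_corpus",
    "write_table",
    "read_table",
]


@dataclass(frozen=True)
class Annotation:
    """One descriptor/qualifier-set annotation on an article."""

    descriptor_id: str
    qualifier_ids: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if not self.descriptor_id:
            raise ValueError("descriptor_id must be non-empty")
        object.__setattr__(self, "qualifier_ids", frozenset(self.qualifier_ids))


@dataclass(frozen=True)
class CitationRecord:
    """One article: identifier plus its deduplicated annotations."""

    article_id: str
    annotations: tuple[Annotation, ...] = ()

    def __post_init__(self) -> None:
        if not self.article_id:
            raise ValueError("article_id must be non-empty")
        seen: dict[tuple[str, frozenset[str]], Annotation] = {}
        for ann in self.annotations:
            seen.setdefault((ann.descriptor_id, ann.qualifier_ids), ann)
        object.__setattr__(self, "annotations", tuple(seen.values()))


@dataclass
class Corpus:
    """An ordered collection of citation records with unique article ids."""

    records: list[CitationRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [r.article_id for r in self.records]
        if len(ids) != len(set(ids)):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate article_id(s): {dupes[:5]}")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[CitationRecord]:
        return iter(self.records)


def _record_from_obj(obj: Mapping, lineno: int) -> CitationRecord:
    try:
        article_id = obj["id"]
        raw_anns = obj.get("anns", [])
        anns = tuple(
            Annotation(descriptor_id=d, qualifier_ids=frozenset(q))
            for d, q in raw_anns
        )
        return CitationRecord(article_id=article_id, annotations=anns)
    except (KeyError, TypeError, ValueError) as exc:
        raise ValueError(f"malformed citation record on line {lineno}: {exc}") from exc


def read_corpus(path: str | Path) -> Corpus:
    """Read a JSON-lines citation corpus, preserving line order.

    Duplicate (descriptor, qualifier-set) annotations within a record are
    collapsed.  A duplicate ``article_id`` across lines is an error, as is
    any malformed line (reported with its line number).
    """
    records: list[CitationRecord] = []
    seen_ids: set[str] = set()
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            try:
                obj = json.loads(line)
            except json.JSONDecodeError as exc:
                raise ValueError(f"invalid JSON on line {lineno}: {exc}") from exc
            rec = _record_from_obj(obj, lineno)
            if rec.article_id in seen_ids:
                raise ValueError(
                    f"duplicate article_id {rec.article_id!r} on line {lineno}"
                )
            seen_ids.add(rec.article_id)
            records.append(rec)
    return Corpus(records=records)


def write_corpus(corpus: Corpus, path: str | Path) -> None:
    """Write a corpus as JSON-lines; ``read_corpus`` round-trips it."""
    with open(path, "w", encoding="utf-8") as fh:
        for rec in corpus:
            obj = {
                "id": rec.article_id,
                "anns": [
                    [a.descriptor_id, sorted(a.qualifier_ids)]
                    for a in rec.annotations
                ],
            }
            fh.write(json.dumps(obj) + "\n")


def write_table(rows: Sequence[Mapping] | pd.DataFrame, path: str | Path) -> None:
    """Write uniform records as a TSV with a header row.

    Floats are serialized with enough significant digits (repr precision)
    that reading the table back reproduces the values exactly.
    """
    if isinstance(rows, pd.DataFrame):
        df = rows
    else:
        df = pd.DataFrame(list(rows))
    df.to_csv(path, sep="\t", index=False)


def read_table(path: str | Path) -> pd.DataFrame:
    """Read a TSV written by :func:`write_table`."""
    return pd.read_csv(path, sep="\t")
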