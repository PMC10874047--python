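"""Core domain types: labels, bibliographic records, corpora.

A :class:`Corpus` is the in-memory container every other module operates on.
Labels are three-valued: a record is known-relevant, known-irrelevant, or
*noisy* — present in a reconstructed dataset but never screened, so its true
relevance is unknown.
"""

from __future__ import annotations

import re
import unicodedata
from dataclasses import dataclass, replace
from enum import Enum
from typing import Iterable, Iterator, NamedTuple


class Label(str, Enum):
    """Three-valued relevance label of a bibliographic record."""

    RELEVANT = "relevant"
    IRRELEVANT = "irrelevant"
    NOISY = "noisy"


_WS_RE = re.compile(r"\s+")


def normalize_text(text: str) -> str:
    """Casefold, strip Unicode punctuation, collapse whitespace.

    Produces the comparison key used for deduplication; deterministic and
    locale-independent.
    """
    folded = text.casefold()
    chars = []
    for ch in folded:
        if unicodedata.category(ch).startswith("P"):
            chars.append(" ")
        else:
            chars.append(ch)
    return _WS_RE.sub(" ", "".join(chars)).strip()


def normalize_doi(doi: str | None) -> str:
    """Lowercase a DOI and strip ``https://doi.org/`` / ``doi:`` prefixes."""
    if not doi:
        return ""
    d = doi.strip().lower()
    for prefix in ("https://doi.org/", "http://doi.org/", "https://dx.doi.org/",
                   "http://dx.doi.org/", "doi.org/", "doi:"):
        if d.startswith(prefix):
            d = d[len(prefix):]
            d = d.strip()
    return d


class RecordKey(NamedTuple):
    """Derived comparison key of a record (never stored on the record)."""

    title: str
    abstract: str
    doi: str


@dataclass(frozen=True)
class Record:
    """One bibliographic reference.

    ``record_id`` is an opaque token, unique within a corpus.  ``doi`` and
    ``year`` may be absent (``None``); ``title``/``abstract`` may be empty.
    """

    record_id: str
    title: str = ""
    abstract: str = ""
    doi: str | None = None
    year: int | None = None
    authors: tuple[str, ...] = ()
    source_db: str | None = None
    label: Label = Label.NOISY

    def __post_init__(self) -> None:
        # DOIs are stored normalized: no scheme prefix, no uppercase.
        norm = normalize_doi(self.doi) or None
        if norm != self.doi:
            object.__setattr__(self, "doi", norm)
        if not isinstance(self.authors, tuple):
            object.__setattr__(self, "authors", tuple(self.authors))

    def key(self) -> RecordKey:
        return RecordKey(
            title=normalize_text(self.title),
            abstract=normalize_text(self.abstract),
            doi=normalize_doi(self.doi),
        )

    def with_label(self, label: Label) -> "Record":
        return replace(self, label=label)

    @property
    def text(self) -> str:
        """Feature text: title and abstract joined by a single space."""
        return f"{self.title} {self.abstract}".strip()


def normalize_record(record: Record) -> tuple[Record, RecordKey]:
    """Return the record untouched together with its derived comparison key."""
    return record, record.key()


class Corpus:
    """Ordered collection of :class:`Record` with unique ids.

    Maintains the label partition invariant
    ``|RELEVANT| + |IRRELEVANT| + |NOISY| == len(corpus)`` by construction.
    """

    def __init__(self, records: Iterable[Record] = (), provenance: Iterable[str] = ()):
        self._records: list[Record] = list(records)
        self.provenance: list[str] = list(provenance)
        seen: set[str] = set()
        for r in self._records:
            if r.record_id in seen:
                raise ValueError(f"duplicate record_id {r.record_id!r} in corpus")
            seen.add(r.record_id)
        self._index: dict[str, int] = {
            r.record_id: i for i, r in enumerate(self._records)
        }

    # -- container protocol -------------------------------------------------
    def __len__(self) -> int:
        return len(self._records)

    def __iter__(self) -> Iterator[Record]:
        return iter(self._records)

    def __getitem__(self, record_id: str) -> Record:
        return self._records[self._index[record_id]]

    def __contains__(self, record_id: str) -> bool:
        return record_id in self._index

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Corpus):
            return NotImplemented
        return self._records == other._records

    @property
    def records(self) -> tuple[Record, ...]:
        return tuple(self._records)

    @property
    def record_ids(self) -> tuple[str, ...]:
        return tuple(r.record_id for r in self._records)

    def ids_with_label(self, label: Label) -> tuple[str, ...]:
        return tuple(r.record_id for r in self._records if r.label is label)

    def label_counts(self) -> dict[Label, int]:
        counts = {lab: 0 for lab in Label}
        for r in self._records:
            counts[r.label] += 1
        return counts

    def set_label(self, record_id: str, label: Label) -> None:
        i = self._index[record_id]
        self._records[i] = self._records[i].with_label(label)

    def remove(self, record_ids: Iterable[str]) -> "Corpus":
        """New corpus without the given ids, original order preserved."""
        drop = set(record_ids)
        missing = drop - set(self._index)
        if missing:
            raise KeyError(f"unknown record ids: {sorted(missing)}")
        kept = [r for r in self._records if r.record_id not in drop]
        return Corpus(kept, provenance=self.provenance)

    def copy(self) -> "Corpus":
        return Corpus(self._records, provenance=self.provenance)

    def with_note(self, note: str) -> "Corpus":
        c = self.copy()
        c.provenance.append(note)
        return c
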