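"""Read and write bibliographic corpora as RIS or CSV.

The RIS dialect follows the convention of labelled screening exports: the
relevance decision rides in a keyword tag (``KW`` by default) carrying one of
the strings ``ASReview_relevant`` / ``ASReview_irrelevant`` /
``ASReview_not_seen``.  Records without a label tag are treated as noisy
(unseen), never silently as irrelevant.
"""

from __future__ import annotations

import csv
import logging
import re
from pathlib import Path
from typing import Iterable

from .records import Corpus, Label, Record, normalize_doi

log = logging.getLogger(__name__)

LABEL_TO_TAG = {
    Label.RELEVANT: "ASReview_relevant",
    Label.IRRELEVANT: "ASReview_irrelevant",
    Label.NOISY: "ASReview_not_seen",
}
TAG_TO_LABEL = {v: k for k, v in LABEL_TO_TAG.items()}

#: RIS tags accepted for each field on read (first occurrence wins).
_TITLE_TAGS = ("TI", "T1")
_ABSTRACT_TAGS = ("AB", "N2")

_TAG_LINE = re.compile(r"^([A-Z][A-Z0-9])  - ?(.*)$")

CSV_COLUMNS = ("record_id", "title", "abstract", "doi", "year", "label")


def _parse_entries(lines: Iterable[str]) -> Iterable[list[tuple[str, str]]]:
    """Yield one (tag, value) list per RIS entry (TY ... ER)."""
    entry: list[tuple[str, str]] = []
    in_entry = False
    for lineno, raw in enumerate(lines, start=1):
        line = raw.rstrip("\n").rstrip("\r")
        if not line.strip():
            continue
        m = _TAG_LINE.match(line)
        if m is None:
            if in_entry and entry:
                # continuation line: append to previous tag's value
                tag, value = entry[-1]
                entry[-1] = (tag, f"{value} {line.strip()}")
            else:
                log.warning("skipping malformed RIS line %d: %r", lineno, line)
            continue
        tag, value = m.group(1), m.group(2).strip()
        if tag == "TY":
            in_entry = True
            entry = [(tag, value)]
        elif tag == "ER":
            if in_entry:
                yield entry
            in_entry = False
            entry = []
        elif in_entry:
            entry.append((tag, value))
        else:
            log.warning("RIS tag outside entry at line %d: %r", lineno, line)


def read_ris(path: str | Path, label_tag: str = "KW") -> Corpus:
    """Read an RIS file into a :class:`Corpus`, input order preserved.

    Parameters
    ----------
    path : file location
    label_tag : RIS tag carrying the label string (``KW`` default; ``N1``
        is a common alternative in reference-manager exports).
    """
    path = Path(path)
    records: list[Record] = []
    with path.open("r", encoding="utf-8") as fh:
        for n, entry in enumerate(_parse_entries(fh)):
            fields: dict[str, str] = {}
            authors: list[str] = []
            label = Label.NOISY
            record_id: str | None = None
            for tag, value in entry:
                if tag == "AU":
                    authors.append(value)
                elif tag == label_tag and value in TAG_TO_LABEL:
                    label = TAG_TO_LABEL[value]
                elif tag == "ID":
                    record_id = value
                elif tag not in fields:
                    fields[tag] = value
            title = next((fields[t] for t in _TITLE_TAGS if t in fields), "")
            abstract = next((fields[t] for t in _ABSTRACT_TAGS if t in fields), "")
            doi = normalize_doi(fields.get("DO")) or None
            year: int | None = None
            py = fields.get("PY", "")
            m = re.match(r"(\d{4})", py)
            if m:
                year = int(m.group(1))
            if not title and not abstract:
                log.warning("RIS entry %d has neither title nor abstract", n + 1)
            records.append(
                Record(
                    record_id=record_id or f"ris:{n + 1}",
                    title=title,
                    abstract=abstract,
                    doi=doi,
                    year=year,
                    authors=tuple(authors),
                    source_db=fields.get("DB"),
                    label=label,
                )
            )
    return Corpus(records, provenance=[f"read_ris:{path.name}"])


def write_ris(corpus: Corpus, path: str | Path, label_tag: str = "KW") -> None:
    """Write a corpus as RIS; round-trips through :func:`read_ris`."""
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        for r in corpus:
            fh.write("TY  - JOUR\n")
            fh.write(f"ID  - {r.record_id}\n")
            if r.title:
                fh.write(f"TI  - {r.title}\n")
            if r.abstract:
                fh.write(f"AB  - {r.abstract}\n")
            for au in r.authors:
                fh.write(f"AU  - {au}\n")
            if r.doi:
                fh.write(f"DO  - {r.doi}\n")
            if r.year is not None:
                fh.write(f"PY  - {r.year}\n")
            if r.source_db:
                fh.write(f"DB  - {r.source_db}\n")
            fh.write(f"{label_tag}  - {LABEL_TO_TAG[r.label]}\n")
            fh.write("ER  - \n\n")


def read_csv_corpus(path: str | Path) -> Corpus:
    """Read a corpus from CSV with header ``record_id,title,abstract,doi,year,label``."""
    path = Path(path)
    records: list[Record] = []
    with path.open("r", encoding="utf-8", newline="") as fh:
        reader = csv.DictReader(fh)
        header = reader.fieldnames or []
        missing = [c for c in CSV_COLUMNS if c not in header]
        if missing:
            raise ValueError(f"CSV header missing mandatory column(s): {missing}")
        extra = [c for c in header if c not in CSV_COLUMNS and c != "authors"]
        if extra:
            log.warning("ignoring unknown CSV columns: %s", extra)
        for row in reader:
            year = int(row["year"]) if row.get("year") else None
            authors = tuple(a for a in (row.get("authors") or "").split("; ") if a)
            records.append(
                Record(
                    record_id=row["record_id"],
                    title=row.get("title") or "",
                    abstract=row.get("abstract") or "",
                    doi=normalize_doi(row.get("doi")) or None,
                    year=year,
                    authors=authors,
                    label=Label(row["label"]),
                )
            )
    return Corpus(records, provenance=[f"read_csv:{path.name}"])


def write_csv_corpus(corpus: Corpus, path: str | Path) -> None:
    path = Path(path)
    with path.open("w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(CSV_COLUMNS + ("authors",))
        for r in corpus:
            writer.writerow(
                [
                    r.record_id,
                    r.title,
                    r.abstract,
                    r.doi or "",
                    r.year if r.year is not None else "",
                    r.label.value,
                    "; ".join(r.authors),
                ]
            )
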