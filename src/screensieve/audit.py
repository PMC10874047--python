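"""Reconstruction bookkeeping and risk checks.

When a screening dataset must be reconstructed by re-running published
search queries years later, two audits guard against silently divergent
corpora: (1) per-query hit counts are compared against the originally
reported counts, with relative differences above a tolerance (default 5%)
flagged as high risk; (2) every originally included record must be present
in the reconstructed corpus.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .records import Corpus, Label, normalize_doi, normalize_text


@dataclass(frozen=True)
class ReconstructionSummary:
    """Record-count bookkeeping of an initial vs. reconstructed dataset.

    ``k_i`` counts the initially screened records (``+`` included, ``-``
    excluded); ``k_r`` the reconstructed ones (``+`` relevant, ``-``
    irrelevant, ``?`` noisy).
    """

    k_i: int
    k_i_plus: int
    k_i_minus: int
    k_r: int
    k_r_plus: int
    k_r_minus: int
    k_r_q: int

    def __post_init__(self) -> None:
        if self.k_i != self.k_i_plus + self.k_i_minus:
            raise ValueError("k_i must equal k_i_plus + k_i_minus")
        if self.k_r != self.k_r_plus + self.k_r_minus + self.k_r_q:
            raise ValueError("k_r must equal k_r_plus + k_r_minus + k_r_q")

    @classmethod
    def from_corpus(
        cls, corpus: Corpus, k_i: int, k_i_plus: int
    ) -> "ReconstructionSummary":
        counts = corpus.label_counts()
        return cls(
            k_i=k_i,
            k_i_plus=k_i_plus,
            k_i_minus=k_i - k_i_plus,
            k_r=len(corpus),
            k_r_plus=counts[Label.RELEVANT],
            k_r_minus=counts[Label.IRRELEVANT],
            k_r_q=counts[Label.NOISY],
        )


@dataclass(frozen=True)
class QueryCount:
    database: str
    query_id: str
    initial: int
    replicated: int


@dataclass
class QueryCountComparison:
    """Per-query and per-database initial vs. replicated hit counts."""

    rows: list[QueryCount] = field(default_factory=list)

    @classmethod
    def from_csv(cls, path: str | Path) -> "QueryCountComparison":
        rows = []
        with Path(path).open("r", encoding="utf-8", newline="") as fh:
            reader = csv.DictReader(fh)
            required = {"database", "query_id", "initial", "replicated"}
            missing = required - set(reader.fieldnames or [])
            if missing:
                raise ValueError(f"counts CSV missing column(s): {sorted(missing)}")
            for row in reader:
                rows.append(
                    QueryCount(
                        database=row["database"],
                        query_id=row["query_id"],
                        initial=int(row["initial"]),
                        replicated=int(row["replicated"]),
                    )
                )
        return cls(rows=rows)

    def database_totals(self) -> dict[str, tuple[int, int]]:
        totals: dict[str, tuple[int, int]] = {}
        for r in self.rows:
            a, b = totals.get(r.database, (0, 0))
            totals[r.database] = (a + r.initial, b + r.replicated)
        return totals

    def grand_total(self) -> tuple[int, int]:
        return (
            sum(r.initial for r in self.rows),
            sum(r.replicated for r in self.rows),
        )


PREREQUISITES = ("search_terms_per_db", "relevant_record_list", "per_query_counts")


def check_prerequisites(available: Mapping[str, bool]) -> dict:
    """Decide whether dataset reconstruction can proceed at all.

    All three prerequisites — the full search terms per database, the list of
    initially relevant records, and per-query hit counts — must be available.
    """
    missing = [p for p in PREREQUISITES if not available.get(p, False)]
    return {"verdict": "proceed" if not missing else "blocked", "missing": missing}


def _relative_difference(initial: int, replicated: int) -> float | None:
    if initial == 0:
        return None if replicated == 0 else float("inf")
    return abs(replicated - initial) / initial


def compare_counts(
    comparison: QueryCountComparison, tolerance: float = 0.05
) -> dict:
    """Flag count rows and database totals diverging beyond the tolerance.

    The relative difference is taken against the *initial* count (the
    published number).  An initial count of zero with replicated hits is an
    undefined ratio and treated as high risk.  Overall verdict is high risk
    if anything is flagged.
    """
    flags = []
    for r in comparison.rows:
        rel = _relative_difference(r.initial, r.replicated)
        if rel is None:
            continue
        if rel > tolerance:
            flags.append(
                {
                    "level": "query",
                    "database": r.database,
                    "query_id": r.query_id,
                    "initial": r.initial,
                    "replicated": r.replicated,
                    "relative_difference": rel,
                }
            )
    for db, (init, repl) in comparison.database_totals().items():
        rel = _relative_difference(init, repl)
        if rel is not None and rel > tolerance:
            flags.append(
                {
                    "level": "database",
                    "database": db,
                    "initial": init,
                    "replicated": repl,
                    "relative_difference": rel,
                }
            )
    init, repl = comparison.grand_total()
    rel = _relative_difference(init, repl)
    total_flagged = rel is not None and rel > tolerance
    if total_flagged:
        flags.append(
            {
                "level": "total",
                "initial": init,
                "replicated": repl,
                "relative_difference": rel,
            }
        )
    return {
        "risk": "high" if flags else "low",
        "tolerance": tolerance,
        "flags": flags,
        "total_initial": init,
        "total_replicated": repl,
        "total_relative_difference": rel,
    }


def verify_relevant_presence(
    corpus: Corpus,
    relevant_keys: Sequence[Mapping[str, str]],
    exclusions: Iterable[str] = (),
) -> dict:
    """Check that every originally included record is in the corpus.

    Each key is a mapping with ``doi`` and/or ``title``; matching tries the
    DOI first, then the normalized title.  Matched records are labeled
    RELEVANT in place.  ``exclusions`` lists keys to skip (e.g. retracted
    papers).  Keys matching multiple records are reported for manual
    resolution, not auto-chosen.
    """
    excl = {normalize_doi(e) or normalize_text(e) for e in exclusions}
    by_doi: dict[str, list[str]] = {}
    by_title: dict[str, list[str]] = {}
    for r in corpus:
        k = r.key()
        if k.doi:
            by_doi.setdefault(k.doi, []).append(r.record_id)
        if k.title:
            by_title.setdefault(k.title, []).append(r.record_id)

    found: list[str] = []
    missing: list[dict] = []
    ambiguous: list[dict] = []
    excluded: list[dict] = []
    for key in relevant_keys:
        doi = normalize_doi(key.get("doi"))
        title = normalize_text(key.get("title", ""))
        if (doi and doi in excl) or (title and title in excl):
            excluded.append(dict(key))
            continue
        matches = by_doi.get(doi, []) if doi else []
        if not matches and title:
            matches = by_title.get(title, [])
        if not matches:
            missing.append(dict(key))
        elif len(matches) > 1:
            ambiguous.append({"key": dict(key), "record_ids": matches})
        else:
            corpus.set_label(matches[0], Label.RELEVANT)
            found.append(matches[0])
    return {
        "verdict": "complete" if not missing and not ambiguous else "incomplete",
        "found": found,
        "missing": missing,
        "ambiguous": ambiguous,
        "excluded": excluded,
        "k_r_plus": len(found),
    }


def report_to_json(report: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(report, indent=2), encoding="utf-8")
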