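"""Two-phase deduplication of bibliographic corpora.

Phase 1 (automatic): records sharing an identical non-empty normalized DOI,
or identical non-empty normalized title *and* abstract, are merged into one
survivor.  Phase 2 (assisted): near-identical titles are *flagged* as
semi-duplicate candidates for human review — nothing is deleted
automatically, because semi-duplicates (translations, follow-up reports,
indexing variants of the same study) need a judgement call.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import edlib

from .records import Corpus, Label, Record, normalize_text


@dataclass
class DedupReport:
    """Bookkeeping of one deduplication pass."""

    n_input: int = 0
    n_exact_removed: int = 0
    exact_groups: list[tuple[str, tuple[str, ...]]] = field(default_factory=list)
    semi_candidates: list[tuple[tuple[str, str], float, tuple[str, ...]]] = field(
        default_factory=list
    )
    n_output: int = 0

    def to_csv(self, path: str | Path) -> None:
        with Path(path).open("w", encoding="utf-8", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["kind", "kept_or_a", "removed_or_b", "similarity", "fields"])
            for kept, removed in self.exact_groups:
                w.writerow(["exact", kept, ";".join(removed), "", ""])
            for (a, b), sim, fields_ in self.semi_candidates:
                w.writerow(["semi", a, b, f"{sim:.4f}", ";".join(fields_)])


def _merged_label(labels: Iterable[Label]) -> Label:
    labels = set(labels)
    if Label.RELEVANT in labels:
        return Label.RELEVANT
    if Label.IRRELEVANT in labels:
        return Label.IRRELEVANT
    return Label.NOISY


class _UnionFind:
    def __init__(self, n: int):
        self.parent = list(range(n))

    def find(self, i: int) -> int:
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, i: int, j: int) -> None:
        ri, rj = self.find(i), self.find(j)
        if ri != rj:
            # keep the smaller index as root so survivors stay earliest
            if ri > rj:
                ri, rj = rj, ri
            self.parent[rj] = ri


def exact_dedup(corpus: Corpus) -> tuple[Corpus, DedupReport]:
    """Remove exact duplicates; one survivor per group, labels merged.

    A group's survivor is its first RELEVANT member if any, else its earliest
    member in corpus order.  The merged label is RELEVANT if any member is
    RELEVANT, else IRRELEVANT if any member is IRRELEVANT, else NOISY.
    """
    records = list(corpus)
    uf = _UnionFind(len(records))
    by_doi: dict[str, int] = {}
    by_text: dict[tuple[str, str], int] = {}
    for i, r in enumerate(records):
        k = r.key()
        if k.doi:
            if k.doi in by_doi:
                uf.union(by_doi[k.doi], i)
            else:
                by_doi[k.doi] = i
        if k.title and k.abstract:
            tk = (k.title, k.abstract)
            if tk in by_text:
                uf.union(by_text[tk], i)
            else:
                by_text[tk] = i

    groups: dict[int, list[int]] = {}
    for i in range(len(records)):
        groups.setdefault(uf.find(i), []).append(i)

    survivors: list[Record] = []
    report = DedupReport(n_input=len(records))
    for root in sorted(groups):
        members = groups[root]
        if len(members) == 1:
            survivors.append(records[members[0]])
            continue
        label = _merged_label(records[i].label for i in members)
        keep = next(
            (i for i in members if records[i].label is Label.RELEVANT), members[0]
        )
        survivors.append(records[keep].with_label(label))
        removed = tuple(records[i].record_id for i in members if i != keep)
        report.exact_groups.append((records[keep].record_id, removed))
        report.n_exact_removed += len(removed)

    order = {rid: i for i, rid in enumerate(corpus.record_ids)}
    survivors.sort(key=lambda r: order[r.record_id])
    report.n_output = len(survivors)
    out = Corpus(
        survivors,
        provenance=list(corpus.provenance)
        + [f"exact_dedup:removed={report.n_exact_removed}"],
    )
    return out, report


def title_similarity(a: str, b: str) -> float:
    """Normalized edit-distance similarity of two normalized titles, in [0,1]."""
    na, nb = normalize_text(a), normalize_text(b)
    if not na or not nb:
        return 0.0
    if na == nb:
        return 1.0
    dist = edlib.align(na, nb, task="distance")["editDistance"]
    return 1.0 - dist / max(len(na), len(nb))


def flag_semi_duplicates(corpus: Corpus, threshold: float = 0.9) -> DedupReport:
    """Flag candidate semi-duplicate pairs by title similarity; deletes nothing.

    Assumes the corpus is already exact-deduplicated.  Pairs with identical
    exact keys cannot occur then; pairs at or above ``threshold`` normalized
    edit similarity on titles are listed for manual review.
    """
    if not 0.0 <= threshold <= 1.0:
        raise ValueError(f"threshold must be in [0, 1], got {threshold}")
    records = list(corpus)
    keys = [r.key() for r in records]
    report = DedupReport(n_input=len(records), n_output=len(records))
    # length prefilter: |len(a)-len(b)| > (1-threshold)*max_len rules a pair out
    for i in range(len(records)):
        ti = keys[i].title
        if not ti:
            continue
        for j in range(i + 1, len(records)):
            tj = keys[j].title
            if not tj:
                continue
            max_len = max(len(ti), len(tj))
            if abs(len(ti) - len(tj)) > (1.0 - threshold) * max_len:
                continue
            if ti == tj:
                sim = 1.0
            else:
                d = edlib.align(ti, tj, task="distance")["editDistance"]
                sim = 1.0 - d / max_len
            if sim >= threshold:
                report.semi_candidates.append(
                    (
                        (records[i].record_id, records[j].record_id),
                        sim,
                        ("title",),
                    )
                )
    return report


@dataclass(frozen=True)
class ReviewDecision:
    """Outcome of a human look at one flagged semi-duplicate pair.

    ``delete`` names the member to remove, or ``None`` to keep both.
    """

    pair: tuple[str, str]
    delete: str | None = None


def apply_review_decisions(
    corpus: Corpus,
    report: DedupReport,
    decisions: Sequence[ReviewDecision],
) -> Corpus:
    """Apply manual review decisions to flagged semi-duplicate pairs.

    Deletions use the same label-merge rule as :func:`exact_dedup`: the
    surviving member of a pair inherits RELEVANT if either member was
    RELEVANT.
    """
    flagged = {frozenset(pair) for pair, _, _ in report.semi_candidates}
    to_remove: list[str] = []
    for d in decisions:
        if frozenset(d.pair) not in flagged:
            raise ValueError(f"pair {d.pair} was not a flagged candidate")
        if d.delete is None:
            continue
        if d.delete not in d.pair:
            raise ValueError(f"{d.delete!r} is not a member of pair {d.pair}")
        survivor = d.pair[0] if d.delete == d.pair[1] else d.pair[1]
        merged = _merged_label([corpus[d.delete].label, corpus[survivor].label])
        corpus = corpus.copy()
        corpus.set_label(survivor, merged)
        to_remove.append(d.delete)
    out = corpus.remove(to_remove)
    out.provenance.append(f"semi_dedup:removed={len(to_remove)}")
    return out
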