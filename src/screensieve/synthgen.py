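"""Synthetic labeled corpora with a controllable topical signal.

Emulates a reconstructed screening dataset: a heavily imbalanced corpus
(on the order of a thousand records, ~2% relevant) in which relevant records
share topical vocabulary.  Record texts are drawn token-by-token: relevant
records (and planted "additional relevant" records hidden in the noisy pool)
draw each token from a small signal vocabulary with probability ``s``
(the signal strength), otherwise from a long-tailed background distribution
(rank-frequency ∝ 1/rank, the shape of real title/abstract vocabularies).
The two vocabularies are disjoint, so ``s = 0`` makes relevant and irrelevant
records exchangeable in distribution and ``s = 1`` makes them perfectly
separable.

Exact duplicates (verbatim copies under a new record id) and semi-duplicates
(case/punctuation perturbations with truncated abstracts) are injected at
configurable rates, and every injected pair is recorded in the ground truth
so deduplication can be scored exactly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .records import Corpus, Label, Record


@dataclass(frozen=True)
class SynthConfig:
    """Generative parameters for one synthetic corpus.

    Defaults mirror a reconstructed systematic-review corpus: ~1050 records,
    20 known-relevant, moderate topical signal.
    """

    n_records: int = 1050
    n_relevant: int = 20
    signal_strength: float = 0.6
    background_vocab_size: int = 2000
    signal_vocab_size: int = 50
    title_length_mean: float = 10.0
    abstract_length_mean: float = 60.0
    exact_duplicate_rate: float = 0.0
    semi_duplicate_rate: float = 0.0
    n_planted_additional_relevant: int = 0
    fully_labeled: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.signal_strength <= 1.0:
            raise ValueError("signal_strength must be in [0, 1]")
        if self.n_relevant + self.n_planted_additional_relevant > self.n_records:
            raise ValueError(
                "n_relevant + n_planted_additional_relevant exceeds n_records"
            )
        for rate in (self.exact_duplicate_rate, self.semi_duplicate_rate):
            if not 0.0 <= rate < 1.0:
                raise ValueError("duplicate rates must be in [0, 1)")


@dataclass
class GroundTruth:
    """What the generator planted: true relevance, duplicates, planted ids."""

    relevant_ids: list[str] = field(default_factory=list)
    planted_additional_relevant_ids: list[str] = field(default_factory=list)
    exact_duplicate_pairs: list[tuple[str, str]] = field(default_factory=list)
    semi_duplicate_pairs: list[tuple[str, str]] = field(default_factory=list)

    @property
    def all_relevant_ids(self) -> set[str]:
        return set(self.relevant_ids) | set(self.planted_additional_relevant_ids)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "relevant_ids": self.relevant_ids,
                    "planted_additional_relevant_ids": self.planted_additional_relevant_ids,
                    "exact_duplicate_pairs": self.exact_duplicate_pairs,
                    "semi_duplicate_pairs": self.semi_duplicate_pairs,
                },
                indent=2,
            ),
            encoding="utf-8",
        )


def _zipf_probs(size: int) -> np.ndarray:
    ranks = np.arange(1, size + 1, dtype=float)
    p = 1.0 / ranks
    return p / p.sum()


def _draw_text(
    rng: np.random.Generator,
    n_tokens: int,
    s: float,
    background: np.ndarray,
    bg_probs: np.ndarray,
    signal: np.ndarray,
) -> str:
    if n_tokens <= 0:
        return ""
    use_signal = rng.random(n_tokens) < s
    tokens = np.where(
        use_signal,
        signal[rng.integers(0, len(signal), size=n_tokens)],
        background[rng.choice(len(background), size=n_tokens, p=bg_probs)],
    )
    return " ".join(tokens.tolist())


def _perturb_title(rng: np.random.Generator, title: str) -> str:
    """Case/punctuation variant of a title, as database indexing produces."""
    words = title.split()
    words = [w.capitalize() if rng.random() < 0.5 else w.upper() for w in words]
    text = " ".join(words)
    if rng.random() < 0.5:
        text += "."
    if len(words) > 3 and rng.random() < 0.5:
        # drop one word, as truncated indexing sometimes does
        i = int(rng.integers(0, len(words)))
        text = " ".join(words[:i] + words[i + 1:])
    return text


def generate(config: SynthConfig) -> tuple[Corpus, GroundTruth]:
    """Generate a corpus and its ground truth, deterministically from the seed."""
    rng = np.random.default_rng(np.random.SeedSequence(config.seed))
    background = np.array(
        [f"w{i:05d}" for i in range(config.background_vocab_size)]
    )
    signal = np.array([f"topic{i:03d}" for i in range(config.signal_vocab_size)])
    bg_probs = _zipf_probs(config.background_vocab_size)

    n = config.n_records
    idx = rng.permutation(n)
    relevant_idx = set(idx[: config.n_relevant].tolist())
    planted_idx = set(
        idx[config.n_relevant: config.n_relevant
            + config.n_planted_additional_relevant].tolist()
    )

    truth = GroundTruth()
    records: list[Record] = []
    for i in range(n):
        carries_signal = i in relevant_idx or i in planted_idx
        s = config.signal_strength if carries_signal else 0.0
        n_title = max(1, int(rng.poisson(config.title_length_mean)))
        n_abs = max(1, int(rng.poisson(config.abstract_length_mean)))
        rid = f"syn{i:05d}"
        if i in relevant_idx:
            label = Label.RELEVANT
            truth.relevant_ids.append(rid)
        elif i in planted_idx:
            label = Label.IRRELEVANT if config.fully_labeled else Label.NOISY
            truth.planted_additional_relevant_ids.append(rid)
        else:
            label = Label.IRRELEVANT if config.fully_labeled else Label.NOISY
        records.append(
            Record(
                record_id=rid,
                title=_draw_text(rng, n_title, s, background, bg_probs, signal),
                abstract=_draw_text(rng, n_abs, s, background, bg_probs, signal),
                doi=f"10.9999/syn.{i:05d}",
                year=int(rng.integers(1990, 2024)),
                authors=(f"Author {i % 97}",),
                label=label,
            )
        )

    n_exact = int(round(config.exact_duplicate_rate * n))
    n_semi = int(round(config.semi_duplicate_rate * n))
    if n_exact + n_semi > 0:
        originals = rng.choice(n, size=n_exact + n_semi, replace=False)
        for j, oi in enumerate(originals[:n_exact]):
            src = records[oi]
            rid = f"dup{j:05d}"
            records.append(
                Record(
                    record_id=rid,
                    title=src.title,
                    abstract=src.abstract,
                    doi=src.doi,
                    year=src.year,
                    authors=src.authors,
                    label=src.label if config.fully_labeled else Label.NOISY,
                )
            )
            truth.exact_duplicate_pairs.append((src.record_id, rid))
        for j, oi in enumerate(originals[n_exact:]):
            src = records[oi]
            rid = f"semi{j:05d}"
            half = src.abstract[: max(1, len(src.abstract) // 2)]
            records.append(
                Record(
                    record_id=rid,
                    title=_perturb_title(rng, src.title),
                    abstract=half,
                    doi=None,
                    year=src.year,
                    authors=src.authors,
                    label=src.label if config.fully_labeled else Label.NOISY,
                )
            )
            truth.semi_duplicate_pairs.append((src.record_id, rid))

    corpus = Corpus(records, provenance=[f"synthgen:seed={config.seed}"])
    return corpus, truth


def oracle_screener(truth: GroundTruth):
    """Screener callback answering from ground truth (stands in for a human)."""
    relevant = truth.all_relevant_ids

    def screen(record: Record) -> Label:
        if not record.record_id.startswith(("syn", "dup", "semi")):
            raise KeyError(f"unknown record {record.record_id!r}")
        return Label.RELEVANT if record.record_id in relevant else Label.IRRELEVANT

    return screen
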