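"""The Noisy Label Filter (NLF) procedure.

A reconstructed screening dataset contains records whose relevance was never
verified ("noisy labels").  Labeling them all irrelevant risks burying
additional relevant records.  The NLF procedure screens only the noisy
records a model considers most likely relevant, and stops once *x*
consecutive screened records turn out irrelevant — at which point the
remaining noisy records can be labeled irrelevant with much more confidence.

Training starts from all known-relevant records plus a handful of random
noisy records presumed irrelevant; those presumed negatives stand in for
unverified class-0 examples and are never promoted, however high the model
scores them.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable

import numpy as np

from .engine import ModelSpec, build_features, rank_unlabeled, train
from .records import Corpus, Label

Screener = Callable[[object], Label]


class ScreenerError(RuntimeError):
    """Raised when the screener callback fails; carries the partial trace."""

    def __init__(self, message: str, partial_steps: tuple[tuple[str, Label], ...]):
        super().__init__(message)
        self.partial_steps = partial_steps


@dataclass(frozen=True)
class NLFConfig:
    """Stopping rule, training-set construction and model for one NLF run."""

    n_random_irrelevant_priors: int = 5
    consecutive_irrelevant_stop: int = 50
    record_budget: int | None = None
    model: ModelSpec = field(default_factory=ModelSpec)
    seed: int = 0
    retrain_every: int = 1

    def __post_init__(self) -> None:
        if self.consecutive_irrelevant_stop < 1:
            raise ValueError("consecutive_irrelevant_stop must be >= 1")
        if self.n_random_irrelevant_priors < 1:
            raise ValueError(
                "need at least one presumed-irrelevant prior (training "
                "requires both classes)"
            )
        if self.record_budget is not None and self.record_budget < 1:
            raise ValueError("record_budget must be >= 1 or None")


@dataclass
class NLFResult:
    """Outcome of one NLF run."""

    trace: "ScreeningTrace"
    flagged_relevant: list[str]
    stop_reason: str  # consecutive_irrelevant | budget | pool_exhausted
    output_corpus: Corpus
    presumed_irrelevant_priors: tuple[str, ...] = ()

    def trace_to_csv(self, path: str | Path) -> None:
        with Path(path).open("w", encoding="utf-8", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["position", "record_id", "label"])
            for pos, (rid, lab) in enumerate(self.trace.steps, start=1):
                w.writerow([pos, rid, lab.value])


def run_nlf(corpus: Corpus, config: NLFConfig, screener: Screener) -> NLFResult:
    """Screen model-prioritized noisy records until the stopping rule fires.

    ``screener`` is called with each presented :class:`Record` and must
    return RELEVANT or IRRELEVANT.  The trace records screened noisy records
    only; the presumed-irrelevant priors are reported separately and never
    counted as screened.  The returned corpus still contains NOISY labels;
    apply :func:`apply_outcome` to resolve them.
    """
    from .simulate import ScreeningTrace

    relevant = list(corpus.ids_with_label(Label.RELEVANT))
    noisy = list(corpus.ids_with_label(Label.NOISY))
    if not relevant:
        raise ValueError(
            "no RELEVANT records: the procedure needs the known inclusions "
            "as positive training data"
        )
    if not noisy:
        raise ValueError("no NOISY records to filter")

    rng = np.random.default_rng(np.random.SeedSequence(config.seed))
    n_priors = min(config.n_random_irrelevant_priors, len(noisy))
    prior_idx = sorted(rng.choice(len(noisy), size=n_priors, replace=False))
    priors = [noisy[i] for i in prior_idx]

    features = build_features(corpus)
    labeled: dict[str, Label] = {rid: Label.RELEVANT for rid in relevant}
    labeled.update({rid: Label.IRRELEVANT for rid in priors})
    pool = set(noisy) - set(priors)

    steps: list[tuple[str, Label]] = []
    flagged: list[str] = []
    run_length = 0
    stop_reason = "pool_exhausted"
    ranking: list[str] = []
    since_retrain = config.retrain_every
    while pool:
        if run_length >= config.consecutive_irrelevant_stop:
            stop_reason = "consecutive_irrelevant"
            break
        if config.record_budget is not None and len(steps) >= config.record_budget:
            stop_reason = "budget"
            break
        if since_retrain >= config.retrain_every or not ranking:
            predictor = train(config.model, features, labeled)
            ranking = list(rank_unlabeled(predictor, features, pool).order)
            since_retrain = 0
        rid = next(r for r in ranking if r in pool)
        record = corpus[rid]
        try:
            lab = screener(record)
        except Exception as exc:
            raise ScreenerError(
                f"screener failed on record {rid!r} after {len(steps)} labels: {exc}",
                partial_steps=tuple(steps),
            ) from exc
        if lab not in (Label.RELEVANT, Label.IRRELEVANT):
            raise ScreenerError(
                f"screener returned invalid label {lab!r} for record {rid!r}",
                partial_steps=tuple(steps),
            )
        steps.append((rid, lab))
        labeled[rid] = lab
        pool.discard(rid)
        since_retrain += 1
        if lab is Label.RELEVANT:
            flagged.append(rid)
            run_length = 0
        else:
            run_length += 1
    else:
        if run_length >= config.consecutive_irrelevant_stop:
            stop_reason = "consecutive_irrelevant"

    out = corpus.copy()
    for rid, lab in steps:
        if lab is Label.IRRELEVANT:
            out.set_label(rid, Label.IRRELEVANT)
    out.provenance.append(
        f"nlf:screened={len(steps)},flagged={len(flagged)},stop={stop_reason}"
    )
    trace = ScreeningTrace(
        steps=tuple(steps),
        priors=tuple(priors),
        pool_size=len(noisy) - len(priors),
        n_relevant_pool=len(flagged),
    )
    return NLFResult(
        trace=trace,
        flagged_relevant=flagged,
        stop_reason=stop_reason,
        output_corpus=out,
        presumed_irrelevant_priors=tuple(priors),
    )


def apply_outcome(result: NLFResult, policy: dict[str, str]) -> Corpus:
    """Resolve every remaining noisy label after an NLF run.

    ``policy`` maps each flagged record id to one of ``keep_relevant`` /
    ``remove`` / ``mark_irrelevant``.  All screened-irrelevant and all
    unscreened noisy records become IRRELEVANT; the result has no NOISY
    labels left.
    """
    missing = [rid for rid in result.flagged_relevant if rid not in policy]
    if missing:
        raise ValueError(f"policy missing flagged record(s): {missing}")
    valid = {"keep_relevant", "remove", "mark_irrelevant"}
    bad = {v for v in policy.values()} - valid
    if bad:
        raise ValueError(f"unknown policy action(s): {sorted(bad)}")

    corpus = result.output_corpus.copy()
    to_remove = []
    for rid in result.flagged_relevant:
        action = policy[rid]
        if action == "keep_relevant":
            corpus.set_label(rid, Label.RELEVANT)
        elif action == "mark_irrelevant":
            corpus.set_label(rid, Label.IRRELEVANT)
        else:
            to_remove.append(rid)
    corpus = corpus.remove(to_remove)
    for rid in corpus.ids_with_label(Label.NOISY):
        corpus.set_label(rid, Label.IRRELEVANT)
    corpus.provenance.append(
        f"nlf_outcome:removed={len(to_remove)}"
    )
    return corpus
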