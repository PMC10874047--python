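"""Screening simulation on a fully labeled corpus.

Mimics a screener using model prioritization: starting from seeded prior
knowledge (one relevant and one irrelevant record by default), the model is
retrained on everything labelled so far, the pool is ranked, the top record
is "screened" and its true label revealed, until every relevant record has
been found (or the pool is exhausted).  The resulting trace is the input to
the metrics module.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .engine import FeatureMatrix, ModelSpec, build_features, rank_unlabeled, train
from .records import Corpus, Label


@dataclass(frozen=True)
class ScreeningTrace:
    """Ordered (record_id, revealed label) pairs for screened non-prior records."""

    steps: tuple[tuple[str, Label], ...]
    priors: tuple[str, ...]
    pool_size: int
    n_relevant_pool: int

    def __post_init__(self) -> None:
        ids = [rid for rid, _ in self.steps]
        if len(set(ids)) != len(ids):
            raise ValueError("trace contains duplicate record ids")
        if len(ids) > self.pool_size:
            raise ValueError("trace longer than pool")

    @property
    def relevant_ids(self) -> tuple[str, ...]:
        return tuple(rid for rid, lab in self.steps if lab is Label.RELEVANT)

    def to_csv(self, path: str | Path, run: int = 0) -> None:
        with Path(path).open("a", encoding="utf-8", newline="") as fh:
            w = csv.writer(fh)
            for pos, (rid, lab) in enumerate(self.steps, start=1):
                w.writerow([run, pos, rid, lab.value])


@dataclass(frozen=True)
class SimulationConfig:
    """One simulation condition: model, priors, stop rule, seeding."""

    model: ModelSpec
    prior_relevant: Sequence[str] | str = "random:1"
    prior_irrelevant: Sequence[str] | str = "random:1"
    seed: int = 0
    n_runs: int = 1
    stop: str = "all_relevant_found"  # or "full_pool"
    retrain_every: int = 1

    def __post_init__(self) -> None:
        if self.stop not in ("all_relevant_found", "full_pool"):
            raise ValueError(f"unknown stop rule {self.stop!r}")
        if self.retrain_every < 1:
            raise ValueError("retrain_every must be >= 1")


def _resolve_priors(
    spec: Sequence[str] | str, pool: Sequence[str], rng: np.random.Generator
) -> list[str]:
    if isinstance(spec, str):
        if not spec.startswith("random:"):
            raise ValueError(f"unknown prior spec {spec!r}")
        k = int(spec.split(":", 1)[1])
        if k < 1:
            raise ValueError("need at least one prior per class")
        if k > len(pool):
            raise ValueError("not enough records in stratum for priors")
        idx = rng.choice(len(pool), size=k, replace=False)
        return [pool[i] for i in sorted(idx)]
    return list(spec)


def _screening_loop(
    features: FeatureMatrix,
    true_labels: dict[str, Label],
    prior_labels: dict[str, Label],
    model: ModelSpec,
    stop: str,
    retrain_every: int,
    n_relevant_pool: int,
) -> tuple[tuple[str, Label], ...]:
    """Certainty-strategy loop shared by simulation runs."""
    labeled = dict(prior_labels)
    pool = set(true_labels) - set(prior_labels)
    steps: list[tuple[str, Label]] = []
    found = 0
    ranking: list[str] = []
    since_retrain = retrain_every  # force a train on first iteration
    while pool:
        if stop == "all_relevant_found" and found >= n_relevant_pool:
            break
        if since_retrain >= retrain_every or not ranking:
            predictor = train(model, features, labeled)
            ranking = [
                rid for rid in rank_unlabeled(predictor, features, pool).order
            ]
            since_retrain = 0
        rid = next(r for r in ranking if r in pool)
        lab = true_labels[rid]
        steps.append((rid, lab))
        labeled[rid] = lab
        pool.discard(rid)
        since_retrain += 1
        if lab is Label.RELEVANT:
            found += 1
    return tuple(steps)


def run_simulation(
    corpus: Corpus, config: SimulationConfig
) -> list[ScreeningTrace]:
    """Simulate screening runs on a fully labeled corpus, one trace per run."""
    counts = corpus.label_counts()
    if counts[Label.NOISY] > 0:
        raise ValueError(
            f"corpus has {counts[Label.NOISY]} NOISY records; run the noisy "
            "label filter first to obtain a fully labeled corpus"
        )
    relevant = list(corpus.ids_with_label(Label.RELEVANT))
    irrelevant = list(corpus.ids_with_label(Label.IRRELEVANT))
    for spec in (config.prior_relevant, config.prior_irrelevant):
        if not isinstance(spec, str):
            unknown = [rid for rid in spec if rid not in corpus]
            if unknown:
                raise ValueError(f"prior ids not in corpus: {unknown}")
    features = build_features(corpus)
    true_labels = {r.record_id: r.label for r in corpus}
    root = np.random.SeedSequence(config.seed)
    traces: list[ScreeningTrace] = []
    for run_ss in root.spawn(config.n_runs):
        rng = np.random.default_rng(run_ss)
        prior_rel = _resolve_priors(config.prior_relevant, relevant, rng)
        prior_irr = _resolve_priors(config.prior_irrelevant, irrelevant, rng)
        priors = {rid: Label.RELEVANT for rid in prior_rel}
        priors.update({rid: Label.IRRELEVANT for rid in prior_irr})
        n_rel_pool = len(relevant) - len(prior_rel)
        steps = _screening_loop(
            features,
            true_labels,
            priors,
            config.model,
            config.stop,
            config.retrain_every,
            n_rel_pool,
        )
        traces.append(
            ScreeningTrace(
                steps=steps,
                priors=tuple(prior_rel) + tuple(prior_irr),
                pool_size=len(corpus) - len(priors),
                n_relevant_pool=n_rel_pool,
            )
        )
    return traces


def multi_model_compare(
    corpus: Corpus, configs: Sequence[SimulationConfig]
) -> dict[str, list[ScreeningTrace]]:
    """Run several models under identical priors and seeds.

    All configs must share priors and seed so the comparison varies only the
    model.  Returns traces keyed by classifier name.
    """
    keys = {
        (tuple(c.prior_relevant), tuple(c.prior_irrelevant), c.seed)
        if not isinstance(c.prior_relevant, str)
        else (c.prior_relevant, c.prior_irrelevant, c.seed)
        for c in configs
    }
    if len(keys) != 1:
        raise ValueError("all configs must share priors and seed")
    out: dict[str, list[ScreeningTrace]] = {}
    for c in configs:
        out[c.model.classifier_name] = run_simulation(corpus, c)
    return out


def recall_table(
    traces_by_model: dict[str, list[ScreeningTrace]], path: str | Path
) -> None:
    """Write a combined plot-ready recall-curve table (CSV).

    Includes the random-screening diagonal as model ``random`` for reference.
    """
    from .metrics import mean_recall_curve

    with Path(path).open("w", encoding="utf-8", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["model", "proportion_screened", "proportion_found"])
        n = None
        for model, traces in traces_by_model.items():
            curve = mean_recall_curve(traces)
            n = traces[0].pool_size
            for i, rec in curve:
                w.writerow([model, f"{i / n:.6f}", f"{rec:.6f}"])
        if n:
            for i in range(1, n + 1):
                w.writerow(["random", f"{i / n:.6f}", f"{i / n:.6f}"])
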