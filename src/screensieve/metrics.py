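"""Evaluation statistics for screening traces.

Given the ordered labels revealed during a (simulated or real) screening run,
these functions compute the standard prioritization metrics:

* the recall curve — cumulative relevant records found vs. records screened;
* WSS@R, work saved over sampling at recall level R:
  ``(N - i*)/N - (1 - R)`` where ``i*`` is the smallest number of screened
  records whose cumulative relevant count reaches ``ceil(R * rho)``;
* ERF@f, the proportion of relevant records found after screening a fraction
  ``f`` of the pool;
* TD / ATD, the (average) 1-based screening position at which each relevant
  record is discovered.

Prior-knowledge records are excluded throughout: the pool and all positions
count only records actually screened.  Internal values are proportions;
percent formatting belongs to the reporting layer.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

from .records import Label
from .simulate import ScreeningTrace


def recall_curve(trace: ScreeningTrace) -> list[tuple[int, int]]:
    """Points (records screened, cumulative relevant found); empty trace → []."""
    points = []
    found = 0
    for i, (_, label) in enumerate(trace.steps, start=1):
        if label is Label.RELEVANT:
            found += 1
        points.append((i, found))
    return points


def wss_at(trace: ScreeningTrace, recall_level: float = 0.95) -> float:
    """Work saved over sampling at the given recall level.

    Raises if the trace never reaches the recall milestone
    ``ceil(recall_level * n_relevant_pool)``.
    """
    if not 0.0 < recall_level <= 1.0:
        raise ValueError(f"recall_level must be in (0, 1], got {recall_level}")
    n = trace.pool_size
    rho = trace.n_relevant_pool
    if n < 1 or rho < 1:
        raise ValueError("pool must contain at least one record and one relevant")
    target = math.ceil(recall_level * rho)
    found = 0
    for i, (_, label) in enumerate(trace.steps, start=1):
        if label is Label.RELEVANT:
            found += 1
            if found >= target:
                return (n - i) / n - (1.0 - recall_level)
    raise ValueError(
        f"trace reaches recall {found}/{rho}, below the {recall_level:.0%} milestone"
    )


def erf_at(trace: ScreeningTrace, screened_fraction: float = 0.10) -> float:
    """Proportion of relevant records found within the first ``floor(f*N)`` screened."""
    if not 0.0 < screened_fraction <= 1.0:
        raise ValueError(
            f"screened_fraction must be in (0, 1], got {screened_fraction}"
        )
    cutoff = math.floor(screened_fraction * trace.pool_size)
    n_found_total = sum(
        1 for _, label in trace.steps if label is Label.RELEVANT
    )
    if len(trace.steps) < cutoff and n_found_total < trace.n_relevant_pool:
        # a trace that stopped once all relevant were found may legitimately
        # be shorter than the cutoff; an incomplete one cannot
        raise ValueError(
            f"trace covers {len(trace.steps)} records, fewer than the "
            f"{cutoff} needed for f={screened_fraction}"
        )
    found = sum(
        1 for _, label in trace.steps[:cutoff] if label is Label.RELEVANT
    )
    return found / trace.n_relevant_pool


def time_to_discovery(trace: ScreeningTrace, record_id: str) -> int:
    """1-based screening position of a relevant record (priors excluded)."""
    for i, (rid, label) in enumerate(trace.steps, start=1):
        if rid == record_id:
            if label is not Label.RELEVANT:
                raise ValueError(f"record {record_id!r} is not relevant")
            return i
    raise ValueError(f"record {record_id!r} was not screened in this trace")


def atd(traces: Sequence[ScreeningTrace]) -> float:
    """Average time to discovery.

    Per relevant record, TD is averaged across traces (runs); those per-record
    means are then averaged across all relevant records.  Every trace must
    cover the same pool and discover every relevant record.
    """
    if not traces:
        raise ValueError("need at least one trace")
    pools = {frozenset(t.relevant_ids) for t in traces}
    if len(pools) != 1:
        raise ValueError("traces have inconsistent relevant pools")
    relevant = sorted(pools.pop())
    if not relevant:
        raise ValueError("no relevant records in pool")
    per_record_means = [
        sum(time_to_discovery(t, rid) for t in traces) / len(traces)
        for rid in relevant
    ]
    return sum(per_record_means) / len(per_record_means)


@dataclass
class MetricsReport:
    """All metrics for one model's trace set, plus plot-ready curve points."""

    model: str
    wss_at_95: float
    erf_at_10: float
    td: dict[str, list[int]]
    atd: float
    recall_curve: list[tuple[int, float]] = field(default_factory=list)
    n_runs: int = 1
    pool_size: int = 0
    n_relevant_pool: int = 0

    def as_dict(self) -> dict:
        return {
            "model": self.model,
            "wss_at_95": self.wss_at_95,
            "erf_at_10": self.erf_at_10,
            "wss_at_95_percent": round(100 * self.wss_at_95, 2),
            "erf_at_10_percent": round(100 * self.erf_at_10, 2),
            "atd": self.atd,
            "td": self.td,
            "n_runs": self.n_runs,
            "pool_size": self.pool_size,
            "n_relevant_pool": self.n_relevant_pool,
            "recall_curve": self.recall_curve,
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(self.as_dict(), indent=2, sort_keys=True), encoding="utf-8"
        )


def mean_recall_curve(traces: Sequence[ScreeningTrace]) -> list[tuple[int, float]]:
    """Recall averaged over traces at each screened count.

    Traces that stopped once all relevant were found are held at full recall
    beyond their end.
    """
    n = max(t.pool_size for t in traces)
    points = []
    for i in range(1, n + 1):
        vals = []
        for t in traces:
            if i <= len(t.steps):
                found = sum(
                    1 for _, lab in t.steps[:i] if lab is Label.RELEVANT
                )
            else:
                found = t.n_relevant_pool
            vals.append(found / t.n_relevant_pool)
        points.append((i, sum(vals) / len(vals)))
    return points


def summarize(traces: Sequence[ScreeningTrace], model: str) -> MetricsReport:
    """Aggregate all metrics over one model's runs."""
    if not traces:
        raise ValueError("need at least one trace")
    td: dict[str, list[int]] = {}
    for t in traces:
        for rid in sorted(t.relevant_ids):
            td.setdefault(rid, []).append(time_to_discovery(t, rid))
    return MetricsReport(
        model=model,
        wss_at_95=sum(wss_at(t) for t in traces) / len(traces),
        erf_at_10=sum(erf_at(t) for t in traces) / len(traces),
        td=td,
        atd=atd(traces),
        recall_curve=mean_recall_curve(traces),
        n_runs=len(traces),
        pool_size=traces[0].pool_size,
        n_relevant_pool=traces[0].n_relevant_pool,
    )
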