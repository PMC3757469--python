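"""Qualitative activity classification and benchmarking against experiment.

Experimental fold-wild-type activities and computed barriers are reduced to
qualitative activity factors: a mutant at or above ``improve_min`` fold-WT
(default 1.2) is improving (+1), at or below ``degrade_max`` (default 0.8)
degrading (-1), in between neutral (0, excluded from agreement counts).
Computationally, a barrier at or above the cutoff c_S predicts degraded
activity (-1), below it improved (+1).  The cutoff is chosen by scanning
candidates to maximize agreement with experiment; for prospective screening
one simply ranks kept mutants by ascending barrier.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .mutants import MutantID, parse_mutant
from .profiles import BarrierAnalysis


@dataclass(frozen=True)
class ActivityRecord:
    """One benchmark-set mutant: measured activity and computed barrier."""

    mutant: str
    activity: float
    barrier: float
    organism: str | None = None

    def __post_init__(self) -> None:
        if self.activity < 0:
            raise ValueError("activity (fold-WT) must be >= 0")
        if not math.isfinite(self.barrier):
            raise ValueError("barrier must be finite")


@dataclass(frozen=True)
class ClassificationThresholds:
    improve_min: float = 1.2
    degrade_max: float = 0.8
    barrier_cutoff: float = 12.5
    high_activity_min: float = 3.0
    low_activity_max: float = 0.5

    def __post_init__(self) -> None:
        if not self.improve_min > self.degrade_max > 0:
            raise ValueError("require improve_min > degrade_max > 0")


def experimental_factor(
    activity: float, thresholds: ClassificationThresholds | None = None
) -> int:
    """+1 improving / -1 degrading / 0 neutral, from fold-WT activity."""
    t = thresholds or ClassificationThresholds()
    if activity < 0:
        raise ValueError("activity must be >= 0")
    if activity >= t.improve_min:
        return 1
    if activity <= t.degrade_max:
        return -1
    return 0


def computational_factor(barrier: float, cutoff: float = 12.5) -> int:
    """-1 (likely degraded) if barrier >= cutoff, else +1 (likely improved)."""
    return -1 if barrier >= cutoff else 1


@dataclass(frozen=True)
class SubgroupResult:
    threshold: float
    size: int
    n_correct: int


@dataclass(frozen=True)
class MutantComparison:
    mutant: str
    exp_factor: int
    comp_factor: int
    agree: bool


@dataclass(frozen=True)
class BenchmarkReport:
    n_records: int
    comparisons: tuple[MutantComparison, ...]
    n_agree: int
    agreement_rate: float
    high_activity: SubgroupResult
    low_activity: SubgroupResult
    neutral_excluded: tuple[str, ...] = ()

    @property
    def agreement_percent(self) -> int:
        return round(100 * self.agreement_rate)


def benchmark(
    records: Sequence[ActivityRecord],
    thresholds: ClassificationThresholds | None = None,
) -> BenchmarkReport:
    """Compare experimental and computed activity factors over a record set.

    Agreement is counted over records with a nonzero experimental factor;
    neutral records are excluded and listed.  Subgroup hit counts are
    reported for the high-activity (>= ``high_activity_min`` fold) and
    low-activity (<= ``low_activity_max`` fold) subsets.
    """
    if not records:
        raise ValueError("empty record set")
    t = thresholds or ClassificationThresholds()
    comparisons: list[MutantComparison] = []
    neutral: list[str] = []
    for r in records:
        ef = experimental_factor(r.activity, t)
        if ef == 0:
            neutral.append(r.mutant)
            continue
        cf = computational_factor(r.barrier, t.barrier_cutoff)
        comparisons.append(
            MutantComparison(mutant=r.mutant, exp_factor=ef, comp_factor=cf,
                             agree=ef == cf)
        )
    n = len(comparisons)
    n_agree = sum(c.agree for c in comparisons)
    agree_by_mutant = {c.mutant: c.agree for c in comparisons}

    def subgroup(selector, threshold: float) -> SubgroupResult:
        members = [r for r in records if selector(r.activity) and r.mutant in agree_by_mutant]
        return SubgroupResult(
            threshold=threshold,
            size=len(members),
            n_correct=sum(agree_by_mutant[r.mutant] for r in members),
        )

    return BenchmarkReport(
        n_records=n,
        comparisons=tuple(comparisons),
        n_agree=n_agree,
        agreement_rate=n_agree / n if n else 0.0,
        high_activity=subgroup(lambda a: a >= t.high_activity_min, t.high_activity_min),
        low_activity=subgroup(lambda a: a <= t.low_activity_max, t.low_activity_max),
        neutral_excluded=tuple(neutral),
    )


@dataclass(frozen=True)
class CutoffScan:
    candidates: tuple[tuple[float, int], ...]  # (cutoff, agreement count)
    max_agreement: int
    optimal_cutoffs: tuple[float, ...]


def optimize_cutoff(
    records: Sequence[ActivityRecord],
    thresholds: ClassificationThresholds | None = None,
) -> CutoffScan:
    """Scan barrier cutoffs for maximal agreement with experiment.

    Candidates are every observed barrier value plus midpoints between
    adjacent distinct sorted barriers; all candidates attaining the maximum
    are reported, since the optimum is generally a plateau.
    """
    t = thresholds or ClassificationThresholds()
    barriers = sorted({r.barrier for r in records})
    if len(barriers) < 2:
        raise ValueError("need at least 2 distinct barrier values to scan")
    candidates = sorted(
        set(barriers)
        | {(a + b) / 2 for a, b in zip(barriers, barriers[1:])}
    )
    scored: list[tuple[float, int]] = []
    for c in candidates:
        n_agree = sum(
            experimental_factor(r.activity, t) == computational_factor(r.barrier, c)
            for r in records
            if experimental_factor(r.activity, t) != 0
        )
        scored.append((c, n_agree))
    max_agreement = max(s for _, s in scored)
    return CutoffScan(
        candidates=tuple(scored),
        max_agreement=max_agreement,
        optimal_cutoffs=tuple(c for c, s in scored if s == max_agreement),
    )


def rank_candidates(
    analyses: Iterable[BarrierAnalysis | tuple[str, float]],
    n: int,
) -> list[tuple[str, float]]:
    """The ``n`` mutants with the lowest barriers, ascending.

    Ties break on the canonical mutant string for reproducibility.  If ``n``
    exceeds the pool, the whole pool is returned.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    pool = [
        (a.mutant, a.barrier) if isinstance(a, BarrierAnalysis) else (a[0], a[1])
        for a in analyses
    ]
    pool.sort(key=lambda p: (p[1], p[0]))
    return pool[:n]


@dataclass(frozen=True)
class CompositionSummary:
    by_order: dict[int, int] = field(default_factory=dict)
    by_position: dict[int, int] = field(default_factory=dict)


def composition_summary(
    mutants: Iterable[MutantID | str],
) -> CompositionSummary:
    """Histogram of mutant orders and per-position occurrence counts."""
    ids = [parse_mutant(m) if isinstance(m, str) else m for m in mutants]
    by_order = Counter(m.order for m in ids)
    by_position = Counter(p for m in ids for p in m.positions)
    return CompositionSummary(
        by_order=dict(sorted(by_order.items())),
        by_position=dict(sorted(by_position.items())),
    )
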