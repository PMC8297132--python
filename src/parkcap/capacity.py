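"""Carrying-capacity estimation under social distancing.

A simulated day *exceeds the threshold* when at least ``n_visitors``
(default 3) distinct visitors each fail to keep the 2 m distance for the
critical period (headline 10 min; the sweep covers 1-64 min). Because single
days are stochastic, each candidate daily total N is classified by majority
over 10 replicate days ("over" when at least 5 of 10 exceed). The park
capacity for a critical period is the largest daily total classified
"under": found by doubling upward from N=10 to bracket the first "over",
then bisecting to the boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import behavior as bh
from .engine import DayResult, EngineConfig, run_day

HEADLINE_PERIOD_MIN = 10.0
SWEEP_PERIODS_MIN = (1.0, 2.0, 4.0, 8.0, 16.0, 32.0, 64.0)
N_REPLICATES = 10
CONFIRMATION_MAJORITY = 5  # "over" needs at least 5 of 10 exceeding days
HARD_CAP = 10 ** 6


@dataclass(frozen=True)
class CriticalPeriod:
    """Continuous contact duration treated as the onset of infection risk."""

    minutes: float = HEADLINE_PERIOD_MIN

    def __post_init__(self):
        if self.minutes <= 0:
            raise ValueError("critical period must be positive")

    @property
    def ticks(self) -> int:
        return int(round(self.minutes * bh.TICKS_PER_MINUTE))


@dataclass(frozen=True)
class ThresholdRule:
    """Day-level failure rule: n_visitors each violating for the period."""

    n_visitors: int = 3
    period: CriticalPeriod = field(default_factory=CriticalPeriod)
    episode_mode: str = "continuous"  # or "cumulative"

    def __post_init__(self):
        if self.n_visitors < 1:
            raise ValueError("n_visitors must be >= 1")
        if self.episode_mode not in ("continuous", "cumulative"):
            raise ValueError(f"unknown episode mode {self.episode_mode!r}")


@dataclass
class CapacityResult:
    capacity: int
    period: CriticalPeriod
    replicate_outcomes: dict[int, list[bool]] = field(default_factory=dict)
    search_trace: list[tuple[int, str]] = field(default_factory=list)
    seeds: list[int] = field(default_factory=list)
    at_cap: bool = False  # no "over" found below the hard cap


def day_exceeds_threshold(day: DayResult, rule: ThresholdRule) -> bool:
    """True iff enough distinct visitors violated distancing for the period."""
    need = rule.period.ticks
    per_visitor = (day.max_violation if rule.episode_mode == "continuous"
                   else day.total_violation)
    count = sum(1 for v in per_visitor.values() if v >= need)
    return count >= rule.n_visitors


def replicate_seeds(base_seed: int, n: int = N_REPLICATES) -> list[int]:
    """n distinct replicate seeds derived from one base seed."""
    ss = np.random.SeedSequence(base_seed)
    return [int(s) % (2 ** 31) for s in ss.generate_state(n)]


def classify_N(N: int, config: EngineConfig, rule: ThresholdRule,
               seeds: list[int]) -> tuple[str, list[bool]]:
    """Classify daily total N as 'over' or 'under' by majority of replicates.

    Runs one simulated day per seed at ``daily_total=N`` (each day may stop
    early once the threshold is provably exceeded) and returns the label and
    the per-replicate exceed flags.
    """
    if len(set(seeds)) != len(seeds):
        raise ValueError("replicate seeds must be distinct")
    flags = []
    for seed in seeds:
        day = run_day(config.replace(daily_total=N, seed=seed), stop_rule=rule)
        flags.append(day_exceeds_threshold(day, rule))
    label = "over" if sum(flags) >= CONFIRMATION_MAJORITY else "under"
    return label, flags


def estimate_capacity(config: EngineConfig, rule: ThresholdRule,
                      seeds: list[int] | None = None,
                      start_n: int = 10, hard_cap: int = HARD_CAP
                      ) -> CapacityResult:
    """Largest daily total whose replicated days stay under the threshold.

    Doubling search upward from ``start_n`` until the first "over", then
    integer bisection to the under/over boundary. N=0 is under by definition.
    """
    seeds = seeds if seeds is not None else replicate_seeds(config.seed)
    res = CapacityResult(capacity=0, period=rule.period, seeds=list(seeds))

    def classify(n):
        label, flags = classify_N(n, config, rule, seeds)
        res.replicate_outcomes[n] = flags
        res.search_trace.append((n, label))
        return label

    lo, hi = 0, None
    n = start_n
    while n <= hard_cap:
        label = classify(n)
        if label == "over":
            hi = n
            break
        lo = n
        n *= 2
    if hi is None:
        res.capacity = lo
        res.at_cap = True
        return res
    while hi - lo > 1:
        mid = (lo + hi) // 2
        if classify(mid) == "over":
            hi = mid
        else:
            lo = mid
    res.capacity = lo
    return res


def exhaustive_capacity(config: EngineConfig, rule: ThresholdRule,
                        seeds: list[int], n_max: int) -> int:
    """Oracle: scan N=1..n_max with the same seeds; capacity is the largest
    "under" before the first "over" (n_max if no N is over)."""
    capacity = 0
    for n in range(1, n_max + 1):
        label, _ = classify_N(n, config, rule, seeds)
        if label == "over":
            break
        capacity = n
    return capacity


@dataclass
class SweepSummary:
    results: list[CapacityResult]
    slope_first_segment: float | None = None   # capacity per minute, <=16 min
    slope_second_segment: float | None = None  # capacity per minute, >=16 min


def sweep_critical_periods(config: EngineConfig,
                           periods=SWEEP_PERIODS_MIN,
                           rule: ThresholdRule | None = None,
                           seeds: list[int] | None = None) -> SweepSummary:
    """Capacity estimates over several critical periods with shared seeds.

    The summary includes the two-segment slope of capacity against period
    length (the short-contact segment up to 16 min and the long-contact
    segment from 16 min up), where enough periods are present.
    """
    if not periods:
        raise ValueError("periods must be non-empty")
    base = rule or ThresholdRule()
    seeds = seeds if seeds is not None else replicate_seeds(config.seed)
    results = []
    for minutes in periods:
        r = ThresholdRule(n_visitors=base.n_visitors,
                          period=CriticalPeriod(minutes),
                          episode_mode=base.episode_mode)
        results.append(estimate_capacity(config, r, seeds=seeds))

    def seg_slope(pred):
        pts = [(r.period.minutes, r.capacity) for r in results if pred(r.period.minutes)]
        if len(pts) < 2:
            return None
        x = np.array([p[0] for p in pts])
        y = np.array([p[1] for p in pts], dtype=float)
        return float(np.polyfit(x, y, 1)[0])

    return SweepSummary(
        results=results,
        slope_first_segment=seg_slope(lambda m: m <= 16),
        slope_second_segment=seg_slope(lambda m: m >= 16),
    )
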