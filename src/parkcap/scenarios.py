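"""Policy and layout scenarios applied declaratively over a base run.

Three visitor-control policy branches — closing target categories, limiting
the opening hours to one 4 h period, switching the avoidance strategy — and
the layout/information adjustments (widened openings, an added one-way path,
AI warning boards at target entrances) are expressed as pure transformations
of an EngineConfig, then estimated against the unmodified base with shared
replicate seeds for paired comparison.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from . import behavior as bh
from .capacity import (
    CapacityResult,
    ThresholdRule,
    estimate_capacity,
    replicate_seeds,
)
from .engine import EngineConfig
from .environment import TargetCategory, add_one_way_path, widen_opening
from .metrics import adjustment_ratio


class ScenarioError(ValueError):
    pass


@dataclass
class ScenarioConfig:
    """Declarative bundle of policy and layout modifications."""

    base: EngineConfig
    closures: list = field(default_factory=list)  # target ids or categories
    open_window_override: tuple[int, int] | None = None
    avoidance_override: bh.AvoidanceMode | None = None
    widen: list[tuple[str, float]] = field(default_factory=list)
    one_way: list[list[tuple[int, int]]] = field(default_factory=list)
    ai_boards: list[tuple[str, int | None]] = field(default_factory=list)


# ------------------------------------------------------------------ policies
def apply_target_closure(config: EngineConfig, closures) -> EngineConfig:
    """Close targets by id or whole category.

    Visitor types whose preferred category is fully closed stop arriving
    (their share of the demand is dropped, not reassigned to other types).
    """
    closed = set(config.closed_targets)
    for item in closures:
        if isinstance(item, TargetCategory):
            closed |= {t.id for t in config.grid.targets if t.category == item}
        else:
            config.grid.target_by_id(item)  # raises KeyError if unknown
            closed.add(item)
    if all(t.id in closed for t in config.grid.targets):
        raise ScenarioError("cannot close every target")
    return config.replace(closed_targets=frozenset(closed))


#: types admitted in each limited opening period (the midday period admits
#: everyone; morning and evening are exercisers plus social-leisure visitors)
PERIOD_COMPOSITION: dict[tuple[int, int], set] = {
    (7, 11): {bh.VisitorType.EXERCISER, bh.VisitorType.LEISURE},
    (11, 15): set(bh.VisitorType),
    (15, 19): {bh.VisitorType.EXERCISER, bh.VisitorType.LEISURE},
}


def apply_opening_hours(config: EngineConfig, window: tuple[int, int],
                        allowed_types: set | None = None,
                        expected_length: int | None = 4) -> EngineConfig:
    """Restrict arrivals to one opening period and its visitor mix.

    The composition is renormalised over the types admitted in that period
    (override with ``allowed_types``); demand outside the window is zeroed by
    construction of the arrival schedule.
    """
    start, end = window
    if end <= start:
        raise ScenarioError("empty opening window")
    if expected_length is not None and end - start != expected_length:
        raise ScenarioError(f"opening window must span {expected_length} h")
    if allowed_types is None:
        allowed_types = PERIOD_COMPOSITION.get(window, set(bh.VisitorType))
    comp = config.tables.composition
    kept = {k: p for k, p in comp.items() if k in allowed_types and p > 0}
    total = sum(kept.values())
    if total <= 0:
        raise ScenarioError("no admitted visitor type has positive share")
    kept = {k: p / total for k, p in kept.items()}
    return config.replace(open_window=window, composition_override=kept)


def set_avoidance_mode(config: EngineConfig, mode: bh.AvoidanceMode
                       ) -> EngineConfig:
    """Override every visitor's distancing-conflict response."""
    return config.replace(avoidance=mode)


# --------------------------------------------------------------- adjustments
def install_ai_board(config: EngineConfig, target_id: str,
                     safe_count: int | None = None) -> EngineConfig:
    """Add an AI warning board at a target's entrances.

    Visitors about to enter read the interior count and replan immediately
    when it is at or above ``safe_count`` (default: half the interior cells,
    rounded up).
    """
    grid = config.grid.copy()
    t = grid.target_by_id(target_id)
    t.ai_board = True
    t.safe_count = (safe_count if safe_count is not None
                    else max(1, -(-len(t.interior_cells) // 2)))
    return config.replace(grid=grid)


def apply_layout_edits(config: EngineConfig, scenario: ScenarioConfig
                       ) -> EngineConfig:
    grid = config.grid
    for target_id, width in scenario.widen:
        grid = widen_opening(grid, target_id, width)
    for chain in scenario.one_way:
        grid = add_one_way_path(grid, [tuple(c) for c in chain])
    if grid is not config.grid:
        config = config.replace(grid=grid)
    return config


# -------------------------------------------------------------- orchestration
def apply_scenario(scenario: ScenarioConfig) -> EngineConfig:
    """Compose all modifications onto (a copy of) the base config."""
    cfg = scenario.base
    cfg = apply_layout_edits(cfg, scenario)
    if scenario.closures:
        cfg = apply_target_closure(cfg, scenario.closures)
    if scenario.open_window_override is not None:
        cfg = apply_opening_hours(cfg, scenario.open_window_override)
    if scenario.avoidance_override is not None:
        cfg = set_avoidance_mode(cfg, scenario.avoidance_override)
    for target_id, safe in scenario.ai_boards:
        cfg = install_ai_board(cfg, target_id, safe)
    return cfg


@dataclass
class ScenarioResult:
    base: CapacityResult
    scenario: CapacityResult
    ratio: float  # scenario capacity / base capacity, truncated to 2 dp


def run_scenario(scenario: ScenarioConfig, rule: ThresholdRule | None = None,
                 seeds: list[int] | None = None,
                 base_result: CapacityResult | None = None) -> ScenarioResult:
    """Estimate the scenario capacity against the base with shared seeds."""
    rule = rule or ThresholdRule()
    seeds = seeds if seeds is not None else replicate_seeds(scenario.base.seed)
    cfg = apply_scenario(scenario)
    if base_result is None:
        base_result = estimate_capacity(scenario.base, rule, seeds=seeds)
    scen_result = estimate_capacity(cfg, rule, seeds=seeds)
    ratio = (adjustment_ratio(scen_result.capacity, base_result.capacity)
             if base_result.capacity > 0 else float("inf"))
    return ScenarioResult(base=base_result, scenario=scen_result, ratio=ratio)
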