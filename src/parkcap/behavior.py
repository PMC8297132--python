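"""Visitor typing, travel planning, A* routing and per-tick movement rules.

Visitors follow five behavior rules: (1) keep a 2 m distance whenever
possible and stop to wait when they cannot; (2) plan a trip from an entrance
to an exit through a preferred main target, picking secondary targets along
the route; (3) dwell 20-30 min at the main target and 10-30 min at secondary
ones, within a total stay budget; (4) prefer wider/main paths and steer
around visible congestion; (5) avoid crowded targets.

The distancing conflict response comes in two modes: *passive* visitors stop
and wait for the conflict to clear; *aggressive* visitors keep moving —
advancing into free cells regardless of adjacency and side-stepping out of a
violation — which is what lets them accumulate contact time when passing.
"""

from __future__ import annotations

import heapq
import math
from dataclasses import dataclass, field
from enum import IntEnum

import numpy as np

from .environment import (
    CellClass,
    ParkGrid,
    TargetCategory,
    TargetZone,
)

TICK_SECONDS = 2.0  # one tick = 2 s; speed 1 cell (2 m)/tick = 1 m/s walking
TICKS_PER_MINUTE = 60.0 / TICK_SECONDS


class VisitorType(IntEnum):
    EXERCISER = 0
    LEISURE = 1
    TOURIST = 2
    WITH_CHILDREN = 3
    OTHER = 4


class AvoidanceMode(IntEnum):
    PASSIVE = 0
    AGGRESSIVE = 1


class VisitorState(IntEnum):
    TRAVELING = 0
    DWELLING = 1
    WAITING = 2
    EXITING = 3
    EXITED = 4


#: preferred main-target category per visitor type; OTHER draws uniformly
PREFERRED_CATEGORY: dict[VisitorType, TargetCategory | None] = {
    VisitorType.EXERCISER: TargetCategory.TRAIL,
    VisitorType.TOURIST: TargetCategory.POPULAR_SCENERY,
    VisitorType.LEISURE: TargetCategory.OPEN_SPACE,
    VisitorType.WITH_CHILDREN: TargetCategory.ENTERTAINMENT_FACILITY,
    VisitorType.OTHER: None,
}

#: stay-budget bins (minutes) behind the reported duration shares
BUDGET_BINS: dict[str, tuple[float, float]] = {
    "<1h": (30.0, 60.0),
    "2h": (60.0, 150.0),
    "4h": (150.0, 270.0),
    ">4h": (270.0, 360.0),
}


@dataclass
class BehaviorParams:
    """Tunable behavior constants (meters, persons/m², ticks)."""

    distance_threshold: float = 2.0
    visible_radius: float = 20.0
    crowding_density: float = 1.0
    speed: int = 1
    max_wait: int = 150          # 5 min before a forced replan
    retry_interval: int = 30     # replan retry cadence once already forced
    give_up_factor: int = 3      # abandon the plan after this many max_waits
    secondary_buffer: int = 3    # cells around the route for secondary picks
    main_path_pref: float = 1.25
    congestion_check_interval: int = 30  # rule-4 visible-congestion scan cadence

    def __post_init__(self):
        for name in ("distance_threshold", "visible_radius", "crowding_density",
                     "speed", "max_wait", "main_path_pref"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


@dataclass
class TravelPlan:
    entry_gate: str
    exit_gate: str
    main_target: str | None
    main_dwell: float  # minutes
    secondary_targets: list[tuple[str, float]] = field(default_factory=list)
    budget: float = 60.0  # minutes
    est_travel: float = 0.0  # minutes


@dataclass
class Visitor:
    id: int
    vtype: VisitorType
    plan: TravelPlan
    pos: tuple[int, int] | None = None
    state: VisitorState = VisitorState.TRAVELING
    route: list = field(default_factory=list)  # reversed: route[-1] is next
    itinerary: list = field(default_factory=list)  # [(target_id|None, dwell_ticks)]
    dwell_left: int = 0
    violation_clock: int = 0
    total_violation: int = 0
    max_violation: int = 0
    avoidance: AvoidanceMode = AvoidanceMode.PASSIVE
    wait_ticks: int = 0
    replanned: bool = False
    visited: set = field(default_factory=set)
    entry_tick: int = -1
    exit_tick: int = -1

    @property
    def next_cell(self):
        return self.route[-1] if self.route else None


# ------------------------------------------------------------------ sampling
def sample_visitor_type(composition: dict[VisitorType, float],
                        rng: np.random.Generator) -> VisitorType:
    """Draw a visitor type from a composition table (probabilities sum to 1)."""
    kinds = sorted(composition, key=int)
    probs = [composition[k] for k in kinds]
    if any(p < 0 for p in probs):
        raise ValueError("negative probability in composition table")
    if not math.isclose(sum(probs), 1.0, abs_tol=1e-9):
        raise ValueError(f"composition probabilities sum to {sum(probs)}")
    return kinds[int(rng.choice(len(kinds), p=probs))]


def sample_stay_budget(durations: dict[str, float],
                       rng: np.random.Generator) -> float:
    """Draw a total stay budget in minutes from binned duration shares.

    Bins map to uniform minute ranges: <1 h → U[30,60], 2 h → U[60,150],
    4 h → U[150,270], >4 h → U[270,360].
    """
    if not durations:
        raise ValueError("empty duration table")
    bins = [b for b in BUDGET_BINS if durations.get(b, 0) > 0]
    unknown = set(durations) - set(BUDGET_BINS)
    if unknown:
        raise ValueError(f"unknown duration bins {unknown}")
    probs = np.array([durations[b] for b in bins], dtype=float)
    if (probs < 0).any():
        raise ValueError("negative probability in duration table")
    if not math.isclose(probs.sum(), 1.0, abs_tol=1e-9):
        raise ValueError(f"duration probabilities sum to {probs.sum()}")
    b = bins[int(rng.choice(len(bins), p=probs))]
    lo, hi = BUDGET_BINS[b]
    return float(rng.uniform(lo, hi))


def open_targets(grid: ParkGrid, closed: frozenset[str] = frozenset()
                 ) -> list[TargetZone]:
    return [t for t in grid.targets if t.id not in closed]


def choose_main_target(vtype: VisitorType, grid: ParkGrid,
                       rng: np.random.Generator,
                       closed: frozenset[str] = frozenset()) -> str:
    """Pick the main target: uniform within the type's preferred category,
    falling back to a uniform draw over all open targets."""
    avail = open_targets(grid, closed)
    if not avail:
        raise ValueError("no open targets")
    cat = PREFERRED_CATEGORY[vtype]
    pool = [t for t in avail if cat is not None and t.category == cat]
    if not pool:
        pool = avail
    return pool[int(rng.choice(len(pool)))].id


# -------------------------------------------------------------------- routing
def astar_route(grid: ParkGrid, frm: tuple[int, int], to: tuple[int, int],
                main_path_pref: float = 1.25,
                blocked: frozenset | None = None) -> list | None:
    """Minimal-cost 4-connected path honouring one-way masks.

    The cost of entering a cell is 1/preference, with main-path cells
    preferred (default 1.25, i.e. cost 0.8) over all other accessible cells
    (cost 1.0). The Manhattan heuristic is scaled by the minimum cell cost so
    it stays admissible. Ties break deterministically by (row, col). Returns
    the path from ``frm`` to ``to`` inclusive, or None if unreachable.
    """
    if not (grid.is_accessible(frm) and grid.is_accessible(to)):
        return None
    if blocked and to in blocked:
        return None
    main_cost = 1.0 / main_path_pref
    min_cost = min(main_cost, 1.0)
    main_code = int(CellClass.PATH_MAIN)
    cells = grid.cells

    def h(cell):
        return (abs(cell[0] - to[0]) + abs(cell[1] - to[1])) * min_cost

    g: dict[tuple[int, int], float] = {frm: 0.0}
    came: dict[tuple[int, int], tuple[int, int]] = {}
    pq = [(h(frm), frm[0], frm[1])]
    done = set()
    while pq:
        _, r, c = heapq.heappop(pq)
        cur = (r, c)
        if cur in done:
            continue
        if cur == to:
            path = [cur]
            while cur in came:
                cur = came[cur]
                path.append(cur)
            path.reverse()
            return path
        done.add(cur)
        gcur = g[cur]
        for nxt in grid.neighbors(cur):
            if nxt in done or (blocked and nxt in blocked):
                continue
            step = main_cost if cells[nxt] == main_code else 1.0
            ng = gcur + step
            if ng < g.get(nxt, math.inf) - 1e-12:
                g[nxt] = ng
                came[nxt] = cur
                heapq.heappush(pq, (ng + h(nxt), nxt[0], nxt[1]))
    return None


def route_cost(grid: ParkGrid, path: list, main_path_pref: float = 1.25) -> float:
    """Cost of a path under the same per-cell entry costs as astar_route."""
    main_cost = 1.0 / main_path_pref
    main_code = int(CellClass.PATH_MAIN)
    return sum(
        main_cost if grid.cells[cell] == main_code else 1.0 for cell in path[1:]
    )


def ticks_to_minutes(n_ticks: int) -> float:
    return n_ticks / TICKS_PER_MINUTE


# ------------------------------------------------------------------- planning
def build_plan(vtype: VisitorType, grid: ParkGrid, tables, rng: np.random.Generator,
               params: BehaviorParams | None = None,
               closed: frozenset[str] = frozenset()) -> TravelPlan:
    """Construct a travel plan: gates, main target, dwells, secondaries.

    The main dwell is 20-30 min; the travel time entry→target→exit at
    1 cell/tick is estimated and must fit the stay budget together with the
    dwells. A main target too far for the budget is replaced by the nearest
    same-category one; if even that does not fit, the visitor passes through
    without dwelling. Secondary targets are sampled from those whose entrance
    lies within a few cells of the planned route, while the budget allows.
    """
    params = params or BehaviorParams()
    gates = sorted(grid.gates, key=lambda g: g.id)
    weights = np.array([g.weight for g in gates], dtype=float)
    weights = weights / weights.sum()
    entry = gates[int(rng.choice(len(gates), p=weights))]
    exit_ = gates[int(rng.choice(len(gates), p=weights))]
    budget = sample_stay_budget(tables.durations, rng)
    main_id = choose_main_target(vtype, grid, rng, closed)
    main_dwell = float(rng.uniform(20.0, 30.0))

    def est(target_id):
        t = grid.target_by_id(target_id)
        cell = sorted(t.entrance_cells)[0]
        p1 = astar_route(grid, entry.cells[0], cell, params.main_path_pref)
        p2 = astar_route(grid, cell, exit_.cells[0], params.main_path_pref)
        if p1 is None or p2 is None:
            return None, math.inf
        mins = ticks_to_minutes(len(p1) - 1 + len(p2) - 1)
        return (p1, p2), mins

    legs, travel = est(main_id)
    if travel + 20.0 > budget:
        # replace by nearest open target of the same category
        cat = grid.target_by_id(main_id).category
        cands = [t.id for t in open_targets(grid, closed)
                 if t.category == cat and t.id != main_id]
        best = None
        for cid in cands:
            lg, tv = est(cid)
            if best is None or tv < best[2]:
                best = (cid, lg, tv)
        if best is not None and best[2] + 20.0 <= budget:
            main_id, legs, travel = best
        elif travel + 20.0 > budget:
            # pass-through plan: no dwell anywhere
            p = astar_route(grid, entry.cells[0], exit_.cells[0],
                            params.main_path_pref)
            travel = ticks_to_minutes(len(p) - 1) if p else 0.0
            return TravelPlan(entry_gate=entry.id, exit_gate=exit_.id,
                              main_target=None, main_dwell=0.0,
                              budget=budget, est_travel=travel)

    main_dwell = min(main_dwell, budget - travel)  # keep the plan within budget
    route_cells = set(legs[0]) | set(legs[1])
    buffered = [
        t for t in open_targets(grid, closed)
        if t.id != main_id and any(
            min(abs(e[0] - rc[0]) + abs(e[1] - rc[1]) for rc in route_cells)
            <= params.secondary_buffer
            for e in t.entrance_cells
        )
    ]
    secondary: list[tuple[str, float]] = []
    used = travel + main_dwell
    for j in rng.permutation(len(buffered)):
        d = float(rng.uniform(10.0, 30.0))
        if used + d <= budget:
            secondary.append((buffered[int(j)].id, d))
            used += d
    return TravelPlan(entry_gate=entry.id, exit_gate=exit_.id,
                      main_target=main_id, main_dwell=main_dwell,
                      secondary_targets=secondary, budget=budget,
                      est_travel=travel)


# ------------------------------------------------------------------- movement
def movement_intent(visitor: Visitor, grid: ParkGrid,
                    occupancy: dict, params: BehaviorParams):
    """One visitor's movement intent against current occupancy.

    Returns ``('move', cell)`` or ``('blocked', cell)``. Passive visitors
    refuse any move that would create a new sub-threshold adjacency;
    aggressive visitors advance into any free cell and, when already in
    violation with the way ahead occupied, side-step to the free neighbour
    with the fewest adjacent occupants.
    """
    nxt = visitor.next_cell
    pos = visitor.pos
    if nxt is None:
        return ("blocked", None)
    if nxt in occupancy:
        if (visitor.avoidance == AvoidanceMode.AGGRESSIVE
                and visitor.violation_clock > 0):
            esc = _escape_cell(pos, grid, occupancy)
            if esc is not None:
                return ("move", esc)
        # anti-deadlock: a long-blocked visitor steps aside/back to any free
        # cell that does not worsen its adjacency, making room to unjam
        if visitor.wait_ticks >= params.max_wait:
            esc = _escape_cell(pos, grid, occupancy, strict=False)
            if esc is not None:
                return ("move", esc)
        return ("blocked", nxt)
    if visitor.avoidance == AvoidanceMode.PASSIVE and params.distance_threshold > 0:
        # distancing is kept "when possible": a long-blocked visitor squeezes
        # through an adjacency rather than gridlocking forever
        if (_adjacent_occupied(nxt, pos, occupancy)
                and visitor.wait_ticks < params.max_wait):
            return ("blocked", nxt)
    return ("move", nxt)


def _adjacent_occupied(cell, exclude, occupancy) -> bool:
    r, c = cell
    for dr, dc in ((-1, 0), (0, -1), (0, 1), (1, 0)):
        nb = (r + dr, c + dc)
        if nb != exclude and nb in occupancy:
            return True
    return False


def _occupied_neighbors(cell, exclude, occupancy) -> int:
    r, c = cell
    n = 0
    for dr, dc in ((-1, 0), (0, -1), (0, 1), (1, 0)):
        nb = (r + dr, c + dc)
        if nb != exclude and nb in occupancy:
            n += 1
    return n


def _escape_cell(pos, grid: ParkGrid, occupancy, strict: bool = True):
    """Free neighbouring cell minimising adjacent occupants.

    With ``strict`` (the default) only a cell with strictly fewer adjacent
    occupants than the current position qualifies; otherwise ties are
    allowed, which lets a jammed visitor step aside to make room.
    """
    here = _occupied_neighbors(pos, None, occupancy)
    best, best_n = None, here if strict else here + 1
    r, c = pos
    for dr, dc in ((-1, 0), (0, -1), (0, 1), (1, 0)):
        cand = (r + dr, c + dc)
        if cand in occupancy or not grid.step_allowed(pos, cand):
            continue
        n = _occupied_neighbors(cand, pos, occupancy)
        if n < best_n:
            best, best_n = cand, n
    return best


def step(visitor: Visitor, world, params: BehaviorParams | None = None,
         rng: np.random.Generator | None = None) -> Visitor:
    """Advance one visitor a single tick against an otherwise frozen world.

    Convenience wrapper over the engine's single-visitor step; within a full
    simulated day the engine instead resolves all visitors' intents
    concurrently each tick, so that two approaching visitors can land on
    adjacent cells — the "collision" that seeds congestion.
    """
    world.step_single(visitor)
    return visitor
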