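"""Full-day simulation: arrivals, concurrent agent ticks, contact bookkeeping.

One tick is 2 s; visitors move at most one cell (2 m) per tick. Each tick the
engine collects every visitor's movement intent against the start-of-tick
occupancy and then commits them together (conflicts for the same cell go to a
random winner). This concurrency is what lets two approaching visitors end up
on adjacent cells — a distancing "collision" — which is the seed of all
congestion; a sequential update would let everybody stop 4 m apart and no
contact would ever occur.

A distancing violation is another visitor on an orthogonally adjacent cell
(2 m centre distance, sub-threshold once body width is accounted for).
Violation episodes are tracked per visitor (continuous clock, longest
episode, cumulative total) and per pair (the contact log). Congestion is
classified into four stages: transient collisions (1), a persistent cluster
off the main path (2), a cluster reaching the main path (3), and a blocked
entrance queue (4).
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field

import numpy as np

from . import behavior as bh
from .environment import CellClass, ParkGrid

TICKS_PER_HOUR = 1800  # 3600 s / 2 s-per-tick

_OFF = ((-1, 0), (0, -1), (0, 1), (1, 0))


@dataclass
class DemandTables:
    """Demand inputs for one park and day type.

    ``hourly`` holds arrival counts (or shares) per clock hour, ``composition``
    the visitor-type mix, and ``durations`` the binned stay-length shares.
    """

    hourly: dict[int, float]
    composition: dict[bh.VisitorType, float]
    durations: dict[str, float]


@dataclass
class EngineConfig:
    grid: ParkGrid
    tables: DemandTables | None
    params: bh.BehaviorParams = field(default_factory=bh.BehaviorParams)
    daily_total: int = 0
    day_type: str = "weekday"
    open_window: tuple[int, int] = (7, 17)
    seed: int = 0
    drain_hours: float = 2.0
    avoidance: bh.AvoidanceMode = bh.AvoidanceMode.PASSIVE
    closed_targets: frozenset = frozenset()
    composition_override: dict | None = None
    cluster_min: int = 3       # visitors in a mutually-violating waiting cluster
    cluster_persist: int = 30  # ticks a cluster must persist to count
    queue_threshold: int = 10  # gate queue length that marks a blocked entrance
    queue_persist: int = 30

    def __post_init__(self):
        if self.daily_total < 0:
            raise ValueError("daily_total must be >= 0")
        if self.open_window[1] <= self.open_window[0]:
            raise ValueError("empty open window")

    def replace(self, **kw) -> "EngineConfig":
        d = {f: getattr(self, f) for f in self.__dataclass_fields__}
        d.update(kw)
        return EngineConfig(**d)


class ContactLog:
    """Per-pair episodes of continuous sub-threshold separation."""

    def __init__(self):
        self.episodes: dict[tuple[int, int], list[tuple[int, int]]] = {}
        self._open: dict[tuple[int, int], int] = {}

    def update(self, pairs, tick: int) -> None:
        """Extend/open episodes for `pairs` at `tick`, close all others."""
        current = set(pairs)
        for pair in list(self._open):
            if pair not in current:
                start = self._open.pop(pair)
                self.episodes.setdefault(pair, []).append((start, tick - 1))
        for pair in current:
            if pair not in self._open:
                self._open[pair] = tick

    def close_all(self, tick: int) -> None:
        for pair, start in self._open.items():
            self.episodes.setdefault(pair, []).append((start, tick - 1))
        self._open.clear()

    def durations_ticks(self) -> list[int]:
        return [e - s + 1 for eps in self.episodes.values() for s, e in eps]

    def n_episodes(self) -> int:
        return sum(len(v) for v in self.episodes.values())


@dataclass
class CongestionSnapshot:
    tick: int
    clusters: list[set]
    stage: int


@dataclass
class DayResult:
    entered: int = 0
    exited: int = 0
    trapped: int = 0
    dropped: int = 0          # arrivals suppressed by target closures
    queued_unserved: int = 0  # still waiting outside at the end of the day
    max_violation: dict[int, int] = field(default_factory=dict)   # ticks
    total_violation: dict[int, int] = field(default_factory=dict)
    contacts: ContactLog = field(default_factory=ContactLog)
    stage_timeline: list[tuple[int, int]] = field(default_factory=list)
    max_stage: int = 1
    truncated: bool = False
    seed: int = 0
    daily_total: int = 0
    ticks_run: int = 0
    occupancy_cells: dict[tuple[int, int], int] = field(default_factory=dict)


# ---------------------------------------------------------------- violations
def distance_violations(occupancy: dict) -> set:
    """Visitors with at least one orthogonally adjacent occupied cell."""
    out = set()
    for (r, c), vid in occupancy.items():
        right = occupancy.get((r, c + 1))
        down = occupancy.get((r + 1, c))
        if right is not None:
            out.add(vid)
            out.add(right)
        if down is not None:
            out.add(vid)
            out.add(down)
    return out


def violation_pairs(occupancy: dict) -> list[tuple[int, int]]:
    """Unordered violating pairs (each reported once, id-sorted)."""
    pairs = []
    for (r, c), vid in occupancy.items():
        for other in (occupancy.get((r, c + 1)), occupancy.get((r + 1, c))):
            if other is not None:
                pairs.append((vid, other) if vid < other else (other, vid))
    return pairs


def classify_stage(clusters: list[set], gate_blocked: bool,
                   grid: ParkGrid) -> int:
    """Stage of congestion given the persistent waiting clusters.

    1: none; 2: cluster(s) wholly off the main path (recoverable);
    3: a cluster touching the main path or a gate (unrecoverable, site-wide);
    4: a blocked entrance.
    """
    if gate_blocked:
        return 4
    stage = 1
    main = (int(CellClass.PATH_MAIN), int(CellClass.GATE))
    for cluster in clusters:
        if any(int(grid.cells[cell]) in main for cell in cluster):
            return 3
        stage = 2
    return stage


# --------------------------------------------------------------------- world
class World:
    """Mutable state of one simulated day."""

    def __init__(self, config: EngineConfig):
        config.grid.validate()
        self.config = config
        self.grid = config.grid
        self.params = config.params
        self.rng = np.random.default_rng(config.seed)
        self.occupancy: dict[tuple[int, int], int] = {}
        self.visitors: dict[int, bh.Visitor] = {}
        self.inside: list[int] = []
        self.tick_no = 0
        self.result = DayResult(seed=config.seed, daily_total=config.daily_total)
        self._route_cache: dict = {}
        self._next_id = 0
        self._queues: dict[str, deque] = {g.id: deque() for g in config.grid.gates}
        self._queue_streak: dict[str, int] = {g.id: 0 for g in config.grid.gates}
        self._cluster_streak: dict[tuple[int, int], int] = {}
        self.congested_cells: set = set()
        self._blocked_this_tick: set[int] = set()
        self._stage = 1
        # per-target interior occupancy for AI boards
        self._interior_of: dict[tuple[int, int], str] = {}
        self._interior_count: dict[str, int] = {}
        for t in config.grid.targets:
            self._interior_count[t.id] = 0
            for cell in t.interior_cells:
                self._interior_of[cell] = t.id
        self._board_entrances: dict[tuple[int, int], str] = {}
        for t in config.grid.targets:
            if t.ai_board:
                for cell in t.entrance_cells:
                    self._board_entrances[cell] = t.id
        self._exceeded: set[int] = set()

    # ------------------------------------------------------------- utilities
    @classmethod
    def bare(cls, grid: ParkGrid, params: bh.BehaviorParams | None = None,
             seed: int = 0, **kw) -> "World":
        """An empty world over `grid` for micro-simulations."""
        cfg = EngineConfig(grid=grid, tables=None,
                           params=params or bh.BehaviorParams(), daily_total=0,
                           seed=seed, **kw)
        return cls(cfg)

    def add_visitor(self, pos: tuple[int, int], route: list | None = None,
                    itinerary: list | None = None,
                    avoidance: bh.AvoidanceMode | None = None,
                    vtype: bh.VisitorType = bh.VisitorType.OTHER,
                    plan: bh.TravelPlan | None = None) -> bh.Visitor:
        """Place a visitor directly (for micro-sims and tests)."""
        if pos in self.occupancy:
            raise ValueError(f"cell {pos} already occupied")
        vid = self._next_id
        self._next_id += 1
        plan = plan or bh.TravelPlan(entry_gate="", exit_gate="",
                                     main_target=None, main_dwell=0.0)
        v = bh.Visitor(id=vid, vtype=vtype, plan=plan, pos=pos,
                       avoidance=(avoidance if avoidance is not None
                                  else self.config.avoidance),
                       entry_tick=self.tick_no)
        v.route = list(reversed(route)) if route else []
        v.itinerary = itinerary or []
        self.visitors[vid] = v
        self.occupancy[pos] = vid
        self.inside.append(vid)
        self.result.entered += 1
        self._enter_cell_accounting(v, pos)
        return v

    def _enter_cell_accounting(self, v: bh.Visitor, cell) -> None:
        tid = self._interior_of.get(cell)
        if tid is not None:
            self._interior_count[tid] += 1

    def _leave_cell_accounting(self, v: bh.Visitor, cell) -> None:
        tid = self._interior_of.get(cell)
        if tid is not None:
            self._interior_count[tid] -= 1

    def interior_count(self, target_id: str) -> int:
        return self._interior_count[target_id]

    @staticmethod
    def _as_route(v: bh.Visitor, path: list | None) -> list:
        """Reverse a start-inclusive A* path into the visitor's pending route
        (next cell last, current position dropped)."""
        if not path:
            return []
        route = list(reversed(path))
        if route and route[-1] == v.pos:
            route.pop()
        return route

    def route_to(self, frm, to, blocked: frozenset | None = None):
        if blocked:
            return bh.astar_route(self.grid, frm, to,
                                  self.params.main_path_pref, blocked)
        key = (frm, to)
        path = self._route_cache.get(key)
        if path is None and key not in self._route_cache:
            path = bh.astar_route(self.grid, frm, to, self.params.main_path_pref)
            self._route_cache[key] = path
        return list(path) if path else None

    # ------------------------------------------------------------- lifecycle
    def _build_itinerary(self, v: bh.Visitor) -> None:
        plan = v.plan
        legs = []
        if plan.main_target is not None:
            legs.append((plan.main_target, int(round(plan.main_dwell
                                                     * bh.TICKS_PER_MINUTE))))
        for tid, mins in plan.secondary_targets:
            legs.append((tid, int(round(mins * bh.TICKS_PER_MINUTE))))
        legs.append((None, 0))  # exit leg
        v.itinerary = legs

    def _dwell_cell(self, target_id: str):
        """Pick a spot to dwell on inside a target: prefer free cells that
        keep the 2 m distance (rule 1), then any free cell, then any cell."""
        t = self.grid.target_by_id(target_id)
        cells = sorted(t.interior_cells)
        occ = self.occupancy
        free = [c for c in cells if c not in occ]
        compliant = [c for c in free
                     if not bh._adjacent_occupied(c, None, occ)]
        pool = compliant or free or cells
        return pool[int(self.rng.choice(len(pool)))]

    def _exit_cell(self, v: bh.Visitor):
        gid = v.plan.exit_gate or self.grid.gates[0].id
        return self.grid.gate_by_id(gid).cells[0]

    def _start_next_leg(self, v: bh.Visitor, avoid: frozenset | None = None) -> None:
        """Route the visitor to its next itinerary goal (skipping closed or
        unreachable targets); the last leg heads to the exit gate."""
        if not v.itinerary:
            v.itinerary = [(None, 0)]
        while v.itinerary:
            tid, dwell = v.itinerary[0]
            if tid is None:
                goal = self._exit_cell(v)
                path = self.route_to(v.pos, goal, avoid) or self.route_to(v.pos, goal)
                v.state = bh.VisitorState.EXITING
                v.route = self._as_route(v, path)
                v.dwell_left = 0
                return
            if tid in self.config.closed_targets:
                v.itinerary.pop(0)
                continue
            goal = self._dwell_cell(tid)
            path = self.route_to(v.pos, goal, avoid)
            if path is None and avoid:
                path = self.route_to(v.pos, goal)
            if path is None:
                v.itinerary.pop(0)
                continue
            v.state = bh.VisitorState.TRAVELING
            v.route = self._as_route(v, path)
            v.dwell_left = dwell
            return

    def _spawn_schedule(self):
        cfg = self.config
        if cfg.daily_total == 0 or cfg.tables is None:
            return []
        start, end = cfg.open_window
        hours = [h for h in range(start, end) if cfg.tables.hourly.get(h, 0) > 0]
        if not hours:
            raise ValueError("no demand inside the open window")
        shares = np.array([cfg.tables.hourly[h] for h in hours], dtype=float)
        shares /= shares.sum()
        gates = sorted(self.grid.gates, key=lambda g: g.id)
        gw = np.array([g.weight for g in gates], dtype=float)
        gw /= gw.sum()
        hour_ix = self.rng.choice(len(hours), size=cfg.daily_total, p=shares)
        offs = self.rng.integers(0, TICKS_PER_HOUR, size=cfg.daily_total)
        gate_ix = self.rng.choice(len(gates), size=cfg.daily_total, p=gw)
        sched = [
            ((hours[int(h)] - start) * TICKS_PER_HOUR + int(o), gates[int(g)].id)
            for h, o, g in zip(hour_ix, offs, gate_ix)
        ]
        sched.sort()
        return deque(sched)

    def _composition(self) -> dict:
        if self.config.composition_override is not None:
            return self.config.composition_override
        return self.config.tables.composition

    def _closed_categories(self) -> set:
        open_cats = {t.category for t in self.grid.targets
                     if t.id not in self.config.closed_targets}
        return {c for c in bh.PREFERRED_CATEGORY.values()
                if c is not None and c not in open_cats}

    def _make_visitor(self, gate_id: str) -> bh.Visitor | None:
        cfg = self.config
        vtype = bh.sample_visitor_type(self._composition(), self.rng)
        cat = bh.PREFERRED_CATEGORY[vtype]
        if cat is not None and cat in self._closed_cats:
            self.result.dropped += 1
            return None
        plan = bh.build_plan(vtype, self.grid, cfg.tables, self.rng,
                             self.params, cfg.closed_targets)
        plan.entry_gate = gate_id  # arrivals are per-gate in the schedule
        vid = self._next_id
        self._next_id += 1
        v = bh.Visitor(id=vid, vtype=vtype, plan=plan,
                       avoidance=cfg.avoidance)
        self._build_itinerary(v)
        return v

    def _try_place(self, v: bh.Visitor, gate_id: str) -> bool:
        gate = self.grid.gate_by_id(gate_id)
        for cell in gate.cells:
            if cell not in self.occupancy:
                v.pos = cell
                v.entry_tick = self.tick_no
                self.visitors[v.id] = v
                self.occupancy[cell] = v.id
                self.inside.append(v.id)
                self.result.entered += 1
                self._enter_cell_accounting(v, cell)
                self._start_next_leg(v)
                return True
        return False

    # ------------------------------------------------------------------ tick
    def tick(self, record_stage: bool = True) -> None:
        """One 2 s step for every visitor, committed concurrently."""
        rng = self.rng
        occ = self.occupancy
        params = self.params
        order = [self.inside[int(i)]
                 for i in rng.permutation(len(self.inside))]
        moves: list[tuple[int, tuple[int, int]]] = []
        claimed: set[tuple[int, int]] = set()
        blocked: set[int] = set()

        for vid in order:
            v = self.visitors[vid]
            if v.state == bh.VisitorState.DWELLING:
                v.dwell_left -= 1
                if v.dwell_left <= 0:
                    v.visited.add(v.itinerary[0][0])
                    v.itinerary.pop(0)
                    self._start_next_leg(v)
                continue
            if not v.route:
                self._arrive(v)
                continue
            # AI warning board: consult the count before stepping inside
            nxt = v.next_cell
            tid = self._board_entrances.get(nxt)
            if (tid is not None and v.itinerary and v.itinerary[0][0] == tid
                    and nxt not in (v.pos,)):
                t = self.grid.target_by_id(tid)
                safe = t.safe_count if t.safe_count is not None else max(
                    1, -(-len(t.interior_cells) // 2))
                if self._interior_count[tid] >= safe:
                    v.visited.add(tid)
                    v.itinerary.pop(0)
                    self._start_next_leg(v, avoid=frozenset({nxt}))
                    if not v.route:
                        continue
                    nxt = v.next_cell
            kind, cell = bh.movement_intent(v, self.grid, occ, params)
            if kind == "move" and cell not in claimed:
                claimed.add(cell)
                moves.append((vid, cell))
            else:
                blocked.add(vid)

        # commit all winning moves at once
        for vid, cell in moves:
            v = self.visitors[vid]
            old = v.pos
            del occ[old]
            occ[cell] = vid
            self._leave_cell_accounting(v, old)
            self._enter_cell_accounting(v, cell)
            v.pos = cell
            if v.route and v.route[-1] == cell:
                v.route.pop()
            else:  # aggressive side-step off the route: re-route next tick
                v.route = []
                if v.itinerary:
                    self._start_next_leg(v)
                else:
                    v.state = bh.VisitorState.EXITING
                    self._start_next_leg(v)
            v.wait_ticks = 0
            v.replanned = False
            if v.state == bh.VisitorState.WAITING:
                v.state = bh.VisitorState.TRAVELING
            if not v.route:
                self._arrive(v)

        for vid in blocked:
            v = self.visitors[vid]
            if v.state == bh.VisitorState.EXITED:
                continue
            if v.state != bh.VisitorState.EXITING:
                v.state = bh.VisitorState.WAITING
            v.wait_ticks += 1
            self._maybe_replan(v)
        self._blocked_this_tick = blocked

        self.tick_no += 1
        self._violation_pass()
        self._congestion_pass(record_stage)
        self._serve_queues()

    def step_single(self, v: bh.Visitor) -> None:
        """Sequential single-visitor step (the rest of the world frozen)."""
        if v.state == bh.VisitorState.DWELLING:
            v.dwell_left -= 1
            if v.dwell_left <= 0 and v.itinerary:
                v.visited.add(v.itinerary[0][0])
                v.itinerary.pop(0)
                self._start_next_leg(v)
            return
        if not v.route:
            self._arrive(v)
            return
        kind, cell = bh.movement_intent(v, self.grid, self.occupancy, self.params)
        if kind == "move":
            old = v.pos
            del self.occupancy[old]
            self.occupancy[cell] = v.id
            self._leave_cell_accounting(v, old)
            self._enter_cell_accounting(v, cell)
            v.pos = cell
            if v.route and v.route[-1] == cell:
                v.route.pop()
            v.wait_ticks = 0
            if v.state == bh.VisitorState.WAITING:
                v.state = bh.VisitorState.TRAVELING
            if not v.route:
                self._arrive(v)
        else:
            v.state = bh.VisitorState.WAITING
            v.wait_ticks += 1
            self._maybe_replan(v)

    # --------------------------------------------------------------- helpers
    def _arrive(self, v: bh.Visitor) -> None:
        """Handle a visitor whose route is exhausted."""
        if v.state == bh.VisitorState.EXITING or not v.itinerary:
            gid = v.plan.exit_gate or self.grid.gates[0].id
            gate = self.grid.gate_by_id(gid)
            if v.pos in set(gate.cells):
                self._do_exit(v)
            else:
                self._start_next_leg(v)
            return
        tid, dwell = v.itinerary[0]
        if tid is None:
            self._start_next_leg(v)
            return
        # rule 5: crowding check on arrival
        if self._local_density(v.pos) > self.params.crowding_density:
            v.visited.add(tid)
            v.itinerary.pop(0)
            self._start_next_leg(v)
            return
        # rule 1: do not settle on a spot that breaks distancing if a
        # compliant one is free; with none left, move on to the next target
        if bh._adjacent_occupied(v.pos, None, self.occupancy):
            t = self.grid.target_by_id(tid)
            occ = self.occupancy
            compliant = [c for c in sorted(t.interior_cells)
                         if c != v.pos and c not in occ
                         and not bh._adjacent_occupied(c, None, occ)]
            if compliant:
                alt = compliant[int(self.rng.choice(len(compliant)))]
                path = self.route_to(v.pos, alt)
                if path is not None:
                    v.state = bh.VisitorState.TRAVELING
                    v.route = self._as_route(v, path)
                    return
            v.visited.add(tid)
            v.itinerary.pop(0)
            self._start_next_leg(v)
            return
        v.state = bh.VisitorState.DWELLING
        v.dwell_left = max(1, dwell)

    def _do_exit(self, v: bh.Visitor) -> None:
        del self.occupancy[v.pos]
        self._leave_cell_accounting(v, v.pos)
        self.inside.remove(v.id)
        v.state = bh.VisitorState.EXITED
        v.exit_tick = self.tick_no
        self.result.exited += 1
        res = self.result
        res.max_violation[v.id] = v.max_violation
        res.total_violation[v.id] = v.total_violation

    def _local_density(self, cell) -> float:
        r = self.params.visible_radius / self.grid.cell_size
        r2 = r * r
        n = 0
        cr, cc = cell
        for (orr, occ_), _vid in self.occupancy.items():
            dr, dc = orr - cr, occ_ - cc
            if dr * dr + dc * dc <= r2:
                n += 1
        area = 3.141592653589793 * (self.params.visible_radius ** 2)
        return (n - 1) / area if n else 0.0  # exclude the arriving visitor

    def _maybe_replan(self, v: bh.Visitor) -> None:
        p = self.params
        w = v.wait_ticks
        if w < p.max_wait:
            return
        if w >= p.give_up_factor * p.max_wait and v.itinerary and \
                v.itinerary[0][0] is not None:
            # abandon the remaining plan and head for the exit
            v.itinerary = [(None, 0)]
            self._start_next_leg(v, avoid=frozenset({v.next_cell} - {None}))
            return
        if w == p.max_wait or (w - p.max_wait) % p.retry_interval == 0:
            nxt = v.next_cell
            avoid = set(self.congested_cells)
            if nxt is not None:
                avoid.add(nxt)
            goal_tid = v.itinerary[0][0] if v.itinerary else None
            if goal_tid is not None:
                goal = self._dwell_cell(goal_tid)
                path = self.route_to(v.pos, goal, frozenset(avoid))
                if path is not None:
                    v.route = self._as_route(v, path)
                    v.replanned = True
                    return
                # try a different open, unvisited target
                alts = [t.id for t in bh.open_targets(self.grid,
                                                      self.config.closed_targets)
                        if t.id != goal_tid and t.id not in v.visited]
                self.rng.shuffle(alts)
                for alt in alts:
                    path = self.route_to(v.pos, self._dwell_cell(alt),
                                         frozenset(avoid))
                    if path is not None:
                        v.visited.add(goal_tid)
                        v.itinerary[0] = (alt, v.itinerary[0][1])
                        v.route = self._as_route(v, path)
                        v.replanned = True
                        return
            # fall back: head to the exit, avoiding the blockage if possible
            goal = self._exit_cell(v)
            path = self.route_to(v.pos, goal, frozenset(avoid)) \
                or self.route_to(v.pos, goal)
            if path is not None:
                if v.itinerary and v.itinerary[0][0] is not None:
                    v.itinerary = [(None, 0)]
                v.state = bh.VisitorState.EXITING
                v.route = self._as_route(v, path)
                v.replanned = True

    def _violation_pass(self) -> None:
        occ = self.occupancy
        pairs = violation_pairs(occ)
        violators = set()
        for a, b in pairs:
            violators.add(a)
            violators.add(b)
        res = self.result
        stop_ticks = self._stop_ticks
        for vid in self.inside:
            v = self.visitors[vid]
            if vid in violators:
                v.violation_clock += 1
                v.total_violation += 1
                if v.violation_clock > v.max_violation:
                    v.max_violation = v.violation_clock
                if stop_ticks is not None and vid not in self._exceeded:
                    val = (v.max_violation if self._stop_mode == "continuous"
                           else v.total_violation)
                    if val >= stop_ticks:
                        self._exceeded.add(vid)
            else:
                v.violation_clock = 0
        res.contacts.update(pairs, self.tick_no)
        self._violators = violators

    def _congestion_pass(self, record_stage: bool) -> None:
        cfg = self.config
        # clusters: blocked movers in violation, orthogonally connected
        members = {self.visitors[vid].pos for vid in self._blocked_this_tick
                   if vid in self._violators}
        clusters = []
        seen = set()
        for cell in members:
            if cell in seen:
                continue
            comp = {cell}
            q = deque([cell])
            while q:
                r, c = q.popleft()
                for dr, dc in _OFF:
                    nb = (r + dr, c + dc)
                    if nb in members and nb not in comp:
                        comp.add(nb)
                        q.append(nb)
            seen |= comp
            if len(comp) >= cfg.cluster_min:
                clusters.append(comp)
        cluster_cells = set().union(*clusters) if clusters else set()
        streak = self._cluster_streak
        for cell in list(streak):
            if cell not in cluster_cells:
                del streak[cell]
        for cell in cluster_cells:
            streak[cell] = streak.get(cell, 0) + 1
        persistent = {cell for cell, s in streak.items()
                      if s >= cfg.cluster_persist}
        self.congested_cells = persistent
        persistent_clusters = [cl for cl in clusters if cl & persistent]

        gate_blocked = False
        for gid, q in self._queues.items():
            if len(q) > cfg.queue_threshold:
                self._queue_streak[gid] += 1
            else:
                self._queue_streak[gid] = 0
            if self._queue_streak[gid] >= cfg.queue_persist:
                gate_blocked = True
        stage = classify_stage(persistent_clusters, gate_blocked, self.grid)
        if record_stage and stage != self._stage:
            self.result.stage_timeline.append((self.tick_no, stage))
            self._stage = stage
        if stage > self.result.max_stage:
            self.result.max_stage = stage

        # rule 4: steer around visible congestion
        p = self.params
        if persistent and self.tick_no % p.congestion_check_interval == 0:
            look = max(1, int(p.visible_radius / self.grid.cell_size))
            for vid in self.inside:
                v = self.visitors[vid]
                if v.state != bh.VisitorState.TRAVELING or not v.route:
                    continue
                ahead = v.route[-look:]
                if any(cell in persistent for cell in ahead):
                    goal = v.route[0]
                    path = self.route_to(v.pos, goal, frozenset(persistent))
                    if path is not None:
                        v.route = self._as_route(v, path)

    def _serve_queues(self) -> None:
        for gid, q in self._queues.items():
            while q:
                v = q[0]
                if self._try_place(v, gid):
                    q.popleft()
                else:
                    break

    # ------------------------------------------------------------------- run
    def run(self, stop_rule=None, tick_callback=None) -> DayResult:
        """Simulate the whole day (open window plus drain-out).

        ``stop_rule`` (optional, duck-typed with ``n_visitors``,
        ``period.minutes`` and ``episode_mode``) ends the day early once the
        capacity threshold is provably exceeded. ``tick_callback(world)``
        runs after every tick (used by invariant-scanning tests).
        """
        cfg = self.config
        if stop_rule is not None:
            self._stop_ticks = int(round(
                stop_rule.period.minutes * bh.TICKS_PER_MINUTE))
            self._stop_mode = stop_rule.episode_mode
            stop_n = stop_rule.n_visitors
        else:
            self._stop_ticks = None
            self._stop_mode = "continuous"
            stop_n = None
        sched = self._spawn_schedule()
        start, end = cfg.open_window
        close_tick = (end - start) * TICKS_PER_HOUR
        max_tick = close_tick + int(cfg.drain_hours * TICKS_PER_HOUR)
        self._closed_cats = self._closed_categories()

        while self.tick_no < max_tick:
            while sched and sched[0][0] <= self.tick_no:
                _, gate_id = sched.popleft()
                v = self._make_visitor(gate_id)
                if v is not None and not self._try_place(v, gate_id):
                    self._queues[gate_id].append(v)
            self.tick(record_stage=True)
            if tick_callback is not None:
                tick_callback(self)
            if stop_n is not None and len(self._exceeded) >= stop_n:
                self.result.truncated = True
                break
            if (not self.inside and not sched
                    and not any(self._queues.values())):
                break

        res = self.result
        res.contacts.close_all(self.tick_no)
        res.ticks_run = self.tick_no
        for vid in self.inside:  # trapped at the end of the drain-out
            v = self.visitors[vid]
            res.max_violation[v.id] = v.max_violation
            res.total_violation[v.id] = v.total_violation
        res.trapped = len(self.inside)
        res.queued_unserved = sum(len(q) for q in self._queues.values())
        res.occupancy_cells = dict(self.occupancy)
        return res

    _stop_ticks: int | None = None
    _stop_mode: str = "continuous"
    _violators: set = frozenset()
    _closed_cats: set = frozenset()


def run_day(config: EngineConfig, stop_rule=None, tick_callback=None) -> DayResult:
    """Run one full simulated day for `config` (deterministic given its seed)."""
    return World(config).run(stop_rule=stop_rule, tick_callback=tick_callback)


def spawn_arrivals(config: EngineConfig):
    """The day's arrival schedule as (tick, gate_id) pairs.

    Exactly ``daily_total`` arrivals are drawn: each is assigned an hour with
    probability proportional to the hourly demand within the open window and
    a uniform tick inside that hour, keeping realized totals exactly at the
    candidate N under test.
    """
    return list(World(config)._spawn_schedule())


def update_contact_log(log: ContactLog, pairs, tick: int) -> ContactLog:
    log.update(pairs, tick)
    return log
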