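"""Day engine: arrivals, conservation, violation detection, contact log,
congestion staging."""

import math

import numpy as np
import pytest

import parkcap as pc
from parkcap import engine


def test_zero_demand_day_is_empty(corridor_cfg):
    day = pc.run_day(corridor_cfg.replace(daily_total=0))
    assert day.entered == day.exited == 0
    assert day.contacts.n_episodes() == 0


def test_arrival_hours_match_demand_shares(ring):
    """Expected arrivals per hour are proportional to the hourly table
    within 3 sigma at a large daily total."""
    grid, tables = ring
    cfg = pc.EngineConfig(grid=grid, tables=tables, daily_total=10_000,
                          open_window=(7, 17), seed=9)
    sched = pc.spawn_arrivals(cfg)
    assert len(sched) == 10_000
    hours = [7 + t // engine.TICKS_PER_HOUR for t, _ in sched]
    tot = sum(tables.hourly[h] for h in range(7, 17))
    for h in range(7, 17):
        p = tables.hourly[h] / tot
        k = sum(hh == h for hh in hours)
        sigma = math.sqrt(10_000 * p * (1 - p))
        assert abs(k - 10_000 * p) < 3 * sigma


def test_identical_seed_gives_identical_day(corridor_cfg):
    c = corridor_cfg.replace(daily_total=25, seed=42)
    d1, d2 = pc.run_day(c), pc.run_day(c)
    assert d1.entered == d2.entered and d1.exited == d2.exited
    assert d1.max_violation == d2.max_violation
    assert d1.stage_timeline == d2.stage_timeline
    assert d1.contacts.episodes == d2.contacts.episodes


def test_single_visitor_day_clean_exit(corridor_cfg):
    day = pc.run_day(corridor_cfg.replace(daily_total=1, seed=3))
    assert day.entered == day.exited == 1
    assert day.trapped == 0
    assert max(day.max_violation.values()) == 0
    assert day.max_stage == 1


def test_conservation_and_exclusivity_every_tick(corridor_cfg):
    """entered = inside + exited after every tick; one visitor per cell."""
    def check(world):
        assert world.result.entered == len(world.inside) + world.result.exited
        assert len(world.occupancy) == len(world.inside)
        assert len(set(world.occupancy.values())) == len(world.occupancy)
        for cell, vid in world.occupancy.items():
            assert world.visitors[vid].pos == cell

    day = pc.run_day(corridor_cfg.replace(daily_total=30, seed=7),
                     tick_callback=check)
    assert day.entered == day.exited + day.trapped


def test_distance_violations_matches_brute_force(rng):
    """Grid adjacency detection equals the all-pairs metric check
    (centre distance <= 2 m) on random occupancies."""
    for _ in range(100):
        n = int(rng.integers(2, 25))
        cells = rng.choice(100, size=n, replace=False)
        occupancy = {(int(c // 10), int(c % 10)): i
                     for i, c in enumerate(cells)}
        got = pc.distance_violations(occupancy)
        expect = set()
        pos = list(occupancy.items())
        for i in range(len(pos)):
            for j in range(i + 1, len(pos)):
                (r1, c1), a = pos[i]
                (r2, c2), b = pos[j]
                d = 2.0 * math.hypot(r1 - r2, c1 - c2)
                if d <= 2.0:
                    expect |= {a, b}
        assert got == expect


def test_contact_log_episode_semantics():
    log = pc.ContactLog()
    # one pair violating ticks 10..40, interrupted, again 50..55
    for t in range(10, 41):
        log.update([(1, 2)], t)
    for t in range(41, 50):
        log.update([], t)
    for t in range(50, 56):
        log.update([(1, 2)], t)
    log.close_all(56)
    assert log.episodes[(1, 2)] == [(10, 40), (50, 55)]
    assert log.durations_ticks() == [31, 6]


def test_contact_log_pairs_are_symmetric_and_disjoint(corridor_cfg):
    day = pc.run_day(corridor_cfg.replace(daily_total=30, seed=5))
    for (a, b), eps in day.contacts.episodes.items():
        assert a < b  # canonical order, no mirrored duplicates
        for (s1, e1), (s2, e2) in zip(eps, eps[1:]):
            assert e1 < s2  # ordered and non-overlapping


def test_classify_stage_thresholds(trap):
    grid, _ = trap
    assert pc.classify_stage([], False, grid) == 1
    off_path = [{(7, 9), (7, 10), (8, 10)}]          # inside the room
    assert pc.classify_stage(off_path, False, grid) == 2
    on_path = [{(4, 9), (4, 10), (3, 10)}]           # touches the main path
    assert pc.classify_stage(on_path, False, grid) == 3
    assert pc.classify_stage(on_path, True, grid) == 4


def test_update_contact_log_function_form():
    log = pc.ContactLog()
    engine.update_contact_log(log, [(3, 7)], 5)
    engine.update_contact_log(log, [], 6)
    assert log.episodes[(3, 7)] == [(5, 5)]


def test_gate_queue_grows_when_gate_blocked(corridor):
    """With the gate cells held occupied, arrivals queue outside."""
    grid, tables = corridor
    cfg = pc.EngineConfig(grid=grid, tables=tables, daily_total=0,
                          open_window=(8, 9), seed=0)
    w = engine.World(cfg)
    for cell in grid.gates[0].cells:
        w.add_visitor(cell, route=[])  # blockers parked on the gate
    w._closed_cats = set()
    v = w._make_visitor("g0")
    assert not w._try_place(v, "g0")
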