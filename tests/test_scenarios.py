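"""Scenario transformations: closures, opening hours, avoidance, boards."""

import pytest

import parkcap as pc
from parkcap import behavior as bh
from parkcap.scenarios import ScenarioError, apply_scenario


def test_closure_drops_only_affected_visitor_types(ring):
    grid, tables = ring
    cfg = pc.EngineConfig(grid=grid, tables=tables, daily_total=120,
                          open_window=(7, 17), seed=21)
    closed = pc.apply_target_closure(
        cfg, [pc.TargetCategory.ENTERTAINMENT_FACILITY])
    day = pc.run_day(closed)
    base = pc.run_day(cfg)
    # with-children demand (3%) is dropped, not reassigned
    assert day.entered < base.entered
    assert day.entered + day.dropped + day.queued_unserved == 120
    assert day.dropped > 0


def test_closing_everything_is_an_error(ring):
    grid, tables = ring
    cfg = pc.EngineConfig(grid=grid, tables=tables, daily_total=10,
                          open_window=(7, 17), seed=0)
    with pytest.raises(ScenarioError):
        pc.apply_target_closure(cfg, [t.id for t in grid.targets])


def test_closure_of_nothing_is_identity(ring):
    grid, tables = ring
    cfg = pc.EngineConfig(grid=grid, tables=tables, daily_total=10,
                          open_window=(7, 17), seed=0)
    same = pc.apply_target_closure(cfg, [])
    assert same.closed_targets == frozenset()


def test_opening_hours_period_compositions(ring):
    grid, tables = ring
    cfg = pc.EngineConfig(grid=grid, tables=tables, daily_total=10,
                          open_window=(7, 17), seed=0)
    midday = pc.apply_opening_hours(cfg, (11, 15))
    assert set(midday.composition_override) == {
        t for t, p in tables.composition.items() if p > 0}
    evening = pc.apply_opening_hours(cfg, (15, 19))
    assert pc.VisitorType.TOURIST not in evening.composition_override
    assert sum(evening.composition_override.values()) == pytest.approx(1.0)
    with pytest.raises(ScenarioError):
        pc.apply_opening_hours(cfg, (7, 15))  # not a 4 h period
    with pytest.raises(ScenarioError):
        pc.apply_opening_hours(cfg, (11, 11))


def test_avoidance_override_round_trip(corridor_cfg):
    agg = pc.set_avoidance_mode(corridor_cfg, pc.AvoidanceMode.AGGRESSIVE)
    assert agg.avoidance == pc.AvoidanceMode.AGGRESSIVE
    back = pc.set_avoidance_mode(agg, pc.AvoidanceMode.PASSIVE)
    assert back.avoidance == corridor_cfg.avoidance


def test_ai_board_zero_safe_count_blocks_entry(trap_cfg):
    cfg = pc.install_ai_board(trap_cfg, "trap", safe_count=0)
    day = pc.run_day(cfg.replace(daily_total=10, seed=2))
    trap_cells = cfg.grid.target_by_id("trap").interior_cells

    cfg2 = pc.install_ai_board(trap_cfg, "trap", safe_count=0)

    def check(world):
        assert not any(cell in trap_cells for cell in world.occupancy)

    pc.run_day(cfg2.replace(daily_total=10, seed=2), tick_callback=check)
    assert day.entered == day.exited + day.trapped


def test_ai_board_huge_safe_count_changes_nothing(trap_cfg):
    base_day = pc.run_day(trap_cfg.replace(daily_total=12, seed=4))
    cfg = pc.install_ai_board(trap_cfg, "trap", safe_count=10 ** 6)
    board_day = pc.run_day(cfg.replace(daily_total=12, seed=4))
    assert board_day.max_violation == base_day.max_violation
    assert board_day.exited == base_day.exited


def test_scenario_application_is_pure(trap_cfg):
    sc = pc.ScenarioConfig(base=trap_cfg, widen=[("trap", 10.0)],
                           ai_boards=[("trap", 5)])
    cfg = apply_scenario(sc)
    assert cfg is not trap_cfg
    assert trap_cfg.grid.target_by_id("trap").ai_board is False
    assert pc.connection_width(trap_cfg.grid, "trap") == 2.0
    assert pc.connection_width(cfg.grid, "trap") == 10.0
    assert cfg.grid.target_by_id("trap").ai_board is True


def test_empty_scenario_ratio_is_one(corridor_cfg):
    from parkcap.capacity import replicate_seeds
    sc = pc.ScenarioConfig(base=corridor_cfg)
    rule = pc.ThresholdRule(n_visitors=3, period=pc.CriticalPeriod(4))
    res = pc.run_scenario(sc, rule, seeds=replicate_seeds(9))
    assert res.ratio == 1.0
    assert res.base.capacity == res.scenario.capacity
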