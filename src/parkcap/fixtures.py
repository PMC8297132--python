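"""Synthetic benchmark parks and scaled demand fixtures.

The real parks' GIS maps are not redistributable, so capacity experiments
run on synthetic stand-ins: three mini parks reproducing the road-structure
archetypes (single ring, multiple rings, tree) with the surveyed demand
shapes scaled down ×10, plus two micro parks small enough for exhaustive
oracle checks — a single corridor with one destination room, and a
"trap-trail" park whose popular destination hides behind a 2 m opening.
"""

from __future__ import annotations

import numpy as np

from . import demand
from .behavior import VisitorType
from .engine import DemandTables
from .environment import (
    CellClass,
    Gate,
    LayoutPattern,
    LayoutSpec,
    ParkGrid,
    TargetCategory,
    TargetZone,
    generate_layout,
)

FIXTURE_SCALE = 0.1  # mini-park demand = surveyed hourly counts / 10


# -------------------------------------------------------------- mini fixtures
def mini_ring(seed: int = 0) -> tuple[ParkGrid, DemandTables]:
    """~60×60 single-ring park with the small-park demand shape."""
    spec = LayoutSpec(
        pattern=LayoutPattern.RING, extent=(60, 60),
        n_targets={TargetCategory.POPULAR_SCENERY: 2, TargetCategory.TRAIL: 2,
                   TargetCategory.OPEN_SPACE: 1,
                   TargetCategory.ENTERTAINMENT_FACILITY: 1},
        seed=seed,
    )
    grid = generate_layout(spec)
    tables = demand.demand_tables(demand.BAILUZHOU, "weekday", FIXTURE_SCALE)
    _attach_arrivals(grid, demand.BAILUZHOU)
    return grid, tables


def mini_multi_ring(seed: int = 0) -> tuple[ParkGrid, DemandTables]:
    """~100×100 multiple-ring park with the large-park demand shape."""
    spec = LayoutSpec(
        pattern=LayoutPattern.MULTI_RING, extent=(100, 100),
        n_targets={TargetCategory.POPULAR_SCENERY: 3, TargetCategory.TRAIL: 2,
                   TargetCategory.OPEN_SPACE: 2,
                   TargetCategory.ENTERTAINMENT_FACILITY: 1},
        seed=seed,
    )
    grid = generate_layout(spec)
    tables = demand.demand_tables(demand.XUANWU, "weekday", FIXTURE_SCALE)
    _attach_arrivals(grid, demand.XUANWU)
    return grid, tables


def mini_tree(seed: int = 0) -> tuple[ParkGrid, DemandTables]:
    """~100×40 linear (tree) park with the scenic-area demand shape.

    The terminal popular-scenery target sits at the end of the single main
    path; the surveyed composition has no with-children visitors, matching
    the absence of entertainment facilities."""
    spec = LayoutSpec(
        pattern=LayoutPattern.TREE, extent=(40, 100),
        n_targets={TargetCategory.TRAIL: 2, TargetCategory.OPEN_SPACE: 1},
        seed=seed,
    )
    grid = generate_layout(spec)
    tables = demand.demand_tables(demand.MAUSOLEUM, "weekday", FIXTURE_SCALE)
    _attach_arrivals(grid, demand.MAUSOLEUM)
    return grid, tables


def _attach_arrivals(grid: ParkGrid, park: str) -> None:
    for gate in grid.gates:
        gate.hourly_arrivals = {
            day: {h: v * FIXTURE_SCALE for h, v in table.items()}
            for day, table in demand.HOURLY_GATE_COUNTS[park].items()
        }


def generate_fixture_suite(seed: int = 0) -> dict:
    """All three mini parks with their demand tables, deterministic by seed."""
    return {
        "mini_ring": mini_ring(seed),
        "mini_multi_ring": mini_multi_ring(seed),
        "mini_tree": mini_tree(seed),
    }


# ------------------------------------------------------------- micro fixtures
def micro_corridor() -> tuple[ParkGrid, DemandTables]:
    """A single-file corridor park: gate, 24 m main path, one walled room.

    All demand is tourists bound for the one destination; returning visitors
    meet incoming ones head-on in the corridor, so the day classification
    rises steeply with the daily total — small enough for exhaustive
    capacity scans. One demand hour; sub-hour stays.
    """
    h, w = 7, 18
    cells = np.full((h, w), int(CellClass.INACCESSIBLE), dtype=np.int8)
    row = 3
    for c in range(1, 13):
        cells[row, c] = int(CellClass.PATH_MAIN)
    grid = ParkGrid(cells=cells)
    gate_cells = [(row, 0), (row - 1, 0)]
    for cell in gate_cells:
        grid.cells[cell] = int(CellClass.GATE)
    grid.gates.append(Gate(id="g0", cells=gate_cells, weight=1.0))
    interior = {(r, c) for r in range(2, 5) for c in range(14, 17)}
    door = (row, 13)
    for cell in interior | {door}:
        grid.cells[cell] = int(CellClass.TARGET_INTERIOR)
    grid.targets.append(TargetZone(
        id="room", category=TargetCategory.POPULAR_SCENERY,
        interior_cells=interior | {door}, entrance_cells={door}))
    grid.validate()
    tables = DemandTables(
        hourly={8: 1.0},
        composition={VisitorType.TOURIST: 1.0},
        durations={"<1h": 1.0},
    )
    return grid, tables


def trap_trail(seed: int = 0) -> tuple[ParkGrid, DemandTables]:
    """A main path with a popular walled destination behind a 2 m opening.

    Most visitors head for the "trap" room whose single-cell doorway onto
    the main path bottlenecks entry and exit; a second open-space target
    further along gives replanning visitors an alternative. The layout is
    the benchmark for opening-width and AI-board adjustments.
    """
    h, w = 12, 24
    cells = np.full((h, w), int(CellClass.INACCESSIBLE), dtype=np.int8)
    # three-lane main path: opposing streams can pass, so the trap doorway —
    # not the open path — is the binding bottleneck
    for c in range(1, 21):
        for r in (2, 3, 4):
            cells[r, c] = int(CellClass.PATH_MAIN)
    grid = ParkGrid(cells=cells)
    gate_cells = [(2, 0), (3, 0), (4, 0)]
    for cell in gate_cells:
        grid.cells[cell] = int(CellClass.GATE)
    grid.gates.append(Gate(id="g0", cells=gate_cells, weight=1.0))
    # the trap: a roomy scenery garden below the path whose single-cell
    # doorway onto the main path is the bottleneck; the interior is large
    # enough that in-garden density stays low and the doorway binds
    interior = {(r, c) for r in range(6, 11) for c in range(2, 20)}
    door = (5, 10)
    for cell in interior | {door}:
        grid.cells[cell] = int(CellClass.TARGET_INTERIOR)
    grid.targets.append(TargetZone(
        id="trap", category=TargetCategory.POPULAR_SCENERY,
        interior_cells=interior | {door}, entrance_cells={door}))
    # alternative open space above the path further along
    interior2 = {(r, c) for c in range(16, 19) for r in (0,)}
    door2 = (1, 17)
    for cell in interior2 | {door2}:
        grid.cells[cell] = int(CellClass.OPEN_SPACE)
    grid.targets.append(TargetZone(
        id="lawn", category=TargetCategory.OPEN_SPACE,
        interior_cells=interior2 | {door2}, entrance_cells={door2}))
    grid.validate()
    tables = DemandTables(
        hourly={8: 1.0},
        composition={VisitorType.TOURIST: 0.8, VisitorType.LEISURE: 0.2},
        durations={"<1h": 1.0},
    )
    return grid, tables
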