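"""Park grid representation, I/O round-trips, layout generation and edits."""

import numpy as np
import pytest

import parkcap as pc
from parkcap.environment import (
    GridEditError,
    ParkFormatError,
    ParkValidationError,
)
from parkcap.fixtures import generate_fixture_suite


def tiny_park():
    """3x3 all-path park with one gate and one single-cell target."""
    cells = np.full((3, 3), int(pc.CellClass.PATH_MAIN), dtype=np.int8)
    grid = pc.ParkGrid(cells=cells)
    grid.cells[0, 0] = int(pc.CellClass.GATE)
    grid.gates.append(pc.Gate(id="g", cells=[(0, 0)], weight=1.0))
    grid.cells[2, 2] = int(pc.CellClass.TARGET_INTERIOR)
    grid.targets.append(pc.TargetZone(
        id="t", category=pc.TargetCategory.POPULAR_SCENERY,
        interior_cells={(2, 2)}, entrance_cells={(2, 2)}))
    grid.validate()
    return grid


def test_accessible_area_counts_walkable_cells():
    grid = tiny_park()
    assert pc.accessible_area(grid) == 36.0  # 9 cells x 4 m^2
    water = pc.ParkGrid(cells=np.full((3, 3), int(pc.CellClass.WATER),
                                      dtype=np.int8))
    assert pc.accessible_area(water) == 0.0


def test_save_load_round_trip_is_identity(tmp_path, ring, tree):
    for grid in (tiny_park(), ring[0], tree[0]):
        g1, m1 = tmp_path / "a.grid", tmp_path / "a.park.yaml"
        pc.save_park(grid, g1, m1)
        back = pc.load_park(g1, m1)
        g2, m2 = tmp_path / "b.grid", tmp_path / "b.park.yaml"
        pc.save_park(back, g2, m2)
        assert g1.read_text() == g2.read_text()
        assert m1.read_text() == m2.read_text()
        assert (back.cells == grid.cells).all()
        assert back.one_way == grid.one_way


def test_load_rejects_unknown_cell_code(tmp_path):
    grid = tiny_park()
    gf, mf = tmp_path / "p.grid", tmp_path / "p.park.yaml"
    pc.save_park(grid, gf, mf)
    lines = gf.read_text().splitlines()
    lines[1] = lines[1].replace(lines[1].split()[0], "99", 1)
    gf.write_text("\n".join(lines) + "\n")
    with pytest.raises(ParkFormatError):
        pc.load_park(gf, mf)


def test_validate_rejects_gate_on_inaccessible_cell():
    grid = tiny_park()
    grid.cells[0, 0] = int(pc.CellClass.WATER)
    with pytest.raises(ParkValidationError):
        grid.validate()


@pytest.mark.parametrize("pattern,extent", [
    (pc.LayoutPattern.RING, (60, 60)),
    (pc.LayoutPattern.MULTI_RING, (100, 100)),
    (pc.LayoutPattern.TREE, (40, 100)),
])
def test_generated_layouts_validate_and_are_deterministic(pattern, extent):
    nt = {c: 1 for c in pc.TargetCategory}
    spec = pc.LayoutSpec(pattern=pattern, extent=extent, n_targets=nt, seed=5)
    g1 = pc.generate_layout(spec)
    g2 = pc.generate_layout(spec)
    assert (g1.cells == g2.cells).all()
    g1.validate()


def test_generated_layouts_validate_over_many_seeds():
    for seed in range(25):
        for pattern, extent in ((pc.LayoutPattern.RING, (60, 60)),
                                (pc.LayoutPattern.MULTI_RING, (100, 100)),
                                (pc.LayoutPattern.TREE, (40, 100))):
            spec = pc.LayoutSpec(pattern=pattern, extent=extent,
                                 n_targets={c: 1 for c in pc.TargetCategory},
                                 seed=seed)
            pc.generate_layout(spec).validate()


def test_tree_layout_has_unique_main_path_route(tree):
    """The main-path subgraph of a tree park is a simple path: exactly one
    route from the gate to the terminal target."""
    grid, _ = tree
    main = {tuple(map(int, c)) for c in np.argwhere(
        grid.cells == int(pc.CellClass.PATH_MAIN))}
    # every main-path cell has at most 2 main-path neighbours -> simple path
    def deg(cell):
        r, c = cell
        return sum(((r + dr, c + dc) in main)
                   for dr, dc in ((-1, 0), (0, -1), (0, 1), (1, 0)))
    degrees = [deg(c) for c in main]
    assert max(degrees) <= 2
    assert sum(1 for d in degrees if d == 1) == 2  # two endpoints only


def test_connection_width_measures_opening_runs(trap):
    grid, _ = trap
    assert pc.connection_width(grid, "trap") == 2.0  # single-cell doorway
    wide = pc.widen_opening(grid, "trap", 10.0)
    assert pc.connection_width(wide, "trap") == 10.0
    # widening to the current width is the identity
    same = pc.widen_opening(grid, "trap", 2.0)
    assert (same.cells == grid.cells).all()


def test_widen_opening_respects_cap_and_narrowing(trap):
    grid, _ = trap
    with pytest.raises(GridEditError):
        pc.widen_opening(grid, "trap", 12.0)
    wide = pc.widen_opening(grid, "trap", 10.0)
    with pytest.raises(GridEditError):
        pc.widen_opening(wide, "trap", 4.0)  # below current width


def test_connection_width_detached_target_errors():
    grid = tiny_park()
    grid.targets.append(pc.TargetZone(
        id="detached", category=pc.TargetCategory.TRAIL,
        interior_cells={(2, 2)}, entrance_cells=set()))
    with pytest.raises(ParkValidationError):
        pc.connection_width(grid, "detached")


def test_one_way_path_blocks_reverse_routing(tree):
    grid, _ = tree
    chain = [(30, c) for c in range(10, 16)]
    edited = pc.add_one_way_path(grid, chain)
    fwd = pc.astar_route(edited, chain[0], chain[-1])
    assert fwd == chain
    rev = pc.astar_route(edited, chain[-1], chain[0])
    # the reverse route, if any, must not run back along the chain
    assert rev is None or not any(c in set(chain) for c in rev[1:-1])


def test_one_way_path_empty_chain_is_identity(tree):
    grid, _ = tree
    edited = pc.add_one_way_path(grid, [])
    assert (edited.cells == grid.cells).all()
    assert edited.one_way == grid.one_way


def test_one_way_over_accessible_cells_preserves_area(tree):
    grid, _ = tree
    row_cells = [(20, c) for c in range(5, 12)]  # already main path
    edited = pc.add_one_way_path(grid, row_cells)
    assert pc.accessible_area(edited) == pc.accessible_area(grid)


def test_one_way_discontiguous_chain_errors(tree):
    grid, _ = tree
    with pytest.raises(GridEditError):
        pc.add_one_way_path(grid, [(22, 10), (22, 13)])


def test_fixture_suite_regenerates_bit_identically():
    a = generate_fixture_suite(3)
    b = generate_fixture_suite(3)
    for name in a:
        assert (a[name][0].cells == b[name][0].cells).all()
        a[name][0].validate()
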