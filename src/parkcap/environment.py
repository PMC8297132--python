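"""Park environments as 2 m raster grids.

A park is a rectangular raster of surface classes at a fixed 2 m cell size,
plus metadata: entrance gates with hourly arrival counts, typed target zones
(popular scenery, trails, open space, entertainment facilities) with interior
and entrance cells, and optional one-way restrictions on path cells.

Movement is 4-connected: orthogonal neighbours are 2 m apart (the social
distancing threshold), diagonal neighbours 2.83 m (compliant), so a one-cell
wide trail is single file by construction.
"""

from __future__ import annotations

import copy
import math
from collections import deque
from dataclasses import dataclass, field
from enum import IntEnum
from pathlib import Path

import numpy as np
import yaml

CELL_SIZE_M = 2.0
CELL_AREA_M2 = CELL_SIZE_M * CELL_SIZE_M

#: orthogonal step offsets, in deterministic (row, col) scan order
ORTHO = ((-1, 0), (0, -1), (0, 1), (1, 0))


class CellClass(IntEnum):
    """Surface class of one raster cell."""

    INACCESSIBLE = 0  # planted lawn, shrubs, buildings — no entry
    WATER = 1
    PATH_MAIN = 2
    PATH_TRAIL = 3
    OPEN_SPACE = 4
    OPEN_LAWN = 5
    TARGET_INTERIOR = 6
    GATE = 7


ACCESSIBLE_CLASSES = frozenset(
    {
        CellClass.PATH_MAIN,
        CellClass.PATH_TRAIL,
        CellClass.OPEN_SPACE,
        CellClass.OPEN_LAWN,
        CellClass.TARGET_INTERIOR,
        CellClass.GATE,
    }
)


class TargetCategory(IntEnum):
    POPULAR_SCENERY = 0
    TRAIL = 1
    OPEN_SPACE = 2
    ENTERTAINMENT_FACILITY = 3


class LayoutPattern(IntEnum):
    RING = 0
    MULTI_RING = 1
    TREE = 2


class ParkFormatError(ValueError):
    """Raised when a park raster or sidecar file cannot be parsed."""


class ParkValidationError(ValueError):
    """Raised when a grid violates a structural invariant."""


class LayoutGenerationError(ValueError):
    """Raised when a layout spec cannot be realised."""


class GridEditError(ValueError):
    """Raised when a layout edit cannot be applied."""


@dataclass
class Gate:
    id: str
    cells: list[tuple[int, int]]
    hourly_arrivals: dict[str, dict[int, float]] = field(default_factory=dict)
    weight: float = 1.0


@dataclass
class TargetZone:
    id: str
    category: TargetCategory
    interior_cells: set[tuple[int, int]]
    entrance_cells: set[tuple[int, int]]
    ai_board: bool = False
    safe_count: int | None = None


@dataclass
class LayoutSpec:
    """Parameters for a synthetic park layout of one road-structure archetype."""

    pattern: LayoutPattern
    extent: tuple[int, int] = (60, 60)
    n_targets: dict[TargetCategory, int] = field(
        default_factory=lambda: {c: 1 for c in TargetCategory}
    )
    trail_width: int = 1
    opening_width: int = 1
    seed: int = 0


@dataclass(eq=False)
class ParkGrid:
    """A validated 2 m-resolution park raster with gates and target zones.

    ``cells[row, col]`` holds a :class:`CellClass` code; row 0 is the top row.
    ``one_way`` maps a cell to the single (drow, dcol) step allowed out of it.
    """

    cells: np.ndarray
    gates: list[Gate] = field(default_factory=list)
    targets: list[TargetZone] = field(default_factory=list)
    one_way: dict[tuple[int, int], tuple[int, int]] = field(default_factory=dict)
    cell_size: float = CELL_SIZE_M

    # ------------------------------------------------------------------ basics
    @property
    def height(self) -> int:
        return self.cells.shape[0]

    @property
    def width(self) -> int:
        return self.cells.shape[1]

    def in_bounds(self, cell: tuple[int, int]) -> bool:
        r, c = cell
        return 0 <= r < self.height and 0 <= c < self.width

    def cell_class(self, cell: tuple[int, int]) -> CellClass:
        return CellClass(int(self.cells[cell]))

    def is_accessible(self, cell: tuple[int, int]) -> bool:
        return self.in_bounds(cell) and int(self.cells[cell]) in _ACCESSIBLE_CODES

    def step_allowed(self, frm: tuple[int, int], to: tuple[int, int]) -> bool:
        """True if moving frm→to honours accessibility and one-way masks."""
        if not self.is_accessible(to):
            return False
        restr = self.one_way.get(frm)
        if restr is not None and (to[0] - frm[0], to[1] - frm[1]) != restr:
            return False
        return True

    def neighbors(self, cell: tuple[int, int]):
        r, c = cell
        for dr, dc in ORTHO:
            nxt = (r + dr, c + dc)
            if self.step_allowed(cell, nxt):
                yield nxt

    def target_by_id(self, target_id: str) -> TargetZone:
        for t in self.targets:
            if t.id == target_id:
                return t
        raise KeyError(target_id)

    def gate_by_id(self, gate_id: str) -> Gate:
        for g in self.gates:
            if g.id == gate_id:
                return g
        raise KeyError(gate_id)

    def copy(self) -> "ParkGrid":
        return ParkGrid(
            cells=self.cells.copy(),
            gates=copy.deepcopy(self.gates),
            targets=copy.deepcopy(self.targets),
            one_way=dict(self.one_way),
            cell_size=self.cell_size,
        )

    # -------------------------------------------------------------- validation
    def validate(self) -> None:
        """Check structural invariants; raise ParkValidationError on failure.

        Every gate and target entrance cell must be accessible, and the
        accessible subgraph (restricted to allowed directions) must connect
        every gate to every target entrance.
        """
        if not self.gates:
            raise ParkValidationError("park has no gates")
        for g in self.gates:
            for cell in g.cells:
                if not self.is_accessible(cell):
                    raise ParkValidationError(f"gate {g.id} cell {cell} inaccessible")
        for t in self.targets:
            if not t.interior_cells:
                raise ParkValidationError(f"target {t.id} has no interior")
            for cell in t.entrance_cells:
                if not self.is_accessible(cell):
                    raise ParkValidationError(
                        f"target {t.id} entrance {cell} inaccessible"
                    )
        wsum = sum(g.weight for g in self.gates)
        if not math.isclose(wsum, 1.0, abs_tol=1e-6):
            raise ParkValidationError(f"gate weights sum to {wsum}, expected 1")
        for g in self.gates:
            reach = self._reachable_from(g.cells[0])
            for t in self.targets:
                if not (t.entrance_cells & reach):
                    raise ParkValidationError(
                        f"target {t.id} unreachable from gate {g.id}"
                    )

    def _reachable_from(self, start: tuple[int, int]) -> set[tuple[int, int]]:
        seen = {start}
        q = deque([start])
        while q:
            cur = q.popleft()
            for nxt in self.neighbors(cur):
                if nxt not in seen:
                    seen.add(nxt)
                    q.append(nxt)
        return seen


_ACCESSIBLE_CODES = frozenset(int(c) for c in ACCESSIBLE_CLASSES)


# ---------------------------------------------------------------------- areas
def accessible_area(grid: ParkGrid) -> float:
    """Walkable area in m²: 4 m² per accessible cell."""
    codes = np.asarray(sorted(_ACCESSIBLE_CODES))
    return float(np.isin(grid.cells, codes).sum()) * CELL_AREA_M2


def connection_width(grid: ParkGrid, target: TargetZone | str) -> float:
    """Width (m) of a target's widest opening onto the surrounding paths.

    The opening width is 2 m times the longest run of orthogonally contiguous
    entrance cells each adjacent to an accessible cell outside the zone.
    """
    if isinstance(target, str):
        target = grid.target_by_id(target)
    if not target.entrance_cells:
        raise ParkValidationError(f"target {target.id} has no entrance cells")
    zone = target.interior_cells | target.entrance_cells
    open_cells = set()
    for cell in target.entrance_cells:
        r, c = cell
        for dr, dc in ORTHO:
            out = (r + dr, c + dc)
            if out not in zone and grid.is_accessible(out):
                open_cells.add(cell)
                break
    if not open_cells:
        raise ParkValidationError(f"target {target.id} is detached from the paths")
    best = 0
    seen: set[tuple[int, int]] = set()
    for cell in open_cells:
        if cell in seen:
            continue
        comp, q = {cell}, deque([cell])
        while q:
            r, c = q.popleft()
            for dr, dc in ORTHO:
                nb = (r + dr, c + dc)
                if nb in open_cells and nb not in comp:
                    comp.add(nb)
                    q.append(nb)
        seen |= comp
        best = max(best, len(comp))
    return best * CELL_SIZE_M


# ------------------------------------------------------------------- file I/O
def save_park(grid: ParkGrid, grid_file, meta_file) -> None:
    """Write the raster (.grid text) and metadata sidecar (YAML)."""
    grid_file, meta_file = Path(grid_file), Path(meta_file)
    lines = [f"{grid.height} {grid.width} {int(grid.cell_size)}"]
    for row in grid.cells:
        lines.append(" ".join(str(int(v)) for v in row))
    grid_file.write_text("\n".join(lines) + "\n")

    meta = {
        "gates": [
            {
                "id": g.id,
                "cells": [list(c) for c in g.cells],
                "weight": float(g.weight),
                "hourly_arrivals": {
                    day: {int(h): float(v) for h, v in table.items()}
                    for day, table in g.hourly_arrivals.items()
                },
            }
            for g in grid.gates
        ],
        "targets": [
            {
                "id": t.id,
                "category": t.category.name,
                "interior": sorted([list(c) for c in t.interior_cells]),
                "entrances": sorted([list(c) for c in t.entrance_cells]),
                "ai_board": bool(t.ai_board),
                "safe_count": t.safe_count,
            }
            for t in grid.targets
        ],
        "one_way": [
            {"cell": list(cell), "direction": list(d)}
            for cell, d in sorted(grid.one_way.items())
        ],
    }
    meta_file.write_text(yaml.safe_dump(meta, sort_keys=True))


def load_park(grid_file, meta_file) -> ParkGrid:
    """Read a park from raster + sidecar files and validate it."""
    grid_file, meta_file = Path(grid_file), Path(meta_file)
    lines = grid_file.read_text().strip().splitlines()
    try:
        rows, cols, cell_size = (int(float(x)) for x in lines[0].split())
    except Exception as exc:  # noqa: BLE001 - normalise to format error
        raise ParkFormatError(f"bad header line: {lines[0]!r}") from exc
    if len(lines) != rows + 1:
        raise ParkFormatError(f"expected {rows} raster rows, got {len(lines) - 1}")
    cells = np.zeros((rows, cols), dtype=np.int8)
    valid = {int(c) for c in CellClass}
    for i, line in enumerate(lines[1:]):
        vals = [int(x) for x in line.split()]
        if len(vals) != cols:
            raise ParkFormatError(f"row {i} has {len(vals)} columns, expected {cols}")
        for v in vals:
            if v not in valid:
                raise ParkFormatError(f"unknown cell code {v} in row {i}")
        cells[i] = vals

    meta = yaml.safe_load(meta_file.read_text()) or {}
    gates = [
        Gate(
            id=str(g["id"]),
            cells=[tuple(c) for c in g["cells"]],
            weight=float(g.get("weight", 1.0)),
            hourly_arrivals={
                day: {int(h): float(v) for h, v in table.items()}
                for day, table in (g.get("hourly_arrivals") or {}).items()
            },
        )
        for g in meta.get("gates", [])
    ]
    targets = [
        TargetZone(
            id=str(t["id"]),
            category=TargetCategory[t["category"]],
            interior_cells={tuple(c) for c in t["interior"]},
            entrance_cells={tuple(c) for c in t["entrances"]},
            ai_board=bool(t.get("ai_board", False)),
            safe_count=t.get("safe_count"),
        )
        for t in meta.get("targets", [])
    ]
    one_way = {
        tuple(e["cell"]): tuple(e["direction"]) for e in meta.get("one_way", [])
    }
    grid = ParkGrid(
        cells=cells, gates=gates, targets=targets, one_way=one_way,
        cell_size=float(cell_size),
    )
    grid.validate()
    return grid


# ------------------------------------------------------------------- editing
def widen_opening(grid: ParkGrid, target_id: str, new_width: float,
                  max_width: float = 10.0) -> ParkGrid:
    """Return a copy of the grid with a target's opening widened to new_width m.

    The widest existing run of entrance cells is extended sideways by turning
    flanking wall (INACCESSIBLE) cells into entrance cells, provided each new
    cell faces an accessible outside cell. The default cap is a 10 m maximum.
    """
    out = grid.copy()
    target = out.target_by_id(target_id)
    cur = connection_width(out, target)
    if new_width < cur:
        raise GridEditError(f"new width {new_width} m below current {cur} m")
    if new_width > max_width:
        raise GridEditError(f"new width {new_width} m exceeds {max_width} m cap")
    if new_width == cur:
        return out
    need = int(round(new_width / CELL_SIZE_M)) - int(round(cur / CELL_SIZE_M))

    zone = target.interior_cells | target.entrance_cells
    # locate the widest opening run and its outward direction
    run, out_dir = _widest_opening_run(out, target)
    axis = (out_dir[1], out_dir[0])  # run extends perpendicular to outward dir
    ends = sorted(run)
    frontier = [ends[0], ends[-1]]
    added = 0
    while added < need:
        progressed = False
        for i, end in enumerate(frontier):
            if added >= need:
                break
            step = axis if i else (-axis[0], -axis[1])
            cand = (end[0] + step[0], end[1] + step[1])
            face = (cand[0] + out_dir[0], cand[1] + out_dir[1])
            if (
                out.in_bounds(cand)
                and out.cell_class(cand) == CellClass.INACCESSIBLE
                and out.is_accessible(face)
                and cand not in zone
            ):
                out.cells[cand] = int(CellClass.TARGET_INTERIOR)
                target.entrance_cells.add(cand)
                target.interior_cells.add(cand)
                zone.add(cand)
                frontier[i] = cand
                added += 1
                progressed = True
        if not progressed:
            raise GridEditError(
                f"no room to widen target {target_id} to {new_width} m"
            )
    out.validate()
    return out


def _widest_opening_run(grid: ParkGrid, target: TargetZone):
    """Return (cells, outward direction) of the widest opening run."""
    zone = target.interior_cells | target.entrance_cells
    open_dirs: dict[tuple[int, int], tuple[int, int]] = {}
    for cell in target.entrance_cells:
        for dr, dc in ORTHO:
            outc = (cell[0] + dr, cell[1] + dc)
            if outc not in zone and grid.is_accessible(outc):
                open_dirs[cell] = (dr, dc)
                break
    if not open_dirs:
        raise ParkValidationError(f"target {target.id} is detached from the paths")
    best: set[tuple[int, int]] = set()
    seen: set[tuple[int, int]] = set()
    for cell in sorted(open_dirs):
        if cell in seen:
            continue
        comp, q = {cell}, deque([cell])
        while q:
            r, c = q.popleft()
            for dr, dc in ORTHO:
                nb = (r + dr, c + dc)
                if nb in open_dirs and nb not in comp:
                    comp.add(nb)
                    q.append(nb)
        seen |= comp
        if len(comp) > len(best):
            best = comp
    return best, open_dirs[next(iter(sorted(best)))]


def add_one_way_path(grid: ParkGrid, cells: list[tuple[int, int]],
                     ) -> ParkGrid:
    """Return a copy with `cells` carved as a forward-only one-way trail.

    The ordered chain must be orthogonally contiguous. Non-path cells along it
    (including water: the chain may bridge) become PATH_TRAIL; every chain cell
    except the last is masked to allow only the step towards its successor.
    """
    if not cells:
        return grid.copy()
    out = grid.copy()
    for a, b in zip(cells, cells[1:]):
        if abs(a[0] - b[0]) + abs(a[1] - b[1]) != 1:
            raise GridEditError(f"chain discontiguous between {a} and {b}")
    for cell in cells:
        if not out.in_bounds(cell):
            raise GridEditError(f"chain cell {cell} out of bounds")
        if not out.is_accessible(cell):
            out.cells[cell] = int(CellClass.PATH_TRAIL)
    for a, b in zip(cells, cells[1:]):
        out.one_way[a] = (b[0] - a[0], b[1] - a[1])
    out.validate()
    return out


# ----------------------------------------------------------------- generators
def generate_layout(spec: LayoutSpec) -> ParkGrid:
    """Generate a synthetic park of one of the three road-structure archetypes.

    RING: one circular main path with targets hung off it; MULTI_RING: an
    outer and an inner main-path ring joined by spokes, targets on the inner
    ring; TREE: a single linear main path from the gate (parking-lot style
    origin) to a terminal target, with dead-end side trails. Deterministic
    given ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    h, w = spec.extent
    if h < 30 or w < 30:
        raise LayoutGenerationError("extent too small (need at least 30x30)")
    builder = {
        LayoutPattern.RING: _build_ring,
        LayoutPattern.MULTI_RING: _build_multi_ring,
        LayoutPattern.TREE: _build_tree,
    }[spec.pattern]
    grid = builder(spec, rng)
    grid.validate()
    return grid


def _blank(h: int, w: int) -> np.ndarray:
    return np.full((h, w), int(CellClass.INACCESSIBLE), dtype=np.int8)


def _draw_rect_ring(cells: np.ndarray, top: int, left: int, bottom: int,
                    right: int, width: int, code: int) -> list[tuple[int, int]]:
    ring = []
    for k in range(width):
        t, l, b, r = top + k, left + k, bottom - k, right - k
        for c in range(l, r + 1):
            ring.append((t, c))
            ring.append((b, c))
        for rr in range(t + 1, b):
            ring.append((rr, l))
            ring.append((rr, r))
    for cell in ring:
        cells[cell] = code
    return ring


_ROOM_CATEGORIES = {
    TargetCategory.POPULAR_SCENERY: CellClass.TARGET_INTERIOR,
    TargetCategory.OPEN_SPACE: CellClass.OPEN_SPACE,
    TargetCategory.ENTERTAINMENT_FACILITY: CellClass.TARGET_INTERIOR,
}


def _category_order(spec: LayoutSpec) -> list[TargetCategory]:
    order = []
    for cat in TargetCategory:
        order.extend([cat] * spec.n_targets.get(cat, 0))
    return order


def _attach_room(grid: ParkGrid, anchor: tuple[int, int], inward: tuple[int, int],
                 cat: TargetCategory, tid: str, opening_width: int,
                 room: int = 5) -> bool:
    """Attach a walled room target behind `anchor` (a path cell), opening
    towards the path. Returns False if it does not fit."""
    dr, dc = inward
    # room occupies a (room x room) block starting 2 cells inward of anchor
    r0 = anchor[0] + dr * 2 + (-room // 2 if dc else (0 if dr > 0 else -room + 1))
    c0 = anchor[1] + dc * 2 + (-room // 2 if dr else (0 if dc > 0 else -room + 1))
    block = [(r, c) for r in range(r0, r0 + room) for c in range(c0, c0 + room)]
    for cell in block:
        if not grid.in_bounds(cell) or grid.cell_class(cell) != CellClass.INACCESSIBLE:
            return False
    code = _ROOM_CATEGORIES[cat]
    for cell in block:
        grid.cells[cell] = int(code)
    # wall gap: entrance cells between anchor and the room
    door = (anchor[0] + dr, anchor[1] + dc)
    entrances = {door}
    axis = (dc, dr)
    for k in range(1, opening_width):
        side = 1 if k % 2 else -1
        off = (k + 1) // 2 * side
        cand = (door[0] + axis[0] * off, door[1] + axis[1] * off)
        face = (cand[0] - dr, cand[1] - dc)
        if grid.in_bounds(cand) and grid.is_accessible(face):
            entrances.add(cand)
    interior = set(block)
    for cell in entrances:
        grid.cells[cell] = int(code)
        interior.add(cell)
    grid.targets.append(
        TargetZone(id=tid, category=cat, interior_cells=interior,
                   entrance_cells=entrances)
    )
    return True


def _attach_trail(grid: ParkGrid, anchor: tuple[int, int], inward: tuple[int, int],
                  tid: str, length: int = 10) -> bool:
    """Attach a one-cell-wide dead-end trail target behind `anchor`."""
    dr, dc = inward
    cells = []
    for k in range(1, length + 1):
        cell = (anchor[0] + dr * k, anchor[1] + dc * k)
        if not grid.in_bounds(cell) or grid.cell_class(cell) != CellClass.INACCESSIBLE:
            break
        cells.append(cell)
    if len(cells) < 4:
        return False
    for cell in cells:
        grid.cells[cell] = int(CellClass.PATH_TRAIL)
    grid.targets.append(
        TargetZone(id=tid, category=TargetCategory.TRAIL,
                   interior_cells=set(cells), entrance_cells={cells[0]})
    )
    return True


def _place_targets(grid: ParkGrid, anchors: list[tuple[tuple[int, int], tuple[int, int]]],
                   spec: LayoutSpec, rng: np.random.Generator) -> None:
    cats = _category_order(spec)
    order = rng.permutation(len(anchors))
    ai = 0
    for idx, cat in enumerate(cats):
        placed = False
        for j in order[ai:]:
            anchor, inward = anchors[int(j)]
            tid = f"t{idx}_{cat.name.lower()}"
            if cat == TargetCategory.TRAIL:
                ok = _attach_trail(grid, anchor, inward, tid,
                                   length=8 + int(rng.integers(0, 5)))
            else:
                ok = _attach_room(grid, anchor, inward, cat, tid,
                                  spec.opening_width)
            ai += 1
            if ok:
                placed = True
                break
        if not placed:
            raise LayoutGenerationError(f"could not place target of {cat.name}")


def _build_ring(spec: LayoutSpec, rng: np.random.Generator) -> ParkGrid:
    h, w = spec.extent
    cells = _blank(h, w)
    inset = 6
    ring = _draw_rect_ring(cells, inset, inset, h - 1 - inset, w - 1 - inset,
                           2, int(CellClass.PATH_MAIN))
    grid = ParkGrid(cells=cells)
    # gate: two cells on the top edge of the ring
    mid = w // 2
    gate_cells = [(inset, mid), (inset, mid + 1)]
    for cell in gate_cells:
        grid.cells[cell] = int(CellClass.GATE)
    grid.gates.append(Gate(id="g0", cells=gate_cells, weight=1.0))
    # anchors: inner-ring cells on each side, pointing inwards
    anchors = []
    ri, ro = inset + 1, h - 2 - inset
    ci, co = inset + 1, w - 2 - inset
    for c in range(ci + 6, co - 6, 8):
        anchors.append(((ri, c), (1, 0)))
        anchors.append(((ro, c), (-1, 0)))
    for r in range(ri + 6, ro - 6, 8):
        anchors.append(((r, ci), (0, 1)))
        anchors.append(((r, co), (0, -1)))
    _place_targets(grid, anchors, spec, rng)
    # decorative pond in the middle (keeps interiors apart)
    pr, pc = h // 2, w // 2
    free = cells[pr - 2:pr + 3, pc - 2:pc + 3] == int(CellClass.INACCESSIBLE)
    cells[pr - 2:pr + 3, pc - 2:pc + 3][free] = int(CellClass.WATER)
    return grid


def _build_multi_ring(spec: LayoutSpec, rng: np.random.Generator) -> ParkGrid:
    h, w = spec.extent
    if h < 60 or w < 60:
        raise LayoutGenerationError("multi-ring layout needs at least 60x60")
    cells = _blank(h, w)
    outer_in = 6
    inner_in = 22
    _draw_rect_ring(cells, outer_in, outer_in, h - 1 - outer_in, w - 1 - outer_in,
                    2, int(CellClass.PATH_MAIN))
    _draw_rect_ring(cells, inner_in, inner_in, h - 1 - inner_in, w - 1 - inner_in,
                    2, int(CellClass.PATH_MAIN))
    # four spokes joining the rings
    mid_r, mid_c = h // 2, w // 2
    for rr in range(outer_in, inner_in):
        cells[rr, mid_c] = int(CellClass.PATH_MAIN)
        cells[h - 1 - rr, mid_c] = int(CellClass.PATH_MAIN)
    for cc in range(outer_in, inner_in):
        cells[mid_r, cc] = int(CellClass.PATH_MAIN)
        cells[mid_r, w - 1 - cc] = int(CellClass.PATH_MAIN)
    grid = ParkGrid(cells=cells)
    gate_cells = [(outer_in, mid_c - 1), (outer_in, mid_c + 1)]
    for cell in gate_cells:
        grid.cells[cell] = int(CellClass.GATE)
    grid.gates.append(Gate(id="g0", cells=gate_cells, weight=1.0))
    # anchors on the inner ring pointing into the core, and inside the outer ring
    anchors = []
    ri, ro = inner_in + 1, h - 2 - inner_in
    ci, co = inner_in + 1, w - 2 - inner_in
    for c in range(ci + 5, co - 5, 8):
        if abs(c - mid_c) > 3:
            anchors.append(((ri, c), (1, 0)))
            anchors.append(((ro, c), (-1, 0)))
    for r in range(ri + 5, ro - 5, 8):
        if abs(r - mid_r) > 3:
            anchors.append(((r, ci), (0, 1)))
            anchors.append(((r, co), (0, -1)))
    # outer band anchors (between the rings) pointing inward from the outer ring
    for c in range(outer_in + 8, w - outer_in - 8, 12):
        if abs(c - mid_c) > 4:
            anchors.append(((outer_in + 1, c), (1, 0)))
            anchors.append(((h - 2 - outer_in, c), (-1, 0)))
    _place_targets(grid, anchors, spec, rng)
    return grid


def _build_tree(spec: LayoutSpec, rng: np.random.Generator) -> ParkGrid:
    h, w = spec.extent
    cells = _blank(h, w)
    row = h // 2
    start_c, end_c = 3, w - 9
    for c in range(start_c, end_c + 1):
        cells[row, c] = int(CellClass.PATH_MAIN)
    grid = ParkGrid(cells=cells)
    # parking-lot style gate at the path origin
    gate_cells = [(row, start_c - 1), (row - 1, start_c - 1), (row + 1, start_c - 1)]
    for cell in gate_cells:
        grid.cells[cell] = int(CellClass.GATE)
    grid.gates.append(Gate(id="g0", cells=gate_cells, weight=1.0))
    # terminal target (the commemorative destination) at the far end
    ok = _attach_room(grid, (row, end_c), (0, 1),
                      TargetCategory.POPULAR_SCENERY, "t_terminal",
                      spec.opening_width, room=5)
    if not ok:
        raise LayoutGenerationError("no room for terminal target")
    # side trails and other targets hung off the spine
    anchors = []
    for c in range(start_c + 8, end_c - 6, 7):
        anchors.append(((row, c), (-1, 0)))
        anchors.append(((row, c + 3), (1, 0)))
    cats = _category_order(spec)
    cats = [c for c in cats if c != TargetCategory.POPULAR_SCENERY] or cats
    spec2 = LayoutSpec(pattern=spec.pattern, extent=spec.extent,
                       n_targets={}, trail_width=spec.trail_width,
                       opening_width=spec.opening_width, seed=spec.seed)
    for cat in cats:
        spec2.n_targets[cat] = spec2.n_targets.get(cat, 0) + 1
    _place_targets(grid, anchors, spec2, rng)
    return grid
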