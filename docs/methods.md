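# Model and methods

## The world

A park is a raster of 2 m × 2 m cells, each with one surface class:
inaccessible (planted lawn, shrubs, buildings), water, main path, trail,
open space, open lawn, target interior, or gate. The accessible area is
4 m² per walkable cell. Movement is 4-connected: orthogonal neighbours are
2 m apart — exactly the distancing threshold — while diagonal neighbours
(2.83 m) are compliant. A one-cell-wide trail is therefore single file by
construction, which reproduces the observation that paths narrower than 2 m
can only be walked safely in one direction. Target zones carry typed
metadata (popular scenery, trail, open space, entertainment facility),
interior and entrance cell sets, and optionally an AI warning board with a
safe occupancy count. One-way restrictions are per-cell masks allowing a
single outgoing direction.

Distancing violation is operationalized as orthogonal adjacency: two
visitors on cells whose centres are 2 m apart are sub-threshold once finite
body width is accounted for. Diagonal proximity is compliant.

## Visitors

Each visitor draws a type from the park's surveyed composition (exercisers
→ trails, tourists → popular scenery, leisure → open space, with-children →
entertainment facilities, others → uniform), a total stay budget from the
surveyed duration bins (mapped to uniform minute ranges: <1 h → U[30,60],
2 h → U[60,150], 4 h → U[150,270], >4 h → U[270,360]), and builds a travel
plan: entry and exit gates by gate weight, a main target in the preferred
category, a 20–30 min main dwell (capped so travel + dwells fit the
budget), and secondary targets with 10–30 min dwells sampled from zones
whose entrance lies within 3 cells (6 m) of the planned route. A main
target whose round trip does not fit the budget is replaced by the nearest
same-category target; failing that the visitor passes through without
dwelling, which keeps short-stay visitors out of the deep park.

Routing is A* over the movement graph with per-cell entry cost
1/preference; main-path cells have preference 1.25 (cost 0.8), everything
else 1.0, and the Manhattan heuristic is scaled by the minimum cost to stay
admissible. Ties break deterministically by (row, col). One-way masks and
optional avoid-sets (congested cells, a blocked next cell) are honoured.

## Ticks and concurrency

One tick is 2 s and speed is one cell per tick, i.e. 1 m/s — a standard
leisurely walking pace that makes 10 minutes exactly 300 ticks. Each tick
every visitor computes a movement intent against the start-of-tick
occupancy, and all intents are committed together (two claims on one cell:
a random winner). This concurrency is essential: two visitors approaching
head-on both see the gap cell free and land adjacent — the "collision" that
seeds all congestion. A sequential update would let everyone stop 4 m apart
and no contact would ever occur, making capacity infinite.

Passive visitors (the default) refuse any move that would create a new
adjacency and wait; aggressive visitors keep moving — they advance into any
free cell regardless of adjacency and, when already in violation with the
way ahead occupied, side-step to the free neighbour with the fewest
occupied neighbours. Aggressive queues therefore pack shoulder to shoulder
and accumulate contact time while passing, which is why the aggressive
strategy lowers capacity.

Three pragmatic rules prevent gridlock artefacts, all config-exposed in
`BehaviorParams`:

- **Impatience** (`max_wait`, default 150 ticks = 5 min): a passive visitor
  blocked that long accepts a move into adjacency if the cell itself is
  free ("keep 2 m when possible"). Without it, three visitors in a room can
  block each other for ever with no violation at all.
- **Forced replan** (at `max_wait`, retried every `retry_interval` = 30
  ticks): re-route to the current goal avoiding the blocking cell and any
  persistent congestion; failing that, try another open unvisited target;
  failing that, head for the exit. After `give_up_factor` × `max_wait` of
  continuous blocking the visitor abandons its plan and exits.
- **Sidestep** (same trigger): when the way ahead is occupied, step to any
  free neighbour that does not worsen adjacency, which lets opposing
  platoons unwind instead of deadlocking.

Dwelling visitors occupy their cell for the planned dwell. Dwell spots are
chosen compliant-first (free cells with no occupied neighbour, then any
free cell), and a visitor arriving at a spot that has since become
non-compliant re-picks or moves on — both are applications of rule 1, not
extra policy. The crowding rule (rule 5) checks local density within the
visible radius (default 20 m, configurable; the surveyed crowding tolerance
of 1 person/m² is retained verbatim even though it is unreachable under
2 m spacing, so the rule only binds when the threshold is lowered).

## A simulated day

Exactly `daily_total` arrivals are drawn: each gets an hour with
probability proportional to the surveyed hourly gate counts inside the open
window (default 7:00–17:00, the 10 h service day) and a uniform tick within
the hour — uniform rather than Poisson so the realized total equals the
candidate N under test. Arrivals enter on a free gate cell or queue
outside; the simulation continues up to 2 h after closing so the park
drains. Visitors still inside after the drain are reported as trapped —
under heavy congestion of single-file trails this can be non-zero, which is
the "trapped inside trails" phenomenon, not an accounting leak: entered =
exited + trapped always holds.

Per tick the engine records the violating pairs (contact log: per-pair
episodes of continuous adjacency), updates each visitor's continuous
violation clock, longest episode and cumulative total, and classifies the
congestion stage: 1 — only transient collisions; 2 — a cluster of ≥ 3
mutually adjacent blocked visitors persisting ≥ 30 ticks wholly off the
main path (recoverable); 3 — such a cluster touching the main path or a
gate (unrecoverable); 4 — a gate queue longer than 10 visitors persisting
≥ 30 ticks (blocked entrance). The cluster size, persistence and queue
thresholds are decisions exposed in `EngineConfig`; the source material
names the stages but not the cut-offs.

## Capacity estimation

A day exceeds the threshold when ≥ `n_visitors` (default 3) distinct
visitors reach the critical period (continuous episode by default; a
cumulative mode is selectable). A candidate N is classified over 10
replicate seeds, "over" on a majority of 5 — the only reading of
"five of ten identical results" that classifies every N. Capacity is the
largest "under", found by doubling from N = 10 and bisecting the first
over/under bracket; the tests verify on a micro park that this equals an
exhaustive scan with identical seeds. Days may stop early once the
threshold is provably exceeded; this changes no classification. The sweep
re-estimates capacity for periods 1–64 min with shared replicate seeds and
reports two linear slopes (periods ≤ 16 min and ≥ 16 min), the two-segment
summary of capacity growth.

## Scenarios

All scenario operators are pure transformations of an `EngineConfig`:
closures drop the arrival share of visitor types whose preferred category
is fully closed (dropped, not reassigned); opening-hour control restricts
to a 4 h window and renormalises the composition over the admitted types
(morning and evening: exercisers + leisure; midday: everyone — the exact
morning mix is not pinned by the source and is overridable); avoidance mode
switches every visitor's conflict response; AI boards divert a visitor
about to enter a full target (default safe count: half the interior cells,
rounded up); layout edits widen an opening to at most 10 m or carve a
one-way trail. `run_scenario` estimates base and scenario with shared
replicate seeds and reports the capacity ratio truncated to two decimals.

## Rounding conventions

Pinned per metric to match the published convention: truncation for the
distancing circle (π·2² → 12.56), area per person, adjustment ratios and
the coarse floor(area/12.56) estimate; half-up rounding for percentages
(one decimal) and densities (four decimals). These are the unique choices
consistent with the published values 12.56, 85, 3972, 2.15, 8.9 and 1.6
simultaneously.

## Synthetic benchmarks: what they do and do not show

The three mini parks (ring ~60×60, multi-ring ~100×100, tree ~40×100)
reproduce the road-structure archetypes with walled destinations, narrow
trailheads and dead-end trails, and carry the surveyed demand shapes with
hourly totals scaled down ×10. The micro corridor (single-file path to one
walled room) and the trap park (three-lane path with a large walled garden
behind a 2 m doorway) are small enough for exhaustive capacity scans and
paired scenario comparisons within seconds. Test and benchmark runs use
1–2 h open windows and sub-hour stays on the micro parks; the mini-ring
load ladder runs full 10 h days.

Passing tests on these fixtures demonstrate the mechanisms — monotone
congestion-stage growth with load, capacity growth with the critical
period, the aggressive-mode penalty, the non-negative effect of boards and
widened openings — not the absolute capacities of any real park: those
depend on the real geometries, which are not included. On the trap park the
widened opening raises capacity modestly (ratio 1.0–1.13 across seed sets)
while congestion partly re-forms inside the target, and the AI board at its
default safe count is neutral there (the interior never reaches half-full
before the doorway binds); the board's diversion mechanism itself is
exercised directly in the unit tests.

## Known limitations

- Single-agent granularity: no groups or households, uniform 1 m/s speed.
- No infection model: the package tracks contact time, not transmission.
- The anti-gridlock rules (impatience, sidestep, give-up) are pragmatic
  devices; real crowd negotiation is richer, and capacity estimates on
  single-file geometries are sensitive to `max_wait`.
- Bridges are walkable path cells; elevation and multi-level structures are
  out of scope.
- The correlation report reproduces the analysis form (capacity vs.
  per-person area and connection width) but published coefficients are not
  reproducible without the real layouts.
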