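"""Stochastic cellular-automaton tumour growth on a 2D/3D lattice.

A single transformed cell placed at the centre of the grid grows by
stochastic birth/death events scheduled with a next-reaction Gillespie
scheme (exponential clocks with rate k*x per channel, smallest clock wins).
A dividing cell replaces itself with one daughter and places the second in
an empty Moore neighbour; if none is free, cells sufficiently close to the
tumour front (controlled by the boundary parameter ``a``) may push a whole
run of cells one site along a random lattice direction to create space.
Each division generates Pois(u) brand-new mutations that both daughter
cells inherit (infinite sites, no back mutation).  At a fixed clock time
``t_driver`` one wild-type cell is
converted into a mutant whose fitness advantage ``s`` is realised through
an increased birth rate, a decreased death rate, or unconditional pushing.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .params import ParameterError, SimulationParams

WT = 0
MUT = 1

_ROOT = 0


def _moore_offsets(dims: int) -> list[tuple[int, ...]]:
    if dims == 2:
        return [(dx, dy) for dx in (-1, 0, 1) for dy in (-1, 0, 1) if (dx, dy) != (0, 0)]
    return [
        (dx, dy, dz)
        for dx in (-1, 0, 1)
        for dy in (-1, 0, 1)
        for dz in (-1, 0, 1)
        if (dx, dy, dz) != (0, 0, 0)
    ]


class LineageTree:
    """Genealogy of genotype nodes with contiguous blocks of mutation ids.

    Each node records its parent, its creation (division) time and the
    half-open block ``[mut_start, mut_start + mut_n)`` of globally unique
    mutation ids it introduced.  A cell's genotype is the union of the
    blocks on its node's path to the root.
    """

    __slots__ = ("parent", "time", "mut_start", "mut_n", "cum_mut", "next_mut_id")

    def __init__(self) -> None:
        self.parent: list[int] = []
        self.time: list[float] = []
        self.mut_start: list[int] = []
        self.mut_n: list[int] = []
        self.cum_mut: list[int] = []  # total mutations on the root path, inclusive
        self.next_mut_id = 0

    def __len__(self) -> int:
        return len(self.parent)

    def add_node(self, parent: int, t: float, n_new: int) -> int:
        node = len(self.parent)
        self.parent.append(parent)
        self.time.append(t)
        self.mut_start.append(self.next_mut_id)
        self.mut_n.append(n_new)
        self.next_mut_id += n_new
        base = self.cum_mut[parent] if parent >= 0 else 0
        self.cum_mut.append(base + n_new)
        return node

    def path_nodes(self, node: int) -> list[int]:
        """Nodes on the path from ``node`` up to (and including) the root."""
        path = []
        v = node
        while v >= 0:
            path.append(v)
            v = self.parent[v]
        return path

    def node_mutations(self, node: int) -> range:
        s = self.mut_start[node]
        return range(s, s + self.mut_n[node])

    def mutation_ids(self, node: int) -> np.ndarray:
        """All mutation ids carried by a cell whose genotype node is ``node``."""
        blocks = [
            np.arange(self.mut_start[v], self.mut_start[v] + self.mut_n[v])
            for v in self.path_nodes(node)
            if self.mut_n[v]
        ]
        if not blocks:
            return np.empty(0, dtype=np.int64)
        return np.concatenate(blocks[::-1])

    def subtree_cell_counts(self, cell_nodes: np.ndarray, weights=None) -> np.ndarray:
        """Per-node count of cells (from ``cell_nodes``) in each node's subtree.

        Nodes are created with parent < child, so a single reverse pass
        accumulates child counts into parents.
        """
        counts = np.zeros(len(self.parent), dtype=np.float64)
        if weights is None:
            np.add.at(counts, cell_nodes, 1.0)
        else:
            np.add.at(counts, cell_nodes, weights)
        parent = self.parent
        for v in range(len(parent) - 1, 0, -1):
            p = parent[v]
            if p >= 0:
                counts[p] += counts[v]
        return counts

    def mutation_node(self) -> np.ndarray:
        """Map mutation id -> node that introduced it."""
        out = np.empty(self.next_mut_id, dtype=np.int64)
        for v in range(len(self.parent)):
            n = self.mut_n[v]
            if n:
                s = self.mut_start[v]
                out[s : s + n] = v
        return out

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "node_id": np.arange(len(self.parent)),
                "parent_id": self.parent,
                "n_new_mutations": self.mut_n,
                "first_mutation_id": self.mut_start,
                "event_time": self.time,
            }
        )


@dataclass(slots=True)
class CellRecord:
    cell_id: int
    pos: tuple
    clone: int  # WT or MUT
    node: int  # genotype node in the lineage tree
    n_divisions: int  # generations this lineage has gone through
    r: int = 0  # cached Chebyshev distance from the grid centre


class TumourState:
    """The simulator's world: occupancy grid, live cells, lineage and clock."""

    def __init__(self, params: SimulationParams):
        self.params = params
        self.rng = np.random.default_rng(params.seed)
        L = params.grid_extent
        self._L = L
        self._grid = [0] * (L**params.dims)  # flat occupancy, 0 = empty
        self.cells: dict[int, CellRecord] = {}
        self.lineage = LineageTree()
        self.t = 0.0
        self.origin = (L // 2,) * params.dims
        self.offsets = _moore_offsets(params.dims)

        # per-clone uniform selection structures
        self._clone_ids: list[list[int]] = [[], []]
        self._clone_idx: dict[int, int] = {}

        # Chebyshev-radius bookkeeping (max over live cells, exact)
        self._radius_counts = np.zeros(L, dtype=np.int64)
        self.R = 0

        self._next_cell_id = 1
        self.driver_done = False
        self.driver_skipped = False
        self.driver_node: int | None = None
        self.driver_path_nodes: frozenset | None = None
        self.driver_time: float | None = None
        self.boundary_reached = False
        self.extinct = False
        self.n_failed_divisions = 0

        # mutant rates default to WT values until the driver fires
        self.b_mut = params.b
        self.d_mut = params.d
        self.mut_always_pushes = False

        self.event_log: list[tuple[float, int, int]] = []  # (t, n_wt, n_mut)

        self._arrays_cache = None

    # -- basic bookkeeping -------------------------------------------------

    @property
    def grid(self) -> np.ndarray:
        """Occupancy as a numpy array (cell_id per site, 0 = empty); a copy."""
        L = self._L
        return np.asarray(self._grid, dtype=np.int64).reshape((L,) * self.params.dims)

    def _gidx(self, pos) -> int:
        i = pos[0]
        for c in pos[1:]:
            i = i * self._L + c
        return i

    @property
    def n_cells(self) -> int:
        return len(self.cells)

    @property
    def n_wt(self) -> int:
        return len(self._clone_ids[WT])

    @property
    def n_mut(self) -> int:
        return len(self._clone_ids[MUT])

    def _cheb(self, pos) -> int:
        o = self.origin
        r = 0
        for p, q in zip(pos, o):
            d = p - q
            if d < 0:
                d = -d
            if d > r:
                r = d
        return r

    def _register(self, cell: CellRecord) -> None:
        self.cells[cell.cell_id] = cell
        lst = self._clone_ids[cell.clone]
        self._clone_idx[cell.cell_id] = len(lst)
        lst.append(cell.cell_id)
        self._grid[self._gidx(cell.pos)] = cell.cell_id
        r = self._cheb(cell.pos)
        cell.r = r
        self._radius_counts[r] += 1
        if r > self.R:
            self.R = r
        self._check_boundary(cell.pos)
        self._arrays_cache = None

    def _unregister(self, cell_id: int) -> None:
        cell = self.cells.pop(cell_id)
        lst = self._clone_ids[cell.clone]
        i = self._clone_idx.pop(cell_id)
        last = lst[-1]
        if last != cell_id:
            lst[i] = last
            self._clone_idx[last] = i
        lst.pop()
        self._grid[self._gidx(cell.pos)] = 0
        r = cell.r
        self._radius_counts[r] -= 1
        while self.R > 0 and self._radius_counts[self.R] == 0:
            self.R -= 1
        self._arrays_cache = None

    def _switch_clone(self, cell: CellRecord, new_clone: int) -> None:
        lst = self._clone_ids[cell.clone]
        i = self._clone_idx.pop(cell.cell_id)
        last = lst[-1]
        if last != cell.cell_id:
            lst[i] = last
            self._clone_idx[last] = i
        lst.pop()
        cell.clone = new_clone
        dst = self._clone_ids[new_clone]
        self._clone_idx[cell.cell_id] = len(dst)
        dst.append(cell.cell_id)
        self._arrays_cache = None

    def _move(self, cell: CellRecord, new_pos: tuple) -> None:
        self._grid[self._gidx(cell.pos)] = 0
        r_old = cell.r
        cell.pos = new_pos
        self._grid[self._gidx(new_pos)] = cell.cell_id
        r_new = self._cheb(new_pos)
        cell.r = r_new
        if r_new != r_old:
            self._radius_counts[r_old] -= 1
            self._radius_counts[r_new] += 1
            if r_new > self.R:
                self.R = r_new
            while self.R > 0 and self._radius_counts[self.R] == 0:
                self.R -= 1
        self._check_boundary(new_pos)

    def _check_boundary(self, pos) -> None:
        hi = self.params.grid_extent - 1
        for p in pos:
            if p == 0 or p == hi:
                self.boundary_reached = True
                return

    def _log_event(self) -> None:
        if self.params.record_event_log:
            self.event_log.append((self.t, self.n_wt, self.n_mut))

    def as_arrays(self):
        """(cell_ids, positions, clones, nodes, n_divisions) as numpy arrays."""
        if self._arrays_cache is None:
            n = len(self.cells)
            ids = np.empty(n, dtype=np.int64)
            pos = np.empty((n, self.params.dims), dtype=np.int64)
            clone = np.empty(n, dtype=np.int8)
            node = np.empty(n, dtype=np.int64)
            ndiv = np.empty(n, dtype=np.int64)
            for i, c in enumerate(self.cells.values()):
                ids[i] = c.cell_id
                pos[i] = c.pos
                clone[i] = c.clone
                node[i] = c.node
                ndiv[i] = c.n_divisions
            self._arrays_cache = (ids, pos, clone, node, ndiv)
        return self._arrays_cache

    def occupancy_frame(self) -> pd.DataFrame:
        ids, pos, clone, node, ndiv = self.as_arrays()
        cols = {"cell_id": ids}
        for ax, name in enumerate("xyz"[: self.params.dims]):
            cols[name] = pos[:, ax]
        cols["clone"] = np.where(clone == MUT, "MUT", "WT")
        cum = np.asarray(self.lineage.cum_mut, dtype=np.int64)
        cols["n_mutations"] = cum[node]
        cols["n_divisions"] = ndiv
        return pd.DataFrame(cols)


# -- operations -----------------------------------------------------------


def initialize(params: SimulationParams) -> TumourState:
    """Place the founder cell at the centre of the grid at t = 0."""
    state = TumourState(params)
    n_founder_muts = 0
    if params.founder_mutations and params.u > 0:
        n_founder_muts = int(state.rng.poisson(params.u))
    root = state.lineage.add_node(-1, 0.0, n_founder_muts)
    founder = CellRecord(
        cell_id=state._next_cell_id,
        pos=state.origin,
        clone=WT,
        node=root,
        n_divisions=0,
    )
    state._next_cell_id += 1
    state._register(founder)
    state._log_event()
    return state


def _push_eligible(state: TumourState, cell: CellRecord) -> bool:
    if cell.clone == MUT and state.mut_always_pushes:
        return True
    a = state.params.a
    if state.params.push_rule == "bernoulli":
        return bool(state.rng.random() < a)
    # deterministic rim rule: eligible iff within fraction a of the current
    # radius, measured inward from the growing front (Chebyshev metric)
    R = state.R
    return (R - cell.r) <= a * R


def place_daughter(state: TumourState, parent: CellRecord, rng=None):
    """Place the second daughter of a dividing cell; returns its position or None.

    The first daughter replaces the parent in place.  If an empty Moore
    neighbour exists the second daughter takes one uniformly at random;
    otherwise, if the parent is push-eligible, the contiguous run of cells
    from the parent along one uniformly chosen lattice direction shifts one
    site outward and the daughter takes the freed adjacent site.  A ray
    fully occupied up to the grid boundary aborts the attempt; an
    ineligible or unlucky parent fails the division (no state change).
    """
    rng = rng or state.rng
    grid = state._grid
    L = state.params.grid_extent
    if state.params.dims == 2:
        return _place_daughter_2d(state, parent, rng, grid, L)
    pos = parent.pos
    empties = []
    for off in state.offsets:
        q = tuple(p + o for p, o in zip(pos, off))
        ok = True
        for c in q:
            if c < 0 or c >= L:
                ok = False
                break
        if ok and grid[state._gidx(q)] == 0:
            empties.append(q)
    if empties:
        if len(empties) == 1:
            return empties[0]
        return empties[int(rng.integers(len(empties)))]

    if not _push_eligible(state, parent):
        return None

    direction = state.offsets[int(rng.integers(len(state.offsets)))]
    # walk along the ray until the first empty site or the grid edge
    run = []
    q = pos
    while True:
        q = tuple(p + o for p, o in zip(q, direction))
        inside = True
        for c in q:
            if c < 0 or c >= L:
                inside = False
                break
        if not inside:
            return None  # ray occupied all the way to the boundary: abort
        cid = grid[state._gidx(q)]
        if cid == 0:
            break
        run.append(cid)
    # shift the run one site outward, farthest cell first
    for cid in reversed(run):
        cell = state.cells[cid]
        new_pos = tuple(p + o for p, o in zip(cell.pos, direction))
        state._move(cell, new_pos)
    return tuple(p + o for p, o in zip(pos, direction))


def _place_daughter_2d(state: TumourState, parent: CellRecord, rng, grid, L):
    # hot path: identical semantics to the generic branch, specialised to 2D
    x, y = parent.pos
    empties = []
    for dx, dy in state.offsets:
        nx = x + dx
        ny = y + dy
        if 0 <= nx < L and 0 <= ny < L and grid[nx * L + ny] == 0:
            empties.append((nx, ny))
    if empties:
        if len(empties) == 1:
            return empties[0]
        return empties[int(rng.integers(len(empties)))]

    if not _push_eligible(state, parent):
        return None

    dx, dy = state.offsets[int(rng.integers(8))]
    # walk along the ray until the first empty site or the grid edge
    k = 0
    nx, ny = x, y
    while True:
        nx += dx
        ny += dy
        if not (0 <= nx < L and 0 <= ny < L):
            return None  # occupied all the way to the boundary: abort
        k += 1
        if grid[nx * L + ny] == 0:
            break
    # shift the k-1 run cells one site outward, farthest first; only the
    # freed endpoint can newly touch the grid boundary
    ox, oy = state.origin
    counts = state._radius_counts
    cells = state.cells
    for j in range(k - 1, 0, -1):
        fx = x + j * dx
        fy = y + j * dy
        cid = grid[fx * L + fy]
        tx = fx + dx
        ty = fy + dy
        grid[fx * L + fy] = 0
        grid[tx * L + ty] = cid
        cell = cells[cid]
        cell.pos = (tx, ty)
        ax = tx - ox
        ay = ty - oy
        if ax < 0:
            ax = -ax
        if ay < 0:
            ay = -ay
        r_new = ax if ax > ay else ay
        r_old = cell.r
        if r_new != r_old:
            cell.r = r_new
            counts[r_old] -= 1
            counts[r_new] += 1
            if r_new > state.R:
                state.R = r_new
            else:
                while state.R > 0 and counts[state.R] == 0:
                    state.R -= 1
    hi = L - 1
    if nx == 0 or nx == hi or ny == 0 or ny == hi:
        state.boundary_reached = True
    return (x + dx, y + dy)


def _divide(state: TumourState, parent: CellRecord) -> bool:
    site = place_daughter(state, parent)
    if site is None:
        state.n_failed_divisions += 1
        return False
    u = state.params.u
    rng = state.rng
    # one Pois(u) draw per division, assigned to both daughter cells: the
    # new mutations sit on a shared division node, below which each
    # daughter starts its own (initially mutation-free) genotype node
    k = int(rng.poisson(u)) if u > 0 else 0
    t = state.t
    division = state.lineage.add_node(parent.node, t, k)
    node1 = state.lineage.add_node(division, t, 0)
    node2 = state.lineage.add_node(division, t, 0)
    # first daughter replaces the parent in place
    parent.node = node1
    parent.n_divisions += 1
    daughter = CellRecord(
        cell_id=state._next_cell_id,
        pos=site,
        clone=parent.clone,
        node=node2,
        n_divisions=parent.n_divisions,
    )
    state._next_cell_id += 1
    state._register(daughter)
    return True


def introduce_driver(state: TumourState) -> None:
    """Convert one uniformly chosen WT cell into the selected mutant."""
    p = state.params
    if state.n_wt == 0:
        state.driver_skipped = True
        state.driver_done = True
        warnings.warn(
            "no WT cells alive at t_driver; driver skipped (neutral-only run)",
            stacklevel=2,
        )
        return
    ids = state._clone_ids[WT]
    cell = state.cells[ids[int(state.rng.integers(len(ids)))]]
    state._switch_clone(cell, MUT)
    b, d, s = p.b, p.d, p.s
    if p.driver_mode == "birth_increase":
        state.b_mut = d + (1.0 + s) * (b - d)
        state.d_mut = d
    elif p.driver_mode == "death_decrease":
        state.b_mut = b
        state.d_mut = b - (1.0 + s) * (b - d)
    else:  # push_increase: rates unchanged, mutant cells always push
        state.mut_always_pushes = True
    state.driver_done = True
    state.driver_node = cell.node
    state.driver_path_nodes = frozenset(state.lineage.path_nodes(cell.node))
    state.driver_time = state.t


def gillespie_step(state: TumourState, rng=None) -> str:
    """One next-reaction event: draw exponential clocks for the four
    channels (WT/MUT x birth/death, rate k*x), fire the smallest, then
    check the driver trigger.  Returns the event label."""
    rng = rng or state.rng
    p = state.params
    channels = []  # (rate, clone, is_birth)
    n_wt, n_mut = state.n_wt, state.n_mut
    if n_wt:
        channels.append((p.b * n_wt, WT, True))
        if p.d > 0:
            channels.append((p.d * n_wt, WT, False))
    if n_mut:
        channels.append((state.b_mut * n_mut, MUT, True))
        if state.d_mut > 0:
            channels.append((state.d_mut * n_mut, MUT, False))
    if not channels:
        state.extinct = True
        return "extinct"
    best_dt = math.inf
    best = None
    for rate, clone, is_birth in channels:
        dt = rng.exponential(1.0 / rate)
        if dt < best_dt:
            best_dt = dt
            best = (clone, is_birth)
    state.t += best_dt
    clone, is_birth = best
    ids = state._clone_ids[clone]
    cell = state.cells[ids[int(rng.integers(len(ids)))]]
    if is_birth:
        ok = _divide(state, cell)
        label = ("birth" if ok else "failed_birth") + ("_mut" if clone else "_wt")
    else:
        state._unregister(cell.cell_id)
        label = "death" + ("_mut" if clone else "_wt")
        if state.n_cells == 0:
            state.extinct = True
    if (
        not state.driver_done
        and math.isfinite(p.t_driver)
        and state.t >= p.t_driver
        and not state.extinct
    ):
        introduce_driver(state)
    state._log_event()
    return label


def _stop(state: TumourState, max_cells, max_events, n_events) -> bool:
    if state.boundary_reached or state.extinct:
        return True
    if max_cells is not None and state.n_cells >= max_cells:
        return True
    if max_events is not None and n_events >= max_events:
        return True
    return False


def resume(state: TumourState, max_cells: int | None = None) -> TumourState:
    """Continue the Gillespie loop until a stop condition holds."""
    max_cells = max_cells if max_cells is not None else state.params.max_cells
    max_events = state.params.max_events
    n = 0
    while not _stop(state, max_cells, max_events, n):
        gillespie_step(state)
        n += 1
    return state


def run(params: SimulationParams) -> TumourState:
    """Simulate from a single founder until a cell reaches the grid boundary
    (or the optional cell cap / extinction).  Deterministic given the seed."""
    state = initialize(params)
    return resume(state)


def apply_treatment(state: TumourState, kill_fraction: float, rng=None) -> TumourState:
    """Remove a uniform fraction of live cells (always keeping one survivor)."""
    if not 0.0 <= kill_fraction < 1.0:
        raise ParameterError(f"kill_fraction must be in [0, 1), got {kill_fraction}")
    rng = rng or state.rng
    if kill_fraction == 0.0 or state.n_cells <= 1:
        return state
    n_kill = min(int(round(kill_fraction * state.n_cells)), state.n_cells - 1)
    all_ids = list(state.cells.keys())
    victims = rng.choice(len(all_ids), size=n_kill, replace=False)
    for i in victims:
        state._unregister(all_ids[int(i)])
    state._log_event()
    return state


def growth_curves(state: TumourState) -> pd.DataFrame:
    """Per-clone population size time series from the event log.

    Time is in Gillespie units; divide ``t`` by log(2) for doubling times.
    """
    if not state.event_log:
        raise ValueError("event log is empty; run with record_event_log=True")
    arr = np.asarray(state.event_log, dtype=np.float64)
    df = pd.DataFrame(arr, columns=["t", "n_wt", "n_mut"])
    df["n_total"] = df["n_wt"] + df["n_mut"]
    return df[["t", "n_total", "n_wt", "n_mut"]]


def run_with_restarts(params: SimulationParams, max_restarts: int = 20) -> TumourState:
    """Run, restarting (with derived seeds) on extinction.

    ABC needs completed tumours; with d close to b a large fraction of
    founder lineages die out, so the simulation restarts with a fresh seed
    derived deterministically from the original.
    """
    state = run(params)
    attempt = 0
    base = params.seed if params.seed is not None else 0
    while state.extinct and attempt < max_restarts:
        attempt += 1
        reseeded = SimulationParams.from_dict(
            {**params.to_dict(), "seed": (base + 7919 * attempt) % (2**31 - 1)}
        )
        state = run(reseeded)
    return state
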