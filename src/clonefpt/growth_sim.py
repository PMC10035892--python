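"""Agent-based lattice simulator of sub-clonal tumour growth.

A single wild-type cell seeds an expanding colony on a square (2-D) or cubic
(3-D) lattice.  Cells fire in proportion to their birth rate; mutants divide
(1+s) times faster than wild-type cells.  On each firing the cell dies with
probability psi (death coupled to birth, d_i = b_i * psi), otherwise it
attempts to divide by finding a chain of at most q occupied neighbours that
can be pushed one step towards the nearest empty lattice point — q = 0 is
pure boundary-driven (surface) growth.  When the colony first reaches
round(N_max * n_mut) cells, one uniformly chosen wild-type cell acquires the
mutation; descendants inherit it and never revert.  The run ends when the
colony reaches N_max cells.

Pushing prefers straight-line chains among the shortest ones (momentum is
transferred most easily along the push direction); ties are broken uniformly
at random.  The neighbourhood is von Neumann (4 neighbours in 2-D, 6 in 3-D)
for both division adjacency and pushing.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import NamedTuple, Optional

import numba as nb
import numpy as np

from ._rand import rand_below, rand_f64, seed_state
from .patterns import EMPTY, RED, YELLOW, ClassGrid

__all__ = [
    "SimParams",
    "SimRecord",
    "TumourState",
    "PushPath",
    "simulate_tumour",
    "attempt_division",
    "choose_push_path",
    "slice_3d",
    "DEFAULT_S_GRID",
    "DEFAULT_NMUT_GRID",
    "DEFAULT_Q_GRID",
]

# parameter grid the simulated-pattern library spans
DEFAULT_S_GRID = (0.0, 0.1, 0.2, 0.5, 1.0, 2.0, 3.0)
DEFAULT_NMUT_GRID = (0.001, 0.01, 0.03, 0.05, 0.08, 0.1, 0.5)
DEFAULT_Q_GRID = (0, 5, 10, 20)

_STATUS_OK = 0
_STATUS_EXTINCT = 1
_STATUS_MUT_EXTINCT = 2
_STATUS_BOUNDARY = 3
_STATUS_MAX_EVENTS = 4


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


@dataclass
class SimParams:
    """Simulator inputs.

    s       : mutant fitness advantage (>= 0); b_mut = (1+s) * b_wt.
    n_mut   : fraction of N_max at which the mutation is introduced, in (0,1).
    q       : maximum push-chain length in cells (0 = surface growth).
    psi     : death-coupling probability per firing, default 0.3.
    n_max   : final total population.
    b_wt    : wild-type birth rate (arbitrary time units; only the ratio
              (1+s) matters because time is not tracked).
    dims    : 2 or 3.
    seed    : RNG seed; restart r uses seed + r.
    """

    s: float
    n_mut: float
    q: int
    n_max: int
    psi: float = 0.3
    b_wt: float = 1.0
    dims: int = 2
    seed: int = 0
    max_restarts: int = 200

    def __post_init__(self) -> None:
        if self.s < 0:
            raise ValueError("s must be >= 0")
        if not 0.0 < self.n_mut < 1.0:
            raise ValueError("n_mut must be in (0, 1)")
        if self.q < 0:
            raise ValueError("q must be >= 0")
        if not 0.0 <= self.psi <= 1.0:
            raise ValueError("psi must be in [0, 1]")
        if self.n_max < 1:
            raise ValueError("n_max must be positive")
        if self.b_wt <= 0:
            raise ValueError("b_wt must be positive")
        if self.dims not in (2, 3):
            raise ValueError("dims must be 2 or 3")
        if self.n_intro < 1:
            raise ValueError("n_mut * n_max must be >= 1")
        if self.max_restarts < 1:
            raise ValueError("max_restarts must be positive")

    @property
    def n_intro(self) -> int:
        """Population size at which the mutation is introduced."""
        return _round_half_up(self.n_max * self.n_mut)

    @property
    def b_mut(self) -> float:
        """Mutant birth rate, (1 + s) * b_wt."""
        return (1.0 + self.s) * self.b_wt

    @property
    def lattice_side(self) -> int:
        """Side length holding the colony without boundary contact."""
        return int(math.ceil(2.5 * self.n_max ** (1.0 / self.dims)))


@dataclass
class SimRecord:
    """Event bookkeeping for one successful run (plus restart count)."""

    pop_at_mutation: int
    n_firings: int
    n_deaths: int
    n_failed_divisions: int
    n_restarts: int
    final_n_wt: int
    final_n_mut: int
    final_phi: float
    n_wt_firings: int
    n_mut_firings: int
    expected_mut_firings: float  # sum over firings of P(firing cell is mutant)
    lattice_side: int


class SimulationError(RuntimeError):
    pass


# ---------------------------------------------------------------------------
# numba kernels
# ---------------------------------------------------------------------------


@nb.njit(inline="always", cache=True)
def _neighbors(p, side, dims, out):
    x = p % side
    rest = p // side
    y = rest % side
    cnt = 0
    if x > 0:
        out[cnt] = p - 1
        cnt += 1
    if x < side - 1:
        out[cnt] = p + 1
        cnt += 1
    if y > 0:
        out[cnt] = p - side
        cnt += 1
    if y < side - 1:
        out[cnt] = p + side
        cnt += 1
    if dims == 3:
        z = rest // side
        if z > 0:
            out[cnt] = p - side * side
            cnt += 1
        if z < side - 1:
            out[cnt] = p + side * side
            cnt += 1
    return cnt


@nb.njit(inline="always", cache=True)
def _on_boundary(p, side, dims):
    x = p % side
    rest = p // side
    y = rest % side
    if x == 0 or x == side - 1 or y == 0 or y == side - 1:
        return True
    if dims == 3:
        z = rest // side
        if z == 0 or z == side - 1:
            return True
    return False


@nb.njit(cache=True)
def _find_path(lattice, start, q, side, dims, state, parent, depth, stamp,
               stamp_val, queue, terms, path_out):
    """Shortest push chain from ``start`` to the nearest empty site.

    Breadth-first search through occupied sites; empty sites found at the
    first reachable depth d (d <= q+1) are candidate termini, i.e. chains of
    d-1 pushed cells.  Straight-line chains of the same length take priority.
    Fills path_out[0..k] with the chain (divider-adjacent first) and the
    empty terminus at index k; returns k (pushed cells) or -1 if no chain of
    length <= q exists.
    """
    ndirs = 2 * dims
    straight_depth = np.full(6, -1, np.int64)
    for d in range(ndirs):
        axis = d // 2
        sign = 1 if d % 2 == 1 else -1
        if axis == 0:
            offset = sign
            c = start % side
        elif axis == 1:
            offset = sign * side
            c = (start // side) % side
        else:
            offset = sign * side * side
            c = start // (side * side)
        p = start
        for t in range(1, q + 2):
            c += sign
            if c < 0 or c >= side:
                break
            p += offset
            if lattice[p] < 0:
                straight_depth[d] = t
                break

    head = 0
    tail = 0
    queue[tail] = start
    tail += 1
    stamp[start] = stamp_val
    depth[start] = 0
    parent[start] = -1
    nterm = 0
    found = -1
    nbrs = np.empty(6, np.int64)
    while head < tail and found < 0:
        level_end = tail
        while head < level_end:
            u = queue[head]
            head += 1
            du = depth[u]
            if du > q:
                continue
            cnt = _neighbors(u, side, dims, nbrs)
            for i in range(cnt - 1, 0, -1):
                j = rand_below(state, i + 1)
                tmp = nbrs[i]
                nbrs[i] = nbrs[j]
                nbrs[j] = tmp
            for i in range(cnt):
                v = nbrs[i]
                if stamp[v] == stamp_val:
                    continue
                stamp[v] = stamp_val
                parent[v] = u
                depth[v] = du + 1
                if lattice[v] < 0:
                    terms[nterm] = v
                    nterm += 1
                    found = du + 1
                else:
                    queue[tail] = v
                    tail += 1
        if nterm > 0:
            break
    if nterm == 0:
        return -1
    k = found - 1
    nstraight = 0
    for d in range(ndirs):
        if straight_depth[d] == found:
            nstraight += 1
    if nstraight > 0:
        pick = rand_below(state, nstraight)
        for d in range(ndirs):
            if straight_depth[d] == found:
                if pick == 0:
                    axis = d // 2
                    sign = 1 if d % 2 == 1 else -1
                    if axis == 0:
                        offset = sign
                    elif axis == 1:
                        offset = sign * side
                    else:
                        offset = sign * side * side
                    for t in range(1, found + 1):
                        path_out[t - 1] = start + t * offset
                    return k
                pick -= 1
    t = terms[rand_below(state, nterm)]
    path_out[k] = t
    u = parent[t]
    for i in range(k - 1, -1, -1):
        path_out[i] = u
        u = parent[u]
    return k


@nb.njit(cache=True)
def _simulate(side, dims, n_max, n_intro, s, psi, q, state, max_events):
    nsites = side ** dims
    lattice = np.full(nsites, -1, np.int64)
    cpos = np.empty(n_max, np.int64)
    cgen = np.zeros(n_max, np.int8)
    parent = np.empty(nsites, np.int64)
    depth = np.empty(nsites, np.int64)
    stamp = np.zeros(nsites, np.int64)
    queue = np.empty(nsites, np.int64)
    terms = np.empty(nsites, np.int64)
    path_out = np.empty(q + 2, np.int64)
    stamp_val = 0

    if dims == 2:
        centre = (side // 2) * side + side // 2
    else:
        centre = ((side // 2) * side + side // 2) * side + side // 2
    lattice[centre] = 0
    cpos[0] = centre
    n_cells = 1
    n_mut = 0
    mutated = False
    pop_at_mut = 0
    firings = 0
    deaths = 0
    fails = 0
    sum_p_mut = 0.0
    mut_firings = 0
    wt_firings = 0
    bmax = 1.0 + s
    status = _STATUS_OK
    events = 0

    while n_cells < n_max:
        if (not mutated) and n_cells >= n_intro:
            i = rand_below(state, n_cells)  # all cells WT before introduction
            cgen[i] = 1
            n_mut = 1
            mutated = True
            pop_at_mut = n_cells
        events += 1
        if events > max_events:
            status = _STATUS_MAX_EVENTS
            break
        # select the firing cell with probability proportional to birth rate
        while True:
            i = rand_below(state, n_cells)
            if cgen[i] == 1 or rand_f64(state) * bmax < 1.0:
                break
        firings += 1
        denom = (n_cells - n_mut) + n_mut * bmax
        sum_p_mut += n_mut * bmax / denom
        if cgen[i] == 1:
            mut_firings += 1
        else:
            wt_firings += 1
        if rand_f64(state) < psi:
            deaths += 1
            lattice[cpos[i]] = -1
            if cgen[i] == 1:
                n_mut -= 1
            last = n_cells - 1
            if i != last:
                cpos[i] = cpos[last]
                cgen[i] = cgen[last]
                lattice[cpos[i]] = i
            n_cells = last
            if n_cells == 0:
                status = _STATUS_EXTINCT
                break
            if mutated and n_mut == 0:
                status = _STATUS_MUT_EXTINCT
                break
        else:
            stamp_val += 1
            k = _find_path(lattice, cpos[i], q, side, dims, state, parent,
                           depth, stamp, stamp_val, queue, terms, path_out)
            if k < 0:
                fails += 1
            else:
                if _on_boundary(path_out[k], side, dims):
                    status = _STATUS_BOUNDARY
                    break
                for j in range(k - 1, -1, -1):
                    ci = lattice[path_out[j]]
                    lattice[path_out[j + 1]] = ci
                    cpos[ci] = path_out[j + 1]
                d_site = path_out[0]
                cpos[n_cells] = d_site
                cgen[n_cells] = cgen[i]
                lattice[d_site] = n_cells
                if cgen[i] == 1:
                    n_mut += 1
                n_cells += 1
    return (status, cpos[:n_cells].copy(), cgen[:n_cells].copy(), n_mut,
            pop_at_mut, firings, deaths, fails, sum_p_mut, mut_firings,
            wt_firings)


# ---------------------------------------------------------------------------
# python surface
# ---------------------------------------------------------------------------


def _grid_from_cells(cpos: np.ndarray, cgen: np.ndarray, side: int,
                     dims: int, crop: bool = True) -> ClassGrid:
    if dims == 2:
        coords = np.stack([cpos // side, cpos % side], axis=1)
        shape = (side, side)
    else:
        coords = np.stack(
            [cpos // (side * side), (cpos // side) % side, cpos % side], axis=1
        )
        shape = (side, side, side)
    labels = np.zeros(shape, dtype=np.int8)
    labels[tuple(coords.T)] = np.where(cgen == 1, RED, YELLOW)
    if crop and len(cpos) > 0:
        lo = coords.min(axis=0)
        hi = coords.max(axis=0) + 1
        sl = tuple(slice(a, b) for a, b in zip(lo, hi))
        labels = labels[sl]
    return ClassGrid(labels)


def simulate_tumour(params: SimParams, crop: bool = True,
                    max_events: Optional[int] = None):
    """Run the growth model; returns ``(ClassGrid, SimRecord)``.

    On whole-population or mutant-lineage extinction the run restarts with
    seed + restart index, up to ``params.max_restarts`` attempts in total.
    The returned grid is cropped to the colony's bounding box (wild-type ->
    YELLOW, mutant -> RED, unoccupied -> EMPTY).
    """
    if max_events is None:
        max_events = 10_000 * params.n_max + 10_000_000
    side = params.lattice_side
    for attempt in range(params.max_restarts):
        state = seed_state(params.seed + attempt)
        (status, cpos, cgen, n_mut, pop_at_mut, firings, deaths, fails,
         sum_p_mut, mut_f, wt_f) = _simulate(
            side, params.dims, params.n_max, params.n_intro, params.s,
            params.psi, params.q, state, max_events)
        if status == _STATUS_OK:
            n_cells = len(cpos)
            record = SimRecord(
                pop_at_mutation=pop_at_mut,
                n_firings=firings,
                n_deaths=deaths,
                n_failed_divisions=fails,
                n_restarts=attempt,
                final_n_wt=n_cells - n_mut,
                final_n_mut=n_mut,
                final_phi=n_mut / n_cells,
                n_wt_firings=wt_f,
                n_mut_firings=mut_f,
                expected_mut_firings=sum_p_mut,
                lattice_side=side,
            )
            grid = _grid_from_cells(cpos, cgen, side, params.dims, crop=crop)
            return grid, record
        if status == _STATUS_BOUNDARY:
            raise SimulationError(
                f"colony reached the lattice boundary (side={side}); "
                "increase the lattice size")
        if status == _STATUS_MAX_EVENTS:
            raise SimulationError(
                f"event budget {max_events} exhausted at {params}")
    raise SimulationError(
        f"max_restarts={params.max_restarts} exhausted for parameter "
        f"combination s={params.s}, n_mut={params.n_mut}, q={params.q} "
        "(repeated population or mutant-lineage extinction)")


# ---------------------------------------------------------------------------
# single-event surface for tests and direct experimentation
# ---------------------------------------------------------------------------


class PushPath(NamedTuple):
    """A push chain: occupied sites from the divider outward, then the
    empty terminus the chain shifts into."""

    chain: list
    empty_site: tuple


@dataclass
class TumourState:
    """Mutable lattice occupancy for stepping single events by hand."""

    side: int
    dims: int
    lattice: np.ndarray  # flat, -1 empty else cell index
    cpos: np.ndarray
    cgen: np.ndarray
    n_cells: int
    rng: np.ndarray = field(default_factory=lambda: seed_state(0))

    @classmethod
    def from_grid(cls, grid: ClassGrid, seed: int = 0) -> "TumourState":
        labels = grid.labels
        if len(set(labels.shape)) != 1:
            raise ValueError("TumourState requires a square/cubic grid")
        side = labels.shape[0]
        dims = labels.ndim
        flat = labels.ravel()
        occupied = np.flatnonzero(flat != EMPTY)
        lattice = np.full(flat.size, -1, np.int64)
        lattice[occupied] = np.arange(len(occupied))
        cpos = occupied.astype(np.int64)
        cgen = (flat[occupied] == RED).astype(np.int8)
        return cls(side=side, dims=dims, lattice=lattice, cpos=cpos,
                   cgen=cgen, n_cells=len(occupied), rng=seed_state(seed))

    def to_grid(self) -> ClassGrid:
        return _grid_from_cells(self.cpos[: self.n_cells],
                                self.cgen[: self.n_cells],
                                self.side, self.dims, crop=False)

    def _flat(self, site) -> int:
        idx = 0
        for c in site:
            idx = idx * self.side + c
        return idx

    def _coords(self, p: int) -> tuple:
        out = []
        for _ in range(self.dims):
            out.append(p % self.side)
            p //= self.side
        return tuple(reversed(out))


def choose_push_path(state: TumourState, cell, q: int) -> Optional[PushPath]:
    """Pick a push chain for a division at ``cell`` (coordinate tuple).

    Returns the chain of at most q occupied sites to displace (empty when the
    divider already has an empty neighbour) plus the empty terminus, or None
    when no empty site is reachable within chain length q.
    """
    p = state._flat(cell)
    if state.lattice[p] < 0:
        raise ValueError(f"site {cell} is empty")
    nsites = state.side ** state.dims
    parent = np.empty(nsites, np.int64)
    depth = np.empty(nsites, np.int64)
    stamp = np.zeros(nsites, np.int64)
    queue = np.empty(nsites, np.int64)
    terms = np.empty(nsites, np.int64)
    path_out = np.empty(q + 2, np.int64)
    k = _find_path(state.lattice, p, q, state.side, state.dims, state.rng,
                   parent, depth, stamp, 1, queue, terms, path_out)
    if k < 0:
        return None
    chain = [state._coords(int(path_out[i])) for i in range(k)]
    return PushPath(chain=chain, empty_site=state._coords(int(path_out[k])))


def attempt_division(state: TumourState, cell, q: int) -> bool:
    """Attempt one division at ``cell``; mutates ``state`` in place.

    Pushes the chosen chain one step outward and places a same-genotype
    daughter in the freed adjacent site.  Returns False (state unchanged)
    when no chain of length <= q exists.
    """
    path = choose_push_path(state, cell, q)
    if path is None:
        return False
    p = state._flat(cell)
    sites = [state._flat(c) for c in path.chain] + [state._flat(path.empty_site)]
    for j in range(len(sites) - 2, -1, -1):
        ci = state.lattice[sites[j]]
        state.lattice[sites[j + 1]] = ci
        state.cpos[ci] = sites[j + 1]
    d_site = sites[0]
    genotype = state.cgen[state.lattice[p]]
    state.cpos = np.append(state.cpos, d_site)
    state.cgen = np.append(state.cgen, genotype)
    state.lattice[d_site] = state.n_cells
    state.n_cells += 1
    return True


def slice_3d(grid: ClassGrid, axis: str, index: int) -> ClassGrid:
    """Extract the 2-D cross-section of a 3-D grid at the given plane."""
    if grid.labels.ndim != 3:
        raise ValueError("slice_3d requires a 3-D grid")
    ax = {"z": 0, "y": 1, "x": 2}.get(axis)
    if ax is None:
        raise ValueError("axis must be one of 'x', 'y', 'z'")
    if not 0 <= index < grid.labels.shape[ax]:
        raise IndexError(f"index {index} out of range for axis {axis}")
    return ClassGrid(np.take(grid.labels, index, axis=ax))
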