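"""Class mean first passage times (CMFPT) on binned two-class patterns.

A random walker moves over the coloured bins of a :class:`BinnedPattern`
(uniformly over von-Neumann neighbours).  Bins carry fractional class
composition, so the class of a bin is re-sampled on every arrival: red with
probability f_red / (f_red + f_yellow), else yellow.  The first passage time
from class alpha to class beta is the number of steps until an arrival
samples class beta (the start bin is excluded, so tau >= 1).  Per-start
means are aggregated over start bins weighted by the start's class-alpha
fraction.

Raw times are normalised by the same quantity under a null model that keeps
the graph geometry and permutes the per-bin class compositions uniformly at
random (class abundances maintained exactly, spatial structure destroyed).  The
normalised tau_tilde are dimensionless; an iid-random pattern sits at
(tau_ry_tilde, tau_ry_tilde / tau_yr_tilde) = (1, 1), and segregated
patterns move far to the right of it.

``exact_cmfpt`` solves the absorbing-chain hitting-time system exactly and
serves as the independent oracle for the Monte-Carlo estimator.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import NamedTuple, Optional

import numba as nb
import numpy as np
import scipy.sparse as sp
from scipy.sparse.csgraph import connected_components
from scipy.sparse.linalg import spsolve

from ._rand import rand_below, rand_f64
from .patterns import BinnedPattern

__all__ = [
    "WalkConfig",
    "WalkGraph",
    "TauEstimate",
    "CMFPTResult",
    "walk_graph",
    "estimate_cmfpt",
    "exact_cmfpt",
    "null_cmfpt",
    "normalized_cmfpt",
]

RED_IDX, YELLOW_IDX = 0, 1  # row/col order of the 2x2 tau matrices


@dataclass
class WalkConfig:
    """Monte-Carlo settings for CMFPT estimation.

    walks_per_start  : walks launched from every coloured bin (default 5000).
    max_steps        : absolute cap per walk; overrides max_steps_factor.
                       Capped walks are discarded and counted.
    max_steps_factor : cap as a multiple of the node count (default 200;
                       batch jobs over many near-degenerate patterns may
                       lower it to bound runtime, at the price of more
                       discarded walks).
    null_reps        : independent walk campaigns averaged for the null.
    """

    walks_per_start: int = 5000
    max_steps: Optional[int] = None
    seed: int = 0
    null_reps: int = 10
    max_steps_factor: int = 200

    def __post_init__(self) -> None:
        if self.walks_per_start < 1:
            raise ValueError("walks_per_start must be >= 1")
        if self.max_steps is not None and self.max_steps < 1:
            raise ValueError("max_steps must be >= 1")
        if self.null_reps < 1:
            raise ValueError("null_reps must be >= 1")
        if self.max_steps_factor < 1:
            raise ValueError("max_steps_factor must be >= 1")

    def resolve_max_steps(self, n_nodes: int) -> int:
        if self.max_steps is not None:
            return self.max_steps
        return self.max_steps_factor * n_nodes


@dataclass
class WalkGraph:
    """CSR adjacency over coloured bins plus per-node class fractions."""

    indptr: np.ndarray
    indices: np.ndarray
    p_red: np.ndarray     # P(arrival samples red) = f_red / w
    f_red: np.ndarray     # raw bin fraction, start-weighting for alpha = r
    f_yellow: np.ndarray
    component: np.ndarray

    @property
    def n_nodes(self) -> int:
        return len(self.p_red)

    @property
    def degrees(self) -> np.ndarray:
        return np.diff(self.indptr)


def walk_graph(binned: BinnedPattern) -> WalkGraph:
    """Build the walk graph: coloured bins, von-Neumann edges."""
    w = binned.w
    mask = w > 0
    n = int(mask.sum())
    if n < 2:
        raise ValueError("walk graph needs at least 2 coloured bins")
    ids = np.full(mask.shape, -1, dtype=np.int64)
    ids[mask] = np.arange(n)
    rows, cols = [], []
    for axis in range(mask.ndim):
        sl_a = [slice(None)] * mask.ndim
        sl_b = [slice(None)] * mask.ndim
        sl_a[axis] = slice(None, -1)
        sl_b[axis] = slice(1, None)
        a = ids[tuple(sl_a)]
        b = ids[tuple(sl_b)]
        both = (a >= 0) & (b >= 0)
        rows.append(a[both])
        cols.append(b[both])
    r = np.concatenate(rows)
    c = np.concatenate(cols)
    adj = sp.csr_matrix(
        (np.ones(2 * len(r), dtype=np.int8),
         (np.concatenate([r, c]), np.concatenate([c, r]))),
        shape=(n, n),
    )
    adj.sum_duplicates()
    n_comp, labels = connected_components(adj, directed=False)
    if n_comp > 1:
        warnings.warn(
            f"walk graph has {n_comp} connected components; walks stay "
            "within the start's component", stacklevel=2)
    f_red = binned.f_red[mask].astype(np.float64)
    f_yellow = binned.f_yellow[mask].astype(np.float64)
    wm = w[mask].astype(np.float64)
    return WalkGraph(
        indptr=adj.indptr.astype(np.int64),
        indices=adj.indices.astype(np.int64),
        p_red=f_red / wm,
        f_red=f_red,
        f_yellow=f_yellow,
        component=labels,
    )


class TauEstimate(NamedTuple):
    """2x2 CMFPT matrix (rows/cols: red=0, yellow=1), standard errors from
    the per-start walk variance, and the count of discarded capped walks."""

    tau: np.ndarray
    se: np.ndarray
    truncated: int


# ---------------------------------------------------------------------------
# walk kernel
# ---------------------------------------------------------------------------


@nb.njit(inline="always", cache=True)
def _node_state(base, node, out):
    # splitmix64 expansion keyed by (campaign seed, start node): walks from a
    # given start are reproducible independent of launch order
    x = base ^ (np.uint64(node) * np.uint64(0x9E3779B97F4A7C15))
    for i in range(2):
        x = x + np.uint64(0x9E3779B97F4A7C15)
        z = x
        z = (z ^ (z >> np.uint64(30))) * np.uint64(0xBF58476D1CE4E5B9)
        z = (z ^ (z >> np.uint64(27))) * np.uint64(0x94D049BB133111EB)
        out[i] = z ^ (z >> np.uint64(31))
    if out[0] == np.uint64(0) and out[1] == np.uint64(0):
        out[0] = np.uint64(1)


@nb.njit(cache=True)
def _walk_campaign(indptr, indices, p_red, want_r, want_y, walks, max_steps,
                   base_seed):
    """Launch ``walks`` walks from every node wanting at least one target.

    want_r[node] / want_y[node] say whether first passage to red / yellow is
    needed from that start (an entry-selection mask: e.g. tau_ry alone only
    needs yellow-target walks from red-weighted starts).  A walk stops once
    all wanted targets have been hit; walks hitting the step cap first are
    discarded and counted.
    """
    n = len(indptr) - 1
    sum_r = np.zeros(n)
    sumsq_r = np.zeros(n)
    cnt_r = np.zeros(n, np.int64)
    sum_y = np.zeros(n)
    sumsq_y = np.zeros(n)
    cnt_y = np.zeros(n, np.int64)
    trunc = 0
    state = np.empty(2, np.uint64)
    for node in range(n):
        wr = want_r[node]
        wy = want_y[node]
        if not (wr or wy):
            continue
        if indptr[node + 1] - indptr[node] == 0:
            if wr:
                trunc += walks
            if wy:
                trunc += walks
            continue
        _node_state(np.uint64(base_seed), node, state)
        for _ in range(walks):
            pos = node
            t = 0
            hr = not wr
            hy = not wy
            tr = 0
            ty = 0
            while t < max_steps:
                deg = indptr[pos + 1] - indptr[pos]
                pos = indices[indptr[pos] + rand_below(state, deg)]
                t += 1
                p = p_red[pos]
                # pure bins dominate; skip the class draw for them
                if p == 1.0:
                    red = True
                elif p == 0.0:
                    red = False
                else:
                    red = rand_f64(state) < p
                if red:
                    if not hr:
                        tr = t
                        hr = True
                        if hy:
                            break
                else:
                    if not hy:
                        ty = t
                        hy = True
                        if hr:
                            break
            if wr:
                if hr and tr > 0:
                    sum_r[node] += tr
                    sumsq_r[node] += tr * tr
                    cnt_r[node] += 1
                elif not hr:
                    trunc += 1
            if wy:
                if hy and ty > 0:
                    sum_y[node] += ty
                    sumsq_y[node] += ty * ty
                    cnt_y[node] += 1
                elif not hy:
                    trunc += 1
    return sum_r, sumsq_r, cnt_r, sum_y, sumsq_y, cnt_y, trunc


def _aggregate(sums, sumsqs, cnts, weights) -> tuple:
    """Weight per-start means by the start's class weight; SE by delta rule."""
    ok = (weights > 0) & (cnts > 0)
    if not ok.any():
        raise ValueError("no start node of the source class reached the "
                         "target class")
    w = weights[ok]
    m = sums[ok] / cnts[ok]
    tau = float((w * m).sum() / w.sum())
    var_node = np.zeros(len(w))
    multi = cnts[ok] > 1
    if multi.any():
        c = cnts[ok][multi]
        var_node[multi] = np.maximum(
            (sumsqs[ok][multi] - sums[ok][multi] ** 2 / c) / (c - 1), 0.0
        ) / c
    se = float(np.sqrt((w ** 2 * var_node).sum()) / w.sum())
    return tau, se


ALL_ENTRIES = ("rr", "ry", "yr", "yy")
_SOURCE = {"rr": RED_IDX, "ry": RED_IDX, "yr": YELLOW_IDX, "yy": YELLOW_IDX}
_TARGET = {"rr": RED_IDX, "ry": YELLOW_IDX, "yr": RED_IDX, "yy": YELLOW_IDX}


def _normalise_entries(entries) -> tuple:
    if entries is None:
        return ALL_ENTRIES
    entries = tuple(entries)
    bad = set(entries) - set(ALL_ENTRIES)
    if bad:
        raise ValueError(f"unknown tau entries {sorted(bad)}")
    return entries


def _campaign_matrices(graph: WalkGraph, weights_r, weights_y, walks,
                       max_steps, base_seed, entries=ALL_ENTRIES) -> TauEstimate:
    sources = (weights_r, weights_y)
    want_r = np.zeros(graph.n_nodes, dtype=np.bool_)
    want_y = np.zeros(graph.n_nodes, dtype=np.bool_)
    for e in entries:
        want = want_r if _TARGET[e] == RED_IDX else want_y
        want |= sources[_SOURCE[e]] > 0
    sum_r, sq_r, cnt_r, sum_y, sq_y, cnt_y, trunc = _walk_campaign(
        graph.indptr, graph.indices, graph.p_red, want_r, want_y, walks,
        max_steps, np.uint64(base_seed & 0xFFFFFFFFFFFFFFFF))
    tau = np.full((2, 2), np.nan)
    se = np.full((2, 2), np.nan)
    for e in entries:
        a, b = _SOURCE[e], _TARGET[e]
        sums, sqs, cnts = ((sum_r, sq_r, cnt_r) if b == RED_IDX
                           else (sum_y, sq_y, cnt_y))
        tau[a, b], se[a, b] = _aggregate(sums, sqs, cnts, sources[a])
    return TauEstimate(tau=tau, se=se, truncated=int(trunc))


def _check_two_classes(graph: WalkGraph) -> None:
    if graph.f_red.sum() == 0 or graph.f_yellow.sum() == 0:
        raise ValueError("both classes must be present with positive weight")


def estimate_cmfpt(binned: BinnedPattern, config: WalkConfig,
                   entries=None) -> TauEstimate:
    """Monte-Carlo CMFPT of the pattern itself (the raw tau matrix).

    ``entries`` optionally restricts which of ("rr", "ry", "yr", "yy") are
    estimated; the others come back NaN.  Restricting matters when one class
    is rare: walks then stop at the abundant target instead of waiting to
    hit the rare one.
    """
    entries = _normalise_entries(entries)
    graph = walk_graph(binned)
    _check_two_classes(graph)
    max_steps = config.resolve_max_steps(graph.n_nodes)
    est = _campaign_matrices(graph, graph.f_red, graph.f_yellow,
                             config.walks_per_start, max_steps, config.seed,
                             entries)
    _warn_truncation(est, graph, config)
    return est


def _warn_truncation(est: TauEstimate, graph: WalkGraph,
                     config: WalkConfig) -> None:
    total = 2 * graph.n_nodes * config.walks_per_start
    if est.truncated > 0.01 * total:
        warnings.warn(
            f"{est.truncated}/{total} walks hit the step cap and were "
            "discarded", stacklevel=3)


def null_cmfpt(binned: BinnedPattern, config: WalkConfig,
               entries=None) -> TauEstimate:
    """CMFPT of the random-relabelling null, averaged over null_reps draws.

    Each realisation keeps the graph geometry and reassigns the class
    compositions of the coloured bins uniformly at random — a permutation of
    the per-bin class fractions across bins — so class abundances are
    maintained exactly while all spatial structure is destroyed.  A fixed
    relabelling per realisation (rather than re-rolling classes on every
    arrival) is what makes an iid-random pattern its own null, so its
    tau_tilde land at 1.  Walk campaigns on ``null_reps`` independent
    relabellings are averaged.
    """
    entries = _normalise_entries(entries)
    graph = walk_graph(binned)
    _check_two_classes(graph)
    phi = binned.phi()
    if phi == 0 or phi == 1:
        raise ValueError("null model needs both classes present")
    max_steps = config.resolve_max_steps(graph.n_nodes)
    wm = graph.f_red + graph.f_yellow
    rng = np.random.default_rng([config.seed & 0x7FFFFFFF, 0x6E756C6C])
    taus = []
    ses = []
    trunc = 0
    base = np.sort(graph.p_red)  # canonical order: the null depends only on
    # the composition multiset and the geometry, not the input labelling
    for rep in range(config.null_reps):
        perm = rng.permutation(graph.n_nodes)
        p_perm = base[perm]
        null_graph = WalkGraph(
            indptr=graph.indptr, indices=graph.indices,
            p_red=p_perm,
            f_red=wm * p_perm, f_yellow=wm * (1.0 - p_perm),
            component=graph.component,
        )
        est = _campaign_matrices(
            null_graph, null_graph.f_red, null_graph.f_yellow,
            config.walks_per_start, max_steps,
            config.seed + 0x5DEECE66D * (rep + 1), entries)
        taus.append(est.tau)
        ses.append(est.se)
        trunc += est.truncated
    tau = np.mean(taus, axis=0)
    se = np.sqrt(np.mean(np.array(ses) ** 2, axis=0) / len(ses))
    return TauEstimate(tau=tau, se=se, truncated=trunc)


def exact_cmfpt(binned: BinnedPattern) -> np.ndarray:
    """Exact CMFPT by solving the absorbing hitting-time linear system.

    For target class beta, absorption on arrival at node j occurs with
    probability p_j = f_beta(j) / w(j); the expected steps v from each node
    satisfy (I - P diag(1 - p)) v = 1 with P the uniform-neighbour
    transition matrix.  Aggregation over starts matches ``estimate_cmfpt``.
    """
    graph = walk_graph(binned)
    _check_two_classes(graph)
    n = graph.n_nodes
    deg = graph.degrees.astype(np.float64)
    if (deg == 0).any():
        raise ValueError("exact solver requires no isolated nodes")
    adj = sp.csr_matrix(
        (np.ones(len(graph.indices)), graph.indices, graph.indptr),
        shape=(n, n))
    P = sp.diags(1.0 / deg) @ adj
    tau = np.empty((2, 2))
    for b, p_abs in ((RED_IDX, graph.p_red), (YELLOW_IDX, 1 - graph.p_red)):
        for comp in np.unique(graph.component):
            if p_abs[graph.component == comp].max() == 0:
                raise ValueError(
                    "target class unreachable in a connected component")
        M = (sp.identity(n, format="csr") - P @ sp.diags(1.0 - p_abs)).tocsc()
        v = spsolve(M, np.ones(n))
        for a, wts in ((RED_IDX, graph.f_red), (YELLOW_IDX, graph.f_yellow)):
            ok = wts > 0
            tau[a, b] = float((wts[ok] * v[ok]).sum() / wts[ok].sum())
    return tau


@dataclass
class CMFPTResult:
    """Raw, null and normalised CMFPT matrices for one pattern."""

    tau_raw: np.ndarray
    tau_null: np.ndarray
    tau_tilde: np.ndarray
    phi: float
    raw_se: np.ndarray
    null_se: np.ndarray
    truncated_raw: int
    truncated_null: int
    config: WalkConfig

    @property
    def tau_rr_tilde(self) -> float:
        return float(self.tau_tilde[RED_IDX, RED_IDX])

    @property
    def tau_ry_tilde(self) -> float:
        return float(self.tau_tilde[RED_IDX, YELLOW_IDX])

    @property
    def tau_yr_tilde(self) -> float:
        return float(self.tau_tilde[YELLOW_IDX, RED_IDX])

    @property
    def tau_yy_tilde(self) -> float:
        return float(self.tau_tilde[YELLOW_IDX, YELLOW_IDX])

    @property
    def coords(self) -> tuple:
        """Phase-space coordinates (tau_ry_tilde, tau_ry_tilde/tau_yr_tilde)."""
        return (self.tau_ry_tilde, self.tau_ry_tilde / self.tau_yr_tilde)

    def tilde_vector(self) -> np.ndarray:
        """(tau_rr, tau_ry, tau_yr, tau_yy) tilde — the inference coordinates."""
        return np.array([self.tau_rr_tilde, self.tau_ry_tilde,
                         self.tau_yr_tilde, self.tau_yy_tilde])


def normalized_cmfpt(binned: BinnedPattern, config: WalkConfig,
                     entries=None) -> CMFPTResult:
    """Estimate raw and null CMFPT and return the normalised result.

    ``entries`` restricts the estimated matrix entries as in
    ``estimate_cmfpt``; unrequested entries are NaN in all matrices.
    """
    entries = _normalise_entries(entries)
    raw = estimate_cmfpt(binned, config, entries)
    null = null_cmfpt(binned, config, entries)
    sel = ~np.isnan(null.tau)
    if not sel.any() or (null.tau[sel] <= 0).any():
        raise ValueError("null CMFPT could not be estimated for all entries")
    return CMFPTResult(
        tau_raw=raw.tau,
        tau_null=null.tau,
        tau_tilde=raw.tau / null.tau,
        phi=binned.phi(),
        raw_se=raw.se,
        null_se=null.se,
        truncated_raw=raw.truncated,
        truncated_null=null.truncated,
        config=config,
    )
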