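"""Comparator spatial statistics: quadrat Shannon entropy and mean
shortest distance.

Both are single-scale or purely metric summaries that the CMFPT is designed
to improve on; they are kept here for side-by-side comparison of the same
patterns.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
from scipy.sparse.csgraph import shortest_path

from .patterns import RED, YELLOW, ClassGrid

__all__ = [
    "EntropyConfig",
    "MSDResult",
    "shannon_entropy",
    "mean_shortest_distance",
]


@dataclass
class EntropyConfig:
    """Quadrat entropy settings.

    L               : quadrat side in cells (default 10).
    include_partial : count clipped edge quadrats.  Off by default: with
                      partial quadrats in the sum the minimum over offsets
                      is dragged below 1 even for a perfectly mixed
                      checkerboard (a 1x1 corner quadrat is always pure), so
                      the fully-mixed reference value H = 1 only holds when
                      the sum runs over full L x L quadrats.
    """

    L: int = 10
    include_partial: bool = False

    def __post_init__(self) -> None:
        if self.L < 1:
            raise ValueError("L must be >= 1")


def _entropy_term(p: np.ndarray) -> np.ndarray:
    """Binary Shannon entropy in bits, with 0*log0 = 0."""
    out = np.zeros_like(p, dtype=np.float64)
    for q in (p, 1.0 - p):
        pos = q > 0
        out[pos] -= q[pos] * np.log2(q[pos])
    return out


def shannon_entropy(grid: ClassGrid, config: EntropyConfig = EntropyConfig()) -> float:
    """Quadrat Shannon entropy, minimised over tile-grid offsets.

    The grid is tiled into L x L quadrats; per quadrat the mutant frequency
    p_i is computed over coloured cells (background excluded) and the binary
    entropy -[p log2 p + (1-p) log2 (1-p)] averaged over quadrats containing
    coloured cells.  The tile origin is swept over all (x, y) offsets in
    0..L-1 and the minimum H is returned: 0 for fully segregated patterns,
    1 for fully mixed ones.
    """
    labels = grid.labels
    if labels.ndim != 2:
        raise ValueError("quadrat entropy is defined for 2-D grids")
    red = (labels == RED).astype(np.int64)
    col = ((labels == RED) | (labels == YELLOW)).astype(np.int64)
    if col.sum() == 0:
        raise ValueError("pattern has no coloured cells")
    h, w = labels.shape
    L = config.L
    best = np.inf
    for oy in range(L):
        y_edges = _quadrat_edges(h, L, oy)
        for ox in range(L):
            x_edges = _quadrat_edges(w, L, ox)
            reds, cols = _quadrat_counts(red, col, y_edges, x_edges)
            if not config.include_partial:
                full = _full_mask(y_edges, L)[:, None] & _full_mask(x_edges, L)[None, :]
                reds, cols = reds[full], cols[full]
            occupied = cols > 0
            if not occupied.any():
                continue
            p = reds[occupied] / cols[occupied]
            H = float(_entropy_term(p).mean())
            if H < best:
                best = H
    return best


def _quadrat_edges(extent: int, L: int, offset: int) -> np.ndarray:
    """Quadrat boundaries for a tile grid whose origin sits at -offset."""
    start = -offset if offset else 0
    edges = list(range(start, extent, L))
    if edges[0] < 0:
        edges[0] = 0
    edges.append(extent)
    return np.array(edges)


def _full_mask(edges: np.ndarray, L: int) -> np.ndarray:
    return np.diff(edges) == L


def _quadrat_counts(red: np.ndarray, col: np.ndarray, y_edges, x_edges):
    """Per-quadrat red / coloured counts via 2-D prefix sums."""
    out = []
    for arr in (red, col):
        cs = np.zeros((arr.shape[0] + 1, arr.shape[1] + 1), dtype=np.int64)
        cs[1:, 1:] = arr.cumsum(0).cumsum(1)
        out.append(cs[np.ix_(y_edges[1:], x_edges[1:])]
                   - cs[np.ix_(y_edges[1:], x_edges[:-1])]
                   - cs[np.ix_(y_edges[:-1], x_edges[1:])]
                   + cs[np.ix_(y_edges[:-1], x_edges[:-1])])
    return out


@dataclass
class MSDResult:
    """Raw and null-normalised mean shortest distances (edges), rows/cols
    ordered red=0, yellow=1; self-pairs excluded from the diagonal."""

    d_raw: np.ndarray
    d_null: np.ndarray
    d_tilde: np.ndarray
    phi: float


def mean_shortest_distance(grid: ClassGrid, null_reps: int = 10,
                           seed: int = 0) -> MSDResult:
    """Mean shortest-path distance between class pairs on the coloured
    subgraph, normalised by an iid random-relabelling null.

    d_ij is the edge count of the shortest path over coloured cells
    (von-Neumann adjacency); <d_ab> averages over ordered pairs (i in class
    a, j in class b, i != j).  The null keeps the subgraph and relabels each
    coloured cell red with probability phi, averaged over null_reps draws.
    """
    labels = grid.labels
    mask = (labels == RED) | (labels == YELLOW)
    n = int(mask.sum())
    is_red = (labels[mask] == RED) if labels.ndim == 1 else (labels == RED)[mask]
    if is_red.sum() == 0 or (~is_red).sum() == 0:
        raise ValueError("both classes must be present")
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
        (np.ones(2 * len(r)), (np.concatenate([r, c]), np.concatenate([c, r]))),
        shape=(n, n))
    dist = shortest_path(adj, method="D", unweighted=True, directed=False)
    if np.isinf(dist).any():
        warnings.warn("coloured subgraph is disconnected; distances are "
                      "averaged within components", stacklevel=2)
    phi = float(is_red.mean())

    def _means(red_mask: np.ndarray) -> np.ndarray:
        out = np.empty((2, 2))
        sets = (red_mask, ~red_mask)
        for a in range(2):
            for b in range(2):
                d = dist[np.ix_(sets[a], sets[b])]
                if a == b:
                    d = d[~np.eye(d.shape[0], dtype=bool)]
                d = d[np.isfinite(d)]
                out[a, b] = d.mean() if d.size else np.nan
        return out

    d_raw = _means(is_red)
    rng = np.random.default_rng(seed)
    nulls = []
    for _ in range(null_reps):
        null_red = rng.random(n) < phi
        if null_red.all() or not null_red.any():
            continue
        nulls.append(_means(null_red))
    if not nulls:
        raise ValueError("null relabelling produced no two-class draws")
    d_null = np.mean(nulls, axis=0)
    return MSDResult(d_raw=d_raw, d_null=d_null, d_tilde=d_raw / d_null,
                     phi=phi)
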