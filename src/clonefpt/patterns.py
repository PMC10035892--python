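"""Two-class lattice patterns and downsampling.

A pattern is a grid of sites labelled RED (mutant), YELLOW (wild-type) or
EMPTY (background).  This module provides the three artificial mixing-pattern
generators (random clusters, one centred disc, a vertical column interface),
the class ratio, and the fractional-class binning used to put patterns of any
resolution onto a common walk graph.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "EMPTY",
    "YELLOW",
    "RED",
    "ClassGrid",
    "BinnedPattern",
    "generate_clusters",
    "generate_centred",
    "generate_column",
    "class_ratio",
    "downsample",
]

EMPTY: int = 0
YELLOW: int = 1
RED: int = 2


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


@dataclass
class ClassGrid:
    """A 2-D or 3-D grid of {RED, YELLOW, EMPTY} labels.

    ``labels`` has shape (height, width) or (depth, height, width), dtype
    int8.  RED marks mutant cells, YELLOW wild-type cells; everything else
    (non-tumour tissue, unoccupied lattice) is EMPTY.
    """

    labels: np.ndarray

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=np.int8)
        if self.labels.ndim not in (2, 3):
            raise ValueError("labels must be 2-D or 3-D")
        if not np.isin(self.labels, (EMPTY, YELLOW, RED)).all():
            raise ValueError("labels must be in {EMPTY, YELLOW, RED}")

    @property
    def width(self) -> int:
        return self.labels.shape[-1]

    @property
    def height(self) -> int:
        return self.labels.shape[-2]

    @property
    def depth(self) -> int:
        return 1 if self.labels.ndim == 2 else self.labels.shape[0]

    @property
    def n_red(self) -> int:
        return int((self.labels == RED).sum())

    @property
    def n_yellow(self) -> int:
        return int((self.labels == YELLOW).sum())

    def __eq__(self, other: object) -> bool:
        return isinstance(other, ClassGrid) and np.array_equal(self.labels, other.labels)


@dataclass
class BinnedPattern:
    """Downsampled grid with fractional class composition per bin.

    ``f_red + f_yellow + f_empty == 1`` on every bin; ``n_sites`` counts the
    source-grid sites each bin aggregates (edge bins may hold fewer).  Bins
    whose coloured weight ``w = f_red + f_yellow`` is zero are excluded from
    the walk graph built on top of this object.
    """

    f_red: np.ndarray
    f_yellow: np.ndarray
    f_empty: np.ndarray
    n_sites: np.ndarray
    bin_side: int = 1
    adjacency: str = "von_neumann"

    @property
    def w(self) -> np.ndarray:
        """Coloured weight per bin."""
        return self.f_red + self.f_yellow

    @property
    def shape(self) -> tuple:
        return self.f_red.shape

    @property
    def n_bins(self) -> int:
        return int(self.f_red.size)

    def phi(self) -> float:
        """Class ratio of the coloured mass, N_r / (N_r + N_y)."""
        red = float((self.f_red * self.n_sites).sum())
        yel = float((self.f_yellow * self.n_sites).sum())
        if red + yel == 0:
            raise ValueError("pattern has no coloured sites")
        return red / (red + yel)


def _check_phi(phi: float) -> None:
    if not 0.0 <= phi <= 1.0:
        raise ValueError(f"phi must be in [0, 1], got {phi}")


def generate_clusters(
    width: int, height: int, phi: float, cluster_radius: float, seed: int
) -> ClassGrid:
    """Random red discs on a yellow background.

    Fixed-radius discs are dropped at uniformly random centres, one at a
    time, until the realised class ratio first reaches ``phi``.  Discs may
    overlap, so the realised ratio overshoots by at most one disc area.
    """
    _check_phi(phi)
    if width < 1 or height < 1:
        raise ValueError("grid dimensions must be positive")
    if cluster_radius <= 0:
        raise ValueError("cluster_radius must be positive")
    if cluster_radius > min(width, height) / 2:
        raise ValueError("cluster_radius larger than half the smaller grid side")
    labels = np.full((height, width), YELLOW, dtype=np.int8)
    total = width * height
    if phi >= 1.0:
        labels[:] = RED
        return ClassGrid(labels)
    rng = np.random.default_rng(seed)
    yy, xx = np.mgrid[0:height, 0:width]
    r2 = cluster_radius * cluster_radius
    # ratio rises by >=1 site per useful disc; cap guards pathological RNG runs
    max_discs = 100 * total
    for _ in range(max_discs):
        n_red = int((labels == RED).sum())
        if n_red / total >= phi:
            break
        cy = rng.uniform(0, height)
        cx = rng.uniform(0, width)
        disc = (yy - cy) ** 2 + (xx - cx) ** 2 <= r2
        labels[disc] = RED
    return ClassGrid(labels)


def generate_centred(width: int, height: int, phi: float) -> ClassGrid:
    """One red disc at the grid centre holding round(phi*width*height) sites.

    Sites are ranked by Euclidean distance from the grid centre, ties broken
    by row-major order, and the nearest ``round(phi*N)`` sites turn red.
    """
    _check_phi(phi)
    labels = np.full((height, width), YELLOW, dtype=np.int8)
    n_red = _round_half_up(phi * width * height)
    if n_red > 0:
        cy = (height - 1) / 2.0
        cx = (width - 1) / 2.0
        yy, xx = np.mgrid[0:height, 0:width]
        d2 = ((yy - cy) ** 2 + (xx - cx) ** 2).ravel()
        order = np.argsort(d2, kind="stable")  # stable = row-major tie-break
        flat = labels.ravel()
        flat[order[:n_red]] = RED
    return ClassGrid(labels)


def generate_column(width: int, height: int, phi: float) -> ClassGrid:
    """Fully segregated pattern: the leftmost round(phi*width) columns red."""
    _check_phi(phi)
    labels = np.full((height, width), YELLOW, dtype=np.int8)
    n_cols = _round_half_up(phi * width)
    labels[:, :n_cols] = RED
    return ClassGrid(labels)


def class_ratio(grid: ClassGrid) -> float:
    """Fraction of coloured sites that are red: N_r / (N_r + N_y)."""
    n_r = grid.n_red
    n_y = grid.n_yellow
    if n_r + n_y == 0:
        raise ValueError("pattern has no coloured sites")
    return n_r / (n_r + n_y)


def downsample(grid: ClassGrid, target_bins: int = 3000) -> BinnedPattern:
    """Bin a grid into at most ``target_bins`` square (or cubic) bins.

    The bin side k is the smallest integer for which the number of bins,
    prod(ceil(dim/k)), fits the budget.  Each bin records the exact class
    fractions of its constituent sites, so class mass is conserved:
    sum(f_c * n_sites) over bins equals the source count of class c.
    """
    if target_bins < 1:
        raise ValueError("target_bins must be >= 1")
    labels = grid.labels
    dims = labels.shape
    k = 1
    while math.prod(-(-d // k) for d in dims) > target_bins:
        k += 1
    out_shape = tuple(-(-d // k) for d in dims)
    pad = [(0, o * k - d) for o, d in zip(out_shape, dims)]
    counts = {}
    valid = np.pad(np.ones_like(labels, dtype=np.int64), pad)
    for cls in (RED, YELLOW, EMPTY):
        arr = np.pad((labels == cls).astype(np.int64), pad)
        counts[cls] = _block_sum(arr, k)
    n_sites = _block_sum(valid, k).astype(np.float64)
    f_red = counts[RED] / n_sites
    f_yellow = counts[YELLOW] / n_sites
    f_empty = counts[EMPTY] / n_sites
    return BinnedPattern(
        f_red=f_red,
        f_yellow=f_yellow,
        f_empty=f_empty,
        n_sites=n_sites,
        bin_side=k,
    )


def _block_sum(arr: np.ndarray, k: int) -> np.ndarray:
    """Sum over non-overlapping k-blocks along every axis (arr pre-padded)."""
    for axis in range(arr.ndim):
        n = arr.shape[axis] // k
        arr = arr.reshape(
            arr.shape[:axis] + (n, k) + arr.shape[axis + 1 :]
        ).sum(axis=axis + 1)
    return arr
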