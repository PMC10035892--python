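"""Grid-search inference of sub-clonal growth parameters from CMFPT.

A library of simulated patterns is summarised by their normalised CMFPT
vectors (tau_rr, tau_ry, tau_yr, tau_yy) tilde.  For a query pattern the
posterior over (s, n_mut, q) is the set of the n nearest library entries in
the log-transformed 4-D phase space; the point estimate is the most abundant
parameter triple among them and per-parameter 95% credible sets collect grid
values in decreasing posterior-count order.  The class ratio phi is stored
with every entry but deliberately kept out of the metric: it is the quantity
most distorted by how a 2-D section samples a 3-D tumour.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .cmfpt import WalkConfig, normalized_cmfpt
from .growth_sim import SimParams, SimulationError, simulate_tumour
from .patterns import downsample

__all__ = [
    "LIBRARY_COLUMNS",
    "Posterior",
    "build_library",
    "load_library",
    "log_euclidean_distance",
    "infer",
    "validate_inference",
]

logger = logging.getLogger(__name__)

LIBRARY_COLUMNS = ["s", "n_mut", "q", "seed",
                   "tau_rr", "tau_ry", "tau_yr", "tau_yy", "phi"]
_TAU_COLS = ["tau_rr", "tau_ry", "tau_yr", "tau_yy"]


def log_euclidean_distance(u: np.ndarray, v: np.ndarray) -> float:
    """Euclidean distance between componentwise natural logs."""
    u = np.asarray(u, dtype=np.float64)
    v = np.asarray(v, dtype=np.float64)
    if (u <= 0).any() or (v <= 0).any():
        raise ValueError("log-Euclidean distance needs positive components")
    return float(np.linalg.norm(np.log(u) - np.log(v)))


@dataclass
class Posterior:
    """The n nearest library entries and the summaries derived from them."""

    samples: pd.DataFrame            # nearest rows, with a 'distance' column
    point_estimate: tuple            # (s, n_mut, q)
    marginals: dict                  # param -> {grid value: count}
    credible_sets: dict              # param -> set of grid values (>= 95%)
    n: int

    def marginal(self, param: str) -> dict:
        return self.marginals[param]


def _run_seed(base_seed: int, combo_idx: int, rep: int) -> int:
    # stable per-(combo, rep) seed, kept below 2**31
    return (base_seed + 1_000_003 * combo_idx + 7919 * rep) % (2 ** 31 - 1)


def simulate_library_entry(s: float, n_mut: float, q: int, seed: int,
                           n_max: int, walk_config: WalkConfig,
                           target_bins: int = 3000, psi: float = 0.3,
                           max_restarts: int = 200) -> dict:
    """Simulate one tumour and measure its normalised CMFPT vector."""
    params = SimParams(s=s, n_mut=n_mut, q=q, n_max=n_max, psi=psi,
                       seed=seed, max_restarts=max_restarts)
    grid, _ = simulate_tumour(params)
    binned = downsample(grid, target_bins=target_bins)
    phi = binned.phi()
    if phi == 0.0 or phi == 1.0:
        # one class fixed (tiny introduction populations can drift to
        # mutant fixation); the CMFPT of a single-class pattern is undefined
        raise SimulationError(
            f"single-class pattern (phi={phi}) for s={s}, n_mut={n_mut}, "
            f"q={q}, seed={seed}")
    cfg = WalkConfig(walks_per_start=walk_config.walks_per_start,
                     max_steps=walk_config.max_steps,
                     max_steps_factor=walk_config.max_steps_factor,
                     seed=seed, null_reps=walk_config.null_reps)
    res = normalized_cmfpt(binned, cfg)
    vec = res.tilde_vector()
    return dict(s=s, n_mut=n_mut, q=q, seed=seed,
                tau_rr=vec[0], tau_ry=vec[1], tau_yr=vec[2], tau_yy=vec[3],
                phi=res.phi)


def build_library(s_grid: Sequence[float], nmut_grid: Sequence[float],
                  q_grid: Sequence[int], reps_per_combo: int,
                  base_seed: int, n_max: int,
                  walk_config: Optional[WalkConfig] = None,
                  target_bins: int = 3000, psi: float = 0.3,
                  out_path: Optional[str] = None,
                  max_restarts: int = 200) -> pd.DataFrame:
    """Simulate `reps_per_combo` patterns per parameter combination.

    Rows are keyed by (s, n_mut, q, seed); if ``out_path`` exists its rows
    are kept and only missing ones are computed, so a long build can resume.
    Combinations whose simulations keep going extinct (the deep-neutral,
    strong-pushing corner) are skipped with a log entry.
    """
    if walk_config is None:
        walk_config = WalkConfig()
    existing = None
    if out_path is not None and Path(out_path).exists():
        existing = pd.read_csv(out_path, sep="\t")
    rows = [] if existing is None else [existing]
    have = set()
    if existing is not None:
        have = set(map(tuple, existing[["s", "n_mut", "q", "seed"]].values))
    combos = list(itertools.product(s_grid, nmut_grid, q_grid))
    for ci, (s, n_mut, q) in enumerate(combos):
        new = []
        for rep in range(reps_per_combo):
            seed = _run_seed(base_seed, ci, rep)
            if (s, n_mut, q, seed) in have:
                continue
            try:
                new.append(simulate_library_entry(
                    s, n_mut, q, seed, n_max, walk_config,
                    target_bins=target_bins, psi=psi,
                    max_restarts=max_restarts))
            except SimulationError as exc:
                logger.warning("skipping (s=%s, n_mut=%s, q=%s, rep=%s): %s",
                               s, n_mut, q, rep, exc)
        if new:
            rows.append(pd.DataFrame(new))
    library = (pd.concat(rows, ignore_index=True)[LIBRARY_COLUMNS]
               if rows else pd.DataFrame(columns=LIBRARY_COLUMNS))
    if out_path is not None:
        library.to_csv(out_path, sep="\t", index=False)
    return library


def load_library(path: str) -> pd.DataFrame:
    library = pd.read_csv(path, sep="\t")
    missing = set(LIBRARY_COLUMNS) - set(library.columns)
    if missing:
        raise ValueError(f"library is missing columns {sorted(missing)}")
    return library


def infer(query: np.ndarray, library: pd.DataFrame, n: int = 100) -> Posterior:
    """Nearest-neighbour posterior for one query tilde 4-vector.

    Ties in distance are broken by library row order; the point estimate is
    the most abundant (s, n_mut, q) triple among the n nearest (ties broken
    by smallest mean distance); each parameter's 95% credible set greedily
    accumulates grid values in decreasing count order until >= 0.95 n.
    """
    if len(library) < n:
        raise ValueError(
            f"library has {len(library)} rows < n={n}; lower n")
    query = np.asarray(query, dtype=np.float64)
    if query.shape != (4,):
        raise ValueError("query must be a tilde 4-vector")
    if (query <= 0).any():
        raise ValueError("query components must be positive")
    lib_vecs = library[_TAU_COLS].to_numpy(dtype=np.float64)
    if (lib_vecs <= 0).any():
        raise ValueError("library tilde values must be positive")
    d = np.linalg.norm(np.log(lib_vecs) - np.log(query), axis=1)
    order = np.argsort(d, kind="stable")[:n]
    samples = library.iloc[order].copy()
    samples["distance"] = d[order]

    grouped = samples.groupby(["s", "n_mut", "q"], sort=False)["distance"]
    counts = grouped.count()
    means = grouped.mean()
    best = counts[counts == counts.max()].index
    point = min(best, key=lambda combo: (means[combo], best.get_loc(combo)))

    marginals = {}
    credible = {}
    for param in ("s", "n_mut", "q"):
        vc = samples[param].value_counts()
        marginals[param] = vc.to_dict()
        need = 0.95 * n
        acc = 0
        chosen = set()
        for value, cnt in vc.items():
            chosen.add(value)
            acc += cnt
            if acc >= need:
                break
        credible[param] = chosen
    return Posterior(samples=samples, point_estimate=tuple(point),
                     marginals=marginals, credible_sets=credible, n=n)


def validate_inference(library: pd.DataFrame, holdout_fraction: float = 0.2,
                       seed: int = 0, n: Optional[int] = None):
    """Leave-replicate-out parameter recovery on the library itself.

    A random holdout of rows is classified against the remaining rows;
    returns per-parameter confusion matrices (pandas crosstab, true value in
    rows) and the per-true-value probability of exact recovery.
    """
    rng = np.random.default_rng(seed)
    library = library.reset_index(drop=True)
    n_hold = max(1, min(len(library),
                        int(round(holdout_fraction * len(library)))))
    hold_idx = np.sort(rng.choice(len(library), size=n_hold, replace=False))
    if n is None:
        n = min(100, len(library) - 1)
    records = []
    for idx in hold_idx:
        row = library.iloc[idx]
        rest = library.drop(index=idx)  # the replicate may not match itself
        post = infer(row[_TAU_COLS].to_numpy(dtype=np.float64), rest, n=n)
        records.append(dict(
            true_s=row["s"], true_n_mut=row["n_mut"], true_q=row["q"],
            pred_s=post.point_estimate[0], pred_n_mut=post.point_estimate[1],
            pred_q=post.point_estimate[2]))
    preds = pd.DataFrame(records)
    confusion = {}
    recovery = {}
    for param in ("s", "n_mut", "q"):
        confusion[param] = pd.crosstab(preds[f"true_{param}"],
                                       preds[f"pred_{param}"])
        correct = preds[f"true_{param}"] == preds[f"pred_{param}"]
        recovery[param] = correct.groupby(preds[f"true_{param}"]).mean().to_dict()
    return confusion, recovery, preds
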