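"""Canned end-to-end experiments: the package's headline self-checks.

Each routine recomputes one quantitative property of the method from
scratch — generating its own inputs, running the pipeline and measuring the
result — and is shared between the test suite and ``scripts/acceptance.py``.
All randomness derives from the single ``seed`` argument.
"""

from __future__ import annotations

import logging
from typing import Sequence

import numpy as np
from scipy import stats

from .cmfpt import WalkConfig, normalized_cmfpt
from .growth_sim import SimParams, simulate_tumour
from .inference import build_library, validate_inference
from .patterns import RED, YELLOW, ClassGrid, downsample, generate_column

logger = logging.getLogger(__name__)

__all__ = [
    "iid_pattern",
    "checkerboard",
    "iid_null_consistency",
    "division_rate_ratio",
    "neutral_phase_location",
    "death_fraction",
    "mutation_bookkeeping",
    "reduced_recovery",
]


def iid_pattern(width: int = 60, height: int = 50, phi: float = 0.5,
                seed: int = 0) -> ClassGrid:
    """Two-class pattern with iid uniform colours (the null's own fixed point)."""
    rng = np.random.default_rng([seed & 0x7FFFFFFF, 0x11D])
    labels = np.where(rng.random((height, width)) < phi, RED, YELLOW)
    return ClassGrid(labels.astype(np.int8))


def checkerboard(side: int = 54) -> ClassGrid:
    board = np.indices((side, side)).sum(axis=0) % 2
    return ClassGrid(np.where(board == 0, RED, YELLOW).astype(np.int8))


def segregated(side: int = 54) -> ClassGrid:
    return generate_column(side, side, 0.5)


def iid_null_consistency(seed: int = 1, walks: int = 5000,
                         null_reps: int = 10) -> dict:
    """CMFPT phase-space coordinates of an iid-random 60x50 pattern.

    The pattern is statistically identical to the normalising null, so both
    coordinates (tau_ry_tilde, tau_ry_tilde / tau_yr_tilde) sit at 1 up to
    pattern-draw and walk sampling noise (about 2% on the first coordinate).
    """
    grid = iid_pattern(seed=seed)
    binned = downsample(grid, target_bins=3000)
    res = normalized_cmfpt(binned, WalkConfig(
        walks_per_start=walks, null_reps=null_reps, seed=seed))
    return dict(tau_ry_tilde=res.tau_ry_tilde,
                ratio=res.coords[1], phi=res.phi,
                n_bins=binned.n_bins)


def division_rate_ratio(s: float = 3.0, seed: int = 1,
                        n_max: int = 10_000) -> dict:
    """Mutant/wild-type division-rate ratio (1 + s), with an event-log check.

    The analytic ratio comes from the simulator's rate law; a simulation's
    event log is compared against it by a one-degree chi-squared test on the
    observed vs expected number of mutant firings.
    """
    params = SimParams(s=s, n_mut=0.1, q=5, n_max=n_max, seed=seed)
    ratio = params.b_mut / params.b_wt
    _, rec = simulate_tumour(params)
    obs_mut = rec.n_mut_firings
    exp_mut = rec.expected_mut_firings
    exp_wt = rec.n_firings - exp_mut
    chi2 = ((obs_mut - exp_mut) ** 2 / exp_mut
            + (rec.n_wt_firings - exp_wt) ** 2 / exp_wt)
    p = float(stats.chi2.sf(chi2, df=1))
    return dict(ratio=ratio, chi2=float(chi2), p_value=p,
                n_firings=rec.n_firings)


def neutral_phase_location(seed: int = 1, n_reps: int = 10,
                           n_max: int = 10_000, walks: int = 500,
                           null_reps: int = 10,
                           target_bins: int = 500) -> dict:
    """Mean tau_ry_tilde of neutral (s = 0) simulated tumours.

    Neutral sub-clones with moderate pushing occupy the leftmost band of the
    phase space, tau_ry_tilde <= 2.  Half the replicates use n_mut = 0.01,
    half 0.1; base seeds are strided so restart chains never coincide.  The
    bin budget keeps roughly the full-scale ratio of cells per bin (~33),
    so a surviving clone mixes at bin scale the way it does at full size;
    analysing a small colony at full resolution makes clones look
    artificially compact.
    """
    values = []
    nmuts = [0.01] * (n_reps // 2) + [0.1] * (n_reps - n_reps // 2)
    for i, nm in enumerate(nmuts):
        run_seed = (seed + 10_007 * (i + 1)) % (2 ** 31 - 1)
        params = SimParams(s=0.0, n_mut=nm, q=5, n_max=n_max, seed=run_seed)
        grid, _ = simulate_tumour(params)
        binned = downsample(grid, target_bins=target_bins)
        res = normalized_cmfpt(binned, WalkConfig(
            walks_per_start=walks, null_reps=null_reps, seed=run_seed),
            entries=("ry",))
        values.append(res.tau_ry_tilde)
    return dict(mean_tau_ry_tilde=float(np.mean(values)), values=values)


def death_fraction(seed: int = 1, min_firings: int = 100_000,
                   psi: float = 0.3) -> dict:
    """Long-run fraction of firing events resolving to death.

    Death is coupled to birth by the per-firing coin psi, so the fraction
    converges to psi by the binomial law.  Simulations (default parameters,
    moderate size) accumulate at least ``min_firings`` firings.
    """
    firings = 0
    deaths = 0
    i = 0
    while firings < min_firings:
        run_seed = (seed + 20_011 * (i + 1)) % (2 ** 31 - 1)
        params = SimParams(s=1.0, n_mut=0.1, q=5, n_max=20_000, psi=psi,
                           seed=run_seed)
        _, rec = simulate_tumour(params)
        firings += rec.n_firings
        deaths += rec.n_deaths
        i += 1
    return dict(fraction=deaths / firings, n_firings=firings,
                binomial_se=float(np.sqrt(psi * (1 - psi) / firings)))


def mutation_bookkeeping(n_max: int = 100_000,
                         nmut_values: Sequence[float] = (0.1, 0.001, 0.5),
                         seed: int = 1) -> dict:
    """Population size at mutation introduction for several n_mut values.

    The introduction is triggered the first time the colony reaches
    round(n_max * n_mut) cells, so the recorded size matches it exactly.
    """
    out = {}
    for i, nm in enumerate(nmut_values):
        params = SimParams(s=0.0, n_mut=nm, q=0, n_max=n_max,
                           seed=seed + 31 * i)
        _, rec = simulate_tumour(params)
        out[nm] = dict(pop_at_mutation=rec.pop_at_mutation,
                       expected=params.n_intro,
                       final_size=rec.final_n_wt + rec.final_n_mut)
    return out


def reduced_recovery(seed: int = 1, reps_per_combo: int = 20,
                     n_max: int = 10_000, walks: int = 150,
                     null_reps: int = 3, target_bins: int = 500,
                     max_steps_factor: int = 30,
                     n_nearest: int = 5) -> dict:
    """Parameter recovery on a reduced corner-of-the-grid library.

    Builds a library over s in {0, 3}, n_mut in {0.001, 0.5}, q in {0, 20},
    classifies every replicate leave-one-out and reports the
    modal-combination recovery rate plus per-value recovery for the
    selection coefficient and pushing strength.

    Half of this grid (the n_mut = 0.5 column) produces sub-clones of only
    a few cells at this system size, whose normalised CMFPT vectors sit at
    the null point (1, 1, 1, 1) regardless of s and q; the walk-step cap is
    lowered to bound the time spent measuring those near-degenerate
    patterns.
    """
    library = build_library(
        (0.0, 3.0), (0.001, 0.5), (0, 20),
        reps_per_combo=reps_per_combo, base_seed=seed, n_max=n_max,
        walk_config=WalkConfig(walks_per_start=walks, null_reps=null_reps,
                               max_steps_factor=max_steps_factor),
        target_bins=target_bins)
    _, recovery, preds = validate_inference(library, holdout_fraction=1.0,
                                            seed=seed, n=n_nearest)
    exact = float(((preds.true_s == preds.pred_s)
                   & (preds.true_n_mut == preds.pred_n_mut)
                   & (preds.true_q == preds.pred_q)).mean())
    return dict(exact_combo_recovery=exact,
                s_recovery=recovery["s"],
                q_recovery=recovery["q"],
                n_rows=len(library),
                predictions=preds)
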