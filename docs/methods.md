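# Methods

## The statistic: class mean first passage times

A two-class spatial pattern is a grid of sites labelled mutant (red),
wild-type (yellow) or background.  The class mean first passage time
(CMFPT) τ_αβ is the expected number of steps a uniform random walker,
started on a site of class α, needs before it first arrives at a site of
class β.  Four quantities arise from two classes: τ_rr, τ_ry, τ_yr, τ_yy.
Because the walker probes the pattern at every length scale it traverses,
the CMFPT summarises mixing and clustering without committing to a single
analysis scale, unlike quadrat statistics.

**Binning.**  Patterns are first downsampled to at most `target_bins`
(default 3000) square bins; the bin side k is the smallest integer meeting
the budget, so grids already below it are analysed at native resolution.
Each bin stores the exact fractions (f_red, f_yellow, f_empty) of its
constituent sites, which conserves class mass exactly, including in partial
edge bins.  Bins with no coloured content are excluded from the walk graph;
the rest are connected by von-Neumann adjacency.  A walker arriving at a
bin samples the bin's class afresh on every arrival, red with probability
f_red/(f_red+f_yellow) — a memoryless reading of fractional composition
(a bin that is half red and half yellow is seen as either with equal
probability).  First passage from class α aggregates per-start means over
all bins with f_α > 0, weighted by f_α, so partially-red bins contribute
to red-start averages in proportion to their red content.  The start bin
itself is excluded; τ ≥ 1 by construction, including the diagonal entries
τ_rr and τ_yy (the walker must leave and come back).

**Estimation.**  τ is estimated by simulating `walks_per_start` (default
5000) walks from every coloured bin.  A single walk records its first
arrival at red and at yellow simultaneously and stops when all requested
targets are hit; entry selection (`entries=("ry",)` etc.) restricts walks
to the start classes and targets actually needed, which matters enormously
when one class is rare — a red→yellow time is cheap when yellow is
abundant, while a yellow→red time to a tiny sub-clone costs thousands of
steps per walk.  Walks exceeding `max_steps` (default 200 × number of
nodes) are discarded and counted; more than 1% of discards raises a
warning.  Standard errors come from the per-start walk variance propagated
through the weighted aggregation.

**Exact oracle.**  For verification the same quantity is computed exactly:
absorption on arrival at node j occurs with probability equal to j's class-β
weight, and the expected absorption times v solve the sparse linear system
(I − P·diag(1−p)) v = 1 with P the uniform-neighbour transition matrix.
The Monte-Carlo estimator is required (in tests) to agree with this oracle
within three standard errors on every fixture graph; the oracle is never
used in place of the estimator.

**Null model and normalisation.**  Raw CMFPT scales with pattern size and
class ratio, so each τ_αβ is divided by its value under a null model that
keeps the graph geometry and redistributes the per-bin class compositions
uniformly at random — a permutation of the composition multiset across
bins, drawn independently `null_reps` (default 10) times and averaged.
The permutation maintains class abundances exactly and can never produce a
degenerate single-class realisation, which matters for patterns whose
sub-clone occupies a handful of bins.  Two readings of "random
reassignment" were possible: an independent Bernoulli relabelling per bin,
or the abundance-preserving permutation; they agree asymptotically and we
adopt the permutation, which is also what makes an iid-random pattern its
own null.  A fixed relabelling per realisation (rather than re-rolling a
bin's class on every arrival) is essential: on a recurrent 2-D walk,
revisiting a bin known to be yellow is not the same as re-rolling it, and
only the fixed-relabelling null places iid patterns at τ̃ = 1.  The
normalised coordinates used throughout are (τ̃_ry, τ̃_ry/τ̃_yr): ≈(1, 1)
for unstructured patterns, τ̃_ry ≫ 1 for segregated ones, and the ratio
above/below 1 according to whether red or yellow forms the larger clusters.
For a single 3000-bin iid pattern the pattern-draw fluctuation of τ̃_ry is
about 2% (measured with the exact oracle over 20 draws), on top of roughly
1% null-averaging noise at 10 replicates.

## The generative model: lattice growth with pushing

A single wild-type cell seeds a square (2-D) or cubic (3-D) lattice of side
ceil(2.5·N_max^(1/dims)), centred.  Cells fire with probability
proportional to their birth rate (rejection sampling); a mutant's rate is
(1+s)·b_WT.  On each firing the cell dies with probability ψ (default 0.3)
— death coupled to birth, d_i = b_i·ψ — otherwise it attempts to divide.
Because death rides on the firing event, absolute time is never needed and
no clock is kept; the event sequence alone determines the pattern.

Division requires space: a breadth-first search from the divider through
occupied sites finds the nearest empty lattice point; the chain of at most
q occupied cells along the path is shifted one step outward and the freed
adjacent site receives the daughter.  Among minimum-length chains,
straight-line chains (momentum along one lattice axis) take strict
priority; remaining ties are broken uniformly over the minimal-depth empty
termini, with randomised BFS expansion order.  q = 0 reduces to surface
growth: division succeeds only next to an empty site.  A failed division
consumes the firing.  The neighbourhood is von Neumann throughout.

When the colony first reaches round(N_max·n_mut) cells, one uniformly
chosen wild-type cell becomes mutant; descendants inherit the label and
never revert.  Runs that lose the whole population or the mutant lineage
restart with seed+attempt, up to `max_restarts` (default 200 — deep-neutral
introductions of interior cells under surface growth die often, and some
corner combinations are genuinely hard to generate; exhaustion raises an
error naming the combination).  Because the restart chain walks consecutive
seeds, replicate experiments stride their base seeds by large constants so
two replicates can never converge onto the same successful attempt.
Boundary contact raises an error rather than wrapping.  The returned grid
is cropped to the colony's bounding box.

Event bookkeeping (firings per genotype, expected mutant share per firing,
deaths, failed divisions, restart count, population at introduction) is
recorded so the rate law and death coupling are testable against the log:
the observed mutant firing count is compared to its expectation by a
chi-squared test, and the death fraction to ψ by binomial error.

Known deviation from an idealised picture: under pure surface growth
(q = 0, ψ = 0) advancing arms occasionally seal a small concavity, so the
colony can trap a few empty pockets (well under 1% of its area); it is
connected but not always simply connected.

## Comparator statistics

**Quadrat entropy.**  The grid is tiled into L×L quadrats (default L = 10);
per quadrat the mutant frequency p_i is computed over coloured cells and
the mean binary entropy −[p·log2 p + (1−p)·log2(1−p)] taken over occupied
quadrats, with 0·log 0 = 0.  The tile origin is swept over all L² offsets
and the minimum returned.  Only full L×L quadrats enter the sum: clipped
edge quadrats (down to a single cell) are always pure or near-pure, and
including them drags the minimum below 1 even for a perfectly mixed
checkerboard; with full quadrats the reference values are exact — H = 0
for the aligned fully segregated pattern and H = 1 for the checkerboard.
An `include_partial` flag restores the clipped-quadrat variant.

**Mean shortest distance.**  ⟨d_αβ⟩ averages shortest-path edge counts on
the coloured-cell subgraph over ordered class pairs, self-pairs excluded;
normalisation divides by the same quantity under iid random relabelling
(10 draws).  Distances are computed once (scipy's sparse BFS) and only the
labels are redrawn.

## Inference by nearest neighbours in phase space

A library of simulated patterns spans the grid s ∈ {0, 0.1, 0.2, 0.5, 1,
2, 3}, n_mut ∈ {0.001, 0.01, 0.03, 0.05, 0.08, 0.1, 0.5}, q ∈ {0, 5, 10,
20}, with each row holding a replicate's (τ̃_rr, τ̃_ry, τ̃_yr, τ̃_yy) and
ϕ.  For a query vector, the posterior over (s, n_mut, q) is the sample of
the n = 100 nearest rows by Euclidean distance between natural-log vectors
(the log base only rescales distances); ties break by row order.  The
point estimate is the most abundant parameter triple among the n, ties
broken by smaller mean distance; per-parameter 95% credible sets collect
grid values in decreasing count order until they hold at least 0.95·n —
a greedy highest-posterior-density construction on the discrete grid,
which need not be contiguous.  ϕ is stored but excluded from the metric:
it is the quantity most distorted by sectioning a 3-D tumour in 2-D, and
the statistic is meant to stand on pattern structure alone; an optional
fifth coordinate log ϕ can be appended by passing a 5-vector library.
Replicates whose final pattern is single-class (possible when the
introduction population is a handful of cells and the mutant drifts to
fixation) are skipped with a log entry, as are parameter combinations
whose simulations exhaust the restart budget — the deep-neutral,
late-introduction, strong-pushing corner is known to be hard to generate.

Validation is leave-one-out: each library row is classified against the
remaining rows and per-parameter confusion matrices and exact-recovery
probabilities reported.

## Problem sizes used by the packaged experiments

The canned experiments (`clonefpt.experiments`, shared by the test suite
and `scripts/acceptance.py`) run at sizes a single workstation core
handles comfortably while preserving each property being measured:

- Null consistency: one 60×50 iid pattern (3000 bins, the analysis
  default), 5000 walks/start, 10 null replicates.
- Rate law: one 10^4-cell run at s = 3 (≈7×10^4 firings for the
  chi-squared check); the ratio itself is the model's rate law.
- Neutral phase location: ten tumours at N_max = 10^4, q = 5, n_mut ∈
  {0.01, 0.1}, 500 walks/start, τ̃_ry only.
- Death coupling: runs accumulated until ≥10^5 firings.
- Bookkeeping: three runs at the full N_max = 10^5.
- Reduced recovery: the corner grid s ∈ {0, 3} × n_mut ∈ {0.001, 0.5} ×
  q ∈ {0, 20}, 20 replicates per combination at N_max = 10^4, analysed at
  500 bins with 150 walks/start, 3 null replicates and a 30×nodes step cap,
  classified leave-one-out with n = 5 nearest neighbours.  This experiment
  has a known structural limit: the n_mut = 0.5 half of the grid produces
  sub-clones of a handful of cells whose CMFPT vectors sit at the null
  point irrespective of s and q, so those combinations are mutually
  indistinguishable in principle, and at this system size the pushing
  signal for the informative half is weaker than the drift-driven
  replicate-to-replicate spread (at N_max = 3×10^4 the q signal separates
  cleanly, but measuring the degenerate half at that size costs hours of
  walk time).  The recovery rate the experiment reports — around 0.64
  exact-combination recovery — and the inversion of the marginal
  selection-recovery ordering (the degenerate combinations all predict
  s = 0-like values, inflating s = 0 marginal accuracy) are therefore
  properties of the corner design at desk scale, not of the method; the
  corresponding test records the expectation and its measured shortfall.

## What the synthetic data does and does not emulate

The artificial patterns (clusters, centred disc, column) and the simulator
probe the statistic under known ground truth.  The simulator captures
growth-driven segregation, drift, pushing-induced mixing and sub-clone
geometry, but not: non-tumour tissue interleaved with tumour (real stained
sections carry large unlabelled regions; the analysis expects pre-curated
masks and offers sub-region extraction instead), three-dimensional
sectioning effects (2-D slices of 3-D growth produce more diverse patterns
than native 2-D growth, and ϕ varies wildly with slice orientation — the
3-D mode with orthogonal slicing exists at reduced size for exactly this
exploration), cell migration, phenotypic switching, or microenvironment
mechanics.  Passing tests therefore demonstrate correctness of the
statistic and the generative model, not fidelity of any particular
biological inference.

## Numerical choices

- Rounding of count-valued quantities (round(ϕ·w), round(N_max·n_mut)):
  half-up, for determinism and symmetry.
- Centred-disc ties at equal radius break in row-major order.
- Cluster generator: fixed-radius discs at uniform centres, overlap
  allowed, added until the requested ratio is first reached (overshoot at
  most one disc area).
- All Monte-Carlo randomness flows through an explicit xorshift128+ state;
  walker streams are keyed by (campaign seed, start node) so results are
  independent of launch order.  Pattern-level randomness uses numpy
  Generators seeded from the experiment seed.
- The walk-graph null canonicalises the composition multiset (sorts it)
  before permuting, making the null estimate exactly invariant under
  relabellings of the input bins at fixed seed.
- Degenerate inputs fail loudly: single-class patterns, empty masks,
  non-positive τ̃ vectors, a library smaller than n.
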