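# clonefpt

First passage time analysis of two-class tumour cell mixing patterns.

Mutation-specific staining of tumour sections (e.g. BaseScope in-situ
hybridisation) maps, cell by cell, which tumour cells carry a point
mutation (red) and which are wild-type (yellow).  The spatial arrangement
of the mutant sub-clone within the wild-type population is a frozen record
of how that sub-clone grew: how strong its replicative advantage was, how
early it arose, and how much dividing cells pushed their neighbours around.
`clonefpt` provides the three pieces needed to read that record:

1. **A spatial statistic.**  The *class mean first passage time* (CMFPT)
   τ_αβ is the expected number of steps a random walker started on a cell
   of class α needs to first reach a cell of class β (α, β ∈ {r, y}).
   Each τ_αβ is normalised by its value under a null model in which the
   class labels are redistributed uniformly at random over the same
   geometry, giving dimensionless τ̃_αβ.  Unstructured patterns sit at
   (τ̃_ry, τ̃_ry/τ̃_yr) = (1, 1); segregation pushes τ̃_ry ≫ 1; the ratio
   records which class forms the larger clusters.  Quadrat Shannon entropy
   and normalised mean shortest distance are included as comparators.

2. **A generative model.**  An agent-based lattice simulator grows a
   wild-type population from a single cell, with birth-coupled death
   (d_i = b_i·ψ) and bounded cell pushing: a dividing cell may shift a
   chain of at most *q* neighbours one step toward the nearest empty site
   (q = 0 is boundary-driven growth).  At population round(N_max·n_mut)
   one wild-type cell mutates; its descendants divide at rate
   b_mut = (1+s)·b_WT.

3. **Inference.**  A library of simulated patterns over a grid of
   (s, n_mut, q) is summarised by (τ̃_rr, τ̃_ry, τ̃_yr, τ̃_yy); for an
   observed pattern the posterior over the parameters is the set of the
   n = 100 nearest library entries by log-Euclidean distance, with the
   most abundant parameter triple as point estimate and greedy 95%
   credible sets per parameter.

See `docs/methods.md` for assumptions, parameter defaults, null-model
construction and known limitations.

## Worked example

```python
import numpy as np
from clonefpt import (SimParams, simulate_tumour, downsample,
                      WalkConfig, normalized_cmfpt)

# a tumour with a strongly selected, early, weakly pushed sub-clone
params = SimParams(s=1.0, n_mut=0.01, q=5, n_max=10_000, seed=7)
grid, record = simulate_tumour(params)
print(f"introduced at {record.pop_at_mutation} cells, "
      f"final mutant fraction phi = {record.final_phi:.3f}")

binned = downsample(grid, target_bins=3000)
res = normalized_cmfpt(binned, WalkConfig(walks_per_start=500, seed=7))
print(f"(tau_ry~, tau_ry~/tau_yr~) = "
      f"({res.coords[0]:.2f}, {res.coords[1]:.2f})")
```

prints

```
introduced at 100 cells, final mutant fraction phi = 0.448
(tau_ry~, tau_ry~/tau_yr~) = (119.68, 0.85)
```

The sub-clone grew into a single compact domain holding ~45% of the
colony, strongly segregated from the wild-type cells: a walker on the
pattern needs two orders of magnitude longer to travel red→yellow than on
the randomised null.  The ratio near 1 says the red and yellow domains are
of comparable size.  An iid-random pattern would print ≈ (1.00, 1.00).

The same analyses are available from the shell:

```sh
clonefpt simulate --s 1 --nmut 0.01 --q 5 --nmax 10000 --seed 7 --out-dir out/
clonefpt analyze out/sim_s1_n0.01_q5_seed7.txt --walks 500 --seed 7
clonefpt entropy out/sim_s1_n0.01_q5_seed7.txt
clonefpt build-library --out lib.tsv --reps 100 --nmax 100000
clonefpt infer --library lib.tsv --query analysis.json --n 100
```

Patterns travel as plain text grids (`R`/`Y`/`.` characters) or as
red/yellow rasters (PNG/TIFF) with configurable colour matching; both
round-trip through `read_pattern` / `write_pattern`.

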