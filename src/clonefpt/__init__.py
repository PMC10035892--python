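"""clonefpt: first passage time analysis of two-class tumour cell patterns.

Quantifies the spatial mixing of mutant and wild-type cell populations with
class mean first passage times of random walkers, simulates sub-clonal
growth with an agent-based lattice model (selection, mutation timing, cell
pushing), and infers those growth parameters for an observed pattern by
nearest-neighbour matching against a simulated library.
"""

__version__ = "0.1.0"

from .baselines import (EntropyConfig, MSDResult, mean_shortest_distance,
                        shannon_entropy)
from .cmfpt import (CMFPTResult, TauEstimate, WalkConfig, estimate_cmfpt,
                    exact_cmfpt, normalized_cmfpt, null_cmfpt, walk_graph)
from .growth_sim import (DEFAULT_NMUT_GRID, DEFAULT_Q_GRID, DEFAULT_S_GRID,
                         PushPath, SimParams, SimRecord, SimulationError,
                         TumourState, attempt_division, choose_push_path,
                         simulate_tumour, slice_3d)
from .inference import (Posterior, build_library, infer, load_library,
                        log_euclidean_distance, validate_inference)
from .io import (ColourMap, RegionMask, extract_subregion, make_fixtures,
                 read_pattern, read_text_grid, write_pattern, write_text_grid)
from .patterns import (EMPTY, RED, YELLOW, BinnedPattern, ClassGrid,
                       class_ratio, downsample, generate_centred,
                       generate_clusters, generate_column)

__all__ = [name for name in dir() if not name.startswith("_")]
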