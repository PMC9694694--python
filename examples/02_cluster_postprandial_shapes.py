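"""Group postprandial windows with partial-distance fuzzy C-means.

Builds a labeled set of meal-response windows from three known archetypes,
runs the (nC, m) grid search, and checks the recovered structure against the
ground truth.
"""

import numpy as np

from csarima import ClusterSearchGrid, generate_pp_set, select_clustering

X, labels = generate_pp_set(K=3, n_per_cluster=20, noise_sd=5.0, seed=2,
                            truncate_frac=0.3)
print(f"{X.shape[0]} windows of {X.shape[1]} samples; "
      f"{int(np.isnan(X).any(axis=1).sum())} carry NaN padding")

grid = ClusterSearchGrid(nC_range=(2, 3, 4, 5), m_grid=(1.6, 2.0), restarts=3)
cs = select_clustering(X, grid, seed=0)
print(f"selected nC={cs.n_clusters}, m={cs.fuzzifier}, "
      f"Fukuyama-Sugeno={cs.validity:.0f} (lower is better)")

hard = cs.hard_assignments()
from itertools import permutations
accuracy = max(
    np.mean(np.array(p)[hard] == labels) for p in permutations(range(cs.n_clusters))
)
print(f"hard-assignment accuracy vs ground truth: {accuracy:.0%}")
# the grid search recovers the generating cluster count and memberships are
# nearly crisp when archetypes are well separated relative to the noise
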