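"""Cluster 25-week TTL trajectories with the latent-class mixed model.

Simulates a 105-season sprint cohort with three known periodization
profiles, runs the two-stage model search (AIC within each class count,
BIC across class counts), and compares the recovered classes with the
generating truth.
"""

import numpy as np

from swimtraj import (
    SimulationConfig,
    TrajectoryData,
    model_search,
    normalize_components,
    simulate_cohort,
)

cohort = simulate_cohort(SimulationConfig(n_seasons=105, seed=5))
ttls = [normalize_components(s) for s in cohort.seasons]

best, table = model_search(
    ttls,
    k_range=range(1, 5),
    knot_range=(2, 3, 5),
    re_covariances=("diagonal",),
    re_class_structures=("common",),
    n_starts=3,
    seed=0,
)

print(table[["K", "n_interior_knots", "loglik", "AIC", "BIC", "converged"]]
      .to_string(index=False))
print(f"\nselected: K={best.spec.n_classes}, "
      f"{best.spec.n_interior_knots} interior knots "
      f"(BIC {best.bic:.1f})")
print("estimated class shares:", np.round(best.class_shares, 3),
      "(classes ordered by mean TTL level; generating shares 0.53/0.24/0.23)")
print("mean posterior of assigned class:",
      np.round(best.mean_posterior_by_class, 3))

# agreement with the generating labels, up to class relabeling
from itertools import permutations

acc = max(
    np.mean(np.array([p[c - 1] for c in best.modal_class]) == cohort.true_class)
    for p in permutations(range(1, best.spec.n_classes + 1))
)
print(f"modal classification agreement with truth: {100 * acc:.1f}%")

# The BIC-selected class count matches the three generating profiles;
# each row of the table is one model-search cell, and posterior
# probabilities near 1 mean the profiles are cleanly separated.
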