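"""Quantify one swimmer-season: TTL, variability, progressivity, composition.

Simulates a single-season cohort, then computes the normalized Total
Training Load series and the season-level summary metrics.
"""

import numpy as np

from swimtraj import (
    SimulationConfig,
    intensity_composition,
    normalize_components,
    progressivity,
    relative_performance,
    simulate_cohort,
    weekly_variation,
)

cohort = simulate_cohort(SimulationConfig(n_seasons=1, seed=3))
season = cohort.seasons[0]

ttl = normalize_components(season)
print("weeks before best performance:", ttl.week_index[:5], "...")
print("TTL (%):", np.round(ttl.values[:5], 1), "...")

variation = weekly_variation(ttl)
mean_first, mean_second, delta = progressivity(ttl)
comp = intensity_composition(season)
pr = relative_performance(season.performance_s, season.m10wp_s)

print(f"\nweek-to-week TTL variation: {variation:.1f}%")
print(f"mean TTL weeks 25..13: {mean_first:.1f}%  weeks 12..1: {mean_second:.1f}%  "
      f"delta {delta:+.1f}% "
      f"({'progressive' if delta > 0 else 'degressive'})")
print("in-water intensity split (MHI/SI/EI): "
      + "/".join(f"{100 * p:.0f}%" for p in comp.in_water))
print(f"relative performance Pr: {pr:+.1f}% vs the world top-10 mean "
      "(lower is better)")

# TTL is each week's mean of the five max-normalized training components
# (swim meters at moderate-to-heavy / severe / extreme intensity, dryland
# conditioning and strength minutes), so 100% marks the season's heaviest
# training in every category at once.
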