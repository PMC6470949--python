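"""Synthetic swimmer-season cohorts with known latent-class structure.

No training logs of the original elite cohort are publicly deposited,
so every downstream stage (TTL quantification, latent-class trajectory
fitting, profile characterization) is exercised on simulated cohorts
whose generating truth is known.

The generative model mirrors the latent-class linear mixed model that
the fitting module estimates: season i in class g has latent weekly load

    TTL_i(t) = mu_g(t) + b_i [+ s_i * t] + eps_it,

with mu_g a smooth class-specific mean curve over weeks-before-best-
performance, b_i a subject random intercept, an optional random linear
slope, and iid Gaussian residuals; the latent TTL is clipped to
[0, 100].  Weekly raw training volumes (meters per intensity category,
dryland minutes) are then back-computed so that re-running the TTL
normalization on them reproduces the latent TTL exactly (up to clipping
events, which are counted).

Class archetypes emulate the periodization profiles observed in elite
sprint swimmers: ``long`` (two macrocycles, load peaks ~21 and ~5 weeks
out, progressive), ``balanced`` (two balanced macrocycles, peaks ~19
and ~10 weeks out, degressive) and ``stable_flat`` (flat around 60%
TTL, single late peak).  The control points are hand-chosen fixtures,
not measured data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy.interpolate import CubicSpline

from .loads import (
    SwimmerSeason,
    TrainingWeek,
    fit_lactate_profile,
)

__all__ = [
    "SimulationConfig",
    "SimulatedCohort",
    "archetype_curve",
    "simulate_cohort",
    "simulate_lactate_test",
    "ARCHETYPES",
]


class ConfigurationError(ValueError):
    """Raised when a simulation configuration violates its invariants."""


# Control points (week_before_bp, TTL %) for the named archetype curves.
# Chronological time runs from high week_before_bp down to 1.
_ARCHETYPE_POINTS: dict[str, list[tuple[float, float]]] = {
    # two macrocycles ~14/11 weeks, peaks at weeks 21 and 5, progressive
    "long": [
        (1, 42), (3, 60), (5, 82), (7, 70), (9, 63), (12, 55),
        (15, 50), (18, 62), (21, 78), (23, 64), (25, 46),
    ],
    # two balanced macrocycles, peaks at weeks 19 and 10, degressive
    "balanced": [
        (1, 36), (4, 46), (7, 56), (10, 70), (12, 52), (13, 46),
        (16, 57), (19, 76), (22, 66), (25, 50),
    ],
    # flat profile around 60% with a single modest peak ~8 weeks out
    "stable_flat": [
        (1, 52), (2, 55), (5, 60), (8, 65), (10, 62), (15, 60),
        (20, 62), (25, 58),
    ],
}
ARCHETYPES = tuple(_ARCHETYPE_POINTS)

# in-water (MHI, SI, EI) split of maximal weekly volume per archetype,
# and maximal weekly totals (meters in-water / minutes dryland); chosen
# so mean absolute loads sit in the range reported for elite sprinters
_CLASS_MAX_WATER_M = {"long": 46_000.0, "balanced": 40_000.0, "stable_flat": 52_000.0}
_DEFAULT_MAX_WATER_M = 46_000.0
_MAX_DRYLAND_MIN = 180.0
_I1_SHARE_OF_MHI = 0.48  # <2 mmol/L share within the <=4 mmol/L category
_I4_SHARE_OF_EI = 0.80


def archetype_curve(name: str) -> Callable[[np.ndarray], np.ndarray]:
    """Smooth TTL mean curve (% vs week_before_bp) for a named archetype."""
    try:
        pts = _ARCHETYPE_POINTS[name]
    except KeyError:
        raise ConfigurationError(
            f"unknown archetype {name!r}; choose from {sorted(_ARCHETYPE_POINTS)}"
        ) from None
    x = np.array([p[0] for p in pts], dtype=float)
    y = np.array([p[1] for p in pts], dtype=float)
    spline = CubicSpline(x, y, bc_type="natural")
    return lambda t: np.asarray(spline(np.asarray(t, dtype=float)))


@dataclass
class SimulationConfig:
    """Generating truth for a synthetic cohort.

    ``class_mean_curves`` entries are archetype names or callables
    mapping week-before-BP arrays to TTL %.  ``random_effect_sd`` and
    ``residual_sd`` are on the TTL percent scale.  ``performance_means``
    / ``performance_sds`` give the per-class distribution of relative
    performance Pr (%).  Defaults reproduce the three-profile sprint
    cohort structure: shares 53/24/23%, Pr 6.0+-3.1 / 6.8+-3.5 /
    7.4+-2.9%, and an 88/8/4% MHI/SI/EI in-water intensity split.
    """

    n_seasons: int = 105
    n_weeks: int = 25
    class_proportions: tuple[float, ...] = (0.53, 0.24, 0.23)
    class_mean_curves: tuple = ("long", "balanced", "stable_flat")
    random_effect_sd: float = 6.0
    random_slope_sd: float = 0.0
    residual_sd: float = 4.0
    component_jitter_sd: float = 8.0
    composition_in_water: tuple[float, float, float] = (0.88, 0.08, 0.04)
    composition_dryland: tuple[float, float] = (0.65, 0.35)
    performance_means: tuple[float, ...] = (6.0, 6.8, 7.4)
    performance_sds: tuple[float, ...] = (3.1, 3.5, 2.9)
    distance_class: str = "sprint"
    seed: int = 0

    def __post_init__(self) -> None:
        props = np.asarray(self.class_proportions, dtype=float)
        if abs(props.sum() - 1.0) > 1e-12 or np.any(props <= 0):
            raise ConfigurationError(
                "class_proportions must be positive and sum to 1"
            )
        k = len(props)
        for name, val in (
            ("class_mean_curves", self.class_mean_curves),
            ("performance_means", self.performance_means),
            ("performance_sds", self.performance_sds),
        ):
            if len(val) != k:
                raise ConfigurationError(f"{name} must have length K={k}")
        if self.n_weeks < 4:
            raise ConfigurationError("n_weeks must be >= 4")
        water = np.asarray(self.composition_in_water, dtype=float)
        if abs(water.sum() - 1.0) > 1e-12 or np.any(water < 0):
            raise ConfigurationError("in-water composition must sum to 1")
        dry = np.asarray(self.composition_dryland, dtype=float)
        if abs(dry.sum() - 1.0) > 1e-12 or np.any(dry < 0):
            raise ConfigurationError("dryland composition must sum to 1")
        if min(self.random_effect_sd, self.residual_sd, self.random_slope_sd) < 0:
            raise ConfigurationError("standard deviations must be nonnegative")

    @property
    def n_classes(self) -> int:
        return len(self.class_proportions)

    def curve(self, g: int) -> Callable[[np.ndarray], np.ndarray]:
        c = self.class_mean_curves[g]
        return archetype_curve(c) if isinstance(c, str) else c


@dataclass
class SimulatedCohort:
    """A generated cohort plus its ground truth."""

    seasons: list[SwimmerSeason]
    true_class: np.ndarray  # 1-based class labels
    latent_ttl: np.ndarray  # n_seasons x n_weeks, chronological order
    config: SimulationConfig
    n_clipped: int = 0

    @property
    def n_seasons(self) -> int:
        return len(self.seasons)


_COMPONENT_NAMES = ("MHI", "SI", "EI", "GC", "ST")


def _component_percents(
    ttl: np.ndarray, rng: np.random.Generator, jitter_sd: float
) -> np.ndarray:
    """Split a latent TTL series into 5 normalized component series.

    Returns a (n_weeks, 5) array c with row means equal to ttl (up to
    clipping when 5*TTL < 100 at a spike week), each column reaching
    exactly 100 at its own 'spike' week and staying below elsewhere, so
    re-normalizing reproduces ttl.
    """
    n = len(ttl)
    c = np.tile(ttl[:, None], (1, 5)).astype(float)
    # one spike week per component among the 5 highest-TTL weeks
    order = np.argsort(-ttl, kind="stable")[:5]
    spike_weeks = rng.permutation(order)
    for j, t in enumerate(spike_weeks):
        others = max(0.0, (5.0 * ttl[t] - 100.0) / 4.0)
        c[t, :] = others
        c[t, j] = 100.0
    # zero-sum jitter on non-spike weeks, scaled to stay within [0, 99.5]
    cap = 99.5
    for t in range(n):
        if t in spike_weeks:
            continue
        d = rng.normal(0.0, jitter_sd, size=5)
        d -= d.mean()
        s = 1.0
        for j in range(5):
            if d[j] > 0:
                s = min(s, (cap - ttl[t]) / d[j])
            elif d[j] < 0:
                s = min(s, -ttl[t] / d[j])
        s = max(s, 0.0)
        c[t, :] = ttl[t] + s * d
    return c


def simulate_cohort(config: SimulationConfig) -> SimulatedCohort:
    """Draw a synthetic cohort under the latent-class trajectory model.

    Identical configuration (including seed) yields a bit-identical
    cohort.  Latent TTL values falling outside [0, 100] are clipped and
    counted in ``n_clipped``.
    """
    rng = np.random.default_rng(config.seed)
    k = config.n_classes
    weeks = np.arange(config.n_weeks, 0, -1)  # chronological: 25..1
    curves = [config.curve(g) for g in range(k)]
    mu = np.vstack([np.clip(c(weeks), 0.0, 100.0) for c in curves])

    classes = rng.choice(k, size=config.n_seasons, p=config.class_proportions)
    b = rng.normal(0.0, config.random_effect_sd, size=config.n_seasons)
    slopes = (
        rng.normal(0.0, config.random_slope_sd, size=config.n_seasons)
        if config.random_slope_sd > 0
        else np.zeros(config.n_seasons)
    )
    eps = rng.normal(0.0, config.residual_sd, size=(config.n_seasons, config.n_weeks))
    t_centered = weeks - weeks.mean()
    latent = mu[classes] + b[:, None] + slopes[:, None] * t_centered[None, :] + eps
    n_clipped = int(np.sum((latent < 0) | (latent > 100)))
    latent = np.clip(latent, 0.0, 100.0)

    water_frac = np.asarray(config.composition_in_water)
    dry_frac = np.asarray(config.composition_dryland)
    seasons: list[SwimmerSeason] = []
    for i in range(config.n_seasons):
        g = int(classes[i])
        name = config.class_mean_curves[g]
        max_water = _CLASS_MAX_WATER_M.get(
            name if isinstance(name, str) else "", _DEFAULT_MAX_WATER_M
        )
        maxima = np.concatenate([water_frac * max_water, dry_frac * _MAX_DRYLAND_MIN])
        c = _component_percents(latent[i], rng, config.component_jitter_sd)
        raw = c / 100.0 * maxima[None, :]
        pr = rng.normal(config.performance_means[g], config.performance_sds[g])
        m10wp = 50.0  # reference time (s); only the ratio Pr is meaningful
        perf = m10wp * (1.0 + pr / 100.0)
        season_weeks = [
            TrainingWeek(
                week_before_bp=int(weeks[t]),
                i1_m=raw[t, 0] * _I1_SHARE_OF_MHI,
                i2_m=raw[t, 0] * (1 - _I1_SHARE_OF_MHI),
                i3_m=raw[t, 1],
                i4_m=raw[t, 2] * _I4_SHARE_OF_EI,
                i5_m=raw[t, 2] * (1 - _I4_SHARE_OF_EI),
                gc_min=raw[t, 3],
                st_min=raw[t, 4],
            )
            for t in range(config.n_weeks)
        ]
        seasons.append(
            SwimmerSeason(
                swimmer_id=f"S{i:04d}",
                season_label="sim",
                weeks=season_weeks,
                performance_s=perf,
                m10wp_s=m10wp,
                sex=rng.choice(["F", "M"]),
                age=float(np.round(rng.uniform(15, 30), 1)),
                stroke=rng.choice(["free", "breast", "fly", "back"]),
                distance_class=config.distance_class,
                quarter=rng.choice(["2nd", "3rd"]),
                season_in_study=int(rng.integers(1, 5)),
                season_in_quadrennial=rng.choice(
                    ["post_olympic", "world_championship", "pre_olympic", "olympic"]
                ),
                quadrennial=rng.choice(["1992", "1996", "2000", "2004", "2008"]),
            )
        )
    return SimulatedCohort(
        seasons=seasons,
        true_class=classes + 1,
        latent_ttl=latent,
        config=config,
        n_clipped=n_clipped,
    )


def simulate_lactate_test(
    true_thresholds: tuple[float, float, float],
    n_stages: int = 6,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> list[tuple[float, float]]:
    """Simulate one incremental lactate test (stages of speed, lactate).

    The noise-free lactate curve is exponential in speed piecewise
    between the supplied (v2, v4, v6) thresholds — monotone and convex
    on the log scale — and the threshold speeds themselves are included
    among the stages, so at ``noise_sd=0`` the fitted profile recovers
    the thresholds exactly.  Gaussian noise is added to lactate and
    floored at 0.5 mmol/L.
    """
    v2, v4, v6 = true_thresholds
    if not (v2 < v4 < v6):
        raise ConfigurationError("thresholds must be strictly increasing speeds")
    if n_stages < 3:
        raise ConfigurationError("need at least 3 stages")
    rng = np.random.default_rng(seed)
    speeds = [v2, v4, v6]
    below_step, above_step = 0.08, 0.04
    extra = n_stages - 3
    for j in range(extra):
        if j % 2 == 0:
            speeds.insert(0, speeds[0] - below_step)
        else:
            speeds.append(speeds[-1] + above_step)
    speeds_arr = np.array(speeds)
    # piecewise log-linear anchor curve through (v2,2),(v4,4),(v6,6)
    anchors_v = np.array([v2, v4, v6])
    anchors_l = np.log(np.array([2.0, 4.0, 6.0]))
    loglac = np.empty_like(speeds_arr)
    for i, v in enumerate(speeds_arr):
        if v <= anchors_v[0]:
            slope = (anchors_l[1] - anchors_l[0]) / (anchors_v[1] - anchors_v[0])
            loglac[i] = anchors_l[0] + slope * (v - anchors_v[0])
        elif v >= anchors_v[-1]:
            slope = (anchors_l[2] - anchors_l[1]) / (anchors_v[2] - anchors_v[1])
            loglac[i] = anchors_l[2] + slope * (v - anchors_v[2])
        else:
            loglac[i] = np.interp(v, anchors_v, anchors_l)
    lactate = np.exp(loglac)
    if noise_sd > 0:
        lactate = np.maximum(lactate + rng.normal(0, noise_sd, size=len(lactate)), 0.5)
    return [(float(s), float(l)) for s, l in zip(speeds_arr, lactate)]
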