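"""Training-load quantification for swimmer-seasons.

Implements the four quantification approaches used to summarise a
swimmer's 25 weeks of training before the season's best performance:

1. absolute weekly loads per intensity category,
2. progressivity (first-half vs second-half mean load),
3. intensity distribution as compositional data (with the isometric
   log-ratio transform for downstream multivariate testing),
4. the normalized Total Training Load (TTL) statistic and its
   week-to-week variability.

Swim intensity is zoned from an individual blood-lactate/speed profile
fitted on an incremental 6x200 m test: I1 below 2 mmol/L, I2 from 2 to
4 mmol/L, I3 above 4 up to 6 mmol/L, I4 above 6 mmol/L, I5 maximal
sprinting.  The practical categories are MHI = I1+I2 (moderate-to-heavy,
lactate <= 4), SI = I3 (severe), EI = I4+I5 (extreme), plus the dryland
categories GC (general conditioning) and ST (maximal strength), both in
minutes per week.

Weeks are indexed backwards from the season-best performance:
``week_before_bp = 1`` is the final week before the best swim.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "TrainingWeek",
    "SwimmerSeason",
    "LactateProfile",
    "TTLSeries",
    "IntensityComposition",
    "IN_WATER_CATEGORIES",
    "DRYLAND_CATEGORIES",
    "fit_lactate_profile",
    "classify_speed",
    "aggregate_intensities",
    "relative_performance",
    "normalize_components",
    "weekly_variation",
    "progressivity",
    "intensity_composition",
    "ilr_transform",
    "ilr_inverse",
    "zero_replace",
]

IN_WATER_CATEGORIES = ("MHI", "SI", "EI")
DRYLAND_CATEGORIES = ("GC", "ST")
CATEGORIES_5 = IN_WATER_CATEGORIES + DRYLAND_CATEGORIES
COMPONENTS_7 = ("I1", "I2", "I3", "I4", "I5", "GC", "ST")


class InputError(ValueError):
    """Raised on invalid domain inputs (negative volumes, bad shapes...)."""


@dataclass(frozen=True)
class TrainingWeek:
    """One week of logged training volumes.

    In-water volumes ``i1_m``..``i5_m`` are meters per week in intensity
    zones I1-I5; ``gc_min`` and ``st_min`` are dryland minutes per week.
    """

    week_before_bp: int
    i1_m: float = 0.0
    i2_m: float = 0.0
    i3_m: float = 0.0
    i4_m: float = 0.0
    i5_m: float = 0.0
    gc_min: float = 0.0
    st_min: float = 0.0

    def __post_init__(self) -> None:
        for name in ("i1_m", "i2_m", "i3_m", "i4_m", "i5_m", "gc_min", "st_min"):
            if getattr(self, name) < 0:
                raise InputError(f"negative volume {name}={getattr(self, name)}")


@dataclass
class SwimmerSeason:
    """One swimmer-season: covariates, weekly training log, performance.

    ``performance_s`` is the season-best time in seconds and ``m10wp_s``
    the mean of the year's 10 best world performances for the same event.
    """

    swimmer_id: str
    season_label: str
    weeks: list[TrainingWeek]
    performance_s: float = float("nan")
    m10wp_s: float = float("nan")
    sex: str = ""
    age: float = float("nan")
    stroke: str = ""
    distance_class: str = "sprint"
    quarter: str = ""
    season_in_study: int = 1
    season_in_quadrennial: str = ""
    quadrennial: str = ""

    def __post_init__(self) -> None:
        idx = [w.week_before_bp for w in self.weeks]
        if len(set(idx)) != len(idx):
            raise InputError(
                f"duplicate week_before_bp in season {self.swimmer_id}/{self.season_label}"
            )
        self.weeks = sorted(self.weeks, key=lambda w: -w.week_before_bp)

    @property
    def n_weeks(self) -> int:
        return len(self.weeks)

    @property
    def week_index(self) -> np.ndarray:
        """Week indices, chronological order (largest weeks-before-BP first)."""
        return np.array([w.week_before_bp for w in self.weeks])


@dataclass
class LactateProfile:
    """Fitted blood-lactate vs swimming-speed relationship.

    ``v2``, ``v4``, ``v6`` are the speeds (m/s) at 2, 4 and 6 mmol/L;
    any of them is ``None`` when the curve never reaches that lactate
    within the extrapolation cap.  ``extrapolated`` names the thresholds
    obtained outside the observed speed range.
    """

    stages: list[tuple[float, float]]
    v2: float | None
    v4: float | None
    v6: float | None
    extrapolated: frozenset[str] = field(default_factory=frozenset)

    def thresholds(self) -> tuple[float | None, float | None, float | None]:
        return self.v2, self.v4, self.v6


@dataclass
class TTLSeries:
    """Normalized weekly training-load series for one swimmer-season.

    ``values`` holds the TTL (%) per week, chronological order (week 25
    first); ``components`` the matching normalized component series,
    keyed by category name; ``missing_components`` the categories whose
    season total was zero (dropped from the TTL mean unless the fixed
    denominator was requested).
    """

    week_index: np.ndarray
    values: np.ndarray
    components: dict[str, np.ndarray]
    missing_components: tuple[str, ...] = ()

    def __len__(self) -> int:
        return len(self.values)


@dataclass(frozen=True)
class IntensityComposition:
    """Mean training-intensity distribution of a season.

    ``in_water`` are the (MHI, SI, EI) proportions of mean weekly
    in-water meters; ``dryland`` the (GC, ST) proportions of mean weekly
    dryland minutes.  A block is ``None`` when its season total is zero.
    """

    in_water: tuple[float, float, float] | None
    dryland: tuple[float, float] | None


# ---------------------------------------------------------------------------
# Lactate-test calibration


def _loglin_speed_at(
    speeds: np.ndarray, loglac: np.ndarray, target: float
) -> tuple[float | None, bool]:
    """Speed where the piecewise log-linear interpolant reaches ``target``
    lactate.  Returns (speed, extrapolated_flag); speed is None when the
    crossing lies beyond the extrapolation cap (twice the terminal
    segment's speed range past the terminal stage).
    """
    lt = math.log(target)
    # interior: first upward crossing
    for i in range(len(speeds) - 1):
        lo, hi = loglac[i], loglac[i + 1]
        if lo <= lt <= hi and hi > lo:
            frac = (lt - lo) / (hi - lo)
            return float(speeds[i] + frac * (speeds[i + 1] - speeds[i])), False
        if lo == lt:
            return float(speeds[i]), False
    if loglac[-1] == lt:
        return float(speeds[-1]), False
    if lt < loglac[0]:
        seg = speeds[1] - speeds[0]
        slope = (loglac[1] - loglac[0]) / seg
        if slope <= 0:
            return None, True
        v = speeds[0] + (lt - loglac[0]) / slope
        if v < speeds[0] - 2 * seg:
            return None, True
        return float(v), True
    # above observed range
    seg = speeds[-1] - speeds[-2]
    slope = (loglac[-1] - loglac[-2]) / seg
    if slope <= 0:
        return None, True
    v = speeds[-1] + (lt - loglac[-1]) / slope
    if v > speeds[-1] + 2 * seg:
        return None, True
    return float(v), True


def fit_lactate_profile(stages: Sequence[tuple[float, float]]) -> LactateProfile:
    """Fit the lactate/speed relationship of one incremental test.

    Interpolates log(lactate) piecewise-linearly in speed between
    consecutive stages (monotone and exact at the observed stages) and
    reads off the speeds at 2, 4 and 6 mmol/L.  A crossing outside the
    observed speed range is extrapolated from the terminal segment and
    flagged; a crossing further than twice the terminal segment's speed
    range is reported as a missing threshold.
    """
    if len(stages) < 3:
        raise InputError(f"need >= 3 lactate-test stages, got {len(stages)}")
    speeds = np.asarray([s for s, _ in stages], dtype=float)
    lac = np.asarray([l for _, l in stages], dtype=float)
    if np.any(np.diff(speeds) <= 0):
        raise InputError("stage speeds must be strictly increasing")
    if np.any(lac <= 0):
        raise InputError("stage lactates must be positive")
    loglac = np.log(lac)
    out: dict[float, float | None] = {}
    flags: set[str] = set()
    for target in (2.0, 4.0, 6.0):
        v, extra = _loglin_speed_at(speeds, loglac, target)
        out[target] = v
        if extra and v is not None:
            flags.add(f"v{int(target)}")
    return LactateProfile(
        stages=[(float(s), float(l)) for s, l in stages],
        v2=out[2.0],
        v4=out[4.0],
        v6=out[6.0],
        extrapolated=frozenset(flags),
    )


def apply_speed_correction(
    speed: float,
    set_distance_m: float,
    rest_interval_s: float,
    table: dict[tuple[float, float], float] | None = None,
) -> float:
    """Optional correction of a set's swim speed for set distance and
    rest interval before zoning.

    Training sets swum as short repeats with long rest sustain higher
    speeds at the same metabolic intensity than the continuous test
    swims used for calibration, so practitioners subtract a
    distance/rest-dependent offset.  ``table`` maps
    (set_distance_m, rest_interval_s) to a speed offset in m/s; the
    default is no correction.  Unknown (distance, rest) pairs fall back
    to the uncorrected speed.
    """
    if table is None:
        return speed
    return speed - table.get((set_distance_m, rest_interval_s), 0.0)


def classify_speed(
    speed: float, profile: LactateProfile, is_max_sprint: bool = False
) -> str:
    """Assign a swim speed to an intensity level I1-I5.

    Zone boundaries follow the "from 2 to 4" / "above 4 up to 6"
    convention: a speed exactly at the 4 mmol/L threshold is I2 and one
    exactly at 6 mmol/L is I3.  Maximal sprinting is always I5.
    """
    if is_max_sprint:
        return "I5"
    v2, v4, v6 = profile.v2, profile.v4, profile.v6
    if v2 is None or v4 is None or v6 is None:
        raise InputError("profile has missing thresholds; cannot classify")
    if not (v2 <= v4 <= v6):
        raise InputError("profile thresholds must satisfy v2 <= v4 <= v6")
    if speed < v2:
        return "I1"
    if speed <= v4:
        return "I2"
    if speed <= v6:
        return "I3"
    return "I4"


# ---------------------------------------------------------------------------
# Weekly aggregation and the TTL statistic


def aggregate_intensities(week: TrainingWeek) -> dict[str, float]:
    """Collapse a week's zone volumes into the five practical categories:
    MHI = I1+I2 meters, SI = I3 meters, EI = I4+I5 meters, GC and ST
    dryland minutes.
    """
    return {
        "MHI": week.i1_m + week.i2_m,
        "SI": week.i3_m,
        "EI": week.i4_m + week.i5_m,
        "GC": week.gc_min,
        "ST": week.st_min,
    }


def _component_matrix(season: SwimmerSeason, mode: str) -> tuple[tuple[str, ...], np.ndarray]:
    if mode == "5-category":
        names = CATEGORIES_5
        rows = [
            [agg[c] for c in names]
            for agg in (aggregate_intensities(w) for w in season.weeks)
        ]
    elif mode == "7-component":
        names = COMPONENTS_7
        rows = [
            [w.i1_m, w.i2_m, w.i3_m, w.i4_m, w.i5_m, w.gc_min, w.st_min]
            for w in season.weeks
        ]
    else:
        raise InputError(f"unknown component mode {mode!r}")
    return names, np.asarray(rows, dtype=float)


def relative_performance(performance_s: float, m10wp_s: float) -> float:
    """Relative performance Pr (%) = 100 * (P - M10WP) / M10WP.

    Pr is the percent gap to the year's mean of the 10 best world times
    for the event; lower is better and 0 means matching that reference.
    """
    if performance_s <= 0 or m10wp_s <= 0:
        raise InputError("performance times must be positive")
    return 100.0 * (performance_s - m10wp_s) / m10wp_s


def normalize_components(
    season: SwimmerSeason,
    mode: str = "5-category",
    fixed_denominator: bool = False,
) -> TTLSeries:
    """Compute the normalized TTL series of one season.

    Each component series is rescaled to percent of its own season
    maximum, so every nonzero component reaches exactly 100 in at least
    one week; weekly TTL is the arithmetic mean of the normalized
    components.  A component whose season maximum is zero is set to 0
    and by default dropped from the mean (``fixed_denominator=True``
    keeps the full component count in the denominator instead).
    """
    if season.n_weeks == 0:
        raise InputError("season has no weeks")
    names, raw = _component_matrix(season, mode)
    maxima = raw.max(axis=0)
    norm = np.zeros_like(raw)
    present = maxima > 0
    norm[:, present] = 100.0 * raw[:, present] / maxima[present]
    missing = tuple(n for n, p in zip(names, present) if not p)
    denom = len(names) if fixed_denominator else int(present.sum())
    if denom == 0:
        raise InputError("all components are zero for the whole season")
    ttl = norm[:, present].sum(axis=1) / denom if not fixed_denominator else norm.sum(axis=1) / denom
    return TTLSeries(
        week_index=season.week_index,
        values=ttl,
        components={n: norm[:, j] for j, n in enumerate(names)},
        missing_components=missing,
    )


def weekly_variation(ttl: TTLSeries | np.ndarray) -> float:
    """Mean absolute change in TTL between consecutive weeks (%)."""
    values = ttl.values if isinstance(ttl, TTLSeries) else np.asarray(ttl, dtype=float)
    if len(values) < 2:
        raise InputError("need >= 2 weeks for weekly variation")
    return float(np.mean(np.abs(np.diff(values))))


def progressivity(
    ttl: TTLSeries | SwimmerSeason,
    split: tuple[int, int] = (13, 12),
) -> tuple[float, float, float]:
    """Mean load in the first vs second half of the pre-competition period.

    With the default 25-week window the first half is weeks 25..13
    before the best performance (13 weeks, chronologically earlier) and
    the second half weeks 12..1.  Returns (mean_first, mean_second,
    delta) with delta = mean_second - mean_first; positive delta is
    progressivity, negative is degressivity.
    """
    if isinstance(ttl, SwimmerSeason):
        ttl = normalize_components(ttl)
    n_first, n_second = split
    n = n_first + n_second
    weeks = set(int(w) for w in ttl.week_index)
    if weeks != set(range(1, n + 1)):
        raise InputError(
            f"progressivity needs weeks 1..{n} present, got {sorted(weeks)}"
        )
    by_week = dict(zip((int(w) for w in ttl.week_index), ttl.values))
    first = np.array([by_week[w] for w in range(n, n_second, -1)])
    second = np.array([by_week[w] for w in range(n_second, 0, -1)])
    mean_first = float(first.mean())
    mean_second = float(second.mean())
    return mean_first, mean_second, mean_second - mean_first


def intensity_composition(season: SwimmerSeason) -> IntensityComposition:
    """Season-mean intensity distribution as two compositions.

    The in-water block is (mean MHI, mean SI, mean EI) divided by the
    mean total weekly in-water meters; the dryland block is (mean GC,
    mean ST) over mean total dryland minutes.  A block with zero season
    total is reported as missing (None).
    """
    if season.n_weeks == 0:
        raise InputError("season has no weeks")
    aggs = [aggregate_intensities(w) for w in season.weeks]
    means = {c: float(np.mean([a[c] for a in aggs])) for c in CATEGORIES_5}
    water_total = means["MHI"] + means["SI"] + means["EI"]
    dry_total = means["GC"] + means["ST"]
    in_water = None
    if water_total > 0:
        in_water = (
            means["MHI"] / water_total,
            means["SI"] / water_total,
            means["EI"] / water_total,
        )
    dryland = None
    if dry_total > 0:
        dryland = (means["GC"] / dry_total, means["ST"] / dry_total)
    return IntensityComposition(in_water=in_water, dryland=dryland)


# ---------------------------------------------------------------------------
# Compositional data: isometric log-ratio coordinates


def zero_replace(
    compositions: np.ndarray, delta: float | None = None
) -> np.ndarray:
    """Multiplicative zero replacement for compositional data.

    Zeros are replaced by ``delta`` (default 0.65 times the smallest
    nonzero proportion observed anywhere in the array) and the nonzero
    parts shrunk multiplicatively so every row still sums to 1.
    """
    x = np.atleast_2d(np.asarray(compositions, dtype=float)).copy()
    if np.any(x < 0):
        raise InputError("compositions must be nonnegative")
    zeros = x == 0
    if not zeros.any():
        return x if compositions.ndim > 1 else x[0]
    if delta is None:
        nz = x[x > 0]
        if nz.size == 0:
            raise InputError("all-zero composition")
        delta = 0.65 * float(nz.min())
    for i in range(x.shape[0]):
        z = zeros[i]
        if z.any():
            x[i, z] = delta
            x[i, ~z] *= 1.0 - delta * z.sum()
    x /= x.sum(axis=1, keepdims=True)
    return x if compositions.ndim > 1 else x[0]


def ilr_transform(composition: Sequence[float] | np.ndarray) -> np.ndarray:
    """Isometric log-ratio coordinates of a D-part composition.

    Uses the sequential-binary-partition basis: coordinate j
    (j = 1..D-1) is sqrt(j/(j+1)) * ln(gm(x_1..x_j) / x_{j+1}).  Entries
    must be strictly positive (apply :func:`zero_replace` first); the map
    is an isometry from the Aitchison simplex to Euclidean space.
    """
    x = np.atleast_2d(np.asarray(composition, dtype=float))
    if np.any(x <= 0):
        raise InputError("ilr requires strictly positive parts; zero-replace first")
    logx = np.log(x)
    d = x.shape[1]
    coords = np.empty((x.shape[0], d - 1))
    for j in range(1, d):
        gm_log = logx[:, :j].mean(axis=1)
        coords[:, j - 1] = math.sqrt(j / (j + 1)) * (gm_log - logx[:, j])
    return coords if np.asarray(composition).ndim > 1 else coords[0]


def ilr_inverse(coords: Sequence[float] | np.ndarray) -> np.ndarray:
    """Map ilr coordinates back to the simplex (inverse of ilr_transform)."""
    z = np.atleast_2d(np.asarray(coords, dtype=float))
    d = z.shape[1] + 1
    logx = np.zeros((z.shape[0], d))
    # invert sequentially: coordinate j fixes log x_{j+1} relative to the
    # running geometric mean of the first j parts
    for j in range(1, d):
        gm_log = logx[:, :j].mean(axis=1)
        logx[:, j] = gm_log - z[:, j - 1] / math.sqrt(j / (j + 1))
    x = np.exp(logx)
    x /= x.sum(axis=1, keepdims=True)
    return x if np.asarray(coords).ndim > 1 else x[0]
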