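"""CSV input/output for swimmer-season training data.

All tabular interchange is plain CSV so fixtures stay human-auditable.
Schemas (long format, one row per swimmer-season-week for training):

* training:    swimmer_id, season_label, week_before_bp,
               i1_m, i2_m, i3_m, i4_m, i5_m, gc_min, st_min
* performance: swimmer_id, season_label, performance_s, m10wp_s, sex,
               age, stroke, distance_class, quarter, season_in_study,
               season_in_quadrennial, quadrennial
* lactate:     swimmer_id, test_date, stage, speed_ms, lactate_mmol

Reading is strict: unknown or missing columns and negative volumes are
errors that name the offending file location.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .loads import InputError, SwimmerSeason, TrainingWeek
from .simulate import SimulatedCohort

TRAINING_COLUMNS = [
    "swimmer_id", "season_label", "week_before_bp",
    "i1_m", "i2_m", "i3_m", "i4_m", "i5_m", "gc_min", "st_min",
]
VOLUME_COLUMNS = TRAINING_COLUMNS[3:]
PERFORMANCE_COLUMNS = [
    "swimmer_id", "season_label", "performance_s", "m10wp_s", "sex", "age",
    "stroke", "distance_class", "quarter", "season_in_study",
    "season_in_quadrennial", "quadrennial",
]
LACTATE_COLUMNS = ["swimmer_id", "test_date", "stage", "speed_ms", "lactate_mmol"]


def _check_columns(df: pd.DataFrame, expected: list[str], path) -> None:
    unknown = [c for c in df.columns if c not in expected]
    missing = [c for c in expected if c not in df.columns]
    if unknown:
        raise InputError(f"{path}: unknown column(s) {unknown}")
    if missing:
        raise InputError(f"{path}: missing column(s) {missing}")


def read_training_csv(path, performance_path=None) -> list[SwimmerSeason]:
    """Read a long-format training CSV (optionally joined with a
    performance/covariate CSV) into SwimmerSeason objects."""
    path = Path(path)
    df = pd.read_csv(path)
    _check_columns(df, TRAINING_COLUMNS, path)
    for col in VOLUME_COLUMNS:
        bad = df.index[df[col] < 0]
        if len(bad):
            raise InputError(
                f"{path}: negative {col} at row {int(bad[0]) + 2} "
                f"(value {df.loc[bad[0], col]})"
            )
    perf = None
    if performance_path is not None:
        perf = pd.read_csv(performance_path)
        _check_columns(perf, PERFORMANCE_COLUMNS, performance_path)
        perf = perf.set_index(["swimmer_id", "season_label"])
    seasons = []
    for (sid, lab), grp in df.groupby(["swimmer_id", "season_label"], sort=True):
        weeks = [
            TrainingWeek(
                week_before_bp=int(r.week_before_bp),
                i1_m=float(r.i1_m), i2_m=float(r.i2_m), i3_m=float(r.i3_m),
                i4_m=float(r.i4_m), i5_m=float(r.i5_m),
                gc_min=float(r.gc_min), st_min=float(r.st_min),
            )
            for r in grp.itertuples()
        ]
        kwargs = {}
        if perf is not None:
            try:
                row = perf.loc[(sid, lab)]
            except KeyError:
                raise InputError(
                    f"{performance_path}: no performance row for {sid}/{lab}"
                ) from None
            kwargs = dict(
                performance_s=float(row["performance_s"]),
                m10wp_s=float(row["m10wp_s"]),
                sex=str(row["sex"]),
                age=float(row["age"]),
                stroke=str(row["stroke"]),
                distance_class=str(row["distance_class"]),
                quarter=str(row["quarter"]),
                season_in_study=int(row["season_in_study"]),
                season_in_quadrennial=str(row["season_in_quadrennial"]),
                quadrennial=str(row["quadrennial"]),
            )
        seasons.append(SwimmerSeason(swimmer_id=str(sid), season_label=str(lab),
                                     weeks=weeks, **kwargs))
    return seasons


def write_training_csv(seasons: list[SwimmerSeason], path) -> None:
    rows = []
    for s in seasons:
        for w in s.weeks:
            rows.append({
                "swimmer_id": s.swimmer_id, "season_label": s.season_label,
                "week_before_bp": w.week_before_bp,
                "i1_m": w.i1_m, "i2_m": w.i2_m, "i3_m": w.i3_m,
                "i4_m": w.i4_m, "i5_m": w.i5_m,
                "gc_min": w.gc_min, "st_min": w.st_min,
            })
    pd.DataFrame(rows, columns=TRAINING_COLUMNS).to_csv(path, index=False)


def write_performance_csv(seasons: list[SwimmerSeason], path) -> None:
    rows = [
        {
            "swimmer_id": s.swimmer_id, "season_label": s.season_label,
            "performance_s": s.performance_s, "m10wp_s": s.m10wp_s,
            "sex": s.sex, "age": s.age, "stroke": s.stroke,
            "distance_class": s.distance_class, "quarter": s.quarter,
            "season_in_study": s.season_in_study,
            "season_in_quadrennial": s.season_in_quadrennial,
            "quadrennial": s.quadrennial,
        }
        for s in seasons
    ]
    pd.DataFrame(rows, columns=PERFORMANCE_COLUMNS).to_csv(path, index=False)


def write_cohort(cohort: SimulatedCohort, outdir) -> dict[str, Path]:
    """Write a simulated cohort (training, performance, ground truth)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "training": outdir / "training.csv",
        "performance": outdir / "performance.csv",
        "truth": outdir / "truth.csv",
    }
    write_training_csv(cohort.seasons, paths["training"])
    write_performance_csv(cohort.seasons, paths["performance"])
    pd.DataFrame({
        "season_id": [s.swimmer_id for s in cohort.seasons],
        "true_class": cohort.true_class,
    }).to_csv(paths["truth"], index=False)
    return paths


def read_lactate_csv(path) -> dict[tuple[str, str], list[tuple[float, float]]]:
    """Read lactate-test stages keyed by (swimmer_id, test_date)."""
    path = Path(path)
    df = pd.read_csv(path)
    _check_columns(df, LACTATE_COLUMNS, path)
    out: dict[tuple[str, str], list[tuple[float, float]]] = {}
    for (sid, date), grp in df.groupby(["swimmer_id", "test_date"], sort=True):
        grp = grp.sort_values("stage")
        out[(str(sid), str(date))] = list(
            zip(grp["speed_ms"].astype(float), grp["lactate_mmol"].astype(float))
        )
    return out


def write_ttl_csv(seasons, ttl_series, path) -> None:
    """Season x week TTL matrix (long format)."""
    rows = []
    for s, ttl in zip(seasons, ttl_series):
        for w, v in zip(ttl.week_index, ttl.values):
            rows.append({
                "swimmer_id": s.swimmer_id, "season_label": s.season_label,
                "week_before_bp": int(w), "ttl_pct": v,
            })
    pd.DataFrame(rows).to_csv(path, index=False, float_format="%.10g")
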