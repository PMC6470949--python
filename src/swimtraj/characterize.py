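"""Characterization of periodization profiles.

Given a classified cohort, this module reproduces the group-comparison
layer of the analysis: between-group tests on training metrics (one-way
ANOVA alongside Kruskal-Wallis, with normality and variance-homogeneity
diagnostics deciding which result is marked primary), within-group
paired tests of first-half vs second-half loads, one-way MANOVA on
ilr-transformed intensity compositions (Pillai's trace), covariate
cross-tabs with chi-square tests, and a per-profile summary table
(shares, variability, relative performance, progressivity direction,
peak-load weeks, composition means).

Significance is reported at face value without multiplicity correction
(the analysis is exploratory); Benjamini-Hochberg adjustment is
available but off by default.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.signal import find_peaks

__all__ = [
    "GroupComparison",
    "compare_groups",
    "paired_halves_test",
    "manova_compositions",
    "detect_peak_weeks",
    "summarize_profiles",
    "covariate_crosstab",
    "benjamini_hochberg",
]


@dataclass
class GroupComparison:
    """Parametric and rank-based results of one group comparison.

    ``primary`` names the test preferred by the assumption checks
    (Shapiro-Wilk per group and Levene's test at alpha = 0.05); both
    results are always reported.
    """

    variable: str
    group_sizes: dict
    group_means: dict
    group_sds: dict
    parametric_name: str
    parametric_stat: float
    parametric_p: float
    nonparametric_name: str
    nonparametric_stat: float
    nonparametric_p: float
    normality_ok: bool
    variance_homogeneity_ok: bool
    primary: str
    direction: str = ""
    notes: list = field(default_factory=list)


def _assumption_flags(groups: list[np.ndarray], paired_diffs=None):
    """Shapiro-Wilk normality (per group or on paired differences) and
    Levene homogeneity at alpha = 0.05."""
    alpha = 0.05
    samples = [paired_diffs] if paired_diffs is not None else groups
    normal = True
    for s in samples:
        s = np.asarray(s)
        if len(s) < 3 or np.ptp(s) == 0:
            continue
        if len(s) > 4999:
            s = s[:4999]
        if stats.shapiro(s).pvalue < alpha:
            normal = False
    homo = True
    if paired_diffs is None and len(groups) >= 2:
        if all(np.ptp(g) > 0 for g in groups):
            homo = stats.levene(*groups).pvalue >= alpha
    return normal, homo


def compare_groups(values, labels, variable: str = "") -> GroupComparison:
    """One-way between-group comparison of a season-level metric.

    Computes both the ANOVA F test and the Kruskal-Wallis H test across
    the label groups; groups with fewer than 2 observations are dropped
    with a note.  The assumption-preferred test is marked primary.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    notes = []
    groups, names = [], []
    for lab in pd.unique(labels):
        g = values[labels == lab]
        if len(g) < 2:
            notes.append(f"group {lab!r} excluded (n={len(g)} < 2)")
            continue
        groups.append(g)
        names.append(lab)
    if len(groups) < 2:
        raise ValueError("need >= 2 groups with >= 2 observations each")
    if np.ptp(np.concatenate(groups)) == 0:
        f_stat, f_p = 0.0, 1.0
    else:
        f_stat, f_p = stats.f_oneway(*groups)
        if np.isnan(f_stat):  # zero within- and between-group variance
            f_stat, f_p = 0.0, 1.0
    if np.ptp(np.concatenate(groups)) == 0:
        h_stat, h_p = 0.0, 1.0  # all observations tied
    else:
        try:
            h_stat, h_p = stats.kruskal(*groups)
        except ValueError:
            h_stat, h_p = 0.0, 1.0
    normal, homo = _assumption_flags(groups)
    primary = "anova" if (normal and homo) else "kruskal"
    return GroupComparison(
        variable=variable,
        group_sizes={n: len(g) for n, g in zip(names, groups)},
        group_means={n: float(np.mean(g)) for n, g in zip(names, groups)},
        group_sds={n: float(np.std(g, ddof=1)) for n, g in zip(names, groups)},
        parametric_name="anova",
        parametric_stat=float(f_stat),
        parametric_p=float(f_p),
        nonparametric_name="kruskal",
        nonparametric_stat=float(h_stat),
        nonparametric_p=float(h_p),
        normality_ok=normal,
        variance_homogeneity_ok=homo,
        primary=primary,
        notes=notes,
    )


def paired_halves_test(first_half, second_half, variable: str = "") -> GroupComparison:
    """Within-group paired test of first-half vs second-half means.

    Paired t and Wilcoxon signed-rank on the (second - first)
    differences; direction reports progressivity (load increase toward
    competition) or degressivity.  Degenerate cases (all differences
    equal or zero) are reported with explicit notes instead of unstable
    statistics.
    """
    first = np.asarray(first_half, dtype=float)
    second = np.asarray(second_half, dtype=float)
    if first.shape != second.shape or len(first) < 3:
        raise ValueError("need paired vectors of equal length >= 3")
    diffs = second - first
    notes = []
    mean_d = float(diffs.mean())
    direction = (
        "progressivity" if mean_d > 0 else "degressivity" if mean_d < 0 else "none"
    )
    if np.ptp(diffs) == 0:
        if mean_d == 0:
            t_stat, t_p = 0.0, 1.0
            w_stat, w_p = np.nan, np.nan
            notes.append("all differences zero; signed-rank undefined")
        else:
            sign = "all-positive" if mean_d > 0 else "all-negative"
            t_stat, t_p = np.inf if mean_d > 0 else -np.inf, 0.0
            w_stat, w_p = np.nan, np.nan
            notes.append(f"constant nonzero differences ({sign}); p below machine floor")
        normal = True
    else:
        t_stat, t_p = stats.ttest_rel(second, first)
        nz = diffs[diffs != 0]
        if len(nz) == 0:
            w_stat, w_p = np.nan, np.nan
            notes.append("all differences zero; signed-rank undefined")
        else:
            w_stat, w_p = stats.wilcoxon(nz)
        normal, _ = _assumption_flags([], paired_diffs=diffs)
    primary = "t_paired" if normal else "wilcoxon"
    return GroupComparison(
        variable=variable,
        group_sizes={"pairs": len(first)},
        group_means={"first_half": float(first.mean()), "second_half": float(second.mean())},
        group_sds={"first_half": float(first.std(ddof=1)), "second_half": float(second.std(ddof=1))},
        parametric_name="t_paired",
        parametric_stat=float(t_stat),
        parametric_p=float(t_p),
        nonparametric_name="wilcoxon",
        nonparametric_stat=float(w_stat) if not np.isnan(w_stat) else np.nan,
        nonparametric_p=float(w_p) if not np.isnan(w_p) else np.nan,
        normality_ok=normal,
        variance_homogeneity_ok=True,
        primary=primary,
        direction=direction,
        notes=notes,
    )


def manova_compositions(coords, labels):
    """One-way MANOVA on ilr coordinates across groups.

    Returns (pillai_trace, approx_F, p).  Pillai's trace is computed
    from the between-group (H) and within-group (E) scatter matrices as
    trace(H (H+E)^{-1}) with the standard F approximation; it is
    invariant to the choice of orthonormal log-ratio basis.
    """
    Y = np.atleast_2d(np.asarray(coords, dtype=float))
    if Y.ndim == 1 or Y.shape[1] == 0:
        Y = Y.reshape(len(Y), -1)
    labels = np.asarray(labels)
    names = pd.unique(labels)
    k = len(names)
    n, p = Y.shape
    if k < 2:
        raise ValueError("need >= 2 groups")
    for lab in names:
        if (labels == lab).sum() <= p:
            raise ValueError(
                f"group {lab!r} has n <= {p} ilr coordinates; MANOVA unidentified"
            )
    grand = Y.mean(axis=0)
    H = np.zeros((p, p))
    E = np.zeros((p, p))
    for lab in names:
        Yg = Y[labels == lab]
        mg = Yg.mean(axis=0)
        H += len(Yg) * np.outer(mg - grand, mg - grand)
        R = Yg - mg
        E += R.T @ R
    T = H + E
    try:
        Tinv = np.linalg.solve(T, np.eye(p))
    except np.linalg.LinAlgError as err:
        bad = int(np.argmin(np.linalg.svd(T, compute_uv=False)))
        raise ValueError(
            f"singular total scatter matrix (ilr coordinate {bad} degenerate)"
        ) from err
    pillai = float(np.trace(H @ Tinv))
    # Pillai F approximation
    s = min(p, k - 1)
    m = (abs(p - (k - 1)) - 1) / 2.0
    nn = (n - k - p - 1) / 2.0
    df1 = s * (2 * m + s + 1)
    df2 = s * (2 * nn + s + 1)
    if df2 <= 0 or s - pillai <= 0:
        f_stat, p_val = np.inf, 0.0
    else:
        f_stat = (pillai / (s - pillai)) * (df2 / df1)
        p_val = float(stats.f.sf(f_stat, df1, df2))
    return pillai, float(f_stat), p_val


def detect_peak_weeks(
    week_index,
    mean_ttl,
    smooth_window: int = 3,
    min_prominence: float = 2.0,
    min_separation: int = 3,
    top: int = 2,
):
    """Peak-load weeks of a class mean trajectory.

    The trajectory (indexed by weeks before best performance, in
    chronological order) is smoothed with a centered moving average,
    local maxima are found with the given prominence and separation, and
    the ``top`` highest peaks are returned as weeks-before-BP in
    chronological order (earliest macrocycle first).
    """
    weeks = np.asarray(week_index, dtype=float)
    y = np.asarray(mean_ttl, dtype=float)
    order = np.argsort(-weeks)
    weeks, y = weeks[order], y[order]
    if smooth_window > 1:
        kernel = np.ones(smooth_window) / smooth_window
        pad = smooth_window // 2
        yp = np.pad(y, pad, mode="edge")
        y_s = np.convolve(yp, kernel, mode="valid")
    else:
        y_s = y
    idx, _ = find_peaks(y_s, prominence=min_prominence, distance=min_separation)
    if len(idx) == 0:
        return []
    heights = y_s[idx]
    keep = idx[np.argsort(-heights, kind="stable")[:top]]
    return [int(weeks[i]) for i in sorted(keep)]


def covariate_crosstab(labels, covariate, name: str = ""):
    """Cross-tab of class assignment vs a categorical covariate with a
    chi-square independence test.  Returns (table, chi2, p, warning) —
    warning is set when any expected count is below 5."""
    table = pd.crosstab(pd.Series(covariate, name=name or "covariate"),
                        pd.Series(labels, name="class"))
    chi2, p, _, expected = stats.chi2_contingency(table.values)
    warning = bool((expected < 5).any())
    return table, float(chi2), float(p), warning


def summarize_profiles(
    modal_class,
    weekly_variations,
    pr_values,
    progressivity_deltas,
    class_mean_trajectories: pd.DataFrame,
    compositions=None,
    peak_kwargs: dict | None = None,
) -> pd.DataFrame:
    """Per-profile summary table.

    One row per class: share of seasons, mean +- SD week-to-week TTL
    variation, mean +- SD relative performance Pr, progressivity label
    (sign of the mean first-to-second-half delta), the top peak-load
    weeks of the weighted class-mean trajectory, and mean in-water
    composition (when provided).  ``class_mean_trajectories`` is the
    tidy frame from :func:`swimtraj.lcmm.weighted_class_means`.
    """
    modal = np.asarray(modal_class)
    var = np.asarray(weekly_variations, dtype=float)
    pr = np.asarray(pr_values, dtype=float)
    delta = np.asarray(progressivity_deltas, dtype=float)
    peak_kwargs = peak_kwargs or {}
    rows = []
    classes = np.unique(modal)
    n = len(modal)
    for g in classes:
        members = modal == g
        traj = class_mean_trajectories[class_mean_trajectories["class"] == g]
        peaks = detect_peak_weeks(
            traj["week_before_bp"].values, traj["mean"].values, **peak_kwargs
        )
        mean_delta = float(delta[members].mean())
        row = {
            "class": int(g),
            "share": float(members.mean()),
            "n": int(members.sum()),
            "variation_mean": float(var[members].mean()),
            "variation_sd": float(var[members].std(ddof=1)) if members.sum() > 1 else np.nan,
            "pr_mean": float(pr[members].mean()),
            "pr_sd": float(pr[members].std(ddof=1)) if members.sum() > 1 else np.nan,
            "progressivity_delta": mean_delta,
            "progressivity": "progressivity" if mean_delta > 0 else "degressivity",
            "peak_weeks": peaks,
        }
        if compositions is not None:
            comp = np.asarray([compositions[i] for i in np.flatnonzero(members)])
            for j, part in enumerate(("MHI", "SI", "EI")[: comp.shape[1]]):
                row[f"prop_{part}"] = float(comp[:, j].mean())
        rows.append(row)
    out = pd.DataFrame(rows)
    assert abs(out["share"].sum() - 1.0) < 1e-9 or len(classes) < len(set(modal))
    return out


def benjamini_hochberg(p_values):
    """Benjamini-Hochberg adjusted p-values (optional; off by default in
    every pipeline stage)."""
    p = np.asarray(p_values, dtype=float)
    n = len(p)
    order = np.argsort(p)
    adj = np.empty(n)
    running = 1.0
    for rank_from_end, i in enumerate(order[::-1]):
        rank = n - rank_from_end
        running = min(running, p[i] * n / rank)
        adj[i] = running
    return adj
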