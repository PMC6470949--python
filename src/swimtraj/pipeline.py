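"""End-to-end pipeline: simulate/load -> quantify -> fit -> characterize.

A single root seed is split into named per-stage substreams (simulate,
fit, search) so stages are independently reproducible; identical
configuration and seed produce byte-identical artifacts, summarized by
a manifest JSON carrying the config hash and every output path.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as sio
from .loads import (
    InputError,
    intensity_composition,
    normalize_components,
    progressivity,
    relative_performance,
    weekly_variation,
    ilr_transform,
    zero_replace,
)
from .lcmm import TrajectoryData, fit as lcmm_fit, model_search, weighted_class_means
from .characterize import (
    compare_groups,
    covariate_crosstab,
    manova_compositions,
    paired_halves_test,
    summarize_profiles,
)
from .simulate import SimulationConfig, simulate_cohort

log = logging.getLogger("swimtraj")

__all__ = ["PipelineConfig", "run_pipeline", "stage_seed"]


def stage_seed(root_seed: int, stage: str) -> int:
    """Derive a per-stage substream seed (< 2^31) from the root seed."""
    h = hashlib.sha256(f"{root_seed}:{stage}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31)


@dataclass
class PipelineConfig:
    """Configuration of one end-to-end run.

    Either ``training_csv`` (+ ``performance_csv``) point at input data,
    or ``simulate`` holds a :class:`SimulationConfig` (or a plain dict of
    its fields).  The model-search grid is bounded by ``k_range`` and
    ``knot_values`` within (K 1..5, interior knots 1..15).
    """

    outdir: str = "swimtraj_out"
    seed: int = 0
    training_csv: str | None = None
    performance_csv: str | None = None
    simulate: dict | None = None
    distance_class: str = "all"
    n_weeks: int = 25
    component_mode: str = "5-category"
    k_range: tuple[int, int] = (1, 3)
    knot_values: tuple[int, ...] = (2, 3)
    n_starts: int = 4
    max_em_iter: int = 300
    max_polish_iter: int = 30
    peak_kwargs: dict = field(default_factory=dict)

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        path = Path(path)
        with open(path) as fh:
            raw = yaml.safe_load(fh) if path.suffix in (".yml", ".yaml") else json.load(fh)
        return cls(**raw)

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _load_seasons(config: PipelineConfig):
    if config.simulate is not None:
        sim = config.simulate
        if isinstance(sim, dict):
            sim = SimulationConfig(**{**sim, "seed": stage_seed(config.seed, "simulate")})
        cohort = simulate_cohort(sim)
        return cohort.seasons, cohort
    if config.training_csv is None:
        raise InputError("config needs either training_csv or simulate")
    seasons = sio.read_training_csv(config.training_csv, config.performance_csv)
    if config.distance_class != "all":
        seasons = [s for s in seasons if s.distance_class == config.distance_class]
    return seasons, None


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the full analysis and write every artifact plus a manifest.

    Returns the manifest dict.  Raises on malformed inputs, including a
    validation error naming any season whose week count differs from
    ``config.n_weeks``.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seasons, cohort = _load_seasons(config)
    if not seasons:
        raise InputError("no seasons to analyse")
    bad = [f"{s.swimmer_id}/{s.season_label} ({s.n_weeks} weeks)"
           for s in seasons if s.n_weeks != config.n_weeks]
    if bad:
        raise InputError(
            f"seasons with week count != {config.n_weeks}: " + ", ".join(bad)
        )
    artifacts: dict[str, str] = {}

    if cohort is not None:
        for name, p in sio.write_cohort(cohort, outdir / "cohort").items():
            artifacts[f"cohort_{name}"] = str(p)

    # --- quantify -----------------------------------------------------
    ttls = [normalize_components(s, mode=config.component_mode) for s in seasons]
    for s, t in zip(seasons, ttls):
        if t.missing_components:
            log.warning("season %s/%s: zero component(s) %s dropped from TTL",
                        s.swimmer_id, s.season_label, t.missing_components)
    sio.write_ttl_csv(seasons, ttls, outdir / "ttl.csv")
    artifacts["ttl"] = str(outdir / "ttl.csv")

    metrics = []
    compositions = []
    for s, t in zip(seasons, ttls):
        comp = intensity_composition(s)
        compositions.append(comp)
        mean_first, mean_second, delta = progressivity(t)
        pr = (
            relative_performance(s.performance_s, s.m10wp_s)
            if s.performance_s > 0 and s.m10wp_s > 0
            else np.nan
        )
        row = {
            "swimmer_id": s.swimmer_id, "season_label": s.season_label,
            "pr_pct": pr, "weekly_variation": weekly_variation(t),
            "ttl_mean_first_half": mean_first, "ttl_mean_second_half": mean_second,
            "progressivity_delta": delta,
        }
        if comp.in_water is not None:
            row.update(zip(("prop_mhi", "prop_si", "prop_ei"), comp.in_water))
        if comp.dryland is not None:
            row.update(zip(("prop_gc", "prop_st"), comp.dryland))
        metrics.append(row)
    metrics_df = pd.DataFrame(metrics)
    metrics_df.to_csv(outdir / "metrics.csv", index=False, float_format="%.10g")
    artifacts["metrics"] = str(outdir / "metrics.csv")

    desc = metrics_df.describe().reset_index()
    desc.to_csv(outdir / "sample_description.csv", index=False, float_format="%.10g")
    artifacts["sample_description"] = str(outdir / "sample_description.csv")

    # --- fit ----------------------------------------------------------
    k_lo, k_hi = config.k_range
    best, table = model_search(
        ttls,
        k_range=range(k_lo, k_hi + 1),
        knot_range=tuple(config.knot_values),
        re_covariances=("diagonal",),
        re_class_structures=("common",),
        n_starts=config.n_starts,
        seed=stage_seed(config.seed, "fit"),
        max_em_iter=config.max_em_iter,
        max_polish_iter=config.max_polish_iter,
    )
    table.to_csv(outdir / "search_table.csv", index=False, float_format="%.10g")
    artifacts["search_table"] = str(outdir / "search_table.csv")

    fit_json = {
        "spec": asdict(best.spec) if hasattr(best.spec, "__dataclass_fields__") else vars(best.spec),
        "loglik": best.loglik, "n_params": best.n_params,
        "aic": best.aic, "bic": best.bic, "converged": bool(best.converged),
        "pi": best.params.pi.tolist(),
        "beta": best.params.beta.tolist(),
        "B": best.params.B.tolist(),
        "w": best.params.w.tolist(),
        "sigma": best.params.sigma,
        "mean_posterior_by_class": best.mean_posterior_by_class.tolist(),
        "class_shares": best.class_shares.tolist(),
    }
    with open(outdir / "fit.json", "w") as fh:
        json.dump(fit_json, fh, indent=2)
    artifacts["fit"] = str(outdir / "fit.json")

    post_df = pd.DataFrame(
        best.posterior,
        columns=[f"class_{g + 1}" for g in range(best.posterior.shape[1])],
    )
    post_df.insert(0, "swimmer_id", [s.swimmer_id for s in seasons])
    post_df.insert(1, "season_label", [s.season_label for s in seasons])
    post_df["modal_class"] = best.modal_class
    post_df.to_csv(outdir / "posterior.csv", index=False, float_format="%.12g")
    artifacts["posterior"] = str(outdir / "posterior.csv")

    data = TrajectoryData.from_ttl(ttls, best.spec)
    class_means = weighted_class_means(data, best.posterior)
    class_means.to_csv(outdir / "class_means.csv", index=False, float_format="%.10g")
    artifacts["class_means"] = str(outdir / "class_means.csv")

    # --- characterize -------------------------------------------------
    labels = best.modal_class
    water_props = np.array(
        [c.in_water if c.in_water else (np.nan,) * 3 for c in compositions]
    )
    summary = summarize_profiles(
        labels,
        metrics_df["weekly_variation"].values,
        metrics_df["pr_pct"].values,
        metrics_df["progressivity_delta"].values,
        class_means,
        compositions=water_props,
        peak_kwargs=config.peak_kwargs,
    )
    summary.to_csv(outdir / "profile_summary.csv", index=False, float_format="%.10g")
    artifacts["profile_summary"] = str(outdir / "profile_summary.csv")

    tests = []
    if len(np.unique(labels)) >= 2:
        for var in ("pr_pct", "weekly_variation", "progressivity_delta"):
            vals = metrics_df[var].values
            ok = ~np.isnan(vals)
            if ok.sum() >= 4:
                gc = compare_groups(vals[ok], labels[ok], variable=var)
                tests.append(_comparison_row(gc, kind="between_groups"))
        for g in np.unique(labels):
            sub = metrics_df[labels == g]
            if len(sub) >= 3:
                ph = paired_halves_test(
                    sub["ttl_mean_first_half"].values,
                    sub["ttl_mean_second_half"].values,
                    variable=f"ttl_halves_class_{g}",
                )
                tests.append(_comparison_row(ph, kind="paired_halves"))
        ok = ~np.isnan(water_props).any(axis=1)
        counts = pd.Series(labels[ok]).value_counts()
        if ok.sum() >= 6 and (counts > 2).all():
            coords = ilr_transform(zero_replace(water_props[ok]))
            try:
                pillai, f_stat, p = manova_compositions(coords, labels[ok])
                tests.append({
                    "variable": "in_water_composition_ilr", "kind": "manova",
                    "test": "pillai", "statistic": pillai, "p": p,
                    "primary": True, "detail": f"approx F={f_stat:.4g}",
                })
            except ValueError as err:
                log.warning("composition MANOVA skipped: %s", err)
    pd.DataFrame(tests).to_csv(outdir / "tests.csv", index=False, float_format="%.10g")
    artifacts["tests"] = str(outdir / "tests.csv")

    crosstabs = []
    for cov_name in ("sex", "quadrennial", "season_in_quadrennial"):
        values = [getattr(s, cov_name) for s in seasons]
        if len(set(values)) < 2 or len(np.unique(labels)) < 2:
            continue
        tab, chi2, p, warn = covariate_crosstab(labels, values, name=cov_name)
        long = tab.reset_index().melt(id_vars=cov_name, var_name="class", value_name="n")
        long["covariate"] = cov_name
        long["chi2"] = chi2
        long["p"] = p
        long["low_expected_warning"] = warn
        long = long.rename(columns={cov_name: "level"})
        crosstabs.append(long)
    if crosstabs:
        pd.concat(crosstabs, ignore_index=True).to_csv(
            outdir / "covariate_crosstabs.csv", index=False, float_format="%.10g"
        )
        artifacts["covariate_crosstabs"] = str(outdir / "covariate_crosstabs.csv")

    manifest = {
        "config": asdict(config),
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "n_seasons": len(seasons),
        "selected_K": int(best.spec.n_classes),
        "artifacts": artifacts,
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return manifest


def _comparison_row(gc, kind: str) -> dict:
    return {
        "variable": gc.variable, "kind": kind,
        "test": gc.primary,
        "statistic": gc.parametric_stat if gc.primary in ("anova", "t_paired")
        else gc.nonparametric_stat,
        "p": gc.parametric_p if gc.primary in ("anova", "t_paired")
        else gc.nonparametric_p,
        "primary": True,
        "detail": (
            f"{gc.parametric_name}={gc.parametric_stat:.6g} (p={gc.parametric_p:.4g}); "
            f"{gc.nonparametric_name}={gc.nonparametric_stat:.6g} "
            f"(p={gc.nonparametric_p:.4g}); direction={gc.direction}"
        ),
    }
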