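"""Orchestration: run the full analysis on a trap table and write artifacts.

Stages: alpha metrics (+ per distance x season summaries), four-scale beta
dispersion per season, per transect x season nestedness and modularity with
fixed-margin null ensembles, seasonal D-value permutation comparisons, and
Benjamini-Hochberg adjustment of the structure p-value families.  Mixed
models are *not* fitted here; instead a model-ready long table (response,
distance factor, season, transect, sample-point nesting) is exported so any
external mixed-model tool can pick it up.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from statsmodels.stats.multitest import multipletests

from . import __version__
from .beta import dispersion_long_table, multiscale_dispersion
from .community import (TrapTable, build_community_matrix,
                        build_interaction_matrices, read_trap_table,
                        write_trap_table)
from .diversity import alpha_summary, alpha_table
from .errors import ConfigurationError, ValidationError
from .structure import (AnnealSchedule, _null_wins, modularity_significance,
                        patefield_null, seasonal_comparison, wine)
from .synthetic import GeneratorConfig, generate_survey

logger = logging.getLogger(__name__)

ALL_STAGES = ("alpha", "beta", "structure", "seasonal")


@dataclass
class RunConfig:
    """Configuration of one pipeline run."""

    input_path: str | None = None
    generator: GeneratorConfig | None = None
    output_dir: str = "piosphere_run"
    log_base: float = 10.0
    n_null_draws: int = 1000
    n_permutations: int = 9999
    restarts: int = 10
    schedule: AnnealSchedule = field(default_factory=AnnealSchedule)
    alpha_level: float = 0.05
    seed: int = 0
    stages: tuple[str, ...] = ALL_STAGES

    def validate(self) -> None:
        if (self.input_path is None) == (self.generator is None):
            raise ConfigurationError("exactly one of input_path / generator required")
        if not 0.0 < self.alpha_level < 1.0:
            raise ConfigurationError("alpha_level must be in (0, 1)")
        for name in ("n_null_draws", "n_permutations", "restarts"):
            if getattr(self, name) < 1:
                raise ConfigurationError(f"{name} must be >= 1")
        unknown = set(self.stages) - set(ALL_STAGES)
        if unknown:
            raise ConfigurationError(f"unknown stage(s): {sorted(unknown)}")
        if "seasonal" in self.stages and "structure" not in self.stages:
            raise ConfigurationError("seasonal stage requires the structure stage")


def benjamini_hochberg(p_values, alpha: float = 0.05):
    """Step-up FDR control; returns (reject flags, adjusted p-values).

    Adjusted p_i = min over j >= rank(i) of m * p_(j) / j, capped at 1.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size and ((p < 0) | (p > 1)).any():
        raise ValidationError("p-values must lie in [0, 1]")
    if not 0.0 < alpha < 1.0:
        raise ValidationError("alpha must be in (0, 1)")
    if p.size == 0:
        return np.array([], dtype=bool), p
    reject, p_adj, _, _ = multipletests(p, alpha=alpha, method="fdr_bh")
    return reject, p_adj


def run_pipeline(config: RunConfig) -> Path:
    """Execute the configured stages; returns the run directory.

    Every random draw derives from ``config.seed`` through a SeedSequence
    tree recorded in the manifest, so a rerun with the same config is
    numerically identical.
    """
    config.validate()
    t_start = time.time()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    timings: dict[str, float] = {}
    diagnostics: dict[str, object] = {}

    if config.generator is not None:
        table = generate_survey(config.generator)
        write_trap_table(table, out / "trap_table.csv")
        source = {"generator": _jsonable(asdict(config.generator))}
    else:
        table = read_trap_table(config.input_path)
        source = {"input_path": str(config.input_path)}
    seasons = [s for s in table.design.seasons
               if s in set(table.records["season"].unique())]

    ss = np.random.SeedSequence(config.seed)
    seed_null, seed_mod, seed_perm = (int(c.generate_state(1)[0]) & 0x7FFFFFFF
                                      for c in ss.spawn(3))

    stage = "alpha"
    if stage in config.stages:
        t0 = time.time()
        frames = []
        for season in seasons:
            cm = build_community_matrix(table, level="trap", season_filter=season)
            frames.append(alpha_table(cm))
        alpha = pd.concat(frames)
        alpha.to_csv(out / "alpha.csv", index_label="sample")
        alpha_summary(alpha).to_csv(out / "summary_alpha.csv", index=False)
        diagnostics["n_empty_traps"] = int(alpha["empty_sample"].sum())
        timings[stage] = time.time() - t0

    if "beta" in config.stages:
        t0 = time.time()
        all_results = []
        excluded_by_season = {}
        for season in seasons:
            results = multiscale_dispersion(table, season, log_base=config.log_base)
            all_results.extend(results)
            excluded_by_season[season] = results[0].n_excluded_empty
            for r in results:
                r.table.to_csv(out / f"dispersion_{r.scale}_{season}.csv", index=False)
        long = dispersion_long_table(all_results)
        long.to_csv(out / "dispersion_long.csv", index=False)
        disp_summary = (
            long.groupby(["scale", "season"])["distance"]
            .agg(mean="mean", sd="std", n="count").reset_index()
        )
        disp_summary["se"] = disp_summary["sd"] / np.sqrt(disp_summary["n"])
        disp_summary.to_csv(out / "summary_dispersion.csv", index=False)
        diagnostics["beta_excluded_empty"] = excluded_by_season
        diagnostics["beta_clamped"] = int(sum(r.n_clamped for r in all_results))
        timings["beta"] = time.time() - t0

    structure_rows: list[dict] = []
    nulls_by_key: dict[tuple[int, str], dict[str, np.ndarray]] = {}
    obs_by_key: dict[tuple[int, str], dict[str, float]] = {}
    if "structure" in config.stages:
        t0 = time.time()
        mats = build_interaction_matrices(table)
        null_ss = np.random.SeedSequence(seed_null).spawn(len(mats))
        mod_ss = np.random.SeedSequence(seed_mod).spawn(len(mats))
        for i, im in enumerate(mats):
            key = (im.transect, im.season)
            ens = patefield_null(im, n_draws=config.n_null_draws,
                                 seed=int(null_ss[i].generate_state(1)[0]) & 0x7FFFFFFF)
            nest = wine(im, ens)
            mod = modularity_significance(
                im, ens, restarts=config.restarts,
                seed=int(mod_ss[i].generate_state(1)[0]) & 0x7FFFFFFF,
                schedule=config.schedule)
            nulls_by_key[key] = {"win": _null_wins(im.values, ens), "Q": mod.null_Q}
            obs_by_key[key] = {"win": nest.win_observed, "Q": mod.Q}
            structure_rows.append({
                "transect": im.transect, "season": im.season,
                "statistic": "nestedness", "observed": nest.win_observed,
                "null_mean": nest.win_null_mean, "normalized": nest.wine,
                "z": nest.z_score, "p": nest.p_value})
            structure_rows.append({
                "transect": im.transect, "season": im.season,
                "statistic": "modularity", "observed": mod.Q,
                "null_mean": float(mod.null_Q.mean()),
                "normalized": mod.Q, "z": mod.z_score, "p": mod.p_value,
                "n_modules": mod.n_modules})
            modules = pd.DataFrame({
                "node": list(im.counts.index) + [str(c) for c in im.counts.columns],
                "mode": ["species"] * len(im.counts.index)
                        + ["distance"] * len(im.counts.columns),
                "module": list(mod.row_modules) + list(mod.column_modules)})
            modules.to_csv(out / f"modules_t{im.transect}_{im.season}.csv", index=False)
        struct = pd.DataFrame(structure_rows)
        for stat in struct["statistic"].unique():
            mask = struct["statistic"] == stat
            _, p_adj = benjamini_hochberg(struct.loc[mask, "p"].to_numpy(),
                                          config.alpha_level)
            struct.loc[mask, "p_adj"] = p_adj
        struct.to_csv(out / "structure_results.csv", index=False)
        timings["structure"] = time.time() - t0

    if "seasonal" in config.stages and len(seasons) == 2:
        t0 = time.time()
        wet, dry = seasons[0], seasons[1]
        perm_ss = np.random.SeedSequence(seed_perm).spawn(
            2 * len({k[0] for k in obs_by_key}))
        rows = []
        i = 0
        for transect in sorted({k[0] for k in obs_by_key}):
            if (transect, wet) not in obs_by_key or (transect, dry) not in obs_by_key:
                continue
            for stat_key, stat_name in (("win", "nestedness"), ("Q", "modularity")):
                cmp = seasonal_comparison(
                    obs_by_key[(transect, wet)][stat_key],
                    nulls_by_key[(transect, wet)][stat_key],
                    obs_by_key[(transect, dry)][stat_key],
                    nulls_by_key[(transect, dry)][stat_key],
                    n_permutations=config.n_permutations,
                    seed=int(perm_ss[i].generate_state(1)[0]) & 0x7FFFFFFF)
                i += 1
                rows.append({"transect": transect, "statistic": stat_name,
                             "D_wet_mean": float(cmp.D_wet.mean()),
                             "D_dry_mean": float(cmp.D_dry.mean()),
                             "difference": cmp.statistic, "p": cmp.p_value,
                             "n_permutations": cmp.n_permutations})
        pd.DataFrame(rows).to_csv(out / "seasonal_comparisons.csv", index=False)
        timings["seasonal"] = time.time() - t0

    _write_model_ready(table, out, config, seasons)

    manifest = {
        "package": "piosphere", "version": __version__,
        "config": _jsonable({**asdict(config), **source}),
        "seed": config.seed,
        "stage_seeds": {"null": seed_null, "modularity": seed_mod,
                        "permutation": seed_perm},
        "versions": _versions(),
        "diagnostics": diagnostics,
        "timings_s": {k: round(v, 3) for k, v in timings.items()},
        "artifacts": sorted(p.name for p in out.iterdir() if p.is_file()),
        "total_s": round(time.time() - t_start, 3),
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return out


def _write_model_ready(table: TrapTable, out: Path, config: RunConfig,
                       seasons: list[str]) -> None:
    """Long table ready for external mixed-model fitting: one row per trap x
    season with responses and the nesting factors."""
    if "alpha" not in config.stages:
        return
    frames = []
    for season in seasons:
        cm = build_community_matrix(table, level="trap", season_filter=season)
        frames.append(alpha_table(cm))
    long = pd.concat(frames).reset_index(names="sample")
    cols = ["sample", "transect", "distance_m", "sample_point", "trap", "season",
            "abundance", "richness", "effective_species"]
    long[cols].to_csv(out / "model_ready.csv", index=False)


def _versions() -> dict[str, str]:
    import scipy
    import skbio
    import statsmodels
    return {"numpy": np.__version__, "scipy": scipy.__version__,
            "pandas": pd.__version__, "scikit-bio": skbio.__version__,
            "statsmodels": statsmodels.__version__}


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, Path):
        return str(obj)
    return obj


def run_config_from_yaml(path) -> RunConfig:
    """Load a RunConfig (and nested generator config) from YAML."""
    from .synthetic import config_from_yaml  # noqa: F401  (shared loader style)
    from .community import SurveyDesign

    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    gen = raw.pop("generator", None)
    if gen is not None:
        design = gen.pop("design", {})
        if "distance_categories_m" in design:
            design["distance_categories_m"] = tuple(design["distance_categories_m"])
        if "seasons" in design:
            design["seasons"] = tuple(design["seasons"])
        if "module_partition" in gen:
            gen["module_partition"] = tuple(tuple(b) for b in gen["module_partition"])
        gen = GeneratorConfig(design=SurveyDesign(**design), **gen)
    if "schedule" in raw:
        raw["schedule"] = AnnealSchedule(**raw["schedule"])
    if "stages" in raw:
        raw["stages"] = tuple(raw["stages"])
    cfg = RunConfig(generator=gen, **raw)
    cfg.validate()
    return cfg
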