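"""End-to-end analysis pipeline: simulate/load -> metrics -> densities ->
variance-partitioning repeatability -> reports.

The pipeline is a pure function of (input files, configuration, seed):
re-running with the same inputs reproduces every output. Analyses mirror
the two standard scopes of repeatability studies of grouped behaviour:

* **across-context** — first trial in each context, the foraging trial
  split at the food-depletion frame into pre/post, giving a four-level
  context fixed factor; group identity (and individual identity for
  individual-level responses) as random intercepts;
* **within-context** — all trials of the repeatedly tested contexts
  (foraging pre-depletion, cover), trial number as the fixed factor.
"""

from __future__ import annotations

import dataclasses
import glob as _glob
import logging
import os
import time
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import yaml

from . import density as dens
from . import metrics as met
from . import repeatability as rep
from . import synthetic as syn
from . import trajectory as tra

log = logging.getLogger("shoalkit")

FLOAT_FMT = "%.6g"


class ConfigError(ValueError):
    """Bad pipeline configuration (exit code 2)."""


class DataError(ValueError):
    """Bad or missing input data (exit code 3)."""


@dataclass
class MCMCSettings:
    chains: int = 5
    iters: int = 20_000
    burnin: int = 2_000
    thin: int = 10


@dataclass
class PipelineConfig:
    """Everything a pipeline run depends on, resolvable from one YAML file."""

    out_dir: str = "results"
    seed: int = 0
    # input: either simulate an experiment or read files
    simulate: bool = True
    n_groups: int = 25
    trials_per_context: dict = field(
        default_factory=lambda: dict(syn.DEFAULT_TRIALS_PER_CONTEXT)
    )
    sim: syn.SimConfig = field(default_factory=syn.SimConfig)
    trajectories: str | None = None   # glob for trajectory CSVs
    metadata: str | None = None       # metadata YAML
    # smoothing
    smoothing_window: int = 15
    smoothing_polyorder: int = 3
    max_gap: int = 15
    # metric thresholds
    min_step_mm: float = met.DEFAULT_MIN_STEP_MM
    min_centroid_speed_cm_s: float = met.DEFAULT_MIN_CENTROID_SPEED_CM_S
    # analysis scope
    first_trial_only: bool = True
    all_trials: bool = False          # also run the all-trials variant
    cover_all_out_subset: bool = False
    # densities
    run_densities: bool = True
    # MCMC
    mcmc: MCMCSettings = field(default_factory=MCMCSettings)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        try:
            with open(path) as fh:
                raw = yaml.safe_load(fh) or {}
        except OSError as exc:
            raise ConfigError(f"cannot read config {path}: {exc}") from exc
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        raw = dict(raw)
        kwargs = {}
        if "mcmc" in raw:
            kwargs["mcmc"] = MCMCSettings(**raw.pop("mcmc"))
        if "sim" in raw:
            sim_raw = dict(raw.pop("sim"))
            if "foraging" in sim_raw:
                sim_raw["foraging"] = syn.ForagingParams(**sim_raw["foraging"])
            if "cover" in sim_raw:
                sim_raw["cover"] = syn.CoverParams(**sim_raw["cover"])
            kwargs["sim"] = syn.SimConfig(**sim_raw)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        try:
            return cls(**raw, **kwargs)
        except (TypeError, ValueError) as exc:
            raise ConfigError(str(exc)) from exc

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(_as_plain(dataclasses.asdict(self)), fh, sort_keys=False)


def _as_plain(obj):
    if isinstance(obj, dict):
        return {k: _as_plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_as_plain(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj


@dataclass
class PipelineResult:
    ind_metrics: pd.DataFrame
    grp_metrics: pd.DataFrame
    across_context: pd.DataFrame
    across_context_all_trials: pd.DataFrame | None
    within_context: pd.DataFrame
    context_effects: pd.DataFrame
    context_comparisons: pd.DataFrame
    densities: dict
    config: PipelineConfig
    out_dir: str | None = None


# ---------------------------------------------------------------------------
# stage 1: inputs
# ---------------------------------------------------------------------------


def _load_inputs(cfg: PipelineConfig):
    if cfg.simulate:
        sim_dir = os.path.join(cfg.out_dir, "simulated")
        exp = syn.simulate_experiment(
            cfg.sim,
            sim_dir,
            n_groups=cfg.n_groups,
            trials_per_context=cfg.trials_per_context,
            seed=cfg.seed,
        )
        return exp.trajectories, exp.metadata
    if not cfg.trajectories or not cfg.metadata:
        raise ConfigError("set either simulate: true or trajectories+metadata paths")
    paths = sorted(_glob.glob(cfg.trajectories))
    if not paths:
        raise DataError(f"no trajectory files match {cfg.trajectories!r}")
    trajs: list[tra.Trajectory] = []
    metas: list[tra.TrialMetadata] = []
    for path in paths:
        try:
            t, m = tra.read_trajectories(path, cfg.metadata)
        except tra.TrajectoryFormatError as exc:
            raise DataError(str(exc)) from exc
        trajs.extend(t)
        metas.extend(m)
    return trajs, metas


# ---------------------------------------------------------------------------
# stage 2: per-trial metrics
# ---------------------------------------------------------------------------


def _prepare(traj: tra.Trajectory, cfg: PipelineConfig) -> tra.Trajectory:
    if traj.has_gaps():
        traj = tra.fill_gaps(traj, cfg.max_gap)
    return tra.smooth(traj, cfg.smoothing_window, cfg.smoothing_polyorder)


def _windows_for(traj, meta) -> list[tuple[str, tuple[int, int]]]:
    """Analysis windows per trial, splitting foraging at the depletion frame."""
    if meta.context == "foraging":
        (pre, post) = met.split_foraging_trial(traj, meta)
        out = []
        if pre[1] - pre[0] > 1:
            out.append(("foraging_pre", pre))
        if post[1] - post[0] > 1:
            out.append(("foraging_post", post))
        return out
    return [(meta.context, (0, traj.n_frames))]


def build_metric_tables(
    trajs: list[tra.Trajectory],
    metas: list[tra.TrialMetadata],
    cfg: PipelineConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Per-trial metric tables (individual and group rows) for all trials.

    Returns the tidy individual table, the tidy group table and a cache of
    prepared (smoothed) trajectories keyed by trial_id for later stages.
    """
    ind_rows, grp_rows = [], []
    prepared: dict[str, tuple[tra.Trajectory, tra.TrialMetadata]] = {}
    for traj, meta in zip(trajs, metas):
        try:
            straj = _prepare(traj, cfg)
        except (ValueError, tra.GapTooLargeError) as exc:
            raise DataError(f"metrics stage, trial {traj.trial_id}: {exc}") from exc
        prepared[traj.trial_id] = (straj, meta)
        for context4, window in _windows_for(straj, meta):
            try:
                tm = met.summarize_trial(
                    straj,
                    meta,
                    window,
                    min_step=cfg.min_step_mm,
                    min_centroid_speed=cfg.min_centroid_speed_cm_s,
                )
            except met.MetricsError as exc:
                log.warning("skipping %s [%s]: %s", traj.trial_id, context4, exc)
                continue
            base = {
                "trial_id": traj.trial_id,
                "group_id": meta.group_id,
                "context": meta.context,
                "context4": context4,
                "trial_number": meta.trial_number,
            }
            for i, fish in enumerate(tm.individual_ids):
                ind_rows.append(
                    {
                        **base,
                        "individual_id": fish,
                        "median_speed": tm.median_speed[i],
                        "mean_centre_distance": tm.mean_centre_distance[i],
                        "front_proportion": tm.front_proportion[i],
                    }
                )
            grp_rows.append(
                {
                    **base,
                    "median_polarization": tm.median_polarization,
                    "leadership_variance": tm.leadership_variance,
                    "mean_median_speed": float(tm.median_speed.mean()),
                    "mean_centre_distance": float(tm.mean_centre_distance.mean()),
                    "mean_n_out_of_cover": tm.mean_n_out_of_cover,
                    "prop_all_out": tm.prop_all_out,
                }
            )
    if not grp_rows:
        raise DataError("no trials produced metrics")
    return pd.DataFrame(ind_rows), pd.DataFrame(grp_rows), prepared


# ---------------------------------------------------------------------------
# stage 3: repeatability models
# ---------------------------------------------------------------------------

#: across-context responses: (label, table, response column, with individual RE)
ACROSS_MODELS = [
    ("speed", "ind", "median_speed", True),
    ("centre_distance", "ind", "mean_centre_distance", True),
    ("front_proportion", "ind", "front_proportion", True),
    ("polarization", "grp", "median_polarization", False),
    ("leadership_structure", "grp", "leadership_variance", False),
]

#: rows of the headline across-context repeatability table: (response, level)
ACROSS_ROWS = [
    ("speed", "group"),
    ("centre_distance", "group"),
    ("centre_distance", "individual"),
    ("polarization", "group"),
    ("leadership_structure", "group"),
    ("front_proportion", "individual"),
]


def _fit(table, spec, cfg: PipelineConfig, seed: int):
    m = cfg.mcmc
    try:
        draws = rep.fit_lmm_mcmc(
            table,
            spec,
            chains=m.chains,
            iters=m.iters,
            burnin=m.burnin,
            thin=m.thin,
            seed=seed,
        )
    except rep.ModelError:
        raise
    return draws, rep.compute_repeatability(draws)


def _component_summary(draws, which: str):
    arr = draws.flat(which)
    lo, hi = np.quantile(arr, [0.025, 0.975])
    return float(arr.mean()), float(lo), float(hi)


def fit_across_context(
    ind: pd.DataFrame, grp: pd.DataFrame, cfg: PipelineConfig, *, seed_offset: int = 0
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, dict]:
    """Fit the five across-context models and shape the headline repeatability table."""
    fits: dict[str, tuple] = {}
    eff_rows, cmp_rows = [], []
    for k, (label, src, col, with_id) in enumerate(ACROSS_MODELS):
        table = (ind if src == "ind" else grp).copy()
        table = table.dropna(subset=[col])
        spec = rep.ModelSpec(
            response=col,
            fixed=("context4",),
            group="group_id",
            individual="individual_id" if with_id else None,
        )
        t0 = time.perf_counter()
        draws, result = _fit(table, spec, cfg, seed=cfg.seed + seed_offset + k + 1)
        log.info(
            "across-context model %s: n=%d, %.1fs, rhat=%s",
            label, len(table), time.perf_counter() - t0,
            {k2: round(v, 3) for k2, v in draws.rhat.items()},
        )
        fits[label] = (draws, result)
        levels = draws.fixed_levels["context4"]
        for lev in levels:
            comp_self = rep.compare_levels(draws, "context4", lev, levels[0])
            eff_rows.append(
                {
                    "response": label,
                    "context": lev,
                    "mean": comp_self.mean_a,
                    "ci_lo": comp_self.ci_a[0],
                    "ci_hi": comp_self.ci_a[1],
                }
            )
        for a_i in range(len(levels)):
            for b_i in range(a_i + 1, len(levels)):
                c = rep.compare_levels(draws, "context4", levels[a_i], levels[b_i])
                cmp_rows.append(
                    {
                        "response": label,
                        "level_a": c.level_a,
                        "level_b": c.level_b,
                        "significantly_different": c.significantly_different,
                    }
                )

    t1_rows = []
    for response, level in ACROSS_ROWS:
        draws, result = fits[response]
        vg = _component_summary(draws, "v_group")
        ve = _component_summary(draws, "v_res")
        vi = _component_summary(draws, "v_id") if draws.v_id is not None else None
        if level == "group":
            r, ci, point, sig = (
                result.r_group, result.r_group_ci,
                result.r_group_point, result.significant_group,
            )
        else:
            r, ci, point, sig = (
                result.r_id, result.r_id_ci, result.r_id_point, result.significant_id
            )
        t1_rows.append(
            {
                "response": response,
                "level": level,
                "v_group": vg[0], "v_group_lo": vg[1], "v_group_hi": vg[2],
                "v_id": vi[0] if vi else float("nan"),
                "v_id_lo": vi[1] if vi else float("nan"),
                "v_id_hi": vi[2] if vi else float("nan"),
                "v_res": ve[0], "v_res_lo": ve[1], "v_res_hi": ve[2],
                "r_c": r, "r_c_lo": ci[0], "r_c_hi": ci[1],
                "r_c_point": point,
                "significant": bool(sig),
            }
        )
    return pd.DataFrame(t1_rows), pd.DataFrame(eff_rows), pd.DataFrame(cmp_rows), fits


def fit_within_context(
    ind: pd.DataFrame, grp: pd.DataFrame, cfg: PipelineConfig
) -> pd.DataFrame:
    """Within-context repeatability: trial as fixed factor, per context."""
    rows = []
    scopes = [("foraging", "foraging_pre"), ("cover", "cover")]
    for k, (context, context4) in enumerate(scopes):
        for j, (label, src, col, with_id) in enumerate(ACROSS_MODELS):
            table = (ind if src == "ind" else grp)
            table = table[table["context4"] == context4].dropna(subset=[col]).copy()
            if table["trial_number"].nunique() < 2:
                continue
            table["trial"] = table["trial_number"].astype(str)
            spec = rep.ModelSpec(
                response=col,
                fixed=("trial",),
                group="group_id",
                individual="individual_id" if with_id else None,
            )
            try:
                draws, result = _fit(
                    table, spec, cfg, seed=cfg.seed + 1000 + 10 * k + j
                )
            except rep.ModelError as exc:
                log.warning("within-%s model %s skipped: %s", context, label, exc)
                continue
            rows.append(
                {
                    "context": context,
                    "response": label,
                    "r_c_group": result.r_group,
                    "r_c_group_lo": result.r_group_ci[0],
                    "r_c_group_hi": result.r_group_ci[1],
                    "r_c_id": result.r_id if result.r_id is not None else float("nan"),
                    "significant_group": bool(result.significant_group),
                }
            )
    return pd.DataFrame(rows)


def cover_all_out_metric_tables(
    prepared: dict, cfg: PipelineConfig
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Cover-trial metrics restricted to frames with every fish out of cover.

    The subset isolates genuinely collective behaviour from refuge use;
    trials without any all-out frames (or without a defined group front in
    them) are skipped with a warning.
    """
    ind_rows, grp_rows = [], []
    for straj, meta in prepared.values():
        if meta.context != "cover" or meta.cover is None:
            continue
        fm = met.frame_metrics(
            straj, meta,
            min_step=cfg.min_step_mm,
            min_centroid_speed=cfg.min_centroid_speed_cm_s,
        )
        mask = fm.n_out_of_cover == straj.n_individuals
        try:
            tm = met.summarize_trial(
                straj, meta, frame_mask=mask,
                min_step=cfg.min_step_mm,
                min_centroid_speed=cfg.min_centroid_speed_cm_s,
            )
        except met.MetricsError as exc:
            log.warning("all-out subset, skipping %s: %s", straj.trial_id, exc)
            continue
        base = {
            "trial_id": straj.trial_id,
            "group_id": meta.group_id,
            "context": "cover",
            "context4": "cover",
            "trial_number": meta.trial_number,
        }
        for i, fish in enumerate(tm.individual_ids):
            ind_rows.append(
                {
                    **base,
                    "individual_id": fish,
                    "median_speed": tm.median_speed[i],
                    "mean_centre_distance": tm.mean_centre_distance[i],
                    "front_proportion": tm.front_proportion[i],
                }
            )
        grp_rows.append(
            {
                **base,
                "median_polarization": tm.median_polarization,
                "leadership_variance": tm.leadership_variance,
                "mean_median_speed": float(tm.median_speed.mean()),
                "mean_centre_distance": float(tm.mean_centre_distance.mean()),
            }
        )
    return pd.DataFrame(ind_rows), pd.DataFrame(grp_rows)


# ---------------------------------------------------------------------------
# stage 4: densities
# ---------------------------------------------------------------------------


def _slice_trajectory(traj: tra.Trajectory, lo: int, hi: int) -> tra.Trajectory:
    return replace(traj, positions=traj.positions[lo:hi])


def compute_densities(prepared: dict, cfg: PipelineConfig) -> dict:
    """Per-context neighbour-position and speed–polarization maps.

    Pooled over the first trial of each group in each of the four analysis
    contexts (foraging split pre/post depletion).
    """
    by_ctx: dict[str, list] = {}
    for straj, meta in prepared.values():
        if meta.trial_number != 1:
            continue
        for context4, (lo, hi) in _windows_for(straj, meta):
            if hi - lo < 2:
                continue
            by_ctx.setdefault(context4, []).append((_slice_trajectory(straj, lo, hi), meta))
    out = {}
    for context4, pairs in sorted(by_ctx.items()):
        nmaps, fms = [], []
        for straj, meta in pairs:
            fm = met.frame_metrics(
                straj, meta,
                min_step=cfg.min_step_mm,
                min_centroid_speed=cfg.min_centroid_speed_cm_s,
            )
            fms.append(fm)
            try:
                nmaps.append(dens.neighbour_density(straj, meta, fm.heading))
            except dens.DensityError:
                continue
        if nmaps:
            out[f"neighbour_{context4}"] = dens.combine_density_maps(nmaps)
        try:
            out[f"speed_polarization_{context4}"] = dens.speed_polarization_density(fms)
        except dens.DensityError:
            pass
    return out


# ---------------------------------------------------------------------------
# orchestration
# ---------------------------------------------------------------------------


def run_pipeline(cfg: PipelineConfig) -> PipelineResult:
    """Run every stage and write all outputs under ``cfg.out_dir``."""
    t_start = time.perf_counter()
    os.makedirs(cfg.out_dir, exist_ok=True)
    cfg.to_yaml(os.path.join(cfg.out_dir, "resolved_config.yaml"))
    log.info("pipeline start: seed=%d out_dir=%s", cfg.seed, cfg.out_dir)

    trajs, metas = _load_inputs(cfg)
    log.info("inputs: %d trials", len(trajs))
    ind, grp, prepared = build_metric_tables(trajs, metas, cfg)
    ind.to_csv(os.path.join(cfg.out_dir, "trial_metrics_individual.csv"),
               index=False, float_format=FLOAT_FMT)
    grp.to_csv(os.path.join(cfg.out_dir, "trial_metrics_group.csv"),
               index=False, float_format=FLOAT_FMT)

    first_ind = ind[ind["trial_number"] == 1] if cfg.first_trial_only else ind
    first_grp = grp[grp["trial_number"] == 1] if cfg.first_trial_only else grp
    across_context, effects, comparisons, _ = fit_across_context(first_ind, first_grp, cfg)
    across_context.to_csv(os.path.join(cfg.out_dir, "across_context.csv"),
                  index=False, float_format=FLOAT_FMT)
    effects.to_csv(os.path.join(cfg.out_dir, "context_effects.csv"),
                   index=False, float_format=FLOAT_FMT)
    comparisons.to_csv(os.path.join(cfg.out_dir, "context_comparisons.csv"),
                       index=False, float_format=FLOAT_FMT)

    across_all = None
    if cfg.all_trials and cfg.first_trial_only:
        across_all, _, _, _ = fit_across_context(ind, grp, cfg, seed_offset=500)
        across_all.to_csv(os.path.join(cfg.out_dir, "across_context_all_trials.csv"),
                          index=False, float_format=FLOAT_FMT)

    within = fit_within_context(ind, grp, cfg)
    within.to_csv(os.path.join(cfg.out_dir, "within_context.csv"),
                  index=False, float_format=FLOAT_FMT)

    if cfg.cover_all_out_subset:
        ind_ao, grp_ao = cover_all_out_metric_tables(prepared, cfg)
        if len(grp_ao):
            within_ao = fit_within_context(ind_ao, grp_ao, cfg)
            within_ao.to_csv(
                os.path.join(cfg.out_dir, "within_cover_all_out.csv"),
                index=False, float_format=FLOAT_FMT,
            )
        else:
            log.warning("all-out subset requested but no usable cover frames")

    densities = {}
    if cfg.run_densities:
        densities = compute_densities(prepared, cfg)
        for name, dmap in densities.items():
            dens.write_density_csv(dmap, os.path.join(cfg.out_dir, f"density_{name}.csv"))

    result = PipelineResult(
        ind_metrics=ind,
        grp_metrics=grp,
        across_context=across_context,
        across_context_all_trials=across_all,
        within_context=within,
        context_effects=effects,
        context_comparisons=comparisons,
        densities=densities,
        config=cfg,
        out_dir=cfg.out_dir,
    )
    with open(os.path.join(cfg.out_dir, "report.md"), "w") as fh:
        fh.write(report(result))
    log.info("pipeline done in %.1fs", time.perf_counter() - t_start)
    return result


def _fmt(x) -> str:
    return FLOAT_FMT % x


def report(result: PipelineResult) -> str:
    """Human-readable markdown summary of the pipeline outputs.

    Every number shown is formatted exactly as written to the CSVs.
    """
    lines = ["# Shoal collective-behaviour analysis", ""]
    if result.across_context is None or len(result.across_context) == 0:
        lines.append("No models fitted.")
        return "\n".join(lines) + "\n"

    lines.append("## Context effects (posterior mean [95% CI])")
    lines.append("")
    for resp, sub in result.context_effects.groupby("response", sort=False):
        parts = [
            f"{row.context}: {_fmt(row['mean'])} [{_fmt(row.ci_lo)}, {_fmt(row.ci_hi)}]"
            for _, row in sub.iterrows()
        ]
        lines.append(f"- **{resp}** — " + "; ".join(parts))
    lines.append("")

    n_models = len(result.across_context)
    lines.append(f"## Across-context repeatability ({n_models} models)")
    lines.append("")
    lines.append("| response | level | V_group | V_id | V_res | R_C [95% CI] | significant |")
    lines.append("|---|---|---|---|---|---|---|")
    for _, row in result.across_context.iterrows():
        vid = _fmt(row.v_id) if np.isfinite(row.v_id) else "-"
        lines.append(
            f"| {row.response} | {row.level} | {_fmt(row.v_group)} | {vid} | "
            f"{_fmt(row.v_res)} | {_fmt(row.r_c)} "
            f"[{_fmt(row.r_c_lo)}, {_fmt(row.r_c_hi)}] | {bool(row.significant)} |"
        )
    lines.append("")

    if len(result.within_context):
        lines.append("## Within-context group repeatability")
        lines.append("")
        for _, row in result.within_context.iterrows():
            lines.append(
                f"- {row.context} / {row.response}: R_C group = {_fmt(row.r_c_group)} "
                f"[{_fmt(row.r_c_group_lo)}, {_fmt(row.r_c_group_hi)}]"
            )
        lines.append("")
    return "\n".join(lines) + "\n"
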