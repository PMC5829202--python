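"""Synthetic data generators: a mixed-model mirror and a shoal simulator.

Two levels of synthesis, matching what the inference stages need:

* :func:`generate_lmm_data` draws observations directly from the Gaussian
  random-intercept model (group, individual-within-group and residual
  components plus fixed context effects) and returns the true components
  alongside the table — the ground truth for testing the samplers.

* :func:`simulate_trial` / :func:`simulate_experiment` run a zonal
  (metric-zone) agent model of a five-fish shoal in a circular arena through
  three arena configurations — open, foraging (three 5-item food patches,
  split pre/post depletion) and cover (food patches plus a central plant
  refuge) — with group-level and individual-level heterogeneity entering
  through each fish's preferred speed. The zones are disjoint annuli
  (repulsion inside ``r_repulsion``; alignment in ``[r_repulsion,
  r_align)``; attraction in ``[r_align, r_attract)``), so a perfectly
  aligned, noise-free group is an exact fixed point of the update.

The simulator is a study-condition generator, not a behavioural model of
real sticklebacks: its defaults are fixed to produce the qualitative
context effects the analysis pipeline is designed to detect.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .trajectory import (
    DEFAULT_BODY_LENGTH_MM,
    Circle,
    FoodPatch,
    Trajectory,
    TrialMetadata,
    write_metadata,
    write_trajectories,
)

# ---------------------------------------------------------------------------
# metric-level LMM generator
# ---------------------------------------------------------------------------


@dataclass
class LMMGenConfig:
    """Generative settings for the mixed-model mirror."""

    n_groups: int = 25
    n_per_group: int = 5
    n_obs: int = 4                      # observations per individual (contexts)
    mu: float = 0.0
    context_effects: tuple[float, ...] = ()   # length n_obs, zeros if empty
    v_group: float = 1.0
    v_id: float = 0.5
    v_res: float = 1.0
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_groups < 2:
            raise ValueError("need at least 2 groups")
        if min(self.v_group, self.v_id, self.v_res) < 0:
            raise ValueError("variances must be non-negative")
        if self.context_effects and len(self.context_effects) != self.n_obs:
            raise ValueError("context_effects must have length n_obs")


def generate_lmm_data(cfg: LMMGenConfig) -> tuple[pd.DataFrame, dict]:
    """Draw a balanced observation table from the random-intercept model.

    ``y = mu + context + u_group + u_individual + e``. Returns the tidy
    table and a truth dict with the components, the realised effects and
    the implied repeatability ratios.
    """
    rng = np.random.default_rng(cfg.seed)
    G, M, R = cfg.n_groups, cfg.n_per_group, cfg.n_obs
    effects = np.asarray(cfg.context_effects if cfg.context_effects else np.zeros(R))
    u_g = rng.normal(0.0, np.sqrt(cfg.v_group), G)
    u_i = rng.normal(0.0, np.sqrt(cfg.v_id), (G, M))
    e = rng.normal(0.0, np.sqrt(cfg.v_res), (G, M, R))
    y = cfg.mu + effects[None, None, :] + u_g[:, None, None] + u_i[:, :, None] + e

    g_idx, i_idx, r_idx = np.meshgrid(
        np.arange(G), np.arange(M), np.arange(R), indexing="ij"
    )
    table = pd.DataFrame(
        {
            "value": y.ravel(),
            "group_id": [f"g{g + 1:03d}" for g in g_idx.ravel()],
            "individual_id": [
                f"g{g + 1:03d}_i{i + 1}" for g, i in zip(g_idx.ravel(), i_idx.ravel())
            ],
            "context": [f"c{r + 1}" for r in r_idx.ravel()],
        }
    )
    total = cfg.v_group + cfg.v_id + cfg.v_res
    truth = {
        "v_group": cfg.v_group,
        "v_id": cfg.v_id,
        "v_res": cfg.v_res,
        "r_group": cfg.v_group / total,
        "r_id": cfg.v_id / total,
        "group_effects": u_g,
        "individual_effects": u_i,
    }
    return table, truth


# ---------------------------------------------------------------------------
# agent-based shoal simulator
# ---------------------------------------------------------------------------


@dataclass
class ForagingParams:
    n_patches: int = 3
    items_per_patch: int = 5
    patch_radius_mm: float = 25.0
    patch_ring_radius_mm: float = 220.0   # patches on an equilateral triangle
    detection_radius_mm: float = 150.0
    scent_weight: float = 0.15            # weak long-range bias toward food
    detect_weight: float = 1.0            # strong bias once a patch is noticed
    handling_time_s: float = 1.5          # a feeding fish stops this long
    slowdown: float = 0.5                 # speed factor while approaching food


@dataclass
class CoverParams:
    radius_mm: float = 75.0               # 15 cm diameter central plants
    seek_prob_per_s: float = 0.05         # rate of heading for cover
    rest_prob_per_s: float = 0.5          # rate of settling once under cover
    resume_prob_per_s: float = 0.1        # rate of re-emerging

    def __post_init__(self) -> None:
        for p in (self.seek_prob_per_s, self.rest_prob_per_s, self.resume_prob_per_s):
            if not 0.0 <= p <= 1.0:
                raise ValueError("cover probabilities must be in [0, 1]")


@dataclass
class SimConfig:
    """Arena, interaction-zone and heterogeneity settings for the simulator."""

    arena_radius_mm: float = 400.0        # 80 cm diameter circular tank
    start_radius_mm: float = 50.0         # 10 cm release cylinder at the centre
    n_fish: int = 5
    fps: float = 24.0
    durations_s: dict = field(
        default_factory=lambda: {"open": 60.0, "foraging": 90.0, "cover": 60.0}
    )
    r_repulsion: float = 30.0
    r_align: float = 120.0
    r_attract: float = 400.0
    preferred_speed_mean: float = 3.2     # cm/s, population mean
    group_speed_sd: float = 0.8           # cm/s, among-group SD
    ind_speed_sd: float = 0.2             # cm/s, among-individual SD
    heading_noise_sd: float = 0.25        # rad per frame (von Mises)
    turn_weight: float = 0.25             # blend toward the desired direction
    wall_margin_mm: float = 40.0
    body_length_mm: float = DEFAULT_BODY_LENGTH_MM
    foraging: ForagingParams = field(default_factory=ForagingParams)
    cover: CoverParams = field(default_factory=CoverParams)

    def __post_init__(self) -> None:
        if not 0 < self.r_repulsion < self.r_align < self.r_attract:
            raise ValueError("need 0 < r_repulsion < r_align < r_attract")


def draw_traits(
    cfg: SimConfig, n_groups: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Preferred-speed offsets (cm/s): one per group, one per individual."""
    group = rng.normal(0.0, cfg.group_speed_sd, n_groups)
    ind = rng.normal(0.0, cfg.ind_speed_sd, (n_groups, cfg.n_fish))
    return group, ind


def _patch_centres(cfg: SimConfig) -> np.ndarray:
    ring = cfg.foraging.patch_ring_radius_mm
    angles = np.deg2rad([90.0, 210.0, 330.0])[: cfg.foraging.n_patches]
    return np.column_stack([ring * np.cos(angles), ring * np.sin(angles)])


def _unit(v: np.ndarray) -> np.ndarray:
    n = np.hypot(v[..., 0], v[..., 1])
    out = np.zeros_like(v)
    ok = n > 0
    out[ok] = v[ok] / n[ok][:, None] if v.ndim == 2 else v / n
    return out


def simulate_trial(
    cfg: SimConfig,
    group_speed_offset: float,
    ind_speed_offsets: np.ndarray,
    *,
    context: str,
    group_id: str,
    trial_number: int = 1,
    trial_id: str | None = None,
    seed=None,
    duration_s: float | None = None,
    initial_positions: np.ndarray | None = None,
    initial_angles: np.ndarray | None = None,
) -> tuple[Trajectory, TrialMetadata]:
    """Run one trial of the zonal shoal model in the given context.

    Each frame, every agent picks a desired direction (repulsion from
    neighbours inside the repulsion zone dominates; otherwise the mean of
    alignment with neighbours in the alignment annulus and attraction
    toward those in the attraction annulus), plus context terms (food
    scent, cover seeking) and inward wall avoidance near the arena edge.
    The heading is blended toward that direction and perturbed by von Mises
    noise; the step length is the agent's preferred speed modulated by
    feeding (stop during handling, slow near a detected patch) or resting
    under cover. Food items decrement on contact; the depletion frame is
    the frame at which the last item is eaten.
    """
    if context not in ("open", "foraging", "cover"):
        raise ValueError(f"unknown simulation context {context!r}")
    rng = np.random.default_rng(seed)
    n = cfg.n_fish
    fps = cfg.fps
    dur = duration_s if duration_s is not None else cfg.durations_s[context]
    n_frames = int(round(dur * fps))
    if n_frames < 2:
        raise ValueError("trial too short")

    pref_cm_s = np.maximum(
        cfg.preferred_speed_mean + group_speed_offset + np.asarray(ind_speed_offsets),
        0.5,
    )
    pref_step = pref_cm_s * 10.0 / fps  # mm per frame

    if initial_positions is None:
        r = cfg.start_radius_mm * np.sqrt(rng.random(n))
        th = rng.random(n) * 2 * np.pi
        pos = np.column_stack([r * np.cos(th), r * np.sin(th)])
    else:
        pos = np.asarray(initial_positions, dtype=float).copy()
    if initial_angles is None:
        ang = rng.random(n) * 2 * np.pi
    else:
        ang = np.asarray(initial_angles, dtype=float).copy()
    head = np.column_stack([np.cos(ang), np.sin(ang)])

    has_food = context in ("foraging", "cover")
    has_cover = context == "cover"
    patches = _patch_centres(cfg) if has_food else np.zeros((0, 2))
    items = np.full(len(patches), cfg.foraging.items_per_patch)
    handling = np.zeros(n, dtype=int)
    handling_frames = int(round(cfg.foraging.handling_time_s * fps))
    resting = np.zeros(n, dtype=bool)
    seeking = np.zeros(n, dtype=bool)
    depletion_frame: int | None = None

    kappa = 1.0 / cfg.heading_noise_sd**2 if cfg.heading_noise_sd > 0 else None
    cov = cfg.cover
    p_seek = cov.seek_prob_per_s / fps
    p_rest = cov.rest_prob_per_s / fps
    p_resume = cov.resume_prob_per_s / fps

    out = np.empty((n_frames, n, 2))
    for t in range(n_frames):
        out[t] = pos

        diff = pos[None, :, :] - pos[:, None, :]      # diff[i, j] = p_j - p_i
        dist = np.hypot(diff[..., 0], diff[..., 1])
        np.fill_diagonal(dist, np.inf)

        rep_mask = dist < cfg.r_repulsion
        ali_mask = (dist >= cfg.r_repulsion) & (dist < cfg.r_align)
        att_mask = (dist >= cfg.r_align) & (dist < cfg.r_attract)
        with np.errstate(invalid="ignore"):
            unit_diff = np.where(
                np.isfinite(dist[..., None]) & (dist[..., None] > 0),
                diff / dist[..., None],
                0.0,
            )

        desired = np.zeros((n, 2))
        any_rep = rep_mask.any(axis=1)
        rep_dir = -(unit_diff * rep_mask[..., None]).sum(axis=1)
        ali_dir = _unit((head[None, :, :] * ali_mask[..., None]).sum(axis=1))
        att_dir = _unit((unit_diff * att_mask[..., None]).sum(axis=1))
        social = _unit(ali_dir + att_dir)
        no_social = (social == 0).all(axis=1)
        desired = np.where(any_rep[:, None], _unit(rep_dir), social)
        desired[no_social & ~any_rep] = head[no_social & ~any_rep]

        if has_food and items.sum() > 0:
            active = items > 0
            to_patch = patches[None, active, :] - pos[:, None, :]
            pd_dist = np.hypot(to_patch[..., 0], to_patch[..., 1])
            nearest = pd_dist.argmin(axis=1)
            near_d = pd_dist[np.arange(n), nearest]
            near_dir = to_patch[np.arange(n), nearest]
            near_dir = near_dir / np.maximum(near_d, 1e-9)[:, None]
            detected = near_d < cfg.foraging.detection_radius_mm
            w = np.where(detected, cfg.foraging.detect_weight, cfg.foraging.scent_weight)
            desired = desired + w[:, None] * near_dir
        else:
            detected = np.zeros(n, dtype=bool)

        if has_cover:
            start_seek = (~resting) & (~seeking) & (rng.random(n) < p_seek)
            seeking |= start_seek
            to_cover = -pos
            d_cover = np.hypot(to_cover[:, 0], to_cover[:, 1])
            inside = d_cover <= cov.radius_mm
            desired[seeking] = desired[seeking] + 2.0 * _unit(to_cover)[seeking]
            settle = seeking & inside & (rng.random(n) < p_rest)
            resting |= settle
            seeking &= ~settle
            wake = resting & (rng.random(n) < p_resume)
            resting &= ~wake

        # wall avoidance: graded inward push inside the margin band
        d0 = np.hypot(pos[:, 0], pos[:, 1])
        near_wall = d0 > cfg.arena_radius_mm - cfg.wall_margin_mm
        if near_wall.any():
            inward = -_unit(pos)
            strength = (
                (d0 - (cfg.arena_radius_mm - cfg.wall_margin_mm)) / cfg.wall_margin_mm
            ).clip(0, 1)
            desired = desired + 2.0 * strength[:, None] * inward * near_wall[:, None]

        blend = _unit((1 - cfg.turn_weight) * head + cfg.turn_weight * _unit(desired))
        still = (blend == 0).all(axis=1)
        blend[still] = head[still]
        ang = np.arctan2(blend[:, 1], blend[:, 0])
        if kappa is not None:
            ang = ang + rng.vonmises(0.0, kappa, n)
        head = np.column_stack([np.cos(ang), np.sin(ang)])

        step = pref_step.copy()
        step[handling > 0] = 0.0
        step[detected & (handling == 0)] *= cfg.foraging.slowdown
        step[resting] = 0.0
        pos = pos + head * step[:, None]

        # hard containment: reflect off the wall if the step crossed it
        d1 = np.hypot(pos[:, 0], pos[:, 1])
        outside = d1 > cfg.arena_radius_mm - 5.0
        if outside.any():
            nrm = pos[outside] / d1[outside][:, None]
            pos[outside] = nrm * (cfg.arena_radius_mm - 5.0)
            h = head[outside]
            head[outside] = h - 2 * (h * nrm).sum(axis=1)[:, None] * nrm
        if (np.hypot(pos[:, 0], pos[:, 1]) > cfg.arena_radius_mm).any():
            raise RuntimeError("wall model contract violated: agent left the arena")

        handling = np.maximum(handling - 1, 0)
        if has_food and items.sum() > 0:
            for i in range(n):
                if handling[i] > 0:
                    continue
                for k in range(len(patches)):
                    if items[k] <= 0:
                        continue
                    if np.hypot(*(pos[i] - patches[k])) < cfg.foraging.patch_radius_mm:
                        items[k] -= 1
                        handling[i] = handling_frames
                        if items.sum() == 0 and depletion_frame is None:
                            depletion_frame = t
                        break

    if trial_id is None:
        trial_id = f"{group_id}_{context}_t{trial_number}"
    traj = Trajectory(
        trial_id=trial_id,
        fps=fps,
        positions=out,
        individual_ids=[f"{group_id}_f{i + 1}" for i in range(n)],
        smoothed=False,
    )
    meta = TrialMetadata(
        trial_id=trial_id,
        group_id=group_id,
        context=context,
        trial_number=trial_number,
        arena=Circle((0.0, 0.0), cfg.arena_radius_mm),
        food_patches=[
            FoodPatch(tuple(patches[k]), cfg.foraging.patch_radius_mm,
                      int(cfg.foraging.items_per_patch))
            for k in range(len(patches))
        ],
        cover=Circle((0.0, 0.0), cfg.cover.radius_mm) if has_cover else None,
        depletion_frame=(
            (depletion_frame if depletion_frame is not None else traj.n_frames)
            if context == "foraging"
            else None
        ),
        body_length_mm=cfg.body_length_mm,
    )
    return traj, meta


DEFAULT_TRIALS_PER_CONTEXT = {"open": 1, "foraging": 4, "cover": 2}


@dataclass
class SimExperiment:
    """Paths and ground truth written by :func:`simulate_experiment`."""

    trajectory_paths: list[str]
    metadata_path: str
    traits_path: str
    trajectories: list[Trajectory]
    metadata: list[TrialMetadata]
    traits: pd.DataFrame


def simulate_experiment(
    cfg: SimConfig,
    out_dir,
    *,
    n_groups: int = 25,
    trials_per_context: dict | None = None,
    seed: int = 0,
) -> SimExperiment:
    """Simulate the full design: every group through every context and trial.

    One trajectory CSV per trial, one metadata file and one ground-truth
    trait table. Each trial runs on its own deterministic substream spawned
    from the root seed, so the whole file set is reproducible bit-for-bit.
    """
    trials_per_context = dict(trials_per_context or DEFAULT_TRIALS_PER_CONTEXT)
    os.makedirs(out_dir, exist_ok=True)
    root = np.random.SeedSequence(seed)
    n_trials = sum(trials_per_context.values())
    streams = root.spawn(1 + n_groups * n_trials)
    g_off, i_off = draw_traits(cfg, n_groups, np.random.default_rng(streams[0]))

    trajs: list[Trajectory] = []
    metas: list[TrialMetadata] = []
    paths: list[str] = []
    k = 1
    for g in range(n_groups):
        group_id = f"g{g + 1:02d}"
        for context in ("open", "foraging", "cover"):
            for trial in range(1, trials_per_context.get(context, 0) + 1):
                traj, meta = simulate_trial(
                    cfg,
                    g_off[g],
                    i_off[g],
                    context=context,
                    group_id=group_id,
                    trial_number=trial,
                    seed=streams[k],
                )
                k += 1
                path = os.path.join(out_dir, f"{traj.trial_id}.csv")
                write_trajectories([traj], path)
                trajs.append(traj)
                metas.append(meta)
                paths.append(path)

    meta_path = os.path.join(out_dir, "metadata.yaml")
    write_metadata(metas, meta_path)
    traits = pd.DataFrame(
        {
            "group_id": np.repeat([f"g{g + 1:02d}" for g in range(n_groups)], cfg.n_fish),
            "fish_id": [
                f"g{g + 1:02d}_f{i + 1}"
                for g in range(n_groups)
                for i in range(cfg.n_fish)
            ],
            "group_speed_offset_cm_s": np.repeat(g_off, cfg.n_fish),
            "ind_speed_offset_cm_s": i_off.ravel(),
        }
    )
    traits_path = os.path.join(out_dir, "traits.csv")
    traits.to_csv(traits_path, index=False, float_format="%.6f")
    return SimExperiment(
        trajectory_paths=paths,
        metadata_path=meta_path,
        traits_path=traits_path,
        trajectories=trajs,
        metadata=metas,
        traits=traits,
    )
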