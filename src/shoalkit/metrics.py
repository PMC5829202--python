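"""Per-frame and per-trial behavioural measures for tracked shoals.

The measures are the standard descriptors of collective motion:

* **speed** — per-individual displacement speed (cm/s);
* **cohesion** — per-individual Euclidean distance to the group centroid (cm);
* **polarization** — the order parameter ``P(t) = |Σ_i u_i(t)| / n`` over the
  members' unit headings, 0 (headings cancel) to 1 (perfect alignment);
* **leadership** — the proportion of frames an individual spends in front of
  the group centroid along the centroid's direction of travel, and its
  variance across members ("leadership structure").

All per-frame series are frame-aligned with the trajectory: derivative-based
quantities (speed, centroid velocity) carry the preceding value at the last
frame so every series has ``n_frames`` entries. Undefined values are NaN.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .trajectory import Trajectory, TrialMetadata

MM_PER_CM = 10.0

#: headings from displacements below this step (mm) are jitter; carry forward
DEFAULT_MIN_STEP_MM = 0.2
#: a group moving slower than this (cm/s) has no meaningful "front"
DEFAULT_MIN_CENTROID_SPEED_CM_S = 0.5


class MetricsError(ValueError):
    """Raised when a metric is requested on data that cannot support it."""


@dataclass
class FrameMetrics:
    """Per-frame metric series for one trial (arrays indexed by frame)."""

    trial_id: str
    centroid: np.ndarray            # (n_frames, 2) mm
    centroid_velocity: np.ndarray   # (n_frames, 2) mm/s
    individual_speed: np.ndarray    # (n_frames, n) cm/s
    centre_distance: np.ndarray     # (n_frames, n) cm
    heading: np.ndarray             # (n_frames, n, 2) unit vectors, NaN undef
    in_front: np.ndarray            # (n_frames, n) 1.0/0.0, NaN undefined
    polarization: np.ndarray        # (n_frames,) in [0,1], NaN undefined
    n_out_of_cover: np.ndarray | None  # (n_frames,) ints, None without cover


@dataclass
class TrialMetrics:
    """Per-trial summary behaviours — the mixed-model response variables."""

    trial_id: str
    individual_ids: list[str]
    median_speed: np.ndarray          # cm/s, per individual
    mean_centre_distance: np.ndarray  # cm, per individual
    front_proportion: np.ndarray      # [0,1], per individual
    median_polarization: float
    leadership_variance: float        # population variance of front proportions
    mean_n_out_of_cover: float | None
    prop_all_out: float | None


def compute_centroid(traj: Trajectory) -> np.ndarray:
    """Arithmetic mean position of all members at each frame (mm)."""
    return traj.positions.mean(axis=1)


def compute_speeds(traj: Trajectory) -> np.ndarray:
    """Per-individual displacement speed in cm/s.

    ``speed_i(t) = |p_i(t+1) - p_i(t)| * fps``; the final frame repeats the
    preceding value so the series matches the trajectory length.
    """
    step = np.diff(traj.positions, axis=0)
    speed_mm_s = np.hypot(step[..., 0], step[..., 1]) * traj.fps
    return np.concatenate([speed_mm_s, speed_mm_s[-1:]], axis=0) / MM_PER_CM


def compute_headings(
    traj: Trajectory, min_step: float = DEFAULT_MIN_STEP_MM
) -> np.ndarray:
    """Unit headings from frame-to-frame displacement.

    A displacement shorter than ``min_step`` mm is treated as stationary
    jitter and the previous valid heading is carried forward; headings are
    NaN until the first valid step.
    """
    n_frames, n_ind = traj.n_frames, traj.n_individuals
    step = np.diff(traj.positions, axis=0)
    step = np.concatenate([step, step[-1:]], axis=0)
    norm = np.hypot(step[..., 0], step[..., 1])
    heading = np.full((n_frames, n_ind, 2), np.nan)
    valid = norm >= min_step
    heading[valid] = step[valid] / norm[valid][:, None]
    # carry-forward of the last valid heading
    for i in range(n_ind):
        last = np.array([np.nan, np.nan])
        for t in range(n_frames):
            if valid[t, i]:
                last = heading[t, i]
            else:
                heading[t, i] = last
    return heading


def compute_polarization(headings: np.ndarray) -> np.ndarray:
    """Order parameter per frame: resultant length of the defined headings.

    Undefined (NaN) where fewer than two members have a defined heading.
    """
    defined = ~np.isnan(headings[..., 0])
    n_def = defined.sum(axis=1)
    summed = np.nansum(np.where(defined[..., None], headings, 0.0), axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        pol = np.hypot(summed[:, 0], summed[:, 1]) / n_def
    pol[n_def < 2] = np.nan
    return pol


def compute_cohesion(traj: Trajectory) -> np.ndarray:
    """Distance of each individual to the group centroid, in cm."""
    rel = traj.positions - compute_centroid(traj)[:, None, :]
    return np.hypot(rel[..., 0], rel[..., 1]) / MM_PER_CM


def _centroid_velocity(traj: Trajectory) -> np.ndarray:
    c = compute_centroid(traj)
    v = np.diff(c, axis=0) * traj.fps
    return np.concatenate([v, v[-1:]], axis=0)


def compute_in_front(
    traj: Trajectory,
    min_centroid_speed: float = DEFAULT_MIN_CENTROID_SPEED_CM_S,
) -> np.ndarray:
    """Front/back classification of each member at each frame.

    A member is "in front" when its displacement from the centroid projects
    strictly positively on the centroid velocity. Frames where the centroid
    moves slower than ``min_centroid_speed`` cm/s are undefined for every
    member: a stationary group has no front.
    """
    c = compute_centroid(traj)
    v = _centroid_velocity(traj)
    rel = traj.positions - c[:, None, :]
    proj = np.einsum("fid,fd->fi", rel, v)
    out = (proj > 0).astype(float)
    slow = np.hypot(v[:, 0], v[:, 1]) < min_centroid_speed * MM_PER_CM
    out[slow, :] = np.nan
    return out


def frame_metrics(
    traj: Trajectory,
    meta: TrialMetadata | None = None,
    *,
    min_step: float = DEFAULT_MIN_STEP_MM,
    min_centroid_speed: float = DEFAULT_MIN_CENTROID_SPEED_CM_S,
) -> FrameMetrics:
    """Compute all per-frame series for a smoothed, gap-free trajectory."""
    if traj.has_gaps():
        raise MetricsError(f"trial {traj.trial_id}: fill gaps before metrics")
    headings = compute_headings(traj, min_step)
    n_out = None
    if meta is not None and meta.cover is not None:
        n_out = (~meta.cover.contains(traj.positions)).sum(axis=1)
    return FrameMetrics(
        trial_id=traj.trial_id,
        centroid=compute_centroid(traj),
        centroid_velocity=_centroid_velocity(traj),
        individual_speed=compute_speeds(traj),
        centre_distance=compute_cohesion(traj),
        heading=headings,
        in_front=compute_in_front(traj, min_centroid_speed),
        polarization=compute_polarization(headings),
        n_out_of_cover=n_out,
    )


def split_foraging_trial(
    traj: Trajectory, meta: TrialMetadata
) -> tuple[tuple[int, int], tuple[int, int]]:
    """Frame windows before and after food depletion: [0, d) and [d, n)."""
    d = meta.depletion_frame
    if d is None:
        raise MetricsError(f"trial {traj.trial_id}: no depletion_frame in metadata")
    if not 0 <= d <= traj.n_frames:
        raise MetricsError(
            f"trial {traj.trial_id}: depletion_frame {d} outside trial "
            f"of {traj.n_frames} frames"
        )
    return (0, d), (d, traj.n_frames)


def summarize_trial(
    traj: Trajectory,
    meta: TrialMetadata | None = None,
    frame_window: tuple[int, int] | None = None,
    *,
    frame_mask: np.ndarray | None = None,
    min_step: float = DEFAULT_MIN_STEP_MM,
    min_centroid_speed: float = DEFAULT_MIN_CENTROID_SPEED_CM_S,
) -> TrialMetrics:
    """Collapse per-frame series into the per-trial response variables.

    Per individual: median speed, mean centre distance, and the proportion
    of defined-front frames spent in front. Group level: median polarization
    and the population variance of the members' front proportions. The
    optional ``frame_mask`` further restricts the analysed frames (e.g. to
    the frames where all fish are out of cover).
    """
    fm = frame_metrics(
        traj, meta, min_step=min_step, min_centroid_speed=min_centroid_speed
    )
    lo, hi = frame_window if frame_window is not None else (0, traj.n_frames)
    if not 0 <= lo < hi <= traj.n_frames:
        raise MetricsError(
            f"trial {traj.trial_id}: empty or invalid frame window [{lo}, {hi})"
        )
    sel = np.zeros(traj.n_frames, dtype=bool)
    sel[lo:hi] = True
    if frame_mask is not None:
        sel &= np.asarray(frame_mask, dtype=bool)
    if not sel.any():
        raise MetricsError(f"trial {traj.trial_id}: frame selection is empty")

    speed = fm.individual_speed[sel]
    dist = fm.centre_distance[sel]
    front = fm.in_front[sel]
    pol = fm.polarization[sel]

    defined = ~np.isnan(front[:, 0])
    if not defined.any():
        raise MetricsError(
            f"trial {traj.trial_id}: no frames with a defined group front"
        )
    front_prop = front[defined].mean(axis=0)

    n_out = fm.n_out_of_cover[sel] if fm.n_out_of_cover is not None else None
    n = traj.n_individuals
    return TrialMetrics(
        trial_id=traj.trial_id,
        individual_ids=list(traj.individual_ids),
        median_speed=np.median(speed, axis=0),
        mean_centre_distance=dist.mean(axis=0),
        front_proportion=front_prop,
        median_polarization=float(np.nanmedian(pol)),
        leadership_variance=float(np.var(front_prop)),  # population (/n) variance
        mean_n_out_of_cover=float(n_out.mean()) if n_out is not None else None,
        prop_all_out=float((n_out == n).mean()) if n_out is not None else None,
    )
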