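"""Trajectory containers, file I/O, gap filling and smoothing.

Conventions used throughout the package:

* coordinates are millimetres, origin at the arena centre, y pointing up;
* frames are 0-based at a fixed frame rate (default 24 Hz);
* all frame intervals are half-open ``[start, end)``;
* a missing position is an explicit ``NaN`` pair, never an absent row.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import yaml
from scipy.signal import savgol_filter

DEFAULT_FPS = 24.0
DEFAULT_BODY_LENGTH_MM = 40.6

#: trial-level context labels the simulator emits, plus the two analysis-time
#: labels obtained by splitting a foraging trial at the depletion frame.
CONTEXTS = ("open", "foraging", "foraging_pre", "foraging_post", "cover")


class TrajectoryFormatError(ValueError):
    """Raised when a trajectory or metadata file violates the schema."""


class GapTooLargeError(ValueError):
    """Raised when a missing-data run exceeds the interpolation bound."""


@dataclass(frozen=True)
class Circle:
    """A circle in arena coordinates (mm)."""

    centre: tuple[float, float]
    radius: float

    def contains(self, points: np.ndarray) -> np.ndarray:
        """Vectorised point-in-circle test for an (..., 2) array."""
        p = np.asarray(points, dtype=float)
        d = p - np.asarray(self.centre, dtype=float)
        return np.hypot(d[..., 0], d[..., 1]) <= self.radius


@dataclass(frozen=True)
class FoodPatch:
    """A circular food patch holding a number of discrete food items."""

    centre: tuple[float, float]
    radius: float
    n_items: int


@dataclass
class TrialMetadata:
    """Per-trial experimental metadata joined to a :class:`Trajectory`."""

    trial_id: str
    group_id: str
    context: str
    trial_number: int
    arena: Circle
    food_patches: list[FoodPatch] = field(default_factory=list)
    cover: Circle | None = None
    depletion_frame: int | None = None
    body_length_mm: float = DEFAULT_BODY_LENGTH_MM

    def __post_init__(self) -> None:
        if self.context not in CONTEXTS:
            raise TrajectoryFormatError(
                f"trial {self.trial_id}: unknown context {self.context!r}"
            )
        foraging = self.context.startswith("foraging")
        if foraging and self.depletion_frame is None:
            raise TrajectoryFormatError(
                f"trial {self.trial_id}: foraging context requires depletion_frame"
            )
        if not foraging and self.depletion_frame is not None:
            raise TrajectoryFormatError(
                f"trial {self.trial_id}: depletion_frame only valid in a "
                "foraging context"
            )
        if self.body_length_mm <= 0:
            raise TrajectoryFormatError(
                f"trial {self.trial_id}: body_length_mm must be positive"
            )


@dataclass
class Trajectory:
    """Positions of one shoal over one trial.

    ``positions`` is a float array of shape ``(n_frames, n_individuals, 2)``
    in mm; missing observations are ``NaN`` in both coordinates.
    """

    trial_id: str
    fps: float
    positions: np.ndarray
    individual_ids: list[str]
    smoothed: bool = False

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        if self.fps <= 0:
            raise TrajectoryFormatError(f"trial {self.trial_id}: fps must be > 0")
        if self.positions.ndim != 3 or self.positions.shape[2] != 2:
            raise TrajectoryFormatError(
                f"trial {self.trial_id}: positions must have shape (frames, fish, 2)"
            )
        if self.positions.shape[0] < 2:
            raise TrajectoryFormatError(f"trial {self.trial_id}: need >= 2 frames")
        if self.positions.shape[1] < 1:
            raise TrajectoryFormatError(f"trial {self.trial_id}: need >= 1 individual")
        if len(self.individual_ids) != self.positions.shape[1]:
            raise TrajectoryFormatError(
                f"trial {self.trial_id}: individual_ids does not match positions"
            )
        # a half-missing coordinate pair is a schema violation, not a gap
        nan = np.isnan(self.positions)
        if np.any(nan[..., 0] != nan[..., 1]):
            raise TrajectoryFormatError(
                f"trial {self.trial_id}: x/y missingness must agree per observation"
            )

    @property
    def n_frames(self) -> int:
        return self.positions.shape[0]

    @property
    def n_individuals(self) -> int:
        return self.positions.shape[1]

    def has_gaps(self) -> bool:
        return bool(np.isnan(self.positions).any())


# ---------------------------------------------------------------------------
# CSV / YAML I/O
# ---------------------------------------------------------------------------

_TRAJ_COLUMNS = ["trial_id", "frame", "fish_id", "x", "y"]


def write_trajectories(
    trajectories: list[Trajectory], path, *, float_format: str = "%.3f"
) -> None:
    """Write trajectories to a single tidy CSV with a commented unit header."""
    if not trajectories:
        raise ValueError("no trajectories to write")
    fps = trajectories[0].fps
    frames = []
    for traj in trajectories:
        if traj.fps != fps:
            raise ValueError("all trajectories in one file must share fps")
        n_f, n_i = traj.n_frames, traj.n_individuals
        frames.append(
            pd.DataFrame(
                {
                    "trial_id": np.repeat(traj.trial_id, n_f * n_i),
                    "frame": np.repeat(np.arange(n_f), n_i),
                    "fish_id": np.tile(np.asarray(traj.individual_ids), n_f),
                    "x": traj.positions[:, :, 0].ravel(),
                    "y": traj.positions[:, :, 1].ravel(),
                }
            )
        )
    table = pd.concat(frames, ignore_index=True)
    buf = io.StringIO()
    buf.write("# units: mm\n# scale: 1.0\n")
    buf.write(f"# fps: {fps:g}\n")
    table.to_csv(buf, index=False, float_format=float_format)
    with open(path, "w") as fh:
        fh.write(buf.getvalue())


def _parse_header(path) -> dict:
    meta = {"units": "mm", "scale": 1.0, "fps": DEFAULT_FPS}
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            body = line.lstrip("#").strip()
            if ":" not in body:
                continue
            key, _, value = body.partition(":")
            key = key.strip().lower()
            value = value.strip()
            if key == "units":
                meta["units"] = value
            elif key == "scale":
                meta["scale"] = float(value)
            elif key == "fps":
                meta["fps"] = float(value)
    if meta["units"] not in ("mm", "px"):
        raise TrajectoryFormatError(f"{path}: units must be 'mm' or 'px'")
    return meta


def read_trajectory_file(path) -> list[Trajectory]:
    """Read one trajectory CSV (possibly holding several trials).

    Pixel coordinates are converted to mm with the header's scale factor.
    Frame indices must run 0..n-1 without gaps and every (frame, fish) pair
    must appear exactly once; violations are hard errors.
    """
    header = _parse_header(path)
    table = pd.read_csv(path, comment="#")
    missing = set(_TRAJ_COLUMNS) - set(table.columns)
    if missing:
        raise TrajectoryFormatError(f"{path}: missing columns {sorted(missing)}")
    scale = header["scale"] if header["units"] == "px" else 1.0

    out: list[Trajectory] = []
    for trial_id, sub in table.groupby("trial_id", sort=False):
        fish_ids = list(dict.fromkeys(sub["fish_id"]))
        frames = np.sort(sub["frame"].unique())
        expected = np.arange(len(frames))
        if not np.array_equal(frames, expected):
            gap_at = int(expected[frames != expected][0]) if len(frames) else 0
            raise TrajectoryFormatError(
                f"{path}: trial {trial_id}: frame sequence has a gap at frame "
                f"{gap_at} (frames must run 0..n-1)"
            )
        if not sub["frame"].is_monotonic_increasing:
            raise TrajectoryFormatError(
                f"{path}: trial {trial_id}: frame index is not monotone"
            )
        dup = sub.duplicated(subset=["frame", "fish_id"])
        if dup.any():
            row = sub[dup].iloc[0]
            raise TrajectoryFormatError(
                f"{path}: trial {trial_id}: duplicated row for frame "
                f"{int(row['frame'])}, fish {row['fish_id']}"
            )
        if len(sub) != len(frames) * len(fish_ids):
            raise TrajectoryFormatError(
                f"{path}: trial {trial_id}: every individual needs a row "
                "(possibly NaN) at every frame"
            )
        wide = sub.pivot(index="frame", columns="fish_id", values=["x", "y"])
        pos = np.stack(
            [wide["x"][fish_ids].to_numpy(), wide["y"][fish_ids].to_numpy()],
            axis=-1,
        )
        out.append(
            Trajectory(
                trial_id=str(trial_id),
                fps=header["fps"],
                positions=pos * scale,
                individual_ids=[str(f) for f in fish_ids],
            )
        )
    if not out:
        raise TrajectoryFormatError(f"{path}: no trials found")
    return out


def _circle_to_dict(c: Circle) -> dict:
    return {"centre_x": float(c.centre[0]), "centre_y": float(c.centre[1]),
            "radius": float(c.radius)}


def _circle_from_dict(d: dict) -> Circle:
    return Circle((float(d["centre_x"]), float(d["centre_y"])), float(d["radius"]))


def write_metadata(metadata: list[TrialMetadata], path) -> None:
    records = []
    for m in metadata:
        rec = {
            "trial_id": m.trial_id,
            "group_id": m.group_id,
            "context": m.context,
            "trial_number": int(m.trial_number),
            "arena": _circle_to_dict(m.arena),
            "food_patches": [
                {**_circle_to_dict(Circle(p.centre, p.radius)), "n_items": int(p.n_items)}
                for p in m.food_patches
            ],
            "cover": _circle_to_dict(m.cover) if m.cover is not None else None,
            "depletion_frame": (
                int(m.depletion_frame) if m.depletion_frame is not None else None
            ),
            "body_length_mm": float(m.body_length_mm),
        }
        records.append(rec)
    with open(path, "w") as fh:
        yaml.safe_dump(records, fh, sort_keys=False)


def read_metadata(path) -> list[TrialMetadata]:
    with open(path) as fh:
        records = yaml.safe_load(fh)
    if not isinstance(records, list):
        raise TrajectoryFormatError(f"{path}: expected a list of trial records")
    out = []
    for rec in records:
        try:
            out.append(
                TrialMetadata(
                    trial_id=str(rec["trial_id"]),
                    group_id=str(rec["group_id"]),
                    context=str(rec["context"]),
                    trial_number=int(rec["trial_number"]),
                    arena=_circle_from_dict(rec["arena"]),
                    food_patches=[
                        FoodPatch(
                            (float(p["centre_x"]), float(p["centre_y"])),
                            float(p["radius"]),
                            int(p["n_items"]),
                        )
                        for p in rec.get("food_patches") or []
                    ],
                    cover=(
                        _circle_from_dict(rec["cover"])
                        if rec.get("cover") is not None
                        else None
                    ),
                    depletion_frame=(
                        int(rec["depletion_frame"])
                        if rec.get("depletion_frame") is not None
                        else None
                    ),
                    body_length_mm=float(
                        rec.get("body_length_mm", DEFAULT_BODY_LENGTH_MM)
                    ),
                )
            )
        except KeyError as exc:
            raise TrajectoryFormatError(f"{path}: record missing field {exc}") from exc
    return out


def read_trajectories(
    path, metadata_path
) -> tuple[list[Trajectory], list[TrialMetadata]]:
    """Read a trajectory CSV and its metadata file, joined on trial_id.

    Every trial in the trajectory file must have a metadata record; metadata
    records without trajectories are dropped.
    """
    trajectories = read_trajectory_file(path)
    metadata = {m.trial_id: m for m in read_metadata(metadata_path)}
    joined = []
    for traj in trajectories:
        if traj.trial_id not in metadata:
            raise TrajectoryFormatError(
                f"trial {traj.trial_id} has no metadata record in {metadata_path}"
            )
        joined.append(metadata[traj.trial_id])
    return trajectories, joined


# ---------------------------------------------------------------------------
# Gap filling and smoothing
# ---------------------------------------------------------------------------


def fill_gaps(traj: Trajectory, max_gap: int = 15) -> Trajectory:
    """Fill missing positions by linear interpolation.

    Interior gaps are linearly interpolated between the flanking observed
    positions; leading/trailing gaps take the nearest observed position.
    A run of more than ``max_gap`` consecutive missing frames is an error
    (an automated tool must not invent long stretches of movement).
    """
    pos = traj.positions.copy()
    t = np.arange(traj.n_frames)
    for i, fish in enumerate(traj.individual_ids):
        missing = np.isnan(pos[:, i, 0])
        if not missing.any():
            continue
        if missing.all():
            raise GapTooLargeError(
                f"trial {traj.trial_id}: individual {fish} has no observed positions"
            )
        # run-length check on missing stretches
        padded = np.diff(np.concatenate(([0], missing.view(np.int8), [0])))
        starts = np.flatnonzero(padded == 1)
        ends = np.flatnonzero(padded == -1)
        for s, e in zip(starts, ends):
            if e - s > max_gap:
                raise GapTooLargeError(
                    f"trial {traj.trial_id}: individual {fish} missing for "
                    f"{e - s} frames (frames {s}..{e - 1}), max_gap={max_gap}"
                )
        ok = ~missing
        for k in range(2):
            pos[missing, i, k] = np.interp(t[missing], t[ok], pos[ok, i, k])
    return replace(traj, positions=pos)


def _shrinking_window_fit(series: np.ndarray, window: int, polyorder: int) -> np.ndarray:
    """Savitzky–Golay with shrinking-window least-squares fits at the ends.

    Interior points use the standard SG convolution; the first and last
    ``window//2`` points are re-fit with a polynomial over the part of the
    window that lies inside the series, so no positions are fabricated
    outside the observation interval.
    """
    n = len(series)
    half = window // 2
    out = savgol_filter(series, window, polyorder, mode="interp")
    for t in list(range(half)) + list(range(n - half, n)):
        lo, hi = max(0, t - half), min(n, t + half + 1)
        x = np.arange(lo, hi) - t
        coef = np.polynomial.polynomial.polyfit(x, series[lo:hi], polyorder)
        out[t] = coef[0]
    return out


def smooth(traj: Trajectory, window: int = 15, polyorder: int = 3) -> Trajectory:
    """Savitzky–Golay smooth every coordinate series.

    The default 15-frame window with a cubic local fit preserves the speed
    structure of swimming trajectories while suppressing tracking jitter.
    """
    if window % 2 == 0:
        raise ValueError("smoothing window must be odd")
    if polyorder >= window:
        raise ValueError("polyorder must be smaller than window")
    if window > traj.n_frames:
        raise ValueError("smoothing window exceeds trajectory length")
    if traj.has_gaps():
        raise ValueError(
            f"trial {traj.trial_id}: fill gaps before smoothing"
        )
    pos = np.empty_like(traj.positions)
    for i in range(traj.n_individuals):
        for k in range(2):
            pos[:, i, k] = _shrinking_window_fit(
                traj.positions[:, i, k], window, polyorder
            )
    return replace(traj, positions=pos, smoothed=True)
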