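"""Binned density summaries of shoal structure and dynamics.

Two maps: the position of neighbours relative to a focal fish (focal at the
origin, heading rotated to +y, distances in body lengths), and the joint
density of group speed and polarization. Values are normalised to percent of
the densest bin, the conventional display for such maps.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .metrics import FrameMetrics
from .trajectory import Trajectory, TrialMetadata


class DensityError(ValueError):
    pass


@dataclass
class DensityMap:
    """A 2-D histogram normalised to percent of its densest bin."""

    x_edges: np.ndarray
    y_edges: np.ndarray
    values: np.ndarray      # (nx, ny), percent of max, in [0, 100]
    n_samples: int          # samples inside the extent
    n_overflow: int = 0     # samples dropped for falling outside the extent
    peak_count: int = 0     # raw count of the densest bin

    def counts(self) -> np.ndarray:
        """Recover raw bin counts from the percent-normalised values."""
        return self.values / 100.0 * self.peak_count


def _normalize(counts: np.ndarray, x_edges, y_edges, n_overflow: int) -> DensityMap:
    n_samples = int(counts.sum())
    if n_samples == 0:
        raise DensityError("no samples fell inside the histogram extent")
    peak = int(counts.max())
    return DensityMap(
        x_edges=np.asarray(x_edges),
        y_edges=np.asarray(y_edges),
        values=counts / peak * 100.0,
        n_samples=n_samples,
        n_overflow=int(n_overflow),
        peak_count=peak,
    )


def neighbour_density(
    traj: Trajectory,
    meta: TrialMetadata,
    headings: np.ndarray,
    *,
    bin_width_bl: float = 0.25,
    extent_bl: float = 5.0,
) -> DensityMap:
    """Relative neighbour-position map in body lengths.

    For every frame and every ordered (focal, neighbour) pair with a defined
    focal heading, the neighbour position is expressed in the focal frame
    (origin at the focal fish, focal heading rotated to +y) and scaled by the
    body length. Samples outside ``±extent_bl`` are dropped and tallied.
    """
    pos = traj.positions
    n_frames, n = pos.shape[:2]
    if n < 2:
        raise DensityError("neighbour density needs at least two individuals")
    rel = pos[:, None, :, :] - pos[:, :, None, :]   # [t, focal, neighbour, 2]
    u = headings                                     # [t, focal, 2]
    # focal frame: x' = side (right positive), y' = along the heading
    side = rel[..., 0] * u[:, :, None, 1] - rel[..., 1] * u[:, :, None, 0]
    fwd = rel[..., 0] * u[:, :, None, 0] + rel[..., 1] * u[:, :, None, 1]
    ok = ~np.isnan(u[..., 0])
    pair_ok = ok[:, :, None] & ~np.eye(n, dtype=bool)[None, :, :]
    bl = meta.body_length_mm
    xs = side[pair_ok] / bl
    ys = fwd[pair_ok] / bl
    if xs.size == 0:
        raise DensityError(f"trial {traj.trial_id}: no defined focal headings")
    n_bins = int(round(2 * extent_bl / bin_width_bl))
    edges = np.linspace(-extent_bl, extent_bl, n_bins + 1)
    inside = (np.abs(xs) <= extent_bl) & (np.abs(ys) <= extent_bl)
    counts, _, _ = np.histogram2d(xs[inside], ys[inside], bins=[edges, edges])
    return _normalize(counts.astype(int), edges, edges, n_overflow=(~inside).sum())


def speed_polarization_density(
    frame_metrics_seq: list[FrameMetrics],
    *,
    speed_bin_cm_s: float = 0.25,
    max_speed_cm_s: float = 10.0,
    pol_bin: float = 0.05,
) -> DensityMap:
    """Joint density of group speed (mean individual speed) and polarization.

    Accumulated frame by frame over the supplied trials; frames without a
    defined polarization are skipped.
    """
    speeds, pols = [], []
    for fm in frame_metrics_seq:
        defined = ~np.isnan(fm.polarization)
        speeds.append(fm.individual_speed[defined].mean(axis=1))
        pols.append(fm.polarization[defined])
    if not speeds or sum(len(s) for s in speeds) == 0:
        raise DensityError("no frames with defined polarization")
    s = np.concatenate(speeds)
    p = np.concatenate(pols)
    s_edges = np.arange(0.0, max_speed_cm_s + speed_bin_cm_s / 2, speed_bin_cm_s)
    p_edges = np.arange(0.0, 1.0 + pol_bin / 2, pol_bin)
    inside = (s <= max_speed_cm_s) & (p <= 1.0)
    counts, _, _ = np.histogram2d(s[inside], p[inside], bins=[s_edges, p_edges])
    return _normalize(counts.astype(int), s_edges, p_edges, n_overflow=(~inside).sum())


def combine_density_maps(maps: list[DensityMap]) -> DensityMap:
    """Pool several maps with identical binning into one (summed counts)."""
    if not maps:
        raise DensityError("no maps to combine")
    first = maps[0]
    counts = np.zeros_like(first.values)
    overflow = 0
    for m in maps:
        if not (
            np.array_equal(m.x_edges, first.x_edges)
            and np.array_equal(m.y_edges, first.y_edges)
        ):
            raise DensityError("maps have different bin edges")
        counts += m.counts()
        overflow += m.n_overflow
    return _normalize(np.rint(counts).astype(int), first.x_edges, first.y_edges, overflow)


def write_density_csv(dmap: DensityMap, path) -> None:
    """Write a density map as a CSV matrix with edge vectors in the header."""
    with open(path, "w") as fh:
        fh.write("# x_edges: " + ",".join(f"{e:g}" for e in dmap.x_edges) + "\n")
        fh.write("# y_edges: " + ",".join(f"{e:g}" for e in dmap.y_edges) + "\n")
        fh.write(f"# n_samples: {dmap.n_samples}\n")
        fh.write(f"# n_overflow: {dmap.n_overflow}\n")
        fh.write(f"# peak_count: {dmap.peak_count}\n")
        np.savetxt(fh, dmap.values, delimiter=",", fmt="%.4f")


def plot_density(dmap: DensityMap, path, *, xlabel: str = "", ylabel: str = "") -> None:
    """Render a density map as a heat-map image (optional convenience)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(4, 4))
    ax.pcolormesh(dmap.x_edges, dmap.y_edges, dmap.values.T, cmap="viridis")
    ax.set_xlabel(xlabel)
    ax.set_ylabel(ylabel)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
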