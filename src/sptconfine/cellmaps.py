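"""Normalized-cell spatial maps.

Per-cell coordinates are projected into a standardized 3 x 1 um rectangle
(long axis u in [0, 3], short axis v in [0, 1]) by an affine map built from
each cell's centroid, long-axis direction, length and width.  Pooled over
many cells this yields population-level spot-location heat maps, speed maps
(single-step diffusion estimates d^2 / (4 tau) binned over ~0.1 um^2
areas), confined/free maps, and one-dimensional long-axis profiles.

Published maps of this kind are left-right symmetric because pole identity
is arbitrary; to avoid artifactual asymmetry, callers may randomize pole
orientation per cell with ``randomize_poles``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .confinement import ConfinementConfig, classify_dataset
from .core import CellGeometry, TrackDataset, Trajectory

__all__ = [
    "NORM_LENGTH",
    "NORM_WIDTH",
    "HeatMap",
    "SizeClasses",
    "normalize_coordinates",
    "normalize_dataset",
    "randomize_poles",
    "spot_heatmap",
    "speed_map",
    "split_by_cell_size",
    "confined_free_maps",
    "one_dim_probability",
]

NORM_LENGTH = 3.0  # um, normalized long axis
NORM_WIDTH = 1.0  # um, normalized short axis


@dataclass
class HeatMap:
    """Rectangular binning over the normalized cell.

    ``values`` has shape (n_v, n_u): rows are short-axis bins, columns
    long-axis bins.  For spot maps the values are counts (or fractions when
    normalized); for speed maps, mean single-step diffusion (um^2/s) with
    unoccupied bins as NaN.
    """

    values: np.ndarray
    u_edges: np.ndarray
    v_edges: np.ndarray
    kind: str  # spots | speed | ...
    bin_area: float
    normalized: bool = False

    @property
    def total(self) -> float:
        return float(np.nansum(self.values))

    def normalize(self) -> "HeatMap":
        if self.kind != "spots":
            raise ValueError("only spot maps support count normalization")
        return HeatMap(self.values / max(self.total, 1), self.u_edges, self.v_edges,
                       self.kind, self.bin_area, normalized=True)


@dataclass(frozen=True)
class SizeClasses:
    boundaries: tuple[float, float]  # terciles of cell length, um
    labels: tuple[str, ...]
    trajectory_counts: dict[str, int]
    degenerate: bool = False


def normalize_coordinates(traj: Trajectory, cell: CellGeometry) -> Trajectory:
    """Affine-map one trajectory into the 3 x 1 normalized rectangle.

    Long-axis positions are scaled by NORM_LENGTH / cell.length, short-axis
    by NORM_WIDTH / cell.width, both centred; points falling outside the
    rectangle are clipped to it with a warning.
    """
    ux, uy = cell.axis
    rel = traj.xy - np.asarray(cell.origin)
    u_img = rel @ np.array([ux, uy])
    v_img = rel @ np.array([-uy, ux])
    u = u_img * (NORM_LENGTH / cell.length) + NORM_LENGTH / 2.0
    v = v_img * (NORM_WIDTH / cell.width) + NORM_WIDTH / 2.0
    n_out = int(np.sum((u < 0) | (u > NORM_LENGTH) | (v < 0) | (v > NORM_WIDTH)))
    if n_out:
        warnings.warn(
            f"track {traj.track_id!r}: clipped {n_out} point(s) outside the "
            "normalized cell", stacklevel=2,
        )
    u = np.clip(u, 0.0, NORM_LENGTH)
    v = np.clip(v, 0.0, NORM_WIDTH)
    return Trajectory(traj.track_id, traj.frames.copy(),
                      np.column_stack([u, v]), traj.cell_id)


def normalize_dataset(dataset: TrackDataset) -> TrackDataset:
    """Normalize every trajectory using its cell geometry."""
    if dataset.cells is None:
        raise ValueError("dataset carries no cell geometries")
    out = []
    geom = CellGeometry("norm", NORM_LENGTH, NORM_WIDTH,
                        origin=(NORM_LENGTH / 2, NORM_WIDTH / 2), axis=(1.0, 0.0))
    for t in dataset:
        if t.cell_id is None:
            raise ValueError(f"track {t.track_id!r} has no cell_id")
        out.append(normalize_coordinates(t, dataset.cells[t.cell_id]))
    cells = {c: geom for c in {t.cell_id for t in out}}
    return TrackDataset(out, dataset.meta, cells, dataset.truth)


def randomize_poles(dataset: TrackDataset, seed: int) -> TrackDataset:
    """Flip each cell's trajectories end-for-end with probability 1/2.

    Pole identity in the raw images is arbitrary; random flips prevent an
    artifactual left-right asymmetry in pooled maps (applied to an already
    normalized dataset)."""
    rng = np.random.default_rng(seed)
    cell_ids = sorted({t.cell_id for t in dataset})
    flip = {c: rng.random() < 0.5 for c in cell_ids}
    out = []
    for t in dataset:
        if flip.get(t.cell_id, False):
            xy = np.column_stack([NORM_LENGTH - t.xy[:, 0], NORM_WIDTH - t.xy[:, 1]])
            out.append(Trajectory(t.track_id, t.frames.copy(), xy, t.cell_id))
        else:
            out.append(t)
    return dataset.replace_trajectories(out)


def _grid(bin_area: float) -> tuple[np.ndarray, np.ndarray]:
    """Near-square grid whose bins have the requested area (0.1 um^2 ->
    10 x 3 bins of exactly 0.1 um^2 over the 3 x 1 rectangle)."""
    side = np.sqrt(bin_area)
    n_v = max(1, round(NORM_WIDTH / side))
    n_u = max(1, round(NORM_LENGTH * NORM_WIDTH / (bin_area * n_v)))
    return np.linspace(0, NORM_LENGTH, n_u + 1), np.linspace(0, NORM_WIDTH, n_v + 1)


def _clip_points(pts: np.ndarray) -> np.ndarray:
    """Clip into the normalized rectangle so that localization noise at the
    membrane cannot drop points out of the maps (count conservation)."""
    out = np.empty_like(pts)
    out[:, 0] = np.clip(pts[:, 0], 0.0, NORM_LENGTH)
    out[:, 1] = np.clip(pts[:, 1], 0.0, NORM_WIDTH)
    return out


def _collect_points(dataset: TrackDataset) -> np.ndarray:
    if not len(dataset):
        return np.empty((0, 2))
    return _clip_points(np.concatenate([t.xy for t in dataset]))


def spot_heatmap(dataset: TrackDataset, bins: tuple[int, int] = (30, 10),
                 normalized: bool = False) -> HeatMap:
    """2-D histogram of all (normalized) localizations; ``bins`` is
    (n_u, n_v).  With ``normalized`` the counts divide by the total so maps
    from datasets of different size compare directly."""
    pts = _collect_points(dataset)
    u_edges = np.linspace(0, NORM_LENGTH, bins[0] + 1)
    v_edges = np.linspace(0, NORM_WIDTH, bins[1] + 1)
    h, _, _ = np.histogram2d(pts[:, 1], pts[:, 0], bins=(v_edges, u_edges))
    bin_area = (u_edges[1] - u_edges[0]) * (v_edges[1] - v_edges[0])
    hm = HeatMap(h, u_edges, v_edges, "spots", bin_area)
    return hm.normalize() if normalized else hm


def speed_map(dataset: TrackDataset, bin_area: float = 0.1) -> HeatMap:
    """Mean single-step diffusion per spatial bin.

    Each consecutive-frame step contributes d^2 / (4 tau) at the bin of its
    midpoint; a bin's value is the mean over its steps, NaN when no step
    fell there.
    """
    tau = dataset.meta.interval_time
    u_edges, v_edges = _grid(bin_area)
    sums = np.zeros((len(v_edges) - 1, len(u_edges) - 1))
    counts = np.zeros_like(sums)
    any_step = False
    for t in dataset:
        mask = t.consecutive_mask
        if not mask.any():
            continue
        any_step = True
        d = np.diff(t.xy, axis=0)[mask]
        mid = 0.5 * (t.xy[:-1] + t.xy[1:])[mask]
        d_est = (d[:, 0] ** 2 + d[:, 1] ** 2) / (4.0 * tau)
        iu = np.clip(np.searchsorted(u_edges, mid[:, 0], side="right") - 1,
                     0, sums.shape[1] - 1)
        iv = np.clip(np.searchsorted(v_edges, mid[:, 1], side="right") - 1,
                     0, sums.shape[0] - 1)
        np.add.at(sums, (iv, iu), d_est)
        np.add.at(counts, (iv, iu), 1.0)
    if not any_step:
        raise ValueError("dataset contains no consecutive-frame steps")
    with np.errstate(invalid="ignore"):
        values = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    return HeatMap(values, u_edges, v_edges, "speed",
                   (u_edges[1] - u_edges[0]) * (v_edges[1] - v_edges[0]))


def split_by_cell_size(dataset: TrackDataset
                       ) -> tuple[SizeClasses, dict[str, TrackDataset]]:
    """Split cells into small/medium/large by length terciles."""
    if dataset.cells is None:
        raise ValueError("dataset carries no cell geometries")
    lengths = {c: g.length for c, g in dataset.cells.items()}
    vals = np.array(sorted(lengths.values()))
    if np.ptp(vals) == 0:
        warnings.warn("all cell lengths equal; returning a single size class",
                      stacklevel=2)
        counts = {"all": len(dataset)}
        return (SizeClasses((vals[0], vals[0]), ("all",), counts, degenerate=True),
                {"all": dataset})
    q1, q2 = np.quantile(vals, [1 / 3, 2 / 3])
    labels = ("small", "medium", "large")

    def label_of(length: float) -> str:
        return "small" if length <= q1 else "medium" if length <= q2 else "large"

    subsets = {lab: [] for lab in labels}
    for t in dataset:
        subsets[label_of(lengths[t.cell_id])].append(t)
    per_class = {lab: dataset.replace_trajectories(ts) for lab, ts in subsets.items()}
    counts = {lab: len(ts) for lab, ts in subsets.items()}
    return SizeClasses((float(q1), float(q2)), labels, counts), per_class


def confined_free_maps(dataset: TrackDataset, cfg: ConfinementConfig,
                       bins: tuple[int, int] = (30, 10)) -> tuple[HeatMap, HeatMap]:
    """Spot maps of confined versus free motion.

    Confined map: points covered by dwell events.  Free map: all points of
    free tracks plus uncovered points of mixed tracks.  Together the two
    maps partition the localizations.
    """
    verdicts = classify_dataset(dataset, cfg)
    conf_pts, free_pts = [], []
    for t in dataset:
        v = verdicts[t.track_id]
        covered = np.zeros(len(t), dtype=bool)
        for ev in v.events:
            covered[ev.start : ev.end + 1] = True
        conf_pts.append(t.xy[covered])
        free_pts.append(t.xy[~covered])
    u_edges = np.linspace(0, NORM_LENGTH, bins[0] + 1)
    v_edges = np.linspace(0, NORM_WIDTH, bins[1] + 1)
    bin_area = (u_edges[1] - u_edges[0]) * (v_edges[1] - v_edges[0])

    def make(points: list[np.ndarray]) -> HeatMap:
        pts = np.concatenate(points) if points else np.empty((0, 2))
        if len(pts):
            pts = _clip_points(pts)
        h, _, _ = np.histogram2d(pts[:, 1], pts[:, 0], bins=(v_edges, u_edges))
        return HeatMap(h, u_edges, v_edges, "spots", bin_area)

    return make(conf_pts), make(free_pts)


def one_dim_probability(dataset: TrackDataset, bins: int = 30
                        ) -> tuple[np.ndarray, np.ndarray]:
    """Density-normalized marginal over the long axis u in [0, 3]
    (integrates to 1); returns (bin_centers, density)."""
    pts = _collect_points(dataset)
    density, edges = np.histogram(pts[:, 0], bins=bins,
                                  range=(0, NORM_LENGTH), density=True)
    return 0.5 * (edges[:-1] + edges[1:]), density
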