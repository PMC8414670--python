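"""Domain types and trajectory I/O.

Coordinates are stored in micrometres, image convention (origin top-left,
y pointing down); unit conversion happens once at ingest.  Frames are
0-based integers; a *step* is a pair of localizations at consecutive
frames.  Displacements across a 1-frame gap are never counted as single
steps for jump-distance or MSD purposes (dwell detection has its own,
separate gap tolerance).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, NamedTuple, Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "Localization",
    "Trajectory",
    "AcquisitionMeta",
    "CellGeometry",
    "TrackDataset",
    "TrajectoryFormatError",
    "TrajectoryDataError",
    "read_trajectories",
    "write_trajectories",
    "read_cell_geometries",
    "load_config",
    "filter_min_steps",
    "equalize_datasets",
]

CSV_COLUMNS = ["track_id", "frame", "x_um", "y_um"]


class TrajectoryFormatError(ValueError):
    """Raised when a trajectory file violates the CSV dialect."""


class TrajectoryDataError(ValueError):
    """Raised when trajectory data are internally inconsistent."""


class Localization(NamedTuple):
    frame: int
    x: float
    y: float


@dataclass(frozen=True)
class AcquisitionMeta:
    """Acquisition parameters shared by a dataset.

    ``interval_time`` is the frame interval tau in seconds (13.76 ms by
    default, slimfield stream acquisition), ``pixel_size`` in micrometres.
    The analysis is strictly two-dimensional.
    """

    interval_time: float = 0.01376
    pixel_size: float = 0.1
    n_dims: int = 2

    def __post_init__(self) -> None:
        if self.interval_time <= 0:
            raise ValueError("interval_time must be positive")
        if self.n_dims != 2:
            raise ValueError("only 2-D acquisitions are supported")


@dataclass(frozen=True)
class CellGeometry:
    """Rod-shaped cell outline summary used for normalized-cell projection.

    ``origin`` is the cell centroid in image coordinates (um) and ``axis``
    a unit vector along the long axis.
    """

    cell_id: str
    length: float
    width: float
    origin: tuple[float, float] = (0.0, 0.0)
    axis: tuple[float, float] = (1.0, 0.0)

    def __post_init__(self) -> None:
        if not (self.length >= self.width > 0):
            raise ValueError("require length >= width > 0")
        n = float(np.hypot(*self.axis))
        if not np.isclose(n, 1.0, atol=1e-6):
            object.__setattr__(self, "axis", (self.axis[0] / n, self.axis[1] / n))


@dataclass
class Trajectory:
    """Ordered 2-D localizations of one particle at a fixed frame interval."""

    track_id: str
    frames: np.ndarray  # int, strictly increasing
    xy: np.ndarray  # shape (n, 2), um
    cell_id: str | None = None

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=np.int64)
        self.xy = np.asarray(self.xy, dtype=float)
        if self.xy.ndim != 2 or self.xy.shape[1] != 2:
            raise ValueError("xy must have shape (n, 2)")
        if len(self.frames) != len(self.xy):
            raise ValueError("frames and xy length mismatch")
        if len(self.frames) < 2:
            raise ValueError("a trajectory needs at least 2 localizations")
        if np.any(np.diff(self.frames) <= 0):
            raise TrajectoryDataError(
                f"track {self.track_id!r}: frames must be strictly increasing"
            )
        if not np.all(np.isfinite(self.xy)):
            raise TrajectoryDataError(f"track {self.track_id!r}: non-finite coordinates")

    def __len__(self) -> int:
        return len(self.frames)

    @property
    def points(self) -> list[Localization]:
        return [Localization(int(f), float(x), float(y))
                for f, (x, y) in zip(self.frames, self.xy)]

    @property
    def n_steps(self) -> int:
        """Number of consecutive-frame steps (frame gaps do not count)."""
        return int(np.sum(np.diff(self.frames) == 1))

    @property
    def consecutive_mask(self) -> np.ndarray:
        """Boolean mask over intervals: True where frames differ by exactly 1."""
        return np.diff(self.frames) == 1

    def lifetime_s(self, meta: AcquisitionMeta) -> float:
        """Track lifetime in seconds: spanned frames times the interval."""
        return float(self.frames[-1] - self.frames[0]) * meta.interval_time


@dataclass
class TrackDataset:
    """A collection of trajectories plus acquisition metadata.

    ``cells`` optionally maps cell ids to geometries; when present, every
    trajectory's cell_id must be resolvable.  ``truth`` may carry simulator
    ground truth (per-track diffusion coefficient, state sequences) and is
    ignored by all analysis code.
    """

    trajectories: list[Trajectory]
    meta: AcquisitionMeta = field(default_factory=AcquisitionMeta)
    cells: dict[str, CellGeometry] | None = None
    truth: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if self.cells is not None:
            missing = {t.cell_id for t in self.trajectories} - set(self.cells) - {None}
            if missing:
                raise TrajectoryDataError(f"cell ids without geometry: {sorted(missing)}")

    def __len__(self) -> int:
        return len(self.trajectories)

    def __iter__(self):
        return iter(self.trajectories)

    def replace_trajectories(self, trajectories: Sequence[Trajectory]) -> "TrackDataset":
        return TrackDataset(list(trajectories), self.meta, self.cells, self.truth)


# ---------------------------------------------------------------------------
# I/O


def read_trajectories(path: str | Path, meta: AcquisitionMeta | None = None) -> TrackDataset:
    """Read a trajectory CSV (track_id, frame, x_um, y_um[, cell_id]).

    One Trajectory per distinct track_id, points sorted by frame.  Tracks
    with fewer than 2 points are dropped with a warning stating how many.
    """
    meta = meta or AcquisitionMeta()
    df = pd.read_csv(path)
    missing = [c for c in CSV_COLUMNS if c not in df.columns]
    if missing:
        raise TrajectoryFormatError(f"missing mandatory column(s): {', '.join(missing)}")
    has_cell = "cell_id" in df.columns

    if df.duplicated(subset=["track_id", "frame"]).any():
        dup = df[df.duplicated(subset=["track_id", "frame"])].iloc[0]
        raise TrajectoryDataError(
            f"duplicate (track_id, frame) = ({dup['track_id']}, {dup['frame']})"
        )

    trajectories: list[Trajectory] = []
    n_dropped = 0
    for tid, g in df.groupby("track_id", sort=True):
        g = g.sort_values("frame")
        if len(g) < 2:
            n_dropped += 1
            continue
        cell = None
        if has_cell and g["cell_id"].notna().all():
            cell = str(g["cell_id"].iloc[0])
        trajectories.append(
            Trajectory(str(tid), g["frame"].to_numpy(np.int64),
                       g[["x_um", "y_um"]].to_numpy(float), cell)
        )
    if n_dropped:
        warnings.warn(f"dropped {n_dropped} track(s) with < 2 localizations", stacklevel=2)
    return TrackDataset(trajectories, meta)


def write_trajectories(dataset: TrackDataset, path: str | Path) -> None:
    """Write the canonical CSV dialect: rows sorted by (track_id, frame),
    coordinates with 6 decimals."""
    rows = []
    any_cell = any(t.cell_id is not None for t in dataset)
    for t in sorted(dataset, key=lambda t: t.track_id):
        for f, (x, y) in zip(t.frames, t.xy):
            row = {"track_id": t.track_id, "frame": int(f), "x_um": x, "y_um": y}
            if any_cell:
                row["cell_id"] = t.cell_id if t.cell_id is not None else ""
            rows.append(row)
    cols = CSV_COLUMNS + (["cell_id"] if any_cell else [])
    pd.DataFrame(rows, columns=cols).to_csv(path, index=False, float_format="%.6f")


def read_cell_geometries(path: str | Path) -> dict[str, CellGeometry]:
    """Read per-cell geometry CSV: cell_id, length_um, width_um
    [, origin_x_um, origin_y_um, axis_x, axis_y]."""
    df = pd.read_csv(path)
    for c in ("cell_id", "length_um", "width_um"):
        if c not in df.columns:
            raise TrajectoryFormatError(f"missing mandatory column(s): {c}")
    cells = {}
    for _, r in df.iterrows():
        origin = (float(r.get("origin_x_um", 0.0)), float(r.get("origin_y_um", 0.0)))
        axis = (float(r.get("axis_x", 1.0)), float(r.get("axis_y", 0.0)))
        cells[str(r["cell_id"])] = CellGeometry(
            str(r["cell_id"]), float(r["length_um"]), float(r["width_um"]), origin, axis
        )
    return cells


def load_config(path: str | Path) -> AcquisitionMeta:
    """Load acquisition parameters from a YAML or JSON key-value file
    (keys: interval_time_s, pixel_size_um)."""
    text = Path(path).read_text()
    cfg = json.loads(text) if str(path).endswith(".json") else yaml.safe_load(text)
    return AcquisitionMeta(
        interval_time=float(cfg.get("interval_time_s", 0.01376)),
        pixel_size=float(cfg.get("pixel_size_um", 0.1)),
    )


# ---------------------------------------------------------------------------
# Dataset-level bookkeeping


def filter_min_steps(dataset: TrackDataset, min_steps: int) -> TrackDataset:
    """Keep trajectories with at least ``min_steps`` consecutive-frame steps."""
    if min_steps < 1:
        raise ValueError("min_steps must be >= 1")
    return dataset.replace_trajectories(
        [t for t in dataset if t.n_steps >= min_steps]
    )


def equalize_datasets(
    a: TrackDataset, b: TrackDataset, seed: int
) -> tuple[TrackDataset, TrackDataset]:
    """Subsample the larger dataset (uniform, without replacement) to the
    smaller's trajectory count so both contribute equal statistical weight."""
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both datasets must be non-empty")
    if len(a) == len(b):
        return a, b
    rng = np.random.default_rng(seed)

    def subsample(d: TrackDataset, n: int) -> TrackDataset:
        idx = np.sort(rng.choice(len(d), size=n, replace=False))
        return d.replace_trajectories([d.trajectories[i] for i in idx])

    if len(a) > len(b):
        return subsample(a, len(b)), b
    return a, subsample(b, len(a))
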