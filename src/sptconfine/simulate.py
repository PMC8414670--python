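"""Synthetic trajectory generation.

``simulate_brownian_mixture`` reproduces the validation simulation used to
benchmark the motion classifier: N tracks inside a 1 x 3 um model cell,
each track assigned one diffusion coefficient drawn from a weighted
mixture (defaults 0.08 / 0.375 / 1.01 um^2/s at 10 / 65 / 25 %) and kept
for its whole lifetime.  True positions evolve by Gaussian increments in
100 sub-steps per frame (per-axis SD sqrt(2 D tau / sub_steps)), reflected
specularly at the rectangle walls; observed positions add isotropic
Gaussian localization noise of SD 50 nm.  Track lifetimes default to a
geometric law with mean 10 frames (truncated to [2, 100]), emulating
photobleaching-limited track lengths of about 10 frames.

Reflection is implemented by folding the free (unbounded) path with the
triangle map of period 2L, which is the exact specular-reflection image of
a discrete Gaussian walk and preserves the uniform stationary density.

``simulate_confined_mixture`` adds polar trapping zones (reduced mobility
and Bernoulli escape inside caps at both cell poles) so the confinement
pipeline can be exercised against a known ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import AcquisitionMeta, CellGeometry, TrackDataset, Trajectory

__all__ = [
    "LifetimeModel",
    "SimulationConfig",
    "ConfinedZoneConfig",
    "sample_lifetimes",
    "simulate_brownian_mixture",
    "simulate_confined_mixture",
]


@dataclass(frozen=True)
class LifetimeModel:
    """Track lifetime law in frames: 'fixed' or 'geometric' (mean, max)."""

    kind: str = "geometric"
    mean_frames: float = 10.0
    max_frames: int = 100

    def __post_init__(self) -> None:
        if self.kind not in ("fixed", "geometric"):
            raise ValueError("lifetime kind must be 'fixed' or 'geometric'")
        if self.mean_frames < 2:
            raise ValueError("mean_frames must be >= 2 (a track needs 2 points)")


@dataclass(frozen=True)
class SimulationConfig:
    n_tracks: int = 50_000
    D_components: tuple[float, ...] = (0.08, 0.375, 1.01)  # um^2/s
    weights: tuple[float, ...] = (0.10, 0.65, 0.25)
    cell_length: float = 3.0  # um, long axis
    cell_width: float = 1.0  # um, short axis
    tau: float = 0.01376  # s per frame
    sub_steps: int = 100
    loc_error_sd: float = 0.05  # um
    lifetime: LifetimeModel = field(default_factory=LifetimeModel)
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.D_components) != len(self.weights):
            raise ValueError("D_components and weights length mismatch")
        if not np.isclose(sum(self.weights), 1.0):
            raise ValueError("weights must sum to 1")
        if any(d <= 0 for d in self.D_components) and any(d < 0 for d in self.D_components):
            raise ValueError("diffusion coefficients must be non-negative")
        if self.sub_steps < 1:
            raise ValueError("sub_steps must be >= 1")

    @property
    def meta(self) -> AcquisitionMeta:
        return AcquisitionMeta(interval_time=self.tau)


@dataclass(frozen=True)
class ConfinedZoneConfig:
    """Polar trapping caps: within ``depth`` um of either pole a trapped
    particle diffuses with ``D_inside`` and leaves only on an escape
    Bernoulli per frame; an untrapped particle entering a cap is trapped
    with probability ``p_trap`` per frame."""

    depth: float = 0.5  # um from each pole along the long axis
    D_inside: float = 0.02  # um^2/s
    p_escape: float = 0.05  # per frame
    p_trap: float = 0.5  # per frame while inside a cap

    def __post_init__(self) -> None:
        for p in (self.p_escape, self.p_trap):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")


def sample_lifetimes(model: LifetimeModel, n: int,
                     rng: np.random.Generator | int) -> np.ndarray:
    """Sample per-track lifetimes in frames (number of localizations)."""
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    if model.kind == "fixed":
        return np.full(n, int(model.mean_frames), dtype=np.int64)
    # geometric on {1, 2, ...} with the requested mean, clipped to [2, max]
    draws = rng.geometric(1.0 / model.mean_frames, size=n)
    return np.clip(draws, 2, model.max_frames).astype(np.int64)


def _fold(x: np.ndarray, lo: float, hi: float) -> np.ndarray:
    """Triangle-map fold of unbounded coordinates into [lo, hi] (specular
    reflection of the free path)."""
    span = hi - lo
    y = np.mod(x - lo, 2.0 * span)
    return lo + np.where(y <= span, y, 2.0 * span - y)


def _default_cell(cfg: SimulationConfig) -> dict[str, CellGeometry]:
    geom = CellGeometry("sim", cfg.cell_length, cfg.cell_width,
                        origin=(cfg.cell_length / 2.0, cfg.cell_width / 2.0),
                        axis=(1.0, 0.0))
    return {"sim": geom}


def simulate_brownian_mixture(cfg: SimulationConfig) -> TrackDataset:
    """Generate a Brownian-mixture dataset; ground truth (per-track D) is
    attached as ``dataset.truth``.

    x is the long-axis coordinate in [0, cell_length], y the short-axis
    coordinate in [0, cell_width].  Localization noise is added to the
    observed positions only; the true path propagates noise-free.
    """
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_tracks
    comp = rng.choice(len(cfg.D_components), size=n, p=np.asarray(cfg.weights))
    D = np.asarray(cfg.D_components)[comp]
    life = sample_lifetimes(cfg.lifetime, n, rng)

    n_sub = (life - 1) * cfg.sub_steps
    offsets = np.concatenate(([0], np.cumsum(n_sub)))
    total = int(offsets[-1])
    sd_sub = np.sqrt(2.0 * D * cfg.tau / cfg.sub_steps)
    sd_all = np.repeat(sd_sub, n_sub)

    x0 = rng.uniform(0.0, cfg.cell_length, size=n)
    y0 = rng.uniform(0.0, cfg.cell_width, size=n)

    trajectories: list[Trajectory] = []
    frame_idx = [np.arange(L) for L in life]
    for axis, (lo, hi, starts) in enumerate(
        [(0.0, cfg.cell_length, x0), (0.0, cfg.cell_width, y0)]
    ):
        inc = rng.standard_normal(total) * sd_all
        cs = np.cumsum(inc)
        # per-track free path: starts[i] + (cs[a:b] - cs[a-1]); folded walls
        coords_axis = np.empty(int(np.sum(life)))
        pos = 0
        for i in range(n):
            a, b = offsets[i], offsets[i + 1]
            seg = cs[a:b] - (cs[a - 1] if a > 0 else 0.0)
            free = starts[i] + seg[cfg.sub_steps - 1 :: cfg.sub_steps]
            true_path = np.concatenate(([starts[i]], _fold(free, lo, hi)))
            coords_axis[pos : pos + life[i]] = true_path
            pos += life[i]
        if axis == 0:
            xs = coords_axis
        else:
            ys = coords_axis

    noise = rng.standard_normal((int(np.sum(life)), 2)) * cfg.loc_error_sd
    obs = np.column_stack([xs, ys]) + noise

    pos = 0
    width = len(str(n - 1))
    for i in range(n):
        L = int(life[i])
        trajectories.append(
            Trajectory(f"sim{i:0{width}d}", frame_idx[i], obs[pos : pos + L], "sim")
        )
        pos += L

    truth = pd.DataFrame({
        "track_id": [t.track_id for t in trajectories],
        "D_true": D,
        "component": comp,
        "n_frames": life,
    })
    return TrackDataset(trajectories, cfg.meta, _default_cell(cfg), truth)


def simulate_confined_mixture(cfg: SimulationConfig,
                              zones: ConfinedZoneConfig) -> TrackDataset:
    """Brownian mixture plus polar trapping zones.

    Per frame: a trapped particle moves with ``zones.D_inside`` reflected
    inside its cap and escapes with probability ``p_escape`` (resuming free
    motion); a free particle inside a cap becomes trapped with probability
    ``p_trap``.  The per-frame ground-truth state sequence ('free'/'trapped',
    encoded 0/1) is stored in ``dataset.truth``.
    """
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_tracks
    comp = rng.choice(len(cfg.D_components), size=n, p=np.asarray(cfg.weights))
    D_free = np.asarray(cfg.D_components)[comp]
    life = sample_lifetimes(cfg.lifetime, n, rng)
    L_cell, W_cell = cfg.cell_length, cfg.cell_width

    def cap_bounds(x: float) -> tuple[float, float] | None:
        if x <= zones.depth:
            return (0.0, zones.depth)
        if x >= L_cell - zones.depth:
            return (L_cell - zones.depth, L_cell)
        return None

    trajectories: list[Trajectory] = []
    states_all: list[np.ndarray] = []
    width = len(str(n - 1))
    for i in range(n):
        L = int(life[i])
        xy = np.empty((L, 2))
        xy[0] = rng.uniform(0.0, L_cell), rng.uniform(0.0, W_cell)
        state = np.zeros(L, dtype=np.int8)
        trapped = False
        for k in range(1, L):
            x_prev = xy[k - 1]
            cap = cap_bounds(x_prev[0])
            if trapped and rng.random() < zones.p_escape:
                trapped = False
            elif not trapped and cap is not None and rng.random() < zones.p_trap:
                trapped = True
            cap = cap_bounds(x_prev[0]) if trapped else None
            D_now = zones.D_inside if trapped else D_free[i]
            sd = np.sqrt(2.0 * D_now * cfg.tau / cfg.sub_steps)
            steps = rng.standard_normal((cfg.sub_steps, 2)) * sd
            free = x_prev + np.cumsum(steps, axis=0)
            if trapped and cap is not None:
                x_new = _fold(free[-1, 0], cap[0], cap[1])
            else:
                x_new = _fold(free[-1, 0], 0.0, L_cell)
            y_new = _fold(free[-1, 1], 0.0, W_cell)
            xy[k] = x_new, y_new
            state[k] = int(trapped)
        obs = xy + rng.standard_normal((L, 2)) * cfg.loc_error_sd
        trajectories.append(Trajectory(f"sim{i:0{width}d}", np.arange(L), obs, "sim"))
        states_all.append(state)

    truth = pd.DataFrame({
        "track_id": [t.track_id for t in trajectories],
        "D_true": D_free,
        "component": comp,
        "n_frames": life,
        "states": states_all,
    })
    return TrackDataset(trajectories, cfg.meta, _default_cell(cfg), truth)
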