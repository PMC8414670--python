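"""Confined-diffusion detection: dwell events, track verdicts, dwell-time
survival curves, and state transitions.

A dwell event is a maximal stretch of consecutive trajectory points that
fits inside a circle of the confinement radius R centred on one of the
trajectory's own nodes.  One single-frame gap, or one point that leaves the
circle and returns on the next step, is tolerated per event (by default not
both).  Events are found greedily: the centre/window combination covering
the most steps is recorded, excised, and the remainder searched again until
no window of at least ``min_steps`` steps remains.

R is tied to the data quality: 2.5 times the mean estimated localization
error of the dataset.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import lmfit
import numpy as np
import pandas as pd
from scipy import stats

from .core import TrackDataset, Trajectory
from .msd import LocalizationError

__all__ = [
    "ConfinementConfig",
    "DwellEvent",
    "ConfinementVerdict",
    "DwellDecayFit",
    "TransitionCounts",
    "confinement_radius",
    "detect_dwell_events",
    "classify_track",
    "classify_dataset",
    "dwell_survival",
    "fit_dwell_decay",
    "detect_transitions",
    "transition_summary",
]


@dataclass(frozen=True)
class ConfinementConfig:
    radius: float  # um
    min_steps: int = 5
    factor: float = 2.5
    combine_gap_outlier: bool = False  # if True, one gap AND one outlier may coexist

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ValueError("radius must be positive")
        if self.min_steps < 2:
            raise ValueError("min_steps must be >= 2")


@dataclass(frozen=True)
class DwellEvent:
    track_id: str
    center_index: int
    center: tuple[float, float]
    start: int  # localization index (inclusive)
    end: int  # localization index (inclusive)
    n_steps: int  # frames spanned, bridged gaps included
    dwell_time: float  # s
    outliers_used: int
    gaps_bridged: int


@dataclass(frozen=True)
class ConfinementVerdict:
    category: str  # free | mixed | confined
    events: tuple[DwellEvent, ...]
    confined_fraction: float


@dataclass(frozen=True)
class DwellDecayFit:
    n_components: int
    amplitudes: np.ndarray  # sum to 1
    taus: np.ndarray  # s
    mean_dwell: float  # s, sum A_i tau_i
    p_value: float  # nested F-test 1 vs 2 components
    rss: float
    degenerate: bool = False


@dataclass
class TransitionCounts:
    confined_to_free: int = 0
    free_to_confined: int = 0


def confinement_radius(loc_error: LocalizationError, factor: float = 2.5) -> float:
    """R = factor x mean estimated localization error."""
    if loc_error.mean_sigma <= 0:
        raise ValueError("mean localization error must be positive")
    return factor * loc_error.mean_sigma


def _best_window(traj: Trajectory, seg: np.ndarray, center_pos: int,
                 cfg: ConfinementConfig) -> tuple[int, int, int, int] | None:
    """Longest valid window around one candidate centre within a segment.

    Returns (start_pos, end_pos, outliers, gaps) in segment positions, or
    None.  A window starts and ends on in-circle points; between adjacent
    window points frames may differ by 1, or once by 2 (one bridged gap);
    one out-of-circle point is tolerated if the next point returns inside.
    """
    frames = traj.frames[seg]
    center = traj.xy[seg[center_pos]]
    d = traj.xy[seg] - center
    inside = d[:, 0] ** 2 + d[:, 1] ** 2 <= cfg.radius**2
    n = len(seg)
    budget_each = 1
    best: tuple[int, int, int, int] | None = None

    for s in range(n):
        if not inside[s]:
            continue
        gaps = outliers = 0
        last_ok = s
        j = s
        while j + 1 < n:
            dj = frames[j + 1] - frames[j]
            if dj == 2:
                if gaps + 1 > budget_each or (
                    not cfg.combine_gap_outlier and gaps + outliers + 1 > 1
                ):
                    break
                gaps += 1
            elif dj != 1:
                break
            j += 1
            if inside[j]:
                last_ok = j
            else:
                # an excursion must go and come back within one step
                if (
                    outliers + 1 > budget_each
                    or (not cfg.combine_gap_outlier and gaps + outliers + 1 > 1)
                    or j + 1 >= n
                    or not inside[j + 1]
                    or frames[j + 1] - frames[j] != 1
                ):
                    break
                outliers += 1
        e = last_ok
        if e > s:
            steps = int(frames[e] - frames[s])
            cand = (s, e, outliers, gaps)
            if best is None or steps > int(frames[best[1]] - frames[best[0]]) or (
                steps == int(frames[best[1]] - frames[best[0]]) and s < best[0]
            ):
                best = cand
    return best


def detect_dwell_events(traj: Trajectory, cfg: ConfinementConfig,
                        tau: float | None = None) -> list[DwellEvent]:
    """Greedy dwell-event detection (longest window first, then excise).

    Candidate centres are trajectory nodes; ties in window length break
    toward the earliest start index, then the earliest centre index.
    Events are returned in temporal order; dwell times are filled in
    seconds when ``tau`` is given (NaN otherwise).
    """
    events: list[DwellEvent] = []
    segments = [np.arange(len(traj))]
    while segments:
        seg = segments.pop()
        if len(seg) < 2:
            continue
        best = None  # (steps, start_pos, center_pos, end_pos, outliers, gaps)
        frames = traj.frames[seg]
        for c in range(len(seg)):
            w = _best_window(traj, seg, c, cfg)
            if w is None:
                continue
            s, e, outl, gaps = w
            steps = int(frames[e] - frames[s])
            if steps < cfg.min_steps:
                continue
            key = (-steps, s, c)
            if best is None or key < best[0]:
                best = (key, s, e, c, outl, gaps)
        if best is None:
            continue
        _, s, e, c, outl, gaps = best
        gs, ge, gc = int(seg[s]), int(seg[e]), int(seg[c])
        steps = int(traj.frames[ge] - traj.frames[gs])
        events.append(
            DwellEvent(traj.track_id, gc, tuple(traj.xy[gc]), gs, ge, steps,
                       float("nan"), outl, gaps)
        )
        segments.append(seg[:s])
        segments.append(seg[e + 1 :])
    events.sort(key=lambda ev: ev.start)
    if tau is not None:
        events = _with_times(events, tau)
    return events


def _with_times(events: list[DwellEvent], tau: float) -> list[DwellEvent]:
    return [
        DwellEvent(ev.track_id, ev.center_index, ev.center, ev.start, ev.end,
                   ev.n_steps, ev.n_steps * tau, ev.outliers_used, ev.gaps_bridged)
        for ev in events
    ]


def classify_track(traj: Trajectory, events: list[DwellEvent]) -> ConfinementVerdict:
    """free (no events) / confined (events cover every step) / mixed."""
    total = int(traj.frames[-1] - traj.frames[0])
    covered = sum(ev.n_steps for ev in events)
    if not events:
        return ConfinementVerdict("free", (), 0.0)
    frac = covered / total if total else 1.0
    category = "confined" if covered >= total else "mixed"
    return ConfinementVerdict(category, tuple(events), min(frac, 1.0))


def classify_dataset(dataset: TrackDataset, cfg: ConfinementConfig
                     ) -> dict[str, ConfinementVerdict]:
    """Dwell detection + verdict for every track; dwell times in seconds."""
    tau = dataset.meta.interval_time
    out = {}
    for t in dataset:
        events = _with_times(detect_dwell_events(t, cfg), tau)
        out[t.track_id] = classify_track(t, events)
    return out


def dwell_survival(events: list[DwellEvent] | np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Survival (1 - ECDF) of dwell times, right-continuous: S(t) = P(T > t)
    evaluated at the sorted observed times."""
    if len(events) and isinstance(events[0], DwellEvent):
        times = np.asarray([ev.dwell_time for ev in events], dtype=float)
    else:
        times = np.asarray(events, dtype=float)
    if len(times) == 0:
        raise ValueError("no dwell events")
    t = np.sort(times)
    surv = 1.0 - np.arange(1, len(t) + 1) / len(t)
    return t, surv


def fit_dwell_decay(curve: tuple[np.ndarray, np.ndarray],
                    max_components: int = 2) -> DwellDecayFit:
    """Fit the dwell-time survival to sum_i A_i exp(-t / tau_i), sum A_i = 1.

    Levenberg-Marquardt on the survival points; one versus two components
    decided by a nested F-test at p < 0.05.  Fewer than five distinct times
    or a constant sample yields a degenerate single-component fit.
    """
    t, surv = np.asarray(curve[0], float), np.asarray(curve[1], float)
    distinct = np.unique(t)
    tbar = float(np.mean(t))
    if len(distinct) < 5 or tbar <= 0 or np.ptp(distinct) == 0:
        tau1 = tbar if tbar > 0 else np.nan
        return DwellDecayFit(1, np.array([1.0]), np.array([tau1]), tau1,
                             1.0, float("nan"), degenerate=True)

    def fit_k(k: int) -> tuple[lmfit.minimizer.MinimizerResult, float]:
        params = lmfit.Parameters()
        if k == 1:
            params.add("tau0", value=tbar, min=1e-6)

            def resid(p):
                return np.exp(-t / p["tau0"].value) - surv
        else:
            params.add("tau0", value=tbar / 3.0, min=1e-6)
            params.add("tau1", value=tbar * 3.0, min=1e-6)
            params.add("a0", value=0.5, min=0.0, max=1.0)

            def resid(p):
                a = p["a0"].value
                return (a * np.exp(-t / p["tau0"].value)
                        + (1 - a) * np.exp(-t / p["tau1"].value)) - surv

        res = lmfit.minimize(resid, params, method="leastsq")
        return res, float(np.sum(res.residual**2))

    res1, rss1 = fit_k(1)
    if max_components < 2:
        tau1 = res1.params["tau0"].value
        return DwellDecayFit(1, np.array([1.0]), np.array([tau1]), tau1, 1.0, rss1)
    res2, rss2 = fit_k(2)
    rss2 = min(rss2, rss1)
    dof2 = len(t) - 3
    if dof2 <= 0 or rss2 <= 0:
        p = 1.0
    else:
        F = ((rss1 - rss2) / 2.0) / (rss2 / dof2)
        p = float(stats.f.sf(max(F, 0.0), 2, dof2))
    if p < 0.05:
        a0 = res2.params["a0"].value
        taus = np.array([res2.params["tau0"].value, res2.params["tau1"].value])
        amps = np.array([a0, 1.0 - a0])
        order = np.argsort(taus)
        taus, amps = taus[order], amps[order]
        return DwellDecayFit(2, amps, taus, float(np.sum(amps * taus)), p, rss2)
    tau1 = res1.params["tau0"].value
    return DwellDecayFit(1, np.array([1.0]), np.array([tau1]), tau1, p, rss1)


def _free_stretches(traj: Trajectory, events: list[DwellEvent]
                    ) -> list[tuple[int, int]]:
    """Index ranges (inclusive) between/around dwell events."""
    stretches = []
    prev_end = 0
    for ev in sorted(events, key=lambda e: e.start):
        if ev.start > prev_end:
            stretches.append((prev_end, ev.start))
        prev_end = ev.end
    if prev_end < len(traj) - 1:
        stretches.append((prev_end, len(traj) - 1))
    return stretches


def detect_transitions(traj: Trajectory, events: list[DwellEvent], R: float,
                       min_free_steps: int = 3) -> TransitionCounts:
    """Count confined<->free state changes.

    A non-confined stretch counts as a genuine free state only if it spans
    at least ``min_free_steps`` steps with mean step distance above R;
    shorter or slower stretches between dwell events emit no transition.
    """
    counts = TransitionCounts()
    if not events:
        return counts
    ev_sorted = sorted(events, key=lambda e: e.start)
    for a, b in _free_stretches(traj, ev_sorted):
        n_steps = int(traj.frames[b] - traj.frames[a])
        if n_steps < min_free_steps:
            continue
        d = np.diff(traj.xy[a : b + 1], axis=0)
        r = np.hypot(d[:, 0], d[:, 1])
        r = r[traj.consecutive_mask[a:b]]
        if len(r) == 0 or r.mean() <= R:
            continue
        preceded = any(ev.end == a for ev in ev_sorted)
        followed = any(ev.start == b for ev in ev_sorted)
        if preceded:
            counts.confined_to_free += 1
        if followed:
            counts.free_to_confined += 1
    return counts


def transition_summary(dataset: TrackDataset, cfg: ConfinementConfig,
                       min_free_steps: int = 3) -> pd.DataFrame:
    """Per-track-length transition counts and probabilities."""
    rows = []
    tau = dataset.meta.interval_time
    for t in dataset:
        events = _with_times(detect_dwell_events(t, cfg), tau)
        tc = detect_transitions(t, events, cfg.radius, min_free_steps)
        rows.append({
            "track_id": t.track_id,
            "track_steps": int(t.frames[-1] - t.frames[0]),
            "confined_to_free": tc.confined_to_free,
            "free_to_confined": tc.free_to_confined,
        })
    df = pd.DataFrame(rows)
    agg = df.groupby("track_steps").agg(
        n_tracks=("track_id", "count"),
        confined_to_free=("confined_to_free", "sum"),
        free_to_confined=("free_to_confined", "sum"),
    ).reset_index()
    agg["p_transition"] = (
        (agg["confined_to_free"] + agg["free_to_confined"]) / agg["n_tracks"]
    )
    return agg
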