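"""Independent brute-force oracles used by the test suite.

The dwell-event oracle enumerates every (centre, start, end) window triple
and validates each window from scratch against the confinement rules, so
it shares no search logic with the greedy detector it checks.
"""

from __future__ import annotations

import numpy as np

from sptconfine.confinement import ConfinementConfig
from sptconfine.core import Trajectory


def _window_steps(traj: Trajectory, idx: np.ndarray, c: int, s: int, e: int,
                  cfg: ConfinementConfig) -> int | None:
    """Steps spanned by window [s, e] (positions within segment ``idx``)
    centred on node c, or None if the window violates any rule."""
    frames = traj.frames[idx]
    xy = traj.xy[idx]
    center = xy[c]

    def inside(j: int) -> bool:
        d = xy[j] - center
        return float(d @ d) <= cfg.radius**2

    if not inside(s) or not inside(e):
        return None
    gaps = 0
    for j in range(s, e):
        df = frames[j + 1] - frames[j]
        if df == 1:
            continue
        if df == 2:
            gaps += 1
        else:
            return None
    outliers = 0
    for j in range(s + 1, e):
        if not inside(j):
            outliers += 1
            # must return inside on the very next frame
            if not inside(j + 1) or frames[j + 1] - frames[j] != 1:
                return None
    if gaps > 1 or outliers > 1:
        return None
    if not cfg.combine_gap_outlier and gaps + outliers > 1:
        return None
    steps = int(frames[e] - frames[s])
    if steps < cfg.min_steps:
        return None
    return steps


def oracle_dwell_events(traj: Trajectory, cfg: ConfinementConfig
                        ) -> list[tuple[int, int, int]]:
    """Exhaustive greedy reference: returns (start, end, steps) per event
    in temporal order, using full enumeration for the best window."""
    events = []
    segments = [np.arange(len(traj))]
    while segments:
        idx = segments.pop()
        if len(idx) < 2:
            continue
        best = None  # (key, s, e)
        for c in range(len(idx)):
            for s in range(len(idx)):
                for e in range(s + 1, len(idx)):
                    steps = _window_steps(traj, idx, c, s, e, cfg)
                    if steps is None:
                        continue
                    key = (-steps, s, c)
                    if best is None or key < best[0]:
                        best = (key, s, e)
        if best is None:
            continue
        _, s, e = best
        events.append((int(idx[s]), int(idx[e]),
                       int(traj.frames[idx[e]] - traj.frames[idx[s]])))
        segments.append(idx[:s])
        segments.append(idx[e + 1 :])
    return sorted(events)


def rayleigh_mle_D(r: np.ndarray, tau: float) -> float:
    """Closed-form single-Rayleigh scale MLE: D = mean(r^2) / (4 tau)."""
    return float(np.mean(np.asarray(r) ** 2) / (4.0 * tau))
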