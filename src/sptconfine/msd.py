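"""Mean-squared-displacement analysis and per-trajectory motion classification.

For 2-D Brownian motion the MSD grows linearly, <r^2(t)> = 4 D t; anomalous
diffusion generalizes this to a power law, <r^2(t)> = 4 K_alpha t^alpha with
0 < alpha <= 2 and no additive offset.  A trajectory is called Brownian,
subdiffusive (alpha < 1), superdiffusive (1 < alpha < 2) or directed
(alpha = 2) depending on the exponent and on whether a nested-model F-test
rejects the fixed-alpha = 1 fit.

Localization error: with isotropic static localization noise of per-axis SD
sigma, the apparent MSD gains a constant offset 4 sigma^2, so the ordinate
intercept of a linear fit over the first lags estimates sigma as
sqrt(intercept / 4) (clamped at zero).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

from .core import AcquisitionMeta, TrackDataset, Trajectory

__all__ = [
    "MSDCurve",
    "LinearMSDFit",
    "LocalizationError",
    "AnomalousFit",
    "MotionClass",
    "MotionCensus",
    "tamsd",
    "eamsd",
    "fit_linear_msd",
    "estimate_localization_error",
    "fit_anomalous",
    "classify_motion",
    "motion_census",
]

_ALPHA_LO = 1e-3
_ALPHA_HI = 2.0
_BOUND_TOL = 1e-3


@dataclass
class MSDCurve:
    """MSD versus lag time.

    ``lags`` are in seconds (multiples of the frame interval), ``msd`` the
    mean squared displacement per lag (um^2), ``sd`` the standard deviation
    of the squared displacements entering each lag, ``n_pairs`` the number
    of displacement pairs per lag.  ``truncated`` is set when fewer lags
    than requested were available.
    """

    lags: np.ndarray
    msd: np.ndarray
    sd: np.ndarray
    n_pairs: np.ndarray
    truncated: bool = False

    def __len__(self) -> int:
        return len(self.lags)


@dataclass(frozen=True)
class LinearMSDFit:
    D: float  # um^2/s
    intercept: float  # um^2
    r_value: float
    n_lags_used: int


@dataclass(frozen=True)
class LocalizationError:
    per_track_sigma: np.ndarray  # um
    mean_sigma: float  # um


@dataclass(frozen=True)
class AnomalousFit:
    K_alpha: float  # um^2/s^alpha
    alpha: float
    rss: float
    r2: float
    at_bound: str | None = None  # 'lower' | 'upper' | None
    converged: bool = True


@dataclass(frozen=True)
class MotionClass:
    category: str  # brownian | subdiffusive | superdiffusive | directed
    fit: AnomalousFit
    p_value: float


@dataclass
class MotionCensus:
    fractions: dict[str, float]
    counts: dict[str, int]
    alphas: np.ndarray
    r2s: np.ndarray
    n_classified: int


def _squared_displacements(traj: Trajectory, lag: int,
                           overlap: bool = True) -> np.ndarray:
    """Squared displacements between localizations whose frames differ by
    exactly ``lag`` (frame gaps simply contribute no pair).

    With ``overlap`` every admissible (i, j) pair enters; otherwise pairs
    are chained into disjoint windows (i, i+lag, i+2*lag, ...), giving
    approximately independent displacements at the cost of fewer of them.
    """
    f = traj.frames
    target = f + lag
    j = np.searchsorted(f, target)
    ok = j < len(f)
    ok[ok] &= f[j[ok]] == target[ok]
    i = np.nonzero(ok)[0]
    if not overlap and len(i):
        keep = []
        next_allowed = -1
        for idx, jdx in zip(i, j[i]):
            if idx >= next_allowed:
                keep.append(idx)
                next_allowed = jdx
        i = np.array(keep, dtype=int)
    d = traj.xy[j[i]] - traj.xy[i]
    return np.einsum("ij,ij->i", d, d)


def tamsd(traj: Trajectory, max_lag: int, meta: AcquisitionMeta | None = None,
          overlap: bool = True) -> MSDCurve:
    """Time-averaged MSD of a single trajectory.

    ``overlap=True`` uses every (i, i+k) pair (the standard estimator);
    ``overlap=False`` uses disjoint windows only, which is preferable when
    the curve feeds a significance test that assumes independent points.
    """
    meta = meta or AcquisitionMeta()
    if max_lag < 1:
        raise ValueError("max_lag must be >= 1")
    span = int(traj.frames[-1] - traj.frames[0])
    truncated = max_lag > span
    lags, msd, sd, n_pairs = [], [], [], []
    for k in range(1, min(max_lag, span) + 1):
        sq = _squared_displacements(traj, k, overlap)
        if len(sq) == 0:
            continue
        lags.append(k * meta.interval_time)
        msd.append(sq.mean())
        sd.append(sq.std(ddof=0))
        n_pairs.append(len(sq))
    if not lags:
        raise ValueError(f"track {traj.track_id!r}: no displacement pairs")
    return MSDCurve(np.array(lags), np.array(msd), np.array(sd),
                    np.array(n_pairs, dtype=int), truncated)


def eamsd(dataset: TrackDataset, max_lag: int) -> MSDCurve:
    """Ensemble-averaged MSD: squared displacements pooled across all
    trajectories per lag, then averaged."""
    if len(dataset) == 0:
        raise ValueError("empty dataset")
    tau = dataset.meta.interval_time
    lags, msd, sd, n_pairs = [], [], [], []
    for k in range(1, max_lag + 1):
        pooled = [
            _squared_displacements(t, k) for t in dataset
            if t.frames[-1] - t.frames[0] >= k
        ]
        sq = np.concatenate(pooled) if pooled else np.array([])
        if len(sq) == 0:
            continue
        lags.append(k * tau)
        msd.append(sq.mean())
        sd.append(sq.std(ddof=0))
        n_pairs.append(len(sq))
    if not lags:
        raise ValueError("no displacement pairs at any requested lag")
    return MSDCurve(np.array(lags), np.array(msd), np.array(sd),
                    np.array(n_pairs, dtype=int), len(lags) < max_lag)


def fit_linear_msd(curve: MSDCurve, n_lags: int = 5) -> LinearMSDFit:
    """Ordinary least squares of MSD vs lag over the first ``n_lags`` points;
    D = slope / 4 for 2-D motion."""
    if len(curve) < n_lags:
        raise ValueError(f"curve has {len(curve)} lags, need {n_lags}")
    t = curve.lags[:n_lags]
    y = curve.msd[:n_lags]
    if np.ptp(t) == 0:
        raise ValueError("degenerate lag axis")
    res = stats.linregress(t, y)
    return LinearMSDFit(res.slope / 4.0, res.intercept, res.rvalue, n_lags)


def estimate_localization_error(dataset: TrackDataset, n_lags: int = 5) -> LocalizationError:
    """Estimate the mean localization error from per-track TAMSD intercepts.

    For each track with at least ``n_lags`` available lags, a linear fit
    over the first ``n_lags`` TAMSD points yields an ordinate intercept;
    sigma = sqrt(max(intercept, 0) / 4).  The dataset value is the mean
    over tracks.
    """
    sigmas = []
    n_negative = 0
    for t in dataset:
        try:
            curve = tamsd(t, n_lags, dataset.meta)
        except ValueError:
            continue
        if len(curve) < n_lags:
            continue
        fit = fit_linear_msd(curve, n_lags)
        if fit.intercept < 0:
            n_negative += 1
        sigmas.append(np.sqrt(max(fit.intercept, 0.0) / 4.0))
    if not sigmas:
        raise ValueError("no tracks with enough lags for localization-error estimation")
    sigmas = np.array(sigmas)
    if n_negative == len(sigmas):
        warnings.warn("all TAMSD intercepts negative; mean localization error clamps to 0",
                      stacklevel=2)
    return LocalizationError(sigmas, float(sigmas.mean()))


def _power_law_rss(alpha: float, t: np.ndarray, y: np.ndarray,
                   w: np.ndarray) -> tuple[float, float]:
    """Profiled residual sum of squares of y ~ 4 K t^alpha at fixed alpha.

    The amplitude has a weighted closed form, K = sum(w x y) / sum(w x^2)
    with x = 4 t^alpha, clipped at zero; returns (rss, K).
    """
    x = 4.0 * t ** alpha
    denom = np.sum(w * x * x)
    K = max(np.sum(w * x * y) / denom, 0.0) if denom > 0 else 0.0
    r = y - K * x
    return float(np.sum(w * r * r)), K


def fit_anomalous(curve: MSDCurve, weighted: bool = False,
                  fix_alpha: float | None = None) -> AnomalousFit:
    """Fit MSD = 4 K_alpha t^alpha with alpha bounded to (0, 2].

    Bounded least squares with the amplitude profiled out (closed form at
    each alpha) and a scalar bounded minimization over alpha; no additive
    offset term.  When ``weighted``, residuals are divided by the per-lag
    standard deviation of the squared displacements.
    """
    if len(curve) < 4 and fix_alpha is None:
        raise ValueError("need at least 4 lags for a free-exponent fit")
    t, y = curve.lags, curve.msd
    if weighted:
        sd = np.where(curve.sd > 0, curve.sd, np.max(curve.sd) or 1.0)
        w = 1.0 / sd**2
    else:
        w = np.ones_like(y)

    if fix_alpha is not None:
        rss, K = _power_law_rss(fix_alpha, t, y, w)
        return _finish_fit(K, fix_alpha, rss, y, w, at_bound=None)

    res = optimize.minimize_scalar(
        lambda a: _power_law_rss(a, t, y, w)[0],
        bounds=(_ALPHA_LO, _ALPHA_HI), method="bounded",
        options={"xatol": 1e-6},
    )
    # keep the exact Brownian point and both bounds as explicit candidates
    candidates = [float(res.x), 1.0, _ALPHA_LO, _ALPHA_HI]
    rss_all = [(_power_law_rss(a, t, y, w)[0], a) for a in candidates]
    rss, alpha = min(rss_all)
    _, K = _power_law_rss(alpha, t, y, w)
    at_bound = ("lower" if alpha <= _ALPHA_LO * (1 + 1e-9)
                else "upper" if alpha >= _ALPHA_HI - _BOUND_TOL else None)
    return _finish_fit(K, alpha, rss, y, w, at_bound, converged=bool(res.success))


def _finish_fit(K: float, alpha: float, rss: float, y: np.ndarray,
                w: np.ndarray, at_bound: str | None, converged: bool = True) -> AnomalousFit:
    tss = float(np.sum(w * (y - np.average(y, weights=w)) ** 2))
    r2 = 1.0 - rss / tss if tss > 0 else 1.0
    return AnomalousFit(K, alpha, rss, r2, at_bound, converged)


def classify_motion(traj: Trajectory, min_steps: int = 9, conf: float = 0.1,
                    meta: AcquisitionMeta | None = None,
                    weighted: bool = False, loc_error_offset: float = 0.0,
                    overlap: bool = False) -> MotionClass:
    """Classify one trajectory as Brownian / sub- / superdiffusive / directed.

    The TAMSD over the first ``min_steps`` lags is fitted twice: with the
    exponent fixed at 1 (Brownian) and with it free in (0, 2].  The nested
    F statistic F = (RSS1 - RSS2) / (RSS2 / (m - 2)) with m fitted points
    decides: if p >= ``conf`` the track is Brownian regardless of the free
    exponent; otherwise the exponent's position determines the category,
    with the alpha = 2 bound labelled directed.

    By default the TAMSD uses disjoint (non-overlapping) windows — the
    F-test assumes roughly independent points, and overlapping-window TAMSD
    values of short tracks are correlated enough to reject most genuinely
    Brownian trajectories.  ``loc_error_offset`` (um^2, typically
    4 sigma_loc^2 from the dataset's localization-error estimate) is
    subtracted from the curve before fitting because neither nested model
    carries an offset term and static noise otherwise mimics subdiffusion.
    """
    meta = meta or AcquisitionMeta()
    if traj.n_steps < min_steps:
        raise ValueError(
            f"track {traj.track_id!r}: {traj.n_steps} consecutive steps < {min_steps}"
        )
    curve = tamsd(traj, min_steps, meta, overlap=overlap)
    if loc_error_offset:
        curve = MSDCurve(curve.lags, np.maximum(curve.msd - loc_error_offset, 1e-12),
                         curve.sd, curve.n_pairs, curve.truncated)
    m = len(curve)
    if m < 4:
        raise ValueError(f"track {traj.track_id!r}: only {m} usable lags")
    fixed = fit_anomalous(curve, weighted=weighted, fix_alpha=1.0)
    free = fit_anomalous(curve, weighted=weighted)
    rss2 = min(free.rss, fixed.rss)
    if rss2 <= 0:
        p = 1.0 if free.rss >= fixed.rss else 0.0
    else:
        F = (fixed.rss - rss2) / (rss2 / (m - 2))
        p = float(stats.f.sf(max(F, 0.0), 1, m - 2))
    if p >= conf:
        category = "brownian"
    elif free.alpha < 1.0:
        category = "subdiffusive"
    elif free.at_bound == "upper":
        category = "directed"
    else:
        category = "superdiffusive"
    return MotionClass(category, free, p)


def motion_census(dataset: TrackDataset, min_steps: int = 9,
                  conf: float = 0.1, weighted: bool = False,
                  correct_loc_error: bool = True,
                  overlap: bool = False) -> MotionCensus:
    """Classify every sufficiently long trajectory and tabulate proportions.

    With ``correct_loc_error`` the dataset-mean localization error (5-lag
    TAMSD intercepts over all eligible tracks) is estimated first and its
    MSD offset 4 sigma^2 removed from every curve before classification.
    """
    offset = 0.0
    if correct_loc_error:
        try:
            offset = 4.0 * estimate_localization_error(dataset).mean_sigma ** 2
        except ValueError:
            offset = 0.0
    counts = {c: 0 for c in ("brownian", "subdiffusive", "superdiffusive", "directed")}
    alphas, r2s = [], []
    for t in dataset:
        if t.n_steps < min_steps:
            continue
        mc = classify_motion(t, min_steps, conf, dataset.meta, weighted,
                             loc_error_offset=offset, overlap=overlap)
        counts[mc.category] += 1
        alphas.append(mc.fit.alpha)
        r2s.append(mc.fit.r2)
    n = sum(counts.values())
    if n == 0:
        raise ValueError("no classifiable trajectories after the length filter")
    fractions = {c: counts[c] / n for c in counts}
    return MotionCensus(fractions, counts, np.array(alphas), np.array(r2s), n)
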