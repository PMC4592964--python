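"""Trajectory validation statistics and device-performance summaries.

The central validation quantity is the relative axial displacement
statistic: each particle's axial coordinate W_i(t) (measured from the
inlet-end reference plane) is scaled by the ensemble-time maximum W_max,
and the standard deviation over time of w_i(t) - w_i(0) measures how far
the particle departs from perfect axial stationarity.  In a well-operated
rolling tank the maximum across particles stays below a fraction of a
percent over a 30-s observation window.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

from .dynamics import Trajectory

__all__ = [
    "DisplacementStat",
    "OrbitFit",
    "RetentionSummary",
    "axial_displacement_stat",
    "orbit_fit",
    "fit_circle",
    "path_rms_distance",
    "retention_summary",
]


@dataclass
class DisplacementStat:
    """Relative axial displacement ensemble and its dispersion summary.

    ``relative`` is (n_particles, n_samples) of w_i(t) = W_i(t)/W_max;
    ``per_particle_std`` the std over time of w_i(t) - w_i(0); ``max_std``
    the maximum across particles (dimensionless; ``max_std_percent`` in %).
    """

    times: np.ndarray
    relative: np.ndarray
    w_max: float
    per_particle_std: np.ndarray
    max_std: float
    pooled_std: float
    window_s: float
    sample_interval_s: float

    @property
    def n_particles(self) -> int:
        return self.relative.shape[0]

    @property
    def max_std_percent(self) -> float:
        return 100.0 * self.max_std

    def to_dict(self) -> dict:
        return {
            "max_std_percent": self.max_std_percent,
            "pooled_std_percent": 100.0 * self.pooled_std,
            "per_particle_std": (100.0 * self.per_particle_std).tolist(),
            "n_particles": self.n_particles,
            "window_s": self.window_s,
            "sample_interval_s": self.sample_interval_s,
            "w_max_m": self.w_max,
        }


def axial_displacement_stat(
    trajectories: list[Trajectory],
    window_s: float = 30.0,
    sample_interval_s: float = 1.0,
    mode: str = "per_particle",
) -> DisplacementStat:
    """Axial stationarity statistic of an ensemble.

    Samples each trajectory's axial coordinate on a common grid
    ``0, dt, ..., window_s`` (linear interpolation), normalises by the
    ensemble-time maximum, and reports the per-particle standard deviation
    (population, ddof=0) of the deviation from the initial relative
    displacement.  ``mode="pooled"`` makes ``max_std`` the pooled std of
    all deviations instead of the per-particle maximum.
    """
    if not trajectories:
        raise ValueError("empty trajectory ensemble")
    if mode not in ("per_particle", "pooled"):
        raise ValueError(f"unknown mode {mode!r}")
    times = np.arange(0.0, window_s + 0.5 * sample_interval_s, sample_interval_s)
    if len(times) < 2:
        raise ValueError("need at least 2 samples in the window")
    W = np.empty((len(trajectories), len(times)))
    for i, tr in enumerate(trajectories):
        if tr.times[-1] < window_s - 1e-9:
            raise ValueError(
                f"trajectory {i} ends at {tr.times[-1]:.3g} s, before the "
                f"{window_s} s window"
            )
        W[i] = np.interp(times, tr.times, tr.positions[:, 2])
    w_max = float(np.max(W))
    if w_max <= 0:
        raise ValueError("W_max must be positive (axial coordinates non-positive)")
    w = W / w_max
    dev = w - w[:, :1]
    per_std = dev.std(axis=1, ddof=0)
    pooled = float(dev.std(ddof=0))
    max_std = float(per_std.max()) if mode == "per_particle" else pooled
    return DisplacementStat(
        times=times,
        relative=w,
        w_max=w_max,
        per_particle_std=per_std,
        max_std=max_std,
        pooled_std=pooled,
        window_s=window_s,
        sample_interval_s=sample_interval_s,
    )


def fit_circle(xy: np.ndarray) -> tuple[np.ndarray, float]:
    """Least-squares circle through 2-D points: (center (2,), radius).

    Algebraic (Kasa) fit refined by geometric least squares.
    """
    xy = np.asarray(xy, dtype=float)
    if len(xy) < 3:
        raise ValueError("need at least 3 points to fit a circle")
    x, y = xy[:, 0], xy[:, 1]
    A = np.column_stack([2.0 * x, 2.0 * y, np.ones_like(x)])
    b = x * x + y * y
    sol, *_ = np.linalg.lstsq(A, b, rcond=None)
    cx, cy = sol[0], sol[1]
    r = math.sqrt(max(sol[2] + cx * cx + cy * cy, 0.0))

    def resid(p):
        return np.hypot(x - p[0], y - p[1]) - p[2]

    out = least_squares(resid, [cx, cy, r], method="lm")
    cx, cy, r = out.x
    return np.array([cx, cy]), float(abs(r))


@dataclass
class OrbitFit:
    """Per-period circle fits of an x-y orbit."""

    center: np.ndarray  # (2,) mean orbit centre, m
    radius: float  # mean orbit radius, m
    drift_rate: float  # linear slope of per-period radius, m/s
    period_centers: np.ndarray = field(repr=False, default=None)
    period_radii: np.ndarray = field(repr=False, default=None)
    period_times: np.ndarray = field(repr=False, default=None)


def orbit_fit(trajectory: Trajectory, period_s: float) -> OrbitFit:
    """Fit the x-y orbit of a rotating-tank trajectory period by period.

    Requires at least one full rotation period of samples (and >= 8
    samples).  ``drift_rate`` is the slope of the per-period radius versus
    the period's mid time; with a single complete period it is 0.
    """
    t = trajectory.times
    if len(t) < 8:
        raise ValueError("need at least 8 samples for an orbit fit")
    if t[-1] - t[0] < period_s:
        raise ValueError("trajectory shorter than one rotation period")
    centers, radii, mids = [], [], []
    t0 = t[0]
    while t0 + period_s <= t[-1] + 1e-9:
        mask = (t >= t0) & (t <= t0 + period_s)
        if mask.sum() >= 3:
            c, r = fit_circle(trajectory.positions[mask, :2])
            centers.append(c)
            radii.append(r)
            mids.append(t0 + 0.5 * period_s)
        t0 += period_s
    centers = np.array(centers)
    radii = np.array(radii)
    mids = np.array(mids)
    drift = float(np.polyfit(mids, radii, 1)[0]) if len(radii) >= 2 else 0.0
    return OrbitFit(
        center=centers.mean(axis=0),
        radius=float(radii.mean()),
        drift_rate=drift,
        period_centers=centers,
        period_radii=radii,
        period_times=mids,
    )


def path_rms_distance(traj_a: Trajectory, traj_b: Trajectory, resample_n: int = 200) -> float:
    """RMS pointwise distance between two paths over their common time range."""
    t_lo = max(traj_a.times[0], traj_b.times[0])
    t_hi = min(traj_a.times[-1], traj_b.times[-1])
    if t_hi <= t_lo:
        raise ValueError("trajectories have disjoint time ranges")
    t = np.linspace(t_lo, t_hi, resample_n)
    d = traj_a.position_at(t) - traj_b.position_at(t)
    return float(np.sqrt(np.mean(np.sum(d * d, axis=1))))


@dataclass
class RetentionSummary:
    """Ensemble termination fractions and residence-time quantiles."""

    fractions: dict
    residence_quantiles_s: dict
    n_trajectories: int
    exchange_time_s: float | None = None

    def to_dict(self) -> dict:
        return {
            "fractions": self.fractions,
            "residence_quantiles_s": self.residence_quantiles_s,
            "n_trajectories": self.n_trajectories,
            "exchange_time_s": self.exchange_time_s,
        }


def retention_summary(
    ensemble: list[Trajectory], geometry=None, quantiles=(0.25, 0.5, 0.75)
) -> RetentionSummary:
    """Status fractions and residence times of a simulated ensemble.

    Residence quantiles are over the trajectories that terminated (wall
    contact or outlet exit); interior trajectories are censored at t_max.
    If *geometry* is given and has through-flow, the full-volume water
    exchange time V/Q is reported alongside.
    """
    if not ensemble:
        raise ValueError("empty trajectory ensemble")
    statuses = [tr.status for tr in ensemble]
    n = len(ensemble)
    fractions = {
        s: statuses.count(s) / n for s in ("interior", "wall_contact", "exited_outlet")
    }
    ended = [float(tr.times[-1]) for tr in ensemble if tr.status != "interior"]
    rq = (
        {f"q{int(100 * q)}": float(np.quantile(ended, q)) for q in quantiles}
        if ended
        else {}
    )
    exchange = None
    if geometry is not None and geometry.flow_rate > 0:
        exchange = geometry.volume / geometry.flow_rate
    return RetentionSummary(
        fractions=fractions,
        residence_quantiles_s=rq,
        n_trajectories=n,
        exchange_time_s=exchange,
    )
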