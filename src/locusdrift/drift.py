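"""Spatiotemporal drift-velocity profiles, equilibria and occupancy maps.

The drift-velocity profile v(x) bins frame-to-frame steps by their start
position and reports the mean step per unit time in each bin.  Zero
crossings of v(x) with negative slope are stable equilibria of the motion
(a restoring, spring-like drift); the negative reciprocal slope, corrected
for the finite sampling interval, is the relaxation time of the spring.
Before the splitting event the profile has a single stable equilibrium at
mid-cell; immediately after, mid-cell becomes unstable and stable
equilibria appear at the quarter-cell positions.
"""
from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .steps import StepEnsemble, compute_steps
from .tracks import IntervalScheme, TrackEnsemble


@dataclass
class DriftProfile:
    """Binned drift velocity versus relative position.

    ``x_center`` are geometric bin centres; ``x_mean`` the mean start
    position of the steps in each bin, which is the correct abscissa for
    slope fits and conditional-mean comparisons when occupancy varies
    across a bin.  Bins with fewer than ``min_count`` steps are reported
    but flagged unpopulated, never as zero velocity.
    """

    x_center: np.ndarray
    x_mean: np.ndarray
    v: np.ndarray  # relative units / min
    se: np.ndarray
    n: np.ndarray
    bin_width: float
    min_count: int
    interval: str | None
    dt_eff: float
    selection: str

    @property
    def populated(self) -> np.ndarray:
        return self.n >= self.min_count

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "x_bin": self.x_center,
                "x_mean": self.x_mean,
                "v": self.v,
                "se": self.se,
                "n": self.n,
                "populated": self.populated,
            }
        )


@dataclass
class Equilibrium:
    position: float
    slope: float  # d v / d x at the crossing, 1/min
    stable: bool
    tau: float | None  # relaxation time (min) for stable equilibria
    tau_se: float | None


@dataclass
class EquilibriumSet:
    equilibria: list[Equilibrium]

    @property
    def stable(self) -> list[Equilibrium]:
        return [e for e in self.equilibria if e.stable]

    def __len__(self) -> int:
        return len(self.equilibria)


@dataclass
class RelaxationFit:
    tau: float  # minutes
    tau_se: float
    slope: float
    slope_se: float
    n_bins: int
    x_eq: float


def compute_drift_profile(
    ensemble: TrackEnsemble,
    interval: str | None = None,
    bin_width: float = 0.05,
    min_count: int = 25,
    lag: int = 1,
    selection: str = "both",
    scheme: IntervalScheme | None = None,
    steps: StepEnsemble | None = None,
) -> DriftProfile:
    """Bin steps by start position; v(x) = <dx>/dt per bin, SE = sd/sqrt(n)/dt.

    ``selection`` follows :func:`locusdrift.steps.compute_steps`; the
    default pools both post-split foci unmodified, ``"mirror"`` reflects
    the left-destined focus for a pooled single-equilibrium profile.
    A precomputed :class:`StepEnsemble` can be passed to skip extraction.
    """
    if steps is None:
        steps = compute_steps(ensemble, interval, lag=lag, selection=selection, scheme=scheme)
    tab = steps.table
    if tab.empty:
        raise ValueError("insufficient occupancy: no steps in the interval")
    x = tab["x_start"].to_numpy()
    dx = tab["dx"].to_numpy()
    i0 = int(np.floor(x.min() / bin_width))
    idx = np.floor(x / bin_width).astype(int) - i0
    n_bins = idx.max() + 1
    n = np.bincount(idx, minlength=n_bins).astype(float)
    sum_dx = np.bincount(idx, weights=dx, minlength=n_bins)
    sum_dx2 = np.bincount(idx, weights=dx**2, minlength=n_bins)
    sum_x = np.bincount(idx, weights=x, minlength=n_bins)
    with np.errstate(invalid="ignore", divide="ignore"):
        mean_dx = sum_dx / n
        var_dx = np.maximum(sum_dx2 / n - mean_dx**2, 0.0) * n / np.maximum(n - 1, 1)
        v = mean_dx / steps.dt_eff
        se = np.sqrt(var_dx / n) / steps.dt_eff
        x_mean = sum_x / n
    centers = (np.arange(n_bins) + i0 + 0.5) * bin_width
    profile = DriftProfile(
        x_center=centers,
        x_mean=x_mean,
        v=v,
        se=se,
        n=n.astype(int),
        bin_width=bin_width,
        min_count=min_count,
        interval=interval,
        dt_eff=steps.dt_eff,
        selection=steps.selection,
    )
    if not profile.populated.any():
        raise ValueError(
            f"insufficient occupancy: no bin reaches min_count = {min_count}"
        )
    return profile


def _invert_discrete_slope(slope: float, dt: float) -> float:
    """Relaxation time from the slope of v(x).

    A spring with relaxation time tau observed at interval dt yields the
    discrete slope s = -(1 - exp(-dt/tau))/dt, so tau = -dt/log(1 + s*dt);
    this reduces to tau = -1/s as dt -> 0.
    """
    arg = 1.0 + slope * dt
    if arg <= 0:
        raise ValueError(
            f"slope {slope:.4g} too steep to invert at dt = {dt} (relaxation "
            "faster than the sampling interval)"
        )
    return -dt / math.log(arg)


def _weighted_slope(
    x: np.ndarray, v: np.ndarray, se: np.ndarray
) -> tuple[float, float]:
    w = 1.0 / np.maximum(se, 1e-12) ** 2
    xb = np.average(x, weights=w)
    vb = np.average(v, weights=w)
    sxx = np.sum(w * (x - xb) ** 2)
    slope = float(np.sum(w * (x - xb) * (v - vb)) / sxx)
    return slope, float(1.0 / np.sqrt(sxx))


def fit_relaxation_time(
    profile: DriftProfile, x_eq: float = 0.0, window: float = 0.15
) -> RelaxationFit:
    """Relaxation time from the local slope of v(x) around an equilibrium.

    Weighted (1/SE^2) linear fit of v against the per-bin mean position
    over populated bins with |x - x_eq| <= window, then the finite-dt
    slope inversion.  The slope must be negative (restoring drift).
    """
    ok = profile.populated & (np.abs(profile.x_mean - x_eq) <= window)
    if ok.sum() < 3:
        raise ValueError(
            f"need >= 3 populated bins within {window} of x_eq = {x_eq}, "
            f"have {int(ok.sum())}"
        )
    slope, slope_se = _weighted_slope(
        profile.x_mean[ok], profile.v[ok], profile.se[ok]
    )
    if slope >= 0:
        raise ValueError(f"not a restoring profile: slope = {slope:.4g} >= 0")
    dt = profile.dt_eff
    tau = _invert_discrete_slope(slope, dt)
    arg = 1.0 + slope * dt
    dtau_dslope = dt**2 / (arg * math.log(arg) ** 2)
    return RelaxationFit(
        tau=tau,
        tau_se=float(abs(dtau_dslope) * slope_se),
        slope=slope,
        slope_se=slope_se,
        n_bins=int(ok.sum()),
        x_eq=x_eq,
    )


def find_equilibria(profile: DriftProfile, fit_window: float = 0.15) -> EquilibriumSet:
    """Zero crossings of v(x) between adjacent populated bins.

    The crossing position is linearly interpolated between the bracketing
    bins; the local slope comes from a weighted fit within ``fit_window``
    of the crossing.  Negative slope means a stable (restoring)
    equilibrium, for which the relaxation time is also reported; an empty
    set (no sign change) is a valid result.
    """
    ok = np.flatnonzero(profile.populated)
    out: list[Equilibrium] = []
    for a, b in zip(ok[:-1], ok[1:]):
        if b - a != 1:
            continue  # only adjacent populated bins may bracket a crossing
        va, vb = profile.v[a], profile.v[b]
        if va == 0.0 or va * vb >= 0:
            continue
        xa, xb = profile.x_mean[a], profile.x_mean[b]
        x0 = xa - va * (xb - xa) / (vb - va)
        sel = profile.populated & (np.abs(profile.x_mean - x0) <= fit_window)
        if sel.sum() >= 2:
            slope, slope_se = _weighted_slope(
                profile.x_mean[sel], profile.v[sel], profile.se[sel]
            )
        else:
            slope = (vb - va) / (xb - xa)
            slope_se = float("nan")
        stable = slope < 0
        tau = tau_se = None
        if stable:
            try:
                fit = fit_relaxation_time(profile, x_eq=float(x0), window=fit_window)
                tau, tau_se = fit.tau, fit.tau_se
            except ValueError:
                tau = _invert_discrete_slope(slope, profile.dt_eff)
        out.append(
            Equilibrium(position=float(x0), slope=slope, stable=stable,
                        tau=tau, tau_se=tau_se)
        )
    return EquilibriumSet(out)


@dataclass
class OccupancyMap:
    """Per-time-bin position histograms with mean trajectory and mode counts.

    ``occupancy`` rows (time bins) are normalized to sum to 1 where data
    exist and are NaN for empty time bins.  ``mean_traj`` and
    ``mode_counts`` are reported per focus group ("pre" for the single
    pre-split focus, "focus0"/"focus1" for the daughters), since the
    pooled post-split distribution is bimodal by construction while each
    focus should be unimodal at every time point.
    """

    time_edges: np.ndarray
    pos_edges: np.ndarray
    occupancy: np.ndarray  # (n_time_bins, n_pos_bins)
    mean_traj: pd.DataFrame  # time_center, group, mean_x, n
    mode_counts: pd.DataFrame  # time_center, group, n_modes


def _count_modes(hist: np.ndarray, rel_threshold: float = 0.05) -> int:
    k = np.convolve(hist, [0.25, 0.5, 0.25], mode="same")
    if k.max() <= 0:
        return 0
    floor = rel_threshold * k.max()
    pad = np.concatenate([[-np.inf], k, [-np.inf]])
    modes = 0
    i = 1
    while i <= len(k):
        if pad[i] > pad[i - 1] and pad[i] >= floor:
            j = i
            while j + 1 <= len(k) and pad[j + 1] == pad[i]:
                j += 1
            if pad[j + 1] < pad[i]:
                modes += 1
            i = j + 1
        else:
            i += 1
    return modes


def occupancy_map(
    ensemble: TrackEnsemble,
    time_bin: float = 5.0,
    pos_bin: float = 0.05,
) -> OccupancyMap:
    """Locus occupancy as time-since-split x relative-position histograms."""
    if not ensemble.synchronized:
        raise ValueError("occupancy map requires a synchronized ensemble")
    df = ensemble.data
    df = df[df["channel"] == ensemble.locus_channel]
    if df.empty:
        raise ValueError("no locus observations")
    t = df["t_min"].to_numpy()
    x = df["x_rel"].to_numpy()
    t0 = math.floor(t.min() / time_bin) * time_bin
    t1 = math.ceil((t.max() + 1e-9) / time_bin) * time_bin
    time_edges = np.arange(t0, t1 + time_bin / 2, time_bin)
    lo = min(-0.5, math.floor(x.min() / pos_bin) * pos_bin)
    hi = max(0.5, math.ceil(x.max() / pos_bin) * pos_bin)
    pos_edges = np.arange(lo, hi + pos_bin / 2, pos_bin)
    counts, _, _ = np.histogram2d(t, x, bins=[time_edges, pos_edges])
    row_sums = counts.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        occupancy = np.where(row_sums > 0, counts / np.maximum(row_sums, 1), np.nan)
    group = np.where(
        t < 0, "pre", np.char.add("focus", df["focus_id"].astype(int).astype(str))
    )
    gdf = pd.DataFrame({"t": t, "x": x, "group": group})
    gdf["time_center"] = (
        time_edges[np.clip(np.searchsorted(time_edges, gdf["t"], side="right") - 1,
                           0, len(time_edges) - 2)]
        + time_bin / 2
    )
    mean_traj = (
        gdf.groupby(["time_center", "group"])["x"]
        .agg(["mean", "size"])
        .reset_index()
        .rename(columns={"mean": "mean_x", "size": "n"})
    )
    rows = []
    for (tc, grp), sub in gdf.groupby(["time_center", "group"]):
        hist, _ = np.histogram(sub["x"], bins=pos_edges)
        rows.append({"time_center": tc, "group": grp, "n_modes": _count_modes(hist)})
    return OccupancyMap(
        time_edges=time_edges,
        pos_edges=pos_edges,
        occupancy=occupancy,
        mean_traj=mean_traj,
        mode_counts=pd.DataFrame(rows),
    )
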