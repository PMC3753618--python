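"""Ensemble mean-squared displacement and power-law scaling fits.

The MSD at lag tau, averaged over all tracks and all valid start times
within a cell-cycle interval, is fit as MSD(tau) ~ D * tau^alpha on log-log
axes.  The scaling exponent alpha distinguishes sub-diffusive (alpha < 1),
diffusive (alpha = 1) and processive/ballistic (alpha ~ 2) motion; D is the
generalized diffusion constant (the raw intercept, in (relative
units)^2 / min^alpha).
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from ._segments import iter_locus_segments
from .tracks import IntervalScheme, TrackEnsemble

log = logging.getLogger("locusdrift")


@dataclass
class MsdCurve:
    """MSD versus lag with pair counts; lag 0 is included (msd(0) = 0)."""

    lags: np.ndarray  # minutes
    msd: np.ndarray  # (relative units)^2
    n_pairs: np.ndarray
    interval: str | None
    dt: float
    # per-cell sums of squared displacements and pair counts, kept for
    # trajectory-level bootstrap; cells are the resampling unit because a
    # cell's daughter tracks are dependent.
    track_sq: np.ndarray | None = field(default=None, repr=False)
    track_n: np.ndarray | None = field(default=None, repr=False)


@dataclass
class PowerLawFit:
    """Least-squares line on log(msd) vs log(lag)."""

    alpha: float
    D_gen: float
    stderr_alpha: float
    lag_range: tuple[float, float]
    n_lags: int


def compute_msd(
    ensemble: TrackEnsemble,
    interval: str | None = None,
    max_lag: float = 10.0,
    scheme: IntervalScheme | None = None,
    post_split_start: float = 1.0,
) -> MsdCurve:
    """Combined time-and-ensemble MSD over the interval window.

    MSD(tau) averages (x(t + tau) - x(t))^2 over every track and every
    start time with both endpoints inside the window.  Post-split frames
    before ``post_split_start`` (default 1 min) are excluded because the
    precise split frame cannot be resolved.  Both daughter foci contribute
    after the split; displacements never span the branch point.
    """
    dt = ensemble.dt
    n_lag = int(round(max_lag / dt))
    cells: dict[str, int] = {}
    sq_rows: list[np.ndarray] = []
    n_rows: list[np.ndarray] = []
    for seg in iter_locus_segments(
        ensemble, interval, scheme, post_split_start=post_split_start
    ):
        if seg.cell_id not in cells:
            cells[seg.cell_id] = len(sq_rows)
            sq_rows.append(np.zeros(n_lag + 1))
            n_rows.append(np.zeros(n_lag + 1))
        i = cells[seg.cell_id]
        x = seg.x
        n_rows[i][0] += np.sum(~np.isnan(x))
        for k in range(1, min(n_lag, len(x) - 1) + 1):
            d = x[k:] - x[:-k]
            valid = ~np.isnan(d)
            sq_rows[i][k] += np.nansum(d[valid] ** 2)
            n_rows[i][k] += valid.sum()
    if not sq_rows:
        log.warning("no observations in interval %r; empty MSD curve", interval)
        sq = np.zeros((0, n_lag + 1))
        cnt = np.zeros((0, n_lag + 1))
    else:
        sq = np.vstack(sq_rows)
        cnt = np.vstack(n_rows)
    total_n = cnt.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        msd = np.where(total_n > 0, sq.sum(axis=0) / np.maximum(total_n, 1), np.nan)
    msd[0] = 0.0
    if n_lag >= 1 and total_n[1] == 0:
        log.warning("interval %r has no displacement pairs", interval)
    return MsdCurve(
        lags=np.arange(n_lag + 1) * dt,
        msd=msd,
        n_pairs=total_n,
        interval=interval,
        dt=dt,
        track_sq=sq,
        track_n=cnt,
    )


def _loglog_fit(lags: np.ndarray, msd: np.ndarray) -> tuple[float, float, float]:
    lx = np.log(lags)
    ly = np.log(msd)
    slope, intercept = np.polyfit(lx, ly, 1)
    resid = ly - (slope * lx + intercept)
    dof = len(lx) - 2
    if dof > 0:
        sxx = np.sum((lx - lx.mean()) ** 2)
        se = float(np.sqrt(resid @ resid / dof / sxx))
    else:
        se = 0.0
    return float(slope), float(intercept), se


def fit_power_law(
    curve: MsdCurve,
    lag_range: tuple[float, float] = (1.0, 10.0),
    n_boot: int = 1000,
    seed: int = 0,
) -> PowerLawFit:
    """Fit MSD(tau) = D * tau^alpha by least squares on log-log axes.

    Lags outside ``lag_range`` (minutes), with non-positive MSD or with no
    pairs are dropped; at least 3 usable lags are required.  The standard
    error of alpha comes from a bootstrap that resamples whole cells
    (``n_boot`` replicates) when per-track sums are available, falling back
    to the OLS slope error otherwise.
    """
    lo, hi = lag_range
    mask = (
        (curve.lags >= lo)
        & (curve.lags <= hi)
        & (curve.n_pairs > 0)
        & (curve.msd > 0)
    )
    if mask.sum() < 3:
        raise ValueError(
            f"need >= 3 positive MSD lags in range {lag_range}, have {int(mask.sum())}"
        )
    alpha, intercept, ols_se = _loglog_fit(curve.lags[mask], curve.msd[mask])
    stderr = ols_se
    if n_boot > 0 and curve.track_sq is not None and curve.track_sq.shape[0] > 1:
        rng = np.random.default_rng(seed)
        n_cells = curve.track_sq.shape[0]
        alphas = []
        for _ in range(n_boot):
            idx = rng.integers(0, n_cells, n_cells)
            s = curve.track_sq[idx].sum(axis=0)[mask]
            c = curve.track_n[idx].sum(axis=0)[mask]
            ok = c > 0
            if ok.sum() < 3:
                continue
            m = s[ok] / c[ok]
            if np.any(m <= 0):
                continue
            a, _, _ = _loglog_fit(curve.lags[mask][ok], m)
            alphas.append(a)
        if len(alphas) > 1:
            stderr = float(np.std(alphas, ddof=1))
    return PowerLawFit(
        alpha=alpha,
        D_gen=float(np.exp(intercept)),
        stderr_alpha=stderr,
        lag_range=(float(lo), float(hi)),
        n_lags=int(mask.sum()),
    )
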