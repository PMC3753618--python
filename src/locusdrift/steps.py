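"""Frame-to-frame step statistics per cell-cycle interval.

The step dx = x(t + lag*dt) - x(t) is the elementary observable behind the
drift-velocity map: its mean over an interval is the drift velocity
v = <dx>/dt, its variance the effective diffusion constant
D_eff = var(dx)/(2 dt).  The excess-tail statistic compares the empirical
step distribution against a Gaussian with matched mean and variance (the
step distribution of a pure diffusion-with-drift model), and the step
autocorrelation quantifies visco-elastic memory: anti-correlated successive
steps are the signature of sub-diffusive motion.
"""
from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from ._segments import iter_locus_segments
from .tracks import IntervalScheme, TrackEnsemble

log = logging.getLogger("locusdrift")

SELECTIONS = ("right", "left", "both", "mirror")


@dataclass
class StepEnsemble:
    """Steps over a fixed effective time interval, with provenance.

    ``table`` has one row per step: cell_id, focus_id, regime, t_start
    (minutes), x_start and dx.  ``selection`` records the post-split
    focus rule applied: "right" keeps only the right-destined focus (the
    convention used for the biased-step analysis), "left" its mirror
    image, "both" pools foci unmodified and "mirror" pools with the
    left-destined focus reflected (x -> -x, dx -> -dx), which doubles n
    without changing the mean under left/right symmetry.
    """

    table: pd.DataFrame
    dt_eff: float  # lag * dt, minutes
    interval: str | None
    selection: str
    lag: int

    @property
    def steps(self) -> np.ndarray:
        return self.table["dx"].to_numpy()

    def __len__(self) -> int:
        return len(self.table)


@dataclass
class StepSummary:
    v: float  # drift velocity, relative units / min
    v_se: float
    d_eff: float  # effective diffusion constant, (relative units)^2 / min
    d_eff_se: float
    n: int
    excess_tail: float  # at the default 2.5-sigma threshold
    excess_tail_max: float  # max over {2, 2.5, 3}-sigma thresholds
    lag1_autocorr: float
    dt_eff: float
    interval: str | None
    selection: str


@dataclass
class GaussianExcess:
    excess: float
    ci_low: float
    ci_high: float
    threshold_sd: float
    n: int


def compute_steps(
    ensemble: TrackEnsemble,
    interval: str | None = None,
    lag: int = 1,
    selection: str = "right",
    scheme: IntervalScheme | None = None,
) -> StepEnsemble:
    """Steps dx = x(t + lag*dt) - x(t) with both endpoints in the interval."""
    if lag < 1:
        raise ValueError("lag must be >= 1 frame")
    if selection not in SELECTIONS:
        raise ValueError(f"selection must be one of {SELECTIONS}")
    dt = ensemble.dt
    rows = []
    for seg in iter_locus_segments(ensemble, interval, scheme):
        x = seg.x
        if len(x) <= lag:
            continue
        if seg.regime == "post":
            if selection == "right" and seg.focus_id != 1:
                continue
            if selection == "left" and seg.focus_id != 0:
                continue
        sign = -1.0 if (
            selection == "mirror" and seg.regime == "post" and seg.focus_id == 0
        ) else 1.0
        dx = x[lag:] - x[:-lag]
        valid = ~np.isnan(dx)
        if not valid.any():
            continue
        t_start = (seg.frame0 + np.arange(len(x) - lag)[valid]) * dt
        rows.append(
            pd.DataFrame(
                {
                    "cell_id": seg.cell_id,
                    "focus_id": seg.focus_id,
                    "regime": seg.regime,
                    "t_start": t_start,
                    "x_start": sign * x[:-lag][valid],
                    "dx": sign * dx[valid],
                }
            )
        )
    if not rows:
        log.warning("empty step selection for interval %r", interval)
        table = pd.DataFrame(
            columns=["cell_id", "focus_id", "regime", "t_start", "x_start", "dx"]
        )
    else:
        table = pd.concat(rows, ignore_index=True)
    return StepEnsemble(
        table=table, dt_eff=lag * dt, interval=interval, selection=selection, lag=lag
    )


def _excess(x: np.ndarray, threshold_sd: float) -> float:
    mu, sigma = x.mean(), x.std(ddof=1)
    emp = float(np.mean(np.abs(x - mu) > threshold_sd * sigma))
    return emp - 2.0 * float(stats.norm.sf(threshold_sd))


def summarize_steps(steps: StepEnsemble, threshold_sd: float = 2.5) -> StepSummary:
    """Drift velocity, effective diffusion, excess tail and step memory."""
    x = steps.steps
    n = len(x)
    if n < 2:
        raise ValueError(f"need >= 2 steps, have {n}")
    dt = steps.dt_eff
    var = float(np.var(x, ddof=1))
    v = float(x.mean()) / dt
    v_se = float(np.sqrt(var / n)) / dt
    d_eff = var / (2.0 * dt)
    # normal-theory SE of a sample variance: var * sqrt(2 / (n - 1))
    d_eff_se = var * np.sqrt(2.0 / (n - 1)) / (2.0 * dt)
    excess = _excess(x, threshold_sd)
    excess_max = max(_excess(x, c) for c in (2.0, 2.5, 3.0))
    return StepSummary(
        v=v,
        v_se=v_se,
        d_eff=d_eff,
        d_eff_se=float(d_eff_se),
        n=n,
        excess_tail=excess,
        excess_tail_max=excess_max,
        lag1_autocorr=_lag1_autocorr(steps),
        dt_eff=dt,
        interval=steps.interval,
        selection=steps.selection,
    )


def _successive_pairs(steps: StepEnsemble, stride: int = 1) -> tuple[np.ndarray, np.ndarray]:
    """Pairs of steps from the same track separated by ``stride`` frames."""
    a_parts, b_parts = [], []
    dt = steps.dt_eff / steps.lag  # frame interval in minutes
    for _, g in steps.table.groupby(["cell_id", "focus_id", "regime"], sort=False):
        g = g.sort_values("t_start")
        t = g["t_start"].to_numpy()
        d = g["dx"].to_numpy()
        idx = np.round(t / dt).astype(int)  # start frame of each step
        lookup = dict(zip(idx.tolist(), range(len(t))))
        for i, j in lookup.items():
            k = lookup.get(i + stride)
            if k is not None:
                a_parts.append(d[j])
                b_parts.append(d[k])
    return np.asarray(a_parts), np.asarray(b_parts)


def _lag1_autocorr(steps: StepEnsemble) -> float:
    a, b = _successive_pairs(steps, stride=steps.lag)
    if len(a) < 2:
        return float("nan")
    return float(np.corrcoef(a, b)[0, 1])


def gaussian_excess(
    steps: StepEnsemble | np.ndarray,
    threshold_sd: float = 2.5,
    n_boot: int = 500,
    seed: int = 0,
) -> GaussianExcess:
    """Excess large-step probability relative to a matched Gaussian.

    Returns the empirical probability of |dx - mu| > threshold_sd * sigma
    minus the Gaussian tail mass beyond the same cut, with a bootstrap
    percentile confidence interval (95%).  A purely diffusive step
    distribution gives an excess compatible with zero.
    """
    x = steps.steps if isinstance(steps, StepEnsemble) else np.asarray(steps, float)
    n = len(x)
    if n < 2:
        raise ValueError("need >= 2 steps")
    if np.all(x == x[0]):
        raise ValueError("zero step variance: excess tail undefined")
    if n < 200:
        warnings.warn(f"only {n} steps: tail bins are sparsely populated", stacklevel=2)
    point = _excess(x, threshold_sd)
    rng = np.random.default_rng(seed)
    reps = []
    for _ in range(n_boot):
        xb = x[rng.integers(0, n, n)]
        if np.std(xb, ddof=1) > 0:
            reps.append(_excess(xb, threshold_sd))
    lo, hi = (
        np.percentile(reps, [2.5, 97.5]) if reps else (float("nan"), float("nan"))
    )
    return GaussianExcess(
        excess=point, ci_low=float(lo), ci_high=float(hi),
        threshold_sd=threshold_sd, n=n,
    )


@dataclass
class StepAutocorrelation:
    lags: np.ndarray  # in units of steps
    corr: np.ndarray
    n_pairs: np.ndarray
    interval: str | None


def step_autocorrelation(
    ensemble: TrackEnsemble,
    interval: str | None = None,
    max_lag: int = 5,
    selection: str = "both",
    scheme: IntervalScheme | None = None,
) -> StepAutocorrelation:
    """Normalized autocorrelation of within-track 1-frame step sequences.

    For fractional Brownian motion with exponent alpha the lag-1 value is
    2^(alpha-1) - 1 (negative for sub-diffusion); for white-noise steps it
    is 0.  Averaged across tracks using the pooled mean and variance.
    """
    steps = compute_steps(ensemble, interval, lag=1, selection=selection, scheme=scheme)
    d = steps.steps
    if len(d) < 2:
        raise ValueError("not enough steps for autocorrelation")
    mu = d.mean()
    var = d.var()
    corr = np.empty(max_lag)
    n_pairs = np.zeros(max_lag, dtype=int)
    for k in range(1, max_lag + 1):
        a, b = _successive_pairs(steps, stride=k)
        n_pairs[k - 1] = len(a)
        corr[k - 1] = (
            float(np.mean((a - mu) * (b - mu)) / var) if len(a) else float("nan")
        )
    if n_pairs[0] == 0:
        raise ValueError("all tracks shorter than 2 steps in the interval")
    return StepAutocorrelation(
        lags=np.arange(1, max_lag + 1), corr=corr, n_pairs=n_pairs, interval=interval
    )
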