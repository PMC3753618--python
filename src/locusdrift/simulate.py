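"""Synthetic Langevin trajectory generator for locus-segregation analysis.

Three generator modes cover the statistical structure the analysis pipeline
assumes, so every downstream stage is testable without microscopy data:

* :func:`simulate_ou_tracks` -- white-noise Ornstein-Uhlenbeck (damped
  linear spring) tracks, the overdamped-Langevin picture used for drift
  velocity and relaxation-time tests;
* :func:`simulate_fbm_tracks` -- pure fractional Brownian motion tracks
  whose MSD scales as D * tau^alpha, used for scaling-exponent tests;
* :func:`simulate_split_cycle` -- full cell cycles: a single spring-centred
  focus at mid-cell whose equilibrium jumps to the quarter-cell positions
  (+/-0.25) when the track branches into two daughters at the splitting
  event, with optional epoch-dependent diffusion, fractional noise and
  localization error.

No single mode reproduces every observable of real segregating loci at
once: the white-noise spring cannot produce sub-diffusive MSD scaling, and
the spring + fractional-noise mode drives the exact OU update with
correlated increments, an approximation to a true fractional Langevin
equation.  Each mode is exact for the statistics its tests rely on.
"""
from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from ._fgn import sample_fgn
from .tracks import FIDUCIAL_CHANNEL, LOCUS_CHANNEL, TrackEnsemble


@dataclass(frozen=True)
class SimulationConfig:
    """Full parameterization of the synthetic cell-cycle generator.

    Defaults emulate slow-growing cells followed at one frame per minute
    over a ~120-min generation, with the locus splitting around mid-cycle
    and relaxing toward the quarter-cell positions with a ~10-min spring
    relaxation time.  Positions are in relative units (fraction of cell
    length from mid-cell); D is in (relative units)^2 / min.
    """

    n_cells: int = 400
    dt: float = 1.0
    generation_time: float = 120.0
    t_split_mean: float = 60.0
    t_split_sd: float = 10.0
    tau: float = 10.0
    x_eq_post: float = 0.25
    D: float = 2.5e-4
    #: optional epoch-dependent diffusion: (t_lo, t_hi, factor) windows in
    #: minutes relative to the split; D(t) = D * factor inside each window.
    d_schedule: tuple[tuple[float, float, float], ...] | None = None
    noise: str = "white"  # "white" | "fractional"
    alpha: float = 1.0  # MSD exponent of the fractional noise mode
    sigma_loc: float = 0.005  # localization error, relative units
    fiducial_eq: float = 0.15
    fiducial_D: float = 5e-5
    randomize_orientation: bool = True
    L0_um: float = 2.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.tau <= 0:
            raise ValueError("tau must be > 0")
        if self.D < 0:
            raise ValueError("D must be >= 0")
        if not 0 < self.alpha <= 2:
            raise ValueError("alpha must be in (0, 2]")
        if self.dt <= 0:
            raise ValueError("dt must be > 0")
        if self.noise not in ("white", "fractional"):
            raise ValueError("noise must be 'white' or 'fractional'")

    def d_factor(self, t_rel: float) -> float:
        """Diffusion multiplier at time ``t_rel`` (min relative to split)."""
        if self.d_schedule:
            for lo, hi, factor in self.d_schedule:
                if lo <= t_rel < hi:
                    return factor
        return 1.0


def _check_ou_params(tau: float, D: float, dt: float) -> None:
    if D < 0:
        raise ValueError("diffusion constant D must be >= 0")
    if tau <= 0:
        raise ValueError("relaxation time tau must be > 0")
    if tau <= 2 * dt:
        warnings.warn(
            f"tau = {tau} <= 2*dt = {2 * dt}: discretization of the spring "
            "relaxation is inaccurate at this sampling interval",
            stacklevel=3,
        )


def _ou_path(
    x0: float,
    x_eq: float,
    n_steps: int,
    tau: float,
    sigma_steps: np.ndarray,
    noise: np.ndarray,
    dt: float,
    discretization: str,
) -> np.ndarray:
    """Propagate one OU path for n_steps updates; returns length n_steps+1."""
    out = np.empty(n_steps + 1)
    out[0] = x0
    if discretization == "exact":
        a = math.exp(-dt / tau)
        for k in range(n_steps):
            out[k + 1] = x_eq + (out[k] - x_eq) * a + sigma_steps[k] * noise[k]
    elif discretization == "euler":
        for k in range(n_steps):
            out[k + 1] = out[k] - (out[k] - x_eq) * (dt / tau) + sigma_steps[k] * noise[k]
    else:
        raise ValueError("discretization must be 'exact' or 'euler'")
    return out


def _step_sigma(D: float, tau: float, dt: float, discretization: str) -> float:
    """Std of the stochastic term per update for unit-variance noise."""
    if D == 0:
        return 0.0
    if discretization == "exact":
        return math.sqrt(D * tau * (1.0 - math.exp(-2.0 * dt / tau)))
    return math.sqrt(2.0 * D * dt)


def _frame(cell_ids, frames, t, channel, focus, x, length):
    return pd.DataFrame(
        {
            "cell_id": cell_ids,
            "frame": frames,
            "t_min": t,
            "channel": channel,
            "focus_id": focus,
            "x_rel": x,
            "cell_length_um": length,
        }
    )


def simulate_ou_tracks(
    n_tracks: int = 400,
    n_frames: int = 100,
    tau: float = 10.0,
    D: float = 2.5e-4,
    x_eq: float = 0.0,
    x0: float | None = None,
    dt: float = 1.0,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    discretization: str = "exact",
) -> TrackEnsemble:
    """Stationary single-focus Ornstein-Uhlenbeck tracks (damped spring).

    By default each track starts from a draw of the stationary distribution
    N(x_eq, D*tau), so the ensemble is stationary from the first frame; pass
    ``x0`` to start every track at a fixed position (with D = 0 this gives
    the deterministic exponential relaxation toward ``x_eq``).

    With the default exact transition-density discretization the conditional
    step mean is E[dx | x] = -(x - x_eq) * (1 - exp(-dt/tau)) for any dt;
    the Euler variant x_{k+1} = x_k - (x_k - x_eq) dt/tau + sqrt(2 D dt) N
    is available via ``discretization="euler"``.
    """
    _check_ou_params(tau, D, dt)
    if rng is None:
        rng = np.random.default_rng(seed)
    if x0 is None and D == 0:
        raise ValueError("x0 is required when D = 0 (no stationary spread)")
    sigma = _step_sigma(D, tau, dt, discretization)
    n_steps = n_frames - 1
    paths = np.empty((n_tracks, n_frames))
    starts = (
        np.full(n_tracks, x0)
        if x0 is not None
        else x_eq + math.sqrt(D * tau) * rng.standard_normal(n_tracks)
    )
    noise = rng.standard_normal((n_tracks, n_steps))
    for i in range(n_tracks):
        paths[i] = _ou_path(
            starts[i], x_eq, n_steps, tau, np.full(n_steps, sigma), noise[i], dt, discretization
        )
    frames = np.tile(np.arange(n_frames), n_tracks)
    t = frames * dt
    cell_ids = np.repeat([f"ou{i:05d}" for i in range(n_tracks)], n_frames)
    data = _frame(cell_ids, frames, t, LOCUS_CHANNEL, 0, paths.ravel(), np.nan)
    return TrackEnsemble(
        data=data,
        dt=dt,
        meta={"generator": "ou", "tau": tau, "D": D, "x_eq": x_eq,
              "discretization": discretization},
    )


def simulate_fbm_tracks(
    alpha: float,
    D: float = 2.5e-4,
    n_tracks: int = 400,
    n_frames: int = 120,
    dt: float = 1.0,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> TrackEnsemble:
    """Fractional Brownian motion tracks with MSD(tau) = D * tau^alpha.

    Increments are stationary Gaussian with the fractional covariance
    (Hurst index H = alpha/2); alpha = 1 is the Brownian limit with
    independent increments.  The ensemble metadata records which fGn
    sampler ran (circulant embedding, or the recursive fallback).
    """
    if not 0 < alpha <= 2:
        raise ValueError("alpha must be in (0, 2]")
    if D < 0:
        raise ValueError("D must be >= 0")
    if rng is None:
        rng = np.random.default_rng(seed)
    g, sampler = sample_fgn(n_frames - 1, alpha / 2.0, rng, size=n_tracks)
    scale = math.sqrt(D * dt**alpha)
    x = np.concatenate(
        [np.zeros((n_tracks, 1)), np.cumsum(g, axis=1) * scale], axis=1
    )
    frames = np.tile(np.arange(n_frames), n_tracks)
    cell_ids = np.repeat([f"fbm{i:05d}" for i in range(n_tracks)], n_frames)
    data = _frame(cell_ids, frames, frames * dt, LOCUS_CHANNEL, 0, x.ravel(), np.nan)
    return TrackEnsemble(
        data=data,
        dt=dt,
        meta={"generator": "fbm", "alpha": alpha, "D": D, "sampler": sampler},
    )


def constant_velocity_tracks(
    velocities, n_frames: int = 30, dt: float = 1.0
) -> TrackEnsemble:
    """Noise-free processive tracks x(t) = v*t (the ballistic limit)."""
    velocities = np.asarray(velocities, dtype=float)
    frames = np.arange(n_frames)
    t = frames * dt
    pieces = [
        _frame(f"cv{i:04d}", frames, t, LOCUS_CHANNEL, 0, v * t, np.nan)
        for i, v in enumerate(velocities)
    ]
    return TrackEnsemble(
        data=pd.concat(pieces, ignore_index=True),
        dt=dt,
        meta={"generator": "constant_velocity"},
    )


def _fractional_or_white(
    rng: np.random.Generator, n: int, noise: str, alpha: float
) -> np.ndarray:
    if n == 0:
        return np.empty(0)
    if noise == "white":
        return rng.standard_normal(n)
    g, _ = sample_fgn(n, alpha / 2.0, rng, size=1)
    return g[0]


def simulate_split_cycle(config: SimulationConfig) -> TrackEnsemble:
    """Full-cell-cycle ensemble with the split-and-segregate structure.

    Each cell carries a single locus focus spring-centred at mid-cell from
    birth; at a per-cell split time (Gaussian, truncated to the cycle) the
    track branches into two daughters spring-centred at the quarter-cell
    positions -x_eq_post (left, focus 0) and +x_eq_post (right, focus 1).
    A fiducial-channel focus fluctuating about ``fiducial_eq`` provides the
    left-right orientation signal; with ``randomize_orientation`` half the
    cells are written mirrored, as unoriented microscopy tracks would be.
    Localization noise is added last.  The absolute cell length grows
    exponentially, L(t) = L0 * 2^(t / generation_time).

    Identical configs (including the seed) produce identical tables.
    """
    cfg = config
    _check_ou_params(cfg.tau, cfg.D, cfg.dt)
    rng = np.random.default_rng(cfg.seed)
    n_frames = int(round(cfg.generation_time / cfg.dt)) + 1
    t_abs = np.arange(n_frames) * cfg.dt
    a = math.exp(-cfg.dt / cfg.tau)
    pieces = []
    for i in range(cfg.n_cells):
        cid = f"sim{i:05d}"
        t_split = np.nan
        for _ in range(100):
            draw = rng.normal(cfg.t_split_mean, cfg.t_split_sd)
            if 0 < draw < cfg.generation_time:
                t_split = draw
                break
        else:
            raise RuntimeError(
                "could not draw a split time inside the cell cycle in 100 tries"
            )
        # snap to the frame grid, keeping >=1 pre frame and >=2 post frames
        k_split = int(np.clip(round(t_split / cfg.dt), 1, n_frames - 3))
        t_rel = t_abs - t_abs[k_split]

        # per-update noise std, epoch-dependent through the D schedule
        d_t = np.array([cfg.D * cfg.d_factor(t_rel[k]) for k in range(n_frames - 1)])
        if cfg.D > 0:
            sig = np.sqrt(d_t / cfg.D) * _step_sigma(cfg.D, cfg.tau, cfg.dt, "exact")
        else:
            sig = np.zeros(n_frames - 1)

        # parent path covers frames 0 .. k_split-1 (last single-focus frame)
        x0 = math.sqrt(cfg.D * cfg.tau) * rng.standard_normal()
        g_pre = _fractional_or_white(rng, k_split - 1, cfg.noise, cfg.alpha)
        pre = _ou_path(
            x0, 0.0, k_split - 1, cfg.tau, sig[: k_split - 1], g_pre, cfg.dt, "exact"
        )

        n_post = n_frames - 1 - k_split
        daughters = {}
        for focus, x_eq in ((0, -cfg.x_eq_post), (1, +cfg.x_eq_post)):
            g = _fractional_or_white(rng, n_post + 1, cfg.noise, cfg.alpha)
            # first update carries the branch from the parent position at
            # t = -dt to the daughter's new equilibrium at t = 0
            path = _ou_path(
                pre[-1], x_eq, n_post + 1, cfg.tau,
                sig[k_split - 1 :], g, cfg.dt, "exact",
            )
            daughters[focus] = path[1:]

        fid_g = rng.standard_normal(n_frames - 1)
        fid_sig = np.full(
            n_frames - 1, _step_sigma(cfg.fiducial_D, cfg.tau, cfg.dt, "exact")
        )
        fid0 = cfg.fiducial_eq + math.sqrt(cfg.fiducial_D * cfg.tau) * rng.standard_normal()
        fid = _ou_path(fid0, cfg.fiducial_eq, n_frames - 1, cfg.tau, fid_sig, fid_g, cfg.dt, "exact")

        flip = cfg.randomize_orientation and rng.random() < 0.5
        lengths = cfg.L0_um * 2.0 ** (t_abs / cfg.generation_time)

        def obs(xs, t_idx, focus):
            x = np.asarray(xs, dtype=float)
            if cfg.sigma_loc > 0:
                x = x + cfg.sigma_loc * rng.standard_normal(len(x))
            if flip:
                x = -x
            return _frame(
                cid, t_idx, t_abs[t_idx], LOCUS_CHANNEL, focus, x, lengths[t_idx]
            )

        pre_idx = np.arange(0, k_split)
        post_idx = np.arange(k_split, n_frames)
        left = obs(daughters[0], post_idx, 1 if flip else 0)
        right = obs(daughters[1], post_idx, 0 if flip else 1)
        fid_x = fid if not flip else -fid
        if cfg.sigma_loc > 0:
            fid_x = fid_x + cfg.sigma_loc * rng.standard_normal(n_frames)
        fid_df = _frame(
            cid, np.arange(n_frames), t_abs, FIDUCIAL_CHANNEL, 0, fid_x, lengths
        )
        pieces.extend([obs(pre, pre_idx, 0), left, right, fid_df])

    data = pd.concat(pieces, ignore_index=True)
    data = data.sort_values(["cell_id", "t_min", "channel", "focus_id"]).reset_index(
        drop=True
    )
    cfg_dict = asdict(cfg)
    cfg_dict["d_schedule"] = (
        [list(w) for w in cfg.d_schedule] if cfg.d_schedule else None
    )
    return TrackEnsemble(data=data, dt=cfg.dt, meta={"generator": "split_cycle",
                                                     "config": cfg_dict})
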