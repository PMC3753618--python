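"""One-call orchestration: simulate/load -> synchronize -> analyze -> report.

Runs the full analysis sequence on a track table or a synthetic ensemble:
occupancy map, per-interval MSD with power-law fits, step summaries, drift
profiles with equilibria and relaxation times, and the Langevin force
profile, aggregated into one JSON-serializable report that embeds the
resolved configuration and seed.  Re-running the same configuration and
seed reproduces the report byte for byte.
"""
from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import drift as drift_mod
from . import force as force_mod
from . import msd as msd_mod
from . import steps as steps_mod
from .simulate import SimulationConfig, simulate_split_cycle
from .tracks import (
    DEFAULT_SCHEME,
    IntervalScheme,
    TrackEnsemble,
    load_tracks,
    orient,
    synchronize,
)

log = logging.getLogger("locusdrift")


@dataclass
class RunConfig:
    """Fully serializable description of one analysis run."""

    tracks_path: str | None = None
    simulation: SimulationConfig | None = None
    bin_width: float = 0.05
    min_count: int = 25
    lag: int = 1
    threshold_sd: float = 2.5
    n_boot: int = 200
    fit_window: float = 0.15
    seed: int = 0
    outdir: str | None = None
    scheme: IntervalScheme = field(default_factory=IntervalScheme)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        sim = raw.pop("simulation", None)
        scheme = raw.pop("intervals", None)
        cfg = cls(**raw)
        if sim is not None:
            if "d_schedule" in sim and sim["d_schedule"] is not None:
                sim["d_schedule"] = tuple(tuple(w) for w in sim["d_schedule"])
            cfg.simulation = SimulationConfig(**sim)
        if scheme is not None:
            cfg.scheme = IntervalScheme(
                names=tuple(scheme["names"]),
                inner_edges=tuple(scheme["inner_edges"]),
            )
        return cfg


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, float)):
        v = float(obj)
        return v if np.isfinite(v) else None
    if isinstance(obj, (np.integer, int)):
        return int(obj)
    if isinstance(obj, np.ndarray):
        return _jsonable(obj.tolist())
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return _jsonable(dataclasses.asdict(obj))
    return obj


def _fit_ranges(scheme: IntervalScheme, dt: float) -> dict[str, tuple[float, float]]:
    """Usable lag range per interval: window length caps the largest lag."""
    out = {}
    for name in scheme.names:
        lo, hi = scheme.window(name)
        span = hi - lo
        top = 20.0 if not np.isfinite(span) and hi == np.inf and lo == -np.inf else 10.0
        if lo == -np.inf and np.isfinite(hi):
            top = 20.0  # open-ended early interval: longer lags usable
        if np.isfinite(span):
            top = min(top, span - dt)
        out[name] = (dt, max(top, 3 * dt))
    return out


def _prep_ensemble(config: RunConfig) -> tuple[TrackEnsemble, dict]:
    if config.tracks_path is not None:
        ensemble = load_tracks(config.tracks_path)
        source = {"kind": "file", "path": str(config.tracks_path)}
    else:
        sim = config.simulation or SimulationConfig(seed=config.seed)
        ensemble = simulate_split_cycle(sim)
        source = {"kind": "simulation", "config": ensemble.meta["config"]}
    n_in = ensemble.n_cells
    ensemble = orient(synchronize(ensemble))
    log.info(
        "stage input: %d cells in, %d synchronized, %d excluded",
        n_in, ensemble.n_cells, len(ensemble.exclusions),
    )
    source["n_cells_in"] = n_in
    source["n_cells_synchronized"] = ensemble.n_cells
    source["exclusions"] = [list(e) for e in ensemble.exclusions]
    return ensemble, source


def run_full_analysis(config: RunConfig) -> dict:
    """Execute the full pipeline and return (and optionally write) a report."""
    outdir = Path(config.outdir) if config.outdir else None
    if outdir:
        outdir.mkdir(parents=True, exist_ok=True)
    report: dict = {"config": _jsonable(dataclasses.asdict(config)), "seed": config.seed}

    ensemble, source = _run_stage("input", _prep_ensemble, config)
    report["input"] = source
    scheme = config.scheme

    occ = _run_stage("occupancy", drift_mod.occupancy_map, ensemble)
    report["occupancy"] = {
        "n_time_bins": len(occ.time_edges) - 1,
        "max_modes_per_focus": _jsonable(
            occ.mode_counts.groupby("group")["n_modes"].max().to_dict()
        ),
        "mean_trajectory": _jsonable(occ.mean_traj.to_dict(orient="list")),
    }
    if outdir:
        occ.mean_traj.to_csv(outdir / "occupancy_mean_traj.tsv", sep="\t", index=False)

    ranges = _fit_ranges(scheme, ensemble.dt)
    intervals: dict = {}
    for name in scheme.names:
        entry: dict = {}
        lag_range = ranges[name]
        try:
            curve = msd_mod.compute_msd(
                ensemble, interval=name, max_lag=lag_range[1], scheme=scheme
            )
            entry["msd"] = {
                "lags": _jsonable(curve.lags),
                "msd": _jsonable(curve.msd),
                "n_pairs": _jsonable(curve.n_pairs),
            }
            fit = msd_mod.fit_power_law(
                curve, lag_range=lag_range, n_boot=config.n_boot, seed=config.seed
            )
            entry["msd_fit"] = _jsonable(fit)
            if outdir:
                _write_msd_tsv(outdir / f"msd_{_slug(name)}.tsv", curve)
        except (ValueError, RuntimeError) as err:
            entry["msd_error"] = str(err)

        for selection in ("right", "mirror"):
            try:
                se = steps_mod.compute_steps(
                    ensemble, interval=name, lag=config.lag,
                    selection=selection, scheme=scheme,
                )
                summ = steps_mod.summarize_steps(se, threshold_sd=config.threshold_sd)
                excess = steps_mod.gaussian_excess(
                    se, threshold_sd=config.threshold_sd, seed=config.seed
                )
                entry[f"steps_{selection}"] = _jsonable(summ)
                entry[f"steps_{selection}"]["excess_ci"] = [
                    _jsonable(excess.ci_low), _jsonable(excess.ci_high)
                ]
            except (ValueError, RuntimeError) as err:
                entry[f"steps_{selection}_error"] = str(err)

        lo, _ = scheme.window(name)
        selections = ("mirror", "right", "left") if lo >= 0 else ("both",)
        entry["drift"] = {}
        for selection in selections:
            try:
                prof = drift_mod.compute_drift_profile(
                    ensemble, interval=name, bin_width=config.bin_width,
                    min_count=config.min_count, lag=config.lag,
                    selection=selection, scheme=scheme,
                )
                eq = drift_mod.find_equilibria(prof, fit_window=config.fit_window)
                entry["drift"][selection] = {
                    "profile": _jsonable(prof.to_frame().to_dict(orient="list")),
                    "equilibria": _jsonable(eq.equilibria),
                }
                if outdir:
                    prof.to_frame().to_csv(
                        outdir / f"drift_{_slug(name)}_{selection}.tsv",
                        sep="\t", index=False,
                    )
            except (ValueError, RuntimeError) as err:
                entry["drift"][selection] = {"error": str(err)}
        intervals[name] = entry
    report["intervals"] = intervals

    # Langevin force map for the late, quasi-stationary interval
    last = scheme.names[-1]
    try:
        prof = drift_mod.compute_drift_profile(
            ensemble, interval=last, bin_width=config.bin_width,
            min_count=config.min_count, selection="mirror", scheme=scheme,
        )
        d_eff = intervals[last]["steps_mirror"]["d_eff"]
        lengths = ensemble.data["cell_length_um"]
        L = float(lengths.mean()) if lengths.notna().any() else None
        ctx = force_mod.PhysicalContext(dt_min=ensemble.dt)
        fp = force_mod.force_profile(prof, d_eff, ctx, cell_length_um=L)
        report["force"] = _jsonable(fp)
    except (KeyError, TypeError, ValueError, RuntimeError) as err:
        report["force"] = {"error": str(err)}

    if outdir:
        (outdir / "report.json").write_text(
            json.dumps(report, indent=2, sort_keys=True) + "\n"
        )
    return report


def _slug(name: str) -> str:
    return name.lower().replace(" ", "_").replace("-", "_")


def _write_msd_tsv(path: Path, curve) -> None:
    import pandas as pd

    pd.DataFrame(
        {"lag_min": curve.lags, "msd": curve.msd, "n_pairs": curve.n_pairs}
    ).to_csv(path, sep="\t", index=False)


def _run_stage(name, fn, *args, **kwargs):
    try:
        return fn(*args, **kwargs)
    except Exception as err:
        raise RuntimeError(f"pipeline stage '{name}' failed: {err}") from err
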