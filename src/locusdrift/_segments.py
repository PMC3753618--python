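"""Extraction of per-track locus position series from an ensemble.

Analyses operate on contiguous single-focus position series.  A cell with a
split contributes a pre-split segment (the single parent focus, t < 0) and
one post-split segment per daughter focus (t >= 0); displacement pairs never
span the branch point, where a single-focus displacement is undefined.
Cells without split metadata (free tracks, e.g. plasmid or pure-simulation
ensembles) contribute one segment per focus.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator

import numpy as np
import pandas as pd

from .tracks import DEFAULT_SCHEME, IntervalScheme, TrackEnsemble


@dataclass
class Segment:
    cell_id: str
    focus_id: int
    regime: str  # "pre" | "post" | "free"
    frame0: int  # frame index of x[0] (t = frame * dt)
    x: np.ndarray  # dense positions, NaN where a frame is missing


def _dense(sub: pd.DataFrame, dt: float) -> tuple[int, np.ndarray] | None:
    if sub.empty:
        return None
    f = np.round(sub["t_min"].to_numpy() / dt).astype(int)
    x = sub["x_rel"].to_numpy(float)
    f0 = int(f.min())
    arr = np.full(int(f.max()) - f0 + 1, np.nan)
    arr[f - f0] = x
    return f0, arr


def iter_locus_segments(
    ensemble: TrackEnsemble,
    interval: str | None = None,
    scheme: IntervalScheme | None = None,
    post_split_start: float = 0.0,
) -> Iterator[Segment]:
    """Yield contiguous locus segments restricted to an interval window.

    ``interval`` names a window of the (default) scheme; None uses all
    frames and does not require synchronization.  ``post_split_start``
    drops post-split frames earlier than the given time (minutes); the MSD
    analysis uses 1 min because the exact split frame is uncertain.
    """
    scheme = scheme or DEFAULT_SCHEME
    if interval is not None:
        if not ensemble.synchronized:
            raise ValueError("interval selection requires a synchronized ensemble")
        lo, hi = scheme.window(interval)
    else:
        lo, hi = -np.inf, np.inf
    df = ensemble.data
    df = df[df["channel"] == ensemble.locus_channel]
    dt = ensemble.dt
    for cid, cdf in df.groupby("cell_id", sort=False):
        has_split = ensemble.synchronized and cid in ensemble.t_split
        if has_split:
            parts = [("pre", 0, cdf[cdf["t_min"] < 0])]
            post = cdf[cdf["t_min"] >= max(0.0, post_split_start)]
            for fid, fdf in post.groupby("focus_id", sort=True):
                parts.append(("post", int(fid), fdf))
        else:
            parts = [
                ("free", int(fid), fdf)
                for fid, fdf in cdf.groupby("focus_id", sort=True)
            ]
        for regime, fid, sub in parts:
            sub = sub[(sub["t_min"] >= lo) & (sub["t_min"] < hi)]
            dense = _dense(sub.sort_values("t_min"), dt)
            if dense is None:
                continue
            yield Segment(cid, fid, regime, dense[0], dense[1])
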