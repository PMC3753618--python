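"""Track-table data model for locus-segregation trajectories.

A track table holds one row per fluorescent focus per frame for a set of
cells followed over a full cell cycle.  Positions are expressed as the
relative long-axis coordinate ``x_rel``: the focus position as a fraction of
cell length measured from mid-cell, so mid-cell is 0 and the poles are
+/-0.5.  Two channels are distinguished: the tracked ``locus`` (e.g. an
oriC-proximal marker, one focus before the splitting event and two after)
and an optional ``fiducial`` marker used to orient cells by the left-right
chromosome orientation.

The splitting event -- the frame at which the single locus focus resolves
into two sustained foci -- defines t = 0 for synchronization across cells.
"""
from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np
import pandas as pd

log = logging.getLogger("locusdrift")

#: Mandatory columns of the delimited track table (tab-separated, header row).
COLUMNS = (
    "cell_id",
    "frame",
    "t_min",
    "channel",
    "focus_id",
    "x_rel",
    "cell_length_um",
)

LOCUS_CHANNEL = "locus"
FIDUCIAL_CHANNEL = "fiducial"


# ---------------------------------------------------------------------------
# Interval scheme
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class IntervalScheme:
    """Named cell-cycle intervals as half-open windows [lo, hi) in minutes
    relative to the split.

    The default four-interval scheme: Pre-Replication (t < -10), Cohesion
    (-10 <= t < 0), Rapid-Translocation (0 <= t < 10) and Post-Segregation
    (t >= 10).  Boundary times belong to the later interval (half-open
    convention), so t = 0, the first two-focus frame, is Rapid-Translocation.
    """

    names: tuple[str, ...] = (
        "Pre-Replication",
        "Cohesion",
        "Rapid-Translocation",
        "Post-Segregation",
    )
    inner_edges: tuple[float, ...] = (-10.0, 0.0, 10.0)

    def __post_init__(self) -> None:
        if len(self.inner_edges) != len(self.names) - 1:
            raise ValueError("need len(names) - 1 inner edges")
        if np.any(np.diff(self.inner_edges) <= 0):
            raise ValueError("interval edges must be strictly increasing")

    def assign(self, t: float | np.ndarray) -> str | np.ndarray:
        """Map time(s) relative to split to interval label(s)."""
        idx = np.searchsorted(self.inner_edges, t, side="right")
        names = np.asarray(self.names, dtype=object)
        out = names[idx]
        return out if np.ndim(t) else str(out)

    def window(self, name: str) -> tuple[float, float]:
        """Half-open window [lo, hi) of the named interval."""
        i = self.names.index(name)
        edges = (-np.inf, *self.inner_edges, np.inf)
        return edges[i], edges[i + 1]

    @property
    def windows(self) -> dict[str, tuple[float, float]]:
        return {name: self.window(name) for name in self.names}


DEFAULT_SCHEME = IntervalScheme()

#: Short CLI aliases for the default interval names.
INTERVAL_ALIASES = {
    "pre": "Pre-Replication",
    "cohesion": "Cohesion",
    "rapid": "Rapid-Translocation",
    "post": "Post-Segregation",
}


def assign_interval(
    t: float | np.ndarray, scheme: IntervalScheme | None = None
) -> str | np.ndarray:
    """Interval label for time(s) ``t`` (minutes relative to split)."""
    return (scheme or DEFAULT_SCHEME).assign(t)


# ---------------------------------------------------------------------------
# Ensemble containers
# ---------------------------------------------------------------------------


@dataclass
class CellTrajectory:
    """One cell's observations, with its split time and orientation flag."""

    cell_id: str
    data: pd.DataFrame
    dt: float
    t_split: float | None = None
    orientation: int = 1

    def __len__(self) -> int:
        return len(self.data)


@dataclass
class TrackEnsemble:
    """A collection of per-cell trajectories sharing one sampling interval.

    ``data`` is a long-format table with the columns in :data:`COLUMNS`.
    When ``synchronized`` is True the time axis is t = t_abs - t_split, so
    t = 0 is the first frame of the sustained two-focus state.
    """

    data: pd.DataFrame
    dt: float
    synchronized: bool = False
    t_split: dict = field(default_factory=dict)
    orientation: dict = field(default_factory=dict)
    exclusions: list = field(default_factory=list)
    locus_channel: str = LOCUS_CHANNEL
    fiducial_channel: str = FIDUCIAL_CHANNEL
    meta: dict = field(default_factory=dict)

    @property
    def cell_ids(self) -> list:
        return list(dict.fromkeys(self.data["cell_id"]))

    @property
    def n_cells(self) -> int:
        return self.data["cell_id"].nunique()

    def trajectory(self, cell_id) -> CellTrajectory:
        df = self.data[self.data["cell_id"] == cell_id]
        if df.empty:
            raise KeyError(cell_id)
        return CellTrajectory(
            cell_id=cell_id,
            data=df.reset_index(drop=True),
            dt=self.dt,
            t_split=self.t_split.get(cell_id),
            orientation=self.orientation.get(cell_id, 1),
        )

    def __iter__(self) -> Iterator[CellTrajectory]:
        for cid in self.cell_ids:
            yield self.trajectory(cid)

    def copy(self) -> "TrackEnsemble":
        return replace(
            self,
            data=self.data.copy(),
            t_split=dict(self.t_split),
            orientation=dict(self.orientation),
            exclusions=list(self.exclusions),
            meta=dict(self.meta),
        )


# ---------------------------------------------------------------------------
# Split detection
# ---------------------------------------------------------------------------


def _runs(states: np.ndarray) -> list[tuple[int, int, int]]:
    """Compress a state sequence into (state, start, length) runs."""
    out = []
    start = 0
    for i in range(1, len(states) + 1):
        if i == len(states) or states[i] != states[start]:
            out.append((int(states[start]), start, i - start))
            start = i
    return out


def detect_split(
    focus_counts: np.ndarray, sustain: int = 2
) -> tuple[int | None, int, bool]:
    """Locate the splitting event in a per-frame focus-count sequence.

    A splitting event is a block of two-focus frames containing at least
    ``sustain`` consecutive two-focus frames; shorter two-focus runs are
    treated as transient double-detections, and one-focus gaps shorter than
    ``sustain`` inside a block are treated as transient dropouts.

    Returns ``(split_index, n_events, merged_back)`` where ``split_index``
    is the first frame of the first sustained two-focus run (None if there
    is no sustained run), ``n_events`` counts distinct splitting events and
    ``merged_back`` flags a sustained return to one focus after the last
    event.
    """
    states = np.minimum(np.asarray(focus_counts, dtype=int), 2)
    runs = _runs(states)
    # group 2-runs separated by short 1-gaps into blocks
    blocks: list[list[tuple[int, int, int]]] = []
    current: list[tuple[int, int, int]] = []
    merged_back = False
    for state, start, length in runs:
        if state >= 2:
            current.append((state, start, length))
        else:
            if current and length >= sustain:
                blocks.append(current)
                current = []
            # short gap: stays inside the current block
    if current:
        blocks.append(current)
        trailing_gap = False
    else:
        trailing_gap = bool(blocks)
    events = [b for b in blocks if any(r[2] >= sustain for r in b)]
    if events and trailing_gap:
        merged_back = True
    if not events:
        return None, 0, merged_back
    first = events[0]
    split_index = next(start for _, start, length in first if length >= sustain)
    return split_index, len(events), merged_back


def _focus_counts(cell_df: pd.DataFrame, locus_channel: str) -> tuple[np.ndarray, np.ndarray]:
    locus = cell_df[cell_df["channel"] == locus_channel]
    counts = locus.groupby("t_min")["focus_id"].nunique()
    return counts.index.to_numpy(float), counts.to_numpy(int)


def _split_time(
    cell_df: pd.DataFrame, locus_channel: str, sustain: int
) -> tuple[float | None, str | None]:
    """Split time for one cell, or (None, reason) if the trajectory fails
    the single-splitting-event filter."""
    times, counts = _focus_counts(cell_df, locus_channel)
    if len(times) == 0:
        return None, "no locus-channel observations"
    idx, n_events, merged_back = detect_split(counts, sustain)
    if n_events == 0:
        return None, "no sustained splitting event"
    if n_events > 1:
        return None, f"{n_events} splitting events"
    if merged_back:
        return None, "foci re-merged after the split"
    return float(times[idx]), None


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------


def _infer_dt(data: pd.DataFrame) -> float:
    diffs = (
        data.drop_duplicates(["cell_id", "t_min"])
        .sort_values(["cell_id", "t_min"])
        .groupby("cell_id")["t_min"]
        .diff()
        .dropna()
    )
    if diffs.empty:
        return 1.0
    return float(diffs.median())


def load_tracks(
    path,
    dt: float | None = None,
    require_split: bool = True,
    sustain: int = 2,
    locus_channel: str = LOCUS_CHANNEL,
    fiducial_channel: str = FIDUCIAL_CHANNEL,
) -> TrackEnsemble:
    """Read a tab-separated track table into a :class:`TrackEnsemble`.

    Rows with ``x_rel`` outside [-0.5, 0.5] are dropped (and counted), not
    clamped, to avoid biasing tail statistics.  With ``require_split`` the
    full-cell-cycle filter is applied: trajectories must contain exactly one
    sustained splitting event (one focus at birth, two at division); others
    are excluded with a recorded reason.  Set ``require_split=False`` for
    tables of free tracks without a split (e.g. plasmid or simulation test
    ensembles).
    """
    path = Path(path)
    data = pd.read_csv(path, sep="\t")
    missing = set(COLUMNS) - set(data.columns)
    if missing:
        raise ValueError(
            f"malformed track-table header: missing columns {sorted(missing)}"
        )
    data = data[list(COLUMNS)]
    data = data.astype(
        {
            "cell_id": str,
            "frame": int,
            "t_min": float,
            "channel": str,
            "focus_id": int,
            "x_rel": float,
            "cell_length_um": float,
        }
    )
    bad = (data["x_rel"] < -0.5) | (data["x_rel"] > 0.5) | data["x_rel"].isna()
    n_bad = int(bad.sum())
    if n_bad:
        log.warning("%s: dropped %d rows with x_rel outside [-0.5, 0.5]", path, n_bad)
        data = data[~bad]
    data = data.sort_values(["cell_id", "t_min", "channel", "focus_id"]).reset_index(
        drop=True
    )
    ensemble = TrackEnsemble(
        data=data,
        dt=dt if dt is not None else _infer_dt(data),
        locus_channel=locus_channel,
        fiducial_channel=fiducial_channel,
        meta={"source": str(path), "n_rows_dropped": n_bad},
    )
    if require_split and not data.empty:
        keep = []
        for cid, cell_df in data.groupby("cell_id", sort=False):
            _, reason = _split_time(cell_df, locus_channel, sustain)
            if reason is None:
                keep.append(cid)
            else:
                ensemble.exclusions.append((cid, reason))
                log.info("excluded %s: %s", cid, reason)
        ensemble.data = data[data["cell_id"].isin(keep)].reset_index(drop=True)
    return ensemble


def write_tracks(ensemble: TrackEnsemble, path, sidecar: bool = True) -> None:
    """Write the ensemble as a tab-separated track table.

    With ``sidecar`` a ``<path>.meta.json`` file records the sampling
    interval, counts and the exclusion log.
    """
    path = Path(path)
    ensemble.data.to_csv(path, sep="\t", index=False, float_format="%.6f")
    if sidecar:
        meta = {
            "dt_min": ensemble.dt,
            "synchronized": ensemble.synchronized,
            "n_cells": ensemble.n_cells,
            "n_rows": int(len(ensemble.data)),
            "exclusions": [list(e) for e in ensemble.exclusions],
        }
        Path(str(path) + ".meta.json").write_text(json.dumps(meta, indent=2, sort_keys=True))


# ---------------------------------------------------------------------------
# Synchronization, focus identity and orientation
# ---------------------------------------------------------------------------


def _relink_post_split_foci(cell_df: pd.DataFrame, locus_channel: str) -> pd.DataFrame:
    """Assign stable left/right identities (0/1) to post-split locus foci.

    Identity is fixed at the split and maintained by nearest-neighbour
    linking in x_rel frame to frame; the chain with the smaller mean
    position is labelled 0 (left), the other 1 (right).
    """
    df = cell_df
    post = (df["channel"] == locus_channel) & (df["t_min"] >= 0)
    if not post.any():
        return df
    sub = df.loc[post].sort_values(["t_min", "x_rel"])
    chains: tuple[list, list] = ([], [])  # row indices per chain
    last = [np.nan, np.nan]
    for _, frame_df in sub.groupby("t_min", sort=True):
        xs = frame_df["x_rel"].to_numpy()
        idxs = frame_df.index.to_numpy()
        if np.isnan(last[0]):  # first post-split frame
            for j in range(min(len(xs), 2)):
                chains[j].append(idxs[j])
                last[j] = xs[j]
            continue
        if len(xs) >= 2:
            cost_id = abs(xs[0] - last[0]) + abs(xs[1] - last[1])
            cost_sw = abs(xs[0] - last[1]) + abs(xs[1] - last[0])
            order = (0, 1) if cost_id <= cost_sw else (1, 0)
            for j, chain in zip(order, (0, 1)):
                chains[chain].append(idxs[j])
                last[chain] = xs[j]
        else:
            j = 0 if abs(xs[0] - last[0]) <= abs(xs[0] - last[1]) else 1
            chains[j].append(idxs[0])
            last[j] = xs[0]
    means = [
        df.loc[c, "x_rel"].mean() if c else np.inf for c in chains
    ]
    left_chain = int(np.argmin(means))
    df = df.copy()
    df.loc[chains[left_chain], "focus_id"] = 0
    df.loc[chains[1 - left_chain], "focus_id"] = 1
    return df


def synchronize(ensemble: TrackEnsemble, sustain: int = 2) -> TrackEnsemble:
    """Shift each trajectory's time axis so the split is at t = 0.

    The split is the first frame of the first sustained run (>= ``sustain``
    consecutive frames) of the two-focus state.  Trajectories without
    exactly one sustained splitting event are excluded with a reason.
    Post-split foci are relabelled to stable left(0)/right(1) identities.
    Idempotent: an already-synchronized ensemble is returned unchanged.
    """
    if ensemble.synchronized:
        return ensemble.copy()
    pieces = []
    out = replace(
        ensemble.copy(), synchronized=True, t_split={}, orientation=dict(ensemble.orientation)
    )
    out.exclusions = list(ensemble.exclusions)
    for cid, cell_df in ensemble.data.groupby("cell_id", sort=False):
        t0, reason = _split_time(cell_df, ensemble.locus_channel, sustain)
        if reason is not None:
            out.exclusions.append((cid, reason))
            log.info("excluded %s: %s", cid, reason)
            continue
        shifted = cell_df.copy()
        shifted["t_min"] = shifted["t_min"] - t0
        shifted = _relink_post_split_foci(shifted, ensemble.locus_channel)
        out.t_split[cid] = t0
        pieces.append(shifted)
    out.data = (
        pd.concat(pieces, ignore_index=True)
        if pieces
        else ensemble.data.iloc[0:0].copy()
    )
    out.data = _canonical_order(out.data)
    return out


def _canonical_order(df: pd.DataFrame) -> pd.DataFrame:
    return df.sort_values(["cell_id", "t_min", "channel", "focus_id"]).reset_index(
        drop=True
    )


def _mirror_cell(df: pd.DataFrame, mask: pd.Series, locus_channel: str, has_split: bool) -> None:
    """In place: negate x_rel for the masked rows; keep left=0/right=1 post-split."""
    df.loc[mask, "x_rel"] = -df.loc[mask, "x_rel"]
    if has_split:
        post = mask & (df["channel"] == locus_channel) & (df["t_min"] >= 0)
        df.loc[post, "focus_id"] = 1 - df.loc[post, "focus_id"]


def orient(ensemble: TrackEnsemble) -> TrackEnsemble:
    """Mirror cells whose fiducial-channel mean position is negative.

    After orientation every cell's fiducial mean is >= 0, putting all cells
    in a common left-right chromosome frame.  Cells without fiducial
    observations keep orientation +1 with a logged warning.  Involutive on
    the mirrored cells; idempotent on the ensemble.
    """
    out = ensemble.copy()
    df = out.data
    fid = df[df["channel"] == ensemble.fiducial_channel]
    fid_mean = fid.groupby("cell_id")["x_rel"].mean()
    for cid in out.cell_ids:
        if cid not in fid_mean.index:
            log.warning("cell %s has no fiducial channel; orientation left at +1", cid)
            out.orientation[cid] = 1
            continue
        if fid_mean[cid] < 0:
            mask = df["cell_id"] == cid
            _mirror_cell(df, mask, ensemble.locus_channel,
                         has_split=out.synchronized and cid in out.t_split)
            out.orientation[cid] = -out.orientation.get(cid, 1)
        else:
            out.orientation[cid] = out.orientation.get(cid, 1)
    out.data = _canonical_order(out.data)
    return out


def mirror(ensemble: TrackEnsemble) -> TrackEnsemble:
    """Negate every position in the ensemble (whole-ensemble reflection).

    Post-split locus foci are relabelled so left remains focus 0.  Useful
    for symmetry checks: mirroring negates every drift profile and leaves
    every MSD unchanged.
    """
    out = ensemble.copy()
    df = out.data
    for cid in out.cell_ids:
        mask = df["cell_id"] == cid
        _mirror_cell(df, mask, ensemble.locus_channel,
                     has_split=out.synchronized and cid in out.t_split)
        out.orientation[cid] = -out.orientation.get(cid, 1)
    out.data = _canonical_order(out.data)
    return out
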