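"""Trajectory metrics for the ridged stiffness-sorting device.

Cells flow in +x through a channel spanned by diagonal ridges; a stiff cell
resists deforming under a ridge and is pushed along it, accruing positive
y-deflection toward the stiff outlets, while a soft cell squeezes under and
keeps its streamline. The tracker upstream (e.g. TrackMate) exports per-frame
positions; this module windows each track around each ridge, measures the
per-ridge deflection Δy and interaction time τ, and summarises populations.

Conventions:
- positive y points toward the stiffest outlet (outlet 5);
- a cell "interacts" with ridge i while its along-flow distance to the
  inclined ridge centerline, u = x - [x0_i + (y - y_ref) tanθ], satisfies
  |u| <= w/2;
- per-ridge deflection is y(last frame in window) - y(first frame in
  window); cumulative metrics sum the first ``n_cumulative`` ridges, with
  never-entered windows contributing zero.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .stats import GroupComparison, compare_groups

__all__ = [
    "RidgeGeometry",
    "TrackMetrics",
    "read_tracks",
    "write_tracks",
    "ridge_windows",
    "track_metrics",
    "metrics_table",
    "summarize_groups",
    "outlet_fractions",
]

TRACK_COLUMNS = ["TRACK_ID", "FRAME", "POSITION_X", "POSITION_Y"]


@dataclass(frozen=True)
class RidgeGeometry:
    """Ridge layout and outlet binning of the sorting channel.

    ``ridge_x`` are centerline anchor x-positions (μm) at ``y_ref``;
    ``angle_deg`` is the ridge angle to the flow axis; ``width`` is the full
    interaction window width w (μm) — ridge footprint plus roughly one cell
    diameter. ``outlet_edges`` are 6 strictly increasing y-values carving the
    channel into outlets 1 (softest, lowest y) through 5 (stiffest).
    """

    ridge_x: tuple[float, ...]
    angle_deg: float = 45.0
    width: float = 30.0
    y_ref: float = 0.0
    outlet_edges: tuple[float, ...] = (0.0, 100.0, 200.0, 300.0, 400.0, 500.0)

    def __post_init__(self) -> None:
        if len(self.ridge_x) < 1:
            raise ValueError("need at least one ridge")
        if any(b >= a for a, b in zip(self.ridge_x[1:], self.ridge_x[:-1])):
            pass
        if list(self.ridge_x) != sorted(self.ridge_x):
            raise ValueError("ridges must be ordered by x")
        if self.width <= 0:
            raise ValueError("interaction width must be positive")
        if len(self.outlet_edges) != 6 or np.any(np.diff(self.outlet_edges) <= 0):
            raise ValueError("outlet_edges must be 6 strictly increasing values")

    @property
    def n_ridges(self) -> int:
        return len(self.ridge_x)

    @property
    def tan_angle(self) -> float:
        return math.tan(math.radians(self.angle_deg))

    def along_flow_distance(self, x, y, ridge: int):
        """Signed distance u from the inclined centerline of ``ridge`` (0-based)."""
        return np.asarray(x) - (
            self.ridge_x[ridge] + (np.asarray(y) - self.y_ref) * self.tan_angle
        )

    def outlet_of(self, y: float) -> int:
        """Outlet number 1–5 for a final y position (clamped to the channel)."""
        idx = int(np.searchsorted(self.outlet_edges, y, side="right")) - 1
        return min(max(idx, 0), 4) + 1

    # 14 diagonal ridges, as in the multiplexed sorting device
    @classmethod
    def default(cls) -> "RidgeGeometry":
        return cls(ridge_x=tuple(100.0 + 150.0 * i for i in range(14)))

    def to_yaml(self, path: str | Path) -> Path:
        path = Path(path)
        payload = {
            "ridge_x": list(self.ridge_x),
            "angle_deg": self.angle_deg,
            "width": self.width,
            "y_ref": self.y_ref,
            "outlet_edges": list(self.outlet_edges),
        }
        path.write_text(yaml.safe_dump(payload, sort_keys=False))
        return path

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RidgeGeometry":
        payload = yaml.safe_load(Path(path).read_text())
        return cls(
            ridge_x=tuple(float(x) for x in payload["ridge_x"]),
            angle_deg=float(payload.get("angle_deg", 45.0)),
            width=float(payload.get("width", 30.0)),
            y_ref=float(payload.get("y_ref", 0.0)),
            outlet_edges=tuple(float(v) for v in payload["outlet_edges"]),
        )


@dataclass(frozen=True)
class TrackMetrics:
    """Per-track ridge-interaction summary."""

    track_id: int
    deflections: np.ndarray        # Δy per ridge, μm; nan where never in window
    interaction_times: np.ndarray  # τ per ridge, s; nan where never in window
    cumulative_deflection: float   # sum over first n_cumulative ridges (nan -> 0)
    cumulative_time: float
    n_ridges_encountered: int
    predicted_outlet: int          # 1..5 from final y
    final_y: float
    flags: tuple[str, ...] = ()


def read_tracks(path: str | Path) -> pd.DataFrame:
    """Read a tracker-export CSV (TRACK_ID, FRAME, POSITION_X, POSITION_Y).

    Frames are sorted within each track; duplicate (track, frame) pairs and
    non-integer frames are rejected with the offending rows named.
    """
    path = Path(path)
    df = pd.read_csv(path)
    missing = [c for c in TRACK_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    df = df[TRACK_COLUMNS].copy()
    frames = pd.to_numeric(df["FRAME"], errors="coerce")
    bad = frames.isna() | (frames != frames.round())
    if bad.any():
        rows = (df.index[bad] + 2).tolist()[:5]  # +2: header + 0-base
        raise ValueError(f"{path}: non-integer FRAME values at lines {rows}")
    df["FRAME"] = frames.astype(int)
    for col in ("POSITION_X", "POSITION_Y"):
        vals = pd.to_numeric(df[col], errors="coerce")
        if vals.isna().any():
            rows = (df.index[vals.isna()] + 2).tolist()[:5]
            raise ValueError(f"{path}: malformed {col} at lines {rows}")
        df[col] = vals
    dup = df.duplicated(subset=["TRACK_ID", "FRAME"])
    if dup.any():
        pairs = df.loc[dup, ["TRACK_ID", "FRAME"]].head().to_records(index=False)
        raise ValueError(f"{path}: duplicate (track, frame) pairs, e.g. {list(pairs)}")
    return df.sort_values(["TRACK_ID", "FRAME"], kind="stable").reset_index(drop=True)


def write_tracks(df: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    df[TRACK_COLUMNS].to_csv(path, index=False)
    return path


def ridge_windows(
    track: pd.DataFrame, geometry: RidgeGeometry
) -> list[tuple[int, int] | None]:
    """Per-ridge maximal contiguous frame run inside the interaction window.

    Returns, for each ridge, a half-open positional index range (start, stop)
    into the frame-sorted track, or None when the cell never enters the
    window. When the in-window frames fall in several contiguous runs (noise
    jitter at the window edge) the longest run is kept, earliest on ties.
    """
    if len(track) < 2:
        raise ValueError("track needs at least 2 frames")
    t = track.sort_values("FRAME", kind="stable")
    x = t["POSITION_X"].to_numpy(dtype=float)
    y = t["POSITION_Y"].to_numpy(dtype=float)
    out: list[tuple[int, int] | None] = []
    half = geometry.width / 2.0
    for i in range(geometry.n_ridges):
        inside = np.abs(geometry.along_flow_distance(x, y, i)) <= half
        if not inside.any():
            out.append(None)
            continue
        padded = np.concatenate(([False], inside, [False]))
        edges = np.flatnonzero(np.diff(padded.astype(int)))
        starts, stops = edges[::2], edges[1::2]
        best = int(np.argmax(stops - starts))
        out.append((int(starts[best]), int(stops[best])))
    return out


def track_metrics(
    track: pd.DataFrame,
    geometry: RidgeGeometry,
    fps: float,
    n_cumulative: int = 5,
) -> TrackMetrics:
    """Per-ridge Δy and τ for one track plus cumulative summaries.

    Δy_i = y(last in-window frame) - y(first in-window frame);
    τ_i = (frames in window) / fps. Cumulative metrics sum the first
    ``n_cumulative`` ridges, counting never-entered ridges as 0.
    """
    if fps <= 0:
        raise ValueError("fps must be positive")
    t = track.sort_values("FRAME", kind="stable")
    y = t["POSITION_Y"].to_numpy(dtype=float)
    windows = ridge_windows(t, geometry)
    n = geometry.n_ridges
    dy = np.full(n, np.nan)
    tau = np.full(n, np.nan)
    for i, win in enumerate(windows):
        if win is None:
            continue
        a, b = win
        dy[i] = y[b - 1] - y[a]
        tau[i] = (b - a) / fps
    first = slice(0, n_cumulative)
    cum_dy = float(np.nansum(dy[first]))
    cum_tau = float(np.nansum(tau[first]))
    final_y = float(y[-1])
    return TrackMetrics(
        track_id=int(t["TRACK_ID"].iloc[0]),
        deflections=dy,
        interaction_times=tau,
        cumulative_deflection=cum_dy,
        cumulative_time=cum_tau,
        n_ridges_encountered=int(sum(w is not None for w in windows)),
        predicted_outlet=geometry.outlet_of(final_y),
        final_y=final_y,
    )


def metrics_table(
    tracks: pd.DataFrame,
    geometry: RidgeGeometry,
    fps: float,
    n_cumulative: int = 5,
) -> pd.DataFrame:
    """Apply :func:`track_metrics` to every track; short tracks are flagged.

    Tracks with fewer than 2 frames are excluded from the metric rows and
    listed in the DataFrame attribute ``excluded``.
    """
    rows = []
    excluded = []
    for tid, grp in tracks.groupby("TRACK_ID", sort=True):
        if len(grp) < 2:
            excluded.append(int(tid))
            continue
        m = track_metrics(grp, geometry, fps, n_cumulative)
        rows.append(
            {
                "TRACK_ID": m.track_id,
                "cumulative_deflection": m.cumulative_deflection,
                "cumulative_time": m.cumulative_time,
                "n_ridges_encountered": m.n_ridges_encountered,
                "predicted_outlet": m.predicted_outlet,
                "final_y": m.final_y,
            }
        )
    df = pd.DataFrame(
        rows,
        columns=[
            "TRACK_ID",
            "cumulative_deflection",
            "cumulative_time",
            "n_ridges_encountered",
            "predicted_outlet",
            "final_y",
        ],
    )
    df.attrs["excluded"] = excluded
    return df


def summarize_groups(
    metrics_a: pd.DataFrame, metrics_b: pd.DataFrame
) -> dict[str, GroupComparison]:
    """Welch + Brown–Forsythe comparison of the two cumulative metrics."""
    if len(metrics_a) < 2 or len(metrics_b) < 2:
        raise ValueError("need >= 2 tracks per group")
    out = {}
    for metric in ("cumulative_deflection", "cumulative_time"):
        out[metric] = compare_groups(
            metrics_a[metric].to_numpy(), metrics_b[metric].to_numpy()
        )
    return out


def outlet_fractions(metrics: pd.DataFrame) -> np.ndarray:
    """Fraction of tracks predicted to exit through outlets 1..5 (sums to 1)."""
    if len(metrics) == 0:
        raise ValueError("no tracks")
    counts = np.bincount(metrics["predicted_outlet"].to_numpy() - 1, minlength=5)
    return counts / counts.sum()
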