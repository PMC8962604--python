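"""Landmark-track container and CSV I/O.

A trial is a uniformly sampled 2D landmark time series filmed side-on:
head and terminal abdominal segment (always), wing tip (optional).
The x axis points along the flight direction, y points up; positions are
in metres once calibrated, raw digitizer pixels otherwise.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["TrajectoryTrack", "read_track_csv", "write_track_csv"]


@dataclass
class TrajectoryTrack:
    """One digitized flight (or calibration-drop) trial.

    Parameters
    ----------
    t : array of shape (n,)
        Frame times in seconds, uniformly spaced at 1/fps.
    head : array of shape (n, 2)
        Head landmark positions. For a single-landmark calibration drop
        (e.g. a falling ball) this is the only landmark.
    abd : array of shape (n, 2), optional
        Terminal abdominal-segment landmark.
    wing : array of shape (n, 2), optional
        Wing-tip landmark (present only when digitized).
    fps : float
        Camera frame rate, frames per second.
    units_calibrated : bool
        True when positions are metric; False for raw pixel coordinates.
    meta : dict
        Free-form annotations (e.g. ``reversal_frames`` from the
        generator, scale-bar information, individual id).
    """

    t: np.ndarray
    head: np.ndarray
    abd: np.ndarray | None = None
    wing: np.ndarray | None = None
    fps: float = 500.0
    units_calibrated: bool = True
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.head = np.asarray(self.head, dtype=float)
        if self.abd is not None:
            self.abd = np.asarray(self.abd, dtype=float)
        if self.wing is not None:
            self.wing = np.asarray(self.wing, dtype=float)
        if self.fps <= 0:
            raise ValueError("fps must be positive")
        if self.t.ndim != 1 or len(self.t) < 2:
            raise ValueError("track needs at least two frames")
        dt = np.diff(self.t)
        if not np.allclose(dt, dt[0], rtol=1e-6, atol=1e-12) or dt[0] <= 0:
            raise ValueError("frame times must be uniform and increasing")
        for name, arr in (("head", self.head), ("abd", self.abd), ("wing", self.wing)):
            if arr is None:
                continue
            if arr.shape != (len(self.t), 2):
                raise ValueError(f"{name} must have shape (n_frames, 2)")
            if not np.all(np.isfinite(arr)):
                raise ValueError(f"{name} contains non-finite coordinates")

    @property
    def n_frames(self) -> int:
        return len(self.t)

    def copy(self) -> "TrajectoryTrack":
        return TrajectoryTrack(
            t=self.t.copy(),
            head=self.head.copy(),
            abd=None if self.abd is None else self.abd.copy(),
            wing=None if self.wing is None else self.wing.copy(),
            fps=self.fps,
            units_calibrated=self.units_calibrated,
            meta=dict(self.meta),
        )


def write_track_csv(track: TrajectoryTrack, path: str | Path, sidecar: dict | None = None) -> None:
    """Write a track as CSV (frame, t_s, head/abd/wing x,y) plus an optional JSON sidecar."""
    path = Path(path)
    cols = {
        "frame": np.arange(track.n_frames),
        "t_s": track.t,
        "head_x": track.head[:, 0],
        "head_y": track.head[:, 1],
    }
    if track.abd is not None:
        cols["abd_x"] = track.abd[:, 0]
        cols["abd_y"] = track.abd[:, 1]
    if track.wing is not None:
        cols["wing_x"] = track.wing[:, 0]
        cols["wing_y"] = track.wing[:, 1]
    pd.DataFrame(cols).to_csv(path, index=False)
    if sidecar is not None:
        side = dict(sidecar)
        side.setdefault("fps", track.fps)
        side.setdefault("units_calibrated", track.units_calibrated)
        side.setdefault("meta", {k: _jsonable(v) for k, v in track.meta.items()})
        Path(path).with_suffix(".json").write_text(json.dumps(side, indent=2))


def read_track_csv(
    path: str | Path,
    fps: float | None = None,
    units_calibrated: bool = True,
    column_map: dict | None = None,
) -> TrajectoryTrack:
    """Read a track CSV.

    The native layout is ``frame,t_s,head_x,head_y,abd_x,abd_y[,wing_x,wing_y]``.
    ``column_map`` remaps a per-landmark two-column export from other
    digitization tools, e.g. ``{"head_x": "pt1_X", "head_y": "pt1_Y", ...}``.
    """
    df = pd.read_csv(path)
    if column_map:
        df = df.rename(columns={v: k for k, v in column_map.items()})
    if "t_s" in df.columns:
        t = df["t_s"].to_numpy(float)
        fps = fps if fps is not None else 1.0 / float(np.median(np.diff(t)))
    else:
        if fps is None:
            raise ValueError("fps required when the CSV has no t_s column")
        t = np.arange(len(df)) / fps
    head = df[["head_x", "head_y"]].to_numpy(float)
    abd = df[["abd_x", "abd_y"]].to_numpy(float) if "abd_x" in df.columns else None
    wing = df[["wing_x", "wing_y"]].to_numpy(float) if "wing_x" in df.columns else None
    return TrajectoryTrack(t=t, head=head, abd=abd, wing=wing, fps=fps, units_calibrated=units_calibrated)


def _jsonable(v):
    if isinstance(v, np.ndarray):
        return v.tolist()
    if isinstance(v, (np.integer,)):
        return int(v)
    if isinstance(v, (np.floating,)):
        return float(v)
    return v
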