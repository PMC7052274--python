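"""Reading, validating and differencing single-particle trajectory tables.

Trajectories arrive as delimited text with one localization per row
(``traj_id, frame, x[, y]`` or a ``t`` column instead of ``frame``); positions
are in µm, the frame interval Δt in s.  The inference operates on
displacements between consecutive frames, so the central conversion here is
``TrajectorySet`` → ``DisplacementSet``: one record per consecutive-frame
pair, pairs spanning a frame gap dropped (the local Gaussian likelihood
assumes a single fixed Δt; rescaling a longer jump would corrupt the jump
variance).
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "TrajectorySet",
    "DisplacementSet",
    "SchemaError",
    "SamplingError",
    "read_trajectories",
    "to_displacements",
    "write_trajectories",
    "write_field_map",
    "read_field_map",
]


class SchemaError(ValueError):
    """A required column is missing or duplicated rows are present."""


class SamplingError(ValueError):
    """The time column is not uniformly spaced."""


@dataclass(frozen=True)
class TrajectorySet:
    """Recorded positions grouped by particle at a uniform frame interval.

    ``data`` holds one row per localization with columns ``traj_id``,
    ``frame`` and the coordinate columns (``x`` or ``x, y``), sorted by
    (traj_id, frame) with strictly increasing frames inside each trajectory.
    """

    data: pd.DataFrame
    dt: float
    box: tuple | None = None   # periodic box lengths [µm]; None = open domain
    d: int = field(init=False)

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        coord_cols = [c for c in ("x", "y") if c in self.data.columns]
        if not coord_cols or coord_cols != ["x", "y"][: len(coord_cols)]:
            raise SchemaError("coordinate columns must be x or x,y")
        object.__setattr__(self, "d", len(coord_cols))
        df = self.data
        if len(df):
            if df.duplicated(["traj_id", "frame"]).any():
                raise SchemaError("duplicate (traj_id, frame) rows")
            diffs = df.groupby("traj_id", sort=False)["frame"].diff().dropna()
            if (diffs <= 0).any():
                raise ValueError("frames must strictly increase within a trajectory")
            if not np.isfinite(df[coord_cols].to_numpy(float)).all():
                raise ValueError("non-finite coordinates")

    @property
    def coord_columns(self) -> list[str]:
        return ["x", "y"][: self.d]

    @property
    def n_records(self) -> int:
        return len(self.data)

    @property
    def n_trajectories(self) -> int:
        return self.data["traj_id"].nunique()

    def positions(self) -> np.ndarray:
        return self.data[self.coord_columns].to_numpy(float)


@dataclass(frozen=True)
class DisplacementSet:
    """Consecutive-frame displacements with their start positions.

    ``start`` is the position the jump originates from (the point at which
    the locally-constant drift and diffusivity are attributed), ``delta`` the
    displacement vector; both (N, d) in µm.  ``n_gap_dropped`` counts the
    consecutive-row pairs that were discarded because of missing frames.
    """

    start: np.ndarray
    delta: np.ndarray
    traj_id: np.ndarray
    dt: float
    d: int
    n_gap_dropped: int = 0

    def __post_init__(self) -> None:
        if self.start.shape != self.delta.shape:
            raise ValueError("start/delta shape mismatch")
        if self.start.ndim != 2 or self.start.shape[1] != self.d:
            raise ValueError("positions must be (N, d)")

    def __len__(self) -> int:
        return self.start.shape[0]


def _detect_delimiter(path) -> str:
    with open(path, "r", encoding="utf-8") as fh:
        for line in fh:
            if line.strip() and not line.startswith("#"):
                counts = {sep: line.count(sep) for sep in (",", "\t", ";")}
                best = max(counts, key=counts.get)
                return best if counts[best] > 0 else ","
    return ","


def read_trajectories(path, column_map: dict | None = None,
                      dt: float | None = None) -> TrajectorySet:
    """Read a delimited trajectory table into a validated :class:`TrajectorySet`.

    Parameters
    ----------
    path : path-like
        Delimited text with a header; delimiter auto-detected among
        comma/tab/semicolon.  Expected columns: ``traj_id``, ``frame`` (or a
        time column ``t`` in seconds, which must be uniformly spaced), and
        coordinates ``x``/``y`` in µm.
    column_map : dict, optional
        Mapping from canonical names (``traj_id``, ``frame``, ``t``, ``x``,
        ``y``) to the file's column names.
    dt : float, optional
        Frame interval in s.  Required with a ``frame`` column; with a ``t``
        column it is inferred (and cross-checked if also given).
    """
    sep = _detect_delimiter(path)
    df = pd.read_csv(path, sep=sep, comment="#")
    column_map = column_map or {}
    rename = {v: k for k, v in column_map.items()}
    df = df.rename(columns=rename)
    df.columns = [str(c).strip() for c in df.columns]

    has_t = "t" in df.columns and "frame" not in df.columns
    required = ["traj_id", "t" if has_t else "frame", "x"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"missing column(s): {missing}")
    coord_cols = ["x", "y"] if "y" in df.columns else ["x"]

    if has_t:
        steps = np.diff(np.unique(df["t"].to_numpy(float)))
        if len(steps) == 0:
            step = dt if dt else 1.0
        else:
            step = float(np.min(steps))
            if np.any(np.abs(steps / step - np.round(steps / step)) > 1e-6):
                raise SamplingError("time column is not uniformly spaced")
        if dt is not None and len(steps) and abs(step - dt) > 1e-6 * dt:
            raise SamplingError(f"time step {step} != declared dt {dt}")
        df["frame"] = np.round(df["t"].to_numpy(float) / step).astype(np.int64)
        dt = step
    if dt is None:
        raise ValueError("dt is required when the file has a frame column")

    df = df[["traj_id", "frame"] + coord_cols].copy()
    df["frame"] = df["frame"].astype(np.int64)
    if df.duplicated(["traj_id", "frame"]).any():
        raise SchemaError("duplicate (traj_id, frame) rows")
    df = df.sort_values(["traj_id", "frame"], kind="stable").reset_index(drop=True)
    return TrajectorySet(data=df, dt=float(dt))


def to_displacements(ts: TrajectorySet) -> DisplacementSet:
    """Difference each trajectory into consecutive-frame displacements.

    Pairs whose frame numbers differ by more than 1 are dropped (counted in
    ``n_gap_dropped``), never rescaled.  For trajectories recorded in a
    periodic box the minimal-image convention unwraps jumps that cross a
    boundary (jumps are assumed much shorter than half the box).
    """
    df = ts.data
    if not len(df):
        empty = np.empty((0, ts.d))
        return DisplacementSet(empty, empty.copy(), np.empty(0, object),
                               ts.dt, ts.d, 0)
    pos = ts.positions()
    frames = df["frame"].to_numpy()
    ids = df["traj_id"].to_numpy()
    same_traj = ids[1:] == ids[:-1]
    gap = frames[1:] - frames[:-1]
    keep = same_traj & (gap == 1)
    dropped = int(np.sum(same_traj & (gap != 1)))
    delta = pos[1:][keep] - pos[:-1][keep]
    if ts.box is not None:
        box = np.asarray(ts.box, dtype=float)
        delta = delta - box * np.round(delta / box)
    return DisplacementSet(
        start=pos[:-1][keep],
        delta=delta,
        traj_id=ids[:-1][keep],
        dt=ts.dt,
        d=ts.d,
        n_gap_dropped=dropped,
    )


def write_trajectories(ts: TrajectorySet, path) -> None:
    """Write a TrajectorySet back to comma-delimited text (lossless)."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# dt = {ts.dt!r}\n")
        ts.data.to_csv(fh, index=False, float_format="%.17g")


def write_field_map(field_map, path) -> None:
    """Write a per-bin result map as delimited text.

    One row per bin; a ``#``-prefixed header carries run metadata (Δt, σ_L,
    prior settings, seed) so the file is self-describing and round-trips.
    """
    df = field_map.table
    with open(path, "w", encoding="utf-8") as fh:
        for key, value in field_map.metadata.items():
            fh.write(f"# {key} = {value}\n")
        df.to_csv(fh, index=False, float_format="%.17g")


def read_field_map(path) -> tuple[pd.DataFrame, dict]:
    """Read back a field-map file; returns (table, metadata)."""
    metadata = {}
    lines = []
    with open(path, "r", encoding="utf-8") as fh:
        for line in fh:
            if line.startswith("#"):
                body = line[1:].strip()
                if "=" in body:
                    key, _, value = body.partition("=")
                    metadata[key.strip()] = value.strip()
            else:
                lines.append(line)
    table = pd.read_csv(io.StringIO("".join(lines)))
    return table, metadata
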