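"""Reading, validating and writing single-particle-tracking trajectory tables.

The canonical on-disk dialect is a per-localization delimited table with a
header ``track_id,frame,x_um,y_um[,label]``: one row per localization,
0-based integer frame indices, positions in micrometres.  Other column
layouts (e.g. externally deposited datasets) are accommodated through a
configurable :class:`Dialect`.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

DEFAULT_DT = 0.05  # acquisition frame interval in seconds (50 ms)


class FormatError(ValueError):
    """Raised when an input table does not conform to the declared dialect."""


class EmptyDatasetError(ValueError):
    """Raised when a file yields no usable trajectories."""


@dataclass(frozen=True)
class Dialect:
    """Column-role mapping and separator for a delimited trajectory table."""

    track_id: str = "track_id"
    frame: str = "frame"
    x: str = "x_um"
    y: str = "y_um"
    label: str | None = "label"
    sep: str = ","

    @property
    def mandatory(self) -> tuple[str, ...]:
        return (self.track_id, self.frame, self.x, self.y)


CANONICAL_DIALECT = Dialect()
TSV_DIALECT = Dialect(sep="\t")


@dataclass
class Trajectory:
    """One tracked particle: time-ordered 2D positions at a fixed frame interval.

    Parameters
    ----------
    track_id : str
        Identifier, unique within a dataset.
    frames : ndarray of int
        Strictly increasing frame indices.  Gaps are allowed and are the
        concern of downstream segmentation.
    x, y : ndarray of float
        Positions in micrometres.
    dt : float
        Frame interval in seconds (default 0.05, i.e. 50 ms).
    label : str or None
        Class name (e.g. cell line of origin), if known.
    """

    track_id: str
    frames: np.ndarray
    x: np.ndarray
    y: np.ndarray
    dt: float = DEFAULT_DT
    label: str | None = None

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=np.int64)
        self.x = np.asarray(self.x, dtype=np.float64)
        self.y = np.asarray(self.y, dtype=np.float64)
        if not (len(self.frames) == len(self.x) == len(self.y)):
            raise ValueError(
                f"track {self.track_id!r}: frames/x/y lengths differ "
                f"({len(self.frames)}/{len(self.x)}/{len(self.y)})"
            )
        if len(self.frames) < 2:
            raise ValueError(f"track {self.track_id!r}: needs >= 2 localizations")
        if np.any(np.diff(self.frames) <= 0):
            raise ValueError(f"track {self.track_id!r}: frames not strictly increasing")
        if self.dt <= 0:
            raise ValueError(f"track {self.track_id!r}: dt must be positive")

    def __len__(self) -> int:
        return len(self.frames)

    @property
    def positions(self) -> np.ndarray:
        """(n, 2) array of positions in micrometres."""
        return np.column_stack([self.x, self.y])

    @property
    def duration_s(self) -> float:
        """Elapsed time between first and last localization, seconds."""
        return float(self.frames[-1] - self.frames[0]) * self.dt

    @property
    def has_gaps(self) -> bool:
        return bool(np.any(np.diff(self.frames) > 1))


@dataclass
class ReadReport:
    """Row/track-level accounting of a read operation."""

    n_rows: int = 0
    n_rows_dropped_nonfinite: int = 0
    n_tracks: int = 0
    n_tracks_dropped_short: int = 0
    n_tracks_with_gaps: int = 0

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class TrajectoryDataset:
    """Ordered collection of trajectories with a shared acquisition context."""

    trajectories: list[Trajectory] = field(default_factory=list)
    provenance: str = ""
    read_report: ReadReport | None = None

    def __post_init__(self) -> None:
        ids = [t.track_id for t in self.trajectories]
        if len(set(ids)) != len(ids):
            seen, dupes = set(), set()
            for i in ids:
                (dupes if i in seen else seen).add(i)
            raise ValueError(f"duplicate track ids: {sorted(dupes)[:5]}")

    def __len__(self) -> int:
        return len(self.trajectories)

    def __iter__(self) -> Iterator[Trajectory]:
        return iter(self.trajectories)

    def __getitem__(self, i: int) -> Trajectory:
        return self.trajectories[i]

    @property
    def label_set(self) -> list[str]:
        """Distinct labels present, sorted."""
        return sorted({t.label for t in self.trajectories if t.label is not None})

    @property
    def labels(self) -> list[str | None]:
        return [t.label for t in self.trajectories]

    def subset(self, label: str) -> "TrajectoryDataset":
        return TrajectoryDataset(
            [t for t in self.trajectories if t.label == label],
            provenance=f"{self.provenance} [label={label}]",
        )


def read_trajectories(
    path: str | Path,
    dialect: Dialect = CANONICAL_DIALECT,
    dt: float = DEFAULT_DT,
) -> TrajectoryDataset:
    """Read a delimited per-localization table into a :class:`TrajectoryDataset`.

    Rows with non-finite coordinates are dropped, frames are sorted within
    each track, and tracks with fewer than two localizations are excluded;
    all drops are counted in ``dataset.read_report``.

    Raises
    ------
    FormatError
        If a mandatory column is missing.
    EmptyDatasetError
        If no usable trajectory remains.
    """
    path = Path(path)
    df = pd.read_csv(path, sep=dialect.sep, float_precision="round_trip")
    for col in dialect.mandatory:
        if col not in df.columns:
            raise FormatError(f"{path}: missing mandatory column {col!r}")
    has_label = dialect.label is not None and dialect.label in df.columns

    report = ReadReport(n_rows=len(df))
    finite = np.isfinite(df[dialect.x].to_numpy(dtype=float)) & np.isfinite(
        df[dialect.y].to_numpy(dtype=float)
    )
    report.n_rows_dropped_nonfinite = int((~finite).sum())
    df = df.loc[finite]
    if len(df) == 0:
        raise EmptyDatasetError(f"{path}: no rows with finite coordinates")

    trajectories: list[Trajectory] = []
    for track_id, group in df.groupby(dialect.track_id, sort=False):
        group = group.sort_values(dialect.frame, kind="mergesort")
        frames = group[dialect.frame].to_numpy(dtype=np.int64)
        if len(frames) < 2:
            report.n_tracks_dropped_short += 1
            continue
        label = None
        if has_label:
            labels = group[dialect.label].dropna().unique()
            if len(labels) > 1:
                raise FormatError(f"{path}: track {track_id!r} has mixed labels {labels}")
            if len(labels) == 1:
                label = str(labels[0])
        traj = Trajectory(
            track_id=str(track_id),
            frames=frames,
            x=group[dialect.x].to_numpy(dtype=float),
            y=group[dialect.y].to_numpy(dtype=float),
            dt=dt,
            label=label,
        )
        if traj.has_gaps:
            report.n_tracks_with_gaps += 1
        trajectories.append(traj)

    if not trajectories:
        raise EmptyDatasetError(f"{path}: no track has >= 2 localizations")
    report.n_tracks = len(trajectories)
    if report.n_rows_dropped_nonfinite or report.n_tracks_dropped_short:
        logger.info(
            "%s: dropped %d non-finite rows, %d single-localization tracks",
            path, report.n_rows_dropped_nonfinite, report.n_tracks_dropped_short,
        )
    return TrajectoryDataset(trajectories, provenance=str(path), read_report=report)


def write_trajectories(
    dataset: TrajectoryDataset,
    path: str | Path,
    dialect: Dialect = CANONICAL_DIALECT,
) -> Path:
    """Write a dataset in the canonical dialect; full round-trip precision."""
    if len(dataset) == 0:
        raise ValueError("refusing to write an empty dataset")
    path = Path(path)
    frames = []
    write_label = any(t.label is not None for t in dataset)
    for t in dataset:
        d = {
            dialect.track_id: t.track_id,
            dialect.frame: t.frames,
            dialect.x: t.x,
            dialect.y: t.y,
        }
        if write_label:
            d[dialect.label or "label"] = t.label
        frames.append(pd.DataFrame(d))
    table = pd.concat(frames, ignore_index=True)
    # 17 significant digits: exact float64 round trip through read_csv
    table.to_csv(path, sep=dialect.sep, index=False, float_format="%.17g")
    return path


def write_metadata_sidecar(dataset: TrajectoryDataset, path: str | Path, **extra) -> Path:
    """Write a JSON sidecar with dt, label set and provenance."""
    path = Path(path)
    dts = {t.dt for t in dataset}
    meta = {
        "dt_s": sorted(dts) if len(dts) > 1 else next(iter(dts)),
        "label_set": dataset.label_set,
        "n_tracks": len(dataset),
        "provenance": dataset.provenance,
        **extra,
    }
    path.write_text(json.dumps(meta, indent=2))
    return path


def summarize_dataset(dataset: TrajectoryDataset | Iterable[Trajectory]) -> pd.DataFrame:
    """Per-label summary: track and localization counts, duration quartiles.

    Durations are in frame steps (``len - 1`` displacements per track).
    An unlabeled track is tallied under the pseudo-label ``"<unlabeled>"``.
    """
    trajectories = list(dataset)
    rows = []
    by_label: dict[str, list[Trajectory]] = {}
    for t in trajectories:
        by_label.setdefault(t.label if t.label is not None else "<unlabeled>", []).append(t)
    for label in sorted(by_label):
        group = by_label[label]
        n_steps = np.array([len(t) - 1 for t in group], dtype=float)
        q25, q50, q75 = np.percentile(n_steps, [25, 50, 75]) if len(group) else (0, 0, 0)
        rows.append(
            {
                "label": label,
                "n_tracks": len(group),
                "n_localizations": int(sum(len(t) for t in group)),
                "steps_q25": float(q25),
                "steps_median": float(q50),
                "steps_q75": float(q75),
            }
        )
    if not rows:
        rows.append(
            {"label": "<none>", "n_tracks": 0, "n_localizations": 0,
             "steps_q25": 0.0, "steps_median": 0.0, "steps_q75": 0.0}
        )
    return pd.DataFrame(rows)
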