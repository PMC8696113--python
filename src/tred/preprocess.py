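"""Turn raw variable-length trajectories into fixed-length reassembled ones.

Raw single-particle tracks vary in duration, so they are not equally
informative training inputs.  The pipeline equalizes information content:

1. split each track into non-overlapping fixed-length segments
   (default 300 steps; trailing remainders are discarded),
2. remove "stalled" segments whose spatial extent is indistinguishable
   from localization noise,
3. translate each surviving segment so it starts at the origin,
4. within each class, randomly shuffle the segments and stitch runs of
   ``target_length / segment_length`` of them (default 10) into one
   fixed-length reassembled trajectory (default 3,000 steps).

Stitching preserves translational continuity by default: each next
segment is shifted so that it continues from the previous segment's end
with its own first displacement.  Ten identical straight-line segments
therefore stitch into one continuous straight line, and no artificial
jump (or zero-length stall) is injected at the joins.  An ``origin`` mode
(plain concatenation of origin-anchored segments) is kept for sensitivity
analysis.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Literal, Sequence

import numpy as np
from scipy.spatial.distance import pdist

from .io import Trajectory, TrajectoryDataset

logger = logging.getLogger(__name__)

SEGMENT_LENGTH = 300  # steps per segment
TARGET_LENGTH = 3000  # steps per reassembled trajectory


@dataclass
class Segment:
    """A fixed-length contiguous excerpt of one trajectory."""

    positions: np.ndarray  # (segment_length, 2), µm
    source_track: str
    label: str | None
    recentred: bool = False
    segment_id: str = ""

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=np.float64)
        if self.positions.ndim != 2 or self.positions.shape[1] != 2:
            raise ValueError("positions must be (n, 2)")

    def __len__(self) -> int:
        return len(self.positions)


@dataclass
class ReassembledTrajectory:
    """Fixed-length stitched sequence of shuffled same-class segments."""

    positions: np.ndarray  # (target_length, 2), µm
    label: str | None
    segment_sources: list[str] = field(default_factory=list)
    rng_seed: int | None = None

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=np.float64)

    def __len__(self) -> int:
        return len(self.positions)


@dataclass(frozen=True)
class StallCriteria:
    """Thresholds below which a segment carries no usable dynamics.

    A segment is stalled when its maximum pairwise displacement falls
    below ``max_span_um`` OR its radius of gyration falls below
    ``min_rg_um``.  Either criterion can be disabled by setting it to
    ``None``.  Defaults (0.2 µm span, 0.05 µm gyration radius) sit a few
    multiples above typical localization precision.
    """

    max_span_um: float | None = 0.2
    min_rg_um: float | None = 0.05

    def __post_init__(self) -> None:
        for v in (self.max_span_um, self.min_rg_um):
            if v is not None and v < 0:
                raise ValueError("thresholds must be >= 0")


def segment_trajectory(
    traj: Trajectory,
    segment_length: int = SEGMENT_LENGTH,
    gap_policy: Literal["split", "bridge"] = "split",
) -> list[Segment]:
    """Cut a trajectory into non-overlapping fixed-length segments.

    With ``gap_policy="split"`` (default) windows never span a gap in the
    frame index: each maximal contiguous run is windowed separately.  With
    ``"bridge"`` the localizations are treated as consecutive regardless
    of missing frames (this fabricates displacements across gaps and is
    only appropriate when gaps are rare and short).

    Trailing remainders shorter than ``segment_length`` are discarded.
    """
    if segment_length < 2:
        raise ValueError("segment_length must be >= 2")
    pos = traj.positions
    if gap_policy == "bridge":
        runs = [(0, len(pos))]
    elif gap_policy == "split":
        breaks = np.flatnonzero(np.diff(traj.frames) != 1)
        starts = np.concatenate([[0], breaks + 1])
        ends = np.concatenate([breaks + 1, [len(pos)]])
        runs = list(zip(starts, ends))
    else:
        raise ValueError(f"unknown gap_policy {gap_policy!r}")

    segments = []
    for start, end in runs:
        n_windows = (end - start) // segment_length
        for w in range(n_windows):
            a = start + w * segment_length
            segments.append(
                Segment(
                    positions=pos[a : a + segment_length].copy(),
                    source_track=traj.track_id,
                    label=traj.label,
                    segment_id=f"{traj.track_id}/{a}",
                )
            )
    return segments


def max_span(positions: np.ndarray) -> float:
    """Maximum pairwise displacement (diameter) of a point set, µm."""
    return float(pdist(positions).max()) if len(positions) > 1 else 0.0


def radius_of_gyration(positions: np.ndarray) -> float:
    """Root-mean-square distance from the centroid, µm."""
    centred = positions - positions.mean(axis=0)
    return float(np.sqrt(np.mean(np.sum(centred**2, axis=1))))


def is_stalled(segment: Segment, criteria: StallCriteria = StallCriteria()) -> bool:
    """True iff the segment fails an enabled stall criterion."""
    if criteria.max_span_um is not None and max_span(segment.positions) < criteria.max_span_um:
        return True
    if criteria.min_rg_um is not None and radius_of_gyration(segment.positions) < criteria.min_rg_um:
        return True
    return False


def recentre(segment: Segment) -> Segment:
    """Translate the segment so its first position is the origin."""
    return Segment(
        positions=segment.positions - segment.positions[0],
        source_track=segment.source_track,
        label=segment.label,
        recentred=True,
        segment_id=segment.segment_id,
    )


def reassemble(
    segments: Sequence[Segment],
    target_length: int = TARGET_LENGTH,
    rng: np.random.Generator | int | None = None,
    stitch: Literal["continuity", "origin"] = "continuity",
) -> list[ReassembledTrajectory]:
    """Shuffle same-class segments and stitch them into fixed-length inputs.

    Segments are permuted, grouped into runs of
    ``target_length // segment_length`` and stitched.  Leftover segments
    that do not fill a complete run are discarded.
    """
    if not segments:
        return []
    labels = {s.label for s in segments}
    if len(labels) > 1:
        raise ValueError(f"segments mix labels: {sorted(map(str, labels))}")
    seg_len = len(segments[0])
    if any(len(s) != seg_len for s in segments):
        raise ValueError("segments have unequal lengths")
    if not all(s.recentred for s in segments):
        raise ValueError("segments must be recentred before reassembly")
    if target_length % seg_len != 0:
        raise ValueError(
            f"target_length {target_length} is not a multiple of segment length {seg_len}"
        )
    per = target_length // seg_len
    seed = rng if isinstance(rng, (int, np.integer)) else None
    gen = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)

    order = gen.permutation(len(segments))
    out = []
    label = next(iter(labels))
    for i in range(len(segments) // per):
        chunk = [segments[j] for j in order[i * per : (i + 1) * per]]
        if stitch == "continuity":
            # each segment continues from the previous end with its own first
            # displacement: no jump and no artificial zero-step at the join
            pieces = [chunk[0].positions.copy()]
            for s in chunk[1:]:
                first_step = s.positions[1] - s.positions[0]
                shift = pieces[-1][-1] + first_step - s.positions[0]
                pieces.append(s.positions + shift)
            positions = np.vstack(pieces)
        elif stitch == "origin":
            positions = np.vstack([s.positions for s in chunk])
        else:
            raise ValueError(f"unknown stitch mode {stitch!r}")
        out.append(
            ReassembledTrajectory(
                positions=positions,
                label=label,
                segment_sources=[s.segment_id for s in chunk],
                rng_seed=seed if isinstance(seed, int) else None,
            )
        )
    return out


@dataclass(frozen=True)
class PreprocessConfig:
    """Parameters of the full segmentation/filter/reassembly pipeline."""

    segment_length: int = SEGMENT_LENGTH
    target_length: int = TARGET_LENGTH
    stall: StallCriteria = StallCriteria()
    gap_policy: Literal["split", "bridge"] = "split"
    stitch: Literal["continuity", "origin"] = "continuity"

    def __post_init__(self) -> None:
        if self.segment_length < 2:
            raise ValueError("segment_length must be >= 2")
        if self.target_length % self.segment_length != 0:
            raise ValueError("target_length must be a multiple of segment_length")


@dataclass
class LabelCounts:
    """Per-label stage accounting of one preprocessing run."""

    raw_tracks: int = 0
    segments_produced: int = 0
    segments_removed: int = 0
    reassembled: int = 0

    @property
    def segments_kept(self) -> int:
        return self.segments_produced - self.segments_removed


@dataclass
class PreprocessReport:
    """Counts per stage per label, plus the configuration and seed used."""

    per_label: dict[str, LabelCounts]
    config: PreprocessConfig
    seed: int
    warnings: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        per = self.config.target_length // self.config.segment_length
        labels = {}
        for lab, c in self.per_label.items():
            labels[lab] = {
                "raw_tracks": c.raw_tracks,
                "segments_produced": c.segments_produced,
                "segments_removed": c.segments_removed,
                "segments_kept": c.segments_kept,
                "reassembled": c.reassembled,
                "leftover": c.segments_kept - per * c.reassembled,
            }
        return {
            "per_label": labels,
            "segments_per_reassembled": per,
            "config": {
                "segment_length": self.config.segment_length,
                "target_length": self.config.target_length,
                "stall_max_span_um": self.config.stall.max_span_um,
                "stall_min_rg_um": self.config.stall.min_rg_um,
                "gap_policy": self.config.gap_policy,
                "stitch": self.config.stitch,
            },
            "seed": self.seed,
            "warnings": self.warnings,
        }

    def save(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(json.dumps(self.to_dict(), indent=2))
        return path


@dataclass
class ReassembledDataset:
    """Collection of reassembled trajectories ready for model consumption."""

    trajectories: list[ReassembledTrajectory]

    def __len__(self) -> int:
        return len(self.trajectories)

    def __iter__(self) -> Iterator[ReassembledTrajectory]:
        return iter(self.trajectories)

    def __getitem__(self, i: int) -> ReassembledTrajectory:
        return self.trajectories[i]

    @property
    def label_set(self) -> list[str]:
        return sorted({t.label for t in self.trajectories if t.label is not None})

    @property
    def labels(self) -> np.ndarray:
        return np.array([t.label for t in self.trajectories])

    def to_array(self) -> np.ndarray:
        """(n, target_length, 2) stacked positions."""
        return np.stack([t.positions for t in self.trajectories])

    def to_trajectory_dataset(self, dt: float = 0.05) -> TrajectoryDataset:
        """Repackage as ordinary trajectories (for serialization in the CSV dialect)."""
        trajs = [
            Trajectory(
                track_id=f"reassembled-{i:05d}",
                frames=np.arange(len(t)),
                x=t.positions[:, 0],
                y=t.positions[:, 1],
                dt=dt,
                label=t.label,
            )
            for i, t in enumerate(self.trajectories)
        ]
        return TrajectoryDataset(trajs, provenance="reassembled")


def preprocess_dataset(
    dataset: TrajectoryDataset,
    config: PreprocessConfig = PreprocessConfig(),
    seed: int = 0,
) -> tuple[ReassembledDataset, PreprocessReport]:
    """Run segment → stall-filter → recentre → shuffle/stitch per class.

    Every trajectory must be labeled.  Returns the reassembled dataset and
    a stage-count report satisfying, per label,
    ``segments_produced == segments_removed + per·reassembled + leftover``
    with ``0 <= leftover < per`` where ``per = target_length / segment_length``.
    """
    if any(t.label is None for t in dataset):
        raise ValueError("preprocess_dataset requires every trajectory to be labeled")
    per_label: dict[str, LabelCounts] = {}
    warnings: list[str] = []
    out: list[ReassembledTrajectory] = []
    rng = np.random.default_rng(seed)
    for label in dataset.label_set:
        counts = per_label[label] = LabelCounts()
        kept: list[Segment] = []
        for traj in dataset:
            if traj.label != label:
                continue
            counts.raw_tracks += 1
            for seg in segment_trajectory(traj, config.segment_length, config.gap_policy):
                counts.segments_produced += 1
                if is_stalled(seg, config.stall):
                    counts.segments_removed += 1
                else:
                    kept.append(recentre(seg))
        built = reassemble(kept, config.target_length, rng, stitch=config.stitch)
        counts.reassembled = len(built)
        out.extend(built)
        if not built:
            msg = f"label {label!r} yielded 0 reassembled trajectories"
            warnings.append(msg)
            logger.warning(msg)
    report = PreprocessReport(per_label=per_label, config=config, seed=seed, warnings=warnings)
    return ReassembledDataset(out), report
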