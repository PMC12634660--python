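"""Domain types, file formats and configuration.

The package operates on four plain-text artifact formats produced either by an
upstream behavioral-decomposition run or by :mod:`soseq.synthetic`:

``labels.csv``
    ``frame,syllable`` — one integer syllable label per video frame
    (``-1`` marks an unassigned/missing frame), with a ``metadata.json``
    sidecar holding ``recording_id, animal_id, context, light_cycle,
    frame_rate``.
``track.csv``
    ``frame,x_mm,y_mm`` — per-frame 2D body centroid in arena millimetres.
``keypoints.csv``
    ``frame,point,x_mm,y_mm`` — ten body points per frame; the centroid is
    the coordinate-wise median.
``annotations.csv``
    ``contact_type,start_frame,end_frame`` — experimenter-scored active or
    passive contact intervals (half-open).

All frame indices are 0-based; all intervals are half-open ``[start, end)``.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("soseq")

CONTEXTS = ("solitary", "dyadic")
LIGHT_CYCLES = ("normal", "reversed")
CONTACT_TYPES = ("active", "passive")

MISSING_LABEL = -1


class FormatError(ValueError):
    """Malformed artifact file; the message names the offending record."""


class MetadataError(ValueError):
    """Missing or invalid recording metadata."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass
class SyllableSequence:
    """Frame-wise syllable labels for one animal in one recording."""

    recording_id: str
    animal_id: str
    context: str
    light_cycle: str
    labels: np.ndarray
    frame_rate: float = 25.0

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=np.int64)
        if self.labels.ndim != 1 or self.labels.size == 0:
            raise FormatError("labels must be a non-empty 1D array")
        if self.labels.min() < MISSING_LABEL:
            raise FormatError(
                f"labels must be >= -1; found {self.labels.min()}"
            )
        if self.context not in CONTEXTS:
            raise MetadataError(f"unknown context {self.context!r}")
        if self.light_cycle not in LIGHT_CYCLES:
            raise MetadataError(f"unknown light_cycle {self.light_cycle!r}")
        if not self.frame_rate > 0:
            raise MetadataError("frame_rate must be positive")

    @property
    def n_frames(self) -> int:
        return int(self.labels.size)

    @property
    def key(self) -> tuple[str, str]:
        return (self.recording_id, self.animal_id)


@dataclass(frozen=True)
class Bout:
    """Maximal run of one syllable: half-open frame interval [start, end)."""

    syllable: int
    start: int
    end: int

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise FormatError(
                f"bout of syllable {self.syllable}: start {self.start} "
                f"must be < end {self.end}"
            )

    @property
    def duration(self) -> int:
        return self.end - self.start


@dataclass
class CentroidTrack:
    """Per-frame 2D body-centroid positions (mm) inside the arena.

    Missing frames are NaN rows.  The default arena is the 453 mm square
    open field.
    """

    recording_id: str
    animal_id: str
    positions: np.ndarray
    arena_size: tuple[float, float] = (453.0, 453.0)

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        if self.positions.ndim != 2 or self.positions.shape[1] != 2:
            raise FormatError("positions must be an (n, 2) array")
        w, d = self.arena_size
        finite = np.isfinite(self.positions).all(axis=1)
        xy = self.positions[finite]
        if xy.size and (
            (xy[:, 0] < -1e-6).any()
            or (xy[:, 0] > w + 1e-6).any()
            or (xy[:, 1] < -1e-6).any()
            or (xy[:, 1] > d + 1e-6).any()
        ):
            bad = np.where(
                finite
                & (
                    (self.positions[:, 0] < 0)
                    | (self.positions[:, 0] > w)
                    | (self.positions[:, 1] < 0)
                    | (self.positions[:, 1] > d)
                )
            )[0][0]
            raise FormatError(
                f"frame {bad}: position outside the {w} x {d} mm arena"
            )

    @property
    def n_frames(self) -> int:
        return int(self.positions.shape[0])

    @property
    def missing(self) -> np.ndarray:
        return ~np.isfinite(self.positions).all(axis=1)


@dataclass(frozen=True)
class AnnotationBout:
    """Experimenter-scored contact interval (half-open frames)."""

    recording_id: str
    contact_type: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.contact_type not in CONTACT_TYPES:
            raise FormatError(f"unknown contact_type {self.contact_type!r}")
        if not self.start < self.end:
            raise FormatError(
                f"annotation [{self.start}, {self.end}): start must be < end"
            )


@dataclass
class TestResult:
    """Outcome of one hypothesis test inside a corrected family."""

    statistic: float
    p_raw: float
    p_adjusted: float
    method: str
    correction: str
    significant: bool
    name: str = ""

    def __post_init__(self) -> None:
        for p in (self.p_raw, self.p_adjusted):
            if np.isfinite(p) and not (0.0 <= p <= 1.0 + 1e-12):
                raise ValueError(f"p-value {p} outside [0, 1]")


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------


@dataclass
class AnalysisConfig:
    """Global analysis parameters.

    Defaults follow the study conditions: 25 Hz video, alpha 0.05,
    0.5% onset-proportion retention threshold, 6 s annotation pooling gap,
    5 s pre-contact control window, 100 mm contact threshold and a 30-frame
    rolling window for the distance/occupancy relation.
    """

    frame_rate: float = 25.0
    alpha: float = 0.05
    onset_threshold: float = 0.005
    syntax_length: int = 3
    pooling_gap_s: float = 6.0
    pre_contact_window_s: float = 5.0
    post_contact_window_s: float = 10.0
    contact_mm: float = 100.0
    rolling_window_frames: int = 30
    min_bin_support: int = 5
    min_edge_count: int = 10
    dkl_pseudocount: float = 1e-6

    def seconds_to_frames(self, seconds: float) -> int:
        """Convert a duration in seconds to a whole number of frames."""
        return int(round(seconds * self.frame_rate))

    @property
    def pooling_gap_frames(self) -> int:
        return self.seconds_to_frames(self.pooling_gap_s)

    @property
    def pre_contact_window_frames(self) -> int:
        return self.seconds_to_frames(self.pre_contact_window_s)

    @property
    def post_contact_window_frames(self) -> int:
        return self.seconds_to_frames(self.post_contact_window_s)

    @classmethod
    def from_file(cls, path: str | Path) -> "AnalysisConfig":
        path = Path(path)
        text = path.read_text()
        if path.suffix in (".yaml", ".yml"):
            import yaml

            data = yaml.safe_load(text)
        else:
            data = json.loads(text)
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise MetadataError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_dict(self) -> dict:
        return asdict(self)


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------


def _check_contiguous(frames: np.ndarray, what: str) -> None:
    expected = np.arange(len(frames))
    if len(frames) == 0:
        raise FormatError(f"{what}: file contains no rows")
    if not np.array_equal(frames, expected):
        dup = pd.Series(frames).duplicated()
        if dup.any():
            raise FormatError(
                f"{what}: frame {frames[dup.idxmax()]} duplicated"
            )
        missing = np.setdiff1d(np.arange(frames.max() + 1), frames)
        if missing.size:
            raise FormatError(f"{what}: frame {missing[0]} missing")
        raise FormatError(f"{what}: frames must be contiguous from 0")


def read_metadata(path: str | Path) -> dict:
    path = Path(path)
    if not path.exists():
        raise MetadataError(f"metadata file {path} not found")
    meta = json.loads(path.read_text())
    required = {"recording_id", "animal_id", "context", "light_cycle"}
    missing = required - set(meta)
    if missing:
        raise MetadataError(f"{path}: missing metadata keys {sorted(missing)}")
    if meta["context"] not in CONTEXTS:
        raise MetadataError(
            f"{path}: unknown context {meta['context']!r} "
            f"(expected one of {CONTEXTS})"
        )
    if meta["light_cycle"] not in LIGHT_CYCLES:
        raise MetadataError(
            f"{path}: unknown light_cycle {meta['light_cycle']!r}"
        )
    meta.setdefault("frame_rate", 25.0)
    return meta


def read_labels(path: str | Path, metadata: dict | None = None) -> SyllableSequence:
    """Read a ``labels.csv`` (+ ``metadata.json`` sidecar) into a sequence."""
    path = Path(path)
    df = pd.read_csv(path)
    if not {"frame", "syllable"} <= set(df.columns):
        raise FormatError(f"{path}: expected columns frame,syllable")
    _check_contiguous(df["frame"].to_numpy(), str(path))
    if metadata is None:
        metadata = read_metadata(path.parent / "metadata.json")
    return SyllableSequence(
        recording_id=str(metadata["recording_id"]),
        animal_id=str(metadata["animal_id"]),
        context=metadata["context"],
        light_cycle=metadata["light_cycle"],
        frame_rate=float(metadata.get("frame_rate", 25.0)),
        labels=df["syllable"].to_numpy(dtype=np.int64),
    )


def write_labels(seq: SyllableSequence, directory: str | Path) -> Path:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    out = directory / "labels.csv"
    pd.DataFrame(
        {"frame": np.arange(seq.n_frames), "syllable": seq.labels}
    ).to_csv(out, index=False)
    meta = {
        "recording_id": seq.recording_id,
        "animal_id": seq.animal_id,
        "context": seq.context,
        "light_cycle": seq.light_cycle,
        "frame_rate": seq.frame_rate,
    }
    (directory / "metadata.json").write_text(json.dumps(meta, indent=1))
    return out


def read_track(path: str | Path, metadata: dict | None = None,
               arena_size: tuple[float, float] = (453.0, 453.0)) -> CentroidTrack:
    """Read a centroid ``track.csv`` (``frame,x_mm,y_mm``)."""
    path = Path(path)
    df = pd.read_csv(path)
    if not {"frame", "x_mm", "y_mm"} <= set(df.columns):
        raise FormatError(f"{path}: expected columns frame,x_mm,y_mm")
    _check_contiguous(df["frame"].to_numpy(), str(path))
    if metadata is None:
        metadata = read_metadata(path.parent / "metadata.json")
    pos = df[["x_mm", "y_mm"]].to_numpy(dtype=float)
    n_missing = int((~np.isfinite(pos).all(axis=1)).sum())
    if n_missing:
        logger.info("%s: %d frames with missing coordinates", path, n_missing)
    return CentroidTrack(
        recording_id=str(metadata["recording_id"]),
        animal_id=str(metadata["animal_id"]),
        positions=pos,
        arena_size=arena_size,
    )


def write_track(track: CentroidTrack, directory: str | Path) -> Path:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    out = directory / "track.csv"
    pd.DataFrame(
        {
            "frame": np.arange(track.n_frames),
            "x_mm": track.positions[:, 0],
            "y_mm": track.positions[:, 1],
        }
    ).to_csv(out, index=False, float_format="%.3f")
    return out


N_BODY_POINTS = 10


def read_keypoints(path: str | Path, metadata: dict | None = None,
                   arena_size: tuple[float, float] = (453.0, 453.0)) -> CentroidTrack:
    """Read a 10-point ``keypoints.csv`` and reduce to a centroid track.

    The centroid is the coordinate-wise median of the ten tracked body
    points (tail excluded upstream), matching the body-center convention
    used for distance-moved and inter-mouse-distance measures.
    """
    path = Path(path)
    df = pd.read_csv(path)
    if not {"frame", "point", "x_mm", "y_mm"} <= set(df.columns):
        raise FormatError(f"{path}: expected columns frame,point,x_mm,y_mm")
    counts = df.groupby("frame").size()
    bad = counts[counts != N_BODY_POINTS]
    if len(bad):
        raise FormatError(
            f"{path}: frame {bad.index[0]} has {bad.iloc[0]} points "
            f"(expected {N_BODY_POINTS})"
        )
    frames = counts.index.to_numpy()
    _check_contiguous(frames, str(path))
    med = df.groupby("frame")[["x_mm", "y_mm"]].median()
    pos = med.to_numpy(dtype=float)
    n_missing = int((~np.isfinite(pos).all(axis=1)).sum())
    if n_missing:
        logger.info("%s: %d frames with missing centroid", path, n_missing)
    if metadata is None:
        metadata = read_metadata(path.parent / "metadata.json")
    return CentroidTrack(
        recording_id=str(metadata["recording_id"]),
        animal_id=str(metadata["animal_id"]),
        positions=pos,
        arena_size=arena_size,
    )


def pool_annotation_bouts(
    bouts: Iterable[AnnotationBout], gap_frames: int
) -> list[AnnotationBout]:
    """Merge same-type bouts separated by a gap strictly shorter than
    ``gap_frames`` (the 6 s pooling rule), independently per contact type."""
    pooled: list[AnnotationBout] = []
    by_type: dict[str, list[AnnotationBout]] = {}
    for b in bouts:
        by_type.setdefault(b.contact_type, []).append(b)
    for ctype, group in by_type.items():
        group = sorted(group, key=lambda b: (b.start, b.end))
        cur = group[0]
        for nxt in group[1:]:
            if nxt.start - cur.end < gap_frames:
                cur = AnnotationBout(
                    cur.recording_id, ctype, cur.start, max(cur.end, nxt.end)
                )
            else:
                pooled.append(cur)
                cur = nxt
        pooled.append(cur)
    return sorted(pooled, key=lambda b: (b.start, b.end, b.contact_type))


def read_annotations(
    path: str | Path,
    recording_id: str | None = None,
    gap_frames: int = 150,
    pool: bool = True,
) -> list[AnnotationBout]:
    """Read scored contact bouts and apply the pooling rule."""
    path = Path(path)
    df = pd.read_csv(path)
    if not {"contact_type", "start_frame", "end_frame"} <= set(df.columns):
        raise FormatError(
            f"{path}: expected columns contact_type,start_frame,end_frame"
        )
    if recording_id is None:
        recording_id = path.parent.name
    bouts = []
    for i, row in df.iterrows():
        if row["end_frame"] <= row["start_frame"]:
            raise FormatError(
                f"{path}: row {i}: end_frame {row['end_frame']} <= "
                f"start_frame {row['start_frame']}"
            )
        bouts.append(
            AnnotationBout(
                recording_id=recording_id,
                contact_type=str(row["contact_type"]),
                start=int(row["start_frame"]),
                end=int(row["end_frame"]),
            )
        )
    if pool and bouts:
        bouts = pool_annotation_bouts(bouts, gap_frames)
    return bouts


def write_annotations(
    bouts: Sequence[AnnotationBout], directory: str | Path
) -> Path:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    out = directory / "annotations.csv"
    pd.DataFrame(
        {
            "contact_type": [b.contact_type for b in bouts],
            "start_frame": [b.start for b in bouts],
            "end_frame": [b.end for b in bouts],
        }
    ).to_csv(out, index=False)
    return out


# ---------------------------------------------------------------------------
# dataset container
# ---------------------------------------------------------------------------


@dataclass
class Recording:
    """All artifacts of one recording (one or two animals)."""

    recording_id: str
    context: str
    light_cycle: str
    sequences: dict[str, SyllableSequence] = field(default_factory=dict)
    tracks: dict[str, CentroidTrack] = field(default_factory=dict)
    annotations: list[AnnotationBout] | None = None

    @property
    def animal_ids(self) -> list[str]:
        return sorted(self.sequences)

    def pair(self) -> tuple[str, str]:
        ids = self.animal_ids
        if len(ids) != 2:
            raise ValueError(
                f"recording {self.recording_id} has {len(ids)} animals, "
                "expected a dyad"
            )
        return ids[0], ids[1]


@dataclass
class Dataset:
    """A collection of recordings plus the shared analysis configuration."""

    recordings: list[Recording]
    config: AnalysisConfig = field(default_factory=AnalysisConfig)

    def by_context(self, context: str) -> list[Recording]:
        return [r for r in self.recordings if r.context == context]

    def sequences(self, context: str | None = None) -> list[SyllableSequence]:
        recs = self.recordings if context is None else self.by_context(context)
        return [s for r in recs for s in r.sequences.values()]

    @property
    def n_syllables(self) -> int:
        return int(max(s.labels.max() for s in self.sequences()) + 1)


def load_dataset(
    data_dir: str | Path, config: AnalysisConfig | None = None
) -> Dataset:
    """Load a dataset directory laid out as
    ``<recording_id>/<animal_id>/{labels.csv,track.csv,metadata.json}``
    with an optional per-recording ``annotations.csv``."""
    data_dir = Path(data_dir)
    config = config or AnalysisConfig()
    recordings = []
    rec_dirs = sorted(p for p in data_dir.iterdir() if p.is_dir())
    if not rec_dirs:
        raise FormatError(f"{data_dir}: no recording directories found")
    for rec_dir in rec_dirs:
        animal_dirs = sorted(
            p for p in rec_dir.iterdir() if (p / "metadata.json").exists()
        )
        if not animal_dirs:
            continue
        rec = None
        for adir in animal_dirs:
            meta = read_metadata(adir / "metadata.json")
            seq = read_labels(adir / "labels.csv", meta)
            if rec is None:
                rec = Recording(
                    recording_id=seq.recording_id,
                    context=seq.context,
                    light_cycle=seq.light_cycle,
                )
            rec.sequences[seq.animal_id] = seq
            track_path = adir / "track.csv"
            if track_path.exists():
                rec.tracks[seq.animal_id] = read_track(track_path, meta)
        ann_path = rec_dir / "annotations.csv"
        if ann_path.exists():
            rec.annotations = read_annotations(
                ann_path,
                recording_id=rec.recording_id,
                gap_frames=config.pooling_gap_frames,
            )
        recordings.append(rec)
    return Dataset(recordings=recordings, config=config)


def write_recording(rec: Recording, data_dir: str | Path) -> Path:
    """Write one recording in the :func:`load_dataset` layout."""
    rec_dir = Path(data_dir) / rec.recording_id
    for animal_id, seq in rec.sequences.items():
        adir = rec_dir / animal_id
        write_labels(seq, adir)
        if animal_id in rec.tracks:
            write_track(rec.tracks[animal_id], adir)
    if rec.annotations is not None:
        write_annotations(rec.annotations, rec_dir)
    return rec_dir
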