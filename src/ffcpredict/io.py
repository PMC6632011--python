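"""Per-frame facial-feature tables: channel registry, feature sets, CSV I/O.

The upstream extractor (OpenFace) emits one CSV per participant with head-pose
rotations, 17 action-unit (AU) intensity channels (0-5) and 18 AU presence
channels (0/1).  This module defines the fixed 38-channel registry, the four
feature subsets FF1-FF4 used throughout the experiments, and the container
types for groups and datasets.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import (
    ConfigurationError,
    EmptyInputError,
    FormatError,
)

# --------------------------------------------------------------------------
# Channel registry
# --------------------------------------------------------------------------

POSE_CHANNELS = ("pose_Rx", "pose_Ry", "pose_Rz")  # pitch, yaw, roll (radians)

_AU_INTENSITY_IDS = (1, 2, 4, 5, 6, 7, 9, 10, 12, 14, 15, 17, 20, 23, 25, 26, 45)
_AU_PRESENCE_IDS = (1, 2, 4, 5, 6, 7, 9, 10, 12, 14, 15, 17, 20, 23, 25, 26, 28, 45)

AU_INTENSITY_CHANNELS = tuple(f"AU{i:02d}_r" for i in _AU_INTENSITY_IDS)
AU_PRESENCE_CHANNELS = tuple(f"AU{i:02d}_c" for i in _AU_PRESENCE_IDS)


@dataclass(frozen=True)
class Channel:
    name: str
    kind: str  # pose | au_intensity | au_presence
    lo: float
    hi: float


@dataclass(frozen=True)
class ChannelRegistry:
    """The fixed, ordered set of 38 per-frame channels."""

    channels: tuple[Channel, ...]

    def __post_init__(self) -> None:
        kinds = [c.kind for c in self.channels]
        names = [c.name for c in self.channels]
        if len(set(names)) != len(names):
            raise ConfigurationError("duplicate channel names in registry")
        if kinds.count("pose") != 3:
            raise ConfigurationError("registry must contain exactly 3 pose channels")
        if kinds.count("au_intensity") != 17:
            raise ConfigurationError("registry must contain exactly 17 AU intensity channels")
        if kinds.count("au_presence") != 18:
            raise ConfigurationError("registry must contain exactly 18 AU presence channels")

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(c.name for c in self.channels)

    def __len__(self) -> int:
        return len(self.channels)

    def index(self, name: str) -> int:
        try:
            return self.names.index(name)
        except ValueError:
            raise ConfigurationError(f"unknown channel name: {name!r}") from None

    def kind(self, name: str) -> str:
        return self.channels[self.index(name)].kind


def default_registry() -> ChannelRegistry:
    chans = [Channel(n, "pose", -np.inf, np.inf) for n in POSE_CHANNELS]
    chans += [Channel(n, "au_intensity", 0.0, 5.0) for n in AU_INTENSITY_CHANNELS]
    chans += [Channel(n, "au_presence", 0.0, 1.0) for n in AU_PRESENCE_CHANNELS]
    return ChannelRegistry(tuple(chans))


REGISTRY = default_registry()

# --------------------------------------------------------------------------
# Feature sets FF1-FF4
# --------------------------------------------------------------------------

# AUs whose estimates are robust enough for the hand-picked subset FF4
# (starred in the upstream extractor's evaluation).
FF4_INTENSITY_IDS = (2, 7, 14, 15, 17, 20, 23, 45)
FF4_PRESENCE_IDS = (1, 2, 4, 5, 9, 20, 23, 26, 28, 45)


@dataclass(frozen=True)
class FeatureSetSpec:
    """A named subset of registry channels, in registry order."""

    name: str
    selected: tuple[str, ...]

    def __len__(self) -> int:
        return len(self.selected)


def _make_feature_sets() -> dict[str, FeatureSetSpec]:
    ff1 = POSE_CHANNELS + AU_INTENSITY_CHANNELS + AU_PRESENCE_CHANNELS
    ff2 = POSE_CHANNELS + AU_PRESENCE_CHANNELS
    ff3 = POSE_CHANNELS + AU_INTENSITY_CHANNELS
    ff4 = (
        POSE_CHANNELS
        + tuple(f"AU{i:02d}_r" for i in FF4_INTENSITY_IDS)
        + tuple(f"AU{i:02d}_c" for i in FF4_PRESENCE_IDS)
    )
    # reorder FF4 into registry order
    order = {n: i for i, n in enumerate(REGISTRY.names)}
    sets = {
        "FF1": ff1,
        "FF2": ff2,
        "FF3": ff3,
        "FF4": tuple(sorted(ff4, key=order.__getitem__)),
    }
    return {k: FeatureSetSpec(k, tuple(v)) for k, v in sets.items()}


FEATURE_SETS = _make_feature_sets()


def feature_set(name: str) -> FeatureSetSpec:
    try:
        return FEATURE_SETS[name]
    except KeyError:
        raise ConfigurationError(
            f"unknown feature set {name!r}; expected one of {sorted(FEATURE_SETS)}"
        ) from None


# --------------------------------------------------------------------------
# Containers
# --------------------------------------------------------------------------


@dataclass
class FrameFeatureTable:
    """One participant's per-frame channel time-series.

    ``values`` has shape (n_frames, n_channels) in the order of ``channel_names``;
    ``valid`` marks frames that passed the tracking-quality gate (invalid frames
    have been repaired in ``values``).
    """

    participant_id: str
    fps: float
    t: np.ndarray
    valid: np.ndarray
    values: np.ndarray
    channel_names: tuple[str, ...] = field(default_factory=lambda: REGISTRY.names)

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.valid = np.asarray(self.valid, dtype=bool)
        self.values = np.asarray(self.values, dtype=float)
        if self.fps <= 0:
            raise ConfigurationError("fps must be positive")
        if self.values.ndim != 2 or self.values.shape[1] != len(self.channel_names):
            raise FormatError("values must be (n_frames, n_channels)")
        if len(self.t) != len(self.values) or len(self.valid) != len(self.values):
            raise FormatError("t, valid and values must have equal length")
        if len(self.t) > 1 and not np.all(np.diff(self.t) > 0):
            raise FormatError("frame times must be strictly increasing")

    @property
    def n_frames(self) -> int:
        return len(self.t)

    def select(self, spec: FeatureSetSpec) -> "FrameFeatureTable":
        """Restrict the table to the channels of ``spec`` (a projection)."""
        missing = [n for n in spec.selected if n not in self.channel_names]
        if missing:
            raise ConfigurationError(f"channel not present in table: {missing[0]!r}")
        idx = [self.channel_names.index(n) for n in spec.selected]
        return FrameFeatureTable(
            participant_id=self.participant_id,
            fps=self.fps,
            t=self.t,
            valid=self.valid,
            values=self.values[:, idx],
            channel_names=tuple(spec.selected),
        )


def select_feature_set(table: FrameFeatureTable, spec: FeatureSetSpec) -> FrameFeatureTable:
    return table.select(spec)


@dataclass
class GroupRecord:
    """One 4-participant group conversation with its end-game label."""

    session_id: str
    group_id: str
    participants: list[FrameFeatureTable]
    label: int

    def __post_init__(self) -> None:
        if len(self.participants) != 4:
            raise FormatError(
                f"group {self.group_id}: expected exactly 4 participants, "
                f"got {len(self.participants)}"
            )
        if self.label not in (0, 1):
            raise FormatError(f"group {self.group_id}: label must be 0 or 1")
        layouts = {p.channel_names for p in self.participants}
        if len(layouts) != 1:
            raise FormatError(f"group {self.group_id}: participants use different registries")


@dataclass
class Dataset:
    """All groups of a study, partitioned into experimental sessions."""

    groups: list[GroupRecord]

    def __post_init__(self) -> None:
        owner: dict[str, str] = {}
        for g in self.groups:
            for p in g.participants:
                prev = owner.setdefault(p.participant_id, g.session_id)
                if prev != g.session_id:
                    raise FormatError(
                        f"participant {p.participant_id!r} appears in sessions "
                        f"{prev!r} and {g.session_id!r}"
                    )

    @property
    def session_ids(self) -> list[str]:
        seen: list[str] = []
        for g in self.groups:
            if g.session_id not in seen:
                seen.append(g.session_id)
        return seen

    @property
    def sessions(self) -> dict[str, list[GroupRecord]]:
        out: dict[str, list[GroupRecord]] = defaultdict(list)
        for g in self.groups:
            out[g.session_id].append(g)
        return dict(out)

    def __len__(self) -> int:
        return len(self.groups)


# --------------------------------------------------------------------------
# CSV dialect
# --------------------------------------------------------------------------

META_COLUMNS = ("frame", "face_id", "timestamp", "confidence", "success")
CSV_COLUMNS = META_COLUMNS + REGISTRY.names

DEFAULT_CONFIDENCE_FLOOR = 0.5


def _repair_invalid(values: np.ndarray, valid: np.ndarray, presence_idx: Sequence[int]) -> np.ndarray:
    """Linear interpolation over invalid frames; edge runs copy the nearest
    valid frame; presence channels are re-binarised afterwards."""
    out = values.copy()
    n = len(out)
    good = np.flatnonzero(valid)
    bad = np.flatnonzero(~valid)
    if len(bad) == 0:
        return out
    x = np.arange(n, dtype=float)
    for j in range(out.shape[1]):
        out[bad, j] = np.interp(x[bad], x[good], out[good, j])
    for j in presence_idx:
        out[:, j] = (out[:, j] >= 0.5).astype(float)
    return out


def read_feature_csv(
    path,
    fps: float,
    confidence_floor: float = DEFAULT_CONFIDENCE_FLOOR,
    participant_id: str | None = None,
) -> FrameFeatureTable:
    """Read one participant's per-frame table in the upstream extractor dialect.

    Frames with ``success == 0`` or ``confidence < confidence_floor`` are marked
    invalid and repaired by linear interpolation between the nearest valid
    neighbours (edge runs copy the nearest valid frame).
    """
    df = pd.read_csv(path, float_precision="round_trip")
    df.columns = [c.strip() for c in df.columns]
    for col in CSV_COLUMNS:
        if col not in df.columns:
            raise FormatError(f"{path}: missing mandatory column {col!r}")
    valid = (df["success"].to_numpy() != 0) & (
        df["confidence"].to_numpy() >= confidence_floor
    )
    if not valid.any():
        raise EmptyInputError(f"{path}: no valid frames after quality filtering")
    values = df[list(REGISTRY.names)].to_numpy(dtype=float)
    presence_idx = [i for i, c in enumerate(REGISTRY.channels) if c.kind == "au_presence"]
    values = _repair_invalid(values, valid, presence_idx)
    if not np.all(np.isfinite(values)):
        raise FormatError(f"{path}: non-finite channel values after repair")
    pid = participant_id if participant_id is not None else str(path)
    return FrameFeatureTable(
        participant_id=pid,
        fps=fps,
        t=df["timestamp"].to_numpy(dtype=float),
        valid=valid,
        values=values,
    )


def write_feature_csv(table: FrameFeatureTable, path) -> None:
    """Write a table back to the upstream dialect (valid frames only are
    assumed; the success/confidence columns reflect the ``valid`` mask)."""
    if tuple(table.channel_names) != REGISTRY.names:
        raise FormatError("only full-registry tables can be written to the dialect")
    n = table.n_frames
    df = pd.DataFrame({
        "frame": np.arange(1, n + 1),
        "face_id": np.zeros(n, dtype=int),
        "timestamp": table.t,
        "confidence": np.where(table.valid, 1.0, 0.0),
        "success": table.valid.astype(int),
    })
    for j, name in enumerate(REGISTRY.names):
        df[name] = table.values[:, j]
    df.to_csv(path, index=False)


def load_dataset(
    metadata_path,
    fps: float,
    confidence_floor: float = DEFAULT_CONFIDENCE_FLOOR,
) -> Dataset:
    """Assemble a :class:`Dataset` from a group-metadata CSV.

    The metadata file has columns ``session_id, group_id, participant_id,
    feature_csv_path, label``; feature paths are resolved relative to the
    metadata file's directory.
    """
    import os

    meta = pd.read_csv(metadata_path)
    for col in ("session_id", "group_id", "participant_id", "feature_csv_path", "label"):
        if col not in meta.columns:
            raise FormatError(f"{metadata_path}: missing metadata column {col!r}")
    base = os.path.dirname(os.fspath(metadata_path))
    groups: list[GroupRecord] = []
    for (sid, gid), rows in meta.groupby(["session_id", "group_id"], sort=False):
        labels = set(rows["label"].astype(int))
        if len(labels) != 1:
            raise FormatError(f"group {gid}: inconsistent labels {labels}")
        parts = [
            read_feature_csv(
                os.path.join(base, r.feature_csv_path),
                fps=fps,
                confidence_floor=confidence_floor,
                participant_id=str(r.participant_id),
            )
            for r in rows.itertuples()
        ]
        groups.append(GroupRecord(str(sid), str(gid), parts, labels.pop()))
    return Dataset(groups)
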