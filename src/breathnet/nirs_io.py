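"""Reading, windowing, channel selection and splitting of NIRS recordings.

A recording is one participant performing one breathing condition: a few
minutes of multichannel hemodynamic signal sampled at 10 Hz. Recordings are
stored as plain CSV (one sample per row, header row naming the channels, a
time column optional), optionally accompanied by a JSON exclusion-mask
sidecar listing sample ranges contaminated by movement artifacts.

The classifier consumes fixed-length windows (default 64 samples = 6.4 s),
cut left-to-right without overlap; only the O2Hb and HHb channels may feed
the model (THb and TSI are linear/ratio functions of them and are excluded
by design). Train/test splitting is stratified within each class by default,
with a subject-level mode that assigns whole participants to one side.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import h5py
import numpy as np
import pandas as pd

__all__ = [
    "Condition",
    "CHANNEL_NAMES",
    "MODEL_CHANNELS",
    "EXCLUDED_CHANNELS",
    "NirsRecording",
    "Window",
    "SplitSpec",
    "ExcludedChannelError",
    "load_recording",
    "crop_windows",
    "select_channels",
    "split_dataset",
    "normalize_windows",
    "windows_to_arrays",
    "save_windows",
    "load_windows",
]


class Condition(str, Enum):
    """The three breathing conditions, in canonical (class-index) order."""

    BASELINE = "baseline"
    LOADED = "loaded"
    RAPID_SHALLOW = "rapid_shallow"

    @property
    def index(self) -> int:
        return list(Condition).index(self)


#: All channels a device file may contain, in canonical order.
CHANNEL_NAMES = ("O2Hb", "HHb", "THb", "TSI")
#: Channels the classifier may consume, in the fixed model order.
MODEL_CHANNELS = ("O2Hb", "HHb")
#: Channels excluded from modeling because they are functions of the above.
EXCLUDED_CHANNELS = ("THb", "TSI")

#: Standard condition durations (seconds): baseline 3 min, others 5 min.
CONDITION_DURATIONS_S = {
    Condition.BASELINE: 180.0,
    Condition.LOADED: 300.0,
    Condition.RAPID_SHALLOW: 300.0,
}


class ExcludedChannelError(ValueError):
    """Raised when a channel excluded by design is requested for modeling."""


@dataclass
class NirsRecording:
    """One participant-condition time series with per-channel samples."""

    subject_id: str
    condition: Condition
    channels: dict[str, np.ndarray]
    sampling_rate: float = 10.0

    def __post_init__(self):
        self.condition = Condition(self.condition)
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        if not self.channels:
            raise ValueError("at least one channel is required")
        for name in self.channels:
            if name not in CHANNEL_NAMES:
                raise ValueError(f"unknown channel {name!r}; expected {CHANNEL_NAMES}")
        self.channels = {k: np.asarray(v, dtype=np.float64).ravel()
                         for k, v in self.channels.items()}
        lengths = {len(v) for v in self.channels.values()}
        if len(lengths) != 1:
            raise ValueError(f"channel lengths differ: {lengths}")

    @property
    def n_samples(self) -> int:
        return len(next(iter(self.channels.values())))

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.sampling_rate

    @property
    def channel_names(self) -> tuple[str, ...]:
        return tuple(c for c in CHANNEL_NAMES if c in self.channels)


@dataclass
class Window:
    """A fixed-length labeled segment: the classifier's input unit."""

    values: np.ndarray  # (channels, length)
    label: Condition
    subject_id: str
    source_offset: int
    channel_names: tuple[str, ...]

    def __post_init__(self):
        self.values = np.atleast_2d(np.asarray(self.values, dtype=np.float32))
        self.label = Condition(self.label)
        if self.values.shape[0] != len(self.channel_names):
            raise ValueError("values rows must match channel_names")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("window contains non-finite values")

    @property
    def length(self) -> int:
        return self.values.shape[1]


@dataclass(frozen=True)
class SplitSpec:
    """How to divide windows into train and test sets."""

    train_fraction: float = 0.8
    mode: str = "stratified_random"
    seed: int = 0

    def __post_init__(self):
        if not 0.0 < self.train_fraction < 1.0:
            raise ValueError("train_fraction must be in (0, 1)")
        if self.mode not in ("stratified_random", "subject_level"):
            raise ValueError(f"unknown split mode {self.mode!r}")


def _apply_exclusion_mask(values: np.ndarray, mask_ranges, path) -> np.ndarray:
    keep = np.ones(len(values), dtype=bool)
    for rng in mask_ranges:
        start, stop = int(rng[0]), int(rng[1])
        if not 0 <= start <= stop <= len(values):
            raise ValueError(f"exclusion range {rng} out of bounds for {path}")
        keep[start:stop] = False
    return values[keep]


def load_recording(
    path,
    format_spec: Mapping[str, str] | None = None,
    *,
    subject_id: str | None = None,
    condition: Condition | str,
    sampling_rate: float = 10.0,
    exclusion_mask: Path | str | None = None,
) -> NirsRecording:
    """Read one CSV recording into a :class:`NirsRecording`.

    ``format_spec`` maps channel names to CSV column names; by default any
    header column whose name matches a known channel is used as-is. A cell
    that is missing or fails numeric parsing raises a ``ValueError`` naming
    the row and column rather than being silently filled.

    ``exclusion_mask`` may point to a JSON sidecar of the form
    ``{"exclude": [[start, stop], ...]}`` (sample indices, half-open); the
    masked samples are removed before windowing.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    frame = pd.read_csv(path, dtype=str, skipinitialspace=True)
    if format_spec is None:
        format_spec = {c: c for c in frame.columns if c in CHANNEL_NAMES}
    if not format_spec:
        raise ValueError(f"{path}: no recognized channel columns in header "
                         f"{list(frame.columns)}")
    for chan, col in format_spec.items():
        if chan not in CHANNEL_NAMES:
            raise ValueError(f"unknown channel {chan!r}; expected {CHANNEL_NAMES}")
        if col not in frame.columns:
            raise ValueError(f"{path}: declared column {col!r} not present")

    channels: dict[str, np.ndarray] = {}
    for chan, col in format_spec.items():
        raw = frame[col]
        parsed = pd.to_numeric(raw, errors="coerce")
        bad = parsed.isna()
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            cell = raw.iloc[row]
            raise ValueError(
                f"{path}: non-numeric value {cell!r} in column {col!r}, "
                f"data row {row}")
        channels[chan] = parsed.to_numpy(dtype=np.float64)

    if exclusion_mask is not None:
        ranges = json.loads(Path(exclusion_mask).read_text()).get("exclude", [])
        channels = {k: _apply_exclusion_mask(v, ranges, path)
                    for k, v in channels.items()}

    return NirsRecording(
        subject_id=subject_id if subject_id is not None else path.stem,
        condition=Condition(condition),
        channels=channels,
        sampling_rate=sampling_rate,
    )


def crop_windows(
    recording: NirsRecording,
    window_len: int = 64,
    stride: int = 64,
    channels: Sequence[str] | None = None,
) -> list[Window]:
    """Cut a recording into fixed-length windows, left to right.

    Any trailing remainder shorter than ``window_len`` is discarded; a
    recording shorter than one window yields an empty list. Each window
    inherits the recording's label and subject id.
    """
    if window_len < 1 or stride < 1:
        raise ValueError("window_len and stride must be >= 1")
    names = tuple(channels) if channels is not None else recording.channel_names
    for name in names:
        if name not in recording.channels:
            raise ValueError(f"channel {name!r} not in recording")
    stacked = np.stack([recording.channels[c] for c in names])
    n = recording.n_samples
    out: list[Window] = []
    for start in range(0, n - window_len + 1, stride):
        out.append(Window(
            values=stacked[:, start:start + window_len].astype(np.float32),
            label=recording.condition,
            subject_id=recording.subject_id,
            source_offset=start,
            channel_names=names,
        ))
    return out


def select_channels(windows: Sequence[Window],
                    channel_set: Iterable[str]) -> list[Window]:
    """Restrict windows to a subset of {O2Hb, HHb}, in fixed model order.

    The order is always O2Hb first, HHb second, regardless of the order in
    ``channel_set``. Requesting THb or TSI raises
    :class:`ExcludedChannelError`: both are deterministic functions of O2Hb
    and HHb and are excluded from modeling by design.
    """
    requested = set(channel_set)
    for name in requested:
        if name in EXCLUDED_CHANNELS:
            raise ExcludedChannelError(
                f"channel {name!r} is excluded by design: THb = O2Hb + HHb and "
                "TSI = O2Hb / THb carry no information beyond O2Hb and HHb")
        if name not in MODEL_CHANNELS:
            raise ValueError(f"unknown channel {name!r}; model channels are "
                             f"{MODEL_CHANNELS}")
    if not requested:
        raise ValueError("channel_set must not be empty")
    ordered = tuple(c for c in MODEL_CHANNELS if c in requested)
    out = []
    for w in windows:
        missing = requested - set(w.channel_names)
        if missing:
            raise ValueError(f"window lacks channels {sorted(missing)}")
        idx = [w.channel_names.index(c) for c in ordered]
        out.append(Window(
            values=w.values[idx],
            label=w.label,
            subject_id=w.subject_id,
            source_offset=w.source_offset,
            channel_names=ordered,
        ))
    return out


def split_dataset(windows: Sequence[Window],
                  spec: SplitSpec) -> tuple[list[Window], list[Window]]:
    """Split windows into disjoint train/test sets.

    ``stratified_random`` draws within each class with per-class train count
    ``ceil(train_fraction * class_size)`` — the rounding convention that the
    published per-class train/test counts follow. ``subject_level`` assigns
    whole subjects, train subject count ``ceil(train_fraction * n_subjects)``
    (17 of 21 at 0.8), so no subject contributes to both sides. Identical
    seeds produce identical splits.
    """
    rng = np.random.default_rng(spec.seed)
    train_idx: list[int] = []
    test_idx: list[int] = []

    if spec.mode == "stratified_random":
        labels = np.array([w.label.index for w in windows])
        for cls in sorted(set(labels.tolist())):
            members = np.flatnonzero(labels == cls)
            n_train = math.ceil(spec.train_fraction * len(members))
            if n_train == 0 or n_train == len(members):
                raise ValueError(
                    f"class {list(Condition)[cls].value!r} has {len(members)} "
                    "windows: too few to populate both sides of the split")
            perm = rng.permutation(members)
            train_idx.extend(perm[:n_train].tolist())
            test_idx.extend(perm[n_train:].tolist())
    else:  # subject_level
        subjects = sorted({w.subject_id for w in windows})
        n_train = math.ceil(spec.train_fraction * len(subjects))
        if n_train == 0 or n_train == len(subjects):
            raise ValueError(f"{len(subjects)} subjects: too few to populate "
                             "both sides of a subject-level split")
        perm = rng.permutation(len(subjects))
        train_subjects = {subjects[i] for i in perm[:n_train]}
        for i, w in enumerate(windows):
            (train_idx if w.subject_id in train_subjects else test_idx).append(i)
        if not test_idx:
            raise ValueError("subject-level split produced an empty test set")

    train = [windows[i] for i in sorted(train_idx)]
    test = [windows[i] for i in sorted(test_idx)]
    return train, test


def normalize_windows(x: np.ndarray) -> np.ndarray:
    """Per-window, per-channel zero-mean scaling (the default preprocessing).

    Removes each window's mean offset (and with it most slow drift) while
    preserving oscillation amplitude, which carries class information.
    """
    x = np.asarray(x, dtype=np.float32)
    return x - x.mean(axis=-1, keepdims=True)


def windows_to_arrays(windows: Sequence[Window],
                      normalize: bool = True) -> tuple[np.ndarray, np.ndarray]:
    """Stack windows into ``(n, channels, length)`` values and int labels."""
    if not windows:
        raise ValueError("empty window sequence")
    shapes = {w.values.shape for w in windows}
    if len(shapes) != 1:
        raise ValueError(f"inconsistent window shapes: {shapes}")
    x = np.stack([w.values for w in windows]).astype(np.float32)
    y = np.array([w.label.index for w in windows], dtype=np.int64)
    if normalize:
        x = normalize_windows(x)
    return x, y


# ---------------------------------------------------------------------------
# Windowed-dataset container (HDF5)
# ---------------------------------------------------------------------------

def save_windows(path, windows: Sequence[Window],
                 split: Mapping[int, str] | None = None) -> None:
    """Write a window set (and optional split membership) to one HDF5 file."""
    if not windows:
        raise ValueError("nothing to save")
    shapes = {w.values.shape for w in windows}
    if len(shapes) != 1:
        raise ValueError(f"inconsistent window shapes: {shapes}")
    membership = np.array(
        [(split or {}).get(i, "") for i in range(len(windows))], dtype="S8")
    with h5py.File(path, "w") as f:
        f.create_dataset("values", data=np.stack([w.values for w in windows]))
        f.create_dataset("labels", data=np.array(
            [w.label.value.encode() for w in windows]))
        f.create_dataset("subject_ids", data=np.array(
            [w.subject_id.encode() for w in windows]))
        f.create_dataset("source_offsets", data=np.array(
            [w.source_offset for w in windows], dtype=np.int64))
        f.create_dataset("split", data=membership)
        f.attrs["channel_names"] = ",".join(windows[0].channel_names)


def load_windows(path) -> tuple[list[Window], dict[int, str]]:
    """Read a window set written by :func:`save_windows`.

    Returns the windows plus a ``{index: "train"|"test"}`` mapping (empty
    when no split was stored).
    """
    with h5py.File(path, "r") as f:
        values = f["values"][...]
        labels = [s.decode() for s in f["labels"][...]]
        subjects = [s.decode() for s in f["subject_ids"][...]]
        offsets = f["source_offsets"][...]
        membership = [s.decode() for s in f["split"][...]]
        names = tuple(f.attrs["channel_names"].split(","))
    windows = [
        Window(values=values[i], label=Condition(labels[i]),
               subject_id=subjects[i], source_offset=int(offsets[i]),
               channel_names=names)
        for i in range(len(labels))
    ]
    split = {i: m for i, m in enumerate(membership) if m}
    return windows, split
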