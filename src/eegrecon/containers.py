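"""In-memory and on-disk containers for epoched multichannel EEG.

The native epoch container is deliberately plain text: a ``key: value``
header followed by one whitespace-delimited numeric block per trial
(rows = channels, columns = samples, values in microvolts).  It is
self-describing, diff-able, and carries the channel order explicitly —
channel order is authoritative from the header and never re-sorted,
because downstream spatial filtering is order-sensitive.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Montage",
    "EpochSet",
    "Recording",
    "ParseError",
    "read_epochs",
    "write_epochs",
    "select_channels",
    "select_trials",
    "standard_montage_22",
    "CHANNELS_22",
    "INPUT_CHANNELS_8",
]


class ParseError(ValueError):
    """Raised when an epoch container cannot be parsed."""


#: Full montage used throughout: 22 electrodes of the 10-20 system covering
#: frontal, central, centro-parietal and parietal midline/lateral sites.
CHANNELS_22 = (
    "Fz", "FC3", "FC1", "FCz", "FC2", "FC4",
    "C5", "C3", "C1", "Cz", "C2", "C4", "C6",
    "CP3", "CP1", "CPz", "CP2", "CP4",
    "P1", "Pz", "P2", "POz",
)

#: Reduced recording set: 8 electrodes over the central/centro-parietal
#: strip (sensorimotor cortex), from which the full montage is predicted.
INPUT_CHANNELS_8 = ("C3", "C1", "Cz", "C2", "C4", "CP1", "CPz", "CP2")

# Schematic 2D scalp coordinates (unit-circle head, nose up, Cz at origin).
_POSITIONS_22 = {
    "Fz": (0.0, 0.5),
    "FC3": (-0.35, 0.25), "FC1": (-0.15, 0.25), "FCz": (0.0, 0.25),
    "FC2": (0.15, 0.25), "FC4": (0.35, 0.25),
    "C5": (-0.6, 0.0), "C3": (-0.4, 0.0), "C1": (-0.2, 0.0),
    "Cz": (0.0, 0.0), "C2": (0.2, 0.0), "C4": (0.4, 0.0), "C6": (0.6, 0.0),
    "CP3": (-0.35, -0.25), "CP1": (-0.15, -0.25), "CPz": (0.0, -0.25),
    "CP2": (0.15, -0.25), "CP4": (0.35, -0.25),
    "P1": (-0.15, -0.5), "Pz": (0.0, -0.5), "P2": (0.15, -0.5),
    "POz": (0.0, -0.65),
}


@dataclass(frozen=True)
class Montage:
    """Electrode labels, schematic scalp positions, and the reduced subset.

    Parameters
    ----------
    labels : ordered channel names (unique).
    positions : (n_channels, 2) coordinates on the unit-circle head scheme.
    input_subset : ordered labels designated as the reduced recording set.
    """

    labels: tuple[str, ...]
    positions: np.ndarray
    input_subset: tuple[str, ...]

    def __post_init__(self) -> None:
        labels = tuple(self.labels)
        subset = tuple(self.input_subset)
        object.__setattr__(self, "labels", labels)
        object.__setattr__(self, "input_subset", subset)
        pos = np.asarray(self.positions, dtype=float)
        object.__setattr__(self, "positions", pos)
        if len(set(labels)) != len(labels):
            raise ValueError("montage labels must be unique")
        if pos.shape != (len(labels), 2):
            raise ValueError("positions must be (n_labels, 2)")
        missing = [c for c in subset if c not in labels]
        if missing:
            raise ValueError(f"input_subset labels not in montage: {missing}")

    def position_of(self, label: str) -> np.ndarray:
        return self.positions[self.labels.index(label)]


def standard_montage_22() -> Montage:
    """The 22-channel 10-20 montage with its 8-channel central subset."""
    pos = np.array([_POSITIONS_22[c] for c in CHANNELS_22])
    return Montage(labels=CHANNELS_22, positions=pos,
                   input_subset=INPUT_CHANNELS_8)


@dataclass
class EpochSet:
    """Labelled trials of multichannel EEG.

    Attributes
    ----------
    data : (n_trials, n_channels, n_samples) array, microvolts.
    fs : sampling rate in Hz.
    labels : channel names, order matching the channel axis.
    classes : per-trial integer class id.
    class_names : id -> human-readable name.
    """

    data: np.ndarray
    fs: float
    labels: tuple[str, ...]
    classes: np.ndarray
    class_names: dict[int, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.classes = np.asarray(self.classes, dtype=int)
        self.labels = tuple(self.labels)
        if self.data.ndim != 3:
            raise ValueError("data must be (trials, channels, samples)")
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if self.data.shape[1] != len(self.labels):
            raise ValueError("channel axis does not match labels")
        if self.classes.shape != (self.data.shape[0],):
            raise ValueError("classes length must equal trial count")
        for cid in np.unique(self.classes):
            if int(cid) not in self.class_names:
                raise ValueError(f"class id {int(cid)} has no name")
        for name in self.class_names.values():
            if any(ch.isspace() for ch in name):
                raise ValueError("class names must not contain whitespace")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def n_samples(self) -> int:
        return self.data.shape[2]


@dataclass
class Recording:
    """Continuous multichannel EEG with cue markers.

    ``events`` is a list of ``(sample_index, class_id)`` pairs with strictly
    increasing sample indices; it feeds cue-locked epoch extraction.
    """

    data: np.ndarray
    fs: float
    labels: tuple[str, ...]
    events: list[tuple[int, int]]

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.labels = tuple(self.labels)
        if self.data.ndim != 2:
            raise ValueError("data must be (channels, samples)")
        if self.data.shape[0] != len(self.labels):
            raise ValueError("channel axis does not match labels")
        last = -1
        for s, _ in self.events:
            if not 0 <= s < self.data.shape[1]:
                raise ValueError(f"event sample {s} out of bounds")
            if s <= last:
                raise ValueError("event samples must be strictly increasing")
            last = s


_MAGIC = "# eegrecon epochs v1"


def write_epochs(epochs: EpochSet, path: str | Path) -> Path:
    """Write an :class:`EpochSet` to the native plain-text container.

    Values are written with 17 significant digits so the round-trip is
    exact at float64 precision.
    """
    path = Path(path)
    buf = io.StringIO()
    buf.write(_MAGIC + "\n")
    buf.write(f"fs: {epochs.fs!r}\n")
    buf.write(f"n_trials: {epochs.n_trials}\n")
    buf.write(f"n_channels: {epochs.n_channels}\n")
    buf.write(f"n_samples: {epochs.n_samples}\n")
    buf.write("channels: " + " ".join(epochs.labels) + "\n")
    names = " ".join(f"{k}:{v}" for k, v in sorted(epochs.class_names.items()))
    buf.write("class_names: " + names + "\n")
    buf.write("classes: " + " ".join(str(int(c)) for c in epochs.classes) + "\n")
    path.write_text(buf.getvalue())
    with path.open("a") as fh:
        for i in range(epochs.n_trials):
            fh.write(f"# trial {i}\n")
            np.savetxt(fh, epochs.data[i], fmt="%.17g")
    return path


def _parse_header(lines: list[str]) -> dict:
    hdr: dict = {}
    if not lines or lines[0].strip() != _MAGIC:
        raise ParseError("not an epoch container (missing magic line)")
    for ln in lines[1:]:
        key, _, val = ln.partition(":")
        hdr[key.strip()] = val.strip()
    for key in ("fs", "n_trials", "n_channels", "n_samples",
                "channels", "class_names", "classes"):
        if key not in hdr:
            raise ParseError(f"malformed header: missing '{key}'")
    return hdr


def read_epochs(path: str | Path) -> EpochSet:
    """Read an :class:`EpochSet` written by :func:`write_epochs`."""
    path = Path(path)
    header_lines: list[str] = []
    blocks: list[list[str]] = []
    with path.open() as fh:
        in_header = True
        for ln in fh:
            if ln.startswith("# trial"):
                in_header = False
                blocks.append([])
                continue
            if in_header:
                if ln.strip():
                    header_lines.append(ln.rstrip("\n"))
            else:
                blocks[-1].append(ln)
    hdr = _parse_header(header_lines)
    try:
        fs = float(hdr["fs"])
        n_trials = int(hdr["n_trials"])
        n_channels = int(hdr["n_channels"])
        n_samples = int(hdr["n_samples"])
        labels = tuple(hdr["channels"].split())
        class_names = {}
        if hdr["class_names"]:
            for item in hdr["class_names"].split():
                k, _, v = item.partition(":")
                class_names[int(k)] = v
        classes = np.array([int(c) for c in hdr["classes"].split()], dtype=int)
    except ValueError as exc:
        raise ParseError(f"malformed header: {exc}") from exc
    if len(labels) != n_channels:
        raise ParseError("header channel list does not match n_channels")
    if len(blocks) != n_trials:
        raise ParseError(
            f"expected {n_trials} trial blocks, found {len(blocks)}")
    if classes.shape != (n_trials,):
        raise ParseError("classes line does not match n_trials")
    for cid in np.unique(classes) if n_trials else []:
        if int(cid) not in class_names:
            raise ParseError(f"unknown class id {int(cid)} in classes line")

    data = np.empty((n_trials, n_channels, n_samples))
    for i, block in enumerate(blocks):
        try:
            frame = pd.read_csv(io.StringIO("".join(block)), sep=r"\s+",
                                header=None, dtype=float,
                                float_precision="round_trip")
        except Exception as exc:
            raise ParseError(f"trial {i}: unreadable numeric block ({exc})") \
                from exc
        arr = frame.to_numpy()
        if arr.shape != (n_channels, n_samples) or np.isnan(arr).any():
            raise ParseError(
                f"trial {i}: block shape {arr.shape} does not match "
                f"({n_channels}, {n_samples})")
        data[i] = arr
    return EpochSet(data=data, fs=fs, labels=labels, classes=classes,
                    class_names=class_names)


def select_channels(epochs: EpochSet, wanted: Sequence[str]) -> EpochSet:
    """Subset/reorder channels; returned axis is ordered exactly as ``wanted``."""
    idx = []
    for lab in wanted:
        if lab not in epochs.labels:
            raise KeyError(f"channel '{lab}' not present in epochs")
        idx.append(epochs.labels.index(lab))
    return replace(epochs, data=epochs.data[:, idx, :].copy(),
                   labels=tuple(wanted))


def select_trials(epochs: EpochSet, indices: Sequence[int]) -> EpochSet:
    """Subset trials by index (order preserved as given)."""
    idx = np.asarray(indices, dtype=int)
    return replace(epochs, data=epochs.data[idx].copy(),
                   classes=epochs.classes[idx].copy())
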