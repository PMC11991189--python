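"""Band-pass filtering, cue-locked window extraction, and standardization.

Motor-imagery information lives in the mu/beta rhythms, so the pipeline
restricts signals to 8-30 Hz with a zero-phase Butterworth band-pass
before any spatial modelling.  Windows are cut relative to the cue marker:
the window starts ``start_offset_s`` seconds before/after the cue and
lasts ``duration_s`` seconds.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
from scipy import signal

from .containers import EpochSet, Recording

__all__ = [
    "FilterSpec",
    "WindowSpec",
    "bandpass",
    "extract_windows",
    "standardize_columns",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class FilterSpec:
    """Band-pass filter parameters.

    The default is a 4th-order Butterworth between 8 and 30 Hz, applied
    forward-backward (zero phase) so spatial-filter estimation downstream
    sees phase-faithful signals.
    """

    low_hz: float = 8.0
    high_hz: float = 30.0
    order: int = 4
    kind: str = "butter"

    def validate(self, fs: float) -> None:
        if not 0 < self.low_hz < self.high_hz:
            raise ValueError("need 0 < low_hz < high_hz")
        if self.high_hz >= fs / 2:
            raise ValueError(
                f"high cutoff {self.high_hz} Hz >= Nyquist {fs / 2} Hz")
        if self.kind != "butter":
            raise ValueError(f"unknown filter kind '{self.kind}'")

    def sos(self, fs: float) -> np.ndarray:
        self.validate(fs)
        return signal.butter(self.order, [self.low_hz, self.high_hz],
                             btype="bandpass", fs=fs, output="sos")


@dataclass(frozen=True)
class WindowSpec:
    """Cue-locked window geometry.

    ``start_offset_s`` is relative to cue onset and, together with
    ``duration_s``, uniquely determines the sample range
    ``[cue + round(start_offset_s*fs), +round(duration_s*fs))`` (0-based,
    half-open).  ``end_offset_s`` and ``mi_duration_s`` are retained as
    metadata describing the paradigm (nominal imagery length) but do not
    enter the sample arithmetic.
    """

    duration_s: float = 6.8
    start_offset_s: float = -1.9
    end_offset_s: float = 2.0
    mi_duration_s: float = 3.0
    overlap: float = 0.0

    def __post_init__(self) -> None:
        if self.duration_s <= 0:
            raise ValueError("duration_s must be positive")
        if not 0 <= self.overlap < 1:
            raise ValueError("overlap must be in [0, 1)")


def bandpass(epochs: EpochSet, spec: FilterSpec = FilterSpec()) -> EpochSet:
    """Zero-phase band-pass every trial and channel; shape preserved."""
    sos = spec.sos(epochs.fs)
    out = signal.sosfiltfilt(sos, epochs.data, axis=-1)
    return replace(epochs, data=np.ascontiguousarray(out))


def bandpass_array(data: np.ndarray, fs: float,
                   spec: FilterSpec = FilterSpec()) -> np.ndarray:
    """Zero-phase band-pass along the last axis of a raw array."""
    sos = spec.sos(fs)
    return np.ascontiguousarray(signal.sosfiltfilt(sos, data, axis=-1))


def extract_windows(rec: Recording, spec: WindowSpec,
                    classes_wanted: Sequence[int],
                    class_names: dict[int, str] | None = None) -> EpochSet:
    """Cut one cue-locked epoch per retained event.

    Cues whose window would run past the recording bounds are dropped
    (count logged).  Raises if no window survives.
    """
    wanted = set(int(c) for c in classes_wanted)
    length = int(round(spec.duration_s * rec.fs))
    offset = int(round(spec.start_offset_s * rec.fs))
    n_samp = rec.data.shape[1]
    epochs, classes, dropped = [], [], 0
    for cue, cid in rec.events:
        if int(cid) not in wanted:
            continue
        start = cue + offset
        if start < 0 or start + length > n_samp:
            dropped += 1
            continue
        epochs.append(rec.data[:, start:start + length])
        classes.append(int(cid))
    if dropped:
        log.info("extract_windows: dropped %d out-of-bounds window(s)", dropped)
    if not epochs:
        raise ValueError("no cue window fits within the recording bounds")
    if class_names is None:
        class_names = {c: f"class_{c}" for c in sorted(set(classes))}
    return EpochSet(data=np.stack(epochs), fs=rec.fs, labels=rec.labels,
                    classes=np.array(classes), class_names=class_names)


def standardize_columns(mat: np.ndarray
                        ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Center each row and scale it to unit sum of squares.

    ``mat`` is variables x observations (rows are predictors or targets,
    columns are samples).  Returns ``(standardized, center, scale)`` such
    that ``standardized = (mat - center[:, None]) / scale[:, None]`` holds
    exactly, each output row has mean 0, and — for non-constant rows —
    sum of squares 1.  Constant rows get scale 1 and a warning.
    """
    mat = np.asarray(mat, dtype=float)
    if mat.ndim != 2 or mat.shape[1] < 2:
        raise ValueError("need a 2-D matrix with at least 2 columns")
    center = mat.mean(axis=1)
    centered = mat - center[:, None]
    scale = np.sqrt((centered ** 2).sum(axis=1))
    zero = scale == 0
    if zero.any():
        warnings.warn(
            f"{int(zero.sum())} constant row(s); scale set to 1",
            RuntimeWarning, stacklevel=2)
        scale[zero] = 1.0
    return centered / scale[:, None], center, scale
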