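"""Synthetic motor-imagery EEG with known ground truth.

The generator emulates the structure the reconstruction pipeline relies
on: band-limited (mu/beta, 8-30 Hz) oscillatory sources co-located with
the 8 central electrodes, mixed linearly into all 22 montage channels by
a distance-based leadfield, with class-dependent lateralized event-
related desynchronization (ERD) — left-hand imagery attenuates the
left-lateralized sources (class 1), right-hand imagery the right ones
(class 2) — during the central 3 s imagery window.  Sensor noise is
white Gaussian at a configurable SNR.

Because the sources sit at the input electrodes and the mixing is
linear, the reduced subset is *sufficient* for reconstruction by
construction; with ``deterministic_map=True`` (and no sensor noise) all
22 channels are exact linear functions of the 8 input channels, giving
an analytically known recovery target.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .containers import EpochSet, Montage, standard_montage_22
from .preprocess import FilterSpec, bandpass, bandpass_array

__all__ = ["SynthConfig", "generate", "band_power", "implied_channel_map"]

#: Standard-deviation of a single oscillatory source, microvolts.
_SOURCE_STD_UV = 10.0
#: Width (head-radius units) of the Gaussian leadfield falloff.
_LEADFIELD_SIGMA = 0.3
#: Imagery onset within the window: the window starts 1.9 s before the
#: cue and imagery starts at the cue.
_MI_ONSET_S = 1.9


@dataclass(frozen=True)
class SynthConfig:
    """Generator parameters; the defaults define the benchmark conditions.

    ``erd_depth`` is the fractional amplitude attenuation of the
    lateralized sources during imagery (0.5 halves the amplitude).
    ``snr_db`` is per-channel sensor SNR; ``None`` means noise-free and is
    required when ``deterministic_map`` is set.
    """

    n_trials_per_class: int = 100
    fs: float = 250.0
    duration_s: float = 6.8
    n_channels: int = 22
    n_sources: int = 8
    band_hz: tuple[float, float] = (8.0, 30.0)
    erd_depth: float = 0.5
    mi_duration_s: float = 3.0
    snr_db: float | None = 10.0
    mixing: np.ndarray | None = field(default=None, repr=False)
    deterministic_map: bool = False
    seed: int = 42

    def __post_init__(self) -> None:
        if not 0 <= self.erd_depth < 1:
            raise ValueError("erd_depth must lie in [0, 1)")
        if self.n_sources > self.n_channels:
            raise ValueError("n_sources must not exceed n_channels")
        if self.deterministic_map and self.snr_db is not None:
            raise ValueError(
                "deterministic_map requires snr_db=None (noise-free); "
                "finite sensor noise would break the exact linear map")


def _default_mixing(montage: Montage, n_channels: int,
                    n_sources: int) -> np.ndarray:
    """Distance-based leadfield from montage geometry (full column rank
    because source positions are distinct)."""
    src_pos = np.array([montage.position_of(c)
                        for c in montage.input_subset[:n_sources]])
    ch_pos = montage.positions[:n_channels]
    d2 = ((ch_pos[:, None, :] - src_pos[None, :, :]) ** 2).sum(axis=2)
    return np.exp(-d2 / (2 * _LEADFIELD_SIGMA ** 2))


def generate(config: SynthConfig = SynthConfig(),
             montage: Montage | None = None) -> EpochSet:
    """Draw a labelled :class:`EpochSet`; fully reproducible from the seed.

    Class labels alternate deterministically (1, 2, 1, 2, ...).
    """
    if montage is None:
        montage = standard_montage_22()
    if config.n_channels > len(montage.labels):
        raise ValueError("n_channels exceeds montage size")
    if config.n_sources > len(montage.input_subset):
        raise ValueError("n_sources exceeds the montage input subset")
    rng = np.random.default_rng(config.seed)
    n_trials = 2 * config.n_trials_per_class
    m = int(round(config.duration_s * config.fs))
    n_src = config.n_sources

    # Band-limited sources: white noise filtered into the mu/beta band,
    # rescaled so each source has the nominal amplitude.
    white = rng.standard_normal((n_trials, n_src, m))
    fspec = FilterSpec(low_hz=config.band_hz[0], high_hz=config.band_hz[1])
    sources = bandpass_array(white, config.fs, fspec)
    sources *= _SOURCE_STD_UV / sources.std()

    # Lateralized ERD: class 1 attenuates left-hemisphere sources
    # (x < 0), class 2 the right-hemisphere ones, during imagery.
    classes = np.tile([1, 2], config.n_trials_per_class)[:n_trials]
    src_x = np.array([montage.position_of(c)[0]
                      for c in montage.input_subset[:n_src]])
    mi_start = int(round(_MI_ONSET_S * config.fs))
    mi_stop = min(m, mi_start + int(round(config.mi_duration_s * config.fs)))
    gain = 1.0 - config.erd_depth
    left, right = src_x < 0, src_x > 0
    for t in range(n_trials):
        side = left if classes[t] == 1 else right
        sources[t, side, mi_start:mi_stop] *= gain

    A = config.mixing
    if A is None:
        A = _default_mixing(montage, config.n_channels, n_src)
    A = np.asarray(A, dtype=float)
    if A.shape != (config.n_channels, n_src):
        raise ValueError("mixing must be (n_channels, n_sources)")
    if np.linalg.matrix_rank(A) < n_src:
        raise ValueError("mixing matrix must have full column rank")
    sensors = np.einsum("cs,tsm->tcm", A, sources)

    if config.snr_db is not None:
        power = (sensors ** 2).mean(axis=(0, 2))
        noise_std = np.sqrt(power / 10 ** (config.snr_db / 10))
        sensors = sensors + noise_std[None, :, None] * \
            rng.standard_normal(sensors.shape)

    return EpochSet(data=sensors, fs=config.fs,
                    labels=montage.labels[:config.n_channels],
                    classes=classes,
                    class_names={1: "left_hand", 2: "right_hand"})


def implied_channel_map(config: SynthConfig,
                        montage: Montage | None = None) -> np.ndarray:
    """The exact linear map from the input channels to all channels.

    Only meaningful under ``deterministic_map``: with sources co-located
    with the input electrodes, ``channels = A A_in^-1 inputs`` where
    ``A_in`` is the mixing restricted to the input-channel rows.
    """
    if montage is None:
        montage = standard_montage_22()
    A = config.mixing
    if A is None:
        A = _default_mixing(montage, config.n_channels, config.n_sources)
    labels = montage.labels[:config.n_channels]
    rows = [labels.index(c) for c in montage.input_subset[:config.n_sources]]
    return A @ np.linalg.inv(A[rows])


def band_power(epochs: EpochSet,
               band_hz: tuple[float, float] = (8.0, 30.0)) -> np.ndarray:
    """Mean squared amplitude of the band-passed signal per trial/channel."""
    fspec = FilterSpec(low_hz=band_hz[0], high_hz=band_hz[1])
    filtered = bandpass(epochs, fspec)
    return (filtered.data ** 2).mean(axis=2)
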