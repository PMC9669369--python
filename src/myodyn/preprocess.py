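"""sEMG conditioning: band-pass, notch, rectification, sub-sampling, envelope.

The chain turns a 6-channel raw surface-EMG record at 2 kHz into a
nonnegative activation envelope at the joint-angle rate (100 Hz):

1. band-pass 20-500 Hz (4th-order Butterworth) -- keeps the sEMG energy band;
2. 50 Hz notch -- removes power-line interference;
3. full-wave rectification ``|x|``;
4. block sub-sampling: mean of ``N`` consecutive rectified samples
   (``N = 20`` maps 2 kHz to 100 Hz);
5. first-order low-pass Butterworth at 5 Hz -- smooths the envelope, since
   joint motion itself is a low-frequency process.

All filters are causal (forward-only): the pipeline targets real-time
interaction control, where zero-phase filtering is not realizable.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
from scipy import signal as sps

from .dataio import TimeSeriesTable, InvalidTableError

__all__ = [
    "FilterConfig",
    "RawEMG",
    "EnvelopeFeatures",
    "MUSCLES",
    "bandpass",
    "notch",
    "full_wave_rectify",
    "subsample",
    "envelope_lowpass",
    "process_recording",
    "FilterDesignError",
]

#: The six recorded muscles, fixed order: one agonist/antagonist pair per
#: joint (shoulder, elbow, wrist).
MUSCLES = (
    "anterior_deltoid",
    "posterior_deltoid",
    "biceps_brachii",
    "triceps_brachii",
    "extensor_carpi_radialis",
    "flexor_carpi_radialis",
)


class FilterDesignError(ValueError):
    """Filter parameters incompatible with the signal's sampling rate."""


@dataclass
class FilterConfig:
    """Parameters of the sEMG conditioning chain.

    band_low/band_high : Hz
        Band-pass edges; ``band_high`` is capped at 0.99x Nyquist because a
        digital edge cannot sit at Nyquist (at 2 kHz the 500 Hz analog edge
        is realizable directly).
    notch_freq, notch_quality
        Power-line notch (50 Hz, Q = 30 by default).
    envelope_cutoff, envelope_order
        Final envelope low-pass; the first-order 5 Hz Butterworth has power
        gain 1/(1 + (w/wc)^2), i.e. -3.01 dB at the cutoff.
    subsample_n
        Block length of the rectified-mean sub-sampler (2000/100 = 20).
    """

    band_low: float = 20.0
    band_high: float = 500.0
    band_order: int = 4
    notch_freq: float = 50.0
    notch_quality: float = 30.0
    envelope_cutoff: float = 5.0
    envelope_order: int = 1
    subsample_n: int = 20

    def __post_init__(self) -> None:
        if not (0 < self.band_low < self.band_high):
            raise FilterDesignError(
                f"need 0 < band_low < band_high, got ({self.band_low}, {self.band_high})"
            )
        if not (self.band_low < self.notch_freq < self.band_high):
            raise FilterDesignError(
                f"notch_freq {self.notch_freq} must lie inside the pass band"
            )
        if self.envelope_cutoff <= 0:
            raise FilterDesignError("envelope_cutoff must be positive")
        if self.envelope_order < 1:
            raise FilterDesignError("envelope_order must be >= 1")
        if self.subsample_n < 1:
            raise FilterDesignError("subsample_n must be a positive integer")

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class RawEMG:
    """Six-muscle raw sEMG record (millivolts) at the EMG sampling rate."""

    table: TimeSeriesTable

    def __post_init__(self) -> None:
        if tuple(self.table.channel_names) != MUSCLES:
            raise InvalidTableError(
                f"RawEMG needs exactly the channels {list(MUSCLES)}, "
                f"got {self.table.channel_names}"
            )

    @property
    def rate(self) -> float:
        return self.table.rate


@dataclass
class EnvelopeFeatures:
    """Nonnegative six-channel activation envelope at the angle rate."""

    table: TimeSeriesTable

    def __post_init__(self) -> None:
        if tuple(self.table.channel_names) != MUSCLES:
            raise InvalidTableError(
                f"EnvelopeFeatures needs the channels {list(MUSCLES)}, "
                f"got {self.table.channel_names}"
            )
        if np.any(self.table.values() < 0):
            raise InvalidTableError("envelope values must be nonnegative")

    @property
    def rate(self) -> float:
        return self.table.rate


def _band_edges(rate: float, cfg: FilterConfig) -> tuple[float, float]:
    nyq = rate / 2.0
    high = min(cfg.band_high, 0.99 * nyq)
    if cfg.band_low >= high:
        raise FilterDesignError(
            f"band [{cfg.band_low}, {cfg.band_high}] Hz not realizable at rate {rate} Hz"
        )
    return cfg.band_low, high


def bandpass(x: np.ndarray, rate: float, cfg: FilterConfig | None = None) -> np.ndarray:
    """Causal Butterworth band-pass (default 20-500 Hz, order 4)."""
    cfg = cfg or FilterConfig()
    low, high = _band_edges(rate, cfg)
    sos = sps.butter(cfg.band_order, [low, high], btype="bandpass", fs=rate, output="sos")
    return sps.sosfilt(sos, np.asarray(x, dtype=float))


def notch(x: np.ndarray, rate: float, cfg: FilterConfig | None = None) -> np.ndarray:
    """Causal second-order notch at the power-line frequency."""
    cfg = cfg or FilterConfig()
    if not (0 < cfg.notch_freq < rate / 2.0):
        raise FilterDesignError(
            f"notch frequency {cfg.notch_freq} Hz not below Nyquist at rate {rate} Hz"
        )
    b, a = sps.iirnotch(cfg.notch_freq, cfg.notch_quality, fs=rate)
    return sps.lfilter(b, a, np.asarray(x, dtype=float))


def full_wave_rectify(x: np.ndarray) -> np.ndarray:
    """Full-wave rectification: pointwise absolute value."""
    return np.abs(np.asarray(x, dtype=float))


def subsample(x: np.ndarray, n: int) -> np.ndarray:
    """Mean of ``|x|`` over non-overlapping blocks of ``n`` samples.

    The trailing remainder (fewer than ``n`` samples) is discarded, so the
    output length is ``floor(len(x) / n)``.
    """
    if n < 1:
        raise ValueError(f"block length must be positive, got {n}")
    x = np.asarray(x, dtype=float)
    if x.size < n:
        raise ValueError(f"signal of length {x.size} shorter than block length {n}")
    m = x.size // n
    return np.abs(x[: m * n]).reshape(m, n).mean(axis=1)


def envelope_lowpass(x: np.ndarray, rate: float, cfg: FilterConfig | None = None) -> np.ndarray:
    """Causal low-order Butterworth envelope smoother (default 5 Hz, order 1)."""
    cfg = cfg or FilterConfig()
    if not (0 < cfg.envelope_cutoff < rate / 2.0):
        raise FilterDesignError(
            f"envelope cutoff {cfg.envelope_cutoff} Hz not below Nyquist at {rate} Hz"
        )
    sos = sps.butter(cfg.envelope_order, cfg.envelope_cutoff, btype="lowpass", fs=rate, output="sos")
    return sps.sosfilt(sos, np.asarray(x, dtype=float))


def process_recording(raw: RawEMG, cfg: FilterConfig | None = None) -> EnvelopeFeatures:
    """Full conditioning chain per channel; output rate = input rate / N.

    Small negative transients from the final causal low-pass are clamped to
    zero to keep the envelope nonnegative.
    """
    cfg = cfg or FilterConfig()
    rate = raw.rate
    out_rate = rate / cfg.subsample_n
    cols: dict[str, np.ndarray] = {}
    for name in MUSCLES:
        x = raw.table.channel(name)
        x = bandpass(x, rate, cfg)
        x = notch(x, rate, cfg)
        x = full_wave_rectify(x)
        x = subsample(x, cfg.subsample_n)
        x = envelope_lowpass(x, out_rate, cfg)
        cols[name] = np.clip(x, 0.0, None)
    table = TimeSeriesTable(rate=out_rate, data=pd.DataFrame(cols), t0=raw.table.t0)
    return EnvelopeFeatures(table=table)
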