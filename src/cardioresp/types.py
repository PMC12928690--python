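"""Shared containers for cardiorespiratory signals and derived estimates.

Conventions: all times are seconds from recording start; segments are
half-open ``[start, end)``; RRIs are in milliseconds; lung volume in mL;
airflow in mL/s.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

__all__ = [
    "SampledSignal",
    "BeatSeries",
    "SegmentSelection",
    "Rejection",
    "BandScheme",
    "Psd",
    "HrvFeatures",
    "FrfEstimate",
    "FrfFeatures",
    "IrEstimate",
    "IrFeatures",
    "NoBeatsError",
    "IllConditionedError",
]


class NoBeatsError(ValueError):
    """R-peak detection found no beats in the record."""


class IllConditionedError(ValueError):
    """The regression design is rank-deficient (e.g. constant input)."""


@dataclass
class SampledSignal:
    """A uniformly sampled physiological time series.

    Parameters
    ----------
    t0 : float
        Time of the first sample, seconds from recording start.
    fs : float
        Sampling rate, Hz.
    samples : ndarray
        Signal values; must be finite.
    units : str
        Physical units of the samples (e.g. ``"mL/s"``, ``"ms"``).
    channel : str
        One of ``ecg``, ``airflow``, ``ilv``, ``rri_resampled``.
    """

    t0: float
    fs: float
    samples: np.ndarray
    units: str = ""
    channel: str = ""

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.fs <= 0:
            raise ValueError(f"sampling rate must be positive, got {self.fs}")
        if self.samples.ndim != 1:
            raise ValueError("samples must be one-dimensional")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("samples contain non-finite values")

    @property
    def n(self) -> int:
        return self.samples.size

    @property
    def duration_s(self) -> float:
        return self.n / self.fs

    def times(self) -> np.ndarray:
        """Sample times in seconds from recording start."""
        return self.t0 + np.arange(self.n) / self.fs

    def crop(self, start_s: float, end_s: float) -> "SampledSignal":
        """Return the sub-signal on the half-open window [start_s, end_s)."""
        t = self.times()
        mask = (t >= start_s - 1e-12) & (t < end_s - 1e-12)
        if not mask.any():
            raise ValueError("crop window contains no samples")
        first = int(np.argmax(mask))
        return SampledSignal(
            t0=float(t[first]),
            fs=self.fs,
            samples=self.samples[mask],
            units=self.units,
            channel=self.channel,
        )


@dataclass
class BeatSeries:
    """R-peak times and the implied RR-interval tachogram.

    ``rri_ms[i]`` is the interval ending at beat ``i + 1``; the tachogram
    is conventionally indexed by the time of the later beat.
    """

    r_times_s: np.ndarray
    quality: Optional[np.ndarray] = None  # "normal" / "suspect" per beat

    def __post_init__(self) -> None:
        self.r_times_s = np.asarray(self.r_times_s, dtype=float)
        if self.r_times_s.size < 2:
            raise ValueError("a beat series needs at least two beats")
        if np.any(np.diff(self.r_times_s) <= 0):
            raise ValueError("beat times must be strictly increasing")
        if self.quality is None:
            self.quality = np.full(self.r_times_s.size, "normal", dtype=object)

    @property
    def rri_ms(self) -> np.ndarray:
        return np.diff(self.r_times_s) * 1000.0

    @property
    def n_beats(self) -> int:
        return self.r_times_s.size


@dataclass
class SegmentSelection:
    """An accepted analysis window (half-open, fixed length)."""

    start_s: float
    end_s: float
    posture: str = "sitting"
    exclusion_reasons: list = field(default_factory=list)

    @property
    def length_s(self) -> float:
        return self.end_s - self.start_s


@dataclass
class Rejection:
    """Typed outcome when no acceptable segment exists (not an exception)."""

    reasons: list


@dataclass(frozen=True)
class BandScheme:
    """Frequency bands for spectral HRV and gain averaging.

    Defaults follow the short-term HRV convention: LF 0.04-0.15 Hz,
    HF 0.15-0.4 Hz.  Band membership is half-open, ``lo <= f < hi``.
    """

    lf: tuple = (0.04, 0.15)
    hf: tuple = (0.15, 0.4)
    total: tuple = (0.04, 0.4)

    def __post_init__(self) -> None:
        for name in ("lf", "hf", "total"):
            lo, hi = getattr(self, name)
            if not 0 <= lo < hi:
                raise ValueError(f"invalid {name} band ({lo}, {hi})")


@dataclass
class Psd:
    """One-sided Welch power spectral density (power per Hz)."""

    freqs_hz: np.ndarray
    density: np.ndarray
    nperseg: int = 0
    noverlap: int = 0
    window: str = "hann"


@dataclass
class HrvFeatures:
    """Spectral HRV features: band powers in ms^2 and their ratio."""

    hrv_lf: float
    hrv_hf: float
    hrv_lf_hf: Optional[float]  # None when HF power is zero


@dataclass
class FrfEstimate:
    """Frequency response function from ILV (input) to RRI (output).

    Cross-spectrum convention: S_xy = E[X*(f) Y(f)], so a positive phase
    means the output leads the input.
    """

    freqs_hz: np.ndarray
    gain: np.ndarray  # |H(f)|, ms/mL
    phase: np.ndarray  # radians
    coherence: np.ndarray  # gamma^2(f) in [0, 1]


@dataclass
class FrfFeatures:
    frf_gain_lf: Optional[float]
    frf_gain_hf: Optional[float]


@dataclass
class IrEstimate:
    """Causal FIR kernel from ILV to RRI.

    ``coeffs[j]`` is the response at lag ``delay_s + j / fs`` in ms per mL.
    """

    lags_s: np.ndarray
    coeffs: np.ndarray
    delay_s: float
    fs: float
    nmse: float
    ridge_lambda: float
    residual_var: float

    def full_kernel(self) -> tuple:
        """Kernel on the lag grid starting at 0, delay zero-filled.

        Returns (lags_s, coeffs) where lags start at 0 with step 1/fs.
        """
        n_delay = int(round(self.delay_s * self.fs))
        coeffs = np.concatenate([np.zeros(n_delay), self.coeffs])
        lags = np.arange(coeffs.size) / self.fs
        return lags, coeffs


@dataclass
class IrFeatures:
    ir_magnitude: float
    dg_total: float
    dg_lf: float
    dg_hf: float
    t_char: float
    degenerate: bool = False  # all-zero kernel
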