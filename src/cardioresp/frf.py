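"""Frequency response function (FRF) from ILV to RRI.

The FRF is the noncausal spectral transfer estimate
H(f) = S_xy(f) / S_xx(f) from Welch cross- and auto-spectra, with the
magnitude-squared coherence gamma^2 = |S_xy|^2 / (S_xx S_yy) used to
mask noise-dominated bins when averaging band gains.  Because respiration
drives RRI both directly (vagal gating) and through feedback loops, the
FRF mixes feedforward and feedback pathways; the causal impulse-response
estimator is the directional counterpart.

Cross-spectrum convention: S_xy = E[X*(f) Y(f)], so positive phase means
the output leads the input; a pure output delay of tau gives phase
-2 pi f tau.
"""

from __future__ import annotations

import numpy as np
from scipy import signal as sps

from .spectral import WelchConfig
from .types import BandScheme, FrfEstimate, FrfFeatures, SampledSignal

__all__ = ["estimate_frf", "frf_band_gains"]


def estimate_frf(
    ilv4hz: SampledSignal,
    rri4hz: SampledSignal,
    cfg: WelchConfig = WelchConfig(),
) -> FrfEstimate:
    """Welch-based transfer estimate from ILV (input) to RRI (output).

    Uses the same windowing as the HRV spectra so FRF gains and band
    powers live on an identical frequency grid.
    """
    if ilv4hz.n != rri4hz.n:
        raise ValueError("input and output must have equal length")
    if abs(ilv4hz.fs - rri4hz.fs) > 1e-9:
        raise ValueError("input and output must share a sampling rate")
    x, y = ilv4hz.samples, rri4hz.samples
    if np.var(x) < 1e-300:
        raise ValueError("degenerate input: zero variance")
    nperseg = min(cfg.nperseg, x.size)
    noverlap = int(cfg.overlap * nperseg)
    kw = dict(fs=ilv4hz.fs, window=cfg.window, nperseg=nperseg, noverlap=noverlap, detrend="constant")
    freqs, sxx = sps.welch(x, **kw)
    _, syy = sps.welch(y, **kw)
    _, sxy = sps.csd(x, y, **kw)  # scipy: conj(X) * Y, matching our convention
    h = sxy / np.where(sxx > 0, sxx, np.inf)
    denom = sxx * syy
    coh = np.where(denom > 0, np.abs(sxy) ** 2 / np.where(denom > 0, denom, 1.0), 0.0)
    return FrfEstimate(
        freqs_hz=freqs,
        gain=np.abs(h),
        phase=np.angle(h),
        coherence=np.clip(coh, 0.0, 1.0),
    )


def frf_band_gains(
    frf: FrfEstimate,
    bands: BandScheme = BandScheme(),
    coherence_min: float = 0.0,
) -> FrfFeatures:
    """Unweighted mean of |H| over each band's bins.

    By default every bin in the band contributes (plain average).  With
    ``coherence_min > 0``, bins below that coherence are excluded as
    noise-dominated; a band left empty after masking yields a missing
    (None) feature.
    """
    out = {}
    for name, band in (("frf_gain_lf", bands.lf), ("frf_gain_hf", bands.hf)):
        lo, hi = band
        mask = (frf.freqs_hz >= lo) & (frf.freqs_hz < hi)
        if coherence_min > 0:
            mask &= frf.coherence >= coherence_min
        out[name] = float(np.mean(frf.gain[mask])) if mask.any() else None
    return FrfFeatures(**out)
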