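"""Raw ECG + airflow -> aligned, detrended 4 Hz RRI and ILV series.

The chain is: R-peak detection with a Pan-Tompkins-style cascade,
quality screening of beats and airflow, trapezoidal integration of the
airflow into instantaneous lung volume (ILV) with linear drift removal,
and cubic-spline resampling of both the tachogram and ILV onto a
uniform 4 Hz grid after polynomial detrending.  4 Hz comfortably covers
the 0.04-0.4 Hz band of interest while keeping the system-identification
design matrices small.
"""

from __future__ import annotations

from typing import Union

import numpy as np
from scipy import signal as sps
from scipy.integrate import cumulative_trapezoid
from scipy.interpolate import CubicSpline

from .types import BeatSeries, NoBeatsError, Rejection, SampledSignal, SegmentSelection

__all__ = [
    "detect_r_peaks",
    "screen_quality",
    "integrate_airflow",
    "resample_detrend",
]

# Pan-Tompkins constants: canonical published values (band-pass 5-15 Hz,
# 150 ms moving-window integration, 200 ms refractory period).
_BP_LO_HZ = 5.0
_BP_HI_HZ = 15.0
_MWI_S = 0.150
_REFRACTORY_S = 0.200


def detect_r_peaks(ecg: SampledSignal) -> BeatSeries:
    """Detect R-waves with a Pan-Tompkins-based cascade.

    Band-pass (5-15 Hz) -> differentiate -> square -> 150 ms
    moving-window integration -> adaptive signal/noise threshold with a
    200 ms refractory period; each detection is then refined to the
    local maximum of the band-passed ECG within +-100 ms.

    Raises
    ------
    NoBeatsError
        If fewer than two beats are found (e.g. flat-line input).
    ValueError
        If the channel is not ECG, the rate is below 100 Hz, or the
        record is shorter than 10 s.
    """
    if ecg.channel != "ecg":
        raise ValueError(f"expected an ECG channel, got {ecg.channel!r}")
    if ecg.fs < 100:
        raise ValueError("ECG sampling rate must be at least 100 Hz")
    if ecg.duration_s < 10:
        raise ValueError("need at least 10 s of ECG")

    fs = ecg.fs
    x = ecg.samples - np.mean(ecg.samples)
    sos = sps.butter(2, [_BP_LO_HZ, _BP_HI_HZ], btype="bandpass", fs=fs, output="sos")
    bp = sps.sosfiltfilt(sos, x)
    deriv = np.gradient(bp) * fs
    sq = deriv**2
    mwi = sps.convolve(sq, np.ones(max(int(_MWI_S * fs), 1)) / max(int(_MWI_S * fs), 1), mode="same")

    if np.max(mwi) <= 0 or np.ptp(bp) < 1e-12:
        raise NoBeatsError("flat-line or featureless ECG")

    refractory = int(_REFRACTORY_S * fs)
    # adaptive thresholding over the integrated signal
    spki = float(np.percentile(mwi, 99))  # running signal-peak estimate
    npki = float(np.percentile(mwi, 50))  # running noise-peak estimate
    threshold = npki + 0.25 * (spki - npki)
    peaks, _ = sps.find_peaks(mwi, distance=refractory)
    detections = []
    for p in peaks:
        if mwi[p] >= threshold:
            spki = 0.125 * mwi[p] + 0.875 * spki
            detections.append(p)
        else:
            npki = 0.125 * mwi[p] + 0.875 * npki
        threshold = npki + 0.25 * (spki - npki)
    if len(detections) < 2:
        raise NoBeatsError("fewer than two beats detected")

    # refine each detection to the band-passed ECG's local maximum
    half = int(0.100 * fs)
    refined = []
    for p in detections:
        lo, hi = max(p - half, 0), min(p + half + 1, ecg.n)
        refined.append(lo + int(np.argmax(bp[lo:hi])))
    refined = np.unique(refined)
    r_times = ecg.t0 + refined / fs
    keep = np.concatenate([[True], np.diff(r_times) > _REFRACTORY_S])
    return BeatSeries(r_times_s=r_times[keep])


def screen_quality(
    beats: BeatSeries,
    airflow: SampledSignal,
    segment_s: float = 240.0,
    suspect_rel_dev: float = 0.20,
    suspect_budget: float = 0.05,
    flattening_win_s: float = 10.0,
) -> Union[SegmentSelection, Rejection]:
    """Find the earliest clean analysis window, or reject with reasons.

    A beat is *suspect* when its RRI deviates more than 20% from the
    local (11-beat) median — a proxy for ectopy or detection error.  An
    airflow span is *flattening* when its variance over a 10 s window
    falls below 1e-4 of the whole-record variance.  The earliest
    ``segment_s`` window with under 5% suspect beats and no flattening
    is returned; otherwise a typed Rejection listing every reason seen.
    """
    # candidate windows live on the airflow/recording span; beats must
    # cover the window except for sub-interval edges (< 2 mean RRIs)
    t_start = airflow.t0
    t_end = airflow.t0 + airflow.duration_s
    if t_end - t_start < segment_s - 1e-9:
        return Rejection(reasons=["record shorter than segment length"])
    beat_margin = 2.0 * float(np.mean(beats.rri_ms)) / 1000.0

    rri = beats.rri_ms
    med = _local_median(rri, 5)
    suspect = np.abs(rri - med) > suspect_rel_dev * med
    beat_mid = beats.r_times_s[1:]  # RRI timestamped at the later beat

    flow_t = airflow.times()
    global_var = np.var(airflow.samples)
    win = max(int(flattening_win_s * airflow.fs), 2)
    n_win = airflow.n // win
    flat_spans = []
    for i in range(n_win):
        seg = airflow.samples[i * win : (i + 1) * win]
        if np.var(seg) < 1e-4 * max(global_var, 1e-300):
            flat_spans.append((flow_t[i * win], flow_t[min((i + 1) * win, airflow.n) - 1]))

    reasons = set()
    start = t_start
    step = flattening_win_s
    while start + segment_s <= t_end + 1e-9:
        end = start + segment_s
        in_win = (beat_mid >= start) & (beat_mid < end)
        n_in = int(in_win.sum())
        frac_suspect = suspect[in_win].mean() if n_in else 1.0
        has_flat = any(not (b <= start or a >= end) for a, b in flat_spans)
        covered = (
            beats.r_times_s[0] <= start + beat_margin and beats.r_times_s[-1] >= end - beat_margin
        )
        if n_in >= 2 and covered and frac_suspect < suspect_budget and not has_flat:
            return SegmentSelection(start_s=float(start), end_s=float(end))
        if frac_suspect >= suspect_budget:
            reasons.add("excessive ectopic")
        if has_flat:
            reasons.add("flattening")
        start += step
    return Rejection(reasons=sorted(reasons) or ["no valid window"])


def _local_median(x: np.ndarray, half: int) -> np.ndarray:
    out = np.empty_like(x)
    for i in range(x.size):
        lo, hi = max(i - half, 0), min(i + half + 1, x.size)
        out[i] = np.median(x[lo:hi])
    return out


def integrate_airflow(airflow: SampledSignal, remove_drift: bool = True) -> SampledSignal:
    """Integrate airflow (mL/s) into instantaneous lung volume (mL).

    Cumulative trapezoidal integration; a least-squares line is then
    subtracted to remove the slow drift that any DC offset or leak in
    the flow signal accumulates (breath-by-breath re-zeroing would
    distort HF phase, so a single linear fit per segment is used).
    """
    if airflow.channel != "airflow":
        raise TypeError(f"expected an airflow channel, got {airflow.channel!r}")
    vol = cumulative_trapezoid(airflow.samples, dx=1.0 / airflow.fs, initial=0.0)
    if remove_drift:
        t = np.arange(vol.size) / airflow.fs
        coef = np.polynomial.polynomial.polyfit(t, vol, 1)
        vol = vol - np.polynomial.polynomial.polyval(t, coef)
    return SampledSignal(t0=airflow.t0, fs=airflow.fs, samples=vol, units="mL", channel="ilv")


def resample_detrend(
    series: Union[BeatSeries, SampledSignal],
    target_fs: float = 4.0,
    start_s: float = None,
    end_s: float = None,
    detrend_deg: int = 3,
) -> SampledSignal:
    """Cubic-resample onto a uniform grid and remove a slow polynomial trend.

    A tachogram (BeatSeries) is interpolated as RRI against beat time; a
    SampledSignal is interpolated sample-against-time.  A degree-3
    polynomial fit over the segment is subtracted, which suppresses
    <0.04 Hz drift without attenuating the LF band; the detrended output
    is therefore approximately zero-mean.  A 240 s segment at 4 Hz
    yields 960 samples.
    """
    if isinstance(series, BeatSeries):
        # each RRI is stamped at its interval midpoint: stamping at the
        # later beat would impose a spurious half-interval phase lag on
        # the tachogram relative to the respiratory drive
        t_src = (series.r_times_s[:-1] + series.r_times_s[1:]) / 2
        x_src = series.rri_ms
        units, channel = "ms", "rri_resampled"
    else:
        t_src = series.times()
        x_src = series.samples
        units, channel = series.units, series.channel
    if start_s is None:
        start_s = float(t_src[0])
    if end_s is None:
        end_s = float(t_src[-1])
    if end_s - start_s < 25.0:
        raise ValueError("need at least 25 s of data (one full LF period)")

    n_out = int(round((end_s - start_s) * target_fs))
    t_out = start_s + np.arange(n_out) / target_fs
    cs = CubicSpline(t_src, x_src, extrapolate=True)
    y = cs(t_out)

    tt = t_out - t_out[0]
    coef = np.polynomial.polynomial.polyfit(tt, y, detrend_deg)
    y = y - np.polynomial.polynomial.polyval(tt, coef)
    return SampledSignal(t0=start_s, fs=target_fs, samples=y, units=units, channel=channel)
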