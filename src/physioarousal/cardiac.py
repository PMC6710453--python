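"""ECG preprocessing, R-wave detection, heart period/rate and HRV band power.

The heart-period series is the unit of cardiac analysis: HP is the mean
interval between successive R waves inside an analysis window, HR its
reciprocal in beats per minute.  Heart-rate-variability band powers are
computed from the inter-beat-interval series, evenly resampled and subjected
to Welch spectral estimation; the high-frequency band is 0.14-0.4 Hz and the
low-frequency band 0.07-0.14 Hz, reported as natural-log power.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import interpolate, signal

from ._dsp import butter_filter, moving_average, notch_filter, resample_to

__all__ = ["BeatSeries", "HrvResult", "preprocess_ecg", "detect_r_waves",
           "heart_period", "hrv_band_power", "HF_BAND", "LF_BAND"]

HF_BAND = (0.14, 0.4)
LF_BAND = (0.07, 0.14)

ECG_RATE = 400.0  # Hz after preprocessing


@dataclass
class BeatSeries:
    """Detected R-wave times with per-interval artifact flags.

    ``artifact_flags[i]`` marks the interval between ``r_times[i]`` and
    ``r_times[i+1]``.
    """

    r_times: np.ndarray
    artifact_flags: np.ndarray = None
    quality_flag: str = "ok"  # "ok" | "flat" | "empty"

    def __post_init__(self) -> None:
        self.r_times = np.asarray(self.r_times, dtype=float)
        if self.r_times.size and np.any(np.diff(self.r_times) <= 0):
            raise ValueError("r_times must be strictly increasing")
        n_int = max(len(self.r_times) - 1, 0)
        if self.artifact_flags is None:
            self.artifact_flags = np.zeros(n_int, dtype=bool)
        else:
            self.artifact_flags = np.asarray(self.artifact_flags, dtype=bool)
            if len(self.artifact_flags) != n_int:
                raise ValueError("one artifact flag per interval expected")

    @property
    def ibis(self) -> np.ndarray:
        """Inter-beat intervals in milliseconds."""
        return np.diff(self.r_times) * 1000.0

    def with_edits(self, add=(), delete=(), tol: float = 0.05) -> "BeatSeries":
        """Manual-correction hook: add/remove beats (times in seconds)."""
        times = list(self.r_times)
        for t in delete:
            times = [x for x in times if abs(x - t) > tol]
        times.extend(add)
        return BeatSeries(np.sort(np.unique(times)), quality_flag=self.quality_flag)


@dataclass
class HrvResult:
    """ln band powers in ln(ms^2); ``flag`` notes degenerate inputs."""

    ln_hf: float
    ln_lf: float
    flag: str = "ok"  # "ok" | "floored" | "missing"


def preprocess_ecg(samples: np.ndarray, rate: float) -> np.ndarray:
    """Standard ECG conditioning chain, output at 400 Hz.

    0.5 Hz high-pass (drift/DC), 50 Hz notch (mains), 40 Hz low-pass, then
    polyphase resampling to 400 Hz.
    """
    if rate < 100:
        raise ValueError("ECG sampling rate must be at least 100 Hz")
    x = butter_filter(samples, rate, 0.5, "highpass", order=2)
    x = notch_filter(x, rate, 50.0)
    x = butter_filter(x, rate, 40.0, "lowpass", order=4)
    return resample_to(x, rate, ECG_RATE)


def detect_r_waves(ecg: np.ndarray, rate: float = ECG_RATE,
                   add=(), delete=(),
                   refractory: float = 0.25) -> BeatSeries:
    """Adaptive-threshold R detection on a rectified band-emphasized derivative.

    Pan-Tompkins-style: band-pass 5-15 Hz, differentiate, square, integrate
    over a 150 ms window, pick peaks above an adaptive threshold with a
    250 ms refractory period, then refine each detection to the local ECG
    maximum.  Flat or saturated input yields an empty, flagged series rather
    than silent zeros.  ``add``/``delete`` apply manual corrections.
    """
    ecg = np.asarray(ecg, dtype=float)
    if len(ecg) / rate < 10.0:
        raise ValueError("at least 10 s of ECG required")
    if np.ptp(ecg) < 1e-6 or np.std(ecg) < 1e-9:
        return BeatSeries(np.array([]), quality_flag="flat")

    band = butter_filter(ecg, rate, (5.0, 15.0), "bandpass", order=2)
    deriv = np.gradient(band) * rate
    integ = moving_average(deriv ** 2, int(0.150 * rate))
    threshold = 0.25 * np.percentile(integ, 99)
    peaks, _ = signal.find_peaks(integ, height=threshold,
                                 distance=max(int(refractory * rate), 1))
    if peaks.size == 0:
        return BeatSeries(np.array([]), quality_flag="empty")

    # refine to local maximum of the conditioned ECG
    half = int(0.05 * rate)
    r_idx = []
    for p in peaks:
        lo, hi = max(p - half, 0), min(p + half + 1, len(ecg))
        r_idx.append(lo + int(np.argmax(ecg[lo:hi])))
    r_times = np.unique(np.asarray(r_idx)) / rate

    series = BeatSeries(r_times)
    if add or delete:
        series = series.with_edits(add=add, delete=delete)
    # physiologically implausible intervals get artifact flags
    ibis = series.ibis
    flags = (ibis < 300.0) | (ibis > 2000.0)
    return BeatSeries(series.r_times, artifact_flags=flags,
                      quality_flag=series.quality_flag)


def _intervals_in_window(beats: BeatSeries, window) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """IBIs whose midpoint lies in ``[start, end)`` plus midpoints and flags."""
    start, end = window
    mids = (beats.r_times[:-1] + beats.r_times[1:]) / 2.0
    sel = (mids >= start) & (mids < end)
    return beats.ibis[sel], mids[sel], beats.artifact_flags[sel]


def heart_period(beats: BeatSeries, window) -> tuple[float, float]:
    """Mean heart period (ms) and heart rate (bpm) in ``window``.

    Artifact-flagged intervals are excluded.  Fewer than two beats (one
    usable interval) yields ``(nan, nan)``, feeding the missing-data stage.
    """
    ibis, _, flags = _intervals_in_window(beats, window)
    ibis = ibis[~flags]
    if ibis.size < 1:
        return (np.nan, np.nan)
    hp = float(np.mean(ibis))
    return hp, 60000.0 / hp


def hrv_band_power(beats: BeatSeries, window, resample_rate: float = 4.0,
                   power_floor: float = 1e-6,
                   max_interp_run: int = 2) -> HrvResult:
    """HF and LF band power of the IBI series over ``window``.

    The interval series is evenly resampled at ``resample_rate`` Hz by cubic
    interpolation, Welch-transformed (60 s segments, 50% overlap, linear
    detrend) and integrated over each band.  Artifact-flagged intervals are
    linearly interpolated when at most ``max_interp_run`` occur consecutively;
    longer artifact runs mark the window missing.  Powers are floored at
    ``power_floor`` ms^2 before the log so degenerate (constant) series
    return a finite, flagged value.
    """
    start, end = window
    if end - start < 60.0:
        raise ValueError("HRV requires a window of at least 60 s")
    ibis, mids, flags = _intervals_in_window(beats, (start, end))
    if ibis.size < 4:
        return HrvResult(np.nan, np.nan, flag="missing")
    runs = _flag_runs(flags)
    if any(r > max_interp_run for r in runs):
        return HrvResult(np.nan, np.nan, flag="missing")
    if flags.any():
        good = ~flags
        ibis = np.interp(mids, mids[good], ibis[good])
    if mids[-1] - mids[0] < 0.8 * (end - start):
        return HrvResult(np.nan, np.nan, flag="missing")

    grid = np.arange(mids[0], mids[-1], 1.0 / resample_rate)
    kind = "cubic" if ibis.size >= 4 else "linear"
    series = interpolate.interp1d(mids, ibis, kind=kind)(grid)
    nperseg = min(int(60.0 * resample_rate), len(series))
    freqs, psd = signal.welch(series, fs=resample_rate, nperseg=nperseg,
                              noverlap=nperseg // 2, detrend="linear")

    def band_power(lo: float, hi: float) -> float:
        sel = (freqs >= lo) & (freqs <= hi)
        if sel.sum() < 2:
            return 0.0
        return float(np.trapezoid(psd[sel], freqs[sel]))

    p_hf = band_power(*HF_BAND)
    p_lf = band_power(*LF_BAND)
    floored = (p_hf <= power_floor) or (p_lf <= power_floor)
    return HrvResult(float(np.log(max(p_hf, power_floor))),
                     float(np.log(max(p_lf, power_floor))),
                     flag="floored" if floored else "ok")


def _flag_runs(flags: np.ndarray) -> list[int]:
    runs, count = [], 0
    for f in flags:
        count = count + 1 if f else 0
        if f:
            if count == 1:
                runs.append(1)
            else:
                runs[-1] = count
    return runs
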