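"""Respiration-rate and electrodermal nonspecific-fluctuation derivation.

Respiration is measured with up to two inductive belts (thorax, abdomen);
the rate is the number of respiratory cycles per minute, averaged across the
belts that provide usable data.  Electrodermal arousal is quantified as the
nonspecific skin-conductance fluctuation rate (NSFR): fluctuations are
counted at qualifying onsets (local minima of the 25 Hz conductance signal,
at least 1 s apart) whose ensuing local maximum occurs 3.5-12 s later and
rises by more than 0.02 uS.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._dsp import butter_filter, resample_to

__all__ = ["BreathSeries", "NsfEvent", "NsfSeries", "preprocess_resp",
           "detect_breaths", "resp_rate", "detect_nsf",
           "NSF_AMP_THRESHOLD_US", "NSF_PEAK_WINDOW_S", "NSF_MIN_ONSET_GAP_S"]

RESP_RATE_HZ = 25.0   # after preprocessing
EDA_RATE_HZ = 25.0

NSF_AMP_THRESHOLD_US = 0.02       # strict: amplitude must exceed this
NSF_PEAK_WINDOW_S = (3.5, 12.0)   # closed window for the qualifying peak
NSF_MIN_ONSET_GAP_S = 1.0


@dataclass
class BreathSeries:
    """Alternating inspiration/expiration onsets (seconds) from one belt."""

    insp_onsets: np.ndarray
    exp_onsets: np.ndarray
    belt: str = "thorax"
    quality_flag: str = "ok"  # "ok" | "flat"

    def __post_init__(self) -> None:
        for arr in (self.insp_onsets, self.exp_onsets):
            a = np.asarray(arr, dtype=float)
            if a.size and np.any(np.diff(a) <= 0):
                raise ValueError("onsets must be strictly increasing")

    @property
    def usable(self) -> bool:
        return self.quality_flag == "ok" and len(self.insp_onsets) >= 2


@dataclass
class NsfEvent:
    onset: float       # s
    peak: float        # s
    amplitude: float   # uS, peak value minus onset value


@dataclass
class NsfSeries:
    events: list[NsfEvent] = field(default_factory=list)

    def count_in(self, window) -> int:
        start, end = window
        return sum(start <= e.onset < end for e in self.events)


def preprocess_resp(samples: np.ndarray, rate: float) -> np.ndarray:
    """0.033 Hz high-pass, 1 Hz low-pass, resampled to 25 Hz."""
    if rate < 4:
        raise ValueError("respiration sampling rate must be at least 4 Hz")
    x = butter_filter(samples, rate, 0.033, "highpass", order=2)
    x = butter_filter(x, rate, 1.0, "lowpass", order=4)
    return resample_to(x, rate, RESP_RATE_HZ)


def detect_breaths(resp: np.ndarray, rate: float = RESP_RATE_HZ,
                   belt: str = "thorax", min_cycle: float = 1.0) -> BreathSeries:
    """Breath onsets from zero crossings of the detrended belt signal.

    Upward crossings mark inspiration onset, downward crossings expiration
    onset; crossings closer than ``min_cycle`` seconds to the previous kept
    crossing of the same type are discarded (the 1 Hz low-pass makes faster
    cycles physically meaningless).  Flat signals yield an empty, flagged
    series.
    """
    x = np.asarray(resp, dtype=float)
    if x.size < 2 or np.ptp(x) < 1e-9:
        return BreathSeries(np.array([]), np.array([]), belt=belt, quality_flag="flat")
    x = x - np.mean(x)
    sign = np.signbit(x)
    up = np.flatnonzero(sign[:-1] & ~sign[1:]) + 1
    down = np.flatnonzero(~sign[:-1] & sign[1:]) + 1

    def enforce_gap(idx: np.ndarray) -> np.ndarray:
        kept = []
        for i in idx:
            if not kept or (i - kept[-1]) / rate >= min_cycle:
                kept.append(i)
        return np.asarray(kept)

    up, down = enforce_gap(up), enforce_gap(down)
    return BreathSeries(up / rate, down / rate, belt=belt)


def resp_rate(breaths, window) -> float:
    """Respiratory cycles per minute over ``window``, averaged across belts.

    ``breaths`` is one BreathSeries or a sequence of them (one per belt);
    unusable belts are skipped, and the result is missing (nan) when no belt
    is usable.
    """
    if isinstance(breaths, BreathSeries):
        breaths = [breaths]
    start, end = window
    duration = end - start
    if duration <= 0:
        raise ValueError("window must have positive duration")
    rates = []
    for series in breaths:
        if not series.usable:
            continue
        onsets = series.insp_onsets[(series.insp_onsets >= start)
                                    & (series.insp_onsets < end)]
        if onsets.size >= 2:
            # mean cycle length among onsets in the window: avoids the +-1
            # cycle discretization of a plain count
            rates.append((onsets.size - 1) / (onsets[-1] - onsets[0]) * 60.0)
        elif onsets.size:
            rates.append(onsets.size / duration * 60.0)
    return float(np.mean(rates)) if rates else np.nan


def _local_minima(x: np.ndarray) -> np.ndarray:
    """3-sample local minima (strict on the left, non-strict on the right)."""
    return np.flatnonzero((x[1:-1] < x[:-2]) & (x[1:-1] <= x[2:])) + 1


def _local_maxima(x: np.ndarray) -> np.ndarray:
    return np.flatnonzero((x[1:-1] > x[:-2]) & (x[1:-1] >= x[2:])) + 1


def detect_nsf(eda: np.ndarray, window, rate: float = EDA_RATE_HZ,
               min_gap: float = NSF_MIN_ONSET_GAP_S,
               peak_window: tuple[float, float] = NSF_PEAK_WINDOW_S,
               amp_threshold: float = NSF_AMP_THRESHOLD_US) -> tuple[NsfSeries, float]:
    """Nonspecific fluctuations and their per-minute rate in ``window``.

    Qualifying onsets are local minima of the 25 Hz signal at least
    ``min_gap`` s apart (earliest kept).  Local maxima are then counted as
    fluctuations: a maximum qualifies when it falls inside the closed
    ``peak_window`` (seconds) after a qualifying onset and rises strictly
    more than ``amp_threshold`` uS above that onset's value (the nearest
    preceding qualifying onset is used).  Each maximum is counted at most
    once, and an event belongs to the segment containing its onset even if
    the peak falls outside.  Windows shorter than 10 s return (empty, nan).
    """
    x = np.asarray(eda, dtype=float)
    start, end = window
    duration = end - start
    if duration < 10.0:
        return NsfSeries(), np.nan

    minima = _local_minima(x)
    onsets: list[int] = []
    for i in minima:
        if not onsets or (i - onsets[-1]) / rate >= min_gap:
            onsets.append(i)
    onset_arr = np.asarray(onsets)
    maxima = _local_maxima(x)

    lag_lo = int(np.ceil(peak_window[0] * rate))
    lag_hi = int(np.floor(peak_window[1] * rate))
    events = []
    for j in maxima:
        cand = onset_arr[(onset_arr <= j - lag_lo) & (onset_arr >= j - lag_hi)]
        if cand.size == 0:
            continue
        i = int(cand[-1])  # nearest preceding qualifying onset
        t_on = i / rate
        if not (start <= t_on < end):
            continue
        if x[j] - x[i] > amp_threshold:
            events.append(NsfEvent(onset=t_on, peak=j / rate,
                                   amplitude=float(x[j] - x[i])))
    series = NsfSeries(events)
    return series, len(events) / duration * 60.0
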