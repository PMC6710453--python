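"""Impedance-cardiographic and blood-pressure derivations.

From the dZ/dt signal, beats are ensemble-averaged (pointwise median,
R-locked) and the B, Z and X landmarks detected: B marks aortic valve
opening, Z the maximum ejection velocity (dZ/dt)max, X aortic valve closure.
With the Q point fixed 20 ms before the R wave, PEP = (B - R) + 20 ms and
LVET = X - B.  Stroke volume follows the Kubicek formula

    SV = rho * (L / Z0)^2 * LVET * (dZ/dt)max,    rho = 135 Ohm*cm,

cardiac output CO = SV * HR / 1000 (l/min), mean arterial pressure
MAP = sys/3 + 2*dia/3, and total peripheral resistance TPR = MAP / CO.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as _signal

from ._dsp import butter_filter, resample_to
from .cardiac import BeatSeries
from .design import BP_SLOT_OF_SEGMENT

__all__ = [
    "EnsembleBeat", "BzxPoints", "preprocess_dzdt", "ensemble_average",
    "detect_bzx", "pep_from_b", "stroke_volume_kubicek", "cardiac_output",
    "mean_arterial_pressure", "total_peripheral_resistance", "assign_bp_slots",
    "RHO_OHM_CM", "Q_BEFORE_R_MS",
]

RHO_OHM_CM = 135.0     # assumed thoracic resistivity
Q_BEFORE_R_MS = 20.0   # fixed Q-point latency before the R wave
DZDT_RATE = 1000.0     # Hz after preprocessing


@dataclass
class EnsembleBeat:
    """R-locked pointwise-median dZ/dt waveform."""

    waveform: np.ndarray     # Ohm/s
    time_ms: np.ndarray      # ms relative to R, spans at least [-100, 500]
    n_beats: int
    z0_mean: float = np.nan  # Ohm

    def __post_init__(self) -> None:
        if self.n_beats < 10:
            raise ValueError("ensemble requires at least 10 beats")
        if self.time_ms[0] > -100 or self.time_ms[-1] < 500:
            raise ValueError("ensemble window must span [-100, 500] ms around R")


@dataclass
class BzxPoints:
    """B/Z/X latencies in ms after R; ``valid`` is False on degenerate shapes."""

    b: float
    z: float
    x: float
    valid: bool = True


def preprocess_dzdt(samples: np.ndarray, rate: float) -> np.ndarray:
    """50 Hz band-stop (mains) then polyphase resampling to 1000 Hz."""
    if rate < 120:
        raise ValueError("dZ/dt sampling rate must be at least 120 Hz")
    x = butter_filter(samples, rate, (48.0, 52.0), "bandstop", order=4)
    return resample_to(x, rate, DZDT_RATE)


def ensemble_average(dzdt: np.ndarray, beats: BeatSeries, window,
                     rate: float = DZDT_RATE,
                     pre_ms: float = 100.0, post_ms: float = 550.0,
                     exclude_beats=()) -> EnsembleBeat | None:
    """Pointwise-median, R-locked ensemble of dZ/dt sweeps in ``window``.

    The median makes the ensemble robust to occasional ectopic or
    movement-contaminated sweeps.  ``exclude_beats`` is the manual-correction
    hook (beat times in seconds to drop).  Returns None (missing) with fewer
    than 10 usable beats.
    """
    start, end = window
    r = beats.r_times
    sel = (r >= start) & (r < end)
    r = r[sel]
    if exclude_beats:
        r = np.array([t for t in r if all(abs(t - e) > 0.05 for e in exclude_beats)])
    n_pre, n_post = int(pre_ms * rate / 1000), int(post_ms * rate / 1000)
    sweeps = []
    for t in r:
        c = int(round(t * rate))
        if c - n_pre >= 0 and c + n_post < len(dzdt):
            sweeps.append(dzdt[c - n_pre:c + n_post + 1])
    if len(sweeps) < 10:
        return None
    waveform = np.median(np.asarray(sweeps), axis=0)
    time_ms = (np.arange(-n_pre, n_post + 1)) * 1000.0 / rate
    return EnsembleBeat(waveform, time_ms, n_beats=len(sweeps))


def detect_bzx(ens: EnsembleBeat,
               z_search_ms: tuple[float, float] = (30.0, 300.0),
               b_lookback_ms: float = 160.0,
               b_amp_fraction: float = 0.4,
               x_search_ms: float = 450.0) -> BzxPoints:
    """Locate the B, Z and X points on an ensemble-averaged dZ/dt beat.

    Z is the global maximum in the systolic search window.  B is the maximum
    of the (smoothed) second derivative within the sub-40%-of-Z-amplitude
    region preceding Z, a common operationalization of the upstroke onset.
    X is the minimum within 450 ms after Z.  Non-physiological orderings or
    boundary solutions are returned with ``valid=False`` (missing + flag).
    """
    t, w = ens.time_ms, ens.waveform
    dt = t[1] - t[0]

    z_lo, z_hi = np.searchsorted(t, z_search_ms[0]), np.searchsorted(t, z_search_ms[1])
    if z_hi - z_lo < 5:
        return BzxPoints(np.nan, np.nan, np.nan, valid=False)
    zi = z_lo + int(np.argmax(w[z_lo:z_hi]))
    z_amp = w[zi]
    if z_amp <= 0 or zi in (z_lo, z_hi - 1):   # monotone ramp / no systolic peak
        return BzxPoints(np.nan, np.nan, np.nan, valid=False)

    # B: curvature maximum in the low-amplitude region before Z
    win = max(int(round(11 / dt)) | 1, 5)
    d2 = _signal.savgol_filter(w, window_length=win, polyorder=3, deriv=2)
    look = np.searchsorted(t, t[zi] - b_lookback_ms)
    region = np.arange(look, zi)
    region = region[w[region] < b_amp_fraction * z_amp]
    if region.size < 3:
        return BzxPoints(np.nan, np.nan, np.nan, valid=False)
    bi = region[int(np.argmax(d2[region]))]

    # X: minimum (valve-closure notch) after Z
    x_hi = np.searchsorted(t, t[zi] + x_search_ms)
    xi = zi + 1 + int(np.argmin(w[zi + 1:x_hi]))
    if xi >= x_hi - 2:    # no notch before the search boundary
        return BzxPoints(np.nan, np.nan, np.nan, valid=False)

    b_ms, z_ms, x_ms = float(t[bi]), float(t[zi]), float(t[xi])
    if not (0 < b_ms < z_ms < x_ms):
        return BzxPoints(b_ms, z_ms, x_ms, valid=False)
    return BzxPoints(b_ms, z_ms, x_ms)


def pep_from_b(b_latency_ms: float) -> float:
    """PEP (ms) from the B latency: Q-to-B interval with Q at R - 20 ms."""
    return b_latency_ms + Q_BEFORE_R_MS


def stroke_volume_kubicek(z0: float, distance_cm: float, lvet_s: float,
                          dzdt_max: float, rho: float = RHO_OHM_CM) -> float:
    """Kubicek stroke volume in ml."""
    if z0 <= 0:
        raise ValueError("basal impedance must be positive")
    if distance_cm <= 0 or lvet_s <= 0 or dzdt_max < 0:
        raise ValueError("electrode distance and LVET must be positive, dZ/dt max non-negative")
    return rho * (distance_cm / z0) ** 2 * lvet_s * dzdt_max


def cardiac_output(sv_ml: float, hr_bpm: float) -> float:
    """Cardiac output in l/min."""
    return sv_ml * hr_bpm / 1000.0


def mean_arterial_pressure(sys_mmhg: float, dia_mmhg: float) -> float:
    """MAP = sys/3 + 2*dia/3 (mmHg)."""
    if not (sys_mmhg >= dia_mmhg > 0):
        raise ValueError("require sys >= dia > 0")
    return sys_mmhg / 3.0 + 2.0 * dia_mmhg / 3.0


def total_peripheral_resistance(map_mmhg: float, co_l_min: float) -> float:
    """TPR = MAP / CO (mmHg*min/l)."""
    if co_l_min <= 0:
        raise ValueError("cardiac output must be positive")
    return map_mmhg / co_l_min


def assign_bp_slots(readings) -> dict[str, float | None]:
    """Map three spot BP readings to per-analysis-segment MAP values.

    Reading 1 (mid-baseline) backs BL; reading 2 (after R1) backs Q1 and R1;
    reading 3 (after the 6-min rest) backs Q2 and R2a-R2f.  A missing reading
    propagates as None for its segments.
    """
    if len(readings) != 3:
        raise ValueError("exactly 3 BP readings expected")
    maps = [mean_arterial_pressure(*r) if r is not None else None for r in readings]
    return {seg: maps[slot] for seg, slot in BP_SLOT_OF_SEGMENT.items()}
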