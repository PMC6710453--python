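"""Shared digital signal processing helpers (filtering, resampling)."""

from __future__ import annotations

from fractions import Fraction

import numpy as np
from scipy import signal


def resample_to(x: np.ndarray, rate_in: float, rate_out: float) -> np.ndarray:
    """Polyphase resampling from ``rate_in`` to ``rate_out`` Hz."""
    if rate_in <= 0 or rate_out <= 0:
        raise ValueError("sampling rates must be positive")
    if rate_in == rate_out:
        return np.asarray(x, dtype=float)
    frac = Fraction(rate_out / rate_in).limit_denominator(10000)
    return signal.resample_poly(np.asarray(x, dtype=float), frac.numerator,
                                frac.denominator, padtype="line")


def butter_filter(x: np.ndarray, rate: float, cutoff, btype: str, order: int = 4) -> np.ndarray:
    """Zero-phase Butterworth filter; ``cutoff`` in Hz (scalar or pair).

    Generous edge padding keeps start/end transients small; a residual
    transient of a few time constants at each boundary is unavoidable.
    """
    sos = signal.butter(order, cutoff, btype=btype, fs=rate, output="sos")
    x = np.asarray(x, dtype=float)
    padlen = min(len(x) - 1, int(3 * rate))
    return signal.sosfiltfilt(sos, x, padlen=padlen)


def notch_filter(x: np.ndarray, rate: float, freq: float = 50.0, q: float = 30.0) -> np.ndarray:
    """Zero-phase IIR notch at ``freq`` Hz (mains interference)."""
    b, a = signal.iirnotch(freq, q, fs=rate)
    x = np.asarray(x, dtype=float)
    # the high-Q biquad rings; generous padding keeps edge transients out
    padlen = min(len(x) - 1, int(2 * rate))
    return signal.filtfilt(b, a, x, padlen=padlen)


def moving_average(x: np.ndarray, width: int) -> np.ndarray:
    """Centered moving average with edge padding."""
    width = max(int(width), 1)
    kernel = np.ones(width) / width
    return np.convolve(np.pad(x, (width // 2, width - 1 - width // 2), mode="edge"),
                       kernel, mode="valid")
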