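"""Shared low-level signal filters."""

from __future__ import annotations

import numpy as np
from scipy import signal

BAND_LOW = 0.02  # Hz, infra-slow BOLD band
BAND_HIGH = 0.1


def butter_bandpass(
    data: np.ndarray,
    fs: float,
    low: float = BAND_LOW,
    high: float = BAND_HIGH,
    axis: int = 0,
) -> np.ndarray:
    """Zero-phase 2nd-order Butterworth band-pass (forward-backward)."""
    nyq = fs / 2.0
    if not (0.0 < low < high):
        raise ValueError("need 0 < low < high")
    if high >= nyq:
        raise ValueError(
            f"high cutoff {high} Hz is at or above the Nyquist frequency {nyq} Hz"
        )
    b, a = signal.butter(2, [low / nyq, high / nyq], btype="band")
    return signal.filtfilt(b, a, data, axis=axis)
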