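"""Zero-phase IIR band-pass filtering helpers.

All band-limited operations in the toolkit (ERD power, the FBCSP filter
bank, narrowband synthesis) go through the same 4th-order Butterworth
band-pass applied forward-backward, so the effective magnitude response
is 8th-order and the phase response is zero.
"""

from __future__ import annotations

import numpy as np
from scipy import signal

from lmbci.errors import ConfigError


def bandpass_sos(band: tuple[float, float], fs: float, order: int = 4) -> np.ndarray:
    """Second-order sections for a Butterworth band-pass.

    Parameters
    ----------
    band
        (low, high) edge frequencies in Hz; must satisfy 0 < low < high < fs/2.
    fs
        Sampling rate in Hz.
    order
        Filter order of the underlying design (doubled by filtfilt).
    """
    low, high = band
    nyq = fs / 2.0
    if not (0.0 < low < high):
        raise ConfigError(f"invalid band {band!r}: need 0 < low < high")
    if high >= nyq:
        raise ConfigError(f"band {band!r} exceeds Nyquist frequency {nyq} Hz")
    return signal.butter(order, [low / nyq, high / nyq], btype="bandpass", output="sos")


def bandpass_filter(
    x: np.ndarray, band: tuple[float, float], fs: float, order: int = 4, axis: int = -1
) -> np.ndarray:
    """Zero-phase band-pass of ``x`` along ``axis``."""
    sos = bandpass_sos(band, fs, order=order)
    return signal.sosfiltfilt(sos, x, axis=axis)
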