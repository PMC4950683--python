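"""Zero-phase band-pass filtering shared by the simulator and the
connectivity stage.

The filter is a second-order Butterworth band-pass applied forward and
backward (``sosfiltfilt``), i.e. zero phase shift, so temporal lag
structure is preserved. The default band 0.009-0.08 Hz is the
conventional resting-state fluctuation band.
"""

from __future__ import annotations

import numpy as np
from scipy.signal import butter, sosfiltfilt

__all__ = ["MIN_VOLUMES", "bandpass_timeseries"]

#: shortest series the zero-phase filter accepts
MIN_VOLUMES = 12


def bandpass_timeseries(
    series: np.ndarray,
    tr: float,
    low: float = 0.009,
    high: float = 0.08,
    order: int = 2,
) -> np.ndarray:
    """Band-pass a (time,) or (time, channels) array along its first axis."""
    series = np.asarray(series, dtype=float)
    n = series.shape[0]
    if n < MIN_VOLUMES:
        raise ValueError(
            f"band-pass filtering needs at least {MIN_VOLUMES} volumes, got {n}"
        )
    fs = 1.0 / tr
    nyquist = fs / 2.0
    if not (0.0 < low < high < nyquist):
        raise ValueError(
            f"band ({low}, {high}) Hz must satisfy 0 < low < high < Nyquist ({nyquist:.4g})"
        )
    sos = butter(order, [low, high], btype="bandpass", fs=fs, output="sos")
    default_padlen = 3 * (2 * sos.shape[0] + 1)
    padlen = min(default_padlen, n - 1)
    return sosfiltfilt(sos, series, axis=0, padlen=padlen)
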