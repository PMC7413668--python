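"""Shared filtering / analytic-signal helpers.

All filters are zero-phase (forward-backward application). Band-pass filters
are FIR with a length of at least three cycles of the band's low edge.
"""

from __future__ import annotations

import numpy as np
from scipy import signal


def _fir_taps(fs: float, low: float, high: float | None, n_cycles: float = 3.0) -> np.ndarray:
    """Design FIR taps; ``high=None`` gives a high-pass, ``low<=0`` a low-pass."""
    if high is not None and high >= fs / 2:
        raise ValueError(f"band edge {high} Hz at or above Nyquist ({fs / 2} Hz)")
    if low <= 0:  # low-pass
        edge = high
        ntaps = int(n_cycles * fs / edge) | 1
        return signal.firwin(ntaps, edge, pass_zero=True, fs=fs)
    ntaps = int(n_cycles * fs / low) | 1
    if high is None:
        return signal.firwin(ntaps, low, pass_zero=False, fs=fs)
    return signal.firwin(ntaps, [low, high], pass_zero=False, fs=fs)


def _filtfilt(taps: np.ndarray, x: np.ndarray) -> np.ndarray:
    n = x.shape[0]
    padlen = min(3 * len(taps), n - 1)
    if n <= len(taps):
        raise ValueError(
            f"signal length {n} too short for filter of {len(taps)} taps"
        )
    return signal.filtfilt(taps, 1.0, x, axis=0, padlen=padlen)


def bandpass(x: np.ndarray, fs: float, low: float, high: float) -> np.ndarray:
    """Zero-phase FIR band-pass."""
    return _filtfilt(_fir_taps(fs, low, high), x)


def lowpass(x: np.ndarray, fs: float, cutoff: float) -> np.ndarray:
    return _filtfilt(_fir_taps(fs, 0.0, cutoff), x)


def highpass(x: np.ndarray, fs: float, cutoff: float) -> np.ndarray:
    return _filtfilt(_fir_taps(fs, cutoff, None), x)


def notch(x: np.ndarray, fs: float, freq: float, half_width: float = 1.0) -> np.ndarray:
    """Zero-phase narrow band-stop (IIR notch, ``half_width`` Hz each side)."""
    b, a = signal.iirnotch(freq, freq / (2.0 * half_width), fs=fs)
    return signal.filtfilt(b, a, x, axis=0)


def analytic(x: np.ndarray) -> np.ndarray:
    return signal.hilbert(x, axis=0)


def envelope(x: np.ndarray) -> np.ndarray:
    return np.abs(signal.hilbert(x, axis=0))


def instantaneous_phase(x: np.ndarray) -> np.ndarray:
    """Unwrapped analytic-signal phase (0 at the positive peak of a cosine)."""
    return np.unwrap(np.angle(signal.hilbert(x, axis=0)), axis=0)


def phase_level_crossings(ph: np.ndarray, fs: float, offset: float) -> np.ndarray:
    """Sub-sample times where unwrapped phase crosses ``offset + 2*pi*k``.

    Returns times in seconds. Linear interpolation between the bracketing
    samples; robust to brief phase regressions (only upward level crossings
    are counted, one per level).
    """
    levels = np.floor((ph - offset) / (2 * np.pi))
    jumps = np.nonzero(np.diff(levels) > 0)[0]
    times = []
    for i in jumps:
        for k in np.arange(levels[i] + 1, levels[i + 1] + 1):
            target = offset + 2 * np.pi * k
            p0, p1 = ph[i], ph[i + 1]
            if p1 == p0:
                frac = 0.0
            else:
                frac = (target - p0) / (p1 - p0)
            frac = min(max(frac, 0.0), 1.0)
            times.append((i + frac) / fs)
    return np.asarray(times)
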