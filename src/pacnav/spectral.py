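"""Band-pass filtering, analytic-signal phase/envelope extraction, and PSD.

Filtering uses a 4th-order Butterworth applied forward-backward (zero group
delay), the standard choice in phase-amplitude coupling work where any phase
distortion of the slow band would bias the coupling phase.  Instantaneous
phase and envelope come from the Hilbert analytic signal; 50 ms is trimmed
from each end of extracted series to discard filter edge transients before
any coupling statistic is computed.
"""

from __future__ import annotations

import numpy as np
from scipy import fft as _fft
from scipy import signal as _sig

__all__ = ["bandpass", "extract_phase", "extract_amplitude", "trim_edges", "psd", "band_power"]

_FILTER_ORDER = 4


def _design(f_lo: float, f_hi: float, fs: float) -> np.ndarray:
    if not 0 < f_lo < f_hi:
        raise ValueError(f"invalid band ({f_lo}, {f_hi}) Hz")
    if f_hi >= fs / 2:
        raise ValueError(f"band edge {f_hi} Hz at or above Nyquist ({fs / 2} Hz)")
    return _sig.butter(_FILTER_ORDER, [f_lo, f_hi], btype="bandpass", fs=fs, output="sos")


def bandpass(x: np.ndarray, f_lo: float, f_hi: float, fs: float) -> np.ndarray:
    """Zero-phase Butterworth band-pass of ``x`` to the ``(f_lo, f_hi)`` Hz band."""
    x = np.asarray(x, dtype=float)
    if x.ndim != 1:
        raise ValueError("bandpass expects a 1-D series; filter channels separately")
    sos = _design(f_lo, f_hi, fs)
    return _sig.sosfiltfilt(sos, x)


def _analytic(x: np.ndarray) -> np.ndarray:
    # zero-pad the FFT to the next fast length; hilbert is O(n log n)
    x = np.asarray(x, dtype=float)
    n = x.size
    return _sig.hilbert(x, N=_fft.next_fast_len(n))[:n]


def extract_phase(filtered: np.ndarray) -> np.ndarray:
    """Instantaneous phase (radians in [-pi, pi)) of a narrow-band signal.

    Phase 0 sits at the positive peak of the oscillation (cosine convention).
    Samples where the analytic signal vanishes (e.g. an all-zero input) have
    undefined phase and are returned as NaN.
    """
    z = _analytic(filtered)
    phase = np.angle(z)
    phase[np.abs(z) == 0.0] = np.nan
    # np.angle returns (-pi, pi]; fold +pi to -pi for the [-pi, pi) convention
    phase[phase == np.pi] = -np.pi
    return phase


def extract_amplitude(filtered: np.ndarray) -> np.ndarray:
    """Instantaneous amplitude envelope (same units as the input) via Hilbert."""
    return np.abs(_analytic(filtered))


def trim_edges(series: np.ndarray, fs: float, trim_ms: float = 50.0) -> np.ndarray:
    """Drop ``trim_ms`` of samples from both ends (filter edge-effect guard)."""
    series = np.asarray(series)
    k = int(round(trim_ms * fs / 1000.0))
    if series.shape[0] <= 2 * k:
        raise ValueError(
            f"series of {series.shape[0]} samples too short to trim {k} from each end"
        )
    return series[k:-k] if k else series


def psd(x: np.ndarray, fs: float, window_s: float = 1.0) -> tuple[np.ndarray, np.ndarray]:
    """Welch power spectral density: Hann windows of ``window_s``, 50% overlap.

    Returns (frequencies in Hz, density in input-units^2/Hz).
    """
    x = np.asarray(x, dtype=float)
    if x.size < fs:
        raise ValueError("need at least 1 s of signal for a PSD")
    nperseg = min(int(window_s * fs), x.size)
    return _sig.welch(x, fs=fs, window="hann", nperseg=nperseg, noverlap=nperseg // 2)


def band_power(freqs: np.ndarray, power: np.ndarray, band: tuple[float, float]) -> float:
    """Integrate a PSD over ``band`` (Hz); returns power in input-units^2."""
    f_lo, f_hi = band
    if f_lo < freqs[0] or f_hi > freqs[-1]:
        raise ValueError(f"band {band} outside PSD range ({freqs[0]}, {freqs[-1]}) Hz")
    sel = (freqs >= f_lo) & (freqs <= f_hi)
    if sel.sum() < 2:
        raise ValueError(f"band {band} narrower than PSD resolution")
    return float(np.trapezoid(power[sel], freqs[sel]))
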