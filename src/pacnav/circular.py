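"""Circular statistics for theta phases at high-frequency envelope peaks.

Peaks are local maxima of the fast-band envelope exceeding mean + k*SD
(default k = 2); the slow-band phase at each peak forms a circular sample.
The summary is the mean resultant vector (direction avgAng, length r), a
Fisher-style 95% confidence interval for the mean direction, and the Rayleigh
test of uniformity (z = n r^2 with the standard small-sample p approximation).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as _sig

__all__ = [
    "CircularSample",
    "CircularSummary",
    "phases_at_hf_peaks",
    "mean_resultant",
    "circular_ci95",
    "rayleigh_test",
    "circular_summary",
]

_CHI2_95_DF1 = 3.841458820694124  # chi2.ppf(0.95, 1)


def _wrap(a):
    """Wrap angles to [-pi, pi)."""
    return np.mod(np.asarray(a, dtype=float) + np.pi, 2 * np.pi) - np.pi


@dataclass
class CircularSample:
    """A set of angles (radians, wrapped to [-pi, pi))."""

    angles: np.ndarray

    def __post_init__(self) -> None:
        self.angles = _wrap(np.atleast_1d(self.angles))

    @property
    def n(self) -> int:
        return self.angles.size


@dataclass
class CircularSummary:
    n: int
    avg_ang: float  # radians; NaN if r == 0
    r: float
    ci95: tuple[float, float]  # radians; (NaN, NaN) if undefined
    rayleigh_z: float
    rayleigh_p: float


def phases_at_hf_peaks(
    theta_phase: np.ndarray,
    hf_envelope: np.ndarray,
    threshold_sd: float = 2.0,
) -> CircularSample:
    """Slow-band phase at each supra-threshold local maximum of the envelope.

    A peak is a local maximum of ``hf_envelope`` above mean + ``threshold_sd``
    standard deviations.  An envelope with no qualifying peaks yields an empty
    sample (flagged by n == 0), not an error.
    """
    theta_phase = np.asarray(theta_phase, dtype=float)
    hf_envelope = np.asarray(hf_envelope, dtype=float)
    if theta_phase.shape != hf_envelope.shape:
        raise ValueError("phase and envelope must have equal length")
    height = hf_envelope.mean() + threshold_sd * hf_envelope.std()
    peaks, _ = _sig.find_peaks(hf_envelope, height=height)
    return CircularSample(angles=theta_phase[peaks])


def mean_resultant(sample: CircularSample) -> tuple[float, float]:
    """Mean direction avgAng = atan2(sum sin, sum cos) and resultant length r.

    For a perfectly balanced sample (r = 0) the direction is undefined and
    returned as NaN.
    """
    if sample.n < 1:
        raise ValueError("empty circular sample")
    c = np.cos(sample.angles).sum()
    s = np.sin(sample.angles).sum()
    r = float(np.hypot(c, s) / sample.n)
    avg = float(np.arctan2(s, c)) if r > 1e-12 else float("nan")
    return avg, min(r, 1.0)


def circular_ci95(sample: CircularSample) -> tuple[float, float]:
    """95% confidence interval for the circular mean (Fisher/Zar arccos form).

    Half-width d satisfies cos(d) = t/R with

        t = sqrt(2n(2R^2 - n chi2) / (4n - chi2))          for r < 0.9
        t = sqrt(n^2 - (n^2 - R^2) exp(chi2 / n))          for r >= 0.9

    where R = n r and chi2 is the 95th chi-square percentile at 1 df.  For
    samples too dispersed for the interval to exist (t/R > 1 or r near 0) the
    CI is undefined and (NaN, NaN) is returned.
    """
    if sample.n < 2:
        raise ValueError("need n >= 2 for a confidence interval")
    avg, r = mean_resultant(sample)
    n = sample.n
    R = n * r
    if r <= np.sqrt(_CHI2_95_DF1 / (2 * n)):
        return (float("nan"), float("nan"))
    if r < 0.9:
        t2 = 2 * n * (2 * R**2 - n * _CHI2_95_DF1) / (4 * n - _CHI2_95_DF1)
        t = np.sqrt(t2) if t2 > 0 else 0.0
    else:
        t = np.sqrt(n**2 - (n**2 - R**2) * np.exp(_CHI2_95_DF1 / n))
    ratio = t / R
    if ratio > 1:
        return (float("nan"), float("nan"))
    d = float(np.arccos(ratio))
    return (avg - d, avg + d)


def rayleigh_test(sample: CircularSample) -> tuple[float, float]:
    """Rayleigh test of circular uniformity: z = n r^2 and approximate p.

    p = exp(sqrt(1 + 4n + 4(n^2 - R^2)) - (1 + 2n)) with R = n r, the standard
    small-sample correction; accurate for n >= 5.
    """
    _, r = mean_resultant(sample)
    n = sample.n
    R = n * r
    z = n * r**2
    p = float(np.exp(np.sqrt(1 + 4 * n + 4 * (n**2 - R**2)) - (1 + 2 * n)))
    return float(z), min(p, 1.0)


def circular_summary(sample: CircularSample) -> CircularSummary:
    """Full circular summary: (n, avgAng, r, 95% CI, Rayleigh z and p)."""
    avg, r = mean_resultant(sample)
    ci = circular_ci95(sample) if sample.n >= 2 else (float("nan"), float("nan"))
    z, p = rayleigh_test(sample)
    return CircularSummary(n=sample.n, avg_ang=avg, r=r, ci95=ci, rayleigh_z=z, rayleigh_p=p)
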