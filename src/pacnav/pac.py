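"""Phase-amplitude coupling: binned distributions, modulation index, comodulograms.

The coupling statistic is the Kullback-Leibler modulation index (Tort-style):
the slow band's instantaneous phase is binned into 18 intervals of 20 degrees,
the mean fast-band envelope per bin is normalized to a probability vector P,
and

    MI = [log N - H(P)] / log N,      H(P) = -sum_j p_j log p_j

(natural log; 0*log 0 = 0), i.e. the KL distance of P from the uniform
distribution, normalized so MI = 0 for no coupling and MI = 1 when the whole
envelope mass falls in a single phase bin.  MI is invariant to cyclic rotation
of P, so a separate Pearson correlation between each trial's P and a
per-subject standard distribution captures coupling-phase consistency across
trials.  A circular time-shift surrogate gives the null MI level.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .spectral import bandpass, extract_amplitude, extract_phase, trim_edges

__all__ = [
    "PhaseAmplitudeDistribution",
    "Comodulogram",
    "phase_amplitude_distribution",
    "modulation_index",
    "mi_for_pair",
    "comodulogram",
    "comodulogram_epochs",
    "standard_distribution",
    "distribution_correlation",
    "surrogate_mi_null",
    "select_best_channel",
    "DEFAULT_PHASE_FREQS",
    "DEFAULT_AMP_FREQS",
]

logger = logging.getLogger(__name__)

N_BINS = 18  # 20-degree phase bins over [-180, 180)

#: Comodulogram grid centers: phase 2-20 Hz step 1, amplitude 20-180 Hz step 5.
DEFAULT_PHASE_FREQS = np.arange(2.0, 21.0, 1.0)
DEFAULT_AMP_FREQS = np.arange(20.0, 181.0, 5.0)

#: Half-bandwidths of the grid filters.  Amplitude bands are wide (+-15 Hz) so
#: that the modulation sidebands at f_A +- f_p pass the filter.
PHASE_HALF_BW = 1.0
AMP_HALF_BW = 15.0


@dataclass
class PhaseAmplitudeDistribution:
    """Normalized mean-envelope-per-phase-bin vector for one (f_p, f_A) pair."""

    p: np.ndarray
    f_p_band: tuple[float, float] | None = None
    f_A_band: tuple[float, float] | None = None
    bin_edges_deg: np.ndarray = field(
        default_factory=lambda: np.linspace(-180.0, 180.0, N_BINS + 1)
    )

    def __post_init__(self) -> None:
        self.p = np.asarray(self.p, dtype=float)
        if self.p.ndim != 1:
            raise ValueError("p must be a 1-D vector of bin masses")
        if np.any(self.p < 0):
            raise ValueError("bin masses must be non-negative")
        if abs(self.p.sum() - 1.0) > 1e-6:
            raise ValueError(f"p must sum to 1 (got {self.p.sum()!r})")

    @property
    def n_bins(self) -> int:
        return self.p.size

    @property
    def bin_centers_deg(self) -> np.ndarray:
        return 0.5 * (self.bin_edges_deg[:-1] + self.bin_edges_deg[1:])


@dataclass
class Comodulogram:
    """MI over a (phase frequency x amplitude frequency) grid of band centers."""

    mi: np.ndarray  # [n_phase, n_amp]; NaN where the band was invalid
    phase_freqs: np.ndarray
    amp_freqs: np.ndarray
    phase_half_bw: float = PHASE_HALF_BW
    amp_half_bw: float = AMP_HALF_BW

    def argmax(self) -> tuple[float, float]:
        """(phase center, amplitude center) in Hz of the largest MI cell."""
        i, j = np.unravel_index(np.nanargmax(self.mi), self.mi.shape)
        return float(self.phase_freqs[i]), float(self.amp_freqs[j])

    def max(self) -> float:
        return float(np.nanmax(self.mi))

    def to_frame(self):
        """Amplitude centers as rows, phase centers as columns."""
        import pandas as pd

        return pd.DataFrame(self.mi.T, index=self.amp_freqs, columns=self.phase_freqs)


def _bin_index(phase: np.ndarray, n_bins: int) -> np.ndarray:
    """Map phases in [-pi, pi) to bin indices 0..n_bins-1 (edges start at -180 deg)."""
    idx = np.floor((phase + np.pi) / (2 * np.pi / n_bins)).astype(np.intp)
    # guard the phase == pi edge case
    return np.clip(idx, 0, n_bins - 1)


def phase_amplitude_distribution(
    phase: np.ndarray,
    amplitude: np.ndarray,
    n_bins: int = N_BINS,
    f_p_band: tuple[float, float] | None = None,
    f_A_band: tuple[float, float] | None = None,
) -> PhaseAmplitudeDistribution:
    """Bin ``amplitude`` by ``phase`` (20-degree bins) and normalize to P.

    ``p[j]`` is the mean envelope in phase bin ``j`` divided by the sum of the
    per-bin means.  Every bin must receive at least one sample — an epoch too
    short to cover the phase circle raises rather than returning a biased P.
    """
    phase = np.asarray(phase, dtype=float)
    amplitude = np.asarray(amplitude, dtype=float)
    if phase.shape != amplitude.shape:
        raise ValueError("phase and amplitude must have equal length")
    ok = ~np.isnan(phase)
    phase, amplitude = phase[ok], amplitude[ok]
    idx = _bin_index(phase, n_bins)
    counts = np.bincount(idx, minlength=n_bins)
    if (counts == 0).any():
        empty = int(np.flatnonzero(counts == 0)[0])
        raise ValueError(
            f"phase bin {empty} received no samples; lengthen the epoch so the "
            f"phase covers all {n_bins} bins"
        )
    mean_amp = np.bincount(idx, weights=amplitude, minlength=n_bins) / counts
    total = mean_amp.sum()
    if total <= 0:
        raise ValueError("envelope is identically zero; distribution undefined")
    return PhaseAmplitudeDistribution(
        p=mean_amp / total,
        f_p_band=f_p_band,
        f_A_band=f_A_band,
        bin_edges_deg=np.linspace(-180.0, 180.0, n_bins + 1),
    )


def modulation_index(P: PhaseAmplitudeDistribution | np.ndarray) -> float:
    """KL-distance modulation index of P from uniform, normalized to [0, 1]."""
    p = P.p if isinstance(P, PhaseAmplitudeDistribution) else np.asarray(P, dtype=float)
    if abs(p.sum() - 1.0) > 1e-6:
        raise ValueError(f"P not normalized: sum = {p.sum()!r}")
    if np.any(p < 0):
        raise ValueError("P has negative mass")
    n = p.size
    pos = p[p > 0]
    entropy = -float(np.sum(pos * np.log(pos)))  # 0*log 0 = 0 by exclusion
    mi = (np.log(n) - entropy) / np.log(n)
    # the index is [0, 1] by construction; clamp float round-off at the ends
    return float(min(max(mi, 0.0), 1.0))


def _phase_amp_series(
    signal: np.ndarray,
    fs: float,
    f_p_band: tuple[float, float],
    f_A_band: tuple[float, float],
    trim_ms: float = 50.0,
) -> tuple[np.ndarray, np.ndarray]:
    theta = bandpass(signal, *f_p_band, fs)
    fast = bandpass(signal, *f_A_band, fs)
    phase = trim_edges(extract_phase(theta), fs, trim_ms)
    amp = trim_edges(extract_amplitude(fast), fs, trim_ms)
    return phase, amp


def mi_for_pair(
    signal: np.ndarray,
    fs: float,
    f_p_band: tuple[float, float],
    f_A_band: tuple[float, float],
    n_bins: int = N_BINS,
    trim_ms: float = 50.0,
) -> float:
    """Full MI pipeline for one band pair: filter, extract, trim, bin, MI."""
    phase, amp = _phase_amp_series(signal, fs, f_p_band, f_A_band, trim_ms)
    P = phase_amplitude_distribution(phase, amp, n_bins, f_p_band, f_A_band)
    return modulation_index(P)


def _grid_bands(
    centers: np.ndarray, half_bw: float, fs: float
) -> list[tuple[float, float] | None]:
    """Band edges per center; None where the band is invalid at this fs."""
    bands: list[tuple[float, float] | None] = []
    for c in centers:
        lo, hi = c - half_bw, c + half_bw
        if lo <= 0 or hi >= fs / 2:
            bands.append(None)
        else:
            bands.append((lo, hi))
    return bands


def comodulogram(
    signal: np.ndarray,
    fs: float,
    phase_freqs: np.ndarray = DEFAULT_PHASE_FREQS,
    amp_freqs: np.ndarray = DEFAULT_AMP_FREQS,
    phase_half_bw: float = PHASE_HALF_BW,
    amp_half_bw: float = AMP_HALF_BW,
    n_bins: int = N_BINS,
    trim_ms: float = 50.0,
) -> Comodulogram:
    """MI over the full (phase x amplitude) frequency grid for one signal.

    Each band is filtered once and shared across all pairs, so cost scales
    with n_phase + n_amp filters, not their product.  Cells whose amplitude
    band would cross Nyquist (or whose phase band would reach 0 Hz) are
    returned as NaN, never silently zero.
    """
    signal = np.asarray(signal, dtype=float)
    phase_freqs = np.asarray(phase_freqs, dtype=float)
    amp_freqs = np.asarray(amp_freqs, dtype=float)
    p_bands = _grid_bands(phase_freqs, phase_half_bw, fs)
    a_bands = _grid_bands(amp_freqs, amp_half_bw, fs)

    phases = [
        trim_edges(extract_phase(bandpass(signal, *b, fs)), fs, trim_ms) if b else None
        for b in p_bands
    ]
    amps = [
        trim_edges(extract_amplitude(bandpass(signal, *b, fs)), fs, trim_ms) if b else None
        for b in a_bands
    ]

    mi = np.full((phase_freqs.size, amp_freqs.size), np.nan)
    for i, phase in enumerate(phases):
        if phase is None:
            continue
        ok = ~np.isnan(phase)
        idx = _bin_index(phase[ok], n_bins)
        counts = np.bincount(idx, minlength=n_bins)
        if (counts == 0).any():
            continue  # phase too short for this band; leave the row NaN
        for j, amp in enumerate(amps):
            if amp is None:
                continue
            mean_amp = np.bincount(idx, weights=amp[ok], minlength=n_bins) / counts
            mi[i, j] = modulation_index(mean_amp / mean_amp.sum())
    return Comodulogram(mi, phase_freqs, amp_freqs, phase_half_bw, amp_half_bw)


def comodulogram_epochs(
    epochs: list[np.ndarray],
    fs: float,
    phase_freqs: np.ndarray = DEFAULT_PHASE_FREQS,
    amp_freqs: np.ndarray = DEFAULT_AMP_FREQS,
    **kwargs,
) -> Comodulogram:
    """Average of per-epoch comodulograms (MI computed per epoch, then meaned)."""
    if not epochs:
        raise ValueError("no epochs")
    maps = [comodulogram(e, fs, phase_freqs, amp_freqs, **kwargs).mi for e in epochs]
    mean_mi = np.nanmean(np.stack(maps), axis=0)
    return Comodulogram(mean_mi, np.asarray(phase_freqs, float), np.asarray(amp_freqs, float))


def standard_distribution(
    Ps: list[PhaseAmplitudeDistribution],
) -> PhaseAmplitudeDistribution:
    """Bin-wise mean of trial distributions, renormalized.

    Used as the per-subject reference ("standard distribution") against which
    individual trial distributions are correlated.
    """
    if not Ps:
        raise ValueError("need at least one distribution")
    n = {P.n_bins for P in Ps}
    if len(n) > 1:
        raise ValueError(f"mixed bin counts: {sorted(n)}")
    mean_p = np.mean([P.p for P in Ps], axis=0)
    return PhaseAmplitudeDistribution(
        p=mean_p / mean_p.sum(),
        f_p_band=Ps[0].f_p_band,
        f_A_band=Ps[0].f_A_band,
        bin_edges_deg=Ps[0].bin_edges_deg,
    )


def distribution_correlation(
    P_trial: PhaseAmplitudeDistribution,
    P_standard: PhaseAmplitudeDistribution,
    method: str = "pearson",
) -> float:
    """Correlation between a trial's P and the standard P across bins.

    Returns NaN (flagged undefined, never 0) when either distribution has zero
    variance across bins — a uniform P carries no phase information.
    """
    if P_trial.n_bins != P_standard.n_bins:
        raise ValueError("distributions have different bin counts")
    a, b = P_trial.p, P_standard.p
    if np.std(a) == 0 or np.std(b) == 0:
        return float("nan")
    if method == "pearson":
        return float(np.corrcoef(a, b)[0, 1])
    if method == "spearman":
        from scipy.stats import spearmanr

        return float(spearmanr(a, b).statistic)
    raise ValueError(f"unknown correlation method {method!r}")


def surrogate_mi_null(
    phase: np.ndarray,
    amplitude: np.ndarray,
    n_surrogates: int = 200,
    min_shift_ms: float = 100.0,
    fs: float | None = None,
    seed: int | None = None,
    n_bins: int = N_BINS,
) -> tuple[np.ndarray, PhaseAmplitudeDistribution]:
    """Circular time-shift null for the MI of a (phase, amplitude) pair.

    Each surrogate rotates the amplitude series relative to the phase series
    by a uniform random offset of at least ``min_shift_ms`` (both directions),
    destroying the phase-amplitude relationship while preserving both
    marginals.  Returns the ``n_surrogates`` MI values and the mean surrogate
    distribution (which converges to uniform as surrogates accumulate).
    """
    if seed is None:
        raise ValueError("surrogate_mi_null requires an explicit seed")
    if fs is None:
        raise ValueError("fs (Hz) is required to convert min_shift_ms to samples")
    phase = np.asarray(phase, dtype=float)
    amplitude = np.asarray(amplitude, dtype=float)
    n = phase.size
    min_shift = int(round(min_shift_ms * fs / 1000.0))
    if n <= 2 * min_shift:
        raise ValueError("series too short for the minimum surrogate shift")
    rng = np.random.default_rng(seed)
    shifts = rng.integers(min_shift, n - min_shift, size=n_surrogates)
    mis = np.empty(n_surrogates)
    acc = np.zeros(n_bins)
    for k, s in enumerate(shifts):
        P = phase_amplitude_distribution(phase, np.roll(amplitude, int(s)), n_bins)
        mis[k] = modulation_index(P)
        acc += P.p
    mean_P = PhaseAmplitudeDistribution(p=acc / acc.sum())
    return mis, mean_P


def select_best_channel(
    per_channel_session_mi: dict[str, list[float]],
) -> str:
    """Channel with the highest session-averaged MI in the band of interest.

    ``per_channel_session_mi`` maps channel id to its per-session MI values
    (already restricted to the frequency pairs of interest).  Ties break to
    the lexicographically lowest channel id and are logged.
    """
    if not per_channel_session_mi:
        raise ValueError("no channels to select from")
    means = {ch: float(np.mean(v)) for ch, v in per_channel_session_mi.items()}
    best_mi = max(means.values())
    winners = sorted(ch for ch, m in means.items() if m == best_mi)
    if len(winners) > 1:
        logger.info("channel selection tie among %s; choosing %s", winners, winners[0])
    return winners[0]
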