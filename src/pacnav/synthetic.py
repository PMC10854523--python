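"""Synthetic recordings, maze sessions, and homing-flight GPS tracks with
known, controllable phase-amplitude coupling.

The signal model superimposes a slow (theta-band) oscillation, a fast
oscillation whose envelope follows a raised cosine of the slow oscillation's
instantaneous phase, and white Gaussian noise:

    x(t) = A_theta cos(2 pi f_p t)
         + A_hf [ (1 - chi) + chi (1 + cos(2 pi f_p t - phi)) / 2 ] sin(2 pi f_A t)
         + eps(t),      eps ~ N(0, sigma^2)

The coupling depth chi in [0, 1] interpolates from a constant fast-band
envelope (chi = 0, no coupling) to an envelope that vanishes at the
anti-preferred phase (chi = 1, maximal coupling); phi is the slow-band phase
at which the fast envelope peaks.  The slow carrier is a cosine so that its
analytic-signal phase equals 2 pi f_p t and the injected preferred phase is
exactly the phase an analysis pipeline should recover at envelope peaks.

Every stochastic generator requires an explicit seed; there is no silent
default randomness.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import EventStream, GpsTrack, Recording
from .segmentation import haversine_m

__all__ = [
    "PacSimConfig",
    "FlightSimConfig",
    "simulate_pac_signal",
    "simulate_maze_session",
    "simulate_flight_track",
    "simulate_flight_session",
]

_DEG = np.pi / 180.0
_EARTH_R = 6_371_000.0


@dataclass
class PacSimConfig:
    """Parameters of one coupled-oscillation channel.

    Amplitudes are in microvolts; defaults mimic a hippocampal LFP with a
    prominent theta rhythm (50 uV), a weaker fast band (10 uV), and broadband
    noise (15 uV SD).
    """

    seed: int
    fs: float = 2000.0
    duration: float = 10.0
    f_p: float = 6.0
    f_A: float = 150.0
    depth: float = 0.9
    preferred_phase: float = 0.0
    theta_amp: float = 50.0
    hf_amp: float = 10.0
    noise_sd: float = 15.0
    freq_drift_hz: float = 0.5  # SD of theta instantaneous-frequency wander
    drift_tau_s: float = 0.5    # correlation time of the wander
    pink_noise: bool = False

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("a seed is required; unseeded simulation is an error")
        if not 0.0 <= self.depth <= 1.0:
            raise ValueError(f"coupling depth must be in [0, 1], got {self.depth}")
        if self.fs <= 2 * self.f_A:
            raise ValueError(
                f"fs = {self.fs} Hz aliases f_A = {self.f_A} Hz (need fs > 2 f_A)"
            )
        if self.duration <= 0:
            raise ValueError("duration must be positive")


@dataclass
class FlightSimConfig:
    """Geometry and noise of a simulated homing flight (release site -> loft)."""

    seed: int
    release: tuple[float, float] = (113.5300, 34.8200)  # (lon, lat)
    loft: tuple[float, float] = (113.5450, 34.8270)     # ~1.5 km away
    n_fixes: int | None = None  # None: enough 0.1 s fixes to reach the loft
    lateral_jitter_m: float = 20.0
    speed_mps: float = 15.0
    speed_sd_mps: float = 1.5  # per-fix ground-speed variability
    gps_rate_hz: float = 10.0

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("a seed is required; unseeded simulation is an error")
        if haversine_m(self.release, self.loft) <= 500.0:
            raise ValueError("release and loft must be more than 500 m apart")
        if self.n_fixes is not None and self.n_fixes < 10:
            raise ValueError("need at least 10 fixes")
        if self.speed_mps <= 0:
            raise ValueError("speed must be positive")


def _noise(rng: np.random.Generator, n: int, sd: float, pink: bool) -> np.ndarray:
    if sd == 0:
        return np.zeros(n)
    white = rng.standard_normal(n)
    if not pink:
        return sd * white
    # 1/f shaping in the frequency domain, rescaled to the requested SD
    spectrum = np.fft.rfft(white)
    f = np.fft.rfftfreq(n)
    f[0] = f[1] if n > 1 else 1.0
    shaped = np.fft.irfft(spectrum / np.sqrt(f), n=n)
    return sd * shaped / shaped.std()


def _theta_phase(
    t: np.ndarray, cfg: PacSimConfig, rng: np.random.Generator
) -> np.ndarray:
    """Slow-band instantaneous phase with quasi-periodic frequency wander.

    Real theta is not a strict sinusoid: its instantaneous frequency drifts.
    The deviation follows an Ornstein-Uhlenbeck process (SD ``freq_drift_hz``,
    correlation time ``drift_tau_s``), which keeps the theta spectrum
    concentrated near f_p (the smooth wander contributes nothing to distant
    bands) while the integrated phase decorrelates within a couple of
    seconds.  That decorrelation is also what makes circular time-shift
    surrogates a valid null: shifting a strictly periodic carrier would
    merely rotate the preferred phase without destroying the coupling.
    """
    base = 2 * np.pi * cfg.f_p * t
    if cfg.freq_drift_hz == 0:
        return base
    dt = 1.0 / cfg.fs
    a = np.exp(-dt / cfg.drift_tau_s)
    innov = rng.standard_normal(t.size) * cfg.freq_drift_hz * np.sqrt(1 - a * a)
    # OU recursion d[i] = a d[i-1] + innov[i] via a linear filter
    from scipy.signal import lfilter

    dev_hz = lfilter([1.0], [1.0, -a], innov)
    return base + 2 * np.pi * np.cumsum(dev_hz) * dt


def _pac_waveform(
    t: np.ndarray,
    cfg: PacSimConfig,
    theta_phase: np.ndarray,
    depth: np.ndarray | float | None = None,
) -> np.ndarray:
    """Noise-free coupled waveform; ``depth`` may vary per sample."""
    chi = cfg.depth if depth is None else depth
    theta = cfg.theta_amp * np.cos(theta_phase)
    envelope = cfg.hf_amp * (
        (1.0 - chi) + chi * (1.0 + np.cos(theta_phase - cfg.preferred_phase)) / 2.0
    )
    return theta + envelope * np.sin(2 * np.pi * cfg.f_A * t)


def simulate_pac_signal(cfg: PacSimConfig) -> Recording:
    """Single-channel recording with the configured coupling depth.

    Deterministic given the seed; at depth 0 (and zero noise) the fast-band
    envelope is constant over time.
    """
    rng = np.random.default_rng(cfg.seed)
    n = int(round(cfg.duration * cfg.fs))
    t = np.arange(n) / cfg.fs
    x = _pac_waveform(t, cfg, _theta_phase(t, cfg, rng)) + _noise(
        rng, n, cfg.noise_sd, cfg.pink_noise
    )
    return Recording(data=x[:, None], fs=cfg.fs, channel_ids=["sim0"])


def simulate_maze_session(
    n_trials: int,
    positions: list[str],
    fs: float,
    pac: PacSimConfig,
    seed: int,
    goal: str | None = None,
    n_channels: int = 16,
    pac_channel: int = 0,
    event_spacing_s: float = 2.0,
) -> tuple[Recording, EventStream]:
    """Simulated maze session: continuous multichannel LFP plus beam crossings.

    Each trial visits every position in order, one beam-crossing event per
    position, spaced ``event_spacing_s`` apart (must be >= 1 s so analysis
    windows never overlap).  Around each event's [-250, +750] ms analysis
    window, channel ``pac_channel`` carries the configured coupling at
    navigation positions and an uncoupled (depth 0) fast band at the ``goal``
    position; other channels carry theta plus noise only.  The navigate-vs-goal
    coupling contrast is therefore recoverable by construction.
    """
    if len(set(positions)) < 2:
        raise ValueError("need at least 2 distinct position labels")
    if event_spacing_s < 1.0:
        raise ValueError("event spacing under 1 s would overlap analysis windows")
    goal = positions[-1] if goal is None else goal
    if goal not in positions:
        raise ValueError(f"goal {goal!r} not among positions")
    if seed is None:
        raise ValueError("a seed is required")

    rng = np.random.default_rng(seed)
    events: list[tuple[float, str]] = []
    t_cursor = 1.0
    for _ in range(n_trials):
        for pos in positions:
            events.append((t_cursor, pos))
            t_cursor += event_spacing_s
    duration = t_cursor + 1.0
    n = int(round(duration * fs))
    t = np.arange(n) / fs

    theta_phase = _theta_phase(t, pac, rng)
    data = np.empty((n, n_channels))
    theta = pac.theta_amp * np.cos(theta_phase)
    for ch in range(n_channels):
        data[:, ch] = theta + _noise(rng, n, pac.noise_sd, pac.pink_noise)

    # per-sample coupling depth on the PAC channel: cfg.depth inside navigation
    # windows, 0 inside goal windows, fast band absent elsewhere
    depth = np.zeros(n)
    gate = np.zeros(n)
    pad = 0.1  # extend beyond the analysis window so filters see coupled signal
    for t_ev, label in events:
        i0 = max(0, int((t_ev - 0.25 - pad) * fs))
        i1 = min(n, int((t_ev + 0.75 + pad) * fs))
        gate[i0:i1] = 1.0
        if label != goal:
            depth[i0:i1] = pac.depth
    envelope = pac.hf_amp * (
        (1.0 - depth) + depth * (1.0 + np.cos(theta_phase - pac.preferred_phase)) / 2.0
    )
    data[:, pac_channel] += gate * envelope * np.sin(2 * np.pi * pac.f_A * t)

    rec = Recording(data=data, fs=fs, channel_ids=[f"ch{i}" for i in range(n_channels)])
    return rec, EventStream(events=events)


def _local_plane(origin: tuple[float, float]):
    """Meters-per-degree scale factors of the local equirectangular plane."""
    lon0, lat0 = origin
    mx = _EARTH_R * np.cos(lat0 * _DEG) * _DEG  # m per deg lon
    my = _EARTH_R * _DEG                        # m per deg lat
    return lon0, lat0, mx, my


def simulate_flight_track(cfg: FlightSimConfig) -> GpsTrack:
    """GPS fixes marching from the release site to the loft at constant speed.

    Fixes are spaced 1/``gps_rate_hz`` s apart; each is displaced
    perpendicular to the route by Gaussian lateral jitter (GPS error plus
    path meander).  With ``n_fixes=None`` the track runs until the loft is
    reached; an explicit ``n_fixes`` truncates or pads (hovering at the loft).
    """
    rng = np.random.default_rng(cfg.seed)
    lon0, lat0, mx, my = _local_plane(cfg.release)
    dx = (cfg.loft[0] - lon0) * mx
    dy = (cfg.loft[1] - lat0) * my
    dist = float(np.hypot(dx, dy))
    ux, uy = dx / dist, dy / dist          # along-route unit vector
    px, py = -uy, ux                       # perpendicular unit vector

    dt = 1.0 / cfg.gps_rate_hz
    n_nominal = int(np.ceil(dist / (cfg.speed_mps * dt))) + 1
    n_fixes = (n_nominal + 20) if cfg.n_fixes is None else cfg.n_fixes

    # ground speed fluctuates around the nominal cruise speed
    speeds = np.maximum(
        rng.normal(cfg.speed_mps, cfg.speed_sd_mps, size=n_fixes), 0.2 * cfg.speed_mps
    )
    s = np.minimum(np.concatenate([[0.0], np.cumsum(speeds[:-1] * dt)]), dist)
    arrived = s >= dist
    speeds[arrived] = 0.0
    jitter = (
        rng.normal(0.0, cfg.lateral_jitter_m, size=n_fixes)
        if cfg.lateral_jitter_m > 0
        else np.zeros(n_fixes)
    )
    x = s * ux + jitter * px
    y = s * uy + jitter * py
    fixes = np.column_stack(
        [np.arange(n_fixes) * dt, lon0 + x / mx, lat0 + y / my, speeds]
    )
    return GpsTrack(fixes=fixes)


def simulate_flight_session(
    flight: FlightSimConfig,
    pac: PacSimConfig,
    seed: int,
    fs: float = 1000.0,
    n_channels: int = 8,
    pac_channel: int = 0,
    coupled_phases: tuple[str, ...] = ("ER",),
) -> tuple[Recording, GpsTrack]:
    """Homing flight with LFP coupled only during the chosen flight phases.

    Generates the GPS track, labels each fix DM/ER/LN by the release/loft
    radii, and synthesizes a synchronized multichannel recording in which
    channel ``pac_channel`` carries the configured coupling whenever the
    concurrent fix is in ``coupled_phases`` and an uncoupled fast band
    elsewhere.  Neural and GPS streams share the time base (t = 0 at release).
    """
    from .segmentation import label_flight_phases

    track = simulate_flight_track(flight)
    labels = label_flight_phases(track, flight.release, flight.loft)
    rng = np.random.default_rng(seed)

    duration = float(track.times[-1]) + 1.0
    n = int(round(duration * fs))
    t = np.arange(n) / fs

    theta_phase = _theta_phase(t, pac, rng)
    data = np.empty((n, n_channels))
    theta = pac.theta_amp * np.cos(theta_phase)
    for ch in range(n_channels):
        data[:, ch] = theta + _noise(rng, n, pac.noise_sd, pac.pink_noise)

    # nearest-fix flight phase per neural sample -> per-sample coupling depth
    fix_idx = np.clip(
        np.searchsorted(track.times, t, side="right") - 1, 0, len(track) - 1
    )
    coupled = np.isin(np.asarray(labels)[fix_idx], coupled_phases)
    depth = np.where(coupled, pac.depth, 0.0)
    envelope = pac.hf_amp * (
        (1.0 - depth) + depth * (1.0 + np.cos(theta_phase - pac.preferred_phase)) / 2.0
    )
    data[:, pac_channel] += envelope * np.sin(2 * np.pi * pac.f_A * t)

    rec = Recording(data=data, fs=fs, channel_ids=[f"ch{i}" for i in range(n_channels)])
    return rec, track
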