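"""Behavioral segmentation: event-locked maze epochs, GPS flight phases,
speed series, trajectory similarity, and bad-channel screening.

Maze epochs are 1000 ms windows from 250 ms before to 750 ms after each
infrared-detector first contact.  Homing flights split into three phases by
distance along the track: decision-making (DM, within 300 m of the release
site), local navigation (LN, within 200 m of the loft), and en route (ER,
everything between).  DM epochs are labeled but conventionally excluded from
coupling statistics, which focus on ER and LN.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .io import EventStream, GpsTrack, Recording

__all__ = [
    "Epoch",
    "EpochSet",
    "MazeGeometry",
    "DM_RADIUS_M",
    "LN_RADIUS_M",
    "SAME_PATH_THRESHOLD_M",
    "extract_maze_epochs",
    "maze_speed",
    "haversine_m",
    "label_flight_phases",
    "extract_flight_epochs",
    "detect_bad_channels",
    "flight_speed",
    "path_distance",
    "same_path",
]

logger = logging.getLogger(__name__)

EPOCH_PRE_S = 0.25   # window starts 250 ms before the event
EPOCH_POST_S = 0.75  # and extends 750 ms after
DM_RADIUS_M = 300.0  # decision-making: within 300 m of the release site
LN_RADIUS_M = 200.0  # local navigation: within 200 m of the loft
SAME_PATH_THRESHOLD_M = 200.0
EARTH_RADIUS_M = 6_371_000.0


@dataclass
class Epoch:
    """One labeled 1000 ms analysis window (samples x channels)."""

    signal: np.ndarray
    fs: float
    label: str
    trial_id: int
    start_s: float = 0.0
    path_id: str | None = None

    def channel(self, j: int) -> np.ndarray:
        return self.signal[:, j]


@dataclass
class EpochSet:
    epochs: list[Epoch]
    channel_ids: list[str] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.epochs)

    def __iter__(self):
        return iter(self.epochs)

    def with_label(self, *labels: str) -> "EpochSet":
        return EpochSet(
            [e for e in self.epochs if e.label in labels], channel_ids=self.channel_ids
        )

    @property
    def labels(self) -> list[str]:
        return [e.label for e in self.epochs]


@dataclass
class MazeGeometry:
    """Pairwise path distances (m) between named detector positions."""

    distances: dict[tuple[str, str], float]

    def __post_init__(self) -> None:
        sym = {}
        for (a, b), d in self.distances.items():
            if d <= 0:
                raise ValueError(f"distance {a}-{b} must be positive, got {d}")
            rev = self.distances.get((b, a))
            if rev is not None and rev != d:
                raise ValueError(f"asymmetric distances for {a}-{b}: {d} vs {rev}")
            sym[(a, b)] = d
            sym[(b, a)] = d
        self.distances = sym

    def distance(self, a: str, b: str) -> float:
        try:
            return self.distances[(a, b)]
        except KeyError:
            raise KeyError(f"no path distance declared for detectors {a!r}-{b!r}") from None


def extract_maze_epochs(rec: Recording, ev: EventStream) -> EpochSet:
    """One 1000 ms epoch per beam-crossing event ([-250, +750] ms around it).

    Only the first contact per detector per trial should appear in the event
    stream (repeat contacts within 1 s are collapsed here as a guard).  Events
    whose window would run off either end of the recording are dropped with a
    logged reason.  Trial ids count completed passes through the position set.
    """
    n_pre = int(round(EPOCH_PRE_S * rec.fs))
    n_post = int(round(EPOCH_POST_S * rec.fs))
    epochs: list[Epoch] = []
    last_contact: dict[str, float] = {}
    seen_in_trial: set[str] = set()
    trial = 0
    for t, label in ev.events:
        prev = last_contact.get(label)
        if prev is not None and t - prev < 1.0:
            logger.info("repeat contact at %s (t=%.3f) collapsed", label, t)
            continue
        last_contact[label] = t
        if label in seen_in_trial:
            trial += 1
            seen_in_trial = set()
        seen_in_trial.add(label)
        i0 = int(round((t - rec.t0) * rec.fs)) - n_pre
        i1 = i0 + n_pre + n_post
        if i0 < 0 or i1 > rec.n_samples:
            logger.warning("event at t=%.3f s dropped: window outside recording", t)
            continue
        epochs.append(
            Epoch(signal=rec.data[i0:i1], fs=rec.fs, label=label, trial_id=trial, start_s=t - EPOCH_PRE_S)
        )
    return EpochSet(epochs, channel_ids=list(rec.channel_ids))


def maze_speed(ev: EventStream, geom: MazeGeometry) -> list[tuple[tuple[str, str], float]]:
    """Average speed per consecutive detector pair: path distance / elapsed time."""
    out = []
    for (t0, a), (t1, b) in zip(ev.events, ev.events[1:]):
        dt = t1 - t0
        if dt <= 0:
            raise ValueError(f"non-positive elapsed time between {a} and {b}")
        out.append(((a, b), geom.distance(a, b) / dt))
    return out


def haversine_m(p1: tuple[float, float], p2: tuple[float, float]) -> float:
    """Great-circle distance in meters between (lon, lat) points, R = 6371 km."""
    lon1, lat1 = np.radians(p1)
    lon2, lat2 = np.radians(p2)
    a = (
        np.sin((lat2 - lat1) / 2) ** 2
        + np.cos(lat1) * np.cos(lat2) * np.sin((lon2 - lon1) / 2) ** 2
    )
    return float(2 * EARTH_RADIUS_M * np.arcsin(np.sqrt(a)))


def _haversine_vec(lonlat_a: np.ndarray, lonlat_b: np.ndarray) -> np.ndarray:
    """Pairwise haversine matrix (m) between two (n, 2) lon/lat arrays."""
    a = np.radians(lonlat_a)[:, None, :]
    b = np.radians(lonlat_b)[None, :, :]
    dlat = b[..., 1] - a[..., 1]
    dlon = b[..., 0] - a[..., 0]
    h = np.sin(dlat / 2) ** 2 + np.cos(a[..., 1]) * np.cos(b[..., 1]) * np.sin(dlon / 2) ** 2
    return 2 * EARTH_RADIUS_M * np.arcsin(np.sqrt(h))


def label_flight_phases(
    track: GpsTrack,
    release: tuple[float, float],
    loft: tuple[float, float],
    dm_radius_m: float = DM_RADIUS_M,
    ln_radius_m: float = LN_RADIUS_M,
) -> list[str]:
    """Per-fix flight-phase labels: DM / ER / LN, partitioning the track.

    DM = within ``dm_radius_m`` of the release site, LN = within
    ``ln_radius_m`` of the loft, ER = everything between.  Should a fix fall
    inside both radii (geometrically impossible for well-separated sites), the
    tie resolves temporally: DM before the first ER fix, LN after.
    """
    if len(track) == 0:
        raise ValueError("empty track")
    d_release = _haversine_vec(track.lonlat, np.array([release]))[:, 0]
    d_loft = _haversine_vec(track.lonlat, np.array([loft]))[:, 0]
    in_dm = d_release <= dm_radius_m
    in_ln = d_loft <= ln_radius_m
    er_idx = np.flatnonzero(~in_dm & ~in_ln)
    first_er = int(er_idx[0]) if er_idx.size else len(track)
    labels = []
    for i in range(len(track)):
        if in_dm[i] and in_ln[i]:
            labels.append("DM" if i < first_er else "LN")
        elif in_dm[i]:
            labels.append("DM")
        elif in_ln[i]:
            labels.append("LN")
        else:
            labels.append("ER")
    return labels


def extract_flight_epochs(
    rec: Recording,
    track: GpsTrack,
    labels: list[str],
    path_id: str | None = None,
) -> EpochSet:
    """Non-overlapping 1000 ms windows labeled by the flight phase of their fixes.

    Neural and GPS data share one time base.  A window containing fixes from
    more than one phase straddles a boundary and is dropped; windows with no
    fixes are dropped too.
    """
    if len(labels) != len(track):
        raise ValueError("one label per fix required")
    n_win = int(rec.fs)  # 1000 ms
    fix_t = track.times
    labels_arr = np.asarray(labels)
    epochs: list[Epoch] = []
    trial = 0
    for i0 in range(0, rec.n_samples - n_win + 1, n_win):
        t_start = rec.t0 + i0 / rec.fs
        sel = (fix_t >= t_start) & (fix_t < t_start + 1.0)
        if not sel.any():
            continue
        win_labels = set(labels_arr[sel])
        if len(win_labels) > 1:
            continue  # straddles a phase boundary
        epochs.append(
            Epoch(
                signal=rec.data[i0 : i0 + n_win],
                fs=rec.fs,
                label=win_labels.pop(),
                trial_id=trial,
                start_s=t_start,
                path_id=path_id,
            )
        )
        trial += 1
    return EpochSet(epochs, channel_ids=list(rec.channel_ids))


def detect_bad_channels(
    rec: Recording,
    flatline_frac: float = 0.10,
    sd_ratio: float = 5.0,
) -> np.ndarray:
    """Boolean mask of channels to drop (True = bad).

    A channel is bad if more than ``flatline_frac`` of its samples sit in
    flat runs (zero first difference — intermittent connection / electrode
    separation), or if its robust SD (1.4826 * MAD) exceeds ``sd_ratio`` times
    the median robust SD across channels (motion noise).  All channels bad is
    a hard error.
    """
    if rec.n_samples < rec.fs:
        raise ValueError("need at least 1 s of data to screen channels")
    data = rec.data
    flat = np.mean(np.diff(data, axis=0) == 0, axis=0)
    mad = np.median(np.abs(data - np.median(data, axis=0)), axis=0)
    robust_sd = 1.4826 * mad
    med_sd = np.median(robust_sd)
    bad = (flat > flatline_frac) | (med_sd > 0) & (robust_sd > sd_ratio * med_sd)
    if bad.all():
        raise ValueError("all channels flagged bad; recording unusable")
    return bad


def flight_speed(track: GpsTrack) -> list[tuple[float, float]]:
    """Average GPS speed per 1 s window: (window start time, mean m/s).

    Windows tile the track from its first timestamp; windows containing no
    fixes are omitted.
    """
    if len(track) < 10:
        raise ValueError("need at least 10 fixes for a speed series")
    t = track.times
    start, stop = t[0], t[-1]
    out = []
    w = start
    while w < stop:
        sel = (t >= w) & (t < w + 1.0)
        if sel.any():
            out.append((float(w), float(track.speeds[sel].mean())))
        w += 1.0
    return out


def path_distance(track_a: GpsTrack, track_b: GpsTrack) -> float:
    """Symmetric mean nearest-neighbor distance (m) between two trajectories.

    For each fix in one track, the distance to the nearest fix of the other;
    the two directed means are averaged.  Tracks closer than 200 m count as
    the same flight path.
    """
    if len(track_a) == 0 or len(track_b) == 0:
        raise ValueError("both tracks must be non-empty")
    d = _haversine_vec(track_a.lonlat, track_b.lonlat)
    return float(0.5 * (d.min(axis=1).mean() + d.min(axis=0).mean()))


def same_path(track_a: GpsTrack, track_b: GpsTrack, threshold_m: float = SAME_PATH_THRESHOLD_M) -> bool:
    """True when the symmetric mean nearest-neighbor distance is under threshold."""
    return path_distance(track_a, track_b) < threshold_m
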