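"""Containers and file formats for recordings, behavioral events, and GPS tracks.

A :class:`Recording` is a samples x channels array of local field potentials in
microvolts with a sampling rate; the on-disk dialect is an HDF5 file with a
``/data`` dataset and ``fs`` / ``channel_ids`` / ``t0`` attributes, with a CSV
fallback (``# key=value`` header lines) for small fixtures.  Event streams
(infrared beam crossings) and GPS tracks are plain CSV.  All timestamps are
seconds from session start on a single time base shared by neural and GPS data.

Readers are total: every input either parses or raises an error that names the
offending field or line; there is no silent coercion.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

__all__ = [
    "Recording", "EventStream", "GpsTrack",
    "read_recording", "write_recording",
    "read_events_csv", "write_events_csv",
    "read_gps_csv", "write_gps_csv",
]


@dataclass
class Recording:
    """Multichannel LFP recording: ``data`` is samples x channels, in microvolts."""

    data: np.ndarray
    fs: float
    channel_ids: list[str] = field(default_factory=list)
    t0: float = 0.0

    def __post_init__(self) -> None:
        arr = np.asarray(self.data, dtype=float)
        if arr.ndim == 1:
            arr = arr[:, None]
        if arr.ndim != 2:
            raise ValueError("data must be a samples x channels array")
        self.data = arr
        if self.fs <= 0:
            raise ValueError(f"sampling rate must be positive, got {self.fs}")
        if not self.channel_ids:
            self.channel_ids = [f"ch{i}" for i in range(self.data.shape[1])]
        if len(self.channel_ids) != self.data.shape[1]:
            raise ValueError(
                f"{len(self.channel_ids)} channel_ids for {self.data.shape[1]} channels"
            )
        if len(set(self.channel_ids)) != len(self.channel_ids):
            raise ValueError("channel_ids must be unique")

    @property
    def n_samples(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        """Recording length in seconds."""
        return self.n_samples / self.fs

    def channel(self, channel_id: str) -> np.ndarray:
        """Return one channel's series by id."""
        try:
            j = self.channel_ids.index(channel_id)
        except ValueError:
            raise KeyError(f"no channel {channel_id!r}; have {self.channel_ids}") from None
        return self.data[:, j]

    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.n_samples) / self.fs


@dataclass
class EventStream:
    """Time-ordered behavioral events: (time_s, position_label) pairs."""

    events: list[tuple[float, str]]

    def __post_init__(self) -> None:
        times = [t for t, _ in self.events]
        if any(b <= a for a, b in zip(times, times[1:])):
            i = next(i for i, (a, b) in enumerate(zip(times, times[1:])) if b <= a)
            raise ValueError(
                f"event times must be strictly increasing; violation at event {i + 1} "
                f"(t={times[i + 1]} after t={times[i]})"
            )

    def __len__(self) -> int:
        return len(self.events)

    @property
    def times(self) -> np.ndarray:
        return np.array([t for t, _ in self.events], dtype=float)

    @property
    def labels(self) -> list[str]:
        return [lab for _, lab in self.events]


@dataclass
class GpsTrack:
    """GPS fixes at nominal 10 Hz: (time_s, lon_deg, lat_deg, speed_mps) rows."""

    fixes: np.ndarray  # (n, 4) float array: time, lon, lat, speed

    def __post_init__(self) -> None:
        self.fixes = np.asarray(self.fixes, dtype=float)
        if self.fixes.ndim != 2 or self.fixes.shape[1] != 4:
            raise ValueError("fixes must be an (n, 4) array of (time, lon, lat, speed)")
        t = self.fixes[:, 0]
        if np.any(np.diff(t) <= 0):
            i = int(np.argmax(np.diff(t) <= 0))
            raise ValueError(
                f"GPS timestamps must be strictly increasing; violation at fix {i + 1}"
            )
        if np.any(np.abs(self.fixes[:, 1]) > 180):
            raise ValueError("longitude out of [-180, 180]")
        if np.any(np.abs(self.fixes[:, 2]) > 90):
            raise ValueError("latitude out of [-90, 90]")

    def __len__(self) -> int:
        return self.fixes.shape[0]

    @property
    def times(self) -> np.ndarray:
        return self.fixes[:, 0]

    @property
    def lonlat(self) -> np.ndarray:
        return self.fixes[:, 1:3]

    @property
    def speeds(self) -> np.ndarray:
        return self.fixes[:, 3]


# ---------------------------------------------------------------------------
# Recording I/O

def write_recording(rec: Recording, path: str | Path) -> None:
    """Write a recording to HDF5 (``.h5``/``.hdf5``) or CSV (anything else).

    The HDF5 dialect is a ``/data`` float32 dataset with root attributes
    ``fs``, ``channel_ids`` and ``t0``.  The CSV dialect stores the same
    metadata as ``# key=value`` comment lines before the header row.
    """
    path = Path(path)
    if path.suffix.lower() in (".h5", ".hdf5"):
        with h5py.File(path, "w") as f:
            f.create_dataset("data", data=rec.data.astype(np.float32))
            f.attrs["fs"] = float(rec.fs)
            f.attrs["channel_ids"] = [str(c) for c in rec.channel_ids]
            f.attrs["t0"] = float(rec.t0)
    else:
        with open(path, "w") as f:
            f.write(f"# fs={rec.fs!r}\n# t0={rec.t0!r}\n")
            f.write(f"# channel_ids={','.join(rec.channel_ids)}\n")
            pd.DataFrame(rec.data.astype(np.float32), columns=rec.channel_ids).to_csv(
                f, index=False
            )


def _mask_long_nan_runs(data: np.ndarray, fs: float) -> None:
    """Warn about NaN runs longer than 1 s; shorter gaps pass through silently."""
    max_run = int(fs)
    for j in range(data.shape[1]):
        isnan = np.isnan(data[:, j])
        if not isnan.any():
            continue
        # run-length encode the NaN mask
        edges = np.flatnonzero(np.diff(np.concatenate(([0], isnan.view(np.int8), [0]))))
        runs = edges[1::2] - edges[::2]
        if (runs > max_run).any():
            warnings.warn(
                f"channel {j}: NaN run longer than 1 s; samples left masked as NaN",
                stacklevel=3,
            )


def read_recording(path: str | Path) -> Recording:
    """Read a recording written by :func:`write_recording`.

    Raises if the sampling-rate metadata is absent.  NaN runs longer than 1 s
    trigger a warning; the samples stay NaN (masked) rather than being filled.
    """
    path = Path(path)
    if path.suffix.lower() in (".h5", ".hdf5"):
        with h5py.File(path, "r") as f:
            if "fs" not in f.attrs:
                raise ValueError(f"{path}: missing required attribute 'fs'")
            data = np.asarray(f["data"], dtype=float)
            fs = float(f.attrs["fs"])
            ids = [c.decode() if isinstance(c, bytes) else str(c) for c in f.attrs.get("channel_ids", [])]
            t0 = float(f.attrs.get("t0", 0.0))
    else:
        meta: dict[str, str] = {}
        with open(path) as f:
            pos = f.tell()
            while True:
                line = f.readline()
                if not line.startswith("#"):
                    f.seek(pos)
                    break
                key, _, val = line[1:].strip().partition("=")
                meta[key.strip()] = val
                pos = f.tell()
            df = pd.read_csv(f)
        if "fs" not in meta:
            raise ValueError(f"{path}: missing required metadata field 'fs'")
        data = df.to_numpy(dtype=float)
        fs = float(meta["fs"])
        t0 = float(meta.get("t0", 0.0))
        ids = meta["channel_ids"].split(",") if "channel_ids" in meta else list(df.columns)
    _mask_long_nan_runs(data, fs)
    return Recording(data=data, fs=fs, channel_ids=ids or [], t0=t0)


# ---------------------------------------------------------------------------
# Events / GPS CSV

def read_events_csv(path: str | Path) -> EventStream:
    """Read a ``time_s,label`` CSV into an :class:`EventStream`.

    Malformed or out-of-order rows are rejected with their 1-based line number.
    """
    df = pd.read_csv(path)
    for col in ("time_s", "label"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing required column {col!r}")
    times = pd.to_numeric(df["time_s"], errors="coerce")
    bad = np.flatnonzero(times.isna().to_numpy())
    if bad.size:
        raise ValueError(f"{path}: non-numeric time_s at line {bad[0] + 2}")
    t = times.to_numpy(dtype=float)
    off = np.flatnonzero(np.diff(t) <= 0)
    if off.size:
        raise ValueError(
            f"{path}: non-monotone timestamps, first offending line {off[0] + 3}"
        )
    return EventStream(events=list(zip(t, df["label"].astype(str))))


def write_events_csv(ev: EventStream, path: str | Path) -> None:
    pd.DataFrame(ev.events, columns=["time_s", "label"]).to_csv(path, index=False)


def read_gps_csv(path: str | Path) -> GpsTrack:
    """Read a ``time_s,lon,lat,speed`` CSV into a :class:`GpsTrack`."""
    df = pd.read_csv(path)
    cols = ["time_s", "lon", "lat", "speed"]
    for col in cols:
        if col not in df.columns:
            raise ValueError(f"{path}: missing required column {col!r}")
    arr = df[cols].apply(pd.to_numeric, errors="coerce").to_numpy(dtype=float)
    bad = np.flatnonzero(np.isnan(arr).any(axis=1))
    if bad.size:
        raise ValueError(f"{path}: malformed row at line {bad[0] + 2}")
    off = np.flatnonzero(np.diff(arr[:, 0]) <= 0)
    if off.size:
        raise ValueError(
            f"{path}: non-monotone timestamps, first offending line {off[0] + 3}"
        )
    return GpsTrack(fixes=arr)


def write_gps_csv(track: GpsTrack, path: str | Path) -> None:
    pd.DataFrame(track.fixes, columns=["time_s", "lon", "lat", "speed"]).to_csv(
        path, index=False, float_format="%.9f"
    )
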