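"""End-to-end analysis of the two study arms: ground maze and homing flight.

`run_maze_analysis` takes maze sessions (recording + beam-crossing events) and
produces per-epoch coupling statistics on the best channel, per-position
comodulograms, the position-wise Kruskal-Wallis/Dunn comparison, and the
circular summary of slow-band phases at fast-envelope peaks.
`run_flight_analysis` does the flight arm: GPS phase labeling, ER/LN epoching,
ER-vs-LN and path-vs-path Mann-Whitney contrasts, the per-epoch
phase-amplitude heatmap over the flight, and speed correlations.

Both are deterministic given the config seed; every stochastic step (the
surrogate null) draws from one seeded root generator.  CSV exports carry a
hash of the config in a header comment for provenance.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, asdict, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .circular import CircularSample, CircularSummary, circular_summary, phases_at_hf_peaks
from .io import EventStream, GpsTrack, Recording
from .pac import (
    DEFAULT_AMP_FREQS,
    DEFAULT_PHASE_FREQS,
    Comodulogram,
    PhaseAmplitudeDistribution,
    _phase_amp_series,
    comodulogram_epochs,
    distribution_correlation,
    modulation_index,
    phase_amplitude_distribution,
    select_best_channel,
    standard_distribution,
    surrogate_mi_null,
)
from .segmentation import (
    EpochSet,
    detect_bad_channels,
    extract_flight_epochs,
    extract_maze_epochs,
    flight_speed,
    label_flight_phases,
)
from .spectral import band_power, psd
from .stats import TestResult, kruskal_wallis_dunn, mann_whitney, spearman

__all__ = [
    "AnalysisConfig",
    "MazeSession",
    "FlightSession",
    "MazeResult",
    "FlightResult",
    "run_maze_analysis",
    "run_flight_analysis",
]


@dataclass
class AnalysisConfig:
    """Per-task band choices and thresholds.

    Defaults follow the two study arms: maze coupling between 3-6 Hz theta
    phase and 140-180 Hz fast amplitude; flight coupling between 5-10 Hz theta
    phase and 20-30 Hz (beta2) amplitude.  ``task`` only switches which band
    defaults apply; explicit bands always win.
    """

    task: str = "maze"
    seed: int = 0
    theta_band: tuple[float, float] | None = None
    amp_band: tuple[float, float] | None = None
    phase_freqs: tuple[float, ...] = tuple(DEFAULT_PHASE_FREQS)
    amp_freqs: tuple[float, ...] = tuple(DEFAULT_AMP_FREQS)
    peak_threshold_sd: float = 2.0
    n_surrogates: int = 200
    path_threshold_m: float = 200.0
    include_dm: bool = False
    corr_method: str = "pearson"
    compute_comodulograms: bool = True
    reference_label: str | None = None  # standard-distribution position/phase

    def __post_init__(self) -> None:
        if self.task not in ("maze", "flight"):
            raise ValueError(f"task must be 'maze' or 'flight', got {self.task!r}")
        if self.theta_band is None:
            self.theta_band = (3.0, 6.0) if self.task == "maze" else (5.0, 10.0)
        if self.amp_band is None:
            self.amp_band = (140.0, 180.0) if self.task == "maze" else (20.0, 30.0)
        self.theta_band = tuple(self.theta_band)
        self.amp_band = tuple(self.amp_band)
        for name in ("peak_threshold_sd", "n_surrogates", "path_threshold_m"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @property
    def amp_filter_band(self) -> tuple[float, float]:
        """Amplitude-extraction filter band: the band of interest widened by the
        top of the phase band on each side, so the modulation sidebands at
        f_A +- f_p survive the filter (the standard PAC bandwidth rule)."""
        pad = self.theta_band[1]
        return (max(self.amp_band[0] - pad, 0.5), self.amp_band[1] + pad)

    def hash(self) -> str:
        payload = repr(sorted(asdict(self).items())).encode()
        return hashlib.md5(payload).hexdigest()[:12]

    @classmethod
    def from_file(cls, path: str | Path) -> "AnalysisConfig":
        """Load a flat ``key=value`` config file (bands as ``lo,hi``)."""
        kwargs: dict = {}
        for lineno, raw in enumerate(Path(path).read_text().splitlines(), 1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ValueError(f"{path}:{lineno}: expected key=value, got {raw!r}")
            key, val = (s.strip() for s in line.split("=", 1))
            if key in ("theta_band", "amp_band", "phase_freqs", "amp_freqs"):
                kwargs[key] = tuple(float(v) for v in val.split(","))
            elif key in ("seed", "n_surrogates"):
                kwargs[key] = int(val)
            elif key in ("include_dm", "compute_comodulograms"):
                kwargs[key] = val.lower() in ("1", "true", "yes")
            elif key in ("peak_threshold_sd", "path_threshold_m"):
                kwargs[key] = float(val)
            else:
                kwargs[key] = val
        return cls(**kwargs)


@dataclass
class MazeSession:
    recording: Recording
    events: EventStream
    path_id: str = "path1"


@dataclass
class FlightSession:
    recording: Recording
    track: GpsTrack
    release: tuple[float, float]
    loft: tuple[float, float]
    path_id: str = "path1"


@dataclass
class MazeResult:
    epoch_table: pd.DataFrame  # session, path, trial, label, mi, corr
    tests: dict[str, TestResult]
    circular: CircularSummary | None
    comodulograms: dict[str, Comodulogram]
    standard_p: PhaseAmplitudeDistribution
    surrogate_mi: np.ndarray
    surrogate_p: PhaseAmplitudeDistribution
    best_channel: str
    config: AnalysisConfig

    def to_csv(self, outdir: str | Path) -> None:
        _export(self, outdir)


@dataclass
class FlightResult:
    epoch_table: pd.DataFrame  # session, path, trial, label, start_s, mi, corr, speed, theta_power
    tests: dict[str, TestResult]
    spearman_table: pd.DataFrame
    heatmap: pd.DataFrame  # epochs x 18 phase bins, flight order
    comodulograms: dict[str, Comodulogram]
    standard_p: PhaseAmplitudeDistribution
    best_channel: str
    config: AnalysisConfig

    def to_csv(self, outdir: str | Path) -> None:
        _export(self, outdir)


def _export(result, outdir: str | Path) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    stamp = f"# config={result.config.hash()}\n"

    def dump(df: pd.DataFrame, name: str, index: bool = False) -> None:
        with open(outdir / name, "w") as f:
            f.write(stamp)
            df.to_csv(f, index=index)

    dump(result.epoch_table, "epochs.csv")
    rows = []
    for name, tr in result.tests.items():
        rows.append(
            dict(test=name, statistic=tr.statistic, z=tr.z, df=tr.df, p=tr.p,
                 groups="|".join(tr.groups))
        )
        for (a, b), p_adj in tr.posthoc:
            rows.append(dict(test=f"{name}:{a}-vs-{b}", statistic=np.nan, z=np.nan,
                             df=np.nan, p=p_adj, groups=f"{a}|{b}"))
    dump(pd.DataFrame(rows), "tests.csv")
    for label, cm in result.comodulograms.items():
        dump(cm.to_frame(), f"comodulogram_{label}.csv", index=True)
    if getattr(result, "spearman_table", None) is not None:
        dump(result.spearman_table, "spearman.csv")
    if getattr(result, "heatmap", None) is not None:
        dump(result.heatmap, "phase_amplitude_heatmap.csv", index=True)
    circ = getattr(result, "circular", None)
    if circ is not None:
        dump(
            pd.DataFrame(
                [dict(n=circ.n, avgAng_deg=np.degrees(circ.avg_ang), r=circ.r,
                      ci_lo_deg=np.degrees(circ.ci95[0]), ci_hi_deg=np.degrees(circ.ci95[1]),
                      rayleigh_z=circ.rayleigh_z, rayleigh_p=circ.rayleigh_p)]
            ),
            "circular_summary.csv",
        )


# ---------------------------------------------------------------------------
# shared steps

def _good_channels(recs: list[Recording]) -> list[str]:
    """Channels passing the bad-channel screen in every session."""
    good = None
    for rec in recs:
        bad = detect_bad_channels(rec)
        ok = {cid for cid, b in zip(rec.channel_ids, bad) if not b}
        good = ok if good is None else good & ok
    if not good:
        raise ValueError("no channel passes the bad-channel screen in all sessions")
    return sorted(good, key=recs[0].channel_ids.index)


def _epoch_series(epoch_signal: np.ndarray, fs, cfg: AnalysisConfig):
    return _phase_amp_series(epoch_signal, fs, cfg.theta_band, cfg.amp_filter_band)


def _epoch_mi(signal: np.ndarray, fs, cfg: AnalysisConfig) -> float:
    phase, amp = _epoch_series(signal, fs, cfg)
    return modulation_index(phase_amplitude_distribution(phase, amp))


def _pick_channel(
    epoch_sets: list[EpochSet], channels: list[str], cfg: AnalysisConfig, labels: list[str]
) -> str:
    """Session-averaged MI per channel in the band of interest -> argmax."""
    per_channel: dict[str, list[float]] = {c: [] for c in channels}
    for es in epoch_sets:
        idx = {cid: j for j, cid in enumerate(es.channel_ids)}
        use = [e for e in es if e.label in labels]
        for c in channels:
            mis = [
                _epoch_mi(e.signal[:, idx[c]], e.fs, cfg)
                for e in use
            ]
            if mis:
                per_channel[c].append(float(np.mean(mis)))
    per_channel = {c: v for c, v in per_channel.items() if v}
    return select_best_channel(per_channel)


def _epoch_distributions(
    epoch_sets: list[EpochSet], channel: str, cfg: AnalysisConfig, session_names: list[str]
) -> pd.DataFrame:
    """Per-epoch P, MI and metadata for one channel across sessions."""
    rows = []
    for name, es in zip(session_names, epoch_sets):
        j = es.channel_ids.index(channel)
        for e in es:
            phase, amp = _epoch_series(e.signal[:, j], e.fs, cfg)
            P = phase_amplitude_distribution(phase, amp, f_p_band=cfg.theta_band, f_A_band=cfg.amp_band)
            rows.append(
                dict(session=name, path=e.path_id, trial=e.trial_id, label=e.label,
                     start_s=e.start_s, mi=modulation_index(P), P=P,
                     phase=phase, amp=amp)
            )
    return pd.DataFrame(rows)


def _attach_corr(df: pd.DataFrame, standard: PhaseAmplitudeDistribution, method: str) -> None:
    df["corr"] = [distribution_correlation(P, standard, method) for P in df["P"]]


def _concat_series(df: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    phase = np.concatenate(list(df["phase"]))
    amp = np.concatenate(list(df["amp"]))
    return phase, amp


# ---------------------------------------------------------------------------
# maze arm

def run_maze_analysis(
    config: AnalysisConfig,
    sessions: list[MazeSession] | MazeSession,
    goal: str | None = None,
) -> MazeResult:
    """Full maze-arm analysis across one or more sessions.

    ``goal`` names the goal position (coupling is expected to vanish there);
    when omitted, the last position label of the first session is used.  The
    standard distribution is the mean epoch distribution at the reference
    position (``config.reference_label``, default the first position) on the
    first session's path.
    """
    if isinstance(sessions, MazeSession):
        sessions = [sessions]
    if not sessions:
        raise ValueError("no sessions")
    cfg = config if config.task == "maze" else replace(config, task="maze")

    epoch_sets = []
    for s in sessions:
        es = extract_maze_epochs(s.recording, s.events)
        for e in es:
            e.path_id = s.path_id
        epoch_sets.append(es)
    position_order = list(dict.fromkeys(sessions[0].events.labels))
    goal = goal if goal is not None else position_order[-1]
    nav_labels = [p for p in position_order if p != goal]
    reference = cfg.reference_label or nav_labels[0]

    channels = _good_channels([s.recording for s in sessions])
    best = _pick_channel(epoch_sets, channels, cfg, nav_labels)

    names = [f"session{i}" for i in range(len(sessions))]
    df = _epoch_distributions(epoch_sets, best, cfg, names)
    if df.empty:
        raise ValueError("no epochs extracted from any session")

    ref_path = sessions[0].path_id
    ref_mask = (df["label"] == reference) & (df["path"] == ref_path)
    if not ref_mask.any():
        raise ValueError(f"no epochs at reference position {reference!r} on {ref_path!r}")
    standard = standard_distribution(list(df.loc[ref_mask, "P"]))
    _attach_corr(df, standard, cfg.corr_method)

    tests: dict[str, TestResult] = {}
    by_label_mi = {lab: df.loc[df["label"] == lab, "mi"].to_numpy() for lab in position_order}
    by_label_corr = {
        lab: df.loc[df["label"] == lab, "corr"].dropna().to_numpy() for lab in position_order
    }
    if len(position_order) >= 3:
        tests["positions_mi"] = kruskal_wallis_dunn(by_label_mi)
        tests["positions_corr"] = kruskal_wallis_dunn(by_label_corr)
    else:
        a, b = position_order
        tests["positions_mi"] = mann_whitney(by_label_mi[a], by_label_mi[b], (a, b))
        tests["positions_corr"] = mann_whitney(by_label_corr[a], by_label_corr[b], (a, b))

    paths = sorted(df["path"].unique())
    if len(paths) >= 2:
        at_ref = df[df["label"] == reference]
        by_path = {p: at_ref.loc[at_ref["path"] == p, "mi"].to_numpy() for p in paths}
        if len(paths) >= 3:
            tests["paths_mi"] = kruskal_wallis_dunn(by_path)
        else:
            tests["paths_mi"] = mann_whitney(by_path[paths[0]], by_path[paths[1]], (paths[0], paths[1]))

    nav = df[df["label"] != goal]
    phase_cat, amp_cat = _concat_series(nav)
    sample = phases_at_hf_peaks(phase_cat, amp_cat, cfg.peak_threshold_sd)
    circ = circular_summary(sample) if sample.n >= 2 else None

    fs = sessions[0].recording.fs
    surr_mi, surr_p = surrogate_mi_null(
        phase_cat, amp_cat, n_surrogates=cfg.n_surrogates, fs=fs, seed=cfg.seed
    )

    comods: dict[str, Comodulogram] = {}
    if cfg.compute_comodulograms:
        j = epoch_sets[0].channel_ids.index(best)
        for lab in position_order:
            sigs = [
                e.signal[:, j] for es in epoch_sets for e in es if e.label == lab
            ]
            if sigs:
                comods[lab] = comodulogram_epochs(
                    sigs, fs, np.asarray(cfg.phase_freqs), np.asarray(cfg.amp_freqs)
                )

    table = df.drop(columns=["P", "phase", "amp"])
    return MazeResult(
        epoch_table=table, tests=tests, circular=circ, comodulograms=comods,
        standard_p=standard, surrogate_mi=surr_mi, surrogate_p=surr_p,
        best_channel=best, config=cfg,
    )


# ---------------------------------------------------------------------------
# flight arm

def run_flight_analysis(
    config: AnalysisConfig,
    sessions: list[FlightSession] | FlightSession,
) -> FlightResult:
    """Full flight-arm analysis across one or more homing flights.

    Labels every GPS fix DM/ER/LN, extracts 1 s windows on the shared time
    base, computes per-epoch coupling on the best channel, contrasts ER vs LN
    (distribution correlation) and path vs path (MI, ER only), and correlates
    1 s flight speed with MI and theta-band power.  DM epochs are labeled but
    excluded from statistics unless ``config.include_dm``.
    """
    if isinstance(sessions, FlightSession):
        sessions = [sessions]
    if not sessions:
        raise ValueError("no sessions")
    cfg = config if config.task == "flight" else replace(config, task="flight")

    epoch_sets, all_labels = [], []
    for s in sessions:
        labels = label_flight_phases(s.track, s.release, s.loft)
        if set(labels) == {"DM"}:
            raise ValueError("track never leaves the 300 m decision-making radius")
        all_labels.append(labels)
        epoch_sets.append(extract_flight_epochs(s.recording, s.track, labels, path_id=s.path_id))

    stat_labels = ["ER", "LN"] + (["DM"] if cfg.include_dm else [])
    channels = _good_channels([s.recording for s in sessions])
    best = _pick_channel(epoch_sets, channels, cfg, ["ER"])

    names = [f"flight{i}" for i in range(len(sessions))]
    df = _epoch_distributions(epoch_sets, best, cfg, names)
    if df.empty:
        raise ValueError("no flight epochs extracted")

    ref_path = sessions[0].path_id
    ref_mask = (df["label"] == "ER") & (df["path"] == ref_path)
    if not ref_mask.any():
        raise ValueError(f"no ER epochs on reference path {ref_path!r}")
    standard = standard_distribution(list(df.loc[ref_mask, "P"]))
    _attach_corr(df, standard, cfg.corr_method)

    # per-epoch speed and band powers from the synchronized streams
    speed_by_session = {}
    for name, s in zip(names, sessions):
        speed_by_session[name] = dict(flight_speed(s.track))
    j = epoch_sets[0].channel_ids.index(best)
    speeds, theta_pw, hf_pw = [], [], []
    sig_by_session = {name: s.recording for name, s in zip(names, sessions)}
    for row in df.itertuples():
        speeds.append(speed_by_session[row.session].get(float(row.start_s), np.nan))
        rec = sig_by_session[row.session]
        i0 = int(round((row.start_s - rec.t0) * rec.fs))
        seg = rec.data[i0 : i0 + int(rec.fs), j]
        freqs, power = psd(seg, rec.fs)
        theta_pw.append(band_power(freqs, power, cfg.theta_band))
        hf_pw.append(band_power(freqs, power, cfg.amp_band))
    df["speed"] = speeds
    df["theta_power"] = theta_pw
    df["hf_power"] = hf_pw

    stat = df[df["label"].isin(stat_labels)]
    tests: dict[str, TestResult] = {}
    er = stat[stat["label"] == "ER"]
    ln = stat[stat["label"] == "LN"]
    if len(er) and len(ln):
        tests["er_vs_ln_corr"] = mann_whitney(
            er["corr"].dropna(), ln["corr"].dropna(), ("ER", "LN")
        )
        tests["er_vs_ln_theta_power"] = mann_whitney(
            er["theta_power"], ln["theta_power"], ("ER", "LN")
        )
    paths = sorted(stat["path"].unique())
    if len(paths) >= 2:
        by_path = {p: er.loc[er["path"] == p, "mi"].to_numpy() for p in paths}
        tests["paths_mi"] = mann_whitney(
            by_path[paths[0]], by_path[paths[1]], (paths[0], paths[1])
        )

    sp_rows = []
    er_valid = er.dropna(subset=["speed"])
    if len(er_valid) >= 3:
        for col in ("mi", "theta_power", "hf_power"):
            r_s, p = spearman(er_valid["speed"], er_valid[col])
            sp_rows.append(dict(x="speed", y=col, r_s=r_s, p=p, n=len(er_valid)))
    spearman_table = pd.DataFrame(sp_rows)

    # flight-ordered phase-amplitude heatmap (epochs x bins), first session
    first = df[df["session"] == names[0]].sort_values("start_s")
    heatmap = pd.DataFrame(
        np.vstack([P.p for P in first["P"]]),
        index=first["start_s"].to_numpy(),
        columns=[f"{c:.0f}deg" for c in first["P"].iloc[0].bin_centers_deg],
    )

    comods: dict[str, Comodulogram] = {}
    if cfg.compute_comodulograms:
        fs = sessions[0].recording.fs
        for lab in ("ER", "LN"):
            sigs = [e.signal[:, j] for es in epoch_sets for e in es if e.label == lab]
            if sigs:
                comods[lab] = comodulogram_epochs(
                    sigs, fs, np.asarray(cfg.phase_freqs), np.asarray(cfg.amp_freqs)
                )

    table = df.drop(columns=["P", "phase", "amp"])
    return FlightResult(
        epoch_table=table, tests=tests, spearman_table=spearman_table,
        heatmap=heatmap, comodulograms=comods, standard_p=standard,
        best_channel=best, config=cfg,
    )
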