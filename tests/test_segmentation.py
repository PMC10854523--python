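"""Epoch windows, maze speed, haversine, flight phases, bad channels, paths."""

import numpy as np
import pytest

from pacnav import (
    EventStream,
    FlightSimConfig,
    GpsTrack,
    MazeGeometry,
    PacSimConfig,
    Recording,
    detect_bad_channels,
    extract_flight_epochs,
    extract_maze_epochs,
    flight_speed,
    haversine_m,
    label_flight_phases,
    maze_speed,
    path_distance,
    simulate_flight_track,
    simulate_maze_session,
)
from pacnav.segmentation import same_path


@pytest.fixture(scope="module")
def flat_rec():
    rng = np.random.default_rng(0)
    return Recording(rng.normal(size=(40000, 2)), fs=2000.0)


def test_epoch_window_covers_minus250_plus750_ms(flat_rec):
    es = extract_maze_epochs(flat_rec, EventStream([(10.0, "S8")]))
    assert len(es) == 1
    e = es.epochs[0]
    assert e.signal.shape == (2000, 2)
    assert e.start_s == pytest.approx(9.75)
    np.testing.assert_array_equal(e.signal, flat_rec.data[19500:21500])


def test_truncated_window_dropped(flat_rec):
    es = extract_maze_epochs(flat_rec, EventStream([(0.1, "S8"), (10.0, "S9")]))
    assert [e.label for e in es] == ["S9"]


def test_full_simulated_session_yields_all_epochs():
    rec, ev = simulate_maze_session(
        20, ["S8", "S9", "S10", "G1"], 2000.0, PacSimConfig(seed=1), seed=1, n_channels=2
    )
    es = extract_maze_epochs(rec, ev)
    assert len(es) == 80


def test_epoch_extraction_idempotent(flat_rec):
    ev = EventStream([(5.0, "S8"), (7.0, "S9")])
    a = extract_maze_epochs(flat_rec, ev)
    b = extract_maze_epochs(flat_rec, ev)
    assert [e.start_s for e in a] == [e.start_s for e in b]


def test_maze_speed_arithmetic():
    geom = MazeGeometry({("S8", "S9"): 1.0})
    out = maze_speed(EventStream([(0.0, "S8"), (2.0, "S9")]), geom)
    assert out == [(("S8", "S9"), 0.5)]


def test_maze_speed_recovers_constant_rate():
    geom = MazeGeometry({("A", "B"): 2.0, ("B", "C"): 3.0})
    ev = EventStream([(0.0, "A"), (4.0, "B"), (10.0, "C")])  # 0.5 m/s throughout
    speeds = [v for _, v in maze_speed(ev, geom)]
    np.testing.assert_allclose(speeds, 0.5, atol=1e-12)


def test_maze_geometry_validation():
    with pytest.raises(ValueError, match="positive"):
        MazeGeometry({("A", "B"): -1.0})


def test_haversine_closed_forms():
    assert haversine_m((12.0, 34.0), (12.0, 34.0)) == 0.0
    assert haversine_m((0.0, 0.0), (0.0, 1.0)) == pytest.approx(111194.9, abs=0.1)
    assert haversine_m((0.0, 0.0), (180.0, 0.0)) == pytest.approx(np.pi * 6_371_000, abs=1.0)
    # symmetry
    assert haversine_m((3.0, 50.0), (4.0, 51.0)) == haversine_m((4.0, 51.0), (3.0, 50.0))


def test_flight_phase_labels_partition_track():
    cfg = FlightSimConfig(seed=4)
    track = simulate_flight_track(cfg)
    labels = label_flight_phases(track, cfg.release, cfg.loft)
    assert len(labels) == len(track)
    counts = {lab: labels.count(lab) for lab in ("DM", "ER", "LN")}
    assert all(v >= 1 for v in counts.values())
    assert sum(counts.values()) == len(track)
    # DM first, LN last, no DM after ER begins
    first_er = labels.index("ER")
    assert "DM" not in labels[first_er:]
    assert labels[0] == "DM" and labels[-1] == "LN"


def test_phase_radii():
    release, loft = (0.0, 0.0), (0.02, 0.0)  # ~2.2 km apart on the equator
    deg_per_m = 1.0 / 111194.9
    fixes = []
    for i, dist in enumerate([50.0, 700.0, 1500.0]):
        fixes.append([i * 0.1, dist * deg_per_m, 0.0, 15.0])
    fixes.append([0.3, 0.02 - 150.0 * deg_per_m, 0.0, 15.0])
    labels = label_flight_phases(GpsTrack(np.array(fixes)), release, loft)
    assert labels == ["DM", "ER", "ER", "LN"]


def test_flight_epochs_labeled_and_boundary_windows_dropped():
    fs = 100.0
    rec = Recording(np.zeros((int(10 * fs), 1)), fs=fs)
    t = np.arange(0.05, 10.0, 0.1)
    track = GpsTrack(np.column_stack([t, np.zeros_like(t), np.zeros_like(t), np.full_like(t, 15.0)]))
    labels = ["ER" if ti < 4.55 else "LN" for ti in t]  # boundary inside window 4
    es = extract_flight_epochs(rec, track, labels)
    got = [e.label for e in es]
    assert got.count("ER") == 4 and got.count("LN") == 5
    assert len(es) == 9  # the straddling window was dropped


def test_simulated_flight_has_all_phase_epochs():
    from pacnav import simulate_flight_session

    fl = FlightSimConfig(seed=6)
    rec, track = simulate_flight_session(
        fl, PacSimConfig(seed=6, f_p=7.0, f_A=25.0, fs=1000.0), seed=6, fs=1000.0, n_channels=1
    )
    labels = label_flight_phases(track, fl.release, fl.loft)
    es = extract_flight_epochs(rec, track, labels)
    got = set(e.label for e in es)
    assert got == {"DM", "ER", "LN"}


# -- bad channels -----------------------------------------------------------

def test_flatline_channel_flagged(rng):
    data = rng.normal(size=(4000, 4)) * 30
    data[:, 2] = 0.0
    bad = detect_bad_channels(Recording(data, fs=2000.0))
    assert bad.tolist() == [False, False, True, False]


def test_identical_clean_channels_pass(rng):
    col = rng.normal(size=4000) * 30
    bad = detect_bad_channels(Recording(np.tile(col[:, None], (1, 4)), fs=2000.0))
    assert not bad.any()


def test_high_amplitude_artifact_channel_flagged(rng):
    data = rng.normal(size=(4000, 4)) * 30
    data[:, 1] *= 20.0
    bad = detect_bad_channels(Recording(data, fs=2000.0))
    assert bad.tolist() == [False, True, False, False]


def test_all_bad_is_hard_error():
    with pytest.raises(ValueError, match="all channels"):
        detect_bad_channels(Recording(np.zeros((4000, 3)), fs=2000.0))


# -- flight speed -----------------------------------------------------------

def test_constant_speed_windows():
    t = np.arange(0, 30, 0.1)
    track = GpsTrack(np.column_stack([t, t * 1e-5, np.zeros_like(t), np.full_like(t, 15.0)]))
    out = flight_speed(track)
    assert len(out) == 30
    assert all(v == pytest.approx(15.0) for _, v in out)


def test_window_mean_of_varying_speeds():
    t = np.arange(10) * 0.1
    speeds = np.arange(1.0, 11.0)
    track = GpsTrack(np.column_stack([t, t * 1e-5, np.zeros_like(t), speeds]))
    out = flight_speed(track)
    assert out[0][1] == pytest.approx(5.5)


# -- path similarity --------------------------------------------------------

def test_identical_tracks_distance_zero():
    track = simulate_flight_track(FlightSimConfig(seed=8))
    assert path_distance(track, track) == 0.0
    assert same_path(track, track)


def test_parallel_offset_tracks_are_different_paths():
    t = np.arange(0, 60, 0.1)
    deg_per_m = 1.0 / 111194.9
    lon = t * 15.0 * deg_per_m  # due-east leg at 15 m/s
    base = GpsTrack(np.column_stack([t, lon, np.zeros_like(t), np.full_like(t, 15.0)]))
    offset = GpsTrack(
        np.column_stack([t, lon, np.full_like(t, 500.0 * deg_per_m), np.full_like(t, 15.0)])
    )
    d = path_distance(base, offset)
    assert d == pytest.approx(500.0, rel=0.01)
    assert not same_path(base, offset)


def test_rejittered_flight_is_same_path():
    cfg = dict(lateral_jitter_m=20.0)
    a = simulate_flight_track(FlightSimConfig(seed=1, **cfg))
    b = simulate_flight_track(FlightSimConfig(seed=2, **cfg))
    assert path_distance(a, b) < 200.0
    assert same_path(a, b)
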