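"""Modulation index, distributions, comodulograms, surrogates, channel choice."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from pacnav import (
    PhaseAmplitudeDistribution,
    comodulogram,
    distribution_correlation,
    mi_for_pair,
    modulation_index,
    phase_amplitude_distribution,
    select_best_channel,
    standard_distribution,
    surrogate_mi_null,
)
from pacnav.pac import N_BINS, _phase_amp_series


def brute_force_mi(p: np.ndarray) -> float:
    """Independent oracle: KL(P || U) / log N by direct summation."""
    n = p.size
    total = 0.0
    for pj in p:
        if pj > 0:
            total += pj * np.log(pj / (1.0 / n))
    return total / np.log(n)


# -- distribution construction ----------------------------------------------

def test_constant_amplitude_gives_uniform_distribution():
    phase = np.linspace(-np.pi, np.pi, 3600, endpoint=False)
    P = phase_amplitude_distribution(phase, np.ones_like(phase))
    np.testing.assert_allclose(P.p, 1.0 / N_BINS, atol=1e-12)


def test_amplitude_concentrated_in_one_bin():
    phase = np.linspace(-np.pi, np.pi, 3600, endpoint=False)
    idx5 = (phase >= -np.pi + 5 * np.pi / 9) & (phase < -np.pi + 6 * np.pi / 9)
    amp = np.where(idx5, 1.0, 1e-6)
    P = phase_amplitude_distribution(phase, amp)
    assert P.p[5] > 0.9


def test_raised_cosine_amplitude_matches_closed_form_bin_means():
    phase = np.linspace(-np.pi, np.pi, 36000, endpoint=False)
    P = phase_amplitude_distribution(phase, 1.0 + np.cos(phase))
    centers = np.radians(P.bin_centers_deg)
    expected = 1.0 + np.sinc(1.0 / N_BINS) * np.cos(centers)  # exact bin mean of 1+cos
    expected /= expected.sum()
    np.testing.assert_allclose(P.p, expected, atol=1e-5)
    # the cosine peak at 0 deg sits on a bin edge: the two flanking bins tie
    assert abs(P.bin_centers_deg[np.argmax(P.p)]) == pytest.approx(10.0)


def test_empty_bin_is_a_named_error():
    phase = np.full(100, 0.1)  # a single bin
    with pytest.raises(ValueError, match="bin"):
        phase_amplitude_distribution(phase, np.ones(100))


# -- modulation index -------------------------------------------------------

def test_mi_endpoints():
    assert modulation_index(np.full(N_BINS, 1.0 / N_BINS)) == pytest.approx(0.0, abs=1e-12)
    point = np.zeros(N_BINS)
    point[7] = 1.0
    assert modulation_index(point) == pytest.approx(1.0, abs=1e-12)


def test_mi_two_half_bins():
    p = np.zeros(N_BINS)
    p[[2, 11]] = 0.5
    assert modulation_index(p) == pytest.approx(1.0 - np.log(2) / np.log(18), abs=1e-12)


def test_mi_matches_brute_force_kl_on_random_simplex(rng):
    for _ in range(100):
        p = rng.dirichlet(np.ones(N_BINS))
        assert modulation_index(p) == pytest.approx(brute_force_mi(p), abs=1e-12)


def test_mi_bounds_over_many_simplex_draws(rng):
    draws = rng.dirichlet(np.full(N_BINS, 0.3), size=10_000)
    mis = np.array([modulation_index(p) for p in draws])
    assert (mis >= 0).all() and (mis <= 1).all()


def test_mi_invariant_to_cyclic_rotation(rng):
    p = rng.dirichlet(np.ones(N_BINS))
    for k in range(1, N_BINS):
        assert modulation_index(np.roll(p, k)) == pytest.approx(modulation_index(p), abs=1e-12)


def test_mi_rejects_unnormalized_input():
    with pytest.raises(ValueError, match="not normalized"):
        modulation_index(np.full(N_BINS, 1.0))


@settings(deadline=None, max_examples=50, derandomize=True)
@given(st.lists(st.floats(1e-6, 1.0), min_size=N_BINS, max_size=N_BINS))
def test_mi_in_unit_interval_property(weights):
    p = np.asarray(weights)
    p = p / p.sum()
    mi = modulation_index(p)
    assert -1e-12 <= mi <= 1.0 + 1e-12


# -- full pipeline MI -------------------------------------------------------

def test_white_noise_mi_is_tiny_across_seeds():
    for seed in range(20):
        x = np.random.default_rng(seed).standard_normal(20000)
        assert mi_for_pair(x, 2000.0, (3.0, 6.0), (140.0, 180.0)) < 0.01


def test_coupled_mi_dwarfs_uncoupled_mi(coupled_signal, uncoupled_signal):
    x1, cfg = coupled_signal
    x0, _ = uncoupled_signal
    mi1 = mi_for_pair(x1, cfg.fs, (3.0, 6.0), (140.0, 180.0))
    mi0 = mi_for_pair(x0, cfg.fs, (3.0, 6.0), (140.0, 180.0))
    assert mi1 > 20 * mi0


def test_mi_scale_invariant(coupled_signal):
    x, cfg = coupled_signal
    a = mi_for_pair(x, cfg.fs, (3.0, 6.0), (140.0, 180.0))
    b = mi_for_pair(10.0 * x, cfg.fs, (3.0, 6.0), (140.0, 180.0))
    assert a == pytest.approx(b, abs=1e-12)


# -- comodulogram -----------------------------------------------------------

def test_default_grid_shape(coupled_signal):
    x, cfg = coupled_signal
    cm = comodulogram(x[: int(2 * cfg.fs)], cfg.fs)
    assert cm.mi.shape == (19, 33)


def test_cells_above_nyquist_flagged_not_zero(coupled_signal):
    x, cfg = coupled_signal
    cm = comodulogram(x[: int(2 * cfg.fs)], 400.0, amp_freqs=np.array([100.0, 250.0]))
    assert np.isnan(cm.mi[:, 1]).all()  # 250 + 15 > 200 Hz Nyquist
    assert np.isfinite(cm.mi[:, 0]).any()


# -- standard distribution and correlation ----------------------------------

def _raised_cosine_P(shift_deg: float = 0.0) -> PhaseAmplitudeDistribution:
    centers = np.radians(np.arange(-170.0, 180.0, 20.0) - shift_deg)
    p = 1.0 + np.cos(centers)
    return PhaseAmplitudeDistribution(p=p / p.sum())


def test_standard_distribution_identity_and_symmetry():
    P = _raised_cosine_P()
    np.testing.assert_allclose(standard_distribution([P]).p, P.p, atol=1e-12)
    mixed = standard_distribution([P, _raised_cosine_P(180.0)])
    np.testing.assert_allclose(mixed.p, 1.0 / N_BINS, atol=1e-3)


def test_standard_distribution_recovers_generative_shape(rng):
    base = _raised_cosine_P()
    Ps = []
    for _ in range(100):
        noisy = base.p * rng.uniform(0.8, 1.2, N_BINS)
        Ps.append(PhaseAmplitudeDistribution(p=noisy / noisy.sum()))
    mean_P = standard_distribution(Ps)
    assert np.abs(mean_P.p - base.p).max() < 0.01


def test_standard_distribution_rejects_mixed_bins():
    P18 = _raised_cosine_P()
    P9 = PhaseAmplitudeDistribution(
        p=np.full(9, 1 / 9), bin_edges_deg=np.linspace(-180, 180, 10)
    )
    with pytest.raises(ValueError, match="bin counts"):
        standard_distribution([P18, P9])


def test_distribution_correlation_endpoints():
    P = _raised_cosine_P()
    assert distribution_correlation(P, P) == pytest.approx(1.0)
    assert distribution_correlation(P, _raised_cosine_P(180.0)) <= -0.9
    uniform = PhaseAmplitudeDistribution(p=np.full(N_BINS, 1.0 / N_BINS))
    assert np.isnan(distribution_correlation(uniform, P))


# -- surrogates -------------------------------------------------------------

@pytest.fixture(scope="module")
def coupled_series(coupled_signal):
    x, cfg = coupled_signal
    return _phase_amp_series(x, cfg.fs, (3.0, 6.0), (140.0, 180.0)), cfg.fs


def test_surrogates_kill_coupling_and_converge_to_uniform(coupled_series):
    (phase, amp), fs = coupled_series
    mis200, p200 = surrogate_mi_null(phase, amp, n_surrogates=200, fs=fs, seed=7)
    mis20, p20 = surrogate_mi_null(phase, amp, n_surrogates=20, fs=fs, seed=7)
    observed = modulation_index(phase_amplitude_distribution(phase, amp))
    assert observed > np.percentile(mis200, 95)
    dev200 = np.abs(p200.p - 1.0 / N_BINS).max()
    dev20 = np.abs(p20.p - 1.0 / N_BINS).max()
    assert dev200 < dev20


def test_surrogates_deterministic_given_seed(coupled_series):
    (phase, amp), fs = coupled_series
    a, _ = surrogate_mi_null(phase, amp, n_surrogates=30, fs=fs, seed=42)
    b, _ = surrogate_mi_null(phase, amp, n_surrogates=30, fs=fs, seed=42)
    np.testing.assert_array_equal(a, b)


def test_surrogates_require_seed(coupled_series):
    (phase, amp), fs = coupled_series
    with pytest.raises(ValueError, match="seed"):
        surrogate_mi_null(phase, amp, fs=fs)


# -- channel selection ------------------------------------------------------

def test_best_channel_is_session_averaged_argmax():
    mi = {"ch0": [0.01, 0.02], "ch1": [0.2, 0.3], "ch2": [0.05, 0.04]}
    assert select_best_channel(mi) == "ch1"


def test_single_channel_trivial_and_tie_breaks_low():
    assert select_best_channel({"ch3": [0.1]}) == "ch3"
    assert select_best_channel({"ch2": [0.1], "ch1": [0.1]}) == "ch1"


def test_no_channels_is_error():
    with pytest.raises(ValueError):
        select_best_channel({})
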