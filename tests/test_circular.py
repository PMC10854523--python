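"""Mean resultant vector, circular CI, Rayleigh test, envelope-peak phases."""

import numpy as np
import pytest

from pacnav import (
    CircularSample,
    circular_ci95,
    circular_summary,
    mean_resultant,
    phases_at_hf_peaks,
    rayleigh_test,
)

pingouin = pytest.importorskip("pingouin")


def test_identical_angles_have_unit_resultant():
    s = CircularSample(np.full(50, np.radians(30.0)))
    avg, r = mean_resultant(s)
    assert np.degrees(avg) == pytest.approx(30.0, abs=1e-9)
    assert r == pytest.approx(1.0, abs=1e-12)


def test_balanced_four_point_sample_has_zero_resultant():
    s = CircularSample(np.radians([0.0, 90.0, 180.0, 270.0]))
    avg, r = mean_resultant(s)
    assert r == pytest.approx(0.0, abs=1e-12)
    assert np.isnan(avg)


def test_two_vector_closed_form():
    s = CircularSample(np.radians([0.0, 90.0]))
    avg, r = mean_resultant(s)
    assert np.degrees(avg) == pytest.approx(45.0)
    assert r == pytest.approx(np.cos(np.radians(45.0)), abs=1e-12)


def test_rotation_equivariance():
    rng = np.random.default_rng(3)
    base = rng.vonmises(0.5, 2.0, size=200)
    avg0, r0 = mean_resultant(CircularSample(base))
    z0, p0 = rayleigh_test(CircularSample(base))
    for delta in np.radians([37.0, -120.0, 200.0]):
        rotated = CircularSample(base + delta)
        avg, r = mean_resultant(rotated)
        z, p = rayleigh_test(rotated)
        diff = np.angle(np.exp(1j * (avg - avg0 - delta)))
        assert abs(diff) < 1e-12
        assert r == pytest.approx(r0, abs=1e-12)
        assert z == pytest.approx(z0, abs=1e-9) and p == pytest.approx(p0, abs=1e-12)


def test_resultant_length_grows_with_concentration():
    rng = np.random.default_rng(9)
    rs = [mean_resultant(CircularSample(rng.vonmises(0.0, k, 1000)))[1] for k in (0.5, 1, 2, 5)]
    assert rs == sorted(rs)


def test_mean_direction_matches_pingouin():
    rng = np.random.default_rng(5)
    angles = rng.vonmises(1.0, 2.0, size=300)
    avg, r = mean_resultant(CircularSample(angles))
    assert avg == pytest.approx(float(pingouin.circ_mean(angles)), abs=1e-9)
    assert r == pytest.approx(float(pingouin.circ_r(angles)), abs=1e-9)


# -- confidence interval ----------------------------------------------------

def test_ci_coverage_on_von_mises_draws():
    hits = 0
    for seed in range(100):
        rng = np.random.default_rng(seed)
        s = CircularSample(rng.vonmises(1.0, 5.0, size=1000))
        lo, hi = circular_ci95(s)
        half = (hi - lo) / 2
        center = (lo + hi) / 2
        if abs(np.angle(np.exp(1j * (1.0 - center)))) <= half:
            hits += 1
    assert hits >= 93


def test_ci_shrinks_with_sample_size():
    rng = np.random.default_rng(1)
    big = rng.vonmises(0.0, 3.0, size=2000)
    widths = []
    for n in (100, 500, 2000):
        lo, hi = circular_ci95(CircularSample(big[:n]))
        widths.append(hi - lo)
    assert widths == sorted(widths, reverse=True)


def test_ci_degenerate_concentration_is_tight():
    lo, hi = circular_ci95(CircularSample(np.full(50, 1.2)))
    assert hi - lo == pytest.approx(0.0, abs=1e-6)


def test_ci_undefined_for_near_uniform_sample():
    angles = np.linspace(-np.pi, np.pi, 40, endpoint=False)
    lo, hi = circular_ci95(CircularSample(angles))
    assert np.isnan(lo) and np.isnan(hi)


# -- Rayleigh test ----------------------------------------------------------

def test_rayleigh_fully_concentrated():
    z, p = rayleigh_test(CircularSample(np.full(100, 0.7)))
    assert z == pytest.approx(100.0, abs=1e-9)
    assert p < 1e-10


def test_rayleigh_uniform_grid():
    z, p = rayleigh_test(CircularSample(np.linspace(-np.pi, np.pi, 100, endpoint=False)))
    assert z == pytest.approx(0.0, abs=1e-12)
    assert p > 0.99


def test_rayleigh_power_on_von_mises():
    rejections = sum(
        rayleigh_test(CircularSample(np.random.default_rng(s).vonmises(0.0, 2.0, 200)))[1] < 0.01
        for s in range(100)
    )
    assert rejections >= 99


def test_rayleigh_matches_pingouin():
    rng = np.random.default_rng(17)
    angles = rng.vonmises(0.3, 1.5, size=150)
    z, p = rayleigh_test(CircularSample(angles))
    z_ref, p_ref = pingouin.circ_rayleigh(angles)
    assert z == pytest.approx(float(z_ref), rel=1e-9)
    assert p == pytest.approx(float(p_ref), rel=1e-6)


# -- envelope peaks ---------------------------------------------------------

def test_isolated_peaks_are_counted():
    env = np.zeros(1000)
    peaks_at = [100, 300, 500, 700, 900]
    for i in peaks_at:
        env[i] = 10.0
    phase = np.linspace(-np.pi, np.pi, 1000, endpoint=False)
    sample = phases_at_hf_peaks(phase, env, threshold_sd=2.0)
    assert sample.n == len(peaks_at)
    np.testing.assert_allclose(sample.angles, phase[peaks_at])


def test_flat_envelope_yields_empty_sample():
    sample = phases_at_hf_peaks(np.zeros(100), np.ones(100))
    assert sample.n == 0


def test_summary_of_empty_sample_raises():
    with pytest.raises(ValueError, match="empty"):
        circular_summary(CircularSample(np.array([])))
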