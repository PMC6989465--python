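import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gma.features import FeatureSeries
from gma.indices import (
    INDEX_NAMES,
    SpectralConfig,
    balance_ratio,
    centre_magnitude,
    compute_index_vector,
    compute_indices,
    movement_count,
    movement_frequency,
    movement_strength,
    rhythm_indices,
    spectral_centre,
    spectral_spread,
    symmetry,
)

from _oracles import i1_loop, i2_loop, i3_loop, i6_loop, magnitude_loop

SMALL_CFG = SpectralConfig(fft_window=64, fft_overlap=63, corr_window=60,
                           corr_overlap=59, subinterval=150)


class TestMagnitudeIndices:
    def test_movement_frequency_extremes(self):
        assert movement_frequency(np.zeros(100), 0.05) == 0.0
        assert movement_frequency(np.full(100, 0.2), 0.05) == 100.0

    def test_movement_frequency_count(self):
        m = np.zeros(900)
        m[:45] = 0.1
        assert movement_frequency(m, 0.05) == pytest.approx(5.0)

    def test_movement_strength(self):
        m = np.zeros(900)
        m[100:110] = 0.2
        assert movement_strength(m, 0.05) == pytest.approx(0.2)
        assert movement_strength(np.zeros(100), 0.05) == 0.0
        assert movement_strength(np.full(50, 0.3), 0.05) == pytest.approx(0.3)

    def test_movement_count_episodes(self):
        m = np.zeros(900)
        for start in (100, 300, 500):  # three separated bursts
            m[start : start + 20] = 0.1
        assert movement_count(m, 0.05) == pytest.approx(3 / 900)
        assert movement_count(np.zeros(900), 0.05) == 0.0

    def test_episode_active_at_end_counted_once(self):
        m = np.zeros(100)
        m[90:] = 0.2
        assert movement_count(m, 0.05) == pytest.approx(1 / 100)

    def test_against_run_length_scan(self, rng):
        for _ in range(20):
            m = rng.random(200) * 0.1
            assert movement_frequency(m, 0.05) == pytest.approx(i1_loop(m, 0.05))
            assert movement_strength(m, 0.05) == pytest.approx(i2_loop(m, 0.05))
            assert movement_count(m, 0.05) == pytest.approx(i3_loop(m, 0.05))

    def test_doubling_m_doubles_strength(self, rng):
        m = rng.random(300) * 0.2
        assert movement_strength(2 * m, 0.1) == pytest.approx(
            2 * movement_strength(m, 0.05)
        )


class TestBalance:
    def test_equal_activity_gives_unity(self):
        assert balance_ratio(10.0, 10.0) == 1.0

    def test_zero_denominator_convention(self):
        assert balance_ratio(10.0, 0.0) == 0.0

    def test_ratio_arithmetic(self):
        assert balance_ratio(10.0, 4.0) == pytest.approx(2.5)

    def test_symmetry_identical_series(self, rng):
        m = rng.random(400)
        assert symmetry(m, m, 300, 299) == pytest.approx(1.0)

    def test_symmetry_negated_series(self, rng):
        m = rng.random(400)
        assert symmetry(m, 1.0 - m, 300, 299) == pytest.approx(-1.0)

    def test_independent_noise_decorrelated(self):
        r = np.random.default_rng(7)
        m1, m2 = r.random(900), r.random(900)
        assert abs(symmetry(m1, m2, 300, 299)) < 0.1

    def test_matches_window_loop(self, rng):
        m1 = rng.random(150)
        m2 = rng.random(150)
        assert symmetry(m1, m2, 60, 59) == pytest.approx(i6_loop(m1, m2, 60, 59))

    def test_constant_series_skips_all_windows(self):
        assert symmetry(np.ones(100), np.ones(100), 60, 59) == 0.0


class TestSpectralMoments:
    def test_delta_spectrum(self):
        f = np.array([0.0, 1.0, 2.0, 3.0])
        p = np.array([0.0, 0.0, 1.0, 0.0])
        assert spectral_centre(f, p, 5.0) == 2.0
        assert spectral_spread(f, p, 5.0) == 0.0

    def test_two_equal_lines(self):
        f = np.array([0.0, 1.0, 2.0, 3.0, 4.0])
        p = np.array([0.0, 1.0, 0.0, 1.0, 0.0])
        assert spectral_centre(f, p, 5.0) == pytest.approx(2.0)
        assert spectral_spread(f, p, 5.0) == pytest.approx(1.0)

    def test_flat_spectrum_uniform_moments(self):
        f = np.linspace(0, 5, 2001)
        p = np.ones_like(f)
        assert spectral_centre(f, p, 5.0) == pytest.approx(2.5, rel=1e-6)
        assert spectral_spread(f, p, 5.0) == pytest.approx(5 / np.sqrt(12), rel=0.01)

    def test_band_limit_excludes_high_lines(self):
        f = np.array([1.0, 7.0])
        p = np.array([1.0, 1.0])
        assert spectral_centre(f, p, 5.0) == 1.0

    def test_zero_spectrum_flagged(self):
        with pytest.raises(ValueError, match="all-zero"):
            spectral_centre(np.arange(4.0), np.zeros(4), 5.0)


class TestRhythm:
    def test_sinusoid_centre_recovered(self):
        t = np.arange(900) / 30.0
        m = 0.5 + 0.3 * np.sin(2 * np.pi * 1.5 * t)
        c, s = rhythm_indices(m, 30.0, SpectralConfig())
        assert c == pytest.approx(1.5, abs=0.2)
        assert s > 0

    def test_bandlimited_noise_centre_near_midband(self):
        r = np.random.default_rng(5)
        x = r.standard_normal(900)
        c, _ = rhythm_indices(x, 10.0, SpectralConfig())  # white up to 5 Hz
        assert c == pytest.approx(2.5, abs=0.35)

    def test_constant_signal_degenerate(self):
        c, s = rhythm_indices(np.full(900, 2.0), 30.0, SpectralConfig())
        assert (c, s) == (0.0, 0.0)

    def test_interval_not_divisible_rejected(self):
        with pytest.raises(ValueError, match="multiple"):
            rhythm_indices(np.zeros(700), 30.0, SpectralConfig(subinterval=300))

    def test_sd_spread_mode(self):
        t = np.arange(900) / 30.0
        m = np.sin(2 * np.pi * 2.0 * t)
        _, s = rhythm_indices(m, 30.0, SpectralConfig(spread_mode="sd"))
        assert s < 0.1  # same tone in every subinterval


class TestCentreMagnitude:
    def test_zero_signal(self):
        assert centre_magnitude(np.zeros(10)) == 0.0

    def test_constant_velocity(self):
        assert centre_magnitude(np.full(10, 0.1)) == pytest.approx(0.1)

    def test_alternating_magnitude(self):
        x = np.tile([1.0, -1.0], 50)
        assert centre_magnitude(x) == pytest.approx(1.0)
        assert centre_magnitude(x, signed=True) == pytest.approx(0.0)

    def test_matches_loop(self, rng):
        x = rng.standard_normal(100)
        assert centre_magnitude(x) == pytest.approx(magnitude_loop(x))


class TestIndexVector:
    def _features(self, n, rng=None, f_s=30.0):
        if rng is None:
            m = {k: np.zeros(n) for k in range(1, 10)}
            g = np.tile([50.0, 60.0], (n, 1))
        else:
            m = {k: rng.random(n) * 0.1 for k in range(1, 10)}
            g = 50 + rng.random((n, 2))
        p = {k: np.full(n, 100.0) for k in range(1, 10)}
        gv = np.zeros((n, 2))
        return FeatureSeries(P=p, M=m, G=g, Gv=gv, p_ave=400.0, f_s=f_s,
                             missing_centre_frames=[])

    def test_vector_has_25_canonical_entries(self, rng):
        m = rng.random(300) * 0.1
        v = compute_index_vector(m, m, np.zeros((300, 2)), np.zeros((300, 2)),
                                 30.0, SpectralConfig(subinterval=150))
        assert len(v.values) == 25
        assert tuple(v.as_dict()) == INDEX_NAMES

    def test_static_interval_all_zero_magnitudes(self):
        f = self._features(300)
        vecs = compute_indices(f, interval_length=300,
                               cfg=SpectralConfig(subinterval=150))
        v = vecs[0]
        for name in ("I1_A5", "I2_A5", "I3_A5", "I1_A6", "I13_x", "I13_y",
                     "I14_x", "I14_y", "I7_A5", "I7_A6"):
            assert v[name] == 0.0

    def test_sliding_mode_window_count(self, rng):
        f = self._features(302, rng)
        vecs = compute_indices(f, interval_length=300, step=1,
                               cfg=SpectralConfig(subinterval=150))
        assert len(vecs) == 3
        assert [v.start_frame for v in vecs] == [0, 1, 2]

    def test_short_recording_yields_nothing(self, rng):
        f = self._features(100, rng)
        assert compute_indices(f, interval_length=300) == []

    @settings(deadline=None, derandomize=True, max_examples=15)
    @given(seed=st.integers(0, 10_000))
    def test_index_bounds_hold_on_random_input(self, seed):
        r = np.random.default_rng(seed)
        n = 300
        m5 = np.abs(r.standard_normal(n)) * 0.1
        m6 = np.abs(r.standard_normal(n)) * 0.1
        gv = r.standard_normal((n, 2)) * 0.05
        gd = r.standard_normal((n, 2)) * 0.05
        v = compute_index_vector(m5, m6, gv, gd, 30.0,
                                 SpectralConfig(subinterval=150))
        d = v.as_dict()
        assert 0 <= d["I1_A5"] <= 100 and 0 <= d["I1_A6"] <= 100
        assert -1 <= d["I6_56"] <= 1
        for name in ("I7_A5", "I7_A6", "I9_x", "I9_y", "I11_x", "I11_y"):
            assert 0 <= d[name] <= 5.0
        assert d["I2_A5"] >= 0 and d["I3_A5"] >= 0
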