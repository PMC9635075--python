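"""Per-movement feature operations against analytic and brute-force oracles."""

import numpy as np
import pytest
import pywt
from scipy import signal, stats

from limbacc.features.movement import (
    axis_correlation_features,
    frequency_features,
    gravity_change_features,
    inclination_features,
    median_crossing_features,
    movement_timing_features,
    recent_movement_features,
    stat_features,
    velocity_distance_features,
    wavelet_features,
)
from limbacc.types import MovementEvent

FS = 30.0


class TestStatFeatures:
    def test_constant_segment(self):
        out = stat_features(np.full(20, 0.7))
        assert out["stat.sd"] == 0.0 and out["stat.range"] == 0.0
        assert np.isnan(out["stat.skewness"]) and np.isnan(out["stat.kurtosis"])

    def test_symmetric_segment_has_zero_skewness(self, rng):
        half = rng.normal(size=50)
        x = np.concatenate([half, -half])  # exactly mirror-symmetric
        assert stat_features(x)["stat.skewness"] == pytest.approx(0.0, abs=1e-10)

    def test_matches_scipy_moments(self, rng):
        x = rng.lognormal(size=80)
        out = stat_features(x)
        assert out["stat.mean"] == pytest.approx(np.mean(x))
        assert out["stat.sd"] == pytest.approx(np.std(x, ddof=1))
        assert out["stat.rms"] == pytest.approx(np.sqrt(np.mean(x**2)))
        assert out["stat.skewness"] == pytest.approx(stats.skew(x, bias=False), abs=1e-12)
        assert out["stat.kurtosis"] == pytest.approx(
            stats.kurtosis(x, fisher=True, bias=False), abs=1e-12
        )


class TestFrequencyFeatures:
    def test_pure_tone_dominant_frequency(self):
        t = np.arange(int(10 * FS)) / FS
        out = frequency_features(np.sin(2 * np.pi * 2.0 * t), FS)
        assert out["freq.dom_freq_1"] == pytest.approx(2.0, abs=0.5)

    def test_two_tone_peak_ordering(self):
        t = np.arange(int(20 * FS)) / FS
        x = np.sin(2 * np.pi * 2.0 * t) + 0.5 * np.sin(2 * np.pi * 5.0 * t)
        out = frequency_features(x, FS)
        assert out["freq.dom_freq_1"] == pytest.approx(2.0, abs=0.5)
        assert out["freq.dom_freq_2"] == pytest.approx(5.0, abs=0.5)
        assert out["freq.power_dom_1"] > out["freq.power_dom_2"]

    def test_matches_scipy_welch_oracle(self, rng):
        x = rng.normal(size=90)
        freqs, psd = signal.welch(x, fs=FS, nperseg=60, detrend="constant")
        out = frequency_features(x, FS)
        assert out["freq.dom_freq_1"] == pytest.approx(freqs[1:][np.argmax(psd[1:])])
        assert out["freq.total_power"] == pytest.approx(np.sum(psd[1:]), rel=1e-10)
        assert out["freq.mean_freq"] == pytest.approx(
            np.sum(freqs[1:] * psd[1:]) / np.sum(psd[1:]), rel=1e-10
        )

    def test_bounds(self, rng):
        for _ in range(10):
            out = frequency_features(rng.normal(size=rng.integers(10, 200)), FS)
            assert 0 < out["freq.power_dom1_over_total"] <= 1
            assert 0 < out["freq.dom_freq_1"] <= FS / 2
            assert out["freq.med_freq"] <= out["freq.spectral_edge_95"]

    def test_all_zero_segment_is_missing(self):
        out = frequency_features(np.zeros(60), FS)
        assert all(np.isnan(v) for v in out.values())


def brute_force_dwt_energies(x, wavelet="db4", levels=3):
    """Manual periodized convolution/decimation filter bank."""
    w = pywt.Wavelet(wavelet)
    lo, hi = np.array(w.dec_lo), np.array(w.dec_hi)

    def periodized_step(a, f):
        # circular convolution + dyadic decimation; the phase offset of half
        # the filter length selects the standard periodized DWT alignment
        n = len(a)
        if n % 2:
            a = np.concatenate([a, a[-1:]])
            n += 1
        off = len(f) // 2
        out = []
        for k in range(n // 2):
            acc = 0.0
            for m, fm in enumerate(f):
                acc += fm * a[(2 * k + off - m) % n]
            out.append(acc)
        return np.array(out)

    energies = []
    a = np.asarray(x, dtype=float)
    for _ in range(levels):
        d = periodized_step(a, hi)
        a = periodized_step(a, lo)
        energies.append(np.sum(d**2))
    return np.sum(a**2), energies  # approx, [d1, d2, d3]


class TestWaveletFeatures:
    def test_constant_segment(self):
        out = wavelet_features(np.full(32, 1.0))
        assert out["sc.wave_energy_1"] == pytest.approx(0.0, abs=1e-20)
        assert out["sc.wave_energy_2"] == pytest.approx(0.0, abs=1e-20)
        assert out["sc.wave_entropy"] == pytest.approx(0.0, abs=1e-12)

    def test_parseval_energy_conservation(self, rng):
        x = rng.normal(size=64)
        out = wavelet_features(x)
        total = (
            out["sc.wave_approx"]
            + out["sc.wave_energy_1"]
            + out["sc.wave_energy_2"]
            + out["sc.wave_energy_3"]
        )
        assert total == pytest.approx(np.sum(x**2), rel=1e-8)

    def test_matches_brute_force_filter_bank(self, rng):
        x = rng.normal(size=64)
        approx, (d1, d2, d3) = brute_force_dwt_energies(x)
        out = wavelet_features(x)
        assert out["sc.wave_approx"] == pytest.approx(approx, rel=1e-8)
        assert out["sc.wave_energy_1"] == pytest.approx(d1, rel=1e-8)
        assert out["sc.wave_energy_2"] == pytest.approx(d2, rel=1e-8)
        assert out["sc.wave_energy_3"] == pytest.approx(d3, rel=1e-8)

    def test_entropy_is_shannon_of_band_distribution(self, rng):
        x = rng.normal(size=128)
        out = wavelet_features(x)
        bands = np.array(
            [out["sc.wave_approx"], out["sc.wave_energy_3"], out["sc.wave_energy_2"], out["sc.wave_energy_1"]]
        )
        p = bands / bands.sum()
        assert out["sc.wave_entropy"] == pytest.approx(-np.sum(p * np.log(p)), rel=1e-10)


class TestAxisCorrelation:
    def test_identical_axes(self, rng):
        x = rng.normal(size=40)
        axes = np.column_stack([x, x, rng.normal(size=40)])
        assert axis_correlation_features(axes)["cc.corr_xy"] == pytest.approx(1.0)

    def test_anti_correlated_axes(self, rng):
        x = rng.normal(size=40)
        axes = np.column_stack([x, -x, rng.normal(size=40)])
        assert axis_correlation_features(axes)["cc.corr_xy"] == pytest.approx(-1.0)

    def test_quadrature_tones_uncorrelated(self):
        t = np.arange(300) / FS  # integer number of 1-Hz periods
        axes = np.column_stack([np.sin(2 * np.pi * t), np.cos(2 * np.pi * t), t * 0 + 1])
        out = axis_correlation_features(axes)
        assert out["cc.corr_xy"] == pytest.approx(0.0, abs=1e-10)
        assert np.isnan(out["cc.corr_xz"])  # z axis constant


class TestOrientationFeatures:
    def test_static_orientation(self):
        g = np.tile([0.0, 0.0, 1.0], (60, 1))
        out = inclination_features(g, FS)
        assert out["ang.incl_angle_change"] == 0.0
        assert out["ang.angle_rate_change"] == 0.0
        cga = gravity_change_features(g)
        assert all(v == 0.0 for v in cga.values())

    def test_quarter_turn_in_one_second(self):
        n = int(FS)
        theta = np.linspace(0, np.pi / 2, n)
        g = np.column_stack([np.sin(theta), np.zeros(n), np.cos(theta)])
        out = inclination_features(g, FS)
        assert out["ang.incl_angle_change"] == pytest.approx(90.0, abs=2.0)
        assert out["ang.angle_rate_change"] == pytest.approx(90.0, abs=5.0)
        assert out["ang.roll_flag"] == 1.0
        cga = gravity_change_features(g)
        assert cga["cga.grav_change_x"] == pytest.approx(1.0, abs=0.02)
        assert cga["cga.grav_change_z"] == pytest.approx(1.0, abs=0.02)
        assert cga["cga.grav_change_y"] == pytest.approx(0.0, abs=1e-9)

    def test_random_rotation_matches_endpoint_arithmetic(self, rng):
        n = 90
        theta = np.cumsum(rng.uniform(0, 0.02, size=n))
        phi = rng.uniform(0, 2 * np.pi)
        g = np.column_stack(
            [np.sin(theta) * np.cos(phi), np.sin(theta) * np.sin(phi), np.cos(theta)]
        )
        out = inclination_features(g, FS)
        angles = np.degrees(np.arccos(g[:, 2] / np.linalg.norm(g, axis=1)))
        assert out["ang.incl_angle_change"] == pytest.approx(abs(angles[-1] - angles[0]), abs=1e-9)
        cga = gravity_change_features(g)
        assert cga["cga.grav_change_y"] == pytest.approx(abs(g[-1, 1] - g[0, 1]), abs=1e-12)

    def test_freefall_is_missing(self):
        g = np.full((60, 3), 0.05)
        assert all(np.isnan(v) for v in inclination_features(g, FS).values())


class TestMedianCrossings:
    def test_constant(self):
        out = median_crossing_features(np.ones(20), 20 / FS)
        assert out["mc.num_med_crossings"] == 0.0

    def test_three_period_sine(self):
        t = np.arange(int(3 * FS)) / FS
        x = np.sin(2 * np.pi * 1.0 * t)  # 3 full periods
        out = median_crossing_features(x, 3.0)
        assert out["mc.num_med_crossings"] in (5.0, 6.0)
        assert out["mc.num_med_crossings_norm"] == pytest.approx(
            out["mc.num_med_crossings"] / 3.0
        )

    def test_matches_brute_force(self, rng):
        x = rng.normal(size=70)
        out = median_crossing_features(x, 70 / FS)
        s = np.sign(x - np.median(x))
        s = s[s != 0]
        brute = sum(1 for a, b in zip(s, s[1:]) if a != b)
        assert out["mc.num_med_crossings"] == brute


class TestVelocityDistance:
    def test_zero_acceleration(self):
        out = velocity_distance_features(np.zeros((60, 3)), FS)
        assert all(v == 0.0 for v in out.values())

    def test_constant_acceleration_analytic(self):
        n = int(FS) + 1
        axes = np.zeros((n, 3))
        axes[:, 0] = 1.0 / 9.80665  # exactly 1 m/s^2 for 1 s
        out = velocity_distance_features(axes, FS, detrend=False)
        assert out["vd.peak_velocity"] == pytest.approx(1.0, rel=0.02)
        assert out["vd.mean_velocity"] == pytest.approx(0.5, rel=0.02)

    def test_matches_trapezoid_oracle(self, rng):
        axes = rng.normal(0, 0.1, size=(90, 3))
        out = velocity_distance_features(axes, FS, detrend=False)
        a = axes * 9.80665
        dt = 1 / FS
        v = np.zeros_like(a)
        for i in range(1, len(a)):
            v[i] = v[i - 1] + 0.5 * (a[i] + a[i - 1]) * dt
        speed = np.linalg.norm(v, axis=1)
        assert out["vd.peak_velocity"] == pytest.approx(speed.max(), rel=1e-9)
        assert out["vd.path_length"] == pytest.approx(np.trapezoid(speed, dx=dt), rel=1e-9)


class TestTimingAndRecentMovements:
    def _event(self, start, end, vm=None, prev_index=None):
        vm = vm if vm is not None else np.ones(end - start)
        return MovementEvent(
            limbs={"left_ankle"},
            start_idx=start,
            end_idx=end,
            sampling_rate_hz=FS,
            vm=vm,
            axes=np.zeros((end - start, 3)),
            prev_index=prev_index,
        )

    def test_duration_and_onset(self):
        e = self._event(300, 450)
        out = movement_timing_features(e, (0, int(3600 * FS)))
        assert out["time.duration_s"] == pytest.approx(5.0)
        e0 = self._event(0, 30)
        assert movement_timing_features(e0, (0, 10000))["time.onset_hours"] == 0.0

    def test_night_fraction_brute_force(self, rng):
        s0, s1 = 1000, 100000
        start = int(rng.integers(s0, s1 - 100))
        e = self._event(start, start + 60)
        out = movement_timing_features(e, (s0, s1))
        assert out["time.night_fraction"] == pytest.approx((start - s0) / (s1 - s0))

    def test_identical_consecutive_movements(self, rng):
        wave = rng.normal(size=60) ** 2 + 0.1
        prev = self._event(1000, 1060, vm=wave.copy())
        cur = self._event(4000, 4060, vm=wave.copy(), prev_index=0)
        vm_trace = np.zeros(10000)
        out = recent_movement_features(cur, prev, [prev, cur], vm_trace, (0, 10000))
        assert out["rrm.max_cross_corr"] == pytest.approx(1.0, abs=1e-9)
        assert out["rrm.close_cross_corr_peak"] == pytest.approx(0.0, abs=1e-9)
        assert out["rrm.time_since_prev"] == pytest.approx((4000 - 1060) / FS)
        assert out["rrm.corr_with_prev"] == pytest.approx(1.0, abs=1e-9)

    def test_solitary_movement_has_no_follower(self):
        cur = self._event(4000, 4060)
        out = recent_movement_features(cur, None, [cur], np.zeros(10000), (0, 10000))
        assert out["rrm.move_next_90s"] == 0.0
        assert np.isnan(out["rrm.time_since_prev"])
        assert np.isnan(out["rrm.max_cross_corr"])

    def test_follower_within_90s_is_flagged(self):
        cur = self._event(1000, 1060)
        nxt = self._event(1060 + int(30 * FS), 1060 + int(30 * FS) + 30)
        out = recent_movement_features(cur, None, [cur, nxt], np.zeros(100000), (0, 100000))
        assert out["rrm.move_next_90s"] == 1.0

    def test_constructed_lag_offset_recovered(self, rng):
        base = np.zeros(90)
        base[30:45] = signal.windows.hann(15)
        shifted = np.roll(base, 12)  # same waveform, 12-sample internal lag
        prev = self._event(1000, 1090, vm=base)
        cur = self._event(3000, 3090, vm=shifted, prev_index=0)
        out = recent_movement_features(cur, prev, [prev, cur], np.zeros(10000), (0, 10000))
        assert out["rrm.close_cross_corr_peak"] == pytest.approx(12 / FS, abs=1.5 / FS)
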