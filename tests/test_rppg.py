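"""GREEN-method signal chain: detrending, resampling, windowing,
normalisation, spectrum and end-to-end rate recovery."""
import numpy as np
import pytest

from pulsecam import SignalBuffer
from pulsecam.errors import SignalError
from pulsecam.roi import GreenSample
from pulsecam.rppg import (
    RPPGConfig,
    Trace,
    amplitude_spectrum,
    apply_hamming,
    detrend,
    detrend_moving_average,
    estimate_vitals_rppg,
    interpolate_uniform,
    l2_normalize,
)

FS = 30.0
N = 180


def dense_smoothness_priors_oracle(z, lam):
    """Independent dense-matrix solve of the smoothness-priors system."""
    n = z.size
    d2 = np.zeros((n - 2, n))
    for i in range(n - 2):
        d2[i, i : i + 3] = (1.0, -2.0, 1.0)
    trend = np.linalg.solve(np.eye(n) + lam * lam * d2.T @ d2, z)
    return z - trend


class TestDetrend:
    def test_constant_maps_to_zero(self):
        out = detrend(np.full(N, 42.0), lam=10.0)
        assert np.max(np.abs(out)) < 1e-9

    def test_matches_dense_oracle_on_random_input(self, rng):
        z = rng.normal(size=N)
        assert np.max(np.abs(detrend(z, 10.0) - dense_smoothness_priors_oracle(z, 10.0))) < 1e-6

    def test_linear_ramp_removed(self):
        ramp = np.arange(N, dtype=float)
        out = detrend(ramp, lam=10.0)
        assert np.max(np.abs(out)) < 0.01 * (ramp.max() - ramp.min())

    def test_ramp_plus_sinusoid_keeps_sinusoid(self):
        t = np.arange(N) / FS
        sine = np.sin(2 * np.pi * 1.2 * t)
        out = detrend(5.0 * t + sine)
        r = np.corrcoef(out, sine)[0, 1]
        assert r > 0.99

    def test_too_short_rejected(self):
        with pytest.raises(SignalError):
            detrend(np.array([1.0, 2.0]))

    def test_moving_average_fallback_removes_offset(self):
        t = np.arange(N) / FS
        sig = 100.0 + np.sin(2 * np.pi * 1.5 * t)
        out = detrend_moving_average(sig)
        assert abs(out.mean()) < 0.2


class TestInterpolateUniform:
    def test_uniform_timestamps_identity(self, rng):
        v = rng.normal(size=N)
        tr = Trace(values=v, timestamps_s=np.arange(N) / FS, fs=FS)
        out = interpolate_uniform(tr)
        assert np.array_equal(out.values, v)

    def test_linear_interpolation_example(self):
        tr = Trace(values=np.array([0.0, 1.0, 3.0]),
                   timestamps_s=np.array([0.0, 1.0, 3.0]), fs=1.0)
        out = interpolate_uniform(tr)
        # uniform grid over [0, 3] with 3 samples: t = 0, 1.5, 3
        assert np.allclose(out.timestamps_s, [0.0, 1.5, 3.0])
        assert out.values[1] == pytest.approx(1.5)

    def test_duplicate_timestamps_rejected(self):
        tr = Trace(values=np.zeros(3), timestamps_s=np.array([0.0, 0.0, 1.0]), fs=FS)
        with pytest.raises(SignalError):
            interpolate_uniform(tr)

    def test_jittered_sinusoid_recovers_true_peak(self, rng):
        f0 = 1.5  # exactly bin 9 of n=180 at 30 fps
        t = np.arange(N) / FS + rng.uniform(-0.008, 0.008, size=N)
        t = np.sort(t)
        tr = Trace(values=np.sin(2 * np.pi * f0 * t), timestamps_s=t, fs=FS)
        out = interpolate_uniform(tr)
        spec = amplitude_spectrum(out.values, out.fs)
        assert spec.freqs[np.argmax(spec.amps[1:]) + 1] == pytest.approx(f0, abs=FS / N)


class TestHammingAndNorm:
    def test_hamming_endpoints_and_midpoint(self):
        n = 181  # odd: midpoint exists
        out = apply_hamming(np.ones(n))
        assert out[0] == pytest.approx(0.08)
        assert out[-1] == pytest.approx(0.08)
        assert out[n // 2] == pytest.approx(1.0)

    def test_all_ones_input_yields_window(self):
        out = apply_hamming(np.ones(64))
        k = np.arange(64)
        assert np.allclose(out, 0.54 - 0.46 * np.cos(2 * np.pi * k / 63))

    def test_l2_example_and_norm(self, rng):
        assert np.allclose(l2_normalize(np.array([3.0, 4.0])), [0.6, 0.8])
        v = rng.normal(size=50)
        assert np.linalg.norm(l2_normalize(v)) == pytest.approx(1.0, abs=1e-9)
        assert np.allclose(l2_normalize(v), l2_normalize(7.0 * v))

    def test_zero_vector_rejected(self):
        with pytest.raises(SignalError):
            l2_normalize(np.zeros(10))


class TestAmplitudeSpectrum:
    def test_pure_cosine_at_bin_8(self):
        k0 = 8
        t = np.arange(N)
        sig = np.cos(2 * np.pi * k0 * t / N)
        spec = amplitude_spectrum(sig, FS)
        assert np.argmax(spec.amps) == k0
        assert spec.amps[k0] == pytest.approx(1.0)

    def test_constant_energy_at_dc(self):
        spec = amplitude_spectrum(np.full(N, 3.0), FS)
        assert np.argmax(spec.amps) == 0
        assert spec.amps[1:].max() < 1e-12

    def test_parseval_identity(self, rng):
        for n in (180, 181):  # even and odd windows
            x = rng.normal(size=n)
            spec = amplitude_spectrum(x, FS)
            a = spec.amps.copy()
            energy = a[0] ** 2 + np.sum((a[1:-1] / 2) ** 2) * 2 + (
                a[-1] ** 2 if n % 2 == 0 else (a[-1] / 2) ** 2 * 2
            )
            assert np.sum(x ** 2) == pytest.approx(n * energy, rel=1e-9)


def _buffer_from_trace(values, fs=FS):
    buf = SignalBuffer(capacity=len(values), fs=fs)
    for i, v in enumerate(values):
        buf.push(GreenSample(value=float(v), frame_index=i, timestamp_s=i / fs))
    return buf


def _synthetic_green(hr_hz=1.2, rr_hz=0.25, hr_amp=2.0, rr_add=1.0,
                     noise=0.0, seed=0, n=N, fs=FS):
    t = np.arange(n) / fs
    rng = np.random.default_rng(seed)
    g = 120.0 + hr_amp * np.sin(2 * np.pi * hr_hz * t) + rr_add * np.sin(
        2 * np.pi * rr_hz * t
    )
    if noise:
        g = g + rng.normal(0, noise, size=n)
    return np.clip(g, 0, 255)


class TestEstimateVitals:
    def test_noiseless_recovery_at_nearest_bins(self):
        est = estimate_vitals_rppg(_buffer_from_trace(_synthetic_green()))
        freqs = np.fft.rfftfreq(N, d=1.0 / FS)
        hr_bins = freqs[(freqs >= 0.83) & (freqs <= 3.0)]
        rr_bins = freqs[(freqs >= 0.18) & (freqs <= 0.5)]
        assert est.hr_peak_hz == pytest.approx(hr_bins[np.argmin(np.abs(hr_bins - 1.2))])
        assert est.rr_peak_hz == pytest.approx(rr_bins[np.argmin(np.abs(rr_bins - 0.25))])
        assert est.hr_bpm == pytest.approx(60 * est.hr_peak_hz)

    def test_deterministic_given_seed(self):
        a = estimate_vitals_rppg(_buffer_from_trace(_synthetic_green(noise=1.0, seed=5)))
        b = estimate_vitals_rppg(_buffer_from_trace(_synthetic_green(noise=1.0, seed=5)))
        assert (a.hr_bpm, a.rr_bpm) == (b.hr_bpm, b.rr_bpm)

    def test_affine_invariance_of_estimates(self):
        g = _synthetic_green(noise=0.5, seed=2)
        a = estimate_vitals_rppg(_buffer_from_trace(g))
        # gain and offset are removed by detrending + L2 normalisation
        b = estimate_vitals_rppg(_buffer_from_trace(2.0 * g - 170.0))
        c = estimate_vitals_rppg(_buffer_from_trace(0.3 * g + 50.0))
        assert a.hr_peak_hz == b.hr_peak_hz == c.hr_peak_hz
        assert a.rr_peak_hz == b.rr_peak_hz == c.rr_peak_hz

    def test_band_argmax_contract_without_rr_energy(self):
        # pure cardiac tone: the RR estimate is still the in-band argmax
        est = estimate_vitals_rppg(_buffer_from_trace(_synthetic_green(rr_add=0.0)))
        assert 11.0 <= est.rr_bpm <= 30.0

    def test_not_ready_buffer_rejected(self):
        buf = SignalBuffer(capacity=180, fs=FS)
        buf.push(GreenSample(value=1.0, frame_index=0, timestamp_s=0.0))
        with pytest.raises(SignalError):
            estimate_vitals_rppg(buf)

    def test_recovery_rate_over_random_seeds(self):
        """HR snapped to FFT bins, SNR >= 3: >= 95% exact-bin recovery."""
        rng = np.random.default_rng(99)
        freqs = np.fft.rfftfreq(N, d=1.0 / FS)
        candidate_bins = freqs[(freqs >= 50 / 60) & (freqs <= 170 / 60)]
        hits = 0
        n_runs = 50
        for seed in range(n_runs):
            f0 = rng.choice(candidate_bins)
            g = _synthetic_green(hr_hz=f0, noise=2.0 / 3.0, seed=seed)  # SNR = 3
            est = estimate_vitals_rppg(_buffer_from_trace(g))
            if est.hr_peak_hz == pytest.approx(f0, abs=1e-9):
                hits += 1
        assert hits / n_runs >= 0.95
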