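"""Eulerian magnification: pyramid identities, ideal temporal filtering
and spectral rate estimation from ROI stacks."""
import numpy as np
import pytest

from pulsecam import Band, HR_BAND, RR_BAND, SignalBuffer
from pulsecam.errors import BandError, SignalError
from pulsecam.evm import (
    EVMConfig,
    EVMEngine,
    amplify_and_reconstruct,
    collapse,
    estimate_vitals_evm,
    gaussian_pyramid,
    laplacian_pyramid,
    temporal_bandpass,
    upsample_to,
)
from pulsecam.roi import RoiImageEVM

FS = 30.0


class TestGaussianPyramid:
    def test_level_sizes_ceil_halving(self):
        pyr = gaussian_pyramid(np.zeros((180, 180)), levels=3)
        assert [lv.shape[0] for lv in pyr.levels] == [180, 90, 45, 23]

    def test_constant_image_stays_constant(self):
        pyr = gaussian_pyramid(np.full((64, 64), 7.5), levels=3)
        for lv in pyr.levels:
            assert np.allclose(lv, 7.5, atol=1e-12)

    def test_zero_levels_is_input(self, rng):
        img = rng.random((32, 32))
        pyr = gaussian_pyramid(img, levels=0)
        assert len(pyr.levels) == 1 and np.array_equal(pyr.levels[0], img)

    def test_too_small_image_rejected(self):
        with pytest.raises(SignalError):
            gaussian_pyramid(np.zeros((4, 4)), levels=3)


class TestLaplacianPyramid:
    @pytest.mark.parametrize("levels", [1, 2, 3])
    def test_collapse_identity(self, rng, levels):
        img = rng.random((45, 45)) * 255
        rec = collapse(laplacian_pyramid(img, levels))
        assert np.max(np.abs(rec - img)) < 1e-6

    def test_collapse_identity_color(self, rng):
        img = rng.random((36, 36, 3)) * 255
        rec = collapse(laplacian_pyramid(img, 3))
        assert np.max(np.abs(rec - img)) < 1e-6

    def test_constant_image_bandpass_levels_zero(self):
        pyr = laplacian_pyramid(np.full((64, 64), 50.0), levels=3)
        for lv in pyr.levels[:-1]:
            assert np.max(np.abs(lv)) < 1e-9
        assert np.allclose(pyr.levels[-1], 50.0)

    def test_delta_energy_concentrates_at_level_zero(self):
        img = np.zeros((64, 64))
        img[32, 32] = 255.0
        pyr = laplacian_pyramid(img, levels=3)
        energies = [float(np.sum(lv ** 2)) for lv in pyr.levels]
        assert energies[0] == max(energies)
        assert energies[0] > sum(energies[1:])

    def test_top_level_equals_gaussian_top(self, rng):
        img = rng.random((40, 40))
        lap = laplacian_pyramid(img, 2)
        gauss = gaussian_pyramid(img, 2)
        assert np.array_equal(lap.levels[-1], gauss.levels[-1])


class TestTemporalBandpass:
    def _stack(self, freq, n=60, shape=(8, 8), fs=FS):
        t = np.arange(n) / fs
        wave = np.sin(2 * np.pi * freq * t)
        return np.tile(wave[:, None, None], (1,) + shape)

    def test_in_band_sinusoid_passes_unchanged(self):
        stack = self._stack(1.5)  # exactly a bin of n=60 @ 30 fps (0.5 Hz bins)
        out = temporal_bandpass(stack, HR_BAND, FS)
        assert np.max(np.abs(out - stack)) < 1e-6

    def test_constant_stack_maps_to_zero(self):
        stack = np.full((60, 8, 8), 80.0)
        for band in (HR_BAND, RR_BAND):
            assert np.max(np.abs(temporal_bandpass(stack, band, FS))) < 1e-9

    def test_band_separation_of_mixture(self):
        in_band = self._stack(1.5)
        out_band = self._stack(5.0)
        filtered = temporal_bandpass(in_band + out_band + 40.0, HR_BAND, FS)
        assert np.max(np.abs(filtered - in_band)) < 1e-6

    def test_idempotence(self, rng):
        stack = rng.normal(size=(60, 6, 6))
        once = temporal_bandpass(stack, HR_BAND, FS)
        twice = temporal_bandpass(once, HR_BAND, FS)
        assert np.max(np.abs(twice - once)) < 1e-9

    def test_unresolvable_band_raises(self):
        with pytest.raises(BandError):
            temporal_bandpass(np.zeros((4, 4, 4)), RR_BAND, fs=30.0)  # 7.5 Hz bins


class TestAmplifyReconstruct:
    def test_zero_alpha_returns_frame(self, rng):
        img = rng.random((45, 45)) * 200
        filtered = laplacian_pyramid(rng.random((45, 45)), 2)
        assert np.allclose(amplify_and_reconstruct(img, filtered, 0.0), img)

    def test_zero_pyramid_returns_frame(self, rng):
        img = rng.random((45, 45)) * 200
        zero = laplacian_pyramid(np.zeros((45, 45)), 2)
        assert np.max(np.abs(amplify_and_reconstruct(img, zero, 50.0) - img)) < 1e-9

    def test_level0_offset_adds_through(self, rng):
        img = rng.random((64, 64)) * 100 + 50
        pyr = laplacian_pyramid(np.zeros((64, 64)), 2)
        pyr.levels[0] = np.full((64, 64), 5.0)
        out = amplify_and_reconstruct(img, pyr, 1.0)
        # away from the upsample border the delta is exactly +5
        assert np.max(np.abs(out - (img + 5.0))[4:-4, 4:-4]) < 1e-9

    def test_output_clipped_to_intensity_range(self):
        img = np.full((32, 32), 250.0)
        pyr = laplacian_pyramid(np.zeros((32, 32)), 1)
        pyr.levels[0] = np.full((32, 32), 10.0)
        out = amplify_and_reconstruct(img, pyr, 5.0)
        assert out.max() <= 255.0


def _roi_stack(hr_hz=1.2, rr_hz=None, hr_amp=2.0, rr_amp=1.0, n=180,
               base=120.0, fs=FS):
    """180x180 ROI frames whose green channel oscillates globally."""
    t = np.arange(n) / fs
    g = base + hr_amp * np.sin(2 * np.pi * hr_hz * t)
    if rr_hz is not None:
        g = g + rr_amp * np.sin(2 * np.pi * rr_hz * t)
    items = []
    for i in range(n):
        pix = np.full((180, 180, 3), base, dtype=np.float32)
        pix[:, :, 1] = g[i]
        items.append(RoiImageEVM(pixels=pix, frame_index=i))
    return items


def _buffer(items, fs=FS):
    buf = SignalBuffer(capacity=len(items), fs=fs)
    for item in items:
        buf.push(item)
    return buf


class TestEstimateVitalsEVM:
    def test_global_oscillation_recovers_hr(self):
        est = estimate_vitals_evm(_buffer(_roi_stack()))
        freqs = np.fft.rfftfreq(180, d=1.0 / FS)
        hr_bins = freqs[(freqs >= 0.83) & (freqs <= 3.0)]
        assert est.method == "evm"
        assert est.hr_peak_hz == pytest.approx(hr_bins[np.argmin(np.abs(hr_bins - 1.2))])

    def test_static_stack_yields_no_estimate(self):
        items = _roi_stack(hr_amp=0.0)
        est = estimate_vitals_evm(_buffer(items))
        assert est.hr_bpm is None and est.rr_bpm is None

    def test_two_frequency_band_separation(self):
        est = estimate_vitals_evm(_buffer(_roi_stack(hr_hz=1.2, rr_hz=1.0 / 3.0,
                                                     hr_amp=2.0, rr_amp=0.5)))
        assert est.hr_peak_hz == pytest.approx(7.0 / 6.0)  # bin nearest 1.2 Hz
        assert est.rr_peak_hz == pytest.approx(1.0 / 3.0)

    def test_engine_matches_functional_api(self):
        items = _roi_stack(n=180)
        engine = EVMEngine(capacity=180, cfg=EVMConfig(fs=FS))
        ready = False
        for item in items:
            ready = engine.push(item)
        assert ready
        a = engine.estimate()
        b = estimate_vitals_evm(_buffer(items))
        assert a.hr_peak_hz == b.hr_peak_hz and a.rr_peak_hz == b.rr_peak_hz
        assert a.hr_bpm == pytest.approx(b.hr_bpm)

    def test_wrong_roi_size_rejected(self):
        with pytest.raises(ValueError):
            RoiImageEVM(pixels=np.zeros((90, 90, 3), dtype=np.float32), frame_index=0)

    def test_not_ready_rejected(self):
        buf = SignalBuffer(capacity=180, fs=FS)
        with pytest.raises(SignalError):
            estimate_vitals_evm(buf)


def test_upsample_matches_target_shape_exactly(rng):
    for shape in [(45, 45), (23, 31), (10, 10)]:
        small = rng.random((int(np.ceil(shape[0] / 2)), int(np.ceil(shape[1] / 2))))
        assert upsample_to(small, shape).shape == shape
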