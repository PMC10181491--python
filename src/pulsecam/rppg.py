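"""GREEN-method remote photoplethysmography.

The pulse signal is the per-frame mean of the green channel over the
skin ROI. A buffered window of that trace is cleaned and transformed:

    detrend -> resample to a uniform grid -> Hamming window
            -> L2 normalisation -> one-sided amplitude spectrum

and the heart and respiratory rates are read off the highest in-band
spectral peaks.

Detrending uses the smoothness-priors method: the trend is the solution
of ``(I + lambda^2 D2' D2) t = z`` with D2 the second-difference
operator, and the detrended signal is ``z - t``. Larger ``lambda`` makes
the trend stiffer (removes only slower drifts); the default of 300 at
30 Hz puts the detrender's half-power point near 0.28 Hz, so drift and
illumination changes are removed while the heart-rate band passes
essentially untouched and the respiratory band survives attenuated but
detectable. (A much smaller lambda moves the cutoff into the HR band
and erases the respiratory component entirely.) A
moving-average-subtraction fallback is selectable for comparison.

FFT scaling convention (fixed, internal): one-sided amplitudes are
``|DFT|/n`` with bins ``0 < k < n/2`` doubled, so a unit-amplitude
bin-centred sinusoid shows amplitude 1.0 at its bin and Parseval's
identity reads ``sum x^2 = n*(A_0^2 + sum_mid A_k^2 / 2 + A_nyq^2)``.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .errors import SignalError
from .vitals import (
    Band,
    HR_BAND,
    RR_BAND,
    SignalBuffer,
    Spectrum,
    VitalsEstimate,
    band_peak,
    freq_to_rate,
)

__all__ = [
    "Trace",
    "RPPGConfig",
    "detrend",
    "detrend_moving_average",
    "interpolate_uniform",
    "apply_hamming",
    "l2_normalize",
    "amplitude_spectrum",
    "estimate_vitals_rppg",
]


@dataclass
class Trace:
    """A scalar time series sampled once per buffered frame."""

    values: np.ndarray
    timestamps_s: np.ndarray
    fs: float

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.timestamps_s = np.asarray(self.timestamps_s, dtype=float)
        if self.values.shape != self.timestamps_s.shape:
            raise ValueError("values and timestamps must have equal length")

    def __len__(self) -> int:
        return self.values.size

    def replace_values(self, values: np.ndarray) -> "Trace":
        return Trace(values=np.asarray(values, dtype=float),
                     timestamps_s=self.timestamps_s, fs=self.fs)


@dataclass
class RPPGConfig:
    detrend_lambda: float = 300.0
    detrend_method: str = "smoothness_priors"  # | "moving_average"
    window: str = "hamming"
    hr_band: Band = field(default_factory=lambda: HR_BAND)
    rr_band: Band = field(default_factory=lambda: RR_BAND)
    fs: float = 30.0

    def __post_init__(self) -> None:
        if self.detrend_lambda <= 0:
            raise ValueError("detrend_lambda must be positive")


def _second_difference(n: int) -> sp.spmatrix:
    return sp.diags([1.0, -2.0, 1.0], [0, 1, 2], shape=(n - 2, n), format="csc")


def detrend(values: np.ndarray, lam: float = 300.0) -> np.ndarray:
    """Smoothness-priors detrending (second-difference penalty, weight lam^2)."""
    z = np.asarray(values, dtype=float)
    n = z.size
    if n < 3:
        raise SignalError(f"detrend requires n >= 3, got {n}")
    d2 = _second_difference(n)
    a = sp.identity(n, format="csc") + (lam * lam) * (d2.T @ d2)
    trend = spla.spsolve(a, z)
    return z - trend


def detrend_moving_average(values: np.ndarray, window: int = 31) -> np.ndarray:
    """Fallback: subtract a centred moving average (edge-padded)."""
    z = np.asarray(values, dtype=float)
    if z.size < 3:
        raise SignalError("detrend requires n >= 3")
    w = min(window | 1, z.size if z.size % 2 else z.size - 1)  # odd, <= n
    pad = w // 2
    zp = np.pad(z, pad, mode="edge")
    kernel = np.ones(w) / w
    return z - np.convolve(zp, kernel, mode="valid")


def interpolate_uniform(trace: Trace) -> Trace:
    """Resample onto a uniform grid spanning the same interval.

    Frame products may arrive at slightly non-periodic instants (dropped
    or delayed camera frames); linear interpolation onto an evenly spaced
    grid of the same length restores the uniform sampling the FFT
    assumes. Identity when the timestamps are already uniform.
    """
    t = trace.timestamps_s
    if np.any(np.diff(t) <= 0):
        raise SignalError("timestamps must be strictly increasing")
    n = len(trace)
    grid = np.linspace(t[0], t[-1], n)
    spacing = np.diff(t)
    if np.allclose(spacing, spacing[0], rtol=0, atol=1e-12):
        return Trace(values=trace.values.copy(), timestamps_s=grid, fs=trace.fs)
    values = np.interp(grid, t, trace.values)
    fs_eff = (n - 1) / (t[-1] - t[0]) if n > 1 else trace.fs
    return Trace(values=values, timestamps_s=grid, fs=fs_eff)


def apply_hamming(values: np.ndarray) -> np.ndarray:
    """Pointwise Hamming taper w[k] = 0.54 - 0.46 cos(2 pi k / (n-1))."""
    z = np.asarray(values, dtype=float)
    if z.size < 2:
        raise SignalError("window requires n >= 2")
    return z * np.hamming(z.size)


def l2_normalize(values: np.ndarray) -> np.ndarray:
    """Scale to unit Euclidean norm."""
    z = np.asarray(values, dtype=float)
    norm = np.linalg.norm(z)
    if norm == 0:
        raise SignalError("cannot L2-normalize an all-zero signal")
    return z / norm


def amplitude_spectrum(values: np.ndarray, fs: float) -> Spectrum:
    """One-sided amplitude spectrum with bins at k*fs/n, k = 0..floor(n/2)."""
    z = np.asarray(values, dtype=float)
    n = z.size
    if n < 2:
        raise SignalError("spectrum requires n >= 2")
    amps = np.abs(np.fft.rfft(z)) / n
    if n % 2 == 0:
        amps[1:-1] *= 2.0  # Nyquist bin is not mirrored
    else:
        amps[1:] *= 2.0
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    return Spectrum(freqs=freqs, amps=amps, n=n, fs=fs)


def trace_from_buffer(buffer: SignalBuffer) -> Trace:
    """Assemble the green trace from a buffer of GreenSamples."""
    values = np.array([s.value for s in buffer], dtype=float)
    ts = np.array([s.timestamp_s for s in buffer], dtype=float)
    return Trace(values=values, timestamps_s=ts, fs=buffer.fs)


def preprocess(trace: Trace, cfg: RPPGConfig) -> Trace:
    """The full pre-processing chain up to (but excluding) the FFT."""
    if cfg.detrend_method == "smoothness_priors":
        v = detrend(trace.values, cfg.detrend_lambda)
    elif cfg.detrend_method == "moving_average":
        v = detrend_moving_average(trace.values)
    else:
        raise ValueError(f"unknown detrend method {cfg.detrend_method!r}")
    t = interpolate_uniform(trace.replace_values(v))
    v = apply_hamming(t.values)
    v = l2_normalize(v)
    return Trace(values=v, timestamps_s=t.timestamps_s, fs=t.fs)


def estimate_vitals_rppg(buffer: SignalBuffer, cfg: Optional[RPPGConfig] = None) -> VitalsEstimate:
    """Estimate HR and RR from a full buffer of green-channel samples."""
    if not buffer.ready:
        raise SignalError(f"buffer not ready ({len(buffer)}/{buffer.capacity})")
    cfg = cfg or RPPGConfig(fs=buffer.fs)
    trace = trace_from_buffer(buffer)
    clean = preprocess(trace, cfg)
    spec = amplitude_spectrum(clean.values, clean.fs)
    hr_hz = band_peak(spec, cfg.hr_band)
    rr_hz = band_peak(spec, cfg.rr_band)
    last_index = trace_last_index(buffer)
    return VitalsEstimate(
        frame_index=last_index,
        method="rppg",
        hr_bpm=freq_to_rate(hr_hz),
        rr_bpm=freq_to_rate(rr_hz),
        hr_peak_hz=hr_hz,
        rr_peak_hz=rr_hz,
    )


def trace_last_index(buffer: SignalBuffer) -> int:
    return int(buffer.items[-1].frame_index)
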