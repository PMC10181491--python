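"""Eulerian video magnification over buffered face crops.

Each 180x180 ROI frame is decomposed into a Laplacian pyramid (built on
a Gaussian pyramid with a 5-tap binomial kernel, halving each level).
Stacking one pyramid level over the buffer window gives a time x H x W
array per level; an ideal (brick-wall) temporal bandpass — FFT along
time, zero every bin outside the band, inverse FFT — isolates the
physiological frequencies. The filtered signal can be amplified and
collapsed back for visualisation, and the spatial mean of the coarsest
filtered level provides the trace whose spectral peak gives the vital
sign.

Rate estimation uses the coarsest Laplacian level (the Gaussian top),
which aggregates the largest spatial support and therefore the best SNR
for a global skin-color oscillation, on the green channel by default for
consistency with the rPPG engine; both are configurable.
"""
from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field
from typing import Deque, List, Optional, Sequence

import numpy as np
from scipy.ndimage import convolve1d

from .errors import BandError, SignalError
from .roi import RoiImageEVM
from .rppg import amplitude_spectrum
from .vitals import (
    Band,
    HR_BAND,
    RR_BAND,
    SignalBuffer,
    VitalsEstimate,
    band_peak,
    freq_to_rate,
)

__all__ = [
    "EVMConfig",
    "Pyramid",
    "gaussian_pyramid",
    "laplacian_pyramid",
    "collapse",
    "upsample_to",
    "temporal_bandpass",
    "amplify_and_reconstruct",
    "estimate_vitals_evm",
    "EVMEngine",
]

# 5-tap binomial (Gaussian-like) kernel used for all pyramid blurs
_KERNEL = np.array([1.0, 4.0, 6.0, 4.0, 1.0]) / 16.0

#: In-band squared-amplitude mass below this is treated as "no signal"
#: (static input) and yields no estimate instead of an arbitrary argmax.
DEGENERATE_MASS = 1e-12

_CHANNELS = {"red": 0, "green": 1, "blue": 2}


@dataclass
class EVMConfig:
    levels: int = 3
    alpha: float = 50.0  # magnification factor, visualization only
    channel: str = "green"
    hr_band: Band = field(default_factory=lambda: HR_BAND)
    rr_band: Band = field(default_factory=lambda: RR_BAND)
    fs: float = 30.0

    def __post_init__(self) -> None:
        if self.levels < 0:
            raise ValueError("levels must be >= 0")
        if self.alpha < 0:
            raise ValueError("alpha must be >= 0")
        if self.channel not in _CHANNELS:
            raise ValueError(f"channel must be one of {sorted(_CHANNELS)}")

    @property
    def channel_index(self) -> int:
        return _CHANNELS[self.channel]


@dataclass
class Pyramid:
    """Ordered multiscale decomposition; level k is at scale 1/2^k."""

    levels: List[np.ndarray]
    kind: str  # "gaussian" | "laplacian"


def _blur(img: np.ndarray, kernel: np.ndarray = _KERNEL) -> np.ndarray:
    out = convolve1d(img, kernel, axis=0, mode="mirror")
    out = convolve1d(out, kernel, axis=1, mode="mirror")
    return out


def _decimate(img: np.ndarray) -> np.ndarray:
    return img[::2, ::2]


def gaussian_pyramid(image: np.ndarray, levels: int) -> Pyramid:
    """Blur-then-halve pyramid; level 0 is the input, sizes ceil-halve."""
    img = np.asarray(image, dtype=float)
    side = min(img.shape[:2])
    if side < 2 ** levels:
        raise SignalError(f"image side {side} too small for {levels} pyramid levels")
    out = [img]
    for _ in range(levels):
        img = _decimate(_blur(img))
        out.append(img)
    return Pyramid(levels=out, kind="gaussian")


def upsample_to(img: np.ndarray, shape: Sequence[int]) -> np.ndarray:
    """Zero-stuff by 2 and blur with the doubled kernel, trimmed to
    exactly ``shape`` so pyramid arithmetic is shape-exact."""
    th, tw = shape[0], shape[1]
    up_shape = (img.shape[0] * 2, img.shape[1] * 2) + img.shape[2:]
    up = np.zeros(up_shape, dtype=float)
    up[::2, ::2] = img
    up = convolve1d(up, 2.0 * _KERNEL, axis=0, mode="mirror")
    up = convolve1d(up, 2.0 * _KERNEL, axis=1, mode="mirror")
    return up[:th, :tw]


def laplacian_pyramid(image: np.ndarray, levels: int) -> Pyramid:
    """Band-pass levels G_k - up(G_{k+1}); the top level equals the
    Gaussian top, so collapsing reproduces the input exactly."""
    gauss = gaussian_pyramid(image, levels)
    lap: List[np.ndarray] = []
    for k in range(levels):
        g_k = gauss.levels[k]
        lap.append(g_k - upsample_to(gauss.levels[k + 1], g_k.shape))
    lap.append(gauss.levels[levels])
    return Pyramid(levels=lap, kind="laplacian")


def collapse(pyramid: Pyramid) -> np.ndarray:
    """Reconstruct the image from a Laplacian pyramid."""
    if pyramid.kind != "laplacian":
        raise ValueError("collapse expects a laplacian pyramid")
    img = pyramid.levels[-1]
    for lap in reversed(pyramid.levels[:-1]):
        img = lap + upsample_to(img, lap.shape)
    return img


def temporal_bandpass(stack: np.ndarray, band: Band, fs: float) -> np.ndarray:
    """Ideal per-pixel temporal bandpass along axis 0.

    FFT in time, zero every bin whose |frequency| falls outside
    [f_lo, f_hi] (inclusive), inverse FFT. Being a projection onto a set
    of bins, the filter is idempotent; output is real.
    """
    stack = np.asarray(stack, dtype=float)
    n = stack.shape[0]
    if n < 2:
        raise SignalError("temporal filter requires at least 2 frames")
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    keep = band.contains(freqs)
    if not np.any(keep):
        raise BandError(
            f"band [{band.f_lo}, {band.f_hi}] Hz contains no bins at resolution {fs / n:.4g} Hz"
        )
    spec = np.fft.rfft(stack, axis=0)
    spec[~keep] = 0.0
    return np.fft.irfft(spec, n=n, axis=0)


def amplify_and_reconstruct(
    frame: np.ndarray, filtered: Pyramid, alpha: float
) -> np.ndarray:
    """Visualisation path: frame + alpha * collapse(filtered bandpass
    pyramid), clipped to the 0-255 intensity range."""
    frame = np.asarray(frame, dtype=float)
    delta = collapse(filtered)
    if delta.shape != frame.shape:
        raise SignalError(f"pyramid/frame shape mismatch: {delta.shape} vs {frame.shape}")
    return np.clip(frame + alpha * delta, 0.0, 255.0)


def coarsest_level(pixels: np.ndarray, cfg: EVMConfig) -> np.ndarray:
    """The coarsest Laplacian level of the configured channel (2D)."""
    chan = np.asarray(pixels, dtype=float)[:, :, cfg.channel_index]
    return gaussian_pyramid(chan, cfg.levels).levels[-1]


def _estimate_from_levels(
    levels: Sequence[np.ndarray], last_index: int, cfg: EVMConfig
) -> VitalsEstimate:
    stack = np.stack(levels, axis=0)
    stack = stack - stack.mean(axis=0, keepdims=True)
    rates = {}
    peaks = {}
    for name, band in (("hr", cfg.hr_band), ("rr", cfg.rr_band)):
        filtered = temporal_bandpass(stack, band, cfg.fs)
        trace = filtered.mean(axis=(1, 2))
        spec = amplitude_spectrum(trace, cfg.fs)
        if spec.band_mass(band) < DEGENERATE_MASS:
            rates[name], peaks[name] = None, None
            continue
        peak_hz = band_peak(spec, band)
        peaks[name] = peak_hz
        rates[name] = freq_to_rate(peak_hz)
    return VitalsEstimate(
        frame_index=last_index,
        method="evm",
        hr_bpm=rates["hr"],
        rr_bpm=rates["rr"],
        hr_peak_hz=peaks["hr"],
        rr_peak_hz=peaks["rr"],
    )


def estimate_vitals_evm(buffer: SignalBuffer, cfg: Optional[EVMConfig] = None) -> VitalsEstimate:
    """Estimate HR and RR from a full buffer of 180x180 ROI crops.

    Builds each frame's pyramid, stacks the coarsest level, applies the
    ideal temporal bandpass per band, spatially averages to a trace and
    reads the in-band spectral peak. Emits ``None`` rates when the band
    holds no spectral mass above numerical noise (static input).
    """
    if not buffer.ready:
        raise SignalError(f"buffer not ready ({len(buffer)}/{buffer.capacity})")
    cfg = cfg or EVMConfig(fs=buffer.fs)
    items: Sequence[RoiImageEVM] = buffer.items
    levels = [coarsest_level(item.pixels, cfg) for item in items]
    return _estimate_from_levels(levels, int(items[-1].frame_index), cfg)


class EVMEngine:
    """Incremental EVM estimator for per-frame streaming use.

    Computes each frame's coarsest pyramid level once at push time and
    keeps a sliding window of levels, so emitting an estimate every
    frame does not rebuild the whole window's pyramids. Numerically
    identical to :func:`estimate_vitals_evm` on the same window.
    """

    def __init__(self, capacity: int = 180, cfg: Optional[EVMConfig] = None):
        self.cfg = cfg or EVMConfig()
        self.capacity = capacity
        self._levels: Deque[np.ndarray] = deque(maxlen=capacity)
        self._last_index: Optional[int] = None

    @property
    def ready(self) -> bool:
        return len(self._levels) == self.capacity

    def push(self, item: RoiImageEVM) -> bool:
        if self._last_index is not None and item.frame_index <= self._last_index:
            raise SignalError("frame_index must be strictly increasing")
        self._levels.append(coarsest_level(item.pixels, self.cfg))
        self._last_index = int(item.frame_index)
        return self.ready

    def estimate(self) -> VitalsEstimate:
        if not self.ready:
            raise SignalError(f"buffer not ready ({len(self._levels)}/{self.capacity})")
        return _estimate_from_levels(list(self._levels), self._last_index, self.cfg)
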