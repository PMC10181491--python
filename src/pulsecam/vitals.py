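"""Shared vital-sign machinery: the frame buffer, frequency bands and
spectral peak -> rate conversion.

Both estimation engines (rPPG and EVM) funnel their per-frame products
through a fixed-capacity shift-register buffer and read rates off an
amplitude spectrum restricted to a physiological frequency band:

* heart rate:        0.83 - 3.0 Hz  (50 - 180 beats per minute)
* respiratory rate:  0.18 - 0.5 Hz  (11 - 30 breaths per minute)

Band edges are inclusive and kept exactly as printed (0.83 Hz, not the
exact 50/60 Hz), so a peak on the edge bin is accepted.
"""
from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field
from typing import Any, Iterator, Optional

import numpy as np

from .errors import BandError, StreamOrderError

__all__ = [
    "Band",
    "HR_BAND",
    "RR_BAND",
    "Spectrum",
    "VitalsEstimate",
    "SignalBuffer",
    "band_peak",
    "freq_to_rate",
]

DEFAULT_BUFFER_FRAMES = 180


@dataclass(frozen=True)
class Band:
    """A closed frequency interval [f_lo, f_hi] in Hz."""

    f_lo: float
    f_hi: float

    def __post_init__(self) -> None:
        if not (0 < self.f_lo < self.f_hi):
            raise ValueError(f"require 0 < f_lo < f_hi, got ({self.f_lo}, {self.f_hi})")

    def contains(self, freq_hz: np.ndarray | float) -> np.ndarray | bool:
        return (np.asarray(freq_hz) >= self.f_lo) & (np.asarray(freq_hz) <= self.f_hi)


HR_BAND = Band(0.83, 3.0)
RR_BAND = Band(0.18, 0.5)


@dataclass
class Spectrum:
    """One-sided amplitude spectrum of a real signal.

    ``amps[k]`` is the amplitude at ``freqs[k] = k * fs / n``; bins are
    uniformly spaced by ``fs / n``.
    """

    freqs: np.ndarray
    amps: np.ndarray
    n: int
    fs: float

    def __post_init__(self) -> None:
        self.freqs = np.asarray(self.freqs, dtype=float)
        self.amps = np.asarray(self.amps, dtype=float)
        if self.freqs.shape != self.amps.shape:
            raise ValueError("freqs and amps must have identical shape")

    def band_mass(self, band: Band) -> float:
        """Total squared amplitude inside the band (degeneracy check)."""
        sel = band.contains(self.freqs)
        return float(np.sum(self.amps[sel] ** 2))


@dataclass
class VitalsEstimate:
    """HR/RR estimate for one buffer window, with the peak bins behind it.

    ``hr_bpm``/``rr_bpm`` are ``None`` when the corresponding band held no
    spectral mass above numerical noise (degenerate static input).
    """

    frame_index: int
    method: str  # "evm" | "rppg"
    hr_bpm: Optional[float]
    rr_bpm: Optional[float]
    hr_peak_hz: Optional[float]
    rr_peak_hz: Optional[float]


class SignalBuffer:
    """Fixed-capacity FIFO of per-frame products (a shift register).

    Items must carry a ``frame_index`` attribute and arrive in strictly
    increasing index order. Once full, each push drops the oldest item,
    so estimates slide frame by frame.
    """

    def __init__(self, capacity: int = DEFAULT_BUFFER_FRAMES, fs: float = 30.0):
        if capacity < 1:
            raise ValueError("capacity must be >= 1")
        if fs <= 0:
            raise ValueError("fs must be positive")
        self.capacity = int(capacity)
        self.fs = float(fs)
        self._items: deque[Any] = deque(maxlen=self.capacity)
        self._last_index: Optional[int] = None

    def __len__(self) -> int:
        return len(self._items)

    def __iter__(self) -> Iterator[Any]:
        return iter(self._items)

    @property
    def ready(self) -> bool:
        return len(self._items) == self.capacity

    @property
    def items(self) -> tuple:
        return tuple(self._items)

    def push(self, item: Any) -> bool:
        """Append one per-frame product; returns True when the buffer is full."""
        idx = int(item.frame_index)
        if self._last_index is not None and idx <= self._last_index:
            raise StreamOrderError(
                f"frame_index {idx} not greater than last pushed {self._last_index}"
            )
        self._items.append(item)
        self._last_index = idx
        return self.ready


def band_peak(spectrum: Spectrum, band: Band) -> float:
    """Frequency (Hz) of the maximum-amplitude bin inside the band.

    Ties break toward the lower frequency. Raises :class:`BandError` when
    the spectrum has no bin inside the band.
    """
    sel = np.flatnonzero(band.contains(spectrum.freqs))
    if sel.size == 0:
        raise BandError(
            f"no spectral bin inside [{band.f_lo}, {band.f_hi}] Hz "
            f"(resolution {spectrum.fs / spectrum.n:.4g} Hz)"
        )
    k = sel[np.argmax(spectrum.amps[sel])]  # argmax returns first max -> lowest freq
    return float(spectrum.freqs[k])


def freq_to_rate(peak_hz: float) -> float:
    """Convert a spectral peak in Hz to a per-minute rate (60 x Hz)."""
    if peak_hz <= 0:
        raise ValueError("peak frequency must be positive")
    return 60.0 * peak_hz
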