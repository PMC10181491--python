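"""Deterministic synthetic face videos with known HR/RR ground truth.

The generator emulates the optical effect rPPG and color-amplification
methods exploit: cardiac blood-volume changes modulate skin reflectance,
strongest in the green channel. A static rectangular "face" sits on a
static background; inside the face box the green channel carries

    g(t) = base_g
         + hr_amp * (1 + rr_mod * sin(2*pi*rr_hz*t)) * wave(2*pi*hr_hz*t)
         + rr_add_amp * sin(2*pi*rr_hz*t)
         + illumination_slope * t

plus i.i.d. per-pixel Gaussian noise on every channel; values are clipped
to 0-255. Respiration therefore appears both as amplitude modulation of
the cardiac component and as a direct low-frequency term, so the
respiratory band holds first-order spectral energy. The cardiac waveform
is a pure sinusoid by default so the spectral ground truth is a single
line; a skewed ``"pulse"`` waveform is available for robustness tests.

The module also provides fixture detectors (known face box, parametric
468-point landmark template) so the full pipeline runs without any
external CNN model.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterator, Tuple

import numpy as np
import yaml

from .errors import SpecError
from .video_io import FrameSample, FrameStream

__all__ = [
    "SyntheticSpec",
    "GroundTruth",
    "generate",
    "green_mean_trace",
    "fixture_detection",
    "mesh_template_unit",
    "FOREHEAD_IDX",
    "LEFT_CHEEK_IDX",
    "RIGHT_CHEEK_IDX",
    "N_MESH_POINTS",
    "write_image_sequence",
    "write_video",
]

N_MESH_POINTS = 468

# Polygon vertex indices into the 468-point fixture template (unit-face
# coordinates; the first twelve template points are the region corners).
FOREHEAD_IDX = (0, 1, 2, 3)
LEFT_CHEEK_IDX = (4, 5, 6, 7)
RIGHT_CHEEK_IDX = (8, 9, 10, 11)

_ANCHORS_UNIT = np.array(
    [
        # forehead (clockwise)
        (0.25, 0.08), (0.75, 0.08), (0.75, 0.28), (0.25, 0.28),
        # left cheek (image-left)
        (0.15, 0.45), (0.38, 0.45), (0.38, 0.70), (0.15, 0.70),
        # right cheek
        (0.62, 0.45), (0.85, 0.45), (0.85, 0.70), (0.62, 0.70),
    ],
    dtype=float,
)


@dataclass
class SyntheticSpec:
    """Parameters of one synthetic face video.

    Defaults give a 12 s, 30 fps, 640x360 clip with a 72 bpm cardiac
    oscillation (1.2 Hz, amplitude 2 intensity units on green) amplitude-
    modulated at 15 breaths/min (0.25 Hz), unit per-pixel noise, seed 7.
    """

    resolution: Tuple[int, int] = (640, 360)
    fps: float = 30.0
    duration_s: float = 12.0
    face_box: Tuple[int, int, int, int] = (240, 90, 160, 160)
    skin_base_rgb: Tuple[int, int, int] = (190, 150, 120)
    hr_hz: float = 1.2
    hr_amp: float = 2.0
    rr_hz: float = 0.25
    rr_mod: float = 0.3
    rr_add_amp: float = 1.0
    noise_sigma: float = 1.0
    illumination_slope: float = 0.0
    waveform: str = "sine"  # "sine" | "pulse"
    background_rgb: Tuple[int, int, int] = (60, 60, 60)
    seed: int = 7

    def __post_init__(self) -> None:
        w, h = self.resolution
        x, y, bw, bh = self.face_box
        if not (w > 0 and h > 0 and self.fps > 0 and self.duration_s > 0):
            raise SpecError("resolution, fps and duration must be positive")
        if bw <= 0 or bh <= 0 or x < 0 or y < 0 or x + bw > w or y + bh > h:
            raise SpecError(f"face_box {self.face_box} outside resolution {self.resolution}")
        if not (0 <= self.rr_mod < 1):
            raise SpecError("rr_mod must be in [0, 1)")
        if self.waveform not in ("sine", "pulse"):
            raise SpecError(f"unknown waveform {self.waveform!r}")

    @property
    def n_frames(self) -> int:
        return int(round(self.fps * self.duration_s))

    def to_yaml(self, path: str | Path) -> None:
        d = asdict(self)
        # tuples -> lists for clean YAML
        for k, v in d.items():
            if isinstance(v, tuple):
                d[k] = list(v)
        Path(path).write_text(yaml.safe_dump(d, sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SyntheticSpec":
        d = yaml.safe_load(Path(path).read_text())
        for k in ("resolution", "face_box", "skin_base_rgb", "background_rgb"):
            if k in d:
                d[k] = tuple(d[k])
        return cls(**d)


@dataclass
class GroundTruth:
    """True rates and the noiseless face-region green mean per frame."""

    hr_bpm_true: float
    rr_bpm_true: float
    green_mean: np.ndarray


def _cardiac_wave(phase: np.ndarray, waveform: str) -> np.ndarray:
    if waveform == "sine":
        return np.sin(phase)
    # skewed pulse: sharpened systolic upstroke, still dominated by the
    # fundamental so band peaks stay at hr_hz
    return 0.85 * np.sin(phase) + 0.15 * np.sin(2 * phase - 0.8)


def green_mean_trace(spec: SyntheticSpec) -> np.ndarray:
    """Noiseless green mean inside the face box at every frame time."""
    t = np.arange(spec.n_frames) / spec.fps
    phase = 2 * math.pi * spec.hr_hz * t
    resp = np.sin(2 * math.pi * spec.rr_hz * t)
    g = (
        spec.skin_base_rgb[1]
        + spec.hr_amp * (1 + spec.rr_mod * resp) * _cardiac_wave(phase, spec.waveform)
        + spec.rr_add_amp * resp
        + spec.illumination_slope * t
    )
    return g


def generate(spec: SyntheticSpec) -> Tuple[FrameStream, GroundTruth]:
    """Render the frame stream and its ground truth.

    Frames are generated lazily; two generators built from equal specs
    (same seed) yield bitwise-identical frames.
    """
    truth = GroundTruth(
        hr_bpm_true=60.0 * spec.hr_hz,
        rr_bpm_true=60.0 * spec.rr_hz,
        green_mean=green_mean_trace(spec),
    )
    return _frame_iter(spec, truth.green_mean), truth


def _frame_iter(spec: SyntheticSpec, green_mean: np.ndarray) -> Iterator[FrameSample]:
    w, h = spec.resolution
    x, y, bw, bh = spec.face_box
    rng = np.random.default_rng(spec.seed)
    base = np.empty((h, w, 3), dtype=np.float64)
    base[:] = spec.background_rgb
    base[y : y + bh, x : x + bw, :] = spec.skin_base_rgb
    for i in range(spec.n_frames):
        frame = base.copy()
        frame[y : y + bh, x : x + bw, 1] = green_mean[i]
        if spec.noise_sigma > 0:
            frame += rng.normal(0.0, spec.noise_sigma, size=frame.shape)
        pix = np.clip(np.rint(frame), 0, 255).astype(np.uint8)
        yield FrameSample(
            index=i,
            timestamp_s=i / spec.fps,
            pixels=pix,
            source_resolution=(w, h),
        )


def mesh_template_unit() -> np.ndarray:
    """The parametric 468-point face template in unit-face coordinates.

    The first 12 points are the forehead / left-cheek / right-cheek
    polygon corners; the remaining 456 lie on concentric ellipses filling
    the face oval. Deterministic (no RNG) and identical across calls.
    """
    pts = np.zeros((N_MESH_POINTS, 3), dtype=float)
    pts[:12, :2] = _ANCHORS_UNIT
    n_fill = N_MESH_POINTS - 12
    n_rings = 8
    per_ring = n_fill // n_rings  # 57
    k = 0
    for r in range(n_rings):
        radius = 0.10 + 0.38 * (r + 1) / n_rings
        count = per_ring if r < n_rings - 1 else n_fill - per_ring * (n_rings - 1)
        ang = 2 * math.pi * np.arange(count) / count + 0.1 * r
        pts[12 + k : 12 + k + count, 0] = 0.5 + radius * np.cos(ang)
        pts[12 + k : 12 + k + count, 1] = 0.5 + 0.95 * radius * np.sin(ang)
        k += count
    np.clip(pts[:, :2], 0.01, 0.99, out=pts[:, :2])
    return pts


def fixture_detection(spec: SyntheticSpec, mode: str = "box"):
    """Ground-truth detection for a synthetic stream.

    ``mode="box"`` returns the known face box (score 1.0); ``mode="mesh"``
    returns the 468-point template affinely mapped into the face box.
    Deterministic and frame-independent (static geometry).
    """
    from .roi import FaceDetection, FaceLandmarks  # local: roi imports this module

    x, y, bw, bh = spec.face_box
    if mode == "box":
        return FaceDetection(box=(x, y, bw, bh), score=1.0, landmarks6=None)
    if mode == "mesh":
        unit = mesh_template_unit()
        pts = unit.copy()
        pts[:, 0] = x + unit[:, 0] * bw
        pts[:, 1] = y + unit[:, 1] * bh
        return FaceLandmarks(points=pts)
    raise ValueError(f"unknown fixture mode {mode!r}")


def write_image_sequence(
    spec: SyntheticSpec, out_dir: str | Path, pattern: str = "frame_%06d.png"
) -> Path:
    """Render the spec to a numbered PNG sequence; returns the directory."""
    import imageio.v2 as iio

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stream, _ = generate(spec)
    for frame in stream:
        iio.imwrite(out / (pattern % frame.index), frame.pixels)
    return out


def write_video(spec: SyntheticSpec, out_path: str | Path) -> Path:
    """Render the spec to a video container (requires an imageio plugin
    that supports the container, e.g. an ffmpeg backend)."""
    import imageio.v2 as iio

    from .errors import SourceError

    stream, _ = generate(spec)
    try:
        writer = iio.get_writer(str(out_path), fps=spec.fps)
    except Exception as exc:  # noqa: BLE001
        raise SourceError(
            f"no imageio plugin can write {out_path}; "
            "use write_image_sequence for a plugin-free path"
        ) from exc
    with writer:
        for frame in stream:
            writer.append_data(frame.pixels)
    return Path(out_path)
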