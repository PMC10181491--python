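"""Frame sources and the EVM input resize.

Frames are carried as ``FrameSample`` objects holding an H x W x 3 uint8
array in RGB order (decoders that emit BGR must be converted at this
boundary; everything downstream assumes green = channel 1). Timestamps of
file and synthetic sources are synthesized as ``index / nominal_fps``
rather than read from container PTS; live cameras use the wall clock.

Supported sources:

* a directory of numbered image frames (``frame_%06d.png`` or any
  lexicographically ordered set of images),
* a video file, dispatched to whatever imageio plugin can decode it,
* a live camera (``camera id`` int), via imageio's ``<videoN>`` URI,
* a :class:`~pulsecam.synthetic.SyntheticSpec`, rendered on the fly.
"""
from __future__ import annotations

import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Optional, Tuple, Union

import imageio.v2 as iio
import numpy as np
from skimage.transform import resize as _sk_resize

from .errors import EmptyStreamError, SourceError

__all__ = [
    "FrameSample",
    "StreamSpec",
    "FrameStream",
    "open_source",
    "resize_frame",
    "resize_for_evm",
    "EVM_INPUT_SIZE",
]

#: EVM-path working resolution; larger frames are downscaled to this before
#: detection to bound memory on constrained devices.
EVM_INPUT_SIZE: Tuple[int, int] = (640, 360)

_IMAGE_EXTS = {".png", ".bmp", ".tif", ".tiff", ".jpg", ".jpeg", ".ppm"}


@dataclass
class FrameSample:
    """One decoded frame.

    Attributes
    ----------
    index : 0-based ordinal within the stream, strictly increasing.
    timestamp_s : seconds since stream start, non-decreasing.
    pixels : H x W x 3 uint8, RGB.
    source_resolution : (width, height) of the originating stream.
    """

    index: int
    timestamp_s: float
    pixels: np.ndarray
    source_resolution: Tuple[int, int]

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 3 or self.pixels.shape[2] != 3:
            raise ValueError(f"pixels must be HxWx3, got shape {self.pixels.shape}")
        if self.timestamp_s < 0:
            raise ValueError("timestamp_s must be non-negative")

    @property
    def resolution(self) -> Tuple[int, int]:
        """(width, height) of this frame's pixel array."""
        h, w = self.pixels.shape[:2]
        return (w, h)


@dataclass
class StreamSpec:
    """Where frames come from and at what nominal rate.

    ``source`` is a file/directory path, an integer camera id, or a
    synthetic-video spec object.
    """

    source: Union[str, Path, int, object]
    nominal_fps: float = 30.0
    resolution: Optional[Tuple[int, int]] = None

    def __post_init__(self) -> None:
        if self.nominal_fps <= 0:
            raise ValueError("nominal_fps must be positive")


FrameStream = Iterator[FrameSample]


def _to_rgb_uint8(arr: np.ndarray) -> np.ndarray:
    arr = np.asarray(arr)
    if arr.ndim == 2:
        arr = np.stack([arr] * 3, axis=-1)
    if arr.shape[2] == 4:
        arr = arr[:, :, :3]
    if arr.dtype != np.uint8:
        arr = np.clip(arr, 0, 255).astype(np.uint8)
    return arr


def _iter_directory(path: Path, fps: float) -> FrameStream:
    files = sorted(p for p in path.iterdir() if p.suffix.lower() in _IMAGE_EXTS)
    if not files:
        raise EmptyStreamError(f"no image frames found in directory {path}")
    for i, f in enumerate(files):
        try:
            arr = iio.imread(f)
        except Exception as exc:  # noqa: BLE001 - normalize decoder errors
            raise SourceError(f"cannot decode frame {f}: {exc}") from exc
        pix = _to_rgb_uint8(arr)
        h, w = pix.shape[:2]
        yield FrameSample(index=i, timestamp_s=i / fps, pixels=pix, source_resolution=(w, h))


def _iter_video_file(path: Path, fps: float) -> FrameStream:
    try:
        reader = iio.get_reader(str(path))
    except Exception as exc:  # noqa: BLE001
        raise SourceError(f"cannot open video file {path}: {exc}") from exc
    got_any = False
    try:
        for i, arr in enumerate(reader):
            got_any = True
            pix = _to_rgb_uint8(arr)
            h, w = pix.shape[:2]
            yield FrameSample(index=i, timestamp_s=i / fps, pixels=pix, source_resolution=(w, h))
    finally:
        reader.close()
    if not got_any:
        raise EmptyStreamError(f"no decodable frames in {path}")


def _iter_camera(cam_id: int) -> FrameStream:
    try:
        reader = iio.get_reader(f"<video{cam_id}>")
    except Exception as exc:  # noqa: BLE001
        raise SourceError(f"camera {cam_id} unavailable: {exc}") from exc
    t0 = time.monotonic()
    try:
        for i, arr in enumerate(reader):
            pix = _to_rgb_uint8(arr)
            h, w = pix.shape[:2]
            yield FrameSample(
                index=i,
                timestamp_s=time.monotonic() - t0,
                pixels=pix,
                source_resolution=(w, h),
            )
    finally:
        reader.close()


def open_source(spec: StreamSpec) -> FrameStream:
    """Open a frame stream per the spec.

    Raises :class:`SourceError` for unreadable sources and
    :class:`EmptyStreamError` when a source yields no frames.
    """
    src = spec.source
    # synthetic spec handle (duck-typed to avoid an import cycle)
    from .synthetic import SyntheticSpec, generate  # local: synthetic imports this module

    if isinstance(src, SyntheticSpec):
        stream, _truth = generate(src)
        return stream
    if isinstance(src, int):
        return _iter_camera(src)
    path = Path(src)
    if not path.exists():
        raise SourceError(f"source does not exist: {path}")
    if path.is_dir():
        return _iter_directory(path, spec.nominal_fps)
    return _iter_video_file(path, spec.nominal_fps)


def _area_downscale(img: np.ndarray, fy: int, fx: int) -> np.ndarray:
    """Exact block-mean downscale by integer factors (area averaging)."""
    h, w = img.shape[:2]
    blocks = img.reshape(h // fy, fy, w // fx, fx, img.shape[2])
    return blocks.mean(axis=(1, 3))


def resize_frame(pixels: np.ndarray, size: Tuple[int, int]) -> np.ndarray:
    """Resize an HxWx3 image to (width, height).

    Downscaling uses area averaging (exact block means when the factors
    are integral, anti-aliased resampling otherwise); upscaling is
    bilinear. A same-size input is returned unchanged.
    """
    tw, th = size
    h, w = pixels.shape[:2]
    if (w, h) == (tw, th):
        return pixels
    was_uint8 = pixels.dtype == np.uint8
    if w % tw == 0 and h % th == 0 and w >= tw and h >= th:
        out = _area_downscale(pixels.astype(np.float64), h // th, w // tw)
    else:
        downscaling = tw < w or th < h
        out = _sk_resize(
            pixels.astype(np.float64),
            (th, tw),
            order=1,
            anti_aliasing=downscaling,
            preserve_range=True,
        )
    if was_uint8:
        out = np.clip(np.rint(out), 0, 255).astype(np.uint8)
    return out


def resize_for_evm(frame: FrameSample, size: Tuple[int, int] = EVM_INPUT_SIZE) -> FrameSample:
    """Resize a frame to the EVM working resolution (identity if already there)."""
    if frame.resolution == size:
        return frame
    return FrameSample(
        index=frame.index,
        timestamp_s=frame.timestamp_s,
        pixels=resize_frame(frame.pixels, size),
        source_resolution=frame.source_resolution,
    )
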