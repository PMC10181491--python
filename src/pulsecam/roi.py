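"""Face localisation and region-of-interest extraction.

Two detection modes mirror the two lightweight CNNs the pipeline is
designed around:

* **box** — a single-shot face detector (BlazeFace-class, 128x128 input)
  giving one bounding box; the whole face box is the ROI.
* **mesh** — a two-step face-mesh model (192x192 input) regressing 468
  3D landmarks; configured landmark-index sets define forehead and
  left/right cheek polygons, dropping face areas (eyes, mouth, hair)
  that carry no pulse signal.

The CNNs themselves are consumed through the adapter contract below:
anything callable on a FrameSample that returns a FaceDetection,
FaceLandmarks or None (no face). The shipped adapters are deterministic
fixtures driven by a synthetic-video spec, so the full pipeline and test
suite run without model downloads; a real model wraps into the same
contract (see ``letterbox`` for the input pre-processing step).

Coordinates are 0-based source-frame pixels; boxes are half-open on the
right/bottom edge.
"""
from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Protocol, Sequence, Tuple, Union

import numpy as np
from skimage.draw import polygon as _raster_polygon

from .errors import AdapterContractError
from .synthetic import (
    FOREHEAD_IDX,
    LEFT_CHEEK_IDX,
    N_MESH_POINTS,
    RIGHT_CHEEK_IDX,
    SyntheticSpec,
    fixture_detection,
)
from .video_io import FrameSample, resize_frame

__all__ = [
    "FaceDetection",
    "FaceLandmarks",
    "Region",
    "ROISet",
    "RoiImageEVM",
    "GreenSample",
    "DetectorAdapter",
    "FixtureBoxDetector",
    "FixtureMeshDetector",
    "letterbox",
    "extract_rois",
    "postprocess_evm",
    "postprocess_rppg",
    "write_rois_jsonl",
    "read_rois_jsonl",
    "DEFAULT_LANDMARK_SETS",
    "BOX_DETECTOR_INPUT",
    "MESH_DETECTOR_INPUT",
    "EVM_ROI_SIZE",
]

BOX_DETECTOR_INPUT: Tuple[int, int] = (128, 128)
MESH_DETECTOR_INPUT: Tuple[int, int] = (192, 192)
EVM_ROI_SIZE = 180

#: Landmark-index sets defining the mesh-mode polygons. Configuration
#: with documented defaults: indices refer to the fixture template, where
#: the first twelve points are the region corners. A real face-mesh
#: adapter supplies its own sets for the model's topology.
DEFAULT_LANDMARK_SETS: Dict[str, Tuple[int, ...]] = {
    "forehead": FOREHEAD_IDX,
    "left_cheek": LEFT_CHEEK_IDX,
    "right_cheek": RIGHT_CHEEK_IDX,
}


@dataclass
class FaceDetection:
    """One face bounding box with confidence and the detector's six
    keypoints (unused downstream, kept for contract fidelity)."""

    box: Tuple[int, int, int, int]  # (x, y, w, h)
    score: float
    landmarks6: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        if self.box[2] <= 0 or self.box[3] <= 0:
            raise ValueError(f"box must have positive size, got {self.box}")
        if not (0.0 <= self.score <= 1.0):
            raise ValueError("score must be in [0, 1]")


@dataclass
class FaceLandmarks:
    """468 (x, y, z) landmarks; x/y in source-frame pixels, z relative depth."""

    points: np.ndarray

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        if self.points.shape != (N_MESH_POINTS, 3):
            raise AdapterContractError(
                f"expected {N_MESH_POINTS} landmarks, got shape {self.points.shape}"
            )


@dataclass
class Region:
    """A named ROI: either an axis-aligned box or a polygon, in
    source-frame pixel coordinates."""

    kind: str  # "box" | "polygon"
    coords: np.ndarray  # box: [x, y, w, h]; polygon: Nx2 vertices (x, y)

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)

    def bounding_box(self) -> Tuple[int, int, int, int]:
        if self.kind == "box":
            x, y, w, h = self.coords
            return int(x), int(y), int(w), int(h)
        xs, ys = self.coords[:, 0], self.coords[:, 1]
        x0, y0 = int(np.floor(xs.min())), int(np.floor(ys.min()))
        x1, y1 = int(np.ceil(xs.max())), int(np.ceil(ys.max()))
        return x0, y0, x1 - x0, y1 - y0

    def mask(self, frame_shape: Tuple[int, int]) -> np.ndarray:
        """Boolean mask of the region rasterized onto (H, W)."""
        h, w = frame_shape
        m = np.zeros((h, w), dtype=bool)
        if self.kind == "box":
            x, y, bw, bh = (int(v) for v in self.coords)
            m[max(y, 0) : min(y + bh, h), max(x, 0) : min(x + bw, w)] = True
        else:
            rr, cc = _raster_polygon(self.coords[:, 1], self.coords[:, 0], shape=(h, w))
            m[rr, cc] = True
        return m


@dataclass
class ROISet:
    """Named regions extracted from one frame."""

    regions: Dict[str, Region]
    frame_index: int

    def __post_init__(self) -> None:
        if not self.regions:
            raise ValueError("ROISet requires at least one region")

    def union_mask(self, frame_shape: Tuple[int, int]) -> np.ndarray:
        m = np.zeros(frame_shape, dtype=bool)
        for region in self.regions.values():
            m |= region.mask(frame_shape)
        return m

    def union_bounding_box(self) -> Tuple[int, int, int, int]:
        boxes = [r.bounding_box() for r in self.regions.values()]
        x0 = min(b[0] for b in boxes)
        y0 = min(b[1] for b in boxes)
        x1 = max(b[0] + b[2] for b in boxes)
        y1 = max(b[1] + b[3] for b in boxes)
        return x0, y0, x1 - x0, y1 - y0


@dataclass
class RoiImageEVM:
    """Square float RGB crop feeding the EVM signal-processing stage."""

    pixels: np.ndarray  # 180 x 180 x 3 float32
    frame_index: int

    def __post_init__(self) -> None:
        if self.pixels.shape[:2] != (EVM_ROI_SIZE, EVM_ROI_SIZE):
            raise ValueError(
                f"EVM ROI must be {EVM_ROI_SIZE}x{EVM_ROI_SIZE}, got {self.pixels.shape[:2]}"
            )


@dataclass
class GreenSample:
    """Mean green-channel intensity over the ROI pixels of one frame."""

    value: float
    frame_index: int
    timestamp_s: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.value <= 255.0):
            raise ValueError(f"green mean {self.value} outside [0, 255]")


class DetectorAdapter(Protocol):
    """Contract every face detector plugs into.

    ``input_size`` is the (width, height) the underlying model consumes;
    callers may letterbox frames to it for timing realism. The call
    returns a FaceDetection (box mode), FaceLandmarks (mesh mode) or
    ``None`` when no face clears the score threshold.
    """

    input_size: Tuple[int, int]

    def __call__(self, frame: FrameSample) -> Union[FaceDetection, FaceLandmarks, None]:
        ...


def letterbox(pixels: np.ndarray, size: Tuple[int, int]) -> Tuple[np.ndarray, float, Tuple[int, int]]:
    """Aspect-preserving resize onto a padded square model input.

    Returns ``(image, scale, (pad_x, pad_y))`` where
    ``model_xy = source_xy * scale + pad`` maps source coordinates into
    the model input; invert it to map detections back.
    """
    tw, th = size
    h, w = pixels.shape[:2]
    scale = min(tw / w, th / h)
    nw, nh = max(1, int(round(w * scale))), max(1, int(round(h * scale)))
    resized = resize_frame(pixels, (nw, nh))
    out = np.zeros((th, tw, 3), dtype=pixels.dtype)
    pad_x, pad_y = (tw - nw) // 2, (th - nh) // 2
    out[pad_y : pad_y + nh, pad_x : pad_x + nw] = resized
    return out, scale, (pad_x, pad_y)


class FixtureBoxDetector:
    """Deterministic box detector backed by a synthetic-video spec.

    Mimics the real adapter's data flow (letterbox to 128x128, then
    "detect") but reads the face box straight from the spec. Scales the
    box when the incoming frame was resized relative to the spec
    resolution. ``no_face=True`` simulates a frame with no detection.
    """

    input_size = BOX_DETECTOR_INPUT

    def __init__(self, spec: SyntheticSpec, no_face: bool = False, score: float = 1.0):
        self.spec = spec
        self.no_face = no_face
        self.score = score

    def __call__(self, frame: FrameSample) -> Optional[FaceDetection]:
        letterbox(frame.pixels, self.input_size)  # adapter pre-process contract
        if self.no_face:
            return None
        det = fixture_detection(self.spec, mode="box")
        fw, fh = frame.resolution
        sw, sh = self.spec.resolution
        if (fw, fh) != (sw, sh):
            x, y, w, h = det.box
            sx, sy = fw / sw, fh / sh
            det = FaceDetection(
                box=(int(round(x * sx)), int(round(y * sy)),
                     max(1, int(round(w * sx))), max(1, int(round(h * sy)))),
                score=det.score,
            )
        return FaceDetection(box=det.box, score=self.score, landmarks6=det.landmarks6)


class FixtureMeshDetector:
    """Deterministic 468-landmark detector backed by a synthetic spec."""

    input_size = MESH_DETECTOR_INPUT

    def __init__(self, spec: SyntheticSpec, no_face: bool = False):
        self.spec = spec
        self.no_face = no_face

    def __call__(self, frame: FrameSample) -> Optional[FaceLandmarks]:
        letterbox(frame.pixels, self.input_size)
        if self.no_face:
            return None
        lm = fixture_detection(self.spec, mode="mesh")
        fw, fh = frame.resolution
        sw, sh = self.spec.resolution
        if (fw, fh) != (sw, sh):
            pts = lm.points.copy()
            pts[:, 0] *= fw / sw
            pts[:, 1] *= fh / sh
            lm = FaceLandmarks(points=pts)
        return lm


def _clamp_box(
    box: Tuple[int, int, int, int], frame_shape: Tuple[int, int]
) -> Optional[Tuple[int, int, int, int]]:
    h, w = frame_shape
    x, y, bw, bh = box
    x0, y0 = max(int(x), 0), max(int(y), 0)
    x1, y1 = min(int(x + bw), w), min(int(y + bh), h)
    if x1 <= x0 or y1 <= y0:
        return None
    return x0, y0, x1 - x0, y1 - y0


def extract_rois(
    frame: FrameSample,
    det: Union[FaceDetection, FaceLandmarks],
    mode: str = "box",
    landmark_sets: Optional[Dict[str, Sequence[int]]] = None,
) -> Optional[ROISet]:
    """Turn a detection into named ROIs in source-frame coordinates.

    Box mode yields a single ``face`` region (the detection box, clamped
    to the frame); mesh mode yields forehead / left_cheek / right_cheek
    polygons from the configured landmark-index sets. Returns ``None``
    for a degenerate (zero-area after clamping) result, which the
    pipeline treats like a missed detection.
    """
    h, w = frame.pixels.shape[:2]
    if mode == "box":
        if not isinstance(det, FaceDetection):
            raise TypeError("box mode requires a FaceDetection")
        clamped = _clamp_box(det.box, (h, w))
        if clamped is None:
            return None
        return ROISet(
            regions={"face": Region(kind="box", coords=np.array(clamped, dtype=float))},
            frame_index=frame.index,
        )
    if mode == "mesh":
        if not isinstance(det, FaceLandmarks):
            raise TypeError("mesh mode requires FaceLandmarks")
        sets = landmark_sets or DEFAULT_LANDMARK_SETS
        regions: Dict[str, Region] = {}
        for name, idx in sets.items():
            poly = det.points[list(idx), :2].copy()
            poly[:, 0] = np.clip(poly[:, 0], 0, w - 1)
            poly[:, 1] = np.clip(poly[:, 1], 0, h - 1)
            region = Region(kind="polygon", coords=poly)
            if region.mask((h, w)).sum() > 0:
                regions[name] = region
        if not regions:
            return None
        return ROISet(regions=regions, frame_index=frame.index)
    raise ValueError(f"unknown ROI mode {mode!r}")


def postprocess_evm(
    frame: FrameSample,
    rois: ROISet,
    out_size: int = EVM_ROI_SIZE,
    mesh_merge: str = "zero",
) -> RoiImageEVM:
    """Crop the ROI to the square fixed-size image EVM consumes.

    Box mode crops the face box; mesh mode crops the bounding box of the
    union of the three regions and, when ``mesh_merge="zero"`` (default),
    zeroes the pixels outside the polygon masks before resizing
    (``"crop"`` keeps them).
    """
    h, w = frame.pixels.shape[:2]
    x, y, bw, bh = rois.union_bounding_box()
    clamped = _clamp_box((x, y, bw, bh), (h, w))
    if clamped is None:
        raise ValueError("degenerate ROI bounding box")
    x, y, bw, bh = clamped
    crop = frame.pixels[y : y + bh, x : x + bw].astype(np.float32)
    is_mesh = any(r.kind == "polygon" for r in rois.regions.values())
    if is_mesh and mesh_merge == "zero":
        mask = rois.union_mask((h, w))[y : y + bh, x : x + bw]
        crop = crop * mask[:, :, None]
    out = resize_frame(crop, (out_size, out_size)).astype(np.float32)
    return RoiImageEVM(pixels=out, frame_index=frame.index)


def postprocess_rppg(frame: FrameSample, rois: ROISet) -> Optional[GreenSample]:
    """Mean green-channel intensity over the (pixel-weighted) union of the
    ROI regions, at native frame resolution."""
    h, w = frame.pixels.shape[:2]
    green = frame.pixels[:, :, 1]
    if all(r.kind == "box" for r in rois.regions.values()) and len(rois.regions) == 1:
        x, y, bw, bh = next(iter(rois.regions.values())).bounding_box()
        clamped = _clamp_box((x, y, bw, bh), (h, w))
        if clamped is None:
            return None
        x, y, bw, bh = clamped
        value = float(green[y : y + bh, x : x + bw].mean())
    else:
        mask = rois.union_mask((h, w))
        if not mask.any():
            return None
        value = float(green[mask].mean())
    return GreenSample(value=value, frame_index=frame.index, timestamp_s=frame.timestamp_s)


def write_rois_jsonl(rois: Iterable[ROISet], path: str | Path) -> None:
    """Serialize ROI sets as JSON lines so detection and signal stages
    can be exercised independently."""
    with open(path, "w") as fh:
        for rs in rois:
            rec = {
                "frame_index": rs.frame_index,
                "regions": {
                    name: {"kind": r.kind, "coords": r.coords.tolist()}
                    for name, r in rs.regions.items()
                },
            }
            fh.write(json.dumps(rec) + "\n")


def read_rois_jsonl(path: str | Path) -> List[ROISet]:
    out: List[ROISet] = []
    with open(path) as fh:
        for line in fh:
            if not line.strip():
                continue
            rec = json.loads(line)
            regions = {
                name: Region(kind=r["kind"], coords=np.asarray(r["coords"], dtype=float))
                for name, r in rec["regions"].items()
            }
            out.append(ROISet(regions=regions, frame_index=int(rec["frame_index"])))
    return out
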