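"""Pipeline orchestration, per-stage timing and evaluation metrics.

The per-frame pipeline follows the generic edge block diagram:

    Read Frame -> CNN -> Post-Process -> (Buffer ->) Signal Process
               -> Overlay/Display (optional)

Each stage is timed with a monotonic clock; per-stage means exclude a
configurable number of warm-up frames (default 10) so one-time costs
(allocations, cache warming) do not skew the averages.

Evaluation metrics:

* latency — mean per-stage wall time in ms;
* throughput — FPS = 1 / total per-frame latency; both the sum of the
  five stage means and the measured whole-frame time are exposed, since
  loop overhead makes them differ slightly;
* accuracy — ``100 - 100*|estimation - real| / estimation`` (from an
  estimate/reference pair) or ``100 - error%``;
* value — FPS / device cost (USD); efficiency — FPS / average power (W).
  Cost and power are user-supplied inputs: power comes from an external
  meter, never from software.
"""
from __future__ import annotations

import csv
import json
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np

from .errors import SignalError
from .evm import EVMConfig, EVMEngine
from .roi import (
    DetectorAdapter,
    extract_rois,
    postprocess_evm,
    postprocess_rppg,
)
from .rppg import RPPGConfig, estimate_vitals_rppg
from .video_io import FrameSample, FrameStream, resize_for_evm
from .vitals import DEFAULT_BUFFER_FRAMES, SignalBuffer, VitalsEstimate

__all__ = [
    "STAGES",
    "PlatformInfo",
    "BenchmarkReport",
    "run_pipeline",
    "fps",
    "value_metric",
    "efficiency_metric",
    "accuracy_eq1",
    "accuracy_eq2",
    "stage_share",
    "average_fps",
    "write_vitals_csv",
]

#: The five pipeline stages, in execution order.
STAGES: Tuple[str, ...] = (
    "read_frame",
    "cnn",
    "post_process",
    "signal_process",
    "overlay_display",
)


@dataclass
class PlatformInfo:
    """User-supplied device facts for value/efficiency metrics."""

    name: str = "local"
    cost_usd: Optional[float] = None
    avg_power_w: Optional[float] = None


@dataclass
class BenchmarkReport:
    """Per-stage latency statistics and derived throughput metrics."""

    method: str
    stage_means_ms: Dict[str, float]
    n_frames: int
    n_estimates: int
    n_skipped: int
    warmup_frames: int
    measured_total_latency_ms: float  # mean whole-frame wall time
    platform: PlatformInfo = field(default_factory=PlatformInfo)
    per_resolution_fps: Dict[str, float] = field(default_factory=dict)

    @property
    def total_stage_latency_ms(self) -> float:
        return float(sum(self.stage_means_ms.values()))

    @property
    def fps_from_stages(self) -> float:
        return fps(self.total_stage_latency_ms / 1000.0)

    @property
    def fps_measured(self) -> float:
        return fps(self.measured_total_latency_ms / 1000.0)

    @property
    def stage_shares(self) -> Dict[str, float]:
        return stage_share(self.stage_means_ms)

    @property
    def value(self) -> Optional[float]:
        if self.platform.cost_usd is None:
            return None
        return value_metric(self.fps_measured, self.platform.cost_usd)

    @property
    def efficiency(self) -> Optional[float]:
        if self.platform.avg_power_w is None:
            return None
        return efficiency_metric(self.fps_measured, self.platform.avg_power_w)

    def to_dict(self) -> dict:
        return {
            "method": self.method,
            "stage_means_ms": dict(self.stage_means_ms),
            "n_frames": self.n_frames,
            "n_estimates": self.n_estimates,
            "n_skipped": self.n_skipped,
            "warmup_frames": self.warmup_frames,
            "measured_total_latency_ms": self.measured_total_latency_ms,
            "platform": {
                "name": self.platform.name,
                "cost_usd": self.platform.cost_usd,
                "avg_power_w": self.platform.avg_power_w,
            },
            "per_resolution_fps": dict(self.per_resolution_fps),
            "derived": {
                "total_stage_latency_ms": self.total_stage_latency_ms,
                "fps_from_stages": self.fps_from_stages,
                "fps_measured": self.fps_measured,
                "stage_shares_percent": self.stage_shares,
                "value": self.value,
                "efficiency": self.efficiency,
            },
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))

    @classmethod
    def from_dict(cls, d: dict) -> "BenchmarkReport":
        p = d.get("platform", {})
        return cls(
            method=d["method"],
            stage_means_ms=dict(d["stage_means_ms"]),
            n_frames=int(d["n_frames"]),
            n_estimates=int(d["n_estimates"]),
            n_skipped=int(d["n_skipped"]),
            warmup_frames=int(d["warmup_frames"]),
            measured_total_latency_ms=float(d["measured_total_latency_ms"]),
            platform=PlatformInfo(
                name=p.get("name", "local"),
                cost_usd=p.get("cost_usd"),
                avg_power_w=p.get("avg_power_w"),
            ),
            per_resolution_fps=dict(d.get("per_resolution_fps", {})),
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "BenchmarkReport":
        return cls.from_dict(json.loads(Path(path).read_text()))


def fps(total_latency_s: float) -> float:
    """Throughput = 1 / total per-frame latency (seconds)."""
    if total_latency_s <= 0:
        raise ValueError("total latency must be positive")
    return 1.0 / total_latency_s


def value_metric(fps_value: float, cost_usd: float) -> float:
    """Value = FPS / device cost in USD."""
    if cost_usd <= 0:
        raise ValueError("cost must be positive")
    if fps_value < 0:
        raise ValueError("fps must be non-negative")
    return fps_value / cost_usd


def efficiency_metric(fps_value: float, avg_power_w: float) -> float:
    """Efficiency = FPS / mean power draw in watts."""
    if avg_power_w <= 0:
        raise ValueError("power must be positive")
    if fps_value < 0:
        raise ValueError("fps must be non-negative")
    return fps_value / avg_power_w


def accuracy_eq1(estimation: float, real: float) -> float:
    """Accuracy(%) = 100 - 100*|estimation - real| / estimation.

    The magnitude of the relative deviation is used so accuracy never
    exceeds 100% regardless of the error's sign.
    """
    if estimation == 0:
        raise ValueError("estimation must be nonzero")
    return 100.0 - 100.0 * abs(estimation - real) / abs(estimation)


def accuracy_eq2(error_percent: float) -> float:
    """Accuracy(%) = 100 - error(%)."""
    if not (0.0 <= error_percent <= 100.0):
        raise ValueError("error must be in [0, 100]")
    return 100.0 - error_percent


def stage_share(stage_means_ms: Dict[str, float]) -> Dict[str, float]:
    """Percent of total mean latency spent in each stage."""
    total = sum(stage_means_ms.values())
    if total <= 0:
        raise ValueError("total mean latency must be positive")
    return {k: 100.0 * v / total for k, v in stage_means_ms.items()}


def average_fps(per_resolution_fps: Sequence[float]) -> float:
    """Arithmetic mean FPS over resolutions, reported to one decimal."""
    vals = list(per_resolution_fps)
    if not vals:
        raise ValueError("need at least one FPS value")
    return round(float(np.mean(vals)), 1)


def _overlay(frame: FrameSample, box: Optional[Tuple[int, int, int, int]]) -> np.ndarray:
    """Headless-safe overlay: draw the detection box into a copy of the
    frame (no GUI window is ever opened)."""
    img = frame.pixels.copy()
    if box is not None:
        x, y, w, h = box
        h_img, w_img = img.shape[:2]
        x0, y0 = max(x, 0), max(y, 0)
        x1, y1 = min(x + w, w_img - 1), min(y + h, h_img - 1)
        color = np.array([0, 255, 0], dtype=img.dtype)
        img[y0, x0:x1] = color
        img[y1, x0:x1] = color
        img[y0:y1, x0] = color
        img[y0:y1, x1] = color
    return img


def run_pipeline(
    stream: FrameStream,
    method: str,
    detector: DetectorAdapter,
    roi_mode: str = "box",
    buffer_frames: int = DEFAULT_BUFFER_FRAMES,
    fs: float = 30.0,
    rppg_cfg: Optional[RPPGConfig] = None,
    evm_cfg: Optional[EVMConfig] = None,
    warmup_frames: int = 10,
    overlay: bool = False,
    platform: Optional[PlatformInfo] = None,
    max_frames: Optional[int] = None,
) -> Tuple[List[VitalsEstimate], BenchmarkReport]:
    """Run the full per-frame pipeline over a stream, timing every stage.

    Estimates are emitted every frame once the buffer is full (sliding
    window). Frames without a detection are skipped without disturbing
    the buffer order. Returns the estimate list and the timing report.
    """
    if method not in ("evm", "rppg"):
        raise ValueError("method must be 'evm' or 'rppg'")
    timings: Dict[str, List[float]] = {s: [] for s in STAGES}
    frame_times: List[float] = []
    estimates: List[VitalsEstimate] = []
    n_frames = n_skipped = 0

    if method == "rppg":
        buffer = SignalBuffer(capacity=buffer_frames, fs=fs)
        rppg_cfg = rppg_cfg or RPPGConfig(fs=fs)
    else:
        evm_cfg = evm_cfg or EVMConfig(fs=fs)
        engine = EVMEngine(capacity=buffer_frames, cfg=evm_cfg)

    it = iter(stream)
    while True:
        t_frame0 = time.perf_counter()

        # --- Read Frame (incl. the EVM working-resolution resize) ---
        t0 = time.perf_counter()
        try:
            frame = next(it)
        except StopIteration:
            break
        if method == "evm":
            frame = resize_for_evm(frame)
        timings["read_frame"].append(time.perf_counter() - t0)
        n_frames += 1

        # --- CNN ---
        t0 = time.perf_counter()
        det = detector(frame)
        timings["cnn"].append(time.perf_counter() - t0)

        # --- Post-Process ---
        t0 = time.perf_counter()
        product = None
        box = None
        if det is not None:
            rois = extract_rois(frame, det, mode=roi_mode)
            if rois is not None:
                box = rois.union_bounding_box()
                if method == "evm":
                    product = postprocess_evm(frame, rois)
                else:
                    product = postprocess_rppg(frame, rois)
        timings["post_process"].append(time.perf_counter() - t0)

        # --- Buffer + Signal Process ---
        t0 = time.perf_counter()
        if product is None:
            n_skipped += 1
        elif method == "rppg":
            if buffer.push(product):
                estimates.append(estimate_vitals_rppg(buffer, rppg_cfg))
        else:
            if engine.push(product):
                estimates.append(engine.estimate())
        timings["signal_process"].append(time.perf_counter() - t0)

        # --- Overlay/Display (optional, headless-safe) ---
        if overlay:
            t0 = time.perf_counter()
            _overlay(frame, box)
            timings["overlay_display"].append(time.perf_counter() - t0)

        frame_times.append(time.perf_counter() - t_frame0)
        if max_frames is not None and n_frames >= max_frames:
            break

    if n_frames == 0:
        raise SignalError("stream yielded no frames")

    skip = min(warmup_frames, max(n_frames - 1, 0))
    stage_means = {}
    for name in STAGES:
        lat = timings[name][skip:]
        if lat:
            stage_means[name] = 1000.0 * float(np.mean(lat))
        elif name != "overlay_display":  # disabled overlay drops its row
            stage_means[name] = 0.0
    report = BenchmarkReport(
        method=method,
        stage_means_ms=stage_means,
        n_frames=n_frames,
        n_estimates=len(estimates),
        n_skipped=n_skipped,
        warmup_frames=skip,
        measured_total_latency_ms=1000.0 * float(np.mean(frame_times[skip:])),
        platform=platform or PlatformInfo(),
    )
    return estimates, report


def write_vitals_csv(estimates: Iterable[VitalsEstimate], path: str | Path) -> None:
    """Write the estimate stream as CSV (frame_index, method, hr_bpm, rr_bpm)."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["frame_index", "method", "hr_bpm", "rr_bpm"])
        for e in estimates:
            writer.writerow([e.frame_index, e.method, e.hr_bpm, e.rr_bpm])


def write_report_csv(report: BenchmarkReport, path: str | Path) -> None:
    """Stage-latency table row in the style of the benchmark tables."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        header = ["method"] + [f"{s} (ms)" for s in report.stage_means_ms] + [
            "total (ms)", "fps_measured", "fps_from_stages",
        ]
        writer.writerow(header)
        writer.writerow(
            [report.method]
            + [f"{v:.3f}" for v in report.stage_means_ms.values()]
            + [
                f"{report.total_stage_latency_ms:.3f}",
                f"{report.fps_measured:.2f}",
                f"{report.fps_from_stages:.2f}",
            ]
        )
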