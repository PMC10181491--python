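"""Per-stage latency profiling and the throughput/value/efficiency metrics.

Times every pipeline stage (Read Frame, CNN, Post-Process, Signal
Process, Overlay/Display) over a synthetic clip, then derives FPS and —
given a user-supplied device cost and measured average power — the
value (FPS/USD) and efficiency (FPS/W) figures of merit. Absolute
latencies are hardware-dependent; the metric arithmetic is not.
"""
from pulsecam import (
    FixtureBoxDetector,
    PlatformInfo,
    StreamSpec,
    SyntheticSpec,
    open_source,
    run_pipeline,
)

spec = SyntheticSpec(duration_s=8.0)
stream = open_source(StreamSpec(source=spec, nominal_fps=spec.fps))
platform = PlatformInfo(name="workstation", cost_usd=900.0, avg_power_w=111.7)
estimates, report = run_pipeline(
    stream, method="rppg", detector=FixtureBoxDetector(spec), fs=spec.fps,
    overlay=True, platform=platform,
)

print(f"{report.n_frames} frames, {report.n_estimates} estimates, "
      f"warm-up excluded: {report.warmup_frames} frames")
for stage, ms in report.stage_means_ms.items():
    print(f"  {stage:16s} {ms:7.3f} ms  ({report.stage_shares[stage]:5.1f}% of stage total)")
print(f"sum of stages: {report.total_stage_latency_ms:.2f} ms "
      f"-> {report.fps_from_stages:.1f} FPS")
print(f"measured whole-frame latency: {report.measured_total_latency_ms:.2f} ms "
      f"-> {report.fps_measured:.1f} FPS")
print(f"value      = FPS/cost  = {report.value:.4f} FPS/USD")
print(f"efficiency = FPS/power = {report.efficiency:.3f} FPS/W")
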