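# Methods

## Signal model and pipeline

Both engines share one per-frame pipeline: frames are decoded (or
generated), a face detector locates the region of interest, a per-method
post-processing step reduces the frame to its signal product, products
accumulate in a fixed-capacity buffer, and once the buffer is full a
spectral estimator emits one heart-rate/respiratory-rate estimate per
frame (sliding window). Internally every frame is an H×W×3 uint8 RGB
array; any decoder that emits BGR is converted at the I/O boundary so
"green" is always channel 1.

**Buffering.** The buffer holds 180 frames and behaves as a shift
register: after the first fill, each push drops the oldest product. At
30 fps this is a 6 s window with spectral resolution fs/n = 1/6 Hz
(10 bpm per FFT bin for HR, 10 breaths/min for RR). Frames without a
detection are skipped without disturbing buffer order; estimates simply
arrive later. File and synthetic timestamps are synthesized as
`index/fps` (containers' presentation timestamps vary by dialect and the
pipeline assumes a nominal fixed rate); live cameras use a monotonic
clock, which is what the uniform-grid resampling step in the rPPG chain
exists to clean up.

**Frequency bands.** HR 0.83–3.0 Hz (50–180 bpm), RR 0.18–0.5 Hz (11–30
breaths/min). Band edges are inclusive and kept as printed (0.83 Hz
rather than 50/60 Hz exactly). Peak picking is the argmax over in-band
bins with ties broken toward the lower frequency; there is no sub-bin
interpolation, so estimates are quantised to the bin grid by design.

## rPPG (GREEN)

The trace is the mean green intensity over the ROI pixels at native
resolution. Per window: smoothness-priors detrend → linear resample onto
a uniform time grid of the same span and length → Hamming taper
(w[k] = 0.54 − 0.46·cos(2πk/(n−1))) → division by the L2 norm → one-sided
amplitude spectrum (|DFT|/n, interior bins doubled; Parseval pins the
convention in the tests). Detrending makes the chain invariant to
intensity offsets and the L2 norm to gain, which the tests assert as an
affine-invariance property.

**Detrending parameter.** The trend solves (I + λ²D₂ᵀD₂)t = z with D₂
the second-difference operator; the detrended signal is z − t. The
filter is a high-pass whose half-power point sits near f ≈ fs/(2π√λ).
Default λ = 300 — the canonical smoothness-priors setting for
cardiovascular time series — puts the cutoff near 0.28 Hz at 30 fps:
illumination drift and slow baseline wander are removed, the HR band
passes with gain ≈ 1, and the respiratory band is attenuated but
detectable (gain ≈ 0.45 at 0.25 Hz). Much smaller λ is unusable here:
λ = 10 moves the half-power point to ≈ 1.5 Hz, inside the HR band, and
attenuates 0.25 Hz by ≈ 2000×, erasing the respiratory signal. A
moving-average-subtraction detrender is config-selectable for
comparison. The solve is a sparse banded system (n = 180), so cost is
negligible.

**"Interpolating by one."** Resampling is linear interpolation onto a
uniform n-point grid spanning the first-to-last timestamp — i.e. onto a
unit-spaced index grid — which is the identity when sampling was already
uniform. The alternative reading (upsampling by one extra sample) would
change the window length without addressing non-periodic sampling, which
is the stated purpose of the step.

## EVM

Per 180×180 ROI frame, a Gaussian pyramid (5-tap binomial kernel
[1,4,6,4,1]/16, blur-then-decimate, ceil halving: 180 → 90 → 45 → 23 at
the default 3 levels) and from it a Laplacian pyramid
L_k = G_k − up(G_{k+1}), top level = Gaussian top. Upsampling zero-stuffs
by 2, blurs with the doubled kernel, and trims to the partner level's
exact shape, so collapsing reconstructs the input to float precision.
Convolutions use whole-sample-symmetric ("mirror") boundaries: with
edge-repeating reflection the zero-stuffed upsample fails to preserve
constant images at the border, which would leak spurious energy into the
bandpass levels of a static scene.

The temporal filter is an ideal (brick-wall) bandpass applied per pixel
along the window: FFT in time, zero every bin outside the band, inverse
FFT. It is a projection, hence idempotent, and passes a bin-centred
in-band sinusoid unchanged — both are regression-tested identities.

**Estimation path.** Rates are read from the spatial mean of the
band-passed *coarsest* Laplacian level (the Gaussian top) of the green
channel. The coarsest level aggregates the largest spatial support,
maximising SNR for a global skin-colour oscillation; green matches the
rPPG engine so the two are directly comparable (channel and level are
configurable). When a band's spectral mass is below 1e-12 (a static
input) the engine reports "no estimate" (`None`) instead of an arbitrary
argmax. Amplification (α, default 50) and pyramid recollapse are a
visualisation-only path and do not feed estimation.

The streaming engine caches each frame's coarsest level at push time, so
per-frame estimates cost one pyramid per new frame rather than 180; it
is numerically identical to the batch function and tested as such.

## ROI extraction

Box mode uses the single best face box (score threshold 0.5, single
subject). Mesh mode builds forehead and left/right cheek polygons from
configured landmark-index sets; the defaults index the fixture
template's designated corner points, and a real face-mesh adapter
supplies sets matching its topology. For EVM the union bounding box of
the mesh regions is cropped, out-of-mask pixels zeroed (config flag
`mesh_merge="crop"` keeps them), and the crop resized to 180×180; for
rPPG the green mean is taken over the pixel-weighted union of regions at
native resolution — per-region averaging followed by a region mean would
weight small regions up, which has no physical justification here.
Downscaling uses area averaging (exact block means for integral factors)
and upscaling bilinear interpolation; both preserve constant images,
which several contracts rely on.

Detection models are consumed through an adapter contract (frame in;
box + score, 468 landmarks, or `None` out; `input_size` documents the
model's expected input for letterboxing). The package ships
deterministic fixture adapters driven by the synthetic spec, so the full
pipeline and test suite run with no model files.

## Synthetic data

The generator emulates the one optical phenomenon the methods rely on: a
static frontal face whose green channel oscillates at the cardiac
frequency, amplitude-modulated by respiration, with a direct additive
respiratory term and i.i.d. per-pixel Gaussian noise, clipped to uint8.
Defaults — 640×360 at 30 fps for 12 s, 160×160 face box, HR 1.2 Hz with
amplitude 2 intensity units, RR 0.25 Hz with modulation depth 0.3 and
additive amplitude 1, noise σ = 1, seed 7 — represent a realistic
pulse-signal strength (a few intensity units on skin) at a comfortable
ROI-mean SNR, since averaging ~25k ROI pixels shrinks the noise on the
trace by ~160×. The cardiac waveform is a pure sinusoid so spectral
ground truth is a single line (a skewed-pulse option exists); an
optional linear illumination ramp exercises detrending.

What the generator does **not** model: head motion, photorealistic skin
texture, specular highlights, lighting flicker, camera compression
artefacts, or the spatially varying pulse amplitude of real faces.
Passing tests therefore demonstrate correctness of the signal chain and
its contracts — quantisation-limited parameter recovery, band
separation, buffering semantics — not clinical accuracy on human
subjects.

## Benchmarking

Stage latencies use `time.perf_counter` around each stage body; the
first 10 frames are excluded from means as warm-up (JIT-free Python
still pays allocator and cache warm-up costs early). FPS is reported two
ways: 1/(sum of stage means) and 1/(measured whole-frame time); loop
overhead makes the printed stage sums of published tables not invert
exactly to their printed FPS, and exposing both makes that visible.
Value (FPS/USD) and efficiency (FPS/W) take cost and power as inputs —
power must come from an external meter. Accuracy formulas use
|estimation − real|: the magnitude keeps accuracy ≤ 100% for either
error sign, which is how the quantity is used in practice. The overlay
stage is optional and headless-safe (it draws into an array, never opens
a window); disabling it removes its timing row without changing
estimates.

Test and acceptance problem sizes: the single-spec recovery checks run
the full default 12 s clip; the 50-seed recovery sweep runs a 320×180
geometry with a proportionally scaled face box, which changes only the
(already negligible) noise on the ROI mean while keeping every study
condition — rates, amplitudes, fs, buffer, SNR ≥ 3 — intact.

## Known limitations

* No container codecs are bundled: MP4/AVI decode works only where an
  imageio plugin supports it; numbered image sequences are the portable
  file path.
* Single subject, single face; no tracking between frames.
* Estimates are bin-quantised (10 bpm at the default window); clinical
  use would need longer windows or sub-bin interpolation, both out of
  scope.
* The respiratory band at the default window holds only two FFT bins
  (1/3 and 1/2 Hz), so RR estimates are coarse by construction.
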