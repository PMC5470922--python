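# Methods

## Background model

Each pixel stores `n_samples` (N, default 20) raw observed values.
Classification counts stored samples within strict Euclidean distance
`radius` (R, default 20, in 8-bit pixel-value units) of the current
value; at least `min_matches` (λ, default 2) matches make the pixel
background.  The pseudo-code convention `matches ≥ λ` is used (the
boundary case λ exact matches is background).  Distances are Euclidean
in the k-dimensional value space — k = 3 for color and fused frames,
k = 1 for depth-only runs — with no color-space conversion.

Initialization draws all N samples of a pixel uniformly with
replacement from the pixel's 8-neighborhood including itself in frame
1 (border pixels use their clipped in-bounds neighborhood).  This
makes frame 1 classifiable, at the cost that frame-1 foreground is
adopted into the model — which is precisely how ghosts arise, and what
the depth path later corrects.

Updating is memoryless: a background-classified pixel replaces, with
probability 1/ϕ (`subsample_factor`, default 16), one uniformly chosen
sample of its own bag with the current value, and independently, with
probability 1/ϕ, one uniformly chosen sample of one uniformly chosen
in-bounds 8-neighbor (no wrap-around; the *current pixel's* value is
inserted).  The expected per-update survival of a stored sample is
(N−1)/N, hence ((N−1)/N)^dt = exp(−ln(N/(N−1))·dt) after dt update
opportunities; folding in the 1/ϕ pixel-selection coin, a sample of a
permanently-background pixel survives a frame with probability
1 − 1/(Nϕ) under the self-update channel.

## Depth path

Raw depth is millimeters, 0 meaning the active-IR sensor returned
nothing (a hole).  `to_proximity` maps valid depth linearly onto
[0, 1] with closer = larger, clipping at `max_range_mm` (default
8000 mm, the practical range of consumer structured-light sensors);
holes map to 0.  The uncertainty is the exact complement,
σ = 1 − proximity, so holes and far surfaces are maximally uncertain.

Fusion is applied per color channel with a shared depth term:
Î = ½[(1−σ)d̂ + (1+σ)ĉ], with ĉ the color channel divided by 255.
At σ = 1 this is exactly ĉ (holes fall back to color); at σ = 0 it is
the color–proximity average.  Pre-rescale values lie in [0, 1.5] and
are multiplied by 255/1.5 = 170 onto the usual 8-bit working scale, so
the default R = 20 retains its customary meaning; the fused frame is a
3-channel image classified by the unchanged sample-model machinery.
(A 4-channel variant — appending depth as an extra channel — was the
obvious alternative; the 3-channel form keeps R's scale interpretable
and needs no per-channel reweighting.)

The depth model MD(x) is a single reference proximity per pixel,
initialized from frame 1.  A foreground-labelled pixel is a ghost when
MD(x) − d̂(x) > τ on the 8-bit proximity scale (both values ×255).
The comparison is deliberately *signed*: a ghost is physically a
surface that moved away (proximity dropped), and an unsigned distance
would also fire on approaching objects, erasing genuine foreground.
τ defaults to 2 on that scale and is configuration, as is the scale
itself — the conventional recommendation τ ∈ [1, 3] comes without
units, so the choice of scale is ours and documented rather than
asserted.

Ghost-reclassified pixels are stored as background and update the
*sample* model (self + neighbor channels), but **not** the depth
model.  This placement matters: the depth reference must keep
remembering the departed object until the sample model has genuinely
absorbed the revealed background — only then does the pixel stop
reaching the ghost branch, and only genuinely-matched pixels refresh
MD(x).  Refreshing MD(x) on the ghost branch lets the single-value
depth reference converge (rate 1/ϕ per frame) far faster than the
20-sample color model (which needs ≥ λ matching samples), silencing
the ghost test while the stale color samples still misfire; in our
ghost experiment this raised the steady-state ghost-region FP fraction
from ~0.004 to ~0.35.  Hole pixels do write proximity 0 into MD(x)
when matched, which is faithful to treating the current reading as the
reference; a pixel that was a hole in frame 1 (MD = 0) can never fire
the ghost test and may linger as an isolated false positive — visible
as the single residual pixel in the worked example.

## Frame loop and randomness

Per frame, fusion is computed for the whole frame; classification uses
the model as it stood at the end of the previous frame; all updates
are then applied in one vectorized pass.  (The classical formulation
updates in raster order so an early pixel's neighbor-write can affect
a later pixel within the same frame; deferring the writes by less than
one frame changes nothing measurable at ϕ = 16 and makes the frame
loop array-parallel, which is what keeps the experiments below in
seconds.)  When several pixels elect the same neighbor slot in a
frame, the highest flat pixel index wins — a deterministic tie-break.

Random draws are whole-frame arrays in a fixed order (self coin, self
slot, neighbor coin, neighbor choice, neighbor slot), drawn for
*every* pixel and gated by the background mask afterwards.  Stream
consumption therefore does not depend on classification outcomes, so
two runs sharing a seed and frame geometry stay in lockstep even if
their masks differ.  DEVB's depth model consumes an independent child
stream (`SeedSequence(seed).spawn`).  Together these give the exact
reduction: with τ = ∞ and constant-proximity depth, DEVB's masks equal
a plain ViBe run on the fused frames bit-for-bit under the same seed.
Identical seed + identical inputs ⇒ bit-identical trajectories,
masks, PNGs and CSVs.

## Synthetic study conditions

The generator renders what a consumer RGB-D camera sees in a fixed
indoor scene, and its defaults are the conditions every experiment
uses: a 64×64 background plane at 3000 mm, color (100,100,100) with
frozen i.i.d. uniform ±5 texture; depth holes as an independent
per-pixel, per-frame 1% coin (5% in the dedicated holes scenario,
matching the heavy speckle of real sensors near edges); optional
global illumination flicker (±20 gray levels) with per-frame texture
redraw.  The ghost inducer is a quarter-frame (16×16) object at
1500 mm present only in frame 1.  The black-shadow pair: object A
(150,150,150) at 2200 mm on region Q in frame 1 only; object B
(155,155,155) — a 5-gray-level look-alike, far inside R = 20 for a
color-only matcher — at 600 mm crossing Q at 4 px/frame from frame 9.
The depth separation (≈ 51 proximity levels between A and B) is what a
Kinect actually reports for a person walking a meter and a half in
front of furniture, and is what lets the fused value of B clear R
against A's stored samples.

What the generator does *not* emulate: texture on objects, soft
shadows and reflections, depth noise correlated with surface geometry,
motion blur, or camera motion.  Passing tests therefore demonstrate
the mechanism (ghost suppression, black-shadow robustness, the update
law) under controlled conditions, not field performance on recorded
video, which additionally stresses the color model's tolerance R.

## Experiment sizes and numerical choices

The lifespan experiment tags all frame-1 samples of a 100×100 static
scene (200 000 tags) and runs T = 320 frames through the real update
path with the *spatial channel disabled*: the expected law
(1 − 1/(Nϕ))^T describes only the pixel's own subsampling, and the
neighbor channel adds a second, comparable hazard (≈ doubling the
decay rate for interior pixels) that the law deliberately does not
model.  The 3σ acceptance band uses the binomial standard deviation of
the mean, which is conservative given the slight negative correlation
of slot deaths within a pixel.  Ghost and black-shadow experiments use
64×64 scenes of 60 and 30 frames; these sizes put every experiment
under a few seconds while leaving Monte-Carlo bands narrow.

Matching uses strict `<` with squared distances (no square roots);
model storage is float32, scalar utilities compute in float64.  The
16-bit depth "bit-shuffle" dialect of public benchmark PNGs is
implemented as both 3-bit rotations (each the other's inverse,
verified exhaustively over all 65 536 values) because the prose
description of the shuffle is ambiguous; the default is no transform.
PWC is undefined (raises) on zero evaluated pixels; an optional ignore
mask excludes unknown regions from all four confusion buckets, and
omitting it reproduces the plain whole-image metric.

## Known limitations

- A frame-1 depth hole freezes MD(x) = 0 there; the ghost test can
  then never fire for that pixel (see above).
- The ghost test reclassifies *any* foreground pixel whose current
  depth reading is a hole (MD > 0 = d̂), so genuine foreground standing
  on a sensor dropout is suppressed for that frame.  At realistic hole
  rates this costs ~1% recall.
- A foreground object that stays still long enough is absorbed into
  the model at rate 1/ϕ, as in all conservative background-subtraction
  schemes.
- The fusion assumes color and depth are co-registered and synchronous;
  no calibration, hole-filling or depth denoising is performed.
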