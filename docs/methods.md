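# Methods

## Problem and model

Iris recognition degrades when eyelids and eyelashes occlude the iris
texture. The package implements a two-stage generative adversarial
inpainting method for such occlusions, together with the surrounding
pipeline: geometric preprocessing, occlusion-dataset construction, and
objective evaluation.

**Stage 1 (coarse repair).** A U-Net — four encoder layers of two
Conv3×3–BN–LReLU modules plus 2×2 max pooling, a two-module transition at
the 16×16 bottleneck (for 256×256 input), four decoder layers of
nearest-neighbour ×2 upsampling, a plain skip concatenation and two conv
modules, and a final 1×1 convolution with sigmoid. It is trained with the
mean absolute error (L1) against the unoccluded target, and repairs
contours and rough texture.

**Stage 2 (fine repair).** The coarse output (not the original image) feeds
a second encoder–decoder. Encoder layer 1 is a conv module + pool; layers
2–5 are modified residual blocks (MRB) + pool, reaching an 8×8 bottleneck.
Each MRB chains two Conv1×1–BN–LReLU / Conv3×3–BN–LReLU pairs; the first
pair's output `y1` both feeds the second pair (`y2`) and is concatenated
with it, and `Concat(y1, y2)` is added to an identity branch:

    y1 = M2(M1(x)),   y2 = M4(M3(y1)),   y = Concat(y1, y2) + P(x)

with `P` a bias-free 1×1 projection inserted when the channel counts
differ; `y1` and `y2` each carry half of the output channels so the Concat
matches the identity branch. Decoder layers apply a 1×1 convolution,
nearest-neighbour upsampling, an attention-gated skip merge and one
Conv3×3–BN–LReLU module.

**Attention-gated skips (DACC).** Each skip level fuses the encoder feature
`x_en` and the decoder feature `x_de`:

    SE(x_en) = σ( LReLU(GAP(x_en) W1) W2 )               (per-channel gains)
    SA(x_en) = σ( Conv7×7(Concat(mean_c(x_en), max_c(x_en))) )  (per-pixel gains)
    out      = Concat( LReLU(BN1(x_de · SA)),  SE · σ(BN2(x_de)) )

GAP in the SE branch is the spatial global average; the pooling in the SA
branch is over the channel axis. Both gain maps lie strictly in (0, 1) and
are *not* pre-multiplied into `x_en`. C-channel inputs give a 2C-channel
output. Of the two natural orderings of the first branch —
normalise-then-multiply and multiply-then-normalise — the latter (BN
applied to the product `x_de · SA`) is implemented. Two ablation
wirings are selectable: a plain `Concat(x_en, x_de)` skip, and an SA-only
variant (the SE gains forced to 1), both preserving the 2C output contract.

**Critic.** Six Conv5×5 stride-2 + LReLU layers (no batch normalisation —
a gradient-penalty critic must not mix per-sample gradients through batch
statistics), then Conv3×3 + LReLU, global average pooling and a linear map
to one unbounded score per image. For 256×256 input the pre-pooling map is
4×4.

**Losses and schedule.** The critic minimises

    E[D(fake)] − E[D(real)] + λ · E[( sqrt(‖∇x̂ D(x̂)‖² + C) − 1 )²]

with x̂ a per-sample uniform interpolation of real and fake, λ = 10 and a
smoothing constant C = 1e-8 inside the root. With C = 0 the norm has an
undefined derivative wherever the critic gradient vanishes and training
NaNs on degenerate batches; the test suite demonstrates both behaviours.
The fine generator minimises −E[D(fake)]. Per training step the critic is
updated `gd_ratio = 5` times per single generator update; the coarse
network is updated once per step from its L1 loss alone, and adversarial
gradients never reach it. Optimisers are Adam with learning rate 5e-4 for
all three networks, β₁ = 0.5, β₂ = 0.9, batch size 8, 100 epochs (the
reference configuration; miniature runs override the batch size and step
count). All weights use He (fan-in) initialisation from a seed; biases
start at zero, BN at gain 1 / bias 0.

## Autodiff engine

No deep-learning framework is part of the dependency set; the networks run
on a small reverse-mode autodiff engine over numpy arrays
(`irispaint.nn.tensor`). Every vector-Jacobian product is itself composed
of engine ops, so gradients built with `create_graph=True` are again
differentiable — the property the gradient penalty needs, since its loss
contains ∇x̂ D(x̂) and updating the critic differentiates through that
gradient. Convolution is im2col + BLAS matmul with symmetric padding
k//2 (so stride 1 preserves and stride 2 halves even sizes); its adjoint
pair im2col/col2im are mutually-inverse linear primitives. `max`-type ops
route gradient to every tied argmax (a measure-zero event for continuous
inputs). The engine is validated against central finite differences for
every op family, including double backprop, and end-to-end through the
fine network.

## Preprocessing

Steps, given an acquired image and its binary ground-truth (GT) iris mask:
mask the image by the GT (iris on black); crop both to the GT bounding
box; measure, along the four axis rays through the pupil-hole centroid,
the annulus width `d_i` (mask pixels on the ray) and the inner-border
margin `x_i` (inner crossing to image border); pad side `i` with
`max(d1..d4) − x_i + c` zeros (c = 20 px default); resize to 256×256
(bilinear; nearest + re-threshold for masks). After padding, every inner
border sits `max(d) + c` pixels from its border, which centres the pupil
up to rasterisation. Negative pads are clamped to zero. Ray-through-
centroid measurement is a documented choice — per-direction extrema would
also be defensible; rays through the pupil are the simpler geometry. The
pipeline is idempotent up to resampling of band-limited texture and
strictly increases the iris fraction of the frame whenever the input
margin exceeds c.

## Synthetic data

Real iris texture runs radially near the pupil and circumferentially near
the outer boundary. The generator renders band-limited harmonic noise in
polar coordinates: a field varying along the angle (radial ridges) and a
field varying along the radius (circumferential ridges), blended by the
weight `radial_blend · (1 − r̂)` with r̂ the normalised annulus position, so
`radial_blend = 0` is circumferential everywhere — a testable orientation
statistic (variance along circles below variance along rays). Texture
amplitude is mapped to [0.15, 0.9]; outside the annulus the image is 0.

Occlusions come in three styles: upper/lower eyelid arcs (a parabolic
boundary entering from the edge, depth bisected so the occluded fraction of
the GT area lands in the requested coverage range) and eyelash strokes
(thin quadratic Bézier curves accumulated until coverage reaches the
range, the last stroke trimmed). Default coverage is 10–30 % of the iris
area. Occluded pixels are set to 0; the mask is *not* given to the
networks. Data expansion is eight deterministic modes — clockwise /
counterclockwise rotation (±10°), horizontal flip, four directional
shifts-with-crop (fraction 0.1) and a centre crop (ratio 0.9), all resized
back — so n base images × 8 modes × 3 mask styles = 24 n triplets.

What the synthetic data does *not* emulate: specular reflections,
off-angle gaze, motion blur, sensor noise, or the long-range correlations
of real iris crypts and furrows. Passing tests therefore certify the
machinery (geometry, losses, schedules, metrics), not recognition-grade
realism.

## Metrics

PSNR = 10·log10(peak²/MSE), capped at 100 dB for identical images. The
Fréchet distance ‖μa−μb‖² + tr(Σa+Σb−2(ΣaΣb)^{1/2}) uses the similarity
trick tr((Σa^{1/2}ΣbΣa^{1/2})^{1/2}) with eigendecomposition; eigenvalues
below a −1e-8 drift tolerance raise, smaller negatives are clipped. The
image-set variant (FID-style) takes a pluggable embedding; the default is
a fixed-seed random-projection conv stack (three stride-2 convolutions,
LReLU, global average pooling, random linear projection), adequate for
relative desk-scale comparisons — an Inception-grade embedding can be
passed in for comparability with published FID numbers. ROC sweeps all
distinct thresholds (score convention: higher = genuine); EER interpolates
the FAR/FRR crossing and TAR@FAR takes the loosest threshold within the
FAR budget, interpolating between attained FARs. Both are reported in
percent.

## Miniature study conditions

Tests and the acceptance script exercise the full method at desk scale,
chosen once as: 64×64 images, channel widths divided by 4, 200 training
steps, batch size 4, six base irises (five train / one held out, i.e.
120/24 triplets), occlusion coverage 10–30 %, one CPU, single seed fan-out
(fixed offsets per subsystem, so data, initialisation and the training
loop are independently reproducible). At these conditions the coarse
stage's held-out L1 drops several-fold below its step-0 value and the
coarse output exceeds the occluded input's PSNR by a wide margin. The
fine stage — trained by the adversarial loss alone —
acquires the right global statistics (annulus/pupil layout; its Fréchet
score against targets improves on the occluded set's) but, at 200
generator updates, not reliably pixel-aligned detail: a purely
distribution-matching objective has no mechanism that forces PSNR above
the occluded input at this update count, and whether the fine output's
PSNR clears that bar at miniature scale varies from seed to seed (observed
both outcomes across seeds) while the remaining checks pass throughout.

## Known limitations

* Channel widths, rotation angles, crop ratios, λ, β₂ and the SE reduction
  ratio are open design choices; the defaults are standard values, all
  configurable, and recorded above.
* BN running statistics update during the no-grad fake-generation pass;
  this is deliberate (the pass is part of training) but means eval-mode
  outputs depend slightly on the schedule.
* The engine is CPU/numpy only; full-scale 256×256 × 100-epoch training is
  supported by configuration but not practical without hardware
  acceleration.
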