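# Methods

## Detector family

All four variants share the nano-scale skeleton: a strided-conv backbone
with aggregation blocks at eight sites (four backbone, four neck), an SPPF
pooling block, a PAN-style neck, and an anchor-free head over P3/P4/P5
(strides 8/16/32). Variants:

| variant          | aggregation block | head              |
|------------------|-------------------|-------------------|
| `yolov8n`        | C2f               | decoupled stock   |
| `rgcspelan_only` | RGCSPELAN         | decoupled stock   |
| `lscd_only`      | C2f               | LSCD (shared, GN) |
| `yolov8_rl`      | RGCSPELAN         | LSCD (shared, GN) |

**RGCSPELAN.** `Conv1x1(c1 → 2c)` → split into halves of width
`c = c2/2`; the extraction branch applies `n` RepConv units at width `m`
and a 3×3 tail conv; the pass-through half, every RepConv output and the
tail output are concatenated (ELAN style) and projected by a 1×1 conv to
`c2`. RepConv has a 3×3 and a 1×1 branch, each conv + batch norm, summed
before the SiLU; no identity branch. Fusion folds each branch's norm
statistics into kernel and bias (in float64), zero-pads the 1×1 kernel to
the 3×3 center, and sums; it is idempotent and only allowed in evaluation
mode, because running statistics are the fold source. Train/deploy
equivalence holds to < 1e-4 max abs difference in float32.

**LSCD.** Per level, a 1×1 Conv_GN unifies the input width (this layer is
per-level: P3/P4/P5 have different widths); then a shared 3×3 Conv_GN
trunk and shared 1×1 regression (4·reg_max channels) and classification
(nc channels) projections; the regression output is multiplied by a
per-level learnable scalar so each level can adapt to its box-size regime.
Group normalization uses ε = 1e-5 and 16 groups, reduced to the largest
divisor of the channel count when 16 does not divide it (the calibrated
trunk widths 65 and 55 use 13 and 11 groups).

**Decode.** Box sides are discrete distributions over reg_max = 16 bins
decoded by expectation (soft-argmax) in stride units; corners are
(cell center ∓ distance)·stride. NMS is greedy per class with strict
`>` suppression (a tie exactly at the IoU threshold keeps both boxes) and
score ties broken by box coordinates, making the result independent of
input order.

## Width calibration

The reference accounting for this family (80-class head) is 3,157,200 /
2,197,561 / 2,362,518 / 1,553,846 parameters. The baseline follows from
the stock nano layout with no freedom. The internal widths of RGCSPELAN
and LSCD are not derivable from their block descriptions alone, so they
are calibrated: exhaustive search showed that no single global
width-multiplier pair can reproduce the printed totals exactly, so the
manifest (`configs/manifest.yaml`) fixes per-site RepConv widths
`m = [3,7,9,28,15,7,15,37]` for the ablation variant and
`[4,7,49,28,28,7,48,37]` for the full model, and a tapered LSCD trunk
(65, 55, 64). The full model widens the three 40×40-grid sites relative to
the ablation variant; that placement also fixes the FLOP ratio: full/base
= 0.508 at 640 px (counting conv layers only, one multiply–accumulate
= 2 FLOPs, RepConv fused). Parameter counts include the 16 frozen
distribution-focal projection weights, matching the convention of printed
model summaries; the counts are independent of input resolution.

## Training

SGD with momentum 0.937, weight decay 5e-4 (matrix-shaped parameters
only), initial learning rate 1e-3, batch 16, 640 px input — the reference
recipe; a 3-epoch linear warmup and linear decay to `lrf`·lr0. Loss:
task-aligned assignment (anchor centers inside the box; metric
score^0.5·IoU^6; top-10 per ground truth; conflicts to the higher metric;
soft targets normalized per ground truth by its best IoU), then binary
cross-entropy (weight 0.5), complete IoU (7.5) and distribution-focal
cross-entropy on the two neighbor bins (1.5). Classification projections
are initialized with a low-objectness prior bias, log(5/nc/grid²) —
without it the normalized BCE saturates the head at initialization. With
no ground truth in a batch the box and distribution terms are exactly
zero. Training is single-threaded-deterministic: identical seeds give
bit-identical loss curves.

The engine is a small numpy reverse-mode autodiff (im2col convolution on
BLAS matmul, analytic batch/group-norm backward, consumer-counted
backward traversal). It is CPU-bound, which sets the problem sizes used
in the test suite.

## Synthetic scenes

Scenes emulate the statistics of orchard imagery: layered-foliage
background; objects placed in Poisson-sized clusters at center-biased
positions; class-styled rendering (white petal clusters with yellow
cores, bright-green discs hue-offset from foliage, orange discs with
highlights); per-object occlusion by leaf polygons up to a configurable
fraction; optional gamma/backlight variation. Labels cover the *visible*
extent from an instance mask; remnants under 8 px² get no label. Box
aspect ratios are sampled log-uniformly in [0.8, 1.25], so the generated
aspect distribution has median ≈ 1 ("close to square"). Generation is
byte-deterministic under the scene seed.

What the generator does not emulate: real texture and bokeh, class
confusions from color-similar foliage at realistic difficulty, motion
blur, resolution extremes (default canvas is 640², not a 4096×3072
capture). Passing detection tests on these scenes therefore demonstrates
that the pipeline — assignment, loss, optimization, decoding, metrics —
works end to end, not that field-accuracy numbers transfer.

Tree-level pairs for the yield model: true counts uniform on [50, 140];
the visible count is visibility·actual + Gaussian counting noise, clipped
to [0, actual], with visibility defaulting to the inverse of the linear
model slope so a downstream fit recovers the slope in expectation
(verified to within 10 % at n = 50, σ = 5).

## Smoke-training problem size

The seeded end-to-end training check uses 48 training + 16 validation
scenes at 160 px with 8 objects per scene on average, the full
(`yolov8_rl`) variant with a 3-class head, batch 8, 60 epochs at lr0
0.02. This size was chosen so the run completes in minutes on one CPU
core while leaving a wide margin over its assertions (final loss below
half the first-epoch loss; validation mAP@.5 ≥ 0.5 — the measured run
reaches ≈ 0.84). Validation during training decodes at confidence 0.05 so
mAP integrates the full precision–recall curve; the counting default is
0.25.

## Yield regression conventions

* Fits are ordinary least squares (`numpy.polyfit`); degree 1 for the
  green stage, degree 2 for ripening.
* Both R² conventions are always reported. The green-stage reference
  value matches the plain coefficient of determination
  (1 − SSres/SStot); the ripening-stage value matches the adjusted form
  (1 − (SSres/(n−p−1))/(SStot/(n−1))). The packaged tables reproduce both
  to all five printed decimals.
* Predictions are rounded half away from zero and floored at 0.
* Display error rates are truncated (not rounded) at one decimal, and
  their mean at two decimals — the only convention that reproduces the
  reference per-tree rates and both mean rates exactly. One green-stage
  printed rate cell ("8 %") is inconsistent with its own row (5/56 →
  8.9 %); the packaged validation table carries the printed rate column
  so the reference mean (6.96 %) is reproducible, while
  `evaluate_predictions` recomputes rates from the counts.
* The ripening-stage quadratic's leading coefficient is stored as the
  refit value 0.01100; per-row prediction checks use only the validation
  rows that are self-consistent with the printed integer detect values
  (green trees 2 and 4; ripening trees 1, 2, 3, 5, 6 — the others differ
  by one count, consistent with predictions made from unrounded
  three-run averages that are not tabulated).

## Known limitations

* CPU-only: full-resolution (640 px) training at realistic dataset sizes
  is out of reach; the package targets desk-scale verification and
  small-scene experimentation.
* FLOP totals depend on counting conventions (here: conv layers only,
  MAC×2); absolute values are therefore approximate even though ratios
  between variants are stable.
* The accuracy, FPS and inference-time figures of the original field
  study require its imagery and hardware and are not reproduced here;
  the property-based checks in `tests/test_acceptance.py` stand in for
  them.
* Checkpoint size is serialization-dependent; the fp16 checkpoint of the
  full model measures 3.2 MB.
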