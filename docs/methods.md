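# Methods

This note records the model, the procedures, the defaults and the design
choices of the package, including the points where the design was genuinely
open and what the synthetic experiments do and do not demonstrate.

## Pipeline and scope

The package implements the *reader* stage of a two-stage BAA system. ROI
detection is out of scope: an external detector (any tool emitting YOLO text
labels with 18 classes) is the upstream contract, and
`filter_complete_samples` accepts any callable `path -> DetectionSet` as a
pluggable loader. The stages implemented here are: label I/O and data
cleaning → pose alignment → ROI cropping → sex-token fusion + windowed
attention → hybrid loss training → evaluation statistics.

## Coordinate and geometry conventions

* Normalised box coordinates, origin top-left, x rightwards, y downwards,
  matching the detector's native output; pixel index p corresponds to
  normalised coordinate (p + 0.5)/W, so the mirror of pixel x is W−1−x and
  of a normalised centre cx is exactly 1 − cx.
* The mirror test compares mean **x** centroids (ulnar column {8,15,16,17}
  vs radial column {0,9,10,11}); the flip test compares mean **y** centroids
  (fingertip band {11,13,14,17} vs wrist band {0,8,1,2}). Each test's axis
  is forced by its geometric purpose. Decisions are sequential: the flip
  test sees mirror-corrected coordinates and the rotation sees both
  corrections, so the correcting transform (mirror, then flip, then
  de-rotation) exactly inverts the pose.
* Rotation is measured from the ROI-14 → ROI-1 segment against the downward
  vertical, positive clockwise on screen, range (−180°, 180°]; the angle is
  computed from normalised coordinates, which assumes a square canvas (the
  generator's default, 256×256). Rotation is about the image centre —
  canvas-preserving and invertible; the rotation centre is otherwise
  arbitrary and only changes an irrelevant translation of the ROI cloud.
* Ties (equal means) mean "already aligned": the strict inequalities leave
  the image untouched.
* If one ROI of a reference pair/set is missing, the present subset is used;
  an entirely missing reference set raises an alignment-undecidable error.
  A missing ROI 1 or 14 yields rotation 0 with a `rotation_valid=False`
  flag by default (strict mode raises instead), because the data-cleaning
  filter (≥ 14 of 18 classes) makes complete reference sets the common case.
* Images are resampled bilinearly with zero fill on a same-size canvas;
  boxes are mapped corner-wise and replaced by their axis-aligned bounding
  box. For the rigid transforms used here the mapped centre is exactly the
  bounding-box centre, which is why pose recovery from boxes is exact to
  floating-point rounding.

## Patch extraction

Each detected ROI is cropped as a square of side max(w, h)·(1 + 2·margin)
pixels (margin 0.1 per side by default; square crops preserve the aspect of
epiphyseal regions) and resized to 58×58. Missing ROI channels are zero with
a false `present_mask` entry, keeping the tensor shape (18, 58, 58) fixed
for batching. Intensities are scaled to [0, 1] by dtype range; no further
intensity normalisation is applied.

## Model

* **Embedding.** The expansion from the 18-channel stack to the C-channel
  working representation is a learned non-overlapping p×p patch embedding
  (flatten + linear). The data layer stays at 18 channels; all learned
  computation lives in the model. The 58×58 patches are centre-cropped to a
  56×56 working map so every stage side is divisible by the window size.
* **Sex token.** Male (0,1), female (1,0); a linear layer and sigmoid give a
  per-channel gate in (0,1) applied multiplicatively once, on the embedding
  before stage 1. Sigmoid (not softmax) is used for the activation, and the
  gate bias is initialised to +2 ("open gate", ≈ 0.88) so gating does not
  attenuate the features before a sex-specific modulation has been learned —
  the same reasoning as LSTM forget-gate bias initialisation. Without this,
  a freshly initialised gate of ≈ 0.5 uniformly halves the feature scale and
  the gated model trains more slowly than an ungated one.
* **Backbone.** Pre-norm residual blocks x + Attn(LN(x)) + MLP(LN(·)) with
  GELU MLPs; even-indexed blocks use W-MSA, odd-indexed SW-MSA with shift
  w/2, cyclic shift and additive boundary masks (−1e9 on cross-region
  pairs). When a stage's map side equals the window size, shifting is a
  no-op and those blocks fall back to W-MSA. No positional encoding is used
  anywhere — the sex token takes the position token's architectural slot.
  Patch merging concatenates 2×2 neighbours and reduces 4C → 2C linearly.
* **Head.** Global average pooling then a linear map to K logits. K = 240
  one-month classes by default (covers 0–20 years at month granularity);
  class j maps to j months, so the distribution moments are already in
  months. The predicted age is the distribution mean — the functional the
  mean loss trains.
* **Default vs tiny configuration.** The default mirrors the four-stage
  halve-resolution/double-channel layout (C = 144, depths (2,2,2,2), heads
  (3,6,12,24), window 7, 56 → 7). The `tiny()` preset used in the package's
  own experiments is C = 24, 2×2 patch embed (28×28 working map), two stages
  (2,2) with heads (2,4), window 7, ~66k parameters — sized so a full
  500-sample, 10-epoch training runs in about two minutes on one CPU core.
  Backbone depths, head counts and the classifier head have no single
  canonical choice at this scale; both configurations satisfy the same
  shape contracts and tests.
* Weight init is Glorot-normal with zero biases (except the gate bias),
  from a recorded seed; evaluation is deterministic (bit-stable repeat
  outputs on the same machine).

## Autodiff and optimisation

No deep-learning framework is used. The model runs on a purpose-built
reverse-mode autodiff engine over numpy arrays (broadcast arithmetic,
batched matmul, data-movement ops, GELU/sigmoid, fused softmax and
layer-norm, reductions), checked op-by-op against central finite
differences. Adam (β = 0.9/0.999, ε = 1e−8) optimises all parameters; the
learning rate is computed as lr0 / 3^(epoch div 10) so the scheduled values
at epochs 10 and 20 are exactly 0.001/3 and 0.001/9. An epoch is taken as
the schedule's decay unit. Batch size defaults to 32; month labels are
rounded to the nearest class in [1, K] before loss evaluation.

## Loss

All three terms share one stabilised softmax pass (max subtraction,
log-sum-exp, log-probabilities floored at 1e−12 — the mean–variance terms
are known to fluctuate early in training, so the floors matter). The
analytic gradient is closed-form:

    dLs/dz_ik = (p_ik − [k = y_i]) / N
    dLm/dz_ik = (m_i − y_i) p_ik (k − m_i) / N
    dLv/dz_ik = p_ik ((k − m_i)² − v_i) / N

and is used both by the trainer (the backbone receives dL/dz through the
tape) and as the object of the finite-difference acceptance check. Lm and Lv
are invariant to per-row logit shifts; Lv alone drives rows toward point
masses.

## Synthetic data generator

The generator emulates exactly the structure the pipeline needs to be
tested end-to-end, and no more:

* a fixed canonical 18-ROI left-hand layout satisfying the alignment rules'
  canonical inequalities (ulnar column left, fingertips up, ROI 14 directly
  above ROI 1);
* per-ROI Gaussian blobs whose radius and peak intensity grow affinely with
  *effective age* = age + δ·[female], δ = 24 months by default (females
  appear skeletally older at equal chronological age, consistent with the
  clinical one-to-two-year remark); additive Gaussian noise (sd 0.02 of the
  intensity range);
* pose corruption by mirror/flip Bernoulli (p = 0.5 each) and rotation
  uniform within ±30° by default, applied as the exact inverse of the
  alignment module's correcting transform, with ground truth recorded;
* ages uniform over [1, 228] months, sexes balanced; optional "dropout"
  samples whose label files keep only 10 of 18 classes, to exercise the
  completeness filter;
* independent random streams for labels, pose and noise; a spec + seed is
  bit-reproducible.

What passing tests on this corpus show: the pipeline's geometry is exact,
the loss and its gradient are correct, the model can recover a monotone
age-appearance relationship and exploit the sex code, and the training loop
is deterministic and schedule-faithful. What they do not show: performance
on real radiographs — the blobs have none of the texture, occlusion,
contrast variation or anatomical variability of clinical images, and the
age signal is far cleaner than real ossification patterns.

## Evaluation

MAE and RMSE in months; per-age-group tables over half-open one-year bins
[k, k+1) on the true age, with empty bins omitted; cumulative accuracy with
inclusive thresholds 0…24 months. MAE ≤ RMSE always (Jensen); the curve is
nondecreasing with value 1 at any threshold ≥ the maximum error.

## Desk-scale experiment sizes

The package's own experiments (test suite and acceptance script) use: a
20-sample corpus with 6 incomplete samples for the filter check; 200 random
poses over ±60° for the alignment round trip; and a 500-sample corpus,
tiny model, 10 epochs, batch 32, 80/20 split for the parameter-recovery
runs. The sex-token ablation is a paired design: three training seeds, each
run with the trained gate and with the gate frozen at all-ones on an
identical train/validation split, compared on mean held-out MAE — at this
training horizon single-run MAE fluctuates by several months between seeds,
which is of the same order as the sex-token benefit, so the paired mean is
the meaningful comparison. These sizes are the package's choice of a
reproducible laptop-scale experiment; the architecture and all procedures
are identical at larger configurations.

## Known limitations

* ROI class ids are opaque indices wired into the alignment rules; the
  anatomical identity of each index is not modelled.
* Rotation from normalised coordinates assumes square images.
* The completeness filter treats an unreadable label file as an incomplete
  sample (dropped with a logged reason) rather than an error.
* Only rigid pose normalisation is performed — no scale normalisation
  beyond ROI cropping, no non-rigid or landmark registration.
* The numpy autodiff engine is single-threaded apart from BLAS matmuls;
  GPU-scale configurations are out of reach by design.
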