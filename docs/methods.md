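# Methods

`seedlingscreen` screens individual plug-tray seedlings from side-view RGB
images during selective transplantation: each station of a captured frame is
classified as *healthy*, *unhealthy* or *none* (no seedling), and every
non-healthy station is flagged for removal. Two classifiers are provided — a
rule-based screen on measured leaf and substrate pixel areas, and a 3-class
residual-network classifier — together with the confusion-matrix arithmetic
used to compare them. This note records the model choices, defaults and known
limitations.

## Color model and threshold table

Images are converted to HSV in the *half-range encoding*: hue in 0–180
(degrees halved), saturation and value scaled to 0–255. Per pixel, with
R′ = R/255 etc., Cmax = max(R′,G′,B′), Cmin = min, Δ = Cmax − Cmin:

- H = 0° when Δ = 0; otherwise 60°·((G′−B′)/Δ), 60°·((B′−R′)/Δ + 2) or
  60°·((R′−G′)/Δ + 4) according to which channel attains Cmax. The first
  branch can be negative (magenta-ish pixels); 360° is added before halving so
  H stays in the table's 0–180 domain.
- S = Δ/Cmax (0 when Cmax = 0), V = Cmax; both scaled by 255.
- Scaling rounds half-away-from-zero to integers, so masks are
  bit-reproducible. The conversion agrees with the standard-library
  `colorsys` oracle within ±1 unit on every channel (rounding).

Thresholding uses a ten-color table of inclusive HSV boxes shipped as a
versioned JSON resource (`data/hsv_color_table.json`), overridable by the
user. **Interpretation caveat:** the threshold table this reproduces
circulates in a mis-aligned printed form (eleven hue columns for ten color
labels); the packaged table is the canonical reconstruction — red carries two
hue intervals (0–10 and 156–180), "ash" is gray (S 0–43, V 46–220), "young"
is cyan (H 78–99), and black spans H 0–180, S 0–255, V 0–46.

## Background removal and cropping

The extraction mask is the union of the five chromatic plant ranges (orange,
yellow, green, cyan, blue) and the black substrate range; the background on
the capture rig is white/gray and falls in neither. Pixels inside the mask
keep their values, all others become white. This single masked overlay is
algebraically identical to the two-pass composition through a
black-background intermediate (which remains available as
`extraction.black_background` for debugging) and is idempotent, since pure
white lies in no extraction range.

Frames holding several seedlings are cut into equal-width vertical slices
(remainder pixels to the rightmost slice), numbered 1..n left to right; the
capture geometry is not encoded beyond the station count, which defaults
to 6. Cropping and background removal commute under this design, so the
order is immaterial; the pipeline removes background per crop. Network input
is a direct 224×224 bilinear resize without aspect preservation, the common
default for classification preprocessing.

## Rule-based screen

Leaf pixels are the yellow ∪ green ranges (deliberately narrower than the
five-color extraction set — foliage is yellow-green, and the wider set would
admit chromatic noise); substrate pixels are the black range. Each mask is
denoised by dilation then erosion with a 3×3 elliptical (cross) structuring
element, one iteration each, followed by Gaussian smoothing (σ = 1.0,
truncated at 2σ — a 5×5 kernel) and re-thresholding at the 127 mid-level,
which restores a binary mask and deletes isolated single pixels while moving
region boundaries by at most about one pixel. Areas are counted **after** the
full denoise chain; the kernel sizes, iterations, σ and threshold are all
exposed in `DenoiseConfig`.

Classification is a total three-way rule on the measured areas: both zero →
*none* (strict zero test; a configurable epsilon, default 0, can tolerate
sensor noise); leaf ≥ 2,300 px **and** substrate ≥ 1,300 px → *healthy*;
anything else → *unhealthy*. Thresholds are inclusive and configurable
(`ScreeningThresholds`). The rule partitions the nonnegative quadrant and is
monotone: growing either area never demotes a healthy verdict. By design it
cannot detect the "three leaves and one heart" maturity criterion — that is
precisely the failure mode that motivates the learned screen.

## Networks

Both classifiers are residual networks with bias-free convolutions followed
by batch normalisation, global average pooling and a 3-way fully connected
head, emitting logits in the fixed class order (healthy, unhealthy, none);
ties resolve to the lowest index.

- **Transfer architecture**: the standard 18-layer residual backbone (7×7/64
  stride-2 stem, 3×3 stride-2 max pool, four stages of two basic blocks at
  64/128/256/512 channels, 1×1 projection shortcuts on shape change) with the
  1000-way head replaced by the 3-way layer. Trainable parameter count:
  **11,178,051** exactly. Pretrained initialisation is a user-supplied
  option; the package defaults to (and its tests use) seeded random
  initialisation and never downloads weights.
- **Compact architecture**: 3×3/16 stem at stride 3 (224 → 74) and four
  two-block stages at 32/64/128/256 channels. The published layer table for
  this variant fixes only kernels, channels and output sizes (74, 25, 9, 5,
  3); strides, shortcut type and biases are underdetermined. The only stride
  assignment consistent with those output sizes is stem stride 3 pad 0,
  stage strides 3, 3, 2, 2 with pad 1, and that is what is built, with
  projection shortcuts wherever shape changes. The resulting count is
  **2,791,315** parameters; the total of 1,230,275 printed alongside the
  original table cannot be reconciled with any standard residual reading of
  it, so the package reports its own count.

The layers (im2col convolution, batch norm with momentum 0.1 and ε = 1e-5,
max/global-average pooling, linear head) are implemented directly over
numpy in float32 with hand-written backward passes, verified against
finite-difference gradients in the test suite. Convolutions use He-normal
initialisation (fan-in); the linear head uses the usual ±1/√fan_in uniform.

## Training

Cross-entropy minimised with Adam (β = 0.9/0.999, ε = 1e-8) over shuffled
mini-batches of 32; learning rate, epochs and batch size are configurable
(the reference protocol explores 1e-3/1e-4/1e-5 and 20–30 epochs). Inputs
are extracted (white-background) crops resized to 224×224, scaled to [-1, 1].
Each epoch records train/validation loss and accuracy; the final model is
the epoch with the highest validation accuracy, ties broken by lower
validation loss. A non-finite loss aborts with a diagnostic rather than
continuing from a poisoned state. One config seed drives weight
initialisation, shuffling and batch order, making runs bit-reproducible.
Checkpoints serialise all parameters and buffers to `.npz` with training
curves alongside as JSON.

Augmentation (used to expand under-represented classes) composes shear
(≤25°), rotation (≤20°), optional horizontal flip and shifts (≤0.3 of each
dimension) about the image centre, filling vacated pixels with white to match
the extracted background; it preserves size, dtype and label.

Dataset manifests are CSV (`path,label,split`); the 60/20/20 split is
stratified per class with floor-then-largest-remainder rounding, so each
class deviates from the exact fractions by at most one image per split
(1,085 images split 651/217/217).

## Synthetic data

No captured lettuce dataset is distributed, so every pipeline is exercised
on synthetic side-view frames that reproduce exactly the structure the
method consumes: a light neutral gray background with per-pixel brightness
jitter (inside the gray threshold range, hence removed by extraction), a
dark substrate rectangle at the bottom centre whose colors sit inside the
black range, and a fan of disjoint green ellipses for foliage. Rendered
areas land within 5% of their targets (rectangles exact, ellipses after one
corrective rescale) and the record stores the exact pixel counts from the
drawing masks, so the generator doubles as a parameter-recovery oracle: the
rule-based measurement recovers rendered areas within 10% (boundary effects
of the denoise chain).

The "three leaves and one heart" maturity criterion has no published
geometric definition; the generator represents it only as the **blob
count** — an explicit proxy. Unhealthy seedlings are drawn in two modes
mirroring the described defect types: *wilt* (flattened ellipses,
vertical/horizontal axis ratio 0.45 instead of 1.6, with total leaf area
20% or more below threshold) and *substrate loss* (plug area 20% or more
below threshold). Healthy draws keep both areas at least 20% above
threshold (leaf 2,760–5,500 px, substrate 1,560–3,000 px, 3–5 blobs);
absent seedlings are blank frames. These margins guarantee that the area
rule and the generator label agree on every render, which is what the
end-to-end tests assert.

What the synthetic frames deliberately lack: leaf texture and venation,
overlapping or occluding leaves, roots protruding from the plug, lighting
gradients, and borderline specimens near the thresholds. Passing the
synthetic suites therefore demonstrates that the implementation is
internally correct and learnable-from, **not** that the published real-data
accuracies transfer; those can only be checked as arithmetic on the
published confusion matrices, which the evaluation tests do exactly.

## Evaluation conventions

Confusion matrices are oriented rows = predicted, columns = true, so
published tables paste directly as fixtures. Per-class TP/FP/FN/TN always
sum to the matrix total, and micro-averaged recall equals accuracy (both
property-tested). Zero denominators return 0 with an `undefined` flag
instead of raising. Percentages render at two decimals, rounded
half-away-from-zero, with trailing zeros trimmed ("92%", "97.56%"); note
that the healthy-class F1 of the published network matrix is exactly
878/901 = 97.45% at this precision — the source prints that one cell at one
decimal as 97.4%.

## Problem sizes

The end-to-end suite uses 300 synthetic frames (100 per class) at the
640×480 capture size, training the compact network for 10 epochs at
learning rate 1e-4 with batch 32 — enough for the margin-separated classes
to reach ≥95% held-out accuracy on a single CPU in a few minutes. Unit
tests use reduced frames (320×240 or single-station widths) and smaller
draws; these sizes are package choices that keep the default suite quick
while exercising every code path at full input resolution where it matters
(the networks always see 224×224).

## Known limitations

- The color table is a reconstruction (see caveat above); users with
  different lighting should override the JSON resource.
- The rule-based screen shares the reference method's blind spots: occluded
  substrate, protruding roots and maturity (blob count) are invisible to
  pure area measurement.
- The numpy training stack is single-threaded BLAS-bound and intended for
  the package's scale (hundreds of images); it is not a general training
  framework, and pretrained transfer weights must be supplied by the user
  if desired.
- Timing/throughput of the original robotic rig is hardware-dependent and
  out of scope.
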