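# Methods

## Problem setting

A pupil light reflex is a single bright corneal reflection produced by the
camera flash during standardised facial photography. It anchors the
marginal reflex distances MRD1/MRD2 used to grade ptosis and Graves'
orbitopathy. As a segmentation target it is extreme: in 512 × 512 eye
crops the foreground averages ~17 px — about 0.0066 % of the pixels — so
a model must preserve pixel-level localisation through its entire
downsampling/upsampling path, and losses/metrics must be robust to a
10⁻⁴-level class ratio.

## Preprocessing model

Clinical photographs are 1200 × 797 (width × height). The fixed chain is:

1. **Halving.** The photograph is cut into left/right halves of width
   ⌊W/2⌋ each, one eye per half, to remove eye interdependence. For odd
   widths the centre column is dropped so the halves stay symmetric (the
   clinical width is even, so this never triggers on conformant data).
2. **Mirroring.** Right-eye halves are flipped horizontally (configurable,
   default on) so a single crop box serves both sides.
3. **Fixed crop.** 200 px off the top and 450 px off the right of the
   half. Taken literally this yields a tall 150 × 597 region; because the
   ordering (halve before crop) and per-axis assignment are a protocol
   convention rather than a derivable fact, both values are config fields.
4. **Resize + pad.** Bilinear resize so the longer side is exactly 512
   (scale = 512 / max(h, w), short side rounded), anchored top-left, with
   zero padding right/bottom; intensities divided by 255.

Every step is recorded in a `PreprocessRecord` (crop offsets, scale, pads,
half origin, mirroring), so a predicted 512 × 512 mask can be mapped back
to raw-photograph coordinates: drop the padding, nearest-neighbour resize
back to the crop box, undo the crop, undo the mirror, re-place the half.
Round trips are rounding-limited: blobs ≥ 3 px across keep their component
count and overlap the original with IoU ≥ 0.5. Masks travel through the
forward chain with nearest-neighbour interpolation so they stay binary.

Top-left anchoring was chosen over centring because it makes the inverse
map a pure crop-and-scale with no offset bookkeeping; bilinear/nearest is
the standard image/mask pairing.

## Architecture

The backbone is a five-stage SegNet-style encoder–decoder.

**Encoder.** Stage 1 is the initial stage (below); stage 2 has two
3×3-conv blocks; stages 3–5 have three each (the three lowest-resolution
stages are the deeper ones). A conv block is 3×3 conv (stride 1, pad 1,
no bias) → BatchNorm (momentum 0.1) → ReLU. Each stage ends in 2×2/stride-2
max pooling that records the within-window argmax. Output channels per
stage: 64, 128, 256, 512, 512.

**Decoder.** Stage *j* max-unpools with the indices of encoder stage
6 − *j*, concatenates the skip input where the variant admits it, and runs
its conv blocks (three for stages 1–3, two for 4–5). Index-based
unpooling pins the channel count of the tensor each stage must hand to the
next unpool: the tensor entering unpool *j* must have exactly the
channels of the encoder map whose indices it reuses. The decoder therefore
follows the classic SegNet convention — each stage computes at its nominal
width (512, 512, 256, 128, 64) and its **last** conv block reduces to the
width the next unpool requires (512, 256, 128, 64). With skips active the
concatenated widths entering stages 1–5 are 1024, 1024, 512, 256 and 320.
A final 1×1 convolution to one channel plus a sigmoid produces the
probability map; outputs are clamped to the open interval (0, 1) at
float32 resolution.

**Initial stage (proposed).** A stem — 3×3 conv expanding 3→64 channels,
then a 1×1 conv (both BN+ReLU; the 1×1 adds channel-mixing non-linearity
while the receptive field is still 3×3) — followed by three ConvUNeXt-style
residual blocks: depthwise conv (kernel 5, 7 or 9; one per block) → BN →
1×1 expand to 256 → GELU → 1×1 project back to 64 → residual add. The
kernel sizes are read as the blocks' depthwise kernels (the simplest
reading of "receptive fields 5/7/9"); the blocks run sequentially by
default with a `initial_parallel` switch for the alternative reading. The
four taps (stem output + three block outputs) are all 64-channel,
full-resolution, and are concatenated into the final decoder stage.
Dropout is omitted throughout (never part of this protocol).

**Ablation variants.** `proposed` = proposed initial stage + all skips;
`A` removes only the initial-stage skip; `B` keeps only the initial-stage
skip; `C` swaps the initial stage for a plain two-conv-block stem with all
skips; `D` = `C` with every skip removed. Index-based unpooling is the
backbone, not a skip, and is retained in all variants. Counting
concatenation junctions gives 5/4/1/5/0.

**Initialisation.** Conv weights are Kaiming-normal (fan-in, ReLU gain),
seeded; BN starts at identity. The final 1×1 head bias is initialised to
−4 (a prior-probability initialisation): with foreground fractions of
10⁻²–10⁻⁴, a zero-initialised head starts at p ≈ 0.5 everywhere and
spends many epochs suppressing background before learning anything about
the target; starting near the true background prior removes that phase and
is what makes desk-scale training converge in a handful of epochs.

**Implementation.** The layers run on a compact NumPy reverse-mode
autodiff engine (`reflexseg.nn`): channels-last feature maps, stride-1
convolution as im2col (small maps) or shifted GEMMs (large maps),
hand-written vector–Jacobian products for conv/BN/pooling, exact
index-tracked max-unpooling, and AdamW. GELU uses the standard tanh
approximation. All primitives are verified against finite differences and
scipy correlation oracles in the test suite.

## Loss and metrics

Soft confusion counts over a probability map p and binary target g:
TP = Σ p·g, FP = Σ p·(1−g), FN = Σ (1−p)·g. The Tversky index
TI = (TP + s)/(TP + α·FN + β·FP + s) with stabiliser s = 10⁻⁶, and the
focal Tversky loss L = (1 − TI)^γ. Defaults α = 0.7, β = 0.3, γ = 4/3
follow the loss's original formulation (the protocol names the loss
without parameters); γ = 3/4 gives the reciprocal-exponent form some
implementations use. The loss is computed **per image and averaged over
the batch**: pooling pixels across a batch would let images whose targets
happen to be larger dominate the gradient when targets are ~17 px.

Evaluation metrics are hard Dice, IoU, Precision and Recall at threshold
0.5 (strictly-greater convention; the threshold is fixed, not tuned).
Reports **macro-average** per-image metrics (each image counts equally;
micro averaging over pooled pixels is available by flag). An image where
both truth and prediction are empty scores 1 by default ("the prediction
is exactly right"), configurable to exclusion; the identities
iou ≤ dice = 2·iou/(1 + iou) hold for every count vector and are enforced
by property tests.

## Synthetic scenes

The generator renders, per sample: a skin-toned background with a gentle
vertical gradient, an elliptical palpebral opening filled with sclera, an
iris disk (radius 11–16.5 % of the image side) with a darker pupil, an
optional upper-lid droop covering 0–35 % of the iris diameter from above,
and **one** anti-aliased bright reflex disk placed inside the visible
iris, clear of the lid (a single camera flash in primary gaze produces a
single corneal reflex). Pixel coverage of the disk is computed
analytically and thresholded at 0.5, so sub-pixel radii yield exact
masks; Gaussian noise (σ = 0.02) is added to the image only. The reflex
radius is drawn from U(1.6, 3.0) px, giving E[area] = π·E[r²] ≈ 16.9 px —
the clinical regime of ~17 px per 512 × 512 image (≈ 0.0066 %); the
clinical spread around that mean is not reported anywhere, so the range is
a free parameter chosen to bracket it. Infeasible geometry (e.g. full
droop) is retried a bounded number of times and then raises.

Each sample is a pure function of `(seed, index)` — the RNG is keyed per
sample, not shared — so datasets are reproducible and samples independent.
The generator emulates the statistical regime (target size, contrast,
occlusion, class ratio) but not photorealism: passing tests demonstrate
that the architecture, loss and harness behave correctly on data with the
clinical difficulty profile, not that the trained weights transfer to
clinical photographs.

## Training and evaluation protocol

AdamW (betas 0.9/0.999, weight decay 0.01 — standard defaults; the
protocol fixes only the optimiser and learning rate 1e-4), batch size 8,
at most 50 epochs. Augmentation: random horizontal flip (p = 0.5) and
random crop retaining ≥ 80 % of the area, resized back (bilinear image /
nearest mask); a crop that would erase all foreground is redrawn. Early
stopping halts after 15 consecutive epochs without a *strictly* lower
validation loss (no minimum delta), and the returned weights are the
minimum-validation-loss snapshot. Data are split 60/20/20 by seeded
shuffle with largest-remainder rounding (ties to the later split: 408 →
245/81/82).

Experiments repeat the full pipeline: each repetition re-draws the
synthetic corpus, the split and the initialisation from a keyed seed
(`SeedSequence([master, rep])`), and every variant within a repetition
sees byte-identical data, so per-repetition metric vectors are paired.
Repetitions are interpreted as i.i.d. replicates with re-drawn splits (a
`redraw_split=False` switch keeps the split fixed and re-initialises
only). A failed repetition is recorded as NaN with a warning, not silently
dropped. Variants are compared by two-sided paired t-tests
(t = mean(d)/(sd(d)/√n), df = n − 1) with significance flagged at 0.1 and
0.05; zero-variance differences degenerate to t = 0, p = 1 (all-zero) or
t = ±∞, p = 0. Report tables print "mean ± std" with `*`/`**` markers.

## Problem sizes used in tests and the acceptance script

Full clinical-scale training (512 × 512, full widths, 30 repetitions) is a
GPU-scale undertaking; this package's experiments run at desk scale as a
deliberate design point, with the clinical configuration reachable through
the same config fields:

* **capacity (overfit) check** — 8 synthetic samples at 64 × 64,
  channel_scale 0.25, lr 3e-3, trained until training Dice ≥ 0.9 (≤ 200
  epochs; typically ~50);
* **ablation comparison** — 200 synthetic samples at 64 × 64,
  channel_scale 0.25, 5 repetitions, 3 epochs per run at lr 3e-3. The
  elevated learning rate and short schedule suit the 16-fold-narrower
  network and are part of the desk-scale configuration. The check is
  directional — the fully-connected network's mean test Dice is expected
  to be at least variant D's — not a reproduction of clinical-scale
  scores;
* architecture contracts are exercised at full width on 512 × 512 inputs
  (forward only).

## Known limitations

* Desk-scale ablation results are directional; clinical-scale magnitudes
  (e.g. test Dice around 0.77) require the restricted clinical corpus and
  GPU-scale training, neither of which ships here.
* The synthetic scenes contain exactly one reflex and no eyelashes,
  specular skin highlights or make-up — the main false-positive sources in
  real photographs.
* The crop convention (step 3 above) encodes a protocol reading that
  cannot be verified from first principles; all values are configurable.
* The NumPy engine is single-threaded BLAS-bound; full-width training at
  512 × 512 is possible but impractically slow compared to a GPU
  framework.
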