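# Methods

This note documents the models, procedures and design choices behind the
package, in the spirit of a methods section: what is computed, under which
assumptions, and where the genuinely open decisions were resolved.

## Synthetic phantoms

Real mammographic ROI datasets require clinical data access and manual
annotation, so the package generates phantoms carrying the statistical
features the pipeline relies on:

- **Background**: a white-noise field smoothed with a Gaussian kernel
  (`background_texture_scale / 2` standard deviation) and min–max rescaled
  into `dynamic_range` (default (0.3, 0.7)).  The compressed band gives
  contrast-limited equalization something to expand, and the smooth texture
  provides bright distractor patches so that segmentation is not a trivial
  global threshold.
- **Lesions**: disks with base radius drawn uniformly from
  `lesion_radius_range`, deformed by a low-frequency radial perturbation
  (harmonics k = 2…5 with 1/k amplitudes, rescaled to `boundary_irregularity`
  and applied *outward only*).  Outward-only deformation keeps the pixel
  count of a lesion between π r² and 4 π r², a property the tests rely on.
  Centers are rejection-sampled so lesions lie fully inside the frame;
  overlaps are allowed and the mask is the union of supports.
- **Intensity**: each lesion adds `lesion_contrast` (default 0.18) on top of
  the background, with any local background dip under the lesion lifted to
  the global background mean first and a Gaussian-smoothed rim outside the
  support.  This guarantees the generator's contract that lesion pixels
  average at least `lesion_contrast / 2` above the mean background before
  noise.  Gaussian pixel noise (`noise_sd`, default 0.02) is added last and
  the image clipped to [0, 1].

Everything is driven by one `numpy` generator seeded from the `PhantomSpec`,
so a given spec renders bit-identical images; datasets derive per-item seeds
as `base_seed + i`.

What the phantoms deliberately do **not** model: BI-RADS density classes,
pectoral muscle, acquisition physics, or realistic lesion texture.  Passing
tests on phantoms demonstrates that the pipeline's machinery (preprocessing,
augmentation arithmetic, architecture, optimization, metrics) works as
specified — not that the model generalizes to clinical mammograms.

## Preprocessing

ROIs are cropped with half-open bounding boxes and resampled to 256×256
(bilinear for intensities, nearest-neighbor plus re-binarization for masks;
an already-256×256 crop passes through bit-identically).  CLAHE quantizes to
256 bins, builds one histogram per tile of `tile_grid`, caps each bin at
`clip_limit` times the tile's mean bin mass (excess redistributed uniformly),
maps levels through the clipped CDF, and blends the (up to) four nearest tile
mappings bilinearly per pixel.  Defaults are `clip_limit = 2.0` with an
8×8 grid at the 256-pixel scale — i.e. 32-pixel tiles, the common
medical-imaging setting.  **Tile size is a length scale**: the 64-pixel
desk-scale profile uses a 2×2 grid so tiles stay 32 pixels; an 8×8 grid on a
64-pixel image would equalize 8-pixel tiles, discarding the absolute
intensity information that distinguishes lesions from bright background
patches.  In the limit of one tile and an unbounded clip the implementation
reduces exactly to global histogram equalization, which a test verifies
against an independent CDF-mapping oracle.

The processing order is crop → resize → CLAHE, applied identically to
training, validation and test images.

## Augmentation and splitting

Each training/validation ROI expands into the 8 elements of the dihedral
group D4 (four 90° counter-clockwise rotations × optional horizontal
mirror).  Rotations by 90° multiples are exact grid permutations, so image
and mask transform without interpolation loss; the test split is never
augmented.  The augmented pool is shuffled with a seeded generator and split
train : validation = floor(0.8 N) : remainder, which reproduces exactly the
published 576/144, 4659/1165 and 947/237 splits of the 720-, 5824- and
1184-image pools.

## Architecture

The network follows a 54-row layer schedule exposed as data
(`table_schedule`): a VGG16-style encoder (64–128–256–512–512 channels,
index-recording 2×2 max pools), a mirrored index-unpooling decoder, a bridge
concatenation into a second SegNet whose encoder concatenates transformed
first-decoder features at four scales, a second decoder, and a head of
dilated 3×3 convolution (rate 3) → ReLU clamped to 1 → 1×1 convolution.
Resolved ambiguities:

- the published schedule prints one concatenation at 16×16×512 where the
  surrounding rows force 32×32×512; the corrected shape is implemented and
  asserted;
- a duplicated schedule row for the last first-decoder convolution is
  treated as a single layer;
- the prose mentions three skip connections but the schedule lists four
  concatenation rows; the schedule wins;
- each sub-network's decoder consumes its own encoder's pooling indices
  (the only shape- and index-consistent wiring);
- the final 1×1 convolution is followed by a sigmoid by default so
  predictions lie in [0, 1] for the IoU loss; `final_activation =
  "advanced_relu"` switches to the capped-ReLU-only head;
- batch normalization follows the activation (conv → ReLU → BN), as
  published; `bn_before_relu` swaps the order for ablation;
- weights are He-normal from a seeded generator, biases zero.

`width_multiplier` and `input_size` scale channel counts and resolution with
identical topology; the tiny profile (width 1/8, 64×64) has ~1.0 M
parameters versus ~66 M at full scale.  Every forward pass can record its
realized per-row output shapes for conformance checking against the
schedule.

All tensor computation runs on the package's own NumPy reverse-mode
autodiff engine (`consegnet.nn`): convolution as im2col plus one BLAS
matrix product (dilation = tap spacing), per-channel batch normalization,
2×2 index pooling/unpooling (ties broken toward the first window cell in
row-major order), channel concatenation, ReLU/clamp/sigmoid, the soft-IoU
loss, and bias-corrected Adam.  Every backward closure is verified against
central finite differences in the test suite.

## Training and evaluation

Adam at learning rate 10⁻⁴ with batch size 4 and the soft-IoU loss is the
default protocol.  After each epoch the mean validation loss feeds the
early-stop tracker: a strict improvement resets the non-improvement counter
and snapshots the weights; a tie or regression increments it; once the
counter exceeds the patience (20) training stops and the best-validation
weights are restored.  A NaN loss aborts immediately, keeping the last good
weights.  History (epoch, train/validation loss, validation Dice/IoU/pixel
accuracy) is written as CSV; the best checkpoint as a single
layer-name-keyed archive.  An optional `target_val_dice` stops a run once
validation Dice reaches a requested level — a convergence criterion for
bounded-time experiments, off by default.

Evaluation binarizes predictions at 0.5 (configurable), reports per-sample
and pixel-pooled precision/recall/Dice/IoU, and renders the 2×2 confusion
table normalized within each ground-truth class (tumor row: TP% + FN% = 100;
non-tumor row: FP% + TN% = 100).  When prediction and truth are both empty
the overlap metrics are defined as 1.

## Desk-scale study conditions

The tiny profile is the package's CPU-scale experiment: 64×64 phantoms
(lesion radii 8–12 px, texture scale 8 px — length scales divided by
four), 200 training / 50 validation / 50 test images, width-1/8 model,
batch 4.  Its learning rate is 3·10⁻³ rather than the full-scale 10⁻⁴: a
desk-scale run has ~50× fewer optimization steps than a full-scale training
campaign, and at 10⁻⁴ a 46-conv-layer network cannot leave the
neighborhood of its initialization within that budget.  The raised rate is
the standard compensation when shrinking a training schedule; the
full-scale default remains 10⁻⁴.

Convergence under this profile is gradual: held-out Dice keeps improving
through tens of epochs, and run-to-run (seed) variation of a few points
persists because batch-4 batch-norm statistics are noisy.  The bundled
tests bound each training run to roughly twenty epochs so the whole suite
stays within a practical single-core budget; the convergence check across
five seeds therefore exercises the pipeline at the edge of what that
schedule can deliver, and a full-framework or longer-running setup is
expected to land higher on the same conditions.  The training loop itself
has no such cap — `max_epochs` and the early-stop patience are free
parameters.

## Numerical choices

- float32 throughout the network; float64 in preprocessing and metrics;
- soft-IoU ε = 10⁻⁶ in numerator and denominator (loss is 0 exactly for a
  perfect binary prediction, and both-empty pairs score 0 rather than 1);
- batch-norm ε = 10⁻⁵, running-stat momentum 0.9 with the unbiased variance
  correction for inference;
- pooling ties take the first cell in row-major window order;
- prediction threshold 0.5 at evaluation;
- checkpoints store the model config, so loading rebuilds the exact
  architecture.

## Known limitations

- Phantoms are far simpler than clinical mammograms; scores on them say
  nothing about clinical performance, and the published full-scale results
  on real datasets are out of this package's scope.
- The NumPy engine is single-threaded BLAS-bound; full-scale (256×256,
  64-base-channel) training is possible in principle but impractically slow
  on CPU — the full-scale model is exercised for architecture conformance
  and inference, not trained to convergence.
- Batch statistics with batch size 4 make batch norm noisy; validation
  metrics fluctuate a few points between adjacent epochs.
- `input_size` must be divisible by 32 (five pooling stages); the two
  deepest channel counts must be equal for the unpooling wiring to close.
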