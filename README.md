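# connected-segnets

Breast-tumor segmentation from mammographic regions of interest with
**Connected-SegNets**: two SegNet-style encoder–decoder networks joined in
series by skip connections, trained with a differentiable IoU loss after
CLAHE contrast enhancement and deterministic 8-fold rotation/flip
augmentation.

The package is aimed at medical-image-analysis practitioners and method
developers who want a fully testable, CPU-runnable implementation of this
segmentation pipeline.  Real mammogram datasets are large and partly
private, so the package ships a synthetic-phantom generator that emulates
the statistical structure the pipeline assumes — textured low-contrast
backgrounds with a compressed intensity band and irregular blob lesions
slightly brighter than their surroundings — with exact ground-truth masks.
Everything, from preprocessing to training, runs end to end on phantoms.

## The model

A SegNet encoder follows VGG16's first 13 convolutional layers (3×3 conv →
ReLU → batch norm, in blocks of 2/2/3/3/3) with 2×2 max pooling that
*records the argmax index of every pooling window*.  Its decoder upsamples
by placing each value back at its recorded index (max-unpooling) instead of
using learned transposed convolutions, followed by mirrored convolution
blocks.  Connected-SegNets chains two such networks:

- the first decoder's full-resolution output is concatenated with a
  3×3-conv transform of itself (the *bridge*) and fed to the second encoder;
- at each scale of the second encoder, the corresponding first-decoder
  feature map passes through a 3×3 convolution and is concatenated in
  (four *skip connections*);
- the head is a dilated 3×3 convolution (rate 3), a ReLU capped at 1
  ("advanced ReLU"), and a 1×1 convolution to a single channel (sigmoid by
  default so predictions live in [0, 1]).

Training minimizes the soft IoU (Jaccard) loss

    L(p, g) = 1 − (Σ p·g + ε) / (Σ p + Σ g − Σ p·g + ε),       ε = 10⁻⁶,

with Adam (learning rate 10⁻⁴, batch size 4) and early stopping once the
validation loss has not improved for 20 consecutive epochs.  Evaluation
uses the pixel confusion (TP, FP, FN, TN):

    precision = TP/(TP+FP)   recall = TP/(TP+FN)
    Dice = 2TP/(2TP+FP+FN)   IoU = TP/(TP+FP+FN)

The network — including convolution, batch normalization, index pooling /
unpooling, and Adam — is implemented on a compact NumPy reverse-mode
autodiff engine (`consegnet.nn`), so the package has no deep-learning
framework dependency and runs anywhere NumPy does.

## Worked example

The package's desk-scale profile (64×64 phantoms, width-1/8 model — identical
topology, ~1 M parameters) trains in a few minutes on one CPU core:

```bash
python examples/03_augmentation_counts.py
```

```
dataset A: 90 raw -> 720 augmented -> 576 train / 144 val
dataset B: 728 raw -> 5824 augmented -> 4659 train / 1165 val
dataset C: 148 raw -> 1184 augmented -> 947 train / 237 val
total augmented: 7728
```

Those are the 8-fold augmentation counts and floor(0.8·N) train/validation
splits of the three emulated dataset sizes.  And the architecture check:

```bash
python examples/04_architecture_summary.py
```

```
schedule rows: 54, realized-shape matches: 54
bottleneck: (2, 2, 64), output: (64, 64, 1)
stage counts: {'segnet1': {'pools': 5, 'unpools': 5, 'concats': 0},
               'segnet2': {'pools': 5, 'unpools': 5, 'concats': 5}}
parameters: 1,042,745
```

Every realized layer output matches the 54-row layer schedule; each
sub-network pools and unpools five times, and the second SegNet receives
five concatenations (four skips plus the bridge).  A full training run of
the tiny profile (`python examples/05_train_tiny_model.py`) writes its
history, best checkpoint, held-out Dice/IoU metrics and normalized
confusion table into a run directory.

The same pipeline is scriptable from the shell:

```bash
consegnet pipeline --tiny --seed 0 --out run0     # generate → ... → evaluate
consegnet predict --checkpoint run0/train/checkpoint_best.npz \
    --out run0/pred run0/preprocess/images/*.png
```

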