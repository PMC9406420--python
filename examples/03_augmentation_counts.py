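"""Reproduce the published augmentation and split arithmetic.

Each training ROI expands into 8 variants (4 rotations x optional mirror);
the augmented pool is split into train/validation as floor(0.8 N) versus
the remainder.
"""

import numpy as np

from consegnet import RoiSample, SplitSpec, augment_eightfold, split_train_val

datasets = {"dataset A": 90, "dataset B": 728, "dataset C": 148}
sample = RoiSample(np.zeros((16, 16)), np.zeros((16, 16), np.uint8))

total = 0
for name, n_raw in datasets.items():
    augmented = n_raw * len(augment_eightfold(sample))
    train, val = split_train_val(list(range(augmented)), SplitSpec(train_fraction=0.8, seed=0))
    total += augmented
    print(f"{name}: {n_raw} raw -> {augmented} augmented -> {len(train)} train / {len(val)} val")
print(f"total augmented: {total}")

# Expected: 720 -> 576/144, 5824 -> 4659/1165, 1184 -> 947/237, total 7728.
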