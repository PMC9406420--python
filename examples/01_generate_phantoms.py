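"""Generate a few mammogram-like phantoms and inspect their properties.

Each phantom is a textured low-contrast background (intensities compressed
into a narrow band) with an irregular blob lesion slightly brighter than its
surroundings, plus the exact ground-truth mask.
"""

import numpy as np

from consegnet import PhantomSpec, generate_phantom

for seed in range(3):
    spec = PhantomSpec(seed=seed, size=64, lesion_radius_range=(6, 16),
                       background_texture_scale=8.0)
    pair = generate_phantom(spec)
    fg = pair.mask.mean()
    lesion = pair.image[pair.mask == 1].mean()
    background = pair.image[pair.mask == 0].mean()
    print(f"seed {seed}: image range [{pair.image.min():.3f}, {pair.image.max():.3f}], "
          f"foreground {100 * fg:.1f}% of pixels, "
          f"lesion mean {lesion:.3f} vs background mean {background:.3f}")

# The lesion mean sits at least `lesion_contrast` above the background mean,
# while the background occupies the compressed band that `dynamic_range`
# requests -- the structure CLAHE preprocessing is designed to expand.
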