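"""Train the desk-scale model end to end on phantoms and evaluate it.

Runs the full pipeline (generate -> CLAHE -> split -> train -> evaluate)
with the tiny profile: 64x64 phantoms, width-1/8 model, 200 train / 50 val /
50 test, IoU loss, Adam, early stopping on validation loss.  Takes a few
minutes on one CPU core.
"""

import json
from pathlib import Path

from consegnet.pipeline import RunConfig, run_pipeline

cfg = RunConfig.tiny(seed=0, out_dir="scratch/example_run")
out = run_pipeline(cfg)

metrics = json.loads((out / "evaluate" / "metrics.json").read_text())
print("held-out pixel-pooled metrics (%):", metrics)
print("history:", (out / "train" / "history.csv").read_text().splitlines()[0])
print("run directory:", out)

# dice/iou are the pixel-pooled Dice and Jaccard overlap of predicted vs
# true lesion masks on the 50 held-out phantoms, as percentages.
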