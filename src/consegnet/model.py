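"""The Connected-SegNets architecture: two index-unpooling SegNets in series.

The first SegNet is a VGG16-style encoder (13 conv layers in blocks of
2/2/3/3/3 with 2x2 index-recording max pools) and a mirrored decoder that
upsamples by placing values at the recorded argmax indices.  Its final
full-resolution feature map is concatenated with a 3x3-conv transform of
itself (the "bridge") and fed to a second SegNet whose encoder additionally
concatenates, at each scale, a 3x3-conv transform of the corresponding
first-decoder feature (four skip connections).  The head is a dilated 3x3
convolution (rate 3), an activation capped at 1, and a 1x1 convolution to a
single channel; a final sigmoid (default) keeps predictions in [0,1] for the
IoU loss.

The layer schedule (names Conv1..Conv27, pool/unpool/concat stages, output
shapes) is exposed as data via :func:`table_schedule` and every forward pass
can record realized shapes against it.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np

from .errors import ConfigError, ShapeError
from .nn import functional as F
from .nn.layers import Conv2d, ConvBlock, Module
from .nn.tensor import Tensor, no_grad

__all__ = ["ModelConfig", "LayerSpec", "table_schedule", "ConnectedSegNets",
           "build_architecture", "count_stages", "save_checkpoint", "load_checkpoint"]

#: VGG16-style conv repeats per scale, shared by every encoder/decoder stage.
_REPEATS = (2, 2, 3, 3, 3)


@dataclass(frozen=True)
class ModelConfig:
    """Hyperparameters fixing the network topology and width.

    ``channel_schedule`` gives the per-scale channel counts before width
    scaling; ``width_multiplier`` shrinks every count (minimum 1) for
    CPU-scale variants with identical topology.  ``input_size`` must be
    divisible by 32 (five pooling stages).
    """

    input_size: int = 256
    base_channels: int = 64
    channel_schedule: tuple[int, ...] = (64, 128, 256, 512, 512)
    dilation_rate: int = 3
    width_multiplier: float = 1.0
    final_activation: str = "sigmoid"  # or "advanced_relu"
    bn_before_relu: bool = False
    seed: int = 0

    def validate(self) -> None:
        if self.input_size % 32 != 0 or self.input_size < 32:
            raise ConfigError(f"input_size must be a positive multiple of 32, got {self.input_size}")
        if len(self.channel_schedule) != 5:
            raise ConfigError("channel_schedule must have exactly 5 entries")
        if self.width_multiplier <= 0:
            raise ConfigError("width_multiplier must be > 0")
        if self.final_activation not in ("sigmoid", "advanced_relu"):
            raise ConfigError(f"unknown final_activation {self.final_activation!r}")
        if self.dilation_rate < 1:
            raise ConfigError("dilation_rate must be >= 1")
        ch = self.channels()
        if ch[3] != ch[4]:
            raise ConfigError("the two deepest channel counts must match (decoder unpool wiring)")

    def channels(self) -> tuple[int, ...]:
        return tuple(max(1, int(round(c * self.width_multiplier))) for c in self.channel_schedule)

    @classmethod
    def tiny(cls, seed: int = 0) -> "ModelConfig":
        """Desk-scale profile: 64x64 inputs, base 8 channels, same topology."""
        return cls(input_size=64, width_multiplier=1.0 / 8.0, seed=seed)


@dataclass(frozen=True)
class LayerSpec:
    """One row of the architecture schedule."""

    index: int
    name: str
    kind: str  # input | conv_block | pool | unpool | concat | dilated_conv | output_conv
    output_shape: tuple[int, int, int]
    filter_size: str = ""
    n_filters: int | None = None
    n_layers: int = 1
    dilation: int = 1
    duplicate_of: int | None = None


def table_schedule(config: ModelConfig = ModelConfig()) -> list[LayerSpec]:
    """The 54-row layer schedule, scaled to ``config``'s size and width."""
    config.validate()
    s = config.input_size
    c = config.channels()
    d = config.dilation_rate
    rows: list[LayerSpec] = []

    def add(name, kind, shape, fs="", nf=None, nl=1, dil=1, dup=None):
        rows.append(LayerSpec(len(rows) + 1, name, kind, shape, fs, nf, nl, dil, dup))

    add("Input", "input", (s, s, 1))
    # SegNet1 encoder
    for i, (ch, rep) in enumerate(zip(c, _REPEATS)):
        scale = s // 2 ** i
        add(f"Conv{i + 1}", "conv_block", (scale, scale, ch), "3x3", ch, rep)
        add("Maxpool", "pool", (scale // 2, scale // 2, ch))
    # SegNet1 decoder: Conv6..Conv13
    dec1 = [("Conv6", c[4], 3, None), ("Conv7", c[3], 2, "Conv8"), ("Conv9", c[2], 2, "Conv10"),
            ("Conv11", c[1], 2, "Conv12"), ("Conv13", c[0], 1, None)]
    reduce_to = [None, c[2], c[1], c[0], None]
    for j, (name, ch, rep, reducer) in enumerate(dec1):
        scale = s // 2 ** (4 - j)
        add("Upsampling", "unpool", (scale, scale, ch))
        add(name, "conv_block", (scale, scale, ch), "3x3", ch, rep)
        if reducer:
            add(reducer, "conv_block", (scale, scale, reduce_to[j]), "3x3", reduce_to[j], 1)
    rows_conv13 = len(rows)
    add("Conv13", "conv_block", (s, s, c[0]), dup=rows_conv13)  # printed twice; same layer
    # bridge + SegNet2 encoder
    add("Conv14", "conv_block", (s, s, c[0]), "3x3", c[0], 2)
    enc2 = [(2 * c[0], c[1], "Conv15", 2), (2 * c[1], c[2], "Conv16", 3),
            (2 * c[2], c[3], "Conv17", 3), (2 * c[3], c[4], "Conv18", 3)]
    feed = c[0]
    for j, (cat_ch, out_ch, name, rep) in enumerate(enc2):
        scale = s // 2 ** (j + 1)
        add("Maxpool", "pool", (scale, scale, feed))
        add("Concatenate", "concat", (scale, scale, cat_ch))
        add(name, "conv_block", (scale, scale, out_ch), "3x3", out_ch, rep)
        feed = out_ch
    add("Maxpool", "pool", (s // 32, s // 32, c[4]))
    # SegNet2 decoder: Conv19..Conv26
    dec2 = [("Conv19", c[4], 3, None), ("Conv20", c[3], 2, "Conv21"), ("Conv22", c[2], 2, "Conv23"),
            ("Conv24", c[1], 2, "Conv25"), ("Conv26", c[0], 1, None)]
    for j, (name, ch, rep, reducer) in enumerate(dec2):
        scale = s // 2 ** (4 - j)
        add("Upsampling", "unpool", (scale, scale, ch))
        add(name, "conv_block", (scale, scale, ch), "3x3", ch, rep)
        if reducer:
            add(reducer, "conv_block", (scale, scale, reduce_to[j]), "3x3", reduce_to[j], 1)
    add("Conv27", "dilated_conv", (s, s, c[0]), f"3x3 (D={d})", c[0], 1, dil=d)
    add("Output", "output_conv", (s, s, 1), "1x1", 1, 1)
    assert len(rows) == 54
    return rows


class ConnectedSegNets(Module):
    """The assembled two-SegNet model; forward maps N x H x W x 1 -> N x H x W x 1."""

    def __init__(self, config: ModelConfig = ModelConfig()):
        super().__init__()
        config.validate()
        self.config = config
        c = config.channels()
        rng = np.random.default_rng(config.seed)
        bn = config.bn_before_relu

        def block(name, cin, cout, rep, dilation=1):
            self.add_module(name, ConvBlock(cin, cout, rep, rng=rng,
                                            bn_before_relu=bn, dilation=dilation))

        # SegNet1 encoder (VGG16's 13 conv layers)
        prev = 1
        for i, (ch, rep) in enumerate(zip(c, _REPEATS)):
            block(f"Conv{i + 1}", prev, ch, rep)
            prev = ch
        # SegNet1 decoder
        block("Conv6", c[4], c[4], 3)
        block("Conv7", c[4], c[3], 2)
        block("Conv8", c[3], c[2], 1)
        block("Conv9", c[2], c[2], 2)
        block("Conv10", c[2], c[1], 1)
        block("Conv11", c[1], c[1], 2)
        block("Conv12", c[1], c[0], 1)
        block("Conv13", c[0], c[0], 1)
        # bridge: transform of Conv13's output, concatenated back, reduced by Conv14
        block("Bridge", c[0], c[0], 1)
        block("Conv14", 2 * c[0], c[0], 2)
        # skip transforms of the SegNet1 decoder features
        block("Skip1", c[0], c[0], 1)   # from Conv12
        block("Skip2", c[1], c[1], 1)   # from Conv10
        block("Skip3", c[2], c[2], 1)   # from Conv8
        block("Skip4", c[4], c[3], 1)   # from Conv6
        # SegNet2 encoder
        block("Conv15", 2 * c[0], c[1], 2)
        block("Conv16", 2 * c[1], c[2], 3)
        block("Conv17", 2 * c[2], c[3], 3)
        block("Conv18", 2 * c[3], c[4], 3)
        # SegNet2 decoder
        block("Conv19", c[4], c[4], 3)
        block("Conv20", c[4], c[3], 2)
        block("Conv21", c[3], c[2], 1)
        block("Conv22", c[2], c[2], 2)
        block("Conv23", c[2], c[1], 1)
        block("Conv24", c[1], c[1], 2)
        block("Conv25", c[1], c[0], 1)
        block("Conv26", c[0], c[0], 1)
        self.add_module("Conv27", Conv2d(c[0], c[0], k=3,
                                         dilation=config.dilation_rate, rng=rng))
        self.add_module("Output", Conv2d(c[0], 1, k=1, rng=rng))
        self.last_trace: list[tuple[int, str, tuple[int, int, int]]] = []

    # -- forward ---------------------------------------------------------

    def forward(self, x, record_shapes: bool = False) -> Tensor:
        t = self._prepare_input(x)
        trace: list[tuple[int, str, tuple[int, int, int]]] = []
        row = [0]

        def rec(name, tensor, dup=False):
            row[0] += 1
            if record_shapes:
                trace.append((row[0], name, tuple(tensor.data.shape[1:])))

        m = self._modules
        rec("Input", t)
        # SegNet1 encoder
        feats = t
        idx1 = []
        for i in range(5):
            feats = m[f"Conv{i + 1}"].forward(feats)
            rec(f"Conv{i + 1}", feats)
            feats, idx = F.maxpool2x2(feats)
            idx1.append(idx)
            rec("Maxpool", feats)
        # SegNet1 decoder
        dec_feats = {}
        plan = [("Conv6", None), ("Conv7", "Conv8"), ("Conv9", "Conv10"),
                ("Conv11", "Conv12"), ("Conv13", None)]
        for j, (main, reducer) in enumerate(plan):
            feats = F.maxunpool2x2(feats, idx1[4 - j])
            rec("Upsampling", feats)
            feats = m[main].forward(feats)
            rec(main, feats)
            if reducer:
                feats = m[reducer].forward(feats)
                rec(reducer, feats)
            dec_feats[reducer or main] = feats
        rec("Conv13", feats, dup=True)  # schedule prints Conv13 on two rows
        # bridge
        feats = F.concat(feats, m["Bridge"].forward(feats))
        feats = m["Conv14"].forward(feats)
        rec("Conv14", feats)
        # SegNet2 encoder with skip concatenations
        skips = [("Skip1", "Conv12", "Conv15"), ("Skip2", "Conv10", "Conv16"),
                 ("Skip3", "Conv8", "Conv17"), ("Skip4", "Conv6", "Conv18")]
        idx2 = []
        for skip_name, source, conv_name in skips:
            feats, idx = F.maxpool2x2(feats)
            idx2.append(idx)
            rec("Maxpool", feats)
            feats = F.concat(feats, m[skip_name].forward(dec_feats[source]))
            rec("Concatenate", feats)
            feats = m[conv_name].forward(feats)
            rec(conv_name, feats)
        feats, idx = F.maxpool2x2(feats)
        idx2.append(idx)
        rec("Maxpool", feats)
        # SegNet2 decoder
        plan2 = [("Conv19", None), ("Conv20", "Conv21"), ("Conv22", "Conv23"),
                 ("Conv24", "Conv25"), ("Conv26", None)]
        for j, (main, reducer) in enumerate(plan2):
            feats = F.maxunpool2x2(feats, idx2[4 - j])
            rec("Upsampling", feats)
            feats = m[main].forward(feats)
            rec(main, feats)
            if reducer:
                feats = m[reducer].forward(feats)
                rec(reducer, feats)
        # head: dilated conv -> advanced ReLU -> 1x1 conv (-> sigmoid)
        feats = F.clip01(m["Conv27"].forward(feats))
        rec("Conv27", feats)
        out = m["Output"].forward(feats)
        if self.config.final_activation == "sigmoid":
            out = F.sigmoid(out)
        else:
            out = F.clip01(out)
        rec("Output", out)
        if record_shapes:
            self.last_trace = trace
        return out

    def _prepare_input(self, x) -> Tensor:
        if isinstance(x, Tensor):
            data = x.data
        else:
            data = np.asarray(x, dtype=np.float32)
        if data.ndim == 3:
            data = data[..., None]
        if data.ndim != 4 or data.shape[-1] != 1:
            raise ShapeError(f"expected N x H x W (x 1) input, got shape {data.shape}")
        h, w = data.shape[1:3]
        if h % 32 or w % 32 or h < 32 or w < 32:
            raise ShapeError(f"input spatial dims must be multiples of 32, got {h}x{w}")
        return x if isinstance(x, Tensor) else Tensor(data)

    def predict(self, images: np.ndarray, threshold: float | None = 0.5,
                batch_size: int = 4) -> np.ndarray:
        """Deterministic inference; returns probabilities, or binary masks if thresholded."""
        self.eval()
        outs = []
        images = np.asarray(images, dtype=np.float32)
        with no_grad():
            for i in range(0, len(images), batch_size):
                outs.append(self.forward(images[i:i + batch_size]).data[..., 0])
        probs = np.concatenate(outs, axis=0)
        if threshold is None:
            return probs
        return (probs >= threshold).astype(np.uint8)

    # -- introspection ---------------------------------------------------

    def trace_shapes(self, batch: int = 1) -> list[tuple[int, str, tuple[int, int, int]]]:
        """Run a real forward pass recording every stage's realized output shape."""
        self.eval()
        s = self.config.input_size
        with no_grad():
            self.forward(np.zeros((batch, s, s, 1), dtype=np.float32), record_shapes=True)
        return self.last_trace

    def summary(self) -> str:
        """Text dump mirroring the schedule columns (for diffing against it)."""
        lines = ["No.\tLayer Name\tOutput\tFilter Size\tNo. of Filters\tNo. of Layers"]
        for spec in table_schedule(self.config):
            h, w, c = spec.output_shape
            lines.append(f"{spec.index}\t{spec.name}\t{h} x {w} x {c}\t{spec.filter_size}"
                         f"\t{spec.n_filters or ''}\t{spec.n_layers}")
        return "\n".join(lines)


def build_architecture(config: ModelConfig = ModelConfig()) -> ConnectedSegNets:
    """Build the layered model graph for ``config`` (validates it first)."""
    return ConnectedSegNets(config)


def count_stages(model: ConnectedSegNets) -> dict[str, dict[str, int]]:
    """Pools/unpools/concats per sub-network, counted from a realized trace."""
    trace = model.trace_shapes()
    conv14_row = next(r for r, n, _ in trace if n == "Conv14")
    out = {"segnet1": {"pools": 0, "unpools": 0, "concats": 0},
           "segnet2": {"pools": 0, "unpools": 0, "concats": 0}}
    for r, name, _ in trace:
        part = "segnet1" if r < conv14_row else "segnet2"
        if name == "Maxpool":
            out[part]["pools"] += 1
        elif name == "Upsampling":
            out[part]["unpools"] += 1
        elif name == "Concatenate":
            out[part]["concats"] += 1
    out["segnet2"]["concats"] += 1  # the bridge concatenation feeding Conv14
    return out


def save_checkpoint(model: ConnectedSegNets, path: str | Path) -> None:
    """Single-archive checkpoint: layer-name-keyed weights plus the config."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    state = model.state_dict()
    state["__config__"] = np.frombuffer(
        json.dumps(asdict(model.config)).encode(), dtype=np.uint8)
    np.savez(path, **state)


def load_checkpoint(path: str | Path) -> ConnectedSegNets:
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"missing checkpoint: {path}")
    with np.load(path) as archive:
        cfg = json.loads(bytes(archive["__config__"]).decode())
        cfg["channel_schedule"] = tuple(cfg["channel_schedule"])
        model = ConnectedSegNets(ModelConfig(**cfg))
        model.load_state_dict({k: archive[k] for k in archive.files if k != "__config__"})
    return model
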