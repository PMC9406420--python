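"""End-to-end orchestration: generate -> preprocess -> augment -> train -> evaluate -> predict.

Each stage reads a manifest, writes its artifacts plus an updated manifest
into its own subdirectory of the run directory, and drops a completion
marker.  Stages are idempotent: rerunning with identical config and seeds
reproduces byte-identical manifests.  No stage mutates its inputs.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import imgio
from .augment import SplitSpec, VARIANTS, apply_variant, split_train_val
from .errors import ConfigError, DataError, DependencyError
from .model import ConnectedSegNets, ModelConfig, load_checkpoint, save_checkpoint
from .phantom import PhantomSpec, generate_dataset
from .preprocess import ClaheParams, RoiSample, apply_clahe
from .training import TrainConfig, evaluate as _evaluate, train as _train

__all__ = ["RunConfig", "STAGES", "run_pipeline", "predict"]

STAGES = ("generate", "preprocess", "augment", "train", "evaluate")


@dataclass(frozen=True)
class RunConfig:
    """Everything one pipeline run needs; round-trips through YAML unchanged."""

    out_dir: str = "run"
    seed: int = 0
    n_train_pool: int = 90      # raw ROIs generated for the train/val pool
    n_test: int = 17            # held-out test ROIs (never augmented)
    phantom: PhantomSpec = field(default_factory=PhantomSpec)
    clahe: ClaheParams = field(default_factory=ClaheParams)
    split: SplitSpec = field(default_factory=SplitSpec)
    model: ModelConfig = field(default_factory=ModelConfig)
    train: TrainConfig = field(default_factory=TrainConfig)
    augment_enabled: bool = True
    threshold: float = 0.5

    @classmethod
    def tiny(cls, seed: int = 0, out_dir: str = "run") -> "RunConfig":
        """Desk-scale profile: 64x64 phantoms, 200 train / 50 val / 50 test, width-1/8 model.

        Every length scale shrinks by 4 relative to the 256-pixel profile
        (lesion radii, background texture, CLAHE tiles stay 32 pixels), and
        the learning rate rises to 3e-3: with ~50x fewer optimization steps
        than a full-scale run, the full-scale rate of 1e-4 cannot move a
        46-conv-layer network far from its initialization.
        """
        return cls(
            out_dir=out_dir, seed=seed,
            n_train_pool=250, n_test=50, augment_enabled=False,
            phantom=PhantomSpec(size=64, lesion_radius_range=(8.0, 12.0),
                                background_texture_scale=8.0, seed=seed),
            clahe=ClaheParams(clip_limit=2.0, tile_grid=(2, 2)),
            split=SplitSpec(train_fraction=0.8, seed=seed),
            model=ModelConfig.tiny(seed=seed),
            train=TrainConfig(learning_rate=3e-3, max_epochs=25, seed=seed),
        )

    def validate(self) -> None:
        if self.n_train_pool < 2 or self.n_test < 1:
            raise ConfigError("need n_train_pool >= 2 and n_test >= 1")
        if self.phantom.size != self.model.input_size:
            raise ConfigError(f"phantom size {self.phantom.size} must match model "
                              f"input_size {self.model.input_size}")
        self.phantom.validate()
        self.clahe.validate()
        self.split.validate()
        self.model.validate()
        self.train.validate()

    def to_yaml(self, path: str | Path) -> None:
        doc = asdict(self)
        Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        doc = yaml.safe_load(Path(path).read_text())
        return cls.from_dict(doc)

    @classmethod
    def from_dict(cls, doc: dict) -> "RunConfig":
        def tup(d, *keys):
            for k in keys:
                if k in d and d[k] is not None:
                    d[k] = tuple(d[k])
        phantom = dict(doc.get("phantom", {}))
        tup(phantom, "lesion_radius_range", "dynamic_range")
        clahe = dict(doc.get("clahe", {}))
        tup(clahe, "tile_grid")
        model = dict(doc.get("model", {}))
        tup(model, "channel_schedule")
        kwargs = {k: v for k, v in doc.items()
                  if k in ("out_dir", "seed", "n_train_pool", "n_test",
                           "augment_enabled", "threshold")}
        return cls(phantom=PhantomSpec(**phantom), clahe=ClaheParams(**clahe),
                   split=SplitSpec(**doc.get("split", {})),
                   model=ModelConfig(**model), train=TrainConfig(**doc.get("train", {})),
                   **kwargs)


def _marker(stage_dir: Path) -> Path:
    return stage_dir / ".complete"


def _require(stage_dir: Path, stage: str, needed_by: str) -> None:
    if not _marker(stage_dir).exists():
        raise DependencyError(f"stage {needed_by!r} needs completed stage {stage!r} "
                              f"(missing {_marker(stage_dir)})")


def _stage_generate(cfg: RunConfig, out: Path) -> None:
    stage = out / "generate"
    generate_dataset(cfg.n_train_pool, cfg.seed, replace(cfg.phantom, seed=cfg.seed),
                     stage, split="trainval", dataset_tag="phantom")
    generate_dataset(cfg.n_test, cfg.seed + 10_000_000, cfg.phantom, stage,
                     split="test", dataset_tag="phantom", manifest_name="manifest_test.csv")
    df = pd.concat([imgio.read_manifest(stage / "manifest.csv"),
                    imgio.read_manifest(stage / "manifest_test.csv")])
    imgio.write_manifest(df, stage / "manifest.csv")
    (stage / "manifest_test.csv").unlink()
    _marker(stage).touch()


def _stage_preprocess(cfg: RunConfig, out: Path) -> None:
    _require(out / "generate", "generate", "preprocess")
    stage = out / "preprocess"
    (stage / "images").mkdir(parents=True, exist_ok=True)
    (stage / "masks").mkdir(parents=True, exist_ok=True)
    src_manifest = out / "generate" / "manifest.csv"
    df = imgio.read_manifest(src_manifest)
    rows = []
    for image, mask, row in imgio.load_pairs(src_manifest, df):
        enhanced = apply_clahe(image, cfg.clahe)
        rel_img = f"images/{row.source_id}.png"
        rel_msk = f"masks/{row.source_id}_mask.png"
        imgio.write_image(stage / rel_img, enhanced)
        imgio.write_mask(stage / rel_msk, mask)
        rows.append({**row, "image_path": rel_img, "mask_path": rel_msk})
    imgio.write_manifest(pd.DataFrame(rows)[df.columns], stage / "manifest.csv")
    _marker(stage).touch()


def _stage_augment(cfg: RunConfig, out: Path) -> None:
    _require(out / "preprocess", "preprocess", "augment")
    stage = out / "augment"
    (stage / "images").mkdir(parents=True, exist_ok=True)
    (stage / "masks").mkdir(parents=True, exist_ok=True)
    src_manifest = out / "preprocess" / "manifest.csv"
    df = imgio.read_manifest(src_manifest)
    rows = []
    for image, mask, row in imgio.load_pairs(src_manifest, df):
        if row.split == "test" or not cfg.augment_enabled:
            variants = [(VARIANTS[0], RoiSample(image, mask, row.source_id, row.dataset_tag))]
        else:
            sample = RoiSample(image, mask, row.source_id, row.dataset_tag)
            variants = [(v, apply_variant(sample, v)) for v in VARIANTS]
        for v, s in variants:
            stem = f"{row.source_id}_r{v.rotation}{'f' if v.flipped else ''}"
            rel_img = f"images/{stem}.png"
            rel_msk = f"masks/{stem}_mask.png"
            imgio.write_image(stage / rel_img, s.image)
            imgio.write_mask(stage / rel_msk, s.mask)
            rows.append({**row, "image_path": rel_img, "mask_path": rel_msk,
                         "variant_rotation": v.rotation, "variant_flipped": v.flipped})
    aug = pd.DataFrame(rows)
    # split the augmented train/val pool; test rows pass through untouched
    pool = aug[aug.split != "test"]
    idx_train, idx_val = split_train_val(list(pool.index), cfg.split)
    aug.loc[idx_train, "split"] = "train"
    aug.loc[idx_val, "split"] = "val"
    imgio.write_manifest(aug, stage / "manifest.csv")
    _marker(stage).touch()


def _load_split(manifest: Path, split: str, size: int):
    df = imgio.read_manifest(manifest)
    part = df[df.split == split]
    if part.empty:
        raise ConfigError(f"no rows with split={split!r} in {manifest}")
    images, masks = [], []
    for image, mask, _ in imgio.load_pairs(manifest, part):
        if image.shape != (size, size):
            raise DataError(f"expected {size}x{size} images, got {image.shape}")
        images.append(image)
        masks.append(mask)
    return np.stack(images).astype(np.float32), np.stack(masks).astype(np.float32)


def _stage_train(cfg: RunConfig, out: Path) -> None:
    _require(out / "augment", "augment", "train")
    stage = out / "train"
    stage.mkdir(parents=True, exist_ok=True)
    manifest = out / "augment" / "manifest.csv"
    size = cfg.model.input_size
    train_set = _load_split(manifest, "train", size)
    val_set = _load_split(manifest, "val", size)
    model = ConnectedSegNets(cfg.model)
    _train(model, train_set, val_set, cfg.train, run_dir=stage)
    save_checkpoint(model, stage / "checkpoint_best.npz")
    _marker(stage).touch()


def _stage_evaluate(cfg: RunConfig, out: Path) -> None:
    _require(out / "train", "train", "evaluate")
    stage = out / "evaluate"
    stage.mkdir(parents=True, exist_ok=True)
    model = load_checkpoint(out / "train" / "checkpoint_best.npz")
    test_set = _load_split(out / "augment" / "manifest.csv", "test", cfg.model.input_size)
    res = _evaluate(model, test_set, threshold=cfg.threshold,
                    batch_size=cfg.train.batch_size)
    (stage / "metrics.json").write_text(json.dumps(
        res["aggregate"].as_percent_dict(), indent=2) + "\n")
    res["per_sample"].to_csv(stage / "per_sample_metrics.csv", index=False,
                             lineterminator="\n")
    if res["normalized_confusion"] is not None:
        res["normalized_confusion"].to_csv(stage / "normalized_confusion.csv",
                                           lineterminator="\n")
    _marker(stage).touch()


_STAGE_FNS = {
    "generate": _stage_generate,
    "preprocess": _stage_preprocess,
    "augment": _stage_augment,
    "train": _stage_train,
    "evaluate": _stage_evaluate,
}


def run_pipeline(config: RunConfig, stages: tuple[str, ...] = STAGES) -> Path:
    """Run the requested stages in dependency order; returns the run directory."""
    unknown = set(stages) - set(STAGES)
    if unknown:
        raise ConfigError(f"unknown stages: {sorted(unknown)}")
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config.to_yaml(out / "config.yaml")
    for stage in STAGES:
        if stage in stages:
            _STAGE_FNS[stage](config, out)
    return out


def predict(checkpoint: str | Path, image_paths: list[str | Path], out_dir: str | Path,
            threshold: float = 0.5) -> list[Path]:
    """Segment images with a trained checkpoint; write binary masks + overlays.

    Returns the list of mask paths, one per input, in order.
    """
    model = load_checkpoint(checkpoint)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    size = model.config.input_size
    written = []
    for path in image_paths:
        image = imgio.read_image(path)
        if image.shape != (size, size):
            raise DataError(f"{path}: expected {size}x{size}, got {image.shape}")
        mask = model.predict(image[None], threshold=threshold)[0]
        stem = Path(path).stem
        mask_path = out_dir / f"{stem}_pred.png"
        imgio.write_mask(mask_path, mask)
        overlay = np.stack([np.clip(image + 0.5 * mask, 0, 1), image, image], axis=-1)
        import imageio.v3 as iio
        iio.imwrite(out_dir / f"{stem}_overlay.png",
                    (overlay * 255).astype(np.uint8))
        written.append(mask_path)
    return written
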