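"""Model assembly, configuration, training, checkpointing and prediction."""

from __future__ import annotations

import csv
import json
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
import yaml

from .deformable_pathway import DeformablePathway, StageConfig
from .hierarchical_decoder import HierarchicalDecoder
from .losses_metrics import composite_loss, dsc
from .nn import Adam, Conv2d, Module, ReduceLROnPlateau, Tensor
from .phantom_io import AugmentSpec, ImageSample, augment, random_augment_spec
from .semantic_enhance import SEM, SEMConfig
from .ssm_pathway import SSMConfig, SSMPathway

__all__ = [
    "ModelConfig", "TrainConfig", "PaddingRecord", "Network",
    "build_model", "train", "predict", "save_checkpoint", "load_checkpoint",
    "pad_to_multiple",
]


@dataclass(frozen=True)
class ModelConfig:
    stages: StageConfig = StageConfig()
    ssm: SSMConfig = SSMConfig()
    sem: SEMConfig = SEMConfig()
    attention_ratio: int = 4
    disable_tafi: tuple[int, ...] = ()
    # structural ablations (mirror the w/o variants):
    #   'ssp' drops the state-space pathway, 'adp' the deformable pathway,
    #   'tafi' all gated fusion sites, 'sem' the semantic enhance module.
    ablate: tuple[str, ...] = ()
    seed: int = 0

    @staticmethod
    def small(seed: int = 0, **overrides) -> "ModelConfig":
        """A CPU-friendly footprint used by tests and the overfit probe."""
        base = ModelConfig(
            stages=StageConfig(depths=(1, 1, 1, 1), channels=(8, 16, 24, 32),
                               groups=2, droppath_rate=0.0, mlp_ratio=2.0),
            ssm=SSMConfig(stem_channels=4, state_dim=4, mlp_ratio=2.0),
            sem=SEMConfig(fused_channels=32, codewords=8, mlp_ratio=2.0),
            attention_ratio=2, seed=seed)
        return replace(base, **overrides) if overrides else base


@dataclass(frozen=True)
class TrainConfig:
    learning_rate: float = 1e-5
    epochs: int = 50
    batch_size: int = 2
    plateau_patience: int = 5
    plateau_factor: float = 0.1
    w_dice: float = 1.0
    w_ce: float = 1.0
    seed: int = 0
    augment_spec: AugmentSpec | None = None
    max_steps: int | None = None

    def __post_init__(self):
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")


@dataclass(frozen=True)
class PaddingRecord:
    """How an input was padded up to the next multiples of 32."""

    original: tuple[int, int]
    padded: tuple[int, int]

    def crop(self, array: np.ndarray) -> np.ndarray:
        h, w = self.original
        return array[..., :h, :w]


def pad_to_multiple(image: np.ndarray, multiple: int = 32) -> tuple[np.ndarray, PaddingRecord]:
    """Reflect-pad the trailing two axes up to the next multiples."""
    h, w = image.shape[-2:]
    ph = (-h) % multiple
    pw = (-w) % multiple
    rec = PaddingRecord(original=(h, w), padded=(h + ph, w + pw))
    if ph or pw:
        width = [(0, 0)] * (image.ndim - 2) + [(0, ph), (0, pw)]
        image = np.pad(image, width, mode="reflect")
    return image, rec


class Network(Module):
    """Dual-pathway encoder + deep-feature fusion + gated decoder."""

    def __init__(self, config: ModelConfig = ModelConfig()):
        super().__init__()
        self.config = config
        rng = np.random.default_rng(config.seed)
        ch = config.stages.channels
        ablate = set(config.ablate)
        unknown = ablate - {"ssp", "adp", "tafi", "sem"}
        if unknown:
            raise ValueError(f"unknown ablation flags: {sorted(unknown)}")
        if {"ssp", "adp"} <= ablate:
            raise ValueError("cannot ablate both encoder pathways")
        self.deformable = None if "adp" in ablate else DeformablePathway(
            config.stages, rng=rng)
        self.ssm = None if "ssp" in ablate else SSMPathway(
            ch, config.ssm, rng=rng)
        if "sem" in ablate:
            self.sem = None
            self.deep_fuse = Conv2d(2 * ch[3], ch[3], 1, rng=rng)
        else:
            self.sem = SEM(ch[3], ch[3], ch[3], config.sem, rng=rng)
            self.deep_fuse = None
        disable = tuple(range(1, 4)) if "tafi" in ablate else config.disable_tafi
        self.decoder = HierarchicalDecoder(
            ch, attention_ratio=config.attention_ratio,
            disable_tafi=disable, rng=rng)

    def forward(self, image: Tensor) -> Tensor:
        h, w = image.shape[2:]
        if h % 32 or w % 32:
            raise ValueError(
                f"input dims ({h}, {w}) must be multiples of 32; use predict() "
                "for arbitrary sizes")
        if self.deformable is not None:
            px = self.deformable(image)
        if self.ssm is not None:
            py = self.ssm(image)
        if self.deformable is None:      # single-pathway ablation: duplicate
            px = py
        if self.ssm is None:
            py = px
        from .nn import concat
        if self.sem is not None:
            deep = self.sem(px[3], py[3])
        else:
            deep = self.deep_fuse(concat([px[3], py[3]], axis=1))
        return self.decoder(px, py, deep)


def build_model(config: ModelConfig = ModelConfig()) -> Network:
    """Build the network; deterministic given ``config.seed``."""
    return Network(config)


# --------------------------------------------------------------------------
# training
# --------------------------------------------------------------------------

def _to_batch(samples: list[ImageSample]) -> tuple[Tensor, np.ndarray]:
    images = np.stack([s.image for s in samples])
    masks = np.stack([s.mask for s in samples]).astype(np.float64)
    return Tensor(images), masks


def _batch_loss(model: Network, samples: list[ImageSample], cfg: TrainConfig):
    images, masks = _to_batch(samples)
    logits = model(images)
    probs = logits.reshape(*masks.shape).sigmoid()
    return composite_loss(probs, masks, w_dice=cfg.w_dice, w_ce=cfg.w_ce), probs


def train(model: Network, train_set: list[ImageSample],
          val_set: list[ImageSample], config: TrainConfig,
          out_dir: str | Path | None = None,
          log=None) -> tuple[dict[str, np.ndarray], list[dict]]:
    """Adam training with plateau scheduling and best-on-validation
    checkpointing.

    Returns ``(best_state, history)`` where ``best_state`` is the weight
    dict of the best validation epoch and ``history`` a list of per-epoch
    records (also written to ``history.csv`` under ``out_dir``).
    """
    if not train_set or not val_set:
        raise ValueError("train and validation sets must be nonempty")
    rng = np.random.default_rng(config.seed)
    optimizer = Adam(model.parameters(), lr=config.learning_rate)
    scheduler = ReduceLROnPlateau(optimizer, factor=config.plateau_factor,
                                  patience=config.plateau_patience)
    history: list[dict] = []
    best_val = np.inf
    best_state = model.state_arrays()
    step = 0
    done = False
    for epoch in range(config.epochs):
        model.train()
        order = rng.permutation(len(train_set))
        epoch_losses = []
        for start in range(0, len(order), config.batch_size):
            idx = order[start:start + config.batch_size]
            batch = [train_set[i] for i in idx]
            if config.augment_spec is not None:
                batch = [augment(s, random_augment_spec(rng, config.augment_spec))
                         for s in batch]
            loss, _ = _batch_loss(model, batch, config)
            if not np.isfinite(loss.data):
                raise RuntimeError(
                    f"non-finite loss at epoch {epoch}, batch ids "
                    f"{[train_set[i].id for i in idx]}")
            optimizer.zero_grad()
            loss.backward()
            optimizer.step()
            epoch_losses.append(loss.item())
            step += 1
            if config.max_steps is not None and step >= config.max_steps:
                done = True
                break
        model.eval()
        val_losses, val_dices = [], []
        for start in range(0, len(val_set), config.batch_size):
            batch = val_set[start:start + config.batch_size]
            loss, probs = _batch_loss(model, batch, config)
            val_losses.append(loss.item())
            for prob, s in zip(probs.data, [b for b in batch]):
                val_dices.append(dsc(prob > 0.5, s.mask))
        val_loss = float(np.mean(val_losses))
        record = {
            "epoch": epoch, "lr": optimizer.lr,
            "train_loss": float(np.mean(epoch_losses)),
            "val_loss": val_loss, "val_dice": float(np.mean(val_dices)),
        }
        history.append(record)
        if log is not None:
            log(record)
        if val_loss < best_val:
            best_val = val_loss
            best_state = model.state_arrays()
        scheduler.step(val_loss)
        if done:
            break
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        with open(out_dir / "history.csv", "w", newline="") as fh:
            writer = csv.DictWriter(fh, fieldnames=list(history[0]))
            writer.writeheader()
            writer.writerows(history)
        save_checkpoint(out_dir / "best.npz", model, best_state)
    return best_state, history


def save_checkpoint(path: str | Path, model: Network,
                    state: dict[str, np.ndarray] | None = None) -> None:
    """Single-file weights + config echo (JSON string inside the archive)."""
    state = state if state is not None else model.state_arrays()
    cfg = json.dumps(asdict(model.config))
    np.savez(path, __config__=np.array(cfg), **state)


def load_checkpoint(path: str | Path) -> Network:
    with np.load(path, allow_pickle=False) as data:
        cfg_raw = json.loads(str(data["__config__"]))
        state = {k: data[k] for k in data.files if k != "__config__"}
    cfg = ModelConfig(
        stages=StageConfig(**{**cfg_raw["stages"],
                              "depths": tuple(cfg_raw["stages"]["depths"]),
                              "channels": tuple(cfg_raw["stages"]["channels"])}),
        ssm=SSMConfig(**cfg_raw["ssm"]),
        sem=SEMConfig(**cfg_raw["sem"]),
        attention_ratio=cfg_raw["attention_ratio"],
        disable_tafi=tuple(cfg_raw["disable_tafi"]),
        ablate=tuple(cfg_raw["ablate"]),
        seed=cfg_raw["seed"])
    model = build_model(cfg)
    model.load_state_arrays(state)
    return model


# --------------------------------------------------------------------------
# prediction
# --------------------------------------------------------------------------

def predict(model: Network, image: np.ndarray,
            threshold: float = 0.5) -> np.ndarray:
    """Segment an arbitrary-size (3, H, W) image: reflect-pad to multiples
    of 32, forward, sigmoid, threshold, crop back.  Returns a {0,1} mask."""
    if image.ndim != 3 or image.shape[0] != 3:
        raise ValueError(f"expected a (3, H, W) image, got {image.shape}")
    padded, rec = pad_to_multiple(image)
    model.eval()
    logits = model(Tensor(padded[None])).data[0, 0]
    from scipy.special import expit
    probs = expit(logits)
    return rec.crop((probs > threshold).astype(np.uint8))


# --------------------------------------------------------------------------
# yaml config plumbing for the CLI
# --------------------------------------------------------------------------

def configs_from_yaml(path: str | Path) -> tuple[ModelConfig, TrainConfig]:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    model_raw = dict(raw.get("model", {}))
    small = model_raw.pop("small", False)
    kw = _tupled(model_raw)
    if "stages" in kw:
        kw["stages"] = StageConfig(**_tupled(dict(model_raw["stages"])))
    if "ssm" in kw:
        kw["ssm"] = SSMConfig(**model_raw["ssm"])
    if "sem" in kw:
        kw["sem"] = SEMConfig(**model_raw["sem"])
    model_cfg = ModelConfig.small(**kw) if small else ModelConfig(**kw)
    train_raw = dict(raw.get("train", {}))
    if "augment_spec" in train_raw and train_raw["augment_spec"] is not None:
        train_raw["augment_spec"] = AugmentSpec(**_tupled(train_raw["augment_spec"]))
    train_cfg = TrainConfig(**train_raw)
    return model_cfg, train_cfg


def _tupled(d: dict) -> dict:
    return {k: tuple(v) if isinstance(v, list) else v for k, v in d.items()}
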