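"""3D CNN mapping voxel grids to fragment-fingerprint predictions.

The architecture processes a (B, 9, 24, 24, 24) grid through seven stages:
input batch normalization; three Conv(k3, valid)+ReLU pairs (24 -> 22 -> 20
-> 18); max pool k2 + batch normalization (18 -> 9); three more Conv+ReLU
pairs (9 -> 7 -> 5 -> 3); global average pooling and flattening to (B, 64);
dropout 0.5 + fully connected 64 -> 512 + ReLU; dropout 0.5 + fully
connected 512 -> 2048 + sigmoid, yielding per-bit values in (0, 1).

Training minimises the batch-mean cosine distance (1 - cosine similarity)
between predicted continuous fingerprints and binary targets with Adam
(lr 1e-4, batch 16, float32). Every training epoch re-renders each example's
voxel grid under a fresh uniform random rotation; validation always uses the
identity orientation so model selection is reproducible. The production
checkpoint is the epoch with the lowest validation loss (earliest on ties).
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from . import nn
from .fragmenter import FragmentationExample
from .mol import InputError, Molecule
from .splitter import SplitAssignment
from .voxelizer import (
    VoxelReadyExample,
    prepare_example,
    random_rotation,
    voxelize_batch,
    voxelize_prepared,
)


@dataclass(frozen=True)
class ModelConfig:
    in_channels: int = 9
    conv_channels: int = 64
    kernel: int = 3
    pool_kernel: int = 2
    embedding_dim: int = 512
    output_dim: int = 2048
    dropout_rate: float = 0.5


@dataclass(frozen=True)
class TrainConfig:
    optimizer: str = "adam"
    learning_rate: float = 1e-4
    batch_size: int = 16
    precision: int = 32
    epochs: int = 60
    seed: int = 0


@dataclass
class Checkpoint:
    weights: dict[str, np.ndarray]
    epoch: int
    validation_loss: float
    model_config: ModelConfig

    def save(self, path: str | Path) -> None:
        meta = json.dumps(
            {
                "epoch": self.epoch,
                "validation_loss": self.validation_loss,
                "model_config": asdict(self.model_config),
            }
        )
        np.savez(path, __meta__=np.array(meta), **self.weights)

    @classmethod
    def load(cls, path: str | Path) -> "Checkpoint":
        with np.load(path, allow_pickle=False) as data:
            meta = json.loads(str(data["__meta__"]))
            weights = {k: data[k] for k in data.files if k != "__meta__"}
        return cls(
            weights=weights,
            epoch=meta["epoch"],
            validation_loss=meta["validation_loss"],
            model_config=ModelConfig(**meta["model_config"]),
        )


class FragNet:
    """The staged voxel-to-fingerprint network."""

    def __init__(self, config: ModelConfig = ModelConfig(), seed: int = 0):
        self.config = config
        rng = np.random.default_rng(seed)
        self._dropout_rng = np.random.default_rng(seed + 1)
        c = config.conv_channels
        k = config.kernel
        self.net = nn.Sequential(
            [
                nn.BatchNorm(config.in_channels),
                nn.Conv3d(config.in_channels, c, k, rng),
                nn.ReLU(),
                nn.Conv3d(c, c, k, rng),
                nn.ReLU(),
                nn.Conv3d(c, c, k, rng),
                nn.ReLU(),
                nn.MaxPool3d(config.pool_kernel),
                nn.BatchNorm(c),
                nn.Conv3d(c, c, k, rng),
                nn.ReLU(),
                nn.Conv3d(c, c, k, rng),
                nn.ReLU(),
                nn.Conv3d(c, c, k, rng),
                nn.ReLU(),
                nn.GlobalAvgPool(),
                nn.Dropout(config.dropout_rate, self._dropout_rng),
                nn.Linear(c, config.embedding_dim, rng),
                nn.ReLU(),
                nn.Dropout(config.dropout_rate, self._dropout_rng),
                nn.Linear(config.embedding_dim, config.output_dim, rng),
                nn.Sigmoid(),
            ]
        )

    def forward(self, grids: np.ndarray, *, train: bool = False) -> np.ndarray:
        x = np.asarray(grids, dtype=np.float32)
        if x.ndim != 5 or x.shape[1:] != (self.config.in_channels, 24, 24, 24):
            raise InputError(
                f"expected input of shape (B, {self.config.in_channels}, 24, 24, 24), got {x.shape}"
            )
        return self.net.forward(x, train=train)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return self.net.backward(dy)

    def forward_shapes(self, grids: np.ndarray) -> list[tuple[int, ...]]:
        """Shapes after each architecture stage, for the printed-shape contract."""
        x = np.asarray(grids, dtype=np.float32)
        shapes: list[tuple[int, ...]] = []
        record_after = {
            1: False, 2: True, 4: True, 6: True,  # three conv-relu pairs
            8: True,                                # pool + batchnorm
            10: True, 12: True, 14: True,           # three more conv-relu pairs
            15: True,                               # global average pool / flatten
            17: True,                               # fc to embedding (after relu)
            20: True,                               # fc to fingerprint (after sigmoid)
        }
        for i, layer in enumerate(self.net.layers):
            x = layer.forward(x, train=False)
            if record_after.get(i):
                shapes.append(tuple(x.shape))
        return shapes

    # -- weight (de)serialization -----------------------------------------

    def state_dict(self) -> dict[str, np.ndarray]:
        out: dict[str, np.ndarray] = {}
        for key, layer, name in self.net.named_params():
            out[key] = layer.params[name].copy()
        for i, layer in enumerate(self.net.layers):
            if isinstance(layer, nn.BatchNorm):
                out[f"layer{i}.running_mean"] = layer.running_mean.copy()
                out[f"layer{i}.running_var"] = layer.running_var.copy()
        return out

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for key, layer, name in self.net.named_params():
            if key not in state:
                raise InputError(f"checkpoint is missing parameter {key}")
            if state[key].shape != layer.params[name].shape:
                raise InputError(
                    f"checkpoint parameter {key} has shape {state[key].shape}, "
                    f"expected {layer.params[name].shape}"
                )
            layer.params[name] = state[key].astype(np.float32).copy()
        for i, layer in enumerate(self.net.layers):
            if isinstance(layer, nn.BatchNorm):
                layer.running_mean = state[f"layer{i}.running_mean"].copy()
                layer.running_var = state[f"layer{i}.running_var"].copy()


# -- loss -------------------------------------------------------------------


def _cosine_terms(pred: np.ndarray, target: np.ndarray):
    if pred.shape != target.shape:
        raise InputError(f"shape mismatch: {pred.shape} vs {target.shape}")
    t = target.astype(np.float64)
    p = pred.astype(np.float64)
    tn = np.linalg.norm(t, axis=1)
    if np.any(tn == 0):
        raise InputError("cosine loss target contains an all-zero fingerprint")
    pn = np.linalg.norm(p, axis=1)
    pn = np.maximum(pn, 1e-12)
    cos = (p * t).sum(axis=1) / (pn * tn)
    return p, t, pn, tn, cos


def cosine_loss(pred: np.ndarray, target: np.ndarray) -> float:
    """Batch-mean cosine distance 1 - cos(pred, target)."""
    *_, cos = _cosine_terms(pred, target)
    return float(np.mean(1.0 - cos))


def cosine_loss_grad(pred: np.ndarray, target: np.ndarray) -> tuple[float, np.ndarray]:
    p, t, pn, tn, cos = _cosine_terms(pred, target)
    B = p.shape[0]
    dcos = t / (pn * tn)[:, None] - p * (cos / pn**2)[:, None]
    grad = (-dcos / B).astype(np.float32)
    return float(np.mean(1.0 - cos)), grad


# -- training ----------------------------------------------------------------


@dataclass
class TrainResult:
    checkpoints: list[Checkpoint]
    production: Checkpoint
    history: list[dict] = field(default_factory=list)


def warmup_cosine_schedule(peak_lr: float, floor_lr: float, warmup_frac: float = 0.1):
    """Learning-rate schedule: linear warmup from ``floor_lr`` to ``peak_lr``
    over the first ``warmup_frac`` of steps, then cosine decay back to
    ``floor_lr``. Returns a callable (step, total_steps) -> lr.

    Useful for short small-batch runs, where a flat rate high enough to
    converge within the epoch budget destabilises the first steps.
    """

    def schedule(step: int, total: int) -> float:
        warm = max(1, int(warmup_frac * total))
        if step < warm:
            return floor_lr + (peak_lr - floor_lr) * (step + 1) / warm
        span = max(1, total - warm)
        t = (step - warm) / span
        return floor_lr + 0.5 * (peak_lr - floor_lr) * (1 + np.cos(np.pi * t))

    return schedule


def _eval_loss(model: FragNet, grids: np.ndarray, targets: np.ndarray, batch: int) -> float:
    losses, weights = [], []
    for lo in range(0, len(grids), batch):
        sl = slice(lo, lo + batch)
        pred = model.forward(grids[sl], train=False)
        losses.append(cosine_loss(pred, targets[sl]))
        weights.append(len(grids[sl]))
    return float(np.average(losses, weights=weights))


def fit(
    train_set: list[VoxelReadyExample],
    val_set: list[VoxelReadyExample],
    model_config: ModelConfig = ModelConfig(),
    train_config: TrainConfig = TrainConfig(),
    init_state: dict[str, np.ndarray] | None = None,
    checkpoint_dir: str | Path | None = None,
    lr_schedule=None,
) -> TrainResult:
    """Train the network; returns all per-epoch checkpoints and the production one.

    Each epoch renders every training example under a fresh random rotation;
    validation grids are rendered once with the identity rotation. With
    ``epochs=0`` the initial weights become the production checkpoint.
    ``lr_schedule`` is an optional (step, total_steps) -> lr callable
    overriding the constant configured rate.
    """
    if not val_set:
        raise InputError("training requires a non-empty validation set")
    if any(p.target is None for p in train_set + val_set):
        raise InputError("all examples must carry fingerprint targets")

    model = FragNet(model_config, seed=train_config.seed)
    if init_state is not None:
        model.load_state_dict(init_state)
    optimizer = nn.Adam(model.net, lr=train_config.learning_rate)
    rng = np.random.default_rng(train_config.seed)
    batch = train_config.batch_size

    val_grids = voxelize_batch(val_set, [None] * len(val_set))
    val_targets = np.stack([p.target for p in val_set]).astype(np.float32)
    train_targets = np.stack([p.target for p in train_set]).astype(np.float32)

    checkpoints: list[Checkpoint] = []
    history: list[dict] = []

    def snapshot(epoch: int) -> Checkpoint:
        val_loss = _eval_loss(model, val_grids, val_targets, batch)
        ckpt = Checkpoint(
            weights=model.state_dict(),
            epoch=epoch,
            validation_loss=val_loss,
            model_config=model_config,
        )
        if checkpoint_dir is not None:
            Path(checkpoint_dir).mkdir(parents=True, exist_ok=True)
            ckpt.save(Path(checkpoint_dir) / f"epoch_{epoch:03d}.npz")
        checkpoints.append(ckpt)
        return ckpt

    steps_per_epoch = int(np.ceil(len(train_set) / batch))
    total_steps = max(1, train_config.epochs * steps_per_epoch)
    global_step = 0

    if train_config.epochs == 0:
        snapshot(0)
    for epoch in range(1, train_config.epochs + 1):
        rot_seeds = rng.integers(2**31, size=len(train_set))
        grids = voxelize_batch(train_set, [random_rotation(int(s)) for s in rot_seeds])
        order = rng.permutation(len(train_set))
        epoch_losses, epoch_sizes = [], []
        for lo in range(0, len(order), batch):
            idx = order[lo : lo + batch]
            pred = model.forward(grids[idx], train=True)
            loss, grad = cosine_loss_grad(pred, train_targets[idx])
            model.backward(grad)
            if lr_schedule is not None:
                optimizer.lr = lr_schedule(global_step, total_steps)
            optimizer.step()
            global_step += 1
            epoch_losses.append(loss)
            epoch_sizes.append(len(idx))
        ckpt = snapshot(epoch)
        history.append(
            {
                "epoch": epoch,
                "train_loss": float(np.average(epoch_losses, weights=epoch_sizes)),
                "val_loss": ckpt.validation_loss,
            }
        )

    best = min(range(len(checkpoints)), key=lambda i: (checkpoints[i].validation_loss, i))
    return TrainResult(checkpoints=checkpoints, production=checkpoints[best], history=history)


# -- split-aware wrappers -----------------------------------------------------


def prepare_examples(
    examples: list[FragmentationExample], receptors: dict[str, Molecule]
) -> list[VoxelReadyExample]:
    return [
        prepare_example(
            receptors[x.entry_id],
            x.trimmed_ligand,
            x.branch_atom,
            target=x.fingerprint().astype(np.float32),
        )
        for x in examples
    ]


def train(
    examples: list[FragmentationExample],
    receptors: dict[str, Molecule],
    assignment: SplitAssignment,
    train_config: TrainConfig = TrainConfig(),
    model_config: ModelConfig = ModelConfig(),
    checkpoint_dir: str | Path | None = None,
) -> TrainResult:
    """Train from a split assignment (train/val membership by entry id)."""
    tr = [x for x in examples if assignment.split_of(x.entry_id) == "train"]
    va = [x for x in examples if assignment.split_of(x.entry_id) == "val"]
    if not tr or not va:
        raise InputError("split must populate both train and val sets")
    return fit(
        prepare_examples(tr, receptors),
        prepare_examples(va, receptors),
        model_config,
        train_config,
        checkpoint_dir=checkpoint_dir,
    )


def finetune(
    foundational: Checkpoint,
    examples: list[FragmentationExample],
    receptors: dict[str, Molecule],
    ligand_split: dict[str, str],
    epochs: int = 30,
    train_config: TrainConfig | None = None,
    checkpoint_dir: str | Path | None = None,
) -> TrainResult:
    """Continue training from a foundational checkpoint on one receptor class.

    Examples follow their ligand's cluster split; fragments with three or
    fewer heavy atoms are discarded, matching the large-fragment constraint
    of the foundational model.
    """
    cfg = train_config or TrainConfig(epochs=epochs)
    if cfg.epochs != epochs:
        cfg = TrainConfig(
            optimizer=cfg.optimizer,
            learning_rate=cfg.learning_rate,
            batch_size=cfg.batch_size,
            precision=cfg.precision,
            epochs=epochs,
            seed=cfg.seed,
        )
    big = [x for x in examples if x.fragment_heavy_atoms >= 4]
    tr = [x for x in big if ligand_split.get(x.ligand_identity) == "train"]
    va = [x for x in big if ligand_split.get(x.ligand_identity) == "val"]
    if not tr or not va:
        raise InputError("fine-tuning split must populate both train and val sets")
    return fit(
        prepare_examples(tr, receptors),
        prepare_examples(va, receptors),
        foundational.model_config,
        cfg,
        init_state=foundational.weights,
        checkpoint_dir=checkpoint_dir,
    )
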