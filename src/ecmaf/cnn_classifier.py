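"""CNN classifier for ECM-images with majority-of-votes ensembling.

The network takes a 10x219 single-channel ECM-image and outputs softmax
likelihoods for the AF and non-AF classes.  Architecture (activations):

    10x219x1 -> conv(3,9)x10 -> BN -> ReLU -> 10x219x10
             -> maxpool(3,3)/(1,2)        -> 10x110x10
             -> conv(3,9)x15 -> BN -> ReLU -> 10x110x15
             -> maxpool(3,3)/(2,2)        -> 5x55x15
             -> conv(2,4)x20/(2,2) -> BN -> ReLU -> 3x28x20
             -> FC -> softmax             -> 2

for a total of 10,217 trainable parameters.  Three networks are trained on
patient-disjoint 80/20 splits and combined by majority of votes (MoV).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import _nnet
from ._nnet import (
    BatchNorm2d, Conv2d, Flatten, Layer, Linear, MaxPool2d, ReLU, SGDMomentum,
    cross_entropy_grad, softmax,
)
from .ecg_core import AF, NONAF, ECGRecord, PreprocessConfig
from .ecm_builder import ECMDataset, build_ecm_dataset

log = logging.getLogger(__name__)

#: class order of the softmax output: index 0 = AF, index 1 = non-AF
CLASSES = (AF, NONAF)

#: expected activation shapes (C, H, W) after each layer, input excluded
EXPECTED_SHAPES = [
    (10, 10, 219), (10, 10, 219), (10, 10, 219),   # conv1, bn1, relu1
    (10, 10, 110),                                 # pool1
    (15, 10, 110), (15, 10, 110), (15, 10, 110),   # conv2, bn2, relu2
    (15, 5, 55),                                   # pool2
    (20, 3, 28), (20, 3, 28), (20, 3, 28),         # conv3, bn3, relu3
    (1680,), (2,),                                 # flatten, fc
]

TOTAL_PARAMETERS = 10217


@dataclass
class TrainConfig:
    """Published optimizer settings; batch size defaults to a desk-scale 256
    (the published 3,000 remains available by flag)."""

    learning_rate: float = 0.01
    momentum: float = 0.9
    l2: float = 0.0001
    epochs: int = 3
    batch_size: int = 256
    seed: int = 0
    balance: bool = True

    def __post_init__(self) -> None:
        if min(self.learning_rate, self.momentum, self.l2) < 0 or self.batch_size < 1:
            raise ValueError("training hyperparameters must be positive")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")


@dataclass
class NetworkModel:
    layers: list[Layer]
    training_seed: int
    history: list[dict] = field(default_factory=list)

    def forward_batch(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        """Logits for a batch shaped (N, 10, 219)."""
        a = np.asarray(x, dtype=np.float64)[:, None, :, :]
        for layer in self.layers:
            a = layer.forward(a, training=training)
        return a

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        """(N, 2) softmax probabilities, columns ordered (AF, NONAF)."""
        out = []
        x = np.asarray(x, dtype=np.float32)
        for lo in range(0, len(x) if x.ndim == 3 else 1, 256):
            out.append(softmax(self.forward_batch(x[lo : lo + 256], training=False)))
        return np.concatenate(out).astype(np.float64)

    def predict(self, x: np.ndarray) -> np.ndarray:
        return np.array([CLASSES[i] for i in self.predict_proba(x).argmax(axis=1)])


def build_network(seed: int = 0) -> NetworkModel:
    """Instantiate the layer stack with seeded fan-in scaled-uniform init."""
    rng = np.random.default_rng(seed)
    layers: list[Layer] = [
        Conv2d(1, 10, (3, 9), (1, 1), rng),
        BatchNorm2d(10),
        ReLU(),
        MaxPool2d((3, 3), (1, 2)),
        Conv2d(10, 15, (3, 9), (1, 1), rng),  # table stride (1,2) is an erratum
        BatchNorm2d(15),
        ReLU(),
        MaxPool2d((3, 3), (2, 2)),
        Conv2d(15, 20, (2, 4), (2, 2), rng),
        BatchNorm2d(20),
        ReLU(),
        Flatten(),
        Linear(3 * 28 * 20, 2, rng),
    ]
    return NetworkModel(layers=layers, training_seed=seed)


def count_parameters(model: NetworkModel) -> int:
    """Trainable parameters: conv w+b, batch-norm scale+shift, FC w+b.

    Batch-norm running statistics are buffers, not trainable, and are
    excluded.
    """
    return sum(layer.n_trainable() for layer in model.layers)


def forward(model: NetworkModel, image: np.ndarray) -> tuple[float, float]:
    """Softmax likelihoods (p_AF, p_NONAF) for a single 10x219 image."""
    image = np.asarray(image, dtype=np.float64)
    if image.shape != (10, 219):
        raise ValueError(f"expected a 10x219 image, got {image.shape}")
    p = model.predict_proba(image[None])[0]
    return float(p[0]), float(p[1])


def activation_shapes(model: NetworkModel) -> list[tuple[int, ...]]:
    """Per-layer activation shapes for a single input, (C, H, W) order."""
    a = np.zeros((1, 1, 10, 219))
    shapes = []
    for layer in model.layers:
        a = layer.forward(a, training=False)
        shapes.append(tuple(a.shape[1:]) if a.ndim == 4 else (a.shape[1],))
    return shapes


# ---------------------------------------------------------------------------
# Training
# ---------------------------------------------------------------------------

def _targets(labels: np.ndarray) -> np.ndarray:
    return np.array([CLASSES.index(l) for l in labels], dtype=np.int64)


def balance_classes(dataset: ECMDataset, seed: int = 0) -> ECMDataset:
    """Randomly drop the surplus of the larger class (order preserved)."""
    rng = np.random.default_rng(seed)
    idx_af = np.flatnonzero(dataset.labels == AF)
    idx_non = np.flatnonzero(dataset.labels == NONAF)
    if len(idx_af) == 0 or len(idx_non) == 0:
        raise ValueError("both classes must be present to balance")
    n = min(len(idx_af), len(idx_non))
    keep_af = np.sort(rng.choice(idx_af, size=n, replace=False))
    keep_non = np.sort(rng.choice(idx_non, size=n, replace=False))
    keep = np.sort(np.concatenate([keep_af, keep_non]))
    return dataset.subset(keep)


def train(model: NetworkModel, dataset: ECMDataset, cfg: TrainConfig) -> NetworkModel:
    """SGD-momentum with L2 decay minimizing cross-entropy on the softmax."""
    if len(dataset) == 0:
        raise ValueError("empty training dataset")
    x = dataset.pixels.astype(np.float32)
    y = _targets(dataset.labels)
    if len(set(y.tolist())) < 2:
        raise ValueError("both classes must be present for training")
    opt = SGDMomentum(lr=cfg.learning_rate, momentum=cfg.momentum, weight_decay=cfg.l2)
    rng = np.random.default_rng(cfg.seed)
    for epoch in range(cfg.epochs):
        order = rng.permutation(len(x))
        losses, correct = [], 0
        for lo in range(0, len(x), cfg.batch_size):
            sel = order[lo : lo + cfg.batch_size]
            logits = model.forward_batch(x[sel], training=True)
            loss, grad = cross_entropy_grad(logits, y[sel])
            if not np.isfinite(loss):
                raise FloatingPointError(
                    "training diverged (non-finite loss); lower the learning rate"
                )
            losses.append(loss)
            correct += int((logits.argmax(axis=1) == y[sel]).sum())
            for layer in reversed(model.layers):
                grad = layer.backward(grad)
            opt.step(model.layers)
        entry = {
            "epoch": epoch,
            "loss": float(np.mean(losses)),
            "accuracy": correct / len(x),
        }
        model.history.append(entry)
        log.info("epoch %d: loss %.4f acc %.4f", epoch, entry["loss"], entry["accuracy"])
    _finalize_batchnorm(model, x, cfg.batch_size)
    return model


def _finalize_batchnorm(model: NetworkModel, x: np.ndarray, batch_size: int) -> None:
    """Replace batch-norm running stats with population statistics computed
    over the full training set under the final weights (one extra pass)."""
    bns = [l for l in model.layers if isinstance(l, BatchNorm2d)]
    for bn in bns:
        bn.finalize_begin()
    for lo in range(0, len(x), batch_size):
        model.forward_batch(x[lo : lo + batch_size], training=True)
    for bn in bns:
        bn.finalize_end()


@dataclass
class Ensemble:
    """Three independently trained networks combined by majority of votes."""

    nets: list[NetworkModel]
    split_metrics: list[dict] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.nets) != 3:
            raise ValueError("the ensemble holds exactly 3 networks")


def records_to_datasets(
    records: list[ECGRecord],
    hop_beats: int = 5,
    cfg: PreprocessConfig | None = None,
    channel: int = 0,
) -> list[ECMDataset]:
    return [build_ecm_dataset(r, channel=channel, hop_beats=hop_beats, cfg=cfg)
            for r in records]


def train_three_splits(
    records: list[ECGRecord],
    cfg: TrainConfig,
    hop_beats: int = 5,
    preprocess_cfg: PreprocessConfig | None = None,
) -> Ensemble:
    """Three seeded patient-wise 80/20 splits -> balance -> train.

    No patient contributes windows to both sides of any split.  Validation
    accuracy of each net on its held-out patients is recorded.
    """
    patients = sorted({r.patient_id for r in records})
    if len(patients) < 5:
        raise ValueError("need at least 5 distinct patients for patient-wise splits")
    per_patient: dict[str, list[ECMDataset]] = {p: [] for p in patients}
    for r, ds in zip(records, records_to_datasets(records, hop_beats, preprocess_cfg)):
        per_patient[r.patient_id].append(ds)
    patient_ds = {p: ECMDataset.concatenate(v) for p, v in per_patient.items()}

    nets, metrics = [], []
    n_val = max(1, round(0.2 * len(patients)))
    for split in range(3):
        rng = np.random.default_rng([cfg.seed, split])
        order = rng.permutation(patients)
        val_p, train_p = set(order[:n_val]), set(order[n_val:])
        train_ds = ECMDataset.concatenate([patient_ds[p] for p in sorted(train_p)])
        val_ds = ECMDataset.concatenate([patient_ds[p] for p in sorted(val_p)])
        if cfg.balance:
            train_ds = balance_classes(train_ds, seed=int(rng.integers(2**31)))
        net = build_network(seed=cfg.seed * 3 + split)
        split_cfg = TrainConfig(
            learning_rate=cfg.learning_rate, momentum=cfg.momentum, l2=cfg.l2,
            epochs=cfg.epochs, batch_size=cfg.batch_size,
            seed=cfg.seed * 3 + split, balance=cfg.balance,
        )
        train(net, train_ds, split_cfg)
        val_acc = float(np.mean(net.predict(val_ds.pixels) == val_ds.labels)) if len(val_ds) else float("nan")
        metrics.append({
            "split": split,
            "train_patients": sorted(train_p),
            "validation_patients": sorted(val_p),
            "n_train": len(train_ds),
            "n_validation": len(val_ds),
            "validation_accuracy": val_acc,
        })
        log.info("split %d: validation accuracy %.4f", split, val_acc)
        nets.append(net)
    return Ensemble(nets=nets, split_metrics=metrics)


def mov_classify(ens: Ensemble, images: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Majority-of-votes labels plus the (N, 3) per-net vote matrix."""
    images = np.asarray(images, dtype=np.float64)
    if images.ndim == 2:
        images = images[None]
    votes = np.stack([net.predict(images) for net in ens.nets], axis=1)
    af_votes = (votes == AF).sum(axis=1)
    labels = np.where(af_votes >= 2, AF, NONAF)
    return labels, votes


# ---------------------------------------------------------------------------
# Checkpoints
# ---------------------------------------------------------------------------

def save_model(model: NetworkModel, path: str | Path) -> None:
    arrays: dict[str, np.ndarray] = {}
    spec = []
    for i, layer in enumerate(model.layers):
        entry: dict = {"kind": type(layer).__name__}
        if isinstance(layer, (Conv2d, MaxPool2d)):
            entry["kernel"] = list(layer.kernel)
            entry["stride"] = list(layer.stride)
        for k, p in layer.params.items():
            arrays[f"{i}:{k}"] = p
        if isinstance(layer, BatchNorm2d):
            arrays[f"{i}:running_mean"] = layer.running_mean
            arrays[f"{i}:running_var"] = layer.running_var
        spec.append(entry)
    arrays["__spec__"] = np.frombuffer(
        json.dumps({"layers": spec, "training_seed": model.training_seed}).encode(),
        dtype=np.uint8,
    )
    np.savez(path, **arrays)


def load_model(path: str | Path) -> NetworkModel:
    with np.load(path) as z:
        meta = json.loads(bytes(z["__spec__"].tobytes()).decode())
        model = build_network(seed=meta["training_seed"])
        for i, layer in enumerate(model.layers):
            for k in layer.params:
                layer.params[k] = z[f"{i}:{k}"].copy()
            if isinstance(layer, BatchNorm2d):
                layer.running_mean = z[f"{i}:running_mean"].copy()
                layer.running_var = z[f"{i}:running_var"].copy()
    return model


def save_ensemble(ens: Ensemble, directory: str | Path) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for i, net in enumerate(ens.nets, start=1):
        save_model(net, directory / f"net{i}.npz")
    (directory / "splits.json").write_text(json.dumps(ens.split_metrics, indent=2))


def load_ensemble(directory: str | Path) -> Ensemble:
    directory = Path(directory)
    nets = [load_model(directory / f"net{i}.npz") for i in (1, 2, 3)]
    metrics_path = directory / "splits.json"
    metrics = json.loads(metrics_path.read_text()) if metrics_path.exists() else []
    return Ensemble(nets=nets, split_metrics=metrics)
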