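"""Training and evaluation protocol for hypercube classification.

The protocol mirrors a small-data biomedical setting: a stratified 80/20
train/test split (880/220 cubes at the 11x100 design), a 10 % validation
carve-out from the training portion, Adam at an initial learning rate of
1e-4 with per-epoch exponential decay, batch size 2, cross-entropy loss, and
early stopping once the validation loss has failed to decrease for
``patience`` consecutive epochs. The model state at the best validation
epoch is restored before evaluation.

``run_comparison`` is the repeated-seed benchmark: for each band-selection
method and each run seed it selects the window *on the training portion
only*, slices every cube to that window, trains, and evaluates — reporting
mean +- std accuracy (and informational epoch wall-times) across runs.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from sklearn.metrics import confusion_matrix as _sk_confusion
from sklearn.model_selection import train_test_split

from .errors import TrainingError
from .hypercube import LabeledDataset, slice_bands
from .nn import Adam, CNNSpec, SmallCNN, softmax_cross_entropy
from .selection import SelectionConfig, select_for_dataset

__all__ = [
    "TrainConfig",
    "TrainHistory",
    "build_model",
    "split_dataset",
    "dataset_to_arrays",
    "train_model",
    "evaluate",
    "run_comparison",
    "run_single",
]


@dataclass(frozen=True)
class TrainConfig:
    """Optimisation hyper-parameters (defaults follow the reference protocol)."""

    lr_init: float = 1e-4
    lr_decay: float = 0.95  # multiplicative, per epoch
    batch_size: int = 2
    patience: int = 15
    max_epochs: int = 100
    train_fraction: float = 0.8
    val_fraction_of_train: float = 0.1
    conv_filters: tuple[int, int] = (16, 32)
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.train_fraction < 1 and 0 < self.val_fraction_of_train < 1):
            raise ValueError("fractions must lie strictly between 0 and 1")
        if self.patience < 1 or self.max_epochs < 1 or self.batch_size < 1:
            raise ValueError("patience, max_epochs and batch_size must be >= 1")


@dataclass
class TrainHistory:
    """Per-epoch records plus where training stopped and which epoch was best."""

    train_loss: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    test_accuracy: list[float] = field(default_factory=list)
    epoch_seconds: list[float] = field(default_factory=list)
    stopped_epoch: int = 0
    best_epoch: int = 0  # 1-based, minimises validation loss

    def as_frame(self) -> pd.DataFrame:
        d = {"epoch": np.arange(1, len(self.train_loss) + 1),
             "train_loss": self.train_loss, "val_loss": self.val_loss}
        if self.test_accuracy:
            d["test_accuracy"] = self.test_accuracy
        d["epoch_seconds"] = self.epoch_seconds
        return pd.DataFrame(d)


def build_model(spec: CNNSpec, seed: int = 0) -> SmallCNN:
    """Instantiate the two-conv / two-FC network with seeded He initialisation."""
    return SmallCNN(spec, seed=seed)


def split_dataset(
    dataset: LabeledDataset, config: TrainConfig
) -> tuple[LabeledDataset, LabeledDataset, LabeledDataset]:
    """Stratified (train, val, test) split, deterministic given the seed.

    The test portion is ``1 - train_fraction`` of the whole dataset; the
    validation portion is ``val_fraction_of_train`` of the training portion.
    Splits are disjoint and exhaustive.
    """
    idx = np.arange(len(dataset))
    labels = np.asarray(dataset.labels)
    counts = np.bincount(labels, minlength=len(dataset.class_names))
    if np.any(counts[np.unique(labels)] < 2):
        raise ValueError("every present class needs >= 2 cubes for stratification")
    trainval_idx, test_idx = train_test_split(
        idx, test_size=1.0 - config.train_fraction, stratify=labels,
        random_state=config.seed % (2**32),
    )
    # Stratify the validation carve-out only when it can hold every class.
    n_val = max(1, round(config.val_fraction_of_train * trainval_idx.size))
    val_strat = labels[trainval_idx] if n_val >= np.unique(labels).size else None
    train_idx, val_idx = train_test_split(
        trainval_idx, test_size=config.val_fraction_of_train,
        stratify=val_strat, random_state=(config.seed + 1) % (2**32),
    )
    return dataset.subset(train_idx), dataset.subset(val_idx), dataset.subset(test_idx)


def dataset_to_arrays(
    dataset: LabeledDataset, lo: float | None = None, hi: float | None = None
) -> tuple[np.ndarray, np.ndarray, float, float]:
    """Stack cubes into (N, channels, H, W) inputs, min-max scaled to [0, 1].

    The normalisation range defaults to the dataset's own global min/max; pass
    the training portion's (lo, hi) to normalise validation/test data without
    leakage.
    """
    x = np.stack([c.values.transpose(2, 0, 1) for c in dataset.cubes])
    if lo is None:
        lo = float(x.min())
    if hi is None:
        hi = float(x.max())
    scale = hi - lo if hi > lo else 1.0
    x = (x - lo) / scale
    return x, np.asarray(dataset.labels), lo, hi


def _eval_loss(model: SmallCNN, x: np.ndarray, y: np.ndarray, batch: int = 32) -> float:
    total, n = 0.0, x.shape[0]
    for i in range(0, n, batch):
        logits = model.forward(x[i:i + batch], train=False)
        loss, _ = softmax_cross_entropy(logits, y[i:i + batch])
        total += loss * logits.shape[0]
    return total / n


def train_model(
    model: SmallCNN,
    train: tuple[np.ndarray, np.ndarray],
    val: tuple[np.ndarray, np.ndarray],
    config: TrainConfig,
    test: tuple[np.ndarray, np.ndarray] | None = None,
) -> TrainHistory:
    """Adam + cross-entropy training with early stopping on validation loss.

    Stops after ``patience`` consecutive epochs without a new validation-loss
    minimum, or at ``max_epochs``. On return the model carries the
    best-validation-epoch weights; the history holds the full trajectory
    (and per-epoch test accuracy when a test set is supplied).
    """
    x_tr, y_tr = train
    x_val, y_val = val
    rng = np.random.default_rng(config.seed)
    opt = Adam(model.params)
    hist = TrainHistory()
    best_val = np.inf
    best_state = model.state_dict()
    bad_epochs = 0

    for epoch in range(1, config.max_epochs + 1):
        t0 = time.perf_counter()
        lr = config.lr_init * config.lr_decay ** (epoch - 1)
        order = rng.permutation(x_tr.shape[0])
        losses = []
        for i in range(0, order.size, config.batch_size):
            batch = order[i:i + config.batch_size]
            logits = model.forward(x_tr[batch], train=True)
            loss, dlogits = softmax_cross_entropy(logits, y_tr[batch])
            if not np.isfinite(loss):
                raise TrainingError(epoch)
            grads = model.backward(dlogits)
            opt.step(model.params, grads, lr)
            losses.append(loss)
        val_loss = _eval_loss(model, x_val, y_val)
        if not np.isfinite(val_loss):
            raise TrainingError(epoch)
        hist.train_loss.append(float(np.mean(losses)))
        hist.val_loss.append(float(val_loss))
        if test is not None:
            pred = model.predict(test[0])
            hist.test_accuracy.append(float(np.mean(pred == test[1])))
        hist.epoch_seconds.append(time.perf_counter() - t0)

        if val_loss < best_val:
            best_val = val_loss
            hist.best_epoch = epoch
            best_state = model.state_dict()
            bad_epochs = 0
        else:
            bad_epochs += 1
        hist.stopped_epoch = epoch
        if bad_epochs >= config.patience:
            break

    model.load_state_dict(best_state)
    return hist


def evaluate(model: SmallCNN, test: tuple[np.ndarray, np.ndarray],
             n_classes: int | None = None) -> tuple[float, np.ndarray]:
    """Accuracy and confusion matrix (rows true, columns predicted)."""
    x, y = test
    if x.shape[0] == 0:
        raise ValueError("empty test set")
    pred = model.predict(x)
    k = n_classes if n_classes is not None else int(max(y.max(), pred.max())) + 1
    cm = _sk_confusion(y, pred, labels=np.arange(k))
    return float(np.mean(pred == y)), cm


def run_single(
    dataset: LabeledDataset,
    method: SelectionConfig,
    train_cfg: TrainConfig,
    run_seed: int,
) -> dict:
    """One select -> slice -> train -> evaluate pass with a given seed."""
    cfg = replace(train_cfg, seed=run_seed)
    train, val, test = split_dataset(dataset, cfg)
    # Window selection sees the training portion only (no test leakage).
    trainval = LabeledDataset(
        cubes=train.cubes + val.cubes, labels=train.labels + val.labels,
        class_names=list(dataset.class_names),
    )
    sel = replace(method, seed=run_seed) if method.method == "random" else method
    window = select_for_dataset(trainval, sel)

    def sliced(ds: LabeledDataset) -> LabeledDataset:
        return LabeledDataset([slice_bands(c, window) for c in ds.cubes],
                              list(ds.labels), list(ds.class_names))

    train_s, val_s, test_s = sliced(train), sliced(val), sliced(test)
    x_tr, y_tr, lo, hi = dataset_to_arrays(train_s)
    x_val, y_val, _, _ = dataset_to_arrays(val_s, lo, hi)
    x_te, y_te, _, _ = dataset_to_arrays(test_s, lo, hi)

    spec = CNNSpec(in_channels=window.width, n_classes=len(dataset.class_names),
                   spatial=dataset.cubes[0].shape[:2], conv_filters=cfg.conv_filters)
    model = build_model(spec, seed=run_seed)
    hist = train_model(model, (x_tr, y_tr), (x_val, y_val), cfg, test=(x_te, y_te))
    acc_best, _ = evaluate(model, (x_te, y_te), n_classes=len(dataset.class_names))
    return {
        "window": window,
        "history": hist,
        "accuracy": acc_best,                       # at the best-validation epoch
        "accuracy_final": hist.test_accuracy[-1],   # at the last trained epoch
        "mean_epoch_seconds": float(np.mean(hist.epoch_seconds)),
    }


def run_comparison(
    dataset: LabeledDataset,
    methods: list[SelectionConfig],
    n_runs: int,
    config: TrainConfig,
) -> tuple[pd.DataFrame, dict[str, list[dict]]]:
    """Repeated-seed benchmark of band-selection methods.

    Per-run seeds are ``config.seed + run_index``. Returns the summary table
    (method, mean/std accuracy, mean/std epoch seconds, n_runs) and the raw
    per-run records keyed by method name.
    """
    if n_runs < 2:
        raise ValueError("n_runs must be >= 2 to report a standard deviation")
    records: dict[str, list[dict]] = {m.method: [] for m in methods}
    for method in methods:
        for run in range(n_runs):
            records[method.method].append(
                run_single(dataset, method, config, config.seed + run)
            )
    rows = []
    for method in methods:
        accs = np.array([r["accuracy"] for r in records[method.method]])
        times = np.array([r["mean_epoch_seconds"] for r in records[method.method]])
        rows.append({
            "method": method.method,
            "mean_accuracy": accs.mean(),
            "std_accuracy": accs.std(ddof=1),
            "mean_epoch_s": times.mean(),
            "std_epoch_s": times.std(ddof=1),
            "n_runs": n_runs,
        })
    return pd.DataFrame(rows), records
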