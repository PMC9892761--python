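"""CNN and LSTM three-class classifiers, training, metrics and
cross-validation with an optional permuted-label control."""

from __future__ import annotations

import json
import zipfile
from dataclasses import dataclass, field
from io import BytesIO
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold, StratifiedShuffleSplit

from xfnirs import nn
from xfnirs.types import CLASS_NAMES
from xfnirs.windowing import Standardizer, WindowedDataset


class TrainingError(RuntimeError):
    """Raised when optimization diverges (non-finite loss)."""


@dataclass
class ModelSpec:
    """Architecture description for either classifier.

    cnn: conv(32 filters, kernel 3, stride 1) -> maxpool(2) -> flatten ->
    dense 500 -> dropout 0.5 -> dense 120 -> dropout 0.5 -> dense 3 softmax.
    lstm: 120 recurrent units emitting per-timestep outputs -> flatten ->
    the same dense head. All hidden activations are relu.

    ``conv_padding`` selects "same" (conv keeps 50 steps, pool -> 25,
    flatten 800) or "valid" (48 -> 24, flatten 768); the published pooled
    length of 28 is unreachable with pool size 2 from a 50-step input, so
    both standard conventions are offered.
    """

    kind: str
    ws: int = 50
    n_features: int = 26
    n_classes: int = 3
    conv_filters: int = 32
    conv_kernel: int = 3
    conv_padding: str = "same"
    pool_size: int = 2
    lstm_units: int = 120
    dense_sizes: tuple[int, int] = (500, 120)
    dropout: float = 0.5

    def __post_init__(self) -> None:
        if self.kind not in ("cnn", "lstm"):
            raise ValueError("kind must be 'cnn' or 'lstm'")
        if self.ws <= 0 or self.n_features <= 0:
            raise ValueError("ws and n_features must be positive")


@dataclass
class TrainConfig:
    learning_rate: float = 1e-3
    batch_size: int = 64
    epochs: int = 50
    seed: int = 0
    optimizer: str = "adam"

    def __post_init__(self) -> None:
        if self.learning_rate <= 0 or self.batch_size <= 0 or self.epochs < 0:
            raise ValueError("hyperparameters must be positive (epochs >= 0)")
        if self.optimizer != "adam":
            raise ValueError("only adam is supported")


@dataclass
class TrainedModel:
    spec: ModelSpec
    network: nn.Sequential
    standardizer: Standardizer
    config: TrainConfig
    class_names: tuple[str, ...] = CLASS_NAMES
    history: dict[str, list[float]] = field(default_factory=dict)

    def predict_proba(self, frames: np.ndarray) -> np.ndarray:
        frames = _check_frames(frames, self.spec)
        return self.network.predict_proba(self.standardizer.transform(frames))

    def predict_logits(self, frames: np.ndarray) -> np.ndarray:
        frames = _check_frames(frames, self.spec)
        return self.network.predict_logits(self.standardizer.transform(frames))

    def predict(self, frames: np.ndarray) -> np.ndarray:
        idx = self.predict_proba(frames).argmax(axis=1)
        return np.array([self.class_names[i] for i in idx], dtype=object)


def _check_frames(frames: np.ndarray, spec: ModelSpec) -> np.ndarray:
    frames = np.asarray(frames)
    if frames.ndim == 2:
        frames = frames[None]
    if frames.ndim != 3 or frames.shape[1:] != (spec.ws, spec.n_features):
        raise ValueError(
            f"frames must be (n, {spec.ws}, {spec.n_features}), got {frames.shape}"
        )
    return frames


def build_model(spec: ModelSpec, seed: int = 0) -> nn.Sequential:
    """Instantiate the network for ``spec`` with seeded initialization."""
    rng = np.random.default_rng(seed)
    layers: list[nn.Layer] = []
    if spec.kind == "cnn":
        layers.append(
            nn.Conv1D(
                spec.n_features,
                spec.conv_filters,
                kernel_size=spec.conv_kernel,
                padding=spec.conv_padding,
                rng=rng,
            )
        )
        layers.append(nn.ReLU())
        layers.append(nn.MaxPool1D(spec.pool_size))
        layers.append(nn.Flatten())
        if spec.conv_padding == "same":
            flat = (spec.ws // spec.pool_size) * spec.conv_filters
        else:
            flat = ((spec.ws - spec.conv_kernel + 1) // spec.pool_size) * spec.conv_filters
    else:
        layers.append(nn.LSTM(spec.n_features, spec.lstm_units, rng=rng))
        layers.append(nn.Flatten())
        flat = spec.ws * spec.lstm_units
    d1, d2 = spec.dense_sizes
    layers.append(nn.Dense(flat, d1, rng=rng))
    layers.append(nn.ReLU())
    layers.append(nn.Dropout(spec.dropout))
    layers.append(nn.Dense(d1, d2, rng=rng))
    layers.append(nn.ReLU())
    layers.append(nn.Dropout(spec.dropout))
    layers.append(nn.Dense(d2, spec.n_classes, rng=rng))
    return nn.Sequential(layers, input_shape=(spec.ws, spec.n_features))


def flatten_length(spec: ModelSpec) -> int:
    """Length of the flattened vector feeding the dense head."""
    net = build_model(spec, seed=0)
    flat_idx = next(
        i for i, l in enumerate(net.layers) if isinstance(l, nn.Flatten)
    )
    return net.layer_shapes[flat_idx][0]


def train_model(
    model: nn.Sequential | None,
    train: WindowedDataset,
    cfg: TrainConfig,
    spec: ModelSpec | None = None,
    val: WindowedDataset | None = None,
) -> TrainedModel:
    """Fit with Adam on z-scored frames; returns the model plus history.

    Either pass an already-built network (with its ``spec``) or just a spec
    and let this build one. History holds per-epoch train loss/accuracy and
    validation loss/accuracy (NaN when no validation set is given).
    """
    if spec is None:
        raise ValueError("spec is required")
    if model is None:
        model = build_model(spec, seed=cfg.seed)
    if len(train) == 0:
        raise ValueError("empty training set")
    if len(set(train.labels.tolist())) < 2 and cfg.epochs > 0:
        raise ValueError("training needs at least two classes")

    standardizer = Standardizer()
    x = standardizer.fit_transform(train.frames).astype(nn.DTYPE)
    y = train.y
    x_val = y_val = None
    if val is not None and len(val) > 0:
        x_val = standardizer.transform(val.frames).astype(nn.DTYPE)
        y_val = val.y

    rng = np.random.default_rng(cfg.seed)
    opt = nn.Adam(model.params(), lr=cfg.learning_rate)
    history: dict[str, list[float]] = {
        "train_loss": [], "train_acc": [], "val_loss": [], "val_acc": []
    }
    n = len(x)
    for _epoch in range(cfg.epochs):
        order = rng.permutation(n)
        losses, correct = [], 0
        for start in range(0, n, cfg.batch_size):
            idx = order[start : start + cfg.batch_size]
            xb, yb = x[idx], y[idx]
            logits = model.forward(xb, train=True, rng=rng)
            loss, gy = nn.cross_entropy_grad(logits, yb)
            if not np.isfinite(loss):
                raise TrainingError(f"loss diverged to {loss}")
            model.backward(gy)
            opt.step(model.grads())
            losses.append(loss * len(idx))
            correct += int((logits.argmax(axis=1) == yb).sum())
        history["train_loss"].append(float(np.sum(losses) / n))
        history["train_acc"].append(correct / n)
        if x_val is not None:
            logits = model.predict_logits(x_val)
            vloss, _ = nn.cross_entropy_grad(logits, y_val)
            history["val_loss"].append(vloss)
            history["val_acc"].append(
                float((logits.argmax(axis=1) == y_val).mean())
            )
        else:
            history["val_loss"].append(float("nan"))
            history["val_acc"].append(float("nan"))
    return TrainedModel(
        spec=spec,
        network=model,
        standardizer=standardizer,
        config=cfg,
        class_names=train.class_names,
        history=history,
    )


def predict_proba(model: TrainedModel, frames: np.ndarray) -> np.ndarray:
    return model.predict_proba(frames)


# ---------------------------------------------------------------------------
# metrics

@dataclass
class ConfusionCounts:
    """3x3 confusion matrix plus one-vs-rest counts per class."""

    matrix: np.ndarray
    class_names: tuple[str, ...]

    @classmethod
    def from_labels(
        cls,
        y_true: np.ndarray,
        y_pred: np.ndarray,
        class_names: tuple[str, ...] = CLASS_NAMES,
    ) -> "ConfusionCounts":
        k = len(class_names)
        lut = {name: i for i, name in enumerate(class_names)}
        mat = np.zeros((k, k), dtype=np.int64)
        for t, p in zip(y_true, y_pred, strict=True):
            mat[lut[str(t)], lut[str(p)]] += 1
        return cls(matrix=mat, class_names=tuple(class_names))

    def one_vs_rest(self, class_index: int) -> dict[str, int]:
        m = self.matrix
        tp = int(m[class_index, class_index])
        fp = int(m[:, class_index].sum() - tp)
        fn = int(m[class_index, :].sum() - tp)
        tn = int(m.sum() - tp - fp - fn)
        return {"TP": tp, "FP": fp, "FN": fn, "TN": tn}


@dataclass
class MetricsReport:
    accuracy: float
    precision_macro: float
    recall_macro: float
    f1_macro: float
    per_class: dict[str, dict[str, float]]


def _safe_div(num: float, den: float) -> float:
    return num / den if den > 0 else float("nan")


def compute_metrics(cc: ConfusionCounts) -> MetricsReport:
    """Accuracy, precision, recall and F1 from one-vs-rest counts.

    precision = TP/(TP+FP), recall = TP/(TP+FN),
    F1 = 2*precision*recall/(precision+recall). Undefined ratios (empty
    denominator) are reported as NaN, never coerced to zero; macro averages
    skip undefined classes.
    """
    total = int(cc.matrix.sum())
    if total == 0:
        raise ValueError("no samples")
    per_class: dict[str, dict[str, float]] = {}
    for i, name in enumerate(cc.class_names):
        c = cc.one_vs_rest(i)
        precision = _safe_div(c["TP"], c["TP"] + c["FP"])
        recall = _safe_div(c["TP"], c["TP"] + c["FN"])
        if np.isnan(precision) or np.isnan(recall) or (precision + recall) == 0:
            f1 = float("nan")
        else:
            f1 = 2.0 * precision * recall / (precision + recall)
        per_class[name] = {
            "accuracy": (c["TP"] + c["TN"]) / total,
            "precision": precision,
            "recall": recall,
            "f1": f1,
        }
    def _macro(key: str) -> float:
        vals = [v[key] for v in per_class.values() if not np.isnan(v[key])]
        return float(np.mean(vals)) if vals else float("nan")

    return MetricsReport(
        accuracy=float(np.trace(cc.matrix)) / total,
        precision_macro=_macro("precision"),
        recall_macro=_macro("recall"),
        f1_macro=_macro("f1"),
        per_class=per_class,
    )


# ---------------------------------------------------------------------------
# cross-validation

@dataclass
class CVResult:
    mode: str
    fold_accuracies: list[float]
    fold_metrics: list[MetricsReport]
    permuted: bool
    fold_test_indices: list[np.ndarray] = field(default_factory=list)

    @property
    def mean_accuracy(self) -> float:
        return float(np.mean(self.fold_accuracies))

    @property
    def std_accuracy(self) -> float:
        return float(np.std(self.fold_accuracies))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "fold": np.arange(len(self.fold_accuracies)),
                "accuracy": self.fold_accuracies,
                "precision": [m.precision_macro for m in self.fold_metrics],
                "recall": [m.recall_macro for m in self.fold_metrics],
                "f1": [m.f1_macro for m in self.fold_metrics],
            }
        )

    def summary(self) -> dict:
        return {
            "mode": self.mode,
            "permuted": self.permuted,
            "n_folds": len(self.fold_accuracies),
            "mean_accuracy": self.mean_accuracy,
            "std_accuracy": self.std_accuracy,
        }


def cross_validate(
    ds: WindowedDataset,
    model_kind: str = "cnn",
    k: int = 10,
    cfg: TrainConfig | None = None,
    permute_labels: bool = False,
    seed: int = 0,
    mode: str = "kfold",
    spec: ModelSpec | None = None,
) -> CVResult:
    """Stratified cross-validation with per-fold retraining.

    ``mode='kfold'`` is classic k-fold (each fold validates on ~1/k of the
    data); ``mode='shuffle'`` runs k repeated stratified 75/25 splits — both
    readings of the published protocol, named explicitly in the result.
    Labels are permuted once (seeded) before folding when
    ``permute_labels`` is set, giving the chance-level control.
    """
    if cfg is None:
        cfg = TrainConfig()
    if mode not in ("kfold", "shuffle"):
        raise ValueError("mode must be 'kfold' or 'shuffle'")
    if spec is None:
        spec = ModelSpec(kind=model_kind, ws=ds.ws, n_features=ds.n_features)
    counts = ds.class_counts()
    small = [n for n, c in counts.items() if 0 < c < k]
    if small:
        raise ValueError(f"classes with fewer than k={k} frames: {small}")

    labels = ds.labels
    if permute_labels:
        rng = np.random.default_rng(seed)
        labels = labels[rng.permutation(len(labels))]
        ds = ds.subset(np.arange(len(ds)))
        ds.labels = labels

    y = ds.y
    if mode == "kfold":
        splitter = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    else:
        splitter = StratifiedShuffleSplit(
            n_splits=k, test_size=0.25, random_state=seed
        )
    fold_accs, fold_metrics, fold_test_indices = [], [], []
    for fold, (train_idx, test_idx) in enumerate(splitter.split(ds.frames, y)):
        fold_test_indices.append(np.array(test_idx))
        train_ds = ds.subset(train_idx)
        test_ds = ds.subset(test_idx)
        fold_cfg = TrainConfig(
            learning_rate=cfg.learning_rate,
            batch_size=cfg.batch_size,
            epochs=cfg.epochs,
            seed=cfg.seed + fold,
        )
        trained = train_model(None, train_ds, fold_cfg, spec=spec)
        pred = trained.predict(test_ds.frames)
        cc = ConfusionCounts.from_labels(
            test_ds.labels, pred, class_names=ds.class_names
        )
        report = compute_metrics(cc)
        fold_accs.append(report.accuracy)
        fold_metrics.append(report)
    return CVResult(
        mode=mode,
        fold_accuracies=fold_accs,
        fold_metrics=fold_metrics,
        permuted=permute_labels,
        fold_test_indices=fold_test_indices,
    )


# ---------------------------------------------------------------------------
# checkpoints

def save_model(model: TrainedModel, path: str | Path) -> None:
    """Single-file checkpoint: architecture JSON + weights + config."""
    meta = {
        "spec": model.spec.__dict__ | {"dense_sizes": list(model.spec.dense_sizes)},
        "config": model.config.__dict__,
        "class_names": list(model.class_names),
        "history": model.history,
        "standardizer": {
            "mean": model.standardizer.mean_.tolist(),
            "std": model.standardizer.std_.tolist(),
        },
    }
    with zipfile.ZipFile(path, "w") as zf:
        zf.writestr("meta.json", json.dumps(meta))
        buf = BytesIO()
        np.savez(buf, *model.network.get_weights())
        zf.writestr("weights.npz", buf.getvalue())


def load_model(path: str | Path) -> TrainedModel:
    with zipfile.ZipFile(path, "r") as zf:
        meta = json.loads(zf.read("meta.json"))
        with zf.open("weights.npz") as fh:
            arrays = np.load(BytesIO(fh.read()))
            weights = [arrays[k] for k in arrays.files]
    spec_doc = dict(meta["spec"])
    spec_doc["dense_sizes"] = tuple(spec_doc["dense_sizes"])
    spec = ModelSpec(**spec_doc)
    cfg = TrainConfig(**meta["config"])
    net = build_model(spec, seed=cfg.seed)
    net.set_weights([w.astype(nn.DTYPE) for w in weights])
    std = Standardizer()
    std.mean_ = np.array(meta["standardizer"]["mean"])
    std.std_ = np.array(meta["standardizer"]["std"])
    return TrainedModel(
        spec=spec,
        network=net,
        standardizer=std,
        config=cfg,
        class_names=tuple(meta["class_names"]),
        history=meta["history"],
    )
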