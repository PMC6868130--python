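"""Training and inference of the per-time-step mobility classifier.

A single bidirectional LSTM layer (200 hidden units per direction by
default) reads the per-step feature sequence of a trajectory and emits a
softmax over mobility classes at every step.  Training follows the
protocol used throughout the package: fixed-length simulated windows,
categorical cross-entropy, Adam, batch size 256, and patience-based
early stopping on validation loss with best-weights restoration.
Repeated random splits of a window pool give a spread-aware estimate of
the accuracy.  Inference never windows: a trajectory of any length is
featurized and classified in one bidirectional pass.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .exceptions import (
    CompatibilityError,
    DegenerateDataError,
    ParameterError,
    TooShortError,
    ValidationError,
)
from .features import FeatureConfig, LabeledWindow, featurize, n_features
from .nn import Adam, BiLSTM, cross_entropy

__all__ = [
    "ModelConfig",
    "SplitReport",
    "SegmenterModel",
    "train",
    "evaluate_splits",
    "save_model",
    "load_model",
]


@dataclass(frozen=True)
class ModelConfig:
    """Hyperparameters of the classifier and its training loop."""

    hidden_units: int = 200
    n_classes: int = 3
    batch_size: int = 256
    max_epochs: int = 100
    early_stop_patience: int = 10
    learning_rate: float = 7e-3
    lr_decay: str = "cosine"  # "cosine" anneals to 1/10 of the base rate; "none"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.hidden_units < 1:
            raise ParameterError("hidden_units must be >= 1")
        if self.n_classes < 2:
            raise ParameterError("n_classes must be >= 2")


@dataclass
class SplitReport:
    """Accuracies over repeated random train/val/test splits."""

    per_split: list[tuple[float, float, float]] = field(default_factory=list)

    @property
    def mean_test_acc(self) -> float:
        return float(np.mean([s[2] for s in self.per_split]))

    @property
    def mean_train_acc(self) -> float:
        return float(np.mean([s[0] for s in self.per_split]))


def _stack_windows(windows: list[LabeledWindow]):
    if not windows:
        raise DegenerateDataError("empty window set")
    F = windows[0].features.shape[1]
    W = windows[0].features.shape[0]
    for w in windows:
        if w.features.shape != (W, F):
            raise ValidationError(
                f"inconsistent window shape {w.features.shape}, expected {(W, F)}"
            )
    X = np.stack([w.features for w in windows]).astype(np.float32)
    y = np.stack([w.labels for w in windows]).astype(np.int64)
    return X, y


class SegmenterModel:
    """A trained classifier plus everything needed to apply it.

    Bundles the network weights, the feature configuration and the
    per-feature standardization statistics computed on the training
    set, so that prediction on raw coordinates needs no further setup.
    """

    def __init__(
        self,
        net: BiLSTM,
        feature_config: FeatureConfig,
        feat_mean: np.ndarray,
        feat_std: np.ndarray,
    ) -> None:
        self.net = net
        self.feature_config = feature_config
        self.feat_mean = np.asarray(feat_mean, dtype=np.float32)
        self.feat_std = np.asarray(feat_std, dtype=np.float32)

    @property
    def n_classes(self) -> int:
        return self.net.n_classes

    def _standardize(self, X: np.ndarray) -> np.ndarray:
        return (X - self.feat_mean) / self.feat_std

    def predict(self, positions: np.ndarray):
        """Per-step labels and class probabilities for one trajectory.

        The full-length featurized sequence is classified in a single
        bidirectional pass (no windowing).  Returns ``(labels, probs)``
        with ``labels`` of length T−1 and ``probs`` of shape (T−1, C).
        """
        positions = np.asarray(positions, dtype=float)
        if len(positions) < 2:
            raise TooShortError("prediction needs at least 2 positions")
        feats = featurize(positions, self.feature_config)
        X = self._standardize(feats.astype(np.float32))[None]
        probs = self.net.forward(X)[0]
        return probs.argmax(axis=1), probs

    def predict_points(self, positions: np.ndarray) -> np.ndarray:
        """Point-level labels (length T): point t takes the label of step
        t, the final point the label of the last step."""
        step_labels, _ = self.predict(positions)
        return np.concatenate([step_labels, step_labels[-1:]])


def _accuracy(model_net: BiLSTM, X: np.ndarray, y: np.ndarray, batch: int = 512):
    correct = 0
    loss_sum = 0.0
    n = 0
    for s in range(0, len(X), batch):
        xb, yb = X[s : s + batch], y[s : s + batch]
        probs = model_net.forward(xb)
        correct += int(np.sum(probs.argmax(axis=-1) == yb))
        loss_sum += cross_entropy(probs, yb) * yb.size
        n += yb.size
    return correct / n, loss_sum / n


def train(
    train_windows: list[LabeledWindow],
    val_windows: list[LabeledWindow],
    test_windows: list[LabeledWindow] | None = None,
    cfg: ModelConfig = ModelConfig(),
    feature_config: FeatureConfig = FeatureConfig(),
    verbose: bool = False,
):
    """Train one classifier; returns (model, (train_acc, val_acc, test_acc)).

    Test accuracy is ``nan`` when no test windows are supplied.
    """
    Xtr, ytr = _stack_windows(train_windows)
    Xva, yva = _stack_windows(val_windows)
    if Xtr.shape[2] != n_features(feature_config):
        raise ValidationError(
            f"window feature dim {Xtr.shape[2]} does not match configuration "
            f"({n_features(feature_config)})"
        )
    if len(np.unique(ytr)) < 2:
        raise DegenerateDataError("training labels contain a single class")

    mean = Xtr.reshape(-1, Xtr.shape[2]).mean(axis=0)
    std = Xtr.reshape(-1, Xtr.shape[2]).std(axis=0)
    std[std == 0] = 1.0
    Xtr = (Xtr - mean) / std
    Xva = (Xva - mean) / std

    rng = np.random.default_rng(cfg.seed)
    net = BiLSTM(Xtr.shape[2], cfg.hidden_units, cfg.n_classes, rng)
    opt = Adam(net.params, lr=cfg.learning_rate)

    best_val = np.inf
    best_params = net.get_params()
    patience_left = cfg.early_stop_patience
    for epoch in range(cfg.max_epochs):
        if cfg.lr_decay == "cosine":
            frac = epoch / max(1, cfg.max_epochs - 1)
            opt.lr = cfg.learning_rate * (0.1 + 0.45 * (1 + np.cos(np.pi * frac)))
        order = rng.permutation(len(Xtr))
        for s in range(0, len(order), cfg.batch_size):
            idx = order[s : s + cfg.batch_size]
            _, grads = net.loss_and_grads(Xtr[idx], ytr[idx])
            opt.step(net.params, grads)
        _, val_loss = _accuracy(net, Xva, yva)
        if verbose:
            tr_acc, tr_loss = _accuracy(net, Xtr, ytr)
            print(
                f"epoch {epoch + 1}: train loss {tr_loss:.4f} acc {tr_acc:.4f} "
                f"| val loss {val_loss:.4f}"
            )
        if val_loss < best_val - 1e-5:
            best_val = val_loss
            best_params = net.get_params()
            patience_left = cfg.early_stop_patience
        else:
            patience_left -= 1
            if patience_left <= 0:
                break
    net.set_params(best_params)

    model = SegmenterModel(net, feature_config, mean, std)
    train_acc, _ = _accuracy(net, Xtr, ytr)
    val_acc, _ = _accuracy(net, Xva, yva)
    if test_windows:
        Xte, yte = _stack_windows(test_windows)
        Xte = (Xte - mean) / std
        test_acc, _ = _accuracy(net, Xte, yte)
    else:
        test_acc = float("nan")
    return model, (train_acc, val_acc, test_acc)


def evaluate_splits(
    pool: list[LabeledWindow],
    cfg: ModelConfig = ModelConfig(),
    feature_config: FeatureConfig = FeatureConfig(),
    n_splits: int = 10,
    sizes: tuple[int, int, int] = (10_000, 5_000, 5_000),
    verbose: bool = False,
) -> SplitReport:
    """Repeated random splits of a window pool; fresh model per split.

    Each split draws disjoint train/val/test sets of the given sizes
    from the pool; per-split seeds are derived deterministically from
    ``cfg.seed``.
    """
    n_tr, n_va, n_te = sizes
    if len(pool) < n_tr + n_va + n_te:
        raise DegenerateDataError(
            f"window pool has {len(pool)} windows, need {n_tr + n_va + n_te}"
        )
    report = SplitReport()
    master = np.random.default_rng(cfg.seed)
    for split in range(n_splits):
        split_seed = int(master.integers(2**31 - 1))
        rng = np.random.default_rng(split_seed)
        perm = rng.permutation(len(pool))
        tr = [pool[i] for i in perm[:n_tr]]
        va = [pool[i] for i in perm[n_tr : n_tr + n_va]]
        te = [pool[i] for i in perm[n_tr + n_va : n_tr + n_va + n_te]]
        split_cfg = ModelConfig(**{**asdict(cfg), "seed": split_seed})
        _, accs = train(tr, va, te, split_cfg, feature_config, verbose=verbose)
        report.per_split.append(accs)
    return report


# ---------------- persistence ----------------

_FORMAT = "dlmss-bilstm-v1"


def save_model(model: SegmenterModel, path: str | Path) -> None:
    """Write a self-contained model artifact (weights + feature config +
    standardization statistics) as a single .npz file."""
    meta = {
        "format": _FORMAT,
        "n_features": model.net.n_features,
        "hidden_units": model.net.hidden_units,
        "n_classes": model.net.n_classes,
        "feature_config": {
            "window_len": model.feature_config.window_len,
            "avg_orders": list(model.feature_config.avg_orders),
            "center_coords": model.feature_config.center_coords,
        },
    }
    arrays = {f"param_{k}": v for k, v in model.net.params.items()}
    arrays["feat_mean"] = model.feat_mean
    arrays["feat_std"] = model.feat_std
    arrays["meta_json"] = np.frombuffer(
        json.dumps(meta).encode("utf-8"), dtype=np.uint8
    )
    with open(path, "wb") as fh:
        np.savez(fh, **arrays)


def load_model(path: str | Path) -> SegmenterModel:
    """Load a model artifact written by :func:`save_model`."""
    try:
        data = np.load(path, allow_pickle=False)
    except (OSError, ValueError) as exc:
        raise CompatibilityError(f"cannot read model file {path}: {exc}") from exc
    if "meta_json" not in data:
        raise CompatibilityError(f"{path} is not a dlmss model artifact")
    meta = json.loads(bytes(data["meta_json"]).decode("utf-8"))
    if meta.get("format") != _FORMAT:
        raise CompatibilityError(f"unsupported model format {meta.get('format')!r}")
    fc = meta["feature_config"]
    feature_config = FeatureConfig(
        window_len=fc["window_len"],
        avg_orders=tuple(fc["avg_orders"]),
        center_coords=fc["center_coords"],
    )
    if meta["n_features"] != n_features(feature_config):
        raise CompatibilityError(
            "model metadata inconsistent: stored n_features "
            f"{meta['n_features']} vs feature config {n_features(feature_config)}"
        )
    net = BiLSTM(
        meta["n_features"],
        meta["hidden_units"],
        meta["n_classes"],
        np.random.default_rng(0),
    )
    params = {k[len("param_") :]: data[k] for k in data.files if k.startswith("param_")}
    expected = net.params["W_out"].shape
    if params["W_out"].shape != expected:
        raise CompatibilityError(
            f"stored output layer {params['W_out'].shape} does not match "
            f"declared classes ({expected})"
        )
    net.set_params(params)
    return SegmenterModel(net, feature_config, data["feat_mean"], data["feat_std"])
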