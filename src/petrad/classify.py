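"""Binary classification of controls versus dementia patients.

Two arms share one held-out test set:

- the radiomics arm: z-score-normalized selected features feeding a small
  feed-forward network (input -> 16 -> 8 -> 2, ReLU);
- the image arm: a 3D convolutional network (three conv/batch-norm/ReLU/
  max-pool blocks with 8/16/32 channels, then dense 64 -> 2, softmax) on
  whole volumes, optionally resampled to a reduced cube.

Both emit a per-subject score table: the winning-class posterior
probability on a 0-100 scale (the two class scores always sum to 100; the
prediction is the class with score >= 50).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from sklearn.neural_network import MLPClassifier

from . import nnet
from .grids import VolumeGrid

__all__ = [
    "SplitSpec",
    "NNConfig",
    "CNNConfig",
    "make_splits",
    "shared_test_split",
    "zscore_fit_apply",
    "train_feature_nn",
    "train_cnn_3d",
    "predict_scores",
    "resample_volume",
]

LABEL_ORDER = ("control", "dementia")


@dataclass
class SplitSpec:
    """Train/validation/test fractions (must sum to 1), stratified by
    class, reproducible from the seed."""

    fractions: tuple[float, float, float] = (0.8, 0.1, 0.1)
    stratified: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if abs(sum(self.fractions) - 1.0) > 1e-9:
            raise ValueError("split fractions must sum to 1")


@dataclass
class NNConfig:
    hidden_sizes: tuple[int, ...] = (16, 8)
    epochs: int = 2000
    learning_rate: float = 1e-3
    seed: int = 0


@dataclass
class CNNConfig:
    channels: tuple[int, ...] = (8, 16, 32)
    dense_size: int = 64
    input_shape: tuple[int, int, int] = (32, 32, 32)
    epochs: int = 20
    batch_size: int = 16
    learning_rate: float = 1e-3
    patience: int = 4
    seed: int = 0


def shared_test_split(labels: np.ndarray, n_per_class: int = 10, seed: int = 0) -> np.ndarray:
    """Indices of the shared held-out test set: ``n_per_class`` subjects
    drawn from each class, the same for both arms."""
    labels = np.asarray(labels)
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0x7E57]))
    picks = []
    for cls in np.unique(labels):
        idx = np.flatnonzero(labels == cls)
        if len(idx) < n_per_class:
            raise ValueError(f"class {cls!r} has fewer than {n_per_class} subjects")
        picks.append(rng.choice(idx, size=n_per_class, replace=False))
    return np.sort(np.concatenate(picks))


def make_splits(
    labels: np.ndarray, spec: SplitSpec, test_indices: np.ndarray | None = None
) -> dict[str, np.ndarray]:
    """Stratified train/val/test index split.  When ``test_indices`` is
    given (the shared test set), only train/val are drawn from the rest,
    proportionally to the spec's train:val ratio."""
    labels = np.asarray(labels)
    n = len(labels)
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 0x5917]))
    f_train, f_val, f_test = spec.fractions

    if test_indices is None:
        test_mask = np.zeros(n, dtype=bool)
        want_test = f_test
    else:
        test_mask = np.zeros(n, dtype=bool)
        test_mask[test_indices] = True
        want_test = 0.0

    train_idx, val_idx, test_idx = [], [], []
    if spec.stratified:
        groups = [np.flatnonzero(labels == c) for c in np.unique(labels)]
    else:
        groups = [np.arange(n)]
    for idx in groups:
        pool = idx[~test_mask[idx]]
        pool = rng.permutation(pool)
        n_pool = len(pool)
        if want_test > 0:
            n_test = max(1, round(want_test * len(idx)))
            test_idx.append(pool[:n_test])
            pool = pool[n_test:]
            n_pool = len(pool)
        n_val = max(1, round(f_val / (f_train + f_val) * n_pool))
        val_idx.append(pool[:n_val])
        train_idx.append(pool[n_val:])
        test_idx.append(idx[test_mask[idx]])

    splits = {
        "train": np.sort(np.concatenate(train_idx)),
        "val": np.sort(np.concatenate(val_idx)),
        "test": np.sort(np.concatenate([t for t in test_idx if t.size])),
    }
    for name in ("train", "val", "test"):
        if len(np.unique(labels[splits[name]])) < 2:
            raise ValueError(f"degenerate split: {name} set lacks both classes")
    return splits


def zscore_fit_apply(
    train: pd.DataFrame, *others: pd.DataFrame
) -> tuple[pd.DataFrame, ...]:
    """Per-feature z-score normalization fitted on the training table only
    (sample SD, ddof=1) and applied unchanged to the other tables."""
    if len(train) < 2:
        raise ValueError("need more than one training subject")
    mean = train.mean(axis=0)
    sd = train.std(axis=0, ddof=1)
    zero = sd[sd == 0]
    if len(zero):
        raise ValueError(f"zero-variance feature(s) in training data: {list(zero.index)}")
    out = tuple((t - mean) / sd for t in (train, *others))
    return out


def _score_table(
    subject_ids, y_true: np.ndarray, proba: np.ndarray, model_tag: str
) -> pd.DataFrame:
    """Winning-class probability on the 0-100 scale, rows by subject_id."""
    pred = proba.argmax(axis=1)
    table = pd.DataFrame(
        {
            "subject_id": list(subject_ids),
            "true_group": [LABEL_ORDER[int(v)] for v in y_true],
            "predicted_group": [LABEL_ORDER[int(v)] for v in pred],
            "score": 100.0 * proba.max(axis=1),
            "model": model_tag,
        }
    )
    return table.sort_values("subject_id", ignore_index=True)


def encode_labels(groups) -> np.ndarray:
    return np.array([LABEL_ORDER.index(g) for g in groups])


# ------------------------------------------------------- radiomics arm

def train_feature_nn(
    table: pd.DataFrame,
    labels: np.ndarray,
    splits: dict[str, np.ndarray],
    config: NNConfig | None = None,
) -> tuple[MLPClassifier, pd.DataFrame, dict[str, float]]:
    """Train the feed-forward network on selected features.

    Returns the fitted model (with the z-score parameters attached), the
    test ScoreTable, and accuracy metrics.  Deterministic given the seed.
    """
    config = config or NNConfig()
    y = np.asarray(labels)
    tr, va, te = splits["train"], splits["val"], splits["test"]
    z_tr, z_va, z_te = zscore_fit_apply(table.iloc[tr], table.iloc[va], table.iloc[te])

    model = MLPClassifier(
        hidden_layer_sizes=config.hidden_sizes,
        activation="relu",
        solver="adam",
        learning_rate_init=config.learning_rate,
        max_iter=config.epochs,
        random_state=config.seed,
    )
    model.fit(z_tr.to_numpy(), y[tr])
    metrics = {
        "train_accuracy": float(model.score(z_tr.to_numpy(), y[tr])),
        "val_accuracy": float(model.score(z_va.to_numpy(), y[va])),
        "test_accuracy": float(model.score(z_te.to_numpy(), y[te])),
    }
    proba = model.predict_proba(z_te.to_numpy())
    ids = table.index[te] if table.index.name == "subject_id" else te
    scores = _score_table(ids, y[te], proba, "radiomics_nn")
    return model, scores, metrics


# ------------------------------------------------------------ CNN arm

def resample_volume(volume: VolumeGrid, target_shape) -> np.ndarray:
    """Trilinear resample of a volume's intensities to ``target_shape``."""
    factors = [t / s for t, s in zip(target_shape, volume.shape)]
    return ndimage.zoom(volume.data, factors, order=1)


def build_cnn(config: CNNConfig, rng: np.random.Generator) -> nnet.Sequential:
    layers: list[nnet.Layer] = []
    in_ch = 1
    shape = np.array(config.input_shape)
    for ch in config.channels:
        layers += [nnet.Conv3D(in_ch, ch, rng), nnet.BatchNorm(ch), nnet.ReLU(), nnet.MaxPool3D()]
        in_ch = ch
        shape //= 2
    flat = int(in_ch * np.prod(shape))
    layers += [
        nnet.Flatten(),
        nnet.Dense(flat, config.dense_size, rng),
        nnet.ReLU(),
        nnet.Dense(config.dense_size, 2, rng),
    ]
    return nnet.Sequential(layers)


def _cnn_accuracy(model: nnet.Sequential, X: np.ndarray, y: np.ndarray,
                  batch: int = 16) -> float:
    correct = 0
    for i in range(0, len(X), batch):
        logits = model.forward(X[i: i + batch], train=False)
        correct += int((logits.argmax(axis=1) == y[i: i + batch]).sum())
    return correct / len(X)


def train_cnn_3d(
    volumes: list[VolumeGrid],
    labels: np.ndarray,
    splits: dict[str, np.ndarray],
    config: CNNConfig | None = None,
    subject_ids=None,
) -> tuple[nnet.Sequential, pd.DataFrame, dict[str, float]]:
    """Train the 3D CNN on (optionally resampled) whole volumes.

    Inputs are standardized by the training set's global mean/SD.  Early
    stopping tracks validation loss; the best-validation parameters are
    restored before scoring.  Deterministic given the seed.
    """
    config = config or CNNConfig()
    shapes = {v.shape for v in volumes}
    if len(shapes) != 1:
        raise ValueError(f"volumes have mismatched shapes: {shapes}")
    y = np.asarray(labels)

    if next(iter(shapes)) == tuple(config.input_shape):
        data = np.stack([v.data for v in volumes])
    else:
        data = np.stack([resample_volume(v, config.input_shape) for v in volumes])
    X = data[:, None].astype(np.float64)  # NCDHW

    tr, va, te = splits["train"], splits["val"], splits["test"]
    mu, sd = X[tr].mean(), X[tr].std()
    X = (X - mu) / sd

    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0xC33]))
    model = build_cnn(config, rng)
    opt = nnet.Adam(model.params, lr=config.learning_rate)

    best_val, best_state, patience_left = np.inf, model.get_state(), config.patience
    for _ in range(config.epochs):
        order = rng.permutation(tr)
        for i in range(0, len(order), config.batch_size):
            idx = order[i: i + config.batch_size]
            logits = model.forward(X[idx], train=True)
            _, grad = nnet.softmax_cross_entropy(logits, y[idx])
            model.backward(grad)
            opt.step(model.grads)
        val_logits = model.forward(X[va], train=False)
        val_loss, _ = nnet.softmax_cross_entropy(val_logits, y[va])
        if val_loss < best_val - 1e-6:
            best_val, best_state, patience_left = val_loss, model.get_state(), config.patience
        else:
            patience_left -= 1
            if patience_left <= 0:
                break
    model.set_state(best_state)

    metrics = {
        "train_accuracy": _cnn_accuracy(model, X[tr], y[tr]),
        "val_accuracy": _cnn_accuracy(model, X[va], y[va]),
        "test_accuracy": _cnn_accuracy(model, X[te], y[te]),
    }
    proba = nnet.softmax(model.forward(X[te], train=False))
    ids = list(np.asarray(subject_ids)[te]) if subject_ids is not None else list(te)
    scores = _score_table(ids, y[te], proba, "cnn_3d")
    return model, scores, metrics


def predict_scores(model, inputs, subject_ids, y_true, model_tag: str) -> pd.DataFrame:
    """Score arbitrary inputs with a trained model of either arm."""
    if isinstance(model, nnet.Sequential):
        proba = nnet.softmax(model.forward(np.asarray(inputs), train=False))
    else:
        proba = model.predict_proba(np.asarray(inputs))
    return _score_table(subject_ids, np.asarray(y_true), proba, model_tag)
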