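"""CNN classification of feature tensors: training, evaluation, prediction.

A small convolutional network maps an 11 x 105 feature tensor to a sweep
probability.  The default architecture follows the design constraints that
matter for this problem: 2-D convolution kernels spanning at least three
statistic rows and three window columns (so filters mix different
statistic types and neighbouring centres early), three conv blocks with
pooling, dropout 0.25, a dense head and a sigmoid output trained with
binary cross-entropy, Adam, an 80/20 train/validation split and early
stopping on validation loss.  The implementation is self-contained numpy
(im2col convolution, explicit backprop) and exactly reproducible under a
seed, which the tests rely on.

A trained model records a manifest (architecture, seed, row order and the
provenance of the norms its training tensors were standardized with) and
refuses to classify tensors whose row order or norms provenance differ —
mixing normalizations silently is the classic way to get nonsense
probabilities.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from sklearn.metrics import auc as _auc
from sklearn.metrics import roc_curve as _roc_curve

from .features import FeatureTensor, stack_tensors

DEFAULT_THRESHOLDS = (0.001, 0.01, 0.02, 0.5, 0.8, 0.99)


# ---------------------------------------------------------------------------
# Layers
# ---------------------------------------------------------------------------

class _Conv2D:
    def __init__(self, rng, in_ch: int, filters: int, kh: int, kw: int) -> None:
        scale = np.sqrt(2.0 / (in_ch * kh * kw))
        self.W = rng.normal(0.0, scale, size=(filters, in_ch, kh, kw))
        self.b = np.zeros(filters)
        self.params = ["W", "b"]

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        from numpy.lib.stride_tricks import sliding_window_view

        kh, kw = self.W.shape[2], self.W.shape[3]
        self._x = x
        view = sliding_window_view(x, (kh, kw), axis=(2, 3))
        self._view = view
        return np.einsum("nchwij,fcij->nfhw", view, self.W, optimize=True) + self.b[None, :, None, None]

    def backward(self, dout: np.ndarray) -> np.ndarray:
        kh, kw = self.W.shape[2], self.W.shape[3]
        self.dW = np.einsum("nchwij,nfhw->fcij", self._view, dout, optimize=True)
        self.db = dout.sum(axis=(0, 2, 3))
        dx = np.zeros_like(self._x, dtype=np.float64)
        ho, wo = dout.shape[2], dout.shape[3]
        for i in range(kh):
            for j in range(kw):
                dx[:, :, i : i + ho, j : j + wo] += np.einsum(
                    "nfhw,fc->nchw", dout, self.W[:, :, i, j], optimize=True
                )
        return dx


class _ReLU:
    params: list[str] = []

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        self._mask = x > 0
        return x * self._mask

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout * self._mask


class _MaxPool:
    params: list[str] = []

    def __init__(self, ph: int, pw: int) -> None:
        self.ph, self.pw = ph, pw

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        n, c, h, w = x.shape
        ho, wo = h // self.ph, w // self.pw
        self._in_shape = x.shape
        xr = (
            x[:, :, : ho * self.ph, : wo * self.pw]
            .reshape(n, c, ho, self.ph, wo, self.pw)
            .transpose(0, 1, 2, 4, 3, 5)
            .reshape(n, c, ho, wo, self.ph * self.pw)
        )
        self._argmax = xr.argmax(axis=-1)
        return np.take_along_axis(xr, self._argmax[..., None], axis=-1)[..., 0]

    def backward(self, dout: np.ndarray) -> np.ndarray:
        n, c, h, w = self._in_shape
        ho, wo = h // self.ph, w // self.pw
        dxr = np.zeros((n, c, ho, wo, self.ph * self.pw))
        np.put_along_axis(dxr, self._argmax[..., None], dout[..., None], axis=-1)
        dx = np.zeros(self._in_shape)
        dx[:, :, : ho * self.ph, : wo * self.pw] = (
            dxr.reshape(n, c, ho, wo, self.ph, self.pw)
            .transpose(0, 1, 2, 4, 3, 5)
            .reshape(n, c, ho * self.ph, wo * self.pw)
        )
        return dx


class _Flatten:
    params: list[str] = []

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout.reshape(self._shape)


class _Dense:
    def __init__(self, rng, n_in: int, n_out: int) -> None:
        self.W = rng.normal(0.0, np.sqrt(2.0 / n_in), size=(n_in, n_out))
        self.b = np.zeros(n_out)
        self.params = ["W", "b"]

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        self._x = x
        return x @ self.W + self.b

    def backward(self, dout: np.ndarray) -> np.ndarray:
        self.dW = self._x.T @ dout
        self.db = dout.sum(axis=0)
        return dout @ self.W.T


class _Dropout:
    params: list[str] = []

    def __init__(self, rate: float, rng) -> None:
        self.rate = rate
        self.rng = rng

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        if not training or self.rate <= 0:
            self._mask = None
            return x
        self._mask = (self.rng.random(x.shape) >= self.rate) / (1.0 - self.rate)
        return x * self._mask

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout if self._mask is None else dout * self._mask


# ---------------------------------------------------------------------------
# Model
# ---------------------------------------------------------------------------

@dataclass
class Hyperparams:
    conv_blocks: tuple[tuple[int, int, int, int, int], ...] = (
        # (filters, kernel_h, kernel_w, pool_h, pool_w)
        (16, 3, 3, 1, 2),
        (32, 3, 3, 1, 2),
        (32, 3, 3, 2, 2),
    )
    dense_units: int = 64
    dropout: float = 0.25
    learning_rate: float = 1e-3
    batch_size: int = 32
    max_epochs: int = 100
    patience: int = 10
    validation_split: float = 0.2


@dataclass
class TrainedModel:
    """A trained CNN plus the manifest binding it to its training context."""

    layers: list
    manifest: dict

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        """Sweep probabilities for a (N, H, W) or (H, W) array."""
        x = np.asarray(x, dtype=np.float64)
        if x.ndim == 2:
            x = x[None]
        out = x[:, None, :, :]
        for layer in self.layers:
            out = layer.forward(out, training=False)
        return _sigmoid(out[:, 0])

    def save(self, path: str | Path) -> None:
        path = Path(path)
        arrays = {}
        for i, layer in enumerate(self.layers):
            for p in layer.params:
                arrays[f"l{i}_{p}"] = getattr(layer, p)
        np.savez_compressed(path.with_suffix(".npz"), **arrays)
        path.with_suffix(".json").write_text(json.dumps(self.manifest, indent=1))

    @classmethod
    def load(cls, path: str | Path) -> "TrainedModel":
        path = Path(path)
        manifest = json.loads(path.with_suffix(".json").read_text())
        model = _build_network(
            Hyperparams(**{
                k: (tuple(tuple(b) for b in v) if k == "conv_blocks" else v)
                for k, v in manifest["hyperparams"].items()
            }),
            tuple(manifest["input_shape"]),
            np.random.default_rng(0),
        )
        arrays = np.load(path.with_suffix(".npz"))
        for i, layer in enumerate(model):
            for p in layer.params:
                setattr(layer, p, arrays[f"l{i}_{p}"])
        return cls(model, manifest)


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z, dtype=np.float64)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def _build_network(hp: Hyperparams, input_shape: tuple[int, int], rng) -> list:
    h, w = input_shape
    layers: list = []
    in_ch = 1
    for filters, kh, kw, ph, pw in hp.conv_blocks:
        if h - kh + 1 < 1 or w - kw + 1 < 1:
            raise ValueError("input too small for configured conv blocks")
        layers.append(_Conv2D(rng, in_ch, filters, kh, kw))
        layers.append(_ReLU())
        h, w = h - kh + 1, w - kw + 1
        if ph * pw > 1 and h // ph >= 1 and w // pw >= 1:
            layers.append(_MaxPool(ph, pw))
            h, w = h // ph, w // pw
        in_ch = filters
    layers.append(_Flatten())
    layers.append(_Dense(rng, in_ch * h * w, hp.dense_units))
    layers.append(_ReLU())
    layers.append(_Dropout(hp.dropout, rng))
    layers.append(_Dense(rng, hp.dense_units, 1))
    return layers


def _forward(layers: list, x: np.ndarray, training: bool) -> np.ndarray:
    out = x
    for layer in layers:
        out = layer.forward(out, training)
    return out[:, 0]


def _backward(layers: list, dlogit: np.ndarray) -> None:
    dout = dlogit[:, None]
    for layer in reversed(layers):
        dout = layer.backward(dout)


class _Adam:
    def __init__(self, layers: list, lr: float) -> None:
        self.layers, self.lr = layers, lr
        self.b1, self.b2, self.eps = 0.9, 0.999, 1e-8
        self.t = 0
        self.m = {}
        self.v = {}
        for i, layer in enumerate(layers):
            for p in layer.params:
                self.m[(i, p)] = np.zeros_like(getattr(layer, p))
                self.v[(i, p)] = np.zeros_like(getattr(layer, p))

    def step(self) -> None:
        self.t += 1
        for i, layer in enumerate(self.layers):
            for p in layer.params:
                g = getattr(layer, "d" + p)
                m = self.m[(i, p)] = self.b1 * self.m[(i, p)] + (1 - self.b1) * g
                v = self.v[(i, p)] = self.b2 * self.v[(i, p)] + (1 - self.b2) * g * g
                mh = m / (1 - self.b1 ** self.t)
                vh = v / (1 - self.b2 ** self.t)
                setattr(layer, p, getattr(layer, p) - self.lr * mh / (np.sqrt(vh) + self.eps))


def _bce_loss(logits: np.ndarray, y: np.ndarray) -> tuple[float, np.ndarray]:
    # numerically stable binary cross-entropy with logits
    loss = np.mean(np.maximum(logits, 0) - logits * y + np.log1p(np.exp(-np.abs(logits))))
    grad = (_sigmoid(logits) - y) / y.size
    return float(loss), grad


def _get_weights(layers: list) -> list:
    return [[getattr(l, p).copy() for p in l.params] for l in layers]


def _set_weights(layers: list, weights: list) -> None:
    for layer, ws in zip(layers, weights):
        for p, w in zip(layer.params, ws):
            setattr(layer, p, w.copy())


def train(
    tensors: list[FeatureTensor] | np.ndarray,
    labels: np.ndarray,
    hyperparams: Hyperparams | None = None,
    seed: int = 0,
) -> TrainedModel:
    """Train the CNN on a balanced binary dataset.

    ``tensors`` may be a list of :class:`FeatureTensor` (their row order
    and norms provenance are recorded in the manifest) or a raw
    (N, H, W) array.  20% of the data is held back for in-model
    validation; training stops early when validation loss has not
    improved for ``patience`` epochs and the best weights are restored.
    Deterministic under ``seed``.
    """
    hp = hyperparams or Hyperparams()
    if isinstance(tensors, np.ndarray):
        X = np.asarray(tensors, dtype=np.float64)
        row_order: list[str] = []
        provenance = ""
    else:
        X = stack_tensors(tensors)
        row_order = list(tensors[0].row_order)
        provenance = tensors[0].metadata.get("norms_provenance", "")
    y = np.asarray(labels, dtype=np.float64)
    if X.shape[0] != y.size:
        raise ValueError("labels length mismatch")
    classes = np.unique(y)
    if classes.size < 2:
        raise ValueError("training data contains a single class")

    rng = np.random.default_rng(seed)
    # stratified 80/20 split: the early-stopping signal must not be
    # class-skewed by the luck of the shuffle
    val_idx = []
    train_idx = []
    for cls in classes:
        members = rng.permutation(np.flatnonzero(y == cls))
        k = max(1, int(round(hp.validation_split * members.size)))
        val_idx.append(members[:k])
        train_idx.append(members[k:])
    val_idx = rng.permutation(np.concatenate(val_idx))
    train_idx = rng.permutation(np.concatenate(train_idx))
    Xval, yval = X[val_idx, None], y[val_idx]
    Xtr, ytr = X[train_idx, None], y[train_idx]
    n_val = val_idx.size

    layers = _build_network(hp, X.shape[1:], rng)
    opt = _Adam(layers, hp.learning_rate)
    best_loss = np.inf
    best_weights = _get_weights(layers)
    best_epoch = 0
    history: list[float] = []
    for epoch in range(hp.max_epochs):
        order = rng.permutation(Xtr.shape[0])
        for start in range(0, Xtr.shape[0], hp.batch_size):
            idx = order[start : start + hp.batch_size]
            logits = _forward(layers, Xtr[idx], training=True)
            _, grad = _bce_loss(logits, ytr[idx])
            _backward(layers, grad)
            opt.step()
        val_logits = _forward(layers, Xval, training=False)
        val_loss, _ = _bce_loss(val_logits, yval)
        history.append(val_loss)
        if val_loss < best_loss - 1e-6:
            best_loss = val_loss
            best_weights = _get_weights(layers)
            best_epoch = epoch
        elif epoch - best_epoch >= hp.patience:
            break
    _set_weights(layers, best_weights)
    val_acc = float(np.mean((_sigmoid(_forward(layers, Xval, False)) > 0.5) == yval))
    manifest = {
        "row_order": row_order,
        "norms_provenance": provenance,
        "seed": seed,
        "input_shape": list(X.shape[1:]),
        "epochs_run": len(history),
        "best_epoch": best_epoch,
        "val_loss_history": history,
        "val_loss": best_loss,
        "val_accuracy": val_acc,
        "n_train": int(Xtr.shape[0]),
        "n_val": int(n_val),
        "hyperparams": {
            "conv_blocks": [list(b) for b in hp.conv_blocks],
            "dense_units": hp.dense_units,
            "dropout": hp.dropout,
            "learning_rate": hp.learning_rate,
            "batch_size": hp.batch_size,
            "max_epochs": hp.max_epochs,
            "patience": hp.patience,
            "validation_split": hp.validation_split,
        },
    }
    return TrainedModel(layers, manifest)


def predict(model: TrainedModel, tensor: FeatureTensor | np.ndarray) -> float | np.ndarray:
    """Sweep probability in [0, 1] for one tensor (or a batch array).

    Raises when the tensor's row order or norms provenance contradict the
    model's training manifest.
    """
    if isinstance(tensor, FeatureTensor):
        if model.manifest["row_order"] and list(tensor.row_order) != model.manifest["row_order"]:
            raise ValueError("tensor row_order does not match the model manifest")
        prov = tensor.metadata.get("norms_provenance", "")
        want = model.manifest["norms_provenance"]
        if want and prov and prov != want:
            raise ValueError(
                f"norms provenance mismatch: model={want!r}, tensor={prov!r}"
            )
        return float(model.predict_proba(tensor.values)[0])
    return model.predict_proba(np.asarray(tensor))


def predict_batch(model: TrainedModel, tensors: list[FeatureTensor]) -> np.ndarray:
    return np.asarray([predict(model, t) for t in tensors])


# ---------------------------------------------------------------------------
# Evaluation
# ---------------------------------------------------------------------------

@dataclass
class EvalReport:
    """ROC/AUC/confusion evaluation of a model on a labeled test set.

    Two false-positive rates are reported at each threshold because both
    conventions are in use: ``fpr_neutral`` = FP / true neutrals (the ROC
    sense) and ``fpr_of_positives`` = FP / all positive classifications
    (the discovery-oriented sense used for FDR work).
    """

    roc_fpr: np.ndarray
    roc_tpr: np.ndarray
    auc: float
    threshold: float
    confusion: np.ndarray  # [[TN, FP], [FN, TP]]
    by_threshold: dict[float, dict[str, float]]
    accuracy: float
    precision: float

    def fpr_at(self, threshold: float) -> float:
        return self.by_threshold[threshold]["fpr_neutral"]

    def tpr_at(self, threshold: float) -> float:
        return self.by_threshold[threshold]["tpr"]

    def to_json(self) -> str:
        d = {
            "auc": self.auc,
            "threshold": self.threshold,
            "confusion": self.confusion.tolist(),
            "accuracy": self.accuracy,
            "precision": self.precision,
            "by_threshold": {str(k): v for k, v in self.by_threshold.items()},
        }
        return json.dumps(d, indent=1)


def evaluate(
    model_or_scores: TrainedModel | np.ndarray,
    tensors: list[FeatureTensor] | np.ndarray | None = None,
    labels: np.ndarray | None = None,
    threshold: float = 0.5,
    thresholds: tuple[float, ...] = DEFAULT_THRESHOLDS,
) -> EvalReport:
    """Evaluate a model (or precomputed scores) against true labels."""
    if isinstance(model_or_scores, TrainedModel):
        if tensors is None or (hasattr(tensors, "__len__") and len(tensors) == 0):
            raise ValueError("empty test set")
        if isinstance(tensors, np.ndarray):
            scores = model_or_scores.predict_proba(tensors)
        else:
            scores = predict_batch(model_or_scores, tensors)
    else:
        scores = np.asarray(model_or_scores, dtype=np.float64)
    y = np.asarray(labels, dtype=np.int64)
    if y.size == 0:
        raise ValueError("empty test set")
    fpr, tpr, _ = _roc_curve(y, scores)
    roc_auc = float(_auc(fpr, tpr))
    by_threshold = {}
    for th in sorted(set(thresholds) | {threshold}):
        by_threshold[th] = _rates(scores, y, th)
    conf = _confusion(scores, y, threshold)
    tn, fp, fn, tp = conf[0, 0], conf[0, 1], conf[1, 0], conf[1, 1]
    return EvalReport(
        roc_fpr=fpr,
        roc_tpr=tpr,
        auc=roc_auc,
        threshold=threshold,
        confusion=conf,
        by_threshold=by_threshold,
        accuracy=float((tn + tp) / y.size),
        precision=float(tp / (tp + fp)) if (tp + fp) > 0 else float("nan"),
    )


def _confusion(scores: np.ndarray, y: np.ndarray, threshold: float) -> np.ndarray:
    pred = scores > threshold
    tn = int(np.sum((y == 0) & ~pred))
    fp = int(np.sum((y == 0) & pred))
    fn = int(np.sum((y == 1) & ~pred))
    tp = int(np.sum((y == 1) & pred))
    return np.array([[tn, fp], [fn, tp]])


def _rates(scores: np.ndarray, y: np.ndarray, threshold: float) -> dict[str, float]:
    conf = _confusion(scores, y, threshold)
    tn, fp, fn, tp = conf[0, 0], conf[0, 1], conf[1, 0], conf[1, 1]
    n_neut, n_sweep, n_pos = tn + fp, fn + tp, fp + tp
    return {
        "tpr": tp / n_sweep if n_sweep else float("nan"),
        "fpr_neutral": fp / n_neut if n_neut else float("nan"),
        "fpr_of_positives": fp / n_pos if n_pos else float("nan"),
    }


def power_by_stratum(
    scores: np.ndarray,
    values: np.ndarray,
    bin_edges: np.ndarray,
    threshold: float = 0.5,
) -> dict[str, float]:
    """Detection rate of sweep replicates stratified by a parameter.

    ``values`` holds the parameter (e.g. tau) of each sweep replicate;
    bins are (lo, hi] per ``bin_edges``.
    """
    scores = np.asarray(scores)
    values = np.asarray(values)
    out = {}
    for lo, hi in zip(bin_edges[:-1], bin_edges[1:]):
        sel = (values > lo) & (values <= hi)
        out[f"({lo:g},{hi:g}]"] = (
            float(np.mean(scores[sel] > threshold)) if sel.any() else float("nan")
        )
    return out
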