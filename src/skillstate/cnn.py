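"""Topography-preserving 3-D CNN with temporal attentive pooling (TAP).

The classifier takes 16 x 16 x 360 EEG tensors and applies three strided
valid convolutions (kernel/stride (2,2,10)/(2,2,4), (2,2,2)/(2,2,2),
(2,2,3)/(2,2,2); widths 16 -> 32 -> 64), each followed by batch
normalization and ReLU; a TAP layer collapses the temporal axis by learned
softmax attention; a dense head (batch norm, ReLU, dropout) and softmax
produce the two class probabilities.  Cross-entropy is minimized by Adam
(learning rate 0.001, batch 32) with L2 weight 0.01 on the dense layers'
kernels and biases; weights are Glorot-uniform initialized.

Note on shapes: the intermediate temporal length is derived from the
kernels and strides rather than fixed a priori — a 360-sample input gives
88 -> 44 -> 21 under valid convolution — and the layer-by-layer shapes are
recorded so they can be asserted and audited.

Grad-CAM saliency is computed from the gradients of a class logit with
respect to any convolutional (or TAP) feature map.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import zoom

from .evaluate import (
    ClassifierReport,
    confusion,
    make_splits,
    metrics,
    summarize_repeats,
)
from .io import ValidationError
from .nn import (
    Adam,
    BatchNorm,
    Conv3D,
    Dense,
    Dropout,
    Flatten,
    ReLU,
    TemporalAttentivePooling,
    softmax,
    softmax_xent,
)

__all__ = [
    "ESNetConfig",
    "ESNet",
    "SaliencyMap",
    "train",
    "evaluate_protocol",
    "protocol_table",
    "gradcam",
]

F32 = np.float32


@dataclass
class ESNetConfig:
    """Architecture and training hyperparameters."""

    input_shape: tuple = (16, 16, 360)
    conv_kernels: tuple = ((2, 2, 10), (2, 2, 2), (2, 2, 3))
    conv_strides: tuple = ((2, 2, 4), (2, 2, 2), (2, 2, 2))
    c1: int = 16              # first conv width; doubles per layer
    hidden: int = 64          # dense-head width
    dropout: float = 0.5
    l2_weight: float = 0.01   # on dense kernels and biases
    batch_size: int = 32
    epochs: int = 200
    learning_rate: float = 0.001
    seed: int = 0
    dtype: type = np.float32  # float64 for gradient verification

    @property
    def widths(self) -> tuple:
        return tuple(self.c1 * 2**i for i in range(len(self.conv_kernels)))


class ESNet:
    """The 3-D CNN assembled from :mod:`skillstate.nn` primitives."""

    GRADCAM_LAYERS = ("conv1", "conv2", "conv3", "tap")

    def __init__(self, config: ESNetConfig | None = None):
        self.config = config or ESNetConfig()
        cfg = self.config
        rng = np.random.default_rng(cfg.seed)
        self.rng = np.random.default_rng(cfg.seed + 1)  # dropout / shuffling

        shape = tuple(cfg.input_shape)
        in_ch = 1
        self.layers: list = []
        self.names: list[str] = []
        self.shape_trace: list[tuple] = [shape + (in_ch,)]
        for i, (k, s, w) in enumerate(
            zip(cfg.conv_kernels, cfg.conv_strides, cfg.widths), start=1
        ):
            conv = Conv3D(in_ch, w, k, s, rng)
            shape = conv.out_shape(shape)
            if min(shape) < 1:
                raise ValidationError(f"conv{i} output collapsed: {shape}")
            self._add(conv, f"conv{i}")
            self._add(BatchNorm(w), f"bn{i}")
            self._add(ReLU(), f"relu{i}")
            self.shape_trace.append(shape + (w,))
            in_ch = w
        self._add(
            TemporalAttentivePooling(shape + (in_ch,), rng), "tap"
        )
        self.shape_trace.append(shape[:2] + (1, in_ch))
        flat = int(np.prod(shape[:2])) * in_ch
        self._add(Flatten(), "flatten")
        self._add(Dense(flat, cfg.hidden, rng), "fc1")
        self._add(BatchNorm(cfg.hidden), "bn_fc")
        self._add(ReLU(), "relu_fc")
        self._add(Dropout(cfg.dropout, self.rng), "dropout")
        self._add(Dense(cfg.hidden, 2, rng), "fc2")
        if cfg.dtype is not F32:
            for layer in self.layers:
                for k in layer.params:
                    layer.params[k] = layer.params[k].astype(cfg.dtype)
                if isinstance(layer, BatchNorm):
                    layer.running_mean = layer.running_mean.astype(cfg.dtype)
                    layer.running_var = layer.running_var.astype(cfg.dtype)

    def _add(self, layer, name):
        self.layers.append(layer)
        self.names.append(name)

    # -- forward / backward -------------------------------------------------

    def _prep(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=self.config.dtype)
        if x.ndim == 4:
            x = x[..., None]
        return x

    def forward(self, x, train=False, capture=None):
        """Logits for a batch; optionally capture named activations.

        The activation captured for a conv block is the post-ReLU feature
        map (the conventional Grad-CAM target); for "tap" it is the pooled
        output.
        """
        x = self._prep(x)
        captured = {}
        for layer, name in zip(self.layers, self.names):
            x = layer.forward(x, train)
            if capture:
                if name.startswith("relu") and name[-1].isdigit():
                    key = "conv" + name[-1]
                    if key in capture:
                        captured[key] = x
                elif name in capture:
                    captured[name] = x
        self._captured = captured
        return x

    def predict_proba(self, x) -> np.ndarray:
        return softmax(self.forward(x, train=False), axis=1)

    def predict(self, x) -> np.ndarray:
        return self.predict_proba(x).argmax(axis=1)

    def backward(self, dlogits, stop_at: str | None = None):
        """Backpropagate; with ``stop_at`` return the gradient w.r.t. that
        layer's (post-ReLU for conv blocks) activation."""
        dy = dlogits
        for layer, name in zip(reversed(self.layers), reversed(self.names)):
            if stop_at is not None:
                key = (
                    "conv" + name[-1]
                    if name.startswith("relu") and name[-1].isdigit()
                    else name
                )
                if key == stop_at:
                    return dy
            dy = layer.backward(dy)
        if stop_at is not None:
            raise ValidationError(f"unknown layer {stop_at!r}")
        return dy

    # -- losses -------------------------------------------------------------

    def _l2_layers(self):
        for layer, name in zip(self.layers, self.names):
            if name in ("fc1", "fc2", "tap"):
                yield layer, name

    def l2_penalty(self) -> float:
        cfg = self.config
        total = 0.0
        for layer, name in self._l2_layers():
            keys = ("Wt", "bt") if name == "tap" else ("W", "b")
            total += sum(float((layer.params[k] ** 2).sum()) for k in keys)
        return cfg.l2_weight * total

    def _apply_l2_grads(self) -> None:
        lam = self.config.l2_weight
        for layer, name in self._l2_layers():
            keys = ("Wt", "bt") if name == "tap" else ("W", "b")
            for k in keys:
                layer.grads[k] = layer.grads[k] + 2 * lam * layer.params[k]

    def loss_and_grads(self, x, y) -> tuple[float, np.ndarray]:
        logits = self.forward(x, train=True)
        ce, p, dlogits = softmax_xent(logits, y)
        self.backward(dlogits)
        self._apply_l2_grads()
        return ce + self.l2_penalty(), p

    @property
    def n_params(self) -> int:
        return sum(l.n_params for l in self.layers)


# --------------------------------------------------------------------------
# training and evaluation protocol
# --------------------------------------------------------------------------

def _xy(dataset) -> tuple[np.ndarray, np.ndarray]:
    if hasattr(dataset, "tensors"):
        return dataset.tensors, dataset.y
    x, y = dataset
    return np.asarray(x), np.asarray(y)


def train(
    dataset,
    config: ESNetConfig | None = None,
    val=None,
    verbose: bool = False,
):
    """Train a fresh model; returns (model, learning-curve DataFrame).

    ``dataset`` is an EEGTensorDataset or an ``(X, y)`` pair with X of
    shape (N, 16, 16, 360) and integer targets (expert=1).
    """
    config = config or ESNetConfig()
    X, y = _xy(dataset)
    if len(np.unique(y)) < 2:
        raise ValidationError("training data must contain both classes")
    model = ESNet(config)
    opt = Adam(model.layers, lr=config.learning_rate)
    rng = model.rng
    n = len(y)
    curves = []
    for epoch in range(config.epochs):
        order = rng.permutation(n)
        losses, correct = [], 0
        for s in range(0, n, config.batch_size):
            idx = order[s : s + config.batch_size]
            loss, p = model.loss_and_grads(X[idx], y[idx])
            opt.step()
            losses.append(loss)
            correct += int((p.argmax(axis=1) == y[idx]).sum())
        row = {
            "epoch": epoch + 1,
            "train_loss": float(np.mean(losses)),
            "train_acc": correct / n,
        }
        if val is not None:
            Xv, yv = _xy(val)
            row["val_acc"] = float((model.predict(Xv) == yv).mean())
        curves.append(row)
        if verbose:
            print({k: round(v, 4) for k, v in row.items()})
    return model, pd.DataFrame(curves)


def _report(model: ESNet, X, y) -> ClassifierReport:
    pred = model.predict(X)
    names = np.array(["novice", "expert"])
    return metrics(confusion(names[y], names[pred]))


def evaluate_protocol(
    dataset,
    config: ESNetConfig | None = None,
    n_repeats: int = 10,
    folds: int = 5,
    holdout: float = 0.1,
    seed: int = 0,
) -> list[list[ClassifierReport]]:
    """Fixed-holdout, repeated k-fold training protocol.

    One holdout split (fraction ``holdout``) is fixed once; each repeat
    draws a fresh fold partition of the remaining data and trains one
    freshly initialized model per fold, evaluated on the holdout.  Returns
    per-repeat lists of per-fold holdout reports (summarize with
    :func:`protocol_table`).
    """
    config = config or ESNetConfig()
    X, y = _xy(dataset)
    plan = make_splits(len(y), holdout, folds, seed)
    Xh, yh = X[plan.holdout], y[plan.holdout]
    trainval = np.concatenate(plan.folds)
    results: list[list[ClassifierReport]] = []
    for r in range(n_repeats):
        rng = np.random.default_rng([seed, r + 1])
        perm = rng.permutation(trainval)
        fold_parts = np.array_split(perm, folds)
        fold_reports = []
        for f in range(folds):
            tr = np.concatenate([p for i, p in enumerate(fold_parts) if i != f])
            cfg = ESNetConfig(**{
                **config.__dict__,
                "seed": int(np.random.default_rng([seed, r + 1, f]).integers(2**31)),
            })
            model, _ = train((X[tr], y[tr]), cfg)
            fold_reports.append(_report(model, Xh, yh))
        results.append(fold_reports)
    return results


def protocol_table(results: list[list[ClassifierReport]]) -> pd.DataFrame:
    """Per-repeat mean +/- SD and max of each metric over folds."""
    rows = []
    for r, fold_reports in enumerate(results, start=1):
        summ = summarize_repeats(fold_reports)
        row = {"iteration": r}
        for m, s in summ.items():
            row[f"{m}_mean"] = s["mean"]
            row[f"{m}_sd"] = s["sd"]
            row[f"{m}_max"] = s["max"]
        rows.append(row)
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# Grad-CAM
# --------------------------------------------------------------------------

@dataclass
class SaliencyMap:
    """Nonnegative class-discriminative heatmaps for one input tensor."""

    layer: str
    heatmap: np.ndarray        # (16, 16) time-collapsed, upsampled
    timemap: np.ndarray        # (16, 16, t_layer) upsampled spatially
    raw: np.ndarray            # (h, w, t) at the layer's own resolution
    attention: np.ndarray | None = None  # TAP attention over time, if any

    def quadrant_means(self) -> dict[str, float]:
        h = self.heatmap
        g = h.shape[0]
        half = g // 2
        return {
            "upper-left": float(h[:half, :half].mean()),
            "upper-right": float(h[:half, half:].mean()),
            "lower-left": float(h[half:, :half].mean()),
            "lower-right": float(h[half:, half:].mean()),
        }


def gradcam(
    model: ESNet,
    tensor: np.ndarray,
    target_class: int = 1,
    layer: str = "tap",
) -> SaliencyMap:
    """Gradient-weighted class activation map at a chosen layer.

    Channel weights are the global-average gradients of the target-class
    logit with respect to the layer's feature map; the heatmap is the
    ReLU of the weight-summed features, upsampled to the input grid.
    """
    if layer not in ESNet.GRADCAM_LAYERS:
        raise ValidationError(
            f"layer must be one of {ESNet.GRADCAM_LAYERS}, got {layer!r}"
        )
    x = np.asarray(tensor, dtype=F32)
    if x.ndim == 3:
        x = x[None]
    logits = model.forward(x, train=False, capture={layer})
    feat = model._captured[layer]          # (1, h, w, t, c)
    dlogits = np.zeros_like(logits)
    dlogits[:, target_class] = 1.0
    grad = model.backward(dlogits, stop_at=layer)

    weights = grad.mean(axis=(1, 2, 3))            # (1, c)
    cam = np.einsum("bhwtc,bc->hwt", feat, weights)
    cam = np.maximum(cam, 0.0)

    g = model.config.input_shape[0]
    zf = (g / cam.shape[0], g / cam.shape[1], 1.0)
    timemap = zoom(cam, zf, order=1)
    heatmap = timemap.mean(axis=2)
    att = None
    tap = model.layers[model.names.index("tap")]
    if hasattr(tap, "_a"):
        att = tap.attention[0].copy()
    return SaliencyMap(layer, heatmap, timemap, cam, att)
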