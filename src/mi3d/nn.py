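"""Dual-branch 3D-EEG convolutional network in pure numpy.

The network consumes topographic tensors of shape ``(W, W, T)`` — the T
axis (time samples or PSD bins) is treated as the channel axis of 2-D
convolutions over the ``W x W`` scalp plane.  One branch per input
orientation:

====== ============================================== ==================
layer  operation                                       output (C, H, W)
====== ============================================== ==================
in     tensor, channels-first                          (T, 9, 9)
L1     conv (9,1), 'same', out depth W; ELU; dropout   (9, 9, 9)
L2     depthwise conv (3,6) + pointwise to 36; BN;     (36, 9, 9)
       ELU; dropout; avg-pool (3,6), ceil              (36, 3, 2)
L3     depthwise conv (2,3) + pointwise to 72; BN;     (72, 3, 2)
       ELU; avg-pool (2,4), ceil                       (72, 2, 1)
flat   flatten                                         144
====== ============================================== ==================

The dual-branch variant feeds the 90-degree-rotated tensor to a second,
independently weighted branch and concatenates the flattened branch outputs
before the dense head (256 units, ELU, softmax over the classes).  All
shapes are validated at build time; a mismatch raises naming the layer.

Training is Adam + softmax cross-entropy.  A single seeded generator drives
weight init, dropout masks and shuffling, so runs are bit-reproducible on a
fixed thread count.
"""

from __future__ import annotations

import hashlib
import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.model_selection import train_test_split

__all__ = ["ModelConfig", "TrainConfig", "Metrics", "build_model", "train",
           "evaluate", "cohen_kappa", "param_count", "weights_checksum",
           "CNN3DEEG"]


# ---------------------------------------------------------------------------
# layers
# ---------------------------------------------------------------------------

class Layer:
    def params(self):
        return []

    def grads(self):
        return []

    def forward(self, x, train=False):  # pragma: no cover - interface
        raise NotImplementedError

    def backward(self, g):  # pragma: no cover - interface
        raise NotImplementedError


def _same_pad(k: int) -> tuple[int, int]:
    return (k - 1) // 2, k - 1 - (k - 1) // 2


class Conv2D(Layer):
    """Grouped 2-D convolution, stride 1, 'same' zero padding."""

    def __init__(self, cin, cout, kh, kw, groups=1, rng=None, name="conv"):
        if cin % groups or cout % groups:
            raise ValueError(f"{name}: groups={groups} must divide "
                             f"cin={cin} and cout={cout}")
        self.cin, self.cout, self.kh, self.kw, self.groups = cin, cout, kh, kw, groups
        self.name = name
        fan_in = (cin // groups) * kh * kw
        rng = rng or np.random.default_rng()
        self.W = rng.normal(0.0, np.sqrt(2.0 / fan_in),
                            size=(cout, cin // groups, kh, kw))
        self.b = np.zeros(cout)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)

    def params(self):
        return [self.W, self.b]

    def grads(self):
        return [self.dW, self.db]

    def forward(self, x, train=False):
        b, cin, H, Wd = x.shape
        if cin != self.cin:
            raise ValueError(f"{self.name}: expected {self.cin} input "
                             f"channels, got {cin}")
        pt, pb = _same_pad(self.kh)
        pl, pr = _same_pad(self.kw)
        xp = np.pad(x, ((0, 0), (0, 0), (pt, pb), (pl, pr)))
        self._xp, self._shape = xp, (H, Wd)
        y = np.zeros((b, self.cout, H, Wd))
        cig, cog = self.cin // self.groups, self.cout // self.groups
        for g in range(self.groups):
            xg = xp[:, g * cig:(g + 1) * cig]
            Wg = self.W[g * cog:(g + 1) * cog]
            yg = y[:, g * cog:(g + 1) * cog]
            for u in range(self.kh):
                for v in range(self.kw):
                    yg += np.einsum("bchw,oc->bohw",
                                    xg[:, :, u:u + H, v:v + Wd], Wg[:, :, u, v])
        return y + self.b[None, :, None, None]

    def backward(self, g):
        H, Wd = self._shape
        xp = self._xp
        dxp = np.zeros_like(xp)
        self.dW[...] = 0.0
        self.db[...] = g.sum(axis=(0, 2, 3))
        cig, cog = self.cin // self.groups, self.cout // self.groups
        for gi in range(self.groups):
            xg = xp[:, gi * cig:(gi + 1) * cig]
            Wg = self.W[gi * cog:(gi + 1) * cog]
            gg = g[:, gi * cog:(gi + 1) * cog]
            dxg = dxp[:, gi * cig:(gi + 1) * cig]
            for u in range(self.kh):
                for v in range(self.kw):
                    patch = xg[:, :, u:u + H, v:v + Wd]
                    self.dW[gi * cog:(gi + 1) * cog, :, u, v] = np.einsum(
                        "bohw,bchw->oc", gg, patch)
                    dxg[:, :, u:u + H, v:v + Wd] += np.einsum(
                        "bohw,oc->bchw", gg, Wg[:, :, u, v])
        pt, _ = _same_pad(self.kh)
        pl, _ = _same_pad(self.kw)
        return dxp[:, :, pt:pt + H, pl:pl + Wd]


class BatchNorm2D(Layer):
    def __init__(self, c, momentum=0.1, eps=1e-5):
        self.gamma, self.beta = np.ones(c), np.zeros(c)
        self.dgamma, self.dbeta = np.zeros(c), np.zeros(c)
        self.run_mean, self.run_var = np.zeros(c), np.ones(c)
        self.momentum, self.eps = momentum, eps

    def params(self):
        return [self.gamma, self.beta]

    def grads(self):
        return [self.dgamma, self.dbeta]

    def forward(self, x, train=False):
        if train:
            mu = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            self.run_mean += self.momentum * (mu - self.run_mean)
            self.run_var += self.momentum * (var - self.run_var)
        else:
            mu, var = self.run_mean, self.run_var
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mu[None, :, None, None]) * inv[None, :, None, None]
        self._xhat, self._inv, self._n = xhat, inv, x.shape[0] * x.shape[2] * x.shape[3]
        return self.gamma[None, :, None, None] * xhat + self.beta[None, :, None, None]

    def backward(self, g):
        xhat, inv, n = self._xhat, self._inv, self._n
        self.dgamma[...] = (g * xhat).sum(axis=(0, 2, 3))
        self.dbeta[...] = g.sum(axis=(0, 2, 3))
        gx = g * self.gamma[None, :, None, None]
        mean_gx = gx.mean(axis=(0, 2, 3), keepdims=True)
        mean_gxx = (gx * xhat).mean(axis=(0, 2, 3), keepdims=True)
        return inv[None, :, None, None] * (gx - mean_gx - xhat * mean_gxx)


class ELU(Layer):
    def __init__(self, alpha=1.0):
        self.alpha = alpha

    def forward(self, x, train=False):
        y = np.where(x > 0, x, self.alpha * np.expm1(x))
        self._x, self._y = x, y
        return y

    def backward(self, g):
        return g * np.where(self._x > 0, 1.0, self._y + self.alpha)


class Dropout(Layer):
    def __init__(self, p=0.25):
        self.p = p
        self.rng = np.random.default_rng()

    def forward(self, x, train=False):
        if not train or self.p == 0:
            self._mask = None
            return x
        self._mask = (self.rng.random(x.shape) >= self.p) / (1.0 - self.p)
        return x * self._mask

    def backward(self, g):
        return g if self._mask is None else g * self._mask


class AvgPool2D(Layer):
    """Average pooling with ceil-mode zero padding (pad counted in the mean)."""

    def __init__(self, kh, kw):
        self.kh, self.kw = kh, kw

    def out_shape(self, H, W):
        return -(-H // self.kh), -(-W // self.kw)

    def forward(self, x, train=False):
        b, c, H, W = x.shape
        Ho, Wo = self.out_shape(H, W)
        self._in = (H, W)
        xp = np.pad(x, ((0, 0), (0, 0), (0, Ho * self.kh - H),
                        (0, Wo * self.kw - W)))
        return xp.reshape(b, c, Ho, self.kh, Wo, self.kw).mean(axis=(3, 5))

    def backward(self, g):
        H, W = self._in
        up = np.repeat(np.repeat(g, self.kh, axis=2), self.kw, axis=3)
        return up[:, :, :H, :W] / (self.kh * self.kw)


class Flatten(Layer):
    def forward(self, x, train=False):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, g):
        return g.reshape(self._shape)


class Dense(Layer):
    def __init__(self, nin, nout, rng=None, name="dense"):
        rng = rng or np.random.default_rng()
        self.W = rng.normal(0.0, np.sqrt(2.0 / nin), size=(nin, nout))
        self.b = np.zeros(nout)
        self.dW, self.db = np.zeros_like(self.W), np.zeros_like(self.b)
        self.name = name

    def params(self):
        return [self.W, self.b]

    def grads(self):
        return [self.dW, self.db]

    def forward(self, x, train=False):
        self._x = x
        return x @ self.W + self.b

    def backward(self, g):
        self.dW[...] = self._x.T @ g
        self.db[...] = g.sum(axis=0)
        return g @ self.W.T


class Sequential(Layer):
    def __init__(self, layers):
        self.layers = layers

    def params(self):
        return [p for l in self.layers for p in l.params()]

    def grads(self):
        return [g for l in self.layers for g in l.grads()]

    def forward(self, x, train=False):
        for l in self.layers:
            x = l.forward(x, train=train)
        return x

    def backward(self, g):
        for l in reversed(self.layers):
            g = l.backward(g)
        return g


# ---------------------------------------------------------------------------
# model
# ---------------------------------------------------------------------------

@dataclass
class ModelConfig:
    """Architecture hyper-parameters (defaults match the shipped network)."""

    W: int = 9
    T: int = 750
    n_classes: int = 4
    dual_branch: bool = False
    dropout: float = 0.25
    dense_units: int = 256

    def __post_init__(self) -> None:
        if self.n_classes < 2:
            raise ValueError("need at least two classes")
        if self.W < 2 or self.T < 1:
            raise ValueError("W must be >= 2 and T >= 1")


@dataclass
class TrainConfig:
    """Optimisation settings: Adam, cross-entropy, lr 1e-3, 200 epochs."""

    learning_rate: float = 1e-3
    epochs: int = 200
    batch_size: int = 16
    seed: int = 0
    val_fraction: float = 0.16
    shuffle: bool = True

    def __post_init__(self) -> None:
        if self.learning_rate <= 0 or self.epochs <= 0 or self.batch_size <= 0:
            raise ValueError("learning rate, epochs and batch size must be positive")
        if not 0.0 <= self.val_fraction < 1.0:
            raise ValueError("val_fraction must lie in [0, 1)")


@dataclass
class Metrics:
    """Evaluation summary: accuracy, Cohen's kappa, confusion counts."""

    accuracy: float
    kappa: float
    confusion: np.ndarray
    traces: dict = field(default_factory=dict)


def _branch_layers(cfg: ModelConfig, rng, tag: str):
    W = cfg.W
    layers = [
        Conv2D(cfg.T, W, W, 1, rng=rng, name=f"{tag}/L1-conv(W,1)"),
        ELU(),
        Dropout(cfg.dropout),
        Conv2D(W, W, 3, 6, groups=W, rng=rng, name=f"{tag}/L2-depthwise(3,6)"),
        Conv2D(W, 36, 1, 1, rng=rng, name=f"{tag}/L2-pointwise"),
        BatchNorm2D(36),
        ELU(),
        Dropout(cfg.dropout),
        AvgPool2D(3, 6),
        Conv2D(36, 36, 2, 3, groups=36, rng=rng, name=f"{tag}/L3-depthwise(2,3)"),
        Conv2D(36, 72, 1, 1, rng=rng, name=f"{tag}/L3-pointwise"),
        BatchNorm2D(72),
        ELU(),
        AvgPool2D(2, 4),
        Flatten(),
    ]
    # propagate the spatial shape to size the head and catch mismatches early
    H = Wd = W
    for l in layers:
        if isinstance(l, AvgPool2D):
            H, Wd = l.out_shape(H, Wd)
            if H < 1 or Wd < 1:
                raise ValueError(f"{tag}: pooling ({l.kh},{l.kw}) collapses "
                                 f"the spatial plane to {H}x{Wd}")
    flat = 72 * H * Wd
    return Sequential(layers), flat


def _rotate_batch(x: np.ndarray) -> np.ndarray:
    # cell (r, c) -> (c, W-1-r) on the trailing two (spatial) axes
    return x.swapaxes(2, 3)[..., ::-1].copy()


class CNN3DEEG:
    """Single- or dual-branch topographic EEG classifier."""

    def __init__(self, cfg: ModelConfig, seed: int = 0):
        self.cfg = cfg
        self.rng = np.random.default_rng(seed)
        self.branches = []
        flat = 0
        n_branches = 2 if cfg.dual_branch else 1
        for i in range(n_branches):
            br, f = _branch_layers(cfg, self.rng, tag=f"branch{i}")
            self.branches.append(br)
            flat += f
        self.head = Sequential([
            Dense(flat, cfg.dense_units, rng=self.rng, name="head/dense"),
            ELU(),
            Dense(cfg.dense_units, cfg.n_classes, rng=self.rng,
                  name="head/logits"),
        ])
        self.classes_: np.ndarray | None = None
        for l in self._all_layers():
            if isinstance(l, Dropout):
                l.rng = self.rng

    def _all_layers(self):
        for br in self.branches:
            yield from br.layers
        yield from self.head.layers

    def params(self):
        return [p for br in self.branches for p in br.params()] + self.head.params()

    def grads(self):
        return [g for br in self.branches for g in br.grads()] + self.head.grads()

    def branch_param_count(self) -> int:
        return sum(p.size for p in self.branches[0].params())

    def head_param_count(self) -> int:
        return sum(p.size for p in self.head.params())

    def _inputs(self, x: np.ndarray):
        if x.ndim == 3:
            x = x[None]
        if x.shape[1] == self.cfg.W and x.shape[3] == self.cfg.T:
            # accept (b, W, W, T) tensors and move T to the channel axis
            x = np.moveaxis(x, 3, 1)
        if x.shape[1:] != (self.cfg.T, self.cfg.W, self.cfg.W):
            raise ValueError(f"expected input (T={self.cfg.T}, W={self.cfg.W}, "
                             f"W) per sample, got {x.shape[1:]}")
        if self.cfg.dual_branch:
            return [x, _rotate_batch(x)]
        return [x]

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        feats = [br.forward(xi, train=train)
                 for br, xi in zip(self.branches, self._inputs(x))]
        return self.head.forward(np.concatenate(feats, axis=1), train=train)

    def backward(self, g: np.ndarray) -> None:
        g = self.head.backward(g)
        start = 0
        for br in self.branches:
            width = g.shape[1] // len(self.branches)
            br.backward(g[:, start:start + width])
            start += width

    def predict_proba(self, x: np.ndarray, batch_size: int = 64) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        if x.ndim == 3:
            x = x[None]
        out = []
        for i in range(0, len(x), batch_size):
            out.append(_softmax(self.forward(x[i:i + batch_size], train=False)))
        return np.concatenate(out)

    def predict(self, x: np.ndarray) -> np.ndarray:
        proba = self.predict_proba(x)
        idx = np.argmax(proba, axis=1)
        if self.classes_ is None:
            return idx
        return self.classes_[idx]


def build_model(cfg: ModelConfig, seed: int = 0) -> CNN3DEEG:
    """Construct (and shape-validate) the network."""
    return CNN3DEEG(cfg, seed=seed)


def param_count(model: CNN3DEEG) -> int:
    return sum(p.size for p in model.params())


def weights_checksum(model: CNN3DEEG) -> str:
    h = hashlib.sha256()
    for p in model.params():
        h.update(np.ascontiguousarray(p).tobytes())
    return h.hexdigest()


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------

def _softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


class Adam:
    def __init__(self, params, grads, lr=1e-3, beta1=0.9, beta2=0.999, eps=1e-8):
        self.params, self.grads = params, grads
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self):
        self.t += 1
        for p, g, m, v in zip(self.params, self.grads, self.m, self.v):
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            mh = m / (1 - self.b1 ** self.t)
            vh = v / (1 - self.b2 ** self.t)
            p -= self.lr * mh / (np.sqrt(vh) + self.eps)


def _xent(logits: np.ndarray, yidx: np.ndarray):
    p = _softmax(logits)
    n = len(yidx)
    loss = float(-np.log(np.maximum(p[np.arange(n), yidx], 1e-12)).mean())
    g = p.copy()
    g[np.arange(n), yidx] -= 1.0
    return loss, g / n


def train(model: CNN3DEEG, X: np.ndarray, y: np.ndarray,
          cfg: TrainConfig | None = None):
    """Adam + cross-entropy training with per-epoch accuracy/loss traces.

    A stratified ``val_fraction`` split monitors convergence; it is skipped
    (with a warning) when the set is too small to stratify.  Returns
    ``(model, traces)`` where traces holds ``train_loss``, ``train_acc`` and,
    when a validation split exists, ``val_loss``/``val_acc``.
    """
    cfg = cfg or TrainConfig()
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    classes, yidx = np.unique(y, return_inverse=True)
    if len(classes) > model.cfg.n_classes:
        raise ValueError(f"{len(classes)} classes exceed the model's "
                         f"{model.cfg.n_classes} outputs")
    model.classes_ = classes
    rng = np.random.default_rng(cfg.seed)
    for l in model._all_layers():
        if isinstance(l, Dropout):
            l.rng = rng

    n_val = int(round(cfg.val_fraction * len(X)))
    if cfg.val_fraction > 0 and n_val >= len(classes):
        tr, va = train_test_split(np.arange(len(X)), test_size=cfg.val_fraction,
                                  stratify=yidx, random_state=cfg.seed)
    else:
        if cfg.val_fraction > 0:
            warnings.warn("training set too small for a stratified validation "
                          "split; monitoring on the training set only",
                          RuntimeWarning, stacklevel=2)
        tr, va = np.arange(len(X)), np.array([], dtype=int)

    opt = Adam(model.params(), model.grads(), lr=cfg.learning_rate)
    traces = {"train_loss": [], "train_acc": [], "val_loss": [], "val_acc": []}

    # standardise inputs once (per-feature scale helps Adam on microvolt data)
    for _epoch in range(cfg.epochs):
        order = rng.permutation(tr) if cfg.shuffle else tr
        losses, hits, seen = [], 0, 0
        for i in range(0, len(order), cfg.batch_size):
            idx = order[i:i + cfg.batch_size]
            logits = model.forward(X[idx], train=True)
            loss, g = _xent(logits, yidx[idx])
            if not np.isfinite(loss):
                raise RuntimeError(f"NaN/inf loss at epoch {_epoch}; "
                                   "lower the learning rate or rescale inputs")
            model.backward(g)
            opt.step()
            losses.append(loss * len(idx))
            hits += int((np.argmax(logits, axis=1) == yidx[idx]).sum())
            seen += len(idx)
        traces["train_loss"].append(float(np.sum(losses) / seen))
        traces["train_acc"].append(hits / seen)
        if len(va):
            logits = model.forward(X[va], train=False)
            loss, _ = _xent(logits, yidx[va])
            traces["val_loss"].append(loss)
            traces["val_acc"].append(
                float((np.argmax(logits, axis=1) == yidx[va]).mean()))
    return model, traces


def cohen_kappa(confusion: np.ndarray) -> float:
    """Chance-corrected agreement (p_o - p_e) / (1 - p_e) from counts."""
    cm = np.asarray(confusion, dtype=float)
    if (cm < 0).any() or cm.sum() <= 0:
        raise ValueError("confusion matrix must be non-negative with a "
                         "positive total")
    total = cm.sum()
    p_o = np.trace(cm) / total
    p_e = float((cm.sum(axis=1) / total) @ (cm.sum(axis=0) / total))
    if np.isclose(p_e, 1.0):
        warnings.warn("degenerate confusion matrix (expected agreement 1); "
                      "kappa defined as 0", RuntimeWarning, stacklevel=2)
        return 0.0
    return float((p_o - p_e) / (1.0 - p_e))


def evaluate(model: CNN3DEEG, X: np.ndarray, y: np.ndarray) -> Metrics:
    """Accuracy, Cohen's kappa and the confusion-count matrix on a test set."""
    y = np.asarray(y)
    if len(y) == 0:
        raise ValueError("empty test set")
    pred = model.predict(np.asarray(X, dtype=float))
    classes = model.classes_ if model.classes_ is not None else np.unique(y)
    k = len(classes)
    lookup = {int(c): i for i, c in enumerate(classes)}
    cm = np.zeros((k, k), dtype=int)
    for t, p in zip(y, pred):
        cm[lookup[int(t)], lookup[int(p)]] += 1
    return Metrics(accuracy=float((pred == y).mean()),
                   kappa=cohen_kappa(cm), confusion=cm)
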