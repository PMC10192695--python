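"""Image-stack rendering and convolutional classification of segments.

Each 10 s segment becomes a 23-channel stack of Hilbert-spectrum images
(frequency x time, min-max normalized per segment).  Stacks are classified
by a small convolutional network: two conv/ReLU/max-pool blocks (32 and 64
filters of size 3 x 3, 2 x 2 pooling), dropout, a dense hidden layer and a
two-way softmax, trained with the Adam optimizer on an 80/20 split.

The network is implemented directly on numpy arrays (im2col convolutions,
hand-written backward passes and Adam updates); training is deterministic
for a fixed configuration seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .defaults import N_CHANNELS


@dataclass
class SpectrogramStack:
    """Per-segment image stack: (23, n_freq, n_time) in [0, 1]."""

    tensor: np.ndarray
    label: str = "unknown"

    def __post_init__(self):
        t = np.asarray(self.tensor, dtype=np.float32)
        if t.ndim != 3:
            raise ValueError("stack tensor must be 3-D (channels, freq, time)")
        self.tensor = t


@dataclass
class ClassifierConfig:
    """Architecture and training settings (see module docstring)."""

    conv_filters: tuple = (32, 64)
    kernel_size: int = 3
    pool_size: int = 2
    dense_units: int = 64
    dropout: float = 0.5
    learning_rate: float = 1e-3
    epochs: int = 15
    batch_size: int = 16
    split_fraction: float = 0.8
    input_pool: int = 2   # average-pool factor applied to stacks before training
    seed: int = 0

    def __post_init__(self):
        if not (0 < self.split_fraction < 1):
            raise ValueError("split_fraction must be in (0, 1)")
        if not (0 <= self.dropout < 1):
            raise ValueError("dropout must be in [0, 1)")


@dataclass
class EvalMetrics:
    """Binary-classification summary at a fixed decision threshold.

    ``auc`` is threshold-free: the probability that a random positive
    outscores a random negative (ties count one half).
    """

    sensitivity: float
    specificity: float
    accuracy: float
    f1: float
    auc: float
    tp: int
    fp: int
    tn: int
    fn: int


LABEL_TO_CLASS = {"interictal": 0, "ictal": 1}


def render_stack(spectra: list, label: str = "unknown",
                 tile: bool = False) -> SpectrogramStack:
    """Stack 23 per-channel Hilbert spectra into one normalized tensor.

    Requires exactly 23 spectra on identical grids; images are oriented
    frequency x time and the whole stack is min-max normalized globally
    (an all-constant stack maps to zeros).  By default channels occupy a
    depth axis, preserving per-channel topology; ``tile=True`` instead
    concatenates the images vertically into a single-channel image.
    """
    if len(spectra) != N_CHANNELS:
        raise ValueError(f"expected {N_CHANNELS} spectra, got {len(spectra)}")
    ref = spectra[0]
    for hs in spectra[1:]:
        if hs.grid.shape != ref.grid.shape \
                or not np.array_equal(hs.freq_edges, ref.freq_edges) \
                or not np.array_equal(hs.time_edges, ref.time_edges):
            raise ValueError("all channel spectra must share one grid")
    tensor = np.stack([hs.grid.T for hs in spectra])  # (ch, freq, time)
    lo, hi = tensor.min(), tensor.max()
    tensor = (tensor - lo) / (hi - lo) if hi > lo else np.zeros_like(tensor)
    if tile:
        tensor = tensor.reshape(1, -1, tensor.shape[2])
    return SpectrogramStack(tensor=tensor.astype(np.float32), label=label)


# ---------------------------------------------------------------------------
# numpy CNN internals
# ---------------------------------------------------------------------------

def _im2col(x: np.ndarray, k: int):
    """(B, C, H, W) -> (B, H', W', C*k*k) patches for a valid k x k conv."""
    b, c, h, w = x.shape
    win = np.lib.stride_tricks.sliding_window_view(x, (k, k), axis=(2, 3))
    # win: (B, C, H', W', k, k) -> (B, H', W', C*k*k)
    return np.ascontiguousarray(win.transpose(0, 2, 3, 1, 4, 5)).reshape(
        b, h - k + 1, w - k + 1, c * k * k)


class _Conv:
    def __init__(self, c_in, c_out, k, rng):
        scale = np.sqrt(2.0 / (c_in * k * k))
        self.w = (rng.standard_normal((c_in * k * k, c_out)) * scale).astype(np.float32)
        self.b = np.zeros(c_out, dtype=np.float32)
        self.k = k
        self.c_in = c_in

    def forward(self, x):
        self.x_shape = x.shape
        self.cols = _im2col(x, self.k)
        out = self.cols @ self.w + self.b  # (B, H', W', c_out)
        return out.transpose(0, 3, 1, 2)

    def backward(self, grad):
        # grad: (B, c_out, H', W')
        g = grad.transpose(0, 2, 3, 1)
        b, hp, wp, c_out = g.shape
        cols2d = self.cols.reshape(-1, self.w.shape[0])
        g2d = g.reshape(-1, c_out)
        self.gw = cols2d.T @ g2d
        self.gb = g2d.sum(axis=0)
        gcols = (g2d @ self.w.T).reshape(b, hp, wp, self.c_in, self.k, self.k)
        gx = np.zeros(self.x_shape, dtype=np.float32)
        for di in range(self.k):
            for dj in range(self.k):
                gx[:, :, di:di + hp, dj:dj + wp] += gcols[:, :, :, :, di, dj].transpose(0, 3, 1, 2)
        return gx

    def params(self):
        return [(self.w, "gw"), (self.b, "gb")]


class _ReLU:
    def forward(self, x):
        self.mask = x > 0
        return x * self.mask

    def backward(self, grad):
        return grad * self.mask


class _MaxPool:
    def __init__(self, size=2):
        self.s = size

    def forward(self, x):
        s = self.s
        b, c, h, w = x.shape
        hp, wp = h // s, w // s
        self.x_shape = x.shape
        xt = x[:, :, :hp * s, :wp * s].reshape(b, c, hp, s, wp, s)
        xt = xt.transpose(0, 1, 2, 4, 3, 5).reshape(b, c, hp, wp, s * s)
        self.arg = xt.argmax(axis=-1)
        return xt.max(axis=-1)

    def backward(self, grad):
        s = self.s
        b, c, hp, wp = grad.shape
        gx = np.zeros((b, c, hp, wp, s * s), dtype=np.float32)
        np.put_along_axis(gx, self.arg[..., None], grad[..., None], axis=-1)
        gx = gx.reshape(b, c, hp, wp, s, s).transpose(0, 1, 2, 4, 3, 5)
        out = np.zeros(self.x_shape, dtype=np.float32)
        out[:, :, :hp * s, :wp * s] = gx.reshape(b, c, hp * s, wp * s)
        return out


class _Dense:
    def __init__(self, n_in, n_out, rng):
        scale = np.sqrt(2.0 / n_in)
        self.w = (rng.standard_normal((n_in, n_out)) * scale).astype(np.float32)
        self.b = np.zeros(n_out, dtype=np.float32)

    def forward(self, x):
        self.x = x
        return x @ self.w + self.b

    def backward(self, grad):
        self.gw = self.x.T @ grad
        self.gb = grad.sum(axis=0)
        return grad @ self.w.T

    def params(self):
        return [(self.w, "gw"), (self.b, "gb")]


class _Adam:
    def __init__(self, layers, lr=1e-3, beta1=0.9, beta2=0.999, eps=1e-8):
        self.entries = []
        for layer in layers:
            if hasattr(layer, "params"):
                for param, gname in layer.params():
                    self.entries.append([layer, param, gname,
                                         np.zeros_like(param), np.zeros_like(param)])
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.t = 0

    def step(self):
        self.t += 1
        for entry in self.entries:
            layer, param, gname, m, v = entry
            g = getattr(layer, gname)
            m[:] = self.b1 * m + (1 - self.b1) * g
            v[:] = self.b2 * v + (1 - self.b2) * g * g
            mhat = m / (1 - self.b1 ** self.t)
            vhat = v / (1 - self.b2 ** self.t)
            param -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


def _avg_pool_input(x: np.ndarray, s: int) -> np.ndarray:
    if s <= 1:
        return x
    b, c, h, w = x.shape
    hp, wp = h // s, w // s
    return x[:, :, :hp * s, :wp * s].reshape(b, c, hp, s, wp, s).mean(axis=(3, 5))


class TrainedClassifier:
    """Handle to a trained network plus its train/test split."""

    def __init__(self, layers, cfg, train_idx, test_idx):
        self._layers = layers
        self.config = cfg
        self.train_indices = train_idx
        self.test_indices = test_idx

    def _forward(self, x):
        for layer in self._layers:
            x = layer.forward(x)
        return x

    def predict_proba(self, stacks: list) -> np.ndarray:
        """Class-1 (ictal) probability per stack."""
        x = np.stack([s.tensor for s in stacks]).astype(np.float32)
        x = _avg_pool_input(x, self.config.input_pool)
        out = []
        for i in range(0, len(x), 64):
            logits = self._forward(x[i:i + 64])
            e = np.exp(logits - logits.max(axis=1, keepdims=True))
            out.append((e / e.sum(axis=1, keepdims=True))[:, 1])
        return np.concatenate(out)


def _build_layers(input_shape, cfg, rng):
    c, h, w = input_shape
    layers = []
    c_in = c
    for c_out in cfg.conv_filters:
        layers += [_Conv(c_in, c_out, cfg.kernel_size, rng), _ReLU(),
                   _MaxPool(cfg.pool_size)]
        h = (h - cfg.kernel_size + 1) // cfg.pool_size
        w = (w - cfg.kernel_size + 1) // cfg.pool_size
        c_in = c_out
    n_flat = c_in * h * w
    dense1 = _Dense(n_flat, cfg.dense_units, rng)
    dense2 = _Dense(cfg.dense_units, 2, rng)
    return layers, dense1, dense2, n_flat


def train_classifier(stacks: list, cfg: ClassifierConfig = ClassifierConfig()) -> TrainedClassifier:
    """Train the network on a seeded stratified 80/20 split of the stacks.

    Needs at least two examples per class.  Returns a handle whose
    ``test_indices`` mark the held-out 20%.
    """
    labels = np.array([LABEL_TO_CLASS.get(s.label, -1) for s in stacks])
    if np.any(labels < 0):
        raise ValueError("all stacks must be labeled ictal or interictal")
    classes, counts = np.unique(labels, return_counts=True)
    if len(classes) < 2:
        raise ValueError("need both classes present")
    if counts.min() < 2:
        raise ValueError("need >= 2 examples per class")

    rng = np.random.default_rng(cfg.seed)
    train_idx, test_idx = [], []
    for cls in classes:
        idx = np.where(labels == cls)[0]
        idx = idx[rng.permutation(len(idx))]
        n_train = max(1, int(round(cfg.split_fraction * len(idx))))
        n_train = min(n_train, len(idx) - 1)  # keep at least one held out
        train_idx.extend(idx[:n_train])
        test_idx.extend(idx[n_train:])
    train_idx = np.array(sorted(train_idx))
    test_idx = np.array(sorted(test_idx))

    x_all = np.stack([s.tensor for s in stacks]).astype(np.float32)
    x_all = _avg_pool_input(x_all, cfg.input_pool)
    x_train, y_train = x_all[train_idx], labels[train_idx]

    conv_layers, dense1, dense2, _ = _build_layers(x_all.shape[1:], cfg, rng)
    relu_d = _ReLU()
    all_layers = conv_layers + [dense1, relu_d, dense2]
    opt = _Adam(all_layers, lr=cfg.learning_rate)

    n = len(x_train)
    for _epoch in range(cfg.epochs):
        order = rng.permutation(n)
        for start in range(0, n, cfg.batch_size):
            sel = order[start:start + cfg.batch_size]
            xb, yb = x_train[sel], y_train[sel]
            h = xb
            for layer in conv_layers:
                h = layer.forward(h)
            shape_conv = h.shape
            h = h.reshape(len(xb), -1)
            if cfg.dropout > 0:
                mask = (rng.random(h.shape) >= cfg.dropout) / (1 - cfg.dropout)
                h = h * mask
            else:
                mask = None
            h1 = relu_d.forward(dense1.forward(h))
            logits = dense2.forward(h1)
            # softmax cross-entropy
            e = np.exp(logits - logits.max(axis=1, keepdims=True))
            p = e / e.sum(axis=1, keepdims=True)
            grad = p.copy()
            grad[np.arange(len(yb)), yb] -= 1.0
            grad = (grad / len(yb)).astype(np.float32)
            g = dense1.backward(relu_d.backward(dense2.backward(grad)))
            if mask is not None:
                g = g * mask
            g = g.reshape(shape_conv).astype(np.float32)
            for layer in reversed(conv_layers):
                g = layer.backward(g)
            opt.step()

    # inference-mode layer list: conv stack, flatten, dense1, relu, dense2
    class _Flatten:
        def forward(self, x):
            return x.reshape(len(x), -1)

    layers = conv_layers + [_Flatten(), dense1, relu_d, dense2]
    return TrainedClassifier(layers, cfg, train_idx, test_idx)


def evaluate_holdout(model: TrainedClassifier, stacks: list,
                     threshold: float = 0.5) -> EvalMetrics:
    """Metrics of the model on its own held-out split."""
    held = [stacks[i] for i in model.test_indices]
    scores = model.predict_proba(held)
    labels = np.array([LABEL_TO_CLASS[s.label] for s in held])
    return compute_metrics(scores, labels, threshold=threshold)


def compute_metrics(scores, labels, threshold: float = 0.5) -> EvalMetrics:
    """Confusion counts at the threshold plus rank-based AUC.

    AUC is the normalized Mann-Whitney statistic over all positive/negative
    pairs with ties counting one half; it requires both classes present.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if scores.shape != labels.shape:
        raise ValueError("scores and labels must have the same length")
    pos = labels == 1
    neg = labels == 0
    n_pos, n_neg = int(pos.sum()), int(neg.sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC undefined: both classes must be present")

    pred = scores >= threshold
    tp = int(np.sum(pred & pos))
    fp = int(np.sum(pred & neg))
    tn = int(np.sum(~pred & neg))
    fn = int(np.sum(~pred & pos))

    from scipy.stats import rankdata
    ranks = rankdata(scores)
    auc = (ranks[pos].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg)

    sens = tp / (tp + fn)
    spec = tn / (tn + fp)
    acc = (tp + tn) / (tp + tn + fp + fn)
    f1 = 2 * tp / (2 * tp + fp + fn) if (2 * tp + fp + fn) > 0 else 0.0
    return EvalMetrics(sensitivity=sens, specificity=spec, accuracy=acc,
                       f1=f1, auc=float(auc), tp=tp, fp=fp, tn=tn, fn=fn)
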