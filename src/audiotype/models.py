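"""Sequence classifiers for encoded audiograms.

Two model families are provided:

* A recurrent network, authored here in numpy with explicit
  backpropagation-through-time: the 7-step, 2-channel feature sequence feeds
  a first recurrent layer — bidirectional LSTM in the proposed variant, plain
  LSTM in the initial one — followed by dropout, a second (unidirectional)
  LSTM layer, dropout, and a dense softmax head over the four diagnostic
  classes.  Training minimises class-weighted cross-entropy with Adam,
  mini-batches, and early stopping on a held-out validation split.  Every
  stochastic element (initialisation, shuffling, dropout masks, the
  validation split) is driven by one seeded generator, so a fixed
  (data, config, seed) triple reproduces predictions bit-for-bit on one
  machine.

* A gain-ratio decision tree over the flat 12-dimensional threshold vector
  (7 air + 5 bone), the classical top-down induction used by C4.5-style
  learners: candidate thresholds are midpoints of sorted distinct feature
  values, splits maximise information gain divided by split information,
  leaves take the majority label (ties broken in fixed class order).
  Pruning is off by default.

Probability rows always lie on the simplex; argmax ties resolve in the fixed
class order (normal, conductive, mixed, sensorineural).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit as _sigmoid

from .core import CLINICAL_LABELS, HearingLossLabel
from .preprocessing import ClassWeights

__all__ = [
    "ModelConfig",
    "TreeConfig",
    "SequenceModel",
    "TreeModel",
    "train_sequence_model",
    "train_tree_baseline",
    "predict_proba",
    "predict_label",
    "labels_to_indices",
    "indices_to_labels",
]


def labels_to_indices(labels) -> np.ndarray:
    return np.array([CLINICAL_LABELS.index(lab) for lab in labels], dtype=int)


def indices_to_labels(idx) -> list[HearingLossLabel]:
    return [CLINICAL_LABELS[int(i)] for i in idx]


# ---------------------------------------------------------------------------
# Recurrent network
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ModelConfig:
    """Hyperparameters of the recurrent classifier.

    Defaults are conventional for a 7-step, 2-channel sequence: 64 recurrent
    units in the (bi)directional first layer, 32 in the second, dropout 0.2
    after each, Adam at 1e-3, batches of 32, up to 150 epochs with early
    stopping (patience 10 on validation loss).
    """

    architecture: str = "bilstm"  # "bilstm" | "lstm"
    units1: int = 64
    units2: int = 32
    dropout1: float = 0.2
    dropout2: float = 0.2
    learning_rate: float = 1e-3
    batch_size: int = 32
    max_epochs: int = 150
    patience: int = 10
    val_fraction: float = 0.1
    n_classes: int = 4
    seed: int = 0

    def __post_init__(self) -> None:
        if self.architecture not in ("bilstm", "lstm"):
            raise ValueError(f"architecture must be bilstm|lstm, got {self.architecture!r}")
        if not (0.0 <= self.dropout1 < 1.0 and 0.0 <= self.dropout2 < 1.0):
            raise ValueError("dropout rates must lie in [0, 1)")
        if self.n_classes != 4:
            raise ValueError("the classifier is defined over the 4 clinical classes")


def _glorot(rng: np.random.Generator, shape: tuple[int, int]) -> np.ndarray:
    lim = math.sqrt(6.0 / (shape[0] + shape[1]))
    return rng.uniform(-lim, lim, shape)


class _LSTMCell:
    """One direction of an LSTM layer; gate order i, f, g, o."""

    def __init__(self, d_in: int, d_hidden: int, rng: np.random.Generator):
        h = d_hidden
        self.h = h
        self.Wx = _glorot(rng, (d_in, 4 * h))
        self.Wh = _glorot(rng, (h, 4 * h))
        self.b = np.zeros(4 * h)
        self.b[h:2 * h] = 1.0  # forget-gate bias
        self.zero_grads()

    def params(self):
        return [self.Wx, self.Wh, self.b]

    def grads(self):
        return [self.dWx, self.dWh, self.db]

    def zero_grads(self):
        self.dWx = np.zeros_like(self.Wx)
        self.dWh = np.zeros_like(self.Wh)
        self.db = np.zeros_like(self.b)

    def forward(self, X: np.ndarray):
        """X: (B, T, D) → H_seq (B, T, h) plus cache for backprop."""
        B, T, _ = X.shape
        h = self.h
        h_t = np.zeros((B, h))
        c_t = np.zeros((B, h))
        H_seq = np.empty((B, T, h))
        cache = []
        for t in range(T):
            x_t = X[:, t, :]
            z = x_t @ self.Wx + h_t @ self.Wh + self.b
            i = _sigmoid(z[:, :h])
            f = _sigmoid(z[:, h:2 * h])
            g = np.tanh(z[:, 2 * h:3 * h])
            o = _sigmoid(z[:, 3 * h:])
            c_prev = c_t
            c_t = f * c_prev + i * g
            tc = np.tanh(c_t)
            h_prev = h_t
            h_t = o * tc
            H_seq[:, t, :] = h_t
            cache.append((x_t, h_prev, c_prev, i, f, g, o, tc))
        return H_seq, cache

    def backward(self, cache, dH_seq: np.ndarray) -> np.ndarray:
        """dH_seq: (B, T, h) gradients w.r.t. each output step → dX."""
        B, T, _ = dH_seq.shape
        h = self.h
        dX = np.empty((B, T, self.Wx.shape[0]))
        dh_next = np.zeros((B, h))
        dc_next = np.zeros((B, h))
        for t in range(T - 1, -1, -1):
            x_t, h_prev, c_prev, i, f, g, o, tc = cache[t]
            dh = dH_seq[:, t, :] + dh_next
            do = dh * tc
            dc = dc_next + dh * o * (1.0 - tc * tc)
            di = dc * g
            df = dc * c_prev
            dg = dc * i
            dz = np.concatenate([
                di * i * (1.0 - i),
                df * f * (1.0 - f),
                dg * (1.0 - g * g),
                do * o * (1.0 - o),
            ], axis=1)
            self.dWx += x_t.T @ dz
            self.dWh += h_prev.T @ dz
            self.db += dz.sum(axis=0)
            dX[:, t, :] = dz @ self.Wx.T
            dh_next = dz @ self.Wh.T
            dc_next = dc * f
        return dX


class _Adam:
    def __init__(self, params: list[np.ndarray], lr: float):
        self.params = params
        self.lr = lr
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads: list[np.ndarray]) -> None:
        self.t += 1
        b1, b2, eps = 0.9, 0.999, 1e-8
        lr_t = self.lr * math.sqrt(1 - b2 ** self.t) / (1 - b1 ** self.t)
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            p -= lr_t * m / (np.sqrt(v) + eps)


def _softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


class SequenceModel:
    """Trained recurrent classifier.  Build via :func:`train_sequence_model`."""

    def __init__(self, cfg: ModelConfig, d_in: int, rng: np.random.Generator):
        self.cfg = cfg
        self.d_in = d_in
        h1, h2 = cfg.units1, cfg.units2
        self.cell_fw = _LSTMCell(d_in, h1, rng)
        self.cell_bw = _LSTMCell(d_in, h1, rng) if cfg.architecture == "bilstm" else None
        d_mid = 2 * h1 if self.cell_bw is not None else h1
        self.cell2 = _LSTMCell(d_mid, h2, rng)
        self.Wd = _glorot(rng, (h2, cfg.n_classes))
        self.bd = np.zeros(cfg.n_classes)
        self.history: dict = {}

    # -- parameter plumbing ------------------------------------------------

    def _cells(self):
        cells = [self.cell_fw]
        if self.cell_bw is not None:
            cells.append(self.cell_bw)
        cells.append(self.cell2)
        return cells

    def parameters(self) -> list[np.ndarray]:
        out: list[np.ndarray] = []
        for c in self._cells():
            out.extend(c.params())
        out.extend([self.Wd, self.bd])
        return out

    def get_weights(self) -> list[np.ndarray]:
        return [p.copy() for p in self.parameters()]

    def set_weights(self, weights: list[np.ndarray]) -> None:
        for p, w in zip(self.parameters(), weights):
            p[...] = w

    # -- forward / backward ------------------------------------------------

    def _forward(self, X: np.ndarray, drop_rng: np.random.Generator | None = None):
        """Full forward pass; dropout active iff drop_rng is given."""
        H1, cache_fw = self.cell_fw.forward(X)
        cache_bw = None
        if self.cell_bw is not None:
            Hb, cache_bw = self.cell_bw.forward(X[:, ::-1, :])
            H1 = np.concatenate([H1, Hb[:, ::-1, :]], axis=2)
        mask1 = None
        if drop_rng is not None and self.cfg.dropout1 > 0:
            keep = 1.0 - self.cfg.dropout1
            mask1 = (drop_rng.random(H1.shape) < keep) / keep
            H1 = H1 * mask1
        H2, cache2 = self.cell2.forward(H1)
        h_last = H2[:, -1, :]
        mask2 = None
        if drop_rng is not None and self.cfg.dropout2 > 0:
            keep = 1.0 - self.cfg.dropout2
            mask2 = (drop_rng.random(h_last.shape) < keep) / keep
            h_last = h_last * mask2
        logits = h_last @ self.Wd + self.bd
        cache = (X, cache_fw, cache_bw, mask1, cache2, h_last, mask2)
        return logits, cache

    def _backward(self, cache, dlogits: np.ndarray) -> None:
        X, cache_fw, cache_bw, mask1, cache2, h_last, mask2 = cache
        self.dWd = h_last.T @ dlogits
        self.dbd = dlogits.sum(axis=0)
        dh_last = dlogits @ self.Wd.T
        if mask2 is not None:
            dh_last = dh_last * mask2
        B, T, _ = X.shape
        dH2 = np.zeros((B, T, self.cfg.units2))
        dH2[:, -1, :] = dh_last
        dH1 = self.cell2.backward(cache2, dH2)
        if mask1 is not None:
            dH1 = dH1 * mask1
        if self.cell_bw is not None:
            h1 = self.cfg.units1
            self.cell_fw.backward(cache_fw, dH1[:, :, :h1])
            self.cell_bw.backward(cache_bw, dH1[:, ::-1, h1:])
        else:
            self.cell_fw.backward(cache_fw, dH1)

    def _grads(self) -> list[np.ndarray]:
        out: list[np.ndarray] = []
        for c in self._cells():
            out.extend(c.grads())
        out.extend([self.dWd, self.dbd])
        return out

    def _zero_grads(self) -> None:
        for c in self._cells():
            c.zero_grads()

    def loss_and_grad(
        self, X: np.ndarray, y: np.ndarray, sample_w: np.ndarray,
        drop_rng: np.random.Generator | None = None,
    ) -> float:
        """Mean weighted cross-entropy on one batch; gradients accumulated."""
        self._zero_grads()
        logits, cache = self._forward(X, drop_rng)
        proba = _softmax(logits)
        n = X.shape[0]
        eps = 1e-12
        loss = float(np.mean(sample_w * -np.log(proba[np.arange(n), y] + eps)))
        dlogits = proba.copy()
        dlogits[np.arange(n), y] -= 1.0
        dlogits *= (sample_w / n)[:, None]
        self._backward(cache, dlogits)
        if not math.isfinite(loss):
            raise RuntimeError("non-finite training loss")
        return loss

    # -- inference ---------------------------------------------------------

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        """(n, 7, channels) → (n, 4) rows on the probability simplex."""
        X = np.asarray(X, dtype=float)
        if X.ndim != 3 or X.shape[1] != 7 or X.shape[2] != self.d_in:
            raise ValueError(f"expected (n, 7, {self.d_in}) input, got {X.shape}")
        out = np.empty((X.shape[0], self.cfg.n_classes))
        for start in range(0, X.shape[0], 1024):
            logits, _ = self._forward(X[start:start + 1024])
            out[start:start + 1024] = _softmax(logits)
        return out

    def predict_label(self, X: np.ndarray) -> list[HearingLossLabel]:
        return indices_to_labels(_argmax_fixed_order(self.predict_proba(X)))


def _argmax_fixed_order(proba: np.ndarray) -> np.ndarray:
    # np.argmax returns the first maximal index, which is exactly the fixed
    # class-order tie rule (normal < conductive < mixed < sensorineural)
    return np.argmax(proba, axis=1)


def _stratified_val_split(y: np.ndarray, frac: float, rng: np.random.Generator):
    train_idx, val_idx = [], []
    for c in np.unique(y):
        idx = np.flatnonzero(y == c)
        idx = idx[rng.permutation(len(idx))]
        n_val = int(round(frac * len(idx)))
        val_idx.extend(idx[:n_val])
        train_idx.extend(idx[n_val:])
    return np.sort(np.array(train_idx, dtype=int)), np.sort(np.array(val_idx, dtype=int))


def train_sequence_model(
    X: np.ndarray,
    labels,
    weights: ClassWeights | None,
    cfg: ModelConfig,
) -> SequenceModel:
    """Train the recurrent classifier on encoded, normalised sequences.

    *X* is (n, 7, channels); *labels* are clinical class labels (or integer
    indices in fixed class order).  *weights* scales each sample's loss by
    its class weight; None trains unweighted.  Returns the fitted model with
    ``model.history`` holding epochs run and loss curves.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 3 or X.shape[1] != 7:
        raise ValueError(f"expected (n, 7, channels) input, got {X.shape}")
    y = np.asarray(labels) if np.asarray(labels).dtype.kind == "i" \
        else labels_to_indices(labels)
    if len(y) != X.shape[0]:
        raise ValueError("labels length does not match input")
    if not np.isfinite(X).all():
        raise ValueError("non-finite values in input sequences")

    rng = np.random.default_rng(cfg.seed)
    model = SequenceModel(cfg, d_in=X.shape[2], rng=rng)
    w_class = weights.as_array() if weights is not None else np.ones(cfg.n_classes)

    if cfg.val_fraction > 0:
        tr_idx, val_idx = _stratified_val_split(y, cfg.val_fraction, rng)
    else:
        tr_idx, val_idx = np.arange(len(y)), np.array([], dtype=int)
    X_tr, y_tr = X[tr_idx], y[tr_idx]
    X_val, y_val = X[val_idx], y[val_idx]
    w_tr = w_class[y_tr]
    w_val = w_class[y_val] if len(val_idx) else None

    opt = _Adam(model.parameters(), cfg.learning_rate)
    best_val = math.inf
    best_weights = model.get_weights()
    best_epoch = 0
    wait = 0
    train_losses: list[float] = []
    val_losses: list[float] = []
    n_tr = len(y_tr)
    for epoch in range(cfg.max_epochs):
        order = rng.permutation(n_tr)
        epoch_loss = 0.0
        for start in range(0, n_tr, cfg.batch_size):
            b = order[start:start + cfg.batch_size]
            loss = model.loss_and_grad(X_tr[b], y_tr[b], w_tr[b], drop_rng=rng)
            opt.step(model._grads())
            epoch_loss += loss * len(b)
        train_losses.append(epoch_loss / n_tr)

        if len(val_idx):
            proba = model.predict_proba(X_val)
            eps = 1e-12
            val_loss = float(np.mean(
                w_val * -np.log(proba[np.arange(len(y_val)), y_val] + eps)))
            val_losses.append(val_loss)
            if val_loss < best_val - 1e-6:
                best_val = val_loss
                best_weights = model.get_weights()
                best_epoch = epoch
                wait = 0
            else:
                wait += 1
                if wait >= cfg.patience:
                    break
    if len(val_idx):
        model.set_weights(best_weights)
    model.history = {
        "epochs_run": len(train_losses),
        "best_epoch": best_epoch if len(val_idx) else len(train_losses) - 1,
        "train_loss": train_losses,
        "val_loss": val_losses,
        "final_train_loss": train_losses[-1] if train_losses else None,
        "best_val_loss": best_val if len(val_idx) else None,
    }
    return model


def predict_proba(model, X: np.ndarray) -> np.ndarray:
    """Per-sample 4-vector of class probabilities (rows sum to 1)."""
    return model.predict_proba(X)


def predict_label(model, X: np.ndarray) -> list[HearingLossLabel]:
    """Argmax labels; exact ties resolve in fixed class order."""
    return model.predict_label(X)


# ---------------------------------------------------------------------------
# Gain-ratio decision tree
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TreeConfig:
    min_samples_leaf: int = 2
    max_depth: int | None = None
    n_classes: int = 4


@dataclass
class _Node:
    feature: int | None = None
    threshold: float | None = None
    left: "_Node | None" = None
    right: "_Node | None" = None
    counts: np.ndarray | None = None  # class counts at this node


def _entropy(counts: np.ndarray) -> float:
    n = counts.sum()
    if n == 0:
        return 0.0
    p = counts[counts > 0] / n
    return float(-(p * np.log2(p)).sum())


def _best_split(X: np.ndarray, y: np.ndarray, n_classes: int, min_leaf: int):
    """Best (feature, threshold, gain_ratio) over midpoint candidates, or None.

    Gain ratio = information gain / split information; splits with
    non-positive gain are discarded.
    """
    n = len(y)
    parent_counts = np.bincount(y, minlength=n_classes).astype(float)
    h_parent = _entropy(parent_counts)
    if h_parent == 0.0:
        return None
    best = None  # (gain_ratio, gain, feature, threshold)
    onehot = np.eye(n_classes)[y]
    for j in range(X.shape[1]):
        order = np.argsort(X[:, j], kind="stable")
        xs = X[order, j]
        cum = np.cumsum(onehot[order], axis=0)  # (n, K) left counts after i+1
        # candidate boundaries: between distinct consecutive values,
        # respecting the minimum leaf size on both sides
        boundary = np.flatnonzero(xs[1:] > xs[:-1]) + 1  # left size
        boundary = boundary[(boundary >= min_leaf) & (n - boundary >= min_leaf)]
        if boundary.size == 0:
            continue
        left = cum[boundary - 1]
        right = parent_counts - left
        nl = boundary.astype(float)
        nr = n - nl
        with np.errstate(divide="ignore", invalid="ignore"):
            pl = left / nl[:, None]
            pr = right / nr[:, None]
            hl = -np.nansum(np.where(pl > 0, pl * np.log2(pl), 0.0), axis=1)
            hr = -np.nansum(np.where(pr > 0, pr * np.log2(pr), 0.0), axis=1)
        gain = h_parent - (nl / n) * hl - (nr / n) * hr
        fl, fr = nl / n, nr / n
        split_info = -(fl * np.log2(fl) + fr * np.log2(fr))
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = np.where((gain > 1e-12) & (split_info > 0), gain / split_info, -1.0)
        k = int(np.argmax(ratio))
        if ratio[k] <= 0:
            continue
        thr = 0.5 * (xs[boundary[k] - 1] + xs[boundary[k]])
        cand = (float(ratio[k]), float(gain[k]), j, float(thr))
        if best is None or cand[0] > best[0]:
            best = cand
    return best


class TreeModel:
    """Fitted gain-ratio decision tree.  Build via :func:`train_tree_baseline`."""

    def __init__(self, root: _Node, cfg: TreeConfig):
        self.root = root
        self.cfg = cfg

    def _leaf(self, x: np.ndarray) -> _Node:
        node = self.root
        while node.feature is not None:
            node = node.left if x[node.feature] <= node.threshold else node.right
        return node

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        out = np.empty((len(X), self.cfg.n_classes))
        for i, x in enumerate(X):
            counts = self._leaf(x).counts
            out[i] = counts / counts.sum()
        return out

    def predict_label(self, X: np.ndarray) -> list[HearingLossLabel]:
        return indices_to_labels(_argmax_fixed_order(self.predict_proba(X)))

    def depth(self) -> int:
        def _d(node):
            if node.feature is None:
                return 0
            return 1 + max(_d(node.left), _d(node.right))
        return _d(self.root)

    def n_leaves(self) -> int:
        def _n(node):
            if node.feature is None:
                return 1
            return _n(node.left) + _n(node.right)
        return _n(self.root)


def train_tree_baseline(X: np.ndarray, labels, cfg: TreeConfig = TreeConfig()) -> TreeModel:
    """Top-down gain-ratio induction on flat feature vectors.

    Deterministic given the data: candidate thresholds are midpoints of
    sorted distinct values, recursion stops on purity, the minimum leaf
    size, the depth limit, or when no split has positive gain.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or len(X) == 0:
        raise ValueError("X must be a non-empty (n, d) array")
    if not np.isfinite(X).all():
        raise ValueError("tree features must be finite")
    y = np.asarray(labels) if np.asarray(labels).dtype.kind == "i" \
        else labels_to_indices(labels)

    def grow(idx: np.ndarray, depth: int) -> _Node:
        counts = np.bincount(y[idx], minlength=cfg.n_classes).astype(float)
        node = _Node(counts=counts)
        if cfg.max_depth is not None and depth >= cfg.max_depth:
            return node
        best = _best_split(X[idx], y[idx], cfg.n_classes, cfg.min_samples_leaf)
        if best is None:
            return node
        _, _, j, thr = best
        mask = X[idx, j] <= thr
        node.feature, node.threshold = j, thr
        node.left = grow(idx[mask], depth + 1)
        node.right = grow(idx[~mask], depth + 1)
        return node

    return TreeModel(grow(np.arange(len(y)), 0), cfg)


# ---------------------------------------------------------------------------
# Persistence
# ---------------------------------------------------------------------------

def save_model(model, outdir, normalizer=None) -> None:
    """Persist a trained model (and optionally its fitted normaliser) to a
    directory for exact reload: weights/tree plus config and seed."""
    import json
    from dataclasses import asdict
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if isinstance(model, SequenceModel):
        np.savez(outdir / "weights.npz",
                 **{f"p{i}": p for i, p in enumerate(model.parameters())})
        meta = {"kind": "sequence", "d_in": model.d_in, "config": asdict(model.cfg)}
    elif isinstance(model, TreeModel):
        def node_dict(n: _Node):
            d: dict = {"counts": n.counts.tolist()}
            if n.feature is not None:
                d.update(feature=n.feature, threshold=n.threshold,
                         left=node_dict(n.left), right=node_dict(n.right))
            return d
        (outdir / "tree.json").write_text(json.dumps(node_dict(model.root)))
        meta = {"kind": "tree", "config": asdict(model.cfg)}
    else:
        raise TypeError(f"cannot save model of type {type(model)}")
    if normalizer is not None:
        meta["normalizer"] = {
            "method": normalizer.method,
            "center": normalizer.center.tolist(),
            "scale": normalizer.scale.tolist(),
            "pooled": normalizer.pooled,
        }
    (outdir / "model.json").write_text(json.dumps(meta, indent=2))


def load_model(outdir):
    """Reload a model saved by :func:`save_model`; returns
    (model, normalizer-or-None)."""
    import json
    from pathlib import Path

    from .preprocessing import NormalizerParams

    outdir = Path(outdir)
    meta = json.loads((outdir / "model.json").read_text())
    norm = None
    if "normalizer" in meta:
        nz = meta["normalizer"]
        norm = NormalizerParams(method=nz["method"], center=np.asarray(nz["center"]),
                                scale=np.asarray(nz["scale"]), pooled=nz["pooled"])
    if meta["kind"] == "sequence":
        cfg = ModelConfig(**meta["config"])
        model = SequenceModel(cfg, d_in=meta["d_in"],
                              rng=np.random.default_rng(cfg.seed))
        with np.load(outdir / "weights.npz") as data:
            model.set_weights([data[f"p{i}"] for i in range(len(model.parameters()))])
        return model, norm
    if meta["kind"] == "tree":
        def build(d: dict) -> _Node:
            node = _Node(counts=np.asarray(d["counts"], dtype=float))
            if "feature" in d:
                node.feature = d["feature"]
                node.threshold = d["threshold"]
                node.left = build(d["left"])
                node.right = build(d["right"])
            return node
        root = build(json.loads((outdir / "tree.json").read_text()))
        return TreeModel(root, TreeConfig(**meta["config"])), norm
    raise ValueError(f"unknown model kind {meta['kind']!r}")


def audiograms_to_flat_features(records) -> np.ndarray:
    """Flat 12-dim vectors (7 air + 5 bone) for the tree baseline; an absent
    bone threshold falls back to the paired air value (zero-gap sentinel),
    and absent 125 Hz air to the 250 Hz value."""
    from .core import AIR_FREQS, BONE_FREQS
    out = np.empty((len(records), 12))
    for i, a in enumerate(records):
        for j, f in enumerate(AIR_FREQS):
            out[i, j] = a.ac.get(f, a.ac.get(250))
        for j, f in enumerate(BONE_FREQS):
            out[i, 7 + j] = a.bc.get(f, a.ac.get(f))
    return out
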