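"""Non-linear node model: a two-branch feed-forward network.

The network joins (a) a dense branch with hidden widths 256/128/64/48/24,
mish activations and alpha-dropout (rate 0.2) after the first three layers,
and (b) a random-Fourier-features projection of the input to 24 dimensions
followed by dense layers 24/24/16.  The concatenated branch outputs feed a
softmax over the node's classes.  Training minimizes categorical
cross-entropy with Adam (learning rate 0.001), batch size 32, a 90/10
train/validation split and early stopping (min_delta 1e-4, patience 40)
within at most 300 epochs.

Implemented directly over numpy with explicit backpropagation; the fitted
model exposes the same ``predict`` surface as the linear splitters.
"""

from __future__ import annotations

import numpy as np

__all__ = ["NeuralSplitter"]

# alpha-dropout constants (negative saturation of the SELU family)
_ALPHA_P = -1.7580993408473766


def _mish(x: np.ndarray) -> np.ndarray:
    return x * np.tanh(np.logaddexp(0.0, x))


def _mish_grad(x: np.ndarray) -> np.ndarray:
    sp = np.logaddexp(0.0, x)
    t = np.tanh(sp)
    sig = 1.0 / (1.0 + np.exp(-np.clip(x, -60, 60)))
    return t + x * (1.0 - t * t) * sig


class _Dense:
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        limit = np.sqrt(6.0 / (n_in + n_out))
        self.W = rng.uniform(-limit, limit, size=(n_in, n_out))
        self.b = np.zeros(n_out)
        self._adam = [np.zeros_like(self.W), np.zeros_like(self.W),
                      np.zeros_like(self.b), np.zeros_like(self.b)]

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return x @ self.W + self.b

    def backward(self, grad: np.ndarray) -> np.ndarray:
        self.dW = self._x.T @ grad
        self.db = grad.sum(axis=0)
        return grad @ self.W.T

    def adam_step(self, lr: float, t: int, beta1=0.9, beta2=0.999, eps=1e-8):
        mW, vW, mb, vb = self._adam
        for m, v, g, p in ((mW, vW, self.dW, self.W), (mb, vb, self.db, self.b)):
            m *= beta1
            m += (1 - beta1) * g
            v *= beta2
            v += (1 - beta2) * g * g
            mhat = m / (1 - beta1**t)
            vhat = v / (1 - beta2**t)
            p -= lr * mhat / (np.sqrt(vhat) + eps)


class _AlphaDropout:
    """Dropout that preserves the self-normalizing mean/variance by mapping
    dropped activations to the negative saturation value."""

    def __init__(self, rate: float):
        self.rate = rate
        q = 1.0 - rate
        self.a = (q + _ALPHA_P**2 * q * rate) ** -0.5
        self.b = -self.a * rate * _ALPHA_P

    def forward(self, x: np.ndarray, rng: np.random.Generator, training: bool) -> np.ndarray:
        if not training or self.rate == 0.0:
            self._mask = None
            return x
        self._mask = rng.random(x.shape) >= self.rate
        return self.a * np.where(self._mask, x, _ALPHA_P) + self.b

    def backward(self, grad: np.ndarray) -> np.ndarray:
        if self._mask is None:
            return grad
        return self.a * grad * self._mask


class NeuralSplitter:
    """Two-branch mish/random-Fourier network used as a non-linear node model."""

    def __init__(
        self,
        hidden=(256, 128, 64, 48, 24),
        rff_dim: int = 24,
        rff_hidden=(24, 24, 16),
        dropout_rate: float = 0.2,
        learning_rate: float = 1e-3,
        batch_size: int = 32,
        max_epochs: int = 300,
        validation_split: float = 0.10,
        min_delta: float = 1e-4,
        patience: int = 40,
        random_state: int | None = None,
    ):
        self.hidden = tuple(hidden)
        self.rff_dim = rff_dim
        self.rff_hidden = tuple(rff_hidden)
        self.dropout_rate = dropout_rate
        self.learning_rate = learning_rate
        self.batch_size = batch_size
        self.max_epochs = max_epochs
        self.validation_split = validation_split
        self.min_delta = min_delta
        self.patience = patience
        self.random_state = random_state

    # ------------------------------------------------------------------
    def _build(self, n_features: int, n_classes: int, rng: np.random.Generator):
        self.dense_ = [_Dense(n_features, self.hidden[0], rng)]
        for a, b in zip(self.hidden[:-1], self.hidden[1:]):
            self.dense_.append(_Dense(a, b, rng))
        self.dropout_ = _AlphaDropout(self.dropout_rate)
        # unit-Gaussian random Fourier features with a fixed per-node seed
        self.rff_W_ = rng.normal(size=(n_features, self.rff_dim))
        self.rff_b_ = rng.uniform(0.0, 2.0 * np.pi, size=self.rff_dim)
        self.rffdense_ = []
        prev = self.rff_dim
        for h in self.rff_hidden:
            self.rffdense_.append(_Dense(prev, h, rng))
            prev = h
        self.out_ = _Dense(self.hidden[-1] + prev, n_classes, rng)

    def _forward(self, X: np.ndarray) -> np.ndarray:
        """Inference pass (dropout disabled)."""
        a = X
        for layer in self.dense_:
            a = _mish(layer.forward(a))
        rff = np.sqrt(2.0 / self.rff_dim) * np.cos(X @ self.rff_W_ + self.rff_b_)
        b = rff
        for layer in self.rffdense_:
            b = _mish(layer.forward(b))
        logits = self.out_.forward(np.concatenate([a, b], axis=1))
        logits = logits - logits.max(axis=1, keepdims=True)
        e = np.exp(logits)
        return e / e.sum(axis=1, keepdims=True)

    def _forward_train(self, X, rng):
        # dropout after layers 1-3 needs masks retained for backprop
        masks = {}
        a = X
        self._pre = []
        for i, layer in enumerate(self.dense_):
            z = layer.forward(a)
            self._pre.append(z)
            a = _mish(z)
            if i < 3:
                drop = _AlphaDropout(self.dropout_rate)
                a = drop.forward(a, rng, True)
                masks[i] = drop
        branch_a = a
        rff = np.sqrt(2.0 / self.rff_dim) * np.cos(X @ self.rff_W_ + self.rff_b_)
        b = rff
        self._pre_rff = []
        for layer in self.rffdense_:
            z = layer.forward(b)
            self._pre_rff.append(z)
            b = _mish(z)
        concat = self.out_.forward(np.concatenate([branch_a, b], axis=1))
        logits = concat - concat.max(axis=1, keepdims=True)
        e = np.exp(logits)
        return e / e.sum(axis=1, keepdims=True), masks

    def _backward(self, probs, onehot, masks):
        nb = probs.shape[0]
        grad = (probs - onehot) / nb
        grad = self.out_.backward(grad)
        ga = grad[:, : self.hidden[-1]]
        gb = grad[:, self.hidden[-1]:]
        for layer, z in zip(reversed(self.rffdense_), reversed(self._pre_rff)):
            gb = layer.backward(gb * _mish_grad(z))
        for i in range(len(self.dense_) - 1, -1, -1):
            if i < 3 and i in masks:
                ga = masks[i].backward(ga)
            ga = self.dense_[i].backward(ga * _mish_grad(self._pre[i]))
        return ga

    # ------------------------------------------------------------------
    def fit(self, X: np.ndarray, y) -> "NeuralSplitter":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        rng = np.random.default_rng(self.random_state)
        self.classes_, y_idx = np.unique(y, return_inverse=True)
        n, d = X.shape
        k = len(self.classes_)
        if k < 2:
            raise ValueError("neural splitter needs at least two classes")
        self._build(d, k, rng)

        perm = rng.permutation(n)
        n_val = max(1, int(round(self.validation_split * n)))
        val_idx, tr_idx = perm[:n_val], perm[n_val:]
        onehot = np.eye(k)[y_idx]
        Xtr, Ytr = X[tr_idx], onehot[tr_idx]
        Xva, Yva = X[val_idx], onehot[val_idx]

        # early stopping mirrors the usual min_delta/patience convention:
        # stop once the validation loss has not improved by more than
        # min_delta for `patience` consecutive epochs, keeping final weights
        best_loss, wait, t = np.inf, 0, 0
        layers = self.dense_ + self.rffdense_ + [self.out_]
        for _epoch in range(self.max_epochs):
            order = rng.permutation(len(tr_idx))
            for start in range(0, len(order), self.batch_size):
                batch = order[start: start + self.batch_size]
                probs, masks = self._forward_train(Xtr[batch], rng)
                self._backward(probs, Ytr[batch], masks)
                t += 1
                for layer in layers:
                    layer.adam_step(self.learning_rate, t)
            val_probs = self._forward(Xva)
            val_loss = -np.mean(np.sum(Yva * np.log(val_probs + 1e-12), axis=1))
            if val_loss < best_loss - self.min_delta:
                best_loss = val_loss
                wait = 0
            else:
                wait += 1
                if wait >= self.patience:
                    break
        return self

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        return self._forward(np.asarray(X, dtype=float))

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.classes_[np.argmax(self.predict_proba(X), axis=1)]

    # -- persistence ---------------------------------------------------
    def to_dict(self) -> dict:
        layers = self.dense_ + self.rffdense_ + [self.out_]
        return {
            "kind": "neural",
            "hidden": list(self.hidden),
            "rff_dim": self.rff_dim,
            "rff_hidden": list(self.rff_hidden),
            "classes": [str(c) for c in self.classes_],
            "rff_W": self.rff_W_.tolist(),
            "rff_b": self.rff_b_.tolist(),
            "weights": [[l.W.tolist(), l.b.tolist()] for l in layers],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "NeuralSplitter":
        obj = cls(hidden=d["hidden"], rff_dim=d["rff_dim"], rff_hidden=d["rff_hidden"])
        obj.classes_ = np.asarray(d["classes"])
        obj.rff_W_ = np.asarray(d["rff_W"], dtype=float)
        obj.rff_b_ = np.asarray(d["rff_b"], dtype=float)
        rng = np.random.default_rng(0)
        obj._build(obj.rff_W_.shape[0], len(obj.classes_), rng)
        layers = obj.dense_ + obj.rffdense_ + [obj.out_]
        for layer, (W, b) in zip(layers, d["weights"]):
            layer.W = np.asarray(W, dtype=float)
            layer.b = np.asarray(b, dtype=float)
        return obj
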