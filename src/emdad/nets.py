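"""Compact feed-forward, recurrent and convolutional classifiers.

These are small, self-contained numpy implementations sized for the
trials x (channels x 8) feature matrices this pipeline produces, with
the hyperparameter surface the evaluation layer expects:

* ``ANNClassifier`` — one hidden layer of logistic-sigmoid units, softmax
  output, trained on a mean-absolute-error objective with an L2 weight
  penalty (a portable stand-in for Bayesian-regularized training).
* ``RNNClassifier`` — an Elman network with hidden-state delays 1:2 and
  tanh units; the flat feature row is presented as a length-8 sequence of
  per-component channel slices, and a linear readout of the final hidden
  state is trained with the same MAE objective.
* ``CNNClassifier`` — two conv blocks (conv, batch norm, leaky ReLU,
  dropout) over the channels x components feature map, two fully
  connected layers and a softmax classification output trained with
  cross-entropy.  Filters larger than the map are clamped to fit.

All three train full- or mini-batch Adam with explicit seeds, so
``fit``/``predict`` are deterministic functions of (data, config, seed).
They follow the scikit-learn estimator calling convention (fit(X, y) /
predict(X)) closely enough for the evaluation layer to treat every
classifier uniformly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


def _one_hot(y: np.ndarray, classes: np.ndarray) -> np.ndarray:
    idx = np.searchsorted(classes, y)
    out = np.zeros((len(y), len(classes)))
    out[np.arange(len(y)), idx] = 1.0
    return out


def _softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def _softmax_backward(p: np.ndarray, dp: np.ndarray) -> np.ndarray:
    # dz_j = p_j * (dp_j - sum_k dp_k p_k)
    return p * (dp - np.sum(dp * p, axis=1, keepdims=True))


class _Adam:
    def __init__(self, params: list, lr: float):
        self.params = params
        self.lr = lr
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads: list) -> None:
        self.t += 1
        b1, b2, eps = 0.9, 0.999, 1e-8
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            mhat = m / (1 - b1 ** self.t)
            vhat = v / (1 - b2 ** self.t)
            p -= self.lr * mhat / (np.sqrt(vhat) + eps)


class ANNClassifier:
    """Single-hidden-layer network: logistic hidden units, softmax output,
    MAE objective with L2 penalty."""

    def __init__(self, hidden: int = 10, epochs: int = 100, lr: float = 0.01,
                 l2: float = 1e-4, seed: int = 0):
        self.hidden = hidden
        self.epochs = epochs
        self.lr = lr
        self.l2 = l2
        self.seed = seed

    def fit(self, X: np.ndarray, y: np.ndarray) -> "ANNClassifier":
        rng = np.random.default_rng(self.seed)
        X = np.asarray(X, dtype=float)
        self.classes_ = np.unique(y)
        Y = _one_hot(np.asarray(y), self.classes_)
        n, d = X.shape
        k = len(self.classes_)
        w1 = rng.normal(0, np.sqrt(1.0 / d), (d, self.hidden))
        b1 = np.zeros(self.hidden)
        w2 = rng.normal(0, np.sqrt(1.0 / self.hidden), (self.hidden, k))
        b2 = np.zeros(k)
        opt = _Adam([w1, b1, w2, b2], self.lr)
        for _ in range(self.epochs):
            h = 1.0 / (1.0 + np.exp(-(X @ w1 + b1)))
            p = _softmax(h @ w2 + b2)
            dp = np.sign(p - Y) / (n * k)
            dz2 = _softmax_backward(p, dp)
            gw2 = h.T @ dz2 + self.l2 * w2
            gb2 = dz2.sum(axis=0)
            dh = dz2 @ w2.T * h * (1 - h)
            gw1 = X.T @ dh + self.l2 * w1
            gb1 = dh.sum(axis=0)
            opt.step([gw1, gb1, gw2, gb2])
        self.w1_, self.b1_, self.w2_, self.b2_ = w1, b1, w2, b2
        return self

    def predict(self, X: np.ndarray) -> np.ndarray:
        h = 1.0 / (1.0 + np.exp(-(np.asarray(X, float) @ self.w1_ + self.b1_)))
        p = _softmax(h @ self.w2_ + self.b2_)
        return self.classes_[np.argmax(p, axis=1)]


class RNNClassifier:
    """Elman recurrent network with hidden-state delays 1 and 2.

    A flat feature row of width ``seq_len * input_dim`` is reshaped to a
    (seq_len, input_dim) sequence — for the pipeline's matrices the
    component index plays the role of time and each step presents one
    20-channel slice.
    """

    def __init__(self, hidden: int = 10, seq_len: int = 8, epochs: int = 100,
                 lr: float = 0.01, l2: float = 1e-4, seed: int = 0):
        self.hidden = hidden
        self.seq_len = seq_len
        self.epochs = epochs
        self.lr = lr
        self.l2 = l2
        self.seed = seed

    def _sequence(self, X: np.ndarray) -> np.ndarray:
        n, d = X.shape
        if d % self.seq_len:
            raise ValueError(f"feature width {d} not divisible by seq_len {self.seq_len}")
        # channel-major rows: column index = channel * seq_len + component,
        # so the time (component) axis is the fastest-varying one
        return X.reshape(n, d // self.seq_len, self.seq_len).transpose(0, 2, 1)

    def fit(self, X: np.ndarray, y: np.ndarray) -> "RNNClassifier":
        rng = np.random.default_rng(self.seed)
        X = np.asarray(X, dtype=float)
        self.classes_ = np.unique(y)
        Y = _one_hot(np.asarray(y), self.classes_)
        seq = self._sequence(X)
        n, T, d = seq.shape
        k = len(self.classes_)
        H = self.hidden
        wx = rng.normal(0, np.sqrt(1.0 / d), (d, H))
        w1 = rng.normal(0, np.sqrt(1.0 / H), (H, H))
        w2 = rng.normal(0, np.sqrt(1.0 / H), (H, H))
        bh = np.zeros(H)
        wo = rng.normal(0, np.sqrt(1.0 / H), (H, k))
        bo = np.zeros(k)
        params = [wx, w1, w2, bh, wo, bo]
        opt = _Adam(params, self.lr)
        for _ in range(self.epochs):
            hs = [np.zeros((n, H)), np.zeros((n, H))]  # h_{t-2}, h_{t-1}
            cache = []
            for t in range(T):
                a = seq[:, t] @ wx + hs[-1] @ w1 + hs[-2] @ w2 + bh
                h = np.tanh(a)
                cache.append((hs[-2], hs[-1], h))
                hs.append(h)
            out = hs[-1] @ wo + bo           # linear output layer
            dout = np.sign(out - Y) / (n * k)
            gwo = hs[-1].T @ dout + self.l2 * wo
            gbo = dout.sum(axis=0)
            dh_next = {T - 1: dout @ wo.T}
            gwx = self.l2 * wx
            gw1 = self.l2 * w1
            gw2 = self.l2 * w2
            gbh = np.zeros(H)
            for t in range(T - 1, -1, -1):
                dh = dh_next.pop(t, 0.0)
                if np.isscalar(dh):
                    continue
                h_m2, h_m1, h = cache[t]
                da = dh * (1 - h * h)
                gwx += seq[:, t].T @ da
                gw1 += h_m1.T @ da
                gw2 += h_m2.T @ da
                gbh += da.sum(axis=0)
                if t - 1 >= 0:
                    dh_next[t - 1] = dh_next.get(t - 1, 0.0) + da @ w1.T
                if t - 2 >= 0:
                    dh_next[t - 2] = dh_next.get(t - 2, 0.0) + da @ w2.T
            opt.step([gwx, gw1, gw2, gbh, gwo, gbo])
        self.params_ = params
        return self

    def predict(self, X: np.ndarray) -> np.ndarray:
        wx, w1, w2, bh, wo, bo = self.params_
        seq = self._sequence(np.asarray(X, float))
        n, T, _ = seq.shape
        hs = [np.zeros((n, self.hidden)), np.zeros((n, self.hidden))]
        for t in range(T):
            hs.append(np.tanh(seq[:, t] @ wx + hs[-1] @ w1 + hs[-2] @ w2 + bh))
        out = hs[-1] @ wo + bo
        return self.classes_[np.argmax(out, axis=1)]


def _im2col(x: np.ndarray, kh: int, kw: int) -> np.ndarray:
    """Same-padded patch matrix: (n, H*W, C*kh*kw) from (n, C, H, W)."""
    n, c, h, w = x.shape
    ph, pw = kh // 2, kw // 2
    xp = np.pad(x, ((0, 0), (0, 0), (ph, ph), (pw, pw)))
    windows = np.lib.stride_tricks.sliding_window_view(xp, (kh, kw), axis=(2, 3))
    # windows: (n, c, H, W, kh, kw) -> (n, H*W, c*kh*kw)
    return windows.transpose(0, 2, 3, 1, 4, 5).reshape(n, h * w, c * kh * kw)


def _col2im(cols: np.ndarray, shape: tuple, kh: int, kw: int) -> np.ndarray:
    """Adjoint of :func:`_im2col` (scatter-add patches back)."""
    n, c, h, w = shape
    ph, pw = kh // 2, kw // 2
    xp = np.zeros((n, c, h + 2 * ph, w + 2 * pw))
    cols = cols.reshape(n, h, w, c, kh, kw)
    for i in range(kh):
        for j in range(kw):
            xp[:, :, i : i + h, j : j + w] += cols[:, :, :, :, i, j].transpose(0, 3, 1, 2)
    return xp[:, :, ph : ph + h, pw : pw + w]


class _ConvBlock:
    """conv (same padding) -> batch norm -> leaky ReLU -> dropout."""

    def __init__(self, rng, c_in: int, filters: int, kh: int, kw: int,
                 dropout: float, leak: float = 0.01):
        self.kh, self.kw, self.c_in = kh, kw, c_in
        self.w = rng.normal(0, np.sqrt(2.0 / (c_in * kh * kw)), (c_in * kh * kw, filters))
        self.b = np.zeros(filters)
        self.gamma = np.ones(filters)
        self.beta = np.zeros(filters)
        self.run_mean = np.zeros(filters)
        self.run_var = np.ones(filters)
        self.dropout = dropout
        self.leak = leak

    @property
    def params(self):
        return [self.w, self.b, self.gamma, self.beta]

    def forward(self, x: np.ndarray, rng=None):
        n, _, h, w_ = x.shape
        cols = _im2col(x, self.kh, self.kw)
        conv = cols @ self.w + self.b       # (n, H*W, F)
        training = rng is not None
        if training:
            mean = conv.mean(axis=(0, 1))
            var = conv.var(axis=(0, 1))
            self.run_mean = 0.9 * self.run_mean + 0.1 * mean
            self.run_var = 0.9 * self.run_var + 0.1 * var
        else:
            mean, var = self.run_mean, self.run_var
        inv = 1.0 / np.sqrt(var + 1e-5)
        xhat = (conv - mean) * inv
        bn = self.gamma * xhat + self.beta
        act = np.where(bn > 0, bn, self.leak * bn)
        if training and self.dropout > 0:
            mask = (rng.random(act.shape) >= self.dropout) / (1 - self.dropout)
            out = act * mask
        else:
            mask = None
            out = act
        self._cache = (x.shape, cols, bn, xhat, inv, mask)
        return out.transpose(0, 2, 1).reshape(n, -1, h, w_)

    def backward(self, dout: np.ndarray, l2: float):
        shape, cols, bn, xhat, inv, mask = self._cache
        n, _, h, w_ = shape
        dact = dout.reshape(n, -1, h * w_).transpose(0, 2, 1)
        if mask is not None:
            dact = dact * mask
        dbn = np.where(bn > 0, dact, self.leak * dact)
        m = dbn.shape[0] * dbn.shape[1]
        dgamma = np.sum(dbn * xhat, axis=(0, 1))
        dbeta = np.sum(dbn, axis=(0, 1))
        dxhat = dbn * self.gamma
        dconv = inv * (
            dxhat
            - dxhat.mean(axis=(0, 1))
            - xhat * np.mean(dxhat * xhat, axis=(0, 1))
        )
        dw = cols.reshape(-1, cols.shape[2]).T @ dconv.reshape(-1, dconv.shape[2])
        dw += l2 * self.w
        db = dconv.sum(axis=(0, 1))
        dcols = dconv @ self.w.T
        dx = _col2im(dcols, shape, self.kh, self.kw)
        self._grads = [dw, db, dgamma, dbeta]
        return dx


class CNNClassifier:
    """Two conv blocks over the channels x components map, two FC layers,
    softmax classification output, Adam with mini-batches.

    ``input_shape`` is (height, width) of the map a feature row reshapes
    to (channel-major rows reshape to channels x components).  Requested
    filter sizes wider than the map are clamped to the largest odd size
    that fits.
    """

    def __init__(self, input_shape: tuple = (20, 8), filters: int = 96,
                 filter_size: tuple = (11, 11), fc_units: int = 32,
                 dropout: float = 0.25, epochs: int = 100, lr: float = 0.01,
                 batch_size: int = 64, l2: float = 1e-4, seed: int = 0,
                 lr_drop_period: int = 125, lr_drop_factor: float = 0.2):
        self.input_shape = tuple(input_shape)
        self.filters = filters
        self.filter_size = tuple(filter_size)
        self.fc_units = fc_units
        self.dropout = dropout
        self.epochs = epochs
        self.lr = lr
        self.batch_size = batch_size
        self.l2 = l2
        self.seed = seed
        self.lr_drop_period = lr_drop_period
        self.lr_drop_factor = lr_drop_factor

    def _clamped_kernel(self) -> tuple:
        h, w = self.input_shape
        kh = min(self.filter_size[0], h if h % 2 else h - 1)
        kw = min(self.filter_size[1], w if w % 2 else w - 1)
        return kh, kw

    def fit(self, X: np.ndarray, y: np.ndarray) -> "CNNClassifier":
        rng = np.random.default_rng(self.seed)
        X = np.asarray(X, dtype=float)
        self.classes_ = np.unique(y)
        Y = _one_hot(np.asarray(y), self.classes_)
        h, w = self.input_shape
        n = X.shape[0]
        k = len(self.classes_)
        kh, kw = self._clamped_kernel()
        imgs = X.reshape(n, 1, h, w)
        self.blocks_ = [
            _ConvBlock(rng, 1, self.filters, kh, kw, self.dropout),
            _ConvBlock(rng, self.filters, self.filters, kh, kw, self.dropout),
        ]
        flat_dim = self.filters * h * w
        wf1 = rng.normal(0, np.sqrt(2.0 / flat_dim), (flat_dim, self.fc_units))
        bf1 = np.zeros(self.fc_units)
        wf2 = rng.normal(0, np.sqrt(2.0 / self.fc_units), (self.fc_units, k))
        bf2 = np.zeros(k)
        params = self.blocks_[0].params + self.blocks_[1].params + [wf1, bf1, wf2, bf2]
        opt = _Adam(params, self.lr)
        for epoch in range(self.epochs):
            opt.lr = self.lr * (
                self.lr_drop_factor ** (epoch // self.lr_drop_period)
            )
            order = rng.permutation(n)
            for start in range(0, n, self.batch_size):
                idx = order[start : start + self.batch_size]
                xb, yb = imgs[idx], Y[idx]
                a1 = self.blocks_[0].forward(xb, rng)
                a2 = self.blocks_[1].forward(a1, rng)
                flat = a2.reshape(len(idx), -1)
                z1 = flat @ wf1 + bf1
                r1 = np.maximum(z1, 0.0)
                logits = r1 @ wf2 + bf2
                p = _softmax(logits)
                dz = (p - yb) / len(idx)     # cross-entropy + softmax
                gwf2 = r1.T @ dz + self.l2 * wf2
                gbf2 = dz.sum(axis=0)
                dr1 = dz @ wf2.T
                dz1 = dr1 * (z1 > 0)
                gwf1 = flat.T @ dz1 + self.l2 * wf1
                gbf1 = dz1.sum(axis=0)
                dflat = dz1 @ wf1.T
                da2 = dflat.reshape(a2.shape)
                da1 = self.blocks_[1].backward(da2, self.l2)
                self.blocks_[0].backward(da1, self.l2)
                grads = (
                    self.blocks_[0]._grads + self.blocks_[1]._grads
                    + [gwf1, gbf1, gwf2, gbf2]
                )
                opt.step(grads)
        self.fc_ = (wf1, bf1, wf2, bf2)
        return self

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        h, w = self.input_shape
        imgs = X.reshape(X.shape[0], 1, h, w)
        a = self.blocks_[0].forward(imgs)
        a = self.blocks_[1].forward(a)
        wf1, bf1, wf2, bf2 = self.fc_
        r1 = np.maximum(a.reshape(X.shape[0], -1) @ wf1 + bf1, 0.0)
        p = _softmax(r1 @ wf2 + bf2)
        return self.classes_[np.argmax(p, axis=1)]
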