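"""Minimal NumPy convolutional network used by the distress classifier.

Three blocks of (3x3 same-padding convolution, batch normalisation,
ReLU, 2x2 max pooling) followed by one dense hidden layer and a
softmax output, trained with Adam on cross-entropy with early stopping
on validation loss.  Convolutions are evaluated as matrix products
over im2col patch matrices; everything is float32.
"""
from __future__ import annotations

import numpy as np

_F32 = np.float32


def _im2col(x: np.ndarray, k: int = 3) -> np.ndarray:
    """(N, C, H, W) -> (N, C*k*k, H*W) patch matrix with same padding."""
    n, c, h, w = x.shape
    p = k // 2
    xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
    cols = np.empty((n, c * k * k, h * w), dtype=x.dtype)
    idx = 0
    for dy in range(k):
        for dx in range(k):
            patch = xp[:, :, dy : dy + h, dx : dx + w]
            cols[:, idx * c : (idx + 1) * c, :] = patch.reshape(n, c, h * w)
            idx += 1
    return cols


def _col2im(dcols: np.ndarray, shape, k: int = 3) -> np.ndarray:
    n, c, h, w = shape
    p = k // 2
    dxp = np.zeros((n, c, h + 2 * p, w + 2 * p), dtype=dcols.dtype)
    idx = 0
    for dy in range(k):
        for dx in range(k):
            dxp[:, :, dy : dy + h, dx : dx + w] += dcols[
                :, idx * c : (idx + 1) * c, :
            ].reshape(n, c, h, w)
            idx += 1
    return dxp[:, :, p : p + h, p : p + w]


class _Conv:
    def __init__(self, c_in, c_out, rng):
        scale = np.sqrt(2.0 / (c_in * 9))
        self.w = (rng.standard_normal((c_out, c_in * 9)) * scale).astype(_F32)
        self.b = np.zeros(c_out, dtype=_F32)
        self.c_in = c_in

    def forward(self, x):
        self.x_shape = x.shape
        self.cols = _im2col(x)
        n, _, hw = self.cols.shape
        out = np.einsum("fk,nkp->nfp", self.w, self.cols) + self.b[None, :, None]
        h, w = self.x_shape[2], self.x_shape[3]
        return out.reshape(n, -1, h, w)

    def backward(self, dout):
        n, f, h, w = dout.shape
        dflat = dout.reshape(n, f, h * w)
        self.dw = np.einsum("nfp,nkp->fk", dflat, self.cols) / n
        self.db = dflat.sum(axis=(0, 2)) / n
        dcols = np.einsum("fk,nfp->nkp", self.w, dflat)
        return _col2im(dcols, self.x_shape)

    def params(self):
        return [("w", self.w, self.dw), ("b", self.b, self.db)]


class _BatchNorm:
    def __init__(self, c, momentum=0.9, eps=1e-5):
        self.gamma = np.ones(c, dtype=_F32)
        self.beta = np.zeros(c, dtype=_F32)
        self.run_mean = np.zeros(c, dtype=_F32)
        self.run_var = np.ones(c, dtype=_F32)
        self.momentum, self.eps = momentum, eps

    def forward(self, x, train):
        axes = (0, 2, 3) if x.ndim == 4 else (0,)
        shape = (1, -1, 1, 1) if x.ndim == 4 else (1, -1)
        if train:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            self.run_mean = self.momentum * self.run_mean + (1 - self.momentum) * mean
            self.run_var = self.momentum * self.run_var + (1 - self.momentum) * var
        else:
            mean, var = self.run_mean, self.run_var
        self.inv_std = (1.0 / np.sqrt(var + self.eps)).astype(_F32)
        self.xhat = (x - mean.reshape(shape)) * self.inv_std.reshape(shape)
        self.shape, self.axes = shape, axes
        return self.gamma.reshape(shape) * self.xhat + self.beta.reshape(shape)

    def backward(self, dout):
        m = dout.size / dout.shape[1]
        self.dgamma = (dout * self.xhat).sum(axis=self.axes) / dout.shape[0]
        self.dbeta = dout.sum(axis=self.axes) / dout.shape[0]
        g = self.gamma.reshape(self.shape) * self.inv_std.reshape(self.shape)
        sum_d = dout.sum(axis=self.axes).reshape(self.shape)
        sum_dx = (dout * self.xhat).sum(axis=self.axes).reshape(self.shape)
        return g * (dout - sum_d / m - self.xhat * sum_dx / m)

    def params(self):
        return [("gamma", self.gamma, self.dgamma), ("beta", self.beta, self.dbeta)]


class _ReLU:
    def forward(self, x):
        self.mask = x > 0
        return x * self.mask

    def backward(self, dout):
        return dout * self.mask


class _MaxPool2:
    def forward(self, x):
        n, c, h, w = x.shape
        self.in_shape = x.shape
        h2, w2 = h // 2, w // 2
        xc = x[:, :, : h2 * 2, : w2 * 2].reshape(n, c, h2, 2, w2, 2)
        self.xc_shape = xc.shape
        flat = xc.transpose(0, 1, 2, 4, 3, 5).reshape(n, c, h2, w2, 4)
        self.arg = flat.argmax(axis=-1)
        return flat.max(axis=-1)

    def backward(self, dout):
        n, c, h2, w2 = dout.shape
        dflat = np.zeros((n, c, h2, w2, 4), dtype=dout.dtype)
        np.put_along_axis(dflat, self.arg[..., None], dout[..., None], axis=-1)
        dxc = dflat.reshape(n, c, h2, w2, 2, 2).transpose(0, 1, 2, 4, 3, 5)
        dx = np.zeros(self.in_shape, dtype=dout.dtype)
        dx[:, :, : h2 * 2, : w2 * 2] = dxc.reshape(n, c, h2 * 2, w2 * 2)
        return dx


class _Dense:
    def __init__(self, n_in, n_out, rng):
        scale = np.sqrt(2.0 / n_in)
        self.w = (rng.standard_normal((n_in, n_out)) * scale).astype(_F32)
        self.b = np.zeros(n_out, dtype=_F32)

    def forward(self, x):
        self.x = x
        return x @ self.w + self.b

    def backward(self, dout):
        self.dw = self.x.T @ dout / len(dout)
        self.db = dout.mean(axis=0)
        return dout @ self.w.T

    def params(self):
        return [("w", self.w, self.dw), ("b", self.b, self.db)]


class SmallCNN:
    """Fixed small architecture for two-class spectrogram classification."""

    def __init__(self, input_shape, filters=(16, 32, 64), dense_units=64,
                 n_classes=2, seed=0):
        rng = np.random.default_rng(seed)
        h, w = input_shape
        self.blocks = []
        c_in = 1
        for f in filters:
            self.blocks.append((_Conv(c_in, f, rng), _BatchNorm(f), _ReLU(), _MaxPool2()))
            c_in = f
            h, w = h // 2, w // 2
        self.flat_dim = c_in * h * w
        self.fc1 = _Dense(self.flat_dim, dense_units, rng)
        self.bn_fc = _BatchNorm(dense_units)
        self.relu_fc = _ReLU()
        self.fc2 = _Dense(dense_units, n_classes, rng)

    # ------------------------------------------------------------------
    def forward(self, x, train=False):
        h = x.astype(_F32)
        if h.ndim == 3:
            h = h[:, None, :, :]
        for conv, bn, relu, pool in self.blocks:
            h = pool.forward(relu.forward(bn.forward(conv.forward(h), train)))
        self._pool_out_shape = h.shape
        h = h.reshape(len(h), -1)
        if h.shape[1] != self.flat_dim:  # guard against odd sizes
            raise ValueError("input spatial size incompatible with architecture")
        h = self.relu_fc.forward(self.bn_fc.forward(self.fc1.forward(h), train))
        return self.fc2.forward(h)

    def backward(self, dlogits):
        d = self.fc2.backward(dlogits)
        d = self.fc1.backward(self.bn_fc.backward(self.relu_fc.backward(d)))
        d = d.reshape(self._pool_out_shape)
        for conv, bn, relu, pool in reversed(self.blocks):
            d = conv.backward(bn.backward(relu.backward(pool.backward(d))))
        return d

    def _layers(self):
        for conv, bn, _, _ in self.blocks:
            yield conv
            yield bn
        yield self.fc1
        yield self.bn_fc
        yield self.fc2

    # ------------------------------------------------------------------
    def loss_and_grad(self, x, y, train=True):
        logits = self.forward(x, train=train)
        logits = logits - logits.max(axis=1, keepdims=True)
        expl = np.exp(logits)
        probs = expl / expl.sum(axis=1, keepdims=True)
        n = len(y)
        loss = float(-np.log(np.maximum(probs[np.arange(n), y], 1e-12)).mean())
        dlogits = probs.copy()
        dlogits[np.arange(n), y] -= 1.0
        return loss, dlogits.astype(_F32)

    def fit(self, x_train, y_train, x_val, y_val, epochs=10, batch_size=32,
            lr=1e-3, patience=2, seed=0, verbose=False):
        rng = np.random.default_rng(seed)
        state = {}
        best = (np.inf, None)
        bad_epochs = 0
        history = []
        for epoch in range(epochs):
            order = rng.permutation(len(x_train))
            for i0 in range(0, len(order), batch_size):
                idx = order[i0 : i0 + batch_size]
                if len(idx) < 2:
                    continue  # batch norm needs >1 sample
                loss, dlogits = self.loss_and_grad(x_train[idx], y_train[idx])
                self.backward(dlogits)
                self._adam_step(state, lr)
            val_loss = self.evaluate_loss(x_val, y_val)
            history.append(val_loss)
            if verbose:
                print(f"epoch {epoch}: val loss {val_loss:.4f}")
            if val_loss < best[0] - 1e-4:
                best = (val_loss, self._snapshot())
                bad_epochs = 0
            else:
                bad_epochs += 1
                if bad_epochs > patience:
                    break
        if best[1] is not None:
            self._restore(best[1])
        return history

    def _adam_step(self, state, lr, beta1=0.9, beta2=0.999, eps=1e-8):
        t = state.setdefault("t", 0) + 1
        state["t"] = t
        for li, layer in enumerate(self._layers()):
            for name, param, grad in layer.params():
                key = (li, name)
                m, v = state.setdefault(key, (np.zeros_like(param), np.zeros_like(param)))
                m = beta1 * m + (1 - beta1) * grad
                v = beta2 * v + (1 - beta2) * grad**2
                state[key] = (m, v)
                mhat = m / (1 - beta1**t)
                vhat = v / (1 - beta2**t)
                param -= (lr * mhat / (np.sqrt(vhat) + eps)).astype(param.dtype)

    def _snapshot(self):
        out = []
        for layer in self._layers():
            out.append([p.copy() for _, p, _ in layer.params()])
            if isinstance(layer, _BatchNorm):
                out.append([layer.run_mean.copy(), layer.run_var.copy()])
        return out

    def _restore(self, snap):
        i = 0
        for layer in self._layers():
            for (name, p, _), saved in zip(layer.params(), snap[i]):
                p[...] = saved
            i += 1
            if isinstance(layer, _BatchNorm):
                layer.run_mean, layer.run_var = snap[i]
                i += 1

    # ------------------------------------------------------------------
    def predict_proba(self, x, batch_size=128):
        probs = []
        for i0 in range(0, len(x), batch_size):
            logits = self.forward(x[i0 : i0 + batch_size], train=False)
            logits = logits - logits.max(axis=1, keepdims=True)
            e = np.exp(logits)
            probs.append(e / e.sum(axis=1, keepdims=True))
        return np.concatenate(probs)

    def predict(self, x):
        return self.predict_proba(x).argmax(axis=1)

    def evaluate_loss(self, x, y, batch_size=128):
        probs = self.predict_proba(x, batch_size)
        return float(-np.log(np.maximum(probs[np.arange(len(y)), y], 1e-12)).mean())
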