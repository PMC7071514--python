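"""Minimal NumPy layer engine with hand-derived backpropagation.

Implements exactly the layers the fall-detection networks need: same-padded
2-D convolution, 2x2 max pooling, dense, dropout, ReLU, softmax
cross-entropy, the peephole ConvLSTM-1D layer (backprop-through-time over
the forward pass defined in :mod:`uwbfall.convlstm`), and the Nadam
optimizer.  Every layer caches what its backward pass needs and accumulates
parameter gradients in place; ``params_and_grads`` pairs are consumed by the
optimizer.

All kernels are initialized orthogonally (flattened per-matrix QR), biases
and peepholes at zero.
"""

from __future__ import annotations

import numpy as np

from .convlstm import GATES, PEEPHOLE_GATES, _orthogonal, init_orthogonal, sigmoid


class Layer:
    def params_and_grads(self):
        return []

    def zero_grads(self) -> None:
        for _, g in self.params_and_grads():
            g[...] = 0.0


def relu(x: np.ndarray) -> np.ndarray:
    return np.maximum(x, 0.0)


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


class Conv2D(Layer):
    """Same-padded 2-D convolution (cross-correlation), odd square kernels."""

    def __init__(self, c_in: int, c_out: int, k: int, seed: int, dtype=np.float64):
        if k % 2 == 0:
            raise ValueError("kernel size must be odd")
        self.c_in, self.c_out, self.k = c_in, c_out, k
        rng = np.random.default_rng(np.random.SeedSequence([seed & 0x7FFFFFFF, 11]))
        self.w = _orthogonal(c_in * k * k, c_out, rng).astype(dtype)  # (C_in*k*k, C_out)
        self.b = np.zeros(c_out, dtype=dtype)
        self.dw = np.zeros_like(self.w)
        self.db = np.zeros_like(self.b)
        self._cols = None
        self._in_shape = None

    def params_and_grads(self):
        return [(self.w, self.dw), (self.b, self.db)]

    def forward(self, x: np.ndarray) -> np.ndarray:
        b, c, h, w = x.shape
        k, p = self.k, self.k // 2
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
        win = np.lib.stride_tricks.sliding_window_view(xp, (k, k), axis=(2, 3))
        # (B, C, H, W, k, k) -> (B, H, W, C*k*k)
        cols = np.ascontiguousarray(win.transpose(0, 2, 3, 1, 4, 5)).reshape(b, h, w, c * k * k)
        self._cols = cols
        self._in_shape = x.shape
        y = cols @ self.w + self.b
        return y.transpose(0, 3, 1, 2)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        b, c, h, w = self._in_shape
        k, p = self.k, self.k // 2
        d = dout.transpose(0, 2, 3, 1)  # (B, H, W, C_out)
        cols2 = self._cols.reshape(-1, self._cols.shape[-1])
        d2 = d.reshape(-1, self.c_out)
        self.dw += cols2.T @ d2
        self.db += d2.sum(axis=0)
        dcols = (d2 @ self.w.T).reshape(b, h, w, c, k, k).transpose(0, 3, 1, 2, 4, 5)
        dxp = np.zeros((b, c, h + 2 * p, w + 2 * p), dtype=dout.dtype)
        for i in range(k):
            for j in range(k):
                dxp[:, :, i : i + h, j : j + w] += dcols[:, :, :, :, i, j]
        return dxp[:, :, p : p + h, p : p + w]


class MaxPool2(Layer):
    """2x2 max pooling, stride 2; trailing odd rows/cols are dropped."""

    def forward(self, x: np.ndarray) -> np.ndarray:
        b, c, h, w = x.shape
        h2, w2 = h // 2 * 2, w // 2 * 2
        xr = x[:, :, :h2, :w2].reshape(b, c, h2 // 2, 2, w2 // 2, 2)
        xr = xr.transpose(0, 1, 2, 4, 3, 5).reshape(b, c, h2 // 2, w2 // 2, 4)
        self._idx = xr.argmax(axis=-1)
        self._in_shape = x.shape
        return np.take_along_axis(xr, self._idx[..., None], axis=-1)[..., 0]

    def backward(self, dout: np.ndarray) -> np.ndarray:
        b, c, h, w = self._in_shape
        h2, w2 = h // 2 * 2, w // 2 * 2
        dflat = np.zeros(dout.shape + (4,), dtype=dout.dtype)
        np.put_along_axis(dflat, self._idx[..., None], dout[..., None], axis=-1)
        dx = np.zeros((b, c, h, w), dtype=dout.dtype)
        dr = dflat.reshape(b, c, h2 // 2, w2 // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5)
        dx[:, :, :h2, :w2] = dr.reshape(b, c, h2, w2)
        return dx


class ReLU(Layer):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return np.where(self._mask, x, 0.0)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return np.where(self._mask, dout, 0.0)


class Dense(Layer):
    def __init__(self, n_in: int, n_out: int, seed: int, dtype=np.float64):
        rng = np.random.default_rng(np.random.SeedSequence([seed & 0x7FFFFFFF, 13]))
        self.w = _orthogonal(n_in, n_out, rng).astype(dtype)
        self.b = np.zeros(n_out, dtype=dtype)
        self.dw = np.zeros_like(self.w)
        self.db = np.zeros_like(self.b)

    def params_and_grads(self):
        return [(self.w, self.dw), (self.b, self.db)]

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return x @ self.w + self.b

    def backward(self, dout: np.ndarray) -> np.ndarray:
        self.dw += self._x.T @ dout
        self.db += dout.sum(axis=0)
        return dout @ self.w.T


class Dropout(Layer):
    """Inverted dropout; identity at inference."""

    def __init__(self, rate: float):
        if not (0.0 <= rate < 1.0):
            raise ValueError("dropout rate must be in [0, 1)")
        self.rate = rate
        self._mask = None

    def forward(self, x: np.ndarray, train: bool, rng: np.random.Generator | None) -> np.ndarray:
        if not train or self.rate == 0.0:
            self._mask = None
            return x
        if rng is None:
            raise ValueError("training-mode dropout needs an rng")
        self._mask = (rng.random(x.shape) >= self.rate).astype(x.dtype) / (1.0 - self.rate)
        return x * self._mask

    def backward(self, dout: np.ndarray) -> np.ndarray:
        if self._mask is None:
            return dout
        return dout * self._mask


def _cols1d(x: np.ndarray, k: int) -> np.ndarray:
    """(B, L, C) -> (B, L, k*C) same-padded sliding windows."""
    p = k // 2
    xp = np.pad(x, ((0, 0), (p, p), (0, 0)))
    win = np.lib.stride_tricks.sliding_window_view(xp, k, axis=1)  # (B, L, C, k)
    win = win.swapaxes(-1, -2)  # (B, L, k, C)
    return np.ascontiguousarray(win).reshape(x.shape[0], x.shape[1], k * x.shape[2])


def _cols1d_adjoint(dcols: np.ndarray, k: int, length: int, c: int) -> np.ndarray:
    """Adjoint of _cols1d: (B, L, k, C) window grads -> (B, L, C)."""
    p = k // 2
    b = dcols.shape[0]
    dxp = np.zeros((b, length + 2 * p, c), dtype=dcols.dtype)
    for tap in range(k):
        dxp[:, tap : tap + length, :] += dcols[:, :, tap, :]
    return dxp[:, p : p + length, :]


class ConvLSTM1D(Layer):
    """Trainable peephole ConvLSTM-1D in return-last mode with BPTT.

    The forward recurrence is identical to :func:`uwbfall.convlstm`'s
    reference implementation (same gate equations, same convolution
    convention); tests assert the match.
    """

    def __init__(
        self,
        c_in: int,
        c_hidden: int,
        k: int,
        spatial_length: int,
        seed: int,
        peephole_mode: str = "full",
        dtype=np.float64,
    ):
        p = init_orthogonal(
            c_in, c_hidden, k, spatial_length=spatial_length, seed=seed, peephole_mode=peephole_mode
        )
        self.c_in, self.c_h, self.k, self.length = c_in, c_hidden, k, spatial_length
        self.w_x = {g: p.w_x[g].astype(dtype) for g in GATES}
        self.w_h = {g: p.w_h[g].astype(dtype) for g in GATES}
        self.w_c = {g: p.w_c[g].astype(dtype) for g in PEEPHOLE_GATES}
        self.b = {g: p.b[g].astype(dtype) for g in GATES}
        self.d_w_x = {g: np.zeros_like(self.w_x[g]) for g in GATES}
        self.d_w_h = {g: np.zeros_like(self.w_h[g]) for g in GATES}
        self.d_w_c = {g: np.zeros_like(self.w_c[g]) for g in PEEPHOLE_GATES}
        self.d_b = {g: np.zeros_like(self.b[g]) for g in GATES}
        self.peephole_mode = peephole_mode

    def params_and_grads(self):
        out = []
        for g in GATES:
            out += [(self.w_x[g], self.d_w_x[g]), (self.w_h[g], self.d_w_h[g]), (self.b[g], self.d_b[g])]
        for g in PEEPHOLE_GATES:
            out.append((self.w_c[g], self.d_w_c[g]))
        return out

    def to_reference_params(self):
        """Expose weights as a ConvLSTMParams for the reference forward pass."""
        from .convlstm import ConvLSTMParams

        return ConvLSTMParams(
            input_channels=self.c_in,
            hidden_channels=self.c_h,
            kernel_width=self.k,
            w_x={g: self.w_x[g].astype(float) for g in GATES},
            w_h={g: self.w_h[g].astype(float) for g in GATES},
            w_c={g: self.w_c[g].astype(float) for g in PEEPHOLE_GATES},
            b={g: self.b[g].astype(float) for g in GATES},
            peephole_mode=self.peephole_mode,
            spatial_length=self.length,
        )

    def forward(self, x: np.ndarray) -> np.ndarray:
        """x: (B, T, L, C_in) -> H_T (B, L, C_h)."""
        b, n_t, length, _ = x.shape
        dtype = x.dtype
        wxm = {g: self.w_x[g].reshape(self.k * self.c_in, self.c_h) for g in GATES}
        whm = {g: self.w_h[g].reshape(self.k * self.c_h, self.c_h) for g in GATES}
        h = np.zeros((b, length, self.c_h), dtype=dtype)
        c = np.zeros((b, length, self.c_h), dtype=dtype)
        self._cache = []
        for t in range(n_t):
            xcols = _cols1d(x[:, t], self.k)
            hcols = _cols1d(h, self.k)
            pre = {g: xcols @ wxm[g] + hcols @ whm[g] + self.b[g] for g in GATES}
            c_prev = c
            i_t = sigmoid(pre["i"] + self.w_c["i"] * c_prev)
            f_t = sigmoid(pre["f"] + self.w_c["f"] * c_prev)
            g_t = np.tanh(pre["c"])
            c = f_t * c_prev + i_t * g_t
            o_t = sigmoid(pre["o"] + self.w_c["o"] * c)
            tanh_c = np.tanh(c)
            h = o_t * tanh_c
            self._cache.append((xcols, hcols, i_t, f_t, g_t, o_t, c_prev, c, tanh_c))
        self._in_shape = x.shape
        return h

    def backward(self, dh_last: np.ndarray) -> np.ndarray:
        b, n_t, length, c_in = self._in_shape
        dtype = dh_last.dtype
        wxm = {g: self.w_x[g].reshape(self.k * self.c_in, self.c_h) for g in GATES}
        whm = {g: self.w_h[g].reshape(self.k * self.c_h, self.c_h) for g in GATES}

        def reduce_peep(arr):
            if self.peephole_mode == "full":
                return arr.sum(axis=0)
            return arr.sum(axis=(0, 1))

        dx = np.zeros(self._in_shape, dtype=dtype)
        dh_next = dh_last
        dc_next = np.zeros_like(dh_last)
        for t in range(n_t - 1, -1, -1):
            xcols, hcols, i_t, f_t, g_t, o_t, c_prev, c_t, tanh_c = self._cache[t]
            dh = dh_next
            do = dh * tanh_c
            dao = do * o_t * (1.0 - o_t)
            dc = dc_next + dh * o_t * (1.0 - tanh_c**2) + dao * self.w_c["o"]
            di = dc * g_t
            df = dc * c_prev
            dg = dc * i_t
            dai = di * i_t * (1.0 - i_t)
            daf = df * f_t * (1.0 - f_t)
            dac = dg * (1.0 - g_t**2)
            self.d_w_c["o"] += reduce_peep(dao * c_t)
            self.d_w_c["i"] += reduce_peep(dai * c_prev)
            self.d_w_c["f"] += reduce_peep(daf * c_prev)
            dc_prev = dc * f_t + dai * self.w_c["i"] + daf * self.w_c["f"]
            dxcols = np.zeros((b, length, self.k * self.c_in), dtype=dtype)
            dhcols = np.zeros((b, length, self.k * self.c_h), dtype=dtype)
            for g, da in zip(GATES, (dai, daf, dac, dao)):
                da2 = da.reshape(-1, self.c_h)
                self.d_w_x[g] += (xcols.reshape(-1, self.k * self.c_in).T @ da2).reshape(self.w_x[g].shape)
                self.d_w_h[g] += (hcols.reshape(-1, self.k * self.c_h).T @ da2).reshape(self.w_h[g].shape)
                self.d_b[g] += da2.sum(axis=0)
                dxcols += da @ wxm[g].T
                dhcols += da @ whm[g].T
            dx[:, t] = _cols1d_adjoint(dxcols.reshape(b, length, self.k, self.c_in), self.k, length, self.c_in)
            dh_next = _cols1d_adjoint(dhcols.reshape(b, length, self.k, self.c_h), self.k, length, self.c_h)
            dc_next = dc_prev
        return dx


def cross_entropy_grad(logits: np.ndarray, labels0: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean cross-entropy over the batch and its gradient w.r.t. logits.

    ``labels0`` are 0-based class indices.
    """
    b = logits.shape[0]
    p = softmax(logits)
    eps = np.finfo(logits.dtype).tiny
    loss = -float(np.mean(np.log(p[np.arange(b), labels0] + eps)))
    grad = p.copy()
    grad[np.arange(b), labels0] -= 1.0
    return loss, grad / b


class Nadam:
    """Nesterov-accelerated adaptive moment estimation."""

    def __init__(self, params_and_grads, lr=1e-3, beta1=0.9, beta2=0.999, eps=1e-8):
        self.pg = list(params_and_grads)
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p, _ in self.pg]
        self.v = [np.zeros_like(p) for p, _ in self.pg]
        self.t = 0

    def step(self) -> None:
        self.t += 1
        b1t = 1.0 - self.b1**self.t
        b2t = 1.0 - self.b2**self.t
        for (p, g), m, v in zip(self.pg, self.m, self.v):
            m *= self.b1
            m += (1.0 - self.b1) * g
            v *= self.b2
            v += (1.0 - self.b2) * g * g
            m_hat = m / b1t
            v_hat = v / b2t
            p -= self.lr * (self.b1 * m_hat + (1.0 - self.b1) * g / b1t) / (np.sqrt(v_hat) + self.eps)
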