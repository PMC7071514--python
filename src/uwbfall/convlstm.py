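"""Peephole convolutional LSTM with 1-D kernels, from the gate equations.

The cell replaces the matrix products of a standard peephole LSTM with
same-padded 1-D convolutions over the range axis, so each gate sees a small
spatial reception field of the input and the previous hidden state:

    I_t = sigma(W_xi * X_t + W_hi * H_{t-1} + W_ci o C_{t-1} + b_i)
    F_t = sigma(W_xf * X_t + W_hf * H_{t-1} + W_cf o C_{t-1} + b_f)
    C_t = F_t o C_{t-1} + I_t o tanh(W_xc * X_t + W_hc * H_{t-1} + b_c)
    O_t = sigma(W_xo * X_t + W_ho * H_{t-1} + W_co o C_t + b_o)
    H_t = O_t o tanh(C_t)

where ``*`` is same-padded 1-D convolution (cross-correlation convention,
zero boundary) and ``o`` is the element-wise product.  Peephole weights are
element-wise tensors shaped like the cell state ("full" mode, the direct
reading of the ``o`` notation) or per-channel vectors ("channel" mode).

Everything here is plain float64 NumPy; this module is the reference
forward pass that training layers and test oracles are measured against.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

GATES = ("i", "f", "c", "o")
PEEPHOLE_GATES = ("i", "f", "o")


def sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def conv1d_same(x: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Same-padded 1-D cross-correlation over the spatial axis.

    ``x``: (..., L, C_in); ``w``: (k, C_in, C_out) -> (..., L, C_out).
    Zero boundary; k must be odd.
    """
    k, c_in, c_out = w.shape
    if k % 2 == 0:
        raise ValueError("kernel width must be odd")
    if x.shape[-1] != c_in:
        raise ValueError(f"input has {x.shape[-1]} channels, kernel expects {c_in}")
    p = k // 2
    pad = [(0, 0)] * (x.ndim - 2) + [(p, p), (0, 0)]
    xp = np.pad(x, pad)
    win = np.lib.stride_tricks.sliding_window_view(xp, k, axis=-2)  # (..., L, C_in, k)
    win = np.swapaxes(win, -1, -2)  # (..., L, k, C_in)
    cols = win.reshape(win.shape[:-2] + (k * c_in,))
    return cols @ w.reshape(k * c_in, c_out)


@dataclass
class ConvLSTMParams:
    """All weights of one peephole ConvLSTM-1D cell.

    ``w_x[g]``: input-to-state kernel (k, C_in, C_h); ``w_h[g]``:
    state-to-state kernel (k, C_h, C_h); ``w_c[g]`` for g in i/f/o:
    peephole weights, shaped (L, C_h) in "full" mode or (C_h,) in
    "channel" mode; ``b[g]``: bias (C_h,).
    """

    input_channels: int
    hidden_channels: int
    kernel_width: int
    w_x: dict = field(default_factory=dict)
    w_h: dict = field(default_factory=dict)
    w_c: dict = field(default_factory=dict)
    b: dict = field(default_factory=dict)
    peephole_mode: str = "full"
    spatial_length: int | None = None

    def validate(self) -> None:
        if self.kernel_width % 2 == 0:
            raise ValueError("kernel_width must be odd")
        for g in GATES:
            if g not in self.w_x or g not in self.w_h or g not in self.b:
                raise ValueError(f"missing weights for gate '{g}'")
            if self.w_x[g].shape != (self.kernel_width, self.input_channels, self.hidden_channels):
                raise ValueError(f"w_x[{g}] has wrong shape")
            if self.w_h[g].shape != (self.kernel_width, self.hidden_channels, self.hidden_channels):
                raise ValueError(f"w_h[{g}] has wrong shape")
        for g in PEEPHOLE_GATES:
            if g not in self.w_c:
                raise ValueError(f"missing peephole weights for gate '{g}'")

    def zeros_state(self, spatial_length: int, batch: int | None = None) -> "ConvLSTMState":
        shape = (spatial_length, self.hidden_channels)
        if batch is not None:
            shape = (batch,) + shape
        return ConvLSTMState(hidden=np.zeros(shape), cell=np.zeros(shape))


@dataclass
class ConvLSTMState:
    """Hidden tensor H_t and cell tensor C_t, each (..., L, C_h)."""

    hidden: np.ndarray
    cell: np.ndarray


def convlstm_step(x_t: np.ndarray, state: ConvLSTMState, params: ConvLSTMParams) -> ConvLSTMState:
    """One slow-time update of the cell; ``x_t`` is (..., L, C_in)."""
    params.validate()
    h_prev, c_prev = state.hidden, state.cell
    if x_t.shape[:-1] != h_prev.shape[:-1]:
        raise ValueError("input and state spatial shapes do not match")

    def pre(g: str) -> np.ndarray:
        return conv1d_same(x_t, params.w_x[g]) + conv1d_same(h_prev, params.w_h[g]) + params.b[g]

    i_t = sigmoid(pre("i") + params.w_c["i"] * c_prev)
    f_t = sigmoid(pre("f") + params.w_c["f"] * c_prev)
    c_t = f_t * c_prev + i_t * np.tanh(pre("c"))
    o_t = sigmoid(pre("o") + params.w_c["o"] * c_t)
    h_t = o_t * np.tanh(c_t)
    return ConvLSTMState(hidden=h_t, cell=c_t)


def convlstm_forward(
    sequence: np.ndarray, params: ConvLSTMParams, return_last: bool = True
) -> np.ndarray:
    """Unroll the cell over a sequence with zero initial state.

    ``sequence``: (T, L, C_in) or (B, T, L, C_in).  Returns H_T of shape
    (..., L, C_h) in return-last mode, else the stacked H sequence with the
    time axis where it was.
    """
    sequence = np.asarray(sequence, dtype=float)
    if sequence.ndim not in (3, 4):
        raise ValueError("sequence must be (T, L, C_in) or (B, T, L, C_in)")
    batched = sequence.ndim == 4
    t_axis = 1 if batched else 0
    n_t = sequence.shape[t_axis]
    if n_t < 1:
        raise ValueError("sequence must contain at least one step")
    spatial = sequence.shape[-2]
    batch = sequence.shape[0] if batched else None
    state = params.zeros_state(spatial, batch)
    outputs = []
    for t in range(n_t):
        x_t = sequence[:, t] if batched else sequence[t]
        state = convlstm_step(x_t, state, params)
        if not return_last:
            outputs.append(state.hidden)
    if return_last:
        return state.hidden
    return np.stack(outputs, axis=t_axis)


def _orthogonal(rows: int, cols: int, rng: np.random.Generator) -> np.ndarray:
    """A (rows, cols) matrix with orthonormal columns (or rows if wider)."""
    flip = cols > rows
    a = rng.standard_normal((max(rows, cols), min(rows, cols)))
    q, r = np.linalg.qr(a)
    q = q * np.sign(np.diag(r))
    return q.T if flip else q


def init_orthogonal(
    input_channels: int,
    hidden_channels: int,
    kernel_width: int,
    *,
    spatial_length: int | None = None,
    seed: int = 0,
    peephole_mode: str = "full",
) -> ConvLSTMParams:
    """Random orthogonal kernel initialization; zero biases and peepholes.

    Each gate kernel, flattened to a (k*C_in, C_h) matrix, has orthonormal
    columns.  Peephole weights start at zero (they are element-wise state
    tensors, not kernels) and the "full" mode requires ``spatial_length``.
    """
    if peephole_mode not in ("full", "channel"):
        raise ValueError("peephole_mode must be 'full' or 'channel'")
    if peephole_mode == "full" and spatial_length is None:
        raise ValueError("full peephole mode requires spatial_length")
    rng = np.random.default_rng(np.random.SeedSequence([int(seed) & 0x7FFFFFFF, 101]))
    w_x, w_h, w_c, b = {}, {}, {}, {}
    for g in GATES:
        w_x[g] = _orthogonal(kernel_width * input_channels, hidden_channels, rng).reshape(
            kernel_width, input_channels, hidden_channels
        )
        w_h[g] = _orthogonal(kernel_width * hidden_channels, hidden_channels, rng).reshape(
            kernel_width, hidden_channels, hidden_channels
        )
        b[g] = np.zeros(hidden_channels)
    for g in PEEPHOLE_GATES:
        if peephole_mode == "full":
            w_c[g] = np.zeros((spatial_length, hidden_channels))
        else:
            w_c[g] = np.zeros(hidden_channels)
    return ConvLSTMParams(
        input_channels=input_channels,
        hidden_channels=hidden_channels,
        kernel_width=kernel_width,
        w_x=w_x,
        w_h=w_h,
        w_c=w_c,
        b=b,
        peephole_mode=peephole_mode,
        spatial_length=spatial_length,
    )
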