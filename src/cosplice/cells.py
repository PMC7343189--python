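"""Recurrent-cell step equations and parameter containers.

The three cell types are implemented directly from their defining
equations.  With sigma the logistic sigmoid and (*) the Hadamard product:

simple RNN:
    h_t = tanh(W_h^T h_{t-1} + W_x^T x_t + b)

LSTM (gates f forget, i input/update, o output, g candidate):
    f_t = sigma(W_hf^T h_{t-1} + W_xf^T x_t + b_f)
    i_t = sigma(W_hi^T h_{t-1} + W_xi^T x_t + b_i)
    o_t = sigma(W_ho^T h_{t-1} + W_xo^T x_t + b_o)
    g_t = tanh (W_hg^T h_{t-1} + W_xg^T x_t + b_g)
    c_t = f_t (*) c_{t-1} + i_t (*) g_t
    h_t = o_t (*) tanh(c_t)

GRU (z update, r reset):
    z_t = sigma(W_hz^T h_{t-1} + W_xz^T x_t + b_z)
    r_t = sigma(W_hr^T h_{t-1} + W_xr^T x_t + b_r)
    h_t = (1 - z_t) (*) h_{t-1} + z_t (*) tanh(W_hh^T (r_t (*) h_{t-1}) + W_xh^T x_t + b_h)

Weights are stored fused across gates — W_x is (C, G*H), W_h is (H, G*H),
b is (G*H,) with G the gate count — and sliced per gate on access, so the
step functions read exactly like the equations while training can use one
matmul per step.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit as sigmoid

GATE_ORDER = {
    "lstm": ("f", "i", "o", "g"),
    "gru": ("z", "r", "h"),
    "simple": ("h",),
}


@dataclass
class CellParams:
    """Fused gate parameters for one recurrent cell."""

    cell_type: str  # lstm | gru | simple
    W_x: np.ndarray  # (C, G*H)
    W_h: np.ndarray  # (H, G*H)
    b: np.ndarray  # (G*H,)
    hidden_size: int = field(init=False)

    def __post_init__(self) -> None:
        gates = GATE_ORDER[self.cell_type]
        H = self.W_h.shape[0]
        if self.W_x.shape[1] != len(gates) * H or self.W_h.shape != (H, len(gates) * H):
            raise ValueError("gate weight shapes inconsistent with hidden size")
        if self.b.shape != (len(gates) * H,):
            raise ValueError("bias shape inconsistent with hidden size")
        self.hidden_size = H

    @property
    def gates(self) -> tuple[str, ...]:
        return GATE_ORDER[self.cell_type]

    def _slice(self, gate: str) -> slice:
        i = self.gates.index(gate)
        H = self.hidden_size
        return slice(i * H, (i + 1) * H)

    def Wx(self, gate: str) -> np.ndarray:
        return self.W_x[:, self._slice(gate)]

    def Wh(self, gate: str) -> np.ndarray:
        return self.W_h[:, self._slice(gate)]

    def bias(self, gate: str) -> np.ndarray:
        return self.b[self._slice(gate)]


def init_cell_params(
    rng: np.random.Generator,
    cell_type: str,
    n_input: int,
    hidden_size: int,
    dtype=np.float32,
) -> CellParams:
    """Glorot-style uniform initialisation, seeded; biases start at zero."""
    G = len(GATE_ORDER[cell_type])
    lim_x = np.sqrt(6.0 / (n_input + hidden_size))
    lim_h = np.sqrt(6.0 / (hidden_size + hidden_size))
    W_x = rng.uniform(-lim_x, lim_x, size=(n_input, G * hidden_size)).astype(dtype)
    W_h = rng.uniform(-lim_h, lim_h, size=(hidden_size, G * hidden_size)).astype(dtype)
    b = np.zeros(G * hidden_size, dtype=dtype)
    return CellParams(cell_type=cell_type, W_x=W_x, W_h=W_h, b=b)


def _check_input(x: np.ndarray, h: np.ndarray, params: CellParams, gate: str) -> None:
    if x.shape[-1] != params.W_x.shape[0]:
        raise ValueError(f"input size {x.shape[-1]} != expected {params.W_x.shape[0]}")
    if h.shape[-1] != params.hidden_size:
        raise ValueError(f"hidden size {h.shape[-1]} != expected {params.hidden_size}")


def simple_rnn_step(x_t: np.ndarray, h_prev: np.ndarray, params: CellParams) -> np.ndarray:
    """h_t = tanh(W_h^T h_{t-1} + W_x^T x_t + b).  Accepts (C,) or (B, C)."""
    if params.cell_type != "simple":
        raise ValueError("params are not for a simple RNN cell")
    _check_input(x_t, h_prev, params, "h")
    return np.tanh(h_prev @ params.Wh("h") + x_t @ params.Wx("h") + params.bias("h"))


def lstm_step(
    x_t: np.ndarray,
    state_prev: tuple[np.ndarray, np.ndarray],
    params: CellParams,
) -> tuple[np.ndarray, np.ndarray]:
    """One LSTM step; state is (h, c).  Returns (h_t, c_t)."""
    if params.cell_type != "lstm":
        raise ValueError("params are not for an LSTM cell")
    h_prev, c_prev = state_prev
    _check_input(x_t, h_prev, params, "f")
    f = sigmoid(h_prev @ params.Wh("f") + x_t @ params.Wx("f") + params.bias("f"))
    i = sigmoid(h_prev @ params.Wh("i") + x_t @ params.Wx("i") + params.bias("i"))
    o = sigmoid(h_prev @ params.Wh("o") + x_t @ params.Wx("o") + params.bias("o"))
    g = np.tanh(h_prev @ params.Wh("g") + x_t @ params.Wx("g") + params.bias("g"))
    c = f * c_prev + i * g
    h = o * np.tanh(c)
    return h, c


def gru_step(x_t: np.ndarray, h_prev: np.ndarray, params: CellParams) -> np.ndarray:
    """One GRU step with the reset gate applied inside the candidate term."""
    if params.cell_type != "gru":
        raise ValueError("params are not for a GRU cell")
    _check_input(x_t, h_prev, params, "z")
    z = sigmoid(h_prev @ params.Wh("z") + x_t @ params.Wx("z") + params.bias("z"))
    r = sigmoid(h_prev @ params.Wh("r") + x_t @ params.Wx("r") + params.bias("r"))
    n = np.tanh((r * h_prev) @ params.Wh("h") + x_t @ params.Wx("h") + params.bias("h"))
    return (1.0 - z) * h_prev + z * n


def output_head(h: np.ndarray, W_y: np.ndarray, b_y: np.ndarray | None = None, kind: str = "softmax") -> np.ndarray:
    """Dense projection of the final hidden state to an inclusion probability.

    kind="softmax": W_y is (H, 2); returns the two-class probability vector
    (class order [skipped, included]).  kind="sigmoid": W_y is (H, 1);
    returns sigma(W_y^T h) as a scalar probability of inclusion.
    """
    logits = h @ W_y
    if b_y is not None:
        logits = logits + b_y
    if kind == "sigmoid":
        return sigmoid(logits)
    if kind != "softmax":
        raise ValueError(f"unknown head kind {kind!r}")
    shifted = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(shifted)
    return e / e.sum(axis=-1, keepdims=True)
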