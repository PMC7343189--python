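"""NumPy training engine: batched recurrent layers with backprop through
time, the two-branch network graph, and the Adam optimizer.

The per-step recurrences here are algebraically identical to the step
functions in :mod:`cosplice.cells` (the unit suite checks this); they are
restructured so the input projection for a whole sequence is one matmul
and only the hidden-to-hidden product stays inside the time loop.
"""

from __future__ import annotations

import numpy as np
from scipy.special import expit as sigmoid

from .cells import CellParams


class RecurrentLayer:
    """Shared plumbing for batched forward/backward over a sequence."""

    def __init__(self, params: CellParams):
        self.p = params

    def forward(self, X: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dH_ext: np.ndarray) -> tuple[np.ndarray, dict[str, np.ndarray]]:
        raise NotImplementedError

    def _input_grads(self, DA: np.ndarray, X: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Common gradient assembly: dW_x, b, dX from the accumulated
        pre-activation gradients DA of shape (B, T, G*H)."""
        B, T, GH = DA.shape
        Cin = X.shape[2]
        DA2 = DA.reshape(B * T, GH)
        dWx = X.reshape(B * T, Cin).T @ DA2
        db = DA2.sum(axis=0)
        dX = (DA2 @ self.p.W_x.T).reshape(B, T, Cin)
        return dWx, db, dX


class LSTMLayer(RecurrentLayer):
    def forward(self, X: np.ndarray) -> np.ndarray:
        p = self.p
        B, T, _ = X.shape
        H = p.hidden_size
        pre = X @ p.W_x + p.b  # (B, T, 4H)
        F = np.empty((B, T, H), dtype=X.dtype)
        I = np.empty_like(F)
        O = np.empty_like(F)
        G = np.empty_like(F)
        Cs = np.empty_like(F)
        Hs = np.empty_like(F)
        h = np.zeros((B, H), dtype=X.dtype)
        c = np.zeros((B, H), dtype=X.dtype)
        for t in range(T):
            a = pre[:, t] + h @ p.W_h
            sig = sigmoid(a[:, : 3 * H])  # f, i, o share the slice
            f = sig[:, :H]
            i = sig[:, H : 2 * H]
            o = sig[:, 2 * H :]
            g = np.tanh(a[:, 3 * H :])
            c = f * c + i * g
            h = o * np.tanh(c)
            F[:, t], I[:, t], O[:, t], G[:, t], Cs[:, t], Hs[:, t] = f, i, o, g, c, h
        self._cache = (X, F, I, O, G, Cs, Hs)
        return Hs

    def backward(self, dH_ext: np.ndarray):
        p = self.p
        X, F, I, O, G, Cs, Hs = self._cache
        B, T, H = F.shape
        TC = np.tanh(Cs)
        DA = np.empty((B, T, 4 * H), dtype=X.dtype)
        dh = np.zeros((B, H), dtype=X.dtype)
        dc = np.zeros((B, H), dtype=X.dtype)
        WhT = p.W_h.T
        for t in range(T - 1, -1, -1):
            dht = dH_ext[:, t] + dh
            o, tc = O[:, t], TC[:, t]
            do = dht * tc
            dc = dc + dht * o * (1.0 - tc * tc)
            c_prev = Cs[:, t - 1] if t > 0 else 0.0
            f, i, g = F[:, t], I[:, t], G[:, t]
            df = dc * c_prev
            di = dc * g
            dg = dc * i
            dc = dc * f
            DA[:, t, :H] = df * f * (1.0 - f)
            DA[:, t, H : 2 * H] = di * i * (1.0 - i)
            DA[:, t, 2 * H : 3 * H] = do * o * (1.0 - o)
            DA[:, t, 3 * H :] = dg * (1.0 - g * g)
            dh = DA[:, t] @ WhT
        H_prev = np.concatenate([np.zeros((B, 1, H), dtype=X.dtype), Hs[:, :-1]], axis=1)
        dWx, db, dX = self._input_grads(DA, X)
        dWh = H_prev.reshape(B * T, H).T @ DA.reshape(B * T, 4 * H)
        return dX, {"W_x": dWx, "W_h": dWh, "b": db}


class GRULayer(RecurrentLayer):
    def forward(self, X: np.ndarray) -> np.ndarray:
        p = self.p
        B, T, _ = X.shape
        H = p.hidden_size
        pre = X @ p.W_x + p.b  # (B, T, 3H)
        Whz = p.W_h[:, :H]
        Whr = p.W_h[:, H : 2 * H]
        Whh = p.W_h[:, 2 * H :]
        Z = np.empty((B, T, H), dtype=X.dtype)
        R = np.empty_like(Z)
        N = np.empty_like(Z)
        RH = np.empty_like(Z)
        Hs = np.empty_like(Z)
        h = np.zeros((B, H), dtype=X.dtype)
        for t in range(T):
            z = sigmoid(pre[:, t, :H] + h @ Whz)
            r = sigmoid(pre[:, t, H : 2 * H] + h @ Whr)
            rh = r * h
            n = np.tanh(pre[:, t, 2 * H :] + rh @ Whh)
            Z[:, t], R[:, t], N[:, t], RH[:, t] = z, r, n, rh
            h = (1.0 - z) * h + z * n
            Hs[:, t] = h
        self._cache = (X, Z, R, N, RH, Hs)
        return Hs

    def backward(self, dH_ext: np.ndarray):
        p = self.p
        X, Z, R, N, RH, Hs = self._cache
        B, T, H = Z.shape
        Whz = p.W_h[:, :H]
        Whr = p.W_h[:, H : 2 * H]
        Whh = p.W_h[:, 2 * H :]
        DA = np.empty((B, T, 3 * H), dtype=X.dtype)
        dh_rec = np.zeros((B, H), dtype=X.dtype)
        for t in range(T - 1, -1, -1):
            dh = dH_ext[:, t] + dh_rec
            z, r, n = Z[:, t], R[:, t], N[:, t]
            h_prev = Hs[:, t - 1] if t > 0 else np.zeros_like(dh)
            dz = dh * (n - h_prev)
            dn = dh * z
            dh_prev = dh * (1.0 - z)
            dan = dn * (1.0 - n * n)
            drh = dan @ Whh.T
            dr = drh * h_prev
            dh_prev = dh_prev + drh * r
            daz = dz * z * (1.0 - z)
            dar = dr * r * (1.0 - r)
            dh_prev = dh_prev + daz @ Whz.T + dar @ Whr.T
            DA[:, t, :H] = daz
            DA[:, t, H : 2 * H] = dar
            DA[:, t, 2 * H :] = dan
            dh_rec = dh_prev
        H_prev = np.concatenate([np.zeros((B, 1, H), dtype=X.dtype), Hs[:, :-1]], axis=1)
        dWx, db, dX = self._input_grads(DA, X)
        BT = B * T
        dWh = np.empty_like(p.W_h)
        dWh[:, : 2 * H] = H_prev.reshape(BT, H).T @ DA[:, :, : 2 * H].reshape(BT, 2 * H)
        dWh[:, 2 * H :] = RH.reshape(BT, H).T @ DA[:, :, 2 * H :].reshape(BT, H)
        return dX, {"W_x": dWx, "W_h": dWh, "b": db}


class SimpleRNNLayer(RecurrentLayer):
    def forward(self, X: np.ndarray) -> np.ndarray:
        p = self.p
        B, T, _ = X.shape
        H = p.hidden_size
        pre = X @ p.W_x + p.b
        Hs = np.empty((B, T, H), dtype=X.dtype)
        h = np.zeros((B, H), dtype=X.dtype)
        for t in range(T):
            h = np.tanh(pre[:, t] + h @ p.W_h)
            Hs[:, t] = h
        self._cache = (X, Hs)
        return Hs

    def backward(self, dH_ext: np.ndarray):
        p = self.p
        X, Hs = self._cache
        B, T, H = Hs.shape
        DA = np.empty((B, T, H), dtype=X.dtype)
        dh = np.zeros((B, H), dtype=X.dtype)
        WhT = p.W_h.T
        for t in range(T - 1, -1, -1):
            dht = dH_ext[:, t] + dh
            h = Hs[:, t]
            DA[:, t] = dht * (1.0 - h * h)
            dh = DA[:, t] @ WhT
        H_prev = np.concatenate([np.zeros((B, 1, H), dtype=X.dtype), Hs[:, :-1]], axis=1)
        dWx, db, dX = self._input_grads(DA, X)
        dWh = H_prev.reshape(B * T, H).T @ DA.reshape(B * T, H)
        return dX, {"W_x": dWx, "W_h": dWh, "b": db}


LAYER_TYPES = {"lstm": LSTMLayer, "gru": GRULayer, "simple": SimpleRNNLayer}


class TwoBranchNet:
    """Acceptor and donor branch RNNs feeding a merge RNN and a dense head.

    The branch hidden-state sequences are concatenated along the position
    axis (acceptor first) by default, so the merge layer reads the full
    event in transcription order; ``merge_mode="feature"`` concatenates
    along the feature axis instead.
    """

    def __init__(
        self,
        branch_acc: CellParams,
        branch_don: CellParams,
        merge: CellParams,
        W_y: np.ndarray,
        b_y: np.ndarray,
        merge_mode: str = "time",
        head: str = "softmax",
    ):
        if merge_mode not in ("time", "feature"):
            raise ValueError(f"unknown merge mode {merge_mode!r}")
        if head not in ("softmax", "sigmoid"):
            raise ValueError(f"unknown head {head!r}")
        self.branch_acc = branch_acc
        self.branch_don = branch_don
        self.merge = merge
        self.W_y = W_y
        self.b_y = b_y
        self.merge_mode = merge_mode
        self.head = head
        self._layer_cls = LAYER_TYPES[merge.cell_type]
        self._branch_cls = LAYER_TYPES[branch_acc.cell_type]

    # --- parameter bookkeeping -------------------------------------------

    def param_list(self) -> list[np.ndarray]:
        out = []
        for cp in (self.branch_acc, self.branch_don, self.merge):
            out += [cp.W_x, cp.W_h, cp.b]
        out += [self.W_y, self.b_y]
        return out

    # --- forward / backward ----------------------------------------------

    def forward(
        self,
        X_acc: np.ndarray,
        X_don: np.ndarray,
        dropout_mask: np.ndarray | None = None,
    ) -> np.ndarray:
        la = self._branch_cls(self.branch_acc)
        ld = self._branch_cls(self.branch_don)
        lm = self._layer_cls(self.merge)
        Ha = la.forward(X_acc)
        Hd = ld.forward(X_don)
        if self.merge_mode == "time":
            Hm_in = np.concatenate([Ha, Hd], axis=1)
        else:
            Hm_in = np.concatenate([Ha, Hd], axis=2)
        Hm = lm.forward(Hm_in)
        h_last = Hm[:, -1, :]
        if dropout_mask is not None:
            h_last = h_last * dropout_mask
        logits = h_last @ self.W_y + self.b_y
        if self.head == "softmax":
            shifted = logits - logits.max(axis=1, keepdims=True)
            e = np.exp(shifted)
            probs = e / e.sum(axis=1, keepdims=True)
            p_incl = probs[:, 1]
        else:
            p_incl = sigmoid(logits[:, 0])
            probs = p_incl
        self._cache = (la, ld, lm, Hm.shape, h_last, probs, dropout_mask, X_acc.shape[1])
        return p_incl

    def backward(self, y: np.ndarray) -> dict[str, np.ndarray | dict]:
        """Gradients of mean binary cross-entropy w.r.t. all parameters.

        Call after :meth:`forward`; ``y`` holds 0/1 labels for the batch.
        """
        la, ld, lm, Hm_shape, h_last, probs, dropout_mask, T_acc = self._cache
        B = y.shape[0]
        if self.head == "softmax":
            dlogits = probs.copy()
            dlogits[np.arange(B), y] -= 1.0
            dlogits /= B
        else:
            dlogits = ((probs - y) / B).reshape(B, 1).astype(h_last.dtype)
        dW_y = h_last.T @ dlogits
        db_y = dlogits.sum(axis=0)
        dh_last = dlogits @ self.W_y.T
        if dropout_mask is not None:
            dh_last = dh_last * dropout_mask
        dHm = np.zeros(Hm_shape, dtype=h_last.dtype)
        dHm[:, -1, :] = dh_last
        dHm_in, g_merge = lm.backward(dHm)
        if self.merge_mode == "time":
            dHa, dHd = dHm_in[:, :T_acc], dHm_in[:, T_acc:]
        else:
            H1 = self.branch_acc.hidden_size
            dHa, dHd = dHm_in[:, :, :H1], dHm_in[:, :, H1:]
        _, g_acc = la.backward(np.ascontiguousarray(dHa))
        _, g_don = ld.backward(np.ascontiguousarray(dHd))
        return {
            "branch_acc": g_acc,
            "branch_don": g_don,
            "merge": g_merge,
            "W_y": dW_y,
            "b_y": db_y,
        }

    def grad_list(self, grads: dict) -> list[np.ndarray]:
        out = []
        for key in ("branch_acc", "branch_don", "merge"):
            g = grads[key]
            out += [g["W_x"], g["W_h"], g["b"]]
        out += [grads["W_y"], grads["b_y"]]
        return out

    def loss(self, p_incl: np.ndarray, y: np.ndarray, eps: float = 1e-7) -> float:
        """Mean binary cross-entropy of the inclusion probability."""
        p = np.clip(p_incl, eps, 1.0 - eps)
        return float(-(y * np.log(p) + (1 - y) * np.log(1.0 - p)).mean())


class Adam:
    """Adam over a fixed list of parameter arrays (updated in place)."""

    def __init__(self, params: list[np.ndarray], lr: float = 1e-3, beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads: list[np.ndarray]) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bias1 = 1.0 - b1**self.t
        bias2 = 1.0 - b2**self.t
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m *= b1
            m += (1.0 - b1) * g
            v *= b2
            v += (1.0 - b2) * g * g
            p -= self.lr * (m / bias1) / (np.sqrt(v / bias2) + self.eps)
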