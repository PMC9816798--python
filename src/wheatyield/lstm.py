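"""A small sequence-to-scalar LSTM regressor in pure numpy.

The recurrent cell follows the standard gated update

    i_t = sigmoid(W_ih h_{t-1} + W_ix x_t + b_i)
    f_t = sigmoid(W_fh h_{t-1} + W_fx x_t + b_f)
    g_t = tanh   (W_gh h_{t-1} + W_gx x_t + b_g)
    c_t = i_t * g_t + f_t * c_{t-1}
    o_t = sigmoid(W_oh h_{t-1} + W_ox x_t + b_o)
    h_t = o_t * tanh(c_t)

with elementwise (Hadamard) products.  The regressor stacks two such
layers, applies ReLU to the final hidden state, then a dense head;
dropout is applied between the layers and before the head during
training.  Training is full backpropagation through time with Adam
and L2 weight decay, minimizing mean squared error.

The implementation is deliberately compact: feature counts here are
tiny (4 indices x 9 months), so dense numpy matmuls are fast enough
and the whole training loop stays inspectable.
"""

from __future__ import annotations

import numpy as np

__all__ = ["lstm_cell_step", "LSTMLayer", "LSTMRegressor"]


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-x))


def lstm_cell_step(x_t, h_prev, c_prev, W_x, W_h, b):
    """One LSTM cell step; gate order along the last axis is [i, f, g, o].

    ``W_x`` is (n_in, 4H), ``W_h`` is (H, 4H), ``b`` is (4H,).  Returns
    (h_t, c_t).  This is the reference evaluation of the gate
    equations, used directly by the layer forward pass.
    """
    H = h_prev.shape[-1]
    z = x_t @ W_x + h_prev @ W_h + b
    i = _sigmoid(z[..., :H])
    f = _sigmoid(z[..., H : 2 * H])
    g = np.tanh(z[..., 2 * H : 3 * H])
    o = _sigmoid(z[..., 3 * H :])
    c = i * g + f * c_prev
    h = o * np.tanh(c)
    return h, c


class LSTMLayer:
    """A single LSTM layer over (batch, time, features) input."""

    def __init__(self, n_in: int, n_units: int, rng: np.random.Generator):
        self.n_in, self.n_units = n_in, n_units
        lim_x = np.sqrt(6.0 / (n_in + n_units))
        lim_h = np.sqrt(6.0 / (2 * n_units))
        self.W_x = rng.uniform(-lim_x, lim_x, size=(n_in, 4 * n_units))
        self.W_h = rng.uniform(-lim_h, lim_h, size=(n_units, 4 * n_units))
        self.b = np.zeros(4 * n_units)
        self.b[n_units : 2 * n_units] = 1.0  # forget-gate bias
        self._cache = None

    @property
    def params(self):
        return [self.W_x, self.W_h, self.b]

    def forward(self, x: np.ndarray) -> np.ndarray:
        """Run the cell over time; returns the full hidden sequence."""
        B, T, _ = x.shape
        H = self.n_units
        h = np.zeros((B, H))
        c = np.zeros((B, H))
        hs = np.empty((B, T, H))
        cache = []
        for t in range(T):
            x_t = x[:, t, :]
            z = x_t @ self.W_x + h @ self.W_h + self.b
            i = _sigmoid(z[:, :H])
            f = _sigmoid(z[:, H : 2 * H])
            g = np.tanh(z[:, 2 * H : 3 * H])
            o = _sigmoid(z[:, 3 * H :])
            c_new = i * g + f * c
            tc = np.tanh(c_new)
            h_new = o * tc
            cache.append((x_t, h, c, i, f, g, o, c_new, tc))
            h, c = h_new, c_new
            hs[:, t, :] = h
        self._cache = cache
        return hs

    def backward(self, dh_seq: np.ndarray):
        """BPTT given gradients w.r.t. each output hidden state.

        Returns gradient w.r.t. the input sequence and stores
        (dW_x, dW_h, db) on the layer.
        """
        cache = self._cache
        B, T, _ = dh_seq.shape
        H = self.n_units
        dW_x = np.zeros_like(self.W_x)
        dW_h = np.zeros_like(self.W_h)
        db = np.zeros_like(self.b)
        dx_seq = np.empty((B, T, self.n_in))
        dh_next = np.zeros((B, H))
        dc_next = np.zeros((B, H))
        for t in range(T - 1, -1, -1):
            x_t, h_prev, c_prev, i, f, g, o, c_new, tc = cache[t]
            dh = dh_seq[:, t, :] + dh_next
            do = dh * tc
            dc = dh * o * (1.0 - tc**2) + dc_next
            di = dc * g
            dg = dc * i
            df = dc * c_prev
            dc_next = dc * f
            dz = np.concatenate(
                [
                    di * i * (1.0 - i),
                    df * f * (1.0 - f),
                    dg * (1.0 - g**2),
                    do * o * (1.0 - o),
                ],
                axis=1,
            )
            dW_x += x_t.T @ dz
            dW_h += h_prev.T @ dz
            db += dz.sum(axis=0)
            dx_seq[:, t, :] = dz @ self.W_x.T
            dh_next = dz @ self.W_h.T
        self.grads = [dW_x, dW_h, db]
        return dx_seq


class _Adam:
    def __init__(self, params, lr, beta1=0.9, beta2=0.999, eps=1e-8):
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads):
        self.t += 1
        lr_t = self.lr * np.sqrt(1 - self.b2**self.t) / (1 - self.b1**self.t)
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            p -= lr_t * m / (np.sqrt(v) + self.eps)


class LSTMRegressor:
    """Stacked-LSTM scalar regressor with dropout and L2 weight decay.

    Architecture: ``n_layers`` LSTM layers of ``hidden_units`` each
    (full sequences passed between layers), ReLU on the last hidden
    state, then a dense layer to one output.  Inputs and targets are
    z-scored with statistics from the training call; predictions are
    returned on the original scale.
    """

    def __init__(
        self,
        n_features: int,
        hidden_units: int = 100,
        n_layers: int = 2,
        dropout: float = 0.3,
        l2_lambda: float = 1e-4,
        learning_rate: float = 1e-3,
        batch_size: int = 64,
        epochs: int = 700,
        seed: int = 0,
    ):
        self.n_features = n_features
        self.hidden = hidden_units
        self.dropout = dropout
        self.l2 = l2_lambda
        self.lr = learning_rate
        self.batch_size = batch_size
        self.epochs = epochs
        self.rng = np.random.default_rng(seed)
        self.layers = []
        n_in = n_features
        for _ in range(n_layers):
            self.layers.append(LSTMLayer(n_in, hidden_units, self.rng))
            n_in = hidden_units
        lim = np.sqrt(6.0 / (hidden_units + 1))
        self.W_out = self.rng.uniform(-lim, lim, size=(hidden_units, 1))
        self.b_out = np.zeros(1)
        self.training_log: list[tuple[int, float]] = []
        self._fitted = False

    # -- internals ----------------------------------------------------
    def _params(self):
        ps = []
        for layer in self.layers:
            ps.extend(layer.params)
        ps.extend([self.W_out, self.b_out])
        return ps

    def _forward(self, x: np.ndarray, train: bool):
        h = x
        masks = []
        for layer in self.layers[:-1]:
            h = layer.forward(h)
            if train and self.dropout > 0:
                m = (self.rng.random(h.shape) >= self.dropout) / (1 - self.dropout)
                h = h * m
                masks.append(m)
            else:
                masks.append(None)
        h_seq = self.layers[-1].forward(h)
        h_last = h_seq[:, -1, :]
        relu = np.maximum(h_last, 0.0)
        if train and self.dropout > 0:
            m_head = (self.rng.random(relu.shape) >= self.dropout) / (1 - self.dropout)
            relu_d = relu * m_head
        else:
            m_head = None
            relu_d = relu
        yhat = relu_d @ self.W_out + self.b_out
        cache = (masks, h_last, relu, m_head, relu_d, h_seq.shape)
        return yhat[:, 0], cache

    def _backward(self, x, yhat, y, cache):
        masks, h_last, relu, m_head, relu_d, seq_shape = cache
        B = y.shape[0]
        dyhat = (2.0 / B) * (yhat - y)[:, None]
        dW_out = relu_d.T @ dyhat
        db_out = dyhat.sum(axis=0)
        drelu_d = dyhat @ self.W_out.T
        drelu = drelu_d * m_head if m_head is not None else drelu_d
        dh_last = drelu * (h_last > 0)
        dh_seq = np.zeros(seq_shape)
        dh_seq[:, -1, :] = dh_last
        d = self.layers[-1].backward(dh_seq)
        for layer, m in zip(reversed(self.layers[:-1]), reversed(masks)):
            if m is not None:
                d = d * m
            d = layer.backward(d)
        grads = []
        for layer in self.layers:
            gx, gh, gb = layer.grads
            grads.extend(
                [gx + 2 * self.l2 * layer.W_x, gh + 2 * self.l2 * layer.W_h, gb]
            )
        grads.extend([dW_out + 2 * self.l2 * self.W_out, db_out])
        return grads

    # -- public API ---------------------------------------------------
    def fit(self, X: np.ndarray, y: np.ndarray) -> "LSTMRegressor":
        """Train on sequences X (n, T, F) and targets y (n,), in t/ha."""
        X = np.asarray(X, float)
        y = np.asarray(y, float)
        if X.ndim != 3 or X.shape[2] != self.n_features:
            raise ValueError(
                f"expected sequences (n, T, {self.n_features}), got {X.shape}"
            )
        self.x_mean = X.mean(axis=(0, 1))
        self.x_sd = X.std(axis=(0, 1))
        self.x_sd = np.where(self.x_sd < 1e-12, 1.0, self.x_sd)
        self.y_mean = y.mean()
        self.y_sd = y.std() if y.std() > 1e-12 else 1.0
        Xs = (X - self.x_mean) / self.x_sd
        ys = (y - self.y_mean) / self.y_sd

        n = Xs.shape[0]
        opt = _Adam(self._params(), self.lr)
        self.training_log = []
        for epoch in range(self.epochs):
            order = self.rng.permutation(n)
            losses = []
            for start in range(0, n, self.batch_size):
                idx = order[start : start + self.batch_size]
                xb, yb = Xs[idx], ys[idx]
                yhat, cache = self._forward(xb, train=True)
                loss = float(np.mean((yhat - yb) ** 2))
                if not np.isfinite(loss):
                    raise RuntimeError(
                        f"training diverged: non-finite loss at epoch {epoch}"
                    )
                grads = self._backward(xb, yhat, yb, cache)
                opt.step(grads)
                losses.append(loss)
            self.training_log.append((epoch, float(np.mean(losses))))
        self._fitted = True
        return self

    def predict(self, X: np.ndarray) -> np.ndarray:
        """Predict yields (t/ha) for sequences X (n, T, F)."""
        if not self._fitted:
            raise RuntimeError("model is not fitted")
        X = np.asarray(X, float)
        if X.ndim != 3 or X.shape[2] != self.n_features:
            raise ValueError(
                f"expected sequences (n, T, {self.n_features}), got {X.shape}"
            )
        Xs = (X - self.x_mean) / self.x_sd
        yhat, _ = self._forward(Xs, train=False)
        return yhat * self.y_sd + self.y_mean
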