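"""Cascade feed-forward network regressor.

A 12-block (by default) feed-forward network with dense skip connectivity:
block ``i`` receives the standardized inputs concatenated with the outputs of
all previous blocks, and the linear output head sees the inputs plus every
block's output.  This is the standard reading of a "cascade" network.  Because
the raw inputs reach the output head directly, the network nests ordinary
linear regression; after gradient training the head is re-solved exactly by
ridge least squares, which guarantees the fit is never worse than the best
linear readout of the learned representation.

Training is full-batch Adam on squared error with early stopping on an
internal validation split.  Everything is seeded and deterministic.
"""

from __future__ import annotations

import numpy as np

from .errors import ValidationError

__all__ = ["CascadeNetRegressor"]


class CascadeNetRegressor:
    """Cascade network mapping a feature vector to an age estimate.

    Parameters
    ----------
    n_blocks : number of hidden blocks (depth of the cascade).
    width : units per block, tanh activation.
    learning_rate, max_epochs, patience, val_fraction : Adam / early-stopping
        controls.  ``patience`` counts epochs without validation improvement.
    l2 : weight decay applied to all weights (not biases).
    refit_head : if True (default), re-solve the linear output head by ridge
        least squares on the full training set after gradient training.
    seed : controls initialization and the validation split.
    """

    def __init__(self, n_blocks: int = 12, width: int = 16,
                 learning_rate: float = 0.01, max_epochs: int = 400,
                 patience: int = 30, val_fraction: float = 0.1,
                 l2: float = 1e-4, refit_head: bool = True, seed: int = 0):
        self.n_blocks = int(n_blocks)
        self.width = int(width)
        self.learning_rate = float(learning_rate)
        self.max_epochs = int(max_epochs)
        self.patience = int(patience)
        self.val_fraction = float(val_fraction)
        self.l2 = float(l2)
        self.refit_head = bool(refit_head)
        self.seed = int(seed)
        self._fitted = False

    # -- forward ---------------------------------------------------------

    def _forward(self, X, params):
        """Return (prediction, block activations)."""
        Ws, bs, w_out, b_out = params
        C = X
        hs = []
        for W, b in zip(Ws, bs):
            h = np.tanh(C @ W + b)
            hs.append(h)
            C = np.concatenate([C, h], axis=1)
        yhat = C @ w_out + b_out
        return yhat, hs, C

    def _init_params(self, p, rng):
        Ws, bs = [], []
        fan_in = p
        for _ in range(self.n_blocks):
            # Xavier-style init scaled by the growing fan-in
            Ws.append(rng.normal(0.0, np.sqrt(1.0 / fan_in), size=(fan_in, self.width)))
            bs.append(np.zeros(self.width))
            fan_in += self.width
        w_out = rng.normal(0.0, np.sqrt(1.0 / fan_in), size=fan_in)
        return Ws, bs, w_out, 0.0

    def _grads(self, X, y, params):
        Ws, bs, w_out, b_out = params
        n, p = X.shape
        yhat, hs, C = self._forward(X, params)
        r = (yhat - y) / n
        gw_out = C.T @ r + self.l2 * w_out
        gb_out = r.sum()
        # accumulate gradient flowing into each column-block of C
        # C layout: [X | h_1 | ... | h_L]
        gC = np.outer(r, w_out)
        offsets = [p + i * self.width for i in range(self.n_blocks)]
        gWs = [None] * self.n_blocks
        gbs = [None] * self.n_blocks
        for i in range(self.n_blocks - 1, -1, -1):
            o = offsets[i]
            gh = gC[:, o:o + self.width]
            dZ = gh * (1.0 - hs[i] ** 2)
            C_prev_w = o  # columns of C feeding block i
            gWs[i] = C[:, :C_prev_w].T @ dZ + self.l2 * Ws[i]
            gbs[i] = dZ.sum(axis=0)
            gC[:, :C_prev_w] += dZ @ Ws[i].T
        loss = 0.5 * np.mean((yhat - y) ** 2)
        return (gWs, gbs, gw_out, gb_out), loss

    # -- sklearn-style API ----------------------------------------------

    def fit(self, X, y):
        X = np.asarray(X, float)
        y = np.asarray(y, float).ravel()
        n, p = X.shape
        if n < 10:
            raise ValidationError("cascade network needs at least 10 subjects")
        rng = np.random.default_rng(self.seed)
        self._y_mean = y.mean()
        self._y_scale = y.std() or 1.0
        ys = (y - self._y_mean) / self._y_scale

        n_val = max(2, int(round(self.val_fraction * n)))
        perm = rng.permutation(n)
        val_idx, tr_idx = perm[:n_val], perm[n_val:]
        Xtr, ytr = X[tr_idx], ys[tr_idx]
        Xval, yval = X[val_idx], ys[val_idx]

        params = self._init_params(p, rng)
        flat = self._flatten(params)
        m = np.zeros_like(flat)
        v = np.zeros_like(flat)
        beta1, beta2, eps = 0.9, 0.999, 1e-8
        best_val = np.inf
        best_flat = flat.copy()
        since_best = 0
        for t in range(1, self.max_epochs + 1):
            params = self._unflatten(flat, p)
            grads, _ = self._grads(Xtr, ytr, params)
            g = self._flatten(grads)
            m = beta1 * m + (1 - beta1) * g
            v = beta2 * v + (1 - beta2) * g ** 2
            mhat = m / (1 - beta1 ** t)
            vhat = v / (1 - beta2 ** t)
            flat = flat - self.learning_rate * mhat / (np.sqrt(vhat) + eps)
            yv, _, _ = self._forward(Xval, self._unflatten(flat, p))
            val_loss = np.mean((yv - yval) ** 2)
            if val_loss < best_val - 1e-9:
                best_val = val_loss
                best_flat = flat.copy()
                since_best = 0
            else:
                since_best += 1
                if since_best >= self.patience:
                    break
        params = self._unflatten(best_flat, p)

        if self.refit_head:
            _, _, C = self._forward(X, params)
            A = np.column_stack([np.ones(n), C])
            lam = 1e-6 * n
            reg = lam * np.eye(A.shape[1])
            reg[0, 0] = 0.0
            coef = np.linalg.solve(A.T @ A + reg, A.T @ ys)
            params = (params[0], params[1], coef[1:], coef[0])

        self._params = params
        self._n_inputs = p
        self._fitted = True
        return self

    def predict(self, X):
        if not self._fitted:
            raise ValidationError("CascadeNetRegressor is not fitted")
        X = np.asarray(X, float)
        if X.shape[1] != self._n_inputs:
            raise ValidationError(
                f"expected {self._n_inputs} inputs, got {X.shape[1]}")
        yhat, _, _ = self._forward(X, self._params)
        return yhat * self._y_scale + self._y_mean

    # -- parameter vector plumbing ---------------------------------------

    def _flatten(self, params):
        Ws, bs, w_out, b_out = params
        parts = [w.ravel() for w in Ws] + list(bs) + [np.asarray(w_out).ravel(),
                                                      np.atleast_1d(b_out)]
        return np.concatenate(parts)

    def _unflatten(self, flat, p):
        Ws, bs = [], []
        pos = 0
        fan_in = p
        for _ in range(self.n_blocks):
            size = fan_in * self.width
            Ws.append(flat[pos:pos + size].reshape(fan_in, self.width))
            pos += size
            fan_in += self.width
        for _ in range(self.n_blocks):
            bs.append(flat[pos:pos + self.width])
            pos += self.width
        w_out = flat[pos:pos + fan_in]
        pos += fan_in
        b_out = float(flat[pos])
        return Ws, bs, w_out, b_out

    def get_params(self, deep=True):  # sklearn-compatible plumbing
        return {k: getattr(self, k) for k in
                ("n_blocks", "width", "learning_rate", "max_epochs", "patience",
                 "val_fraction", "l2", "refit_head", "seed")}

    def set_params(self, **kw):
        for k, v in kw.items():
            setattr(self, k, v)
        return self
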