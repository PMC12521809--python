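"""Minimal seeded feed-forward network engine (full-batch Adam, ReLU, masks).

This is the training core behind the regression and explainable-network
estimators: linear layers with ReLU between them, mean-squared-error loss,
full-batch Adam updates, and optional binary connectivity masks.  Masks are
enforced multiplicatively on both weights and gradients, so a masked-zero
weight is exactly zero after initialization and after every optimizer step —
the sparsity pattern is a hard structural constraint, not a penalty.

Weights are initialized with a seeded uniform fan-in scheme,
U(-1/sqrt(fan_in), 1/sqrt(fan_in)); biases start at a small positive
constant so every rectified unit is initially active — with sparse (masked)
fan-in a zero-centered start leaves many units dead from the first epoch.
"""

from __future__ import annotations

from typing import Callable, Sequence

import numpy as np


class MLP:
    """Feed-forward net: linear layers with ReLU after every hidden layer.

    Parameters
    ----------
    sizes : layer widths, input first, output last (output width 1 for the
        regressors here, but any width works).
    masks : optional per-layer binary arrays of shape (fan_in, fan_out); a
        ``None`` entry means the layer is dense.
    relu_output_of : number of leading layers followed by ReLU (default: all
        but the last, i.e. the final layer is a linear readout).
    """

    def __init__(
        self,
        sizes: Sequence[int],
        masks: Sequence[np.ndarray | None] | None = None,
        seed: int = 0,
    ):
        if len(sizes) < 2:
            raise ValueError("need at least input and output layer sizes")
        self.sizes = [int(s) for s in sizes]
        n_layers = len(sizes) - 1
        if masks is None:
            masks = [None] * n_layers
        if len(masks) != n_layers:
            raise ValueError("one mask slot per layer required")
        self.masks: list[np.ndarray | None] = []
        for li, m in enumerate(masks):
            if m is not None:
                m = np.asarray(m, dtype=float)
                if m.shape != (self.sizes[li], self.sizes[li + 1]):
                    raise ValueError(
                        f"mask {li} shape {m.shape} != {(self.sizes[li], self.sizes[li + 1])}"
                    )
            self.masks.append(m)
        rng = np.random.default_rng(seed)
        self.W: list[np.ndarray] = []
        self.b: list[np.ndarray] = []
        for li in range(n_layers):
            fan_in = self.sizes[li]
            bound = 1.0 / np.sqrt(fan_in)
            w = rng.uniform(-bound, bound, size=(fan_in, self.sizes[li + 1]))
            if self.masks[li] is not None:
                w *= self.masks[li]
            self.W.append(w)
            self.b.append(np.full(self.sizes[li + 1], 0.1))
        self._adam_state: dict | None = None

    # ------------------------------------------------------------------ forward
    def forward(self, X: np.ndarray, return_hidden: bool = False):
        """Forward pass; optionally return post-activation values per layer."""
        a = np.asarray(X, dtype=float)
        hidden = []
        last = len(self.W) - 1
        for li, (w, b) in enumerate(zip(self.W, self.b)):
            a = a @ w + b
            if li < last:
                a = np.maximum(a, 0.0)
                hidden.append(a)
        return (a, hidden) if return_hidden else a

    def predict(self, X: np.ndarray) -> np.ndarray:
        out = self.forward(X)
        return out[:, 0] if out.shape[1] == 1 else out

    # ----------------------------------------------------------------- backward
    def _backprop(self, X: np.ndarray, y: np.ndarray):
        """Gradients of the MSE loss w.r.t. all weights and biases."""
        n = X.shape[0]
        zs, acts = [], [np.asarray(X, dtype=float)]
        a = acts[0]
        last = len(self.W) - 1
        for li, (w, b) in enumerate(zip(self.W, self.b)):
            z = a @ w + b
            zs.append(z)
            a = np.maximum(z, 0.0) if li < last else z
            acts.append(a)
        delta = 2.0 * (acts[-1] - y.reshape(n, -1)) / n  # dL/d(output)
        gW = [None] * len(self.W)
        gb = [None] * len(self.W)
        for li in range(last, -1, -1):
            gW[li] = acts[li].T @ delta
            gb[li] = delta.sum(axis=0)
            if self.masks[li] is not None:
                gW[li] *= self.masks[li]
            if li > 0:
                delta = (delta @ self.W[li].T) * (zs[li - 1] > 0)
        return gW, gb

    def input_gradient(self, X: np.ndarray) -> np.ndarray:
        """d(output)/d(input) for a width-1 output, one row per sample."""
        if self.sizes[-1] != 1:
            raise ValueError("input_gradient requires a scalar output")
        X = np.asarray(X, dtype=float)
        zs = []
        a = X
        last = len(self.W) - 1
        for li, (w, b) in enumerate(zip(self.W, self.b)):
            z = a @ w + b
            zs.append(z)
            a = np.maximum(z, 0.0) if li < last else z
        grad = np.ones((X.shape[0], 1))
        for li in range(last, -1, -1):
            if li < last:
                grad = grad * (zs[li] > 0)
            grad = grad @ self.W[li].T
        return grad

    # ---------------------------------------------------------------- training
    def fit(
        self,
        X: np.ndarray,
        y: np.ndarray,
        lr: float = 1e-6,
        epochs: int = 2500,
        betas: tuple[float, float] = (0.9, 0.999),
        eps: float = 1e-8,
        callback: Callable[[int, "MLP"], None] | None = None,
    ) -> np.ndarray:
        """Full-batch Adam on the MSE loss; returns the per-epoch loss curve."""
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float).reshape(len(X), -1)
        if not (np.all(np.isfinite(X)) and np.all(np.isfinite(y))):
            raise ValueError("non-finite training inputs")
        b1, b2 = betas
        mW = [np.zeros_like(w) for w in self.W]
        vW = [np.zeros_like(w) for w in self.W]
        mB = [np.zeros_like(b) for b in self.b]
        vB = [np.zeros_like(b) for b in self.b]
        losses = np.empty(epochs)
        for t in range(1, epochs + 1):
            gW, gb = self._backprop(X, y)
            corr1 = 1.0 - b1**t
            corr2 = 1.0 - b2**t
            for li in range(len(self.W)):
                mW[li] = b1 * mW[li] + (1 - b1) * gW[li]
                vW[li] = b2 * vW[li] + (1 - b2) * gW[li] ** 2
                step = lr * (mW[li] / corr1) / (np.sqrt(vW[li] / corr2) + eps)
                if self.masks[li] is not None:
                    step *= self.masks[li]
                self.W[li] -= step
                mB[li] = b1 * mB[li] + (1 - b1) * gb[li]
                vB[li] = b2 * vB[li] + (1 - b2) * gb[li] ** 2
                self.b[li] -= lr * (mB[li] / corr1) / (np.sqrt(vB[li] / corr2) + eps)
            resid = self.forward(X) - y
            losses[t - 1] = float(np.mean(resid**2))
            if callback is not None:
                callback(t, self)
        return losses

    def n_parameters(self, nonzero_only: bool = False) -> int:
        total = 0
        for li, w in enumerate(self.W):
            if nonzero_only and self.masks[li] is not None:
                total += int(self.masks[li].sum())
            else:
                total += w.size
            total += self.b[li].size
        return total
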