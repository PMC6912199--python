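"""Shallow symmetric autoencoder for compressing similarity pair vectors.

The similarity-based pair vector concatenates a disease's row of the DS
matrix with a miRNA's row of the RS matrix (913-dimensional at the
336-disease / 577-miRNA scale), which is large and sparse; the encoder
maps it to a dense low-dimensional code (256 by default, layer widths
913-512-256 mirrored in the decoder).

Implementation: fully-connected layers with ReLU hidden activations and a
linear output, trained to minimise mean squared reconstruction error with
Adam.  Inputs are min-max scaled per coordinate to [0, 1] before training;
the fitted scaler is applied to later inputs.  All initialisation is
seeded, so training is reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["AutoencoderSpec", "Autoencoder"]


@dataclass(frozen=True)
class AutoencoderSpec:
    """Layer widths and training hyperparameters.

    ``hidden``/``latent`` give encoder widths (input, hidden, latent); the
    decoder mirrors them.  Defaults follow the 913-512-256 layout.
    """

    input_dim: int = 913
    hidden: int = 512
    latent: int = 256
    epochs: int = 100
    batch_size: int = 64
    learning_rate: float = 1e-3
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.input_dim, self.hidden, self.latent) < 1:
            raise ValueError("layer widths must be positive")
        if self.epochs < 0 or self.learning_rate <= 0:
            raise ValueError("epochs >= 0 and learning_rate > 0 required")


def _relu(x: np.ndarray) -> np.ndarray:
    return np.maximum(x, 0.0)


class Autoencoder:
    """Encoder 'input-hidden-latent', decoder mirrored; MSE + Adam."""

    def __init__(self, spec: AutoencoderSpec):
        self.spec = spec
        rng = np.random.default_rng(spec.seed)
        widths = [spec.input_dim, spec.hidden, spec.latent, spec.hidden, spec.input_dim]
        self.weights: list[np.ndarray] = []
        self.biases: list[np.ndarray] = []
        for fan_in, fan_out in zip(widths[:-1], widths[1:]):
            scale = np.sqrt(2.0 / fan_in)  # He init for the ReLU stack
            self.weights.append(rng.normal(0.0, scale, size=(fan_in, fan_out)))
            self.biases.append(np.zeros(fan_out))
        self._lo: np.ndarray | None = None
        self._span: np.ndarray | None = None
        self.fitted = False

    # -- scaling -----------------------------------------------------------
    def _fit_scaler(self, X: np.ndarray) -> None:
        self._lo = X.min(axis=0)
        span = X.max(axis=0) - self._lo
        span[span == 0] = 1.0  # constant coordinates map to 0
        self._span = span

    def _scale(self, X: np.ndarray) -> np.ndarray:
        if self._lo is None:
            raise RuntimeError("autoencoder has not been fitted")
        return (X - self._lo) / self._span

    # -- forward / backward ------------------------------------------------
    def _forward(self, X: np.ndarray) -> list[np.ndarray]:
        acts = [X]
        h = X
        last = len(self.weights) - 1
        for i, (W, b) in enumerate(zip(self.weights, self.biases)):
            z = h @ W + b
            h = z if i == last else _relu(z)  # linear output layer
            acts.append(h)
        return acts

    def reconstruction_error(self, X: np.ndarray, scaled: bool = False) -> float:
        """Mean squared reconstruction error on (optionally pre-scaled) X."""
        Xs = np.asarray(X, dtype=float) if scaled else self._scale(np.asarray(X, float))
        out = self._forward(Xs)[-1]
        return float(np.mean((out - Xs) ** 2))

    def fit(self, X: np.ndarray) -> "Autoencoder":
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[0] == 0:
            raise ValueError("training set must be a non-empty 2-D array")
        if X.shape[1] != self.spec.input_dim:
            raise ValueError(
                f"input width {X.shape[1]} != configured {self.spec.input_dim}"
            )
        self._fit_scaler(X)
        Xs = self._scale(X)
        rng = np.random.default_rng(self.spec.seed + 1)

        m_w = [np.zeros_like(W) for W in self.weights]
        v_w = [np.zeros_like(W) for W in self.weights]
        m_b = [np.zeros_like(b) for b in self.biases]
        v_b = [np.zeros_like(b) for b in self.biases]
        beta1, beta2, eps = 0.9, 0.999, 1e-8
        step = 0
        n = Xs.shape[0]
        bs = min(self.spec.batch_size, n)

        for _ in range(self.spec.epochs):
            order = rng.permutation(n)
            for start in range(0, n, bs):
                batch = Xs[order[start : start + bs]]
                acts = self._forward(batch)
                delta = 2.0 * (acts[-1] - batch) / batch.shape[0]
                grads_w: list[np.ndarray] = [None] * len(self.weights)  # type: ignore
                grads_b: list[np.ndarray] = [None] * len(self.biases)  # type: ignore
                for i in range(len(self.weights) - 1, -1, -1):
                    grads_w[i] = acts[i].T @ delta
                    grads_b[i] = delta.sum(axis=0)
                    if i > 0:
                        delta = (delta @ self.weights[i].T) * (acts[i] > 0)
                step += 1
                lr_t = (
                    self.spec.learning_rate
                    * np.sqrt(1 - beta2**step)
                    / (1 - beta1**step)
                )
                for i in range(len(self.weights)):
                    m_w[i] = beta1 * m_w[i] + (1 - beta1) * grads_w[i]
                    v_w[i] = beta2 * v_w[i] + (1 - beta2) * grads_w[i] ** 2
                    self.weights[i] -= lr_t * m_w[i] / (np.sqrt(v_w[i]) + eps)
                    m_b[i] = beta1 * m_b[i] + (1 - beta1) * grads_b[i]
                    v_b[i] = beta2 * v_b[i] + (1 - beta2) * grads_b[i] ** 2
                    self.biases[i] -= lr_t * m_b[i] / (np.sqrt(v_b[i]) + eps)
        self.fitted = True
        return self

    def encode(self, X: np.ndarray) -> np.ndarray:
        """Map inputs to latent codes (deterministic once fitted)."""
        if not self.fitted:
            raise RuntimeError("autoencoder has not been fitted")
        X = np.asarray(X, dtype=float)
        if X.shape[-1] != self.spec.input_dim:
            raise ValueError(
                f"input width {X.shape[-1]} != configured {self.spec.input_dim}"
            )
        h = self._scale(np.atleast_2d(X))
        for i in range(2):  # encoder half: two layers, both ReLU
            h = _relu(h @ self.weights[i] + self.biases[i])
        return h
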