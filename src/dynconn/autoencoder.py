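"""Fully connected autoencoder for dimensionality reduction of windowed FC.

Architecture: three encoding layers (default 512, 256, 32 units) with a
symmetric decoder; ReLU on hidden layers, linear activations on the
bottleneck and output layers; trained with Adam to minimize reconstruction
mean squared error. Implemented directly on numpy so training is exactly
reproducible from a seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["AutoencoderSpec", "Autoencoder", "standardize_features"]


@dataclass(frozen=True)
class AutoencoderSpec:
    encoder_units: tuple[int, ...] = (512, 256, 32)
    epochs: int = 200
    batch_size: int = 50
    learning_rate: float = 1e-3  # Adam default
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.encoder_units) < 1:
            raise ValueError("need at least one encoding layer")
        if self.epochs < 1 or self.batch_size < 1:
            raise ValueError("epochs and batch_size must be >= 1")

    @property
    def bottleneck(self) -> int:
        return self.encoder_units[-1]


def standardize_features(x: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-feature z-scoring across samples; returns (standardized, mean, sd).

    Features with zero variance are left centred with unit divisor. Applied to
    edge features before training so the MSE objective weights all edges
    comparably.
    """
    x = np.asarray(x, dtype=float)
    mu = x.mean(axis=0)
    sd = x.std(axis=0)
    sd = np.where(sd == 0, 1.0, sd)
    return (x - mu) / sd, mu, sd


class Autoencoder:
    """MLP autoencoder with mirrored encoder/decoder and Adam training."""

    def __init__(self, n_features: int, spec: AutoencoderSpec = AutoencoderSpec()):
        self.spec = spec
        if spec.bottleneck >= n_features:
            # still trainable (identity is achievable); no error — used in capacity tests
            pass
        dims = [n_features, *spec.encoder_units, *spec.encoder_units[-2::-1], n_features]
        self.dims = dims
        # activation per layer output: ReLU everywhere except bottleneck and final output
        n_layers = len(dims) - 1
        bottleneck_layer = len(spec.encoder_units) - 1
        self.linear_layers = {bottleneck_layer, n_layers - 1}
        rng = np.random.default_rng(spec.seed)
        # all parameters live in one flat float32 buffer (training is memory
        # bound; a single fused Adam pass per step beats one per tensor) and
        # the per-layer weight/bias arrays are reshaped views into it
        sizes = [dims[i] * dims[i + 1] for i in range(n_layers)]
        sizes += [dims[i + 1] for i in range(n_layers)]
        total = sum(sizes)
        self._params = np.empty(total, dtype=np.float32)
        self._grads = np.zeros(total, dtype=np.float32)
        self.weights: list[np.ndarray] = []
        self.biases: list[np.ndarray] = []
        self._wgrads: list[np.ndarray] = []
        self._bgrads: list[np.ndarray] = []
        offset = 0
        for i in range(n_layers):
            fan_in, fan_out = dims[i], dims[i + 1]
            if i in self.linear_layers:
                scale = np.sqrt(2.0 / (fan_in + fan_out))  # Glorot for linear layers
            else:
                scale = np.sqrt(2.0 / fan_in)              # He for ReLU layers
            w = self._params[offset:offset + fan_in * fan_out].reshape(fan_in, fan_out)
            w[...] = rng.normal(scale=scale, size=(fan_in, fan_out))
            self.weights.append(w)
            self._wgrads.append(
                self._grads[offset:offset + fan_in * fan_out].reshape(fan_in, fan_out)
            )
            offset += fan_in * fan_out
        for i in range(n_layers):
            fan_out = dims[i + 1]
            b = self._params[offset:offset + fan_out]
            b[...] = 0.0
            self.biases.append(b)
            self._bgrads.append(self._grads[offset:offset + fan_out])
            offset += fan_out
        self._rng = rng
        self.final_mse: float | None = None
        self.loss_history: list[float] = []

    # -- forward -----------------------------------------------------------
    def _forward(self, x: np.ndarray) -> list[np.ndarray]:
        acts = [x]
        h = x
        for i, (w, b) in enumerate(zip(self.weights, self.biases)):
            h = h @ w + b
            if i not in self.linear_layers:
                h = np.maximum(h, 0.0)
            acts.append(h)
        return acts

    def encode(self, x: np.ndarray) -> np.ndarray:
        h = np.asarray(x, dtype=np.float32)
        for i in range(len(self.spec.encoder_units)):
            h = h @ self.weights[i] + self.biases[i]
            if i not in self.linear_layers:
                h = np.maximum(h, 0.0)
        return h.astype(float)

    def reconstruct(self, x: np.ndarray) -> np.ndarray:
        return self._forward(np.asarray(x, dtype=np.float32))[-1].astype(float)

    # -- training ----------------------------------------------------------
    @staticmethod
    def _adam_update(
        param: np.ndarray, g: np.ndarray, mom: np.ndarray, vel: np.ndarray,
        scratch: np.ndarray, lr: float, bias1: float, bias2: float, eps: float,
    ) -> None:
        # allocation-free in-place Adam step; bias correction is folded into
        # the step size and the second-moment rescaling
        np.subtract(g, mom, out=scratch)
        scratch *= 1.0 - 0.9
        mom += scratch
        np.multiply(g, g, out=g)
        np.subtract(g, vel, out=scratch)
        scratch *= 1.0 - 0.999
        vel += scratch
        np.divide(vel, bias2, out=scratch)
        np.sqrt(scratch, out=scratch)
        scratch += eps
        np.divide(mom, scratch, out=scratch)
        scratch *= lr / bias1
        param -= scratch

    def fit(self, x: np.ndarray) -> "Autoencoder":
        """Train on samples x features data; records per-epoch MSE."""
        x = np.asarray(x, dtype=np.float32)
        n = x.shape[0]
        if n < self.spec.batch_size:
            raise ValueError(
                f"need at least batch_size={self.spec.batch_size} samples, got {n}"
            )
        lr = self.spec.learning_rate
        beta1, beta2, eps = 0.9, 0.999, 1e-8
        mom = np.zeros_like(self._params)
        vel = np.zeros_like(self._params)
        scratch = np.empty_like(self._params)
        step = 0
        n_layers = len(self.weights)
        # preallocated activation/gradient buffers per batch size (the last
        # batch of an epoch may be ragged): training is allocation-sensitive
        buffers: dict[int, tuple[list[np.ndarray], list[np.ndarray]]] = {}

        def _buffers(b_n: int):
            if b_n not in buffers:
                buffers[b_n] = (
                    [np.empty((b_n, d), dtype=np.float32) for d in self.dims],
                    [np.empty((b_n, d), dtype=np.float32) for d in self.dims],
                )
            return buffers[b_n]

        for epoch in range(self.spec.epochs):
            order = self._rng.permutation(n)
            epoch_loss = 0.0
            for start in range(0, n, self.spec.batch_size):
                batch = x[order[start:start + self.spec.batch_size]]
                b_n = batch.shape[0]
                acts, grads = _buffers(b_n)
                acts[0][...] = batch
                for i in range(n_layers):
                    np.matmul(acts[i], self.weights[i], out=acts[i + 1])
                    acts[i + 1] += self.biases[i]
                    if i not in self.linear_layers:
                        np.maximum(acts[i + 1], 0.0, out=acts[i + 1])
                np.subtract(acts[-1], batch, out=grads[-1])
                loss = float(np.mean(grads[-1] ** 2))
                if not np.isfinite(loss):
                    raise FloatingPointError(
                        f"non-finite training loss at epoch {epoch}, step {step}"
                    )
                epoch_loss += loss * b_n
                # backprop: dL/dout = 2 err / (b_n * n_features)
                grads[-1] *= 2.0 / grads[-1].size
                step += 1
                for i in range(n_layers - 1, -1, -1):
                    if i not in self.linear_layers:
                        grads[i + 1] *= acts[i + 1] > 0
                    np.matmul(acts[i].T, grads[i + 1], out=self._wgrads[i])
                    grads[i + 1].sum(axis=0, out=self._bgrads[i])
                    if i > 0:
                        np.matmul(grads[i + 1], self.weights[i].T, out=grads[i])
                # one fused Adam pass over the flat parameter buffer
                self._adam_update(self._params, self._grads, mom, vel, scratch,
                                  lr, 1.0 - beta1 ** step, 1.0 - beta2 ** step, eps)
            self.loss_history.append(epoch_loss / n)
        self.final_mse = self.loss_history[-1]
        return self
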