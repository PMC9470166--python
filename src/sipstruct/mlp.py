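"""A small feedforward network trained with Adam on categorical cross-entropy.

This is the classification backend: dense layers with rectifier (ReLU)
hidden activations and a softmax output, He-initialized, trained by
mini-batch gradient descent with the Adam update rule.  It is deliberately
dependency-free (numpy only) and fully deterministic given a seed, so
cross-validation results are bit-reproducible on any machine.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["MLP", "TrainingDiverged"]


class TrainingDiverged(RuntimeError):
    """Raised when the loss becomes non-finite during training."""


def _softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def _cross_entropy(p: np.ndarray, y: np.ndarray) -> float:
    eps = 1e-12
    return float(-(y * np.log(p + eps)).sum(axis=1).mean())


@dataclass
class MLP:
    """Fully connected rectifier network with softmax output.

    Parameters
    ----------
    layer_widths:
        Hidden and output widths, e.g. ``(2048, 512, 64, 4)``; the input
        width is inferred from the data at :meth:`fit`.
    learning_rate:
        Adam step size.
    """

    layer_widths: tuple[int, ...] = (2048, 512, 64, 4)
    learning_rate: float = 1e-3
    beta1: float = 0.9
    beta2: float = 0.999
    eps: float = 1e-8
    weights: list[np.ndarray] = field(default_factory=list, repr=False)
    biases: list[np.ndarray] = field(default_factory=list, repr=False)

    def __post_init__(self) -> None:
        if any(w <= 0 for w in self.layer_widths):
            raise ValueError("layer widths must be positive")

    @property
    def n_classes(self) -> int:
        return self.layer_widths[-1]

    def _init_params(self, n_in: int, rng: np.random.Generator) -> None:
        self.weights, self.biases = [], []
        fan_in = n_in
        for width in self.layer_widths:
            scale = np.sqrt(2.0 / fan_in)  # He init for rectifier units
            self.weights.append(rng.normal(0.0, scale, size=(fan_in, width)))
            self.biases.append(np.zeros(width))
            fan_in = width

    def _forward(self, X: np.ndarray) -> list[np.ndarray]:
        acts = [X]
        h = X
        last = len(self.weights) - 1
        for i, (W, b) in enumerate(zip(self.weights, self.biases)):
            z = h @ W + b
            h = _softmax(z) if i == last else np.maximum(z, 0.0)
            acts.append(h)
        return acts

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        return self._forward(np.asarray(X, dtype=float))[-1]

    def predict(self, X: np.ndarray) -> np.ndarray:
        # np.argmax breaks ties toward the lowest class index (documented).
        return np.argmax(self.predict_proba(X), axis=1)

    def evaluate(self, X: np.ndarray, Y: np.ndarray) -> tuple[float, float]:
        """Return (cross-entropy loss, accuracy) on one-hot labels ``Y``."""
        p = self.predict_proba(X)
        acc = float((np.argmax(p, axis=1) == np.argmax(Y, axis=1)).mean())
        return _cross_entropy(p, Y), acc

    def fit(
        self,
        X: np.ndarray,
        Y: np.ndarray,
        epochs: int = 100,
        batch_size: int = 32,
        seed: int = 0,
        eval_set: tuple[np.ndarray, np.ndarray] | None = None,
    ) -> dict[str, list[float]]:
        """Train and return per-epoch loss/accuracy histories."""
        X = np.asarray(X, dtype=float)
        Y = np.asarray(Y, dtype=float)
        rng = np.random.default_rng(seed)
        self._init_params(X.shape[1], rng)
        m = [np.zeros_like(W) for W in self.weights] + [np.zeros_like(b) for b in self.biases]
        v = [np.zeros_like(g) for g in m]
        t = 0
        history: dict[str, list[float]] = {"train_loss": [], "train_accuracy": []}
        if eval_set is not None:
            history["test_loss"] = []
            history["test_accuracy"] = []
        n = X.shape[0]
        for _ in range(epochs):
            order = rng.permutation(n)
            for start in range(0, n, batch_size):
                idx = order[start : start + batch_size]
                grads = self._gradients(X[idx], Y[idx])
                t += 1
                params = self.weights + self.biases
                for k, (p, g) in enumerate(zip(params, grads)):
                    m[k] = self.beta1 * m[k] + (1 - self.beta1) * g
                    v[k] = self.beta2 * v[k] + (1 - self.beta2) * g * g
                    mhat = m[k] / (1 - self.beta1**t)
                    vhat = v[k] / (1 - self.beta2**t)
                    p -= self.learning_rate * mhat / (np.sqrt(vhat) + self.eps)
            loss, acc = self.evaluate(X, Y)
            if not np.isfinite(loss):
                raise TrainingDiverged(f"non-finite training loss at epoch {len(history['train_loss'])}")
            history["train_loss"].append(loss)
            history["train_accuracy"].append(acc)
            if eval_set is not None:
                tl, ta = self.evaluate(*eval_set)
                history["test_loss"].append(tl)
                history["test_accuracy"].append(ta)
        return history

    def _gradients(self, X: np.ndarray, Y: np.ndarray) -> list[np.ndarray]:
        acts = self._forward(X)
        n = X.shape[0]
        # softmax + cross-entropy: delta at the output is (p - y)/n
        delta = (acts[-1] - Y) / n
        grad_W: list[np.ndarray] = []
        grad_b: list[np.ndarray] = []
        for i in range(len(self.weights) - 1, -1, -1):
            grad_W.append(acts[i].T @ delta)
            grad_b.append(delta.sum(axis=0))
            if i > 0:
                delta = (delta @ self.weights[i].T) * (acts[i] > 0)
        grad_W.reverse()
        grad_b.reverse()
        return grad_W + grad_b
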