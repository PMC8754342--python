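"""Minimal dense-network toolkit backing the learned components.

Every trainable model in this package (label-free fluorescence predictor,
live/dead classifier, variational / vanilla / adversarial autoencoders) is a
small fully-connected encoder or encoder-decoder trained with the Adam
optimizer.  The implementation is deliberately compact: plain NumPy forward
passes, hand-written backward passes, no computation graph.  Networks are
deterministic given a seed and a fixed thread count, up to floating-point
associativity.

Loss helpers (:func:`binary_cross_entropy`, :func:`gaussian_kld`,
:func:`vae_loss`) are exposed as pure functions so their closed-form values
can be checked independently of any training loop.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Dense",
    "Relu",
    "Sigmoid",
    "MLP",
    "Adam",
    "binary_cross_entropy",
    "gaussian_kld",
    "vae_loss",
]

_EPS = 1e-12


# ---------------------------------------------------------------------------
# losses
# ---------------------------------------------------------------------------

def binary_cross_entropy(p, y, reduce: str = "mean") -> float | np.ndarray:
    """Cross-entropy of predicted probabilities ``p`` against 0/1 labels ``y``.

    ``-(y log p + (1 - y) log(1 - p))`` per sample.  Non-negative, zero only
    at a perfectly confident correct prediction; ``p = 0.5`` costs ``ln 2``
    per sample regardless of the label.
    """
    p = np.clip(np.asarray(p, dtype=float), _EPS, 1.0 - _EPS)
    y = np.asarray(y, dtype=float)
    per_sample = -(y * np.log(p) + (1.0 - y) * np.log(1.0 - p))
    if reduce == "none":
        return per_sample
    if reduce == "sum":
        return float(per_sample.sum())
    return float(per_sample.mean())


def gaussian_kld(mu, sigma, reduce: str = "mean") -> float | np.ndarray:
    """KL divergence of a diagonal Gaussian posterior from the unit Gaussian.

    ``KLD = -1/2 * sum_j (1 + log sigma_j^2 - mu_j^2 - sigma_j^2)`` summed
    over latent dimensions, per sample.  Zero iff mu = 0 and sigma = 1.
    """
    mu = np.atleast_2d(np.asarray(mu, dtype=float))
    sigma = np.atleast_2d(np.asarray(sigma, dtype=float))
    if np.any(sigma <= 0):
        raise ValueError("sigma must be strictly positive")
    var = sigma**2
    per_sample = -0.5 * np.sum(1.0 + np.log(var) - mu**2 - var, axis=-1)
    if reduce == "none":
        return per_sample
    if reduce == "sum":
        return float(per_sample.sum())
    return float(per_sample.mean())


def vae_loss(x, recon, mu, sigma, a: float = 1.0, gamma: float = 0.9) -> float:
    """Weighted combination ``A * (gamma * MSE + (1 - gamma) * KLD)``.

    MSE is the squared reconstruction error ``||X - F(z, X)||^2`` summed over
    pixels and averaged over the batch; KLD is the batch-mean Gaussian KL
    term.  ``gamma = 1`` reduces the loss to ``A * MSE`` exactly.
    """
    if not 0.0 <= gamma <= 1.0:
        raise ValueError(f"gamma must lie in [0, 1], got {gamma}")
    if a <= 0:
        raise ValueError(f"A must be positive, got {a}")
    x = np.atleast_2d(np.asarray(x, dtype=float))
    recon = np.atleast_2d(np.asarray(recon, dtype=float))
    mse = float(np.sum((x - recon) ** 2, axis=-1).mean())
    kld = gaussian_kld(mu, sigma) if gamma < 1.0 else 0.0
    return a * (gamma * mse + (1.0 - gamma) * kld)


# ---------------------------------------------------------------------------
# layers
# ---------------------------------------------------------------------------

class Dense:
    """Fully-connected layer, Glorot-uniform initialised."""

    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        limit = np.sqrt(6.0 / (n_in + n_out))
        self.w = rng.uniform(-limit, limit, size=(n_in, n_out))
        self.b = np.zeros(n_out)
        self.dw = np.zeros_like(self.w)
        self.db = np.zeros_like(self.b)
        self._x: np.ndarray | None = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return x @ self.w + self.b

    def backward(self, g: np.ndarray) -> np.ndarray:
        self.dw = self._x.T @ g
        self.db = g.sum(axis=0)
        return g @ self.w.T

    @property
    def params(self):
        return [self.w, self.b]

    @property
    def grads(self):
        return [self.dw, self.db]


class Relu:
    def __init__(self):
        self._mask = None

    def forward(self, x):
        self._mask = x > 0
        return x * self._mask

    def backward(self, g):
        return g * self._mask

    params: list = []
    grads: list = []


class Sigmoid:
    def __init__(self):
        self._y = None

    def forward(self, x):
        self._y = 1.0 / (1.0 + np.exp(-np.clip(x, -60, 60)))
        return self._y

    def backward(self, g):
        return g * self._y * (1.0 - self._y)

    params: list = []
    grads: list = []


_ACTIVATIONS = {"relu": Relu, "sigmoid": Sigmoid, "linear": None}


class MLP:
    """Stack of Dense layers with ReLU hidden units.

    ``sizes`` gives the layer widths including input and output; ``out`` names
    the output nonlinearity ("sigmoid" or "linear").
    """

    def __init__(self, sizes, rng: np.random.Generator, out: str = "linear"):
        if out not in _ACTIVATIONS:
            raise ValueError(f"unknown output activation {out!r}")
        self.layers = []
        for i in range(len(sizes) - 1):
            self.layers.append(Dense(sizes[i], sizes[i + 1], rng))
            if i < len(sizes) - 2:
                self.layers.append(Relu())
        if _ACTIVATIONS[out] is not None:
            self.layers.append(_ACTIVATIONS[out]())

    def forward(self, x: np.ndarray) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x)
        return x

    __call__ = forward

    def backward(self, g: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            g = layer.backward(g)
        return g

    @property
    def params(self):
        return [p for layer in self.layers for p in layer.params]

    @property
    def grads(self):
        return [g for layer in self.layers for g in layer.grads]


class Adam:
    """Adaptive-moment optimizer; updates parameter arrays in place."""

    def __init__(self, params, lr: float = 1e-3, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.params = list(params)
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in self.params]
        self.v = [np.zeros_like(p) for p in self.params]
        self.t = 0

    def step(self, grads) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g**2
            m_hat = m / (1 - b1**self.t)
            v_hat = v / (1 - b2**self.t)
            p -= self.lr * m_hat / (np.sqrt(v_hat) + self.eps)
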