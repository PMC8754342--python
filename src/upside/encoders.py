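"""Twin autoencoders for shape and texture, latent fusion, and decoding.

Two variational autoencoders are trained side by side — one on canonical
binary mask images (shape), one on canonical texture images — and their
latent codes are fused by a weighted concatenation

    z = concat(w * z_shape, (1 - w) * z_texture),    0 <= w <= 1,

where the fusion weight ``w`` sets the relative importance of shape versus
texture for downstream clustering.  The VAE loss is a weighted combination
of reconstruction error and the Gaussian KL penalty,

    L = A * (gamma * MSE + (1 - gamma) * KLD),

with ``MSE = ||X - F(z, X)||^2`` and ``KLD = -1/2 sum_j (1 + log sigma_j^2
- mu_j^2 - sigma_j^2)``.  Inference encodes each image as the posterior
mean mu, which makes encodings deterministic.

Baselines with the same encode/decode surface are provided for comparison:
a vanilla autoencoder (pure MSE), adversarial autoencoders whose latents are
pushed by a discriminator toward a unit Gaussian (1x) or a four-component
Gaussian mixture (4x), and PCA on flattened images.

Interpretation works through the decoder: a latent feature (or a correlated
feature group) is exaggerated from the population-mean latent vector and the
decoded image is compared against the mean decoding; the signed difference
image shows what the feature encodes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.decomposition import PCA

from ._nn import MLP, Adam, Dense, gaussian_kld, vae_loss

__all__ = [
    "VaeLossConfig",
    "LatentVector",
    "VAEEncoder",
    "AutoencoderBaseline",
    "AdversarialAutoencoder",
    "PCAEncoder",
    "train_vae",
    "train_baseline",
    "encode",
    "decode",
    "combine_latents",
    "exaggerate_features",
]


@dataclass
class VaeLossConfig:
    """Training configuration: loss scale A, balance gamma, latent size J."""

    a: float = 1.0
    gamma: float = 0.9
    latent_dim: int = 100
    steps: int = 3000
    seed: int = 0
    hidden: int = 256
    batch_size: int = 32
    lr: float = 1e-3

    def __post_init__(self):
        if not 0.0 <= self.gamma <= 1.0:
            raise ValueError("gamma must lie in [0, 1]")
        if self.a <= 0:
            raise ValueError("A must be positive")
        if self.latent_dim < 1:
            raise ValueError("latent_dim must be >= 1")


@dataclass
class LatentVector:
    """Per-cell twin encoding and its weighted concatenation."""

    z_shape: np.ndarray
    z_texture: np.ndarray
    w: float = 0.5
    mu_shape: np.ndarray | None = None
    sigma_shape: np.ndarray | None = None
    mu_texture: np.ndarray | None = None
    sigma_texture: np.ndarray | None = None

    @property
    def fused(self) -> np.ndarray:
        return combine_latents(self.z_shape, self.z_texture, self.w)


def _flatten(images) -> np.ndarray:
    X = np.asarray(images, dtype=float)
    if X.ndim == 3:
        X = X.reshape(len(X), -1)
    elif X.ndim != 2:
        raise ValueError("images must be (n, H, W) or (n, d)")
    return X


class _EncoderBase(BaseEstimator, TransformerMixin):
    """Shared surface: fit / transform (encode) / inverse_transform (decode)."""

    def _prepare(self, images):
        X = _flatten(images)
        if len(X) == 0:
            raise ValueError("no training images")
        arr = np.asarray(images, dtype=float)
        self.image_shape_ = arr.shape[1:] if arr.ndim == 3 else (X.shape[1],)
        self.n_features_in_ = X.shape[1]
        return X

    def _check(self, X):
        if X.shape[1] != self.n_features_in_:
            raise ValueError("image size differs from the training size")
        return X

    def reconstruct(self, images) -> np.ndarray:
        return self.inverse_transform(self.transform(images))

    def reconstruction_error(self, images) -> float:
        X = _flatten(images)
        R = _flatten(self.reconstruct(images))
        return float(((X - R) ** 2).sum(axis=1).mean())


class VAEEncoder(_EncoderBase):
    """Dense variational autoencoder on flattened canonical images.

    Encoder body -> (mu, log-variance) heads; reparameterised sampling during
    training; the deterministic encoding returned by :meth:`transform` is the
    posterior mean mu.
    """

    def __init__(self, latent_dim: int = 100, hidden: int = 256,
                 a: float = 1.0, gamma: float = 0.9, steps: int = 3000,
                 batch_size: int = 32, lr: float = 1e-3, seed: int = 0):
        self.latent_dim = latent_dim
        self.hidden = hidden
        self.a = a
        self.gamma = gamma
        self.steps = steps
        self.batch_size = batch_size
        self.lr = lr
        self.seed = seed

    def fit(self, images, y=None):
        if not 0.0 <= self.gamma <= 1.0:
            raise ValueError("gamma must lie in [0, 1]")
        if self.a <= 0:
            raise ValueError("A must be positive")
        X = self._prepare(images)
        rng = np.random.default_rng(self.seed)
        d, J = X.shape[1], self.latent_dim
        self.body_ = MLP([d, self.hidden], rng, out="relu")
        self.head_mu_ = Dense(self.hidden, J, rng)
        self.head_lv_ = Dense(self.hidden, J, rng)
        self.decoder_ = MLP([J, self.hidden, d], rng, out="sigmoid")
        params = (self.body_.params + self.head_mu_.params
                  + self.head_lv_.params + self.decoder_.params)
        opt = Adam(params, lr=self.lr)
        self.loss_history_ = []
        n, a, g = len(X), self.a, self.gamma
        for step in range(self.steps):
            idx = rng.integers(0, n, size=min(self.batch_size, n))
            xb = X[idx]
            B = len(xb)
            h = self.body_.forward(xb)
            mu = self.head_mu_.forward(h)
            logvar = np.clip(self.head_lv_.forward(h), -10.0, 10.0)
            sigma = np.exp(0.5 * logvar)
            eps = rng.normal(size=mu.shape)
            z = mu + sigma * eps
            recon = self.decoder_.forward(z)
            loss = vae_loss(xb, recon, mu, sigma, a=a, gamma=g)
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"NaN/inf VAE loss at step {step}; "
                    f"|mu|max={np.abs(mu).max():.3g}, lr={self.lr}")
            self.loss_history_.append(loss)
            g_recon = a * g * 2.0 * (recon - xb) / B
            g_z = self.decoder_.backward(g_recon)
            g_mu = g_z + a * (1 - g) * mu / B
            g_lv = g_z * (0.5 * sigma * eps) \
                + a * (1 - g) * (-0.5 * (1.0 - sigma**2)) / B
            g_h = self.head_mu_.backward(g_mu) + self.head_lv_.backward(g_lv)
            self.body_.backward(g_h)
            grads = (self.body_.grads + self.head_mu_.grads
                     + self.head_lv_.grads + self.decoder_.grads)
            opt.step(grads)
        return self

    def encode_full(self, images):
        """(mu, sigma) of the latent posterior per image."""
        X = self._check(_flatten(images))
        h = self.body_.forward(X)
        mu = self.head_mu_.forward(h)
        sigma = np.exp(0.5 * np.clip(self.head_lv_.forward(h), -10.0, 10.0))
        return mu, sigma

    def transform(self, images) -> np.ndarray:
        return self.encode_full(images)[0]

    def inverse_transform(self, z) -> np.ndarray:
        z = np.atleast_2d(np.asarray(z, dtype=float))
        if z.shape[1] != self.latent_dim:
            raise ValueError(f"latent length must be {self.latent_dim}")
        imgs = self.decoder_.forward(z)
        return imgs.reshape((len(z),) + self.image_shape_)


class AutoencoderBaseline(_EncoderBase):
    """Vanilla autoencoder: same layout as the VAE, pure reconstruction loss."""

    def __init__(self, latent_dim: int = 100, hidden: int = 256,
                 steps: int = 3000, batch_size: int = 32, lr: float = 1e-3,
                 seed: int = 0):
        self.latent_dim = latent_dim
        self.hidden = hidden
        self.steps = steps
        self.batch_size = batch_size
        self.lr = lr
        self.seed = seed

    def _build(self, d, rng):
        self.encoder_ = MLP([d, self.hidden, self.latent_dim], rng)
        self.decoder_ = MLP([self.latent_dim, self.hidden, d], rng,
                            out="sigmoid")

    def fit(self, images, y=None):
        X = self._prepare(images)
        rng = np.random.default_rng(self.seed)
        self._build(X.shape[1], rng)
        params = self.encoder_.params + self.decoder_.params
        opt = Adam(params, lr=self.lr)
        self.loss_history_ = []
        n = len(X)
        for _ in range(self.steps):
            idx = rng.integers(0, n, size=min(self.batch_size, n))
            xb = X[idx]
            z = self.encoder_.forward(xb)
            recon = self.decoder_.forward(z)
            self.loss_history_.append(
                float(((recon - xb) ** 2).sum(axis=1).mean()))
            g_z = self.decoder_.backward(2.0 * (recon - xb) / len(xb))
            self.encoder_.backward(g_z)
            opt.step(self.encoder_.grads + self.decoder_.grads)
        return self

    def transform(self, images) -> np.ndarray:
        return self.encoder_.forward(self._check(_flatten(images)))

    def inverse_transform(self, z) -> np.ndarray:
        z = np.atleast_2d(np.asarray(z, dtype=float))
        imgs = self.decoder_.forward(z)
        return imgs.reshape((len(z),) + self.image_shape_)


class AdversarialAutoencoder(AutoencoderBaseline):
    """Autoencoder whose latents are adversarially matched to a prior.

    A discriminator is trained to tell encoded latents from samples of the
    target prior (L_disc = -mean[log D(z_real) + log(1 - D(z_enc))]); the
    encoder is simultaneously trained to fool it.  ``mixture = 1`` targets a
    unit Gaussian; ``mixture = 4`` a four-component Gaussian mixture with
    component means (-1, -0.5, 0.5, 1) and unit standard deviations, sampled
    independently per latent element.
    """

    _MIX4_MEANS = np.array([-1.0, -0.5, 0.5, 1.0])

    def __init__(self, latent_dim: int = 100, hidden: int = 256,
                 steps: int = 3000, batch_size: int = 32, lr: float = 1e-3,
                 seed: int = 0, mixture: int = 1,
                 adversarial_weight: float = 10.0, disc_steps: int = 5):
        super().__init__(latent_dim, hidden, steps, batch_size, lr, seed)
        self.mixture = mixture
        self.adversarial_weight = adversarial_weight
        self.disc_steps = disc_steps

    def _sample_prior(self, rng, shape):
        if self.mixture == 1:
            return rng.normal(size=shape)
        comp = rng.integers(0, len(self._MIX4_MEANS), size=shape)
        return self._MIX4_MEANS[comp] + rng.normal(size=shape)

    def fit(self, images, y=None):
        if self.mixture not in (1, 4):
            raise ValueError("mixture must be 1 or 4")
        X = self._prepare(images)
        rng = np.random.default_rng(self.seed)
        self._build(X.shape[1], rng)
        self.discriminator_ = MLP([self.latent_dim, 64, 1], rng, out="sigmoid")
        opt_ae = Adam(self.encoder_.params + self.decoder_.params, lr=self.lr)
        opt_d = Adam(self.discriminator_.params, lr=self.lr)
        self.loss_history_, self.disc_history_ = [], []
        n, eps = len(X), 1e-7
        for _ in range(self.steps):
            idx = rng.integers(0, n, size=min(self.batch_size, n))
            xb = X[idx]
            B = len(xb)
            z = self.encoder_.forward(xb)
            recon = self.decoder_.forward(z)
            self.loss_history_.append(
                float(((recon - xb) ** 2).sum(axis=1).mean()))
            g_z_rec = self.decoder_.backward(2.0 * (recon - xb) / B)
            dec_grads = [g.copy() for g in self.decoder_.grads]
            # discriminator: real prior samples vs encoded latents (detached)
            for _ in range(self.disc_steps):
                z_real = self._sample_prior(rng, z.shape)
                d_real = np.clip(self.discriminator_.forward(z_real),
                                 eps, 1 - eps)
                self.discriminator_.backward(-1.0 / d_real / B)
                g_real = [g.copy() for g in self.discriminator_.grads]
                d_fake = np.clip(self.discriminator_.forward(z), eps, 1 - eps)
                self.discriminator_.backward(1.0 / (1 - d_fake) / B)
                opt_d.step([a + b for a, b in
                            zip(g_real, self.discriminator_.grads)])
            self.disc_history_.append(
                float(-(np.log(d_real) + np.log(1 - d_fake)).mean()))
            # encoder: one combined reconstruction + fooling gradient
            d_fake = np.clip(self.discriminator_.forward(z), eps, 1 - eps)
            g_z_adv = self.discriminator_.backward(
                -self.adversarial_weight / d_fake / B)
            self.encoder_.backward(g_z_rec + g_z_adv)
            opt_ae.step(self.encoder_.grads + dec_grads)
        return self


class PCAEncoder(_EncoderBase):
    """PCA on flattened images with the shared encode/decode surface."""

    def __init__(self, latent_dim: int = 100, seed: int = 0):
        self.latent_dim = latent_dim
        self.seed = seed

    def fit(self, images, y=None):
        X = self._prepare(images)
        n_comp = min(self.latent_dim, X.shape[0], X.shape[1])
        self.pca_ = PCA(n_components=n_comp, random_state=self.seed)
        self.pca_.fit(X)
        return self

    def transform(self, images) -> np.ndarray:
        return self.pca_.transform(self._check(_flatten(images)))

    def inverse_transform(self, z) -> np.ndarray:
        z = np.atleast_2d(np.asarray(z, dtype=float))
        imgs = np.clip(self.pca_.inverse_transform(z), 0.0, 1.0)
        return imgs.reshape((len(z),) + self.image_shape_)


# ---------------------------------------------------------------------------
# functional wrappers
# ---------------------------------------------------------------------------

_BASELINES = {
    "AE": lambda cfg: AutoencoderBaseline(
        latent_dim=cfg.latent_dim, hidden=cfg.hidden, steps=cfg.steps,
        batch_size=cfg.batch_size, lr=cfg.lr, seed=cfg.seed),
    "AAE1x": lambda cfg: AdversarialAutoencoder(
        latent_dim=cfg.latent_dim, hidden=cfg.hidden, steps=cfg.steps,
        batch_size=cfg.batch_size, lr=cfg.lr, seed=cfg.seed, mixture=1),
    "AAE4x": lambda cfg: AdversarialAutoencoder(
        latent_dim=cfg.latent_dim, hidden=cfg.hidden, steps=cfg.steps,
        batch_size=cfg.batch_size, lr=cfg.lr, seed=cfg.seed, mixture=4),
    "PCA": lambda cfg: PCAEncoder(latent_dim=cfg.latent_dim, seed=cfg.seed),
}


def train_vae(images, cfg: VaeLossConfig | None = None) -> VAEEncoder:
    cfg = cfg or VaeLossConfig()
    return VAEEncoder(latent_dim=cfg.latent_dim, hidden=cfg.hidden, a=cfg.a,
                      gamma=cfg.gamma, steps=cfg.steps,
                      batch_size=cfg.batch_size, lr=cfg.lr,
                      seed=cfg.seed).fit(images)


def train_baseline(kind: str, images, cfg: VaeLossConfig | None = None):
    cfg = cfg or VaeLossConfig()
    try:
        model = _BASELINES[kind](cfg)
    except KeyError:
        raise ValueError(f"unknown baseline kind {kind!r}; "
                         f"choose from {sorted(_BASELINES)}") from None
    return model.fit(images)


def encode(model, images) -> np.ndarray:
    """Deterministic per-image latent codes (posterior mean for the VAE)."""
    return model.transform(images)


def decode(model, z) -> np.ndarray:
    """Decode latent vectors back into canonical-size images in [0, 1]."""
    return model.inverse_transform(z)


def combine_latents(z_shape, z_texture, w: float) -> np.ndarray:
    """Weighted concatenation: first block w*z_shape, second (1-w)*z_texture."""
    if not 0.0 <= w <= 1.0:
        raise ValueError("w must lie in [0, 1]")
    z_shape = np.asarray(z_shape, dtype=float)
    z_texture = np.asarray(z_texture, dtype=float)
    if z_shape.shape != z_texture.shape:
        raise ValueError("shape and texture latents differ in shape")
    return np.concatenate([w * z_shape, (1.0 - w) * z_texture], axis=-1)


def exaggerate_features(model, base_latent, indices, magnitude: float):
    """Exaggerate latent features and decode, with a signed difference image.

    Adds ``magnitude`` to the chosen latent dimensions of ``base_latent``
    (conventionally the population-mean latent vector), decodes both vectors,
    and returns ``(decoded, difference)`` where
    ``difference = decode(exaggerated) - decode(base)``.  Shifting a group of
    features at once equals composing the single-feature shifts, since the
    shifts are additive in latent space.
    """
    base = np.asarray(base_latent, dtype=float).ravel().copy()
    indices = np.atleast_1d(np.asarray(indices, dtype=int))
    if indices.size and (indices.min() < 0 or indices.max() >= base.size):
        raise IndexError("feature index out of range")
    exaggerated = base.copy()
    exaggerated[indices] += magnitude
    dec_base = decode(model, base[None, :])[0]
    dec_exag = decode(model, exaggerated[None, :])[0]
    return dec_exag, dec_exag - dec_base
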