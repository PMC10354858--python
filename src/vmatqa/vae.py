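"""Variational autoencoder on 27x27 dose-difference maps.

The encoder (three stride-2 convolution blocks, 16/32/64 filters, batch norm
and ReLU) outputs the mean and log-variance of a 30-dimensional Gaussian
latent; the decoder mirrors it with transposed convolutions and a linear
output (DD maps live in [-0.2, 0.2], so no squashing activation).  Training
uses the reparameterization trick with standard-normal noise and an ELBO
whose reconstruction term is a Gaussian log-likelihood with a fixed
observation scale ``obs_sigma`` (the ~1 % residual level of error-free maps):

    loss = sum_pixels (x - xhat)^2 / (2 obs_sigma^2) + kl_weight * KL.

Only error-free maps are used for training; anomaly scoring happens
downstream on the encoder means (see :mod:`vmatqa.anomaly`).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import nn
from .ddmap import MAP_SIZE

__all__ = [
    "VAEConfig", "LatentStats", "TrainedVAE",
    "kl_loss", "reparameterize", "elbo_loss",
    "build_vae", "train_vae", "encode", "encode_batch", "reconstruct",
]


@dataclass
class VAEConfig:
    latent_dim: int = 30
    epochs: int = 200
    batch_size: int = 64
    learning_rate: float = 1e-3
    kl_weight: float = 1.0
    #: observation scale of the Gaussian reconstruction likelihood
    obs_sigma: float = 0.01
    conv_filters: tuple[int, int, int] = (16, 32, 64)
    seed: int = 0

    def validate(self) -> None:
        if self.latent_dim < 1 or self.epochs < 1 or self.batch_size < 1:
            raise ValueError("latent_dim, epochs and batch_size must be >= 1")
        if self.obs_sigma <= 0 or self.learning_rate <= 0:
            raise ValueError("obs_sigma and learning_rate must be positive")


@dataclass
class LatentStats:
    """Encoder output for one map: mean and standard deviation vectors."""

    mu: np.ndarray
    sigma: np.ndarray

    def __post_init__(self) -> None:
        if self.mu.shape != self.sigma.shape:
            raise ValueError("mu/sigma shape mismatch")
        if not (np.all(np.isfinite(self.mu)) and np.all(np.isfinite(self.sigma))):
            raise ValueError("latent statistics must be finite")
        if np.any(self.sigma <= 0):
            raise ValueError("sigma must be strictly positive")


def kl_loss(mu: np.ndarray, sigma: np.ndarray) -> float:
    """Closed-form KL divergence against N(0, I):
    -1/2 sum_i (1 + log s_i - mu_i^2 - s_i), with ``sigma`` the latent
    *variance* vector (strictly positive).

    This is the standard Gaussian KL; the commonly printed variant writes the
    last term as sigma_i^2 with sigma_i denoting the standard deviation.  The
    training loop passes exp(log-variance) here.
    """
    mu = np.asarray(mu, dtype=float)
    sigma = np.asarray(sigma, dtype=float)
    if mu.shape != sigma.shape:
        raise ValueError("mu/sigma shape mismatch")
    if np.any(sigma <= 0):
        raise ValueError("sigma must be strictly positive")
    return float(-0.5 * np.sum(1.0 + np.log(sigma) - mu**2 - sigma))


def reparameterize(mu: np.ndarray, sigma: np.ndarray,
                   epsilon: np.ndarray) -> np.ndarray:
    """z = mu + epsilon * sigma, elementwise."""
    mu, sigma, epsilon = (np.asarray(a, dtype=float) for a in (mu, sigma, epsilon))
    if not (mu.shape == sigma.shape == epsilon.shape):
        raise ValueError("mu, sigma and epsilon must share a shape")
    return mu + epsilon * sigma


def elbo_loss(input_map: np.ndarray, reconstruction: np.ndarray,
              mu: np.ndarray, sigma: np.ndarray, kl_weight: float = 1.0) -> float:
    """Pixel-mean squared error plus ``kl_weight`` times the KL term."""
    x = np.asarray(input_map, dtype=float)
    r = np.asarray(reconstruction, dtype=float)
    if x.shape != r.shape:
        raise ValueError("input/reconstruction shape mismatch")
    return float(np.mean((x - r) ** 2)) + kl_weight * kl_loss(mu, sigma)


class _VAENet:
    """Encoder trunk + (mu, log-variance) heads + decoder."""

    def __init__(self, config: VAEConfig, rng: np.random.Generator):
        f1, f2, f3 = config.conv_filters
        n = config.latent_dim
        feat = f3 * 4 * 4
        self.trunk = nn.Sequential([
            nn.Conv2d(1, f1, 3, 2, 1, rng), nn.BatchNorm(f1), nn.ReLU(),
            nn.Conv2d(f1, f2, 3, 2, 1, rng), nn.BatchNorm(f2), nn.ReLU(),
            nn.Conv2d(f2, f3, 3, 2, 1, rng), nn.BatchNorm(f3), nn.ReLU(),
            nn.Flatten(),
        ])
        self.head_mu = nn.Dense(feat, n, rng)
        self.head_logvar = nn.Dense(feat, n, rng)
        self.decoder = nn.Sequential([
            nn.Dense(n, feat, rng), nn.ReLU(), nn.Reshape((f3, 4, 4)),
            nn.ConvTranspose2d(f3, f2, 3, 2, 1, 0, rng), nn.BatchNorm(f2), nn.ReLU(),
            nn.ConvTranspose2d(f2, f1, 3, 2, 1, 1, rng), nn.BatchNorm(f1), nn.ReLU(),
            nn.ConvTranspose2d(f1, 1, 3, 2, 1, 0, rng),
        ])

    def params(self):
        return (self.trunk.params() + self.head_mu.params()
                + self.head_logvar.params() + self.decoder.params())

    def encode(self, x: np.ndarray, train: bool):
        feat = self.trunk.forward(x, train)
        return self.head_mu.forward(feat, train), self.head_logvar.forward(feat, train)

    def backward_encoder(self, g_mu: np.ndarray, g_logvar: np.ndarray):
        g = self.head_mu.backward(g_mu) + self.head_logvar.backward(g_logvar)
        self.trunk.backward(g)


@dataclass
class TrainedVAE:
    net: _VAENet
    config: VAEConfig
    history: dict[str, list[float]] = field(default_factory=dict)


def build_vae(config: VAEConfig | None = None) -> TrainedVAE:
    config = config or VAEConfig()
    config.validate()
    rng = np.random.default_rng(config.seed)
    return TrainedVAE(_VAENet(config, rng), config, {})


def _as_batch(maps: np.ndarray) -> np.ndarray:
    maps = np.asarray(maps, dtype=float)
    if maps.ndim == 2:
        maps = maps[None]
    if maps.shape[-2:] != (MAP_SIZE, MAP_SIZE):
        raise ValueError(f"maps must be {MAP_SIZE}x{MAP_SIZE}")
    return maps.reshape(-1, 1, MAP_SIZE, MAP_SIZE)


def train_vae(train_maps: np.ndarray, validation_maps: np.ndarray | None,
              config: VAEConfig | None = None) -> TrainedVAE:
    """Train the VAE on error-free maps; returns model plus per-epoch losses.

    History keys: ``elbo`` (training objective), ``mse``, ``kl`` and
    ``val_elbo`` (validation objective, deterministic latent).  Reproducible
    for a fixed config seed.
    """
    model = build_vae(config)
    config = model.config
    x_all = _as_batch(train_maps)
    if len(x_all) == 0:
        raise ValueError("empty training set")
    x_val = _as_batch(validation_maps) if validation_maps is not None else None

    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    net = model.net
    opt = nn.Adam(net.params(), lr=config.learning_rate)
    inv2s2 = 1.0 / (2.0 * config.obs_sigma**2)
    hist: dict[str, list[float]] = {"elbo": [], "mse": [], "kl": [], "val_elbo": []}

    for _ in range(config.epochs):
        order = rng.permutation(len(x_all))
        ep_elbo = ep_mse = ep_kl = 0.0
        for start in range(0, len(x_all), config.batch_size):
            idx = order[start:start + config.batch_size]
            x = x_all[idx]
            b = len(x)
            opt.zero_grad()

            mu, logv = net.encode(x, train=True)
            std = np.exp(0.5 * logv)
            eps = rng.standard_normal(mu.shape)
            z = mu + eps * std
            recon = net.decoder.forward(z, train=True)

            resid = recon - x
            sse = float((resid**2).sum() / b)
            kl = float(-0.5 * np.sum(1.0 + logv - mu**2 - np.exp(logv)) / b)
            loss = sse * inv2s2 + config.kl_weight * kl

            g_recon = resid * (2.0 * inv2s2 / b)
            g_z = net.decoder.backward(g_recon)
            g_mu = g_z + config.kl_weight * mu / b
            g_logv = (g_z * eps * 0.5 * std
                      + config.kl_weight * 0.5 * (np.exp(logv) - 1.0) / b)
            net.backward_encoder(g_mu, g_logv)
            opt.step()

            ep_elbo += loss * b
            ep_mse += sse / (MAP_SIZE**2) * b
            ep_kl += kl * b
        n = len(x_all)
        hist["elbo"].append(ep_elbo / n)
        hist["mse"].append(ep_mse / n)
        hist["kl"].append(ep_kl / n)

        if x_val is not None and len(x_val):
            mu, logv = net.encode(x_val, train=False)
            recon = net.decoder.forward(mu, train=False)
            sse = float(((recon - x_val) ** 2).sum() / len(x_val))
            kl = float(-0.5 * np.sum(1.0 + logv - mu**2 - np.exp(logv)) / len(x_val))
            hist["val_elbo"].append(sse * inv2s2 + config.kl_weight * kl)
        else:
            hist["val_elbo"].append(np.nan)

    model.history = hist
    return model


def encode_batch(model: TrainedVAE, maps: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Deterministic (mu, sigma) arrays for a stack of maps; no sampling."""
    x = _as_batch(maps)
    mu, logv = model.net.encode(x, train=False)
    return mu, np.exp(0.5 * logv)


def encode(model: TrainedVAE, ddmap: np.ndarray) -> LatentStats:
    """Deterministic latent statistics of a single map."""
    mu, sigma = encode_batch(model, ddmap)
    return LatentStats(mu[0], sigma[0])


def reconstruct(model: TrainedVAE, ddmap: np.ndarray) -> np.ndarray:
    """Decode the deterministic latent mean back to a 27x27 map."""
    x = _as_batch(ddmap)
    mu, _ = model.net.encode(x, train=False)
    out = model.net.decoder.forward(mu, train=False)
    return out.reshape(x.shape[0], MAP_SIZE, MAP_SIZE)[0] if len(x) == 1 else \
        out.reshape(x.shape[0], MAP_SIZE, MAP_SIZE)
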