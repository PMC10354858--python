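"""Mahalanobis-distance anomaly scoring in the VAE latent space.

The encoder means of the (error-free) training maps define the reference
distribution: their mean vector and sample covariance.  A test map's anomaly
is the Mahalanobis distance of its encoder mean from that reference; a beam
case is scored by the mean distance of its two plane maps.  The latent
standard deviations play no role in scoring.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import linalg

from .ddmap import BeamCase
from .vae import TrainedVAE, encode_batch

__all__ = [
    "ReferenceModel", "CaseScore",
    "fit_reference", "mahalanobis", "score_case", "score_cases", "classify_md",
]


@dataclass
class ReferenceModel:
    """Mean and (regularized) covariance of the reference latent means."""

    xbar: np.ndarray
    sigma: np.ndarray
    sigma_inv: np.ndarray
    n_ref: int
    ridge: float


@dataclass
class CaseScore:
    beam_id: int
    error: str
    md_plane1: float
    md_plane2: float

    @property
    def md_mean(self) -> float:
        return 0.5 * (self.md_plane1 + self.md_plane2)


def fit_reference(mu_vectors: np.ndarray, ridge: float | None = None) -> ReferenceModel:
    """Fit the reference distribution from (n, d) encoder means.

    ``ridge`` is added to the covariance diagonal before inversion; the
    default is ``1e-6 * trace(Sigma) / d``, guarding against ill-conditioned
    finite-sample covariances.  With ``ridge=0`` the sample covariance must be
    full rank (requires more vectors than dimensions).
    """
    x = np.asarray(mu_vectors, dtype=float)
    if x.ndim != 2:
        raise ValueError("mu_vectors must be a 2D array")
    n, d = x.shape
    if n < 2:
        raise ValueError("need at least two reference vectors")
    xbar = x.mean(axis=0)
    centered = x - xbar
    sigma = centered.T @ centered / (n - 1)

    if ridge is None:
        ridge = 1e-6 * np.trace(sigma) / d
    if ridge < 0:
        raise ValueError("ridge must be non-negative")
    if ridge == 0 and n <= d:
        raise ValueError(
            f"covariance is singular with {n} vectors in {d} dimensions; "
            "provide more vectors or a positive ridge")

    reg = sigma + ridge * np.eye(d)
    try:
        cho = linalg.cho_factor(reg)
        sigma_inv = linalg.cho_solve(cho, np.eye(d))
    except linalg.LinAlgError as exc:
        raise ValueError("covariance not positive definite; "
                         "increase the ridge") from exc
    return ReferenceModel(xbar, sigma, sigma_inv, n, float(ridge))


def mahalanobis(x: np.ndarray, reference: ReferenceModel) -> float | np.ndarray:
    """sqrt((x - xbar) Sigma^-1 (x - xbar)^T); vectorized over rows of x."""
    x = np.asarray(x, dtype=float)
    single = x.ndim == 1
    x2 = np.atleast_2d(x)
    if x2.shape[1] != reference.xbar.shape[0]:
        raise ValueError("dimension mismatch with the reference model")
    delta = x2 - reference.xbar
    q = np.einsum("ni,ij,nj->n", delta, reference.sigma_inv, delta)
    md = np.sqrt(np.maximum(q, 0.0))
    return float(md[0]) if single else md


def score_case(model: TrainedVAE, reference: ReferenceModel,
               case: BeamCase) -> CaseScore:
    """Per-plane Mahalanobis distances of a beam case and their mean."""
    mu, _ = encode_batch(model, np.stack([m.values for m in case.maps]))
    md = mahalanobis(mu, reference)
    return CaseScore(case.beam_id, case.error, float(md[0]), float(md[1]))


def score_cases(model: TrainedVAE, reference: ReferenceModel,
                cases: list[BeamCase]) -> list[CaseScore]:
    """Score many cases with batched encoding."""
    maps = np.stack([m.values for c in cases for m in c.maps])
    mu, _ = encode_batch(model, maps)
    md = mahalanobis(mu, reference)
    return [
        CaseScore(c.beam_id, c.error, float(md[2 * i]), float(md[2 * i + 1]))
        for i, c in enumerate(cases)
    ]


def classify_md(md_mean: float, threshold: float) -> str:
    """'error-free' if the score is at or below the threshold, else 'any-error'."""
    if threshold < 0:
        raise ValueError("threshold must be non-negative")
    return "error-free" if md_mean <= threshold else "any-error"
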