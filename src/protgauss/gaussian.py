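"""Gaussian summary of a sequence's embedded k-mers.

The rows of a feature matrix are modelled as i.i.d. draws from a
multivariate normal N(mu, Sigma); the sequence is summarized by the
maximum-likelihood estimates: the empirical mean and the empirical
covariance with divisor 1/L (not the unbiased 1/(L-1) that numeric
libraries default to). A single-token sequence therefore has a zero
covariance matrix, which the downstream similarity handles explicitly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .embeddings import FeatureMatrix
from .errors import ValidationError


@dataclass
class GaussianRep:
    """MLE mean vector and covariance matrix of one sequence."""

    parent_id: str
    mu: np.ndarray
    sigma: np.ndarray
    n_tokens: int

    @property
    def d(self) -> int:
        return self.mu.shape[0]


def empirical_mean(X: FeatureMatrix | np.ndarray) -> np.ndarray:
    """Componentwise average of the rows: mu = (1/L) sum_i x_i."""
    rows = X.rows if isinstance(X, FeatureMatrix) else np.asarray(X, dtype=float)
    if rows.size == 0 or rows.shape[0] == 0:
        raise ValidationError("cannot take the mean of an empty feature matrix")
    return rows.mean(axis=0)


def empirical_covariance(X: FeatureMatrix | np.ndarray, mu: np.ndarray) -> np.ndarray:
    """MLE covariance: Sigma = (1/L) sum_i (x_i - mu)(x_i - mu)^T.

    The divisor is the number of rows L, not L-1. The result is
    symmetrized as (A + A^T)/2 to remove floating-point asymmetry.
    """
    rows = X.rows if isinstance(X, FeatureMatrix) else np.asarray(X, dtype=float)
    if rows.size == 0 or rows.shape[0] == 0:
        raise ValidationError("cannot estimate covariance of an empty feature matrix")
    mu = np.asarray(mu, dtype=float)
    if mu.shape != (rows.shape[1],):
        raise ValidationError(
            f"mean length {mu.shape} does not match column count {rows.shape[1]}"
        )
    dev = rows - mu
    sigma = dev.T @ dev / rows.shape[0]
    return (sigma + sigma.T) / 2.0


def to_gaussian(X: FeatureMatrix) -> GaussianRep:
    """Compose the two estimators into a :class:`GaussianRep`."""
    mu = empirical_mean(X)
    sigma = empirical_covariance(X, mu)
    return GaussianRep(parent_id=X.parent_id, mu=mu, sigma=sigma, n_tokens=X.rows.shape[0])


def save_gaussians(reps: list[GaussianRep], path) -> None:
    """Persist representations losslessly in a single .npz container."""
    if not reps:
        raise ValidationError("nothing to save")
    np.savez(
        path,
        ids=np.array([r.parent_id for r in reps]),
        mus=np.stack([r.mu for r in reps]),
        sigmas=np.stack([r.sigma for r in reps]),
        n_tokens=np.array([r.n_tokens for r in reps]),
    )


def load_gaussians(path) -> list[GaussianRep]:
    """Inverse of :func:`save_gaussians`; bit-exact round trip."""
    with np.load(path, allow_pickle=False) as data:
        return [
            GaussianRep(
                parent_id=str(data["ids"][i]),
                mu=data["mus"][i],
                sigma=data["sigmas"][i],
                n_tokens=int(data["n_tokens"][i]),
            )
            for i in range(len(data["ids"]))
        ]
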