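"""Similarity kernel between Gaussian sequence representations.

The similarity of two sequences is a convex combination, weighted by
``alpha``, of (a) the cosine similarity of their mean vectors and (b) a
normalized Frobenius inner product of their covariance matrices:

    sim(s_i, s_j) = alpha * cos(mu_i, mu_j)
                  + (1 - alpha) * <Sigma_i, Sigma_j>_F / (|Sigma_i|_F |Sigma_j|_F)

Both components are Gram matrices of unit-normalized objects, so every
square kernel built here is positive semi-definite and needs no
correction before use as a precomputed SVM kernel. A zero mean vector
or zero covariance (single-token sequence) contributes similarity 0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .embeddings import FeatureMatrix
from .errors import ValidationError
from .gaussian import GaussianRep, empirical_mean

#: Mixing weight at which the model performs best on held-out data;
#: alpha=1 uses only mean cosine, alpha=0 only covariance similarity.
DEFAULT_ALPHA = 0.3


@dataclass
class KernelMatrix:
    """Pairwise similarities; square (col_ids is None) or rectangular."""

    row_ids: list[str]
    values: np.ndarray
    alpha: float
    col_ids: list[str] | None = None

    @property
    def is_square(self) -> bool:
        return self.col_ids is None

    def to_text(self, path) -> None:
        """Export as tab-delimited text with id header row and column."""
        cols = self.col_ids if self.col_ids is not None else self.row_ids
        with open(path, "w") as fh:
            fh.write("id\t" + "\t".join(cols) + "\n")
            for rid, row in zip(self.row_ids, self.values):
                fh.write(rid + "\t" + "\t".join(repr(float(v)) for v in row) + "\n")


def _check_alpha(alpha: float) -> None:
    if not 0.0 <= alpha <= 1.0:
        raise ValidationError(f"alpha must lie in [0, 1], got {alpha}")


def mean_similarity(mu_i: np.ndarray, mu_j: np.ndarray) -> float:
    """Cosine similarity of the two mean vectors; 0 if either is zero."""
    mu_i = np.asarray(mu_i, dtype=float)
    mu_j = np.asarray(mu_j, dtype=float)
    if mu_i.shape != mu_j.shape:
        raise ValidationError("mean vectors have different lengths")
    ni, nj = np.linalg.norm(mu_i), np.linalg.norm(mu_j)
    if ni == 0.0 or nj == 0.0:
        return 0.0
    return float(mu_i @ mu_j / (ni * nj))


def cov_similarity(sigma_i: np.ndarray, sigma_j: np.ndarray) -> float:
    """Normalized Frobenius inner product of two covariance matrices.

    sum(Sigma_i . Sigma_j) / (|Sigma_i|_F |Sigma_j|_F); 0 if either
    matrix is entirely zero (degenerate single-token sequences).
    """
    sigma_i = np.asarray(sigma_i, dtype=float)
    sigma_j = np.asarray(sigma_j, dtype=float)
    if sigma_i.shape != sigma_j.shape:
        raise ValidationError("covariance matrices have different shapes")
    ni = np.linalg.norm(sigma_i)
    nj = np.linalg.norm(sigma_j)
    if ni == 0.0 or nj == 0.0:
        return 0.0
    return float(np.sum(sigma_i * sigma_j) / (ni * nj))


def sequence_similarity(g_i: GaussianRep, g_j: GaussianRep, alpha: float = DEFAULT_ALPHA) -> float:
    """Convex combination of mean and covariance similarities."""
    _check_alpha(alpha)
    return alpha * mean_similarity(g_i.mu, g_j.mu) + (1.0 - alpha) * cov_similarity(
        g_i.sigma, g_j.sigma
    )


def _normalized_stacks(reps: list[GaussianRep]) -> tuple[np.ndarray, np.ndarray]:
    """Unit-normalize stacked means and flattened covariances (zero rows stay zero)."""
    M = np.stack([r.mu for r in reps])
    S = np.stack([r.sigma.reshape(-1) for r in reps])
    mn = np.linalg.norm(M, axis=1, keepdims=True)
    sn = np.linalg.norm(S, axis=1, keepdims=True)
    M = np.divide(M, mn, out=np.zeros_like(M), where=mn > 0)
    S = np.divide(S, sn, out=np.zeros_like(S), where=sn > 0)
    return M, S


def build_kernel_matrix(reps: list[GaussianRep], alpha: float = DEFAULT_ALPHA) -> KernelMatrix:
    """Square kernel K_ij = sim(s_i, s_j) over one list of representations."""
    _check_alpha(alpha)
    if not reps:
        raise ValidationError("cannot build a kernel from an empty list")
    if len({r.d for r in reps}) != 1:
        raise ValidationError("all representations must share the embedding dimension")
    M, S = _normalized_stacks(reps)
    K = alpha * (M @ M.T) + (1.0 - alpha) * (S @ S.T)
    K = (K + K.T) / 2.0  # exact symmetry despite round-off
    return KernelMatrix(row_ids=[r.parent_id for r in reps], values=K, alpha=alpha)


def build_cross_kernel(
    reps_a: list[GaussianRep], reps_b: list[GaussianRep], alpha: float = DEFAULT_ALPHA
) -> KernelMatrix:
    """|a| x |b| rectangle of similarities (rows: a, columns: b)."""
    _check_alpha(alpha)
    if not reps_a or not reps_b:
        raise ValidationError("cannot build a kernel from an empty list")
    if len({r.d for r in reps_a} | {r.d for r in reps_b}) != 1:
        raise ValidationError("all representations must share the embedding dimension")
    Ma, Sa = _normalized_stacks(reps_a)
    Mb, Sb = _normalized_stacks(reps_b)
    K = alpha * (Ma @ Mb.T) + (1.0 - alpha) * (Sa @ Sb.T)
    return KernelMatrix(
        row_ids=[r.parent_id for r in reps_a],
        col_ids=[r.parent_id for r in reps_b],
        values=K,
        alpha=alpha,
    )


def mean_feature_vector(X: FeatureMatrix) -> np.ndarray:
    """Row-average of the feature matrix — the baselines' d-vector feature.

    Numerically identical to :func:`protgauss.gaussian.empirical_mean`;
    exposed separately because it is the entire representation used by
    the off-the-shelf baseline classifiers.
    """
    return empirical_mean(X)
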