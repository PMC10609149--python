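"""Dimensionality reduction: PCA by covariance eigendecomposition, and a
from-scratch t-SNE (Gaussian conditional similarities calibrated to a target
perplexity, symmetrized joint similarities, Student-t low-dimensional
affinities, KL-divergence gradient descent with momentum and early
exaggeration).

Both reducers are deterministic: PCA fixes component signs so the
largest-magnitude entry of each component is positive; t-SNE draws its
initial coordinates from a seeded generator.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .errors import ValidationError

logger = logging.getLogger(__name__)

__all__ = [
    "PCAModel",
    "TSNEConfig",
    "Embedding",
    "pca_fit",
    "pca_transform",
    "tsne_conditional_probs",
    "tsne_symmetrize",
    "tsne_low_dim_affinities",
    "kl_divergence",
    "tsne_embed",
]


@dataclass
class PCAModel:
    mean: np.ndarray
    components: np.ndarray  # rows are orthonormal eigenvectors, leading first
    eigenvalues: np.ndarray  # descending, non-negative

    def __post_init__(self) -> None:
        gram = self.components @ self.components.T
        if not np.allclose(gram, np.eye(self.components.shape[0]), atol=1e-8):
            raise ValidationError("PCA components are not row-orthonormal")
        if np.any(np.diff(self.eigenvalues) > 1e-10):
            raise ValidationError("PCA eigenvalues must be sorted descending")


@dataclass(frozen=True)
class TSNEConfig:
    out_dim: int = 3
    perplexity: float | None = None  # None -> min(30, (N - 1) / 3)
    n_iter: int = 1000
    learning_rate_embed: float = 200.0
    momentum_start: float = 0.5
    momentum_final: float = 0.8
    momentum_switch_iter: int = 250
    early_exaggeration: float = 4.0
    exaggeration_iters: int = 50
    init_sd: float = 1e-2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.out_dim not in (2, 3):
            raise ValidationError(f"out_dim must be 2 or 3, got {self.out_dim}")
        if self.perplexity is not None and self.perplexity <= 0:
            raise ValidationError("perplexity must be positive")
        if self.n_iter < 1:
            raise ValidationError("n_iter must be >= 1")
        if not (0 <= self.momentum_start < 1 and 0 <= self.momentum_final < 1):
            raise ValidationError("momentum must be in [0, 1)")


@dataclass
class Embedding:
    coords: np.ndarray
    method: str  # 'pca' or 'tsne'
    final_kl: float = 0.0
    kl_history: list[float] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not np.isfinite(self.coords).all():
            raise ValidationError("embedding coordinates must be finite")
        if self.method == "tsne" and self.final_kl < 0:
            raise ValidationError("final KL divergence must be non-negative")


# --- PCA -------------------------------------------------------------------

def pca_fit(matrix: np.ndarray, n_components: int) -> PCAModel:
    """Eigendecompose the sample covariance of the centered data.

    Components are the leading eigenvectors; each is sign-fixed so its
    largest-magnitude entry is positive.
    """
    X = np.asarray(matrix, dtype=float)
    n, m = X.shape
    if n < 2:
        raise ValidationError("PCA needs at least 2 samples")
    if not (1 <= n_components <= min(n, m)):
        raise ValidationError(
            f"n_components must be in [1, {min(n, m)}], got {n_components}"
        )
    mean = X.mean(axis=0)
    centered = X - mean
    cov = centered.T @ centered / (n - 1)
    eigvals, eigvecs = np.linalg.eigh(cov)
    order = np.argsort(eigvals)[::-1][:n_components]
    eigvals = np.clip(eigvals[order], 0.0, None)
    comps = eigvecs[:, order].T
    for i in range(comps.shape[0]):
        j = np.argmax(np.abs(comps[i]))
        if comps[i, j] < 0:
            comps[i] = -comps[i]
    return PCAModel(mean=mean, components=comps, eigenvalues=eigvals)


def pca_transform(model: PCAModel, matrix: np.ndarray) -> Embedding:
    """Project (possibly out-of-sample) data onto the fitted components."""
    X = np.atleast_2d(np.asarray(matrix, dtype=float))
    if X.shape[1] != model.mean.shape[0]:
        raise ValidationError(
            f"matrix has {X.shape[1]} columns, model expects {model.mean.shape[0]}"
        )
    return Embedding(coords=(X - model.mean) @ model.components.T, method="pca")


# --- t-SNE -----------------------------------------------------------------

def _squared_distances(X: np.ndarray) -> np.ndarray:
    sq = np.sum(X * X, axis=1)
    d2 = sq[:, None] + sq[None, :] - 2.0 * (X @ X.T)
    np.fill_diagonal(d2, 0.0)
    return np.clip(d2, 0.0, None)


def _row_probs(d2_row: np.ndarray, beta: float, i: int) -> tuple[np.ndarray, float]:
    """Conditional probabilities for one row at precision beta = 1/(2 sigma^2);
    returns (probs, Shannon entropy in bits)."""
    logits = -d2_row * beta
    logits[i] = -np.inf
    logits -= logits.max()
    w = np.exp(logits)
    w[i] = 0.0
    p = w / w.sum()
    nz = p > 0
    h = -np.sum(p[nz] * np.log2(p[nz]))
    return p, h


def tsne_conditional_probs(
    matrix: np.ndarray,
    perplexity: float,
    tol: float = 1e-5,
    max_iter: int = 64,
) -> np.ndarray:
    """Per-point Gaussian conditional probabilities Pr(j|i).

    Each bandwidth sigma_i is found by binary search on the precision so
    that 2^H(Pr(.|i)) matches the target perplexity within ``tol``.  The
    diagonal is zero and each row sums to one.
    """
    X = np.asarray(matrix, dtype=float)
    n = X.shape[0]
    if n < 3:
        raise ValidationError("t-SNE conditional probabilities need >= 3 points")
    if not (0 < perplexity < n):
        raise ValidationError(f"perplexity must be in (0, {n}), got {perplexity}")
    target_h = np.log2(perplexity)
    d2 = _squared_distances(X)
    P = np.zeros((n, n))
    for i in range(n):
        beta, beta_lo, beta_hi = 1.0, 0.0, np.inf
        p, h = _row_probs(d2[i], beta, i)
        for _ in range(max_iter):
            if abs(h - target_h) <= tol:
                break
            if h > target_h:  # too many effective neighbors: sharpen
                beta_lo = beta
                beta = beta * 2.0 if beta_hi == np.inf else (beta + beta_hi) / 2.0
            else:
                beta_hi = beta
                beta = beta / 2.0 if beta_lo == 0.0 else (beta + beta_lo) / 2.0
            p, h = _row_probs(d2[i], beta, i)
        else:
            logger.warning(
                "perplexity search did not converge for point %d (H=%.6f)", i, h
            )
        P[i] = p
    return P


def tsne_symmetrize(P: np.ndarray) -> np.ndarray:
    """Joint similarities s_ij = (Pr(i|j) + Pr(j|i)) / (2N); sums to 1."""
    P = np.asarray(P, dtype=float)
    if P.ndim != 2 or P.shape[0] != P.shape[1]:
        raise ValidationError("conditional matrix must be square")
    n = P.shape[0]
    return (P + P.T) / (2.0 * n)


def tsne_low_dim_affinities(coords: np.ndarray) -> np.ndarray:
    """Student-t (df=1) affinities Q_ij, normalized over all i != j pairs."""
    Y = np.asarray(coords, dtype=float)
    if Y.shape[0] < 2:
        raise ValidationError("need at least 2 points")
    kernel = 1.0 / (1.0 + _squared_distances(Y))
    np.fill_diagonal(kernel, 0.0)
    return kernel / kernel.sum()


def kl_divergence(S: np.ndarray, Q: np.ndarray, eps: float = 1e-12) -> float:
    """KL(S || Q) summed over off-diagonal entries; 0*log(0/q) = 0."""
    S = np.asarray(S, dtype=float)
    Q = np.asarray(Q, dtype=float)
    if S.shape != Q.shape:
        raise ValidationError("S and Q must have the same shape")
    mask = S > 0
    if np.any(Q[mask] <= 0):
        logger.warning("Q has zero entries where S > 0; flooring Q at %g", eps)
    q = np.maximum(Q, eps)
    return float(np.sum(S[mask] * np.log(S[mask] / q[mask])))


def tsne_embed(matrix: np.ndarray, config: TSNEConfig) -> Embedding:
    """Minimize KL(S||Q) by seeded momentum gradient descent.

    The joint similarities are multiplied by ``early_exaggeration`` for the
    first ``exaggeration_iters`` iterations; the KL history is recorded
    against the un-exaggerated S.
    """
    X = np.asarray(matrix, dtype=float)
    n = X.shape[0]
    perplexity = config.perplexity
    if perplexity is None:
        perplexity = min(30.0, max((n - 1) / 3.0, 2.0))
    if perplexity >= n:
        raise ValidationError(f"perplexity {perplexity} must be < n points {n}")

    S = tsne_symmetrize(tsne_conditional_probs(X, perplexity))
    rng = np.random.default_rng(config.seed)
    Y = rng.normal(0.0, config.init_sd, size=(n, config.out_dim))
    velocity = np.zeros_like(Y)
    gains = np.ones_like(Y)  # per-coordinate step adaptation, as in classic t-SNE
    kl_history: list[float] = []

    for it in range(config.n_iter):
        exaggerate = it < config.exaggeration_iters
        S_eff = S * config.early_exaggeration if exaggerate else S
        d2 = _squared_distances(Y)
        kernel = 1.0 / (1.0 + d2)
        np.fill_diagonal(kernel, 0.0)
        Q = kernel / kernel.sum()

        # grad_i = 4 * sum_j (s_ij - q_ij) (y_i - y_j) / (1 + |y_i - y_j|^2)
        W = (S_eff - Q) * kernel
        grad = 4.0 * ((np.diag(W.sum(axis=1)) - W) @ Y)

        momentum = (
            config.momentum_start
            if it < config.momentum_switch_iter
            else config.momentum_final
        )
        same_sign = np.sign(grad) == np.sign(velocity)
        gains = np.where(same_sign, gains * 0.8, gains + 0.2)
        np.clip(gains, 0.01, None, out=gains)
        velocity = momentum * velocity - config.learning_rate_embed * gains * grad
        Y = Y + velocity

        kl = kl_divergence(S, Q)
        if not np.isfinite(kl) or not np.isfinite(Y).all():
            raise ValidationError(f"t-SNE diverged at iteration {it}")
        kl_history.append(kl)

    final_kl = kl_divergence(S, tsne_low_dim_affinities(Y))
    return Embedding(coords=Y, method="tsne", final_kl=final_kl, kl_history=kl_history)
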