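"""Similarity-regularized matrix factorization (MDMF) and feature reduction.

Approximates the binary association matrix A as U V^T while pulling the
factor Gram matrices toward the integrated similarity matrices:

    L(U, V) = ||A - U V^T||_F^2
              + lambda (||U||_F^2 + ||V||_F^2
                        + ||U U^T - Sm||_F^2 + ||V V^T - Sd||_F^2)

minimized by full-batch gradient descent with backtracking line search.
Zeros of A are treated as weak negatives (the full Frobenius objective);
an optional mask restricts reconstruction to observed positives.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.decomposition import PCA

from .containers import AssociationMatrix, FeatureBlock, SimilarityMatrix

__all__ = ["FactorModel", "mdmf_loss", "mdmf_gradients", "fit_mdmf", "mdmf_features", "gip_feature_block"]


@dataclass
class FactorModel:
    U: np.ndarray  # (m, l)
    V: np.ndarray  # (n, l)
    l: int
    lambda_reg: float
    loss_trace: list[float] = field(default_factory=list)
    mirna_ids: list[str] = field(default_factory=list)
    disease_ids: list[str] = field(default_factory=list)


def _residual(A: np.ndarray, U: np.ndarray, V: np.ndarray, mask: np.ndarray | None) -> np.ndarray:
    R = A - U @ V.T
    if mask is not None:
        R = R * mask
    return R


def mdmf_loss(
    A: np.ndarray,
    U: np.ndarray,
    V: np.ndarray,
    Sm: np.ndarray,
    Sd: np.ndarray,
    lam: float,
    mask: np.ndarray | None = None,
) -> float:
    R = _residual(A, U, V, mask)
    loss = float((R * R).sum())
    if lam:
        Gu = U @ U.T - Sm
        Gv = V @ V.T - Sd
        loss += lam * float((U * U).sum() + (V * V).sum() + (Gu * Gu).sum() + (Gv * Gv).sum())
    return loss


def mdmf_gradients(
    A: np.ndarray,
    U: np.ndarray,
    V: np.ndarray,
    Sm: np.ndarray,
    Sd: np.ndarray,
    lam: float,
    mask: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Analytic gradients of the MDMF objective w.r.t. U and V."""
    R = _residual(A, U, V, mask)
    gU = -2.0 * R @ V
    gV = -2.0 * R.T @ U
    if lam:
        # d/dU ||UU^T - Sm||_F^2 = 4 (UU^T - Sm) U   (Sm symmetric)
        gU += lam * (2.0 * U + 4.0 * (U @ U.T - Sm) @ U)
        gV += lam * (2.0 * V + 4.0 * (V @ V.T - Sd) @ V)
    return gU, gV


def fit_mdmf(
    A: AssociationMatrix,
    Sm: SimilarityMatrix,
    Sd: SimilarityMatrix,
    l: int = 42,
    lambda_reg: float = 0.0121,
    max_iters: int = 300,
    tol: float = 1e-7,
    step: float = 1e-3,
    seed: int = 0,
    mask_observed_only: bool = False,
) -> FactorModel:
    """Gradient-descent fit with backtracking; deterministic under seed.

    The step size halves whenever a step would increase the loss, so the
    recorded loss trace is non-increasing after the first accepted step.
    """
    m, n = A.shape
    if Sm.values.shape != (m, m) or Sd.values.shape != (n, n):
        raise ValueError("similarity matrix shapes do not match A")
    if l < 1:
        raise ValueError("latent dimension must be >= 1")
    rng = np.random.default_rng(seed)
    Av = A.values.astype(float)
    U = rng.normal(scale=1.0 / np.sqrt(l), size=(m, l))
    V = rng.normal(scale=1.0 / np.sqrt(l), size=(n, l))
    mask = Av.copy() if mask_observed_only else None
    Smv, Sdv = Sm.values, Sd.values
    loss = mdmf_loss(Av, U, V, Smv, Sdv, lambda_reg, mask)
    trace = [loss]
    for _ in range(max_iters):
        gU, gV = mdmf_gradients(Av, U, V, Smv, Sdv, lambda_reg, mask)
        while True:
            U_new = U - step * gU
            V_new = V - step * gV
            new_loss = mdmf_loss(Av, U_new, V_new, Smv, Sdv, lambda_reg, mask)
            if not np.isfinite(new_loss):
                raise FloatingPointError("MDMF loss diverged; step size too large")
            if new_loss <= loss or step < 1e-15:
                break
            step *= 0.5
        step = min(step * 1.2, 1.0)  # regrow after accepted steps; backtracking guards descent
        U, V = U_new, V_new
        rel = abs(loss - new_loss) / max(abs(loss), 1e-12)
        loss = new_loss
        trace.append(loss)
        if rel < tol:
            break
    return FactorModel(U, V, l, lambda_reg, trace, list(A.mirna_ids), list(A.disease_ids))


def mdmf_features(model: FactorModel, pca_dim: int = 32) -> FeatureBlock:
    """PCA-reduce the stacked factors [U; V] onto a shared basis."""
    if pca_dim > model.l:
        raise ValueError(f"pca_dim={pca_dim} exceeds latent dimension l={model.l}")
    stacked = np.vstack([model.U, model.V])
    n_comp = min(pca_dim, stacked.shape[0])
    pca = PCA(n_components=n_comp, svd_solver="full")
    Z = pca.fit_transform(stacked)
    if n_comp < pca_dim:  # degenerate tiny inputs: pad to requested width
        Z = np.hstack([Z, np.zeros((Z.shape[0], pca_dim - n_comp))])
    m = model.U.shape[0]
    return FeatureBlock(Z[:m], Z[m:], "mdmf", pca_dim)


def gip_feature_block(
    mirna_sim: SimilarityMatrix, disease_sim: SimilarityMatrix, pca_dim: int = 32
) -> FeatureBlock:
    """Similarity-profile node features, PCA-reduced per entity type.

    Rows of the integrated similarity matrices are the raw profiles; miRNA
    and disease profiles have different lengths, so each type gets its own
    PCA basis, padded with zero columns when an entity type has fewer
    directions than ``pca_dim``.
    """

    def reduce(S: np.ndarray) -> np.ndarray:
        n_comp = min(pca_dim, *S.shape)
        pca = PCA(n_components=n_comp, svd_solver="full")
        Z = pca.fit_transform(S)
        if n_comp < pca_dim:
            Z = np.hstack([Z, np.zeros((Z.shape[0], pca_dim - n_comp))])
        return Z

    return FeatureBlock(reduce(mirna_sim.values), reduce(disease_sim.values), "gipk", pca_dim)
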