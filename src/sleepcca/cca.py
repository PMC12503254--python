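"""Canonical correlation analysis via paired orthogonal decompositions.

Each centered block is reduced to an orthonormal basis by economy QR; the
cross-product of the two bases is a correlation-like matrix whose SVD yields
the canonical structure.  Weights are back-solved through the triangular
factors so that the canonical variates are exact linear images of the data:
``U = X_c @ A`` and ``V = Y_c @ B``.  The number of components equals the
numerical rank of the cross-product, which for full-rank blocks is the
smaller block width — seven when seven sleep sub-scores face a wide
biopsychosocial block.

Loadings (structure coefficients) are Pearson correlations between original
variables and the canonical variate of their own block; the share of
cross-block covariance carried by component ``i`` is its squared singular
value over the total.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
from scipy.linalg import qr, solve_triangular, svd

from .datatypes import BlockMatrix, CCAModel

logger = logging.getLogger(__name__)


def _orthonormalize(M: np.ndarray, name: str):
    """Economy QR of a centered block, falling back to an SVD basis when the
    block is numerically rank deficient.

    Returns ``(Q, backsolve)`` where ``Q`` is an orthonormal column basis and
    ``backsolve(W)`` maps weights expressed in the basis to weights on the
    original variables (so ``M @ backsolve(W) == Q @ W``).
    """
    n, p = M.shape
    Q, R = qr(M, mode="economic")
    diag = np.abs(np.diag(R))
    tol = max(n, p) * np.finfo(float).eps * (diag.max() if diag.size else 0.0)
    if diag.size and diag.min() > tol:
        return Q, lambda W: solve_triangular(R, W)
    # rank collapse: use the SVD column basis restricted to retained directions
    U, s, Vt = svd(M, full_matrices=False)
    r = int((s > max(n, p) * np.finfo(float).eps * s[0]).sum())
    warnings.warn(
        f"{name} block is numerically rank deficient (rank {r} < {p}); "
        "components reduced",
        RuntimeWarning,
        stacklevel=3,
    )
    Ur, sr, Vr = U[:, :r], s[:r], Vt[:r].T
    return Ur, lambda W: Vr @ (W / sr[:, None])


def fit_cca(X: BlockMatrix, Y: BlockMatrix) -> CCAModel:
    """Fit the canonical decomposition of two row-aligned blocks.

    Blocks are column-centered internally (residualization with an intercept
    already centers them; centering again is a no-op in that case).
    Canonical correlations are returned both as the singular values of the
    basis cross-product and as the Pearson correlations of the paired
    variates — the two agree to round-off and that agreement is asserted.
    """
    n = X.n_subjects
    if Y.n_subjects != n:
        raise ValueError("blocks have different numbers of subjects")
    p, q = X.n_variables, Y.n_variables
    if p >= n or q >= n:
        raise ValueError(
            f"need more subjects than variables per block (n={n}, p={p}, q={q})"
        )
    for blk, name in ((X, "sleep"), (Y, "biopsychosocial")):
        if np.any(np.ptp(blk.values, axis=0) == 0):
            j = int(np.argmin(np.ptp(blk.values, axis=0)))
            raise ValueError(
                f"constant column '{blk.variable_names[j]}' in {name} block"
            )

    x_mean = X.values.mean(axis=0)
    y_mean = Y.values.mean(axis=0)
    Xc = X.values - x_mean
    Yc = Y.values - y_mean

    Q1, solve_x = _orthonormalize(Xc, "sleep")
    Q2, solve_y = _orthonormalize(Yc, "biopsychosocial")

    cross = Q1.T @ Q2
    A0, s, B0t = svd(cross, full_matrices=False)
    # clip tiny overshoots of 1 from round-off
    s = np.clip(s, 0.0, 1.0)
    tol = max(p, q) * np.finfo(float).eps * (s[0] if s.size else 0.0)
    k = int((s > tol).sum())
    if k < min(Q1.shape[1], Q2.shape[1]):
        logger.warning("cross-product rank collapsed to k=%d", k)

    A = solve_x(A0[:, :k])
    B = solve_y(B0t.T[:, :k])
    U = Xc @ A
    V = Yc @ B

    corrs = np.array(
        [np.corrcoef(U[:, i], V[:, i])[0, 1] for i in range(k)]
    )
    if not np.allclose(corrs, s[:k], atol=1e-8):
        raise AssertionError("canonical correlations disagree with singular values")

    model = CCAModel(
        sleep_weights=A,
        bps_weights=B,
        singular_values=s[:k],
        canonical_corrs=corrs,
        sleep_scores=U,
        bps_scores=V,
        x_mean=x_mean,
        y_mean=y_mean,
    )
    model.explained_cov = explained_covariance(model)
    return model


def compute_loadings(model: CCAModel, X: BlockMatrix, Y: BlockMatrix) -> CCAModel:
    """Attach structure coefficients: per-variable Pearson correlations with
    the canonical variate of the variable's own block."""
    for scores, name in ((model.sleep_scores, "sleep"), (model.bps_scores, "bps")):
        if np.any(scores.std(axis=0) == 0):
            raise ValueError(f"zero-variance {name} score column")
    model.sleep_loadings = _block_loadings(X.values, model.sleep_scores)
    model.bps_loadings = _block_loadings(Y.values, model.bps_scores)
    return model


def _block_loadings(data: np.ndarray, scores: np.ndarray) -> np.ndarray:
    dc = data - data.mean(axis=0)
    sc = scores - scores.mean(axis=0)
    num = dc.T @ sc
    denom = np.outer(
        np.sqrt((dc**2).sum(axis=0)), np.sqrt((sc**2).sum(axis=0))
    )
    return num / denom


def explained_covariance(model: CCAModel) -> np.ndarray:
    """Fraction of cross-block covariance carried by each component:
    squared singular values normalized to sum to one."""
    s2 = model.singular_values**2
    return s2 / s2.sum()


def orient_components(model: CCAModel) -> CCAModel:
    """Fix the arbitrary sign of each component.

    Convention: the sleep variable with the largest absolute loading gets a
    positive loading.  U, V, both weight matrices and both loading matrices
    flip coherently, so all paired correlations are unchanged.  Idempotent.
    """
    if model.sleep_loadings is None:
        raise ValueError("compute_loadings must run before orientation")
    for i in range(model.k):
        j = int(np.argmax(np.abs(model.sleep_loadings[:, i])))
        if model.sleep_loadings[j, i] < 0:
            for arr in (
                model.sleep_weights,
                model.bps_weights,
                model.sleep_scores,
                model.bps_scores,
                model.sleep_loadings,
                model.bps_loadings,
            ):
                arr[:, i] *= -1
    return model


def composite_scores(model: CCAModel) -> np.ndarray:
    """Per-subject composite: mean of the standardized paired variates.

    ``composite[:, i] = (zscore(U[:, i]) + zscore(V[:, i])) / 2``.  This is
    the per-component subject score used as the predictor in the connectome
    GLMs.
    """
    U, V = model.sleep_scores, model.bps_scores
    zu = (U - U.mean(axis=0)) / U.std(axis=0)
    zv = (V - V.mean(axis=0)) / V.std(axis=0)
    return (zu + zv) / 2.0


def project(model: CCAModel, X: BlockMatrix, Y: BlockMatrix) -> tuple[np.ndarray, np.ndarray]:
    """Project new blocks through fitted weights using the training means.

    Returns out-of-sample canonical variates ``(U*, V*)``; the basis of
    cross-validated generalization tests.
    """
    U = (X.values - model.x_mean) @ model.sleep_weights
    V = (Y.values - model.y_mean) @ model.bps_weights
    return U, V
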