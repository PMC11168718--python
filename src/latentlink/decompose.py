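"""SVD-based fitting of PLS and CCA latent-variable models.

Both methods decompose a cross-product matrix by singular value
decomposition.  PLS decomposes the between-block correlation matrix ``R_XY``
directly and its loadings are the singular vectors ``U`` and ``V``.  CCA
decomposes the whitened matrix ``Omega = R_XX^{-1/2} R_XY R_YY^{-1/2}``; its
singular values are the canonical correlations and its singular vectors
("generalized singular vectors") are reweighted into canonical weights
``Wx = R_XX^{-1/2} U`` and ``Wy = R_YY^{-1/2} V``.  The number of latent
variables always equals min(p, q).

Sign convention: the direction of a latent variable is arbitrary, so each LV
is oriented to make its largest-magnitude behavior loading positive.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .preprocess import CrossProductSet, ResidualizedBlock

__all__ = ["LatentModel", "LatentScores", "fit_pls", "fit_cca",
           "latent_scores", "variance_explained"]

log = logging.getLogger(__name__)


@dataclass
class LatentModel:
    """Singular vectors, singular values and (for CCA) canonical weights."""

    method: str                     # 'pls' or 'cca'
    U: np.ndarray                   # p x L left singular vectors
    V: np.ndarray                   # q x L right singular vectors
    S: np.ndarray                   # L singular values, non-increasing
    varexp: np.ndarray              # s_i^2 / sum s^2
    x_names: list[str]
    y_names: list[str]
    Wx: np.ndarray | None = None    # canonical weights (cca only)
    Wy: np.ndarray | None = None
    structure_x: np.ndarray | None = None  # correlations of variables with scores
    structure_y: np.ndarray | None = None

    @property
    def L(self) -> int:
        return self.S.shape[0]

    @property
    def loadings_x(self) -> np.ndarray:
        """The reported per-variable loadings: U for PLS, Wx for CCA."""
        return self.U if self.method == "pls" else self.Wx

    @property
    def loadings_y(self) -> np.ndarray:
        return self.V if self.method == "pls" else self.Wy


@dataclass
class LatentScores:
    scores_x: np.ndarray
    scores_y: np.ndarray
    standardized_by_singular_values: bool


def _checked_svd(M: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    if not np.all(np.isfinite(M)):
        raise ValueError("cross-product matrix has non-finite entries")
    U, S, Vt = np.linalg.svd(M, full_matrices=False)
    gaps = -np.diff(S)
    if np.any(gaps < 1e-6):
        log.info("near-equal singular values (gap < 1e-6) at %s",
                 np.where(gaps < 1e-6)[0].tolist())
    return U, S, Vt.T


def _orient(U: np.ndarray, V: np.ndarray, ref_y: np.ndarray) -> None:
    """Flip LV signs in place so the largest-|loading| behavior element > 0."""
    for j in range(V.shape[1]):
        i = int(np.argmax(np.abs(ref_y[:, j])))
        if ref_y[i, j] < 0:
            U[:, j] *= -1.0
            V[:, j] *= -1.0


def variance_explained(S: np.ndarray) -> np.ndarray:
    """Fraction of the squared spectrum carried by each LV: s_i^2 / sum s^2."""
    S = np.asarray(S, float)
    if np.any(S < 0):
        raise ValueError("singular values must be non-negative")
    total = float(np.sum(S ** 2))
    if total == 0:
        raise ValueError("all singular values are zero")
    return S ** 2 / total


def fit_pls(cp: CrossProductSet, compute_structure: bool = False) -> LatentModel:
    """Partial least squares correlation: SVD of R_XY.

    Loadings are the singular vectors themselves; singular values are
    correlation-scale covariances of unit-weight latent score pairs.
    """
    U, S, V = _checked_svd(cp.R_XY)
    _orient(U, V, V)
    model = LatentModel(
        method="pls", U=U, V=V, S=S, varexp=variance_explained(S),
        x_names=list(cp.x_names), y_names=list(cp.y_names),
    )
    if compute_structure:
        model.structure_x = cp.R_XX @ U
        model.structure_y = cp.R_YY @ V
    return model


def fit_cca(cp: CrossProductSet, compute_structure: bool = False) -> LatentModel:
    """Canonical correlation analysis: SVD of Omega, vectors reweighted.

    The singular values are the canonical correlations; canonical weights
    satisfy Wx^T R_XX Wx = I so latent score pairs have unit variance and
    correlation equal to the singular value.
    """
    if cp.Omega is None:
        raise ValueError("CrossProductSet has no Omega matrix")
    U, S, V = _checked_svd(cp.Omega)
    Kx = cp.R_XX_inv_sqrt
    Ky = cp.R_YY_inv_sqrt
    Wx = Kx @ U
    Wy = Ky @ V
    # orient by the reported (reweighted) behavior loadings
    for j in range(V.shape[1]):
        i = int(np.argmax(np.abs(Wy[:, j])))
        if Wy[i, j] < 0:
            U[:, j] *= -1.0
            V[:, j] *= -1.0
            Wx[:, j] *= -1.0
            Wy[:, j] *= -1.0
    model = LatentModel(
        method="cca", U=U, V=V, S=S, varexp=variance_explained(S),
        x_names=list(cp.x_names), y_names=list(cp.y_names), Wx=Wx, Wy=Wy,
    )
    if compute_structure:
        model.structure_x = cp.R_XX @ Wx
        model.structure_y = cp.R_YY @ Wy
    return model


def latent_scores(model: LatentModel, X: ResidualizedBlock, Y: ResidualizedBlock,
                  standardize: bool = False) -> LatentScores:
    """Project the analysis-transformed blocks onto the model's weights.

    PLS scores are X U and Y V; CCA scores are X Wx and Y Wy, so that on the
    same transformed matrices used to build the cross-products the i-th score
    pair has Pearson correlation equal to the i-th canonical correlation.
    With ``standardize`` the columns are scaled by the singular values (a
    display convention for score scatter plots).
    """
    Xv = X.values if hasattr(X, "values") else np.asarray(X, float)
    Yv = Y.values if hasattr(Y, "values") else np.asarray(Y, float)
    Wx = model.U if model.method == "pls" else model.Wx
    Wy = model.V if model.method == "pls" else model.Wy
    if Xv.shape[1] != Wx.shape[0] or Yv.shape[1] != Wy.shape[0]:
        raise ValueError("block dimensions do not match model loadings")
    sx = Xv @ Wx
    sy = Yv @ Wy
    if standardize:
        sx = sx * model.S
        sy = sy * model.S
    return LatentScores(sx, sy, standardized_by_singular_values=standardize)
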