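"""Covariate residualization, rank/Z standardization and cross-product matrices.

The two-block analyses downstream (CCA and PLS) both decompose a between-block
correlation matrix.  This module produces the matrices they need:

* ``residualize`` removes linear nuisance effects (age, sex, head size, site,
  scanner, plus any extra covariates) from every column of a data block by
  ordinary least squares and Z-transforms the residuals.
* ``rank_standardize`` replaces each column by average ranks and Z-transforms
  them, so that ordinary Pearson products of the output equal Spearman
  correlations of the input (exactly, including ties).
* ``build_cross_products`` assembles ``R_XY`` (decomposed by PLS) together
  with the within-block matrices ``R_XX``, ``R_YY`` and the adjusted matrix
  ``Omega = R_XX^{-1/2} R_XY R_YY^{-1/2}`` (decomposed by CCA).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import scipy.linalg
from scipy.stats import rankdata

__all__ = [
    "DataBlock",
    "CovariateTable",
    "ResidualizedBlock",
    "CrossProductSet",
    "residualize",
    "rank_standardize",
    "correlation_matrix",
    "inv_sqrt_psd",
    "build_cross_products",
    "transform_block",
]


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class DataBlock:
    """A participant-by-variable numeric table (brain or behavior role)."""

    values: np.ndarray
    participant_ids: list[str]
    variable_names: list[str]
    role: str = "brain"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("DataBlock values must be 2-D")
        n, p = self.values.shape
        if n != len(self.participant_ids) or p != len(self.variable_names):
            raise ValueError("DataBlock shape does not match id/name lists")
        if np.isnan(self.values).any():
            raise ValueError("DataBlock contains missing values")
        if n < p:
            warnings.warn(
                f"{self.role} block has more variables ({p}) than rows ({n})",
                stacklevel=2,
            )

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def p(self) -> int:
        return self.values.shape[1]

    def subset(self, idx: np.ndarray) -> "DataBlock":
        idx = np.asarray(idx)
        return DataBlock(
            self.values[idx],
            [self.participant_ids[i] for i in idx],
            list(self.variable_names),
            self.role,
        )

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=self.variable_names)
        df.insert(0, "participant_id", self.participant_ids)
        return df

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, role: str = "brain") -> "DataBlock":
        if "participant_id" not in df.columns:
            raise ValueError("expected a 'participant_id' column")
        ids = df["participant_id"].astype(str).tolist()
        rest = df.drop(columns=["participant_id"])
        return cls(rest.to_numpy(float), ids, [str(c) for c in rest.columns], role)

    def write_tsv(self, path) -> None:
        self.to_dataframe().to_csv(path, sep="\t", index=False, float_format="%.10g")

    @classmethod
    def read_tsv(cls, path, role: str = "brain") -> "DataBlock":
        return cls.from_dataframe(pd.read_csv(path, sep="\t"), role)


@dataclass
class CovariateTable:
    """Per-participant nuisance covariates.

    ``site`` and ``scanner`` (and any column listed in ``categorical``) are
    dummy-coded with a first-level reference; remaining columns enter the
    design as-is.  Extra columns (e.g. household income for sensitivity
    analyses) are simply extra columns of ``frame``.
    """

    frame: pd.DataFrame
    participant_ids: list[str]
    categorical: tuple[str, ...] = ("site", "scanner")

    def __post_init__(self) -> None:
        if len(self.frame) != len(self.participant_ids):
            raise ValueError("covariate frame length does not match ids")

    @property
    def n(self) -> int:
        return len(self.frame)

    def subset(self, idx: np.ndarray) -> "CovariateTable":
        idx = np.asarray(idx)
        return CovariateTable(
            self.frame.iloc[idx].reset_index(drop=True),
            [self.participant_ids[i] for i in idx],
            self.categorical,
        )

    def design_matrix(self) -> tuple[np.ndarray, list[str], list[str]]:
        """Intercept + continuous columns + dummy-coded categoricals.

        Returns ``(D, names, dropped)``.  Continuous columns that are mutually
        collinear raise an error naming the offenders; dummy columns aliased
        by earlier columns (e.g. scanner dummies when sites are nested within
        scanners) are dropped and reported in ``dropped``, mirroring the
        aliasing behaviour of standard linear-model software.
        """
        n = self.n
        cols: list[np.ndarray] = [np.ones(n)]
        names: list[str] = ["intercept"]
        for c in self.frame.columns:
            if c in self.categorical or self.frame[c].dtype == object:
                continue
            cols.append(self.frame[c].to_numpy(float))
            names.append(str(c))
        D = np.column_stack(cols)
        if np.linalg.matrix_rank(D) < D.shape[1]:
            bad = _collinear_columns(D, names)
            raise ValueError(f"collinear continuous covariates: {bad}")
        for c in self.frame.columns:
            if not (c in self.categorical or self.frame[c].dtype == object):
                continue
            dummies = pd.get_dummies(self.frame[c].astype(str), prefix=str(c),
                                     drop_first=True)
            for dc in dummies.columns:
                cols.append(dummies[dc].to_numpy(float))
                names.append(str(dc))
        D = np.column_stack(cols)
        # left-to-right scan: a column already spanned by earlier ones is
        # aliased and dropped, so nested scanner dummies (appearing after the
        # site dummies) are the ones removed
        Q = np.empty_like(D)
        kept: list[int] = []
        dropped: list[str] = []
        for j in range(D.shape[1]):
            v = D[:, j].copy()
            norm0 = np.linalg.norm(v)
            if kept:
                v -= Q[:, :len(kept)] @ (Q[:, :len(kept)].T @ v)
                v -= Q[:, :len(kept)] @ (Q[:, :len(kept)].T @ v)
            norm = np.linalg.norm(v)
            if norm <= 1e-9 * max(norm0, 1.0):
                dropped.append(names[j])
                continue
            Q[:, len(kept)] = v / norm
            kept.append(j)
        D = D[:, kept]
        names = [names[j] for j in kept]
        return D, names, dropped

    def to_dataframe(self) -> pd.DataFrame:
        df = self.frame.copy()
        df.insert(0, "participant_id", self.participant_ids)
        return df

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame,
                       categorical: tuple[str, ...] = ("site", "scanner")
                       ) -> "CovariateTable":
        if "participant_id" not in df.columns:
            raise ValueError("expected a 'participant_id' column")
        ids = df["participant_id"].astype(str).tolist()
        return cls(df.drop(columns=["participant_id"]).reset_index(drop=True),
                   ids, categorical)

    def write_tsv(self, path) -> None:
        self.to_dataframe().to_csv(path, sep="\t", index=False, float_format="%.10g")

    @classmethod
    def read_tsv(cls, path, categorical: tuple[str, ...] = ("site", "scanner")
                 ) -> "CovariateTable":
        return cls.from_dataframe(pd.read_csv(path, sep="\t"), categorical)


@dataclass
class ResidualizedBlock:
    """Residuals of a DataBlock after nuisance regression, Z-transformed.

    ``transform`` records whether columns are plain Z-scored residuals
    (``z_only``) or average ranks of residuals, Z-scored (``rank_then_z``).
    Columns have mean 0 and SD 1 (n-1 denominator).
    """

    values: np.ndarray
    participant_ids: list[str]
    variable_names: list[str]
    role: str
    design_columns_used: list[str]
    transform: str = "z_only"
    #: orthonormal basis of the design column space, kept so permutation
    #: procedures can re-project shuffled rows onto the residual subspace
    design_basis: np.ndarray | None = None

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def p(self) -> int:
        return self.values.shape[1]

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=self.variable_names)
        df.insert(0, "participant_id", self.participant_ids)
        return df

    def write_tsv(self, path) -> None:
        self.to_dataframe().to_csv(path, sep="\t", index=False, float_format="%.10g")


@dataclass
class CrossProductSet:
    """The matrices both methods decompose, for one correlation type.

    ``R_XY`` is the between-block correlation matrix (PLS target);
    ``Omega = R_XX^{-1/2} R_XY R_YY^{-1/2}`` is its within-block-whitened
    counterpart (CCA target).  The inverse square roots are retained because
    CCA needs them again to reweight singular vectors into canonical weights.
    """

    R_XY: np.ndarray
    R_XX: np.ndarray
    R_YY: np.ndarray
    Omega: np.ndarray
    correlation_type: str
    ridge_eps: float
    R_XX_inv_sqrt: np.ndarray | None = None
    R_YY_inv_sqrt: np.ndarray | None = None
    x_names: list[str] = field(default_factory=list)
    y_names: list[str] = field(default_factory=list)

    @property
    def p(self) -> int:
        return self.R_XY.shape[0]

    @property
    def q(self) -> int:
        return self.R_XY.shape[1]


# ---------------------------------------------------------------------------
# helpers
# ---------------------------------------------------------------------------

def _collinear_columns(D: np.ndarray, names: Sequence[str]) -> list[str]:
    _, R, piv = scipy.linalg.qr(D, mode="economic", pivoting=True)
    diag = np.abs(np.diag(R))
    tol = diag.max() * max(D.shape) * np.finfo(float).eps
    rank = int((diag > tol).sum())
    return [names[j] for j in sorted(piv[rank:])]


def _zscore(a: np.ndarray, names: Sequence[str]) -> np.ndarray:
    mu = a.mean(axis=0)
    sd = a.std(axis=0, ddof=1)
    bad = np.where(sd == 0)[0]
    if bad.size:
        raise ValueError(f"constant column(s): {[names[j] for j in bad]}")
    return (a - mu) / sd


def _values_of(block) -> np.ndarray:
    return block.values if hasattr(block, "values") else np.asarray(block, float)


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def residualize(block: DataBlock, covariates: CovariateTable) -> ResidualizedBlock:
    """OLS-residualize every column of ``block`` on the covariate design.

    The design is an intercept plus all continuous covariates plus dummy-coded
    categoricals; residuals are exactly orthogonal to every design column and
    are returned Z-transformed (mean 0, SD 1 with the n-1 denominator).
    """
    if list(block.participant_ids) != list(covariates.participant_ids):
        raise ValueError("participant IDs of block and covariates do not match")
    D, names, _dropped = covariates.design_matrix()
    if np.linalg.matrix_rank(D) < D.shape[1]:
        raise ValueError(
            f"rank-deficient design; collinear columns: {_collinear_columns(D, names)}"
        )
    beta, *_ = np.linalg.lstsq(D, block.values, rcond=None)
    resid = block.values - D @ beta
    resid = _zscore(resid, block.variable_names)
    Q, _ = np.linalg.qr(D)
    return ResidualizedBlock(
        values=resid,
        participant_ids=list(block.participant_ids),
        variable_names=list(block.variable_names),
        role=block.role,
        design_columns_used=names,
        transform="z_only",
        design_basis=Q,
    )


def rank_standardize(block: ResidualizedBlock) -> ResidualizedBlock:
    """Replace each column by average ranks (ties -> mean rank), then Z-score.

    Pearson products of the output equal Spearman correlations of the input.
    Idempotent up to the affine rescaling: ranking a ranked column returns the
    same ranks.
    """
    vals = _values_of(block)
    for j in range(vals.shape[1]):
        if np.all(vals[:, j] == vals[0, j]):
            raise ValueError(
                f"constant column '{block.variable_names[j]}': ranks undefined"
            )
    ranked = rankdata(vals, axis=0, method="average")
    ranked = _zscore(ranked, block.variable_names)
    return ResidualizedBlock(
        values=ranked,
        participant_ids=list(block.participant_ids),
        variable_names=list(block.variable_names),
        role=block.role,
        design_columns_used=list(block.design_columns_used),
        transform="rank_then_z",
        design_basis=getattr(block, "design_basis", None),
    )


def transform_block(block: ResidualizedBlock, correlation_type: str) -> ResidualizedBlock:
    """Return the block on the scale matching ``correlation_type``.

    For the Spearman path the analysis matrices are rank-then-Z transformed,
    which keeps latent-score identities (e.g. corr of CCA score pairs equals
    the singular value) exact; for Pearson the residualized block is used
    directly.
    """
    if correlation_type == "spearman":
        if block.transform == "rank_then_z":
            return block
        return rank_standardize(block)
    if correlation_type == "pearson":
        return block
    raise ValueError(f"unknown correlation type: {correlation_type!r}")


def correlation_matrix(A, B, type: str = "pearson") -> np.ndarray:
    """Column-by-column correlation matrix between two matrices.

    ``spearman`` is computed exactly as Pearson on average ranks.
    """
    A = _values_of(A)
    B = _values_of(B)
    if A.ndim == 1:
        A = A[:, None]
    if B.ndim == 1:
        B = B[:, None]
    if A.shape[0] != B.shape[0]:
        raise ValueError("row counts differ")
    n = A.shape[0]
    if n < 3:
        raise ValueError("need at least 3 rows for a correlation")
    if type == "spearman":
        A = rankdata(A, axis=0, method="average")
        B = rankdata(B, axis=0, method="average")
    elif type != "pearson":
        raise ValueError(f"unknown correlation type: {type!r}")
    Za = _zscore(A, [f"A[{j}]" for j in range(A.shape[1])])
    Zb = _zscore(B, [f"B[{j}]" for j in range(B.shape[1])])
    R = Za.T @ Zb / (n - 1)
    return np.clip(R, -1.0, 1.0)


def inv_sqrt_psd(M: np.ndarray, eps: float = 1e-10) -> np.ndarray:
    """Inverse square root of a symmetric PSD matrix by eigendecomposition.

    Eigenvalues below ``eps`` times the largest are treated as zero
    (pseudo-inverse square root); eigenvalues negative beyond tolerance raise.
    """
    M = np.asarray(M, float)
    if M.shape[0] != M.shape[1] or not np.allclose(M, M.T, atol=1e-8):
        raise ValueError("matrix is not symmetric")
    w, Q = np.linalg.eigh((M + M.T) / 2.0)
    wmax = max(w.max(), 0.0)
    if w.min() < -1e-8 * max(wmax, 1.0):
        raise ValueError(f"matrix is not PSD (min eigenvalue {w.min():.3e})")
    floor = eps * wmax
    inv = np.where(w > floor, 1.0 / np.sqrt(np.clip(w, floor, None)), 0.0)
    R = (Q * inv) @ Q.T
    return (R + R.T) / 2.0


def build_cross_products(X, Y, type: str = "spearman",
                         eps: float = 1e-10) -> CrossProductSet:
    """Compute R_XY, R_XX, R_YY and Omega with one correlation type.

    All four matrices use the same correlation type; ``Omega`` is the
    between-block matrix whitened by the within-block inverse square roots,
    the matrix whose SVD yields canonical correlations.
    """
    Xv = _values_of(X)
    Yv = _values_of(Y)
    if Xv.shape[0] != Yv.shape[0]:
        raise ValueError("X and Y row counts differ")
    if hasattr(X, "participant_ids") and hasattr(Y, "participant_ids"):
        if list(X.participant_ids) != list(Y.participant_ids):
            raise ValueError("participant order differs between blocks")
    R_XY = correlation_matrix(Xv, Yv, type)
    R_XX = correlation_matrix(Xv, Xv, type)
    R_YY = correlation_matrix(Yv, Yv, type)
    for R in (R_XX, R_YY):
        R[:] = (R + R.T) / 2.0
        np.fill_diagonal(R, 1.0)
    Kx = inv_sqrt_psd(R_XX, eps)
    Ky = inv_sqrt_psd(R_YY, eps)
    Omega = Kx @ R_XY @ Ky
    return CrossProductSet(
        R_XY=R_XY, R_XX=R_XX, R_YY=R_YY, Omega=Omega,
        correlation_type=type, ridge_eps=eps,
        R_XX_inv_sqrt=Kx, R_YY_inv_sqrt=Ky,
        x_names=list(getattr(X, "variable_names", [f"x{j}" for j in range(Xv.shape[1])])),
        y_names=list(getattr(Y, "variable_names", [f"y{j}" for j in range(Yv.shape[1])])),
    )
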