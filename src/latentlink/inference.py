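"""Sum-of-squares permutation test on the eigenspectrum, and the Z-test.

The permutation test shuffles the rows of the (already residualized and
transformed) brain matrix, recomputes the cross-product matrix and its SVD,
and compares trailing sums of squared singular values ("the eigenspectrum")
against their permuted null: the statistic for LV k is T_k = sum_{i>=k} s_i^2
(analogous to Wilks' lambda), which controls for the variance already
captured by earlier LVs and is stricter than testing each singular value
alone.

Covariate residualization leaves both blocks' residuals in the same
(n - k)-dimensional subspace orthogonal to the nuisance design.  A plain row
shuffle ejects the brain residuals from that subspace, so raw permuted
cross-correlations are systematically smaller than the observed ones (degrees
of freedom n - 1 versus n - k) and the test rejects too often.  Each shuffled
matrix is therefore re-projected onto the residual subspace and its columns
re-standardized before the cross-product is rebuilt (the same device as
Freedman-Lane permutation of residuals in regression); the observed statistic
is computed through the identical projection, which is a no-op for plain
residuals and a negligible adjustment after rank transformation.

Resampling summaries elsewhere in the package use the shared Z-test
(mean divided by standard deviation of a distribution, |z| > 1.96 <=> p < .05).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .preprocess import (ResidualizedBlock, build_cross_products,
                         inv_sqrt_psd, transform_block)

__all__ = ["PermutationResult", "ZTestResult", "sum_of_squares_spectrum",
           "permutation_test", "ztest"]


@dataclass
class PermutationResult:
    observed_S: np.ndarray      # observed singular values
    observed_T: np.ndarray      # T_k = sum_{i>=k} s_i^2
    null_T: np.ndarray          # B x L permuted statistics
    p_values: np.ndarray        # add-one estimator, in [1/(B+1), 1]
    significant: np.ndarray     # p < alpha
    method: str
    B: int
    seed: int
    alpha: float = 0.05


@dataclass
class ZTestResult:
    mean: float
    sd: float
    z: float
    significant: bool
    threshold: float = 1.96


def sum_of_squares_spectrum(S: np.ndarray) -> np.ndarray:
    """Trailing sums of squared singular values: T_k = sum_{i=k..L} s_i^2."""
    S = np.asarray(S, float)
    if np.any(S < -1e-12):
        raise ValueError("singular values must be non-negative")
    if np.any(np.diff(S) > 1e-10):
        raise ValueError("singular values must be non-increasing")
    return np.cumsum((S ** 2)[::-1])[::-1]


def permutation_test(X: ResidualizedBlock, Y: ResidualizedBlock,
                     method: str = "pls", B: int = 500, seed: int = 0,
                     correlation_type: str = "spearman",
                     eps: float = 1e-10, alpha: float = 0.05) -> PermutationResult:
    """Permutation significance of each LV via the trailing sum-of-squares.

    Rows of the residualized brain block are permuted without replacement and
    re-projected onto the nuisance-orthogonal residual subspace (see module
    docstring); the p-value for LV k is the add-one estimator
    ``(#{T_k^(b) >= T_k^obs} + 1) / (B + 1)``, flagged significant at
    ``alpha``.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    if method not in ("pls", "cca"):
        raise ValueError(f"unknown method {method!r}")
    Xt = transform_block(X, correlation_type)
    Yt = transform_block(Y, correlation_type)
    Q = getattr(Xt, "design_basis", None)

    def proj_std(M: np.ndarray) -> np.ndarray:
        if Q is not None:
            M = M - Q @ (Q.T @ M)
        M = M - M.mean(axis=0)
        return M / M.std(axis=0, ddof=1)

    n = Xt.values.shape[0]
    X0 = proj_std(Xt.values)
    Y0 = proj_std(Yt.values)
    Ky = inv_sqrt_psd(Y0.T @ Y0 / (n - 1), eps) if method == "cca" else None

    def stat(Xm: np.ndarray) -> np.ndarray:
        R = Xm.T @ Y0 / (n - 1)
        if method == "cca":
            Kx = inv_sqrt_psd(Xm.T @ Xm / (n - 1), eps)
            R = Kx @ R @ Ky
        return np.linalg.svd(R, compute_uv=False)

    S_obs = stat(X0)
    T_obs = sum_of_squares_spectrum(S_obs)
    L = S_obs.shape[0]

    rng = np.random.default_rng(seed)
    null_T = np.empty((B, L))
    for b in range(B):
        perm = rng.permutation(n)
        s_b = stat(proj_std(X0[perm]))
        null_T[b] = np.cumsum((s_b ** 2)[::-1])[::-1]
    p = (np.sum(null_T >= T_obs[None, :], axis=0) + 1) / (B + 1)
    return PermutationResult(
        observed_S=S_obs, observed_T=T_obs, null_T=null_T, p_values=p,
        significant=p < alpha, method=method, B=B, seed=seed, alpha=alpha,
    )


def ztest(distribution: np.ndarray, threshold: float = 1.96) -> ZTestResult:
    """Mean divided by standard deviation of a resampling distribution."""
    d = np.asarray(distribution, float)
    if d.size < 2:
        raise ValueError("need at least 2 values")
    sd = float(d.std(ddof=1))
    if sd == 0:
        raise ValueError("degenerate distribution: zero variance")
    mean = float(d.mean())
    z = mean / sd
    return ZTestResult(mean=mean, sd=sd, z=z,
                       significant=abs(z) > threshold, threshold=threshold)
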