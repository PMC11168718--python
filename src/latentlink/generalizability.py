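"""Resampling assessments of latent-variable generalizability.

Three procedures, each rerunning the full analysis (residualization inside
every resample, then rank/Z transform, cross-products and SVD) on resampled
participants:

* split-half reproducibility — loadings are estimated independently in two
  random halves and correlated per LV (Pearson), the distribution over
  iterations summarized by a Z-test;
* train-test reliability — singular vectors from a random 80% training split
  are projected onto the held-out cross-product matrix to predict its
  singular values; a predicted-singular-value distribution consistently above
  zero marks a reliable LV;
* bootstrap stability — per-element percentile confidence intervals of the
  loadings over bootstrap resamples; an element whose 95% interval excludes
  zero is flagged stable.

Because SVD signs are arbitrary, every resampled model is sign-aligned to the
full-sample reference model (joint flip of each LV's brain/behavior pair)
before loadings are compared or accumulated.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .decompose import LatentModel, fit_cca, fit_pls
from .inference import ZTestResult, ztest
from .preprocess import (CovariateTable, DataBlock, build_cross_products,
                         residualize, transform_block)

__all__ = ["SplitHalfResult", "TrainTestResult", "BootstrapResult",
           "sign_align", "split_half", "predict_singular_values",
           "train_test", "bootstrap_stability", "fit_from_raw"]

log = logging.getLogger(__name__)


@dataclass
class SplitHalfResult:
    r_U: np.ndarray                 # iters x L half-vs-half brain-loading correlations
    r_V: np.ndarray                 # iters x L behavior-loading correlations
    z_U: list[ZTestResult]
    z_V: list[ZTestResult]
    iters: int
    seed: int
    alignment_mode: str
    n_skipped: int = 0


@dataclass
class TrainTestResult:
    s_pred: np.ndarray              # iters x L predicted test-set singular values
    z: list[ZTestResult]
    train_fraction: float
    iters: int
    seed: int


@dataclass
class BootstrapResult:
    ci_U_lo: np.ndarray             # p x L lower 95% bounds
    ci_U_hi: np.ndarray
    ci_V_lo: np.ndarray
    ci_V_hi: np.ndarray
    stable_U: np.ndarray            # interval excludes zero
    stable_V: np.ndarray
    n_boot: int
    seed: int
    ci_level: float = 0.95
    n_redrawn: int = 0


# ---------------------------------------------------------------------------
# building blocks
# ---------------------------------------------------------------------------

def fit_from_raw(X: DataBlock, Y: DataBlock, cov: CovariateTable,
                 method: str, correlation_type: str = "spearman",
                 eps: float = 1e-10):
    """Residualize, transform and fit one model from raw blocks.

    Returns ``(model, Xt, Yt, cp)`` — the fitted model together with the
    transformed blocks and cross-products, so callers can reuse them.
    """
    Xt = transform_block(residualize(X, cov), correlation_type)
    Yt = transform_block(residualize(Y, cov), correlation_type)
    cp = build_cross_products(Xt, Yt, correlation_type, eps)
    model = fit_cca(cp) if method == "cca" else fit_pls(cp)
    return model, Xt, Yt, cp


def sign_align(U: np.ndarray, V: np.ndarray, U_ref: np.ndarray,
               V_ref: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Resolve arbitrary SVD sign flips against a reference model.

    Per LV, if the combined alignment ``<u, u_ref> + <v, v_ref>`` is negative
    both the brain and behavior vectors are negated; the joint flip leaves the
    latent-variable solution unchanged.
    """
    if U.shape != U_ref.shape or V.shape != V_ref.shape:
        raise ValueError("shape mismatch between model and reference loadings")
    U = U.copy()
    V = V.copy()
    d = np.einsum("ij,ij->j", U, U_ref) + np.einsum("ij,ij->j", V, V_ref)
    flip = d < 0
    U[:, flip] *= -1.0
    V[:, flip] *= -1.0
    return U, V


def predict_singular_values(U_train: np.ndarray, V_train: np.ndarray,
                            C_test: np.ndarray) -> np.ndarray:
    """Project training singular vectors onto a test cross-product matrix.

    Returns ``diag(U_train^T C_test V_train)``.  On the training matrix
    itself this reproduces the training singular values exactly, so any
    shrinkage of the prediction is an out-of-sample effect.
    """
    if U_train.shape[0] != C_test.shape[0] or V_train.shape[0] != C_test.shape[1]:
        raise ValueError("loading/cross-product shapes are not conformable")
    if U_train.shape[1] != V_train.shape[1]:
        raise ValueError("U and V have different LV counts")
    return np.einsum("il,ij,jl->l", U_train, C_test, V_train)


def _safe_ztest(dist: np.ndarray) -> ZTestResult:
    """Z-test that tolerates an exactly constant resampling distribution.

    A zero-variance distribution arises only in degenerate designs (e.g.
    literally identical halves); report it as infinitely concentrated rather
    than failing the whole resampling run.
    """
    try:
        return ztest(dist)
    except ValueError:
        mean = float(np.mean(dist))
        z = float(np.sign(mean)) * np.inf if mean != 0 else 0.0
        return ZTestResult(mean=mean, sd=0.0, z=z, significant=mean != 0)


def _columnwise_pearson(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    Az = (A - A.mean(0)) / A.std(0, ddof=1)
    Bz = (B - B.mean(0)) / B.std(0, ddof=1)
    return np.einsum("ij,ij->j", Az, Bz) / (A.shape[0] - 1)


# ---------------------------------------------------------------------------
# resampling procedures
# ---------------------------------------------------------------------------

def split_half(X: DataBlock, Y: DataBlock, cov: CovariateTable,
               method: str = "pls", iters: int = 200, seed: int = 0,
               correlation_type: str = "spearman", eps: float = 1e-10,
               alignment_mode: str = "reference",
               splitter=None) -> SplitHalfResult:
    """Split-half reproducibility of loadings.

    Each iteration randomly splits participants into two halves (the odd
    participant going to the first half), refits the full analysis in each
    half, sign-aligns both halves to the full-sample reference model, and
    records the per-LV Pearson correlation of the half-1 vs half-2 loadings.
    ``alignment_mode='none'`` skips the sign correction.  ``splitter`` may be
    a callable ``(rng, n) -> (idx1, idx2)`` overriding the random split
    (used for controlled checks).
    """
    if X.n < 4:
        raise ValueError("need at least 4 participants to split")
    if alignment_mode not in ("reference", "none"):
        raise ValueError(f"unknown alignment_mode {alignment_mode!r}")
    ref, *_ = fit_from_raw(X, Y, cov, method, correlation_type, eps)
    L = ref.L
    rng = np.random.default_rng(seed)
    r_U = np.full((iters, L), np.nan)
    r_V = np.full((iters, L), np.nan)
    n = X.n
    n_skipped = 0
    for it in range(iters):
        if splitter is None:
            perm = rng.permutation(n)
            cut = (n + 1) // 2
            idx1, idx2 = perm[:cut], perm[cut:]
        else:
            idx1, idx2 = splitter(rng, n)
        try:
            m1, *_ = fit_from_raw(X.subset(idx1), Y.subset(idx1),
                                  cov.subset(idx1), method, correlation_type, eps)
            m2, *_ = fit_from_raw(X.subset(idx2), Y.subset(idx2),
                                  cov.subset(idx2), method, correlation_type, eps)
        except (ValueError, np.linalg.LinAlgError):
            n_skipped += 1
            continue
        lx1, ly1 = m1.loadings_x, m1.loadings_y
        lx2, ly2 = m2.loadings_x, m2.loadings_y
        if alignment_mode == "reference":
            lx1, ly1 = sign_align(lx1, ly1, ref.loadings_x, ref.loadings_y)
            lx2, ly2 = sign_align(lx2, ly2, ref.loadings_x, ref.loadings_y)
        r_U[it] = _columnwise_pearson(lx1, lx2)
        r_V[it] = _columnwise_pearson(ly1, ly2)
    if n_skipped:
        log.info("split_half: skipped %d degenerate iterations", n_skipped)
    ok = ~np.isnan(r_U[:, 0])
    z_U = [_safe_ztest(r_U[ok, l]) for l in range(L)]
    z_V = [_safe_ztest(r_V[ok, l]) for l in range(L)]
    return SplitHalfResult(r_U=r_U[ok], r_V=r_V[ok], z_U=z_U, z_V=z_V,
                           iters=iters, seed=seed,
                           alignment_mode=alignment_mode, n_skipped=n_skipped)


def train_test(X: DataBlock, Y: DataBlock, cov: CovariateTable,
               method: str = "pls", iters: int = 200,
               train_fraction: float = 0.8, seed: int = 0,
               correlation_type: str = "spearman",
               eps: float = 1e-10) -> TrainTestResult:
    """Train-test reliability of singular values.

    Each iteration splits participants into train/test sets, fits the model
    on the training set, builds the test set's own cross-product matrix
    (``R_XY`` for PLS, ``Omega`` for CCA — each side residualized and
    transformed independently), and projects the training singular vectors
    onto it to predict the test singular values.
    """
    if not 0.0 < train_fraction < 1.0:
        raise ValueError("train_fraction must be in (0, 1)")
    n = X.n
    n_test = n - int(round(train_fraction * n))
    if n_test < Y.p + 2:
        raise ValueError(
            f"test split too small ({n_test} rows) for {Y.p} behavior variables"
        )
    rng = np.random.default_rng(seed)
    s_pred_rows = []
    for _ in range(iters):
        perm = rng.permutation(n)
        tr, te = perm[:n - n_test], perm[n - n_test:]
        m_tr, *_ = fit_from_raw(X.subset(tr), Y.subset(tr), cov.subset(tr),
                                method, correlation_type, eps)
        Xt_te = transform_block(residualize(X.subset(te), cov.subset(te)),
                                correlation_type)
        Yt_te = transform_block(residualize(Y.subset(te), cov.subset(te)),
                                correlation_type)
        cp_te = build_cross_products(Xt_te, Yt_te, correlation_type, eps)
        C_te = cp_te.R_XY if method == "pls" else cp_te.Omega
        s_pred_rows.append(predict_singular_values(m_tr.U, m_tr.V, C_te))
    s_pred = np.vstack(s_pred_rows)
    z = [ztest(s_pred[:, l]) for l in range(s_pred.shape[1])]
    return TrainTestResult(s_pred=s_pred, z=z, train_fraction=train_fraction,
                           iters=iters, seed=seed)


def bootstrap_stability(X: DataBlock, Y: DataBlock, cov: CovariateTable,
                        method: str = "pls", n_boot: int = 1000, seed: int = 0,
                        correlation_type: str = "spearman", eps: float = 1e-10,
                        ci_level: float = 0.95) -> BootstrapResult:
    """Bootstrap stability of individual loading elements.

    Participants are resampled with replacement to the original sample size
    (rows of X and Y resampled together, conserving their pairing); each
    resampled model is sign-aligned to the full-sample reference, and
    per-element percentile confidence intervals are computed from the
    resampled loading distributions.  Degenerate resamples (e.g. a constant
    column) are redrawn and counted.
    """
    if X.n < 10:
        raise ValueError("need at least 10 participants for the bootstrap")
    ref, *_ = fit_from_raw(X, Y, cov, method, correlation_type, eps)
    rng = np.random.default_rng(seed)
    n = X.n
    boot_U = np.empty((n_boot,) + ref.loadings_x.shape)
    boot_V = np.empty((n_boot,) + ref.loadings_y.shape)
    n_redrawn = 0
    for b in range(n_boot):
        for _attempt in range(20):
            idx = rng.integers(0, n, size=n)
            try:
                m, *_ = fit_from_raw(X.subset(idx), Y.subset(idx),
                                     cov.subset(idx), method,
                                     correlation_type, eps)
                break
            except (ValueError, np.linalg.LinAlgError):
                n_redrawn += 1
        else:
            raise RuntimeError("bootstrap: too many degenerate resamples")
        lx, ly = sign_align(m.loadings_x, m.loadings_y,
                            ref.loadings_x, ref.loadings_y)
        boot_U[b] = lx
        boot_V[b] = ly
    if n_redrawn:
        log.info("bootstrap_stability: redrew %d degenerate resamples", n_redrawn)
    a = 100.0 * (1.0 - ci_level) / 2.0
    ci_U_lo, ci_U_hi = np.percentile(boot_U, [a, 100.0 - a], axis=0)
    ci_V_lo, ci_V_hi = np.percentile(boot_V, [a, 100.0 - a], axis=0)
    return BootstrapResult(
        ci_U_lo=ci_U_lo, ci_U_hi=ci_U_hi, ci_V_lo=ci_V_lo, ci_V_hi=ci_V_hi,
        stable_U=(ci_U_lo > 0) | (ci_U_hi < 0),
        stable_V=(ci_V_lo > 0) | (ci_V_hi < 0),
        n_boot=n_boot, seed=seed, ci_level=ci_level, n_redrawn=n_redrawn,
    )
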