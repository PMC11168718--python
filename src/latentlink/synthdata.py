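"""Synthetic paired brain/behavior/covariate tables with planted latent structure.

The generator emulates the statistical shape of a large multi-site pediatric
cohort: a brain block of correlated, roughly Gaussian cortical-thickness-like
columns; a behavior block that is either continuous and near-Gaussian
(performance-score-like) or ordinal, right-skewed and zero-inflated
(symptom-checklist-like); and linear nuisance effects of age, sex, head size,
site and scanner on both blocks.  Cross-block association is planted along a
configurable number of latent directions with known loadings and effect
sizes, recorded as :class:`GroundTruth` so parameter recovery can be tested.

Construction, per participant i and latent l with effect size r_l:

    x_i = sum_l c_l z_il a_l + covariate effects + e_i
    y_i = sum_l c_l z_il b_l + covariate effects + f_i

with z_il ~ N(0,1) i.i.d., unit-norm orthogonal loading columns a_l, b_l,
c_l = sqrt(r_l / (1 - r_l)), and equicorrelated Gaussian noise e, f.  With
uncorrelated noise the population correlation of the planted score pair
(x a_l, y b_l) is exactly r_l.  The behavior block is then optionally pushed
through :func:`apply_ordinal_copula` to produce zero-inflated ordinal scores.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .preprocess import CovariateTable, DataBlock

__all__ = [
    "SynthConfig",
    "GroundTruth",
    "SyntheticStudy",
    "generate_covariates",
    "generate_study",
    "apply_ordinal_copula",
]

#: decay ratio of the geometric-like target marginal over nonzero ordinal
#: scores {1..max_score}; smaller means steeper right skew
ORDINAL_DECAY = 0.55

#: age range in months (a 9-11-year-old cohort)
AGE_RANGE_MONTHS = (107.0, 133.0)


@dataclass
class SynthConfig:
    """Parameters of one synthetic study.

    Defaults mirror the intended use case: 68 cortical-thickness columns, 11
    checklist-like behavior columns, one weak-to-moderate planted latent
    effect, moderate within-block correlation, heavy zero inflation of the
    behavior marginals, and 21 sites nested within 5 scanner models.
    """

    n_participants: int
    n_brain: int = 68
    n_behavior: int = 11
    n_latent: int = 1
    effect_sizes: tuple[float, ...] = (0.3,)
    within_block_rho_brain: float = 0.3
    within_block_rho_behavior: float = 0.3
    zero_inflation: float = 0.5
    max_score: int = 10
    behavior_family: str = "ordinal_zero_inflated"
    covariate_effect_scale: float = 0.1
    n_sites: int = 21
    n_scanners: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        self.effect_sizes = tuple(float(r) for r in self.effect_sizes)
        if self.n_participants < 2:
            raise ValueError("n_participants must be >= 2")
        if self.n_latent > min(self.n_brain, self.n_behavior):
            raise ValueError("n_latent exceeds min(n_brain, n_behavior)")
        if len(self.effect_sizes) != self.n_latent:
            raise ValueError("effect_sizes length must equal n_latent")
        for r in self.effect_sizes:
            if not 0.0 <= r < 1.0:
                raise ValueError("effect sizes must lie in [0, 1)")
        if any(a < b for a, b in zip(self.effect_sizes, self.effect_sizes[1:])):
            raise ValueError("effect_sizes must be non-increasing")
        for name in ("within_block_rho_brain", "within_block_rho_behavior"):
            if not 0.0 <= getattr(self, name) < 1.0:
                raise ValueError(f"{name} must lie in [0, 1)")
        if not 0.0 <= self.zero_inflation <= 1.0:
            raise ValueError("zero_inflation must lie in [0, 1]")
        if self.behavior_family not in ("ordinal_zero_inflated", "gaussian"):
            raise ValueError(f"unknown behavior_family {self.behavior_family!r}")
        if self.max_score < 1:
            raise ValueError("max_score must be >= 1")
        if self.n_sites < 1 or self.n_scanners < 1:
            raise ValueError("n_sites and n_scanners must be >= 1")

    def to_dict(self) -> dict:
        return {
            "n_participants": self.n_participants,
            "n_brain": self.n_brain,
            "n_behavior": self.n_behavior,
            "n_latent": self.n_latent,
            "effect_sizes": list(self.effect_sizes),
            "within_block_rho_brain": self.within_block_rho_brain,
            "within_block_rho_behavior": self.within_block_rho_behavior,
            "zero_inflation": self.zero_inflation,
            "max_score": self.max_score,
            "behavior_family": self.behavior_family,
            "covariate_effect_scale": self.covariate_effect_scale,
            "n_sites": self.n_sites,
            "n_scanners": self.n_scanners,
            "seed": self.seed,
        }


@dataclass
class GroundTruth:
    """Planted loadings and effect sizes, the recovery oracle."""

    true_brain_loadings: np.ndarray   # n_brain x n_latent, unit-norm columns
    true_behavior_loadings: np.ndarray
    effect_sizes: tuple[float, ...]
    covariate_slopes: dict[str, pd.DataFrame] = field(default_factory=dict)

    def to_json(self, path) -> None:
        payload = {
            "true_brain_loadings": self.true_brain_loadings.tolist(),
            "true_behavior_loadings": self.true_behavior_loadings.tolist(),
            "effect_sizes": list(self.effect_sizes),
        }
        Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))


@dataclass
class SyntheticStudy:
    brain: DataBlock
    behavior: DataBlock
    covariates: CovariateTable
    truth: GroundTruth
    config: SynthConfig

    def write_dir(self, out_dir) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.brain.write_tsv(out / "brain.tsv")
        self.behavior.write_tsv(out / "behavior.tsv")
        self.covariates.write_tsv(out / "covariates.tsv")
        self.truth.to_json(out / "truth.json")


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def generate_covariates(n: int, n_sites: int = 21, n_scanners: int = 5,
                        seed: int = 0) -> CovariateTable:
    """Age, sex, site, scanner and head-size covariates for ``n`` participants.

    Sites are assigned roughly uniformly; each site uses a single scanner
    model (sites nested within scanners), as in a multi-site consortium where
    a site owns one machine.
    """
    if n < 2:
        raise ValueError("n must be >= 2")
    if n_sites < 1 or n_scanners < 1:
        raise ValueError("n_sites and n_scanners must be >= 1")
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    age = rng.uniform(*AGE_RANGE_MONTHS, size=n)
    sex = rng.integers(0, 2, size=n)
    site = rng.integers(0, n_sites, size=n)
    scanner = site % n_scanners  # nesting: one scanner model per site
    head_size = rng.normal(1450.0, 120.0, size=n)  # intracranial volume, cm^3
    frame = pd.DataFrame({
        "age": age,
        "sex": sex.astype(float),
        "head_size": head_size,
        "site": [f"site{s:02d}" for s in site],
        "scanner": [f"scanner{s}" for s in scanner],
    })
    ids = [f"P{i:06d}" for i in range(n)]
    return CovariateTable(frame, ids)


def apply_ordinal_copula(y_continuous: np.ndarray, zero_inflation: float,
                         max_score: int, seed: int | None = None) -> np.ndarray:
    """Map continuous columns to zero-inflated right-skewed ordinal scores.

    Per column, values below the ``zero_inflation`` empirical quantile map to
    0; the remaining values map to ``{1..max_score}`` by monotone quantile
    binning against a geometric-like decaying target marginal (ratio
    ``ORDINAL_DECAY``), reproducing checklist-style right skew.  The map is a
    monotone function of the input, so ranks among non-zero entries are
    preserved.  ``seed`` is accepted for interface symmetry but unused: the
    transform is a deterministic function of its input.
    """
    if max_score < 1:
        raise ValueError("max_score must be >= 1")
    if not 0.0 <= zero_inflation <= 1.0:
        raise ValueError("zero_inflation must lie in [0, 1]")
    Y = np.asarray(y_continuous, dtype=float)
    squeeze = Y.ndim == 1
    if squeeze:
        Y = Y[:, None]
    out = np.zeros_like(Y)
    if zero_inflation >= 1.0:
        if max_score > 0:
            warnings.warn("zero_inflation=1 produces all-zero columns",
                          stacklevel=2)
        return out[:, 0] if squeeze else out
    # geometric-like decaying target marginal over {1..max_score}
    w = ORDINAL_DECAY ** np.arange(max_score)
    cum = np.concatenate([[0.0], np.cumsum(w) / w.sum()])  # len max_score+1
    for j in range(Y.shape[1]):
        col = Y[:, j]
        thr = np.quantile(col, zero_inflation)
        nz = col >= thr if zero_inflation > 0 else np.ones_like(col, bool)
        m = int(nz.sum())
        if m == 0:
            continue
        # empirical cdf position of each nonzero entry among nonzero entries
        order = np.argsort(col[nz], kind="stable")
        ranks = np.empty(m)
        ranks[order] = np.arange(m)
        # mean rank for ties so equal inputs get equal scores
        vals = col[nz]
        df = pd.Series(ranks).groupby(vals).transform("mean").to_numpy()
        u = (df + 0.5) / m
        scores = np.searchsorted(cum[1:-1], u, side="right") + 1
        out[nz, j] = scores
    return out[:, 0] if squeeze else out


def _orthonormal_columns(rng: np.random.Generator, p: int, k: int) -> np.ndarray:
    M = rng.normal(size=(p, k))
    Q, R = np.linalg.qr(M)
    # fix reflection ambiguity of QR for determinism across platforms
    Q = Q * np.sign(np.diag(R))
    return Q[:, :k]


def _equicorrelated_noise(rng: np.random.Generator, n: int, p: int,
                          rho: float) -> np.ndarray:
    """Rows i.i.d. N(0, S) with S = (1-rho) I + rho 11^T (unit variances)."""
    shared = rng.normal(size=(n, 1))
    idio = rng.normal(size=(n, p))
    return np.sqrt(rho) * shared + np.sqrt(1.0 - rho) * idio


def generate_study(config: SynthConfig) -> SyntheticStudy:
    """Generate one synthetic study with recorded ground truth.

    One master seed spawns independent substreams for covariates, loadings,
    latent scores, noise and covariate slopes, so the same configuration
    always yields the same study.
    """
    ss = np.random.SeedSequence(config.seed)
    ss_cov, ss_load, ss_lat, ss_noise, ss_slope = ss.spawn(5)
    n, p, q, L = (config.n_participants, config.n_brain,
                  config.n_behavior, config.n_latent)

    cov = generate_covariates(
        n, config.n_sites, config.n_scanners,
        seed=int(ss_cov.generate_state(1)[0] & 0x7FFFFFFF),
    )

    rng_load = np.random.default_rng(ss_load)
    A = _orthonormal_columns(rng_load, p, L)
    Bm = _orthonormal_columns(rng_load, q, L)
    c = np.sqrt(np.array(config.effect_sizes) / (1.0 - np.array(config.effect_sizes)))

    rng_lat = np.random.default_rng(ss_lat)
    Z = rng_lat.normal(size=(n, L))

    rng_noise = np.random.default_rng(ss_noise)
    Ex = _equicorrelated_noise(rng_noise, n, p, config.within_block_rho_brain)
    Ey = _equicorrelated_noise(rng_noise, n, q, config.within_block_rho_behavior)

    X = (Z * c) @ A.T + Ex
    Yc = (Z * c) @ Bm.T + Ey

    # linear nuisance effects: standardized continuous slopes of fixed
    # magnitude with random sign, plus additive site/scanner level shifts
    rng_slope = np.random.default_rng(ss_slope)
    scale = config.covariate_effect_scale
    cont = {
        "age": (cov.frame["age"] - cov.frame["age"].mean()).to_numpy()
        / cov.frame["age"].std(ddof=1),
        "sex": (cov.frame["sex"] - cov.frame["sex"].mean()).to_numpy(),
        "head_size": (cov.frame["head_size"] - cov.frame["head_size"].mean()).to_numpy()
        / cov.frame["head_size"].std(ddof=1),
    }
    slopes: dict[str, pd.DataFrame] = {}
    for role, mat, k in (("brain", X, p), ("behavior", Yc, q)):
        rows = {}
        for name, col in cont.items():
            b = scale * rng_slope.choice([-1.0, 1.0], size=k)
            mat += np.outer(col, b)
            rows[name] = b
        for cat, levels in (("site", cov.frame["site"]), ("scanner", cov.frame["scanner"])):
            uniq = sorted(levels.unique())
            shifts = rng_slope.normal(0.0, scale, size=(len(uniq), k))
            level_idx = levels.map({u: i for i, u in enumerate(uniq)}).to_numpy()
            mat += shifts[level_idx]
            for i, u in enumerate(uniq):
                rows[u] = shifts[i]
        slopes[role] = pd.DataFrame(rows).T

    if config.behavior_family == "ordinal_zero_inflated":
        Y = apply_ordinal_copula(Yc, config.zero_inflation, config.max_score)
        behav_names = [f"subscale_{j:02d}" for j in range(q)]
    else:
        Y = 100.0 + 15.0 * Yc  # performance-score-like scale
        behav_names = [f"task_{j:02d}" for j in range(q)]

    X_mm = 2.7 + 0.16 * X  # cortical-thickness-like scale (mm)
    brain_names = [f"region_{j:02d}" for j in range(p)]

    ids = list(cov.participant_ids)
    brain = DataBlock(X_mm, ids, brain_names, role="brain")
    behavior = DataBlock(Y, ids, behav_names, role="behavior")
    truth = GroundTruth(A, Bm, config.effect_sizes, slopes)
    return SyntheticStudy(brain, behavior, cov, truth, config)
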