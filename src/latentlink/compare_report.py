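"""Between-method comparison, data-structure diagnostics and orchestration.

``between_method_correlation`` quantifies between-method generalizability as
the Pearson correlation between CCA and PLS loadings, over all LV pairs (not
just respective ones, since a latent dimension may surface at a different
rank in the two methods).  ``distribution_diagnostics`` and
``pca_variance_profile`` summarize the distributional pathology (skew, zero
inflation, compressed variance structure) that drives how similar and how
generalizable the two methods are.  ``run_pipeline`` chains every stage —
preprocessing, both fits, permutation, split-half, train-test, bootstrap,
comparison, diagnostics — into one deterministic report.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import stats

from .decompose import LatentModel, fit_cca, fit_pls, latent_scores
from .generalizability import (bootstrap_stability, fit_from_raw, split_half,
                               train_test)
from .inference import permutation_test
from .preprocess import (CovariateTable, DataBlock, correlation_matrix,
                         residualize, transform_block, build_cross_products)

__all__ = ["MethodComparison", "BlockDiagnostics", "AnalysisConfig",
           "between_method_correlation", "pca_variance_profile",
           "distribution_diagnostics", "run_pipeline"]

log = logging.getLogger(__name__)


@dataclass
class MethodComparison:
    """All-pairs Pearson correlations between CCA and PLS loadings."""

    r_U_cross: np.ndarray   # L_cca x L_pls, brain loadings
    r_V_cross: np.ndarray   # L_cca x L_pls, behavior loadings

    @property
    def diagonal_U(self) -> np.ndarray:
        k = min(self.r_U_cross.shape)
        return np.diag(self.r_U_cross[:k, :k])

    @property
    def diagonal_V(self) -> np.ndarray:
        k = min(self.r_V_cross.shape)
        return np.diag(self.r_V_cross[:k, :k])


@dataclass
class BlockDiagnostics:
    skewness: np.ndarray            # per-column third standardized moment
    zero_proportion: np.ndarray
    condition_number: float         # of the within-block correlation matrix
    pca_components_for_threshold: int
    threshold: float = 0.90
    constant_columns: list[str] = field(default_factory=list)


@dataclass
class AnalysisConfig:
    """Everything an end-to-end run needs beyond the data itself."""

    correlation_type: str = "spearman"
    methods: tuple[str, ...] = ("cca", "pls")
    n_permutations: int = 1000
    n_splithalf: int = 200
    n_traintest: int = 200
    n_bootstrap: int = 200
    train_fraction: float = 0.8
    z_threshold: float = 1.96
    alpha: float = 0.05
    ci_level: float = 0.95
    eps: float = 1e-10
    seed: int = 0

    def __post_init__(self) -> None:
        self.methods = tuple(self.methods)
        for m in self.methods:
            if m not in ("cca", "pls"):
                raise ValueError(f"unknown method {m!r}")
        if not 0 < self.alpha < 1 or not 0 < self.ci_level < 1:
            raise ValueError("alpha and ci_level must lie in (0, 1)")
        if not 0 < self.train_fraction < 1:
            raise ValueError("train_fraction must lie in (0, 1)")

    @classmethod
    def from_yaml(cls, path) -> "AnalysisConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["methods"] = list(self.methods)
        return d


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def between_method_correlation(cca: LatentModel, pls: LatentModel) -> MethodComparison:
    """Pearson correlations between CCA and PLS loadings for every LV pair.

    CCA contributes its reweighted (canonical) weights, PLS its singular
    vectors; Pearson correlation is scale-free, so the differing loading
    normalizations of the two methods do not affect the comparison.
    """
    if cca.x_names != pls.x_names or cca.y_names != pls.y_names:
        raise ValueError("models were fitted on different variable sets")
    r_U = correlation_matrix(cca.loadings_x, pls.loadings_x, "pearson")
    r_V = correlation_matrix(cca.loadings_y, pls.loadings_y, "pearson")
    return MethodComparison(r_U_cross=r_U, r_V_cross=r_V)


def pca_variance_profile(block, threshold: float = 0.90) -> int:
    """Components needed to reach a cumulative variance threshold.

    Accepts a data block/matrix (columns correlated internally) or a
    ready-made correlation matrix; returns the smallest k whose top-k
    eigenvalues of the correlation matrix sum to >= threshold * total.
    """
    if not 0.0 < threshold <= 1.0:
        raise ValueError("threshold must lie in (0, 1]")
    M = block.values if hasattr(block, "values") else np.asarray(block, float)
    if M.shape[0] == M.shape[1] and np.allclose(M, M.T, atol=1e-8) \
            and np.allclose(np.diag(M), 1.0, atol=1e-8):
        C = (M + M.T) / 2.0
    else:
        C = correlation_matrix(M, M, "pearson")
    w = np.linalg.eigvalsh(C)
    if w.min() < -1e-8 * max(w.max(), 1.0):
        raise ValueError("correlation matrix is not PSD")
    w = np.sort(np.clip(w, 0.0, None))[::-1]
    frac = np.cumsum(w) / w.sum()
    return int(np.searchsorted(frac, threshold - 1e-12) + 1)


def distribution_diagnostics(block: DataBlock, threshold: float = 0.90
                             ) -> BlockDiagnostics:
    """Per-column skewness and zero proportions, plus variance-structure summaries."""
    V = block.values
    if V.size == 0:
        raise ValueError("empty block")
    sd = V.std(axis=0, ddof=0)
    constant = [block.variable_names[j] for j in np.where(sd == 0)[0]]
    skew = np.full(V.shape[1], np.nan)
    ok = sd > 0
    skew[ok] = stats.skew(V[:, ok], axis=0, bias=True)
    zero_prop = (V == 0).mean(axis=0)
    C = correlation_matrix(V[:, ok], V[:, ok], "pearson")
    cond = float(np.linalg.cond(C))
    k = pca_variance_profile(C, threshold)
    return BlockDiagnostics(
        skewness=skew, zero_proportion=zero_prop, condition_number=cond,
        pca_components_for_threshold=k, threshold=threshold,
        constant_columns=constant,
    )


# ---------------------------------------------------------------------------
# end-to-end pipeline
# ---------------------------------------------------------------------------

def _ztable(zs) -> dict:
    return {
        "mean": [t.mean for t in zs],
        "sd": [t.sd for t in zs],
        "z": [t.z for t in zs],
        "significant": [bool(t.significant) for t in zs],
    }


def _bootstrap_frame(res, model: LatentModel) -> pd.DataFrame:
    rows = []
    for blockname, names, lo, hi, stable in (
        ("brain", model.x_names, res.ci_U_lo, res.ci_U_hi, res.stable_U),
        ("behavior", model.y_names, res.ci_V_lo, res.ci_V_hi, res.stable_V),
    ):
        for l in range(lo.shape[1]):
            for i, nm in enumerate(names):
                rows.append((blockname, l + 1, nm, lo[i, l], hi[i, l],
                             bool(stable[i, l])))
    return pd.DataFrame(rows, columns=["block", "lv", "variable",
                                       "lo", "hi", "stable"])


def run_pipeline(config: AnalysisConfig, brain: DataBlock, behavior: DataBlock,
                 cov: CovariateTable, out_dir=None,
                 subset: np.ndarray | None = None) -> dict:
    """Run every stage end to end and return (and optionally write) a report.

    ``subset`` is an optional boolean mask or index array restricting the run
    to a participant subset — sensitivity and post hoc reruns are exactly the
    same pipeline on a row subset, possibly with extra covariate columns in
    ``cov``.  Per-stage seeds are spawned deterministically from
    ``config.seed``, so identical inputs and config give identical reports.
    """
    if subset is not None:
        subset = np.asarray(subset)
        idx = np.where(subset)[0] if subset.dtype == bool else subset
        brain, behavior, cov = brain.subset(idx), behavior.subset(idx), cov.subset(idx)

    ss = np.random.SeedSequence(config.seed)
    stage_seed = {name: int(child.generate_state(1)[0] & 0x7FFFFFFF)
                  for name, child in zip(
                      ("permutation", "splithalf", "traintest", "bootstrap"),
                      ss.spawn(4))}

    Xr = residualize(brain, cov)
    Yr = residualize(behavior, cov)
    Xt = transform_block(Xr, config.correlation_type)
    Yt = transform_block(Yr, config.correlation_type)
    cp = build_cross_products(Xt, Yt, config.correlation_type, config.eps)

    report: dict = {
        "config": config.to_dict(),
        "n_participants": brain.n,
        "singular_values": {}, "varexp": {}, "permutation": {},
        "splithalf": {}, "traintest": {}, "bootstrap": {},
        "comparison": None, "diagnostics": {},
    }
    models: dict[str, LatentModel] = {}
    tsvs: dict[str, pd.DataFrame] = {}

    for method in config.methods:
        log.info("fitting %s", method)
        model = fit_cca(cp) if method == "cca" else fit_pls(cp)
        models[method] = model
        report["singular_values"][method] = model.S.tolist()
        report["varexp"][method] = model.varexp.tolist()
        tsvs[f"loadings_brain_{method}.tsv"] = pd.DataFrame(
            model.loadings_x, index=model.x_names,
            columns=[f"LV{l+1}" for l in range(model.L)])
        tsvs[f"loadings_behavior_{method}.tsv"] = pd.DataFrame(
            model.loadings_y, index=model.y_names,
            columns=[f"LV{l+1}" for l in range(model.L)])
        scores = latent_scores(model, Xt, Yt)
        tsvs[f"latent_scores_{method}.tsv"] = pd.DataFrame(
            np.hstack([scores.scores_x, scores.scores_y]),
            columns=[f"X_LV{l+1}" for l in range(model.L)]
            + [f"Y_LV{l+1}" for l in range(model.L)])

        log.info("permutation test (%s, B=%d)", method, config.n_permutations)
        perm = permutation_test(Xr, Yr, method, B=config.n_permutations,
                                seed=stage_seed["permutation"],
                                correlation_type=config.correlation_type,
                                eps=config.eps, alpha=config.alpha)
        report["permutation"][method] = {
            "observed_T": perm.observed_T.tolist(),
            "p_values": perm.p_values.tolist(),
            "significant": perm.significant.tolist(),
            "B": perm.B, "seed": perm.seed,
        }

        log.info("split-half (%s, iters=%d)", method, config.n_splithalf)
        sh = split_half(brain, behavior, cov, method,
                        iters=config.n_splithalf, seed=stage_seed["splithalf"],
                        correlation_type=config.correlation_type, eps=config.eps)
        report["splithalf"][method] = {
            "brain": _ztable(sh.z_U), "behavior": _ztable(sh.z_V),
            "n_skipped": sh.n_skipped,
        }
        tsvs[f"splithalf_r_{method}.tsv"] = pd.DataFrame(
            np.hstack([sh.r_U, sh.r_V]),
            columns=[f"U_LV{l+1}" for l in range(sh.r_U.shape[1])]
            + [f"V_LV{l+1}" for l in range(sh.r_V.shape[1])])

        log.info("train-test (%s, iters=%d)", method, config.n_traintest)
        tt = train_test(brain, behavior, cov, method,
                        iters=config.n_traintest,
                        train_fraction=config.train_fraction,
                        seed=stage_seed["traintest"],
                        correlation_type=config.correlation_type, eps=config.eps)
        report["traintest"][method] = _ztable(tt.z)
        tsvs[f"traintest_spred_{method}.tsv"] = pd.DataFrame(
            tt.s_pred, columns=[f"LV{l+1}" for l in range(tt.s_pred.shape[1])])

        log.info("bootstrap (%s, n_boot=%d)", method, config.n_bootstrap)
        bs = bootstrap_stability(brain, behavior, cov, method,
                                 n_boot=config.n_bootstrap,
                                 seed=stage_seed["bootstrap"],
                                 correlation_type=config.correlation_type,
                                 eps=config.eps, ci_level=config.ci_level)
        report["bootstrap"][method] = {
            "n_stable_brain": [int(bs.stable_U[:, l].sum())
                               for l in range(bs.stable_U.shape[1])],
            "n_stable_behavior": [int(bs.stable_V[:, l].sum())
                                  for l in range(bs.stable_V.shape[1])],
            "n_boot": bs.n_boot, "n_redrawn": bs.n_redrawn,
        }
        tsvs[f"bootstrap_ci_{method}.tsv"] = _bootstrap_frame(bs, model)

    if "cca" in models and "pls" in models:
        comp = between_method_correlation(models["cca"], models["pls"])
        report["comparison"] = {
            "r_U_cross": comp.r_U_cross.tolist(),
            "r_V_cross": comp.r_V_cross.tolist(),
            "diagonal_U": comp.diagonal_U.tolist(),
            "diagonal_V": comp.diagonal_V.tolist(),
        }

    for name, blk in (("brain", brain), ("behavior", behavior)):
        d = distribution_diagnostics(blk)
        report["diagnostics"][name] = {
            "mean_skewness": float(np.nanmean(d.skewness)),
            "mean_zero_proportion": float(d.zero_proportion.mean()),
            "condition_number": d.condition_number,
            "pca_components_for_90pct": d.pca_components_for_threshold,
            "constant_columns": d.constant_columns,
        }

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "report.json").write_text(
            json.dumps(report, indent=1, sort_keys=True))
        for fname, df in tsvs.items():
            df.to_csv(out / fname, sep="\t", float_format="%.10g",
                      index=fname.startswith("loadings"))
        sv = pd.DataFrame({m: models[m].S for m in models})
        sv.index = [f"LV{l+1}" for l in range(len(sv))]
        sv.to_csv(out / "singular_values.tsv", sep="\t", float_format="%.10g")
    return report
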