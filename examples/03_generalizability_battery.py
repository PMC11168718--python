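"""Split-half, train-test and bootstrap assessment of a planted LV.

Three complementary questions about the first latent variable:
reproducibility (do two independent halves of the sample find the same
loadings? — Pearson r of half-vs-half loadings, summarized by a Z-test),
reliability (do training-set singular vectors predict positive singular
values on held-out data?), and stability (which individual loadings have
bootstrap 95% intervals excluding zero?).  |Z| > 1.96 marks a distribution
significantly different from zero.
"""

from latentlink import (SynthConfig, bootstrap_stability, generate_study,
                        split_half, train_test)

study = generate_study(SynthConfig(n_participants=1500, n_latent=1,
                                   effect_sizes=(0.4,), seed=3))
args = (study.brain, study.behavior, study.covariates, "pls")

sh = split_half(*args, iters=200, seed=10)
print(f"split-half LV1: mean r_U = {sh.r_U[:, 0].mean():.3f}, "
      f"z_U = {sh.z_U[0].z:.2f}; mean r_V = {sh.r_V[:, 0].mean():.3f}, "
      f"z_V = {sh.z_V[0].z:.2f}")

tt = train_test(*args, iters=200, seed=11)
print(f"train-test LV1: mean predicted s = {tt.s_pred[:, 0].mean():.3f}, "
      f"z = {tt.z[0].z:.2f}")

bs = bootstrap_stability(*args, n_boot=300, seed=12)
print(f"bootstrap LV1:  {int(bs.stable_V[:, 0].sum())}/"
      f"{bs.stable_V.shape[0]} behavior elements stable, "
      f"{int(bs.stable_U[:, 0].sum())}/{bs.stable_U.shape[0]} brain elements")
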