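"""Parameter-recovery check on synthetic data.

Generates a pool of 200 synthetic species whose market counts are driven by
a single dominant latent-vulnerability axis plus Gaussian noise, then runs
the same scoring + PCA + regression pipeline and measures how well the
latent structure is recovered.
"""

import numpy as np

from capturedkit import SyntheticConfig, analyze, build_score_matrix
from capturedkit.synthetic import generate_study, recovery_experiment

config = SyntheticConfig(
    n_species=200,
    seed=42,
    noise_sd=40.0,
    intercept=2000.0,
    align_weights_to_pc1=True,
    axis_scale=250.0,
)

study = generate_study(config)
report = analyze(build_score_matrix(study.profiles), study.counts, k=2)
eta = np.array(study.true_parameters["latent_axis"])
axis_r = abs(np.corrcoef(report.pca.scores[:, 0], eta)[0, 1])

print(f"single study:   R^2 = {report.regression.r_squared:.4f}, "
      f"|corr(PC1, true axis)| = {axis_r:.4f}")

summary = recovery_experiment(config, k=2, replicates=20)
print(f"20 replicates:  mean R^2 = {summary.mean_r_squared:.4f} "
      f"(SD {summary.sd_r_squared:.4f}), "
      f"intercept +/-2SE coverage = {summary.intercept_coverage:.2f}")
print()
print(
    "R^2 near 1 and axis correlation near 1 mean the regression recovers "
    "the latent vulnerability direction; coverage near 0.95 means the "
    "intercept's standard error is calibrated."
)
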