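"""Score the spatial-inference method with the bin-averaged CV harness.

Cells are reduced to equal-count bin averages, split into calibration and
validation sets, and the weighted monovariate combination fitted on the
calibration points predicts the validation points. The summary statistic
rank = (1 - |R|) * 100 + NRMSE is 0 for a perfect method.
"""

import numpy as np

from pestmap import WorldConfig, crossvalidate, generate_world

# a perfectly linear single-covariate surface: the harness must score 0
perfect = generate_world(WorldConfig(
    grid_rows=36, grid_cols=72, n_covariates=1, covariates_per_response=(1, 1),
    noise_sd_frac=0.0, highlow_spread_frac=0.0, missing_rate=0.0,
    faostat_perturb_frac=0.0, seed=13,
))
key = (perfect.config.ais[0], perfect.config.crops[0])
cv = crossvalidate(perfect.true_apr[key], perfect.covariates, calib_frac=0.07,
                   n_bins=100, seed=1)
print(f"perfect surface:  R = {cv.r:.3f}  NRMSE = {cv.nrmse:.2f}%  rank = {cv.rank:.2f}")

# a noisy multi-covariate surface at several calibration fractions
world = generate_world(WorldConfig(grid_rows=48, grid_cols=96, seed=5))
key = (world.config.ais[0], world.config.crops[0])
rng = np.random.default_rng(5)
truth = world.true_apr[key]
noisy = truth + rng.normal(0, 0.10 * truth.mean(), truth.shape)
for frac in (0.07, 0.2, 0.5):
    cv = crossvalidate(noisy, world.covariates, calib_frac=frac, n_bins=150, seed=2)
    print(f"calib_frac {frac:.2f}: R = {cv.r:+.3f}  NRMSE = {cv.nrmse:5.2f}%  "
          f"rank = {cv.rank:6.2f}  (n_cal={cv.n_cal}, n_val={cv.n_val})")
# Lower rank is better; ranks near 100 indicate the method failed to
# generalize from the calibration bins.
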