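"""Ridge-regression decoding of trial outcome from regional calcium traces.

Builds synthetic trials in which only anterior-lateral motor cortex (ALM)
activity differs between correct and error trials after the cue, then
decodes outcome frame by frame, and measures each region's unique
contribution with permutation-reduced models and a label-shuffled null.
"""

import numpy as np

from mesocage.decoder import DecoderConfig, RoiTraceMatrix, cross_validated_accuracy, reduced_models
from mesocage.imaging import ATLAS

rng = np.random.default_rng(4)
n_trials, n_frames = 120, 12
y = np.where(np.arange(n_trials) % 2 == 0, 1, -1)  # +1 correct / -1 error
X = rng.standard_normal((n_trials, 8, n_frames))
X[:, 0, 6:] += 1.5 * y[:, None]  # ALM carries the outcome signal post-cue

matrix = RoiTraceMatrix(X=X, region_names=list(ATLAS), frame_times=np.arange(n_frames) / 30.0)
cfg = DecoderConfig(runs=6, permutation_iterations=6)
res = cross_validated_accuracy(matrix, y, cfg, np.random.default_rng(5))
print("accuracy by frame:", " ".join(f"{a:.2f}" for a in res.accuracy))
# Pre-cue frames hover at the majority rate (0.50); post-cue frames climb
# toward 1.0 because ALM separates the outcomes.

imp, null, full = reduced_models(matrix, y, cfg, np.random.default_rng(6),
                                 frames=range(5, n_frames), full_result=res)
print(imp[["region", "minus_importance", "plus_accuracy"]].round(3).to_string(index=False))
print(f"label-shuffled null: {null.mean():.2f} (majority rate {full.majority_rate:.2f})")
# -ALM shows the largest accuracy drop and +ALM the best single-region
# model: the decoder attributes the outcome information to ALM alone.
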