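"""Gaussian-process hyperparameter search with EI/PI acquisitions.

First a transparent 1-D demo (minimize a quadratic), then the decoder's
actual search space: Mega Block repeat count 1..5, learning rate, momentum
and L2 strength, on a cheap stand-in objective so the mechanics are
visible without an hour of CNN training.
"""

import numpy as np

from midecode import SearchSpace, optimize_hyperparameters
from midecode.bayesopt import Dimension

# -- 1-D quadratic ----------------------------------------------------------
space = SearchSpace((Dimension("x", -1.0, 1.0),), budget=15)
res = optimize_hyperparameters(lambda c: (c["x"] - 0.25) ** 2, space, seed=0)
print(f"quadratic: best x = {res.best_config['x']:+.3f} "
      f"(true minimum +0.250), f = {res.best_value:.5f}")
print("best-so-far trace:",
      np.array2string(res.best_trace, precision=4))

# -- decoder search space ---------------------------------------------------
space = SearchSpace.decoder_default(budget=12)


def surrogate_validation_error(c):
    """Stand-in for 'train the CNN, return validation error': smooth bowl
    with a preferred depth of 3 repeats and lr near 1e-3."""
    return (0.1 * (c["n_conv_layers"] - 3) ** 2
            + (np.log10(c["learning_rate"]) + 3) ** 2 * 0.05
            + 0.02 * (c["momentum"] - 0.9) ** 2)


res = optimize_hyperparameters(surrogate_validation_error, space, seed=1)
b = res.best_config
print(f"\ndecoder space ({len(res.history)} evaluations):")
print(f"  repeats={b['n_conv_layers']}  lr={b['learning_rate']:.2e}  "
      f"momentum={b['momentum']:.3f}  l2={b['l2']:.2e}")
# In the full pipeline the objective is the CNN's held-out validation
# error; see midecode.pipeline.run_inter(architecture='bayesopt').
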