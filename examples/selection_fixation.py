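"""Fixation probability of a fitter class vs the diffusion approximation.

Two labels, no mutation: one class starts at frequency p = 0.1 with a
fitness advantage s = 0.05 in a population of N = 200.  Classical
diffusion theory predicts it fixes with probability
(1 - exp(-2Nsp)) / (1 - exp(-2Ns)) ~ 0.865.
"""

import math

from mutrace import generate_fixture, run_experiment

N, s, p, reps = 200, 0.05, 0.1, 1000
config = generate_fixture("two_class_selection", seed=6, N=N, s=s, p=p, reps=reps)
result = run_experiment(config)

empirical = (result.records["fixed_label"] == 2).mean()
theory = (1 - math.exp(-2 * N * s * p)) / (1 - math.exp(-2 * N * s))
print(f"empirical fixation probability of the fitter class: {empirical:.3f}")
print(f"diffusion approximation:                            {theory:.3f}")
print(f"(Monte-Carlo standard error ~ {math.sqrt(theory*(1-theory)/reps):.3f})")
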