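"""Sample the distribution of fitness effects and check its moments.

The beneficial effects are exponential with mean 1/lambda; the deleterious
effects are gamma(alpha, beta) truncated at 1.0 by rejection, which pulls
the realized mean slightly below the nominal alpha*beta.
"""

import numpy as np

from mutrace import resolve_model, truncated_gamma_mean
from mutrace.effects import draw_beneficial_magnitudes, draw_deleterious_magnitudes

rng = np.random.default_rng(0)
model = resolve_model(p_b=0.03, mean_beneficial=0.01, shape=0.6, mean_deleterious=0.3)

n = 200_000
s_b = draw_beneficial_magnitudes(model.beneficial, n, rng)
s_d = draw_deleterious_magnitudes(model.deleterious, n, rng)

print(f"beneficial:  sample mean {s_b.mean():.5f}  (exponential mean 1/lambda = 0.01)")
print(f"deleterious: sample mean {s_d.mean():.5f}  (nominal alpha*beta = 0.30, "
      f"truncated mean = {truncated_gamma_mean(0.6, 0.5):.5f})")
print(f"deleterious maximum: {s_d.max():.5f}  (never exceeds the truncation bound 1.0)")
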