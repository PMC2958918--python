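"""Effect of a fertility limit on competition time.

Caps the number of offspring any single parent may contribute per
generation.  A tight cap slows the spread of fit lineages, so mean
competition time G grows as the cap tightens.  (At this small desk scale,
N = 1000, the modal fixed rate sits in a flat low-rate region and wanders
between adjacent rates; the competition-time effect is the robust readout.)
"""

from dataclasses import replace

from mutrace import FertilitySpec, generate_fixture, run_experiment
from mutrace.io import rate_key

for cap in (2, 4, None):
    config = generate_fixture(
        "fig_preset_scaled", seed=9, name="fig2_N1e4", reps=30
    )
    config = replace(
        config,
        base=replace(
            config.base, population_size=1000, fertility=FertilitySpec(cap=cap)
        ),
    )
    summary = run_experiment(config).summary
    label = "unlimited" if cap is None else f"cap={cap}"
    print(
        f"{label:>9}:  U_opt={rate_key(summary.optimum_rate):<7} "
        f"G={summary.mean_generations:7.1f}"
    )
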