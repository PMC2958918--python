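"""Estimate the optimum mutation rate at desk scale.

Runs a reduced-replicate version of the N = 1e4 baseline scenario (ten
subpopulations on the Ru1 rate ladder, p_b = 3%, mean effects 0.01
beneficial / 0.3 deleterious) and prints the frequency with which each rate
fixed.  The mode of this distribution is the optimum mutation rate U_opt;
G is the mean number of generations a competition took.
"""

from mutrace import generate_fixture, run_experiment
from mutrace.io import rate_key

config = generate_fixture("fig_preset_scaled", seed=11, name="fig2_N1e4", reps=40)
summary = run_experiment(config).summary

print("rate      frequency")
for rate, freq in summary.frequency.items():
    bar = "#" * round(40 * freq)
    print(f"{rate_key(rate):<8}  {freq:5.3f}  {bar}")
print(f"\nU_opt = {rate_key(summary.optimum_rate)}  (mode of fixed rates)")
print(f"G     = {summary.mean_generations:.0f} generations (mean competition time)")
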