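"""Neutral control: with no mutations every subpopulation is equivalent.

Each of the ten labels should fix in about 10% of competitions — pure
random drift from initial frequency 1/10.  This is the basic sanity check
that the reproduction step carries no hidden bias.
"""

from mutrace import generate_fixture, run_experiment

config = generate_fixture("tiny_neutral", seed=5, reps=500)
result = run_experiment(config)

counts = result.records["fixed_label"].value_counts().sort_index()
print("label  fixations  frequency (expected 0.100)")
for label, count in counts.items():
    print(f"{label:>5}  {count:>9}  {count / len(result.records):.3f}")
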