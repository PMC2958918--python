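# mutrace

Forward-time Wright–Fisher simulator of competition among asexual
subpopulations that differ only in their **genome mutation rate** — a tool
for studying how natural selection tunes mutation rates in finite haploid
populations, for population geneticists and students of molecular
evolution.

## The model

A population of constant size *N* is split into *K* = 10 labeled
subpopulations, each assigned a distinct genome mutation rate *U*
(mutations per genome per generation, spanning roughly 10⁻⁴–10⁻¹ on a
logarithmic ladder).  Every generation:

1. each individual of subpopulation *k* gains *m* ~ Poisson(*U_k*) new
   mutations; a mutation is beneficial with probability *p_b* (effect
   *s_b* ~ Exp(λ), fitness factor 1 + *s_b*) and deleterious otherwise
   (*s_d* ~ Gamma(α, β) truncated at 1, fitness factor 1 − *s_d*), acting
   multiplicatively: *w_n* = *w_{n−1}* · Π(1 ± *s_j*);
2. *N* offspring are resampled with replacement, weighted by fitness
   (multinomial Wright–Fisher reproduction); labels are heritable and never
   mutate.

Selection and drift eliminate subpopulations until one label fixes; its
rate is that competition's *fixed* mutation rate.  Over hundreds of
replicate competitions, the mode of the fixed rates is the **optimum
mutation rate** *U_opt* and the mean time to fixation is the **competition
time** *G*.  Presets cover the published scenarios: sweeps over *N*, *p_b*,
the gamma parameters (α, β), the beneficial mean effect, rate-range /
founder-fitness / fertility robustness checks, and an empirical
virus-derived DFE.

## Worked example

```sh
python examples/optimum_rate.py
```

runs 40 desk-scale competitions at *N* = 10⁴ with the baseline DFE
(*p_b* = 3 %, mean effects 0.01 beneficial / 0.3 deleterious) and prints:

```
rate      frequency
0.0001    0.025  #
0.0003    0.025  #
0.001     0.150  ######
0.003     0.200  ########
0.01      0.200  ########
0.02      0.175  #######
0.03      0.150  ######
0.04      0.075  ###
0.06      0.000
0.1       0.000

U_opt = 0.003  (mode of fixed rates)
G     = 700 generations (mean competition time)
```

The bell-shaped frequency table shows that intermediate rates win the
competition far more often than the extremes: deleterious load penalizes
the highest rates while beneficial supply penalizes the lowest, and the
mode of the distribution — here 0.003 — is the optimum rate.  Other
examples demonstrate the neutral-drift control, the diffusion-theory
fixation check, DFE sampling, and fertility limitation.

The same experiment is available from the shell:

```sh
mutrace presets                      # list registered scenarios
mutrace run --preset fig2_N1e4 --n-reps 40 --seed 11 --out out/
```

which writes `replicates.csv` (one row per competition), `summary.json`
(frequency table, U_opt, G) and `manifest.json` (enough to re-execute the
run bit-identically).

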