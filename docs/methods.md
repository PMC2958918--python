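# Methods

## Model

`mutrace` simulates a finite, strictly asexual, haploid population of
constant size `N` with discrete, non-overlapping generations.  The
population is partitioned into `K` labeled subpopulations (default `K = 10`,
founded at `N/K` individuals each).  A label is heritable, is never changed
by mutation, and controls exactly one property: the genome mutation rate
`U_k` (expected new mutations per genome per generation) of its carriers.
The subpopulations therefore compete — under selection on accumulated
fitness and under random drift — until a single label remains, and the rate
of that label is the competition's *fixed* mutation rate.  Repeating the
competition many times estimates the distribution of fixed rates; its mode
is the *optimum* mutation rate `U_opt`, and the mean number of generations
to fixation is the mean competition time `G`.

One generation cycle is:

1. **Mutation.** Each individual of subpopulation `k` receives
   `m ~ Poisson(U_k)` new mutations.  Each mutation is beneficial with
   probability `p_b`, deleterious with probability `p_d = 1 − p_b`.
   Beneficial selection coefficients are exponential,
   `s_b ~ Exp(λ)` with mean `s̄_b = 1/λ`; deleterious coefficients are
   gamma, `s_d ~ Gamma(α, β)` (scale convention, mean `αβ`), truncated at
   1.0 so the fitness factor `1 − s_d` cannot go negative.  Mutations act
   multiplicatively and without epistasis:
   `w_n = w_{n−1} · Π (1 + s_b,j) · Π (1 − s_d,j)`.
2. **Reproduction.** `N` offspring are sampled with replacement, each
   parent drawn with probability `w_i / Σ w` — offspring counts are
   multinomial, Wright–Fisher fashion.  Offspring inherit fitness and label
   unchanged.

Fixation is checked after reproduction (mutation cannot lose a label).  A
run ends `fixed`, `censored` (generation safeguard hit, default 10^6), or
`extinct` (total fitness reached zero, possible only with lethal
mutations, i.e. `s_d = 1`).

## Parameters and defaults

| parameter | meaning | default | units |
|---|---|---|---|
| `N` | population size | scenario-dependent (10^4–10^7) | individuals |
| `K` | number of subpopulations | 10 | — |
| `U_1..U_K` | genome mutation rates | rate set `Ru1` (10^-4 … 10^-1) | mutations/genome/generation |
| `p_b` | beneficial fraction of new mutations | 0.03 | probability |
| `λ` | exponential rate for `s_b` | 100 (mean `s̄_b = 0.01`) | 1/selection coefficient |
| `α, β` | gamma shape and scale for `s_d` | 0.6, 0.5 (mean `s̄_d = 0.3`) | — |
| `n_competitions` | replicates per experiment | 300 | — |
| `max_generations` | censoring safeguard | 10^6 | generations |

The five registered rate sets `Ru1`–`Ru5` place `lg U` roughly uniformly on
[−4, −1], with `Ru4` shifted up to [−3.7, −0.7] and `Ru5` stretched to
[−4.3, 0].  The named presets (`fig2_*`, `fig3_*`, … `table1_VSV`) bundle
these with the DFE parameters of each published scenario; the baseline DFE
(`p_b = 3%`, `s̄_b = 0.01`, `s̄_d = 0.3`) reflects empirical microbial
estimates (for vesicular stomatitis virus, mean effects 0.042 beneficial /
0.24 deleterious; the `table1_VSV` preset uses those means with the
beneficial fraction conditioned on a mutation being non-neutral).

## Numerical and design choices

**Truncation of the deleterious gamma.** "Truncated at 1.0" is implemented
by rejection (redraw until `s_d ≤ 1`), i.e. the renormalized conditional
distribution.  The default gamma is heavy-tailed: `P(s_d > 1) ≈ 6.0%`, and
the truncated mean is ≈ 0.227 rather than the nominal 0.3;
`truncated_gamma_mean` computes it exactly via the regularized incomplete
gamma function, and the tests cross-check that value by numeric quadrature.
A `clamp` mode (mass at exactly 1.0 — a lethal mutation) is available for
sensitivity analysis.

**Cycle order.** Mutation precedes reproduction, so offspring are sampled
by post-mutation fitness; this realizes the recursion in which a newborn's
fitness is its parent's fitness times its own mutation factors.  The
alternative order (`reproduce-first`) is a config switch; in side-by-side
runs it does not change the fixed-rate distribution detectably.

**Randomness contract.** Each competition consumes a single seeded numpy
`Generator`, with a fixed documented draw order per generation: (1) one
Poisson draw of the total mutation count per subpopulation in label order
(mean `n_k U_k` — equivalent to per-individual Poisson(`U_k`) draws by
Poisson splitting), (2) a uniform member assignment per mutation, (3) a
uniform direction draw per mutation, (4) beneficial magnitudes, then
deleterious magnitudes in rejection rounds, (5) reproduction draws.
Reproduction generates sorted uniforms on `(0, Σw)` as normalized cumulative
sums of `N + 1` standard exponentials and inverts them through the
cumulative fitness vector; the resulting offspring counts are exactly
multinomial(`N`, `w/Σw`), and the merge is O(N).  A deliberately naive
loop-based engine (`mutrace.reference`) replays the identical stream with
scalar draws; the test suite asserts bit-identical trajectories across
seeds, fertility caps and both cycle orders.  Per-replicate seeds derive
from the experiment master seed as
`SeedSequence(master_seed, spawn_key=(i,))` (31 bits), so replicates are
order-independent and parallelizable.

**Fertility cap.** A finite cap on offspring per parent is realized by
sequential weighted sampling with rejection: candidates are drawn from the
*fixed* fitness distribution and draws of saturated parents are discarded
(equivalent to renormalizing over unsaturated parents).  An infeasible cap
(`cap × #positive-fitness parents < N`) raises an error.  With `cap = ∞`
the scheme reduces exactly to plain multinomial sampling.

**Founder fitness.** Besides the uniform-1.0 default, founders may be drawn
from a normal distribution (non-positive draws rejected and redrawn, which
shifts the realized mean slightly upward — e.g. 0.538 for nominal
mean 0.5, variance 0.1) or a gamma distribution.  The gamma founder
parameters "(20, 20)" are read with `β` as a *rate* (mean 1.0) by default,
since founders with mean fitness 400 next to a 1.0 baseline would be
biologically meaningless; the scale convention remains selectable.  For the
deleterious-effect gamma, by contrast, `β` is a scale (the published
density uses `e^{−s/β}`), giving the stated mean `αβ = 0.3`.

**Ties and degenerate inputs.** `U_opt` ties break toward the smaller rate
(conservative; full frequency tables are always emitted).  Rate sets must
be sorted but may contain equal values, admitting all-zero neutral control
configurations; fixation frequencies in such controls are analyzed per
label.  `G` averages fixed replicates only; censored and extinct replicates
are counted and reported separately.

## What the experiments show — and at what scale

The suite and the acceptance script rerun the published scenarios at desk
scale on one CPU: the N = 10^4 baseline at the full 300 competitions, the
N = 10^5 sweep endpoints at 50 competitions, monotonicity and null-result
properties at 50–100 competitions with N = 10^3–10^5.  These sizes were
chosen so a full run completes in minutes while keeping Monte-Carlo error
on modal rates and mean times small relative to the published contrasts.

Verified against independent theory: neutral fixation frequencies are
uniform across subpopulations (chi-square), and two-class selective
fixation matches Kimura's diffusion approximation
`(1 − e^{−2Nsp})/(1 − e^{−2Ns})` within Monte-Carlo error.

Observed against the published readouts: mean competition times agree
closely (e.g. ≈ 206 vs 210 and ≈ 990 vs 1106 generations at the
beneficial-effect sweep endpoints), and `U_opt` matches where the mode is
well separated (0.01 at `p_b = 1%`; 0.005 at `s̄_b = 0.005`).  Where two
adjacent rates on the discrete ladder are nearly tied (the N = 10^4
baseline; the strong-beneficial endpoint), this implementation's modal rate
can land one grid step above the published one; a single 300-competition
realization of a near-tied mode is itself noisy, and the direction of every
trend (in `N`, `p_b`, `s̄_b`) reproduces.

## Limitations

- Fitness is the only individual state besides the label: no explicit
  genomes, no epistasis, no back-mutation, no recombination, no
  environmental change.
- The fixed-rate mode is a discrete statistic on the configured rate
  ladder; conclusions about `U_opt` are resolution-limited by that ladder
  (the rate-range presets `Ru1`–`Ru5` exist to probe exactly this).
- Capped-fertility sampling is exact but uses rejection; it slows down
  markedly when nearly all capacity is saturated (e.g. `cap = 1` with
  strongly skewed fitness).
- Competitions at `N ≥ 10^6` are supported but not exercised by the default
  suite; runtimes grow linearly in `N` and in `G`.
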