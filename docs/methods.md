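# Methods

## The model

Neutrophils that fail to resolve an inflammatory insult commit to one of
two death pathways. Apoptosis is quiet and anti-inflammatory; necrosis
ruptures the cell, damaging nearby tissue but recruiting reinforcements
that help clear inflammation-triggering moieties (ITMs, e.g. bacterial
LPS). We treat the choice as a two-player symmetric game. With benefit of
apoptosis `b ≥ 0` and cost of necrosis `c ≥ 0`, the row player's payoffs
are

|            | necrosis | apoptosis |
|------------|----------|-----------|
| necrosis   | A = −c   | B = −c+b  |
| apoptosis  | C = b    | D = 2b    |

For b, c > 0 the ordering D > C > B > A makes the stage game a deadlock
game: apoptosis is dominant and mutually preferred, so the payoff matrix
alone can never sustain necrosis. The matrix is stored as the pair (b, c)
rather than four numbers, so the defining identities cannot drift; every
closed form below depends on the payoffs only through b + c (the
"apoptosis advantage" per opponent, C − A = D − B = b + c).

## Mean field

A focal cell playing necrosis with probability q in a population with
necrotic fraction p has average fitness

    F(q,p) = qpA + q(1−p)B + (1−q)pC + (1−q)(1−p)D − exp(α·R(q,p))
    R(q,p) = I^k − p·m·(N_T−1) − q·m − (1−p)·n·(N_T−1) − (1−q)·n

where I is the initial ITM concentration, m (n) the ITMs a necrotic
(apoptotic) neutrophil eventually neutralizes, N_T the population size,
α > 0 the strength of the global threat posed by unresolved ITMs, and k
the empirical dose–response exponent. R is used verbatim, with no floor
at zero: the exponential keeps the cost itself positive, and negative R
simply means a cleared system with a vanishing threat. Setting
∂F/∂q = 0 at the self-consistent point q* = p gives

    p = q* = −( ln((b+c)/(α(m−n))) + α·n·N_T − α·I^k ) / ( α·N_T·(m−n) )

F is strictly concave in q (the cost is the exponential of a function
linear in q), so this stationary point is the maximum. Validity requires
b+c ≠ 0, m ≠ n, α ≠ 0, a positive log argument, and p ∈ [0,1]. Each
failure mode is reported with a reason code; p is never clipped here —
sweeps mask invalid regions instead, which keeps parameter-space figures
honest about where the model breaks down.

Numerical choices: all logarithms are natural (the fitted coefficient
β = e^−0.6 fixes base e); cost exponents above 700 are flagged as an
infinite cost (−∞ fitness) rather than allowed to overflow.

## Dose–response data fit and parameter identification

Measured necrotic fractions follow a power law in the initial dose,

    p − γ = β · I^k,   k = 0.0929, β = e^−0.6, γ = 0.17,

with γ the baseline necrotic fraction observed with no insult and 500
ng/ml LPS the fatal dose, identified with 100% necrosis. Matching the
closed-form equilibrium term-by-term against the power law gives

    γ = −( ln((b+c)/(α(m−n))) + α·n·N_T ) / ( α·N_T·(m−n) )
    β = 1 / ( N_T·(m−n) )        ⇒   n = m − 1/(N_T·β)

so for any anchor (α, m) the remaining parameters follow:

    b + c = α(m−n) · exp( −γ·α·N_T·(m−n) − α·n·N_T )

This closed inversion of the γ identity is package plumbing (the forward
map is the published result); tests verify it against an independent
one-dimensional numerical solve. The sampler draws α and m uniformly from
configurable bounds — defaults α ∈ (0, 3], m ∈ (1/(N_T β), 0.01], chosen
to bracket the quoted anchor values (α = 1.0, m = 0.0015, m = 0.0008,
n = 0.0004) while keeping n ≥ 0 — and splits b + c by a uniform ratio.
The split is invisible to every equilibrium quantity, which is exactly
the degeneracy the parameter clouds visualize: all sampled tuples trace
the *same* curve p(I) = γ + β·I^k. Above I ≈ ((1−γ)/β)^(1/k) ≈ 86 the
raw curve exceeds 1 and the equilibrium is flagged invalid; only the
explicit power-law predictor offers clipping to [0, 1] (used to express
the fatal dose as 100% necrosis).

## Cellular automaton

A side×side torus (default 50×50, so side² = 2500 cells stand in for
N_T) starts fully *activated* (undecided). Each iteration resolves one
activated cell, drawn uniformly at random — implemented as a seeded
permutation of all sites consumed in order, which is distributionally
equivalent to re-sampling until an activated cell is hit, and cheaper.
The cell computes one fitness per hypothetical choice: the payoff summed
against every *decided* Moore-range-1 neighbor (undecided neighbors have
no strategy and contribute nothing) minus exp(α·R̂) with R̂ the
remaining-ITM ledger under that choice. Higher fitness wins; exact ties
(relative tolerance 1e−12) go to apoptosis, the default death pathway.
The run ends after exactly side² decisions.

The ledger R̂ transcribes the mean-field R with the observed state in
place of p: necrotic cells are booked at rate m, and *all other* cells —
decided apoptotic and still-undecided alike — at the default apoptotic
rate n, because apoptosis is the pathway every neutrophil takes absent a
decision to the contrary. Under the **Global** scheme the booking runs
over the whole lattice; under the **Local** scheme only over the focal
cell's 3×3 neighborhood, while the sensed pool is still the full
concentration (ITMs are spatially homogeneous). The pool entering R̂ is
the raw concentration I, not I^k: k is an exponent of the empirical
dose–response bridge, not a property of the dose a cell senses. Both
choices are configurable (`apply_power_k`, `undecided_neutralize`,
`floor_pool_at_zero`) because the alternative readings are plausible;
the defaults are the pair that reproduces the observed dose response.
With the alternative ledger (decided-only depletion of a transformed
pool) the fatal-dose response saturates near 80% rather than 100%, for a
structural reason: total depletion capacity α·m·N_T ≥ α/β ≈ 1.82α always
exceeds the transformed pool α·500^k ≈ 1.78α, so every run would end in
an apoptosis-dominated regime regardless of dose.

Decisions are made on the sign of the fitness *difference*,

    f(APO) − f(NEC) = (b+c)·d − exp(α·R̂_nec)·expm1(α·(R̂_apo − R̂_nec)),

with d the number of decided neighbors, evaluated in log domain. This is
algebraically identical to comparing the two fitnesses but exact and
overflow-free at high doses, where both raw fitnesses overflow float64
and a naive comparison would degenerate into a spurious "tie". The
exposed `strategy_fitness` still reports −∞ on overflow for inspection.

Emergent behavior under the defaults, with data-consistent tuples: at
dose 0 necrosis is chosen while fewer than d* ≈ exp(α[(m−n)(γN_T −
#necrotic) + n]) neighbors have decided, which self-arrests at #necrotic
≈ γN_T — the automaton finds the 17% baseline without being told it. At
the fatal dose the surviving threat term keeps d* above 8 throughout and
necrosis goes to ~100%, committed early in the run (the cumulative curve
at dose 0 likewise saturates in the first few hundred steps). Local
sensing never sees the lattice-wide resolution of the insult, so
necrosis stays near 100% at every dose — the model's argument that
neutrophils need global information to pick pathways proportionate to
the insult.

## Experiment sizes and reproducibility

Default campaign sizes: dose–response comparisons use 20 sampled tuples
× 3 replicate seeds per dose on 50×50 lattices (240 runs across doses
{0, 10, 100, 500} take well under a minute); trajectory averages use 20
tuples × 1 run per dose. Run seeds derive as `seed·100003 + tuple_index`
so campaigns are bitwise reproducible from their recorded metadata while
replicates stay decorrelated. Every experiment emits CSV tables plus a
JSON metadata sidecar (seed, bounds, constants); plots are deliberately
out of scope — the tables carry every plotted quantity.

## What the generated data does and does not show

The model's "data" are self-generated: parameter tuples reconstructed
from three printed fit constants, not raw dose–response measurements.
Passing checks therefore demonstrate internal consistency (the inversion
round-trips, the equilibrium reproduces the power law it was built from,
the automaton's collective behavior matches the mean-field target) — not
that the power law is the true biological dose–response, which rests on
a small in-vitro dataset. Iteration steps are decision events, not
calendar time; lattice geometry is a topological stand-in for tissue
adjacency; and the population is fixed during a run (no recruitment or
influx). The γ = 0.17 baseline is treated as an experimental offset with
sources outside the modeled insult.

## Known limitations

- The Local-scheme ledger is one reading of "sensing the ITMs in a
  cell's proximity"; the biological picture is qualitative, so the
  package exposes the bookkeeping switches rather than claiming
  uniqueness.
- Equilibria are stationary-state only; no replicator-dynamics
  integration is provided.
- At doses just above zero the automaton's global response jumps to the
  70–100% range (the sensed pool enters the cost exponentially), so the
  simulated dose–response is steeper at tiny doses than the fitted power
  law; at the measured dose grid {0, 10, 100, 500} the two agree.
- b and c are identified only through their sum; conclusions about the
  benefit/cost split would need data the model does not have.
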