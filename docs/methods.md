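# Methods

## The model

`equisim` simulates a biological market for cooperative partners. A
population of `n` individuals lives for `L` time units per generation.
Each individual carries a non-heritable *productivity* — its contribution
to joint production per unit time — and a heritable *division policy*
consisting of rewards (the fraction it concedes when it unilaterally sets
the division) and minimum acceptable rewards, MARs (the least it accepts
when it is the one deciding whether to cooperate).

Within a generation, time runs continuously and only two events exist:

- **encounter**: two solitary individuals meet. A fair coin names one the
  *partner*, who sets the division through its reward policy, and the
  other the *decision maker*, who accepts iff the offered reward is at
  least its MAR (ties accept). On acceptance the dyad produces the sum of
  the two productivities per unit time, of which the decision maker
  receives the promised fraction; on rejection both return to the
  solitary pool with nothing.
- **split**: an established pair dissolves; both become solitary again.

After any event at time *t*, the waiting time to the next event is
exponential with rate λ(t) = C(t)·τ/2 + S(t)·β, where C counts paired
individuals (so C/2 pairs, each splitting at rate τ) and S counts
solitary ones; the event is an encounter with probability S·β/λ. The
ratio β/τ sets the fluidity of the market: with fast encounters and
long-lived pairs, rejecting a partner costs almost nothing, and
choosiness pays.

At time `L` everyone reproduces and dies (Wright–Fisher, non-overlapping
generations). An individual with lifetime resources *z* contributes
round(*f*·*z*/*z̄*) offspring to a pool, from which `n` survivors are
drawn; each trait of each offspring mutates independently with
probability `m` by a normal step (sd `d`), clipped to [0, 1].
Productivity is redrawn at every birth, keeping both classes present in
every generation.

Two policy encodings are provided:

- **two_productivities**: productivities are `a` or `b` (default 1 and
  2, equiprobable), and the policy is eight scalars — r_ij and MAR_ij
  for each (own class, other's class) pair.
- **continuum**: productivities are uniform on [a, b] and the policy is a
  pair of 2-5-1 feedforward networks (logistic units, weights clipped to
  [−5, 5], mutation step `weight_mut_sd`), mapping (own, other's)
  productivity to a reward or a MAR. Networks encode a *reaction norm*:
  they answer for productivity pairs never encountered during evolution.

The analytic benchmark, valid as β/τ → ∞, is that the reward to the
decision maker equals its relative contribution p_dm/(p_dm+p_partner):
each party is paid its opportunity cost, and output/input ratios are
equal for both — equity in Aristotle's proportional sense.

## Parameters that matter

| name | meaning | default | notes |
|------|---------|---------|-------|
| n | population size | 500 | reference setup |
| a, b | low/high productivity (resources per unit time) | 1, 2 | b/a sets the contribution asymmetry |
| β | encounter rate per solitary individual (1/time) | 1.0 | 1e-4…1 spans costly→cheap partner choice |
| τ | split rate per pair (1/time) | 0.01 | 1/τ ≈ pair lifetime |
| L | lifespan (time) | 500 | L·τ ≈ pair episodes per lifetime |
| m | per-trait mutation probability | 0.002 | applies per offspring copy |
| d | trait mutation sd | 0.02 | desk-scale recipes use 0.05 |
| f | fecundity factor | 2 | pool ≈ 2n offspring |
| p_high | P(newborn is high-productivity) | 0.5 | class counts are binomial, not fixed |
| weight_bound | network weight half-range | 5 | continuum mode |
| weight_mut_sd | network weight mutation sd | 0.2 | desk-scale recipe uses 0.5 |
| hidden_units / use_bias | network topology | 5 / no bias | bias terms optional, off by default |

## Design choices where the design was open

- **Split-rate reading.** λ uses C·τ/2: τ is a per-pair rate (a pair of
  cooperating individuals is chosen to split), so C/2 pairs each split at
  rate τ.
- **Lone-solitary corner.** A single solitary individual cannot
  encounter anyone, so its β contribution is dropped from λ. With even
  `n` the corner is unreachable (pairings change S by 2).
- **End-of-life settlement.** Pairs still together at L are settled at
  exactly L: production accrues per unit time while together, and life
  ends at L. An event whose waiting time crosses L is not executed.
- **Rounding in reproduction.** round() is half-away-from-zero (0.5 → 1);
  banker's rounding would bias small offspring numbers downward.
- **z̄ = 0 generations** (nobody cooperated, possible at β ≈ 0 early on):
  every individual leaves round(f) offspring — pure drift, no selection.
- **Offspring pool sampling.** The n survivors are drawn uniformly with
  replacement from the pool — canonical Wright-Fisher multinomial
  resampling with the pool composition as weights. (Sampling distinct
  pool members instead would halve offspring-number variance and hence
  neutral drift, which visibly slows the offer/MAR co-evolutionary
  ratchet.) This also covers pools smaller than n.
- **Per-offspring mutation.** Each offspring copy mutates independently;
  operationally the mutation is applied to the n sampled copies, which is
  distributionally identical to mutating the whole pool first.
- **Network inputs.** Input neurons pass raw productivities through;
  squashing 1–2 through a logistic before the hidden layer would discard
  most input variance. Inputs are always ordered (own, other's).
- **Bias terms** default off — the evolvable parameters are the synaptic
  weights between layers — with `use_bias` as an escape hatch (biases
  then evolve and mutate like weights).
- **Trajectory statistic.** Two reward statistics are recorded every
  generation: the genotypic class mean over the whole population
  (well-defined even when a class transacts rarely) and the
  transaction-weighted mean of the offers actually accepted. They do not
  coincide: rejection censors low offers, so accepted-offer means sit a
  few percentage points above genotypic means near equilibrium. The
  headline equilibrium quantities are accepted-reward means — the reward
  actually changing hands in cooperative interactions; the genotypic
  variant is reported alongside in the time series.
- **Sweep seeding.** Each (β, replicate) cell derives its seed from
  (base seed, β index, replicate) through `numpy.random.SeedSequence`;
  the derived seed is recorded in the manifest.

## Desk-scale recipes and problem sizes

The reference experiment (n=500, L=500, 8000 generations) takes tens of
minutes per run, so the packaged recipes (`equisim.recipes`) shrink the
problem while raising the mutation supply to keep the co-evolutionary
search fed:

- **Set 1 desk scale** — n=300, L=100, β=1, τ=0.01, d=0.05, 3000
  generations, 5 replicate seeds; equilibrium rewards are genotypic class
  means averaged over the final 10% of generations and replicates.
- **Set 2 desk scale** — n=200, L=100, 1500 generations, 3 replicate
  seeds, m=0.01 and weight_mut_sd=0.5. The reference per-weight rate
  (0.002) at n=200 supplies ~12 mutations per generation across 6000
  weights, too few for the networks to leave their initial neighbourhood
  within 1500 generations; the recipe raises the rate fivefold (matching
  the fivefold-shortened run) and the step 2.5-fold (as Set 1's d).

Two systematic effects of desk scaling are worth knowing when reading
results. First, at L=100 with τ=0.01 an individual experiences roughly
one pair episode per lifetime (versus ~5 at L=500), so rejecting a
partner carries a real cost even at β/τ=100; the traits under the
weakest selection — what high producers concede to low-productivity
decision makers, and the low–low market — equilibrate noticeably below
the fluid-market prediction and wander between replicates. Second, at
equilibrium a decision maker is exactly indifferent at its proportional
MAR, so the MAR is selectively pinned only from below; with the stronger
mutation noise of the scaled recipes the mean MAR at extreme inputs
(e.g. the (2, 1) corner of the continuum model) drifts upward of the
proportional value in some replicates. Both effects shrink as n, L and
the run length grow toward the reference setup.

## What the generator emulates, and what it does not

All inputs are generated internally; there is no empirical data path.
The model deliberately omits: reputation formation (a partner's reward
policy is simply known), population structure, overlapping generations,
within-lifetime learning, recombination between reward and MAR loci, and
heritable productivity. Passing tests therefore demonstrate the internal
logic of partner-choice markets — not that human or animal data follow
it.

## Numerical notes

- One `numpy.random.Generator` per run; every stochastic draw flows
  through it, so a manifest (parameters + seed + replicate) reproduces a
  run byte-for-byte.
- Resource settlement is exact arithmetic on (p₁+p₂)·duration; shares
  always sum to joint production to machine precision.
- The population is stored struct-of-arrays; the event loop is O(1) per
  event via swap-pop index lists for the solitary pool and the pair
  list.
- Trait clipping creates genuine atoms at interval ends (e.g. traits
  exactly 0 in the ancestral population stay exactly 0 until mutated).

## Known limitations

- Desk-scale equilibrium estimates carry replicate-to-replicate sd of a
  few percentage points; the recipes average over seeds and a generation
  window but remain stochastic.
- The continuum-mode corner statistics extrapolate the networks slightly
  beyond the empirical input distribution (exact (2,1) encounters have
  measure zero).
- `offsprings = round(f·z/z̄)` makes realized selection gradients depend
  weakly on f through rounding; f=2 keeps the pool comfortably above n
  without magnifying this.
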