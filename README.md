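# equisim

Agent-based simulation of **partner choice and the evolution of
equitable resource division** in biological markets, for researchers in
evolutionary game theory, behavioral ecology and the evolution of
fairness.

Why do cooperators divide spoils *in proportion to contribution*? The
model: a population of `n` individuals, each with a non-heritable
productivity (low `a` or high `b`, or uniform on `[a,b]`), pairs up to
produce resources in continuous time. Solitary individuals encounter
each other at rate β; pairs dissolve at rate τ. At each encounter one
individual (the *partner*) unilaterally sets the division through its
heritable reward policy r, and the other (the *decision maker*) accepts
iff r ≥ its heritable minimum acceptable reward (MAR). While paired, the
dyad produces p₁+p₂ per unit time, the decision maker receiving the
fraction r. At the end of life L each individual leaves
round(f·z/z̄) offspring (z = lifetime resources) with per-trait mutation —
Wright–Fisher selection on market success.

The waiting time between events is exponential with rate

    λ(t) = C(t)·τ/2 + S(t)·β,      P(encounter) = S(t)·β / λ(t),

with C(t) paired and S(t) solitary individuals. When β/τ is large,
finding partners is cheap relative to interaction length and choosiness
is nearly free; the evolutionarily stable division then pays each party
its opportunity cost, i.e. the decision maker's share equals its
relative contribution p_dm/(p_dm+p_partner) — **equity**. When β/τ is
small, partner choice is costly and offers stay near zero. A second
encoding replaces the eight scalar traits with two evolvable 2-5-1
logistic networks (weights in [−5,5]) mapping (own, other's)
productivity to reward/MAR — an evolved reaction norm that generalizes
the proportionality rule to unseen productivities.

## Worked example

```sh
python examples/analytic_prediction.py
```

```
p_dm  p_partner  reward_to_dm  dm_share_per_unit_time
 2.0        1.0        0.6667    2.0000
 1.0        2.0        0.3333    1.0000
 1.0        1.0        0.5000    1.0000
```

A high producer (b=2) deciding for a low-producing partner (a=1) must
receive 2/3 of the 3 resources produced per unit time — exactly the 2 it
could earn with another high producer; its opportunity cost is
compensated, and both parties' output/input ratios are equal.

Evolution finds the same answer. A miniature run
(`python examples/evolve_equity_quickrun.py`, ~1 min) prints the
class-mean reward trajectory from the all-stingy ancestral state:

```
generation  LP->HP  HP->LP  HP->HP  LP->LP
         0  0.000  0.000  0.000  0.000
       400  0.137  0.066  0.149  0.086
       799  0.249  0.311  0.191  0.007
```

— rewards ratchet up from the stingy ancestral state, each dyad class on
its own stochastic schedule, toward the proportional 0.667 / 0.333 /
0.500 / 0.500 (reaching equilibrium needs the full desk-scale recipe in
`equisim.recipes`: 3000 generations × 5 seeds), while with β lowered
to 10⁻⁴ (`examples/partner_choice_cost.py`) they stay near 0.
`examples/neural_reaction_norm.py` prints the evolved network MAR
surface (demanding more the more you produce) and a
lifetime-gain-vs-productivity slope near 1: everyone is paid roughly
what they contribute.

Other entry points: `examples/one_generation_market.py` (the event
engine with its log), and a thin CLI —

```sh
equisim run --out runs/demo --n 200 --generations 500 --seed 1
equisim sweep --out runs/sweep --beta-value 0.0001 --beta-value 1 --replicates 3
equisim summarize runs/sweep/*/summary.tsv --out runs/sweep/agg.tsv
```

Each run directory holds a flat-text manifest sufficient to reproduce
the run byte-for-byte, a generation time series, and a terminal genotype
dump.

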