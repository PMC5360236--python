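"""Documented experiment recipes, full-scale and desk-scale.

The full-scale two-productivity experiment (the reference setup: n=500,
L=500, 8000 generations) takes tens of minutes per run; the desk-scale
recipes below reproduce its equilibrium structure in minutes by shrinking
the population, lifespan and run length while raising the mutation supply
to keep the co-evolutionary search fed:

- Set 1 desk scale: n=300, L=100, beta=1, tau=0.01, d=0.05 (2.5x the
  reference mutation step), 3000 generations, 5 replicate seeds;
  equilibrium rewards are read as the genotypic class means averaged over
  the final 10% of generations and over replicates.
- Set 2 desk scale: n=200, L=100, 1500 generations, 3 replicate seeds,
  with per-weight mutation probability 0.01 and weight step 0.5 (the
  reference per-trait rate 0.002 applied to 30 weights at n=200 supplies
  too few mutations for the networks to equilibrate within the shortened
  run).

Shortening the lifespan to L=100 at tau=0.01 leaves roughly one pair
episode per lifetime (versus ~5 at L=500), so partner rejection carries a
real cost even at beta/tau=100 and the evolved rewards sit slightly below
the fluid-market analytic prediction; see docs/methods.md.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .analytics import dyad_label
from .experiment import RunResult, run_experiment
from .networks import forward_population
from .params import Params

SET1_DESK = dict(n=300, L=100.0, beta=1.0, tau=0.01, d=0.05, m=0.002,
                 generations=3000)
SET1_REPLICATES = 5

SET2_DESK = dict(mode="continuum", n=200, L=100.0, beta=1.0, tau=0.01,
                 m=0.01, weight_mut_sd=0.5, generations=1500)
SET2_REPLICATES = 3

#: full-scale reference setup, provided as a recipe (long-running)
SET1_FULL = dict(n=500, L=500.0, beta=1.0, tau=0.01, d=0.02, m=0.002,
                 generations=8000)

LOW_BETA = 1e-4   # costly-partner-choice regime of the reference setup


def set1_desk_params(seed: int, **overrides) -> Params:
    cfg = {**SET1_DESK, "seed": seed, **overrides}
    return Params(**cfg)


def set2_desk_params(seed: int, **overrides) -> Params:
    cfg = {**SET2_DESK, "seed": seed, **overrides}
    return Params(**cfg)


def run_set1_desk(seed: int, replicates: int = SET1_REPLICATES,
                  beta: float | None = None,
                  record_every: int = 10) -> list[RunResult]:
    """The desk-scale two-productivity experiment, one run per replicate."""
    params = set1_desk_params(seed, **({} if beta is None else
                                       {"beta": beta}))
    return [run_experiment(params, replicate=rep, record_every=record_every)
            for rep in range(replicates)]


def equilibrium_class_means(runs: list[RunResult],
                            tail_fraction: float = 0.10,
                            statistic: str = "accepted") -> pd.Series:
    """Equilibrium reward means per dyad class.

    Averages each class's per-generation mean over the final
    `tail_fraction` of recorded generations and over runs. With
    ``statistic="accepted"`` (default) the per-generation mean is over the
    rewards of interactions actually accepted that generation — the
    quantity the reward trajectories report; rejection censors low offers,
    so this sits slightly above the ``"genotypic"`` population-mean trait,
    which is also available. Generations without any accepted interaction
    of a class are skipped (NaN-aware).

    Returns a Series indexed ``mean_reward_<class>_<class>`` regardless of
    statistic.
    """
    prefix = {"accepted": "txn_mean_reward",
              "genotypic": "mean_reward"}[statistic]
    labels = [dyad_label(i, j) for i in (0, 1) for j in (0, 1)]
    per_run = []
    for run in runs:
        df = run.summaries
        cutoff = (1.0 - tail_fraction) * run.params.generations
        tail = df[df.generation >= cutoff]
        per_run.append(pd.Series(
            {f"mean_reward_{lbl}": np.nanmean(tail[f"{prefix}_{lbl}"])
             for lbl in labels}))
    return pd.concat(per_run, axis=1).mean(axis=1)


def run_set2_desk(seed: int,
                  replicates: int = SET2_REPLICATES) -> list[RunResult]:
    """The desk-scale continuum-of-productivities experiment."""
    params = set2_desk_params(seed)
    return [run_experiment(params, replicate=rep, record_every=50)
            for rep in range(replicates)]


def mean_terminal_mar(runs: list[RunResult], own: float,
                      other: float) -> float:
    """Mean MAR-network output at (own, other) over every final-generation
    individual of every run."""
    outs = []
    for run in runs:
        st = run.final_state
        p = run.params
        outs.append(forward_population(st.mar_weights, [own], [other],
                                       p.hidden_units, p.use_bias).ravel())
    return float(np.concatenate(outs).mean())
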