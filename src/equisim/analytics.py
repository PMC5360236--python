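"""Equilibrium predictions and summary statistics.

The analytic benchmark: when the partner market is perfectly fluid
(beta/tau -> infinity), rejecting a partner costs nothing, competition to
be chosen drives the division to compensate each party's opportunity
cost, and the evolutionarily stable reward to the decision maker equals
its relative contribution p_dm / (p_dm + p_partner). That is Aristotle's
proportionality rule O_A/I_A = O_B/I_B: at this division both parties'
output-to-input ratios are equal.

Summaries condense a population state into the tables behind the reward
trajectories, terminal reward distributions, and (continuum mode) the
reaction-norm surfaces and gain-versus-productivity scatter.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .dynamics import GenerationStats
from .networks import forward_population
from .params import TWO_PRODUCTIVITIES, Params
from .population import CLASS_NAMES, PopulationState

#: dyad classes in canonical order: (giver/own class, decision-maker class)
DYAD_CLASSES = tuple((i, j) for i in (0, 1) for j in (0, 1))


def dyad_label(i: int, j: int) -> str:
    return f"{CLASS_NAMES[i]}_{CLASS_NAMES[j]}"


def equilibrium_reward(p_decision_maker: float, p_partner: float) -> float:
    """Analytic equilibrium reward to the decision maker.

    Equals the decision maker's relative contribution
    p_dm / (p_dm + p_partner); valid in the fluid-market limit. Shares of
    the two roles are complementary: f(p, q) + f(q, p) = 1.
    """
    if p_decision_maker <= 0 or p_partner <= 0:
        raise ValueError(
            f"productivities must be positive (got {p_decision_maker}, "
            f"{p_partner})")
    return p_decision_maker / (p_decision_maker + p_partner)


@dataclass
class GenerationSummary:
    """Per-generation population summary.

    Two-productivity mode: genotypic population means of each reward and
    MAR trait by dyad class (every individual carries all eight traits, so
    the mean is over the whole population), plus, when generation stats are
    supplied, transaction-weighted means of the rewards actually accepted.
    Continuum mode: population-mean network outputs at the four corner
    input pairs of [a,b]^2, standing in for the four dyad classes.
    """

    generation: int
    mean_fitness: float
    mean_reward: Optional[dict[str, float]] = None
    mean_mar: Optional[dict[str, float]] = None
    transaction_mean_reward: Optional[dict[str, float]] = None
    stats: Optional[GenerationStats] = None

    def to_row(self) -> dict:
        row: dict = {"generation": self.generation,
                     "mean_fitness": self.mean_fitness}
        for key, vals in (("mean_reward", self.mean_reward),
                          ("mean_mar", self.mean_mar),
                          ("txn_mean_reward", self.transaction_mean_reward)):
            if vals is not None:
                for lbl, v in vals.items():
                    row[f"{key}_{lbl}"] = v
        if self.stats is not None:
            s = self.stats
            row.update(encounters_proposed=s.encounters_proposed,
                       encounters_accepted=s.encounters_accepted,
                       splits=s.splits,
                       paired_individual_time=s.paired_individual_time)
        return row


def summarize_generation(state: PopulationState, params: Params,
                         stats: Optional[GenerationStats] = None
                         ) -> GenerationSummary:
    """Condense a generation-boundary state into a GenerationSummary."""
    mean_fitness = float(state.accumulated.mean())
    if params.mode == TWO_PRODUCTIVITIES:
        mr = {dyad_label(i, j): float(state.rewards[:, i, j].mean())
              for i, j in DYAD_CLASSES}
        mm = {dyad_label(i, j): float(state.mars[:, i, j].mean())
              for i, j in DYAD_CLASSES}
        txn = None
        if stats is not None:
            txn = {}
            for i, j in DYAD_CLASSES:
                c = stats.reward_count[i, j]
                txn[dyad_label(i, j)] = (float(stats.reward_sum[i, j] / c)
                                         if c else np.nan)
        return GenerationSummary(state.generation, mean_fitness,
                                 mean_reward=mr, mean_mar=mm,
                                 transaction_mean_reward=txn, stats=stats)
    # continuum mode: corner means of the two networks
    a, b = params.a, params.b
    corners = [(a, a), (a, b), (b, a), (b, b)]
    labels = ["lo_lo", "lo_hi", "hi_lo", "hi_hi"]
    own = np.array([c[0] for c in corners])
    oth = np.array([c[1] for c in corners])
    h, ub = params.hidden_units, params.use_bias
    mr_vals = forward_population(state.reward_weights, own, oth, h, ub).mean(0)
    mm_vals = forward_population(state.mar_weights, own, oth, h, ub).mean(0)
    return GenerationSummary(
        state.generation, mean_fitness,
        mean_reward=dict(zip(labels, mr_vals.tolist())),
        mean_mar=dict(zip(labels, mm_vals.tolist())),
        stats=stats)


def mean_policy_surface(state: PopulationState, params: Params,
                        which: str = "mar",
                        grid_size: int = 21) -> pd.DataFrame:
    """Population-mean network output over a productivity grid.

    Evaluates every individual's reward or MAR network on a
    grid_size x grid_size grid of (own, other) productivities covering
    [a, b]^2 and averages over the population — the evolved reaction-norm
    surface. Returns tidy rows (own, other, mean_output).
    """
    if params.mode == TWO_PRODUCTIVITIES:
        raise RuntimeError("policy surfaces require mode='continuum'")
    weights = state.mar_weights if which == "mar" else state.reward_weights
    axis = np.linspace(params.a, params.b, grid_size)
    own, oth = np.meshgrid(axis, axis, indexing="ij")
    out = forward_population(weights, own.ravel(), oth.ravel(),
                             params.hidden_units, params.use_bias)
    return pd.DataFrame({"own": own.ravel(), "other": oth.ravel(),
                         "mean_output": out.mean(axis=0)})


def gain_rate_table(state: PopulationState, params: Params) -> pd.DataFrame:
    """Per-individual (productivity, lifetime gain rate) pairs.

    Gain rate is accumulated resources divided by lifespan L. At the fluid-
    market equilibrium each individual's gain rate matches its productivity
    (slope 1), because equitable divisions return exactly what each party
    contributes.
    """
    return pd.DataFrame({
        "productivity": state.productivity,
        "gain_rate": state.accumulated / params.L,
    })


def terminal_reward_distribution(runs: Sequence, dyad: tuple[int, int] = (0, 1),
                                 bins: int = 20) -> pd.DataFrame:
    """Histogram of individual terminal reward traits, per run.

    `runs` are completed RunResult objects (two-productivity mode); `dyad`
    is (giver class, decision-maker class), defaulting to LP -> HP, the
    class pair whose terminal distribution diagnoses whether equity
    evolved. Returns tidy rows (beta, seed, bin_left, bin_right, count,
    frequency) with a common binning of [0, 1].
    """
    edges = np.linspace(0.0, 1.0, bins + 1)
    i, j = dyad
    frames = []
    for run in runs:
        state = run.final_state
        values = state.rewards[:, i, j]
        counts, _ = np.histogram(values, bins=edges)
        frames.append(pd.DataFrame({
            "beta": run.params.beta,
            "seed": run.seed,
            "bin_left": edges[:-1],
            "bin_right": edges[1:],
            "count": counts,
            "frequency": counts / len(values),
        }))
    return pd.concat(frames, ignore_index=True)
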