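"""Continuous-time social dynamics of one generation.

Only two kinds of event can occur: the encounter of two solitary
individuals, or the split of an established pair. After any event at time
t (or at birth, t = 0) the waiting time to the next event is exponential
with total rate

    lambda(t) = (C(t) * tau / 2) + S_eff(t) * beta

where C(t) is the number of currently cooperating individuals (so C/2
pairs, each splitting at rate tau) and S_eff(t) the number of solitary
individuals, zeroed when fewer than two are available since a lone
individual cannot encounter anyone. The event is an encounter with
probability S_eff * beta / lambda, else a split.

An encounter draws two distinct solitary individuals uniformly; a fair
coin designates one the "partner" (who unilaterally sets the division
through its reward policy) and the other the "decision maker" (who
accepts iff the offered reward is at least its own minimum acceptable
reward, ties accepting). While paired, the dyad produces the sum of the
two productivities per unit time; production is settled lazily when the
pair dissolves — at a split event, or at the end of life L for pairs
still together then. An event whose waiting time would carry past L is
not executed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .networks import forward_from_flat
from .params import TWO_PRODUCTIVITIES, Params
from .population import ROLE_DECISION_MAKER, Individual, PopulationState

ENCOUNTER = "encounter"
SPLIT = "split"


class AbsorbedError(RuntimeError):
    """No further event is possible (total event rate is zero)."""


@dataclass
class EventDraw:
    dt: float
    kind: str  # ENCOUNTER or SPLIT


@dataclass
class EventRecord:
    """One row of the optional event log."""

    generation: int
    time: float
    kind: str
    id1: int        # partner (reward setter) for encounters
    id2: int        # decision maker for encounters
    accepted: bool
    reward_fraction: float

    HEADER = "generation\ttime\tkind\tid1\tid2\taccepted\treward_fraction"

    def row(self) -> str:
        return (f"{self.generation}\t{self.time:.10g}\t{self.kind}\t"
                f"{self.id1}\t{self.id2}\t{int(self.accepted)}\t"
                f"{self.reward_fraction:.10g}")


def write_event_log(events: list[EventRecord], path) -> None:
    with open(path, "w") as fh:
        fh.write(EventRecord.HEADER + "\n")
        for ev in events:
            fh.write(ev.row() + "\n")


@dataclass
class GenerationStats:
    """Per-generation audit counters collected by run_generation."""

    encounters_proposed: int = 0
    encounters_accepted: int = 0
    splits: int = 0
    paired_individual_time: float = 0.0   # sum over individuals of paired time
    # accepted-offer tallies by (partner class, decision-maker class);
    # two-productivity mode only
    reward_sum: np.ndarray = field(default_factory=lambda: np.zeros((2, 2)))
    reward_count: np.ndarray = field(
        default_factory=lambda: np.zeros((2, 2), dtype=np.int64))


def _effective_solitary(state: PopulationState) -> int:
    s = state.num_solitary
    return s if s >= 2 else 0


def total_event_rate(state: PopulationState, params: Params) -> float:
    """lambda(t) = (C * tau / 2) + S_eff * beta, in events per unit time."""
    return (state.num_pairs * params.tau
            + _effective_solitary(state) * params.beta)


def encounter_probability(state: PopulationState, params: Params) -> float:
    """Probability that the next event is an encounter rather than a split."""
    lam = total_event_rate(state, params)
    if lam <= 0:
        raise AbsorbedError("total event rate is zero; no event possible")
    return _effective_solitary(state) * params.beta / lam


def draw_event(state: PopulationState, params: Params,
               rng: np.random.Generator) -> Optional[EventDraw]:
    """Draw the waiting time and kind of the next event.

    Returns None when the state is absorbed (rate zero).
    """
    lam = total_event_rate(state, params)
    if lam <= 0:
        return None
    dt = rng.exponential(1.0 / lam)
    p = _effective_solitary(state) * params.beta / lam
    kind = ENCOUNTER if rng.random() < p else SPLIT
    return EventDraw(dt=dt, kind=kind)


def _policy_values(state: PopulationState, params: Params,
                   partner: int, dm: int) -> tuple[float, float]:
    """(reward offered by `partner`, MAR demanded by `dm`), by array id."""
    if params.mode == TWO_PRODUCTIVITIES:
        cls = state.cls
        reward = state.rewards[partner, cls[partner], cls[dm]]
        mar = state.mars[dm, cls[dm], cls[partner]]
        return float(reward), float(mar)
    h, ub = params.hidden_units, params.use_bias
    reward = forward_from_flat(state.reward_weights[partner],
                               state.productivity[partner],
                               state.productivity[dm], h, ub)
    mar = forward_from_flat(state.mar_weights[dm],
                            state.productivity[dm],
                            state.productivity[partner], h, ub)
    return reward, mar


def attempt_pairing(decision_maker: Individual, partner: Individual,
                    params: Optional[Params] = None) -> tuple[bool, float]:
    """Pure acceptance predicate for a proposed pairing.

    The partner's reward policy is read at (partner's own productivity,
    decision maker's productivity); the decision maker's MAR policy at
    (own, partner's). Returns (accepted, reward): accepted iff
    reward >= MAR — a tie accepts, so the all-zero initial population
    cooperates unconditionally. No state is changed. `params` is only
    needed for network genotypes (hidden_units / use_bias layout).
    """
    g_p, g_d = partner.genotype, decision_maker.genotype
    if g_p.rewards is not None:
        i, j = partner.productivity_class, decision_maker.productivity_class
        reward = float(g_p.rewards[i, j])
        mar = float(g_d.mars[j, i])
    else:
        if params is not None:
            hidden, use_bias = params.hidden_units, params.use_bias
        else:
            # bias-free layout has 3h weights
            hidden, use_bias = g_p.reward_weights.shape[0] // 3, False
        reward = forward_from_flat(g_p.reward_weights, partner.productivity,
                                   decision_maker.productivity, hidden,
                                   use_bias)
        mar = forward_from_flat(g_d.mar_weights, decision_maker.productivity,
                                partner.productivity, hidden, use_bias)
    return reward >= mar, reward


def resolve_encounter(state: PopulationState, params: Params,
                      rng: np.random.Generator,
                      stats: Optional[GenerationStats] = None,
                      log: Optional[list] = None) -> bool:
    """Execute one encounter event at the current state time.

    Two distinct solitary individuals are drawn uniformly without
    replacement; a fair coin designates the partner (offer maker) and the
    decision maker. On acceptance both become paired from state.time; on
    rejection both stay solitary and receive nothing. Returns acceptance.
    """
    s = state.num_solitary
    if s < 2:
        raise RuntimeError("encounter proposed with fewer than 2 solitary")
    pos_a = int(rng.integers(s))
    pos_b = int(rng.integers(s - 1))
    if pos_b >= pos_a:
        pos_b += 1
    ia, ib = state._solitary[pos_a], state._solitary[pos_b]
    if rng.random() < 0.5:
        partner, dm = ia, ib
    else:
        partner, dm = ib, ia
    reward, mar = _policy_values(state, params, partner, dm)
    accepted = reward >= mar
    if accepted:
        state.form_pair(dm, partner, state.time, reward)
    if stats is not None:
        stats.encounters_proposed += 1
        if accepted:
            stats.encounters_accepted += 1
            if params.mode == TWO_PRODUCTIVITIES:
                stats.reward_sum[state.cls[partner], state.cls[dm]] += reward
                stats.reward_count[state.cls[partner], state.cls[dm]] += 1
    if log is not None:
        log.append(EventRecord(state.generation, state.time, ENCOUNTER,
                               partner, dm, accepted, reward))
    return accepted


def settle_pair(state: PopulationState, member: int, end_time: float,
                stats: Optional[GenerationStats] = None) -> None:
    """Settle and dissolve the pair containing `member` at `end_time`.

    The dyad produced (p1 + p2) resources per unit time since pairing; the
    decision maker receives the fraction r promised at the encounter, the
    partner the complement. Shares are exact: dm + partner = (p1+p2)*duration.
    """
    j = int(state.partner_of[member])
    if j < 0:
        raise RuntimeError(f"individual {member} is not paired")
    start = float(state.pair_start[member])
    if end_time < start:
        raise RuntimeError(
            f"settlement time {end_time} precedes pair start {start}")
    duration = end_time - start
    total = (state.productivity[member] + state.productivity[j]) * duration
    r = float(state.pair_reward[member])
    dm = member if state.role[member] == ROLE_DECISION_MAKER else j
    pt = j if dm == member else member
    state.accumulated[dm] += r * total
    state.accumulated[pt] += (1.0 - r) * total
    if stats is not None:
        stats.paired_individual_time += 2.0 * duration
    state.dissolve_pair(member)


def run_generation(state: PopulationState, params: Params,
                   rng: np.random.Generator,
                   log: Optional[list] = None) -> GenerationStats:
    """Run one generation's social life to time L, in place.

    Repeatedly draws the next event (memoryless redraw after every event),
    executes encounters and splits, and finally settles every pair still
    together at exactly L. An event whose waiting time would carry past L is
    not executed. Returns the generation's audit counters.
    """
    if state.time != 0.0 or state.num_paired:
        raise RuntimeError("run_generation requires a fresh generation")
    L = params.L
    beta, tau = params.beta, params.tau
    two_prod = params.mode == TWO_PRODUCTIVITIES
    stats = GenerationStats()
    solitary = state._solitary
    pairs = state._pairs
    t = 0.0
    exponential = rng.exponential
    random = rng.random
    integers = rng.integers
    while True:
        s = len(solitary)
        s_eff = s if s >= 2 else 0
        lam = len(pairs) * tau + s_eff * beta
        if lam <= 0:
            break
        t_next = t + exponential(1.0 / lam)
        if t_next > L:
            break
        t = t_next
        state.time = t
        if random() < (s_eff * beta) / lam:
            resolve_encounter(state, params, rng, stats, log)
        else:
            k = int(integers(len(pairs)))
            dm = pairs[k]
            pt = int(state.partner_of[dm])
            r = float(state.pair_reward[dm])
            settle_pair(state, dm, t, stats)
            stats.splits += 1
            if log is not None:
                log.append(EventRecord(state.generation, t, SPLIT,
                                       pt, dm, True, r))
    # end of life: settle remaining pairs at exactly L
    while pairs:
        settle_pair(state, pairs[0], L, stats)
    state.time = L
    return stats
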