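"""Domain types and population construction.

The population is stored struct-of-arrays for speed: one NumPy array per
field, indexed by generation-local individual id 0..n-1. `Individual` and
`Genotype` dataclass views are built on demand for inspection and for the
pure per-pair operations; their array fields alias the population storage,
so they are cheap and reflect the live state.

Productivity classes in two-productivity mode are indexed LP=0, HP=1.
Class-indexed traits r_ij / MAR_ij are stored as (n, 2, 2) arrays with axes
(individual, own class i, other's class j).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .params import CONTINUUM, TWO_PRODUCTIVITIES, ConfigurationError, Params

LP, HP = 0, 1
CLASS_NAMES = ("LP", "HP")

SOLITARY = "solitary"
PAIRED = "paired"
ROLE_NONE, ROLE_PARTNER, ROLE_DECISION_MAKER = 0, 1, 2


@dataclass
class Genotype:
    """Heritable division policy of one individual.

    Two-productivity mode: four reward fractions ``rewards[i, j]`` (what an
    individual of class i offers a decision maker of class j) and four
    minimum acceptable rewards ``mars[i, j]`` (the least an individual of
    class i accepts from a partner of class j), all in [0, 1].

    Continuum mode: flat weight vectors of the reward and MAR networks
    (see :mod:`equisim.networks` for the layout), each weight in
    [-weight_bound, +weight_bound].
    """

    rewards: Optional[np.ndarray] = None
    mars: Optional[np.ndarray] = None
    reward_weights: Optional[np.ndarray] = None
    mar_weights: Optional[np.ndarray] = None

    @property
    def mode(self) -> str:
        return TWO_PRODUCTIVITIES if self.rewards is not None else CONTINUUM

    @classmethod
    def scalar(cls, rewards, mars) -> "Genotype":
        return cls(rewards=np.asarray(rewards, float).reshape(2, 2),
                   mars=np.asarray(mars, float).reshape(2, 2))

    @classmethod
    def network(cls, reward_weights, mar_weights) -> "Genotype":
        return cls(reward_weights=np.asarray(reward_weights, float),
                   mar_weights=np.asarray(mar_weights, float))


@dataclass
class Individual:
    """Snapshot view of one individual (arrays alias population storage)."""

    id: int
    productivity: float
    genotype: Genotype
    accumulated: float
    status: str
    pair_partner: Optional[int] = None
    pair_start_time: Optional[float] = None
    pair_reward_to_dm: Optional[float] = None
    pair_role: Optional[str] = None
    productivity_class: Optional[int] = None  # LP/HP, two-productivity mode


class PopulationState:
    """All individuals of the current generation plus pairing bookkeeping.

    Pairing state is kept both as per-individual arrays (partner id, pair
    start time, reward fraction promised to the decision maker, role) and as
    swap-pop index lists of solitary ids and of pair representatives
    (the decision maker's id), so that uniform sampling of a solitary
    individual or of a pair is O(1).
    """

    def __init__(self, params: Params, productivity: np.ndarray,
                 *, rewards=None, mars=None,
                 reward_weights=None, mar_weights=None,
                 generation: int = 0):
        n = len(productivity)
        self.params = params
        self.generation = generation
        self.time = 0.0
        self.productivity = np.asarray(productivity, float)
        if params.mode == TWO_PRODUCTIVITIES:
            self.rewards = np.asarray(rewards, float)
            self.mars = np.asarray(mars, float)
            self.reward_weights = None
            self.mar_weights = None
            self.cls = (self.productivity == params.b).astype(np.int8)
        else:
            self.rewards = None
            self.mars = None
            self.reward_weights = np.asarray(reward_weights, float)
            self.mar_weights = np.asarray(mar_weights, float)
            self.cls = None
        self.accumulated = np.zeros(n)
        self.partner_of = np.full(n, -1, dtype=np.int64)
        self.pair_start = np.full(n, np.nan)
        self.pair_reward = np.full(n, np.nan)
        self.role = np.zeros(n, dtype=np.int8)
        # swap-pop structures
        self._solitary: list[int] = list(range(n))
        self._sol_pos = np.arange(n, dtype=np.int64)
        self._pairs: list[int] = []          # decision-maker id per pair
        self._pair_pos = np.full(n, -1, dtype=np.int64)

    # ---- bookkeeping -----------------------------------------------------

    @property
    def n(self) -> int:
        return len(self.productivity)

    @property
    def num_solitary(self) -> int:
        return len(self._solitary)

    @property
    def num_paired(self) -> int:
        return 2 * len(self._pairs)

    @property
    def num_pairs(self) -> int:
        return len(self._pairs)

    @property
    def solitary_ids(self) -> list[int]:
        return list(self._solitary)

    @property
    def pair_representatives(self) -> list[int]:
        """Decision-maker id of every current pair."""
        return list(self._pairs)

    def is_solitary(self, i: int) -> bool:
        return self.partner_of[i] < 0

    def _remove_solitary(self, i: int) -> None:
        pos = self._sol_pos[i]
        last = self._solitary[-1]
        self._solitary[pos] = last
        self._sol_pos[last] = pos
        self._solitary.pop()
        self._sol_pos[i] = -1

    def _add_solitary(self, i: int) -> None:
        self._sol_pos[i] = len(self._solitary)
        self._solitary.append(i)

    def form_pair(self, decision_maker: int, partner: int,
                  time: float, reward: float) -> None:
        """Record an accepted pairing at `time` with reward fraction
        `reward` promised to the decision maker."""
        for i in (decision_maker, partner):
            if not self.is_solitary(i):
                raise RuntimeError(f"individual {i} is not solitary")
        self._remove_solitary(decision_maker)
        self._remove_solitary(partner)
        self.partner_of[decision_maker] = partner
        self.partner_of[partner] = decision_maker
        self.pair_start[decision_maker] = self.pair_start[partner] = time
        self.pair_reward[decision_maker] = self.pair_reward[partner] = reward
        self.role[decision_maker] = ROLE_DECISION_MAKER
        self.role[partner] = ROLE_PARTNER
        self._pair_pos[decision_maker] = len(self._pairs)
        self._pairs.append(decision_maker)

    def dissolve_pair(self, member: int) -> None:
        """Clear pairing state of `member`'s pair; both become solitary.

        Resource settlement is the caller's job (see dynamics.settle_pair).
        """
        j = int(self.partner_of[member])
        if j < 0:
            raise RuntimeError(f"individual {member} is not paired")
        dm = member if self.role[member] == ROLE_DECISION_MAKER else j
        pos = self._pair_pos[dm]
        last = self._pairs[-1]
        self._pairs[pos] = last
        self._pair_pos[last] = pos
        self._pairs.pop()
        self._pair_pos[dm] = -1
        for i in (member, j):
            self.partner_of[i] = -1
            self.pair_start[i] = np.nan
            self.pair_reward[i] = np.nan
            self.role[i] = ROLE_NONE
            self._add_solitary(i)

    # ---- views -----------------------------------------------------------

    def genotype(self, i: int) -> Genotype:
        if self.rewards is not None:
            return Genotype(rewards=self.rewards[i], mars=self.mars[i])
        return Genotype(reward_weights=self.reward_weights[i],
                        mar_weights=self.mar_weights[i])

    def individual(self, i: int) -> Individual:
        paired = self.partner_of[i] >= 0
        return Individual(
            id=i,
            productivity=float(self.productivity[i]),
            genotype=self.genotype(i),
            accumulated=float(self.accumulated[i]),
            status=PAIRED if paired else SOLITARY,
            pair_partner=int(self.partner_of[i]) if paired else None,
            pair_start_time=float(self.pair_start[i]) if paired else None,
            pair_reward_to_dm=float(self.pair_reward[i]) if paired else None,
            pair_role=({ROLE_PARTNER: "partner",
                        ROLE_DECISION_MAKER: "decision_maker"}
                       [int(self.role[i])] if paired else None),
            productivity_class=(int(self.cls[i]) if self.cls is not None
                                else None),
        )

    @property
    def individuals(self) -> list[Individual]:
        return [self.individual(i) for i in range(self.n)]

    def check_consistency(self) -> None:
        """Assert the bookkeeping invariants (used by tests)."""
        n = self.n
        assert self.num_solitary + self.num_paired == n
        assert self.num_paired % 2 == 0
        for dm in self._pairs:
            pt = int(self.partner_of[dm])
            assert self.partner_of[pt] == dm
            assert self.role[dm] == ROLE_DECISION_MAKER
            assert self.role[pt] == ROLE_PARTNER
            assert self.pair_start[dm] == self.pair_start[pt]
        for i in self._solitary:
            assert self.partner_of[i] == -1


def assign_productivities(params: Params, count: int,
                          rng: np.random.Generator) -> np.ndarray:
    """Draw `count` i.i.d. productivities for newborns.

    Two-productivity mode: each newborn is high-productivity (value ``b``)
    with probability ``p_high``, else low-productivity (value ``a``).
    Continuum mode: productivities are uniform on [a, b]. Productivity is
    never inherited; it is redrawn at every birth.
    """
    if count < 1:
        raise ValueError(f"count must be >= 1 (got {count})")
    if params.mode == TWO_PRODUCTIVITIES:
        high = rng.random(count) < params.p_high
        return np.where(high, params.b, params.a)
    return rng.uniform(params.a, params.b, size=count)


def make_initial_population(params: Params,
                            rng: np.random.Generator) -> PopulationState:
    """Build generation 0: all solitary, nothing accumulated.

    Two-productivity mode starts stingy and undemanding (every reward and
    every MAR exactly 0), so any cooperative division must evolve from
    scratch. Continuum mode starts with all synaptic weights drawn uniformly
    on [-weight_bound, +weight_bound].
    """
    params.validate()
    n = params.n
    prod = assign_productivities(params, n, rng)
    if params.mode == TWO_PRODUCTIVITIES:
        return PopulationState(params, prod,
                               rewards=np.zeros((n, 2, 2)),
                               mars=np.zeros((n, 2, 2)))
    k = params.weights_per_network
    wb = params.weight_bound
    return PopulationState(
        params, prod,
        reward_weights=rng.uniform(-wb, wb, size=(n, k)),
        mar_weights=rng.uniform(-wb, wb, size=(n, k)))


def make_fixture_population(spec: Sequence[dict],
                            params: Params) -> PopulationState:
    """Hand-build a population from explicit genotypes and productivities.

    Each entry of `spec` is a dict with key ``productivity`` plus either
    ``rewards`` and ``mars`` (anything reshapeable to (2, 2), or a scalar
    broadcast to all four dyad classes) or ``reward_weights`` and
    ``mar_weights``. Intended for deterministic unit-test populations that
    bypass random initialization.
    """
    if len(spec) < 2:
        raise ConfigurationError(
            f"fixture population needs >= 2 individuals (got {len(spec)})")
    prod = []
    for k, entry in enumerate(spec):
        if "productivity" not in entry:
            raise ConfigurationError(f"individual {k}: missing productivity")
        prod.append(float(entry["productivity"]))
    prod = np.array(prod)
    n = len(spec)
    if params.mode == TWO_PRODUCTIVITIES:
        rewards = np.zeros((n, 2, 2))
        mars = np.zeros((n, 2, 2))
        for k, entry in enumerate(spec):
            try:
                rewards[k] = np.broadcast_to(
                    np.asarray(entry["rewards"], float), (2, 2))
                mars[k] = np.broadcast_to(
                    np.asarray(entry["mars"], float), (2, 2))
            except KeyError as exc:
                raise ConfigurationError(
                    f"individual {k}: missing {exc.args[0]}") from None
        return PopulationState(params, prod, rewards=rewards, mars=mars)
    kw = params.weights_per_network
    rw = np.zeros((n, kw))
    mw = np.zeros((n, kw))
    for k, entry in enumerate(spec):
        try:
            rw[k] = np.asarray(entry["reward_weights"], float)
            mw[k] = np.asarray(entry["mar_weights"], float)
        except KeyError as exc:
            raise ConfigurationError(
                f"individual {k}: missing {exc.args[0]}") from None
    return PopulationState(params, prod, reward_weights=rw, mar_weights=mw)
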