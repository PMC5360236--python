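"""Run parameterization.

All symbols of the model live here: the demographic and market-fluidity
parameters of the two-productivity simulations (set 1), plus the extensions
needed for the continuum-of-productivities simulations (set 2), in which the
heritable division policy is a pair of small feedforward networks.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path

import yaml

TWO_PRODUCTIVITIES = "two_productivities"
CONTINUUM = "continuum"

_MODES = (TWO_PRODUCTIVITIES, CONTINUUM)


class ConfigurationError(ValueError):
    """Raised when a parameter set violates a model constraint."""


@dataclass
class Params:
    """Parameters of the partner-choice market model.

    Defaults reproduce the reference two-productivity setup: a population of
    ``n`` individuals living for ``L`` time units per generation, in which
    solitary individuals encounter each other at rate ``beta`` (per solitary
    individual) and established pairs dissolve at rate ``tau`` (per pair).
    The ratio ``beta/tau`` sets the fluidity of the partner market and hence
    the implicit cost of being choosy.

    Attributes
    ----------
    n : population size (constant across generations).
    a, b : low / high productivity, in resources per unit time. In
        ``two_productivities`` mode every individual produces ``a`` or ``b``;
        in ``continuum`` mode productivities are uniform on ``[a, b]``.
    beta : encounter rate per solitary individual (events per unit time).
    tau : split rate per established pair (events per unit time).
    L : lifespan of a generation, in time units.
    m : per-trait (or per-weight) mutation probability at reproduction.
    d : mutation kernel standard deviation for the scalar reward/MAR traits.
    f : fecundity multiplication factor; an individual with resources ``z``
        leaves ``round(f * z / z_bar)`` offspring.
    generations : number of non-overlapping (Wright-Fisher) generations.
    mode : ``"two_productivities"`` (eight scalar traits) or ``"continuum"``
        (two evolvable 2-``hidden_units``-1 networks per individual).
    seed : seed of the single RNG stream driving a run.
    p_high : probability that a newborn is high-productivity (set 1 only).
    weight_bound : half-width of the admissible synaptic-weight interval.
    weight_mut_sd : mutation kernel standard deviation for network weights.
    hidden_units : hidden-layer width of the policy networks.
    use_bias : whether the networks carry evolvable bias terms.
    """

    n: int = 500
    a: float = 1.0
    b: float = 2.0
    beta: float = 1.0
    tau: float = 0.01
    L: float = 500.0
    m: float = 0.002
    d: float = 0.02
    f: float = 2.0
    generations: int = 8000
    mode: str = TWO_PRODUCTIVITIES
    seed: int = 0
    p_high: float = 0.5
    weight_bound: float = 5.0
    weight_mut_sd: float = 0.2
    hidden_units: int = 5
    use_bias: bool = False

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        """Check every model invariant; raise ConfigurationError naming the
        violated bound."""
        checks = [
            (self.n >= 2, f"require n >= 2 (got n={self.n})"),
            (0 < self.a <= self.b,
             f"require 0 < a <= b (got a={self.a}, b={self.b})"),
            (self.beta > 0, f"require beta > 0 (got beta={self.beta})"),
            (self.tau > 0, f"require tau > 0 (got tau={self.tau})"),
            (self.L > 0, f"require L > 0 (got L={self.L})"),
            (0 <= self.m <= 1, f"require 0 <= m <= 1 (got m={self.m})"),
            (self.d >= 0, f"require d >= 0 (got d={self.d})"),
            (self.f >= 1, f"require f >= 1 (got f={self.f})"),
            (self.generations >= 1,
             f"require generations >= 1 (got {self.generations})"),
            (self.mode in _MODES,
             f"require mode in {_MODES} (got {self.mode!r})"),
            (0 <= self.p_high <= 1,
             f"require 0 <= p_high <= 1 (got p_high={self.p_high})"),
            (self.weight_bound > 0,
             f"require weight_bound > 0 (got {self.weight_bound})"),
            (self.weight_mut_sd >= 0,
             f"require weight_mut_sd >= 0 (got {self.weight_mut_sd})"),
            (self.hidden_units >= 1,
             f"require hidden_units >= 1 (got {self.hidden_units})"),
        ]
        for ok, msg in checks:
            if not ok:
                raise ConfigurationError(msg)

    @property
    def weights_per_network(self) -> int:
        """Number of evolvable parameters in one policy network."""
        k = 2 * self.hidden_units + self.hidden_units
        if self.use_bias:
            k += self.hidden_units + 1
        return k

    def replace(self, **changes) -> "Params":
        """Return a validated copy with the given fields changed."""
        return dataclasses.replace(self, **changes)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


_FIELD_TYPES = {f.name: f.type for f in dataclasses.fields(Params)}


def load_config(path: str | Path) -> Params:
    """Load a flat key/value configuration file (YAML mapping).

    Keys mirror :class:`Params` field names exactly; any unknown key is a
    configuration error.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ConfigurationError(
            f"config file {path} must be a flat key/value mapping")
    unknown = sorted(set(raw) - set(_FIELD_TYPES))
    if unknown:
        raise ConfigurationError(f"unknown config keys: {', '.join(unknown)}")
    return Params(**raw)


def dump_config(params: Params, path: str | Path) -> None:
    """Write a Params as a flat key/value YAML file (load_config inverse)."""
    with open(path, "w") as fh:
        yaml.safe_dump(params.to_dict(), fh, sort_keys=False)
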