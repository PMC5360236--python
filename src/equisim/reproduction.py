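"""Wright-Fisher generation turnover.

At the end of life L every individual reproduces and dies. An individual
with accumulated resources z leaves round(f * z / z_bar) offspring in a
common pool (round = half away from zero); each offspring inherits its
parent's genotype with independent per-trait mutation; the n survivors
are drawn uniformly with replacement from the pool (standard
Wright-Fisher multinomial resampling, with the pool's composition as the
sampling weights), which also covers pools smaller than n. Productivity
is redrawn at birth, never inherited.

Degenerate case, chosen once and documented: z_bar = 0 (nobody
cooperated) gives every individual round(f) offspring — a pure-drift,
selection-neutral generation.
"""

from __future__ import annotations

import math

import numpy as np

from .params import TWO_PRODUCTIVITIES, Params
from .population import Genotype, PopulationState, assign_productivities


def _round_half_away(x: float) -> int:
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def offspring_count(z: float, z_bar: float, f: float) -> int:
    """Number of offspring for one individual: round(f * z / z_bar).

    Rounding is half away from zero (0.5 -> 1). With z_bar = 0 every
    individual gets round(f) — the selection-neutral fallback.
    """
    if z < 0 or z_bar < 0:
        raise ValueError(f"negative resources (z={z}, z_bar={z_bar})")
    if z_bar == 0:
        return _round_half_away(f)
    return _round_half_away(f * z / z_bar)


def offspring_counts(z: np.ndarray, f: float) -> np.ndarray:
    """Vectorized offspring_count for a whole population."""
    z = np.asarray(z, float)
    if np.any(z < 0):
        raise ValueError("negative accumulated resources")
    z_bar = z.mean()
    if z_bar == 0:
        return np.full(len(z), _round_half_away(f), dtype=np.int64)
    return np.floor(f * z / z_bar + 0.5).astype(np.int64)


def mutate_genotype(g: Genotype, params: Params,
                    rng: np.random.Generator) -> Genotype:
    """Return a mutated copy of one genotype.

    Each trait (scalar mode) or weight (network mode) independently mutates
    with probability m; a mutated value is redrawn from a normal centered on
    the old value (sd d for traits, weight_mut_sd for weights) and clipped
    to its admissible interval ([0,1] or [-weight_bound, +weight_bound]).
    """
    if g.rewards is not None:
        traits = np.stack([g.rewards, g.mars]).copy()
        mask = rng.random(traits.shape) < params.m
        if mask.any():
            traits[mask] = np.clip(
                traits[mask] + rng.normal(0.0, params.d, mask.sum()), 0.0, 1.0)
        return Genotype(rewards=traits[0], mars=traits[1])
    w = np.stack([g.reward_weights, g.mar_weights]).copy()
    mask = rng.random(w.shape) < params.m
    if mask.any():
        wb = params.weight_bound
        w[mask] = np.clip(
            w[mask] + rng.normal(0.0, params.weight_mut_sd, mask.sum()),
            -wb, wb)
    return Genotype(reward_weights=w[0], mar_weights=w[1])


def _mutate_array(values: np.ndarray, m: float, sd: float, lo: float,
                  hi: float, rng: np.random.Generator) -> None:
    """In-place i.i.d. per-entry mutation with clipping (bulk path)."""
    if m == 0:
        return
    mask = rng.random(values.shape) < m
    k = int(mask.sum())
    if k:
        values[mask] = np.clip(values[mask] + rng.normal(0.0, sd, k), lo, hi)


def next_generation(state: PopulationState, params: Params,
                    rng: np.random.Generator) -> PopulationState:
    """Build the next generation from a completed one.

    Each parent contributes offspring_count(z, z_bar, f) genotype copies to
    the pool; the n survivors are drawn uniformly with replacement from the
    pool (Wright-Fisher multinomial resampling), each sampled offspring
    mutates independently, productivities are redrawn, and all social
    bookkeeping is reset.
    """
    if state.num_paired:
        raise RuntimeError("next_generation requires all pairs settled")
    n = state.n
    counts = offspring_counts(state.accumulated, params.f)
    pool_parents = np.repeat(np.arange(n), counts)
    if len(pool_parents) == 0:
        raise RuntimeError("empty offspring pool")
    parents = pool_parents[rng.integers(0, len(pool_parents), size=n)]
    prod = assign_productivities(params, n, rng)
    if params.mode == TWO_PRODUCTIVITIES:
        rewards = state.rewards[parents].copy()
        mars = state.mars[parents].copy()
        _mutate_array(rewards, params.m, params.d, 0.0, 1.0, rng)
        _mutate_array(mars, params.m, params.d, 0.0, 1.0, rng)
        new = PopulationState(params, prod, rewards=rewards, mars=mars,
                              generation=state.generation + 1)
    else:
        rw = state.reward_weights[parents].copy()
        mw = state.mar_weights[parents].copy()
        wb = params.weight_bound
        _mutate_array(rw, params.m, params.weight_mut_sd, -wb, wb, rng)
        _mutate_array(mw, params.m, params.weight_mut_sd, -wb, wb, rng)
        new = PopulationState(params, prod, reward_weights=rw,
                              mar_weights=mw,
                              generation=state.generation + 1)
    return new
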