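"""Evolvable feedforward policy networks (continuum-of-productivities mode).

Each individual carries two small networks with identical 2-H-1 topology
(H = ``hidden_units``, default 5): one maps (own productivity, other's
productivity) to the reward fraction offered when playing partner, the
other maps the same inputs to the minimum acceptable reward demanded when
playing decision maker. Every non-input neuron applies the logistic
sigmoid 1/(1+exp(-x)) to the weighted sum of its inputs; the two input
neurons pass the raw productivities through untransformed. Outputs
therefore lie strictly in (0, 1) for any admissible weights, so rewards
and MARs can never leave the valid fraction range.

Flat weight-vector layout (the genotype and dump-file order):
  [input->hidden, row-major over (input neuron, hidden neuron): 2*H values]
  [hidden->output: H values]
  [hidden biases: H values, only if use_bias]
  [output bias: 1 value, only if use_bias]
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .params import CONTINUUM, Params
from .population import Individual


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-x))


@dataclass
class NetworkWeights:
    """Structured view of one policy network's parameters."""

    input_to_hidden: np.ndarray          # shape (2, H)
    hidden_to_output: np.ndarray         # shape (H,)
    hidden_bias: Optional[np.ndarray] = None   # shape (H,)
    output_bias: Optional[float] = None

    @classmethod
    def from_vector(cls, w: np.ndarray, hidden_units: int = 5,
                    use_bias: bool = False) -> "NetworkWeights":
        w = np.asarray(w, float)
        h = hidden_units
        expected = 3 * h + (h + 1 if use_bias else 0)
        if w.shape != (expected,):
            raise ValueError(
                f"weight vector has shape {w.shape}, expected ({expected},)")
        w_in = w[: 2 * h].reshape(2, h)
        w_out = w[2 * h: 3 * h]
        if use_bias:
            return cls(w_in, w_out, hidden_bias=w[3 * h: 4 * h],
                       output_bias=float(w[4 * h]))
        return cls(w_in, w_out)

    def to_vector(self) -> np.ndarray:
        parts = [self.input_to_hidden.ravel(), self.hidden_to_output]
        if self.hidden_bias is not None:
            parts += [self.hidden_bias, np.array([self.output_bias])]
        return np.concatenate(parts)


def network_forward(w: NetworkWeights, own_productivity: float,
                    other_productivity: float) -> float:
    """Single forward pass: (own, other) productivities -> fraction in (0,1)."""
    x = np.array([own_productivity, other_productivity])
    pre_h = x @ w.input_to_hidden
    if w.hidden_bias is not None:
        pre_h = pre_h + w.hidden_bias
    hidden = _sigmoid(pre_h)
    pre_o = hidden @ w.hidden_to_output
    if w.output_bias is not None:
        pre_o = pre_o + w.output_bias
    return float(_sigmoid(pre_o))


def forward_from_flat(w: np.ndarray, own: float, other: float,
                      hidden_units: int, use_bias: bool) -> float:
    """Forward pass straight from the flat genotype vector (hot path)."""
    h = hidden_units
    pre = own * w[:h] + other * w[h:2 * h]
    if use_bias:
        pre = pre + w[3 * h:4 * h]
        out = _sigmoid(pre) @ w[2 * h:3 * h] + w[4 * h]
    else:
        out = _sigmoid(pre) @ w[2 * h:3 * h]
    return float(_sigmoid(out))


def forward_population(weights: np.ndarray, own: np.ndarray,
                       other: np.ndarray, hidden_units: int,
                       use_bias: bool) -> np.ndarray:
    """Vectorized forward pass.

    Parameters
    ----------
    weights : (n, k) flat weight matrix, one network per row.
    own, other : input arrays, broadcast together to shape (g,).

    Returns
    -------
    (n, g) array of outputs: row i is network i evaluated at every input
    pair. Used for summary surfaces and terminal statistics.
    """
    h = hidden_units
    own = np.atleast_1d(np.asarray(own, float))
    other = np.atleast_1d(np.asarray(other, float))
    own, other = np.broadcast_arrays(own, other)
    w_own = weights[:, :h]                     # (n, h)
    w_oth = weights[:, h:2 * h]
    w_out = weights[:, 2 * h:3 * h]
    pre = (own[None, :, None] * w_own[:, None, :]
           + other[None, :, None] * w_oth[:, None, :])   # (n, g, h)
    if use_bias:
        pre = pre + weights[:, 3 * h:4 * h][:, None, :]
    hid = _sigmoid(pre)
    out = np.einsum("ngh,nh->ng", hid, w_out)
    if use_bias:
        out = out + weights[:, 4 * h][:, None]
    return _sigmoid(out)


def evaluate_policies(ind: Individual, other: Individual,
                      params: Params) -> tuple[float, float]:
    """Evaluate `ind`'s two networks against `other`.

    Returns ``(reward, mar)``: the reward `ind` would offer if playing
    partner to `other` as decision maker, and the MAR `ind` would demand if
    playing decision maker facing `other` as partner. Both networks take the
    inputs in the fixed order (own productivity, other's productivity).
    """
    if params.mode != CONTINUUM:
        raise RuntimeError("evaluate_policies requires mode='continuum'")
    g = ind.genotype
    reward = forward_from_flat(g.reward_weights, ind.productivity,
                               other.productivity, params.hidden_units,
                               params.use_bias)
    mar = forward_from_flat(g.mar_weights, ind.productivity,
                            other.productivity, params.hidden_units,
                            params.use_bias)
    return reward, mar
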