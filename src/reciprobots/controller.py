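"""Feed-forward neural controller mapping sensor activations to wheel speeds.

The controller is a three-layer logistic network.  The input layer holds a
constant bias of 1 plus 17 sensory neurons (8 proximity + 9 camera), or 18
with the optional memory input appended.  The hidden layer has 9 logistic
units, the output layer 2 logistic units whose activations are scaled
linearly onto wheel velocities in [-8.2, 8.2] cm/s.

Weight layout (the order in which a decoded genotype fills the network):

1. input-to-hidden block, row-major over hidden units: for each hidden unit
   ``h``, 18 weights for [bias, 17 sensors];
2. if the memory input exists, 9 further weights (memory-to-hidden, one per
   hidden unit), appended after the base block so that a 182-weight
   genotype is a prefix of a 191-weight one;
3. hidden-to-output block: for each output ``o``, 9 hidden weights followed
   by one bias weight.

This gives 18*9 + 10*2 = 182 weights without memory and 191 with it.  The
hidden-to-output bias is required for the count 182 to be consistent with
the stated layer sizes (18*9 + 9*2 = 180 would fall short).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "TopologyError",
    "NetworkTopology",
    "Network",
    "MemoryState",
    "build_network",
    "activate",
    "memory_activation",
    "WHEEL_VMAX_CM_S",
]

WHEEL_VMAX_CM_S = 8.2

N_PROXIMITY = 8
N_CAMERA = 9


class TopologyError(ValueError):
    """Weight count inconsistent with the network topology."""


@dataclass(frozen=True)
class NetworkTopology:
    """Layer sizes of the controller network."""

    has_memory: bool = False
    n_hidden: int = 9
    n_outputs: int = 2

    @property
    def n_sensor_inputs(self) -> int:
        return N_PROXIMITY + N_CAMERA + (1 if self.has_memory else 0)

    @property
    def n_weights(self) -> int:
        return (1 + self.n_sensor_inputs) * self.n_hidden + (
            self.n_hidden + 1
        ) * self.n_outputs


@dataclass(frozen=True)
class Network:
    """Weight matrices of a built controller.

    ``w_in`` has shape (n_hidden, 1 + n_sensor_inputs) with the bias in
    column 0; ``w_out`` has shape (n_outputs, n_hidden + 1) with the bias in
    the last column.
    """

    w_in: np.ndarray
    w_out: np.ndarray
    topology: NetworkTopology


def build_network(weights: np.ndarray, topology: NetworkTopology) -> Network:
    """Assemble weight matrices from a flat decoded weight vector."""
    weights = np.asarray(weights, dtype=np.float64)
    if weights.ndim != 1 or weights.size != topology.n_weights:
        raise TopologyError(
            f"topology expects {topology.n_weights} weights, got {weights.size}"
        )
    nh, no = topology.n_hidden, topology.n_outputs
    base_cols = 1 + N_PROXIMITY + N_CAMERA  # bias + 17 sensors
    n_base = base_cols * nh
    w_in = np.empty((nh, 1 + topology.n_sensor_inputs))
    w_in[:, :base_cols] = weights[:n_base].reshape(nh, base_cols)
    offset = n_base
    if topology.has_memory:
        w_in[:, base_cols] = weights[offset : offset + nh]
        offset += nh
    w_out = weights[offset:].reshape(no, nh + 1)
    return Network(w_in=w_in, w_out=w_out, topology=topology)


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def activate(network: Network, sensor_values: np.ndarray) -> np.ndarray:
    """Forward pass: sensor activations in [0, 1] to wheel velocities in cm/s.

    Pure and deterministic; identical inputs give bit-identical outputs.
    """
    s = np.asarray(sensor_values, dtype=np.float64)
    if s.shape != (network.topology.n_sensor_inputs,):
        raise ValueError(
            f"expected {network.topology.n_sensor_inputs} sensor values, "
            f"got shape {s.shape}"
        )
    if s.size and (s.min() < 0.0 or s.max() > 1.0):
        raise ValueError("sensor activations must lie in [0, 1]")
    x = np.concatenate(([1.0], s))
    hidden = _sigmoid(network.w_in @ x)
    out = _sigmoid(network.w_out @ np.concatenate((hidden, [1.0])))
    return -WHEEL_VMAX_CM_S + 2.0 * WHEEL_VMAX_CM_S * out


@dataclass(frozen=True)
class MemoryState:
    """Counters behind the memory input.

    ``opportunities`` counts completed stuck episodes (chances to receive
    help); ``helps`` counts those that ended through the partner's help.
    """

    opportunities: int = 0
    helps: int = 0

    def __post_init__(self) -> None:
        if self.opportunities < 0 or not 0 <= self.helps <= self.opportunities:
            raise ValueError(
                f"invalid memory state: helps={self.helps}, "
                f"opportunities={self.opportunities}"
            )


def memory_activation(state: MemoryState) -> float:
    """Activation of the memory input: fraction of past episodes that were
    helped, starting at the maximum value 1 before any episode completes."""
    if state.opportunities == 0:
        return 1.0
    return state.helps / state.opportunities
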