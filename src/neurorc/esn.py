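"""Discrete-time echo-state reservoir dynamics on a fixed connectome.

State update (row-vector convention, ``W[i, j]`` from i to j)::

    x(t) = f( x(t-1) @ W  +  u(t) @ M * g ),   t = 1..T,  x(0) = x0

where ``M`` is the C x n input map routing task channels to input nodes and
``g`` an input gain. The recorded trace row ``t`` is the state *after*
consuming input row ``t``; x(0) itself is not recorded.

The activation ``f`` is applied elementwise: linear, tanh, sigmoid, ReLU or
leaky ReLU. Note sigmoid has f(0) = 0.5, so its zero-input equilibrium is
nonzero; the zero fixed point holds only for activations with f(0) = 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .errors import DivergenceError, ParameterError, ShapeError, ValidationError

_BOUNDED = {"tanh", "sigmoid"}


def _leaky_relu(slope: float) -> Callable[[np.ndarray], np.ndarray]:
    return lambda z: np.where(z > 0, z, slope * z)


def get_activation(name: str, leaky_slope: float = 0.01) -> Callable[[np.ndarray], np.ndarray]:
    if name == "linear":
        return lambda z: z
    if name == "tanh":
        return np.tanh
    if name == "sigmoid":
        return lambda z: 1.0 / (1.0 + np.exp(-z))
    if name == "relu":
        return lambda z: np.maximum(z, 0.0)
    if name == "leaky_relu":
        if not (0 < leaky_slope < 1):
            raise ParameterError("leaky_relu slope must lie in (0, 1)")
        return _leaky_relu(leaky_slope)
    raise ParameterError(
        f"unknown activation {name!r}; choose from linear, tanh, sigmoid, relu, leaky_relu"
    )


def build_input_map(
    n_channels: int,
    n_nodes: int,
    input_nodes: Sequence[int],
    mode: str = "constant",
    seed: int | None = None,
) -> np.ndarray:
    """C x n input map supported only on ``input_nodes``.

    ``constant`` broadcasts every channel with weight 1 to every input node;
    ``random`` draws weights uniformly from [-1, 1] (seeded).
    """
    input_nodes = np.asarray(input_nodes, dtype=int)
    if input_nodes.size == 0:
        raise ParameterError("need at least one input node")
    if input_nodes.min() < 0 or input_nodes.max() >= n_nodes:
        raise ParameterError("input node index out of range")
    m = np.zeros((n_channels, n_nodes))
    if mode == "constant":
        m[:, input_nodes] = 1.0
    elif mode == "random":
        rng = np.random.default_rng(seed)
        m[:, input_nodes] = rng.uniform(-1.0, 1.0, size=(n_channels, input_nodes.size))
    else:
        raise ParameterError(f"unknown input_map mode {mode!r}")
    return m


@dataclass
class EchoStateReservoir:
    """Fixed recurrent network plus input routing and local nonlinearity.

    ``leak_rate`` is an optional leaky-integration hook,
    ``x(t) = (1 - a) x(t-1) + a f(...)``; the default ``a = 1`` disables it
    (plain state replacement).
    """

    weights: np.ndarray
    input_map: np.ndarray
    activation: str = "tanh"
    leaky_slope: float = 0.01
    input_gain: float = 1.0
    initial_state: np.ndarray | None = None
    leak_rate: float = 1.0
    divergence_threshold: float = 1e6
    input_nodes: Sequence[int] | None = None

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        self.input_map = np.asarray(self.input_map, dtype=float)
        n = self.weights.shape[0]
        if self.weights.ndim != 2 or self.weights.shape[1] != n:
            raise ShapeError("weights must be square")
        if self.input_map.ndim != 2 or self.input_map.shape[1] != n:
            raise ShapeError("input_map must be C x n")
        get_activation(self.activation, self.leaky_slope)  # validate early
        if not (0 < self.leak_rate <= 1):
            raise ParameterError("leak_rate must lie in (0, 1]")
        if self.input_nodes is not None:
            outside = np.ones(n, dtype=bool)
            outside[np.asarray(self.input_nodes, dtype=int)] = False
            if np.any(self.input_map[:, outside] != 0):
                raise ValidationError("input_map has support outside declared input nodes")

    @property
    def n_nodes(self) -> int:
        return self.weights.shape[0]


@dataclass
class ReservoirTrace:
    """T x n matrix of simulated unit states with provenance metadata."""

    states: np.ndarray
    activation: str
    alpha: float | None = None
    seed: int | None = None
    meta: dict = field(default_factory=dict)

    @property
    def n_timesteps(self) -> int:
        return self.states.shape[0]


def simulate_esn(
    r: EchoStateReservoir,
    inputs: np.ndarray,
    alpha: float | None = None,
) -> ReservoirTrace:
    """Run the reservoir over an input sequence and return the full trace.

    Raises :class:`DivergenceError` if any state magnitude exceeds
    ``r.divergence_threshold`` under an unbounded activation (linear/ReLU
    family); bounded activations cannot diverge.
    """
    inputs = np.asarray(inputs, dtype=float)
    if inputs.ndim != 2:
        raise ShapeError("inputs must be T x C")
    if not np.all(np.isfinite(inputs)):
        raise ValidationError("inputs contain non-finite values")
    if inputs.shape[1] != r.input_map.shape[0]:
        raise ShapeError(
            f"inputs have {inputs.shape[1]} channels but input_map expects {r.input_map.shape[0]}"
        )
    f = get_activation(r.activation, r.leaky_slope)
    T = inputs.shape[0]
    n = r.n_nodes
    drive = inputs @ r.input_map * r.input_gain  # T x n
    x = (
        np.zeros(n)
        if r.initial_state is None
        else np.asarray(r.initial_state, dtype=float).copy()
    )
    states = np.empty((T, n))
    check = r.activation not in _BOUNDED
    a = r.leak_rate
    for t in range(T):
        new = f(x @ r.weights + drive[t])
        x = new if a == 1.0 else (1.0 - a) * x + a * new
        if check and np.max(np.abs(x)) > r.divergence_threshold:
            raise DivergenceError(
                f"state magnitude exceeded {r.divergence_threshold:g} at t={t} "
                f"(activation={r.activation}); dynamics are diverging"
            )
        states[t] = x
    return ReservoirTrace(states=states, activation=r.activation, alpha=alpha)


def retrieve_states(
    tr: ReservoirTrace | np.ndarray,
    readout_nodes: Sequence[int],
    mask: np.ndarray | None = None,
) -> np.ndarray:
    """Masked rows x selected node columns of a trace, preserving time order."""
    states = tr.states if isinstance(tr, ReservoirTrace) else np.asarray(tr)
    readout_nodes = np.asarray(readout_nodes, dtype=int)
    if readout_nodes.size == 0:
        raise ParameterError("readout node set is empty")
    if mask is None:
        return states[:, readout_nodes]
    mask = np.asarray(mask, dtype=bool)
    if mask.shape[0] != states.shape[0]:
        raise ShapeError("mask length does not match trace length")
    return states[mask][:, readout_nodes]
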