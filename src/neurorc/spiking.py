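"""Leaky integrate-and-fire reservoir with double-exponential synapses.

Membrane dynamics are integrated with forward Euler::

    tau_m dV_i/dt = -(V_i - v_rest) + I_syn,i + I_ext,i

A neuron fires when V crosses ``v_thresh``, is reset to ``v_reset`` and held
there for the refractory period ``t_ref``. Each presynaptic spike of neuron
j at time ``t_s`` contributes to the postsynaptic current of neuron i the
kernel::

    w[j, i] * (exp(-(t - t_s)/tau_decay) - exp(-(t - t_s)/tau_rise)) / (tau_decay - tau_rise)

implemented exactly (up to the spike-time discretization) with two auxiliary
exponential state variables per neuron. Time constants may be scalars or
per-neuron vectors (heterogeneous synapses). Neurons flagged in
``inhibitory_mask`` have the sign of their *outgoing* weights flipped.

External input channels are injected as currents (amplitude times
``input_current_gain``) into the designated input nodes. To drive the model
with a task dataset whose timestep is coarser than ``dt``, hold each task
step for a fixed number of integration steps (`upsample_inputs`) and sample
the filtered trace back at task-step boundaries (`sample_task_steps`).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .errors import ParameterError, ShapeError, ValidationError
from .connectome import Connectome
from .esn import build_input_map


@dataclass
class LIFParams:
    """Parameters of the leaky integrate-and-fire reservoir.

    Units: milliseconds for all time constants and ``dt``; millivolts for
    the voltages. ``tau_m``, ``tau_rise`` and ``tau_decay`` may be scalars
    or length-n vectors. Defaults are standard cortical-neuron figures.
    """

    dt: float = 0.1
    tau_m: float | np.ndarray = 20.0
    v_rest: float = -65.0
    v_thresh: float = -50.0
    v_reset: float = -65.0
    t_ref: float = 2.0
    tau_rise: float | np.ndarray = 0.5
    tau_decay: float | np.ndarray = 5.0
    input_current_gain: float = 1.0
    inhibitory_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        tr = np.asarray(self.tau_rise, dtype=float)
        td = np.asarray(self.tau_decay, dtype=float)
        if np.any(tr <= 0) or np.any(td <= tr):
            raise ParameterError("need tau_decay > tau_rise > 0")
        if self.v_thresh <= self.v_reset:
            raise ParameterError("v_thresh must exceed v_reset")
        if not (0 < self.dt < float(np.min(tr))):
            raise ParameterError(
                "dt must satisfy 0 < dt < tau_rise (synaptic kernel under-resolved otherwise)"
            )
        if self.t_ref < 0:
            raise ParameterError("t_ref must be non-negative")


@dataclass
class SpikeTrace:
    """Spike raster plus the continuous post-synaptic (filtered) trace."""

    spikes: np.ndarray           # T x n bool
    filtered: np.ndarray         # T x n, synaptic current trace
    voltages: np.ndarray | None = None
    dt: float = 0.1
    meta: dict = field(default_factory=dict)


def simulate_lif(
    c: Connectome,
    p: LIFParams,
    inputs: np.ndarray,
    input_nodes: Sequence[int],
    record_voltage: bool = False,
) -> SpikeTrace:
    """Euler-integrate the LIF reservoir over an input current sequence.

    ``inputs`` is T x C at resolution ``p.dt``; every channel is broadcast as
    a current into each node of ``input_nodes``.
    """
    inputs = np.asarray(inputs, dtype=float)
    if inputs.ndim != 2:
        raise ShapeError("inputs must be T x C")
    if not np.all(np.isfinite(inputs)):
        raise ValidationError("inputs contain non-finite values")
    n = c.n_nodes
    T = inputs.shape[0]
    W = c.weights.copy()
    if p.inhibitory_mask is not None:
        mask = np.asarray(p.inhibitory_mask, dtype=bool)
        if mask.shape[0] != n:
            raise ShapeError("inhibitory_mask length must equal node count")
        W[mask, :] *= -1.0
    M = build_input_map(inputs.shape[1], n, input_nodes, mode="constant")
    I_ext = inputs @ M * p.input_current_gain

    tau_m = np.broadcast_to(np.asarray(p.tau_m, dtype=float), (n,))
    tau_r = np.broadcast_to(np.asarray(p.tau_rise, dtype=float), (n,))
    tau_d = np.broadcast_to(np.asarray(p.tau_decay, dtype=float), (n,))
    ed = np.exp(-p.dt / tau_d)
    er = np.exp(-p.dt / tau_r)
    norm = 1.0 / (tau_d - tau_r)
    ref_steps = int(round(p.t_ref / p.dt))

    V = np.full(n, p.v_rest, dtype=float)
    A = np.zeros(n)
    B = np.zeros(n)
    refractory = np.zeros(n, dtype=int)
    spikes = np.zeros((T, n), dtype=bool)
    filtered = np.empty((T, n))
    volts = np.empty((T, n)) if record_voltage else None

    for t in range(T):
        A *= ed
        B *= er
        I_syn = A - B
        filtered[t] = I_syn
        active = refractory == 0
        dV = (-(V - p.v_rest) + I_syn + I_ext[t]) * (p.dt / tau_m)
        V = np.where(active, V + dV, p.v_reset)
        refractory = np.maximum(refractory - 1, 0)
        fired = active & (V >= p.v_thresh)
        if fired.any():
            spikes[t, fired] = True
            V[fired] = p.v_reset
            refractory[fired] = ref_steps
            inc = (fired.astype(float) @ W) * norm
            A += inc
            B += inc
        if volts is not None:
            volts[t] = V
    return SpikeTrace(spikes=spikes, filtered=filtered, voltages=volts, dt=p.dt,
                      meta={"n_nodes": n, "T": T})


def states_from_spikes(tr: SpikeTrace, mode: str = "filtered", window: int = 1) -> np.ndarray:
    """Continuous T x n reservoir states from a spike trace.

    ``filtered`` returns the double-exponential synaptic trace; ``rate``
    returns a causal moving-average spike count divided by the window length
    (so values lie in [0, 1]).
    """
    if mode == "filtered":
        return tr.filtered.copy()
    if mode == "rate":
        if window < 1:
            raise ParameterError("rate window must be >= 1")
        s = tr.spikes.astype(float)
        cs = np.cumsum(s, axis=0)
        out = cs.copy()
        out[window:] = cs[window:] - cs[:-window]
        return out / window
    raise ParameterError(f"unknown state mode {mode!r}")


def upsample_inputs(task_inputs: np.ndarray, steps_per_task_step: int = 100) -> np.ndarray:
    """Hold each task timestep constant for a fixed number of dt steps."""
    if steps_per_task_step < 1:
        raise ParameterError("steps_per_task_step must be >= 1")
    return np.repeat(np.asarray(task_inputs, dtype=float), steps_per_task_step, axis=0)


def sample_task_steps(trace_matrix: np.ndarray, steps_per_task_step: int = 100) -> np.ndarray:
    """Sample a dt-resolution T x n matrix at task-step boundaries (last sub-step)."""
    return np.asarray(trace_matrix)[steps_per_task_step - 1 :: steps_per_task_step]


def spikes_to_csv(tr: SpikeTrace, path) -> None:
    """Write the raster as two-column CSV (time_ms, neuron_id)."""
    t_idx, n_idx = np.nonzero(tr.spikes)
    import pandas as pd

    pd.DataFrame({"time_ms": t_idx * tr.dt, "neuron_id": n_idx}).to_csv(path, index=False)


def synaptic_kernel_peak_time(tau_rise: float, tau_decay: float) -> float:
    """Closed-form peak time of the double-exponential kernel (ms)."""
    return tau_rise * tau_decay / (tau_decay - tau_rise) * np.log(tau_decay / tau_rise)


def lif_isi(p: LIFParams, current: float) -> float:
    """Closed-form inter-spike interval under constant suprathreshold current.

    ``t = tau_m * ln((I - (v_reset - v_rest)) / (I - (v_thresh - v_rest))) + t_ref``.
    """
    num = current - (p.v_reset - p.v_rest)
    den = current - (p.v_thresh - p.v_rest)
    if den <= 0:
        raise ParameterError("current is subthreshold; no spiking")
    tau = float(np.asarray(p.tau_m, dtype=float).mean())
    return tau * np.log(num / den) + p.t_ref
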