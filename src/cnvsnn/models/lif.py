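"""Leaky integrate-and-fire dynamics and the surrogate gradient.

The neuron keeps a membrane potential that decays by a factor β per step,
integrates its input current, and fires a binary spike when the potential
reaches the threshold θ (firing on equality).  After a spike the potential
is reset by subtraction of θ, preserving any residual drive.  The hard
spike has no usable derivative, so the backward pass substitutes the
sigmoid-like surrogate ``1 / (k·|U − θ| + 1)²``, which is 1 exactly at
threshold, symmetric about it, and sharpens toward a delta as k grows.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["LIFParams", "LIFState", "lif_step", "surrogate_grad"]


@dataclass
class LIFParams:
    """Spiking dynamics constants."""

    beta: float = 0.5  # membrane decay per step
    theta: float = 0.5  # firing threshold
    k: float = 0.25  # surrogate slope / smoothness
    n_steps: int = 25  # presentation steps per input

    def __post_init__(self) -> None:
        if not 0.0 <= self.beta <= 1.0:
            raise ValueError("beta must lie in [0, 1]")
        if self.theta <= 0:
            raise ValueError("theta must be positive")
        if self.k <= 0:
            raise ValueError("k must be positive")
        if self.n_steps < 1:
            raise ValueError("n_steps must be >= 1")


@dataclass
class LIFState:
    """Membrane potentials and the spikes emitted at the last step."""

    u_mem: np.ndarray
    spikes_out: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.u_mem = np.asarray(self.u_mem, dtype=float)
        if self.spikes_out is None:
            self.spikes_out = np.zeros_like(self.u_mem)

    @classmethod
    def zeros(cls, shape) -> "LIFState":
        return cls(u_mem=np.zeros(shape))


def lif_step(state: LIFState, input_current: np.ndarray, p: LIFParams) -> LIFState:
    """One update: decay, integrate, fire at ≥ θ, reset by subtraction."""
    input_current = np.asarray(input_current, dtype=float)
    if np.isnan(input_current).any():
        raise FloatingPointError("NaN input current")
    if input_current.shape != state.u_mem.shape:
        raise ValueError(
            f"input shape {input_current.shape} != state shape {state.u_mem.shape}"
        )
    u = p.beta * state.u_mem + input_current
    spikes = (u >= p.theta).astype(float)
    u_after = u - p.theta * spikes
    return LIFState(u_mem=u_after, spikes_out=spikes)


def surrogate_grad(u_mem: np.ndarray, p: LIFParams) -> np.ndarray:
    """Surrogate derivative ``∂S̃/∂U = 1/(k·|U − θ| + 1)²`` of the spike
    nonlinearity, evaluated at membrane potential ``u_mem``."""
    u_mem = np.asarray(u_mem, dtype=float)
    return 1.0 / (p.k * np.abs(u_mem - p.theta) + 1.0) ** 2
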