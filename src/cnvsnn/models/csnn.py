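"""Convolutional spiking neural network with spike-count readout.

Two convolutional-spiking layers (conv → max-pool → LIF spiking tensor)
followed by an output layer (fully connected linear → two output LIF
neurons, one per class).  The static channels × time input is presented
identically at every one of ``n_steps`` presentation steps; the prediction
is the class whose output neuron spiked most over the steps, with ties
going to class 0.  Training backpropagates through the unrolled membrane
dynamics using the surrogate gradient in place of the Heaviside derivative;
the subtractive reset is treated as constant in the backward pass.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ..nn.autograd import Tensor, bce_with_logits, concat0, conv2d, maxpool2d, spike
from .lif import LIFParams

__all__ = ["CSNNConfig", "CSNN", "csnn_forward", "predict", "derive_shapes"]

_DIFF = np.array([[-1.0], [1.0]])  # spike-count difference → binary logit


@dataclass
class CSNNConfig:
    """Architecture constants: 5×5 kernels, stride 1, no padding, 12 then 64
    filters, 2×2/stride-2 pooling after each convolution, two output classes."""

    conv1_filters: int = 12
    conv2_filters: int = 64
    kernel: int = 5
    pool: int = 2
    n_classes: int = 2
    lif: LIFParams = field(default_factory=LIFParams)

    def __post_init__(self) -> None:
        if self.n_classes != 2:
            raise ValueError("the spike-count readout is binary (2 classes)")


def _plan(input_shape: tuple[int, int], cfg: CSNNConfig):
    """Stage shapes and effective kernel sizes for a channels × time input.

    Kernels and pool regions clip to the available extent per dimension (a
    5×5 kernel on a height-1 map becomes 1×5, a 2×2 pool on it pools width
    only) — this is what lets the fixed two-layer architecture run on very
    few input channels, e.g. the five-channel ablation.  Raises with the
    full shape chain if any stage still collapses.
    """
    h, w = input_shape
    shapes: list[tuple[int, ...]] = [(1, h, w)]
    kernels: list[tuple[int, int]] = []
    k, p = cfg.kernel, cfg.pool
    for f in (cfg.conv1_filters, cfg.conv2_filters):
        kh, kw = min(k, h), min(k, w)
        kernels.append((kh, kw))
        h, w = h - kh + 1, w - kw + 1
        shapes.append((f, h, w))
        h, w = h // min(p, max(h, 1)), w // min(p, max(w, 1))
        shapes.append((f, h, w))
        if h < 1 or w < 1:
            raise ValueError(
                f"input {input_shape} collapses in the conv/pool chain: {shapes}"
            )
    flat = shapes[-1][0] * h * w
    shapes.append((flat,))
    shapes.append((cfg.n_classes,))
    return shapes, kernels


def derive_shapes(input_shape: tuple[int, int], cfg: CSNNConfig) -> list[tuple[int, ...]]:
    """Per-stage feature-map shapes for a channels × time input."""
    return _plan(input_shape, cfg)[0]


def _uniform(rng: np.random.Generator, shape, fan_in: int) -> np.ndarray:
    bound = 1.0 / np.sqrt(fan_in)
    return rng.uniform(-bound, bound, size=shape)


class CSNN:
    """Trainable CSNN bound to a fixed channels × time input shape."""

    name = "CSNN"

    def __init__(self, input_shape: tuple[int, int], cfg: CSNNConfig | None = None, seed: int = 0):
        self.cfg = cfg or CSNNConfig()
        self.input_shape = tuple(input_shape)
        shapes, kernels = _plan(self.input_shape, self.cfg)
        self.shapes = shapes
        (k1h, k1w), (k2h, k2w) = kernels
        rng = np.random.default_rng(seed)
        f1, f2 = self.cfg.conv1_filters, self.cfg.conv2_filters
        flat = shapes[-2][0]
        self.w1 = Tensor(_uniform(rng, (f1, 1, k1h, k1w), k1h * k1w), requires_grad=True)
        self.b1 = Tensor(_uniform(rng, (f1,), k1h * k1w), requires_grad=True)
        self.w2 = Tensor(_uniform(rng, (f2, f1, k2h, k2w), f1 * k2h * k2w), requires_grad=True)
        self.b2 = Tensor(_uniform(rng, (f2,), f1 * k2h * k2w), requires_grad=True)
        self.wf = Tensor(_uniform(rng, (flat, 2), flat), requires_grad=True)
        self.bf = Tensor(_uniform(rng, (2,), flat), requires_grad=True)

    def parameters(self) -> list[Tensor]:
        return [self.w1, self.b1, self.w2, self.b2, self.wf, self.bf]

    # -- forward -------------------------------------------------------------
    def spike_counts(self, x: np.ndarray) -> Tensor:
        """Per-class output spike counts over the presentation steps.

        ``x``: (batch, channels, time) with values in [0, 1] (floating-point
        segments or binary spike arrays).  Returns a (batch, 2) tensor; each
        count lies in [0, n_steps].
        """
        x = np.asarray(x, dtype=np.float64)
        if x.ndim == 2:
            x = x[None]
        if x.shape[1:] != self.input_shape:
            raise ValueError(
                f"input shape {x.shape[1:]} does not match model shape "
                f"{self.input_shape}; stage shapes: {self.shapes}"
            )
        p = self.cfg.lif
        B = x.shape[0]

        # The input is static across steps, so the first convolution (and its
        # pooling) see the same drive every step: hoist them out of the loop.
        drive1 = maxpool2d(conv2d(Tensor(x[:, None]), self.w1, self.b1), self.cfg.pool)

        # Layer-1 membrane recurrence is the only inter-step dependency of the
        # first spiking layer; its spikes across all steps are then stacked so
        # the second conv and the readout run as single large batched ops.
        u1 = Tensor(np.zeros(drive1.shape))
        s1_steps = []
        for _ in range(p.n_steps):
            u1 = u1 * p.beta + drive1
            s1 = spike(u1 - p.theta, p.k)
            u1 = u1 - Tensor(p.theta * s1.data)  # reset detached
            s1_steps.append(s1)
        drive2 = maxpool2d(
            conv2d(concat0(s1_steps), self.w2, self.b2), self.cfg.pool
        )  # (n_steps·B, ...)

        u2 = Tensor(np.zeros((B,) + drive2.shape[1:]))
        s2_steps = []
        for t in range(p.n_steps):
            u2 = u2 * p.beta + drive2.narrow0(t * B, (t + 1) * B)
            s2 = spike(u2 - p.theta, p.k)
            u2 = u2 - Tensor(p.theta * s2.data)
            s2_steps.append(s2)
        z_all = concat0(s2_steps).reshape(p.n_steps * B, -1) @ self.wf + self.bf

        u3 = Tensor(np.zeros((B, 2)))
        counts = Tensor(np.zeros((B, 2)))
        for t in range(p.n_steps):
            u3 = u3 * p.beta + z_all.narrow0(t * B, (t + 1) * B)
            s3 = spike(u3 - p.theta, p.k)
            u3 = u3 - Tensor(p.theta * s3.data)
            counts = counts + s3
        return counts

    # -- interface -----------------------------------------------------------
    def predict(self, x: np.ndarray) -> np.ndarray:
        counts = self.spike_counts(x).data
        return predict(counts)

    def loss(self, x: np.ndarray, y: np.ndarray, sample_weight=None) -> Tensor:
        """Class-weighted cross entropy on softmaxed, step-normalized counts.

        With two classes the softmax collapses to a sigmoid of the
        normalized count difference, so the stable logit BCE applies.
        """
        counts = self.spike_counts(x)
        logit = (counts @ Tensor(_DIFF)) * (1.0 / self.cfg.lif.n_steps)
        return bce_with_logits(logit, y, sample_weight)


def csnn_forward(x: np.ndarray, model: CSNN) -> np.ndarray:
    """Spike counts as plain integers, shape (batch, 2)."""
    return model.spike_counts(x).data.astype(int)


def predict(spike_counts: np.ndarray) -> np.ndarray:
    """Class with the most output spikes; a tie predicts class 0."""
    counts = np.atleast_2d(np.asarray(spike_counts))
    if (counts < 0).any():
        raise ValueError("spike counts must be nonnegative")
    return (counts[:, 1] > counts[:, 0]).astype(int)
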