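"""Matched non-spiking CNN baseline.

Same convolution/pooling stack as the spiking network — two conv layers
(5×5, stride 1, no padding; 12 then 64 filters), each followed by 2×2
max pooling — then a fully connected linear layer to a single logistic
sigmoid unit giving the class-1 probability, thresholded at 0.5.  The
architecture is kept exactly as stated (no extra activations), so any
performance difference against the CSNN is attributable to the spiking
dynamics.
"""

from __future__ import annotations

import numpy as np

from ..nn.autograd import Tensor, bce_with_logits, conv2d, maxpool2d
from .csnn import CSNNConfig, _plan, _uniform

__all__ = ["CNN", "cnn_forward"]


class CNN:
    """Trainable CNN bound to a fixed channels × time input shape."""

    name = "CNN"

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
        self.wf = Tensor(_uniform(rng, (flat, 1), flat), requires_grad=True)
        self.bf = Tensor(_uniform(rng, (1,), flat), requires_grad=True)

    def parameters(self) -> list[Tensor]:
        return [self.w1, self.b1, self.w2, self.b2, self.wf, self.bf]

    def logits(self, x: np.ndarray) -> Tensor:
        x = np.asarray(x, dtype=np.float64)
        if x.ndim == 2:
            x = x[None]
        if x.shape[1:] != self.input_shape:
            raise ValueError(
                f"input shape {x.shape[1:]} does not match model shape "
                f"{self.input_shape}; stage shapes: {self.shapes}"
            )
        B = x.shape[0]
        h = maxpool2d(conv2d(Tensor(x[:, None]), self.w1, self.b1), self.cfg.pool)
        h = maxpool2d(conv2d(h, self.w2, self.b2), self.cfg.pool)
        return h.reshape(B, -1) @ self.wf + self.bf

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        return self.logits(x).sigmoid().data.reshape(-1)

    def predict(self, x: np.ndarray) -> np.ndarray:
        return (self.predict_proba(x) > 0.5).astype(int)

    def loss(self, x: np.ndarray, y: np.ndarray, sample_weight=None) -> Tensor:
        return bce_with_logits(self.logits(x), y, sample_weight)


def cnn_forward(x: np.ndarray, model: CNN) -> np.ndarray:
    """Class-1 probabilities in (0, 1)."""
    return model.predict_proba(x)
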