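"""Delta-modulation of normalized segments into binary spike trains.

Each channel of a [0, 1]-normalized segment is scanned sample by sample;
a spike (1) is emitted wherever the change relative to the previous sample
exceeds the threshold.  The result is a binary array of the same shape as
the input.  Threshold choice trades off spike density: tiny thresholds
saturate the train, thresholds above 1 silence it entirely on [0, 1] data.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import Segment

__all__ = ["SpikeArray", "delta_modulate", "spike_density", "FULL_SWEEP_THRESHOLDS"]

#: The reference threshold-sweep grid of the full-scale protocol.
FULL_SWEEP_THRESHOLDS = (0.05, 0.25, 0.375, 0.5, 0.625, 0.75, 1.0)


@dataclass
class SpikeArray:
    """Binary channels × time spike array with its generating threshold."""

    spikes: np.ndarray
    threshold: float
    source_segment: tuple[int, tuple[str, str]] | None = None  # (trial_id, marker_pair)

    def __post_init__(self) -> None:
        self.spikes = np.asarray(self.spikes)
        if not np.isin(self.spikes, (0, 1)).all():
            raise ValueError("spike values must be binary")


def delta_modulate(seg: Segment, threshold: float, signed: bool = False) -> SpikeArray:
    """Encode successive-sample changes above ``threshold`` as spikes.

    By default the change is taken in absolute value, so both the steep
    negative CNV ramp and positive deflections register; ``signed`` emits
    spikes only for positive-going changes.  The first sample never spikes,
    keeping the output the same shape as the input.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    x = seg.data
    diffs = np.diff(x, axis=1)
    if not signed:
        diffs = np.abs(diffs)
    spikes = np.zeros_like(x, dtype=np.uint8)
    spikes[:, 1:] = diffs > threshold
    return SpikeArray(
        spikes=spikes, threshold=threshold, source_segment=(seg.trial_id, seg.marker_pair)
    )


def spike_density(sa: SpikeArray) -> float:
    """Fraction of array entries that are spikes."""
    return float(np.asarray(sa.spikes, dtype=float).mean())
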