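"""Core containers shared across the pipeline stages.

An :class:`EEGRecording` is one countdown trial: a channels × samples array
of scalp potentials in µV together with the audio-countdown event markers
("5".."1", "Stop").  A :class:`Segment` is one inter-marker window cut from
a recording, carrying its binary intention label (1 only for the window
between the "1" count and the "Stop" command) and provenance.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "EEGRecording",
    "Segment",
    "MARKER_LABELS",
    "START_LABEL",
    "ALLOWED_LABELS",
    "REJECTED",
    "Rejected",
]

#: The countdown marker alphabet written by the experiment, ending in "Stop".
MARKER_LABELS = ("5", "4", "3", "2", "1", "Stop")
#: The audible go cue; recordings may carry pre-cue context before it.
START_LABEL = "Start"
ALLOWED_LABELS = (START_LABEL,) + MARKER_LABELS


@dataclass
class EEGRecording:
    """One trial of multichannel EEG with ordered event markers."""

    data: np.ndarray  # (n_channels, n_samples), µV
    fs: float  # Hz
    labels: tuple[str, ...]
    markers: list[tuple[int, str]]  # ordered (sample_index, label)
    trial_id: int = 0

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be channels × samples")
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        if len(self.labels) != self.data.shape[0]:
            raise ValueError(
                f"{len(self.labels)} labels for {self.data.shape[0]} channels"
            )
        idx = [i for i, _ in self.markers]
        if any(b <= a for a, b in zip(idx, idx[1:])):
            raise ValueError("marker indices must be strictly increasing")
        if idx and (idx[0] < 0 or idx[-1] >= self.data.shape[1]):
            raise ValueError("marker index outside the recording")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def marker_index(self, label: str) -> int:
        """Sample index of the first marker with the given label."""
        for i, lab in self.markers:
            if lab == label:
                return i
        raise KeyError(f"marker {label!r} not present")

    @property
    def start_index(self) -> int:
        """Sample of the "Start" cue (0 when no pre-cue context exists)."""
        try:
            return self.marker_index(START_LABEL)
        except KeyError:
            return 0

    def copy_with(self, **kw) -> "EEGRecording":
        if "data" not in kw:
            kw["data"] = self.data.copy()
        if "markers" not in kw:
            kw["markers"] = list(self.markers)
        return replace(self, **kw)


@dataclass
class Segment:
    """One inter-marker window: channels × time, with label and provenance."""

    data: np.ndarray  # (n_channels, n_times), µV (or normalized units)
    label: int  # 0 = no intention, 1 = intention (the 1→Stop window)
    trial_id: int
    marker_pair: tuple[str, str]
    original_length: int
    channel_labels: tuple[str, ...] = ()
    removed_channels: set[int] = field(default_factory=set)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("segment data must be channels × time")
        if self.label not in (0, 1):
            raise ValueError("label must be 0 or 1")
        if self.original_length <= 0:
            raise ValueError("original_length must be positive")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_times(self) -> int:
        return self.data.shape[1]

    def copy_with(self, **kw) -> "Segment":
        if "data" not in kw:
            kw["data"] = self.data.copy()
        if "removed_channels" not in kw:
            kw["removed_channels"] = set(self.removed_channels)
        return replace(self, **kw)


class Rejected:
    """Sentinel returned for segments dropped by the cleaning rules."""

    _instance = None

    def __new__(cls):
        if cls._instance is None:
            cls._instance = super().__new__(cls)
        return cls._instance

    def __repr__(self) -> str:  # pragma: no cover
        return "REJECTED"

    def __bool__(self) -> bool:
        return False


#: Singleton sentinel: a segment with too many bad channels is omitted.
REJECTED = Rejected()
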