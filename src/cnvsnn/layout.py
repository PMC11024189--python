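"""Scalp channel layout (10-20 system) with 2-D schematic coordinates.

The shipped fixture projects the 19 standard 10-20 positions onto the unit
disc (nose toward +y, right ear toward +x, Cz at the origin).  Coordinates
are used for channel interpolation after artifact cleaning and for the
centro-medial spatial weighting of the synthetic CNV.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from importlib import resources

import numpy as np

__all__ = ["ChannelLayout", "standard_1020_layout"]


@dataclass(frozen=True)
class ChannelLayout:
    """Ordered channel names with 2-D scalp coordinates."""

    labels: tuple[str, ...]
    positions: np.ndarray  # (n_channels, 2)

    def __post_init__(self) -> None:
        if len(self.labels) != len(set(self.labels)):
            raise ValueError("channel labels must be unique")
        if self.positions.shape != (len(self.labels), 2):
            raise ValueError("positions must be (n_channels, 2)")

    @property
    def n_channels(self) -> int:
        return len(self.labels)

    def index(self, label: str) -> int:
        try:
            return self.labels.index(label)
        except ValueError:
            raise KeyError(f"unknown channel label {label!r}") from None

    def distances_from(self, label: str) -> np.ndarray:
        """Euclidean distance of every channel from the named one."""
        ref = self.positions[self.index(label)]
        return np.linalg.norm(self.positions - ref, axis=1)


def standard_1020_layout() -> ChannelLayout:
    """Load the 19-channel 10-20 fixture shipped with the package."""
    ref = resources.files("cnvsnn.data").joinpath("layout_1020.csv")
    labels: list[str] = []
    pos: list[tuple[float, float]] = []
    with ref.open("r") as fh:
        for row in csv.DictReader(fh):
            labels.append(row["label"])
            pos.append((float(row["x"]), float(row["y"])))
    return ChannelLayout(tuple(labels), np.asarray(pos, dtype=float))
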