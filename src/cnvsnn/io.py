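"""Readers/writers for trial matrices, marker files and segment containers.

Trials are exchanged as plain delimited text: a matrix file with one column
per channel (header row = channel labels) and a marker file with rows
``sample_index,label``.  Processed segments are stored in a single HDF5
container with arrays ``data`` (n_segments × channels × target_len),
``labels``, ``trial_id`` and ``original_length``; spike-encoded versions
live under ``spikes/<threshold>``.
"""

from __future__ import annotations

from pathlib import Path

import h5py
import numpy as np

from .core import ALLOWED_LABELS, EEGRecording, Segment

__all__ = [
    "FormatError",
    "read_recording",
    "write_recording",
    "save_segments",
    "load_segments",
    "save_spikes",
    "load_spikes",
]


class FormatError(ValueError):
    """Raised for malformed trial matrix or marker files."""


def read_recording(matrix_path, marker_path, fs: float = 500.0, trial_id: int = 0) -> EEGRecording:
    """Read one trial from a delimited matrix file plus a marker file.

    Raises :class:`FormatError` (with the offending row number) for ragged
    rows, unknown marker labels, non-monotone marker indices, or an empty
    marker file.
    """
    matrix_path, marker_path = Path(matrix_path), Path(marker_path)
    with open(matrix_path) as fh:
        header = fh.readline().strip()
        labels = tuple(h.strip() for h in header.split(","))
        rows: list[list[float]] = []
        for lineno, line in enumerate(fh, start=2):
            line = line.strip()
            if not line:
                continue
            parts = line.split(",")
            if len(parts) != len(labels):
                raise FormatError(
                    f"{matrix_path.name}: row {lineno} has {len(parts)} fields, "
                    f"expected {len(labels)}"
                )
            try:
                rows.append([float(p) for p in parts])
            except ValueError as exc:
                raise FormatError(f"{matrix_path.name}: row {lineno}: {exc}") from None
    if not rows:
        raise FormatError(f"{matrix_path.name}: no data rows")
    data = np.asarray(rows, dtype=float).T

    markers: list[tuple[int, str]] = []
    with open(marker_path) as fh:
        fh.readline()  # header
        for lineno, line in enumerate(fh, start=2):
            line = line.strip()
            if not line:
                continue
            parts = line.split(",")
            if len(parts) != 2:
                raise FormatError(f"{marker_path.name}: row {lineno}: expected 2 fields")
            try:
                idx = int(parts[0])
            except ValueError:
                raise FormatError(
                    f"{marker_path.name}: row {lineno}: bad sample index {parts[0]!r}"
                ) from None
            lab = parts[1].strip()
            if lab not in ALLOWED_LABELS:
                raise FormatError(
                    f"{marker_path.name}: row {lineno}: unknown marker label {lab!r}"
                )
            if markers and idx <= markers[-1][0]:
                raise FormatError(
                    f"{marker_path.name}: row {lineno}: marker indices must increase"
                )
            markers.append((idx, lab))
    if not markers:
        raise FormatError(f"{marker_path.name}: no markers")
    return EEGRecording(data=data, fs=fs, labels=labels, markers=markers, trial_id=trial_id)


def write_recording(rec: EEGRecording, matrix_path, marker_path) -> None:
    """Write a recording in the delimited format read by :func:`read_recording`."""
    from .synthio import write_trial

    write_trial(rec, matrix_path, marker_path)


def _segment_arrays(segments: list[Segment]):
    data = np.stack([s.data for s in segments])
    labels = np.array([s.label for s in segments], dtype=np.int64)
    trial = np.array([s.trial_id for s in segments], dtype=np.int64)
    orig = np.array([s.original_length for s in segments], dtype=np.int64)
    pairs = np.array([f"{a}->{b}" for a, b in (s.marker_pair for s in segments)], dtype="S16")
    return data, labels, trial, orig, pairs


def save_segments(path, segments: list[Segment]) -> None:
    if not segments:
        raise ValueError("no segments to save")
    data, labels, trial, orig, pairs = _segment_arrays(segments)
    with h5py.File(path, "w") as f:
        f.create_dataset("data", data=data)
        f.create_dataset("labels", data=labels)
        f.create_dataset("trial_id", data=trial)
        f.create_dataset("original_length", data=orig)
        f.create_dataset("marker_pair", data=pairs)
        f.attrs["channel_labels"] = ",".join(segments[0].channel_labels)


def load_segments(path) -> list[Segment]:
    with h5py.File(path, "r") as f:
        data = f["data"][...]
        labels = f["labels"][...]
        trial = f["trial_id"][...]
        orig = f["original_length"][...]
        pairs = [p.decode().split("->") for p in f["marker_pair"][...]]
        ch = tuple(f.attrs["channel_labels"].split(","))
    return [
        Segment(
            data=data[i],
            label=int(labels[i]),
            trial_id=int(trial[i]),
            marker_pair=(pairs[i][0], pairs[i][1]),
            original_length=int(orig[i]),
            channel_labels=ch,
        )
        for i in range(data.shape[0])
    ]


def save_spikes(path, threshold: float, spikes: np.ndarray) -> None:
    """Store a spike-encoded dataset under ``spikes/<threshold>``."""
    with h5py.File(path, "a") as f:
        grp = f.require_group("spikes")
        name = f"{threshold:g}"
        if name in grp:
            del grp[name]
        d = grp.create_dataset(name, data=spikes.astype(np.uint8))
        d.attrs["threshold"] = threshold


def load_spikes(path, threshold: float) -> np.ndarray:
    with h5py.File(path, "r") as f:
        return f["spikes"][f"{threshold:g}"][...].astype(np.float64)
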