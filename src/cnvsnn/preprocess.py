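"""Preprocessing of countdown-trial EEG into model-ready segments.

The pipeline order is fixed: zero-phase FIR band-pass (0.1–1 Hz, the slow
cortical potential band) → recording-level cleaning → segmentation by the
countdown markers → per-segment baseline correction → per-segment artifact
cleaning with channel interpolation → zero-padding to a uniform length →
per-channel min–max normalization to [0, 1].  The intention label is 1 for
the window between the "1" count and the "Stop" command and 0 for the
earlier windows.

Also provided: the acquisition-time signal quality index
``QI = tanh(sqrt((ζL/WζL)² + (ζm/Wζm)² + (O/WO)²))`` with its green /
orange / red bands, grand averaging over trials for visualizing the CNV,
and the five-channel (Cz, Pz, C3, C4, Fz) ablation selector.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import signal

from .core import EEGRecording, MARKER_LABELS, REJECTED, Segment
from .io import read_recording, write_recording  # re-exported module surface
from .layout import ChannelLayout, standard_1020_layout

__all__ = [
    "CleaningConfig",
    "QualityWeights",
    "PreprocessConfig",
    "read_recording",
    "write_recording",
    "design_bandpass",
    "bandpass_fir",
    "clean_recording",
    "segment_by_markers",
    "baseline_correct",
    "clean_segment",
    "interpolate_channels",
    "pad_segment",
    "minmax_normalize",
    "quality_index",
    "qi_color",
    "grand_average",
    "select_channels",
    "preprocess_recordings",
    "ABLATION_CHANNELS",
]

#: Channel subset of the five-channel ablation study.
ABLATION_CHANNELS = ("Cz", "Pz", "C3", "C4", "Fz")


@dataclass
class CleaningConfig:
    """Per-segment artifact rejection thresholds.

    A sample is bad if its magnitude exceeds ``amplitude_limit`` (µV) or its
    z-score against the channel's own distribution (local) or against all
    channels pooled (global) exceeds ``z_limit``.  Channels bad for at least
    ``max_bad_fraction`` of the segment are removed and re-interpolated;
    shorter bad periods are excised and linearly interpolated.  Segments
    losing more than ``max_removed_channels`` channels are rejected.
    """

    amplitude_limit: float = 100.0
    z_limit: float = 3.0
    max_bad_fraction: float = 0.10
    max_removed_channels: int = 10

    def __post_init__(self) -> None:
        if self.amplitude_limit <= 0 or self.z_limit <= 0:
            raise ValueError("cleaning thresholds must be positive")
        if not 0.0 < self.max_bad_fraction < 1.0:
            raise ValueError("max_bad_fraction must lie in (0, 1)")
        if self.max_removed_channels < 0:
            raise ValueError("max_removed_channels must be >= 0")


@dataclass
class QualityWeights:
    """Normalizing weights of the acquisition quality index."""

    w_line: float = 100.0  # µV
    w_main: float = 250.0  # µV
    w_offset: float = 280.0  # mV

    def __post_init__(self) -> None:
        if min(self.w_line, self.w_main, self.w_offset) <= 0:
            raise ValueError("quality weights must be strictly positive")


# ---------------------------------------------------------------------------
# filtering


def design_bandpass(numtaps: int, lo: float, hi: float, fs: float) -> np.ndarray:
    """Hamming-window FIR band-pass taps (zero gain at DC and Nyquist)."""
    if not 0 < lo < hi < fs / 2:
        raise ValueError("require 0 < lo < hi < fs/2")
    if numtaps % 2 == 0:
        numtaps += 1
    return signal.firwin(numtaps, [lo, hi], pass_zero=False, fs=fs)


def default_numtaps(fs: float, lo: float, n_samples: int) -> int:
    """Longest usable odd tap count: aims at a transition width ≈ ``lo`` Hz
    (Hamming ≈ 3.3·fs/numtaps) but keeps the forward–backward pad inside the
    recording."""
    desired = int(round(3.3 * fs / lo))
    cap = (n_samples - 2) // 3
    n = min(desired, cap)
    return n if n % 2 == 1 else n - 1


def bandpass_fir(
    rec: EEGRecording, lo: float = 0.1, hi: float = 1.0, numtaps: int | None = None
) -> EEGRecording:
    """Zero-phase FIR band-pass; markers stay aligned (forward–backward)."""
    if not 0 < lo < hi < rec.fs / 2:
        raise ValueError("require 0 < lo < hi < fs/2")
    if numtaps is None:
        numtaps = default_numtaps(rec.fs, lo, rec.n_samples)
    if numtaps < 9:
        raise ValueError(
            "recording shorter than the filter warm-up; use a shorter filter "
            "(smaller numtaps) or a longer recording"
        )
    taps = design_bandpass(numtaps, lo, hi, rec.fs)
    padlen = min(3 * len(taps), rec.n_samples - 1)
    out = signal.filtfilt(taps, [1.0], rec.data, axis=1, padlen=padlen)
    return rec.copy_with(data=out)


# ---------------------------------------------------------------------------
# recording-level cleaning

def clean_recording(
    rec: EEGRecording,
    layout: ChannelLayout | None = None,
    *,
    flat_seconds: float = 5.0,
    corr_limit: float | None = None,
    line_sd_limit: float | None = None,
    burst_sd_limit: float = 20.0,
    burst_window_s: float = 0.5,
) -> tuple[EEGRecording, set[int]]:
    """Recording-level channel rejection plus windowed burst suppression.

    Channels flat for ``flat_seconds`` or more are removed, as are channels
    correlating below ``corr_limit`` with an inverse-distance estimate from
    their three nearest neighbours, or carrying more than ``line_sd_limit``
    standard deviations of high-frequency residual relative to their signal.
    The two latter criteria assume volume-conducted (inter-channel
    correlated) EEG and are opt-in (pass a limit to enable).  Bursts —
    ``burst_window_s`` windows whose SD exceeds ``burst_sd_limit`` × the
    channel SD — are excised and linearly interpolated.  Removed channels
    are re-interpolated from the layout.  Returns the cleaned recording and
    the set of removed channel indices.
    """
    if layout is None:
        layout = standard_1020_layout()
    x = rec.data.copy()
    n_ch, n_s = x.shape
    bad: set[int] = set()

    flat_run = int(round(flat_seconds * rec.fs))
    if 0 < flat_run <= n_s:
        d = np.abs(np.diff(x, axis=1)) < 1e-12
        for c in range(n_ch):
            run = best = 0
            for v in d[c]:
                run = run + 1 if v else 0
                best = max(best, run)
            if best + 1 >= flat_run:
                bad.add(c)

    if corr_limit is not None:
        for c in range(n_ch):
            est = _idw_estimate(x, c, rec.labels, layout, exclude=bad | {c})
            if est is None:
                continue
            sx, se = x[c].std(), est.std()
            if sx == 0 or se == 0:
                continue
            if np.corrcoef(x[c], est)[0, 1] < corr_limit:
                bad.add(c)

    if line_sd_limit is not None:
        kernel = np.ones(5) / 5.0
        for c in range(n_ch):
            smooth = np.convolve(x[c], kernel, mode="same")
            resid = x[c] - smooth
            s = x[c].std()
            if s > 0 and resid.std() > line_sd_limit * s:
                bad.add(c)

    win = max(2, int(round(burst_window_s * rec.fs)))
    for c in range(n_ch):
        if c in bad:
            continue
        s = x[c].std()
        if s == 0:
            continue
        mask = np.zeros(n_s, dtype=bool)
        for start in range(0, n_s - win + 1, win):
            w = x[c, start : start + win]
            if w.std() > burst_sd_limit * s:
                mask[start : start + win] = True
        if mask.any() and not mask.all():
            good = np.flatnonzero(~mask)
            x[c, mask] = np.interp(np.flatnonzero(mask), good, x[c, good])

    out = rec.copy_with(data=x)
    if bad:
        seg = Segment(
            data=out.data, label=0, trial_id=rec.trial_id,
            marker_pair=("", ""), original_length=n_s, channel_labels=rec.labels,
        )
        out = out.copy_with(data=interpolate_channels(seg, bad, layout).data)
    return out, bad


def _idw_estimate(x, c, labels, layout, exclude):
    dists = layout.distances_from(labels[c])
    order = [i for i in np.argsort(dists) if i != c and i not in exclude]
    if not order:
        return None
    near = order[:3]
    w = 1.0 / np.maximum(dists[near], 1e-9)
    return (w[:, None] * x[near]).sum(axis=0) / w.sum()


# ---------------------------------------------------------------------------
# segmentation and per-segment operations

def segment_by_markers(rec: EEGRecording, include_prestart: bool = True) -> list[Segment]:
    """Cut a trial into inter-marker windows and label them.

    The four inter-count windows (5→4 … 2→1) — plus the Start→"5" window
    when present and ``include_prestart`` is set — are labelled 0; the
    1→Stop window is labelled 1.  Stream context before the "Start" cue
    (when the recording carries one) belongs to no window.  Missing
    markers or zero-length windows raise ``ValueError``.
    """
    present = {lab for _, lab in rec.markers}
    for lab in MARKER_LABELS:
        if lab not in present:
            raise ValueError(f"missing marker {lab!r}")
    idx = {lab: rec.marker_index(lab) for lab in MARKER_LABELS}

    windows: list[tuple[str, str, int, int, int]] = []
    start = rec.start_index
    if include_prestart and idx["5"] > start:
        windows.append(("Start", "5", start, idx["5"], 0))
    for a, b in zip(MARKER_LABELS[:-1], MARKER_LABELS[1:]):
        label = 1 if (a, b) == ("1", "Stop") else 0
        if idx[b] == idx[a]:
            raise ValueError(f"zero-length window {a}->{b}")
        windows.append((a, b, idx[a], idx[b], label))

    return [
        Segment(
            data=rec.data[:, i0:i1].copy(),
            label=lab,
            trial_id=rec.trial_id,
            marker_pair=(a, b),
            original_length=i1 - i0,
            channel_labels=rec.labels,
        )
        for a, b, i0, i1, lab in windows
    ]


def baseline_correct(seg: Segment) -> Segment:
    """Subtract each channel's mean over the segment."""
    if seg.n_times == 0:
        raise ValueError("empty segment")
    return seg.copy_with(data=seg.data - seg.data.mean(axis=1, keepdims=True))


def clean_segment(
    seg: Segment, cfg: CleaningConfig | None = None, layout: ChannelLayout | None = None
):
    """Per-segment artifact cleaning; returns a Segment or ``REJECTED``.

    Bad-sample mask per channel: |x| above the amplitude limit, or z-score
    beyond the limit against the channel's own distribution (local) or the
    pooled all-channel distribution (global).  Channels bad for at least
    ``max_bad_fraction`` of the segment are removed and re-interpolated
    from their neighbours; shorter bad stretches are excised and linearly
    interpolated in time.
    """
    cfg = cfg or CleaningConfig()
    layout = layout or standard_1020_layout()
    x = seg.data
    sd_ch = x.std(axis=1, keepdims=True)
    sd_ch[sd_ch == 0] = np.inf
    z_local = (x - x.mean(axis=1, keepdims=True)) / sd_ch
    sd_all = x.std() or np.inf
    z_global = (x - x.mean()) / sd_all

    bad = (
        (np.abs(x) > cfg.amplitude_limit)
        | (np.abs(z_local) > cfg.z_limit)
        | (np.abs(z_global) > cfg.z_limit)
    )
    frac = bad.mean(axis=1)
    remove = set(np.flatnonzero(frac >= cfg.max_bad_fraction).tolist())
    if len(remove) > cfg.max_removed_channels:
        return REJECTED

    out = x.copy()
    for c in range(seg.n_channels):
        if c in remove or not bad[c].any():
            continue
        good = np.flatnonzero(~bad[c])
        out[c, bad[c]] = np.interp(np.flatnonzero(bad[c]), good, out[c, good])

    cleaned = seg.copy_with(data=out, removed_channels=remove)
    if remove:
        cleaned = interpolate_channels(cleaned, remove, layout)
        cleaned.removed_channels = remove
    return cleaned


def interpolate_channels(seg: Segment, removed: set[int], layout: ChannelLayout) -> Segment:
    """Replace removed channels by the inverse-distance-weighted mean of the
    three nearest surviving channels (layout coordinates)."""
    removed = set(removed)
    if not removed:
        return seg.copy_with()
    surviving = [c for c in range(seg.n_channels) if c not in removed]
    if not surviving:
        raise ValueError("cannot interpolate: all channels removed")
    labels = seg.channel_labels or layout.labels
    out = seg.data.copy()
    for c in removed:
        d = np.linalg.norm(layout.positions - layout.positions[layout.index(labels[c])], axis=1)
        order = sorted(surviving, key=lambda i: d[i])[:3]
        w = 1.0 / np.maximum(np.array([d[i] for i in order]), 1e-9)
        out[c] = (w[:, None] * seg.data[order]).sum(axis=0) / w.sum()
    return seg.copy_with(data=out, removed_channels=set(removed))


def pad_segment(seg: Segment, target_len: int = 1848) -> Segment:
    """Append zeros up to ``target_len`` samples (never truncates)."""
    n = seg.n_times
    if n > target_len:
        raise ValueError(f"segment length {n} exceeds target {target_len}; padding never truncates")
    if n == target_len:
        return seg.copy_with()
    pad = np.zeros((seg.n_channels, target_len - n))
    return seg.copy_with(data=np.concatenate([seg.data, pad], axis=1))


def minmax_normalize(seg: Segment, use_unpadded: bool = False) -> Segment:
    """Per-channel min–max scaling to [0, 1].

    With ``use_unpadded`` the min/max are taken over the unpadded extent
    only and the padded tail is left at zero.  Constant channels map to all
    zeros (a warning is emitted).
    """
    x = seg.data
    extent = seg.original_length if use_unpadded else seg.n_times
    core = x[:, :extent]
    lo = core.min(axis=1, keepdims=True)
    hi = core.max(axis=1, keepdims=True)
    rng = hi - lo
    flat = rng[:, 0] == 0
    if flat.any():
        warnings.warn(
            f"constant channel(s) {np.flatnonzero(flat).tolist()} mapped to zeros",
            RuntimeWarning,
            stacklevel=2,
        )
    rng[flat] = 1.0
    out = x.copy()
    scaled = (core - lo) / rng
    scaled[flat] = 0.0
    out[:, :extent] = scaled
    if use_unpadded:
        out[:, extent:] = 0.0
    return seg.copy_with(data=out)


# ---------------------------------------------------------------------------
# quality index, grand average, channel selection

def quality_index(
    line_noise: float, main_noise: float, offset: float, w: QualityWeights | None = None
) -> float:
    """Acquisition quality index in [0, 1).

    ``QI = tanh(sqrt((ζL/WζL)² + (ζm/Wζm)² + (O/WO)²))`` with line/main
    noise in µV and offset in mV.  Monotone non-decreasing in the magnitude
    of each input.
    """
    w = w or QualityWeights()
    vals = np.array([line_noise / w.w_line, main_noise / w.w_main, offset / w.w_offset])
    if not np.all(np.isfinite(vals) | np.isinf(vals)):
        raise ValueError("quality index inputs must not be NaN")
    return float(np.tanh(np.sqrt(np.sum(vals**2))))


def qi_color(qi: float) -> str:
    """Map a quality index to the acquisition monitor's color bands."""
    if qi < 0.5:
        return "green"
    if qi < 0.8:
        return "orange"
    return "red"


def grand_average(
    segments: list[Segment], channel: str = "Cz", align: str = "start"
) -> np.ndarray:
    """Pointwise mean of one channel across segments.

    Only the unpadded extent of each segment contributes (mask on
    ``original_length``).  With ``align="start"`` segments are locked to
    their first sample and the output spans the maximum extent (the tail is
    averaged over however many segments reach it).  With ``align="end"``
    segments are locked to their final unpadded sample — the natural choice
    for a response-locked potential such as the CNV, whose extremum sits at
    the imperative stimulus — and the output spans the minimum extent so
    every segment contributes at every point.
    """
    if not segments:
        raise ValueError("no segments")
    if align not in ("start", "end"):
        raise ValueError("align must be 'start' or 'end'")

    def chan(s: Segment) -> np.ndarray:
        labels = s.channel_labels
        if channel not in labels:
            raise KeyError(f"channel {channel!r} not present")
        n = min(s.original_length, s.n_times)
        return s.data[labels.index(channel), :n]

    if align == "end":
        length = min(min(s.original_length, s.n_times) for s in segments)
        return np.mean([chan(s)[-length:] for s in segments], axis=0)

    length = max(min(s.original_length, s.n_times) for s in segments)
    total = np.zeros(length)
    count = np.zeros(length)
    for s in segments:
        x = chan(s)
        total[: len(x)] += x
        count[: len(x)] += 1
    if (count == 0).any():
        length = int(np.argmax(count == 0))
        total, count = total[:length], count[:length]
    return total / count


def select_channels(seg: Segment, keep: list[str]) -> Segment:
    """Reduce to the named channels, in the order given."""
    if not keep:
        raise ValueError("keep list must not be empty")
    labels = seg.channel_labels
    idx = []
    for lab in keep:
        if lab not in labels:
            raise KeyError(f"unknown channel label {lab!r}")
        idx.append(labels.index(lab))
    return seg.copy_with(data=seg.data[idx].copy(), channel_labels=tuple(keep))


# ---------------------------------------------------------------------------
# end-to-end driver

@dataclass
class PreprocessConfig:
    """Configuration of the full preprocessing chain."""

    lo: float = 0.1  # Hz
    hi: float = 1.0  # Hz
    numtaps: int | None = None  # None → longest usable (see default_numtaps)
    cleaning: CleaningConfig = field(default_factory=CleaningConfig)
    target_len: int = 1848
    include_prestart: bool = True
    normalize_unpadded: bool = False
    recording_cleaning: bool = True
    flat_seconds: float = 5.0
    burst_sd_limit: float = 20.0


def preprocess_recordings(
    recordings: list[EEGRecording],
    cfg: PreprocessConfig | None = None,
    layout: ChannelLayout | None = None,
) -> tuple[list[Segment], int]:
    """Run filter → clean → segment → baseline → clean → pad → normalize.

    Returns the surviving segments and the number rejected by the
    per-segment cleaning rules.
    """
    cfg = cfg or PreprocessConfig()
    layout = layout or standard_1020_layout()
    out: list[Segment] = []
    n_rejected = 0
    for rec in recordings:
        rec = bandpass_fir(rec, cfg.lo, cfg.hi, cfg.numtaps)
        if cfg.recording_cleaning:
            rec, _ = clean_recording(
                rec, layout, flat_seconds=cfg.flat_seconds, burst_sd_limit=cfg.burst_sd_limit
            )
        for seg in segment_by_markers(rec, include_prestart=cfg.include_prestart):
            seg = baseline_correct(seg)
            cleaned = clean_segment(seg, cfg.cleaning, layout)
            if cleaned is REJECTED:
                n_rejected += 1
                continue
            cleaned = pad_segment(cleaned, cfg.target_len)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                cleaned = minmax_normalize(cleaned, use_unpadded=cfg.normalize_unpadded)
            out.append(cleaned)
    return out, n_rejected
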