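"""Synthetic countdown-trial EEG with a contingent negative variation (CNV).

The generator emulates the structure of a cued-braking experiment: each
trial starts with a "Start" cue (sample 0), is marked by an audible
countdown "5".."1" roughly one second apart, and ends with a "Stop" command
upon which the subject brakes.  The window between the "1" count and "Stop"
carries the intention signature: a slow negative potential ramp (the CNV)
that is strongest at the vertex (Cz) and falls off over the scalp, riding
on zero-mean background noise.  Occasional high-amplitude blink-like
transients exercise the artifact-cleaning rules downstream.

Every trial is generated from a seed stream derived from ``(seed,
trial_id)``, so any subset of a dataset is reproducible independently of
generation order.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .core import EEGRecording, MARKER_LABELS, START_LABEL
from .layout import ChannelLayout, standard_1020_layout

__all__ = [
    "SyntheticConfig",
    "cz_gaussian_profile",
    "generate_trial",
    "generate_dataset",
    "inject_artifact",
    "write_trial",
    "write_dataset",
]


def cz_gaussian_profile(layout: ChannelLayout, sigma: float = 0.45) -> np.ndarray:
    """Centro-medial spatial weights: Gaussian fall-off with distance from Cz.

    Returns per-channel weights in [0, 1] with the maximum (1.0) at Cz.
    ``sigma`` is in the layout's unit-disc coordinates; the default puts the
    ring of neighbours (Fz, Pz, C3, C4, distance 0.5) near weight 0.54 and
    the outer ring below 0.1.
    """
    d = layout.distances_from("Cz")
    w = np.exp(-(d**2) / (2.0 * sigma**2))
    return w / w.max()


@dataclass
class SyntheticConfig:
    """Parameters of the synthetic experiment.

    Amplitudes are in µV; ``cnv_amplitude`` is the peak negativity reached
    at the "Stop" marker on the best-weighted channel (Cz) and must be ≤ 0.
    ``marker_jitter`` is the uniform fractional jitter (±) applied to each
    inter-marker gap.
    """

    n_trials: int = 1
    n_channels: int = 19
    fs: float = 500.0
    marker_interval_s: float = 1.0
    marker_jitter: float = 0.1
    cnv_amplitude: float = -10.0
    cnv_onset: float = 0.0  # fraction of the 1→Stop window where the ramp starts
    spatial_profile: np.ndarray | None = None  # default: Gaussian fall-off from Cz
    spatial_sigma: float = 0.45
    noise_sd: float = 5.0
    one_over_f: bool = False
    artifact_rate: float = 0.05  # per segment-window probability
    artifact_amplitude: float = 150.0
    post_stop_s: float = 0.25
    context_s: float = 2.0  # pre-"Start" / post-trial stream context
    seed: int = 0
    layout: ChannelLayout = field(default_factory=standard_1020_layout)

    def __post_init__(self) -> None:
        if self.n_channels < 1:
            raise ValueError("configuration error: n_channels must be >= 1")
        if self.fs <= 0:
            raise ValueError("configuration error: fs must be positive")
        if self.cnv_amplitude > 0:
            raise ValueError("configuration error: cnv_amplitude must be <= 0")
        if not 0.0 <= self.marker_jitter < 1.0:
            raise ValueError("configuration error: marker_jitter in [0, 1)")
        if self.n_trials < 1:
            raise ValueError("configuration error: n_trials must be >= 1")
        if self.spatial_profile is not None:
            w = np.asarray(self.spatial_profile, dtype=float)
            if w.shape != (self.n_channels,):
                raise ValueError("configuration error: spatial_profile shape")
            if w.min() < 0 or not np.isclose(w.max(), 1.0):
                raise ValueError(
                    "configuration error: weights must lie in [0,1] with max 1"
                )
            self.spatial_profile = w

    @property
    def channel_labels(self) -> tuple[str, ...]:
        if self.n_channels == self.layout.n_channels:
            return self.layout.labels
        return tuple(f"ch{i:02d}" for i in range(self.n_channels))

    def profile(self) -> np.ndarray:
        if self.spatial_profile is not None:
            return self.spatial_profile
        if self.n_channels == self.layout.n_channels:
            return cz_gaussian_profile(self.layout, self.spatial_sigma)
        # generic fallback: peak at the middle channel, Gaussian over index
        idx = np.arange(self.n_channels, dtype=float)
        mid = (self.n_channels - 1) / 2.0
        w = np.exp(-((idx - mid) ** 2) / (2.0 * max(self.n_channels / 4.0, 1.0) ** 2))
        return w / w.max()


def _trial_rng(cfg: SyntheticConfig, trial_id: int) -> np.random.Generator:
    ss = np.random.SeedSequence(entropy=cfg.seed, spawn_key=(trial_id,))
    return np.random.default_rng(ss)


def _pink_noise(rng: np.random.Generator, shape: tuple[int, int], sd: float) -> np.ndarray:
    """Zero-mean 1/f-shaped noise, per-channel SD equal to ``sd``."""
    n = shape[1]
    white = rng.standard_normal(shape)
    spec = np.fft.rfft(white, axis=1)
    f = np.fft.rfftfreq(n)
    scale = np.ones_like(f)
    scale[1:] = 1.0 / np.sqrt(f[1:])
    spec *= scale
    x = np.fft.irfft(spec, n=n, axis=1)
    x -= x.mean(axis=1, keepdims=True)
    s = x.std(axis=1, keepdims=True)
    s[s == 0] = 1.0
    return sd * x / s


def inject_artifact(
    segment_data: np.ndarray,
    channel: int,
    amplitude: float,
    rng: np.random.Generator,
    fs: float = 500.0,
) -> np.ndarray:
    """Add a short (~0.2 s) blink-like transient at a random onset.

    The transient is a Hann bump whose peak equals ``amplitude``.  Returns a
    new array; the input is not modified.
    """
    if np.isnan(amplitude):
        raise ValueError("artifact amplitude must not be NaN")
    data = np.array(segment_data, dtype=float)
    if not 0 <= channel < data.shape[0]:
        raise IndexError(f"channel {channel} out of range")
    n = data.shape[1]
    dur = min(n, max(3, int(round(0.2 * fs))))
    onset = int(rng.integers(0, n - dur + 1))
    bump = amplitude * np.hanning(dur)
    data[channel, onset : onset + dur] += bump
    return data


def _marker_samples(cfg: SyntheticConfig, rng: np.random.Generator) -> list[int]:
    """Countdown marker samples relative to the "Start" cue."""
    gaps = cfg.marker_interval_s * (
        1.0 + cfg.marker_jitter * rng.uniform(-1.0, 1.0, size=len(MARKER_LABELS))
    )
    times = np.cumsum(gaps)
    return [int(round(t * cfg.fs)) for t in times]


def generate_trial(cfg: SyntheticConfig, trial_id: int) -> EEGRecording:
    """Generate one countdown trial, deterministic in ``(cfg.seed, trial_id)``.

    The stream carries ``context_s`` seconds of plain background before the
    "Start" cue and after the trial — as a continuous acquisition would —
    so later zero-phase filtering has room for its edge transients outside
    the analysed windows.  The six markers "5".."1","Stop" follow the cue at
    jittered ``marker_interval_s`` gaps.  The CNV ramp runs from
    ``cnv_onset`` (as a fraction of the 1→Stop window) to the "Stop" sample,
    where the Cz trace reaches exactly ``cnv_amplitude`` in the noiseless
    limit, then relaxes linearly back to baseline over the short post-stop
    tail.
    """
    if trial_id < 0:
        raise ValueError("trial_id must be >= 0")
    rng = _trial_rng(cfg, trial_id)
    ctx = int(round(cfg.context_s * cfg.fs))
    marks = [m + ctx for m in _marker_samples(cfg, rng)]
    n_samples = marks[-1] + max(1, int(round(cfg.post_stop_s * cfg.fs))) + 1 + ctx

    shape = (cfg.n_channels, n_samples)
    if cfg.noise_sd > 0:
        noise = (
            _pink_noise(rng, shape, cfg.noise_sd)
            if cfg.one_over_f
            else rng.normal(0.0, cfg.noise_sd, size=shape)
        )
    else:
        noise = np.zeros(shape)
    data = noise

    # CNV: linear ramp 0 → cnv_amplitude inside the 1→Stop window, scaled by
    # the centro-medial spatial profile; linear recovery after "Stop".
    m1, mstop = marks[-2], marks[-1]
    onset = m1 + cfg.cnv_onset * (mstop - m1)
    t = np.arange(n_samples, dtype=float)
    ramp = np.clip((t - onset) / max(mstop - onset, 1.0), 0.0, None)
    ramp[t > mstop] = np.clip(
        1.0 - (t[t > mstop] - mstop) / max(n_samples - 1 - mstop, 1.0), 0.0, 1.0
    )
    ramp = np.minimum(ramp, 1.0)
    data = data + cfg.cnv_amplitude * np.outer(cfg.profile(), ramp)

    # blink-like artifacts, at most one per inter-marker window
    labels = cfg.channel_labels
    frontal = [i for i, lab in enumerate(labels) if lab in ("Fp1", "Fp2")]
    bounds = [ctx] + marks  # windows between the Start cue and the markers
    for a, b in zip(bounds, bounds[1:]):
        if b - a > 3 and rng.uniform() < cfg.artifact_rate:
            ch = int(rng.choice(frontal)) if frontal else int(rng.integers(cfg.n_channels))
            data[:, a:b] = inject_artifact(
                data[:, a:b], ch, cfg.artifact_amplitude, rng, fs=cfg.fs
            )

    markers = ([(ctx, START_LABEL)] if ctx > 0 else []) + list(zip(marks, MARKER_LABELS))
    return EEGRecording(data=data, fs=cfg.fs, labels=labels, markers=markers, trial_id=trial_id)


def generate_dataset(cfg: SyntheticConfig) -> list[EEGRecording]:
    """Generate ``cfg.n_trials`` trials with independent per-trial seed streams."""
    return [generate_trial(cfg, i) for i in range(cfg.n_trials)]


# ---------------------------------------------------------------------------
# plain-text export (round-trips through cnvsnn.io readers)

def write_trial(rec: EEGRecording, matrix_path, marker_path) -> None:
    """Write one trial as a delimited matrix (columns = channels) + markers."""
    header = ",".join(rec.labels)
    np.savetxt(matrix_path, rec.data.T, delimiter=",", header=header, comments="", fmt="%.6f")
    with open(marker_path, "w") as fh:
        fh.write("sample_index,label\n")
        for idx, lab in rec.markers:
            fh.write(f"{idx},{lab}\n")


def write_dataset(recordings: list[EEGRecording], out_dir, cfg: SyntheticConfig) -> Path:
    """Write all trials plus a manifest describing the generating config."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    entries = []
    for rec in recordings:
        mat = out / f"trial{rec.trial_id:04d}_eeg.csv"
        mrk = out / f"trial{rec.trial_id:04d}_markers.csv"
        write_trial(rec, mat, mrk)
        entries.append({"trial_id": rec.trial_id, "matrix": mat.name, "markers": mrk.name})
    manifest = {
        "config": {
            "n_trials": cfg.n_trials,
            "n_channels": cfg.n_channels,
            "fs": cfg.fs,
            "marker_interval_s": cfg.marker_interval_s,
            "marker_jitter": cfg.marker_jitter,
            "cnv_amplitude": cfg.cnv_amplitude,
            "cnv_onset": cfg.cnv_onset,
            "noise_sd": cfg.noise_sd,
            "one_over_f": cfg.one_over_f,
            "artifact_rate": cfg.artifact_rate,
            "artifact_amplitude": cfg.artifact_amplitude,
            "post_stop_s": cfg.post_stop_s,
            "context_s": cfg.context_s,
            "seed": cfg.seed,
        },
        "trials": entries,
    }
    path = out / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2))
    return path
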