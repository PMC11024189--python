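"""Configuration loading, the end-to-end pipeline, and run manifests.

A single YAML/JSON key-value file configures every stage; all defaults are
the full-scale protocol values (LIF β 0.5, θ 0.5, k 0.25, 25 steps; Adam lr
5e-4; batch 8; patience 50; pad length 1848; 0.1–1 Hz band).  Unknown keys
are rejected and type mismatches name the offending key.  A run writes its
result tables plus a manifest (config snapshot, per-fold seeds, output
digests, timestamps) that fully determines a re-run.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import synthio, train_eval
from .models import CNN, CSNN, CSNNConfig, GNNClassifier, GNNConfig, build_adjacency
from .models.lif import LIFParams
from .preprocess import CleaningConfig, PreprocessConfig, preprocess_recordings
from .train_eval import TrainConfig, fold_seed, segments_to_arrays, summarize

__all__ = ["PipelineConfig", "ConfigError", "RunManifest", "load_config", "run_pipeline"]


class ConfigError(ValueError):
    """Malformed or inconsistent configuration."""


@dataclass
class SynthSection:
    n_trials: int = 10
    n_channels: int = 19
    fs: float = 500.0
    marker_interval_s: float = 1.0
    marker_jitter: float = 0.1
    cnv_amplitude: float = -10.0
    cnv_onset: float = 0.0
    noise_sd: float = 5.0
    one_over_f: bool = False
    artifact_rate: float = 0.05
    artifact_amplitude: float = 150.0
    post_stop_s: float = 0.25
    context_s: float = 2.0
    seed: int = 0


@dataclass
class PreprocessSection:
    lo: float = 0.1
    hi: float = 1.0
    numtaps: int | None = None
    target_len: int = 1848
    include_prestart: bool = True
    normalize_unpadded: bool = False
    recording_cleaning: bool = True
    amplitude_limit: float = 100.0
    z_limit: float = 3.0
    max_bad_fraction: float = 0.10
    max_removed_channels: int = 10


@dataclass
class LIFSection:
    beta: float = 0.5
    theta: float = 0.5
    k: float = 0.25
    n_steps: int = 25


@dataclass
class TrainSection:
    max_epochs: int = 1000
    batch_size: int = 8
    patience: int = 50
    lr: float = 5e-4
    seed: int = 0
    folds: int = 10


@dataclass
class PipelineConfig:
    synth: SynthSection = field(default_factory=SynthSection)
    preprocess: PreprocessSection = field(default_factory=PreprocessSection)
    lif: LIFSection = field(default_factory=LIFSection)
    train: TrainSection = field(default_factory=TrainSection)
    case: str = "full19"
    models: tuple[str, ...] = ("csnn",)
    thresholds: tuple[float, ...] = (0.05, 0.25, 0.375, 0.5, 0.625, 0.75, 1.0)
    gnn_layer_sizes: tuple[int, ...] | None = None
    gnn_mlp_hidden: tuple[int, ...] = (256, 256, 256, 256, 256)


_SECTIONS = {
    "synth": SynthSection,
    "preprocess": PreprocessSection,
    "lif": LIFSection,
    "train": TrainSection,
}


def _coerce(value, target, key: str):
    if target is bool:
        if not isinstance(value, bool):
            raise ConfigError(f"key {key!r}: expected bool, got {type(value).__name__}")
        return value
    if target is int:
        if isinstance(value, bool) or not isinstance(value, int):
            raise ConfigError(f"key {key!r}: expected int, got {type(value).__name__}")
        return value
    if target is float:
        if isinstance(value, bool) or not isinstance(value, (int, float)):
            raise ConfigError(f"key {key!r}: expected float, got {type(value).__name__}")
        return float(value)
    if target is str:
        if not isinstance(value, str):
            raise ConfigError(f"key {key!r}: expected str, got {type(value).__name__}")
        return value
    return value


def _build_section(cls, d: dict, prefix: str):
    fields = {f.name: f for f in dataclasses.fields(cls)}
    unknown = set(d) - set(fields)
    if unknown:
        raise ConfigError(f"unknown key {prefix}{sorted(unknown)[0]!r}")
    kwargs = {}
    for name, value in d.items():
        f = fields[name]
        key = f"{prefix}{name}"
        t = f.type
        if value is None:
            kwargs[name] = None
            continue
        if t in ("int", "int | None"):
            kwargs[name] = _coerce(value, int, key)
        elif t == "float":
            kwargs[name] = _coerce(value, float, key)
        elif t == "bool":
            kwargs[name] = _coerce(value, bool, key)
        elif t == "str":
            kwargs[name] = _coerce(value, str, key)
        elif t.startswith("tuple"):
            if not isinstance(value, (list, tuple)):
                raise ConfigError(f"key {key!r}: expected a list")
            kwargs[name] = tuple(value)
        else:
            kwargs[name] = value
    return cls(**kwargs)


def load_config(path) -> PipelineConfig:
    """Load and validate a pipeline config; missing keys take the defaults."""
    text = Path(path).read_text()
    raw = yaml.safe_load(text)
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ConfigError("config root must be a mapping")
    return config_from_dict(raw)


def config_from_dict(raw: dict) -> PipelineConfig:
    top_fields = {f.name for f in dataclasses.fields(PipelineConfig)}
    unknown = set(raw) - top_fields
    if unknown:
        raise ConfigError(f"unknown key {sorted(unknown)[0]!r}")
    kwargs: dict = {}
    for name, cls in _SECTIONS.items():
        if name in raw:
            section = raw[name]
            if not isinstance(section, dict):
                raise ConfigError(f"key {name!r}: expected a mapping")
            kwargs[name] = _build_section(cls, section, f"{name}.")
    rest = {k: v for k, v in raw.items() if k not in _SECTIONS}
    cfg = _build_section(PipelineConfig, rest, "")
    for name, value in kwargs.items():
        setattr(cfg, name, value)
    if cfg.case not in ("full19", "ablation5", "spike_sweep"):
        raise ConfigError(f"key 'case': unknown case {cfg.case!r}")
    for m in cfg.models:
        if m not in ("csnn", "cnn", "gcn", "gcs", "gin"):
            raise ConfigError(f"key 'models': unknown model {m!r}")
    return cfg


@dataclass
class RunManifest:
    """Everything needed to reproduce a run."""

    config: dict
    fold_seeds: list[int]
    outputs: dict[str, str]  # path → sha256
    started: str = ""
    finished: str = ""
    failed_stage: str | None = None

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2)


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def model_factories(cfg: PipelineConfig) -> dict:
    """Name → factory(input_shape, seed, train_X) for the configured models."""
    lif = LIFParams(beta=cfg.lif.beta, theta=cfg.lif.theta, k=cfg.lif.k, n_steps=cfg.lif.n_steps)
    csnn_cfg = CSNNConfig(lif=lif)

    def make_csnn(shape, seed, train_X=None):
        return CSNN(shape, csnn_cfg, seed=seed)

    def make_cnn(shape, seed, train_X=None):
        return CNN(shape, csnn_cfg, seed=seed)

    def make_gnn(arch):
        def f(shape, seed, train_X=None):
            if train_X is None:
                raise ValueError("GNN factory needs training data for the adjacency")
            adj = build_adjacency(train_X)
            gcfg = GNNConfig(
                arch=arch, layer_sizes=cfg.gnn_layer_sizes, gin_mlp_hidden=cfg.gnn_mlp_hidden
            )
            return GNNClassifier(shape, adj, gcfg, seed=seed)

        return f

    table = {
        "csnn": make_csnn,
        "cnn": make_cnn,
        "gcn": make_gnn("gcn"),
        "gcs": make_gnn("gcs"),
        "gin": make_gnn("gin"),
    }
    return {m: table[m] for m in cfg.models}


def run_pipeline(cfg: PipelineConfig, out_dir) -> RunManifest:
    """simulate → preprocess → (encode) → train/eval, writing result tables.

    Deterministic for a fixed config: re-running reproduces the tables.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(
        config=dataclasses.asdict(cfg),
        fold_seeds=[fold_seed(cfg.train.seed, i) for i in range(cfg.train.folds)],
        outputs={},
        started=time.strftime("%Y-%m-%dT%H:%M:%S"),
    )
    stage = "simulate"
    try:
        s = cfg.synth
        scfg = synthio.SyntheticConfig(
            n_trials=s.n_trials, n_channels=s.n_channels, fs=s.fs,
            marker_interval_s=s.marker_interval_s, marker_jitter=s.marker_jitter,
            cnv_amplitude=s.cnv_amplitude, cnv_onset=s.cnv_onset, noise_sd=s.noise_sd,
            one_over_f=s.one_over_f, artifact_rate=s.artifact_rate,
            artifact_amplitude=s.artifact_amplitude, post_stop_s=s.post_stop_s,
            context_s=s.context_s, seed=s.seed,
        )
        recordings = synthio.generate_dataset(scfg)

        stage = "preprocess"
        p = cfg.preprocess
        pcfg = PreprocessConfig(
            lo=p.lo, hi=p.hi, numtaps=p.numtaps,
            cleaning=CleaningConfig(
                amplitude_limit=p.amplitude_limit, z_limit=p.z_limit,
                max_bad_fraction=p.max_bad_fraction,
                max_removed_channels=p.max_removed_channels,
            ),
            target_len=p.target_len, include_prestart=p.include_prestart,
            normalize_unpadded=p.normalize_unpadded,
            recording_cleaning=p.recording_cleaning,
        )
        segments, n_rejected = preprocess_recordings(recordings, pcfg, scfg.layout)
        X, y, labels = segments_to_arrays(segments)

        stage = "train"
        tcfg = TrainConfig(
            max_epochs=cfg.train.max_epochs, batch_size=cfg.train.batch_size,
            patience=cfg.train.patience, lr=cfg.train.lr, seed=cfg.train.seed,
        )
        factories = model_factories(cfg)
        results = train_eval.run_case(
            cfg.case, (X, y), factories, tcfg, k=cfg.train.folds,
            thresholds=cfg.thresholds, channel_labels=labels,
        )
        results_path = out / "results.csv"
        results.to_csv(results_path, index=False)

        per_model = {}
        for name, group in results.groupby("model"):
            per_model[name] = [
                train_eval.FoldResult(
                    fold=int(r.fold), tp=int(r.tp), fp=int(r.fp), tn=int(r.tn),
                    fn=int(r.fn), epochs_trained=int(r.epochs), model=name,
                )
                for r in group.itertuples()
            ]
        ref = "csnn" if "csnn" in per_model else next(iter(per_model))
        summary = summarize(per_model, ref)
        summary_path = out / "summary.csv"
        summary.table.to_csv(summary_path)

        manifest.outputs = {
            "results.csv": _digest(results_path),
            "summary.csv": _digest(summary_path),
        }
        manifest.config["n_segments"] = int(len(y))
        manifest.config["n_rejected_segments"] = int(n_rejected)
    except Exception:
        manifest.failed_stage = stage
        manifest.finished = time.strftime("%Y-%m-%dT%H:%M:%S")
        (out / "manifest.json").write_text(manifest.to_json())
        raise
    manifest.finished = time.strftime("%Y-%m-%dT%H:%M:%S")
    (out / "manifest.json").write_text(manifest.to_json())
    return manifest
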