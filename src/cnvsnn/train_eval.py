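"""Class-weighted training, stratified 10-fold CV, metrics and case drivers.

The protocol mirrors the study design: per fold, models are re-initialized
from a fold-specific seed shared across architectures, trained with Adam
(lr 5e-4) and a class-weighted binary cross entropy — weights
``w_c = N_D / (2·N_c)`` computed on the training partition only — for up to
``max_epochs`` with early termination once the training loss has not
improved for ``patience`` consecutive epochs.  Per-fold confusion counts
yield Acc/TPR/TNR/F1; across-fold summaries report mean (SD) and
two-sample t-tests against a reference model.

Three experiment drivers: ``full19`` (all channels, floating-point input,
all models), ``ablation5`` (Cz, Pz, C3, C4, Fz only) and ``spike_sweep``
(delta-modulated input to the CSNN over a threshold grid).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.model_selection import StratifiedKFold

from .core import Segment
from .encode import FULL_SWEEP_THRESHOLDS
from .nn.optim import Adam
from .preprocess import ABLATION_CHANNELS

__all__ = [
    "TrainConfig",
    "ClassWeights",
    "FoldResult",
    "MetricsSummary",
    "class_weights",
    "stratified_kfold",
    "train_model",
    "evaluate",
    "summarize",
    "cross_validate",
    "run_case",
    "segments_to_arrays",
]

METRICS = ("acc", "tpr", "tnr", "f1")


@dataclass
class TrainConfig:
    """Optimization constants (study defaults)."""

    max_epochs: int = 1000
    batch_size: int = 8
    patience: int = 50
    lr: float = 5e-4
    beta1: float = 0.9
    beta2: float = 0.999
    eps: float = 1e-8
    seed: int = 0

    def __post_init__(self) -> None:
        if self.lr <= 0:
            raise ValueError("learning rate must be positive")
        if not 0 < self.patience < self.max_epochs:
            raise ValueError("require 0 < patience < max_epochs")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")


@dataclass
class ClassWeights:
    """Per-class loss weights ``w_c = N_D / (2·N_c)``."""

    w0: float
    w1: float
    n_total: int
    n_class: tuple[int, int]

    def per_sample(self, y: np.ndarray) -> np.ndarray:
        return np.where(np.asarray(y) == 1, self.w1, self.w0)


def class_weights(labels: np.ndarray) -> ClassWeights:
    """Weights from the training partition; both classes must be present."""
    y = np.asarray(labels)
    n0, n1 = int((y == 0).sum()), int((y == 1).sum())
    if n0 == 0 or n1 == 0:
        raise ValueError("both classes must be present in the training partition")
    nd = n0 + n1
    return ClassWeights(w0=nd / (2.0 * n0), w1=nd / (2.0 * n1), n_total=nd, n_class=(n0, n1))


def stratified_kfold(labels: np.ndarray, k: int = 10, seed: int = 0):
    """Shuffled stratified folds preserving the class ratio within ±1 sample."""
    y = np.asarray(labels)
    counts = np.bincount(y)
    if (counts[counts > 0] < k).any():
        raise ValueError(f"every class needs at least k={k} members")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    return [(tr, te) for tr, te in skf.split(np.zeros(len(y)), y)]


@dataclass
class FoldResult:
    """Confusion counts and derived metrics for one test fold."""

    fold: int
    tp: int
    fp: int
    tn: int
    fn: int
    epochs_trained: int = 0
    model: str = ""

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    @property
    def acc(self) -> float:
        return (self.tp + self.tn) / self.n

    @property
    def tpr(self) -> float:
        d = self.tp + self.fn
        return self.tp / d if d else 0.0

    @property
    def tnr(self) -> float:
        d = self.tn + self.fp
        return self.tn / d if d else 0.0

    @property
    def f1(self) -> float:
        d = 2 * self.tp + self.fp + self.fn
        return 2 * self.tp / d if d else 0.0

    def metric(self, name: str) -> float:
        return getattr(self, name)


def train_model(model, train_data, cfg: TrainConfig, weights: ClassWeights | None = None):
    """Train in place; returns (model, history dict with per-epoch loss).

    Stops at ``max_epochs`` or when the epoch training loss has not been
    strictly lower than the best so far for ``patience`` consecutive
    epochs.  Deterministic for a fixed seed.
    """
    X, y = train_data
    X, y = np.asarray(X), np.asarray(y)
    if len(X) == 0:
        raise ValueError("empty training set")
    w = weights.per_sample(y) if weights is not None else None
    opt = Adam(model.parameters(), lr=cfg.lr, beta1=cfg.beta1, beta2=cfg.beta2, eps=cfg.eps)
    rng = np.random.default_rng(cfg.seed)
    history: list[float] = []
    best = np.inf
    stale = 0
    for epoch in range(cfg.max_epochs):
        order = rng.permutation(len(X))
        losses = []
        for start in range(0, len(X), cfg.batch_size):
            idx = order[start : start + cfg.batch_size]
            opt.zero_grad()
            loss = model.loss(X[idx], y[idx], None if w is None else w[idx])
            if not np.isfinite(loss.data):
                raise FloatingPointError(
                    f"divergent loss {loss.data!r} at epoch {epoch + 1}"
                )
            loss.backward()
            opt.step()
            losses.append(float(loss.data))
        epoch_loss = float(np.mean(losses))
        history.append(epoch_loss)
        if epoch_loss < best:
            best = epoch_loss
            stale = 0
        else:
            stale += 1
            if stale >= cfg.patience:
                break
    return model, {"loss": history, "epochs": len(history)}


def evaluate(model, test_data, fold: int = 0, batch: int = 64) -> FoldResult:
    """Confusion counts and metrics of the trained model on a test fold."""
    X, y = test_data
    X, y = np.asarray(X), np.asarray(y)
    if len(X) == 0:
        raise ValueError("empty test set")
    preds = np.concatenate(
        [model.predict(X[i : i + batch]) for i in range(0, len(X), batch)]
    )
    tp = int(((preds == 1) & (y == 1)).sum())
    fp = int(((preds == 1) & (y == 0)).sum())
    tn = int(((preds == 0) & (y == 0)).sum())
    fn = int(((preds == 0) & (y == 1)).sum())
    return FoldResult(fold=fold, tp=tp, fp=fp, tn=tn, fn=fn, model=getattr(model, "name", ""))


@dataclass
class MetricsSummary:
    """Across-fold mean (SD) per metric per model, with t-test p-values
    against a reference model."""

    table: pd.DataFrame  # rows: model; columns: metric mean/sd/p
    reference: str


def summarize(
    folds: dict[str, list[FoldResult]], reference: str, welch: bool = False
) -> MetricsSummary:
    """Mean/SD over folds and two-sample t-tests versus the reference.

    The default t-test is the classic equal-variance two-sided variant with
    df = 2k − 2; pass ``welch=True`` for the unequal-variance form.  When
    both samples have zero variance, p is 1 for equal means and 0 otherwise.
    """
    if reference not in folds:
        raise ValueError(f"reference model {reference!r} not in results")
    ref_vals = {m: np.array([f.metric(m) for f in folds[reference]]) for m in METRICS}
    rows = []
    for name, fr in folds.items():
        if len(fr) < 2:
            raise ValueError("need at least 2 folds per model")
        row: dict = {"model": name}
        for m in METRICS:
            vals = np.array([f.metric(m) for f in fr])
            row[f"{m}_mean"] = vals.mean()
            row[f"{m}_sd"] = vals.std(ddof=1)
            if name == reference:
                row[f"{m}_p"] = np.nan
            else:
                r = ref_vals[m]
                if r.std(ddof=1) == 0 and vals.std(ddof=1) == 0:
                    row[f"{m}_p"] = 1.0 if np.isclose(r.mean(), vals.mean()) else 0.0
                else:
                    row[f"{m}_p"] = float(
                        stats.ttest_ind(vals, r, equal_var=not welch).pvalue
                    )
        row["epochs_mean"] = float(np.mean([f.epochs_trained for f in fr]))
        rows.append(row)
    return MetricsSummary(table=pd.DataFrame(rows).set_index("model"), reference=reference)


def fold_seed(base_seed: int, fold: int) -> int:
    """Fold-specific init seed, shared across architectures (< 2^31)."""
    return (base_seed * 1009 + fold) % (2**31 - 1)


def cross_validate(
    factory,
    X: np.ndarray,
    y: np.ndarray,
    cfg: TrainConfig,
    k: int = 10,
    use_class_weights: bool = True,
) -> list[FoldResult]:
    """Stratified k-fold CV of one model family.

    ``factory(input_shape, seed, train_X)`` builds a fresh model per fold;
    class weights and any fitted statistic (e.g. the GNN adjacency) are
    computed on the training partition only.
    """
    X, y = np.asarray(X), np.asarray(y)
    results = []
    for i, (tr, te) in enumerate(stratified_kfold(y, k=k, seed=cfg.seed)):
        model = factory(X.shape[1:], fold_seed(cfg.seed, i), X[tr])
        w = class_weights(y[tr]) if use_class_weights else None
        fold_cfg = TrainConfig(
            max_epochs=cfg.max_epochs, batch_size=cfg.batch_size, patience=cfg.patience,
            lr=cfg.lr, beta1=cfg.beta1, beta2=cfg.beta2, eps=cfg.eps,
            seed=fold_seed(cfg.seed, i),
        )
        _, hist = train_model(model, (X[tr], y[tr]), fold_cfg, w)
        res = evaluate(model, (X[te], y[te]), fold=i)
        res.epochs_trained = hist["epochs"]
        res.model = getattr(model, "name", "")
        results.append(res)
    return results


def segments_to_arrays(segments: list[Segment]):
    """Stack processed segments into (X, y, channel_labels)."""
    X = np.stack([s.data for s in segments])
    y = np.array([s.label for s in segments], dtype=int)
    return X, y, segments[0].channel_labels


def _results_frame(per_model: dict[str, list[FoldResult]]) -> pd.DataFrame:
    rows = []
    for name, folds in per_model.items():
        for f in folds:
            rows.append(
                {
                    "model": name, "fold": f.fold, "tp": f.tp, "fp": f.fp,
                    "tn": f.tn, "fn": f.fn, "acc": f.acc, "tpr": f.tpr,
                    "tnr": f.tnr, "f1": f.f1, "epochs": f.epochs_trained,
                }
            )
    return pd.DataFrame(rows)


def run_case(
    case: str,
    dataset,
    models: dict,
    cfg: TrainConfig,
    k: int = 10,
    thresholds=FULL_SWEEP_THRESHOLDS,
    channel_labels: tuple[str, ...] | None = None,
) -> pd.DataFrame:
    """Run one benchmark case and return a tidy per-fold results table.

    ``dataset`` is ``(X, y)`` with X (n_segments, channels, time) already
    preprocessed to [0, 1].  ``models`` maps name → factory(input_shape,
    seed, train_X).  Cases: ``full19`` (all channels, all models),
    ``ablation5`` (Cz/Pz/C3/C4/Fz subset), ``spike_sweep`` (CSNN-style
    model over delta-modulation thresholds; one table row set per
    threshold).
    """
    X, y = dataset
    X, y = np.asarray(X), np.asarray(y)
    if case == "full19":
        per_model = {
            name: cross_validate(f, X, y, cfg, k=k) for name, f in models.items()
        }
        return _results_frame(per_model)
    if case == "ablation5":
        if channel_labels is None:
            raise ValueError("ablation5 needs channel_labels")
        idx = [channel_labels.index(c) for c in ABLATION_CHANNELS]
        Xa = X[:, idx]
        per_model = {
            name: cross_validate(f, Xa, y, cfg, k=k) for name, f in models.items()
        }
        return _results_frame(per_model)
    if case == "spike_sweep":
        if len(models) != 1:
            raise ValueError("spike_sweep runs a single (CSNN) model family")
        ((name, factory),) = models.items()
        frames = []
        for th in thresholds:
            spikes = np.zeros_like(X)
            spikes[:, :, 1:] = np.abs(np.diff(X, axis=2)) > th
            folds = cross_validate(factory, spikes, y, cfg, k=k)
            frame = _results_frame({name: folds})
            frame.insert(0, "threshold", th)
            frames.append(frame)
        return pd.concat(frames, ignore_index=True)
    raise ValueError(f"unknown case {case!r}")
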