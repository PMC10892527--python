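"""Seeded training, repeated runs, K-fold cross-validation, sweeps, ablations.

Training minimizes softmax cross-entropy with Adam (the fixed learning-rate
grids spanning 1e-4..5e-2 that the sweeps use are only workable with an
adaptive optimizer; SGD + momentum is available by config).  Every source of
randomness — weight initialization, minibatch order, splits — derives from
the config seed, so a run is reproducible bit-for-bit on the same backend.
"""

from __future__ import annotations

import itertools
import time
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold

from . import nn
from .exceptions import (DivergenceError, EmptyDatasetError, SizeError,
                         StratificationError)
from .metrics import MetricsReport, build_report, confusion_matrix
from .networks import NetworkSpec, build_3d_rnet_o, count_parameters, instantiate
from .preprocess import PatchDataset, SplitSpec, standardize, stratified_split

__all__ = [
    "TrainConfig", "TrainResult", "CVResult",
    "train_model", "evaluate_model", "repeat_experiment", "kfold_cv",
    "ablation_suite", "hyperparameter_sweep",
]


@dataclass(frozen=True)
class TrainConfig:
    """Hyperparameters of one training run."""

    learning_rate: float = 0.003
    epochs: int = 200
    batch_size: int = 64
    optimizer: str = "adam"
    momentum: float = 0.9  # SGD only
    seed: int = 0

    def __post_init__(self):
        if self.learning_rate <= 0:
            raise SizeError("learning rate must be > 0")
        if self.epochs < 1:
            raise SizeError("epochs must be >= 1")
        if self.optimizer not in {"adam", "sgd"}:
            raise SizeError(f"unknown optimizer {self.optimizer!r}")


@dataclass
class TrainResult:
    """History, fitted model and provenance of one training run."""

    history: pd.DataFrame  # one row per epoch: loss, accuracy[, val_accuracy]
    model: nn.Network
    wall_time: float
    seed: int
    config: TrainConfig
    spec_name: str = ""

    def summary(self) -> str:
        last = self.history.iloc[-1]
        lines = [f"Training run: {self.spec_name or self.model.name}",
                 f"  epochs: {len(self.history)}  seed: {self.seed}  "
                 f"lr: {self.config.learning_rate}  "
                 f"batch: {self.config.batch_size}",
                 f"  parameters: {self.model.n_parameters():,}",
                 f"  final loss: {last['loss']:.4f}  "
                 f"train acc: {100 * last['accuracy']:.2f}%"]
        if "val_accuracy" in self.history and np.isfinite(last.get("val_accuracy", np.nan)):
            lines.append(f"  val acc: {100 * last['val_accuracy']:.2f}%")
        lines.append(f"  wall time: {self.wall_time:.1f} s")
        return "\n".join(lines)


def _make_optimizer(model: nn.Network, cfg: TrainConfig):
    if cfg.optimizer == "adam":
        return nn.Adam(model.params(), cfg.learning_rate)
    return nn.SGD(model.params(), cfg.learning_rate, cfg.momentum)


def train_model(spec: NetworkSpec, train: PatchDataset,
                val: PatchDataset | None, cfg: TrainConfig) -> TrainResult:
    """Train a network spec on a patch dataset.

    Labels must lie in 1..n_classes.  Raises :class:`DivergenceError` naming
    the epoch if the loss goes non-finite.
    """
    if len(train) == 0:
        raise EmptyDatasetError("training set is empty")
    if train.labels.min() < 1 or train.labels.max() > spec.head.n_classes:
        raise SizeError(f"labels must lie in 1..{spec.head.n_classes}")
    if not train.standardized:
        warnings.warn("training on non-standardized patches", stacklevel=2)

    t0 = time.perf_counter()
    model = instantiate(spec, cfg.seed)
    opt = _make_optimizer(model, cfg)
    shuffle_rng = np.random.default_rng((cfg.seed, 0x5eed))

    n = len(train)
    y0 = (train.labels - 1).astype(np.int64)
    rows = []
    for epoch in range(cfg.epochs):
        order = shuffle_rng.permutation(n)
        losses, hits = [], 0
        for start in range(0, n, cfg.batch_size):
            idx = order[start:start + cfg.batch_size]
            x = model.patches_to_input(train.patches[idx])
            logits = model.forward(x, train=True)
            loss, grad = nn.cross_entropy(logits, y0[idx])
            if not np.isfinite(loss):
                raise DivergenceError(epoch)
            opt.zero_grad()
            model.backward(grad)
            opt.step()
            losses.append(loss * len(idx))
            hits += int((logits.argmax(axis=1) == y0[idx]).sum())
        row = {"epoch": epoch, "loss": sum(losses) / n, "accuracy": hits / n}
        if val is not None and len(val):
            pred = model.predict(val.patches)
            row["val_accuracy"] = float(np.mean(pred == val.labels))
        rows.append(row)
    history = pd.DataFrame(rows)
    return TrainResult(history, model, time.perf_counter() - t0, cfg.seed,
                       cfg, spec.name)


def evaluate_model(model: nn.Network, test: PatchDataset,
                   class_names: list[str] | None = None) -> MetricsReport:
    """Score argmax predictions on a held-out patch dataset."""
    if len(test) == 0:
        raise EmptyDatasetError("test set is empty")
    pred = model.predict(test.patches)
    cm = confusion_matrix(test.labels, pred, model.n_classes, class_names)
    return build_report(cm)


def repeat_experiment(spec: NetworkSpec, train: PatchDataset,
                      val: PatchDataset | None, test: PatchDataset,
                      cfg: TrainConfig, n_runs: int,
                      full_ds: PatchDataset | None = None,
                      split_spec: SplitSpec | None = None
                      ) -> tuple[pd.DataFrame, dict]:
    """Average metrics over repeated runs differing only in derived seeds.

    By default, runs reinitialize weights and minibatch order only.  Passing
    ``full_ds`` + ``split_spec`` additionally resamples the split each run
    (both conventions are plausible readings of repeated-experiment
    averaging, so both are provided).
    """
    if n_runs < 1:
        raise SizeError("n_runs must be >= 1")
    rows = []
    for run in range(n_runs):
        run_cfg = replace(cfg, seed=cfg.seed + run)
        if full_ds is not None:
            sp = replace(split_spec or SplitSpec(), seed=(split_spec or SplitSpec()).seed + run)
            tr, va, te = stratified_split(full_ds, sp)
            (tr, *rest), _ = standardize(tr, *( [va] if len(va) else [] ), te)
            te = rest[-1]
            va = rest[0] if len(rest) == 2 else None
        else:
            tr, va, te = train, val, test
        result = train_model(spec, tr, va, run_cfg)
        report = evaluate_model(result.model, te)
        rows.append({"run": run, "seed": run_cfg.seed, "OA": report.oa,
                     "AA": report.aa, "kappa": report.kappa})
    df = pd.DataFrame(rows)
    agg = {}
    for col in ("OA", "AA", "kappa"):
        agg[col] = {"mean": float(df[col].mean()), "sd": float(df[col].std(ddof=0))}
    return df, agg


@dataclass
class CVResult:
    """K-fold cross-validation outcome."""

    K: int
    fold_accuracies: np.ndarray  # percent
    mean_accuracy: float
    accuracy_variance: float     # population variance over folds

    def summary(self) -> str:
        folds = "  ".join(f"{a:.2f}" for a in self.fold_accuracies)
        return (f"{self.K}-fold cross-validation\n"
                f"  fold OA (%): {folds}\n"
                f"  mean: {self.mean_accuracy:.2f}  "
                f"variance: {self.accuracy_variance:.4f}")


def kfold_cv(ds: PatchDataset, K: int, spec: NetworkSpec,
             cfg: TrainConfig) -> CVResult:
    """Stratified K-fold: each sample tested exactly once; folds seeded."""
    if K < 2:
        raise SizeError("K must be >= 2")
    if K > len(ds):
        raise SizeError(f"K={K} exceeds dataset size {len(ds)}")
    _, counts = np.unique(ds.labels, return_counts=True)
    if counts.min() < K:
        raise StratificationError(
            f"smallest class has {counts.min()} samples < K={K}")
    skf = StratifiedKFold(n_splits=K, shuffle=True,
                          random_state=cfg.seed % (2 ** 31))
    accs = []
    for fold, (tr_idx, te_idx) in enumerate(skf.split(ds.patches[:, 0, 0, 0],
                                                      ds.labels)):
        tr, te = ds.subset(tr_idx), ds.subset(te_idx)
        (tr, te), _ = standardize(tr, te)
        fold_cfg = replace(cfg, seed=cfg.seed + fold)
        result = train_model(spec, tr, None, fold_cfg)
        report = evaluate_model(result.model, te)
        accs.append(report.oa)
    accs = np.asarray(accs)
    return CVResult(K, accs, float(accs.mean()), float(accs.var(ddof=0)))


# ---------------------------------------------------------------------------
# Ablations and sweeps
# ---------------------------------------------------------------------------

_ABLATION_CONFIGS = (
    ("a", False, False),
    ("b", True, False),
    ("c", False, True),
    ("d", True, True),
)


def ablation_suite(train: PatchDataset, val: PatchDataset | None,
                   test: PatchDataset, cfg: TrainConfig,
                   widths: tuple[int, int, int, int] = (128, 256, 512, 1024),
                   a: int = 3,
                   stem_kernel: tuple[int, int, int] = (3, 5, 5),
                   pool_window: tuple[int, int, int] = (2, 2, 2),
                   n_classes: int | None = None) -> pd.DataFrame:
    """Branch ablation: plain 3-D block (a), +first (b), +second (c), +both (d).

    All four variants train under identical seeds and data; the table carries
    OA/AA/kappa and the parameter count per variant.
    """
    k = n_classes or train.n_classes
    rows = []
    for label, b1, b2 in _ABLATION_CONFIGS:
        spec = build_3d_rnet_o(widths=widths, a=a, stem_kernel=stem_kernel,
                               pool_window=pool_window, n_classes=k,
                               branches=(b1, b2),
                               default_input=(train.B, train.S, train.S))
        result = train_model(spec, train, val, cfg)
        report = evaluate_model(result.model, test)
        rows.append({"config": label, "3d_conv": True,
                     "first_branch": b1, "second_branch": b2,
                     "OA": report.oa, "AA": report.aa, "kappa": report.kappa,
                     "params": count_parameters(spec)})
    return pd.DataFrame(rows)


_SWEEP_AXES = ("learning_rate", "stage_widths", "train_fraction",
               "pool_window", "stem_kernel")


def hyperparameter_sweep(ds: PatchDataset, grid: dict, cfg: TrainConfig,
                         base_split: SplitSpec | None = None,
                         widths: tuple[int, int, int, int] = (128, 256, 512, 1024),
                         a: int = 3,
                         stem_kernel: tuple[int, int, int] = (3, 5, 5),
                         pool_window: tuple[int, int, int] = (2, 2, 2),
                         mode: str = "marginal") -> pd.DataFrame:
    """Sweep hyperparameter axes over a full (unsplit) patch dataset.

    ``grid`` maps axis names (learning_rate, stage_widths, train_fraction,
    pool_window, stem_kernel) to value lists.  ``marginal`` mode varies one
    axis at a time from the baseline (one row per value); ``product`` mode
    runs the full Cartesian product.  An empty grid yields the single
    baseline row.  Fixed seeds throughout.
    """
    for axis in grid:
        if axis not in _SWEEP_AXES:
            raise SizeError(f"unknown sweep axis {axis!r}; "
                            f"expected one of {_SWEEP_AXES}")
    if mode not in {"marginal", "product"}:
        raise SizeError("mode must be 'marginal' or 'product'")
    base_split = base_split or SplitSpec(0.7, 0.0, 0.3, seed=cfg.seed)
    baseline = {"learning_rate": cfg.learning_rate, "stage_widths": tuple(widths),
                "train_fraction": base_split.train,
                "pool_window": tuple(pool_window),
                "stem_kernel": tuple(stem_kernel)}

    if not grid:
        cells = [dict(baseline)]
    elif mode == "marginal":
        cells = []
        for axis, values in grid.items():
            for v in values:
                cell = dict(baseline)
                cell[axis] = tuple(v) if isinstance(v, (list, tuple)) else v
                cell["_axis"] = axis
                cells.append(cell)
    else:
        axes = list(grid)
        cells = []
        for combo in itertools.product(*(grid[ax] for ax in axes)):
            cell = dict(baseline)
            for ax, v in zip(axes, combo):
                cell[ax] = tuple(v) if isinstance(v, (list, tuple)) else v
            cells.append(cell)

    n_classes = ds.n_classes
    rows = []
    for cell in cells:
        frac = float(cell["train_fraction"])
        if abs(frac - base_split.train) > 1e-12:
            # the training-ratio sweep holds validation at 10%
            split = SplitSpec(frac, 0.1, round(1.0 - frac - 0.1, 12),
                              seed=base_split.seed)
        else:
            split = base_split
        tr, va, te = stratified_split(ds, split)
        parts, _ = standardize(tr, *( [va] if len(va) else [] ), te)
        tr, te = parts[0], parts[-1]
        va = parts[1] if len(parts) == 3 else None
        spec = build_3d_rnet_o(widths=cell["stage_widths"], a=a,
                               stem_kernel=cell["stem_kernel"],
                               pool_window=cell["pool_window"],
                               n_classes=n_classes,
                               default_input=(ds.B, ds.S, ds.S))
        run_cfg = replace(cfg, learning_rate=float(cell["learning_rate"]))
        result = train_model(spec, tr, va, run_cfg)
        report = evaluate_model(result.model, te)
        row = {k: v for k, v in cell.items() if not k.startswith("_")}
        if "_axis" in cell:
            row["swept_axis"] = cell["_axis"]
        row.update({"OA": report.oa, "AA": report.aa, "kappa": report.kappa})
        rows.append(row)
    return pd.DataFrame(rows)
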