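"""Hyperparameter search with cross-validated reconstruction error.

Model selection uses a partial k-fold protocol: the samples are split into
``k`` near-equal folds (default 8) but only ``n_eval`` of them (default 4,
chosen in seeded order) are actually evaluated -- each evaluated fold is
held out while a DBN is trained on the complement, and the held-out MSE is
recorded per fine-tuning epoch.  Configurations are compared on the mean
final held-out error; a configuration whose final held-out error exceeds its
own per-epoch minimum by more than a margin (default 5%) is flagged as
overfitting.  Architectures are chosen by inspecting 'elbows' in the error
vs layer-size curve; :func:`elbow` reports the maximum-curvature point but
never auto-applies it.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dbn import DbnModel, TrainConfig, finetune, stack_pretrain, unfold

logger = logging.getLogger(__name__)


@dataclass
class FoldPlan:
    """k disjoint folds covering all samples; ``eval_folds`` are the fold
    indices actually held out for evaluation."""

    folds: list[np.ndarray]
    eval_folds: list[int]

    @property
    def k(self) -> int:
        return len(self.folds)


def make_folds(n_samples: int, k: int = 8, n_eval: int = 4,
               seed: int = 0) -> FoldPlan:
    """Seeded split into ``k`` near-equal disjoint folds; the first
    ``n_eval`` folds of a seeded fold-order are marked for evaluation."""
    if k > n_samples:
        raise ValueError(f"k={k} exceeds n_samples={n_samples}")
    if not 1 <= n_eval <= k:
        raise ValueError("n_eval must be in 1..k")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n_samples)
    folds = [np.sort(f) for f in np.array_split(perm, k)]
    eval_folds = list(rng.permutation(k)[:n_eval])
    return FoldPlan(folds=folds, eval_folds=eval_folds)


@dataclass
class EvaluationRecord:
    """Cross-validated outcome for one hyperparameter configuration."""

    config: TrainConfig
    test_curves: list[list[float]]      # per evaluated fold, per epoch held-out MSE
    mean_test_error: float
    train_error: float
    overfit_flag: bool
    error: str | None = None            # training failure, recorded not fatal

    def mean_curve(self) -> np.ndarray:
        return np.mean(np.asarray(self.test_curves), axis=0)


def _train_eval(cfg: TrainConfig, train: np.ndarray, test: np.ndarray):
    rng = np.random.default_rng(cfg.seed)
    rbms = stack_pretrain(train, cfg, rng=rng)
    model = unfold(rbms)
    model = finetune(model, train, cfg, rng=rng, eval_data=test)
    return model


def evaluate_config(
    cfg: TrainConfig,
    data: np.ndarray,
    folds: FoldPlan,
    overfit_margin: float = 0.05,
) -> EvaluationRecord:
    """Train on the complement of each evaluated fold; record held-out MSE
    per fine-tuning epoch.

    ``overfit_flag`` is set when the final mean held-out error exceeds the
    mean curve's minimum by more than ``overfit_margin`` (relative).
    Training failures are recorded in ``error`` rather than raised, so a
    sweep survives individual divergent configs.
    """
    data = np.asarray(data, dtype=float)
    curves: list[list[float]] = []
    train_errors: list[float] = []
    try:
        for fi in folds.eval_folds:
            test_idx = folds.folds[fi]
            train_idx = np.setdiff1d(np.arange(data.shape[0]), test_idx)
            model = _train_eval(cfg, data[train_idx], data[test_idx])
            curves.append(list(model.training_log["eval_mse"]))
            train_errors.append(model.training_log["finetune_mse"][-1])
    except RuntimeError as exc:  # divergence etc.
        logger.warning("config failed: %s", exc)
        return EvaluationRecord(config=cfg, test_curves=curves,
                                mean_test_error=float("inf"),
                                train_error=float("nan"),
                                overfit_flag=False, error=str(exc))
    mean_curve = np.mean(np.asarray(curves), axis=0)
    final = float(mean_curve[-1])
    overfit = final > float(mean_curve.min()) * (1.0 + overfit_margin)
    return EvaluationRecord(config=cfg, test_curves=curves,
                            mean_test_error=final,
                            train_error=float(np.mean(train_errors)),
                            overfit_flag=bool(overfit))


@dataclass
class SearchSpace:
    """Ranges for random search.  Learning rates are drawn log-uniformly;
    layer sizes, epochs and batch sizes are integer ranges.  Structural
    constraints: strictly decreasing layer sizes and a per-layer unit cap.
    """

    layer_size_ranges: list[tuple[int, int]] = field(
        default_factory=lambda: [(20, 120), (8, 60), (4, 20)])
    lr_pretrain_range: tuple[float, float] = (1e-4, 1e-1)
    lr_finetune_range: tuple[float, float] = (1e-3, 3e-1)
    epochs_pretrain_range: tuple[int, int] = (5, 30)
    epochs_finetune_range: tuple[int, int] = (10, 60)
    batch_size_range: tuple[int, int] = (10, 100)
    max_units: int | None = None
    decreasing_layers: bool = True

    def draw(self, rng: np.random.Generator, max_tries: int = 1000) -> TrainConfig:
        for _ in range(max_tries):
            sizes = tuple(int(rng.integers(lo, hi + 1))
                          for lo, hi in self.layer_size_ranges)
            if self.decreasing_layers and not all(
                    sizes[i] > sizes[i + 1] for i in range(len(sizes) - 1)):
                continue
            if self.max_units is not None and max(sizes) > self.max_units:
                continue
            return TrainConfig(
                layer_sizes=sizes,
                lr_pretrain=float(np.exp(rng.uniform(
                    np.log(self.lr_pretrain_range[0]),
                    np.log(self.lr_pretrain_range[1])))),
                lr_finetune=float(np.exp(rng.uniform(
                    np.log(self.lr_finetune_range[0]),
                    np.log(self.lr_finetune_range[1])))),
                epochs_pretrain=int(rng.integers(*self.epochs_pretrain_range)),
                epochs_finetune=int(rng.integers(*self.epochs_finetune_range)),
                batch_size=int(rng.integers(*self.batch_size_range)),
                seed=int(rng.integers(0, 2**31 - 1)),
            )
        raise ValueError("search-space constraints appear infeasible")


def random_search(
    space: SearchSpace,
    n_draws: int,
    data: np.ndarray,
    folds: FoldPlan,
    seed: int = 0,
) -> list[EvaluationRecord]:
    """Seeded random search; records ranked by mean held-out error."""
    if n_draws < 1:
        raise ValueError("n_draws must be >= 1")
    rng = np.random.default_rng(seed)
    records = [evaluate_config(space.draw(rng), data, folds)
               for _ in range(n_draws)]
    return sorted(records, key=lambda r: r.mean_test_error)


def grid_search(
    architectures: list[tuple[int, ...]],
    fixed: TrainConfig,
    data: np.ndarray,
    folds: FoldPlan,
) -> pd.DataFrame:
    """Evaluate each architecture with otherwise-fixed hyperparameters;
    returns a table for elbow inspection (one row per architecture)."""
    if not architectures:
        raise ValueError("empty architecture grid")
    rows = []
    for arch in architectures:
        rec = evaluate_config(fixed.replace(layer_sizes=tuple(arch)), data, folds)
        rows.append({
            "layer_sizes": "-".join(map(str, arch)),
            "n_layers": len(arch),
            "first_layer": arch[0],
            "top_layer": arch[-1],
            "mean_test_error": rec.mean_test_error,
            "train_error": rec.train_error,
            "overfit_flag": rec.overfit_flag,
            "per_fold_final": [c[-1] for c in rec.test_curves] or None,
        })
    return pd.DataFrame(rows)


def elbow(sizes: np.ndarray, errors: np.ndarray) -> int:
    """Maximum-curvature point of an error-vs-size curve.

    Uses the discrete second derivative on a possibly non-uniform size grid
    and returns the interior size with the largest positive curvature (error
    flattening).  Reported for inspection, never auto-applied.
    """
    sizes = np.asarray(sizes, dtype=float)
    errors = np.asarray(errors, dtype=float)
    if len(sizes) < 3:
        raise ValueError("need >= 3 grid points to locate an elbow")
    order = np.argsort(sizes)
    s, e = sizes[order], errors[order]
    h1 = s[1:-1] - s[:-2]
    h2 = s[2:] - s[1:-1]
    d2 = 2 * (h1 * e[2:] - (h1 + h2) * e[1:-1] + h2 * e[:-2]) / (h1 * h2 * (h1 + h2))
    return int(s[1 + int(np.argmax(d2))])
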