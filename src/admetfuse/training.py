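"""Training protocol: splits, early stopping, multi-seed replication.

The protocol is fixed by the study design: data split 7:1.5:1.5 into
train/validation/test, minibatches of 32, AdamW at learning rate 5e-5,
early stopping when validation loss has not improved for 5 consecutive
epochs, at most 30 epochs, and five replicate fits from different random
seeds whose test metrics are reported as ``mean (SD)``.

Split sizes: ``n_train = round(0.7 n)``, ``n_val = floor(0.15 n)`` and the
remainder goes to test — 700/150/150 at n = 1000, 7/1/2 at n = 10.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np

from .models import build_model, _FusionBase

__all__ = ["TrainConfig", "RunRecord", "split", "train_model", "multi_seed_run", "format_mean_sd"]


@dataclass
class TrainConfig:
    train_fraction: float = 0.70
    val_fraction: float = 0.15
    test_fraction: float = 0.15
    batch_size: int = 32
    learning_rate: float = 5e-5
    patience: int = 5
    max_epochs: int = 30
    weight_decay: float = 0.01
    n_seeds: int = 5
    seeds: tuple[int, ...] | None = None

    def __post_init__(self):
        total = self.train_fraction + self.val_fraction + self.test_fraction
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"split fractions must sum to 1, got {total}")
        if self.patience >= self.max_epochs:
            raise ValueError("patience must be smaller than max_epochs")
        if self.seeds is not None and len(self.seeds) != self.n_seeds:
            raise ValueError("seeds list length must equal n_seeds")

    def seed_list(self, base_seed: int = 0) -> list[int]:
        if self.seeds is not None:
            return list(self.seeds)
        return [base_seed + k for k in range(self.n_seeds)]


@dataclass
class RunRecord:
    """One training run: losses, stopping bookkeeping and test metrics."""

    seed: int
    architecture: str
    train_losses: list[float]
    val_losses: list[float]
    best_epoch: int
    stopped_epoch: int
    test_metrics: dict = field(default_factory=dict)
    model: _FusionBase | None = None

    def to_dict(self) -> dict:
        out = asdict(self)
        out.pop("model")
        return out


def split(n_or_items, ratio=(0.70, 0.15, 0.15), seed: int = 0):
    """Shuffle and split into disjoint, exhaustive train/val/test parts.

    Accepts a count (returns index arrays) or a sequence (returns sub-lists).
    Requires n >= 10 so each part is non-empty at the default ratio.
    """
    items = None
    if isinstance(n_or_items, (int, np.integer)):
        n = int(n_or_items)
    else:
        items = list(n_or_items)
        n = len(items)
    if n < 10:
        raise ValueError(f"need at least 10 records to split, got {n}")
    if abs(sum(ratio) - 1.0) > 1e-9:
        raise ValueError("split ratio must sum to 1")
    n_train = int(round(n * ratio[0]))
    n_val = int(math.floor(n * ratio[1]))
    perm = np.random.default_rng(seed).permutation(n)
    parts = perm[:n_train], perm[n_train : n_train + n_val], perm[n_train + n_val :]
    if items is None:
        return parts
    return tuple([items[i] for i in part] for part in parts)


def train_model(
    architecture: str,
    X_train,
    y_train,
    X_val,
    y_val,
    X_test=None,
    y_test=None,
    config: TrainConfig | None = None,
    seed: int = 0,
    **model_kwargs,
) -> RunRecord:
    """Build and fit one architecture under the training protocol.

    Returns the RunRecord with loss curves, stopping epochs, and — when a
    test split is given — per-label metrics from the evaluator.
    """
    config = config or TrainConfig()
    model = build_model(
        architecture,
        learning_rate=config.learning_rate,
        batch_size=config.batch_size,
        max_epochs=config.max_epochs,
        patience=config.patience,
        weight_decay=config.weight_decay,
        random_state=seed,
        **model_kwargs,
    )
    model.fit(X_train, y_train, X_val=X_val, y_val=y_val)
    record = RunRecord(
        seed=seed,
        architecture=model.architecture,
        train_losses=model.loss_curve_,
        val_losses=model.val_loss_curve_,
        best_epoch=model.best_epoch_,
        stopped_epoch=model.stopped_epoch_,
        model=model,
    )
    if X_test is not None and y_test is not None:
        from .evaluator import evaluate_predictions

        probs = model.predict_proba(X_test)
        record.test_metrics = evaluate_predictions(probs, np.asarray(y_test), model.label_names_).summary()
    return record


def multi_seed_run(
    architecture: str,
    X_train,
    y_train,
    X_val,
    y_val,
    X_test=None,
    y_test=None,
    config: TrainConfig | None = None,
    base_seed: int = 0,
    **model_kwargs,
) -> tuple[list[RunRecord], dict]:
    """Replicate a fit across seeds; aggregate test metrics as mean (SD).

    Each replicate draws an independent initialization and batch order from
    its seed; the data split is held fixed by the caller.
    """
    config = config or TrainConfig()
    records = [
        train_model(architecture, X_train, y_train, X_val, y_val, X_test, y_test, config, seed, **model_kwargs)
        for seed in config.seed_list(base_seed)
    ]
    aggregate: dict[str, dict] = {}
    if records and records[0].test_metrics:
        keys = records[0].test_metrics.keys()
        for key in keys:
            values = np.array([r.test_metrics[key] for r in records if r.test_metrics.get(key) is not None], dtype=float)
            if values.size:
                aggregate[key] = {
                    "mean": float(values.mean()),
                    "sd": float(values.std(ddof=1)) if values.size > 1 else 0.0,
                    "formatted": format_mean_sd(values),
                }
    return records, aggregate


def format_mean_sd(values, percent: bool = True) -> str:
    """Render replicate metrics in the conventional "82.3 (0.9)" style."""
    values = np.asarray(values, dtype=float)
    mean = values.mean()
    sd = values.std(ddof=1) if values.size > 1 else 0.0
    if percent:
        return f"{100 * mean:.1f} ({100 * sd:.1f})"
    return f"{mean:.3f} ({sd:.3f})"
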