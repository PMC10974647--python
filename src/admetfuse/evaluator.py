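"""Evaluation: per-label metrics, six-model ensemble voting, CYP450 aggregation.

Metrics are computed from explicit confusion counts at a 0.5 threshold
(configurable); ratios with zero denominators are reported as ``None``
rather than 0, and AUROC is the Mann-Whitney concordance probability with
ties counted half — computed via average ranks, so it agrees exactly with
pairwise counting.

The ensemble rule: binarize each of the six models' probabilities, take the
majority; on a 3:3 tie the cell is positive iff the mean of the six
probabilities reaches the threshold.

CYP450 substrate aggregation turns the three subtype-substrate predictions
(2C9, 2D6, 3A4) into one substrate call by one of three methods: a small
trained synthesis network, the 3A4 probability taken directly, or soft
voting weighted by hepatic abundance (12% / 4% / 30%), normalized by the
weight sum so scores stay in [0, 1].
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .autodiff import _stable_sigmoid
from .models import PredictionMatrix

__all__ = [
    "MetricsReport",
    "CypAggregationConfig",
    "binary_metrics",
    "auroc",
    "evaluate_predictions",
    "ensemble_vote",
    "cyp_aggregate",
    "matched_proportion",
    "CypSynthesisClassifier",
]

DEFAULT_CYP_WEIGHTS = {
    "cyp450_2c9_substrate": 0.12,
    "cyp450_2d6_substrate": 0.04,
    "cyp450_3a4_substrate": 0.30,
}


def binary_metrics(probabilities, labels, threshold: float = 0.5) -> dict:
    """Confusion-count metrics for one label at the given threshold.

    Returns accuracy, precision, recall, F1 and AUROC; any ratio whose
    denominator is zero comes back as None, and AUROC is None (with a
    warning) when only one class is present.
    """
    p = np.asarray(probabilities, dtype=float)
    y = np.asarray(labels)
    if p.shape != y.shape:
        raise ValueError("probabilities and labels must be aligned")
    if not np.isin(y, (0, 1)).all():
        raise ValueError("labels must be binary")
    calls = p >= threshold
    tp = int(np.sum(calls & (y == 1)))
    fp = int(np.sum(calls & (y == 0)))
    fn = int(np.sum(~calls & (y == 1)))
    tn = int(np.sum(~calls & (y == 0)))
    n = tp + fp + fn + tn
    precision = tp / (tp + fp) if (tp + fp) else None
    recall = tp / (tp + fn) if (tp + fn) else None
    f1 = None
    if precision is not None and recall is not None and (precision + recall) > 0:
        f1 = 2 * precision * recall / (precision + recall)
    return {
        "n": n,
        "tp": tp,
        "fp": fp,
        "fn": fn,
        "tn": tn,
        "accuracy": (tp + tn) / n if n else None,
        "precision": precision,
        "recall": recall,
        "f1": f1,
        "auroc": auroc(p, y, warn=False),
    }


def auroc(scores, labels, warn: bool = True) -> float | None:
    """Mann-Whitney AUROC: probability a positive outranks a negative, ties half.

    Computed from average ranks, which is algebraically identical to counting
    concordant pairs with ties worth 1/2.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels).astype(int)
    n_pos = int((y == 1).sum())
    n_neg = int((y == 0).sum())
    if n_pos == 0 or n_neg == 0:
        if warn:
            warnings.warn("AUROC undefined: only one class present", stacklevel=2)
        return None
    ranks = rankdata(s)  # average ranks on ties
    return float((ranks[y == 1].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


@dataclass
class MetricsReport:
    """Per-label and macro-mean metrics for a multi-label prediction."""

    per_label: pd.DataFrame
    threshold: float = 0.5

    _METRICS = ("accuracy", "auroc", "f1", "precision", "recall")

    def macro(self) -> dict:
        return {m: (float(self.per_label[m].dropna().mean()) if self.per_label[m].notna().any() else None) for m in self._METRICS}

    def summary(self) -> dict:
        out = {f"macro_{k}": v for k, v in self.macro().items()}
        out["n_labels"] = len(self.per_label)
        return out

    def to_json(self, path):
        payload = {"threshold": self.threshold, "macro": self.macro(), "per_label": json.loads(self.per_label.to_json(orient="index"))}
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)

    def to_csv(self, path):
        self.per_label.to_csv(path)


def evaluate_predictions(probabilities, labels, label_names: list[str] | None = None, threshold: float = 0.5) -> MetricsReport:
    """MetricsReport over an (n, k) probability matrix and matching labels."""
    p = np.atleast_2d(np.asarray(probabilities, dtype=float))
    y = np.atleast_2d(np.asarray(labels))
    if p.shape != y.shape:
        raise ValueError(f"shape mismatch: probabilities {p.shape} vs labels {y.shape}")
    names = label_names or [f"label_{j:02d}" for j in range(p.shape[1])]
    rows = {}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for j, name in enumerate(names):
            rows[name] = binary_metrics(p[:, j], y[:, j], threshold)
    frame = pd.DataFrame.from_dict(rows, orient="index")
    return MetricsReport(per_label=frame, threshold=threshold)


def ensemble_vote(
    inputs: list[PredictionMatrix] | list[np.ndarray],
    threshold: float = 0.5,
    n_expected: int | None = 6,
) -> tuple[np.ndarray, np.ndarray]:
    """Majority vote across model prediction matrices.

    Each model's probabilities are binarized at `threshold`; the majority
    call wins per cell. On an exact tie the cell is positive iff the mean
    probability across models reaches the threshold. Returns
    (binary calls, mean probability matrix).
    """
    mats = [m.values if isinstance(m, PredictionMatrix) else np.asarray(m, dtype=float) for m in inputs]
    if n_expected is not None and len(mats) != n_expected:
        raise ValueError(f"expected {n_expected} prediction matrices, got {len(mats)}")
    shape = mats[0].shape
    if any(m.shape != shape for m in mats):
        raise ValueError("prediction matrices must share one shape")
    names = [m.label_names for m in inputs if isinstance(m, PredictionMatrix)]
    if names and any(n != names[0] for n in names):
        raise ValueError("prediction matrices must share label order")
    stack = np.stack(mats)  # (models, n, k)
    votes = (stack >= threshold).sum(axis=0)
    mean_prob = stack.mean(axis=0)
    k = len(mats)
    calls = np.where(votes * 2 > k, 1, 0)
    tie = votes * 2 == k
    calls[tie] = (mean_prob[tie] >= threshold).astype(int)
    return calls.astype(np.int64), mean_prob


def matched_proportion(calls, reference) -> float:
    """Fraction of binary calls agreeing exactly with the reference labels."""
    c = np.asarray(calls)
    r = np.asarray(reference)
    if c.shape != r.shape:
        raise ValueError(f"length mismatch: {c.shape} vs {r.shape}")
    return float((c == r).mean())


@dataclass
class CypAggregationConfig:
    """How to collapse subtype-substrate predictions into one substrate call."""

    weights: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_CYP_WEIGHTS))
    threshold: float = 0.5
    method: str = "weighted_soft_vote"  # dnn_synthesis | cyp3a4_direct | weighted_soft_vote
    cyp3a4_name: str = "cyp450_3a4_substrate"

    def __post_init__(self):
        if any(w < 0 for w in self.weights.values()):
            raise ValueError("abundance weights must be non-negative")
        if self.method not in ("dnn_synthesis", "cyp3a4_direct", "weighted_soft_vote"):
            raise ValueError(f"unknown aggregation method {self.method!r}")


class CypSynthesisClassifier:
    """Small trained network mapping the subtype prediction vector to one call.

    One hidden layer (width 8 by default), sigmoid output, AdamW with early
    stopping — the same protocol as the main models, at miniature scale.
    """

    def __init__(self, hidden: int = 8, learning_rate: float = 1e-2, max_epochs: int = 200, patience: int = 20, random_state: int | None = None):
        self.hidden = hidden
        self.learning_rate = learning_rate
        self.max_epochs = max_epochs
        self.patience = patience
        self.random_state = random_state

    def fit(self, subtype_probs, labels, val=None):
        from . import nn
        from .autodiff import Tensor

        X = np.asarray(subtype_probs, dtype=np.float32)
        y = np.asarray(labels, dtype=np.float32).reshape(-1)
        rng = np.random.default_rng(self.random_state)
        self._l1 = nn.Linear(X.shape[1], self.hidden, rng)
        self._l2 = nn.Linear(self.hidden, 1, rng)
        params = self._l1.parameters() + self._l2.parameters()
        opt = nn.AdamW(params, lr=self.learning_rate)
        Xv, yv = (np.asarray(val[0], dtype=np.float32), np.asarray(val[1], dtype=np.float32)) if val else (X, y)
        best, since, best_state = np.inf, 0, None
        for _ in range(self.max_epochs):
            logits = self._l2(self._l1(Tensor(X)).relu()).reshape(-1)
            loss = nn.bce_with_logits(logits, y)
            for p in params:
                p.grad = None
            loss.backward()
            opt.step()
            vlogit = self._l2(self._l1(Tensor(Xv)).relu()).data.reshape(-1)
            vl = float(np.mean(np.maximum(vlogit, 0) - vlogit * yv + np.log1p(np.exp(-np.abs(vlogit)))))
            if vl < best - 1e-7:
                best, since = vl, 0
                best_state = [p.data.copy() for p in params]
            else:
                since += 1
                if since >= self.patience:
                    break
        if best_state is not None:
            for p, s in zip(params, best_state):
                p.data = s
        return self

    def predict_proba(self, subtype_probs) -> np.ndarray:
        from .autodiff import Tensor

        X = np.asarray(subtype_probs, dtype=np.float32)
        logits = self._l2(self._l1(Tensor(X)).relu()).data.reshape(-1)
        return _stable_sigmoid(logits.astype(np.float64))


def cyp_aggregate(
    subtype_probs: pd.DataFrame,
    config: CypAggregationConfig | None = None,
    synthesizer: CypSynthesisClassifier | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Collapse per-subtype substrate probabilities into substrate calls.

    `subtype_probs` must carry one column per subtype named in the config
    weights. Returns (binary calls, scores); scores are suitable for AUROC.

    weighted_soft_vote: score = sum(w_i p_i) / sum(w_i), call at threshold.
    cyp3a4_direct: the 3A4 probability is the score.
    dnn_synthesis: a fitted CypSynthesisClassifier maps the subtype vector
    to the score (pass it in, trained on reference data).
    """
    config = config or CypAggregationConfig()
    missing = [c for c in config.weights if c not in subtype_probs.columns]
    if missing:
        raise KeyError(f"missing subtype columns: {missing}")
    if config.method == "weighted_soft_vote":
        names = list(config.weights)
        w = np.array([config.weights[c] for c in names], dtype=float)
        total = w.sum()
        if total <= 0:
            raise ValueError("abundance weights sum to zero")
        scores = subtype_probs[names].to_numpy(float) @ w / total
    elif config.method == "cyp3a4_direct":
        scores = subtype_probs[config.cyp3a4_name].to_numpy(float)
    else:  # dnn_synthesis
        if synthesizer is None:
            raise ValueError("dnn_synthesis requires a fitted CypSynthesisClassifier")
        scores = synthesizer.predict_proba(subtype_probs[list(config.weights)].to_numpy(float))
    calls = (scores >= config.threshold).astype(np.int64)
    return calls, scores
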