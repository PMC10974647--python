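"""The six fusion architectures as scikit-learn-style multi-label estimators.

All variants predict 21 binary ADMET outcomes (sigmoid per label) and differ
in what they read and how they fuse it:

``dnn``
    physicochemical features only: the Boolean feature passes through a
    2-row embedding to 10 dimensions, the five integer and seven float
    groups each through an affine map to 10 dimensions; the three group
    vectors concatenate to a 30-dimensional fused vector feeding the
    output head.
``encoder``
    SMILES only: a transformer encoder pools to an H-dimensional vector
    (H = 768 at published scale) feeding the head.
``concat``
    both, in parallel: the 30-d fused vector and the H-d encoder vector
    concatenate (798-d at defaults) before the head.
``pipe``
    both, in sequence: the encoder vector first predicts the 13-feature
    physicochemical block, whose predictions then feed the DNN trunk.
``dnn_a`` / ``pipe_a``
    as dnn / pipe with dot-product self-attention over the three group
    vectors (query = key = value = the group vectors), tanh-activated.

Head layers are plain affine stacks — no hidden nonlinearity — except
inside the attention block, which uses tanh; `activation="relu"` opts into
nonlinear heads.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin

from . import nn
from .autodiff import Tensor, concat, _stable_sigmoid
from .data import FeatureSchema, default_schema
from .encoder import EncoderConfig, TransformerEncoder
from .tokenizer import TokenVocab, encode_batch

__all__ = [
    "ModelConfig",
    "PredictionMatrix",
    "DNNClassifier",
    "EncoderClassifier",
    "ConcatClassifier",
    "PipeClassifier",
    "build_model",
    "self_attention",
    "ARCHITECTURES",
]

ARCHITECTURES = ("dnn", "encoder", "concat", "pipe", "dnn_a", "pipe_a")


@dataclass(frozen=True)
class ModelConfig:
    """Architecture hyperparameters; the defaults reproduce the published dims."""

    architecture: str = "dnn"
    bool_width: int = 10
    int_width: int = 10
    float_width: int = 10
    encoder_hidden: int = 768
    n_labels: int = 21
    pipe_head_size: int = 13
    attention: bool = False

    @property
    def fused_width(self) -> int:
        return self.bool_width + self.int_width + self.float_width

    @property
    def concat_width(self) -> int:
        return self.fused_width + self.encoder_hidden


@dataclass
class PredictionMatrix:
    """n_compounds x n_labels probabilities from one model."""

    model_tag: str
    values: np.ndarray
    label_names: list[str]
    ids: list[str] | None = None

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[1] != len(self.label_names):
            raise ValueError("values must be (n, n_labels) aligned with label_names")
        if np.any((self.values < 0) | (self.values > 1)):
            raise ValueError("probabilities must lie in [0, 1]")

    def to_csv(self, path):
        frame = pd.DataFrame(self.values, columns=self.label_names)
        if self.ids is not None:
            frame.insert(0, "id", self.ids)
        frame.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, model_tag: str = "") -> "PredictionMatrix":
        frame = pd.read_csv(path)
        ids = frame.pop("id").astype(str).tolist() if "id" in frame.columns else None
        return cls(model_tag=model_tag, values=frame.to_numpy(float), label_names=list(frame.columns), ids=ids)


def self_attention(groups: Tensor | np.ndarray) -> tuple[Tensor, np.ndarray]:
    """Dot-product self-attention over a (n, g, d) stack of group vectors.

    The group vectors serve as query, key and value alike; scores are scaled
    by sqrt(d), softmax-normalized per query, and the weighted sum passes
    through tanh. Returns the attended stack and the (n, g, g) attention
    weights for inspection.
    """
    x = groups if isinstance(groups, Tensor) else Tensor(np.asarray(groups, dtype=np.float32))
    d = x.shape[-1]
    scores = (x @ x.transpose(0, 2, 1)) * (1.0 / np.sqrt(d))
    weights = scores.softmax(-1)
    out = (weights @ x).tanh()
    return out, weights.data.copy()


class _DNNTrunk(nn.Module):
    """Feature block -> fused 30-d vector (plus optional attention mixing)."""

    def __init__(self, config: ModelConfig, rng: np.random.Generator):
        super().__init__()
        self.config = config
        if config.attention and not (config.bool_width == config.int_width == config.float_width):
            raise ValueError("attention requires equal group widths")
        self.bool_emb = nn.Embedding(2, config.bool_width, rng, scale=0.5)
        self.int_fc = nn.Linear(5, config.int_width, rng)
        self.float_fc = nn.Linear(7, config.float_width, rng)
        self.attention_weights_: np.ndarray | None = None

    def forward(self, bool_in: np.ndarray | Tensor, ints: np.ndarray, floats: np.ndarray) -> Tensor:
        if isinstance(bool_in, Tensor):  # soft mixture of the two embedding rows
            p = bool_in.reshape(-1, 1)
            b = p * self.bool_emb.weight[1] + (1.0 - p) * self.bool_emb.weight[0]
        else:
            b = self.bool_emb(np.asarray(bool_in, dtype=np.int64))
        i = self.int_fc(ints if isinstance(ints, Tensor) else Tensor(np.asarray(ints, dtype=np.float32)))
        f = self.float_fc(floats if isinstance(floats, Tensor) else Tensor(np.asarray(floats, dtype=np.float32)))
        if self.config.attention:
            n, d = b.shape[0], self.config.bool_width
            stack = concat([b.reshape(n, 1, d), i.reshape(n, 1, d), f.reshape(n, 1, d)], axis=1)
            attended, self.attention_weights_ = self_attention(stack)
            return attended.reshape(n, 3 * d)
        return concat([b, i, f], axis=-1)


def _head(in_width: int, n_labels: int, depth: int, activation: str | None, rng) -> nn.Module:
    layers: list[nn.Module] = []
    width = in_width
    for _ in range(max(depth - 1, 0)):
        layers.append(nn.Linear(width, width, rng))
        if activation == "relu":
            layers.append(_Relu())
    layers.append(nn.Linear(width, n_labels, rng))
    return nn.Sequential(*layers)


class _Relu(nn.Module):
    def forward(self, x):
        return x.relu()


class _DNNModel(nn.Module):
    def __init__(self, config: ModelConfig, rng, head_depth=1, activation=None):
        super().__init__()
        self.trunk = _DNNTrunk(config, rng)
        self.head = _head(config.fused_width, config.n_labels, head_depth, activation, rng)

    def forward(self, batch) -> Tensor:
        return self.head(self.trunk(batch["bool"], batch["ints"], batch["floats"]))


class _EncoderModel(nn.Module):
    def __init__(self, config: ModelConfig, encoder: TransformerEncoder, rng, head_depth=1, activation=None, pooling="cls"):
        super().__init__()
        self.encoder = encoder
        self.pooling = pooling
        self.head = _head(encoder.config.hidden_size, config.n_labels, head_depth, activation, rng)

    def _embed(self, batch) -> Tensor:
        hidden = self.encoder(batch["ids"], batch["attn"])
        return self.encoder.pool(hidden, batch["attn"], self.pooling)

    def forward(self, batch) -> Tensor:
        return self.head(self._embed(batch))


class _ConcatModel(nn.Module):
    def __init__(self, config: ModelConfig, encoder: TransformerEncoder, rng, head_depth=1, activation=None, pooling="cls"):
        super().__init__()
        self.trunk = _DNNTrunk(config, rng)
        self.encoder = encoder
        self.pooling = pooling
        fused = config.fused_width + encoder.config.hidden_size
        self.head = _head(fused, config.n_labels, head_depth, activation, rng)

    def forward(self, batch) -> Tensor:
        fused = self.trunk(batch["bool"], batch["ints"], batch["floats"])
        hidden = self.encoder(batch["ids"], batch["attn"])
        pooled = self.encoder.pool(hidden, batch["attn"], self.pooling)
        return self.head(concat([fused, pooled], axis=-1))


class _PipeModel(nn.Module):
    """Encoder -> physchem predictions -> DNN trunk -> labels.

    Stage 1 regresses the 12 numeric features and emits a logit for the
    Boolean one; stage 2 feeds those predictions (Boolean as a soft
    probability) into the DNN trunk. Both stages' outputs are returned.
    """

    def __init__(self, config: ModelConfig, encoder: TransformerEncoder, rng, head_depth=1, activation=None, pooling="cls"):
        super().__init__()
        self.encoder = encoder
        self.pooling = pooling
        self.stage1 = nn.Linear(encoder.config.hidden_size, config.pipe_head_size, rng)
        self.trunk = _DNNTrunk(config, rng)
        self.head = _head(config.fused_width, config.n_labels, head_depth, activation, rng)

    def forward(self, batch, physchem_override: dict | None = None) -> tuple[Tensor, Tensor]:
        hidden = self.encoder(batch["ids"], batch["attn"])
        pooled = self.encoder.pool(hidden, batch["attn"], self.pooling)
        phys = self.stage1(pooled)  # (n, 13): [bool logit, 5 ints, 7 floats]
        if physchem_override is not None:
            bool_p = physchem_override["bool"]
            ints = physchem_override["ints"]
            floats = physchem_override["floats"]
        else:
            bool_p = phys[:, 0].sigmoid()
            ints = phys[:, 1:6]
            floats = phys[:, 6:13]
        fused = self.trunk(bool_p, ints, floats)
        return phys, self.head(fused)


# -- estimators ---------------------------------------------------------------


def _split_features(X, schema: FeatureSchema):
    """Pull (bool ids, int block, float block, smiles) out of X.

    X may be a DataFrame carrying the schema's feature columns and/or a
    ``smiles`` column, or a plain sequence of SMILES strings.
    """
    if isinstance(X, (list, tuple)) or (isinstance(X, (pd.Series, np.ndarray)) and np.asarray(X).dtype.kind in "OU"):
        return None, None, None, [str(s) for s in X]
    if not isinstance(X, pd.DataFrame):
        raise TypeError("X must be a DataFrame or a sequence of SMILES strings")
    smiles = X["smiles"].astype(str).tolist() if "smiles" in X.columns else None
    bool_col = ints = floats = None
    if all(c in X.columns for c in schema.input_feature_names):
        bool_col = X[schema.bool_features[0]].to_numpy()
        bool_col = np.asarray(bool_col, dtype=float).round().astype(np.int64)
        ints = X[list(schema.int_features)].to_numpy(np.float32)
        floats = X[list(schema.float_features)].to_numpy(np.float32)
        if np.isnan(ints).any() or np.isnan(floats).any():
            raise ValueError("feature block contains missing values; run exclude_incomplete")
    return bool_col, ints, floats, smiles


class _FusionBase(BaseEstimator, ClassifierMixin):
    """Shared fit/predict machinery for all six architectures.

    Training follows the published protocol: minibatch AdamW on summed
    per-label binary cross-entropy, early stopping on validation loss,
    best-epoch weight restoration. Defaults (batch 32, lr 5e-5, patience 5,
    max 30 epochs) are the protocol's; small-scale work overrides them.
    """

    architecture: str = ""
    _needs_features = True
    _needs_smiles = False

    def __init__(
        self,
        n_labels: int = 21,
        bool_width: int = 10,
        int_width: int = 10,
        float_width: int = 10,
        pipe_head_size: int = 13,
        attention: bool = False,
        head_depth: int = 1,
        activation: str | None = None,
        learning_rate: float = 5e-5,
        batch_size: int = 32,
        max_epochs: int = 30,
        patience: int = 5,
        weight_decay: float = 0.01,
        stage_loss_weight: float = 1.0,
        schema: FeatureSchema | None = None,
        encoder: TransformerEncoder | None = None,
        encoder_config: EncoderConfig | None = None,
        vocab: TokenVocab | None = None,
        freeze_encoder: bool = False,
        pooling: str = "cls",
        max_len: int | None = None,
        random_state: int | None = None,
    ):
        self.n_labels = n_labels
        self.bool_width = bool_width
        self.int_width = int_width
        self.float_width = float_width
        self.pipe_head_size = pipe_head_size
        self.attention = attention
        self.head_depth = head_depth
        self.activation = activation
        self.learning_rate = learning_rate
        self.batch_size = batch_size
        self.max_epochs = max_epochs
        self.patience = patience
        self.weight_decay = weight_decay
        self.stage_loss_weight = stage_loss_weight
        self.schema = schema
        self.encoder = encoder
        self.encoder_config = encoder_config
        self.vocab = vocab
        self.freeze_encoder = freeze_encoder
        self.pooling = pooling
        self.max_len = max_len
        self.random_state = random_state

    # -- construction ---------------------------------------------------------

    def _model_config(self) -> ModelConfig:
        H = 768
        if self.encoder is not None:
            H = self.encoder.config.hidden_size
        elif self.encoder_config is not None:
            H = self.encoder_config.hidden_size
        return ModelConfig(
            architecture=self.architecture,
            bool_width=self.bool_width,
            int_width=self.int_width,
            float_width=self.float_width,
            encoder_hidden=H,
            n_labels=self.n_labels,
            pipe_head_size=self.pipe_head_size,
            attention=self.attention,
        )

    def _make_encoder(self, seed: int) -> TransformerEncoder:
        if self.vocab is None:
            raise ValueError(f"{self.architecture} model requires a trained vocab")
        if self.encoder is not None:
            enc = TransformerEncoder(self.encoder.config, seed=seed)
            enc.load_state_dict(self.encoder.state_dict())  # private copy of the weights
            return enc
        config = self.encoder_config or EncoderConfig(vocab_size=max(self.vocab.vocab_size, 8))
        if config.vocab_size < self.vocab.vocab_size:
            raise ValueError("encoder vocab_size smaller than the tokenizer vocabulary")
        return TransformerEncoder(config, seed=seed)

    def _build(self, rng: np.random.Generator):
        config = self._model_config()
        seed = int(rng.integers(0, 2**31 - 1))
        kw = dict(head_depth=self.head_depth, activation=self.activation)
        if self.architecture in ("dnn", "dnn_a"):
            return _DNNModel(config, rng, **kw)
        encoder = self._make_encoder(seed)
        if self.architecture == "encoder":
            return _EncoderModel(config, encoder, rng, pooling=self.pooling, **kw)
        if self.architecture == "concat":
            return _ConcatModel(config, encoder, rng, pooling=self.pooling, **kw)
        if self.architecture in ("pipe", "pipe_a"):
            return _PipeModel(config, encoder, rng, pooling=self.pooling, **kw)
        raise ValueError(f"unknown architecture {self.architecture!r}")

    # -- data plumbing --------------------------------------------------------

    def _prepare(self, X):
        schema = self.schema or default_schema()
        bool_col, ints, floats, smiles = _split_features(X, schema)
        batch: dict = {}
        if self._needs_features:
            if ints is None:
                raise ValueError(f"{self.architecture} model requires the feature block")
            batch.update({"bool": bool_col, "ints": ints, "floats": floats})
        if self._needs_smiles or self.architecture in ("pipe", "pipe_a"):
            if smiles is None:
                raise ValueError(f"{self.architecture} model requires SMILES input")
            max_len = self.max_len or (self.encoder.config.max_len if self.encoder is not None else None) or (
                self.encoder_config.max_len if self.encoder_config is not None else 128
            )
            ids, attn = encode_batch(smiles, self.vocab, max_len)
            batch.update({"ids": ids, "attn": attn})
        # pipe stage-1 targets: the true feature block, when supplied
        if self.architecture in ("pipe", "pipe_a") and ints is not None:
            batch.update({"bool": bool_col, "ints": ints, "floats": floats})
        return batch

    @staticmethod
    def _take(batch: dict, idx: np.ndarray) -> dict:
        return {k: v[idx] for k, v in batch.items() if v is not None}

    def _forward(self, model, batch) -> Tensor:
        if self.architecture in ("pipe", "pipe_a"):
            _, logits = model(batch)
            return logits
        return model(batch)

    def _loss(self, model, batch, y: np.ndarray) -> Tensor:
        if self.architecture in ("pipe", "pipe_a"):
            phys, logits = model(batch)
            loss = nn.bce_with_logits(logits, y)
            if "ints" in batch and batch["ints"] is not None:
                numeric = np.concatenate([batch["ints"], batch["floats"]], axis=1)
                stage1 = nn.mse_loss(phys[:, 1:], numeric)
                stage1 = stage1 + nn.bce_with_logits(phys[:, 0], np.asarray(batch["bool"], dtype=np.float32))
                loss = loss + self.stage_loss_weight * stage1
            return loss
        logits = model(batch)
        return nn.bce_with_logits(logits, y)

    # -- sklearn API ----------------------------------------------------------

    def fit(self, X, y, X_val=None, y_val=None, label_names: list[str] | None = None):
        """Fit on (X, y); with a validation pair, early-stop on its loss.

        y is an (n, n_labels) binary matrix. Training state is recorded in
        ``loss_curve_``, ``val_loss_curve_``, ``best_epoch_`` (1-based) and
        ``n_epochs_``.
        """
        y = np.asarray(y, dtype=np.float32)
        if y.ndim == 1:
            y = y[:, None]
        if y.shape[1] != self.n_labels:
            raise ValueError(f"y has {y.shape[1]} labels, expected n_labels={self.n_labels}")
        rng = np.random.default_rng(self.random_state)
        batch = self._prepare(X)
        val_batch = self._prepare(X_val) if X_val is not None else None
        y_val = np.asarray(y_val, dtype=np.float32) if y_val is not None else None

        model = self._build(rng)
        params = model.parameters()
        if self.freeze_encoder and hasattr(model, "encoder"):
            frozen = set(id(p) for p in model.encoder.parameters())
            params = [p for p in params if id(p) not in frozen]
        opt = nn.AdamW(params, lr=self.learning_rate, weight_decay=self.weight_decay)

        n = y.shape[0]
        self.loss_curve_: list[float] = []
        self.val_loss_curve_: list[float] = []
        stopper = nn.EarlyStopping(self.patience)
        best_state = None
        stopped = self.max_epochs
        for epoch in range(1, self.max_epochs + 1):
            model.train()
            order = rng.permutation(n)
            epoch_losses = []
            for start in range(0, n, self.batch_size):
                idx = order[start : start + self.batch_size]
                loss = self._loss(model, self._take(batch, idx), y[idx])
                if not np.isfinite(loss.data):
                    raise RuntimeError(
                        f"non-finite loss at epoch {epoch} ({self.architecture}); reduce the learning rate"
                    )
                model.zero_grad()
                loss.backward()
                opt.step()
                epoch_losses.append(float(loss.data))
            self.loss_curve_.append(float(np.mean(epoch_losses)))
            if val_batch is not None:
                model.eval()
                val_loss = float(self._loss(model, val_batch, y_val).data)
                self.val_loss_curve_.append(val_loss)
                stop = stopper.update(val_loss)
                if stopper.best_epoch == epoch:
                    best_state = model.state_dict()
                if stop:
                    stopped = epoch
                    break
        if best_state is not None:
            model.load_state_dict(best_state)
        self.model_ = model
        self.best_epoch_ = stopper.best_epoch if best_state is not None else len(self.loss_curve_)
        self.n_epochs_ = len(self.loss_curve_)
        self.stopped_epoch_ = min(stopped, self.n_epochs_)
        schema = self.schema or default_schema()
        self.label_names_ = list(label_names) if label_names is not None else list(schema.final_label_names)[: self.n_labels]
        if len(self.label_names_) != self.n_labels:
            self.label_names_ = [f"label_{j:02d}" for j in range(self.n_labels)]
        return self

    def predict_proba(self, X) -> np.ndarray:
        if not hasattr(self, "model_"):
            raise RuntimeError("estimator is not fitted")
        batch = self._prepare(X)
        self.model_.eval()
        n = len(next(iter(batch.values())))
        out = []
        for start in range(0, n, 256):
            idx = np.arange(start, min(start + 256, n))
            logits = self._forward(self.model_, self._take(batch, idx))
            out.append(_stable_sigmoid(logits.data.astype(np.float64)))
        return np.concatenate(out, axis=0)

    def predict(self, X, threshold: float = 0.5) -> np.ndarray:
        return (self.predict_proba(X) >= threshold).astype(np.int64)

    def predict_matrix(self, X, tag: str | None = None, ids: list[str] | None = None) -> PredictionMatrix:
        return PredictionMatrix(
            model_tag=tag or self.architecture,
            values=self.predict_proba(X),
            label_names=self.label_names_,
            ids=ids,
        )

    def score(self, X, y) -> float:
        """Mean per-label accuracy at threshold 0.5."""
        y = np.asarray(y)
        return float((self.predict(X) == y).mean())

    def predict_physchem(self, X) -> np.ndarray:
        """Pipe models only: the stage-1 physicochemical predictions."""
        if self.architecture not in ("pipe", "pipe_a"):
            raise AttributeError("stage-1 predictions exist only for pipe architectures")
        batch = self._prepare(X)
        self.model_.eval()
        phys, _ = self.model_(batch)
        return phys.data.copy()


class DNNClassifier(_FusionBase):
    """Feature-block-only architecture (with optional attention: dnn_a)."""

    _needs_features = True
    _needs_smiles = False

    @property
    def architecture(self) -> str:
        return "dnn_a" if self.attention else "dnn"


class EncoderClassifier(_FusionBase):
    """SMILES-only transformer architecture."""

    architecture = "encoder"
    _needs_features = False
    _needs_smiles = True


class ConcatClassifier(_FusionBase):
    """Parallel fusion of the feature block and the encoder vector."""

    architecture = "concat"
    _needs_features = True
    _needs_smiles = True


class PipeClassifier(_FusionBase):
    """Sequential fusion: encoder predicts physchem, physchem predicts labels."""

    _needs_features = False  # features are stage-1 targets, required in fit only
    _needs_smiles = True

    @property
    def architecture(self) -> str:
        return "pipe_a" if self.attention else "pipe"


_CLASSES = {
    "dnn": (DNNClassifier, {}),
    "dnn_a": (DNNClassifier, {"attention": True}),
    "encoder": (EncoderClassifier, {}),
    "concat": (ConcatClassifier, {}),
    "pipe": (PipeClassifier, {}),
    "pipe_a": (PipeClassifier, {"attention": True}),
}


def build_model(architecture: str, **kwargs) -> _FusionBase:
    """Instantiate an estimator by architecture name (one of ARCHITECTURES)."""
    try:
        cls, extra = _CLASSES[architecture]
    except KeyError:
        raise ValueError(f"unknown architecture {architecture!r}; choose from {ARCHITECTURES}") from None
    return cls(**{**extra, **kwargs})
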