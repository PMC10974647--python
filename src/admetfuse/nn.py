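"""Neural-network building blocks over the autodiff engine.

Layers follow the familiar module pattern: a :class:`Module` owns named
parameters (and sub-modules), exposes ``parameters()`` for the optimizer and
``state_dict``/``load_state_dict`` for checkpointing. Initialization is
fan-in uniform for affine maps and small-Gaussian for embeddings, always
drawn from a caller-supplied :class:`numpy.random.Generator` so runs are
reproducible bit-for-bit.
"""

from __future__ import annotations

import numpy as np

from .autodiff import Tensor, concat

__all__ = [
    "Module",
    "Linear",
    "Embedding",
    "LayerNorm",
    "Dropout",
    "Sequential",
    "AdamW",
    "bce_with_logits",
    "softmax_cross_entropy",
    "mse_loss",
    "sigmoid",
]


class Module:
    """Base class: tracks parameters and sub-modules by attribute name."""

    def __init__(self):
        self._params: dict[str, Tensor] = {}
        self._modules: dict[str, Module] = {}
        self.training = True

    def __setattr__(self, name, value):
        if isinstance(value, Tensor) and value.requires_grad:
            self.__dict__.setdefault("_params", {})[name] = value
        elif isinstance(value, Module):
            self.__dict__.setdefault("_modules", {})[name] = value
        object.__setattr__(self, name, value)

    def parameters(self) -> list[Tensor]:
        out = list(self._params.values())
        for m in self._modules.values():
            out.extend(m.parameters())
        return out

    def named_parameters(self, prefix: str = "") -> dict[str, Tensor]:
        out = {prefix + k: v for k, v in self._params.items()}
        for name, m in self._modules.items():
            out.update(m.named_parameters(prefix + name + "."))
        return out

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None

    def train(self, mode: bool = True):
        self.training = mode
        for m in self._modules.values():
            m.train(mode)
        return self

    def eval(self):
        return self.train(False)

    def state_dict(self) -> dict[str, np.ndarray]:
        return {k: v.data.copy() for k, v in self.named_parameters().items()}

    def load_state_dict(self, state: dict[str, np.ndarray]):
        params = self.named_parameters()
        missing = set(params) - set(state)
        if missing:
            raise KeyError(f"state dict missing parameters: {sorted(missing)}")
        for k, p in params.items():
            arr = np.asarray(state[k], dtype=p.data.dtype)
            if arr.shape != p.data.shape:
                raise ValueError(f"shape mismatch for {k}: {arr.shape} vs {p.data.shape}")
            p.data = arr.copy()

    def n_parameters(self) -> int:
        return sum(p.data.size for p in self.parameters())

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


class Linear(Module):
    """Affine map x @ W + b with fan-in uniform initialization."""

    def __init__(self, in_features: int, out_features: int, rng: np.random.Generator):
        super().__init__()
        bound = 1.0 / np.sqrt(in_features)
        self.weight = Tensor(
            rng.uniform(-bound, bound, size=(in_features, out_features)).astype(np.float32),
            requires_grad=True,
        )
        self.bias = Tensor(rng.uniform(-bound, bound, size=out_features).astype(np.float32), requires_grad=True)

    def forward(self, x: Tensor) -> Tensor:
        return x @ self.weight + self.bias


class Embedding(Module):
    """Lookup table mapping integer ids to learned vectors."""

    def __init__(self, num_embeddings: int, dim: int, rng: np.random.Generator, scale: float = 0.02):
        super().__init__()
        self.weight = Tensor(rng.normal(0.0, scale, size=(num_embeddings, dim)).astype(np.float32), requires_grad=True)

    def forward(self, ids: np.ndarray) -> Tensor:
        return self.weight.take_rows(np.asarray(ids))


class LayerNorm(Module):
    def __init__(self, dim: int, eps: float = 1e-5):
        super().__init__()
        self.gamma = Tensor(np.ones(dim, dtype=np.float32), requires_grad=True)
        self.beta = Tensor(np.zeros(dim, dtype=np.float32), requires_grad=True)
        self.eps = eps

    def forward(self, x: Tensor) -> Tensor:
        return x.layer_norm(self.gamma, self.beta, self.eps)


class Dropout(Module):
    """Inverted dropout; identity in eval mode. Uses its own seeded stream."""

    def __init__(self, rate: float, rng: np.random.Generator):
        super().__init__()
        if not 0.0 <= rate < 1.0:
            raise ValueError("dropout rate must be in [0, 1)")
        self.rate = rate
        self.rng = rng

    def forward(self, x: Tensor) -> Tensor:
        if not self.training or self.rate == 0.0:
            return x
        keep = 1.0 - self.rate
        mask = (self.rng.random(x.shape) < keep).astype(np.float32) / keep
        return x * Tensor(mask)


class Sequential(Module):
    def __init__(self, *layers: Module):
        super().__init__()
        self.layers = list(layers)
        for i, layer in enumerate(layers):
            setattr(self, f"layer{i}", layer)

    def forward(self, x):
        for layer in self.layers:
            x = layer(x)
        return x


class AdamW:
    """AdamW: Adam with decoupled weight decay.

    Defaults mirror common transformer practice (betas 0.9/0.999,
    weight decay 0.01). Bias-corrected moment estimates.
    """

    def __init__(self, params: list[Tensor], lr: float = 5e-5, betas=(0.9, 0.999), eps: float = 1e-8, weight_decay: float = 0.01):
        self.params = params
        self.lr = lr
        self.beta1, self.beta2 = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]

    def step(self):
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bc1 = 1.0 - b1**self.t
        bc2 = 1.0 - b2**self.t
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None:
                continue
            g = p.grad
            m *= b1
            m += (1.0 - b1) * g
            v *= b2
            v += (1.0 - b2) * (g * g)
            update = (m / bc1) / (np.sqrt(v / bc2) + self.eps)
            if self.weight_decay:
                update = update + self.weight_decay * p.data
            p.data = p.data - self.lr * update

    def zero_grad(self):
        for p in self.params:
            p.grad = None


class EarlyStopping:
    """Stop when the monitored loss has not improved for `patience` epochs.

    ``update`` returns True when training should stop. Improvement is a
    strict decrease below the best value seen; `best_epoch` is 1-based.
    """

    def __init__(self, patience: int):
        if patience < 1:
            raise ValueError("patience must be >= 1")
        self.patience = patience
        self.best = np.inf
        self.best_epoch = 0
        self.epochs_since_best = 0
        self.epoch = 0

    def update(self, loss: float) -> bool:
        self.epoch += 1
        if loss < self.best:
            self.best = loss
            self.best_epoch = self.epoch
            self.epochs_since_best = 0
            return False
        self.epochs_since_best += 1
        return self.epochs_since_best >= self.patience


# -- losses -------------------------------------------------------------------


def sigmoid(x: Tensor) -> Tensor:
    return x.sigmoid()


def bce_with_logits(logits: Tensor, targets: np.ndarray, mask: np.ndarray | None = None) -> Tensor:
    """Mean binary cross-entropy computed stably from logits.

    `mask`, if given, zeroes out entries (e.g. labels absent for a record)
    and the mean is taken over unmasked entries only.
    """
    from .autodiff import _stable_sigmoid

    t = np.asarray(targets, dtype=np.float32)
    x = logits
    parent = x
    xd = x.data
    sig = _stable_sigmoid(xd)
    # elementwise loss: max(x,0) - x*t + log(1+exp(-|x|))
    loss = np.maximum(xd, 0.0) - xd * t + np.log1p(np.exp(-np.abs(xd)))
    if mask is not None:
        mask = np.asarray(mask, dtype=np.float32)
        n = max(mask.sum(), 1.0)
        loss = loss * mask
    else:
        n = loss.size
    value = loss.sum() / n

    def backward(g):
        grad = (sig - t) / n
        if mask is not None:
            grad = grad * mask
        parent._accumulate(g * grad)

    return Tensor._from_op(np.asarray(value, dtype=xd.dtype), (parent,), backward)


def softmax_cross_entropy(logits: Tensor, targets: np.ndarray) -> Tensor:
    """Mean cross-entropy of integer `targets` under softmax of `logits` (N, V)."""
    t = np.asarray(targets)
    z = logits.data - logits.data.max(axis=-1, keepdims=True)
    e = np.exp(z)
    p = e / e.sum(axis=-1, keepdims=True)
    n = t.shape[0]
    rows = np.arange(n)
    value = -np.mean(np.log(p[rows, t] + 1e-12))
    parent = logits

    def backward(g):
        grad = p.copy()
        grad[rows, t] -= 1.0
        parent._accumulate(g * grad / n)

    return Tensor._from_op(np.asarray(value, dtype=logits.data.dtype), (parent,), backward)


def mse_loss(pred: Tensor, targets: np.ndarray) -> Tensor:
    t = Tensor(np.asarray(targets, dtype=np.float32))
    diff = pred - t
    return (diff * diff).mean()
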