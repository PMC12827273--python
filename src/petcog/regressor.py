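"""Feature-wise-attention transformer regressor for tabular SUV features.

Architecture: a feature-wise attention layer

    A  = softmax(W2 . ReLU(W1 . X + b1) + b2)   (softmax over the feature axis)
    X' = X (.) A                                 (elementwise reweighting)

followed by a linear embedding into a 512-dimensional latent vector, a stack
of transformer encoder layers (multi-head self-attention + feed-forward +
layer normalization, applied to the single latent token per subject), and a
fully connected regression head with ReLU and dropout producing one scalar
score.  Trained with AdamW, Huber (SmoothL1) loss and global gradient-norm
clipping; features and targets are z-scaled on the training split only.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import autodiff as ad
from .autodiff import DTYPE, Tensor
from .errors import (
    ConfigurationError,
    DivergenceError,
    DomainError,
    ModelStateError,
    UndefinedMetricError,
)


@dataclass
class RegressorConfig:
    """Hyperparameters of the attention regressor."""

    n_features: int = 37
    attn_hidden: int | None = None  # default max(n_features // 2, 8)
    embed_dim: int = 512
    n_encoder_layers: int = 2
    n_heads: int = 4
    ff_mult: int = 2
    head_hidden: int = 128
    dropout: float = 0.3
    lr: float = 5e-5
    weight_decay: float = 1e-8
    grad_clip_norm: float = 1.0
    huber_delta: float = 1.0
    split_ratio: float = 0.9
    epochs: int = 300
    batch_size: int = 32
    seed: int = 0

    def __post_init__(self):
        if self.attn_hidden is None:
            self.attn_hidden = max(self.n_features // 2, 8)

    def validate(self) -> None:
        if not 0 <= self.dropout < 1:
            raise ConfigurationError("dropout must be in [0, 1)")
        if self.embed_dim % self.n_heads != 0:
            raise ConfigurationError("embed_dim must be divisible by n_heads")
        if not 0 < self.split_ratio < 1:
            raise ConfigurationError("split_ratio must be in (0, 1)")
        if self.n_features < 1:
            raise ConfigurationError("n_features must be >= 1")
        if self.epochs < 1 or self.batch_size < 1:
            raise ConfigurationError("epochs and batch_size must be >= 1")


@dataclass
class AttentionParams:
    """Parameters of the feature-wise attention layer."""

    W1: np.ndarray  # (f, hidden)
    b1: np.ndarray  # (hidden,)
    W2: np.ndarray  # (hidden, f)
    b2: np.ndarray  # (f,)


def feature_attention(X: np.ndarray, params: AttentionParams):
    """Reference (pure numpy) feature-wise attention.

    Returns ``(A, X_attended)`` where each row of A is a positive simplex
    weight vector over the features and ``X_attended = X * A``.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[1] != params.W1.shape[0]:
        raise DomainError(
            f"X has {X.shape[1]} features, attention expects {params.W1.shape[0]}"
        )
    h = np.maximum(X @ params.W1 + params.b1, 0.0)
    logits = h @ params.W2 + params.b2
    logits = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(logits)
    A = e / e.sum(axis=1, keepdims=True)
    return A, X * A


@dataclass
class Metrics:
    r2: float
    mse: float
    mae: float


def compute_metrics(y_true, y_pred) -> Metrics:
    """R^2, MSE and MAE of predictions against targets."""
    y_true = np.asarray(y_true, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    mse = float(np.mean((y_true - y_pred) ** 2))
    mae = float(np.mean(np.abs(y_true - y_pred)))
    ss_tot = float(np.sum((y_true - y_true.mean()) ** 2))
    if ss_tot == 0.0:
        raise UndefinedMetricError(
            "R^2 undefined: test targets have zero variance",
            partial_metrics=Metrics(r2=float("nan"), mse=mse, mae=mae),
        )
    r2 = 1.0 - float(np.sum((y_true - y_pred) ** 2)) / ss_tot
    return Metrics(r2=r2, mse=mse, mae=mae)


class AttentionRegressor:
    """The trainable model: attention -> embedding -> encoder stack -> head."""

    def __init__(self, config: RegressorConfig, feature_names=None):
        config.validate()
        self.config = config
        self.feature_names = (
            list(feature_names)
            if feature_names is not None
            else [f"x{i}" for i in range(config.n_features)]
        )
        if len(self.feature_names) != config.n_features:
            raise ConfigurationError("feature_names length must equal n_features")
        self._rng_init = np.random.default_rng(
            np.random.SeedSequence([int(config.seed), 0x1417])
        )
        self.params: dict[str, Tensor] = {}
        self._build()
        self.x_mean = None
        self.x_std = None
        self.y_mean = None
        self.y_std = None

    # -- parameter construction ------------------------------------------
    def _param(self, name: str, shape, fan_in: int):
        std = 1.0 / np.sqrt(max(fan_in, 1))
        data = self._rng_init.normal(0.0, std, shape).astype(DTYPE)
        t = Tensor(data, requires_grad=True)
        self.params[name] = t
        return t

    def _zeros(self, name: str, shape):
        t = Tensor(np.zeros(shape, dtype=DTYPE), requires_grad=True)
        self.params[name] = t
        return t

    def _ones(self, name: str, shape):
        t = Tensor(np.ones(shape, dtype=DTYPE), requires_grad=True)
        self.params[name] = t
        return t

    def _build(self):
        c = self.config
        f, h, d = c.n_features, c.attn_hidden, c.embed_dim
        ff = c.ff_mult * d
        self._param("attn.W1", (f, h), f)
        self._zeros("attn.b1", (h,))
        # zero-init the logit projection: attention starts exactly uniform
        # (X' = X/f) and differentiates features only as training warrants
        self._zeros("attn.W2", (h, f))
        self._zeros("attn.b2", (f,))
        self._param("embed.W", (f, d), f)
        self._zeros("embed.b", (d,))
        for i in range(c.n_encoder_layers):
            for w in ("Wq", "Wk", "Wv", "Wo"):
                self._param(f"enc{i}.{w}", (d, d), d)
                self._zeros(f"enc{i}.{w}_b", (d,))
            self._ones(f"enc{i}.ln1_g", (d,))
            self._zeros(f"enc{i}.ln1_b", (d,))
            self._param(f"enc{i}.ff1", (d, ff), d)
            self._zeros(f"enc{i}.ff1_b", (ff,))
            self._param(f"enc{i}.ff2", (ff, d), ff)
            self._zeros(f"enc{i}.ff2_b", (d,))
            self._ones(f"enc{i}.ln2_g", (d,))
            self._zeros(f"enc{i}.ln2_b", (d,))
        self._param("head.W1", (d, c.head_hidden), d)
        self._zeros("head.b1", (c.head_hidden,))
        self._param("head.W2", (c.head_hidden, 1), c.head_hidden)
        self._zeros("head.b2", (1,))

    @property
    def attention_params(self) -> AttentionParams:
        p = self.params
        return AttentionParams(
            W1=np.asarray(p["attn.W1"].data, float),
            b1=np.asarray(p["attn.b1"].data, float),
            W2=np.asarray(p["attn.W2"].data, float),
            b2=np.asarray(p["attn.b2"].data, float),
        )

    # -- forward ----------------------------------------------------------
    def _encoder_layer(self, x: Tensor, i: int, training: bool, rng, b: int, s: int):
        """One encoder layer on a flattened (b*s, d) token matrix.

        Linear layers act on the 2-D view (weight gradients collapse to a
        single GEMM); only the attention-score computation reshapes to
        (b, heads, s, head_dim).
        """
        c = self.config
        p = self.params
        d = c.embed_dim
        nh, dh = c.n_heads, d // c.n_heads

        def heads(t):
            t = ad.reshape(t, (b, s, nh, dh))
            return ad.transpose(t, (0, 2, 1, 3))  # (b, nh, s, dh)

        q = heads(ad.add(ad.matmul(x, p[f"enc{i}.Wq"]), p[f"enc{i}.Wq_b"]))
        k = heads(ad.add(ad.matmul(x, p[f"enc{i}.Wk"]), p[f"enc{i}.Wk_b"]))
        v = heads(ad.add(ad.matmul(x, p[f"enc{i}.Wv"]), p[f"enc{i}.Wv_b"]))
        scores = ad.scale(ad.matmul(q, ad.transpose(k, (0, 1, 3, 2))), 1.0 / np.sqrt(dh))
        attn = ad.softmax(scores, axis=-1)
        ctx = ad.matmul(attn, v)  # (b, nh, s, dh)
        ctx = ad.reshape(ad.transpose(ctx, (0, 2, 1, 3)), (b * s, d))
        ctx = ad.add(ad.matmul(ctx, p[f"enc{i}.Wo"]), p[f"enc{i}.Wo_b"])
        ctx = ad.dropout(ctx, c.dropout, rng, training)
        x = ad.layer_norm(ad.add(x, ctx), p[f"enc{i}.ln1_g"], p[f"enc{i}.ln1_b"])

        ffo = ad.relu(ad.add(ad.matmul(x, p[f"enc{i}.ff1"]), p[f"enc{i}.ff1_b"]))
        ffo = ad.dropout(ffo, c.dropout, rng, training)
        ffo = ad.add(ad.matmul(ffo, p[f"enc{i}.ff2"]), p[f"enc{i}.ff2_b"])
        ffo = ad.dropout(ffo, c.dropout, rng, training)
        return ad.layer_norm(ad.add(x, ffo), p[f"enc{i}.ln2_g"], p[f"enc{i}.ln2_b"])

    def _forward_graph(self, X: np.ndarray, training: bool, rng):
        """Forward pass on (already scaled) inputs; returns (pred, A) tensors."""
        c = self.config
        p = self.params
        xt = Tensor(X.astype(DTYPE))
        hid = ad.relu(ad.add(ad.matmul(xt, p["attn.W1"]), p["attn.b1"]))
        logits = ad.add(ad.matmul(hid, p["attn.W2"]), p["attn.b2"])
        A = ad.softmax(logits, axis=-1)
        attended = ad.mul(xt, A)
        z = ad.add(ad.matmul(attended, p["embed.W"]), p["embed.b"])  # (b, d)
        # each subject contributes a single latent token (seq length 1)
        for i in range(c.n_encoder_layers):
            z = self._encoder_layer(z, i, training, rng, b=X.shape[0], s=1)
        hh = ad.relu(ad.add(ad.matmul(z, p["head.W1"]), p["head.b1"]))
        hh = ad.dropout(hh, c.dropout, rng, training)
        out = ad.add(ad.matmul(hh, p["head.W2"]), p["head.b2"])
        return ad.reshape(out, (X.shape[0],)), A

    # -- scaling ----------------------------------------------------------
    @property
    def is_fitted(self) -> bool:
        return self.x_mean is not None

    def _require_fitted(self):
        if not self.is_fitted:
            raise ModelStateError("model has not been fitted (no scaling statistics)")

    def _scale_x(self, X: np.ndarray) -> np.ndarray:
        return (np.asarray(X, float) - self.x_mean) / self.x_std

    def fit(self, X: np.ndarray, y: np.ndarray) -> pd.DataFrame:
        """Train with AdamW + Huber loss; returns per-epoch history."""
        c = self.config
        X = np.atleast_2d(np.asarray(X, dtype=float))
        y = np.asarray(y, dtype=float).ravel()
        if len(X) == 0:
            raise DomainError("training set is empty")
        if X.shape[1] != c.n_features:
            raise DomainError(
                f"X has {X.shape[1]} features, model expects {c.n_features}"
            )
        self.x_mean = X.mean(axis=0)
        self.x_std = np.where(X.std(axis=0) > 0, X.std(axis=0), 1.0)
        self.y_mean = float(y.mean())
        self.y_std = float(y.std()) or 1.0
        Xs = self._scale_x(X)
        ys = (y - self.y_mean) / self.y_std

        ss = np.random.SeedSequence([int(c.seed), 0x7124])
        rng_shuffle, rng_drop = (np.random.default_rng(s) for s in ss.spawn(2))
        opt = ad.AdamW(
            self.params.values(),
            lr=c.lr,
            weight_decay=c.weight_decay,
            clip_norm=c.grad_clip_norm,
        )
        n = len(Xs)
        history = []
        best_loss = np.inf
        best_state = None
        for epoch in range(c.epochs):
            order = rng_shuffle.permutation(n)
            losses = []
            for start in range(0, n, c.batch_size):
                idx = order[start:start + c.batch_size]
                pred, _ = self._forward_graph(Xs[idx], training=True, rng=rng_drop)
                loss = ad.huber_loss(pred, ys[idx], delta=c.huber_delta)
                val = float(loss.data)
                if not np.isfinite(val):
                    raise DivergenceError(epoch)
                loss.backward()
                opt.step()
                losses.append(val)
            epoch_loss = float(np.mean(losses))
            history.append({"epoch": epoch, "train_loss": epoch_loss})
            if epoch_loss < best_loss:
                best_loss = epoch_loss
                best_state = {k: t.data.copy() for k, t in self.params.items()}
        if best_state is not None:
            for k, t in self.params.items():
                t.data = best_state[k]
        return pd.DataFrame(history)

    def predict(self, X: np.ndarray) -> np.ndarray:
        """Deterministic (dropout-off) predictions on the original score scale."""
        self._require_fitted()
        X = np.atleast_2d(np.asarray(X, dtype=float))
        pred, _ = self._forward_graph(self._scale_x(X), training=False, rng=None)
        return np.asarray(pred.data, dtype=float) * self.y_std + self.y_mean

    def attention_weights(self, X: np.ndarray) -> np.ndarray:
        """Per-sample attention weight vectors over the input features."""
        self._require_fitted()
        X = np.atleast_2d(np.asarray(X, dtype=float))
        _, A = self._forward_graph(self._scale_x(X), training=False, rng=None)
        return np.asarray(A.data, dtype=float)

    # -- persistence ------------------------------------------------------
    def save(self, path: str | Path) -> None:
        self._require_fitted()
        arrays = {f"param::{k}": t.data for k, t in self.params.items()}
        arrays.update(
            x_mean=self.x_mean, x_std=self.x_std,
            y_stats=np.array([self.y_mean, self.y_std]),
        )
        meta = json.dumps(
            {"config": asdict(self.config), "feature_names": self.feature_names}
        )
        np.savez(path, meta=np.array(meta), **arrays)

    @classmethod
    def load(cls, path: str | Path) -> "AttentionRegressor":
        with np.load(path, allow_pickle=False) as z:
            meta = json.loads(str(z["meta"]))
            model = cls(RegressorConfig(**meta["config"]), meta["feature_names"])
            for k, t in model.params.items():
                t.data = z[f"param::{k}"].astype(DTYPE)
            model.x_mean = z["x_mean"]
            model.x_std = z["x_std"]
            model.y_mean, model.y_std = (float(v) for v in z["y_stats"])
        return model


# ---------------------------------------------------------------------------
# Data handling and train/evaluate entry points
# ---------------------------------------------------------------------------

def split_data(
    table: pd.DataFrame,
    split_ratio: float = 0.9,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Seed-reproducible train/test split, stratified by ``group`` if present.

    The test size is ``round((1 - ratio) * n)`` (at least 1), allocated to
    strata by largest remainder so that per-group proportions are preserved.
    """
    n = len(table)
    if n < 2:
        raise DomainError("need at least 2 rows to split")
    if not 0 < split_ratio < 1:
        raise ConfigurationError("split_ratio must be in (0, 1)")
    n_test = max(int(round((1 - split_ratio) * n)), 1)
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0x5B117]))

    if "group" in table.columns:
        groups = sorted(table["group"].unique())
        quotas = {g: (table["group"] == g).sum() * n_test / n for g in groups}
        alloc = {g: int(np.floor(q)) for g, q in quotas.items()}
        leftover = n_test - sum(alloc.values())
        for g in sorted(groups, key=lambda g: (-(quotas[g] - alloc[g]), g))[:leftover]:
            alloc[g] += 1
        test_idx = []
        for g in groups:
            idx = table.index[table["group"] == g].to_numpy()
            take = min(alloc[g], len(idx))
            test_idx.extend(rng.permutation(idx)[:take])
        test_idx = np.array(sorted(test_idx))
    else:
        test_idx = np.array(sorted(rng.permutation(table.index.to_numpy())[:n_test]))

    test = table.loc[test_idx]
    train = table.drop(index=test_idx)
    return train, test


def train_model(
    train: pd.DataFrame,
    target: str,
    feature_names,
    config: RegressorConfig | None = None,
) -> tuple[AttentionRegressor, pd.DataFrame]:
    """Fit an :class:`AttentionRegressor` on the given rows and feature columns."""
    feature_names = list(feature_names)
    if config is None:
        config = RegressorConfig(n_features=len(feature_names))
    if config.n_features != len(feature_names):
        raise ConfigurationError("config.n_features must match feature_names")
    model = AttentionRegressor(config, feature_names)
    history = model.fit(
        train[feature_names].to_numpy(float), train[target].to_numpy(float)
    )
    return model, history


def evaluate(model: AttentionRegressor, test: pd.DataFrame, target: str) -> Metrics:
    """Held-out metrics (R^2 / MSE / MAE) in score points."""
    if len(test) == 0:
        raise DomainError("test set is empty")
    preds = model.predict(test[list(model.feature_names)].to_numpy(float))
    return compute_metrics(test[target].to_numpy(float), preds)
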