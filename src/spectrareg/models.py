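"""The seven calibration models: PLSR, SVR, CNN, LSTM, CNN-LSTM,
Transformer, and CNN-Transformer.

The linear/kernel baselines (PLSR, SVR) ride on scikit-learn with the
hyperparameter grids fixed by the study design: PLSR components searched
over 1-21, SVR gamma over [1e-4, 1e5] across linear/polynomial/Gaussian
kernels, both by cross-validated grid search on the calibration set only.

The deep models are built on the package's own numpy autodiff stack
(:mod:`spectrareg.nn`).  The flagship CNN-Transformer feeds the spectrum
through two same-padded 1-D convolutions (1 -> 128 -> 256 channels,
kernel 3), so each of the 209 retained bands becomes one 256-wide token;
sinusoidal position codes are added and six Transformer encoder layers
(4 heads, d_k = d_q = d_v = 64, feed-forward width 1024) refine the
sequence before mean-pooling and a linear regression head.  Training
minimises MSE with AdamW (lr 0.0008, batch 10) and early stopping on
validation RMSE.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import numpy as np
from sklearn.model_selection import GridSearchCV
from sklearn.cross_decomposition import PLSRegression
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVR

from .exceptions import DivergedTrainingError, ParameterError
from .nn import (
    AdamW,
    Conv1d,
    Dropout,
    LSTMCell,
    Linear,
    Module,
    Tensor,
    TransformerEncoderLayer,
    no_grad,
    positional_encoding,
)

__all__ = [
    "PlsrSpec",
    "SvrSpec",
    "CnnSpec",
    "LstmSpec",
    "CnnLstmSpec",
    "TransformerSpec",
    "TrainConfig",
    "TrainedModel",
    "MODEL_KINDS",
    "positional_encoding",
    "scaled_attention",
    "build_model",
    "train_model",
    "fit_plsr",
    "fit_svr",
    "fit_model",
    "predict",
    "n_parameters",
    "save_model",
    "load_model",
]

MODEL_KINDS = ("plsr", "svr", "cnn", "lstm", "cnn_lstm", "transformer", "cnn_transformer")


# ---------------------------------------------------------------------------
# Specs
# ---------------------------------------------------------------------------

@dataclass
class PlsrSpec:
    component_grid: tuple = tuple(range(1, 22))
    cv_folds: int = 5

    def validate(self, n_bands: int):
        if not self.component_grid:
            raise ParameterError("component grid must be non-empty")
        if any(c < 1 for c in self.component_grid):
            raise ParameterError("component counts must be >= 1")
        if min(self.component_grid) >= n_bands:
            raise ParameterError("no component count is < the number of bands")


@dataclass
class SvrSpec:
    kernel_set: tuple = ("linear", "polynomial", "gaussian")
    gamma_grid: tuple = tuple(np.logspace(-4, 5, 10))
    c_grid: tuple = (0.1, 1.0, 10.0, 100.0)
    poly_degree: int = 3
    cv_folds: int = 5

    def validate(self, n_bands: int):
        if not self.kernel_set or not self.gamma_grid or not self.c_grid:
            raise ParameterError("SVR grids must be non-empty")
        bad = set(self.kernel_set) - {"linear", "polynomial", "gaussian"}
        if bad:
            raise ParameterError(f"unknown kernels: {sorted(bad)}")


@dataclass
class CnnSpec:
    conv_channels: tuple = (128, 256)
    kernel_size: int = 3
    dropout_p: float = 0.3
    fc_hidden: int = 64
    lr: float = 0.0005


@dataclass
class LstmSpec:
    input_dim: int = 1024
    hidden_dim: int = 1024


@dataclass
class CnnLstmSpec:
    conv_channels: tuple = (128, 256, 512)
    kernel_size: int = 3
    lstm_hidden: int = 256


@dataclass
class TransformerSpec:
    d_model: int = 256
    n_layers: int = 6
    n_heads: int = 4
    ff_hidden: int = 1024
    front_end: str = "conv"  # "conv" -> CNN-Transformer; "none" -> Transformer alone
    conv_channels: tuple = (128, 256)
    kernel_size: int = 3
    lr: float = 0.0008

    def validate(self, n_bands: int):
        if self.d_model % self.n_heads != 0:
            raise ParameterError("d_model must be divisible by n_heads")
        if self.front_end not in ("conv", "none"):
            raise ParameterError("front_end must be 'conv' or 'none'")
        if self.front_end == "conv" and self.conv_channels[-1] != self.d_model:
            raise ParameterError("last conv channel count must equal d_model")


@dataclass
class TrainConfig:
    """Optimisation settings for the deep models (MSE loss, AdamW)."""

    lr: float = 0.0008
    batch_size: int = 10
    max_epochs: int = 500
    patience: int = 50
    weight_decay: float = 0.01
    warmup_steps: int = 50
    grad_clip: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if self.lr <= 0:
            raise ParameterError("lr must be positive")
        if self.batch_size < 1:
            raise ParameterError("batch_size must be >= 1")


# ---------------------------------------------------------------------------
# Closed-form building blocks
# ---------------------------------------------------------------------------

def scaled_attention(q: np.ndarray, k: np.ndarray, v: np.ndarray) -> np.ndarray:
    """Scaled dot-product attention, ``softmax(Q K^T / sqrt(d_k)) V``.

    ``q``: (n, d_k); ``k``: (m, d_k); ``v``: (m, d_v).  Pure numpy, used
    both as the reference formula and (through the autodiff twin in
    :mod:`spectrareg.nn.layers`) inside the encoder.
    """
    q, k, v = (np.asarray(a, dtype=float) for a in (q, k, v))
    if q.ndim != 2 or k.ndim != 2 or v.ndim != 2:
        raise ParameterError("Q, K, V must be 2-D")
    if q.shape[1] != k.shape[1] or k.shape[0] != v.shape[0]:
        raise ParameterError("incompatible Q/K/V shapes")
    scores = q @ k.T / np.sqrt(q.shape[1])
    scores -= scores.max(axis=1, keepdims=True)
    w = np.exp(scores)
    w /= w.sum(axis=1, keepdims=True)
    return w @ v


# ---------------------------------------------------------------------------
# Deep architectures
# ---------------------------------------------------------------------------

class _DeepRegressor(Module):
    """Common surface: forward (N, B) counts -> (N, 1) Tensor."""

    n_bands: int
    has_conv: bool = False

    def forward(self, x) -> Tensor:  # pragma: no cover - abstract
        raise NotImplementedError


class CnnRegressor(_DeepRegressor):
    def __init__(self, n_bands: int, spec: CnnSpec, rng: np.random.Generator):
        super().__init__()
        self.n_bands = n_bands
        self.spec = spec
        self.has_conv = True
        c1, c2 = spec.conv_channels
        self.conv1 = Conv1d(1, c1, spec.kernel_size, rng)
        self.conv2 = Conv1d(c1, c2, spec.kernel_size, rng)
        self.fc = Linear(c2 * n_bands, spec.fc_hidden, rng)
        self.dropout = Dropout(spec.dropout_p, rng)
        self.head = Linear(spec.fc_hidden, 1, rng)
        self.conv_features: Tensor | None = None

    def forward(self, x) -> Tensor:
        h = Tensor(np.asarray(x, dtype=np.float32)[:, None, :]) if not isinstance(x, Tensor) else x
        h = self.conv1(h).relu()
        h = self.conv2(h).relu()
        self.conv_features = h
        n = h.shape[0]
        h = self.fc(h.reshape(n, h.shape[1] * h.shape[2])).relu()
        return self.head(self.dropout(h))


class TransformerRegressor(_DeepRegressor):
    """Transformer encoder over the band sequence; optional conv front-end."""

    def __init__(self, n_bands: int, spec: TransformerSpec, rng: np.random.Generator):
        super().__init__()
        spec.validate(n_bands)
        self.n_bands = n_bands
        self.spec = spec
        self.has_conv = spec.front_end == "conv"
        if self.has_conv:
            # bias-free so the feature map is proportional to spectral
            # deviations: a constant bias pedestal in the conv activations
            # floods Grad-CAM profiles with a position-independent offset
            c1, c2 = spec.conv_channels
            self.conv1 = Conv1d(1, c1, spec.kernel_size, rng, bias=False)
            self.conv2 = Conv1d(c1, c2, spec.kernel_size, rng, bias=False)
        else:
            self.lift = Linear(1, spec.d_model, rng)
        self.pe = positional_encoding(n_bands, spec.d_model).astype(np.float32)
        self.layers = [TransformerEncoderLayer(spec.d_model, spec.n_heads, spec.ff_hidden, rng)
                       for _ in range(spec.n_layers)]
        self.head = Linear(spec.d_model, 1, rng)
        self.conv_features: Tensor | None = None

    def forward(self, x) -> Tensor:
        arr = np.asarray(x, dtype=np.float32)
        if self.has_conv:
            h = Tensor(arr[:, None, :])
            h = self.conv1(h).relu()
            h = self.conv2(h).relu()
            self.conv_features = h
            tokens = h.transpose(0, 2, 1)  # (N, L, d_model)
        else:
            n = arr.shape[0]
            tokens = self.lift(Tensor(arr.reshape(n, self.n_bands, 1)))
        tokens = tokens + self.pe[None, :, :]
        for layer in self.layers:
            tokens = layer(tokens)
        pooled = tokens.mean(axis=1)
        return self.head(pooled)


class LstmRegressor(_DeepRegressor):
    """Linear lift of the spectrum to 1024 dims, consumed as one LSTM step."""

    def __init__(self, n_bands: int, spec: LstmSpec, rng: np.random.Generator):
        super().__init__()
        self.n_bands = n_bands
        self.spec = spec
        self.lift = Linear(n_bands, spec.input_dim, rng)
        self.cell = LSTMCell(spec.input_dim, spec.hidden_dim, rng)
        self.head = Linear(spec.hidden_dim, 1, rng)
        self.hidden_dim = spec.hidden_dim

    def forward(self, x) -> Tensor:
        arr = np.asarray(x, dtype=np.float32)
        n = arr.shape[0]
        z = self.lift(Tensor(arr))
        h0 = Tensor(np.zeros((n, self.hidden_dim), dtype=np.float32))
        c0 = Tensor(np.zeros((n, self.hidden_dim), dtype=np.float32))
        h, _ = self.cell(z, h0, c0)
        return self.head(h)


class CnnLstmRegressor(_DeepRegressor):
    def __init__(self, n_bands: int, spec: CnnLstmSpec, rng: np.random.Generator):
        super().__init__()
        self.n_bands = n_bands
        self.spec = spec
        self.has_conv = True
        c1, c2, c3 = spec.conv_channels
        self.conv1 = Conv1d(1, c1, spec.kernel_size, rng)
        self.conv2 = Conv1d(c1, c2, spec.kernel_size, rng)
        self.conv3 = Conv1d(c2, c3, spec.kernel_size, rng)
        self.cell = LSTMCell(c3, spec.lstm_hidden, rng)
        self.head = Linear(spec.lstm_hidden, 1, rng)
        self.hidden_dim = spec.lstm_hidden
        self.conv_features: Tensor | None = None

    def forward(self, x) -> Tensor:
        arr = np.asarray(x, dtype=np.float32)
        h = Tensor(arr[:, None, :])
        h = self.conv1(h).relu()
        h = self.conv2(h).relu()
        h = self.conv3(h).relu()
        self.conv_features = h
        tokens = h.transpose(0, 2, 1)  # (N, L, C)
        n, length, _ = tokens.shape
        state_h = Tensor(np.zeros((n, self.hidden_dim), dtype=np.float32))
        state_c = Tensor(np.zeros((n, self.hidden_dim), dtype=np.float32))
        for t in range(length):
            state_h, state_c = self.cell(tokens[:, t, :], state_h, state_c)
        return self.head(state_h)


_SPEC_DEFAULTS = {
    "cnn": CnnSpec,
    "lstm": LstmSpec,
    "cnn_lstm": CnnLstmSpec,
    "transformer": lambda: TransformerSpec(front_end="none"),
    "cnn_transformer": TransformerSpec,
}

_ARCH = {
    "cnn": (CnnRegressor, CnnSpec),
    "lstm": (LstmRegressor, LstmSpec),
    "cnn_lstm": (CnnLstmRegressor, CnnLstmSpec),
    "transformer": (TransformerRegressor, TransformerSpec),
    "cnn_transformer": (TransformerRegressor, TransformerSpec),
}


def build_model(kind: str, n_bands: int, spec=None, seed: int = 0) -> _DeepRegressor:
    """Instantiate an untrained deep regressor with seeded initialisation."""
    if kind not in _ARCH:
        raise ParameterError(f"unknown deep model kind {kind!r}; choose from {list(_ARCH)}")
    cls, spec_cls = _ARCH[kind]
    if spec is None:
        spec = _SPEC_DEFAULTS[kind]()
    if not isinstance(spec, spec_cls):
        raise ParameterError(f"{kind} expects a {spec_cls.__name__}")
    if kind == "transformer" and spec.front_end != "none":
        raise ParameterError("plain transformer must have front_end='none'")
    if kind == "cnn_transformer" and spec.front_end != "conv":
        raise ParameterError("cnn_transformer must have front_end='conv'")
    rng = np.random.default_rng(seed)
    return cls(n_bands, spec, rng)


def n_parameters(model: Module) -> int:
    return int(sum(p.data.size for p in model.parameters()))


# ---------------------------------------------------------------------------
# Trained-model wrapper
# ---------------------------------------------------------------------------

@dataclass
class TrainedModel:
    """A fitted model plus the input/target scalers and training history."""

    kind: str
    model: object
    n_bands: int
    x_mean: np.ndarray | None = None
    x_sd: np.ndarray | None = None
    y_mean: float = 0.0
    y_sd: float = 1.0
    history: list = field(default_factory=list)
    best_epoch: int = 0
    seed: int = 0
    extra: dict = field(default_factory=dict)

    def predict(self, x: np.ndarray) -> np.ndarray:
        return predict(self, x)


def predict(trained: TrainedModel, x: np.ndarray) -> np.ndarray:
    """Deterministic predictions on the original target scale."""
    x = np.asarray(x, dtype=float)
    if x.ndim != 2 or x.shape[1] != trained.n_bands:
        raise ParameterError(
            f"expected N x {trained.n_bands} input, got {x.shape}")
    if isinstance(trained.model, Module):
        z = x
        if trained.x_mean is not None:
            z = (x - trained.x_mean) / trained.x_sd
        trained.model.eval()
        out = _forward_chunked(trained.model, z.astype(np.float32))
        return out * trained.y_sd + trained.y_mean
    # scikit-learn estimator (PLSR / SVR pipeline)
    out = np.asarray(trained.model.predict(x)).ravel()
    return out * trained.y_sd + trained.y_mean


# ---------------------------------------------------------------------------
# Training
# ---------------------------------------------------------------------------

def _forward_chunked(model: Module, x: np.ndarray, chunk: int = 64) -> np.ndarray:
    """Inference in bounded-memory chunks (attention maps grow as N·L²)."""
    outs = []
    with no_grad():
        for start in range(0, x.shape[0], chunk):
            outs.append(model(x[start:start + chunk]).data.ravel().astype(float))
    return np.concatenate(outs)


def _clip_global_norm(params, max_norm: float):
    total = np.sqrt(sum(float((p.grad ** 2).sum()) for p in params if p.grad is not None))
    if np.isfinite(total) and total > max_norm:
        scale = max_norm / total
        for p in params:
            if p.grad is not None:
                p.grad *= scale


def _standardize_fit(x: np.ndarray):
    """Per-band centering with a single global scale.

    A per-band variance scale would whiten away the amplitude contrast
    between analyte-informative bands and the rest of the spectrum —
    contrast that both the convolutions and Grad-CAM attribution rely
    on — so only one scalar standard deviation (over the whole centred
    calibration matrix) is used.
    """
    mu = x.mean(axis=0)
    sd = float((x - mu).std())
    if sd < 1e-12:
        sd = 1.0
    return mu, np.full(1, sd)


def train_model(model: _DeepRegressor, x_cal: np.ndarray, y_cal: np.ndarray,
                x_val: np.ndarray, y_val: np.ndarray, cfg: TrainConfig | None = None,
                kind: str = "deep") -> TrainedModel:
    """Mini-batch AdamW training with early stopping on validation RMSE.

    Inputs are standardised per band and the target z-scored, both using
    calibration statistics only; predictions are mapped back to the
    original scale.  The learning rate ramps linearly over
    ``cfg.warmup_steps`` optimiser steps and gradients are clipped to a
    global norm of ``cfg.grad_clip`` — both standard stabilisers for
    training Transformer encoders from scratch at a fixed base rate.
    The parameter state with the lowest validation RMSE is kept; training
    stops after ``cfg.patience`` epochs without improvement or at
    ``cfg.max_epochs``.
    """
    cfg = cfg or TrainConfig()
    x_cal = np.asarray(x_cal, dtype=float)
    x_val = np.asarray(x_val, dtype=float)
    y_cal = np.asarray(y_cal, dtype=float).ravel()
    y_val = np.asarray(y_val, dtype=float).ravel()
    if x_cal.shape[0] != y_cal.size or x_val.shape[0] != y_val.size:
        raise ParameterError("X/y length mismatch")

    x_mean, x_sd = _standardize_fit(x_cal)
    y_mean = float(y_cal.mean())
    y_sd = float(y_cal.std())
    if y_sd < 1e-12:
        y_sd = 1.0
    xc = ((x_cal - x_mean) / x_sd).astype(np.float32)
    xv = ((x_val - x_mean) / x_sd).astype(np.float32)
    yc = ((y_cal - y_mean) / y_sd).astype(np.float32)[:, None]
    yv_true = y_val

    rng = np.random.default_rng(cfg.seed)
    opt = AdamW(model.parameters(), lr=cfg.lr, weight_decay=cfg.weight_decay)
    trained = TrainedModel(kind=kind, model=model, n_bands=x_cal.shape[1],
                           x_mean=x_mean, x_sd=x_sd, y_mean=y_mean, y_sd=y_sd,
                           seed=cfg.seed)

    n = xc.shape[0]
    best_rmse = np.inf
    best_state = model.state_dict()
    best_epoch = 0
    since_best = 0
    step = 0
    for epoch in range(1, cfg.max_epochs + 1):
        model.train()
        order = rng.permutation(n)
        epoch_loss = 0.0
        for start in range(0, n, cfg.batch_size):
            idx = order[start:start + cfg.batch_size]
            step += 1
            if cfg.warmup_steps:
                opt.lr = cfg.lr * min(1.0, step / cfg.warmup_steps)
            pred = model(xc[idx])
            err = pred - yc[idx]
            loss = (err * err).mean()
            value = float(loss.data)
            if not np.isfinite(value):
                raise DivergedTrainingError(epoch)
            opt.zero_grad()
            loss.backward()
            if cfg.grad_clip:
                _clip_global_norm(opt.params, cfg.grad_clip)
            opt.step()
            epoch_loss += value * idx.size
        epoch_loss /= n

        model.eval()
        val_pred = _forward_chunked(model, xv) * y_sd + y_mean
        val_rmse = float(np.sqrt(np.mean((val_pred - yv_true) ** 2)))
        trained.history.append({"epoch": epoch, "train_loss": epoch_loss, "val_rmse": val_rmse})

        if val_rmse < best_rmse:
            best_rmse = val_rmse
            best_state = model.state_dict()
            best_epoch = epoch
            since_best = 0
        else:
            since_best += 1
            if since_best >= cfg.patience:
                break

    model.load_state_dict(best_state)
    trained.best_epoch = best_epoch
    return trained


# ---------------------------------------------------------------------------
# Classical models
# ---------------------------------------------------------------------------

def fit_plsr(x: np.ndarray, y: np.ndarray, spec: PlsrSpec | None = None) -> TrainedModel:
    """PLSR with the component count chosen by cross-validated grid search."""
    spec = spec or PlsrSpec()
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    spec.validate(x.shape[1])
    grid = [c for c in spec.component_grid if c < min(x.shape[0], x.shape[1])]
    if not grid:
        raise ParameterError("no feasible component count for this data size")
    search = GridSearchCV(PLSRegression(scale=False), {"n_components": grid},
                          cv=spec.cv_folds, scoring="neg_mean_squared_error")
    search.fit(x, y)
    trained = TrainedModel(kind="plsr", model=search.best_estimator_, n_bands=x.shape[1])
    trained.extra["n_components"] = int(search.best_params_["n_components"])
    return trained


_KERNEL_NAMES = {"linear": "linear", "polynomial": "poly", "gaussian": "rbf"}


def fit_svr(x: np.ndarray, y: np.ndarray, spec: SvrSpec | None = None) -> TrainedModel:
    """SVR over linear/polynomial/Gaussian kernels with CV grid search.

    Inputs are standardised inside the pipeline; the target is z-scored
    so the default epsilon-tube width is meaningful across targets.
    """
    spec = spec or SvrSpec()
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    spec.validate(x.shape[1])
    y_mean, y_sd = float(y.mean()), float(y.std())
    if y_sd < 1e-12:
        y_sd = 1.0
    yz = (y - y_mean) / y_sd

    param_grid = []
    c_list = list(spec.c_grid)
    gammas = list(spec.gamma_grid)
    if "linear" in spec.kernel_set:
        param_grid.append({"svr__kernel": ["linear"], "svr__C": c_list})
    if "polynomial" in spec.kernel_set:
        param_grid.append({"svr__kernel": ["poly"], "svr__C": c_list,
                           "svr__gamma": gammas, "svr__degree": [spec.poly_degree]})
    if "gaussian" in spec.kernel_set:
        param_grid.append({"svr__kernel": ["rbf"], "svr__C": c_list, "svr__gamma": gammas})
    pipe = Pipeline([("scale", StandardScaler()), ("svr", SVR())])
    search = GridSearchCV(pipe, param_grid, cv=spec.cv_folds, scoring="neg_mean_squared_error")
    search.fit(x, yz)
    trained = TrainedModel(kind="svr", model=search.best_estimator_, n_bands=x.shape[1],
                           y_mean=y_mean, y_sd=y_sd)
    trained.extra["best_params"] = {k.replace("svr__", ""): v
                                    for k, v in search.best_params_.items()}
    return trained


def save_model(trained: TrainedModel, path) -> None:
    """Persist a deep TrainedModel (spec, seed, scalers, history, weights).

    Classical models (PLSR/SVR) are cheap to refit and are not
    serialised here.
    """
    if not isinstance(trained.model, Module):
        raise ParameterError("save_model supports the deep (numpy) models only")
    spec = getattr(trained.model, "spec", None)
    meta = {
        "kind": trained.kind,
        "n_bands": trained.n_bands,
        "y_mean": trained.y_mean,
        "y_sd": trained.y_sd,
        "seed": trained.seed,
        "best_epoch": trained.best_epoch,
        "history": trained.history,
        "extra": {k: v for k, v in trained.extra.items()
                  if isinstance(v, (int, float, str, list))},
        "spec": dataclasses.asdict(spec) if spec is not None else None,
    }
    arrays = {f"param_{i}": p for i, p in enumerate(trained.model.state_dict())}
    if trained.x_mean is not None:
        arrays["x_mean"] = trained.x_mean
        arrays["x_sd"] = trained.x_sd
    np.savez(path, meta=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8), **arrays)


def load_model(path) -> TrainedModel:
    """Rebuild a deep TrainedModel written by :func:`save_model`."""
    with np.load(path) as bundle:
        meta = json.loads(bytes(bundle["meta"].tobytes()).decode())
        kind = meta["kind"]
        if kind not in _ARCH:
            raise ParameterError(f"cannot rebuild model kind {kind!r}")
        spec = None
        if meta["spec"] is not None:
            spec_cls = _ARCH[kind][1]
            fields = {f.name for f in dataclasses.fields(spec_cls)}
            raw = {k: tuple(v) if isinstance(v, list) else v
                   for k, v in meta["spec"].items() if k in fields}
            spec = spec_cls(**raw)
        model = build_model(kind, meta["n_bands"], spec=spec, seed=meta["seed"])
        state = [bundle[f"param_{i}"] for i in range(len(model.parameters()))]
        model.load_state_dict(state)
        trained = TrainedModel(
            kind=kind, model=model, n_bands=meta["n_bands"],
            x_mean=bundle["x_mean"] if "x_mean" in bundle else None,
            x_sd=bundle["x_sd"] if "x_sd" in bundle else None,
            y_mean=meta["y_mean"], y_sd=meta["y_sd"],
            history=meta["history"], best_epoch=meta["best_epoch"], seed=meta["seed"])
        trained.extra.update(meta.get("extra", {}))
    return trained


def fit_model(kind: str, x_cal, y_cal, x_val=None, y_val=None,
              cfg: TrainConfig | None = None, spec=None, seed: int = 0) -> TrainedModel:
    """One entry point for all seven model families.

    Classical models (``plsr``, ``svr``) use the calibration part only;
    deep models additionally need the validation part for early stopping.
    Deep learning rates default to the per-family values (0.0005 for the
    CNN, 0.0008 otherwise) unless ``cfg`` overrides them.
    """
    if kind == "plsr":
        return fit_plsr(x_cal, y_cal, spec)
    if kind == "svr":
        return fit_svr(x_cal, y_cal, spec)
    if kind not in _ARCH:
        raise ParameterError(f"unknown model kind {kind!r}")
    if x_val is None or y_val is None:
        raise ParameterError("deep models need a validation part for early stopping")
    if cfg is None:
        lr = 0.0005 if kind == "cnn" else 0.0008
        cfg = TrainConfig(lr=lr, seed=seed)
    model = build_model(kind, np.asarray(x_cal).shape[1], spec=spec, seed=cfg.seed)
    return train_model(model, x_cal, y_cal, x_val, y_val, cfg, kind=kind)
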