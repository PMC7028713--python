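"""Dimensionality reduction: sigmoid autoencoder and PCA baseline.

The central computation of the package.  Ten biomarkers are min-max scaled
into a subinterval of (0, 1) (sigmoid outputs cannot reach raw clinical
scales such as SBP ~ 120 mmHg), then fed through a symmetric multilayer
autoencoder with sigmoid activations everywhere and a one-unit bottleneck.
The network is trained by backpropagation to minimize the mean squared
reconstruction error; the bottleneck activation is the extracted scalar —
the general chronic condition score (GCC).  A PCA projection onto the first
principal component, fit on the same scaled training data, is the linear
baseline.  Hyper-parameters (depth, widths, learning rate, batch size) can
be chosen by coordinate-wise greedy search on a validation split.

The implementation is plain NumPy: these networks have a few hundred
parameters, and an explicit forward/backward pass keeps the gradients
checkable against finite differences.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np
from scipy.special import expit
from sklearn.decomposition import PCA as _SKPCA

from .exceptions import ConfigError, DomainError, TrainingError

#: Default architecture (layer widths, input to output) when search is off.
DEFAULT_ARCH: tuple[int, ...] = (10, 8, 4, 1, 4, 8, 10)

_ACTIVATIONS: dict[str, tuple[Callable, Callable]] = {
    # (f(z), f'(a) expressed in terms of the activation a = f(z))
    "sigmoid": (expit, lambda a: a * (1.0 - a)),
    "identity": (lambda z: z, lambda a: np.ones_like(a)),
}


# ---------------------------------------------------------------------------
# feature scaling

@dataclass
class FeatureScaler:
    """Per-feature affine map from the observed [min, max] to [lo, hi].

    Fit on training data only.  Values outside the training range map
    outside [lo, hi] — deliberately not clipped, so held-out extremes keep
    their ordering.  ``transform`` then ``inverse_transform`` recovers the
    input to ~1e-12 relative accuracy.
    """

    lo: float = 0.1
    hi: float = 0.9
    mins: np.ndarray | None = None
    maxs: np.ndarray | None = None
    feature_names: list[str] | None = None
    n_fit: int | None = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.lo < self.hi <= 1.0):
            raise ConfigError("target interval must satisfy 0 <= lo < hi <= 1")

    def fit(self, X, feature_names: Sequence[str] | None = None) -> "FeatureScaler":
        X = np.asarray(X, dtype=float)
        mins, maxs = X.min(axis=0), X.max(axis=0)
        constant = np.flatnonzero(maxs - mins <= 0)
        if constant.size:
            names = ([feature_names[i] for i in constant] if feature_names is not None
                     else list(constant))
            raise DomainError(f"constant feature(s), cannot scale: {names}")
        self.mins, self.maxs = mins, maxs
        self.feature_names = list(feature_names) if feature_names is not None else None
        self.n_fit = X.shape[0]
        return self

    def transform(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        return self.lo + (X - self.mins) / (self.maxs - self.mins) * (self.hi - self.lo)

    def inverse_transform(self, S) -> np.ndarray:
        S = np.asarray(S, dtype=float)
        return self.mins + (S - self.lo) / (self.hi - self.lo) * (self.maxs - self.mins)


# ---------------------------------------------------------------------------
# autoencoder

@dataclass
class TrainConfig:
    """Backpropagation settings.

    Adam (learning rate 0.01) is the default optimizer: on these targets —
    min-max-compressed into a 0.8-wide interval, so per-entry error signals
    are of order 1e-2 — plain SGD with momentum stalls at the mean-predictor
    plateau for any practical epoch budget, while Adam's per-parameter step
    normalisation escapes it within tens of epochs.  SGD with momentum 0.9
    remains available via ``optimizer="sgd"``.  Early stopping monitors the MSE on an internal
    validation split (``val_fraction`` of rows) with the given patience and
    improvement tolerance; with ``val_fraction=0`` it monitors training MSE.
    """

    learning_rate: float = 0.01
    batch_size: int = 32
    max_epochs: int = 300
    patience: int = 20
    tol: float = 1e-7
    seed: int = 0
    momentum: float = 0.9
    optimizer: str = "adam"
    val_fraction: float = 0.1

    def __post_init__(self) -> None:
        if self.learning_rate < 0:
            raise ConfigError("learning rate must be >= 0")
        if self.batch_size < 1:
            raise ConfigError("batch size must be >= 1")
        if self.optimizer not in ("sgd", "adam"):
            raise ConfigError(f"unknown optimizer {self.optimizer!r}")
        if not (0.0 <= self.val_fraction < 1.0):
            raise ConfigError("val_fraction must lie in [0, 1)")


def n_parameters(widths: Sequence[int]) -> int:
    """Total weight + bias count of the architecture."""
    return sum(widths[i] * widths[i + 1] + widths[i + 1] for i in range(len(widths) - 1))


def _validate_arch(widths: Sequence[int], n_features: int) -> None:
    if len(widths) < 3:
        raise ConfigError("architecture needs at least input, bottleneck, output")
    if widths[0] != n_features or widths[-1] != n_features:
        raise ConfigError(
            f"architecture must start and end at {n_features} features, got {widths}")
    if not (1 <= min(widths[1:-1]) < n_features):
        raise ConfigError("bottleneck must be narrower than the input "
                          "(width 1 for the GCC; wider only as a test hook)")


@dataclass
class AutoencoderModel:
    """Trained autoencoder: layer widths, weights/biases, activation name,
    the scaler used on its inputs, and the per-epoch training-loss history
    (full-data MSE in scaled space)."""

    widths: tuple[int, ...]
    weights: list[np.ndarray]
    biases: list[np.ndarray]
    activation: str = "sigmoid"
    scaler: FeatureScaler | None = None
    loss_history: list[float] = field(default_factory=list)

    @property
    def bottleneck_index(self) -> int:
        """Index (into ``widths``) of the bottleneck layer."""
        interior = self.widths[1:-1]
        return 1 + int(np.argmin(interior))

    # -- passes ----------------------------------------------------------
    def forward(self, S: np.ndarray) -> list[np.ndarray]:
        """All layer activations for scaled input S (first entry is S)."""
        act, _ = _ACTIVATIONS[self.activation]
        a = np.asarray(S, dtype=float)
        acts = [a]
        for W, b in zip(self.weights, self.biases):
            a = act(a @ W + b)
            acts.append(a)
        return acts

    def encode_scaled(self, S: np.ndarray) -> np.ndarray:
        act, _ = _ACTIVATIONS[self.activation]
        a = np.asarray(S, dtype=float)
        for W, b in zip(self.weights[: self.bottleneck_index],
                        self.biases[: self.bottleneck_index]):
            a = act(a @ W + b)
        return a[:, 0] if a.shape[1] == 1 else a

    def encode(self, X_raw) -> np.ndarray:
        """GCC scores for raw biomarker rows (applies the stored scaler)."""
        X = np.asarray(X_raw, dtype=float)
        if X.ndim != 2 or X.shape[1] != self.widths[0]:
            raise ConfigError(
                f"expected {self.widths[0]} columns, got {X.shape}")
        if self.scaler is None:
            raise ConfigError("model has no stored scaler; pass scaled data "
                              "to encode_scaled instead")
        return self.encode_scaled(self.scaler.transform(X))

    def reconstruct(self, X_raw) -> tuple[np.ndarray, np.ndarray]:
        """Full encoder->decoder pass.

        Returns the reconstruction in original units and the per-row MSE
        measured in scaled space (so features contribute comparably).
        """
        X = np.asarray(X_raw, dtype=float)
        if X.ndim != 2 or X.shape[1] != self.widths[0]:
            raise ConfigError(f"expected {self.widths[0]} columns, got {X.shape}")
        if self.scaler is None:
            raise ConfigError("model has no stored scaler")
        S = self.scaler.transform(X)
        out = self.forward(S)[-1]
        per_row = ((out - S) ** 2).mean(axis=1)
        return self.scaler.inverse_transform(out), per_row


def init_autoencoder(widths: Sequence[int], activation: str = "sigmoid",
                     seed: int = 0) -> AutoencoderModel:
    """Glorot-uniform initialisation, seeded."""
    rng = np.random.default_rng(seed)
    weights, biases = [], []
    for fan_in, fan_out in zip(widths[:-1], widths[1:]):
        limit = np.sqrt(6.0 / (fan_in + fan_out))
        weights.append(rng.uniform(-limit, limit, size=(fan_in, fan_out)))
        biases.append(np.zeros(fan_out))
    return AutoencoderModel(tuple(int(w) for w in widths), weights, biases, activation)


def loss_and_grads(model: AutoencoderModel, S: np.ndarray
                   ) -> tuple[float, list[np.ndarray], list[np.ndarray]]:
    """MSE reconstruction loss and its analytic gradients.

    Loss is the mean of squared errors over all entries of the batch;
    gradients are exact, suitable for finite-difference checking.
    """
    _, dact = _ACTIVATIONS[model.activation]
    acts = model.forward(S)
    Y = acts[0]
    out = acts[-1]
    n, d = Y.shape
    loss = float(((out - Y) ** 2).mean())
    delta = (2.0 / (n * d)) * (out - Y) * dact(out)
    gW = [np.empty(0)] * len(model.weights)
    gb = [np.empty(0)] * len(model.biases)
    for layer in range(len(model.weights) - 1, -1, -1):
        gW[layer] = acts[layer].T @ delta
        gb[layer] = delta.sum(axis=0)
        if layer > 0:
            delta = (delta @ model.weights[layer].T) * dact(acts[layer])
    return loss, gW, gb


def train_autoencoder(S: np.ndarray, widths: Sequence[int] = DEFAULT_ARCH,
                      cfg: TrainConfig | None = None,
                      scaler: FeatureScaler | None = None,
                      activation: str = "sigmoid") -> AutoencoderModel:
    """Train an autoencoder on pre-scaled data by minibatch backpropagation.

    ``S`` must already lie in (0, 1) when the activation is sigmoid (the
    output layer cannot reach values outside it).  The per-epoch loss
    history records the full-data MSE; on early stop the weights of the
    best monitored epoch are restored and the history truncated there, so
    the final history entry always equals the model's current training MSE.

    Raises TrainingError on divergence (non-finite loss), reporting the
    epoch and learning rate.
    """
    cfg = cfg or TrainConfig()
    S = np.asarray(S, dtype=float)
    _validate_arch(widths, S.shape[1])
    if activation == "sigmoid" and (S.min() < 0.0 or S.max() > 1.0):
        raise DomainError("sigmoid autoencoder requires inputs scaled into [0, 1]")

    model = init_autoencoder(widths, activation, seed=cfg.seed)
    model.scaler = scaler
    rng = np.random.default_rng(cfg.seed + 1)
    n = S.shape[0]
    n_val = int(round(cfg.val_fraction * n))
    perm = rng.permutation(n)
    val_idx, train_idx = perm[:n_val], perm[n_val:]
    S_train, S_val = S[train_idx], S[val_idx]

    vel_W = [np.zeros_like(W) for W in model.weights]
    vel_b = [np.zeros_like(b) for b in model.biases]
    # Adam state
    mW = [np.zeros_like(W) for W in model.weights]
    vW = [np.zeros_like(W) for W in model.weights]
    mb = [np.zeros_like(b) for b in model.biases]
    vb = [np.zeros_like(b) for b in model.biases]
    b1, b2, eps = 0.9, 0.999, 1e-8
    t = 0

    def full_loss(data: np.ndarray) -> float:
        out = model.forward(data)[-1]
        return float(((out - data) ** 2).mean())

    history: list[float] = [full_loss(S)]
    monitor = full_loss(S_val) if n_val else history[0]
    best_monitor = monitor
    best_weights = [W.copy() for W in model.weights]
    best_biases = [b.copy() for b in model.biases]
    best_epoch = 0
    stall = 0

    for epoch in range(1, cfg.max_epochs + 1):
        order = rng.permutation(len(S_train))
        for start in range(0, len(S_train), cfg.batch_size):
            batch = S_train[order[start:start + cfg.batch_size]]
            loss, gW, gb = loss_and_grads(model, batch)
            if not np.isfinite(loss):
                raise TrainingError(
                    f"non-finite loss at epoch {epoch} "
                    f"(learning rate {cfg.learning_rate})")
            if cfg.optimizer == "adam":
                t += 1
                for layer in range(len(model.weights)):
                    mW[layer] = b1 * mW[layer] + (1 - b1) * gW[layer]
                    vW[layer] = b2 * vW[layer] + (1 - b2) * gW[layer] ** 2
                    mb[layer] = b1 * mb[layer] + (1 - b1) * gb[layer]
                    vb[layer] = b2 * vb[layer] + (1 - b2) * gb[layer] ** 2
                    mWh = mW[layer] / (1 - b1 ** t)
                    vWh = vW[layer] / (1 - b2 ** t)
                    mbh = mb[layer] / (1 - b1 ** t)
                    vbh = vb[layer] / (1 - b2 ** t)
                    model.weights[layer] -= cfg.learning_rate * mWh / (np.sqrt(vWh) + eps)
                    model.biases[layer] -= cfg.learning_rate * mbh / (np.sqrt(vbh) + eps)
            else:
                for layer in range(len(model.weights)):
                    vel_W[layer] = cfg.momentum * vel_W[layer] - cfg.learning_rate * gW[layer]
                    vel_b[layer] = cfg.momentum * vel_b[layer] - cfg.learning_rate * gb[layer]
                    model.weights[layer] += vel_W[layer]
                    model.biases[layer] += vel_b[layer]
        epoch_loss = full_loss(S)
        if not np.isfinite(epoch_loss):
            raise TrainingError(
                f"non-finite loss at epoch {epoch} (learning rate {cfg.learning_rate})")
        history.append(epoch_loss)
        monitor = full_loss(S_val) if n_val else epoch_loss
        if best_monitor - monitor > cfg.tol:
            best_monitor = monitor
            best_weights = [W.copy() for W in model.weights]
            best_biases = [b.copy() for b in model.biases]
            best_epoch = epoch
            stall = 0
        else:
            stall += 1
            if stall >= cfg.patience:
                break

    model.weights = best_weights
    model.biases = best_biases
    model.loss_history = history[: best_epoch + 1]
    return model


def fit_autoencoder(X_raw, widths: Sequence[int] = DEFAULT_ARCH,
                    cfg: TrainConfig | None = None,
                    interval: tuple[float, float] = (0.1, 0.9),
                    feature_names: Sequence[str] | None = None,
                    activation: str = "sigmoid") -> AutoencoderModel:
    """Convenience wrapper: fit the min-max scaler on X, scale, train."""
    X = np.asarray(X_raw, dtype=float)
    scaler = FeatureScaler(lo=interval[0], hi=interval[1]).fit(X, feature_names)
    return train_autoencoder(scaler.transform(X), widths, cfg,
                             scaler=scaler, activation=activation)


# ---------------------------------------------------------------------------
# PCA baseline

@dataclass
class PCAModel:
    """PCA fit: training means, orthonormal loading rows (components),
    explained-variance fractions, and the optional input scaler."""

    mean: np.ndarray
    components: np.ndarray
    explained_variance_ratio: np.ndarray
    scaler: FeatureScaler | None = None


def fit_pca(X_raw, scaler: FeatureScaler | None = None) -> PCAModel:
    """Fit full-rank PCA on (optionally scaled) data, centering on the
    training means."""
    X = np.asarray(X_raw, dtype=float)
    if X.shape[0] < 2:
        raise ConfigError("PCA needs at least 2 rows")
    S = scaler.transform(X) if scaler is not None else X
    pca = _SKPCA(n_components=min(S.shape)).fit(S)
    return PCAModel(mean=pca.mean_, components=pca.components_,
                    explained_variance_ratio=pca.explained_variance_ratio_,
                    scaler=scaler)


def pca_score(model: PCAModel, X_raw, k: int = 1) -> np.ndarray:
    """Projections onto the first k loading vectors (k=1 gives the scalar
    PCA risk score)."""
    if k < 1 or k > model.components.shape[0]:
        raise ConfigError(f"k must lie in 1..{model.components.shape[0]}")
    X = np.asarray(X_raw, dtype=float)
    S = model.scaler.transform(X) if model.scaler is not None else X
    Z = (S - model.mean) @ model.components[:k].T
    return Z[:, 0] if k == 1 else Z


# ---------------------------------------------------------------------------
# greedy hyper-parameter search

@dataclass
class SearchSpace:
    """Candidate axes for coordinate-wise greedy search.

    Architectures are parameterised by encoder depth and first hidden
    width; subsequent hidden widths halve down to the one-unit bottleneck,
    and the decoder mirrors the encoder.  Candidates whose parameter count
    reaches the training-row count are skipped (degrees-of-freedom guard).
    """

    depths: tuple[int, ...] = (1, 2, 3)
    first_widths: tuple[int, ...] = (6, 8, 12)
    learning_rates: tuple[float, ...] = (0.005, 0.01, 0.05)
    batch_sizes: tuple[int, ...] = (16, 32, 64)

    def architecture(self, depth: int, first_width: int, n_features: int = 10
                     ) -> tuple[int, ...]:
        hidden = [max(2, int(round(first_width / 2 ** i))) for i in range(depth)]
        return tuple([n_features] + hidden + [1] + hidden[::-1] + [n_features])


def greedy_search(S: np.ndarray, space: SearchSpace,
                  base_cfg: TrainConfig | None = None, seed: int = 0,
                  val_fraction: float = 0.2
                  ) -> tuple[tuple[int, ...], TrainConfig, list[dict]]:
    """Coordinate-wise greedy hyper-parameter selection by validation MSE.

    Axes are optimized one at a time, in the order depth -> first width ->
    learning rate -> batch size, each axis holding the others at their
    current best (initially the first candidate of each axis).  For every
    candidate a fresh model is trained on the training split (seeded
    identically) and scored by MSE on a held-out validation split fixed by
    ``seed``.  Returns the winning architecture, the winning TrainConfig,
    and the full search log.

    Raises ConfigError if the space is empty or every candidate violates
    the parameter-count guard; TrainingError if all candidates diverge.
    """
    if not (space.depths and space.first_widths and space.learning_rates
            and space.batch_sizes):
        raise ConfigError("empty search space")
    S = np.asarray(S, dtype=float)
    rng = np.random.default_rng(seed)
    n = S.shape[0]
    n_val = max(1, int(round(val_fraction * n)))
    perm = rng.permutation(n)
    val_idx, train_idx = perm[:n_val], perm[n_val:]
    S_train, S_val = S[train_idx], S[val_idx]
    base_cfg = base_cfg or TrainConfig(seed=seed)

    current = {
        "depth": space.depths[0], "first_width": space.first_widths[0],
        "learning_rate": space.learning_rates[0], "batch_size": space.batch_sizes[0],
    }
    log: list[dict] = []
    cache: dict[tuple, float] = {}

    def evaluate(state: dict) -> float:
        key = tuple(sorted(state.items()))
        if key in cache:
            return cache[key]
        widths = space.architecture(state["depth"], state["first_width"],
                                    S.shape[1])
        if n_parameters(widths) >= len(S_train):
            cache[key] = np.inf
            return np.inf
        cfg = replace(base_cfg, learning_rate=state["learning_rate"],
                      batch_size=state["batch_size"], seed=seed, val_fraction=0.0)
        try:
            model = train_autoencoder(S_train, widths, cfg)
        except TrainingError:
            cache[key] = np.inf
            return np.inf
        out = model.forward(S_val)[-1]
        mse = float(((out - S_val) ** 2).mean())
        cache[key] = mse
        return mse

    axes = [("depth", space.depths), ("first_width", space.first_widths),
            ("learning_rate", space.learning_rates), ("batch_size", space.batch_sizes)]
    for axis, candidates in axes:
        best_val, best_cand = np.inf, None
        for cand in candidates:
            state = dict(current)
            state[axis] = cand
            mse = evaluate(state)
            log.append({"axis": axis, "candidate": cand, "val_mse": mse})
            if mse < best_val:
                best_val, best_cand = mse, cand
        if best_cand is None or not np.isfinite(best_val):
            raise TrainingError(f"all candidates failed on axis {axis!r}; log: {log}")
        current[axis] = best_cand

    widths = space.architecture(current["depth"], current["first_width"], S.shape[1])
    best_cfg = replace(base_cfg, learning_rate=current["learning_rate"],
                       batch_size=current["batch_size"], seed=seed)
    return widths, best_cfg, log


# ---------------------------------------------------------------------------
# serialization

def model_to_dict(model: AutoencoderModel) -> dict:
    d = {
        "widths": list(model.widths),
        "activation": model.activation,
        "weights": [W.tolist() for W in model.weights],
        "biases": [b.tolist() for b in model.biases],
        "loss_history": list(model.loss_history),
        "scaler": None,
    }
    if model.scaler is not None:
        s = model.scaler
        d["scaler"] = {
            "lo": s.lo, "hi": s.hi,
            "mins": s.mins.tolist(), "maxs": s.maxs.tolist(),
            "feature_names": s.feature_names, "n_fit": s.n_fit,
        }
    return d


def model_from_dict(d: dict) -> AutoencoderModel:
    scaler = None
    if d.get("scaler") is not None:
        sd = d["scaler"]
        scaler = FeatureScaler(lo=sd["lo"], hi=sd["hi"])
        scaler.mins = np.asarray(sd["mins"], dtype=float)
        scaler.maxs = np.asarray(sd["maxs"], dtype=float)
        scaler.feature_names = sd.get("feature_names")
        scaler.n_fit = sd.get("n_fit")
    return AutoencoderModel(
        widths=tuple(d["widths"]),
        weights=[np.asarray(W, dtype=float) for W in d["weights"]],
        biases=[np.asarray(b, dtype=float) for b in d["biases"]],
        activation=d["activation"],
        scaler=scaler,
        loss_history=list(d.get("loss_history", [])),
    )


def save_model(model: AutoencoderModel, path) -> None:
    """Write the model as a JSON manifest (floats serialized at full
    round-trip precision, so a reloaded model reproduces encode outputs
    exactly)."""
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(model_to_dict(model), fh)


def load_model(path) -> AutoencoderModel:
    with open(path, "r", encoding="utf-8") as fh:
        return model_from_dict(json.load(fh))
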