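"""The two dense networks: forward (curve -> parameters) and surrogate
(parameters -> curve).

Both are multilayer perceptrons with rectifier activations trained by
Adam at learning rate 0.001 on a mean-squared-error loss, with early
stopping once the validation loss has not decreased for 10 consecutive
epochs (best-validation weights restored).  The forward net halves its
width over 8 hidden layers starting from 512; the surrogate uses
4 hidden layers (128, 512, 512, 512) and emits one node per grid point.

Networks operate in normalized spaces -- log10-standardized intensities
and standardized labels -- with all transforms stored on the model, so
the public API speaks physical units only.
"""

from __future__ import annotations

import copy
import time
import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.exceptions import ConvergenceWarning
from sklearn.neural_network import MLPRegressor

from .dataset import (NormalizationStats, TrainingDataset, apply_q_cutoff,
                      normalize_features)
from .scattering import SAXSCurve

__all__ = [
    "ForwardModelSpec",
    "SurrogateModelSpec",
    "TrainingConfig",
    "TrainingHistory",
    "EarlyStopping",
    "ForwardModel",
    "SurrogateModel",
    "train_forward",
    "train_surrogate",
    "predict_params",
    "select_q_cutoff",
    "QCutoffResult",
    "evaluate_forward",
]


@dataclass
class ForwardModelSpec:
    """Architecture of the curve -> (Z_eff, kappa^-1) network."""

    input_width: int | None = None  # number of retained q points
    hidden_layers: tuple[int, ...] = (512, 256, 128, 64, 32, 16, 8, 4)
    output_width: int = 2
    activation: str = "relu"

    def __post_init__(self):
        h = self.hidden_layers
        if len(h) != 8 or h[0] != 512 or any(h[i] != h[i - 1] // 2
                                             for i in range(1, 8)):
            raise ValueError("hidden widths must halve from 512 over 8 layers")
        if self.output_width != 2:
            raise ValueError("forward net outputs exactly (z_eff, kappa_inv)")


@dataclass
class SurrogateModelSpec:
    """Architecture of the (Z_eff, kappa^-1) -> curve network."""

    input_width: int = 2
    hidden_layers: tuple[int, ...] = (128, 512, 512, 512)
    output_width: int = 225

    def __post_init__(self):
        h = self.hidden_layers
        if len(h) != 4 or h[0] != 128 or any(w != 512 for w in h[1:]):
            raise ValueError("surrogate hidden layers must be (128, 512, 512, 512)")
        if self.input_width != 2:
            raise ValueError("surrogate input is the parameter pair")


@dataclass
class TrainingConfig:
    learning_rate: float = 0.001
    loss: str = "mse"
    early_stop_patience: int = 10
    batch_size: int = 128
    max_epochs: int = 500
    seed: int = 0


@dataclass
class TrainingHistory:
    train_loss: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    best_epoch: int = -1
    stopped_epoch: int = -1


class EarlyStopping:
    """Patience counter on a validation metric (strict decrease resets it)."""

    def __init__(self, patience: int):
        self.patience = patience
        self.best = np.inf
        self.best_epoch = -1
        self.wait = 0

    def update(self, epoch: int, value: float) -> bool:
        """Record this epoch's metric; return True when training should stop."""
        if value < self.best:
            self.best = value
            self.best_epoch = epoch
            self.wait = 0
            return False
        self.wait += 1
        return self.wait >= self.patience


def _standardize_labels(labels_train: np.ndarray) -> NormalizationStats:
    std = labels_train.std(axis=0)
    # NormalizationStats is a log10 transform pair; labels use plain z-scores
    return _ZScore(labels_train.mean(axis=0), np.where(std > 0, std, 1.0))


@dataclass
class _ZScore:
    mean: np.ndarray
    std: np.ndarray

    def forward(self, x):
        return (x - self.mean) / self.std

    def inverse(self, x):
        return x * self.std + self.mean


def _fit_mlp(x_train, y_train, x_val, y_val, hidden, config: TrainingConfig,
             ) -> tuple[MLPRegressor, TrainingHistory]:
    """Epoch loop with explicit validation-loss early stopping.

    sklearn's built-in early stopping carves its own validation split, so
    the loop drives one epoch at a time (warm_start) and monitors the
    corpus's held-out split instead, restoring the best weights at the end.
    """
    if x_train.shape[0] == 0 or x_val.shape[0] == 0:
        raise ValueError("training and validation splits must be non-empty")
    mlp = MLPRegressor(
        hidden_layer_sizes=hidden, activation="relu", solver="adam",
        learning_rate_init=config.learning_rate,
        batch_size=min(config.batch_size, x_train.shape[0]),
        max_iter=1, warm_start=True, shuffle=True,
        random_state=config.seed, tol=0.0)
    stopper = EarlyStopping(config.early_stop_patience)
    history = TrainingHistory()
    best_weights = None
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        for epoch in range(config.max_epochs):
            mlp.fit(x_train, y_train)
            val = float(np.mean((mlp.predict(x_val) - y_val) ** 2))
            history.train_loss.append(float(mlp.loss_))
            history.val_loss.append(val)
            improved = val < stopper.best
            stop = stopper.update(epoch, val)
            if improved:
                best_weights = (copy.deepcopy(mlp.coefs_),
                                copy.deepcopy(mlp.intercepts_))
            if stop:
                break
    history.best_epoch = stopper.best_epoch
    history.stopped_epoch = len(history.val_loss) - 1
    if best_weights is not None:
        mlp.coefs_, mlp.intercepts_ = best_weights
    return mlp, history


def _match_grid(curve_q: np.ndarray, model_q: np.ndarray,
                values: np.ndarray) -> np.ndarray:
    """Project a curve onto the model's grid; error on any mismatch."""
    if curve_q.shape == model_q.shape and np.allclose(curve_q, model_q):
        return values
    if curve_q.size > model_q.size and np.allclose(curve_q[:model_q.size],
                                                   model_q):
        return values[..., :model_q.size]  # model trained with a q cutoff
    raise ValueError(
        "curve grid does not match the model's training grid "
        f"({curve_q.size} vs {model_q.size} points)")


@dataclass
class ForwardModel:
    """Trained curve -> (z_eff, kappa_inv) predictor in physical units."""

    mlp: MLPRegressor
    q: np.ndarray
    feature_stats: NormalizationStats
    label_stats: _ZScore
    spec: ForwardModelSpec
    config: TrainingConfig
    history: TrainingHistory

    def predict(self, curve) -> np.ndarray:
        """De-standardized predictions; out-of-box values are not clipped."""
        if isinstance(curve, SAXSCurve):
            values = _match_grid(curve.q, self.q, curve.intensity)
            x = self.feature_stats.forward(values[None, :])
            return self.label_stats.inverse(self.mlp.predict(x))[0]
        values = np.atleast_2d(np.asarray(curve, dtype=float))
        if values.shape[1] != self.q.size:
            raise ValueError(
                f"expected {self.q.size} intensity values, got {values.shape[1]}")
        x = self.feature_stats.forward(values)
        return self.label_stats.inverse(self.mlp.predict(x))


@dataclass
class SurrogateModel:
    """Trained (z_eff, kappa_inv) -> curve emulator in physical units.

    ``model_error_fraction`` is the per-grid-point RMS relative residual
    of the emulator on the validation split.  It quantifies how far an
    emulated curve sits from a freshly simulated one (emulator error plus
    the simulator's own sampling noise) and is folded into the chi-square
    likelihood in quadrature, so the posterior width reflects the
    emulator's actual fidelity rather than the measurement alone.
    """

    mlp: MLPRegressor
    q: np.ndarray
    feature_stats: NormalizationStats  # output-space (curve) transform
    label_stats: _ZScore               # input-space (parameter) transform
    spec: SurrogateModelSpec
    config: TrainingConfig
    history: TrainingHistory
    model_error_fraction: np.ndarray | None = None

    def predict_curve(self, params) -> np.ndarray:
        """Physical intensities on the training grid, one row per pair."""
        theta = np.atleast_2d(np.asarray(params, dtype=float))
        x = self.label_stats.forward(theta)
        out = self.feature_stats.inverse(np.atleast_2d(self.mlp.predict(x)))
        return out[0] if np.ndim(params) == 1 else out


def train_forward(dataset: TrainingDataset,
                  spec: ForwardModelSpec | None = None,
                  config: TrainingConfig | None = None) -> ForwardModel:
    """Train the forward network on a (possibly q-truncated) corpus."""
    spec = spec or ForwardModelSpec()
    config = config or TrainingConfig()
    features, stats = normalize_features(dataset)
    if spec.input_width is None:
        spec = ForwardModelSpec(input_width=dataset.q.size,
                                hidden_layers=spec.hidden_layers)
    if spec.input_width != dataset.q.size:
        raise ValueError("spec.input_width does not match the dataset grid")
    label_stats = _standardize_labels(dataset.labels[dataset.mask("train")])
    y = label_stats.forward(dataset.labels)
    tr, va = dataset.mask("train"), dataset.mask("val")
    mlp, history = _fit_mlp(features[tr], y[tr], features[va], y[va],
                            spec.hidden_layers, config)
    return ForwardModel(mlp, dataset.q.copy(), stats, label_stats,
                        spec, config, history)


def predict_params(model: ForwardModel, curve) -> np.ndarray:
    """Functional alias for :meth:`ForwardModel.predict`."""
    return model.predict(curve)


def train_surrogate(dataset: TrainingDataset,
                    spec: SurrogateModelSpec | None = None,
                    config: TrainingConfig | None = None) -> SurrogateModel:
    """Train the inverse surrogate on the full-grid corpus."""
    spec = spec or SurrogateModelSpec(output_width=dataset.q.size)
    config = config or TrainingConfig()
    if spec.output_width != dataset.q.size:
        raise ValueError("spec.output_width does not match the dataset grid")
    features, stats = normalize_features(dataset)
    label_stats = _standardize_labels(dataset.labels[dataset.mask("train")])
    theta = label_stats.forward(dataset.labels)
    tr, va = dataset.mask("train"), dataset.mask("val")
    mlp, history = _fit_mlp(theta[tr], features[tr], theta[va], features[va],
                            spec.hidden_layers, config)
    model = SurrogateModel(mlp, dataset.q.copy(), stats, label_stats,
                           spec, config, history)
    predicted = model.predict_curve(dataset.labels[va])
    rel = (predicted - dataset.curves[va]) / dataset.curves[va]
    model.model_error_fraction = np.sqrt(np.mean(rel ** 2, axis=0))
    return model


@dataclass
class QCutoffResult:
    best_cutoff: float
    val_losses: dict[float, float]
    best_model: ForwardModel


def select_q_cutoff(dataset: TrainingDataset, candidate_cutoffs,
                    spec: ForwardModelSpec | None = None,
                    config: TrainingConfig | None = None) -> QCutoffResult:
    """Train one forward model per cutoff; return the validation winner.

    All candidates are validated against the grid before any training
    starts; every model shares the same seed and recipe so only the
    retained q range differs.
    """
    candidates = [float(c) for c in candidate_cutoffs]
    if len(candidates) < 2:
        raise ValueError("need at least 2 candidate cutoffs")
    q = dataset.q
    for c in candidates:
        if c < q[0] or c > q[-1]:
            raise ValueError(f"cutoff {c} outside the grid ({q[0]}, {q[-1]}]")
    losses: dict[float, float] = {}
    best_model = None
    for c in candidates:
        truncated = apply_q_cutoff(dataset, c)
        model = train_forward(truncated, spec=None if spec is None else
                              ForwardModelSpec(hidden_layers=spec.hidden_layers),
                              config=config)
        losses[c] = min(model.history.val_loss)
        if best_model is None or losses[c] < losses[best_model[0]]:
            best_model = (c, model)
    return QCutoffResult(best_model[0], losses, best_model[1])


def evaluate_forward(model: ForwardModel, dataset: TrainingDataset,
                     split: str = "test") -> dict:
    """Predicted-vs-true regression metrics on one split.

    Returns per-parameter Pearson r^2 and RMSE of the residuals plus the
    percentage-error arrays, mirroring the usual predicted/actual scatter
    evaluation.
    """
    curves, labels = dataset.split(split)
    if curves.shape[0] == 0:
        raise ValueError(f"empty split {split!r}")
    preds = model.predict(curves)
    out: dict = {"n": int(curves.shape[0])}
    for k, name in enumerate(("z_eff", "kappa_inv")):
        true, pred = labels[:, k], preds[:, k]
        r = np.corrcoef(true, pred)[0, 1]
        out[f"r2_{name}"] = float(r * r)
        out[f"rmse_{name}"] = float(np.sqrt(np.mean((pred - true) ** 2)))
        out[f"pct_errors_{name}"] = 100.0 * (pred - true) / true
    pct = np.concatenate([out["pct_errors_z_eff"], out["pct_errors_kappa_inv"]])
    out["fraction_within_20pct"] = float(np.mean(np.abs(pct) <= 20.0))
    return out


def time_surrogate_speedup(surrogate: SurrogateModel, mc_seconds: float,
                           n_eval: int = 200) -> float:
    """Wall-time ratio (one MC curve) / (one surrogate evaluation)."""
    theta = np.tile([[40.0, 5.0]], (1, 1))
    surrogate.predict_curve(theta)  # warm call
    start = time.perf_counter()
    for _ in range(n_eval):
        surrogate.predict_curve(theta)
    per_eval = (time.perf_counter() - start) / n_eval
    return mc_seconds / per_eval
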