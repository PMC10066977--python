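"""Deep-learning shunt inverter.

A dense multilayer perceptron maps the ten bedside features to the true
shunt percentage.  The default architecture is 10 inputs, six hidden layers
of 128 rectified-linear units and one linear output — 84,097 trainable
parameters — trained with mean-squared-error loss and an adaptive
per-parameter gradient optimizer for 500 epochs on z-scored features.
Because the simulated records are free of observational noise, the network
interpolates the forward model essentially perfectly and overfitting is not
a practical concern.

The backend is scikit-learn's ``MLPRegressor``; any dense-MLP
implementation with this architecture satisfies the contract.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import joblib
import numpy as np
import pandas as pd
from sklearn.exceptions import ConvergenceWarning
from sklearn.neural_network import MLPRegressor

from .config import MLPConfig
from .scenarios import FEATURE_COLUMNS, ScenarioDataset

__all__ = ["MLPConfig", "TrainedModel", "count_params", "train", "predict",
           "save_model", "load_model"]


def count_params(cfg: MLPConfig = MLPConfig()) -> int:
    """Trainable parameter count of the dense MLP (weights + biases).

    ``(f+1)u`` for the input layer, ``(L-1)(u+1)u`` for the hidden stack,
    ``(u+1)o`` for the output layer.
    """
    f, u = cfg.n_features, cfg.units_per_layer
    L, o = cfg.hidden_layers, cfg.output_units
    if L == 0:
        return (f + 1) * o
    return (f + 1) * u + (L - 1) * (u + 1) * u + (u + 1) * o


@dataclass
class TrainedModel:
    """Fitted MLP plus the training-split normalization statistics."""

    estimator: MLPRegressor
    feature_names: list[str]
    feat_mean: np.ndarray      # per-feature mean of the training rows
    feat_std: np.ndarray       # per-feature SD of the training rows
    loss_history: list[float] = field(default_factory=list)
    config: MLPConfig = field(default_factory=MLPConfig)
    val_mse: float = float("nan")

    def normalize(self, x: np.ndarray) -> np.ndarray:
        return (x - self.feat_mean) / self.feat_std


def _feature_matrix(records: pd.DataFrame, feature_names: list[str]) -> np.ndarray:
    missing = [c for c in feature_names if c not in records.columns]
    if missing:
        raise KeyError(f"records are missing feature column(s): {missing}")
    x = records[feature_names].to_numpy(dtype=float)
    if not np.isfinite(x).all():
        raise ValueError("non-finite values in feature matrix")
    return x


def train(ds: ScenarioDataset, cfg: MLPConfig = MLPConfig(),
          target: str = "shunt") -> TrainedModel:
    """Fit the MLP to predict ``target`` (shunt %) from the training split.

    Features are z-scored with statistics computed on training rows only.
    An optional validation fraction is held out purely to report a final
    validation MSE; it never influences the fit.
    """
    train_df = ds.train
    if len(train_df) == 0:
        raise ValueError("training split is empty")
    x = _feature_matrix(train_df, FEATURE_COLUMNS)
    y = train_df[target].to_numpy(dtype=float)

    rng = np.random.default_rng(cfg.seed)
    n_val = int(round(cfg.validation_fraction * len(x)))
    order = rng.permutation(len(x))
    val_idx, fit_idx = order[:n_val], order[n_val:]

    mean = x[fit_idx].mean(axis=0)
    std = x[fit_idx].std(axis=0)
    std = np.where(std < 1e-12, 1.0, std)
    xz = (x - mean) / std

    est = MLPRegressor(
        hidden_layer_sizes=(cfg.units_per_layer,) * cfg.hidden_layers,
        activation=cfg.activation,
        solver="adam",
        learning_rate_init=cfg.learning_rate,
        batch_size=min(cfg.batch_size, len(fit_idx)),
        max_iter=cfg.epochs,
        shuffle=True,
        random_state=cfg.seed,
        tol=0.0,
        n_iter_no_change=cfg.epochs,   # run the full epoch budget
        alpha=0.0,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        est.fit(xz[fit_idx], y[fit_idx])
    if not np.isfinite(est.loss_):
        raise RuntimeError(f"training diverged: final loss {est.loss_}")

    model = TrainedModel(estimator=est, feature_names=list(FEATURE_COLUMNS),
                         feat_mean=mean, feat_std=std,
                         loss_history=[float(v) for v in est.loss_curve_],
                         config=cfg)
    if n_val:
        pred = est.predict(xz[val_idx])
        model.val_mse = float(np.mean((pred - y[val_idx]) ** 2))
    return model


def predict(model: TrainedModel, records: pd.DataFrame | ScenarioDataset) -> np.ndarray:
    """Shunt estimates (% of pulmonary blood flow), one per record."""
    if isinstance(records, ScenarioDataset):
        records = records.records
    x = _feature_matrix(records, model.feature_names)
    return model.estimator.predict(model.normalize(x))


def save_model(model: TrainedModel, path: str | Path) -> None:
    joblib.dump(model, path)


def load_model(path: str | Path) -> TrainedModel:
    model = joblib.load(path)
    if not isinstance(model, TrainedModel):
        raise TypeError(f"{path} does not contain a TrainedModel")
    return model
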