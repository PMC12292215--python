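"""Multi-output feed-forward surrogate for {RD, SA/VR, U, EA}.

Architecture: three ReLU hidden layers (128, 64, 32) and a four-output
linear layer, trained with Adam (lr 1e-3) on mean-squared error for 150
epochs, batch size 32, on an 80/20 shuffled split.  Targets are z-scored
for training (the four outputs span percent, 1/mm, MPa and MJ/m^3, so raw
MSE would be dominated by the largest scale) and inverse-transformed for
reporting.  The backend is scikit-learn's MLPRegressor driven one epoch at
a time so train/validation loss histories are recorded.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.neural_network import MLPRegressor

from .design_space import FEATURE_COLUMNS, FeatureEncoder

#: canonical target columns and their natural units
TARGET_COLUMNS = ["rd_pct", "savr_per_mm", "u_mpa", "ea_mj_m3"]
TARGET_UNITS = {"rd_pct": "%", "savr_per_mm": "1/mm",
                "u_mpa": "MPa", "ea_mj_m3": "MJ/m^3"}


@dataclass
class SurrogateConfig:
    hidden_sizes: tuple = (128, 64, 32)
    activation: str = "relu"
    learning_rate: float = 1e-3
    epochs: int = 150
    batch_size: int = 32
    train_fraction: float = 0.8
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.train_fraction < 1:
            raise ValueError("train_fraction must lie in (0, 1)")
        if self.epochs < 1 or self.batch_size < 1:
            raise ValueError("epochs and batch_size must be >= 1")


@dataclass
class EvalReport:
    """Per-target goodness of fit on a held-out set."""

    r2: dict
    mae: dict
    residuals: pd.DataFrame  # signed prediction - truth, per sample x target

    @property
    def residual_mean(self) -> dict:
        return self.residuals.mean().to_dict()


class SurrogateModel:
    """Fitted network plus target scaler and training history."""

    def __init__(self, net: MLPRegressor, target_mean: np.ndarray,
                 target_std: np.ndarray, config: SurrogateConfig,
                 history: pd.DataFrame,
                 encoder: FeatureEncoder | None = None) -> None:
        self.net = net
        self.target_mean = target_mean
        self.target_std = target_std
        self.config = config
        self.history = history  # columns: epoch, train_loss, val_loss
        self.encoder = encoder

    @property
    def n_features(self) -> int:
        return self.net.coefs_[0].shape[0]

    def predict(self, X: np.ndarray) -> np.ndarray:
        """Predictions in natural units; X is the encoded feature matrix."""
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != self.n_features:
            raise ValueError(
                f"feature layout mismatch: model expects {self.n_features} "
                f"columns {FEATURE_COLUMNS}, got {X.shape[1]}")
        Ys = self.net.predict(X)
        Y = Ys * self.target_std + self.target_mean
        # zero-variance targets are constants by definition
        const = self.target_std == 0
        if const.any():
            Y[:, const] = self.target_mean[const]
        return Y

    def predict_frame(self, designs: pd.DataFrame) -> pd.DataFrame:
        """Predict for raw designs using the stored feature encoder."""
        if self.encoder is None:
            raise RuntimeError("model was built without a feature encoder")
        Y = self.predict(self.encoder.transform(designs))
        return pd.DataFrame(Y, columns=TARGET_COLUMNS, index=designs.index)

    # -- persistence --------------------------------------------------------

    def save(self, directory) -> None:
        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        np.savez(d / "weights.npz",
                 **{f"coef_{i}": c for i, c in enumerate(self.net.coefs_)},
                 **{f"intercept_{i}": b
                    for i, b in enumerate(self.net.intercepts_)})
        meta = {"config": self.config.__dict__.copy(),
                "target_mean": self.target_mean.tolist(),
                "target_std": self.target_std.tolist(),
                "target_columns": TARGET_COLUMNS}
        meta["config"]["hidden_sizes"] = list(self.config.hidden_sizes)
        with open(d / "model.json", "w") as fh:
            json.dump(meta, fh, indent=2)
        self.history.to_csv(d / "history.csv", index=False)
        if self.encoder is not None:
            self.encoder.to_json(d / "scaler.json")

    @classmethod
    def load(cls, directory) -> "SurrogateModel":
        d = Path(directory)
        with open(d / "model.json") as fh:
            meta = json.load(fh)
        cfg = SurrogateConfig(**{**meta["config"],
                                 "hidden_sizes": tuple(meta["config"]["hidden_sizes"])})
        wz = np.load(d / "weights.npz")
        n_layers = len([k for k in wz.files if k.startswith("coef_")])
        coefs = [wz[f"coef_{i}"] for i in range(n_layers)]
        intercepts = [wz[f"intercept_{i}"] for i in range(n_layers)]
        net = _init_net(cfg, coefs[0].shape[0], intercepts[-1].shape[0])
        net.coefs_ = coefs
        net.intercepts_ = intercepts
        history = pd.read_csv(d / "history.csv")
        encoder = None
        if (d / "scaler.json").exists():
            encoder = FeatureEncoder.from_json(d / "scaler.json")
        return cls(net, np.asarray(meta["target_mean"]),
                   np.asarray(meta["target_std"]), cfg, history, encoder)


def split_dataset(df: pd.DataFrame, train_fraction: float = 0.8,
                  seed: int = 0):
    """Seeded shuffled split; train size = floor(n * fraction)."""
    if len(df) == 0:
        raise ValueError("dataset is empty")
    if not 0 < train_fraction < 1:
        raise ValueError("train_fraction must lie in (0, 1)")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(df))
    n_train = int(np.floor(len(df) * train_fraction))
    return df.iloc[perm[:n_train]], df.iloc[perm[n_train:]]


def _init_net(config: SurrogateConfig, n_features: int,
              n_targets: int) -> MLPRegressor:
    net = MLPRegressor(
        hidden_layer_sizes=tuple(config.hidden_sizes),
        activation=config.activation, solver="adam",
        learning_rate_init=config.learning_rate,
        batch_size=config.batch_size, random_state=config.seed,
        max_iter=1, warm_start=False, shuffle=True)
    # one dormant partial_fit initializes the layer shapes
    n0 = max(2, config.batch_size)
    net.partial_fit(np.zeros((n0, n_features)), np.zeros((n0, n_targets)))
    return net


def fit(X_train: np.ndarray, Y_train: np.ndarray, config: SurrogateConfig,
        X_val: np.ndarray | None = None, Y_val: np.ndarray | None = None,
        encoder: FeatureEncoder | None = None) -> SurrogateModel:
    """Train the surrogate; targets are z-scored internally.

    Validation loss (scaled-target MSE) is recorded per epoch when a
    validation set is supplied.
    """
    X_train = np.asarray(X_train, dtype=float)
    Y_train = np.asarray(Y_train, dtype=float)
    if not np.isfinite(Y_train).all():
        raise ValueError("targets contain non-finite values")
    mu = Y_train.mean(axis=0)
    sd = Y_train.std(axis=0)  # zero std kept: predict() pins those constants
    safe_sd = np.where(sd == 0, 1.0, sd)
    Ys = (Y_train - mu) / safe_sd
    Yvs = None if Y_val is None else (np.asarray(Y_val) - mu) / safe_sd

    net = _init_net(config, X_train.shape[1], Y_train.shape[1])
    rows = []
    for epoch in range(config.epochs):
        net.partial_fit(X_train, Ys)  # one pass over shuffled minibatches
        train_loss = float(net.loss_)
        if not np.isfinite(train_loss):
            raise RuntimeError(
                f"training diverged (loss={train_loss}) at epoch {epoch}: "
                f"lr={config.learning_rate}, "
                f"target ranges={list(zip(Y_train.min(0), Y_train.max(0)))}")
        val_loss = np.nan
        if Yvs is not None:
            pv = net.predict(X_val)
            val_loss = float(np.mean((pv - Yvs) ** 2))
        rows.append({"epoch": epoch + 1, "train_loss": train_loss,
                     "val_loss": val_loss})
    history = pd.DataFrame(rows)
    return SurrogateModel(net, mu, sd, config, history, encoder)


def evaluate(model: SurrogateModel, X: np.ndarray,
             Y: np.ndarray) -> EvalReport:
    """R^2 = 1 - SSres/SStot and MAE per target, in natural units."""
    Y = np.asarray(Y, dtype=float)
    pred = model.predict(X)
    r2, mae = {}, {}
    for j, name in enumerate(TARGET_COLUMNS[:Y.shape[1]]):
        y, p = Y[:, j], pred[:, j]
        ss_tot = float(((y - y.mean()) ** 2).sum())
        ss_res = float(((y - p) ** 2).sum())
        r2[name] = 1.0 - ss_res / ss_tot if ss_tot > 0 else float("nan")
        mae[name] = float(np.abs(y - p).mean())
    residuals = pd.DataFrame(pred - Y, columns=TARGET_COLUMNS[:Y.shape[1]])
    return EvalReport(r2=r2, mae=mae, residuals=residuals)


def train_surrogate(dataset: pd.DataFrame,
                    config: SurrogateConfig | None = None):
    """Encode, split, fit and evaluate on a synthetic or measured dataset.

    Returns (model, report, train_frame, test_frame).
    """
    config = config or SurrogateConfig()
    train_df, test_df = split_dataset(dataset, config.train_fraction,
                                      config.seed)
    encoder = FeatureEncoder().fit(train_df)
    Xtr = encoder.transform(train_df)
    Xte = encoder.transform(test_df)
    Ytr = train_df[TARGET_COLUMNS].to_numpy(dtype=float)
    Yte = test_df[TARGET_COLUMNS].to_numpy(dtype=float)
    model = fit(Xtr, Ytr, config, X_val=Xte, Y_val=Yte, encoder=encoder)
    report = evaluate(model, Xte, Yte)
    return model, report, train_df, test_df


__all__ = [
    "TARGET_COLUMNS", "TARGET_UNITS", "SurrogateConfig", "SurrogateModel",
    "EvalReport", "split_dataset", "fit", "evaluate", "train_surrogate",
]
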