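"""Feed-forward regressors for alcohol score, BMI and chronological age.

The reference protocol trains feed-forward networks on the top correlated
CpGs (M values) with the Adam optimizer at learning rate 1e-6 for 2,500
epochs under 5-fold cross-validation, pooling the held-out predictions into
one out-of-fold vector, then refits on all data.  Architecture presets cover
zero to three hidden layers (widths 2000, 2000/500, 2000/500/50) with ReLU
between layers.  Alcohol is regressed on a 0-1 scale where 1 = no alcohol
(healthiest) and 0 = 15+ drinks per week, with the three intermediate
categories evenly spaced.

Inputs are standardized per probe on the training fold before optimization;
the library exposes the reference learning rate and epoch count as defaults
but any deviation is recorded in the fit provenance.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import numpy as np
from scipy import stats
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.model_selection import KFold
from sklearn.utils.validation import check_is_fitted

from .nn import MLP
from .results import FitResult

ARCH_PRESETS = {
    "linear": (),
    "h1": (2000,),
    "h2": (2000, 500),
    "h3": (2000, 500, 50),
}

# 5 ordered weekly-consumption categories, healthiest (1.0) to heaviest (0.0)
ALCOHOL_SCALE = {
    "0": 1.0,
    "1-4": 0.75,
    "4-7": 0.5,
    "8-14": 0.25,
    "15+": 0.0,
}


@dataclass
class ArchSpec:
    """Hidden-layer widths of a feed-forward regressor (empty = linear)."""

    hidden_sizes: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        if any(int(h) != h or h <= 0 for h in self.hidden_sizes):
            raise ValueError("hidden sizes must be positive integers")

    @classmethod
    def preset(cls, name: str) -> "ArchSpec":
        if name not in ARCH_PRESETS:
            raise ValueError(f"unknown preset {name!r}; choose from {sorted(ARCH_PRESETS)}")
        return cls(ARCH_PRESETS[name])


@dataclass
class TrainConfig:
    """Optimization settings (defaults follow the reference protocol)."""

    learning_rate: float = 1e-6
    epochs: int = 2500
    folds: int = 5
    seed: int = 0
    standardize: bool = True

    def __post_init__(self) -> None:
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")

    def is_reference_protocol(self) -> bool:
        return self.learning_rate == 1e-6 and self.epochs == 2500


@dataclass
class RegressionMetrics:
    pearson_r: float
    r_pvalue: float
    mae: float
    rmse: float


def _canon_alcohol(label: str) -> str:
    """Normalize '0 drinks per week', '8–14 drinks', '15 or more' etc."""
    s = str(label).lower().replace("–", "-").replace("—", "-")
    s = re.sub(r"\s*drinks?( per week)?\s*", "", s).strip()
    s = s.replace("15 or more", "15+")
    return s


def scale_alcohol(categories) -> np.ndarray:
    """Map the five weekly-alcohol categories onto [0, 1] (1 = no alcohol).

    Categories are 0, 1-4, 4-7, 8-14 and 15+ drinks per week, mapped to
    1.0, 0.75, 0.5, 0.25 and 0.0: higher is healthier, matching the scaling
    of the other lifestyle scores.
    """
    out = np.empty(len(categories))
    for i, lab in enumerate(categories):
        key = _canon_alcohol(lab)
        if key not in ALCOHOL_SCALE:
            raise ValueError(f"unknown alcohol category {lab!r}")
        out[i] = ALCOHOL_SCALE[key]
    return out


class FFNNRegressor(BaseEstimator, RegressorMixin):
    """Feed-forward regressor with ReLU hidden layers and full-batch Adam.

    Parameters
    ----------
    hidden_sizes : hidden-layer widths; () gives a purely linear model.
    lr, epochs : Adam step size and epoch count (reference protocol:
        1e-6 and 2500).
    standardize : z-score each input feature on the training data first.
    seed : controls weight initialization; training itself is deterministic.

    Attributes (after ``fit``)
    --------------------------
    network_ : the underlying :class:`~methylpredict.nn.MLP`
    loss_curve_ : per-epoch training MSE
    """

    def __init__(
        self,
        hidden_sizes: tuple[int, ...] = (2000, 500),
        lr: float = 1e-6,
        epochs: int = 2500,
        standardize: bool = True,
        seed: int = 0,
    ):
        self.hidden_sizes = hidden_sizes
        self.lr = lr
        self.epochs = epochs
        self.standardize = standardize
        self.seed = seed

    def _prep(self, X, fitting: bool):
        X = np.asarray(X, dtype=float)
        if not np.all(np.isfinite(X)):
            raise ValueError("non-finite inputs")
        if self.standardize:
            if fitting:
                self.x_mean_ = X.mean(axis=0)
                sd = X.std(axis=0)
                self.x_scale_ = np.where(sd > 0, sd, 1.0)
            X = (X - self.x_mean_) / self.x_scale_
        return X

    def fit(self, X, y, callback=None):
        y = np.asarray(y, dtype=float)
        if not np.all(np.isfinite(y)):
            raise ValueError("non-finite target")
        if np.ptp(y) == 0:
            raise ValueError("constant target")
        X = self._prep(X, fitting=True)
        # fit the residual around the training mean: Adam steps are bounded by
        # the learning rate, so the output bias cannot travel to a far-away
        # target mean within any reasonable epoch budget
        self.y_mean_ = float(y.mean())
        sizes = [X.shape[1], *self.hidden_sizes, 1]
        self.network_ = MLP(sizes, seed=self.seed)
        self.loss_curve_ = self.network_.fit(
            X, y - self.y_mean_, lr=self.lr, epochs=self.epochs, callback=callback
        )
        self.n_features_in_ = X.shape[1]
        return self

    def predict(self, X):
        check_is_fitted(self, "network_")
        return self.y_mean_ + self.network_.predict(self._prep(X, fitting=False))

    def input_gradient(self, X):
        """Gradient of the prediction w.r.t. the raw (unstandardized) inputs."""
        check_is_fitted(self, "network_")
        g = self.network_.input_gradient(self._prep(X, fitting=False))
        if self.standardize:
            g = g / self.x_scale_
        return g


def train_ffnn_cv(
    X,
    y,
    arch: ArchSpec | None = None,
    cfg: TrainConfig | None = None,
    features: list[str] | None = None,
) -> FitResult:
    """K-fold out-of-fold predictions plus a final refit on all samples."""
    arch = arch or ArchSpec.preset("h2")
    cfg = cfg or TrainConfig()
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    oof = np.empty(len(y))
    fold_id = np.full(len(y), -1, dtype=int)
    kf = KFold(n_splits=cfg.folds, shuffle=True, random_state=cfg.seed)
    for k, (train, test) in enumerate(kf.split(X)):
        est = FFNNRegressor(
            arch.hidden_sizes, lr=cfg.learning_rate, epochs=cfg.epochs,
            standardize=cfg.standardize, seed=cfg.seed,
        )
        est.fit(X[train], y[train])
        oof[test] = est.predict(X[test])
        fold_id[test] = k
    final = FFNNRegressor(
        arch.hidden_sizes, lr=cfg.learning_rate, epochs=cfg.epochs,
        standardize=cfg.standardize, seed=cfg.seed,
    )
    final.fit(X, y)
    met = regression_metrics(oof, y)
    return FitResult(
        model=final,
        features=list(features) if features is not None else [f"f{j}" for j in range(X.shape[1])],
        oof_pred=oof,
        fold=fold_id,
        metrics={"oof_pearson_r": met.pearson_r, "oof_mae": met.mae, "oof_rmse": met.rmse},
        provenance={
            "model": "FFNNRegressor",
            "hidden_sizes": list(arch.hidden_sizes),
            "learning_rate": cfg.learning_rate,
            "epochs": cfg.epochs,
            "folds": cfg.folds,
            "seed": cfg.seed,
            "standardize": cfg.standardize,
            "reference_protocol": cfg.is_reference_protocol(),
        },
    )


def regression_metrics(pred, actual) -> RegressionMetrics:
    """Pearson r (with two-sided p from the t transform), MAE and RMSE."""
    pred = np.asarray(pred, dtype=float)
    actual = np.asarray(actual, dtype=float)
    if pred.shape != actual.shape or pred.ndim != 1:
        raise ValueError("pred and actual must be equal-length vectors")
    if len(pred) < 3:
        raise ValueError("need at least 3 points")
    if np.ptp(pred) == 0 or np.ptp(actual) == 0:
        raise ValueError("correlation undefined for a constant vector")
    r, p = stats.pearsonr(pred, actual)
    err = pred - actual
    return RegressionMetrics(
        pearson_r=float(r),
        r_pvalue=float(p),
        mae=float(np.mean(np.abs(err))),
        rmse=float(np.sqrt(np.mean(err**2))),
    )


def delta_age(pred_age, chron_age) -> np.ndarray:
    """Age acceleration: epigenetic (predicted) age minus chronological age."""
    pred_age = np.asarray(pred_age, dtype=float)
    chron_age = np.asarray(chron_age, dtype=float)
    if pred_age.shape != chron_age.shape:
        raise ValueError("length mismatch")
    return pred_age - chron_age
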