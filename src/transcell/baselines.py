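"""Baseline model suite used for comparison against the transfer network.

Continuous tasks: LASSO, elastic net (both with cross-validated
regularization paths), random forest, PCA-features + DNN, and the
transfer architecture trained from default initialization (dnn_default —
identical layer shapes, no pre-training).  Binary (mutation) tasks:
logistic LASSO and logistic elastic net.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator
from sklearn.decomposition import PCA
from sklearn.ensemble import RandomForestClassifier, RandomForestRegressor
from sklearn.linear_model import ElasticNetCV, LassoCV, LogisticRegressionCV

from ._nn import IDENTITY, LEAKY, SIGMOID, MLP, train_mlp
from .networks import TransCellClassifier, TransCellRegressor

CONTINUOUS_METHODS = ("lasso", "en", "rf", "pca_dnn", "dnn_default")
BINARY_METHODS = ("logistic_lasso", "logistic_en", "rf", "dnn_default")
ALL_METHODS = ("lasso", "en", "rf", "logistic_lasso", "logistic_en", "pca_dnn", "dnn_default")


class BaselineModel(BaseEstimator):
    """One member of the comparison suite, behind a uniform fit/predict API.

    Parameters
    ----------
    method : str
        One of lasso, en, rf, logistic_lasso, logistic_en, pca_dnn,
        dnn_default.
    l1_ratio : float
        Elastic-net mixing (1.0 recovers the LASSO limit).
    n_estimators : int
        Random-forest tree count.
    n_components : int
        PCA width for pca_dnn; defaults to the encoder bottleneck (200) so
        the PCA-vs-encoder comparison is dimensionally fair.
    """

    def __init__(
        self,
        method: str = "lasso",
        l1_ratio: float = 0.5,
        n_estimators: int = 500,
        n_components: int = 200,
        head_hidden=(128, 32),
        hidden_dim: int = 512,
        bottleneck_dim: int = 200,
        epochs: int = 200,
        batch_size: int = 32,
        lr: float = 1e-3,
        patience: int | None = 20,
        cv: int = 5,
        random_state: int = 0,
    ):
        self.method = method
        self.l1_ratio = l1_ratio
        self.n_estimators = n_estimators
        self.n_components = n_components
        self.head_hidden = head_hidden
        self.hidden_dim = hidden_dim
        self.bottleneck_dim = bottleneck_dim
        self.epochs = epochs
        self.batch_size = batch_size
        self.lr = lr
        self.patience = patience
        self.cv = cv
        self.random_state = random_state

    # ------------------------------------------------------------------
    def fit(self, X, y):
        if self.method not in ALL_METHODS:
            raise ValueError(f"unknown baseline method {self.method!r}")
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float).ravel()
        if X.shape[0] < 5:
            raise ValueError("need at least 5 samples")
        binary = self.method in ("logistic_lasso", "logistic_en")
        if binary and set(np.unique(y)) - {0.0, 1.0}:
            raise ValueError(f"{self.method} requires binary 0/1 targets")

        seed = self.random_state
        if self.method == "lasso":
            self.model_ = LassoCV(cv=self.cv, random_state=seed, max_iter=10000).fit(X, y)
        elif self.method == "en":
            self.model_ = ElasticNetCV(
                cv=self.cv, l1_ratio=self.l1_ratio, random_state=seed, max_iter=10000
            ).fit(X, y)
        elif self.method == "rf":
            cls = RandomForestClassifier if set(np.unique(y)) <= {0.0, 1.0} and len(
                np.unique(y)
            ) == 2 else RandomForestRegressor
            self.model_ = cls(
                n_estimators=self.n_estimators,
                max_features="sqrt",
                random_state=seed,
                n_jobs=1,
            ).fit(X, y if cls is RandomForestRegressor else y.astype(int))
        elif self.method == "logistic_lasso":
            self.model_ = LogisticRegressionCV(
                cv=self.cv,
                l1_ratios=(1.0,),
                solver="saga",
                scoring="neg_log_loss",
                random_state=seed,
                max_iter=5000,
            ).fit(X, y.astype(int))
        elif self.method == "logistic_en":
            self.model_ = LogisticRegressionCV(
                cv=self.cv,
                l1_ratios=(self.l1_ratio,),
                solver="saga",
                scoring="neg_log_loss",
                random_state=seed,
                max_iter=5000,
            ).fit(X, y.astype(int))
        elif self.method == "pca_dnn":
            self._fit_pca_dnn(X, y)
        elif self.method == "dnn_default":
            self._fit_dnn_default(X, y)
        self.n_features_in_ = X.shape[1]
        return self

    def _task(self, y) -> str:
        return "classification" if set(np.unique(y)) <= {0.0, 1.0} else "regression"

    def _fit_pca_dnn(self, X, y):
        n_comp = min(self.n_components, X.shape[1] - 1, X.shape[0] - 1)
        self.pca_ = PCA(n_components=n_comp, random_state=self.random_state).fit(X)
        Z = self.pca_.transform(X)
        task = self._task(y)
        dims = [n_comp, *self.head_hidden, 1]
        acts = [LEAKY] * (len(dims) - 2) + [SIGMOID if task == "classification" else IDENTITY]
        mlp = MLP(dims, acts, alpha=0.1, rng=np.random.default_rng(self.random_state))
        self.history_ = train_mlp(
            mlp,
            Z,
            y,
            loss="bce" if task == "classification" else "mse",
            epochs=self.epochs,
            batch_size=self.batch_size,
            lr=self.lr,
            patience=self.patience,
            val_fraction=0.1,
            seed=self.random_state,
        )
        self.model_ = mlp
        self.task_ = task

    def _fit_dnn_default(self, X, y):
        task = self._task(y)
        cls = TransCellClassifier if task == "classification" else TransCellRegressor
        hidden = min(self.hidden_dim, max(2, X.shape[1] - 1))
        bottleneck = min(self.bottleneck_dim, max(1, hidden - 1))
        self.model_ = cls(
            encoder=None,
            hidden_dim=hidden,
            bottleneck_dim=bottleneck,
            head_hidden=self.head_hidden,
            epochs=self.epochs,
            batch_size=self.batch_size,
            lr=self.lr,
            patience=self.patience,
            random_state=self.random_state,
        ).fit(X, y)
        self.task_ = task

    # ------------------------------------------------------------------
    def predict(self, X) -> np.ndarray:
        """Point predictions; probabilities for the logistic variants."""
        if not hasattr(self, "model_"):
            raise RuntimeError("baseline model is not fitted")
        X = np.asarray(X, dtype=float)
        if X.shape[1] != self.n_features_in_:
            raise ValueError(
                f"expected {self.n_features_in_} features, got {X.shape[1]}"
            )
        if self.method in ("logistic_lasso", "logistic_en"):
            return self.model_.predict_proba(X)[:, 1]
        if self.method == "pca_dnn":
            return self.model_.forward(self.pca_.transform(X)).ravel()
        if self.method == "dnn_default":
            if self.task_ == "classification":
                return self.model_.predict_proba(X)[:, 1]
            return self.model_.predict(X)
        if isinstance(self.model_, RandomForestClassifier):
            return self.model_.predict_proba(X)[:, 1]
        return self.model_.predict(X)

    def layer_shape_manifest(self) -> list:
        """Weight-matrix shapes, for architecture-identity assertions."""
        if self.method == "dnn_default":
            state = self.model_.state_
            return [tuple(W.shape) for W, _ in state.encoder.layers + state.head_layers]
        if self.method == "pca_dnn":
            return [tuple(W.shape) for W, _ in self.model_.weights]
        raise ValueError("layer shapes defined only for the network baselines")


def fit_baseline(method: str, X, y, config: dict | None = None, seed: int = 0) -> BaselineModel:
    """Fit one baseline; ``config`` overrides the constructor defaults."""
    return BaselineModel(method=method, random_state=seed, **(config or {})).fit(X, y)


def predict_baseline(model: BaselineModel, X) -> np.ndarray:
    return model.predict(X)
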