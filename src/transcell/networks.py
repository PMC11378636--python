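"""Autoencoder, two-step pre-training weight transfer, and prediction network.

The transfer procedure: (1) train an autoencoder on the large source
domain (pan-cancer tumor expression); (2) copy the source encoder weights
into a fresh autoencoder as the initialization of the target-domain
(cell-line) autoencoder, re-initializing the decoder; (3) train on the
target domain; (4) extract the encoder.  The resulting "two_step" encoder
feeds a 4-layer feed-forward prediction head (merge layer over the
bottleneck, two fully connected layers, one output unit) and the joint
network is fine-tuned end-to-end on each measurement feature.

Encoder layers use LeakyReLU (negative slope alpha, default 0.1); the
decoder mirrors the encoder with an identity output activation.  The
reconstruction objective is the per-sample squared Euclidean error
averaged over samples.
"""

from __future__ import annotations

import copy
import dataclasses
from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin, RegressorMixin, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from ._nn import IDENTITY, LEAKY, SIGMOID, MLP, train_mlp

PROVENANCES = ("two_step", "target_only", "source_only")


@dataclass
class AutoencoderSpec:
    """Layer dimensions and activation slope of the autoencoder.

    Defaults match the production architecture: 5000-unit input (the
    KS-selected genes), one 512-unit hidden layer, a 200-unit bottleneck,
    LeakyReLU with negative slope 0.1 throughout the encoder/decoder and
    an identity decoder output.
    """

    input_dim: int = 5000
    hidden_dim: int = 512
    bottleneck_dim: int = 200
    alpha: float = 0.1

    def __post_init__(self):
        if not (self.input_dim > self.hidden_dim > self.bottleneck_dim > 0):
            raise ValueError(
                "require input_dim > hidden_dim > bottleneck_dim > 0, got "
                f"{self.input_dim}/{self.hidden_dim}/{self.bottleneck_dim}"
            )
        if self.alpha <= 0:
            raise ValueError("alpha must be positive")

    @property
    def encoder_dims(self):
        return [self.input_dim, self.hidden_dim, self.bottleneck_dim]

    @property
    def decoder_dims(self):
        return [self.bottleneck_dim, self.hidden_dim, self.input_dim]


@dataclass
class TrainConfig:
    """Optimization settings shared by all network training phases."""

    epochs: int = 200
    batch_size: int = 32
    lr: float = 1e-3
    patience: int | None = 20
    seed: int = 0

    @classmethod
    def coerce(cls, obj) -> "TrainConfig":
        if obj is None:
            return cls()
        if isinstance(obj, cls):
            return obj
        if isinstance(obj, dict):
            return cls(**obj)
        raise TypeError(f"cannot interpret train config {obj!r}")


@dataclass
class AutoencoderWeights:
    """Encoder/decoder weight matrices and the training history."""

    spec: AutoencoderSpec
    encoder_layers: list  # [[W, b], [W, b]]
    decoder_layers: list
    history: list = field(default_factory=list)

    def copy(self) -> "AutoencoderWeights":
        return AutoencoderWeights(
            spec=self.spec,
            encoder_layers=[[W.copy(), b.copy()] for W, b in self.encoder_layers],
            decoder_layers=[[W.copy(), b.copy()] for W, b in self.decoder_layers],
            history=copy.deepcopy(self.history),
        )


@dataclass
class EncoderState:
    """An extracted encoder plus its provenance tag.

    provenance is one of "two_step" (source pre-training then target
    training), "target_only" (no transfer) or "source_only" (never sees
    the target domain); it is recorded at creation and never mutated.
    """

    spec: AutoencoderSpec
    layers: list
    provenance: str
    selected_genes: list | None = None
    history: list = field(default_factory=list)

    def __post_init__(self):
        if self.provenance not in PROVENANCES:
            raise ValueError(f"provenance must be one of {PROVENANCES}")
        if self.selected_genes is not None and len(self.selected_genes) != self.spec.input_dim:
            raise ValueError("first-layer input dim must equal number of selected genes")

    def copy(self) -> "EncoderState":
        return EncoderState(
            spec=self.spec,
            layers=[[W.copy(), b.copy()] for W, b in self.layers],
            provenance=self.provenance,
            selected_genes=list(self.selected_genes) if self.selected_genes else None,
            history=copy.deepcopy(self.history),
        )

    def encode(self, X) -> np.ndarray:
        mlp = _encoder_mlp(self.spec)
        mlp.set_weights(self.layers)
        return mlp.forward(X)


@dataclass
class PredictorState:
    """Encoder + 4-layer head forming the full prediction network."""

    encoder: EncoderState
    head_layers: list
    head_dims: list
    task: str  # regression | classification
    alpha: float = 0.1
    history: list = field(default_factory=list)

    def __post_init__(self):
        if self.task not in ("regression", "classification"):
            raise ValueError("task must be 'regression' or 'classification'")
        if self.head_dims[0] != self.encoder.spec.bottleneck_dim:
            raise ValueError("head input dim must equal the encoder bottleneck dim")

    def copy(self) -> "PredictorState":
        return PredictorState(
            encoder=self.encoder.copy(),
            head_layers=[[W.copy(), b.copy()] for W, b in self.head_layers],
            head_dims=list(self.head_dims),
            task=self.task,
            alpha=self.alpha,
            history=copy.deepcopy(self.history),
        )

    def to_mlp(self) -> MLP:
        spec = self.encoder.spec
        dims = spec.encoder_dims + self.head_dims[1:]
        acts = [LEAKY] * (len(dims) - 2) + [
            SIGMOID if self.task == "classification" else IDENTITY
        ]
        mlp = MLP(dims, acts, alpha=self.alpha, rng=np.random.default_rng(0))
        mlp.set_weights(self.encoder.layers + self.head_layers)
        return mlp


# ---------------------------------------------------------------------------
# core operations
# ---------------------------------------------------------------------------


def reconstruction_loss(X, X_hat) -> float:
    """(1/n) sum_i ||x_i - x_hat_i||^2 over samples i."""
    X = np.asarray(X, dtype=float)
    X_hat = np.asarray(X_hat, dtype=float)
    if X.shape != X_hat.shape:
        raise ValueError(f"shape mismatch: {X.shape} vs {X_hat.shape}")
    return float(np.sum((X - X_hat) ** 2) / X.shape[0])


def _encoder_mlp(spec: AutoencoderSpec) -> MLP:
    return MLP(spec.encoder_dims, [LEAKY, LEAKY], alpha=spec.alpha, rng=np.random.default_rng(0))


def _autoencoder_mlp(spec: AutoencoderSpec, rng) -> MLP:
    dims = spec.encoder_dims + spec.decoder_dims[1:]
    acts = [LEAKY, LEAKY, LEAKY, IDENTITY]
    return MLP(dims, acts, alpha=spec.alpha, rng=rng)


def init_autoencoder(spec: AutoencoderSpec, seed: int = 0) -> AutoencoderWeights:
    """Default (fan-in-scaled uniform) initialization of a full autoencoder."""
    mlp = _autoencoder_mlp(spec, np.random.default_rng(seed))
    w = mlp.get_weights()
    return AutoencoderWeights(spec=spec, encoder_layers=w[:2], decoder_layers=w[2:])


def autoencoder_reconstruct(weights: AutoencoderWeights, X) -> np.ndarray:
    mlp = _autoencoder_mlp(weights.spec, np.random.default_rng(0))
    mlp.set_weights(weights.encoder_layers + weights.decoder_layers)
    return mlp.forward(X)


def validation_reconstruction_loss(weights: AutoencoderWeights, X) -> float:
    return reconstruction_loss(X, autoencoder_reconstruct(weights, X))


def train_autoencoder(
    X,
    spec: AutoencoderSpec,
    init: AutoencoderWeights | None = None,
    val_fraction: float = 0.1,
    config: TrainConfig | dict | None = None,
    phase: str = "train",
    freeze_encoder: bool = False,
) -> AutoencoderWeights:
    """Gradient-train the autoencoder, returning the best-validation checkpoint.

    90% of the rows train and 10% validate by default.  With an explicit
    ``init`` the provided weights are the starting point (zero-epoch
    budgets therefore return them unchanged).
    """
    X = np.asarray(X, dtype=float)
    cfg = TrainConfig.coerce(config)
    if X.shape[1] != spec.input_dim:
        raise ValueError(f"X has {X.shape[1]} columns but spec.input_dim is {spec.input_dim}")
    if X.shape[0] < 10:
        raise ValueError("need at least 10 samples for a non-empty validation split")

    mlp = _autoencoder_mlp(spec, np.random.default_rng(cfg.seed))
    if init is not None:
        if init.spec.encoder_dims != spec.encoder_dims:
            raise ValueError("init weights do not match the requested architecture")
        mlp.set_weights(init.encoder_layers + init.decoder_layers)
    history = train_mlp(
        mlp,
        X,
        X,
        loss="recon",
        epochs=cfg.epochs,
        batch_size=cfg.batch_size,
        lr=cfg.lr,
        patience=cfg.patience,
        val_fraction=val_fraction,
        seed=cfg.seed,
        freeze_layers=(0, 1) if freeze_encoder else (),
    )
    w = mlp.get_weights()
    prior = list(init.history) if init is not None else []
    return AutoencoderWeights(
        spec=spec,
        encoder_layers=w[:2],
        decoder_layers=w[2:],
        history=prior + [{"phase": phase, **history}],
    )


def transfer_encoder_weights(
    source: AutoencoderWeights, spec: AutoencoderSpec, seed: int = 0
) -> AutoencoderWeights:
    """Step (ii) of the two-step procedure: source encoder weights become the
    initialization of a fresh target autoencoder; the decoder is re-initialized
    by the default scheme."""
    fresh = init_autoencoder(spec, seed=seed)
    return AutoencoderWeights(
        spec=spec,
        encoder_layers=[[W.copy(), b.copy()] for W, b in source.encoder_layers],
        decoder_layers=fresh.decoder_layers,
        history=list(source.history),
    )


def two_step_pretrain(
    source_X,
    target_X,
    spec: AutoencoderSpec,
    config: TrainConfig | dict | None = None,
    selected_genes=None,
    warmup_fraction: float = 0.25,
) -> EncoderState:
    """Train on the source domain, transfer the encoder, train on the target,
    extract the encoder (provenance "two_step").

    Both matrices must hold the same selected genes in the same order.
    The target phase spends the first ``warmup_fraction`` of its epoch
    budget training only the freshly re-initialized decoder with the
    transferred encoder frozen (gradual unfreezing): gradients flowing
    back through a random decoder would otherwise corrupt the transferred
    weights before the decoder has re-converged.  The total target budget
    (warm-up + joint) equals ``config.epochs``, so comparisons against the
    no-transfer encoder are budget-matched.
    """
    source_X = np.asarray(source_X, dtype=float)
    target_X = np.asarray(target_X, dtype=float)
    if source_X.shape[1] != target_X.shape[1]:
        raise ValueError(
            f"gene-order mismatch: source has {source_X.shape[1]} columns, "
            f"target has {target_X.shape[1]}"
        )
    if not 0.0 <= warmup_fraction < 1.0:
        raise ValueError("warmup_fraction must lie in [0, 1)")
    cfg = TrainConfig.coerce(config)
    source_ae = train_autoencoder(source_X, spec, config=cfg, phase="source")
    target_init = transfer_encoder_weights(source_ae, spec, seed=cfg.seed + 1)
    warm_epochs = int(round(cfg.epochs * warmup_fraction))
    if warm_epochs:
        target_init = train_autoencoder(
            target_X,
            spec,
            init=target_init,
            config=dataclasses.replace(cfg, epochs=warm_epochs),
            phase="target_warmup",
            freeze_encoder=True,
        )
    target_ae = train_autoencoder(
        target_X,
        spec,
        init=target_init,
        config=dataclasses.replace(cfg, epochs=cfg.epochs - warm_epochs, seed=cfg.seed + 1),
        phase="target",
    )
    return EncoderState(
        spec=spec,
        layers=target_ae.encoder_layers,
        provenance="two_step",
        selected_genes=list(selected_genes) if selected_genes is not None else None,
        history=target_ae.history,
    )


def make_encoder_variant(
    source_X,
    target_X,
    spec: AutoencoderSpec,
    variant: str,
    config: TrainConfig | dict | None = None,
    selected_genes=None,
) -> EncoderState:
    """Build one of the three encoder variants compared in the ablation:
    two_step (transfer), target_only (no transfer), source_only (tumor
    encoder used as-is)."""
    if variant not in PROVENANCES:
        raise ValueError(f"variant must be one of {PROVENANCES}")
    if variant == "two_step":
        return two_step_pretrain(source_X, target_X, spec, config, selected_genes)
    cfg = TrainConfig.coerce(config)
    X = np.asarray(target_X if variant == "target_only" else source_X, dtype=float)
    ae = train_autoencoder(X, spec, config=cfg, phase=variant)
    return EncoderState(
        spec=spec,
        layers=ae.encoder_layers,
        provenance=variant,
        selected_genes=list(selected_genes) if selected_genes is not None else None,
        history=ae.history,
    )


def build_predictor(
    encoder: EncoderState,
    task: str = "regression",
    head_config: dict | None = None,
) -> PredictorState:
    """Attach the 4-layer head (merge layer -> two FC layers -> one output)
    to an encoder.  The head uses default initialization; the encoder
    weights carry over unchanged as the joint network's initialization."""
    head_config = dict(head_config or {})
    widths = tuple(head_config.get("hidden", (128, 32)))
    seed = int(head_config.get("seed", 0))
    dims = [encoder.spec.bottleneck_dim, *widths, 1]
    rng = np.random.default_rng(seed)
    acts = [LEAKY] * (len(dims) - 2) + [SIGMOID if task == "classification" else IDENTITY]
    head = MLP(dims, acts, alpha=encoder.spec.alpha, rng=rng)
    return PredictorState(
        encoder=encoder.copy(),
        head_layers=head.get_weights(),
        head_dims=dims,
        task=task,
        alpha=encoder.spec.alpha,
    )


def fit_predictor(
    model: PredictorState,
    X,
    y,
    val_fraction: float = 0.1,
    config: TrainConfig | dict | None = None,
    freeze_encoder: bool = False,
) -> PredictorState:
    """Fine-tune all layers (encoder + head) on one measurement feature.

    Regression minimizes MSE; classification minimizes binary
    cross-entropy with a stratified validation split.  The
    best-validation checkpoint is returned; with ``freeze_encoder`` the
    encoder layers are excluded from the updates.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    cfg = TrainConfig.coerce(config)
    if X.shape[0] < 10:
        raise ValueError("need at least 10 samples to fine-tune")
    if X.shape[1] != model.encoder.spec.input_dim:
        raise ValueError(
            f"X has {X.shape[1]} columns but the encoder expects "
            f"{model.encoder.spec.input_dim}"
        )
    stratify = None
    if model.task == "classification":
        classes = np.unique(y)
        if len(classes) < 2:
            raise ValueError("classification requires both classes in y")
        stratify = y

    out = model.copy()
    mlp = out.to_mlp()
    n_enc = len(out.encoder.layers)
    history = train_mlp(
        mlp,
        X,
        y,
        loss="bce" if model.task == "classification" else "mse",
        epochs=cfg.epochs,
        batch_size=cfg.batch_size,
        lr=cfg.lr,
        patience=cfg.patience,
        val_fraction=val_fraction,
        seed=cfg.seed,
        stratify=stratify,
        freeze_layers=tuple(range(n_enc)) if freeze_encoder else (),
    )
    w = mlp.get_weights()
    out.encoder.layers = w[:n_enc]
    out.head_layers = w[n_enc:]
    out.history = out.history + [{"phase": "finetune", **history}]
    return out


def predict(model: PredictorState, X) -> np.ndarray:
    """Deterministic forward pass; probabilities for classification."""
    X = np.asarray(X, dtype=float)
    return model.to_mlp().forward(X).ravel()


# ---------------------------------------------------------------------------
# scikit-learn estimator surface
# ---------------------------------------------------------------------------


class Autoencoder(TransformerMixin, BaseEstimator):
    """Autoencoder transformer: fit reconstructs X, transform encodes it.

    Parameters mirror :class:`AutoencoderSpec` plus training settings;
    ``transform`` returns the bottleneck representation.
    """

    def __init__(
        self,
        hidden_dim: int = 512,
        bottleneck_dim: int = 200,
        alpha: float = 0.1,
        epochs: int = 200,
        batch_size: int = 32,
        lr: float = 1e-3,
        patience: int | None = 20,
        val_fraction: float = 0.1,
        random_state: int = 0,
    ):
        self.hidden_dim = hidden_dim
        self.bottleneck_dim = bottleneck_dim
        self.alpha = alpha
        self.epochs = epochs
        self.batch_size = batch_size
        self.lr = lr
        self.patience = patience
        self.val_fraction = val_fraction
        self.random_state = random_state

    def _config(self) -> TrainConfig:
        return TrainConfig(
            epochs=self.epochs,
            batch_size=self.batch_size,
            lr=self.lr,
            patience=self.patience,
            seed=self.random_state,
        )

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        spec = AutoencoderSpec(X.shape[1], self.hidden_dim, self.bottleneck_dim, self.alpha)
        self.weights_ = train_autoencoder(
            X, spec, val_fraction=self.val_fraction, config=self._config()
        )
        self.spec_ = spec
        self.n_features_in_ = X.shape[1]
        self.history_ = self.weights_.history
        return self

    def transform(self, X) -> np.ndarray:
        check_is_fitted(self, "weights_")
        enc = EncoderState(self.spec_, self.weights_.encoder_layers, "target_only")
        return enc.encode(X)

    def inverse_transform(self, H) -> np.ndarray:
        check_is_fitted(self, "weights_")
        mlp = MLP(
            self.spec_.decoder_dims,
            [LEAKY, IDENTITY],
            alpha=self.spec_.alpha,
            rng=np.random.default_rng(0),
        )
        mlp.set_weights(self.weights_.decoder_layers)
        return mlp.forward(H)


class _TransCellBase(BaseEstimator):
    """Shared fit logic for the regression / classification networks."""

    _task = "regression"

    def __init__(
        self,
        encoder: EncoderState | None = None,
        hidden_dim: int = 512,
        bottleneck_dim: int = 200,
        head_hidden=(128, 32),
        alpha: float = 0.1,
        epochs: int = 200,
        batch_size: int = 32,
        lr: float = 1e-3,
        patience: int | None = 20,
        val_fraction: float = 0.1,
        freeze_encoder: bool = False,
        random_state: int = 0,
    ):
        self.encoder = encoder
        self.hidden_dim = hidden_dim
        self.bottleneck_dim = bottleneck_dim
        self.head_hidden = head_hidden
        self.alpha = alpha
        self.epochs = epochs
        self.batch_size = batch_size
        self.lr = lr
        self.patience = patience
        self.val_fraction = val_fraction
        self.freeze_encoder = freeze_encoder
        self.random_state = random_state

    def _config(self) -> TrainConfig:
        return TrainConfig(
            epochs=self.epochs,
            batch_size=self.batch_size,
            lr=self.lr,
            patience=self.patience,
            seed=self.random_state,
        )

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float).ravel()
        if X.shape[0] != len(y):
            raise ValueError("X and y disagree on sample count")
        if self.encoder is not None:
            encoder = self.encoder
        else:
            # no pre-training: default-initialized encoder of the same shape
            spec = AutoencoderSpec(X.shape[1], self.hidden_dim, self.bottleneck_dim, self.alpha)
            mlp = _encoder_mlp(spec)
            mlp.set_weights(
                MLP(
                    spec.encoder_dims,
                    [LEAKY, LEAKY],
                    alpha=self.alpha,
                    rng=np.random.default_rng(self.random_state),
                ).get_weights()
            )
            encoder = EncoderState(spec, mlp.get_weights(), "target_only")
        state = build_predictor(
            encoder,
            task=self._task,
            head_config={"hidden": tuple(self.head_hidden), "seed": self.random_state},
        )
        self.state_ = fit_predictor(
            state,
            X,
            y,
            val_fraction=self.val_fraction,
            config=self._config(),
            freeze_encoder=self.freeze_encoder,
        )
        self.history_ = self.state_.history
        self.n_features_in_ = X.shape[1]
        return self

    def _forward(self, X) -> np.ndarray:
        check_is_fitted(self, "state_")
        return predict(self.state_, X)


class TransCellRegressor(RegressorMixin, _TransCellBase):
    """Pre-trained-encoder network for continuous measurement prediction."""

    _task = "regression"

    def predict(self, X) -> np.ndarray:
        return self._forward(X)


class TransCellClassifier(ClassifierMixin, _TransCellBase):
    """Pre-trained-encoder network for binary (mutation) prediction."""

    _task = "classification"

    def fit(self, X, y):
        y = np.asarray(y, dtype=float).ravel()
        self.classes_ = np.unique(y)
        return super().fit(X, y)

    def predict_proba(self, X) -> np.ndarray:
        p = self._forward(X)
        return np.column_stack([1.0 - p, p])

    def decision_function(self, X) -> np.ndarray:
        return self._forward(X)

    def predict(self, X) -> np.ndarray:
        return (self._forward(X) >= 0.5).astype(float)
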