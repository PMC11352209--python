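"""Four classification models behind one scoring contract.

Every fitted model exposes ``score_dataset(dataset) -> per-spectrum score``
where a higher score means more malignant, plus a default decision
threshold (0.5 for probability-like scores — RF vote fraction, CNN sigmoid
— and 0 for margin scores — PCA-LDA discriminant, SVM decision value).
Class encoding is malignant = 1, benign = 0 everywhere.

* PCA-LDA: principal components retained up to 95% explained variance,
  capped at 12; two-class Fisher discriminant on the scores, with a small
  ridge (1e-6 * trace / k) on the within-class scatter for conditioning.
* RF: 200 trees on raw preprocessed intensities; score = mean tree vote.
* SVM: soft-margin SVC (default RBF kernel, C = 1, data-scaled gamma; the
  kernel and C are configuration, not dogma — no canonical values exist
  for this assay).
* CNN: conv/ReLU/max-pool blocks + dense head + sigmoid, Adam on binary
  cross-entropy, batch 64, initial lr 1e-3 halved on a validation-loss
  plateau, at most 50 epochs; the returned parameters are the snapshot
  from the epoch with minimum validation loss.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field, asdict

import numpy as np
from sklearn.decomposition import PCA
from sklearn.ensemble import RandomForestClassifier
from sklearn.svm import SVC

from . import nn
from .core import SpectrumDataset
from .errors import ConfigError, ValidationError

__all__ = [
    "PcaLdaConfig", "RfConfig", "SvmConfig", "CnnConfig",
    "ClassifierModel", "fit_pca_lda", "fit_rf", "fit_svm", "fit_cnn", "fit_model",
]


# ------------------------------------------------------------------ configs


@dataclass
class PcaLdaConfig:
    variance_target: float = 0.95
    max_components: int = 12

    def __post_init__(self):
        if not 0 < self.variance_target <= 1:
            raise ConfigError("variance_target must be in (0, 1]")
        if self.max_components < 1:
            raise ConfigError("max_components must be >= 1")


@dataclass
class RfConfig:
    n_estimators: int = 200
    seed: int = 0

    def __post_init__(self):
        if self.n_estimators < 1:
            raise ConfigError("n_estimators must be >= 1")


@dataclass
class SvmConfig:
    kernel: str = "rbf"
    C: float = 1.0
    gamma: str | float = "scale"

    def __post_init__(self):
        if self.kernel not in ("rbf", "linear"):
            raise ConfigError(f"kernel must be 'rbf' or 'linear', got {self.kernel!r}")
        if self.C <= 0:
            raise ConfigError("C must be > 0")


@dataclass
class CnnConfig:
    conv_blocks: list[tuple[int, int]] = field(default_factory=lambda: [(16, 7), (32, 7), (64, 7)])
    fc_sizes: list[int] = field(default_factory=lambda: [64])
    learning_rate: float = 1e-3
    lr_decay_factor: float = 0.5
    lr_patience: int = 5
    early_stop_patience: int = 15
    batch_size: int = 64
    max_epochs: int = 50
    seed: int = 0

    def __post_init__(self):
        if self.learning_rate <= 0:
            raise ConfigError("learning_rate must be > 0")
        if not 0 < self.lr_decay_factor < 1:
            raise ConfigError("lr_decay_factor must be in (0, 1)")
        if self.batch_size < 1 or self.max_epochs < 1:
            raise ConfigError("batch_size and max_epochs must be >= 1")


# ------------------------------------------------------------------- models


class ClassifierModel:
    """Fitted model: opaque state + the shared scoring contract."""

    model_kind: str = ""
    threshold: float = 0.5

    def __init__(self, train_shifts: np.ndarray, metadata: dict):
        self.train_shifts = np.asarray(train_shifts, dtype=float)
        self.metadata = metadata

    def _check_grid(self, dataset: SpectrumDataset) -> np.ndarray:
        if len(dataset.shifts) != len(self.train_shifts) or not np.allclose(
            dataset.shifts, self.train_shifts
        ):
            raise ValidationError(
                f"{self.model_kind}: dataset grid does not match the training grid"
            )
        return dataset.intensities

    def score_dataset(self, dataset: SpectrumDataset) -> np.ndarray:
        """Per-spectrum malignancy score (higher = more malignant)."""
        return self._score(self._check_grid(dataset))

    def predict_labels(self, dataset: SpectrumDataset) -> np.ndarray:
        return (self.score_dataset(dataset) >= self.threshold).astype(int)

    def _score(self, X: np.ndarray) -> np.ndarray:  # pragma: no cover - interface
        raise NotImplementedError


def _check_train(dataset: SpectrumDataset) -> tuple[np.ndarray, np.ndarray]:
    y = dataset.labels
    if (y == 0).sum() < 2 or (y == 1).sum() < 2:
        raise ValidationError("training needs at least 2 spectra of each class")
    return dataset.intensities, y


class PcaLdaModel(ClassifierModel):
    model_kind = "pca_lda"
    threshold = 0.0

    def __init__(self, train_shifts, metadata, mean, components, w, offset):
        super().__init__(train_shifts, metadata)
        self.mean, self.components, self.w, self.offset = mean, components, w, offset

    @property
    def n_components(self) -> int:
        return len(self.components)

    def transform(self, X: np.ndarray) -> np.ndarray:
        return (X - self.mean) @ self.components.T

    def _score(self, X: np.ndarray) -> np.ndarray:
        return self.transform(X) @ self.w - self.offset


def fit_pca_lda(train: SpectrumDataset, config: PcaLdaConfig | None = None) -> PcaLdaModel:
    """PCA (deterministic full SVD) followed by two-class Fisher LDA.

    The number of retained components k is the smallest count whose
    cumulative explained variance reaches ``variance_target``, capped at
    ``max_components`` (and at the data rank).
    """
    config = config or PcaLdaConfig()
    X, y = _check_train(train)
    pca = PCA(n_components=min(config.max_components, min(X.shape) - 1 or 1), svd_solver="full")
    scores = pca.fit_transform(X)
    cum = np.cumsum(pca.explained_variance_ratio_)
    reached = np.flatnonzero(cum >= config.variance_target - 1e-12)
    k = int(reached[0]) + 1 if len(reached) else pca.n_components_
    k = max(1, min(k, config.max_components))
    scores = scores[:, :k]
    mu0, mu1 = scores[y == 0].mean(axis=0), scores[y == 1].mean(axis=0)
    sw = np.zeros((k, k))
    for cls, mu in ((0, mu0), (1, mu1)):
        d = scores[y == cls] - mu
        sw += d.T @ d
    sw += np.eye(k) * (1e-6 * np.trace(sw) / k)  # ridge for ill-conditioned scatter
    w = np.linalg.solve(sw, mu1 - mu0)
    offset = float(w @ (mu0 + mu1) / 2.0)
    meta = {"config": asdict(config), "n_components": k,
            "explained_variance": float(cum[k - 1])}
    return PcaLdaModel(train.shifts, meta, pca.mean_, pca.components_[:k], w, offset)


class SklearnModel(ClassifierModel):
    def __init__(self, model_kind, threshold, train_shifts, metadata, estimator, probability):
        super().__init__(train_shifts, metadata)
        self.model_kind = model_kind
        self.threshold = threshold
        self.estimator = estimator
        self._probability = probability

    def _score(self, X: np.ndarray) -> np.ndarray:
        if self._probability:
            return self.estimator.predict_proba(X)[:, 1]
        return self.estimator.decision_function(X)


def fit_rf(train: SpectrumDataset, config: RfConfig | None = None) -> SklearnModel:
    """Random forest on raw preprocessed channel intensities; score = mean
    tree vote for malignant (trees are grown to purity, so per-tree
    probabilities are 0/1 votes)."""
    config = config or RfConfig()
    X, y = _check_train(train)
    est = RandomForestClassifier(
        n_estimators=config.n_estimators, random_state=config.seed, n_jobs=1
    ).fit(X, y)
    return SklearnModel("rf", 0.5, train.shifts, {"config": asdict(config)}, est, probability=True)


def fit_svm(train: SpectrumDataset, config: SvmConfig | None = None) -> SklearnModel:
    """Soft-margin SVM; score = signed decision value, malignant positive."""
    config = config or SvmConfig()
    X, y = _check_train(train)
    est = SVC(kernel=config.kernel, C=config.C, gamma=config.gamma).fit(X, y)
    return SklearnModel("svm", 0.0, train.shifts, {"config": asdict(config)}, est, probability=False)


class CnnModel(ClassifierModel):
    model_kind = "cnn"
    threshold = 0.5

    def __init__(self, train_shifts, metadata, network: nn.Network):
        super().__init__(train_shifts, metadata)
        self.network = network

    def _logits(self, X: np.ndarray, batch: int = 256) -> np.ndarray:
        X3 = X.astype(np.float32)[:, None, :]
        return np.concatenate(
            [self.network.forward(X3[i : i + batch]) for i in range(0, len(X3), batch)]
        )

    def _score(self, X: np.ndarray) -> np.ndarray:
        return 1.0 / (1.0 + np.exp(-self._logits(X).astype(np.float64)))

    def input_gradients(self, dataset: SpectrumDataset, batch: int = 256) -> np.ndarray:
        """d(pre-sigmoid logit)/d(input channel) per spectrum, (n, channels)."""
        X3 = self._check_grid(dataset).astype(np.float32)[:, None, :]
        grads = [
            self.network.input_gradient(X3[i : i + batch])[:, 0, :]
            for i in range(0, len(X3), batch)
        ]
        return np.concatenate(grads).astype(np.float64)

    @property
    def history(self) -> dict:
        return self.metadata["history"]

    @property
    def selected_epoch(self) -> int:
        return self.metadata["selected_epoch"]


def fit_cnn(train: SpectrumDataset, val: SpectrumDataset, config: CnnConfig | None = None) -> CnnModel:
    """Train the 1-D CNN with Adam on binary cross-entropy.

    The learning rate is multiplied by ``lr_decay_factor`` whenever the
    validation loss has not improved for ``lr_patience`` consecutive
    epochs; training stops early after ``early_stop_patience`` epochs
    without improvement (the selected snapshot is the minimum-validation-
    loss epoch either way, so a long plateau cannot change the result).
    Fully seeded: initialization and batch order derive from
    ``config.seed``.
    """
    config = config or CnnConfig()
    if len(val) == 0:
        raise ValidationError("cnn training requires a nonempty validation set")
    if len(val.shifts) != len(train.shifts) or not np.allclose(val.shifts, train.shifts):
        raise ValidationError("train and validation sets must share one grid")
    X, y = _check_train(train)
    Xv, yv = val.intensities, val.labels
    rng = np.random.default_rng(config.seed)
    network = nn.build_cnn(X.shape[1], [tuple(b) for b in config.conv_blocks],
                           list(config.fc_sizes), rng)
    opt = nn.Adam(network, lr=config.learning_rate)
    X3 = X.astype(np.float32)[:, None, :]
    Xv3 = Xv.astype(np.float32)[:, None, :]
    yf = y.astype(np.float32)

    history = {"train_loss": [], "val_loss": [], "lr": []}
    best_loss, best_state, best_epoch = np.inf, network.state(), 0
    stale = 0
    for epoch in range(1, config.max_epochs + 1):
        order = rng.permutation(len(X3))
        epoch_loss = 0.0
        for start in range(0, len(order), config.batch_size):
            idx = order[start : start + config.batch_size]
            logits = network.forward(X3[idx])
            loss, dlogits = nn.bce_with_logits(logits, yf[idx])
            if not np.isfinite(loss):
                raise nn.TrainingError(f"non-finite training loss at epoch {epoch}")
            epoch_loss += loss * len(idx)
            network.backward(dlogits)
            opt.step()
        val_logits = np.concatenate(
            [network.forward(Xv3[i : i + 256]) for i in range(0, len(Xv3), 256)]
        )
        val_loss, _ = nn.bce_with_logits(val_logits, yv.astype(np.float32))
        if not np.isfinite(val_loss):
            raise nn.TrainingError(f"non-finite validation loss at epoch {epoch}")
        history["train_loss"].append(epoch_loss / len(X3))
        history["val_loss"].append(val_loss)
        history["lr"].append(opt.lr)
        if val_loss < best_loss - 1e-9:
            best_loss, best_state, best_epoch = val_loss, network.state(), epoch
            stale = 0
        else:
            stale += 1
            if stale % config.lr_patience == 0:
                opt.lr *= config.lr_decay_factor
            if stale >= config.early_stop_patience:
                break
    network.load_state(best_state)
    meta = {"config": asdict(config), "history": history, "selected_epoch": best_epoch}
    return CnnModel(train.shifts, meta, network)


_FITTERS = {"pca_lda": fit_pca_lda, "rf": fit_rf, "svm": fit_svm}


def fit_model(kind: str, train: SpectrumDataset, val: SpectrumDataset | None = None,
              config=None) -> ClassifierModel:
    """Dispatch by model kind; ``val`` is required for (and only used by) the cnn."""
    if kind == "cnn":
        if val is None:
            raise ValidationError("cnn requires a validation dataset")
        return fit_cnn(train, val, config)
    if kind not in _FITTERS:
        raise ConfigError(f"unknown model kind {kind!r}")
    return _FITTERS[kind](train, config)
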