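"""Per-pixel tissue classifiers: classical spectrum models and the 3-D patch CNN.

The classical models (RBF/linear SVM, MLP, random forest, logistic
regression) classify a pixel from its SNV spectrum alone.  The 3-D CNN
classifies each pixel from the 5×5×L sub-volume centered on it, so it can
exploit local spatial context in addition to the spectrum.  The CNN is a
light architecture in the decomposed-convolution family: two 3-D
convolutions interleaved with strided dilated spectral convolutions, two
further spectral convolutions and a fully connected head — 32,232 trainable
weights in the default (5×5×100 → 2) configuration, small enough to train
on cohorts of tens of patients.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import nn
from .hsio import AnnotationMask, Hypercube
from .preprocess import (
    PatchConfig,
    Sample,
    extract_patch,
    inverse_frequency_weights,
    split_train_validation,
)

__all__ = [
    "ClassicalModelSpec",
    "CNNConfig",
    "TrainingConfig",
    "TrainedModel",
    "ScoreMap",
    "CLASSICAL_KINDS",
    "DEFAULT_CNN_WEIGHT_COUNT",
    "build_3dcnn",
    "count_trainable_weights",
    "train_3dcnn",
    "train_classical",
    "predict_scores",
    "save_checkpoint",
    "load_checkpoint",
]

CLASSICAL_KINDS = ("rbf_svm", "linear_svm", "mlp", "random_forest", "logistic_regression")

#: trainable-weight checksum of the default (window 5, 100 bands, 2 classes) CNN
DEFAULT_CNN_WEIGHT_COUNT = 32_232


@dataclass(frozen=True)
class ClassicalModelSpec:
    kind: str
    hyperparameters: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.kind not in CLASSICAL_KINDS:
            raise ValueError(f"unknown classical model kind {self.kind!r}")


@dataclass(frozen=True)
class CNNConfig:
    window: int = 5
    bands: int = 100
    n_classes: int = 2


@dataclass(frozen=True)
class TrainingConfig:
    learning_rate: float = 0.01
    weight_decay: float = 0.0005
    epochs: int = 200
    batch_size: int = 3000
    validation_fraction: float = 0.10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.learning_rate <= 0 or self.weight_decay < 0:
            raise ValueError("learning rate must be positive, weight decay non-negative")
        if self.epochs < 1 or self.batch_size < 1:
            raise ValueError("epochs and batch size must be >= 1")


@dataclass(frozen=True)
class ScoreMap:
    """Per-pixel cancer-probability raster with a validity mask."""

    scores: np.ndarray  # H×W float in [0, 1] where valid
    valid: np.ndarray  # H×W bool
    patient_id: str = ""

    def __post_init__(self) -> None:
        if self.scores.shape != self.valid.shape:
            raise ValueError("scores and validity mask must share a shape")
        object.__setattr__(self, "valid", np.asarray(self.valid, dtype=bool))
        s = self.scores[self.valid]
        if s.size and (s.min() < 0 or s.max() > 1):
            raise ValueError("scores must lie in [0, 1]")


@dataclass
class TrainedModel:
    """A fitted classifier plus the metadata needed to score new cubes."""

    kind: str
    input_kind: str  # "spectrum" | "patch"
    normalization: str  # SNV-convention tag ("snv")
    _scorer: object
    metadata: dict = field(default_factory=dict)
    patch_config: PatchConfig | None = None

    def score_samples(self, X: np.ndarray) -> np.ndarray:
        """Positive-class (cancer) probability for a batch of inputs."""
        p = self._scorer(X)  # type: ignore[operator]
        return np.clip(np.asarray(p, dtype=np.float64), 0.0, 1.0)


# ---------------------------------------------------------------------------
# 3-D CNN
# ---------------------------------------------------------------------------

def _cnn_plan(cfg: CNNConfig) -> list:
    """The pinned layer plan (depth axis = spectral axis)."""
    return [
        nn.Conv3d(1, 20, (3, 3, 3), padding=(1, 0, 0)),
        nn.ReLU(),
        nn.Conv3d(20, 20, (3, 1, 1), stride=(2, 1, 1), dilation=(3, 1, 1), padding=(1, 0, 0)),
        nn.ReLU(),
        nn.Conv3d(20, 35, (3, 3, 3), padding=(1, 0, 0)),
        nn.ReLU(),
        nn.Conv3d(35, 35, (3, 1, 1), stride=(2, 1, 1), padding=(0, 0, 0)),
        nn.ReLU(),
        nn.Conv3d(35, 35, (3, 1, 1), padding=(1, 0, 0)),
        nn.ReLU(),
        nn.Conv3d(35, 35, (2, 1, 1), dilation=(2, 1, 1), padding=(1, 0, 0)),
        nn.ReLU(),
        nn.Flatten(),
    ]


def build_3dcnn(cfg: CNNConfig = CNNConfig()) -> nn.Network:
    """Build the patch CNN for ``cfg`` and verify the default checksum.

    The network maps a ``1×L×window×window`` input volume to ``n_classes``
    logits.  For the default (5, 100, 2) configuration the total trainable
    weight count must equal :data:`DEFAULT_CNN_WEIGHT_COUNT`; a plan that
    cannot reach it raises a configuration error reporting the achieved
    count.
    """
    layers = _cnn_plan(cfg)
    # shape inference for the fully connected head
    shape = (cfg.bands, cfg.window, cfg.window)
    channels = 1
    for layer in layers:
        if isinstance(layer, nn.Conv3d):
            shape = layer.out_shape(shape)
            channels = layer.c_out
    n_features = channels * int(np.prod(shape))
    layers.append(nn.Linear(n_features, cfg.n_classes))
    network = nn.Network(layers)
    if (cfg.window, cfg.bands, cfg.n_classes) == (5, 100, 2):
        count = network.n_weights()
        if count != DEFAULT_CNN_WEIGHT_COUNT:
            raise ValueError(
                f"default CNN plan has {count} trainable weights, "
                f"expected {DEFAULT_CNN_WEIGHT_COUNT}"
            )
    return network


def count_trainable_weights(network: nn.Network) -> int:
    """Total element count of all weight tensors and bias vectors."""
    return network.n_weights()


def _patches_to_input(samples: list[Sample]) -> np.ndarray:
    # (w, w, L) patch -> (1, L, w, w) network input
    X = np.stack([np.moveaxis(s.patch, 2, 0) for s in samples])
    return X[:, None, :, :, :].astype(np.float32)


def train_3dcnn(
    samples: list[Sample],
    cfg: CNNConfig = CNNConfig(),
    tcfg: TrainingConfig = TrainingConfig(),
) -> TrainedModel:
    """Train the patch CNN with SGD on class-weighted cross-entropy.

    Each epoch draws one batch of ``batch_size`` patches uniformly without
    replacement from the training pool (a single smaller batch when the
    pool is smaller than ``batch_size``); the validation loss is evaluated
    after every epoch and the weights of the best-validation epoch are
    returned.  Fully deterministic given ``tcfg.seed``.
    """
    labels = np.array([s.label for s in samples])
    if len(set(labels.tolist())) < 2:
        raise ValueError("training requires both classes present")
    if any(s.patch is None for s in samples):
        raise ValueError("CNN training samples must carry patches")

    rng = np.random.default_rng(tcfg.seed)
    train, val = split_train_validation(
        samples, fraction=tcfg.validation_fraction, seed=tcfg.seed
    )
    counts = {c: int((labels == c).sum()) for c in sorted(set(labels.tolist()))}
    wmap = inverse_frequency_weights(counts)
    class_weights = np.array([wmap[0], wmap[1]])

    Xtr = _patches_to_input(train)
    ytr = np.array([s.label for s in train])
    Xval = _patches_to_input(val)
    yval = np.array([s.label for s in val])

    network = build_3dcnn(cfg)
    network.init_kaiming(rng)
    opt = nn.SGD(network, lr=tcfg.learning_rate, weight_decay=tcfg.weight_decay)

    best_state = network.get_state()
    best_val = np.inf
    best_epoch = -1
    history = []
    n = len(train)
    bs = min(tcfg.batch_size, n)
    for epoch in range(tcfg.epochs):
        idx = rng.choice(n, size=bs, replace=False)
        network.zero_grad()
        logits = network.forward(Xtr[idx], train=True)
        loss, grad = nn.weighted_cross_entropy(logits, ytr[idx], class_weights)
        network.backward(grad)
        opt.step()
        val_logits = network.forward(Xval, train=False)
        val_loss, _ = nn.weighted_cross_entropy(val_logits, yval, class_weights)
        history.append({"epoch": epoch, "train_loss": loss, "val_loss": val_loss})
        if val_loss < best_val:
            best_val = val_loss
            best_state = network.get_state()
            best_epoch = epoch
    network.set_state(best_state)

    def scorer(X: np.ndarray) -> np.ndarray:
        logits = network.forward(X, train=False)
        z = logits - logits.max(axis=1, keepdims=True)
        p = np.exp(z)
        return p[:, 1] / p.sum(axis=1)

    return TrainedModel(
        kind="cnn3d",
        input_kind="patch",
        normalization="snv",
        _scorer=scorer,
        metadata={
            "seed": tcfg.seed,
            "epochs_run": tcfg.epochs,
            "best_epoch": best_epoch,
            "best_validation_loss": best_val,
            "history": history,
            "class_counts": counts,
            "network": network,
            "cnn_config": cfg,
        },
        patch_config=PatchConfig(window=cfg.window, bands=cfg.bands),
    )


# ---------------------------------------------------------------------------
# Classical models
# ---------------------------------------------------------------------------

def _build_classical(spec: ClassicalModelSpec, seed: int):
    from sklearn.ensemble import RandomForestClassifier
    from sklearn.linear_model import LogisticRegression
    from sklearn.neural_network import MLPClassifier
    from sklearn.svm import SVC, LinearSVC

    hp = dict(spec.hyperparameters)
    if spec.kind == "rbf_svm":
        return SVC(kernel="rbf", C=hp.get("C", 1.0), gamma=hp.get("gamma", "scale"),
                   random_state=seed)
    if spec.kind == "linear_svm":
        return LinearSVC(C=hp.get("C", 1.0), random_state=seed)
    if spec.kind == "mlp":
        # two tanh hidden layers, quasi-Newton (L-BFGS) solver on log-loss
        return MLPClassifier(
            hidden_layer_sizes=hp.get("hidden_layer_sizes", (100, 50)),
            activation="tanh",
            solver="lbfgs",
            max_iter=hp.get("max_iter", 300),
            random_state=seed,
        )
    if spec.kind == "random_forest":
        return RandomForestClassifier(
            n_estimators=hp.get("n_estimators", 100), random_state=seed
        )
    if spec.kind == "logistic_regression":
        return LogisticRegression(max_iter=hp.get("max_iter", 1000), random_state=seed)
    raise ValueError(spec.kind)


def train_classical(
    spec: ClassicalModelSpec, samples: list[Sample], seed: int = 0
) -> TrainedModel:
    """Fit a classical per-pixel model on SNV spectra (balanced upstream)."""
    y = np.array([s.label for s in samples])
    if len(set(y.tolist())) < 2:
        raise ValueError("training requires both classes present")
    X = np.stack([s.spectrum for s in samples]).astype(np.float64)
    est = _build_classical(spec, seed)
    est.fit(X, y)

    if hasattr(est, "predict_proba"):
        def scorer(Xq: np.ndarray) -> np.ndarray:
            return est.predict_proba(Xq)[:, 1]
    else:
        # margin models: monotone logistic squashing of the decision
        # function — rank-preserving, so threshold-free metrics are unchanged
        def scorer(Xq: np.ndarray) -> np.ndarray:
            return 1.0 / (1.0 + np.exp(-est.decision_function(Xq)))

    return TrainedModel(
        kind=spec.kind,
        input_kind="spectrum",
        normalization="snv",
        _scorer=scorer,
        metadata={"seed": seed, "estimator": est,
                  "class_counts": {c: int((y == c).sum()) for c in (0, 1)}},
    )


# ---------------------------------------------------------------------------
# Whole-cube inference
# ---------------------------------------------------------------------------

def predict_scores(
    model: TrainedModel,
    cube: Hypercube,
    mask: AnnotationMask,
    cfg: PatchConfig | None = None,
    exclude: np.ndarray | None = None,
    batch_size: int = 4096,
) -> ScoreMap:
    """Score every annotated pixel of a cube; unannotated pixels are invalid.

    Refuses cubes whose normalization tag differs from the one the model
    was trained with, and cubes whose band count mismatches.
    """
    if cube.normalized != model.normalization:
        raise ValueError(
            f"cube normalization {cube.normalized!r} does not match the "
            f"model's {model.normalization!r}"
        )
    cfg = cfg or model.patch_config or PatchConfig(bands=cube.n_bands)
    if cfg.bands != cube.n_bands:
        raise ValueError("cube band count differs from training")
    valid = mask.annotated()
    if exclude is not None:
        valid = valid & ~exclude
    scores = np.zeros(mask.shape, dtype=np.float64)
    rows, cols = np.nonzero(valid)
    for start in range(0, rows.size, batch_size):
        r = rows[start : start + batch_size]
        c = cols[start : start + batch_size]
        if model.input_kind == "spectrum":
            X = cube.values[r, c].astype(np.float64)
        else:
            patches = [
                np.moveaxis(extract_patch(cube.values, int(ri), int(ci), cfg.window), 2, 0)
                for ri, ci in zip(r, c)
            ]
            X = np.stack(patches)[:, None].astype(np.float32)
        scores[r, c] = model.score_samples(X)
    return ScoreMap(scores=scores, valid=valid, patient_id="")


# ---------------------------------------------------------------------------
# CNN checkpoints
# ---------------------------------------------------------------------------

def save_checkpoint(model: TrainedModel, path: str | Path) -> Path:
    """Persist a trained CNN (weights + config + normalization tag) as .npz."""
    if model.kind != "cnn3d":
        raise ValueError("checkpoints are supported for the CNN only")
    network: nn.Network = model.metadata["network"]
    cfg: CNNConfig = model.metadata["cnn_config"]
    arrays = {f"param_{i}": p for i, (p, _) in enumerate(network.params())}
    np.savez(
        Path(path),
        window=cfg.window,
        bands=cfg.bands,
        n_classes=cfg.n_classes,
        normalization=model.normalization,
        seed=model.metadata.get("seed", -1),
        best_epoch=model.metadata.get("best_epoch", -1),
        **arrays,
    )
    return Path(path)


def load_checkpoint(path: str | Path) -> TrainedModel:
    with np.load(Path(path), allow_pickle=False) as data:
        cfg = CNNConfig(
            window=int(data["window"]),
            bands=int(data["bands"]),
            n_classes=int(data["n_classes"]),
        )
        network = build_3dcnn(cfg)
        state = [data[f"param_{i}"] for i in range(len(network.params()))]
        network.set_state(state)
        normalization = str(data["normalization"])
        seed = int(data["seed"])
        best_epoch = int(data["best_epoch"])

    def scorer(X: np.ndarray) -> np.ndarray:
        logits = network.forward(X, train=False)
        z = logits - logits.max(axis=1, keepdims=True)
        p = np.exp(z)
        return p[:, 1] / p.sum(axis=1)

    return TrainedModel(
        kind="cnn3d",
        input_kind="patch",
        normalization=normalization,
        _scorer=scorer,
        metadata={"seed": seed, "best_epoch": best_epoch, "network": network,
                  "cnn_config": cfg},
        patch_config=PatchConfig(window=cfg.window, bands=cfg.bands),
    )
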