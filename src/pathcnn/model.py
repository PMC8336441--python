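"""The pathway-image CNN classifier: model object, training loop, and the
repeated stratified cross-validation protocol.

``PathCNNClassifier`` follows the model/results idiom: construct it from a
``PathwayImageSet`` + labels (+ optional age), call :meth:`fit` for a
full-cohort model (used for Grad-CAM interpretation) or :meth:`fit_cv` for
the repeated 5-fold protocol.  Both return results objects carrying the
learned state, history/per-split AUCs, and ``summary()`` tables.

Training follows the fixed recipe: weighted softmax cross-entropy
(class weight w_c = N / (2 n_c), so the minority survival class counts
more), Adam at learning rate 1e-4, 30 epochs, batch size 64, and the
parameter snapshot with the best validation AUC is kept when a validation
set is available.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold, train_test_split

from .datatypes import LTS, NON_LTS, LabelSet, PathwayImageSet
from .nn import Adam, PathCNNNet, conv2d_geometry, pooled_geometry

__all__ = [
    "ModelConfig",
    "CVResults",
    "TrainHistory",
    "build_cnn",
    "compute_class_weights",
    "train_model",
    "evaluate_auc",
    "repeated_cv",
    "PathCNNClassifier",
    "PathCNNResults",
]


@dataclass
class ModelConfig:
    """Architecture and optimisation hyper-parameters (all fixed defaults)."""

    conv_filters: tuple = (32, 64)
    kernel: tuple = (3, 3)
    pool: tuple = (4, 2)
    dropout_conv: float = 0.25
    dense_units: int = 64
    dropout_dense: float = 0.50
    epochs: int = 30
    batch_size: int = 64
    learning_rate: float = 1e-4
    use_age: bool = False
    padding_mode: str = "same"
    seed: int = 0

    def __post_init__(self):
        if min(self.conv_filters) < 1 or self.dense_units < 1 or self.epochs < 1 or self.batch_size < 1:
            raise ValueError("all counts must be positive")
        if not (0 <= self.dropout_conv < 1 and 0 <= self.dropout_dense < 1):
            raise ValueError("dropout rates must lie in [0, 1)")
        if self.padding_mode not in ("same", "valid"):
            raise ValueError("padding_mode must be 'same' or 'valid'")


def build_cnn(image_shape: tuple[int, int], config: ModelConfig,
              rng: Optional[np.random.Generator] = None) -> PathCNNNet:
    """Instantiate the two-conv network for the given image geometry; raises
    with the minimal viable shape if the image is too small."""
    return PathCNNNet(
        image_shape=image_shape,
        conv_filters=config.conv_filters,
        kernel=config.kernel,
        pool=config.pool,
        dense_units=config.dense_units,
        dropout_conv=config.dropout_conv,
        dropout_dense=config.dropout_dense,
        padding=config.padding_mode,
        use_age=config.use_age,
        rng=rng if rng is not None else np.random.default_rng(config.seed),
    )


def compute_class_weights(labels: LabelSet | np.ndarray) -> dict:
    """Balanced class weights w_c = N / (2 n_c); the minority class gets the
    larger weight, with w_LTS / w_nonLTS = n_nonLTS / n_LTS."""
    y = labels.y if isinstance(labels, LabelSet) else np.asarray(labels, dtype=int)
    n_lts = int((y == 1).sum())
    n_non = int((y == 0).sum())
    if n_lts == 0 or n_non == 0:
        raise ValueError("both survival classes must be present to weight them")
    n = n_lts + n_non
    return {LTS: n / (2.0 * n_lts), NON_LTS: n / (2.0 * n_non)}


def evaluate_auc(scores: np.ndarray, y: np.ndarray) -> float:
    """Area under the ROC curve: P(score_LTS > score_nonLTS) with ties 1/2.

    ``scores`` is the predicted probability (or any monotone score) of the
    LTS class; ``y`` the 0/1 labels (1 = LTS).
    """
    y = np.asarray(y, dtype=int)
    if len(np.unique(y)) < 2:
        raise ValueError("AUC undefined: test set contains a single class")
    return float(roc_auc_score(y, np.asarray(scores, dtype=float)))


@dataclass
class TrainHistory:
    train_loss: list = field(default_factory=list)
    train_auc: list = field(default_factory=list)
    val_loss: list = field(default_factory=list)
    val_auc: list = field(default_factory=list)
    best_epoch: int = -1  # epoch whose snapshot was returned (-1 = final)


def _weighted_loss(net: PathCNNNet, x, y, age, weights_vec) -> float:
    proba = net.predict_proba(x, age=age)
    ce = -np.log(np.clip(proba[np.arange(len(y)), y], 1e-12, None))
    return float(np.mean(weights_vec * ce))


def train_model(
    net: PathCNNNet,
    x_train: np.ndarray,
    y_train: np.ndarray,
    x_val: Optional[np.ndarray],
    y_val: Optional[np.ndarray],
    class_weights: dict,
    config: ModelConfig,
    age_train: Optional[np.ndarray] = None,
    age_val: Optional[np.ndarray] = None,
    rng: Optional[np.random.Generator] = None,
) -> TrainHistory:
    """Train in place with weighted cross-entropy; restore the snapshot with
    the best validation AUC (falls back to the final epoch when no usable
    validation set exists)."""
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    if net.use_age:
        if age_train is None:
            raise ValueError("use_age=True requires an age vector")
        net.age_mean = float(np.mean(age_train))
        net.age_sd = float(np.std(age_train)) or 1.0
    y_train = np.asarray(y_train, dtype=int)
    w = np.where(y_train == 1, class_weights[LTS], class_weights[NON_LTS]).astype(np.float32)
    opt = Adam(net.params, learning_rate=config.learning_rate)
    history = TrainHistory()
    have_val = x_val is not None and y_val is not None and len(x_val) > 0
    if have_val and len(np.unique(y_val)) < 2:
        warnings.warn("validation set contains a single class; using final-epoch weights")
        have_val = False
    best_auc, best_params, best_epoch = -np.inf, None, -1
    n = len(x_train)
    for epoch in range(config.epochs):
        order = rng.permutation(n)
        for start in range(0, n, config.batch_size):
            idx = order[start : start + config.batch_size]
            cache = net.forward(
                x_train[idx],
                age=None if age_train is None or not net.use_age else age_train[idx],
                train=True,
                rng=rng,
            )
            _, grads = net.loss_and_grads(cache, y_train[idx], w[idx])
            opt.step(net.params, grads)
        tr_proba = net.predict_proba(x_train, age=age_train if net.use_age else None)
        history.train_loss.append(_weighted_loss(net, x_train, y_train, age_train if net.use_age else None, w))
        history.train_auc.append(
            evaluate_auc(tr_proba[:, 1], y_train) if len(np.unique(y_train)) > 1 else np.nan
        )
        if have_val:
            va = age_val if net.use_age else None
            val_proba = net.predict_proba(x_val, age=va)
            wv = np.where(np.asarray(y_val) == 1, class_weights[LTS], class_weights[NON_LTS])
            history.val_loss.append(_weighted_loss(net, x_val, np.asarray(y_val, dtype=int), va, wv))
            v_auc = evaluate_auc(val_proba[:, 1], y_val)
            history.val_auc.append(v_auc)
            if v_auc > best_auc:
                best_auc, best_params, best_epoch = v_auc, net.get_weights(), epoch
    if best_params is not None:
        net.set_weights(best_params)
        history.best_epoch = best_epoch
    return history


@dataclass
class CVResults:
    """Per-split test AUCs of the repeated stratified 5-fold protocol."""

    aucs: np.ndarray  # repeats x folds
    fold_assignments: list  # per repeat: array of fold index per sample
    splits: list  # per repeat: list of (train_idx, val_idx, test_idx) per fold
    config: ModelConfig
    n_repeats: int
    n_folds: int
    seed: int

    @property
    def mean_auc(self) -> float:
        return float(np.mean(self.aucs))

    @property
    def sd_auc(self) -> float:
        return float(np.std(self.aucs, ddof=1))

    def summary(self) -> str:
        lines = [
            "Repeated stratified cross-validation",
            f"  repeats x folds : {self.n_repeats} x {self.n_folds}",
            f"  AUC             : {self.mean_auc:.3f} +/- {self.sd_auc:.3f}",
            f"  per-repeat means: "
            + " ".join(f"{m:.3f}" for m in self.aucs.mean(axis=1)),
        ]
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "mean_auc": self.mean_auc,
            "sd_auc": self.sd_auc,
            "aucs": self.aucs.tolist(),
            "n_repeats": self.n_repeats,
            "n_folds": self.n_folds,
            "seed": self.seed,
        }


def repeated_cv(
    images: np.ndarray | PathwayImageSet,
    labels: LabelSet | np.ndarray,
    age: Optional[np.ndarray] = None,
    n_repeats: int = 30,
    n_folds: int = 5,
    config: Optional[ModelConfig] = None,
    seed: int = 0,
) -> CVResults:
    """Repeated stratified k-fold evaluation.

    Per repeat: a stratified partition into ``n_folds`` test folds; for
    each fold the remaining samples are split 80/20 (stratified) into
    training and validation sets, a fresh network is trained, and the test
    AUC recorded.  All randomness derives from ``seed`` via named
    substreams, so a rerun reproduces every split and AUC exactly.
    """
    config = config or ModelConfig()
    x = images.images if isinstance(images, PathwayImageSet) else np.asarray(images)
    y = labels.y if isinstance(labels, LabelSet) else np.asarray(labels, dtype=int)
    n = len(x)
    counts = np.bincount(y, minlength=2)
    if counts.min() < n_folds:
        raise ValueError(f"smallest class has {counts.min()} samples; need >= n_folds={n_folds}")
    if counts.min() < 10:
        raise ValueError("need at least 10 samples per class for the CV protocol")
    weights = compute_class_weights(y)
    ss = np.random.SeedSequence(seed)
    repeat_seeds = [int(s.generate_state(1)[0] % (2**31 - 1)) for s in ss.spawn(n_repeats)]
    aucs = np.zeros((n_repeats, n_folds))
    assignments = []
    all_splits = []
    for r in range(n_repeats):
        rseed = repeat_seeds[r]
        skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=rseed)
        fold_of = np.full(n, -1, dtype=int)
        repeat_splits = []
        for f, (rest_idx, test_idx) in enumerate(skf.split(x, y)):
            fold_of[test_idx] = f
            tr_idx, val_idx = train_test_split(
                rest_idx, test_size=0.2, stratify=y[rest_idx], random_state=rseed + f
            )
            repeat_splits.append((np.array(tr_idx), np.array(val_idx), np.array(test_idx)))
            net_rng = np.random.default_rng(np.random.SeedSequence((seed, r, f, 1)))
            train_rng = np.random.default_rng(np.random.SeedSequence((seed, r, f, 2)))
            net = build_cnn(x.shape[1:3], config, rng=net_rng)
            train_model(
                net,
                x[tr_idx], y[tr_idx],
                x[val_idx], y[val_idx],
                class_weights=weights,
                config=config,
                age_train=None if age is None else age[tr_idx],
                age_val=None if age is None else age[val_idx],
                rng=train_rng,
            )
            proba = net.predict_proba(x[test_idx], age=None if age is None or not config.use_age else age[test_idx])
            aucs[r, f] = evaluate_auc(proba[:, 1], y[test_idx])
        assignments.append(fold_of)
        all_splits.append(repeat_splits)
    return CVResults(aucs=aucs, fold_assignments=assignments, splits=all_splits,
                     config=config, n_repeats=n_repeats, n_folds=n_folds, seed=seed)


# --------------------------------------------------------------------------- #
# Model / Results objects


class PathCNNClassifier:
    """Long-term-survival classifier on pathway images.

    Parameters
    ----------
    images : PathwayImageSet
        Normalized pathway images, sample order matching ``labels``.
    labels : LabelSet
        LTS / non-LTS labels; sample ids must equal the image sample ids.
    age : optional per-sample age vector (years), required when
        ``config.use_age`` is set.
    config : ModelConfig, optional.
    """

    def __init__(self, images: PathwayImageSet, labels: LabelSet,
                 age: Optional[np.ndarray] = None, config: Optional[ModelConfig] = None):
        if list(images.sample_ids) != list(labels.sample_ids):
            raise ValueError("image and label sample ids are not aligned")
        self.images = images
        self.labels = labels
        self.age = None if age is None else np.asarray(age, dtype=float)
        self.config = config or ModelConfig()
        if self.config.use_age and self.age is None:
            raise ValueError("config.use_age=True but no age vector given")

    def fit(self, seed: Optional[int] = None) -> "PathCNNResults":
        """Train one network on the full cohort (no held-out validation), as
        used for the Grad-CAM interpretation stage."""
        seed = self.config.seed if seed is None else seed
        x = self.images.images
        y = self.labels.y
        net = build_cnn(x.shape[1:3], self.config, rng=np.random.default_rng(np.random.SeedSequence((seed, 0))))
        history = train_model(
            net, x, y, None, None,
            class_weights=compute_class_weights(y),
            config=self.config,
            age_train=self.age,
            rng=np.random.default_rng(np.random.SeedSequence((seed, 1))),
        )
        return PathCNNResults(model=self, net=net, history=history, seed=seed)

    def fit_cv(self, n_repeats: int = 30, n_folds: int = 5, seed: int = 0) -> CVResults:
        """Run the repeated stratified cross-validation protocol."""
        return repeated_cv(
            self.images, self.labels, age=self.age,
            n_repeats=n_repeats, n_folds=n_folds, config=self.config, seed=seed,
        )


@dataclass
class PathCNNResults:
    """A trained full-cohort classifier plus its training history."""

    model: PathCNNClassifier
    net: PathCNNNet
    history: TrainHistory
    seed: int

    def predict_proba(self, images: Optional[np.ndarray] = None,
                      age: Optional[np.ndarray] = None) -> np.ndarray:
        x = self.model.images.images if images is None else images
        a = self.model.age if images is None else age
        return self.net.predict_proba(x, age=a if self.net.use_age else None)

    def training_auc(self) -> float:
        return evaluate_auc(self.predict_proba()[:, 1], self.model.labels.y)

    def interpret(self, alpha: float = 0.001):
        """Grad-CAM difference maps, pixel-wise rank tests and hot spots on
        the training cohort (see :mod:`pathcnn.interpret`)."""
        from .interpret import interpret_model

        return interpret_model(self.net, self.model.images, self.model.labels, alpha=alpha)

    def summary(self) -> str:
        counts = self.model.labels.counts()
        lines = [
            "PathCNN full-cohort classifier",
            f"  samples          : {len(self.model.labels.sample_ids)} "
            f"(LTS {counts[LTS]}, non-LTS {counts[NON_LTS]})",
            f"  image geometry   : {self.model.images.shape[1]} x {self.model.images.shape[2]}",
            f"  age covariate    : {'yes' if self.net.use_age else 'no'}",
            f"  epochs           : {self.model.config.epochs}",
            f"  final train loss : {self.history.train_loss[-1]:.4f}",
            f"  training AUC     : {self.training_auc():.3f}",
            "  architecture:",
        ]
        lines += ["    " + row for row in self.net.layer_summary()]
        return "\n".join(lines)
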