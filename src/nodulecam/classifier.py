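"""Residual CNN nodule classifier: focal loss, training recipe, evaluation.

The core object is :class:`NoduleCNNClassifier`, a scikit-learn style
estimator (``fit`` / ``predict_proba`` / ``get_params``) wrapping the numpy
residual network in :mod:`nodulecam.nn`.  Training minimises the focal loss

    FL(p_t) = -alpha_t (1 - p_t)^gamma log(p_t)

with p_t the predicted probability of the true class, which down-weights
easy examples and counteracts the benign-heavy class imbalance.  The
positive class is *malignant* throughout (TP = correctly flagged malignant),
the clinical convention.

Module-level functions (``focal_loss``, ``stratified_split``,
``compute_metrics``, ``roc_auc``, ``train``, ``repeat_experiment``) are thin
wrappers that keep a functional surface over the estimator.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
from scipy import ndimage
from skimage.transform import resize as _sk_resize
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.metrics import roc_auc_score, roc_curve
from sklearn.utils.validation import check_is_fitted

from . import nn
from .synthetic import BENIGN, MALIGNANT, DatasetManifest, LabeledImage

#: class order: index 0 = benign (negative), index 1 = malignant (positive)
CLASS_ORDER = (BENIGN, MALIGNANT)
EPS_PROB = 1e-7  # probability clamp inside the focal loss


# --------------------------------------------------------------------------
# configs
# --------------------------------------------------------------------------
@dataclass
class FocalLossParams:
    alpha: float = 0.25  # weight on the positive (malignant) class
    gamma: float = 2.0

    def __post_init__(self):
        if not (0.0 <= self.alpha <= 1.0):
            raise ValueError("alpha must lie in [0, 1]")
        if self.gamma < 0:
            raise ValueError("gamma must be >= 0")


@dataclass
class BackboneConfig:
    """Architecture description.

    ``resnet18``: 7×7/2 stem (64ch) + 3×3/2 max pool + 4 stages of two basic
    blocks at widths (64, 128, 256, 512); final feature maps are 7×7 for a
    224×224 input.  ``tiny``: same topology in miniature — 3×3/2 stem +
    pool + one block per stage at widths (16, 32), with the last stage kept
    at stride 1 so the feature maps stay at 1/8 resolution (28×28 at 224),
    fine enough for saliency-shape analysis.
    """

    variant: str = "tiny"
    in_channels: int = 1
    num_classes: int = 2

    def build_kwargs(self) -> dict:
        if self.variant == "resnet18":
            return dict(
                stem_channels=64, stem_kernel=7, stem_stride=2, stem_pool=3,
                stage_channels=(64, 128, 256, 512),
                blocks_per_stage=(2, 2, 2, 2),
                stage_strides=(1, 2, 2, 2),
            )
        if self.variant == "tiny":
            return dict(
                stem_channels=8, stem_kernel=3, stem_stride=2, stem_pool=2,
                stage_channels=(16, 32),
                blocks_per_stage=(1, 1),
                stage_strides=(2, 1),
            )
        if self.variant == "tiny_hr":
            # high-resolution tail: feature maps at 1/4 input resolution,
            # twice the saliency detail of "tiny" at ~2x the compute
            return dict(
                stem_channels=8, stem_kernel=3, stem_stride=2, stem_pool=2,
                stage_channels=(16, 32),
                blocks_per_stage=(1, 1),
                stage_strides=(1, 1),
            )
        raise ValueError(f"unknown backbone variant {self.variant!r}")


@dataclass
class TrainConfig:
    learning_rate: float = 1e-4
    epochs: int = 10
    batch_size: int = 16
    input_size: int = 224
    augment: bool = True
    rotation_deg: float = 15.0
    normalize_mean: float = 0.5
    normalize_std: float = 0.25
    pretrained: str | None = None  # optional checkpoint path
    seed: int = 0

    def __post_init__(self):
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be > 0")


@dataclass
class ConfusionTable:
    TP: int
    TN: int
    FP: int
    FN: int

    def __post_init__(self):
        if min(self.TP, self.TN, self.FP, self.FN) < 0:
            raise ValueError("confusion counts must be non-negative")


@dataclass
class Split:
    train_idx: np.ndarray
    test_idx: np.ndarray
    fraction: float
    train_counts: dict[str, int]
    test_counts: dict[str, int]


@dataclass
class EvalReport:
    per_repeat: list[dict] = field(default_factory=list)

    @property
    def means(self) -> dict[str, float]:
        keys = ("accuracy", "recall", "precision", "f1", "auc")
        out = {}
        for k in keys:
            vals = [r[k] for r in self.per_repeat if not math.isnan(r[k])]
            out[k] = float(np.mean(vals)) if vals else float("nan")
        return out

    def to_dict(self) -> dict:
        return {"per_repeat": self.per_repeat, "means": self.means}


# --------------------------------------------------------------------------
# focal loss
# --------------------------------------------------------------------------
def focal_loss(p, y, params: FocalLossParams = FocalLossParams(), reduce: bool = True):
    """Focal loss from probabilities of the positive class.

    ``p`` is P(class=1); ``y`` in {0,1}.  p_t = p if y=1 else 1-p;
    alpha_t = alpha if y=1 else 1-alpha; loss = -alpha_t (1-p_t)^gamma log p_t.
    """
    p = np.asarray(p, dtype=float)
    y = np.asarray(y)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("probabilities must lie in [0, 1]")
    pt = np.where(y == 1, p, 1.0 - p)
    pt = np.clip(pt, EPS_PROB, 1.0 - EPS_PROB)
    at = np.where(y == 1, params.alpha, 1.0 - params.alpha)
    loss = -at * (1.0 - pt) ** params.gamma * np.log(pt)
    return float(np.mean(loss)) if reduce else loss


def _focal_loss_and_grad_logits(logits, y, params: FocalLossParams):
    """Mean focal loss and its gradient w.r.t. the two-class logits."""
    z = logits - logits.max(axis=1, keepdims=True)
    ez = np.exp(z)
    p = ez / ez.sum(axis=1, keepdims=True)
    p1 = p[:, 1]
    sign = np.where(y == 1, 1.0, -1.0)
    pt = np.where(y == 1, p1, 1.0 - p1)
    pt = np.clip(pt, EPS_PROB, 1.0 - EPS_PROB)
    at = np.where(y == 1, params.alpha, 1.0 - params.alpha)
    one_m = 1.0 - pt
    loss = float(np.mean(-at * one_m**params.gamma * np.log(pt)))
    # dL/dpt; pt is clipped so both pt and 1-pt stay >= EPS_PROB
    g = params.gamma
    if g == 0:
        dpt = -at / pt
    else:
        dpt = at * (g * one_m ** (g - 1.0) * np.log(pt) - one_m**g / pt)
    # pt -> p1 -> logits:  dp1/dz1 = p1 p0, dz0 = -dz1
    dz1 = dpt * sign * (p[:, 1] * p[:, 0])
    dlogits = np.stack([-dz1, dz1], axis=1) / len(y)
    return loss, dlogits.astype(logits.dtype)


# --------------------------------------------------------------------------
# splitting and metrics
# --------------------------------------------------------------------------
def stratified_split(manifest: DatasetManifest | list[str], train_fraction: float = 0.7,
                     seed: int = 0) -> Split:
    """Per-class split: train count = ceil(train_fraction * n_class), shuffled
    within class by ``seed``.  415/93 at 0.7 gives train 291+66=357,
    test 124+27=151."""
    labels = (
        [rec[1] for rec in manifest.records]
        if isinstance(manifest, DatasetManifest)
        else [str(l) for l in manifest]
    )
    labels_arr = np.asarray(labels)
    classes = sorted(set(labels))
    if len(classes) < 2:
        raise ValueError("stratification needs at least one sample of each class")
    rng = np.random.default_rng(seed)
    train_idx, test_idx = [], []
    train_counts, test_counts = {}, {}
    for c in classes:
        idx = np.flatnonzero(labels_arr == c)
        rng.shuffle(idx)
        n_train = math.ceil(train_fraction * len(idx))
        train_idx.extend(idx[:n_train])
        test_idx.extend(idx[n_train:])
        train_counts[c] = n_train
        test_counts[c] = len(idx) - n_train
    if not test_idx:
        warnings.warn("train_fraction leaves an empty test set", stacklevel=2)
    return Split(
        train_idx=np.sort(np.array(train_idx, dtype=int)),
        test_idx=np.sort(np.array(test_idx, dtype=int)),
        fraction=train_fraction,
        train_counts=train_counts,
        test_counts=test_counts,
    )


def compute_metrics(table: ConfusionTable) -> dict[str, float]:
    """Accuracy, recall, precision, F1 from a confusion table.  Undefined
    ratios (zero denominator) are reported as NaN with a warning, not 0."""
    tp, tn, fp, fn = table.TP, table.TN, table.FP, table.FN
    total = tp + tn + fp + fn
    if total == 0:
        raise ValueError("empty confusion table")
    acc = (tp + tn) / total
    if tp + fn == 0:
        warnings.warn("recall undefined: no positive ground truth", stacklevel=2)
        rec = float("nan")
    else:
        rec = tp / (tp + fn)
    if tp + fp == 0:
        warnings.warn("precision undefined: no positive predictions", stacklevel=2)
        prec = float("nan")
    else:
        prec = tp / (tp + fp)
    if math.isnan(rec) or math.isnan(prec) or (prec + rec) == 0:
        f1 = float("nan") if (math.isnan(rec) or math.isnan(prec)) else 0.0
    else:
        f1 = 2 * prec * rec / (prec + rec)
    return {"accuracy": acc, "recall": rec, "precision": prec, "f1": f1}


def confusion_from_predictions(y_true, y_pred) -> ConfusionTable:
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    return ConfusionTable(
        TP=int(np.sum((y_true == 1) & (y_pred == 1))),
        TN=int(np.sum((y_true == 0) & (y_pred == 0))),
        FP=int(np.sum((y_true == 0) & (y_pred == 1))),
        FN=int(np.sum((y_true == 1) & (y_pred == 0))),
    )


def roc_auc(scores, labels):
    """AUC (Mann–Whitney statistic, ties ½) plus the ROC curve points."""
    labels = np.asarray(labels)
    if len(set(labels.tolist())) < 2:
        raise ValueError("both classes must be present to compute ROC/AUC")
    auc = float(roc_auc_score(labels, scores))
    fpr, tpr, thresholds = roc_curve(labels, scores)
    return auc, np.column_stack([thresholds, fpr, tpr])


# --------------------------------------------------------------------------
# preprocessing
# --------------------------------------------------------------------------
def preprocess(
    image,
    train_mode: bool = False,
    augment_seed: int | None = None,
    input_size: int = 224,
    rotation_deg: float = 15.0,
    normalize_mean: float = 0.5,
    normalize_std: float = 0.25,
) -> np.ndarray:
    """Resize → (optional flip/rotate augmentation) → normalize → (C,H,W)."""
    px = image.pixels if isinstance(image, LabeledImage) else np.asarray(image, dtype=float)
    if px.ndim == 3:  # RGB → luminance
        px = px.mean(axis=2)
    if px.shape != (input_size, input_size):
        px = _sk_resize(px, (input_size, input_size), order=1, anti_aliasing=True)
    if train_mode:
        rng = np.random.default_rng(augment_seed)
        if rng.random() < 0.5:
            px = px[:, ::-1]
        if rng.random() < 0.5:
            px = px[::-1, :]
        angle = rng.uniform(-rotation_deg, rotation_deg)
        if abs(angle) > 1e-9:
            px = ndimage.rotate(px, angle, reshape=False, order=1, mode="reflect")
    out = (px - normalize_mean) / normalize_std
    return np.ascontiguousarray(out[None].astype(np.float32))


def _coerce_X(X, input_size, mean, std):
    """Stack raw images/arrays into an (n, 1, S, S) float tensor."""
    tensors = [
        preprocess(img, train_mode=False, input_size=input_size,
                   normalize_mean=mean, normalize_std=std)
        for img in X
    ]
    return np.stack(tensors)


def _coerce_y(y) -> np.ndarray:
    y = np.asarray(y)
    if y.dtype.kind in "UO":
        return np.asarray([CLASS_ORDER.index(str(v)) for v in y], dtype=int)
    return y.astype(int)


# --------------------------------------------------------------------------
# estimator
# --------------------------------------------------------------------------
class NoduleCNNClassifier(BaseEstimator, ClassifierMixin):
    """Residual CNN for benign/malignant nodule images, trained with focal
    loss and Adam.

    Parameters mirror the training recipe: images are resized to
    ``input_size``, optionally augmented (horizontal/vertical flips, ±15°
    rotation), normalized, and fed to a residual backbone chosen by
    ``variant``.  ``fit`` accepts ``X`` as an (n, H, W) array, a list of 2-D
    arrays, or a list of :class:`~nodulecam.synthetic.LabeledImage`; ``y``
    as {0,1} or {"benign","malignant"} (malignant = positive class 1).

    Fitted attributes: ``model_`` (the numpy network), ``loss_trace_``
    (mean focal loss per epoch), ``classes_``.
    """

    def __init__(
        self,
        variant: str = "tiny",
        learning_rate: float = 1e-4,
        epochs: int = 10,
        batch_size: int = 16,
        input_size: int = 224,
        alpha: float = 0.25,
        gamma: float = 2.0,
        augment: bool = True,
        rotation_deg: float = 15.0,
        normalize_mean: float = 0.5,
        normalize_std: float = 0.25,
        pretrained: str | None = None,
        lr_decay: bool = True,
        tta: bool = False,
        random_state: int = 0,
    ):
        self.variant = variant
        self.learning_rate = learning_rate
        self.epochs = epochs
        self.batch_size = batch_size
        self.input_size = input_size
        self.alpha = alpha
        self.gamma = gamma
        self.augment = augment
        self.rotation_deg = rotation_deg
        self.normalize_mean = normalize_mean
        self.normalize_std = normalize_std
        self.pretrained = pretrained
        self.lr_decay = lr_decay
        self.tta = tta
        self.random_state = random_state

    # -- construction -----------------------------------------------------
    def _build(self) -> nn.ResidualCNN:
        cfg = BackboneConfig(variant=self.variant, in_channels=1, num_classes=2)
        rng = np.random.default_rng(self.random_state)
        return nn.ResidualCNN(in_channels=1, num_classes=2, rng=rng, **cfg.build_kwargs())

    def fit(self, X, y):
        y_int = _coerce_y(y)
        if len(set(y_int.tolist())) < 2:
            raise ValueError("training set must contain both classes")
        params = FocalLossParams(alpha=self.alpha, gamma=self.gamma)
        model = self._build()
        if self.pretrained:
            state = np.load(self.pretrained)
            model.load_state_dict({k: state[k] for k in state.files})
        rng = np.random.default_rng(self.random_state + 1)
        # preprocess once without augmentation; augmentation is re-applied
        # per epoch on the raw images when enabled
        raw = list(X)
        base = _coerce_X(raw, self.input_size, self.normalize_mean, self.normalize_std)
        n = len(raw)
        opt = nn.Adam(model.params(), lr=self.learning_rate)
        self.loss_trace_ = []
        decay_at = {int(0.6 * self.epochs), int(0.85 * self.epochs)}
        for epoch in range(self.epochs):
            if self.lr_decay and epoch in decay_at and epoch > 0:
                opt.lr /= 3.0  # step decay stabilises the late phase
            order = rng.permutation(n)
            losses = []
            for start in range(0, n, self.batch_size):
                idx = order[start : start + self.batch_size]
                if self.augment:
                    xb = np.stack([
                        preprocess(
                            raw[i], train_mode=True,
                            augment_seed=int(rng.integers(2**31 - 1)),
                            input_size=self.input_size,
                            rotation_deg=self.rotation_deg,
                            normalize_mean=self.normalize_mean,
                            normalize_std=self.normalize_std,
                        )
                        for i in idx
                    ])
                else:
                    xb = base[idx]
                yb = y_int[idx]
                logits = model.forward(xb, train=True)
                loss, dlogits = _focal_loss_and_grad_logits(logits, yb, params)
                if not np.isfinite(loss):
                    raise RuntimeError(
                        f"training diverged at epoch {epoch}: non-finite loss"
                    )
                opt.zero_grad()
                model.backward(dlogits)
                opt.step()
                losses.append(loss)
            self.loss_trace_.append(float(np.mean(losses)))
        if self.epochs > 0:
            model.recalibrate_bn(
                base[s : s + self.batch_size] for s in range(0, n, self.batch_size)
            )
        self.model_ = model
        self.classes_ = np.array([0, 1])
        self.n_features_in_ = self.input_size * self.input_size
        return self

    # -- inference --------------------------------------------------------
    def decision_logits(self, X, batch_size: int = 32) -> np.ndarray:
        check_is_fitted(self, "model_")
        xb = _coerce_X(list(X), self.input_size, self.normalize_mean, self.normalize_std)
        out = []
        for start in range(0, len(xb), batch_size):
            out.append(self.model_.forward(xb[start : start + batch_size], train=False))
        return np.concatenate(out)

    @staticmethod
    def _softmax(logits: np.ndarray) -> np.ndarray:
        z = logits - logits.max(axis=1, keepdims=True)
        ez = np.exp(z)
        return ez / ez.sum(axis=1, keepdims=True)

    def predict_proba(self, X) -> np.ndarray:
        X = list(X)
        if not self.tta:
            return self._softmax(self.decision_logits(X))
        # flip-averaged test-time augmentation: mean probability over the
        # four axis flips (the augmentation group used in training)
        raw = [np.asarray(x.pixels if isinstance(x, LabeledImage) else x, dtype=float)
               for x in X]
        acc = np.zeros((len(raw), 2))
        for fr, fc in ((1, 1), (1, -1), (-1, 1), (-1, -1)):
            flipped = [a[::fr, ::fc] for a in raw]
            acc += self._softmax(self.decision_logits(flipped))
        return acc / 4.0

    def predict(self, X) -> np.ndarray:
        return self.predict_proba(X).argmax(axis=1)

    def evaluate(self, X, y) -> dict:
        """Confusion-table metrics + AUC on a labelled set."""
        y_int = _coerce_y(y)
        proba = self.predict_proba(X)[:, 1]
        pred = (proba >= 0.5).astype(int)
        metrics = compute_metrics(confusion_from_predictions(y_int, pred))
        auc, curve = roc_auc(proba, y_int)
        metrics["auc"] = auc
        metrics["roc_curve"] = curve
        return metrics

    def save(self, path) -> None:
        check_is_fitted(self, "model_")
        state = self.model_.state_dict()
        meta = {f"meta_{k}": np.asarray(v) for k, v in self.get_params().items()
                if v is not None and not isinstance(v, str)}
        meta["meta_variant_str"] = np.asarray(self.variant)
        np.savez(path, **state, **meta)

    @classmethod
    def load(cls, path, **overrides) -> "NoduleCNNClassifier":
        data = np.load(path, allow_pickle=False)
        kwargs = {}
        for k in data.files:
            if k.startswith("meta_") and k != "meta_variant_str":
                name = k[5:]
                v = data[k].item()
                kwargs[name] = v
        kwargs["variant"] = str(data["meta_variant_str"])
        kwargs.update(overrides)
        for int_key in ("epochs", "batch_size", "input_size", "random_state"):
            if int_key in kwargs:
                kwargs[int_key] = int(kwargs[int_key])
        est = cls(**kwargs)
        est.model_ = est._build()
        est.model_.load_state_dict({k: data[k] for k in data.files if not k.startswith("meta_")})
        est.classes_ = np.array([0, 1])
        est.loss_trace_ = []
        return est


# --------------------------------------------------------------------------
# functional wrappers
# --------------------------------------------------------------------------
def build_model(config: BackboneConfig, seed: int = 0) -> nn.ResidualCNN:
    """Construct the backbone; the returned model exposes ``feature_maps_``
    (final conv activations) and ``grad_features`` for Grad-CAM."""
    rng = np.random.default_rng(seed)
    return nn.ResidualCNN(
        in_channels=config.in_channels, num_classes=config.num_classes,
        rng=rng, **config.build_kwargs()
    )


def train(images: list, labels, config: TrainConfig, variant: str = "tiny",
          focal: FocalLossParams = FocalLossParams()) -> NoduleCNNClassifier:
    """Train an estimator from a TrainConfig (thin wrapper over ``fit``)."""
    est = NoduleCNNClassifier(
        variant=variant,
        learning_rate=config.learning_rate,
        epochs=config.epochs,
        batch_size=config.batch_size,
        input_size=config.input_size,
        alpha=focal.alpha,
        gamma=focal.gamma,
        augment=config.augment,
        rotation_deg=config.rotation_deg,
        normalize_mean=config.normalize_mean,
        normalize_std=config.normalize_std,
        pretrained=config.pretrained,
        random_state=config.seed,
    )
    est.fit(images, labels)
    return est


#: fixed prime offset between per-repeat seeds so any repeat reproduces alone
REPEAT_SEED_STRIDE = 9973


def repeat_experiment(
    images: list,
    labels,
    n_repeats: int = 10,
    train_fraction: float = 0.7,
    master_seed: int = 0,
    estimator: NoduleCNNClassifier | None = None,
    keep_models: bool = False,
):
    """Repeated random-split evaluation: ``n_repeats`` stratified 70/30
    splits with derived seeds, train + evaluate each, report per-repeat
    metrics and their means."""
    if n_repeats < 1:
        raise ValueError("n_repeats must be >= 1")
    labels = list(labels)
    base = estimator or NoduleCNNClassifier()
    report = EvalReport()
    models = []
    for rep in range(n_repeats):
        seed = (master_seed + rep * REPEAT_SEED_STRIDE) % (2**31 - 1)
        split = stratified_split(labels, train_fraction=train_fraction, seed=seed)
        est = clone_estimator(base, random_state=seed)
        X_train = [images[i] for i in split.train_idx]
        y_train = [labels[i] for i in split.train_idx]
        X_test = [images[i] for i in split.test_idx]
        y_test = [labels[i] for i in split.test_idx]
        try:
            est.fit(X_train, y_train)
            metrics = est.evaluate(X_test, y_test)
        except Exception as exc:  # annotate with the repeat index
            raise RuntimeError(f"repeat {rep} failed: {exc}") from exc
        row = {k: v for k, v in metrics.items() if k != "roc_curve"}
        row["repeat"] = rep
        row["seed"] = seed
        row["roc_curve"] = metrics["roc_curve"].tolist()
        report.per_repeat.append(row)
        if keep_models:
            models.append(est)
    return (report, models) if keep_models else report


def clone_estimator(est: NoduleCNNClassifier, **overrides) -> NoduleCNNClassifier:
    params = est.get_params()
    params.update(overrides)
    return NoduleCNNClassifier(**params)
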