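"""Gesture classifiers and joint-angle regressors.

Three classifier families (extra-trees, logistic regression, neural
network) and three regressor families (ridge, Laplacian kernel ridge,
neural network) operate on standardized lagged-RMS feature rows.  The
network is a fully connected stack — hidden layers 1000/500 for
classification, 4000/1000/500 for regression — with batch norm, ReLU and
dropout, trained with Adam under a one-cycle schedule; the classifier
uses label-smoothing cross-entropy and the regressor mean-squared error
with per-joint output truncation to training bounds.  Cross-sleeve
transfer maps any layout onto the 70-channel medium sleeve by grid
nearest-neighbor assignment; pretrained networks are fine-tuned in
session with a shorter schedule and a re-fit scaler.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from sklearn.ensemble import ExtraTreesClassifier
from sklearn.kernel_ridge import KernelRidge
from sklearn.linear_model import LogisticRegression, Ridge

from ._mlp import MLP, TrainingCurve
from .errors import ConfigurationError, FittingError
from .sigproc import FeatureMatrix, Scaler, apply_scaler, fit_scaler
from .simdata import SleeveLayout

log = logging.getLogger(__name__)

#: Frozen snapshot of the library hyperparameters we rely on, so "default
#: parameters" stays reproducible across library versions.  max_iter for
#: the logistic model is raised from the stock 100, which does not
#: converge on lagged-RMS features.
SKLEARN_DEFAULTS: dict[str, dict] = {
    "extra_trees": {"n_estimators": 100, "criterion": "gini", "max_features": "sqrt"},
    "logistic_regression": {"C": 1.0, "solver": "lbfgs", "max_iter": 1000},
    "ridge": {"alpha": 1.0},
    "laplacian_kernel_ridge": {"alpha": 1.0, "kernel": "laplacian", "gamma": None},
}


@dataclass(frozen=True)
class ClassifierSpec:
    kind: str = "nn"  # extra_trees | logistic_regression | nn
    hidden: tuple[int, ...] = (1000, 500)
    dropout: float = 0.20
    label_smoothing: float = 0.10  # smoothed target confidence 0.9
    lr_max: float = 1e-3
    epochs: int = 200
    finetune_epochs: int = 50
    batch_size: int = 64


@dataclass(frozen=True)
class RegressorSpec:
    kind: str = "nn"  # ridge | laplacian_kernel_ridge | nn
    hidden: tuple[int, ...] = (4000, 1000, 500)
    dropout: float = 0.40
    lr_max: float = 1e-3
    epochs: int = 200
    # larger batches than the classifier: the 4000-unit first hidden layer
    # makes per-step optimizer overhead dominate at small batches
    batch_size: int = 128


@dataclass
class FittedClassifier:
    """A trained classifier plus its class registry."""

    spec: ClassifierSpec
    classes_: np.ndarray
    _impl: object
    curves: list[TrainingCurve] = field(default_factory=list)

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        if isinstance(self._impl, MLP):
            return self._impl.predict_proba(x)
        return self._impl.predict_proba(x)

    def predict(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        if isinstance(self._impl, MLP):
            return self.classes_[self._impl.predict(x)]
        return self._impl.predict(x)


@dataclass
class FittedRegressor:
    spec: RegressorSpec
    target_names: tuple[str, ...]
    _impl: object
    train_lo: np.ndarray | None = None
    train_hi: np.ndarray | None = None
    curves: list[TrainingCurve] = field(default_factory=list)

    def predict(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        out = self._impl.predict(x)
        if self.train_lo is not None:  # nn truncation handled inside MLP too
            out = np.clip(out, self.train_lo, self.train_hi)
        return out


def train_classifier(
    spec: ClassifierSpec, x: np.ndarray, labels: np.ndarray, seed: int
) -> FittedClassifier:
    """Fit one classifier; NN training is deterministic given ``seed``."""
    x = np.asarray(x, dtype=float)
    labels = np.asarray(labels)
    if x.shape[0] != labels.shape[0]:
        raise FittingError("feature and label row counts differ")
    classes = np.unique(labels)
    if len(classes) < 2:
        raise FittingError("need at least 2 classes to train a classifier")
    if spec.kind == "extra_trees":
        impl = ExtraTreesClassifier(random_state=seed, **SKLEARN_DEFAULTS["extra_trees"])
        impl.fit(x, labels)
        return FittedClassifier(spec, impl.classes_, impl)
    if spec.kind == "logistic_regression":
        impl = LogisticRegression(**SKLEARN_DEFAULTS["logistic_regression"])
        impl.fit(x, labels)
        return FittedClassifier(spec, impl.classes_, impl)
    if spec.kind == "nn":
        y = np.searchsorted(classes, labels)
        net = MLP(
            n_in=x.shape[1],
            hidden=spec.hidden,
            n_out=len(classes),
            dropout=spec.dropout,
            seed=seed,
            task="classify",
            label_smoothing=spec.label_smoothing,
        )
        curve = net.fit(x, y, epochs=spec.epochs, lr_max=spec.lr_max,
                        batch_size=spec.batch_size)
        return FittedClassifier(spec, classes, net, curves=[curve])
    raise ConfigurationError(f"unknown classifier kind {spec.kind!r}")


def predict_proba(model: FittedClassifier, x: np.ndarray) -> np.ndarray:
    """Per-bin class probability rows (order follows ``model.classes_``)."""
    p = model.predict_proba(x)
    if p.shape[1] != len(model.classes_):
        raise ConfigurationError("probability width does not match class registry")
    return p


def train_regressor(
    spec: RegressorSpec,
    x: np.ndarray,
    targets: np.ndarray,
    target_names: tuple[str, ...],
    seed: int,
) -> FittedRegressor:
    """Fit one multi-output regressor on joint-angle targets (degrees)."""
    x = np.asarray(x, dtype=float)
    targets = np.asarray(targets, dtype=float)
    if x.shape[0] != targets.shape[0]:
        raise FittingError("feature and target row counts differ")
    if spec.kind == "ridge":
        impl = Ridge(**SKLEARN_DEFAULTS["ridge"])
        impl.fit(x, targets)
        return FittedRegressor(spec, target_names, impl)
    if spec.kind == "laplacian_kernel_ridge":
        impl = KernelRidge(**SKLEARN_DEFAULTS["laplacian_kernel_ridge"])
        impl.fit(x, targets)
        return FittedRegressor(spec, target_names, impl)
    if spec.kind == "nn":
        net = MLP(
            n_in=x.shape[1],
            hidden=spec.hidden,
            n_out=targets.shape[1],
            dropout=spec.dropout,
            seed=seed,
            task="regress",
        )
        curve = net.fit(x, targets, epochs=spec.epochs, lr_max=spec.lr_max,
                        batch_size=spec.batch_size)
        return FittedRegressor(
            spec, target_names, net,
            train_lo=targets.min(axis=0), train_hi=targets.max(axis=0),
            curves=[curve],
        )
    raise ConfigurationError(f"unknown regressor kind {spec.kind!r}")


# ---------------------------------------------------------------------------
# cross-sleeve channel mapping
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ChannelMap:
    """Per-target-channel source index mapping any layout to a target layout."""

    source_tag: str
    target_tag: str
    assignment: np.ndarray  # len = target n_channels

    @property
    def n_duplicated(self) -> int:
        uniq, counts = np.unique(self.assignment, return_counts=True)
        return int((counts - 1).sum())


def build_channel_map(
    source: SleeveLayout, target: SleeveLayout | None = None
) -> ChannelMap:
    """Nearest-neighbor assignment on normalized grid coordinates.

    Each target channel takes its spatially nearest source channel (ties
    broken toward the lower source index).  Mapping a smaller sleeve onto
    a larger target necessarily duplicates sources.
    """
    target = target or SleeveLayout.from_size("medium")
    src = source.normalized_coords
    tgt = target.normalized_coords
    d2 = ((tgt[:, None, :] - src[None, :, :]) ** 2).sum(axis=2)
    assignment = d2.argmin(axis=1)  # argmin returns the lowest index on ties
    return ChannelMap(source.size_tag, target.size_tag, assignment)


def map_channels(
    rms: np.ndarray, source: SleeveLayout, target: SleeveLayout | None = None
) -> np.ndarray:
    """Re-express a bins x channels RMS matrix on the target layout."""
    rms = np.asarray(rms)
    if rms.shape[1] != source.n_channels:
        raise ConfigurationError(
            f"RMS has {rms.shape[1]} channels, source layout {source.n_channels}"
        )
    cmap = build_channel_map(source, target)
    return rms[:, cmap.assignment]


# ---------------------------------------------------------------------------
# pretraining / fine-tuning
# ---------------------------------------------------------------------------


@dataclass
class PretrainedBundle:
    model: FittedClassifier
    scaler: Scaler
    pretrain_curve: TrainingCurve
    finetune_curve: TrainingCurve


def _scale_rows(values: np.ndarray, scaler: Scaler) -> np.ndarray:
    fm = FeatureMatrix(
        values=values,
        bin_times_s=np.arange(values.shape[0], dtype=float),
        n_channels=values.shape[1],
        n_lags=1,
    )
    return apply_scaler(fm, scaler).values


def fit_row_scaler(values: np.ndarray) -> Scaler:
    fm = FeatureMatrix(
        values=values,
        bin_times_s=np.arange(values.shape[0], dtype=float),
        n_channels=values.shape[1],
        n_lags=1,
    )
    return fit_scaler(fm, np.ones(values.shape[0], dtype=bool))


def pretrain_finetune(
    spec: ClassifierSpec,
    pretrain_sets: list[tuple[np.ndarray, np.ndarray]],
    insession: tuple[np.ndarray, np.ndarray],
    seed: int,
) -> PretrainedBundle:
    """Pretrain an NN on pooled historical sessions, then fine-tune in session.

    All feature sets must already be on a common channel layout (see
    :func:`map_channels`) and unstandardized: standardization is fit on
    the pooled pretraining rows for pretraining and re-fit on the
    in-session rows before fine-tuning.  If the in-session class set
    differs from the pretraining one, the output head is reinitialized
    (logged); otherwise all layers fine-tune for ``spec.finetune_epochs``.
    """
    if spec.kind != "nn":
        raise ConfigurationError("pretraining is defined for the nn classifier")
    xs = [np.asarray(x, dtype=float) for x, _ in pretrain_sets]
    ys = [np.asarray(y) for _, y in pretrain_sets]
    x_pre = np.vstack(xs)
    y_pre = np.concatenate(ys)
    pre_classes = np.unique(y_pre)
    pre_scaler = fit_row_scaler(x_pre)

    net = MLP(
        n_in=x_pre.shape[1],
        hidden=spec.hidden,
        n_out=len(pre_classes),
        dropout=spec.dropout,
        seed=seed,
        task="classify",
        label_smoothing=spec.label_smoothing,
    )
    pre_curve = net.fit(
        _scale_rows(x_pre, pre_scaler),
        np.searchsorted(pre_classes, y_pre),
        epochs=spec.epochs,
        lr_max=spec.lr_max,
        batch_size=spec.batch_size,
    )

    x_in, y_in = insession
    x_in = np.asarray(x_in, dtype=float)
    y_in = np.asarray(y_in)
    in_classes = np.unique(y_in)
    if list(in_classes) != list(pre_classes):
        log.warning("class-set mismatch between stages; reinitializing output head")
        net.reinit_head(len(in_classes))
    in_scaler = fit_row_scaler(x_in)
    fine_curve = net.fit(
        _scale_rows(x_in, in_scaler),
        np.searchsorted(in_classes, y_in),
        epochs=spec.finetune_epochs,
        lr_max=spec.lr_max,
        batch_size=spec.batch_size,
    )
    model = FittedClassifier(spec, in_classes, net, curves=[pre_curve, fine_curve])
    return PretrainedBundle(model, in_scaler, pre_curve, fine_curve)
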