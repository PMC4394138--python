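"""Classifier back end: normalization, SVM, probabilities, decisions.

Features are normalized anisotropically — per-feature mean subtraction and
division by the training-set standard deviation — and the frozen normalizing
template is applied unchanged to test data. A Gaussian-kernel SVM is trained
on per-channel epochs; its decision values are mapped to probability-like
scores by a sigmoid (Platt) calibration fitted on held-out folds. At test
time the classifier runs separately on each channel (neonatal seizures can be
confined to a single channel), each channel's probability trace is smoothed
by a centered moving average, and the per-timepoint maximum across channels
forms the fused trace. Comparing the fused trace with a threshold yields
binary decisions, and each detected interval is extended on both sides by a
"collar" to compensate the smoothing delay and uncertain seizure boundaries.

Defaults: smoothing window 15 epochs (60 s), threshold 0.5 (the value fixed
for clinical use), collar 32 s. Window and collar lengths are configurable
package defaults, not clinically fixed values.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import joblib
import numpy as np
from sklearn.calibration import CalibratedClassifierCV
from sklearn.model_selection import GroupKFold
from sklearn.svm import SVC

from .core import AnnotationTrack, merge_intervals
from .features import FeatureMatrix

__all__ = [
    "NormalizerTemplate",
    "SeizureModel",
    "ProbabilityTrace",
    "DecisionTrace",
    "fit_normalizer",
    "train_model",
    "predict_probabilities",
    "binarize",
    "moving_average",
    "grid_search_svm",
    "save_model",
    "load_model",
]

DEFAULT_SMOOTHING_EPOCHS = 15
DEFAULT_THRESHOLD = 0.5
DEFAULT_COLLAR_S = 32.0
EPOCH_HOP_S = 4.0
EPOCH_LENGTH_S = 8.0


@dataclass
class NormalizerTemplate:
    """Per-feature mean/std estimated on training data and frozen."""

    mean: np.ndarray
    std: np.ndarray
    zero_variance: np.ndarray  # flags for features whose std was clamped to 1

    def transform(self, X: np.ndarray) -> np.ndarray:
        Z = (X - self.mean) / self.std
        Z[:, self.zero_variance] = 0.0  # flagged features carry no information
        return Z


@dataclass
class SeizureModel:
    """Trained SVM with sigmoid calibration, plus the frozen normalizer and
    the fingerprint of the feature registry it was trained on."""

    svc: object  # calibrated SVC exposing predict_proba
    normalizer: NormalizerTemplate
    registry_fingerprint: str
    config: dict = field(default_factory=dict)


@dataclass
class ProbabilityTrace:
    """Smoothed per-channel and fused (max across channels) probabilities.

    ``times_s`` timestamps each epoch at its start + 4 s (hop-aligned); the
    epoch's binary decision covers ``[time, time + 4)``.
    """

    per_channel: np.ndarray  # channels x epochs, in [0, 1]
    fused: np.ndarray  # epochs, in [0, 1]
    times_s: np.ndarray
    channel_labels: list[str] = field(default_factory=list)
    smoothing_window_epochs: int = DEFAULT_SMOOTHING_EPOCHS
    duration_s: float | None = None

    @property
    def record_bounds_s(self) -> tuple[float, float]:
        start = float(self.times_s[0] - EPOCH_HOP_S)
        end = (
            float(self.duration_s)
            if self.duration_s is not None
            else float(self.times_s[-1] + EPOCH_HOP_S)
        )
        return start, end


@dataclass
class DecisionTrace:
    """Thresholded fused trace with collar-extended detected events."""

    binary: np.ndarray  # per epoch, {0, 1} (pre-collar)
    threshold: float
    collar_s: float
    events: AnnotationTrack
    times_s: np.ndarray
    duration_s: float


def fit_normalizer(X: np.ndarray) -> NormalizerTemplate:
    """Estimate the anisotropic normalizing template on training vectors.

    Zero-variance features are flagged and their std clamped to 1 (the
    transformed column is then all zeros) with a warning.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("need a 2-D matrix with at least 2 training vectors")
    mean = X.mean(axis=0)
    std = X.std(axis=0)
    # constant columns can carry ~1e-16 float residue; treat those as zero-variance
    zero = std <= 1e-12 * np.maximum(1.0, np.abs(mean))
    if zero.any():
        warnings.warn(
            f"{int(zero.sum())} zero-variance feature(s); std clamped to 1",
            stacklevel=2,
        )
        std = np.where(zero, 1.0, std)
    return NormalizerTemplate(mean=mean, std=std, zero_variance=zero)


def _flatten_training(feats: FeatureMatrix, labels: np.ndarray):
    """Stack (epoch, channel) pairs into rows; broadcast per-epoch labels."""
    E, C, F = feats.values.shape
    X = feats.values.transpose(1, 0, 2).reshape(C * E, F)
    y = np.asarray(labels)
    if y.shape == (E,):
        y = np.tile(y, C)
    elif y.shape == (C, E):
        y = y.reshape(C * E)
    else:
        raise ValueError(f"labels shape {y.shape} matches neither (epochs,) nor (channels, epochs)")
    return X, y.astype(int)


def train_model(
    feats: FeatureMatrix,
    labels: np.ndarray,
    C: float = 1.0,
    gamma="scale",
    seed: int = 0,
    class_weight="balanced",
    max_train_vectors: int | None = None,
) -> SeizureModel:
    """Train the per-channel seizure classifier.

    ``labels`` is either per-epoch (broadcast to all channels) or a
    (channels, epochs) boolean/int array. Both classes must be present.
    Deterministic given ``seed``. ``max_train_vectors`` optionally subsamples
    the training set (stratified by class) to bound fit time.
    """
    X, y = _flatten_training(feats, labels)
    if np.unique(y).size < 2:
        raise ValueError("training labels contain a single class")
    rng = np.random.default_rng(seed)
    if max_train_vectors is not None and X.shape[0] > max_train_vectors:
        keep = []
        for cls in np.unique(y):
            idx = np.nonzero(y == cls)[0]
            n_keep = max(1, int(round(max_train_vectors * idx.size / y.size)))
            keep.append(rng.choice(idx, size=min(n_keep, idx.size), replace=False))
        keep = np.sort(np.concatenate(keep))
        X, y = X[keep], y[keep]

    norm = fit_normalizer(X)
    base = SVC(
        C=C,
        gamma=gamma,
        kernel="rbf",
        class_weight=class_weight,
        random_state=int(seed),
        cache_size=500,
    )
    # Platt sigmoid fitted on internal held-out folds (not training scores)
    svc = CalibratedClassifierCV(base, method="sigmoid", cv=5, ensemble=False)
    svc.fit(norm.transform(X), y)
    return SeizureModel(
        svc=svc,
        normalizer=norm,
        registry_fingerprint=feats.registry_fingerprint,
        config={"C": C, "gamma": gamma, "seed": int(seed), "class_weight": str(class_weight)},
    )


def moving_average(x: np.ndarray, window: int) -> np.ndarray:
    """Centered moving average with shrinking windows at the edges.

    ``window`` = 1 is the identity; a constant input is a fixed point.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    x = np.asarray(x, dtype=float)
    if window == 1:
        return x.copy()
    n = x.size
    idx = np.arange(n) - window // 2
    lo = np.maximum(0, idx)
    hi = np.minimum(n, idx + window)
    csum = np.concatenate(([0.0], np.cumsum(x)))
    return (csum[hi] - csum[lo]) / (hi - lo)


def predict_probabilities(
    model: SeizureModel,
    feats: FeatureMatrix,
    smoothing_window_epochs: int = DEFAULT_SMOOTHING_EPOCHS,
) -> ProbabilityTrace:
    """Per-channel sigmoid probabilities, smoothed, then max-fused."""
    if feats.registry_fingerprint != model.registry_fingerprint:
        raise ValueError(
            "feature registry fingerprint does not match the trained model"
        )
    E, C, F = feats.values.shape
    per_channel = np.empty((C, E))
    for c in range(C):
        Xc = model.normalizer.transform(feats.values[:, c, :])
        raw = model.svc.predict_proba(Xc)[:, 1]
        per_channel[c] = moving_average(raw, smoothing_window_epochs)
    fused = per_channel.max(axis=0) if C else np.zeros(E)
    times = np.asarray(feats.epoch_start_s, dtype=float) + EPOCH_HOP_S
    duration = float(feats.epoch_start_s[-1] + EPOCH_LENGTH_S) if E else 0.0
    return ProbabilityTrace(
        per_channel=per_channel,
        fused=fused,
        times_s=times,
        channel_labels=list(feats.channel_labels or [f"ch{i}" for i in range(C)]),
        smoothing_window_epochs=smoothing_window_epochs,
        duration_s=duration,
    )


def binarize(
    trace: ProbabilityTrace,
    threshold: float = DEFAULT_THRESHOLD,
    collar_s: float = DEFAULT_COLLAR_S,
) -> DecisionTrace:
    """Threshold the fused trace and extend each detection by the collar.

    ``binary[t] = 1`` iff ``fused[t] >= threshold``; each maximal run of ones
    maps to the interval covering its epochs' hop windows, is extended by
    ``collar_s`` on both sides (clipped to the record bounds), and runs made
    adjacent by the extension are merged.
    """
    if not 0.0 <= threshold <= 1.0:
        raise ValueError("threshold must lie in [0, 1]")
    binary = (trace.fused >= threshold).astype(int)
    lo, hi = trace.record_bounds_s
    lo = max(lo, 0.0)
    events: list[tuple[float, float]] = []
    t = trace.times_s
    in_run = False
    for i, b in enumerate(binary):
        if b and not in_run:
            start = t[i]
            in_run = True
        if in_run and (not b or i == len(binary) - 1):
            end_i = i if not b else i + 1
            onset = max(lo, float(start) - collar_s)
            offset = min(hi, float(t[end_i - 1]) + EPOCH_HOP_S + collar_s)
            events.append((onset, offset))
            in_run = False
    return DecisionTrace(
        binary=binary,
        threshold=float(threshold),
        collar_s=float(collar_s),
        events=AnnotationTrack(merge_intervals(events)),
        times_s=t.copy(),
        duration_s=hi,
    )


def grid_search_svm(
    feats_by_record: list[FeatureMatrix],
    labels_by_record: list[np.ndarray],
    C_grid=(0.1, 1.0, 10.0),
    gamma_grid=("scale", 0.01, 0.1),
    seed: int = 0,
) -> dict:
    """Select (C, gamma) by held-out-record cross-validated epoch AUC.

    Records are the grouping unit so no record contributes to both fit and
    validation. Returns the best parameter dict.
    """
    from sklearn.metrics import roc_auc_score

    Xs, ys, groups = [], [], []
    for g, (fm, lab) in enumerate(zip(feats_by_record, labels_by_record)):
        X, y = _flatten_training(fm, lab)
        Xs.append(X)
        ys.append(y)
        groups.append(np.full(y.size, g))
    X = np.vstack(Xs)
    y = np.concatenate(ys)
    groups = np.concatenate(groups)

    n_splits = min(3, len(feats_by_record))
    best = {"C": 1.0, "gamma": "scale", "auc": -np.inf}
    for C in C_grid:
        for gamma in gamma_grid:
            aucs = []
            for tr, te in GroupKFold(n_splits=n_splits).split(X, y, groups):
                if np.unique(y[tr]).size < 2 or np.unique(y[te]).size < 2:
                    continue
                norm = fit_normalizer(X[tr])
                svc = SVC(C=C, gamma=gamma, kernel="rbf", class_weight="balanced",
                          random_state=int(seed))
                svc.fit(norm.transform(X[tr]), y[tr])
                aucs.append(roc_auc_score(y[te], svc.decision_function(norm.transform(X[te]))))
            score = float(np.mean(aucs)) if aucs else -np.inf
            if score > best["auc"]:
                best = {"C": C, "gamma": gamma, "auc": score}
    return best


def save_model(model: SeizureModel, path) -> None:
    """Persist the model (SVM + normalizer + fingerprint + config) as one archive."""
    joblib.dump(
        {
            "svc": model.svc,
            "normalizer": {
                "mean": model.normalizer.mean,
                "std": model.normalizer.std,
                "zero_variance": model.normalizer.zero_variance,
            },
            "registry_fingerprint": model.registry_fingerprint,
            "config": model.config,
        },
        path,
    )


def load_model(path) -> SeizureModel:
    d = joblib.load(path)
    return SeizureModel(
        svc=d["svc"],
        normalizer=NormalizerTemplate(**d["normalizer"]),
        registry_fingerprint=d["registry_fingerprint"],
        config=d.get("config", {}),
    )
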