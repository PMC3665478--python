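"""Binary SVM with calibrated disease probability O(D) and reliability index.

An RBF support vector machine (Platt-style probability calibration) predicts
the probability that a substitution is disease-related.  The decision rule is
strict: Disease iff O(D) > 0.5.  The reliability index grades confidence as
RI = floor(20 * |O(D) - 0.5|), an integer 0..10.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from sklearn.svm import SVC

from .errors import CompatibilityError, SapgoError, TrainingError
from .feature_assembly import FeatureVector

LABELS = ("Neutral", "Disease")  # index = numeric class (N -> 0, D -> 1)


def reliability_index(o_d: float) -> int:
    """RI = floor(20 * |O(D) - 0.5|), clamped to 0..10."""
    if not 0.0 <= o_d <= 1.0:
        raise SapgoError(f"O(D) = {o_d} outside [0,1]")
    return min(10, int(math.floor(20.0 * abs(o_d - 0.5) + 1e-12)))


@dataclass(frozen=True)
class Prediction:
    """O(D), the hard label under the strict >0.5 rule, and the RI grade."""

    o_d: float
    label: str
    ri: int

    @staticmethod
    def from_probability(o_d: float) -> "Prediction":
        label = "Disease" if o_d > 0.5 else "Neutral"
        return Prediction(o_d=o_d, label=label, ri=reliability_index(o_d))


@dataclass
class SvmParams:
    """Kernel configuration; defaults follow common RBF practice."""

    kernel: str = "rbf"
    C: float = 1.0
    gamma: Optional[float] = None  # None -> 1 / n_features


@dataclass
class TrainedModel:
    """A fitted classifier plus everything needed to apply it safely."""

    svc: SVC
    mean: np.ndarray
    std: np.ndarray
    layout_tag: str
    params: SvmParams
    seed: int
    training_clusters: frozenset[str] = frozenset()
    go_stats: Optional[object] = None  # GoTermStats bundled for prediction time

    def _check_layout(self, vector: FeatureVector) -> None:
        if vector.layout_tag != self.layout_tag:
            raise CompatibilityError(
                f"feature layout mismatch: model expects {self.layout_tag!r}, "
                f"vector carries {vector.layout_tag!r}"
            )

    def _transform(self, matrix: np.ndarray) -> np.ndarray:
        return (matrix - self.mean) / self.std


def train(
    vectors: Sequence[FeatureVector],
    labels: Sequence[str],
    params: Optional[SvmParams] = None,
    seed: int = 0,
    training_clusters: frozenset[str] = frozenset(),
    go_stats: Optional[object] = None,
) -> TrainedModel:
    """Fit the SVM with per-feature z-scaling learned on the training data.

    Deterministic given (data order, params, seed).  Requires at least two
    examples of each class and a uniform feature layout.
    """
    params = params or SvmParams()
    if len(vectors) != len(labels):
        raise TrainingError("vectors and labels differ in length")
    if not vectors:
        raise TrainingError("empty training set")
    tags = {v.layout_tag for v in vectors}
    if len(tags) != 1:
        raise CompatibilityError(f"mixed feature layouts in training set: {sorted(tags)}")
    y = np.array([1 if l == "Disease" else 0 for l in labels], dtype=int)
    for cls in (0, 1):
        if (y == cls).sum() < 2:
            raise TrainingError(
                f"need >= 2 examples of class {LABELS[cls]}, got {(y == cls).sum()}"
            )
    X = np.stack([v.as_array() for v in vectors])
    mean = X.mean(axis=0)
    std = X.std(axis=0)
    std[std == 0] = 1.0
    Xs = (X - mean) / std
    gamma = params.gamma if params.gamma is not None else 1.0 / X.shape[1]
    svc = SVC(
        kernel=params.kernel,
        C=params.C,
        gamma=gamma,
        probability=True,
        random_state=seed,
    )
    svc.fit(Xs, y)
    return TrainedModel(
        svc=svc,
        mean=mean,
        std=std,
        layout_tag=next(iter(tags)),
        params=params,
        seed=seed,
        training_clusters=training_clusters,
        go_stats=go_stats,
    )


def predict(model: TrainedModel, vector: FeatureVector) -> Prediction:
    """Score one variant; layout tags must match."""
    model._check_layout(vector)
    x = model._transform(vector.as_array()[None, :])
    disease_col = int(np.where(model.svc.classes_ == 1)[0][0])
    o_d = float(model.svc.predict_proba(x)[0, disease_col])
    return Prediction.from_probability(o_d)


def predict_many(model: TrainedModel, vectors: Sequence[FeatureVector]) -> list[Prediction]:
    if not vectors:
        return []
    for v in vectors:
        model._check_layout(v)
    X = model._transform(np.stack([v.as_array() for v in vectors]))
    disease_col = int(np.where(model.svc.classes_ == 1)[0][0])
    probs = model.svc.predict_proba(X)[:, disease_col]
    return [Prediction.from_probability(float(p)) for p in probs]
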