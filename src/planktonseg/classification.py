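"""Feature extraction and the one-vs-one multi-class linear SVM.

The classifier follows the one-vs-one scheme: for ``k`` classes, one binary
linear max-margin classifier ``f(X) = W^T X + b`` is trained per unordered
class pair — ``k(k-1)/2`` in total (21 for the 7-way plankton scheme).  At
prediction time every pairwise classifier emits a calibrated probability
for each of its two classes; a class's score is the sum of the pairwise
probabilities it receives across its ``k-1`` pairs, and the predicted label
is the argmax (ties broken toward the lexicographically smaller label).

Features are pluggable.  The shipped baseline is a HOG descriptor on crops
resized to a canonical square; embedding extractors (e.g. CNN
fully-connected outputs) plug in through `FeatureExtractor` — any callable
mapping a crop to a fixed-length 1-D vector qualifies, no weights ship here.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from skimage.feature import hog as _sk_hog
from skimage.transform import resize as _sk_resize
from sklearn.linear_model import LogisticRegression
from sklearn.svm import LinearSVC

__all__ = [
    "HOGConfig",
    "hog_features",
    "FeatureExtractor",
    "register_extractor",
    "extract_features",
    "PairwiseClassifier",
    "SVMEnsemble",
    "train_ovo_svm",
    "predict",
    "predict_batch",
    "EvaluationReport",
    "evaluate",
    "evaluate_replicates",
]


# ---------------------------------------------------------------------------
# features
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class HOGConfig:
    resize_to: int = 64          # canonical square side for the HOG baseline
    orientations: int = 9
    pixels_per_cell: tuple[int, int] = (8, 8)
    cells_per_block: tuple[int, int] = (2, 2)


def _canonical(crop: np.ndarray, side: int) -> np.ndarray:
    c = np.asarray(crop, dtype=np.float64)
    if c.ndim != 2 or min(c.shape) < 2:
        raise ValueError(f"degenerate crop of shape {c.shape}")
    if c.shape != (side, side):
        c = _sk_resize(c, (side, side), order=1, anti_aliasing=True,
                       preserve_range=True)
    return c


def hog_features(crop: np.ndarray, config: HOGConfig = HOGConfig()) -> np.ndarray:
    """Histogram-of-oriented-gradients descriptor of a crop (deterministic)."""
    c = _canonical(crop, config.resize_to)
    return _sk_hog(
        c,
        orientations=config.orientations,
        pixels_per_cell=config.pixels_per_cell,
        cells_per_block=config.cells_per_block,
        block_norm="L2-Hys",
        feature_vector=True,
    )


FeatureExtractor = Callable[[np.ndarray], np.ndarray]

_EXTRACTORS: dict[str, FeatureExtractor] = {
    "hog": lambda crop: hog_features(crop),
}


def register_extractor(extractor_id: str, fn: FeatureExtractor) -> None:
    """Register a pluggable embedding extractor (crop -> fixed-length vector)."""
    _EXTRACTORS[extractor_id] = fn


def extract_features(crops: Sequence[np.ndarray],
                     extractor: str | FeatureExtractor = "hog") -> np.ndarray:
    """Stack per-crop feature vectors into an (n, d) matrix.

    Rejects extractors that return non-1-D or inconsistent-length vectors.
    """
    if isinstance(extractor, str):
        if extractor not in _EXTRACTORS:
            raise KeyError(f"unknown extractor id {extractor!r}; "
                           f"registered: {sorted(_EXTRACTORS)}")
        fn = _EXTRACTORS[extractor]
    else:
        fn = extractor
    vecs = []
    length = None
    for i, crop in enumerate(crops):
        v = np.asarray(fn(crop), dtype=np.float64)
        if v.ndim != 1:
            raise ValueError(f"extractor returned non-1-D output for crop {i}")
        if length is None:
            length = v.size
        elif v.size != length:
            raise ValueError(
                f"extractor length mismatch at crop {i}: {v.size} != {length}")
        if not np.all(np.isfinite(v)):
            raise ValueError(f"non-finite feature values at crop {i}")
        vecs.append(v)
    return np.vstack(vecs) if vecs else np.empty((0, 0))


# ---------------------------------------------------------------------------
# one-vs-one ensemble
# ---------------------------------------------------------------------------

@dataclass
class PairwiseClassifier:
    class_a: str
    class_b: str
    w: np.ndarray
    b: float
    # Platt-style sigmoid p(class_b | x) = 1/(1+exp(-(alpha*f(x)+beta)))
    alpha: float
    beta: float

    def decision(self, x: np.ndarray) -> float:
        return float(self.w @ x + self.b)

    def prob_b(self, x: np.ndarray) -> float:
        z = self.alpha * self.decision(x) + self.beta
        return float(1.0 / (1.0 + np.exp(-z)))


@dataclass
class SVMEnsemble:
    classes: tuple[str, ...]
    pairs: list[PairwiseClassifier]
    c: float = 1.0
    extractor_id: str = "hog"

    def __post_init__(self) -> None:
        k = len(self.classes)
        if len(self.pairs) != k * (k - 1) // 2:
            raise ValueError("ensemble must hold exactly k(k-1)/2 pairwise classifiers")


def train_ovo_svm(features: np.ndarray, labels: Sequence[str],
                  c: float = 1.0, seed: int = 0,
                  extractor_id: str = "hog") -> SVMEnsemble:
    """Train one calibrated linear max-margin classifier per class pair.

    Each pair's margin problem is solved on the samples of its two classes
    only; a sigmoid (Platt) calibration is then fitted on the decision
    values of those same samples.  Deterministic under a fixed seed.
    """
    X = np.asarray(features, dtype=np.float64)
    y = np.asarray(labels)
    classes = tuple(sorted(set(map(str, y))))
    if len(classes) < 2:
        raise ValueError("need at least 2 classes")
    for cls in classes:
        if (y == cls).sum() < 2:
            raise ValueError(f"class {cls!r} has fewer than 2 samples")
    pairs: list[PairwiseClassifier] = []
    for i in range(len(classes)):
        for j in range(i + 1, len(classes)):
            a, b = classes[i], classes[j]
            sel = (y == a) | (y == b)
            Xp, yp = X[sel], (y[sel] == b).astype(int)
            svm = LinearSVC(C=c, random_state=seed, max_iter=20000)
            svm.fit(Xp, yp)
            dec = svm.decision_function(Xp).reshape(-1, 1)
            cal = LogisticRegression(random_state=seed, max_iter=1000)
            cal.fit(dec, yp)
            pairs.append(PairwiseClassifier(
                class_a=a, class_b=b,
                w=svm.coef_.ravel().copy(), b=float(svm.intercept_[0]),
                alpha=float(cal.coef_[0, 0]), beta=float(cal.intercept_[0]),
            ))
    return SVMEnsemble(classes=classes, pairs=pairs, c=c, extractor_id=extractor_id)


def class_scores(ensemble: SVMEnsemble, x: np.ndarray) -> dict[str, float]:
    """Sum of calibrated pairwise probabilities per class.

    Each pair splits one unit of probability between its two classes, so
    the scores over all classes sum to the number of pairs, k(k-1)/2.
    """
    x = np.asarray(x, dtype=np.float64)
    d = ensemble.pairs[0].w.size
    if x.size != d:
        raise ValueError(f"feature length {x.size} != trained length {d}")
    scores = {cls: 0.0 for cls in ensemble.classes}
    for pc in ensemble.pairs:
        pb = pc.prob_b(x)
        scores[pc.class_a] += 1.0 - pb
        scores[pc.class_b] += pb
    return scores


def predict(ensemble: SVMEnsemble, x: np.ndarray) -> tuple[str, dict[str, float]]:
    """Label by highest aggregated probability; ties break lexicographically."""
    scores = class_scores(ensemble, x)
    best = min(scores, key=lambda cls: (-scores[cls], cls))
    return best, scores


def predict_batch(ensemble: SVMEnsemble, X: np.ndarray) -> list[str]:
    return [predict(ensemble, x)[0] for x in np.asarray(X, dtype=np.float64)]


# ---------------------------------------------------------------------------
# evaluation
# ---------------------------------------------------------------------------

@dataclass
class EvaluationReport:
    classes: tuple[str, ...]
    confusion: np.ndarray                 # rows: true class, cols: predicted
    precision: dict[str, float] = field(default_factory=dict)
    recall: dict[str, float] = field(default_factory=dict)
    macro_precision: float = 0.0
    macro_recall: float = 0.0
    accuracy: float = 0.0
    n_test: int = 0


def evaluate(ensemble: SVMEnsemble, features: np.ndarray,
             labels: Sequence[str]) -> EvaluationReport:
    """Per-class precision/recall, macro averages and the confusion matrix."""
    y = np.asarray(labels)
    if y.size == 0:
        raise ValueError("empty test set")
    unknown = set(map(str, y)) - set(ensemble.classes)
    if unknown:
        raise ValueError(f"labels outside ensemble classes: {sorted(unknown)}")
    preds = np.asarray(predict_batch(ensemble, features))
    classes = ensemble.classes
    idx = {cls: i for i, cls in enumerate(classes)}
    k = len(classes)
    conf = np.zeros((k, k), dtype=np.int64)
    for t, p in zip(y, preds):
        conf[idx[str(t)], idx[p]] += 1
    precision, recall = {}, {}
    for cls in classes:
        i = idx[cls]
        tp = conf[i, i]
        fp = conf[:, i].sum() - tp
        fn = conf[i, :].sum() - tp
        precision[cls] = tp / (tp + fp) if (tp + fp) else 0.0
        recall[cls] = tp / (tp + fn) if (tp + fn) else 0.0
    return EvaluationReport(
        classes=classes, confusion=conf,
        precision=precision, recall=recall,
        macro_precision=float(np.mean(list(precision.values()))),
        macro_recall=float(np.mean(list(recall.values()))),
        accuracy=float(conf.trace() / conf.sum()),
        n_test=int(y.size),
    )


def evaluate_replicates(features_train: np.ndarray, labels_train: Sequence[str],
                        features_test: np.ndarray, labels_test: Sequence[str],
                        n_replicates: int = 5, c: float = 1.0,
                        seed: int = 0) -> dict[str, float]:
    """Mean macro precision/recall over reseeded training replicates."""
    precs, recs = [], []
    for r in range(n_replicates):
        ens = train_ovo_svm(features_train, labels_train, c=c, seed=seed + r)
        rep = evaluate(ens, features_test, labels_test)
        precs.append(rep.macro_precision)
        recs.append(rep.macro_recall)
    return {
        "macro_precision_mean": float(np.mean(precs)),
        "macro_recall_mean": float(np.mean(recs)),
        "n_replicates": float(n_replicates),
    }
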