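"""32-feature random-forest tissue-of-origin classifier with LOOCV.

Features, in fixed order: the three NPCC values (BRCA, DLBC, LIHC), the
z-scores of the 22 autosomes (chr19 included — its exclusion applies only
to MTOP5Zscores), and the seven plasma tumor marker concentrations.

The forest uses ntree=500 and mtry=floor(sqrt(32))=5, matching the
reference implementation's classification default; leave-one-out
cross-validation re-seeds deterministically per fold from the master seed.
"""

from __future__ import annotations

from collections.abc import Mapping, Sequence
from dataclasses import dataclass

import numpy as np
from sklearn.ensemble import RandomForestClassifier

from mcanary.io_formats import AUTOSOMES
from mcanary.ptm_panel import PTM_MARKERS, PTMPanel
from mcanary.zscore_engine import ChromosomeZScores

NPCC_TYPES: tuple[str, ...] = ("BRCA", "DLBC", "LIHC")

FEATURE_NAMES: tuple[str, ...] = (
    tuple(f"npcc_{t}" for t in NPCC_TYPES)
    + tuple(f"z_{c}" for c in AUTOSOMES)
    + PTM_MARKERS
)

CLASS_LABELS: tuple[str, ...] = ("breast", "gastric", "liver", "lymphoma")

DEFAULT_NTREE = 500
DEFAULT_MTRY = 5  # floor(sqrt(32))


def assemble_features(
    npcc: Mapping[str, float], z: ChromosomeZScores, ptm: PTMPanel
) -> np.ndarray:
    """Build the 32-vector in declared order; missing components raise."""
    vals = []
    for t in NPCC_TYPES:
        if t not in npcc:
            raise ValueError(f"missing NPCC component: {t}")
        vals.append(float(npcc[t]))
    for c in AUTOSOMES:
        v = z.get(c)
        if v is None:
            raise ValueError(f"missing z-score: {c}")
        vals.append(float(v))
    for m in PTM_MARKERS:
        if m not in ptm.concentrations:
            raise ValueError(f"missing PTM marker: {m}")
        vals.append(float(ptm[m]))
    out = np.array(vals, dtype=float)
    if not np.all(np.isfinite(out)):
        raise ValueError("feature vector contains non-finite values")
    return out


@dataclass
class ClassifierModel:
    forest: RandomForestClassifier
    classes: list[str]
    ntree: int
    mtry: int
    seed: int

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        return self.forest.predict_proba(np.atleast_2d(X))

    def predict(self, X: np.ndarray) -> list[str]:
        return list(self.forest.predict(np.atleast_2d(X)))


@dataclass
class PredictionResult:
    """Class probabilities and argmax call for one held-out subject."""

    probabilities: dict[str, float]
    predicted: str

    def __post_init__(self) -> None:
        p = np.array(list(self.probabilities.values()))
        if (p < 0).any() or abs(p.sum() - 1.0) > 1e-9:
            raise ValueError("probabilities must be a distribution")


def train_classifier(
    features: Sequence[Sequence[float]],
    labels: Sequence[str],
    ntree: int = DEFAULT_NTREE,
    mtry: int = DEFAULT_MTRY,
    seed: int = 0,
) -> ClassifierModel:
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels, dtype=object)
    if X.ndim != 2 or len(X) != len(y):
        raise ValueError("features must be 2-D with one row per label")
    classes = sorted(set(y.tolist()))
    if len(classes) < 2:
        raise ValueError("training requires >= 2 classes")
    forest = RandomForestClassifier(
        n_estimators=ntree,
        max_features=min(mtry, X.shape[1]),
        random_state=seed,
    )
    forest.fit(X, y)
    return ClassifierModel(forest, list(forest.classes_), ntree, mtry, seed)


def _fold_seed(master_seed: int, fold: int) -> int:
    # deterministic per-fold stream derived from the master seed
    return int(np.random.SeedSequence([master_seed, fold]).generate_state(1)[0] % (2**31))


def loocv(
    features: Sequence[Sequence[float]],
    labels: Sequence[str],
    ntree: int = DEFAULT_NTREE,
    mtry: int = DEFAULT_MTRY,
    seed: int = 0,
) -> list[PredictionResult]:
    """Leave-one-out cross-validation: one held-out prediction per subject."""
    X = np.asarray(features, dtype=float)
    y = list(labels)
    n = len(y)
    if n < 8:
        raise ValueError(f"LOOCV requires n >= 8, got {n}")
    all_classes = sorted(set(y))
    results = []
    for i in range(n):
        mask = np.ones(n, dtype=bool)
        mask[i] = False
        model = train_classifier(
            X[mask], [y[j] for j in range(n) if mask[j]],
            ntree=ntree, mtry=mtry, seed=_fold_seed(seed, i),
        )
        proba = model.predict_proba(X[i])[0]
        probs = {c: 0.0 for c in all_classes}
        for c, p in zip(model.classes, proba):
            probs[c] = float(p)
        predicted = max(probs, key=lambda c: (probs[c], c))
        results.append(PredictionResult(probs, predicted))
    return results


def feature_importance(
    model: ClassifierModel, feature_names: Sequence[str] = FEATURE_NAMES
) -> list[tuple[str, float]]:
    """Mean-decrease-in-Gini-impurity importances, descending."""
    imp = model.forest.feature_importances_
    if len(imp) != len(feature_names):
        raise ValueError("feature name count does not match model")
    ranked = sorted(zip(feature_names, imp), key=lambda ni: -ni[1])
    return [(n, float(v)) for n, v in ranked]


def loocv_accuracy(results: Sequence[PredictionResult], labels: Sequence[str]) -> float:
    return float(np.mean([r.predicted == t for r, t in zip(results, labels)]))


def per_class_auc(
    results: Sequence[PredictionResult], labels: Sequence[str]
) -> dict[str, float]:
    """One-vs-rest AUC per class from held-out probabilities."""
    from mcanary.evaluation import roc_auc

    classes = sorted(set(labels))
    out = {}
    for c in classes:
        scores = [r.probabilities.get(c, 0.0) for r in results]
        y = [1 if t == c else 0 for t in labels]
        out[c] = roc_auc(scores, y).auc
    return out
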