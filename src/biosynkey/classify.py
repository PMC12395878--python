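"""Multilabel natural-product class prediction from counted fingerprints.

A single multi-output Random Forest is trained on the fingerprint table
against binarised label sets (a compound may carry several class labels).
Because each fingerprint position is a concrete biosynthetic substructure,
the forest's impurity importances are directly interpretable, and summing
them over the keys of each metabolic pathway gives a pathway-level view of
what drives the classification.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import precision_recall_fscore_support
from sklearn.model_selection import KFold
from sklearn.preprocessing import MultiLabelBinarizer

from .keyset import KeyRegistry

logger = logging.getLogger(__name__)

__all__ = [
    "LabelledSet",
    "FittedClassifier",
    "CVResult",
    "ImportanceReport",
    "train_multilabel_rf",
    "cross_validate",
    "importance_report",
    "prevalence_baseline_f1",
]

DEFAULT_TREES = 10_000  # full-scale ensemble; desk-scale runs pass trees=100
DEFAULT_MAX_DEPTH = 100


@dataclass(frozen=True)
class LabelledSet:
    """Fingerprint table plus a multilabel annotation per compound."""

    fingerprints: pd.DataFrame  # index: compound id, columns: key names
    labels: dict[str, frozenset[str]]

    def __post_init__(self) -> None:
        missing = [i for i in self.labels if i not in self.fingerprints.index]
        if missing:
            raise ValueError(f"labelled ids without fingerprints: {missing[:5]}")
        if len(self.classes) < 2:
            raise ValueError("need at least two distinct classes")

    @property
    def ids(self) -> list[str]:
        return [i for i in self.fingerprints.index if i in self.labels]

    @property
    def classes(self) -> list[str]:
        return sorted(set().union(*self.labels.values())) if self.labels else []

    def design(
        self, classes: list[str] | None = None
    ) -> tuple[np.ndarray, np.ndarray, list[str]]:
        """(X, Y, class names) for the labelled compounds, in id order.

        ``classes`` pins the label-matrix columns (needed when scoring a
        fold that happens to miss a class of the parent set).
        """
        ids = self.ids
        x = self.fingerprints.loc[ids].to_numpy(dtype=float)
        mlb = MultiLabelBinarizer(classes=classes or self.classes)
        y = mlb.fit_transform([sorted(self.labels[i]) for i in ids])
        return x, y, list(mlb.classes_)

    def subset(self, ids: list[str]) -> "LabelledSet":
        return LabelledSet(
            fingerprints=self.fingerprints.loc[ids],
            labels={i: self.labels[i] for i in ids},
        )


@dataclass
class FittedClassifier:
    """A fitted multi-output forest plus the metadata needed to interpret it."""

    forest: RandomForestClassifier
    classes: list[str]
    feature_names: list[str]
    params: dict = field(default_factory=dict)

    def predict(self, x: np.ndarray) -> np.ndarray:
        return np.asarray(self.forest.predict(x))


def train_multilabel_rf(
    train: LabelledSet,
    trees: int = DEFAULT_TREES,
    max_depth: int = DEFAULT_MAX_DEPTH,
    seed: int = 0,
    classes: list[str] | None = None,
) -> FittedClassifier:
    """Fit one multi-output Random Forest on the labelled set.

    Defaults follow the full-scale configuration (10,000 trees, depth cap
    100); pass ``trees=100`` for desk-scale work.  Degenerate labels
    (present on every compound or on none) trigger a warning but stay in
    the model.
    """
    x, y, classes = train.design(classes)
    if x.shape[0] < 10:
        raise ValueError("need at least 10 training samples")
    for j, cls in enumerate(classes):
        prevalence = y[:, j].mean()
        if prevalence in (0.0, 1.0):
            logger.warning("class %r is degenerate (prevalence %.0f)", cls, prevalence)
    forest = RandomForestClassifier(
        n_estimators=trees, max_depth=max_depth, random_state=seed, n_jobs=1
    )
    forest.fit(x, y)
    return FittedClassifier(
        forest=forest,
        classes=classes,
        feature_names=list(train.fingerprints.columns),
        params={"trees": trees, "max_depth": max_depth, "seed": seed},
    )


def _scores(y_true: np.ndarray, y_pred: np.ndarray, classes: list[str]) -> pd.DataFrame:
    precision, recall, f1, support = precision_recall_fscore_support(
        y_true, y_pred, average=None, zero_division=0
    )
    frame = pd.DataFrame(
        {"precision": precision, "recall": recall, "f1": f1, "support": support},
        index=classes,
    )
    # a class absent from the truth of this split has no defined score
    frame.loc[frame["support"] == 0, ["precision", "recall", "f1"]] = np.nan
    return frame


@dataclass
class CVResult:
    """Per-fold train/test metrics and the seeded fold assignment."""

    fold_train: list[pd.DataFrame]
    fold_test: list[pd.DataFrame]
    fold_assignment: dict[str, int]  # compound id -> test fold
    fold_importances: list[pd.Series]

    @property
    def n_folds(self) -> int:
        return len(self.fold_test)

    def macro_f1(self, split: str = "test") -> list[float]:
        frames = self.fold_test if split == "test" else self.fold_train
        return [float(f["f1"].mean(skipna=True)) for f in frames]

    def mean_macro_f1(self, split: str = "test") -> float:
        return float(np.mean(self.macro_f1(split)))


def cross_validate(
    labelled: LabelledSet,
    folds: int = 5,
    seed: int = 0,
    trees: int = DEFAULT_TREES,
    max_depth: int = DEFAULT_MAX_DEPTH,
) -> CVResult:
    """Seeded k-fold cross-validation of the multilabel forest.

    Folds are a seeded shuffled partition of the compounds; each model is
    fit only on its training fold (no leakage), and per-class
    precision/recall/F1 are reported for both splits of every fold.
    Classes absent from a fold's truth are flagged as NaN rather than
    scored.
    """
    ids = labelled.ids
    if len(ids) < folds:
        raise ValueError(f"need at least {folds} samples for {folds}-fold CV")
    splitter = KFold(n_splits=folds, shuffle=True, random_state=seed)
    fold_train, fold_test, fold_importances = [], [], []
    assignment: dict[str, int] = {}
    id_array = np.array(ids)
    for fold_idx, (train_pos, test_pos) in enumerate(splitter.split(id_array)):
        train_ids = list(id_array[train_pos])
        test_ids = list(id_array[test_pos])
        for i in test_ids:
            assignment[i] = fold_idx
        classes = labelled.classes
        model = train_multilabel_rf(
            labelled.subset(train_ids),
            trees=trees,
            max_depth=max_depth,
            seed=seed,
            classes=classes,
        )
        x_tr, y_tr, _ = labelled.subset(train_ids).design(classes)
        x_te, y_te, _ = labelled.subset(test_ids).design(classes)
        fold_train.append(_scores(y_tr, model.predict(x_tr), classes))
        fold_test.append(_scores(y_te, model.predict(x_te), classes))
        fold_importances.append(
            pd.Series(model.forest.feature_importances_, index=model.feature_names)
        )
    return CVResult(
        fold_train=fold_train,
        fold_test=fold_test,
        fold_assignment=assignment,
        fold_importances=fold_importances,
    )


@dataclass(frozen=True)
class ImportanceReport:
    """Normalised per-key importances with pathway-level aggregates."""

    per_key: pd.Series
    per_pathway: pd.Series

    def top_key(self) -> str:
        return str(self.per_key.idxmax())


def importance_report(model: FittedClassifier, registry: KeyRegistry) -> ImportanceReport:
    """Impurity importances per key, and summed per biosynthetic pathway."""
    try:
        raw = model.forest.feature_importances_
    except Exception as exc:  # sklearn raises NotFittedError
        raise ValueError(f"model is not fitted: {exc}") from exc
    per_key = pd.Series(raw, index=model.feature_names)
    total = per_key.sum()
    if total > 0:
        per_key = per_key / total
    pathways = pd.Series(
        {name: registry[name].pathway for name in model.feature_names}
    )
    per_pathway = per_key.groupby(pathways).sum()
    return ImportanceReport(per_key=per_key, per_pathway=per_pathway)


def prevalence_baseline_f1(labelled: LabelledSet) -> float:
    """Macro-F1 of an always-predict-every-label classifier.

    For a class with prevalence p, predicting all-positive scores
    F1 = 2p / (p + 1); the macro average over classes is the chance-level
    reference used in permutation checks.
    """
    _, y, _ = labelled.design()
    prevalence = y.mean(axis=0)
    with np.errstate(invalid="ignore"):
        f1 = 2 * prevalence / (prevalence + 1)
    return float(np.nanmean(f1))
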