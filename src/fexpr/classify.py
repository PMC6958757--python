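"""Random-forest emotion classification under subject-independent protocols.

The model object, :class:`ExpressionClassifier`, is built from a feature
matrix, labels and subject ids (or directly from a :class:`~fexpr.corpus.Corpus`).
``fit()`` runs subject-independent k-fold cross-validation within one
dataset; ``fit_transfer()`` trains the k fold models on one dataset and
tests every one of them on a second, subject-disjoint dataset. Both return
a :class:`ClassificationResults` carrying fold accuracies, the pooled
confusion matrix, per-class recalls, per-fold impurity importances and a
``summary()`` table.

The forest hyperparameters default to: 500 trees, maximum depth 16, Gini
impurity, at most 220 candidate features per split, at least 40 examples
to split a node, and inverse-frequency class weighting for the skewed
label distribution.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import confusion_matrix as _sk_confusion

from .corpus import Corpus
from .landmarks import EMOTIONS


@dataclass(frozen=True)
class RFConfig:
    """Random-forest hyperparameters."""

    n_trees: int = 500
    max_depth: int = 16
    criterion: str = "gini"
    max_features_per_split: int = 220
    min_samples_split: int = 40
    class_weighting: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_trees, self.max_depth, self.max_features_per_split,
               self.min_samples_split) <= 0:
            raise ValueError("all RF hyperparameters must be positive")

    def build(self, n_features: int, seed: int | None = None) -> RandomForestClassifier:
        if self.max_features_per_split > n_features:
            raise ValueError(
                f"max_features_per_split={self.max_features_per_split} "
                f"exceeds feature count {n_features}")
        return RandomForestClassifier(
            n_estimators=self.n_trees,
            max_depth=self.max_depth,
            criterion=self.criterion,
            max_features=self.max_features_per_split,
            min_samples_split=self.min_samples_split,
            class_weight="balanced" if self.class_weighting else None,
            random_state=self.seed if seed is None else int(seed),
            n_jobs=1,
        )


#: reduced-size config for quick runs (same protocol, smaller forest)
FAST_RF = RFConfig(n_trees=100)


@dataclass(frozen=True)
class FoldPlan:
    """A subject-level partition into k folds."""

    folds: tuple[tuple[str, ...], ...]
    seed: int

    @property
    def k(self) -> int:
        return len(self.folds)

    def fold_of(self) -> dict[str, int]:
        return {s: i for i, fold in enumerate(self.folds) for s in fold}

    def validate(self) -> None:
        all_subjects = [s for fold in self.folds for s in fold]
        if len(all_subjects) != len(set(all_subjects)):
            raise ValueError("a subject appears in two folds")


def make_folds(subjects: Sequence[str] | Corpus, k: int = 10,
               seed: int = 0) -> FoldPlan:
    """Shuffle subjects by seed and deal them round-robin into k folds.

    Every video inherits its subject's fold, so no subject ever spans the
    train/test boundary.
    """
    if isinstance(subjects, Corpus):
        subjects = list(subjects.subjects["subject_id"])
    subjects = sorted(set(subjects))
    if len(subjects) < k:
        raise ValueError(f"need at least {k} subjects, got {len(subjects)}")
    rng = np.random.default_rng(seed)
    order = [subjects[i] for i in rng.permutation(len(subjects))]
    folds = tuple(tuple(order[i::k]) for i in range(k))
    plan = FoldPlan(folds=folds, seed=seed)
    plan.validate()
    return plan


def _fold_seed(master: int, regime: str, fold: int) -> int:
    """Deterministic per-(regime, fold) forest seed below 2**31."""
    tag = zlib.crc32(regime.encode())
    return int(np.random.SeedSequence([int(master), tag, int(fold)])
               .generate_state(1)[0] % (2 ** 31))


def train(features: np.ndarray, labels: Sequence[str],
          config: RFConfig | None = None,
          seed: int | None = None) -> RandomForestClassifier:
    """Train one forest with inverse-frequency class weighting.

    The fitted model exposes impurity-decrease feature importances summing
    to 1. Reproducible for a fixed seed.
    """
    config = config or RFConfig()
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels)
    if not np.isfinite(X).all():
        raise ValueError("features must be finite")
    if len(np.unique(y)) < 2:
        raise ValueError("need at least 2 classes to train")
    model = config.build(X.shape[1], seed=seed)
    model.fit(X, y)
    return model


class ClassificationResults:
    """Cross-validated evaluation of one train/test regime.

    Attributes
    ----------
    regime : str
        Label of the train/test regime.
    fold_accuracies : ndarray
        Global accuracy (%) of each fold's model on its test set.
    confusion : DataFrame
        Pooled 4x4 confusion counts (rows true, columns predicted).
    fold_importances : ndarray, (k, p)
        Impurity-decrease importance vector of each fold's forest.
    """

    def __init__(self, regime: str, fold_accuracies: np.ndarray,
                 confusion: np.ndarray, fold_importances: np.ndarray,
                 feature_names: Sequence[str], config: RFConfig,
                 classes: Sequence[str] = EMOTIONS) -> None:
        self.regime = regime
        self.fold_accuracies = np.asarray(fold_accuracies, dtype=float)
        self.classes = tuple(classes)
        self.confusion = pd.DataFrame(np.asarray(confusion, dtype=int),
                                      index=list(self.classes),
                                      columns=list(self.classes))
        self.fold_importances = np.asarray(fold_importances, dtype=float)
        self.feature_names = tuple(feature_names)
        self.config = config

    @property
    def n_test(self) -> int:
        return int(self.confusion.to_numpy().sum())

    @property
    def accuracy(self) -> float:
        """Mean fold global accuracy, %."""
        return float(self.fold_accuracies.mean())

    @property
    def accuracy_sd(self) -> float:
        """SD of the fold global accuracies, %."""
        return float(self.fold_accuracies.std(ddof=1))

    @property
    def pooled_accuracy(self) -> float:
        """100 x trace / total of the pooled confusion matrix."""
        c = self.confusion.to_numpy()
        return 100.0 * np.trace(c) / c.sum()

    def per_class_recall(self) -> pd.Series:
        """Per-class recall (%): diagonal / row sum of pooled confusion."""
        c = self.confusion.to_numpy().astype(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            rec = 100.0 * np.diag(c) / c.sum(axis=1)
        return pd.Series(rec, index=list(self.classes), name="recall")

    def confusion_percentages(self) -> pd.DataFrame:
        """Row-normalised confusion matrix, rows summing to 100."""
        c = self.confusion.to_numpy().astype(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            pct = 100.0 * c / c.sum(axis=1, keepdims=True)
        return pd.DataFrame(pct, index=list(self.classes),
                            columns=list(self.classes))

    def importances(self) -> pd.Series:
        """Mean per-feature impurity importance across fold models."""
        return pd.Series(self.fold_importances.mean(axis=0),
                         index=list(self.feature_names), name="importance")

    def summary(self) -> str:
        lines = [
            f"Expression classification results — regime: {self.regime}",
            "=" * 60,
            f"folds: {len(self.fold_accuracies)}   "
            f"test examples (pooled): {self.n_test}",
            f"forest: {self.config.n_trees} trees, depth<= {self.config.max_depth}, "
            f"{self.config.max_features_per_split} features/split",
            "-" * 60,
            f"global accuracy (mean over folds): {self.accuracy:6.2f} % "
            f"(SD {self.accuracy_sd:.2f})",
            "per-class recall (pooled):",
        ]
        for e, r in self.per_class_recall().items():
            lines.append(f"    {e:<10s} {r:6.2f} %")
        lines.append("pooled confusion (rows true, columns predicted):")
        lines.append(self.confusion.to_string())
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "regime": self.regime,
            "fold_accuracies": self.fold_accuracies.tolist(),
            "accuracy_mean": self.accuracy,
            "accuracy_sd": self.accuracy_sd,
            "per_class_recall": self.per_class_recall().to_dict(),
            "confusion": self.confusion.to_numpy().tolist(),
            "classes": list(self.classes),
            "config": {"n_trees": self.config.n_trees,
                       "max_depth": self.config.max_depth,
                       "max_features_per_split": self.config.max_features_per_split,
                       "min_samples_split": self.config.min_samples_split},
        }


class ExpressionClassifier:
    """Random-forest emotion classifier over one dataset.

    Parameters
    ----------
    features : DataFrame or ndarray
        (n_videos, n_features) matrix; a DataFrame's index is used as the
        video ids and its columns as feature names.
    labels, subject_ids : sequences aligned with the rows.
    config : RFConfig
    """

    def __init__(self, features, labels: Sequence[str],
                 subject_ids: Sequence[str],
                 config: RFConfig | None = None,
                 feature_names: Sequence[str] | None = None) -> None:
        if isinstance(features, pd.DataFrame):
            feature_names = feature_names or list(features.columns)
            features = features.to_numpy(dtype=float)
        self.X = np.asarray(features, dtype=float)
        self.y = np.asarray(labels)
        self.subject_ids = np.asarray(subject_ids)
        if not (len(self.X) == len(self.y) == len(self.subject_ids)):
            raise ValueError("features, labels and subject_ids disagree in length")
        self.config = config or RFConfig()
        self.feature_names = tuple(
            feature_names if feature_names is not None
            else (f"f{i}" for i in range(self.X.shape[1])))

    @classmethod
    def from_corpus(cls, corpus: Corpus, config: RFConfig | None = None,
                    feature_table: pd.DataFrame | None = None
                    ) -> "ExpressionClassifier":
        """Build the model from a corpus, extracting features if needed."""
        from .features import feature_matrix

        if feature_table is None:
            feature_table = feature_matrix(corpus)
        meta = corpus.metadata().set_index("video_id")
        feature_table = feature_table.loc[meta.index]
        return cls(feature_table, meta["target_emotion"].to_numpy(),
                   meta["subject_id"].to_numpy(), config=config)

    def _splits(self, plan: FoldPlan):
        fold_of = plan.fold_of()
        fold_idx = np.array([fold_of[s] for s in self.subject_ids])
        for f in range(plan.k):
            yield np.flatnonzero(fold_idx != f), np.flatnonzero(fold_idx == f)

    def fit(self, fold_plan: FoldPlan | None = None, k: int = 10,
            seed: int = 0, regime: str = "within") -> ClassificationResults:
        """Subject-independent k-fold cross-validation within the dataset."""
        plan = fold_plan or make_folds(list(self.subject_ids), k=k, seed=seed)
        accs, imps = [], []
        pooled = np.zeros((len(EMOTIONS), len(EMOTIONS)), dtype=int)
        for f, (tr, te) in enumerate(self._splits(plan)):
            if len(te) == 0:
                raise ValueError(f"fold {f} has an empty test set")
            assert not set(self.subject_ids[tr]) & set(self.subject_ids[te])
            model = train(self.X[tr], self.y[tr], self.config,
                          seed=_fold_seed(seed, regime, f))
            pred = model.predict(self.X[te])
            accs.append(100.0 * float(np.mean(pred == self.y[te])))
            pooled += _sk_confusion(self.y[te], pred, labels=list(EMOTIONS))
            imps.append(model.feature_importances_)
        return ClassificationResults(regime, np.array(accs), pooled,
                                     np.vstack(imps), self.feature_names,
                                     self.config)

    def fit_transfer(self, test: "ExpressionClassifier",
                     fold_plan: FoldPlan | None = None, k: int = 10,
                     seed: int = 0, regime: str = "cross") -> ClassificationResults:
        """Train k fold models here; test each on the full second dataset.

        The two datasets must share the feature schema and have disjoint
        subject sets. The SD across the k models is the reported spread.
        """
        if self.feature_names != test.feature_names:
            raise ValueError("train and test feature schemas differ")
        overlap = set(self.subject_ids) & set(test.subject_ids)
        if overlap:
            raise ValueError(f"subjects shared across train/test: {sorted(overlap)[:5]}")
        plan = fold_plan or make_folds(list(self.subject_ids), k=k, seed=seed)
        accs, imps = [], []
        pooled = np.zeros((len(EMOTIONS), len(EMOTIONS)), dtype=int)
        for f, (tr, _) in enumerate(self._splits(plan)):
            model = train(self.X[tr], self.y[tr], self.config,
                          seed=_fold_seed(seed, regime, f))
            pred = model.predict(test.X)
            accs.append(100.0 * float(np.mean(pred == test.y)))
            pooled += _sk_confusion(test.y, pred, labels=list(EMOTIONS))
            imps.append(model.feature_importances_)
        return ClassificationResults(regime, np.array(accs), pooled,
                                     np.vstack(imps), self.feature_names,
                                     self.config)


def evaluate_within(corpus: Corpus, config: RFConfig | None = None,
                    fold_plan: FoldPlan | None = None, k: int = 10,
                    seed: int = 0, feature_table: pd.DataFrame | None = None,
                    regime: str = "within") -> ClassificationResults:
    """Within-group subject-independent CV on one corpus."""
    model = ExpressionClassifier.from_corpus(corpus, config=config,
                                             feature_table=feature_table)
    return model.fit(fold_plan=fold_plan, k=k, seed=seed, regime=regime)


def evaluate_cross(train_corpus: Corpus, test_corpus: Corpus,
                   config: RFConfig | None = None,
                   fold_plan: FoldPlan | None = None, k: int = 10,
                   seed: int = 0,
                   train_features: pd.DataFrame | None = None,
                   test_features: pd.DataFrame | None = None,
                   regime: str = "cross") -> ClassificationResults:
    """Train fold models on one corpus, test each on another corpus."""
    model = ExpressionClassifier.from_corpus(train_corpus, config=config,
                                             feature_table=train_features)
    test = ExpressionClassifier.from_corpus(test_corpus, config=config,
                                            feature_table=test_features)
    return model.fit_transfer(test, fold_plan=fold_plan, k=k, seed=seed,
                              regime=regime)
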