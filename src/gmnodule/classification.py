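"""Random-forest benign/malignant classification of feature tables.

The classifier is an ensemble of entropy-criterion decision trees with
bootstrap aggregation (400 trees by default); the reported metrics are
accuracy, sensitivity (true-positive rate, positive = malignant = 1)
and specificity (true-negative rate).  The default split is a
stratified 70-30 hold-out; a group-aware option keeps augmented
siblings of one nodule on one side of the split to measure the leakage
the plain split incurs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import confusion_matrix

from .dataset_io import FEATURE_COLUMNS, validate_feature_table
from .errors import ConfigError, GMNoduleError, SchemaError
from .features import FEATURE_NAMES, TIRADS11_NAMES

__all__ = [
    "SplitConfig",
    "ForestConfig",
    "ClassificationReport",
    "feature_columns_for_arm",
    "stratified_split",
    "train_rfc",
    "evaluate",
    "run_experiment",
]


@dataclass(frozen=True)
class SplitConfig:
    """Hold-out split parameters (default: stratified 70-30)."""

    test_fraction: float = 0.30
    stratified: bool = True
    group_aware: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.test_fraction < 1.0:
            raise ConfigError("test_fraction must be in (0, 1)")


@dataclass(frozen=True)
class ForestConfig:
    """Random-forest parameters (400 entropy trees with bootstrap by default)."""

    n_trees: int = 400
    split_criterion: str = "entropy"
    bootstrap: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_trees < 1:
            raise ConfigError("n_trees must be >= 1")


@dataclass(frozen=True)
class ClassificationReport:
    """Confusion matrix and the three reported metrics.

    ``confusion`` is ``(TN, FP, FN, TP)`` with positive = 1 (malignant).
    Undefined metrics (an empty class in the test set) are NaN, never a
    silent zero.
    """

    confusion: tuple[int, int, int, int]
    accuracy: float
    sensitivity: float
    specificity: float
    n_train: int = 0
    n_test: int = 0
    arm: str | None = None

    @classmethod
    def from_confusion(
        cls, tn: int, fp: int, fn: int, tp: int, **extra
    ) -> "ClassificationReport":
        total = tn + fp + fn + tp
        if total == 0:
            raise GMNoduleError("empty confusion matrix")
        acc = (tp + tn) / total
        if tp + fn > 0:
            sens = tp / (tp + fn)
        else:
            warnings.warn("sensitivity undefined: no positive cases in test", stacklevel=2)
            sens = float("nan")
        if tn + fp > 0:
            spec = tn / (tn + fp)
        else:
            warnings.warn("specificity undefined: no negative cases in test", stacklevel=2)
            spec = float("nan")
        return cls(
            confusion=(tn, fp, fn, tp),
            accuracy=acc,
            sensitivity=sens,
            specificity=spec,
            **extra,
        )

    def as_dict(self) -> dict:
        tn, fp, fn, tp = self.confusion
        return {
            "confusion": {"TN": tn, "FP": fp, "FN": fn, "TP": tp},
            "accuracy": self.accuracy,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "n_train": self.n_train,
            "n_test": self.n_test,
            "arm": self.arm,
        }


def feature_columns_for_arm(arm: str) -> list[str]:
    """Numeric table columns belonging to a feature arm."""
    if arm == "tirads11":
        names = TIRADS11_NAMES
    elif arm == "global27":
        names = FEATURE_NAMES
    elif arm == "discounted16":
        names = tuple(n for n in FEATURE_NAMES if n not in TIRADS11_NAMES)
    else:
        raise ValueError(f"unknown feature arm {arm!r}")
    cols: list[str] = []
    for n in names:
        cols.extend(("centroid_x", "centroid_y") if n == "centroid" else (n,))
    return cols


def _allocate(counts: np.ndarray, n_test: int) -> np.ndarray:
    """Per-class test counts proportional to class sizes (largest remainder)."""
    exact = counts * n_test / counts.sum()
    base = np.floor(exact).astype(int)
    short = n_test - base.sum()
    order = np.argsort(-(exact - base))
    for i in range(short):
        base[order[i % len(base)]] += 1
    return np.minimum(base, counts)


def stratified_split(
    table: pd.DataFrame, cfg: SplitConfig
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Split a labeled table into train and test partitions.

    The test partition has ``round(test_fraction * n)`` rows; when
    stratified, per-class proportions are preserved within one row.
    With ``group_aware`` every row sharing a ``case_id`` lands on one
    side (test quota then holds approximately).
    """
    labels = table["label"].to_numpy()
    classes = np.unique(labels)
    if cfg.stratified and len(classes) < 2:
        raise GMNoduleError("cannot stratify: a class is absent")
    if min(np.bincount(labels, minlength=2)) < 1:
        raise GMNoduleError("cannot split: a class is absent")
    n = len(table)
    n_test = int(round(cfg.test_fraction * n))
    rng = np.random.default_rng(cfg.seed)

    if cfg.group_aware:
        test_idx: list[int] = []
        groups = table["case_id"].to_numpy()
        uniq = pd.unique(groups)
        perm = rng.permutation(len(uniq))
        picked = 0
        for g in uniq[perm]:
            if picked >= n_test:
                break
            members = np.nonzero(groups == g)[0]
            test_idx.extend(members.tolist())
            picked += len(members)
        test_mask = np.zeros(n, dtype=bool)
        test_mask[test_idx] = True
    elif cfg.stratified:
        counts = np.array([(labels == c).sum() for c in classes])
        per_class = _allocate(counts, n_test)
        test_mask = np.zeros(n, dtype=bool)
        for c, k in zip(classes, per_class):
            idx = np.nonzero(labels == c)[0]
            test_mask[rng.choice(idx, size=int(k), replace=False)] = True
    else:
        test_mask = np.zeros(n, dtype=bool)
        test_mask[rng.choice(n, size=n_test, replace=False)] = True

    return table[~test_mask].copy(), table[test_mask].copy()


def train_rfc(train: pd.DataFrame, cfg: ForestConfig) -> RandomForestClassifier:
    """Fit the bootstrap-aggregated decision-tree ensemble.

    Prediction is the majority vote of the individual trees; the fit is
    deterministic given the seed.
    """
    if len(train) == 0:
        raise GMNoduleError("empty training set")
    feats = [c for c in train.columns if c in FEATURE_COLUMNS]
    y = train["label"].to_numpy()
    if len(np.unique(y)) < 2:
        raise GMNoduleError("training set contains a single class")
    model = RandomForestClassifier(
        n_estimators=cfg.n_trees,
        criterion=cfg.split_criterion,
        bootstrap=cfg.bootstrap,
        random_state=cfg.seed,
        n_jobs=1,
    )
    model.fit(train[feats], y)
    return model


def evaluate(model: RandomForestClassifier, test: pd.DataFrame, **extra) -> ClassificationReport:
    """Confusion matrix and accuracy/sensitivity/specificity on held-out rows."""
    if len(test) == 0:
        raise GMNoduleError("empty test set")
    feats = list(model.feature_names_in_)
    missing = [c for c in feats if c not in test.columns]
    if missing:
        raise SchemaError(f"schema mismatch: test table lacks {missing}")
    if len(test) == 1:
        warnings.warn("single-row test set: metrics are degenerate", stacklevel=2)
    pred = model.predict(test[feats])
    tn, fp, fn, tp = confusion_matrix(
        test["label"].to_numpy(), pred, labels=[0, 1]
    ).ravel()
    return ClassificationReport.from_confusion(
        int(tn), int(fp), int(fn), int(tp), n_train=0, n_test=len(test), **extra
    )


def run_experiment(
    cohort: pd.DataFrame,
    feature_set: str = "tirads11",
    split_cfg: SplitConfig | None = None,
    forest_cfg: ForestConfig | None = None,
) -> ClassificationReport:
    """Select features, split, train and evaluate in one call."""
    split_cfg = split_cfg or SplitConfig()
    forest_cfg = forest_cfg or ForestConfig()
    validate_feature_table(cohort)
    cols = ["case_id", "source_tag"] + feature_columns_for_arm(feature_set) + ["label"]
    sub = cohort[cols]
    train, test = stratified_split(sub, split_cfg)
    model = train_rfc(train, forest_cfg)
    report = evaluate(model, test, arm=feature_set)
    return ClassificationReport(
        confusion=report.confusion,
        accuracy=report.accuracy,
        sensitivity=report.sensitivity,
        specificity=report.specificity,
        n_train=len(train),
        n_test=len(test),
        arm=feature_set,
    )
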