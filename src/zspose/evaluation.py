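"""Evaluation protocols: leave-one-class-out ZSL, k-shot, random baseline.

The zero-shot protocol holds out one class at a time: its samples are
never used for training, and its prototype is the expanded symbolic
definition row, while every other (seen) class is represented by the mean
of its attribute vectors.  Each held-out class's samples are classified
over the full label space (seen + unseen), every fold's predictions go
into one aggregate confusion matrix, and per-class precision / recall /
F-measure plus their unweighted average are computed from it.

The k-shot protocol replaces the definition prototype by the mean of k
randomly drawn samples of the held-out class, cycling through
floor(Nc/k) disjoint k-subsets and averaging the folds per class.

The random-importance baseline reruns the ZSL protocol with fair-coin
binary importance weights (all-zero class rows redrawn, since the
weighted metric is undefined there) and reports the mean over R draws.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .attribute_space import (
    AttributeSchema,
    ImportanceTable,
    PoseDefinitionTable,
    default_schema,
    expand_pose_definition,
)
from .zsl_core import ClassPrototype, DistanceParams, classify_batch

__all__ = [
    "EvalConfig",
    "EvalResult",
    "f_measures",
    "loco_zsl_evaluate",
    "kshot_evaluate",
    "random_importance_baseline",
]

logger = logging.getLogger("zspose.evaluation")

METRICS = ("naive", "weighted")


@dataclass(frozen=True)
class EvalConfig:
    """Evaluation settings: metric, distance parameters, shots, repetitions."""

    metric: str = "weighted"
    params: DistanceParams = field(default_factory=DistanceParams)
    k: int = 1
    R: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.metric not in METRICS:
            raise ValueError(f"metric must be one of {METRICS}, got {self.metric!r}")
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if self.R < 1:
            raise ValueError("R must be >= 1")


@dataclass(frozen=True)
class EvalResult:
    """Per-class precision/recall/F and their unweighted average.

    ``confusion`` is a classes x classes matrix (rows = true class); its
    counts may be fractional where folds were averaged (k-shot) or
    repetitions were averaged (random baseline).
    """

    per_class: pd.DataFrame  # columns: precision, recall, f
    average_f: float
    confusion: pd.DataFrame

    @property
    def classes(self) -> list[str]:
        return list(self.per_class.index)


def f_measures(confusion: pd.DataFrame | np.ndarray, classes: Sequence[str] | None = None) -> EvalResult:
    """Precision, recall and F per class from a confusion matrix.

    P = TP/(TP+FP) over each predicted column, R = TP/(TP+FN) over each
    true row, F = 2PR/(P+R); all three fall back to 0 where the
    denominator is 0.  The average F is the unweighted mean over classes.
    """
    if isinstance(confusion, pd.DataFrame):
        classes = list(confusion.index)
        M = confusion.to_numpy(dtype=float)
    else:
        M = np.asarray(confusion, dtype=float)
        classes = [str(i) for i in range(len(M))] if classes is None else list(classes)
    if M.size == 0:
        raise ValueError("empty confusion matrix")
    if M.shape[0] != M.shape[1] or M.shape[0] != len(classes):
        raise ValueError("confusion must be square with one row per class")
    if np.any(M < 0):
        raise ValueError("confusion counts must be non-negative")
    tp = np.diag(M)
    col = M.sum(axis=0)
    row = M.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        precision = np.where(col > 0, tp / col, 0.0)
        recall = np.where(row > 0, tp / row, 0.0)
        pr = precision + recall
        f = np.where(pr > 0, 2 * precision * recall / pr, 0.0)
    per_class = pd.DataFrame(
        {"precision": precision, "recall": recall, "f": f}, index=list(classes)
    )
    conf = pd.DataFrame(M, index=list(classes), columns=list(classes))
    return EvalResult(per_class, float(f.mean()), conf)


def _check_inputs(
    X: np.ndarray,
    labels: np.ndarray,
    defs: PoseDefinitionTable,
    importance: ImportanceTable | None,
    metric: str,
) -> list[str]:
    classes = list(defs.classes)
    present = set(map(str, labels))
    if len(present) < 2:
        raise ValueError("need samples from at least two classes")
    missing = sorted(present - set(classes))
    if missing:
        raise ValueError(f"classes missing from the definition table: {missing}")
    if metric == "weighted":
        if importance is None:
            raise ValueError("weighted metric needs an importance table")
        missing = sorted(set(classes) - set(importance.classes))
        if missing:
            raise ValueError(f"classes missing from the importance table: {missing}")
    return classes


def _class_means(X: np.ndarray, labels: np.ndarray, classes: Sequence[str]) -> dict[str, np.ndarray]:
    means = {}
    for c in classes:
        mask = labels == c
        if mask.any():
            means[c] = X[mask].mean(axis=0)
    return means


def _histogram(pred: np.ndarray, classes: Sequence[str]) -> np.ndarray:
    idx = {c: i for i, c in enumerate(classes)}
    h = np.zeros(len(classes))
    for p in pred:
        h[idx[str(p)]] += 1
    return h


def loco_zsl_evaluate(
    X: np.ndarray,
    labels: Sequence[str],
    defs: PoseDefinitionTable,
    importance: ImportanceTable | None = None,
    cfg: EvalConfig = EvalConfig(),
    schema: AttributeSchema | None = None,
) -> EvalResult:
    """Leave-one-class-out zero-shot evaluation.

    For each fold class c, prototypes are the data means of all other
    classes plus the expanded definition of c; all of c's samples are
    classified over the full label space.  Fold predictions are pooled
    into one confusion matrix before computing per-class P/R/F.
    """
    schema = schema or default_schema()
    X = np.asarray(X, dtype=float)
    labels = np.asarray(labels, dtype=object)
    classes = _check_inputs(X, labels, defs, importance, cfg.metric)
    imp = importance if cfg.metric == "weighted" else None
    means = _class_means(X, labels, classes)
    def_vecs = {c: expand_pose_definition(defs.row(c), schema) for c in classes}

    confusion = np.zeros((len(classes), len(classes)))
    for ci, c in enumerate(classes):
        test_mask = labels == c
        if not test_mask.any():
            continue
        protos = [
            ClassPrototype(o, means[o], "data_mean")
            for o in classes
            if o != c and o in means
        ]
        protos.append(ClassPrototype(c, def_vecs[c], "definition"))
        pred = classify_batch(
            X[test_mask], protos, imp, schema, cfg.params, class_order=classes
        )
        confusion[ci] += _histogram(pred, classes)
        logger.info(
            "zsl fold %d/%d class=%s n_test=%d correct=%.3f",
            ci + 1, len(classes), c, int(test_mask.sum()),
            float((pred == c).mean()),
        )
    return f_measures(confusion, classes)


def kshot_evaluate(
    X: np.ndarray,
    labels: Sequence[str],
    defs: PoseDefinitionTable,
    importance: ImportanceTable | None = None,
    k: int = 1,
    cfg: EvalConfig = EvalConfig(),
    schema: AttributeSchema | None = None,
) -> EvalResult:
    """k-shot evaluation: the held-out class is represented by the mean of
    k of its own samples instead of its definition row.

    Per class the (seeded) permutation is cut into floor(Nc/k) disjoint
    k-subsets; fold l trains on subset l and tests on the remaining
    Nc - k samples.  Fold confusion rows are averaged per class before
    the cross-class P/R/F computation.
    """
    schema = schema or default_schema()
    X = np.asarray(X, dtype=float)
    labels = np.asarray(labels, dtype=object)
    classes = _check_inputs(X, labels, defs, importance, cfg.metric)
    imp = importance if cfg.metric == "weighted" else None
    means = _class_means(X, labels, classes)
    rng = np.random.default_rng(cfg.seed)

    confusion = np.zeros((len(classes), len(classes)))
    for ci, c in enumerate(classes):
        idx_c = np.flatnonzero(labels == c)
        n_c = len(idx_c)
        if n_c <= k:
            raise ValueError(f"class {c!r} has Nc={n_c} <= k={k} samples")
        perm = idx_c[rng.permutation(n_c)]
        n_folds = n_c // k
        others = [
            ClassPrototype(o, means[o], "data_mean")
            for o in classes
            if o != c and o in means
        ]
        fold_rows = np.zeros((n_folds, len(classes)))
        for l in range(n_folds):
            train = perm[l * k : (l + 1) * k]
            test = np.setdiff1d(perm, train)
            protos = others + [ClassPrototype(c, X[train].mean(axis=0), "data_mean")]
            pred = classify_batch(
                X[test], protos, imp, schema, cfg.params, class_order=classes
            )
            fold_rows[l] = _histogram(pred, classes)
        confusion[ci] = fold_rows.mean(axis=0)
        logger.info(
            "kshot class %d/%d class=%s k=%d folds=%d", ci + 1, len(classes), c, k, n_folds
        )
    return f_measures(confusion, classes)


def random_importance_baseline(
    X: np.ndarray,
    labels: Sequence[str],
    defs: PoseDefinitionTable,
    R: int = 1000,
    cfg: EvalConfig = EvalConfig(),
    schema: AttributeSchema | None = None,
) -> EvalResult:
    """Mean ZSL result over R random binary importance tables.

    Each repetition draws an independent fair coin per (class, joint);
    all-zero class rows are redrawn because the weighted metric is
    undefined at Wai = 0.  Per-class metrics and the confusion matrix are
    averaged over repetitions; fully seeded and reproducible.
    """
    if R < 1:
        raise ValueError("R must be >= 1")
    schema = schema or default_schema()
    rng = np.random.default_rng(cfg.seed)
    joints = schema.joint_names
    classes = list(defs.classes)
    per_class_sum = None
    confusion_sum = None
    weighted_cfg = EvalConfig("weighted", cfg.params, cfg.k, cfg.R, cfg.seed)
    for r in range(R):
        weights = {}
        for c in classes:
            row = rng.integers(0, 2, len(joints))
            while not row.any():
                row = rng.integers(0, 2, len(joints))
            weights[c] = dict(zip(joints, row.astype(float)))
        imp = ImportanceTable(tuple(classes), weights)
        res = loco_zsl_evaluate(X, labels, defs, imp, weighted_cfg, schema)
        per_class_sum = res.per_class if per_class_sum is None else per_class_sum + res.per_class
        confusion_sum = res.confusion if confusion_sum is None else confusion_sum + res.confusion
        logger.info("random-importance repetition %d/%d avgF=%.4f", r + 1, R, res.average_f)
    per_class = per_class_sum / R
    return EvalResult(per_class, float(per_class["f"].mean()), confusion_sum / R)
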