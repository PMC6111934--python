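"""Nearest-prototype classification with per-class attribute importance.

Two distances over the attribute space are provided.  The naive metric
treats every attribute equally (up to the range-equalising weight wrc):

    d(a, v) = ( sum_d wrc(d) |a_d - v_d|^p )^(1/p)

The importance-weighted metric additionally masks, per candidate class i,
the attribute dimensions that are not diagnostic for that class and
normalises by the number of valid joints Wai(i):

    d(a, v(i)) = (1/Wai(i)) ( sum_d wai(d,i) wrc(d) |a_d - v_d(i)|^p )^(1/p)
                 + lambda / Wai(i)

where wai(d,i) is copied from the per-joint importance of the joint that
dimension d belongs to, and Wai(i) is the sum of per-joint importances.
With binary weights and p = 1 the first term is the average wrc-scaled
deviation over the class's important joints; the lambda term penalises
classes defined by few joints.  Classification assigns the label of the
minimum-distance class prototype (mean vector for seen classes, expanded
definition row for unseen ones).
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .attribute_space import (
    AttributeSchema,
    ImportanceTable,
    expand_importance,
    importance_matrix,
    wrc_weights,
)

__all__ = [
    "DistanceParams",
    "ClassPrototype",
    "naive_distance",
    "weighted_distance",
    "compute_prototypes",
    "classify",
    "classify_batch",
    "save_prototypes",
    "load_prototypes",
]


@dataclass(frozen=True)
class DistanceParams:
    """Order ``p`` of the distance and penalty coefficient ``lam`` (λ)."""

    p: float = 1.0
    lam: float = 0.1

    def __post_init__(self) -> None:
        if self.p < 1:
            raise ValueError(f"distance order p must be >= 1, got {self.p}")
        if self.lam < 0:
            raise ValueError(f"penalty lambda must be >= 0, got {self.lam}")


@dataclass(frozen=True)
class ClassPrototype:
    """A labeled prototype vector: a class-definition row or a data mean."""

    label: str
    vector: np.ndarray
    source: str = "definition"  # "definition" | "data_mean"

    def __post_init__(self) -> None:
        if self.source not in ("definition", "data_mean"):
            raise ValueError(f"unknown prototype source {self.source!r}")
        object.__setattr__(self, "vector", np.asarray(self.vector, dtype=float))


def _check_dims(a: np.ndarray, v: np.ndarray, schema: AttributeSchema) -> None:
    if a.shape[-1] != schema.D or v.shape[-1] != schema.D:
        raise ValueError(
            f"dimension mismatch: expected {schema.D}, "
            f"got {a.shape[-1]} and {v.shape[-1]}"
        )


def naive_distance(
    a: np.ndarray,
    v: np.ndarray,
    schema: AttributeSchema,
    params: DistanceParams = DistanceParams(),
) -> float:
    """Importance-free distance with wrc range equalisation (no penalty term)."""
    a = np.asarray(a, dtype=float)
    v = np.asarray(v, dtype=float)
    _check_dims(a, v, schema)
    wrc = wrc_weights(schema)
    return float(np.sum(wrc * np.abs(a - v) ** params.p) ** (1.0 / params.p))


def weighted_distance(
    a: np.ndarray,
    proto: ClassPrototype | np.ndarray,
    importance_row: Mapping[str, float],
    schema: AttributeSchema,
    params: DistanceParams = DistanceParams(),
) -> float:
    """Importance-weighted distance of ``a`` to one class prototype.

    ``importance_row`` maps joint name -> weight in [0, 1] for the
    prototype's class.  Raises ValueError when all weights are zero
    (the metric is undefined at Wai = 0).
    """
    v = proto.vector if isinstance(proto, ClassPrototype) else np.asarray(proto, float)
    a = np.asarray(a, dtype=float)
    _check_dims(a, v, schema)
    w_dim, wai = expand_importance(importance_row, schema)
    wrc = wrc_weights(schema)
    core = np.sum(w_dim * wrc * np.abs(a - v) ** params.p) ** (1.0 / params.p)
    return float(core / wai + params.lam / wai)


def compute_prototypes(
    X: np.ndarray, labels: Sequence[str]
) -> list[ClassPrototype]:
    """Per-class mean vectors (one prototype per class, in first-seen order).

    The mean-vector representation keeps severely imbalanced classes from
    dominating the nearest-neighbour search.
    """
    X = np.asarray(X, dtype=float)
    labels = np.asarray(labels, dtype=object)
    if X.ndim != 2 or len(labels) != len(X):
        raise ValueError("X must be (n, D) with one label per row")
    if len(X) == 0:
        raise ValueError("no samples to build prototypes from")
    protos = []
    for lab in dict.fromkeys(labels):  # preserves first-seen order
        protos.append(
            ClassPrototype(str(lab), X[labels == lab].mean(axis=0), "data_mean")
        )
    return protos


def _distance_matrix(
    A: np.ndarray,
    V: np.ndarray,
    schema: AttributeSchema,
    params: DistanceParams,
    W_dim: np.ndarray | None,
    Wai: np.ndarray | None,
) -> np.ndarray:
    """(n, K) distances of samples A to prototype matrix V; vectorised."""
    wrc = wrc_weights(schema)
    diff = np.abs(A[:, None, :] - V[None, :, :]) ** params.p  # (n, K, D)
    if W_dim is None:
        return np.einsum("nkd,d->nk", diff, wrc) ** (1.0 / params.p)
    core = np.einsum("nkd,kd->nk", diff, W_dim * wrc) ** (1.0 / params.p)
    return core / Wai[None, :] + params.lam / Wai[None, :]


def classify_batch(
    A: np.ndarray,
    prototypes: Sequence[ClassPrototype],
    importance: ImportanceTable | None,
    schema: AttributeSchema,
    params: DistanceParams = DistanceParams(),
    class_order: Sequence[str] | None = None,
) -> np.ndarray:
    """Vectorised nearest-prototype labels for a batch of attribute vectors.

    Uses the weighted metric when an importance table is supplied, the
    naive metric otherwise.  Distance ties break towards the first class in
    canonical order — ``class_order`` if given, else the importance table's
    class order, else lexicographic — so the result does not depend on the
    order in which prototypes are supplied.
    """
    if len(prototypes) == 0:
        raise ValueError("need at least one prototype")
    A = np.atleast_2d(np.asarray(A, dtype=float))
    if A.shape[1] != schema.D:
        raise ValueError(f"dimension mismatch: expected D={schema.D}")
    protos = list(prototypes)
    if class_order is None and importance is not None:
        class_order = importance.classes
    if class_order is not None:
        order = {c: i for i, c in enumerate(class_order)}
        protos.sort(key=lambda pr: (order.get(pr.label, len(order)), pr.label))
    else:
        protos.sort(key=lambda pr: pr.label)
    V = np.stack([pr.vector for pr in protos])
    if importance is None:
        W_dim = Wai = None
    else:
        W_dim, Wai = importance_matrix(
            importance, schema, [pr.label for pr in protos]
        )
    d = _distance_matrix(A, V, schema, params, W_dim, Wai)
    labels = np.array([pr.label for pr in protos], dtype=object)
    return labels[np.argmin(d, axis=1)]  # argmin takes the first minimum


def save_prototypes(path, prototypes: Sequence[ClassPrototype]) -> None:
    """Write prototypes as CSV: label, source, one column per dimension."""
    import pandas as pd

    rows = [
        {"label": p.label, "source": p.source,
         **{f"d{i}": x for i, x in enumerate(p.vector)}}
        for p in prototypes
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def load_prototypes(path) -> list[ClassPrototype]:
    import pandas as pd

    df = pd.read_csv(path)
    dims = [c for c in df.columns if c.startswith("d")]
    return [
        ClassPrototype(r["label"], r[dims].to_numpy(dtype=float), r["source"])
        for _, r in df.iterrows()
    ]


def classify(
    a: np.ndarray,
    prototypes: Sequence[ClassPrototype],
    importance: ImportanceTable | None,
    schema: AttributeSchema,
    params: DistanceParams = DistanceParams(),
    class_order: Sequence[str] | None = None,
) -> str:
    """Nearest-prototype label for a single attribute vector."""
    a = np.asarray(a, dtype=float)
    return str(
        classify_batch(a[None, :], prototypes, importance, schema, params, class_order)[0]
    )
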