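"""Attribute-space schema and symbolic-table handling.

Human poses are represented in a D-dimensional attribute space built from
the states of 14 body joints.  Joints with several mutually exclusive
states (head, shoulders, hands, waist) are *classification* joints and
contribute one dimension per category (a probability simplex slice);
one-degree-of-freedom joints (elbows, wrists, hip joints, knees) are
*regression* joints and contribute a single scalar in [0, 1]
(0 = straight, 1 = bent).  With the default 14-joint schema D = 33.

Symbolic per-class tables — a pose-definition table (the semantic
description of every class) and a per-class, per-joint attribute-importance
table — are expanded here into numeric vectors and weights used by the
nearest-prototype classifier in :mod:`zspose.zsl_core`.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

SIMPLEX_TOL = 1e-6

_JOINT_KINDS = ("classification", "regression")


# ---------------------------------------------------------------------------
# schema
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class JointSpec:
    """One body joint and how its state is represented.

    Parameters
    ----------
    name
        Joint identifier, e.g. ``"S(L)"`` for the left shoulder.
    kind
        ``"classification"`` (simplex over ``categories``) or
        ``"regression"`` (single scalar in [0, 1]).
    categories
        Ordered category labels; empty for regression joints.
    sensor_ids
        IMU identifiers whose channels feed this joint's estimator.
    """

    name: str
    kind: str
    categories: tuple[str, ...] = ()
    sensor_ids: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.kind not in _JOINT_KINDS:
            raise ValueError(f"joint {self.name!r}: unknown kind {self.kind!r}")
        if self.kind == "regression" and self.categories:
            raise ValueError(f"regression joint {self.name!r} must not list categories")
        if self.kind == "classification" and len(self.categories) < 2:
            raise ValueError(
                f"classification joint {self.name!r} needs >=2 categories, "
                f"got {len(self.categories)}"
            )

    @property
    def dim(self) -> int:
        """Attribute dimensions contributed by this joint."""
        return len(self.categories) if self.kind == "classification" else 1


@dataclass(frozen=True)
class AttributeSchema:
    """Ordered joint layout mapping joints to slices of the attribute vector."""

    joints: tuple[JointSpec, ...]
    slices: dict[str, slice] = field(init=False, repr=False)
    D: int = field(init=False)

    def __post_init__(self) -> None:
        names = [j.name for j in self.joints]
        if len(set(names)) != len(names):
            dup = sorted({n for n in names if names.count(n) > 1})
            raise ValueError(f"duplicate joint name(s): {dup}")
        slices: dict[str, slice] = {}
        start = 0
        for j in self.joints:
            slices[j.name] = slice(start, start + j.dim)
            start += j.dim
        object.__setattr__(self, "slices", slices)
        object.__setattr__(self, "D", start)

    def __iter__(self):
        return iter(self.joints)

    def __len__(self) -> int:
        return len(self.joints)

    @property
    def joint_names(self) -> list[str]:
        return [j.name for j in self.joints]

    def joint(self, name: str) -> JointSpec:
        for j in self.joints:
            if j.name == name:
                return j
        raise KeyError(name)

    @property
    def sensor_ids(self) -> list[str]:
        """All sensors referenced by the schema, first-use order, deduplicated."""
        seen: dict[str, None] = {}
        for j in self.joints:
            for s in j.sensor_ids:
                seen.setdefault(s)
        return list(seen)


def _packaged(name: str) -> Path:
    return Path(str(resources.files("zspose.data").joinpath(name)))


def load_schema(path: str | Path) -> AttributeSchema:
    """Read a joint schema from CSV.

    Expected columns: ``joint``, ``kind``, ``categories`` (semicolon
    separated, ordered; empty for regression) and ``sensor_ids`` (semicolon
    separated).  Joint order in the file defines the attribute-vector layout.
    """
    df = pd.read_csv(path, dtype=str).fillna("")
    joints = []
    for _, row in df.iterrows():
        cats = tuple(c for c in row["categories"].split(";") if c)
        sensors = tuple(s for s in row["sensor_ids"].split(";") if s)
        joints.append(JointSpec(row["joint"], row["kind"].strip(), cats, sensors))
    return AttributeSchema(tuple(joints))


def default_schema() -> AttributeSchema:
    """The packaged 14-joint, 33-dimensional schema."""
    return load_schema(_packaged("table2_schema.csv"))


# ---------------------------------------------------------------------------
# symbolic tables
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PoseDefinitionTable:
    """Symbolic per-joint class definitions: one row per pose.

    ``values[pose][joint]`` is a category label for classification joints
    or a float in [0, 1] for regression joints.
    """

    classes: tuple[str, ...]
    values: Mapping[str, Mapping[str, str | float]]

    def row(self, pose: str) -> Mapping[str, str | float]:
        try:
            return self.values[pose]
        except KeyError:
            raise KeyError(f"pose {pose!r} not in definition table") from None


@dataclass(frozen=True)
class ImportanceTable:
    """Per-class, per-joint attribute importance weights in [0, 1]."""

    classes: tuple[str, ...]
    weights: Mapping[str, Mapping[str, float]]

    def row(self, pose: str) -> Mapping[str, float]:
        try:
            return self.weights[pose]
        except KeyError:
            raise KeyError(f"pose {pose!r} not in importance table") from None


def _load_pose_table(path: str | Path) -> tuple[tuple[str, ...], dict]:
    df = pd.read_csv(path)
    if "pose" not in df.columns:
        raise ValueError("pose table needs a 'pose' column")
    classes = tuple(df["pose"].astype(str))
    if len(set(classes)) != len(classes):
        raise ValueError("duplicate pose names in table")
    values = {
        str(row["pose"]): {c: row[c] for c in df.columns if c != "pose"}
        for _, row in df.iterrows()
    }
    return classes, values


def load_definitions(path: str | Path) -> PoseDefinitionTable:
    classes, values = _load_pose_table(path)
    return PoseDefinitionTable(classes, values)


def default_definitions() -> PoseDefinitionTable:
    """The packaged 22-pose definition table."""
    return load_definitions(_packaged("table3_definitions.csv"))


def load_importance(path: str | Path) -> ImportanceTable:
    classes, values = _load_pose_table(path)
    weights = {p: {j: float(v) for j, v in row.items()} for p, row in values.items()}
    for p, row in weights.items():
        for j, w in row.items():
            if not 0.0 <= w <= 1.0:
                raise ValueError(f"importance out of [0,1] for ({p!r}, {j!r}): {w}")
    return ImportanceTable(classes, weights)


def default_importance() -> ImportanceTable:
    """The packaged 22-pose importance table (binary)."""
    return load_importance(_packaged("table4_importance.csv"))


# ---------------------------------------------------------------------------
# expansion to numeric vectors / weights
# ---------------------------------------------------------------------------

def expand_pose_definition(
    row: Mapping[str, str | float], schema: AttributeSchema
) -> np.ndarray:
    """Expand one symbolic definition row to a length-D attribute vector.

    Classification joints become one-hot in the joint's category order
    (one-of-K); regression joints keep their stated scalar value.
    """
    out = np.zeros(schema.D)
    for j in schema:
        sl = schema.slices[j.name]
        if j.name not in row:
            raise KeyError(f"definition row is missing joint {j.name!r}")
        val = row[j.name]
        if j.kind == "classification":
            label = str(val)
            try:
                idx = j.categories.index(label)
            except ValueError:
                raise ValueError(
                    f"label {label!r} not a category of joint {j.name!r} "
                    f"(expected one of {j.categories})"
                ) from None
            out[sl.start + idx] = 1.0
        else:
            v = float(val)
            if not 0.0 <= v <= 1.0:
                raise ValueError(
                    f"regression value for joint {j.name!r} outside [0,1]: {v}"
                )
            out[sl.start] = v
    return out


def expand_definition_table(
    defs: PoseDefinitionTable, schema: AttributeSchema
) -> tuple[np.ndarray, list[str]]:
    """Expand every definition row; returns (n_classes, D) matrix + class order."""
    mat = np.stack([expand_pose_definition(defs.row(c), schema) for c in defs.classes])
    return mat, list(defs.classes)


def read_back_definition(
    vector: np.ndarray, schema: AttributeSchema
) -> dict[str, str | float]:
    """Inverse of :func:`expand_pose_definition` (argmax for classification)."""
    row: dict[str, str | float] = {}
    for j in schema:
        sl = schema.slices[j.name]
        if j.kind == "classification":
            row[j.name] = j.categories[int(np.argmax(vector[sl]))]
        else:
            row[j.name] = float(vector[sl.start])
    return row


def expand_importance(
    row: Mapping[str, float], schema: AttributeSchema
) -> tuple[np.ndarray, float]:
    """Per-dimension importance weights and the per-joint total Wai.

    Every attribute dimension inherits the weight of its parent joint;
    Wai is the sum of *per-joint* weights (the effective number of valid
    joints for the class), not the sum over dimensions.
    """
    w = np.zeros(schema.D)
    wai_total = 0.0
    for j in schema:
        if j.name not in row:
            raise KeyError(f"importance row is missing joint {j.name!r}")
        wj = float(row[j.name])
        if not 0.0 <= wj <= 1.0:
            raise ValueError(f"importance for joint {j.name!r} outside [0,1]: {wj}")
        w[schema.slices[j.name]] = wj
        wai_total += wj
    if wai_total == 0.0:
        raise ValueError("all-zero importance row: the class metric is undefined")
    return w, wai_total


def importance_matrix(
    imp: ImportanceTable, schema: AttributeSchema, classes: Sequence[str] | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Stack per-dimension weights / Wai totals for a list of classes."""
    classes = list(imp.classes) if classes is None else list(classes)
    rows = [expand_importance(imp.row(c), schema) for c in classes]
    return np.stack([r[0] for r in rows]), np.array([r[1] for r in rows])


def wrc_weights(schema: AttributeSchema) -> np.ndarray:
    """Range-equalising per-dimension weights.

    A classification joint's simplex slice has L1 diameter 2 while a
    regression dimension has diameter 1, so classification dimensions get
    0.5 and regression dimensions 1.0.
    """
    w = np.empty(schema.D)
    for j in schema:
        w[schema.slices[j.name]] = 1.0 if j.kind == "regression" else 0.5
    return w


def validate_attribute_vector(
    v: np.ndarray, schema: AttributeSchema, tol: float = SIMPLEX_TOL
) -> None:
    """Raise ValueError unless ``v`` is a valid attribute vector.

    Checks length D, all elements in [0, 1], and each classification
    joint's slice summing to 1 within ``tol``.
    """
    v = np.asarray(v)
    if v.shape != (schema.D,):
        raise ValueError(f"expected shape ({schema.D},), got {v.shape}")
    if np.any(v < -tol) or np.any(v > 1 + tol):
        raise ValueError("attribute values outside [0,1]")
    for j in schema:
        if j.kind == "classification":
            s = float(v[schema.slices[j.name]].sum())
            if abs(s - 1.0) > tol:
                raise ValueError(
                    f"slice of classification joint {j.name!r} sums to {s}, not 1"
                )


# ---------------------------------------------------------------------------
# labeled attribute-sample CSV I/O
# ---------------------------------------------------------------------------

def attribute_columns(schema: AttributeSchema) -> list[str]:
    cols = []
    for j in schema:
        if j.kind == "classification":
            cols += [f"{j.name}:{c}" for c in j.categories]
        else:
            cols.append(j.name)
    return cols


def save_attribute_samples(
    path: str | Path,
    X: np.ndarray,
    labels: Iterable[str],
    schema: AttributeSchema,
    subjects: Iterable[str] | None = None,
) -> None:
    """Write labeled attribute vectors as CSV (one row per window)."""
    X = np.asarray(X)
    df = pd.DataFrame(X, columns=attribute_columns(schema))
    df["label"] = list(labels)
    df["subject"] = list(subjects) if subjects is not None else ""
    df.to_csv(path, index=False)


def load_attribute_samples(
    path: str | Path, schema: AttributeSchema
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Read labeled attribute vectors; returns (X, labels, subjects)."""
    df = pd.read_csv(path)
    cols = attribute_columns(schema)
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ValueError(f"attribute CSV missing columns: {missing}")
    X = df[cols].to_numpy(dtype=float)
    labels = df["label"].to_numpy(dtype=object)
    subjects = (
        df["subject"].to_numpy(dtype=object)
        if "subject" in df.columns
        else np.full(len(df), "", dtype=object)
    )
    return X, labels, subjects
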