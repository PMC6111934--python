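"""End-to-end plumbing: recordings -> trained estimators -> attributes.

Convenience layer used by the CLI, the examples and the acceptance run;
everything here is a thin composition of :mod:`zspose.attribute_cnn`.
"""
from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np

from .attribute_cnn import (
    JointEstimator,
    Recording,
    TrainConfig,
    estimate_attributes,
    sliding_windows,
    train_all_estimators,
)
from .attribute_space import AttributeSchema, PoseDefinitionTable

__all__ = [
    "default_training_profile",
    "train_attribute_pipeline",
    "corpus_attribute_estimates",
    "joint_recovery_metrics",
]


def default_training_profile(seed: int = 0) -> dict[str, tuple[TrainConfig, int]]:
    """Per-joint-group (TrainConfig, window cap) defaults for corpus training.

    The sensor-dense hand estimators are the costly ones; they get a lower
    window cap, fewer epochs and the more conservative learning rate their
    large fully-connected layer needs.
    """
    return {
        "hand": (TrainConfig(epochs=6, batch_size=32, lr=0.01, seed=seed), 250),
        "classification": (TrainConfig(epochs=8, batch_size=32, lr=0.02, seed=seed), 400),
        "regression": (TrainConfig(epochs=8, batch_size=32, lr=0.02, seed=seed), 400),
    }


def train_attribute_pipeline(
    train_recs: Sequence[Recording],
    defs: PoseDefinitionTable,
    schema: AttributeSchema,
    seed: int = 0,
    profile: Mapping[str, tuple[TrainConfig, int]] | None = None,
) -> dict[str, JointEstimator]:
    """Train all 14 joint estimators with per-joint-group settings."""
    profile = profile or default_training_profile(seed)
    models: dict[str, JointEstimator] = {}
    for j in schema:
        if j.name.startswith("Ha"):
            group = "hand"
        elif j.kind == "classification":
            group = "classification"
        else:
            group = "regression"
        config, cap = profile[group]
        sub = AttributeSchema((j,))
        models.update(train_all_estimators(train_recs, defs, sub, config, cap))
    return models


def corpus_attribute_estimates(
    models: Mapping[str, JointEstimator],
    recs: Sequence[Recording],
    schema: AttributeSchema,
) -> tuple[np.ndarray, np.ndarray]:
    """Estimated attribute vectors + pose labels for a recording corpus."""
    xs, labels = [], []
    for rec in recs:
        A = estimate_attributes(models, rec, schema)
        xs.append(A)
        labels += [rec.label] * len(A)
    return np.concatenate(xs), np.asarray(labels, dtype=object)


def joint_recovery_metrics(
    models: Mapping[str, JointEstimator],
    recs: Sequence[Recording],
    schema: AttributeSchema,
) -> dict[str, dict[str, float]]:
    """Held-out per-joint recovery: accuracy for classification joints,
    mean absolute error for regression joints, against each recording's
    ground-truth states."""
    out: dict[str, dict[str, float]] = {}
    for j in schema:
        correct, err, n = 0.0, 0.0, 0
        for rec in recs:
            if rec.states is None:
                raise ValueError("recordings need ground-truth states")
            wins = sliding_windows(rec)[:, :, rec.channel_indices(j.sensor_ids)]
            pred = models[j.name].predict(wins)
            if j.kind == "classification":
                target = j.categories.index(str(rec.states[j.name]))
                correct += float(np.sum(pred.argmax(axis=1) == target))
            else:
                err += float(np.sum(np.abs(pred - float(rec.states[j.name]))))
            n += len(wins)
        out[j.name] = (
            {"accuracy": correct / n} if j.kind == "classification" else {"mae": err / n}
        )
    return out
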