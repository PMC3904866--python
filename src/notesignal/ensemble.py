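"""Model ensembles and the cascaded three-way risk classifier.

Two binary tasks are derived from the three cohorts by group
combination:

* task ``A``: cohort 1 (non-mental-health control) vs cohorts {2, 3};
* task ``B``: cohort 2 (suicide) vs cohorts {1, 3}.

Each task gets an ensemble of independently seeded GP models whose
majority vote is the task prediction (vote fractions are exposed for
score-based use).  The cascade applies A first: a patient recognized as
group 1 is labeled 1; otherwise B decides between label 2 and label 3.
A tied vote predicts the positive (differentiated, clinically riskier)
class — a screening application favors sensitivity.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .gp import (
    GPParams,
    TrainedModel,
    _eval_mask,
    _mask_to_array,
    _max_feature,
    matrix_to_masks,
    train_model,
)

log = logging.getLogger("notesignal")

TASK_A = "A"  # cohort 1 vs {2,3}
TASK_B = "B"  # cohort 2 vs {1,3}

_POSITIVE_COHORT = {TASK_A: 1, TASK_B: 2}

__all__ = [
    "TASK_A",
    "TASK_B",
    "relabel",
    "Ensemble",
    "train_ensemble",
    "predict_ensemble",
    "CascadeClassifier",
    "predict_cascade",
]


def relabel(labels, task: str) -> np.ndarray:
    """Map cohort labels {1,2,3} to the binary labels of one task.

    Task A: 1 -> 1, {2,3} -> 0.  Task B: 2 -> 1, {1,3} -> 0.
    """
    if task not in _POSITIVE_COHORT:
        raise ValueError(f"unknown task {task!r}")
    labels = np.asarray(labels)
    bad = set(np.unique(labels)) - {1, 2, 3}
    if bad:
        raise ValueError(f"unknown cohort labels {sorted(bad)}")
    return (labels == _POSITIVE_COHORT[task]).astype(np.int64)


@dataclass
class Ensemble:
    """Independently seeded models for one binary task, majority-voted."""

    models: tuple[TrainedModel, ...]
    task: str
    feature_names: tuple[str, ...] = ()
    tie_break: int = 1  # predicted class at vote_fraction exactly 0.5

    def __post_init__(self) -> None:
        if not self.models:
            raise ValueError("ensemble needs >= 1 model")
        tags = {m.task for m in self.models}
        if tags != {self.task}:
            raise ValueError(f"model task tags {tags} do not all match {self.task!r}")

    def __len__(self) -> int:
        return len(self.models)

    def seeds(self) -> list[int]:
        return [m.seed for m in self.models]

    def predict_matrix(self, matrix_binary) -> tuple[np.ndarray, np.ndarray]:
        """Vote fraction and 0/1 prediction for every row of a matrix."""
        cols, n, full = matrix_to_masks(matrix_binary)
        votes = np.zeros(n, dtype=np.int64)
        for m in self.models:
            if _max_feature(m.program.tree) >= len(cols):
                raise IndexError("model references a feature beyond the matrix")
            votes += _mask_to_array(_eval_mask(m.program.tree, cols, full), n)
        frac = votes / len(self.models)
        if self.tie_break == 1:
            pred = (frac >= 0.5).astype(np.int64)
        else:
            pred = (frac > 0.5).astype(np.int64)
        return frac, pred

    def predict_row(self, row) -> tuple[float, int]:
        frac, pred = self.predict_matrix(np.asarray(row).reshape(1, -1))
        return float(frac[0]), int(pred[0])


def train_ensemble(
    matrix_binary,
    binary_labels,
    n_models: int,
    base_seed: int,
    params: GPParams = GPParams(),
    *,
    task: str,
    feature_names=(),
) -> Ensemble:
    """Train ``n_models`` GP models; model i uses seed ``base_seed + i``."""
    if n_models < 1:
        raise ValueError("n_models must be >= 1")
    models = []
    for i in range(n_models):
        p = GPParams(
            population_size=params.population_size,
            generations=params.generations,
            tournament_size=params.tournament_size,
            crossover_rate=params.crossover_rate,
            mutation_rate=params.mutation_rate,
            max_depth=params.max_depth,
            parsimony_lambda=params.parsimony_lambda,
            seed=base_seed + i,
        )
        models.append(train_model(matrix_binary, binary_labels, p, task=task))
    return Ensemble(tuple(models), task, tuple(feature_names))


def predict_ensemble(ensemble: Ensemble, binary_row) -> tuple[float, int]:
    """(vote_fraction, prediction) for one patient row; ties go positive."""
    return ensemble.predict_row(binary_row)


@dataclass
class CascadeClassifier:
    """Two binary ensembles composed into the 1v2v3 risk classifier."""

    ensemble_a: Ensemble
    ensemble_b: Ensemble

    def __post_init__(self) -> None:
        if self.ensemble_a.task != TASK_A or self.ensemble_b.task != TASK_B:
            raise ValueError("cascade needs ensembles tagged A and B, in order")

    def predict(self, row_a, row_b) -> int:
        return predict_cascade(self, row_a, row_b)

    def predict_matrix(self, matrix_a, matrix_b) -> np.ndarray:
        """Cohort predictions in {1,2,3} for aligned task-A/task-B rows."""
        _, pa = self.ensemble_a.predict_matrix(matrix_a)
        _, pb = self.ensemble_b.predict_matrix(matrix_b)
        out = np.full(pa.shape, 3, dtype=np.int64)
        out[pb == 1] = 2
        out[pa == 1] = 1
        return out


def predict_cascade(cascade: CascadeClassifier, row_a, row_b) -> int:
    """Group 1 if task A says so; else group 2 if task B says so; else 3.

    ``row_a`` / ``row_b`` use each task's own selected vocabulary.
    """
    _, pa = cascade.ensemble_a.predict_row(row_a)
    if pa == 1:
        return 1
    _, pb = cascade.ensemble_b.predict_row(row_b)
    return 2 if pb == 1 else 3
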