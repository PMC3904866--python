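"""Cross-validation harness, score histograms and informative features.

The harness runs patient-level stratified k-fold cross-validation of the
full pipeline: feature selection is re-run on the training folds only
(selecting on the full dataset in CV mode is a hard error — it leaks the
held-out labels), an ensemble is trained per binary task, and the
cascade's held-out three-way accuracy is averaged over folds.  Per-model
held-out scores are kept so score distributions can be histogrammed by
model type (unigram vs word-pair).

Informative-feature extraction assigns each high-MI term to the cohort
whose patients carry it most and ranks terms by that frequency — the
data behind per-cohort word-cloud style term lists.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from sklearn.model_selection import KFold, StratifiedKFold

from .ensemble import (
    TASK_A,
    TASK_B,
    CascadeClassifier,
    Ensemble,
    relabel,
    train_ensemble,
)
from .features import (
    ClinicalNote,
    FeatureMatrix,
    PatientDocument,
    Vocabulary,
    aggregate_patients,
    binarize,
    count_pairs,
    count_unigrams,
)
from .gp import GPParams, _eval_mask, _mask_to_array, matrix_to_masks
from .selection import PairFilterRules, filter_pairs, rank_features, select_top_k

log = logging.getLogger("notesignal")

__all__ = [
    "CVConfig",
    "CVReport",
    "ScoreHistogram",
    "FeatureReport",
    "kfold_split",
    "cross_validate",
    "score_histogram",
    "extract_informative_features",
    "permutation_null",
    "LeakageError",
]


class LeakageError(RuntimeError):
    """Raised when CV is asked to reuse features selected on full data."""


def kfold_split(
    patient_ids,
    labels,
    k: int,
    seed: int = 0,
    stratified: bool = True,
) -> list[np.ndarray]:
    """Partition patient ids into k test folds (sizes differ by <= 1).

    Stratified mode preserves per-cohort proportions within +-1 per fold.
    Returns the list of test-id arrays; their union is the id set and
    they are pairwise disjoint.
    """
    patient_ids = np.asarray(patient_ids)
    labels = np.asarray(labels)
    if k < 2:
        raise ValueError("k must be >= 2")
    if k > len(patient_ids):
        raise ValueError(f"k={k} exceeds {len(patient_ids)} patients")
    if stratified:
        splitter = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    else:
        splitter = KFold(n_splits=k, shuffle=True, random_state=seed)
    return [patient_ids[test] for _, test in splitter.split(patient_ids, labels)]


@dataclass(frozen=True)
class CVConfig:
    """Everything one cross-validated pipeline run needs."""

    k: int = 5
    stratified: bool = True
    seed: int = 0
    feature_kind: str = "unigram"  # "unigram" | "pair"
    pair_mode: str = "adjacent"
    select_k: int = 2000
    binarize_threshold: int = 1
    pair_rules: PairFilterRules = field(default_factory=PairFilterRules)
    gp: GPParams = field(default_factory=GPParams)
    n_models: int = 100
    base_seed: int = 1000
    tasks: tuple[str, ...] = (TASK_A, TASK_B)
    dry_run: bool = False
    strip_table_lines: bool = False
    fixed_vocabulary: Vocabulary | None = None

    def validate(self) -> None:
        if self.feature_kind not in ("unigram", "pair"):
            raise ValueError(f"unknown feature kind {self.feature_kind!r}")
        if self.select_k < 1 or self.n_models < 1:
            raise ValueError("select_k and n_models must be >= 1")
        self.gp.validate()
        self.pair_rules.validate()
        unknown = set(self.tasks) - {TASK_A, TASK_B}
        if unknown:
            raise ValueError(f"unknown tasks {unknown}")


@dataclass
class CVReport:
    """Bookkeeping and scores of one cross-validated run."""

    k: int
    feature_kind: str
    n_models: int
    fold_test_ids: list[list[str]]
    model_scores: dict[str, list[list[float]]]  # task -> per fold -> per model
    ensemble_scores: dict[str, list[float]]  # task -> per-fold binary accuracy
    cascade_scores: list[float]  # per-fold 3-way accuracy
    cascade_balanced: list[float]  # per-fold mean per-class recall
    total_models_per_task: int
    dry_run: bool = False
    pair_filter_reports: list[dict[str, int]] = field(default_factory=list)

    @property
    def mean_cascade_accuracy(self) -> float:
        return float(np.mean(self.cascade_scores)) if self.cascade_scores else float("nan")

    @property
    def mean_balanced_accuracy(self) -> float:
        return float(np.mean(self.cascade_balanced)) if self.cascade_balanced else float("nan")

    def all_model_scores(self, task: str | None = None) -> list[float]:
        tasks = [task] if task else sorted(self.model_scores)
        return [s for t in tasks for fold in self.model_scores[t] for s in fold]

    def summary(self) -> dict:
        out = {
            "k": self.k,
            "feature_kind": self.feature_kind,
            "n_models": self.n_models,
            "total_models_per_task": self.total_models_per_task,
            "dry_run": self.dry_run,
            "mean_cascade_accuracy": self.mean_cascade_accuracy,
            "mean_balanced_accuracy": self.mean_balanced_accuracy,
            "cascade_fold_accuracies": list(self.cascade_scores),
        }
        for t in sorted(self.ensemble_scores):
            scores = self.all_model_scores(t)
            out[f"task_{t}_mean_ensemble_accuracy"] = (
                float(np.mean(self.ensemble_scores[t]))
                if self.ensemble_scores[t]
                else float("nan")
            )
            if scores:
                out[f"task_{t}_model_score_mean"] = float(np.mean(scores))
                out[f"task_{t}_model_score_range"] = [
                    float(np.min(scores)),
                    float(np.max(scores)),
                ]
        return out


def _holdout_model_scores(
    models, test_matrix_binary, y_test: np.ndarray
) -> list[float]:
    cols, n, full = matrix_to_masks(test_matrix_binary)
    out = []
    for m in models:
        pred = _mask_to_array(_eval_mask(m.program.tree, cols, full), n)
        out.append(float(np.mean(pred == y_test)))
    return out


def _select_task_features(
    train_docs: list[PatientDocument],
    train_unigrams: FeatureMatrix,
    y_train: np.ndarray,
    config: CVConfig,
) -> tuple[list[str], FeatureMatrix | None, dict[str, int] | None]:
    """Per-task feature selection on training data only."""
    mi = rank_features(
        train_unigrams, y_train, binarize_threshold=config.binarize_threshold
    )
    if config.feature_kind == "unigram":
        return select_top_k(mi, config.select_k), None, None
    pair_train = count_pairs(train_docs, config.pair_mode)
    retained, report = filter_pairs(pair_train, mi, y_train, config.pair_rules)
    if not retained:
        raise ValueError("pair filter removed every pair; relax the rules")
    if len(retained) > config.select_k:
        pair_mi = rank_features(
            FeatureMatrix(
                pair_train.row_ids,
                Vocabulary(tuple(retained), "pair"),
                pair_train.counts[:, [pair_train.vocab.index[n] for n in retained]],
            ),
            y_train,
            binarize_threshold=config.binarize_threshold,
        )
        retained = select_top_k(pair_mi, config.select_k)
    return retained, pair_train, report


def _task_matrices(
    docs: list[PatientDocument],
    selected: list[str],
    config: CVConfig,
    unigram_matrix: FeatureMatrix | None = None,
) -> FeatureMatrix:
    vocab = Vocabulary(tuple(selected), config.feature_kind)
    if config.feature_kind == "unigram":
        if unigram_matrix is not None:
            cols = [unigram_matrix.vocab.index[n] for n in selected]
            return binarize(
                FeatureMatrix(
                    unigram_matrix.row_ids,
                    vocab,
                    unigram_matrix.counts[:, cols],
                    unigram_matrix.labels,
                ),
                config.binarize_threshold,
            )
        return binarize(count_unigrams(docs, vocab), config.binarize_threshold)
    return binarize(count_pairs(docs, config.pair_mode, vocab), config.binarize_threshold)


def cross_validate(
    notes: list[ClinicalNote] | list[PatientDocument],
    config: CVConfig = CVConfig(),
) -> CVReport:
    """k-fold cross-validate the full pipeline; average over folds.

    Feature vocabularies are recomputed from each training fold alone.
    ``config.dry_run`` skips GP training and records the bookkeeping only
    (folds, model counts), useful to audit experiment size cheaply.
    """
    config.validate()
    if config.fixed_vocabulary is not None:
        raise LeakageError(
            "CV mode must re-select features per training fold; a fixed "
            "vocabulary selected on the full dataset leaks held-out labels"
        )
    if notes and isinstance(notes[0], ClinicalNote):
        docs = aggregate_patients(notes, strip_table_lines=config.strip_table_lines)
    else:
        docs = list(notes)
    if any(d.cohort is None for d in docs):
        raise ValueError("cross-validation requires cohort labels on every patient")
    ids = np.array([d.patient_id for d in docs])
    labels = np.array([d.cohort for d in docs], dtype=np.int64)
    by_id = {d.patient_id: d for d in docs}

    folds = kfold_split(ids, labels, config.k, config.seed, config.stratified)
    tasks = [t for t in (TASK_A, TASK_B) if t in config.tasks]

    report = CVReport(
        k=config.k,
        feature_kind=config.feature_kind,
        n_models=config.n_models,
        fold_test_ids=[list(map(str, f)) for f in folds],
        model_scores={t: [] for t in tasks},
        ensemble_scores={t: [] for t in tasks},
        cascade_scores=[],
        cascade_balanced=[],
        total_models_per_task=config.k * config.n_models,
        dry_run=config.dry_run,
    )

    for fold_idx, test_ids in enumerate(folds):
        test_set = set(map(str, test_ids))
        train_docs = [d for d in docs if d.patient_id not in test_set]
        test_docs = [by_id[str(t)] for t in test_ids]
        y3_test = np.array([d.cohort for d in test_docs], dtype=np.int64)
        train_unigrams = count_unigrams(train_docs)
        y3_train = np.array([d.cohort for d in train_docs], dtype=np.int64)

        ensembles: dict[str, Ensemble] = {}
        test_mats: dict[str, FeatureMatrix] = {}
        for task in tasks:
            y_train = relabel(y3_train, task)
            selected, _, pair_report = _select_task_features(
                train_docs, train_unigrams, y_train, config
            )
            if pair_report is not None:
                report.pair_filter_reports.append(pair_report)
            if config.dry_run:
                continue
            train_x = _task_matrices(train_docs, selected, config, train_unigrams)
            test_x = _task_matrices(test_docs, selected, config)
            ens = train_ensemble(
                train_x.counts,
                y_train,
                config.n_models,
                config.base_seed + fold_idx * config.n_models,
                config.gp,
                task=task,
                feature_names=selected,
            )
            y_test = relabel(y3_test, task)
            report.model_scores[task].append(
                _holdout_model_scores(ens.models, test_x.counts, y_test)
            )
            _, pred = ens.predict_matrix(test_x.counts)
            report.ensemble_scores[task].append(float(np.mean(pred == y_test)))
            ensembles[task] = ens
            test_mats[task] = test_x

        if config.dry_run or set(tasks) != {TASK_A, TASK_B}:
            continue
        cascade = CascadeClassifier(ensembles[TASK_A], ensembles[TASK_B])
        pred3 = cascade.predict_matrix(
            test_mats[TASK_A].counts, test_mats[TASK_B].counts
        )
        report.cascade_scores.append(float(np.mean(pred3 == y3_test)))
        recalls = [
            float(np.mean(pred3[y3_test == c] == c))
            for c in np.unique(y3_test)
        ]
        report.cascade_balanced.append(float(np.mean(recalls)))
        log.info(
            "fold %d/%d: cascade accuracy %.3f",
            fold_idx + 1,
            config.k,
            report.cascade_scores[-1],
        )

    return report


@dataclass
class ScoreHistogram:
    """Fixed-width histogram of individual model held-out scores."""

    bin_edges: np.ndarray
    series: dict[str, np.ndarray]  # model type -> counts per bin

    def to_frame(self) -> pd.DataFrame:
        frame = pd.DataFrame(
            {"bin_left": self.bin_edges[:-1], "bin_right": self.bin_edges[1:]}
        )
        for name, counts in self.series.items():
            frame[name] = counts
        return frame


def score_histogram(
    reports: CVReport | list[CVReport], bin_width: float = 0.05
) -> ScoreHistogram:
    """Histogram model scores over [0,1], one series per model type."""
    if isinstance(reports, CVReport):
        reports = [reports]
    if not 0 < bin_width <= 1:
        raise ValueError("bin_width must be in (0,1]")
    n_bins = int(round(1.0 / bin_width))
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    series: dict[str, np.ndarray] = {}
    for rep in reports:
        scores = rep.all_model_scores()
        counts, _ = np.histogram(scores, bins=edges)
        if rep.feature_kind in series:
            series[rep.feature_kind] = series[rep.feature_kind] + counts
        else:
            series[rep.feature_kind] = counts
    return ScoreHistogram(edges, series)


@dataclass
class FeatureReport:
    """Frequency-ranked informative terms per cohort (word-cloud data)."""

    cohorts: dict[int, list[tuple[str, int]]]
    dropped_ties: list[str] = field(default_factory=list)


def extract_informative_features(
    mi_table: pd.DataFrame,
    top_n: int,
    *,
    n_top_mi: int | None = None,
) -> FeatureReport:
    """Assign high-MI terms to the cohort where they occur most.

    Takes the ``n_top_mi`` highest-MI rows (all rows by default), assigns
    each term to the cohort with the strictly greatest document
    frequency (ties are dropped and logged), sorts within cohort by that
    frequency descending, and caps each list at ``top_n``.
    """
    if top_n < 0:
        raise ValueError("top_n must be >= 0")
    df_cols = [c for c in mi_table.columns if c.startswith("df_") and c != "df_total"]
    if not df_cols:
        raise ValueError("MI table lacks per-cohort document frequencies")
    cohort_of_col = {c: int(c.split("_", 1)[1]) for c in df_cols}
    rows = mi_table.head(n_top_mi) if n_top_mi is not None else mi_table

    assigned: dict[int, list[tuple[str, int]]] = {
        cohort_of_col[c]: [] for c in df_cols
    }
    dropped: list[str] = []
    for _, row in rows.iterrows():
        freqs = {cohort_of_col[c]: int(row[c]) for c in df_cols}
        best = max(freqs.values())
        winners = [c for c, v in freqs.items() if v == best]
        if len(winners) != 1:
            dropped.append(str(row["feature"]))
            continue
        assigned[winners[0]].append((str(row["feature"]), best))
    if dropped:
        log.info("informative features: %d term(s) dropped as frequency ties", len(dropped))
    for c in assigned:
        assigned[c].sort(key=lambda tf: (-tf[1], tf[0]))
        assigned[c] = assigned[c][:top_n]
    return FeatureReport(cohorts=assigned, dropped_ties=dropped)


def permutation_null(
    notes: list[ClinicalNote],
    config: CVConfig,
    n_permutations: int,
    seed: int = 0,
) -> np.ndarray:
    """Mean cascade accuracies of CV runs with cohort labels permuted.

    Labels are shuffled at the patient level (every note of a patient
    keeps the same permuted label), which preserves note-volume structure
    while destroying any text-label association.
    """
    rng = np.random.default_rng(seed)
    docs = aggregate_patients(notes, strip_table_lines=config.strip_table_lines)
    pids = [d.patient_id for d in docs]
    labels = np.array([d.cohort for d in docs], dtype=np.int64)
    out = []
    for i in range(n_permutations):
        perm = rng.permutation(labels)
        permuted = [
            replace(d, cohort=int(c), _counter=d._counter)
            for d, c in zip(docs, perm)
        ]
        rep = cross_validate(permuted, replace(config, seed=config.seed + i))
        out.append(rep.mean_cascade_accuracy)
    return np.array(out)
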