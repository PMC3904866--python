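"""Mutual-information feature ranking and word-pair filtering.

Features are scored by the plug-in mutual information (in bits) between
their binarized presence and the class label, estimated from the
empirical contingency table.  The dimensionality cut keeps the few
thousand highest-MI features.  Word pairs additionally pass a staged
exclusion process: a pair must contain a word that itself ranks highly,
must not be rare, must clear an MI floor, and must show a statistically
significant class association.

MI is computed on presence/absence by default (count >= threshold); an
optional quantile-binned variant on raw counts is available via
``scheme="quantile"``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy import stats

from .features import PAIR_SEP, FeatureMatrix

log = logging.getLogger("notesignal")

__all__ = [
    "mutual_information",
    "mi_from_table",
    "rank_features",
    "select_top_k",
    "association_test",
    "PairFilterRules",
    "filter_pairs",
]


def mi_from_table(table: np.ndarray) -> float:
    """Plug-in mutual information (bits) of a contingency table."""
    t = np.asarray(table, dtype=np.float64)
    n = t.sum()
    if n == 0:
        return 0.0
    p = t / n
    pr = p.sum(axis=1, keepdims=True)
    pc = p.sum(axis=0, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = p * np.log2(p / (pr * pc))
    return float(np.nansum(terms))


def _contingency(column: np.ndarray, labels: np.ndarray) -> np.ndarray:
    classes = np.unique(labels)
    values = np.unique(column)
    table = np.zeros((len(values), len(classes)))
    for i, v in enumerate(values):
        for j, c in enumerate(classes):
            table[i, j] = np.sum((column == v) & (labels == c))
    return table


def mutual_information(column: np.ndarray, labels: np.ndarray) -> float:
    """MI in bits between a feature column and the class label.

    The column is typically binary presence/absence but any discrete
    values are accepted.  Constant columns score 0.
    """
    column = np.asarray(column)
    labels = np.asarray(labels)
    if column.shape != labels.shape:
        raise ValueError(
            f"length mismatch: column {column.shape} vs labels {labels.shape}"
        )
    return mi_from_table(_contingency(column, labels))


def _mi_binary_bulk(df_by_class: np.ndarray, class_counts: np.ndarray) -> np.ndarray:
    """Vectorized plug-in MI for many binary features.

    ``df_by_class``: (n_classes, n_features) presence counts;
    ``class_counts``: (n_classes,) rows per class.
    """
    n = class_counts.sum()
    n1c = df_by_class.astype(np.float64)  # present
    n0c = class_counts[:, None] - n1c  # absent
    joint = np.stack([n0c, n1c])  # (2, n_classes, n_features)
    p = joint / n
    p_feat = p.sum(axis=1, keepdims=True)  # (2, 1, n_features)
    p_class = (class_counts / n)[None, :, None]
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = p * np.log2(p / (p_feat * p_class))
    return np.nansum(terms, axis=(0, 1))


def rank_features(
    matrix: FeatureMatrix,
    labels: np.ndarray | None = None,
    *,
    binarize_threshold: int = 1,
    scheme: str = "presence",
    n_bins: int = 4,
) -> pd.DataFrame:
    """Score every feature by MI with the label; sort descending.

    Ties are broken lexicographically by feature name.  The returned
    frame carries per-class document frequencies (``df_<label>``) and the
    overall document frequency.  ``scheme="quantile"`` bins raw counts at
    per-feature quantiles instead of binarizing.
    """
    if labels is None:
        labels = matrix.labels
    if labels is None:
        raise ValueError("labels are required (matrix has none attached)")
    labels = np.asarray(labels)
    if labels.shape[0] != matrix.shape[0]:
        raise ValueError("labels must align with matrix rows")
    classes = np.unique(labels)
    present = sp.csr_matrix((matrix.counts >= binarize_threshold).astype(np.int64))
    class_ind = np.stack([(labels == c) for c in classes]).astype(np.int64)
    df_by_class = np.asarray(class_ind @ present)  # (n_classes, n_features)
    class_counts = class_ind.sum(axis=1)

    if len(classes) < 2:
        log.warning("single-class labels: all MI values are 0")
        mi = np.zeros(matrix.shape[1])
    elif scheme == "presence":
        mi = _mi_binary_bulk(df_by_class, class_counts)
    elif scheme == "quantile":
        dense = matrix.toarray()
        qs = np.linspace(0, 1, n_bins + 1)[1:-1]
        mi = np.empty(matrix.shape[1])
        for j in range(matrix.shape[1]):
            col = dense[:, j]
            edges = np.unique(np.quantile(col, qs))
            binned = np.searchsorted(edges, col, side="right")
            mi[j] = mutual_information(binned, labels)
    else:
        raise ValueError(f"unknown MI scheme {scheme!r}")

    frame = pd.DataFrame(
        {
            "feature": matrix.vocab.names,
            "mi_bits": np.maximum(mi, 0.0),
            "df_total": df_by_class.sum(axis=0),
        }
    )
    for c, row in zip(classes, df_by_class):
        frame[f"df_{int(c)}"] = row
    frame = frame.sort_values(
        ["mi_bits", "feature"], ascending=[False, True], kind="mergesort"
    ).reset_index(drop=True)
    return frame


def select_top_k(mi_table: pd.DataFrame, k: int) -> list[str]:
    """Names of the top-k features of a ranked MI table."""
    if k < 1:
        raise ValueError("k must be >= 1")
    return mi_table["feature"].head(k).tolist()


def association_test(
    column: np.ndarray, labels: np.ndarray
) -> tuple[float, float]:
    """Chi-squared test of independence on the presence x class table.

    Yates' continuity correction is applied for 2x2 tables (the standard
    1-df correction).  Degenerate margins (constant column or single
    class) give (0.0, 1.0).
    """
    column = np.asarray(column)
    labels = np.asarray(labels)
    if column.shape != labels.shape:
        raise ValueError("length mismatch between column and labels")
    table = _contingency(column, labels)
    if table.shape[0] < 2 or table.shape[1] < 2:
        return 0.0, 1.0
    stat, p, _, _ = stats.chi2_contingency(table, correction=(table.shape == (2, 2)))
    return float(stat), float(p)


@dataclass(frozen=True)
class PairFilterRules:
    """Thresholds of the staged word-pair exclusion process.

    seed_top_m: a pair is eligible only if one member word is among the
        top-m unigrams by MI ("already correlated well with the cohort").
    min_doc_freq: minimum number of patients containing the pair.
    mi_floor: minimum pair MI in bits.
    alpha: significance level for the per-pair chi-squared test.
    bh_correct: apply Benjamini-Hochberg across surviving pairs before
        the alpha cut (off by default).
    """

    seed_top_m: int = 500
    min_doc_freq: int = 3
    mi_floor: float = 0.0
    alpha: float = 0.05
    bh_correct: bool = False

    def validate(self) -> None:
        if self.seed_top_m < 0 or self.min_doc_freq < 0 or self.mi_floor < 0:
            raise ValueError("thresholds must be >= 0")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must be in (0,1)")


def filter_pairs(
    pair_matrix: FeatureMatrix,
    unigram_mi_table: pd.DataFrame,
    labels: np.ndarray | None = None,
    rules: PairFilterRules = PairFilterRules(),
) -> tuple[list[str], dict[str, int]]:
    """Apply the four-stage pair exclusion process; keep survivors.

    Stages, in order: (a) seed-word membership in the top-m unigrams by
    MI; (b) pair document frequency >= min_doc_freq; (c) pair MI >=
    mi_floor; (d) chi-squared association p < alpha.  Returns the
    retained pair names (vocabulary order) and a per-stage count report.
    """
    rules.validate()
    if labels is None:
        labels = pair_matrix.labels
    if labels is None:
        raise ValueError("labels are required")
    labels = np.asarray(labels)

    names = list(pair_matrix.vocab.names)
    report = {"initial": len(names)}

    seed_words = set(select_top_k(unigram_mi_table, max(1, rules.seed_top_m)))
    keep = [
        n for n in names if any(w in seed_words for w in n.split(PAIR_SEP, 1))
    ]
    report["after_seed_word"] = len(keep)

    df = dict(zip(pair_matrix.vocab.names, pair_matrix.doc_freq()))
    keep = [n for n in keep if df[n] >= rules.min_doc_freq]
    report["after_min_doc_freq"] = len(keep)

    idx = pair_matrix.vocab.index
    dense = (pair_matrix.counts[:, [idx[n] for n in keep]] > 0).toarray().astype(
        np.int64
    ) if keep else np.zeros((pair_matrix.shape[0], 0), dtype=np.int64)
    mi = np.array(
        [mutual_information(dense[:, j], labels) for j in range(len(keep))]
    )
    survivors = [n for n, m in zip(keep, mi) if m >= rules.mi_floor]
    surv_cols = [j for j, m in enumerate(mi) if m >= rules.mi_floor]
    report["after_mi_floor"] = len(survivors)

    pvals = np.array(
        [association_test(dense[:, j], labels)[1] for j in surv_cols]
    )
    if rules.bh_correct and len(pvals):
        order = np.argsort(pvals)
        ranked = pvals[order] * len(pvals) / (np.arange(len(pvals)) + 1)
        adj = np.minimum.accumulate(ranked[::-1])[::-1]
        out = np.empty_like(pvals)
        out[order] = np.minimum(adj, 1.0)
        pvals = out
    keep = [n for n, p in zip(survivors, pvals) if p < rules.alpha]
    report["after_association_test"] = len(keep)

    log.info("pair filter: %s", report)
    return keep, report
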