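"""Bag-of-words and bag-of-word-pairs featurization of clinical notes.

Free text is reduced to lowercased alphanumeric token runs; linguistic
structure, punctuation and markup are deliberately discarded, and no
stemming or spell-correction is applied — clinical notes are full of
abbreviations and typos, and those strings are kept verbatim as features.
Counts are accumulated per *patient*: all of a patient's notes are pooled
into one document before a patient x feature matrix is built.

Word-pair features never span note boundaries.  Two pair notions are
supported: ordered adjacent bigrams within a note (default) and unordered
within-note co-occurrence counted once per note.
"""

from __future__ import annotations

import datetime as _dt
import itertools
import logging
import re
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import scipy.sparse as sp

log = logging.getLogger("notesignal")

#: separator used to build a pair feature name from its two member words
PAIR_SEP = ">"

_TOKEN_RE = re.compile(r"[a-z0-9]+")
_TABLE_LINE_RE = re.compile(r"\|")


@dataclass(frozen=True)
class ClinicalNote:
    """One timestamped free-text note attached to a patient.

    ``cohort`` is the risk-group label in {1, 2, 3} when known (training
    data) and ``None`` at prediction time.
    """

    patient_id: str
    cohort: int | None
    date: _dt.date
    text: str

    def __post_init__(self) -> None:
        if not self.patient_id:
            raise ValueError("patient_id must be nonempty")
        if self.cohort is not None and self.cohort not in (1, 2, 3):
            raise ValueError(f"cohort must be in {{1,2,3}}, got {self.cohort!r}")


def tokenize(text: str, *, strip_table_lines: bool = False) -> list[str]:
    """Lowercased maximal alphanumeric runs, in order of appearance.

    Length-1 tokens are retained; empty text yields an empty list.  With
    ``strip_table_lines`` lines containing a pipe delimiter (the marker of
    script-generated table blocks) are dropped before tokenization.
    """
    if strip_table_lines:
        text = "\n".join(
            line for line in text.split("\n") if not _TABLE_LINE_RE.search(line)
        )
    return _TOKEN_RE.findall(text.lower())


@dataclass
class PatientDocument:
    """All of one patient's notes, tokenized, with note boundaries kept."""

    patient_id: str
    cohort: int | None
    note_tokens: list[list[str]]
    _counter: Counter[str] | None = field(default=None, repr=False, compare=False)

    @property
    def tokens(self) -> list[str]:
        """Flat token multiset (concatenation over notes)."""
        return list(itertools.chain.from_iterable(self.note_tokens))

    def counter(self) -> Counter[str]:
        # cached; note_tokens must not be mutated after first use
        if self._counter is None:
            c: Counter[str] = Counter()
            for toks in self.note_tokens:
                c.update(toks)
            self._counter = c
        return self._counter

    @property
    def n_tokens(self) -> int:
        return sum(len(t) for t in self.note_tokens)


def aggregate_patients(
    notes: Iterable[ClinicalNote], *, strip_table_lines: bool = False
) -> list[PatientDocument]:
    """Group notes into per-patient documents, ordered by patient id.

    A patient whose every note tokenizes to nothing yields an empty
    document and is logged.  Conflicting cohort labels for one patient are
    a data error.
    """
    by_patient: dict[str, PatientDocument] = {}
    for note in notes:
        doc = by_patient.get(note.patient_id)
        if doc is None:
            doc = PatientDocument(note.patient_id, note.cohort, [])
            by_patient[note.patient_id] = doc
        elif note.cohort is not None:
            if doc.cohort is None:
                doc.cohort = note.cohort
            elif doc.cohort != note.cohort:
                raise ValueError(
                    f"conflicting cohort labels for patient {note.patient_id}: "
                    f"{doc.cohort} vs {note.cohort}"
                )
        doc.note_tokens.append(tokenize(note.text, strip_table_lines=strip_table_lines))
    docs = [by_patient[pid] for pid in sorted(by_patient)]
    n_empty = sum(1 for d in docs if d.n_tokens == 0)
    if n_empty:
        log.warning("%d patient(s) have notes but zero tokens", n_empty)
    return docs


@dataclass
class Vocabulary:
    """Ordered, duplicate-free list of feature names."""

    names: tuple[str, ...]
    kind: str = "unigram"  # "unigram" | "pair"
    _index: dict[str, int] | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        if self.kind not in ("unigram", "pair"):
            raise ValueError(f"unknown feature kind {self.kind!r}")
        if len(set(self.names)) != len(self.names):
            raise ValueError("vocabulary contains duplicate feature names")

    def __len__(self) -> int:
        return len(self.names)

    def __contains__(self, name: str) -> bool:
        return name in self.index

    @property
    def index(self) -> dict[str, int]:
        if self._index is None:
            self._index = {n: i for i, n in enumerate(self.names)}
        return self._index


@dataclass
class FeatureMatrix:
    """Patients x features nonnegative count matrix with aligned metadata.

    ``counts`` is CSR; row order matches ``row_ids`` and column order
    matches ``vocab.names``.  ``labels`` (cohorts), when present, align to
    rows.
    """

    row_ids: tuple[str, ...]
    vocab: Vocabulary
    counts: sp.csr_matrix
    labels: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.counts = sp.csr_matrix(self.counts)
        if self.counts.shape != (len(self.row_ids), len(self.vocab)):
            raise ValueError(
                f"count matrix shape {self.counts.shape} does not match "
                f"{len(self.row_ids)} rows x {len(self.vocab)} features"
            )
        if self.counts.nnz and self.counts.data.min() < 0:
            raise ValueError("counts must be nonnegative")
        if self.labels is not None:
            self.labels = np.asarray(self.labels)
            if self.labels.shape != (len(self.row_ids),):
                raise ValueError("labels must align with rows")

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape

    def toarray(self) -> np.ndarray:
        return self.counts.toarray()

    def column(self, name: str) -> np.ndarray:
        """Dense count column for one feature."""
        j = self.vocab.index[name]
        return self.counts[:, j].toarray().ravel()

    def doc_freq(self) -> np.ndarray:
        """Per-feature number of patients with count >= 1."""
        return np.asarray((self.counts > 0).sum(axis=0)).ravel()


def _matrix_from_counters(
    counters: Sequence[Counter[str]],
    row_ids: Sequence[str],
    labels: np.ndarray | None,
    names: Sequence[str],
    kind: str,
) -> FeatureMatrix:
    index = {n: i for i, n in enumerate(names)}
    rows, cols, data = [], [], []
    for i, c in enumerate(counters):
        for name, n in c.items():
            j = index.get(name)
            if j is not None:
                rows.append(i)
                cols.append(j)
                data.append(n)
    counts = sp.csr_matrix(
        (data, (rows, cols)), shape=(len(row_ids), len(names)), dtype=np.int64
    )
    return FeatureMatrix(tuple(row_ids), Vocabulary(tuple(names), kind), counts, labels)


def _doc_labels(docs: Sequence[PatientDocument]) -> np.ndarray | None:
    if any(d.cohort is None for d in docs):
        return None
    return np.array([d.cohort for d in docs], dtype=np.int64)


def count_unigrams(
    docs: Sequence[PatientDocument], vocabulary: Vocabulary | None = None
) -> FeatureMatrix:
    """Patient x word count matrix.

    With no ``vocabulary`` given, the vocabulary is every distinct token
    across the documents, lexicographically ordered (deterministic).  With
    one given (e.g. a training-fold vocabulary applied to held-out
    patients) tokens outside it are dropped.
    """
    if not docs:
        raise ValueError("document list is empty")
    counters = [d.counter() for d in docs]
    if vocabulary is None:
        names: Sequence[str] = sorted(set().union(*(c.keys() for c in counters)))
        kind = "unigram"
    else:
        names, kind = vocabulary.names, vocabulary.kind
    return _matrix_from_counters(
        counters, [d.patient_id for d in docs], _doc_labels(docs), names, kind
    )


def note_pairs(tokens: Sequence[str], mode: str = "adjacent") -> Counter[str]:
    """Pair features of a single note.

    ``adjacent``: ordered adjacent bigrams, one count per occurrence.
    ``cooccur``: unordered pairs of distinct tokens, counted once per note.
    """
    c: Counter[str] = Counter()
    if mode == "adjacent":
        for a, b in zip(tokens, tokens[1:]):
            c[a + PAIR_SEP + b] += 1
    elif mode == "cooccur":
        for a, b in itertools.combinations(sorted(set(tokens)), 2):
            c[a + PAIR_SEP + b] = 1
    else:
        raise ValueError(f"unknown pair mode {mode!r}")
    return c


def count_pairs(
    docs: Sequence[PatientDocument],
    mode: str = "adjacent",
    vocabulary: Vocabulary | None = None,
) -> FeatureMatrix:
    """Patient x word-pair count matrix; pairs never span note boundaries."""
    if not docs:
        raise ValueError("document list is empty")
    counters = []
    for d in docs:
        c: Counter[str] = Counter()
        for toks in d.note_tokens:
            c.update(note_pairs(toks, mode))
        counters.append(c)
    if vocabulary is None:
        names: Sequence[str] = sorted(set().union(*(c.keys() for c in counters)))
    else:
        names = vocabulary.names
    return _matrix_from_counters(
        counters, [d.patient_id for d in docs], _doc_labels(docs), names, "pair"
    )


def binarize(matrix: FeatureMatrix, threshold: int = 1) -> FeatureMatrix:
    """Presence/absence matrix: cell = 1 iff count >= threshold."""
    if threshold < 1:
        raise ValueError("threshold must be >= 1")
    b = (matrix.counts >= threshold).astype(np.int64)
    return FeatureMatrix(matrix.row_ids, matrix.vocab, sp.csr_matrix(b), matrix.labels)
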