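"""Shared fixtures: small deterministic corpora reused across test files."""

from __future__ import annotations

import numpy as np
import pytest

import notesignal as ns


@pytest.fixture(scope="session")
def default_corpus():
    """One default-scale corpus (70/70/70 patients) at seed 1."""
    return ns.generate_corpus(ns.default_config(seed=1))


@pytest.fixture(scope="session")
def default_docs(default_corpus):
    notes, _ = default_corpus
    return ns.aggregate_patients(notes)


@pytest.fixture(scope="session")
def multiseed_corpora():
    """Twenty default corpora at seeds 1..20 for distributional properties."""
    return [ns.generate_corpus(ns.default_config(seed=s)) for s in range(1, 21)]


@pytest.fixture(scope="session")
def small_corpus():
    """A desk-scale corpus (20 patients/cohort, short notes) for fast CV."""
    profiles = tuple(
        ns.CohortProfile(
            label=p.label,
            n_patients=20,
            mean_notes_per_patient=p.mean_notes_per_patient / 3,
            notes_dispersion=p.notes_dispersion,
            signature_terms=p.signature_terms,
        )
        for p in ns.default_profiles()
    )
    cfg = ns.GeneratorConfig(
        profiles=profiles,
        background_vocab_size=1200,
        note_length_mean=60,
        signature_rank_range=(400, 1000),
        seed=11,
    )
    return ns.generate_corpus(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
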