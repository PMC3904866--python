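"""Synthetic corpus generator: determinism, calibration, planted signal."""

from collections import Counter

import numpy as np
import pytest

import notesignal as ns
from notesignal.corpus import bigram_signal_config


def notes_per_patient(notes, truth, cohort):
    n_notes = sum(1 for n in notes if n.cohort == cohort)
    n_patients = sum(1 for c in truth.labels.values() if c == cohort)
    return n_notes / n_patients


def cohort1_only_config(seed, n_zero=0, n_patients=70):
    p1 = ns.default_profiles()[0]
    profile = ns.CohortProfile(
        label=1,
        n_patients=n_patients,
        mean_notes_per_patient=p1.mean_notes_per_patient,
        notes_dispersion=p1.notes_dispersion,
        n_zero_note_patients=n_zero,
        signature_terms=p1.signature_terms,
    )
    return ns.GeneratorConfig(profiles=(profile,), seed=seed)


class TestDeterminismAndShape:
    def test_same_seed_is_byte_identical(self):
        cfg = ns.default_config(seed=7)
        notes_a, truth_a = ns.generate_corpus(cfg)
        notes_b, truth_b = ns.generate_corpus(cfg)
        assert notes_a == notes_b
        assert truth_a.labels == truth_b.labels

    def test_different_seeds_differ(self):
        notes_a, _ = ns.generate_corpus(cohort1_only_config(seed=1))
        notes_b, _ = ns.generate_corpus(cohort1_only_config(seed=2))
        assert notes_a != notes_b

    def test_empty_config_gives_empty_corpus(self):
        profiles = tuple(
            ns.CohortProfile(label=c, n_patients=0, mean_notes_per_patient=27.0)
            for c in (1, 2, 3)
        )
        notes, truth = ns.generate_corpus(ns.GeneratorConfig(profiles=profiles, seed=1))
        assert notes == [] and truth.labels == {}

    def test_cohort_sizes_and_labels(self, default_corpus):
        notes, truth = default_corpus
        counts = Counter(truth.labels.values())
        assert counts == {1: 70, 2: 70, 3: 70}
        assert {n.cohort for n in notes} == {1, 2, 3}
        assert all(truth.labels[n.patient_id] == n.cohort for n in notes)

    def test_dates_inside_observation_year(self, default_corpus):
        notes, _ = default_corpus
        years = {n.date.year for n in notes}
        assert years == {2009}


class TestValidation:
    def test_negative_cohort_size_rejected(self):
        with pytest.raises(ValueError, match="n_patients"):
            ns.CohortProfile(label=1, n_patients=-1, mean_notes_per_patient=5).validate()

    def test_enrichment_below_one_rejected(self):
        p = ns.CohortProfile(
            label=1, n_patients=5, mean_notes_per_patient=5,
            signature_terms={"agitation": 0.5},
        )
        with pytest.raises(ValueError, match="enrichment"):
            p.validate()

    def test_vocab_smaller_than_signatures_rejected(self):
        cfg = ns.GeneratorConfig(
            profiles=ns.default_profiles(), background_vocab_size=10,
            signature_rank_range=(1, 10), seed=0,
        )
        with pytest.raises(ValueError, match="vocabulary"):
            cfg.validate()

    def test_multiword_signature_rejected(self):
        p = ns.CohortProfile(
            label=1, n_patients=5, mean_notes_per_patient=5,
            signature_terms={"two words": 2.0},
        )
        with pytest.raises(ValueError, match="single token"):
            p.validate()


class TestRenderNote:
    def test_tokens_recovered_without_typos(self, rng):
        toks = ["agitation", "noted", "overnight", "x1", "stable"] * 7
        text = ns.render_note(toks, typo_rate=0.0, rng=rng)
        assert Counter(ns.tokenize(text)) == Counter(toks)

    def test_simple_note_single_blob(self, rng):
        text = ns.render_note(["agitation", "noted", "overnight"], rng=rng)
        for w in ("agitation", "noted", "overnight"):
            assert w in text.lower()

    def test_table_block_adds_tokens_superset(self, rng):
        toks = ["patient", "resting", "comfortably"]
        block = "MEDICATIONS:\nlisinopril | 10 mg | daily\nmetformin | 50 mg | bid\nibuprofen | 20 mg | prn"
        got = Counter(ns.tokenize(ns.render_note(toks, block, rng=rng)))
        assert not Counter(toks) - got  # original multiset fully contained
        assert got["lisinopril"] == 1

    def test_typos_change_some_tokens(self):
        toks = ["abcdefgh"] * 500
        rng = np.random.default_rng(0)
        text = ns.render_note(toks, typo_rate=0.2, rng=rng)
        recovered = ns.tokenize(text)
        assert len(recovered) == 500
        assert 20 < sum(t != "abcdefgh" for t in recovered) < 200

    def test_empty_tokens_rejected(self):
        with pytest.raises(ValueError):
            ns.render_note([])


class TestSignatureLists:
    def test_cohort2_contains_required_terms(self):
        lists = ns.default_signature_lists()
        required = {
            "agitation", "frightened", "delusional", "tense", "aggravated",
            "analgesia", "demerol", "lumbago", "terminal", "nebulizer",
        }
        assert required <= set(lists[2])

    def test_lists_pairwise_disjoint(self):
        lists = ns.default_signature_lists()
        assert not set(lists[1]) & set(lists[2])
        assert not set(lists[1]) & set(lists[3])
        assert not set(lists[2]) & set(lists[3])

    def test_every_term_in_default_vocabulary(self, default_corpus):
        notes, _ = default_corpus
        vocab = set().union(*(ns.tokenize(n.text) for n in notes[:4000]))
        # every planted term should actually occur somewhere in a large sample
        lists = ns.default_signature_lists()
        all_terms = {t for terms in lists.values() for t in terms}
        assert len(all_terms - vocab) <= 2  # rare terms may miss a small sample


class TestCalibration:
    def test_cohort_note_means_match_design(self, multiseed_corpora):
        """Grand mean notes/patient within 15% of 27/61/77 over 20 seeds."""
        targets = {1: 27.0, 2: 61.0, 3: 77.0}
        for cohort, target in targets.items():
            grand = np.mean(
                [notes_per_patient(n, t, cohort) for n, t in multiseed_corpora]
            )
            assert abs(grand - target) / target < 0.15

    def test_single_seed_within_band(self, default_corpus):
        notes, truth = default_corpus
        assert abs(notes_per_patient(notes, truth, 1) - 27) / 27 < 0.15

    def test_note_counts_overdispersed(self, default_corpus):
        notes, truth = default_corpus
        per_patient = Counter(n.patient_id for n in notes if n.cohort == 1)
        counts = np.array(list(per_patient.values()))
        assert counts.var() > 2 * counts.mean()  # far beyond Poisson


class TestPlantedSignal:
    def test_cohort2_signature_docfreq_enriched(self, multiseed_corpora):
        """Majority of cohort-2 terms occur in more cohort-2 than cohort-1
        patients, in every one of 20 seeds."""
        terms = ns.default_signature_lists()[2]
        for notes, truth in multiseed_corpora:
            docs = ns.aggregate_patients(notes)
            m = ns.binarize(ns.count_unigrams(docs))
            labels = np.array([truth.labels[d.patient_id] for d in docs])
            wins = 0
            for t in terms:
                if t not in m.vocab:
                    continue
                col = m.column(t)
                if col[labels == 2].sum() > col[labels == 1].sum():
                    wins += 1
            assert wins > len(terms) / 2

    def test_zero_note_exclusion(self):
        notes, truth = ns.generate_corpus(
            cohort1_only_config(seed=5, n_zero=30, n_patients=100)
        )
        noted = {n.patient_id for n in notes}
        assert len(truth.labels) == 100
        assert len(noted) == 70
        assert len(set(truth.labels) - noted) == 30


class TestBigramSignalCorpus:
    def test_unigram_marginals_matched_but_adjacency_differs(self):
        notes, truth = ns.generate_corpus(bigram_signal_config(seed=3))
        docs = ns.aggregate_patients(notes)
        labels = np.array([truth.labels[d.patient_id] for d in docs])
        uni = ns.count_unigrams(docs)
        pair = ns.count_pairs(docs)
        pair_name = "sig0a" + ">" + "sig0b"
        # injected words occur in both cohorts at comparable token rates
        col = uni.column("sig0a")
        rate1 = col[labels == 1].sum() / sum(d.n_tokens for d, l in zip(docs, labels) if l == 1)
        rate2 = col[labels == 2].sum() / sum(d.n_tokens for d, l in zip(docs, labels) if l == 2)
        assert rate1 > 0 and rate2 > 0
        assert 0.5 < rate1 / rate2 < 2.0
        # but the adjacent bigram is (almost) cohort-2 only
        pcol = pair.column(pair_name) if pair_name in pair.vocab else np.zeros(len(docs))
        assert pcol[labels == 2].sum() > 5 * max(1, pcol[labels == 1].sum())
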