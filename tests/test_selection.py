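"""Mutual information, chi-squared association and pair filtering."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats
from sklearn.metrics import mutual_info_score

import notesignal as ns
from notesignal.features import PAIR_SEP, Vocabulary, FeatureMatrix
import scipy.sparse as sp


def mi_oracle(table):
    """Brute-force plug-in MI over an explicit contingency table (bits)."""
    table = np.asarray(table, dtype=float)
    n = table.sum()
    out = 0.0
    for i in range(table.shape[0]):
        for j in range(table.shape[1]):
            nij = table[i, j]
            if nij == 0:
                continue
            out += (nij / n) * math.log2(nij * n / (table[i].sum() * table[:, j].sum()))
    return out


def column_from_table(table):
    """Expand a (values x classes) table into (column, labels) arrays."""
    col, lab = [], []
    for v in range(table.shape[0]):
        for c in range(table.shape[1]):
            col += [v] * int(table[v, c])
            lab += [c + 1] * int(table[v, c])
    return np.array(col), np.array(lab)


class TestMutualInformation:
    def test_identical_balanced_column_gives_one_bit(self):
        labels = np.array([0] * 35 + [1] * 35)
        assert ns.mutual_information(labels.copy(), labels) == pytest.approx(1.0)

    def test_constant_column_gives_zero(self):
        labels = np.array([1] * 30 + [2] * 40)
        assert ns.mutual_information(np.ones(70), labels) == 0.0

    def test_2x2_example_matches_oracle(self):
        # 140 patients, feature present in 30 of 70 cases vs 10 of 70 controls
        table = np.array([[40, 60], [30, 10]])
        col, lab = column_from_table(table)
        assert ns.mutual_information(col, lab) == pytest.approx(
            mi_oracle(table), abs=1e-12
        )

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="mismatch"):
            ns.mutual_information(np.zeros(3), np.zeros(4))

    @given(
        st.lists(st.integers(0, 8), min_size=4, max_size=4).filter(
            lambda c: sum(c[:2]) and sum(c[2:]) and c[0] + c[2] and c[1] + c[3]
        )
    )
    @settings(max_examples=200, deadline=None)
    def test_2x2_matches_oracle_everywhere(self, cells):
        table = np.array(cells).reshape(2, 2)
        col, lab = column_from_table(table)
        assert ns.mutual_information(col, lab) == pytest.approx(
            mi_oracle(table), abs=1e-12
        )

    def test_2x3_enumeration_matches_oracle(self):
        for a in range(4):
            for b in range(4):
                for c in range(4):
                    for d in range(4):
                        table = np.array([[a, b, 3], [c, d, 2]])
                        if not (table.sum(0).all() and table.sum(1).all()):
                            continue
                        col, lab = column_from_table(table)
                        got = ns.mutual_information(col, lab)
                        assert got == pytest.approx(mi_oracle(table), abs=1e-12)
                        # independent library cross-check (nats -> bits)
                        lib = mutual_info_score(col, lab) / math.log(2)
                        assert got == pytest.approx(lib, abs=1e-9)

    def test_bounded_by_class_entropy(self, rng):
        labels = rng.integers(1, 4, size=60)
        for _ in range(25):
            col = rng.integers(0, 2, size=60)
            mi = ns.mutual_information(col, labels)
            assert 0.0 <= mi <= math.log2(3) + 1e-12


def toy_matrix(cols: dict[str, list[int]], labels=None):
    names = tuple(sorted(cols))
    data = np.array([cols[n] for n in names]).T
    return FeatureMatrix(
        tuple(f"P{i}" for i in range(data.shape[0])),
        Vocabulary(names, "unigram"),
        sp.csr_matrix(data),
        None if labels is None else np.array(labels),
    )


class TestRankFeatures:
    def test_ties_broken_lexicographically(self):
        m = toy_matrix(
            {"zeta": [1, 0, 1, 0], "alpha": [1, 0, 1, 0], "mid": [1, 1, 0, 0]},
            labels=[1, 2, 1, 2],
        )
        table = ns.rank_features(m)
        top2 = table["feature"].head(2).tolist()
        assert top2 == ["alpha", "zeta"]  # identical columns, adjacent ranks

    def test_per_cohort_docfreq_attached(self):
        m = toy_matrix({"a": [1, 1, 0, 0]}, labels=[1, 1, 2, 3])
        row = ns.rank_features(m).iloc[0]
        assert (row["df_1"], row["df_2"], row["df_3"], row["df_total"]) == (2, 0, 0, 2)

    def test_single_class_warns_and_zeroes(self, caplog):
        m = toy_matrix({"a": [1, 0, 1]}, labels=[2, 2, 2])
        with caplog.at_level("WARNING", logger="notesignal"):
            table = ns.rank_features(m)
        assert (table["mi_bits"] == 0).all()
        assert any("single-class" in r.message for r in caplog.records)

    def test_permuted_labels_fall_in_null_band(self, default_docs, rng):
        """Max MI under permuted labels matches the permutation null."""
        docs = default_docs[:60]
        m = ns.count_unigrams(docs)
        sub = FeatureMatrix(m.row_ids, Vocabulary(m.vocab.names[:300], "unigram"),
                            m.counts[:, :300], m.labels)
        perm_labels = rng.permutation(np.asarray(m.labels))
        observed = ns.rank_features(sub, perm_labels)["mi_bits"].max()
        null_max = [
            ns.rank_features(sub, rng.permutation(perm_labels))["mi_bits"].max()
            for _ in range(30)
        ]
        lo, hi = np.quantile(null_max, [0.0, 1.0])
        assert lo * 0.5 <= observed <= hi * 1.5

    def test_signature_terms_rank_high(self, default_corpus):
        """Majority of cohort-2 planted terms land in the top 5% by MI."""
        notes, truth = default_corpus
        docs = ns.aggregate_patients(notes)
        m = ns.count_unigrams(docs)
        table = ns.rank_features(m, np.array([truth.labels[d.patient_id] for d in docs]))
        cutoff = max(1, len(table) // 20)
        top = set(table["feature"].head(cutoff))
        terms = ns.default_signature_lists()[2]
        assert sum(t in top for t in terms) > len(terms) / 2


class TestSelectTopK:
    def test_k_smaller_than_table(self):
        m = toy_matrix(
            {"a": [1, 0], "b": [1, 0], "c": [0, 1], "d": [1, 1], "e": [0, 0]},
            labels=[1, 2],
        )
        table = ns.rank_features(m)
        assert ns.select_top_k(table, 3) == table["feature"].head(3).tolist()

    def test_k_beyond_table_returns_all(self):
        m = toy_matrix({"a": [1, 0], "b": [0, 1]}, labels=[1, 2])
        assert len(ns.select_top_k(ns.rank_features(m), 10)) == 2

    def test_k_zero_rejected(self):
        m = toy_matrix({"a": [1, 0]}, labels=[1, 2])
        with pytest.raises(ValueError):
            ns.select_top_k(ns.rank_features(m), 0)


class TestAssociationTest:
    def test_independent_column_by_construction(self):
        # identical per-class proportions -> statistic 0, p 1
        col = np.array([1, 1, 0, 0, 1, 1, 0, 0])
        lab = np.array([1, 1, 1, 1, 2, 2, 2, 2])
        stat, p = ns.association_test(col, lab)
        assert stat == 0.0 and p == 1.0

    def test_matches_hand_computed_chi2(self):
        # 2x2 table [[40,30],[10,60]] with Yates correction
        col = np.array([1] * 40 + [0] * 30 + [1] * 10 + [0] * 60)
        lab = np.array([1] * 70 + [2] * 70)
        stat, p = ns.association_test(col, lab)
        table = np.array([[30, 60], [40, 10]])
        exp = np.outer(table.sum(1), table.sum(0)) / table.sum()
        hand = ((np.abs(table - exp) - 0.5) ** 2 / exp).sum()
        assert stat == pytest.approx(hand, rel=1e-12)
        assert p == pytest.approx(stats.chi2.sf(hand, 1), rel=1e-12)

    def test_perfect_separation_significant(self):
        col = np.array([1] * 70 + [0] * 70)
        lab = np.array([1] * 70 + [2] * 70)
        _, p = ns.association_test(col, lab)
        assert p < 1e-20

    def test_degenerate_margin_gives_null_result(self):
        assert ns.association_test(np.ones(10), np.repeat([1, 2], 5)) == (0.0, 1.0)


def pair_name(a, b):
    return a + PAIR_SEP + b


class TestFilterPairs:
    @staticmethod
    def build(labels, pair_cols, unigram_cols):
        uni = toy_matrix(unigram_cols, labels=labels)
        names = tuple(sorted(pair_cols))
        data = np.array([pair_cols[n] for n in names]).T
        pairs = FeatureMatrix(
            uni.row_ids, Vocabulary(names, "pair"), sp.csr_matrix(data),
            np.array(labels),
        )
        return uni, pairs

    def test_stagewise_removal(self):
        labels = [1] * 6 + [2] * 6
        sig = [1, 1, 1, 1, 1, 0, 0, 0, 0, 0, 0, 0]
        uni, pairs = self.build(
            labels,
            {
                pair_name("good", "one"): sig,
                pair_name("junk", "word"): [0] * 11 + [1],   # seed-word fail
                pair_name("good", "rare"): [1] + [0] * 11,   # doc-freq fail
                pair_name("good", "flat"): [1, 0, 1, 0, 1, 0] * 2,  # not significant
            },
            {"good": sig, "one": sig, "junk": [0] * 12, "word": [0] * 12,
             "rare": [0] * 12, "flat": [1, 0] * 6},
        )
        rules = ns.PairFilterRules(seed_top_m=2, min_doc_freq=3, mi_floor=0.0, alpha=0.05)
        kept, report = ns.filter_pairs(pairs, ns.rank_features(uni), np.array(labels), rules)
        assert kept == [pair_name("good", "one")]
        assert report["initial"] == 4
        assert report["after_seed_word"] == 3
        assert report["after_min_doc_freq"] == 2
        assert report["after_association_test"] == 1

    def test_relaxing_thresholds_is_monotone(self, rng):
        labels = rng.integers(1, 3, size=40)
        words = [f"w{i}" for i in range(6)]
        uni_cols = {w: rng.integers(0, 2, size=40).tolist() for w in words}
        pair_cols = {
            pair_name(words[i], words[j]): rng.integers(0, 2, size=40).tolist()
            for i in range(5) for j in range(i + 1, 6)
        }
        uni, pairs = self.build(labels.tolist(), pair_cols, uni_cols)
        table = ns.rank_features(uni)
        strict = ns.PairFilterRules(seed_top_m=2, min_doc_freq=5, mi_floor=0.01, alpha=0.2)
        kept_strict, _ = ns.filter_pairs(pairs, table, labels, strict)
        for relaxed in [
            ns.PairFilterRules(seed_top_m=6, min_doc_freq=5, mi_floor=0.01, alpha=0.2),
            ns.PairFilterRules(seed_top_m=2, min_doc_freq=1, mi_floor=0.01, alpha=0.2),
            ns.PairFilterRules(seed_top_m=2, min_doc_freq=5, mi_floor=0.0, alpha=0.2),
            ns.PairFilterRules(seed_top_m=2, min_doc_freq=5, mi_floor=0.01, alpha=0.9),
        ]:
            kept_relaxed, _ = ns.filter_pairs(pairs, table, labels, relaxed)
            assert set(kept_strict) <= set(kept_relaxed)

    def test_deterministic(self, rng):
        labels = rng.integers(1, 3, size=30)
        uni_cols = {f"w{i}": rng.integers(0, 2, size=30).tolist() for i in range(4)}
        pair_cols = {pair_name("w0", "w1"): rng.integers(0, 2, size=30).tolist()}
        uni, pairs = self.build(labels.tolist(), pair_cols, uni_cols)
        table = ns.rank_features(uni)
        a = ns.filter_pairs(pairs, table, labels)
        b = ns.filter_pairs(pairs, table, labels)
        assert a == b

    def test_planted_bigram_survives(self):
        """The adjacency-planted pair passes all four stages."""
        notes, truth = ns.generate_corpus(ns.bigram_signal_config(seed=5))
        docs = ns.aggregate_patients(notes)
        labels = np.array([truth.labels[d.patient_id] for d in docs])
        y = (labels == 2).astype(int) + 1  # binary task as cohort labels {1,2}
        uni = ns.count_unigrams(docs)
        pairs = ns.count_pairs(docs)
        table = ns.rank_features(uni, y)
        rules = ns.PairFilterRules(seed_top_m=2000, min_doc_freq=3)
        kept, _ = ns.filter_pairs(pairs, table, y, rules)
        planted = [pair_name(f"sig{i}a", f"sig{i}b") for i in range(6)]
        assert sum(p in kept for p in planted) > 3
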