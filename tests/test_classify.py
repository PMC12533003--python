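"""Encodings, metrics against brute-force oracles, baselines, nested CV."""

import warnings

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from multipcr.classify import (
    HyperParams,
    auprc,
    auroc,
    build_cnn,
    build_cnn_pe,
    build_rnn,
    composition_features,
    encode_sequences,
    kmer_gbm_scores,
    logistic_scores,
    nested_cv,
    one_hot_decode,
    one_hot_encode,
    positional_encoding,
    positional_kmer_features,
    sample_hparams,
    train_kmer_gbm,
    train_logistic_baseline,
)
from multipcr.nn.train import fit, predict_scores
from multipcr.pool import generate_random_insert

warnings.filterwarnings("ignore", category=FutureWarning)
warnings.filterwarnings("ignore", category=UserWarning)


class TestOneHot:
    def test_acgt_is_identity_pattern(self):
        assert np.array_equal(one_hot_encode("ACGT"), np.eye(4))

    def test_homopolymer_single_channel(self):
        enc = one_hot_encode("AAAA")
        assert np.array_equal(enc[:, 0], np.ones(4))
        assert enc[:, 1:].sum() == 0

    def test_rejects_ambiguity_codes(self):
        with pytest.raises(ValueError):
            one_hot_encode("ACGN")

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.text(alphabet="ACGT", min_size=1, max_size=50))
    def test_round_trip(self, s):
        assert one_hot_decode(one_hot_encode(s)) == s


class TestPositionalEncoding:
    def test_position_zero_rows(self):
        pe = positional_encoding(5, 8)
        assert np.allclose(pe[0, 0::2], 0.0)  # sin 0
        assert np.allclose(pe[0, 1::2], 1.0)  # cos 0

    def test_d2_p1_direct_values(self):
        pe = positional_encoding(3, 2)
        assert pe[1, 0] == pytest.approx(np.sin(1.0))
        assert pe[1, 1] == pytest.approx(np.cos(1.0))

    def test_pythagorean_identity(self):
        pe = positional_encoding(108, 64)
        assert np.allclose(pe[:, 0::2] ** 2 + pe[:, 1::2] ** 2, 1.0)

    def test_entries_bounded(self):
        pe = positional_encoding(200, 32)
        assert pe.min() >= -1.0 and pe.max() <= 1.0

    def test_odd_dimension_rejected(self):
        with pytest.raises(ValueError):
            positional_encoding(10, 7)


def _auroc_bruteforce(scores, labels):
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


def _auprc_bruteforce(scores, labels):
    # Step-wise integration: walk thresholds in score order, AP = sum over
    # positives of precision at their rank (average-precision formulation).
    order = np.argsort(-scores, kind="mergesort")
    y = labels[order]
    tp = np.cumsum(y)
    ranks = np.arange(1, len(y) + 1)
    precision = tp / ranks
    return float((precision * y).sum() / y.sum())


class TestMetrics:
    def test_perfect_and_reversed_ranking(self):
        assert auroc(np.array([0.9, 0.1, 0.2]), np.array([1, 0, 0])) == 1.0
        assert auprc(np.array([0.9, 0.1, 0.2]), np.array([1, 0, 0])) == 1.0
        assert auroc(np.array([0.1, 0.5, 0.9]), np.array([1, 0, 0])) == 0.0

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            auroc(np.array([0.1, 0.2]), np.array([1, 1]))

    def test_matches_bruteforce_on_random_small_cases(self):
        rng = np.random.default_rng(0)
        for trial in range(60):
            n = int(rng.integers(4, 21))
            labels = np.zeros(n, dtype=int)
            labels[: int(rng.integers(1, n))] = 1
            rng.shuffle(labels)
            if labels.sum() in (0, n):
                continue
            # ties are likely with quantised scores
            scores = rng.integers(0, 5, size=n) / 4.0
            assert auroc(scores, labels) == pytest.approx(
                _auroc_bruteforce(scores, labels), abs=1e-12
            )
            # AP comparison without ties (sklearn and the rank oracle differ
            # in tie handling conventions)
            scores2 = rng.random(n)
            assert auprc(scores2, labels) == pytest.approx(
                _auprc_bruteforce(scores2, labels), abs=1e-12
            )


class TestHyperParams:
    def test_sampled_configs_come_from_grid(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            sample_hparams(rng).validate()

    def test_off_grid_rejected(self):
        with pytest.raises(ValueError):
            HyperParams(n_filters=48).validate()


class TestBaselines:
    def _position_labelled_data(self, n, L, seed):
        """All sequences contain CGTG; the label says whether it sits in the
        first 8 nt.  Composition is uninformative by construction."""
        rng = np.random.default_rng(seed)
        seqs, labels = [], []
        for i in range(n):
            s = generate_random_insert(L, rng=rng)
            s = s.replace("CGTG", "ATAC")  # scrub chance occurrences
            lab = i % 2
            off = int(rng.integers(0, 5)) if lab else int(rng.integers(12, L - 4))
            s = s[:off] + "CGTG" + s[off + 4 :]
            seqs.append(s)
            labels.append(lab)
        return np.asarray(seqs), np.array(labels, dtype=float)

    def test_lasso_zeroes_constant_gc_feature(self):
        rng = np.random.default_rng(1)
        seqs = [generate_random_insert(50, "GCfix", rng=rng) for _ in range(200)]
        y = (rng.random(200) > 0.5).astype(int)
        clf = train_logistic_baseline(seqs, y, seed=0)
        feats = composition_features(seqs)
        assert np.allclose(feats[:, 4], 0.5)  # GC genuinely constant
        assert abs(clf.coef_[0][4]) < 1e-8

    def test_kmer_gbm_recovers_planted_positional_feature(self):
        rng = np.random.default_rng(2)
        seqs, labels = [], []
        for i in range(400):
            s = generate_random_insert(30, rng=rng)
            if i % 2:
                s = s[:3] + "CGTG" + s[7:]
            seqs.append(s)
            labels.append(i % 2)
        clf = train_kmer_gbm(seqs, np.array(labels), k=4, seed=0, n_estimators=60)
        X = positional_kmer_features(seqs, 4)
        top = int(np.argmax(clf.feature_importances_))
        offset, code = divmod(top, 4**4)
        kmer = "".join("ACGT"[(code >> (2 * (3 - j))) & 3] for j in range(4))
        assert (offset, kmer) == (3, "CGTG")
        scores = kmer_gbm_scores(clf, seqs)
        assert auroc(scores, np.array(labels)) > 0.95

    def test_positional_encoding_required_for_position_signal(self):
        # CNN+PE beats CNN-PE on a purely position-defined label (mean over
        # seeds); without PE the motif is present in every sequence and only
        # its position separates the classes.
        n, L = 240, 30
        gaps = []
        for seed in range(3):
            seqs, y = self._position_labelled_data(n, L, seed)
            X = encode_sequences(seqs)
            hp = HyperParams(n_filters=16, filter_length=4)
            a = build_cnn_pe(hp, L, d=16, seed=seed)
            b = build_cnn(hp, L, d=16, seed=seed, with_positional_encoding=False)
            for m in (a, b):
                fit(m, X, y, lr=1e-3, batch_size=64, epochs=25, seed=seed)
            gaps.append(
                auroc(predict_scores(a, X), y) - auroc(predict_scores(b, X), y)
            )
        assert np.mean(gaps) > 0.1

    def test_rnn_baseline_learns_presence_signal(self):
        rng = np.random.default_rng(3)
        seqs, labels = [], []
        for i in range(200):
            s = generate_random_insert(20, rng=rng)
            if i % 2:
                s = "CGTGCG" + s[6:]
            seqs.append(s)
            labels.append(i % 2)
        X = encode_sequences(seqs)
        y = np.array(labels, dtype=float)
        model = build_rnn(20, hidden=12, seed=0)
        fit(model, X, y, lr=1e-2, batch_size=32, epochs=40, seed=0)
        assert auroc(predict_scores(model, X), y) > 0.9


class TestNestedCV:
    def _presence_data(self, n, L, seed):
        rng = np.random.default_rng(seed)
        seqs, labels = [], []
        for i in range(n):
            s = generate_random_insert(L, rng=rng)
            if i % 4 == 0:
                s = s[:2] + "CGTGTG" + s[8:]
            seqs.append(s)
            labels.append(1 if i % 4 == 0 else 0)
        return encode_sequences(seqs), np.array(labels, dtype=float)

    def test_degenerate_single_iteration_search(self):
        X, y = self._presence_data(150, 20, 0)
        report = nested_cv(X, y, search_iters=1, seed=0, epochs=3, d=8)
        assert len(report.fold_auroc) == 5
        report.selected.validate()

    def test_shuffled_labels_score_near_chance(self):
        X, y = self._presence_data(200, 20, 1)
        rng = np.random.default_rng(5)
        y_shuf = rng.permutation(y)
        report = nested_cv(X, y_shuf, search_iters=1, seed=1, epochs=4, d=8)
        assert abs(report.mean_auroc - 0.5) < 0.12

    def test_planted_motif_recovery_end_to_end(self):
        X, y = self._presence_data(320, 24, 2)
        report = nested_cv(X, y, search_iters=3, seed=3, epochs=10, d=16)
        assert report.mean_auroc >= 0.75

    def test_class_too_small_for_stratification(self):
        X = np.random.default_rng(0).random((40, 10, 4))
        y = np.zeros(40)
        y[:3] = 1
        with pytest.raises(ValueError):
            nested_cv(X, y, search_iters=1, seed=0, epochs=1)
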