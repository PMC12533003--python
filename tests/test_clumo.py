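"""CluMo components: attribution, candidate extraction, clustering, PWMs,
presence/enrichment, substitution."""

import itertools

import numpy as np
import pytest

from multipcr.classify import HyperParams, build_cnn_pe, encode_sequences
from multipcr.clumo import (
    CandidateKmer,
    CluMoConfig,
    attribute,
    best_window_offset,
    build_pwm,
    embed_and_cluster,
    enrichment_test,
    extract_candidate_kmers,
    hamming_matrix,
    positional_profile,
    presence_score,
    run_clumo,
    substitute_motif,
    substitution_analysis,
    uniform_reference,
)
from multipcr.nn import Dense, GlobalMeanPool, Sequential, Squeeze
from multipcr.nn.train import fit, predict_scores
from multipcr.pool import generate_random_insert


class _ConstantModel:
    """Scores every input identically; attributions must vanish."""

    def forward(self, x, train=False):
        self._shape = x.shape
        return np.zeros(len(x))

    def backward(self, dy):
        return np.zeros(self._shape)


class TestAttribution:
    def test_constant_model_gets_zero_attribution(self):
        X = encode_sequences(["ACGTACGT", "TTTTACGT"])
        attr = attribute(_ConstantModel(), X, steps=4)
        assert np.allclose(attr, 0.0)

    def test_linear_single_position_model_closed_form(self):
        # Model: logit = w . x[:, 5, :]; integrated gradients on a linear
        # model equal (x - ref) . w exactly, concentrated at position 5.
        rng = np.random.default_rng(0)
        w = rng.normal(size=4)

        class _Linear:
            def forward(self, x, train=False):
                self._x = x
                return x[:, 5, :] @ w

            def backward(self, dy):
                g = np.zeros_like(self._x)
                g[:, 5, :] = np.outer(dy, w)
                return g

        X = encode_sequences(["ACGTACGTAC"])
        attr = attribute(_Linear(), X, steps=8)
        expected = (X[0, 5] - 0.25) @ w
        assert attr[0, 5] == pytest.approx(expected, rel=1e-9)
        mask = np.ones(10, dtype=bool)
        mask[5] = False
        assert np.allclose(attr[0, mask], 0.0)

    def test_completeness_on_small_network(self):
        rng = np.random.default_rng(1)
        seqs = ["".join(rng.choice(list("ACGT"), 12)) for _ in range(6)]
        X = encode_sequences(seqs)
        model = build_cnn_pe(HyperParams(n_filters=8, filter_length=4), L=12, d=8, seed=0)
        # attribution sums approximate logit(x) - logit(reference)
        attr = attribute(model, X, steps=256)
        ref = uniform_reference(12)[None]
        gap = model.forward(X, train=False) - model.forward(ref, train=False)
        assert np.allclose(attr.sum(axis=1), gap, atol=0.02 * max(1, np.abs(gap).max()))

    def test_model_without_hooks_rejected(self):
        with pytest.raises(TypeError):
            attribute(object(), np.zeros((1, 5, 4)))


class TestCandidateExtraction:
    def test_spike_window_selected(self):
        attr = np.zeros((1, 20))
        attr[0, 10] = 5.0
        seqs = ["ACGTACGTACGTACGTACGT"]
        cands = extract_candidate_kmers(attr, seqs, w_range=(4, 4))
        # all windows covering the spike tie; the leftmost (offset 7) wins
        assert cands[0].position == 7
        assert cands[0].bases == seqs[0][7:11]

    def test_uniform_attribution_tie_breaks_left(self):
        cands = extract_candidate_kmers(np.zeros((1, 10)), ["ACGTACGTAC"], w_range=(4, 6))
        assert all(c.position == 0 for c in cands)

    def test_one_candidate_per_sequence_and_window(self):
        rng = np.random.default_rng(0)
        attr = rng.normal(size=(3, 108))
        seqs = [generate_random_insert(108, rng=rng) for _ in range(3)]
        cands = extract_candidate_kmers(attr, seqs, w_range=(4, 12))
        assert len(cands) == 3 * 9
        for c in cands:
            assert len(c.bases) == c.w
            # cumulative score equals the window sum of the attribution
            i = seqs.index([s for s in seqs if s[c.position : c.position + c.w] == c.bases][0])

    def test_window_count_identity(self):
        attr = np.zeros((1, 108))
        seqs = [generate_random_insert(108, rng=1)]
        # L - w + 1 windows are scanned; verify via the argmax bound
        cands = extract_candidate_kmers(attr, seqs, w_range=(12, 12))
        assert 0 <= cands[0].position <= 108 - 12

    def test_short_sequence_skipped(self):
        cands = extract_candidate_kmers(np.zeros((1, 5)), ["ACGTA"], w_range=(4, 12))
        assert {c.w for c in cands} == {4, 5}


class TestHamming:
    def test_identities(self):
        D = hamming_matrix(["AAAA", "AAAT", "AAAA"])
        assert D[0, 0] == 0 and D[0, 1] == 1 and D[0, 2] == 0
        assert np.array_equal(D, D.T)

    def test_mixed_lengths_rejected(self):
        with pytest.raises(ValueError):
            hamming_matrix(["AAAA", "AAA"])

    def test_matches_bruteforce(self):
        rng = np.random.default_rng(2)
        kmers = ["".join(rng.choice(list("ACGT"), 6)) for _ in range(10)]
        D = hamming_matrix(kmers)
        for i, j in itertools.combinations(range(10), 2):
            assert D[i, j] == sum(a != b for a, b in zip(kmers[i], kmers[j]))


class TestClustering:
    def test_two_planted_groups_recovered(self):
        kmers = ["AAAA"] * 6 + ["AAAT"] * 4 + ["GGGG"] * 6 + ["GGGC"] * 4
        res = embed_and_cluster(kmers, c_range=(2, 3), seed=0)
        assert res.n_clusters == 2
        lab = dict(zip(res.kmers, res.labels))
        assert lab["AAAA"] == lab["AAAT"]
        assert lab["GGGG"] == lab["GGGC"]
        assert lab["AAAA"] != lab["GGGG"]

    def test_identical_kmers_degenerate_single_cluster(self):
        res = embed_and_cluster(["CGTG"] * 5)
        assert res.n_clusters == 1
        assert res.weights.tolist() == [5.0]

    def test_deterministic_under_seed(self):
        kmers = ["AAAA", "AAAT", "GGGG", "GGGC", "ACGT", "TTTT"] * 3
        a = embed_and_cluster(kmers, seed=7)
        b = embed_and_cluster(kmers, seed=7)
        assert np.array_equal(a.labels, b.labels)
        assert np.allclose(a.embedding, b.embedding)


class TestPWM:
    def test_single_member_one_hot(self):
        pwm = build_pwm(["CGTG"])
        assert pwm.consensus == "CGTG"
        assert np.allclose(pwm.P.max(axis=1), 1.0)

    def test_counting_oracle(self):
        pwm = build_pwm(["CGTG", "CGTG", "CGTA"])
        # position 4: G twice, A once
        assert pwm.P[3, 2] == pytest.approx(2 / 3)
        assert pwm.P[3, 0] == pytest.approx(1 / 3)
        assert pwm.consensus == "CGTG"

    def test_rows_sum_to_one(self):
        pwm = build_pwm(["CGTG", "ACGT", "TTTT"], weights=[2.0, 1.0, 3.0])
        assert np.allclose(pwm.P.sum(axis=1), 1.0)


class TestPresenceScore:
    def test_perfect_match_scores_one(self):
        pwm = build_pwm(["CGTGTG"])
        seq = "AAAA" + "CGTGTG" + "AAAA"
        assert presence_score(pwm, seq) == pytest.approx(1.0)

    def test_uniform_pwm_scores_quarter(self):
        from multipcr.clumo import MotifPWM

        pwm = MotifPWM(P=np.full((5, 4), 0.25), members=[], member_weights=np.zeros(0))
        assert presence_score(pwm, "ACGTACGTA") == pytest.approx(0.25)

    def test_matches_exhaustive_enumeration(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            k = int(rng.integers(4, 8))
            P = rng.dirichlet(np.ones(4), size=k)
            seq = "".join(rng.choice(list("ACGT"), int(rng.integers(k, 30))))
            brute = max(
                sum(P[j, "ACGT".index(seq[i + j])] for j in range(k)) / k
                for i in range(len(seq) - k + 1)
            )
            from multipcr.clumo import MotifPWM

            pwm = MotifPWM(P=P, members=[], member_weights=np.zeros(0))
            assert presence_score(pwm, seq) == pytest.approx(brute, rel=1e-12)

    def test_bounded_and_attains_one_only_for_consensus(self):
        pwm = build_pwm(["CGTG", "CGTA"])  # not one-hot at the last position
        seqs = ["CGTG", "CGTAT", "TTTT"]
        for s in seqs:
            assert 0.0 < presence_score(pwm, s) <= 1.0
        assert presence_score(pwm, "CGTG") < 1.0

    def test_too_short_sequence_rejected(self):
        with pytest.raises(ValueError):
            presence_score(build_pwm(["CGTGTG"]), "CGT")


class TestEnrichment:
    def test_equal_proportions_not_significant(self):
        pwm = build_pwm(["CGTG"])
        low = ["CGTG" + "A" * 10, "A" * 14]
        normal = ["CGTG" + "C" * 10, "A" * 14]
        res = enrichment_test(pwm, low, normal, n_tests=1)
        assert res.chi2 == pytest.approx(0.0, abs=1e-12)
        assert not res.significant

    def test_chi2_matches_hand_formula(self):
        import scipy.stats

        table = np.array([[40, 60], [5, 95]])
        expected = np.outer(table.sum(1), table.sum(0)) / table.sum()
        chi2_hand = ((table - expected) ** 2 / expected).sum()
        chi2_lib = scipy.stats.chi2_contingency(table, correction=False)[0]
        assert chi2_lib == pytest.approx(chi2_hand, rel=1e-12)

    def test_chi2_equals_formula_on_small_table_sweep(self):
        import scipy.stats

        # exhaustive sweep over all 2x2 tables with cells in 1..6
        for a, b, c, d in itertools.product(range(1, 7), repeat=4):
            table = np.array([[a, b], [c, d]])
            expected = np.outer(table.sum(1), table.sum(0)) / table.sum()
            chi2_hand = ((table - expected) ** 2 / expected).sum()
            chi2_lib = scipy.stats.chi2_contingency(table, correction=False)[0]
            assert chi2_lib == pytest.approx(chi2_hand, rel=1e-10)

    def test_bonferroni_multiplication(self):
        pwm = build_pwm(["CGTG"])
        low = ["CGTG" + "A" * 6] * 8 + ["T" * 10] * 2
        normal = ["CGTG" + "A" * 6] * 2 + ["T" * 10] * 8
        res1 = enrichment_test(pwm, low, normal, n_tests=1)
        res20 = enrichment_test(pwm, low, normal, n_tests=20)
        assert res20.p_bonferroni == pytest.approx(min(1.0, res1.p_raw * 20))

    def test_cochran_rule_guards_sparse_tables(self):
        # a table with expected counts below 5 is flagged invalid, never
        # significant, regardless of its nominal chi2
        pwm = build_pwm(["CGTGTG"])
        low = ["CGTGTG" + "A" * 6] * 3 + ["A" * 12] * 17
        normal = ["A" * 12] * 200
        res = enrichment_test(pwm, low, normal, n_tests=1)
        assert res.skipped and not res.significant
        # disabling the guard recovers the raw test
        res_raw = enrichment_test(pwm, low, normal, n_tests=1, min_expected=0.0)
        assert not res_raw.skipped

    def test_zero_margin_table_skipped(self):
        pwm = build_pwm(["A"])  # present in every A-containing sequence
        low = ["AAAA"]
        normal = ["AATA"]
        res = enrichment_test(pwm, low, normal)
        assert res.skipped and not res.significant


class TestPositionalProfile:
    def test_planted_offset_mass(self):
        pwm = build_pwm(["CGTGTG"])
        seqs = ["CGTGTG" + "A" * 10 for _ in range(5)]
        hist = positional_profile(pwm, seqs)
        assert hist[0] == 5 and hist[1:].sum() == 0

    def test_literal_motif_counts_every_occurrence(self):
        hist = positional_profile("CGTG", ["CGTGCGTG" + "A" * 4])
        assert hist[0] == 1 and hist[4] == 1

    def test_uniform_plants_give_flat_histogram(self):
        rng = np.random.default_rng(0)
        seqs = []
        L, k = 20, 4
        for _ in range(600):
            s = generate_random_insert(L, rng=rng).replace("CGTG", "AAAA")
            off = int(rng.integers(0, L - k + 1))
            seqs.append(s[:off] + "CGTG" + s[off + k :])
        hist = positional_profile("CGTG", seqs).astype(float)
        # multinomial flatness: each bin within 4 sigma of the uniform mean
        mean = hist.sum() / len(hist)
        assert np.abs(hist - mean).max() < 4 * np.sqrt(mean)


class TestSubstitution:
    def _trained_toy(self):
        # 5'-proximal planted motif in a 48 nt insert: substitutions of an
        # unrelated motif land mostly away from the signal region.
        rng = np.random.default_rng(4)
        seqs, labels = [], []
        for i in range(200):
            s = generate_random_insert(48, rng=rng).replace("CGTG", "TATA")
            if i % 2:
                s = s[:2] + "CGTGTG" + s[8:]
            seqs.append(s)
            labels.append(i % 2)
        X = encode_sequences(seqs)
        y = np.array(labels, dtype=float)
        model = build_cnn_pe(HyperParams(n_filters=16, filter_length=4), L=48, d=16, seed=0)
        fit(model, X, y, lr=1e-3, batch_size=32, epochs=30, seed=0)
        return model, seqs, y

    def test_identity_prefix_keeps_performance(self):
        model, seqs, y = self._trained_toy()
        trace = substitution_analysis(model, seqs, y, [], seed=0)
        assert trace.n_substituted == [0]
        assert len(trace.auroc) == 1

    def test_substituting_planted_motif_drops_auroc(self):
        from multipcr.classify import auroc

        model, seqs, y = self._trained_toy()
        base = auroc(predict_scores(model, encode_sequences(seqs)), y)
        trace = substitution_analysis(model, seqs, y, [build_pwm(["CGTGTG"])], seed=0)
        assert base > 0.95
        assert trace.auroc[0] == pytest.approx(base)
        assert trace.auroc[1] < base - 0.15

    def test_substituting_irrelevant_motif_changes_little(self):
        # a soft PWM averaged over unrelated random k-mers (the shape a
        # non-significant cluster takes) is rarely called present and leaves
        # performance essentially unchanged
        model, seqs, y = self._trained_toy()
        rng = np.random.default_rng(9)
        members = ["".join(rng.choice(list("ACGT"), 6)) for _ in range(6)]
        trace = substitution_analysis(model, seqs, y, [build_pwm(members)], seed=0)
        assert abs(trace.auroc[1] - trace.auroc[0]) <= 0.05

    def test_random_mode_is_seeded(self):
        model, seqs, y = self._trained_toy()
        X = encode_sequences(seqs)
        pwm = build_pwm(["CGTGTG"])
        a = substitute_motif(X, seqs, pwm, mode="random", rng=np.random.default_rng(1))
        b = substitute_motif(X, seqs, pwm, mode="random", rng=np.random.default_rng(1))
        assert np.array_equal(a, b)
        # average mode writes the uniform element
        c = substitute_motif(X, seqs, pwm, mode="average")
        sub_rows = np.any(c != X, axis=(1, 2))
        assert sub_rows.any()


class TestRunCluMo:
    def test_config_window_range_respected(self):
        rng = np.random.default_rng(5)
        seqs = [generate_random_insert(20, rng=rng) for _ in range(12)]
        model = build_cnn_pe(HyperParams(n_filters=8, filter_length=4), L=20, d=8, seed=0)
        res = run_clumo(model, seqs[:6], seqs[6:], CluMoConfig(w_range=(4, 4), attribution_steps=4, seed=0))
        assert all(c.w == 4 for c in res.candidates)
        assert all(e.pwm.k == 4 for e in res.enrichments)
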