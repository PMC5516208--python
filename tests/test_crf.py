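"""CRF correctness against exhaustive enumeration, finite differences, and
training behavior on toy problems."""

import itertools

import numpy as np
import pytest
from scipy.special import logsumexp

from forumrx.corpus import TAG_ALPHABET, is_valid_bio
from forumrx.crf import (
    CrfModel,
    TrainConfig,
    bio_transition_mask,
    log_partition,
    marginals,
    nll_gradient,
    score_sequence,
    train,
    viterbi,
)

FEATS = [f"f{i}" for i in range(8)]


def random_model(rng, masked, sigma=10.0):
    m = CrfModel(FEATS, labels=TAG_ALPHABET, l2_sigma=sigma, masked=masked)
    m.set_weights(rng.normal(size=m.n_parameters))
    return m


def random_features(rng, T, k=3):
    return [
        {f: float(rng.normal()) for f in rng.choice(FEATS, size=k, replace=False)}
        for _ in range(T)
    ]


_SEQ_CACHE: dict[int, np.ndarray] = {}


def all_sequences(T, L=11):
    if T not in _SEQ_CACHE:
        _SEQ_CACHE[T] = np.array(
            list(itertools.product(range(L), repeat=T)), dtype=np.intp
        )
    return _SEQ_CACHE[T]


def enumerate_scores(model, fvs):
    """Score of every one of the L^T tag sequences, by explicit summation."""
    ids, vals = model.encode(fvs)
    S = model.state_scores(ids, vals)
    L = len(model.labels)
    lt = model._log_trans()
    seqs = all_sequences(len(fvs), L)
    scores = lt[L, seqs[:, 0]] + S[0, seqs[:, 0]]
    for t in range(1, seqs.shape[1]):
        scores = scores + lt[seqs[:, t - 1], seqs[:, t]] + S[t, seqs[:, t]]
    scores = scores + lt[seqs[:, -1], L]
    return seqs, scores


class TestOracleEquivalence:
    """Viterbi, log-partition and marginals versus brute-force enumeration
    over all 11^T sequences, 200 random models, T <= 4."""

    def test_enumeration_agreement(self):
        rng = np.random.default_rng(1234)
        for trial in range(200):
            masked = trial % 2 == 0
            model = random_model(rng, masked)
            T = int(rng.integers(1, 5))
            fvs = random_features(rng, T)
            seqs, scores = enumerate_scores(model, fvs)
            finite = np.isfinite(scores)
            logZ = logsumexp(scores[finite])
            assert log_partition(model, fvs) == pytest.approx(logZ, abs=1e-8)
            # argmax (continuous weights: ties have measure zero)
            best = seqs[int(np.argmax(scores))]
            decoded = [model.label_index[t] for t in viterbi(model, fvs)]
            assert decoded == list(best)
            # per-position marginals
            probs = np.exp(scores[finite] - logZ)
            marg = np.zeros((T, 11))
            for t in range(T):
                np.add.at(marg[t], seqs[finite, t], probs)
            assert np.max(np.abs(marginals(model, fvs) - marg)) < 1e-8

    def test_score_sequence_matches_enumeration_entry(self):
        rng = np.random.default_rng(7)
        model = random_model(rng, masked=False)
        fvs = random_features(rng, 3)
        seqs, scores = enumerate_scores(model, fvs)
        for k in rng.choice(len(seqs), size=20, replace=False):
            tags = [model.labels[i] for i in seqs[k]]
            assert score_sequence(model, fvs, tags) == pytest.approx(scores[k], abs=1e-10)


class TestClosedForms:
    def test_zero_weights_all_scores_zero(self):
        model = CrfModel(FEATS, masked=False)
        fvs = [{"f0": 1.0}, {"f1": 2.0}]
        for tags in (["O", "O"], ["B-pt", "I-pt"], ["B-gen", "O"]):
            assert score_sequence(model, fvs, tags) == 0.0

    def test_zero_weights_log_partition_closed_form(self):
        model = CrfModel(FEATS, masked=False)
        for T in (1, 2, 3, 5):
            fvs = [{"f0": 1.0}] * T
            assert log_partition(model, fvs) == pytest.approx(T * np.log(11), abs=1e-9)

    def test_single_token_weight_identity(self):
        model = CrfModel(FEATS, masked=False)
        w = model.get_weights()
        k = model.feature_index["f0"] * 11 + model.label_index["B-pt"]
        w[k] = 1.7
        model.set_weights(w)
        fvs = [{"f0": 1.0}]
        assert score_sequence(model, fvs, ["B-pt"]) - score_sequence(model, fvs, ["O"]) == pytest.approx(1.7)

    def test_state_feature_shift_invariance(self):
        """Adding a constant to all state scores at one position shifts
        log Z by exactly that constant."""
        rng = np.random.default_rng(3)
        model = random_model(rng, masked=True)
        fvs = random_features(rng, 3)
        base = log_partition(model, fvs)
        c = 0.37
        w = model.get_weights()
        # add c to every label's weight for a fresh feature active only at pos 1
        model2 = CrfModel(FEATS + ["shift"], labels=TAG_ALPHABET, masked=True)
        w2 = np.zeros(model2.n_parameters)
        for f in FEATS:
            for y in range(11):
                w2[model2.feature_index[f] * 11 + y] = w[model.feature_index[f] * 11 + y]
        w2[-((11 + 1) ** 2):] = w[-((11 + 1) ** 2):]
        for y in range(11):
            w2[model2.feature_index["shift"] * 11 + y] = c
        model2.set_weights(w2)
        fvs2 = [dict(fv) for fv in fvs]
        fvs2[1]["shift"] = 1.0
        assert log_partition(model2, fvs2) == pytest.approx(base + c, abs=1e-9)

    def test_zero_weights_uniform_marginals_mask_off(self):
        model = CrfModel(FEATS, masked=False)
        m = marginals(model, [{"f0": 1.0}] * 3)
        assert np.allclose(m, 1.0 / 11, atol=1e-12)

    def test_marginals_rows_sum_to_one(self):
        rng = np.random.default_rng(5)
        model = random_model(rng, masked=True)
        m = marginals(model, random_features(rng, 6))
        assert np.allclose(m.sum(axis=1), 1.0, atol=1e-9)


class TestMaskAndTieBreak:
    def test_zero_weights_mask_on_decodes_all_o(self):
        model = CrfModel(FEATS, masked=True)
        assert viterbi(model, [{"f0": 1.0}] * 4) == ["O"] * 4

    def test_masked_decode_always_valid_bio(self):
        rng = np.random.default_rng(17)
        for _ in range(50):
            model = random_model(rng, masked=True)
            tags = viterbi(model, random_features(rng, int(rng.integers(1, 8))))
            assert is_valid_bio(tags)

    def test_mask_matrix_grammar(self):
        allowed = bio_transition_mask(TAG_ALPHABET)
        L = len(TAG_ALPHABET)
        o = TAG_ALPHABET.index("O")
        ipt = TAG_ALPHABET.index("I-pt")
        bgen = TAG_ALPHABET.index("B-gen")
        bpt = TAG_ALPHABET.index("B-pt")
        assert not allowed[o, ipt]  # O -> I-c
        assert not allowed[bgen, ipt]  # B-c' -> I-c
        assert allowed[bpt, ipt]
        assert not allowed[L, ipt]  # BOS -> I-c
        assert allowed[:L, L].all()  # anything may end


class TestGradient:
    def test_finite_differences(self):
        """Analytic gradient vs central differences, 30 random coordinates,
        relative error < 1e-5."""
        rng = np.random.default_rng(99)
        model = random_model(rng, masked=False, sigma=2.0)
        batch = []
        for _ in range(4):
            T = int(rng.integers(1, 4))
            fvs = random_features(rng, T, k=2)
            tags = [TAG_ALPHABET[i] for i in rng.integers(0, 11, size=T)]
            batch.append((fvs, tags))
        w0 = model.get_weights()
        _, grad = nll_gradient(model, batch)
        eps = 1e-6
        for k in rng.choice(model.n_parameters, size=30, replace=False):
            wp, wm = w0.copy(), w0.copy()
            wp[k] += eps
            wm[k] -= eps
            model.set_weights(wp)
            fp, _ = nll_gradient(model, batch)
            model.set_weights(wm)
            fm, _ = nll_gradient(model, batch)
            model.set_weights(w0)
            fd = (fp - fm) / (2 * eps)
            assert abs(fd - grad[k]) <= 1e-5 * max(1.0, abs(fd))

    def test_zero_weight_gradient_is_expected_minus_empirical(self):
        """At w=0 the gradient's state block equals enumeration-computed
        expected counts minus empirical counts (length <= 3)."""
        model = CrfModel(["a", "b"], masked=False)
        fvs = [{"a": 1.0}, {"b": 1.0}, {"a": 1.0, "b": 0.5}]
        tags = ["B-pt", "I-pt", "O"]
        _, grad = nll_gradient(model, [(fvs, tags)])
        seqs, scores = enumerate_scores_small(model, fvs)
        probs = np.exp(scores - logsumexp(scores))
        expected = np.zeros((2, 11))
        empirical = np.zeros((2, 11))
        for t, fv in enumerate(fvs):
            for f, v in fv.items():
                fi = model.feature_index[f]
                for s, p in zip(seqs, probs):
                    expected[fi, s[t]] += v * p
                empirical[fi, model.label_index[tags[t]]] += v
        state_grad = grad[: 2 * 11].reshape(2, 11)
        assert np.allclose(state_grad, expected - empirical, atol=1e-8)


def enumerate_scores_small(model, fvs):
    ids, vals = model.encode(fvs)
    S = model.state_scores(ids, vals)
    L = len(model.labels)
    lt = model._log_trans()
    seqs = np.array(list(itertools.product(range(L), repeat=len(fvs))), dtype=np.intp)
    scores = lt[L, seqs[:, 0]] + S[0, seqs[:, 0]]
    for t in range(1, seqs.shape[1]):
        scores = scores + lt[seqs[:, t - 1], seqs[:, t]] + S[t, seqs[:, t]]
    scores = scores + lt[seqs[:, -1], L]
    return seqs, scores


def _toy_dataset(n=50, seed=0):
    """Separable toy: a cue feature names the gold tag outright."""
    rng = np.random.default_rng(seed)
    data = []
    for _ in range(n):
        T = int(rng.integers(2, 5))
        labels = ["O", "B-pt", "B-gen", "B-cg"]
        tags = [labels[int(rng.integers(len(labels)))] for _ in range(T)]
        fvs = [{f"cue={tag}": 1.0, "bias": 1.0} for tag in tags]
        data.append((fvs, tags))
    return data


def _toy_model(data, sigma=10.0):
    names = sorted({f for fvs, _ in data for fv in fvs for f in fv})
    return CrfModel(names, l2_sigma=sigma, masked=True)


class TestTraining:
    def test_separable_toy_reaches_perfect_accuracy(self):
        data = _toy_dataset()
        model = train(_toy_model(data), data, TrainConfig(max_iterations=100))
        for fvs, tags in data:
            assert viterbi(model, fvs) == tags

    def test_retrain_deterministic(self):
        data = _toy_dataset()
        cfg = TrainConfig(max_iterations=40)
        w1 = train(_toy_model(data), data, cfg).get_weights()
        w2 = train(_toy_model(data), data, cfg).get_weights()
        assert np.array_equal(w1, w2)

    def test_weight_norm_monotone_in_sigma(self):
        data = _toy_dataset(n=20)
        norms = []
        for sigma in (0.1, 1.0, 10.0):
            m = train(_toy_model(data, sigma), data, TrainConfig(max_iterations=80, l2_sigma=sigma))
            norms.append(float(np.linalg.norm(m.get_weights())))
        assert norms[0] < norms[1] < norms[2]

    def test_convexity_proxy_at_optimum(self):
        """Perturbing the trained weights along random directions never
        decreases the regularized NLL."""
        data = _toy_dataset(n=20)
        model = train(
            _toy_model(data, sigma=1.0), data,
            TrainConfig(max_iterations=200, gradient_tolerance=1e-8, l2_sigma=1.0),
        )
        w_star = model.get_weights()
        model.set_weights(w_star)
        base, _ = nll_gradient(model, data)
        rng = np.random.default_rng(0)
        for _ in range(5):
            d = rng.normal(size=w_star.size)
            d /= np.linalg.norm(d)
            for eps in (0.1, 1.0):
                model.set_weights(w_star + eps * d)
                val, _ = nll_gradient(model, data)
                assert val >= base - 1e-6
        model.set_weights(w_star)

    def test_empty_training_data_rejected(self):
        with pytest.raises(ValueError, match="non-empty"):
            train(CrfModel(["a"]), [], TrainConfig())

    def test_monotone_objective_log(self):
        data = _toy_dataset(n=30)
        vals = []
        train(_toy_model(data), data, TrainConfig(max_iterations=30),
              callback=lambda it, nll: vals.append(nll))
        assert len(vals) >= 3
        # L-BFGS accepted iterates: objective non-increasing
        assert all(b <= a + 1e-9 for a, b in zip(vals, vals[1:]))


class TestSerialization:
    def test_save_load_identity(self, tmp_path):
        data = _toy_dataset(n=10)
        model = train(_toy_model(data), data, TrainConfig(max_iterations=30))
        path = tmp_path / "crf.json"
        model.save(path)
        loaded = CrfModel.load(path)
        assert loaded.labels == model.labels
        assert loaded.feature_index == model.feature_index
        assert np.array_equal(loaded.state_weights, model.state_weights)
        assert np.array_equal(loaded.trans_weights, model.trans_weights)
        for fvs, _ in data:
            assert viterbi(loaded, fvs) == viterbi(model, fvs)

    def test_bad_file_rejected(self, tmp_path):
        path = tmp_path / "x.json"
        path.write_text('{"format_version": 99}')
        with pytest.raises(ValueError, match="not a version"):
            CrfModel.load(path)
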