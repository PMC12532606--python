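"""Hidden Markov model: exact oracles, EM behaviour, recovery, BIC."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy.stats import multivariate_normal

import mscourse as m
from mscourse.hmm import (
    GaussianHMM,
    HMMResults,
    fit_hmm,
    log_likelihood,
    select_states_bic,
    viterbi_decode,
)


def _toy_model(S=2, K=1):
    pi = np.array([0.6, 0.4])[:S]
    pi = pi / pi.sum()
    A = np.array([[0.8, 0.2], [0.3, 0.7]])[:S, :S]
    A = A / A.sum(axis=1, keepdims=True)
    means = np.array([[-1.0], [2.0]])[:S, :K]
    covs = np.array([np.eye(K) * 0.5, np.eye(K) * 1.5])[:S]
    return HMMResults(
        initial=pi, transition=A, means=means, covariances=covs,
        log_likelihood=np.nan, converged=True,
    )


def _brute_force_loglik(model, seq):
    """Sum over every state path of the joint density."""
    S = model.n_states
    T = len(seq)
    total = 0.0
    for path in itertools.product(range(S), repeat=T):
        p = model.initial[path[0]]
        for t in range(1, T):
            p *= model.transition[path[t - 1], path[t]]
        for t, s in enumerate(path):
            p *= multivariate_normal.pdf(
                seq[t], model.means[s], model.covariances[s]
            )
        total += p
    return np.log(total)


def _brute_force_viterbi(model, seq):
    S, T = model.n_states, len(seq)
    best, best_lp = None, -np.inf
    for path in itertools.product(range(S), repeat=T):
        lp = np.log(model.initial[path[0]])
        for t in range(1, T):
            lp += np.log(model.transition[path[t - 1], path[t]])
        for t, s in enumerate(path):
            lp += multivariate_normal.logpdf(
                seq[t], model.means[s], model.covariances[s]
            )
        if lp > best_lp:  # strict: ties keep the lexicographically first
            best, best_lp = path, lp
    return np.array(best) + 1, best_lp


class TestLogLikelihood:
    def test_single_state_equals_sum_of_gaussian_logpdfs(self, rng):
        X = rng.normal(size=(30, 2))
        model = HMMResults(
            initial=np.array([1.0]),
            transition=np.array([[1.0]]),
            means=np.zeros((1, 2)),
            covariances=np.eye(2)[None],
            log_likelihood=np.nan,
            converged=True,
        )
        ll = log_likelihood(model, [X[:15], X[15:]])
        expected = multivariate_normal.logpdf(X, np.zeros(2), np.eye(2)).sum()
        assert ll == pytest.approx(expected, abs=1e-8)

    def test_matches_exhaustive_path_enumeration(self, rng):
        model = _toy_model()
        seqs = [rng.normal(size=(3, 1)), rng.normal(size=(2, 1))]
        ll = log_likelihood(model, seqs)
        expected = sum(_brute_force_loglik(model, s) for s in seqs)
        assert ll == pytest.approx(expected, abs=1e-10)

    def test_impossible_observation_decreases_loglik(self, rng):
        model = _toy_model()
        seq = rng.normal(size=(3, 1))
        extended = np.vstack([seq, [[150.0]]])
        assert log_likelihood(model, [extended]) < log_likelihood(model, [seq])

    def test_dimension_mismatch_rejected(self, rng):
        with pytest.raises(ValueError):
            log_likelihood(_toy_model(), [rng.normal(size=(3, 2))])

    def test_invariant_under_state_relabelling(self, rng):
        model = _toy_model()
        perm = [1, 0]
        permuted = HMMResults(
            initial=model.initial[perm],
            transition=model.transition[np.ix_(perm, perm)],
            means=model.means[perm],
            covariances=model.covariances[perm],
            log_likelihood=np.nan,
            converged=True,
        )
        seqs = [rng.normal(size=(5, 1))]
        assert log_likelihood(model, seqs) == pytest.approx(
            log_likelihood(permuted, seqs), abs=1e-10
        )

    def test_agrees_with_hmmlearn_forward_pass(self, rng):
        hmmlearn = pytest.importorskip("hmmlearn.hmm")
        model = _toy_model()
        ref = hmmlearn.GaussianHMM(n_components=2, covariance_type="full",
                                   init_params="")
        ref.startprob_ = model.initial
        ref.transmat_ = model.transition
        ref.means_ = model.means
        ref.covars_ = model.covariances
        seqs = [rng.normal(size=(6, 1)), rng.normal(size=(4, 1))]
        ours = log_likelihood(model, seqs)
        theirs = ref.score(np.vstack(seqs), lengths=[6, 4])
        assert ours == pytest.approx(theirs, abs=1e-8)


class TestViterbi:
    def test_single_state_path(self, rng):
        model = HMMResults(
            initial=np.array([1.0]), transition=np.array([[1.0]]),
            means=np.zeros((1, 1)), covariances=np.eye(1)[None],
            log_likelihood=np.nan, converged=True,
        )
        out = viterbi_decode(model, [rng.normal(size=(4, 1))])
        assert out["state"].tolist() == [1, 1, 1, 1]

    def test_matches_exhaustive_argmax(self, rng):
        model = _toy_model()
        for _ in range(5):
            seq = rng.normal(size=(3, 1)) * 2
            out = viterbi_decode(model, [seq])
            expected, _ = _brute_force_viterbi(model, seq)
            np.testing.assert_array_equal(out["state"].to_numpy(), expected)

    def test_ties_break_toward_lowest_state_index(self):
        model = HMMResults(
            initial=np.array([0.5, 0.5]),
            transition=np.full((2, 2), 0.5),
            means=np.zeros((2, 1)),
            covariances=np.stack([np.eye(1), np.eye(1)]),
            log_likelihood=np.nan,
            converged=True,
        )
        out = viterbi_decode(model, [np.zeros((3, 1))])
        assert out["state"].tolist() == [1, 1, 1]

    def test_posteriors_normalize_and_beat_random_paths(self, rng):
        model = _toy_model()
        seq = rng.normal(size=(6, 1))
        out = viterbi_decode(model, [seq])
        post = out[["post_1", "post_2"]].to_numpy()
        np.testing.assert_allclose(post.sum(axis=1), 1.0, atol=1e-10)

        def joint_lp(path):
            lp = np.log(model.initial[path[0]])
            for t in range(1, len(path)):
                lp += np.log(model.transition[path[t - 1], path[t]])
            for t, s in enumerate(path):
                lp += multivariate_normal.logpdf(
                    seq[t], model.means[s], model.covariances[s]
                )
            return lp

        vit = joint_lp(out["state"].to_numpy() - 1)
        for _ in range(100):
            rand = rng.integers(0, 2, size=6)
            assert vit >= joint_lp(rand) - 1e-10

    def test_near_deterministic_emissions_recover_generating_path(self, rng):
        A = np.array([[0.7, 0.3], [0.2, 0.8]])
        means = np.array([[-5.0], [5.0]])
        paths, seqs = [], []
        for _ in range(20):
            s = [rng.choice(2)]
            for _ in range(14):
                s.append(rng.choice(2, p=A[s[-1]]))
            paths.append(np.array(s))
            seqs.append(
                means[s] + rng.normal(scale=1e-2, size=(15, 1))
            )
        model = HMMResults(
            initial=np.array([0.5, 0.5]), transition=A, means=means,
            covariances=np.stack([np.eye(1) * 1e-4, np.eye(1) * 1e-4]),
            log_likelihood=np.nan, converged=True,
        )
        out = viterbi_decode(model, seqs)
        decoded = out.groupby("patient_id")["state"].apply(np.array)
        for i, true in enumerate(paths):
            np.testing.assert_array_equal(decoded.iloc[i] - 1, true)


class TestFit:
    def test_single_state_closed_form(self, rng):
        seqs = [rng.normal(size=(20, 2)) for _ in range(5)]
        res = fit_hmm(seqs, 1, restarts=1, seed=0)
        pooled = np.vstack(seqs)
        assert res.transition == pytest.approx(np.array([[1.0]]))
        np.testing.assert_allclose(res.means[0], pooled.mean(axis=0),
                                   atol=1e-8)
        np.testing.assert_allclose(
            res.covariances[0], np.cov(pooled.T, bias=True), atol=1e-6
        )

    def test_nonswitching_clusters_give_identity_transitions(self, rng):
        seqs = [
            rng.normal(loc=-5.0, size=(12, 2)) for _ in range(25)
        ] + [
            rng.normal(loc=5.0, size=(12, 2)) for _ in range(25)
        ]
        res = fit_hmm(seqs, 2, restarts=3, seed=1)
        off_diag = res.transition[~np.eye(2, dtype=bool)]
        assert (off_diag < 0.02).all()

    def test_three_state_chain_recovered(self, rng):
        A = np.array([[0.85, 0.10, 0.05],
                      [0.10, 0.80, 0.10],
                      [0.05, 0.15, 0.80]])
        means = np.array([[-3.0, 0.0], [0.0, 3.0], [3.0, -1.0]])
        seqs = []
        for _ in range(500):
            s = [rng.choice(3)]
            for _ in range(29):
                s.append(rng.choice(3, p=A[s[-1]]))
            seqs.append(means[s] + rng.normal(scale=0.5, size=(30, 2)))
        res = fit_hmm(seqs, 3, restarts=3, seed=2)
        # match estimated states to truth via emission means
        order = [
            int(np.argmin(np.linalg.norm(res.means - mu, axis=1)))
            for mu in means
        ]
        assert sorted(order) == [0, 1, 2]
        A_hat = res.transition[np.ix_(order, order)]
        assert np.max(np.abs(A_hat - A)) < 0.05

    def test_em_loglik_is_nondecreasing(self, rng):
        seqs = [rng.normal(size=(15, 2)) + np.arange(2) for _ in range(30)]
        res = fit_hmm(seqs, 2, restarts=1, seed=3)
        deltas = np.diff(res.loglik_path)
        assert deltas.min() >= -1e-8 * (1 + abs(res.log_likelihood))

    def test_more_states_than_visits_rejected(self, rng):
        with pytest.raises(ValueError):
            GaussianHMM([rng.normal(size=(2, 1))], 5)

    def test_n_params_formula(self):
        res = _toy_model()
        S, K = 2, 1
        assert res.n_params == (S - 1) + S * (S - 1) + S * (K + K * (K + 1) // 2)


class TestModelSelection:
    def test_iid_gaussian_prefers_single_state(self, rng):
        seqs = [rng.normal(size=(20, 2)) for _ in range(40)]
        best, table = select_states_bic(seqs, [1, 2, 3], restarts=2, seed=4)
        assert best == 1
        assert set(table["n_states"]) == {1, 2, 3}
        assert {"bic", "bic_patients", "converged"} <= set(table.columns)

    def test_two_state_mixture_prefers_two_states(self, rng):
        A = np.array([[0.9, 0.1], [0.1, 0.9]])
        means = np.array([[-3.0], [3.0]])
        seqs = []
        for _ in range(60):
            s = [rng.choice(2)]
            for _ in range(19):
                s.append(rng.choice(2, p=A[s[-1]]))
            seqs.append(means[s] + rng.normal(scale=0.5, size=(20, 1)))
        best, _ = select_states_bic(seqs, [1, 2, 4], restarts=2, seed=5)
        assert best == 2


def test_roundtrip_serialization(tmp_path, rng):
    seqs = [rng.normal(size=(10, 2)) for _ in range(10)]
    res = fit_hmm(seqs, 2, restarts=1, seed=6)
    res.to_json(tmp_path / "hmm.json")
    back = HMMResults.from_json(tmp_path / "hmm.json")
    np.testing.assert_allclose(back.transition, res.transition)
    assert back.log_likelihood == pytest.approx(res.log_likelihood)
    assert log_likelihood(back, seqs) == pytest.approx(res.log_likelihood,
                                                       rel=1e-9)
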