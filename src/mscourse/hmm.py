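"""Hidden Markov model with multivariate-Gaussian emissions on composite scores.

Each patient contributes an independent chain sharing one parameter set
(initial distribution, unconstrained transition matrix, per-state full
Gaussian emissions).  Fitting is multi-sequence Baum-Welch in log space;
the number of states is selected by BIC; decoded paths come from the
Viterbi algorithm with forward-backward posteriors alongside.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import logsumexp
from sklearn.cluster import KMeans

__all__ = [
    "GaussianHMM",
    "HMMResults",
    "fit_hmm",
    "log_likelihood",
    "select_states_bic",
    "viterbi_decode",
    "sequences_from_scores",
]

def sequences_from_scores(scores: pd.DataFrame) -> tuple[list, list]:
    """Split a (patient_id, month, score_*) frame into per-patient arrays."""
    score_cols = [c for c in scores.columns if c.startswith("score_")]
    seqs, ids = [], []
    for pid, g in scores.sort_values(["patient_id", "month"]).groupby(
        "patient_id", sort=False
    ):
        seqs.append(g[score_cols].to_numpy(dtype=float))
        ids.append(pid)
    return seqs, ids


def _pack(sequences) -> tuple[np.ndarray, np.ndarray]:
    """Pad unequal-length sequences into (N, Tmax, K) plus lengths."""
    seqs = [np.atleast_2d(np.asarray(s, dtype=float)) for s in sequences]
    if not seqs:
        raise ValueError("no sequences")
    K = seqs[0].shape[1]
    if any(s.shape[1] != K for s in seqs):
        raise ValueError("inconsistent score dimension across sequences")
    if any(s.shape[0] < 1 for s in seqs):
        raise ValueError("every sequence must have length >= 1")
    lengths = np.array([s.shape[0] for s in seqs])
    X = np.zeros((len(seqs), lengths.max(), K))
    for i, s in enumerate(seqs):
        X[i, : s.shape[0]] = s
    return X, lengths


def _emission_loglik(X, lengths, means, covs) -> np.ndarray:
    """(N, T, S) Gaussian log-densities; padded steps get 0 so the backward
    recursion stays exact (rows of the transition matrix sum to one)."""
    N, T, K = X.shape
    S = means.shape[0]
    B = np.empty((N, T, S))
    flat = X.reshape(-1, K)
    for s in range(S):
        L = np.linalg.cholesky(covs[s])
        diff = flat - means[s]
        sol = np.linalg.solve(L, diff.T)
        quad = (sol**2).sum(axis=0)
        logdet = 2 * np.log(np.diag(L)).sum()
        B[:, :, s] = (-0.5 * (K * np.log(2 * np.pi) + logdet + quad)).reshape(N, T)
    mask = np.arange(T)[None, :] >= lengths[:, None]
    B[mask] = 0.0
    return B


def _forward_backward(B, lengths, log_pi, log_A):
    N, T, S = B.shape
    log_alpha = np.empty((N, T, S))
    log_alpha[:, 0] = log_pi[None, :] + B[:, 0]
    for t in range(1, T):
        log_alpha[:, t] = B[:, t] + logsumexp(
            log_alpha[:, t - 1, :, None] + log_A[None, :, :], axis=1
        )
    ll = logsumexp(log_alpha[np.arange(N), lengths - 1], axis=1)

    log_beta = np.zeros((N, T, S))
    for t in range(T - 2, -1, -1):
        log_beta[:, t] = logsumexp(
            log_A[None, :, :] + (B[:, t + 1] + log_beta[:, t + 1])[:, None, :],
            axis=2,
        )
    return log_alpha, log_beta, ll


@dataclass
class HMMResults:
    """Fitted HMM: distributions, emissions, and fit diagnostics."""

    initial: np.ndarray
    transition: np.ndarray
    means: np.ndarray
    covariances: np.ndarray
    log_likelihood: float
    converged: bool
    n_iter: int = 0
    loglik_path: np.ndarray | None = None
    n_obs: int = 0
    n_sequences: int = 0

    @property
    def n_states(self) -> int:
        return len(self.initial)

    @property
    def n_dim(self) -> int:
        return self.means.shape[1]

    @property
    def n_params(self) -> int:
        S, K = self.n_states, self.n_dim
        return (S - 1) + S * (S - 1) + S * (K + K * (K + 1) // 2)

    def bic(self, n: int | None = None) -> float:
        n = self.n_obs if n is None else n
        return -2.0 * self.log_likelihood + self.n_params * np.log(n)

    def summary(self) -> str:
        lines = [
            f"Gaussian HMM: {self.n_states} states, {self.n_dim} score dimensions",
            f"sequences: {self.n_sequences}, visits: {self.n_obs}",
            f"log-likelihood: {self.log_likelihood:.3f}  "
            f"BIC: {self.bic():.1f}  converged: {self.converged}",
            "initial: " + np.array2string(self.initial, precision=3),
            "transition:",
            np.array2string(self.transition, precision=3, suppress_small=True),
            "state means:",
            np.array2string(self.means, precision=2),
        ]
        return "\n".join(lines)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "initial": self.initial.tolist(),
                    "transition": self.transition.tolist(),
                    "means": self.means.tolist(),
                    "covariances": self.covariances.tolist(),
                    "log_likelihood": self.log_likelihood,
                    "converged": self.converged,
                    "n_obs": self.n_obs,
                    "n_sequences": self.n_sequences,
                },
                fh,
                indent=1,
            )

    @classmethod
    def from_json(cls, path) -> "HMMResults":
        with open(path) as fh:
            d = json.load(fh)
        return cls(
            initial=np.asarray(d["initial"]),
            transition=np.asarray(d["transition"]),
            means=np.asarray(d["means"]),
            covariances=np.asarray(d["covariances"]),
            log_likelihood=float(d["log_likelihood"]),
            converged=bool(d["converged"]),
            n_obs=int(d.get("n_obs", 0)),
            n_sequences=int(d.get("n_sequences", 0)),
        )


class GaussianHMM:
    """Multi-sequence Gaussian HMM estimated by Baum-Welch EM.

    Initialization uses k-means state means on the pooled scores (jittered
    per restart), a 0.9-diagonal transition matrix, and the pooled
    covariance; covariance eigenvalues are floored at 1e-6 for numerical
    safety.  All transitions are a priori possible.
    """

    def __init__(self, sequences, n_states: int):
        self.X, self.lengths = _pack(sequences)
        if n_states < 1:
            raise ValueError("n_states must be >= 1")
        if n_states > int(self.lengths.sum()):
            raise ValueError("more states than total visits")
        self.S = int(n_states)

    # ------------------------------------------------------------ fitting
    def _init_params(self, rng, jitter):
        N, T, K = self.X.shape
        valid = np.arange(T)[None, :] < self.lengths[:, None]
        pooled = self.X[valid]
        S = self.S
        km = KMeans(
            n_clusters=S,
            n_init=3,
            random_state=int(rng.integers(2**31 - 1)),
        ).fit(pooled)
        means = km.cluster_centers_ + jitter * pooled.std(axis=0) * (
            rng.standard_normal((S, K))
        )
        cov = np.cov(pooled.T, bias=True).reshape(K, K) + 1e-4 * np.eye(K)
        covs = np.repeat(cov[None], S, axis=0)
        A = np.full((S, S), 0.1 / max(S - 1, 1))
        np.fill_diagonal(A, 0.9 if S > 1 else 1.0)
        A /= A.sum(axis=1, keepdims=True)
        pi = np.full(S, 1.0 / S)
        return pi, A, means, covs

    @staticmethod
    def _floor_cov(C, floor=1e-6):
        C = (C + C.T) / 2
        w, U = np.linalg.eigh(C)
        return (U * np.maximum(w, floor)) @ U.T

    def _em(self, pi, A, means, covs, max_iter, tol):
        X, lengths, S = self.X, self.lengths, self.S
        N, T, K = X.shape
        valid = np.arange(T)[None, :] < lengths[:, None]
        path = []
        prev = -np.inf
        converged = False
        for it in range(max_iter):
            B = _emission_loglik(X, lengths, means, covs)
            log_pi = np.log(np.maximum(pi, 1e-300))
            log_A = np.log(np.maximum(A, 1e-300))
            log_alpha, log_beta, ll_n = _forward_backward(B, lengths, log_pi, log_A)
            ll = float(ll_n.sum())
            path.append(ll)

            log_gamma = log_alpha + log_beta - ll_n[:, None, None]
            gamma = np.exp(log_gamma)
            gamma[~valid] = 0.0

            xi_sum = np.zeros((S, S))
            trans_valid = np.arange(T - 1)[None, :] < (lengths - 1)[:, None]
            for t in range(T - 1):
                w = trans_valid[:, t]
                if not w.any():
                    continue
                log_xi = (
                    log_alpha[w, t, :, None]
                    + log_A[None, :, :]
                    + (B[w, t + 1] + log_beta[w, t + 1])[:, None, :]
                    - ll_n[w, None, None]
                )
                xi_sum += np.exp(log_xi).sum(axis=0)

            pi = gamma[:, 0].mean(axis=0)
            pi /= pi.sum()
            denom = xi_sum.sum(axis=1, keepdims=True)
            A = np.where(denom > 0, xi_sum / np.maximum(denom, 1e-300), A)
            A /= A.sum(axis=1, keepdims=True)

            g = gamma[valid]          # (n_visits, S)
            obs = X[valid]            # (n_visits, K)
            wsum = g.sum(axis=0)
            means = (g.T @ obs) / wsum[:, None]
            for s in range(S):
                diff = obs - means[s]
                C = (g[:, s, None] * diff).T @ diff / wsum[s]
                covs[s] = self._floor_cov(C)

            if it > 0 and (ll - prev) < tol * (1 + abs(prev)):
                converged = True
                prev = ll
                break
            prev = ll
        # report the likelihood of the returned parameters (one E-pass past
        # the last M-step; monotone, so the path stays non-decreasing)
        B = _emission_loglik(X, lengths, means, covs)
        _, _, ll_n = _forward_backward(
            B, lengths,
            np.log(np.maximum(pi, 1e-300)),
            np.log(np.maximum(A, 1e-300)),
        )
        prev = float(ll_n.sum())
        path.append(prev)
        return pi, A, means, covs, prev, np.asarray(path), converged

    def fit(
        self,
        restarts: int = 10,
        seed: int = 0,
        max_iter: int = 500,
        tol: float = 1e-6,
    ) -> HMMResults:
        seeds = np.random.SeedSequence(seed).spawn(max(restarts, 1))
        best = None
        for r in range(max(restarts, 1)):
            rng = np.random.default_rng(seeds[r])
            init = self._init_params(rng, jitter=0.0 if r == 0 else 0.2)
            fitted = self._em(*init, max_iter=max_iter, tol=tol)
            if best is None or fitted[4] > best[4]:
                best = fitted
        pi, A, means, covs, ll, path, converged = best
        return HMMResults(
            initial=pi,
            transition=A,
            means=means,
            covariances=covs,
            log_likelihood=ll,
            converged=converged,
            n_iter=len(path),
            loglik_path=path,
            n_obs=int(self.lengths.sum()),
            n_sequences=len(self.lengths),
        )


# ------------------------------------------------------- module-level ops
def fit_hmm(
    sequences, n_states: int, restarts: int = 10, seed: int = 0, **kwargs
) -> HMMResults:
    return GaussianHMM(sequences, n_states).fit(
        restarts=restarts, seed=seed, **kwargs
    )


def log_likelihood(model: HMMResults, sequences) -> float:
    """Sum of per-sequence forward log-likelihoods."""
    X, lengths = _pack(sequences)
    if X.shape[2] != model.n_dim:
        raise ValueError("score dimension does not match the model")
    B = _emission_loglik(X, lengths, model.means, model.covariances)
    _, _, ll = _forward_backward(
        B,
        lengths,
        np.log(np.maximum(model.initial, 1e-300)),
        np.log(np.maximum(model.transition, 1e-300)),
    )
    return float(ll.sum())


def select_states_bic(
    sequences,
    S_range,
    restarts: int = 10,
    seed: int = 0,
    **kwargs,
) -> tuple[int, pd.DataFrame]:
    """Fit over a range of state counts and pick the BIC minimizer.

    BIC uses the total number of visits as the sample size; a patient-based
    BIC column is reported alongside.  Ties break toward the smaller state
    count; fits that never converge are flagged and excluded from the argmin.
    """
    S_range = sorted(set(int(s) for s in S_range))
    if not S_range:
        raise ValueError("empty S_range")
    rows, fits = [], {}
    child = np.random.SeedSequence(seed).spawn(len(S_range))
    for i, S in enumerate(S_range):
        res = fit_hmm(
            sequences,
            S,
            restarts=restarts,
            seed=int(child[i].generate_state(1)[0] % (2**31 - 1)),
            **kwargs,
        )
        fits[S] = res
        rows.append(
            {
                "n_states": S,
                "log_likelihood": res.log_likelihood,
                "n_params": res.n_params,
                "bic": res.bic(),
                "bic_patients": res.bic(res.n_sequences),
                "converged": res.converged,
            }
        )
    table = pd.DataFrame(rows)
    usable = table[table["converged"]]
    if usable.empty:
        raise RuntimeError("no state count converged; see the BIC table")
    best = int(usable.sort_values(["bic", "n_states"]).iloc[0]["n_states"])
    table.attrs["fits"] = fits
    return best, table


def viterbi_decode(model: HMMResults, sequences, ids=None) -> pd.DataFrame:
    """Maximum-a-posteriori state paths plus forward-backward posteriors.

    Returns one row per visit: ``patient_id``, ``month`` (position within
    the sequence), 1-based ``state``, its posterior probability, and the
    full posterior columns ``post_1..post_S``.  Ties break toward the
    lowest state index.
    """
    X, lengths = _pack(sequences)
    N, T, _ = X.shape
    S = model.n_states
    B = _emission_loglik(X, lengths, model.means, model.covariances)
    log_pi = np.log(np.maximum(model.initial, 1e-300))
    log_A = np.log(np.maximum(model.transition, 1e-300))

    delta = np.empty((N, T, S))
    arg = np.zeros((N, T, S), dtype=np.int32)
    delta[:, 0] = log_pi[None, :] + B[:, 0]
    for t in range(1, T):
        cand = delta[:, t - 1, :, None] + log_A[None, :, :]
        arg[:, t] = cand.argmax(axis=1)
        delta[:, t] = cand.max(axis=1) + B[:, t]

    log_alpha, log_beta, ll = _forward_backward(B, lengths, log_pi, log_A)
    post = np.exp(log_alpha + log_beta - ll[:, None, None])

    if ids is None:
        ids = list(range(1, N + 1))
    frames = []
    for i in range(N):
        L = lengths[i]
        path = np.empty(L, dtype=int)
        path[-1] = int(delta[i, L - 1].argmax())
        for t in range(L - 2, -1, -1):
            path[t] = arg[i, t + 1, path[t + 1]]
        block = {
            "patient_id": np.repeat(ids[i], L),
            "month": np.arange(L),
            "state": path + 1,
        }
        p = post[i, :L]
        p /= p.sum(axis=1, keepdims=True)
        block["max_posterior"] = p[np.arange(L), path]
        for s in range(S):
            block[f"post_{s + 1}"] = p[:, s]
        frames.append(pd.DataFrame(block))
    return pd.concat(frames, ignore_index=True)
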