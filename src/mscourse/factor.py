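"""Sparse probabilistic factor analysis of the eight MS measures.

The model is a Gaussian factor analyser ``x = Lambda eta + eps`` with
``eta ~ N(0, I_K)`` and diagonal residual variance (uniquenesses).  Sparsity
of the loading matrix comes from a spike-and-slab prior with Laplace
components on each loading, and the number of active dimensions from a
finite Indian-buffet-process-style Beta prior on the per-column inclusion
probabilities.  Estimation is MAP via EM: the E-step integrates the scores
and the spike/slab responsibilities in closed form; the M-step solves a
weighted-lasso problem for the loadings by coordinate descent.  Columns
whose every posterior inclusion probability stays at or below 1/2 are
pruned, which realizes the published rule that a measure belongs to a
dimension only when its slab probability exceeds 0.5.

Mixed measurement modalities enter through fixed link transforms (log for
times and volumes, log1p for lesion counts, a two-point latent-Gaussian
encoding for the binary relapse flag) followed by standardization, so the
Gaussian factor layer always sees continuous, centred data.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm

from .cohort import DIMENSION_LABELS, FEATURES, obs_col

__all__ = [
    "SparseFactorModel",
    "SparseFactorResults",
    "fit_pfa",
    "assign_dimensions",
    "score_visits",
    "baseline_matrix",
    "transform_to_latent_scale",
]


# --------------------------------------------------------------- transforms
def binary_encoding(prevalence: float) -> tuple[float, float]:
    """Two-point encoding of a binary feature under a probit threshold model.

    Returns the conditional means of a standard-normal latent variable given
    the observed 0/1 outcome at the stated prevalence, scaled to unit
    marginal variance.
    """
    p = float(np.clip(prevalence, 1e-6, 1 - 1e-6))
    tau = norm.ppf(1 - p)
    c1 = norm.pdf(tau) / p
    c0 = -norm.pdf(tau) / (1 - p)
    scale = np.sqrt(c1**2 * p + c0**2 * (1 - p))
    return c0 / scale, c1 / scale


def transform_to_latent_scale(
    df: pd.DataFrame, relapse_encoding: tuple[float, float]
) -> np.ndarray:
    """Map raw measurements to the continuous latent scale (n x 8)."""
    from .preprocess import transform_feature

    cols = []
    c0, c1 = relapse_encoding
    for f in FEATURES:
        v = df[f].to_numpy(dtype=float)
        if f == "relapse":
            cols.append(np.where(v > 0.5, c1, c0))
        else:
            cols.append(transform_feature(f, v))
    return np.column_stack(cols)


def baseline_matrix(cohort: pd.DataFrame) -> tuple[np.ndarray, dict]:
    """Complete-case baseline rows on the latent scale, plus link metadata.

    Baseline is each patient's first fully observed grid row; the loading
    matrix is estimated from these complete records only.
    """
    obs = cohort[[obs_col(f) for f in FEATURES]].to_numpy(dtype=bool)
    complete = obs.all(axis=1) & cohort[FEATURES].notna().all(axis=1).to_numpy()
    rows = (
        cohort.loc[complete]
        .sort_values(["patient_id", "month"], kind="stable")
        .groupby("patient_id", as_index=False)
        .first()
    )
    prevalence = float(rows["relapse"].mean())
    encoding = binary_encoding(prevalence)
    X = transform_to_latent_scale(rows, encoding)
    meta = {"relapse_prevalence": prevalence, "relapse_encoding": encoding}
    return X, meta


# ------------------------------------------------------------------- model
def _laplace_logpdf(x: np.ndarray, b: float) -> np.ndarray:
    return -np.log(2 * b) - np.abs(x) / b


def _varimax(lam: np.ndarray, max_iter: int = 100, tol: float = 1e-8) -> np.ndarray:
    """Varimax rotation; used only to orient the EM starting point toward a
    simple structure (the penalized fit is rotation-sensitive)."""
    F, K = lam.shape
    if K < 2:
        return lam
    scale = np.abs(lam).max() or 1.0
    R = np.eye(K)
    var = 0.0
    for _ in range(max_iter):
        L = lam @ R
        u, s, vt = np.linalg.svd(
            lam.T @ (L**3 - (L * (L**2).sum(axis=0)) / F)
        )
        if s.sum() < 1e-10 * scale**4:
            break  # flat objective (e.g. rank-1 with equal rows): keep as is
        R = u @ vt
        new_var = s.sum()
        if new_var < var * (1 + tol):
            break
        var = new_var
    return lam @ R


def _responsibilities(lam, theta, b_slab, b_spike):
    l1 = np.log(theta)[None, :] + _laplace_logpdf(lam, b_slab)
    l0 = np.log1p(-theta)[None, :] + _laplace_logpdf(lam, b_spike)
    return 1.0 / (1.0 + np.exp(np.clip(l0 - l1, -700, 700)))


@dataclass
class SparseFactorResults:
    """Fitted loading model: sparse loadings, inclusion probabilities,
    uniquenesses, and the scaling needed to score new visits."""

    loadings: np.ndarray           # F x K_active, standardized feature scale
    inclusion_prob: np.ndarray     # F x K_active
    uniquenesses: np.ndarray       # F
    feature_names: list[str]
    center: np.ndarray
    scale: np.ndarray
    link_meta: dict = field(default_factory=dict)
    theta: np.ndarray | None = None
    objective: float = float("nan")
    objective_path: np.ndarray | None = None
    n_iter: int = 0
    converged: bool = True
    n_obs: int = 0

    @property
    def active_dimensions(self) -> int:
        return self.loadings.shape[1]

    # ------------------------------------------------------------- scoring
    def posterior_precision(self) -> np.ndarray:
        L, psi = self.loadings, self.uniquenesses
        return np.eye(L.shape[1]) + (L / psi[:, None]).T @ L

    def score_matrix(self, X_std: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Posterior mean and covariance of the composite scores given
        standardized data (ridge-regression form)."""
        L, psi = self.loadings, self.uniquenesses
        V = np.linalg.inv(self.posterior_precision())
        M = X_std @ (L / psi[:, None]) @ V
        return M, V

    def standardize(self, X_latent: np.ndarray) -> np.ndarray:
        return (X_latent - self.center) / self.scale

    def assign_dimensions(self):
        return assign_dimensions(self)

    def summary(self) -> pd.DataFrame:
        labels = assign_dimensions(self)[1]
        cols = [f"{lab} (dim {k + 1})" for k, lab in enumerate(labels)]
        tab = pd.DataFrame(self.loadings, index=self.feature_names, columns=cols)
        tab["uniqueness"] = self.uniquenesses
        return tab

    # ---------------------------------------------------------------- io
    def to_json(self, path) -> None:
        payload = {
            "loadings": self.loadings.tolist(),
            "inclusion_prob": self.inclusion_prob.tolist(),
            "uniquenesses": self.uniquenesses.tolist(),
            "feature_names": self.feature_names,
            "center": self.center.tolist(),
            "scale": self.scale.tolist(),
            "link_meta": self.link_meta,
            "theta": None if self.theta is None else self.theta.tolist(),
            "objective": self.objective,
            "converged": self.converged,
            "n_obs": self.n_obs,
            "labels": assign_dimensions(self)[1],
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "SparseFactorResults":
        with open(path) as fh:
            d = json.load(fh)
        return cls(
            loadings=np.asarray(d["loadings"], dtype=float),
            inclusion_prob=np.asarray(d["inclusion_prob"], dtype=float),
            uniquenesses=np.asarray(d["uniquenesses"], dtype=float),
            feature_names=list(d["feature_names"]),
            center=np.asarray(d["center"], dtype=float),
            scale=np.asarray(d["scale"], dtype=float),
            link_meta=d.get("link_meta", {}),
            theta=None if d.get("theta") is None else np.asarray(d["theta"]),
            objective=d.get("objective", float("nan")),
            converged=d.get("converged", True),
            n_obs=d.get("n_obs", 0),
        )


class SparseFactorModel:
    """Spike-and-slab factor analyser fit by MAP-EM.

    Parameters
    ----------
    X : array (n, F)
        Complete baseline rows on the latent scale (standardized internally).
    k_max : int
        Truncation level of the nonparametric column prior.
    spike_scale, slab_scale : float
        Scales of the two Laplace components, in standardized units.  The
        ratio sets the loading magnitude at which a feature flips from
        spike to slab (about 0.09 at the defaults with an even prior).
    alpha : float
        Concentration of the column-inclusion prior; columns receive a
        Beta(alpha / k_max, 1) prior on their slab probability.
    theta_max : float
        Upper clamp on each column's inclusion weight.  The MAP update
        would otherwise saturate at 1 for any active column, at which
        point the inclusion rule stops discriminating between dominant
        and incidental loadings.
    """

    def __init__(
        self,
        X: np.ndarray,
        feature_names: list[str] | None = None,
        k_max: int = 10,
        spike_scale: float = 0.05,
        slab_scale: float = 1.0,
        alpha: float = 1.0,
        theta_max: float = 0.8,
        link_meta: dict | None = None,
    ):
        X = np.asarray(X, dtype=float)
        if X.ndim != 2:
            raise ValueError("X must be a 2-D matrix")
        if not np.isfinite(X).all():
            raise ValueError("baseline matrix contains non-finite values")
        names = feature_names or [f"x{j}" for j in range(X.shape[1])]
        sd = X.std(axis=0)
        dead = [names[j] for j in np.flatnonzero(sd < 1e-10)]
        if dead:
            raise ValueError(f"zero-variance feature(s): {dead}")
        self.center = X.mean(axis=0)
        self.scale = sd
        self.X = (X - self.center) / self.scale
        self.feature_names = names
        self.k_max = int(k_max)
        self.b_spike = float(spike_scale)
        self.b_slab = float(slab_scale)
        self.alpha = float(alpha)
        self.theta_max = float(theta_max)
        self.link_meta = link_meta or {}

    # ------------------------------------------------------------ objective
    def _penalized_loglik(self, lam, psi, theta) -> float:
        n, F = self.X.shape
        S = self.X.T @ self.X / n
        V = np.linalg.inv(np.eye(lam.shape[1]) + (lam / psi[:, None]).T @ lam)
        sign, logdet_inner = np.linalg.slogdet(
            np.eye(lam.shape[1]) + (lam / psi[:, None]).T @ lam
        )
        logdet = np.sum(np.log(psi)) + logdet_inner
        Sinv_S = S / psi[:, None] - (lam / psi[:, None]) @ V @ (
            (lam / psi[:, None]).T @ S
        )
        ll = -0.5 * n * (F * np.log(2 * np.pi) + logdet + np.trace(Sinv_S))
        mix = np.logaddexp(
            np.log(theta)[None, :] + _laplace_logpdf(lam, self.b_slab),
            np.log1p(-theta)[None, :] + _laplace_logpdf(lam, self.b_spike),
        ).sum()
        a = self.alpha / self.k_max
        prior_theta = np.sum((a - 1.0) * np.log(theta))
        return float(ll + mix + prior_theta)

    # ---------------------------------------------------------------- EM
    def _em_loop(self, lam, psi, theta, max_iter, tol, mask=None):
        """Run the EM updates; loadings excluded by the boolean ``mask``
        (feature x column) are pinned at zero."""
        n, F = self.X.shape
        K = lam.shape[1]
        a = self.alpha / self.k_max
        path = []
        obj = -np.inf
        converged = False
        for it in range(max_iter):
            # E-step over scores.
            W = lam / psi[:, None]
            V = np.linalg.inv(np.eye(K) + W.T @ lam)
            M = self.X @ W @ V
            S_xh = self.X.T @ M
            S_hh = M.T @ M + n * V
            # E-step over spike/slab memberships.
            gamma = _responsibilities(lam, theta, self.b_slab, self.b_spike)
            # M-step: weighted lasso per feature row, by coordinate descent.
            w = gamma / self.b_slab + (1 - gamma) / self.b_spike
            diag = np.diag(S_hh).copy()
            for _ in range(8):
                for k in range(K):
                    r = S_xh[:, k] - lam @ S_hh[:, k] + lam[:, k] * diag[k]
                    thr = psi * w[:, k]
                    lam[:, k] = (
                        np.sign(r) * np.maximum(np.abs(r) - thr, 0.0) / diag[k]
                    )
                if mask is not None:
                    lam[~mask] = 0.0
            # M-step: uniquenesses and column inclusion weights.
            sxx = n  # columns are standardized
            psi = (
                sxx
                - 2 * np.einsum("fk,fk->f", lam, S_xh)
                + np.einsum("fk,kj,fj->f", lam, S_hh, lam)
            ) / n
            psi = np.maximum(psi, 1e-4)
            theta = np.clip(
                (gamma.sum(axis=0) + a - 1.0) / (F + a - 1.0),
                1e-3,
                self.theta_max,
            )
            new_obj = self._penalized_loglik(lam, psi, theta)
            path.append(new_obj)
            if it > 0 and abs(new_obj - obj) < tol * (1 + abs(obj)):
                obj = new_obj
                converged = True
                break
            obj = new_obj
        gamma = _responsibilities(lam, theta, self.b_slab, self.b_spike)
        return lam, psi, theta, gamma, obj, np.asarray(path), converged

    def _fit_once(self, rng, max_iter, tol, init_jitter):
        n, F = self.X.shape
        K = self.k_max
        # Varimax-rotated, eigenvalue-shrunk PCA start: the factor-analytic
        # signal scale is sqrt(max(eigenvalue - 1, 0)), so noise directions
        # start at zero instead of on the variance-splitting ridge, and the
        # rotation points the penalized fit at a simple structure.
        _, s, Vt = np.linalg.svd(self.X, full_matrices=False)
        lam = np.zeros((F, K))
        k0 = min(F, K)
        sig = np.sqrt(np.maximum(s[:k0] ** 2 / n - 1.0, 0.0))
        lam[:, :k0] = Vt[:k0].T * sig
        # jitter before rotating: varimax has a saddle at symmetric mixtures
        # of equally strong factors
        lam += max(init_jitter, 0.01) * rng.standard_normal((F, K))
        lam = _varimax(lam)
        psi = np.full(F, 0.5)
        theta = np.full(K, 0.5)
        fitted = self._em_loop(lam, psi, theta, max_iter, tol)
        lam, psi, theta, gamma, obj, path, converged = fitted

        # Discrete column search: zeroing or merging whole columns are moves
        # the smooth EM updates cannot make (inclusion responsibilities
        # saturate, and symmetric splits of one factor across columns are
        # fixed points), yet they often carry a higher posterior.  Weakest
        # candidates first; a move is kept when the polished objective
        # improves.
        F, K = lam.shape

        def polish(lam_t, trial_mask):
            return self._em_loop(
                np.where(trial_mask, lam_t, 0.0),
                psi.copy(),
                theta.copy(),
                150,
                tol,
                trial_mask,
            )

        mask = np.repeat(
            (np.abs(lam) > 1e-12).any(axis=0)[None, :], F, axis=0
        )
        while True:
            strength = np.abs(lam).sum(axis=0)
            active_cols = np.flatnonzero(strength > 1e-12)
            improved = False
            for k in active_cols[np.argsort(strength[active_cols])]:
                trial = mask.copy()
                trial[:, k] = False
                cand = polish(lam, trial)
                if cand[4] > obj:
                    lam, psi, theta, gamma, obj, _, converged = cand
                    mask = trial
                    improved = True
                    break
            if not improved and len(active_cols) >= 2:
                for i in range(len(active_cols)):
                    for j in range(i + 1, len(active_cols)):
                        a, b = active_cols[i], active_cols[j]
                        merged = lam.copy()
                        merged[:, a] = np.sign(
                            lam[:, a] + lam[:, b]
                        ) * np.sqrt(lam[:, a] ** 2 + lam[:, b] ** 2)
                        merged[:, b] = 0.0
                        trial = mask.copy()
                        trial[:, b] = False
                        cand = polish(merged, trial)
                        if cand[4] > obj:
                            lam, psi, theta, gamma, obj, _, converged = cand
                            mask = trial
                            improved = True
                            break
                    if improved:
                        break
            if not improved:
                break
        return lam, psi, theta, gamma, obj, path, converged

    def fit(
        self,
        restarts: int = 10,
        seed: int = 0,
        max_iter: int = 1500,
        tol: float = 1e-9,
    ) -> SparseFactorResults:
        """Run seeded EM restarts and keep the highest penalized likelihood."""
        seeds = np.random.SeedSequence(seed).spawn(restarts)
        best = None
        for r in range(restarts):
            rng = np.random.default_rng(seeds[r])
            jitter = 0.0 if r == 0 else 0.1
            fitted = self._fit_once(rng, max_iter, tol, jitter)
            if best is None or fitted[4] > best[4]:
                best = fitted
        lam, psi, theta, gamma, obj, path, converged = best

        active = (gamma > 0.5).any(axis=0)
        lam_a, gamma_a = lam[:, active], gamma[:, active]
        # Sign convention: orient each column so its dominant feature loads
        # positively.
        for k in range(lam_a.shape[1]):
            j = int(np.argmax(np.abs(lam_a[:, k])))
            if lam_a[j, k] < 0:
                lam_a[:, k] = -lam_a[:, k]
        # Stable ordering: by explained variance, descending.
        order = np.argsort(-(lam_a**2).sum(axis=0), kind="stable")
        return SparseFactorResults(
            loadings=lam_a[:, order],
            inclusion_prob=gamma_a[:, order],
            uniquenesses=psi,
            feature_names=list(self.feature_names),
            center=self.center,
            scale=self.scale,
            link_meta=dict(self.link_meta),
            theta=theta[active][order],
            objective=obj,
            objective_path=path,
            n_iter=len(path),
            converged=converged,
            n_obs=self.X.shape[0],
        )


# ------------------------------------------------------- module-level ops
def fit_pfa(
    baseline: np.ndarray | pd.DataFrame,
    feature_names: list[str] | None = None,
    seed: int = 0,
    restarts: int = 10,
    **prior,
) -> SparseFactorResults:
    """Fit the sparse factor analyser on complete baseline data."""
    if isinstance(baseline, pd.DataFrame):
        feature_names = feature_names or list(baseline.columns)
        baseline = baseline.to_numpy(dtype=float)
    model = SparseFactorModel(baseline, feature_names=feature_names, **prior)
    return model.fit(restarts=restarts, seed=seed)


def fit_pfa_cohort(
    cohort: pd.DataFrame, seed: int = 0, restarts: int = 10, **prior
) -> SparseFactorResults:
    """Convenience: baseline extraction, link transforms, then :func:`fit_pfa`."""
    X, meta = baseline_matrix(cohort)
    model = SparseFactorModel(
        X, feature_names=list(FEATURES), link_meta=meta, **prior
    )
    return model.fit(restarts=restarts, seed=seed)


_LABEL_RULES = [
    ("relapse", DIMENSION_LABELS["relapse"]),
    ("gd_count", DIMENSION_LABELS["activity"]),
    (("edss", "t25fwt", "nhpt"), DIMENSION_LABELS["disability"]),
    (("t2_volume", "nbv"), DIMENSION_LABELS["brain_damage"]),
]


def assign_dimensions(
    results: SparseFactorResults, feature_names: list[str] | None = None
) -> tuple[dict[str, set[int]], list[str]]:
    """Feature-to-dimension assignment and automatic dimension labels.

    A feature belongs to a dimension iff its posterior slab probability is
    strictly greater than 0.5.  Labels follow the clinical signature of the
    included features: relapse flag -> relapse; Gd count (without relapse)
    -> asymptomatic activity; EDSS/walk/peg -> physical disability; T2
    volume/brain volume -> brain damage; otherwise unassigned.
    """
    names = feature_names or results.feature_names
    incl = results.inclusion_prob > 0.5
    K = incl.shape[1]
    assignment = {
        f: {k for k in range(K) if incl[i, k]} for i, f in enumerate(names)
    }

    def strength(k, keys):
        idx = [names.index(f) for f in keys if f in names]
        return sum(
            abs(results.loadings[i, k]) for i in idx if incl[i, k]
        )

    # Greedy pass: each clinical label goes first to the column with the
    # strongest defining loadings, so a cross-loading (e.g. some Gd signal
    # on the brain-damage column) cannot steal a label from the column it
    # defines.
    labels: list[str | None] = [None] * K
    for key, lab in _LABEL_RULES:
        keys = (key,) if isinstance(key, str) else key
        open_cols = [k for k in range(K) if labels[k] is None]
        scored = [(strength(k, keys), k) for k in open_cols]
        scored = [t for t in scored if t[0] > 0]
        if scored:
            labels[max(scored)[1]] = lab
    # Residual pass: remaining columns take the first matching rule
    # (duplicate labels are legitimate when the structure repeats).
    for k in range(K):
        if labels[k] is not None:
            continue
        members = {names[i] for i in np.flatnonzero(incl[:, k])}
        labels[k] = "unassigned"
        for key, lab in _LABEL_RULES:
            keys = (key,) if isinstance(key, str) else key
            if members & set(keys):
                labels[k] = lab
                break
    return assignment, labels


def score_visits(
    results: SparseFactorResults, visits: pd.DataFrame
) -> pd.DataFrame:
    """Posterior mean composite scores for every (patient, month) visit.

    Visits must be complete on the model's features (imputation precedes
    scoring); the posterior covariance, shared by all visits, is stored in
    ``df.attrs['posterior_cov']`` together with the dimension labels.
    """
    bad = visits[FEATURES].isna().any(axis=1)
    if bad.any():
        rows = visits.loc[bad, ["patient_id", "month"]].head(20).to_records(
            index=False
        )
        raise ValueError(
            f"{int(bad.sum())} visits have missing features after imputation, "
            f"e.g. {list(rows)}"
        )
    encoding = tuple(results.link_meta.get("relapse_encoding", (0.0, 1.0)))
    X = transform_to_latent_scale(visits, encoding)
    M, V = results.score_matrix(results.standardize(X))
    out = visits[["patient_id", "month"]].copy().reset_index(drop=True)
    for k in range(M.shape[1]):
        out[f"score_{k}"] = M[:, k]
    out.attrs["posterior_cov"] = V
    out.attrs["dimension_labels"] = assign_dimensions(results)[1]
    return out
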