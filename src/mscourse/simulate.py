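"""Synthetic longitudinal MS cohorts.

Each patient follows a hidden Markov chain over disease states; every visit
draws a 4-dimensional composite-score vector from the state's Gaussian
emission, maps it through a sparse loading matrix plus feature noise, and
then through per-feature observation links (log-normal times and volumes,
rounded and clamped EDSS/PASAT, Poisson lesion counts, probit relapse flag).
Feature-specific missingness is applied afterwards, except at baseline
(month 0, the complete trial-entry battery) and for EDSS/relapse, which are
complete by design.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .cohort import (
    FEATURES,
    cohort_columns,
    obs_col,
    score_col,
)
from .config import ConfigError, GeneratorConfig


def _simulate_states(
    config: GeneratorConfig, n: int, T: int, rng: np.random.Generator
) -> np.ndarray:
    S = config.n_states
    states = np.empty((n, T), dtype=np.int64)
    states[:, 0] = rng.choice(S, size=n, p=config.initial)
    for t in range(1, T):
        prev = states[:, t - 1]
        # Inverse-CDF sampling with one uniform per patient keeps the draw
        # order independent of the state layout, hence reproducible.
        u = rng.random(n)
        cdf = np.cumsum(config.transition, axis=1)
        states[:, t] = (u[:, None] > cdf[prev]).sum(axis=1)
    return states


def _apply_link(name: str, link, u: np.ndarray, rng: np.random.Generator):
    if link.kind == "identity":
        x = link.loc + link.scale * u
    elif link.kind == "log":
        x = np.exp(link.loc + link.scale * u)
    elif link.kind == "count":
        rate = np.exp(np.clip(link.loc + link.scale * u, -30, 12))
        x = rng.poisson(rate).astype(float)
    elif link.kind == "binary":
        x = (u > link.loc).astype(float)
    else:  # pragma: no cover - guarded by config validation
        raise ConfigError(f"unknown link kind for {name}")
    if link.round == "half":
        x = np.round(2 * x) / 2
    elif link.round == "int":
        x = np.round(x)
    if link.clip is not None:
        x = np.clip(x, link.clip[0], link.clip[1])
    return x


def generate_cohort(config: GeneratorConfig, seed: int | None = None) -> pd.DataFrame:
    """Simulate a cohort table; identical ``(config, seed)`` give identical output."""
    config.validate()
    if seed is None:
        seed = config.seed
    rng = np.random.default_rng(int(seed))

    n, T = config.n_patients, config.n_months
    F, K = len(config.features), config.n_dimensions
    if n == 0:
        return pd.DataFrame(columns=cohort_columns(truth=True))

    states = _simulate_states(config, n, T, rng)

    chols = np.stack([np.linalg.cholesky(C) for C in config.state_covs])
    eps = rng.standard_normal((n, T, K))
    scores = config.state_means[states] + np.einsum(
        "ntk,ntjk->ntj", eps, chols[states]
    )

    noise = rng.standard_normal((n, T, F)) * np.sqrt(config.uniquenesses)
    latent = scores @ config.loading.T + noise

    values = np.empty((n, T, F))
    for j, f in enumerate(config.features):
        values[:, :, j] = _apply_link(f, config.feature_links[f], latent[:, :, j], rng)

    observed = rng.random((n, T, F)) >= config.missing_rates
    observed[:, 0, :] = True  # complete baseline battery
    for j, f in enumerate(config.features):
        if f in ("edss", "relapse"):
            observed[:, :, j] = True

    pid = np.repeat(np.arange(1, n + 1), T)
    month = np.tile(np.arange(T), n)
    data = {"patient_id": pid, "month": month}
    flat_vals = values.reshape(n * T, F)
    flat_obs = observed.reshape(n * T, F)
    for j, f in enumerate(config.features):
        col = flat_vals[:, j].astype(float)
        col = np.where(flat_obs[:, j], col, np.nan)
        data[f] = col
        data[obs_col(f)] = flat_obs[:, j].astype(int)
    data["relapse"] = flat_vals[:, config.features.index("relapse")].astype(int)
    data["treated"] = np.full(n * T, int(config.treated))
    data["true_state"] = states.reshape(-1) + 1
    for k, d in enumerate(config.dimensions):
        data[score_col(d)] = scores[:, :, k].reshape(-1)

    df = pd.DataFrame(data)
    return df[cohort_columns(truth=True)]


def simulate_two_arm(
    config: GeneratorConfig, multiplier: float, seed: int
) -> pd.DataFrame:
    """Placebo plus treated arm of equal size, with distinct patient ids."""
    from .config import apply_treatment_effect

    placebo = generate_cohort(config.replace(treated=False), seed=seed)
    treated_cfg = apply_treatment_effect(config, multiplier)
    treated = generate_cohort(treated_cfg, seed=int(seed) + 1)
    treated = treated.assign(
        patient_id=treated["patient_id"] + config.n_patients
    )
    return pd.concat([placebo, treated], ignore_index=True)
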