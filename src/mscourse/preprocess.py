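"""Visit-grid mapping, imputation, PIRA derivation and cohort splitting.

These steps turn raw visit records into the regular monthly (or six-monthly)
analysis grid the state model assumes, fill partially observed visits from
each patient's own trajectory, derive confirmed disability-progression
events, and build clustered discovery/holdout partitions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.interpolate import make_smoothing_spline
from sklearn.cluster import KMeans

from .cohort import FEATURES, obs_col

DAYS_PER_MONTH = 30.44

#: Features eligible for trajectory imputation (EDSS and relapse are complete).
IMPUTABLE_FEATURES = ["t25fwt", "nhpt", "pasat", "t2_volume", "nbv", "gd_count"]

#: Transform applied before smoothing, per feature (positive features are
#: smoothed on the log scale, counts on log1p).
_TRANSFORMS = {
    "t25fwt": (np.log, np.exp),
    "nhpt": (np.log, np.exp),
    "t2_volume": (lambda x: np.log(np.maximum(x, 1e-3)), np.exp),
    "gd_count": (np.log1p, np.expm1),
}


def transform_feature(name: str, values: np.ndarray) -> np.ndarray:
    fwd = _TRANSFORMS.get(name, (None, None))[0]
    return fwd(values) if fwd is not None else np.asarray(values, dtype=float)


def _back_transform(name: str, values: np.ndarray) -> np.ndarray:
    inv = _TRANSFORMS.get(name, (None, None))[1]
    out = inv(values) if inv is not None else np.asarray(values, dtype=float)
    if name == "gd_count":
        out = np.clip(np.round(out), 0, None)
    elif name == "pasat":
        out = np.clip(np.round(out), 0, 60)
    return out


@dataclass
class GridSpec:
    """Analysis grid: monthly for clinical trials, six-monthly for real-world data."""

    interval_months: int = 1

    def __post_init__(self):
        if self.interval_months not in (1, 6):
            raise ValueError("interval_months must be 1 or 6")


@dataclass
class PiraEvent:
    """Confirmed disability worsening with no attributable relapse."""

    patient_id: object
    onset_month: int
    confirmed: bool
    baseline_edss: float


def map_to_grid(raw_visits: pd.DataFrame, spec: GridSpec) -> pd.DataFrame:
    """Map day-offset visits to the regular grid and merge collisions.

    Month index is ``round(days / 30.44 / interval) * interval`` with ties
    rounded half-up.  When two visits fall in the same slot, non-missing
    values win, relapse flags are OR-ed, and conflicts on the same feature
    resolve toward the unscheduled (relapse) visit.  Already-gridded input
    (a ``month`` column and no ``day`` column) passes through unchanged.
    """
    df = raw_visits.copy()
    if "day" not in df.columns:
        if "month" not in df.columns:
            raise ValueError("raw visits need a 'day' or 'month' column")
        return df
    days = df["day"].to_numpy(dtype=float)
    if np.any(days < 0):
        raise ValueError("negative day offsets")
    i = spec.interval_months
    df["month"] = (np.floor(days / DAYS_PER_MONTH / i + 0.5) * i).astype(int)
    df = df.drop(columns=["day"])

    # Within each slot, sort so the preferred source (relapse visit) comes
    # last; groupby(...).last() then takes the last non-null per column.
    df = df.sort_values(["patient_id", "month", "relapse"], kind="stable")
    grouped = df.groupby(["patient_id", "month"], as_index=False)
    merged = grouped.last()
    merged["relapse"] = grouped["relapse"].max()["relapse"]
    for f in FEATURES:
        oc = obs_col(f)
        if oc in df.columns:
            merged[oc] = grouped[oc].max()[oc]
            merged.loc[merged[f].isna(), oc] = 0
    return merged.reset_index(drop=True)


def _impute_series(
    months: np.ndarray,
    values: np.ndarray,
    targets: np.ndarray,
    min_spline_points: int = 5,
) -> np.ndarray:
    """Fill ``targets`` from observed (months, values) with a penalized spline,
    falling back to linear interpolation then carry-forward.

    The spline is only trusted inside the observed span (nearest observed
    value is carried beyond it) and predictions are clipped to the range of
    the patient's own observations: imputation interpolates a trajectory,
    it must not extrapolate new extremes.
    """
    n = len(months)
    months = months.astype(float)
    targets = targets.astype(float)
    values = values.astype(float)
    if n >= 2:
        out = np.interp(targets, months, values)
    else:
        return np.full(len(targets), values[0], dtype=float)
    if n >= min_spline_points:
        try:
            spl = make_smoothing_spline(months, values)
            inside = (targets >= months[0]) & (targets <= months[-1])
            out[inside] = np.asarray(spl(targets[inside]), dtype=float)
        except Exception:
            pass  # degenerate geometry: keep the linear fill
    return np.clip(out, values.min(), values.max())


def impute_partial_visits(
    cohort: pd.DataFrame,
    features: list[str] | None = None,
    min_spline_points: int = 5,
) -> pd.DataFrame:
    """Fill missing cells at rows where at least one feature is observed.

    Observed values are never altered; rows with no observed feature stay
    absent; cells that cannot be filled (feature never observed for the
    patient) remain missing and are reported in ``df.attrs['unimputable']``.
    Filled cells keep ``obs_<feature> = 0``, which doubles as the imputation
    flag.
    """
    features = IMPUTABLE_FEATURES if features is None else features
    df = cohort.sort_values(["patient_id", "month"], kind="stable").reset_index(
        drop=True
    )
    any_observed = (
        df[[obs_col(f) for f in FEATURES if obs_col(f) in df.columns]]
        .to_numpy()
        .any(axis=1)
    )
    unimputable: list[tuple[object, str]] = []
    for pid, idx in df.groupby("patient_id").indices.items():
        idx = np.asarray(idx)
        months = df.loc[idx, "month"].to_numpy(dtype=float)
        eligible = any_observed[idx]
        for f in features:
            vals = df.loc[idx, f].to_numpy(dtype=float)
            obs = df.loc[idx, obs_col(f)].to_numpy(dtype=bool) & np.isfinite(vals)
            need = eligible & ~obs
            if not need.any():
                continue
            if not obs.any():
                unimputable.append((pid, f))
                continue
            fitted = _impute_series(
                months[obs],
                transform_feature(f, vals[obs]),
                months[need],
                min_spline_points,
            )
            df.loc[idx[need], f] = _back_transform(f, fitted)
    df.attrs["unimputable"] = unimputable
    return df


def evaluate_imputation(
    cohort: pd.DataFrame,
    holdout_fraction: float = 0.1,
    seed: int = 0,
    features: list[str] | None = None,
) -> pd.Series:
    """Mask a random fraction of observed cells, re-impute, and report the
    per-feature mean absolute error on the standardized (transform) scale."""
    if not 0 < holdout_fraction < 1:
        raise ValueError("holdout_fraction must be in (0, 1)")
    features = IMPUTABLE_FEATURES if features is None else features
    rng = np.random.default_rng(seed)
    df = cohort.copy().reset_index(drop=True)
    held: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for f in features:
        obs = (df[obs_col(f)].to_numpy(dtype=bool)) & df[f].notna().to_numpy()
        candidates = np.flatnonzero(obs)
        k = int(round(holdout_fraction * len(candidates)))
        if k == 0:
            continue
        drop = rng.choice(candidates, size=k, replace=False)
        held[f] = (drop, df.loc[drop, f].to_numpy(dtype=float))
        df.loc[drop, f] = np.nan
        df.loc[drop, obs_col(f)] = 0
    imputed = impute_partial_visits(df, features=features)
    mae = {}
    for f, (drop, truth) in held.items():
        t_truth = transform_feature(f, truth)
        scale = np.nanstd(transform_feature(f, cohort[f].to_numpy(dtype=float)))
        scale = scale if scale > 0 else 1.0
        est = transform_feature(f, imputed.loc[drop, f].to_numpy(dtype=float))
        mae[f] = float(np.nanmean(np.abs(est - t_truth)) / scale)
    return pd.Series(mae, name="mae_standardized")


def update_brain_volume(baseline_nbv: float, pbvc_series) -> np.ndarray:
    """Longitudinal normalized brain volume from baseline volume and percent
    change from baseline: ``nbv_t = baseline * (1 + pbvc_t / 100)``."""
    if baseline_nbv <= 0:
        raise ValueError("baseline normalized brain volume must be positive")
    pbvc = np.asarray(pbvc_series, dtype=float)
    if np.any(pbvc <= -100):
        raise ValueError("percent brain-volume change must exceed -100")
    return baseline_nbv * (1.0 + pbvc / 100.0)


def edss_worsening_threshold(baseline_edss: float) -> float:
    """Minimal EDSS increase that counts as worsening, by baseline band."""
    if baseline_edss == 0:
        return 1.5
    if baseline_edss <= 5.0:
        return 1.0
    return 0.5


def derive_pira(
    edss_series,
    relapse_series,
    baseline_edss: float,
    months=None,
    confirm_months: int = 3,
    pre_onset_window: int = 1,
) -> PiraEvent | None:
    """First confirmed disability worsening independent of relapse activity.

    Onset is the first visit with an EDSS increase over baseline of at least
    the band threshold; the event is confirmed if every assessment from onset
    through at least ``confirm_months`` later stays at/above threshold, with
    no relapse from ``pre_onset_window`` months before onset through the
    confirmatory visit, and no later drop below threshold within follow-up.
    """
    edss = np.asarray(edss_series, dtype=float)
    relapse = np.asarray(relapse_series, dtype=int)
    if edss.size == 0:
        raise ValueError("empty EDSS series")
    if months is None:
        months = np.arange(edss.size)
    months = np.asarray(months)
    thr = edss_worsening_threshold(baseline_edss)
    level = baseline_edss + thr

    for i in range(edss.size):
        if not np.isfinite(edss[i]) or edss[i] < level:
            continue
        # Onset = first crossing of the worsening level; a sustained plateau
        # has a single onset (a relapse-attributed crossing is not re-dated
        # to the next visit).
        if i > 0 and np.isfinite(edss[i - 1]) and edss[i - 1] >= level:
            continue
        t0 = months[i]
        if relapse[(months >= t0 - pre_onset_window) & (months <= t0)].any():
            continue
        conf = np.flatnonzero(months >= t0 + confirm_months)
        if conf.size == 0:
            continue
        j = conf[0]
        window = slice(i, j + 1)
        if np.any(edss[window] < level) or relapse[window].any():
            continue
        if np.any(edss[j + 1 :] < level):  # irreversibility over follow-up
            continue
        return PiraEvent(
            patient_id=None,
            onset_month=int(t0),
            confirmed=True,
            baseline_edss=float(baseline_edss),
        )
    return None


def derive_pira_cohort(cohort: pd.DataFrame) -> pd.DataFrame:
    """Per-patient time-to-first-PIRA table (time, event flag, baseline EDSS)."""
    rows = []
    for pid, g in cohort.sort_values(["patient_id", "month"]).groupby("patient_id"):
        months = g["month"].to_numpy()
        baseline = float(g["edss"].iloc[0])
        ev = derive_pira(
            g["edss"].to_numpy(), g["relapse"].to_numpy(), baseline, months=months
        )
        if ev is not None:
            rows.append((pid, ev.onset_month, 1, baseline))
        else:
            rows.append((pid, int(months.max()), 0, baseline))
    return pd.DataFrame(
        rows, columns=["patient_id", "time", "event", "baseline_edss"]
    )


def kmeans_elbow_curve(
    mean_scores: pd.DataFrame, k_range=range(1, 9), seed: int = 0
) -> pd.Series:
    """Total within-cluster variance by k, for elbow inspection."""
    X = mean_scores.to_numpy(dtype=float)
    inertia = {}
    for k in k_range:
        km = KMeans(n_clusters=k, n_init=10, random_state=seed).fit(X)
        inertia[k] = float(km.inertia_)
    return pd.Series(inertia, name="within_cluster_variance")


def split_discovery_holdout(
    mean_scores: pd.DataFrame,
    k: int = 5,
    holdout_frac: float = 0.2,
    seed: int = 0,
) -> pd.DataFrame:
    """Clustered discovery/holdout partition of patients.

    Patients are k-means-clustered on their per-patient mean composite
    scores; within each cluster ``round(holdout_frac * size)`` patients go to
    the holdout set.  ``mean_scores`` is indexed by patient id.
    """
    if k < 1:
        raise ValueError("k must be at least 1")
    if not 0 < holdout_frac < 1:
        raise ValueError("holdout_frac must be in (0, 1)")
    n = len(mean_scores)
    if k > n:
        raise ValueError(f"k={k} exceeds the number of patients ({n})")
    X = mean_scores.to_numpy(dtype=float)
    labels = KMeans(n_clusters=k, n_init=10, random_state=seed).fit_predict(X)
    rng = np.random.default_rng(seed)
    assignment = np.full(n, "discovery", dtype=object)
    for c in range(k):
        members = np.flatnonzero(labels == c)
        n_hold = int(round(holdout_frac * len(members)))
        if n_hold:
            assignment[rng.choice(members, size=n_hold, replace=False)] = "holdout"
    return pd.DataFrame(
        {"patient_id": mean_scores.index, "set": assignment, "cluster": labels}
    )
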