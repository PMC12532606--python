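"""Long-format patient-visit tables and feature metadata.

A cohort is a plain :class:`pandas.DataFrame` with one row per patient-visit.
Besides the eight modelled measurements it carries a per-feature observation
mask (``obs_<feature>`` columns, 1 = measured, 0 = missing or imputed), a
treatment flag, and — for synthetic cohorts — latent ground-truth columns
(``true_state`` and one ``true_score_<dimension>`` per latent dimension).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

#: Modelled measurements, in canonical order.
FEATURES = [
    "edss",        # Expanded Disability Status Scale, 0-10 in half points
    "t25fwt",      # timed 25-foot walk, seconds
    "nhpt",        # 9-hole peg test, seconds
    "pasat",       # paced auditory serial addition test, 0-60 correct
    "t2_volume",   # T2 lesion volume, ml
    "nbv",         # normalized brain volume, liters
    "gd_count",    # gadolinium-enhancing T1 lesion count
    "relapse",     # physician-confirmed relapse at the visit, 0/1
]

#: Latent MS dimensions, in canonical order.
DIMENSIONS = ["disability", "brain_damage", "relapse", "activity"]

#: Human-readable dimension names used by the labelling rules.
DIMENSION_LABELS = {
    "disability": "physical disability",
    "brain_damage": "brain damage",
    "relapse": "relapse",
    "activity": "asymptomatic activity",
}

#: Meta-state names in canonical (severity) order.
META_STATES = ["eme", "activity", "relapse", "advanced"]

ID_COLS = ["patient_id", "month"]


def obs_col(feature: str) -> str:
    return f"obs_{feature}"


def score_col(dimension: str) -> str:
    return f"true_score_{dimension}"


OBS_COLS = [obs_col(f) for f in FEATURES]
SCORE_COLS = [score_col(d) for d in DIMENSIONS]


def cohort_columns(truth: bool = True) -> list[str]:
    cols = ID_COLS + FEATURES + ["treated"] + OBS_COLS
    if truth:
        cols += ["true_state"] + SCORE_COLS
    return cols


def on_half_grid(values: np.ndarray) -> bool:
    """True if all finite values lie on the EDSS half-point grid in [0, 10]."""
    v = np.asarray(values, dtype=float)
    v = v[np.isfinite(v)]
    if v.size == 0:
        return True
    return bool(
        np.all(v >= 0) and np.all(v <= 10) and np.allclose(2 * v, np.round(2 * v))
    )


def validate_cohort(df: pd.DataFrame, require_truth: bool = False) -> None:
    """Check the cohort-table invariants, raising ``ValueError`` on violation."""
    missing = [c for c in cohort_columns(truth=False) if c not in df.columns]
    if missing:
        raise ValueError(f"cohort table lacks columns: {missing}")
    if require_truth:
        lost = [c for c in ["true_state"] + SCORE_COLS if c not in df.columns]
        if lost:
            raise ValueError(f"cohort table lacks ground-truth columns: {lost}")
    if df.duplicated(subset=ID_COLS).any():
        raise ValueError("duplicate (patient_id, month) pairs")
    if not on_half_grid(df["edss"].to_numpy()):
        raise ValueError("edss values off the half-point grid")
    relapse_obs = df[obs_col("relapse")].to_numpy()
    if np.any((df["relapse"].to_numpy() == 1) & (relapse_obs != 1)):
        raise ValueError("relapse=1 rows must have the relapse flag observed")


def write_cohort(df: pd.DataFrame, path, truth: bool = True) -> None:
    """Write a cohort as UTF-8 CSV with NA for missing cells."""
    cols = [c for c in cohort_columns(truth=truth) if c in df.columns]
    df[cols].to_csv(path, index=False, na_rep="NA", float_format="%.10g")


def read_cohort(path) -> pd.DataFrame:
    df = pd.read_csv(path, na_values=["NA"])
    for c in OBS_COLS + ["treated", "relapse"]:
        if c in df.columns:
            df[c] = df[c].astype(int)
    return df
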