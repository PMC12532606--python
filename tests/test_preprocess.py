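"""Grid mapping, imputation, brain-volume updates, PIRA, cohort splits."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import mscourse as m
from mscourse.cohort import FEATURES, obs_col
from mscourse.preprocess import (
    GridSpec,
    derive_pira,
    edss_worsening_threshold,
    evaluate_imputation,
    kmeans_elbow_curve,
)


def _raw_visits(rows):
    """rows: list of (patient_id, day, edss, relapse)."""
    recs = []
    for pid, day, edss, relapse in rows:
        rec = {f: np.nan for f in FEATURES}
        rec.update({obs_col(f): 0 for f in FEATURES})
        rec.update(
            patient_id=pid, day=day, edss=edss, relapse=relapse,
            treated=0,
        )
        rec[obs_col("edss")] = 1
        rec[obs_col("relapse")] = 1
        recs.append(rec)
    return pd.DataFrame(recs)


class TestGridMapping:
    def test_baseline_day_maps_to_month_zero(self):
        df = m.map_to_grid(_raw_visits([(1, 0, 2.0, 0)]), GridSpec(1))
        assert df["month"].tolist() == [0]

    def test_nearby_days_merge_into_one_slot(self):
        raw = _raw_visits([(1, 29, 2.0, 0), (1, 33, np.nan, 1)])
        raw.loc[1, obs_col("edss")] = 0
        df = m.map_to_grid(raw, GridSpec(1))
        assert len(df) == 1
        assert df.loc[0, "month"] == 1
        assert df.loc[0, "edss"] == 2.0       # non-missing value wins
        assert df.loc[0, "relapse"] == 1      # flags OR-ed

    def test_conflicts_resolve_toward_relapse_visit(self):
        raw = _raw_visits([(1, 29, 2.0, 0), (1, 33, 3.5, 1)])
        df = m.map_to_grid(raw, GridSpec(1))
        assert df.loc[0, "edss"] == 3.5

    def test_six_month_grid(self):
        df = m.map_to_grid(_raw_visits([(1, 183, 2.0, 0)]), GridSpec(6))
        assert df.loc[0, "month"] == 6

    def test_idempotent_on_gridded_data(self, small_cohort):
        out = m.map_to_grid(small_cohort, GridSpec(1))
        pd.testing.assert_frame_equal(out, small_cohort)

    def test_negative_day_rejected(self):
        with pytest.raises(ValueError, match="negative"):
            m.map_to_grid(_raw_visits([(1, -3, 2.0, 0)]), GridSpec(1))

    def test_interval_restricted_to_supported_grids(self):
        with pytest.raises(ValueError):
            GridSpec(3)


def _series_cohort(values, feature="nbv", months=None):
    months = np.arange(len(values)) if months is None else months
    rec = {
        "patient_id": 1,
        "month": months,
        "treated": 0,
    }
    df = pd.DataFrame(rec)
    for f in FEATURES:
        df[f] = 2.0 if f != feature else values
        df[obs_col(f)] = 1
    df.loc[:, "edss"] = 2.0
    df.loc[:, "relapse"] = 0
    vals = np.asarray(values, dtype=float)
    df[feature] = vals
    df[obs_col(feature)] = (~np.isnan(vals)).astype(int)
    return df


class TestImputation:
    def test_fully_observed_returned_unchanged(self, small_cohort):
        complete = small_cohort[small_cohort["month"] == 0].copy()
        out = m.impute_partial_visits(complete)
        pd.testing.assert_frame_equal(
            out.reset_index(drop=True), complete.reset_index(drop=True)
        )

    def test_linear_trend_gap_recovers_interpolant(self):
        vals = 1.5 - 0.01 * np.arange(10)
        vals_gap = vals.copy()
        vals_gap[4] = np.nan
        df = m.impute_partial_visits(_series_cohort(vals_gap))
        assert df.loc[4, "nbv"] == pytest.approx(vals[4], abs=1e-6)

    def test_constant_series_imputes_constant(self):
        vals = np.full(4, 1.48)
        vals[2] = np.nan
        df = m.impute_partial_visits(_series_cohort(vals))
        assert df.loc[2, "nbv"] == pytest.approx(1.48, abs=1e-9)

    def test_observed_cells_never_altered_and_no_new_rows(self, small_cohort):
        out = m.impute_partial_visits(small_cohort)
        assert len(out) == len(small_cohort)
        key = ["patient_id", "month"]
        merged = small_cohort.merge(out, on=key, suffixes=("_a", "_b"))
        for f in FEATURES:
            obs = merged[f"{obs_col(f)}_a"] == 1
            np.testing.assert_allclose(
                merged.loc[obs, f + "_a"], merged.loc[obs, f + "_b"]
            )

    def test_never_observed_feature_reported_unimputable(self):
        vals = np.full(6, np.nan)
        df = m.impute_partial_visits(_series_cohort(vals))
        assert df["nbv"].isna().all()
        assert (1, "nbv") in df.attrs["unimputable"]

    def test_imputed_values_stay_in_observed_range(self, small_cohort):
        out = m.impute_partial_visits(small_cohort)
        for f in ("t2_volume", "nbv"):
            imputed = out[(out[obs_col(f)] == 0) & out[f].notna()]
            lo, hi = small_cohort[f].min(), small_cohort[f].max()
            assert imputed[f].between(lo, hi).all()


class TestImputationError:
    def test_noise_free_linear_trajectories_recovered(self):
        vals = np.linspace(1.55, 1.40, 12)
        df = _series_cohort(vals)
        mae = evaluate_imputation(df, holdout_fraction=0.25, seed=1,
                                  features=["nbv"])
        assert mae["nbv"] < 1e-6

    def test_default_cohort_reports_all_imputable_features(self, small_cohort):
        mae = evaluate_imputation(small_cohort, holdout_fraction=0.1, seed=2)
        expected = {"t25fwt", "nhpt", "pasat", "t2_volume", "nbv", "gd_count"}
        assert set(mae.index) == expected
        assert np.isfinite(mae.to_numpy()).all()
        assert (mae > 0).all()

    def test_invalid_fraction_rejected(self, small_cohort):
        with pytest.raises(ValueError):
            evaluate_imputation(small_cohort, holdout_fraction=1.5)


class TestBrainVolume:
    @pytest.mark.parametrize(
        "baseline,pbvc,expected",
        [(1.5, 0.0, 1.5), (1.5, -1.0, 1.485), (1.44, 2.0, 1.4688)],
    )
    def test_update_formula(self, baseline, pbvc, expected):
        out = m.update_brain_volume(baseline, [pbvc])
        assert out[0] == pytest.approx(expected)

    def test_total_loss_rejected(self):
        with pytest.raises(ValueError):
            m.update_brain_volume(1.5, [-100.0])
        with pytest.raises(ValueError):
            m.update_brain_volume(0.0, [1.0])


class TestPira:
    def test_flat_series_has_no_event(self):
        assert derive_pira([2.0] * 24, [0] * 24, 2.0) is None

    def test_sustained_worsening_confirmed_at_onset(self):
        edss = [3.0] * 6 + [4.0] * 18
        ev = derive_pira(edss, [0] * 24, 3.0)
        assert ev is not None and ev.confirmed
        assert ev.onset_month == 6

    def test_relapse_at_onset_excludes_event(self):
        edss = [3.0] * 6 + [4.0] * 18
        relapse = [0] * 24
        relapse[6] = 1
        assert derive_pira(edss, relapse, 3.0) is None

    def test_relapse_before_confirmation_excludes_event(self):
        edss = [3.0] * 6 + [4.0] * 18
        relapse = [0] * 24
        relapse[8] = 1
        assert derive_pira(edss, relapse, 3.0) is None

    def test_reversible_worsening_not_counted(self):
        edss = [3.0] * 6 + [4.0] * 10 + [3.0] * 8
        assert derive_pira(edss, [0] * 24, 3.0) is None

    @pytest.mark.parametrize(
        "baseline,thr", [(0.0, 1.5), (1.0, 1.0), (4.5, 1.0), (5.5, 0.5)]
    )
    def test_worsening_thresholds_by_baseline_band(self, baseline, thr):
        assert edss_worsening_threshold(baseline) == thr

    def test_empty_series_rejected(self):
        with pytest.raises(ValueError):
            derive_pira([], [], 2.0)

    @given(delay=st.integers(min_value=0, max_value=8))
    @settings(max_examples=9, deadline=None, derandomize=True)
    def test_onset_shifts_with_the_worsening(self, delay):
        base = 6 + delay
        edss = [3.0] * base + [4.0] * (30 - base)
        ev = derive_pira(edss, [0] * 30, 3.0)
        assert ev is not None and ev.onset_month == base


class TestSplit:
    def _mean_scores(self, n, rng, centers=None):
        X = rng.normal(size=(n, 4))
        if centers is not None:
            X = X * 0.01 + centers
        return pd.DataFrame(X, index=pd.RangeIndex(1, n + 1, name="patient_id"))

    def test_single_cluster_eighty_twenty(self, rng):
        df = self._mean_scores(10, rng)
        out = m.split_discovery_holdout(df, k=1, holdout_frac=0.2, seed=0)
        assert (out["set"] == "holdout").sum() == 2
        assert (out["set"] == "discovery").sum() == 8

    def test_separable_clusters_recovered(self, rng):
        centers = np.repeat([[0.0] * 4, [5.0] * 4], 20, axis=0)
        df = self._mean_scores(40, rng, centers)
        out = m.split_discovery_holdout(df, k=2, holdout_frac=0.2, seed=0)
        lab = out.set_index("patient_id")["cluster"]
        assert lab.iloc[:20].nunique() == 1
        assert lab.iloc[20:].nunique() == 1
        assert lab.iloc[0] != lab.iloc[-1]

    def test_same_seed_reproduces_partition(self, rng):
        df = self._mean_scores(50, rng)
        a = m.split_discovery_holdout(df, k=5, holdout_frac=0.2, seed=3)
        b = m.split_discovery_holdout(df, k=5, holdout_frac=0.2, seed=3)
        pd.testing.assert_frame_equal(a, b)

    def test_holdout_fraction_within_cluster_tolerance(self, rng):
        df = self._mean_scores(200, rng)
        out = m.split_discovery_holdout(df, k=5, holdout_frac=0.2, seed=1)
        sizes = out.groupby("cluster")["set"].count()
        frac = (out["set"] == "holdout").mean()
        assert abs(frac - 0.2) <= 1.0 / sizes.min()

    def test_more_clusters_than_patients_rejected(self, rng):
        with pytest.raises(ValueError):
            m.split_discovery_holdout(self._mean_scores(3, rng), k=5)

    def test_elbow_curve_is_nonincreasing(self, rng):
        df = self._mean_scores(60, rng)
        curve = kmeans_elbow_curve(df, k_range=range(1, 6), seed=0)
        assert (np.diff(curve.to_numpy()) <= 1e-9).all()
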