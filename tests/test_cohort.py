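"""Cohort generator and preprocessing behaviour."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from sarsmon.cohort import (
    CHANNELS,
    CohortConfig,
    ConfigurationError,
    LABEL_NORMAL,
    LABEL_RISK,
    PreprocessParams,
    Preprocessor,
    generate_cohort,
    inject_missingness,
    preprocess,
)


class TestGenerate:
    def test_shape_and_exact_class_counts(self, small_cohort):
        df = small_cohort
        assert len(df) == 100 * 30
        per_patient = df.groupby("patient_id")["label"].agg(["first", "nunique"])
        assert (per_patient["nunique"] == 1).all(), "label must be constant per patient"
        counts = per_patient["first"].value_counts()
        assert counts[LABEL_NORMAL] == 60 and counts[LABEL_RISK] == 40

    @pytest.mark.parametrize("fraction,expected", [(0.5, 5), (0.61, 6), (0.349, 3)])
    def test_class_count_rounding(self, fraction, expected):
        cfg = CohortConfig(
            n_patients=10, records_per_patient=2, normal_fraction=fraction, seed=0
        )
        assert cfg.n_normal == expected
        df = generate_cohort(cfg)
        n_normal = df.groupby("patient_id")["label"].first().eq(LABEL_NORMAL).sum()
        assert n_normal == expected

    def test_degenerate_single_patient(self):
        df = generate_cohort(
            CohortConfig(n_patients=1, records_per_patient=3, missing_rate=0.0, seed=1)
        )
        assert len(df) == 3
        assert df["label"].nunique() == 1
        assert list(df["tick"]) == [0, 1, 2]

    def test_seed_determinism(self):
        cfg = CohortConfig(n_patients=20, records_per_patient=5, seed=3)
        a, b = generate_cohort(cfg), generate_cohort(cfg)
        pd.testing.assert_frame_equal(a, b)
        c = generate_cohort(CohortConfig(n_patients=20, records_per_patient=5, seed=4))
        assert not a[list(CHANNELS)].equals(c[list(CHANNELS)])

    def test_values_within_class_clip_ranges(self, small_cohort):
        cfg = CohortConfig()
        for label, clip_attr in ((LABEL_NORMAL, "normal_clip"), (LABEL_RISK, "risk_clip")):
            sub = small_cohort[small_cohort["label"] == label]
            for name in CHANNELS:
                lo, hi = getattr(cfg.channels[name], clip_attr)
                vals = sub[name].dropna()
                assert vals.between(lo, hi).all(), f"{name} out of range for {label}"

    @pytest.mark.parametrize(
    "kwargs",
        [
            {"n_patients": 0},
            {"records_per_patient": -1},
            {"normal_fraction": 1.2},
            {"missing_rate": 1.0},
        ],
    )
    def test_invalid_config_rejected(self, kwargs):
        with pytest.raises(ConfigurationError):
            CohortConfig(**kwargs)

    def test_config_dict_round_trip(self):
        cfg = CohortConfig(n_patients=12, records_per_patient=4, seed=9)
        again = CohortConfig.from_dict(cfg.to_dict())
        assert again == cfg
        pd.testing.assert_frame_equal(generate_cohort(cfg), generate_cohort(again))


class TestMissingness:
    def test_rate_zero_masks_nothing(self, small_cohort):
        clean = small_cohort.dropna()
        out = inject_missingness(clean, 0.0, seed=1)
        assert out.notna().all().all()

    def test_masked_fraction_within_binomial_interval(self):
        df = generate_cohort(
            CohortConfig(n_patients=125, records_per_patient=120, missing_rate=0.0, seed=2)
        )
        rate = 0.05
        out = inject_missingness(df, rate, seed=5)
        n_cells = len(out) * len(CHANNELS)
        n_missing = int(out[list(CHANNELS)].isna().sum().sum())
        lo, hi = stats.binom.interval(0.99, n_cells, rate)
        assert lo <= n_missing <= hi
        # identifiers and label untouched
        assert out[["patient_id", "tick", "label"]].notna().all().all()

    def test_reproducible_under_seed(self, small_cohort):
        a = inject_missingness(small_cohort, 0.1, seed=42)
        b = inject_missingness(small_cohort, 0.1, seed=42)
        pd.testing.assert_frame_equal(a, b)

    def test_rate_one_rejected(self, small_cohort):
        with pytest.raises(ConfigurationError):
            inject_missingness(small_cohort, 1.0, seed=0)


def _series_frame(values, channel="heart_rate"):
    df = pd.DataFrame(
        {
            "patient_id": 0,
            "tick": np.arange(len(values)),
            channel: values,
            "label": LABEL_NORMAL,
        }
    )
    return df


class TestPreprocess:
    def test_forward_fill_short_gap(self):
        df = _series_frame([5.0, np.nan, np.nan, 8.0])
        out = preprocess(df, PreprocessParams(ffill_limit=2, smoothing_window=1))
        # min-max on [5,5,5,8] -> [0,0,0,1]
        assert list(out["heart_rate"]) == [0.0, 0.0, 0.0, 1.0]

    def test_gap_beyond_limit_falls_back_to_mean(self):
        df = _series_frame([5.0, np.nan, np.nan, np.nan, 8.0])
        pre = Preprocessor(PreprocessParams(ffill_limit=2, smoothing_window=1)).fit(df)
        out = pre.transform(df)
        assert out["heart_rate"].notna().all()
        # third gap tick exceeded the ffill limit: imputed with the channel mean
        raw = pre.channel_means_["heart_rate"]
        scaled = (raw - pre.minmax_lo_["heart_rate"]) / (
            pre.minmax_hi_["heart_rate"] - pre.minmax_lo_["heart_rate"]
        )
        assert out["heart_rate"].iloc[3] == pytest.approx(scaled)

    def test_trailing_moving_average_hand_case(self):
        df = _series_frame([1.0, 3.0, 5.0])
        pre = Preprocessor(PreprocessParams(ffill_limit=0, smoothing_window=2))
        smoothed = pre.fit(df)._impute_smooth(df, ["heart_rate"])
        assert list(smoothed["heart_rate"]) == [1.0, 2.0, 4.0]

    def test_constant_channel_scales_to_zero(self):
        df = _series_frame([7.0, 7.0, 7.0])
        out = preprocess(df, PreprocessParams(smoothing_window=1))
        assert (out["heart_rate"] == 0.0).all()

    def test_smoothing_preserves_constant_series(self):
        df = _series_frame([4.2] * 10)
        out = Preprocessor(PreprocessParams(smoothing_window=5)).fit(df)._impute_smooth(
            df, ["heart_rate"]
        )
        assert np.allclose(out["heart_rate"], 4.2)

    def test_no_missing_and_unit_interval_after_fit_transform(self, small_cohort):
        out = Preprocessor().fit_transform(small_cohort)
        block = out[list(CHANNELS)]
        assert block.notna().all().all()
        assert ((block >= 0.0) & (block <= 1.0)).all().all()

    def test_smoothing_is_per_patient(self):
        # last value of patient 0 must not bleed into patient 1's head window
        df = pd.concat(
            [_series_frame([100.0, 100.0]), _series_frame([0.0, 0.0])], ignore_index=True
        )
        df.loc[2:, "patient_id"] = 1
        pre = Preprocessor(PreprocessParams(smoothing_window=2))
        smoothed = pre.fit(df)._impute_smooth(df, ["heart_rate"])
        assert list(smoothed["heart_rate"]) == [100.0, 100.0, 0.0, 0.0]

    def test_empty_input_passes_through(self):
        out = preprocess(_series_frame([]).iloc[0:0])
        assert len(out) == 0

    def test_all_missing_channel_raises_with_name(self):
        df = _series_frame([np.nan, np.nan])
        with pytest.raises(ConfigurationError, match="heart_rate"):
            Preprocessor().fit(df)

    def test_bounds_fitted_on_train_only(self, small_cohort):
        train_ids = small_cohort["patient_id"].unique()[:50]
        pre = Preprocessor().fit(
            small_cohort[small_cohort["patient_id"].isin(train_ids)]
        )
        full = pre.transform(small_cohort)
        train_part = full[full["patient_id"].isin(train_ids)]
        assert ((train_part[list(CHANNELS)] >= 0) & (train_part[list(CHANNELS)] <= 1)).all().all()

    def test_pipeline_is_deterministic(self, small_cohort):
        a = Preprocessor().fit_transform(small_cohort)
        b = Preprocessor().fit_transform(small_cohort)
        pd.testing.assert_frame_equal(a, b)
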