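"""Normalization, interval adjustment model, and target integration."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from nirglucose import preprocess as pp
from nirglucose.errors import (
    ConfigurationError,
    CoverageError,
    DegenerateIntervalError,
    SchemaError,
)


def records_from(refs, volts=None, tones=None):
    """Minimal sample table for preprocessing tests."""
    n = len(refs)
    volts = volts if volts is not None else np.linspace(0.18, 0.14, n)
    tones = tones if tones is not None else ["dark", "wheatish", "fair"] * (n // 3 + 1)
    return pd.DataFrame(
        {
            "volunteer_id": [f"V{i}" for i in range(n)],
            "site": "wrist",
            "visit": 1,
            "reference_mgdl": refs,
            "skin_tone": tones[:n],
            "age": 50,
            "sex": (["M", "F"] * (n // 2 + 1))[:n],
            "bmi": 26.0,
            "diabetic": 1,
            "meal_state": "fasting",
            "sleep": 1,
            "stress": 0,
            "spo2": 97.0,
            "wrist_hair": 0,
            "hv_volts": volts,
            "dc_volts": 0.002,
            "lv_volts": 0.192,
        }
    ).iloc[:n]


class TestNormalization:
    @pytest.mark.parametrize(
        "hv, dc, lv, expected",
        [
            (0.9, 0.1, 0.9, 100.0),   # HV = LV
            (0.1, 0.1, 0.9, 0.0),     # HV = DC
            (0.5, 0.1, 0.9, 50.0),    # midpoint, forced by linearity
        ],
    )
    def test_endpoints_and_midpoint(self, hv, dc, lv, expected):
        assert pp.normalize_voltage(hv, dc, lv) == pytest.approx(expected)

    def test_undefined_calibration_rejected(self):
        with pytest.raises(ConfigurationError):
            pp.normalize_voltage(0.5, 0.2, 0.2)


class TestBinning:
    @pytest.mark.parametrize(
        "ref, lower",
        [(83, 81), (81, 81), (85, 81), (86, 86), (80, 76), (488, 486), (501, 501)],
    )
    def test_interval_assignment(self, ref, lower):
        assert pp.bin_lower(ref) == lower

    def test_boundary_values_in_adjacent_bins(self):
        assert pp.bin_lower(85) + 5 == pp.bin_lower(86)

    def test_repeated_value_single_bin(self):
        binned = pp.assign_bins(records_from([84, 84, 84]))
        assert binned["bin_lower"].nunique() == 1
        assert (binned["bin_lower"] == 81).all()

    def test_non_positive_width_rejected(self):
        with pytest.raises(ConfigurationError):
            pp.bin_lower(100, width=0)


class TestIntervalStatistics:
    def test_pilot_voltage_variance(self):
        # pooled wrist post-breakfast voltages of the three-tone pilot
        values = [0.164059, 0.142742, 0.155480]
        assert pp.interval_variance(values) == pytest.approx(1.15045e-4, rel=1e-4)

    @pytest.mark.parametrize("values, expected", [([0.0, 2.0], 2.0), ([3.0, 3.0, 3.0], 0.0)])
    def test_hand_computed(self, values, expected):
        assert pp.interval_variance(values) == pytest.approx(expected, abs=1e-15)

    def test_single_member_degenerate(self):
        with pytest.raises(DegenerateIntervalError):
            pp.interval_variance([0.15])

    @given(st.lists(st.floats(min_value=-10, max_value=10, allow_nan=False),
                    min_size=2, max_size=30))
    def test_matches_two_pass_oracle(self, values):
        arr = np.array(values)
        mean = arr.sum() / arr.size              # pass 1
        ss = sum((x - mean) ** 2 for x in arr)   # pass 2
        oracle = ss / (arr.size - 1)
        assert pp.interval_variance(arr) == pytest.approx(oracle, abs=1e-12)

    @pytest.mark.parametrize("x_var, expected", [(1.0, 1.0), (4.0, 0.5)])
    def test_correction_factor(self, x_var, expected):
        assert pp.correction_factor(x_var) == pytest.approx(expected)

    def test_correction_factor_from_stated_pilot_variance(self):
        assert pp.correction_factor(0.000375) == pytest.approx(51.64, rel=1e-4)

    def test_correction_factor_degenerate(self):
        with pytest.raises(DegenerateIntervalError):
            pp.correction_factor(0.0)

    @pytest.mark.parametrize("x_var, expected", [(1.0, 1.0), (4.0, 2.0)])
    def test_adjustment_factor(self, x_var, expected):
        assert pp.adjustment_factor(x_var) == pytest.approx(expected)

    @given(st.floats(min_value=1e-12, max_value=1e6, allow_nan=False))
    def test_adjustment_factor_is_sqrt_of_variance(self, x_var):
        # chaining F = 1/sqrt(v) and A = v*F collapses to A = sqrt(v)
        assert pp.adjustment_factor(x_var) == pytest.approx(
            np.sqrt(x_var), rel=1e-12
        )


class TestAdjustmentModel:
    def test_degenerate_bins_carry_identity_factor(self):
        # single member, and identical voltages across tones
        recs = records_from([83, 92, 92], volts=[0.15, 0.16, 0.16])
        model = pp.fit_adjustment_model(recs)
        assert model.lookup(83).a_factor == 1.0      # n = 1
        assert model.lookup(92).a_factor == 1.0      # zero variance

    def test_pooled_tone_variance_gives_sqrt_factor(self):
        volts = [0.164059, 0.142742, 0.155480]
        recs = records_from([128, 126, 128], volts=volts,
                            tones=["dark", "wheatish", "fair"])
        model = pp.fit_adjustment_model(recs)
        v = np.var(volts, ddof=1)
        assert model.lookup(127).a_factor == pytest.approx(np.sqrt(v), rel=1e-12)

    def test_empty_input_rejected(self):
        with pytest.raises(SchemaError):
            pp.fit_adjustment_model(records_from([]))

    def test_apply_identity_model_returns_input(self):
        recs = records_from([83, 90, 97])  # all bins singleton -> A = 1
        model = pp.fit_adjustment_model(recs)
        adjusted = pp.apply_adjustment(recs, model)
        assert np.allclose(adjusted["adjusted_volts"], recs["hv_volts"])

    def test_same_bin_same_multiplier(self):
        recs = records_from([82, 84], volts=[0.10, 0.20])
        model = pp.fit_adjustment_model(recs)
        adjusted = pp.apply_adjustment(recs, model)
        ratio = adjusted["adjusted_volts"] / recs["hv_volts"]
        assert ratio.iloc[0] == pytest.approx(ratio.iloc[1], rel=1e-12)
        assert ratio.iloc[0] == pytest.approx(model.lookup(82).a_factor)

    def test_known_multiplier(self):
        recs = records_from([82], volts=[0.10])
        model = pp.AdjustmentModel(
            bins=[pp.AdjustmentBin(81, 85, np.array([0.1]), 0.1, 1, None, 50.0, 0.02)]
        )
        adjusted = pp.apply_adjustment(recs, model)
        assert adjusted["adjusted_volts"].iloc[0] == pytest.approx(0.002)

    def test_uncovered_bin_error_names_reference(self):
        recs = records_from([83])
        model = pp.fit_adjustment_model(recs)
        far = records_from([300])
        with pytest.raises(CoverageError, match="300"):
            pp.apply_adjustment(far, model)

    def test_adjustment_is_linear_in_voltage_scale(self):
        # scaling every voltage by c scales every adjusted voltage by c
        refs = [82, 83, 84, 91, 92, 93]
        volts = np.array([0.15, 0.16, 0.14, 0.13, 0.12, 0.125])
        c = 3.7
        a1 = pp.apply_adjustment(records_from(refs, volts),
                                 pp.fit_adjustment_model(records_from(refs, volts)))
        a2 = pp.apply_adjustment(records_from(refs, c * volts),
                                 pp.fit_adjustment_model(records_from(refs, c * volts)))
        # A scales by c as well, so adjusted voltages scale by c^2
        assert np.allclose(a2["adjusted_volts"], c * c * a1["adjusted_volts"])


class TestTargetIntegration:
    def test_interval_average_worked_example(self):
        # members at 4.22 and 4.44 mmol average to 4.33 mmol
        recs = records_from([75.96, 79.92])
        out = pp.integrate_targets(recs, width=5, origin=75)
        assert out["bin_lower"].nunique() == 1
        assert np.allclose(out["target_mmol"], (4.22 + 4.44) / 2)

    def test_constant_members_keep_value(self):
        out = pp.integrate_targets(records_from([90, 90, 90]))
        assert np.allclose(out["target_mmol"], 5.0)

    def test_arithmetic_mean(self):
        # 5.0, 5.1, 5.2 mmol sharing one interval
        out = pp.integrate_targets(records_from([90.0, 91.8, 93.6]), origin=90)
        assert np.allclose(out["target_mmol"], 5.1)

    def test_row_count_conserved_and_bounded(self, finger_records):
        out = pp.integrate_targets(finger_records)
        assert len(out) == len(finger_records)
        grouped = out.groupby("bin_lower")
        assert np.allclose(grouped["target_mmol"].mean(),
                           grouped["reference_mmol"].mean())
        assert (grouped["target_mmol"].max() <= grouped["reference_mmol"].max() + 1e-12).all()
        assert (grouped["target_mmol"].min() >= grouped["reference_mmol"].min() - 1e-12).all()


class TestFeatureEncoding:
    def test_column_layout(self, finger_records):
        X = pp.encode_features(pp.assign_bins(finger_records), "raw")
        # ten inputs, three-level meal state one-hot expanded
        assert X.shape[1] == 12
        assert list(X.columns)[:2] == ["voltage", "age"]
        assert set(X.dtypes) == {np.dtype(float)}

    def test_normalized_branch_voltage_is_eq14(self, finger_records):
        X = pp.encode_features(finger_records, "normalized")
        expected = pp.normalize_voltage(
            finger_records["hv_volts"], finger_records["dc_volts"],
            finger_records["lv_volts"],
        )
        assert np.allclose(X["voltage"], expected)

    def test_missing_covariate_reported(self, finger_records):
        broken = finger_records.copy()
        broken.loc[3, "bmi"] = np.nan
        with pytest.raises(SchemaError, match="bmi"):
            pp.encode_features(broken, "raw")

    def test_framework_branch_requires_adjusted_column(self, finger_records):
        with pytest.raises(SchemaError, match="adjusted_volts"):
            pp.encode_features(finger_records, "framework")

    def test_unknown_branch_rejected(self, finger_records):
        with pytest.raises(ConfigurationError):
            pp.encode_features(finger_records, "fancy")


class TestBuildBranch:
    def test_framework_branch_targets_are_bin_means(self, finger_records):
        ds = pp.build_branch(finger_records, "framework")
        assert len(ds.features) == len(finger_records)
        df = pd.DataFrame({"bin": ds.bin_lower, "t": ds.target_mmol})
        assert (df.groupby("bin")["t"].nunique() == 1).all()

    def test_raw_branch_targets_are_individual_references(self, finger_records):
        ds = pp.build_branch(finger_records, "raw")
        assert np.allclose(ds.target_mmol, finger_records["reference_mgdl"] / 18.0)
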