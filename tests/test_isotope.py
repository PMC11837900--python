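"""Delta calibration, enrichment factors and the two-source mixing model."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from mixotroph import isotope
from mixotroph.isotope import (
    EnrichmentFactors,
    FungalCarbonMixingModel,
    ProtocormBaseline,
    TwoPointCalibration,
    delta_from_ratio,
    enrichment_factors,
    group_summary,
    percent_fungal_carbon,
    plot_autotroph_baseline,
    protocorm_baseline,
)


class TestDeltaFromRatio:
    @pytest.mark.parametrize("factor, expected", [
        (1.0, 0.0),       # R_sample == R_standard
        (1.005, 5.0),
        (0.99, -10.0),
    ])
    def test_closed_form(self, factor, expected):
        assert delta_from_ratio(factor * 0.0112372, 0.0112372) == pytest.approx(expected)

    def test_non_positive_ratio_rejected(self):
        with pytest.raises(ValueError):
            delta_from_ratio(-1.0, 0.0112372)
        with pytest.raises(ValueError):
            delta_from_ratio(0.011, 0.0)


class TestTwoPointCalibration:
    def test_identity_when_measured_equals_known(self, standards_frame):
        line = TwoPointCalibration(element="C").fit(standards_frame)
        assert line.slope_ == pytest.approx(1.0)
        assert line.intercept_ == pytest.approx(0.0)

    def test_uniform_offset_gives_unit_slope(self, standards_frame):
        # measured shifted by −1.00‰: solving the 2x2 system by hand gives
        # slope 1, intercept +1.00
        std = standards_frame.copy()
        std["measured_delta13C"] = [-35.92, -10.45]
        line = TwoPointCalibration(element="C").fit(std)
        assert line.slope_ == pytest.approx(1.0)
        assert line.intercept_ == pytest.approx(1.0)
        assert line.transform(-35.92) == pytest.approx(-34.92)

    def test_general_two_point_solution(self, standards_frame):
        # hand solution: slope (−34.92+9.45)/(−36+9) = 0.94333…, intercept −0.96
        std = standards_frame.copy()
        std["measured_delta13C"] = [-36.0, -9.0]
        line = TwoPointCalibration(element="C").fit(std)
        assert line.slope_ == pytest.approx(25.47 / 27.0, abs=1e-12)
        assert line.intercept_ == pytest.approx(-0.96, abs=1e-10)

    def test_line_interpolates_both_standards_exactly(self, standards_frame):
        std = standards_frame.copy()
        std["measured_delta13C"] = [-36.0, -9.0]
        std["measured_delta15N"] = [2.5, -3.3]
        for element, kcol, mcol in (("C", "known_delta13C", "measured_delta13C"),
                                    ("N", "known_delta15N", "measured_delta15N")):
            line = TwoPointCalibration(element=element).fit(std)
            np.testing.assert_allclose(line.transform(std[mcol].to_numpy()),
                                       std[kcol].to_numpy(), atol=1e-12)

    def test_identical_measured_values_singular(self, standards_frame):
        std = standards_frame.copy()
        std["measured_delta13C"] = [-20.0, -20.0]
        with pytest.raises(ValueError, match="singular"):
            TwoPointCalibration(element="C").fit(std)


class TestPlotBaseline:
    def test_constant_refs(self, toy_isotope_frame):
        frame = toy_isotope_frame.copy()
        frame.loc[frame.category == "AUTO_REF", "delta13C"] = -31.5
        base = plot_autotroph_baseline(frame, "P1")
        assert base["mean_delta13C_ref"] == pytest.approx(-31.5)
        assert base["n_refs"] == 3

    def test_arithmetic_mean(self, toy_isotope_frame):
        # refs are −30, −32, −31 → mean −31
        base = plot_autotroph_baseline(toy_isotope_frame, "P1")
        assert base["mean_delta13C_ref"] == pytest.approx(-31.0)
        assert base["mean_delta15N_ref"] == pytest.approx(-1.8)

    def test_two_references_is_an_error(self, toy_isotope_frame):
        frame = toy_isotope_frame.drop(index=0)
        with pytest.raises(ValueError, match="P1"):
            plot_autotroph_baseline(frame, "P1")


class TestEnrichmentFactors:
    def test_worked_example(self, toy_isotope_frame):
        # δ13C −27.6 against baseline −31 → ε13C 3.4; δ15N 2.0 vs −1.8 → 3.8
        enriched = enrichment_factors(toy_isotope_frame)
        rhz = enriched[enriched.category == "OP_RHIZOME"].iloc[0]
        assert rhz["eps13C"] == pytest.approx(-27.6 - (-31.0))
        assert rhz["eps15N"] == pytest.approx(3.8)

    def test_reference_eps_average_to_zero_per_plot(self, default_dataset):
        specimens, _ = default_dataset
        enriched = enrichment_factors(specimens)
        refs = enriched[enriched.category == "AUTO_REF"]
        for _, grp in refs.groupby("plot_id"):
            assert grp["eps13C"].mean() == pytest.approx(0.0, abs=1e-10)
            assert grp["eps15N"].mean() == pytest.approx(0.0, abs=1e-10)

    def test_specimen_without_baseline_plot_is_an_error(self, toy_isotope_frame):
        fitted = EnrichmentFactors().fit(toy_isotope_frame)
        stray = toy_isotope_frame.assign(plot_id="P9")
        with pytest.raises(ValueError, match="P9"):
            fitted.transform(stray)


class TestProtocormBaseline:
    def test_constant_protocorms(self):
        frame = pd.DataFrame({"category": ["OP_PROTOCORM"] * 3, "eps13C": [6.7] * 3})
        base = protocorm_baseline(frame)
        assert base.mean_eps13C_fmh == pytest.approx(6.7)
        assert base.sd == pytest.approx(0.0, abs=1e-12)
        assert base.n == 3

    def test_sample_sd_uses_n_minus_one(self):
        # {6.5, 6.7, 6.9}: mean 6.7, sample SD sqrt(0.08/2) = 0.2
        frame = pd.DataFrame({"category": ["OP_PROTOCORM"] * 3,
                              "eps13C": [6.5, 6.7, 6.9]})
        base = protocorm_baseline(frame)
        assert base.mean_eps13C_fmh == pytest.approx(6.7)
        assert base.sd == pytest.approx(0.2)

    def test_no_protocorms_instructs_endpoint_override(self):
        frame = pd.DataFrame({"category": ["OP_RHIZOME"], "eps13C": [3.9]})
        with pytest.raises(ValueError, match="endpoint"):
            protocorm_baseline(frame)


class TestMixingModel:
    def test_printed_worked_example(self):
        # ε 3.9 over endpoint 6.7 → 58.2% at one decimal
        assert percent_fungal_carbon(3.9, 6.7) == pytest.approx(58.2, abs=0.05)

    @pytest.mark.parametrize("eps, expected", [(6.7, 100.0), (0.0, 0.0)])
    def test_endpoints(self, eps, expected):
        base = ProtocormBaseline(6.7, 0.2, 5)
        assert percent_fungal_carbon(eps, base) == pytest.approx(expected)

    def test_negative_estimates_returned_unclamped_and_flagged(self):
        assert percent_fungal_carbon(-1.0, 6.7) == pytest.approx(-14.925373, abs=1e-5)
        frame = pd.DataFrame({"category": ["OP_ROOTS", "OP_PROTOCORM"],
                              "eps13C": [-1.0, 6.7]})
        model = FungalCarbonMixingModel(endpoint=6.7).fit()
        out = model.transform(frame)
        assert out.loc[0, "pct_cdf"] == pytest.approx(-14.925373, abs=1e-5)
        assert bool(out.loc[0, "pct_cdf_out_of_range"])
        assert not bool(out.loc[1, "pct_cdf_out_of_range"])

    def test_auto_ref_gets_no_pct_cdf(self, toy_isotope_frame):
        enriched = enrichment_factors(toy_isotope_frame)
        out = FungalCarbonMixingModel().fit(enriched).transform(enriched)
        assert out.loc[out.category == "AUTO_REF", "pct_cdf"].isna().all()
        assert out.loc[out.category != "AUTO_REF", "pct_cdf"].notna().all()

    def test_zero_endpoint_rejected(self):
        with pytest.raises(ZeroDivisionError):
            percent_fungal_carbon(3.9, 0.0)

    @given(st.floats(-2.0, 10.0), st.floats(0.1, 5.0))
    @settings(max_examples=50, deadline=None)
    def test_mixing_model_is_linear(self, eps, scale):
        base = ProtocormBaseline(6.7, 0.2, 5)
        assert percent_fungal_carbon(scale * eps, base) == pytest.approx(
            scale * percent_fungal_carbon(eps, base), rel=1e-9, abs=1e-9)


class TestGroupSummary:
    def test_single_record_sd_missing(self):
        frame = pd.DataFrame({"category": ["OP_RHIZOME"], "eps13C": [3.9]})
        row = group_summary(frame).iloc[0]
        assert row["eps13C_mean"] == pytest.approx(3.9)
        assert np.isnan(row["eps13C_sd"])
        assert row["eps13C_n"] == 1

    def test_two_records_mean_and_sd(self):
        frame = pd.DataFrame({"category": ["a", "a"], "eps13C": [3.0, 5.0]})
        row = group_summary(frame).iloc[0]
        assert row["eps13C_mean"] == pytest.approx(4.0)
        assert row["eps13C_sd"] == pytest.approx(np.sqrt(2.0))

    def test_group_mean_pct_equals_scaled_group_mean_eps(self, default_dataset):
        # linearity of the mixing model: mean %Cdf = mean ε / endpoint × 100
        specimens, _ = default_dataset
        enriched = enrichment_factors(specimens)
        model = FungalCarbonMixingModel().fit(enriched)
        out = model.transform(enriched)
        summary = group_summary(out).set_index("category")
        for cat in ("OP_RHIZOME", "OP_ROOTS"):
            expected = (summary.loc[cat, "eps13C_mean"]
                        / model.endpoint_.mean_eps13C_fmh * 100.0)
            assert summary.loc[cat, "pct_cdf_mean"] == pytest.approx(expected)

    def test_protocorm_group_mean_pct_is_exactly_100(self, default_dataset):
        specimens, _ = default_dataset
        enriched = enrichment_factors(specimens)
        out = FungalCarbonMixingModel().fit(enriched).transform(enriched)
        pro = out[out.category == "OP_PROTOCORM"]
        assert pro["pct_cdf"].mean() == pytest.approx(100.0)
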