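"""Report queries, cohort filters and the volumetric linear models."""

from __future__ import annotations

import re

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from clinmri.cohort import (
    GROUPS,
    RegressionSpec,
    ReportTable,
    filter_age,
    fit_model,
    iqr_filter,
    query_reports,
    simulate_cohort,
    success_rate_report,
)

TRUE_BETAS = {
    "const": 300.0,
    "gender": 2.0,
    "age": -0.9,
    "group[dementia+]": -20.0,
    "group[dementia-]": -5.0,
    "group[MS+]": 3.0,
    "group[MS-]": 2.0,
    "seq[SE]": 4.0,
    "type[Discovery]": 6.0,
    "type[Signa]": -3.0,
    "type[Sonata]": 2.0,
    "fs": 5.0,
    "icv": 0.55,
}


class TestQueryReports:
    @pytest.fixture
    def reports(self):
        return ReportTable(
            pd.DataFrame(
                {
                    "study_id": ["S1", "S2", "S3"],
                    "report_text": [
                        "scanned under the Dementia protocol",
                        "MS protocol, follow-up",
                        "open question; no findings",
                    ],
                }
            )
        )

    def test_substring_match_case_insensitive(self, reports):
        assert query_reports(reports, "dementia") == ["S1"]

    def test_no_match_returns_empty(self, reports):
        assert query_reports(reports, "angiography") == []

    def test_anchored_regex_semantics(self, reports):
        assert query_reports(reports, r"^MS\b") == ["S2"]

    def test_invalid_pattern_is_error(self, reports):
        with pytest.raises(re.error):
            query_reports(reports, "(unclosed")

    def test_duplicate_study_ids_rejected(self):
        with pytest.raises(ValueError):
            ReportTable(
                pd.DataFrame({"study_id": ["S1", "S1"],
                              "report_text": ["a", "b"]})
            )


class TestFilterAge:
    def test_forty_five_inclusive(self):
        df = pd.DataFrame({"age": [44, 45, 46]})
        kept = filter_age(df)
        assert kept["age"].tolist() == [45, 46]

    def test_empty_in_empty_out(self):
        df = pd.DataFrame({"age": pd.Series([], dtype=float)})
        assert filter_age(df).empty

    def test_missing_age_dropped_with_warning(self):
        df = pd.DataFrame({"age": [50.0, np.nan]})
        with pytest.warns(UserWarning):
            kept = filter_age(df)
        assert len(kept) == 1


def oracle_iqr_outliers(values: np.ndarray) -> np.ndarray:
    """Direct quantile formula on the sorted sample (independent oracle)."""
    srt = np.sort(values)
    n = len(srt)

    def quantile(q):
        pos = q * (n - 1)
        lo, hi = int(np.floor(pos)), int(np.ceil(pos))
        return srt[lo] + (pos - lo) * (srt[hi] - srt[lo])

    q1, q3 = quantile(0.25), quantile(0.75)
    iqr = q3 - q1
    return (values < q1 - 1.5 * iqr) | (values > q3 + 1.5 * iqr)


class TestIqrFilter:
    def test_single_outlier_in_even_spread(self):
        values = np.linspace(0.70, 0.80, 11).tolist() + [0.95]
        df = pd.DataFrame(
            {"brain_ml": values, "icv_ml": 1.0, "group": "open"}
        )
        kept, excluded = iqr_filter(df)
        assert excluded["brain_ml"].tolist() == [0.95]

    def test_identical_values_exclude_nothing(self):
        df = pd.DataFrame(
            {"brain_ml": [0.75] * 8, "icv_ml": 1.0, "group": "open"}
        )
        kept, excluded = iqr_filter(df)
        assert excluded.empty

    def test_partition_of_input(self):
        rng = np.random.default_rng(0)
        df = pd.DataFrame(
            {
                "brain_ml": rng.normal(0.75, 0.05, 40),
                "icv_ml": 1.0,
                "group": rng.choice(["a", "b"], 40),
            }
        )
        kept, excluded = iqr_filter(df)
        assert len(kept) + len(excluded) == len(df)
        assert not set(kept.index) & set(excluded.index)

    def test_fewer_than_four_records_warns_and_keeps(self):
        df = pd.DataFrame(
            {"brain_ml": [0.1, 0.9, 0.5], "icv_ml": 1.0, "group": "open"}
        )
        with pytest.warns(UserWarning):
            kept, excluded = iqr_filter(df)
        assert excluded.empty

    @given(
        values=st.lists(
            st.floats(0.3, 1.2, allow_nan=False), min_size=4, max_size=50
        )
    )
    @settings(max_examples=100, deadline=None)
    def test_agrees_with_brute_force_oracle(self, values):
        arr = np.array(values)
        df = pd.DataFrame({"brain_ml": arr, "icv_ml": 1.0, "group": "g"})
        _, excluded = iqr_filter(df)
        expected = oracle_iqr_outliers(arr)
        assert sorted(excluded.index) == sorted(np.flatnonzero(expected))


class TestFitModel:
    def test_zero_noise_recovers_betas_exactly(self):
        df = simulate_cohort(650, TRUE_BETAS, noise_sd=0.0, seed=1)
        fit = fit_model(df, RegressionSpec(response="brain_ml"))
        for name, true in [
            ("const", 300.0),
            ("gender", 2.0),
            ("age", -0.9),
            ("group[dementia+]", -20.0),
            ("seq[SE]", 4.0),
            ("fs", 5.0),
            ("icv", 0.55),
        ]:
            assert fit.params.loc[name, "coef"] == pytest.approx(true, abs=1e-8)

    def test_adjusted_mean_is_dot_product_of_design_row(self):
        df = simulate_cohort(650, TRUE_BETAS, noise_sd=5.0, seed=2)
        fit = fit_model(df, RegressionSpec(response="brain_ml"))
        row = fit.adjusted_means.iloc[0]
        from clinmri.cohort import _eval_row

        exog = _eval_row(fit, row["group"], 0.0 if row["gender"] == "F" else 1.0,
                         df)
        assert row["mean"] == pytest.approx(
            float(exog @ fit.results.params.to_numpy()), abs=1e-9
        )

    def test_reference_level_change_keeps_fitted_values(self):
        df = simulate_cohort(400, TRUE_BETAS, noise_sd=5.0, seed=3)
        fit_a = fit_model(df, RegressionSpec(response="brain_ml"))
        fit_b = fit_model(
            df,
            RegressionSpec(response="brain_ml", group_reference="MS+",
                           scanner_reference="Signa"),
        )
        assert np.allclose(
            fit_a.results.fittedvalues, fit_b.results.fittedvalues, atol=1e-8
        )
        merged = fit_a.adjusted_means.merge(
            fit_b.adjusted_means, on=["group", "gender"]
        )
        assert np.allclose(merged["mean_x"], merged["mean_y"], atol=1e-8)

    def test_single_level_factor_dropped_with_warning(self):
        df = simulate_cohort(200, TRUE_BETAS, noise_sd=5.0, seed=4)
        df["field_strength"] = 1.5
        with pytest.warns(UserWarning, match="field_strength"):
            fit = fit_model(df, RegressionSpec(response="brain_ml"))
        assert "fs" not in fit.params.index

    def test_rank_deficient_design_names_aliased_terms(self):
        df = simulate_cohort(200, TRUE_BETAS, noise_sd=5.0, seed=5)
        df["sequence"] = np.where(df["group"] == "open", "GR", "SE")
        df.loc[df["group"] != "open", "group"] = "MS+"
        with pytest.raises(ValueError, match="aliased"):
            fit_model(df, RegressionSpec(response="brain_ml"))

    def test_bonferroni_adjusts_all_pairs(self):
        df = simulate_cohort(650, TRUE_BETAS, noise_sd=5.0, seed=6)
        fit = fit_model(df, RegressionSpec(response="brain_ml"))
        n_pairs = len(GROUPS) * (len(GROUPS) - 1) // 2
        assert len(fit.contrasts) == n_pairs
        assert np.all(
            fit.contrasts["p_bonferroni"]
            >= np.minimum(fit.contrasts["p"] * n_pairs, 1.0) - 1e-12
        )

    def test_icv_model_has_no_icv_term(self):
        df = simulate_cohort(400, TRUE_BETAS, noise_sd=5.0, seed=7,
                             response="icv_ml")
        fit = fit_model(df, RegressionSpec(response="icv_ml"))
        assert "icv" not in fit.params.index
        assert fit.r_squared_adj <= fit.r_squared


class TestSuccessRateReport:
    def test_percentages_of_selected(self):
        report = success_rate_report(
            {"dementia": {"selected": 100, "retrieved": 97, "qa": 86,
                          "bio": 84, "visual": 82}}
        )
        assert report.iloc[0][["selected", "retrieved", "qa", "bio",
                               "visual"]].tolist() == [100.0, 97.0, 86.0,
                                                       84.0, 82.0]

    def test_zero_selected_warns_with_empty_row(self):
        with pytest.warns(UserWarning):
            report = success_rate_report({"g": {"selected": 0, "qa": 0}})
        assert report.iloc[0]["qa"] != report.iloc[0]["qa"]  # NaN

    def test_increasing_counts_rejected(self):
        with pytest.raises(ValueError):
            success_rate_report({"g": {"selected": 10, "qa": 12}})

    def test_percentages_monotone_non_increasing(self):
        report = success_rate_report(
            {"g": {"selected": 50, "retrieved": 48, "qa": 40, "bio": 39}}
        )
        row = report.iloc[0][["selected", "retrieved", "qa", "bio"]].to_numpy()
        assert np.all(np.diff(row.astype(float)) <= 0)
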