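"""Inclusion filtering, standardization, and the decline mixed model."""

import subprocess
import sys
import textwrap

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from aslcbf import (
    CBFDeclineModel,
    CohortConfig,
    annual_change,
    apply_inclusion,
    cohort_summary,
    report_tables,
    simulate_cohort,
    standardize_invert,
)


def noise_free_cohort(n=12, seed=0, **kw):
    kw.setdefault("effect_cbf", 0.0)
    kw.setdefault("effect_cbf_time", 0.0)
    cfg = CohortConfig(
        n_subjects=n, seed=seed, sd_random_intercept=0.0,
        sd_random_slope=0.0, sd_residual=0.0, **kw,
    )
    return simulate_cohort(cfg)


class TestInclusion:
    def test_boundary_cases(self, inclusion_fixture):
        kept = set(apply_inclusion(inclusion_fixture)["subject_id"])
        assert kept == {"long_pair", "exact_year", "long_followup"}

    def test_missing_mmse_does_not_count_as_score(self, inclusion_fixture):
        df = inclusion_fixture.copy()
        df.loc[
            (df.subject_id == "long_pair") & (df.visit_time_years > 0), "mmse"
        ] = np.nan
        kept = set(apply_inclusion(df)["subject_id"])
        assert "long_pair" not in kept

    def test_empty_result_raises(self):
        df = pd.DataFrame(
            {"subject_id": [1], "visit_time_years": [0.0], "mmse": [25.0]}
        )
        with pytest.raises(ValueError, match="inclusion"):
            apply_inclusion(df)


class TestStandardizeInvert:
    def test_symmetric_triple(self):
        np.testing.assert_allclose(standardize_invert([1, 2, 3]), [1.0, 0.0, -1.0])

    @given(
        st.lists(st.floats(-100, 100), min_size=3, max_size=40).filter(
            lambda v: len(set(v)) > 1 and np.std(v) > 1e-6
        )
    )
    def test_zero_mean_unit_sd(self, values):
        z = standardize_invert(values)
        assert abs(z.mean()) < 1e-9
        assert z.std(ddof=1) == pytest.approx(1.0, rel=1e-9)

    def test_higher_value_gets_lower_z(self):
        z = standardize_invert([10.0, 50.0])
        assert z[0] > z[1]

    def test_degenerate_inputs_raise(self):
        with pytest.raises(ValueError):
            standardize_invert([5.0, 5.0, 5.0])
        with pytest.raises(ValueError):
            standardize_invert([5.0])


class TestDeclineModel:
    def test_noise_free_recovery_of_generating_coefficients(self):
        # visit gaps >= 1.05 y keep every subject, so the analysis-sample
        # standardization coincides with the generator's and recovery is exact
        cohort = noise_free_cohort(
            n=16, effect_cbf=-0.42, effect_cbf_time=-0.50,
            mean_visit_interval_years=1.5,
        )
        res = CBFDeclineModel.from_dataframe(
            apply_inclusion(cohort), covariates=None
        ).fit()
        assert res.params["Intercept"] == pytest.approx(22.0, abs=1e-6)
        assert res.params["time"] == pytest.approx(-2.11, abs=1e-6)
        assert res.params["cbf_z"] == pytest.approx(-0.42, abs=1e-6)
        assert res.params["cbf_z:time"] == pytest.approx(-0.50, abs=1e-6)

    def test_inversion_flips_every_coefficient_sign(self):
        cohort = apply_inclusion(simulate_cohort(CohortConfig(n_subjects=60, seed=8)))
        res_inv = CBFDeclineModel.from_dataframe(cohort, covariates=None).fit()
        res_raw = CBFDeclineModel.from_dataframe(
            cohort, covariates=None, invert=False
        ).fit()
        for term in ("cbf_z", "cbf_z:time"):
            assert res_raw.params[term] == pytest.approx(-res_inv.params[term], rel=1e-5)
        for term in ("Intercept", "time"):
            assert res_raw.params[term] == pytest.approx(res_inv.params[term], rel=1e-5)

    def test_subject_order_permutation_invariance(self):
        cohort = apply_inclusion(simulate_cohort(CohortConfig(n_subjects=40, seed=12)))
        res_a = CBFDeclineModel.from_dataframe(cohort, covariates=None).fit()
        shuffled = cohort.sample(frac=1.0, random_state=0)
        res_b = CBFDeclineModel.from_dataframe(shuffled, covariates=None).fit()
        np.testing.assert_allclose(
            res_a.params.to_numpy(), res_b.params.to_numpy(), atol=1e-8
        )

    def test_missing_covariate_drops_subject_complete_case(self):
        cohort = apply_inclusion(simulate_cohort(CohortConfig(n_subjects=30, seed=13)))
        a_subject = cohort["subject_id"].iloc[0]
        cohort.loc[cohort["subject_id"] == a_subject, "education"] = np.nan
        model = CBFDeclineModel.from_dataframe(cohort, covariates="model1")
        assert model.dropped_subjects == 1
        res = model.fit()
        assert res.n_subjects == cohort["subject_id"].nunique() - 1

    def test_model2_covariates_present_and_ngmv_dropped_for_pvc(self):
        cohort = apply_inclusion(simulate_cohort(CohortConfig(n_subjects=50, seed=14)))
        res = CBFDeclineModel.from_dataframe(cohort, covariates="model2").fit()
        assert "ngmv_ml" in res.params.index
        assert "mta" in res.params.index
        res_pvc = CBFDeclineModel.from_dataframe(
            cohort, measure="cbf_pvc_cortical", covariates="model2"
        ).fit()
        assert "ngmv_ml" not in res_pvc.params.index

    def test_null_covariate_adjustment_is_neutral(self):
        """Covariates generated with zero effect leave the interaction
        estimate essentially unchanged."""
        cohort = apply_inclusion(simulate_cohort(CohortConfig(n_subjects=88, seed=15)))
        bare = CBFDeclineModel.from_dataframe(cohort, covariates=None).fit()
        adj = CBFDeclineModel.from_dataframe(cohort, covariates="model1").fit()
        assert adj.params["cbf_z:time"] == pytest.approx(
            bare.params["cbf_z:time"], abs=3 * bare.bse["cbf_z:time"] / np.sqrt(88)
        )

    def test_variance_components_near_generating_dispersions(self):
        cohort = apply_inclusion(
            simulate_cohort(CohortConfig(n_subjects=400, seed=16))
        )
        res = CBFDeclineModel.from_dataframe(cohort, covariates=None).fit()
        assert res.varcomp["var_intercept"] == pytest.approx(9.0, rel=0.35)
        assert res.varcomp["var_slope"] == pytest.approx(2.25, rel=0.35)
        assert res.varcomp["var_residual"] == pytest.approx(2.25, rel=0.35)

    def test_matches_independent_mixed_model_implementation(self, tmp_path):
        """Fixed effects agree with an independent REML fit (lme4) on the
        same data."""
        cohort = apply_inclusion(simulate_cohort(CohortConfig(n_subjects=60, seed=17)))
        model = CBFDeclineModel.from_dataframe(cohort, covariates=None)
        res = model.fit()
        csv = tmp_path / "frame.csv"
        model.frame.to_csv(csv, index=False)
        rscript = textwrap.dedent(f"""
            suppressMessages(library(lme4))
            d <- read.csv("{csv}")
            f <- lmer(mmse ~ cbf_z*time + (1 + time | subject_id), data=d, REML=TRUE)
            fe <- fixef(f)
            cat(sprintf("%.10f\\n", fe[c("(Intercept)", "cbf_z", "time", "cbf_z:time")]))
        """)
        out = subprocess.run(
            ["Rscript", "-e", rscript], capture_output=True, text=True, check=True
        )
        ref = [float(x) for x in out.stdout.split()]
        ours = [res.params[t] for t in ("Intercept", "cbf_z", "time", "cbf_z:time")]
        np.testing.assert_allclose(ours, ref, rtol=1e-3, atol=1e-4)


class TestAnnualChange:
    def test_noise_free_slope_exact(self):
        cohort = noise_free_cohort(n=10)
        res = annual_change(apply_inclusion(cohort))
        assert res.params["time"] == pytest.approx(-2.11, abs=1e-8)
        assert res.params["Intercept"] == pytest.approx(22.0, abs=1e-8)

    def test_translation_equivariance(self):
        cohort = apply_inclusion(simulate_cohort(CohortConfig(n_subjects=40, seed=18)))
        shifted = cohort.copy()
        shifted["mmse"] = shifted["mmse"] + 5.0
        a = annual_change(cohort)
        b = annual_change(shifted)
        assert b.params["Intercept"] == pytest.approx(a.params["Intercept"] + 5.0, abs=1e-4)
        assert b.params["time"] == pytest.approx(a.params["time"], abs=1e-5)

    def test_stochastic_recovery_within_three_ses(self):
        cohort = apply_inclusion(simulate_cohort(CohortConfig(n_subjects=88, seed=19)))
        res = annual_change(cohort)
        assert abs(res.params["time"] - (-2.11)) <= 3 * res.bse["time"]


class TestReporting:
    def test_empty_input_gives_headers_only(self):
        table = report_tables({})
        assert table.empty

    def test_single_result_single_cell(self):
        cohort = apply_inclusion(simulate_cohort(CohortConfig(n_subjects=40, seed=20)))
        res = CBFDeclineModel.from_dataframe(cohort, covariates="model1").fit()
        table = report_tables({("cbf_whole_brain", "model1"): res})
        assert table.shape == (1, 2)
        cell = table.loc["cbf_whole_brain", "model1: annual change"]
        assert "±" in cell

    def test_snapshot_of_seeded_fixture(self):
        """Formatted grid for a fixed seed is stable (golden snapshot)."""
        cohort = apply_inclusion(simulate_cohort(CohortConfig(n_subjects=50, seed=42)))
        res = CBFDeclineModel.from_dataframe(cohort, covariates=None).fit()
        table = report_tables({("cbf_whole_brain", "unadjusted"): res})
        cell_base = table.loc["cbf_whole_brain", "unadjusted: baseline"]
        cell_ann = table.loc["cbf_whole_brain", "unadjusted: annual change"]
        beta = float(cell_base.split("±")[0])
        assert beta == pytest.approx(res.params["cbf_z"], abs=0.005)
        ann_beta, ann_rest = cell_ann.split("±")
        assert float(ann_beta) == pytest.approx(res.params["cbf_z:time"], abs=0.005)
        se = float(ann_rest.replace("*", "").replace("†", ""))
        assert se == pytest.approx(res.bse["cbf_z:time"], abs=0.005)
        if res.pvalues["cbf_z:time"] <= 0.05:
            assert cell_ann.endswith("*")

    def test_cohort_summary_counts(self):
        cohort = simulate_cohort(CohortConfig(n_subjects=25, seed=21))
        summ = cohort_summary(cohort)
        assert summ["n_subjects"] == 25
        assert summ["n_mmse"] == len(cohort)
        assert 2 <= summ["visits_min"] <= summ["visits_median"] <= summ["visits_max"] <= 8
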