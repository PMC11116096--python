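"""Mixed-model associations, BH-FDR, AIC comparison, suite structure."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

import pubertyage as pa
from pubertyage.association import (
    bh_fdr,
    compare_aic,
    fit_interaction_lmm,
    fit_lmm,
    run_association_suite,
)
from pubertyage.simulate import OUTCOME_COLUMNS


def brute_force_bh(p: np.ndarray) -> np.ndarray:
    """Step-up definition applied literally: adj_i = min_{j>=i} p_(j) m / j."""
    m = len(p)
    order = np.argsort(p)
    adj = np.empty(m)
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, p[i] * m / rank)
        adj[i] = running
    return np.minimum(adj, 1.0)


class TestBhFdr:
    def test_worked_examples(self):
        np.testing.assert_allclose(
            bh_fdr([0.005, 0.05, 0.5]), [0.015, 0.075, 0.5]
        )
        np.testing.assert_allclose(
            bh_fdr([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04]
        )
        np.testing.assert_allclose(bh_fdr([1.0, 1.0, 1.0]), [1.0, 1.0, 1.0])

    def test_matches_brute_force_on_fuzzed_vectors(self):
        rng = np.random.default_rng(11)
        for _ in range(200):
            m = rng.integers(1, 13)
            p = np.round(rng.uniform(0, 1, m), 3)
            np.testing.assert_allclose(bh_fdr(p), brute_force_bh(p), atol=1e-12)

    def test_adjusted_at_least_raw(self):
        rng = np.random.default_rng(12)
        p = rng.uniform(0, 1, 11)
        assert (bh_fdr(p) >= p - 1e-15).all()

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_fdr([0.5, 1.2])
        with pytest.raises(ValueError):
            bh_fdr([-0.1])


class TestCompareAic:
    def test_cutoff_two_rule(self):
        res = compare_aic({"physical": 100.0, "combined": 103.0})
        assert res["preferred"] == "physical" and res["verdict"] == "better"
        assert res["deltas"]["combined"] == pytest.approx(3.0)

    def test_within_two_indistinguishable(self):
        res = compare_aic({"a": 100.0, "b": 101.0})
        assert res["verdict"] == "indistinguishable"

    def test_single_model_trivially_preferred(self):
        assert compare_aic({"only": 42.0})["verdict"] == "better"

    def test_mismatched_row_counts_rejected(self):
        with pytest.raises(ValueError, match="different fitting sets"):
            compare_aic({"a": 1.0, "b": 2.0}, {"a": 100, "b": 99})


class TestFitLmm:
    def test_single_site_equals_ols(self):
        rng = np.random.default_rng(13)
        n = 300
        gap = rng.normal(0, 0.5, n)
        age = rng.uniform(9, 13, n)
        y = 50 + 2.0 * gap + 0.5 * age + rng.normal(0, 5, n)
        site = np.repeat("site00", n)
        res = fit_lmm(y, gap, age, site)
        X = sm.add_constant(np.column_stack([gap, age]))
        ols = sm.OLS(y, X).fit()
        assert res["coefficient"] == pytest.approx(ols.params[1], abs=1e-8)

    def test_recovers_injected_effect(self):
        cfg = pa.GeneratorConfig(
            n_families=4000, sibling_prob=0.0, n_waves=1,
            outcome_effect=0.3, site_sd=2.0, seed=14,
        )
        df = pa.generate_cohort(cfg)
        z = df["truth_timing"] / cfg.timing_sd
        res = fit_lmm(df["cbcl_totprob"], z, df["age"], df["site_id"])
        assert res["coefficient"] / cfg.outcome_sd == pytest.approx(0.3, abs=0.05)
        assert res["n"] == 4000

    def test_null_permutation_calibration(self):
        cfg = pa.GeneratorConfig(
            n_families=400, sibling_prob=0.0, n_waves=1, outcome_effect=0.0, seed=15
        )
        df = pa.generate_cohort(cfg)
        rng = np.random.default_rng(16)
        z = (df["truth_timing"] / cfg.timing_sd).to_numpy()
        hits = 0
        reps = 300
        for _ in range(reps):
            res = fit_lmm(df["cbcl_totprob"], rng.permutation(z), df["age"], df["site_id"])
            hits += abs(res["t"]) < 1.96
        assert 0.92 <= hits / reps <= 0.985

    def test_zero_variance_outcome_rejected(self):
        with pytest.raises(ValueError, match="zero-variance"):
            fit_lmm(np.full(50, 50.0), np.zeros(50), np.full(50, 11.0),
                    np.repeat(["a", "b"], 25))


class TestInteraction:
    def test_centering_invariance(self):
        rng = np.random.default_rng(17)
        n = 500
        gap = rng.normal(0, 0.5, n)
        age = rng.uniform(9, 13, n)
        site = rng.integers(0, 10, n).astype(str)
        y = 50 + 2 * gap + 0.5 * age + 0.8 * gap * (age - 11) + rng.normal(0, 5, n)
        t1 = fit_interaction_lmm(y, gap, age, site)["interaction_t"]
        t2 = fit_interaction_lmm(y, gap, age + 100.0, site)["interaction_t"]
        assert t1 == pytest.approx(t2, rel=1e-5)

    def test_injected_age_moderation_detected(self):
        cfg = pa.GeneratorConfig(
            n_families=4000, sibling_prob=0.0, n_waves=1,
            outcome_effect=0.2, outcome_effect_age_slope=0.3, seed=18,
        )
        df = pa.generate_cohort(cfg)
        z = df["truth_timing"] / cfg.timing_sd
        res = fit_interaction_lmm(df["cbcl_totprob"], z, df["age"], df["site_id"])
        assert res["interaction_p"] < 0.05

    def test_age_constant_effect_gives_null_interaction(self):
        cfg = pa.GeneratorConfig(
            n_families=2000, sibling_prob=0.0, n_waves=2,
            outcome_effect=0.3, outcome_effect_age_slope=0.0, seed=19,
        )
        df = pa.generate_cohort(cfg)
        z = df["truth_timing"] / cfg.timing_sd
        res = fit_interaction_lmm(df["cbcl_totprob"], z, df["age"], df["site_id"])
        assert abs(res["interaction_t"]) < 3.0


@pytest.fixture(scope="module")
def suite_inputs(medium_prepared):
    _, strat, part = medium_prepared
    gaps = {}
    for model in ("physical", "hormonal", "combined"):
        frames = [
            pa.PubertyAgeModel(strat, part, model=model, sex=s).fit(k=10, seed=4).gap_frame
            for s in ("F", "M")
        ]
        gaps[model] = pd.concat(frames)
    return gaps, strat


class TestSuite:
    def test_output_shape_is_66_primary_rows(self, suite_inputs):
        gaps, strat = suite_inputs
        suite = run_association_suite(gaps, strat)
        assert len(suite.table) == 2 * 3 * 11
        assert set(suite.table["outcome"]) == set(OUTCOME_COLUMNS)
        assert len(suite.aic_table) == 22

    def test_fdr_family_scope_changes_only_adjusted_p(self, suite_inputs):
        gaps, strat = suite_inputs
        per = run_association_suite(gaps, strat, fdr_family="per-sex-model")
        glob = run_association_suite(gaps, strat, fdr_family="global")
        key = ["sex", "model", "outcome"]
        a = per.table.set_index(key).sort_index()
        b = glob.table.set_index(key).sort_index()
        np.testing.assert_allclose(a["p_raw"], b["p_raw"], atol=1e-14)
        assert not np.allclose(a["p_fdr"], b["p_fdr"])

    def test_aic_models_fitted_on_common_rows(self, suite_inputs):
        gaps, strat = suite_inputs
        suite = run_association_suite(gaps, strat)
        for _, grp in suite.table.groupby(["sex", "outcome"]):
            assert grp["n"].nunique() == 1

    def test_interactions_add_columns(self, suite_inputs):
        gaps, strat = suite_inputs
        suite = run_association_suite(gaps, strat, interactions=True)
        assert {"interaction_t", "interaction_p"} <= set(suite.table.columns)

    def test_covariate_adjusted_run(self, suite_inputs):
        gaps, strat = suite_inputs
        suite = run_association_suite(gaps, strat, covariates=["bmi", "ses", "race"])
        assert len(suite.table) == 66
        assert suite.table["aic"].notna().all()

    def test_missing_model_reported(self, suite_inputs):
        gaps, strat = suite_inputs
        with pytest.raises(ValueError):
            run_association_suite({}, strat)
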