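"""Preprocessing: menarche coding, hormone cleaning, TD split, stratification."""

import logging

import numpy as np
import pandas as pd
import pytest

import pubertyage as pa
from pubertyage.preprocessing import (
    FeatureSet,
    bmi_zscore,
    build_feature_matrix,
    clean_hormones,
    code_menarche,
    select_td,
    stratify_families,
)
from pubertyage.simulate import DSM_SCALES


class TestCodeMenarche:
    def test_paper_coding(self):
        assert code_menarche("no") == 1
        assert code_menarche("yes") == 4

    def test_invalid_rejected(self):
        with pytest.raises(ValueError):
            code_menarche("unknown")

    def test_nan_propagates(self):
        assert np.isnan(code_menarche(float("nan")))

    def test_generator_consistency(self, small_cohort):
        fem = small_cohort[small_cohort.sex == "F"]
        coded = fem["menarche"].map(code_menarche)
        assert set(coded.unique()) <= {1, 4}
        assert (coded[fem["menarche"] == "yes"] == 4).all()


class TestCleanHormones:
    def test_no_confounds_means_centered_log(self):
        cfg = pa.GeneratorConfig(
            n_families=1500, sibling_prob=0.0, n_waves=2, seed=21,
            confound_effects={},
        )
        df = pa.generate_cohort(cfg)
        out = clean_hormones(df)
        for sex in ("F", "M"):
            sub = out[out.sex == sex]
            logh = np.log(sub["dhea"])
            z = (logh - logh.mean()) / logh.std(ddof=0)
            # nothing to remove beyond finite-sample noise in the
            # estimated (true-zero) confound coefficients
            assert np.corrcoef(z, sub["dhea_clean"])[0, 1] > 0.995
            assert np.max(np.abs(z - sub["dhea_clean"])) < 0.5

    def test_caffeine_confound_removed(self):
        eff = {"caffeine": 0.5}
        cfg = pa.GeneratorConfig(
            n_families=2000, sibling_prob=0.0, n_waves=2,
            confound_effects=eff, seed=22,
        )
        df = pa.generate_cohort(cfg)
        out = clean_hormones(df)
        for sex in ("F", "M"):
            sub = out[out.sex == sex]
            raw_r = np.corrcoef(np.log(sub["dhea"]), sub["caffeine"])[0, 1]
            clean_r = np.corrcoef(sub["dhea_clean"], sub["caffeine"])[0, 1]
            assert abs(raw_r) > 0.1  # confound visible before cleaning
            assert abs(clean_r) < 0.03

    def test_single_subject_falls_back_to_ols(self, caplog):
        cfg = pa.GeneratorConfig(n_families=1, sibling_prob=0.0, n_waves=8, seed=23)
        df = pa.generate_cohort(cfg)
        with caplog.at_level(logging.WARNING, logger="pubertyage.preprocessing"):
            out = clean_hormones(df)
        assert "falling back to OLS" in caplog.text
        sex = df["sex"].iloc[0]
        assert out.loc[out.sex == sex, "dhea_clean"].notna().all()

    def test_nonpositive_hormone_rejected(self, small_cohort):
        df = small_cohort.copy()
        df.loc[df.index[0], "tst"] = 0.0
        with pytest.raises(ValueError, match="non-positive"):
            clean_hormones(df)

    def test_recleaning_is_fixed_point(self):
        cfg = pa.GeneratorConfig(n_families=300, n_waves=2, sibling_prob=0.0, seed=24)
        df = pa.generate_cohort(cfg)
        once = clean_hormones(df)
        again = once.copy()
        again["dhea"] = np.exp(once["dhea_clean"])
        again["tst"] = np.exp(once["tst_clean"])
        twice = clean_hormones(again)
        np.testing.assert_allclose(
            twice["dhea_clean"], once["dhea_clean"], atol=1e-8
        )
        np.testing.assert_allclose(
            twice["tst_clean"], once["tst_clean"], atol=1e-8
        )


class TestSelectTd:
    def _record(self, scores):
        row = {c: s for c, s in zip(DSM_SCALES, scores)}
        row.update(observation_id="o1", sex="F")
        return pd.DataFrame([row])

    def test_all_at_or_below_threshold_is_td(self):
        part = select_td(self._record([55, 58, 60, 49, 51, 57]))
        assert part.td_ids == ["o1"] and part.nontd_ids == []

    def test_one_above_threshold_is_nontd(self):
        part = select_td(self._record([50, 61, 50, 50, 50, 50]))
        assert part.nontd_ids == ["o1"] and part.td_ids == []

    def test_empty_input(self):
        part = select_td(pd.DataFrame(columns=["observation_id", *DSM_SCALES]))
        assert part.td_ids == [] and part.nontd_ids == []

    def test_missing_score_unassignable(self):
        part = select_td(self._record([50, np.nan, 50, 50, 50, 50]))
        assert part.unassignable_ids == ["o1"]
        assert part.td_ids == [] and part.nontd_ids == []

    def test_idempotent_and_threshold_monotone(self, small_cohort):
        p60 = select_td(small_cohort, threshold=60)
        sub = small_cohort[small_cohort.observation_id.isin(p60.td_ids)]
        assert set(select_td(sub, threshold=60).td_ids) == set(p60.td_ids)
        p70 = select_td(small_cohort, threshold=70)
        assert set(p60.td_ids) <= set(p70.td_ids)


class TestStratifyFamilies:
    def test_one_record_per_family(self):
        df = pd.DataFrame(
            {
                "family_id": ["a", "b", "b", "c", "c", "c", "c"],
                "observation_id": list("1234567"),
            }
        )
        kept = stratify_families(df, seed=0)
        assert len(kept) == 3
        assert kept["family_id"].is_unique

    def test_deterministic(self, small_cohort):
        a = stratify_families(small_cohort, seed=5)
        b = stratify_families(small_cohort, seed=5)
        pd.testing.assert_frame_equal(a, b)

    def test_uniform_selection(self):
        df = pd.DataFrame({"family_id": ["f", "f"], "observation_id": ["x", "y"]})
        picks = sum(
            stratify_families(df, seed=s)["observation_id"].iloc[0] == "x"
            for s in range(1000)
        )
        assert 0.45 <= picks / 1000 <= 0.55


class TestBmiZscore:
    def test_constant_bin_gives_zero(self):
        df = pd.DataFrame(
            {"sex": ["F"] * 12, "age": [9.5] * 12, "bmi": [18.0] * 12}
        )
        out = bmi_zscore(df)
        assert (out["bmi_z"] == 0).all()

    def test_two_bin_hand_computation(self):
        bmis9 = [16.0, 18.0] * 6     # mean 17, sd 1
        bmis10 = [20.0, 24.0] * 6    # mean 22, sd 2
        df = pd.DataFrame(
            {
                "sex": ["M"] * 24,
                "age": [9.2] * 12 + [10.7] * 12,
                "bmi": bmis9 + bmis10,
            }
        )
        out = bmi_zscore(df)
        np.testing.assert_allclose(out.loc[:11, "bmi_z"], [-1.0, 1.0] * 6)
        np.testing.assert_allclose(out.loc[12:, "bmi_z"], [-1.0, 1.0] * 6)

    def test_sparse_bin_merged(self):
        df = pd.DataFrame(
            {
                "sex": ["F"] * 13,
                "age": [9.5] * 12 + [12.5],  # 12-bin too sparse alone
                "bmi": list(np.linspace(15, 20, 12)) + [30.0],
            }
        )
        out = bmi_zscore(df)
        assert out["bmi_z"].notna().all()
        assert out["bmi_z"].iloc[-1] == out["bmi_z"].max()


class TestFeatureMatrix:
    def test_physical_female_has_five_items(self, medium_prepared):
        _, strat, _ = medium_prepared
        X, age, ids = build_feature_matrix(strat, FeatureSet("physical"), "F")
        assert list(X.columns) == [
            "pds_growth", "pds_body_hair", "pds_skin", "pds_breast", "menarche_coded",
        ]
        assert len(X) == len(age) == len(ids)

    def test_hormonal_has_two_columns(self, medium_prepared):
        _, strat, _ = medium_prepared
        X, _, _ = build_feature_matrix(strat, FeatureSet("hormonal"), "M")
        assert list(X.columns) == ["dhea_clean", "tst_clean"]

    def test_combined_is_union(self, medium_prepared):
        _, strat, _ = medium_prepared
        X, _, _ = build_feature_matrix(strat, FeatureSet("combined"), "M")
        assert list(X.columns) == [
            "pds_growth", "pds_body_hair", "pds_skin", "pds_voice",
            "pds_facial_hair", "dhea_clean", "tst_clean",
        ]

    def test_incomplete_row_dropped(self, medium_prepared):
        _, strat, _ = medium_prepared
        broken = strat.copy()
        male_idx = broken[broken.sex == "M"].index[:5]
        broken.loc[male_idx, "tst_clean"] = np.nan
        X_full, _, _ = build_feature_matrix(strat, FeatureSet("combined"), "M")
        X_less, _, _ = build_feature_matrix(broken, FeatureSet("combined"), "M")
        assert len(X_less) == len(X_full) - 5

    def test_invalid_feature_set_name(self):
        with pytest.raises(ValueError):
            FeatureSet("everything")
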