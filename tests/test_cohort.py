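import numpy as np
import pandas as pd
import pytest

from ovarisk.cohort import (DEFAULT_PREVALENCES, GeneratorConfig, OUTCOME_LEVELS,
                            PAPILLATION_LEVELS, default_latent_coefficients,
                            generate_cohort, generate_from_latent_mlr,
                            inject_ca125_missingness, read_cohort,
                            validate_cohort_frame, write_cohort)


class TestGenerateCohort:
    def test_seeded_determinism(self):
        cfg = GeneratorConfig(n_patients=300, n_centers=3, seed=42)
        a = generate_cohort(cfg)
        b = generate_cohort(cfg)
        pd.testing.assert_frame_equal(a, b)

    def test_default_benign_fraction_near_62_percent(self):
        table = generate_cohort(GeneratorConfig(seed=7))  # n=3199, 25 centers
        frac = (table["outcome"] == "benign").mean()
        assert abs(frac - 0.62) < 0.03

    def test_marginal_fidelity_at_n_10000(self):
        # tolerance bands fixed in the methods note: age median +-3y of 49,
        # CA125 median within [20, 32], class proportions within 2.5pp
        table = generate_cohort(GeneratorConfig(n_patients=10_000, n_centers=10, seed=11))
        assert abs(table["age"].median() - 49) < 3
        assert 20 < table["ca125"].median() < 32
        props = table["outcome"].value_counts(normalize=True)
        for level, p in zip(OUTCOME_LEVELS, DEFAULT_PREVALENCES):
            assert abs(props[level] - p) < 0.025

    def test_predictor_invariants(self, small_cohort):
        t = small_cohort
        assert t["patient_id"].is_unique
        assert ((t["prop_solid"] >= 0) & (t["prop_solid"] <= 1)).all()
        assert (t["max_diameter"] > 0).all()
        assert (t["age"] > 0).all()
        assert (t["ca125"] > 0).all()
        assert t["papillations"].isin(PAPILLATION_LEVELS).all()
        assert t.groupby("center_id").size().min() >= 1

    def test_degenerate_prevalence_warns(self):
        cfg = GeneratorConfig(n_patients=100, n_centers=2,
                              class_prevalences=(1.0, 0.0, 0.0, 0.0, 0.0), seed=1)
        with pytest.warns(UserWarning, match="lacks outcome classes"):
            table = generate_cohort(cfg)
        assert (table["outcome"] == "benign").all()

    @pytest.mark.parametrize("bad, err", [
        ({"class_prevalences": (0.5, 0.2, 0.2, 0.2, 0.2)}, "sum to 1"),
        ({"n_patients": 3, "n_centers": 5}, "n_patients"),
        ({"n_centers": 1}, "n_centers"),
        ({"ca125_missing_rate": 1.0}, "missing"),
    ])
    def test_invalid_config_rejected(self, bad, err):
        with pytest.raises(ValueError, match=err):
            generate_cohort(GeneratorConfig(seed=0, **bad))

    def test_oncology_centers_have_higher_malignancy(self):
        table = generate_cohort(GeneratorConfig(n_patients=20_000, n_centers=20, seed=5))
        mal = table["outcome"] != "benign"
        rate_onc = mal[table["center_oncology"] == 1].mean()
        rate_gen = mal[table["center_oncology"] == 0].mean()
        assert rate_onc > rate_gen


class TestLatentMlr:
    def test_zero_coefficients_give_uniform_probabilities(self):
        cfg = GeneratorConfig(n_patients=50, n_centers=2, seed=3,
                              latent_mlr_coefficients=np.zeros((10, 4)))
        _, true_p = generate_from_latent_mlr(cfg)
        assert np.allclose(true_p, 0.2)

    def test_bad_coefficient_shape_rejected(self):
        cfg = GeneratorConfig(n_patients=50, n_centers=2, seed=3,
                              latent_mlr_coefficients=np.zeros((9, 4)))
        with pytest.raises(ValueError, match="coefficient matrix"):
            generate_from_latent_mlr(cfg)

    def test_ascites_coefficient_raises_stage_II_IV_prevalence(self):
        coef = np.zeros((10, 4))
        coef[0] = [-1.5, -1.5, -1.5, -1.5]
        coef[7, 2] = 3.0  # ascites -> stage II-IV
        cfg = GeneratorConfig(n_patients=10_000, n_centers=2, seed=9,
                              latent_mlr_coefficients=coef)
        table, _ = generate_from_latent_mlr(cfg)
        adv = table["outcome"] == "stage_II_IV"
        with_asc = adv[table["ascites"] == 1].mean()
        without = adv[table["ascites"] == 0].mean()
        assert with_asc > without

    def test_true_probabilities_match_class_frequencies(self, latent_cohort):
        table, true_p, _ = latent_cohort
        freq = np.array([(table["outcome"] == c).mean() for c in OUTCOME_LEVELS])
        mc_se = np.sqrt(freq * (1 - freq) / len(table))
        assert np.all(np.abs(true_p.mean(axis=0) - freq) < 4 * np.maximum(mc_se, 1e-3))

    def test_seeded_determinism(self):
        cfg = GeneratorConfig(n_patients=200, n_centers=2, seed=17,
                              latent_mlr_coefficients=default_latent_coefficients())
        a, pa = generate_from_latent_mlr(cfg)
        b, pb = generate_from_latent_mlr(cfg)
        pd.testing.assert_frame_equal(a, b)
        assert np.array_equal(pa, pb)


class TestMissingness:
    def test_target_rate_achieved(self):
        table = generate_cohort(GeneratorConfig(n_patients=3199, n_centers=25, seed=13))
        out = inject_ca125_missingness(table, 0.30, seed=1)
        assert abs(out["ca125"].isna().mean() - 0.30) < 0.02

    def test_suspicious_tumors_more_often_measured(self):
        table = generate_cohort(GeneratorConfig(n_patients=5000, n_centers=5, seed=14))
        out = inject_ca125_missingness(table, 0.30, suspicion_slope=2.0, seed=2)
        measured = ~out["ca125"].isna()
        solid_measured = out.loc[measured, "prop_solid"].mean()
        solid_missing = out.loc[~measured, "prop_solid"].mean()
        assert solid_measured > solid_missing

    def test_zero_slope_is_mcar(self):
        table = generate_cohort(GeneratorConfig(n_patients=5000, n_centers=5, seed=15))
        out = inject_ca125_missingness(table, 0.30, suspicion_slope=0.0, seed=3)
        measured = ~out["ca125"].isna()
        diff = out.loc[measured, "prop_solid"].mean() - out.loc[~measured, "prop_solid"].mean()
        assert abs(diff) < 0.02

    def test_rate_zero_identity(self, small_cohort):
        out = inject_ca125_missingness(small_cohort, 0.0, seed=4)
        pd.testing.assert_frame_equal(out, small_cohort)

    def test_rate_one_rejected(self, small_cohort):
        with pytest.raises(ValueError):
            inject_ca125_missingness(small_cohort, 1.0, seed=5)


class TestIO:
    def test_round_trip(self, tmp_path, cohort_with_missing):
        path = tmp_path / "cohort.csv"
        write_cohort(cohort_with_missing, path)
        back = read_cohort(path)
        pd.testing.assert_frame_equal(
            back.drop(columns="ca125_missing"),
            cohort_with_missing.drop(columns="ca125_missing").reset_index(drop=True),
            check_dtype=False, check_exact=False, rtol=1e-9,
        )

    def test_out_of_range_prop_solid_names_row(self, tmp_path, small_cohort):
        bad = small_cohort.copy()
        bad.loc[bad.index[5], "prop_solid"] = 1.2
        with pytest.raises(ValueError, match="prop_solid.*row 5"):
            validate_cohort_frame(bad)

    def test_missing_age_rejected(self, tmp_path, small_cohort):
        bad = small_cohort.copy()
        bad.loc[bad.index[2], "age"] = np.nan
        with pytest.raises(ValueError, match="age"):
            validate_cohort_frame(bad)

    def test_unknown_outcome_level_rejected(self, small_cohort):
        bad = small_cohort.copy()
        bad.loc[bad.index[0], "outcome"] = "cystic"
        with pytest.raises(ValueError, match="cystic"):
            validate_cohort_frame(bad)
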