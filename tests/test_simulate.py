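"""Generator contracts: determinism, noise-free limits, parameter recovery,
and conservation of unmasked cells under contamination."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import bioage as ba
from bioage.errors import ConfigurationError, PanelError


def _noise_free_config(n=50, seed=3, **kw):
    specs = tuple(
        ba.BiomarkerSpec(s.name, s.intercept, s.slope, 0.0)
        for s in ba.kdm8_specs()
    )
    return ba.GenerativeConfig(n_subjects=n, biomarker_specs=specs, s_ba=0.0,
                               seed=seed, **kw)


class TestControls:
    def test_noise_free_markers_are_affine_in_ca(self):
        cohort = ba.generate_controls(_noise_free_config())
        assert np.allclose(cohort["true_dage"], 0.0)
        for spec in ba.kdm8_specs():
            expected = spec.intercept + spec.slope * cohort["ca"]
            np.testing.assert_allclose(cohort[spec.name], expected, rtol=1e-12)

    def test_same_seed_reproduces_byte_identical_tables(self):
        cfg = ba.GenerativeConfig(n_subjects=200, seed=7, missing_rate=0.05,
                                  outlier_rate=0.02)
        a = ba.generate_controls(cfg)
        b = ba.generate_controls(cfg)
        pd.testing.assert_frame_equal(a, b)

    def test_ba_noise_sd_recovered(self):
        # chi-square CI for a sample sd at n = 10000 is well within +/- 0.15
        cohort = ba.generate_controls(
            ba.GenerativeConfig(n_subjects=10_000, s_ba=5.0, seed=21)
        )
        sd = np.std(cohort["true_ba"] - cohort["ca"], ddof=1)
        assert abs(sd - 5.0) < 0.15

    def test_ca_uniform_over_range_and_gender_fraction(self):
        cfg = ba.GenerativeConfig(n_subjects=5000, age_range=(30, 40),
                                  female_fraction=0.25, seed=9)
        cohort = ba.generate_controls(cfg)
        assert cohort["ca"].between(30, 40).all()
        assert abs((cohort["gender"] == "female").mean() - 0.25) < 0.03

    @pytest.mark.parametrize(
        "field,value",
        [("n_subjects", 0), ("age_range", (50, 50)), ("female_fraction", 1.5),
         ("s_ba", -1.0), ("missing_rate", 2.0)],
    )
    def test_invalid_config_names_the_field(self, field, value):
        with pytest.raises(ConfigurationError) as err:
            ba.GenerativeConfig(**{"n_subjects": 10, field: value})
        assert field in str(err.value)


class TestDiseaseGroup:
    def test_zero_shift_matches_controls_distribution(self):
        # at delta = 0 the rank test on true_ba should be non-significant
        # in the vast majority of replicates
        nonsig = 0
        reps = 60
        for seed in range(reps):
            cfg = ba.GenerativeConfig(n_subjects=300, seed=seed)
            ctrl = ba.generate_controls(cfg)
            dis = ba.generate_disease_group(
                ba.GenerativeConfig(n_subjects=300, seed=seed + 10_000), "t2d"
            )
            p = stats.mannwhitneyu(ctrl["true_ba"], dis["true_ba"],
                                   alternative="two-sided").pvalue
            nonsig += p >= 0.05
        assert nonsig / reps >= 0.88

    def test_injected_shift_recovered_in_mean_dage(self):
        cfg = ba.GenerativeConfig(n_subjects=5000, s_ba=5.0,
                                  group_shift_delta=12.0, seed=4)
        dis = ba.generate_disease_group(cfg, "t2d")
        assert (dis["group"] == "t2d").all()
        assert abs(dis["true_dage"].mean() - 12.0) < 0.2

    def test_negative_shift_gives_negative_mean_dage(self):
        cfg = ba.GenerativeConfig(n_subjects=2000, group_shift_delta=-3.0, seed=5)
        dis = ba.generate_disease_group(cfg, "t1d")
        assert dis["true_dage"].mean() < 0


class TestContamination:
    def test_masking_preserves_unmasked_cells(self, kdm_panel):
        clean = ba.generate_controls(ba.GenerativeConfig(n_subjects=400, seed=13))
        dirty = ba.generate_controls(
            ba.GenerativeConfig(n_subjects=400, seed=13, missing_rate=0.1,
                                outlier_rate=0.05)
        )
        changed = 0
        for name in kdm_panel:
            a, b = clean[name].to_numpy(), dirty[name].to_numpy()
            untouched = ~np.isnan(b) & (b == a)
            touched = len(a) - untouched.sum()
            changed += touched
            # every touched cell is either missing or an exact x3/x5 multiple
            mask = ~untouched
            is_missing = np.isnan(b[mask])
            ratio = b[mask][~is_missing] / a[mask][~is_missing]
            assert np.all(np.isclose(ratio[:, None], [3.0, 5.0]).any(axis=1))
        assert changed > 0

    def test_outlier_cells_at_expected_rate(self):
        dirty = ba.generate_controls(
            ba.GenerativeConfig(n_subjects=2000, seed=1, missing_rate=0.1)
        )
        rate = dirty[[s.name for s in ba.kdm8_specs()]].isna().to_numpy().mean()
        assert abs(rate - 0.1) < 0.01


class TestSurvivalGeneration:
    def test_null_log_hr_gives_uncorrelated_times(self):
        cohort = ba.generate_controls(ba.GenerativeConfig(n_subjects=3000, seed=2))
        surv = ba.generate_survival(cohort, 0.05, 0.0, censor_time=50.0, seed=3)
        rho = stats.spearmanr(surv["true_dage"], surv["time"]).statistic
        assert abs(rho) < 0.05

    def test_zero_censor_time_censors_everyone(self):
        cohort = ba.generate_controls(ba.GenerativeConfig(n_subjects=100, seed=2))
        surv = ba.generate_survival(cohort, 0.05, 0.1, censor_time=0.0, seed=3)
        assert (surv["event"] == 0).all()
        assert (surv["time"] == 0.0).all()

    def test_positive_log_hr_shortens_high_dage_lives(self):
        cohort = ba.generate_controls(ba.GenerativeConfig(n_subjects=4000, seed=8))
        surv = ba.generate_survival(cohort, 0.05, 0.2, censor_time=100.0, seed=9)
        rho = stats.spearmanr(surv["true_dage"], surv["time"]).statistic
        assert rho < -0.3

    def test_nonpositive_baseline_hazard_rejected(self):
        cohort = ba.generate_controls(ba.GenerativeConfig(n_subjects=10, seed=1))
        with pytest.raises(ConfigurationError):
            ba.generate_survival(cohort, 0.0, 0.1, 10.0)


class TestPhagePanel:
    def test_missing_markers_listed(self):
        specs = tuple(s for s in ba.phage9_specs() if s.name not in ("rdw", "wbc"))
        cfg = ba.GenerativeConfig(n_subjects=10, biomarker_specs=specs)
        with pytest.raises(PanelError) as err:
            ba.generate_phage_panel(cfg)
        assert "rdw" in str(err.value) and "wbc" in str(err.value)

    def test_crp_strictly_positive(self):
        cfg = ba.GenerativeConfig(n_subjects=2000, biomarker_specs=ba.phage9_specs(),
                                  seed=6)
        panel = ba.generate_phage_panel(cfg)
        assert (panel["crp"] > 0).all()

    def test_marker_means_match_generative_laws(self):
        cfg = ba.GenerativeConfig(n_subjects=1000, biomarker_specs=ba.phage9_specs(),
                                  seed=17)
        panel = ba.generate_phage_panel(cfg)
        mean_ba = panel["true_ba"].mean()
        for spec in ba.phage9_specs():
            if spec.transform_hint == "log-normal":
                continue  # multiplicative noise shifts the mean
            expected = spec.intercept + spec.slope * mean_ba
            se = np.sqrt(
                spec.noise_sd**2 + (spec.slope * panel["true_ba"].std()) ** 2
            ) / np.sqrt(len(panel))
            assert abs(panel[spec.name].mean() - expected) < 3 * max(se, 1e-9)
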