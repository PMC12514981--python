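import numpy as np
import pandas as pd
import pytest

from cycloref.accommodation import delta_radii, fit_quadratic
from cycloref.cohort import (
    AccommodationSeriesConfig,
    CohortConfig,
    generate_accommodation_series,
    generate_cohort,
    inject_missingness,
    MISSABLE_COLUMNS,
)


class TestCohortContracts:
    def test_deterministic_under_fixed_seed(self):
        a = generate_cohort(seed=11)
        b = generate_cohort(seed=11)
        pd.testing.assert_frame_equal(a, b)
        c = generate_cohort(seed=12)
        assert not a["S"].equals(c["S"])

    def test_row_and_subject_counts(self, cohort306):
        assert len(cohort306) == 306
        assert cohort306["subject_id"].nunique() == 153
        assert cohort306["eye_id"].is_unique

    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError):
            CohortConfig(n_eyes=305)  # odd
        with pytest.raises(ValueError):
            CohortConfig(missing_rate=1.0)
        with pytest.raises(ValueError):
            CohortConfig(ds_sd=0.0, ds_mean=0.34)  # zero-spread tonus must be null

    def test_config_round_trips_through_dict(self):
        cfg = CohortConfig(n_eyes=100, missing_rate=0.05, lens_share=0.3)
        assert CohortConfig.from_dict(cfg.to_dict()) == cfg


class TestCohortStatistics:
    def test_moments_converge_to_configured_values(self):
        ms, md = [], []
        for seed in range(1, 11):
            df = generate_cohort(seed=seed)
            ms.append(df["S"].mean())
            md.append((df["S_cyclo"] - df["S"]).mean())
        # 10-cohort grand means vs configured -1.53 and +0.34 (within MC error)
        assert np.mean(ms) == pytest.approx(-1.53, abs=0.18)
        assert np.mean(md) == pytest.approx(0.34, abs=0.03)

    def test_cycloplegic_shift_nonnegative_and_age_declining(self):
        negative = 0
        for seed in range(1, 11):
            df = generate_cohort(seed=seed)
            ds = df["S_cyclo"] - df["S"]
            assert (ds >= 0).all()
            if np.corrcoef(ds, df["age"])[0, 1] < 0:
                negative += 1
        assert negative >= 9

    def test_biometry_respects_physiologic_invariants(self, cohort306):
        df = cohort306
        assert df["AL"].between(15, 35, inclusive="neither").all()
        assert df["CCT"].between(0.3, 0.8, inclusive="neither").all()
        assert df["ACD"].between(1.5, 5.5, inclusive="neither").all()
        assert df["LT"].between(2.5, 6.0, inclusive="neither").all()
        assert df["Km"].between(35, 52, inclusive="neither").all()
        assert (df["ACD"] + df["LT"] + df["CCT"] < df["AL"]).all()
        assert (df["C"] <= 0).all() and (df["C_cyclo"] <= 0).all()
        assert df["axis"].between(0, 180, inclusive="left").all()
        assert (df["S"].between(-7.5, 10.5)).all()
        assert np.allclose(df["Km"], (df["K1"] + df["K2"]) / 2.0)

    def test_fellow_eyes_strongly_correlated(self, cohort306):
        od = cohort306[cohort306["eye"] == "OD"].reset_index()
        os_ = cohort306[cohort306["eye"] == "OS"].reset_index()
        assert np.corrcoef(od["S"], os_["S"])[0, 1] > 0.6
        assert np.corrcoef(od["AL"], os_["AL"])[0, 1] > 0.6

    def test_null_cohort_has_identical_refractions(self):
        df = generate_cohort(CohortConfig(ds_mean=0.0, ds_sd=0.0), seed=3)
        np.testing.assert_array_equal(df["S_cyclo"], df["S"])


class TestMissingness:
    def test_zero_rate_is_identity(self, cohort306):
        pd.testing.assert_frame_equal(inject_missingness(cohort306, 0.0, 1), cohort306)

    def test_blank_count_is_binomial(self, cohort306):
        rate = 0.1
        out = inject_missingness(cohort306, rate, seed=5)
        n_cells = len(cohort306) * len(MISSABLE_COLUMNS)
        blanked = int(out[MISSABLE_COLUMNS].isna().sum().sum())
        sigma = np.sqrt(n_cells * rate * (1 - rate))
        assert abs(blanked - n_cells * rate) < 4 * sigma

    def test_protected_columns_never_blanked(self, cohort306):
        out = inject_missingness(cohort306, 0.3, seed=5)
        for col in ("subject_id", "eye_id", "gender", "age", "S", "C", "axis", "S_cyclo"):
            assert not out[col].isna().any()

    def test_same_seed_same_pattern(self, cohort306):
        a = inject_missingness(cohort306, 0.2, seed=9)
        b = inject_missingness(cohort306, 0.2, seed=9)
        pd.testing.assert_frame_equal(a, b)


class TestAccommodationSeries:
    noiseless = AccommodationSeriesConfig(acr_noise_sd=0.0, pcr_noise_sd=0.0, lt_noise_sd=0.0)

    def test_baseline_only_series_has_zero_deltas(self):
        cfg = AccommodationSeriesConfig(stimulus_levels=(0.0,), acr_noise_sd=0.0, pcr_noise_sd=0.0, lt_noise_sd=0.0)
        series = generate_accommodation_series(cfg, seed=1)
        deltas = delta_radii(series)
        assert np.allclose(deltas[["delta_ACR", "delta_PCR"]], 0.0)

    def test_zero_noise_round_trips_generating_coefficients(self):
        series = generate_accommodation_series(self.noiseless, seed=2)
        deltas = delta_radii(series)
        nz = deltas[deltas["stimulus_D"] > 0]  # baseline is anchored off-curve by design
        acr = fit_quadratic(nz["delta_ACR"], nz["stimulus_D"])
        pcr = fit_quadratic(nz["delta_PCR"], nz["stimulus_D"])
        assert (acr.a, acr.b, acr.c) == pytest.approx(self.noiseless.quad_acr, abs=1e-6)
        assert (pcr.a, pcr.b, pcr.c) == pytest.approx(self.noiseless.quad_pcr, abs=1e-6)

    def test_radii_shrink_monotonically_with_stimulus(self):
        series = generate_accommodation_series(self.noiseless, seed=4)
        for _, grp in series.groupby("eye_id"):
            grp = grp.sort_values("stimulus_D")
            assert (np.diff(grp["ACR"]) < 0).all()
            assert (np.diff(grp["PCR"]) < 0).all()
            assert (np.diff(grp["LT"]) > 0).all()

    def test_default_noise_recovers_anterior_slope(self):
        fitted = []
        for seed in range(10):
            series = generate_accommodation_series(seed=seed)
            deltas = delta_radii(series)
            fitted.append(abs(fit_quadratic(deltas["delta_ACR"], deltas["stimulus_D"]).b))
        assert np.mean(fitted) == pytest.approx(1.21, rel=0.10)

    def test_determinism_and_eye_count(self):
        a = generate_accommodation_series(seed=6)
        b = generate_accommodation_series(seed=6)
        pd.testing.assert_frame_equal(a, b)
        assert a["eye_id"].nunique() == 16

    def test_stimulus_beyond_quadratic_range_rejected(self):
        cfg = AccommodationSeriesConfig(stimulus_levels=(0.0, 9.0))
        with pytest.raises(ValueError):
            generate_accommodation_series(cfg, seed=0)

    def test_invalid_stimulus_grid_rejected(self):
        with pytest.raises(ValueError):
            AccommodationSeriesConfig(stimulus_levels=(2.0, 1.0))
        with pytest.raises(ValueError):
            AccommodationSeriesConfig(acr_noise_sd=-0.1)
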