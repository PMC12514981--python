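import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import _formula_oracle as oracle
from cycloref import optics
from cycloref.optics import (
    OcularBiometry,
    OpticalConstants,
    RefractionRecord,
    anterior_radius,
    anterior_surface_power,
    contact_lens_power,
    corneal_radius,
    corrected_axial_length,
    corrected_corneal_radius_cl,
    derive_lens_features,
    iol_contact_lens,
    iol_emmetropia,
    iol_myopia,
    power_vectors,
    spherical_equivalent,
    thick_lens_total_power,
)

biometry_st = st.fixed_dictionaries(
    {
        "al": st.floats(21.0, 26.5),
        "acd": st.floats(2.8, 4.2),
        "lt": st.floats(3.0, 4.4),
        "km": st.floats(40.0, 46.0),
    }
)


class TestCornealRadius:
    @pytest.mark.parametrize(
        "km, expected",
        [(45.0, 7.5), (33.75, 10.0), (43.0, 337.5 / 43.0)],
    )
    def test_keratometric_conversion(self, km, expected):
        assert corneal_radius(km) == pytest.approx(expected, abs=1e-12)

    def test_nonpositive_keratometry_rejected(self):
        with pytest.raises(ValueError):
            corneal_radius(0.0)
        with pytest.raises(ValueError):
            corneal_radius(-43.0)


class TestCorrectedAxialLength:
    def test_constant_term_at_zero_length(self):
        assert corrected_axial_length(1e-12) == pytest.approx(0.65696, abs=1e-6)

    def test_arithmetic(self):
        assert corrected_axial_length(23.0) == pytest.approx(23.19029, abs=1e-9)

    def test_fixed_point(self):
        al = 0.65696 / 0.02029  # retinal correction cancels exactly here
        assert corrected_axial_length(al) == pytest.approx(al, abs=1e-9)


class TestIolVariants:
    def test_emmetropic_matches_oracle_fixture(self):
        r = corneal_radius(43.0)
        assert iol_emmetropia(23.65, 3.60, r) == pytest.approx(
            oracle.iol_emmetropia(23.65, 3.60, oracle.corneal_radius(43.0)), abs=1e-9
        )

    def test_longer_eye_needs_less_power(self):
        r = corneal_radius(43.0)
        assert iol_emmetropia(22.0, 3.6, r) > iol_emmetropia(26.0, 3.6, r)

    def test_myopic_retention_needs_more_power(self):
        r = corneal_radius(43.0)
        assert iol_myopia(23.65, 3.6, r, -3.0) > iol_myopia(23.65, 3.6, r, 3.0)

    def test_myopia_variant_matches_oracle(self):
        r = corneal_radius(43.0)
        assert iol_myopia(23.65, 3.60, r, -3.0) == pytest.approx(
            oracle.iol_myopia(23.65, 3.60, oracle.corneal_radius(43.0), -3.0), abs=1e-9
        )

    def test_contact_lens_variant_matches_composed_oracle(self):
        assert iol_contact_lens(23.65, 3.60, 43.0, -3.0) == pytest.approx(
            oracle.iol_contact_lens(23.65, 3.60, 43.0, -3.0), abs=1e-9
        )

    def test_myopic_contact_lens_exceeds_emmetropic(self):
        r = corneal_radius(43.0)
        assert iol_contact_lens(23.65, 3.6, 43.0, -3.0) > iol_emmetropia(23.65, 3.6, r)

    def test_degenerate_geometry_rejected(self):
        r = corneal_radius(43.0)
        with pytest.raises(ValueError):
            iol_emmetropia(3.0, 3.6, r)  # LOPT <= ACD

    @given(biometry_st)
    def test_zero_se_reduces_to_emmetropic(self, bio):
        r = corneal_radius(bio["km"])
        e = iol_emmetropia(bio["al"], bio["acd"], r)
        assert iol_myopia(bio["al"], bio["acd"], r, 0.0) == pytest.approx(e, abs=1e-9)
        assert iol_contact_lens(bio["al"], bio["acd"], bio["km"], 0.0) == pytest.approx(
            e, abs=1e-9
        )


class TestContactLensConversion:
    @pytest.mark.parametrize(
        "se, expected",
        [(0.0, 0.0), (-5.0, -5.0 / 1.06), (10.0, 10.0 / 0.88)],
    )
    def test_vertex_correction(self, se, expected):
        assert contact_lens_power(se) == pytest.approx(expected, abs=1e-9)

    def test_vertex_singularity_rejected(self):
        with pytest.raises(ValueError):
            contact_lens_power(1.0 / 0.012)

    @given(st.floats(-20.0, -0.01))
    def test_myopic_magnitude_shrinks_at_cornea(self, se):
        assert abs(contact_lens_power(se)) < abs(se)

    @given(st.floats(0.01, 20.0))
    def test_hyperopic_magnitude_grows_at_cornea(self, se):
        assert abs(contact_lens_power(se)) > abs(se)

    @pytest.mark.parametrize(
        "km, fc, expected", [(45.0, 0.0, 7.5), (45.0, -5.0, 8.4375), (43.0, 2.0, 7.5)]
    )
    def test_corrected_radius(self, km, fc, expected):
        assert corrected_corneal_radius_cl(km, fc) == pytest.approx(expected, abs=1e-9)

    def test_corrected_radius_domain(self):
        with pytest.raises(ValueError):
            corrected_corneal_radius_cl(43.0, -43.0)


class TestThickLens:
    def test_thin_lens_limit(self):
        assert anterior_surface_power(20.0, 1e-9) == pytest.approx(20.0 - 9.26, abs=1e-6)

    def test_arithmetic_fixture(self):
        assert anterior_surface_power(20.0, 3.6) == pytest.approx(
            oracle.anterior_surface_power(20.0, 3.6), abs=1e-12
        )
        assert anterior_surface_power(20.0, 3.6) == pytest.approx(11.00198, abs=1e-5)

    @given(st.floats(5.0, 40.0), st.floats(2.5, 6.0))
    def test_round_trip_identity(self, f_total, lt):
        fa = anterior_surface_power(f_total, lt)
        assert thick_lens_total_power(fa, 9.26, lt) == pytest.approx(f_total, abs=1e-9)

    @pytest.mark.parametrize("fa, expected", [(64.0, 1.0), (8.0, 8.0), (11.00198, 64.0 / 11.00198)])
    def test_anterior_radius(self, fa, expected):
        assert anterior_radius(fa) == pytest.approx(expected, abs=1e-9)

    def test_zero_power_radius_rejected(self):
        with pytest.raises(ValueError):
            anterior_radius(0.0)


class TestPowerVectors:
    @pytest.mark.parametrize(
        "c, axis, j0, j45",
        [(0.0, 37.0, 0.0, 0.0), (-1.0, 90.0, -0.5, 0.0), (-2.0, 45.0, 0.0, 1.0)],
    )
    def test_cardinal_conversions(self, c, axis, j0, j45):
        got = power_vectors(c, axis)
        assert got[0] == pytest.approx(j0, abs=1e-12)
        assert got[1] == pytest.approx(j45, abs=1e-12)

    def test_plus_cylinder_rejected(self):
        with pytest.raises(ValueError):
            power_vectors(1.0, 90.0)

    @given(st.floats(-6.0, 0.0), st.floats(0.0, 179.99))
    def test_norm_identity(self, c, axis):
        j0, j45 = power_vectors(c, axis)
        assert j0**2 + j45**2 == pytest.approx((c / 2.0) ** 2, abs=1e-9)

    def test_axis_0_and_180_identified(self):
        assert power_vectors(-1.5, 0.0) == pytest.approx(power_vectors(-1.5, 180.0))


class TestRecordsAndConstants:
    def test_spherical_equivalent(self):
        assert spherical_equivalent(-1.0, 0.0) == -1.0
        assert spherical_equivalent(-1.0, -1.0) == -1.5
        assert spherical_equivalent(2.0, -4.0) == 0.0

    def test_refraction_record_derives_consistent_vectors(self):
        rec = RefractionRecord.from_measurement(-2.0, -1.5, 170.0)
        assert rec.spherical_equivalent == pytest.approx(-2.75)
        assert rec.J0**2 + rec.J45**2 == pytest.approx((rec.cylinder / 2.0) ** 2)

    def test_biometry_invariants_enforced(self):
        with pytest.raises(ValueError):
            OcularBiometry(8.0, 0.5, 4.0, 4.0, 42.0, 44.0, 43.0, 15.0)
        with pytest.raises(ValueError):
            OcularBiometry(24.0, 0.5, 3.5, 3.6, 42.0, 44.0, 60.0, 15.0)

    def test_constants_validated(self):
        with pytest.raises(ValueError):
            OpticalConstants(n_lens=1.2)  # below aqueous index
        with pytest.raises(ValueError):
            OpticalConstants(delta_n=-0.1)

    def test_derive_lens_features_bundles_variants(self):
        bio = OcularBiometry(23.65, 0.55, 3.60, 3.6, 42.0, 44.0, 43.0, 15.0)
        e = derive_lens_features(bio, -3.0, "e")
        cl = derive_lens_features(bio, -3.0, "cl")
        assert e.fc is None and cl.fc == pytest.approx(oracle.contact_lens_power(-3.0))
        assert cl.iol > e.iol
        assert e.ra == pytest.approx(oracle.anterior_radius(e.fa), abs=1e-9)
        with pytest.raises(ValueError):
            derive_lens_features(bio, 0.0, "x")


def test_array_inputs_mask_invalid_entries_as_nan():
    km = np.array([43.0, -1.0, 45.0])
    r = corneal_radius(km)
    assert np.isnan(r[1]) and r[0] == pytest.approx(337.5 / 43.0)
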