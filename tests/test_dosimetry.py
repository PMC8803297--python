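"""Closed-form dosimetry chain: calibration, kerma, AGD and uncertainty."""
import numpy as np
import pytest

from dbtdose import dosimetry as d


class TestPmmaBreast:
    @pytest.mark.parametrize("pmma,breast,gland", [(2.0, 2.1, 97.0),
                                                   (4.0, 4.5, 40.0),
                                                   (7.0, 9.0, 4.0)])
    def test_equivalence_table(self, pmma, breast, gland):
        assert d.pmma_to_breast(pmma) == (breast, gland)

    def test_interpolation_between_entries(self):
        breast, gland = d.pmma_to_breast(3.0)
        assert 2.1 < breast < 4.5
        assert 40.0 < gland < 97.0

    @pytest.mark.parametrize("bad", [1.5, 7.5])
    def test_range_error(self, bad):
        with pytest.raises(ValueError):
            d.pmma_to_breast(bad)


class TestCalibration:
    def test_exact_cancellation(self):
        assert d.calibration_factor(1.0, 1.2, 0.2).C == pytest.approx(1.0)

    def test_hand_division(self):
        assert d.calibration_factor(1.9, 1.9, 0.1).C == pytest.approx(
            1.9 / 1.8, rel=1e-12)

    def test_signal_below_background(self):
        with pytest.raises(ValueError, match="background"):
            d.calibration_factor(1.0, 0.5, 0.6)

    @pytest.mark.parametrize("kvp,c", [(25, 1.053), (28, 1.005), (34, 1.021)])
    def test_stored_constants(self, kvp, c):
        assert d.stored_calibration_factor(kvp) == c

    def test_apply_identity(self):
        rec = d.CalibrationRecord(Ki=1.0, Ko=2.0, BG=1.0)  # C = 1
        assert d.apply_calibration(5.0, rec) == pytest.approx(5.0 - 1.0)

    def test_apply_round_trip(self):
        rec = d.calibration_factor(Ki=2.5, Ko=2.0, BG=0.1)
        assert d.apply_calibration(2.0, rec) == pytest.approx(2.5, rel=1e-12)

    def test_apply_hand_value(self):
        rec = d.CalibrationRecord(Ki=1.053, Ko=1.0, BG=0.0)  # C = 1.053
        assert d.apply_calibration(2.0, rec) == pytest.approx(
            (2.0 - 0.0) * 1.053, rel=1e-12)

    def test_apply_below_background(self):
        rec = d.CalibrationRecord(Ki=1.0, Ko=2.0, BG=0.5)
        with pytest.raises(ValueError):
            d.apply_calibration(0.4, rec)


class TestIncidentKerma:
    def test_unit_bsf(self):
        assert d.incident_kerma_from_esak(2.0, 1.0) == 2.0

    def test_hand_division(self):
        assert d.incident_kerma_from_esak(2.0, 1.079) == pytest.approx(
            2.0 / 1.079, rel=1e-12)

    def test_unphysical_bsf(self):
        with pytest.raises(ValueError, match="unphysical"):
            d.incident_kerma_from_esak(2.0, 0.9)


class TestAgd:
    def test_identity_factors(self):
        f = d.ConversionFactors(28, g=0.5, c=1.0, s=1.0, T=1.0)
        assert d.compute_agd(2.0, f, "2D").AGD == pytest.approx(1.0)

    def test_28kv_2d_product(self):
        """K = 1 mGy with the stored 28 kV factors gives 0.3300 mGy."""
        agd = d.compute_agd(1.0, d.get_factors(28), "2D").AGD
        assert agd == pytest.approx(0.306 * 1.035 * 1.042, rel=1e-12)
        assert agd == pytest.approx(0.3300, abs=5e-5)

    def test_25kv_round_trip_to_reported_agd(self):
        """Inverting the 2D formula at the study's smallest breast gives
        back the reported AGD when re-applied."""
        f = d.get_factors(25)
        K = 0.91 / (f.g * f.c * f.s)
        assert d.compute_agd(K, f, "2D").AGD == pytest.approx(0.91, rel=1e-12)

    def test_t_only_in_3d(self):
        f = d.get_factors(34)
        agd2d = d.compute_agd(1.0, f, "2D").AGD
        agd3d = d.compute_agd(1.0, f, "3D").AGD
        assert agd3d == pytest.approx(agd2d * f.T, rel=1e-12)
        assert agd3d < agd2d  # T <= 1

    def test_linearity_in_k(self):
        f = d.get_factors(28)
        assert d.compute_agd(3.7, f, "2D").AGD == pytest.approx(
            3.7 * d.compute_agd(1.0, f, "2D").AGD, rel=1e-12)

    def test_missing_kvp(self):
        with pytest.raises(KeyError):
            d.get_factors(30)

    def test_factor_validation(self):
        with pytest.raises(ValueError):
            d.ConversionFactors(28, g=1.2, c=1.0, s=1.0, T=1.0)
        with pytest.raises(ValueError):
            d.ConversionFactors(28, g=0.3, c=1.0, s=1.0, T=1.1)


class TestUncertainty:
    def test_study_budget(self):
        """5.0% energy response and 3.0% angular response combine to 5.8%."""
        b = d.combined_uncertainty(5.0, 3.0)
        assert b.display == 5.8
        assert b.combined == pytest.approx(np.sqrt(34), rel=1e-12)

    def test_single_zero(self):
        assert d.combined_uncertainty(0.0).combined == 0.0

    def test_pythagorean_triple(self):
        assert d.combined_uncertainty(3.0, 4.0).combined == pytest.approx(5.0)

    def test_permutation_invariance_and_monotonicity(self):
        assert d.combined_uncertainty(2, 5, 3).combined == pytest.approx(
            d.combined_uncertainty(5, 3, 2).combined)
        assert d.combined_uncertainty(5, 3.5).combined > \
            d.combined_uncertainty(5, 3).combined

    def test_combined_at_least_max_component(self):
        b = d.combined_uncertainty(1.0, 7.0, 2.0)
        assert b.combined >= 7.0

    def test_negative_component(self):
        with pytest.raises(ValueError):
            d.combined_uncertainty(5.0, -1.0)


class TestPercentDifference:
    def test_zero(self):
        assert d.percent_difference(1.0, 1.0) == 0.0

    def test_hand_value(self):
        assert d.percent_difference(1.042, 1.0) == pytest.approx(4.2)

    def test_antisymmetry_identity(self):
        # algebraic identity: pd(a,b) = -pd(b,a) * (a/b)
        a, b = 1.3, 0.9
        assert d.percent_difference(a, b) == pytest.approx(
            -d.percent_difference(b, a) * (a / b), rel=1e-12)

    def test_zero_reference(self):
        with pytest.raises(ValueError):
            d.percent_difference(1.0, 0.0)


def test_full_chain_consistency():
    """ESAK -> /BSF -> x g c s T reproduces the direct formula exactly."""
    f = d.get_factors(28)
    esak, bsf = 2.0, 1.079
    K = d.incident_kerma_from_esak(esak, bsf)
    agd = d.compute_agd(K, f, "3D").AGD
    assert agd == pytest.approx(esak / bsf * f.g * f.c * f.s * f.T, rel=1e-14)
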