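"""Tube spectrum model: filtration algebra, air kerma, HVL and heel."""
import numpy as np
import pytest

from dbtdose import spectrum as sp
from dbtdose.physics_data import get_table


class TestGeneration:
    def test_duane_hunt_limit(self):
        s = sp.generate_spectrum(25, filtration=[])
        assert np.all(s.fluence[s.energies >= 25.0] == 0)
        assert s.bin_edges[-1] == 25.0

    def test_normalized_and_positive(self, spectrum28):
        assert spectrum28.fluence.sum() == pytest.approx(1.0)
        assert np.all(spectrum28.fluence >= 0)

    def test_unsupported_anode(self):
        with pytest.raises(ValueError, match="anode"):
            sp.generate_spectrum(28, anode="Mo")

    def test_kvp_range(self):
        with pytest.raises(ValueError):
            sp.generate_spectrum(45)


class TestFiltration:
    def test_zero_thickness_identity(self, spectrum28):
        out = sp.filter_spectrum(spectrum28, "Al", 0.0)
        assert np.array_equal(out.fluence, spectrum28.fluence)

    def test_halving_thickness_single_bin(self, mono20):
        """A monoenergetic bin is halved by t = ln2 / mu."""
        mu_lin = get_table("Al").linear_mu(20.125)  # bin midpoint energy
        t_half_mm = 10.0 * np.log(2) / mu_lin
        out = sp.filter_spectrum(mono20, "Al", t_half_mm)
        assert out.fluence.sum() == pytest.approx(0.5 * mono20.fluence.sum(),
                                                  rel=1e-6)

    def test_filter_additivity(self, spectrum28):
        one = sp.filter_spectrum(spectrum28, "Al", 0.7)
        two = sp.filter_spectrum(sp.filter_spectrum(spectrum28, "Al", 0.3),
                                 "Al", 0.4)
        assert np.allclose(one.fluence, two.fluence, rtol=1e-12)

    def test_negative_thickness(self, spectrum28):
        with pytest.raises(ValueError):
            sp.filter_spectrum(spectrum28, "Al", -0.1)


class TestAirKerma:
    def test_linearity(self, spectrum28):
        doubled = sp.EnergySpectrum(spectrum28.kvp, spectrum28.bin_edges,
                                    2 * spectrum28.fluence)
        assert sp.air_kerma(doubled) == pytest.approx(
            2 * sp.air_kerma(spectrum28), rel=1e-12)

    def test_two_bin_hand_sum(self):
        edges = 1.0 + 0.25 * np.arange(97)
        fl = np.zeros(96)
        i1, i2 = 40, 80
        fl[i1], fl[i2] = 2.0, 3.0
        s = sp.EnergySpectrum(25.0, edges, fl)
        air = get_table("air")
        e1 = 0.5 * (edges[i1] + edges[i1 + 1])
        e2 = 0.5 * (edges[i2] + edges[i2 + 1])
        expected = (2.0 * e1 * air.mu(e1, "energy_absorption")
                    + 3.0 * e2 * air.mu(e2, "energy_absorption"))
        assert sp.air_kerma(s) == pytest.approx(expected, rel=1e-12)


class TestHVL:
    def test_monoenergetic_closed_form(self, mono20):
        mu_lin = get_table("Al").linear_mu(20.125)
        assert sp.compute_hvl(mono20) == pytest.approx(
            10.0 * np.log(2) / mu_lin, abs=2e-4)

    def test_hvl_round_trip(self, spectrum28):
        """Filtering by the computed HVL thickness halves the air kerma."""
        hvl = sp.compute_hvl(spectrum28)
        k = sp.air_kerma(sp.filter_spectrum(spectrum28, "Al", hvl))
        assert k == pytest.approx(0.5 * sp.air_kerma(spectrum28), rel=5e-3)

    def test_hvl_monotone_in_kvp(self, spectrum25, spectrum28, spectrum34):
        h = [sp.compute_hvl(s) for s in (spectrum25, spectrum28, spectrum34)]
        assert h[0] < h[1] < h[2]

    def test_reference_anchor(self, spectrum28):
        """The inherent filtration is tuned so the 28 kV beam reproduces
        the system's measured half-value layer."""
        assert sp.compute_hvl(spectrum28) == pytest.approx(
            sp.HVL_REFERENCE_MM_AL, abs=2e-3)

    def test_beam_hardening(self, spectrum28):
        harder = sp.filter_spectrum(spectrum28, "Al", 1.0)
        assert sp.mean_energy(harder) > sp.mean_energy(spectrum28)

    def test_quarter_value_layer_inequality(self, spectrum28):
        """For a polyenergetic beam the quarter-value layer exceeds twice
        the HVL (hardening); equality holds only for monoenergetic."""
        hvl = sp.compute_hvl(spectrum28)
        k0 = sp.air_kerma(spectrum28)
        k2 = sp.air_kerma(sp.filter_spectrum(spectrum28, "Al", 2 * hvl))
        assert k2 > 0.25 * k0


class TestHeel:
    def test_edges_and_midpoint(self):
        h = sp.HeelModel(endpoint_ratio=0.85)
        assert sp.heel_weight(h, 0.0) == pytest.approx(1.0)
        assert sp.heel_weight(h, 1.0) == pytest.approx(0.85)
        assert sp.heel_weight(h, 0.5) == pytest.approx((1 + 0.85) / 2)

    def test_outside_field(self):
        with pytest.raises(ValueError):
            sp.heel_weight(sp.HeelModel(), 1.2)

    def test_ratio_validation(self):
        with pytest.raises(ValueError):
            sp.HeelModel(endpoint_ratio=1.3)


def test_spectrum_file_round_trip(tmp_path, spectrum28):
    path = tmp_path / "spec.txt"
    sp.write_spectrum(spectrum28, path)
    back = sp.read_spectrum(path)
    assert back.kvp == spectrum28.kvp
    assert np.allclose(back.fluence, spectrum28.fluence, rtol=1e-6)
    assert back.filtration == spectrum28.filtration
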