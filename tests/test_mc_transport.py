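"""Monte Carlo engine: samplers against closed forms, geometry, estimator
consistency, determinism and energy bookkeeping."""
import numpy as np
import pytest

from dbtdose import mc_transport as mc
from dbtdose import spectrum as sp
from dbtdose.physics_data import get_table


def small_run(scene, n=20_000, seed=5, **kw):
    return mc.run_projection(scene, n_photons=n, n_batches=4, seed=seed, **kw)


class TestGeometry:
    def test_rectangle_solid_angle_vs_quadrature(self):
        point = np.array([3.0, -2.0, 50.0])
        rect = (-10.0, 10.0, 0.0, 16.5)
        exact = mc.rectangle_solid_angle(point, rect)
        xs = np.linspace(rect[0], rect[1], 400)
        ys = np.linspace(rect[2], rect[3], 400)
        X, Y = np.meshgrid(xs, ys)
        r2 = (X - point[0])**2 + (Y - point[1])**2 + point[2]**2
        quad = np.trapezoid(np.trapezoid(point[2] / r2**1.5, xs, axis=1), ys)
        assert exact == pytest.approx(quad, rel=1e-4)

    def test_focal_spot_rotation(self):
        g = mc.BeamGeometry()
        assert np.allclose(g.focal_spot, [0, 0, 65.0])
        g25 = g.with_angle(25.0)
        radius = 61.0
        assert g25.focal_spot[0] == pytest.approx(-radius * np.sin(np.deg2rad(25)))
        assert g25.focal_spot[1] == 0.0
        # focal stays on the rotation circle
        centre = np.array([0, 0, 4.0])
        assert np.linalg.norm(g25.focal_spot - centre) == pytest.approx(radius)

    def test_default_layout_numbering(self):
        discs = mc.default_disc_layout(4.0)
        assert len(discs) == 20
        dot8 = discs[7]
        assert (dot8.id, dot8.x, dot8.y) == (8, 0.0, 6.0)
        assert not any(
            np.hypot(a.x - b.x, a.y - b.y) < a.radius + b.radius
            for i, a in enumerate(discs) for b in discs[i + 1:])

    def test_layout_file_round_trip(self, tmp_path):
        discs = mc.default_disc_layout(2.0)
        path = tmp_path / "layout.tsv"
        mc.save_disc_layout(discs, path)
        back = mc.load_disc_layout(path, 2.0)
        assert [(d.id, d.x, d.y) for d in back] == \
            [(d.id, d.x, d.y) for d in discs]


class TestSource:
    def test_energy_histogram_matches_spectrum(self, spectrum28, rng):
        n = 100_000
        _, _, e, _ = mc.sample_source_photons(
            spectrum28, mc.BeamGeometry(), sp.HeelModel(), rng, n)
        counts, _ = np.histogram(e, bins=spectrum28.bin_edges)
        expect = spectrum28.fluence / spectrum28.fluence.sum() * n
        mask = expect > 50
        sigma = np.sqrt(expect[mask])
        assert np.all(np.abs(counts[mask] - expect[mask]) < 5 * sigma)
        # and the coarse 3-sigma check on broad quartile bins
        q = np.quantile(e, [0.25, 0.5, 0.75])
        assert q[0] < q[1] < q[2]

    def test_heel_disabled_unit_weights(self, spectrum28, rng):
        _, _, _, w = mc.sample_source_photons(
            spectrum28, mc.BeamGeometry(), sp.HeelModel(endpoint_ratio=1.0),
            rng, 5_000)
        assert np.all(w == 1.0)

    def test_rays_hit_field(self, spectrum28, rng):
        geo = mc.BeamGeometry()
        pos, dirs, _, _ = mc.sample_source_photons(
            spectrum28, geo, sp.HeelModel(), rng, 5_000)
        t = -pos[:, 2] / dirs[:, 2]
        hit = pos + dirs * t[:, None]
        x_lo, x_hi, y_lo, y_hi = geo.field
        assert np.all((hit[:, 0] >= x_lo - 1e-9) & (hit[:, 0] <= x_hi + 1e-9))
        assert np.all((hit[:, 1] >= y_lo - 1e-9) & (hit[:, 1] <= y_hi + 1e-9))


class TestCompton:
    def test_sampler_matches_quadrature_deciles(self, rng):
        """Sampled scattered-energy distribution at 30 keV agrees with a
        brute-force quadrature of the Klein-Nishina cross section."""
        e0 = 30.0
        k = e0 / mc.MEC2
        n = 200_000
        _, e_out = mc.sample_compton(e0, n, rng)
        eps = np.linspace(1 / (1 + 2 * k), 1.0, 4001)
        cos = 1.0 - (1.0 / eps - 1.0) / k
        pdf = eps + 1.0 / eps - (1.0 - cos**2)  # d sigma / d eps, unnormalized
        cdf = np.concatenate([[0], np.cumsum(0.5 * (pdf[1:] + pdf[:-1])
                                             * np.diff(eps))])
        cdf /= cdf[-1]
        deciles = np.interp(np.linspace(0.1, 0.9, 9), cdf, eps) * e0
        counts, _ = np.histogram(e_out, bins=np.concatenate(
            [[0], deciles, [e0]]))
        expect = n / 10
        assert np.all(np.abs(counts - expect) < 3 * np.sqrt(expect * 0.9) + 1)

    def test_energy_shift_consistency(self, rng):
        e0 = 25.0
        cos, e_out = mc.sample_compton(e0, 50_000, rng)
        k = e0 / mc.MEC2
        assert np.allclose(e_out, e0 / (1 + k * (1 - cos)), rtol=1e-12)
        assert e_out.min() >= e0 / (1 + 2 * k) - 1e-9

    def test_kn_total_cross_section_low_energy_limit(self):
        # reduced sigma / (2 pi re^2) -> 4/3 (Thomson) as k -> 0
        assert mc.sigma_kn_reduced(np.array([1e-3]))[0] == pytest.approx(
            4.0 / 3.0, rel=3e-3)
        # and matches direct quadrature of the differential form at 30 keV
        k = 30.0 / mc.MEC2
        c = np.linspace(-1, 1, 20001)
        eps = 1 / (1 + k * (1 - c))
        d_kn = 0.5 * eps**2 * (eps + 1 / eps - 1 + c * c)
        quad = 2 * np.pi * np.trapezoid(d_kn, c) / (2 * np.pi)
        assert mc.sigma_kn_reduced(np.array([k]))[0] == pytest.approx(
            quad, rel=1e-6)


class TestCoherent:
    def test_forward_peaked_and_bounded(self, rng):
        cos = mc.sample_coherent_angle("pmma", 20.0, 20_000, rng)
        assert np.all((cos >= -1) & (cos <= 1))
        assert np.mean(cos) > 0.5  # strongly forward at mammographic energies

    def test_harder_photons_scatter_more_forward(self, rng):
        c15 = np.mean(mc.sample_coherent_angle("pmma", 15.0, 20_000, rng))
        c35 = np.mean(mc.sample_coherent_angle("pmma", 35.0, 20_000, rng))
        assert c35 > c15


class TestTransport:
    def test_vacuum_straight_line(self, spectrum28):
        scene = mc.Scene(spectrum28, phantom=mc.PhantomStack(4.0),
                         physics=mc.ScenePhysics(vacuum=True,
                                                 estimator="analog"))
        res = small_run(scene, n=5_000, keep_ledger=True)
        led = res.energy_ledger
        assert np.all(led["deposited"] == 0)
        assert np.allclose(led["escaped"], led["injected"])

    def test_exponential_attenuation_scatter_off(self, mono20):
        """With scattering disabled every interaction absorbs, so a pencil
        beam crossing the slab survives with probability exp(-mu t)."""
        t_cm = 2.0
        scene = mc.Scene(mono20, phantom=mc.PhantomStack(t_cm),
                         support_thickness=0.0,
                         physics=mc.ScenePhysics(scatter=False,
                                                 estimator="analog"))
        engine = mc._Engine(scene)
        n = 40_000
        rng = np.random.default_rng(3)
        pos = np.tile([0.0, 6.0, 30.0], (n, 1))
        dirs = np.tile([0.0, 0.0, -1.0], (n, 1))
        e = np.full(n, 20.0)
        w = np.ones(n)
        acc = np.zeros(20)
        ev = np.zeros(20, dtype=np.int64)
        led = mc.transport_photons(engine, pos, dirs, e, w, rng, acc, ev)
        survived = int((led["escaped"] > 0).sum())
        mu_pmma = get_table("pmma").linear_mu(20.0)
        mu_air = get_table("air").linear_mu(20.0)
        p = np.exp(-mu_pmma * t_cm - mu_air * 28.0)  # 28 cm of air to exit
        sigma = np.sqrt(n * p * (1 - p))
        assert abs(survived - n * p) < 3 * sigma

    def test_energy_conservation_per_history(self, scene4):
        res = small_run(scene4, n=20_000, keep_ledger=True)
        led = res.energy_ledger
        total = led["deposited"] + led["escaped"] + led["cutoff"]
        assert np.allclose(total, led["injected"], rtol=1e-12, atol=1e-9)

    def test_determinism_same_seed(self, scene4):
        r1 = small_run(scene4, n=10_000, seed=42)
        r2 = small_run(scene4, n=10_000, seed=42)
        assert np.array_equal(r1.kerma, r2.kerma)
        assert np.array_equal(r1.batch_se, r2.batch_se)

    def test_inverse_square(self, mono20):
        """Free-in-air kerma at two disc heights follows 1/r^2 (vacuum,
        analog track-length tally)."""
        discs_near = [mc.DosimeterDisc(1, 0.0, 3.0, 45.0)]
        discs_far = [mc.DosimeterDisc(1, 0.0, 3.0, 25.0)]
        phys = mc.ScenePhysics(vacuum=True, estimator="analog")
        flat = sp.HeelModel(endpoint_ratio=1.0)  # no heel: pure 1/r^2
        k = {}
        for tag, discs in (("near", discs_near), ("far", discs_far)):
            scene = mc.Scene(mono20, heel=flat, discs=discs,
                             support_thickness=0.0,
                             physics=phys, disc_surface_z=discs[0].z)
            res = mc.run_projection(scene, n_photons=400_000, n_batches=4,
                                    seed=9)
            k[tag] = (res.kerma[0], res.batch_se[0])
        r_near = np.hypot(3.0, 65.0 - 45.01)
        r_far = np.hypot(3.0, 65.0 - 25.01)
        expected = (r_far / r_near) ** 2
        ratio = k["near"][0] / k["far"][0]
        sigma = ratio * np.hypot(k["near"][1] / k["near"][0],
                                 k["far"][1] / k["far"][0])
        assert abs(ratio - expected) < max(3 * sigma, 0.02 * expected)

    def test_estimator_consistency_nee_vs_analog(self, scene2):
        """The default estimator (deterministic primary + next-event
        scatter) agrees with the analog track-length oracle."""
        analog_scene = mc.Scene(scene2.spectrum, scene2.geometry, scene2.heel,
                                scene2.phantom, list(scene2.discs),
                                physics=mc.ScenePhysics(estimator="analog"))
        r_nee = mc.run_projection(scene2, n_photons=100_000, n_batches=5,
                                  seed=21)
        r_an = mc.run_projection(analog_scene, n_photons=1_000_000,
                                 n_batches=5, seed=22)
        total_ratio = r_nee.kerma.sum() / r_an.kerma.sum()
        assert total_ratio == pytest.approx(1.0, abs=0.03)

    def test_variance_scales_with_photons(self, scene4):
        r1 = mc.run_projection(scene4, n_photons=20_000, n_batches=10, seed=6)
        r4 = mc.run_projection(scene4, n_photons=80_000, n_batches=10, seed=6)
        s1 = np.median(r1.rel_uncertainty)
        s4 = np.median(r4.rel_uncertainty)
        assert s4 < s1  # 1/sqrt(n): expect about half, allow wide noise
        assert s4 > s1 / 6

    def test_photon_and_batch_minimums(self, scene4):
        with pytest.raises(ValueError):
            mc.run_projection(scene4, n_photons=10)
        with pytest.raises(ValueError):
            mc.run_projection(scene4, n_photons=2_000, n_batches=1)


class TestTally:
    def test_tally_kerma_closed_form(self):
        disc = mc.DosimeterDisc(1, 0.0, 6.0, 4.0)
        muen = get_table("al2o3").mu(20.0, "energy_absorption")
        expected = 1.0 * disc.thickness * 20.0 * muen / disc.volume
        got = mc.tally_kerma(disc.thickness, 20.0, 1.0, disc)
        assert got == pytest.approx(expected, rel=1e-12)
        assert mc.tally_kerma(0.0, 20.0, 1.0, disc) == 0.0
        with pytest.raises(ValueError):
            mc.tally_kerma(-0.1, 20.0, 1.0, disc)

    def test_single_perpendicular_crossing(self, mono20):
        """A photon fired straight down through a disc centre records one
        crossing with the full disc thickness."""
        scene = mc.Scene(mono20, phantom=mc.PhantomStack(4.0),
                         physics=mc.ScenePhysics(vacuum=True))
        crossings = mc.transport_photon(scene, [0.0, 6.0, 30.0],
                                        [0.0, 0.0, -1.0], 20.0)
        assert len(crossings) == 1
        disc_id, length, energy, weight = crossings[0]
        assert disc_id == 8
        assert length == pytest.approx(0.02, rel=1e-6)
        assert energy == 20.0 and weight == 1.0

    def test_miss_records_nothing(self, mono20):
        scene = mc.Scene(mono20, physics=mc.ScenePhysics(vacuum=True))
        crossings = mc.transport_photon(scene, [2.0, 8.0, 30.0],
                                        [0.0, 0.0, -1.0], 20.0)
        assert crossings == []

    def test_zero_event_flagging(self, mono20):
        """A disc that never tallies is flagged, not reported as a
        converged zero."""
        scene = mc.Scene(mono20, physics=mc.ScenePhysics(
            vacuum=True, estimator="analog"))
        res = mc.run_projection(scene, n_photons=2_000, n_batches=2, seed=1)
        lonely = res.zero_event_discs
        assert np.all(~res.converged[np.isin(res.disc_ids, lonely)])
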