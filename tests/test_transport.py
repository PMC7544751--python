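import numpy as np
import pytest
from scipy import integrate, stats

from handdose.constants import ANNIHILATION_PHOTON_MEV, ELECTRON_REST_MEV
from handdose.geometry import Box, Region, SceneGeometry
from handdose.materials import get_material, lookup_mu
from handdose.source import NuclideSpec
from handdose.transport import (
    DoseTally,
    Photon,
    TransportSettings,
    compton_scattered_energy,
    rotate_directions,
    run_histories,
    sample_compton,
    step_interaction,
    transport_batch,
)

AIR = get_material("air")
WATER = get_material("water")
TUNGSTEN = get_material("tungsten")


def scene_of(*extra_regions, world_material=AIR, world_side=100.0):
    world = Region(
        "world", Box((0, 0, 0), (world_side,) * 3), world_material
    )
    return SceneGeometry([world, *extra_regions])


def launch(scene, origins, directions, energies, settings, seed=1):
    n = len(energies)
    deposits = np.zeros((n, len(scene.regions)))
    escaped = np.zeros(n)
    transport_batch(
        origins=origins,
        directions=directions,
        energies=np.asarray(energies, dtype=float),
        history_ids=np.arange(n),
        scene=scene,
        settings=settings,
        rng=np.random.default_rng(seed),
        deposits=deposits,
        escaped=escaped,
    )
    return deposits, escaped


class TestComptonKinematics:
    def test_backscatter_closed_form(self):
        # at E = m_e c^2, a 180-degree scatter leaves exactly E/3
        e = compton_scattered_energy(ELECTRON_REST_MEV, -1.0)
        assert e == pytest.approx(ELECTRON_REST_MEV / 3.0, rel=1e-12)
        assert e == pytest.approx(0.1703, abs=5e-5)

    def test_sampled_pairs_satisfy_kinematic_identity(self, rng):
        e0 = np.full(20_000, ANNIHILATION_PHOTON_MEV)
        e_sc, cos_t = sample_compton(rng, e0)
        np.testing.assert_allclose(
            e_sc, compton_scattered_energy(e0, cos_t), rtol=1e-12
        )
        assert np.all(e_sc <= e0)
        assert np.all(e_sc >= e0 / (1 + 2 * e0 / ELECTRON_REST_MEV))

    def test_klein_nishina_goodness_of_fit(self, rng):
        # oracle: numerically integrated KN density in cos(theta)
        k = ANNIHILATION_PHOTON_MEV / ELECTRON_REST_MEV

        def kn(c):
            r = 1.0 / (1.0 + k * (1.0 - c))
            return r * r * (r + 1.0 / r - (1.0 - c * c))

        grid = np.linspace(-1, 1, 4001)
        pdf = kn(grid)
        cdf = np.concatenate([[0.0], np.cumsum((pdf[1:] + pdf[:-1]) / 2)])
        cdf /= cdf[-1]
        _, cos_t = sample_compton(
            rng, np.full(100_000, ANNIHILATION_PHOTON_MEV)
        )
        res = stats.kstest(cos_t, lambda x: np.interp(x, grid, cdf))
        assert res.pvalue > 0.01


class TestStepInteraction:
    def test_energy_balance_every_channel(self, rng):
        settings = TransportSettings()
        for _ in range(300):
            p = Photon(np.zeros(3), np.array([0, 0, 1.0]),
                       ANNIHILATION_PHOTON_MEV)
            new, dep = step_interaction(p, WATER, rng, settings)
            assert dep >= 0
            total = dep + (new.energy_mev if new.alive else 0.0)
            assert total == pytest.approx(ANNIHILATION_PHOTON_MEV,
                                          rel=1e-12)
            if new.alive:
                assert np.linalg.norm(new.direction) == pytest.approx(1.0)

    def test_channel_fractions_match_mu_ratio(self, rng):
        # at 30 keV in tungsten the photoelectric channel dominates per
        # the embedded tables; observed kill fraction matches mu ratio
        e = 0.03
        mu_pe = TUNGSTEN.mu(e, "photoelectric")
        mu_tot = mu_pe + TUNGSTEN.mu(e, "incoherent")
        p_pe = mu_pe / mu_tot
        n = 4000
        kills = 0
        for _ in range(n):
            p = Photon(np.zeros(3), np.array([0, 0, 1.0]), e)
            new, dep = step_interaction(p, TUNGSTEN, rng)
            if not new.alive and dep == pytest.approx(e):
                kills += 1
        sd = np.sqrt(p_pe * (1 - p_pe) / n)
        # photoelectric kills plus sub-cutoff Compton kills: bound below
        assert kills / n >= p_pe - 4 * sd

    def test_dead_photon_rejected(self, rng):
        p = Photon(np.zeros(3), np.array([0, 0, 1.0]), 0.5, alive=False)
        with pytest.raises(ValueError):
            step_interaction(p, WATER, rng)


class TestRotation:
    def test_rotation_preserves_norm_and_angle(self, rng):
        d = np.array([[0.0, 0.6, 0.8], [0.0, 0.0, 1.0], [1.0, 0.0, 0.0]])
        cos_t = np.array([0.3, -0.7, 0.99])
        out = rotate_directions(d, cos_t, rng.random(3) * 2 * np.pi)
        np.testing.assert_allclose(np.linalg.norm(out, axis=1), 1.0,
                                   atol=1e-12)
        np.testing.assert_allclose(np.sum(out * d, axis=1), cos_t,
                                   atol=1e-9)


class TestTransportBatch:
    def test_no_interaction_limit_zero_deposit(self):
        scene = scene_of()
        settings = TransportSettings(interactions_enabled=False)
        deposits, escaped = launch(
            scene,
            np.zeros((100, 3)),
            np.tile([0, 0, 1.0], (100, 1)),
            np.full(100, ANNIHILATION_PHOTON_MEV),
            settings,
        )
        assert deposits.sum() == 0.0
        np.testing.assert_allclose(escaped, ANNIHILATION_PHOTON_MEV)

    def test_free_path_exponential_in_water_world(self):
        # fraction of photons with zero deposit equals the analytic
        # no-interaction probability over the 50 cm to the wall
        scene = scene_of(world_material=WATER)
        n = 100_000
        deposits, _ = launch(
            scene,
            np.zeros((n, 3)),
            np.tile([0, 0, 1.0], (n, 1)),
            np.full(n, ANNIHILATION_PHOTON_MEV),
            TransportSettings(),
            seed=3,
        )
        virgin = (deposits.sum(axis=1) == 0.0).mean()
        mu = lookup_mu("water", ANNIHILATION_PHOTON_MEV)
        expected = np.exp(-mu * 50.0)
        sd = np.sqrt(expected * (1 - expected) / n)
        assert abs(virgin - expected) < 3 * sd

    def test_tungsten_slab_narrow_beam_transmission(self):
        # 9 mm tungsten slab; unscattered fraction = exp(-mu t) with the
        # residual air path folded into the analytic oracle
        slab = Region(
            "slab", Box((0, 0, 5.0), (20.0, 20.0, 0.9)), TUNGSTEN
        )
        scene = scene_of(slab)
        n = 60_000
        deposits, _ = launch(
            scene,
            np.zeros((n, 3)),
            np.tile([0, 0, 1.0], (n, 1)),
            np.full(n, ANNIHILATION_PHOTON_MEV),
            TransportSettings(),
            seed=4,
        )
        virgin = (deposits.sum(axis=1) == 0.0).mean()
        mu_w = lookup_mu("tungsten", ANNIHILATION_PHOTON_MEV)
        mu_air = lookup_mu("air", ANNIHILATION_PHOTON_MEV)
        expected = np.exp(-mu_w * 0.9 - mu_air * 49.1)
        sd = np.sqrt(expected * (1 - expected) / n)
        assert abs(virgin - expected) < 3 * sd


class TestRunHistories:
    def test_zero_decays_all_zero_tally(self, default_scene):
        tally = run_histories(0, default_scene, seed=1)
        assert tally.histories == 0
        assert tally.edep_mev.sum() == 0.0

    def test_energy_conservation_per_history(self, default_scene):
        tally, (deposits, escaped, emitted) = run_histories(
            5000, default_scene, seed=5, return_history_detail=True
        )
        np.testing.assert_allclose(
            deposits.sum(axis=1) + escaped, emitted, rtol=0, atol=1e-9
        )
        assert tally.aborted_histories == 0

    def test_total_deposit_bounded_by_emission(self, default_scene):
        n = 3000
        tally, (_, _, emitted) = run_histories(
            n, default_scene, seed=6, return_history_detail=True
        )
        assert tally.edep_mev.sum() <= emitted.sum() + 1e-9

    def test_same_seed_bit_identical(self, default_scene):
        a = run_histories(2000, default_scene, seed=7)
        b = run_histories(2000, default_scene, seed=7)
        np.testing.assert_array_equal(a.edep_mev, b.edep_mev)
        np.testing.assert_array_equal(a.edep_sq_mev2, b.edep_sq_mev2)
        assert a.escaped_mev == b.escaped_mev

    def test_independent_seeds_agree_within_3_sigma(self, default_scene):
        n = 100_000
        a = run_histories(n, default_scene, seed=11)
        b = run_histories(n, default_scene, seed=12)
        sig = np.sqrt(a.sigma_mev() ** 2 + b.sigma_mev() ** 2)
        for region in ("index_distal", "middle_distal", "ring_distal",
                       "pastern"):
            i = a.index(region)
            diff = abs(a.mean_mev()[i] - b.mean_mev()[i])
            assert diff < 3.0 * sig[i], region

    def test_tally_merge_matches_combined_run(self, default_scene):
        a = run_histories(1500, default_scene, seed=8)
        b = run_histories(2500, default_scene, seed=9)
        merged = a.merge(b)
        assert merged.histories == 4000
        np.testing.assert_allclose(
            merged.edep_mev, a.edep_mev + b.edep_mev
        )
        np.testing.assert_allclose(
            merged.edep_sq_mev2, a.edep_sq_mev2 + b.edep_sq_mev2
        )


class TestInvariantChecks:
    def test_inverse_square_in_air(self):
        # isotropic point source; tissue cubes at 10 and 20 cm
        tissue = get_material("soft_tissue")
        near = Region(
            "near", Box((10.0, 0, 0), (2.0, 2.0, 2.0)), tissue, scoring=True
        )
        far = Region(
            "far", Box((20.0, 0, 0), (2.0, 2.0, 2.0)), tissue, scoring=True
        )
        scene = scene_of(near, far, world_side=60.0)
        n = 400_000
        rng = np.random.default_rng(13)
        mu_iso = 2 * rng.random(n) - 1
        phi = 2 * np.pi * rng.random(n)
        s = np.sqrt(1 - mu_iso**2)
        dirs = np.column_stack(
            [s * np.cos(phi), s * np.sin(phi), mu_iso]
        )
        deposits, _ = launch(
            scene,
            np.zeros((n, 3)),
            dirs,
            np.full(n, ANNIHILATION_PHOTON_MEV),
            TransportSettings(),
            seed=14,
        )
        i_near = [r.name for r in scene.regions].index("near")
        i_far = [r.name for r in scene.regions].index("far")
        e_near = deposits[:, i_near]
        e_far = deposits[:, i_far]
        ratio = e_near.sum() / e_far.sum()
        rel = np.sqrt(
            e_near.std() ** 2 / (n * e_near.mean() ** 2)
            + e_far.std() ** 2 / (n * e_far.mean() ** 2)
        )
        assert abs(ratio - 4.0) < 3.0 * 4.0 * rel

    def test_linearity_of_total_deposit(self, default_scene):
        ns = [2000, 10_000, 50_000]
        totals = [
            run_histories(n, default_scene, seed=20 + i).edep_mev.sum()
            for i, n in enumerate(ns)
        ]
        fit = stats.linregress(ns, totals)
        assert fit.rvalue**2 >= 0.999

    def test_settings_invariants(self):
        with pytest.raises(ValueError):
            TransportSettings(energy_cutoff_mev=0.5)
        with pytest.raises(ValueError):
            TransportSettings(max_crossings=0)

    def test_tally_block_shape_guard(self):
        tally = DoseTally.empty(["a", "b"])
        with pytest.raises(ValueError):
            tally.add_history_block(np.zeros((3, 5)))
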