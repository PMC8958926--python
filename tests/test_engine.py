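"""Agent traits, the migration rule, and the simulation loop."""

import numpy as np
import pytest
from scipy import stats

from nscmigrate.chemo import ChemoField, TumorSite
from nscmigrate.engine import (SimulationConfig, initialize, migration_step,
                               random_unit_vector, run,
                               sample_sensitivity_factor, sample_speed_factor)
from nscmigrate.field import TissueField


def _flat_tissue(shape=(64, 64), white=False, direction=(1.0, 0.0)):
    """Hand-built tissue field: all white (one direction) or all grey."""
    d = len(shape)
    aniso = np.full(shape, 0.9 if white else 0.0)
    wm = np.full(shape, white, dtype=bool)
    dirs = np.zeros(shape + (d,))
    dirs[...] = np.asarray(direction)
    return TissueField(anisotropy=aniso, wm_mask=wm, direction=dirs,
                       epsilon_M=0.4, pixel_size=1.0)


class TestSpeedFactor:
    def test_uniform_at_beta_one(self, rng):
        psi = sample_speed_factor(1.0, 100_000, rng)
        assert stats.kstest(psi, "uniform").pvalue > 0.01

    @pytest.mark.parametrize("beta_w", [1.0, 2.0, 4.0])
    def test_rescaled_mean_is_half(self, rng, beta_w):
        n = 100_000
        psi = sample_speed_factor(beta_w, n, rng)
        # Beta(1, b) scaled by (1+b)/2: var = b/((1+b)^2 (2+b)) * ((1+b)/2)^2
        se = np.sqrt(beta_w / (4 * (2 + beta_w)) / n)
        assert abs(psi.mean() - 0.5) < 3 * se

    def test_heavier_right_tail_and_lower_median_at_large_beta(self, rng):
        psi1 = sample_speed_factor(1.0, 100_000, rng)
        psi4 = sample_speed_factor(4.0, 100_000, rng)
        assert psi4.max() > 1.0 >= psi1.max()
        assert np.median(psi4) < np.median(psi1)

    def test_beta_below_one_rejected(self, rng):
        with pytest.raises(ValueError, match="beta_w"):
            sample_speed_factor(0.5, 10, rng)


class TestSensitivityFactor:
    def test_uniform_at_alpha_one(self, rng):
        eta = sample_sensitivity_factor(1.0, 100_000, rng)
        assert stats.kstest(eta, "uniform").pvalue > 0.01

    def test_mean_concentrates_near_one(self, rng):
        n = 100_000
        eta = sample_sensitivity_factor(50.0, n, rng)
        mean = 50 / 51
        se = np.sqrt(50 / (51 ** 2 * 52) / n)
        assert abs(eta.mean() - mean) < 3 * se
        assert np.all((eta >= 0) & (eta <= 1))

    def test_alpha_below_one_rejected(self, rng):
        with pytest.raises(ValueError, match="alpha_c"):
            sample_sensitivity_factor(0.2, 10, rng)


class TestRandomUnitVector:
    @pytest.mark.parametrize("dim", [2, 3])
    def test_unit_norm(self, rng, dim):
        v = random_unit_vector(dim, rng, 1000)
        assert np.allclose(np.linalg.norm(v, axis=1), 1.0, atol=1e-12)

    def test_2d_angles_uniform(self, rng):
        v = random_unit_vector(2, rng, 100_000)
        ang = np.arctan2(v[:, 1], v[:, 0]) + np.pi
        assert stats.kstest(ang, "uniform", args=(0, 2 * np.pi)).pvalue > 0.01

    def test_3d_component_means_vanish(self, rng):
        n = 100_000
        v = random_unit_vector(3, rng, n)
        assert np.all(np.abs(v.mean(axis=0)) < 3 / np.sqrt(n))

    def test_bad_dim(self, rng):
        with pytest.raises(ValueError):
            random_unit_vector(4, rng)


class TestInitialize:
    def test_radius_zero_stacks_agents_at_center(self):
        tissue = _flat_tissue()
        cfg = SimulationConfig(n_agents=50, injection_center=(30.0, 30.0),
                               injection_radius=0.0, seed=1)
        pop = initialize(cfg, tissue)
        assert np.all(pop.pos == [30.0, 30.0])
        assert np.all(pop.prev_pos == pop.pos)

    def test_positions_within_radius_and_brain(self):
        tissue = _flat_tissue()
        cfg = SimulationConfig(n_agents=500, injection_center=(30.0, 30.0),
                               injection_radius=12.0, seed=1)
        pop = initialize(cfg, tissue)
        assert np.all(np.linalg.norm(pop.pos - [30.0, 30.0], axis=1) <= 12.0)
        assert np.all((pop.speed_factor >= 0))
        assert np.all((pop.sens_factor >= 0) & (pop.sens_factor <= 1))

    def test_injection_outside_brain_raises(self, straight_phantom):
        _, _, tissue = straight_phantom
        cfg = SimulationConfig(n_agents=10, injection_center=(1.0, 1.0),
                               injection_radius=0.0, seed=1)
        with pytest.raises(ValueError, match="outside the brain"):
            initialize(cfg, tissue)


class TestMigrationStep:
    def test_grey_step_has_length_dg(self, rng):
        tissue = _flat_tissue(white=False)
        cfg = SimulationConfig(d_g=0.7, injection_center=(30.0, 30.0))
        disp = migration_step(np.array([[30.0, 30.0]]), np.array([[30.0, 30.0]]),
                              np.array([0.5]), np.array([0.5]),
                              tissue, None, cfg, rng)
        assert np.linalg.norm(disp[0]) == pytest.approx(0.7, abs=1e-12)

    @pytest.mark.parametrize("prev_disp, sign", [((0.3, 0.1), 1.0),
                                                 ((-0.3, 0.1), -1.0)])
    def test_white_step_follows_inertia_sign(self, rng, prev_disp, sign):
        tissue = _flat_tissue(white=True, direction=(1.0, 0.0))
        cfg = SimulationConfig(d_w=5.0, injection_center=(30.0, 30.0))
        pos = np.array([[30.0, 30.0]])
        disp = migration_step(pos, pos - np.array([prev_disp]),
                              np.array([0.6]), np.array([0.5]),
                              tissue, None, cfg, rng)
        assert np.allclose(disp[0], [sign * 5.0 * 0.6, 0.0])

    def test_chemo_term_vanishes_at_tumor_center(self, rng):
        tissue = _flat_tissue(white=False)
        cf = ChemoField([TumorSite(center=np.array([30.0, 30.0]),
                                   half_decay=10.0)])
        cfg = SimulationConfig(d_g=1.0, lambda_c=8.0,
                               injection_center=(30.0, 30.0))
        pos = np.array([[30.0, 30.0]])
        disp = migration_step(pos, pos, np.array([0.5]), np.array([1.0]),
                              tissue, cf, cfg, rng)
        assert np.linalg.norm(disp[0]) == pytest.approx(1.0, abs=1e-12)

    def test_chemo_gated_by_epsilon_c(self, rng):
        tissue = _flat_tissue(white=False)
        cf = ChemoField([TumorSite(center=np.array([30.0, 30.0]),
                                   half_decay=2.0)])
        # far away: C < eps_c, pure random step despite lambda_c
        cfg = SimulationConfig(d_g=1.0, lambda_c=50.0, epsilon_c=0.5,
                               injection_center=(30.0, 30.0))
        pos = np.array([[55.0, 30.0]])
        disp = migration_step(pos, pos, np.array([0.5]), np.array([1.0]),
                              tissue, cf, cfg, rng)
        assert np.linalg.norm(disp[0]) == pytest.approx(1.0, abs=1e-12)


class TestRun:
    def test_all_zero_speeds_freeze_population(self, straight_phantom):
        _, _, tissue = straight_phantom
        cfg = SimulationConfig(d_w=0.0, d_g=0.0, lambda_c=0.0, n_steps=50,
                               n_agents=40, injection_center=(45.0, 80.0),
                               injection_radius=5.0, seed=4)
        rec = run(cfg, tissue, None)
        assert np.all(rec.snapshots == rec.snapshots[0])
        assert np.all(rec.path_length == 0)

    def test_determinism_bitwise(self, near_scenario):
        cfg = near_scenario.config.replace(n_steps=300, n_agents=100, seed=9)
        r1 = run(cfg, near_scenario.tissue, near_scenario.chemo)
        r2 = run(cfg, near_scenario.tissue, near_scenario.chemo)
        assert np.array_equal(r1.snapshots, r2.snapshots)
        assert np.array_equal(r1.wm_count, r2.wm_count)
        assert np.array_equal(r1.arrival_counts, r2.arrival_counts)

    def test_step_displacement_bounded(self, near_scenario):
        cfg = near_scenario.config.replace(n_steps=200, n_agents=200, seed=5,
                                           snapshot_stride=1)
        rec = run(cfg, near_scenario.tissue, near_scenario.chemo)
        steps = np.diff(rec.snapshots, axis=0)
        norms = np.linalg.norm(steps, axis=-1)
        bound = max(cfg.d_w * rec.speed_factor.max(), cfg.d_g) + cfg.lambda_c
        assert np.max(norms) <= bound + 1e-9

    def test_arrival_monotone_and_conserved(self, near_scenario):
        cfg = near_scenario.config.replace(n_steps=600, n_agents=300, seed=6)
        rec = run(cfg, near_scenario.tissue, near_scenario.chemo)
        assert np.all(np.diff(rec.arrival_counts[:, 0]) >= 0)
        arrived = rec.arrived_step >= 0
        assert arrived.sum() + (~arrived).sum() == cfg.n_agents
        # path length cannot shrink and arrived agents stay arrived
        assert np.all(rec.path_length >= 0)

    def test_absorbed_agents_freeze(self, straight_phantom):
        _, _, tissue = straight_phantom
        cf = ChemoField([TumorSite(center=np.array([80.0, 80.0]),
                                   half_decay=30.0, arrival_radius_um=200.0)])
        cfg = SimulationConfig(d_w=3.0, d_g=3.0, lambda_c=0.0, n_steps=40,
                               n_agents=30, injection_center=(80.0, 80.0),
                               injection_radius=0.0, seed=2,
                               chemotaxis_absorb=True)
        rec = run(cfg, tissue, cf)
        # everyone starts inside the arrival disc and never moves again
        assert np.all(rec.arrived_step == 0)
        assert np.all(rec.snapshots == rec.snapshots[0])

    def test_dimension_mismatch_rejected(self, straight_phantom):
        _, _, tissue = straight_phantom
        cf = ChemoField([TumorSite(center=np.array([10.0, 10.0, 10.0]),
                                   half_decay=5.0)])
        cfg = SimulationConfig(n_steps=1, n_agents=2,
                               injection_center=(80.0, 80.0), seed=0)
        with pytest.raises(ValueError, match="dimension mismatch"):
            run(cfg, tissue, cf)

    def test_speed_stochasticity_fattens_distance_tail(self, no_tumor_scenario):
        """Larger beta_w yields more very-long-range migrators."""
        scen = no_tumor_scenario
        recs = {}
        for beta in (1.0, 4.0):
            cfg = scen.config.replace(beta_w=beta, n_steps=800, n_agents=600,
                                      seed=13)
            recs[beta] = run(cfg, scen.tissue, scen.chemo)
        pooled = np.concatenate([recs[1.0].path_length, recs[4.0].path_length])
        q = np.quantile(pooled, 0.95)
        assert (recs[4.0].path_length > q).sum() > (recs[1.0].path_length > q).sum()


class TestConfigValidation:
    @pytest.mark.parametrize("kw, key", [
        ({"beta_w": 0.5}, "beta_w"),
        ({"alpha_c": 0.0}, "alpha_c"),
        ({"d_w": -1.0}, "d_w"),
        ({"dt": 0.0}, "dt"),
        ({"epsilon_c": 1.0}, "epsilon_c"),
    ])
    def test_out_of_range_named(self, kw, key):
        with pytest.raises(ValueError, match=key):
            SimulationConfig(**kw).validate()
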