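import math

import numpy as np
import pytest

from forcemap import trajectory_io
from forcemap.bayes_core import PriorHyperparameters
from forcemap.simulators import (CrowdingSimConfig, OLESimConfig,
                                 TriangularProfile, expected_bayes_factor,
                                 simulate_crowding, simulate_ole,
                                 triangular_D)


def _flat_profile(D):
    return TriangularProfile(D_min=D, D_max=D + 1e-12, apex=0.5, period=1.0)


class TestTriangularProfile:
    def test_apex_gives_maximum(self):
        prof = TriangularProfile(D_min=0.05, D_max=0.3, apex=0.5)
        assert triangular_D(0.5, prof) == pytest.approx(0.3)

    def test_edges_give_minimum_periodically(self):
        prof = TriangularProfile(D_min=0.05, D_max=0.3, apex=0.5, period=1.0)
        assert triangular_D(0.0, prof) == pytest.approx(0.05)
        assert triangular_D(1.0, prof) == pytest.approx(0.05)

    def test_rising_branch_is_linear(self):
        prof = TriangularProfile(D_min=0.05, D_max=0.3, apex=0.5)
        assert triangular_D(0.25, prof) == pytest.approx((0.05 + 0.3) / 2)

    def test_slope_matches_finite_difference(self):
        prof = TriangularProfile()
        for x in (0.2, 0.7):
            fd = (prof.D(x + 1e-6) - prof.D(x - 1e-6)) / 2e-6
            assert prof.dD_dx(x) == pytest.approx(fd, rel=1e-6)


class TestSimulateOLE:
    @pytest.mark.filterwarnings("ignore:substep noise")
    def test_free_diffusion_moments(self):
        # free diffusion is exact at any step size; the coarse-substep
        # warning does not apply
        D = 0.2
        cfg = OLESimConfig(profile=_flat_profile(D), n_particles=100,
                           n_steps=1000, substeps=2, seed=9)
        ds = trajectory_io.to_displacements(simulate_ole(cfg))
        n = len(ds)
        assert n == 100000
        V = np.sum((ds.delta - ds.delta.mean(0)) ** 2) / n
        D_hat = V / (2 * 2 * cfg.dt)
        se = D * math.sqrt(2.0 / (n * 2))
        assert abs(D_hat - D) < 3 * se
        drift_se = math.sqrt(2 * D * cfg.dt / n) / cfg.dt
        assert np.all(np.abs(ds.delta.mean(0) / cfg.dt) < 3 * drift_se)

    @pytest.mark.filterwarnings("ignore:substep noise")
    def test_uniform_drift_recovered(self):
        cfg = OLESimConfig(profile=_flat_profile(0.1), total_drift=(0.5, 0.0),
                           n_particles=100, n_steps=500, substeps=2, seed=10)
        ds = trajectory_io.to_displacements(simulate_ole(cfg))
        drift = ds.delta.mean(0) / cfg.dt
        se = math.sqrt(2 * 0.1 * cfg.dt / len(ds)) / cfg.dt
        np.testing.assert_allclose(drift, [0.5, 0.0], atol=3 * se)

    def test_zero_steps_gives_single_frame_trajectories(self):
        cfg = OLESimConfig(n_particles=5, n_steps=0, seed=1)
        ts = simulate_ole(cfg)
        assert ts.n_records == 5
        assert len(trajectory_io.to_displacements(ts)) == 0

    def test_seeded_determinism(self):
        cfg = OLESimConfig(n_particles=7, n_steps=20, seed=123)
        a = simulate_ole(cfg).positions()
        b = simulate_ole(cfg).positions()
        np.testing.assert_array_equal(a, b)

    def test_convention_sensitivity(self):
        # the Itô–Stratonovich dilemma in action: with zero non-diffusive
        # force, λ_true = 1 walkers drift up the diffusivity gradient at
        # b∇b = ∇D, while λ_true = 0 walkers show no drift at all
        drifts = {}
        for lam in (0.0, 1.0):
            cfg = OLESimConfig(a=(0.0, 0.0), lambda_true=lam,
                               n_particles=300, n_steps=150, seed=77)
            ds = trajectory_io.to_displacements(simulate_ole(cfg))
            sel = (ds.start[:, 0] > 0.1) & (ds.start[:, 0] < 0.4)
            drifts[lam] = ds.delta[sel, 0].mean() / cfg.dt
            n_sel = sel.sum()
            d_bar = 0.175
            se = math.sqrt(2 * d_bar * cfg.dt / n_sel) / cfg.dt
        grad = (0.3 - 0.05) / 0.5   # ∇D on the rising branch [µm/s]
        assert abs(drifts[0.0]) < 3 * se
        assert abs(drifts[1.0] - grad) < 3 * se


class TestSimulateCrowding:
    def test_zero_radius_is_free_diffusion(self):
        cfg = CrowdingSimConfig(box=(2.0, 2.0), r_min=0.0, r_max=0.0,
                                n_particles=100, n_steps=200, substeps=2,
                                seed=4)
        ds = trajectory_io.to_displacements(simulate_crowding(cfg))
        V = np.sum((ds.delta - ds.delta.mean(0)) ** 2) / len(ds)
        D_hat = V / (2 * 2 * cfg.dt)
        se = cfg.D * math.sqrt(2.0 / (len(ds) * 2))
        assert abs(D_hat - cfg.D) < 3 * se

    def test_no_recorded_position_inside_a_bead(self):
        cfg = CrowdingSimConfig(box=(2.0, 2.0), r_min=0.03, r_max=0.045,
                                n_particles=50, n_steps=100, substeps=3,
                                seed=5)
        ts = simulate_crowding(cfg)
        pos = ts.positions()
        nearest = np.round(pos / cfg.pitch) * cfg.pitch
        radii = cfg.radius_at(np.mod(nearest[:, 0], cfg.box[0]))
        dist = np.linalg.norm(pos - nearest, axis=1)
        assert np.all(dist >= radii - 1e-12)

    def test_effective_diffusivity_decreases_with_bead_radius(self):
        cfg = CrowdingSimConfig(box=(3.0, 3.0), n_particles=150,
                                n_steps=250, substeps=3, seed=6)
        ds = trajectory_io.to_displacements(simulate_crowding(cfg))
        x = ds.start[:, 0]
        d_eff = []
        for lo, hi in ((0, 1.0), (1.0, 2.0), (2.0, 3.0)):
            sel = (x >= lo) & (x < hi)
            V = np.sum((ds.delta[sel] - ds.delta[sel].mean(0)) ** 2) \
                / sel.sum()
            d_eff.append(V / (2 * 2 * cfg.dt))
        assert d_eff[0] > d_eff[1] > d_eff[2]

    def test_overlapping_beads_rejected(self):
        with pytest.raises(ValueError):
            CrowdingSimConfig(r_max=0.06, pitch=0.1)

    def test_seeded_determinism(self):
        cfg = CrowdingSimConfig(box=(1.0, 1.0), n_particles=10, n_steps=20,
                                seed=11)
        np.testing.assert_array_equal(simulate_crowding(cfg).positions(),
                                      simulate_crowding(cfg).positions())


class TestExpectedBayesFactor:
    def test_null_bin_sits_at_the_analytic_floor(self):
        cfg = OLESimConfig(profile=_flat_profile(0.2))
        n = 200
        expected = expected_bayes_factor(cfg, 0.1, 0.2, n)
        floor = math.log10(3 / (n + 3))
        assert expected == pytest.approx(floor, abs=1e-9)

    def test_monotone_in_injected_residual(self):
        cfg0 = OLESimConfig()
        vals = [expected_bayes_factor(
            OLESimConfig(total_drift=(mag, 0.0)), 0.1, 0.2, 150)
            for mag in (1.0, 2.0, 4.0)]
        assert vals[0] < vals[1] < vals[2]

    def test_doubling_n_increases_evidence(self):
        cfg = OLESimConfig(total_drift=(1.0, 0.0))
        assert expected_bayes_factor(cfg, 0.1, 0.2, 300) > \
            expected_bayes_factor(cfg, 0.1, 0.2, 150)

    def test_uses_prior_settings(self):
        cfg = OLESimConfig(total_drift=(1.0, 0.0))
        a = expected_bayes_factor(cfg, 0.1, 0.2, 150,
                                  PriorHyperparameters(u=1.0))
        b = expected_bayes_factor(cfg, 0.1, 0.2, 150,
                                  PriorHyperparameters(u=2.0))
        assert a != b
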