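"""Walker simulator: free-diffusion calibration, impermeability, signal synthesis."""

import math

import numpy as np
import pytest

from axodiff import montecarlo as mc
from axodiff.protocol import PGSEShell, Protocol
from axodiff.substrates import CylinderSubstrate


def perp_protocol(shell_params, TE):
    """Protocol with a b=0 measurement plus x-direction measurements."""
    shells = [PGSEShell(1, 0.0, shell_params[0][1], shell_params[0][2], TE, np.zeros((1, 3)))]
    for G, de, De in shell_params:
        shells.append(PGSEShell(1, G, de, De, TE, np.array([[1.0, 0.0, 0.0]])))
    return Protocol(shells, G_max=max(p[0] for p in shell_params))


def axial_protocol(shell_params, TE):
    shells = [PGSEShell(1, 0.0, shell_params[0][1], shell_params[0][2], TE, np.zeros((1, 3)))]
    for G, de, De in shell_params:
        shells.append(PGSEShell(1, G, de, De, TE, np.array([[0.0, 0.0, 1.0]])))
    return Protocol(shells, G_max=max(p[0] for p in shell_params))


class TestWalk:
    def test_free_diffusion_variance(self):
        cfg = mc.WalkConfig(n_spins=4000, n_steps=300, duration=40.0, seed=1)
        traj = mc.run_walk(None, cfg)
        disp = (traj[-1] - traj[0]) * 1e-6  # m
        expected = 2 * cfg.diffusivity * cfg.duration * 1e-3
        # MC standard error of a variance estimate: var * sqrt(2/(n-1))
        se = expected * math.sqrt(2.0 / (cfg.n_spins - 1))
        for ax in range(3):
            assert abs(disp[:, ax].var() - expected) < 3 * se

    def test_impermeability_spins_stay_inside(self, single_cylinder):
        cfg = mc.WalkConfig(n_spins=300, n_steps=400, duration=36.0, seed=2,
                            placement="intra")
        traj = mc.run_walk(single_cylinder, cfg)
        c = single_cylinder.centers[0]
        r = single_cylinder.radii[0]
        d2 = (traj[:, :, 0] - c[0]) ** 2 + (traj[:, :, 1] - c[1]) ** 2
        assert np.all(d2 <= (r * (1 + 1e-6)) ** 2)

    def test_seed_determinism_bitwise(self):
        cfg = mc.WalkConfig(n_spins=50, n_steps=50, duration=10.0, seed=3)
        t1 = mc.run_walk(None, cfg)
        t2 = mc.run_walk(None, cfg)
        assert np.array_equal(t1, t2)

    def test_step_size_warning_for_fine_geometry(self):
        sub = CylinderSubstrate(cell_size=4.0, centers=[[2.0, 2.0]], radii=[0.25])
        cfg = mc.WalkConfig(n_spins=5, n_steps=20, duration=30.0, seed=0)
        with pytest.warns(UserWarning, match="step length"):
            mc.run_walk(sub, cfg)


class TestSignalSynthesis:
    def test_zero_gradient_gives_unity(self):
        cfg = mc.WalkConfig(n_spins=200, n_steps=100, duration=30.0, seed=4)
        traj = mc.run_walk(None, cfg)
        proto = perp_protocol([(0.0, 5.0, 15.0)], 30.0)
        # the synthetic b=0 shell plus a dw shell at G=0
        proto.shells[1] = PGSEShell(1, 0.0, 5.0, 15.0, 30.0, np.zeros((1, 3)))
        sig = mc.synthesize_pgse(traj, proto, cfg.dt)
        assert np.allclose(sig.values, 1.0)

    def test_free_diffusion_matches_closed_form(self):
        cfg = mc.WalkConfig(n_spins=20000, n_steps=500, duration=30.0, seed=5)
        traj = mc.run_walk(None, cfg)
        proto = perp_protocol([(80.0, 8.0, 16.0)], 30.0)
        sig = mc.synthesize_pgse(traj, proto, cfg.dt)
        b = proto.shells[1].b * 1e6  # s/m²
        expected = math.exp(-b * cfg.diffusivity)
        se = 1.0 / math.sqrt(cfg.n_spins)  # phasor-mean error scale
        assert abs(sig.values[1] - expected) < 3 * se

    def test_axial_gradient_unrestricted_in_cylinder(self, single_cylinder):
        cfg = mc.WalkConfig(n_spins=20000, n_steps=500, duration=30.0, seed=6,
                            placement="intra")
        traj = mc.run_walk(single_cylinder, cfg)
        proto = axial_protocol([(80.0, 8.0, 16.0)], 30.0)
        sig = mc.synthesize_pgse(traj, proto, cfg.dt)
        b = proto.shells[1].b * 1e6
        expected = math.exp(-b * cfg.diffusivity)
        assert abs(sig.values[1] - expected) < 3.0 / math.sqrt(cfg.n_spins)

    def test_restriction_attenuates_less_than_free(self, single_cylinder):
        cfg = mc.WalkConfig(n_spins=4000, n_steps=500, duration=30.0, seed=7,
                            placement="intra")
        traj = mc.run_walk(single_cylinder, cfg)
        proto = perp_protocol([(120.0, 8.0, 16.0)], 30.0)
        sig = mc.synthesize_pgse(traj, proto, cfg.dt)
        b = proto.shells[1].b * 1e6
        free = math.exp(-b * cfg.diffusivity)
        assert sig.values[1] >= free - 3.0 / math.sqrt(cfg.n_spins)

    def test_signal_decreases_with_diameter(self):
        vals = []
        for i, d in enumerate((2.0, 4.0, 8.0)):
            sub = CylinderSubstrate(cell_size=3 * d, centers=[[1.5 * d, 1.5 * d]],
                                    radii=[d / 2])
            cfg = mc.WalkConfig(n_spins=3000, n_steps=900, duration=30.0,
                                seed=10 + i, placement="intra")
            traj = mc.run_walk(sub, cfg)
            proto = perp_protocol([(120.0, 8.0, 16.0)], 30.0)
            sig = mc.synthesize_pgse(traj, proto, cfg.dt)
            vals.append(sig.values[1])
        assert vals[0] > vals[1] > vals[2]

    def test_te_exceeding_duration_rejected(self):
        cfg = mc.WalkConfig(n_spins=10, n_steps=20, duration=10.0, seed=0)
        traj = mc.run_walk(None, cfg)
        proto = perp_protocol([(60.0, 5.0, 15.0)], 25.0)
        with pytest.raises(ValueError, match="duration"):
            mc.synthesize_pgse(traj, proto, cfg.dt)


class TestRicianNoise:
    def test_high_snr_is_identity(self):
        s = np.linspace(0.1, 1.0, 20)
        noisy = mc.add_rician_noise(s, 1e9, seed=1)
        assert np.allclose(noisy, s, atol=1e-6)

    def test_zero_signal_rayleigh_mean(self):
        snr = 5.0
        sigma = 1.0 / snr
        trials = mc.add_rician_noise(np.zeros(200000), snr, seed=2)
        expected = sigma * math.sqrt(math.pi / 2.0)
        sd = sigma * math.sqrt(2.0 - math.pi / 2.0)
        assert abs(trials.mean() - expected) < 3 * sd / math.sqrt(trials.size)

    def test_seed_reproducibility(self):
        s = np.full(50, 0.5)
        assert np.array_equal(mc.add_rician_noise(s, 20, seed=3),
                              mc.add_rician_noise(s, 20, seed=3))

    def test_invalid_snr(self):
        with pytest.raises(ValueError):
            mc.add_rician_noise(np.ones(3), 0.0)


class TestFreeDisplacementStats:
    def test_rms_displacement(self):
        st = mc.free_displacement_stats(0.45e-9, 18.0)
        assert st["rms_1d"] == pytest.approx(4.0, abs=0.05)

    def test_boundary_reaching_fraction(self):
        st = mc.free_displacement_stats(0.45e-9, 18.1)
        assert st["p_exceed"](5.0) == pytest.approx(0.215, abs=0.005)

    def test_short_time_limits(self):
        st = mc.free_displacement_stats(0.45e-9, 1e-6)
        assert st["rms_1d"] < 1e-3
        assert st["p_exceed"](1.0) < 1e-12


class TestSignalFiles:
    def test_signal_round_trip_with_sidecar(self, tmp_path, fixtures):
        proto = fixtures["ActiveAx300"]
        import numpy as np

        vals = np.linspace(1.0, 0.2, proto.total_meas)
        sig = mc.SyntheticSignal(vals, proto, noise_free=False, snr=20.0,
                                 meta={"seed": 5})
        path = tmp_path / "sig.txt"
        mc.save_signal(sig, path)
        back = mc.load_signal(path, proto)
        assert np.allclose(back.values, vals)
        assert back.snr == 20.0 and not back.noise_free
        assert back.meta["seed"] == 5

    def test_length_mismatch_rejected(self, tmp_path, fixtures):
        path = tmp_path / "sig.txt"
        path.write_text("1.0\n0.5\n")
        with pytest.raises(ValueError, match="measurements"):
            mc.load_signal(path, fixtures["ActiveAx300"])
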