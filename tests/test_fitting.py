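"""Three-stage fitting: orientation, grid, MAP refinement, MCMC posteriors."""

import math

import numpy as np
import pytest

from axodiff import fitting as F
from axodiff.model import ForwardModel, MMWMDParams, total_signal
from axodiff.montecarlo import add_rician_noise


@pytest.fixture(scope="module")
def clean_signals(proto300):
    fm = ForwardModel(proto300)
    p = MMWMDParams(f=(0.7, 0.3, 0.0, 0.0), a_prime=4.0)
    return fm.signal(p.f, p.a_prime, 1.0, p.orientation)


class TestOrientation:
    def test_round_trip_recovery_within_two_degrees(self, proto300):
        n_true = np.array([0.3, -0.5, 0.81])
        n_true /= np.linalg.norm(n_true)
        p = MMWMDParams(f=(0.7, 0.3, 0.0, 0.0), a_prime=4.0, orientation=tuple(n_true))
        sig = total_signal(p, proto300).values
        est = F.estimate_orientation(sig, proto300)
        angle = math.degrees(math.acos(min(1.0, abs(est.vector @ n_true))))
        assert angle < 2.0
        assert not est.low_anisotropy

    def test_isotropic_signals_flagged(self, proto300):
        fm = ForwardModel(proto300)
        iso = np.exp(-fm.b * 0.45e-9)  # pure isotropic decay
        est = F.estimate_orientation(iso, proto300)
        assert est.low_anisotropy

    def test_equivariance_under_axis_swap(self, proto300):
        # swapping two coordinate axes of orientation and directions swaps the output
        from axodiff.protocol import PGSEShell, Protocol

        n_true = np.array([0.2, 0.5, np.sqrt(1 - 0.04 - 0.25)])
        p = MMWMDParams(f=(0.7, 0.3, 0.0, 0.0), a_prime=4.0, orientation=tuple(n_true))
        sig = total_signal(p, proto300).values
        e1 = F.estimate_orientation(sig, proto300).vector

        perm = [1, 0, 2]
        shells_p = [
            PGSEShell(s.n_meas, s.G, s.delta, s.Delta, s.TE, s.directions[:, perm])
            for s in proto300.shells
        ]
        proto_p = Protocol(shells_p, G_max=proto300.G_max)
        p2 = MMWMDParams(f=p.f, a_prime=4.0, orientation=tuple(n_true[perm]))
        sig2 = total_signal(p2, proto_p).values
        e2 = F.estimate_orientation(sig2, proto_p).vector
        assert np.allclose(np.abs(e2), np.abs(e1[perm]), atol=1e-6)


class TestStage1:
    def test_grid_point_self_consistency(self, proto300):
        fm = ForwardModel(proto300)
        truth = MMWMDParams(f=(0.5, 0.35, 0.1, 0.05), a_prime=6.0)
        sig = fm.signal(truth.f, truth.a_prime, 1.0, truth.orientation)
        init = F.stage1_grid(sig, proto300, truth.orientation)
        assert init.a_prime == pytest.approx(6.0)
        assert init.f[0] == pytest.approx(0.5, abs=1e-9)
        assert init.f[2] == pytest.approx(0.1, abs=1e-9)

    def test_degenerate_signals_return_default(self, proto300):
        init = F.stage1_grid(np.ones(proto300.total_meas), proto300, (0, 0, 1))
        assert init.a_prime == 4.0  # flagged default grid centre

    def test_deterministic(self, proto300, clean_signals):
        i1 = F.stage1_grid(clean_signals, proto300, (0, 0, 1))
        i2 = F.stage1_grid(clean_signals, proto300, (0, 0, 1))
        assert i1.a_prime == i2.a_prime and i1.f == i2.f


class TestStage2:
    @pytest.mark.parametrize("a_true", [3.0, 4.0, 6.0])
    def test_noise_free_recovery_within_one_percent(self, proto300, a_true):
        fm = ForwardModel(proto300)
        p = MMWMDParams(f=(0.7, 0.3, 0.0, 0.0), a_prime=a_true)
        sig = fm.signal(p.f, p.a_prime, 1.0, p.orientation)
        init = F.stage1_grid(sig, proto300, p.orientation)
        est = F.stage2_map(sig, proto300, init, snr=None)
        assert abs(est.a_prime - a_true) / a_true < 0.01

    def test_start_at_optimum_returns_unchanged(self, proto300, clean_signals):
        truth = MMWMDParams(f=(0.7, 0.3, 0.0, 0.0), a_prime=4.0)
        est = F.stage2_map(clean_signals, proto300, truth, snr=None)
        assert est.a_prime == pytest.approx(4.0, rel=5e-3)
        assert est.f[0] == pytest.approx(0.7, abs=5e-3)

    def test_never_worse_than_init(self, proto300, clean_signals):
        noisy = add_rician_noise(clean_signals, 10.0, seed=3)
        init = F.stage1_grid(noisy, proto300, (0, 0, 1))
        fm = ForwardModel(proto300)
        est = F.stage2_map(noisy, proto300, init, snr=10.0)
        sigma = float(np.mean(noisy[fm.is_b0])) / 10.0

        def obj(p):
            pred = fm.signal(p.f, p.a_prime, p.S0, p.orientation)
            r = np.sqrt(pred**2 + sigma**2) - noisy
            return float(r @ r)

        assert obj(est) <= obj(init) + 1e-12


class TestStage3:
    def test_invalid_iteration_counts(self, proto300, clean_signals):
        truth = MMWMDParams(f=(0.7, 0.3, 0.0, 0.0), a_prime=4.0)
        with pytest.raises(ValueError):
            F.stage3_mcmc(clean_signals, proto300, truth, n_iter=100, burn_in=200)

    def test_seeded_chain_reproducible(self, proto300, clean_signals):
        noisy = add_rician_noise(clean_signals, 20.0, seed=1)
        truth = MMWMDParams(f=(0.7, 0.3, 0.0, 0.0), a_prime=4.0)
        kw = dict(snr=20.0, n_iter=600, burn_in=200, thin=4, seed=9)
        p1 = F.stage3_mcmc(noisy, proto300, truth, **kw)
        p2 = F.stage3_mcmc(noisy, proto300, truth, **kw)
        assert np.array_equal(p1.a_prime, p2.a_prime)

    def test_acceptance_rate_in_window_and_posterior_covers_truth(
        self, proto300, clean_signals
    ):
        noisy = add_rician_noise(clean_signals, 20.0, seed=2)
        init = F.stage1_grid(noisy, proto300, (0, 0, 1))
        mapest = F.stage2_map(noisy, proto300, init, snr=20.0)
        post = F.stage3_mcmc(noisy, proto300, mapest, snr=20.0,
                             n_iter=2000, burn_in=600, thin=4, seed=5)
        assert 0.1 <= post.acceptance_rate <= 0.6
        lo, hi = np.quantile(post.a_prime, [0.005, 0.995])
        assert lo <= 4.0 <= hi + 1.0  # truth within (generously padded) interval

    def test_two_seeds_agree_within_mc_error(self, proto300, clean_signals):
        noisy = add_rician_noise(clean_signals, 20.0, seed=4)
        init = F.stage1_grid(noisy, proto300, (0, 0, 1))
        mapest = F.stage2_map(noisy, proto300, init, snr=20.0)
        kw = dict(snr=20.0, n_iter=3000, burn_in=800, thin=4)
        pa = F.stage3_mcmc(noisy, proto300, mapest, seed=11, **kw)
        pb = F.stage3_mcmc(noisy, proto300, mapest, seed=12, **kw)
        pooled = math.hypot(pa.a_prime.std() / math.sqrt(pa.n_draws / 10),
                            pb.a_prime.std() / math.sqrt(pb.n_draws / 10))
        # autocorrelation-inflated MC error (effective sample ~ n/10)
        assert abs(F.a_prime_estimate(pa) - F.a_prime_estimate(pb)) < 4 * pooled


class TestSummaries:
    def _const_posterior(self, value, n=100):
        return F.PosteriorSamples(
            a_prime=np.full(n, value), fractions=np.tile([0.7, 0.3, 0, 0], (n, 1)),
            S0=np.ones(n), acceptance_rate=0.3, seed=0, n_iter=n, burn_in=0, thin=1,
        )

    def test_constant_chain(self):
        p = self._const_posterior(3.0)
        assert F.a_prime_estimate(p) == 3.0
        assert F.posterior_overlap(p, p) == 1.0

    def test_disjoint_chains(self):
        assert F.posterior_overlap(self._const_posterior(1.0),
                                   self._const_posterior(9.0)) == 0.0

    def test_empty_posterior_rejected(self):
        with pytest.raises(ValueError):
            F.PosteriorSamples(
                a_prime=np.array([]), fractions=np.zeros((0, 4)), S0=np.array([]),
                acceptance_rate=0.0, seed=0, n_iter=0, burn_in=0, thin=1,
            )
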