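"""Experiment drivers: batteries, signal sources, summaries, bounds."""

import numpy as np
import pytest

from axodiff import experiments as E
from axodiff import fitting
from axodiff.model import ForwardModel
from axodiff.substrates import CylinderSubstrate, alpha_index


class TestBattery:
    def test_battery_spans_alpha_range(self):
        subs = E.default_substrate_battery(8, n_axons=40, seed=4)
        alphas = [s.meta["alpha"] for s in subs]
        assert len(subs) == 8
        assert min(alphas) < 1.5 and max(alphas) > 8.0
        for s in subs:
            assert not s.has_overlaps()

    def test_battery_reproducible(self):
        a = E.default_substrate_battery(4, n_axons=30, seed=7)
        b = E.default_substrate_battery(4, n_axons=30, seed=7)
        for s1, s2 in zip(a, b):
            assert np.array_equal(s1.centers, s2.centers)
            assert np.array_equal(s1.radii, s2.radii)


class TestAnalyticSignals:
    def test_single_diameter_substrate_matches_model(self, single_cylinder, proto300):
        sig = E.substrate_signal_analytic(single_cylinder, proto300)
        fm = ForwardModel(proto300)
        f1 = single_cylinder.f_ic
        expected = f1 * fm.intra(4.0, (0, 0, 1)) + (1 - f1) * fm.extra(f1, 1 - f1, (0, 0, 1))
        assert np.allclose(sig.values, expected)

    def test_b0_normalized_to_unity(self, single_cylinder, proto300):
        sig = E.substrate_signal_analytic(single_cylinder, proto300)
        fm = ForwardModel(proto300)
        assert np.allclose(sig.values[fm.is_b0], 1.0)


@pytest.fixture(scope="module")
def tiny_run(fixtures):
    subs = E.default_substrate_battery(2, n_axons=30, seed=3)
    protos = {"ActiveAx300": fixtures["ActiveAx300"]}
    kw = dict(n_trials=2, snr_mode="fixed", seed=5,
              mcmc=dict(n_iter=400, burn_in=150, thin=4))
    return subs, protos, kw


class TestGmaxComparison:
    def test_bit_identical_reruns(self, tiny_run):
        subs, protos, kw = tiny_run
        df1 = E.run_gmax_comparison(subs, protos, **kw)
        df2 = E.run_gmax_comparison(subs, protos, **kw)
        assert df1.equals(df2)

    def test_alpha_depends_only_on_diameters(self, fixtures):
        from axodiff.substrates import pack_cylinders, sample_diameters, DiameterDistribution

        diam = sample_diameters(DiameterDistribution.gamma(3, 1.2), 30, seed=11)
        s_lo = pack_cylinders(diam, 0.45, seed=1)
        s_hi = pack_cylinders(diam, 0.65, seed=2)
        for s in (s_lo, s_hi):
            s.meta["alpha"] = alpha_index(diam)
        df = E.run_gmax_comparison(
            [s_lo, s_hi], {"ActiveAx300": fixtures["ActiveAx300"]},
            n_trials=1, snr_mode="fixed", seed=5,
            mcmc=dict(n_iter=300, burn_in=100, thin=4),
        )
        assert df.groupby("substrate")["alpha"].first().nunique() == 1

    def test_invalid_modes_rejected(self, fixtures):
        with pytest.raises(ValueError):
            E.run_gmax_comparison([], {}, snr_mode="bogus")


class TestRoiSummary:
    def test_constant_vector(self):
        assert E.roi_summary([2.0, 2.0, 2.0]) == {"mean": 2.0, "se": 0.0}

    def test_hand_computed_example(self):
        out = E.roi_summary([1.0, 2.0, 3.0])
        assert out["mean"] == pytest.approx(2.0)
        assert out["se"] == pytest.approx(1.0 / np.sqrt(3.0), rel=1e-9)

    def test_se_scaling_with_n(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=400)
        se_small = E.roi_summary(x[:100])["se"]
        se_big = E.roi_summary(x)["se"]
        assert se_big == pytest.approx(se_small / 2.0, rel=0.25)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            E.roi_summary([])


def _point_mass(value, n=200):
    return fitting.PosteriorSamples(
        a_prime=np.full(n, float(value)),
        fractions=np.tile([0.7, 0.3, 0, 0], (n, 1)),
        S0=np.ones(n), acceptance_rate=0.3, seed=0, n_iter=n, burn_in=0, thin=1,
    )


class TestBoundsReport:
    def test_disjoint_point_masses_give_smallest_diameter(self):
        posts = {d: _point_mass(d) for d in (1.0, 2.0, 4.0, 8.0)}
        out = E.bounds_report(posts)
        assert out["lower_bound"] == 1.0
        assert out["lower_bound_found"]

    def test_identical_posteriors_flagged_unbounded(self):
        posts = {d: _point_mass(3.0) for d in (1.0, 2.0, 4.0, 8.0)}
        out = E.bounds_report(posts)
        assert out["lower_bound"] is None
        assert not out["lower_bound_found"]

    def test_requires_at_least_four_diameters(self):
        with pytest.raises(ValueError):
            E.bounds_report({1.0: _point_mass(1), 2.0: _point_mass(2)})


class TestConfigAndOutputs:
    def test_run_config_round_trip(self, tmp_path):
        cfg = tmp_path / "run.cfg"
        cfg.write_text(
            "protocol: ActiveAx300\n"
            "snr: 20\n"
            "t2: 50.0\n"
            "noise_free: false  # comment\n"
            "seed: 3\n"
        )
        out = E.load_run_config(cfg)
        assert out["snr"] == 20 and isinstance(out["snr"], int)
        assert out["t2"] == 50.0
        assert out["noise_free"] is False
        assert out["protocol_obj"].G_max == 300.0

    def test_malformed_config_line(self, tmp_path):
        cfg = tmp_path / "bad.cfg"
        cfg.write_text("just a line without separator\n")
        with pytest.raises(ValueError, match="line 1"):
            E.load_run_config(cfg)

    def test_result_table_with_manifest(self, tmp_path):
        import json
        import pandas as pd

        df = pd.DataFrame({"a": [1, 2], "b": [0.5, 0.7]})
        path = tmp_path / "table.csv"
        E.write_result_table(df, path, meta={"seed": 9})
        back = pd.read_csv(path)
        assert back.equals(df)
        manifest = json.loads(path.with_suffix(".csv.json").read_text())
        assert manifest["n_rows"] == 2 and manifest["seed"] == 9
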