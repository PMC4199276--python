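"""Desk-scale pipeline drivers: substrate batteries, G_max comparisons, posteriors.

These functions wire the modules together the way the simulation studies are
run: build substrates with known axon diameter distributions, synthesize
noise-free PGSE signals (Monte-Carlo walkers or the analytic cylinder-mixture
forward), inject independent Rician noise trials, fit the MMWMD per trial and
summarize the axon diameter index ``a'`` against the idealized index ``alpha``.
Default problem sizes are deliberately small (a dozen substrates, ten noise
trials, reduced MCMC) so a full comparison runs on one CPU in minutes; every
size is a parameter.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import fitting, montecarlo
from .model import ForwardModel, MMWMDParams
from .montecarlo import SyntheticSignal, WalkConfig, add_rician_noise
from .protocol import Protocol, snr_at_te, SNR_REF, TE_REF_MS, table_fixtures
from .substrates import (
    CylinderSubstrate,
    DiameterDistribution,
    alpha_index,
    alpha_truncated,
    pack_cylinders,
    sample_diameters,
)

__all__ = [
    "default_substrate_battery",
    "substrate_signal_analytic",
    "substrate_signal_mc",
    "run_gmax_comparison",
    "run_single_diameter_posteriors",
    "roi_summary",
    "bounds_report",
]

_TEST_MCMC = dict(n_iter=2500, burn_in=600, thin=4)


# ---------------------------------------------------------------------------
# substrate battery


def default_substrate_battery(
    n_substrates: int = 12,
    n_axons: int = 60,
    seed: int = 0,
    densities: tuple[float, ...] = (0.45, 0.6),
    gamma_shapes: tuple[float, ...] = (3.0, 10.0),
) -> list[CylinderSubstrate]:
    """A battery of gamma-ADD substrates spanning idealized indices ~0.5–15 μm.

    Target volume-weighted mean diameters are log-spaced over 0.5–15 μm, one
    per substrate, with wide/narrow gamma shapes and the two packing
    densities cycled across them; the gamma scale is chosen so the
    distribution's volume-weighted mean ``(k + 2) * theta`` hits the target.
    ``n_substrates=44`` reproduces a full-scale battery; the default 12 is
    desk scale.
    """
    alphas = np.geomspace(0.5, 15.0, n_substrates)
    subs: list[CylinderSubstrate] = []
    rng = np.random.default_rng(seed)
    for i, target_alpha in enumerate(alphas):
        k = gamma_shapes[i % len(gamma_shapes)]
        f_ic = densities[(i // len(gamma_shapes)) % len(densities)]
        theta = target_alpha / (k + 2.0)
        dist = DiameterDistribution.gamma(k, theta)
        diam = sample_diameters(dist, n_axons, seed=rng)
        sub = pack_cylinders(diam, f_ic, seed=rng)
        sub.meta.update(
            {
                "index": i,
                "gamma_k": k,
                "gamma_theta": theta,
                "target_alpha": float(target_alpha),
                "alpha": alpha_index(diam),
                "alpha_trunc10": alpha_truncated(diam, 10.0)
                if np.any(diam <= 10.0)
                else float("nan"),
            }
        )
        subs.append(sub)
    return subs


# ---------------------------------------------------------------------------
# signal sources


def substrate_signal_analytic(
    substrate: CylinderSubstrate,
    protocol: Protocol,
    d_par: float = montecarlo.D_EX_VIVO,
    orientation=(0.0, 0.0, 1.0),
) -> SyntheticSignal:
    """Noise-free signal from the analytic parallel-cylinder mixture.

    The intra-cylinder signal is the volume-weighted (area-weighted, for
    equal-length cylinders) mixture of single-diameter GPD signals over the
    substrate's diameters; the extracellular space is the hindered tensor
    with tortuosity set by the substrate's intracellular fraction.  This
    isolates model-fitting behaviour from walker noise.
    """
    fm = ForwardModel(protocol, d_par=d_par)
    diam = substrate.diameters
    w = diam**2
    w = w / w.sum()
    intra = np.zeros(fm.n_meas)
    for d, wi in zip(diam, w):
        intra += wi * fm.intra(d, orientation)
    f1 = substrate.f_ic
    extra = fm.extra(f1, 1.0 - f1, orientation)
    vals = f1 * intra + (1.0 - f1) * extra
    return SyntheticSignal(vals, protocol, noise_free=True,
                           meta={"source": "analytic", "f_ic": f1})


def substrate_signal_mc(
    substrate: CylinderSubstrate,
    protocol: Protocol,
    n_spins: int = 10_000,
    n_steps: int = 2000,
    d_par: float = montecarlo.D_EX_VIVO,
    seed: int = 0,
) -> SyntheticSignal:
    """Noise-free signal from a Monte-Carlo walk through the substrate."""
    te_max = max(s.TE for s in protocol.shells)
    cfg = WalkConfig(
        n_spins=n_spins, n_steps=n_steps, diffusivity=d_par,
        duration=te_max, seed=seed, placement="uniform",
    )
    traj = montecarlo.run_walk(substrate, cfg)
    sig = montecarlo.synthesize_pgse(traj, protocol, cfg.dt)
    sig.meta.update({"source": "mc", "n_spins": n_spins, "seed": seed})
    return sig


# ---------------------------------------------------------------------------
# G_max comparison (distributed-diameter substrates)


def run_gmax_comparison(
    substrates: list[CylinderSubstrate] | None = None,
    protocols: dict[str, Protocol] | None = None,
    n_trials: int = 10,
    snr_mode: str = "fixed",
    snr: float = SNR_REF,
    signal_source: str = "analytic",
    mcmc: dict | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Idealized index alpha versus fitted index a' across G_max protocols.

    For each substrate x protocol the noise-free signal is synthesized once;
    ``n_trials`` independent Rician noise realizations are each fitted through
    the three stages and the posterior-mean a' recorded.  ``snr_mode``:
    ``fixed`` (same SNR for every protocol), ``te`` (SNR rescaled for each
    protocol's echo time by T2 decay from the reference TE) or ``noise_free``
    (a single fit of the clean signal).  Returns a tidy table with one row per
    substrate x protocol x trial.
    """
    if substrates is None:
        substrates = default_substrate_battery(seed=seed)
    if protocols is None:
        fx = table_fixtures(seed=seed)
        protocols = {k: fx[k] for k in ("ActiveAx060", "ActiveAx140",
                                        "ActiveAx200", "ActiveAx300")}
    if snr_mode not in ("fixed", "te", "noise_free"):
        raise ValueError(f"unknown snr_mode {snr_mode!r}")
    mcmc_kw = dict(_TEST_MCMC if mcmc is None else mcmc)
    rows = []
    rng = np.random.default_rng(seed)
    for si, sub in enumerate(substrates):
        alpha = sub.meta.get("alpha", alpha_index(sub.diameters))
        for pname, proto in protocols.items():
            if signal_source == "analytic":
                clean = substrate_signal_analytic(sub, proto)
            elif signal_source == "mc":
                clean = substrate_signal_mc(sub, proto,
                                            seed=int(rng.integers(2**31 - 1)))
            else:
                raise ValueError(f"unknown signal_source {signal_source!r}")
            if snr_mode == "te":
                te = proto.shells[0].TE
                snr_eff = snr_at_te(snr, TE_REF_MS, te, proto.assumed_T2)
            else:
                snr_eff = snr
            n_fit = 1 if snr_mode == "noise_free" else n_trials
            for trial in range(n_fit):
                if snr_mode == "noise_free":
                    data = clean.values
                    fit_snr = None
                else:
                    data = add_rician_noise(clean.values, snr_eff,
                                            seed=int(rng.integers(2**31 - 1)))
                    fit_snr = snr_eff
                try:
                    _, post = fitting.fit_voxel(
                        data, proto, snr=fit_snr, orientation=(0.0, 0.0, 1.0),
                        seed=int(rng.integers(2**31 - 1)), **mcmc_kw,
                    )
                    a_hat = fitting.a_prime_estimate(post)
                    ok = True
                except Exception:  # record the failure, keep the batch going
                    a_hat = float("nan")
                    ok = False
                rows.append(
                    {
                        "substrate": si,
                        "protocol": pname,
                        "trial": trial,
                        "alpha": alpha,
                        "alpha_trunc10": sub.meta.get("alpha_trunc10", float("nan")),
                        "f_ic": sub.f_ic,
                        "snr": None if snr_mode == "noise_free" else snr_eff,
                        "a_prime": a_hat,
                        "fit_ok": ok,
                    }
                )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# single-diameter posteriors

SINGLE_DIAMETERS = (0.5, 1.0, 1.5, 2.0, 3.0, 4.0, 6.0, 8.0, 10.0)


def run_single_diameter_posteriors(
    diameters=SINGLE_DIAMETERS,
    protocols: dict[str, Protocol] | None = None,
    f_ic: float = 0.7,
    snr: float = SNR_REF,
    mcmc: dict | None = None,
    seed: int = 0,
) -> dict[str, dict[float, fitting.PosteriorSamples]]:
    """Posterior distributions of a' for single-diameter substrates.

    For each diameter and protocol, synthesizes the analytic two-compartment
    signal at intracylinder fraction ``f_ic``, adds one Rician noise
    realization at the given SNR, and runs the full fit.  Returns
    ``{protocol: {diameter: posterior}}``.
    """
    if any(d <= 0 for d in diameters):
        raise ValueError("diameters must be positive")
    if protocols is None:
        fx = table_fixtures(seed=seed)
        protocols = {k: fx[k] for k in ("ActiveAx060", "ActiveAx140",
                                        "ActiveAx200", "ActiveAx300")}
    mcmc_kw = dict(_TEST_MCMC if mcmc is None else mcmc)
    rng = np.random.default_rng(seed)
    out: dict[str, dict[float, fitting.PosteriorSamples]] = {}
    for pname, proto in protocols.items():
        fm = ForwardModel(proto)
        out[pname] = {}
        for d in diameters:
            params = MMWMDParams(f=(f_ic, 1.0 - f_ic, 0.0, 0.0), a_prime=float(d))
            clean = fm.signal(params.f, params.a_prime, 1.0, params.orientation)
            data = add_rician_noise(clean, snr, seed=int(rng.integers(2**31 - 1)))
            _, post = fitting.fit_voxel(
                data, proto, snr=snr, orientation=(0.0, 0.0, 1.0),
                seed=int(rng.integers(2**31 - 1)), **mcmc_kw,
            )
            out[pname][float(d)] = post
    return out


def overlap_matrix(
    posteriors: dict[float, fitting.PosteriorSamples]
) -> pd.DataFrame:
    """Pairwise histogram-intersection overlaps between diameter posteriors."""
    ds = sorted(posteriors)
    M = np.eye(len(ds))
    for i, a in enumerate(ds):
        for j, b in enumerate(ds):
            if j > i:
                M[i, j] = M[j, i] = fitting.posterior_overlap(
                    posteriors[a], posteriors[b]
                )
    return pd.DataFrame(M, index=ds, columns=ds)


# ---------------------------------------------------------------------------
# summaries


def load_run_config(path) -> dict:
    """Parse a plain ``key: value`` run-config file.

    Values are coerced to int/float/bool where possible; the key ``protocol``
    may name a built-in fixture (ActiveAx060/140/200/300, T2_400, T2_4000)
    and is resolved to a :class:`Protocol` under ``protocol_obj``.
    """
    from pathlib import Path

    out: dict = {}
    for i, line in enumerate(Path(path).read_text().splitlines(), start=1):
        line = line.split("#", 1)[0].strip()
        if not line:
            continue
        if ":" not in line:
            raise ValueError(f"line {i}: expected 'key: value'")
        key, _, raw = line.partition(":")
        raw = raw.strip()
        if raw.lower() in ("true", "false"):
            val: object = raw.lower() == "true"
        else:
            try:
                val = int(raw)
            except ValueError:
                try:
                    val = float(raw)
                except ValueError:
                    val = raw
        out[key.strip()] = val
    name = out.get("protocol")
    if isinstance(name, str):
        fixtures = table_fixtures(seed=int(out.get("seed", 0)))
        if name in fixtures:
            out["protocol_obj"] = fixtures[name]
    return out


def write_result_table(df: pd.DataFrame, path, meta: dict | None = None) -> None:
    """Write an experiment table as CSV with a JSON manifest sidecar."""
    import json
    from pathlib import Path

    path = Path(path)
    df.to_csv(path, index=False)
    manifest = {"n_rows": int(len(df)), "columns": list(df.columns)}
    manifest.update(meta or {})
    path.with_suffix(path.suffix + ".json").write_text(
        json.dumps(manifest, indent=2, default=float) + "\n"
    )


def roi_summary(values) -> dict[str, float]:
    """Mean and standard error of the sample mean for a set of voxel values."""
    v = np.asarray(values, dtype=float).ravel()
    if v.size == 0:
        raise ValueError("empty input")
    se = 0.0 if v.size == 1 else float(np.std(v, ddof=1) / math.sqrt(v.size))
    return {"mean": float(np.mean(v)), "se": se}


def bounds_report(
    posteriors: dict[float, fitting.PosteriorSamples],
    overlap_threshold: float = 0.5,
) -> dict:
    """Locate the lower bound of the diameter sensitivity window.

    Scanning adjacent diameter pairs in ascending order, the lower bound is
    the smallest diameter whose posterior is distinguishable from the next
    larger one (their overlap falls below ``overlap_threshold``); below it,
    diameters are identified as small but not mutually distinguishable.
    Also reports posterior spreads so the reduced sensitivity at the largest
    diameters (the upper bound) can be read off.  Needs posteriors for at
    least 4 diameters.
    """
    ds = sorted(posteriors)
    if len(ds) < 4:
        raise ValueError("need posteriors for at least 4 diameters")
    overlaps = {}
    lower = None
    for cur, nxt in zip(ds[:-1], ds[1:]):
        ov = fitting.posterior_overlap(posteriors[cur], posteriors[nxt])
        overlaps[(cur, nxt)] = ov
        if lower is None and ov < overlap_threshold:
            lower = cur
    spreads = {d: float(np.std(posteriors[d].a_prime)) for d in ds}
    return {
        "lower_bound": lower,
        "lower_bound_found": lower is not None,
        "overlap_threshold": overlap_threshold,
        "adjacent_overlaps": overlaps,
        "posterior_spreads": spreads,
    }
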