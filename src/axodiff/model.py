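"""Minimal model of white matter diffusion (MMWMD): forward signals and Fisher information.

Four compartments with volume fractions summing to one:

* intra-axonal — parallel impermeable cylinders of a single diameter, the
  "axon diameter index" ``a'``; free Gaussian diffusion along the axis,
  Gaussian-phase-distribution (GPD) restricted attenuation perpendicular;
* extra-axonal — hindered axially symmetric diffusion tensor, with the
  perpendicular diffusivity tied to the intra fraction by the tortuosity
  relation ``d_perp = d_par * (1 - f1 / (f1 + f2))``;
* CSF — isotropic free water, ``exp(-b * d_iso)``;
* stationary ("dot") — isotropically restricted water with no attenuation,
  appropriate for fixed tissue.

The GPD perpendicular attenuation for a cylinder of radius ``R`` uses the
classical series over roots of ``J1'(x) = 0``:

    ln S = -2 gamma^2 G_perp^2 * sum_m num_m / (D^2 a_m^6 (R^2 a_m^2 - 1))
    num_m = 2 D a_m^2 delta - 2 + 2 e^{-D a_m^2 delta} + 2 e^{-D a_m^2 Delta}
            - e^{-D a_m^2 (Delta-delta)} - e^{-D a_m^2 (Delta+delta)}

with ``a_m = beta_m / R`` and the first 30 Bessel-derivative roots.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from scipy.special import jnp_zeros

from .montecarlo import SyntheticSignal
from .protocol import GAMMA, Protocol, bvalue

__all__ = [
    "MMWMDParams",
    "intra_signal",
    "extra_signal",
    "csf_signal",
    "dot_signal",
    "total_signal",
    "fisher_information",
    "crlb",
    "ForwardModel",
]

#: First 30 roots of J1'(x) = 0 (the m >= 1 extrema of J1).
BESSEL_ROOTS = jnp_zeros(1, 30)

#: Default diffusivities (m²/s): parallel intrinsic (ex-vivo fixed tissue)
#: and free-water CSF.
D_PAR_DEFAULT = 0.45e-9
D_ISO_DEFAULT = 2.0e-9


@dataclass
class MMWMDParams:
    """MMWMD parameter set.

    Fractions ``f = (f1, f2, f3, f4)`` are (intra, extra, CSF, stationary) and
    must sum to 1; ``a_prime`` is the cylinder diameter in micrometres;
    diffusivities in m²/s; ``orientation`` the fibre axis (unit 3-vector);
    ``S0`` the unweighted signal scale.
    """

    f: tuple[float, float, float, float] = (0.7, 0.3, 0.0, 0.0)
    a_prime: float = 4.0
    d_par: float = D_PAR_DEFAULT
    d_iso: float = D_ISO_DEFAULT
    orientation: tuple[float, float, float] = (0.0, 0.0, 1.0)
    S0: float = 1.0

    def __post_init__(self) -> None:
        f = np.asarray(self.f, dtype=float)
        if f.shape != (4,) or np.any(f < -1e-12):
            raise ValueError("need four non-negative fractions")
        if abs(float(np.sum(f)) - 1.0) > 1e-9:
            raise ValueError(f"fractions must sum to 1, got {np.sum(f):.12f}")
        if self.a_prime < 0:
            raise ValueError("a_prime must be non-negative")
        if self.d_par <= 0 or self.d_iso <= 0:
            raise ValueError("diffusivities must be positive")
        n = np.asarray(self.orientation, dtype=float)
        nn = np.linalg.norm(n)
        if nn == 0:
            raise ValueError("orientation must be a non-zero vector")
        self.orientation = tuple(n / nn)

    @property
    def f1(self) -> float:
        return self.f[0]

    @property
    def d_perp(self) -> float:
        """Tortuosity-linked extra-axonal perpendicular diffusivity."""
        f1, f2 = self.f[0], self.f[1]
        if f1 + f2 <= 0:
            return self.d_par
        return self.d_par * (1.0 - f1 / (f1 + f2))

    def to_json(self, path: str | Path) -> None:
        d = {
            "f": list(self.f),
            "a_prime_um": self.a_prime,
            "d_par_m2s": self.d_par,
            "d_iso_m2s": self.d_iso,
            "orientation": list(self.orientation),
            "S0": self.S0,
        }
        Path(path).write_text(json.dumps(d, indent=2) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "MMWMDParams":
        d = json.loads(Path(path).read_text())
        return cls(
            f=tuple(d["f"]),
            a_prime=d["a_prime_um"],
            d_par=d["d_par_m2s"],
            d_iso=d["d_iso_m2s"],
            orientation=tuple(d["orientation"]),
            S0=d["S0"],
        )


def gpd_log_perp_attenuation(
    G_perp: np.ndarray, delta: np.ndarray, Delta: np.ndarray, radius_m: float, D: float
) -> np.ndarray:
    """Log of the GPD perpendicular cylinder attenuation (SI inputs).

    ``G_perp`` in T/m, times in s, ``radius_m`` in m.  Vectorized over
    measurements; returns 0 where ``G_perp`` or the radius is zero.
    """
    if radius_m <= 0.0:
        return np.zeros_like(np.asarray(G_perp, dtype=float))
    G_perp = np.asarray(G_perp, dtype=float)
    delta = np.asarray(delta, dtype=float)
    Delta = np.asarray(Delta, dtype=float)
    am = BESSEL_ROOTS / radius_m  # (30,)
    dam2 = D * am**2
    # broadcast (n_meas, 30)
    e = np.multiply.outer(delta, dam2)
    E = np.multiply.outer(Delta, dam2)
    num = (
        2.0 * e
        - 2.0
        + 2.0 * np.exp(-e)
        + 2.0 * np.exp(-E)
        - np.exp(-(E - e))
        - np.exp(-(E + e))
    )
    denom = D**2 * am**6 * (radius_m**2 * am**2 - 1.0)
    s = np.sum(num / denom, axis=-1)
    return -2.0 * GAMMA**2 * G_perp**2 * s


def _angles(dirs: np.ndarray, orientation) -> tuple[np.ndarray, np.ndarray]:
    """cos² and sin² of the angle between each gradient direction and the axis."""
    n = np.asarray(orientation, dtype=float)
    n = n / np.linalg.norm(n)
    c = np.asarray(dirs, dtype=float) @ n
    c2 = np.clip(c**2, 0.0, 1.0)
    return c2, 1.0 - c2


def intra_signal(
    G: float,
    delta: float,
    Delta: float,
    direction,
    a_prime: float,
    d_par: float = D_PAR_DEFAULT,
    orientation=(0.0, 0.0, 1.0),
) -> float:
    """Normalized intra-axonal signal for one measurement (table units).

    ``G`` mT/m, times ms, ``a_prime`` the cylinder diameter in μm.  Product of
    free Gaussian attenuation along the axis and GPD restricted attenuation
    perpendicular to it.
    """
    dirs = np.asarray(direction, dtype=float).reshape(1, 3)
    G_si = np.array([G * 1e-3])
    de = np.array([delta * 1e-3])
    De = np.array([Delta * 1e-3])
    c2, s2 = _angles(dirs, orientation)
    b_si = (bvalue(G, delta, Delta) if G > 0 else 0.0) * 1e6
    log_par = -b_si * c2 * d_par
    log_perp = gpd_log_perp_attenuation(G_si * np.sqrt(s2), de, De, a_prime * 1e-6 / 2.0, d_par)
    return float(np.exp(log_par + log_perp)[0])


def extra_signal(
    b: float, direction, d_par: float, d_perp: float, orientation=(0.0, 0.0, 1.0)
) -> float:
    """Hindered extra-axonal signal, axially symmetric Gaussian.

    ``b`` in s/mm²; ``exp(-b (d_perp + (d_par - d_perp) cos² psi))``.
    """
    if not 0.0 < d_perp <= d_par:
        raise ValueError("require 0 < d_perp <= d_par")
    dirs = np.asarray(direction, dtype=float).reshape(1, 3)
    c2, _ = _angles(dirs, orientation)
    return float(np.exp(-b * 1e6 * (d_perp + (d_par - d_perp) * c2))[0])


def csf_signal(b: float, d_iso: float = D_ISO_DEFAULT) -> float:
    """Free-water signal ``exp(-b * d_iso)``, ``b`` in s/mm²."""
    if b < 0:
        raise ValueError("b must be non-negative")
    return float(np.exp(-b * 1e6 * d_iso))


def dot_signal() -> float:
    """Stationary-water compartment: no diffusion attenuation."""
    return 1.0


class ForwardModel:
    """Vectorized MMWMD forward signal for a fixed protocol.

    Precomputes per-measurement SI pulse arrays and per-shell groupings so
    repeated evaluations (fitting, MCMC) are cheap: the GPD root series is
    evaluated once per unique (delta, Delta) pair per call.
    """

    def __init__(self, protocol: Protocol, d_par: float = D_PAR_DEFAULT,
                 d_iso: float = D_ISO_DEFAULT):
        self.protocol = protocol
        self.d_par = d_par
        self.d_iso = d_iso
        flat = protocol.flatten()
        self.G = flat["G"]
        self.delta = flat["delta"]
        self.Delta = flat["Delta"]
        self.b = flat["b"]  # s/m²
        self.dirs = flat["dirs"]
        self.n_meas = len(self.G)
        # group measurements by unique pulse timing (shells share these)
        key = np.stack([self.delta, self.Delta], axis=1)
        _, self.group_index = np.unique(key, axis=0, return_inverse=True)
        self.n_groups = int(self.group_index.max()) + 1
        self.group_delta = np.array(
            [self.delta[self.group_index == g][0] for g in range(self.n_groups)]
        )
        self.group_Delta = np.array(
            [self.Delta[self.group_index == g][0] for g in range(self.n_groups)]
        )
        self.is_b0 = self.G == 0.0
        self._angle_cache: dict[tuple, tuple[np.ndarray, np.ndarray]] = {}
        self._csf_cache: np.ndarray | None = None

    def _angles_cached(self, orientation) -> tuple[np.ndarray, np.ndarray]:
        key = tuple(np.asarray(orientation, dtype=float))
        hit = self._angle_cache.get(key)
        if hit is None:
            if len(self._angle_cache) > 32:
                self._angle_cache.clear()
            hit = _angles(self.dirs, orientation)
            self._angle_cache[key] = hit
        return hit

    def intra(self, a_prime: float, orientation) -> np.ndarray:
        c2, s2 = self._angles_cached(orientation)
        R = a_prime * 1e-6 / 2.0
        log_par = -self.b * c2 * self.d_par
        if R <= 0:
            return np.exp(log_par)
        # per-group GPD series coefficient: ln S_perp = -2 g^2 Gperp^2 * S(group)
        am = BESSEL_ROOTS / R
        dam2 = self.d_par * am**2
        e = np.multiply.outer(self.group_delta, dam2)
        E = np.multiply.outer(self.group_Delta, dam2)
        num = 2.0 * e - 2.0 + 2.0 * np.exp(-e) + 2.0 * np.exp(-E) - np.exp(-(E - e)) - np.exp(-(E + e))
        denom = self.d_par**2 * am**6 * (R**2 * am**2 - 1.0)
        series = np.sum(num / denom, axis=-1)  # (n_groups,)
        log_perp = -2.0 * GAMMA**2 * (self.G**2 * s2) * series[self.group_index]
        return np.exp(log_par + log_perp)

    def extra(self, f1: float, f2: float, orientation) -> np.ndarray:
        c2, _ = self._angles_cached(orientation)
        if f1 + f2 <= 0:
            d_perp = self.d_par
        else:
            d_perp = self.d_par * (1.0 - f1 / (f1 + f2))
        d_perp = max(d_perp, 1e-13)
        return np.exp(-self.b * (d_perp + (self.d_par - d_perp) * c2))

    def csf(self) -> np.ndarray:
        if self._csf_cache is None:
            self._csf_cache = np.exp(-self.b * self.d_iso)
        return self._csf_cache

    def signal(self, f, a_prime: float, S0: float, orientation) -> np.ndarray:
        """Total normalized signal per measurement (b = 0 predicts S0)."""
        f1, f2, f3, f4 = f
        s = f1 * self.intra(a_prime, orientation) + f3 * self.csf() + f4
        if f2 != 0.0:
            s = s + f2 * self.extra(f1, f2, orientation)
        return S0 * s


def total_signal(params: MMWMDParams, protocol: Protocol) -> SyntheticSignal:
    """MMWMD prediction for every measurement of a protocol."""
    fm = ForwardModel(protocol, d_par=params.d_par, d_iso=params.d_iso)
    vals = fm.signal(params.f, params.a_prime, params.S0, params.orientation)
    return SyntheticSignal(vals, protocol, noise_free=True)


# ---------------------------------------------------------------------------
# Fisher information

#: Free parameters for information analysis: three independent fractions
#: (f4 = 1 - f1 - f2 - f3), the diameter index (μm) and the signal scale.
FREE_PARAMS = ("f1", "f2", "f3", "a_prime", "S0")
A_PRIME_INDEX = FREE_PARAMS.index("a_prime")


def _theta_from_params(params: MMWMDParams) -> np.ndarray:
    return np.array([params.f[0], params.f[1], params.f[2], params.a_prime, params.S0])


def _signal_from_theta(theta: np.ndarray, fm: ForwardModel, orientation) -> np.ndarray:
    f1, f2, f3, a, S0 = theta
    f4 = 1.0 - f1 - f2 - f3
    return fm.signal((f1, f2, f3, f4), max(a, 0.0), S0, orientation)


def measurement_jacobian(
    params: MMWMDParams, protocol: Protocol, rel_step: float = 1e-4
) -> np.ndarray:
    """Numerical Jacobian dS/dtheta, shape (n_meas, n_free), central differences."""
    fm = ForwardModel(protocol, d_par=params.d_par, d_iso=params.d_iso)
    theta0 = _theta_from_params(params)
    J = np.empty((fm.n_meas, len(theta0)))
    for j, t0 in enumerate(theta0):
        h = rel_step * max(abs(t0), 1e-3)
        tp, tm = theta0.copy(), theta0.copy()
        tp[j] += h
        tm[j] -= h
        J[:, j] = (
            _signal_from_theta(tp, fm, params.orientation)
            - _signal_from_theta(tm, fm, params.orientation)
        ) / (2.0 * h)
    return J


def fisher_information(params: MMWMDParams, protocol: Protocol, snr: float) -> np.ndarray:
    """Gaussian-noise Fisher information matrix over :data:`FREE_PARAMS`.

    Noise standard deviation is ``S0 / snr`` (offset-Gaussian justification
    for magnitude data at moderate SNR); ``FIM = J^T J / sigma^2``.
    """
    if snr <= 0:
        raise ValueError("snr must be positive")
    J = measurement_jacobian(params, protocol)
    sigma = params.S0 / snr
    return J.T @ J / sigma**2


def crlb(params: MMWMDParams, protocol: Protocol, snr: float,
         param: str = "a_prime") -> float:
    """Cramér–Rao lower bound on the variance of one free parameter.

    Returns ``inf`` (rather than raising) when the information matrix is
    singular, i.e. the parameter set is unidentifiable under the protocol.
    """
    F = fisher_information(params, protocol, snr)
    idx = FREE_PARAMS.index(param)
    try:
        Finv = np.linalg.inv(F)
    except np.linalg.LinAlgError:
        return float("inf")
    v = Finv[idx, idx]
    if not np.isfinite(v) or v < 0:
        return float("inf")
    return float(v)
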