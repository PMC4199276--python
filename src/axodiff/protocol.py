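"""Multishell PGSE protocols and their derived diffusion quantities.

A pulsed-gradient spin-echo (PGSE) measurement is defined by the gradient
amplitude ``G``, pulse width ``delta``, pulse separation ``Delta`` and echo
time ``TE``.  The derived quantities are the effective diffusion time
``t_d = Delta - delta/3``, the wavenumber ``q = (2*pi)^-1 * gamma * delta * G``
and the diffusion weighting ``b = (2*pi*q)**2 * t_d``.

Public interfaces accept the units the field's protocol tables print
(mT/m, ms, micrometres); all internal computation is in SI.  The module also
ships the optimized ex-vivo ActiveAx multishell protocols for maximal
gradient strengths of 60, 140, 200 and 300 mT/m (plus the two
artificially-long-T2 variants) as built-in fixtures, and reads/writes
Camino-style STEJSKALTANNER scheme files.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "GAMMA",
    "PGSEShell",
    "Protocol",
    "diffusion_time",
    "wavenumber",
    "inverse_wavenumber_um",
    "bvalue",
    "snr_at_te",
    "generate_directions",
    "make_shell",
    "table_fixtures",
    "load_scheme",
    "save_scheme",
]

#: Proton gyromagnetic ratio used throughout, rad/s/T.  Fixed to
#: 2*pi*42.57e6 (the value the protocol tables were computed with) rather
#: than the CODATA figure, so printed table quantities are reproduced.
GAMMA = 2.0 * math.pi * 42.57e6

#: Reference TE (ms) and SNR for SNR-versus-TE adjustment of simulations.
SNR_REF = 20.0
TE_REF_MS = 62.7


def diffusion_time(delta: float, Delta: float) -> float:
    """Effective PGSE diffusion time ``t_d = Delta - delta/3``.

    Parameters are pulse width and separation in any common time unit;
    the result is in the same unit.
    """
    if not delta < Delta:
        raise ValueError(f"require delta < Delta, got delta={delta}, Delta={Delta}")
    return Delta - delta / 3.0


def wavenumber(G: float, delta: float) -> float:
    """PGSE wavenumber ``q = gamma * delta * G / (2*pi)`` in 1/m.

    ``G`` in mT/m, ``delta`` in ms.
    """
    if G < 0 or delta < 0:
        raise ValueError("G and delta must be non-negative")
    return GAMMA * (delta * 1e-3) * (G * 1e-3) / (2.0 * math.pi)


def inverse_wavenumber_um(G: float, delta: float) -> float:
    """Length scale ``1/q`` in micrometres for ``G`` in mT/m, ``delta`` in ms."""
    q = wavenumber(G, delta)
    if q == 0.0:
        return math.inf
    return 1e6 / q


def bvalue(G: float, delta: float, Delta: float) -> float:
    """Diffusion weighting ``b = (2*pi*q)**2 * t_d`` in s/mm².

    ``G`` in mT/m, ``delta`` and ``Delta`` in ms.
    """
    if not delta < Delta:
        raise ValueError(f"require delta < Delta, got delta={delta}, Delta={Delta}")
    q = wavenumber(G, delta)
    td_s = diffusion_time(delta, Delta) * 1e-3
    return (2.0 * math.pi * q) ** 2 * td_s / 1e6


def snr_at_te(snr_ref: float, te_ref: float, te: float, T2: float) -> float:
    """SNR rescaled from a reference echo time by mono-exponential T2 decay.

    ``snr_ref * exp((te_ref - te) / T2)``; all times in ms.  Shorter echo
    times give higher SNR.
    """
    if T2 <= 0:
        raise ValueError("T2 must be positive")
    return snr_ref * math.exp((te_ref - te) / T2)


# ---------------------------------------------------------------------------
# gradient direction sets


def generate_directions(n: int, seed: int = 0, n_iter: int = 200) -> np.ndarray:
    """Spread ``n`` unit vectors on the sphere by antipodal electrostatic repulsion.

    Points are initialised at random (seeded) and relaxed under a Coulomb-like
    repulsion that treats each point and its antipode as charges, the standard
    construction for diffusion gradient schemes.  Returns an (n, 3) array of
    unit vectors; no two are antipodal copies of each other.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    x = rng.standard_normal((n, 3))
    x /= np.linalg.norm(x, axis=1, keepdims=True)
    if n == 1:
        return x
    step = 0.1
    for it in range(n_iter):
        # force from every other point and its antipode
        diff = x[:, None, :] - x[None, :, :]
        dist2 = np.sum(diff**2, axis=-1) + np.eye(n)
        f = np.sum(diff / dist2[..., None] ** 1.5, axis=1)
        diffa = x[:, None, :] + x[None, :, :]
        dist2a = np.sum(diffa**2, axis=-1) + 1e-12
        f += np.sum(diffa / dist2a[..., None] ** 1.5, axis=1)
        # project force onto the tangent plane and take a small step
        f -= np.sum(f * x, axis=1, keepdims=True) * x
        nrm = np.linalg.norm(f, axis=1, keepdims=True)
        nrm[nrm == 0] = 1.0
        x = x + step * f / nrm
        x /= np.linalg.norm(x, axis=1, keepdims=True)
        step *= 0.98
    return x


# ---------------------------------------------------------------------------
# shells and protocols


@dataclass
class PGSEShell:
    """One HARDI shell: shared pulse parameters plus a set of directions.

    Units as printed in protocol tables: ``G`` mT/m, times ms.  A ``b = 0``
    shell has ``G = 0`` and all-zero direction rows.
    """

    n_meas: int
    G: float
    delta: float
    Delta: float
    TE: float
    directions: np.ndarray = field(default_factory=lambda: np.zeros((0, 3)))

    def __post_init__(self) -> None:
        self.directions = np.asarray(self.directions, dtype=float)
        if self.directions.size == 0:
            self.directions = np.zeros((self.n_meas, 3))
        if self.directions.shape != (self.n_meas, 3):
            raise ValueError("directions must have shape (n_meas, 3)")
        if not (0 <= self.delta < self.Delta):
            raise ValueError("require 0 <= delta < Delta")
        if self.Delta + self.delta > self.TE + 1e-9:
            raise ValueError("require Delta + delta <= TE")
        if self.G < 0:
            raise ValueError("G must be non-negative")
        norms = np.linalg.norm(self.directions, axis=1)
        if self.G > 0 and not np.allclose(norms, 1.0, atol=1e-9):
            raise ValueError("directions of a diffusion-weighted shell must be unit vectors")

    @property
    def is_b0(self) -> bool:
        return self.G == 0.0

    @property
    def t_d(self) -> float:
        """Diffusion time in ms."""
        return diffusion_time(self.delta, self.Delta)

    @property
    def q(self) -> float:
        """Wavenumber in 1/m."""
        return wavenumber(self.G, self.delta)

    @property
    def one_over_q_um(self) -> float:
        """Probed length scale 1/q in micrometres."""
        return inverse_wavenumber_um(self.G, self.delta)

    @property
    def b(self) -> float:
        """b-value in s/mm²."""
        return bvalue(self.G, self.delta, self.Delta)


@dataclass
class Protocol:
    """An ordered list of PGSE shells; by convention the first is b = 0."""

    shells: list[PGSEShell]
    G_max: float
    assumed_T2: float = 50.0
    assumed_T1: float = 800.0
    name: str = ""

    def __post_init__(self) -> None:
        for s in self.shells:
            if s.G > self.G_max + 1e-9:
                raise ValueError(
                    f"shell G={s.G} mT/m exceeds protocol G_max={self.G_max} mT/m"
                )

    @property
    def total_meas(self) -> int:
        return sum(s.n_meas for s in self.shells)

    @property
    def dw_shells(self) -> list[PGSEShell]:
        return [s for s in self.shells if not s.is_b0]

    def flatten(self) -> dict[str, np.ndarray]:
        """Per-measurement arrays in SI units.

        Returns a dict with keys ``G`` (T/m), ``delta``/``Delta``/``TE`` (s),
        ``b`` (s/m²), ``dirs`` (n, 3) and ``shell_index``.
        """
        G, de, De, TE, b, dirs, idx = [], [], [], [], [], [], []
        for k, s in enumerate(self.shells):
            G.append(np.full(s.n_meas, s.G * 1e-3))
            de.append(np.full(s.n_meas, s.delta * 1e-3))
            De.append(np.full(s.n_meas, s.Delta * 1e-3))
            TE.append(np.full(s.n_meas, s.TE * 1e-3))
            b.append(np.full(s.n_meas, s.b * 1e6))
            dirs.append(s.directions)
            idx.append(np.full(s.n_meas, k, dtype=int))
        return {
            "G": np.concatenate(G),
            "delta": np.concatenate(de),
            "Delta": np.concatenate(De),
            "TE": np.concatenate(TE),
            "b": np.concatenate(b),
            "dirs": np.concatenate(dirs, axis=0),
            "shell_index": np.concatenate(idx),
        }


def make_shell(
    n_meas: int, G: float, delta: float, Delta: float, TE: float, seed: int = 0
) -> PGSEShell:
    """Build a shell, generating a seeded spread direction set (or zeros for b=0)."""
    if G == 0:
        dirs = np.zeros((n_meas, 3))
    else:
        dirs = generate_directions(n_meas, seed=seed)
    return PGSEShell(n_meas, G, delta, Delta, TE, dirs)


# ---------------------------------------------------------------------------
# built-in protocol fixtures
#
# (n_meas, G mT/m, delta ms, Delta ms) per diffusion-weighted shell; TE ms is
# shared within a protocol.  The b=0 shell count is the stated 360-measurement
# total minus the printed shell counts.

_TOTAL_MEAS = 360

_TABLE1 = {
    "ActiveAx060": (60.0, 67.2, [(89, 60, 15.9, 22.4), (98, 54, 15.9, 43.3), (105, 60, 26.4, 32.9)]),
    "ActiveAx140": (140.0, 49.5, [(100, 140, 10.4, 16.5), (105, 108, 11.2, 29.9), (84, 140, 17.4, 23.9)]),
    "ActiveAx200": (200.0, 43.0, [(102, 200, 7.7, 14.2), (106, 153, 8.8, 25.5), (81, 200, 13.8, 20.4)]),
    "ActiveAx300": (300.0, 35.9, [(103, 300, 5.6, 12.1), (106, 219, 7.0, 20.4), (80, 300, 10.5, 16.9)]),
}

# The long-T2 variants print pulse parameters only; counts are split equally
# (90 per shell including b=0) and TE is set just above the longest delta+Delta.
_TABLE2 = {
    "T2_400": (300.0, 111.0, 400.0, [(90, 57, 11.8, 99.1), (90, 300, 7.2, 13.7), (90, 137, 9.3, 101.6)]),
    "T2_4000": (300.0, 346.1, 4000.0, [(90, 3.9, 146.0, 200.0), (90, 300, 7.5, 14.0), (90, 8.7, 146.0, 200.0)]),
}


def table_fixtures(seed: int = 0) -> dict[str, Protocol]:
    """The optimized ex-vivo ActiveAx protocols as :class:`Protocol` objects.

    Keys ``ActiveAx060/140/200/300`` carry the four G_max protocols
    (T2 = 50 ms, T1 = 800 ms, 360 measurements each, the b=0 shell holding the
    remainder of the printed shell counts); ``T2_400`` and ``T2_4000`` are the
    300 mT/m protocols re-optimized for artificially long T2.  Direction sets
    are generated deterministically from ``seed``.
    """
    out: dict[str, Protocol] = {}
    for name, (gmax, te, rows) in _TABLE1.items():
        n_b0 = _TOTAL_MEAS - sum(r[0] for r in rows)
        shells = [make_shell(n_b0, 0.0, rows[0][2], rows[0][3], te)]
        for j, (n, G, de, De) in enumerate(rows):
            shells.append(make_shell(n, G, de, De, te, seed=seed + 101 * j + 7))
        out[name] = Protocol(shells, G_max=gmax, assumed_T2=50.0, assumed_T1=800.0, name=name)
    for name, (gmax, te, t2, rows) in _TABLE2.items():
        n_b0 = _TOTAL_MEAS - sum(r[0] for r in rows)
        shells = [make_shell(n_b0, 0.0, rows[0][2], rows[0][3], te)]
        for j, (n, G, de, De) in enumerate(rows):
            shells.append(make_shell(n, G, de, De, te, seed=seed + 101 * j + 7))
        out[name] = Protocol(shells, G_max=gmax, assumed_T2=t2, assumed_T1=800.0, name=name)
    return out


# ---------------------------------------------------------------------------
# Camino-style scheme file I/O

_SCHEME_HEADER = "VERSION: STEJSKALTANNER"


def save_scheme(protocol: Protocol, path: str | Path) -> None:
    """Write a STEJSKALTANNER scheme file (SI units, one measurement per line).

    Columns: gx gy gz |G| (T/m), Delta (s), delta (s), TE (s).  b=0 lines carry
    a zero direction vector.
    """
    lines = [_SCHEME_HEADER]
    for s in protocol.shells:
        for d in s.directions:
            lines.append(
                f"{d[0]:.16g} {d[1]:.16g} {d[2]:.16g} "
                f"{s.G * 1e-3:.16g} {s.Delta * 1e-3:.16g} {s.delta * 1e-3:.16g} {s.TE * 1e-3:.16g}"
            )
    Path(path).write_text("\n".join(lines) + "\n")


class SchemeParseError(ValueError):
    """Raised for malformed scheme files; names the offending line."""


def load_scheme(
    path: str | Path,
    G_max: float | None = None,
    assumed_T2: float = 50.0,
    assumed_T1: float = 800.0,
) -> Protocol:
    """Read a STEJSKALTANNER scheme file back into a :class:`Protocol`.

    Consecutive lines sharing pulse parameters are grouped into shells.  If
    ``G_max`` (mT/m) is given, any line exceeding it raises; otherwise G_max
    is taken as the largest amplitude present (0 for an empty file).
    """
    text = Path(path).read_text().splitlines()
    rows: list[tuple[np.ndarray, float, float, float, float]] = []
    for i, line in enumerate(text, start=1):
        stripped = line.strip()
        if not stripped or stripped.upper().startswith("VERSION"):
            continue
        parts = stripped.split()
        if len(parts) != 7:
            raise SchemeParseError(f"line {i}: expected 7 fields, got {len(parts)}")
        try:
            vals = [float(p) for p in parts]
        except ValueError as exc:
            raise SchemeParseError(f"line {i}: non-numeric field ({exc})") from None
        d = np.array(vals[:3])
        Gmtm = vals[3] * 1e3
        Delta_ms, delta_ms, TE_ms = vals[4] * 1e3, vals[5] * 1e3, vals[6] * 1e3
        rows.append((d, Gmtm, delta_ms, Delta_ms, TE_ms))

    if not rows:
        return Protocol([], G_max=G_max if G_max is not None else 0.0,
                        assumed_T2=assumed_T2, assumed_T1=assumed_T1)

    inferred_gmax = max(r[1] for r in rows)
    gmax = inferred_gmax if G_max is None else G_max
    shells: list[PGSEShell] = []
    group: list[np.ndarray] = []
    key = None
    for d, G, de, De, TE in rows + [(None, None, None, None, None)]:
        k = (G, de, De, TE)
        if key is None:
            key = k
        if k != key:
            dirs = np.vstack(group)
            shells.append(PGSEShell(len(group), key[0], key[1], key[2], key[3], dirs))
            group, key = [], k
        if d is not None:
            group.append(d)
    return Protocol(shells, G_max=gmax, assumed_T2=assumed_T2, assumed_T1=assumed_T1)
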