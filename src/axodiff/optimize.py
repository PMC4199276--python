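"""Greedy reassignment of measurements among HARDI shells under a CRLB objective.

Given a fixed set of shell pulse parameters (M diffusion-weighted shells plus
one b = 0 shell) and a total measurement budget (default 360), the optimizer
starts from an equal split and repeatedly moves the single measurement whose
reassignment most increases the design objective, stopping when no move
improves it.  The objective scores an assignment by the Cramér–Rao lower
bound on the axon diameter index: per-shell unit information matrices are
precomputed for each a-priori tissue model, the assignment's information is
the count-weighted sum, and the score aggregates ``-CRLB(a')`` across the
a-priori models (mean by default).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .model import (
    A_PRIME_INDEX,
    MMWMDParams,
    measurement_jacobian,
)
from .protocol import PGSEShell, Protocol, generate_directions

__all__ = [
    "ShellAssignment",
    "default_apriori_models",
    "shell_unit_fims",
    "design_objective",
    "greedy_reassign",
]

#: Sentinel for assignments carrying no diameter information.
WORST = -math.inf


@dataclass
class ShellAssignment:
    """Measurement counts per shell (index 0 = b = 0 shell) and their score."""

    counts: np.ndarray
    objective: float = WORST

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=int)
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")

    @property
    def total(self) -> int:
        return int(self.counts.sum())


def default_apriori_models(
    f1: float = 0.7, diameters=(1.0, 4.0, 20.0), d_par: float = 0.45e-9
) -> list[MMWMDParams]:
    """The a-priori tissue models the protocol is optimized for.

    Diameters bracket the plausible range (1, 4 and 20 μm) at an
    intracellular fraction of 0.7 and the ex-vivo parallel diffusivity.
    """
    return [
        MMWMDParams(f=(f1, 1.0 - f1, 0.0, 0.0), a_prime=a, d_par=d_par)
        for a in diameters
    ]


def shell_unit_fims(
    shells: list[PGSEShell],
    apriori_models: list[MMWMDParams] | None = None,
    snr: float = 20.0,
    n_dirs: int = 30,
    seed: int = 0,
) -> np.ndarray:
    """Per-shell, per-model mean single-measurement information matrices.

    Each shell's pulse parameters are paired with a representative spread
    direction set — the shell's own directions when it carries any, otherwise
    a generated set of size ``n_dirs`` (direction geometry is secondary at
    realistic counts); the returned array has shape
    (n_shells, n_models, p, p) where p is the number of free model parameters.
    """
    if apriori_models is None:
        apriori_models = default_apriori_models()
    if snr <= 0:
        raise ValueError("snr must be positive")
    fallback = generate_directions(n_dirs, seed=seed)
    out = []
    for shell in shells:
        if shell.is_b0:
            rep = PGSEShell(1, 0.0, shell.delta, shell.Delta, shell.TE,
                            np.zeros((1, 3)))
            nd = 1
        else:
            dirs = shell.directions if shell.n_meas > 0 else fallback
            nd = len(dirs)
            rep = PGSEShell(nd, shell.G, shell.delta, shell.Delta, shell.TE, dirs)
        proto = Protocol([rep], G_max=max(shell.G, 1e-9))
        per_model = []
        for m in apriori_models:
            J = measurement_jacobian(m, proto)
            sigma = m.S0 / snr
            per_model.append(J.T @ J / (nd * sigma**2))
        out.append(per_model)
    return np.asarray(out)


def _crlb_from_fim(F: np.ndarray) -> float:
    try:
        Finv = np.linalg.inv(F)
    except np.linalg.LinAlgError:
        return math.inf
    v = Finv[A_PRIME_INDEX, A_PRIME_INDEX]
    if not np.isfinite(v) or v <= 0:
        return math.inf
    return float(v)


def design_objective(
    counts: np.ndarray,
    unit_fims: np.ndarray,
    is_b0: np.ndarray,
    aggregate: str = "mean",
) -> float:
    """Score an assignment: aggregated ``-CRLB(a')`` across a-priori models.

    ``counts`` per shell, ``unit_fims`` from :func:`shell_unit_fims`,
    ``is_b0`` marking the b = 0 shell(s).  Returns the :data:`WORST` sentinel
    when no diffusion-weighted measurement is assigned or the information
    matrix is singular for some model.  Adding measurements to any shell can
    only add (positive semi-definite) information, so the objective is
    monotone non-decreasing in every count.
    """
    counts = np.asarray(counts, dtype=float)
    if counts.sum() <= 0 or np.all(counts[~np.asarray(is_b0, bool)] == 0):
        return WORST
    n_models = unit_fims.shape[1]
    scores = np.empty(n_models)
    for m in range(n_models):
        F = np.tensordot(counts, unit_fims[:, m], axes=(0, 0))
        c = _crlb_from_fim(F)
        if not np.isfinite(c):
            return WORST
        scores[m] = -c
    if aggregate == "mean":
        return float(np.mean(scores))
    if aggregate == "min":
        return float(np.min(scores))
    if aggregate == "product":
        # product of CRLBs, negated: maximize by minimizing the product
        return -float(np.prod(-scores))
    raise ValueError(f"unknown aggregate {aggregate!r}")


def greedy_reassign(
    initial: ShellAssignment,
    unit_fims: np.ndarray,
    is_b0: np.ndarray,
    aggregate: str = "mean",
    tol: float = 1e-12,
    max_steps: int | None = None,
) -> tuple[ShellAssignment, list[dict]]:
    """Greedy one-measurement reassignment until no move improves the objective.

    At each step every (source, destination) pair is scored and the move with
    the largest strict increase is taken; ties break toward the lowest
    destination shell index.  Returns the final assignment and a trace of
    moves ``{step, from, to, objective}`` with strictly increasing objective
    values.  The total count is conserved at every step.
    """
    counts = initial.counts.copy()
    n_shells = len(counts)
    if max_steps is None:
        max_steps = int(counts.sum()) * n_shells * 4
    cur = design_objective(counts, unit_fims, is_b0, aggregate)
    trace: list[dict] = []
    for step in range(max_steps):
        best_gain = tol
        best_move = None
        for src in range(n_shells):
            if counts[src] == 0:
                continue
            for dst in range(n_shells):
                if dst == src:
                    continue
                counts[src] -= 1
                counts[dst] += 1
                obj = design_objective(counts, unit_fims, is_b0, aggregate)
                counts[src] += 1
                counts[dst] -= 1
                gain = obj - cur
                if gain > best_gain or (
                    best_move is not None
                    and abs(gain - best_gain) <= tol
                    and dst < best_move[1]
                ):
                    if gain > tol:
                        best_gain = gain
                        best_move = (src, dst, obj)
        if best_move is None:
            break
        src, dst, obj = best_move
        counts[src] -= 1
        counts[dst] += 1
        cur = obj
        trace.append({"step": step, "from": src, "to": dst, "objective": obj})
    return ShellAssignment(counts, objective=cur), trace
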