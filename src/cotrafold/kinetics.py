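"""Deterministic master-equation kinetics over representative structures.

Occupancies evolve as dp/dt = R p with a column-generator rate matrix
built from Arrhenius rates.  The propagator exploits detailed balance:
with Ω = diag(sqrt(p∞)), U = Ω⁻¹RΩ is symmetric, so one real
eigendecomposition per transcription step serves every requested time
point.  A dense matrix-exponential (Padé) fallback covers numerically
hostile cases.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence as Seq, Tuple

import numpy as np
import scipy.linalg

from .coarse_graining import CoarseLandscape
from .energy_model import GAS_CONSTANT
from .expansion import rate_from_saddle
from .rna_structures import Structure

#: Occupancies below this are treated as zero before renormalization.
OCCUPANCY_FLOOR = 1e-16

#: Points in the linear time regime.
LINEAR_POINTS = 10

#: Points per decade in the logarithmic regime.
LOG_POINTS_PER_DECADE = 30


class DetailedBalanceError(ValueError):
    """The rate matrix violates detailed balance beyond tolerance."""


@dataclass
class TimeGrid:
    """A linear regime [t0, t1] and a logarithmic regime (t1, t8]."""

    t1: float
    t8: float
    t0: float = 0.0
    linear_points: int = LINEAR_POINTS
    log_points_per_decade: int = LOG_POINTS_PER_DECADE

    def __post_init__(self) -> None:
        if not (self.t0 < self.t1 <= self.t8):
            raise ValueError("need t0 < t1 <= t8")

    def linear_times(self) -> np.ndarray:
        return np.linspace(self.t0, self.t1, self.linear_points + 1)[1:]

    def log_times(self) -> np.ndarray:
        if self.t8 <= self.t1:
            return np.empty(0)
        decades = math.log10(self.t8 / self.t1)
        count = max(int(math.ceil(decades * self.log_points_per_decade)), 1)
        return np.geomspace(self.t1, self.t8, count + 1)[1:]

    def all_times(self) -> np.ndarray:
        return np.concatenate([self.linear_times(), self.log_times()])


def lookahead_times(
    l: int,
    L: int,
    t1_per_nt: float,
    t_end: float,
    pause_sites: Optional[Dict[int, float]] = None,
) -> TimeGrid:
    """Time grid for the simulation at transcript length ``l``.

    During transcription the logarithmic regime looks ahead to the
    projected end of transcription, t8 = Σ_{k=l+1..L} t1_k, where t1_k is
    the extension time at length k (plus any pause).  After transcription
    (l = L) it runs to the post-transcriptional time ``t_end``.
    """
    if not 1 <= l <= L:
        raise ValueError("need 1 <= l <= L")
    pauses = pause_sites or {}
    t1 = t1_per_nt + pauses.get(l, 0.0)
    if l == L:
        return TimeGrid(t1=min(t1_per_nt, t_end) if t_end > 0 else t1_per_nt, t8=t_end)
    t8 = sum(t1_per_nt + pauses.get(k, 0.0) for k in range(l + 1, L + 1))
    return TimeGrid(t1=t1, t8=max(t8, t1))


def build_rate_matrix(
    coarse: CoarseLandscape, k0: float, T: float
) -> Tuple[np.ndarray, List[Structure]]:
    """Column-generator rate matrix over sorted representatives.

    R[i, j] = k_{j→i} for i ≠ j and R[ii] = −Σ_j k_{i→j}; every column
    sums to zero.  ``T`` in Kelvin.
    """
    reps = coarse.representatives
    index = {r: i for i, r in enumerate(reps)}
    n = len(reps)
    R = np.zeros((n, n))
    for (a, b), saddle in coarse.edges.items():
        ia, ib = index[a], index[b]
        R[ib, ia] = rate_from_saddle(coarse.energies[a], saddle, k0, T)
        R[ia, ib] = rate_from_saddle(coarse.energies[b], saddle, k0, T)
    np.fill_diagonal(R, 0.0)
    np.fill_diagonal(R, -R.sum(axis=0))
    return R, reps


def boltzmann_distribution(energies: Seq[float], RT: float) -> np.ndarray:
    e = np.asarray(energies, dtype=float)
    w = np.exp(-(e - e.min()) / RT)
    return w / w.sum()


def equilibrium_distribution(
    R: np.ndarray, energies: Seq[float], RT: float, tol: float = 1e-6
) -> np.ndarray:
    """Stationary distribution from detailed balance (Boltzmann on the reps).

    Raises :class:`DetailedBalanceError` when R is inconsistent with the
    Boltzmann distribution implied by the energies — that signals a bug
    upstream in saddle bookkeeping, not a numerical issue.
    """
    p = boltzmann_distribution(energies, RT)
    n = len(p)
    for i in range(n):
        for j in range(i + 1, n):
            fij = p[j] * R[i, j]  # flow j -> i
            fji = p[i] * R[j, i]
            scale = max(fij, fji, 1e-300)
            if abs(fij - fji) / scale > tol and max(fij, fji) > 1e-30:
                raise DetailedBalanceError(
                    f"detailed balance violated between states {i} and {j}"
                )
    return p


def propagate(
    R: np.ndarray,
    p0: np.ndarray,
    times: Seq[float],
    p_inf: Optional[np.ndarray] = None,
    energies: Optional[Seq[float]] = None,
    RT: Optional[float] = None,
) -> np.ndarray:
    """Occupancy vectors at the requested times (rows) via p_t = e^{Rt} p0.

    Primary path: symmetrized eigendecomposition using Ω = diag(sqrt(p∞));
    fallback: dense Padé matrix exponential per time point.  Outputs are
    clipped at zero and renormalized.
    """
    times = np.asarray(times, dtype=float)
    p0 = np.asarray(p0, dtype=float)
    n = len(p0)
    if n == 1:
        return np.ones((len(times), 1))
    if not np.all(np.isfinite(R)) or not np.all(np.isfinite(p0)):
        raise ValueError("non-finite input")
    if p_inf is None:
        if energies is None or RT is None:
            raise ValueError("need p_inf or (energies, RT)")
        p_inf = boltzmann_distribution(energies, RT)

    out = _propagate_eigen(R, p0, times, p_inf)
    if out is None:
        out = _propagate_expm(R, p0, times)
    out = np.where(out < OCCUPANCY_FLOOR, 0.0, np.clip(out, 0.0, None))
    out /= out.sum(axis=1, keepdims=True)
    return out


def _propagate_eigen(R, p0, times, p_inf) -> Optional[np.ndarray]:
    sqrt_p = np.sqrt(np.clip(p_inf, 1e-300, None))
    U = R * (sqrt_p[np.newaxis, :] / sqrt_p[:, np.newaxis])
    asym = np.max(np.abs(U - U.T)) / max(np.max(np.abs(U)), 1e-300)
    if asym > 1e-8:
        return None
    U = 0.5 * (U + U.T)
    try:
        lam, S = np.linalg.eigh(U)
    except np.linalg.LinAlgError:  # pragma: no cover
        return None
    lam = np.minimum(lam, 0.0)  # generator spectrum is non-positive
    y0 = S.T @ (p0 / sqrt_p)
    with np.errstate(under="ignore"):
        phases = np.exp(np.outer(times, lam))
    out = (phases * y0[np.newaxis, :]) @ S.T * sqrt_p[np.newaxis, :]
    if not np.all(np.isfinite(out)):
        return None
    if np.min(out) < -1e-6:  # eigen path went unstable; use the Padé fallback
        return None
    return out


def _propagate_expm(R, p0, times) -> np.ndarray:
    out = np.empty((len(times), len(p0)))
    order = np.argsort(times)
    sorted_times = np.asarray(times)[order]
    p = p0.copy()
    prev_t = 0.0
    for row, t in zip(order, sorted_times):
        dt = t - prev_t
        if dt > 0:
            p = scipy.linalg.expm(R * dt) @ p
        prev_t = t
        out[row] = p
    return out


def free_energy_functional(p: np.ndarray, energies: Seq[float], RT: float) -> float:
    """F(p) = Σ p_i (E_i + RT ln p_i); non-increasing under the dynamics."""
    p = np.asarray(p, dtype=float)
    e = np.asarray(energies, dtype=float)
    mask = p > 0
    return float(np.sum(p[mask] * (e[mask] + RT * np.log(p[mask]))))
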