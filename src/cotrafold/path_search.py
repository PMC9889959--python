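"""Direct-path search between structures and 1-D flooding of energy profiles.

A *direct* refolding path between structures x and y has exactly
d(x, y) + 1 steps: every move removes a pair of x \\ y or adds a pair of
y \\ x.  The beam search here mirrors the classic findpath heuristic: it
explores move orders level by level, keeping the ``width`` best partial
paths ranked by their saddle so far.  The production pipeline may instead
use the thermodynamic engine's own findpath (same contract, C speed); this
implementation is the self-contained reference used by the oracle tests.

Flooding turns a path's 1-D energy profile into δ-minima and the saddles
between them: an interior point is a δ-minimum when every escape to a
strictly lower point crosses a barrier of at least δ.  Path endpoints are
externally supplied candidates and are never merged away.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence as Seq, Tuple

from .energy_model import EnergyModel
from .rna_structures import Structure, _crosses, base_pair_distance

_EPS = 1e-9


@dataclass
class DirectPath:
    """An ordered direct path with per-step energies."""

    steps: List[Structure]
    energies: List[float]
    width: int

    @property
    def saddle(self) -> float:
        return max(self.energies)

    def __len__(self) -> int:
        return len(self.steps)


@dataclass
class FloodResult:
    """δ-minima of a 1-D profile and the saddles linking adjacent minima."""

    minima: List[int]
    minima_energies: List[float]
    saddles: List[Tuple[int, float]]  # (index of maximum, energy), one per adjacent pair


def _valid_addition(pairs: frozenset, i: int, j: int) -> bool:
    for p, q in pairs:
        if i in (p, q) or j in (p, q):
            return False
    return not _crosses(i, j, pairs)


def find_direct_path(
    em: EnergyModel, x: Structure, y: Structure, width: Optional[int] = None
) -> DirectPath:
    """Bounded-width search for a minimal-saddle direct path from x to y.

    ``width`` defaults to 4·d(x, y).  Deterministic: ties between partial
    paths are broken by (saddle, current energy, dot-bracket).
    """
    d = base_pair_distance(x, y)
    if width is None:
        width = 4 * max(d, 1)
    to_remove = x.pairs - y.pairs
    to_add = y.pairs - x.pairs

    ex = em.free_energy(x)
    # beam entries: (saddle, energy, pairs, parent_entry)
    start = (ex, ex, x.pairs, None)
    beam = [start]
    for _ in range(d):
        expanded = {}
        for entry in beam:
            saddle, energy, pairs, _ = entry
            for p in to_remove & pairs:
                np_ = pairs - {p}
                if np_ not in expanded:
                    e = em.free_energy(Structure(np_, x.length, _trusted=True))
                    expanded[np_] = (max(saddle, e), e, np_, entry)
                else:
                    old = expanded[np_]
                    cand = (max(saddle, old[1]), old[1], np_, entry)
                    if cand[0] < old[0]:
                        expanded[np_] = cand
            for p in to_add - pairs:
                if not _valid_addition(pairs, *p):
                    continue
                np_ = pairs | {p}
                if np_ not in expanded:
                    e = em.free_energy(Structure(np_, x.length, _trusted=True))
                    expanded[np_] = (max(saddle, e), e, np_, entry)
                else:
                    old = expanded[np_]
                    cand = (max(saddle, old[1]), old[1], np_, entry)
                    if cand[0] < old[0]:
                        expanded[np_] = cand
        ranked = sorted(
            expanded.values(),
            key=lambda t: (t[0], t[1], Structure(t[2], x.length, _trusted=True).dot_bracket()),
        )
        beam = ranked[:width]
        if not beam:  # pragma: no cover - a direct path always exists
            raise RuntimeError("beam search lost all paths")
    best = next(e for e in beam if e[2] == y.pairs) if any(
        e[2] == y.pairs for e in beam
    ) else None
    if best is None:
        # the beam dropped the goal; fall back to the best entry that can
        # still be completed greedily (open remaining x-pairs first)
        best = _complete_greedily(em, x, y, beam[0])
        return best
    steps: List[Structure] = []
    energies: List[float] = []
    entry = best
    while entry is not None:
        steps.append(Structure(entry[2], x.length, _trusted=True))
        energies.append(entry[1])
        entry = entry[3]
    steps.reverse()
    energies.reverse()
    return DirectPath(steps, energies, width)


def _complete_greedily(em, x, y, entry) -> DirectPath:
    """Finish a partial path: remove leftover x-pairs, then add y-pairs."""
    saddle, energy, pairs, _ = entry
    steps = []
    energies = []
    e = entry
    while e is not None:
        steps.append(Structure(e[2], x.length, _trusted=True))
        energies.append(e[1])
        e = e[3]
    steps.reverse()
    energies.reverse()
    cur = pairs
    for p in sorted(cur - y.pairs):
        cur = cur - {p}
        s = Structure(cur, x.length, _trusted=True)
        steps.append(s)
        energies.append(em.free_energy(s))
    for p in sorted(y.pairs - cur):
        cur = cur | {p}
        s = Structure(cur, x.length, _trusted=True)
        steps.append(s)
        energies.append(em.free_energy(s))
    return DirectPath(steps, energies, 0)


def exhaustive_min_saddle(em: EnergyModel, x: Structure, y: Structure) -> float:
    """Minimal saddle over *all* direct paths, by exhaustive enumeration.

    Exponential in d(x, y); oracle for the beam search on small instances.
    """
    best = [float("inf")]
    to_remove = x.pairs - y.pairs
    to_add = y.pairs - x.pairs

    def rec(pairs: frozenset, saddle: float) -> None:
        if saddle >= best[0]:
            return
        if pairs == y.pairs:
            best[0] = saddle
            return
        for p in to_remove & pairs:
            np_ = pairs - {p}
            e = em.free_energy(Structure(np_, x.length, _trusted=True))
            rec(np_, max(saddle, e))
        for p in to_add - pairs:
            if _valid_addition(pairs, *p):
                np_ = pairs | {p}
                e = em.free_energy(Structure(np_, x.length, _trusted=True))
                rec(np_, max(saddle, e))

    rec(x.pairs, em.free_energy(x))
    return best[0]


def flood_path(energies: Seq[float], delta: float) -> FloodResult:
    """Identify δ-minima and inter-minima saddles of a 1-D energy profile.

    An interior index k is a δ-minimum iff every path along the profile to
    a strictly lower-energy index crosses a maximum of at least
    ``energies[k] + delta``.  Endpoints always count as minima.  Between
    adjacent minima the saddle is the maximum energy over the closed
    interval; at equal maxima the leftmost index is reported (profile
    points at the same level are treated left to right).
    """
    m = len(energies)
    if m < 2:
        raise ValueError("profile needs at least two points")
    if delta <= 0:
        raise ValueError("delta must be positive")

    def escapes(k: int) -> bool:
        # scan left
        high = energies[k]
        for j in range(k - 1, -1, -1):
            high = max(high, energies[j])
            if energies[j] < energies[k] - _EPS and high - energies[k] < delta - _EPS:
                return True
        high = energies[k]
        for j in range(k + 1, m):
            high = max(high, energies[j])
            if energies[j] < energies[k] - _EPS and high - energies[k] < delta - _EPS:
                return True
        return False

    minima = [0] + [k for k in range(1, m - 1) if not escapes(k)] + [m - 1]
    saddles: List[Tuple[int, float]] = []
    for a, b in zip(minima, minima[1:]):
        idx = a
        for k in range(a, b + 1):
            if energies[k] > energies[idx] + _EPS:
                idx = k
        saddles.append((idx, energies[idx]))
    return FloodResult(minima, [energies[k] for k in minima], saddles)


@dataclass
class Decomposition:
    """Outcome of analyzing a direct path between two candidates.

    Either a direct transition (``direct=True`` with its saddle energy) or
    a set of newly found intermediate candidates plus the subpath endpoint
    pairs that still need their own saddle search.
    """

    direct: bool
    saddle: Optional[float] = None
    candidates: Optional[List[Structure]] = None
    subpaths: Optional[List[Tuple[Structure, Structure]]] = None


def decompose_reaction(path: DirectPath, delta: float) -> Decomposition:
    """Split a direct path at interior δ-minima no higher than its endpoints.

    Interior δ-minima *above* both endpoints are short-lived: the reaction
    stays a single transition whose saddle is the global path maximum.
    Interior δ-minima at or below max(E_x, E_y) become new candidate
    structures, and the stretches between consecutive kept minima are
    returned as subpaths.
    """
    e = path.energies
    endpoint_max = max(e[0], e[-1])
    flood = flood_path(e, delta)
    keep = [
        k for k in flood.minima[1:-1] if e[k] <= endpoint_max + _EPS
    ]
    if not keep:
        return Decomposition(direct=True, saddle=max(e))
    bounds = [0] + keep + [len(e) - 1]
    subpaths = [
        (path.steps[a], path.steps[b]) for a, b in zip(bounds, bounds[1:])
    ]
    return Decomposition(
        direct=False,
        candidates=[path.steps[k] for k in keep],
        subpaths=subpaths,
    )
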