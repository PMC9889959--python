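"""Top-down coarse graining of a landscape into δ-minimum representatives.

Structures are processed from high to low energy.  A structure with a
*fast* escape (saddle within δ of its own energy) to an equal-or-lower
energy neighbor is transient: its occupancy flows to the minimal-saddle
neighbors and its reactions are contracted through it.  Everything else
is a δ-minimum and becomes a representative.  Total occupancy is
conserved exactly (up to floating point).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Set, Tuple

from .expansion import Landscape
from .rna_structures import Structure

_EPS = 1e-9


@dataclass
class CoarseLandscape:
    """Representatives with occupancies, representative reactions, and the
    mapping of each transient structure onto the representatives that
    absorbed its occupancy."""

    length: int
    energies: Dict[Structure, float]
    occupancies: Dict[Structure, float]
    edges: Dict[Tuple[Structure, Structure], float]
    basin_map: Dict[Structure, Dict[Structure, float]] = field(default_factory=dict)

    @property
    def representatives(self) -> List[Structure]:
        return sorted(self.energies)

    def total_occupancy(self) -> float:
        return sum(self.occupancies.values())

    def adjacency(self) -> Dict[Structure, Dict[Structure, float]]:
        adj: Dict[Structure, Dict[Structure, float]] = {x: {} for x in self.energies}
        for (a, b), s in self.edges.items():
            adj[a][b] = s
            adj[b][a] = s
        return adj

    def edges_as_text(self) -> str:
        """Same edge-list debug format as the full landscape."""
        lines = []
        for (a, b), saddle in sorted(
            self.edges.items(), key=lambda kv: (kv[0][0].dot_bracket(), kv[0][1].dot_bracket())
        ):
            lines.append(
                f"{a.dot_bracket()}\t{b.dot_bracket()}\t"
                f"{self.energies[a]:.2f}\t{self.energies[b]:.2f}\t{saddle:.2f}"
            )
        return "\n".join(lines)


def coarse_grain(landscape: Landscape, delta: float) -> CoarseLandscape:
    """Contract the landscape onto its δ-minima.

    Ties in the descending-energy order are broken by dot-bracket string
    so repeated runs are bit-identical.  A transient's occupancy is split
    equally among its minimal-saddle neighbors; every fast-reachable
    neighbor of a transient is connected to all its other neighbors (two
    slow-only neighbors are not connected), the new saddle being the
    larger of the two contracted saddles, keeping minima over duplicates.
    """
    if delta <= 0:
        raise ValueError("delta must be positive")
    energies = dict(landscape.energies)
    occ = dict(landscape.occupancies)
    adj = landscape.adjacency()

    order = sorted(energies, key=lambda s: (-energies[s], s.dot_bracket()))
    flow: Dict[Structure, List[Structure]] = {}
    reps: Set[Structure] = set()

    for k in order:
        ek = energies[k]
        nbrs = adj[k]
        fast_lower = [
            x
            for x, saddle in nbrs.items()
            if energies[x] <= ek + _EPS and saddle - ek < delta - _EPS
        ]
        if not fast_lower:
            reps.add(k)
            continue
        # transient: occupancy to the minimal-saddle neighbors
        min_saddle = min(nbrs.values())
        targets = sorted(x for x, s in nbrs.items() if s <= min_saddle + _EPS)
        flow[k] = targets
        share = occ[k] / len(targets)
        for x in targets:
            occ[x] += share
        occ[k] = 0.0
        # contract reactions through k
        fast = [x for x, s in nbrs.items() if s - ek < delta - _EPS]
        for x in fast:
            for y in nbrs:
                if y == x:
                    continue
                saddle = max(nbrs[x], nbrs[y])
                old = adj[x].get(y)
                if old is None or saddle < old:
                    adj[x][y] = saddle
                    adj[y][x] = saddle
        for x in list(nbrs):
            del adj[x][k]
        del adj[k]

    # resolve transient -> representative weights through the flow DAG
    basin: Dict[Structure, Dict[Structure, float]] = {}

    def resolve(s: Structure) -> Dict[Structure, float]:
        if s in reps:
            return {s: 1.0}
        if s in basin:
            return basin[s]
        out: Dict[Structure, float] = {}
        targets = flow[s]
        w = 1.0 / len(targets)
        for t in targets:
            for r, f in resolve(t).items():
                out[r] = out.get(r, 0.0) + w * f
        basin[s] = out
        return out

    for s in flow:
        resolve(s)

    edges: Dict[Tuple[Structure, Structure], float] = {}
    for x in adj:
        for y, s in adj[x].items():
            key = (x, y) if x < y else (y, x)
            old = edges.get(key)
            if old is None or s < old:
                edges[key] = s
    return CoarseLandscape(
        length=landscape.length,
        energies={r: energies[r] for r in reps},
        occupancies={r: occ[r] for r in reps},
        edges=edges,
        basin_map=basin,
    )
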