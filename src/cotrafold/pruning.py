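"""Removal of low-occupancy representatives between transcription steps.

A representative whose occupancy stays below the threshold ``o``
throughout the look-ahead simulation is prunable; prunable structures are
removed greedily from the least occupied upward while the total removed
occupancy stays strictly below ``o``, so the surviving parents always
keep a combined occupancy of at least 1 − o.  Removed occupancy is
redistributed evenly over neighboring surviving representatives
(recursively through removed neighbors if necessary) — but only lazily:
a structure re-discovered during the next expansion keeps its occupancy.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Sequence as Seq, Set, Tuple

import numpy as np

from .expansion import Landscape
from .rna_structures import Structure

_EPS = 1e-12


@dataclass
class PruneReport:
    """Outcome of one pruning pass."""

    pruned: List[Tuple[Structure, float]]
    parents: Dict[Structure, float]
    #: pruned structure -> surviving representatives receiving its occupancy
    redistributed: Dict[Structure, List[Structure]] = field(default_factory=dict)


def select_prunable(
    lookahead: np.ndarray, reps: Seq[Structure], o: float
) -> Set[Structure]:
    """Representatives whose occupancy stays below ``o`` at every
    look-ahead time point (rows of ``lookahead``).  Structures that
    transiently rise above the threshold are exempt."""
    if o <= 0:
        return set()
    lookahead = np.asarray(lookahead)
    if lookahead.size == 0:
        return set()
    peak = lookahead.max(axis=0)
    return {r for r, pk in zip(reps, peak) if pk < o}


def prune(landscape: Landscape, prunable: Set[Structure], o: float) -> PruneReport:
    """Greedy removal in ascending occupancy order, cumulative < o (strict).

    ``landscape`` is modified in place: removed nodes disappear together
    with their edges.  Redistribution targets are computed over the
    landscape edges as of pruning time, walking through removed nodes to
    the nearest surviving representatives; the actual occupancy transfer
    is deferred to the next expansion (see the driver).
    """
    occ = landscape.occupancies
    ranked = sorted(prunable, key=lambda s: (occ[s], s.dot_bracket()))
    removed: List[Tuple[Structure, float]] = []
    cum = 0.0
    for s in ranked:
        if cum + occ[s] < o - _EPS:
            cum += occ[s]
            removed.append((s, occ[s]))
        else:
            break
    removed_set = {s for s, _ in removed}
    adj = landscape.adjacency()

    redistributed: Dict[Structure, List[Structure]] = {}
    for s, _ in removed:
        targets: List[Structure] = []
        frontier = {s}
        seen = {s}
        while frontier and not targets:
            nxt: Set[Structure] = set()
            for u in frontier:
                for v in adj[u]:
                    if v in seen:
                        continue
                    seen.add(v)
                    if v in removed_set:
                        nxt.add(v)
                    else:
                        targets.append(v)
            frontier = nxt
        redistributed[s] = sorted(targets)

    for s, _ in removed:
        landscape.remove_node(s)
    parents = dict(landscape.occupancies)
    return PruneReport(pruned=removed, parents=parents, redistributed=redistributed)
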