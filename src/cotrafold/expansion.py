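"""Per-nucleotide landscape expansion.

Each time a nucleotide is added, the set of parent structures is grown
into a set of candidate structures (helix fraying + constrained refolds +
the current MFE), a guiding neighborhood over the candidates is built from
base-pair distances, and every new guide/shortcut edge gets a saddle
energy from a direct-path search, recursively discovering intermediate
δ-minima where a single rate constant cannot describe the transition.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, FrozenSet, Iterable, List, Optional, Set, Tuple

from .energy_model import ENERGY_TOL, GAS_CONSTANT, EnergyModel
from .path_search import decompose_reaction, DirectPath, find_direct_path, flood_path
from .rna_structures import Pair, Sequence, Structure, base_pair_distance, parse_dotbracket

_EPS = 1e-9

#: Reaction-cache key: unordered pair of pair sets (transcript-length free,
#: valid across steps because energies follow the full-length convention).
EdgeKey = FrozenSet[FrozenSet[Pair]]


def edge_key(x: Structure, y: Structure) -> EdgeKey:
    return frozenset((x.pairs, y.pairs))


@dataclass
class Landscape:
    """Structures with energies/occupancies plus reversible reactions.

    Edges are stored once per unordered pair with their minimal observed
    saddle energy; rates follow from the Arrhenius model at simulation
    time.  Strong connectivity over the nodes is an invariant maintained
    by the expansion step.
    """

    length: int
    energies: Dict[Structure, float] = field(default_factory=dict)
    occupancies: Dict[Structure, float] = field(default_factory=dict)
    edges: Dict[Tuple[Structure, Structure], float] = field(default_factory=dict)

    def add_node(self, x: Structure, energy: float, occupancy: float = 0.0) -> None:
        if x not in self.energies:
            self.energies[x] = energy
            self.occupancies[x] = occupancy

    def _canon(self, x: Structure, y: Structure) -> Tuple[Structure, Structure]:
        return (x, y) if x < y else (y, x)

    def add_edge(self, x: Structure, y: Structure, saddle: float) -> None:
        if x == y:
            return
        lo = max(self.energies[x], self.energies[y])
        saddle = max(saddle, lo)  # a saddle can never undercut its endpoints
        key = self._canon(x, y)
        old = self.edges.get(key)
        if old is None or saddle < old:
            self.edges[key] = saddle

    def neighbors(self, x: Structure) -> Dict[Structure, float]:
        out: Dict[Structure, float] = {}
        for (a, b), s in self.edges.items():
            if a == x:
                out[b] = s
            elif b == x:
                out[a] = s
        return out

    def adjacency(self) -> Dict[Structure, Dict[Structure, float]]:
        adj: Dict[Structure, Dict[Structure, float]] = {x: {} for x in self.energies}
        for (a, b), s in self.edges.items():
            adj[a][b] = s
            adj[b][a] = s
        return adj

    def total_occupancy(self) -> float:
        return sum(self.occupancies.values())

    def remove_node(self, x: Structure) -> None:
        del self.energies[x]
        del self.occupancies[x]
        for key in [k for k in self.edges if x in k]:
            del self.edges[key]

    def edges_as_text(self) -> str:
        """Edge list for debugging: dot-brackets, energies, saddle."""
        lines = []
        for (a, b), saddle in sorted(
            self.edges.items(), key=lambda kv: (kv[0][0].dot_bracket(), kv[0][1].dot_bracket())
        ):
            lines.append(
                f"{a.dot_bracket()}\t{b.dot_bracket()}\t"
                f"{self.energies[a]:.2f}\t{self.energies[b]:.2f}\t{saddle:.2f}"
            )
        return "\n".join(lines)

    def connected_components(self) -> List[Set[Structure]]:
        adj = self.adjacency()
        seen: Set[Structure] = set()
        comps: List[Set[Structure]] = []
        for start in sorted(self.energies):
            if start in seen:
                continue
            comp = {start}
            stack = [start]
            while stack:
                u = stack.pop()
                for v in adj[u]:
                    if v not in comp:
                        comp.add(v)
                        stack.append(v)
            seen |= comp
            comps.append(comp)
        return comps


# ---------------------------------------------------------------------------
# fraying constraints
# ---------------------------------------------------------------------------


def _exterior_pairs(x: Structure) -> List[Pair]:
    """Outermost pairs (not enclosed by any other pair), 5' to 3'."""
    out = []
    for i, j in x.sorted_pairs:
        if not any(p < i and j < q for p, q in x.pairs):
            out.append((i, j))
    return out


def _helix_from(x: Structure, outer: Pair) -> List[Pair]:
    """The stack of pairs starting at ``outer`` going inward."""
    helix = [outer]
    i, j = outer
    while (i + 1, j - 1) in x.pairs:
        i, j = i + 1, j - 1
        helix.append((i, j))
    return helix


def _children(x: Structure, inner: Pair) -> List[Pair]:
    """Outermost pairs strictly inside ``inner``."""
    i, j = inner
    out = []
    for p, q in x.sorted_pairs:
        if i < p and q < j:
            if not any(
                a < p and q < b and (a, b) != inner and i < a for a, b in x.pairs
            ):
                out.append((p, q))
    return out


def _open_fraying_helix(x: Structure, outer: Pair, mfree: int) -> Set[Pair]:
    """Pairs to open for one fraying helix, growing inward until at least
    ``mfree`` nucleotides are liberated (or nothing is left to open)."""
    opened: Set[Pair] = set()
    frontier = [outer]
    while frontier:
        new_frontier: List[Pair] = []
        for pair in frontier:
            helix = _helix_from(Structure(x.pairs - opened, x.length), pair)
            opened |= set(helix)
            new_frontier.extend(_children(x, helix[-1]))
        kept = x.pairs - opened
        i, j = outer
        span = set(range(i, j + 1))
        fixed: Set[int] = set()
        for p, q in kept:
            if i <= p and q <= j:
                fixed |= set(range(p, q + 1))
        liberated = len(span - fixed)
        if liberated >= mfree or not new_frontier:
            break
        frontier = new_frontier
    return opened


def _constraint_string(x: Structure, opened: Set[Pair]) -> str:
    kept = x.pairs - opened
    chars = ["."] * x.length
    for i, j in kept:
        chars[i - 1] = "("
        chars[j - 1] = ")"
    for k in range(1, x.length + 1):
        if chars[k - 1] == "." and any(i < k < j for i, j in kept):
            chars[k - 1] = "x"
    return "".join(chars)


def fraying_constraints(seq: Sequence, parent: Structure, mfree: int) -> List[str]:
    """Fold constraints opening each fraying helix (and all at once).

    One constraint per exterior-loop-adjacent helix with that helix opened
    (extended inward when fewer than ``mfree`` nucleotides are liberated),
    plus one with every fraying helix opened simultaneously.  Enclosed
    helices and their loop regions stay fixed.  Duplicates are removed,
    preserving order.
    """
    ext = _exterior_pairs(parent)
    constraints: List[str] = []
    opened_sets = [_open_fraying_helix(parent, pair, mfree) for pair in ext]
    for opened in opened_sets:
        constraints.append(_constraint_string(parent, opened))
    if len(opened_sets) > 1:
        all_open: Set[Pair] = set()
        for o in opened_sets:
            all_open |= o
        constraints.append(_constraint_string(parent, all_open))
    if not constraints:
        constraints.append("." * parent.length)
    seen: Set[str] = set()
    unique = []
    for c in constraints:
        if c not in seen:
            seen.add(c)
            unique.append(c)
    return unique


# ---------------------------------------------------------------------------
# candidate structures
# ---------------------------------------------------------------------------


def find_candidates(
    em: EnergyModel, parents: Iterable[Structure], mfree: int, length: int
) -> Set[Structure]:
    """Parents plus fraying refolds that are at least as good, plus the MFE."""
    seq = em.seq_prefix(length)
    candidates: Set[Structure] = set()
    for parent in parents:
        candidates.add(parent)
        e_parent = em.free_energy(parent)
        for constraint in fraying_constraints(seq, parent, mfree):
            refold, e = em.constrained_mfe(constraint, length, enforce=True)
            if e <= e_parent + ENERGY_TOL + _EPS:
                candidates.add(refold)
    mfe_structure, _ = em.mfe(length)
    candidates.add(mfe_structure)
    return candidates


# ---------------------------------------------------------------------------
# guiding neighborhood
# ---------------------------------------------------------------------------


def guide_edges_from_distances(
    nodes: List[Structure],
) -> Tuple[Set[Tuple[Structure, Structure]], Set[Tuple[Structure, Structure]]]:
    """Pure distance-based guide and shortcut edges over ``nodes``.

    A guide edge (x, y) exists iff no third node i satisfies
    max{d(x,i), d(i,y)} < d(x,y) (strict, so distance ties never suppress
    an edge).  Then, for every node i and every pair of its guide
    neighbors (x, y), a shortcut edge is added when d(x,i) + d(i,y) >
    d(x,y).
    """
    import numpy as np

    nodes = sorted(nodes)
    n = len(nodes)
    d = np.zeros((n, n), dtype=np.int32)
    for a in range(n):
        pa = nodes[a].pairs
        for b in range(a + 1, n):
            d[a, b] = d[b, a] = len(pa ^ nodes[b].pairs)
    # min over intermediates i of max(d(a,i), d(i,b)); a guide edge exists
    # when no intermediate beats the direct distance strictly
    guide: Set[Tuple[int, int]] = set()
    big = d.max() + 1 if n else 0
    dmask = d.astype(np.int64)
    np.fill_diagonal(dmask, big)  # i = a or i = b never counts
    for a in range(n):
        via = np.maximum(dmask[a][:, None], dmask).min(axis=0)
        for b in range(a + 1, n):
            if via[b] >= d[a, b]:
                guide.add((a, b))
    nbrs: Dict[int, List[int]] = {i: [] for i in range(n)}
    for a, b in guide:
        nbrs[a].append(b)
        nbrs[b].append(a)
    shortcut: Set[Tuple[int, int]] = set()
    for i in range(n):
        adj = sorted(nbrs[i])
        for ai in range(len(adj)):
            for bi in range(ai + 1, len(adj)):
                a, b = adj[ai], adj[bi]
                lo, hi = min(a, b), max(a, b)
                if (lo, hi) in guide:
                    continue
                if d[a][i] + d[i][b] > d[lo][hi]:
                    shortcut.add((lo, hi))
    g = {(nodes[a], nodes[b]) for a, b in guide}
    s = {(nodes[a], nodes[b]) for a, b in shortcut}
    return g, s


def build_guide_graph(
    em: EnergyModel,
    candidates: Set[Structure],
    max_rounds: int = 50,
) -> Tuple[Set[Tuple[Structure, Structure]], Set[Tuple[Structure, Structure]], Set[Structure]]:
    """Iterative guide-graph construction, enlarging the candidate set.

    Each round: (1) extend every node by its compatible-constraint MFE,
    (2) build guide/shortcut edges from distances, (3) insert the
    direct-path constrained MFE of every edge when it differs from both
    endpoints.  Edges are rebuilt from scratch whenever the candidate set
    grows; terminates because the structure space at fixed length is
    finite.
    """
    candidates = set(candidates)
    length = next(iter(candidates)).length
    compat_done: Set[Structure] = set()
    dp_done: Set[EdgeKey] = set()
    for _ in range(max_rounds):
        changed = False
        for node in sorted(candidates):
            if node in compat_done:
                continue
            compat_done.add(node)
            refold, _ = em.constrained_mfe(node.dot_bracket(), length, enforce=False)
            if refold not in candidates:
                candidates.add(refold)
                changed = True
        guide, shortcut = guide_edges_from_distances(sorted(candidates))
        for x, y in sorted(guide | shortcut):
            key = edge_key(x, y)
            if key in dp_done:
                continue
            dp_done.add(key)
            z, _ = em.direct_path_constrained_mfe(x, y)
            if z != x and z != y and z not in candidates:
                candidates.add(z)
                changed = True
        if not changed:
            return guide, shortcut, candidates
    return guide, shortcut, candidates  # round cap reached; graph is still valid


# ---------------------------------------------------------------------------
# rates
# ---------------------------------------------------------------------------


def rate_from_saddle(e_x: float, e_saddle: float, k0: float, T: float) -> float:
    """Arrhenius rate k0·exp(−(E_saddle − E_x)/RT), T in Kelvin."""
    if e_saddle < e_x - _EPS:
        raise ValueError(f"saddle energy {e_saddle} below state energy {e_x}")
    if k0 <= 0:
        raise ValueError("k0 must be positive")
    return k0 * math.exp(-max(e_saddle - e_x, 0.0) / (GAS_CONSTANT * T))


# ---------------------------------------------------------------------------
# expansion step
# ---------------------------------------------------------------------------


def _resolve_edge(
    em: EnergyModel,
    landscape: Landscape,
    x: Structure,
    y: Structure,
    delta: float,
    reaction_cache: Dict[EdgeKey, float],
    width_factor: int,
    width_cap: int = 32,
) -> None:
    """Find the saddle for edge (x, y), recursing on interior δ-minima."""
    pending: List[Tuple[Structure, Structure, int]] = [(x, y, width_factor)]
    seen: Set[EdgeKey] = set()
    while pending:
        a, b, wf = pending.pop()
        key = edge_key(a, b)
        cached = reaction_cache.get(key)
        if cached is not None:
            landscape.add_edge(a, b, cached)
            continue
        if key in seen:
            continue
        seen.add(key)
        d = base_pair_distance(a, b)
        if d == 1:
            # a single-move path has no interior: the saddle is forced
            saddle = max(em.free_energy(a), em.free_energy(b))
            reaction_cache[key] = saddle
            landscape.add_edge(a, b, saddle)
            continue
        # beam width wf*d, bounded so that one search costs O(width*d) ~
        # constant: long paths get a narrow first pass — they decompose into
        # subpaths which are re-searched at doubled width anyway
        width = max(min(wf * d, width_cap, max(8, 512 // d)), 1)
        if d > 2 and hasattr(em, "findpath_profile"):
            # fast route: flood the raw profile, build structures only for
            # the minima that actually become candidates
            dbs, energies = em.findpath_profile(a, b, width)
            endpoint_max = max(energies[0], energies[-1])
            flood = flood_path(energies, delta)
            keep = [k for k in flood.minima[1:-1] if energies[k] <= endpoint_max + _EPS]
            if not keep:
                saddle = max(energies)
                reaction_cache[key] = saddle
                landscape.add_edge(a, b, saddle)
                continue
            bounds = [0] + keep + [len(energies) - 1]
            bstructs = {0: a, len(energies) - 1: b}
            for k in keep:
                s = parse_dotbracket(dbs[k][: a.length])
                em._energy_cache.setdefault(s.pairs, energies[k])
                bstructs[k] = s
                landscape.add_node(s, energies[k])
            for ia, ib in zip(bounds, bounds[1:]):
                pending.append((bstructs[ia], bstructs[ib], wf * 2))
            continue
        path = _search_path(em, a, b, width) if d > 2 else _best_two_move_path(em, a, b)
        dec = decompose_reaction(path, delta)
        if dec.direct:
            reaction_cache[key] = dec.saddle
            landscape.add_edge(a, b, dec.saddle)
        else:
            for k in dec.candidates:
                landscape.add_node(k, em.free_energy(k))
            # subpaths are re-searched with doubled beam width
            for u, v in dec.subpaths:
                pending.append((u, v, wf * 2))


def _search_path(em: EnergyModel, a: Structure, b: Structure, width: int) -> DirectPath:
    if hasattr(em, "findpath"):
        steps = em.findpath(a, b, width)
        return DirectPath([s for s, _ in steps], [e for _, e in steps], width)
    return find_direct_path(em, a, b, width)


def _best_two_move_path(em: EnergyModel, a: Structure, b: Structure) -> DirectPath:
    """Exhaustive minimal-saddle direct path for d(a, b) = 2."""
    from .path_search import _valid_addition

    best: Optional[Tuple[float, float, Structure]] = None
    for p in sorted(a.pairs - b.pairs):
        mid = a.without_pair(*p)
        e = em.free_energy(mid)
        if best is None or (e, mid.dot_bracket()) < (best[0], best[2].dot_bracket()):
            best = (e, e, mid)
    for p in sorted(b.pairs - a.pairs):
        if not _valid_addition(a.pairs, *p):
            continue
        mid = a.with_pair(*p)
        e = em.free_energy(mid)
        if best is None or (e, mid.dot_bracket()) < (best[0], best[2].dot_bracket()):
            best = (e, e, mid)
    assert best is not None
    mid = best[2]
    return DirectPath(
        [a, mid, b], [em.free_energy(a), best[0], em.free_energy(b)], 0
    )


def expand(
    em: EnergyModel,
    parents: Dict[Structure, float],
    new_length: int,
    delta: float,
    mfree: int = 6,
    reaction_cache: Optional[Dict[EdgeKey, float]] = None,
    previous_edges: Optional[Set[EdgeKey]] = None,
    width_factor: int = 4,
    width_cap: int = 32,
    caged: int = 0,
) -> Landscape:
    """One expansion step: candidates, guiding neighborhood, saddles, rates.

    ``parents`` maps structures (at length ``new_length - 1`` or already
    extended) to occupancies; an empty dict starts transcription, yielding
    the MFE structure of the first nucleotide(s) with occupancy 1.
    Reactions cached from previous steps are reused: the full-length
    energy convention keeps their saddles valid.  With ``caged > 0`` the
    3'-most ``caged`` nucleotides are kept unpaired (polymerase
    footprint); structure search then runs on the shorter prefix.
    """
    if reaction_cache is None:
        reaction_cache = {}
    eff = max(new_length - caged, 1) if caged else new_length
    landscape = Landscape(new_length)
    if not parents:
        mfe_structure, e = em.mfe(eff)
        landscape.add_node(mfe_structure.extended(new_length), e, occupancy=1.0)
        return landscape

    parents_eff = {
        Structure(p.pairs, eff): occ for p, occ in parents.items()
    }
    candidates = find_candidates(em, parents_eff, mfree, eff)
    guide, shortcut, candidates = build_guide_graph(em, candidates)

    if caged:
        # carry everything back to the true transcript length
        ext = {n: n.extended(new_length) for n in candidates}
        parents_ext = {ext[n]: parents_eff[n] for n in parents_eff}
        candidates = set(ext.values())
        guide = {(ext[a], ext[b]) for a, b in guide}
        shortcut = {(ext[a], ext[b]) for a, b in shortcut}
    else:
        parents_ext = parents_eff

    for node in sorted(candidates):
        landscape.add_node(node, em.free_energy(node), parents_ext.get(node, 0.0))

    for x, y in sorted(guide | shortcut):
        _resolve_edge(em, landscape, x, y, delta, reaction_cache, width_factor, width_cap)

    # merge the previous step's reactions whose endpoints are still present
    if previous_edges:
        by_pairs = {n.pairs: n for n in landscape.energies}
        for key in previous_edges:
            try:
                pa, pb = tuple(key)
            except ValueError:
                continue
            a, b = by_pairs.get(pa), by_pairs.get(pb)
            if a is not None and b is not None and key in reaction_cache:
                landscape.add_edge(a, b, reaction_cache[key])

    _ensure_connected(em, landscape, delta, reaction_cache, width_factor, width_cap)
    return landscape


def _ensure_connected(em, landscape, delta, reaction_cache, width_factor, width_cap=32) -> None:
    """Reconnect stray components (rare; guide graphs are connected by
    construction, but recursive decomposition may leave an orphan when the
    round cap bites)."""
    comps = landscape.connected_components()
    while len(comps) > 1:
        main = comps[0]
        other = comps[1]
        best = min(
            ((a, b) for a in sorted(main) for b in sorted(other)),
            key=lambda ab: (base_pair_distance(*ab), ab[0].dot_bracket(), ab[1].dot_bracket()),
        )
        _resolve_edge(em, landscape, best[0], best[1], delta, reaction_cache, width_factor, width_cap)
        comps = landscape.connected_components()
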