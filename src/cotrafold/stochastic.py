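"""Elementary-move Gillespie simulator (reference oracle).

A stochastic simulator of cotranscriptional folding on the full
elementary move set (single base-pair opening/closing) with Metropolis
rates k = k0·min(1, exp(−ΔE/RT)).  It is the ground-truth model the
deterministic pipeline approximates, kept here for validation: state
spaces are memoized, so it is practical for sequences up to ~25 nt and
thousands of trajectories, not for production use.
"""

from __future__ import annotations

import math
from collections import Counter
from typing import Dict, List, Tuple

import numpy as np

from .energy_model import EnergyModel
from .rna_structures import Structure, elementary_neighbors


class GillespieSimulator:
    """Stochastic folding over elementary moves with Metropolis rates.

    Energies come from the supplied model (full-length evaluation
    convention), so deterministic and stochastic simulations share one
    landscape definition.
    """

    def __init__(self, em: EnergyModel, k0: float = 1e5):
        self.em = em
        self.k0 = k0
        self._cache: Dict[Tuple[frozenset, int], Tuple[List[Structure], np.ndarray, float]] = {}

    def _transitions(self, x: Structure) -> Tuple[List[Structure], np.ndarray, float]:
        key = (x.pairs, x.length)
        hit = self._cache.get(key)
        if hit is not None:
            return hit
        seq = self.em.seq_prefix(x.length)
        ex = self.em.free_energy(x)
        RT = self.em.RT
        nbrs = sorted(elementary_neighbors(seq, x))
        rates = np.array(
            [
                self.k0 * min(1.0, math.exp(-(self.em.free_energy(y) - ex) / RT))
                for y in nbrs
            ]
        )
        cum = np.cumsum(rates)
        total = float(cum[-1]) if len(cum) else 0.0
        entry = (nbrs, cum, total)
        self._cache[key] = entry
        return entry

    def fold_during_transcription(
        self,
        rng: np.random.Generator,
        t_ext: float,
        t_end: float,
        start_length: int = 1,
    ) -> Structure:
        """One trajectory; returns the structure at ``t_end`` after the
        final nucleotide."""
        L = self.em.full_length
        state = Structure(frozenset(), start_length)
        for l in range(start_length, L + 1):
            state = state.extended(l)
            horizon = t_ext if l < L else t_end
            state = self._evolve(state, horizon, rng)
        return state

    def _evolve(self, state: Structure, horizon: float, rng: np.random.Generator) -> Structure:
        t = 0.0
        while True:
            nbrs, cum, total = self._transitions(state)
            if total <= 0:
                return state
            t += rng.exponential(1.0 / total)
            if t >= horizon:
                return state
            idx = int(np.searchsorted(cum, rng.random() * total, side="right"))
            state = nbrs[idx]

    def end_of_transcription_distribution(
        self,
        n_trajectories: int,
        t_ext: float,
        t_end: float,
        seed: int = 0,
        start_length: int = 1,
    ) -> Counter:
        """Empirical structure distribution over many trajectories."""
        rng = np.random.default_rng(seed)
        counts: Counter = Counter()
        for _ in range(n_trajectories):
            final = self.fold_during_transcription(rng, t_ext, t_end, start_length)
            counts[final.pairs] += 1
        return counts
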