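"""Adapter to a nearest-neighbor thermodynamics engine.

Two backends implement one contract:

* :class:`ViennaEnergyModel` — the production backend on top of the
  ViennaRNA bindings (energies, constrained MFE, findpath).
* :class:`ToyEnergyModel` — a deterministic pair/stack table model so that
  the landscape algorithms can be unit-tested without the thermodynamics
  engine.

Both follow the full-length evaluation convention: the free energy of a
structure on a transcript prefix is evaluated on the *full* sequence with a
3' tail of unpaired nucleotides.  A stored energy therefore never changes
retroactively when the transcript grows; the open chain has energy 0.
"""

from __future__ import annotations

import itertools
from typing import Dict, FrozenSet, List, Optional, Tuple

from .rna_structures import (
    MIN_HAIRPIN,
    Pair,
    Sequence,
    Structure,
    StructureError,
    _crosses,
    enumerate_structures,
    parse_dotbracket,
    validate,
)

#: Gas constant in kcal/(mol*K).
GAS_CONSTANT = 0.00198717

#: Energies within one parameter-file quantum count as equal.
ENERGY_TOL = 0.01


class InfeasibleConstraintError(ValueError):
    """A fold constraint admits no valid structure."""


class EnergyModel:
    """Shared interface of the thermodynamic backends."""

    seq: Sequence
    temperature: float  # Celsius

    @property
    def full_length(self) -> int:
        return len(self.seq)

    @property
    def RT(self) -> float:
        """Thermal energy in kcal/mol at the model temperature."""
        return GAS_CONSTANT * (self.temperature + 273.15)

    def free_energy(self, x: Structure) -> float:
        raise NotImplementedError

    def mfe(self, up_to: int) -> Tuple[Structure, float]:
        """Unconstrained MFE over the first ``up_to`` nucleotides."""
        raise NotImplementedError

    def constrained_mfe(
        self, constraint: str, up_to: int, enforce: bool = True
    ) -> Tuple[Structure, float]:
        """MFE subject to a dot-bracket fold constraint over the prefix.

        ``constraint`` uses the standard dialect: ``.`` unconstrained,
        ``x`` forced unpaired, ``(``/``)`` a constrained pair.  With
        ``enforce=True`` constrained pairs must be present in the result
        (base pairs and loop regions fixed); with ``enforce=False`` they
        only exclude incompatible pairs.
        """
        raise NotImplementedError

    def direct_path_constrained_mfe(
        self, x: Structure, y: Structure
    ) -> Tuple[Structure, float]:
        """MFE among structures whose pairs are a subset of ``x.pairs | y.pairs``."""
        raise NotImplementedError


class ViennaEnergyModel(EnergyModel):
    """Nearest-neighbor energies via the ViennaRNA bindings.

    Parameters
    ----------
    seq:
        The full-length sequence; prefix structures are padded with an
        unpaired 3' tail for evaluation.
    temperature:
        Folding temperature in Celsius (default 37).
    noLP:
        Disallow lonely pairs in folds (pass-through to the engine,
        default off).
    parameter_file:
        Optional nearest-neighbor parameter file in the engine's format.
    """

    def __init__(
        self,
        seq: Sequence,
        temperature: float = 37.0,
        noLP: bool = False,
        parameter_file: Optional[str] = None,
    ):
        import RNA

        self._RNA = RNA
        self.seq = seq
        self.temperature = float(temperature)
        self.noLP = bool(noLP)
        if parameter_file:
            RNA.params_load(parameter_file)
        self._md = RNA.md()
        self._md.temperature = self.temperature
        self._md.noLP = 1 if noLP else 0
        self._fc = RNA.fold_compound(seq.residues, self._md)
        self._energy_cache: Dict[FrozenSet[Pair], float] = {}
        self._union_cache: Dict[FrozenSet[Pair], FrozenSet[Pair]] = {}

    # -- energies -----------------------------------------------------------

    def _padded(self, x: Structure) -> str:
        return x.dot_bracket() + "." * (self.full_length - x.length)

    def free_energy(self, x: Structure) -> float:
        key = x.pairs
        e = self._energy_cache.get(key)
        if e is None:
            bad = validate(self.seq_prefix(x.length), x)
            if bad:
                raise StructureError("; ".join(bad))
            e = round(self._fc.eval_structure(self._padded(x)), 2)
            self._energy_cache[key] = e
        return e

    def seq_prefix(self, up_to: int) -> Sequence:
        if up_to == self.full_length:
            return self.seq
        return Sequence(self.seq.residues[:up_to], self.seq.name)

    # -- folding ------------------------------------------------------------

    def _fold(self, up_to: int, setup) -> Tuple[Structure, float]:
        fc = self._RNA.fold_compound(self.seq.residues[:up_to], self._md)
        if setup is not None:
            setup(fc)
        db, e = fc.mfe()
        if e > 1e5:
            raise InfeasibleConstraintError("constraint admits no structure")
        x = parse_dotbracket(db)
        if validate(self.seq_prefix(up_to), x):
            # the engine satisfied the constraint only by leaving the class
            # of valid structures (e.g. an enforced non-canonical pair)
            raise InfeasibleConstraintError("constraint admits no valid structure")
        return x, self.free_energy(x)

    def mfe(self, up_to: int) -> Tuple[Structure, float]:
        return self._fold(up_to, None)

    def constrained_mfe(
        self, constraint: str, up_to: int, enforce: bool = True
    ) -> Tuple[Structure, float]:
        if len(constraint) != up_to:
            raise ValueError("constraint length must equal up_to")
        RNA = self._RNA
        opts = RNA.CONSTRAINT_DB_DEFAULT
        if enforce:
            opts |= RNA.CONSTRAINT_DB_ENFORCE_BP
        return self._fold(up_to, lambda fc: fc.hc_add_from_db(constraint, opts))

    def direct_path_constrained_mfe(
        self, x: Structure, y: Structure
    ) -> Tuple[Structure, float]:
        if x.length != y.length:
            raise ValueError("structures live on different transcript lengths")
        union = x.pairs | y.pairs
        if x.pairs == y.pairs:
            return x, self.free_energy(x)
        # the result only depends on the union pair set (everything else is
        # forced unpaired), so it is cacheable across transcript lengths
        cached = self._union_cache.get(union)
        if cached is not None:
            z = Structure(cached, x.length)
            return z, self.free_energy(z)
        RNA = self._RNA
        up_to = max(j for _, j in union)  # tail beyond the union is unpaired anyway
        positions = sorted({k for p in union for k in p})
        in_union = set(positions)
        res = self.seq.residues
        pairable = self.seq._pairable

        def setup(fc):
            for k in range(1, up_to + 1):
                if k not in in_union:
                    fc.hc_add_up(k, RNA.CONSTRAINT_CONTEXT_ALL_LOOPS)
            # prohibit every other canonical pair among the union positions;
            # NO_REMOVE so only that one pair is touched per call
            forbid = RNA.CONSTRAINT_CONTEXT_NONE | RNA.CONSTRAINT_CONTEXT_NO_REMOVE
            for a, i in enumerate(positions):
                allowed = pairable[i - 1]
                for j in positions[a + 1 :]:
                    if (
                        j - i > MIN_HAIRPIN
                        and res[j - 1] in allowed
                        and (i, j) not in union
                    ):
                        fc.hc_add_bp(i, j, forbid)

        z, e = self._fold(up_to, setup)
        z = Structure(z.pairs, x.length)
        self._union_cache[union] = z.pairs
        if not z.pairs <= union:
            raise AssertionError("constrained fold escaped the allowed pair set")
        # x and y are always feasible, so the fold can never do worse than both
        return z, e

    # -- paths --------------------------------------------------------------

    def findpath(
        self, x: Structure, y: Structure, width: int
    ) -> List[Tuple[Structure, float]]:
        """Best direct path via the engine's findpath heuristic.

        Energies are evaluated on the full-length compound, so they agree
        with :meth:`free_energy` for every step.
        """
        dbs, energies = self.findpath_profile(x, y, width)
        out: List[Tuple[Structure, float]] = []
        for db, e in zip(dbs, energies):
            s = parse_dotbracket(db[: x.length])
            self._energy_cache.setdefault(s.pairs, e)
            out.append((s, e))
        return out

    def findpath_profile(
        self, x: Structure, y: Structure, width: int
    ) -> Tuple[List[str], List[float]]:
        """Like :meth:`findpath` but returns raw dot-bracket strings and
        energies, deferring structure construction to the caller (hot path)."""
        path = self._fc.path_findpath(self._padded(x), self._padded(y), max(1, width))
        return [p.s for p in path], [round(p.en, 2) for p in path]


class ToyEnergyModel(EnergyModel):
    """Deterministic pair/stack table energies for engine-free tests.

    Every canonical pair contributes ``pair_energy``; every stacked
    adjacency ((i,j) on top of (i+1,j-1)) contributes ``stack_energy``.
    Constrained folds are brute-force enumerations and therefore only
    usable on short sequences.
    """

    def __init__(
        self,
        seq: Sequence,
        temperature: float = 37.0,
        pair_energy: float = -1.0,
        stack_energy: float = -1.0,
    ):
        self.seq = seq
        self.temperature = float(temperature)
        self.pair_energy = pair_energy
        self.stack_energy = stack_energy

    def free_energy(self, x: Structure) -> float:
        e = len(x.pairs) * self.pair_energy
        for i, j in x.pairs:
            if (i + 1, j - 1) in x.pairs:
                e += self.stack_energy
        return e

    def _all(self, up_to: int) -> List[Structure]:
        return enumerate_structures(self.seq_prefix(up_to))

    def seq_prefix(self, up_to: int) -> Sequence:
        if up_to == self.full_length:
            return self.seq
        return Sequence(self.seq.residues[:up_to], self.seq.name)

    def mfe(self, up_to: int) -> Tuple[Structure, float]:
        best = min(self._all(up_to), key=lambda s: (self.free_energy(s), s.dot_bracket()))
        return best, self.free_energy(best)

    def constrained_mfe(
        self, constraint: str, up_to: int, enforce: bool = True
    ) -> Tuple[Structure, float]:
        if len(constraint) != up_to:
            raise ValueError("constraint length must equal up_to")
        forced = parse_dotbracket(constraint.replace("x", "."))
        unpaired = {k + 1 for k, c in enumerate(constraint) if c == "x"}
        feasible = []
        for s in self._all(up_to):
            partner = s.partner()
            if any(k in partner for k in unpaired):
                continue
            if enforce:
                if not forced.pairs <= s.pairs:
                    continue
            else:
                if any(_crosses(i, j, forced.pairs) for i, j in s.pairs - forced.pairs):
                    continue
                if any(
                    (k in forced.partner() and partner[k] != forced.partner()[k])
                    for k in partner
                ):
                    continue
            feasible.append(s)
        if not feasible:
            raise InfeasibleConstraintError("constraint admits no structure")
        best = min(feasible, key=lambda s: (self.free_energy(s), s.dot_bracket()))
        return best, self.free_energy(best)

    def direct_path_constrained_mfe(
        self, x: Structure, y: Structure
    ) -> Tuple[Structure, float]:
        union = sorted(x.pairs | y.pairs)
        best = None
        for r in range(len(union) + 1):
            for sub in itertools.combinations(union, r):
                try:
                    s = Structure(frozenset(sub), x.length)
                except StructureError:
                    continue
                if validate(self.seq_prefix(x.length), s):
                    continue
                e = self.free_energy(s)
                if best is None or (e, s.dot_bracket()) < (best[1], best[0].dot_bracket()):
                    best = (s, e)
        assert best is not None
        return best
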