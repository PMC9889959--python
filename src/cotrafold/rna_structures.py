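"""Sequences, secondary structures, elementary moves and base-pair distance.

Secondary structures are sets of nested canonical base pairs over a
transcript prefix, written 1-based so that the hairpin condition reads
literally ``j - i > 3``.  This module is format-free: FASTA handling lives
in the driver, dot-bracket strings are the only textual interface here.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import FrozenSet, Iterator, List, Set, Tuple

Pair = Tuple[int, int]

#: Canonical (isosteric) base pairs.
CANONICAL_PAIRS = frozenset(
    {("A", "U"), ("U", "A"), ("C", "G"), ("G", "C"), ("G", "U"), ("U", "G")}
)

#: Minimum number of unpaired nucleotides in a hairpin loop.
MIN_HAIRPIN = 3


class StructureError(ValueError):
    """Raised for malformed dot-bracket strings or sequences."""


@dataclass(frozen=True)
class Sequence:
    """An RNA sequence, 5' to 3', positions 1..n.

    DNA input is accepted: ``T`` is mapped to ``U`` and lowercase letters
    are uppercased.  Any other character raises :class:`StructureError`.
    """

    residues: str
    name: str = ""

    def __post_init__(self) -> None:
        cleaned = self.residues.upper().replace("T", "U")
        bad = set(cleaned) - set("ACGU")
        if bad:
            raise StructureError(f"illegal residues {sorted(bad)!r} in sequence {self.name!r}")
        if len(cleaned) < 1:
            raise StructureError("empty sequence")
        object.__setattr__(self, "residues", cleaned)
        pairable = {"A": "U", "U": "AG", "C": "G", "G": "CU"}
        object.__setattr__(
            self,
            "_pairable",
            tuple(frozenset(pairable[c]) for c in cleaned),
        )

    def __len__(self) -> int:
        return len(self.residues)

    def __getitem__(self, i: int) -> str:
        """1-based residue access."""
        return self.residues[i - 1]

    def can_pair(self, i: int, j: int) -> bool:
        return self.residues[j - 1] in self._pairable[i - 1]


class Structure:
    """A set of base pairs (i, j), i < j, over a transcript of given length.

    Hashable and ordered by canonical dot-bracket so that sets and sorted
    lists of structures are stable across runs.  Immutable; dot-bracket
    and hash are cached (this type sits in every hot loop).
    """

    __slots__ = ("pairs", "length", "_hash", "_db", "_sp")

    def __init__(self, pairs, length: int, _trusted: bool = False):
        if not _trusted:
            pairs = frozenset((p, q) if p < q else (q, p) for p, q in pairs)
            for i, j in pairs:
                if not (1 <= i < j <= length):
                    raise StructureError(f"pair {(i, j)} outside 1..{length}")
        object.__setattr__(self, "pairs", pairs)
        object.__setattr__(self, "length", length)
        object.__setattr__(self, "_hash", None)
        object.__setattr__(self, "_db", None)
        object.__setattr__(self, "_sp", None)

    def __setattr__(self, name, value):
        raise AttributeError("Structure is immutable")

    def __eq__(self, other):
        return (
            isinstance(other, Structure)
            and self.length == other.length
            and self.pairs == other.pairs
        )

    def __hash__(self):
        h = self._hash
        if h is None:
            h = hash((self.pairs, self.length))
            object.__setattr__(self, "_hash", h)
        return h

    def __repr__(self):
        return f"Structure({self.dot_bracket()!r})"

    @property
    def sorted_pairs(self) -> Tuple[Pair, ...]:
        sp = self._sp
        if sp is None:
            sp = tuple(sorted(self.pairs))
            object.__setattr__(self, "_sp", sp)
        return sp

    def dot_bracket(self) -> str:
        db = self._db
        if db is None:
            chars = ["."] * self.length
            for i, j in self.pairs:
                chars[i - 1] = "("
                chars[j - 1] = ")"
            db = "".join(chars)
            object.__setattr__(self, "_db", db)
        return db

    def partner(self) -> dict:
        """Map position -> partner for paired positions."""
        pt = {}
        for i, j in self.pairs:
            pt[i] = j
            pt[j] = i
        return pt

    def extended(self, new_length: int) -> "Structure":
        """The same pair set on a longer transcript (3' extension)."""
        if new_length < self.length:
            raise StructureError("cannot shrink a structure")
        return Structure(self.pairs, new_length, _trusted=True)

    def with_pair(self, i: int, j: int) -> "Structure":
        return Structure(self.pairs | {(i, j)}, self.length, _trusted=True)

    def without_pair(self, i: int, j: int) -> "Structure":
        return Structure(self.pairs - {(i, j)}, self.length, _trusted=True)

    def __lt__(self, other: "Structure") -> bool:
        return self.dot_bracket() < other.dot_bracket()


@dataclass(frozen=True)
class Move:
    """An elementary step: opening or closing one base pair."""

    pair: Pair
    direction: str  # "open" | "close"

    def apply(self, seq: Sequence, x: Structure) -> Structure:
        i, j = self.pair
        if self.direction == "close":
            if i in x.partner() or j in x.partner():
                raise StructureError(f"position of pair {(i, j)} already paired")
            y = x.with_pair(i, j)
            bad = validate(seq, y)
            if bad:
                raise StructureError("; ".join(bad))
            return y
        if self.direction == "open":
            if (i, j) not in x.pairs:
                raise StructureError(f"pair {(i, j)} not present")
            return x.without_pair(i, j)
        raise ValueError(f"unknown direction {self.direction!r}")


def parse_dotbracket(text: str) -> Structure:
    """Parse a dot-bracket string into a :class:`Structure` (1-based pairs).

    Only ``.``, ``(`` and ``)`` are accepted; unbalanced strings raise
    :class:`StructureError`.  Parsing alone does not check sequence
    compatibility or the hairpin-size condition — use :func:`validate`.
    """
    pairs: Set[Pair] = set()
    stack: List[int] = []
    for pos, ch in enumerate(text, start=1):
        if ch == "(":
            stack.append(pos)
        elif ch == ")":
            if not stack:
                raise StructureError(f"unbalanced ')' at position {pos}")
            pairs.add((stack.pop(), pos))
        elif ch != ".":
            raise StructureError(f"illegal character {ch!r} at position {pos}")
    if stack:
        raise StructureError(f"unbalanced '(' at position {stack[-1]}")
    return Structure(frozenset(pairs), len(text), _trusted=True)


def validate(seq: Sequence, x: Structure) -> List[str]:
    """Check the four structure conditions; return a list of violations.

    (i) canonical pairs only, (ii) each position in at most one pair,
    (iii) pairs nested, (iv) hairpin loops of at least three nucleotides.
    All violations are reported, not just the first.
    """
    violations: List[str] = []
    if x.length != len(seq):
        violations.append(f"length mismatch: structure {x.length}, sequence {len(seq)}")
        return violations
    seen: dict = {}
    for i, j in x.sorted_pairs:
        if not seq.can_pair(i, j):
            violations.append(
                f"condition i: {seq[i]}-{seq[j]} at {(i, j)} is not a canonical pair"
            )
        for k in (i, j):
            if k in seen:
                violations.append(f"condition ii: position {k} pairs twice")
            seen[k] = True
        if j - i <= MIN_HAIRPIN:
            violations.append(f"condition iv: hairpin of pair {(i, j)} too small (j-i={j - i})")
    sp = x.sorted_pairs
    for a in range(len(sp)):
        i, j = sp[a]
        for b in range(a + 1, len(sp)):
            p, q = sp[b]
            if i < p < j < q:
                violations.append(f"condition iii: pairs {(i, j)} and {(p, q)} cross")
    return violations


def base_pair_distance(x: Structure, y: Structure) -> int:
    """Base-pair distance: cardinality of the symmetric difference."""
    return len(x.pairs ^ y.pairs)


def _crosses(i: int, j: int, pairs) -> bool:
    for p, q in pairs:
        if (i < p < j < q) or (p < i < q < j):
            return True
    return False


def closing_moves(seq: Sequence, x: Structure) -> Iterator[Pair]:
    """All pairs (i, j) whose addition keeps the structure valid."""
    paired = x.partner()
    free = [k for k in range(1, x.length + 1) if k not in paired]
    for a, i in enumerate(free):
        for j in free[a + 1 :]:
            if j - i <= MIN_HAIRPIN:
                continue
            if seq.can_pair(i, j) and not _crosses(i, j, x.pairs):
                yield (i, j)


def elementary_neighbors(seq: Sequence, x: Structure) -> Set[Structure]:
    """All valid structures at base-pair distance exactly 1 from ``x``.

    Used by the Gillespie reference simulator and by the full-ensemble
    limit tests; opening any pair is always valid, closing is subject to
    the structure conditions.
    """
    out: Set[Structure] = set()
    for i, j in x.pairs:
        out.add(x.without_pair(i, j))
    for i, j in closing_moves(seq, x):
        out.add(x.with_pair(i, j))
    return out


def enumerate_structures(seq: Sequence, length: int | None = None) -> List[Structure]:
    """Exhaustively enumerate every valid structure of ``seq``.

    Exponential: intended for the full-ensemble limit tests on sequences
    of ~10 nt and the brute-force oracles.
    """
    n = length if length is not None else len(seq)
    from functools import lru_cache

    @lru_cache(maxsize=None)
    def interval(a: int, b: int) -> Tuple[FrozenSet[Pair], ...]:
        """All pair sets over positions a..b (nested within one loop)."""
        if b - a < MIN_HAIRPIN:
            return (frozenset(),)
        results = []
        # position a unpaired
        for rest in interval(a + 1, b):
            results.append(rest)
        # position a paired with j
        for j in range(a + MIN_HAIRPIN + 1, b + 1):
            if seq.can_pair(a, j):
                for inner in interval(a + 1, j - 1):
                    for outer in interval(j + 1, b):
                        results.append(inner | outer | {(a, j)})
        return tuple(results)

    return sorted(Structure(p, n) for p in interval(1, n))
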