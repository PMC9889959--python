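"""Transcription-loop orchestration, experiment harness and file I/O.

The driver wires the four phases together for every nucleotide:
expansion → coarse graining → kinetic simulation (with look-ahead) →
pruning, and streams trajectory records.  The core run is deterministic;
randomness only enters the random-sequence experiment harness through an
explicit seed.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Dict, Iterator, List, Optional, Set, TextIO, Tuple

import numpy as np

from .coarse_graining import coarse_grain
from .energy_model import GAS_CONSTANT, EnergyModel, ViennaEnergyModel
from .expansion import EdgeKey, Landscape, edge_key, expand
from .kinetics import boltzmann_distribution, build_rate_matrix, lookahead_times, propagate
from .pruning import PruneReport, prune, select_prunable
from .rna_structures import Sequence, Structure

logger = logging.getLogger(__name__)

_EPS = 1e-9


@dataclass
class SimulationConfig:
    """Parameters of a cotranscriptional folding run.

    ``t_ext`` is the extension time per nucleotide in seconds (0.04 s
    corresponds to 25 nt/s), ``t_end`` the post-transcriptional
    simulation time, ``k0`` the Arrhenius pre-exponential factor mapping
    energy differences to wall-clock time, ``delta`` the coarse-graining
    barrier in kcal/mol (``None`` resolves to the barrier whose rate
    equals 1/t_ext, i.e. RT·ln(k0·t_ext)), ``o_prune`` the maximum
    occupancy discarded per step and ``mfree`` the minimum number of
    nucleotides a fraying helix must liberate.
    """

    t_ext: float = 0.04
    t_end: float = 60.0
    k0: float = 1e5
    delta: Optional[float] = None
    o_prune: float = 0.05
    mfree: int = 6
    temperature: float = 37.0
    pause_sites: Dict[int, float] = field(default_factory=dict)
    start_length: int = 1
    caged: int = 0
    noLP: bool = False
    parameter_file: Optional[str] = None
    fp_width_factor: int = 4
    fp_width_cap: int = 32

    def __post_init__(self) -> None:
        if self.t_ext <= 0 or self.t_end <= 0 or self.k0 <= 0:
            raise ValueError("t_ext, t_end and k0 must be positive")
        if not 0 <= self.o_prune < 1:
            raise ValueError("o_prune must be in [0, 1)")
        if self.start_length < 1:
            raise ValueError("start_length must be >= 1")
        if any(p <= 0 for p in self.pause_sites.values()):
            raise ValueError("pause durations must be positive")

    @property
    def RT(self) -> float:
        return GAS_CONSTANT * (self.temperature + 273.15)

    def resolve_delta(self) -> float:
        """Coarse-graining barrier; reactions over smaller barriers are
        faster than the extension interval and count as instantaneous."""
        if self.delta is not None:
            if self.delta <= 0:
                raise ValueError("delta must be positive")
            return self.delta
        return max(self.RT * math.log(self.k0 * self.t_ext), 0.01)


def delta_for_timescale(t_fast: float, k0: float = 1e5, temperature: float = 37.0) -> float:
    """Coarse-graining barrier for a folding timescale: the largest barrier
    whose Arrhenius rate is at least 1/t_fast (kcal/mol)."""
    if t_fast <= 0 or k0 <= 0:
        raise ValueError("t_fast and k0 must be positive")
    RT = GAS_CONSTANT * (temperature + 273.15)
    return max(RT * math.log(k0 * t_fast), 0.01)


@dataclass
class TrajectoryRecord:
    """One output row: the occupancy of one structure at one time point."""

    transcript_length: int
    time: float
    structure_id: int
    dot_bracket: str
    energy: float
    occupancy: float


@dataclass
class StepResult:
    """Internal per-nucleotide result handed to record writers."""

    length: int
    reps: List[Structure]
    energies: List[float]
    times: np.ndarray  # simulation times within the step (reported part)
    occupancies: np.ndarray  # len(times) x len(reps)
    final_occ: Dict[Structure, float]  # at the end of the extension interval
    start_time: float  # global time at the beginning of the step


def _consume_ledger(
    landscape: Landscape, ledger: List[Tuple[frozenset, float, List[frozenset]]]
) -> None:
    """Deferred redistribution: re-discovered structures keep their
    occupancy, everything else flows to the recorded survivors."""
    if not ledger:
        return
    by_pairs = {n.pairs: n for n in landscape.energies}
    for pairs, occ, target_keys in ledger:
        node = by_pairs.get(pairs)
        if node is not None:
            landscape.occupancies[node] += occ
            continue
        targets = [by_pairs[t] for t in target_keys if t in by_pairs]
        if not targets:
            targets = sorted(landscape.energies)
        share = occ / len(targets)
        for t in targets:
            landscape.occupancies[t] += share
    ledger.clear()


def iterate_steps(
    seq: Sequence, cfg: SimulationConfig, em: Optional[EnergyModel] = None
) -> Iterator[StepResult]:
    """Run the transcription loop, yielding one :class:`StepResult` per
    transcript length (the last one covers the post-transcriptional
    simulation)."""
    if em is None:
        em = ViennaEnergyModel(
            seq, temperature=cfg.temperature, noLP=cfg.noLP,
            parameter_file=cfg.parameter_file,
        )
    L = len(seq)
    delta = cfg.resolve_delta()
    T_kelvin = cfg.temperature + 273.15
    reaction_cache: Dict[EdgeKey, float] = {}
    prev_edges: Set[EdgeKey] = set()
    ledger: List[Tuple[frozenset, float, List[frozenset]]] = []
    parents: Dict[Structure, float] = {}
    global_time = 0.0

    for l in range(cfg.start_length, L + 1):
        landscape = expand(
            em, parents, l, delta, mfree=cfg.mfree,
            reaction_cache=reaction_cache, previous_edges=prev_edges,
            width_factor=cfg.fp_width_factor, width_cap=cfg.fp_width_cap,
            caged=cfg.caged,
        )
        _consume_ledger(landscape, ledger)
        total = landscape.total_occupancy()
        if abs(total - 1.0) > 1e-6:
            raise RuntimeError(f"occupancy leak at length {l}: sum={total}")
        for n in landscape.occupancies:
            landscape.occupancies[n] /= total

        coarse = coarse_grain(landscape, delta)
        grid = lookahead_times(l, L, cfg.t_ext, cfg.t_end, cfg.pause_sites)
        R, reps = build_rate_matrix(coarse, cfg.k0, T_kelvin)
        energies = [coarse.energies[r] for r in reps]
        p0 = np.array([coarse.occupancies[r] for r in reps])
        p_inf = boltzmann_distribution(energies, cfg.RT)
        lin = grid.linear_times()
        log = grid.log_times()
        times = np.concatenate([lin, log])
        occ = propagate(R, p0, times, p_inf=p_inf)
        occ_lin, occ_log = occ[: len(lin)], occ[len(lin):]

        final_occ = dict(zip(reps, occ_lin[-1] if l < L else occ[-1]))
        reported_times = lin if l < L else times
        reported_occ = occ_lin if l < L else occ
        yield StepResult(
            length=l,
            reps=reps,
            energies=energies,
            times=reported_times,
            occupancies=reported_occ,
            final_occ=final_occ,
            start_time=global_time,
        )

        if l == L:
            break

        # pruning on the representative landscape with post-simulation occupancies
        rep_landscape = Landscape(l)
        for r, e in coarse.energies.items():
            rep_landscape.add_node(r, e, final_occ[r])
        for (a, b), s in coarse.edges.items():
            rep_landscape.add_edge(a, b, s)
            reaction_cache.setdefault(edge_key(a, b), s)
        prunable = select_prunable(occ_log, reps, cfg.o_prune)
        report = prune(rep_landscape, prunable, cfg.o_prune)
        for s, o_removed in report.pruned:
            ledger.append(
                (s.pairs, o_removed, [t.pairs for t in report.redistributed[s]])
            )
        parents = report.parents
        prev_edges = {edge_key(a, b) for (a, b) in rep_landscape.edges}
        logger.info(
            "length %d: %d candidates, %d representatives, %d pruned, %d edges",
            l, len(landscape.energies), len(reps), len(report.pruned),
            len(rep_landscape.edges),
        )
        global_time += grid.t1


def transcribe(
    seq: Sequence, cfg: Optional[SimulationConfig] = None, em: Optional[EnergyModel] = None
) -> Iterator[TrajectoryRecord]:
    """Simulate cotranscriptional folding; stream trajectory records.

    Times are global (seconds since the start of transcription); within
    each (length, time) block the occupancies of the reported structures
    sum to one.
    """
    cfg = cfg or SimulationConfig()
    ids: Dict[frozenset, int] = {}
    for step in iterate_steps(seq, cfg, em):
        for r in step.reps:
            ids.setdefault(r.pairs, len(ids) + 1)
        for ti, t in enumerate(step.times):
            for ri, r in enumerate(step.reps):
                yield TrajectoryRecord(
                    transcript_length=step.length,
                    time=step.start_time + float(t),
                    structure_id=ids[r.pairs],
                    dot_bracket=r.dot_bracket(),
                    energy=step.energies[ri],
                    occupancy=float(step.occupancies[ti, ri]),
                )


def final_distribution(
    seq: Sequence, cfg: Optional[SimulationConfig] = None, em: Optional[EnergyModel] = None
) -> Dict[Structure, float]:
    """Occupancy distribution at the end of the run (t_end after
    transcription)."""
    cfg = cfg or SimulationConfig()
    last: Optional[StepResult] = None
    for last in iterate_steps(seq, cfg, em):
        pass
    assert last is not None
    return last.final_occ


# ---------------------------------------------------------------------------
# experiment harness
# ---------------------------------------------------------------------------


def random_sequence(rng: np.random.Generator, length: int, name: str = "") -> Sequence:
    return Sequence("".join(rng.choice(list("ACGU"), size=length)), name=name)


def mfe_fraction_experiment(
    n_seqs: int,
    length: int,
    time_after: float,
    cfg: Optional[SimulationConfig] = None,
    rng_seed: int = 0,
) -> float:
    """Fraction of random sequences whose most-occupied structure at
    ``time_after`` seconds past the end of transcription is the
    full-length MFE structure."""
    if n_seqs < 1:
        raise ValueError("n_seqs must be >= 1")
    base = cfg or SimulationConfig()
    cfg_run = replace(base, t_end=time_after)
    rng = np.random.default_rng(rng_seed)
    hits = 0
    for i in range(n_seqs):
        seq = random_sequence(rng, length, name=f"random-{i}")
        em = ViennaEnergyModel(
            seq, temperature=cfg_run.temperature, noLP=cfg_run.noLP,
            parameter_file=cfg_run.parameter_file,
        )
        dist = final_distribution(seq, cfg_run, em)
        top = max(dist.items(), key=lambda kv: (kv[1], kv[0].dot_bracket()))[0]
        mfe_structure, _ = em.mfe(length)
        if top.pairs == mfe_structure.pairs:
            hits += 1
        logger.info("sequence %d/%d: mfe %s", i + 1, n_seqs,
                    "hit" if top.pairs == mfe_structure.pairs else "miss")
    return hits / n_seqs


# ---------------------------------------------------------------------------
# file I/O
# ---------------------------------------------------------------------------


def read_fasta(path: str) -> Sequence:
    """Read the first record of a FASTA file (warn when more follow).

    ``T`` is mapped to ``U`` with a logged notice, so DNA input is
    transcribed on the fly.
    """
    from Bio import SeqIO

    records = list(SeqIO.parse(path, "fasta"))
    if not records:
        raise ValueError(f"no FASTA records in {path}")
    if len(records) > 1:
        logger.warning("%s contains %d records; using the first", path, len(records))
    raw = str(records[0].seq)
    if "T" in raw.upper():
        logger.info("input contains T; transcribing to U")
    return Sequence(raw, name=records[0].id)


_HEADER = ["length", "time_s", "id", "structure", "energy_kcal", "occupancy"]


def write_trajectory(records: Iterator[TrajectoryRecord], out: TextIO) -> int:
    """Write records as TSV (times with 6 significant digits); returns the
    number of rows written."""
    out.write("\t".join(_HEADER) + "\n")
    n = 0
    for r in records:
        out.write(
            f"{r.transcript_length}\t{r.time:.6g}\t{r.structure_id}\t"
            f"{r.dot_bracket}\t{r.energy:.2f}\t{r.occupancy:.6g}\n"
        )
        n += 1
    return n


def read_trajectory(inp: TextIO) -> List[TrajectoryRecord]:
    header = inp.readline().strip().split("\t")
    if header != _HEADER:
        raise ValueError("unrecognized trajectory header")
    out = []
    for line in inp:
        l, t, i, s, e, o = line.rstrip("\n").split("\t")
        out.append(TrajectoryRecord(int(l), float(t), int(i), s, float(e), float(o)))
    return out
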