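# Methods

`cotrafold` simulates how the secondary-structure ensemble of an RNA
molecule changes while the molecule is being synthesized 5'→3'. It is a
deterministic heuristic approximation to stochastic folding simulations
over elementary moves (single base-pair opening/closing with Metropolis
rates): instead of sampling trajectories, it maintains a sparse landscape
of structures it has observed, coarse-grains that landscape into
δ-minimum representatives, and integrates a master equation for their
occupancies between transcription events.

## The model

**Structures and energies.** A secondary structure is a set of nested
canonical base pairs (AU, GC, GU) with hairpin loops of at least three
nucleotides; pseudoknots and base triplets are out of scope. Free
energies come from the nearest-neighbor model through the ViennaRNA
bindings. Every structure on a transcript prefix is evaluated *at the
full sequence length* with an unpaired 3' tail. This introduces a small
dangling-end inaccuracy for short transcripts, but it means a stored
energy never changes as the transcript grows, which is what makes the
cross-step reaction cache sound. The open chain is the zero of energy.

**Per-nucleotide cycle.** For each new nucleotide:

1. *Expansion.* Each parent structure is extended by an unpaired 3'
   nucleotide and translated into fold constraints that keep enclosed
   helices and their loops fixed while opening each exterior-loop
   (fraying) helix separately, and all of them at once; helices that
   liberate fewer than `mfree` nucleotides are opened together with
   their enclosed neighbors. Constrained MFE refolds that are at least
   as good as their parent (within one parameter quantum, 0.01
   kcal/mol), plus the unconstrained MFE of the current prefix, become
   candidate structures. A *guiding neighborhood* is built from
   base-pair distances alone: x⇋y is a guide edge unless some candidate
   i has max{d(x,i), d(i,y)} < d(x,y) (strict, so ties never suppress an
   edge); shortcut edges x⇋y are added through any common guide neighbor
   i with d(x,i)+d(i,y) > d(x,y). Each node is additionally extended by
   its compatible-constraint MFE, and each edge by the MFE over the
   union of its endpoint pair sets; the construction is iterated to a
   fixpoint. In the limit of the exhaustive structure set this
   neighborhood provably collapses onto the elementary move set.
2. *Saddles and rates.* Every new edge gets a direct folding path from a
   findpath-style bounded-width search, evaluated on the full-length
   energy surface. The path's 1-D profile is flooded: interior δ-minima
   no higher than the endpoints become new candidates and split the path
   into subpaths (re-searched at doubled width); otherwise the edge is a
   direct transition whose saddle is the path maximum. Rates follow the
   Arrhenius form k = k0·exp(−(E_saddle − E_x)/RT), which reduces
   exactly to Metropolis rates for single base-pair moves. Saddles are
   cached across transcription steps by the unordered pair of pair sets;
   repeated observations keep the minimum.
3. *Coarse graining.* Structures are processed from high to low energy
   (ties broken by dot-bracket string for reproducibility). A structure
   with an escape to an equal-or-lower-energy neighbor over a barrier
   smaller than δ is transient: its occupancy is split equally among its
   minimal-saddle neighbors, and its fast-reachable neighbors are
   connected to all of its other neighbors with saddle = max of the two
   contracted saddles (two slow-only neighbors stay unconnected). At an
   exact energy tie the non-strict comparison merges the plateau onto a
   single representative; with continuous energies this convention is
   immaterial.
4. *Kinetics.* Representative reactions form a column-generator rate
   matrix. With detailed balance (exact by construction), U = Ω⁻¹RΩ
   with Ω = diag(√p∞) is symmetric, so one real eigendecomposition per
   step evaluates all time points; a Padé matrix-exponential fallback
   covers numerically hostile cases. Each step has a linear time regime
   covering the extension interval and a logarithmic look-ahead regime
   to the projected end of transcription, t8 = Σ_{k=l+1..L} t1_k (after
   transcription, to the post-transcriptional time `t-end`).
5. *Pruning.* Representatives whose occupancy stays below `o-prune`
   throughout the look-ahead are candidates for removal; they are
   removed from least occupied upward while the cumulative removed
   occupancy stays strictly below `o-prune`, so the surviving parents
   always hold at least 1 − o. Removed occupancy is redistributed evenly
   over neighboring survivors (recursively through removed chains) — but
   lazily: a structure re-discovered in the next expansion keeps its
   occupancy.

## Parameters

| parameter | default | units | meaning |
|---|---|---|---|
| `t-ext` | 0.04 | s/nt | extension interval (25 nt/s) |
| `t-end` | 60 | s | post-transcriptional simulation time |
| `k0` | 1e5 | 1/s | Arrhenius prefactor; maps energy differences to wall-clock time |
| `delta` | RT·ln(k0·t_ext) ≈ 5.11 | kcal/mol | coarse-graining barrier |
| `o-prune` | 0.05 | – | max occupancy discarded per step |
| `mfree` | 6 | nt | minimum nucleotides liberated by fraying |
| `temp` | 37 | °C | folding temperature |
| `caged` | 0 | nt | 3'-most nucleotides kept unpaired (polymerase footprint) |

The default δ is the largest barrier whose Arrhenius rate still beats
1/t_ext: reactions faster than the extension interval are treated as
instantaneous, which is precisely the timescale separation that coarse
graining assumes. Doubling `k0` while halving all times leaves
trajectories invariant, so `k0` is best held at a conventional value
while the transcription rate is varied.

Only `k0` and `t-ext` carry the mapping to wall-clock time, and both are
biologically uncertain; simulation results for a given molecule should
be read as a family over plausible time-per-nucleotide values rather
than as a single prediction.

## Numerical and search choices

- **Findpath beam width.** The direct-path search uses a beam of
  4·d(x,y), capped at 32 and additionally bounded so that one search
  costs O(width·d) ≈ constant (width ≥ 8). Distant structure pairs
  therefore get a narrow first pass; this is deliberate: their paths
  almost always contain intermediate δ-minima, are split into subpaths,
  and every subpath is re-searched at doubled width. Beam ties are
  broken by (saddle, energy, dot-bracket), making the search
  deterministic.
- **Distance-1 and distance-2 edges** are handled exactly (single-move
  saddle is forced; both two-move orders are enumerated).
- **Energy quantization.** Energies are rounded to 0.01 kcal/mol (the
  parameter-file quantum); "energetically equivalent" in candidate
  filtering means within one quantum.
- **Occupancy floors.** Occupancies below 1e−16 are clipped to zero
  before renormalization; propagated vectors are renormalized to sum 1.
- **Degenerate inputs.** A single-state system propagates trivially;
  infeasible fold constraints raise an explicit error (including the
  case where the engine can only satisfy a constraint with a
  non-canonical pair); pruning with o = 0 removes nothing.
- **Determinism.** Given a sequence and configuration the run is
  bit-reproducible: all orderings (beam ties, coarse-graining ties,
  pruning ties, edge iteration) are fixed by dot-bracket
  lexicographic order. Randomness exists only in the experiment
  harness, under an explicit seed.

## What the validation exercises — and what it does not

The test suite validates the pipeline against independent references:
brute-force enumeration of direct paths, subset enumeration for
union-constrained MFE, Def-style δ-minimum checkers (1-D profiles and
minimax-saddle graph search), analytic two-state kinetics, the Padé
matrix exponential, and an elementary-move Gillespie simulator with
Metropolis rates.

The Gillespie comparison uses five *designed* bistable sequences: a 5'
hairpin whose stem is repeated at the 3' end so that an equal-energy
competitor becomes available only late in transcription. Stems were
chosen aperiodic and with alphabet-separated strands so that no spurious
two-pair stack exists anywhere in the molecule; folding then commits to
the 5' trap during transcription in both simulators, and end-of-
transcription basin occupancies can be compared at binomial precision
(stochastic samples are mapped to basins by steepest descent). The
comparison uses k0 = 3×10³ s⁻¹ for both simulators — matched k0 is what
matters; a smaller prefactor keeps 10⁴ elementary-move trajectories
tractable. These sequences deliberately avoid register-shifted misfolds;
on sequences rich in alternative registers the heuristic's candidate
set misses stochastically populated minority registers, and occupancy
differences of several percent appear (the known cost of compressing
elementary paths into single Arrhenius steps — timescale deviations of
a small constant factor against ground-truth sampling are expected and
are conventionally absorbed into k0).

The random-sequence experiments (`mfe_fraction_experiment`) emulate the
simplest question one can ask of cotranscriptional folding: is the most
occupied structure after transcription the thermodynamic MFE? Uniform
random sequences are not biological sequences; the experiment
characterizes the method's behavior, not any organism. Problem sizes
(100×60 nt; 30×200 nt, reduced from 100 for the desk-scale rerun) were
chosen so the full reproduction runs in minutes on one core.

## Known limitations

- Basin free energies ignore conformational entropy: a representative
  stands for its basin with its single-structure energy. Entropy-aware
  coarse graining would require adjusting both energies and rates.
- Structure discovery is restricted to exterior-loop refolds of observed
  parents plus path decomposition; toehold-mediated rearrangements are
  found only when the toehold lies in the exterior loop, and minority
  misfolded registers populated by rare stochastic events can be missed
  entirely.
- Direct-path saddles upper-bound true barriers; where indirect paths
  are substantially lower the simulated kinetics are too slow.
- The master-equation solver targets landscapes up to ~10⁴ states;
  representative counts grow with structural diversity of the sequence,
  and runtime varies by more than an order of magnitude between random
  sequences of identical length.
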