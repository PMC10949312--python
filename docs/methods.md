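# Methods

## Scope and model

`dwmine` answers one structural question per chain: *do two or more
P-loop-like backbone motifs sit on a single continuous hydrogen-bonded
β-sheet?* The pipeline treats a protein as an ordered list of residues with
backbone (and optionally side-chain) atoms from one polymer chain of a
PDB/mmCIF file; predicted-model confidence (pLDDT) rides in the B-factor
column and is averaged over Cα atoms for reporting. Multi-chain files are
analyzed one chain at a time; waters and hetero groups are dropped, and the
highest-occupancy alternate location wins (first on ties). Residue indices
are 0-based and consecutive internally; all user-facing reports use author
numbering so residue labels match the literature on any given family.

## Conformation alphabet

Backbone torsions are computed in degrees under the IUPAC sign convention;
φ is undefined for the first residue, ψ for the last, ω for the first.
The ABEGO letter of a residue is decided in this order: `O` when the
peptide bond is cis (|ω| < 90°); `-` when φ or ψ is undefined; otherwise
`A` if φ<0 and −100<ψ≤50, `B` if φ<0 otherwise, `G` if φ≥0 and −100<ψ≤100,
`E` otherwise. These bin boundaries are a convention rather than physics —
alternative conventions move marginal residues between neighboring bins but
leave canonical helix/strand/left-handed conformations in A/B/G, which is
all the motif patterns rely on. The bins are exposed in
`dwmine.config.AbegoBins` so another convention can be swapped in.

Terminal residues always read `-` and therefore can never be part of a
motif match; a 14-residue pattern needs at least 16 residues of context.

## Motif search and geometric verification

The two built-in 14-letter patterns (`BBBEBBGAGAAAAA`, `BBBBBBGAGAAAAA`)
describe the strand→left-handed turn→helix junction of a Walker-A P-loop.
Matching is exact and overlapping; extra patterns may be supplied for
exploration but no wildcards are interpreted, since the motif definition is
deliberately literal. Matched 14-residue Cα traces are superposed onto a
reference fragment by the Kabsch algorithm (equal weights, proper rotation
enforced by flipping the sign of the smallest singular value) and matches
with RMSD above 2.0 Å are discarded. Because the two patterns differ at
only two positions, they can co-match nearby starts; overlapping survivors
are reduced to the single lowest-RMSD match (ties to the earlier start), so
one physical loop is never counted twice.

The packaged reference fragment is a synthetic stand-in: the 14-residue
motif built at ideal geometry from region-center torsions, stored with a
provenance string that says exactly that. `reference_from_structure()`
extracts a crystallographic reference (e.g. an F1-ATPase P-loop) from a
local file when one is available; the filter logic is identical either way,
and the 2.0 Å acceptance band is wide relative to the difference between an
idealized and a crystallographic P-loop backbone.

## Hydrogen bonds and sheet topology

Backbone N–H⋯O=C bonds are scored with the Kabsch–Sander electrostatic
model, E = 0.084·(1/r_ON + 1/r_CH − 1/r_OH − 1/r_CN)·332 kcal/mol, bond if
E < −0.5 (cutoff configurable). The amide hydrogen is rebuilt on the
nitrogen 1.0 Å along the previous residue's O→C direction; the first
residue and prolines never donate. A Cα–Cα 9 Å neighbor prefilter bounds
the pair search; sequence neighbors (|i−j| < 2) are never reported, and
residues missing C or O are skipped as acceptors with a warning.

β-bridges follow the standard two-bond rules, written here with
donor→acceptor arrows: parallel (i,j) iff {hb(j→i−1) ∧ hb(i+1→j)} or
{hb(i→j−1) ∧ hb(j+1→i)}; antiparallel iff {hb(i→j) ∧ hb(j→i)} or
{hb(i−1→j+1) ∧ hb(j−1→i+1)}; bridge partners must satisfy |i−j| ≥ 3.
Strands are maximal runs of bridge-bearing residues; two runs merge across
a β-bulge when two same-type bridges are separated by at most one residue
on one strand and at most four on the other. A single bridge residue is a
valid one-residue strand (minimum length configurable). Sheets are
connected components of strands linked by bridges.

The sheet decision for mining: a motif belongs to a sheet when either of
its flanking strands does, where *before* is the strand ending last before
the motif start and *after* is the earliest strand reaching the motif start
or beyond — the motif's own leading β-run, when it bonds into a sheet, is
its after-flank. Structures whose sheets hold ≥2 distinct motifs are the
candidates; tandem repeats fail because each motif's flanks stay on its own
domain's sheet.

STRIDE-style empirical H-bond energies would mark essentially the same
contacts at idealized geometry; the electrostatic model was chosen because
it is fully specified by four interatomic distances and therefore exactly
testable. Marginal geometries can differ between the two definitions; the
cutoff and H placement are configurable for sensitivity checks.

## Alignment, TM-score and clustering

TM-score: TM = (1/L_norm)·Σ 1/(1+(dᵢ/d0)²) with d0 = 1.24·(L_norm−15)^⅓ −
1.8, defined for L_norm ≥ 16. The score-maximizing superposition is
approximated by iterating the least-squares fit on the subset of pairs
closer than d0 (widened in 0.5 Å steps when fewer than three pairs qualify)
until the subset fixes, keeping the best score seen.

`align_pair` is a deliberately simple sequential aligner: seeds from (a)
gapless threading at every offset with at least max(16, L_min/2) overlap and
(b) Needleman–Wunsch over the two ABEGO strings (match +2, mismatch −1, gap
−1); the best few seeds by quick TM are refined by alternating superposition
with zero-gap dynamic programming on the score matrix 1/(1+(d/d0)²) until
the pair set repeats. It is validated by parameter recovery (≥96% of true
pairs around an internal deletion, and TM at least that of a refinement
seeded with the true pairing minus 0.02) rather than by matching any
particular external program. Sequence-order-independent (rewiring)
alignment is out of scope.

Clustering is exact all-vs-all single linkage on min(TM_A, TM_B) ≥ 0.5 —
the conservative normalization, configurable to max/avg/query since
published thresholds rarely state one. This targets hundreds of structures,
not database-scale search; no prefilter is implemented. The cluster
representative maximizes the mean TM to the other members, ties to the
lexicographically smallest id.

## Symmetry and conservation

Half-vs-half identity aligns the Cα traces of two disjoint residue-range
unions with `align_pair` and reports identical residues / aligned pairs ×
100. For a two-fold pseudo-symmetric protein this equals the second-best
self-alignment a rewiring aligner would report, while remaining testable by
construction (an exact tandem repeat must give 100%). Alignments with TM <
0.5 are flagged: identity over a bad alignment is noise. Net charge is
count(K)+count(R)−count(D)−count(E), histidine excluded.

MSA rows with more than 10 deletions against the representative row
(counted only over representative-occupied columns; insertions elsewhere
are ignored) are dropped — these are typically fragments matching only the
motif consensus. Per-column Shannon entropy is computed in nats over the 20
amino acids with gaps excluded from the frequencies; coverage (non-gap
fraction) is reported alongside so low-coverage columns can be judged.
Columns with no residues at all are flagged rather than scored. No sequence
weighting is applied — plain counts keep the statistic transparent; with
weighting the ranking of near-invariant columns would rarely change. The
`top_conserved` selection returns the n lowest-entropy positions inside a
window (e.g. a ligand-tunnel residue range), ascending, ties by residue
number.

## Side-chain constellation search

A query is ≥3 residues with Cα, Cβ and side-chain atoms. Candidate tuples
in the target preserve amino-acid type exactly (no exchange sets by
default; a hook exists). Pruning: every pairwise Cβ–Cβ distance must match
the query's within ±1.5 Å — this cannot create false negatives at a 1.0 Å
RMSD acceptance threshold, since a tuple whose superposition RMSD is ≤1 Å
cannot have any pairwise distance off by more than 2·RMSD·√N; the pruned
search is nonetheless asserted equal to a pruning-free brute-force
enumerator on every fixture. Survivors are Kabsch-superposed over the
intersection of resolved atoms; chemically symmetric atom pairs (Asp
OD1/OD2, Glu OE1/OE2, Phe/Tyr ring pairs, Arg NH1/NH2) are tried in both
labelings and the lower RMSD kept.

## Synthetic data: what it emulates and what it does not

The generator produces the exact inputs each stage consumes, with labels:

- **Torsion recipes → backbones** via internal-to-Cartesian chaining with
  ideal geometry (N–CA 1.458, CA–C 1.525, C–N 1.329, C=O 1.231 Å; angles
  N-CA-C 111.2°, CA-C-N 116.2°, C-N-CA 121.7°). Recomputing torsions on the
  result reproduces the recipe within 0.5° at interior residues, so the
  intended conformation string is exact ground truth.
- **Idealized sheets** from an analytic pleated-strand template (3.4 Å
  rise, 4.8 Å default inter-strand spacing, carbonyls tilted 0.15 Å along
  the strand): strands are placed as rigid, axis-aligned copies whose
  x-offsets are solved so the designed rung bonds satisfy the
  electrostatic criterion exactly; designed (donor, acceptor) lists and the
  expected strand/sheet partition are returned. The residue preceding each
  strand has its carbonyl oriented so the strand's first residue donates
  correctly.
- **Dual-P-loop chimeras**: motif fragments grafted above a sheet whose
  strand slots interleave with the motifs in chain order, making the
  flanking-strand assignment unambiguous; the decoy places its two
  three-strand sheets 80 Å apart.
- **MSAs** with planted zero-entropy columns and fragment rows; **tandem
  repeats** with a controlled fraction of second-copy mutations;
  **constellations** from fixed idealized side-chain templates under
  seeded random rotations.

Linkers between rigidly placed fragments are *not* stereochemically valid
(no clash checking, arbitrary junction torsions): only H-bond geometry and
the torsions of scored regions matter to the pipeline under test, and this
keeps the ground truth exact. Consequently, passing tests demonstrate the
correctness of the detection and decision logic — they do not demonstrate
robustness to the looser geometry of real predicted models (sheet twist,
bulge irregularity, marginal H-bonds), which is governed by the
configurable energy cutoff and RMSD threshold.

## Numerical choices and degenerate inputs

- Kabsch requires ≥3 non-collinear points; reflections are corrected, so
  rmsd(A,B) = rmsd(B,A) to 1e-9.
- TM normalization length must exceed 15 (d0 domain). The
  `all-distances-at-d0` identity (every term ½) is checked without
  re-superposition, since re-fitting would move off the construction.
- Atom pairs closer than 0.5 Å are treated as clashes and score no H-bond.
- The torsion of four collinear atoms is undefined; builders avoid exact
  collinearity, readers leave such torsions undefined and the residue
  unassigned.
- Entropy of a column seen only in the representative is 0 by definition
  (single count); flagged columns (no residues) are excluded from ranking.
- Directory scans sort by structure id and isolate per-file failures, so
  output is deterministic and a corrupt file costs one warning, not a run.

## Problem sizes

Default test and acceptance runs use 6–12-strand sheets (6–8 residues per
strand), 60–110-residue chimeras and folds, 200 random torsion recipes, 50
random 14-point superposition problems, 30-row × 120-column MSAs, and
constellation targets under 15 residues. These sizes exercise every code
path — larger inputs change runtime, not logic.

## Known limitations

- Sequential alignment only; circular permutations and rewired topologies
  are invisible to `align_pair` and therefore to the half-identity metric
  on folds whose symmetry is not sequence-collinear.
- The H-bond model is the plain electrostatic one; no angular terms.
- One chain per analysis; inter-chain sheets are out of scope.
- Exact-type constellation matching; chemically conservative substitutions
  (Asp↔Glu) require configuring exchange sets.
- The NMR path reads the first model only.
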