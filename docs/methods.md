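# Methods

This note documents the models, conventions and numerical choices behind
capsidphylo, and what the synthetic validation does and does not show.

## Coordinate model and I/O

All computations operate on ordered single-chain Cα traces
(`CaStructure`): author residue numbers (1-based, insertion codes ordered
alphabetically after their number), one-letter amino-acid codes and one
Cα position per residue. PDB-format input is parsed with gemmi; only
ATOM records of the first model are honored, residues without a Cα are
dropped, and alternate locations keep the highest-occupancy altloc
(ties: lexicographically smallest altloc id). The temperature-factor
column is interpreted as per-residue confidence (pLDDT, 0–100) only when
the caller flags the file as a predicted model, so experimental B-factors
are never mistaken for confidences.

Residue-range strings ("34-275,332-609") denote inclusive intervals in
author numbering; sets of intervals are normalized (sorted, merged) and
support exact difference/intersection arithmetic, which is all that
modeled/unmodeled residue accounting needs.

## Superposition and correspondence

`kabsch_superpose` computes the least-squares rigid fit by SVD of the
3×3 covariance; a reflection in the raw optimum is suppressed by flipping
the sign of the smallest singular vector (chirality is biology, not a
free parameter). Correctness is cross-checked in the tests against an
independent quaternion eigenvalue oracle (largest eigenvalue of the 4×4
key matrix) to 1e-8 on random point sets.

`pair_align` establishes residue correspondence between two traces by the
usual iterative scheme:

1. two seeds — a global Needleman–Wunsch alignment of the amino-acid
   strings (BLOSUM62, gap open −10, extend −0.5) and the best gapless
   threading offset (every offset with ≥ 10 overlapping residues is
   scored by a rigid fit);
2. superpose on the current pairs; build the TM-style score matrix
   `S(i,j) = 1/(1+(d_ij/d0)²)` with `d0 = 5 Å`;
3. re-derive the correspondence by global affine-gap dynamic programming
   (Gotoh; gap open −1.0, extend −0.1 on the score scale; ties prefer
   match over gap, then gap-in-A over gap-in-B — alignments are
   deterministic);
4. iterate until the pair set repeats, at most 20 rounds; the
   best-scoring trajectory over both seeds wins.

All parameters are carried in `AlignParams` and configurable. Overall
RMSDs are reported by `core_rmsd`: iteratively refit and drop pairs
deviating more than `core_cutoff` (default 4.0 Å) until a fixed point.
Published per-protein core counts ("164 Cα" etc.) depend on the original
tools' undisclosed trimming rules, so exact core sizes are not expected
to match across programs; the deposition-based tests therefore check the
RMSD value at ±0.15 Å and report the achieved core size.

The N-terminal arm — conformationally variable and unreliable in
predicted models — is removed before distance calculations by
`trim_nterm_arm`; boundaries are per-structure user inputs, since no
universal residue number exists.

## Divergence profiles

Per-residue deviations are Euclidean Cα distances under the single global
superposition from `pair_align` — there is deliberately no per-window
refitting. Profiles from many homologs against one reference average
arithmetically per residue, with missing (unmatched) residues excluded
from the mean rather than zero-filled. The default window is 1 (plots
are per-residue); RMS windowing over ±(w−1)/2 is available. Region
summaries take means/maxima over present values only; region definitions
for the CsfrRNAV VP1 surface loops ship as an editable TOML config —
the loop boundaries are drawn from figures, not stated numerically, so
they are approximate working definitions.

## Phylogenies

**Structure side.** The all-vs-all matrix holds pairwise core RMSDs (Å)
of the trimmed traces, computed for i < j and mirrored. RMSD is fed to
neighbor joining unnormalized, matching the original analysis convention.
Note that RMSD need not satisfy the triangle inequality and nothing here
assumes it does.

**Sequence side.** A progressive multiple alignment (guide tree: NJ on
3-mer distances; profile–profile Gotoh with BLOSUM62, column scores
averaged over non-gap residue pairs) feeds p-distances (mismatches over
columns where neither row is gapped; Poisson correction −ln(1−p)
available behind a flag). Bootstrap supports resample columns with
replacement; support is the percentage of completed replicates whose NJ
tree contains each internal bipartition of the full-data tree (degenerate
replicates — a pair with no comparable columns — are skipped with a
warning and excluded from the denominator). The production default is
1000 replicates; tests and the analysis scripts use 100.

**NJ.** Standard Saitou–Nei with the Studier–Keppler criterion
`Q_ij = (n−2)d_ij − r_i − r_j`; ties on Q join the first pair in
label-sorted scan order (trees are reproducible); branch lengths by the
rate-corrected split formula; negative lengths clamped to zero with the
deficit moved to the sibling. Exactness — topology and branch lengths —
is verified on random additive matrices, and topology is cross-checked
against scikit-bio's independent NJ on noisy matrices. UPGMA is available
behind a flag for sensitivity analyses.

**Comparison.** Robinson–Foulds distance counts internal bipartitions
present in exactly one tree (cross-checked against dendropy). Host
monophyly asks, per host, whether its leaves are exactly one side of a
bipartition of the unrooted tree. The reported purity is the host
fraction of the smallest bipartition side containing every leaf of that
host — 1.0 exactly when monophyletic, and a graded measure of how much
foreign material the best enclosing clade carries otherwise.

## Synthetic families

The generator emulates a family of homologous capsid-protein chains with
hypervariable surface loops. Along a random unrooted binary tree
(sequential random attachment; branch lengths exponential, mean 0.1),
coordinates evolve by Cartesian Brownian motion: per edge of length t,
i.i.d. Gaussian displacement N(0, σ²·t·w_i) per coordinate, with
w_i = 4 inside three designated loop windows and 1 elsewhere. Each leaf
then receives a random rotation and translation, so superposition is
always load-bearing in downstream tests. Sequences evolve by a Poisson
process on the same tree (substitution probability 1−exp(−r·t) per site
per edge, uniform over the other 19 residues). Optional uniform
N-terminal deletions (off by default) exercise trimming and offset
handling. The base fold is an idealized helical trace (rise 1.5 Å,
radius 2.3 Å, 100°/residue) — topologically trivial, which is fine
because nothing downstream uses fold topology.

Default study conditions: 12 taxa, 250 residues, σ = 0.4 Å,
r = 0.3 subs/site, per-unit branch length.

**What passing tests show, and a known limitation.** The synthetic model
validates correspondence recovery, superposition, profile statistics and
tree construction end to end against known ground truth. It does not
produce physically realistic folds, side chains, internal indels, or
correlated structure/sequence noise beyond the shared tree. One
consequence of the Brownian model deserves emphasis: expected *squared*
deviation is additive along the tree (E[d²] = 3σ²·w̄·T), so RMSD grows as
√T and is *not* tree-additive. NJ applied to raw RMSDs — the convention
this pipeline follows — therefore distorts short internal edges, and
exponential branch lengths regularly produce internal edges carrying less
than one expected substitution across the whole chain. In consequence,
exact (RF-0) recovery of both trees holds robustly on trees with long,
homogeneous internal edges (verified in the tests) but only in a minority
of random exponential-length trees under the default conditions; the
acceptance report states the measured recovery fractions rather than an
aspirational one. Practitioners who want structural trees robust to this
effect should feed squared RMSDs to NJ; the package keeps raw RMSD as the
default to match the original analysis.

## Pipeline runs

`run_structure_phylogeny_pipeline` executes trim → all-vs-all → NJ
structure tree; MSA → p-distance → NJ + bootstrap sequence tree;
profiles against a designated reference; RF comparison and host reports —
writing every artifact plus a timestamped log and a JSON manifest with
all parameters and the seed. Outputs are deterministic for a fixed
config and seed (verified byte-for-byte in the tests). Stage failures
abort with the stage name and leave a FAILED marker beside partial
outputs.

## Problem sizes

Tests and analysis scripts run the full study conditions (12 × 250) for
the recovery checks and smaller families (4–8 taxa, 40–120 residues)
elsewhere; bootstrap uses 100 replicates. These sizes are the package's
own choices for routine validation; all of them scale up by argument.
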